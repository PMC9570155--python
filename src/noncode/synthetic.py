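"""Synthetic transcript generator.

Generates labeled coding-like and noncoding-like transcripts carrying the
statistical structure the classifier exploits, so every pipeline stage can
be exercised without downloading real data:

* **coding-like** — length drawn from a lognormal centred on a median of
  1029 nt (matching curated plant mRNA sets); one planted ORF (ATG, a run
  of stop-free codons drawn with configurable codon-usage bias, then a stop
  codon) covering ``orf_fraction_of_length`` of the transcript at a random
  offset; background nucleotides i.i.d. at the coding GC target.
* **noncoding-like** — length lognormal with median 321 nt (typical of
  plant ncRNA sets); i.i.d. nucleotides at the noncoding GC target with no
  constraint on stop codons.

Codon bias interpolates between uniform sense-codon usage (strength 0) and
a GC3-weighted preference (common in plant genomes); it is what gives the
3-mer frequencies class signal beyond the ORF itself.  Everything is
driven by a single seed: same config + same seed gives byte-identical
FASTA output.

An optional two-component length mixture emulates the long/small ncRNA
substructure (90% lncRNA-like, 10% sncRNA-like < 200 nt), off by default.

:func:`planted_feature_table` is a separate tabular generator used to test
the feature-selection and model stages in isolation: Gaussian noise on all
91 canonical features with a class-mean shift planted into a few of them.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .features import FEATURE_NAMES, FeatureTable
from .seqio import SequenceRecord, write_fasta

STOP_CODONS = ("TAA", "TAG", "TGA")
SENSE_CODONS = tuple(
    "".join(c) for c in product("ACGT", repeat=3) if "".join(c) not in STOP_CODONS
)


@dataclass
class SimulationConfig:
    """Study-condition parameters for the generator.

    Length medians default to the curated plant benchmark medians (1029 nt
    coding, 321 nt noncoding); sigmas are the lognormal shape of
    log-length.  ``orf_fraction_of_length`` is the fraction of a
    coding-like transcript occupied by its planted ORF.
    """

    n_coding: int = 100
    n_noncoding: int = 100
    coding_length_median: float = 1029.0
    coding_length_sigma: float = 0.55
    noncoding_length_median: float = 321.0
    noncoding_length_sigma: float = 0.70
    orf_fraction_of_length: float = 0.7
    gc_coding: float = 0.44
    gc_noncoding: float = 0.38
    codon_bias_strength: float = 1.0
    sncrna_mixture: bool = False  # 10% short (<200 nt) noncoding component
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_coding < 0 or self.n_noncoding < 0:
            raise ValidationError("class sizes must be >= 0")
        if self.coding_length_median <= 0 or self.noncoding_length_median <= 0:
            raise ValidationError("length medians must be > 0")
        if not 0 < self.orf_fraction_of_length <= 1:
            raise ValidationError("orf_fraction_of_length must be in (0, 1]")
        for gc in (self.gc_coding, self.gc_noncoding):
            if not 0 <= gc <= 1:
                raise ValidationError("GC targets must be in [0, 1]")
        if self.codon_bias_strength < 0:
            raise ValidationError("codon_bias_strength must be >= 0")


def _codon_weights(strength: float) -> np.ndarray:
    """Sense-codon sampling weights: exp(strength * z), z = +/-0.5 by GC3."""
    z = np.array([0.5 if c[2] in "GC" else -0.5 for c in SENSE_CODONS])
    w = np.exp(strength * z)
    return w / w.sum()


def _random_background(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(list("ACGT"), size=n, p=p)) if n else ""


def _planted_orf(rng: np.random.Generator, n_codons: int, strength: float) -> str:
    """ATG + (n_codons - 2) biased sense codons + one stop codon."""
    weights = _codon_weights(strength)
    body = rng.choice(len(SENSE_CODONS), size=max(n_codons - 2, 0), p=weights)
    stop = STOP_CODONS[rng.integers(0, len(STOP_CODONS))]
    return "ATG" + "".join(SENSE_CODONS[i] for i in body) + stop


def _lognormal_length(
    rng: np.random.Generator, median: float, sigma: float, minimum: int
) -> int:
    return max(int(round(rng.lognormal(mean=np.log(median), sigma=sigma))), minimum)


def simulate_transcripts(
    config: SimulationConfig,
) -> tuple[list[SequenceRecord], np.ndarray]:
    """Generate labeled records: returns (records, labels) with ncRNA = 1.

    Coding-like records come first (label 0), then noncoding-like (label
    1); downstream consumers shuffle via CV fold assignment, so generation
    order carries no information.
    """
    rng = np.random.default_rng(config.seed)
    records: list[SequenceRecord] = []
    labels: list[int] = []
    for i in range(config.n_coding):
        length = _lognormal_length(
            rng, config.coding_length_median, config.coding_length_sigma, minimum=60
        )
        n_codons = max(int(length * config.orf_fraction_of_length) // 3, 2)
        orf = _planted_orf(rng, n_codons, config.codon_bias_strength)
        if len(orf) > length:
            raise ValidationError(
                f"planted ORF ({len(orf)} nt) longer than transcript ({length} nt)"
            )
        offset = int(rng.integers(0, length - len(orf) + 1))
        seq = (
            _random_background(rng, offset, config.gc_coding)
            + orf
            + _random_background(rng, length - offset - len(orf), config.gc_coding)
        )
        records.append(
            SequenceRecord(id=f"coding_{i:05d}", seq=seq, original_length=len(seq))
        )
        labels.append(0)
    for i in range(config.n_noncoding):
        if config.sncrna_mixture and rng.random() < 0.1:
            length = max(int(rng.integers(30, 200)), 21)
        else:
            length = _lognormal_length(
                rng,
                config.noncoding_length_median,
                config.noncoding_length_sigma,
                minimum=21,
            )
        seq = _random_background(rng, length, config.gc_noncoding)
        records.append(
            SequenceRecord(id=f"ncrna_{i:05d}", seq=seq, original_length=len(seq))
        )
        labels.append(1)
    return records, np.asarray(labels, dtype=int)


def write_simulation(
    records: list[SequenceRecord],
    labels: np.ndarray,
    fasta_path: str | Path,
    labels_path: str | Path,
) -> None:
    """Write the simulated set as FASTA + a two-column label TSV."""
    if len(records) != len(labels):
        raise ValidationError("records and labels differ in length")
    write_fasta(records, fasta_path)
    pd.DataFrame(
        {"id": [r.id for r in records], "label": labels}
    ).to_csv(labels_path, sep="\t", index=False)


def planted_feature_table(
    n: int = 400,
    informative: tuple[str, ...] = ("gc_content", "score", "cds_size"),
    shift: float = 2.0,
    seed: int = 0,
) -> FeatureTable:
    """Tabular test-bed: N(0,1) noise on all 91 features, a class-mean
    shift of ``shift`` standard deviations planted into ``informative``.

    Balanced classes (n//2 each, label 1 shifted).  Values deliberately do
    not respect the frequency-sum invariants — this table tests ranking
    and model code, not feature extraction.
    """
    unknown = [f for f in informative if f not in FEATURE_NAMES]
    if unknown:
        raise ValidationError(f"unknown feature name(s): {unknown}")
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, len(FEATURE_NAMES)))
    y = np.zeros(n, dtype=int)
    y[n // 2 :] = 1
    cols = {name: i for i, name in enumerate(FEATURE_NAMES)}
    for name in informative:
        X[y == 1, cols[name]] += shift
    ids = pd.Index([f"row_{i:05d}" for i in range(n)], name="id")
    data = pd.DataFrame(X, index=ids, columns=list(FEATURE_NAMES))
    return FeatureTable(data=data, labels=pd.Series(y, index=ids))
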