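"""The canonical 91-feature representation of a transcript.

Per transcript the feature vector holds, in this fixed order:

* 84 k-mer frequencies for k = 1, 2, 3 (4 + 16 + 64 entries, each k-block
  in lexicographic A < C < G < T order);
* the five CDS features ``score``, ``cds_start``, ``cds_stop``, ``cds_size``,
  ``cds_percent``;
* ``length`` (total nucleotide count);
* ``gc_content`` ((C+G) / (A+C+G+T)).

k-mer frequencies are computed over sliding windows; windows containing an
N are excluded from both numerator and denominator so ambiguity codes do
not deflate the frequencies of real k-mers.  With no valid window the whole
k-block is zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cds import CdsPrediction, predict_cds
from .errors import ValidationError
from .seqio import SequenceRecord

_BASES = "ACGT"

CDS_FEATURE_NAMES = ("score", "cds_start", "cds_stop", "cds_size", "cds_percent")


def kmer_names(k: int) -> list[str]:
    """All 4^k k-mers over {A,C,G,T} in lexicographic order."""
    return ["".join(p) for p in product(_BASES, repeat=k)]


#: Canonical 91-entry feature-name order shared by every table in the package.
FEATURE_NAMES: tuple[str, ...] = tuple(
    kmer_names(1) + kmer_names(2) + kmer_names(3)
) + CDS_FEATURE_NAMES + ("length", "gc_content")

N_FEATURES = len(FEATURE_NAMES)  # 91
N_KMER_FEATURES = 4 + 16 + 64  # 84

_KMER_INDEX = {k: {name: i for i, name in enumerate(kmer_names(k))} for k in (1, 2, 3)}


def kmer_frequencies(record: SequenceRecord, k: int) -> np.ndarray:
    """Sliding-window k-mer frequencies (length 4^k, sums to 1 or all zero).

    A window counts only if all of its k characters are A/C/G/T; the
    denominator is the number of such valid windows.
    """
    if k not in (1, 2, 3):
        raise ValueError(f"k must be 1, 2 or 3, got {k}")
    index = _KMER_INDEX[k]
    counts = np.zeros(4**k, dtype=np.float64)
    seq = record.seq
    valid = 0
    for i in range(len(seq) - k + 1):
        window = seq[i : i + k]
        idx = index.get(window)
        if idx is not None:
            counts[idx] += 1
            valid += 1
    if valid == 0:
        return counts
    return counts / valid


def gc_content(record: SequenceRecord) -> float:
    """(C + G) / (A + C + G + T); 0.0 for an all-N sequence."""
    seq = record.seq
    acgt = sum(seq.count(b) for b in _BASES)
    if acgt == 0:
        return 0.0
    return (seq.count("C") + seq.count("G")) / acgt


def feature_vector(
    record: SequenceRecord,
    cds: CdsPrediction | None = None,
    percent_mode: str = "size",
) -> np.ndarray:
    """One canonical 91-entry feature row for a transcript."""
    if cds is None:
        cds = predict_cds(record, percent_mode=percent_mode)
    parts = [kmer_frequencies(record, k) for k in (1, 2, 3)]
    tail = np.array(
        [
            cds.score,
            cds.cds_start,
            cds.cds_stop,
            cds.cds_size,
            cds.cds_percent,
            record.original_length,
            gc_content(record),
        ],
        dtype=np.float64,
    )
    return np.concatenate(parts + [tail])


@dataclass
class FeatureTable:
    """A labeled (or unlabeled) matrix of canonical feature vectors.

    ``data`` is a DataFrame indexed by transcript id with exactly the 91
    canonical columns; ``labels`` is an optional parallel Series with
    ncRNA = 1 and coding = 0 for every row, or None.
    """

    data: pd.DataFrame
    labels: pd.Series | None = None

    def __post_init__(self) -> None:
        if tuple(self.data.columns) != FEATURE_NAMES:
            raise ValidationError(
                "feature table columns do not match the canonical 91-name order"
            )
        if self.labels is not None:
            if not self.data.index.equals(self.labels.index):
                raise ValidationError("labels index does not match feature rows")
            bad = set(self.labels.unique()) - {0, 1}
            if bad:
                raise ValidationError(f"labels must be 0/1, found {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def is_labeled(self) -> bool:
        return self.labels is not None

    def require_labels(self) -> pd.Series:
        if self.labels is None:
            raise ValidationError("operation requires a labeled feature table")
        return self.labels

    def matrix(self, subset: Sequence[str] | None = None) -> np.ndarray:
        """Feature matrix restricted to ``subset`` (canonical order check)."""
        if subset is None:
            return self.data.to_numpy(dtype=np.float64)
        missing = [name for name in subset if name not in self.data.columns]
        if missing:
            raise ValidationError(f"missing feature column(s): {missing}")
        return self.data.loc[:, list(subset)].to_numpy(dtype=np.float64)

    def to_tsv(self, path: str | Path) -> None:
        df = self.data.copy()
        if self.labels is not None:
            df.insert(0, "label", self.labels)
        df.index.name = "id"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FeatureTable":
        df = pd.read_csv(path, sep="\t", index_col="id")
        labels = None
        if "label" in df.columns:
            labels = df.pop("label").astype(int)
        return cls(data=df.loc[:, list(FEATURE_NAMES)], labels=labels)


def extract_features(
    records: Sequence[SequenceRecord],
    cds_source: Mapping[str, CdsPrediction] | None = None,
    labels: Mapping[str, int] | pd.Series | None = None,
    percent_mode: str = "size",
) -> FeatureTable:
    """Build the 91-column :class:`FeatureTable` for a set of transcripts.

    ``cds_source`` = None runs the internal ORF scorer; otherwise it must
    map every record id to an imported :class:`CdsPrediction` (a missing id
    is an error naming the transcript).
    """
    rows = np.empty((len(records), N_FEATURES), dtype=np.float64)
    ids = []
    for i, rec in enumerate(records):
        if cds_source is None:
            cds = None
        else:
            if rec.id not in cds_source:
                raise ValidationError(
                    f"no imported CDS prediction for transcript {rec.id!r}"
                )
            cds = cds_source[rec.id]
        rows[i] = feature_vector(rec, cds=cds, percent_mode=percent_mode)
        ids.append(rec.id)
    data = pd.DataFrame(rows, index=pd.Index(ids, name="id"), columns=list(FEATURE_NAMES))
    label_series = None
    if labels is not None:
        if isinstance(labels, pd.Series):
            label_series = labels.reindex(data.index)
            if label_series.isna().any():
                missing = list(label_series[label_series.isna()].index[:5])
                raise ValidationError(f"missing label(s) for id(s): {missing}")
            label_series = label_series.astype(int)
        else:
            try:
                label_series = pd.Series(
                    [labels[i] for i in ids], index=data.index, dtype=int
                )
            except KeyError as exc:
                raise ValidationError(f"missing label for id {exc.args[0]!r}") from exc
    return FeatureTable(data=data, labels=label_series)
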