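"""Transcript sequence I/O.

Reads FASTA transcript sets into validated :class:`SequenceRecord` objects
and writes prediction tables.  Normalization makes RNA and DNA input
equivalent (U -> T) and maps any residual IUPAC ambiguity code to N, so that
downstream feature extraction only ever sees the {A, C, G, T, N} alphabet.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO as _BioSeqIO

from .errors import ValidationError

logger = logging.getLogger(__name__)

#: Alphabet after normalization.
ALPHABET = frozenset("ACGTN")

_NORMALIZE = str.maketrans("U", "T")

#: Probability-threshold convention: a transcript is called ncRNA when
#: prob_ncRNA >= 0.5, i.e. ties go to the positive (ncRNA) class.  The tool is
#: meant to be sensitive for the rarer noncoding class, so borderline calls
#: fall on the noncoding side.
NCRNA_LABEL = "ncRNA"
CODING_LABEL = "coding"


@dataclass(frozen=True)
class SequenceRecord:
    """One transcript: identifier plus normalized nucleotide string.

    ``seq`` is uppercase over {A,C,G,T,N}; ``original_length`` equals
    ``len(seq)`` and is kept as an explicit field because total sequence
    length is itself one of the classifier's features.
    """

    id: str
    seq: str
    original_length: int

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("sequence record must have a non-empty id")
        if self.original_length != len(self.seq):
            raise ValidationError(
                f"record {self.id!r}: original_length {self.original_length} "
                f"!= sequence length {len(self.seq)}"
            )
        if self.original_length < 1:
            raise ValidationError(f"record {self.id!r} has an empty sequence")
        bad = set(self.seq) - ALPHABET
        if bad:
            raise ValidationError(
                f"record {self.id!r} contains non-normalized characters: "
                f"{sorted(bad)}"
            )


def normalize_sequence(raw: str, record_id: str = "?") -> str:
    """Uppercase, map U->T, and replace anything outside ACGTUN with N.

    A single warning is logged per record that contained replaced
    characters; sequence databases routinely carry IUPAC ambiguity codes
    (R, Y, S, W, ...) and aborting on them would reject real inputs.
    """
    seq = raw.upper().translate(_NORMALIZE)
    cleaned = []
    n_replaced = 0
    for ch in seq:
        if ch in ALPHABET:
            cleaned.append(ch)
        else:
            cleaned.append("N")
            n_replaced += 1
    if n_replaced:
        logger.warning(
            "record %s: replaced %d non-ACGTUN character(s) with N",
            record_id,
            n_replaced,
        )
    return "".join(cleaned)


def make_record(record_id: str, raw_seq: str) -> SequenceRecord:
    """Build a validated, normalized :class:`SequenceRecord`."""
    if len(raw_seq) == 0:
        raise ValidationError(f"record {record_id!r} has an empty sequence")
    seq = normalize_sequence(raw_seq, record_id)
    return SequenceRecord(id=record_id, seq=seq, original_length=len(seq))


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into normalized records, preserving file order.

    Raises ``FileNotFoundError`` for a missing file and
    :class:`ValidationError` (naming the offending id) for an entry with an
    empty sequence or a duplicated identifier.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for entry in _BioSeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise ValidationError(f"duplicate record id {entry.id!r} in {path}")
        seen.add(entry.id)
        records.append(make_record(entry.id, str(entry.seq)))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write normalized records back out as FASTA (one line per sequence)."""
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.seq}\n")


PREDICTION_HEADER = ("id", "length", "predicted_class", "prob_ncRNA")


def write_predictions(
    records: Sequence[SequenceRecord],
    probs_ncrna: Sequence[float],
    path: str | Path,
    threshold: float = 0.5,
) -> None:
    """Write the prediction TSV: id, length, predicted_class, prob_ncRNA.

    ``predicted_class`` is ncRNA when ``prob >= threshold`` (ties to the
    positive class).  Raises :class:`ValidationError` on a length mismatch
    between records and probabilities.
    """
    if len(records) != len(probs_ncrna):
        raise ValidationError(
            f"{len(records)} records but {len(probs_ncrna)} probabilities"
        )
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(PREDICTION_HEADER) + "\n")
        for rec, p in zip(records, probs_ncrna):
            p = float(p)
            if not 0.0 <= p <= 1.0:
                raise ValidationError(
                    f"record {rec.id!r}: probability {p} outside [0, 1]"
                )
            label = NCRNA_LABEL if p >= threshold else CODING_LABEL
            fh.write(f"{rec.id}\t{rec.original_length}\t{label}\t{p:.6f}\n")
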