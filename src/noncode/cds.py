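"""ORF detection and CDS feature computation.

Five of the classifier's features describe the best predicted coding region
of a transcript: a protein-likeness ``score`` plus ``cds_start``,
``cds_stop``, ``cds_size`` and ``cds_percent``.  Two sources are supported:

* :func:`predict_cds` — an internal, deterministic ORF scorer.  It scans the
  forward strand in all three frames for ATG-initiated open reading frames
  and scores each candidate as

      score = w_len * cds_size + w_kozak * [A/G at -3] + w_stop * [in-frame stop]

  so that ORF length dominates, with small bonuses for a Kozak-like context
  and for having a proper stop codon.  Coordinates are 0-based, half-open,
  which makes ``cds_size == cds_stop - cds_start`` exact.

* :func:`import_txcdspredict` — an importer for native UCSC txCdsPredict
  output, for users who want that program's exact scores.

Transcripts (not genomic DNA) are the expected input, so only the forward
strand is considered.  ORFs truncated at the 3' end (no stop codon before
the end of the transcript) are allowed, since transcript databases contain
many partial sequences; such ORFs end at the last complete in-frame codon.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

from .errors import ValidationError
from .seqio import SequenceRecord

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
START_CODON = "ATG"

# Score weights: length dominates; context/stop bonuses only break near-ties
# between similar-length ORFs.
W_LEN = 1.0
W_KOZAK = 50.0
W_STOP = 50.0


@dataclass(frozen=True)
class CdsPrediction:
    """Best coding-region call for one transcript.

    ``score`` is a protein-likeness score (larger = more protein-like;
    for the native txCdsPredict scale, values above ~800 usually indicate a
    protein).  ``cds_start``/``cds_stop`` are 0-based half-open nucleotide
    coordinates into the transcript; ``cds_percent`` is the fraction of the
    transcript covered by the CDS.  The no-ORF prediction is all zeros.
    """

    score: float
    cds_start: int
    cds_stop: int
    cds_size: int
    cds_percent: float

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValidationError(f"negative CDS score: {self.score}")
        if not 0 <= self.cds_start <= self.cds_stop:
            raise ValidationError(
                f"invalid CDS coordinates: start={self.cds_start}, "
                f"stop={self.cds_stop}"
            )
        if self.cds_size != self.cds_stop - self.cds_start:
            raise ValidationError(
                f"cds_size {self.cds_size} != cds_stop - cds_start "
                f"({self.cds_stop - self.cds_start})"
            )
        if not 0.0 <= self.cds_percent <= 1.0:
            raise ValidationError(f"cds_percent {self.cds_percent} outside [0, 1]")


NO_ORF = CdsPrediction(score=0.0, cds_start=0, cds_stop=0, cds_size=0, cds_percent=0.0)


def _candidate_orfs(seq: str) -> list[tuple[int, int, bool]]:
    """All ATG-initiated forward-strand ORFs as (start, stop, has_stop).

    ``stop`` is half-open and includes the stop codon when one exists;
    otherwise the ORF runs to the last complete in-frame codon.  A codon
    containing N never counts as a start or stop.
    """
    n = len(seq)
    # in-frame stop codon positions per frame, ascending
    stops_by_frame: dict[int, list[int]] = {0: [], 1: [], 2: []}
    starts: list[int] = []
    for i in range(n - 2):
        codon = seq[i : i + 3]
        if codon == START_CODON:
            starts.append(i)
        elif codon in STOP_CODONS:
            stops_by_frame[i % 3].append(i)
    orfs: list[tuple[int, int, bool]] = []
    for s in starts:
        frame_stops = stops_by_frame[s % 3]
        j = bisect_left(frame_stops, s + 3)
        if j < len(frame_stops):
            stop_pos = frame_stops[j]
            orfs.append((s, stop_pos + 3, True))
        else:
            # open 3' end: last complete in-frame codon boundary
            end = s + 3 * ((n - s) // 3)
            orfs.append((s, end, False))
    return orfs


def _score_orf(seq: str, start: int, stop: int, has_stop: bool) -> float:
    score = W_LEN * (stop - start)
    if start >= 3 and seq[start - 3] in "AG":
        score += W_KOZAK
    if has_stop:
        score += W_STOP
    return score


def predict_cds(
    record: SequenceRecord, percent_mode: str = "size"
) -> CdsPrediction:
    """Best-scoring ORF of a transcript as a :class:`CdsPrediction`.

    Deterministic: among all candidates the highest score wins, ties broken
    by smaller start, then lower frame index.  ``percent_mode`` selects the
    coverage definition: ``"size"`` (default) is cds_size / length;
    ``"start_stop_sum"`` is (cds_start + cds_stop) / length, an alternative
    convention found in some feature tables.
    """
    if percent_mode not in ("size", "start_stop_sum"):
        raise ValueError(f"unknown percent_mode: {percent_mode!r}")
    orfs = _candidate_orfs(record.seq)
    if not orfs:
        return NO_ORF
    best = max(
        orfs,
        key=lambda o: (_score_orf(record.seq, *o), -o[0], -(o[0] % 3)),
    )
    start, stop, has_stop = best
    size = stop - start
    length = record.original_length
    if percent_mode == "size":
        percent = size / length
    else:
        percent = min((start + stop) / length, 1.0)
    return CdsPrediction(
        score=_score_orf(record.seq, start, stop, has_stop),
        cds_start=start,
        cds_stop=stop,
        cds_size=size,
        cds_percent=percent,
    )


def import_txcdspredict(
    path: str | Path,
    lengths: Mapping[str, int],
    percent_mode: str = "size",
) -> dict[str, CdsPrediction]:
    """Parse native txCdsPredict tab-separated output.

    Expects at least four columns per row: name, start, end, score (extra
    columns are ignored).  ``cds_size`` and ``cds_percent`` are recomputed
    from start/end and the supplied transcript lengths, so the importer is
    consistent with the internal scorer's conventions.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"txCdsPredict file not found: {path}")
    out: dict[str, CdsPrediction] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValidationError(
                    f"{path}:{lineno}: expected >= 4 tab-separated columns, "
                    f"got {len(fields)}"
                )
            name = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
                score = float(fields[3])
            except ValueError as exc:
                raise ValidationError(f"{path}:{lineno}: malformed row: {exc}") from exc
            if name not in lengths:
                raise ValidationError(
                    f"{path}:{lineno}: no transcript length known for id {name!r}"
                )
            length = lengths[name]
            if end < start:
                raise ValidationError(
                    f"{path}:{lineno}: end {end} < start {start} for {name!r}"
                )
            if end > length:
                raise ValidationError(
                    f"{path}:{lineno}: end {end} exceeds transcript length "
                    f"{length} for {name!r}"
                )
            size = end - start
            if percent_mode == "size":
                percent = size / length if length else 0.0
            else:
                percent = min((start + end) / length, 1.0) if length else 0.0
            out[name] = CdsPrediction(
                score=max(score, 0.0),
                cds_start=start,
                cds_stop=end,
                cds_size=size,
                cds_percent=percent,
            )
    return out
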