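"""Assembly-level summary statistics and expression-weighted N50 curves.

The N50 of an assembly is the length L such that transcripts of length >= L,
taken from the longest down, contain at least half of the assembled bases.
The ExN50 curve generalizes this: for each x in 1..100, restrict to the
minimal set of most highly expressed transcripts that accounts for x% of the
total TPM mass (the "Ex subset") and report the N50 of that subset. The
curve typically peaks well below x = 100 in a de novo assembly, because the
lowly expressed tail is dominated by short fragmentary contigs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import ValidationError
from .io_formats import ExpressionRecord, TranscriptRecord


@dataclass(frozen=True, slots=True)
class AssemblySummary:
    """Whole-assembly length and composition statistics."""

    n_transcripts: int
    total_bases: int
    gc_percent: float
    median_length: float
    mean_length: float
    n50: int


@dataclass(frozen=True, slots=True)
class ExN50Point:
    """One point of the ExN50 curve.

    ``subset_size`` is the number of transcripts in the Ex subset and
    ``min_tpm`` the smallest TPM inside it; both are monotone in x.
    """

    x: int
    exn50_length: int
    subset_size: int
    min_tpm: float


def n50(lengths: Sequence[int]) -> int:
    """N50 of a set of contig lengths.

    Sort descending and return the length at which the cumulative sum first
    reaches half of the total. Always one of the observed lengths.
    """
    if len(lengths) == 0:
        raise ValidationError("n50 of an empty length set is undefined")
    arr = np.asarray(lengths, dtype=np.int64)
    if (arr <= 0).any():
        raise ValidationError("all lengths must be positive")
    arr = np.sort(arr)[::-1]
    csum = np.cumsum(arr)
    idx = int(np.searchsorted(csum, csum[-1] / 2.0, side="left"))
    return int(arr[idx])


def summarize_assembly(transcripts: Sequence[TranscriptRecord]) -> AssemblySummary:
    """Length, GC and N50 summary of an assembly.

    GC% is pooled over all sequences and computed over unambiguous bases
    only: 100 * (G+C) / (A+C+G+T). Median of an even-sized length set is the
    midpoint of the two central values.
    """
    if len(transcripts) == 0:
        raise ValidationError("cannot summarize an empty assembly")
    lengths = np.array([len(t) for t in transcripts], dtype=np.int64)
    gc = at = 0
    for t in transcripts:
        s = t.sequence
        gc += s.count("G") + s.count("C")
        at += s.count("A") + s.count("T")
    denom = gc + at
    gc_percent = 100.0 * gc / denom if denom else 0.0
    total = int(lengths.sum())
    return AssemblySummary(
        n_transcripts=len(transcripts),
        total_bases=total,
        gc_percent=gc_percent,
        median_length=float(np.median(lengths)),
        mean_length=total / len(transcripts),
        n50=n50(lengths),
    )


def exn50_curve(
    transcripts: Iterable[TranscriptRecord | tuple[str, int]],
    expression: Sequence[ExpressionRecord],
    xs: Sequence[int] | None = None,
) -> list[ExN50Point]:
    """Expression-weighted N50 curve over x = 1..100 (percent of TPM mass).

    Transcripts may be records or plain ``(id, length)`` pairs. Transcripts
    without an expression value get TPM 0 with a warning. Transcripts are
    ranked by TPM descending (ties: length descending, then id ascending);
    the Ex subset for a given x is the shortest prefix of that ranking whose
    cumulative TPM reaches x% of the total. A zero total TPM leaves the
    curve undefined and is an error.
    """
    if xs is None:
        xs = range(1, 101)
    pairs = [
        (t.id, len(t)) if isinstance(t, TranscriptRecord) else (str(t[0]), int(t[1]))
        for t in transcripts
    ]
    if not pairs:
        raise ValidationError("no transcripts given")
    for x in xs:
        if not 1 <= x <= 100:
            raise ValidationError(f"x must be in 1..100, got {x}")
    tpm_by_id = {e.transcript_id: e.tpm for e in expression}
    missing = [tid for tid, _ in pairs if tid not in tpm_by_id]
    if missing:
        warnings.warn(
            f"{len(missing)} transcript(s) lack expression values; "
            "treated as TPM 0 (e.g. " + ", ".join(missing[:3]) + ")",
            stacklevel=2,
        )
    rows = sorted(
        ((tpm_by_id.get(tid, 0.0), length, tid) for tid, length in pairs),
        key=lambda r: (-r[0], -r[1], r[2]),
    )
    tpms = np.array([r[0] for r in rows], dtype=float)
    lengths = np.array([r[1] for r in rows], dtype=np.int64)
    total_tpm = float(tpms.sum())
    if total_tpm <= 0:
        raise ValidationError("total TPM is zero: ExN50 curve is undefined")
    ctpm = np.cumsum(tpms)
    points = []
    for x in xs:
        target = total_tpm * (x / 100.0)
        k = int(np.searchsorted(ctpm, target, side="left"))
        k = min(k, len(rows) - 1)  # guard float round-off at x = 100
        subset_lengths = lengths[: k + 1]
        points.append(
            ExN50Point(
                x=int(x),
                exn50_length=n50(subset_lengths),
                subset_size=k + 1,
                min_tpm=float(tpms[k]),
            )
        )
    return points


def count_above_tpm(
    expression: Sequence[ExpressionRecord], threshold: float
) -> int:
    """Number of transcripts with TPM >= threshold (inclusive keep)."""
    if threshold < 0:
        raise ValidationError(f"threshold must be non-negative, got {threshold}")
    return sum(1 for e in expression if e.tpm >= threshold)
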