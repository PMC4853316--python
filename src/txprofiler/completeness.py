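"""Full-length transcript assessment from homology hits.

A de novo assembly has no reference to compare against, so completeness is
judged by homology: each transcript's best hit against a curated protein
database is taken, and the fraction of the homolog (subject) covered by the
alignment is used as a proxy for the transcript being full length. Coverage
fractions are then binned (10% bins by default) with a cumulative count
running from the full-length bin downward.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .errors import ValidationError
from .io_formats import AlignmentHit

DEFAULT_EVALUE_CUTOFF = 1e-20


@dataclass(frozen=True, slots=True)
class CoverageBin:
    """One histogram bin over subject-coverage percent.

    Bins are half-open ``(lower, upper]`` (an exact 0 goes to the lowest
    bin); ``cumulative`` counts transcripts with coverage above this bin's
    lower bound, i.e. the suffix sum of counts from the top bin down.
    """

    lower: float
    upper: float
    count: int
    cumulative: int


def best_hit_per_query(
    hits: Sequence[AlignmentHit], evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF
) -> dict[str, AlignmentHit]:
    """Keep, per query, the single best hit at or under the e-value cutoff.

    Best = maximal bitscore; ties broken by minimal e-value, then by first
    occurrence in the input. Queries whose every hit fails the cutoff are
    absent from the result.
    """
    best: dict[str, AlignmentHit] = {}
    for hit in hits:
        if hit.evalue > evalue_cutoff:
            continue
        cur = best.get(hit.query_id)
        if (
            cur is None
            or hit.bitscore > cur.bitscore
            or (hit.bitscore == cur.bitscore and hit.evalue < cur.evalue)
        ):
            best[hit.query_id] = hit
    return best


def subject_coverage(hit: AlignmentHit) -> float:
    """Fraction of the subject's length spanned by the aligned interval.

    Uses the subject-coordinate span ``|s_end - s_start| + 1`` (1-based
    inclusive; orientation-insensitive), not the alignment-length column,
    which counts gap columns and can exceed the subject span. Clamped to 1.
    """
    span = abs(hit.s_end - hit.s_start) + 1
    return min(span / hit.subject_length, 1.0)


def bin_coverage(
    coverages: Sequence[float], bin_width: int = 10
) -> list[CoverageBin]:
    """Histogram coverage fractions into percent bins with cumulative counts.

    A value v lands in the bin with ``lower < 100*v <= upper``; exact zeros
    go to the lowest bin. Cumulative counts run from the 100% bin downward,
    so the lowest bin's cumulative equals the total.
    """
    if bin_width <= 0 or 100 % bin_width != 0:
        raise ValidationError(
            f"bin width must be a positive divisor of 100, got {bin_width}"
        )
    n_bins = 100 // bin_width
    counts = [0] * n_bins
    for v in coverages:
        if not 0.0 <= v <= 1.0:
            raise ValidationError(f"coverage fraction {v} outside [0, 1]")
        pct = 100.0 * v
        if pct <= bin_width:  # includes exact 0
            idx = 0
        else:
            # smallest idx with pct <= (idx+1)*bin_width
            idx = int(-(-pct // bin_width)) - 1
            idx = min(idx, n_bins - 1)
        counts[idx] += 1
    bins = []
    suffix = 0
    cumulative = [0] * n_bins
    for i in range(n_bins - 1, -1, -1):
        suffix += counts[i]
        cumulative[i] = suffix
    for i in range(n_bins):
        bins.append(
            CoverageBin(
                lower=float(i * bin_width),
                upper=float((i + 1) * bin_width),
                count=counts[i],
                cumulative=cumulative[i],
            )
        )
    return bins


def coverage_bins_from_hits(
    hits: Sequence[AlignmentHit],
    evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF,
    bin_width: int = 10,
) -> tuple[Mapping[str, AlignmentHit], list[CoverageBin]]:
    """Best-hit selection, coverage computation and binning in one step."""
    best = best_hit_per_query(hits, evalue_cutoff=evalue_cutoff)
    bins = bin_coverage(
        [subject_coverage(h) for h in best.values()], bin_width=bin_width
    )
    return best, bins
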