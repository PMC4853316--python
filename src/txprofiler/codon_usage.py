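"""Codon counting and relative synonymous codon usage (RSCU).

RSCU of codon j within the synonymous family of amino acid i is

    RSCU_ij = x_ij / ((1/n_i) * sum_j x_ij)

where x_ij is the observed count of codon j and n_i the number of
synonymous codons for amino acid i. RSCU = 1 means the codon is used
exactly as often as expected under uniform synonymous usage; the values of
a family always sum to n_i. The per-amino-acid range (max - min) and
standard deviation of RSCU summarize how biased a species' usage is: an
expression host with small ranges (such as lepidopteran cell lines)
tolerates heterologous coding sequences without codon optimization, while a
host with a large range (e.g. E. coli) punishes rare codons.

Counting walks each CDS 5'->3' in non-overlapping triplets from position 1,
assuming the sequence is in frame; short sequences (< 100 codons by
default) are excluded, and triplets containing ambiguity characters are
skipped rather than failing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .errors import ValidationError
from .genetics import (
    AA_TO_CODONS,
    ALL_CODONS,
    AMINO_ACIDS,
    CODON_TO_AA,
)
from .io_formats import TranscriptRecord

DEFAULT_MIN_CDS_LEN = 300  # nt; = 100 codons


@dataclass(frozen=True, slots=True)
class CodonCountTable:
    """Raw codon counts for one sample (all 64 codons, zero-filled)."""

    sample_id: str
    counts: Mapping[str, int]
    n_sequences_used: int
    n_sequences_filtered: int
    n_triplets_skipped: int = 0

    def total_codons(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True, slots=True)
class RSCUTable:
    """RSCU per codon for one sample; families never observed are missing."""

    sample_id: str
    rscu: Mapping[str, float | None]
    counts: Mapping[str, int]


@dataclass(frozen=True, slots=True)
class AminoAcidBiasStats:
    """Bias summary for one amino acid's synonymous family."""

    amino_acid: str
    rscu_min: float
    rscu_max: float
    rscu_range: float
    rscu_sd: float
    min_codon: str
    max_codon: str


def count_codons(
    cds: Sequence[TranscriptRecord],
    min_len: int = DEFAULT_MIN_CDS_LEN,
    sample_id: str = "sample",
) -> CodonCountTable:
    """Count codons over a CDS set, excluding sequences shorter than min_len.

    Sequences are walked in-frame from position 1 in non-overlapping
    triplets; a trailing 1-2 nt remainder is dropped, and any triplet with a
    character outside {A,C,G,T} is skipped (counted in n_triplets_skipped).
    """
    counts = dict.fromkeys(ALL_CODONS, 0)
    used = filtered = skipped = 0
    for rec in cds:
        if len(rec) < min_len:
            filtered += 1
            continue
        used += 1
        seq = rec.sequence
        for i in range(0, len(seq) - len(seq) % 3, 3):
            codon = seq[i : i + 3]
            if codon in counts:
                counts[codon] += 1
            else:
                skipped += 1
    if used == 0:
        raise ValidationError(
            f"no CDS of length >= {min_len} nt; lower min_len or check input"
        )
    return CodonCountTable(
        sample_id=sample_id,
        counts=counts,
        n_sequences_used=used,
        n_sequences_filtered=filtered,
        n_triplets_skipped=skipped,
    )


def rscu(counts: CodonCountTable, include_stop: bool = False) -> RSCUTable:
    """Relative synonymous codon usage from a codon-count table.

    Stop codons are excluded by default (codon-usage comparisons are over
    the 20 amino acids); ``include_stop`` treats the three stop codons as
    one more synonymous family. An amino acid with zero total count yields
    missing (None) RSCU for all its codons — the formula is 0/0 there.
    """
    families = list(AMINO_ACIDS) + (["*"] if include_stop else [])
    values: dict[str, float | None] = {}
    for aa in families:
        codons = AA_TO_CODONS[aa]
        total = sum(counts.counts[c] for c in codons)
        if total == 0:
            for c in codons:
                values[c] = None
            continue
        n_i = len(codons)
        for c in codons:
            values[c] = counts.counts[c] * n_i / total
    return RSCUTable(sample_id=counts.sample_id, rscu=values, counts=dict(counts.counts))


def bias_stats(table: RSCUTable) -> list[AminoAcidBiasStats]:
    """Per-amino-acid RSCU range, extremes and population SD.

    Amino acids with entirely missing RSCU are omitted. The SD divides by
    the family size n_i (population form). Tied extremes resolve to the
    lexicographically smallest codon.
    """
    out = []
    for aa in sorted({CODON_TO_AA[c] for c in table.rscu}):
        codons = [c for c in AA_TO_CODONS[aa] if c in table.rscu]
        vals = [table.rscu[c] for c in codons]
        if any(v is None for v in vals):
            continue
        mean = sum(vals) / len(vals)
        sd = math.sqrt(sum((v - mean) ** 2 for v in vals) / len(vals))
        vmin, vmax = min(vals), max(vals)
        out.append(
            AminoAcidBiasStats(
                amino_acid=aa,
                rscu_min=vmin,
                rscu_max=vmax,
                rscu_range=vmax - vmin,
                rscu_sd=sd,
                min_codon=next(c for c in codons if table.rscu[c] == vmin),
                max_codon=next(c for c in codons if table.rscu[c] == vmax),
            )
        )
    return out


@dataclass(frozen=True, slots=True)
class CodonComparison:
    """Cross-sample RSCU comparison matrices.

    ``rscu_wide``: codon x sample matrix with an amino_acid column;
    ``rscu_long``: tidy (sample, codon, amino_acid, count, rscu) rows;
    ``range_wide`` / ``sd_wide``: amino acid x sample bias summaries.
    """

    rscu_wide: pd.DataFrame
    rscu_long: pd.DataFrame
    range_wide: pd.DataFrame
    sd_wide: pd.DataFrame


def compare_samples(tables: Sequence[RSCUTable]) -> CodonComparison:
    """Align RSCU tables from several samples/species into matrices.

    Missing values (unobserved families in a sample) stay missing. Sample
    ids must be unique.
    """
    if not tables:
        raise ValidationError("need at least one RSCU table")
    ids = [t.sample_id for t in tables]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"duplicate sample id(s) in {ids}")
    long_rows = []
    for t in tables:
        for codon in sorted(t.rscu):
            long_rows.append(
                {
                    "sample": t.sample_id,
                    "codon": codon,
                    "amino_acid": CODON_TO_AA[codon],
                    "count": t.counts[codon],
                    "rscu": t.rscu[codon],
                }
            )
    long = pd.DataFrame(long_rows)
    wide = long.pivot(index="codon", columns="sample", values="rscu")
    wide.insert(0, "amino_acid", [CODON_TO_AA[c] for c in wide.index])
    stats_rows = []
    for t in tables:
        for s in bias_stats(t):
            stats_rows.append(
                {
                    "sample": t.sample_id,
                    "amino_acid": s.amino_acid,
                    "range": s.rscu_range,
                    "sd": s.rscu_sd,
                }
            )
    stats = pd.DataFrame(stats_rows)
    if stats.empty:
        empty = pd.DataFrame()
        return CodonComparison(wide, long, empty, empty)
    range_wide = stats.pivot(index="amino_acid", columns="sample", values="range")
    sd_wide = stats.pivot(index="amino_acid", columns="sample", values="sd")
    return CodonComparison(wide, long, range_wide, sd_wide)
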