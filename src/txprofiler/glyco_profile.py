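"""Glycogene presence/expression profiling against a reference catalogue.

Expression hosts differ in which glycan-synthesis enzymes (glycogenes) they
transcribe; a missing family (e.g. sialyltransferases in lepidopteran
cells) explains missing terminal modifications on recombinant proteins.
Presence of each reference glycogene in a transcriptome is called from
protein-level homology hits under explicit thresholds (e-value, percent
identity, subject coverage), the best supporting transcript's TPM is
attached, and the resulting profile is summarized as category counts,
between-sample overlap, and mechanism/fold proportions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

from .completeness import subject_coverage
from .errors import ValidationError
from .io_formats import AlignmentHit, ExpressionRecord, GlycogeneAnnotation

DEFAULT_EVALUE = 1e-20
DEFAULT_MIN_IDENTITY = 30.0
DEFAULT_MIN_COVERAGE = 0.5


@dataclass(frozen=True, slots=True)
class GlycogeneProfileRow:
    """One (reference gene x sample) cell of the presence/expression matrix."""

    gene_id: str
    sample_id: str
    present: bool
    category: str
    mechanism: str
    fold: str
    best_transcript: str | None = None
    tpm: float | None = None

    def __post_init__(self):
        if not self.present and (self.best_transcript is not None or self.tpm is not None):
            raise ValidationError(
                f"gene {self.gene_id!r}: absent rows cannot carry a "
                "transcript or TPM"
            )


def call_presence(
    hits: Sequence[AlignmentHit],
    annotations: Sequence[GlycogeneAnnotation] | Mapping[str, GlycogeneAnnotation],
    evalue_cutoff: float = DEFAULT_EVALUE,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_subject_coverage: float = DEFAULT_MIN_COVERAGE,
) -> dict[str, AlignmentHit]:
    """Call reference glycogenes present from sample-protein -> reference hits.

    A gene is present iff at least one hit passes all three thresholds
    (evalue <= cutoff, identity >= min_identity, subject coverage >=
    min_subject_coverage); the passing hit with maximal bitscore (ties:
    minimal e-value, then first occurrence) is recorded as support. Hits to
    subjects absent from the annotation table are ignored with a warning.
    """
    ann = _as_mapping(annotations)
    unknown = sorted({h.subject_id for h in hits} - set(ann))
    if unknown:
        warnings.warn(
            f"{len(unknown)} hit subject(s) not in the glycogene reference, "
            "ignored (e.g. " + ", ".join(unknown[:3]) + ")",
            stacklevel=2,
        )
    best: dict[str, AlignmentHit] = {}
    for hit in hits:
        if hit.subject_id not in ann:
            continue
        if hit.evalue > evalue_cutoff:
            continue
        if hit.pct_identity < min_identity:
            continue
        if subject_coverage(hit) < min_subject_coverage:
            continue
        cur = best.get(hit.subject_id)
        if (
            cur is None
            or hit.bitscore > cur.bitscore
            or (hit.bitscore == cur.bitscore and hit.evalue < cur.evalue)
        ):
            best[hit.subject_id] = hit
    return best


def build_profile(
    presence_by_sample: Mapping[str, Mapping[str, AlignmentHit]],
    expression_by_sample: Mapping[str, Sequence[ExpressionRecord]],
    annotations: Sequence[GlycogeneAnnotation] | Mapping[str, GlycogeneAnnotation],
) -> list[GlycogeneProfileRow]:
    """Join presence calls with expression into one row per (gene x sample).

    A present gene's TPM is that of its single best supporting transcript;
    transcripts missing from the expression table leave TPM missing with a
    warning.
    """
    ann = _as_mapping(annotations)
    rows: list[GlycogeneProfileRow] = []
    n_missing_expr = 0
    for sample_id in presence_by_sample:
        presence = presence_by_sample[sample_id]
        tpm_by_id = {
            e.transcript_id: e.tpm
            for e in expression_by_sample.get(sample_id, ())
        }
        for gene_id in sorted(ann):
            a = ann[gene_id]
            hit = presence.get(gene_id)
            if hit is None:
                rows.append(
                    GlycogeneProfileRow(
                        gene_id=gene_id,
                        sample_id=sample_id,
                        present=False,
                        category=a.category,
                        mechanism=a.mechanism,
                        fold=a.fold,
                    )
                )
                continue
            tpm = tpm_by_id.get(hit.query_id)
            if tpm is None:
                n_missing_expr += 1
            rows.append(
                GlycogeneProfileRow(
                    gene_id=gene_id,
                    sample_id=sample_id,
                    present=True,
                    category=a.category,
                    mechanism=a.mechanism,
                    fold=a.fold,
                    best_transcript=hit.query_id,
                    tpm=tpm,
                )
            )
    if n_missing_expr:
        warnings.warn(
            f"{n_missing_expr} supporting transcript(s) absent from the "
            "expression table; TPM left missing",
            stacklevel=2,
        )
    return rows


def overlap_counts(
    profile_a: Sequence[GlycogeneProfileRow],
    profile_b: Sequence[GlycogeneProfileRow],
) -> tuple[int, int, int]:
    """(nA, nB, n_shared) present-gene counts for two single-sample profiles."""
    genes_a = {r.gene_id for r in profile_a}
    genes_b = {r.gene_id for r in profile_b}
    if genes_a != genes_b:
        raise ValidationError(
            "profiles cover different glycogene references "
            f"({len(genes_a)} vs {len(genes_b)} genes)"
        )
    present_a = {r.gene_id for r in profile_a if r.present}
    present_b = {r.gene_id for r in profile_b if r.present}
    return len(present_a), len(present_b), len(present_a & present_b)


def category_counts(
    profile: Sequence[GlycogeneProfileRow],
) -> dict[str, int]:
    """Present-gene count per functional category (sorted by category)."""
    out: dict[str, int] = {}
    for r in profile:
        if r.present:
            out[r.category] = out.get(r.category, 0) + 1
    return dict(sorted(out.items()))


def mechanism_fold_proportions(
    profile: Sequence[GlycogeneProfileRow],
) -> tuple[dict[str, float], dict[str, float]]:
    """Proportions of present genes per mechanism and per fold.

    Each axis sums to 1 over its vocabulary; with no present genes both
    results are explicitly empty.
    """
    present = [r for r in profile if r.present]
    if not present:
        return {}, {}
    n = len(present)
    mech: dict[str, float] = {}
    fold: dict[str, float] = {}
    for r in present:
        mech[r.mechanism] = mech.get(r.mechanism, 0) + 1
        fold[r.fold] = fold.get(r.fold, 0) + 1
    return (
        {k: v / n for k, v in sorted(mech.items())},
        {k: v / n for k, v in sorted(fold.items())},
    )


def _as_mapping(
    annotations: Sequence[GlycogeneAnnotation] | Mapping[str, GlycogeneAnnotation],
) -> Mapping[str, GlycogeneAnnotation]:
    if isinstance(annotations, Mapping):
        return annotations
    return {a.gene_id: a for a in annotations}
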