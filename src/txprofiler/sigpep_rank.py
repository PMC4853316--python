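"""Expression-ranked selection of predicted signal peptides.

For secretory expression, the most promising endogenous signal peptides are
those of the host's own most abundant secreted proteins: their sequences
demonstrably drive high-flux secretion in that cell. This module joins
signal-peptide predictions with transcript expression, ranks positive
predictions by TPM, extracts each signal sequence (residues 1 ..
cleavage_pos - 1), and flags predictions on proteins that do not begin with
methionine — those likely come from 5'-truncated transcripts or an
upstream in-frame start, and deserve manual review rather than silent
removal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

from .errors import ValidationError
from .io_formats import ExpressionRecord, ProteinRecord, SignalPeptideRecord


@dataclass(frozen=True, slots=True)
class RankedSignalPeptide:
    """One ranked positive prediction with its extracted signal sequence."""

    rank: int
    transcript_id: str
    protein_id: str
    tpm: float
    d_score: float
    signal_sequence: str
    truncation_flag: bool


def rank_signal_peptides(
    predictions: Sequence[SignalPeptideRecord],
    expression: Sequence[ExpressionRecord],
    proteins: Sequence[ProteinRecord],
    id_map: Mapping[str, str],
) -> list[RankedSignalPeptide]:
    """Rank positive signal predictions by their transcript's TPM.

    Only ``is_signal`` predictions are considered. Each protein id must
    resolve to a transcript via ``id_map`` and to a sequence in
    ``proteins``; unresolvable ones are dropped with a warning. A transcript
    without an expression record is kept at TPM 0 with a warning. Sorting is
    TPM descending, ties by D-score descending then protein id ascending;
    ranks are contiguous from 1.
    """
    seq_by_id = {p.id: p.sequence for p in proteins}
    tpm_by_id = {e.transcript_id: e.tpm for e in expression}
    entries = []
    dropped: list[str] = []
    missing_expr: list[str] = []
    for pred in predictions:
        if not pred.is_signal:
            continue
        transcript_id = id_map.get(pred.protein_id)
        seq = seq_by_id.get(pred.protein_id)
        if transcript_id is None or seq is None:
            dropped.append(pred.protein_id)
            continue
        if pred.cleavage_pos > len(seq):
            raise ValidationError(
                f"protein {pred.protein_id!r}: cleavage position "
                f"{pred.cleavage_pos} exceeds protein length {len(seq)}"
            )
        tpm = tpm_by_id.get(transcript_id)
        if tpm is None:
            missing_expr.append(transcript_id)
            tpm = 0.0
        entries.append(
            (
                tpm,
                pred.d_score,
                pred.protein_id,
                transcript_id,
                seq[: pred.cleavage_pos - 1],
                not seq.startswith("M"),
            )
        )
    if dropped:
        warnings.warn(
            f"{len(dropped)} signal prediction(s) with unresolvable protein "
            "ids dropped (e.g. " + ", ".join(dropped[:3]) + ")",
            stacklevel=2,
        )
    if missing_expr:
        warnings.warn(
            f"{len(missing_expr)} transcript(s) lack expression records; "
            "ranked at TPM 0",
            stacklevel=2,
        )
    entries.sort(key=lambda e: (-e[0], -e[1], e[2]))
    return [
        RankedSignalPeptide(
            rank=i + 1,
            transcript_id=t_id,
            protein_id=p_id,
            tpm=tpm,
            d_score=d,
            signal_sequence=sig,
            truncation_flag=trunc,
        )
        for i, (tpm, d, p_id, t_id, sig, trunc) in enumerate(entries)
    ]


def top_n(
    ranked: Sequence[RankedSignalPeptide], n: int = 100
) -> list[RankedSignalPeptide]:
    """First min(n, len) entries of a ranked list, ranks preserved."""
    if n <= 0:
        raise ValidationError(f"n must be positive, got {n}")
    return list(ranked[:n])
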