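"""Readers and writers for the external formats the pipeline consumes.

Every reader normalizes its format into one of the small domain dataclasses
below; all downstream stages work only on those. Formats handled:

* FASTA (nucleotide and protein), via Bio.SeqIO;
* expression tables — the RSEM ``isoforms.results`` dialect or a generic
  two-column ``id<TAB>TPM`` file;
* tabular homology hits — the 12 standard tabular-alignment columns plus a
  mandatory 13th column carrying the subject (hit) sequence length, which
  subject-coverage computation needs;
* SignalP v4 "short" prediction tables;
* a glycogene reference annotation TSV (gene, category, mechanism, fold).

All writers emit UTF-8 with ``\\n`` line endings and tab separators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError, ValidationError

# IUPAC nucleotide codes (U is normalized to T on read)
DNA_ALPHABET = frozenset("ACGTNRYSWKMBDHV")
# 20 standard amino acids plus X (unknown) and '*' (stop)
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY" + "X*")

MECHANISM_VOCAB = ("inverting", "retaining", "unknown")
FOLD_VOCAB = ("GT-A", "GT-B", "unknown")

RSEM_COLUMNS = (
    "transcript_id",
    "length",
    "effective_length",
    "expected_count",
    "TPM",
    "FPKM",
)


@dataclass(frozen=True, slots=True)
class TranscriptRecord:
    """One assembled transcript or CDS: id, optional description, DNA sequence."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self):
        if not self.id:
            raise ValidationError("transcript id must be non-empty")
        if not self.sequence:
            raise ValidationError(f"transcript {self.id!r}: empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True, slots=True)
class ProteinRecord:
    """A predicted protein sequence; may carry a trailing stop ('*')."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self):
        if not self.id:
            raise ValidationError("protein id must be non-empty")
        if not self.sequence:
            raise ValidationError(f"protein {self.id!r}: empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True, slots=True)
class ExpressionRecord:
    """Per-transcript abundance. TPM is mandatory; the rest may be missing."""

    transcript_id: str
    tpm: float
    fpkm: float | None = None
    length: int | None = None
    effective_length: float | None = None

    def __post_init__(self):
        if self.tpm < 0:
            raise ValidationError(
                f"transcript {self.transcript_id!r}: negative TPM {self.tpm}"
            )


@dataclass(frozen=True, slots=True)
class AlignmentHit:
    """One tabular homology hit (blast outfmt-6 style) plus subject length.

    Coordinates are 1-based inclusive, the tabular-alignment convention;
    subject coordinates may be reversed for minus-strand hits.
    """

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float
    subject_length: int

    def __post_init__(self):
        if self.evalue < 0:
            raise ValidationError(
                f"hit {self.query_id}->{self.subject_id}: negative e-value"
            )
        if self.subject_length <= 0:
            raise ValidationError(
                f"hit {self.query_id}->{self.subject_id}: "
                f"subject_length must be positive, got {self.subject_length}"
            )
        if not (
            1 <= self.s_start <= self.subject_length
            and 1 <= self.s_end <= self.subject_length
        ):
            raise ValidationError(
                f"hit {self.query_id}->{self.subject_id}: subject coordinates "
                f"({self.s_start},{self.s_end}) outside 1..{self.subject_length}"
            )


@dataclass(frozen=True, slots=True)
class SignalPeptideRecord:
    """One SignalP v4 prediction: D-score, cutoff, cleavage, and the Y/N call.

    ``cleavage_pos`` is the first residue of the mature protein, so the
    signal peptide occupies residues ``1 .. cleavage_pos - 1``.
    """

    protein_id: str
    d_score: float
    d_cutoff: float
    is_signal: bool
    cleavage_pos: int | None = None

    def __post_init__(self):
        if self.is_signal:
            if self.cleavage_pos is None:
                raise ValidationError(
                    f"protein {self.protein_id!r}: positive signal call "
                    "without a cleavage position"
                )
            if self.cleavage_pos < 2:
                raise ValidationError(
                    f"protein {self.protein_id!r}: cleavage position "
                    f"{self.cleavage_pos} leaves an empty signal peptide"
                )


@dataclass(frozen=True, slots=True)
class GlycogeneAnnotation:
    """Reference glycogene with its functional category, catalytic mechanism
    (inverting / retaining / unknown) and structural fold (GT-A / GT-B /
    unknown), as catalogued by the GGDB/CAZy-style references."""

    gene_id: str
    category: str
    mechanism: str
    fold: str

    def __post_init__(self):
        if not self.gene_id:
            raise ValidationError("glycogene id must be non-empty")
        if not self.category:
            raise ValidationError(f"glycogene {self.gene_id!r}: empty category")
        if self.mechanism not in MECHANISM_VOCAB:
            raise ValidationError(
                f"glycogene {self.gene_id!r}: mechanism {self.mechanism!r} "
                f"not in {MECHANISM_VOCAB}"
            )
        if self.fold not in FOLD_VOCAB:
            raise ValidationError(
                f"glycogene {self.gene_id!r}: fold {self.fold!r} "
                f"not in {FOLD_VOCAB}"
            )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def _check_fasta_head(path: Path) -> bool:
    """Return False (with a warning) for an empty file; raise on non-FASTA."""
    text = path.read_text(encoding="utf-8")
    stripped = text.lstrip()
    if not stripped:
        warnings.warn(f"empty FASTA file: {path}", stacklevel=3)
        return False
    if not stripped.startswith(">"):
        raise FormatError("not a FASTA file (first byte is not '>')", path=path)
    return True


def read_fasta(
    path: str | Path, kind: Literal["dna", "protein"] = "dna"
) -> list[TranscriptRecord] | list[ProteinRecord]:
    """Parse a FASTA file into transcript or protein records.

    Sequences are uppercased; for DNA, ``U`` is normalized to ``T``.
    Duplicate ids and out-of-alphabet characters are errors.
    """
    path = Path(path)
    if not _check_fasta_head(path):
        return []
    records: list = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate sequence id {rec.id!r}", path=path)
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        desc = rec.description[len(rec.id) :].strip()
        if kind == "dna":
            seq = seq.replace("U", "T")
            bad = set(seq) - DNA_ALPHABET
            if bad:
                raise FormatError(
                    f"sequence {rec.id!r} contains non-IUPAC DNA characters "
                    f"{sorted(bad)}",
                    path=path,
                )
            records.append(TranscriptRecord(id=rec.id, sequence=seq, description=desc))
        elif kind == "protein":
            bad = set(seq) - PROTEIN_ALPHABET
            if bad:
                raise FormatError(
                    f"sequence {rec.id!r} contains non-standard amino-acid "
                    f"characters {sorted(bad)}",
                    path=path,
                )
            records.append(ProteinRecord(id=rec.id, sequence=seq, description=desc))
        else:
            raise ValidationError(f"unknown FASTA kind {kind!r}")
    return records


def write_fasta(
    records: Iterable[TranscriptRecord | ProteinRecord],
    path: str | Path,
    width: int = 60,
) -> None:
    """Write records as FASTA, wrapping sequence lines at ``width`` columns."""
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


# ---------------------------------------------------------------------------
# Expression tables
# ---------------------------------------------------------------------------


def read_expression_table(
    path: str | Path, dialect: Literal["rsem", "generic"] = "rsem"
) -> list[ExpressionRecord]:
    """Read per-transcript expression values.

    ``rsem``: the tab-separated ``isoforms.results`` layout with a header
    containing at least transcript_id, length, effective_length,
    expected_count, TPM and FPKM. ``generic``: two columns id<TAB>TPM with an
    optional header line. Duplicate transcript ids are an error in both.
    """
    path = Path(path)
    if dialect == "rsem":
        try:
            df = pd.read_csv(path, sep="\t")
        except pd.errors.EmptyDataError:
            warnings.warn(f"empty expression table: {path}", stacklevel=2)
            return []
        missing = [c for c in RSEM_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(
                f"RSEM table missing mandatory column(s) {missing}", path=path
            )
        if df.empty:
            warnings.warn(f"expression table has no data rows: {path}", stacklevel=2)
            return []
        records = []
        for i, row in enumerate(df.itertuples(index=False)):
            tpm = float(row.TPM)
            if tpm < 0:
                raise FormatError(
                    f"negative TPM {tpm} for {row.transcript_id!r}",
                    path=path,
                    line=i + 2,
                )
            records.append(
                ExpressionRecord(
                    transcript_id=str(row.transcript_id),
                    tpm=tpm,
                    fpkm=float(row.FPKM),
                    length=int(row.length),
                    effective_length=float(row.effective_length),
                )
            )
    elif dialect == "generic":
        records = []
        with open(path, encoding="utf-8") as fh:
            lines = fh.read().splitlines()
        data_lines = [
            (i + 1, ln) for i, ln in enumerate(lines) if ln.strip() and not ln.startswith("#")
        ]
        if data_lines:
            # optional single header line: second field not parseable as float
            first_fields = data_lines[0][1].split("\t")
            try:
                float(first_fields[1])
            except (ValueError, IndexError):
                data_lines = data_lines[1:]
        if not data_lines:
            warnings.warn(f"expression table has no data rows: {path}", stacklevel=2)
            return []
        for lineno, ln in data_lines:
            fields = ln.split("\t")
            if len(fields) < 2:
                raise FormatError("expected id<TAB>TPM", path=path, line=lineno)
            try:
                tpm = float(fields[1])
            except ValueError:
                raise FormatError(
                    f"unparseable TPM value {fields[1]!r}", path=path, line=lineno
                ) from None
            if tpm < 0:
                raise FormatError(f"negative TPM {tpm}", path=path, line=lineno)
            records.append(ExpressionRecord(transcript_id=fields[0], tpm=tpm))
    else:
        raise ValidationError(f"unknown expression dialect {dialect!r}")

    ids = [r.transcript_id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise FormatError(f"duplicate transcript id(s) {dupes[:5]}", path=path)
    return records


def write_expression_table(
    records: Iterable[ExpressionRecord], path: str | Path
) -> None:
    """Write records in the RSEM isoforms.results dialect (missing -> 0)."""
    rows = [
        (
            r.transcript_id,
            r.length if r.length is not None else 0,
            r.effective_length if r.effective_length is not None else 0.0,
            0.0,
            r.tpm,
            r.fpkm if r.fpkm is not None else 0.0,
        )
        for r in records
    ]
    df = pd.DataFrame(rows, columns=list(RSEM_COLUMNS))
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# Tabular alignment hits
# ---------------------------------------------------------------------------

_HIT_FIELDS = 13


def read_tabular_hits(path: str | Path) -> list[AlignmentHit]:
    """Read 13-column tabular alignment hits (outfmt-6 + subject length).

    The 13th column is required because subject-coverage computation needs
    the subject's full length, which the standard 12 columns do not carry.
    Lines starting with '#' are ignored.
    """
    path = Path(path)
    hits: list[AlignmentHit] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, ln in enumerate(fh, start=1):
            ln = ln.rstrip("\n")
            if not ln.strip() or ln.startswith("#"):
                continue
            fields = ln.split("\t")
            if len(fields) != _HIT_FIELDS:
                raise FormatError(
                    f"expected {_HIT_FIELDS} tab-separated columns, got "
                    f"{len(fields)}; regenerate the table with the subject "
                    "length appended as column 13 "
                    "(e.g. outfmt '6 std slen')",
                    path=path,
                    line=lineno,
                )
            try:
                hit = AlignmentHit(
                    query_id=fields[0],
                    subject_id=fields[1],
                    pct_identity=float(fields[2]),
                    aln_length=int(fields[3]),
                    mismatches=int(fields[4]),
                    gap_opens=int(fields[5]),
                    q_start=int(fields[6]),
                    q_end=int(fields[7]),
                    s_start=int(fields[8]),
                    s_end=int(fields[9]),
                    evalue=float(fields[10]),
                    bitscore=float(fields[11]),
                    subject_length=int(fields[12]),
                )
            except ValueError as exc:
                raise FormatError(
                    f"unparseable numeric field: {exc}", path=path, line=lineno
                ) from None
            hits.append(hit)
    return hits


def write_tabular_hits(
    hits: Iterable[AlignmentHit], path: str | Path, header_comment: str | None = None
) -> None:
    """Write hits as 13-column TSV; optional '#' comment line first."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        for h in hits:
            fh.write(
                "\t".join(
                    str(v)
                    for v in (
                        h.query_id,
                        h.subject_id,
                        h.pct_identity,
                        h.aln_length,
                        h.mismatches,
                        h.gap_opens,
                        h.q_start,
                        h.q_end,
                        h.s_start,
                        h.s_end,
                        h.evalue,
                        h.bitscore,
                        h.subject_length,
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# SignalP v4 short format
# ---------------------------------------------------------------------------


def read_signalp(path: str | Path) -> list[SignalPeptideRecord]:
    """Read SignalP v4 'short'-format predictions.

    Data columns: name, Cmax, pos, Ymax, pos, Smax, pos, Smean, D, ?,
    Dmaxcut, networks-used. The Ymax position is the first mature-protein
    residue; the '?' column is the Y/N signal call. Other SignalP versions
    (different header) are rejected.
    """
    path = Path(path)
    records: list[SignalPeptideRecord] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, ln in enumerate(fh, start=1):
            ln = ln.rstrip("\n")
            if not ln.strip():
                continue
            if ln.startswith("#"):
                if "SignalP-" in ln and "SignalP-4" not in ln:
                    version = ln.split("SignalP-")[1].split()[0]
                    raise FormatError(
                        f"unsupported SignalP version {version!r}; only v4 "
                        "short format is accepted",
                        path=path,
                        line=lineno,
                    )
                continue
            fields = ln.split()
            if len(fields) < 12:
                raise FormatError(
                    f"expected >= 12 whitespace-separated columns, got "
                    f"{len(fields)}",
                    path=path,
                    line=lineno,
                )
            try:
                ymax_pos = int(fields[4])
                d_score = float(fields[8])
                call = fields[9]
                d_cutoff = float(fields[10])
            except ValueError as exc:
                raise FormatError(
                    f"unparseable field: {exc}", path=path, line=lineno
                ) from None
            if call not in ("Y", "N"):
                raise FormatError(
                    f"signal call must be Y or N, got {call!r}",
                    path=path,
                    line=lineno,
                )
            is_signal = call == "Y"
            records.append(
                SignalPeptideRecord(
                    protein_id=fields[0],
                    d_score=d_score,
                    d_cutoff=d_cutoff,
                    is_signal=is_signal,
                    cleavage_pos=ymax_pos if is_signal else None,
                )
            )
    return records


def write_signalp(
    records: Iterable[SignalPeptideRecord], path: str | Path
) -> None:
    """Write records in SignalP 4.1 short format."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("# SignalP-4.1 euk predictions\n")
        fh.write(
            "# name                     Cmax  pos  Ymax  pos  Smax  pos  "
            "Smean   D     ?  Dmaxcut    Networks-used\n"
        )
        for r in records:
            pos = r.cleavage_pos if r.cleavage_pos is not None else 1
            call = "Y" if r.is_signal else "N"
            fh.write(
                f"{r.protein_id}  {r.d_score:.3f}  {pos}  {r.d_score:.3f}  "
                f"{pos}  {r.d_score:.3f}  {max(pos - 1, 1)}  {r.d_score:.3f}  "
                f"{r.d_score:.3f}  {call}  {r.d_cutoff:.3f}  SignalP-noTM\n"
            )


# ---------------------------------------------------------------------------
# Glycogene reference annotations
# ---------------------------------------------------------------------------

_GLYCO_COLUMNS = ("gene_id", "category", "mechanism", "fold")


def read_glyco_reference(path: str | Path) -> list[GlycogeneAnnotation]:
    """Read the glycogene reference TSV (gene_id, category, mechanism, fold).

    Mechanism and fold must come from their controlled vocabularies;
    duplicate gene ids are an error.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        warnings.warn(f"empty glycogene reference: {path}", stacklevel=2)
        return []
    missing = [c for c in _GLYCO_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(
            f"glycogene reference missing column(s) {missing}", path=path
        )
    annotations = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            annotations.append(
                GlycogeneAnnotation(
                    gene_id=row.gene_id,
                    category=row.category,
                    mechanism=row.mechanism,
                    fold=row.fold,
                )
            )
        except ValidationError as exc:
            raise FormatError(str(exc), path=path, line=i + 2) from None
    ids = [a.gene_id for a in annotations]
    if len(set(ids)) != len(ids):
        dupes = sorted({g for g in ids if ids.count(g) > 1})
        raise FormatError(f"duplicate glycogene id(s) {dupes[:5]}", path=path)
    return annotations


def write_glyco_reference(
    annotations: Iterable[GlycogeneAnnotation], path: str | Path
) -> None:
    df = pd.DataFrame(
        [(a.gene_id, a.category, a.mechanism, a.fold) for a in annotations],
        columns=list(_GLYCO_COLUMNS),
    )
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")
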