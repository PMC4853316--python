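"""Seeded synthetic corpus generator with known ground truth.

Every input the pipeline consumes can be generated here with its governing
parameters recorded, so each stage supports parameter-recovery tests
without any downloads:

* CDS sets: lengths log-normal (rounded to codons), bodies of i.i.d.
  uniform amino acids whose codons are drawn from per-amino-acid
  probability vectors sampled once from a symmetric Dirichlet — the implied
  true RSCU of codon j in family i is n_i * p_ij;
* expression tables: heavy-tailed log-normal TPMs normalized to 1e6, in
  the RSEM isoforms.results dialect;
* homology hit tables: subject-coverage fractions drawn from a Beta
  distribution and realized as integer 1-based subject coordinates
  (exact to +-1/subject_length);
* SignalP v4 short tables: Bernoulli signal calls with cleavage positions
  uniform over a configurable signal-length range;
* a glycogene reference and per-sample supporting hits with known
  presence sets.

A single master seed is fanned out to independent child streams via
``numpy.random.SeedSequence``, so the full corpus is byte-identical across
runs for a fixed seed, and regenerating one piece never perturbs another.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .genetics import AA_TO_CODONS, AMINO_ACIDS
from .io_formats import (
    AlignmentHit,
    ExpressionRecord,
    GlycogeneAnnotation,
    ProteinRecord,
    SignalPeptideRecord,
    TranscriptRecord,
    write_expression_table,
    write_fasta,
    write_glyco_reference,
    write_signalp,
    write_tabular_hits,
)

# child-stream indices off the master SeedSequence; fixed so that each
# corpus piece has its own reproducible stream
_STREAMS = {
    "profile": 0,
    "cds": 1,
    "expression": 2,
    "hits": 3,
    "signalp": 4,
    "glyco": 5,
    "expression2": 6,
    "glyco2": 7,
}

GLYCO_CATEGORIES = (
    "sialyltransferase",
    "N-acetylgalactosaminyltransferase",
    "N-acetylglucosaminyltransferase",
    "fucosyltransferase",
    "galactosyltransferase",
    "glucosyltransferase",
    "mannosyltransferase",
    "xylosyltransferase",
    "sulfotransferase",
    "glycosidase",
)


@dataclass(frozen=True, slots=True)
class SyntheticSpec:
    """Parameters governing the synthetic corpus.

    Defaults describe a desk-scale transcriptome: a few hundred CDS with a
    log-normal length distribution centred near 1 kb (matching typical
    de novo assemblies), moderate codon bias (Dirichlet alpha = 0.8),
    strongly heavy-tailed expression (sigma = 2 on the log scale), homolog
    coverage skewed toward full length, and ~15% of proteins carrying a
    signal peptide of 15-30 residues.
    """

    seed: int = 0
    n_cds: int = 400
    mu_len: float = 6.8  # log-scale mean; exp(mu + sigma^2/2) ~ 1 kb
    sigma_len: float = 0.55
    min_len: int = 150  # nt floor after rounding to codons
    codon_alpha: float = 0.8  # Dirichlet concentration; smaller = more bias
    mu_tpm: float = 1.0
    sigma_tpm: float = 2.0
    cov_a: float = 2.0  # Beta(a, b) subject coverage; mean a/(a+b)
    cov_b: float = 1.2
    p_extra_hit: float = 0.3  # chance of a weaker secondary hit per query
    p_weak_evalue: float = 0.05  # chance a hit's e-value fails 1e-20
    p_signal: float = 0.15
    signal_len_lo: int = 15
    signal_len_hi: int = 30
    n_glyco_ref: int = 40
    p_glyco_present: float = 0.8

    def __post_init__(self):
        if self.n_cds <= 0 or self.n_glyco_ref <= 0:
            raise ValidationError("counts must be positive")
        if self.codon_alpha <= 0:
            raise ValidationError(
                f"Dirichlet concentration must be > 0, got {self.codon_alpha}"
            )
        if self.min_len < 9:
            raise ValidationError("min_len must allow start + 1 codon + stop")
        if not 0 <= self.p_signal <= 1:
            raise ValidationError("p_signal must be a probability")
        if not 2 <= self.signal_len_lo <= self.signal_len_hi:
            raise ValidationError("signal length range must satisfy 2 <= lo <= hi")


def _rng(spec: SyntheticSpec, stream: str) -> np.random.Generator:
    child = np.random.SeedSequence(spec.seed).spawn(max(_STREAMS.values()) + 1)
    return np.random.default_rng(child[_STREAMS[stream]])


def make_codon_profile(spec: SyntheticSpec) -> dict[str, dict[str, float]]:
    """Per-family codon probability vectors drawn from Dirichlet(alpha).

    Families are the 20 amino acids plus '*' (used only to pick terminal
    stop codons). Vectors sum to 1; reproducible for a fixed seed.
    """
    rng = _rng(spec, "profile")
    profile: dict[str, dict[str, float]] = {}
    for aa in list(AMINO_ACIDS) + ["*"]:
        codons = AA_TO_CODONS[aa]
        p = rng.dirichlet([spec.codon_alpha] * len(codons))
        profile[aa] = dict(zip(codons, (float(x) for x in p)))
    return profile


def true_rscu(profile: dict[str, dict[str, float]]) -> dict[str, float]:
    """The RSCU values implied by a codon profile: n_i * p_ij per codon."""
    out = {}
    for aa in AMINO_ACIDS:
        n_i = len(AA_TO_CODONS[aa])
        for codon, p in profile[aa].items():
            out[codon] = n_i * p
    return out


def generate_cds(
    profile: dict[str, dict[str, float]], spec: SyntheticSpec
) -> list[TranscriptRecord]:
    """In-frame CDS: ATG start, i.i.d. uniform amino-acid body with codons
    from the profile, single terminal stop; no internal stops by
    construction. Lengths are log-normal rounded down to whole codons and
    floored at min_len."""
    rng = _rng(spec, "cds")
    lens = rng.lognormal(spec.mu_len, spec.sigma_len, spec.n_cds)
    lens = np.maximum((lens // 3).astype(np.int64) * 3, 3 * (spec.min_len // 3 + 1))
    n_body = lens // 3 - 2  # minus start and stop codons
    total = int(n_body.sum())
    aa_idx = rng.integers(0, len(AMINO_ACIDS), total)
    codon_arr = np.empty(total, dtype="<U3")
    for i, aa in enumerate(AMINO_ACIDS):
        mask = aa_idx == i
        k = int(mask.sum())
        if k == 0:
            continue
        codons = list(profile[aa])
        probs = np.array([profile[aa][c] for c in codons])
        codon_arr[mask] = rng.choice(codons, size=k, p=probs / probs.sum())
    stop_codons = list(profile["*"])
    stop_probs = np.array([profile["*"][c] for c in stop_codons])
    stops = rng.choice(stop_codons, size=spec.n_cds, p=stop_probs / stop_probs.sum())
    records = []
    off = 0
    for i in range(spec.n_cds):
        nb = int(n_body[i])
        body = "".join(codon_arr[off : off + nb])
        off += nb
        records.append(
            TranscriptRecord(id=f"TN{i:05d}", sequence="ATG" + body + stops[i])
        )
    return records


def translate_cds(cds: Sequence[TranscriptRecord]) -> tuple[list[ProteinRecord], dict[str, str]]:
    """Translate generated CDS (dropping the stop); returns proteins and the
    protein -> transcript id map."""
    from Bio.Seq import Seq

    proteins = []
    id_map = {}
    for rec in cds:
        aa = str(Seq(rec.sequence).translate()).rstrip("*")
        pid = f"{rec.id}.p1"
        proteins.append(ProteinRecord(id=pid, sequence=aa))
        id_map[pid] = rec.id
    return proteins, id_map


def generate_expression(
    spec: SyntheticSpec,
    ids: Sequence[str],
    lengths: dict[str, int] | None = None,
    stream: str = "expression",
) -> list[ExpressionRecord]:
    """Heavy-tailed TPMs (log-normal) normalized to sum exactly to 1e6."""
    if not ids:
        raise ValidationError("no transcript ids given")
    rng = _rng(spec, stream)
    raw = rng.lognormal(spec.mu_tpm, spec.sigma_tpm, len(ids))
    tpm = raw / raw.sum() * 1e6
    records = []
    for i, tid in enumerate(ids):
        length = lengths.get(tid) if lengths else None
        eff = max(float(length) - 200.0, 1.0) if length is not None else None
        records.append(
            ExpressionRecord(
                transcript_id=tid,
                tpm=float(tpm[i]),
                fpkm=float(tpm[i]) * 0.9,  # proportional stand-in
                length=length,
                effective_length=eff,
            )
        )
    return records


def generate_hits(
    spec: SyntheticSpec, ids: Sequence[str]
) -> tuple[list[AlignmentHit], dict[str, float]]:
    """One primary hit per query with coverage ~ Beta(cov_a, cov_b), plus
    occasional weaker secondary hits; returns (hits, true primary coverage
    per query realized to integer coordinates)."""
    if not ids:
        raise ValidationError("no query ids given")
    rng = _rng(spec, "hits")
    hits: list[AlignmentHit] = []
    truth: dict[str, float] = {}
    for qi, qid in enumerate(ids):
        subject_length = int(rng.integers(100, 1200))
        coverage = float(rng.beta(spec.cov_a, spec.cov_b))
        span = max(1, round(coverage * subject_length))
        s_start = 1 + int(rng.integers(0, subject_length - span + 1))
        s_end = s_start + span - 1
        pid = float(rng.uniform(30, 100))
        weak = rng.random() < spec.p_weak_evalue
        evalue = 10.0 ** float(
            rng.uniform(-19, -5) if weak else rng.uniform(-180, -21)
        )
        bitscore = round(span * 2.0 * pid / 100.0, 1)
        primary = AlignmentHit(
            query_id=qid,
            subject_id=f"SP{qi:05d}",
            pct_identity=round(pid, 2),
            aln_length=span,
            mismatches=int(span * (1 - pid / 100)),
            gap_opens=int(rng.integers(0, 3)),
            q_start=1,
            q_end=span,
            s_start=s_start,
            s_end=s_end,
            evalue=evalue,
            bitscore=bitscore,
            subject_length=subject_length,
        )
        hits.append(primary)
        truth[qid] = span / subject_length
        if rng.random() < spec.p_extra_hit:
            sub_len2 = int(rng.integers(100, 1200))
            span2 = max(1, int(span * rng.uniform(0.3, 0.9)))
            span2 = min(span2, sub_len2)
            s_start2 = 1 + int(rng.integers(0, sub_len2 - span2 + 1))
            hits.append(
                AlignmentHit(
                    query_id=qid,
                    subject_id=f"SP{qi:05d}b",
                    pct_identity=round(pid * 0.8, 2),
                    aln_length=span2,
                    mismatches=int(span2 * (1 - pid * 0.8 / 100)),
                    gap_opens=0,
                    q_start=1,
                    q_end=span2,
                    s_start=s_start2,
                    s_end=s_start2 + span2 - 1,
                    evalue=min(evalue * 1e5, 1.0),
                    bitscore=round(bitscore * 0.5, 1),
                    subject_length=sub_len2,
                )
            )
    return hits, truth


def generate_signalp(
    spec: SyntheticSpec,
    proteins: Sequence[ProteinRecord],
    d_cutoff: float = 0.45,
) -> list[SignalPeptideRecord]:
    """Bernoulli(p_signal) calls; positives get a D-score above the cutoff
    and a cleavage position in signal_len_range + 1 (clamped to the protein
    length)."""
    rng = _rng(spec, "signalp")
    records = []
    for prot in proteins:
        cpos = int(rng.integers(spec.signal_len_lo, spec.signal_len_hi + 1)) + 1
        cpos = min(cpos, len(prot.sequence))
        if rng.random() < spec.p_signal and cpos >= 2:
            records.append(
                SignalPeptideRecord(
                    protein_id=prot.id,
                    d_score=round(float(rng.uniform(d_cutoff + 0.05, 0.99)), 3),
                    d_cutoff=d_cutoff,
                    is_signal=True,
                    cleavage_pos=cpos,
                )
            )
        else:
            records.append(
                SignalPeptideRecord(
                    protein_id=prot.id,
                    d_score=round(float(rng.uniform(0.02, d_cutoff - 0.05)), 3),
                    d_cutoff=d_cutoff,
                    is_signal=False,
                )
            )
    return records


def generate_glyco_reference(spec: SyntheticSpec) -> list[GlycogeneAnnotation]:
    """A reference catalogue with realistic mechanism/fold composition
    (inverting majority, GT-A ~30%, GT-B ~20%, remainder unknown)."""
    rng = _rng(spec, "glyco")
    annotations = []
    for i in range(spec.n_glyco_ref):
        category = GLYCO_CATEGORIES[i % len(GLYCO_CATEGORIES)]
        mechanism = str(
            rng.choice(["inverting", "retaining", "unknown"], p=[0.55, 0.25, 0.20])
        )
        fold = str(rng.choice(["GT-A", "GT-B", "unknown"], p=[0.30, 0.20, 0.50]))
        annotations.append(
            GlycogeneAnnotation(
                gene_id=f"GLY{i:03d}",
                category=category,
                mechanism=mechanism,
                fold=fold,
            )
        )
    return annotations


def generate_glyco_hits(
    spec: SyntheticSpec,
    annotations: Sequence[GlycogeneAnnotation],
    query_ids: Sequence[str],
    stream: str = "glyco",
) -> tuple[list[AlignmentHit], set[str]]:
    """Supporting hits per reference gene: present genes (Bernoulli
    p_glyco_present) get a hit passing the default thresholds; a fraction of
    absent genes get a sub-threshold decoy hit. Returns (hits, true present
    set)."""
    if not query_ids:
        raise ValidationError("no query ids given")
    rng = _rng(spec, stream)
    hits: list[AlignmentHit] = []
    present: set[str] = set()
    for a in annotations:
        qid = str(query_ids[int(rng.integers(0, len(query_ids)))])
        subject_length = int(rng.integers(200, 800))
        if rng.random() < spec.p_glyco_present:
            present.add(a.gene_id)
            coverage = float(rng.uniform(0.55, 1.0))
            identity = float(rng.uniform(35, 95))
            evalue = 10.0 ** float(rng.uniform(-150, -25))
        else:
            if rng.random() < 0.7:
                continue  # no hit at all
            coverage = float(rng.uniform(0.05, 0.45))  # fails coverage cut
            identity = float(rng.uniform(35, 95))
            evalue = 10.0 ** float(rng.uniform(-150, -25))
        span = max(1, round(coverage * subject_length))
        s_start = 1 + int(rng.integers(0, subject_length - span + 1))
        hits.append(
            AlignmentHit(
                query_id=qid,
                subject_id=a.gene_id,
                pct_identity=round(identity, 2),
                aln_length=span,
                mismatches=int(span * (1 - identity / 100)),
                gap_opens=0,
                q_start=1,
                q_end=span,
                s_start=s_start,
                s_end=s_start + span - 1,
                evalue=evalue,
                bitscore=round(span * 2.0 * identity / 100.0, 1),
                subject_length=subject_length,
            )
        )
    return hits, present


@dataclass(slots=True)
class SyntheticCorpus:
    """The full in-memory corpus plus its ground truth."""

    spec: SyntheticSpec
    profile: dict[str, dict[str, float]]
    cds: list[TranscriptRecord]
    proteins: list[ProteinRecord]
    id_map: dict[str, str]
    expression: list[ExpressionRecord]
    expression2: list[ExpressionRecord]
    hits: list[AlignmentHit]
    hit_coverage_truth: dict[str, float]
    signalp: list[SignalPeptideRecord]
    glyco_reference: list[GlycogeneAnnotation]
    glyco_hits: list[AlignmentHit]
    glyco_present: set[str]
    glyco_hits2: list[AlignmentHit]
    glyco_present2: set[str]


def generate_corpus(spec: SyntheticSpec | None = None) -> SyntheticCorpus:
    """Generate every pipeline input with ground truth, all from one seed."""
    spec = spec or SyntheticSpec()
    profile = make_codon_profile(spec)
    cds = generate_cds(profile, spec)
    proteins, id_map = translate_cds(cds)
    ids = [r.id for r in cds]
    lengths = {r.id: len(r) for r in cds}
    expression = generate_expression(spec, ids, lengths, stream="expression")
    expression2 = generate_expression(spec, ids, lengths, stream="expression2")
    hits, cov_truth = generate_hits(spec, ids)
    signalp = generate_signalp(spec, proteins)
    glyco_ref = generate_glyco_reference(spec)
    glyco_hits, glyco_present = generate_glyco_hits(spec, glyco_ref, ids, stream="glyco")
    glyco_hits2, glyco_present2 = generate_glyco_hits(
        spec, glyco_ref, ids, stream="glyco2"
    )
    return SyntheticCorpus(
        spec=spec,
        profile=profile,
        cds=cds,
        proteins=proteins,
        id_map=id_map,
        expression=expression,
        expression2=expression2,
        hits=hits,
        hit_coverage_truth=cov_truth,
        signalp=signalp,
        glyco_reference=glyco_ref,
        glyco_hits=glyco_hits,
        glyco_present=glyco_present,
        glyco_hits2=glyco_hits2,
        glyco_present2=glyco_present2,
    )


def write_corpus(corpus: SyntheticCorpus, outdir: str | Path) -> dict[str, Path]:
    """Write the corpus as the text files the CLI consumes, plus truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "cds": outdir / "cds.fa",
        "transcripts": outdir / "transcripts.fa",
        "proteins": outdir / "proteins.fa",
        "id_map": outdir / "id_map.tsv",
        "expression": outdir / "expr.tsv",
        "expression2": outdir / "expr2.tsv",
        "hits": outdir / "hits.tsv",
        "signalp": outdir / "signalp.txt",
        "glyco_reference": outdir / "glyco_reference.tsv",
        "glyco_hits": outdir / "glyco_hits.tsv",
        "glyco_hits2": outdir / "glyco_hits2.tsv",
        "truth": outdir / "truth.json",
    }
    write_fasta(corpus.cds, paths["cds"])
    write_fasta(corpus.cds, paths["transcripts"])  # CDS double as transcripts
    write_fasta(corpus.proteins, paths["proteins"])
    with open(paths["id_map"], "w", encoding="utf-8", newline="\n") as fh:
        fh.write("protein_id\ttranscript_id\n")
        for pid, tid in corpus.id_map.items():
            fh.write(f"{pid}\t{tid}\n")
    write_expression_table(corpus.expression, paths["expression"])
    write_expression_table(corpus.expression2, paths["expression2"])
    write_tabular_hits(corpus.hits, paths["hits"])
    write_signalp(corpus.signalp, paths["signalp"])
    write_glyco_reference(corpus.glyco_reference, paths["glyco_reference"])
    write_tabular_hits(corpus.glyco_hits, paths["glyco_hits"])
    write_tabular_hits(corpus.glyco_hits2, paths["glyco_hits2"])
    truth = {
        "spec": asdict(corpus.spec),
        "codon_profile": corpus.profile,
        "true_rscu": true_rscu(corpus.profile),
        "tpm": {e.transcript_id: e.tpm for e in corpus.expression},
        "hit_coverage": corpus.hit_coverage_truth,
        "signal_truth": {
            r.protein_id: {
                "is_signal": r.is_signal,
                "cleavage_pos": r.cleavage_pos,
            }
            for r in corpus.signalp
        },
        "glyco_present": sorted(corpus.glyco_present),
        "glyco_present2": sorted(corpus.glyco_present2),
    }
    with open(paths["truth"], "w", encoding="utf-8", newline="\n") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths
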