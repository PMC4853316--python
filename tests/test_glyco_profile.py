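"""Glycogene presence calling, profile assembly, overlap and proportions."""

import numpy as np
import pytest

from txprofiler.errors import ValidationError
from txprofiler.glyco_profile import (
    GlycogeneProfileRow,
    build_profile,
    call_presence,
    category_counts,
    mechanism_fold_proportions,
    overlap_counts,
)
from txprofiler.io_formats import (
    AlignmentHit,
    ExpressionRecord,
    GlycogeneAnnotation,
)


def glyco_hit(query="t7", subject="G1", evalue=1e-80, identity=45.0,
              s_start=1, s_end=80, subject_length=100, bitscore=200.0):
    return AlignmentHit(
        query_id=query, subject_id=subject, pct_identity=identity,
        aln_length=abs(s_end - s_start) + 1, mismatches=0, gap_opens=0,
        q_start=1, q_end=80, s_start=s_start, s_end=s_end,
        evalue=evalue, bitscore=bitscore, subject_length=subject_length,
    )


ANN = [
    GlycogeneAnnotation("G1", "sialyltransferase", "inverting", "GT-A"),
    GlycogeneAnnotation("G2", "fucosyltransferase", "retaining", "GT-B"),
    GlycogeneAnnotation("G3", "glycosidase", "unknown", "unknown"),
]


class TestCallPresence:
    def test_passing_hit_makes_gene_present(self):
        present = call_presence([glyco_hit()], ANN, 1e-20, 30.0, 0.5)
        assert set(present) == {"G1"}
        assert present["G1"].query_id == "t7"

    def test_low_coverage_fails(self):
        hit = glyco_hit(s_start=1, s_end=30)  # coverage 0.3
        assert call_presence([hit], ANN, 1e-20, 30.0, 0.5) == {}

    def test_low_identity_fails(self):
        assert call_presence([glyco_hit(identity=25.0)], ANN, 1e-20, 30.0, 0.5) == {}

    def test_weak_evalue_fails(self):
        assert call_presence([glyco_hit(evalue=1e-10)], ANN, 1e-20, 30.0, 0.5) == {}

    def test_empty_hits_all_absent(self):
        assert call_presence([], ANN) == {}

    def test_unknown_subject_warned_and_ignored(self):
        with pytest.warns(UserWarning, match="not in the glycogene reference"):
            present = call_presence([glyco_hit(subject="NOPE")], ANN)
        assert present == {}

    def test_best_supporting_hit_has_max_bitscore(self):
        hits = [
            glyco_hit(query="a", bitscore=150.0),
            glyco_hit(query="b", bitscore=250.0),
        ]
        assert call_presence(hits, ANN)["G1"].query_id == "b"

    def test_loosening_thresholds_is_monotone(self):
        rng = np.random.default_rng(29)
        queries = [f"t{i}" for i in range(10)]
        hits = []
        for i in range(40):
            L = int(rng.integers(50, 300))
            e = int(rng.integers(1, L + 1))
            hits.append(
                glyco_hit(
                    query=str(rng.choice(queries)),
                    subject=str(rng.choice([a.gene_id for a in ANN])),
                    evalue=10.0 ** float(rng.uniform(-100, 0)),
                    identity=float(rng.uniform(10, 100)),
                    s_start=1, s_end=e, subject_length=L,
                    bitscore=float(rng.uniform(40, 400)),
                )
            )
        for _ in range(50):
            e1, e2 = sorted(10.0 ** rng.uniform(-60, 0, 2))
            i1, i2 = sorted(rng.uniform(0, 100, 2))
            c1, c2 = sorted(rng.uniform(0, 1, 2))
            strict = set(call_presence(hits, ANN, e1, i2, c2))
            loose = set(call_presence(hits, ANN, e2, i1, c1))
            assert strict <= loose


class TestBuildProfile:
    def test_present_gene_gets_best_transcript_tpm(self):
        presence = {"hv": call_presence([glyco_hit()], ANN)}
        expr = {"hv": [ExpressionRecord("t7", tpm=33.2)]}
        rows = build_profile(presence, expr, ANN)
        row = next(r for r in rows if r.gene_id == "G1")
        assert row.present and row.best_transcript == "t7"
        assert row.tpm == pytest.approx(33.2)

    def test_absent_gene_row_is_blank(self):
        rows = build_profile({"hv": {}}, {"hv": []}, ANN)
        assert all(not r.present and r.tpm is None for r in rows)

    def test_two_samples_give_full_cartesian_rows(self):
        rows = build_profile({"a": {}, "b": {}}, {"a": [], "b": []}, ANN)
        assert len(rows) == 2 * len(ANN)

    def test_missing_expression_leaves_tpm_missing_with_warning(self):
        presence = {"hv": call_presence([glyco_hit()], ANN)}
        with pytest.warns(UserWarning, match="absent from the expression"):
            rows = build_profile(presence, {"hv": []}, ANN)
        row = next(r for r in rows if r.gene_id == "G1")
        assert row.present and row.tpm is None

    def test_absent_row_cannot_carry_tpm(self):
        with pytest.raises(ValidationError):
            GlycogeneProfileRow(
                gene_id="G1", sample_id="s", present=False,
                category="c", mechanism="unknown", fold="unknown", tpm=1.0,
            )


def profile_of(present_ids, sample="s", annotations=ANN):
    rows = []
    for a in annotations:
        p = a.gene_id in present_ids
        rows.append(
            GlycogeneProfileRow(
                gene_id=a.gene_id, sample_id=sample, present=p,
                category=a.category, mechanism=a.mechanism, fold=a.fold,
                best_transcript="t1" if p else None, tpm=1.0 if p else None,
            )
        )
    return rows


class TestOverlap:
    def test_set_arithmetic(self):
        a = profile_of({"G1", "G2"}, "a")
        b = profile_of({"G2", "G3"}, "b")
        assert overlap_counts(a, b) == (2, 2, 1)

    def test_self_overlap_is_identity(self):
        a = profile_of({"G1", "G3"})
        assert overlap_counts(a, a) == (2, 2, 2)

    def test_disjoint_sets(self):
        assert overlap_counts(profile_of({"G1"}), profile_of({"G2"}))[2] == 0

    def test_shared_bounded_by_min(self):
        rng = np.random.default_rng(31)
        ids = [a.gene_id for a in ANN]
        for _ in range(50):
            sa = {g for g in ids if rng.random() < 0.5}
            sb = {g for g in ids if rng.random() < 0.5}
            na, nb, shared = overlap_counts(profile_of(sa), profile_of(sb))
            assert shared <= min(na, nb)

    def test_mismatched_references_rejected(self):
        other = [GlycogeneAnnotation("X9", "glycosidase", "unknown", "unknown")]
        with pytest.raises(ValidationError, match="different"):
            overlap_counts(profile_of({"G1"}), profile_of(set(), annotations=other))


class TestCategoriesAndProportions:
    def test_category_counts_cover_present_genes(self):
        profile = profile_of({"G1", "G2"})
        counts = category_counts(profile)
        assert counts == {"sialyltransferase": 1, "fucosyltransferase": 1}
        assert sum(counts.values()) == 2

    def test_mechanism_proportion_worked_example(self):
        anns = [
            GlycogeneAnnotation(f"M{i}", "glycosidase", m, "unknown")
            for i, m in enumerate(
                ["inverting", "inverting", "retaining", "unknown"]
            )
        ]
        mech, fold = mechanism_fold_proportions(
            profile_of({a.gene_id for a in anns}, annotations=anns)
        )
        assert mech["inverting"] == pytest.approx(0.5)
        assert sum(mech.values()) == pytest.approx(1.0, abs=1e-9)
        assert fold["unknown"] == pytest.approx(1.0)

    def test_no_present_genes_yields_explicit_empty(self):
        mech, fold = mechanism_fold_proportions(profile_of(set()))
        assert mech == {} and fold == {}
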