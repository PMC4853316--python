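"""Codon counting, RSCU, and per-amino-acid bias statistics."""

import numpy as np
import pytest

from txprofiler.codon_usage import (
    CodonCountTable,
    bias_stats,
    compare_samples,
    count_codons,
    rscu,
)
from txprofiler.errors import ValidationError
from txprofiler.genetics import (
    AA_TO_CODONS,
    ALL_CODONS,
    AMINO_ACIDS,
    SINGLE_CODON_AAS,
)
from txprofiler.io_formats import TranscriptRecord

from _oracles import brute_rscu
from conftest import random_count_table


def table_from(counts: dict, sample_id="s") -> CodonCountTable:
    full = dict.fromkeys(ALL_CODONS, 0)
    full.update(counts)
    return CodonCountTable(
        sample_id=sample_id, counts=full, n_sequences_used=1, n_sequences_filtered=0
    )


class TestCountCodons:
    def test_in_frame_walk(self):
        recs = [TranscriptRecord(id="c1", sequence="ATGAAAAAATGA")]
        t = count_codons(recs, min_len=0)
        assert t.counts["ATG"] == 1
        assert t.counts["AAA"] == 2
        assert t.counts["TGA"] == 1
        assert t.total_codons() == 4

    def test_ambiguous_triplet_skipped(self):
        recs = [TranscriptRecord(id="c1", sequence="ATGAANAAA")]
        t = count_codons(recs, min_len=0)
        assert t.counts["ATG"] == 1
        assert t.counts["AAA"] == 1
        assert t.n_triplets_skipped == 1

    def test_trailing_remainder_dropped(self):
        recs = [TranscriptRecord(id="c1", sequence="ATGAA")]
        t = count_codons(recs, min_len=0)
        assert t.total_codons() == 1

    def test_length_filter_boundary(self):
        short = TranscriptRecord(id="s", sequence="A" * 299)
        kept = TranscriptRecord(id="k", sequence="AAA" * 100)
        t = count_codons([short, kept])  # default min_len 300
        assert t.n_sequences_filtered == 1
        assert t.n_sequences_used == 1

    def test_all_filtered_is_an_error(self):
        with pytest.raises(ValidationError, match="min_len"):
            count_codons([TranscriptRecord(id="s", sequence="ATG")])

    def test_counts_are_additive_over_disjoint_sets(self):
        rng = np.random.default_rng(3)
        def rand_cds(n, tag):
            return [
                TranscriptRecord(
                    id=f"{tag}{i}",
                    sequence="".join(rng.choice(list("ACGT"), 3 * rng.integers(2, 40))),
                )
                for i in range(n)
            ]
        a, b = rand_cds(10, "a"), rand_cds(7, "b")
        ta = count_codons(a, min_len=0)
        tb = count_codons(b, min_len=0)
        tab = count_codons(a + b, min_len=0)
        assert all(
            tab.counts[c] == ta.counts[c] + tb.counts[c] for c in ALL_CODONS
        )


class TestRSCU:
    def test_lysine_worked_example(self):
        t = table_from({"AAA": 3, "AAG": 1})
        r = rscu(t)
        assert r.rscu["AAA"] == pytest.approx(1.5)
        assert r.rscu["AAG"] == pytest.approx(0.5)

    def test_single_codon_amino_acid_is_one(self):
        r = rscu(table_from({"ATG": 17}))
        assert r.rscu["ATG"] == pytest.approx(1.0)

    def test_uniform_counts_give_rscu_one(self):
        counts = {c: 10 for c in AA_TO_CODONS["L"]}
        r = rscu(table_from(counts))
        for c in AA_TO_CODONS["L"]:
            assert r.rscu[c] == pytest.approx(1.0)

    def test_unobserved_family_is_missing(self):
        r = rscu(table_from({"AAA": 3}))
        for c in AA_TO_CODONS["L"]:
            assert r.rscu[c] is None

    def test_stop_family_excluded_by_default(self):
        t = table_from({"TAA": 5, "TGA": 1})
        assert "TAA" not in rscu(t).rscu
        with_stop = rscu(t, include_stop=True)
        assert with_stop.rscu["TAA"] == pytest.approx(2.5)

    def test_sum_invariant_on_random_tables(self):
        # the family-sum property: values of each observed family sum to n_i
        rng = np.random.default_rng(5)
        for _ in range(200):
            r = rscu(table_from(random_count_table(rng)))
            for aa in AMINO_ACIDS:
                vals = [r.rscu[c] for c in AA_TO_CODONS[aa]]
                if vals[0] is None:
                    continue
                assert sum(vals) == pytest.approx(len(vals), abs=1e-9)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(500):
            counts = random_count_table(rng)
            got = rscu(table_from(counts)).rscu
            expected = brute_rscu(counts)
            assert set(got) == set(expected)
            for c in got:
                if expected[c] is None:
                    assert got[c] is None
                else:
                    assert got[c] == pytest.approx(expected[c], abs=1e-12)


class TestBiasStats:
    def test_two_codon_family_range_and_sd(self):
        stats = bias_stats(rscu(table_from({"AAA": 3, "AAG": 1})))
        k = next(s for s in stats if s.amino_acid == "K")
        assert k.rscu_range == pytest.approx(1.0)
        assert k.rscu_sd == pytest.approx(0.5)  # population SD of {1.5, 0.5}
        assert k.min_codon == "AAG"
        assert k.max_codon == "AAA"

    def test_single_codon_amino_acid_degenerate(self):
        stats = bias_stats(rscu(table_from({"ATG": 5})))
        m = next(s for s in stats if s.amino_acid == "M")
        assert m.rscu_range == 0.0
        assert m.rscu_sd == 0.0

    def test_unobserved_amino_acids_omitted(self):
        stats = bias_stats(rscu(table_from({"AAA": 1})))
        assert {s.amino_acid for s in stats} == {"K"}

    def test_range_consistency_on_random_tables(self):
        rng = np.random.default_rng(13)
        for _ in range(100):
            stats = bias_stats(rscu(table_from(random_count_table(rng))))
            for s in stats:
                assert s.rscu_range == pytest.approx(s.rscu_max - s.rscu_min)
                assert s.rscu_range >= 0
                if s.amino_acid in SINGLE_CODON_AAS:
                    assert s.rscu_sd == 0.0


class TestCompareSamples:
    def test_identical_tables_have_zero_differences(self):
        rng = np.random.default_rng(17)
        counts = random_count_table(rng)
        a = rscu(table_from(counts, "a"))
        b = rscu(table_from(counts, "b"))
        cmp_ = compare_samples([a, b])
        diff = (cmp_.rscu_wide["a"] - cmp_.rscu_wide["b"]).abs()
        assert (diff.dropna() == 0).all()

    def test_single_table_matrix_matches_input(self):
        r = rscu(table_from({"AAA": 3, "AAG": 1}, "only"))
        cmp_ = compare_samples([r])
        assert cmp_.rscu_wide.loc["AAA", "only"] == pytest.approx(1.5)

    def test_family_sums_preserved_in_export(self):
        rng = np.random.default_rng(19)
        tables = [
            rscu(table_from(random_count_table(rng), f"s{i}")) for i in range(3)
        ]
        cmp_ = compare_samples(tables)
        for t in tables:
            for aa in AMINO_ACIDS:
                col = cmp_.rscu_wide.loc[
                    list(AA_TO_CODONS[aa]), t.sample_id
                ]
                if col.isna().any():
                    continue
                assert col.sum() == pytest.approx(len(AA_TO_CODONS[aa]), abs=1e-9)

    def test_duplicate_sample_ids_rejected(self):
        r = rscu(table_from({"AAA": 1}, "dup"))
        with pytest.raises(ValidationError, match="dup"):
            compare_samples([r, r])
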