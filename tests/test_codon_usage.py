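"""RSCU, GC3s, ΔRSCU, optimal-codon inference, Fop, ΔRSCU⁺."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from selfsel import codon_usage as cu
from selfsel.genetic_code import STANDARD_CODE
from selfsel.io import GenotypeSequence
from conftest import random_gene


def seq(nt: str, name: str = "x") -> GenotypeSequence:
    return GenotypeSequence.from_nucleotides(name, nt)


class TestCountCodons:
    def test_simple_gene(self):
        counts = cu.count_codons([seq("ATGAAA")])
        assert counts["ATG"] == 1 and counts["AAA"] == 1 and counts.sum() == 2

    def test_het_codon_contributes_fractional_weights(self):
        counts = cu.count_codons([seq("ARAATG")])
        assert counts["AAA"] == 0.5 and counts["AGA"] == 0.5

    def test_additivity(self):
        a, b = seq("ATGAAA"), seq("CCCGGG")
        combined = cu.count_codons([a, b])
        summed = cu.count_codons([a]) + cu.count_codons([b])
        pd.testing.assert_series_equal(combined, summed, check_names=False)

    def test_empty_input_is_error(self):
        with pytest.raises(ValueError):
            cu.count_codons([])


class TestRSCU:
    def test_uniform_four_fold_family(self):
        counts = pd.Series({c: 10.0 for c in ["GCT", "GCC", "GCA", "GCG"]})
        tbl = cu.rscu(counts)
        assert all(tbl.loc[c, "rscu"] == 1.0 for c in ["GCT", "GCC", "GCA", "GCG"])

    def test_extreme_bias_two_fold(self):
        tbl = cu.rscu(pd.Series({"GAC": 10.0, "GAT": 0.0}))
        assert tbl.loc["GAC", "rscu"] == 2.0 and tbl.loc["GAT", "rscu"] == 0.0

    def test_six_fold_leucine_single_codon(self):
        tbl = cu.rscu(pd.Series({"CTG": 6.0}))
        assert tbl.loc["CTG", "rscu"] == 6.0
        assert tbl.loc["CTA", "rscu"] == 0.0

    def test_zero_family_flagged_undefined(self):
        tbl = cu.rscu(pd.Series({"AAA": 3.0}))
        assert math.isnan(tbl.loc["GAC", "rscu"])

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_family_sums_equal_family_size(self, s):
        rng = np.random.default_rng(s)
        counts = pd.Series(
            rng.integers(0, 50, size=61).astype(float), index=list(STANDARD_CODE.sense_codons)
        )
        tbl = cu.rscu(counts)
        for aa, codons in STANDARD_CODE.aa_to_codons.items():
            fam = tbl.loc[list(codons)]
            if fam["count"].sum() > 0:
                assert math.isclose(fam["rscu"].sum(), len(codons), rel_tol=1e-9)
            else:
                assert fam["rscu"].isna().all()


class TestGC3s:
    def test_half_gc(self):
        assert cu.gc3s(seq("TTTTTC")) == 0.5

    def test_no_eligible_codons_undefined(self):
        assert math.isnan(cu.gc3s(seq("ATGTGG")))

    def test_all_gc_is_one(self):
        assert cu.gc3s(seq("GCCGCG")) == 1.0

    def test_matches_bruteforce_on_random_genes(self, rng):
        code = STANDARD_CODE
        for _ in range(100):
            g = seq(random_gene(rng, 30))
            gc = elig = 0
            for i in range(30):
                codon = g.codons[i]
                if code.is_stop(codon) or code.family_size(codon) < 2:
                    continue
                elig += 1
                gc += codon[2] in "GC"
            expect = gc / elig if elig else math.nan
            got = cu.gc3s(g)
            assert (math.isnan(got) and math.isnan(expect)) or math.isclose(got, expect)


class TestPartition:
    def _table(self, values):
        from selfsel.io import ExpressionTable

        return ExpressionTable(pd.DataFrame({"a": values}, index=[f"g{i:03d}" for i in range(len(values))]))

    def test_decile_of_100(self):
        high, low = cu.partition_by_expression(self._table(list(range(100))), quantile=0.1)
        assert len(high) == len(low) == 10
        assert "g099" in high and "g000" in low

    def test_all_equal_deterministic_by_id(self):
        with pytest.warns(UserWarning):
            high, low = cu.partition_by_expression(self._table([1.0] * 30), quantile=0.1)
        assert low == ["g000", "g001", "g002"] and high == ["g027", "g028", "g029"]

    def test_bad_quantile_rejected(self):
        with pytest.raises(ValueError):
            cu.partition_by_expression(self._table([1, 2, 3]), quantile=0.6)


class TestDeltaRSCU:
    def _counts(self, genes):
        return cu.per_gene_codon_counts(
            {f"g{i}": seq(nt) for i, nt in enumerate(genes)}
        )

    def test_identical_usage_gives_zero_delta_no_optimal(self):
        genes = ["GACGATAAA"] * 6
        counts = self._counts(genes)
        tbl = cu.delta_rscu(counts, ["g0", "g1", "g2"], ["g3", "g4", "g5"])
        assert tbl.loc["GAC", "delta_rscu"] == 0.0
        assert not tbl["optimal"].any()

    def test_hand_computed_asp_contrast(self):
        # high genes GAC:3 GAT:1 -> RSCU(GAC)=1.5; low genes GAC:1 GAT:3 -> 0.5
        high = ["GACGACGACGAT"] * 3
        low = ["GACGATGATGAT"] * 3
        counts = self._counts(high + low)
        tbl = cu.delta_rscu(counts, ["g0", "g1", "g2"], ["g3", "g4", "g5"])
        assert math.isclose(tbl.loc["GAC", "delta_rscu"], 1.0)
        assert math.isclose(tbl.loc["GAT", "delta_rscu"], -1.0)
        assert tbl.loc["GAC", "optimal"]  # zero within-group variance, separated

    def test_antisymmetric_under_set_swap(self, rng):
        genes = {f"g{i}": seq(random_gene(rng, 40)) for i in range(12)}
        counts = cu.per_gene_codon_counts(genes)
        ids = list(genes)
        a = cu.delta_rscu(counts, ids[:6], ids[6:])["delta_rscu"]
        b = cu.delta_rscu(counts, ids[6:], ids[:6])["delta_rscu"]
        pd.testing.assert_series_equal(a, -b, check_names=False)

    def test_gene_order_within_group_irrelevant(self, rng):
        genes = {f"g{i}": seq(random_gene(rng, 30)) for i in range(8)}
        counts = cu.per_gene_codon_counts(genes)
        ids = list(genes)
        a = cu.delta_rscu(counts, ids[:4], ids[4:])
        b = cu.delta_rscu(counts, ids[:4][::-1], ids[4:][::-1])
        pd.testing.assert_frame_equal(a, b)


class TestConsensusOptimal:
    def _table(self, optimal, deltas):
        tbl = pd.DataFrame(
            index=list(STANDARD_CODE.sense_codons),
            data={
                "amino_acid": [STANDARD_CODE.translate(c) for c in STANDARD_CODE.sense_codons],
                "delta_rscu": 0.0,
                "optimal": False,
            },
        )
        for c, d in deltas.items():
            tbl.loc[c, "delta_rscu"] = d
        for c in optimal:
            tbl.loc[c, "optimal"] = True
        return tbl

    def test_single_genotype_passthrough(self):
        t = self._table({"GAC"}, {"GAC": 0.3})
        out = cu.consensus_optimal({"g1": t})
        assert out.consensus == {"D": "GAC"}

    def test_tie_break_by_mean_delta(self):
        t = self._table({"GCC", "GCG"}, {"GCC": 0.3, "GCG": 0.2})
        out = cu.consensus_optimal({"g1": t, "g2": t})
        assert out.consensus["A"] == "GCC"

    def test_codon_missing_in_one_genotype_excluded(self):
        t1 = self._table({"GAC"}, {"GAC": 0.3})
        t2 = self._table(set(), {"GAC": 0.3})
        with pytest.warns(UserWarning):
            out = cu.consensus_optimal({"g1": t1, "g2": t2})
        assert out.consensus == {}
        assert out.per_genotype["g1"] == frozenset({"GAC"})


class TestFop:
    def test_all_optimal_gene_is_one(self):
        assert cu.fop(seq("GACGAC"), {"GAC"}) == 1.0

    def test_no_degenerate_codons_undefined(self):
        assert math.isnan(cu.fop(seq("ATGTGG"), {"GAC"}))

    def test_quarter(self):
        assert cu.fop(seq("GACGATGATGAT"), {"GAC"}) == 0.25

    def test_concatenation_bounded_by_parts(self, rng):
        optimal = {"GAC", "GCC", "AAG"}
        for _ in range(20):
            a, b = random_gene(rng, 20), random_gene(rng, 25)
            fa, fb = cu.fop(seq(a), optimal), cu.fop(seq(b), optimal)
            fab = cu.fop(seq(a + b), optimal)
            if math.isnan(fa) or math.isnan(fb):
                continue
            assert min(fa, fb) - 1e-12 <= fab <= max(fa, fb) + 1e-12

    def test_matches_bruteforce_on_random_genes(self, rng):
        code = STANDARD_CODE
        optimal = {"GAC", "GCC", "AAG", "CTC"}
        for _ in range(100):
            g = seq(random_gene(rng, 25))
            num = den = 0
            for codon in g.codons:
                if code.is_stop(codon) or code.family_size(codon) < 2:
                    continue
                den += 1
                num += codon in optimal
            expect = num / den if den else math.nan
            got = cu.fop(g, optimal)
            assert (math.isnan(got) and math.isnan(expect)) or math.isclose(got, expect)


class TestDeltaRscuPlus:
    def _tbl(self, deltas):
        return pd.DataFrame({"delta_rscu": pd.Series(deltas)})

    def test_mean_of_positives(self):
        res = cu.delta_rscu_plus(self._tbl({"A": 0.2, "B": 0.4}))
        assert math.isclose(res.mean, 0.3)

    def test_no_positive_values_undefined(self):
        assert math.isnan(cu.delta_rscu_plus(self._tbl({"A": -0.1, "B": 0.0})).mean)

    def test_negative_values_do_not_shift_statistic(self):
        a = cu.delta_rscu_plus(self._tbl({"A": 0.2, "B": 0.4}))
        b = cu.delta_rscu_plus(self._tbl({"A": 0.2, "B": 0.4, "C": -0.5}))
        assert a.mean == b.mean
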