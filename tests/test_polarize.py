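"""Outgroup-parsimony polarization, change classification, site counting, diversity."""

import math

import numpy as np
import pytest

from selfsel import polarize as _  # noqa: F401  (module import path exercised via package)
from selfsel.genetic_code import BASES, STANDARD_CODE
from selfsel.io import GenotypeSequence
from selfsel.polarize import (
    ANCESTRAL_BRANCH,
    branch_counts,
    classify_change,
    diversity_summary,
    nei_gojobori_sites,
    polarize,
    watterson_theta,
)
from conftest import make_alignment, random_gene


class TestClassifyChange:
    def test_synonymous_u2p(self):
        cls = classify_change("CTG", "CTC", preferred=frozenset({"CTC"}))
        assert cls.syn == 1.0 and cls.nonsyn == 0.0 and cls.u2p == 1.0

    def test_nonsynonymous_no_bias_class(self):
        cls = classify_change("AAA", "AGA")
        assert cls.nonsyn == 1.0 and cls.syn == 0.0
        assert cls.u2p == cls.p2u == cls.p2p == cls.u2u == 0.0
        assert cls.nonsyn_events == (("K", "R", 1.0),)

    def test_identity_rejected(self):
        with pytest.raises(ValueError):
            classify_change("GAC", "GAC")

    def test_two_hit_path_averaging(self):
        # AAA(K)->AGG(R): via AGA (nonsyn, then syn) or AAG (syn, then nonsyn)
        cls = classify_change("AAA", "AGG")
        assert math.isclose(cls.syn, 1.0) and math.isclose(cls.nonsyn, 1.0)

    def test_stop_crossing_paths_dropped(self):
        # TCA(S)->TAT(Y): the path via TAA (stop) is dropped, leaving TCA->TCT->TAT
        cls = classify_change("TCA", "TAT")
        assert math.isclose(cls.syn, 1.0) and math.isclose(cls.nonsyn, 1.0)

    def test_bias_classes_partition_synonymous_total(self, rng):
        pref = frozenset({"GAC", "GCC", "CTC", "AAG"})
        codons = STANDARD_CODE.sense_codons
        for _ in range(200):
            a, b = (codons[rng.integers(len(codons))] for _ in range(2))
            if a == b:
                continue
            cls = classify_change(a, b, preferred=pref)
            if cls is None:
                continue
            assert math.isclose(cls.u2p + cls.p2u + cls.p2p + cls.u2u, cls.syn, abs_tol=1e-12)
            n_diff = sum(x != y for x, y in zip(a, b))
            assert math.isclose(cls.syn + cls.nonsyn, n_diff, abs_tol=1e-12)


class TestPolarize:
    def test_unique_derived_goes_to_terminal_branch(self):
        aln = make_alignment(
            {"out": "AAA", "g1": "AAA", "g2": "AAA", "g3": "AAG"}
        )
        changes, _ = polarize(aln)
        assert len(changes) == 1
        ch = changes[0]
        assert ch.branch == "g3" and ch.derived == "AAG" and ch.weight == 1.0

    def test_shared_derived_goes_to_ancestral_branch(self):
        aln = make_alignment(
            {"out": "AAA", "g1": "AAG", "g2": "AAG", "g3": "AAG"}
        )
        changes, _ = polarize(aln)
        assert len(changes) == 1 and changes[0].branch == ANCESTRAL_BRANCH

    def test_het_contributes_half_weight(self):
        aln = make_alignment(
            {"out": "AAA", "g1": "AAA", "g2": "ARA", "g3": "AAA"}
        )
        changes, _ = polarize(aln)
        assert len(changes) == 1
        ch = changes[0]
        assert ch.branch == "g2" and ch.derived == "AGA" and ch.weight == 0.5

    def test_outgroup_het_column_skipped(self):
        aln = make_alignment(
            {"out": "ARA", "g1": "AAA", "g2": "AGA", "g3": "AAA"}
        )
        changes, skipped = polarize(aln)
        assert changes == [] and skipped == 1

    def test_counts_invariant_to_genotype_relabelling(self, rng):
        seqs = {"out": random_gene(rng, 15)}
        base = random_gene(rng, 15)
        for g in ["g1", "g2", "g3"]:
            seqs[g] = base
        aln1 = make_alignment(seqs)
        renamed = {("out" if k == "out" else {"g1": "g3", "g2": "g1", "g3": "g2"}[k]): v
                   for k, v in seqs.items()}
        aln2 = make_alignment(renamed)
        c1 = branch_counts(polarize(aln1)[0])
        c2 = branch_counts(polarize(aln2)[0])
        assert c1.get(ANCESTRAL_BRANCH, None) == c2.get(ANCESTRAL_BRANCH, None) or (
            c1[ANCESTRAL_BRANCH].n_changes == c2[ANCESTRAL_BRANCH].n_changes
        )

    def test_het_averaging_equals_explicit_haplotype_runs(self):
        """Weighted single run == average of runs over explicit phasings."""
        het = {"out": "CATAAACCC", "g1": "CATAAACCC", "g2": "CRTAAYCCC", "g3": "CATAAACCC"}
        aln = make_alignment(het)
        weighted = branch_counts(polarize(aln)[0])

        import itertools

        from selfsel.io import expand_codon

        combos = []
        g2 = GenotypeSequence.from_nucleotides("g2", het["g2"])
        per_codon = [expand_codon(g2.codons[i]) for i in range(len(g2))]
        for combo in itertools.product(*per_codon):
            nt = "".join(c for c, _ in combo)
            w = 1.0
            for _, wi in combo:
                w *= wi
            combos.append((nt, w))
        agg = {}
        for nt, w in combos:
            sub = dict(het)
            sub["g2"] = nt
            cc = branch_counts(polarize(make_alignment(sub))[0])
            for b, c in cc.items():
                cur = agg.setdefault(b, [0.0, 0.0])
                cur[0] += w * c.n_syn
                cur[1] += w * c.n_nonsyn
        for b, (syn, nonsyn) in agg.items():
            assert math.isclose(weighted[b].n_syn, syn, abs_tol=1e-12)
            assert math.isclose(weighted[b].n_nonsyn, nonsyn, abs_tol=1e-12)

    def test_bruteforce_oracle_random_single_hit_loci(self, rng):
        """Exhaustive per-column enumeration on 100 random homozygous loci."""
        code = STANDARD_CODE
        pref = frozenset({"GAC", "GCC", "CTC", "AAG", "TTC"})
        for _ in range(100):
            n = 10
            out = [code.sense_codons[rng.integers(61)] for _ in range(n)]
            ing = {g: list(out) for g in ["g1", "g2", "g3"]}
            for g in ing:
                for j in range(n):
                    if rng.random() < 0.3:
                        # single-base change to a sense codon
                        for _try in range(10):
                            pos = rng.integers(3)
                            alt = "ACGT"[rng.integers(4)]
                            cand = out[j][:pos] + alt + out[j][pos + 1 :]
                            if cand != out[j] and not code.is_stop(cand):
                                ing[g][j] = cand
                                break
            aln = make_alignment(
                {"out": "".join(out), **{g: "".join(v) for g, v in ing.items()}}
            )
            got = branch_counts(polarize(aln, preferred=pref)[0])

            # independent oracle
            expect: dict[str, dict[str, float]] = {}
            for j in range(n):
                anc = out[j]
                carriers: dict[str, list[str]] = {}
                for g in ["g1", "g2", "g3"]:
                    if ing[g][j] != anc:
                        carriers.setdefault(ing[g][j], []).append(g)
                for der, gs in carriers.items():
                    branches = [ANCESTRAL_BRANCH] if len(gs) == 3 else gs
                    syn = code.translate(anc) == code.translate(der)
                    for b in branches:
                        e = expect.setdefault(b, {"syn": 0, "nonsyn": 0, "u2p": 0, "p2u": 0})
                        e["syn" if syn else "nonsyn"] += 1
                        if syn:
                            if anc not in pref and der in pref:
                                e["u2p"] += 1
                            elif anc in pref and der not in pref:
                                e["p2u"] += 1
            assert set(got) == set(expect)
            for b, e in expect.items():
                assert math.isclose(got[b].n_syn, e["syn"])
                assert math.isclose(got[b].n_nonsyn, e["nonsyn"])
                assert math.isclose(got[b].n_u2p, e["u2p"])
                assert math.isclose(got[b].n_p2u, e["p2u"])


class TestNeiGojobori:
    def test_phe_third_position(self):
        syn, nonsyn = nei_gojobori_sites(GenotypeSequence.from_nucleotides("x", "TTT"))
        assert math.isclose(syn, 1 / 3) and math.isclose(nonsyn, 8 / 3)

    def test_met_has_no_synonymous_sites(self):
        syn, _ = nei_gojobori_sites(GenotypeSequence.from_nucleotides("x", "ATG"))
        assert syn == 0.0

    def test_conservation_for_every_sense_codon(self):
        for codon in STANDARD_CODE.sense_codons:
            syn, nonsyn = nei_gojobori_sites(GenotypeSequence.from_nucleotides("x", codon))
            assert math.isclose(syn + nonsyn, 3.0, abs_tol=1e-12)

    def test_matches_enumeration_oracle(self, rng):
        code = STANDARD_CODE
        for _ in range(100):
            codon = code.sense_codons[rng.integers(61)]
            syn_expect = 0.0
            for pos in range(3):
                ns = nv = 0
                for b in BASES:
                    if b == codon[pos]:
                        continue
                    alt = codon[:pos] + b + codon[pos + 1 :]
                    if code.is_stop(alt):
                        continue
                    nv += 1
                    ns += code.translate(alt) == code.translate(codon)
                syn_expect += ns / nv if nv else 0.0
            syn, _ = nei_gojobori_sites(GenotypeSequence.from_nucleotides("x", codon))
            assert math.isclose(syn, syn_expect)


class TestBranchCounts:
    def test_empty_changes_give_undefined_ratios(self):
        bc = branch_counts([])
        assert bc == {}

    def test_ratio_arithmetic(self):
        aln = make_alignment(
            {
                "out": "AAACATGGTCCAATG",
                # g1: 3 syn (AAA->AAG, GGT->GGC, CCA->CCG) + 2 nonsyn (CAT->CGT, ATG->ATA)
                "g1": "AAGCGTGGCCCGATA",
                "g2": "AAACATGGTCCAATG",
                "g3": "AAACATGGTCCAATG",
            }
        )
        bc = branch_counts(polarize(aln)[0])
        assert math.isclose(bc["g1"].pn_ps, 2 / 3)

    def test_exclude_het_drops_fractional_changes(self):
        aln = make_alignment({"out": "AAA", "g1": "ARA", "g2": "AAA", "g3": "AAA"})
        assert branch_counts(polarize(aln)[0], exclude_het=True) == {}


class TestDiversity:
    def test_watterson_hand_example(self):
        # n=4 haplotypes: a_3 = 1 + 1/2 + 1/3
        assert math.isclose(watterson_theta(3, 4, 100), 3 / ((1 + 0.5 + 1 / 3) * 100))

    def test_no_variable_sites(self):
        aln = make_alignment({g: "ATGAAACCC" for g in ["out", "g1", "g2", "g3"]})
        div = diversity_summary([aln])
        assert div.site_class_table["S"].sum() == 0
        assert (div.pairwise.to_numpy() == 0).all()

    def test_single_het_gives_half_pairwise_difference(self):
        aln = make_alignment({"out": "AAA", "g1": "ARA", "g2": "AAA", "g3": "AAA"})
        div = diversity_summary([aln])
        assert div.pairwise.loc["g1", "g2"] == 0.5
        assert div.pairwise.loc["g2", "g3"] == 0.0
        assert div.site_class_table["S"].sum() == 1  # het site segregates

    def test_fixed_difference_counts_as_divergent(self):
        aln = make_alignment({"out": "AAG", "g1": "AAA", "g2": "AAA", "g3": "AAA"})
        div = diversity_summary([aln])
        assert div.site_class_table.loc["synonymous", "K"] == 1
        assert div.site_class_table["S"].sum() == 0

    def test_hobs_counts_het_fraction(self):
        aln = make_alignment({"out": "AAA", "g1": "ARA", "g2": "AAA", "g3": "AAA"})
        div = diversity_summary([aln])
        assert math.isclose(div.h_obs["g1"], 1 / 3)
        assert div.h_obs["g2"] == 0.0
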