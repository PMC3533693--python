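"""Outgroup-parsimony polarization, change classification, and diversity summaries.

The ancestral state of each codon column is taken to be the outgroup state
(parsimony with a single outgroup). On the star topology over the three ingroup
genotypes, a derived codon carried by every ingroup genotype is assigned to the
shared ancestral branch; a derived codon carried by a strict subset is assigned
to each carrying terminal branch. Unphased heterozygotes are handled by
enumerating all per-genotype phasings with equal weight and averaging branch
counts over the joint configurations, which reproduces the average-of-two-
haplotypes convention for single-het columns.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genetic_code import BASES, GeneticCode, STANDARD_CODE, resolve_base
from .io import CodonAlignment, GenotypeSequence

ANCESTRAL_BRANCH = "ancestral"


@dataclass
class ChangeClass:
    """Per-unit-weight classification fractions of one codon change."""

    syn: float
    nonsyn: float
    u2p: float
    p2u: float
    p2p: float
    u2u: float
    # (ancestral aa, derived aa, fraction) for non-synonymous steps
    nonsyn_events: tuple[tuple[str, str, float], ...]


def classify_change(
    ancestral: str,
    derived: str,
    code: GeneticCode = STANDARD_CODE,
    preferred: frozenset[str] = frozenset(),
) -> ChangeClass | None:
    """Classify a codon change into synonymous/non-synonymous and bias classes.

    Single-position differences are classified directly. Multi-position
    differences are decomposed over all minimal mutational paths (orderings of
    the differing positions); paths passing through a stop codon are dropped
    and the remainder equally weighted (Nei-Gojobori convention). Returns None
    when every path crosses a stop (the change is excluded).

    Bias classes (U2P/P2U/P2P/U2U) apply to synonymous steps only, from
    membership of the step's start/end codon in the ``preferred`` set.
    """
    if ancestral == derived:
        raise ValueError("identical codons: no change to classify")
    diff = [i for i in range(3) if ancestral[i] != derived[i]]
    paths = []
    for order in itertools.permutations(diff):
        steps = []
        cur = ancestral
        ok = True
        for pos in order:
            nxt = cur[:pos] + derived[pos] + cur[pos + 1 :]
            if code.is_stop(nxt):
                ok = False
                break
            steps.append((cur, nxt))
            cur = nxt
        if ok:
            paths.append(steps)
    if not paths:
        return None
    w = 1.0 / len(paths)
    syn = nonsyn = u2p = p2u = p2p = u2u = 0.0
    events: dict[tuple[str, str], float] = {}
    for steps in paths:
        for c_from, c_to in steps:
            if code.is_synonymous(c_from, c_to):
                syn += w
                pf, pt = c_from in preferred, c_to in preferred
                if not pf and pt:
                    u2p += w
                elif pf and not pt:
                    p2u += w
                elif pf and pt:
                    p2p += w
                else:
                    u2u += w
            else:
                nonsyn += w
                key = (code.translate(c_from), code.translate(c_to))
                events[key] = events.get(key, 0.0) + w
    return ChangeClass(
        syn, nonsyn, u2p, p2u, p2p, u2u,
        tuple((a, b, v) for (a, b), v in sorted(events.items())),
    )


@dataclass
class PolarizedChange:
    """One polarized codon change assigned to a branch, with fractional weight."""

    locus: str
    codon_index: int
    branch: str
    ancestral: str
    derived: str
    weight: float
    classification: ChangeClass

    @property
    def is_het_derived(self) -> bool:
        return self.weight < 1.0 - 1e-12


def polarize(
    alignment: CodonAlignment,
    code: GeneticCode = STANDARD_CODE,
    preferred: frozenset[str] = frozenset(),
    ancestral_branch: str = ANCESTRAL_BRANCH,
) -> tuple[list[PolarizedChange], int]:
    """Polarize all codon columns of one locus onto branches.

    Columns are skipped (and tallied) when gapped, when the outgroup codon is
    ambiguous/heterozygous or a stop, or when a multi-hit change admits no
    stop-free mutational path. Returns (changes, n_skipped_columns).
    """
    out_seq = alignment.sequences[alignment.outgroup]
    ingroup = sorted(alignment.ingroup)
    in_seqs = [alignment.sequences[g] for g in ingroup]
    changes: list[PolarizedChange] = []
    skipped = 0

    for j in range(alignment.length):
        if j in alignment.excluded_columns:
            skipped += 1
            continue
        anc_states = out_seq.codon_states(j, code)
        if anc_states is None or len(anc_states) != 1:
            skipped += 1
            continue
        anc = anc_states[0][0]
        if code.is_stop(anc):
            skipped += 1
            continue

        # fast path: every ingroup codon identical to the (unambiguous) ancestor
        if all(s.codons[j] == anc for s in in_seqs):
            continue

        geno_states: list[tuple[str, list[tuple[str, float]]]] = []
        for g, s in zip(ingroup, in_seqs):
            states = s.codon_states(j, code)
            if states is not None:
                geno_states.append((g, states))
        if not geno_states:
            skipped += 1
            continue

        # accumulate branch weights per derived codon over joint phasings
        branch_weights: dict[tuple[str, str], float] = {}
        names = [g for g, _ in geno_states]
        for combo in itertools.product(*[st for _, st in geno_states]):
            w_cfg = 1.0
            for _, w in combo:
                w_cfg *= w
            carriers: dict[str, list[str]] = {}
            for (g, _), (codon, _) in zip(geno_states, combo):
                if codon != anc:
                    carriers.setdefault(codon, []).append(g)
            for derived, gs in carriers.items():
                if len(gs) == len(names):
                    key = (ancestral_branch, derived)
                    branch_weights[key] = branch_weights.get(key, 0.0) + w_cfg
                else:
                    for g in gs:
                        key = (g, derived)
                        branch_weights[key] = branch_weights.get(key, 0.0) + w_cfg

        for (branch, derived), w in sorted(branch_weights.items()):
            if code.is_stop(derived):
                continue
            cls = _classify_cached(anc, derived, code, preferred)
            if cls is None:
                skipped += 1
                continue
            changes.append(
                PolarizedChange(alignment.locus, j, branch, anc, derived, w, cls)
            )
    return changes, skipped


_CLASSIFY_CACHE: dict[tuple, ChangeClass | None] = {}


def _classify_cached(anc, der, code, preferred):
    # memoized: few distinct (codon, codon, preferred-set) triples per run
    key = (anc, der, id(code), preferred)
    if key not in _CLASSIFY_CACHE:
        _CLASSIFY_CACHE[key] = classify_change(anc, der, code, preferred)
    return _CLASSIFY_CACHE[key]


@dataclass
class BranchChangeCounts:
    """Weighted change tallies for one branch."""

    branch: str
    n_syn: float = 0.0
    n_nonsyn: float = 0.0
    n_u2p: float = 0.0
    n_p2u: float = 0.0
    n_p2p: float = 0.0
    n_u2u: float = 0.0
    n_changes: float = 0.0
    n_deleterious: float = 0.0
    n_nonsyn_classified: float = 0.0

    @property
    def pn_ps(self) -> float:
        return self.n_nonsyn / self.n_syn if self.n_syn > 0 else math.nan

    @property
    def u2p_p2u(self) -> float:
        return self.n_u2p / self.n_p2u if self.n_p2u > 0 else math.nan

    @property
    def deleterious_fraction(self) -> float:
        if self.n_nonsyn_classified > 0:
            return self.n_deleterious / self.n_nonsyn_classified
        return math.nan


def branch_counts(
    changes: Iterable[PolarizedChange], exclude_het: bool = False
) -> dict[str, BranchChangeCounts]:
    """Tally polarized changes per branch.

    ``exclude_het=True`` drops changes with fractional weight (heterozygous,
    i.e. polymorphic within a genotype), mirroring the analysis variant that
    considers fixed differences only.
    """
    out: dict[str, BranchChangeCounts] = {}
    for ch in changes:
        if exclude_het and ch.is_het_derived:
            continue
        bc = out.setdefault(ch.branch, BranchChangeCounts(ch.branch))
        w, cls = ch.weight, ch.classification
        bc.n_changes += w
        bc.n_syn += w * cls.syn
        bc.n_nonsyn += w * cls.nonsyn
        bc.n_u2p += w * cls.u2p
        bc.n_p2u += w * cls.p2u
        bc.n_p2p += w * cls.p2p
        bc.n_u2u += w * cls.u2u
    return out


# -- Nei-Gojobori potential sites ----------------------------------------


@lru_cache(maxsize=None)
def _ng_sites_codon(codon: str, code_key: tuple) -> tuple[float, float]:
    code = _NG_CODES[code_key]
    syn = 0.0
    for pos in range(3):
        n_syn = 0
        n_valid = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if code.is_stop(alt):
                continue  # stops excluded from the denominator
            n_valid += 1
            if code.is_synonymous(codon, alt):
                n_syn += 1
        syn += n_syn / n_valid if n_valid else 0.0
    return syn, 3.0 - syn


_NG_CODES: dict[tuple, GeneticCode] = {}


def nei_gojobori_sites(
    seq: GenotypeSequence, code: GeneticCode = STANDARD_CODE
) -> tuple[float, float]:
    """Potential (synonymous, non-synonymous) site counts for one gene.

    Per codon, the synonymous site count is the sum over the three positions of
    the fraction of non-stop single-base changes that are synonymous; syn +
    nonsyn = 3 for every fully counted codon. Heterozygous codons average over
    phasings; excluded codons contribute 0.
    """
    key = (id(code),)
    _NG_CODES[key] = code
    syn = nonsyn = 0.0
    for i in range(len(seq)):
        states = seq.codon_states(i, code)
        if states is None:
            continue
        for codon, w in states:
            if code.is_stop(codon):
                continue
            s, n = _ng_sites_codon(codon, key)
            syn += w * s
            nonsyn += w * n
    return syn, nonsyn


# -- diversity summary ----------------------------------------------------


def watterson_theta(s: float, n_haplotypes: int, length: float) -> float:
    """Watterson's θ = S / (a_n · L), a_n = Σ_{i=1}^{n−1} 1/i."""
    if n_haplotypes < 2:
        raise ValueError("need at least 2 haplotypes")
    if length <= 0:
        return math.nan
    a_n = sum(1.0 / i for i in range(1, n_haplotypes))
    return s / (a_n * length)


def _site_alleles(ch: str) -> tuple[str, ...] | None:
    bases = resolve_base(ch)
    return tuple(bases) if bases is not None else None


@dataclass
class DiversitySummary:
    """Table-1-style summary: per-class sites/S/K/θ_W, pairwise matrix, H_obs."""

    site_class_table: pd.DataFrame  # index: synonymous/non-synonymous
    pairwise: pd.DataFrame  # genotype x genotype mean pairwise differences
    h_obs: pd.Series  # per-genotype observed heterozygosity
    per_locus_theta: pd.DataFrame  # locus x class θ_W


def diversity_summary(
    alignments: Sequence[CodonAlignment],
    code: GeneticCode = STANDARD_CODE,
    haplotypes_per_genotype: int = 2,
) -> DiversitySummary:
    """Segregating/divergent site counts, Watterson θ and pairwise differences.

    S counts sites segregating among the ingroup haplotypes (2 per diploid
    genotype by default; heterozygous sites segregate by definition). K counts
    fixed divergent sites: all ingroup haplotypes share one allele differing
    from the unambiguous outgroup allele. Each variant site is classed
    synonymous/non-synonymous in the context of the majority ingroup codon.
    θ_W is computed per locus per class over Nei-Gojobori potential sites and
    averaged across loci (dispersion = across-locus SD). Pairwise differences
    average over haplotype pairs, so a het-vs-homozygote mismatch counts 0.5.
    """
    if not alignments:
        raise ValueError("no alignments")
    geno_order = [alignments[0].outgroup] + sorted(alignments[0].ingroup)
    n_geno = len(geno_order)
    pair = np.zeros((n_geno, n_geno))
    het_counts = {g: 0 for g in geno_order}
    called = {g: 0 for g in geno_order}
    totals = {"synonymous": [0.0, 0.0, 0.0], "non-synonymous": [0.0, 0.0, 0.0]}
    theta_rows = []

    for aln in alignments:
        ingroup = sorted(aln.ingroup)
        n_hap = haplotypes_per_genotype * len(ingroup)
        out_seq = aln.sequences[aln.outgroup]
        s_loc = {"synonymous": 0.0, "non-synonymous": 0.0}
        k_loc = {"synonymous": 0.0, "non-synonymous": 0.0}
        # potential sites: mean over ingroup genotypes
        ng = [nei_gojobori_sites(aln.sequences[g], code) for g in ingroup]
        l_syn = float(np.mean([x[0] for x in ng]))
        l_non = float(np.mean([x[1] for x in ng]))

        seqs = {g: aln.sequences[g] for g in geno_order}
        # het / called bookkeeping at nucleotide-string level (fast)
        for g in geno_order:
            nts = seqs[g].nucleotides
            if aln.excluded_columns:
                nts = "".join(
                    nts[3 * j : 3 * j + 3]
                    for j in range(aln.length)
                    if j not in aln.excluded_columns
                )
            n_het = sum(nts.count(c) for c in "RYSWKM")
            n_called = sum(nts.count(c) for c in BASES) + n_het
            het_counts[g] += n_het
            called[g] += n_called

        codon_lists = [seqs[g].codons for g in geno_order]
        first = codon_lists[0]
        for j in range(aln.length):
            if j in aln.excluded_columns:
                continue
            c0 = first[j]
            if (
                all(cl[j] == c0 for cl in codon_lists[1:])
                and c0[0] in BASES and c0[1] in BASES and c0[2] in BASES
            ):
                continue  # invariant unambiguous column
            col = {g: seqs[g].codons[j] for g in geno_order}

            # majority unambiguous ingroup codon provides mutation context
            unamb = [col[g] for g in ingroup if all(ch in BASES for ch in col[g])]
            context = max(set(unamb), key=unamb.count) if unamb else None

            for p in range(3):
                alleles = {g: _site_alleles(col[g][p]) for g in geno_order}
                in_ok = [g for g in ingroup if alleles[g] is not None]
                if not in_ok:
                    continue
                # pairwise differences (all genotype pairs, outgroup included)
                for ai in range(n_geno):
                    for bi in range(ai + 1, n_geno):
                        a, b = alleles[geno_order[ai]], alleles[geno_order[bi]]
                        if a is None or b is None:
                            continue
                        match = sum(
                            (1.0 / len(a)) * (1.0 / len(b)) for x in a for y in b if x == y
                        )
                        pair[ai, bi] += 1.0 - match

                in_union = set()
                for g in in_ok:
                    in_union.update(alleles[g])
                site_class = None
                if len(in_union) > 1 or (
                    alleles[aln.outgroup] is not None
                    and len(alleles[aln.outgroup]) == 1
                    and set(alleles[aln.outgroup]) != in_union
                ):
                    site_class = _classify_site(context, p, sorted(in_union), col, aln, code)
                if len(in_union) > 1:  # segregating among ingroup
                    if site_class:
                        s_loc[site_class] += 1
                out_al = alleles[aln.outgroup]
                if (
                    out_al is not None
                    and len(out_al) == 1
                    and len(in_union) == 1
                    and out_al[0] not in in_union
                ):
                    if site_class:
                        k_loc[site_class] += 1

        totals["synonymous"][0] += l_syn
        totals["synonymous"][1] += s_loc["synonymous"]
        totals["synonymous"][2] += k_loc["synonymous"]
        totals["non-synonymous"][0] += l_non
        totals["non-synonymous"][1] += s_loc["non-synonymous"]
        totals["non-synonymous"][2] += k_loc["non-synonymous"]
        theta_rows.append(
            (
                aln.locus,
                watterson_theta(s_loc["synonymous"], n_hap, l_syn),
                watterson_theta(s_loc["non-synonymous"], n_hap, l_non),
            )
        )

    theta_df = pd.DataFrame(
        theta_rows, columns=["locus", "synonymous", "non-synonymous"]
    ).set_index("locus")
    table = pd.DataFrame(
        {
            "n_sites": {k: v[0] for k, v in totals.items()},
            "S": {k: v[1] for k, v in totals.items()},
            "K": {k: v[2] for k, v in totals.items()},
            "theta_w": theta_df.mean(),
            "theta_w_sd": theta_df.std(ddof=1),
        }
    )
    pair = pair + pair.T
    pairwise = pd.DataFrame(pair, index=geno_order, columns=geno_order)
    h_obs = pd.Series(
        {g: het_counts[g] / called[g] if called[g] else math.nan for g in geno_order},
        name="h_obs",
    )
    return DiversitySummary(table, pairwise, h_obs, theta_df)


def _classify_site(context, pos, allele_list, col, aln, code):
    """Class of a variant nucleotide site given its codon context.

    Uses the majority ingroup codon (falling back to the outgroup codon) as
    context; returns 'synonymous'/'non-synonymous', or None when the context is
    ambiguous or a variant codon is a stop.
    """
    if context is None:
        out_codon = col[aln.outgroup]
        if all(ch in BASES for ch in out_codon):
            context = out_codon
        else:
            return None
    alleles = list(allele_list)
    if len(alleles) < 2:
        # divergence case: compare outgroup allele against the ingroup allele
        out_al = _site_alleles(col[aln.outgroup][pos])
        if out_al is None or len(out_al) != 1:
            return None
        alleles = [alleles[0], out_al[0]]
    c1 = context[:pos] + alleles[0] + context[pos + 1 :]
    c2 = context[:pos] + alleles[1] + context[pos + 1 :]
    if code.is_stop(c1) or code.is_stop(c2):
        return None
    return "synonymous" if code.is_synonymous(c1, c2) else "non-synonymous"
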