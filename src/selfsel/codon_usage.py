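"""Codon-usage bias statistics: RSCU, GC3s, ΔRSCU, optimal codons, Fop, ΔRSCU⁺.

RSCU (relative synonymous codon usage) for codon i in a synonymous family of
size k with counts X_j is ``X_i / ((1/k) * sum_j X_j)``: 1 under uniform usage,
k under exclusive usage. ΔRSCU contrasts mean per-gene RSCU between high- and
low-expression gene sets; codons with significantly positive ΔRSCU are the
putative optimal (translationally preferred) codons, and Fop is the fraction of
a gene's degenerate-family codons drawn from the optimal set.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genetic_code import GeneticCode, STANDARD_CODE
from .io import ExpressionTable, GenotypeSequence


def count_codons(
    seqs: Iterable[GenotypeSequence], code: GeneticCode = STANDARD_CODE
) -> pd.Series:
    """Weighted counts over the 61 sense codons for a set of genes.

    Heterozygous codons contribute the fractional weights of their phasings;
    excluded (ambiguous) codons contribute 0. Raises on empty input.
    """
    seqs = list(seqs)
    if not seqs:
        raise ValueError("count_codons: empty input")
    counts: dict[str, float] = {c: 0.0 for c in code.sense_codons}
    for seq in seqs:
        for i in range(len(seq)):
            states = seq.codon_states(i, code)
            if states is None:
                continue
            for codon, w in states:
                if codon in counts:  # stop codons (terminal leftovers) ignored
                    counts[codon] += w
    return pd.Series(counts, name="count")


def rscu(counts: pd.Series, code: GeneticCode = STANDARD_CODE) -> pd.DataFrame:
    """RSCU per sense codon; families with zero total count are NaN (undefined).

    Within every family with nonzero total, RSCU values sum to the family size.
    """
    rows = []
    for aa, codons in code.aa_to_codons.items():
        fam = counts.reindex(list(codons)).fillna(0.0)
        total = float(fam.sum())
        k = len(codons)
        for codon in codons:
            val = float(fam[codon]) * k / total if total > 0 else math.nan
            rows.append((codon, aa, float(fam[codon]), k, val))
    df = pd.DataFrame(rows, columns=["codon", "amino_acid", "count", "family_size", "rscu"])
    return df.set_index("codon").sort_index()


def per_gene_codon_counts(
    genes: Mapping[str, GenotypeSequence], code: GeneticCode = STANDARD_CODE
) -> pd.DataFrame:
    """Genes x 61 sense codons weighted count matrix."""
    data = {gid: count_codons([seq], code) for gid, seq in genes.items()}
    return pd.DataFrame(data).T.reindex(columns=list(code.sense_codons)).fillna(0.0)


def _rscu_matrix(gene_counts: pd.DataFrame, code: GeneticCode) -> pd.DataFrame:
    """Per-gene RSCU matrix; NaN where a gene's family has zero total count."""
    out = pd.DataFrame(index=gene_counts.index, columns=gene_counts.columns, dtype=float)
    for aa, codons in code.aa_to_codons.items():
        cols = [c for c in codons if c in gene_counts.columns]
        fam = gene_counts[cols]
        totals = fam.sum(axis=1)
        k = len(cols)
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = fam.to_numpy() * k / totals.to_numpy()[:, None]
        vals[totals.to_numpy() == 0] = np.nan
        out[cols] = vals
    return out


def gc3s(seq: GenotypeSequence, code: GeneticCode = STANDARD_CODE) -> float:
    """G+C fraction at third positions of degenerate-family codons.

    Codons of non-degenerate amino acids (Met, Trp) and stops are excluded;
    returns NaN when no eligible codons remain. Heterozygous codons contribute
    their phasing weights.
    """
    gc = 0.0
    eligible = 0.0
    for i in range(len(seq)):
        states = seq.codon_states(i, code)
        if states is None:
            continue
        for codon, w in states:
            if code.is_stop(codon) or code.family_size(codon) < 2:
                continue
            eligible += w
            if codon[2] in "GC":
                gc += w
    return gc / eligible if eligible > 0 else math.nan


def partition_by_expression(
    expression: ExpressionTable | pd.Series,
    gene_ids: Sequence[str] | None = None,
    quantile: float = 0.1,
    genotype: str | None = None,
) -> tuple[list[str], list[str]]:
    """Top/bottom expression-quantile gene sets (default: cross-genotype mean).

    Ties are broken deterministically by gene id. Returns (high, low).
    """
    if not 0 < quantile < 0.5:
        raise ValueError(f"quantile must lie in (0, 0.5), got {quantile}")
    if isinstance(expression, ExpressionTable):
        values = expression.values[genotype] if genotype else expression.mean()
    else:
        values = expression
    if gene_ids is not None:
        values = values.reindex(list(gene_ids)).dropna()
    if len(values) == 0:
        raise ValueError("no genes to partition")
    n = max(1, int(round(quantile * len(values))))
    order = sorted(values.index, key=lambda g: (values[g], g))
    low, high = order[:n], order[-n:]
    if n < 10:
        warnings.warn(f"expression classes have only {n} genes each", stacklevel=2)
    if values.nunique() == 1:
        warnings.warn("all expression values equal; classes set by id order", stacklevel=2)
    return high, low


def delta_rscu(
    gene_counts: pd.DataFrame,
    high: Sequence[str],
    low: Sequence[str],
    code: GeneticCode = STANDARD_CODE,
    alpha: float = 0.05,
    multiple_testing: str | None = None,
) -> pd.DataFrame:
    """ΔRSCU table: mean per-gene RSCU in high- minus low-expression genes.

    For each codon the per-gene RSCU values (genes lacking the codon's family
    omitted) are compared between the two sets by a one-way ANOVA, which for
    two groups equals the pooled-variance two-sample t-test. Codons of
    degenerate families with positive ΔRSCU and p < alpha are flagged optimal.
    ``multiple_testing="bh"`` applies Benjamini-Hochberg across codons.
    """
    rs = _rscu_matrix(gene_counts, code)
    hi, lo = rs.loc[list(high)], rs.loc[list(low)]
    rows = []
    for aa, codons in code.aa_to_codons.items():
        for codon in codons:
            x = hi[codon].dropna().to_numpy()
            y = lo[codon].dropna().to_numpy()
            if len(x) == 0 and len(y) == 0:
                rows.append((codon, aa, math.nan, math.nan, math.nan, 0, 0, math.nan, math.nan))
                continue
            mh = float(np.mean(x)) if len(x) else math.nan
            ml = float(np.mean(y)) if len(y) else math.nan
            delta = mh - ml
            f_stat, p = _two_group_anova(x, y)
            rows.append((codon, aa, mh, ml, delta, len(x), len(y), f_stat, p))
    df = pd.DataFrame(
        rows,
        columns=[
            "codon", "amino_acid", "rscu_high", "rscu_low", "delta_rscu",
            "n_high", "n_low", "statistic", "p_value",
        ],
    ).set_index("codon").sort_index()
    fam_sizes = df["amino_acid"].map(lambda a: code.degeneracy[a])
    p_eff = df["p_value"].copy()
    if multiple_testing == "bh":
        mask = p_eff.notna() & (fam_sizes > 1)
        from statsmodels.stats.multitest import multipletests

        p_eff.loc[mask] = multipletests(p_eff[mask], method="fdr_bh")[1]
    df["p_adjusted"] = p_eff
    df["optimal"] = (fam_sizes > 1) & (df["delta_rscu"] > 0) & (p_eff < alpha)
    return df


def _two_group_anova(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """One-way ANOVA F and p for two groups (== pooled-variance t squared)."""
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        return math.nan, math.nan
    grand = (x.sum() + y.sum()) / (n1 + n2)
    ss_between = n1 * (x.mean() - grand) ** 2 + n2 * (y.mean() - grand) ** 2
    ss_within = ((x - x.mean()) ** 2).sum() + ((y - y.mean()) ** 2).sum()
    df2 = n1 + n2 - 2
    if ss_within == 0:
        if ss_between == 0:
            return 0.0, 1.0
        return math.inf, 0.0
    f = ss_between / (ss_within / df2)
    return float(f), float(sps.f.sf(f, 1, df2))


@dataclass
class OptimalCodonTable:
    """Per-genotype optimal codon sets and the one-per-amino-acid consensus."""

    per_genotype: dict[str, frozenset[str]]
    consensus: dict[str, str]  # amino acid -> codon
    mean_delta: pd.Series  # mean ΔRSCU across genotypes, per codon

    @property
    def consensus_set(self) -> frozenset[str]:
        return frozenset(self.consensus.values())

    @property
    def union_set(self) -> frozenset[str]:
        out: set[str] = set()
        for s in self.per_genotype.values():
            out |= s
        return frozenset(out)


def consensus_optimal(
    per_genotype: Mapping[str, pd.DataFrame], code: GeneticCode = STANDARD_CODE
) -> OptimalCodonTable:
    """Intersect per-genotype optimal sets and keep one codon per amino acid.

    Within an amino acid with several shared optimal codons, the codon with the
    greatest mean ΔRSCU across genotypes is kept (ties broken by codon id).
    """
    if not per_genotype:
        raise ValueError("need at least one genotype ΔRSCU table")
    sets = {g: frozenset(df.index[df["optimal"]]) for g, df in per_genotype.items()}
    shared = frozenset.intersection(*sets.values())
    mean_delta = pd.concat(
        [df["delta_rscu"] for df in per_genotype.values()], axis=1
    ).mean(axis=1)
    consensus: dict[str, str] = {}
    for aa, codons in code.aa_to_codons.items():
        members = [c for c in codons if c in shared]
        if members:
            consensus[aa] = max(members, key=lambda c: (mean_delta[c], c))
    if not shared:
        warnings.warn("optimal-codon intersection across genotypes is empty", stacklevel=2)
    return OptimalCodonTable(sets, consensus, mean_delta)


def fop(
    seq: GenotypeSequence,
    optimal: OptimalCodonTable | frozenset[str] | set[str],
    code: GeneticCode = STANDARD_CODE,
) -> float:
    """Frequency of optimal codons among a gene's degenerate-family codons.

    Denominator excludes Met, Trp and stop codons (non-degenerate); NaN when
    no eligible codons. Heterozygous codons contribute phasing weights.
    """
    opt = optimal.consensus_set if isinstance(optimal, OptimalCodonTable) else frozenset(optimal)
    if not opt:
        raise ValueError("optimal codon set is empty")
    num = 0.0
    denom = 0.0
    for i in range(len(seq)):
        states = seq.codon_states(i, code)
        if states is None:
            continue
        for codon, w in states:
            if code.is_stop(codon) or code.family_size(codon) < 2:
                continue
            denom += w
            if codon in opt:
                num += w
    return num / denom if denom > 0 else math.nan


@dataclass
class DeltaRscuPlus:
    """ΔRSCU⁺: mean of a genotype's positive ΔRSCU values."""

    mean: float
    values: pd.Series  # per-codon positive ΔRSCU values


def delta_rscu_plus(table: pd.DataFrame) -> DeltaRscuPlus:
    """Mean over codons with ΔRSCU > 0; NaN mean when no positive values."""
    pos = table["delta_rscu"][table["delta_rscu"] > 0].dropna()
    return DeltaRscuPlus(float(pos.mean()) if len(pos) else math.nan, pos)


def gene_usage_summary(
    genes_by_genotype: Mapping[str, Mapping[str, GenotypeSequence]],
    expression: ExpressionTable,
    optimal: OptimalCodonTable | frozenset[str],
    high: Sequence[str],
    low: Sequence[str],
    code: GeneticCode = STANDARD_CODE,
) -> pd.DataFrame:
    """Per gene x genotype: Fop, GC3s, length (bp), expression, expression class."""
    hi, lo = set(high), set(low)
    rows = []
    for genotype, genes in genes_by_genotype.items():
        for gid, seq in genes.items():
            if gid not in expression.values.index:
                continue
            expr = float(expression.values.loc[gid, genotype]) if genotype in expression.values.columns else float(expression.mean()[gid])
            cls = "high" if gid in hi else ("low" if gid in lo else "mid")
            rows.append(
                (gid, genotype, fop(seq, optimal, code), gc3s(seq, code),
                 3 * len(seq), expr, cls)
            )
    return pd.DataFrame(
        rows,
        columns=["gene_id", "genotype", "fop", "gc3s", "length_bp", "expression", "expression_class"],
    )
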