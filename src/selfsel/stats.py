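"""Inferential layer: χ² homogeneity, one-way ANOVA, Tukey-Kramer, Fop model.

All tests are classical. The χ² homogeneity test accepts fractional counts
because heterozygote averaging produces half-integer tallies (the averaging of
two unphased haplotypes); a strict-integer mode rounds half-to-even first. No
continuity correction is applied anywhere.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class ContingencyResult:
    observed: np.ndarray
    expected: np.ndarray
    statistic: float
    df: int
    p_value: float
    fractional: bool

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
            "observed": self.observed.tolist(),
        }


def chi2_homogeneity(
    table: Sequence[Sequence[float]] | np.ndarray, integer_mode: bool = False
) -> ContingencyResult:
    """Pearson χ² homogeneity test on an r x c table, no continuity correction.

    Fractional counts (from heterozygote averaging) are accepted as-is with a
    warning; ``integer_mode=True`` rounds half-to-even first. Zero margins are
    an error.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2:
        raise ValueError("table must be 2-dimensional")
    if (obs < 0).any():
        raise ValueError("negative counts")
    fractional = bool(np.any(obs != np.round(obs)))
    if fractional:
        if integer_mode:
            obs = np.round(obs)  # numpy rounds half to even
            fractional = False
        else:
            warnings.warn(
                "fractional counts in chi-square table (heterozygote averaging)",
                stacklevel=2,
            )
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        raise ValueError("zero margin in contingency table")
    expected = np.outer(rows, cols) / obs.sum()
    stat = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return ContingencyResult(obs, expected, stat, df, float(sps.chi2.sf(stat, df)), fractional)


@dataclass
class AnovaResult:
    f: float
    df_between: int
    df_within: int
    p_value: float
    group_means: dict[str, float]
    degenerate: bool = False  # zero within-group variance with separated means

    def to_dict(self) -> dict:
        return {
            "F": None if math.isinf(self.f) else self.f,
            "df": [self.df_between, self.df_within],
            "p_value": self.p_value,
            "degenerate": self.degenerate,
        }


def anova_one_way(groups: Mapping[str, Sequence[float]]) -> AnovaResult:
    """Classical one-way ANOVA over labelled value lists."""
    labels = list(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in labels]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(a) < 1 for a in arrays):
        raise ValueError("empty group")
    n_total = sum(len(a) for a in arrays)
    if n_total - len(arrays) < 1:
        raise ValueError("not enough residual degrees of freedom")
    grand = np.concatenate(arrays).mean()
    ss_between = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df1, df2 = len(arrays) - 1, n_total - len(arrays)
    means = {k: float(a.mean()) for k, a in zip(labels, arrays)}
    if ss_within == 0:
        if ss_between == 0:
            return AnovaResult(0.0, df1, df2, 1.0, means)
        return AnovaResult(math.inf, df1, df2, 0.0, means, degenerate=True)
    f = (ss_between / df1) / (ss_within / df2)
    return AnovaResult(float(f), df1, df2, float(sps.f.sf(f, df1, df2)), means)


def tukey_kramer(
    groups: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> pd.DataFrame:
    """Tukey-Kramer HSD pairwise comparisons (studentized range, unequal n).

    For groups i, j: q = |m_i - m_j| / sqrt(MSW/2 * (1/n_i + 1/n_j)),
    p = studentized-range survival at (k groups, N - k df).
    """
    labels = list(groups)
    arrays = {k: np.asarray(groups[k], dtype=float) for k in labels}
    k = len(labels)
    if k < 2:
        raise ValueError("need at least 2 groups")
    n_total = sum(len(a) for a in arrays.values())
    df_w = n_total - k
    if df_w < 1:
        raise ValueError("not enough residual degrees of freedom")
    msw = sum(((a - a.mean()) ** 2).sum() for a in arrays.values()) / df_w
    rows = []
    for g1, g2 in itertools.combinations(labels, 2):
        a, b = arrays[g1], arrays[g2]
        diff = a.mean() - b.mean()
        se = math.sqrt(msw / 2 * (1 / len(a) + 1 / len(b)))
        if se == 0:
            q = math.inf if diff != 0 else 0.0
            p = 0.0 if diff != 0 else 1.0
        else:
            q = abs(diff) / se
            p = float(sps.studentized_range.sf(q, k, df_w))
        rows.append((g1, g2, float(diff), se, q, p, p < alpha))
    return pd.DataFrame(
        rows, columns=["group1", "group2", "diff", "se", "q", "p_value", "significant"]
    )


@dataclass
class ModelResult:
    """Backward-eliminated least-squares model summary."""

    retained: list[str]
    eliminated: list[str]
    anova_table: pd.DataFrame  # per-term F, p, sum_sq, variance share
    r_squared: float

    def to_dict(self) -> dict:
        return {
            "retained": self.retained,
            "eliminated": self.eliminated,
            "r_squared": self.r_squared,
            "terms": {
                t: {
                    "F": (None if not np.isfinite(r["F"]) else float(r["F"])),
                    "p_value": float(r["PR(>F)"]),
                    "variance_share": float(r["variance_share"]),
                }
                for t, r in self.anova_table.iterrows()
                if t != "Residual"
            },
        }


def _contains(interaction: str, term: str) -> bool:
    return term in interaction.split(":")


def fop_model(
    data: pd.DataFrame,
    group: str = "genotype",
    include_gc3s: bool = True,
    alpha: float = 0.05,
    interactions: bool = True,
) -> ModelResult:
    """Fop covariate model with backward elimination at ``alpha``.

    Fits Fop ~ GC3s + length + expression + group (+ all pairwise
    interactions), then repeatedly removes the least significant term that is
    not part of a retained significant interaction (ties broken by largest p,
    then term name). ``group`` is the categorical factor — genotype or mating
    system; the two cannot be fitted together when one mating class has a
    single genotype. ``include_gc3s=False`` fits the GC3s-excluded variant.
    Variance shares are type-II sums of squares over the total sum of squares.
    """
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    df = data.rename(columns={group: "grp"}).copy()
    needed = ["fop", "length_bp", "expression", "grp"] + (["gc3s"] if include_gc3s else [])
    df = df.dropna(subset=[c for c in needed if c in df.columns])
    main = (["gc3s"] if include_gc3s else []) + ["length_bp", "expression", "C(grp)"]
    if df["grp"].nunique() < 2:
        main.remove("C(grp)")
    terms = list(main)
    if interactions:
        terms += [f"{a}:{b}" for a, b in itertools.combinations(main, 2)]

    eliminated: list[str] = []
    while True:
        formula = "fop ~ " + " + ".join(terms)
        model = smf.ols(formula, data=df).fit()
        if np.linalg.matrix_rank(model.model.exog) < model.model.exog.shape[1]:
            raise ValueError(f"rank-deficient design for terms {terms}")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = anova_lm(model, typ=2)
        pvals = table["PR(>F)"].drop("Residual")
        # a term is removable if non-significant and not inside a significant interaction
        removable = []
        for term in terms:
            p = pvals.get(term, math.nan)
            if not (math.isnan(p) or p >= alpha):
                continue
            in_sig_inter = any(
                ":" in other and _contains(other, term) and pvals.get(other, 1.0) < alpha
                for other in terms
            )
            # never drop a main effect while any of its interactions remain
            still_in_inter = any(
                ":" in other and _contains(other, term) for other in terms
            )
            if ":" not in term and still_in_inter:
                continue
            if not in_sig_inter:
                removable.append((p if not math.isnan(p) else 1.0, term))
        if not removable:
            break
        removable.sort(key=lambda x: (-x[0], x[1]))
        worst = removable[0][1]
        terms.remove(worst)
        eliminated.append(worst)
        if not terms:
            model = smf.ols("fop ~ 1", data=df).fit()
            empty = pd.DataFrame(columns=["sum_sq", "df", "F", "PR(>F)", "variance_share"])
            return ModelResult([], eliminated, empty, float(model.rsquared))

    total_ss = float(((df["fop"] - df["fop"].mean()) ** 2).sum())
    table = table.copy()
    table["variance_share"] = table["sum_sq"] / total_ss
    return ModelResult(terms, eliminated, table, float(model.rsquared))


@dataclass
class DeltaRscuPlusTests:
    genotype_anova: AnovaResult
    mating_anova: AnovaResult
    tukey: pd.DataFrame
    selfer_vs_outcrosser_t: float
    selfer_vs_outcrosser_p: float

    def to_dict(self) -> dict:
        return {
            "genotype_anova": self.genotype_anova.to_dict(),
            "mating_anova": self.mating_anova.to_dict(),
            "selfer_vs_outcrosser": {
                "t": self.selfer_vs_outcrosser_t,
                "p_value": self.selfer_vs_outcrosser_p,
            },
            "tukey": self.tukey.to_dict(orient="records"),
        }


def delta_rscu_plus_tests(
    values_by_genotype: Mapping[str, Sequence[float]],
    mating: Mapping[str, str],
    alpha: float = 0.05,
) -> DeltaRscuPlusTests:
    """ANOVA + Tukey-Kramer on log-transformed positive ΔRSCU values.

    Runs the genotype one-way ANOVA, the mating-system (selfing vs outcrossing)
    ANOVA, pairwise Tukey-Kramer among genotypes, and the selfers-combined vs
    outcrosser two-sample pooled t — all on log ΔRSCU⁺ values. Non-positive
    values are an error (the upstream positive-ΔRSCU filter guarantees none).
    """
    logged: dict[str, np.ndarray] = {}
    for g, vals in values_by_genotype.items():
        arr = np.asarray(vals, dtype=float)
        if (arr <= 0).any():
            raise ValueError(f"non-positive ΔRSCU+ value for genotype {g!r}")
        logged[g] = np.log(arr)
    geno_anova = anova_one_way(logged)
    by_mating: dict[str, list[float]] = {}
    for g, arr in logged.items():
        by_mating.setdefault(mating[g], []).extend(arr.tolist())
    mating_anova = anova_one_way(by_mating)
    tukey = tukey_kramer(logged, alpha=alpha)
    selfers = np.asarray(by_mating.get("selfing", []), dtype=float)
    outs = np.asarray(by_mating.get("outcrossing", []), dtype=float)
    if len(selfers) >= 2 and len(outs) >= 2:
        t, p = sps.ttest_ind(outs, selfers, equal_var=True)
        t, p = float(t), float(p)
    else:
        t = p = math.nan
    return DeltaRscuPlusTests(geno_anova, mating_anova, tukey, t, p)
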