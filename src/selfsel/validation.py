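"""Truth-known validation experiments on synthetic data.

These are the package's own end-to-end checks: simulate a dataset with known
selection-efficacy structure, run the measurement pipeline, and compare the
measured codon-bias and deleterious-load statistics against the planted truth.
Shared by the test suite and the acceptance script.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from . import codon_usage as cu
from .genetic_code import STANDARD_CODE
from .polarize import ANCESTRAL_BRANCH, BranchChangeCounts, branch_counts, polarize
from .simulate import (
    ANCESTRAL,
    INGROUP,
    OUTGROUP,
    SimulatedDataset,
    SimulationConfig,
    simulate,
)
from .stats import delta_rscu_plus_tests

SELFERS = ("selfer_j", "selfer_n")


@dataclass
class BiasRecovery:
    """Measured codon-bias statistics for one simulated replicate."""

    delta_rscu_plus: dict[str, float]  # per genotype
    u2p_p2u: dict[str, float]  # per branch
    counts: dict[str, BranchChangeCounts]
    n_consensus_optimal: int
    consensus: frozenset[str]
    delta_tables: dict  # per-genotype ΔRSCU DataFrames

    @property
    def selfers_lower_bias(self) -> bool:
        """Selfers-combined ΔRSCU⁺ and U2P/P2U both below the outcrosser."""
        drp_sel = np.mean([self.delta_rscu_plus[g] for g in SELFERS])
        ratio_sel = np.mean([self.u2p_p2u[g] for g in SELFERS])
        return bool(
            drp_sel < self.delta_rscu_plus["outcrosser"]
            and ratio_sel < self.u2p_p2u["outcrosser"]
        )


def measure_bias_recovery(
    dataset: SimulatedDataset,
    quantile: float = 0.1,
    alpha: float = 0.05,
    multiple_testing: str | None = None,
) -> BiasRecovery:
    """ΔRSCU⁺ per genotype and U2P/P2U per branch on one simulated dataset."""
    import warnings

    alns = dataset.alignments()
    genotypes = list(INGROUP) + [OUTGROUP]
    high, low = cu.partition_by_expression(
        dataset.expression, [a.locus for a in alns], quantile
    )
    wanted = set(high) | set(low)
    tables = {}
    for g in genotypes:
        counts = cu.per_gene_codon_counts(
            {a.locus: a.sequences[g] for a in alns if a.locus in wanted}
        )
        tables[g] = cu.delta_rscu(
            counts, high, low, alpha=alpha, multiple_testing=multiple_testing
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        optimal = cu.consensus_optimal(tables)
    drp = {g: cu.delta_rscu_plus(tables[g]).mean for g in genotypes}

    changes = []
    for aln in alns:
        ch, _ = polarize(aln, preferred=optimal.consensus_set)
        changes.extend(ch)
    counts = branch_counts(changes)
    ratios = {
        b: counts[b].u2p_p2u if b in counts else math.nan
        for b in list(INGROUP) + [ANCESTRAL_BRANCH]
    }
    return BiasRecovery(
        drp, ratios, counts, len(optimal.consensus), optimal.consensus_set, tables
    )


def neutral_null_replicate(
    seed: int, n_genes: int = 800, codon_length: int = 150
) -> tuple[bool, float]:
    """One neutral replicate (no codon selection, equal efficacy everywhere).

    Optimal-codon calls use the Benjamini-Hochberg switch: an "empty consensus
    in ≥95% of null replicates" statement is a family-wise error claim over 59
    codon tests, which the uncorrected per-codon α cannot provide — especially
    as the four genotypes share one gene sample and are almost perfectly
    correlated, so the cross-genotype intersection filters nothing under the
    null. Returns (consensus empty?, mating-system ANOVA p on log ΔRSCU⁺).
    """
    cfg = SimulationConfig(
        n_genes=n_genes,
        codon_length=codon_length,
        s_max=0.0,
        nu={g: 1.0 for g in list(INGROUP) + [ANCESTRAL, OUTGROUP]},
        seed=seed,
    )
    ds = simulate(cfg)
    rec = measure_bias_recovery(ds, multiple_testing="bh")
    vals = {
        g: cu.delta_rscu_plus(rec.delta_tables[g]).values.to_numpy()
        for g in list(INGROUP) + [OUTGROUP]
    }
    mating = {"outcrosser": "outcrossing", "selfer_j": "selfing",
              "selfer_n": "selfing", OUTGROUP: "selfing"}
    if any(len(v) < 2 for v in vals.values()):
        return rec.n_consensus_optimal == 0, math.nan
    tests = delta_rscu_plus_tests(vals, mating)
    return rec.n_consensus_optimal == 0, tests.mating_anova.p_value


def single_hit_change_sets(
    dataset: SimulatedDataset,
) -> tuple[set[tuple], set[tuple]]:
    """Planted vs pipeline-recovered changes at codons hit exactly once.

    Valid when the dataset was generated with t_outgroup = 0 and no
    heterozygote injection: every single-hit change is then recoverable exactly
    by outgroup parsimony. Returns (truth, measured) sets of
    (branch, gene, codon, ancestral, derived) tuples.
    """
    hits = Counter(
        (rec.gene, rec.codon)
        for ledger in dataset.truth.ledgers.values()
        for rec in ledger
    )
    single = {k for k, v in hits.items() if v == 1}
    truth = {
        (branch, rec.gene, rec.codon, rec.from_codon, rec.to_codon)
        for branch, ledger in dataset.truth.ledgers.items()
        if branch != OUTGROUP
        for rec in ledger
        if (rec.gene, rec.codon) in single
    }
    measured = set()
    for aln in dataset.alignments():
        gene = int(aln.locus.lstrip("g"))
        for ch in polarize(aln)[0]:
            if (gene, ch.codon_index) in single:
                measured.add((ch.branch, gene, ch.codon_index, ch.ancestral, ch.derived))
    return truth, measured
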