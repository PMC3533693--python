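"""End-to-end analysis: from alignments + expression to report tables.

``analyze`` is the in-memory core; ``run_pipeline`` wraps it with file input
and writes the report bundle (TSV tables, stats.json, manifest.json).
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import time
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

import importlib

from . import codon_usage as cu
from . import constraint as ct
from . import stats as st

# the package re-exports a function named `polarize`; fetch the module itself
pz = importlib.import_module(".polarize", __package__)
from .genetic_code import GeneticCode, STANDARD_CODE
from .io import (
    CodonAlignment,
    ExpressionTable,
    read_codon_alignments,
    read_expression_table,
)

log = logging.getLogger("selfsel")


@dataclass
class RunConfig:
    """Pipeline configuration (serialized into the run manifest)."""

    outgroup: str
    mating: dict[str, str]  # ingroup genotype -> "selfing"/"outcrossing"
    quantile: float = 0.1
    alpha: float = 0.05
    multiple_testing: str | None = None
    exclude_het_changes: bool = False
    haplotypes_per_genotype: int = 2
    min_homologs: int = 5
    min_identity: float = 0.6
    tau: float | None = None
    sigma_floor_factor: float = 0.1

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PipelineResult:
    table1: pd.DataFrame
    pairwise: pd.DataFrame
    h_obs: pd.Series
    table2: pd.DataFrame
    delta_rscu_tables: dict[str, pd.DataFrame]
    optimal: cu.OptimalCodonTable
    branch_counts: dict[str, pz.BranchChangeCounts]
    fig4_counts: pd.DataFrame
    fig1_counts: pd.DataFrame | None
    polymorphic_deleterious: pd.DataFrame | None
    delta_rscu_plus: dict[str, cu.DeltaRscuPlus]
    stats: dict
    manifest: dict


def _branch_table(counts: Mapping[str, pz.BranchChangeCounts]) -> pd.DataFrame:
    rows = []
    for b, c in sorted(counts.items()):
        rows.append(
            (b, c.n_changes, c.n_syn, c.n_nonsyn, c.pn_ps, c.n_u2p, c.n_p2u,
             c.n_p2p, c.n_u2u, c.u2p_p2u, c.n_deleterious, c.n_nonsyn_classified,
             c.deleterious_fraction)
        )
    return pd.DataFrame(
        rows,
        columns=["branch", "n_changes", "n_syn", "n_nonsyn", "pn_ps", "n_u2p",
                 "n_p2u", "n_p2p", "n_u2u", "u2p_p2u", "n_deleterious",
                 "n_nonsyn_classified", "deleterious_fraction"],
    ).set_index("branch")


def analyze(
    alignments: Sequence[CodonAlignment],
    expression: ExpressionTable,
    config: RunConfig,
    homologs: Mapping[str, Sequence[str]] | None = None,
    code: GeneticCode = STANDARD_CODE,
    exclusions: Sequence[tuple[str, str]] = (),
) -> PipelineResult:
    """Run the full analysis on validated inputs."""
    t0 = time.time()
    if not alignments:
        raise RuntimeError("stage=input: no alignments to analyse")
    genotypes = sorted(alignments[0].ingroup) + [config.outgroup]

    # per-genotype per-gene sequences; drop loci without expression entries
    have_expr = set(expression.values.index)
    used, dropped_expr = [], []
    for aln in alignments:
        (used if aln.locus in have_expr else dropped_expr).append(aln)
    if dropped_expr:
        log.warning("dropping %d loci without expression entries", len(dropped_expr))
    if not used:
        raise RuntimeError("stage=codon_usage: no loci with expression data")
    genes_by_genotype = {
        g: {aln.locus: aln.sequences[g] for aln in used} for g in genotypes
    }

    # expression partition (cross-genotype mean)
    gene_ids = [aln.locus for aln in used]
    high, low = cu.partition_by_expression(expression, gene_ids, config.quantile)
    log.info("expression classes: %d high, %d low", len(high), len(low))

    # ΔRSCU per genotype and consensus optimal codons
    delta_tables: dict[str, pd.DataFrame] = {}
    for g in genotypes:
        counts = cu.per_gene_codon_counts(
            {gid: genes_by_genotype[g][gid] for gid in high + low}, code
        )
        delta_tables[g] = cu.delta_rscu(
            counts, high, low, code, alpha=config.alpha,
            multiple_testing=config.multiple_testing,
        )
    optimal = cu.consensus_optimal(delta_tables, code)
    preferred = optimal.consensus_set
    log.info(
        "optimal codons: union %d, consensus %d", len(optimal.union_set), len(preferred)
    )

    # per-gene usage summary / table 2
    summary = cu.gene_usage_summary(
        genes_by_genotype, expression, optimal, high, low, code
    ) if preferred else pd.DataFrame(
        columns=["gene_id", "genotype", "fop", "gc3s", "length_bp", "expression", "expression_class"]
    )
    if len(summary):
        table2 = (
            summary.groupby(["expression_class", "genotype"])[
                ["expression", "length_bp", "fop", "gc3s"]
            ]
            .mean()
            .reset_index()
        )
    else:
        table2 = pd.DataFrame(columns=["expression_class", "genotype", "expression", "length_bp", "fop", "gc3s"])

    # polarization and branch counts
    all_changes: list[pz.PolarizedChange] = []
    skipped_columns = 0
    for aln in used:
        changes, skipped = pz.polarize(aln, code, preferred)
        all_changes.extend(changes)
        skipped_columns += skipped
    counts = pz.branch_counts(all_changes, exclude_het=config.exclude_het_changes)
    for g in list(genotypes[:-1]) + [pz.ANCESTRAL_BRANCH]:
        counts.setdefault(g, pz.BranchChangeCounts(g))

    # deleterious classification (needs homolog alignments)
    fig1 = None
    poly_del = None
    if homologs:
        profiles: dict[str, dict[int, ct.ConstraintProfile]] = {}
        scales = ct.PropertyScales.default()
        kept = 0
        need_positions: dict[str, set[int]] = {}
        for ch in all_changes:
            if ch.classification.nonsyn > 0:
                need_positions.setdefault(ch.locus, set()).add(ch.codon_index)
        # polymorphism mode needs aa-polymorphic columns too; build all columns
        by_locus = {aln.locus: aln for aln in used}
        for locus, aln in by_locus.items():
            rows = homologs.get(locus)
            if not rows:
                continue
            focal = ct.translate_focal(aln.sequences[config.outgroup], code)
            ident = ct.mean_identity(rows, focal)
            if not ct.apply_filters(len(rows), ident, config.min_homologs, config.min_identity):
                continue
            kept += 1
            positions = set(need_positions.get(locus, set()))
            positions |= _aa_polymorphic_positions(aln, code)
            profiles[locus] = ct.profiles_for_alignment(
                rows, positions, scales, config.sigma_floor_factor, config.tau
            )
        log.info("constraint analysis: %d loci pass homolog filters", kept)
        counts, _ledger = ct.label_deleterious(all_changes, profiles, counts)
        fig1 = _branch_table(counts)[
            ["n_nonsyn", "n_deleterious", "n_nonsyn_classified", "deleterious_fraction"]
        ]
        poly_del = ct.polymorphic_deleterious(
            [by_locus[l] for l in profiles], profiles, code
        )

    fig4 = _branch_table(counts)[["n_syn", "n_u2p", "n_p2u", "n_p2p", "n_u2u", "u2p_p2u"]]

    # diversity summary (table 1)
    div = pz.diversity_summary(used, code, config.haplotypes_per_genotype)

    # ΔRSCU⁺ per genotype
    drp = {g: cu.delta_rscu_plus(delta_tables[g]) for g in genotypes}

    # inferential layer
    stats_block = _stats_block(config, genotypes, counts, drp, summary)

    manifest = {
        "config": config.to_dict(),
        "n_loci": len(used),
        "n_loci_dropped_no_expression": len(dropped_expr),
        "exclusions": [list(e) for e in exclusions],
        "skipped_columns": skipped_columns,
        "genotypes": genotypes,
        "runtime_s": round(time.time() - t0, 2),
    }
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(config.to_dict(), sort_keys=True).encode()
    ).hexdigest()[:16]

    return PipelineResult(
        div.site_class_table, div.pairwise, div.h_obs, table2, delta_tables,
        optimal, counts, fig4, fig1, poly_del, drp, stats_block, manifest,
    )


def _aa_polymorphic_positions(aln: CodonAlignment, code: GeneticCode) -> set[int]:
    out = set()
    ingroup = sorted(aln.ingroup)
    for j in range(aln.length):
        if j in aln.excluded_columns:
            continue
        aas = set()
        ok = True
        for g in ingroup:
            st = aln.sequences[g].codon_states(j, code)
            if st is None:
                continue
            for c, _ in st:
                aas.add(code.translate(c))
        if len(aas) > 1:
            out.add(j)
    return out


def _stats_block(config, genotypes, counts, drp, summary) -> dict:
    ingroup = [g for g in genotypes if g != config.outgroup]
    out: dict = {}

    # χ² homogeneity of nonsyn:syn across ingroup terminal branches
    tab = [[counts[g].n_nonsyn, counts[g].n_syn] for g in ingroup]
    try:
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore")
            out["pn_ps_homogeneity"] = st.chi2_homogeneity(tab).to_dict()
    except ValueError as exc:
        out["pn_ps_homogeneity"] = {"error": str(exc)}

    # per-genotype U2P/P2U vs the ancestral branch (2x2 each)
    out["u2p_p2u_vs_ancestral"] = {}
    anc = counts.get(pz.ANCESTRAL_BRANCH)
    for g in ingroup:
        tab2 = [
            [counts[g].n_u2p, counts[g].n_p2u],
            [anc.n_u2p, anc.n_p2u],
        ]
        try:
            import warnings as _w

            with _w.catch_warnings():
                _w.simplefilter("ignore")
                out["u2p_p2u_vs_ancestral"][g] = st.chi2_homogeneity(tab2).to_dict()
        except ValueError as exc:
            out["u2p_p2u_vs_ancestral"][g] = {"error": str(exc)}

    # deleterious vs non-deleterious across genotypes, when classified
    if all(counts[g].n_nonsyn_classified > 0 for g in ingroup):
        tab3 = [
            [counts[g].n_deleterious, counts[g].n_nonsyn_classified - counts[g].n_deleterious]
            for g in ingroup
        ]
        try:
            import warnings as _w

            with _w.catch_warnings():
                _w.simplefilter("ignore")
                out["deleterious_homogeneity"] = st.chi2_homogeneity(tab3).to_dict()
        except ValueError as exc:
            out["deleterious_homogeneity"] = {"error": str(exc)}

    # ΔRSCU⁺ tests on log values
    vals = {g: d.values.to_numpy() for g, d in drp.items() if len(d.values)}
    mating = dict(config.mating)
    mating.setdefault(config.outgroup, "selfing")
    if len(vals) >= 2 and all(len(v) >= 2 for v in vals.values()):
        try:
            out["delta_rscu_plus_tests"] = st.delta_rscu_plus_tests(
                vals, mating, config.alpha
            ).to_dict()
        except ValueError as exc:
            out["delta_rscu_plus_tests"] = {"error": str(exc)}
    out["delta_rscu_plus"] = {g: d.mean for g, d in drp.items()}

    # Fop covariate models (genotype model and mating-system model, ±GC3s)
    if len(summary) and summary["fop"].notna().sum() > 10:
        data = summary.copy()
        data["mating"] = data["genotype"].map(mating)
        for label, grp in (("genotype", "genotype"), ("mating_system", "mating")):
            for suffix, inc in (("", True), ("_no_gc3s", False)):
                try:
                    res = st.fop_model(data, group=grp, include_gc3s=inc, alpha=config.alpha)
                    out[f"fop_model_{label}{suffix}"] = res.to_dict()
                except Exception as exc:
                    out[f"fop_model_{label}{suffix}"] = {"error": str(exc)}
    return out


def run_pipeline(
    data_dir: str | Path,
    config: RunConfig,
    outdir: str | Path,
    code: GeneticCode = STANDARD_CODE,
) -> PipelineResult:
    """File-based entry point: read ``loci/`` + ``expression.tsv`` (+ optional
    ``homologs/``) under ``data_dir``, run the analysis, write the bundle."""
    data_dir = Path(data_dir)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    loci_dir = data_dir / "loci" if (data_dir / "loci").is_dir() else data_dir
    try:
        alignments, exclusions = read_codon_alignments(loci_dir, config.outgroup, code)
    except Exception as exc:
        raise RuntimeError(f"stage=read_alignments: {exc}") from exc
    log.info("read %d alignments (%d excluded)", len(alignments), len(exclusions))

    expr_path = data_dir / "expression.tsv"
    if not expr_path.exists():
        raise RuntimeError(f"stage=codon_usage: expression table missing at {expr_path}")
    try:
        expression = read_expression_table(expr_path)
    except Exception as exc:
        raise RuntimeError(f"stage=read_expression: {exc}") from exc

    homologs = None
    hom_dir = data_dir / "homologs"
    if hom_dir.is_dir():
        from Bio import SeqIO

        homologs = {}
        for fp in sorted(hom_dir.glob("*.faa")):
            homologs[fp.stem] = [str(r.seq) for r in SeqIO.parse(str(fp), "fasta")]

    result = analyze(alignments, expression, config, homologs, code, exclusions)
    write_bundle(result, outdir)
    return result


def write_bundle(result: PipelineResult, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.table1.to_csv(outdir / "table1.tsv", sep="\t")
    result.pairwise.to_csv(outdir / "table1_pairwise.tsv", sep="\t")
    result.h_obs.to_csv(outdir / "table1_hobs.tsv", sep="\t")
    result.table2.to_csv(outdir / "table2.tsv", sep="\t", index=False)
    for g, df in result.delta_rscu_tables.items():
        df.to_csv(outdir / f"delta_rscu_{g}.tsv", sep="\t")
    opt = pd.DataFrame(
        [(aa, c, result.optimal.mean_delta[c]) for aa, c in sorted(result.optimal.consensus.items())],
        columns=["amino_acid", "codon", "mean_delta_rscu"],
    )
    opt.to_csv(outdir / "optimal_codons.tsv", sep="\t", index=False)
    result.fig4_counts.to_csv(outdir / "fig4_counts.tsv", sep="\t")
    if result.fig1_counts is not None:
        result.fig1_counts.to_csv(outdir / "fig1_counts.tsv", sep="\t")
    if result.polymorphic_deleterious is not None:
        result.polymorphic_deleterious.to_csv(outdir / "polymorphic_deleterious.tsv", sep="\t")
    with open(outdir / "stats.json", "w") as fh:
        json.dump(_jsonify(result.stats), fh, indent=2, sort_keys=True)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(_jsonify(result.manifest), fh, indent=2, sort_keys=True)


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if math.isnan(f) or math.isinf(f) else f
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj
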