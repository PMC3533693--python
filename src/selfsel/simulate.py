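"""Mutation-selection-drift simulator of orthologous codon alignments.

Generates a truth-known dataset with the statistical structure the analysis
assumes: expression-dependent codon usage bias, lineage-specific relaxation of
selection (efficacy multipliers ν < 1 on selfing branches), a tunable
deleterious structure for non-synonymous changes, and elevated heterozygosity
in the outcrossing genotype.

Model
-----
One preferred codon is planted per degenerate amino-acid family. The ancestral
gene g is sampled at codon equilibrium π(codon) ∝ exp(S_g · 1[preferred])
within each family, with S_g = S_max · F(E_g) and F the CDF of the (lognormal)
expression law — highly expressed genes are more biased. Along each branch,
Poisson(rate × codons) single-base proposals are drawn (transition:transversion
bias κ); proposals creating stops are rejected, and the rest are accepted with
probability proportional to the Kimura relative fixation rate
f(ΔS) = ΔS / (1 − e^(−ΔS)), f(0) = 1, where

* synonymous proposal:     ΔS = ν_l · S_g · (1[new preferred] − 1[old preferred])
* non-synonymous proposal: ΔS = −|Gamma| · ν_l at planted constrained positions,
  0 elsewhere.

Selection enters only through these relative fixation rates — no explicit
Wright-Fisher populations — which suffices to generate the branch-rate
asymmetries the analysis measures. Heterozygous sites are injected post hoc
(independent sites) and encoded as IUPAC codes; homolog protein alignments are
emitted with invariant columns at constrained positions.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genetic_code import (
    ALL_CODONS,
    BASES,
    GeneticCode,
    STANDARD_CODE,
    ambiguity_code,
    codon_to_index,
    index_to_codon,
)
from .io import CodonAlignment, ExpressionTable, GenotypeSequence

OUTGROUP = "outgroup"
INGROUP = ("outcrosser", "selfer_j", "selfer_n")
ANCESTRAL = "ancestral"


def kimura_fixation_weight(delta_s: float) -> float:
    """Relative fixation rate f(ΔS) = ΔS / (1 − e^(−ΔS)); f(0) = 1."""
    if delta_s == 0.0:
        return 1.0
    return delta_s / (1.0 - math.exp(-delta_s))


@dataclass
class SimulationConfig:
    """Generator parameters; defaults are the package's study conditions."""

    n_genes: int = 2000
    codon_length: int = 200  # fixed length; (min, max) tuple for uniform lengths
    codon_length_range: tuple[int, int] | None = None
    expression_mu: float = 3.0  # lognormal log-scale mean
    expression_sigma: float = 1.5
    s_max: float = 1.5  # selection scale on preferred codons
    # branch lengths: expected substitution attempts per codon
    t_terminal: float = 0.05
    t_ancestral: float = 0.1
    t_outgroup: float = 0.1
    # per-lineage selection-efficacy multipliers (selfers < 1)
    nu: dict[str, float] = field(
        default_factory=lambda: {
            "outcrosser": 1.0,
            "selfer_j": 0.2,
            "selfer_n": 0.2,
            ANCESTRAL: 1.0,
            OUTGROUP: 1.0,
        }
    )
    # deleterious structure of non-synonymous changes
    constrained_fraction: float = 0.75
    gamma_shape: float = 2.0
    gamma_scale: float = 1.5
    kappa: float = 2.0  # transition:transversion proposal bias
    # per-genotype heterozygous-site injection rates (per nucleotide)
    het_rate: dict[str, float] = field(
        default_factory=lambda: {
            "outcrosser": 1e-3,
            "selfer_j": 2e-4,
            "selfer_n": 1e-4,
            OUTGROUP: 1e-4,
        }
    )
    n_homologs: int = 12
    homolog_match_prob: float = 0.6  # P(homolog = ancestral residue) at free sites
    # constrained columns admit a coherent allowed set of this size (sampled)
    constrained_set_sizes: tuple[int, ...] = (1, 2, 3)
    constrained_set_probs: tuple[float, ...] = (0.5, 0.3, 0.2)
    seed: int = 0

    mating: dict[str, str] = field(
        default_factory=lambda: {
            "outcrosser": "outcrossing",
            "selfer_j": "selfing",
            "selfer_n": "selfing",
            OUTGROUP: "selfing",
        }
    )

    def validate(self) -> None:
        if self.n_genes < 1 or self.codon_length < 1:
            raise ValueError("n_genes and codon_length must be positive")
        for g in INGROUP + (ANCESTRAL, OUTGROUP):
            if not 0 < self.nu.get(g, 1.0) <= 1.0:
                raise ValueError(f"nu[{g!r}] must lie in (0, 1]")
        if not 0 <= self.constrained_fraction <= 1:
            raise ValueError("constrained_fraction must lie in [0, 1]")
        for g, h in self.het_rate.items():
            if not 0 <= h <= 1:
                raise ValueError(f"het_rate[{g!r}] must lie in [0, 1]")
        if min(self.t_terminal, self.t_ancestral, self.t_outgroup) < 0:
            raise ValueError("branch lengths must be non-negative")
        if self.s_max < 0 or self.kappa <= 0:
            raise ValueError("s_max must be >= 0 and kappa > 0")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass
class ChangeRecord:
    """One accepted substitution in the planted ledger."""

    gene: int
    codon: int  # codon index within gene
    from_codon: str
    to_codon: str
    synonymous: bool
    deleterious: bool
    bias_class: str | None  # U2P/P2U/P2P/U2U for synonymous changes


@dataclass
class SimulationTruth:
    """Planted ground truth: preferred codons, per-gene selection, ledgers."""

    preferred: dict[str, str]  # amino acid -> preferred codon
    s_g: np.ndarray  # per-gene selection strength
    ledgers: dict[str, list[ChangeRecord]]  # branch -> ordered changes
    het_sites: dict[str, list[tuple[int, int, str]]]  # genotype -> (gene, nt, code)
    constrained: np.ndarray  # flat bool array over concatenated codons
    config: SimulationConfig

    @property
    def preferred_set(self) -> frozenset[str]:
        return frozenset(self.preferred.values())

    def branch_truth_counts(self) -> pd.DataFrame:
        """Per-branch planted tallies (syn/nonsyn/U2P/P2U/deleterious)."""
        rows = []
        for branch, ledger in self.ledgers.items():
            syn = sum(r.synonymous for r in ledger)
            nonsyn = len(ledger) - syn
            u2p = sum(r.bias_class == "U2P" for r in ledger)
            p2u = sum(r.bias_class == "P2U" for r in ledger)
            dele = sum(r.deleterious for r in ledger)
            rows.append((branch, len(ledger), syn, nonsyn, u2p, p2u, dele))
        return pd.DataFrame(
            rows,
            columns=["branch", "n_changes", "n_syn", "n_nonsyn", "n_u2p", "n_p2u", "n_deleterious"],
        ).set_index("branch")


@dataclass
class SimulatedDataset:
    """In-memory dataset: codon arrays per node plus emitted artifacts."""

    config: SimulationConfig
    truth: SimulationTruth
    lengths: np.ndarray  # per-gene codon lengths
    offsets: np.ndarray  # gene start offsets into flat arrays
    root: np.ndarray  # flat codon-index array at the root
    nodes: dict[str, np.ndarray]  # node name -> flat codon-index array
    tip_nucleotides: dict[str, list[str]]  # genotype -> per-gene nt strings (with het codes)
    expression: ExpressionTable
    homologs: dict[str, list[str]]  # locus -> homolog protein rows

    def gene_ids(self) -> list[str]:
        return [f"g{i:05d}" for i in range(self.config.n_genes)]

    def alignments(self, code: GeneticCode = STANDARD_CODE) -> list[CodonAlignment]:
        out = []
        genotypes = list(INGROUP) + [OUTGROUP]
        for i, gid in enumerate(self.gene_ids()):
            seqs = {
                g: GenotypeSequence.from_nucleotides(g, self.tip_nucleotides[g][i])
                for g in genotypes
            }
            out.append(CodonAlignment(gid, seqs, OUTGROUP))
        return out

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        (outdir / "loci").mkdir(parents=True, exist_ok=True)
        genotypes = list(INGROUP) + [OUTGROUP]
        for i, gid in enumerate(self.gene_ids()):
            with open(outdir / "loci" / f"{gid}.fa", "w") as fh:
                for g in genotypes:
                    fh.write(f">{g}\n{self.tip_nucleotides[g][i]}\n")
        from .io import write_expression_table

        write_expression_table(self.expression, outdir / "expression.tsv")
        (outdir / "homologs").mkdir(exist_ok=True)
        for gid, rows in self.homologs.items():
            with open(outdir / "homologs" / f"{gid}.faa", "w") as fh:
                for k, row in enumerate(rows):
                    fh.write(f">hom{k}\n{row}\n")
        with open(outdir / "roots.fa", "w") as fh:
            for i, gid in enumerate(self.gene_ids()):
                s = self.root[self.offsets[i] : self.offsets[i] + self.lengths[i]]
                fh.write(f">{gid}\n{''.join(index_to_codon(c) for c in s)}\n")
        truth = {
            "config": _config_dict(self.config),
            "preferred": self.truth.preferred,
            "s_g": self.truth.s_g.tolist(),
            "ledgers": {
                b: [asdict(r) for r in ledger] for b, ledger in self.truth.ledgers.items()
            },
            "het_sites": {
                g: [list(t) for t in sites] for g, sites in self.truth.het_sites.items()
            },
        }
        with open(outdir / "truth.json", "w") as fh:
            json.dump(truth, fh)


def _config_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    if d.get("codon_length_range") is not None:
        d["codon_length_range"] = list(d["codon_length_range"])
    return d


# -- lookup tables over the 64-codon integer space ------------------------

_AA64 = np.array(
    [-1 if STANDARD_CODE.codon_to_aa[c] == "*" else ord(STANDARD_CODE.codon_to_aa[c])
     for c in ALL_CODONS],
    dtype=np.int16,
)
_IS_STOP64 = _AA64 < 0
_FAMSIZE64 = np.array(
    [0 if STANDARD_CODE.codon_to_aa[c] == "*" else STANDARD_CODE.family_size(c)
     for c in ALL_CODONS],
    dtype=np.int16,
)
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


def _pick_preferred(rng: np.random.Generator, code: GeneticCode) -> dict[str, str]:
    """One preferred codon per degenerate family, ending in G or C."""
    preferred = {}
    for aa, codons in code.aa_to_codons.items():
        if len(codons) < 2:
            continue
        gc_enders = [c for c in codons if c[2] in "GC"] or list(codons)
        preferred[aa] = gc_enders[rng.integers(len(gc_enders))]
    return preferred


def simulate(
    config: SimulationConfig | None = None,
    seed: int | None = None,
    code: GeneticCode = STANDARD_CODE,
) -> SimulatedDataset:
    """Run the generator; ``seed`` overrides ``config.seed`` when given."""
    config = config or SimulationConfig()
    config.validate()
    if seed is not None:
        config = SimulationConfig(**{**_config_dict(config), "seed": seed})
        if config.codon_length_range is not None:
            config.codon_length_range = tuple(config.codon_length_range)
    rng = np.random.default_rng(config.seed)

    G = config.n_genes
    if config.codon_length_range is not None:
        lo, hi = config.codon_length_range
        lengths = rng.integers(lo, hi + 1, size=G)
    else:
        lengths = np.full(G, config.codon_length, dtype=np.int64)
    offsets = np.concatenate([[0], np.cumsum(lengths)])[:-1]
    total = int(lengths.sum())

    preferred = _pick_preferred(rng, code)
    pref64 = np.zeros(64, dtype=bool)
    for c in preferred.values():
        pref64[codon_to_index(c)] = True

    # expression and per-gene selection strength
    expr = rng.lognormal(config.expression_mu, config.expression_sigma, size=G)
    cdf = sps.lognorm.cdf(expr, s=config.expression_sigma, scale=math.exp(config.expression_mu))
    s_g = config.s_max * cdf
    s_site = np.repeat(s_g, lengths)

    # ancestral sequence at equilibrium within each family
    root = _sample_equilibrium(rng, s_site, pref64, code)

    constrained = rng.random(total) < config.constrained_fraction

    max_w = kimura_fixation_weight(config.s_max) if config.s_max > 0 else 1.0

    def evolve(parent: np.ndarray, rate: float, nu: float):
        child = parent.copy()
        ledger: list[ChangeRecord] = []
        n = rng.poisson(rate * total)
        sites = rng.integers(0, total, size=n)
        poss = rng.integers(0, 3, size=n)
        us = rng.random(n)
        u_acc = rng.random(n)
        shifts = np.array([4, 2, 0])
        for site, pos, u, ua in zip(sites, poss, us, u_acc):
            cur = child[site]
            shift = shifts[pos]
            base = BASES[(cur >> shift) & 3]
            new_base = _propose_base(base, u, config.kappa)
            new = (cur & ~(3 << shift)) | (BASES.index(new_base) << shift)
            if _IS_STOP64[new]:
                continue
            syn = _AA64[new] == _AA64[cur]
            if syn:
                ds = nu * s_site[site] * (float(pref64[new]) - float(pref64[cur]))
            elif constrained[site]:
                ds = -nu * rng.gamma(config.gamma_shape, config.gamma_scale)
            else:
                ds = 0.0
            if ua * max_w > kimura_fixation_weight(ds):
                continue
            bias = None
            if syn:
                pf, pt = bool(pref64[cur]), bool(pref64[new])
                bias = ("P2" if pf else "U2") + ("P" if pt else "U")
            gene = int(np.searchsorted(offsets, site, side="right") - 1)
            ledger.append(
                ChangeRecord(
                    gene, int(site - offsets[gene]), index_to_codon(int(cur)),
                    index_to_codon(int(new)), bool(syn),
                    bool((not syn) and constrained[site]), bias,
                )
            )
            child[site] = new
        return child, ledger

    ledgers: dict[str, list[ChangeRecord]] = {}
    out_tip, ledgers[OUTGROUP] = evolve(root, config.t_outgroup, config.nu.get(OUTGROUP, 1.0))
    anc_node, ledgers[ANCESTRAL] = evolve(root, config.t_ancestral, config.nu.get(ANCESTRAL, 1.0))
    nodes: dict[str, np.ndarray] = {OUTGROUP: out_tip, ANCESTRAL: anc_node}
    for g in INGROUP:
        nodes[g], ledgers[g] = evolve(anc_node, config.t_terminal, config.nu[g])

    # heterozygote injection (post hoc, independent sites)
    het_sites: dict[str, list[tuple[int, int, str]]] = {}
    tip_nt: dict[str, list[str]] = {}
    for g in list(INGROUP) + [OUTGROUP]:
        seqs = _decode_genes(nodes[g], lengths, offsets)
        sites = _inject_hets(rng, seqs, config.het_rate.get(g, 0.0), code)
        het_sites[g] = sites
        tip_nt[g] = seqs

    expr_df = pd.DataFrame(
        {g: expr * rng.lognormal(0.0, 0.05, size=G) for g in list(INGROUP) + [OUTGROUP]},
        index=[f"g{i:05d}" for i in range(G)],
    )
    expression = ExpressionTable(expr_df)

    homologs = _emit_homologs(rng, root, lengths, offsets, constrained, config)

    truth = SimulationTruth(preferred, s_g, ledgers, het_sites, constrained, config)
    return SimulatedDataset(
        config, truth, lengths, offsets, root, nodes, tip_nt, expression, homologs
    )


def _sample_equilibrium(
    rng: np.random.Generator, s_site: np.ndarray, pref64: np.ndarray, code: GeneticCode
) -> np.ndarray:
    """Sample codons: uniform amino acid, then π ∝ exp(S·1[preferred]) in-family."""
    total = len(s_site)
    aas = sorted(code.aa_to_codons)
    aa_choice = rng.integers(0, len(aas), size=total)
    out = np.empty(total, dtype=np.int16)
    u = rng.random(total)
    for ai, aa in enumerate(aas):
        mask = aa_choice == ai
        codons = np.array([codon_to_index(c) for c in code.aa_to_codons[aa]])
        k = len(codons)
        if k == 1:
            out[mask] = codons[0]
            continue
        is_pref = pref64[codons]
        n_mask = int(mask.sum())
        if not is_pref.any():
            out[mask] = codons[(u[mask] * k).astype(int).clip(max=k - 1)]
            continue
        pref_idx = int(np.argmax(is_pref))
        others = np.delete(codons, pref_idx)
        es = np.exp(s_site[mask])
        p_pref = es / (es + (k - 1))
        um = u[mask]
        take_pref = um < p_pref
        rest = ((um - p_pref) / (1 - p_pref) * (k - 1)).astype(int).clip(0, k - 2)
        vals = np.where(take_pref, codons[pref_idx], others[rest])
        out[mask] = vals
    return out


def _propose_base(base: str, u: float, kappa: float) -> str:
    """Mutation-bias-weighted base proposal: transition weight κ, transversions 1."""
    ts = _TRANSITION[base]
    tvs = [b for b in BASES if b != base and b != ts]
    w_total = kappa + 2.0
    if u * w_total < kappa:
        return ts
    return tvs[0] if u * w_total < kappa + 1.0 else tvs[1]


def _decode_genes(flat: np.ndarray, lengths: np.ndarray, offsets: np.ndarray) -> list[str]:
    codon_strs = np.array(ALL_CODONS)
    out = []
    for i in range(len(lengths)):
        s = flat[offsets[i] : offsets[i] + lengths[i]]
        out.append("".join(codon_strs[s]))
    return out


def _inject_hets(
    rng: np.random.Generator, seqs: list[str], rate: float, code: GeneticCode
) -> list[tuple[int, int, str]]:
    """Flip random nucleotide sites to 2-base IUPAC codes, avoiding stop phasings."""
    if rate <= 0:
        return []
    placed: list[tuple[int, int, str]] = []
    for gi, seq in enumerate(seqs):
        n = rng.binomial(len(seq), rate)
        if n == 0:
            continue
        sites = rng.choice(len(seq), size=n, replace=False)
        chars = list(seq)
        for site in sorted(int(s) for s in sites):
            ref = chars[site]
            if ref not in BASES:
                continue
            alts = [b for b in BASES if b != ref]
            rng.shuffle(alts)
            cstart = 3 * (site // 3)
            codon = chars[cstart : cstart + 3]
            for alt in alts:
                trial = codon.copy()
                trial[site - cstart] = alt
                if "".join(trial) in code.stop_codons or "".join(codon) in code.stop_codons:
                    continue
                chars[site] = ambiguity_code(ref, alt)
                placed.append((gi, site, chars[site]))
                break
        seqs[gi] = "".join(chars)
    return placed


def _emit_homologs(
    rng: np.random.Generator,
    root: np.ndarray,
    lengths: np.ndarray,
    offsets: np.ndarray,
    constrained: np.ndarray,
    config: SimulationConfig,
) -> dict[str, list[str]]:
    """Homolog protein rows per gene.

    Constrained columns draw from a small physicochemically coherent allowed
    set centred on the ancestral residue (conservative substitutions only);
    unconstrained columns show the ancestral residue with probability
    ``homolog_match_prob`` and a uniform-random residue otherwise.
    """
    from .constraint import AMINO_ACIDS, conservative_neighbors

    aa_index = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    max_k = max(config.constrained_set_sizes)
    neighbor_table = np.array(
        [[aa_index[n] for n in conservative_neighbors(aa, max_k)] for aa in AMINO_ACIDS]
    )
    aa_of_codon = np.array(
        [aa_index.get(STANDARD_CODE.codon_to_aa[c], 0) for c in ALL_CODONS]
    )
    aa_chars = np.array(list(AMINO_ACIDS))

    total = int(lengths.sum())
    n_hom = config.n_homologs
    focal = aa_of_codon[root]  # flat int residues
    block = np.tile(focal, (n_hom, 1))

    # constrained columns: uniform draws from the allowed neighbor set
    cons_idx = np.flatnonzero(constrained)
    if len(cons_idx):
        sizes = rng.choice(
            np.asarray(config.constrained_set_sizes),
            size=len(cons_idx),
            p=np.asarray(config.constrained_set_probs),
        )
        draw = rng.integers(0, sizes[None, :], size=(n_hom, len(cons_idx)))
        block[:, cons_idx] = neighbor_table[focal[cons_idx][None, :], draw]

    # unconstrained columns: focal w.p. match_prob, else uniform over 20
    free_idx = np.flatnonzero(~constrained)
    if len(free_idx):
        rand_mask = rng.random((n_hom, len(free_idx))) >= config.homolog_match_prob
        n_rand = int(rand_mask.sum())
        if n_rand:
            sub = block[:, free_idx]
            sub[rand_mask] = rng.integers(0, 20, size=n_rand)
            block[:, free_idx] = sub

    chars = aa_chars[block]  # n_hom x total
    out: dict[str, list[str]] = {}
    for i in range(len(lengths)):
        a, b = offsets[i], offsets[i] + lengths[i]
        out[f"g{i:05d}"] = ["".join(row) for row in chars[:, a:b]]
    return out


def replay(
    truth: SimulationTruth,
    root: np.ndarray,
    offsets: np.ndarray,
    branches: Sequence[str],
) -> np.ndarray:
    """Replay a chain of branch ledgers from the root; returns the tip array.

    ``branches`` is the root-to-tip path, e.g. ``("ancestral", "selfer_j")``.
    """
    seq = root.copy()
    for branch in branches:
        for rec in truth.ledgers[branch]:
            site = offsets[rec.gene] + rec.codon
            if seq[site] != codon_to_index(rec.from_codon):
                raise AssertionError(
                    f"ledger inconsistent at gene {rec.gene} codon {rec.codon}"
                )
            seq[site] = codon_to_index(rec.to_codon)
    return seq


def load_truth(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
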