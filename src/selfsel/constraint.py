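"""Physicochemical-constraint classifier for non-synonymous changes.

A simplified reimplementation of the MAPP idea: each column of a homolog
protein alignment defines, per physicochemical property scale, a mean and
dispersion of the observed residues; a candidate amino acid's deviation score

    D(a) = sum_p ((s_p(a) - mu_p) / max(sigma_p, floor_p))^2

is compared against a chi-square quantile with df = number of scales. Residues
with D above the threshold are "bad" (incompatible), the rest "good". This is
an explicitly simplified stand-in for full MAPP (no tree weighting, no
published score calibration); externally computed per-site good/bad tables can
be supplied instead via :func:`read_external_good_bad`.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genetic_code import GeneticCode, STANDARD_CODE
from .io import CodonAlignment
from .polarize import BranchChangeCounts, PolarizedChange

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# Published per-residue property tables. Provenance:
#   hydropathy        Kyte & Doolittle 1982
#   polarity          Grantham 1974
#   charge            net side-chain charge at pH 7 (His partially protonated)
#   volume            Zamyatnin 1972, side-chain volume (A^3)
#   helix_propensity  Chou & Fasman 1978, P-alpha
#   sheet_propensity  Chou & Fasman 1978, P-beta
_DEFAULT_SCALES: dict[str, dict[str, float]] = {
    "hydropathy": {
        "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
        "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
        "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
        "Y": -1.3, "V": 4.2,
    },
    "polarity": {
        "A": 8.1, "R": 10.5, "N": 11.6, "D": 13.0, "C": 5.5, "Q": 10.5,
        "E": 12.3, "G": 9.0, "H": 10.4, "I": 5.2, "L": 4.9, "K": 11.3,
        "M": 5.7, "F": 5.2, "P": 8.0, "S": 9.2, "T": 8.6, "W": 5.4,
        "Y": 6.2, "V": 5.9,
    },
    "charge": {
        "A": 0.0, "R": 1.0, "N": 0.0, "D": -1.0, "C": 0.0, "Q": 0.0,
        "E": -1.0, "G": 0.0, "H": 0.1, "I": 0.0, "L": 0.0, "K": 1.0,
        "M": 0.0, "F": 0.0, "P": 0.0, "S": 0.0, "T": 0.0, "W": 0.0,
        "Y": 0.0, "V": 0.0,
    },
    "volume": {
        "A": 88.6, "R": 173.4, "N": 114.1, "D": 111.1, "C": 108.5,
        "Q": 143.8, "E": 138.4, "G": 60.1, "H": 153.2, "I": 166.7,
        "L": 166.7, "K": 168.6, "M": 162.9, "F": 189.9, "P": 112.7,
        "S": 89.0, "T": 116.1, "W": 227.8, "Y": 193.6, "V": 140.0,
    },
    "helix_propensity": {
        "A": 1.42, "R": 0.98, "N": 0.67, "D": 1.01, "C": 0.70, "Q": 1.11,
        "E": 1.51, "G": 0.57, "H": 1.00, "I": 1.08, "L": 1.21, "K": 1.16,
        "M": 1.45, "F": 1.13, "P": 0.57, "S": 0.77, "T": 0.83, "W": 1.08,
        "Y": 0.69, "V": 1.06,
    },
    "sheet_propensity": {
        "A": 0.83, "R": 0.93, "N": 0.89, "D": 0.54, "C": 1.19, "Q": 1.10,
        "E": 0.37, "G": 0.75, "H": 0.87, "I": 1.60, "L": 1.30, "K": 0.74,
        "M": 1.05, "F": 1.38, "P": 0.55, "S": 0.75, "T": 1.19, "W": 1.37,
        "Y": 1.47, "V": 1.70,
    },
}


_DEFAULT_INSTANCE = None


@dataclass(frozen=True)
class PropertyScales:
    """Per-amino-acid scores on a set of physicochemical scales."""

    scales: Mapping[str, Mapping[str, float]]

    def __post_init__(self) -> None:
        for name, table in self.scales.items():
            missing = set(AMINO_ACIDS) - set(table)
            if missing:
                raise ValueError(f"scale {name!r} missing amino acids {sorted(missing)}")

    @classmethod
    def default(cls) -> "PropertyScales":
        global _DEFAULT_INSTANCE
        if _DEFAULT_INSTANCE is None:
            _DEFAULT_INSTANCE = cls(_DEFAULT_SCALES)
        return _DEFAULT_INSTANCE

    @property
    def names(self) -> list[str]:
        return list(self.scales)

    def matrix(self) -> pd.DataFrame:
        """Scales x 20 amino acids score matrix."""
        return pd.DataFrame(
            {aa: [self.scales[s][aa] for s in self.names] for aa in AMINO_ACIDS},
            index=self.names,
        )

    def global_sd(self) -> pd.Series:
        """Per-scale SD across the 20 amino acids (sets the sigma floor)."""
        return self.matrix().std(axis=1, ddof=0)


from functools import lru_cache


@lru_cache(maxsize=None)
def conservative_neighbors(aa: str, k: int) -> tuple[str, ...]:
    """The k physicochemically nearest amino acids to ``aa`` (including it).

    Distance is Euclidean over the default scales after per-scale
    standardization; used by the synthetic generator to plant coherent
    allowed-residue sets at constrained positions.
    """
    mat = PropertyScales.default().matrix()
    std = (mat.T - mat.mean(axis=1)) / mat.std(axis=1, ddof=0)
    d = ((std - std.loc[aa]) ** 2).sum(axis=1)
    order = sorted(AMINO_ACIDS, key=lambda a: (float(d[a]), a))
    ranked = [aa] + [a for a in order if a != aa]
    return tuple(ranked[:k])


def default_tau(n_scales: int, quantile: float = 0.95) -> float:
    """Default bad/good threshold: chi-square quantile with df = n_scales."""
    return float(sps.chi2.ppf(quantile, df=n_scales))


@dataclass
class ConstraintProfile:
    """Good/bad amino-acid partition for one alignment column."""

    residues: Counter
    d_scores: Mapping[str, float]
    tau: float

    @property
    def good(self) -> frozenset[str]:
        return frozenset(a for a, d in self.d_scores.items() if d <= self.tau)

    @property
    def bad(self) -> frozenset[str]:
        return frozenset(a for a, d in self.d_scores.items() if d > self.tau)

    def is_bad(self, aa: str) -> bool:
        return self.d_scores[aa] > self.tau


def build_profile(
    column: Sequence[str],
    scales: PropertyScales | None = None,
    sigma_floor_factor: float = 0.1,
    tau: float | None = None,
) -> ConstraintProfile | None:
    """Constraint profile of one homolog-alignment column.

    Gaps and unknown residues are dropped; returns None with fewer than 2
    usable residues. The per-scale dispersion is floored at
    ``sigma_floor_factor`` times the scale's SD over the 20 amino acids, so an
    invariant column does not declare every substitution incompatible by a
    division by zero — it still strongly penalizes them.
    """
    scales = scales or PropertyScales.default()
    residues = [r for r in column if r in AMINO_ACIDS]
    if len(residues) < 2:
        return None
    if tau is None:
        tau = default_tau(len(scales.names))
    mat, floors, aa_index = _scale_arrays(scales)
    obs = mat[:, [aa_index[r] for r in residues]]  # scales x n_residues
    mu = obs.mean(axis=1)
    sigma = np.maximum(obs.std(axis=1, ddof=0), sigma_floor_factor * floors)
    d = (((mat - mu[:, None]) / sigma[:, None]) ** 2).sum(axis=0)
    return ConstraintProfile(Counter(residues), dict(zip(AMINO_ACIDS, d)), tau)


_SCALE_CACHE: dict[int, tuple[np.ndarray, np.ndarray, dict[str, int]]] = {}


def _scale_arrays(scales: PropertyScales):
    cached = _SCALE_CACHE.get(id(scales))
    if cached is None:
        mat = scales.matrix().to_numpy()
        cached = (
            mat,
            mat.std(axis=1, ddof=0),
            {aa: i for i, aa in enumerate(AMINO_ACIDS)},
        )
        _SCALE_CACHE[id(scales)] = cached
    return cached


def translate_focal(seq, code: GeneticCode = STANDARD_CODE) -> str:
    """Protein string of a genotype's codon sequence; ambiguous/het codons -> '-'.

    Used as the focal sequence for homolog identity filtering and for mapping
    alignment columns onto transcript codon positions (1:1, no indels).
    """
    out = []
    for i in range(len(seq)):
        states = seq.codon_states(i, code)
        if states is None or len(states) != 1 or code.is_stop(states[0][0]):
            out.append("-")
        else:
            out.append(code.translate(states[0][0]))
    return "".join(out)


def mean_identity(rows: Sequence[str], focal: str) -> float:
    """Mean pairwise identity of homolog rows to the focal sequence."""
    idents = []
    for row in rows:
        pairs = [(a, b) for a, b in zip(focal, row) if a != "-" and b != "-"]
        if pairs:
            idents.append(sum(a == b for a, b in pairs) / len(pairs))
    return float(np.mean(idents)) if idents else 0.0


def apply_filters(
    n_homologs: int,
    identity: float,
    min_homologs: int = 5,
    min_identity: float = 0.6,
) -> bool:
    """Keep a locus for constraint analysis? (>= min homologs, identity strictly >)."""
    return n_homologs >= min_homologs and identity > min_identity


def profiles_for_alignment(
    rows: Sequence[str],
    positions: Iterable[int] | None = None,
    scales: PropertyScales | None = None,
    sigma_floor_factor: float = 0.1,
    tau: float | None = None,
) -> dict[int, ConstraintProfile]:
    """Build profiles for selected columns (all columns when None)."""
    length = len(rows[0])
    if positions is None:
        positions = range(length)
    out = {}
    for pos in positions:
        if pos >= length:
            continue
        prof = build_profile([r[pos] for r in rows], scales, sigma_floor_factor, tau)
        if prof is not None:
            out[pos] = prof
    return out


def label_deleterious(
    changes: Iterable[PolarizedChange],
    profiles_by_locus: Mapping[str, Mapping[int, ConstraintProfile]],
    counts: Mapping[str, BranchChangeCounts],
) -> tuple[dict[str, BranchChangeCounts], pd.DataFrame]:
    """Polarized mode: label each derived non-synonymous change good/bad.

    Augments the per-branch counts with ``n_deleterious`` and
    ``n_nonsyn_classified`` (changes at positions lacking a profile are left
    unclassified) and returns a per-change label ledger for audit.
    """
    rows = []
    for ch in changes:
        if ch.classification.nonsyn == 0:
            continue
        prof = profiles_by_locus.get(ch.locus, {}).get(ch.codon_index)
        if prof is None:
            continue
        bc = counts.get(ch.branch)
        if bc is None:
            continue
        for _, der_aa, frac in ch.classification.nonsyn_events:
            w = ch.weight * frac
            bad = prof.is_bad(der_aa)
            bc.n_nonsyn_classified += w
            if bad:
                bc.n_deleterious += w
            rows.append((ch.locus, ch.codon_index, ch.branch, der_aa, w, bad))
    ledger = pd.DataFrame(
        rows, columns=["locus", "codon_index", "branch", "derived_aa", "weight", "deleterious"]
    )
    return dict(counts), ledger


def polymorphic_deleterious(
    alignments: Sequence[CodonAlignment],
    profiles_by_locus: Mapping[str, Mapping[int, ConstraintProfile]],
    code: GeneticCode = STANDARD_CODE,
) -> pd.DataFrame:
    """Polymorphism mode: at each amino-acid-polymorphic ingroup site, label
    each genotype's allele(s) deleterious or not.

    Sidesteps ancestral-state assignment entirely: a site enters when the
    ingroup genotypes do not all carry the same residue, and every genotype
    with a determinable allele contributes its (phasing-weighted) residues.
    Returns per-genotype n_deleterious / n_total / fraction.
    """
    tallies: dict[str, list[float]] = {}
    for aln in alignments:
        profs = profiles_by_locus.get(aln.locus)
        if not profs:
            continue
        ingroup = sorted(aln.ingroup)
        for j in range(aln.length):
            if j in aln.excluded_columns:
                continue
            states = {}
            for g in ingroup:
                st = aln.sequences[g].codon_states(j, code)
                if st is not None:
                    states[g] = st
            if len(states) < 2:
                continue
            aa_sets = [
                frozenset(code.translate(c) for c, _ in st) for st in states.values()
            ]
            all_aas = frozenset().union(*aa_sets)
            if len(all_aas) < 2:
                continue  # not amino-acid polymorphic
            prof = profs.get(j)
            if prof is None:
                continue
            for g, st in states.items():
                t = tallies.setdefault(g, [0.0, 0.0])
                for codon, w in st:
                    aa = code.translate(codon)
                    t[1] += w
                    if prof.is_bad(aa):
                        t[0] += w
    rows = [
        (g, d, t, d / t if t > 0 else math.nan)
        for g, (d, t) in sorted(tallies.items())
    ]
    return pd.DataFrame(
        rows, columns=["genotype", "n_deleterious", "n_total", "fraction"]
    ).set_index("genotype")


def read_external_good_bad(path: str | Path) -> dict[str, dict[int, ConstraintProfile]]:
    """Load externally computed per-site allowed-residue tables.

    TSV columns: locus, position (1-based), allowed (string of good amino
    acids). Residues outside the allowed string get a D score above threshold.
    """
    df = pd.read_csv(path, sep="\t", dtype={"locus": str})
    out: dict[str, dict[int, ConstraintProfile]] = {}
    for _, row in df.iterrows():
        allowed = set(str(row["allowed"]))
        d = {aa: (0.0 if aa in allowed else math.inf) for aa in AMINO_ACIDS}
        out.setdefault(str(row["locus"]), {})[int(row["position"]) - 1] = ConstraintProfile(
            Counter(), d, tau=1.0
        )
    return out
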