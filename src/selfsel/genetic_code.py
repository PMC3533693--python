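"""Standard genetic code tables and codon arithmetic.

The code table itself comes from Biopython; this module adds the synonymous-family
bookkeeping the rest of the package needs: family membership, degeneracy, and a
compact integer codec used by the simulator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Mapping

from Bio.Data import CodonTable as _CodonTable

BASES = "ACGT"
STOP = "*"

#: 2-base IUPAC ambiguity codes used to encode unphased heterozygotes.
AMBIG2: Mapping[str, str] = {
    "R": "AG",
    "Y": "CT",
    "S": "CG",
    "W": "AT",
    "K": "GT",
    "M": "AC",
}

_BASE_TO_AMBIG = {frozenset(v): k for k, v in AMBIG2.items()}


def ambiguity_code(a: str, b: str) -> str:
    """IUPAC code for the unordered base pair {a, b} (a != b)."""
    return _BASE_TO_AMBIG[frozenset((a, b))]


def resolve_base(ch: str) -> str | None:
    """Bases a nucleotide character can stand for, or None if not resolvable.

    Returns a 1- or 2-character string; 3/4-base codes (B, D, H, V, N) and
    anything else return None — those sites are treated as ambiguous/excluded.
    """
    if ch in BASES:
        return ch
    return AMBIG2.get(ch)


@dataclass(frozen=True)
class GeneticCode:
    """Codon -> amino acid map plus synonymous-family structure.

    ``codon_to_aa`` has 64 entries; stops map to ``"*"``.
    """

    codon_to_aa: Mapping[str, str] = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.codon_to_aa) != 64:
            raise ValueError("genetic code must cover all 64 codons")

    @classmethod
    def standard(cls) -> "GeneticCode":
        table = _CodonTable.unambiguous_dna_by_id[1]
        mapping = dict(table.forward_table)
        for stop in table.stop_codons:
            mapping[stop] = STOP
        return cls(codon_to_aa=mapping)

    # -- structure -------------------------------------------------------

    @cached_property
    def sense_codons(self) -> tuple[str, ...]:
        return tuple(sorted(c for c, aa in self.codon_to_aa.items() if aa != STOP))

    @cached_property
    def stop_codons(self) -> frozenset[str]:
        return frozenset(c for c, aa in self.codon_to_aa.items() if aa == STOP)

    @cached_property
    def aa_to_codons(self) -> Mapping[str, tuple[str, ...]]:
        fams: dict[str, list[str]] = {}
        for codon in self.sense_codons:
            fams.setdefault(self.codon_to_aa[codon], []).append(codon)
        return {aa: tuple(sorted(cs)) for aa, cs in fams.items()}

    @cached_property
    def degeneracy(self) -> Mapping[str, int]:
        """Synonymous-family size k per amino acid."""
        return {aa: len(cs) for aa, cs in self.aa_to_codons.items()}

    def family_size(self, codon: str) -> int:
        return self.degeneracy[self.codon_to_aa[codon]]

    # -- queries ---------------------------------------------------------

    def translate(self, codon: str) -> str:
        return self.codon_to_aa[codon]

    def is_stop(self, codon: str) -> bool:
        return self.codon_to_aa[codon] == STOP

    def is_synonymous(self, c1: str, c2: str) -> bool:
        a1, a2 = self.codon_to_aa[c1], self.codon_to_aa[c2]
        if STOP in (a1, a2):
            raise ValueError(f"stop codon in synonymy query: {c1}/{c2}")
        return a1 == a2


STANDARD_CODE = GeneticCode.standard()

# -- integer codec (simulator fast path) ---------------------------------

_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


def codon_to_index(codon: str) -> int:
    return 16 * _BASE_INDEX[codon[0]] + 4 * _BASE_INDEX[codon[1]] + _BASE_INDEX[codon[2]]


def index_to_codon(idx: int) -> str:
    return BASES[idx >> 4] + BASES[(idx >> 2) & 3] + BASES[idx & 3]


ALL_CODONS = tuple(index_to_codon(i) for i in range(64))
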