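"""Domain types and readers/writers for codon alignments and expression tables.

Input conventions
-----------------
* One locus = one FASTA file whose headers are genotype ids (or a directory of
  such files). Sequences are codon-aligned CDS, length divisible by 3.
* Unphased heterozygous sites are encoded with 2-base IUPAC codes (R, Y, S, W,
  K, M). Any other non-ACGT character (N, B, D, H, V, ...) marks the codon as
  ambiguous: that genotype's codon column is excluded from all counts.
* Expression tables are TSV: ``gene_id`` column plus one column per genotype,
  FPKM-like non-negative values.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio import SeqIO

from .genetic_code import AMBIG2, BASES, GeneticCode, STANDARD_CODE, resolve_base

GAP = "-"


def expand_codon(codon: str) -> list[tuple[str, float]] | None:
    """Resolve a codon's 2-base IUPAC ambiguities into weighted unambiguous codons.

    Returns ``None`` when the codon contains a gap or an unresolvable character
    (N or a 3/4-base code) — the codon is then excluded from counting. A codon
    with h heterozygous positions expands into 2**h equally weighted phasings
    (phase-agnostic expectation; the paper's averaging of two unphased
    haplotypes is the h = 1 special case).
    """
    options: list[str] = []
    for ch in codon:
        bases = resolve_base(ch)
        if bases is None:
            return None
        options.append(bases)
    combos = list(itertools.product(*options))
    w = 1.0 / len(combos)
    return [("".join(c), w) for c in combos]


@dataclass
class GenotypeSequence:
    """One genotype's codon sequence at one locus (possibly with het codes)."""

    genotype: str
    codons: list[str]

    @classmethod
    def from_nucleotides(cls, genotype: str, seq: str) -> "GenotypeSequence":
        seq = seq.upper()
        if len(seq) % 3 != 0:
            raise ValueError(
                f"sequence length {len(seq)} for {genotype!r} not divisible by 3"
            )
        return cls(genotype, [seq[i : i + 3] for i in range(0, len(seq), 3)])

    @property
    def nucleotides(self) -> str:
        return "".join(self.codons)

    def __len__(self) -> int:  # codons
        return len(self.codons)

    @property
    def het_positions(self) -> set[int]:
        """Nucleotide indices carrying a 2-base ambiguity code."""
        out = set()
        for i, ch in enumerate(self.nucleotides):
            if ch in AMBIG2:
                out.add(i)
        return out

    def is_het_codon(self, i: int) -> bool:
        return any(ch in AMBIG2 for ch in self.codons[i])

    def codon_states(
        self, i: int, code: GeneticCode = STANDARD_CODE
    ) -> list[tuple[str, float]] | None:
        """Weighted unambiguous states of codon i, or None if excluded.

        A heterozygous codon any of whose phasings is a stop codon is excluded
        (its reading cannot be trusted); a homozygous stop is returned as-is and
        left to alignment validation.
        """
        codon = self.codons[i]
        if codon[0] in BASES and codon[1] in BASES and codon[2] in BASES:
            return [(codon, 1.0)]
        states = expand_codon(codon)
        if states is None:
            return None
        if len(states) > 1 and any(code.is_stop(c) for c, _ in states):
            return None
        return states


@dataclass
class CodonAlignment:
    """One locus: genotype -> codon sequence, with a designated outgroup."""

    locus: str
    sequences: dict[str, GenotypeSequence]
    outgroup: str
    excluded_columns: set[int] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.outgroup not in self.sequences:
            raise ValueError(f"outgroup {self.outgroup!r} missing from locus {self.locus!r}")
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            raise ValueError(f"unequal sequence lengths in locus {self.locus!r}")

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values())))

    @property
    def ingroup(self) -> list[str]:
        return [g for g in self.sequences if g != self.outgroup]

    def ingroup_sequences(self) -> dict[str, GenotypeSequence]:
        return {g: s for g, s in self.sequences.items() if g != self.outgroup}


class AlignmentValidationError(ValueError):
    pass


def _validate_and_build(
    locus: str,
    records: Mapping[str, str],
    outgroup_id: str,
    code: GeneticCode,
) -> tuple[CodonAlignment | None, str | None]:
    """Build one validated alignment; returns (alignment, exclusion_reason)."""
    if outgroup_id not in records:
        raise AlignmentValidationError(
            f"locus {locus!r}: outgroup {outgroup_id!r} not among headers {sorted(records)}"
        )
    lengths = {len(s) for s in records.values()}
    if len(lengths) != 1:
        return None, "length_mismatch"
    (length,) = lengths
    if length % 3 != 0:
        return None, "frameshift"

    seqs = {g: GenotypeSequence.from_nucleotides(g, s) for g, s in records.items()}
    n_codons = length // 3

    # gap columns are flagged, not fatal
    excluded = set()
    for j in range(n_codons):
        if any(GAP in s.codons[j] for s in seqs.values()):
            excluded.add(j)

    # strip a terminal stop column if any genotype ends in a stop codon
    if n_codons and any(
        GAP not in s.codons[-1]
        and all(ch in BASES for ch in s.codons[-1])
        and code.is_stop(s.codons[-1])
        for s in seqs.values()
    ):
        n_codons -= 1
        seqs = {g: GenotypeSequence(g, s.codons[:-1]) for g, s in seqs.items()}
        excluded.discard(n_codons)

    # internal stop in an unambiguous codon => the ORF is broken, drop the locus
    for s in seqs.values():
        for j, codon in enumerate(s.codons):
            if j in excluded:
                continue
            if all(ch in BASES for ch in codon) and code.is_stop(codon):
                return None, "internal_stop"

    return CodonAlignment(locus, seqs, outgroup_id, excluded), None


def read_codon_alignments(
    path: str | Path,
    outgroup_id: str,
    code: GeneticCode = STANDARD_CODE,
) -> tuple[list[CodonAlignment], list[tuple[str, str]]]:
    """Read per-locus FASTA file(s) into validated CodonAlignments.

    ``path`` may be a single FASTA file (one locus) or a directory of
    ``*.fa/*.fasta/*.fas`` files. Returns the accepted alignments plus an
    exclusion log of ``(locus, reason)`` pairs for loci failing validation
    (frameshift, internal stop, length mismatch). A missing outgroup header or
    an unreadable file is a hard error.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in {".fa", ".fasta", ".fas"}
        )
        if not files:
            raise FileNotFoundError(f"no FASTA files in directory {path}")
    elif path.is_file():
        files = [path]
    else:
        raise FileNotFoundError(f"no such file or directory: {path}")

    alignments: list[CodonAlignment] = []
    exclusions: list[tuple[str, str]] = []
    for fp in files:
        locus = fp.stem
        try:
            records = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fp), "fasta")}
        except Exception as exc:  # unreadable file: hard error with filename
            raise OSError(f"failed to parse FASTA {fp}: {exc}") from exc
        if not records:
            raise OSError(f"no sequences in FASTA {fp}")
        aln, reason = _validate_and_build(locus, records, outgroup_id, code)
        if aln is None:
            exclusions.append((locus, reason))
        else:
            alignments.append(aln)
    return alignments, exclusions


def write_codon_alignment(alignment: CodonAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for g, s in alignment.sequences.items():
            fh.write(f">{g}\n{s.nucleotides}\n")


@dataclass
class ExpressionTable:
    """Per-gene FPKM-like expression, one column per genotype."""

    values: pd.DataFrame  # index: gene_id, columns: genotypes

    def __post_init__(self) -> None:
        if (self.values < 0).any().any():
            bad = self.values[(self.values < 0).any(axis=1)].index[0]
            raise ValueError(f"negative expression value for gene {bad!r}")
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate gene id {dup!r} in expression table")

    @property
    def genotypes(self) -> list[str]:
        return list(self.values.columns)

    def mean(self) -> pd.Series:
        """Cross-genotype mean expression per gene."""
        return self.values.mean(axis=1)

    def __len__(self) -> int:
        return len(self.values)


def read_expression_table(path: str | Path) -> ExpressionTable:
    """Read a TSV of gene_id + per-genotype FPKM columns.

    Malformed (non-numeric) rows raise with the 1-based file line number.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    gene_col = df.columns[0]
    df = df.set_index(gene_col)
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(df.index.get_indexer_for(df.index[bad])[0])
            raise ValueError(
                f"malformed value {df[col][bad].iloc[0]!r} in column {col!r} "
                f"at line {row + 2} of {path}"
            )
        df[col] = coerced
    if df.isna().any().any():
        row = int(df.isna().any(axis=1).to_numpy().argmax())
        raise ValueError(f"missing value at line {row + 2} of {path}")
    return ExpressionTable(df.astype(float))


def write_expression_table(table: ExpressionTable, path: str | Path) -> None:
    table.values.rename_axis("gene_id").to_csv(path, sep="\t")
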