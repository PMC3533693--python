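"""Outgroup-parsimony polarization of codon changes onto branches.

A four-genotype toy locus (outgroup + three ingroup genotypes, one of them
heterozygous at one site) is polarized; each change lands on the branch
implied by which genotypes carry the derived state.
"""

from selfsel.io import CodonAlignment, GenotypeSequence
from selfsel.polarize import branch_counts, polarize

seqs = {
    "outgroup":  "AAACATGGTCCAATGGAC",
    "outcross":  "AAGCATGGTCCAATGGAC",   # private syn change AAA->AAG
    "selfer1":   "AAACGTGGTCCAATGGAC",   # private nonsyn change CAT->CGT (H->R)
    "selfer2":   "AAACATGGTCCRATGGAC",   # het A/G at one site: CCA / CCG (syn)
}
aln = CodonAlignment(
    "demo", {g: GenotypeSequence.from_nucleotides(g, s) for g, s in seqs.items()},
    outgroup="outgroup",
)

preferred = frozenset({"AAG", "GAC", "CCA"})
changes, skipped = polarize(aln, preferred=preferred)
print("polarized changes (branch, codon, ancestral->derived, weight, class):")
for ch in changes:
    kind = "syn" if ch.classification.syn else "nonsyn"
    print(f"  {ch.branch:10s} codon {ch.codon_index:2d}  "
          f"{ch.ancestral}->{ch.derived}  w={ch.weight:.2f}  {kind}")

counts = branch_counts(changes)
print("\nper-branch tallies:")
for b, c in sorted(counts.items()):
    print(f"  {b:10s} syn={c.n_syn:.2f} nonsyn={c.n_nonsyn:.2f} "
          f"U2P={c.n_u2p:.2f} P2U={c.n_p2u:.2f}")
print("\nInterpretation: the heterozygous change counts 0.5 (average of the two")
print("unphased haplotypes); a derived state shared by all ingroup genotypes")
print("would instead be assigned to the shared ancestral branch.")
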