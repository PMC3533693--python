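"""Codon-usage bias on a small gene set: RSCU, ΔRSCU, optimal codons, Fop.

Builds a toy expression-stratified gene sample in which highly expressed genes
prefer C-ending codons, then recovers that preference from the ΔRSCU contrast.
"""

import numpy as np

from selfsel import codon_usage as cu
from selfsel.io import ExpressionTable, GenotypeSequence
import pandas as pd

rng = np.random.default_rng(1)

# 40 genes: the 8 most expressed genes use GAC/AAG/TTC heavily, the rest are balanced
genes = {}
expr = {}
for i in range(40):
    gid = f"g{i:02d}"
    high = i >= 32
    expr[gid] = 200.0 + i if high else 1.0 + i * 0.1
    codons = []
    for _ in range(120):
        aa_pool = [("GAC", "GAT"), ("AAG", "AAA"), ("TTC", "TTT")]
        pref, unpref = aa_pool[rng.integers(3)]
        p = 0.85 if high else 0.5
        codons.append(pref if rng.random() < p else unpref)
    genes[gid] = GenotypeSequence.from_nucleotides(gid, "".join(codons))

expression = ExpressionTable(pd.DataFrame({"sample": expr}))
high_set, low_set = cu.partition_by_expression(expression, quantile=0.2)
counts = cu.per_gene_codon_counts(genes)
table = cu.delta_rscu(counts, high_set, low_set)

called = table[table["optimal"]]
print("codons called optimal (ΔRSCU > 0 and p < 0.05):")
print(called[["amino_acid", "rscu_high", "rscu_low", "delta_rscu", "p_value"]].round(3))

optimal = set(called.index)
fop_high = np.mean([cu.fop(genes[g], optimal) for g in high_set])
fop_low = np.mean([cu.fop(genes[g], optimal) for g in low_set])
print(f"\nmean Fop: high-expression genes {fop_high:.3f}, low-expression {fop_low:.3f}")
print("Interpretation: the three planted C-ending codons are recovered as optimal,")
print("and Fop is higher where selection for translational efficiency is stronger.")
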