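"""Truth-known simulation and recovery of relaxed selection in selfers.

Simulates a reduced-scale dataset (300 loci) in which the two selfing lineages
evolve with selection efficacy ν = 0.2 versus 1.0 in the outcrosser, then
measures ΔRSCU⁺ per genotype and U2P/P2U per branch with the pipeline.
"""

from selfsel.simulate import SimulationConfig, simulate
from selfsel.validation import measure_bias_recovery

cfg = SimulationConfig(n_genes=300, codon_length=150, seed=42)
ds = simulate(cfg)
truth = ds.truth.branch_truth_counts()
print("planted per-branch changes (truth ledger):")
print(truth[["n_syn", "n_nonsyn", "n_u2p", "n_p2u", "n_deleterious"]])

rec = measure_bias_recovery(ds)
print(f"\nconsensus optimal codons recovered: {rec.n_consensus_optimal}")
print("measured ΔRSCU⁺ per genotype:")
for g, v in rec.delta_rscu_plus.items():
    print(f"  {g:12s} {v:.4f}")
print("measured U2P/P2U per branch:")
for b, v in rec.u2p_p2u.items():
    print(f"  {b:12s} {v:.3f}")
print(f"\nselfers show lower codon-bias efficacy than the outcrosser: "
      f"{rec.selfers_lower_bias}")
print("Interpretation: relaxed selection (ν < 1) lets unpreferred codons fix,")
print("dragging U2P/P2U below the outcrosser's value and eroding ΔRSCU⁺.")
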