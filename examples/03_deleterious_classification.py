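"""Physicochemical-constraint classification of amino-acid variants.

Builds constraint profiles for two homolog-alignment columns — one invariant
(leucine only), one freely variable — and scores candidate substitutions.
"""

from selfsel.constraint import build_profile, default_tau

tau = default_tau(6)
print(f"good/bad threshold tau = {tau:.2f} (chi-square 95th pct, 6 scales)\n")

invariant = build_profile("LLLLLLLLLLLL")
variable = build_profile("LKDESTAGYQNV")

for label, prof in [("invariant Leu column", invariant), ("variable column", variable)]:
    print(f"{label}:")
    for cand in "LIVDKW":
        verdict = "bad " if prof.is_bad(cand) else "good"
        print(f"  candidate {cand}: D = {prof.d_scores[cand]:8.1f}  -> {verdict}")
    print()

print("Interpretation: at the conserved position, even moderately different")
print("residues (D, K, W) deviate far beyond tau and are classified deleterious,")
print("while at the unconstrained position almost anything is compatible.")
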