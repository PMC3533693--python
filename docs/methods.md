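# Methods

## Problem and measurement design

Three ingroup genotypes (one outcrossing, two independently derived selfing)
are compared against a selfing outgroup across thousands of codon-aligned
orthologous CDS loci. Two families of statistics index the efficacy of
selection:

1. **Protein-level**: the ratio of derived non-synonymous to synonymous
   changes per branch (P_N/P_S), and the fraction of non-synonymous variants
   classified deleterious by physicochemical constraint.
2. **Codon-usage level**: ΔRSCU between high- and low-expression genes,
   the derived optimal-codon set, Fop, ΔRSCU⁺, and the polarized
   U2P/P2U ratio per branch.

Counts rather than rate estimates are used throughout: with one genotype per
population and a single outgroup, divergence-based ω estimation is not
identifiable, whereas polarized counts need only the parsimony assignment of
ancestral states.

## Polarization model

The ancestral state of a codon column is the outgroup codon (single-outgroup
parsimony). The ingroup is treated as a star over a shared ancestral branch:
a derived codon carried by **all** ingroup genotypes is one change on the
ancestral branch; a derived codon carried by a strict subset is one change on
each carrying terminal branch. This matches the per-genotype derived counts
the analysis reports without committing to a resolved ingroup topology. A
consequence worth keeping in mind: a change that really occurred on the
*outgroup's own* branch is misread as an ancestral-branch change with
inverted direction. The simulator reproduces this bias faithfully; exact
ledger-replay checks therefore set the outgroup branch length to zero.

Columns are skipped when gapped, when the outgroup codon is ambiguous,
heterozygous or a stop, or when no stop-free mutational path connects
ancestral and derived codons.

**Heterozygotes.** Unphased heterozygous codons expand into all consistent
phasings with equal weight (2^h phasings for h het sites); polarization
enumerates the product of per-genotype phasings and averages branch
assignments over joint configurations. For a single het site this reduces to
the usual "average of two unphased haplotypes", and duplicating a genotype
into explicit haplotypes and averaging independent runs reproduces the
weighted result exactly (tested). Codons with a phasing that would be a stop,
and codons with N/3-base ambiguity codes, are excluded for that genotype.
An alternative strict mode drops heterozygous (fractional) changes entirely.

**Multi-hit codons** are decomposed over all orderings of the differing
positions; orderings that pass through a stop are dropped and the remainder
equally weighted (the Nei–Gojobori path convention). Potential-site
denominators use Nei–Gojobori fractional counting with stop mutations
excluded from the per-position denominator, so synonymous + non-synonymous
sites = 3 per codon.

**Diversity.** S counts sites segregating among the 2×3 ingroup haplotypes
(heterozygous sites segregate by definition); K counts fixed differences from
the outgroup (all ingroup haplotypes share one allele that differs from the
unambiguous outgroup allele). Variant sites are classed synonymous or
non-synonymous in the context of the majority ingroup codon; sites whose
variant codon would be a stop, or whose context is ambiguous, are skipped.
θ_W = S/(a_n·L) is computed per locus per site class with n = 6 haplotypes
(a_5 = 2.2833) and averaged across loci; the quoted dispersion is the
across-locus SD. Pairwise genotype differences average over the 2×2
haplotype comparisons, so het-vs-homozygote mismatches contribute ½.

## Codon-usage statistics

Per-codon ΔRSCU is tested with per-gene RSCU values as replicates (high vs
low expression group, one-way ANOVA — equivalently a pooled-variance t): the
analysis unit is the gene, not the codon occurrence, because per-gene RSCU
values are the independent draws under between-gene variation. Genes whose
family count is zero for a codon's amino acid are omitted from that codon's
test. Expression classes default to the top and bottom deciles of the
cross-genotype mean (per-genotype expression is available as an option and
gives the same classes in the simulated data). Optimal calls default to
α = 0.05 uncorrected, with a Benjamini–Hochberg switch; the consensus set
intersects the per-genotype sets and keeps, per amino acid, the codon with
the greatest mean ΔRSCU. The per-genotype union and the one-per-amino-acid
consensus are kept as distinct outputs; all downstream preferred/unpreferred
classification uses the consensus set.

Fop's denominator excludes non-degenerate amino acids (Met, Trp) and stops —
stated explicitly because conventions differ. GC3s likewise covers only
degenerate-family codons. The Fop covariate model is an OLS fit of Fop on
GC3s, length, expression and a categorical factor (genotype **or** mating
system — with a single outcrossing genotype the two are collinear and are
fitted in separate models), with pairwise interactions, reduced by backward
elimination at α = 0.05 (largest p first; a main effect is never dropped
while an interaction containing it remains; ties break by term name).
Because every optimal codon ends in G/C, GC3s is partly confounded with Fop,
so a GC3s-excluded variant is always fitted alongside. ΔRSCU⁺ comparisons
(genotype ANOVA, mating-system ANOVA, Tukey-Kramer, selfers-combined t) are
performed on log-transformed positive ΔRSCU values.

## Constraint classifier

A deliberately simplified MAPP-style scorer. For a homolog-alignment column
with residues r_1..r_m and property scales p (defaults: Kyte–Doolittle
hydropathy, Grantham polarity, net charge at pH 7, Zamyatnin side-chain
volume, Chou–Fasman helix and sheet propensities), the deviation of candidate
amino acid a is

    D(a) = Σ_p ((s_p(a) − μ_p) / max(σ_p, floor_p))²,

with μ_p, σ_p the column mean and SD on scale p and floor_p = 0.1 × the
scale's SD over the 20 amino acids (so invariant columns penalize deviation
strongly but finitely). D(a) above the χ² 95th-percentile with df = number of
scales ⇒ "bad". Loci enter the analysis when they have ≥ 5 homologs with
mean identity to the focal (outgroup-translated) protein strictly > 0.60.
What full MAPP adds and this stand-in omits: tree-weighted sequence
contributions and a calibrated score-to-p mapping; externally computed
good/bad tables can be supplied as TSV to use real MAPP output.

Two deleterious analyses mirror each other: **polarized mode** labels the
derived residue of each polarized non-synonymous change; **polymorphism
mode** labels every genotype's allele at each amino-acid-polymorphic ingroup
site, requiring no ancestral-state assignment.

With few homologs the column SD is noisy, so the χ²-threshold rule is only
calibrated when truly unconstrained columns are diverse; at half-conserved
columns it over-calls incompatibility. Sensitivity/specificity ≥ 0.9 holds
for planted coherent allowed-sets with ~12 homologs (tested); absolute
deleterious fractions from the classifier should be read as an index for
*between-branch comparison*, not an absolute rate — the between-branch
ordering is unaffected because the miscalibration is branch-independent.

## Statistical engine

χ² homogeneity is plain Pearson (no continuity correction), df = (r−1)(c−1),
accepting fractional counts from heterozygote averaging (round-half-even
integer mode available). One published 2×3 deleterious-count table is
carried as a worked example; its printed χ² (8.15) does not reproduce under
the standard Pearson computation (≈ 11.5 from the printed counts) — the
package reports the standard statistic. Similarly, published df bookkeeping
for structurally identical 2×2 U2P/P2U tests is internally inconsistent
("2 DF" vs "1 DF"); the standard df = 1 is used. Tukey–Kramer is implemented
on the studentized-range distribution with the unequal-n correction and is
cross-checked against statsmodels' implementation in the tests.

## Synthetic-data generator

The generator emulates exactly the structure the analysis assumes, with a
planted truth ledger for parameter-recovery tests.

* One preferred codon per degenerate family (G/C-ending, as observed for
  translationally optimal codons in plants).
* Expression E_g ~ lognormal(μ = 3, σ = 1.5) (FPKM-like); per-gene selection
  S_g = S_max · F(E_g) with F the lognormal CDF, S_max = 1.5 — codon bias
  rises with expression, the assumption the ΔRSCU contrast relies on.
* Ancestral codons sampled at equilibrium π ∝ exp(S_g·1[preferred]) within
  each family (amino acids uniform).
* Branch evolution: Poisson(rate × codons) single-base proposals
  (transition:transversion κ = 2), stop-creating proposals rejected, accepted
  with probability ∝ the Kimura relative fixation rate
  f(ΔS) = ΔS/(1 − e^(−ΔS)), f(0) = 1. Synonymous proposals have
  ΔS = ν_l·S_g·(1[new pref] − 1[old pref]); non-synonymous proposals have
  ΔS = −ν_l·|Gamma(shape 2, scale 1.5)| at constrained positions (75% of
  sites) and 0 elsewhere. Selection therefore enters only through relative
  fixation rates — no explicit Wright–Fisher populations — which is
  sufficient to generate the branch-rate asymmetries the pipeline measures
  and is fast at desk scale.
* Efficacy multipliers default to ν = 0.2 on both selfer terminal branches
  and 1.0 elsewhere; branch lengths (attempts/codon) default to 0.05 terminal
  and 0.1 ancestral and outgroup. These were chosen once so that (a) the
  synonymous polymorphism scale (θ_Ws ≈ 0.012) and the ingroup–outgroup
  divergence are of the order observed in comparable transcriptome panels,
  and (b) terminal branches are long enough that standing codon-usage erosion
  (ΔRSCU⁺), not only the change-ratio U2P/P2U, carries the relaxation signal.
* Heterozygote injection is post hoc at independent sites (rates mirror the
  observed ordering: outcrosser 1e-3/site ≫ selfers 1–2e-4), encoded as
  IUPAC codes, avoiding codons whose phasing would be a stop.
* Homolog alignments (12 rows/locus): constrained columns draw from a small
  physicochemically coherent allowed set (size 1–3, nearest neighbours in
  standardized scale space) centred on the ancestral residue; unconstrained
  columns show the ancestral residue with probability 0.6, else a uniform
  random residue. Mean identity to the focal protein ≈ 0.7, comfortably
  above the > 0.6 filter.
* All randomness flows from one seeded generator; `truth.json` embeds the
  config, the per-branch change ledgers with class labels, the planted het
  sites and the root sequences. Replaying the ledger from the root
  reproduces every tip byte-identically (tested).

**What the generator does not emulate** — and hence what passing tests do not
show about real data: linkage and hitchhiking (sites are independent),
demography and population structure, ancestral polymorphism (the root is a
point sequence, so parsimony misinference from shared ancestral variants is
absent), indels and alignment error, expression noise across tissues, and
selection on anything other than codon preference and a scalar deleterious
effect. Absolute values of ΔRSCU⁺ and deleterious fractions in the synthetic
data are cleaner/stronger than in real transcriptomes; the validated claims
are directional (selfer < outcrosser) and structural (ledger equality,
oracle equivalence), not absolute magnitudes.

## Validation experiments and problem sizes

* **Oracle equivalence**: branch counts, RSCU, GC3s, Fop and Nei–Gojobori
  sites equal independent brute-force enumerations on 100 random small loci.
* **Parameter recovery**: 20 replicates at 2000 genes × 200 codons,
  ν_selfer = 0.2 vs 1.0; a replicate succeeds when the selfers-combined mean
  of **both** ΔRSCU⁺ and U2P/P2U falls below the outcrosser's value (the
  selfers-combined contrast is the study's primary comparison); ≥ 90% of
  replicates must succeed.
* **Neutral null**: 50 replicates at 800 genes × 150 codons (a reduced scale
  chosen for desk-scale runtime) with S_max = 0 and equal ν. Optimal-codon
  calls use the Benjamini–Hochberg switch here: "empty consensus in ≥ 95% of
  replicates" is a family-wise claim over 59 codon tests, and the four
  genotypes share one gene sample (near-perfect correlation), so the
  cross-genotype intersection provides no extra protection — per-codon
  uncorrected α = 0.05 would leave ~3 false optimal codons per replicate by
  construction. The mating-system ANOVA on log ΔRSCU⁺ must reject in ≤ 7% of
  replicates; in this design it is conservative, because the genotypes'
  ΔRSCU values share ancestral sampling noise, deflating the between-group F
  under the null.
* **Truth replay**: ledger replay reproduces tips exactly; with zero-length
  outgroup branch, no heterozygotes and codons hit exactly once, pipeline
  change sets equal the planted ledger element-for-element.
* **Engine calibration**: χ² type-I error within [0.03, 0.07] at nominal 0.05
  over 10⁴ multinomial null draws; two-group ANOVA F equals the squared
  pooled t.

## Known limitations

* Single-outgroup parsimony misassigns outgroup-branch changes to the
  ancestral branch (direction inverted); with more outgroups this would be
  resolvable, here it is a documented bias shared by measurement and
  generator.
* The constraint classifier's absolute calibration depends on homolog-column
  diversity; prefer external MAPP-style tables for absolute deleterious rates.
* Derived states shared by exactly two ingroup genotypes are counted once on
  each carrying branch; under a resolved (non-star) ingroup topology some of
  these are single ancestral events. A config option to exclude such columns
  bounds the effect.
* θ_W assumes the 6 ingroup haplotypes are a population sample; with one
  diploid per population it is an index, not an unbiased population estimate.
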