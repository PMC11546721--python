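# Methods

This note documents the models implemented in `rhizolink`, the
assumptions behind the synthetic-data generator, the numerical choices,
and the limits of what the calibration studies demonstrate.

## Sampling design

The design vocabulary is fixed: seven cover-crop variations (fallow
control, three monocultures, three mixtures), three maize growth stages
(T1 seedling, T2 vegetative, T3 bolting), three depth strata (0–30,
30–60, 60–120 cm) and four sources (BS bulk soil, CR cover-crop root
channel, MBS maize root in bulk soil, MCR maize root in a cover-crop
channel). Only 18 (timepoint, depth, source) cells exist: at T1 the
maize-root sources do not yet exist and the pre-maize sources cover all
three strata; T2 samples the topsoil only; T3 reaches 30–60 cm for all
four sources. `validate_design` flags, but never rejects, records
outside this scheme — field datasets legitimately contain salvage
samples, and flagging keeps the decision with the analyst.

## Quantification

* **Standard curve**: least-squares Ct on log₁₀ copies; efficiency
  10^(−1/slope) − 1. Triplicate Cts are averaged arithmetically before
  inversion; a coefficient of variation above 2 % (configurable) logs a
  warning rather than dropping the sample. The dilution factor and
  per-gram conversion enter as explicit columns — nothing is inferred.
* **QMP**: *n_cn* = (*a*/100) × *b_cn*. Conservation (Σ_phyla *n_cn* =
  *b_cn*, 1e-9 relative) is asserted by tests on every synthetic
  dataset. No 16S copy-number-per-genome correction is applied: outputs
  are gene copies, not cell counts.
* **Biomass**: MBC = (C_fum − C_nonfum)/k_C with k_C = 0.45; MBN
  likewise with k_N = 0.54; in µg per g dry soil. Negative differences
  are reported with a flag, not truncated, to keep suspect extractions
  auditable.

## Diversity

Rarefaction subsamples without replacement (multivariate hypergeometric)
to exactly the target depth, default 5000 reads; shallower samples are
dropped and listed. A single rarefaction backs the headline tables; its
seed is a dedicated stream. Shannon entropy is in nats so Pielou's
J = H/ln S; J is undefined (NA) when fewer than two ASVs are detected.
Weighted UniFrac follows the per-branch definition
u = Σ_b ℓ_b·|p_A − p_B| (raw) with the normalized variant dividing by
Σ_leaves d_leaf(p_A + p_B); computation delegates to scikit-bio and is
verified against an independent dendropy-based branch-by-branch
traversal to 1e-12. The raw variant is the default; the choice is a
config key because pipelines differ and the variant changes scale, not
ordering. PCoA is classical scaling on the Gower-centered matrix;
negative eigenvalues are reported unmodified and excluded from both
coordinates and the proportion-explained denominator (no Cailliez or
Lingoes correction).

## Group statistics

ANOVA uses sequential (type-I) sums of squares in the stated factor
order — the default order (source, variation, depth, timepoint) matches
the sequential four-way design test; order is configurable and matters
under imbalance (T1 contributes fewer samples). Tukey's HSD uses the
studentized range with the Tukey–Kramer correction. The compact letter
display implements insert-and-absorb: start from one letter covering all
groups, split on each significant pair, absorb subset columns; letters
are assigned in descending-mean order and the defining biconditional
(shared letter ⇔ adjusted p ≥ α) is property-tested on random instances.

PERMANOVA partitions the Gower-centered inner-product matrix
G = (I − 11ᵀ/n)(−½D∘D)(I − 11ᵀ/n): each sequential term's SS is
tr((H_k − H_{k−1})G) for cumulative hat matrices H_k, pseudo-F is tested
by whole-row label permutation with the add-one convention
p = (1 + #{F* ≥ F})/(1 + n_perm), and an exhaustive mode enumerates all
n! relabelings (p then includes the identity and uses no add-one).
A residual SS at floating-noise level is treated as exactly zero, giving
an infinite pseudo-F that the ≥ tally handles. Agreement is tested
against Anderson's group-distance formula with exhaustive enumeration,
against classical one-way ANOVA on 1-D Euclidean data, and against
vegan's `adonis2` (by="terms") for the multi-way sequential case.

## Metaproteome aggregation

Unknown-KO rows are retained and flagged `unmapped` but excluded from
pathway matrices, so the LFQ mass audit (Σ matrix = Σ retained mapped
rows) stays exact without inventing annotations. Pathway coverage is
defined as distinct detected KOs / reference pathway KO count; the
inclusion filter (≥2 distinct protein groups AND coverage ≥5 %, both
inclusive) is idempotent by construction. Zero or missing LFQ is treated
as missing — no pseudocount — and aggregation sums raw intensities
first, attaching log₂ of the sum for statistics; cells without any
identified protein are absent, not zero, mirroring how missing
identifications appear in real metaproteomes. Protein groups annotated
to more than one phylum are out of scope for phylum-resolved tables.

## Overproduction scoring

For each (phylum, enzyme, variation) cell the score is
r = rescaled LFQ / rescaled copies with min–max rescaling onto [0,1] and
a strict r > 1 classification. Numerical choices: a constant vector
rescales to all zeros (a flat signal can never be called overproduced);
a zero denominator leaves the ratio undefined and the cell unclassified
(calling the minimum-abundance cell overproduced would be a rescaling
artifact); the threshold comparison is exact floating comparison, since
the semantics are strict. Because min–max removes scale, classifications
are invariant to global rescaling of the raw intensities.

The rescaling scope is genuinely underdetermined in the field protocol
("individually normalized"), so four coherent options are exposed:
`per_enzyme` (default: LFQ rescaled per enzyme over all
phylum × variation cells, copies rescaled once over the same cell set),
`per_variation`, `per_pair` and `global`. The scoring unit is the
enzyme (KO) level; cycle-step matrices serve the pathway summaries.

**Specificity caveat (important).** Under a proportional null — enzyme
expression scaling with phylum abundance — the rescaled numerator and
denominator are comonotone noisy quantities, so for any cell away from
the rescaling extremes P(r > 1) ≈ ½ *regardless of how small the noise
is*: a strict threshold placed at the null median is a fair coin. The
calibration study measures cell-level null false-positive rates of
0.39–0.49 for the scoped variants (0.12 for `global`) at default noise.
The procedure's practical specificity therefore comes from effect size,
not calibration: genuinely overproduced pairs separate cleanly (fold-5
injections are recovered with sensitivity 1.0), but isolated cells with
r slightly above 1 should not be read as evidence. Interpreting Fig-7
style outputs requires either large ratios, consistency across
variations, or an explicit permutation null — the scoring module
reports the full ratio table so any of these can be applied.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
not sequences or spectra:

* **Totals**: per-sample 16S copies/g are lognormal (sdlog 0.35) around
  depth × timepoint means. Depth means default to 2.1×10⁹ (0–30 cm),
  3.9×10⁸ (30–60) and 3.3×10⁸ (60–120) copies/g — topsoil roughly an
  order of magnitude above subsoil — with growth-stage multipliers
  (T1 1.0, T2 1.15, T3 0.45) reproducing the mid-season rise and
  late-season fall of root-zone abundance.
* **Composition**: phylum proportions are Dirichlet (concentration 200)
  around a base of ten named soil phyla (Pseudomonadota 28 % …
  Nitrospirota 2 %), tilted in log space by depth (Bacillota,
  Chloroflexota and Nitrospirota enriched at depth), by growth stage
  (Acidobacteriota up at T2; Bacillota/Chloroflexota up at T3), and by a
  random-but-fixed per-variation tilt (sdlog 0.15). The variation and
  stage/depth tilt magnitudes are order-of-magnitude choices exposed as
  parameters, not field-calibrated claims; the depth tilt is what makes
  the depth factor visible to composition-based distances, since
  weighted UniFrac is invariant to total abundance.
* **Counts**: ASVs (12 per phylum) subdivide each phylum by fixed
  Dirichlet weights; per-sample counts are multinomial at a lognormal
  sequencing depth (median 12 000, sdlog 0.3), comfortably above the
  5000-read rarefaction target for almost all samples. The phylogeny is
  a random coalescent-style bifurcation with exponential branch lengths
  — any positive-length rooted tree exercises UniFrac.
* **Proteome**: expected LFQ of enzyme e from phylum p is
  base_e · (copies_p/10⁹)^coupling · fold(p,e) with coupling 1
  (proportional null), lognormal noise sdlog 0.5 (typical LFQ
  variability), two protein groups per expressed (phylum, enzyme) pair,
  80 % expression probability, and an absolute detection floor (2×10⁶)
  below which intensities are censored to missing — as in real
  metaproteomes, where low-abundance proteins in subsoil samples go
  unidentified. The 14-enzyme catalogue spans C-cycle steps (cellulose,
  hemicellulose, starch and lignin degradation; glycolysis; TCA) and
  N-cycle steps (nitrification, denitrification, N fixation, ammonia
  assimilation), with CAZy families on the degradative enzymes.
  Injected `overproduction_pairs` multiply a pair's expected LFQ by a
  chosen fold and define the ground truth for recovery studies.
* **Biomass**: fumigation signals are normal around depth-zone means
  (topsoil 90/27 µg g⁻¹ for C/N, subsoil a third of that), so the
  estimator (signal/k) is linear in the configured mean.
* **qPCR**: measured totals carry lognormal error (sdlog 0.08); a
  Ct mode emits triplicates from a configurable standard curve to
  exercise the quantification path.

All randomness flows from one seed through named `SeedSequence` spawns
(community, tree, proteome, qpcr, biomass), so identical parameters give
byte-identical bundles and individual stages can be regenerated.

What passing on synthetic data does **not** show: robustness to
compositional artifacts of real amplicon data (primer bias, chimeras,
contamination), to taxonomy misassignment, to protein groups shared
across phyla, or to spatial autocorrelation between plots. The
generator's effect sizes are stylized; recovery results quantify the
pipeline's statistical machinery, not field-level power.

## Problem sizes and defaults

The replicate default is 3 plots per design cell (378 samples), matching
the field layout; calibration studies and the reproduction script use 1
replicate per cell (126 samples) and 100 simulations per study
(1000 for the permutation-null calibration, with 199 permutations and
n = 16), sizes chosen to keep the studies' Monte-Carlo error well inside
the decision bands they feed. Analysis defaults: rarefaction depth 5000,
999 permutations, overproduction threshold 1 (strict), pathway filter
(2 proteins, 5 % coverage), k_C = 0.45, k_N = 0.54.

## Known limitations

* Linear mixed models (random plot effects) are not implemented; the
  ANOVA here is fixed-effects only.
* The PERMANOVA permutes rows freely; no restricted permutation within
  plots/strata, which a nested field design would ideally use.
* The overproduction score has the specificity caveat above; no
  multiple-testing control is applied to the ratio table.
* The ASV frequency filter is a plain minimum-total-count threshold;
  identity-based clustering of near-duplicate sequences is upstream of
  this package.
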