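# Methods

This note documents the models, defaults, and numerical choices behind
`oncohub`, and what the synthetic study does and does not establish about
behaviour on real data.

## The synthetic study

All inputs flow from one seed through named child streams
(`default_rng([seed, crc32(name)])`), so adding a generator never perturbs
the draws of another and identical seed + configuration gives bit-identical
outputs.

**Expression compendium.** A planted factor model over 300 samples spread
across 8 synthetic source datasets and six ordered phenotypes (50 samples
each of normal, benign, HGPIN, cancer, CRPC, metastasis). Gene g in module
m has

    x_gs = baseline_g + loading_g · score_{m,s} + batch_{d(s)} + ε_gs

with baseline_g ~ N(8, 1.5²) (log-scale units), loading_g ~ U(0.5, 1),
score_{m,s} = slope_m · rank_s + N(0, 1), batch offsets N(0, 0.2²) per
dataset, and residual noise N(0, 0.4²). Background genes (1,320 of 2,000)
carry only baseline, batch, and noise. Module sizes are 80–120 genes (all
≥ 30 so every planted module is detectable at the minimum module size);
three modules have nonzero phenotype slope (0.6, 0.4, 0.4) and are the
disease modules. These noise levels put typical within-module gene–gene
correlations at 0.5–0.9 — the regime in which soft thresholding and
topological overlap have work to do without making recovery hopeless.

**Knockdown experiment.** Three replicates per condition (matching the
usual three-independent-isolates design), effect size 2.0 expression units,
replicate noise SD 0.5. 75% of the targeted disease module (60 of 80
genes) shifts down upon induction; 120 background genes shift in random
directions; 40 artifact genes shift in the induced state of *both*
constructs, so the control filter has genuine work. With these numbers a
per-gene Welch test at α = 0.05 recovers ≥ 90% of planted regulated genes
— the detector-power regime the generator is calibrated to.

**Deletion screen.** 300 strains, 30 planted interactors (half
suppressors at growth-rate multiplier 0.6, half enhancers at its
reciprocal), four replicate logistic growth curves per condition sampled
every 6 h over 72 h (carrying capacity 1, inoculum 0.01, baseline rate
U(0.10, 0.14) per hour), multiplicative lognormal per-curve noise
(σ = 0.05). The query factor's global mild growth cost is not modelled:
hits are defined within-strain (induced vs its own non-induced control), so
a uniform induced offset would flag every strain and is not part of the hit
concept being exercised. Five essential genes exist only in the interaction
network, each wired to 2–4 planted hits at confidence ≥ 0.7; decoy
structures (library-absent genes with one strong neighbour or two weak
ones, plus 200 random intra-library edges) exercise the augmentation rule's
boundaries. The ortholog map contains one-to-one, many-to-one, and
unmapped yeast genes so every category (suppressor/enhancer/essential/
mixed) is reachable.

**Hub identity.** The generator picks 7 hub genes from the down-regulated
members of the targeted disease module, wires yeast hits to exactly those
human symbols (plus decoy humans outside the expression universe), and
asserts at build time that

    hub = regulated(down) ∩ genes(disease modules) ∩ orthologs(hits ∪ essentials).

**Survival cohort.** 200 patients, 20% altered. Altered patients' hub-gene
expression is shifted by 6 SD and their exponential hazard multiplied by 3
(baseline 0.02 events/month). The shift is deliberately large: under the
all-m-of-m calling rule, flag-level identity with the planted labels needs
per-gene sensitivity ≈ 0.9999 (0.9999⁷ per patient across 40 altered
patients), which a 6 SD shift delivers and a 3 SD shift does not (per-gene
0.85 → patient-level 0.32). Censoring times are uniform U(0, b) with b
solved by bisection from E[P(C < T)] = 0.3.

**Dose-response surfaces.** Single agents follow fa/(1−fa) = (D/Dm)^m
exactly over a 2-fold dose ladder spanning Dm/8 to 8·Dm; combination rows
at a 4 × 4 grid of (Dm-fraction) dose pairs carry the fa solving
d1/Dx1(fa) + d2/Dx2(fa) = α by Brent's method on (10⁻¹², 1 − 10⁻¹²) (the
left side is strictly decreasing in fa, so the root is unique). α = 1 is
exact Loewe additivity; α < 1 plants synergy of that magnitude.

## Analysis choices

**Outlier filtering** is per source dataset before combination
(configurable to post-combination), single pass, threshold 2.5 SD — the
midpoint of the conventional 2–3 SD range. With zero SD of mean
correlations nothing is excluded.

**Quantile normalization** maps each sample's order statistics onto the
across-sample mean of sorted vectors; tied values receive the mean of the
reference values their ranks span. The "identical sorted vectors" postcondition
is exact only for tie-free samples — ties deliberately depart from the
shared reference, which is why idempotence is likewise exact only without
ties.

**Scale-free fit.** Connectivities k_i = Σ_j a_ij (j ≠ i) are split into
10 equal-width bins; log10(bin frequency) is regressed on log10(mean k per
bin) and R² is signed by the slope (a rising "degree distribution" counts
against scale-freeness). Equal-occupancy binning is unusable here: it
forces every bin frequency to be identical, leaving the regression
undefined. The chosen β is the smallest grid value reaching fit 0.8, else
the argmax of the fit, else (every fit undefined) the largest β with a
warning. The network is unsigned by default; signed mode
(((1 + r)/2)^β) is a flag.

**TOM.** ω_ij = (ℓ_ij + a_ij)/(min(k_i, k_j) + 1 − a_ij) with
ℓ_ij = Σ_{u≠i,j} a_iu a_uj, computed as one matrix product minus the u = i
and u = j terms; entries are clipped to [0, 1] against floating-point
drift. At n = 2 the formula reduces to ω = a (empty shared-neighbour sum,
min k = a).

**Module detection.** Average-linkage clustering of 1 − ω with a single
static cut. The default cut height is the midpoint of the largest gap in
the sorted merge heights: tight planted branches merge low, the diffuse
background merges in a dense band near height 1, and the gap separates the
two regimes. A fixed-quantile cut is available (`cut=0.99`), but on data
with a large unassigned background any quantile falls inside the background
band and shreds it into spurious ≥ 30-gene clusters, so the gap rule is the
default. On structureless data the gap lands arbitrarily; the min-size
filter then discards most branches, but module counts on pure noise should
not be over-interpreted. Branches below 30 genes get label 0 ("grey");
labels are ordered by decreasing size and given stable arbitrary colour
names.

**Eigengenes and merging.** Genes are standardized across samples
(SD ddof = 1); the eigengene is the leading right singular vector of the
module submatrix, scaled to unit variance and oriented to correlate
non-negatively with the module mean profile (resolving the PCA sign
ambiguity observably). Merging is iterative closest-pair on eigengene
dissimilarity 1 − cor with recomputation after every merge, stopping when
the minimum reaches the 0.25 threshold.

**Module–trait correlation** uses Pearson r with two-sided p from
t = r√(n−2)/√(1−r²) on n−2 df, unadjusted (as such heatmaps are
conventionally presented); a Benjamini–Hochberg option exists downstream of
the differential tests. Disease modules for the intersection are those
with r > 0 and p < 0.01 against the phenotype rank.

**Differential expression / hit calling** use Welch's two-sample t test
with unadjusted p < 0.05 (the convention of the emulated design;
`adjust="bh"` is available). Zero-variance-in-both-groups genes with equal
means get p = 1. Screen fitness is the trapezoidal area under the growth
curve (robust to lag and saturation; an endpoint-size mode exists). The
fitness ratio induced/non-induced is scale-free, so hit calls are invariant
to uniform rescaling of colony sizes.

**Essential augmentation** counts *distinct primary-hit* neighbours
(significant suppressors/enhancers only) through edges with confidence
≥ 0.7 inclusive; genes already in the deletion library are never added.
Ortholog projection takes the union of human symbols over hits; a human
gene with both essential and non-essential yeast support is "mixed".

**Alteration calls.** Gene-level z-scores use a robust reference by
default: median centre and 1.4826·MAD scale. A cohort-mean/SD reference
(`method="mean"`) is provided but is not the default because a 20%-altered
subpopulation inflates the cohort SD to the point where threshold·σ grows
as fast as the usable signal (at threshold 1.96 and 20% prevalence,
1.96·√(f(1−f)) ≈ 1 − f), making separation impossible at any shift; the
robust reference stays calibrated for any prevalence below 50%. A patient
is altered when ≥ k of m usable genes reach z ≥ 1.96 (k = m by default;
k = 5, m = 7 reproduces the at-least-five variant). Zero-scale genes are
excluded from the rule with a warning.

**Survival.** Kaplan–Meier estimation and the two-group log-rank test are
delegated to lifelines behind the package's function surface; tests verify
the product-limit arithmetic by hand and check the log-rank statistic's
invariance under monotone time transforms and its ranking against a
permutation reference.

**Synergy.** Median-effect fits use least squares on
log10(fa/(1−fa)) vs log10(D), excluding rows with fa ∈ {0, 1} entirely
(a 10⁻⁶ clamp is applied only when reporting a combination row's fa). The
mutually-exclusive CI form is the default; the nonexclusive form adds the
cross-term. Classification uses a ±0.05 band around 1 for "additive".
Replicate rows at the same dose pair are averaged before analysis.

## Problem sizes

The default study — 2,000 genes × 300 samples, 300 strains × 2 conditions
× 4 replicates × 13 time points, 200 patients, 44 dose-response rows — was
chosen so that module structure, screen power, and survival contrast are
all in realistic operating regimes while a full pipeline run completes in
well under a minute; the calibration suites use 500 null and 200
alternative simulated cohorts.

## What passing tests do and do not show

The generator plants clean factor-model modules with uniform loadings, a
single global batch offset per dataset, homoscedastic Gaussian replicate
noise, exactly exponential survival times, and noiseless median-effect
curves. Real microarray compendia have correlated probe effects, nested
batch structure, heavy-tailed noise, and modules of varying density;
recovery rates measured here (ARI, recall, power) are upper bounds for such
data, not estimates. Exact hub-set recovery additionally relies on every
planted hub gene surviving two stochastic α = 0.05 filters, which holds in
the detector-power regime of the defaults but is not guaranteed for
arbitrary reconfiguration.

## Known limitations

- Single-matrix network construction: multi-set consensus TOM and
  blockwise decomposition for very large gene sets are out of scope.
- The static cut is not the adaptive dynamic branch-cutting algorithm; it
  is deterministic and sufficient for planted-truth recovery, but will
  behave differently on dendrograms without a clear module/background gap.
- No Cox modelling or multivariable adjustment; survival validation is
  stratified log-rank only.
- No probe-level preprocessing; inputs are gene-level matrices.
- Two-drug combinations only; no dose-reduction-index reporting.
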