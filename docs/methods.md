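# Methods

## The partitioning model

A root sample's carbon is modeled as a two-source mixture: recent crop
(maize, C4) root biomass C with signature δ¹³C_RB, and extraneous organic
matter (EOM) C with signature δ¹³C_EOM. Mass balance gives the recent-root
C fraction

    f_RBC = (δ¹³C_s − δ¹³C_EOM) / (δ¹³C_RB − δ¹³C_EOM),

with f_RBC + f_EOM = 1 by construction. The model assumes (i) exactly two
isotopically distinct pools, (ii) endmember stability — no fractionation of
the EOM pool between its formation and sampling, and no Suess-type drift —
and (iii) that the reference material used for the EOM endmember resembles
the EOM actually present in the samples. f_RBC is a **C-mass** fraction;
translating it into a biomass fraction assumes equal C concentration in
both pools unless per-pool C concentrations are supplied to the pooling
step.

## Endmember estimation

**Root.** Coarse (>2 mm) root samples are the least contaminated stream, and
their isotopically heaviest members are taken to be pure recent root. The
estimator computes the empirical q-quantile (default q = 0.8) of all coarse
δ¹³C values by linear interpolation at rank 1 + q(n−1) on the sorted values
— the most common quantile definition, recorded in the estimate's `rule`
string for audit — and averages the values **strictly greater** than it;
ties with the quantile are excluded. On the full design (36 coarse values,
robust to 34–36 under 0–2 missing) this selects exactly 7 values. The
estimator is consistent only when at least a fraction 1 − q of coarse
samples are essentially pure; the synthetic generator reproduces that
feature (below).

**EOM.** The mean and SD of all prior-year ley fine-root reference values
(default n = 12), pooled across treatments. Whether the reference spread is
between-sample or includes analytic error is not identifiable from the
inputs; it is treated as between-sample SD.

Before pooling across groups, `group_invariance_check` offers a one-way
permutation test (between-group mean square, free label permutation) as an
advisory check; a significant result logs a warning but does not abort,
since the pooling decision belongs to the analyst.

A pair is rejected as degenerate when the separation Δ = δ¹³C_RB − δ¹³C_EOM
falls below 2‰ (configurable): with the C4/C3 system Δ ≈ 16‰, anything
near zero indicates corrupted inputs rather than a usable mixing system.

## Uncertainty

Three independent Gaussian variance sources are propagated: the instrument
SD of a single measurement (σ_s, default 0.2‰, the analytical precision of
the IRMS working standard), and the two endmember SDs. First order,

    SE² = (σ_s/Δ)² + (σ_RB (δ_s − δ_EOM)/Δ²)² + (σ_EOM (δ_s − δ_RB)/Δ²)²,

evaluated at the unclamped point. The Monte-Carlo route perturbs all three
quantities (default 10 000 draws), recomputes and clamps each draw, and
reports the 2.5/97.5 percentile CI and the SD of clamped draws. Draws whose
perturbed separation falls below 0.1‰ are rejected and redrawn (counted and
logged) — with Δ ≈ 16‰ this never occurs in practice but keeps the
estimator defined for extreme scenarios. In the linear regime (all σ ≪ Δ,
point ≥ 3 SE from both bounds) the two routes agree within 5% relative
error, which the test suite verifies at 10⁵ draws. No endmember covariance
is modeled (none is identifiable from the inputs).

Raw fractions are preserved unclamped for audit; the reported `fraction` is
clamped to [0, 1] with a flag, and all group statistics use the clamped
scale — observed fractions in such studies run up to exactly 100%,
consistent with truncation.

## Size-class pooling

Puerckhauer coarse and fine fractions are combined into pooled records by
weighted average, with weights equal to dry mass, refined to C mass when
both C concentrations are given. The pooled SE combines the member SEs with
the same weights (first order, independence assumed); the pooled CI is the
weighted combination of member CIs, an approximation adequate for the
in-range regime. Pooled records are marked `derived`; they enter only the
EOM-exclusion contrast (row + pooled records across both coring methods).

## Permutation inference

Mixed-model ANOVA with Kenward-Roger degrees of freedom is the classical
analysis for this design. This package deliberately replaces it with a
design-respecting permutation framework: it is assumption-light, exactly
valid under the design's exchangeability, and fully testable. p-values will
not numerically match mixed-model output.

The statistic for a main effect is the between-level mean square of the
fractions. The null distribution permutes the factor at its experimental
unit: treatment labels across whole plots (optionally within blocks — the
default follows the original analysis in treating the three treatments as
independent plot-level labels, ignoring the strip-split structure), depth
labels among the depth groups of each plot, and position/size-class/
exclusion labels within plot × depth cells. When fewer than 20 distinct
permutations exist the null is enumerated exactly (logged). p = (1 + #{perm
≥ obs})/(B + 1), default B = 9 999; ties with the observed statistic count
as extreme, so p ≥ 1/(B+1) and degenerate data give p = 1.

Interactions use the Freedman–Lane scheme: residuals from the additive
two-factor fit are permuted freely, the additive fit is added back, and the
interaction mean square — the RSS drop from the additive to the full
cell-means model over (a−1)(b−1) — is recomputed per permutation. Under a
null simulation both test families hold their 5% level within Monte-Carlo
error (verified at 500 replicates, B = 999).

Cell summaries report mean, SE = SD/√n with the n−1 denominator, and n;
single-value cells report no SE rather than 0.

## The synthetic-study generator

The generator emulates the sampling design the method was developed on:
3 treatments × 4 blocks = 12 plots, 3 depth layers, Humax cores at two
positions (pooled size class, EOM excluded) and Puerckhauer cores within
rows (coarse + fine, no exclusion) — 144 planned records, of which 5
(default) are removed uniformly at random, leaving the realized 139.

Latent truth is logit-normal: logit(f) = logit(baseline) + additive factor
offsets + N(0, dispersion). The logit scale keeps fractions strictly inside
(0, 1) and produces the long lower tail (≈5–100%) such samples show.
Default offsets are calibrated so cell means track the group means reported
for the emulated study (treatment 55/59/66%, depth 52/60/68%, position
73/52%, size class 73/42%, exclusion 53/74%); baseline_fraction 0.55 then
puts the overall mean near 60%. The within-cell dispersion (logit SD 0.9)
is a calibration choice — per-sample spreads are not published — set to
reproduce the observed range. An optional treatment × exclusion offset can
mimic exclusion helping only the heavily amended treatments.

Two generator features matter for what the tests mean:

* **Nearly pure coarse samples.** Each coarse sample is, with probability
  0.25, drawn from a high-purity sub-population (logit ≈ 4.6, i.e. f ≈
  0.99) — cores that happened to catch only recent crop roots. This is the
  feature that makes the empirical CDF of coarse values plateau at the pure
  root signature and the upper-quantile endmember rule consistent; with a
  purely unimodal logit-normal truth the rule would be biased low by more
  than 1‰. With it, the estimated root endmember lands within ~0.2‰ of
  truth and the pipeline's overall fraction recovers the latent truth with
  MAE < 0.01 over 200 replicate studies.
* **Per-sample endmember realization.** Every sample's root and EOM
  material receives its own signature draw (SDs 0.5‰ and 0.3‰), modeling
  biological heterogeneity; instrument noise (0.2‰) is added on top. This
  makes endmember-SD propagation testable but also sets an information
  ceiling: ordering of group means whose true difference is smaller than
  the resulting group-mean error (≈0.005) cannot be recovered reliably. In
  practice that affects only the treatment factor, whose configured
  contrast between the two organic treatments is ~4 percentage points —
  not resolvable at n = 139, just as in the emulated study, where the
  treatment effect was not significant. Ordering recovery is therefore
  ≈94% for treatment and ≥98% for every other factor.

The fine:coarse dry-mass ratio used for pooling weights defaults to 1.5
(fine-root mass in such profile samples typically matches or exceeds coarse
mass once EOM is included); it is a scenario parameter, not an estimate. C
concentration is a constant 0.45 for all simulated roots, so C-mass and
dry-mass weighting coincide in simulated studies.

What the generator does **not** emulate: spatial correlation within plots,
depth-dependent dispersion, non-Gaussian instrument error, decomposition
dynamics of the EOM pool, or informative missingness (missing cells are
uniform because the emulated study does not say which cells were lost).
Passing recovery tests therefore demonstrate correctness of the estimators
under the stated noise model, not robustness to structured field artifacts.

## Problem sizes and numerical choices

The replicated studies run at the design's native size (139 samples):
200 replicates for parameter recovery and 500 null replicates at B = 999
for type-I calibration — both finish in seconds to tens of seconds on one
CPU. Degenerate inputs are handled explicitly: all-tied coarse values are a
selection error, fewer than 5 coarse or 2 reference values an
insufficient-data error, both pooling masses zero a weighting error, and
sub-minimum endmember separation a numeric error (CLI exit code 3; schema
and validation failures exit 2). Validation flags — including samples
outside the plausible mixture window [δ_EOM − 3σ, δ_RB + 3σ] — never drop
data; all samples are kept, mirroring how such studies report their full
observed range.
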