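# Methods

## Data model

Observations live in a long-format table keyed by
(genotype, treatment, trial, replicate, trait, week); `treatment` is PW
(ponded water, the control) or LW (limited water, soil held near 60–65% of
field capacity through the vegetative stage).  `week` is part of the key
because the FTIR-derived traits (cuticular wax, flavonols) are measured
repeatedly through the season; single-time-point traits use week 0.

A trait registry attaches to each trait its units and its *expected
direction of change under LW*.  The defaults encode the moderate-stress
response pattern of temperate rice: quenching parameters (ΦNPQ, NPQt), leaf
temperature, wax and flavonol indices, contact angle, δ¹³C (less negative =
higher intrinsic WUE) and %N increase under LW; stomatal conductance (gs),
stomatal density (SD), relative chlorophyll, ΦPSII, Fv/Fm and the C:N ratio
decrease.  %C and ΦNO have no established direction, are registered
*neutral*, and are excluded from directional index construction unless
re-registered (a YAML override file can change any entry).

## Synthetic experiments

The generator draws each trait value as

    value = baseline + genotype offset + trial shift + treatment shift + noise

with the treatment shift applied to LW plants only and equal to
`d × residual_sd`, so a planted Cohen's *d* is recovered by the sample
effect size without rescaling.  Genotype offsets (one draw per genotype,
default sd 0.5 residual units) create stable genotype rankings; trial
shifts (default sd 0.3) emulate between-trial environment differences
without a planted treatment × trial interaction.  Random streams are keyed
per trait from the master seed, so adding a trait never perturbs the draws
of another.

Defaults mirror a two-trial glasshouse screen: 21 genotypes (2 *indica*),
2 treatments, 2 trials, 8 replicates, and 9 leaf traits with baselines and
residual sds at field-realistic scales (gs 420 ± 60 mmol m⁻² s⁻¹,
SD 440 ± 30 mm⁻², ΦPSII 0.65 ± 0.05, …).  Genotypes carry planted strategy
classes — 10 *stable* (|d| = 0.2) and 11 *plastic* (|d| = 1.3), each signed
along the trait's registered direction — giving clearly separated effect
regimes for recovery tests.

δ¹³C is not drawn independently: per plant it is an intercept (−29.5‰) plus
a linear combination of the standardized values of four *informative*
traits, with coefficients signed along each trait's LW direction
(gs −0.8, CEW +0.6, SD −0.5, ΦPSII −0.4, in ‰ per sd) plus Gaussian noise
(sd 0.78‰, giving R² ≈ 0.7 at plant level).  The sign convention makes
simulated δ¹³C less negative under LW, as observed for C₃ leaves whose
intrinsic WUE improves under stomatal closure.

What the generator does *not* emulate: genotype × treatment interactions
beyond the two-class structure, trait–trait residual correlations within a
plant (traits are conditionally independent given the design effects),
non-Gaussian measurement error, and any mechanistic gas-exchange coupling.
Passing recovery tests therefore demonstrate correctness of the estimators
under the planted statistical structure, not fidelity to any particular
field dataset.

Two auxiliary generators supply test inputs for the spectral and water-loss
modules: Gaussian peaks on a linear baseline over an ascending wavenumber
grid (400–4000 cm⁻¹), and exponential detached-leaf weight decline
(`weight(t) = w₀ · rate^(t/60)`, t in minutes) with multiplicative
log-normal noise at t > 0.

## Effect sizes and tests

Cohen's *d* is the (LW − PW) mean difference over the pooled sd; the Hedges
correction multiplies by 1 − 3/(4N − 9).  The positive direction therefore
means "higher under limited water", consistent with the directional
adjustment used by the composite index.  The default aggregation level is
per-genotype means (one value per genotype per treatment), which avoids
treating replicate plants of one genotype as independent; replicate-level
pooling is available by flag.

Welch's *t* with Welch–Satterthwaite degrees of freedom handles the unequal
variances typical of treatment contrasts; for equal n and equal sample
variances the df collapses to 2(n − 1).

The two-way ANOVA implements the exact balanced decomposition
(SS_A + SS_B + SS_AB + SS_error = SS_total) and refuses unbalanced designs
with an explicit error: hierarchical or unbalanced data call for a
mixed-effects model, which is outside this package's scope by design.

Correlation matrices are Pearson correlations of the genotype × treatment
mean trait matrix (or the treatment-pooled genotype means), with pairs of
|r| ≥ 0.5 flagged as strong; constant traits get undefined rows and are
excluded from flagging.

PCA operates on the trait correlation matrix of the standardized
genotype × treatment mean matrix.  Eigenvalues sum to the trait count *p*,
so the variance share of a component is eigenvalue/*p*; loading columns are
oriented so that their largest-magnitude entry is positive, a deterministic
sign convention.

## PLS1 and VIP

Single-response PLS is fit by NIPALS with both X- and y-deflation after
autoscaling both blocks (traits have incommensurable units; autoscaling
makes predictions invariant to per-trait affine unit changes).  For one
response the algorithm needs no inner iteration and is fully deterministic.
VIP_j = √(p · Σ_k SSY_k w²_jk / Σ_k SSY_k) with SSY_k the response sum of
squares captured by component k; Σ_j VIP²_j = p exactly, and the
conventional VIP > 1 rule flags influential predictors.  The default is
2 components; a cross-validated choice is available, using the
one-standard-error rule (smallest component count whose CV error is within
one between-fold standard error of the minimum) so that near-flat error
curves resolve toward the simpler model.

**Benchmark scale.**  The planted proxy-recovery benchmark (all four
informative traits VIP > 1, ≥ 4 of 5 uninformative VIP < 1) is evaluated on
independent plant-level draws.  The weakest informative trait (ΦPSII,
coefficient 0.4 among 9 predictors) has a *population* VIP of
√(9 × 0.16/1.41) ≈ 1.01 — only 1% above the cutoff — so the ordering is an
asymptotic property: resolving it requires a VIP standard error below
~0.008, i.e. a few hundred thousand plants.  The benchmark therefore uses
n = 300,000 i.i.d. plants per dataset (`generate_pls_benchmark`), at which
the recovery rate is ≈ 96–99%.  At glasshouse scale (21 genotypes ×
8 replicates) the same ordering is present but statistically unresolvable
against the hard VIP = 1 cutoff.

## CMTI construction

Trait panels come from one of three prioritisation modes: |d| ≥ 0.8 (the
conventional "large effect" cutoff, configurable), VIP > 1, or an explicit
list.  Neutral-direction traits are excluded with a warning.

Two normalization readings are implemented because "normalized to 0–1 and
directionally adjusted" admits both:

- **plasticity** (default): the raw score per genotype and trait is the
  signed relative treatment change (LW − PW)/|PW|, multiplied by +1 when
  the change follows the trait's expected LW direction and −1 when it
  opposes it, then min–max scaled across genotypes.  This reading makes
  high CMTI mean *strong adaptive adjustment*, which is how the index is
  interpreted downstream.  It is invariant to positive rescaling of a raw
  trait but not to shifts of its zero point (the relative change has |PW|
  in the denominator); a PW mean of exactly zero is rejected.
- **treatment_level**: per-trait min–max scaling of the genotype ×
  treatment means (jointly over both treatments), with decrease-direction
  traits reflected (1 − scaled).  Rows are genotype × treatment pairs, so
  the index can be displayed per treatment.  This mode is fully invariant
  to affine unit changes.

Min–max (not z-scoring) is used because the index is defined on a 0–1
scale.  The CMTI is the unweighted mean of the normalized values — the
printed-formula definition, with no weighting option — so it is bounded in
[0, 1] and invariant to trait order.  Rank 1 is the highest index.

Classification scans all G − 1 split points of the sorted CMTI values and
takes the split minimizing total within-class sum of squares; this is the
exact two-class 1-D clustering optimum (the optimum of this criterion is
always contiguous in sorted order, and the tests verify equality with a
brute-force search over all bipartitions).  Ties go to the more balanced
split, then to the smaller lower class, making the result fully
deterministic — a seeded k-means would find the same optimum less
reproducibly.  The lower-CMTI class is labelled *stable*, the higher
*plastic*; identical values yield a single-class result with a warning.

## Derived traits and spectra

Density conversion divides a count by the region area (default
600 μm × 450 μm = 0.27 mm²).  The detached-leaf series reports
`pct_retained(t) = 100·weight(t)/weight(0)` *and* its complement under
unambiguous names, because the field protocol's "percentage water loss"
formula computes the retained fraction; a monotonicity flag marks balance
noise.  The dry-down rule takes the limited-water target moisture as the
midpoint between the saturated start and the observed wilting point.
Harvest metrics: filled % = 100·filled/spikelets, HI = grain dry
weight/shoot dry biomass, TGW = 1000·sample mass/sample count (identity at
the standard 1000-grain sample).  Milling yields (brown, milled, head) are
all expressed against the initial paddy mass — the head-rice denominator is
stated because both paddy-mass and milled-mass conventions exist.

Band indices integrate trapezoidally over a local linear ("rubber-band
endpoint") baseline: the line through the band's endpoint absorbances is
subtracted and negative residuals are clipped at zero before integration,
since the indices are semi-quantitative abundances.  The CEW index covers
2800–3000 cm⁻¹; the flavonol index sums five fingerprint bands (1125–1140,
1205–1225, 1270–1310, 1435–1475, 1605–1620 cm⁻¹).  The endpoint-linear
baseline makes the index exactly invariant to any global linear baseline;
integrated area (not peak height) was chosen as the more
resolution-tolerant semi-quantity.  Acquisition parameters (scan averaging,
nominal resolution) are instrument facts; any strictly ascending grid with
≥ 3 points per band is accepted.

## Numerical and reproducibility choices

- All randomness flows through numpy `SeedSequence` streams keyed by
  (seed, purpose), so every stage is bit-reproducible at a fixed seed and
  independent stages do not share streams.
- Exact identities (ANOVA decomposition, Σ VIP² = p, correlation-matrix
  reconstruction, score orthogonality) are tested at 1e-8; closed-form
  examples at 1e-6 or tighter.
- Degenerate inputs fail loudly: zero pooled sd, constant predictors or
  responses, unbalanced ANOVA cells, bands outside the spectral range,
  mass-ordering violations in milling records.
- Pipeline outputs carry a header comment with package version, a hash of
  the analysis-relevant configuration, and the seed; re-running a stage
  from its persisted inputs reproduces its outputs byte-for-byte.

## Problem sizes used in automated checks

Recovery checks run at: 50 synthetic experiments for CMTI classification
(21 genotypes × 2 trials × 8 replicates each), 100 benchmark datasets of
300,000 plants for VIP proxy recovery, 500 experiments of 8 + 8 plants for
Hedges-corrected effect recovery, and 100 seeds for δ¹³C coefficient-sign
recovery.  These sizes put Monte-Carlo error comfortably below the margins
being asserted while keeping the full suite fast.

## Known limitations

- The ANOVA is fixed-effects and balanced-only; multi-trial hierarchical
  analyses should use an external mixed-model tool.
- The CMTI carries equal trait weights by definition; no weighting or
  uncertainty propagation is provided.
- VIP selection against a hard threshold is unstable for predictors whose
  population VIP sits near 1 (see the benchmark-scale note above).
- The plasticity normalization is undefined for traits whose PW mean can be
  zero or change sign across genotypes; such traits should be re-expressed
  before indexing.
- No multi-response PLS2, orthogonal-PLS variants, or permutation inference
  for VIP scores.
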