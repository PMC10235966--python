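# Methods

This note documents the models behind each `follipulse` module, the tunable
parameters that matter, what the synthetic-data generators emulate (and what
they deliberately do not), and the numerical choices made where the design was
genuinely open.

## Hair-germ volume dynamics

Each hair germ's volume trajectory is expressed relative to its own largest
observed volume (set to exactly 100%; ties on the maximum resolve to the
earliest index). Statistics are per time point rather than per duration, so
unevenly sampled trajectories are handled without resampling.

**Behavior classification.** "Substantial contraction" is operationalized
against a single threshold (default 10% of the maximum):

- *continuous contraction* — the trajectory ends at or below 100 − threshold
  **and** never re-inflates more than the threshold above its running minimum
  once past the maximum;
- *continuous enlargement* — it ends no lower than it started **and** its
  maximum drawdown (running peak minus current value) never exceeds the
  threshold;
- *pulsatile* — everything else.

The published prose defines the three behaviors by example rather than by
rule, so this rule set is this package's operationalization; the threshold is
a parameter. Contraction is tested before enlargement so a trajectory that
ends deeply down but re-inflated in between is called pulsatile, not
contracting.

**Pooled contraction fraction.** All time points across trajectories are
pooled and the fraction *strictly* below the threshold (default 90% of the
per-follicle maximum) is reported — "smaller than 90%" reads as strict
inequality. Pooling weights each time point equally; weighting each follicle
equally instead would change the statistic when observation windows differ,
which is why the summary also records the raw point counts.

**Rounding.** Category percentages round half-up to one decimal, matching how
cohort percentages are conventionally printed (e.g. 2/25/4 of 31 →
6.5/80.6/12.9).

**Smoothing.** None by default; registration is assumed done upstream, and no
filtering is described for the source workflow. An optional rolling median
would be the first thing to add for noisier segmentations.

## AFM stiffness

Approach curves (probe travel z in nm, force in pN) are split into a flat
pre-contact baseline and a post-contact rise following a contact-mechanics
law with a geometry-fixed exponent: sphere (Hertz) F ∝ δ^{3/2}, cone
(Sneddon) F ∝ δ². Because the exponent is fixed, the modulus falls out of a
*linear* least-squares fit in δ^p — no iterative optimizer, no convergence
failures, exact noiseless inversion.

**Contact point.** Chosen as the split index minimizing the summed residual
of (constant baseline | contact-law rise). This joint piecewise fit is the
maximum-likelihood change point under Gaussian noise; in a simulation study
at 5%-of-peak force noise and ~3.8 nm sampling it localizes the contact
within ±3 samples (~11 nm) in ≥90% of curves, which leaves the modulus
recoverable to ~2% median error. A curve with no positive rise (pure
baseline) has no admissible split and raises a fit error.

**Parameters.** Poisson ratio ν defaults to 0.5 (incompressible soft
tissue); tip parameter is the sphere radius in µm (default 1 µm) or cone
half-angle in degrees. The indenter geometry of the source measurements is
not stated, so both models ship and sphere is the default; generator and
fitter share the geometry, keeping recovery studies self-consistent.

**Maps and comparisons.** Tissue maps are 8×8 grids (64 points over
15×15 µm). Per-point fit failures are flagged with reason codes
(`no_contact`, `negative_E`, `short_segment`) and excluded from summaries,
never silently dropped; a map with >50% failures raises. Regions are
compared by a two-sided Mann–Whitney U on pooled per-point moduli (points,
not follicles, as the sampling unit — the per-follicle alternative is a
one-line aggregation upstream). The test uses exact enumeration of the
permutation distribution (mid-ranked ties) whenever C(n, n_A) ≤ 2×10⁵ —
which covers all group sizes up to 8 and most unbalanced designs — scipy's
tie-free exact recurrence for remaining small tie-free cases, and the
tie-corrected normal approximation with continuity correction otherwise.
Full enumeration with ties beyond that bound is combinatorially infeasible
(e.g. 20 vs 20 → C(40,20) ≈ 1.4×10¹¹ assignments).

## F-actin / YAP mechano-score

**Cortical score.** From a line profile running interior → membrane: peak
intensity in the boundary window (outer 20% of the line) minus the median of
the interior window (central 40%); both windows configurable. A flat profile
scores 0.

**Permutation test.** Observed statistic is the Spearman correlation between
per-cell cortical F-actin and the nuclear/cytoplasmic YAP ratio (rank-based,
hence invariant to monotone transforms of either readout; Pearson is
available). The null shuffles the YAP column n_resamples times (default
1,000) with a seeded generator; the one-sided "less" p-value is
(1 + #{r_perm ≤ r_obs})/(n_resamples + 1), so p ≥ 1/1001 and a zero p is
impossible. One-sided "less" is the default because the scientific hypothesis
is specifically inverse correlation; two-sided is exposed.

**State score.** score = z(YAP ratio) − z(F-actin), standardized against
pooled reference means/SDs; positive calls anagen, negative telogen, exactly
zero is unassigned. This standardized difference is the simplest model
consistent with a "combined" two-feature score; a logistic fit on the same
two features would be the natural alternative and the evaluation scaffold
(leave-one-out accuracy + confusion counts) does not depend on the choice.

## Actin gene-set score

Counts are library-size normalized to a common total (10⁴) and log1p
transformed (via scanpy). The per-cell score is the mean normalized
expression of the gene set minus the mean of control genes drawn from the
same average-expression bins: genes are ranked by mean expression into
n_bins = 25 equal-size bins and n_ctrl = 50 controls per set gene are sampled
without replacement within the bin (deduplicated across set genes). This
bin-matching removes depth/abundance structure so a null set scores ≈ 0 in
every population; it is the de-facto standard single-cell signature score.
Set genes absent from the matrix are dropped with a warning if at least half
the set remains, otherwise the call errors. The actual actin gene list is an
input, not part of the package: the scoring machinery is the deliverable.

## Recoil kinetics

Post-ablation intervertex distance is modelled as a single exponential
L(t) = L0 + A(1 − e^(−t/τ)) (Kelvin–Voigt-like tissue response); the initial
recoil velocity is reported as the fitted v0 = A/τ rather than a
finite-difference of the first frames, for robustness — the two agree as the
frame interval → 0. Non-convergent fits and amplitudes indistinguishable from
zero (below max(10⁻⁶ µm, 3×residual SD/√n)) return a flagged flat-trace
result instead of raising. Because "the distance decreased by ~50% within
45 s" can mean either the plateau amplitude or the fixed-time displacement,
`compare_recoil` emits percent changes for the median v0, the plateau A *and*
the 45-s displacement, with a Mann–Whitney p on per-junction v0.

## Seed-site scanning

Canonical seed taxonomy, anchored on occurrences of the 6mer core (reverse
complement of miRNA positions 2–7, Watson–Crick only — G:U wobble never
counts inside a seed match): m8 complement immediately 5′ of the core and/or
an adenosine immediately 3′ of it upgrade the site, and each core occurrence
reports exactly one type (8mer > 7mer-m8 > 7mer-A1 > 6mer). Coordinates are
1-based inclusive on the UTR as given; DNA input is auto-converted (T→U)
with a warning. The duplex renderer aligns the full miRNA antiparallel with
position 1 opposite the A1 position and marks Watson–Crick pairs with bars
and G:U wobbles (flanks only, by construction) with colons. Conservation
scoring and duplex thermodynamics are out of scope.

## Synthetic-data generators

All generators draw every random quantity from a single integer seed per
call; no global state. What they emulate, and what they do not:

- **Volume trajectories** (6-min cadence, 4–6 h): per category, a baseline
  (cell count 10–20 × per-cell volume 454–735 µm³) times a shape — linear
  drift ±5%/h for continuous enlargement/contraction, or 1–4 smooth
  raised-cosine contraction pulses (depth 20% ± 20% jitter, half-width
  8–15% of the window, kept clear of the endpoints) for pulsatile — times
  multiplicative Gaussian noise (2% CV; segmentation error scales with
  object size). Pulses are smooth rather than white noise so crossings of
  the 90% line are well defined, matching the slow pulsation seen in
  intravital movies. Defaults were calibrated a priori to the published
  aggregates (category mix 6.5/80.6/12.9%, pooled below-90% fraction ≈ 34%
  in telogen); single-pulse magnitudes are not uniquely determined by the
  published aggregates. The anagen preset (mix 25/65/10%, pulse depth 5%,
  drift 2.5%/h) encodes the reduced-contraction regime; its pooled fraction
  (~11–15%) sits somewhat above the published 9.77% because continuously
  enlarging trajectories necessarily spend early time points below 90% of
  their final maximum. `cohort_point_counts` reproduces the published cohort
  layout exactly: 31 telogen follicles / 1,560 points and 16 anagen
  follicles / 655 points. Not emulated: cell divisions, drift registration
  artifacts, 3-D segmentation bias.
- **Force maps**: per-point truth moduli are constant, or drawn from a
  moment-matched lognormal when a map SD is requested — tissue moduli are
  positive and right-skewed, and a Gaussian at the published SDs (~55% of
  the mean) would produce nonphysical near-zero moduli. The contact point
  sits uniformly in the first third of the ramp, exactly on the sampling
  grid (so noiseless inversion is exact by construction), with a zero-slope
  baseline and additive Gaussian force noise. Not emulated: cantilever
  hydrodynamics, adhesion on retract, substrate (finite-thickness) effects.
- **Mechano records**: per stage, (F-actin, YAP) pairs from a Gaussian
  copula with correlation ρ ∈ [−1, 0]; stage means encode the observed
  structure (telogen: strong actin 100 ± 15 a.u., low YAP ratio 1.0 ± 0.2;
  anagen: 60 ± 15 and 2.0 ± 0.4). ρ = −1 produces an exactly anti-monotone
  pairing. Values are floored just above zero; the floor is effectively
  never hit at the default means.
- **Expression**: negative-binomial counts (gamma–Poisson, shared dispersion
  10 — the standard droplet-data model) over lognormal base expression;
  actin-set genes are scaled by each population's fold-change *before*
  sampling, so the all-ones effect is exactly exchangeable with background.
  Library sizes 8,000–12,000. Not emulated: dropout beyond NB sparsity,
  batch effects, doublets, cell-type-specific dispersion.
- **Recoil**: the exponential model plus additive Gaussian noise, sampled at
  2 Hz over 45 s. Control A = 3 µm, τ = 10 s (v0 = 0.30 µm/s); the treated
  preset A = 1.5 µm, τ = 7.5 s jointly encodes the −50% plateau and −33%
  initial-velocity effects (v0 = 0.20 µm/s).
- **UTRs**: i.i.d. background at a configurable GC fraction with exact site
  sequences spliced in at known 1-based positions; chance background matches
  are logged, and `screen_chance=True` redraws backgrounds until the planted
  sites are the only hits. Not emulated: codon structure, conservation,
  secondary structure.

Passing tests on these generators shows the *estimators* are correct and
calibrated under their stated models; it does not certify performance on
real images or libraries, where segmentation bias, drift, adhesion artifacts
and batch structure violate the generator assumptions in ways the noise
terms here do not capture.

## Numerical choices and degenerate inputs

- Normalization sets the maximum to exactly 100 (not merely within float
  error); normalizing an already-relative trajectory is a no-op.
- Percent rounding uses decimal half-up (not banker's rounding).
- Exact Mann–Whitney p-values are two-sided as 2×min(lower tail, upper
  tail), tails inclusive, clipped at 1; ties are mid-ranked.
- The Hertz fit subtracts the pre-contact baseline mean and requires ≥ 5
  post-contact points; a non-positive fitted coefficient raises rather than
  returning a negative modulus.
- Permutation p-values use the add-one convention; seeds are recorded in the
  result objects.
- Constant inputs raise explicit degenerate-input errors (correlation test,
  state calibration) rather than returning NaN.
- Scenario runs derive one child seed per module from the global seed via
  `SeedSequence.spawn`, so adding a module never perturbs another module's
  stream; manifests record version, seeds, parameters and the report hash.

## Problem sizes

Default test and acceptance runs use 31–200 follicles, 64-point maps with
500-curve recovery studies, 500-dataset permutation calibrations, 50-seed
ranking/ordering studies and 200–1,000 UTRs; the full suite runs in well
under a minute per module on one core.

## Known limitations

- The behavior rule set and the 90%/10% thresholds are an operationalization
  of prose definitions; cohorts classified with different conventions will
  shift category counts for borderline trajectories.
- The AFM model ignores finite sample thickness and tip–sample adhesion,
  which bias absolute moduli on real sliced tissue; relative comparisons are
  more trustworthy than absolute values.
- The state score is linear; strongly non-elliptical stage distributions
  would favor the logistic alternative.
- The module score depends on the binning of average expression; very small
  matrices (< a few hundred genes) leave bins too sparse for clean control
  matching.
- The recoil model is single-exponential; viscoelastic tissues with two
  relaxation times need the double-exponential extension.
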