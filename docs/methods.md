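# Methods

## The measurement model

Gated platelet FSC events from one animal are modelled as draws from a
finite mixture of exponentially modified Gaussians (EMG). The EMG — a
Gaussian core with an exponential right tail — matches the right-skewed,
strictly positive shape of scatter distributions: the Gaussian part absorbs
instrument spread and within-class size variation, the exponential part the
skew toward larger objects. We parameterize by (μ, σ, λ) with λ the *rate*
of the exponential tail (mean μ + 1/λ); the alternative "tail mean"
parameterization τ = 1/λ is a trivial reparameterization.

The analysis is hierarchical with K = 2 at each level:

1. **Level 1** — all events → {normoplatelets, aggregates}. After fitting,
   the component with the larger mean (μ + 1/λ) is the aggregate class,
   always by mean ordering, never by index; this removes label-switching
   ambiguity between fits.
2. **Level 2** — events classified as normoplatelets → {small, large
   platelets}, again by ascending mean.

Per-class percentages are fractions of events assigned by maximum posterior
responsibility (ties broken toward the lower-mean class). This per-object
reading is the default because the study endpoint counts objects; the
fitted mixture weights π are reported alongside and the two agree to
O(1/√N) when components are well separated.

Whether the original analysis fitted per animal or pooled per group is not
determinable from the source; the default is per-animal fitting (group
comparisons need per-animal statistics), with a `pooled` mode that fits each
arm's concatenated events and reports pooled classified fractions.

## EM algorithm

No closed-form M-step exists for EMG mixtures, so the package uses
generalized EM: the E-step is standard; the M-step updates weights in closed
form (mean responsibility) and each component by L-BFGS-B on the
responsibility-weighted negative log-likelihood over (μ, log σ, log λ),
warm-started at the current parameters with analytic gradients. If the
optimizer fails to improve a component, the current parameters are kept, so
every accepted iteration cannot decrease the likelihood; the recorded
log-likelihood trace is enforced non-decreasing (a numerical dip below the
last accepted value terminates the fit).

Numerical choices:

- density evaluated in log space; the erfc factor goes through erfcx on the
  z ≥ 0 branch so the density is accurate out to λσ ~ 10³ (the Gaussian
  limit) and far into both tails;
- convergence: relative log-likelihood change < 1e-8, at most 500
  iterations; inner optimizer capped at 30 iterations per component per
  M-step;
- default initialization: sort the values, split at the (1 − 0.15) quantile
  (anticipating a minority large-object class), method-of-moments EMG per
  block. The moment inversion uses k = (g₁/2)^(1/3), λ = 1/(sk),
  σ² = s²(1 − k²), μ = x̄ − sk, falling back to an even variance split when
  the sample skewness is non-positive or k ≥ 1;
- the level-2 refit instead initializes from a split at the (1 − 0.08)
  quantile, matching the ~7–8% prior share of large platelets; with the
  generic 0.15 split the refit occasionally converged to a wrong-basin
  optimum (observed at roughly 1-in-8 fits on realistic inputs);
- degeneracy (any weight < 1e-3, or σ < 1e-6 × data range) triggers one
  seeded restart from perturbed initial values, then a hard
  `DegenerateFitError`;
- input values are sorted internally, making fits exactly invariant to
  input order;
- a fitted 2-component split is only reported when the component means
  differ by at least 0.1 pooled within-component SDs *and* EM converged;
  otherwise the summary is flagged unreliable rather than reporting a
  spurious split (this is what a single-population input produces);
- the level-2 refit requires ≥ 50 normoplatelet events, below which level-2
  metrics are marked unavailable rather than aborting the animal.

## Group summaries and comparisons

Across-animal summaries are medians with 25th–75th percentiles (linear
interpolation), computed on all animals whose fits passed the reliability
flags; no outlier removal happens inside the pipeline. Grubbs screening is
a separate explicit step: iterative two-sided Grubbs at α = 0.05, critical
value G = ((N−1)/√N)·√(t²/(N−2+t²)) with t the upper α/(2N) Student-t
quantile on N−2 df, repeated until no removal or only three values remain.

"Bootstrap-boosted one-sided Mann–Whitney U" is implemented as: resample
each group with replacement at its original size B = 1000 times, compute the
one-sided p per resample, and report the median bootstrap p plus the
2.5th–97.5th percentile interval and the fraction of resamples with
p < 0.05; the plain test is always reported alongside. This is one
defensible reading of a procedure whose original definition is not public
(alternatives — pooled-null resampling, BCa correction — are noted, not
guessed). The U convention counts evidence that the second sample is
greater, U = #{y_j > x_i} + ½·ties. The exact null (dynamic programming
over the Mann–Whitney recurrence) is used when both n ≤ 12 and no value is
shared *across* the samples; duplicates within one sample keep U integral
and leave extreme-tail permutation probabilities exact, which is what makes
the complete-separation bootstrap case exactly 1/C(14,7) per resample.
Otherwise a midrank tie-corrected normal approximation with continuity
correction is used (zero tie-corrected variance returns p = 0.5).
Comparison directions are always declared explicitly per metric — the
default pipeline tests aggregates *lower* and large platelets *higher* in
the treated arm — never inferred from the data.

## Survival

Kaplan–Meier curves come from lifelines. The two-arm comparison is the
Peto–Prentice (generalized Wilcoxon) weighted log-rank test: at the j-th
distinct event time the weight is the Peto–Peto modified pooled survival
estimate S̃(t_j) = Π_{t_i ≤ t_j} (1 − d_i/(n_i+1)), ties handled by the
multi-death hypergeometric mean/variance, statistic
[Σ w_j(d_1j − e_1j)]²/Σ w_j² v_j against χ²(1). The weight convention
includes time t_j itself; the left-limit variant S̃(t_j−) is available via
`left_limit_weights=True`, and w ≡ 1 gives the standard log-rank (used to
cross-check against lifelines). Weights are non-increasing in time and lie
in (0, 1], so early deaths dominate — appropriate when late follow-up is
truncated by terminal euthanasia.

## Synthetic cohort generator

The generator emulates the statistical design the pipeline assumes: two
arms ("4T1" control, "4T1+ASA/Cl" treated) of 7 mice each, ≥ 10,000 gated
events per mouse, each mouse's events drawn from a three-class EMG mixture
(small normoplatelets / large normoplatelets / aggregates) by level-1 then
level-2 weights. Arm-level default weights are the published group medians:
aggregates 16.2% (control) vs 14.0% (treated); large platelets within
normoplatelets 7.1% vs 7.8%. Mouse-to-mouse variability is logit-normal
jitter on both weights (SD 0.12 on the logit scale, chosen so simulated
7-mouse IQRs are commensurate with the published IQR widths, whose implied
per-arm logit SDs span ~0.08–0.29). Any non-positive FSC draw is rejected
and redrawn, since FSC is physically positive.

Class EMG defaults (FSC arbitrary units): small normo (μ=185, σ=30,
λ=1/42; mean 227), large normo (435, 48, 1/58; mean 493), aggregates
(1150, 140, 1/300; mean 1450). These were calibrated once, by simulation,
to the joint requirement that the components genuinely overlap (the best
pair of fixed FSC thresholds still misclassifies ≈1% of events, so EM has
real work to do) while the two-level EM pipeline recovers the configured
weights with small bias: at 10,000 events/mouse the classified-fraction
bias is ≈0 points at level 1 and ≈ +0.3 points at level 2, with per-mouse
SDs of 0.2–0.3 points. Pushing overlap substantially higher is not
compatible with accurate recovery: the level-1 fit is structurally
misspecified (its "normoplatelet" component really covers a two-component
sub-mixture), and with heavier overlap it acquires multi-point
classified-fraction biases and the level-2 likelihood becomes multimodal.
The overlap was therefore set as high as unbiased recovery allows.

Bead tables follow FSC = 100·size^1.5 over seven sizes in 1–15 μm with
multiplicative lognormal noise of configurable CV (default 5%, unit mean,
so CV = 0 reproduces the law exactly). Survival records are Weibull per
arm — control shape 3, scale 45 d; treated shape 3, scale 38 d (the treated
arm dies earlier, matching the emulated study's direction) — with
administrative censoring at day 35, the terminal-euthanasia horizon. All
outputs are byte-reproducible functions of the configuration seed.

What the generator does *not* emulate: fluorescence channels, antibody
staining and compensation, doublet optics, instrument drift, non-EMG event
shapes, and between-day batch effects. Passing recovery tests therefore
demonstrate that the pipeline inverts its own generative model at realistic
sizes and overlap — not that real cytometry data satisfy the EMG mixture
assumption.

## Problem sizes in the test suite

The acceptance-style recovery checks run the full two-arm study (14 mice ×
10,000 events). Property tests use the sizes at which their guarantees are
informative while keeping the suite fast: mixture recovery at 10⁴ events,
monotone-recovery across 500/5,000/50,000 events over 8 seeds, Grubbs null
calibration over 10⁴ Normal samples of size 10, Peto–Prentice null
calibration over 200 simulated 120-animal studies, and exhaustive
Mann–Whitney enumeration for all sample sizes up to 5.

## Known limitations

- The level-1 model is deliberately misspecified (two fitted components for
  a three-class truth); residual classified-fraction bias at level 2 is
  ≈ +0.3 points under default conditions.
- FCS container files are not read; events must be exported to CSV with a
  mouse/group assignment.
- K is fixed at 2 per level; no model-order selection, no multivariate
  (FSC×SSC) mixtures, no Cox regression or >2-group survival tests.
- Bootstrap-boosted p-values are a resampling summary of the plain test,
  not a calibrated frequentist p-value; both are always reported.
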