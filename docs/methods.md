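# Methods

## Model and assumptions

All procedures assume an i.i.d. sample from the Fisher distribution on the
unit sphere S², the p = 3 member of the von Mises–Fisher family:

    f(θ, φ) = [κ / (4π sinh κ)] exp{κ [cos α cos θ + sin α sin θ cos(φ − β)]} sin θ,

with mean direction (α, β) (colatitude α ∈ [0, π), longitude β ∈ [0, 2π))
and concentration κ > 0. The density is rotationally symmetric about the
mean direction and unimodal; κ plays the role 1/σ² plays for the normal
distribution. The sin θ factor is the area element, so the density above
integrates to one over the (θ, φ) rectangle.

Outliers are modelled by *slippage*: contaminants follow a Fisher
distribution whose mean direction is displaced from the null by an angle
λπ, λ ∈ [0, 1], while remaining concentrated (κ_out = 30 by default).

## Distance and statistics

The working distance is d = 1 − cos θ₁₂ = ‖**x**₁ − **x**₂‖²/2 ∈ [0, 2],
the squared chord length with the constant 2 removed. It is monotone in
the central angle, so nearest-neighbour ranks agree with those of the
great-circle distance, and it is invariant under common rotations.

- Q_i^k: the k-th smallest of the n − 1 distances from observation i,
  obtained by an ascending sort (ties occupy consecutive ranks;
  `numpy.partition` gives the same k-th order statistic). Q_i^k is
  non-decreasing in k.
- C_i and E_i use the leave-one-out resultant lengths R_{n−1}^(−i),
  computed by the algebraic update ‖S − **x**ᵢ‖ of the full component sum S
  (equal, to rounding, to recomputing the resultant on each subset — the
  test suite checks this equivalence against from-scratch recomputation).
- For every statistic both the per-observation values and the per-sample
  maximum are exposed; the detection rule compares each observation's value
  to a single cut-off, so calibrating on the maximum controls the
  family-wise exceedance rate.

## Estimation

The mean direction (α̂, β̂) is the direction of the resultant vector. The
concentration MLE solves the exact S² score equation A(κ) ≡ coth κ − 1/κ =
R̄ by bracketed Brent root-finding (|A(κ̂) − R̄| < 1e−13); the classical
large-κ approximation (n−1)/(n−R) is available as `method="approx"`. On
the packaged eye data the exact MLE (17.92) is far closer to the reported
value (17.91) than the approximation (17.14), which is why it is the
default. A sample with R̄ = 1 (all points identical) has no finite MLE and
raises; R̄ = 0 leaves the mean direction undefined and is flagged as
degenerate.

## Sampling

Fisher variates are drawn about the pole by exact inversion of the
colatitude cosine — w has density ∝ exp(κw) on [−1, 1], so
w = 1 + κ⁻¹ log[e^(−2κ) + u(1 − e^(−2κ))] for u ~ U(0, 1) — with uniform
longitude, then rotated so the pole maps to the requested mean direction
(rotation by α about y, then β about z; the azimuthal gauge is immaterial
by rotational symmetry). The method involves no rejection step, so a fixed
`numpy.random.Generator` seed reproduces every draw. E[w] = A(κ), which
the tests verify at 10⁵ draws.

For κ ≳ 350, e^(−2κ) underflows to zero; the inversion formula degrades
gracefully (w = 1 + log(u)/κ, the κ → ∞ limit) and the normalising
constant of the density is evaluated in log-space, so concentrations up to
at least 10⁶ are usable.

## Cut-off calibration

Cut-offs are empirical upper quantiles of the per-sample maximum statistic
over `reps` null samples (default 3000) drawn at (n, κ) about the pole —
legitimate because the statistics are rotation-invariant, which a test
verifies by rotating matched-seed samples. The quantile convention is
fixed: the cut-off at upper level ℓ is the ⌈reps·(1 − ℓ)⌉-th ascending
order statistic of the maxima. Simulations are vectorised over replicates
and chunked so the reps × n × n distance tensor stays near 160 MB; cut-offs
for several k are extracted from one shared set of samples, which makes
the k-monotonicity of the Q^k cut-offs exact per seed.

When testing real data the cut-off is simulated at the exact n and the
plugged-in κ̂ of that sample, not interpolated from a precomputed grid.
κ̂ is fitted from the full sample *including* suspected outliers; this is
masking-prone but is the conventional plug-in choice and the default, and
a user-supplied κ overrides it.

## Sequential detection

Step k of the procedure flags every observation with Q_i^k strictly above
the level-ℓ cut-off; the first non-empty flag set stops the loop and is
declared a patch of size k. Two deliberate choices:

- Patch membership is "all exceeders", not "the exceeder plus its k − 1
  nearest neighbours": in a genuine patch of k, each member's Q^k reaches
  past the patch to the bulk, so all members exceed together. The
  neighbour-completion variant exists behind `include_neighbours=True`.
- `max_k` defaults to 3. Large k relative to n makes Q^k a bulk property
  rather than an outlier diagnostic, and the calibrated tables cover
  k ≤ 3. If the flag sets at different k disagree, the smallest flagging k
  wins — the procedure never revisits earlier k.

## Power study (P5)

Each replicate plants m contaminants at uniformly random positions (their
indices tracked) in an n-point sample. P5 is the proportion of replicates
counted as *correct* detections; by default that requires every
contaminant index to exceed the cut-off at k = m ("all"), with "exact"
(flag set equals the contaminant set) and "any" as options. At λ = 0 with
κ_out = κ_null the contaminants are exchangeable with the null sample, so
P5 cannot exceed the level — the property tests assert this.

Two variance-reduction devices make curves comparable: all three
statistics are evaluated on the same simulated samples, and the same null
draws, pole-centred contaminant draws and placement permutations serve
every λ (the contaminants are rotated further for larger λ). Points on a
curve are therefore positively correlated across λ, which is intended —
the object of interest is the shape of each curve and the contrast between
statistics, not independent per-λ confidence intervals. Patch contaminants
are drawn i.i.d. from the displaced distribution; correlated ("one draw
shared by the patch") contamination is not modelled.

## Numerical tolerances for the published worked example

The packaged eye-data angles are printed to 3 decimals (±5·10⁻⁴ rad).
Propagating that rounding through the pipeline bounds the reproducible
precision of the published 4-decimal values: about 2·10⁻³ for the Q and C
statistics and the mean direction, 2·10⁻² for E (whose denominator
n − 1 − R_loo is small, ≈ 0.6, and magnifies input error), and 5·10⁻² for
κ̂ (dκ/dR̄ ≈ 300 at R̄ ≈ 0.97). The tests assert the published values at
these input-precision tolerances; computing at full precision from the
printed angles gives e.g. Q²₁₇ = 0.16994 against a published 0.1702.
Published cut-off tables are Monte-Carlo estimates rounded to 2 decimals;
regenerated cells are compared within three bootstrap standard errors of
the replicate maxima plus the 0.005 print-rounding half-ulp.

## Problem sizes used by the test and acceptance runs

Cut-off spot checks regenerate 13 table cells at the full 3000 replicates,
spanning n ∈ {10, …, 200} and κ ∈ {2, …, 50}; the decision-reproduction
check runs 20 independent calibration seeds at 3000 replicates; power-study
properties are asserted at 500 replicates per λ, where the binomial
standard error (≈ 0.022) motivates the 0.03 monotonicity jitter allowance.
Oracle checks use 10⁵ sampler draws and n = 10⁴ fitting samples.

## What the synthetic data do and do not capture

Simulated samples are exactly Fisher — rotationally symmetric, unimodal,
correctly specified. Real directional data may be girdled, bimodal or
asymmetric about the mean direction, and κ̂ plugged into the calibration is
itself estimated from contaminated data. Passing tests demonstrate correct
behaviour *under the model*, including its contaminated (slippage)
variants; they do not certify performance under model misspecification,
nor for other spherical families (Kent, Watson), higher-dimensional
hyperspheres, or axial data, all of which are out of scope.
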