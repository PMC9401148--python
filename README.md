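# spherout

Outlier discordancy tests for spherical directional data.

Spherical observations — directions in three dimensions recorded as a
colatitude/longitude pair (θ, φ) — arise in geology, biology, medical
imaging and environmental science. A single aberrant direction can distort
the estimated mean direction and concentration of a sample, so formal
discordancy tests are needed. `spherout` implements a k-nearest-neighbour
distance statistic, **Q^k**, that detects single outliers, multiple
outliers, and *patches* (clusters of k jointly discordant points) in
samples assumed to follow the Fisher (von Mises–Fisher, p = 3)
distribution, alongside the classical leave-one-out competitors **C^k** and
**E^k**.

## The statistics

Each observation is a unit vector **x**ᵢ = (sin θᵢ cos φᵢ, sin θᵢ sin φᵢ,
cos θᵢ). With the spherical distance d(**x**ᵢ, **x**ⱼ) = 1 − cos θᵢⱼ
(half the squared chord length),

- **Q_i^k** — the k-th smallest distance from **x**ᵢ to the other
  observations. A lone outlier has a large Q¹; a patch of two has small
  Q¹ (its members are mutual neighbours) but a large Q².
- **C_i** = (R̄ₙ₋₁⁽⁻ⁱ⁾ − R̄ₙ)/R̄ₙ — the relative gain in mean resultant
  length when observation i is deleted.
- **E_i** = (n−2)(1 + Rₙ₋₁⁽⁻ⁱ⁾ − Rₙ)/(n−1 − Rₙ₋₁⁽⁻ⁱ⁾) — a
  likelihood-ratio-type analogue.

Null cut-off points are the upper quantiles of the per-sample **maximum**
statistic over Monte-Carlo simulated Fisher samples at the design point
(n, κ) — the null distribution depends only on the sample size and
concentration, not on the mean direction. The sequential procedure starts
at k = 1 and raises k until some Qᵢᵏ exceeds its cut-off, declaring the
exceeding observations a patch of k outliers.

## Worked example

The packaged dataset (`spherout.load_eye_data()`) holds anterior-segment
optical-coherence-tomography angle measurements for 23 patients: the
posterior corneal curvature angle φ and the eye angle θ, in radians.

```python
import spherout as so

table = so.load_eye_data()
V = so.angles_from_table(table)
print(so.fit_fisher(V))            # FisherParams(alpha=0.6832, beta=1.5744, kappa=17.9186)
res = so.detect_sequential(V, level=0.10, max_k=3, reps=3000, seed=11)
print(res.stopped_at_k, res.flagged)   # 2 (16,)  -> patient 17 flagged at k=2
```

or from the shell:

```
$ spherout detect eye --reps 3000 --seed 11
flagged observations 17 as a patch of 2 at k=2 (cutoff 0.1435, level 0.1)
  Q1: max 0.0410 at observation 23 (cutoff 0.1062)
  Q2: max 0.1699 at observation 17 (cutoff 0.1435)
  Q3: max 0.1925 at observation 17 (cutoff 0.1704)
```

Patient 17 sits apart from the rest of the sample, but its nearest
neighbour (patient 10) is close, so the first-nearest distance Q¹ = 0.0365
stays below its cut-off; at k = 2 the isolation shows (Q² = 0.1699 >
0.1435) and the observation is flagged. The one-shot C and E tests do not
reach their critical values on these data. With patient 10 relocated next
to patient 17 (`load_eye_data(modified=True)`) the two form a genuine
patch, and the same command flags both:

```
$ spherout detect eye-modified --reps 3000 --seed 11
flagged observations 10, 17 as a patch of 2 at k=2 (cutoff 0.1553, level 0.1)
```

`spherout calibrate` tabulates cut-off points over an (n, κ) grid and
`spherout power` runs the slippage-contamination study: n − m observations
from the null Fisher(0, 0, κ), m contaminants from Fisher(λπ, 0, κ_out),
reporting P5 — the probability that the contaminants themselves are the
observations flagged — as λ sweeps from 0 to 1.

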