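# Methods

## The binomial release model and MPFA

The package treats a unitary connection as *N* independent release sites,
each releasing at most one vesicle of quantal charge *q* (fC) per
presynaptic action potential with probability *P_r*. The trial-charge
moments are

- mean `m = N · P_r · q`
- variance `σ² = N · P_r (1 − P_r) q² + N · P_r · q² · cv_intra² + noise_sd²`
- failure probability `(1 − P_r)^N`

Across conditions that vary *P_r* (experimentally: extracellular
Ca²⁺/Mg²⁺), (m, σ²) pairs trace the parabola `σ² = q·m − m²/N`. MPFA fits
`σ² = A·m − B·m²` by weighted least squares through the origin and reads
off `q = A`, `N_frs = 1/B`, `P_r = m/(N_frs·q)` (clipped to [0, 1] with a
warning if an epoch mean exceeds the fitted saturation). `N_frs` is an
estimator, reported as a real number and never rounded. A fitted `B ≤ 0`
(collinear variance–mean points) means the sampled release probabilities
are too low to constrain *N*: the fit returns *q* from the initial slope,
leaves `N_frs` undefined and records a "no curvature" warning. An
optional intercept term can absorb unsubtracted baseline-noise variance;
by default the parabola is forced through the origin on the assumption
that baseline variance is negligible at the charge level.

### Pairwise variance

Per-epoch variances use the consecutive-difference estimator
`s² = Σ (x_{i+1} − x_i)² / (2(n−1))`, which is unbiased for iid data and
cancels slow drift exactly: a pure linear ramp of step *b* contributes
`b²/2` independent of *n*, whereas the ordinary sample variance of the
same ramp grows as `b²n²/12`.

### Weighting

Points are weighted by the inverse theoretical variance of the variance,
using the Gaussian approximation `Var(s²) = 2σ⁴/(n−1)`. With reweighting
enabled (the default), weights are refreshed from the fitted parabola's
predicted variances and the fit iterated to a 1e−6 relative tolerance
(max 20 iterations), removing the dependence of the weights on the noisy
per-epoch variance estimates. Two numerical notes:

- The exact sampling variance of the *pairwise* estimator on iid Gaussian
  data is `σ⁴(3n−4)/(n−1)²` — asymptotically 1.5× the Gaussian
  approximation, because consecutive differences are correlated. Since
  WLS is invariant to a constant factor in the weights and both
  expressions scale as σ⁴, the fitted parameters are unaffected; the test
  suite pins both the exact value (by Monte-Carlo) and the 1.5 ratio.
- Degenerate zero-variance points (constant epochs) would get infinite
  weight; they are capped at the largest finite weight and flagged.

### Estimator bias under quantal variability

Intra-site quantal variability inflates the fitted slope: with
trial-to-trial multiplicative quantal noise of coefficient of variation
`cv_intra`, the variance becomes `q(1 + cv_intra²)·m − m²/N`, so `q̂`
estimates `q(1 + cv_intra²)` (≈ 1.09 q at cv_intra = 0.3) while `N̂` stays
unbiased. The acceptance script measures this inflation on 200 simulated
experiments at 400 trials/epoch.

## The synthetic-data generator

`simulate.make_experiment` is the generative twin of the fitted model:
per-trial charges are sums of Bernoulli(P_r) releases over sites.
Defaults reflect the experimental design this package targets: 3–5
calcium conditions, 75 trials per epoch at 5 s inter-trial intervals,
human-like (N = 20, q = 40 fC) and rat-like (N = 5, q = 30 fC) parameter
sets, P_r ladders spanning ~0.1–0.8.

Quantal variability is decomposed as:

- `cv_intra` — independent multiplicative noise per released vesicle per
  trial (default 0.3, a conventional placeholder for central synapses;
  enters the variance and biases q̂ as above);
- `cv_inter` — fixed per-site quanta drawn once per experiment around q
  (default 0; a simulator-only feature not folded into the closed-form
  moments).

Additive Gaussian baseline charge noise (`noise_sd_fc`) and an optional
linear multiplicative drift (quantum scaled to `1 + drift_per_epoch` by
the last trial) complete the noise model. Seeding: one master seed per
experiment; per-epoch streams are spawned via `numpy.random.SeedSequence`
so each epoch is independently reproducible.

What the generator does **not** emulate: calcium-dependence of P_r (a
Hill curve) — conditions carry P_r directly; receptor saturation and
desensitization (handled pharmacologically in the experiments this
emulates); series-resistance artifacts; correlated (non-white) recording
noise; vesicle replenishment dynamics. Passing recovery tests therefore
demonstrate estimator correctness under the model's own assumptions, not
robustness to these real-data departures.

### Rendered traces

Single trials are rendered as negative-going alpha functions,
`I(t′) = −A(t′/τ)exp(1 − t′/τ)` with `A = charge/(τ·e)`, so the waveform
peak is A (pA) and the infinite-window integral equals the requested
charge (1 pA·ms = 1 fC). The alpha function is a surrogate: only kinetic
summaries (rise, decay, latency), not waveform shape, are constrained by
the data this package models. Default τ = 0.5 ms gives a 10–90% rise of
~0.285 ms and a 37%-of-peak decay time of ~1.069 ms, in the physiological
range for these connections.

### Synthetic active zones

`generate_active_zone` draws vesicle distances uniformly within each
class range: docked [0, 0.5] nm, pre-docked (0.5, 5] nm, pool
(5, 100] nm, outside (100, 300] nm, so classification recovers the
requested counts exactly (the round-trip invariant). The pre-docked lower
bound is the contact tolerance, not 0, precisely so the round trip is
exact.

## EPSC detection and measurement

- Noise SD: sample SD of a pre-stimulus baseline window (≥ 50 samples)
  after mean subtraction; the window mean is the baseline level.
- Detection: first excursion beyond k × noise SD below baseline
  (k ∈ [2, 4], default 3) within the onset limit (default 2 ms) after the
  stimulus; the peak (largest deflection) must follow within the peak
  limit (default 3 ms) of the threshold crossing, and a deflection still
  growing at the window edge is rejected. Trials violating any rule are
  failures.
- Onset: the 10–90% rise slope line back-projected to baseline
  (`t_onset = t10 − 0.125·(t90 − t10)` for a linear rise). This is a
  declared convention — isolated in one place so it can be swapped — since
  "onset" admits several operationalizations.
- Kinetics: latency = onset − stimulus time; 10–90% rise and
  37%-of-peak decay via linear interpolation between samples. A trace
  ending before the 37% level flags the event right-censored with decay
  missing.
- Charge: trapezoidal integral of the baseline-subtracted current
  magnitude from onset until the current first returns within 1 noise SD
  of baseline after the peak (or a 50 ms window cap); on noise-free
  rendered traces the measured charge matches the requested charge to
  well under 0.5%.

Single-sample threshold crossing on unfiltered white noise has a
non-negligible per-window false-positive rate at k = 3; the experimental
workflow this mirrors inspects detected events by eye, and the package
leaves any pre-filtering to the caller.

### Epoch stability

Epochs are screened for drift by regressing charge normalized to the
epoch mean against time normalized to the epoch duration; the epoch
passes iff |slope| < 0.05, i.e. < 5% systematic drift across the epoch
(boundary values fail; the comparison guards against float rounding at
the boundary). The normalization makes the criterion scale-free — a
declared convention. Note that for drift-free but high-variability epochs
(low P_r, CV ≫ 1) the slope estimate's sampling SD (~CV·√(12/n)) exceeds
0.05, so the screen rejects clean epochs by chance alone; callers running
simulation studies use the documented `require_stability=False` override,
which keeps all epochs and logs warnings instead.

## Ultrastructure metrics

Classification bounds are closed on the upper end: docked ≤ 0.5 nm
(contact, with tolerance for measurement quantization), pre-docked
≤ 5 nm, pool ≤ 100 nm, outside beyond. Distances arrive pre-measured as
scalars; mesh geometry is out of scope. Docked density = docked count /
AZ area; the proximal pool is all vesicles within 100 nm normalized to AZ
area. Bouton volume from the largest cross-section assumes a sphere:
`V = (4/(3√π))·area^{3/2}`. Cohort summaries delegate the docked-count
vs AZ-area rank correlation to `scipy.stats.spearmanr`.

## Derived cross-species metrics

From cohort means (computed upstream or typed in from published
summaries): release sites per AZ = mean N_frs / mean N_lm (valid because
each bouton contains a single AZ and each LM contact is one bouton);
area per site = mean AZ area / sites per AZ; docking-site occupancy =
mean docked per AZ / sites per AZ (reported unclamped with a note if
> 1 — it is a ratio of estimates, not a probability). Ratios are computed
at full precision; presentation rounding (one decimal) happens only in
the report layer. The rat-to-human age map is linear,
`years = 12 + (day − 38)/3.3`, anchored at sexual maturity, and exactly
invertible.

## Problem sizes and tolerances

The recovery study uses 100 experiments × 4 conditions × 75 trials
(the design scale of the experiments modeled); the bias study uses 200
experiments at 400 trials/epoch; the classification round trip uses
1,000 random AZs. Exact noiseless parabola inversion is asserted to 1e−9
relative error; Monte-Carlo assertions use 3-SE bands or 10–20% median
tolerances appropriate to their replicate counts. The WLS normal
equations are solved by `numpy.linalg.lstsq`; predicted variances are
floored at 1e−12 during reweighting to keep weights finite near the
origin.

## Known limitations

- MPFA assumes uniform q and P_r across sites; heterogeneity biases both
  estimates and is not modeled beyond the intra/inter-site CV terms.
- The variance-of-variance weighting ignores higher moments (kurtosis) of
  the charge distribution; at n ≈ 75 trials per epoch the recovery tests
  bound the practical consequence (median N̂ within a few percent of
  truth), but per-experiment scatter in N̂ remains large (~±30%).
- Failure-rate consistency uses a normal approximation to the binomial;
  it is diagnostic, not a formal test.
- Detection operates on unfiltered traces; heavily noise-contaminated
  recordings need pre-filtering upstream.
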