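# Methods

This note records the model, the numerical choices and the design decisions
behind phenofill, and what the synthetic experiments do and do not show.

## Model and assumptions

Each pixel's descriptor series is modelled as y_i = f(t_i) + ε_i with
ε_i ~ N(0, σ_n²) i.i.d. and a **zero-mean** GP prior on f with the
squared-exponential kernel k(t_i,t_j) = σ_f² exp(−Δ²/(2l²)). Zero mean is
an explicit assumption, not an approximation: far from data the posterior
mean reverts to 0 and the variance to σ_f² + σ_n². For vegetation
descriptors whose off-season baseline is small relative to the seasonal
amplitude this is adequate; for series with a large standing offset
`fit_gpr(..., subtract_mean=True)` removes the sample mean before
conditioning and restores it at prediction, but the flag is off by
default because the method is defined without centering. The kernel
itself is noise-free; σ_n² enters exactly once, on the diagonal of the
training covariance K + σ_n² I. (Formulations that also fold a Kronecker-
delta noise term into the kernel would double-add it in the predictive
equations; we resolve that in the standard way.)

The predictive variance reported includes the observation-noise term
(c* = k(t*,t*) + σ_n²): it is the variance of a new *observation*, not of
the latent curve. This is the convention the uncertainty outputs follow.

## Hyperparameters, units, defaults

θ is carried on the log scale as (log 1/l, log σ_f, log σ_n) — positivity
for free, and the scale on which pooled values are reported and averaged.

| parameter | meaning | unit | default / prior box |
|---|---|---|---|
| l | smoothness length-scale | days | trained; log(1/l) ∈ [−6, −1] (l ≈ 2.7–400 d) |
| σ_f | signal sd | descriptor units | trained; log σ_f ∈ [−2.5, 1] |
| σ_n | noise sd | descriptor units | trained; log σ_n ∈ [−3.5, 0] |
| restarts | optimizer restarts | — | 5 |
| min_obs | min valid points per pixel | — | 4 (below: flagged, not fitted) |
| grid step | prediction grid | days | 10 |
| threshold_frac | SOS/EOS amplitude fraction | — | 0.20 |

The prior box brackets, with a wide margin, the magnitudes found for
multi-year agricultural LAI series (l of a few weeks, σ_f below ~2.7,
σ_n a tenth to a half); the packaged reference ThetaSet sits comfortably
inside it. Training is L-BFGS-B on the negative log marginal likelihood
with the analytic gradient (trace identity, chained to the log scale),
objective tolerance 1e-6, at most 200 iterations per restart; the restart
with the best converged likelihood wins. Time is float days since a
configurable epoch date, stored with every artifact.

## Numerical choices

- One lower Cholesky factorization of K + σ_n² I serves prediction,
  likelihood and gradient; no explicit inverse or determinant is formed
  (the gradient needs K⁻¹ explicitly and computes it from the factor).
- On factorization failure the diagonal jitter escalates from
  1e-10·trace/n by factors of 10 up to 1e-4·trace/n; the jitter actually
  used is recorded on the fit. Beyond that a conditioning error is raised.
- Negative predictive variances from rounding are clipped at zero and the
  clip magnitude logged.
- Averaging of pooled hyperparameters is the unweighted arithmetic mean of
  log-triples within each crop class; the global average runs over all
  trained pixels (pixel-weighted), so with unbalanced classes it is not
  the mean of the per-crop rows. Non-converged pixels are excluded, never
  imputed.
- Fast path: pixels are grouped by (θ rounded to 12 decimals, byte-exact
  valid-mask pattern); each group shares one factorization and one
  predictive variance vector, and per-pixel means are a matrix product.
  This is algebra reuse, not approximation — the naive route is kept as a
  test oracle and agrees to ~1e-14.
- Crossing search for SOS takes the *last* upward crossing before the
  peak, EOS the *first* downward crossing after it (conservative on noisy
  flanks); crossings are linearly interpolated between grid points.
  DOM is the grid argmax of the season's peak, not a refined extremum.
- Season-to-slot assignment uses the detection index by default, or the
  calendar year (365-day blocks from the epoch) containing DOM.

## Design decisions that were genuinely open

- **Blue vs green areas.** Only "area under the curve between SOS and EOS"
  is standard; the split adopted here follows the TIMESAT large/small
  integral convention — blue = integral of the curve above zero, green =
  integral above the season's base level. The lifted-triangle unit test
  pins the distinction exactly (lifting a curve by c moves blue by c·LOS
  and leaves green unchanged).
- **Base level** is per season (mean of the two flanking minima), matching
  the amplitude definition used for the 20% rule.
- **Parcels** come from a parcel-ID raster when available, else from
  4-connected components of same-class pixels.
- **Per-crop averaging** is over pixels (not over parcel means).
- **Evaluation pairing** is on the regular prediction grid by default
  (pairing at acquisition dates is available), and per-crop "mean RMSE" is
  the mean over pixels of per-pixel RMSEs, robust to class imbalance.
  MAD season matching is nearest-DOM within the same calendar year,
  dropped beyond 90 days.
- **Peak detection** has no canonical parameters in this setting; defaults
  are prominence ≥ 0.1 of the series' global range and a minimum season
  span of 30 days.

## Synthetic scenes: what they emulate, what they do not

`synthetic.generate_scene` produces a parcel mosaic (default 60×60 px,
10×10 parcels) of nine crop archetypes with double-logistic seasonal LAI
curves, small per-pixel perturbations of base/amplitude/timing, a ~5-day
jittered revisit over two years (~146 acquisitions), additive Gaussian
noise (sd 0.1 LAI) and spatially correlated cloud blobs removing ~25% of
observations. A 127-acquisition, 4-year uneven schedule generator covers
the longer-collection single-pixel setting. The double logistic is placed
so that its 20%-amplitude limb crossings equal the configured SOS/EOS in
closed form (inverting a single limb is exact; the opposite limb's tail
displaces the full-curve crossing by well under a tenth of a day at the
default rates and separations), which is what makes phenology testable
analytically.

What this does **not** emulate: retrieval error structure of real LAI
products (correlated, heteroscedastic, occasional outliers), sensor-mix
artifacts, snow/soil background effects, multi-modal within-parcel
heterogeneity, or genuinely missing seasons (fallow years). Passing the
synthetic studies therefore demonstrates the *algebraic and statistical
correctness* of the pipeline and the *internal* closeness of pooled-θ to
per-pixel-θ processing — it does not certify accuracy against field data.

## Study sizes

The validation studies are sized for a single CPU: GP-vs-oracle and
gradient checks use 100 random problems (n ≤ 50 and n ≤ 20); recovery uses
20 replicates of n = 300 drawn from the GP at pooled-magnitude θ; the
fast-path check uses a 20×20 scene with 30% cloud; the pooling and
phenology studies run on the default 60×60 scene with per-pixel training
restricted to pixels sampled from parcels (≤ 25 per class) — the same
stratified-sampling logic the method prescribes, since training every
scene pixel is exactly the cost the method exists to avoid.

## Known limitations

- Exact GP only: O(N³) in the number of valid acquisitions per distinct
  pattern; fine for N of a few hundred, no sparse approximations.
- Zero-mean prior pulls long gap interiors toward zero, biasing SOS/EOS
  slightly outward for curves with high baselines.
- Whole scenes are processed in memory; tiled/out-of-core processing is a
  deliberate non-goal at this scale.
- Only the squared-exponential kernel and the percent-of-amplitude
  SOS/EOS rule are implemented; alternative kernels and derivative-based
  phenology definitions are out of scope.
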