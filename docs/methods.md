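# Methods

## Design construction

A central composite design for k factors consists of the full two-level
factorial {−1, +1}ᵏ, two axial points per factor at coded ±α, and
replicated center points.  Coding is affine: x_coded = (x − center)/step,
with the decode transform its exact inverse; round-trips are exact to
floating-point precision.  The reference esterification design uses
k = 5, α = 1.75, 8 center replicates (50 points), with factor centers and
steps of (5, 2) enzyme w/w%, (16, 8) h, (60, 5) °C, (2, 1) molar-ratio
scalar and (400, 150) r.p.m.  Although the source study describes its
design as "fractional factorial", it counts 32 = 2⁵ factorial points, so
the full two-level enumeration is generated.  Point order is fixed
(factorial in binary-counter order, axial low-then-high by factor, then
centers) so emitted designs are byte-stable.

The packaged reference run table carries 48 of the 50 design runs — two
runs were never published — split 30 training / 18 test exactly as
published.  One run's molar ratio is printed "2:2", which is not an r:1
design level; it is stored verbatim (scalar 1.0) with an `anomaly` flag
and excluded from design-lattice invariants rather than silently
corrected.  The published per-run model predictions are carried in a
separate column used only to re-derive the published validation
statistics; they are never training targets.  An sha-256 checksum guards
the fixture against accidental edits.

## Network and training

The surrogate is a fully connected 5-h-1 perceptron, sigmoid in both the
hidden and output layers.  Inputs are min–max scaled to [−1, 1] over the
union of the records supplied to the scaler fit (for the reference data
this equals the ±α design range).  Targets are min–max scaled into
[out_lo, out_hi] of the sigmoid's (0, 1) range; consequently predictions
are always bounded by the inverse image of (0, 1), i.e. the model cannot
produce arbitrarily large extrapolations.

Quickprop is implemented per Fahlman's heuristic, batch mode, per weight:

* first step, or dead previous step: plain gradient descent −ε·S(t);
* otherwise the quadratic (secant) step S(t)/(S(t−1) − S(t)) · Δw(t−1),
  magnitude-capped at μ·|Δw(t−1)|;
* the gradient term −ε·S(t) is added whenever successive slopes share a
  sign (the minimum has not been crossed; this also revives weights whose
  step has decayed to zero while a slope persists);
* any non-finite or ascent-directed step falls back to the gradient step;
* an optional weight-decay term (decay · w added to each slope) bounds
  quickprop's geometric step growth.

Defaults: ε = 0.1, μ = 1.75, max 5000 epochs, decay 0.  The loss is mean
squared error on scaled targets; analytic gradients are verified against
central finite differences in the test suite.  Early stopping monitors
test-set RMSE each epoch, stops after `patience` = 50 epochs without
improvement, and restores the weights of the best test epoch.  This
mirrors the reference study's procedure; it is statistically leaky (the
"test" set steers training), so a held-out-free mode (empty test set, no
early stop) is also provided.  Weights initialize uniform on ±0.3 from a
seeded generator; identical seed, config and data give bit-identical loss
histories.

Hidden width is selected by grid search (default 1–15), training
`repeats` = 10 independently seeded networks per width and choosing the
width with minimum mean test RMSE, ties to the smaller network.  Each
(width, repeat) cell's seed derives deterministically from the base seed.

## Validation statistics

RMSE = √(Σ(y_p − y_a)²/n).  R² is the squared Pearson correlation of
predictions with actuals — this is the definition whose value matches the
published test-set statistic when recomputed from the published table
(the 1 − SSE/SST form does not), and it is invariant under affine
rescaling of either argument, so a biased but perfectly correlated fit
scores 1.  AAD = (100/n)·Σ|y_p − y_a|/y_a requires positive actuals and
is asymmetric in its arguments.  The single-run relative deviation used
for validation experiments is 100·|actual − predicted|/predicted.  The
published *training*-set triple does not recompute from the published
table (the printed training predictions evidently come from a different
network state than the printed statistics), so only the test-set triple
is used as a reference value.

## Surrogate maximization

The optimizer maximizes predicted conversion over a coded box — default
[−1, 1] per factor (the factorial region; the study's own optimum sits on
that boundary in time and molar ratio), optionally ±α.  Because the
surrogate is cheap, the search is a 5-point-per-axis lattice scan
followed by multi-start Nelder–Mead (scipy) from seeded interior starts
plus the lattice incumbent, keeping the best point found.  The reported
optimum is never below any lattice value, and the best objective is
non-decreasing in the number of restarts at a fixed seed stream.
Reported conditions are not rounded or snapped.

`find_optimum` accepts either one fitted network or a committee (a list);
for a committee the mean prediction is maximized.

## Committee surrogates

A single near-interpolating MLP is a poor object to *maximize*: between
design points it wiggles, and its wiggles place the argmax erratically.
Two numerical choices matter when the trained surface itself is the
deliverable:

* **Output headroom.**  With targets mapped to [0.1, 0.9], responses at
  the top of the observed range sit near sigmoid saturation and the model
  cannot rise meaningfully *above* the best observed run — yet a response
  maximum typically lies off the sampled design.  Committee training
  therefore maps targets to [0.25, 0.75] by default, leaving symmetric
  headroom.
* **Weight decay + averaging.**  Quickprop's capped-growth steps still
  inflate weights over long runs, sharpening the fit; a small decay
  (10⁻⁴) keeps members smooth, and averaging several independently
  initialized members (default use: 5) cancels the remaining
  init-dependent wiggle.

`fit_committee` packages these choices.  The single-network path keeps
the [0.1, 0.9] scaling and zero decay as defaults, matching the
conventional recipe.

## Synthetic ground truth

`SurfaceSpec` defines a quadratic response in coded units,
y(x) = b₀ + Σlᵢxᵢ + Σqᵢxᵢ² + Σc₍ᵢⱼ₎xᵢxⱼ, plus iid Gaussian replicate
noise, clipped to [0, 100] conversion%.  With all qᵢ < 0 and no
interactions the surface is strictly concave and its box-constrained
maximum has the closed form clip(−lᵢ/2qᵢ), which serves as the oracle for
end-to-end recovery tests.  The default coefficients — intercept 55,
linear (−1, 6, 2, −5, 1), curvature (−6, −2, −5, −2, −4) — place the
optimum interior in enzyme, temperature and agitation and on the
factorial boundary in time and molar ratio, the qualitative shape of the
reference study's optimum, with a box maximum of ≈ 62.3% at coded
(−0.083, 1, 0.2, −1, 0.125).  The default noise SD of 5 conversion% is
calibrated to the reference center-replicate scatter (sample SD 4.91 over
the seven replicates).  Simulated tables reuse the study's split
proportions deterministically: axial and center points always train
(they pin curvature and intercept), shuffled factorial points fill the
training set to round(0.625·n).

What the generator does *not* emulate: kinetic mechanisms (no time-course
structure), heteroscedastic or non-Gaussian measurement error,
factor-dependent noise, and any model mismatch beyond
quadratic-vs-network.  Passing recovery tests therefore demonstrates that
the pipeline's machinery is sound under its own assumptions, not that a
real reaction surface is quadratic.

End-to-end recovery is measured as (a) the distance of the proposed coded
condition from the true argmax and (b) the *true* surface value at the
proposed condition versus the true maximum — the regret of actually
operating there.  The surrogate's own predicted value at the optimum runs
systematically ~2–3% low because the design places no runs near the
optimum face; that bias appears for any smooth regressor trained on this
design and is a property of the design/surrogate combination, not of the
trainer.

## Problem sizes and determinism

Test-suite and acceptance computations use the study-scale problems: the
48-run table, the 50-point design, 10 seeded restarts for the 5-11-1
reference fit, committees of 5 networks at h = 8 over 10 seeds for the
synthetic recovery checks.  Every stochastic stage derives its seed
deterministically from one global seed via a named-stream hash, so
adding a stage never shifts another stage's stream and any reported run
is exactly repeatable.

## Known limitations

* Early stopping on the 18-run test set leaks information, as in the
  reference procedure; metrics on that set are optimistic.
* R² as squared correlation ignores calibration bias by construction.
* The quickprop constants the original study's software used are
  unknown; the defaults here are conventional values, and the selected
  hidden width for any one seed may differ from the study's 11.
* The optimizer treats the surrogate as truth; no uncertainty or
  desirability weighting (e.g. enzyme cost) is modelled.
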