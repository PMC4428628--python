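# Methods

`epiflim` re-implements, as a reusable and fully synthetic-testable
pipeline, the layer-resolved FLIM analysis of cervical epithelium: TCSPC
decay cubes are fitted per pixel to a bi-exponential decay, the epithelium
is divided into equal-thickness layers along the growth direction,
per-layer statistics of the diagnostic lifetime component feed an extreme
learning machine (ELM), and a cut-off-layer sweep locates the depth zone
that maximizes diagnostic accuracy.

## Decay model and per-pixel fitting

Fluorescence decay follows dI/dt = −I/τ with τ = 1/(K_r + K_nr); the
radiative and non-radiative rates are never separately identified — only τ
is estimated.  Each pixel's photon histogram is modelled as

    I(t) = a1 exp(−t/τ1) + a2 exp(−t/τ2)

convolved with a Gaussian instrument response function (IRF).  τ1
(~30 ps) is instrumental; τ2 (hundreds of ps, from eosin in the stained
section) carries the pathology contrast.  The convolution is evaluated
analytically per time bin through the scaled complementary error function;
no FFT is used, avoiding wrap-around artifacts on short windows.

Fitting is weighted nonlinear least squares by variable projection: the
search runs over (τ1, τ2) (bounds 5–200 ps and 200–5000 ps) while the
amplitudes are solved as a non-negative weighted linear subproblem at every
step.  Initialization: τ2 from a log-linear fit to the decay tail, τ1 at
30 ps; up to 3 deterministic restarts with jittered initial τ2.  Components
are ordered τ1 < τ2 after the fit; a coincident pair collapses to a single
exponential.

Three numerical choices matter for accuracy:

* **Weights.** The first pass uses counting (Neyman) weights 1/max(n, 1);
  a single model-based reweighting pass (1/max(model, 1), standard IRLS
  for Poisson data) follows.  Pure counting weights over-weight downward
  fluctuations in low-count tail bins and leave a systematic ~−4.5% τ2
  bias at 5000 photons/pixel; one reweighting pass removes it (residual
  bias ~0.1%, median error ~1.5%).
* **Fit channel range.** Most of the 10 ns window carries no signal
  (pre-pulse bins, dead tail).  The fit and the reduced chi-square are
  restricted to the contiguous range where a 5-bin moving average of the
  counts reaches max(1 count, 1% of peak); χ²_red uses dof = (channels in
  range) − 4.  Over the full window the statistic is diluted to ~0.6 and
  could never approach unity.
* **IRF.** The IRF center is first placed at the half-maximum crossing of
  the rising edge, with σ from the 10–90% rise time divided by 2.5631
  (the Gaussian-CDF rise).  Because that localizes the center only to
  about one time bin — a bias of half a bin visibly distorts every
  lifetime at coarse binning — the IRF is then refined once per image by a
  free-(center, σ) fit of the pooled (high-count) decay of all
  above-threshold pixels.  Per-pixel fits keep the IRF fixed, so each
  pixel still has 4 free parameters.

Pixels with fewer than 50 cumulative photons are never fitted and never
enter layer statistics.  Whole images are fitted either per pixel with
scipy (`method="exact"`) or with a vectorized variable-projection grid
search plus parabolic refinement (`method="fast"`, default), which is
equivalent to ~1% in τ2 and two orders of magnitude faster; the two paths
are cross-checked in the test suite.

## Layer geometry

The epithelium is bounded by two annotated polylines: basement membrane L
(adjoining the basal layer) and surface M.  Both are smoothed with a
5-point moving average (odd-reflection padding, so endpoints are
preserved).  Each ROI pixel's depth is the normalized fraction
d_L/(d_L + d_M) of its exact point-to-polyline distances — 0 on the
membrane, 1 on the surface — and layer k of K is
min(floor(depth·K) + 1, K): half-open bins, surface folded into the top
layer, boundary points assigned upward.  The fraction-based construction
cannot produce gaps or overlaps, unlike a literal normal-translation of
membrane pixels (available as `method="translate"` for comparison); for
parallel boundaries the two coincide.  Per-layer mean and population SD of
τ2 are computed over valid pixels only; empty layers propagate as missing
features.

## Classifier

The ELM is a single-hidden-layer network: input weights and biases drawn
uniform on [−1, 1] and never trained; logistic hidden nodes; output
weights β = pinv(H) T, the minimum-norm least-squares solution.  Features
are z-scored with training-half statistics.  Targets are one-hot over
{normal, precancerous} with CIN1–3 pooled as the positive class.
Accuracy is estimated by repeated random subsampling: 1000 unstratified
16/16 train/test splits; a split whose test half lacks a class is redrawn.
The split schedule depends only on the labels and the seed, so every
feature set (whole-ROI, 3-layer, each sweep cut-off) is evaluated on
identical splits and differences isolate the features.  The hidden-node
count is tuned per feature set over {5, 10, 15, 20, 30, 40, 50} by mean CV
balanced accuracy (ties to the smaller network), mirroring the practice of
adjusting L for maximum discrimination accuracy; L = 20 is the default
when tuning is disabled.

## Synthetic tissue generator

The generator is the study-design stand-in for the (non-public) clinical
sections: 10 normal / 8 CIN1 / 6 CIN2 / 8 CIN3 samples, 256×256 px at
1.8 μm/px, 10 ns window in 256 bins (~39 ps), epithelium thickness
260 ± 60 μm, boundary waviness sinusoidal (amplitude 15 μm), ~5000
photons/pixel, IRF σ 40 ps centered 1 ns into the window, background
10 photons/pixel outside the ROI (safely below the 50-photon threshold).
Reduced configurations scale the pixel pitch with the image so the band
keeps its relative thickness.

**Depth profiles.**  Normal τ2 rises linearly 700 → 1000 ps from basal to
superficial layer (maturation gradient; whole-ROI mean 850 ps, inside the
observed 670–1000 ps normal range).  The normal-minus-CIN3 contrast is
anchored at ~147 ps (layer 6) rising to ~245 ps (layer 10) with small
(≤40 ps) consistent shortening in the lower half, leaving the CIN3 top
half nearly flat (maturation arrest).  CIN1/CIN2 scale this contrast with
grade weights: 1/3 and 2/3 in the lower half (the classical
depth-of-involvement definition) but near-full at layer 6 decaying toward
the surface in the top half (CIN1 [1.0, 0.50, 0.33, 0.22, 0.15] for
layers 6–10; CIN2 [1.0, 0.78, 0.62, 0.52, 0.45]): lower-grade lesions
shorten the lifetime most strongly near mid-epithelium while retaining
partial superficial maturation.  This grade-by-depth structure makes the
top-half layers complementary — layer 6 carries information about CIN1/2
that layers 8–10 do not — which is what gives the cut-off sweep a genuine
interior optimum.

**Between-sample variability.**  Layer means are multiplied by (i) two
independent zone factors — one for the basal half, one for the superficial
half, lognormal with 14% relative SD each — and (ii) independent per-layer
deviates (18% basal, 5% superficial).  Per-layer totals are ~15% in the
top half and ~23% in the basal half, a layer-averaged between-sample RSD
of ~19%, matching the reported 15–20% averages; the basal half is the
noisier zone (sectioning angle, inflammation, stromal proximity).  Two
properties of this structure are load-bearing.  A single *global* section
factor would let a classifier use basal layers as a clean reference and
accuracy would rise monotonically as layers are added — the opposite of
the observed collapse below cut-off 6; independent zone factors make the
basal half carry no information about top-half noise.  And the zone factor
keeps the whole-ROI mean noisy (RSD ~10%, consistent with the wide
670–1000 ps normal range), which is why whole-epithelium analysis
underperforms layer analysis.  Setting `sample_rsd` replaces the structure
with i.i.d. per-layer deviates (used by several tests); `sample_rsd = 0`
gives the exact profiles.

**Within-layer pixel jitter** is Gaussian with a per-class SD equal to
sqrt(180² − between-layer variance of the class profile) (152–178 ps), and
a per-sample lognormal scale deviate (RSD 0.2).  The expected whole-ROI σ
is therefore ~180 ps for *every* class: σ overlaps the observed bands
(normal ~150–200 ps, CIN ~170–280 ps) but carries no pathology signal,
encoding the reported finding that σ features are diagnostically
redundant.

**Decay cubes.**  Every ROI pixel's expected histogram is the
IRF-convolved two-component model (instrumental fraction
amp_ratio/(1+amp_ratio) = 0.2), normalized to the photon budget and
Poisson-sampled.  Everything is a pure function of (config, seed); each
sample consumes an independent child RNG stream.

What the generator does **not** emulate: nuclear/cellular morphology, H&E
color, detector afterpulsing or dead-time, spatially correlated texture
within a layer, annotation error in the boundary polylines, and any
grade-specific photon-budget differences.  Passing tests therefore
demonstrate the correctness and statistical behaviour of the *pipeline*
under the calibrated model, not clinical performance.

## Experiments and reporting conventions

Three analysis models are compared on identical split schedules:
whole-ROI (features μ, σ; length 2), three-layer (per-layer μ, σ optional;
the μ+σ vector has 6 components), and the ten-layer cut-off sweep
(features μ10 … μc, lengths 1–10).  Balanced accuracy is
(sensitivity + specificity)/2.

The sweep argmax of a single 32-sample pool is a deterministic function of
the drawn pool but varies between pool draws — with 10 normals per pool
this sampling noise is irreducible.  The package therefore reports the
*structural* optimum: sweep curves are averaged over replicate pools
(independent child seeds of one master seed) and the argmax of the mean
curve is reported, together with the per-pool sweeps.  The reproduction
script uses 24 replicate pools at 64 px / 64 time bins with 1000 splits
per feature set (~10–13 minutes on one CPU); the test suite uses 10 pools
at 48 px with 400 splits.  At these desk scales the absolute balanced
accuracies (~60–70%) are lower than clinical-data values — fewer photons
per layer and a deliberately conservative noise calibration — but the
structural findings (optimum at cut-off 6; ten-layer above whole-ROI and
three-layer) are the reproduced quantities.

## Known limitations

* The calibration reproduces the published *structure*; absolute
  sensitivities/specificities at desk scale are not comparable to the
  clinical values.
* χ²_red bands in tests are sampling-theory based (median in [0.85, 1.2],
  ≥90% within [0.7, 1.4] at ~85 effective channels); tighter bands are not
  statistically attainable with Poisson weighting at 5000 photons.
* The literal normal-translation layer construction is approximate where
  boundaries converge; the fraction-based construction is the default.
* K_r and K_nr are not identifiable; the package never reports them.
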