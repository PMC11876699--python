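# Methods

This note documents the models behind each pipeline, the defaults and why
they were chosen, what the synthetic generator does and does not emulate,
and the numerical decisions that were genuinely open.

## Dynamic-instability model

Each stabilized seed nucleates growth at both ends. Per end, growth events
alternate with pauses: an event starts, elongates at constant speed, and
ends in a catastrophe after a gamma-distributed lifetime; the extension
then collapses back to the seed (instantaneously by default — the analyses
use only growth segments, so modelling the shrinkage phase adds nothing;
a finite `shrink_speed_um_min` is supported for rendering realism) and the
end pauses for `regrow_delay_s` (default 10 s) before renucleating. The
delay is our choice: some refractory time is needed for consecutive events
to be resolvable at 2 s/frame, and published kymographs show clear pauses
at the seed between events.

Defaults are the buffer-control study conditions: plus end 1.002 µm/min,
minus end 0.348 µm/min; the `elongator()` preset carries the
reconstituted-complex speeds (1.380 / 0.472 µm/min). Event-to-event speeds
are drawn with a coefficient of variation of 0.16 (clipped at 10% of the
mean), matching the dispersion implied by the published standard errors
(SEM ≈ 0.009 µm/min at n = 335 events). The lifetime law is gamma with
shape k = 3 — the catastrophe literature fits gamma laws with k ≈ 3,
consistent with catastrophe as a multi-step ageing process, and the
published fits never state a shape — and scale set so the distribution's
median equals the control lifetime estimate of 202.61 s. All recovery
targets depend only on the median, not on the shape choice.

## Imaging model

Kymographs and fields of view are rendered with pixel size 0.107 µm/px,
frame interval 2 s, and a Gaussian PSF of σ = 1.3 px — plausible for a
100× / 1.45 NA TIRF objective on an sCMOS camera — plus a constant
background (100 counts) and additive Gaussian noise (σ = 6 counts; a
Poisson model is available). Kymographs use pixel-integrated occupancy
convolved with a 1-D Gaussian; fields of view use the exact closed-form
image of a uniform line segment under a 2-D Gaussian (amplitude ×
perpendicular Gaussian × erf end-cap factor), so pixel sums and linescan
expectations are analytic rather than discretization-dependent.

What the generator does *not* emulate: photobleaching, uneven
illumination, microtubule curvature and crossings (fields of view place
microtubules on a jittered grid with ±3° orientations, emulating a
flow-aligned field, specifically so that linescans and their background
edges are uncontaminated), comet-like tip markers, and rescue events.
Passing recovery tests therefore demonstrate correctness of the
measurement chain under the stated model, not robustness to curved,
crossing, or bleaching real data.

## Kymograph analysis

Tip localization uses the farthest half-maximum crossing of the smoothed
(σ = 1 px) profile beyond the seed, linearly interpolated to subpixel. The
half level is set between the per-side edge background and a *global*
plateau estimated from the whole channel (median of pixels in the upper
half of the intensity range): the polymer's linear density is uniform, so
one plateau serves every frame, including frames whose extension is too
short to display a plateau of its own. A constant intensity offset or
gain rescaling leaves all measurements unchanged.

Within ~3 px of the seed edge the tip response merges with the seed edge
response and the half-maximum estimate is biased; such frames are flagged
low-quality. Two consequences were handled explicitly:

* **Speed fits.** Selecting fit frames by their *measured* position
  truncates the noise asymmetrically near the quality cut and biases
  slopes low for short events. The estimator therefore fits twice: a
  first pass on good frames, then a reselection of frames by their
  *predicted* position from the pass-1 line (independent of each frame's
  own noise), and a refit. This removes the truncation bias (residual
  < 0.3% at default noise). Events with fewer than 3 usable frames are
  dropped with a logged warning and counted.
* **Onsets.** A threshold crossing dates the onset late by
  (threshold / speed), ~5 s at plus-end and ~14 s at minus-end speeds, so
  the onset is refined by extrapolating the fitted line back to the seed
  edge (clamped to a window scaled by the fitted speed). Catastrophe
  times remain frame-quantized (the lifetime ends at the last frame
  before the drop), costing ~1 s on average.

Catastrophes are detected as a single-frame regression exceeding 3 px or
a return below the seed edge; events still growing at the final frame are
censored. A sustained half-threshold extension in the last frames is
accepted as a censored event so late nucleations are not silently lost.
Censored events are excluded from lifetime statistics — a deliberate,
visible bias: the censored count is always reported. Because censoring
preferentially removes long lifetimes, extracted-lifetime distributions
are compared to the generating gamma law on long movies (3600 s), where
the exclusion bias is small; at 600 s movie lengths the bias reaches
several percent of the mean, as it does for any analysis that discards
censored events.

Polarity: the side of a seed with the larger mean fitted speed is the
plus end; ties break toward the side with more events, then
lexicographically, and are flagged ambiguous; single-sided seeds are
labelled unknown rather than guessed.

Whole-event ordinary least squares is used for speeds (no sub-segment
fitting); the RMS fit residual is stored per event so irregular events can
be audited.

## Lifetime statistic

The chain is: empirical CDF → gamma MLE → median of the fitted gamma
("lifetime at half cumulative distribution", t₅₀) → bootstrap error. The
MLE solves log k − ψ(k) = log x̄ − mean(log x) by Newton iteration from the
standard closed-form starting value (relative tolerance 1e-12, shape
clipped to [1e-3, 1e8]); θ̂ = x̄/k̂. t₅₀ = θ̂ · P⁻¹(k̂, ½) via the inverse
regularized incomplete gamma function. The bootstrap draws B = 10,000
resamples with replacement at the original n, refits each, and reports the
75th − 25th percentile of the bootstrapped t₅₀ values (percentiles by
linear interpolation, the type-7 convention — stated because IQR
conventions differ). The Newton solver is vectorized across resamples, so
the full bootstrap takes seconds. Resamples that fail to fit (degenerate
or non-converged) are skipped and counted; more than 1% failures is a
hard error. No censoring-aware likelihood is implemented (known
limitation); whether lifetimes are pooled across experiments before
fitting is the caller's choice and is visible in the recorded n.

## Binding

The 1:1 equilibrium uses the numerically stable quadratic root
2RL/(S + √(S² − 4RL)), S = R + L + K_d, which avoids cancellation when
4RL ≪ S². K_d fitting parameterizes log K_d (respecting positivity across
the nanomolar-to-micromolar span) with plateau signals s_free, s_bound as
free parameters, initialized from the endpoint responses and the
half-maximal-response concentration. A fit is flagged invalid — never
silently returned — if the optimizer fails, the plateaus coincide, or the
fitted K_d lies outside the titrated concentration range (an extrapolation,
not a measurement). Standard errors come from the Jacobian at the optimum
(delta method for K_d itself).

One binding site is assumed for the occupancy prediction: although the
microtubule-binding subcomplex has two potential partner sites, one copy
is preferentially bound; the solver takes explicit totals, so a 2:1 model
can be expressed by doubling the receptor total if desired. No Hill
coefficient is fitted.

Simulated titrations default to the assay design: constant labelled
species at 50 nM, two-fold dilutions (24 or 16 points), additive Gaussian
noise of 5% of the dynamic range. Top concentrations are chosen to
bracket each transition (2 µM for the nanomolar subcomplex affinities,
1 µM for tRNA-scale, 200 µM for the weak tubulin affinity): an
over-saturated series leaves few points in the transition and biases the
median recovered K_d upward by several percent at 5% noise, a design
artifact, not a fitter defect (the bias vanishes as noise → 0, which the
tests check).

## PTM linescans

Linescans sample a polyline at 0.5-px arclength steps, averaging `width`
(default 2) samples at perpendicular offsets j − (width−1)/2 px. Sampling
uses cubic-spline interpolation: bilinear interpolation underestimates a
σ = 1.3 px Gaussian ridge by up to ~7% at cell centers, which would break
per-microtubule recovery. Background is the mean of the outermost
`edge_len` (default 5) samples at both ends of the trace, which must
extend past the microtubule into empty background (the generator pads
traces by 10 px). A trace whose edges are clearly brighter than its
on-structure span — value below −4 standard errors, with the noise scale
taken from the quieter edge so a contaminated edge cannot mask itself —
is excluded and enumerated with its reason; counts always reconcile.

For synthetic data the on-structure span is derived from the known trace
padding, shrunk by 6 samples (~3 px ≳ 2σ) per side to stay clear of the
PSF roll-off at the ends; for real traces a half-maximum extent with the
same margin is available.

The FOV statistic is 100 × (FOV mean of per-microtubule
background-subtracted antibody means) / (FOV mean seed value), with the
seed channel measured by the *same* width-2 linescan machinery on the
seed segments — this makes the normalization exactly unit-free and
cancels the PSF factor when calibrating synthetic ground truth. The ×100
factor is a reporting convention placing typical values on a 1–100 scale
(≈ 12–24 at seed means ≈ 175 counts); all condition comparisons are
ratios, so the constant is neutral. Conditions average FOV means, never
pooled microtubules, so the FOV remains the statistical unit. Per-seed
total signal uses a user-supplied signal-free region for background; no
default region is guessed.

Precision note: at assay-level antibody signals (~20–40 counts over a
100-count background with σ = 6 noise), the per-microtubule error budget
is dominated by the 10-sample edge background (≈ 5–10% per microtubule);
FOV averages over ~70 microtubules reach ~1%. The 3%-per-microtubule
recovery contract holds for bright stains (~100 counts) with generous
edges, and the tests state those conditions.

## Registration

Pairwise shifts between successive frames come from the FFT
cross-correlation of mean-subtracted, Hann-tapered frames (light σ = 1 px
pre-smoothing; detection noise otherwise random-walks into the cumulative
track). Subpixel refinement is quadratic interpolation of the peak and
its neighbours, computed on the correlation of the *integer-aligned* pair:
refining after alignment keeps the peak symmetric under the taper, so
integer drifts are recovered exactly and subpixel drifts to better than
0.1 px/frame. The cumulative track is referenced to frame 0 (the
reference-frame convention is explicit in `DriftTrack`); correction
translates every channel by the negated cumulative shift with bilinear
interpolation, filling uncovered edges with the frame median. No
rotation or scale registration is attempted.

## Problem sizes

The validation experiments use: 150 seeds × 600 s movies per growth-speed
condition (≥ 400 plus-end events), 80 seeds for the minus end, n = 300
lifetimes with B = 10,000 bootstrap resamples, 100 replicate titrations
per affinity, and 9 fields of view × 70 microtubules per PTM condition —
sizes comparable to the published experiments (n = 115–627) and
comfortable on a single CPU.
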