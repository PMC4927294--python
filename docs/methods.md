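# Methods

This note documents the models, estimators and numerical choices behind
`rotaspike`, the parameters that matter, and what the synthetic-data tests do
and do not establish about real recordings.

## The preparation being modelled

A head-fixed animal sits on a platform that is rotated manually, clockwise
and counterclockwise, with occasional rest periods. A single LED on the
platform, in line with the animal's sagittal plane, is video-tracked at
25 Hz (40 ms frames). Because the head cannot move relative to the platform,
the LED's polar angle around the rotation centre *is* the head direction up
to a fixed offset, and no 2-D spatial analysis is possible — the pipeline
deliberately has no place-field or grid machinery.

## Kinematics

1. **Smoothing.** LED x/y are smoothed with a centred 600 ms rectangular
   (boxcar) window; at the session edges the window truncates to the
   available frames so every series stays on the frame grid. Truncation
   compresses the angle within ~0.3 s of the edges, biasing edge velocities
   low (about 0.5% on the session mean for a 60 s constant rotation); we
   accept this rather than discard edge frames.
2. **Head angle.** The rotation centre is estimated by the algebraic
   least-squares (Kåsa) circle fit — closed-form, deterministic, and
   accurate to ≪ 2% of the radius at realistic tracking noise. The head
   angle is `atan2` around that centre, mapped to [0, 2π); a continuous
   (unwrapped) copy is kept for differentiation. The rewrap identity
   `theta == mod(theta_unwrapped, 2π)` holds to 1e-9 (floating-point
   accumulation prevents bit-exactness).
3. **Velocity and acceleration.** ω is the forward finite difference of the
   unwrapped angle over the frame interval, with the last value repeated to
   preserve length; α is the same difference of ω. Using the unwrapped angle
   removes 2π-crossing artifacts by construction.
4. **Movement mask.** Linear LED speed is the frame-to-frame displacement of
   the smoothed coordinates over dt; frames with speed > 1 cm/s are
   "movement", the rest are "rest". Every downstream spike analysis (HD,
   theta, speed) uses movement-period spikes only. Masking happens after
   smoothing; the order is fixed and recorded in the report config.
5. **Inversions.** Successive frame-to-frame angle differences are mapped
   into (−π, π] (raw magnitudes above π are wraparound artifacts of the
   circular representation, not physical jumps — at 25 Hz a real > π/frame
   step would mean > 78 rad/s); differences smaller than ε = 1e-4 rad are
   rest chatter and do not toggle the sign state; an inversion is a sign
   change between consecutive retained differences.

## Head-direction tuning

The tuning curve uses 36 bins of 10°. Each spike inherits the angle of its
containing frame; occupancy is the summed frame time per bin over movement
frames. The analysis requires every bin visited at least once — violations
raise an error listing the offending bins, which the session pipeline
converts to an explicit reason code rather than a silent NaN.

The **HD index** is the mean resultant length of the rate-weighted bin-centre
unit vectors, `R = |Σ rᵢ e^{jθᵢ}| / Σ rᵢ` — the binned-curve (not
spike-wise) form: 0 for a flat curve, 1 for a single-bin curve, exactly 0.5
for `1 + cos(θ − θ₀)` on the symmetric grid. The preferred direction is the
argument of the same vector sum; the peak-rate bin is kept separately for
display ordering only.

**Significance** comes from rigid circular time-shifts: each of 1000
permutations shifts the entire spike sequence by one uniform offset drawn
from [20 s, T − 20 s] (the minimum shift breaks spike-trajectory coupling;
the value is configurable, the analysis is insensitive to it on sessions of
a few minutes) and recomputes the index against the unshifted kinematics.
The p-value is `(1 + #{null ≥ observed}) / (1 + n_perm)`, never exactly
zero; a cell is an HD cell when the observed index exceeds the null's 95th
percentile (the one-sided-fraction and percentile-rank readings coincide at
this criterion), and a strong HD cell when additionally index > 0.8 and
p < 0.01. Tuning curves are not smoothed before the index or the stability
correlation; peak rate is the raw bin maximum.

**Stability** is the linear Pearson correlation between the 36-bin rate
vectors of the two half-sessions; it requires full bin coverage in both
halves and nonzero variance, otherwise an absent value with a reason code.

## Theta rhythmicity

The autocorrelogram histograms all pairwise spike-time differences within
±0.5 s into 10 ms bins with edges at multiples of the bin width (a 25 ms
pair lands in the 20–30 ms bin), mirrored for negative lags; symmetry
`counts[::-1] == counts` is exact. The 0.5 s maximum lag (1 s window) is the
smallest giving 1 Hz native spectral resolution, which is what makes
"average power within 1 Hz of the peak" well defined.

The autocorrelogram mean is subtracted before the discrete Fourier
transform — otherwise the DC lobe dominates the 1–50 Hz denominator at its
low edge; this is the main source of cross-implementation variation in theta
indices and is therefore called out here. The spectrum is zero-padded
fourfold (0.25 Hz grid) for peak localisation; padding does not materially
change the 1 Hz averaging windows. The **theta index** is the mean power
over [peak − 1, peak + 1] Hz divided by the mean power over 1–50 Hz, with
the peak searched in 4–12 Hz. It is invariant to rescaling the counts and to
time-reversal of the train.

The **shuffle** shifts every spike independently by a uniform offset with
session wraparound — count preserved, ISI structure destroyed, no minimum
offset — and recomputes the index; significance at the 95th percentile.
Cells with ≤ 20 spikes are excluded (reason code), and a descriptive
"weak rhythmicity" flag (theta index < 5) is exposed in reports.

## Speed modulation

The instantaneous rate is the spike count per 40 ms frame divided by the
frame duration, unsmoothed (optional smoothing exists but is off by
default). The **speed score** is the Pearson correlation between that rate
and |ω| over movement frames; the signed-ω correlation is reported as a
secondary column because platform rotation is bidirectional. No extreme-
speed filtering is applied. The null is the same rigid whole-train shift as
for HD; degenerate permutations with zero rate variance score 0
(conservative). Rest and rotation rates are counts over time within each
side of the movement mask.

## Spike features

Feature conventions: baseline = mean of the leading 25% of the snippet;
peak-to-trough = time from the positive maximum to the subsequent minimum;
half-width = width of the positive peak at half its baseline-referenced
amplitude, with linear interpolation at the crossings; negativity =
trough depth / peak amplitude. Peak-to-trough and half-width are distinct
width measures and are both reported. The **bursting index** counts spikes
whose *preceding* ISI is < 6 ms over all spikes (the either-adjacent
convention would double-count pairs; the convention is configurable). The
**FS criterion** is peak-to-trough < 0.4 ms AND movement-period rate > 5 Hz;
the thresholds are configuration values with these documented defaults, and
every classification records the thresholds used.

## Group statistics

Mann-Whitney U (two-sided) for continuous statistics and Fisher's exact test
for proportions, via scipy.stats; the Mann-Whitney implementation enumerates
exactly when both groups have ≤ 8 observations and the pooled sample is
tie-free, otherwise uses the tie-corrected normal approximation. An
all-identical pooled sample returns p = 1. No multiple-comparison correction
is applied, and the reports say so. Bootstrap CIs on medians are not
computed by default.

## Synthetic sessions

The generator's defaults are the study conditions the analyses assume:
25 Hz frames, 10 cm LED radius (only used to convert angular to linear speed
at the 1 cm/s cutoff), target angular speed 1.1 rad/s with 1.3 rad/s²
ramps, seven inversions per session, and 20% of the session at rest,
inserted as whole blocks so the movement mask is unambiguous. Within
rotation segments the cruise speed fluctuates smoothly (multiplicative
jitter, CV 0.2, ~0.5 s correlation time, sign-preserving) because manual
rotation is not servo-constant; without it the angular-speed series would be
nearly degenerate and speed correlations meaningless. The schedule is
validated: too many inversions for the requested duration at the target
speed raise an explicit error.

Spike trains come from an inhomogeneous Poisson process, thinned against the
maximum of the intensity over the frame grid:

    λ(t) = r₀ · e^{κ cos(θ(t) − μ)} / I₀(κ)
              · (1 + d cos(2π f t))
              · max(0, 1 + g |ω(t)| / r₀)

with base rate r₀, von Mises concentration κ and preferred direction μ,
theta depth d ∈ [0, 1] and frequency f ∈ [4, 12] Hz, and signed speed gain
g (Hz per rad/s), floored so the intensity is never negative. The I₀
normalisation keeps the mean rate near r₀ under a uniform direction sweep.
An absolute refractory period (default 2 ms) is enforced by deleting spikes
too close to the previously kept one. Waveforms are piecewise-linear
biphasic templates (closed-form feature values: half-width = half the peak
base width; defaults 0.8 ms peak-to-trough for principal cells, 0.25 ms for
fast-spiking) plus optional Gaussian noise.

**What the generator does not emulate:** real tuning curves are not von
Mises (HD cells have sharper-than-von-Mises peaks), rate remapping and
adaptation are absent, theta modulation is stationary, tracking noise is
white rather than structured, and spike sorting errors do not exist here.
Passing tests therefore establish that the estimators recover the parameters
of this generative family and that the permutation nulls are calibrated
under it — not that any particular biological claim holds.

## Problem sizes and randomness

Simulation studies (test suite and acceptance script) use 200 permutations
per shuffle test — the package's documented simulation-study default; the
production default is 1000 — on sessions of 120–600 s, with 100–200
simulated cells per calibration. Null calibration is checked against the
binomial 95% interval around the nominal 5%; detection/recovery checks use
the thresholds stated in their tests (e.g. preferred direction within 10°
in ≥ 95 of 100 runs). Every stochastic component takes an explicit seed;
session fits spawn per-cell substreams from one master seed, so reports are
byte-identical across replays of the same inputs, config and seed.

## Known limitations

* The HD shuffle preserves the ISI multiset but not any spike-trajectory
  coupling subtler than a rigid shift; slow nonstationarities (drift in
  excitability) can inflate false positives in real data, as with any
  time-shift null.
* The circle fit assumes a single fixed rotation centre; a drifting platform
  centre would bias the angle.
* Occupancy-based binning assigns each spike its frame's angle; at 25 Hz and
  ~1 rad/s this quantises direction to ~2.5° within a frame, negligible
  against the 10° bins.
* The theta index depends on the DC-handling convention (mean subtraction
  here); absolute values are comparable only between implementations using
  the same convention, while the within-package shuffle test is unaffected.
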