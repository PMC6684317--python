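# Methods

This note documents the models and numerical choices behind
`thetagamma`: what each stage computes, which parameters matter, what
the synthetic generator does and does not emulate, and the estimator
biases a user should know about.

## Cycle segmentation and phase conventions

Theta phase is the angle of the analytic signal of the zero-phase
(forward–backward 4th-order Butterworth) 5–10 Hz band-passed LFP.
Zero-phase filtering matters: any systematic filter delay would rotate
every gamma field, and the early-fast/late-fast distinction rests
entirely on phase. **Phase 0 is the theta peak** of the
pyramidal-layer LFP; cycles run peak to peak. This convention makes
medium gamma sit near phase 0 and the two fast-gamma states fall on
either side of the trough (±π). All phases are radians in (−π, π];
timestamps are seconds from recording start; positions are cm. Input
LFP is polyphase-resampled to 625 Hz before analysis.

Cycles are spans between successive upward zero crossings of the
wrapped phase, retained when (a) the duration lies in [100, 200] ms —
the per-cycle expression of the 5–10 Hz band — and (b) the unwrapped
phase is non-decreasing within the cycle. Boundary samples are shared
between neighbors. Note that band-passed noise largely *passes* the
duration gate (its instantaneous frequency rarely leaves the filter
band), so the gate is a per-cycle sanity check, not an artifact
detector.

## The FPP feature

The continuous wavelet transform uses a **complex analytic Morlet with
ω₀ = 5** (pywt `cmor2.0-0.7958`), frequencies 20–180 Hz in 2 Hz steps;
power is |W|². The real-valued Morlet of the same center frequency
would give squared output oscillating at 2f; the complex form yields
the envelope power directly, and the ±8 ms smoothing that would mask
the difference is applied anyway (boxcar, ±2 Hz × ±8 ms = 3 × 11 bins
at this grid). Each frequency row is then z-scored across the analyzed
epoch (zero-variance rows map to zero). Z-scoring scope is **per
behavioral epoch per channel**, so wake and REM analyses never share a
normalization. Within a cycle, samples are assigned to 20 equal-width
phase bins by instantaneous phase; a cycle at 625 Hz holds ~60–120
samples, so empty bins are rare and are filled by circular linear
interpolation along phase.

Two properties of the z-scored feature deserve emphasis:

- **Amplitude invariance.** Rescaling the raw trace leaves the FPP
  unchanged (tested), which is what lets cluster templates transfer
  across channels.
- **Peak relocation.** The z-transform divides each row by its
  temporal SD, so a single cycle's argmax slides along the burst's
  spectral tail toward rows with less background variance; with a 1/f
  background that bias is upward (~+10 Hz at 36 Hz). Cluster *means*
  largely cancel this, and the gravity features below are computed on
  means, but single-cycle FPP maxima should not be read as burst
  frequencies.

## Clustering and gamma fields

The affinity graph is B = C + 1 (C = Pearson correlations of flattened
FPPs), which keeps edge weights nonnegative. Louvain community
detection (igraph's multilevel implementation; resolution 1, i.e.
plain Q-modularity; self-loops removed — the diagonal of B only adds a
partition-independent offset) runs on a subsample of at most 2000
cycles with 10 seeded restarts; k is the modal count of communities
holding ≥ 1 % of nodes. k-means then assigns every cycle using
correlation distance: vectors are standardized to zero mean and unit
norm, making the objective spherical k-means, with k-means++ seeding,
10 replicates, tolerance 1e−6 on the objective, ≤ 300 iterations;
empty clusters are re-seeded at the point farthest from all centroids;
zero-variance vectors (correlation undefined) fall back to nearest
centroid in Euclidean distance.

A cluster's gamma field is the set of mean-FPP bins ≥ 95 % of the
peak, restricted to the phase-circularly connected component
containing the peak (clusters occasionally show a second, disconnected
field; gravity over the peak's component keeps the feature unimodal —
the full mask is retained for inspection). Gravity frequency is the
power-weighted mean of masked-bin frequencies, gravity phase the
power-weighted circular mean of phase centers, phase SD the
power-weighted circular SD. Labels: the two lowest gravity frequencies
are S and M; of the two fast fields, EF is the one whose gravity phase
follows the trough (π) by the smaller offset.

## Known estimator biases (measured on the generator's defaults)

With the default synthetic conditions (below), recovered gravity
features carry small systematic biases that users should expect on any
data with similar structure:

- S-gamma gravity frequency: ≈ +3 Hz (spectral-tail asymmetry of the
  constant-Q wavelet interacting with z-scoring).
- S-gamma gravity phase: ≈ +0.35 rad. Bursts preferring phases near
  the cycle boundary are truncated by per-cycle segmentation; the
  retained within-cycle mass is phase-asymmetric. M (planted at
  −0.04 rad, i.e. at the boundary itself) shows a similar-magnitude
  phase wobble.
- EF/LF gravity frequencies: the two fast states are planted 4.1 Hz
  apart at ~130 Hz, where the ω₀ = 5 Morlet's frequency SD is ~26 Hz.
  Their frequencies are not separable at that resolution (LF, the
  upper one, reads ≈ +10 Hz high); they are distinguished by *phase*,
  which is recovered to ~0.1 rad. This is why the labeling rule splits
  the fast pair by phase.

## State dynamics

Occurrence is the per-state fraction of cycles. Transition counts use
consecutive cycle pairs only; pairs separated by a gap (a rejected
cycle or an epoch boundary) are excluded by default, since a "chain"
across an unobserved cycle is not a transition. Rows with no observed
pairs are NaN, never fabricated uniform rows. Occurrence time courses
are 4 s bins from each epoch onset (horizon 120 s), averaged across
epochs, with never-covered bins NaN.

## Pairwise phase consistency

Both PPC estimators are the unbiased pairwise construction: the mean
cosine of phase differences over all distinct pairs, computed via the
|Σe^{iφ}|² identity (O(N) instead of O(N²); equality with the double
loop is asserted to 1e−10 in tests). Spike–field PPC treats each
trial's spikes as one mean resultant vector, so trial count — not
spike count — sets the effective sample size; units must fire in ≥ 10
trials with rate > 5 Hz (interneurons) or > 2 Hz (pyramidal cells),
and exclusions are explicit records. Trials are maze traversals when
position is available, else fixed 2 s windows. The spectrum uses 33
contiguous 6 Hz bands tiling 2–200 Hz. LFP–LFP PPC bins the Morlet
cross-spectrum's angle into the FPP grid per cycle and measures
lag consistency across cycles; per-state profiles average the map over
a circular phase window from (gravity phase − 7·phase SD) to (gravity
phase + 1·phase SD) — asymmetric toward earlier phases because
upstream drive precedes local power. A constant *time* lag between
channels yields PPC ≈ 1 only while lag × bandwidth ≪ 1; at 180 Hz and
625 Hz sampling that means a 1-sample lag, which the tests use.

## Place-cell analyses

Positions are Lowess-smoothed over 21-sample windows (0.525 s at the
40 Hz tracking rate); speed is the derivative of the smoothed track;
samples and spikes below 5 cm/s are excluded. Rate maps divide 5-bin
boxcar-smoothed spike counts by equally smoothed occupancy (5 cm
bins); the boxcar is truncated and renormalized at the track ends,
which conserves mass exactly for interior support. Spatial information
is Σ pᵢ (λᵢ/λ) log₂(λᵢ/λ) bits/spike on that map; an adaptive
(occupancy-dependent) smoothing radius is not implemented — the 5-bin
boxcar map is used for the shuffle test as well, with the smoothing
constant left configurable through the map parameters. The shuffle
test circularly shifts spike times by U(20 s, T − 20 s) 100 times; a
place cell needs SI above the 95th shuffle percentile *and* peak rate
> 2 Hz. Place fields are runs of ≥ 3 contiguous bins above 20 % of
peak. Phase precession: the slope â (cycles per field traversal)
maximizes the mean resultant length of φ − 2πax over a dense grid
(step 0.01 on [−2, 2], refined 10×; ties break toward 0); r is the
circular–linear correlation against 2π|â|x (so precession gives
negative r) with the large-sample normal test. Per-state precession
requires significant pooled precession, ≥ 100 spikes in the field and
≥ 10 per state; the spike-count control deletes down to the minimum
state count 100 times and averages slope and r. TG-state *events*
(cycle midpoints of one state) run through the same map machinery to
give bits/event.

## The synthetic generator

The generator produces the statistical structure the method assumes,
not a biophysical simulation. Defaults define the study conditions:

| parameter | default | why |
|---|---|---|
| fs / duration | 625 Hz / 600 s | analysis rate; ~4–5 × 10³ cycles |
| theta | amp 1.0, frequency random-walking in 6–10 Hz (step SD 0.002 Hz/sample, reflected) | theta dominance with realistic cycle-length jitter |
| state presets | S 36.07 Hz @ 0.58; M 99.12 @ −0.04; EF 127.72 @ −2.57; LF 131.83 @ 2.12; amp 0.5 | the four reference states |
| per-cycle jitter | 2 Hz, 0.2 rad | cycle-to-cycle burst variability |
| burst envelope | Gaussian in theta phase, SD π/3 | ~1.8 gamma cycles at 36 Hz — a realistic slow-gamma burst length; much narrower envelopes make the burst's own bandwidth (≥ 10 Hz) dominate frequency recovery |
| background gamma | Poisson 4 bursts/cycle, amp 0.35, frequency uniform 20–200 Hz, phase uniform | gives every frequency row its own background variance — see below |
| noise | 1/f (exponent 1), amp 0.15 | pink instrumental/biological floor |
| Markov chain | uniform 0.25 | no planted sequential structure unless configured |
| place cells | 8 cells, Gaussian fields (SD 12 cm) on a 200 cm track, peak 8 Hz, precession −2π rad/field | standard linear-track coding |
| interneurons | 4 cells, 12 Hz, von Mises-locked (κ = 4) to the burst carrier within the envelope | gamma-locked spiking |

The background-gamma term is essential, not cosmetic: with *only*
stationary pink noise, every frequency row driven by the same burst
has an identical z-scored time course (z-scoring is scale-invariant),
so the feature degenerates into a plateau along frequency and gravity
frequencies become arbitrary within the burst's spectral support. Real
LFP does not behave this way because each band carries its own ongoing
activity; the uniform background bursts reproduce that property with
one mechanism. One burst per cycle and one label per cycle mirror the
single-state-per-cycle model of the classifier.

What the generator does **not** emulate: multi-shank depth geometry
and CSD structure, ripples and NREM events, spike waveforms or sorting
artifacts, non-stationary behavior (state-dependent theta amplitude,
running-speed modulation of gamma), and 2-D open-field coding.
Passing recovery tests therefore demonstrates the pipeline's
correctness under the assumed structure — not robustness to everything
real recordings contain.

Determinism: a single `numpy` Generator seeded from `config.seed`
drives everything; identical configs give bit-identical sessions.
Position is a back-and-forth linear-track run with a trapezoidal speed
profile (plateau 20 cm/s, 0.5–2 s turn pauses) sampled at 40 Hz.

## Problem sizes

Default test and acceptance runs use one 600 s session (~4.1–4.8 × 10³
cycles) for pipeline recovery, 2000-cycle subsamples for community
detection, 10⁴ draws for Monte-Carlo chance/Markov checks, and 120 s
sessions for unit-level recovery — sizes at which every stochastic
tolerance in the test suite is several standard errors wide.
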