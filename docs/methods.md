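# Methods

This note documents the models, estimators and numerical choices behind
`camapper`, and what the synthetic-data tests do and do not establish about
real recordings.

## Signal model and conventions

A recording is a pair of fluorescence movies, one per channel (Vm, Ca_i),
indexed `(frame, row, col)` with pixel (0, 0) top-left and frame *k* at
exactly `k × frame_interval_ms` (default 4 ms; default grid 128 × 128 at
0.35 mm pitch).  Time windows are half-open `[t0, t1)` in ms.  Readers never
modify raw values; polarity ("down" for most voltage dyes) is declared in the
acquisition metadata and resolved during preprocessing, after which both
channels point up and each pixel is min–max normalized to [0, 1].
Normalization is idempotent and invariant to per-pixel affine maps of the
raw counts, which makes every downstream ratio metric dye- and
gain-independent.

## Preprocessing

- **Tissue mask**: a pixel is analyzed iff its raw dynamic range exceeds
  `amplitude_threshold` (default 0.2) times the 95th percentile of all pixel
  ranges; zero-range (dead) pixels are always excluded rather than raising.
- **Smoothing**: separable boxcar, spatial radius 1 px then temporal width 3
  frames by default — the mildest denoising that stabilizes
  derivative-based landmarks at the generator's default noise.  Boundaries
  use reflection, which for a uniform kernel conserves each frame's mean
  exactly; that conservation property holds exactly for the full-frame
  filter, while with a partial tissue mask the kernel is renormalized over
  included pixels (no bleed-in from outside the tissue) at the cost of exact
  mean conservation near the mask edge.
- **Drift removal**: baseline = smoothed morphological opening (rolling
  minimum then maximum) over a window that must span at least two pacing
  cycles; the opening follows slow trends exactly (a ramp is its own
  opening) while deleting beats, and the first/last half-window — where the
  morphological neighborhood is truncated — is replaced by the linear trend
  of the adjacent interior.

## Action potential analysis

Beats are threshold crossings (default 0.5 of normalized amplitude) with
hysteresis: after a beat the detector re-arms only once Vm has returned
below 0.1, so an EAD that pokes back above threshold mid-repolarization is
not split into a spurious beat.  A beat is "captured" if its upstroke
follows a stimulus within 50 ms.

Activation is the maximum-upstroke-slope instant, refined sub-frame by a
quadratic through the discrete first-difference maximum and its neighbors.
Its attainable precision is set by how many samples the upstroke spans:
with a 4 ms frame interval, upstrokes lasting ≳5 ms localize to ~±0.1 ms,
while the generator's 2 ms-τ upstroke localizes to ~±0.3 ms — well inside
the one-frame tolerance used for map recovery.

APD at level L (default 0.8) interpolates the first crossing of
`peak − L × amplitude` after the peak, guarded by a 2-frame stay-below rule
against noise blips.  Beats that never repolarize before their window ends
are flagged unrepolarized and masked out of maps rather than extrapolated —
inventing durations for non-repolarizing tissue would bias exactly the
long-APD regions of interest.  Isochrone maps subtract the earliest
activation over the mask, so their minimum is 0 by construction.

EAD detection scans the repolarization limb (from the AP peak until
normalized Vm falls below the takeoff band floor) for local minima where the
3-sample-smoothed first difference turns from negative to nonnegative while
Vm lies inside the takeoff band (default (0.1, 0.9)); an event is emitted if
the subsequent rise reaches ≥ 5% of AP amplitude (default) before the next
descent.  These two thresholds are package choices — the source literature
defines EADs qualitatively — and are configurable.

## Calcium analysis

Transients are paired with the co-registered pixel's Vm beats: onset at the
first 10%-amplitude upcrossing after Vm activation, peak before the next
beat, end at the earlier of the next onset and the return below 10%.

The **secondary rise** is detected on the decay limb as the first point
where the smoothed slope recovers to ≥ −`slope_tolerance` (default 0: the
decay stalls or reverses), skipping the rounded top of the transient where
the slope is naturally ~0.  The onset anchor is the local minimum around the
stall and the offset is the interpolated return to the onset value (or the
transient end): anchoring at the flat local minimum and interpolating the
offset makes the chord endpoints second-order accurate in the frame
interval, which is what keeps the 4 ms-sampled amplitude within ~0.4
percentage points of the dense-grid oracle.  The amplitude is the largest
deviation of the trace above the onset–offset chord, as % of the transient's
peak amplitude — the denominator is a package choice (the metric's source
defines the numerator only); normalizing by the same transient's amplitude
makes the percent dimensionless and scale-invariant.

**Decay τ** is a bounded nonlinear least-squares fit of
`A·exp(−(t − t_start)/τ) + C` from the peak to 90% recovery.  Two numerical
guards: the fit starts once the trace leaves the rounded top (below 95% of
amplitude, capped at 12 ms past the peak), because the pre-exponential
shoulder otherwise biases τ upward by ~8%; and the window landmarks are read
off a 3-sample-smoothed copy so single noise samples cannot truncate the
window (the fit itself uses raw values).  Fits with τ exceeding 10× the
window length are flagged unconverged.  Whether to include the offset C is
genuinely open in the literature; it is included here because real diastolic
fluorescence does not decay to zero.

**Rise latency** interpolates each channel's crossing of 10% of its local
amplitude inside a window; negative latency (Ca before Vm) is the Ca_i
pre-fluorescence signature of an EAD initiation site.

## Pseudo-ECG and TdP

The optical pseudo-ECG is the difference of mean normalized Vm over the two
halves of the mask (vertical split by default) — a scale-free surrogate that
converts propagation-direction changes into waveform changes.  Beats are
peaks of the rectified smoothed *slope* of the pseudo-ECG: depolarization
deflections are sharp while the repolarization wave of the same beat moves
the trace equally far but much more slowly, so slope-based detection keeps
repolarization from being double-counted as a beat.  A run is VT when ≥ 2 consecutive
cycle lengths fall below 0.75 × the intrinsic (escape) cycle length;
polymorphism is a minimum successive-beat waveform correlation < 0.8 after
peak alignment; TdP = polymorphic VT of **more than 3 beats** (read
strictly: ≥ 4).  The 0.75 and 0.8 criteria are package choices with no
counterpart in the source definition, chosen so that the generator can
construct unambiguous episodes on both sides of each boundary.  Episodes
starting within 2 s of a stimulus are labelled pacing-induced; both
induction modes count toward inducibility.

## Statistics

Mean ± SEM (sample SD/√n), two-sided paired t (all-zero differences return
t = 0, p = 1; a nonzero constant difference is undefined), one-way
repeated-measures ANOVA via the standard condition/subject/error
sum-of-squares partition with unadjusted LSD pairwise t-tests on the error
df (LSD means unadjusted; no sphericity correction is applied), and
Cochran's Q with p from χ²(k−1).  When every subject row is constant the Q
statistic is a 0/0 limit; the null value (Q = 0, p = 1) is returned with an
`undefined` flag.  At k = 2 the implementations collapse correctly:
F = t² and Q = McNemar without continuity correction, both asserted in the
test suite against independent oracles (closed forms and statsmodels).

## Synthetic data: what it emulates, and what it does not

Templates are analytic so every landmark is controllable:

- **AP**: `V(t) = σ((t − t_act)/τ_up) · σ((t_rep − t)/τ_rep)` with τ_up = 2 ms
  and τ_rep = 15 ms, `t_rep` solved by root finding so the continuous 80%
  crossing sits exactly at the requested APD₈₀.  EAD-carrying traces default
  to τ_rep = 60 ms — a slow, plateau-like repolarization — because EADs
  physiologically arise when repolarization is slow, and only then can a
  modest depolarizing bump actually reverse the downstroke.
- **Ca**: sigmoid rise (shoulder 24 ms after onset) times a one-sided
  exponential with the requested τ; the decay limb is exactly exponential.
- **Calibrated bumps**: a Gaussian bump riding on an exponential decay has a
  chord-deviation amplitude *smaller* than its height (the decay keeps
  falling between onset and offset), so the generator solves for the height
  whose measured chord deviation equals the nominal percentage.  When even
  the nominal-height bump cannot stall the decay (e.g. 1.2% on a 205 ms τ,
  or 1.0% on 63 ms), the bump is left at nominal height and its truth
  amplitude is 0 — such rises are genuinely below the slope-stall detection
  floor, matching the near-zero group means of the corresponding conditions.
  EAD bumps are calibrated the same way so the *observable* net rise equals
  the requested amplitude fraction.
- **Movies**: focal activation from an apex pacing site at 0.5 mm/ms, linear
  base-to-apex APD gradient, Ca delayed 10 ms behind Vm, bumps confined to
  the basal third, Vm stored with "down" polarity and both channels scaled
  to camera-like counts, Gaussian noise (default SD 0.02 of amplitude) and
  linear drift applied last.  Everything is a pure function of
  (scenario, seed).
- **Presets**: the four condition presets pin APD/rise/τ means to the
  published group scales (179/298/457/307 ms; 1.0/8.8/1.2/0.4%;
  63/100/205/126 ms at a 1000 ms cycle length) purely as realistic operating
  points.  Recovery tests estimate the preset parameters; nothing in the
  suite claims to reproduce animal data.

Ground truth comes from oracles that share no code with the analysis path:
root finding on the continuous templates for APDs and takeoffs, a dense-grid
(0.1 ms) chord-deviation scan, and a log-linear regression for τ.

Not emulated: motion artifacts (the experimental preparations suppress
contraction pharmacologically), ionic mechanisms (no I_Ca,L/NCX/SR model —
bumps are phenomenological), spatially discordant alternans, fractionated
electrograms, camera vignetting, and photobleaching beyond linear drift.
Passing recovery tests therefore demonstrates estimator correctness under
the stated signal model, not robustness to every pathology of real optics.

## Problem sizes and defaults

Map-recovery checks run on 64 × 64 grids with 3 beats at a 1000 ms cycle
length (~630 frames); smaller grids (12–32 px) are used where the property
under test is resolution-independent.  The Monte-Carlo τ study uses 100
trials at noise SD 0.02.  These sizes make the whole suite and the
acceptance script run in seconds on a laptop while leaving every tolerance
comfortably met; all thresholds above are exposed through `AnalysisConfig`
with the defaults stated here.

## Known limitations

- Activation sub-frame precision degrades for upstrokes much faster than the
  frame interval (see above); conduction-velocity vector fields are out of
  scope.
- The secondary-rise detector reports at most one rise per transient (the
  first stall); multiple distinct re-rises within one decay are merged into
  the first event's chord window.
- `fit_decay_tau` assumes a monoexponential decay; transients carrying a
  large secondary rise violate that model and their fitted τ absorbs the
  bump (the fit is still reported, with its RMSE).
- The TdP classifier requires a measurable intrinsic cycle length; fully
  disorganized traces with no pre-episode segment need it supplied.
- Inducibility tabulation accepts one recording per heart–condition pair;
  merging repeated provocations is the caller's responsibility.
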