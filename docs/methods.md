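# Methods

`ohcsync` models and analyses spontaneous Ca²⁺ activity of immature outer
hair cells (OHCs) in the pre-hearing mouse cochlea and its synchronization
by intercellular Ca²⁺ waves spreading through the greater epithelial ridge
(GER). Because no raw imaging data are available for this preparation, the
package pairs every analysis stage with a generative model of the same
statistical structure, so that each stage is validated by parameter
recovery rather than by reference outputs.

## The generative model

A recording is `n_frames` frames (default 4,000) at `frame_rate_hz`
(default 30.3 fps) over a square field (125 µm cell mode, 182 µm wave
mode; 512 px default rasterization). OHCs sit in up to three rows spaced
`row_spacing_um` = 8 µm along the radial axis and `cell_spacing_um` = 8 µm
along the tonotopic (x) axis; the GER band occupies y ∈ [70, 150] µm.

**Firing.** Each cell is an inhomogeneous point process. In burst mode
(default) burst initiations are Poisson with mean interval 20 s, burst
length ~ Exp(1 s) and within-burst spiking at 5 Hz; these burst parameters
are free choices representing the qualitative bursting of immature OHC
action potentials and are exposed in `SimulationConfig`. In non-burst mode
the cell is a plain Poisson process at `baseline_rate_hz`; this mode exists
because its expected counts are exactly integrable and anchor the
rate-recovery tests.

**Indicator kernel.** Each spike adds a transient
`kernel_amp · exp(−(t−t_s)/τ)` with τ = `kernel_tau_s` = 0.3 s, the
fluorescence decay constant of the Ca²⁺ indicator in these cells. Rendered
traces are

    F(t) = F₀ · e^(−t/τ_bleach) · (1 + Σ transients) + F₀ · σ_noise · ε(t),

with photobleaching τ_bleach = 600 s and additive white noise
σ_noise = 0.03 ΔF/F₀ by default — a noise floor at which a single
0.6-amplitude transient stands ~11σ above the smoothed noise, comparable
to a clearly visible transient in two-photon data.

**Waves.** A wave has onset time, longitudinal extension L, centre,
amplitude (ΔF/F₀, default 1) and duration (default 5 s — waves visibly
span seconds). Its time course m(t) is a half-Gaussian rise peaking at
onset + duration/5 followed by an exponential fall (constant duration/3).
Spontaneous schedules are Poisson at `wave_rate_per_min` (wild type 2.09,
connexin-30-null preset 1.3), extents uniform on [20, 180] µm, onsets ≥5 s
into the recording so a wave-free baseline prefix always exists, centres
uniform with the footprint kept inside the field.

**Coupling.** Waves raise OHC firing rates multiplicatively:

    rate(t) = base(t) · [1 + G · g(L) · e^(−d/λ) · m(t)],

with gain G = 20, spatial decay λ = 50 µm, d the Euclidean distance from
the cell to the wave footprint rectangle, and g(L) = min(L/182 µm, 1) a
monotone link between extension and coupling strength (only monotonicity
is constrained by the biology; the linear-saturating form is the simplest
choice). Coupling multiplies the firing intensity rather than adding
fluorescence because the OHC Ca²⁺ rise during waves is depolarization- and
AP-driven. Modulating by m(t) (not a boxcar) makes all responding cells
follow the shared wave envelope, which is what produces rank-correlated
windows; G = 20 is calibrated once so that >150 µm waves essentially always
synchronize nearby OHCs while <75 µm waves mostly do not, the qualitative
regime reported for this preparation. The `antagonist_uncoupled` preset
(PPADS/A317491-like) sets coupling off while leaving waves intact; the
`cx30_null` preset only reduces the wave rate.

**Determinism.** One master seed; per-cell and per-purpose substreams are
derived with `SeedSequence((seed, stream, cell_id))`, so identical
(config, seed) gives bit-identical output and growing `n_cells` never
reshuffles existing cells.

**What the generator does not emulate.** Real movies have shot noise,
focal drift, inhomogeneous staining, three-dimensional tissue curvature,
wave shapes far from elliptical, and OHC transients with finite rise
times. Passing tests therefore demonstrate that the analysis recovers the
modelled structure — not that it is robust to every artefact of real
two-photon data.

## Trace extraction

Movies are registered to the first frame by integer-pixel FFT
cross-correlation with the peak search bounded (±20 px), a deliberate
simplification of rigid-body registration: cochlear drift in this
preparation is dominantly translational. Recordings whose |shift| exceeds
`max_drift_px` (default 8 px ≈ 2 µm) are flagged for discard. ROI traces
are unweighted pixel means over 3.7 µm squares centred on each OHC (side
rounded half-up to pixels, clipped at frame edges). ΔF/F₀ uses F₀ = mean
of the first `f0_n_frames` frames (default 10; 1 reproduces the literal
"onset of the recording" reading, 10 is noise-robust).

## The activity classifier

Six steps per trace: (i) centred moving average of length 3 with shrunken
edge windows; (ii) subtraction of a degree-5 polynomial in frame index
(slow Ca²⁺ drift and bleaching) and normalization to the maximum;
(iii) noise floor from Welch's PSD (256-frame Hann segments, 50% overlap)
averaged above 66% of Nyquist, converted to an SD; (iv) spike inference by
nonnegative AR(1) deconvolution plus an event-mass sparsity rule, giving a
per-frame normalized spike count sᵢ and cumulative count S = Σsᵢ;
(v) active iff S exceeds a threshold, with a 4-SD consistency flag;
(vi) flagged cells are kept or dropped by a config switch rather than by
manual review.

Numerical details worth recording:

- **Noise-floor scale.** The length-3 smoothing suppresses exactly the
  high band the Welch estimator reads, so the floor is estimated on the
  *unsmoothed* detrended trace and rescaled by √(1/3) (the filter's noise
  gain) when it refers to the smoothed trace that spike inference
  consumes. The 4-SD review rule divides the smoothed trace's maximum by
  the *unsmoothed* floor; on that scale a pure-noise trace peaks near
  2 SD and a 5σ spike near 4.5 SD, which is what makes 4 a sensible
  split line.
- **Deconvolution.** With γ = exp(−1/(τ·rate)), the innovations
  uₜ = cₜ − γc₍ₜ₋₁₎ invert the sampled kernel exactly; they are clipped at
  zero. Frames with uₜ > 1.5·noise_sd seed candidate events (the centred
  smoothing splits one spike's innovation into three ~equal consecutive
  chunks, all clearing this gate at the amplitudes of interest); an event
  is kept only if its total mass reaches λ·noise_sd with λ = 5.
  Per-frame-only thresholding was measured to fail its operating targets
  (noise exceedances dominate S at small λ; the three-way mass split
  defeats large λ), so the event-mass rule is the package's operating
  point: measured false-active 1.4% and 5σ/3-spike detection 98.8% over
  500 seeded traces each. A unit-amplitude transient from baseline
  contributes S = 1 — the "normalized spike count" convention — and S is
  unbiased for the spike count even when nearby transients merge into one
  discrete event.
- **S threshold.** No principled absolute value exists, so the default is
  calibrated per run as the 99th percentile of S over 500 pure-noise
  simulations of the same geometry (the procedure is scale-free). It is
  exposed in config for users who want a fixed threshold.
- **Event rate.** `spike_frequency` divides the number of discrete events
  by the recording duration, always computed as n_frames/frame_rate.

## Wave detection

Detection operates on ΔF/F₀ movies (per-pixel F₀ from the first 10
frames). Per-pixel baseline mean/SD come from a wave-free prefix (default
100 frames). Candidate voxels exceed k·SD (k = 5, reusing the 5×SD onset
rule — the only threshold stated for this preparation) after per-frame
Gaussian smoothing (σ = 1 px); events are connected components
(8-connected in space, 1-frame adjacency in time) inside the GER band with
peak footprint ≥ 100 µm². A wave entering from outside the field first
appears as a sliver hugging a border, so events whose first-footprint
centroid lies within 3 px of an edge are excluded; events whose *maximal*
footprint touches the longitudinal edges are kept but flagged
extension-censored. Extension is the bounding-box width of the footprint
at the frame of maximal area (bounding box rather than convex hull, a
documented convention). The event's peak frame is the maximum of its
mask-averaged trace within the event's span. Onset timing for delay
measurements uses the first crossing of baseline mean + 5×SD.

## Synchronization statistics

All correlation analysis uses 400-frame (13.2 s at 30.3 fps) half-open
windows: a wave window centred on the wave's peak frame (waves whose
window leaves the recording are excluded) and the earliest 400-frame
window free of any wave span as background (deterministic tie-break).
Traces are conditioned (smoothed + polynomial-detrended) before ranking,
and a per-trace least-squares line is additionally removed *inside each
window*: without this, the global polynomial's leakage around large shared
bumps measurably inflates background correlations in wave-rich recordings.
Pairwise Spearman coefficients (average-rank ties; pairs with an in-window
constant trace excluded and counted) are Fisher-averaged,
rsavg = tanh(⟨arctanh r⟩), with |r| clipped at 1−10⁻⁷. The wave-vs-
background increase is tested per wave with a one-sided Mann–Whitney U
over the defined pairwise coefficients at P < 0.001; these coefficients
share cells and are not independent, a property replicated as printed and
noted here rather than corrected.

Trace integrals use a Savitzky–Golay filter (window 11, order 1 — an
11-point moving average) and are reported in ΔF/F₀·s; the multi-recording
studies integrate the *detrended* traces so the bleaching trend cannot
bias a late wave window against an early background window. Per-cell
fractional increases (Iwave − Ibg)/|Ibg| feed the distance-binned summary
(bins 0–50–100–150–∞ µm, distance = cell centre to nearest footprint
point); the per-wave summary used for the small (<75 µm) vs large
(>150 µm) class comparison is the mean *absolute* increase across cells,
because a quiet cell's near-zero background integral makes its ratio
unstable. Class membership uses strict inequalities; the comparison is a
Welch t-test. rsavg is regressed on extension by OLS; the slope p-value is
the regression f-test.

## Study designs and problem sizes

The pooled analyses use ~2-minute recordings (3,636 frames) of 60 OHCs,
the field scale of the wave-mode acquisitions. Slope-recovery studies pool
per-wave rows from 100 seeded recordings per preset (acceptance suite; the
narrative scripts use 80). Wave-rate comparisons render only the GER band
(70×128 px strip covering y ∈ [60, 160] µm) for 30 recordings per genotype
preset and compare detected events/min with a one-sided rank test.
Wave-recovery checks inject one wave of known extent into 400-frame strip
movies over 100 seeds and require exact count recovery and extension
within ±2 px. These sizes were chosen as the smallest at which the
qualitative contrasts are decisively powered.

## Known limitations

- The S threshold and the normalized-count unit cannot be matched to any
  published absolute value; only operating characteristics are meaningful.
- Spike inference is deterministic deconvolution, not posterior sampling:
  adequate for the binary activity call and mass-based rates, but it does
  not quantify spike-time uncertainty.
- The Mann–Whitney treats pairwise coefficients as independent samples
  (see above).
- Whether distances in the distance-binned summary should be radial,
  longitudinal or Euclidean is not constrained; Euclidean is used.
- Registration is translation-only; rotating preparations are out of
  scope and would be flagged by drift rejection at best.
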