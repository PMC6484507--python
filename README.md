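# ohcsync

Analysis pipeline for spontaneous Ca²⁺ activity of immature outer hair
cells (OHCs) and its synchronization by intercellular Ca²⁺ waves in the
developing cochlea — with a ground-truth-annotated simulator standing in
for the (undeposited) raw two-photon movies.

Before hearing onset, OHCs fire bursts of action potentials that show up
as fast Ca²⁺ transients, and the non-sensory cells of the greater
epithelial ridge (GER) generate spontaneous ATP/connexin-dependent Ca²⁺
waves that transiently depolarize nearby OHCs. This package implements the
quantitative chain that turns time-lapse fluorescence into those claims:

- **ΔF/F₀ extraction** — translation registration, drift rejection, pixel
  averaging over 3.7 µm square ROIs, F₀ from the recording onset;
- **activity classification** — smoothing (moving average, length 3),
  degree-5 polynomial detrending, Welch noise floor (>66% of Nyquist),
  nonnegative AR(1) spike deconvolution, a cumulative-spike-count
  threshold and a 4-SD review flag;
- **wave detection** — 5σ thresholding + spatiotemporal connected
  components in the GER band, longitudinal extension *L* (bounding-box
  width), censoring flags for field-edge truncation, 5×SD onset timing and
  radial propagation delays;
- **synchronization statistics** — pairwise Spearman rₛ over 400-frame
  (13.2 s) windows centred on each wave peak vs a wave-free background
  window, Fisher-z averaging

      z = arctanh(rₛ),   rs_avg = tanh(⟨z⟩),

  a one-sided Mann–Whitney test of the increase (P < 0.001), trace
  integrals (Savitzky–Golay 11/1) binned by distance to the wave, and the
  OLS regression of rs_avg on *L* with its f-test;
- **a generative model** — burst-firing OHCs convolved with a τ ≈ 300 ms
  indicator kernel, photobleaching, additive noise, and scheduled
  elliptical GER waves that multiply OHC firing rates by
  1 + G·g(L)·e^(−d/λ)·m(t). Presets mirror the experimental conditions:
  wild type (2.09 waves/min, coupled), purinergic antagonist (coupling
  off), Cx30 knockout (1.3 waves/min).

Everything is deterministic under a seed, and every stage is tested by
recovering the parameters it was generated with.

## Worked example

Run the numbered analyses (each is a thin driver over the library and
writes its tables under `results/`):

```sh
python analysis/01_simulate_recording.py
python analysis/02_classify_activity.py
python analysis/03_detect_waves.py
python analysis/04_synchronization.py
```

Script 04 pools per-wave statistics from 80 simulated two-minute
recordings of 60 OHCs per preset and prints:

```
coupled (wild-type-like): 354 waves
  slope = (0.64 +/- 0.05) x 10^-3 um^-1, f-test P = 3.9e-29, Pearson r = 0.55
  fraction of waves with significant OHC sync increase (P < 0.001, one-sided Mann-Whitney):
       < 75 um: 0.24 (n=113)
     75-150 um: 0.55 (n=176)
      > 150 um: 0.86 (n=65)
uncoupled (purinergic-antagonist-like): 354 waves
  slope = (-0.00 +/- 0.01) x 10^-3 um^-1, f-test P = 0.94, Pearson r = -0.00
OHC integral increase, small (< 75 um) vs large (> 150 um) waves:
  0.30 vs 0.62 dF/F0*s  (Welch t-test P = 4.3e-06)
```

Read: when waves couple to OHC firing, the Fisher-averaged pairwise
Spearman correlation of OHC activity grows with the wave's longitudinal
extension (positive, strongly significant slope; large waves almost always
synchronize, small ones rarely), and large waves drive bigger increases in
the OHC Ca²⁺ trace integral. With coupling blocked — the antagonist
condition — waves of any size leave OHC correlations flat. Script 03 shows
the reduced-connexin preset is distinguishable by detected wave rate alone
(~1.95 vs ~1.35 events/min, one-sided rank test P ≈ 0.01).

The same pipeline is scriptable end-to-end via the CLI:

```sh
ohcsync all --seed 1 --out run/        # simulate -> classify -> waves -> sync
ohcsync classify --traces traces.csv --out run/
```

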