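#!/usr/bin/env python
"""Detect GER Ca2+ waves in rendered movies: wild type vs Cx30 knockout.

Renders the GER band of 20 wild-type (2.09 waves/min scheduled) and 20
Cx30-null (1.3 waves/min) two-minute recordings, segments wave events by
5-sigma thresholding + spatiotemporal connected components, and compares
the detected rates with a one-sided rank test. Writes a per-recording rate
table and one example wave catalog.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from ohcsync.config import SimulationConfig, cx30_null
from ohcsync.extraction import movie_dff
from ohcsync.io import write_wave_catalog_json
from ohcsync.simulate import render_movie, sample_wave_schedule
from ohcsync.studies import run_wave_rate_study
from ohcsync.waves import detect_waves

ROOT = Path(__file__).resolve().parents[1] / "results"
SEED = 42
N_REC = 20


def main() -> None:
    ROOT.mkdir(parents=True, exist_ok=True)
    wt = SimulationConfig(n_cells=1, n_frames=3636)
    ko = cx30_null(n_cells=1, n_frames=3636)
    res = run_wave_rate_study(wt, ko, n_recordings=N_REC, seed=SEED)

    table = pd.DataFrame({
        "genotype": ["wt"] * N_REC + ["cx30_null"] * N_REC,
        "events_per_min": res["rates_a"] + res["rates_b"],
    })
    table.to_csv(ROOT / "wave_rates.csv", index=False)

    print(f"detected wave rate, wild type : {res['mean_a']:.2f} events/min "
          f"(scheduled 2.09)")
    print(f"detected wave rate, Cx30-null : {res['mean_b']:.2f} events/min "
          f"(scheduled 1.3)")
    print(f"one-sided Mann-Whitney (wt > ko): P = {res['p']:.4f}")

    # one example catalog with extensions and censoring flags
    cfg = wt.with_(seed=SEED)
    rng = np.random.default_rng(np.random.SeedSequence((SEED, 0)))
    waves = sample_wave_schedule(cfg, rng)
    movie = render_movie(None, None, waves, cfg, shape_px=(70, 128),
                         y_range_um=(60.0, 160.0), pixel_noise_sd=0.1)
    catalog = detect_waves(movie_dff(movie))
    write_wave_catalog_json(catalog, ROOT / "wave_catalog_example.json")
    print(f"example recording: {len(waves)} scheduled, "
          f"{len(catalog.events)} detected")
    for ev in catalog.events:
        print(f"  onset frame {ev.onset_frame:5d}  "
              f"L = {ev.extension_um:6.1f} um  censored={ev.extension_censored}")
    print(f"written to {ROOT / 'wave_rates.csv'}")


if __name__ == "__main__":
    main()
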