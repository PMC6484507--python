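#!/usr/bin/env python
"""Simulate one wild-type wave-mode recording and write it to disk.

Produces, under results/recording_wt/: the raw trace CSV (60 OHCs x 3,636
frames at 30.3 fps, ~2 min), the cell map JSON and the ground-truth spike
times / wave schedule JSON. This is the dataset the later scripts analyse.
"""

from pathlib import Path

from ohcsync.config import SimulationConfig
from ohcsync.io import write_cell_map_json, write_json, write_traces_csv
from ohcsync.simulate import simulate_recording

OUT = Path(__file__).resolve().parents[1] / "results" / "recording_wt"
SEED = 42


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SimulationConfig(n_cells=60, n_frames=3636, seed=SEED)
    traces, cell_map, gt = simulate_recording(cfg)

    write_traces_csv(traces, OUT / "traces_raw.csv")
    write_cell_map_json(cell_map, OUT / "cell_map.json")
    write_json(
        {"config": cfg.with_(wave_schedule=tuple(gt.wave_events_true)).to_dict(),
         "spike_times_s": [s.tolist() for s in gt.spike_times],
         "wave_schedule": [w.__dict__ for w in gt.wave_events_true]},
        OUT / "ground_truth.json")

    n_spikes = sum(len(s) for s in gt.spike_times)
    print(f"simulated {cfg.n_cells} OHCs x {cfg.n_frames} frames "
          f"({cfg.duration_s:.1f} s at {cfg.frame_rate_hz} fps)")
    print(f"  {n_spikes} spikes total "
          f"({n_spikes / cfg.n_cells / cfg.duration_s:.3f} Hz per cell)")
    print(f"  {len(gt.wave_events_true)} GER waves scheduled:")
    for w in gt.wave_events_true:
        print(f"    onset {w.onset_s:6.1f} s  extension {w.extent_um:6.1f} um"
              f"  centre {w.center_um:6.1f} um")
    print(f"written to {OUT}")


if __name__ == "__main__":
    main()
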