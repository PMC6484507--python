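"""Configuration objects for the synthetic recordings and pipeline runs.

The simulation parameters encode the acquisition conditions of the study this
package models: 4,000-frame recordings at 30.3 frames/s, a 125 um (cell mode)
or 182 um (wave mode) square field, outer hair cells (OHCs) firing bursts of
action potentials read out through a calcium indicator with a ~300 ms
mono-exponential decay, and intercellular Ca2+ waves in the greater
epithelial ridge (GER) that transiently raise OHC firing rates with
distance- and extension-dependent coupling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Optional, Sequence

import yaml


@dataclass(frozen=True)
class WaveSpec:
    """One scheduled GER Ca2+ wave.

    Parameters
    ----------
    onset_s : float
        Time of wave onset from the start of the recording.
    extent_um : float
        Longitudinal (tonotopic) extension of the wave footprint.
    center_um : float
        Longitudinal position of the footprint centre.
    amplitude : float
        Peak dF/F0 of the wave field.
    duration_s : float
        Nominal duration; the time course is a half-Gaussian rise to the
        peak followed by an exponential fall (see ``simulate.wave_time_course``).
    """

    onset_s: float
    extent_um: float
    center_um: float
    amplitude: float = 1.0
    duration_s: float = 5.0

    def __post_init__(self) -> None:
        if self.extent_um < 0 or self.duration_s <= 0 or self.onset_s < 0:
            raise ValueError("wave onset/extent must be >= 0 and duration > 0")


@dataclass(frozen=True)
class BurstParams:
    """Burst firing of immature OHCs: bursts arrive as a Poisson process,
    last an exponentially distributed time and contain spikes at a fixed
    within-burst rate."""

    interval_mean_s: float = 20.0
    duration_mean_s: float = 1.0
    within_rate_hz: float = 5.0

    def __post_init__(self) -> None:
        if min(self.interval_mean_s, self.duration_mean_s, self.within_rate_hz) < 0:
            raise ValueError("burst parameters must be nonnegative")


@dataclass(frozen=True)
class SimulationConfig:
    """Full generative parameterization of a synthetic recording."""

    n_cells: int = 60
    cell_spacing_um: float = 8.0
    frame_rate_hz: float = 30.3
    n_frames: int = 4000
    field_um: float = 182.0
    baseline_rate_hz: float = 0.05        # burst-initiation rate unless burst_mode
    burst_mode: bool = True
    burst_params: BurstParams = field(default_factory=BurstParams)
    kernel_tau_s: float = 0.3             # indicator decay constant
    kernel_amp: float = 0.6               # dF/F0 per spike
    bleach_tau_s: float = 600.0           # photobleaching decay constant
    noise_sd: float = 0.03                # additive noise SD, dF/F0 units
    f0: float = 100.0                     # baseline fluorescence (arbitrary units)
    wave_schedule: Optional[tuple[WaveSpec, ...]] = None
    wave_rate_per_min: float = 2.09       # wild-type; Cx30-null preset 1.3
    wave_extent_range_um: tuple[float, float] = (20.0, 180.0)
    wave_amplitude: float = 1.0
    wave_duration_s: float = 5.0
    coupling_enabled: bool = True
    coupling_gain: float = 20.0           # rate multiplier increment at d=0, g=1, wave peak
    coupling_length_um: float = 50.0      # spatial decay length of coupling
    coupling_extent_max_um: float = 182.0 # g(extent) = min(extent/this, 1)
    ohc_row_y_um: float = 40.0            # y of the first OHC row
    row_spacing_um: float = 8.0
    n_rows: int = 3
    ger_band_um: tuple[float, float] = (70.0, 150.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1 or self.n_frames < 1:
            raise ValueError("n_cells and n_frames must be >= 1")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be > 0")
        nonneg = (
            self.cell_spacing_um, self.baseline_rate_hz, self.kernel_tau_s,
            self.kernel_amp, self.bleach_tau_s, self.noise_sd,
            self.wave_rate_per_min, self.coupling_gain, self.coupling_length_um,
        )
        if any(v < 0 for v in nonneg):
            raise ValueError("rates, durations and lengths must be >= 0")
        if self.kernel_tau_s <= 0:
            raise ValueError("kernel_tau_s must be > 0")

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate_hz

    def with_(self, **kw) -> "SimulationConfig":
        """Return a copy with fields replaced."""
        return replace(self, **kw)

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.wave_schedule is not None:
            d["wave_schedule"] = [asdict(w) for w in self.wave_schedule]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if d.get("wave_schedule") is not None:
            d["wave_schedule"] = tuple(WaveSpec(**w) for w in d["wave_schedule"])
        if "burst_params" in d and isinstance(d["burst_params"], dict):
            d["burst_params"] = BurstParams(**d["burst_params"])
        for key in ("wave_extent_range_um", "ger_band_um"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


def wildtype_coupled(**overrides) -> SimulationConfig:
    """Wild-type preset: spontaneous waves at 2.09 events/min, coupling on."""
    return SimulationConfig(**overrides)


def antagonist_uncoupled(**overrides) -> SimulationConfig:
    """Purinergic-antagonist preset: waves still occur, OHC coupling is off
    (mirrors PPADS / A317491 conditions)."""
    return SimulationConfig(coupling_enabled=False, **overrides)


def cx30_null(**overrides) -> SimulationConfig:
    """Connexin-30 knockout preset: reduced wave rate (1.3 events/min),
    coupling intact."""
    return SimulationConfig(wave_rate_per_min=1.3, **overrides)


def load_config(path) -> SimulationConfig:
    """Load a SimulationConfig from a flat-key YAML file."""
    with open(path) as fh:
        d = yaml.safe_load(fh) or {}
    return SimulationConfig.from_dict(d)


def save_config(cfg: SimulationConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
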