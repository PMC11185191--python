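"""Pipeline configuration: every tunable of the processing chain in one place.

Defaults follow the published processing chain where it states a value
(17 Hz second-order walking filter, 20 Hz fourth-order step filter, 2.5 s
rest rule, 3-step minimum bout, >=2 valid days, MoCA cutoffs 26/18/10,
SPPB cutoff 7, bout-length bins at 10/30/60 s).  Values the chain leaves
unspecified (activity thresholds, gravity-tracking window, valid-day wear
hours) are documented stand-ins and fully configurable.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml


@dataclass
class PipelineConfig:
    # signal
    fs_hz: float = 100.0
    accel_range_g: float = 8.0
    gravity_lowpass_hz: float = 0.25
    gravity_window_s: float = 10.0
    # non-wear
    nonwear_gap_s: float = 1.0
    nonwear_still_window_min: float = 30.0
    nonwear_still_sd_g: float = 0.005
    # walking-bout candidate detection
    walk_filter_cutoff_hz: float = 17.0
    walk_filter_order: int = 2
    activity_window_s: float = 1.0
    upright_band_g: tuple[float, float] = (-1.15, -0.85)
    sd_threshold_g: float = 0.025
    # bout assembly
    rest_merge_s: float = 2.5
    min_steps: int = 3
    # step detection
    step_filter_cutoff_hz: float = 20.0
    step_filter_order: int = 4
    wavelet_scale_factor: float = 0.4
    cadence_band_hz: tuple[float, float] = (0.5, 3.0)
    step_time_band_s: tuple[float, float] = (0.25, 2.5)
    prominence_frac: float = 0.2
    # macro outcomes
    bout_bins_s: tuple[float, float, float] = (10.0, 30.0, 60.0)
    min_valid_days: int = 2
    valid_day_wear_h: float = 20.0
    alpha_method: str = "mle"  # "mle" (closed form) or "loglog" regression
    # statistics
    moca_cutoffs: tuple[int, int, int] = (26, 18, 10)
    sppb_cutoff: int = 7
    covariates: tuple[str, ...] = ("age", "sex")
    hedges_correction: str = "df"  # J = 1 - 3/(4*df - 1); "n" uses 1 - 3/(4N - 9)
    outlier_iqr_factor: float = 1.5
    alpha_level: float = 0.05
    # reproducibility
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if self.walk_filter_cutoff_hz * 2 >= self.fs_hz:
            raise ValueError("walking-filter cutoff must be below Nyquist")
        if self.rest_merge_s <= 0 or self.min_steps < 1:
            raise ValueError("rest_merge_s must be > 0 and min_steps >= 1")
        if not (0 < self.bout_bins_s[0] < self.bout_bins_s[1] < self.bout_bins_s[2]):
            raise ValueError("bout bins must be strictly increasing and positive")

    def to_yaml(self, path: str) -> None:
        data = asdict(self)
        # YAML round-trips lists, not tuples
        for k, v in data.items():
            if isinstance(v, tuple):
                data[k] = list(v)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for f in fields(cls):
            if f.name in data and isinstance(getattr(cls, f.name, None), tuple):
                data[f.name] = tuple(data[f.name])
        return cls(**data)
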