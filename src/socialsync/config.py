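"""Pipeline configuration.

All numeric method parameters live in :class:`PipelineConfig` so that every
stage of the pipeline (regressor construction, preprocessing, synchrony,
statistics, event alignment) reads from one validated source of truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """Raised when a configuration value violates an invariant."""


@dataclass
class PipelineConfig:
    """Numeric parameters of the dynamic functional-connectivity pipeline.

    Parameters
    ----------
    tr_s : float
        fMRI repetition time in seconds (volume spacing).
    window_s : float
        Length of the sliding synchrony window in seconds.
    window_step_s : float
        Offset between successive windows in seconds.
    band_lo_hz, band_hi_hz : float
        Band of interest for the instantaneous phase. ``band_hi_hz`` may
        equal or exceed the sampling Nyquist (1 / (2 * tr_s)); in that case
        the band reduces to a high-pass at ``band_lo_hz`` because no energy
        above Nyquist exists in the sampled signal.
    hrf_mean_lag_s, hrf_sd_s : float
        Mean lag and standard deviation of the gamma hemodynamic response
        kernel used for all event-series convolution.
    fixation_min_frac : float
        Minimum fraction of a volume the subject must spend fixating for the
        volume to contribute to stimulus regressors; volumes below the
        threshold are zeroed before HRF convolution.
    outlier_sd_mult : float
        Motion-outlier rule: volumes whose volume-to-volume signal change
        exceeds session mean + ``outlier_sd_mult`` * SD are flagged.
    z_threshold : float
        Absolute z threshold defining suprathreshold edges.
    top_edge_frac : float
        Fraction of edges retained by the proportional (top-k) threshold.
    align_pre_s, align_post_s : float
        Extent of clip-onset-aligned segments, seconds before / after the
        (lag-shifted) onset.
    hemo_lag_s : float
        Hemodynamic delay applied when aligning synchrony to clip onsets and
        when assigning windows to stimulus conditions.
    interp_step_s : float
        Grid step of the cubic-spline-interpolated aligned segments.
    regressor_rate_hz : float
        Rate of the volume-level design matrix (1 / tr_s).
    behavior_rate_hz : float
        Sampling rate of the eye-position trace and of frame-level video
        features (luminance, motion energy).
    """

    tr_s: float = 2.0
    window_s: float = 32.0
    window_step_s: float = 2.0
    band_lo_hz: float = 0.01
    band_hi_hz: float = 0.5
    hrf_mean_lag_s: float = 3.0
    hrf_sd_s: float = 1.5
    fixation_min_frac: float = 0.8
    outlier_sd_mult: float = 2.5
    z_threshold: float = 2.05
    top_edge_frac: float = 0.15
    align_pre_s: float = 4.0
    align_post_s: float = 6.0
    hemo_lag_s: float = 2.0
    interp_step_s: float = 0.5
    regressor_rate_hz: float = 0.5
    behavior_rate_hz: float = 25.0

    def __post_init__(self) -> None:
        self.validate()

    # ---- derived quantities -------------------------------------------------

    @property
    def nyquist_hz(self) -> float:
        return 0.5 / self.tr_s

    @property
    def window_len_volumes(self) -> int:
        return int(round(self.window_s / self.tr_s))

    @property
    def window_step_volumes(self) -> int:
        return int(round(self.window_step_s / self.tr_s))

    @property
    def align_grid_s(self):
        """Uniform aligned-segment grid, -align_pre_s .. +align_post_s."""
        import numpy as np

        n = int(round((self.align_pre_s + self.align_post_s) / self.interp_step_s))
        return np.linspace(-self.align_pre_s, self.align_post_s, n + 1)

    # ---- validation ---------------------------------------------------------

    def validate(self) -> None:
        durations = {
            "tr_s": self.tr_s,
            "window_s": self.window_s,
            "window_step_s": self.window_step_s,
            "hrf_mean_lag_s": self.hrf_mean_lag_s,
            "hrf_sd_s": self.hrf_sd_s,
            "interp_step_s": self.interp_step_s,
        }
        for name, value in durations.items():
            if not value > 0:
                raise ConfigError(f"{name} must be > 0, got {value!r}")
        if not 0 < self.fixation_min_frac < 1:
            raise ConfigError("fixation_min_frac must lie in (0, 1)")
        if not 0 < self.top_edge_frac < 1:
            raise ConfigError("top_edge_frac must lie in (0, 1)")
        if not self.band_lo_hz > 0:
            raise ConfigError("band_lo_hz must be > 0")
        if not self.band_lo_hz < self.band_hi_hz:
            raise ConfigError("band_lo_hz must be < band_hi_hz")
        if self.band_lo_hz >= self.nyquist_hz:
            raise ConfigError(
                f"band_lo_hz={self.band_lo_hz} is at or above the sampling "
                f"Nyquist ({self.nyquist_hz} Hz for tr_s={self.tr_s})"
            )
        if self.window_len_volumes < 2:
            raise ConfigError("window must span at least 2 volumes")
        if self.outlier_sd_mult <= 0:
            raise ConfigError("outlier_sd_mult must be > 0")

    # ---- (de)serialisation --------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
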