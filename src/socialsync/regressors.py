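"""Volume-level design matrix built from events, video features and behavior.

Columns are constructed at the volume rate (0.5 Hz for TR = 2 s): a binary
video ON/OFF indicator, frame-averaged luminance, frame-summed motion
energy, exclusive actor-count indicators, behavior-category indicators,
per-volume gaze path length and the fixation fraction. Volumes with poor
fixation are zeroed *before* convolution with the gamma hemodynamic kernel;
the ordering is enforced, not merely conventional.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .config import PipelineConfig
from .datatypes import EventTable, ConfoundBundle, SOCIAL_CATEGORIES, ValidationError

#: Columns that are binary indicators before convolution.
BINARY_COLUMNS = (
    "video_on",
    "actors_0",
    "actors_1",
    "actors_2plus",
    "beh_aggressive",
    "beh_affiliative",
    "beh_ambiguous",
)

#: Nuisance columns used when cleaning synchrony time series.
NUISANCE_COLUMNS = ("luminance", "motion", "gaze_change", "fixation_frac")


@dataclass
class RegressorMatrix:
    """Named per-volume design columns with per-column convolution flags."""

    columns: dict[str, np.ndarray]
    rate_hz: float
    run_starts: list[int] = field(default_factory=lambda: [0])
    convolved: dict[str, bool] = field(default_factory=dict)
    masked: bool = False

    def __post_init__(self) -> None:
        lengths = {len(v) for v in self.columns.values()}
        if len(lengths) > 1:
            raise ValidationError(f"design columns have unequal lengths: {lengths}")
        for name in self.columns:
            self.columns[name] = np.asarray(self.columns[name], dtype=float)
            self.convolved.setdefault(name, False)

    @property
    def n_volumes(self) -> int:
        return len(next(iter(self.columns.values())))

    def run_slices(self) -> list[slice]:
        stops = list(self.run_starts[1:]) + [self.n_volumes]
        return [slice(a, b) for a, b in zip(self.run_starts, stops)]

    def copy(self) -> "RegressorMatrix":
        return RegressorMatrix(
            columns={k: v.copy() for k, v in self.columns.items()},
            rate_hz=self.rate_hz,
            run_starts=list(self.run_starts),
            convolved=dict(self.convolved),
            masked=self.masked,
        )


def gamma_hrf(config: PipelineConfig, dt_s: float | None = None, duration_s: float = 30.0) -> np.ndarray:
    """Gamma hemodynamic kernel sampled at ``dt_s`` (default: one TR).

    The kernel is the unique two-parameter gamma density with the configured
    mean lag and SD (shape = (mean/sd)^2, scale = sd^2/mean), truncated at
    ``duration_s`` and renormalised to unit sum on the sampling grid, so
    convolution preserves the integral of slow inputs.
    """
    dt = config.tr_s if dt_s is None else float(dt_s)
    shape = (config.hrf_mean_lag_s / config.hrf_sd_s) ** 2
    scale = config.hrf_sd_s**2 / config.hrf_mean_lag_s
    t = np.arange(0.0, duration_s + 0.5 * dt, dt)
    kernel = stats.gamma.pdf(t, a=shape, scale=scale)
    total = kernel.sum()
    if total <= 0:
        raise ValidationError("degenerate HRF kernel (all-zero on the grid)")
    return kernel / total


def _volume_reduce(series: np.ndarray, n_volumes: int, frames_per_vol: float, how: str) -> np.ndarray:
    """Reduce a frame-level series to one value per volume (mean or sum)."""
    bounds = np.round(np.arange(n_volumes + 1) * frames_per_vol).astype(int)
    bounds = np.clip(bounds, 0, len(series))
    csum = np.concatenate([[0.0], np.cumsum(series)])
    sums = csum[bounds[1:]] - csum[bounds[:-1]]
    if how == "sum":
        return sums
    counts = np.diff(bounds)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    return means


def build_design(
    events: EventTable,
    confounds: ConfoundBundle,
    config: PipelineConfig,
    run_starts: list[int] | None = None,
) -> RegressorMatrix:
    """Assemble the unconvolved volume-level design matrix.

    Events must be on the same clock as the confound series (session time).
    Frame-level luminance is averaged within each volume; motion energy and
    gaze path length are summed (both are increment-like quantities).
    """
    n_vol = confounds.n_volumes
    tr = config.tr_s
    frames_per_vol = confounds.frame_rate_hz * tr
    if confounds.n_frames < (n_vol - 1) * frames_per_vol:
        raise ValidationError(
            f"frame series too short ({confounds.n_frames} frames) for "
            f"{n_vol} volumes at {confounds.frame_rate_hz} Hz"
        )

    mid_times = (np.arange(n_vol) + 0.5) * tr
    cat = events.category_at(mid_times)
    actors = np.full(n_vol, "", dtype=object)
    for row in events.frame.itertuples(index=False):
        m = (mid_times >= row.onset_s) & (mid_times < row.onset_s + row.duration_s)
        actors[m] = str(row.n_actors)

    video_on = ((cat != "") & (cat != "blank")).astype(float)
    cols: dict[str, np.ndarray] = {"video_on": video_on}
    cols["luminance"] = _volume_reduce(confounds.luminance, n_vol, frames_per_vol, "mean")
    cols["motion"] = _volume_reduce(confounds.motion, n_vol, frames_per_vol, "sum")
    cols["actors_0"] = ((actors == "0") & (video_on > 0)).astype(float)
    cols["actors_1"] = (actors == "1").astype(float)
    cols["actors_2plus"] = (actors == "2+").astype(float)
    for beh in SOCIAL_CATEGORIES:
        cols[f"beh_{beh}"] = (cat == beh).astype(float)

    d = np.diff(confounds.gaze_xy, axis=0)
    step = np.concatenate([[0.0], np.sqrt(d[:, 0] ** 2 + d[:, 1] ** 2)])
    cols["gaze_change"] = _volume_reduce(step, n_vol, frames_per_vol, "sum")
    cols["fixation_frac"] = confounds.fixation_frac.astype(float)

    return RegressorMatrix(
        columns=cols,
        rate_hz=1.0 / tr,
        run_starts=list(run_starts) if run_starts is not None else [0],
    )


def apply_fixation_mask(
    matrix: RegressorMatrix,
    fixation_frac: np.ndarray,
    config: PipelineConfig,
    columns: str | list[str] = "all",
) -> RegressorMatrix:
    """Zero design columns at volumes with inadequate fixation.

    A volume is masked iff its fixation fraction is strictly below
    ``fixation_min_frac`` (a volume fixated for exactly the threshold
    fraction is retained). Masking must precede HRF convolution; a convolved
    input is rejected.
    """
    if any(matrix.convolved.values()):
        raise ValidationError("fixation mask must be applied before HRF convolution")
    fixation_frac = np.asarray(fixation_frac, dtype=float)
    if len(fixation_frac) != matrix.n_volumes:
        raise ValidationError("fixation series length does not match the design")
    mask = fixation_frac < config.fixation_min_frac
    out = matrix.copy()
    names = list(out.columns) if columns == "all" else list(columns)
    for name in names:
        out.columns[name] = out.columns[name].copy()
        out.columns[name][mask] = 0.0
    out.masked = True
    return out


def hrf_convolve(
    matrix: RegressorMatrix,
    config: PipelineConfig,
    columns: str | list[str] = "all",
) -> RegressorMatrix:
    """Causally convolve design columns with the gamma hemodynamic kernel.

    Convolution is applied independently within each run (no bleed across
    run boundaries) and the output has the same length as the input.
    """
    kernel = gamma_hrf(config)
    out = matrix.copy()
    names = list(out.columns) if columns == "all" else list(columns)
    for name in names:
        col = out.columns[name]
        res = np.empty_like(col)
        for sl in out.run_slices():
            seg = col[sl]
            res[sl] = np.convolve(seg, kernel)[: len(seg)]
        out.columns[name] = res
        out.convolved[name] = True
    return out
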