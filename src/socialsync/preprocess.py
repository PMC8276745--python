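"""Volume-level quality control and nuisance residualisation.

Two steps precede the synchrony computation: flagging motion-contaminated
volumes from the volume-to-volume signal change, and removing CSF and
reward-delivery structure from each ROI time series by ordinary least
squares. Flagged volumes are modelled as indicator regressors rather than
excised, preserving the temporal grid that the sliding windows require.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .config import PipelineConfig
from .datatypes import ROITimeSeries, ValidationError
from .regressors import gamma_hrf


@dataclass
class OutlierFlags:
    """Motion-outlier flags with the statistic and threshold that produced them."""

    flagged_volumes: np.ndarray  # sorted volume indices
    stat_series: np.ndarray  # per-volume RMS successive difference (nan at run starts)
    threshold: float

    def indicator_columns(self, n_volumes: int) -> np.ndarray:
        """One 0/1 column per flagged volume, for use as nuisance regressors."""
        cols = np.zeros((n_volumes, len(self.flagged_volumes)))
        for k, v in enumerate(self.flagged_volumes):
            cols[v, k] = 1.0
        return cols


def flag_outliers(ts: ROITimeSeries, config: PipelineConfig) -> OutlierFlags:
    """Flag volumes whose volume-to-volume signal change is extreme.

    The statistic is the root-mean-square across ROIs of the backward
    difference of the signal (a DVARS-style measure), computed within runs so
    run joins never register as motion. Volumes whose statistic exceeds the
    session mean + ``outlier_sd_mult`` * SD are flagged. The first volume of
    each run has no backward difference and can never be flagged.
    """
    if ts.n_volumes < 3:
        raise ValidationError("need at least 3 volumes to flag outliers")
    stat = np.full(ts.n_volumes, np.nan)
    for sl in ts.run_slices():
        seg = ts.values[sl]
        if seg.shape[0] < 2:
            continue
        d = np.diff(seg, axis=0)
        stat[sl.start + 1 : sl.stop] = np.sqrt(np.mean(d * d, axis=1))
    valid = stat[~np.isnan(stat)]
    mean, sd = float(valid.mean()), float(valid.std())
    threshold = mean + config.outlier_sd_mult * sd
    with np.errstate(invalid="ignore"):
        flagged = np.nonzero(stat > threshold)[0] if sd > 0 else np.array([], dtype=int)
    return OutlierFlags(flagged_volumes=flagged, stat_series=stat, threshold=threshold)


def _drop_collinear(X: np.ndarray, names: list[str] | None = None) -> np.ndarray:
    """Drop columns that add no rank, warning about each."""
    keep: list[int] = []
    rank = 0
    for j in range(X.shape[1]):
        cand = X[:, keep + [j]]
        r = np.linalg.matrix_rank(cand)
        if r > rank:
            keep.append(j)
            rank = r
        else:
            label = names[j] if names else f"column {j}"
            warnings.warn(f"dropping collinear confound {label}", stacklevel=3)
    return X[:, keep]


def ols_residuals(X: np.ndarray, Y: np.ndarray, names: list[str] | None = None) -> np.ndarray:
    """Residuals of each column of ``Y`` regressed on the design ``X``.

    Rank-deficient designs are repaired by dropping collinear columns.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        X = _drop_collinear(X, names)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return Y - X @ beta


def reward_regressor(
    reward_times_s: np.ndarray, n_volumes: int, config: PipelineConfig
) -> np.ndarray:
    """Unit impulses at reward onsets binned to volumes, HRF-convolved."""
    impulses = np.zeros(n_volumes)
    for t in np.asarray(reward_times_s, dtype=float):
        v = int(t // config.tr_s)
        if 0 <= v < n_volumes:
            impulses[v] += 1.0
    kernel = gamma_hrf(config)
    return np.convolve(impulses, kernel)[:n_volumes]


def residualize(
    ts: ROITimeSeries,
    csf: np.ndarray,
    reward_times_s: np.ndarray,
    config: PipelineConfig,
    outliers: OutlierFlags | None = None,
) -> ROITimeSeries:
    """Remove CSF, reward-delivery and (optionally) outlier structure.

    Each ROI is regressed on an intercept, the CSF series and the
    HRF-convolved reward-onset series; flagged volumes contribute one
    indicator column each. The residuals (orthogonal to every confound, and
    mean zero because of the intercept) replace the signal.
    """
    csf = np.asarray(csf, dtype=float)
    if len(csf) != ts.n_volumes:
        raise ValidationError("CSF series length must equal the number of volumes")
    cols = [np.ones(ts.n_volumes), csf, reward_regressor(reward_times_s, ts.n_volumes, config)]
    names = ["intercept", "csf", "reward"]
    if outliers is not None and len(outliers.flagged_volumes):
        ind = outliers.indicator_columns(ts.n_volumes)
        cols.extend(ind.T)
        names.extend(f"outlier_v{v}" for v in outliers.flagged_volumes)
    X = np.column_stack(cols)
    resid = ols_residuals(X, ts.values, names)
    return ROITimeSeries(
        values=resid, tr_s=ts.tr_s, roi_labels=list(ts.roi_labels), run_starts=list(ts.run_starts)
    )
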