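"""Clip-onset-aligned synchrony time courses and condition contrasts.

Synchrony around each social clip is extracted on a window-centre grid from
4 s before to 6 s after the hemodynamically lagged onset, resampled onto a
uniform grid by natural cubic spline, normalised to the pre-onset baseline,
and summarised per anatomical edge group: one-sample one-tailed t tests
against baseline and a condition-contrast GLM, both Bonferroni-corrected
within each group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats
from scipy.interpolate import CubicSpline

from .config import PipelineConfig
from .datatypes import ROIRoster, SOCIAL_CATEGORIES, ValidationError
from .edge_stats import BinaryNetwork
from .synchrony import SynchronyTensor

#: The five anatomical connection groups summarised in the aligned analysis.
EDGE_GROUPS: dict[str, tuple[str, str]] = {
    "temporo-temporal": ("temporal", "temporal"),
    "cingulate-temporal": ("cingulate", "temporal"),
    "cingulate-cingulate": ("cingulate", "cingulate"),
    "premotor-temporal": ("premotor", "temporal"),
    "premotor-cingulate": ("cingulate", "premotor"),
}

#: Named condition contrasts: each condition against the mean of the others.
CONTRASTS = {
    f"{cond} > others": cond for cond in SOCIAL_CATEGORIES
}


@dataclass
class AlignedSegments:
    """Per-(series, clip) synchrony samples around lag-shifted clip onsets."""

    rel_times: list[np.ndarray]  # sample times relative to onset + lag
    values: list[np.ndarray]
    conditions: np.ndarray  # (n_segments,) category per segment
    clip_ids: np.ndarray  # (n_segments,) row index into the event table
    series_ids: np.ndarray  # (n_segments,) tensor row each segment came from
    n_dropped: int = 0
    grid: np.ndarray | None = None
    interpolated: np.ndarray | None = None  # (n_segments, n_grid)

    @property
    def n_segments(self) -> int:
        return len(self.rel_times)


def _series_segments(
    series_rows: np.ndarray,
    centers: np.ndarray,
    run_index: np.ndarray,
    events,
    config: PipelineConfig,
) -> AlignedSegments:
    """Extract aligned segments from rows of a window-value matrix."""
    step = config.window_step_s
    rel_list: list[np.ndarray] = []
    val_list: list[np.ndarray] = []
    conds: list[str] = []
    clip_ids: list[int] = []
    series_ids: list[int] = []
    dropped = 0
    social = events.frame[events.frame["category"].isin(SOCIAL_CATEGORIES)]
    if not len(social):
        raise ValidationError("no social clips to align to")
    for clip_id, row in social.iterrows():
        t0 = row["onset_s"] + config.hemo_lag_s
        a, b = t0 - config.align_pre_s, t0 + config.align_post_s
        m = (centers >= a - 1e-9) & (centers <= b + 1e-9)
        ok = m.any()
        if ok:
            sel = np.nonzero(m)[0]
            same_run = len(set(run_index[sel])) == 1
            contiguous = np.allclose(np.diff(centers[sel]), step)
            covered = (centers[sel][0] <= a + step + 1e-9) and (
                centers[sel][-1] >= b - step - 1e-9
            )
            ok = same_run and contiguous and covered
        if not ok:
            dropped += series_rows.shape[0]
            continue
        rel = centers[sel] - t0
        for s in range(series_rows.shape[0]):
            rel_list.append(rel)
            val_list.append(series_rows[s, sel])
            conds.append(row["category"])
            clip_ids.append(int(clip_id))
            series_ids.append(s)
    if not rel_list:
        raise ValidationError("every aligned segment was dropped (run boundaries?)")
    return AlignedSegments(
        rel_times=rel_list,
        values=val_list,
        conditions=np.array(conds, dtype=object),
        clip_ids=np.array(clip_ids),
        series_ids=np.array(series_ids),
        n_dropped=dropped,
    )


def extract_segments(
    tensor: SynchronyTensor, events, config: PipelineConfig
) -> AlignedSegments:
    """Aligned segments for every edge and social clip.

    Samples are the window centres inside ``[onset + lag - pre,
    onset + lag + post]``; segments that straddle a run/sequence boundary or
    do not cover the interval to within one window step are dropped and
    counted in ``n_dropped``.
    """
    return _series_segments(
        tensor.values, tensor.window_center_s, tensor.run_index, events, config
    )


def interpolate_segments(segments: AlignedSegments, config: PipelineConfig) -> AlignedSegments:
    """Resample segments onto the uniform aligned grid by natural cubic spline.

    Sample points that coincide with grid points are reproduced exactly (the
    spline interpolates); segments with fewer than 4 samples fall back to
    linear interpolation with a warning.
    """
    grid = config.align_grid_s
    out = np.empty((segments.n_segments, len(grid)))
    for k, (x, y) in enumerate(zip(segments.rel_times, segments.values)):
        if len(x) >= 4:
            out[k] = CubicSpline(x, y, bc_type="natural")(grid)
        else:
            warnings.warn("segment with fewer than 4 samples: linear interpolation fallback")
            out[k] = np.interp(grid, x, y)
    segments.grid = grid
    segments.interpolated = out
    return segments


@dataclass
class GroupTimecourse:
    """Baseline-normalised clip-level courses per anatomical group/condition."""

    grid: np.ndarray
    #: group -> condition -> (n_clips, n_grid) baseline-subtracted matrices
    clip_courses: dict[str, dict[str, np.ndarray]]
    #: groups with no suprathreshold edges (courses undefined)
    flagged: list[str] = field(default_factory=list)

    def mean(self, group: str, condition: str) -> np.ndarray:
        return self.clip_courses[group][condition].mean(axis=0)

    def sem(self, group: str, condition: str) -> np.ndarray:
        mat = self.clip_courses[group][condition]
        if mat.shape[0] < 2:
            warnings.warn(f"{group}/{condition}: single segment, SEM undefined")
            return np.full(mat.shape[1], np.nan)
        return mat.std(axis=0, ddof=1) / np.sqrt(mat.shape[0])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for group, conds in self.clip_courses.items():
            for cond, mat in conds.items():
                mean = mat.mean(axis=0)
                sem = self.sem(group, cond) if mat.shape[0] >= 2 else np.full(len(self.grid), np.nan)
                for t, m, s in zip(self.grid, mean, sem):
                    rows.append((group, cond, t, m, s, mat.shape[0]))
        return pd.DataFrame(
            rows, columns=["group", "condition", "time_s", "mean", "sem", "n_clips"]
        )


def group_edges(roster: ROIRoster, supra: BinaryNetwork) -> dict[str, np.ndarray]:
    """Suprathreshold edge indices per anatomical connection group."""
    pairs = roster.edge_groups()
    mask = supra.edge_mask()
    out = {}
    for name, pair in EDGE_GROUPS.items():
        out[name] = np.array(
            [e for e, pg in enumerate(pairs) if pg == pair and mask[e]], dtype=int
        )
    return out


def group_timecourses(
    tensor: SynchronyTensor,
    events,
    roster: ROIRoster,
    supra: BinaryNetwork,
    config: PipelineConfig,
) -> GroupTimecourse:
    """Clip-aligned, baseline-normalised courses per anatomical group.

    For each group the suprathreshold edges are averaged first, then one
    segment per clip is extracted and splined onto the grid; each segment's
    pre-onset mean is subtracted, so courses read as change from baseline.
    """
    edges_by_group = group_edges(roster, supra)
    courses: dict[str, dict[str, np.ndarray]] = {}
    flagged: list[str] = []
    grid = config.align_grid_s
    pre = grid < 0
    for name, edges in edges_by_group.items():
        if edges.size == 0:
            warnings.warn(f"group {name}: no suprathreshold edges, course undefined")
            flagged.append(name)
            courses[name] = {
                c: np.full((0, len(grid)), np.nan) for c in SOCIAL_CATEGORIES
            }
            continue
        series = tensor.values[edges].mean(axis=0, keepdims=True)
        segs = _series_segments(series, tensor.window_center_s, tensor.run_index, events, config)
        segs = interpolate_segments(segs, config)
        mat = segs.interpolated - segs.interpolated[:, pre].mean(axis=1, keepdims=True)
        courses[name] = {
            cond: mat[segs.conditions == cond] for cond in SOCIAL_CATEGORIES
        }
    return GroupTimecourse(grid=grid, clip_courses=courses, flagged=flagged)


def test_vs_baseline(tc: GroupTimecourse) -> pd.DataFrame:
    """One-tailed one-sample t tests of baseline-subtracted synchrony > 0.

    Clip-level values are the observations. The Bonferroni family is all
    timepoints x conditions within a group.
    """
    rows = []
    n_grid = len(tc.grid)
    for group, conds in tc.clip_courses.items():
        family = n_grid * len(conds)
        for cond, mat in conds.items():
            if mat.shape[0] < 2:
                t_vals = np.full(n_grid, np.nan)
                p_vals = np.ones(n_grid)
            else:
                with np.errstate(divide="ignore", invalid="ignore"):
                    res = sstats.ttest_1samp(mat, 0.0, axis=0, alternative="greater")
                t_vals = res.statistic
                p_vals = np.where(np.isfinite(res.pvalue), res.pvalue, 1.0)
                # degenerate (zero-variance) timepoints are inconclusive
                p_vals = np.where(mat.std(axis=0) == 0, 1.0, p_vals)
            p_bonf = np.minimum(p_vals * family, 1.0)
            for k in range(n_grid):
                rows.append((group, cond, tc.grid[k], t_vals[k], p_vals[k], p_bonf[k]))
    return pd.DataFrame(
        rows, columns=["group", "condition", "time_s", "t", "p", "p_bonf"]
    )


def contrast_glm(tc: GroupTimecourse) -> pd.DataFrame:
    """Per-timepoint GLM contrasting each condition against the other two.

    Clip-level values are regressed on condition indicators; the contrast
    weight vector is +2/3 on the named condition and -1/3 on each other, so
    the estimate is proportional to (and signed as) "condition minus the
    mean of the others": a pure shift delta yields 2*delta/3. One-tailed
    p values, Bonferroni-corrected over timepoints x contrasts per group.
    """
    rows = []
    conds = list(SOCIAL_CATEGORIES)
    n_grid = len(tc.grid)
    for group, mats in tc.clip_courses.items():
        counts = {c: mats[c].shape[0] for c in conds}
        if min(counts.values()) == 0:
            warnings.warn(f"group {group}: missing condition, contrasts undefined")
            for name in CONTRASTS:
                for k in range(n_grid):
                    rows.append((group, name, tc.grid[k], np.nan, np.nan, np.nan, np.nan))
            continue
        family = n_grid * len(CONTRASTS)
        n_total = sum(counts.values())
        df_err = n_total - len(conds)
        stacked = {c: mats[c] for c in conds}
        means = np.array([stacked[c].mean(axis=0) for c in conds])  # (3, n_grid)
        sse = sum(
            ((stacked[c] - stacked[c].mean(axis=0)) ** 2).sum(axis=0) for c in conds
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            sigma2 = sse / df_err if df_err > 0 else np.full(n_grid, np.nan)
        for name, target in CONTRASTS.items():
            w = np.array([2.0 / 3.0 if c == target else -1.0 / 3.0 for c in conds])
            est = w @ means  # (n_grid,)
            var_scale = sum(w_k**2 / counts[c] for w_k, c in zip(w, conds))
            with np.errstate(divide="ignore", invalid="ignore"):
                se = np.sqrt(sigma2 * var_scale)
                t_vals = est / se
            p_vals = np.where(
                np.isfinite(t_vals), sstats.t.sf(t_vals, df_err), 1.0
            )
            p_bonf = np.minimum(p_vals * family, 1.0)
            for k in range(n_grid):
                rows.append(
                    (group, name, tc.grid[k], est[k], t_vals[k], p_vals[k], p_bonf[k])
                )
    return pd.DataFrame(
        rows, columns=["group", "contrast", "time_s", "estimate", "t", "p", "p_bonf"]
    )
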