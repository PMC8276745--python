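"""Sliding-window phase synchrony between ROI pairs.

The connectivity measure is the phase-locking value (PLV): the modulus of
the time-averaged unit phasor of the instantaneous phase difference between
two band-limited signals. It is bounded in [0, 1], equals 1 for a constant
phase offset, and is independent of signal amplitude. Instantaneous phase
comes from the analytic signal of the band-passed BOLD series, computed
within runs with mirror padding so that run joins never contaminate the
phase estimate.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .config import PipelineConfig
from .datatypes import EventTable, ROITimeSeries, ValidationError, edge_index
from .regressors import NUISANCE_COLUMNS, RegressorMatrix

logger = logging.getLogger(__name__)


@dataclass
class PhaseMatrix:
    """Instantaneous phase per volume and ROI, defined within runs."""

    phases: np.ndarray  # (n_volumes, n_rois), radians in (-pi, pi]
    tr_s: float
    run_starts: list[int]
    band_hz: tuple[float, float]

    @property
    def n_volumes(self) -> int:
        return self.phases.shape[0]

    @property
    def n_rois(self) -> int:
        return self.phases.shape[1]

    def run_slices(self) -> list[slice]:
        stops = list(self.run_starts[1:]) + [self.n_volumes]
        return [slice(a, b) for a, b in zip(self.run_starts, stops)]


@dataclass
class SynchronyTensor:
    """Edge x window synchrony values with window-centre timestamps.

    ``run_index`` records which run (or, after repeat averaging, which video
    sequence) each window belongs to; windows never straddle the boundary.
    """

    values: np.ndarray  # (n_edges, n_windows)
    window_center_s: np.ndarray  # (n_windows,)
    run_index: np.ndarray  # (n_windows,) int
    n_rois: int
    window_len_volumes: int
    tr_s: float
    transformed: bool = False
    estimator: str = "plv"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.window_center_s = np.asarray(self.window_center_s, dtype=float)
        self.run_index = np.asarray(self.run_index, dtype=int)
        expected_edges = self.n_rois * (self.n_rois - 1) // 2
        if self.values.shape[0] != expected_edges:
            raise ValidationError(
                f"expected {expected_edges} edges for {self.n_rois} ROIs, "
                f"got {self.values.shape[0]}"
            )
        if self.values.shape[1] != len(self.window_center_s):
            raise ValidationError("window_center_s length must match value columns")
        if len(self.run_index) != len(self.window_center_s):
            raise ValidationError("run_index length must match windows")

    @property
    def n_edges(self) -> int:
        return self.values.shape[0]

    @property
    def n_windows(self) -> int:
        return self.values.shape[1]

    def edges(self) -> list[tuple[int, int]]:
        return edge_index(self.n_rois)

    def copy(self) -> "SynchronyTensor":
        return SynchronyTensor(
            values=self.values.copy(),
            window_center_s=self.window_center_s.copy(),
            run_index=self.run_index.copy(),
            n_rois=self.n_rois,
            window_len_volumes=self.window_len_volumes,
            tr_s=self.tr_s,
            transformed=self.transformed,
            estimator=self.estimator,
        )


# --------------------------------------------------------------------------
# instantaneous phase
# --------------------------------------------------------------------------

def _band_sos(config: PipelineConfig):
    """Zero-phase 4th-order Butterworth for the configured band.

    The sampled signal carries no energy above the volume-rate Nyquist, so a
    configured upper edge at or beyond Nyquist reduces the band-pass to a
    high-pass at the lower edge.
    """
    fs = 1.0 / config.tr_s
    nyq = config.nyquist_hz
    if config.band_hi_hz >= nyq:
        return signal.butter(4, config.band_lo_hz, btype="highpass", fs=fs, output="sos")
    return signal.butter(
        2, [config.band_lo_hz, config.band_hi_hz], btype="bandpass", fs=fs, output="sos"
    )


def instantaneous_phase(ts: ROITimeSeries, config: PipelineConfig) -> PhaseMatrix:
    """Band-limited analytic-signal phase, computed per run.

    Each run is demeaned, mirror-padded by one window length, zero-phase
    filtered to the configured band, Hilbert-transformed and cropped back, so
    edge transients from the filter and transform fall in the padding.
    """
    L = config.window_len_volumes
    sos = _band_sos(config)
    phases = np.empty_like(ts.values)
    for r, sl in enumerate(ts.run_slices()):
        seg = ts.values[sl]
        if seg.shape[0] < 2 * L:
            raise ValidationError(
                f"run {r} has {seg.shape[0]} volumes; need at least {2 * L} "
                f"for {config.window_s:g} s windows"
            )
        seg = seg - seg.mean(axis=0)
        pad = min(L, seg.shape[0] - 1)
        padded = np.pad(seg, ((pad, pad), (0, 0)), mode="reflect")
        filtered = signal.sosfiltfilt(sos, padded, axis=0)
        analytic = signal.hilbert(filtered, axis=0)
        phases[sl] = np.angle(analytic[pad : pad + seg.shape[0]])
    return PhaseMatrix(
        phases=phases,
        tr_s=ts.tr_s,
        run_starts=list(ts.run_starts),
        band_hz=(config.band_lo_hz, min(config.band_hi_hz, config.nyquist_hz)),
    )


# --------------------------------------------------------------------------
# windowed synchrony
# --------------------------------------------------------------------------

def windowed_synchrony(
    phases: PhaseMatrix, config: PipelineConfig, estimator: str = "plv"
) -> SynchronyTensor:
    """Sliding-window phase synchrony for every ROI pair.

    Windows span ``window_len_volumes`` volumes and advance by
    ``window_step_volumes`` within each run; a run of V volumes yields
    V - L + 1 windows for unit step. ``estimator='plv'`` returns the
    phase-locking value |mean phasor|; ``'circular_variance'`` returns
    1 - PLV (a dispersion measure, monotone in the same quantity).
    """
    if estimator not in ("plv", "circular_variance"):
        raise ValidationError(f"unknown synchrony estimator {estimator!r}")
    L = config.window_len_volumes
    step = config.window_step_volumes
    pairs = edge_index(phases.n_rois)
    i_idx = np.array([i for i, _ in pairs])
    j_idx = np.array([j for _, j in pairs])

    values_parts: list[np.ndarray] = []
    centers_parts: list[np.ndarray] = []
    run_parts: list[np.ndarray] = []
    for r, sl in enumerate(phases.run_slices()):
        ph = phases.phases[sl]
        V = ph.shape[0]
        if V < L:
            continue
        phasors = np.exp(1j * ph)  # (V, R)
        z = phasors[:, i_idx] * np.conj(phasors[:, j_idx])  # (V, E)
        csum = np.concatenate([np.zeros((1, z.shape[1]), dtype=complex), np.cumsum(z, axis=0)])
        starts = np.arange(0, V - L + 1, step)
        win_mean = (csum[starts + L] - csum[starts]) / L
        plv = np.abs(win_mean)
        values_parts.append(plv.T)
        centers_parts.append((sl.start + starts + L / 2.0) * phases.tr_s)
        run_parts.append(np.full(len(starts), r))

    if not values_parts:
        raise ValidationError("no run long enough for a single window")
    values = np.concatenate(values_parts, axis=1)
    if estimator == "circular_variance":
        values = 1.0 - values
    return SynchronyTensor(
        values=values,
        window_center_s=np.concatenate(centers_parts),
        run_index=np.concatenate(run_parts),
        n_rois=phases.n_rois,
        window_len_volumes=L,
        tr_s=phases.tr_s,
        estimator=estimator,
    )


# --------------------------------------------------------------------------
# nuisance cleaning, transform, repeat averaging
# --------------------------------------------------------------------------

def _window_means(column: np.ndarray, tensor: SynchronyTensor) -> np.ndarray:
    """Mean of a volume series over each window's volumes."""
    L = tensor.window_len_volumes
    starts = np.round(tensor.window_center_s / tensor.tr_s - L / 2.0).astype(int)
    csum = np.concatenate([[0.0], np.cumsum(column)])
    return (csum[starts + L] - csum[starts]) / L


def clean_synchrony(
    tensor: SynchronyTensor,
    design: RegressorMatrix,
    config: PipelineConfig,
    columns: tuple[str, ...] = NUISANCE_COLUMNS,
) -> SynchronyTensor:
    """Regress low-level visual and behavioral structure out of synchrony.

    Each nuisance column is averaged over the volumes of each window
    (aligning the volume-level design to window centres), every edge's
    synchrony series is regressed on [intercept, nuisances] by OLS, and the
    residual plus the fitted intercept is returned, leaving the series
    orthogonal to every nuisance but on its original level.
    """
    from .preprocess import ols_residuals  # local import to keep modules acyclic

    missing = [c for c in columns if c not in design.columns]
    if missing:
        raise ValidationError(f"design lacks nuisance columns: {missing}")
    nuis = np.column_stack([_window_means(design.columns[c], tensor) for c in columns])
    X = np.column_stack([np.ones(tensor.n_windows), nuis])
    Y = tensor.values.T  # (W, E)
    resid = ols_residuals(X, Y, names=["intercept", *columns])
    # restore per-edge level: residuals are mean-free, so add the mean back
    out = tensor.copy()
    out.values = (resid + Y.mean(axis=0)).T
    return out


def arcsine_transform(tensor: SynchronyTensor, sqrt_first: bool = False) -> SynchronyTensor:
    """Variance-stabilising arcsine transform of synchrony values.

    Values are mapped by arcsin(r) (or arcsin(sqrt(r)) when ``sqrt_first``),
    a strictly monotone map from [0, 1] to [0, pi/2]. Values pushed outside
    [0, 1] by nuisance cleaning are clipped first; the count is logged.
    """
    if tensor.transformed:
        raise ValidationError("tensor is already transformed")
    vals = tensor.values
    n_clip = int(((vals < 0) | (vals > 1)).sum())
    if n_clip:
        logger.info("arcsine transform clipped %d values to [0, 1]", n_clip)
    vals = np.clip(vals, 0.0, 1.0)
    out = tensor.copy()
    out.values = np.arcsin(np.sqrt(vals) if sqrt_first else vals)
    out.transformed = True
    return out


def average_repeats(
    tensor: SynchronyTensor,
    run_sequences: list[int],
    config: PipelineConfig,
    sequence_duration_s: float,
) -> SynchronyTensor:
    """Average synchrony across repeated viewings of each video sequence.

    ``run_sequences[r]`` names the unique video sequence shown in run ``r``.
    Repeats of a sequence must share the same within-run window grid. The
    output lives on the unique-content clock: sequence ``q`` occupies
    ``[q * sequence_duration_s, (q + 1) * sequence_duration_s)`` and the
    output ``run_index`` holds sequence indices.
    """
    run_sequences = list(run_sequences)
    n_runs = int(tensor.run_index.max()) + 1 if tensor.n_windows else 0
    if len(run_sequences) != n_runs:
        raise ValidationError(
            f"run_sequences has {len(run_sequences)} entries for {n_runs} runs"
        )
    seq_ids = sorted(set(run_sequences))
    values_parts, centers_parts, seq_parts = [], [], []
    for q in seq_ids:
        runs = [r for r, s in enumerate(run_sequences) if s == q]
        rel_centers = None
        stack = []
        for r in runs:
            m = tensor.run_index == r
            centers = tensor.window_center_s[m]
            run_t0 = centers[0] - (tensor.window_len_volumes / 2.0) * tensor.tr_s
            rel = centers - run_t0
            if rel_centers is None:
                rel_centers = rel
            elif len(rel) != len(rel_centers) or not np.allclose(rel, rel_centers):
                raise ValidationError(
                    f"repeats of sequence {q} have misaligned window timelines"
                )
            stack.append(tensor.values[:, m])
        values_parts.append(np.mean(stack, axis=0))
        centers_parts.append(q * sequence_duration_s + rel_centers)
        seq_parts.append(np.full(len(rel_centers), q))
    out = tensor.copy()
    out.values = np.concatenate(values_parts, axis=1)
    out.window_center_s = np.concatenate(centers_parts)
    out.run_index = np.concatenate(seq_parts)
    return out


# --------------------------------------------------------------------------
# summaries and state networks
# --------------------------------------------------------------------------

def network_summary(tensor: SynchronyTensor) -> tuple[np.ndarray, np.ndarray]:
    """Per-window mean and (population) variance of synchrony across edges."""
    if tensor.n_edges < 2:
        raise ValidationError("network summary needs at least 2 edges")
    return tensor.values.mean(axis=0), tensor.values.var(axis=0)


def assign_window_categories(
    tensor: SynchronyTensor, events: EventTable, config: PipelineConfig
) -> np.ndarray:
    """Stimulus category of each window (majority rule with hemodynamic lag).

    Each of the window's volumes is labelled with the category active at its
    midpoint minus ``hemo_lag_s``; a window takes a category iff more than
    half of its volumes carry that label, else the empty string.
    """
    L = tensor.window_len_volumes
    offsets = (np.arange(L) - L / 2.0 + 0.5) * tensor.tr_s
    times = tensor.window_center_s[:, None] + offsets[None, :] - config.hemo_lag_s
    labels = events.category_at(times.ravel())
    vals, codes = np.unique(labels, return_inverse=True)
    codes = codes.reshape(times.shape)
    W = tensor.n_windows
    counts = np.zeros((W, len(vals)), dtype=int)
    np.add.at(counts, (np.repeat(np.arange(W), L), codes.ravel()), 1)
    best = counts.argmax(axis=1)
    majority = counts[np.arange(W), best] > L / 2.0
    out = np.where(majority & (vals[best] != ""), vals[best], "").astype(object)
    return out


def state_network(
    tensor: SynchronyTensor,
    events: EventTable,
    state: set[str] | tuple[str, ...],
    config: PipelineConfig,
    roster=None,
):
    """Mean edge synchrony within a stimulus state and its top-15% network.

    Returns ``(edge_means, BinaryNetwork)`` and, when a roster is supplied,
    a lobe-pair proportion table of the suprathreshold connections as a
    third element.
    """
    from . import edge_stats  # local import: edge_stats imports this module

    cats = assign_window_categories(tensor, events, config)
    mask = np.isin(cats, list(state))
    if not mask.any():
        raise ValidationError(f"no windows assigned to state {sorted(state)}")
    edge_means = tensor.values[:, mask].mean(axis=1)
    net = edge_stats.top_fraction_network(edge_means, tensor.n_rois, config.top_edge_frac)
    if roster is None:
        return edge_means, net
    return edge_means, net, edge_stats.lobe_proportions(net, roster)
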