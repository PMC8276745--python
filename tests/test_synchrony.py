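import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from socialsync import PipelineConfig
from socialsync.datatypes import ValidationError, edge_index
from socialsync.regressors import RegressorMatrix
from socialsync.synchrony import (
    PhaseMatrix,
    SynchronyTensor,
    arcsine_transform,
    assign_window_categories,
    average_repeats,
    clean_synchrony,
    instantaneous_phase,
    network_summary,
    state_network,
    windowed_synchrony,
    _window_means,
)


@pytest.fixture()
def cfg():
    return PipelineConfig()


def _phases(values, run_starts=(0,)):
    return PhaseMatrix(
        phases=np.asarray(values, dtype=float),
        tr_s=2.0,
        run_starts=list(run_starts),
        band_hz=(0.01, 0.25),
    )


def _tensor(values, n_rois, centers=None, runs=None, **kw):
    values = np.asarray(values, dtype=float)
    W = values.shape[1]
    return SynchronyTensor(
        values=values,
        window_center_s=np.arange(W) * 2.0 + 16.0 if centers is None else centers,
        run_index=np.zeros(W, dtype=int) if runs is None else runs,
        n_rois=n_rois,
        window_len_volumes=16,
        tr_s=2.0,
        **kw,
    )


# --------------------------------------------------------------------------
# windowed synchrony
# --------------------------------------------------------------------------

def test_plv_equals_direct_mean_phasor_formula(cfg, rng):
    ph = rng.uniform(-np.pi, np.pi, (80, 3))
    tensor = windowed_synchrony(_phases(ph), cfg)
    L = cfg.window_len_volumes
    for e, (i, j) in enumerate(edge_index(3)):
        for w in range(80 - L + 1):
            d = ph[w : w + L, i] - ph[w : w + L, j]
            oracle = abs(np.exp(1j * d).mean())
            assert abs(tensor.values[e, w] - oracle) < 1e-12


def test_window_count_is_volumes_minus_fifteen(cfg, rng):
    ph = rng.uniform(-np.pi, np.pi, (440, 2))
    tensor = windowed_synchrony(_phases(ph), cfg)
    assert tensor.n_windows == 425


def test_windows_never_straddle_run_boundaries(cfg, rng):
    ph = rng.uniform(-np.pi, np.pi, (100, 2))
    joint = windowed_synchrony(_phases(ph, run_starts=(0, 40)), cfg)
    a = windowed_synchrony(_phases(ph[:40]), cfg)
    b = windowed_synchrony(_phases(ph[40:]), cfg)
    assert joint.n_windows == a.n_windows + b.n_windows == 25 + 45
    assert np.allclose(joint.values, np.concatenate([a.values, b.values], axis=1))
    assert list(np.unique(joint.run_index)) == [0, 1]


def test_window_centers_are_midpoints(cfg, rng):
    ph = rng.uniform(-np.pi, np.pi, (20, 2))
    tensor = windowed_synchrony(_phases(ph), cfg)
    # first window covers volumes 0..15 -> centre at 8 volumes = 16 s
    assert np.allclose(tensor.window_center_s, [16.0, 18.0, 20.0, 22.0, 24.0])


def test_constant_phase_offset_gives_unit_synchrony(cfg):
    t = np.arange(60)
    ph = np.column_stack([0.3 * t, 0.3 * t + 1.0])
    tensor = windowed_synchrony(_phases(ph), cfg)
    assert np.allclose(tensor.values, 1.0, atol=1e-12)


def test_synchrony_symmetric_under_roi_reversal(cfg, rng):
    ph = rng.uniform(-np.pi, np.pi, (50, 4))
    fwd = windowed_synchrony(_phases(ph), cfg)
    rev = windowed_synchrony(_phases(ph[:, ::-1]), cfg)
    pairs = edge_index(4)
    for e, (i, j) in enumerate(pairs):
        mapped = pairs.index(tuple(sorted((3 - i, 3 - j))))
        assert np.allclose(fwd.values[e], rev.values[mapped], atol=1e-12)


def test_circular_variance_estimator_is_one_minus_plv(cfg, rng):
    ph = rng.uniform(-np.pi, np.pi, (40, 3))
    plv = windowed_synchrony(_phases(ph), cfg)
    cv = windowed_synchrony(_phases(ph), cfg, estimator="circular_variance")
    assert np.allclose(cv.values, 1.0 - plv.values, atol=1e-12)
    with pytest.raises(ValidationError, match="estimator"):
        windowed_synchrony(_phases(ph), cfg, estimator="coherence")


@settings(deadline=None, max_examples=25)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_plv_bounded_in_unit_interval(seed):
    cfg = PipelineConfig()
    ph = np.random.default_rng(seed).uniform(-np.pi, np.pi, (30, 3))
    tensor = windowed_synchrony(_phases(ph), cfg)
    assert np.all(tensor.values >= 0.0) and np.all(tensor.values <= 1.0 + 1e-12)


# --------------------------------------------------------------------------
# instantaneous phase
# --------------------------------------------------------------------------

def test_in_band_sinusoid_phase_advances_at_its_frequency(cfg):
    f = 0.05
    t = np.arange(200) * cfg.tr_s
    x = np.cos(2 * np.pi * f * t)
    from socialsync.datatypes import ROITimeSeries

    ts = ROITimeSeries(values=x[:, None], tr_s=cfg.tr_s, roi_labels=["a"])
    ph = instantaneous_phase(ts, cfg)
    d = np.angle(np.exp(1j * np.diff(ph.phases[40:160, 0])))
    assert np.allclose(d, 2 * np.pi * f * cfg.tr_s, atol=0.03)


def test_phase_is_amplitude_invariant(cfg, rng):
    from socialsync.datatypes import ROITimeSeries

    v = rng.normal(0, 1, (120, 3))
    scaled = v.copy()
    scaled[:, 1] *= 1000.0
    ts1 = ROITimeSeries(values=v, tr_s=cfg.tr_s, roi_labels=["a", "b", "c"])
    ts2 = ROITimeSeries(values=scaled, tr_s=cfg.tr_s, roi_labels=["a", "b", "c"])
    p1 = instantaneous_phase(ts1, cfg)
    p2 = instantaneous_phase(ts2, cfg)
    assert np.allclose(p1.phases, p2.phases, atol=1e-10)


def test_phase_computed_independently_per_run(cfg, rng):
    from socialsync.datatypes import ROITimeSeries

    v = rng.normal(0, 1, (100, 2))
    both = instantaneous_phase(
        ROITimeSeries(values=v, tr_s=cfg.tr_s, roi_labels=["a", "b"], run_starts=[0, 50]),
        cfg,
    )
    first = instantaneous_phase(
        ROITimeSeries(values=v[:50], tr_s=cfg.tr_s, roi_labels=["a", "b"]), cfg
    )
    assert np.allclose(both.phases[:50], first.phases, atol=1e-12)


def test_run_shorter_than_two_windows_rejected(cfg, rng):
    from socialsync.datatypes import ROITimeSeries

    ts = ROITimeSeries(
        values=rng.normal(size=(31, 2)), tr_s=cfg.tr_s, roi_labels=["a", "b"]
    )
    with pytest.raises(ValidationError, match="volumes"):
        instantaneous_phase(ts, cfg)


# --------------------------------------------------------------------------
# nuisance cleaning
# --------------------------------------------------------------------------

def test_window_means_match_direct_average(cfg, rng):
    tensor = _tensor(rng.uniform(0, 1, (3, 10)), n_rois=3)
    col = rng.normal(size=25)
    got = _window_means(col, tensor)
    for w in range(10):
        assert abs(got[w] - col[w : w + 16].mean()) < 1e-12


def test_cleaning_orthogonalises_and_preserves_level(cfg, rng):
    n_vol = 60
    design = RegressorMatrix(
        columns={
            "luminance": rng.uniform(0, 1, n_vol),
            "motion": rng.uniform(0, 2, n_vol),
            "gaze_change": rng.uniform(0, 5, n_vol),
            "fixation_frac": rng.uniform(0.5, 1, n_vol),
        },
        rate_hz=0.5,
    )
    tensor = _tensor(rng.uniform(0.1, 0.9, (6, 45)), n_rois=4)
    cleaned = clean_synchrony(tensor, design, cfg)
    nuis = np.column_stack(
        [_window_means(design.columns[c], tensor) for c in design.columns]
    )
    centred = nuis - nuis.mean(axis=0)
    # residual orthogonal to every (centred) nuisance, per edge
    assert np.allclose(centred.T @ (cleaned.values.T - cleaned.values.T.mean(axis=0)), 0.0, atol=1e-8)
    # per-edge mean level is restored
    assert np.allclose(cleaned.values.mean(axis=1), tensor.values.mean(axis=1), atol=1e-10)


def test_cleaning_matches_manual_ols(cfg, rng):
    n_vol = 50
    design = RegressorMatrix(
        columns={
            "luminance": rng.uniform(0, 1, n_vol),
            "motion": rng.uniform(0, 2, n_vol),
            "gaze_change": rng.uniform(0, 5, n_vol),
            "fixation_frac": rng.uniform(0.5, 1, n_vol),
        },
        rate_hz=0.5,
    )
    tensor = _tensor(rng.uniform(0.1, 0.9, (3, 35)), n_rois=3)
    cleaned = clean_synchrony(tensor, design, cfg)
    nuis = np.column_stack(
        [_window_means(design.columns[c], tensor) for c in design.columns]
    )
    X = np.column_stack([np.ones(35), nuis])
    Y = tensor.values.T
    beta = np.linalg.lstsq(X, Y, rcond=None)[0]
    oracle = (Y - X @ beta + Y.mean(axis=0)).T
    assert np.allclose(cleaned.values, oracle, atol=1e-10)


def test_cleaning_requires_nuisance_columns(cfg, rng):
    design = RegressorMatrix(columns={"luminance": np.zeros(40)}, rate_hz=0.5)
    tensor = _tensor(rng.uniform(0, 1, (3, 25)), n_rois=3)
    with pytest.raises(ValidationError, match="nuisance"):
        clean_synchrony(tensor, design, cfg)


# --------------------------------------------------------------------------
# arcsine transform
# --------------------------------------------------------------------------

def test_arcsine_of_half_is_pi_over_six():
    tensor = _tensor(np.full((3, 5), 0.5), n_rois=3)
    out = arcsine_transform(tensor)
    assert np.allclose(out.values, np.pi / 6)
    assert out.transformed


def test_arcsine_clips_out_of_range_values(caplog):
    import logging

    tensor = _tensor(np.array([[-0.1, 0.5, 1.2]] * 3), n_rois=3)
    with caplog.at_level(logging.INFO, logger="socialsync.synchrony"):
        out = arcsine_transform(tensor)
    assert out.values[0, 0] == 0.0
    assert abs(out.values[0, 2] - np.pi / 2) < 1e-12
    assert any("clipped" in r.message for r in caplog.records)


def test_double_transform_rejected():
    tensor = _tensor(np.full((3, 4), 0.3), n_rois=3)
    once = arcsine_transform(tensor)
    with pytest.raises(ValidationError, match="already"):
        arcsine_transform(once)


def test_sqrt_first_variant():
    tensor = _tensor(np.full((3, 4), 0.25), n_rois=3)
    out = arcsine_transform(tensor, sqrt_first=True)
    assert np.allclose(out.values, np.arcsin(0.5))


@given(st.floats(min_value=0.0, max_value=1.0), st.floats(min_value=0.0, max_value=1.0))
def test_arcsine_is_monotone(a, b):
    lo, hi = sorted((a, b))
    assert np.arcsin(lo) <= np.arcsin(hi)


# --------------------------------------------------------------------------
# repeat averaging
# --------------------------------------------------------------------------

def test_average_repeats_means_matching_windows(cfg, rng):
    # two runs, both viewings of sequence 0
    vals = rng.uniform(0, 1, (3, 10))
    centers = np.concatenate([np.arange(5) * 2.0 + 16.0, 100.0 + np.arange(5) * 2.0 + 16.0])
    runs = np.repeat([0, 1], 5)
    tensor = _tensor(vals, n_rois=3, centers=centers, runs=runs)
    out = average_repeats(tensor, [0, 0], cfg, sequence_duration_s=100.0)
    assert out.n_windows == 5
    assert np.allclose(out.values, (vals[:, :5] + vals[:, 5:]) / 2)
    assert np.allclose(out.window_center_s, np.arange(5) * 2.0 + 16.0)
    assert list(np.unique(out.run_index)) == [0]


def test_average_repeats_places_sequences_on_unique_content_clock(cfg, rng):
    vals = rng.uniform(0, 1, (3, 10))
    centers = np.concatenate([np.arange(5) * 2.0 + 16.0, 100.0 + np.arange(5) * 2.0 + 16.0])
    runs = np.repeat([0, 1], 5)
    tensor = _tensor(vals, n_rois=3, centers=centers, runs=runs)
    # run 0 shows sequence 1, run 1 shows sequence 0
    out = average_repeats(tensor, [1, 0], cfg, sequence_duration_s=100.0)
    assert np.allclose(out.window_center_s[:5], np.arange(5) * 2.0 + 16.0)
    assert np.allclose(out.window_center_s[5:], 100.0 + np.arange(5) * 2.0 + 16.0)
    assert np.allclose(out.values[:, :5], vals[:, 5:])  # sequence 0 from run 1
    assert list(out.run_index) == [0] * 5 + [1] * 5


def test_average_repeats_rejects_misaligned_grids(cfg, rng):
    vals = rng.uniform(0, 1, (3, 9))
    centers = np.concatenate([np.arange(5) * 2.0 + 16.0, 100.0 + np.arange(4) * 2.0 + 16.0])
    runs = np.concatenate([np.zeros(5, int), np.ones(4, int)])
    tensor = _tensor(vals, n_rois=3, centers=centers, runs=runs)
    with pytest.raises(ValidationError, match="misaligned"):
        average_repeats(tensor, [0, 0], cfg, sequence_duration_s=100.0)


def test_average_repeats_checks_run_count(cfg, rng):
    tensor = _tensor(rng.uniform(0, 1, (3, 5)), n_rois=3)
    with pytest.raises(ValidationError, match="entries"):
        average_repeats(tensor, [0, 1], cfg, sequence_duration_s=100.0)


# --------------------------------------------------------------------------
# summaries
# --------------------------------------------------------------------------

def test_network_summary_identical_edges_have_zero_variance(rng):
    tensor = _tensor(np.tile(rng.uniform(0, 1, 7), (3, 1)), n_rois=3)
    mean, var = network_summary(tensor)
    assert np.allclose(var, 0.0)


def test_network_summary_population_variance_convention():
    vals = np.array([[0.0], [0.0], [0.0], [1.0], [1.0], [1.0]])
    tensor = _tensor(vals, n_rois=4)
    mean, var = network_summary(tensor)
    assert mean[0] == 0.5 and var[0] == 0.25


def test_network_summary_matches_two_pass_oracle(rng):
    vals = rng.uniform(0, 1, (6, 11))
    tensor = _tensor(vals, n_rois=4)
    mean, var = network_summary(tensor)
    assert np.allclose(mean, vals.mean(axis=0), atol=1e-12)
    assert np.allclose(var, ((vals - vals.mean(axis=0)) ** 2).mean(axis=0), atol=1e-12)


# --------------------------------------------------------------------------
# state-specific networks
# --------------------------------------------------------------------------

def _block_events(block_s=40.0, total_s=800.0):
    import pandas as pd
    from socialsync.datatypes import EventTable

    rows = []
    t = 0.0
    cat = "blank"
    while t < total_s:
        rows.append((t, block_s, cat, "0"))
        cat = "nonsocial" if cat == "blank" else "blank"
        t += block_s
    return EventTable(
        pd.DataFrame(rows, columns=["onset_s", "duration_s", "category", "n_actors"])
    )


def test_window_categories_follow_majority_rule_with_lag(cfg):
    events = _block_events()
    W = 300
    tensor = _tensor(np.zeros((120, W)), n_rois=16)
    cats = assign_window_categories(tensor, events, cfg)
    assert set(cats) <= {"blank", "nonsocial", ""}
    # a window centred mid-block (plus hemodynamic lag) takes that block's label
    centers = tensor.window_center_s
    mid_blank = np.abs(centers - (20.0 + cfg.hemo_lag_s)) < 1e-9
    assert (cats[mid_blank] == "blank").all()
    mid_nonsoc = np.abs(centers - (60.0 + cfg.hemo_lag_s)) < 1e-9
    assert (cats[mid_nonsoc] == "nonsocial").all()


def test_blank_state_coupling_on_temporal_edges_recovered(cfg):
    roster_ = None
    from socialsync.synthetic import default_roster

    roster_ = default_roster()
    temporal = [k for k, g in enumerate(roster_.groups) if g == "temporal"]
    pairs = edge_index(16)
    tt = [e for e, (i, j) in enumerate(pairs) if i in temporal and j in temporal][:18]

    events = _block_events()
    W = 300
    vals = 0.2 + 0.001 * np.arange(120)[:, None] * np.ones((1, W))
    vals[tt] = 0.7
    tensor = _tensor(vals, n_rois=16)

    edge_means, net, props = state_network(tensor, events, {"blank"}, cfg, roster_)
    assert net.n_edges == 18
    assert sorted(np.flatnonzero(net.edge_mask())) == sorted(tt)
    # 100% of suprathreshold connections fall in temporo-temporal cells
    tt_rows = (props["lobe_a"] == "temporal") & (props["lobe_b"] == "temporal")
    assert props.loc[tt_rows, "fraction"].sum() == 1.0
    assert abs(props["fraction"].sum() - 1.0) < 1e-12


def test_state_network_rejects_empty_state(cfg):
    events = _block_events()
    tensor = _tensor(np.zeros((120, 50)), n_rois=16)
    with pytest.raises(ValidationError, match="state"):
        state_network(tensor, events, {"ambiguous"}, cfg)
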