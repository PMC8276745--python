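"""Tests of the synthetic study generator.

The generator is first-class code: these tests pin the stimulus-schedule
contract, the coupling model's monotonicity, the spectral signature of the
oscillators, and the behavioral/physiological confound statistics.
"""

import numpy as np
import pytest
from scipy.signal import find_peaks, periodogram
from scipy.stats import f_oneway

from socialsync import synchrony
from socialsync.datatypes import (
    CATEGORIES,
    SOCIAL_CATEGORIES,
    ValidationError,
    edge_index,
)
from socialsync.synthetic import (
    CLIP_TEMPLATE_S,
    DEFAULT_CATEGORY_MIX,
    DEFAULT_SUBJECT_FIXATION,
    N_SEQUENCES,
    SEQUENCE_DURATION_S,
    CouplingSpec,
    default_coupling_spec,
    default_roster,
    designated_edges,
    generate_confounds,
    generate_dataset,
    generate_schedule,
    generate_session,
    null_coupling_spec,
    sequence_events,
    session_events,
    simulate_bold,
    video_features,
)

# ---------------------------------------------------------------------------
# stimulus schedule
# ---------------------------------------------------------------------------


def test_schedule_structure(schedule):
    df = schedule.frame
    # four 220-s sequences of 5/10/20-s clips and 20-s blanks, end to end
    assert set(df.loc[df["category"] != "blank", "duration_s"]) <= {5.0, 10.0, 20.0}
    assert (df.loc[df["category"] == "blank", "duration_s"] == 20.0).all()
    for q in range(N_SEQUENCES):
        seq = sequence_events(schedule, q)
        assert seq["duration_s"].sum() == SEQUENCE_DURATION_S
        # contiguous: each clip starts where the previous one ended
        ends = (seq["onset_s"] + seq["duration_s"]).to_numpy()
        assert np.allclose(ends[:-1], seq["onset_s"].to_numpy()[1:])
        assert (seq["category"] == "blank").sum() == 3
        assert len(seq) == len(CLIP_TEMPLATE_S) + 3
    assert ((df["onset_s"] + df["duration_s"]) <= 880.0 + 1e-9).all()


def test_schedule_category_shares_near_mix(schedule):
    df = schedule.frame
    clips = df[df["category"] != "blank"]
    total = clips["duration_s"].sum()
    for cat, target in DEFAULT_CATEGORY_MIX.items():
        share = clips.loc[clips["category"] == cat, "duration_s"].sum() / total
        assert abs(share - target) <= 0.03, (cat, share)


def test_schedule_social_pair_coverage(schedule):
    seen = set()
    for q in range(N_SEQUENCES):
        seq = sequence_events(schedule, q)
        social = [c for c in seq["category"] if c in SOCIAL_CATEGORIES]
        seen.update(zip(social[:-1], social[1:]))
    assert seen >= {(a, b) for a in SOCIAL_CATEGORIES for b in SOCIAL_CATEGORIES}


def test_schedule_long_clips_per_social_category(schedule):
    df = schedule.frame
    for cat in SOCIAL_CATEGORIES:
        n_long = ((df["category"] == cat) & (df["duration_s"] == 20.0)).sum()
        assert n_long >= 4, cat


def test_schedule_n_actors_consistent(schedule):
    expect = {
        "aggressive": "2+", "affiliative": "2+", "ambiguous": "2+",
        "single_actor": "1", "nonsocial": "0", "unclassified": "2+", "blank": "0",
    }
    for row in schedule.frame.itertuples(index=False):
        assert row.n_actors == expect[row.category]


def test_schedule_deterministic(config, schedule):
    again = generate_schedule(config, seed=7)
    assert schedule.frame.equals(again.frame)


def test_schedule_blank_only_mode(config):
    sched = generate_schedule(config, seed=1, mix={"blank": 1.0})
    df = sched.frame
    assert (df["category"] == "blank").all()
    assert df["duration_s"].sum() == N_SEQUENCES * SEQUENCE_DURATION_S


def test_schedule_infeasible_mix_rejected(config):
    with pytest.raises(ValidationError, match="mix"):
        generate_schedule(config, seed=1, mix={"aggressive": 0.5, "nope": 0.5})
    with pytest.raises(ValidationError, match="mix"):
        generate_schedule(config, seed=1, mix={"aggressive": 0.2, "affiliative": 0.2})
    with pytest.raises(ValidationError, match="tolerance"):
        # feasible shares but an impossible tolerance
        generate_schedule(config, seed=1, tolerance=0.0)


# ---------------------------------------------------------------------------
# coupling spec validation
# ---------------------------------------------------------------------------


def test_designated_edges_are_cingulate_temporal_and_temporo_temporal():
    roster = default_roster()
    edges = designated_edges(roster)
    assert len(edges) == 18
    assert len(set(edges)) == 18
    kinds = {tuple(sorted((roster.groups[i], roster.groups[j]))) for i, j in edges}
    assert kinds == {("temporal", "temporal"), ("cingulate", "temporal")}


def test_coupling_spec_rejects_budget_violation():
    with pytest.raises(ValidationError, match="kappa"):
        CouplingSpec(baseline_coupling=0.7, condition_boost={"ambiguous": 0.4})
    with pytest.raises(ValidationError, match="baseline_coupling"):
        CouplingSpec(baseline_coupling=1.2)
    with pytest.raises(ValidationError, match="condition"):
        CouplingSpec(condition_boost={"scrambled": 0.2})
    with pytest.raises(ValidationError, match="amplitude"):
        CouplingSpec(base_freqs_hz=(0.02, 0.04), freq_amplitudes=(1.0,))


def test_coupling_spec_band_validation(config):
    spec = CouplingSpec(base_freqs_hz=(0.3,), freq_amplitudes=(1.0,))
    with pytest.raises(ValidationError, match="band"):
        spec.validate_band(config)


def test_simulate_rejects_foreign_edge(config, roster, schedule):
    spec = default_coupling_spec(roster)
    spec.designated_edges = [(0, 99)]
    with pytest.raises(ValidationError, match="edge"):
        simulate_bold(schedule, roster, spec, config, seed=1)


# ---------------------------------------------------------------------------
# BOLD coupling model
# ---------------------------------------------------------------------------


def _plv(ts, config):
    phases = synchrony.instantaneous_phase(ts, config)
    return synchrony.windowed_synchrony(phases, config)


def test_full_coupling_gives_unit_synchrony(config, roster, schedule):
    spec = null_coupling_spec(roster)
    spec.baseline_coupling = 1.0
    spec.noise_sd = 0.0
    spec.drive_amplitude = 0.0
    ts, _ = simulate_bold(schedule, roster, spec, config, seed=4)
    tensor = _plv(ts, config)
    assert tensor.values.min() > 1.0 - 1e-6


def test_no_coupling_matches_noise_floor_oracle(config, roster, schedule):
    # kappa = 0, noise only. The floor for 16-volume windows of analytic-signal
    # phases sits above the iid-phase value sqrt(pi/64) ~ 0.2216 because the
    # Hilbert transform correlates neighbouring phasors (lag-1 correlation
    # 2/pi for white noise); the oracle below reproduces the whole chain
    # independently (numpy noise, scipy filtfilt+hilbert, direct |mean phasor|).
    from scipy.signal import butter, filtfilt, hilbert

    spec = null_coupling_spec(roster)
    spec.baseline_coupling = 0.0
    spec.freq_amplitudes = (0.0, 0.0)
    spec.drive_amplitude = 0.0
    ts, _ = simulate_bold(schedule, roster, spec, config, seed=5)
    tensor = _plv(ts, config)
    assert tensor.n_windows * tensor.n_edges > 1000

    rng = np.random.default_rng(99)
    fs = 1.0 / config.tr_s
    b, a = butter(
        4, [config.band_lo_hz, min(config.band_hi_hz, 0.99 * fs / 2)],
        btype="band", fs=fs,
    )
    means = []
    for _ in range(400):
        x = filtfilt(b, a, rng.normal(size=(110, 2)), axis=0)
        ph = np.angle(hilbert(x, axis=0))
        d = ph[:, 0] - ph[:, 1]
        means.extend(
            np.abs(np.mean(np.exp(1j * d[s : s + 16]))) for s in range(0, 95, 16)
        )
    oracle = float(np.mean(means))
    assert abs(tensor.values.mean() - oracle) < 0.03


def test_expected_synchrony_monotone_in_kappa(config, roster, schedule):
    # >= 200 windows per grid point (4 runs -> 380 windows)
    means = []
    for kappa in (0.0, 0.25, 0.5, 0.75, 1.0):
        spec = null_coupling_spec(roster)
        spec.baseline_coupling = kappa
        ts, _ = simulate_bold(schedule, roster, spec, config, seed=6)
        tensor = _plv(ts, config)
        assert tensor.n_windows >= 200
        means.append(tensor.values.mean())
    assert all(b >= a - 1e-3 for a, b in zip(means, means[1:])), means
    assert means[-1] > means[0] + 0.3


def test_simulation_deterministic(config, roster, schedule):
    spec = default_coupling_spec(roster)
    a, _ = simulate_bold(schedule, roster, spec, config, seed=8)
    b, _ = simulate_bold(schedule, roster, spec, config, seed=8)
    assert np.array_equal(a.values, b.values)


def test_default_spectrum_peaks_at_base_frequencies(config, roster, schedule):
    # top-2 spectral peaks of every ROI at 0.02 and 0.04 Hz: per-run
    # zero-padded periodograms summed over a session and Daniell-smoothed
    spec = default_coupling_spec(roster)
    ts, _ = simulate_bold(
        schedule, roster, spec, config, seed=9, run_sequences=list(range(4)) * 4
    )
    n_vol = 110
    for k in range(len(roster)):
        acc = None
        for r in range(16):
            x = ts.values[r * n_vol : (r + 1) * n_vol, k]
            freqs, power = periodogram(x - x.mean(), fs=1.0 / config.tr_s, nfft=880)
            acc = power if acc is None else acc + power
        smooth = np.convolve(acc, np.ones(5) / 5, mode="same")
        peaks, _ = find_peaks(smooth)
        top2 = sorted(freqs[peaks[np.argsort(smooth[peaks])[-2:]]])
        assert abs(top2[0] - 0.02) < 0.005, (k, top2)
        assert abs(top2[1] - 0.04) < 0.005, (k, top2)


# ---------------------------------------------------------------------------
# confounds
# ---------------------------------------------------------------------------


def _clip_feature_means(schedule, config, series_by_seq, category):
    """Per-clip mean of a frame-level feature for one category."""
    fps = config.behavior_rate_hz
    out = []
    for q in range(N_SEQUENCES):
        seq = sequence_events(schedule, q)
        for row in seq[seq["category"] == category].itertuples(index=False):
            lo = int(round(row.onset_s * fps))
            hi = int(round((row.onset_s + row.duration_s) * fps))
            out.append(series_by_seq[q][lo:hi].mean())
    return out


def test_zero_separation_hides_luminance_condition_effect(config, schedule):
    hidden = 0
    for seed in range(8):
        lum, _ = video_features(schedule, config, seed, feature_separation=0.0)
        groups = [
            _clip_feature_means(schedule, config, lum, cat)
            for cat in SOCIAL_CATEGORIES
        ]
        hidden += f_oneway(*groups).pvalue > 0.05
    assert hidden >= 6


def test_default_separation_shows_feature_condition_effects(config, schedule):
    shown = [cat for cat in CATEGORIES if cat != "blank"]
    # default separation: motion energy differs across behaviour classes
    _, mot = video_features(schedule, config, seed=3)
    groups = [_clip_feature_means(schedule, config, mot, cat) for cat in shown]
    assert f_oneway(*groups).pvalue < 0.05
    # direction: aggressive clips are the most motion-rich social clips
    agg = np.mean(_clip_feature_means(schedule, config, mot, "aggressive"))
    aff = np.mean(_clip_feature_means(schedule, config, mot, "affiliative"))
    assert agg > aff
    # the knob scales up to a clearly detectable luminance effect too
    lum, _ = video_features(schedule, config, seed=3, feature_separation=1.0)
    groups = [_clip_feature_means(schedule, config, lum, cat) for cat in shown]
    assert f_oneway(*groups).pvalue < 0.05


def test_fixation_tracks_subject_mean(config, schedule):
    rng = np.random.default_rng(12)
    means = [
        generate_confounds(
            schedule, config, rng, subject_fixation_mean=0.62
        ).fixation_frac.mean()
        for _ in range(20)
    ]
    assert abs(np.mean(means) - 0.62) < 0.03
    assert sum(abs(m - 0.62) <= 0.08 for m in means) >= 17


def test_reward_pulses_only_during_maintained_fixation(config, schedule):
    conf = generate_confounds(schedule, config, seed=13)
    vols = (conf.reward_times_s // config.tr_s).astype(int)
    assert len(vols) > 0
    assert (conf.fixation_frac[vols] >= config.fixation_min_frac).all()


def test_gaze_bounded_and_csf_smooth(config, schedule):
    conf = generate_confounds(schedule, config, seed=14)
    assert np.abs(conf.gaze_xy).max() <= 6.5
    csf = conf.csf
    r1 = np.corrcoef(csf[:-1], csf[1:])[0, 1]
    assert r1 > 0.5  # low-frequency, not white


def test_confounds_deterministic(config, schedule):
    a = generate_confounds(schedule, config, seed=15)
    b = generate_confounds(schedule, config, seed=15)
    assert np.array_equal(a.fixation_frac, b.fixation_frac)
    assert np.array_equal(a.reward_times_s, b.reward_times_s)


# ---------------------------------------------------------------------------
# sessions and datasets
# ---------------------------------------------------------------------------


def test_session_bundle_consistency(session_bundle, config):
    n_vol = session_bundle.timeseries.n_volumes
    assert n_vol == len(session_bundle.run_sequences) * 110
    assert session_bundle.confounds.n_volumes == n_vol
    # session events replay the schedule in presentation order
    ev = session_events(
        generate_schedule(config, seed=7), session_bundle.run_sequences
    )
    assert ev.frame.equals(session_bundle.events.frame)
    assert session_bundle.events.frame["onset_s"].is_monotonic_increasing


def test_dataset_layout_and_counterbalancing(config):
    ds = generate_dataset(config, seed=30, sessions_per_subject=3, n_repeats=2)
    assert len(ds.sessions) == 9
    assert list(ds.meta["subject"].unique()) == ["M1", "M2", "M3"]
    orders = []
    for s in ds.sessions:
        # every sequence appears exactly n_repeats times, in repeat blocks
        assert sorted(s.run_sequences) == sorted(list(range(N_SEQUENCES)) * 2)
        for block in (s.run_sequences[:4], s.run_sequences[4:]):
            assert sorted(block) == list(range(N_SEQUENCES))
        orders.append(tuple(s.run_sequences))
    assert len(set(orders)) > 1  # orders differ across sessions


def test_dataset_shares_stimulus_features(config):
    ds = generate_dataset(config, seed=31, sessions_per_subject=1, n_repeats=1)
    fps = config.behavior_rate_hz
    frames_per_run = int(SEQUENCE_DURATION_S * fps)
    a, b = ds.sessions[0], ds.sessions[1]
    qa, qb = a.run_sequences.index(0), b.run_sequences.index(0)
    lum_a = a.confounds.luminance[qa * frames_per_run : (qa + 1) * frames_per_run]
    lum_b = b.confounds.luminance[qb * frames_per_run : (qb + 1) * frames_per_run]
    assert np.array_equal(lum_a, lum_b)


def test_dataset_deterministic(config):
    a = generate_dataset(config, seed=32, sessions_per_subject=1, n_repeats=1)
    b = generate_dataset(config, seed=32, sessions_per_subject=1, n_repeats=1)
    for sa, sb in zip(a.sessions, b.sessions):
        assert np.array_equal(sa.timeseries.values, sb.timeseries.values)
        assert sa.run_sequences == sb.run_sequences


def test_subject_fixation_defaults_applied(config):
    ds = generate_dataset(config, seed=33, sessions_per_subject=4, n_repeats=1)
    by_subj = {}
    for s in ds.sessions:
        by_subj.setdefault(s.subject_id, []).append(s.confounds.fixation_frac.mean())
    for subj, target in DEFAULT_SUBJECT_FIXATION.items():
        assert abs(np.mean(by_subj[subj]) - target) < 0.08, subj
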