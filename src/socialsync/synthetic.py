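"""Synthetic naturalistic-viewing fMRI sessions with known phase coupling.

The generator emulates the experimental design the pipeline targets: four 220-s
video sequences (16 clips of 5/10/20 s interleaved with 20-s blanks, 880 s
of unique content), three social behavior categories plus single-actor,
nonsocial and unclassified content, three subjects with twelve sessions
each, and ROI BOLD whose spectrum peaks at 0.02 and 0.04 Hz.

Coupling model: each ROI's oscillatory phase at each base frequency is the
circular blend (argument of a weighted phasor sum) of a network-shared
oscillator (weight = baseline coupling), one shared oscillator per
designated edge the ROI touches (weight = condition boost x the
HRF-convolved condition envelope), and a private oscillator (the
remainder). Expected windowed phase synchrony on an edge rises
monotonically with the blend weight of that edge's shared oscillator, which
gives closed-loop control over which edges are socially modulated, without
integrating a coupled-oscillator ODE.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .datatypes import (
    CATEGORIES,
    ConfoundBundle,
    EventTable,
    ROIRoster,
    ROITimeSeries,
    SOCIAL_CATEGORIES,
    ValidationError,
    edge_index,
)
from .regressors import gamma_hrf

#: Time share of each clip category, as fractions of non-blank content.
DEFAULT_CATEGORY_MIX = {
    "aggressive": 0.15,
    "affiliative": 0.16,
    "ambiguous": 0.14,
    "single_actor": 0.14,
    "nonsocial": 0.18,
    "unclassified": 0.23,
}

_N_ACTORS_OF = {
    "aggressive": "2+",
    "affiliative": "2+",
    "ambiguous": "2+",
    "single_actor": "1",
    "nonsocial": "0",
    "unclassified": "2+",
    "blank": "0",
}

SEQUENCE_DURATION_S = 220.0
N_SEQUENCES = 4
#: Per-sequence clip-duration template: 16 clips summing to 160 s, plus
#: three 20-s blanks -> 220 s.
CLIP_TEMPLATE_S = (5,) * 8 + (10,) * 4 + (20,) * 4

#: Per-subject session-average fixation fractions the generator emulates.
DEFAULT_SUBJECT_FIXATION = {"M1": 0.90, "M2": 0.89, "M3": 0.62}

#: Category offsets for frame luminance (level) and motion energy (rate),
#: scaled by the ``feature_separation`` knob.
_LUMINANCE_OFFSET = {
    "aggressive": 0.08, "affiliative": -0.06, "ambiguous": 0.02,
    "single_actor": 0.0, "nonsocial": 0.04, "unclassified": -0.03,
}
_MOTION_OFFSET = {
    "aggressive": 0.8, "affiliative": -0.3, "ambiguous": 0.1,
    "single_actor": -0.1, "nonsocial": 0.2, "unclassified": 0.0,
}


def default_roster() -> ROIRoster:
    """Synthetic 16-ROI social-network roster (8 per hemisphere).

    Stands in for a macaque social-brain network of temporal, cingulate, premotor and
    prefrontal sphere centres; coordinates are schematic, not stereotaxic.
    """
    rois = [
        ("aSTS_L", "left", "temporal"), ("aSTS_R", "right", "temporal"),
        ("mSTS_L", "left", "temporal"), ("mSTS_R", "right", "temporal"),
        ("pSTS_L", "left", "temporal"), ("pSTS_R", "right", "temporal"),
        ("V4_L", "left", "temporal"), ("V4_R", "right", "temporal"),
        ("ACCg_L", "left", "cingulate"), ("ACCg_R", "right", "cingulate"),
        ("MCC_L", "left", "cingulate"), ("MCC_R", "right", "cingulate"),
        ("PMv_L", "left", "premotor"), ("PMv_R", "right", "premotor"),
        ("dlPFC_L", "left", "other"), ("dlPFC_R", "right", "other"),
    ]
    coords = np.array(
        [[(-1 if h == "left" else 1) * 20.0, -10.0 + 4.0 * k, 5.0 + 2.0 * k]
         for k, (_, h, _) in enumerate(rois)]
    )
    return ROIRoster(
        labels=[r[0] for r in rois],
        hemispheres=[r[1] for r in rois],
        groups=[r[2] for r in rois],
        coords_mm=coords,
    )


def designated_edges(roster: ROIRoster) -> list[tuple[int, int]]:
    """18 cingulate-temporal / temporo-temporal edges carrying the boost.

    Six temporo-temporal and twelve cingulate-temporal pairs, chosen
    deterministically with near-uniform node degrees (36 edge-ends over 12
    nodes; degrees 2-4, almost all 3). Near-equal degrees give every
    designated edge a similar per-node coupling-budget share, so no edge's
    boost is diluted much more than another's.
    """
    temporal = [k for k, g in enumerate(roster.groups) if g == "temporal"]
    cingulate = [k for k, g in enumerate(roster.groups) if g == "cingulate"]
    # a 6-cycle over six temporal ROIs (temporo-temporal degree 2 each) ...
    tt_cycle = [0, 2, 4, 1, 3, 5]
    tt = [
        (temporal[a], temporal[b]) for a, b in zip(tt_cycle, tt_cycle[1:] + tt_cycle[:1])
    ]
    # ... and three temporal partners per cingulate ROI. The cingulate load
    # falls mostly on the two temporal ROIs outside the cycle, so cycle
    # members keep designated-subgraph degree 2-3 (one hub reaches 4) and
    # every edge retains a sizeable per-node coupling-budget share.
    ct = [
        (cingulate[a], temporal[b])
        for a, b in [
            (0, 6), (0, 7), (0, 0),
            (1, 6), (1, 7), (1, 1),
            (2, 6), (2, 7), (2, 2),
            (3, 6), (3, 3), (3, 4),
        ]
    ]
    return sorted(tuple(sorted(e)) for e in tt + ct)


@dataclass
class CouplingSpec:
    """Ground-truth phase-coupling structure of a synthetic dataset."""

    base_freqs_hz: tuple[float, ...] = (0.02, 0.04)
    freq_amplitudes: tuple[float, ...] = (1.0, 0.7)
    baseline_coupling: float = 0.40
    condition_boost: dict[str, float] = field(default_factory=lambda: {"ambiguous": 0.4})
    designated_edges: list[tuple[int, int]] = field(default_factory=list)
    #: Measurement noise keeps window-level synchrony estimates in the
    #: responsive (non-saturated) part of the PLV curve.
    noise_sd: float = 0.2
    #: Stimulus-locked drive is kept weak: a strong common drive inflates
    #: synchrony on every edge at once and distorts null calibration.
    drive_amplitude: float = 0.05
    #: Phase diffusion (rad/volume) of the shared oscillators: small, so the
    #: 0.02 / 0.04 Hz spectral lines stay sharp across a whole session.
    phase_jitter_rad: float = 0.05
    #: Phase diffusion of each node's private and edge oscillators: large, so
    #: that uncoupled node pairs decohere within one analysis window (private
    #: content forms a broadband background rather than a shared line) and so
    #: that windowed synchrony averages over many independent phase
    #: configurations per window, keeping its sampling variance low.
    private_jitter_rad: float = 4.5

    def __post_init__(self) -> None:
        if not 0 <= self.baseline_coupling <= 1:
            raise ValidationError("baseline_coupling must lie in [0, 1]")
        for cond, dk in self.condition_boost.items():
            if cond not in CATEGORIES:
                raise ValidationError(f"unknown boost condition {cond!r}")
            if dk < 0 or self.baseline_coupling + dk > 1:
                raise ValidationError(
                    f"boost for {cond!r} violates kappa0 + dkappa <= 1"
                )
        if len(self.base_freqs_hz) != len(self.freq_amplitudes):
            raise ValidationError("one amplitude per base frequency required")
        self.designated_edges = [tuple(sorted(e)) for e in self.designated_edges]

    def validate_band(self, config: PipelineConfig) -> None:
        hi = min(config.band_hi_hz, config.nyquist_hz)
        for f in self.base_freqs_hz:
            if not config.band_lo_hz < f < hi:
                raise ValidationError(
                    f"base frequency {f} Hz outside the analysis band "
                    f"({config.band_lo_hz}, {hi}) Hz"
                )


def default_coupling_spec(roster: ROIRoster | None = None) -> CouplingSpec:
    roster = roster or default_roster()
    return CouplingSpec(designated_edges=designated_edges(roster))


def null_coupling_spec(roster: ROIRoster | None = None) -> CouplingSpec:
    """Baseline coupling only: no condition modulates any edge."""
    spec = default_coupling_spec(roster)
    spec.condition_boost = {}
    return spec


# --------------------------------------------------------------------------
# stimulus schedule
# --------------------------------------------------------------------------

def _social_pair_coverage(categories_by_seq: list[list[str]]) -> bool:
    """Do all 9 ordered pairs of social categories occur between successive
    social clips (skipping non-social clips) somewhere in the schedule?"""
    seen = set()
    for seq in categories_by_seq:
        social = [c for c in seq if c in SOCIAL_CATEGORIES]
        seen.update(zip(social[:-1], social[1:]))
    want = {(a, b) for a in SOCIAL_CATEGORIES for b in SOCIAL_CATEGORIES}
    return want <= seen


def generate_schedule(
    config: PipelineConfig,
    seed: int | np.random.Generator,
    mix: dict[str, float] | None = None,
    tolerance: float = 0.03,
    long_clips_per_social: int = 4,
) -> EventTable:
    """Pseudo-random 880-s stimulus schedule on the unique-content clock.

    Four 220-s sequences, each 16 clips (5/10/20 s) and three 20-s blanks.
    Clip categories are drawn so that each category's share of non-blank
    time is within ``tolerance`` of the requested mix, so that every
    ordered pair of social categories occurs between successive social
    clips, and so that each social category receives at least
    ``long_clips_per_social`` of the longest clips (social conditions must
    be observable at the multi-volume window scale, not only in brief
    snippets). Deterministic given the seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mix = dict(DEFAULT_CATEGORY_MIX) if mix is None else dict(mix)

    if set(mix) == {"blank"}:
        rows = []
        for q in range(N_SEQUENCES):
            t = q * SEQUENCE_DURATION_S
            while t < (q + 1) * SEQUENCE_DURATION_S - 1e-9:
                rows.append((t, 20.0, "blank", "0"))
                t += 20.0
        return EventTable(pd.DataFrame(rows, columns=["onset_s", "duration_s", "category", "n_actors"]))

    bad = sorted(set(mix) - set(DEFAULT_CATEGORY_MIX))
    if bad or abs(sum(mix.values()) - 1.0) > 1e-6 or min(mix.values()) < 0:
        raise ValidationError(f"infeasible category mix: {mix}")

    durations = np.array(CLIP_TEMPLATE_S * N_SEQUENCES, dtype=float)
    total_clip_s = durations.sum()
    cats = sorted(mix)
    targets = {c: mix[c] * total_clip_s for c in cats}

    longest = durations.max()
    for attempt in range(500):
        # assign categories: longest clips first, to the largest deficit,
        # with a quota of long clips reserved for each social category
        order = np.argsort(-durations + 1e-3 * rng.random(len(durations)))
        remaining = dict(targets)
        # Each social category receives exactly ``long_clips_per_social`` of
        # the longest clips (when its share affords them): at the 32-s window
        # scale only long clips yield majority-assignable windows, so equal
        # long-clip counts give the three social conditions equal effective
        # sample sizes (balanced condition variances in the session means).
        quota = {
            c: min(long_clips_per_social, int(targets[c] // longest))
            for c in SOCIAL_CATEGORIES
            if mix.get(c, 0) > 0
        }
        assigned = np.empty(len(durations), dtype=object)
        for idx in order:
            owed = [c for c, k in quota.items() if k > 0]
            if durations[idx] == longest and owed:
                cat = max(owed, key=lambda c: remaining[c])
                quota[cat] -= 1
            elif durations[idx] == longest:
                # social categories are capped at their long-clip quota
                pool_cats = [c for c in remaining if c not in SOCIAL_CATEGORIES]
                cat = max(pool_cats or remaining, key=lambda c: remaining[c])
            else:
                cat = max(remaining, key=lambda c: remaining[c])
            assigned[idx] = cat
            remaining[cat] -= durations[idx]
        shares = {
            c: durations[assigned == c].sum() / total_clip_s for c in cats
        }
        if any(abs(shares[c] - mix[c]) > tolerance for c in cats):
            continue

        # distribute clips to sequences, keeping category-duration pairs intact
        pool = {d: list(assigned[durations == d]) for d in set(CLIP_TEMPLATE_S)}
        for d in pool:
            rng.shuffle(pool[d])
        seq_items = []
        ok = True
        for q in range(N_SEQUENCES):
            items = [(pool[d].pop(), float(d)) for d in CLIP_TEMPLATE_S]
            # Social clips are never adjacent: every pair of social clips is
            # separated by at least one non-social clip. This keeps the
            # analysis windows of different social conditions from sharing
            # volumes, so their per-condition means stay uncorrelated (the
            # pseudo-random sequences of real experiments interleave content
            # similarly).
            # Ordered-pair coverage is defined on the social subsequence and
            # is unaffected.
            social = [it for it in items if it[0] in SOCIAL_CATEGORIES]
            non_social = [it for it in items if it[0] not in SOCIAL_CATEGORIES]
            if len(social) > len(non_social) + 1:
                ok = False
                break
            rng.shuffle(social)
            rng.shuffle(non_social)
            gaps = sorted(
                rng.choice(len(non_social) + 1, size=len(social), replace=False)
            )
            arranged: list[tuple[str, float]] = []
            for g, it in zip(gaps, social):
                while len(arranged) - sum(
                    1 for a in arranged if a[0] in SOCIAL_CATEGORIES
                ) < g:
                    arranged.append(non_social.pop())
                arranged.append(it)
            arranged.extend(non_social)
            seq_items.append(arranged)
        if not ok:
            continue
        if not _social_pair_coverage([[c for c, _ in items] for items in seq_items]):
            continue

        rows = []
        for q, items in enumerate(seq_items):
            items = list(items)
            # Every sequence opens and closes with a blank (the usual rest
            # bracket of an fMRI run); the third blank falls in the interior.
            # Bracketing also keeps every clip clear of the run boundaries,
            # where analysis windows would be truncated and a condition
            # could lose part of its effective sample.
            blank_slots = [0, int(rng.integers(1, len(items))), len(items)]
            for k, slot in enumerate(sorted(blank_slots)):
                items.insert(slot + k, ("blank", 20.0))
            t = q * SEQUENCE_DURATION_S
            for cat, dur in items:
                rows.append((t, dur, cat, _N_ACTORS_OF[cat]))
                t += dur
        return EventTable(
            pd.DataFrame(rows, columns=["onset_s", "duration_s", "category", "n_actors"])
        )
    raise ValidationError(
        f"could not satisfy category mix {mix} within tolerance {tolerance}"
    )


def sequence_events(schedule: EventTable, q: int) -> pd.DataFrame:
    """Events of sequence ``q``, onsets relative to the sequence start."""
    lo, hi = q * SEQUENCE_DURATION_S, (q + 1) * SEQUENCE_DURATION_S
    sub = schedule.frame[(schedule.frame["onset_s"] >= lo - 1e-9) & (schedule.frame["onset_s"] < hi - 1e-9)].copy()
    sub["onset_s"] = sub["onset_s"] - lo
    return sub


def session_events(schedule: EventTable, run_sequences: list[int]) -> EventTable:
    """Schedule replayed on the session clock, one sequence per run."""
    rows = []
    for r, q in enumerate(run_sequences):
        sub = sequence_events(schedule, q)
        offset = r * SEQUENCE_DURATION_S
        for row in sub.itertuples(index=False):
            rows.append((row.onset_s + offset, row.duration_s, row.category, row.n_actors))
    return EventTable(pd.DataFrame(rows, columns=["onset_s", "duration_s", "category", "n_actors"]))


# --------------------------------------------------------------------------
# BOLD simulation
# --------------------------------------------------------------------------

def _condition_envelopes(
    seq_frame: pd.DataFrame, conditions: list[str], n_vol: int, config: PipelineConfig
) -> dict[str, np.ndarray]:
    """HRF-convolved 0/1 envelope per condition on one run's volume grid."""
    mid = (np.arange(n_vol) + 0.5) * config.tr_s
    kernel = gamma_hrf(config)
    out = {}
    for cond in conditions:
        ind = np.zeros(n_vol)
        for row in seq_frame[seq_frame["category"] == cond].itertuples(index=False):
            m = (mid >= row.onset_s) & (mid < row.onset_s + row.duration_s)
            ind[m] = 1.0
        out[cond] = np.clip(np.convolve(ind, kernel)[:n_vol], 0.0, 1.0)
    return out


def _video_on_envelope(seq_frame: pd.DataFrame, n_vol: int, config: PipelineConfig) -> np.ndarray:
    mid = (np.arange(n_vol) + 0.5) * config.tr_s
    ind = np.zeros(n_vol)
    for row in seq_frame[seq_frame["category"] != "blank"].itertuples(index=False):
        m = (mid >= row.onset_s) & (mid < row.onset_s + row.duration_s)
        ind[m] = 1.0
    kernel = gamma_hrf(config)
    return np.convolve(ind, kernel)[:n_vol]


def _phase_walk(rng: np.random.Generator, n: int, freq_hz: float, tr_s: float, jitter: float) -> np.ndarray:
    theta0 = rng.uniform(-np.pi, np.pi)
    drift = 2 * np.pi * freq_hz * np.arange(n) * tr_s
    walk = np.cumsum(rng.normal(0.0, jitter, size=n))
    return theta0 + drift + walk


def simulate_bold(
    schedule: EventTable,
    roster: ROIRoster,
    spec: CouplingSpec,
    config: PipelineConfig,
    seed: int | np.random.Generator,
    run_sequences: list[int] | None = None,
    envelope_cache: dict | None = None,
) -> tuple[ROITimeSeries, dict]:
    """Simulate session ROI BOLD with the specified phase-coupling truth.

    Each run views one video sequence. Per run, base frequency and ROI, the
    phase is the argument of: baseline_coupling x shared phasor +
    (1 - baseline_coupling) x R, where R is the unit-normalised resultant of
    the ROI's private phasor and, for each designated edge at the ROI, that
    edge's shared phasor weighted by boost(t) — the condition boost scaled
    by the HRF-convolved condition envelope (edge weights beyond the unit
    budget are scaled down proportionally). The ROI signal sums the
    per-frequency cosines, an HRF-convolved video-on drive, and white noise.
    Returns the time series and a truth dict with the per-run condition
    envelopes.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    spec.validate_band(config)
    if run_sequences is None:
        run_sequences = list(range(N_SEQUENCES))
    n_rois = len(roster)
    pairs = edge_index(n_rois)
    for e in spec.designated_edges:
        if tuple(e) not in pairs:
            raise ValidationError(f"designated edge {e} not valid for this roster")
    n_vol_run = int(round(SEQUENCE_DURATION_S / config.tr_s))
    conds = sorted(spec.condition_boost)
    kappa0 = spec.baseline_coupling

    values = np.empty((n_vol_run * len(run_sequences), n_rois))
    run_starts = [r * n_vol_run for r in range(len(run_sequences))]
    cache = envelope_cache if envelope_cache is not None else {}
    envelopes: list[dict[str, np.ndarray]] = []
    for r, q in enumerate(run_sequences):
        key = (q, tuple(conds))
        if key not in cache:
            seq = sequence_events(schedule, q)
            cache[key] = (
                _condition_envelopes(seq, conds, n_vol_run, config),
                _video_on_envelope(seq, n_vol_run, config),
            )
        env, video_env = cache[key]
        envelopes.append(env)
        boost = np.zeros(n_vol_run)
        for cond in conds:
            boost = boost + spec.condition_boost[cond] * env[cond]

        # Coupling is common-phase mixing: each node's non-shared phase
        # content is a circular blend of a private phasor and, per designated
        # edge at the node, that edge's shared phasor. At full boost the edge
        # phasor holds the fraction boost(t) of the node's *total* phase
        # content -- commensurate with kappa0, per kappa0 + dkappa <= 1 -- so
        # its weight inside the (1 - kappa0) resultant is boost / (1 - kappa0).
        # The resultant is renormalised to unit magnitude before entering the
        # node blend, so a node's composition (kappa0 x shared phasor +
        # (1 - kappa0) x unit phasor) is identical whether or not it is
        # boosted -- boosting alters only the pairwise dependence between the
        # two endpoints, not any node's marginal signal law to first order.
        # A node's blend weights must stay a convex combination: edge demands
        # beyond the unit budget are scaled down proportionally.
        edge_w = boost / (1.0 - kappa0) if kappa0 < 1.0 else np.zeros_like(boost)
        demand = np.zeros((n_vol_run, n_rois))
        for (i, j) in spec.designated_edges:
            demand[:, i] += edge_w
            demand[:, j] += edge_w
        with np.errstate(divide="ignore", invalid="ignore"):
            scale = np.where(demand > 1.0, 1.0 / np.maximum(demand, 1e-30), 1.0)

        signal = np.zeros((n_vol_run, n_rois))
        for f, amp in zip(spec.base_freqs_hz, spec.freq_amplitudes):
            shared = np.exp(1j * _phase_walk(rng, n_vol_run, f, config.tr_s, spec.phase_jitter_rad))
            priv = np.exp(
                1j
                * np.stack(
                    [
                        _phase_walk(rng, n_vol_run, f, config.tr_s, spec.private_jitter_rad)
                        for _ in range(n_rois)
                    ],
                    axis=1,
                )
            )
            resultant = (1.0 - demand * scale) * priv
            for (i, j) in spec.designated_edges:
                edge_ph = np.exp(
                    1j * _phase_walk(rng, n_vol_run, f, config.tr_s, spec.private_jitter_rad)
                )
                resultant[:, i] += edge_w * scale[:, i] * edge_ph
                resultant[:, j] += edge_w * scale[:, j] * edge_ph
            mag = np.abs(resultant)
            resultant = np.where(mag > 1e-12, resultant / np.maximum(mag, 1e-12), priv)
            z = kappa0 * shared[:, None] + (1.0 - kappa0) * resultant
            signal += amp * np.cos(np.angle(z))

        drive = spec.drive_amplitude * video_env
        noise = spec.noise_sd * rng.normal(size=(n_vol_run, n_rois))
        values[r * n_vol_run : (r + 1) * n_vol_run] = signal + drive[:, None] + noise

    ts = ROITimeSeries(
        values=values, tr_s=config.tr_s, roi_labels=list(roster.labels), run_starts=run_starts
    )
    truth = {
        "designated_edges": list(spec.designated_edges),
        "condition_boost": dict(spec.condition_boost),
        "baseline_coupling": kappa0,
        "envelopes": envelopes,
    }
    return ts, truth


# --------------------------------------------------------------------------
# confounds
# --------------------------------------------------------------------------

def video_features(
    schedule: EventTable,
    config: PipelineConfig,
    seed: int | np.random.Generator,
    feature_separation: float = 0.15,
) -> tuple[np.ndarray, np.ndarray]:
    """Frame-level luminance and motion-energy series per unique sequence.

    Category-specific means (scaled by ``feature_separation``; zero makes
    all categories indistinguishable) plus smooth noise. Returns two arrays
    of shape (N_SEQUENCES, frames_per_sequence).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fps = config.behavior_rate_hz
    n_frames = int(round(SEQUENCE_DURATION_S * fps))
    lum = np.zeros((N_SEQUENCES, n_frames))
    mot = np.zeros((N_SEQUENCES, n_frames))
    t = (np.arange(n_frames) + 0.5) / fps
    for q in range(N_SEQUENCES):
        seq = sequence_events(schedule, q)
        lum_mean = np.full(n_frames, 0.2)  # blank screen level
        mot_mean = np.zeros(n_frames)
        for row in seq.itertuples(index=False):
            if row.category == "blank":
                continue
            m = (t >= row.onset_s) & (t < row.onset_s + row.duration_s)
            lum_mean[m] = 0.5 + feature_separation * _LUMINANCE_OFFSET[row.category]
            mot_mean[m] = max(0.05, 1.0 + feature_separation * _MOTION_OFFSET[row.category])
        lum_noise = _ar1(rng, n_frames, 0.97, 0.05)
        mot_noise = _ar1(rng, n_frames, 0.9, 0.25)
        lum[q] = np.clip(lum_mean + lum_noise, 0.0, 1.0)
        mot[q] = np.clip(mot_mean + mot_noise, 0.0, None)
        mot[q][mot_mean == 0] = 0.0
    return lum, mot


def _ar1(rng: np.random.Generator, n: int, rho: float, sd: float) -> np.ndarray:
    from scipy.signal import lfilter

    eps = rng.normal(0.0, sd * np.sqrt(1 - rho**2), size=n)
    x0 = rng.normal(0.0, sd)
    out, _ = lfilter([1.0], [1.0, -rho], eps, zi=[rho * x0])
    return out


def generate_confounds(
    schedule: EventTable,
    config: PipelineConfig,
    seed: int | np.random.Generator,
    run_sequences: list[int] | None = None,
    subject_fixation_mean: float = 0.9,
    feature_separation: float = 0.15,
    features: tuple[np.ndarray, np.ndarray] | None = None,
) -> ConfoundBundle:
    """Session confounds: video features, gaze, fixation, CSF, rewards.

    ``features`` may carry precomputed per-sequence luminance/motion (the
    video is fixed across sessions); otherwise they are drawn here.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if run_sequences is None:
        run_sequences = list(range(N_SEQUENCES))
    if features is None:
        features = video_features(schedule, config, rng, feature_separation)
    lum_seq, mot_seq = features
    lum = np.concatenate([lum_seq[q] for q in run_sequences])
    mot = np.concatenate([mot_seq[q] for q in run_sequences])
    n_frames = len(lum)
    n_vol = int(round(SEQUENCE_DURATION_S / config.tr_s)) * len(run_sequences)

    # gaze: mean-reverting wander within the fixation boundary (degrees)
    from scipy.signal import lfilter

    acc0 = rng.normal(0.0, 1.0, size=2)
    steps = rng.normal(0.0, 0.35, size=(n_frames, 2))
    gaze, _ = lfilter([1.0], [1.0, -0.98], steps, axis=0, zi=0.98 * acc0[None, :])
    gaze = np.clip(gaze, -6.5, 6.5)

    # Per-volume fixation fraction is bout-like: some volumes are fixated
    # nearly throughout, others barely at all. A Beta law with modest
    # concentration reproduces that dispersion while pinning the session mean
    # to the subject's habitual level, so even a poorly fixating subject
    # contributes some volumes above a strict per-volume threshold.
    session_mean = float(np.clip(subject_fixation_mean + rng.normal(0.0, 0.04), 0.05, 0.97))
    concentration = 6.0
    fixation = rng.beta(
        session_mean * concentration, (1.0 - session_mean) * concentration, size=n_vol
    )

    csf_raw = rng.normal(0.0, 1.0, size=n_vol)
    kernel = np.exp(-0.5 * (np.arange(-10, 11) / 4.0) ** 2)
    csf = np.convolve(csf_raw, kernel / kernel.sum(), mode="same")

    # reward pulses while the animal maintains fixation
    rewards = []
    t = float(rng.uniform(2.0, 4.0))
    total_s = n_vol * config.tr_s
    while t < total_s:
        v = int(t // config.tr_s)
        if fixation[v] >= config.fixation_min_frac:
            rewards.append(t)
        t += float(rng.uniform(2.0, 4.0))

    return ConfoundBundle(
        luminance=lum,
        motion=mot,
        gaze_xy=gaze,
        fixation_frac=fixation,
        csf=csf,
        reward_times_s=np.array(rewards),
        frame_rate_hz=config.behavior_rate_hz,
    )


# --------------------------------------------------------------------------
# sessions and datasets
# --------------------------------------------------------------------------

@dataclass
class SessionBundle:
    """One synthetic session: BOLD, events, confounds and the truth."""

    session_id: str
    subject_id: str
    timeseries: ROITimeSeries
    events: EventTable  # session clock
    confounds: ConfoundBundle
    run_sequences: list[int]
    truth: dict

    def __post_init__(self) -> None:
        if self.confounds.n_volumes != self.timeseries.n_volumes:
            raise ValidationError("confound series inconsistent with BOLD duration")


@dataclass
class Dataset:
    """A multi-subject collection of synthetic sessions sharing one schedule."""

    roster: ROIRoster
    schedule: EventTable  # unique-content clock
    sessions: list[SessionBundle]
    spec: CouplingSpec
    config: PipelineConfig

    @property
    def meta(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "session": [s.session_id for s in self.sessions],
                "subject": [s.subject_id for s in self.sessions],
            }
        )


def generate_session(
    schedule: EventTable,
    roster: ROIRoster,
    spec: CouplingSpec,
    config: PipelineConfig,
    seed: int | np.random.Generator,
    session_id: str = "S01",
    subject_id: str = "M1",
    n_repeats: int = 4,
    run_sequences: list[int] | None = None,
    subject_fixation_mean: float | None = None,
    features: tuple[np.ndarray, np.ndarray] | None = None,
    events: EventTable | None = None,
    envelope_cache: dict | None = None,
) -> SessionBundle:
    """Simulate one session: ``n_repeats`` viewings of each sequence.

    ``run_sequences`` gives the presentation order (defaults to the
    sequences in index order, repeated ``n_repeats`` times). ``events`` and
    ``envelope_cache`` may carry precomputed session events and per-sequence
    coupling envelopes (both are functions of the schedule alone, so a
    multi-session dataset shares the envelope cache).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if run_sequences is None:
        run_sequences = list(range(N_SEQUENCES)) * n_repeats
    ts, truth = simulate_bold(
        schedule, roster, spec, config, rng, run_sequences, envelope_cache=envelope_cache
    )
    fix_mean = (
        subject_fixation_mean
        if subject_fixation_mean is not None
        else DEFAULT_SUBJECT_FIXATION.get(subject_id, 0.9)
    )
    confounds = generate_confounds(
        schedule, config, rng, run_sequences, fix_mean, features=features
    )
    return SessionBundle(
        session_id=session_id,
        subject_id=subject_id,
        timeseries=ts,
        events=events if events is not None else session_events(schedule, run_sequences),
        confounds=confounds,
        run_sequences=run_sequences,
        truth=truth,
    )


def generate_dataset(
    config: PipelineConfig,
    seed: int,
    spec: CouplingSpec | None = None,
    roster: ROIRoster | None = None,
    n_subjects: int = 3,
    sessions_per_subject: int = 12,
    n_repeats: int = 4,
) -> Dataset:
    """Full synthetic study: ``n_subjects`` x ``sessions_per_subject`` sessions.

    All sessions share one stimulus schedule and one set of video features
    (the stimuli are fixed), while BOLD, behavior and physiology are drawn
    independently per session. Sequence presentation order is counterbalanced:
    each session plays every sequence once per repeat block, in a freshly
    randomised order, so no ordering of the stimulus material is shared
    across the whole dataset. Deterministic given ``seed``.
    """
    roster = roster or default_roster()
    spec = spec if spec is not None else default_coupling_spec(roster)
    root = np.random.SeedSequence(seed)
    sched_ss, feat_ss, sess_root = root.spawn(3)
    schedule = generate_schedule(config, np.random.default_rng(sched_ss))
    features = video_features(schedule, config, np.random.default_rng(feat_ss))
    session_seeds = sess_root.spawn(n_subjects * sessions_per_subject)
    envelope_cache: dict = {}
    sessions = []
    k = 0
    for s in range(n_subjects):
        subject = f"M{s + 1}"
        for j in range(sessions_per_subject):
            rng_s = np.random.default_rng(session_seeds[k])
            order = [
                int(q)
                for _ in range(n_repeats)
                for q in rng_s.permutation(N_SEQUENCES)
            ]
            sessions.append(
                generate_session(
                    schedule,
                    roster,
                    spec,
                    config,
                    rng_s,
                    session_id=f"{subject}_S{j + 1:02d}",
                    subject_id=subject,
                    n_repeats=n_repeats,
                    run_sequences=order,
                    features=features,
                    envelope_cache=envelope_cache,
                )
            )
            k += 1
    return Dataset(roster=roster, schedule=schedule, sessions=sessions, spec=spec, config=config)
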