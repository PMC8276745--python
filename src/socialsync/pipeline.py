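"""End-to-end analysis: session bundles in, edge statistics and aligned
time courses out.

Per session: motion-outlier flagging, CSF/reward residualisation,
band-limited analytic phase, sliding-window phase-locking values, nuisance
cleaning at window centres, arcsine transform, and averaging over repeated
viewings onto the unique-content clock. Across sessions: per-edge condition
means, mixed-design repeated-measures ANOVA, z maps, suprathreshold
networks, centrality, and clip-onset-aligned group contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import edge_stats, event_aligned, synchrony
from .config import PipelineConfig
from .datatypes import ROIRoster, EventTable
from .preprocess import flag_outliers, residualize
from .regressors import apply_fixation_mask, build_design, hrf_convolve
from .synthetic import SEQUENCE_DURATION_S, Dataset, SessionBundle


def analyze_session(
    bundle: SessionBundle, config: PipelineConfig
) -> synchrony.SynchronyTensor:
    """Cleaned, transformed, repeat-averaged synchrony for one session."""
    ts = bundle.timeseries
    flags = flag_outliers(ts, config)
    resid = residualize(
        ts, bundle.confounds.csf, bundle.confounds.reward_times_s, config, flags
    )
    phases = synchrony.instantaneous_phase(resid, config)
    tensor = synchrony.windowed_synchrony(phases, config)

    design = build_design(bundle.events, bundle.confounds, config, run_starts=ts.run_starts)
    design = apply_fixation_mask(design, bundle.confounds.fixation_frac, config)
    design = hrf_convolve(design, config)
    tensor = synchrony.clean_synchrony(tensor, design, config)
    tensor = synchrony.arcsine_transform(tensor)
    return synchrony.average_repeats(
        tensor, bundle.run_sequences, config, SEQUENCE_DURATION_S
    )


@dataclass
class DatasetResults:
    """All dataset-level outputs of the pipeline."""

    condition_means: pd.DataFrame
    stats: edge_stats.EdgeStatMatrix
    net_absolute: edge_stats.BinaryNetwork
    net_proportional: edge_stats.BinaryNetwork
    degree: np.ndarray
    centrality: np.ndarray
    timecourses: event_aligned.GroupTimecourse
    baseline_tests: pd.DataFrame
    contrasts: pd.DataFrame
    state_networks: dict = field(default_factory=dict)
    session_tensors: list = field(default_factory=list)


def pooled_group_timecourses(
    tensors: list[synchrony.SynchronyTensor],
    events: EventTable,
    roster: ROIRoster,
    supra: edge_stats.BinaryNetwork,
    config: PipelineConfig,
) -> event_aligned.GroupTimecourse:
    """Clip-level aligned courses pooled over sessions.

    Every session contributes one clip-level segment per social clip (edges
    averaged within each anatomical group first); clip matrices are stacked
    across sessions.
    """
    per_session = [
        event_aligned.group_timecourses(t, events, roster, supra, config)
        for t in tensors
    ]
    grid = per_session[0].grid
    merged: dict[str, dict[str, np.ndarray]] = {}
    flagged = sorted({g for tc in per_session for g in tc.flagged})
    for group in event_aligned.EDGE_GROUPS:
        merged[group] = {}
        for cond in per_session[0].clip_courses[group]:
            merged[group][cond] = np.concatenate(
                [tc.clip_courses[group][cond] for tc in per_session], axis=0
            )
    return event_aligned.GroupTimecourse(grid=grid, clip_courses=merged, flagged=flagged)


def analyze_dataset(
    dataset: Dataset,
    config: PipelineConfig | None = None,
    keep_tensors: bool = False,
    align: bool = True,
) -> DatasetResults:
    """Run the full statistical analysis on a (synthetic or real) dataset."""
    config = config or dataset.config
    roster = dataset.roster
    tensors = [analyze_session(b, config) for b in dataset.sessions]

    cm = edge_stats.condition_means(tensors, dataset.schedule, dataset.meta, config)
    stats = edge_stats.rm_anova_all(cm, n_rois=len(roster))
    net_abs = edge_stats.threshold_network(stats, config, mode="absolute")
    net_prop = edge_stats.threshold_network(stats, config, mode="proportional")
    deg = edge_stats.degree(net_abs)
    cent = edge_stats.eigencentrality(net_abs) if net_abs.n_edges else np.zeros(len(roster))

    # grand-average tensor over sessions (shared unique-content grid)
    grand = tensors[0].copy()
    grand.values = np.mean([t.values for t in tensors], axis=0)
    state_nets = {}
    for state_name, state in {
        "blank": ("blank",),
        "nonsocial": ("nonsocial",),
    }.items():
        try:
            means, net, props = synchrony.state_network(
                grand, dataset.schedule, state, config, roster=roster
            )
            state_nets[state_name] = {"edge_means": means, "network": net, "proportions": props}
        except Exception:  # a schedule may lack the state entirely
            state_nets[state_name] = None

    if align:
        tc = pooled_group_timecourses(tensors, dataset.schedule, roster, net_prop, config)
        tests = event_aligned.test_vs_baseline(tc)
        contrasts = event_aligned.contrast_glm(tc)
    else:
        tc = event_aligned.GroupTimecourse(grid=config.align_grid_s, clip_courses={})
        tests = pd.DataFrame()
        contrasts = pd.DataFrame()

    return DatasetResults(
        condition_means=cm,
        stats=stats,
        net_absolute=net_abs,
        net_proportional=net_prop,
        degree=deg,
        centrality=cent,
        timecourses=tc,
        baseline_tests=tests,
        contrasts=contrasts,
        state_networks=state_nets,
        session_tensors=tensors if keep_tensors else [],
    )


def designated_edge_recovery(dataset: Dataset, results: DatasetResults) -> float:
    """Fraction of ground-truth boosted edges inside the proportional top set."""
    pairs = dataset.roster.edges()
    mask = results.net_proportional.edge_mask()
    des = [pairs.index(tuple(e)) for e in dataset.spec.designated_edges]
    if not des:
        return float("nan")
    return float(np.mean([mask[e] for e in des]))
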