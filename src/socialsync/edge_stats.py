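"""Edge-wise condition statistics and network construction.

For each ROI pair: session-level mean synchrony per social condition, a
mixed-design repeated-measures ANOVA (between factor: subject; within
factor: social condition, three levels), a one-tailed p-to-z mapping, and
suprathreshold network construction by absolute z threshold or proportional
top-fraction rule, followed by degree and eigenvector centrality.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats
from scipy.sparse.csgraph import connected_components

from .config import PipelineConfig
from .datatypes import ROIRoster, SOCIAL_CATEGORIES, ValidationError, edge_index
from .synchrony import SynchronyTensor, assign_window_categories

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# session-level condition means
# --------------------------------------------------------------------------

def session_condition_means(
    tensor: SynchronyTensor,
    events,
    config: PipelineConfig,
    conditions: tuple[str, ...] = SOCIAL_CATEGORIES,
) -> np.ndarray:
    """Per-edge mean synchrony for each condition in one session.

    Returns an array of shape (n_conditions, n_edges); rows for conditions
    with no qualifying windows are NaN.
    """
    cats = assign_window_categories(tensor, events, config)
    out = np.full((len(conditions), tensor.n_edges), np.nan)
    for k, cond in enumerate(conditions):
        m = cats == cond
        if m.any():
            out[k] = tensor.values[:, m].mean(axis=1)
    return out


def condition_means(
    tensors: dict[str, SynchronyTensor] | list[SynchronyTensor],
    events,
    session_meta: pd.DataFrame,
    config: PipelineConfig,
    conditions: tuple[str, ...] = SOCIAL_CATEGORIES,
) -> pd.DataFrame:
    """Tidy table of session x edge x condition mean synchrony.

    ``session_meta`` must carry one row per tensor with columns ``session``
    and ``subject``. Rows whose condition has no qualifying windows in a
    session are omitted (and logged).
    """
    if isinstance(tensors, dict):
        tensor_list = [tensors[s] for s in session_meta["session"]]
    else:
        tensor_list = list(tensors)
    if len(tensor_list) != len(session_meta):
        raise ValidationError("one tensor per session_meta row is required")
    records = []
    for (_, meta), tensor in zip(session_meta.iterrows(), tensor_list):
        means = session_condition_means(tensor, events, config, conditions)
        for k, cond in enumerate(conditions):
            if np.isnan(means[k]).all():
                logger.warning(
                    "session %s: no windows for condition %s; rows omitted",
                    meta["session"], cond,
                )
                continue
            for e in range(tensor.n_edges):
                records.append(
                    (meta["session"], meta["subject"], e, cond, means[k, e])
                )
    df = pd.DataFrame(records, columns=["session", "subject", "edge", "condition", "value"])
    if not len(df):
        warnings.warn("no session contributed any condition means")
    return df


# --------------------------------------------------------------------------
# repeated-measures (mixed-design) ANOVA
# --------------------------------------------------------------------------

@dataclass
class EdgeStat:
    F: float
    df: tuple[int, int]
    p: float
    z: float


@dataclass
class EdgeStatMatrix:
    """Within-factor F/df/p/z per edge, canonical edge order."""

    F: np.ndarray
    df: tuple[int, int]
    p: np.ndarray
    z: np.ndarray
    n_rois: int

    def to_frame(self, roster: ROIRoster | None = None) -> pd.DataFrame:
        pairs = edge_index(self.n_rois)
        df = pd.DataFrame(
            {
                "edge": np.arange(len(pairs)),
                "roi_i": [i for i, _ in pairs],
                "roi_j": [j for _, j in pairs],
                "F": self.F,
                "df1": self.df[0],
                "df2": self.df[1],
                "p": self.p,
                "z": self.z,
            }
        )
        if roster is not None:
            df["label"] = roster.edge_labels()
        return df


def greenhouse_geisser_epsilon(Y: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """Greenhouse-Geisser sphericity epsilon, vectorised over trailing axes.

    Computed from the pooled within-group covariance of the repeated
    measures: eps = tr(HSH)^2 / ((C-1) * ||HSH||_F^2) with H the centering
    matrix. Bounded in [1/(C-1), 1]; 1 means sphericity holds.
    """
    Y = np.asarray(Y, dtype=float)
    groups = np.asarray(groups)
    S, C = Y.shape[0], Y.shape[1]
    labels = np.unique(groups)
    resid = np.empty_like(Y)
    for g in labels:
        m = groups == g
        resid[m] = Y[m] - Y[m].mean(axis=0)
    cov = np.einsum("sc...,sd...->cd...", resid, resid) / (S - len(labels))
    cov = cov - cov.mean(axis=0, keepdims=True)
    cov = cov - cov.mean(axis=1, keepdims=True)
    tr = np.einsum("cc...->...", cov)
    frob2 = (cov**2).sum(axis=(0, 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        eps = tr**2 / ((C - 1) * frob2)
    eps = np.where(np.isnan(eps), 1.0, eps)  # degenerate (zero) covariance
    return np.clip(eps, 1.0 / (C - 1), 1.0)


def mixed_anova_within_f(
    Y: np.ndarray, groups: np.ndarray, gg_correction: bool = False
) -> tuple[np.ndarray, tuple[int, int], np.ndarray]:
    """Within-factor F of a mixed-design ANOVA, vectorised over trailing axes.

    ``Y`` has shape (n_subjects, n_conditions, ...), ``groups`` assigns each
    subject (observational unit) to a between-factor level. Classic
    split-plot sums of squares, sphericity uncorrected by default: the
    within-factor F is MS_condition / MS_(condition x subject-within-group).
    With ``gg_correction`` the p-value uses Greenhouse-Geisser
    epsilon-scaled degrees of freedom (the F statistic and the reported
    integer df are unchanged).
    """
    Y = np.asarray(Y, dtype=float)
    groups = np.asarray(groups)
    S, C = Y.shape[0], Y.shape[1]
    labels = np.unique(groups)
    G = len(labels)
    if S - G < 1:
        raise ValidationError("need more sessions than subjects for the ANOVA")

    grand = Y.mean(axis=(0, 1))
    subj_mean = Y.mean(axis=1)  # (S, ...)
    cond_mean = Y.mean(axis=0)  # (C, ...)

    ss_cond = S * ((cond_mean - grand) ** 2).sum(axis=0)
    ss_within_total = ((Y - subj_mean[:, None]) ** 2).sum(axis=(0, 1))
    ss_cond_x_group = np.zeros_like(grand)
    for g in labels:
        m = groups == g
        n_g = int(m.sum())
        cell = Y[m].mean(axis=0)  # (C, ...)
        g_mean = Y[m].mean(axis=(0, 1))
        ss_cond_x_group = ss_cond_x_group + n_g * (
            (cell - g_mean[None] - cond_mean + grand[None]) ** 2
        ).sum(axis=0)
    ss_err = ss_within_total - ss_cond - ss_cond_x_group
    # guard against catastrophic cancellation: sums of squares below the
    # rounding floor of the decomposition are exact zeros. The floor covers
    # both relative error of the decomposition and the absolute noise of
    # summing S*C squared eps-scale cancellations of entries of Y.
    msq = (Y**2).mean(axis=(0, 1))
    eps = np.finfo(float).eps
    tol = np.maximum(1e-12 * ss_within_total, 100 * S * C * eps**2 * msq)
    tol = np.maximum(tol, np.finfo(float).tiny)
    ss_err = np.where(ss_err < tol, 0.0, ss_err)
    ss_cond = np.where(ss_cond < tol, 0.0, ss_cond)
    df1 = C - 1
    df2 = (C - 1) * (S - G)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ss_cond / df1) / (ss_err / df2)
    F = np.where(np.isnan(F), 0.0, F)  # 0/0: no effect and no error
    if gg_correction:
        eps_gg = greenhouse_geisser_epsilon(Y, groups)
        p = sstats.f.sf(F, eps_gg * df1, eps_gg * df2)
    else:
        p = sstats.f.sf(F, df1, df2)
    p = np.where(np.isinf(F), np.finfo(float).tiny, p)
    return F, (df1, df2), np.clip(p, np.finfo(float).tiny, 1.0)


def _usable_sessions(means: pd.DataFrame, conditions: tuple[str, ...]) -> pd.DataFrame:
    """Drop sessions that lack any condition cell, warning per session."""
    keep = []
    for session, sub in means.groupby("session", sort=False):
        present = set(sub["condition"])
        if set(conditions) <= present:
            keep.append(session)
        else:
            warnings.warn(
                f"session {session} lacks conditions "
                f"{sorted(set(conditions) - present)}; dropped from ANOVA"
            )
    return means[means["session"].isin(keep)]


def _anova_cube(
    means: pd.DataFrame, conditions: tuple[str, ...]
) -> tuple[np.ndarray, np.ndarray, list]:
    """Pivot a tidy condition-means table to (S, C, E) plus group labels."""
    usable = _usable_sessions(means, conditions)
    sessions = list(dict.fromkeys(usable["session"]))
    if len(sessions) < 2:
        return np.empty((0, len(conditions), 0)), np.empty(0), sessions
    edges = np.sort(usable["edge"].unique())
    piv = usable.pivot_table(
        index="session", columns=["condition", "edge"], values="value", sort=False
    ).loc[sessions]
    S, C, E = len(sessions), len(conditions), len(edges)
    Y = np.empty((S, C, E))
    for k, cond in enumerate(conditions):
        Y[:, k, :] = piv[cond].loc[:, edges].to_numpy()
    subj = usable.drop_duplicates("session").set_index("session")["subject"].loc[sessions]
    return Y, subj.to_numpy(), sessions


def rm_anova_all(
    means: pd.DataFrame,
    conditions: tuple[str, ...] = SOCIAL_CATEGORIES,
    n_rois: int | None = None,
    gg_correction: bool = False,
) -> EdgeStatMatrix:
    """Per-edge mixed-design ANOVA over a tidy condition-means table."""
    Y, groups, sessions = _anova_cube(means, conditions)
    n_edges_found = Y.shape[2]
    if n_rois is None:
        n_rois = int(round((1 + math.isqrt(1 + 8 * n_edges_found)) / 2))
    E = n_rois * (n_rois - 1) // 2
    if len(sessions) < 2:
        warnings.warn("fewer than 2 usable sessions; all edges untestable (p = 1)")
        return EdgeStatMatrix(
            F=np.zeros(E), df=(len(conditions) - 1, 0), p=np.ones(E),
            z=np.full(E, p_to_z(1.0)), n_rois=n_rois,
        )
    F, df, p = mixed_anova_within_f(Y, groups, gg_correction=gg_correction)
    return EdgeStatMatrix(F=F, df=df, p=p, z=p_to_z(p), n_rois=n_rois)


def rm_anova_edge(
    means: pd.DataFrame,
    edge: int,
    conditions: tuple[str, ...] = SOCIAL_CATEGORIES,
    gg_correction: bool = False,
) -> EdgeStat:
    """Mixed-design ANOVA for a single edge of the condition-means table."""
    sub = means[means["edge"] == edge]
    Y, groups, sessions = _anova_cube(sub, conditions)
    if len(sessions) < 2:
        warnings.warn(f"edge {edge}: fewer than 2 usable sessions; untestable (p = 1)")
        return EdgeStat(F=0.0, df=(len(conditions) - 1, 0), p=1.0, z=float(p_to_z(1.0)))
    F, df, p = mixed_anova_within_f(Y[:, :, 0], groups, gg_correction=gg_correction)
    return EdgeStat(F=float(F), df=df, p=float(p), z=float(p_to_z(float(p))))


# --------------------------------------------------------------------------
# p -> z and network thresholding
# --------------------------------------------------------------------------

def p_to_z(p, two_tailed: bool = False):
    """Upper-tail standard-normal quantile of p (one-tailed mapping).

    z(0.5) = 0; small p maps to large positive z. p = 0 is clipped to the
    smallest positive float with a warning. With ``two_tailed``, p is read
    as two-tailed mass and mapped to the positive tail: z = isf(p / 2), so
    z(1.0) = 0.
    """
    p = np.asarray(p, dtype=float)
    if ((p <= 0) & (p != 0)).any() or (p > 1).any():
        raise ValidationError("p values must lie in (0, 1]")
    if (p == 0).any():
        warnings.warn("p = 0 clipped to the smallest positive representable value")
        p = np.where(p == 0, np.finfo(float).tiny, p)
    z = sstats.norm.isf(p / 2 if two_tailed else p)
    return float(z) if z.ndim == 0 else z


@dataclass
class BinaryNetwork:
    """Symmetric 0/1 adjacency over ROIs with a provenance note."""

    adjacency: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        A = np.asarray(self.adjacency)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValidationError("adjacency must be square")
        if not np.array_equal(A, A.T):
            raise ValidationError("adjacency must be symmetric")
        if np.trace(A) != 0:
            raise ValidationError("adjacency must have zero diagonal")
        if not np.isin(A, [0, 1]).all():
            raise ValidationError("adjacency must be binary")
        self.adjacency = A.astype(int)

    @property
    def n_rois(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum() // 2)

    def edge_mask(self) -> np.ndarray:
        """Canonical-edge-order boolean mask of present edges."""
        pairs = edge_index(self.n_rois)
        return np.array([bool(self.adjacency[i, j]) for i, j in pairs])


def _network_from_mask(mask: np.ndarray, n_rois: int, provenance: str) -> BinaryNetwork:
    A = np.zeros((n_rois, n_rois), dtype=int)
    for e, (i, j) in enumerate(edge_index(n_rois)):
        if mask[e]:
            A[i, j] = A[j, i] = 1
    return BinaryNetwork(adjacency=A, provenance=provenance)


def top_fraction_network(values: np.ndarray, n_rois: int, frac: float) -> BinaryNetwork:
    """Binary network of the top ``ceil(frac * E)`` edges by value.

    Boundary ties are broken by canonical edge order (earlier edges win) and
    produce a warning.
    """
    values = np.asarray(values, dtype=float)
    E = len(values)
    k = math.ceil(frac * E)
    order = np.argsort(-values, kind="stable")
    chosen = order[:k]
    if k < E and values[order[k - 1]] == values[order[k]]:
        warnings.warn(
            "tie at the proportional threshold boundary; resolved by canonical edge order"
        )
    mask = np.zeros(E, dtype=bool)
    mask[chosen] = True
    return _network_from_mask(mask, n_rois, provenance=f"top {frac:.0%} of {E} edges")


def threshold_network(
    stats: EdgeStatMatrix, config: PipelineConfig, mode: str = "absolute"
) -> BinaryNetwork:
    """Suprathreshold network from edge statistics.

    ``mode='absolute'`` keeps edges with z > ``z_threshold`` (the default
    rule); ``mode='proportional'`` keeps the top ``top_edge_frac`` fraction
    of edges by z.
    """
    if mode == "absolute":
        mask = stats.z > config.z_threshold
        return _network_from_mask(
            mask, stats.n_rois, provenance=f"z > {config.z_threshold:g}"
        )
    if mode == "proportional":
        return top_fraction_network(stats.z, stats.n_rois, config.top_edge_frac)
    raise ValidationError(f"unknown threshold mode {mode!r}")


# --------------------------------------------------------------------------
# centrality
# --------------------------------------------------------------------------

def degree(net: BinaryNetwork) -> np.ndarray:
    """Number of suprathreshold connections incident to each ROI."""
    return net.adjacency.sum(axis=1)


def eigencentrality(net: BinaryNetwork) -> np.ndarray:
    """Eigenvector centrality: nonnegative leading eigenvector, unit norm.

    Computed on the largest connected component that contains at least one
    edge (ties broken toward the component with the lowest ROI index); ROIs
    outside it score zero. An empty network returns all zeros with a warning.
    """
    A = net.adjacency
    if A.sum() == 0:
        warnings.warn("empty network: eigenvector centrality undefined, returning zeros")
        return np.zeros(net.n_rois)
    n_comp, labels = connected_components(A, directed=False)
    sizes = np.bincount(labels, minlength=n_comp)
    # ignore singleton components (no edges); pick largest, lowest-index tiebreak
    candidates = [c for c in range(n_comp) if sizes[c] > 1]
    best = max(candidates, key=lambda c: (sizes[c], -int(np.nonzero(labels == c)[0][0])))
    nodes = np.nonzero(labels == best)[0]
    sub = A[np.ix_(nodes, nodes)].astype(float)
    evals, evecs = np.linalg.eigh(sub)
    v = evecs[:, -1]
    if v.sum() < 0:
        v = -v
    v = np.clip(v, 0.0, None)  # Perron vector of a connected graph is positive
    v = v / np.linalg.norm(v)
    # power-iteration polish: drives symmetric graphs to their exact
    # fixed point (e.g. every node of K4 scores exactly 0.5)
    for _ in range(100):
        w = sub @ v
        w = w / np.linalg.norm(w)
        if np.array_equal(w, v):
            break
        v = w
    out = np.zeros(net.n_rois)
    out[nodes] = v
    return out


# --------------------------------------------------------------------------
# anatomical summaries
# --------------------------------------------------------------------------

#: ROI group -> coarse lobe used in connection-proportion summaries.
LOBE_OF_GROUP = {
    "temporal": "temporal",
    "cingulate": "frontal",
    "premotor": "frontal",
    "parietal": "other",
    "subcortical": "other",
    "other": "frontal",
}


def lobe_proportions(net: BinaryNetwork, roster: ROIRoster) -> pd.DataFrame:
    """Proportion of suprathreshold connections per lobe pair and hemisphere.

    Rows: (lobe_a, lobe_b, 'inter'|'intra', fraction); fractions sum to 1
    over the suprathreshold selection.
    """
    pairs = edge_index(len(roster))
    mask = net.edge_mask()
    counts: dict[tuple[str, str, str], int] = {}
    total = 0
    for e, (i, j) in enumerate(pairs):
        if not mask[e]:
            continue
        la = LOBE_OF_GROUP[roster.groups[i]]
        lb = LOBE_OF_GROUP[roster.groups[j]]
        lobe_a, lobe_b = sorted((la, lb))
        hemi = "intra" if roster.hemispheres[i] == roster.hemispheres[j] else "inter"
        counts[(lobe_a, lobe_b, hemi)] = counts.get((lobe_a, lobe_b, hemi), 0) + 1
        total += 1
    rows = [
        {"lobe_a": a, "lobe_b": b, "hemisphere": h, "fraction": c / total}
        for (a, b, h), c in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["lobe_a", "lobe_b", "hemisphere", "fraction"])
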