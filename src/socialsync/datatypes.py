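"""Core domain containers shared by every pipeline stage.

The containers are thin, validated wrappers around numpy arrays and pandas
frames; they carry exactly the metadata downstream stages need (TR, run
boundaries, edge order) and nothing else.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Event categories recognised throughout the pipeline.
SOCIAL_CATEGORIES = ("aggressive", "affiliative", "ambiguous")
CATEGORIES = SOCIAL_CATEGORIES + ("single_actor", "nonsocial", "unclassified", "blank")

#: Actor-count codes. Social interactions require at least two actors.
N_ACTOR_CODES = ("0", "1", "2+")

#: Anatomical groupings used by the ROI roster.
ROI_GROUPS = ("temporal", "cingulate", "premotor", "parietal", "subcortical", "other")
HEMISPHERES = ("left", "right")

#: Category -> admissible actor counts.
_CATEGORY_ACTORS = {
    "aggressive": {"2+"},
    "affiliative": {"2+"},
    "ambiguous": {"2+"},
    "single_actor": {"1"},
    "nonsocial": {"0"},
    "unclassified": {"1", "2+"},
    "blank": {"0"},
}


class ValidationError(ValueError):
    """Raised when a domain object violates one of its invariants."""


def edge_index(n_rois: int) -> list[tuple[int, int]]:
    """Canonical ordering of the undirected ROI pairs (edges).

    Pairs ``(i, j)`` with ``i < j`` in lexicographic order over roster
    order. Every edge-indexed array in the pipeline uses this layout.

    >>> edge_index(3)
    [(0, 1), (0, 2), (1, 2)]
    """
    if n_rois < 2:
        raise ValidationError(f"need at least 2 ROIs to form edges, got {n_rois}")
    return [(i, j) for i in range(n_rois) for j in range(i + 1, n_rois)]


def n_edges(n_rois: int) -> int:
    return n_rois * (n_rois - 1) // 2


@dataclass
class ROIRoster:
    """ROI labels with hemisphere / anatomical-group assignments.

    ``coords_mm`` is optional (template-space sphere centres); the analysis
    itself only uses labels and groupings.
    """

    labels: list[str]
    hemispheres: list[str]
    groups: list[str]
    coords_mm: np.ndarray | None = None  # (n, 3) or None

    def __post_init__(self) -> None:
        n = len(self.labels)
        if n < 2:
            raise ValidationError("roster must contain at least 2 ROIs")
        if len(set(self.labels)) != n:
            dupes = sorted({x for x in self.labels if self.labels.count(x) > 1})
            raise ValidationError(f"duplicate ROI labels: {dupes}")
        if len(self.hemispheres) != n or len(self.groups) != n:
            raise ValidationError("labels/hemispheres/groups length mismatch")
        bad_h = sorted(set(self.hemispheres) - set(HEMISPHERES))
        if bad_h:
            raise ValidationError(f"unknown hemispheres: {bad_h}")
        bad_g = sorted(set(self.groups) - set(ROI_GROUPS))
        if bad_g:
            raise ValidationError(f"unknown ROI groups: {bad_g}")
        if self.coords_mm is not None:
            self.coords_mm = np.asarray(self.coords_mm, dtype=float)
            if self.coords_mm.shape != (n, 3):
                raise ValidationError("coords_mm must have shape (n_rois, 3)")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_edges(self) -> int:
        return n_edges(len(self))

    def edges(self) -> list[tuple[int, int]]:
        return edge_index(len(self))

    def edge_labels(self) -> list[str]:
        return [f"{self.labels[i]}--{self.labels[j]}" for i, j in self.edges()]

    def edge_groups(self) -> list[tuple[str, str]]:
        """Sorted anatomical group pair per edge, canonical edge order."""
        return [
            tuple(sorted((self.groups[i], self.groups[j]))) for i, j in self.edges()
        ]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"label": self.labels, "hemisphere": self.hemispheres, "group": self.groups}
        )
        if self.coords_mm is not None:
            df[["x", "y", "z"]] = self.coords_mm
        return df


@dataclass
class ROITimeSeries:
    """BOLD signal per volume and ROI, with run structure.

    ``run_starts`` holds the first volume index of each run; runs tile the
    session contiguously. Volume ``v`` covers the half-open interval
    ``[v * tr_s, (v + 1) * tr_s)`` seconds from session start.
    """

    values: np.ndarray  # (n_volumes, n_rois)
    tr_s: float
    roi_labels: list[str]
    run_starts: list[int] = field(default_factory=lambda: [0])

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D (volumes x ROIs) array")
        if self.values.shape[1] != len(self.roi_labels):
            raise ValidationError("number of ROI labels must match value columns")
        if len(set(self.roi_labels)) != len(self.roi_labels):
            raise ValidationError("duplicate ROI labels")
        if np.isnan(self.values).any():
            rows = sorted(set(np.nonzero(np.isnan(self.values))[0].tolist()))
            raise ValidationError(f"missing values in volumes {rows[:5]}")
        if self.tr_s <= 0:
            raise ValidationError("tr_s must be > 0")
        rs = list(self.run_starts)
        if not rs or rs[0] != 0:
            raise ValidationError("run_starts must begin at volume 0")
        if any(b >= a for a, b in zip(rs[1:], rs[:-1])):
            raise ValidationError("run_starts must be strictly increasing")
        if rs[-1] >= self.n_volumes:
            raise ValidationError("run_starts exceed the number of volumes")
        self.run_starts = rs

    @property
    def n_volumes(self) -> int:
        return self.values.shape[0]

    @property
    def n_rois(self) -> int:
        return self.values.shape[1]

    @property
    def n_runs(self) -> int:
        return len(self.run_starts)

    def run_slices(self) -> list[slice]:
        stops = list(self.run_starts[1:]) + [self.n_volumes]
        return [slice(a, b) for a, b in zip(self.run_starts, stops)]

    def volume_times_s(self) -> np.ndarray:
        return np.arange(self.n_volumes) * self.tr_s


@dataclass
class EventTable:
    """Timed, categorised stimulus intervals (clips and blanks)."""

    frame: pd.DataFrame  # columns: onset_s, duration_s, category, n_actors

    REQUIRED = ("onset_s", "duration_s", "category", "n_actors")

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValidationError(f"event table missing columns: {missing}")
        df = df.reset_index(drop=True)
        bad = sorted(set(df["category"]) - set(CATEGORIES))
        if bad:
            raise ValidationError(f"unknown category: {bad}")
        bad_n = sorted(set(df["n_actors"].astype(str)) - set(N_ACTOR_CODES))
        if bad_n:
            raise ValidationError(f"unknown n_actors code: {bad_n}")
        if (df["duration_s"] <= 0).any():
            raise ValidationError("event durations must be > 0")
        for idx, (cat, n_act) in enumerate(zip(df["category"], df["n_actors"])):
            if str(n_act) not in _CATEGORY_ACTORS[cat]:
                raise ValidationError(
                    f"row {idx}: category {cat!r} inconsistent with n_actors {n_act!r}"
                )
        order = df.sort_values("onset_s", kind="stable")
        ends = (order["onset_s"] + order["duration_s"]).to_numpy()
        starts = order["onset_s"].to_numpy()
        overlap = np.nonzero(starts[1:] < ends[:-1] - 1e-9)[0]
        if overlap.size:
            k = overlap[0]
            a, b = order.index[k], order.index[k + 1]
            raise ValidationError(f"events overlap: rows {a} and {b}")
        self.frame = df

    def __len__(self) -> int:
        return len(self.frame)

    def clips(self) -> pd.DataFrame:
        return self.frame[self.frame["category"] != "blank"]

    def social_clips(self) -> pd.DataFrame:
        return self.frame[self.frame["category"].isin(SOCIAL_CATEGORIES)]

    def end_s(self) -> float:
        if not len(self.frame):
            return 0.0
        return float((self.frame["onset_s"] + self.frame["duration_s"]).max())

    def category_at(self, times_s: np.ndarray) -> np.ndarray:
        """Category label active at each time (empty string where none)."""
        times_s = np.asarray(times_s, dtype=float)
        out = np.full(times_s.shape, "", dtype=object)
        for row in self.frame.itertuples(index=False):
            m = (times_s >= row.onset_s) & (times_s < row.onset_s + row.duration_s)
            out[m] = row.category
        return out


@dataclass
class ConfoundBundle:
    """Frame-level video features and volume-level nuisance series.

    ``luminance`` / ``motion`` are frame series at ``frame_rate_hz``;
    ``gaze_xy`` is the eye-position trace (degrees) at the same rate;
    ``fixation_frac`` and ``csf`` are volume series; ``reward_times_s`` are
    reward-pulse onsets in seconds from session start.
    """

    luminance: np.ndarray
    motion: np.ndarray
    gaze_xy: np.ndarray  # (n_frames, 2)
    fixation_frac: np.ndarray
    csf: np.ndarray
    reward_times_s: np.ndarray
    frame_rate_hz: float = 25.0

    def __post_init__(self) -> None:
        self.luminance = np.asarray(self.luminance, dtype=float)
        self.motion = np.asarray(self.motion, dtype=float)
        self.gaze_xy = np.asarray(self.gaze_xy, dtype=float)
        self.fixation_frac = np.asarray(self.fixation_frac, dtype=float)
        self.csf = np.asarray(self.csf, dtype=float)
        self.reward_times_s = np.asarray(self.reward_times_s, dtype=float)
        if self.luminance.shape != self.motion.shape:
            raise ValidationError("luminance and motion must have equal length")
        if self.gaze_xy.ndim != 2 or self.gaze_xy.shape[1] != 2:
            raise ValidationError("gaze_xy must have shape (n_frames, 2)")
        if self.gaze_xy.shape[0] != self.luminance.shape[0]:
            raise ValidationError("gaze trace length must match frame series")
        if ((self.fixation_frac < 0) | (self.fixation_frac > 1)).any():
            raise ValidationError("fixation_frac must lie in [0, 1]")
        if self.csf.shape != self.fixation_frac.shape:
            raise ValidationError("csf and fixation_frac must both be volume series")

    @property
    def n_volumes(self) -> int:
        return self.csf.shape[0]

    @property
    def n_frames(self) -> int:
        return self.luminance.shape[0]
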