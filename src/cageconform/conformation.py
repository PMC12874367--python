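"""Inter-ligand angle computation and conformational-state assignment.

The cage's conformation is tracked by the acute angle theta between the
best-fit planes of the central aromatic rings of adjacent ligands.  The
three states seen in simulation are, by angle: open (two ring pairs
pi-stacked, theta around 40-50 deg), semiopen (one stacked pair, theta
around 60-70 deg) and closed (the symmetric lantern, theta around
90 deg).  Default class boundaries sit midway between those ranges at
55 and 80 deg and are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .cage_model import CageTopology, Structure
from .errors import ConfigError, FrameError, GeometryError

__all__ = [
    "StateLabel",
    "STATES",
    "Thresholds",
    "AngleSet",
    "ring_plane",
    "adjacent_pairs",
    "theta_series",
    "classify",
    "classify_series",
    "angles_to_frame",
]

StateLabel = Literal["closed", "semiopen", "open"]
STATES: tuple[StateLabel, ...] = ("closed", "semiopen", "open")


@dataclass(frozen=True)
class Thresholds:
    """State boundaries on theta (degrees): open <= open_max <
    semiopen <= semiopen_max < closed."""

    open_max: float = 55.0
    semiopen_max: float = 80.0

    def __post_init__(self) -> None:
        if not (0.0 < self.open_max < self.semiopen_max < 90.0):
            raise ConfigError(
                "thresholds must satisfy 0 < open_max < semiopen_max < 90, "
                f"got {self.open_max}, {self.semiopen_max}"
            )


@dataclass
class AngleSet:
    """Four adjacent-pair angles (deg) for one frame."""

    angles: np.ndarray  # shape (4,), degrees in [0, 90]
    pairs: list[tuple[int, int]]  # ligand-index pairs

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        if self.angles.shape != (4,):
            raise ValueError("an AngleSet holds exactly 4 angles")
        if ((self.angles < -1e-9) | (self.angles > 90 + 1e-9)).any():
            raise ValueError("angles must lie in [0, 90] degrees")
        self.angles = np.clip(self.angles, 0.0, 90.0)

    @property
    def theta_min(self) -> float:
        return float(self.angles.min())


def ring_plane(ring_coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Best-fit plane of ring atoms: (centroid, unit normal).

    The normal is the direction of least variance of the centred
    coordinates (smallest right singular vector).  Its sign is
    arbitrary; downstream angles are acute, so the ambiguity is
    harmless.
    """
    pts = np.asarray(ring_coords, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
        raise GeometryError("need at least 3 points in 3-D")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    # collinear points: second singular value ~ 0 -> plane undefined
    if s[1] < 1e-8 * max(s[0], 1.0):
        raise GeometryError("ring atoms are (nearly) collinear")
    return centroid, vt[2]


def adjacent_pairs(
    topology: CageTopology, frame: Structure
) -> list[tuple[int, int]]:
    """Order ligands by azimuth about the Pd-Pd axis; adjacency is
    consecutive in that cyclic order (4 pairs)."""
    axis = topology.pd_axis
    origin = frame.coords[list(topology.pd_atoms)].mean(axis=0)
    # orthonormal frame perpendicular to the axis
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, axis)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = ref - np.dot(ref, axis) * axis
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    azimuths = []
    for ring in topology.central_rings:
        c = frame.coords[ring].mean(axis=0) - origin
        azimuths.append(np.arctan2(np.dot(c, v), np.dot(c, u)))
    order = np.argsort(azimuths)
    az_sorted = np.asarray(azimuths)[order]
    gaps = np.diff(np.concatenate([az_sorted, [az_sorted[0] + 2 * np.pi]]))
    if (np.abs(gaps) < 1e-9).any():
        raise GeometryError("two ligand centroids at identical azimuth")
    return [
        (int(order[k]), int(order[(k + 1) % 4])) for k in range(4)
    ]


def _pair_angle(n1: np.ndarray, n2: np.ndarray) -> float:
    c = abs(float(np.dot(n1, n2)))
    return float(np.degrees(np.arccos(np.clip(c, 0.0, 1.0))))


def theta_series(
    trajectory: Sequence[Structure], topology: CageTopology
) -> list[AngleSet]:
    """Per-frame adjacent-pair central-ring plane angles (degrees).

    Atom ordering must be constant across frames (the topology is
    perceived once and reused).
    """
    n_atoms = None
    out: list[AngleSet] = []
    for f_i, frame in enumerate(trajectory):
        if n_atoms is None:
            n_atoms = frame.n_atoms
        elif frame.n_atoms != n_atoms:
            raise FrameError(
                f"frame {f_i} has {frame.n_atoms} atoms, expected {n_atoms}"
            )
        normals = [
            ring_plane(frame.coords[ring])[1]
            for ring in topology.central_rings
        ]
        pairs = adjacent_pairs(topology, frame)
        angles = np.array(
            [_pair_angle(normals[i], normals[j]) for i, j in pairs]
        )
        out.append(AngleSet(angles=angles, pairs=pairs))
    return out


def classify(
    angles: AngleSet,
    thresholds: Thresholds = Thresholds(),
    rule: Literal["min", "pair_count"] = "min",
) -> StateLabel:
    """Assign one conformational state to a frame.

    ``min`` (default): theta_min <= open_max -> open;
    open_max < theta_min <= semiopen_max -> semiopen; else closed.
    ``pair_count``: open requires >= 2 pairs at or below open_max
    (the two stacked ring pairs of the open conformation); otherwise
    the min rule applies between semiopen and closed.
    """
    t = thresholds
    tmin = angles.theta_min
    if rule == "pair_count":
        n_low = int((angles.angles <= t.open_max).sum())
        if n_low >= 2:
            return "open"
        if tmin <= t.semiopen_max:
            return "semiopen"
        return "closed"
    if rule != "min":
        raise ConfigError(f"unknown classification rule {rule!r}")
    if tmin <= t.open_max:
        return "open"
    if tmin <= t.semiopen_max:
        return "semiopen"
    return "closed"


def classify_series(
    angle_sets: Sequence[AngleSet],
    thresholds: Thresholds = Thresholds(),
    rule: Literal["min", "pair_count"] = "min",
) -> list[StateLabel]:
    return [classify(a, thresholds, rule) for a in angle_sets]


def angles_to_frame(
    angle_sets: Sequence[AngleSet],
    states: Sequence[StateLabel] | None = None,
) -> pd.DataFrame:
    """Tabulate a theta series: frame, theta_1..4, theta_min[, state]."""
    rows = {
        "frame": np.arange(len(angle_sets)),
    }
    arr = np.array([a.angles for a in angle_sets])
    for k in range(4):
        rows[f"theta_{k + 1}"] = arr[:, k]
    rows["theta_min"] = arr.min(axis=1)
    df = pd.DataFrame(rows)
    if states is not None:
        df["state"] = list(states)
    return df


def write_angle_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, float_format="%.6f")
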