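"""Seeded generators for every fixture the analysis needs.

The real study feeds MD trajectories and quantum-chemical tables into
the analysis; this module replaces those engines with controlled,
seeded surrogates:

* idealized [Pd2L4]4+ lantern cages whose adjacent central-ring plane
  angles hit prescribed targets exactly (a hinge construction: each
  central ring pivots about the vertical chord through its two
  arm-bearing carbons, so an adjacent-pair angle is 90 deg minus the
  hinge-angle difference);
* Markov-switching trajectories with Gaussian in-state angle noise;
* multi-well (d1, d2) energy surfaces with known analytic minima;
* per-atom charge tables that are noisy within symmetry classes but
  exact in total charge.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .cage_model import Structure
from .errors import ConfigError, DataError, GeometryError
from .surface import ScanSurface
from .symmetry import ChargeSet, Partition

__all__ = [
    "TrajectorySpec",
    "WellSpec",
    "gen_ideal_cage",
    "ligand_graph_structure",
    "gen_trajectory",
    "sample_states",
    "markov_stationary",
    "markov_fraction_se",
    "gen_surface",
    "gen_charges",
    "default_well_spec",
]

# idealized bond lengths (Angstrom); textbook values, only the graph
# topology and the ring-plane angles matter downstream
_CC_AROM = 1.39
_CH = 1.09
_C_SP2_SP = 1.43
_CC_TRIPLE = 1.20
_PD_N = 2.02
_RING_RADIUS = _CC_AROM  # regular hexagon

_STATE_ORDER = ("closed", "semiopen", "open")


# ---------------------------------------------------------------------------
# planar ligand template


@dataclass
class _LigandTemplate:
    elements: list[str]
    coords: np.ndarray  # (n, 2): (u, w); u maps radially, w along the axis
    bonds: set[tuple[int, int]]
    central_ring: list[int]
    attach: tuple[int, int]  # arm-bearing ring atoms (on the hinge axis)
    endo: int
    coord_n: tuple[int, int]
    moving: list[int]  # atoms that rotate with the central-ring hinge
    hinge_u: float
    pd_w: float  # Pd sits at (u=0, w=+-pd_w)


def _hexagon(center: np.ndarray, start_angle_deg: float) -> np.ndarray:
    ang = np.radians(start_angle_deg - 60.0 * np.arange(6))
    return center + _RING_RADIUS * np.column_stack([np.cos(ang), np.sin(ang)])


def _build_arm(
    attach_xy: np.ndarray, gamma: float, sign_w: float
) -> dict[str, np.ndarray]:
    """One pyridin-3-yl-ethynyl arm in template coordinates.

    *gamma* tilts the alkyne axis from the +-w direction toward -u;
    *sign_w* = +1 for the top arm, -1 for the bottom (mirror).
    """
    e = np.array([-math.sin(gamma), sign_w * math.cos(gamma)])
    ca = attach_xy + _C_SP2_SP * e
    cb = ca + _CC_TRIPLE * e
    cp = cb + _C_SP2_SP * e
    center = cp + _RING_RADIUS * e
    base = math.degrees(math.atan2(cp[1] - center[1], cp[0] - center[0]))
    verts = _hexagon(center, base)  # verts[0] == cp
    # meta positions (k = +-2); coordinate toward the axis: smaller u
    n_k = 2 if verts[2][0] < verts[4][0] else 4
    n_xy = verts[n_k]
    n_dir = (n_xy - center) / _RING_RADIUS
    pd_xy = center + (_RING_RADIUS + _PD_N) * n_dir
    return {
        "verts": verts,
        "center": center,
        "ca": ca,
        "cb": cb,
        "n_k": np.array([n_k]),
        "pd": pd_xy,
    }


def _solve_gamma(attach_xy: np.ndarray) -> float:
    """Tilt angle placing the arm's Pd site exactly on the cage axis."""

    def pd_u(gamma: float) -> float:
        return float(_build_arm(attach_xy, gamma, +1.0)["pd"][0])

    lo, hi = math.radians(-10.0), math.radians(80.0)
    grid = np.linspace(lo, hi, 200)
    vals = [pd_u(g) for g in grid]
    for a, b, va, vb in zip(grid[:-1], grid[1:], vals[:-1], vals[1:]):
        if va == 0.0:
            return float(a)
        if va * vb < 0:
            return float(brentq(pd_u, a, b, xtol=1e-14))
    raise GeometryError("no arm tilt places Pd on the cage axis")


@lru_cache(maxsize=8)
def _ligand_template(analog: str, ring_radius_u: float) -> _LigandTemplate:
    """Planar ligand of the endo-C or endo-N cage, plus its Pd sites.

    The central ring center sits at u = *ring_radius_u*; the two
    arm-bearing carbons share the same u (the vertical hinge chord).
    """
    if analog not in ("endo-C", "endo-N"):
        raise ConfigError(f"analog must be 'endo-C' or 'endo-N', got {analog!r}")
    R = ring_radius_u
    center = np.array([R, 0.0])
    # vertex order: 0 endo(180deg), 1 C1(120), 2 C4(60), 3 para(0),
    # 4 C6(-60), 5 C3(-120)
    verts = _hexagon(center, 180.0)
    endo_el = "C" if analog == "endo-C" else "N"

    elements: list[str] = []
    coords: list[np.ndarray] = []
    bonds: set[tuple[int, int]] = set()

    def add(el: str, xy: np.ndarray) -> int:
        elements.append(el)
        coords.append(np.asarray(xy, dtype=float))
        return len(elements) - 1

    ring_idx = []
    for k in range(6):
        el = endo_el if k == 0 else "C"
        ring_idx.append(add(el, verts[k]))
    for a, b in zip(ring_idx, ring_idx[1:] + ring_idx[:1]):
        bonds.add((min(a, b), max(a, b)))

    moving: list[int] = [ring_idx[0], ring_idx[2], ring_idx[3], ring_idx[4]]
    # ring hydrogens, radial; endo vertex carries H only in the endo-C cage
    h_verts = [0, 2, 3, 4] if analog == "endo-C" else [2, 3, 4]
    for k in h_verts:
        out_dir = (verts[k] - center) / _RING_RADIUS
        h = add("H", verts[k] + _CH * out_dir)
        bonds.add((min(ring_idx[k], h), max(ring_idx[k], h)))
        moving.append(h)

    attach_top = verts[1]
    gamma = _solve_gamma(attach_top)

    coord_n: list[int] = []
    for sign_w, attach_vertex in ((+1.0, 1), (-1.0, 5)):
        arm = _build_arm(verts[attach_vertex], gamma, sign_w)
        ia = add("C", arm["ca"])
        ib = add("C", arm["cb"])
        bonds.add((min(ring_idx[attach_vertex], ia), max(ring_idx[attach_vertex], ia)))
        bonds.add((min(ia, ib), max(ia, ib)))
        py_idx = []
        n_k = int(arm["n_k"][0])
        for k in range(6):
            el = "N" if k == n_k else "C"
            py_idx.append(add(el, arm["verts"][k]))
        for a, b in zip(py_idx, py_idx[1:] + py_idx[:1]):
            bonds.add((min(a, b), max(a, b)))
        bonds.add((min(ib, py_idx[0]), max(ib, py_idx[0])))
        for k in range(1, 6):
            if k == n_k:
                continue
            out_dir = (arm["verts"][k] - arm["center"]) / _RING_RADIUS
            h = add("H", arm["verts"][k] + _CH * out_dir)
            bonds.add((min(py_idx[k], h), max(py_idx[k], h)))
        coord_n.append(py_idx[n_k])
        pd_w = abs(float(arm["pd"][1]))

    return _LigandTemplate(
        elements=elements,
        coords=np.array(coords),
        bonds=bonds,
        central_ring=ring_idx,
        attach=(ring_idx[1], ring_idx[5]),
        endo=ring_idx[0],
        coord_n=(coord_n[0], coord_n[1]),
        moving=moving,
        hinge_u=float(verts[1][0]),
        pd_w=pd_w,
    )


def ligand_graph_structure(analog: str, ring_radius_u: float = 4.0) -> Structure:
    """A single free ligand (hydrogens included, no Pd) as a Structure.

    This is the graph the symmetry-grouping stage operates on: the
    1,3-bis(pyridin-3-ylethynyl)benzene ligand of the endo-C cage
    (C20H12N2) or the 2,6-bis(pyridin-3-ylethynyl)pyridine ligand of
    the endo-N cage (C19H11N3).
    """
    t = _ligand_template(analog, ring_radius_u)
    coords3 = np.column_stack([t.coords, np.zeros(len(t.elements))])
    return Structure(
        elements=list(t.elements),
        coords=coords3,
        bonds=set(t.bonds),
        title=f"{analog} ligand",
    )


# ---------------------------------------------------------------------------
# hinge-angle solution


def _solve_hinges(theta_pattern: Sequence[float]) -> np.ndarray:
    """Hinge angles beta (deg) realizing 4 adjacent-pair plane angles.

    Pair k (ligands k, k+1 mod 4) has angle 90 - |beta_{k+1} - beta_k|,
    so the targets are feasible iff the deficits 90-theta_k admit signs
    summing to zero around the cycle.
    """
    theta = np.asarray(theta_pattern, dtype=float)
    if theta.shape != (4,):
        raise ConfigError("theta_pattern must contain exactly 4 angles")
    if ((theta <= 0) | (theta > 90)).any():
        raise ConfigError("theta targets must lie in (0, 90] degrees")
    delta = 90.0 - theta
    best: np.ndarray | None = None
    best_span = np.inf
    for mask in range(16):
        signs = np.array([1 if mask & (1 << k) else -1 for k in range(4)])
        if abs(float(np.dot(signs, delta))) > 1e-9:
            continue
        beta = np.concatenate([[0.0], np.cumsum(signs[:-1] * delta[:-1])])
        beta -= 0.5 * (beta.max() + beta.min())
        span = float(np.abs(beta).max())
        if span < best_span:
            best, best_span = beta, span
    if best is None:
        raise GeometryError(
            "theta pattern not realizable on a cycle of four hinged "
            f"planes: {list(theta)} (the angle deficits 90-theta must "
            "admit a signed cyclic sum of zero)"
        )
    return best


# ---------------------------------------------------------------------------
# cage assembly


def gen_ideal_cage(
    analog: str = "endo-C",
    theta_pattern: Sequence[float] = (90.0, 90.0, 90.0, 90.0),
    ring_radius_u: float = 4.0,
) -> Structure:
    """Idealized lantern cage hitting the four adjacent-pair angles.

    Four copies of the planar ligand template are placed at azimuths
    0/90/180/270 deg about the Pd-Pd (z) axis; each central ring is then
    hinged about the vertical chord through its two arm-bearing carbons
    so the adjacent central-ring plane angles equal *theta_pattern*.
    Bond connectivity (including the eight Pd-N contacts) is attached
    explicitly and also recoverable by distance-based perception.
    """
    t = _ligand_template(analog, ring_radius_u)
    beta = np.radians(_solve_hinges(theta_pattern))
    n_lig = len(t.elements)
    elements: list[str] = []
    coords: list[np.ndarray] = []
    bonds: set[tuple[int, int]] = set()
    for k in range(4):
        phi = math.radians(90.0 * k)
        c, s = math.cos(phi), math.sin(phi)
        off = k * n_lig
        xyz = np.column_stack(
            [t.coords[:, 0] * c, t.coords[:, 0] * s, t.coords[:, 1]]
        )
        # hinge rotation about the vertical line through the chord
        p0 = np.array([t.hinge_u * c, t.hinge_u * s])
        cb_, sb_ = math.cos(beta[k]), math.sin(beta[k])
        rot = np.array([[cb_, -sb_], [sb_, cb_]])
        for a in t.moving:
            xy = xyz[a, :2] - p0
            xyz[a, :2] = rot @ xy + p0
        elements.extend(t.elements)
        coords.append(xyz)
        bonds |= {(i + off, j + off) for i, j in t.bonds}
    coords_arr = np.vstack(coords)
    pd_top = len(elements)
    elements.append("Pd")
    coords_arr = np.vstack([coords_arr, [0.0, 0.0, t.pd_w]])
    pd_bot = len(elements)
    elements.append("Pd")
    coords_arr = np.vstack([coords_arr, [0.0, 0.0, -t.pd_w]])
    for k in range(4):
        off = k * n_lig
        n_top, n_bot = t.coord_n
        bonds.add((min(n_top + off, pd_top), max(n_top + off, pd_top)))
        bonds.add((min(n_bot + off, pd_bot), max(n_bot + off, pd_bot)))
    label = ",".join(f"{a:g}" for a in theta_pattern)
    return Structure(
        elements=elements,
        coords=coords_arr,
        bonds=bonds,
        title=f"ideal {analog} cage theta=({label})",
    )


# ---------------------------------------------------------------------------
# Markov state trajectories


@dataclass
class TrajectorySpec:
    """State-switching surrogate for the MD conformational dynamics.

    *transition* is row-stochastic over (closed, semiopen, open);
    *means*/*sigmas* give each state's theta_min Gaussian (degrees).
    Defaults emulate a DMSO-like run: mostly closed with sticky
    excursions, in-state angle noise of 3 deg around 88/65/45 deg.
    """

    transition: np.ndarray = field(
        default_factory=lambda: 0.9 * np.eye(3)
        + 0.1 * np.outer(np.ones(3), [0.70, 0.20, 0.10])
    )
    means: tuple[float, float, float] = (88.0, 65.0, 45.0)
    sigmas: tuple[float, float, float] = (3.0, 3.0, 3.0)
    frames: int = 1000
    seed: int = 0
    analog: str = "endo-C"
    start_state: str | None = None  # None: draw from the stationary law

    def __post_init__(self) -> None:
        self.transition = np.asarray(self.transition, dtype=float)
        if self.transition.shape != (3, 3):
            raise ConfigError("transition matrix must be 3x3")
        if (self.transition < 0).any() or not np.allclose(
            self.transition.sum(axis=1), 1.0, atol=1e-9
        ):
            raise ConfigError("transition matrix rows must sum to 1")
        if any(s < 0 for s in self.sigmas):
            raise ConfigError("sigmas must be nonnegative")
        if self.frames < 1:
            raise ConfigError("frames must be >= 1")


def markov_stationary(transition: np.ndarray) -> np.ndarray:
    """Stationary distribution (left Perron eigenvector) of a chain."""
    p = np.asarray(transition, dtype=float)
    vals, vecs = np.linalg.eig(p.T)
    k = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, k])
    pi = np.abs(pi)
    return pi / pi.sum()


def markov_fraction_se(transition: np.ndarray, n: int) -> np.ndarray:
    """Asymptotic standard error of each state's occupancy fraction.

    Uses the Markov-chain CLT with the fundamental matrix
    Z = (I - P + 1 pi)^-1: var_s = pi_s (2 Z_ss - 1 - pi_s) / n.
    For an iid chain this reduces to the binomial SE.
    """
    p = np.asarray(transition, dtype=float)
    pi = markov_stationary(p)
    z = np.linalg.inv(np.eye(3) - p + np.outer(np.ones(3), pi))
    var = pi * (2.0 * np.diag(z) - 1.0 - pi)
    return np.sqrt(np.maximum(var, 0.0) / n)


def sample_states(
    spec: TrajectorySpec, rng: np.random.Generator | None = None
) -> tuple[list[str], np.ndarray]:
    """Sample the hidden state sequence and per-frame theta_min values."""
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    pi = markov_stationary(spec.transition)
    if spec.start_state is None:
        state = int(rng.choice(3, p=pi))
    else:
        if spec.start_state not in _STATE_ORDER:
            raise ConfigError(f"unknown start state {spec.start_state!r}")
        state = _STATE_ORDER.index(spec.start_state)
    states: list[str] = []
    thetas = np.empty(spec.frames)
    for f in range(spec.frames):
        states.append(_STATE_ORDER[state])
        t = rng.normal(spec.means[state], spec.sigmas[state])
        thetas[f] = min(90.0, max(1.0, t))  # truncate to the valid range
        state = int(rng.choice(3, p=spec.transition[state]))
    return states, thetas


def gen_trajectory(
    spec: TrajectorySpec, rng: np.random.Generator | None = None
) -> tuple[list[Structure], list[str], np.ndarray]:
    """Geometry trajectory realizing a sampled Markov state sequence.

    Each frame is an ideal cage built at pattern (t, 90, 90, t) where t
    is the frame's theta_min draw (hinging one ring changes exactly two
    adjacent-pair angles).  Returns (frames, true labels, theta_min).
    """
    states, thetas = sample_states(spec, rng)
    frames = [
        gen_ideal_cage(spec.analog, (t, 90.0, 90.0, t)) for t in thetas
    ]
    return frames, states, thetas


# ---------------------------------------------------------------------------
# scan surfaces


@dataclass
class WellSpec:
    """Gaussian wells on a (d1, d2) grid: E = baseline - sum depth*g."""

    centers: list[tuple[float, float]]
    depths: list[float]
    widths: list[float]
    baseline: float = 0.0

    def __post_init__(self) -> None:
        if not (len(self.centers) == len(self.depths) == len(self.widths)):
            raise DataError("centers, depths, widths must have equal length")
        if any(w <= 0 for w in self.widths):
            raise DataError("well widths must be positive")


def default_well_spec() -> WellSpec:
    """Three-well surface echoing the closed/semiopen/open landscape.

    Depth differences put the semiopen minimum 2.76 and the open
    minimum 4.85 kcal/mol above the closed one.
    """
    return WellSpec(
        centers=[(9.5, 9.5), (5.0, 9.5), (5.0, 5.0)],
        depths=[10.0, 7.24, 5.15],
        widths=[1.2, 1.2, 1.2],
        baseline=0.0,
    )


def gen_surface(
    spec: WellSpec,
    d1_range: tuple[float, float] = (3.5, 10.5),
    d2_range: tuple[float, float] = (3.5, 10.5),
    n_grid: int = 15,
) -> ScanSurface:
    """Sample the analytic well surface on an n_grid x n_grid lattice.

    With wells separated by more than 3 widths the analytic minima sit
    at the well centers; closer wells trigger a recorded metadata
    warning (their grid minima may merge or shift).
    """
    d1_ax = np.linspace(*d1_range, n_grid)
    d2_ax = np.linspace(*d2_range, n_grid)
    g1, g2 = np.meshgrid(d1_ax, d2_ax, indexing="ij")
    e = np.full(g1.shape, spec.baseline, dtype=float)
    for (c1, c2), depth, width in zip(spec.centers, spec.depths, spec.widths):
        if not (d1_range[0] <= c1 <= d1_range[1]) or not (
            d2_range[0] <= c2 <= d2_range[1]
        ):
            raise DataError(f"well center ({c1}, {c2}) outside the grid")
        dist2 = (g1 - c1) ** 2 + (g2 - c2) ** 2
        e -= depth * np.exp(-dist2 / width**2)
    warnings = []
    for i in range(len(spec.centers)):
        for j in range(i + 1, len(spec.centers)):
            sep = math.dist(spec.centers[i], spec.centers[j])
            min_sep = 3.0 * max(spec.widths[i], spec.widths[j])
            if sep < min_sep:
                warnings.append(
                    f"wells {i} and {j} separated by {sep:.3g} A "
                    f"(< {min_sep:.3g} A); minima may merge"
                )
    return ScanSurface(
        d1=g1.ravel(),
        d2=g2.ravel(),
        energy=e.ravel(),
        metadata={"well_spec": spec, "warnings": warnings},
    )


# ---------------------------------------------------------------------------
# charge tables


def gen_charges(
    partition: Partition,
    class_means: Sequence[float],
    sigma: float = 0.02,
    seed: int | np.random.Generator = 0,
    net_charge: float = 4.0,
    model: str = "ESP",
) -> ChargeSet:
    """Noisy-within-class charges whose sum is exactly *net_charge*.

    Per atom: class mean + Gaussian(0, sigma); the residual to the
    target net charge is then spread uniformly over all atoms, so the
    sum is exact while class means stay recoverable.
    """
    if len(class_means) != partition.n_classes:
        raise DataError(
            f"{len(class_means)} class means for {partition.n_classes} classes"
        )
    if sigma < 0:
        raise DataError("sigma must be nonnegative")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    q = np.empty(partition.n_atoms)
    for mean, cls in zip(class_means, partition.classes):
        q[cls] = mean + rng.normal(0.0, sigma, size=len(cls))
    q += (net_charge - q.sum()) / partition.n_atoms
    return ChargeSet(model=model, charges=q)
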