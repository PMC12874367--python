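"""2-D relaxed-scan energy surfaces over (d1, d2) and their minima.

The cage's conformational landscape is scanned along the two distances
d1, d2 between endo-facing atoms of adjacent ligand pairs; the resulting
energy grid exhibits up to three wells (closed, semiopen, open).  This
module reads such grids, locates local minima and reports conformer
energy gaps relative to the most stable minimum.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import ConfigError, DataError

__all__ = [
    "ScanSurface",
    "Minimum",
    "ConformerGapTable",
    "read_scan",
    "write_scan",
    "find_minima",
    "conformer_gaps",
]


@dataclass
class ScanSurface:
    """Scattered or rectangular grid of (d1, d2, E) scan points."""

    d1: np.ndarray  # Angstrom
    d2: np.ndarray  # Angstrom
    energy: np.ndarray  # kcal/mol
    structure_paths: list[str] | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.d1 = np.asarray(self.d1, dtype=float)
        self.d2 = np.asarray(self.d2, dtype=float)
        self.energy = np.asarray(self.energy, dtype=float)
        if not (self.d1.shape == self.d2.shape == self.energy.shape):
            raise DataError("d1, d2, E must have equal length")
        if not np.isfinite(self.energy).all():
            raise DataError("energies must be finite")
        pts = set(zip(self.d1.tolist(), self.d2.tolist()))
        if len(pts) != self.d1.size:
            raise DataError("duplicate (d1, d2) points in scan")

    @property
    def n_points(self) -> int:
        return int(self.d1.size)

    @property
    def is_rectangular(self) -> bool:
        u1, u2 = np.unique(self.d1), np.unique(self.d2)
        return u1.size * u2.size == self.n_points

    def as_grid(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(d1 axis, d2 axis, E[len(d1), len(d2)]) for rectangular scans."""
        if not self.is_rectangular:
            raise DataError("scan is not a rectangular grid")
        u1, u2 = np.unique(self.d1), np.unique(self.d2)
        i1 = np.searchsorted(u1, self.d1)
        i2 = np.searchsorted(u2, self.d2)
        grid = np.full((u1.size, u2.size), np.nan)
        grid[i1, i2] = self.energy
        return u1, u2, grid


@dataclass
class Minimum:
    d1: float
    d2: float
    energy: float
    index: int  # flat index into the surface arrays
    label: str | None = None


@dataclass
class ConformerGapTable:
    """Energy gaps between labelled minima, relative to the most stable."""

    minima: list[Minimum]
    reference_state: str
    gaps: dict[str, float]  # state -> E(state) - E(reference)
    warnings: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "reference_state": self.reference_state,
                "gaps_kcal_mol": self.gaps,
                "minima": [
                    {
                        "d1": m.d1,
                        "d2": m.d2,
                        "energy_kcal_mol": m.energy,
                        "label": m.label,
                    }
                    for m in self.minima
                ],
                "warnings": self.warnings,
            },
            indent=2,
        )


def read_scan(path: str | Path) -> ScanSurface:
    """Read a scan CSV with columns d1, d2, E[, structure_path]."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise DataError(f"{path}: cannot parse CSV: {exc}") from exc
    for col in ("d1", "d2", "E"):
        if col not in df.columns:
            raise DataError(f"{path}: missing required column {col!r}")
    for col in ("d1", "d2", "E"):
        if not np.issubdtype(df[col].dtype, np.number):
            raise DataError(f"{path}: non-numeric values in column {col!r}")
    paths = (
        [str(p) for p in df["structure_path"]]
        if "structure_path" in df.columns
        else None
    )
    return ScanSurface(
        d1=df["d1"].to_numpy(),
        d2=df["d2"].to_numpy(),
        energy=df["E"].to_numpy(),
        structure_paths=paths,
    )


def write_scan(surface: ScanSurface, path: str | Path) -> None:
    data = {"d1": surface.d1, "d2": surface.d2, "E": surface.energy}
    if surface.structure_paths is not None:
        data["structure_path"] = surface.structure_paths
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.8f")


def _neighbor_lists(surface: ScanSurface) -> list[list[int]]:
    """8-neighbourhood on rectangular grids; symmetrized kNN otherwise."""
    n = surface.n_points
    if surface.is_rectangular:
        u1, u2 = np.unique(surface.d1), np.unique(surface.d2)
        i1 = np.searchsorted(u1, surface.d1)
        i2 = np.searchsorted(u2, surface.d2)
        where = {(int(a), int(b)): k for k, (a, b) in enumerate(zip(i1, i2))}
        out: list[list[int]] = []
        for k in range(n):
            a, b = int(i1[k]), int(i2[k])
            nbrs = [
                where[(a + da, b + db)]
                for da in (-1, 0, 1)
                for db in (-1, 0, 1)
                if (da, db) != (0, 0) and (a + da, b + db) in where
            ]
            out.append(nbrs)
        return out
    # ragged scan: symmetrized 8-nearest-neighbour graph
    pts = np.column_stack([surface.d1, surface.d2])
    k = min(9, n)
    _, idx = cKDTree(pts).query(pts, k=k)
    nbr_sets: list[set[int]] = [set() for _ in range(n)]
    for i in range(n):
        for j in np.atleast_1d(idx[i])[1:]:
            nbr_sets[int(i)].add(int(j))
            nbr_sets[int(j)].add(int(i))
    return [sorted(s) for s in nbr_sets]


def find_minima(surface: ScanSurface) -> list[Minimum]:
    """Local minima of the scan surface.

    A point is a minimum iff its energy is strictly below all existing
    neighbours (8-neighbourhood / Moore connectivity on rectangular
    grids).  Flat plateaus whose entire boundary is strictly higher
    count as one minimum, represented by the lexicographically smallest
    (d1, d2) member.
    """
    n = surface.n_points
    if n < 9:
        raise DataError(f"scan has only {n} points; need at least 9")
    nbrs = _neighbor_lists(surface)
    e = surface.energy
    minima: list[Minimum] = []
    visited = np.zeros(n, dtype=bool)
    for k in range(n):
        if visited[k]:
            continue
        # flood-fill the equal-energy plateau containing k
        plateau = [k]
        stack = [k]
        visited[k] = True
        is_min = True
        while stack:
            cur = stack.pop()
            for j in nbrs[cur]:
                if e[j] == e[cur] and not visited[j]:
                    visited[j] = True
                    plateau.append(j)
                    stack.append(j)
                elif e[j] < e[cur]:
                    is_min = False
        if is_min:
            rep = min(
                plateau, key=lambda i: (surface.d1[i], surface.d2[i])
            )
            minima.append(
                Minimum(
                    d1=float(surface.d1[rep]),
                    d2=float(surface.d2[rep]),
                    energy=float(e[rep]),
                    index=int(rep),
                )
            )
    minima.sort(key=lambda m: (m.energy, m.d1, m.d2))
    return minima


def conformer_gaps(
    minima: Sequence[Minimum],
    labels: Sequence[str] | None = None,
) -> ConformerGapTable:
    """Energy gaps dE(state - reference) between labelled minima.

    The reference is the state of the lowest-energy minimum.  If a state
    labels several minima, all are reported and the gap uses the lower
    energy (a recorded warning, not a hard failure).  A single minimum
    yields an empty gap table.
    """
    mins = list(minima)
    if labels is not None:
        if len(labels) != len(mins):
            raise DataError("one label per minimum required")
        mins = [
            Minimum(m.d1, m.d2, m.energy, m.index, label=str(lab))
            for m, lab in zip(mins, labels)
        ]
    if any(m.label is None for m in mins):
        raise DataError("every minimum needs a state label")
    if len(mins) == 0:
        raise DataError("no minima supplied")
    warnings: list[str] = []
    best: dict[str, Minimum] = {}
    for m in mins:
        if m.label in best:
            warnings.append(
                f"state {m.label!r} labels multiple minima; "
                "gap uses the lower-energy one"
            )
            if m.energy < best[m.label].energy:
                best[m.label] = m
        else:
            best[m.label] = m
    ref = min(best.values(), key=lambda m: m.energy)
    if len(best) < 2:
        gaps: dict[str, float] = {}
    else:
        gaps = {
            s: float(m.energy - ref.energy) for s, m in sorted(best.items())
        }
    return ConformerGapTable(
        minima=mins,
        reference_state=str(ref.label),
        gaps=gaps,
        warnings=warnings,
    )
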