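"""Molecular structures and lantern-cage topology perception.

A :class:`Structure` is a light container of element symbols, Cartesian
coordinates and (optionally perceived) bonds.  :func:`detect_topology`
recognises the [Pd2L4]4+ lantern architecture — two Pd(II) nodes bridged
by four identical bitopic N-donor ligands — and records, per ligand, the
two metal-coordinating nitrogens, the central aromatic ring and the
endo-facing atom (the central-ring member sitting between the two
arm-bearing ring atoms, pointing into the cavity).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .elements import BOND_SCALE, covalent_radius, is_known_element
from .errors import (
    AmbiguityError,
    FrameError,
    GeometryError,
    ParseError,
    TopologyError,
)

__all__ = [
    "Structure",
    "CageTopology",
    "read_structure",
    "write_xyz",
    "perceive_bonds",
    "detect_topology",
]


@dataclass
class Structure:
    """Elements + coordinates + bonds of a single molecular frame."""

    elements: list[str]
    coords: np.ndarray  # (N, 3) Angstrom
    bonds: set[tuple[int, int]] = field(default_factory=set)
    title: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be an (N, 3) array")
        if len(self.elements) != self.coords.shape[0]:
            raise ValueError("element and coordinate counts differ")
        if not np.isfinite(self.coords).all():
            raise ValueError("coordinates must be finite")
        n = self.n_atoms
        for i, j in self.bonds:
            if i == j:
                raise ValueError(f"self-bond on atom {i}")
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond index out of range: ({i}, {j})")
        self.bonds = {(min(i, j), max(i, j)) for i, j in self.bonds}

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def graph(self) -> nx.Graph:
        """Molecular graph with ``element`` node attributes."""
        g = nx.Graph()
        for i, el in enumerate(self.elements):
            g.add_node(i, element=el)
        g.add_edges_from(self.bonds)
        return g

    def select(self, indices: Sequence[int]) -> "Structure":
        """Sub-structure over *indices* (bonds re-indexed, order kept)."""
        idx = list(indices)
        remap = {old: new for new, old in enumerate(idx)}
        keep = set(idx)
        bonds = {
            (remap[i], remap[j])
            for i, j in self.bonds
            if i in keep and j in keep
        }
        return Structure(
            elements=[self.elements[i] for i in idx],
            coords=self.coords[idx].copy(),
            bonds=bonds,
            title=self.title,
        )

    def filtered(
        self,
        allowed_elements: Iterable[str] | None = None,
        excluded_elements: Iterable[str] | None = None,
    ) -> "Structure":
        """Atom-selection filter (counterion/solvent stripping).

        ``allowed_elements`` keeps only listed elements;
        ``excluded_elements`` drops listed ones.  Exactly the convention
        used to strip PF6-/solvent atoms before cage analysis.
        """
        allow = set(allowed_elements) if allowed_elements else None
        deny = set(excluded_elements) if excluded_elements else set()
        idx = [
            i
            for i, el in enumerate(self.elements)
            if (allow is None or el in allow) and el not in deny
        ]
        return self.select(idx)


@dataclass
class CageTopology:
    """Perceived [Pd2L4] lantern topology (0-based atom indices)."""

    pd_atoms: tuple[int, int]
    ligands: list[list[int]]
    coordinating_n: list[tuple[int, int]]
    central_rings: list[list[int]]
    endo_atoms: list[int]
    pd_axis: np.ndarray  # unit vector Pd1 -> Pd2

    def to_json(self, one_based: bool = True) -> str:
        """JSON report; indices are 1-based by default, stated in-band."""
        off = 1 if one_based else 0
        payload = {
            "index_base": off,
            "pd_atoms": [p + off for p in self.pd_atoms],
            "ligands": [[a + off for a in lig] for lig in self.ligands],
            "coordinating_n": [
                [a + off for a in pair] for pair in self.coordinating_n
            ],
            "central_rings": [
                [a + off for a in ring] for ring in self.central_rings
            ],
            "endo_atoms": [a + off for a in self.endo_atoms],
            "pd_axis": [float(x) for x in self.pd_axis],
        }
        return json.dumps(payload, indent=2)


# ---------------------------------------------------------------------------
# file IO


def _parse_xyz(path: Path) -> list[Structure]:
    lines = path.read_text().splitlines()
    frames: list[Structure] = []
    ln = 0
    n_expected: int | None = None
    while ln < len(lines):
        if not lines[ln].strip():
            ln += 1
            continue
        try:
            natoms = int(lines[ln].split()[0])
        except (ValueError, IndexError):
            raise ParseError(
                f"{path}: line {ln + 1}: expected atom count, got "
                f"{lines[ln]!r}"
            )
        if ln + 1 + natoms >= len(lines) + 1 and ln + 1 >= len(lines):
            raise ParseError(f"{path}: line {ln + 1}: truncated frame")
        title = lines[ln + 1] if ln + 1 < len(lines) else ""
        elements: list[str] = []
        coords: list[list[float]] = []
        for k in range(natoms):
            lineno = ln + 2 + k
            if lineno >= len(lines):
                raise ParseError(f"{path}: line {lineno + 1}: truncated frame")
            parts = lines[lineno].split()
            if len(parts) < 4:
                raise ParseError(
                    f"{path}: line {lineno + 1}: malformed atom line "
                    f"{lines[lineno]!r}"
                )
            sym = parts[0].capitalize()
            try:
                xyz = [float(p) for p in parts[1:4]]
            except ValueError:
                raise ParseError(
                    f"{path}: line {lineno + 1}: non-numeric coordinate in "
                    f"{lines[lineno]!r}"
                )
            elements.append(sym)
            coords.append(xyz)
        frames.append(Structure(elements, np.array(coords), title=title))
        ln += 2 + natoms
    if not frames:
        raise ParseError(f"{path}: no frames found")
    n_expected = frames[0].n_atoms
    for f_i, fr in enumerate(frames):
        if fr.n_atoms != n_expected:
            raise FrameError(
                f"{path}: frame {f_i} has {fr.n_atoms} atoms, expected "
                f"{n_expected}"
            )
    return frames


def _parse_pdb(path: Path, keep_resnames: set[str] | None) -> list[Structure]:
    import biotite.structure as bstruc
    import biotite.structure.io.pdb as bpdb

    try:
        pdb = bpdb.PDBFile.read(str(path))
        arr = pdb.get_structure(model=None)
    except Exception as exc:  # biotite raises plain/Invalid errors
        raise ParseError(f"{path}: PDB parse failed: {exc}") from exc
    if isinstance(arr, bstruc.AtomArray):
        arr = bstruc.stack([arr])
    frames: list[Structure] = []
    for model in arr:
        mask = np.ones(model.array_length(), dtype=bool)
        if keep_resnames is not None:
            mask = np.isin(model.res_name, sorted(keep_resnames))
        elements = [
            el.capitalize() for el in np.asarray(model.element)[mask]
        ]
        frames.append(
            Structure(elements, model.coord[mask], title=path.stem)
        )
    return frames


def read_structure(
    path: str | Path,
    fmt: str | None = None,
    keep_resnames: Iterable[str] | None = None,
) -> list[Structure]:
    """Read XYZ (single or multi-frame) or PDB into Structures.

    Parameters
    ----------
    path
        Input file.  Format inferred from the suffix unless *fmt* given.
    fmt
        ``"xyz"`` or ``"pdb"``.
    keep_resnames
        For PDB only: keep atoms whose residue name is listed (the
        cage-vs-solvent selection); ``None`` keeps everything.

    Returns
    -------
    list of Structure, one per frame.
    """
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    if fmt == "xyz":
        return _parse_xyz(path)
    if fmt == "pdb":
        keep = set(keep_resnames) if keep_resnames is not None else None
        return _parse_pdb(path, keep)
    raise ParseError(f"unsupported structure format: {fmt!r}")


def write_xyz(frames: Structure | Sequence[Structure], path: str | Path) -> None:
    """Write one or more frames as (multi-frame) XYZ.

    Coordinates are printed with 8 decimals so a write/read round trip
    is bit-stable at that precision.
    """
    if isinstance(frames, Structure):
        frames = [frames]
    out: list[str] = []
    for fr in frames:
        out.append(str(fr.n_atoms))
        out.append(fr.title.replace("\n", " "))
        for el, (x, y, z) in zip(fr.elements, fr.coords):
            out.append(f"{el:<3s} {x:16.8f} {y:16.8f} {z:16.8f}")
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# bond perception


def perceive_bonds(
    structure: Structure, scale: float = BOND_SCALE
) -> set[tuple[int, int]]:
    """Distance-based bond perception.

    Atoms i, j are bonded iff ``d(i, j) <= scale * (r_cov(i) + r_cov(j))``.
    Pd-N coordination bonds fall out of the same rule via the Pd covalent
    radius.  The structure's ``bonds`` attribute is replaced in place and
    the set is also returned.
    """
    radii = np.array([covalent_radius(el) for el in structure.elements])
    n = structure.n_atoms
    bonds: set[tuple[int, int]] = set()
    if n >= 2:
        tree = cKDTree(structure.coords)
        rmax = scale * 2.0 * radii.max()
        for i, j in tree.query_pairs(rmax):
            d = np.linalg.norm(structure.coords[i] - structure.coords[j])
            if d <= scale * (radii[i] + radii[j]):
                bonds.add((min(i, j), max(i, j)))
    structure.bonds = bonds
    return bonds


# ---------------------------------------------------------------------------
# topology perception


def _rings(graph: nx.Graph) -> list[list[int]]:
    # minimum cycle basis == SSSR for graphs whose rings are isolated
    return [sorted(c) for c in nx.minimum_cycle_basis(graph)]


def detect_topology(structure: Structure) -> CageTopology:
    """Perceive the Pd2L4 lantern topology of a (pre-filtered) cage.

    Requires exactly two Pd atoms; removing them must leave four
    connected components of identical elemental composition (the
    ligands).  The central ring of a ligand is the unique perceived ring
    containing neither Pd-coordinating nitrogen; the endo atom is the
    central-ring member bonded to both arm-bearing ring atoms.
    """
    if not structure.bonds:
        perceive_bonds(structure)
    for el in structure.elements:
        if not is_known_element(el):
            raise TopologyError(f"unknown element {el!r} in structure")
    pd = [i for i, el in enumerate(structure.elements) if el == "Pd"]
    if len(pd) != 2:
        raise TopologyError(f"expected exactly 2 Pd atoms, found {len(pd)}")
    g = structure.graph()
    g_lig = g.copy()
    g_lig.remove_nodes_from(pd)
    comps = [sorted(c) for c in nx.connected_components(g_lig)]
    if len(comps) != 4:
        raise TopologyError(
            f"expected 4 ligand components after Pd removal, found "
            f"{len(comps)}"
        )
    comps.sort()
    compositions = {
        tuple(sorted(structure.elements[i] for i in comp)) for comp in comps
    }
    if len(compositions) != 1:
        raise TopologyError("ligand components have unequal composition")

    pd_neighbors = {p: set(g.neighbors(p)) for p in pd}
    coordinating: list[tuple[int, int]] = []
    central_rings: list[list[int]] = []
    endo_atoms: list[int] = []
    for comp in comps:
        comp_set = set(comp)
        coord_n = sorted(
            a
            for a in comp
            if structure.elements[a] == "N"
            and any(a in pd_neighbors[p] for p in pd)
        )
        if len(coord_n) != 2:
            raise TopologyError(
                f"ligand has {len(coord_n)} Pd-coordinating N atoms, "
                "expected 2"
            )
        sub = g.subgraph(comp_set)
        rings = _rings(sub)
        centrals = [
            r for r in rings if not (set(r) & set(coord_n))
        ]
        if len(centrals) != 1:
            raise AmbiguityError(
                f"no unique central ring (found {len(centrals)} candidates)"
            )
        ring = centrals[0]
        ring_set = set(ring)
        # arm-bearing ring atoms: bonded to a non-H atom outside the ring
        bearers = [
            a
            for a in ring
            if any(
                (nb not in ring_set) and structure.elements[nb] != "H"
                for nb in sub.neighbors(a)
            )
        ]
        if len(bearers) != 2:
            raise AmbiguityError(
                f"central ring has {len(bearers)} arm-bearing atoms, "
                "expected 2"
            )
        endo = [
            a
            for a in ring
            if a not in bearers
            and all(b in set(sub.neighbors(a)) for b in bearers)
        ]
        if len(endo) != 1:
            raise AmbiguityError("no unique endo atom on the central ring")
        coordinating.append((coord_n[0], coord_n[1]))
        central_rings.append(ring)
        endo_atoms.append(endo[0])

    axis = structure.coords[pd[1]] - structure.coords[pd[0]]
    norm = np.linalg.norm(axis)
    if norm < 1e-9:
        raise GeometryError("Pd atoms coincide; no axis")
    return CageTopology(
        pd_atoms=(pd[0], pd[1]),
        ligands=[list(c) for c in comps],
        coordinating_n=coordinating,
        central_rings=central_rings,
        endo_atoms=endo_atoms,
        pd_axis=axis / norm,
    )
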