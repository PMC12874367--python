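"""Symmetry-class grouping, charge averaging and model comparison."""

import itertools

import networkx as nx
import numpy as np
import pytest

from cageconform import (
    ChargeSet,
    average_charges,
    compare_charge_models,
    equivalence_classes,
    gen_charges,
    ligand_graph_structure,
    read_charge_csv,
    write_charge_csv,
)
from cageconform.errors import DataError, GraphError
from cageconform.symmetry import substitute_mol2_charges


def _graph(elements, edges):
    g = nx.Graph()
    for i, el in enumerate(elements):
        g.add_node(i, element=el)
    g.add_edges_from(edges)
    return g


def benzene():
    ring = [(i, (i + 1) % 6) for i in range(6)]
    hs = [(i, i + 6) for i in range(6)]
    return _graph(["C"] * 6 + ["H"] * 6, ring + hs)


def automorphism_orbits(g):
    """True orbits via explicit automorphism enumeration (VF2)."""
    gm = nx.algorithms.isomorphism.GraphMatcher(
        g, g, node_match=lambda a, b: a["element"] == b["element"]
    )
    orbit_of = {i: frozenset([i]) for i in g.nodes}
    for mapping in gm.isomorphisms_iter():
        for i, j in mapping.items():
            if orbit_of[i] is not orbit_of[j]:
                merged = orbit_of[i] | orbit_of[j]
                for k in merged:
                    orbit_of[k] = merged
    return {frozenset(o) for o in orbit_of.values()}


def brute_force_orbits(g):
    """Permutation-search oracle (only viable for tiny graphs)."""
    nodes = sorted(g.nodes)
    edges = {frozenset(e) for e in g.edges}
    els = {i: g.nodes[i]["element"] for i in nodes}
    orbit_of = {i: frozenset([i]) for i in nodes}
    for perm in itertools.permutations(nodes):
        mapping = dict(zip(nodes, perm))
        if any(els[i] != els[mapping[i]] for i in nodes):
            continue
        if {frozenset((mapping[a], mapping[b])) for a, b in g.edges} != edges:
            continue
        for i in nodes:
            j = mapping[i]
            if orbit_of[i] is not orbit_of[j]:
                merged = orbit_of[i] | orbit_of[j]
                for k in merged:
                    orbit_of[k] = merged
    return {frozenset(o) for o in orbit_of.values()}


SMALL_GRAPHS = {
    "benzene": benzene(),
    "water": _graph(["O", "H", "H"], [(0, 1), (0, 2)]),
    "methane": _graph(["C"] + ["H"] * 4, [(0, i) for i in range(1, 5)]),
    "propane_heavy": _graph(["C", "C", "C"], [(0, 1), (1, 2)]),
    "pyridine_heavy": _graph(
        ["N", "C", "C", "C", "C", "C"], [(i, (i + 1) % 6) for i in range(6)]
    ),
    "cyclooctane_heavy": _graph(["C"] * 8, [(i, (i + 1) % 8) for i in range(8)]),
    "star": _graph(["N"] + ["C"] * 5, [(0, i) for i in range(1, 6)]),
    "bipyramid": _graph(
        ["C"] * 5,
        [(0, 2), (0, 3), (0, 4), (1, 2), (1, 3), (1, 4), (2, 3), (3, 4), (2, 4)],
    ),
    "ethanol_like": _graph(
        ["C", "C", "O", "H", "H", "H", "H", "H", "H"],
        [(0, 1), (1, 2), (0, 3), (0, 4), (0, 5), (1, 6), (1, 7), (2, 8)],
    ),
}


class TestEquivalenceClasses:
    def test_benzene_two_classes(self):
        p = equivalence_classes(benzene())
        assert p.n_classes == 2
        sizes = sorted(len(c) for c in p.classes)
        assert sizes == [6, 6]

    @pytest.mark.parametrize("analog, expected", [("endo-C", 19), ("endo-N", 18)])
    def test_ligand_group_counts(self, analog, expected):
        lig = ligand_graph_structure(analog)
        assert equivalence_classes(lig).n_classes == expected

    @pytest.mark.parametrize("name", sorted(SMALL_GRAPHS))
    def test_refinement_equals_automorphism_orbits(self, name):
        g = SMALL_GRAPHS[name]
        p = equivalence_classes(g, require_connected=False)
        got = {frozenset(c) for c in p.classes}
        assert got == automorphism_orbits(g)
        if g.number_of_nodes() <= 8:
            assert got == brute_force_orbits(g)

    def test_ligand_classes_match_rdkit_symmetry_classes(self):
        rdkit = pytest.importorskip("rdkit")
        from rdkit import Chem

        smiles = {
            "endo-C": "c1cc(C#Cc2cccnc2)cc(C#Cc2cccnc2)c1",
            "endo-N": "c1cc(C#Cc2cccnc2)nc(C#Cc2cccnc2)c1",
        }
        for analog, smi in smiles.items():
            mol = Chem.AddHs(Chem.MolFromSmiles(smi))
            ranks = list(Chem.CanonicalRankAtoms(mol, breakTies=False))
            lig = ligand_graph_structure(analog)
            ours = equivalence_classes(lig)
            assert ours.n_classes == len(set(ranks))

    def test_invariant_under_permutation(self, rng):
        lig = ligand_graph_structure("endo-C")
        p_ref = equivalence_classes(lig)
        n = lig.n_atoms
        perm = rng.permutation(n)
        shuffled = lig.select(list(perm))
        p_new = equivalence_classes(shuffled)
        assert p_new.class_labels == p_ref.class_labels
        remapped = {
            frozenset(int(perm[a]) for a in cls) for cls in p_new.classes
        }
        assert remapped == {frozenset(c) for c in p_ref.classes}

    def test_disconnected_graph_rejected(self):
        g = _graph(["C", "C"], [])
        with pytest.raises(GraphError, match="disconnected"):
            equivalence_classes(g)


class TestAverageCharges:
    def test_pair_class_mean(self):
        g = _graph(["C", "C"], [(0, 1)])
        p = equivalence_classes(g)
        out = average_charges(ChargeSet("ESP", np.array([0.1, 0.3])), p)
        assert out.charges == pytest.approx([0.2, 0.2])
        assert out.averaged

    def test_idempotent_and_conserves_total(self):
        lig = ligand_graph_structure("endo-C")
        p = equivalence_classes(lig)
        rng = np.random.default_rng(7)
        cs = ChargeSet("RESP", rng.normal(0, 0.3, lig.n_atoms))
        once = average_charges(cs, p)
        twice = average_charges(once, p)
        assert abs(once.total - cs.total) < 1e-12
        np.testing.assert_array_equal(once.charges, twice.charges)

    def test_recovers_fixture_class_means(self):
        lig = ligand_graph_structure("endo-C")
        p = equivalence_classes(lig)
        rng = np.random.default_rng(7)
        means = rng.uniform(-0.5, 0.5, p.n_classes)
        sizes = np.array([len(c) for c in p.classes])
        net = float(means @ sizes)  # correction term carries noise only
        sigma = 0.02
        cs = gen_charges(p, means, sigma=sigma, seed=7, net_charge=net)
        avg = average_charges(cs, p)
        assert abs(avg.total - net) < 1e-12
        for k, cls in enumerate(p.classes):
            se = 3 * sigma / np.sqrt(len(cls)) + 3 * sigma / np.sqrt(p.n_atoms)
            assert abs(avg.charges[cls[0]] - means[k]) < se

    def test_length_mismatch_raises(self):
        g = _graph(["C", "C"], [(0, 1)])
        p = equivalence_classes(g)
        with pytest.raises(DataError):
            average_charges(ChargeSet("ESP", np.zeros(3)), p)


class TestCompareChargeModels:
    def _partition(self):
        return equivalence_classes(benzene())

    def test_identical_sets_zero_range(self):
        p = self._partition()
        q = np.linspace(-0.1, 0.1, 12)
        df = compare_charge_models(
            [ChargeSet("ESP", q), ChargeSet("RESP", q.copy())], p
        )
        assert (df["cross_model_range"] == 0).all()

    def test_uniform_offset_range(self):
        p = self._partition()
        df = compare_charge_models(
            [ChargeSet("ESP", np.zeros(12)), ChargeSet("MUL", np.full(12, 0.1))],
            p,
        )
        assert df["cross_model_range"].to_numpy() == pytest.approx(0.1)

    def test_wider_model_has_larger_spread(self):
        lig = ligand_graph_structure("endo-C")
        p = equivalence_classes(lig)
        rng = np.random.default_rng(11)
        base = rng.uniform(-0.3, 0.3, p.n_classes)
        resp = gen_charges(p, base, sigma=0.0, seed=1, net_charge=1.0, model="RESP")
        mul = gen_charges(p, base * 2.5, sigma=0.0, seed=2, net_charge=1.0, model="MUL")
        df = compare_charge_models([resp, mul], p)
        spread = df.attrs["model_spread"]
        assert spread["MUL"] > spread["RESP"]


class TestChargeIO:
    def test_csv_round_trip(self, tmp_path):
        lig = ligand_graph_structure("endo-N")
        p = equivalence_classes(lig)
        rng = np.random.default_rng(3)
        sets = [
            gen_charges(p, rng.normal(0, 0.2, p.n_classes), sigma=0.01,
                        seed=rng, net_charge=1.0, model=m)
            for m in ("ESP", "RESP", "MUL", "NBO")
        ]
        path = tmp_path / "charges.csv"
        write_charge_csv(path, lig.elements, sets)
        elements, back = read_charge_csv(path)
        assert elements == lig.elements
        assert [cs.model for cs in back] == ["ESP", "RESP", "MUL", "NBO"]
        for a, b in zip(sets, back):
            np.testing.assert_allclose(b.charges, a.charges, atol=5e-10)

    def test_mol2_substitution_bit_exact_elsewhere(self, tmp_path):
        template = "\n".join(
            [
                "@<TRIPOS>MOLECULE",
                "tiny",
                " 2 1 0 0 0",
                "SMALL",
                "USER_CHARGES",
                "@<TRIPOS>ATOM",
                "      1 C1     0.0000   0.0000   0.0000 C.3   1 LIG 0.123456",
                "      2 H1     1.0900   0.0000   0.0000 H     1 LIG -0.123456",
                "@<TRIPOS>BOND",
                "     1    1    2 1",
            ]
        )
        src = tmp_path / "in.mol2"
        dst = tmp_path / "out.mol2"
        src.write_text(template)
        substitute_mol2_charges(
            src, ChargeSet("ESP", np.array([0.25, -0.25])), dst
        )
        out_lines = dst.read_text().split("\n")
        in_lines = template.split("\n")
        assert out_lines[:6] == in_lines[:6]
        assert out_lines[8:] == in_lines[8:]
        assert out_lines[6].endswith("0.250000")
        assert out_lines[7].endswith("-0.250000")
        assert out_lines[6].rsplit(" ", 1)[0] == in_lines[6].rsplit(" ", 1)[0]
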