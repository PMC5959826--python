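"""Bond perception, the metal-metal window, order and charge conventions."""

import math

import numpy as np
import pytest

from cif2smiles.bonds import (BondPolicy, apply_metal_metal_policy,
                              assign_bond_orders, assign_formal_charges,
                              merge_geom_bonds, perceive_bonds,
                              perceive_aromaticity)
from cif2smiles.canon import canonical_form, canonical_smiles
from cif2smiles.smiles import GraphAtom, MolecularGraph, parse_smiles
from cif2smiles.smiles import write_smiles


class P:
    def __init__(self, element, xyz):
        self.element = element
        self.cart = np.asarray(xyz, float)


def test_distance_rule_arithmetic():
    # C-C radii 0.76+0.76 with offset 0.40 -> cutoff 1.92
    assert perceive_bonds([P("C", (0, 0, 0)), P("C", (1.50, 0, 0))]) == {(0, 1)}
    assert perceive_bonds([P("C", (0, 0, 0)), P("C", (2.00, 0, 0))]) == set()


def test_hydrogen_bonds_single_nearest_heavy():
    atoms = [P("O", (0, 0, 0)), P("H", (0.97, 0, 0)), P("O", (1.95, 0, 0))]
    pairs = perceive_bonds(atoms)
    assert (0, 1) in pairs and (1, 2) not in pairs


def test_perception_is_order_invariant():
    atoms = [P("C", (0, 0, 0)), P("O", (1.2, 0, 0)), P("H", (-1.0, 0.3, 0))]
    fwd = perceive_bonds(atoms)
    rev = perceive_bonds(atoms[::-1])
    n = len(atoms)
    assert {(n - 1 - j, n - 1 - i) for i, j in fwd} == rev


@pytest.mark.parametrize("d,listed,expected", [
    (2.50, False, True),     # short transition-metal contact: bonded
    (2.95, True, True),      # borderline: authors' criterion accepted
    (2.95, False, False),
])
def test_metal_metal_window(d, listed, expected):
    atoms = [P("Fe", (0, 0, 0)), P("Fe", (d, 0, 0))]
    pairs = apply_metal_metal_policy(set(), atoms,
                                     {(0, 1)} if listed else set())
    assert ((0, 1) in pairs) == expected


def test_long_supported_contact_removed():
    # Cu-Cu 3.2 A bridged by an O bonded to both: disregarded
    atoms = [P("Cu", (0, 0, 0)), P("Cu", (3.2, 0, 0)), P("O", (1.6, 1.2, 0))]
    pairs = {(0, 1), (0, 2), (1, 2)}
    out = apply_metal_metal_policy(pairs, atoms, set())
    assert (0, 1) not in out and (0, 2) in out


def test_merge_modes():
    perceived = {(0, 1)}
    listed = {(0, 1), (1, 2)}
    merged, origins = merge_geom_bonds(perceived, listed, "merged")
    assert merged == {(0, 1), (1, 2)}
    assert origins[(1, 2)] == "cif_listed" and origins[(0, 1)] == "distance"
    only_p, _ = merge_geom_bonds(perceived, listed, "perceived")
    assert only_p == perceived
    only_g, _ = merge_geom_bonds(perceived, listed, "geom")
    assert only_g == listed
    empty, _ = merge_geom_bonds(perceived, set(), "merged")
    assert empty == perceived


def graph_from_spec(atoms, bonds):
    g = MolecularGraph()
    for el, h in atoms:
        g.add_atom(GraphAtom(el, explicit_h=h))
    for i, j in bonds:
        g.add_bond(i, j, 1)
    return g


def finish(g):
    leftover = assign_bond_orders(g)
    assign_formal_charges(g, leftover)
    perceive_aromaticity(g)
    return g


def test_terminal_carbonyl_convention():
    g = graph_from_spec([("Ni", 0)] + [("C", 0), ("O", 0)] * 4,
                        [(0, 1), (1, 2), (0, 3), (3, 4), (0, 5), (5, 6),
                         (0, 7), (7, 8)])
    finish(g)
    assert canonical_smiles(g) == canonical_form(
        "[Ni](C#[O])(C#[O])(C#[O])C#[O]")


def test_bridging_carbonyl_is_ketone_like():
    g = graph_from_spec([("Co", 0), ("Co", 0), ("C", 0), ("O", 0)],
                        [(0, 2), (1, 2), (2, 3)])
    finish(g)
    assert g.order(2, 3) == 2


def test_sulfate_like_oxoanion():
    g = graph_from_spec([("S", 0)] + [("O", 0)] * 4,
                        [(0, 1), (0, 2), (0, 3), (0, 4)])
    finish(g)
    orders = sorted(g.order(0, j) for j in (1, 2, 3, 4))
    assert orders == [1, 1, 2, 2]
    charges = sorted(a.charge for a in g.atoms)
    assert charges == [-1, -1, 0, 0, 0]


def test_nitro_written_uncharged():
    g = graph_from_spec([("C", 3), ("N", 0), ("O", 0), ("O", 0)],
                        [(0, 1), (1, 2), (1, 3)])
    finish(g)
    assert canonical_smiles(g) == canonical_form("CN(=O)=O")


def test_aromaticity_verdicts_from_kekule():
    """Published aromatic/non-aromatic choices, from Kekule input graphs."""
    cases = [
        # (kekule input, expected final form)
        ("C1=CC=CC=C1", "c1ccccc1"),
        ("C1(=O)C=CC=C1", "c1(=O)cccc1"),
        ("O=C1C=CC(=O)C=C1", "O=C1C=CC(=O)C=C1"),
        ("C1(=O)C=CC(=C)C=C1", "C1(=O)C=CC(=C)C=C1"),
        ("C(=C)1C2=CC=CC=C2C2=CC=CC=C12",
         "c12ccccc1C(=C)c1ccccc12"),                 # 9-methylene-fluorene
        ("C1(=O)NC(=O)NC=C1", "C1(=O)NC(=O)NC=C1"),  # uracil stays Kekule
    ]
    for kek, want in cases:
        g = parse_smiles(kek)
        perceive_aromaticity(g)
        assert canonical_smiles(g) == canonical_form(want), kek


def test_fullerene_wholesale_aromatic():
    g = c60_graph()
    perceive_aromaticity(g)
    assert all(a.aromatic for a in g.atoms)
    assert len(g) == 60 and all(g.degree(i) == 3 for i in range(60))


def c60_graph():
    phi = (1 + math.sqrt(5)) / 2
    base = [(0.0, 1.0, 3 * phi), (1.0, 2 + phi, 2 * phi),
            (phi, 2.0, 2 * phi + 1)]
    pts = set()
    for x, y, z in base:
        for sx in (1, -1):
            for sy in (1, -1):
                for sz in (1, -1):
                    for p in ((x * sx, y * sy, z * sz),
                              (z * sz, x * sx, y * sy),
                              (y * sy, z * sz, x * sx)):
                        pts.add(tuple(round(v, 6) for v in p))
    pts = sorted(pts)
    assert len(pts) == 60
    g = MolecularGraph()
    for p in pts:
        g.add_atom(GraphAtom("C", cart=np.array(p)))
    dists = []
    for i in range(60):
        for j in range(i + 1, 60):
            d = np.linalg.norm(np.array(pts[i]) - np.array(pts[j]))
            dists.append((d, i, j))
    dists.sort()
    for d, i, j in dists[:90]:          # truncated icosahedron: 90 edges
        g.add_bond(i, j, 1)
    return g


def test_neutral_fixture_charges_sum_to_zero(pipeline_results, fixture_set):
    for name, res in pipeline_results.items():
        if isinstance(res, Exception) or res.built is None:
            continue
        tags = fixture_set[name].tags
        if "ionic" in tags:              # counter-ion conventions differ
            continue
        total = sum(a.charge for a in res.built.graph.atoms)
        assert total == 0, name


def test_standard_valence_invariant(pipeline_results):
    """Organic-subset atoms written without brackets hit a standard valence."""
    from cif2smiles.elements import ORGANIC_SUBSET, STANDARD_VALENCES
    from cif2smiles.smiles import AROMATIC_BOND, _needs_bracket
    for name, res in pipeline_results.items():
        if isinstance(res, Exception) or res.built is None:
            continue
        g = res.built.graph
        for i, a in enumerate(g.atoms):
            if a.element not in ORGANIC_SUBSET or a.aromatic or a.charge:
                continue
            if g.has_metal_neighbor(i) or _needs_bracket(g, i):
                continue
            total = a.explicit_h + sum(
                o for j, o in g._adj[i].items()
                if o != AROMATIC_BOND)
            assert total in STANDARD_VALENCES[a.element], (
                name, i, a.element, total)
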