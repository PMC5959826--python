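"""Discrepancy classification between two SMILES for the same entry.

Categories run from "identical" to "different chemical composition" in
increasing severity; a pair showing several discrepancies is reported
under the most severe one only.  Each category is operationalized as a
graph-normalization equivalence: the two strings are compared after
progressively forgetting explicit H counts, stereo marks, motif depictions
(nitro/azide/N-oxide), charges, aromatic flags, bond orders and finally
connectivity, and the first (most severe) difference that survives wins.
"""

from __future__ import annotations

import math
from enum import IntEnum

import pandas as pd

from .canon import canonical_smiles
from .elements import METALS
from .smiles import (AROMATIC_BOND, MolecularGraph, SmilesError,
                     parse_smiles)

__all__ = ["DiscrepancyCategory", "classify_discrepancy", "summarize"]


class DiscrepancyCategory(IntEnum):
    """Least (0) to most severe, matching the published taxonomy order."""
    identical = 0
    missing_double_bond_config_in_other = 1
    different_explicit_H_count = 2
    missing_chirality_in_other = 3
    missing_chirality_in_ours = 4
    racemate_representation = 5
    nitro_representation = 6
    other_group_representation = 7
    charge_settings = 8
    aromaticity_settings = 9
    bond_orders = 10
    ionic_representation = 11
    missing_O_moieties_in_other = 12
    different_connectivity = 13
    ring_count = 14
    moiety_count = 15
    double_bond_config_differs = 16
    chiral_config_differs = 17
    missing_moieties_in_other = 18
    missing_moieties_in_ours = 19
    missing_C_in_other = 20
    missing_C_in_ours = 21
    stoichiometry = 22
    chemical_composition = 23
    other_reason = 24


# -- normalization helpers ---------------------------------------------------

def _strip_stereo(g: MolecularGraph) -> MolecularGraph:
    g = g.copy()
    for a in g.atoms:
        a.parity = a.parity_ref = None
    return g


def _strip_h(g: MolecularGraph) -> MolecularGraph:
    g = g.copy()
    for a in g.atoms:
        a.explicit_h = 0
        a.parity = a.parity_ref = None
        a.kekule_pi = a.aromatic     # normalize representation metadata
    return g


def _strip_charges(g: MolecularGraph) -> MolecularGraph:
    g = _strip_h(g)
    for a in g.atoms:
        a.charge = 0
    return g


def _skeleton(g: MolecularGraph, keep_aromatic: bool) -> MolecularGraph:
    g = _strip_charges(g)
    for i, j, o in list(g.bonds()):
        g.set_order(i, j, 1)
    if not keep_aromatic:
        for a in g.atoms:
            a.aromatic = False
            a.kekule_pi = False
    return g


def _normalize_nitro(g: MolecularGraph) -> MolecularGraph:
    """[O-][N+](=O) and O=N(=O) collapse onto one depiction."""
    g = g.copy()
    for i, a in enumerate(g.atoms):
        if a.element != "N":
            continue
        terms = [j for j in g.neighbors(i)
                 if g.atoms[j].element == "O" and g.degree(j) == 1
                 and not g.atoms[j].explicit_h]
        if len(terms) >= 2:
            for j in terms:
                g.set_order(i, j, 2)
                g.atoms[j].charge = 0
            a.charge = 0
    return g


def _normalize_other_groups(g: MolecularGraph) -> MolecularGraph:
    """Azide/diazo/N-oxide depiction differences (documented, extensible)."""
    g = g.copy()
    for i, a in enumerate(g.atoms):
        if a.element != "N":
            continue
        # N-oxide: terminal O on N -> neutral double bond
        terms = [j for j in g.neighbors(i)
                 if g.atoms[j].element == "O" and g.degree(j) == 1
                 and not g.atoms[j].explicit_h]
        for j in terms:
            g.set_order(i, j, 2)
            g.atoms[j].charge = 0
        # azide / diazo chains: neutralize and cumulate
        nn = [j for j in g.neighbors(i) if g.atoms[j].element == "N"]
        for j in nn:
            if g.degree(j) <= 2:
                g.set_order(i, j, 2)
                g.atoms[j].charge = 0
        if terms or nn:
            a.charge = 0
    return _normalize_nitro(g)


def _canon(g: MolecularGraph) -> str:
    return canonical_smiles(g)


def _moiety_graphs(g: MolecularGraph):
    return [g.subgraph(m) for m in g.moiety_indices()]


def _n_marks(g: MolecularGraph) -> int:
    return sum(1 for a in g.atoms if a.parity is not None)


def _cycle_rank(g: MolecularGraph) -> int:
    n_edges = sum(1 for _ in g.bonds())
    return n_edges - len(g.atoms) + len(g.moiety_indices())


def _racemate_related(ga: MolecularGraph, gb: MolecularGraph) -> bool:
    """One side holds an enantiomer pair, the other one copy of it."""
    if _n_marks(ga) == 0 and _n_marks(gb) == 0:
        return False
    for two, one in ((ga, gb), (gb, ga)):
        mois = _moiety_graphs(two)
        if len(mois) != 2:
            continue
        a, b = mois
        if canonical_smiles(a) != canonical_smiles(b.mirrored()):
            continue
        other_mois = _moiety_graphs(one)
        if len(other_mois) != 1:
            continue
        target = canonical_smiles(_strip_stereo(other_mois[0]))
        if canonical_smiles(_strip_stereo(a)) == target:
            return True
    return False


def _ionic_related(ga: MolecularGraph, gb: MolecularGraph) -> bool:
    """Same composition; one side shows bare metal ions where the other
    keeps the metal bonded."""
    def metal_free(g):
        keep = [i for i, a in enumerate(g.atoms) if a.element not in METALS]
        return canonical_smiles(_skeleton(g.subgraph(keep), False))

    def bare_metals(g):
        return sorted(a.element for m in g.moiety_indices() if len(m) == 1
                      for a in [g.atoms[m[0]]] if a.element in METALS)

    if bare_metals(ga) == bare_metals(gb):
        return False
    return metal_free(ga) == metal_free(gb)


def classify_discrepancy(ours: str, other: str) -> DiscrepancyCategory:
    """Single most severe discrepancy between two SMILES strings."""
    try:
        ga = parse_smiles(ours)
        gb = parse_smiles(other)
    except SmilesError:
        return DiscrepancyCategory.other_reason

    if canonical_smiles(ga) == canonical_smiles(gb):
        return DiscrepancyCategory.identical

    ca = ga.element_counts(with_h=False)
    cb = gb.element_counts(with_h=False)

    if ca != cb:
        diff_elems = {e for e in set(ca) | set(cb) if ca.get(e, 0) != cb.get(e, 0)}
        if diff_elems == {"C"}:
            return (DiscrepancyCategory.missing_C_in_other
                    if ca.get("C", 0) > cb.get("C", 0)
                    else DiscrepancyCategory.missing_C_in_ours)
        if _racemate_related(ga, gb):
            return DiscrepancyCategory.racemate_representation
        if diff_elems == {"O"} and _missing_o_moieties(ga, gb):
            return DiscrepancyCategory.missing_O_moieties_in_other
        if _missing_moieties(ga, gb):
            return DiscrepancyCategory.missing_moieties_in_other
        if _missing_moieties(gb, ga):
            return DiscrepancyCategory.missing_moieties_in_ours
        if _same_ratios(ca, cb):
            return DiscrepancyCategory.stoichiometry
        return DiscrepancyCategory.chemical_composition

    # same heavy-element composition
    if _racemate_related(ga, gb):
        return DiscrepancyCategory.racemate_representation
    if len(ga.moiety_indices()) != len(gb.moiety_indices()):
        if _ionic_related(ga, gb):
            return DiscrepancyCategory.ionic_representation
        return DiscrepancyCategory.moiety_count
    if _cycle_rank(ga) != _cycle_rank(gb):
        return DiscrepancyCategory.ring_count
    if _canon(_skeleton(ga, False)) != _canon(_skeleton(gb, False)):
        if _ionic_related(ga, gb):
            return DiscrepancyCategory.ionic_representation
        return DiscrepancyCategory.different_connectivity

    # identical skeleton from here on
    if _canon(_normalize_nitro(_strip_h(ga))) == _canon(
            _normalize_nitro(_strip_h(gb))):
        pass_nitro = True
    else:
        pass_nitro = False
    if _canon(_skeleton(ga, True)) != _canon(_skeleton(gb, True)):
        if not pass_nitro and _canon(_normalize_other_groups(ga)) == _canon(
                _normalize_other_groups(gb)):
            return DiscrepancyCategory.other_group_representation
        return DiscrepancyCategory.aromaticity_settings
    if _canon(_strip_charges(ga)) != _canon(_strip_charges(gb)):
        if pass_nitro:
            return DiscrepancyCategory.nitro_representation
        if _canon(_normalize_other_groups(ga)) == _canon(
                _normalize_other_groups(gb)):
            return DiscrepancyCategory.other_group_representation
        return DiscrepancyCategory.bond_orders
    if _canon(_strip_h(ga)) != _canon(_strip_h(gb)):
        if pass_nitro:
            return DiscrepancyCategory.nitro_representation
        if _canon(_normalize_other_groups(ga)) == _canon(
                _normalize_other_groups(gb)):
            return DiscrepancyCategory.other_group_representation
        return DiscrepancyCategory.charge_settings

    # same graph up to H and stereo
    na, nb = _n_marks(ga), _n_marks(gb)
    if _canon(_strip_stereo(ga)) == _canon(_strip_stereo(gb)):
        if na and not nb:
            return DiscrepancyCategory.missing_chirality_in_other
        if nb and not na:
            return DiscrepancyCategory.missing_chirality_in_ours
        if na and nb:
            return DiscrepancyCategory.chiral_config_differs
        return DiscrepancyCategory.different_explicit_H_count
    return DiscrepancyCategory.different_explicit_H_count


def _same_ratios(ca: dict, cb: dict) -> bool:
    if set(ca) != set(cb):
        return False
    items = sorted(ca)
    va = [ca[e] for e in items]
    vb = [cb[e] for e in items]
    ga, gb = math.gcd(*va) if len(va) > 1 else va[0], \
        math.gcd(*vb) if len(vb) > 1 else vb[0]
    return [v // ga for v in va] == [v // gb for v in vb]


def _missing_o_moieties(ga, gb) -> bool:
    """Extra isolated-O (water) moieties on our side only."""
    extra = [m for m in _moiety_graphs(ga)
             if all(a.element == "O" for a in m.atoms)]
    return bool(extra) and ga.element_counts(False).get("O", 0) > \
        gb.element_counts(False).get("O", 0)


def _missing_moieties(ga, gb) -> bool:
    """ga has a moiety type entirely absent from gb (not mere duplication)."""
    a = {canonical_smiles(_strip_stereo(m)) for m in _moiety_graphs(ga)}
    b = {canonical_smiles(_strip_stereo(m)) for m in _moiety_graphs(gb)}
    return bool(a - b) and b <= a


_ROW_ORDER = [c for c in DiscrepancyCategory]


def summarize(classifications) -> pd.DataFrame:
    """Counts and percentages per category, least to most severe."""
    counts = {c: 0 for c in _ROW_ORDER}
    for c in classifications:
        counts[DiscrepancyCategory(c)] += 1
    total = sum(counts.values())
    rows = [{"category": c.name, "count": counts[c],
             "percent": (100.0 * counts[c] / total) if total else 0.0}
            for c in _ROW_ORDER]
    return pd.DataFrame(rows)
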