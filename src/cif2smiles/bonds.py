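"""Bond perception from geometry and bond-order/aromaticity conventions.

Distance-based perception uses the covalent-radius-sum-plus-offset rule.
Bond orders are then placed by maximum matching over unsaturated atom
pairs so that organic-subset atoms reach a standard valence, followed by
convention overrides for metal carbonyls/isocyanides, hypervalent
oxoanions and metal-bound donors.  Aromaticity follows Hueckel's rule for
plain rings; rings carrying exocyclic double bonds are aromatic exactly
when an in-ring single bond flanked by two in-ring double bonds survives
(doubles owned by an already-aromatic ring do not count), which keeps
quinones and the central anthraquinone ring non-aromatic while
cyclopentadienone and 2-pyridone stay aromatic.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .elements import (ALKALI, ALKALINE_EARTH, COVALENT_RADIUS, HALOANION_CENTERS,
                       HALOGENS, HYPERVALENT_MAX, ORGANIC_SUBSET,
                       STANDARD_VALENCES, TRANSITION_METALS)
from .smiles import AROMATIC_BOND, MolecularGraph

logger = logging.getLogger(__name__)

__all__ = ["BondPolicy", "perceive_bonds", "merge_geom_bonds",
           "apply_metal_metal_policy", "assign_bond_orders",
           "perceive_aromaticity", "assign_formal_charges", "RingAnalysis"]


@dataclass
class BondPolicy:
    """Tunable parameters of geometric bond perception."""

    offset: float = 0.40                 # A added to the radius sum
    mm_bond_max: float = 2.85            # transition-metal pair: always bond
    mm_reject_min: float = 3.0           # beyond this + bridging ligand: no bond
    bond_source: str = "perceived"       # perceived | geom | merged
    merge_tol: float = 0.2               # duplicate-placement merge distance
    radius_table: dict = field(default_factory=lambda: dict(COVALENT_RADIUS))

    def __post_init__(self):
        if self.offset < 0:
            raise ValueError("offset must be >= 0")
        if self.mm_bond_max >= self.mm_reject_min:
            raise ValueError("mm_bond_max must be below mm_reject_min")
        if self.bond_source not in ("perceived", "geom", "merged"):
            raise ValueError(f"bad bond_source {self.bond_source!r}")

    def cutoff(self, e1: str, e2: str) -> float:
        return self.radius_table[e1] + self.radius_table[e2] + self.offset


def perceive_bonds(atoms, policy: BondPolicy | None = None) -> set[tuple[int, int]]:
    """Distance-rule bonds among atoms (objects with element/cart).

    Hydrogen bonds only to its single nearest eligible (heavy if possible)
    neighbor.  Result is a set of (i, j) index pairs with i < j.
    """
    policy = policy or BondPolicy()
    n = len(atoms)
    if n < 2:
        return set()
    coords = np.array([np.asarray(a.cart, dtype=float) for a in atoms])
    dist = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    candidates: dict[int, list[tuple[float, int]]] = {i: [] for i in range(n)}
    pairs = set()
    for i in range(n):
        for j in range(i + 1, n):
            d = dist[i, j]
            if 1e-6 < d <= policy.cutoff(atoms[i].element, atoms[j].element):
                pairs.add((i, j))
                candidates[i].append((d, j))
                candidates[j].append((d, i))
    # hydrogen: keep single nearest eligible neighbor
    for i in range(n):
        if atoms[i].element != "H" or not candidates[i]:
            continue
        heavy = [(d, j) for d, j in candidates[i] if atoms[j].element != "H"]
        pool = heavy or candidates[i]
        keep = min(pool)[1]
        for _, j in candidates[i]:
            if j != keep:
                pairs.discard((min(i, j), max(i, j)))
    return pairs


def apply_metal_metal_policy(pairs: set, atoms, listed: set,
                             policy: BondPolicy | None = None) -> set:
    """Metal-metal window: short contacts bond, long supported ones do not,
    borderline cases follow the authors' listed bonds."""
    policy = policy or BondPolicy()
    pairs = set(pairs)
    idx_tm = [i for i, a in enumerate(atoms)
              if a.element in TRANSITION_METALS]
    for i, j in itertools.combinations(idx_tm, 2):
        key = (min(i, j), max(i, j))
        d = float(np.linalg.norm(np.asarray(atoms[i].cart, dtype=float)
                                 - np.asarray(atoms[j].cart, dtype=float)))
        if d < policy.mm_bond_max:
            pairs.add(key)
        elif d <= policy.mm_reject_min:
            if key in listed:
                pairs.add(key)
            else:
                pairs.discard(key)
        else:
            if key in pairs and _has_bridging_ligand(pairs, atoms, i, j):
                pairs.discard(key)
    return pairs


def _has_bridging_ligand(pairs, atoms, i, j) -> bool:
    nb_i = {b if a == i else a for a, b in pairs if i in (a, b)} - {j}
    nb_j = {b if a == j else a for a, b in pairs if j in (a, b)} - {i}
    return bool(nb_i & nb_j)


def merge_geom_bonds(perceived: set, listed: set, mode: str
                     ) -> tuple[set, dict]:
    """Combine perceived and CIF-listed bonds per the bond source mode.

    Returns (bond set, origin map keyed by pair).
    """
    origins = {}
    if mode == "perceived":
        out = set(perceived)
    elif mode == "geom":
        out = set(listed)
    elif mode == "merged":
        out = set(perceived) | set(listed)
    else:
        raise ValueError(f"bad bond source {mode!r}")
    for p in out:
        if p in perceived:
            origins[p] = "distance"
        else:
            origins[p] = "cif_listed"
    return out, origins


# ---------------------------------------------------------------------------
# bond orders
# ---------------------------------------------------------------------------

def _lowest_valence_ge(element: str, n: int):
    for v in STANDARD_VALENCES.get(element, ()):
        if v >= n:
            return v
    return None


def _sigma_nonmetal(graph: MolecularGraph, i: int) -> int:
    a = graph.atoms[i]
    return a.explicit_h + sum(1 for j in graph.neighbors(i)
                              if not graph.atoms[j].metal)


def assign_bond_orders(graph: MolecularGraph) -> dict[int, int]:
    """Place unsaturation and convention bond orders in the graph.

    Returns the map of leftover valence deficits (atom index -> units)
    that neither matching, metal coordination nor hypervalence absorbed;
    the formal-charge stage converts these into charges.
    """
    deficit: dict[int, int] = {}
    for i, a in enumerate(graph.atoms):
        if a.metal or a.element not in ORGANIC_SUBSET:
            deficit[i] = 0
            continue
        sigma = _sigma_nonmetal(graph, i)
        target = _lowest_valence_ge(a.element, sigma)
        if target is None:
            a.needs_bracket = True
            deficit[i] = 0
        else:
            deficit[i] = target - sigma

    _carbonyl_overrides(graph, deficit)
    _unsaturation_matching(graph, deficit)
    _hypervalent_oxo_pass(graph, deficit)
    _metal_absorption(graph, deficit)
    return {i: d for i, d in deficit.items() if d > 0}


def _carbonyl_overrides(graph: MolecularGraph, deficit) -> None:
    """Terminal M-C-O becomes M-C#[O]; mu2-CO becomes a ketone-like C=O;
    metal isocyanides/cyanides are treated like the carbonyls."""
    for i, a in enumerate(graph.atoms):
        if a.element != "C" or a.explicit_h:
            continue
        metals = [j for j in graph.neighbors(i) if graph.atoms[j].metal]
        others = [j for j in graph.neighbors(i) if not graph.atoms[j].metal]
        if not metals or len(others) != 1:
            continue
        x = others[0]
        xa = graph.atoms[x]
        if xa.element == "O" and graph.degree(x) == 1 and not xa.explicit_h:
            order = 3 if len(metals) == 1 else 2
        elif (xa.element == "N" and len(metals) == 1
              and graph.degree(x) <= 2
              and _sigma_nonmetal(graph, x) <= 2):
            order = 3
        else:
            continue
        graph.set_order(i, x, order)
        deficit[i] = 0
        deficit[x] = 0


def _ring_edges(graph: MolecularGraph) -> set:
    g = nx.Graph()
    nodes = [i for i, a in enumerate(graph.atoms) if not a.metal]
    g.add_nodes_from(nodes)
    for i, j, _ in graph.bonds():
        if not graph.atoms[i].metal and not graph.atoms[j].metal:
            g.add_edge(i, j)
    bridges = {(min(u, v), max(u, v)) for u, v in nx.bridges(g)}
    return {(min(i, j), max(i, j)) for i, j in g.edges
            if (min(i, j), max(i, j)) not in bridges}


def _unsaturation_matching(graph: MolecularGraph, deficit) -> None:
    ring = _ring_edges(graph)
    while True:
        g = nx.Graph()
        for i, j, o in graph.bonds():
            if (deficit.get(i, 0) > 0 and deficit.get(j, 0) > 0 and o < 3
                    and not graph.atoms[i].metal and not graph.atoms[j].metal):
                w = 20
                if (i, j) in ring or (j, i) in ring:
                    w += 1
                if graph.has_metal_neighbor(i):
                    w -= 1
                if graph.has_metal_neighbor(j):
                    w -= 1
                g.add_edge(i, j, weight=w)
        if g.number_of_edges() == 0:
            return
        matching = nx.max_weight_matching(g, maxcardinality=True)
        if not matching:
            return
        for i, j in matching:
            graph.set_order(i, j, graph.order(i, j) + 1)
            deficit[i] -= 1
            deficit[j] -= 1


def _valence_sum(graph: MolecularGraph, i: int) -> int:
    a = graph.atoms[i]
    return a.explicit_h + sum(
        o for j, o in graph._adj[i].items() if not graph.atoms[j].metal)


def _hypervalent_oxo_pass(graph: MolecularGraph, deficit) -> None:
    """Raise X=O bonds on oxo centres (nitrate, sulfate, perchlorate...)."""
    for i, a in enumerate(graph.atoms):
        if a.metal or a.element not in HYPERVALENT_MAX:
            continue
        cap = HYPERVALENT_MAX[a.element] - _valence_sum(graph, i)
        if cap <= 0:
            continue
        for j in sorted(graph.neighbors(i)):
            if cap <= 0:
                break
            xj = graph.atoms[j]
            if (xj.element == "O" and graph.degree(j) == 1
                    and not xj.explicit_h and deficit.get(j, 0) > 0
                    and graph.order(i, j) == 1):
                graph.set_order(i, j, 2)
                deficit[j] -= 1
                deficit[i] = max(0, deficit.get(i, 0) - 1)
                cap -= 1


def _metal_absorption(graph: MolecularGraph, deficit) -> None:
    """Metal-bound atoms with leftover deficit act as anionic donors; a
    deficit beyond one raises the metal bond order (carbene-like M=C)."""
    for i, a in enumerate(graph.atoms):
        d = deficit.get(i, 0)
        if d <= 0 or a.metal:
            continue
        metals = [j for j in graph.neighbors(i) if graph.atoms[j].metal]
        if not metals:
            continue
        absorbed = min(d, len(metals))
        d -= absorbed
        a.metal_lp = True      # lone pair handed to the metal (pi donor)
        if d > 0:
            j = min(metals)
            graph.set_order(i, j, graph.order(i, j) + d)
            d = 0
        deficit[i] = 0


# ---------------------------------------------------------------------------
# aromaticity
# ---------------------------------------------------------------------------

@dataclass
class RingAnalysis:
    rings: list[tuple[int, ...]] = field(default_factory=list)
    pi_counts: list[int | None] = field(default_factory=list)
    verdicts: list[bool] = field(default_factory=list)


def _candidate_rings(graph: MolecularGraph):
    g = nx.Graph()
    nodes = [i for i, a in enumerate(graph.atoms) if not a.metal]
    g.add_nodes_from(nodes)
    for i, j, _ in graph.bonds():
        if i in g and j in g:
            g.add_edge(i, j)
    seen = set()
    rings = []
    for cyc in nx.simple_cycles(g, length_bound=6):
        if len(cyc) < 5:
            continue
        key = frozenset(cyc)
        if key not in seen:
            seen.add(key)
            rings.append(tuple(cyc))
    return rings


def _ring_bonds(ring):
    n = len(ring)
    return [(ring[k], ring[(k + 1) % n]) for k in range(n)]


def perceive_aromaticity(graph: MolecularGraph) -> RingAnalysis:
    """Mark aromatic rings per the curated-collection conventions."""
    analysis = RingAnalysis()
    rings = _candidate_rings(graph)
    aromatic_rings: list[tuple[int, ...]] = []
    aromatic_bond_keys: set = set()

    def has_double(i):
        return any(o == 2 for j, o in graph._adj[i].items()
                   if not graph.atoms[j].metal)

    def in_ring_double(i, ring_set):
        return any(o == 2 for j, o in graph._adj[i].items() if j in ring_set)

    def exo_multiple(i, ring_set):
        return any(o >= 2 for j, o in graph._adj[i].items()
                   if j not in ring_set)

    def lone_pair_donor(i):
        a = graph.atoms[i]
        return (a.element in ("N", "O", "S") and not has_double(i))

    def sp2_ok(i, ring_set):
        a = graph.atoms[i]
        if has_double(i) or any(o >= 2 for o in graph._adj[i].values()):
            return True
        if lone_pair_donor(i):
            return True
        if getattr(a, "metal_lp", False) or a.charge < 0:
            return True
        return False

    deferred = []
    for ring in rings:
        ring_set = set(ring)
        if not all(sp2_ok(i, ring_set) for i in ring):
            analysis.rings.append(ring)
            analysis.pi_counts.append(None)
            analysis.verdicts.append(False)
            continue
        if any(exo_multiple(i, ring_set) for i in ring):
            deferred.append(ring)
            continue
        pi = 0
        for a, b in _ring_bonds(ring):
            if graph.order(a, b) == 2:
                pi += 2
        for i in ring:
            if not in_ring_double(i, ring_set):
                if lone_pair_donor(i):
                    pi += 2
                elif (getattr(graph.atoms[i], "metal_lp", False)
                      or graph.atoms[i].charge < 0):
                    pi += 2
        verdict = pi % 4 == 2
        analysis.rings.append(ring)
        analysis.pi_counts.append(pi)
        analysis.verdicts.append(verdict)
        if verdict:
            aromatic_rings.append(ring)
            aromatic_bond_keys.update(
                (min(a, b), max(a, b)) for a, b in _ring_bonds(ring))

    for ring in deferred:
        bonds = _ring_bonds(ring)
        n = len(bonds)
        verdict = False
        for k in range(n):
            a, b = bonds[k]
            if graph.order(a, b) != 1:
                continue
            prev_bond = bonds[(k - 1) % n]
            next_bond = bonds[(k + 1) % n]
            flanks_ok = True
            for fa, fb in (prev_bond, next_bond):
                key = (min(fa, fb), max(fa, fb))
                if graph.order(fa, fb) != 2 or key in aromatic_bond_keys:
                    flanks_ok = False
            if flanks_ok:
                verdict = True
                break
        analysis.rings.append(ring)
        analysis.pi_counts.append(None)
        analysis.verdicts.append(verdict)
        if verdict:
            aromatic_rings.append(ring)
            aromatic_bond_keys.update(
                (min(a, b), max(a, b)) for a, b in _ring_bonds(ring))

    _apply_aromatic_rings(graph, aromatic_rings)
    _fullerene_pass(graph)
    return analysis


def _apply_aromatic_rings(graph, aromatic_rings) -> None:
    for ring in aromatic_rings:
        ring_set = set(ring)
        for i in ring:
            a = graph.atoms[i]
            a.aromatic = True
            if any(o == 2 for j, o in graph._adj[i].items() if j in ring_set):
                a.kekule_pi = True
        for a_, b_ in _ring_bonds(ring):
            graph.set_order(a_, b_, AROMATIC_BOND)


def _fullerene_pass(graph: MolecularGraph) -> None:
    """An all-carbon, 3-connected cage of >= 60 atoms is aromatic wholesale."""
    for moiety in graph.moiety_indices():
        if len(moiety) < 60:
            continue
        atoms = [graph.atoms[i] for i in moiety]
        if not all(a.element == "C" and a.explicit_h == 0 for a in atoms):
            continue
        if not all(graph.degree(i) == 3 for i in moiety):
            continue
        for i in moiety:
            graph.atoms[i].aromatic = True
            graph.atoms[i].kekule_pi = True
        for i in moiety:
            for j in graph.neighbors(i):
                if i < j:
                    graph.set_order(i, j, AROMATIC_BOND)


# ---------------------------------------------------------------------------
# formal charges
# ---------------------------------------------------------------------------

def assign_formal_charges(graph: MolecularGraph, leftover: dict[int, int]
                          ) -> None:
    """Formal charges for simple species only.

    Isolated atoms are charged by group, haloanion terminal halogens and
    oxoanion terminal oxygens carry the negative charges, ammonium-type
    N/P get +1; coordination compounds receive no charges at all.
    """
    leftover = dict(leftover)
    for moiety in graph.moiety_indices():
        atoms = [graph.atoms[i] for i in moiety]
        elements = {a.element for a in atoms}
        if len(moiety) == 1:
            a = atoms[0]
            i = moiety[0]
            if a.element in ALKALI:
                a.charge = 1
            elif a.element in ALKALINE_EARTH:
                a.charge = 2
            elif a.element in HALOGENS:
                a.charge = -1
            leftover.pop(i, None)
            continue
        # haloanion: hypervalent p-block centre, only halogen partners
        centers = [i for i in moiety
                   if graph.atoms[i].element in HALOANION_CENTERS]
        if centers and len(elements) == 2:
            c = centers[0]
            halns = [j for j in graph.neighbors(c)
                     if graph.atoms[j].element in HALOGENS]
            maxv = max(STANDARD_VALENCES.get(
                graph.atoms[c].element,
                (HYPERVALENT_MAX.get(graph.atoms[c].element, 8),)))
            extra = graph.degree(c) - maxv
            if len(halns) >= 3 and len(halns) == graph.degree(c) and extra > 0:
                for j in sorted(halns)[-extra:]:
                    graph.atoms[j].charge = -1
                for i in moiety:
                    leftover.pop(i, None)
                continue
        if any(a.metal for a in atoms):
            # coordination compound: no formal charges anywhere
            for i in moiety:
                leftover.pop(i, None)
            continue
        for i in moiety:
            a = graph.atoms[i]
            if (a.element in ("N", "P") and not a.aromatic
                    and _sigma_nonmetal(graph, i) == 4
                    and all(o == 1 for o in graph._adj[i].values())
                    and not graph.has_metal_neighbor(i)):
                a.charge = 1
                leftover.pop(i, None)
        for i in moiety:
            d = leftover.pop(i, 0)
            if d > 0:
                graph.atoms[i].charge = -d
                logger.info("leftover deficit on %s -> charge %d",
                            graph.atoms[i].element, -d)
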