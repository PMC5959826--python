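"""From a parsed crystal entry to the "molecule" a chemist would draw.

The asymmetric unit is used as the seed; symmetry images (with unit-cell
shifts) are added only where they continue a bonded cluster, so moieties
sitting on special positions are completed while unrelated copies in the
cell are not duplicated.  Pure-translation self-images of a cluster signal
polymerism; the rank of the translation lattice is the polymer dimension.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from itertools import product

import numpy as np

from .bonds import (BondPolicy, apply_metal_metal_policy, assign_bond_orders,
                    assign_formal_charges, merge_geom_bonds, perceive_bonds,
                    perceive_aromaticity)
from .canon import canonical_form, canonical_moiety_smiles
from .cif import CrystalEntry, parse_site_symmetry
from .elements import ALKALI, ALKALINE_EARTH, HALOGENS, METALS
from .smiles import GraphAtom, MolecularGraph
from .triage import EntryFlags, triage

logger = logging.getLogger(__name__)

__all__ = ["PlacedAtom", "Moiety", "MoietySet", "BuiltMolecule",
           "UnsupportedPolymerError", "expand_to_p1", "select_disorder",
           "partition_moieties", "reduce_stoichiometry",
           "infer_missing_hydrogens", "extend_polymer_1d", "build_molecule",
           "SOLVENT_SMILES", "p1_cell_contents"]


class UnsupportedPolymerError(RuntimeError):
    """2-D/3-D covalent polymer without an ionic representation."""


@dataclass
class PlacedAtom:
    source_label: str
    element: str
    cart: np.ndarray
    fract: np.ndarray
    occupancy: float
    symop_index: int
    lattice_shift: tuple[int, int, int]
    disorder_assembly: str | None = None
    disorder_group: str | None = None
    site_index: int = -1

    @property
    def label(self) -> str:
        return self.source_label

    @property
    def is_seed(self) -> bool:
        return self.symop_index == 0 and self.lattice_shift == (0, 0, 0)


@dataclass
class Moiety:
    atom_indices: list[int]
    multiplicity: int = 1
    polymer_dimension: int = 0
    canonical: str = ""
    is_polymer_fragment: bool = False


@dataclass
class MoietySet:
    graph: MolecularGraph
    moieties: list[Moiety]
    log: list[str] = field(default_factory=list)


#: moieties considered "solvent" for the rounding rule (nothing more complex
#: than toluene); canonical forms are computed lazily at first use
_SOLVENT_INPUT = [
    "O", "CO", "CCO", "CC#N", "CC(=O)C", "ClCCl", "ClC(Cl)Cl",
    "C1CCOC1", "C1COCCO1", "CN(C)C=O", "CS(=O)C", "CCOCC",
    "c1ccccc1", "Cc1ccccc1",
]
SOLVENT_SMILES: set[str] = set()


def _solvent_set() -> set[str]:
    if not SOLVENT_SMILES:
        SOLVENT_SMILES.update(canonical_form(s) for s in _SOLVENT_INPUT)
    return SOLVENT_SMILES


# ---------------------------------------------------------------------------
# symmetry expansion
# ---------------------------------------------------------------------------

def _identity_key(site_index: int, fract) -> tuple:
    wrapped = np.mod(np.round(np.asarray(fract), 6), 1.0)
    wrapped = np.mod(np.round(wrapped, 4), 1.0)   # 0.9999... -> 0
    return (site_index, tuple(wrapped))


def expand_to_p1(entry: CrystalEntry, policy: BondPolicy | None = None,
                 max_span: int = 3, max_atoms: int = 800,
                 flags: EntryFlags | None = None):
    """Grow bonded clusters from the asymmetric unit.

    Returns (placements, translations) where translations is a list of
    integer lattice vectors under which some cluster maps onto itself
    (non-empty only for polymeric structures).
    """
    policy = policy or BondPolicy()
    ortho = entry.cell.orthogonalization_matrix()
    placements: list[PlacedAtom] = []
    keys: dict[tuple, int] = {}
    identity_of: list[tuple] = []
    translations: list[np.ndarray] = []

    for si, site in enumerate(entry.sites):
        cart = ortho @ site.fract
        p = PlacedAtom(site.label, site.element, cart, np.array(site.fract),
                       site.occupancy, 0, (0, 0, 0),
                       site.disorder_assembly, site.disorder_group, si)
        keys[(si, 0, (0, 0, 0))] = len(placements)
        identity_of.append(_identity_key(si, site.fract))
        placements.append(p)

    # Even for fast-path entries the growth pass runs: it is a no-op for a
    # clean finite molecule and is what detects hidden polymers.

    # precompute raw images of each site under each operator; operators
    # mapping a special-position site to the same point are deduplicated
    images = []
    seen_img = set()
    for si, site in enumerate(entry.sites):
        for k, op in enumerate(entry.symops):
            img = op.apply(site.fract)
            key = (si, tuple(np.round(np.mod(img, 1.0), 4)))
            if key in seen_img:
                continue
            seen_img.add(key)
            images.append((si, k, img))

    frontier = list(range(len(placements)))
    while frontier:
        new_frontier: list[int] = []
        for pi in frontier:
            p = placements[pi]
            for si, k, img in images:
                site = entry.sites[si]
                n0 = np.round(p.fract - img).astype(int)
                for off in product((-1, 0, 1), repeat=3):
                    shift = tuple(int(x) for x in (n0 + off))
                    if max(abs(s) for s in shift) > max_span:
                        continue
                    key = (si, k, shift)
                    if key in keys:
                        continue
                    fract = img + np.array(shift, dtype=float)
                    cart = ortho @ fract
                    d = float(np.linalg.norm(cart - p.cart))
                    if d <= 1e-6 or d > policy.cutoff(site.element, p.element):
                        continue
                    # merge duplicates from special positions
                    if any(np.linalg.norm(cart - q.cart) < policy.merge_tol
                           for q in placements):
                        keys[key] = -1
                        continue
                    ident = _identity_key(si, fract)
                    if ident in identity_of:
                        ref = placements[identity_of.index(ident)]
                        tvec = np.round(fract - ref.fract).astype(int)
                        if np.any(tvec):
                            translations.append(tvec)
                        keys[key] = -1
                        continue
                    q = PlacedAtom(site.label, site.element, cart, fract,
                                   site.occupancy, k, shift,
                                   site.disorder_assembly,
                                   site.disorder_group, si)
                    keys[key] = len(placements)
                    identity_of.append(ident)
                    placements.append(q)
                    new_frontier.append(len(placements) - 1)
        if len(placements) > max_atoms:
            logger.warning("expansion exceeded %d atoms; treating as polymeric",
                           max_atoms)
            break
        frontier = new_frontier

    uniq = []
    seen = set()
    for t in translations:
        key = tuple(int(x) for x in t)
        if key not in seen and tuple(-x for x in key) not in seen:
            seen.add(key)
            uniq.append(np.array(key))
    return placements, uniq


def select_disorder(placements: list[PlacedAtom], entry: CrystalEntry
                    ) -> tuple[list[PlacedAtom], list[str]]:
    """Keep, per disorder assembly, the group with the largest occupancy sum."""
    log: list[str] = []
    assemblies: dict[str, dict[str, float]] = {}
    for p in placements:
        if p.disorder_group is None:
            continue
        asm = p.disorder_assembly or "."
        assemblies.setdefault(asm, {}).setdefault(p.disorder_group, 0.0)
        assemblies[asm][p.disorder_group] += p.occupancy
    keep_group: dict[str, str] = {}
    for asm, groups in assemblies.items():
        best = sorted(groups.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
        keep_group[asm] = best
        if len(groups) > 1:
            log.append(f"disorder assembly {asm}: kept group {best} "
                       f"(occupancy sums {dict(sorted(groups.items()))})")
    kept = [p for p in placements
            if p.disorder_group is None
            or keep_group[p.disorder_assembly or "."] == p.disorder_group]
    return kept, log


def resolve_geom_bonds(entry: CrystalEntry, placements: list[PlacedAtom]
                       ) -> set[tuple[int, int]]:
    """Map ``_geom_bond_`` records to placement index pairs."""
    index = {(p.source_label, p.symop_index, p.lattice_shift): i
             for i, p in enumerate(placements)}
    by_pos: list[tuple[np.ndarray, int]] = [(p.cart, i)
                                            for i, p in enumerate(placements)]
    out = set()
    for gb in entry.geom_bonds:
        i = index.get((gb.label1, 0, (0, 0, 0)))
        if i is None:
            logger.warning("geom bond %s-%s: atom 1 not placed; skipped",
                           gb.label1, gb.label2)
            continue
        try:
            op_idx, shift = parse_site_symmetry(gb.site_symmetry_2,
                                                len(entry.symops))
        except Exception as exc:
            logger.warning("geom bond %s-%s: %s; skipped",
                           gb.label1, gb.label2, exc)
            continue
        j = index.get((gb.label2, op_idx,
                       tuple(int(x) for x in shift)))
        if j is None:
            # the placement may exist under a different generator; match by
            # geometry
            site2 = next((s for s in entry.sites if s.label == gb.label2), None)
            if site2 is not None:
                target = (entry.cell.orthogonalization_matrix()
                          @ (entry.symops[op_idx].apply(site2.fract)
                             + np.asarray(shift)))
                for cart, cand in by_pos:
                    if (placements[cand].source_label == gb.label2
                            and np.linalg.norm(cart - target) < 0.05):
                        j = cand
                        break
        if j is None:
            logger.warning("geom bond %s-%s (%s): target image not in the "
                           "built molecule; skipped", gb.label1, gb.label2,
                           gb.site_symmetry_2)
            continue
        if i != j:
            out.add((min(i, j), max(i, j)))
    return out


# ---------------------------------------------------------------------------
# graph building
# ---------------------------------------------------------------------------

def _fold_hydrogens(placements, bond_pairs):
    """Heavy-atom graph with hydrogens folded into explicit H counts."""
    adj: dict[int, set[int]] = {i: set() for i in range(len(placements))}
    for i, j in bond_pairs:
        adj[i].add(j)
        adj[j].add(i)
    heavy = [i for i, p in enumerate(placements) if p.element != "H"]
    hmap = {old: new for new, old in enumerate(heavy)}
    graph = MolecularGraph()
    for old in heavy:
        p = placements[old]
        graph.add_atom(GraphAtom(p.element, cart=np.asarray(p.cart, float),
                                 occupancy=p.occupancy))
    for i, p in enumerate(placements):
        if p.element != "H":
            continue
        partners = [j for j in adj[i] if placements[j].element != "H"]
        if not partners:
            logger.warning("hydrogen %s has no heavy partner; dropped",
                           p.source_label)
            continue
        target = hmap[partners[0]]
        atom = graph.atoms[target]
        atom.explicit_h += 1
        if atom.h_cart is None:
            atom.h_cart = np.asarray(p.cart, float)
    for i, j in bond_pairs:
        if placements[i].element != "H" and placements[j].element != "H":
            graph.add_bond(hmap[i], hmap[j], 1)
    return graph, hmap


def partition_moieties(graph: MolecularGraph,
                       translations: list[np.ndarray],
                       placements=None, hmap=None, cell=None) -> MoietySet:
    """Connected components with per-component polymer dimension."""
    comps = graph.moiety_indices()
    mois = []
    dim = 0
    if translations:
        mat = np.array([t for t in translations])
        dim = int(np.linalg.matrix_rank(mat))
    for comp in comps:
        d = dim if translations else 0
        mois.append(Moiety(atom_indices=list(comp), polymer_dimension=d))
    return MoietySet(graph=graph, moieties=mois)


def infer_missing_hydrogens(graph: MolecularGraph,
                            counter_ion_context: bool) -> list[str]:
    """Isolated O becomes water; long terminal C-O gains a hydroxyl H."""
    log = []
    for i, a in enumerate(graph.atoms):
        if a.element != "O" or a.explicit_h or graph.has_metal_neighbor(i):
            continue
        nbrs = graph.neighbors(i)
        if not nbrs:
            a.explicit_h = 2
            log.append("isolated O -> water (2 H added)")
        elif (len(nbrs) == 1 and graph.atoms[nbrs[0]].element == "C"
              and not counter_ion_context
              and a.cart is not None and graph.atoms[nbrs[0]].cart is not None):
            d = float(np.linalg.norm(a.cart - graph.atoms[nbrs[0]].cart))
            if d > 1.38:
                a.explicit_h = 1
                log.append(f"terminal C-O at {d:.2f} A -> hydroxyl (1 H added)")
    return log


def reduce_stoichiometry(mset: MoietySet) -> MoietySet:
    """Merge isomorphic moieties; divide by the gcd; round solvent shares up."""
    groups: dict[str, list[Moiety]] = {}
    for m in mset.moieties:
        if not m.canonical:
            m.canonical = canonical_moiety_smiles(
                mset.graph.subgraph(m.atom_indices))
        groups.setdefault(m.canonical, []).append(m)
    merged: list[Moiety] = []
    for canon, members in groups.items():
        rep = members[0]
        rep.multiplicity = sum(m.multiplicity for m in members)
        merged.append(rep)
    g = math.gcd(*(m.multiplicity for m in merged)) if merged else 1
    for m in merged:
        m.multiplicity //= g
    solvents = _solvent_set()
    non_solvent = [m for m in merged if m.canonical not in solvents]
    if non_solvent:
        main = max(non_solvent, key=lambda m: (len(m.atom_indices),
                                               m.multiplicity))
        k = main.multiplicity
        if k > 1 and all(m.multiplicity % k == 0 or m.canonical in solvents
                         for m in merged):
            for m in merged:
                if m.multiplicity % k == 0:
                    m.multiplicity //= k
                else:
                    mset.log.append(
                        f"solvent share {m.multiplicity}/{k} rounded up to 1 "
                        f"({m.canonical})")
                    m.multiplicity = 1
    merged.sort(key=lambda m: (-len(m.atom_indices), m.canonical))
    mset.moieties = merged
    return mset


def extend_polymer_1d(graph: MolecularGraph, moiety: Moiety,
                      translation_cart: np.ndarray,
                      policy: BondPolicy | None = None) -> MolecularGraph:
    """Finite 1-D polymer fragment: the unit plus one translated image."""
    if moiety.polymer_dimension != 1:
        raise UnsupportedPolymerError(
            f"{moiety.polymer_dimension}-D polymer is outside automated scope")
    policy = policy or BondPolicy()
    sub = graph.subgraph(moiety.atom_indices)
    frag = MolecularGraph()
    for a in sub.atoms:
        frag.add_atom(replace(a))
    n = len(sub.atoms)
    for a in sub.atoms:
        b = GraphAtom(a.element, explicit_h=a.explicit_h,
                      occupancy=a.occupancy,
                      cart=None if a.cart is None
                      else a.cart + translation_cart)
        frag.add_atom(b)
    for i, j, o in sub.bonds():
        frag.add_bond(i, j, o)
        frag.add_bond(i + n, j + n, o)
    # inter-unit bonds from geometry
    for i in range(n):
        for j in range(n, 2 * n):
            ai, aj = frag.atoms[i], frag.atoms[j]
            if ai.cart is None or aj.cart is None or frag.has_bond(i, j):
                continue
            d = float(np.linalg.norm(ai.cart - aj.cart))
            if 1e-6 < d <= policy.cutoff(ai.element, aj.element):
                frag.add_bond(i, j, 1)
    return frag


# ---------------------------------------------------------------------------
# end-to-end molecule construction
# ---------------------------------------------------------------------------

@dataclass
class BuiltMolecule:
    graph: MolecularGraph
    moieties: list[Moiety]
    flags: EntryFlags
    log: list[str] = field(default_factory=list)
    review: bool = False


def _ionic_decomposition(entry: CrystalEntry, dims: int) -> MolecularGraph:
    """Disconnected-ion representation of an extended framework."""
    elements = {s.element for s in entry.sites}
    organic = elements & {"C", "N", "B", "P", "H"}
    all_metal = all(e in METALS for e in elements)
    simple = elements <= (METALS | {"O", "S", "Se", "F", "Cl", "Br", "I"})
    if not (all_metal or simple):
        raise UnsupportedPolymerError(
            f"{dims}-D covalent polymer (elements {sorted(elements)}) has no "
            "automated representation")
    graph = MolecularGraph()
    if all_metal:
        for el in sorted({s.element for s in entry.sites}):
            graph.add_atom(GraphAtom(el))
        return graph
    counts: dict[str, int] = {}
    for s in entry.sites:
        counts[s.element] = counts.get(s.element, 0) + 1
    g = math.gcd(*counts.values())
    for el in sorted(counts):
        for _ in range(counts[el] // g):
            graph.add_atom(GraphAtom(el))
    return graph


def build_molecule(entry: CrystalEntry, policy: BondPolicy | None = None
                   ) -> BuiltMolecule:
    """Full molecule building: expansion, disorder, bonds, orders, charges,
    aromaticity and stoichiometry reduction (stereo is applied later)."""
    policy = policy or BondPolicy()
    flags = triage(entry)
    log: list[str] = []

    placements, translations = expand_to_p1(entry, policy, flags=flags)
    if flags.disordered:
        placements, dlog = select_disorder(placements, entry)
        log.extend(dlog)

    pairs = perceive_bonds(placements, policy)
    listed = resolve_geom_bonds(entry, placements)
    pairs = apply_metal_metal_policy(pairs, placements, listed, policy)
    pairs, origins = merge_geom_bonds(pairs, listed, policy.bond_source)

    dims = 0
    if translations:
        dims = int(np.linalg.matrix_rank(np.array(translations)))
        flags.polymer_dimension = dims
    else:
        flags.polymer_dimension = 0

    if dims >= 2:
        graph = _ionic_decomposition(entry, dims)
        assign_formal_charges(graph, assign_bond_orders(graph))
        mois = [Moiety([i], polymer_dimension=dims,
                       canonical=canonical_moiety_smiles(graph.subgraph([i])))
                for i in range(len(graph))]
        log.append(f"{dims}-D framework represented as disconnected ions")
        mset = MoietySet(graph, mois, log)
        mset = reduce_stoichiometry(mset)
        return BuiltMolecule(graph, mset.moieties, flags, mset.log)

    graph, hmap = _fold_hydrogens(placements, pairs)

    if dims == 1:
        ortho = entry.cell.orthogonalization_matrix()
        tcarts = sorted((np.linalg.norm(ortho @ t.astype(float)), t)
                        for t in translations)
        tvec = ortho @ tcarts[0][1].astype(float)
        log.append(f"1-D polymer: extended once along {tcarts[0][1].tolist()}")
        base = partition_moieties(graph, translations)
        frags = MolecularGraph()
        mois = []
        for m in base.moieties:
            frag = extend_polymer_1d(graph, m, tvec, policy)
            nunit = len(m.atom_indices)
            inter = any(i < nunit <= j for i, j, _ in frag.bonds())
            if not inter:       # finite moiety coexisting with the chain
                frag = graph.subgraph(m.atom_indices)
                m.polymer_dimension = 0
            offset = len(frags.atoms)
            for a in frag.atoms:
                frags.add_atom(a)
            for i, j, o in frag.bonds():
                frags.add_bond(offset + i, offset + j, o)
            mois.append(Moiety(list(range(offset, offset + len(frag.atoms))),
                               polymer_dimension=(1 if inter else 0),
                               is_polymer_fragment=inter))
        graph = frags
        leftovers = assign_bond_orders(graph)
        assign_formal_charges(graph, leftovers)
        perceive_aromaticity(graph)
        mset = MoietySet(graph, mois, log)
        for m in mset.moieties:
            m.canonical = canonical_moiety_smiles(graph.subgraph(m.atom_indices))
        mset = reduce_stoichiometry(mset)
        return BuiltMolecule(graph, mset.moieties, flags, mset.log)

    # finite molecules
    counter_ions = any(a.element in ALKALI | ALKALINE_EARTH
                       for a in graph.atoms)
    log.extend(infer_missing_hydrogens(graph, counter_ions))
    _drop_low_occupancy_moieties(graph, log)
    leftovers = assign_bond_orders(graph)
    assign_formal_charges(graph, leftovers)
    perceive_aromaticity(graph)
    mset = partition_moieties(graph, [])
    mset.log = log
    mset = reduce_stoichiometry(mset)
    return BuiltMolecule(graph, mset.moieties, flags, mset.log)


def _drop_low_occupancy_moieties(graph: MolecularGraph, log: list[str]) -> None:
    drop: set[int] = set()
    for comp in graph.moiety_indices():
        occ = [graph.atoms[i].occupancy for i in comp]
        mean = sum(occ) / len(occ)
        if mean < 0.1:
            drop.update(comp)
            log.append(f"moiety with mean occupancy {mean:.2f} < 0.1 dropped")
    if drop:
        keep = [i for i in range(len(graph)) if i not in drop]
        new = graph.subgraph(keep)
        graph.atoms = new.atoms
        graph._adj = new._adj


def p1_cell_contents(entry: CrystalEntry, merge_tol: float = 0.2
                     ) -> dict[str, int]:
    """Element counts of the full P1 cell (symmetry images merged)."""
    ortho = entry.cell.orthogonalization_matrix()
    counts: dict[str, int] = {}
    placed: list[np.ndarray] = []        # wrapped fractional positions
    for site in entry.sites:
        for op in entry.symops:
            f = np.mod(op.apply(site.fract), 1.0)
            dup = False
            for q in placed:
                delta = np.abs(f - q)
                delta = np.minimum(delta, 1 - delta)
                if np.linalg.norm(ortho @ delta) < merge_tol:
                    dup = True
                    break
            if not dup:
                placed.append(f)
                counts[site.element] = counts.get(site.element, 0) + 1
    return counts
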