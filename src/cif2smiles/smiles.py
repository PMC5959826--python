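"""Molecular graph container plus SMILES writing and parsing.

The dialect follows OpenSMILES with the representation conventions used for
curated crystallographic connectivity: brackets whenever the bond-order sum
differs from a standard valence, lowercase aromatic atoms (bracketed when
metal-bound, as in metallocenes), hydrogens always as in-bracket counts,
ring-closure digits reused after closure with ``%nn`` beyond 9, and moieties
joined with ".".

One deliberate dialect point: a single bond between two aromatic atoms is
written without an explicit "-".  On reading, an implicit bond between two
aromatic atoms is aromatic only if it lies in a ring made entirely of
aromatic atoms (i.e. it is not a bridge of the aromatic-atom subgraph);
otherwise it is single.  This matches how biphenyl-type and fused
quinoid systems are printed in curated collections.
"""

from __future__ import annotations

import heapq
import re
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

from .elements import (ATOMIC_NUMBER, METALS, ORGANIC_SUBSET,
                       STANDARD_VALENCES)

__all__ = [
    "AROMATIC_BOND", "GraphAtom", "MolecularGraph", "SmilesError",
    "SmilesRecord", "parse_smiles", "write_smiles", "invert_stereo_marks",
]

#: sentinel bond order for aromatic bonds
AROMATIC_BOND = 4

_AROMATIC_OK = {"B", "C", "N", "O", "P", "S", "Se", "As"}


class SmilesError(ValueError):
    def __init__(self, message: str, position: int | None = None):
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)
        self.position = position


@dataclass
class GraphAtom:
    element: str
    charge: int = 0
    explicit_h: int = 0
    aromatic: bool = False
    needs_bracket: bool = False
    cart: np.ndarray | None = None
    h_cart: np.ndarray | None = None
    occupancy: float = 1.0
    #: '@' (anticlockwise) or '@@' relative to parity_ref neighbor order
    parity: str | None = None
    #: neighbor order the parity refers to; "H" marks the implicit hydrogen
    parity_ref: tuple | None = None
    #: had an in-ring double bond in the Kekule structure (writer uses this
    #: for the bracket decision on aromatic atoms; not a canonical invariant)
    kekule_pi: bool = False

    @property
    def metal(self) -> bool:
        return self.element in METALS


class MolecularGraph:
    """Undirected molecular graph with typed bonds (heavy atoms only)."""

    def __init__(self):
        self.atoms: list[GraphAtom] = []
        self._adj: dict[int, dict[int, int]] = {}

    # -- construction ---------------------------------------------------
    def add_atom(self, atom: GraphAtom) -> int:
        self.atoms.append(atom)
        idx = len(self.atoms) - 1
        self._adj[idx] = {}
        return idx

    def add_bond(self, i: int, j: int, order: int = 1) -> None:
        if i == j:
            raise ValueError("self-bonds are not allowed")
        self._adj[i][j] = order
        self._adj[j][i] = order

    def set_order(self, i: int, j: int, order: int) -> None:
        if j not in self._adj[i]:
            raise KeyError((i, j))
        self._adj[i][j] = order
        self._adj[j][i] = order

    def remove_bond(self, i: int, j: int) -> None:
        del self._adj[i][j]
        del self._adj[j][i]

    # -- queries --------------------------------------------------------
    def __len__(self):
        return len(self.atoms)

    def neighbors(self, i: int) -> list[int]:
        return list(self._adj[i])

    def order(self, i: int, j: int) -> int:
        return self._adj[i][j]

    def has_bond(self, i: int, j: int) -> bool:
        return j in self._adj[i]

    def bonds(self):
        for i, nb in self._adj.items():
            for j, o in nb.items():
                if i < j:
                    yield i, j, o

    def degree(self, i: int) -> int:
        return len(self._adj[i])

    def sigma_sum(self, i: int) -> int:
        """Bond-order sum counting aromatic bonds as 1."""
        return sum(1 if o == AROMATIC_BOND else o
                   for o in self._adj[i].values())

    def has_metal_neighbor(self, i: int) -> bool:
        return any(self.atoms[j].metal for j in self._adj[i])

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(len(self.atoms)))
        g.add_edges_from((i, j, {"order": o}) for i, j, o in self.bonds())
        return g

    def moiety_indices(self) -> list[list[int]]:
        """Connected components, each sorted, ordered by smallest member."""
        comps = [sorted(c) for c in nx.connected_components(self.to_networkx())]
        return sorted(comps, key=lambda c: c[0])

    # -- derived graphs -------------------------------------------------
    def copy(self) -> "MolecularGraph":
        g = MolecularGraph()
        for a in self.atoms:
            g.add_atom(replace(a))
        for i, j, o in self.bonds():
            g.add_bond(i, j, o)
        return g

    def subgraph(self, nodes) -> "MolecularGraph":
        nodes = list(nodes)
        mapping = {old: new for new, old in enumerate(nodes)}
        g = MolecularGraph()
        for old in nodes:
            a = replace(self.atoms[old])
            if a.parity_ref is not None:
                if all(k == "H" or k in mapping for k in a.parity_ref):
                    a.parity_ref = tuple(
                        "H" if k == "H" else mapping[k] for k in a.parity_ref)
                else:
                    a.parity = a.parity_ref = None
            g.add_atom(a)
        for old in nodes:
            for j, o in self._adj[old].items():
                if j in mapping and mapping[old] < mapping[j]:
                    g.add_bond(mapping[old], mapping[j], o)
        return g

    def permuted(self, order) -> "MolecularGraph":
        """Graph with atoms relabelled so new index k holds old ``order[k]``."""
        assert sorted(order) == list(range(len(self.atoms)))
        return self.subgraph(order)

    def mirrored(self) -> "MolecularGraph":
        g = self.copy()
        for a in g.atoms:
            if a.parity is not None:
                a.parity = "@" if a.parity == "@@" else "@@"
        return g

    def element_counts(self, with_h: bool = True) -> dict[str, int]:
        counts: dict[str, int] = {}
        for a in self.atoms:
            counts[a.element] = counts.get(a.element, 0) + 1
            if with_h and a.explicit_h:
                counts["H"] = counts.get("H", 0) + a.explicit_h
        return counts


@dataclass(frozen=True)
class SmilesRecord:
    smiles: str
    entry_id: str

    def line(self) -> str:
        return f"{self.smiles}\t{self.entry_id}"


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def _lowest_valence_ge(element: str, n: int) -> int | None:
    for v in STANDARD_VALENCES.get(element, ()):
        if v >= n:
            return v
    return None


def _full_sum(graph: MolecularGraph, i: int) -> int:
    """Bond orders with aromatic bonds as 1 plus the Kekule pi electron."""
    a = graph.atoms[i]
    return graph.sigma_sum(i) + (1 if a.aromatic and a.kekule_pi else 0)


def _needs_bracket(graph: MolecularGraph, i: int) -> bool:
    a = graph.atoms[i]
    if (a.element not in ORGANIC_SUBSET or a.charge != 0 or a.needs_bracket
            or a.parity is not None):
        return True
    if a.aromatic:
        if a.element != "C" and a.explicit_h > 0:
            return True          # [nH]-style: aromatic H is never implicit
        if a.element == "C" and graph.has_metal_neighbor(i):
            return True          # metallocene convention
        total = _full_sum(graph, i) + a.explicit_h
        return total not in STANDARD_VALENCES[a.element]
    total = graph.sigma_sum(i)
    v = _lowest_valence_ge(a.element, total)
    if v is None:
        return True
    return v - total != a.explicit_h


def _atom_token(graph: MolecularGraph, i: int, parity_mark: str | None) -> str:
    a = graph.atoms[i]
    sym = a.element.lower() if a.aromatic else a.element
    if not _needs_bracket(graph, i) and parity_mark is None:
        return sym
    tok = "[" + sym
    if parity_mark:
        tok += parity_mark
    if a.explicit_h == 1:
        tok += "H"
    elif a.explicit_h > 1:
        tok += f"H{a.explicit_h}"
    if a.charge == 1:
        tok += "+"
    elif a.charge == -1:
        tok += "-"
    elif a.charge > 1:
        tok += f"+{a.charge}"
    elif a.charge < -1:
        tok += f"-{-a.charge}"
    return tok + "]"


def _bond_token(graph: MolecularGraph, i: int, j: int) -> str:
    o = graph.order(i, j)
    if o == 2:
        return "="
    if o == 3:
        return "#"
    return ""     # single and aromatic are implicit


def _perm_parity(ref, actual) -> int:
    perm = [ref.index(x) for x in actual]
    swaps = 0
    perm = list(perm)
    for k in range(len(perm)):
        while perm[k] != k:
            tgt = perm[k]
            perm[k], perm[tgt] = perm[tgt], perm[k]
            swaps += 1
    return swaps % 2


def _parity_mark(atom: GraphAtom, written_order) -> str | None:
    if atom.parity is None:
        return None
    ref = list(atom.parity_ref)
    if sorted(map(str, ref)) != sorted(map(str, written_order)):
        raise SmilesError("parity reference does not match neighbor set")
    if _perm_parity([str(x) for x in ref],
                    [str(x) for x in written_order]) == 0:
        return atom.parity
    return "@" if atom.parity == "@@" else "@@"


def write_smiles(graph: MolecularGraph, atom_order=None) -> str:
    """Serialize a graph; traversal follows ``atom_order`` (default input)."""
    if atom_order is None:
        atom_order = list(range(len(graph)))
    pos = {a: k for k, a in enumerate(atom_order)}
    parts = []
    for moiety in sorted(graph.moiety_indices(), key=lambda m: min(pos[i] for i in m)):
        parts.append(_write_moiety(graph, moiety, pos))
    return ".".join(parts)


def _write_moiety(graph: MolecularGraph, nodes, pos) -> str:
    root = min(nodes, key=lambda i: pos[i])
    # DFS, neighbors by traversal position
    parent: dict[int, int | None] = {root: None}
    children: dict[int, list[int]] = {n: [] for n in nodes}
    ring_bonds: list[tuple[int, int]] = []   # (first endpoint, second endpoint)
    seen_ring = set()
    emit_order: list[int] = []
    stack = [root]
    visited = set()
    while stack:
        i = stack.pop()
        if i in visited:
            continue
        visited.add(i)
        emit_order.append(i)
        nbrs = sorted(graph.neighbors(i), key=lambda j: pos[j])
        for j in nbrs:
            if j == parent[i]:
                continue
            if j in visited:
                key = (min(i, j), max(i, j))
                if key not in seen_ring:
                    seen_ring.add(key)
                    ring_bonds.append((j, i))   # j was emitted first
            elif j not in parent:
                parent[j] = i
                children[i].append(j)
        for j in reversed(children[i]):
            stack.append(j)

    emit_rank = {a: k for k, a in enumerate(emit_order)}
    # second endpoints fixed: the later endpoint closes the ring
    ring_at: dict[int, list[tuple[int, int]]] = {n: [] for n in nodes}
    for first, second in ring_bonds:
        if emit_rank[first] > emit_rank[second]:
            first, second = second, first
        ring_at[first].append((second, first))
        ring_at[second].append((first, second))

    # assign digits in emission order, reusing a digit once its ring closes
    free: list[int] = list(range(1, 100))
    heapq.heapify(free)
    digit: dict[tuple[int, int], int] = {}
    open_at: dict[tuple[int, int], int] = {}
    for i in emit_order:
        closures = sorted(ring_at[i], key=lambda t: emit_rank[t[0]])
        for other, _me in closures:
            key = (min(i, other), max(i, other))
            if key in open_at:
                digit[key] = open_at.pop(key)
                heapq.heappush(free, digit[key])
            else:
                d = heapq.heappop(free)
                open_at[key] = d
                digit[key] = d

    out: list[str] = []

    def emit(i: int, bond_from: int | None):
        a = graph.atoms[i]
        if bond_from is not None:
            out.append(_bond_token(graph, bond_from, i))
        closures = sorted(ring_at[i], key=lambda t: emit_rank[t[0]])
        written_nbrs: list = []
        if bond_from is not None:
            written_nbrs.append(bond_from)
        if a.parity is not None and a.explicit_h:
            written_nbrs.append("H")
        written_nbrs.extend(other for other, _ in closures)
        written_nbrs.extend(children[i])
        mark = _parity_mark(a, written_nbrs) if a.parity is not None else None
        out.append(_atom_token(graph, i, mark))
        for other, _me in closures:
            key = (min(i, other), max(i, other))
            d = digit[key]
            tok = str(d) if d < 10 else f"%{d:02d}"
            if emit_rank[other] > emit_rank[i]:     # opening occurrence
                out.append(_bond_token(graph, i, other) + tok)
            else:
                out.append(tok)
        kids = children[i]
        for k, j in enumerate(kids):
            if k < len(kids) - 1:
                out.append("(")
                emit(j, i)
                out.append(")")
            else:
                emit(j, i)

    emit(root, None)
    return "".join(out)


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

_ORGANIC_TOKENS = ["Cl", "Br", "B", "C", "N", "O", "P", "S", "F", "I"]
_AROMATIC_TOKENS = ["b", "c", "n", "o", "p", "s"]

_BRACKET_RE = re.compile(
    r"\[(?P<sym>[A-Z][a-z]?|[a-z]{1,2})"
    r"(?P<chiral>@{1,2})?"
    r"(?P<h>H\d*)?"
    r"(?P<charge>\+\d+|-\d+|\++|-+)?\]"
)


def parse_smiles(smiles: str) -> MolecularGraph:
    """Parse an OpenSMILES string into a :class:`MolecularGraph`."""
    graph = MolecularGraph()
    prev: int | None = None
    pending_bond: int | None = None
    branch_stack: list[int | None] = []
    ring_open: dict[int, tuple[int, int | None, int]] = {}
    default_bonds: list[tuple[int, int]] = []
    k = 0
    n = len(smiles)
    if not smiles:
        return graph

    def add_edge(i, j, order, position):
        if i == j:
            raise SmilesError("ring bond to self", position)
        if graph.has_bond(i, j):
            raise SmilesError("duplicate bond", position)
        if order is None:
            graph.add_bond(i, j, 1)
            default_bonds.append((i, j))
        else:
            graph.add_bond(i, j, order)

    def new_atom(atom: GraphAtom, position: int):
        nonlocal prev, pending_bond
        idx = graph.add_atom(atom)
        if prev is not None:
            add_edge(prev, idx, pending_bond, position)
        pending_bond = None
        prev = idx
        return idx

    while k < n:
        ch = smiles[k]
        if ch == "[":
            m = _BRACKET_RE.match(smiles, k)
            if not m:
                raise SmilesError("malformed bracket atom", k)
            sym = m.group("sym")
            aromatic = sym[0].islower()
            element = sym[0].upper() + sym[1:]
            if element not in ATOMIC_NUMBER:
                raise SmilesError(f"unknown element {sym!r}", k)
            if aromatic and element not in _AROMATIC_OK:
                raise SmilesError(f"{sym!r} cannot be aromatic", k)
            h = m.group("h")
            hcount = 0 if h is None else (1 if h == "H" else int(h[1:]))
            c = m.group("charge") or ""
            if c.startswith(("+", "-")) and len(c) > 1 and c[1:].isdigit():
                charge = int(c[0] + c[1:])
            else:
                charge = c.count("+") - c.count("-")
            atom = GraphAtom(element, charge=charge, explicit_h=hcount,
                             aromatic=aromatic)
            atom._bracketed = True        # type: ignore[attr-defined]
            if m.group("chiral"):
                atom.parity = m.group("chiral")
                atom.parity_ref = ()      # filled after parsing
                atom._parity_pos = k      # type: ignore[attr-defined]
            idx = new_atom(atom, k)
            graph.atoms[idx]._src_prev = (   # type: ignore[attr-defined]
                graph.neighbors(idx)[0] if graph.neighbors(idx) else None)
            k = m.end()
            continue
        if ch.isalpha():
            matched = None
            for tok in _ORGANIC_TOKENS:
                if smiles.startswith(tok, k):
                    matched = tok
                    aromatic = False
                    break
            if matched is None:
                for tok in _AROMATIC_TOKENS:
                    if smiles.startswith(tok, k):
                        matched = tok
                        aromatic = True
                        break
            if matched is None:
                raise SmilesError(f"unknown atom symbol {ch!r}", k)
            element = matched.upper() if aromatic else matched
            element = element[0] + element[1:].lower()
            new_atom(GraphAtom(element, aromatic=aromatic), k)
            k += len(matched)
            continue
        if ch in "-=#:/\\":
            if pending_bond is not None:
                raise SmilesError("two bond symbols in a row", k)
            pending_bond = {"-": 1, "=": 2, "#": 3, ":": AROMATIC_BOND,
                            "/": 1, "\\": 1}[ch]
            k += 1
            continue
        if ch.isdigit() or ch == "%":
            if prev is None:
                raise SmilesError("ring closure before any atom", k)
            if ch == "%":
                if k + 2 >= n or not smiles[k + 1:k + 3].isdigit():
                    raise SmilesError("malformed %nn ring closure", k)
                num = int(smiles[k + 1:k + 3])
                k += 3
            else:
                num = int(ch)
                k += 1
            if num in ring_open:
                j, bond0, _pos = ring_open.pop(num)
                order = pending_bond if pending_bond is not None else bond0
                add_edge(j, prev, order, k - 1)
                _note_ring_neighbor(graph, prev, j)
                _fill_ring_placeholder(graph, j, num, prev)
            else:
                ring_open[num] = (prev, pending_bond, k - 1)
                _note_ring_placeholder(graph, prev, num)
            pending_bond = None
            continue
        if ch == "(":
            if prev is None:
                raise SmilesError("branch before any atom", k)
            branch_stack.append(prev)
            k += 1
            continue
        if ch == ")":
            if not branch_stack:
                raise SmilesError("unmatched ')'", k)
            prev = branch_stack.pop()
            k += 1
            continue
        if ch == ".":
            prev = None
            pending_bond = None
            k += 1
            continue
        if ch.isspace():
            break
        raise SmilesError(f"unexpected character {ch!r}", k)

    if branch_stack:
        raise SmilesError("unclosed branch", n - 1)
    if ring_open:
        num, (_, _, position) = next(iter(ring_open.items()))
        raise SmilesError(f"unmatched ring closure {num}", position)
    if pending_bond is not None:
        raise SmilesError("dangling bond symbol", n - 1)

    _resolve_default_bonds(graph, default_bonds)
    _finalize_hydrogens_and_pi(graph)
    _finalize_parities(graph)
    return graph


def _note_ring_placeholder(graph, i, num):
    slots = getattr(graph.atoms[i], "_ring_slots", None)
    if slots is None:
        slots = graph.atoms[i]._ring_slots = []   # type: ignore[attr-defined]
    slots.append(("open", num))


def _note_ring_neighbor(graph, i, j):
    slots = getattr(graph.atoms[i], "_ring_slots", None)
    if slots is None:
        slots = graph.atoms[i]._ring_slots = []   # type: ignore[attr-defined]
    slots.append(("closed", j))


def _fill_ring_placeholder(graph, i, num, partner):
    """Resolve the opener's slot at the digit's original position."""
    slots = getattr(graph.atoms[i], "_ring_slots", None) or []
    for k, (kind, val) in enumerate(slots):
        if kind == "open" and val == num:
            slots[k] = ("closed", partner)
            return
    slots.append(("closed", partner))


def _resolve_default_bonds(graph: MolecularGraph, default_bonds) -> None:
    """Implicit bonds between two aromatic atoms: aromatic unless a bridge
    of the aromatic-atom subgraph (biphenyl/quinoid linkages are single)."""
    arom = [i for i, a in enumerate(graph.atoms) if a.aromatic]
    sub = nx.Graph()
    sub.add_nodes_from(arom)
    arom_set = set(arom)
    for i, j, _ in graph.bonds():
        if i in arom_set and j in arom_set:
            sub.add_edge(i, j)
    bridges = set()
    for u, v in nx.bridges(sub):
        bridges.add((min(u, v), max(u, v)))
    for i, j in default_bonds:
        if (graph.atoms[i].aromatic and graph.atoms[j].aromatic
                and (min(i, j), max(i, j)) not in bridges):
            graph.set_order(i, j, AROMATIC_BOND)


def _finalize_hydrogens_and_pi(graph: MolecularGraph) -> None:
    for i, a in enumerate(graph.atoms):
        sigma = graph.sigma_sum(i)
        has_multiple = any(o in (2, 3) for o in graph._adj[i].values())
        bare = not getattr(a, "_bracketed", False)
        if a.aromatic:
            if bare and a.element in STANDARD_VALENCES:
                low = STANDARD_VALENCES[a.element][0]
                pi = 0 if has_multiple else 1
                a.explicit_h = max(0, low - sigma - pi)
            if a.element == "C":
                a.kekule_pi = not has_multiple and a.charge == 0
            elif a.element == "N":
                if a.explicit_h > 0 or a.charge != 0:
                    a.kekule_pi = False      # pyrrole-type / charged
                elif sigma >= 3:
                    # [n] with three sigma bonds is a donor keeping its ring
                    # double; a bare 3-connected n is pyrrole-type
                    a.kekule_pi = not bare and not has_multiple
                else:
                    a.kekule_pi = not has_multiple
            else:
                a.kekule_pi = False          # o/s/p lone-pair donors
        else:
            if bare:
                v = _lowest_valence_ge(a.element, sigma)
                if v is None:
                    raise SmilesError(
                        f"no standard valence for {a.element} with {sigma} bonds")
                a.explicit_h = v - sigma


def _finalize_parities(graph: MolecularGraph) -> None:
    for i, a in enumerate(graph.atoms):
        if a.parity is None:
            continue
        nbrs = graph.neighbors(i)
        order: list = []
        src_prev = getattr(a, "_src_prev", None)
        if src_prev is not None:
            order.append(src_prev)
        if a.explicit_h:
            order.append("H")
        slots = getattr(a, "_ring_slots", None) or []
        ring_partners = [j for kind, j in slots if kind == "closed"]
        order.extend(ring_partners)
        for j in nbrs:
            if j not in order and j != src_prev:
                order.append(j)
        if len(order) != 4 or a.explicit_h > 1:
            raise SmilesError("chiral atom lacks four distinct neighbors")
        a.parity_ref = tuple(order)


# patch GraphAtom to accept the transient attributes used during parsing
GraphAtom._parity_pos = None        # type: ignore[attr-defined]
GraphAtom._src_prev = None          # type: ignore[attr-defined]
GraphAtom._ring_slots = None        # type: ignore[attr-defined]
GraphAtom._bracketed = False        # type: ignore[attr-defined]


_MARK_RE = re.compile("@@|@")


def invert_stereo_marks(smiles: str) -> str:
    """Swap every "@@" with "@" (tokenized; an involution)."""
    return _MARK_RE.sub(lambda m: "@" if m.group() == "@@" else "@@", smiles)
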