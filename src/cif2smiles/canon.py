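"""Canonical SMILES by iterative invariant refinement + individualization.

Atoms are ranked by (element, charge, degree, explicit H, aromatic flag,
bond-order multiset), the ranking is refined with neighbor ranks to a fixed
point, and remaining ties are broken by individualizing each member of the
first tied cell in turn and keeping the lexicographically smallest output
string.  The search is capped; beyond the cap the best string found so far
is used (reached only for pathologically symmetric cages).
"""

from __future__ import annotations

from .elements import ATOMIC_NUMBER
from .smiles import AROMATIC_BOND, MolecularGraph, parse_smiles, write_smiles

__all__ = ["canonical_smiles", "canonical_form", "refined_ranks",
           "canonical_moiety_smiles"]

#: cap on complete candidate orders explored per moiety
MAX_CANDIDATES = 10_000


def _initial_keys(graph: MolecularGraph):
    keys = []
    for i, a in enumerate(graph.atoms):
        orders = sorted(9 if o == AROMATIC_BOND else o
                        for o in graph._adj[i].values())
        keys.append((ATOMIC_NUMBER[a.element], a.charge, a.explicit_h,
                     a.aromatic, graph.degree(i), tuple(orders)))
    return keys


def _dense_rank(keys):
    uniq = {k: r for r, k in enumerate(sorted(set(keys)))}
    return [uniq[k] for k in keys]


def _refine(graph: MolecularGraph, ranks):
    n = len(ranks)
    while True:
        keys = []
        for i in range(n):
            nbr = tuple(sorted(
                (9 if o == AROMATIC_BOND else o, ranks[j])
                for j, o in graph._adj[i].items()))
            keys.append((ranks[i], nbr))
        new = _dense_rank(keys)
        if new == ranks:
            return ranks
        ranks = new


def refined_ranks(graph: MolecularGraph) -> list[int]:
    """Stereo-free refined atom ranks (equal rank = not distinguished)."""
    return _refine(graph, _dense_rank(_initial_keys(graph)))


def canonical_moiety_smiles(graph: MolecularGraph) -> str:
    """Canonical string of a single connected graph."""
    n = len(graph)
    if n == 0:
        return ""
    ranks = refined_ranks(graph)
    best: list[str | None] = [None]
    count = [0]

    def emit(order):
        s = write_smiles(graph, order)
        if best[0] is None or s < best[0]:
            best[0] = s

    def rec(ranks):
        if count[0] >= MAX_CANDIDATES:
            return
        cells: dict[int, list[int]] = {}
        for i, r in enumerate(ranks):
            cells.setdefault(r, []).append(i)
        tied = [r for r, members in sorted(cells.items()) if len(members) > 1]
        if not tied:
            count[0] += 1
            emit(sorted(range(n), key=lambda i: ranks[i]))
            return
        cell = cells[tied[0]]
        for chosen in cell:
            keys = [(ranks[i], 0 if i == chosen else 1) for i in range(n)]
            rec(_refine(graph, _dense_rank(keys)))

    rec(ranks)
    assert best[0] is not None
    return best[0]


def canonical_smiles(graph: MolecularGraph) -> str:
    """Canonical string of a full graph: canonical moieties, sorted, joined."""
    parts = [canonical_moiety_smiles(graph.subgraph(m))
             for m in graph.moiety_indices()]
    return ".".join(sorted(parts))


def canonical_form(smiles: str) -> str:
    """Canonicalize a SMILES string."""
    return canonical_smiles(parse_smiles(smiles))
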