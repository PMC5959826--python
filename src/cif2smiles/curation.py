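"""Rule-based SMILES curation and haloanion charge redistribution.

The rule catalog covers the recurring repair families seen in crude
machine-generated strings from crystal structures: terminal metal
carbonyls/isocyanides written with single bonds, oxoanions (perchlorate,
nitrate) without their double bonds and charges, coordinated azide,
coordinated solvent nitriles, imines with a wrongly single C-N bond,
coordinated phosphanes carrying spurious hydrogens, hydrogen-less water,
and neutral haloanions.  Rules are matched on the parsed graph and the
result is re-serialized, which is robust against ring-numbering changes; a
strict text mode (plain find/replace) is available for fidelity testing.

Charge redistribution (the alternative collection): a moiety with exactly
two element types, a B/P/S/As/Al/Bi/Sn/Si/Sb centre, only halogen partners
and a negative total charge is rewritten with all halogens neutral and the
whole charge on one central atom; the rewrite is kept only if the total
moiety charge is unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .canon import canonical_smiles
from .elements import HALOANION_CENTERS, HALOGENS, METALS
from .smiles import (MolecularGraph, SmilesError, parse_smiles, write_smiles)

logger = logging.getLogger(__name__)

__all__ = ["CurationRule", "ChangeLog", "default_rules", "apply_rules",
           "recharge_haloanions", "select_recharge_candidates",
           "load_rules", "dump_rules"]


@dataclass
class CurationRule:
    name: str
    category: str
    pattern: str          # human-readable description or literal text pattern
    replacement: str
    note: str = ""
    text_mode: bool = False

    def apply_graph(self, graph: MolecularGraph) -> bool:
        """Rewrite the graph in place; True if anything changed."""
        fn = _GRAPH_RULES.get(self.name)
        if fn is None:
            return False
        return fn(graph)

    def apply_text(self, smiles: str) -> str:
        return smiles.replace(self.pattern, self.replacement)


@dataclass
class ChangeLog:
    changes: list[tuple[str, str, str]] = field(default_factory=list)

    def add(self, category: str, before: str, after: str) -> None:
        self.changes.append((category, before, after))

    def replay(self, start: str) -> str:
        out = start
        for _cat, before, after in self.changes:
            if out != before:
                raise ValueError("change log does not chain")
            out = after
        return out


# -- graph-level rule implementations ---------------------------------------

def _metal_carbonyl(graph: MolecularGraph) -> bool:
    """[M]([C][O]) -> [M](C#[O]); mu2 bridging CO -> ketone-like C=O."""
    changed = False
    for i, a in enumerate(graph.atoms):
        if a.element != "C" or a.explicit_h:
            continue
        metals = [j for j in graph.neighbors(i) if graph.atoms[j].metal]
        others = [j for j in graph.neighbors(i) if not graph.atoms[j].metal]
        if not metals or len(others) != 1:
            continue
        x = others[0]
        xa = graph.atoms[x]
        if xa.element != "O" or graph.degree(x) != 1 or xa.explicit_h:
            continue
        want = 3 if len(metals) == 1 else 2
        if graph.order(i, x) != want:
            graph.set_order(i, x, want)
            xa.charge = 0
            changed = True
    return changed


def _metal_isocyanide(graph: MolecularGraph) -> bool:
    changed = False
    for i, a in enumerate(graph.atoms):
        if a.element != "C" or a.explicit_h:
            continue
        metals = [j for j in graph.neighbors(i) if graph.atoms[j].metal]
        others = [j for j in graph.neighbors(i) if not graph.atoms[j].metal]
        if len(metals) != 1 or len(others) != 1:
            continue
        x = others[0]
        xa = graph.atoms[x]
        if xa.element != "N" or graph.degree(x) > 2 or xa.explicit_h:
            continue
        if graph.order(i, x) != 3:
            graph.set_order(i, x, 3)
            changed = True
    return changed


def _oxoanion(graph: MolecularGraph, center: str, n_oxygens: int,
              n_double: int) -> bool:
    """Terminal-O pattern: n_double double bonds, the rest charged single."""
    changed = False
    for i, a in enumerate(graph.atoms):
        if a.element != center:
            continue
        terms = [j for j in graph.neighbors(i)
                 if graph.atoms[j].element == "O" and graph.degree(j) == 1
                 and not graph.atoms[j].explicit_h]
        if len(terms) != n_oxygens or graph.degree(i) != n_oxygens:
            continue
        terms.sort()
        want = ([2] * n_double + [1] * (n_oxygens - n_double))
        orders = [graph.order(i, j) for j in terms]
        charges = [graph.atoms[j].charge for j in terms]
        want_charges = [0] * n_double + [-1] * (n_oxygens - n_double)
        if sorted(orders) != sorted(want) or sorted(charges) != sorted(want_charges):
            for j, o, q in zip(terms, want, want_charges):
                graph.set_order(i, j, o)
                graph.atoms[j].charge = q
            a.charge = 0
            changed = True
    return changed


def _perchlorate(graph):
    return _oxoanion(graph, "Cl", 4, 3)


def _nitrate(graph):
    changed = False
    for i, a in enumerate(graph.atoms):
        if a.element != "N" or graph.degree(i) != 3:
            continue
        terms = [j for j in graph.neighbors(i)
                 if graph.atoms[j].element == "O" and graph.degree(j) == 1
                 and not graph.atoms[j].explicit_h]
        if len(terms) == 3:
            changed |= _oxoanion(graph, "N", 3, 2)
    return changed


def _coordinated_azide(graph: MolecularGraph) -> bool:
    """M-N-N-N chain -> M-N=[N+]=[N-]."""
    changed = False
    for i, a in enumerate(graph.atoms):
        if a.element != "N" or not graph.has_metal_neighbor(i):
            continue
        chain = [j for j in graph.neighbors(i)
                 if graph.atoms[j].element == "N"]
        if len(chain) != 1:
            continue
        mid = chain[0]
        tail = [j for j in graph.neighbors(mid)
                if graph.atoms[j].element == "N" and j != i
                and graph.degree(j) == 1]
        if len(tail) != 1 or graph.degree(mid) != 2:
            continue
        t = tail[0]
        if (graph.order(i, mid), graph.order(mid, t)) != (2, 2):
            graph.set_order(i, mid, 2)
            graph.set_order(mid, t, 2)
            graph.atoms[mid].charge = 1
            graph.atoms[t].charge = -1
            graph.atoms[i].charge = 0
            changed = True
    return changed


def _coordinated_nitrile(graph: MolecularGraph) -> bool:
    """Coordinated MeCN-type solvent: M-N-C-C with wrong N-C order."""
    changed = False
    for i, a in enumerate(graph.atoms):
        if a.element != "N" or not graph.has_metal_neighbor(i) or a.explicit_h:
            continue
        carbons = [j for j in graph.neighbors(i)
                   if graph.atoms[j].element == "C"]
        if len(carbons) != 1:
            continue
        c = carbons[0]
        if graph.atoms[c].explicit_h or graph.degree(c) != 2:
            continue
        if graph.order(i, c) != 3:
            graph.set_order(i, c, 3)
            changed = True
    return changed


def _imine_fix(graph: MolecularGraph) -> bool:
    """C and N, both one bond short of a standard valence, joined by a
    single bond: make it double (the classic wrong-single-imine)."""
    changed = False
    for i, j, o in list(graph.bonds()):
        if o != 1:
            continue
        ai, aj = graph.atoms[i], graph.atoms[j]
        pair = {ai.element, aj.element}
        if pair != {"C", "N"} or ai.aromatic or aj.aromatic:
            continue
        needs = []
        for k in (i, j):
            a = graph.atoms[k]
            val = a.explicit_h + sum(
                oo for m, oo in graph._adj[k].items()
                if not graph.atoms[m].metal)
            target = 4 if a.element == "C" else 3
            needs.append(target - val == 1)
        if all(needs):
            graph.set_order(i, j, 2)
            changed = True
    return changed


def _phosphane_h(graph: MolecularGraph) -> bool:
    """Coordinated PR3 with spurious explicit H on phosphorus."""
    changed = False
    for i, a in enumerate(graph.atoms):
        if (a.element == "P" and a.explicit_h and graph.has_metal_neighbor(i)
                and sum(1 for j in graph.neighbors(i)
                        if not graph.atoms[j].metal) == 3):
            a.explicit_h = 0
            changed = True
    return changed


def _bare_water(graph: MolecularGraph) -> bool:
    """Lone [O] / [OH] moieties are hydrogen-less water."""
    changed = False
    for i, a in enumerate(graph.atoms):
        if a.element == "O" and graph.degree(i) == 0 and a.charge == 0 \
                and a.explicit_h < 2:
            a.explicit_h = 2
            changed = True
    return changed


def _neutral_haloanion(graph: MolecularGraph) -> bool:
    """Hypervalent all-halogen p-block centre without charges: put -1 on a
    terminal halogen per missing valence unit (the main-collection form)."""
    from .elements import STANDARD_VALENCES, HYPERVALENT_MAX
    changed = False
    for moiety in graph.moiety_indices():
        elements = {graph.atoms[i].element for i in moiety}
        centers = [i for i in moiety
                   if graph.atoms[i].element in HALOANION_CENTERS]
        if len(elements) != 2 or not centers:
            continue
        c = centers[0]
        ce = graph.atoms[c].element
        halns = [j for j in graph.neighbors(c)
                 if graph.atoms[j].element in HALOGENS]
        if len(halns) != graph.degree(c) or len(halns) < 3:
            continue
        maxv = _center_max_valence(ce)
        extra = graph.degree(c) - maxv
        total = sum(graph.atoms[i].charge for i in moiety)
        if extra > 0 and total == 0:
            for j in sorted(halns)[-extra:]:
                graph.atoms[j].charge = -1
            changed = True
    return changed


_CENTER_MAX = {"B": 3, "P": 5, "S": 6, "As": 5, "Al": 3, "Bi": 3,
               "Sn": 4, "Si": 4, "Sb": 5}


def _center_max_valence(element: str) -> int:
    return _CENTER_MAX.get(element, 8)


_GRAPH_RULES = {
    "metal_carbonyl": _metal_carbonyl,
    "metal_isocyanide": _metal_isocyanide,
    "perchlorate": _perchlorate,
    "nitrate": _nitrate,
    "coordinated_azide": _coordinated_azide,
    "coordinated_nitrile": _coordinated_nitrile,
    "imine_bond": _imine_fix,
    "phosphane_h": _phosphane_h,
    "bare_water": _bare_water,
    "haloanion_charge": _neutral_haloanion,
}


def default_rules() -> list[CurationRule]:
    return [
        CurationRule("metal_carbonyl", "carbonyl",
                     "[M]([C][O])", "[M](C#[O])",
                     "terminal carbonyl triple bond; mu2-CO ketone-like"),
        CurationRule("metal_isocyanide", "isocyanide",
                     "[M][C][N]R", "[M]C#[N]R",
                     "isocyanides treated like carbonyls"),
        CurationRule("perchlorate", "oxoanion",
                     "Cl(O)(O)(O)O", "Cl(=O)(=O)(=O)[O-]",
                     "three double bonds, one charged oxygen"),
        CurationRule("nitrate", "oxoanion",
                     "N(O)(O)O", "N(=O)(=O)[O-]",
                     "nitro/nitrate double bonds"),
        CurationRule("coordinated_azide", "azide",
                     "[M]NNN", "[M]N=[N+]=[N-]",
                     "cumulated azide with terminal charge"),
        CurationRule("coordinated_nitrile", "solvent",
                     "[M][N][C]C", "[M][N]#CC",
                     "coordinated MeCN and congeners"),
        CurationRule("imine_bond", "imine",
                     "C-N (both unsaturated)", "C=N",
                     "imines with a wrong single C-N bond"),
        CurationRule("phosphane_h", "phosphane",
                     "[PH](R)(R)R bound to M", "[P](R)(R)R",
                     "spurious H on coordinated phosphane"),
        CurationRule("bare_water", "water",
                     "[O] or [OH] lone moiety", "O",
                     "hydrogen-less water molecules"),
        CurationRule("haloanion_charge", "haloanion",
                     "[P](F)(F)(F)(F)(F)F", "[P](F)(F)(F)(F)(F)[F-]",
                     "terminal charge on neutral haloanions"),
    ]


def apply_rules(smiles: str, rules: list[CurationRule] | None = None,
                text_mode: bool = False) -> tuple[str, ChangeLog]:
    """Apply the rule catalog in order, each exhaustively, logging changes."""
    rules = default_rules() if rules is None else rules
    log = ChangeLog()
    current = smiles
    if text_mode:
        for rule in rules:
            if not rule.text_mode:
                continue
            after = rule.apply_text(current)
            if after != current:
                try:
                    parse_smiles(after)
                except SmilesError:
                    logger.warning("rule %s produced unparseable output; "
                                   "kept input", rule.name)
                    continue
                log.add(rule.category, current, after)
                current = after
        return current, log
    try:
        graph = parse_smiles(current)
    except SmilesError as exc:
        raise SmilesError(f"cannot curate unparseable SMILES: {exc}")
    for rule in rules:
        work = graph.copy()
        if rule.apply_graph(work):
            after = write_smiles(work)
            try:
                parse_smiles(after)
            except SmilesError:
                logger.warning("rule %s produced unparseable output; kept "
                               "input", rule.name)
                continue
            log.add(rule.category, write_smiles(graph), after)
            graph = work
    return write_smiles(graph), log


# -- haloanion recharge ------------------------------------------------------

def recharge_haloanions(smiles: str) -> str:
    """Move the whole negative charge of simple haloanions onto the centre."""
    graph = parse_smiles(smiles)
    changed = False
    for moiety in graph.moiety_indices():
        atoms = [graph.atoms[i] for i in moiety]
        elements = {a.element for a in atoms}
        if len(elements) != 2:
            continue
        halogens = elements & HALOGENS
        centers = elements & HALOANION_CENTERS
        if not halogens or not centers or halogens == centers:
            continue
        total = sum(a.charge for a in atoms)
        if total >= 0:
            continue
        center_atoms = sorted(
            (i for i in moiety if graph.atoms[i].element in centers),
            key=lambda i: (-sum(1 for j in graph.neighbors(i)
                                if graph.atoms[j].element in HALOGENS), i))
        new_charges = {i: 0 for i in moiety}
        new_charges[center_atoms[0]] = total
        if sum(new_charges.values()) != total:
            continue          # conservation check failed: leave unaltered
        for i, q in new_charges.items():
            graph.atoms[i].charge = q
        changed = True
    return write_smiles(graph) if changed else smiles


def select_recharge_candidates(records) -> list:
    """Records containing a centre with at least three halogen neighbors."""
    out = []
    for rec in records:
        try:
            graph = parse_smiles(rec.smiles)
        except SmilesError:
            continue
        for i, a in enumerate(graph.atoms):
            if a.element in HALOANION_CENTERS:
                nh = sum(1 for j in graph.neighbors(i)
                         if graph.atoms[j].element in HALOGENS)
                if nh >= 3:
                    out.append(rec)
                    break
    return out


# -- rule config file --------------------------------------------------------

def dump_rules(rules: list[CurationRule]) -> str:
    lines = ["# name\tcategory\tpattern\treplacement\tnote"]
    for r in rules:
        lines.append(f"{r.name}\t{r.category}\t{r.pattern}\t"
                     f"{r.replacement}\t{r.note}")
    return "\n".join(lines) + "\n"


def load_rules(text: str) -> list[CurationRule]:
    rules = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 4:
            raise ValueError(f"bad rule line: {line!r}")
        name, category, pattern, replacement = parts[:4]
        note = parts[4] if len(parts) > 4 else ""
        rules.append(CurationRule(name, category, pattern, replacement, note))
    return rules
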