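"""Tetrahedral stereocenters from 3-D geometry and the racemate policy.

A crystal in a Sohncke group (only proper symmetry operations) contains a
single enantiomer, so tetrahedral marks read off the asymmetric unit stand
as they are.  In a non-Sohncke group the crystal is racemic: a single mark
is simply removed ("unspecified" meaning both enantiomers), while two or
more marks carry relative configuration and the moiety is written twice,
the second copy with every mark inverted.  Meso moieties, identical to
their mirror image, are written once.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np

from .canon import canonical_smiles, refined_ranks
from .cif import SymOp
from .smiles import MolecularGraph, invert_stereo_marks, parse_smiles

_MARKS = re.compile("@@|@")

logger = logging.getLogger(__name__)

__all__ = ["StereoVerdict", "is_sohncke", "perceive_tetrahedral",
           "apply_racemate_policy", "PLANARITY_CUTOFF"]

#: minimum |signed volume| (A^3) below which no parity is assigned
PLANARITY_CUTOFF = 0.1


@dataclass
class StereoVerdict:
    is_sohncke: bool
    n_stereocenters_per_moiety: dict[int, int] = field(default_factory=dict)
    policy_applied: str = "kept"       # kept|marks_stripped|enantiomer_doubled|meso_single


def is_sohncke(symops: list[SymOp]) -> bool:
    """True iff every rotation part is proper (determinant +1)."""
    if not symops:
        raise ValueError("empty operator list")
    return all(op.determinant == 1 for op in symops)


def perceive_tetrahedral(graph: MolecularGraph) -> int:
    """Assign @/@@ parities from coordinates; returns the number of marks.

    An atom gets a mark when it has four distinct substituents (the
    implicit hydrogen counts as one) whose canonical ranks all differ, and
    the four points are not near-coplanar.
    """
    ranks = refined_ranks(graph)
    n_marked = 0
    for i, a in enumerate(graph.atoms):
        a.parity = None
        a.parity_ref = None
        if a.cart is None or a.aromatic:
            continue
        nbrs = graph.neighbors(i)
        total = len(nbrs) + a.explicit_h
        if total != 4 or a.explicit_h > 1:
            continue
        if any(graph.order(i, j) != 1 for j in nbrs):
            continue
        keys = [ranks[j] for j in nbrs] + (["H"] if a.explicit_h else [])
        if len(set(keys)) != 4:
            continue
        ref: list = sorted(nbrs)
        points = []
        ok = True
        for j in ref:
            if graph.atoms[j].cart is None:
                ok = False
                break
            points.append(np.asarray(graph.atoms[j].cart, float))
        if not ok:
            continue
        if a.explicit_h:
            if a.h_cart is not None:
                hpos = np.asarray(a.h_cart, float)
            else:
                center = np.asarray(a.cart, float)
                dirs = [p - center for p in points]
                s = -sum(d / np.linalg.norm(d) for d in dirs)
                hpos = center + s / max(np.linalg.norm(s), 1e-9)
            ref = ["H"] + ref
            points = [hpos] + points
        v = [p - points[0] for p in points[1:]]
        det = float(np.linalg.det(np.array(v)))
        if abs(det) / 6.0 < PLANARITY_CUTOFF:
            logger.warning("near-planar center at atom %d: no parity", i)
            continue
        a.parity = "@@" if det > 0 else "@"
        a.parity_ref = tuple(ref)
        n_marked += 1
    return n_marked


def _is_meso(smiles: str) -> bool:
    g = parse_smiles(smiles)
    return canonical_smiles(g) == canonical_smiles(g.mirrored())


def apply_racemate_policy(moiety_smiles: str, sohncke: bool) -> tuple[str, str]:
    """Apply the Sohncke/racemate convention to one canonical moiety string.

    Returns (final string, policy label).  Idempotent: a string that is
    already an enantiomer pair is returned unchanged.
    """
    n_marks = len(_MARKS.findall(moiety_smiles))
    if n_marks == 0 or sohncke:
        return moiety_smiles, "kept"
    g = parse_smiles(moiety_smiles)
    mois = g.moiety_indices()
    if len(mois) == 2:
        a = canonical_smiles(g.subgraph(mois[0]))
        b = canonical_smiles(g.subgraph(mois[1]).mirrored())
        if a == b:
            return moiety_smiles, "enantiomer_doubled"
    if n_marks == 1:
        for a_ in g.atoms:
            a_.parity = a_.parity_ref = None
        return canonical_smiles(g), "marks_stripped"
    if _is_meso(moiety_smiles):
        return moiety_smiles, "meso_single"
    return (moiety_smiles + "." + invert_stereo_marks(moiety_smiles),
            "enantiomer_doubled")
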