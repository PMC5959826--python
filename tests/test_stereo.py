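"""Sohncke classification, tetrahedral perception, racemate policy."""

import numpy as np
import pytest

from cif2smiles.canon import canonical_smiles
from cif2smiles.cif import parse_symop
from cif2smiles.smiles import GraphAtom, MolecularGraph, parse_smiles
from cif2smiles.stereo import (apply_racemate_policy, is_sohncke,
                               perceive_tetrahedral)


def test_sohncke_trivials():
    assert is_sohncke([parse_symop("x,y,z")])
    assert not is_sohncke([parse_symop("x,y,z"), parse_symop("-x,-y,-z")])


def test_p212121_is_sohncke():
    ops = ["x,y,z", "-x+1/2,-y,z+1/2", "-x,y+1/2,-z+1/2", "x+1/2,-y+1/2,-z"]
    parsed = [parse_symop(o) for o in ops]
    assert all(op.determinant == 1 for op in parsed)
    assert is_sohncke(parsed)


def test_sohncke_oracle_all_230_settings():
    """Determinant oracle over one setting per space-group number; the
    crystallographically known count of Sohncke groups is 65."""
    from cif2smiles.fixtures import spacegroup_symops
    count = 0
    for number in range(1, 231):
        ops = [parse_symop(t) for t in spacegroup_symops(number)]
        verdict = is_sohncke(ops)
        oracle = all(
            round(np.linalg.det(np.array(op.rotation, dtype=float))) == 1
            for op in ops)
        assert verdict == oracle, number
        count += verdict
    assert count == 65


def _chfclbr(mirror=False):
    g = MolecularGraph()
    dirs = np.array([(1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)],
                    dtype=float) / np.sqrt(3)
    if mirror:
        dirs = dirs * np.array([1, 1, -1])
    g.add_atom(GraphAtom("C", explicit_h=1, cart=np.zeros(3),
                         h_cart=dirs[0] * 1.09))
    for el, d, r in (("F", dirs[1], 1.35), ("Cl", dirs[2], 1.77),
                     ("Br", dirs[3], 1.94)):
        g.add_atom(GraphAtom(el, cart=d * r))
    for j in (1, 2, 3):
        g.add_bond(0, j, 1)
    return g


def test_chfclbr_one_center_and_mirror_flips():
    g = _chfclbr()
    assert perceive_tetrahedral(g) == 1
    m = _chfclbr(mirror=True)
    perceive_tetrahedral(m)
    assert g.atoms[0].parity != m.atoms[0].parity
    assert canonical_smiles(g) == canonical_smiles(m.mirrored())


def test_neopentane_no_marks():
    g = MolecularGraph()
    g.add_atom(GraphAtom("C", cart=np.zeros(3)))
    dirs = np.array([(1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)],
                    dtype=float) / np.sqrt(3)
    for d in dirs:
        g.add_atom(GraphAtom("C", explicit_h=3, cart=d * 1.54))
    for j in range(1, 5):
        g.add_bond(0, j, 1)
    assert perceive_tetrahedral(g) == 0


def test_near_planar_center_refused():
    g = MolecularGraph()
    g.add_atom(GraphAtom("C", explicit_h=1, cart=np.zeros(3),
                         h_cart=np.array([0.0, 0.0, 0.02])))
    for el, ang in (("F", 0.0), ("Cl", 2.1), ("Br", 4.2)):
        g.add_atom(GraphAtom(el, cart=np.array(
            [np.cos(ang), np.sin(ang), 0.0]) * 1.5))
    for j in (1, 2, 3):
        g.add_bond(0, j, 1)
    assert perceive_tetrahedral(g) == 0


def test_racemate_policy_branches():
    # Sohncke: kept
    s = "C[C@H](N)C(=O)O"
    assert apply_racemate_policy(s, sohncke=True) == (s, "kept")
    # single mark, non-Sohncke: stripped
    out, pol = apply_racemate_policy(s, sohncke=False)
    assert pol == "marks_stripped" and "@" not in out
    # two marks: doubled with canonical mirror moieties
    two = "C[C@H](O)[C@@H](N)F"
    out, pol = apply_racemate_policy(two, sohncke=False)
    assert pol == "enantiomer_doubled"
    g = parse_smiles(out)
    a, b = [g.subgraph(m) for m in g.moiety_indices()]
    assert canonical_smiles(a) == canonical_smiles(b.mirrored())


def test_racemate_policy_idempotent():
    for s in ("C[C@H](N)C(=O)O", "C[C@H](O)[C@@H](N)F", "CCO"):
        out1, _ = apply_racemate_policy(s, sohncke=False)
        out2, _ = apply_racemate_policy(out1, sohncke=False)
        assert out1 == out2


def test_meso_single_copy():
    # (R,S)-1,2-difluoro-1,2-dichloroethane: identical to its mirror image
    meso = "[C@@H](F)(Cl)[C@@H](F)Cl"
    g = parse_smiles(meso)
    if canonical_smiles(g) != canonical_smiles(g.mirrored()):
        meso = "[C@H](F)(Cl)[C@@H](F)Cl"
        g = parse_smiles(meso)
    assert canonical_smiles(g) == canonical_smiles(g.mirrored())
    out, pol = apply_racemate_policy(canonical_smiles(g), sohncke=False)
    assert pol == "meso_single" and "." not in out


def test_fixture_policies(pipeline_results):
    assert pipeline_results["sohncke_single"].policy_applied == ["kept"]
    assert pipeline_results["racemic_single"].policy_applied == [
        "marks_stripped"]
    assert pipeline_results["racemic_two"].policy_applied == [
        "enantiomer_doubled"]
    assert pipeline_results["meso"].policy_applied == ["meso_single"]
    out = pipeline_results["racemic_two"].record.smiles
    g = parse_smiles(out)
    mois = g.moiety_indices()
    assert len(mois) == 2
    a, b = [g.subgraph(m) for m in mois]
    assert canonical_smiles(a) == canonical_smiles(b.mirrored())
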