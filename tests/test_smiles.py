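"""SMILES parser/writer round trips and string utilities."""

import random

import pytest

from cif2smiles.canon import canonical_form, canonical_smiles
from cif2smiles.smiles import (SmilesError, invert_stereo_marks,
                               parse_smiles, write_smiles)

PAPER_STRINGS = [
    "c1ccc[nH]1", "c1cccs1", "C1=CC=CC1", "[cH-]1cccc1", "c1(=O)cccc1",
    "c1(=O)[nH]cccc1", "C1(=O)NC(=O)NC=C1", "O=C1C=CC(=O)C=C1",
    "c12ccccc1C(=O)c1ccccc1C2(=O)", "c12ccccc1C(=C)c1ccccc12",
    "[Ni]=C1N(C)C=CN1C",
    "[Ni]1[NH2]CC[NH2]1",
    "[Au][P](c1ccccc1)(c1ccccc1)c1ccccc1",
    "[Zn]([OH2])([OH2])([OH2])([OH2])([OH2])[OH2]",
    "[Co]Oc1ccccc1",
    "[Cu]([n]1ccccc1)([n]1ccccc1)(Cl)Cl",
    "[Mn][n]1c[nH]cc1", "[Mn]n1cncc1",
    "[Cd]12([O]=C(O1)C)[O]=C(O2)C",
    "[Gd]1[O]=C(C)C=C(C)O1",
    "[Ni](C#[O])(C#[O])(C#[O])C#[O]",
    "[Co]1(C#[O])(C#[O])(C#[O])C(=O)[Co](C#[O])(C#[O])(C#[O])C1=O",
    "[Pb](CC)(CC)(CC)CC",
    "[Rh]123[CH]4=[CH]1CC[CH]2=[CH]3CC4",
    "[Ti]123[CH2]=[CH]1[CH]2=[CH2]3",
    "[Pd]1234(C[CH]1=[CH2]2)C[CH]3=[CH2]4",
    "[Fe]12345678([cH]9[cH]1[cH]2[cH]3[cH]49)[cH]1[cH]5[cH]6[cH]7[cH]81",
    "[Zr]1234[cH]5[cH]1[cH]2[c]13[c]45cccc1",
    "[Ru]12345[c]6(C(C)C)[cH]1[cH]2[c]3(C)[cH]4[cH]56",
    "[Na+].[Cl-]", "[Cu][n]1ccccc1",
    "[P](F)(F)(F)(F)(F)[F-]", "[P-](F)(F)(F)(F)(F)F",
    "C[C@H](N)C=O", "C[C@H](O)[C@@H](N)C",
    "Cn1cnc2c1C(=O)N(C)C(=O)N2C",
]


@pytest.mark.parametrize("s", PAPER_STRINGS)
def test_parse_write_roundtrip(s):
    """parse-write-parse preserves atoms, bonds, charges and H counts."""
    g = parse_smiles(s)
    w = write_smiles(g)
    g2 = parse_smiles(w)
    assert g.element_counts() == g2.element_counts()
    assert sorted(o for _, _, o in g.bonds()) == sorted(
        o for _, _, o in g2.bonds())
    assert sorted(a.charge for a in g.atoms) == sorted(
        a.charge for a in g2.atoms)
    assert canonical_form(s) == canonical_form(w)


def test_simple_semantics():
    g = parse_smiles("[Na+].[Cl-]")
    assert len(g.moiety_indices()) == 2
    assert sorted(a.charge for a in g.atoms) == [-1, 1]
    g = parse_smiles("C")
    assert g.atoms[0].explicit_h == 4
    g = parse_smiles("c1ccccc1")
    assert all(a.explicit_h == 1 and a.aromatic for a in g.atoms)
    g = parse_smiles("C[NH3+]")
    assert g.atoms[1].charge == 1 and g.atoms[1].explicit_h == 3


def test_biphenyl_type_bond_is_single():
    g = parse_smiles("c1ccccc1c1ccccc1")
    singles = [(i, j) for i, j, o in g.bonds() if o == 1]
    assert len(singles) == 1


def test_positioned_errors():
    with pytest.raises(SmilesError) as err:
        parse_smiles("C1CC")
    assert err.value.position == 1
    with pytest.raises(SmilesError):
        parse_smiles("C[Xx]")
    with pytest.raises(SmilesError):
        parse_smiles("C(C))C")
    with pytest.raises(SmilesError):
        parse_smiles("C=")


def test_percent_ring_closures():
    s = "[Fe]12345678([cH]9[cH]1[cH]2[cH]3[cH]49)[cH]1[cH]5[cH]6[cH]7[cH]81"
    g = parse_smiles(s)
    w = write_smiles(g)
    assert canonical_form(w) == canonical_form(s)


def test_invert_stereo_marks():
    assert invert_stereo_marks("C[C@H](N)C=O") == "C[C@@H](N)C=O"
    assert invert_stereo_marks("CCO") == "CCO"
    rng = random.Random(7)
    pool = ["C[C@H](N)C=O", "C[C@@H](O)[C@H](F)Cl", "[C@](C)(N)(O)F"]
    for _ in range(1000):
        s = rng.choice(pool) + rng.choice(["", ".CC", ".[Na+]"])
        assert invert_stereo_marks(invert_stereo_marks(s)) == s


def test_mirror_changes_chiral_canonical():
    g = parse_smiles("C[C@H](N)C=O")
    assert canonical_smiles(g) != canonical_smiles(g.mirrored())
    assert canonical_smiles(g.mirrored()) == canonical_form(
        invert_stereo_marks(write_smiles(g)))
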