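"""Curation rule families and haloanion charge redistribution."""

import random

import pytest

from cif2smiles.canon import canonical_form
from cif2smiles.curation import (apply_rules, default_rules, dump_rules,
                                 load_rules, recharge_haloanions,
                                 select_recharge_candidates)
from cif2smiles.smiles import SmilesRecord, parse_smiles


def canon(s):
    return canonical_form(s)


def test_carbonyl_rule_worked_example():
    out, log = apply_rules("[Co][C][O]")
    assert canon(out) == canon("[Co]C#[O]")
    assert log.changes and log.changes[0][0] == "carbonyl"


def test_no_match_is_identity():
    out, log = apply_rules("CCO")
    assert out == "CCO" and log.changes == []


def test_bare_water_rule():
    out, _ = apply_rules("[O]")
    assert canon(out) == canon("O")


def test_nitrate_rule():
    out, _ = apply_rules("[O]N([O])[O]")
    assert canon(out) == canon("[O-]N(=O)=O")


def test_perchlorate_rule():
    out, _ = apply_rules("[O][Cl]([O])([O])[O]")
    assert canon(out) == canon("[O-][Cl](=O)(=O)=O")


def test_coordinated_nitrile_rule():
    out, _ = apply_rules("[Ag][N][C]C")
    assert canon(out) == canon("[Ag][N]#CC")


def test_imine_rule():
    # crude imine with a wrong single C-N bond (both atoms one bond short)
    out, _ = apply_rules("C[CH][N]C")
    assert canon(out) == canon("CC=NC")


def test_phosphane_rule():
    out, _ = apply_rules("[Au][PH](C)(C)C")
    assert canon(out) == canon("[Au][P](C)(C)C")


def test_azide_rule():
    out, _ = apply_rules("[Fe][N][N][N]")
    assert canon(out) == canon("[Fe]N=[N+]=[N-]")


def test_haloanion_rule_neutral_input():
    out, _ = apply_rules("F[P](F)(F)(F)(F)F")
    assert canon(out) == canon("[P](F)(F)(F)(F)(F)[F-]")


def test_changelog_replay():
    out, log = apply_rules("[Co][C][O]")
    assert log.replay(log.changes[0][1]) == out


def test_rules_config_roundtrip():
    text = dump_rules(default_rules())
    rules = load_rules(text)
    assert [r.name for r in rules] == [r.name for r in default_rules()]


def test_recharge_worked_example_exact():
    assert recharge_haloanions("[P](F)(F)(F)(F)(F)[F-]") == \
        "[P-](F)(F)(F)(F)(F)F"


def test_recharge_bf4():
    out = recharge_haloanions("[B](F)(F)(F)[F-]")
    assert canon(out) == canon("[B-](F)(F)(F)F")


def test_recharge_noop_three_element_types():
    s = "[Sn](C)(C)(Cl)Cl"
    assert recharge_haloanions(s) == s


def test_recharge_conserves_charge_randomized():
    rng = random.Random(2024)
    centers = ["P", "B", "Sb", "As", "Si"]
    hals = ["F", "Cl", "Br"]
    for _ in range(500):
        c = rng.choice(centers)
        h = rng.choice(hals)
        n = rng.randint(3, 6)
        q = rng.randint(1, 2)
        parts = []
        for k in range(n):
            parts.append(f"[{h}-]" if k < q else h)
        s = f"[{c}](" + ")(".join(parts[:-1]) + ")" + parts[-1]
        before = sum(a.charge for a in parse_smiles(s).atoms)
        out = recharge_haloanions(s)
        after = sum(a.charge for a in parse_smiles(out).atoms)
        assert before == after
        assert recharge_haloanions(out) == out        # idempotent


def test_recharge_noop_on_non_candidates():
    rng = random.Random(7)
    pool = ["CCO", "c1ccccc1", "C[N+](C)(C)C", "[Na+].[Cl-]",
            "ClC(Cl)Cl", "CC(=O)[O-]"]
    for _ in range(500):
        s = rng.choice(pool)
        assert recharge_haloanions(s) == s


def test_select_recharge_candidates():
    records = [SmilesRecord("[P](F)(F)(F)(F)(F)[F-]", "1"),
               SmilesRecord("ClC(Cl)Cl", "2"),
               SmilesRecord("Cl[Sn]Cl", "3")]
    picked = select_recharge_candidates(records)
    assert [r.entry_id for r in picked] == ["1"]


def test_rules_idempotent_on_own_output():
    for s in ("[Co][C][O]", "[O]N([O])[O]", "F[P](F)(F)(F)(F)F"):
        out1, _ = apply_rules(s)
        out2, log2 = apply_rules(out1)
        assert canon(out1) == canon(out2)
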