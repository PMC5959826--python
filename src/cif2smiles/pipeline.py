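"""End-to-end orchestration: triage, molecule building, bond model, stereo
policy, curation, and collection files.

Each entry is converted twice, once from perceived bonds only and once with
the CIF-listed bonds merged in; when the two canonical results disagree the
record is flagged for review (the perceived-only result is kept), mirroring
the dual-run consistency check used when curating real collections.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace as dc_replace

from .bonds import BondPolicy
from .builder import BuiltMolecule, UnsupportedPolymerError, build_molecule
from .canon import canonical_form
from .cif import CrystalEntry
from .curation import ChangeLog, CurationRule, apply_rules
from .smiles import SmilesError, SmilesRecord, parse_smiles
from .stereo import (apply_racemate_policy, is_sohncke, perceive_tetrahedral)

logger = logging.getLogger(__name__)

__all__ = ["ConversionResult", "run_entry", "write_collection",
           "write_alt_collection", "ConversionError"]


class ConversionError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class ConversionResult:
    record: SmilesRecord
    changelog: ChangeLog
    review: bool = False
    candidates: tuple[str, ...] = ()
    built: BuiltMolecule | None = None
    policy_applied: list[str] = field(default_factory=list)
    log: list[str] = field(default_factory=list)


def _crude_smiles(entry: CrystalEntry, policy: BondPolicy,
                  sohncke: bool) -> tuple[str, BuiltMolecule, list[str]]:
    """Build the molecule and produce the stereo-resolved crude SMILES."""
    built = build_molecule(entry, policy)
    graph = built.graph
    perceive_tetrahedral(graph)
    parts: list[str] = []
    policies: list[str] = []
    from .canon import canonical_moiety_smiles
    for m in built.moieties:
        sub = graph.subgraph(m.atom_indices)
        s = canonical_moiety_smiles(sub)
        s, pol = apply_racemate_policy(s, sohncke)
        policies.append(pol)
        parts.extend([s] * m.multiplicity)
    return ".".join(parts), built, policies


def run_entry(entry: CrystalEntry, policy: BondPolicy | None = None,
              rules: list[CurationRule] | None = None) -> ConversionResult:
    """Convert one entry; never silently skips a stage failure."""
    policy = policy or BondPolicy()
    try:
        sohncke = is_sohncke(entry.symops)
    except Exception as exc:
        raise ConversionError("triage", str(exc)) from exc

    try:
        p_perc = dc_replace(policy, bond_source="perceived")
        crude_p, built, pols = _crude_smiles(entry, p_perc, sohncke)
        if entry.geom_bonds:
            p_merge = dc_replace(policy, bond_source="merged")
            crude_m, _, _ = _crude_smiles(entry, p_merge, sohncke)
        else:
            crude_m = crude_p
    except UnsupportedPolymerError as exc:
        raise ConversionError("molecule", str(exc)) from exc
    except ConversionError:
        raise
    except Exception as exc:
        raise ConversionError("bonds", str(exc)) from exc

    review = False
    candidates: tuple[str, ...] = ()
    crude = crude_p
    if canonical_form(crude_p) != canonical_form(crude_m):
        review = True
        candidates = (crude_p, crude_m)
        logger.warning("entry %s: bond sources disagree; kept perceived-only",
                       entry.id)

    try:
        curated, changelog = apply_rules(crude, rules)
        parse_smiles(curated)       # final validity re-parse
    except SmilesError as exc:
        raise ConversionError("curation", str(exc)) from exc

    return ConversionResult(
        record=SmilesRecord(curated, entry.id),
        changelog=changelog, review=review, candidates=candidates,
        built=built, policy_applied=pols, log=built.log)


def write_collection(records: list[SmilesRecord]) -> str:
    """``SMILES<TAB>ID`` lines; every line re-parsed, any failure aborts."""
    lines = []
    for k, rec in enumerate(sorted(records, key=lambda r: r.entry_id)):
        try:
            parse_smiles(rec.smiles)
        except SmilesError as exc:
            raise ConversionError(
                "collection", f"line {k + 1} ({rec.entry_id}): {exc}")
        lines.append(rec.line())
    return "\n".join(lines) + ("\n" if lines else "")


def write_alt_collection(records: list[SmilesRecord]) -> str:
    """Haloanion-recharged companion collection (candidates only)."""
    from .curation import recharge_haloanions, select_recharge_candidates
    out = []
    for rec in select_recharge_candidates(records):
        out.append(SmilesRecord(recharge_haloanions(rec.smiles),
                                rec.entry_id))
    return write_collection(out)
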