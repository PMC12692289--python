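"""Protease cleavage specificities and cut-site computation.

Each enzyme is reduced to a P1/P1' rule: the set of residues whose flanking
peptide bond is hydrolysed (P1), the flank that is recognized (cleavage
C-terminal or N-terminal to the P1 residue), and an optional set of
opposite-flank residues that suppress cleavage (classically proline).

Bond indexing is 1-based: bond ``i`` joins residues ``i`` and ``i+1`` of the
chain, so valid bonds are ``1 .. N-1`` and there are no terminal
pseudo-bonds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

from .sequence_io import AMINO_ACIDS, ProteinSequence

_AA_SET = frozenset(AMINO_ACIDS)

SIDE_CTERM = "cterm"
SIDE_NTERM = "nterm"

DEFAULT_RULE_FIXTURE = "proteases_v1.json"


class RuleError(ValueError):
    """Raised for invalid cleavage rules or rule fixtures."""


@dataclass(frozen=True)
class ProteaseRule:
    """One enzyme's cleavage specificity at P1/P1' resolution."""

    name: str
    ec_number: str
    side: str
    p1_residues: frozenset[str]
    blocked_p1prime: frozenset[str] = frozenset()
    notes: str = ""

    def __post_init__(self) -> None:
        if self.side not in (SIDE_CTERM, SIDE_NTERM):
            raise RuleError(
                f"rule {self.name!r}: side must be {SIDE_CTERM!r} or {SIDE_NTERM!r}, "
                f"got {self.side!r}"
            )
        if not self.p1_residues:
            raise RuleError(f"rule {self.name!r}: empty P1 residue set")
        for group, residues in (("p1", self.p1_residues), ("blocked_p1prime", self.blocked_p1prime)):
            bad = set(residues) - _AA_SET
            if bad:
                raise RuleError(
                    f"rule {self.name!r}: unknown residue letter(s) {sorted(bad)} in {group}"
                )


@dataclass(frozen=True)
class ProteaseSet:
    """Named collection of cleavage rules with lookup by name or EC number."""

    rules: tuple[ProteaseRule, ...]
    version: str = "unversioned"

    def __post_init__(self) -> None:
        names = [r.name for r in self.rules]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise RuleError(f"duplicate enzyme name(s): {dupes}")

    def __len__(self) -> int:
        return len(self.rules)

    def __iter__(self) -> Iterator[ProteaseRule]:
        return iter(self.rules)

    def names(self) -> list[str]:
        return [r.name for r in self.rules]

    def get(self, key: str) -> ProteaseRule:
        """Look up a rule by enzyme name or EC number."""
        for r in self.rules:
            if r.name == key or r.ec_number == key:
                return r
        raise KeyError(f"no protease named {key!r} in rule set {self.version!r}")


def _rule_from_obj(obj: dict) -> ProteaseRule:
    try:
        return ProteaseRule(
            name=obj["name"],
            ec_number=obj.get("ec", ""),
            side=obj["side"],
            p1_residues=frozenset(obj["p1"]),
            blocked_p1prime=frozenset(obj.get("blocked_p1prime", ())),
            notes=obj.get("notes", ""),
        )
    except KeyError as exc:
        raise RuleError(f"rule object missing required field {exc}") from exc


def load_protease_set(path: str | Path | None = None) -> ProteaseSet:
    """Load a JSON rule fixture; ``None`` loads the shipped 20-enzyme set.

    The fixture is a JSON object with ``version`` and ``rules`` (a list of
    per-enzyme objects: name, ec, side, p1, blocked_p1prime, notes).
    """
    if path is None:
        text = resources.files("umamipep.data").joinpath(DEFAULT_RULE_FIXTURE).read_text()
    else:
        text = Path(path).read_text()
    doc = json.loads(text)
    rules = tuple(_rule_from_obj(o) for o in doc["rules"])
    return ProteaseSet(rules=rules, version=doc.get("version", "unversioned"))


def cut_sites(seq: ProteinSequence, rule: ProteaseRule) -> list[int]:
    """Bond indices hydrolysed by ``rule`` on ``seq``, strictly increasing.

    For a C-terminal rule, bond ``i`` is cut iff residue ``i`` is in the P1
    set and residue ``i+1`` is not blocked; for an N-terminal rule the flanks
    swap roles.
    """
    r = seq.residues
    out = []
    if rule.side == SIDE_CTERM:
        for i in range(1, len(r)):
            if r[i - 1] in rule.p1_residues and r[i] not in rule.blocked_p1prime:
                out.append(i)
    else:
        for i in range(1, len(r)):
            if r[i] in rule.p1_residues and r[i - 1] not in rule.blocked_p1prime:
                out.append(i)
    return out
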