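"""Exhaustive in-silico digestion and its summary statistics.

A digest is the simultaneous, exhaustive action of one or more proteases:
the cut set is the union of each rule's cut sites and the fragments are the
maximal uncut runs. Two statistics summarize a digest of a chain of N
residues and D = N - 1 bonds:

* the theoretical degree of hydrolysis, DH = 100 * d / D, where d is the
  number of hydrolysed bonds;
* the umami-fragment frequency A_umami = a_umami / N, where a_umami counts
  released fragments whose sequence is a known umami peptide (see
  :mod:`umamipep.umami_catalog`).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations as _combinations
from typing import Iterable, Sequence

import pandas as pd

from .protease_rules import ProteaseRule, ProteaseSet, cut_sites
from .sequence_io import ProteinSequence


class DigestError(ValueError):
    pass


@dataclass(frozen=True)
class Fragment:
    """A released peptide with 1-based inclusive coordinates in the parent."""

    residues: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.residues):
            raise DigestError(
                f"fragment {self.residues!r}: coordinates {self.start}-{self.end} "
                f"inconsistent with length {len(self.residues)}"
            )

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class DigestResult:
    """Cut bonds and fragments of one chain under one enzyme selection."""

    source: str
    residues: str
    enzymes: tuple[str, ...]
    cut_bonds: tuple[int, ...]
    fragments: tuple[Fragment, ...]

    @property
    def d(self) -> int:
        """Number of hydrolysed peptide bonds."""
        return len(self.cut_bonds)

    @property
    def total_bonds(self) -> int:
        """Total peptide bonds D = N - 1."""
        return len(self.residues) - 1

    @property
    def n_residues(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class ReleasedPeptide:
    """A unique released sequence with its multiplicity and positions."""

    peptide: str
    multiplicity: int
    positions: tuple[tuple[int, int], ...]


def digest(seq: ProteinSequence, rules: ProteaseRule | Iterable[ProteaseRule]) -> DigestResult:
    """Digest ``seq`` with the union of cut sites of ``rules``.

    Simultaneous exhaustive digestion: every bond recognized by any supplied
    rule is cut. Fragments partition the chain in order.
    """
    if isinstance(rules, ProteaseRule):
        rules = [rules]
    rules = list(rules)
    if not rules:
        raise DigestError("at least one protease rule is required")
    cuts: set[int] = set()
    for rule in rules:
        cuts.update(cut_sites(seq, rule))
    cut_list = sorted(cuts)
    fragments = []
    start = 1
    for bond in cut_list + [len(seq.residues)]:
        fragments.append(
            Fragment(residues=seq.residues[start - 1 : bond], start=start, end=bond)
        )
        start = bond + 1
    return DigestResult(
        source=seq.id,
        residues=seq.residues,
        enzymes=tuple(r.name for r in rules),
        cut_bonds=tuple(cut_list),
        fragments=tuple(fragments),
    )


def degree_of_hydrolysis(result: DigestResult) -> float:
    """Theoretical DH = 100 * d / D on the 0-100 scale."""
    if result.total_bonds < 1:
        raise DigestError(
            f"chain {result.source!r} has a single residue (D = 0); DH undefined"
        )
    return 100.0 * result.d / result.total_bonds


def release_profile(
    result: DigestResult, min_len: int = 2, max_len: int = 4
) -> list[ReleasedPeptide]:
    """Unique released peptides in a length window, by first occurrence.

    Fragments are filtered to ``min_len <= length <= max_len`` and
    deduplicated by residue string; each unique peptide carries its
    multiplicity and all (start, end) positions.
    """
    if min_len > max_len:
        raise DigestError(f"min_len {min_len} exceeds max_len {max_len}")
    seen: dict[str, list[tuple[int, int]]] = {}
    for frag in result.fragments:
        if min_len <= frag.length <= max_len:
            seen.setdefault(frag.residues, []).append((frag.start, frag.end))
    return [
        ReleasedPeptide(peptide=p, multiplicity=len(pos), positions=tuple(pos))
        for p, pos in seen.items()
    ]


def bond_audit(seq: ProteinSequence, rules: Iterable[ProteaseRule]) -> pd.DataFrame:
    """Per-bond audit table: which rule cuts which bond and why.

    One row per peptide bond with the flanking residues and a boolean column
    per enzyme, so discrepancies between rule fixtures can be attributed to
    specific rule entries at specific bonds.
    """
    rules = list(rules)
    n = len(seq.residues)
    rows = []
    per_rule = {r.name: set(cut_sites(seq, r)) for r in rules}
    for i in range(1, n):
        row = {
            "bond": i,
            "p1_residue": seq.residues[i - 1],
            "p1prime_residue": seq.residues[i],
        }
        for r in rules:
            row[r.name] = i in per_rule[r.name]
        row["cut"] = any(row[r.name] for r in rules)
        rows.append(row)
    return pd.DataFrame(rows)


def _stats_row(seq: ProteinSequence, rules: Sequence[ProteaseRule], catalog) -> dict:
    from .umami_catalog import a_umami  # local import to avoid a cycle

    res = digest(seq, rules)
    return {
        "chain": seq.id,
        "a_umami": a_umami(res, catalog),
        "dh_percent": degree_of_hydrolysis(res),
        "d": res.d,
        "total_bonds": res.total_bonds,
    }


def rank_single_proteases(
    seqs: Sequence[ProteinSequence], protease_set: ProteaseSet, catalog
) -> pd.DataFrame:
    """A_umami and DH of every enzyme on every chain, one row per pair."""
    if not seqs or len(protease_set) == 0:
        raise DigestError("rank_single_proteases requires chains and enzymes")
    rows = []
    for rule in protease_set:
        for seq in seqs:
            row = {"enzyme": rule.name, **_stats_row(seq, [rule], catalog)}
            rows.append(row)
    return pd.DataFrame(rows)


def select_top(table: pd.DataFrame, by: str = "a_umami", k: int = 5) -> list[str]:
    """Top-k enzymes by the chain-averaged statistic (default A_umami)."""
    means = table.groupby("enzyme")[by].mean().sort_values(ascending=False)
    return list(means.index[:k])


def enumerate_combinations(
    base: ProteaseRule,
    partners: Sequence[ProteaseRule],
    sizes: Iterable[int],
    seqs: Sequence[ProteinSequence],
    catalog,
) -> pd.DataFrame:
    """Evaluate every combination of the given sizes that contains ``base``.

    Combinations of size s draw s - 1 partners alongside the base enzyme.
    Rows are ranked by chain-averaged A_umami (descending), DH as tiebreak.
    """
    if not partners:
        raise DigestError("enumerate_combinations requires at least one partner")
    rows = []
    for size in sorted(set(sizes)):
        for combo in _combinations(partners, size - 1):
            rules = [base, *combo]
            label = " + ".join(r.name for r in rules)
            for seq in seqs:
                rows.append({"combination": label, "size": size, **_stats_row(seq, rules, catalog)})
    table = pd.DataFrame(rows)
    order = (
        table.groupby("combination")[["a_umami", "dh_percent"]]
        .mean()
        .sort_values(["a_umami", "dh_percent"], ascending=False)
    )
    rank = {name: i for i, name in enumerate(order.index)}
    table["rank"] = table["combination"].map(rank)
    return table.sort_values(["rank", "chain"], kind="stable").drop(columns="rank").reset_index(drop=True)
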