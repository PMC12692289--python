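"""Multi-criteria screening of candidate peptides.

The filter reproduces the staged narrowing of an in-silico taste-peptide
screen. A peptide advances through three stages:

1. physchem stage — non-toxic, non-allergenic, umami-residue proportion
   above threshold, water solubility (log S) above threshold;
2. docking stage — docked successfully and both negated docking energies
   (-CE and -CIE) above threshold;
3. sensory stage — panel umami score above threshold.

All thresholds are strict inequalities by default, exactly as the screen
defines them (equality at a threshold fails); ``strict=False`` switches to
``>=`` for sensitivity analysis. Toxicity, allergenicity, solubility,
docking energies and sensory scores are *ingested* annotations — they come
from external predictors and measurements, never computed here. A peptide
missing an annotation needed by a required criterion fails that criterion
("fails closed") and is flagged unannotated.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .sequence_io import AMINO_ACIDS

_AA_SET = frozenset(AMINO_ACIDS)

PUBLISHED_SCREEN_FIXTURE = "published_screen_annotations.tsv"
DOCKING_SENSORY_FIXTURE = "docking_sensory_synthetic.tsv"

TOXICITY_LEVELS = ("Non", "Toxin")
ALLERGEN_LEVELS = ("Non", "Allergen")


class ScreeningError(ValueError):
    pass


@dataclass(frozen=True)
class AnnotationRecord:
    """Ingested per-peptide annotations (external predictors/measurements)."""

    peptide: str
    toxicity: str | None = None
    allergen: str | None = None
    log_solubility: float | None = None
    hia: float | None = None
    hob: float | None = None
    ce: float | None = None
    cie: float | None = None
    docking_failed: bool = False
    sensory_umami: float | None = None

    def __post_init__(self) -> None:
        if not self.peptide or set(self.peptide) - _AA_SET:
            raise ScreeningError(f"invalid peptide {self.peptide!r}")
        if self.toxicity is not None and self.toxicity not in TOXICITY_LEVELS:
            raise ScreeningError(
                f"{self.peptide}: toxicity must be one of {TOXICITY_LEVELS}, got {self.toxicity!r}"
            )
        if self.allergen is not None and self.allergen not in ALLERGEN_LEVELS:
            raise ScreeningError(
                f"{self.peptide}: allergen must be one of {ALLERGEN_LEVELS}, got {self.allergen!r}"
            )
        if self.hia is not None and not 0.0 <= self.hia <= 1.0:
            raise ScreeningError(f"{self.peptide}: HIA probability {self.hia} out of [0, 1]")
        if self.sensory_umami is not None and not 0.0 <= self.sensory_umami <= 10.0:
            raise ScreeningError(f"{self.peptide}: sensory score {self.sensory_umami} out of [0, 10]")
        if self.docking_failed and (self.ce is not None or self.cie is not None):
            raise ScreeningError(f"{self.peptide}: docking energies present despite docking_failed")


@dataclass(frozen=True)
class FilterCriteria:
    """Thresholds of the staged screen (strict inequalities by default)."""

    require_nontoxic: bool = True
    require_nonallergen: bool = True
    min_umami_fraction: float = 0.0
    min_log_solubility: float = 0.0
    min_ce: float = 40.0
    min_cie: float = 40.0
    min_sensory: float = 5.0
    strict: bool = True

    def __post_init__(self) -> None:
        for name in ("min_umami_fraction", "min_log_solubility", "min_ce", "min_cie", "min_sensory"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ScreeningError(f"criterion {name} must be finite, got {v}")
        if not 0.0 <= self.min_umami_fraction <= 100.0:
            raise ScreeningError(f"min_umami_fraction {self.min_umami_fraction} out of [0, 100]")

    def exceeds(self, value: float | None, threshold: float) -> bool:
        if value is None:
            return False
        return value > threshold if self.strict else value >= threshold


@dataclass(frozen=True)
class CandidateReport:
    """Per-peptide pass/fail table plus the criteria that produced it."""

    table: pd.DataFrame
    criteria: FilterCriteria


def _parse_optional_float(value: str, label: str) -> float | None:
    value = value.strip()
    if value == "":
        return None
    try:
        return float(value)
    except ValueError as exc:
        raise ScreeningError(f"{label}: unparseable numeric {value!r}") from exc


def load_annotations(path: str | Path) -> list[AnnotationRecord]:
    """Read an annotation TSV (header required; peptide column unique).

    Recognized columns: peptide, toxicity, allergen, log_s, hia, hob, ce,
    cie, docking_failed, sensory_umami. Missing optional columns are
    recorded as absent. Comment lines start with ``#``.
    """
    text = Path(path).read_text()
    return _parse_annotations(text, str(path))


def _packaged_annotations(name: str) -> list[AnnotationRecord]:
    text = resources.files("umamipep.data").joinpath(name).read_text()
    return _parse_annotations(text, name)


def load_published_annotations() -> list[AnnotationRecord]:
    """The shipped 82-peptide toxicity/allergen/solubility table."""
    return _packaged_annotations(PUBLISHED_SCREEN_FIXTURE)


def load_docking_sensory_fixture() -> list[AnnotationRecord]:
    """The shipped synthetic docking/sensory pattern fixture (44 peptides)."""
    return _packaged_annotations(DOCKING_SENSORY_FIXTURE)


def _parse_annotations(text: str, label: str) -> list[AnnotationRecord]:
    lines = [l for l in text.splitlines() if l.strip() and not l.startswith("#")]
    if not lines:
        raise ScreeningError(f"{label}: empty annotation table")
    reader = csv.DictReader(lines, delimiter="\t")
    if reader.fieldnames is None or "peptide" not in reader.fieldnames:
        raise ScreeningError(f"{label}: header with a 'peptide' column is required")
    records = []
    seen: set[str] = set()
    for rowno, row in enumerate(reader, start=2):
        where = f"{label}:row {rowno}"
        peptide = (row.get("peptide") or "").strip()
        if peptide in seen:
            raise ScreeningError(f"{where}: duplicate peptide {peptide!r}")
        seen.add(peptide)
        failed_raw = (row.get("docking_failed") or "").strip()
        records.append(
            AnnotationRecord(
                peptide=peptide,
                toxicity=(row.get("toxicity") or "").strip() or None,
                allergen=(row.get("allergen") or "").strip() or None,
                log_solubility=_parse_optional_float(row.get("log_s") or "", where),
                hia=_parse_optional_float(row.get("hia") or "", where),
                hob=_parse_optional_float(row.get("hob") or "", where),
                ce=_parse_optional_float(row.get("ce") or "", where),
                cie=_parse_optional_float(row.get("cie") or "", where),
                docking_failed=failed_raw in ("1", "true", "True", "yes"),
                sensory_umami=_parse_optional_float(row.get("sensory_umami") or "", where),
            )
        )
    return records


def merge_annotations(
    base: Sequence[AnnotationRecord], extra: Sequence[AnnotationRecord]
) -> list[AnnotationRecord]:
    """Overlay ``extra`` fields onto ``base`` records, matched by peptide.

    Non-None fields from ``extra`` win; peptides only in ``extra`` are
    appended. Used to combine a predictor table with a docking/sensory table.
    """
    by_pep = {r.peptide: r for r in base}
    out = dict(by_pep)
    for e in extra:
        b = by_pep.get(e.peptide)
        if b is None:
            out[e.peptide] = e
            continue
        out[e.peptide] = AnnotationRecord(
            peptide=e.peptide,
            toxicity=e.toxicity if e.toxicity is not None else b.toxicity,
            allergen=e.allergen if e.allergen is not None else b.allergen,
            log_solubility=e.log_solubility if e.log_solubility is not None else b.log_solubility,
            hia=e.hia if e.hia is not None else b.hia,
            hob=e.hob if e.hob is not None else b.hob,
            ce=e.ce if e.ce is not None else b.ce,
            cie=e.cie if e.cie is not None else b.cie,
            docking_failed=e.docking_failed or b.docking_failed,
            sensory_umami=e.sensory_umami if e.sensory_umami is not None else b.sensory_umami,
        )
    return list(out.values())


def apply_filters(
    peptides: Iterable[str],
    umami_fractions: Mapping[str, float],
    annotations: Sequence[AnnotationRecord],
    criteria: FilterCriteria | None = None,
) -> CandidateReport:
    """Evaluate every criterion for every peptide and compose stage flags.

    ``umami_fractions`` maps each peptide to its computed umami-residue
    percentage (the one criterion derived from sequence rather than
    ingested). Every peptide must appear in it; annotation coverage may be
    partial and fails closed.
    """
    criteria = criteria or FilterCriteria()
    peptides = list(peptides)
    missing = [p for p in peptides if p not in umami_fractions]
    if missing:
        raise ScreeningError(f"no physchem record for peptide(s) {missing}")
    ann = {r.peptide: r for r in annotations}
    rows = []
    for p in peptides:
        r = ann.get(p)
        has_tox = r is not None and r.toxicity is not None
        has_alg = r is not None and r.allergen is not None
        has_sol = r is not None and r.log_solubility is not None
        has_dock = r is not None and not r.docking_failed and r.ce is not None and r.cie is not None
        has_sens = r is not None and r.sensory_umami is not None
        pass_nontoxic = (not criteria.require_nontoxic) or (has_tox and r.toxicity == "Non")
        pass_nonallergen = (not criteria.require_nonallergen) or (has_alg and r.allergen == "Non")
        pass_umami = criteria.exceeds(umami_fractions[p], criteria.min_umami_fraction)
        pass_sol = has_sol and criteria.exceeds(r.log_solubility, criteria.min_log_solubility)
        docking_failed = r is not None and r.docking_failed
        pass_ce = has_dock and criteria.exceeds(r.ce, criteria.min_ce)
        pass_cie = has_dock and criteria.exceeds(r.cie, criteria.min_cie)
        pass_sensory = has_sens and criteria.exceeds(r.sensory_umami, criteria.min_sensory)
        physchem_pass = pass_nontoxic and pass_nonallergen and pass_umami and pass_sol
        docked = physchem_pass and has_dock
        docking_pass = docked and pass_ce and pass_cie
        sensory_pass = docking_pass and pass_sensory
        rows.append(
            {
                "peptide": p,
                "umami_fraction": umami_fractions[p],
                "toxicity": r.toxicity if r else None,
                "allergen": r.allergen if r else None,
                "log_s": r.log_solubility if r else None,
                "ce": r.ce if r else None,
                "cie": r.cie if r else None,
                "docking_failed": docking_failed,
                "sensory_umami": r.sensory_umami if r else None,
                "pass_nontoxic": pass_nontoxic,
                "pass_nonallergen": pass_nonallergen,
                "pass_umami_fraction": pass_umami,
                "pass_solubility": pass_sol,
                "pass_ce": pass_ce,
                "pass_cie": pass_cie,
                "pass_sensory": pass_sensory,
                "physchem_pass": physchem_pass,
                "docked": docked,
                "docking_pass": docking_pass,
                "sensory_pass": sensory_pass,
                "unannotated": r is None or not (has_tox and has_alg and has_sol),
                "docking_unannotated": r is None or (r.ce is None and not r.docking_failed),
            }
        )
    columns = [
        "peptide", "umami_fraction", "toxicity", "allergen", "log_s", "ce", "cie",
        "docking_failed", "sensory_umami", "pass_nontoxic", "pass_nonallergen",
        "pass_umami_fraction", "pass_solubility", "pass_ce", "pass_cie",
        "pass_sensory", "physchem_pass", "docked", "docking_pass", "sensory_pass",
        "unannotated", "docking_unannotated",
    ]
    table = pd.DataFrame(rows, columns=columns)
    flag_cols = [c for c in columns if c.startswith("pass_")] + [
        "docking_failed", "physchem_pass", "docked", "docking_pass",
        "sensory_pass", "unannotated", "docking_unannotated",
    ]
    table[flag_cols] = table[flag_cols].astype(bool)
    # deterministic report order: descending -CIE, then -CE, then peptide
    table = table.sort_values(
        by=["cie", "ce", "peptide"],
        ascending=[False, False, True],
        na_position="last",
        kind="stable",
    ).reset_index(drop=True)
    return CandidateReport(table=table, criteria=criteria)


def summarize_stages(report: CandidateReport) -> dict:
    """Stage counts, named stage lists, and per-criterion exclusion lists."""
    t = report.table
    in_stage = t[t["physchem_pass"]]
    failed_dock = sorted(in_stage[in_stage["docking_failed"]]["peptide"])
    summary = {
        "input": int(len(t)),
        "physchem_pass": int(t["physchem_pass"].sum()),
        "docked": int(t["docked"].sum()),
        "docking_pass": int(t["docking_pass"].sum()),
        "sensory_pass": int(t["sensory_pass"].sum()),
        "failed_docking": failed_dock,
        "docking_pass_peptides": sorted(t[t["docking_pass"]]["peptide"]),
        "sensory_pass_peptides": sorted(t[t["sensory_pass"]]["peptide"]),
        "unannotated": sorted(t[t["unannotated"]]["peptide"]),
        "excluded_by": {
            crit: sorted(t[~t[f"pass_{crit}"]]["peptide"])
            for crit in ("nontoxic", "nonallergen", "umami_fraction", "solubility")
        },
    }
    return summary
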