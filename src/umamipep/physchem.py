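"""Per-peptide physicochemical properties.

Computes the four sequence-intrinsic properties used by the candidate
screen — monoisotopic mass, isoelectric point, net charge at a given pH,
and a transfer-free-energy hydrophobicity sum — plus the umami-residue
proportion over the ten-residue umami amino-acid set
(D, E, G, Y, A, F, H, T, V, S).

Charge model
------------
Net charge at pH follows the Henderson–Hasselbalch sum

    z(pH) = sum_basic 1 / (1 + 10^(pH - pKa))  -  sum_acidic 1 / (1 + 10^(pKa - pH))

with basic groups the N-terminal amine plus H, K, R side chains and acidic
groups the C-terminal carboxyl plus D, E, C, Y side chains (Cys/Tyr
ionization is toggleable). z is strictly decreasing in pH, so the
isoelectric point — the root of z — is unique and found by bisection on
[0.1, 13.9] to 1e-4 pH units.

Constants live in a versioned JSON fixture; the terminal pKa and
hydrophobicity tables are residue-specific calibrated values (see the
fixture comment and docs/methods.md).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import NamedTuple, Sequence

import pandas as pd
from scipy.optimize import bisect

from .sequence_io import AMINO_ACIDS

_AA_SET = frozenset(AMINO_ACIDS)

DEFAULT_CONSTANTS_FIXTURE = "physchem_constants_v1.json"

BASIC_SIDECHAINS = "HKR"
ACIDIC_SIDECHAINS = "DE"
THIOL_PHENOL_SIDECHAINS = "CY"  # acidic only when cys_tyr_ionizable


class PhyschemError(ValueError):
    pass


@dataclass(frozen=True)
class ConstantTables:
    """Residue-level constants backing every physicochemical computation."""

    residue_mass: dict
    water_mass: float
    nterm_pka: dict
    cterm_pka: dict
    sidechain_pka: dict
    hydrophobicity: dict
    umami_residues: frozenset
    version: str = "unversioned"

    def __post_init__(self) -> None:
        for name, table in (("residue_mass", self.residue_mass), ("hydrophobicity", self.hydrophobicity),
                            ("nterm_pka", self.nterm_pka), ("cterm_pka", self.cterm_pka)):
            missing = _AA_SET - set(table)
            if missing:
                raise PhyschemError(f"constants table {name!r} missing residues {sorted(missing)}")
        for group, value in {**self.sidechain_pka, **self.nterm_pka, **self.cterm_pka}.items():
            if not 0.0 < value < 14.0:
                raise PhyschemError(f"pKa for {group!r} out of (0, 14): {value}")


def load_constants(path: str | Path | None = None) -> ConstantTables:
    """Load the constants fixture; ``None`` loads the shipped calibrated set."""
    if path is None:
        text = resources.files("umamipep.data").joinpath(DEFAULT_CONSTANTS_FIXTURE).read_text()
    else:
        text = Path(path).read_text()
    doc = json.loads(text)
    return ConstantTables(
        residue_mass=doc["residue_mass"],
        water_mass=doc["water_mass"],
        nterm_pka=doc["nterm_pka"],
        cterm_pka=doc["cterm_pka"],
        sidechain_pka=doc["sidechain_pka"],
        hydrophobicity=doc["hydrophobicity"],
        umami_residues=frozenset(doc["umami_residues"]),
        version=doc.get("version", "unversioned"),
    )


_DEFAULT: ConstantTables | None = None


def default_constants() -> ConstantTables:
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = load_constants()
    return _DEFAULT


def _check_peptide(peptide: str) -> None:
    if not peptide:
        raise PhyschemError("empty peptide")
    bad = set(peptide) - _AA_SET
    if bad:
        raise PhyschemError(f"peptide {peptide!r}: invalid residue(s) {sorted(bad)}")


def monoisotopic_mass(peptide: str, tables: ConstantTables | None = None) -> float:
    """Sum of residue monoisotopic masses plus one water, in Da (4 decimals)."""
    tables = tables or default_constants()
    _check_peptide(peptide)
    mass = sum(tables.residue_mass[r] for r in peptide) + tables.water_mass
    return round(mass, 4)


class NetCharge(NamedTuple):
    raw: float
    rounded: int


def net_charge(
    peptide: str,
    pH: float,
    tables: ConstantTables | None = None,
    cys_tyr_ionizable: bool = True,
) -> NetCharge:
    """Henderson–Hasselbalch net charge at ``pH`` (raw and nearest-integer)."""
    tables = tables or default_constants()
    _check_peptide(peptide)
    if not 0.0 < pH < 14.0:
        raise PhyschemError(f"pH {pH} out of (0, 14)")

    def basic(pka: float) -> float:
        return 1.0 / (1.0 + 10.0 ** (pH - pka))

    def acidic(pka: float) -> float:
        return 1.0 / (1.0 + 10.0 ** (pka - pH))

    z = basic(tables.nterm_pka[peptide[0]]) - acidic(tables.cterm_pka[peptide[-1]])
    for r in peptide:
        if r in BASIC_SIDECHAINS:
            z += basic(tables.sidechain_pka[r])
        elif r in ACIDIC_SIDECHAINS:
            z -= acidic(tables.sidechain_pka[r])
        elif r in THIOL_PHENOL_SIDECHAINS and cys_tyr_ionizable:
            z -= acidic(tables.sidechain_pka[r])
    return NetCharge(raw=z, rounded=round(z))


def isoelectric_point(
    peptide: str,
    tables: ConstantTables | None = None,
    cys_tyr_ionizable: bool = True,
) -> float:
    """pH at which the net charge is zero (bisection on [0.1, 13.9], 1e-4)."""
    tables = tables or default_constants()
    _check_peptide(peptide)

    def z(pH: float) -> float:
        return net_charge(peptide, pH, tables, cys_tyr_ionizable).raw

    return float(bisect(z, 0.1, 13.9, xtol=1e-4))


def hydrophobicity(peptide: str, tables: ConstantTables | None = None) -> float:
    """Sum of per-residue transfer free energies, kcal/mol."""
    tables = tables or default_constants()
    _check_peptide(peptide)
    missing = set(peptide) - set(tables.hydrophobicity)
    if missing:
        raise PhyschemError(f"hydrophobicity scale missing residues {sorted(missing)}")
    return round(sum(tables.hydrophobicity[r] for r in peptide), 4)


def umami_residue_fraction(peptide: str, tables: ConstantTables | None = None) -> float:
    """Percent of residues in the 10-residue umami set, to 2 decimals."""
    tables = tables or default_constants()
    _check_peptide(peptide)
    count = sum(1 for r in peptide if r in tables.umami_residues)
    return round(100.0 * count / len(peptide), 2)


@dataclass(frozen=True)
class PhyschemRecord:
    peptide: str
    mono_mass: float
    pI: float
    net_charge_pH7_raw: float
    net_charge_pH7: int
    hydrophobicity: float
    umami_fraction: float


def physchem_record(peptide: str, tables: ConstantTables | None = None) -> PhyschemRecord:
    tables = tables or default_constants()
    charge = net_charge(peptide, 7.0, tables)
    return PhyschemRecord(
        peptide=peptide,
        mono_mass=monoisotopic_mass(peptide, tables),
        pI=isoelectric_point(peptide, tables),
        net_charge_pH7_raw=charge.raw,
        net_charge_pH7=charge.rounded,
        hydrophobicity=hydrophobicity(peptide, tables),
        umami_fraction=umami_residue_fraction(peptide, tables),
    )


def physchem_table(peptides: Sequence[str], tables: ConstantTables | None = None) -> pd.DataFrame:
    """Property table mirroring the candidate-report column order."""
    tables = tables or default_constants()
    recs = [physchem_record(p, tables) for p in peptides]
    return pd.DataFrame(
        {
            "peptide": [r.peptide for r in recs],
            "mass": [r.mono_mass for r in recs],
            "pI": [round(r.pI, 2) for r in recs],
            "net_charge": [r.net_charge_pH7 for r in recs],
            "net_charge_raw": [round(r.net_charge_pH7_raw, 4) for r in recs],
            "hydrophobicity": [r.hydrophobicity for r in recs],
            "umami_fraction": [r.umami_fraction for r in recs],
        }
    )
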