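"""Synthetic collagen-like chains and annotation tables with ground truth.

Collagen α-chains are dominated by Gly-X-Y triplet repeats — glycine at
every third position, proline-rich X/Y positions — flanked by short
non-repetitive telopeptides. The generator emulates that composition on the
20-letter alphabet (hydroxyproline is written as proline, since cleavage
rules act on canonical residues) with tunable X/Y residue distributions.
Default compositions follow reported type I collagen composition: repeats
one-third glycine with X/Y rich in P, A, and a spread of L, E, K, R, S, T,
Q, D, V — so the chains are rich in G, A, L, T as real yak/bovine α-chains
are. Default size is 450 triplets plus 16-residue telopeptides,
~1380 residues, within the length range of real α1(I)/α2(I) chains.

The annotation generator draws toxicity, allergenicity, solubility, docking
and sensory fields from configurable distributions and returns the true
per-criterion pass labels alongside, so the screening stage counts can be
validated by exact comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .screening import AnnotationRecord, FilterCriteria
from .sequence_io import ProteinSequence


class GeneratorError(ValueError):
    pass


_DEFAULT_X = {
    "P": 0.28, "A": 0.16, "L": 0.09, "E": 0.07, "S": 0.06, "K": 0.05,
    "V": 0.05, "F": 0.04, "Q": 0.04, "D": 0.04, "T": 0.04, "N": 0.02,
    "R": 0.025, "M": 0.015, "I": 0.01, "H": 0.005, "Y": 0.005,
}
_DEFAULT_Y = {
    "P": 0.35, "A": 0.12, "R": 0.08, "T": 0.06, "Q": 0.06, "K": 0.06,
    "S": 0.05, "E": 0.05, "D": 0.04, "L": 0.04, "V": 0.03, "M": 0.02,
    "I": 0.02, "H": 0.01, "F": 0.005, "N": 0.005,
}


def _validate_composition(name: str, comp: Mapping[str, float]) -> None:
    if not comp:
        raise GeneratorError(f"{name}: empty composition")
    if any(p < 0 for p in comp.values()):
        raise GeneratorError(f"{name}: negative probability")
    total = sum(comp.values())
    if abs(total - 1.0) > 1e-9:
        raise GeneratorError(f"{name}: probabilities sum to {total}, not 1")


@dataclass(frozen=True)
class CollagenGeneratorConfig:
    n_triplets: int = 450
    x_composition: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_X))
    y_composition: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_Y))
    telopeptide_length: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_triplets < 1:
            raise GeneratorError(f"n_triplets must be >= 1, got {self.n_triplets}")
        if self.telopeptide_length < 0:
            raise GeneratorError("telopeptide_length must be >= 0")
        _validate_composition("x_composition", self.x_composition)
        _validate_composition("y_composition", self.y_composition)


def _draw(rng: np.random.Generator, comp: Mapping[str, float], n: int) -> list[str]:
    letters = sorted(comp)  # sorted for seed-stable draws regardless of dict order
    probs = np.array([comp[l] for l in letters], dtype=float)
    probs = probs / probs.sum()
    return list(rng.choice(letters, size=n, p=probs))


def generate_collagen_like(
    config: CollagenGeneratorConfig | None = None, chain_id: str = "synthetic-collagen"
) -> ProteinSequence:
    """N-telopeptide + (G·X·Y)^n + C-telopeptide, reproducible per seed."""
    config = config or CollagenGeneratorConfig()
    rng = np.random.default_rng(config.seed)
    xs = _draw(rng, config.x_composition, config.n_triplets)
    ys = _draw(rng, config.y_composition, config.n_triplets)
    repeat = "".join(f"G{x}{y}" for x, y in zip(xs, ys))
    telo_comp = {k: (config.x_composition.get(k, 0) + config.y_composition.get(k, 0)) / 2
                 for k in set(config.x_composition) | set(config.y_composition)}
    _validate_composition("telopeptide composition", telo_comp)
    n_telo = config.telopeptide_length
    ntelo = "".join(_draw(rng, telo_comp, n_telo)) if n_telo else ""
    ctelo = "".join(_draw(rng, telo_comp, n_telo)) if n_telo else ""
    return ProteinSequence(
        id=chain_id,
        residues=ntelo + repeat + ctelo,
        description=f"synthetic Gly-X-Y chain, {config.n_triplets} triplets, seed {config.seed}",
    )


def mutate_chain(
    seq: ProteinSequence, n_substitutions: int, seed: int = 0, chain_id: str | None = None
) -> ProteinSequence:
    """A near-identical homolog: ``n_substitutions`` random point changes.

    Substituted positions keep the Gly backbone intact (glycine positions
    are never touched) so the result still looks collagen-like.
    """
    rng = np.random.default_rng(seed)
    residues = list(seq.residues)
    candidates = [i for i, r in enumerate(residues) if r != "G"]
    if n_substitutions > len(candidates):
        raise GeneratorError("more substitutions requested than mutable positions")
    picks = rng.choice(len(candidates), size=n_substitutions, replace=False)
    alphabet = [a for a in "ADEFHIKLMNPQRSTVWY"]
    for idx in picks:
        pos = candidates[idx]
        choices = [a for a in alphabet if a != residues[pos]]
        residues[pos] = choices[rng.integers(len(choices))]
    return ProteinSequence(
        id=chain_id or f"{seq.id}-mut{n_substitutions}",
        residues="".join(residues),
        description=f"{seq.description}; {n_substitutions} substitutions, seed {seed}",
    )


@dataclass(frozen=True)
class AnnotationGeneratorConfig:
    toxin_rate: float = 0.0
    allergen_rate: float = 0.2
    log_s_mean: float = 1.4
    log_s_sd: float = 1.0
    ce_mean: float = 39.0
    ce_sd: float = 4.0
    cie_mean: float = 37.0
    cie_sd: float = 4.0
    docking_failure_rate: float = 0.2
    sensory_mean: float = 5.0
    sensory_sd: float = 1.2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("toxin_rate", "allergen_rate", "docking_failure_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise GeneratorError(f"{name} {v} out of [0, 1]")
        for name in ("log_s_sd", "ce_sd", "cie_sd", "sensory_sd"):
            if getattr(self, name) < 0:
                raise GeneratorError(f"{name} must be >= 0")


def generate_annotations(
    peptides: Sequence[str],
    config: AnnotationGeneratorConfig | None = None,
    umami_fractions: Mapping[str, float] | None = None,
    criteria: FilterCriteria | None = None,
) -> tuple[list[AnnotationRecord], pd.DataFrame]:
    """Draw annotation records plus their true per-criterion pass labels.

    The returned DataFrame holds one row per peptide with the boolean
    criterion labels and composed stage labels computed directly from the
    drawn values, so a screening run over the records can be checked
    label-for-label. ``umami_fractions`` defaults to computing from the
    peptide sequences with the default constants.
    """
    config = config or AnnotationGeneratorConfig()
    criteria = criteria or FilterCriteria()
    if umami_fractions is None:
        from .physchem import umami_residue_fraction

        umami_fractions = {p: umami_residue_fraction(p) for p in peptides}
    rng = np.random.default_rng(config.seed)
    records = []
    labels = []
    for p in peptides:
        toxic = bool(rng.random() < config.toxin_rate)
        allergen = bool(rng.random() < config.allergen_rate)
        log_s = float(rng.normal(config.log_s_mean, config.log_s_sd))
        failed = bool(rng.random() < config.docking_failure_rate)
        ce = None if failed else float(rng.normal(config.ce_mean, config.ce_sd))
        cie = None if failed else float(rng.normal(config.cie_mean, config.cie_sd))
        sensory = float(np.clip(rng.normal(config.sensory_mean, config.sensory_sd), 0.0, 10.0))
        records.append(
            AnnotationRecord(
                peptide=p,
                toxicity="Toxin" if toxic else "Non",
                allergen="Allergen" if allergen else "Non",
                log_solubility=log_s,
                ce=ce,
                cie=cie,
                docking_failed=failed,
                sensory_umami=sensory,
            )
        )
        pass_nontoxic = not toxic if criteria.require_nontoxic else True
        pass_nonallergen = not allergen if criteria.require_nonallergen else True
        pass_umami = criteria.exceeds(umami_fractions[p], criteria.min_umami_fraction)
        pass_sol = criteria.exceeds(log_s, criteria.min_log_solubility)
        physchem_pass = pass_nontoxic and pass_nonallergen and pass_umami and pass_sol
        docked = physchem_pass and not failed
        docking_pass = docked and criteria.exceeds(ce, criteria.min_ce) and criteria.exceeds(
            cie, criteria.min_cie
        )
        sensory_pass = docking_pass and criteria.exceeds(sensory, criteria.min_sensory)
        labels.append(
            {
                "peptide": p,
                "pass_nontoxic": pass_nontoxic,
                "pass_nonallergen": pass_nonallergen,
                "pass_umami_fraction": pass_umami,
                "pass_solubility": pass_sol,
                "physchem_pass": physchem_pass,
                "docked": docked,
                "docking_pass": docking_pass,
                "sensory_pass": sensory_pass,
            }
        )
    return records, pd.DataFrame(labels)


def random_peptides(
    n: int, min_len: int = 2, max_len: int = 4, seed: int = 0
) -> list[str]:
    """Unique random peptides in a length window (test/benchmark helper)."""
    rng = np.random.default_rng(seed)
    alphabet = list("ACDEFGHIKLMNPQRSTVWY")
    out: list[str] = []
    seen: set[str] = set()
    while len(out) < n:
        length = int(rng.integers(min_len, max_len + 1))
        pep = "".join(rng.choice(alphabet, size=length))
        if pep not in seen:
            seen.add(pep)
            out.append(pep)
    return out
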