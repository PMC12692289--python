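"""End-to-end orchestration: digest → stats → novelty → physchem → screen.

A run is described by a small YAML/JSON config, validated up front with all
errors collected at once. Outputs are plain TSV tables plus one JSON
summary and a provenance record (fixture versions, criteria, seed), so runs
diff cleanly and re-running an identical config byte-reproduces every table.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Sequence

import pandas as pd
import yaml

from . import __version__
from .digestion import (
    digest,
    degree_of_hydrolysis,
    enumerate_combinations,
    rank_single_proteases,
    release_profile,
    select_top,
)
from .physchem import default_constants, physchem_table
from .protease_rules import ProteaseSet, load_protease_set
from .screening import FilterCriteria, apply_filters, load_annotations, summarize_stages
from .sequence_io import ProteinSequence, read_fasta
from .synthetic_data import CollagenGeneratorConfig, generate_collagen_like
from .umami_catalog import a_umami, load_catalog, novelty_screen

log = logging.getLogger("umamipep")

ENZYME_MODES = ("single", "all-singles", "combinations")


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    output_dir: str
    fasta: list[str] = field(default_factory=list)
    synthetic: dict | None = None
    proteases: str | None = None
    catalog: list[str] | None = None
    annotations: str | None = None
    enzyme_mode: str = "all-singles"
    enzyme: str | None = None
    base_enzyme: str | None = None
    partners: list[str] | None = None
    combination_sizes: list[int] = field(default_factory=lambda: [2, 3])
    top_k: int = 5
    min_len: int = 2
    max_len: int = 4
    criteria: dict = field(default_factory=dict)
    seed: int = 0

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        if "output_dir" not in doc:
            raise ConfigError("config requires output_dir")
        return cls(**doc)


def _load_config_doc(path: str | Path) -> dict:
    text = Path(path).read_text()
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    return doc


def validate_config(path: str | Path) -> tuple[PipelineConfig | None, list[str]]:
    """Validate a config file, returning (config, all errors found)."""
    errors: list[str] = []
    try:
        doc = _load_config_doc(path)
        config = PipelineConfig.from_dict(doc)
    except (ConfigError, yaml.YAMLError, TypeError) as exc:
        return None, [str(exc)]
    if not config.fasta and config.synthetic is None:
        errors.append("either fasta paths or a synthetic block is required")
    for p in config.fasta:
        if not Path(p).exists():
            errors.append(f"fasta path does not exist: {p}")
    for p in config.catalog or []:
        if not Path(p).exists():
            errors.append(f"catalog path does not exist: {p}")
    if config.annotations and not Path(config.annotations).exists():
        errors.append(f"annotation path does not exist: {config.annotations}")
    if config.proteases and not Path(config.proteases).exists():
        errors.append(f"protease fixture does not exist: {config.proteases}")
    if config.enzyme_mode not in ENZYME_MODES:
        errors.append(f"enzyme_mode must be one of {ENZYME_MODES}, got {config.enzyme_mode!r}")
    pset: ProteaseSet | None = None
    if not errors or (config.proteases is None or Path(config.proteases).exists()):
        try:
            pset = load_protease_set(config.proteases)
        except Exception as exc:  # fixture-level problem
            errors.append(f"protease fixture: {exc}")
    if pset is not None:
        for name in filter(None, [config.enzyme, config.base_enzyme, *(config.partners or [])]):
            try:
                pset.get(name)
            except KeyError:
                errors.append(f"enzyme name does not resolve in fixture: {name!r}")
        if config.enzyme_mode == "single" and not config.enzyme:
            errors.append("enzyme_mode 'single' requires an enzyme name")
        if config.enzyme_mode == "combinations" and not config.base_enzyme:
            errors.append("enzyme_mode 'combinations' requires base_enzyme")
    try:
        FilterCriteria(**config.criteria)
    except (TypeError, ValueError) as exc:
        errors.append(f"criteria: {exc}")
    return (config if not errors else None), errors


def _load_chains(config: PipelineConfig) -> list[ProteinSequence]:
    if config.fasta:
        chains: list[ProteinSequence] = []
        for p in config.fasta:
            chains.extend(read_fasta(p))
        return chains
    syn = dict(config.synthetic or {})
    n_chains = int(syn.pop("n_chains", 2))
    seed = int(syn.pop("seed", config.seed))
    chains = []
    for i in range(n_chains):
        cfg = CollagenGeneratorConfig(seed=seed + i, **syn)
        chains.append(generate_collagen_like(cfg, chain_id=f"synthetic-chain-{i + 1}"))
    return chains


def _selected_rules(config: PipelineConfig, pset: ProteaseSet, singles: pd.DataFrame | None):
    if config.enzyme_mode == "single":
        return [pset.get(config.enzyme)], config.enzyme
    if config.enzyme_mode == "all-singles":
        top = select_top(singles, by="a_umami", k=1)[0]
        return [pset.get(top)], top
    return None, None  # combinations: decided after ranking


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute a validated config; returns the run directory."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables = default_constants()
    pset = load_protease_set(config.proteases)
    catalog = load_catalog(config.catalog)
    chains = _load_chains(config)
    log.info("loaded %d chain(s), %d protease rule(s), %d catalog entries",
             len(chains), len(pset), len(catalog))

    singles = None
    if config.enzyme_mode in ("all-singles", "combinations"):
        singles = rank_single_proteases(chains, pset, catalog)
        singles.to_csv(outdir / "single_protease_stats.tsv", sep="\t", index=False)

    if config.enzyme_mode == "combinations":
        base = pset.get(config.base_enzyme)
        if config.partners:
            partner_names = config.partners
        else:
            ranked = select_top(singles, by="a_umami", k=config.top_k)
            partner_names = [n for n in ranked if n != base.name][: config.top_k - 1]
        partners = [pset.get(n) for n in partner_names]
        combos = enumerate_combinations(base, partners, config.combination_sizes, chains, catalog)
        combos.to_csv(outdir / "combination_stats.tsv", sep="\t", index=False)
        best = combos.iloc[0]["combination"]
        selected = [pset.get(n.strip()) for n in best.split(" + ")]
        selected_label = best
    else:
        selected, selected_label = _selected_rules(config, pset, singles)
    log.info("selected enzyme set: %s", selected_label)

    digest_rows = []
    released: dict[str, None] = {}
    profile_rows = []
    for chain in chains:
        res = digest(chain, selected)
        digest_rows.append(
            {
                "chain": chain.id,
                "enzymes": selected_label,
                "d": res.d,
                "total_bonds": res.total_bonds,
                "dh_percent": degree_of_hydrolysis(res),
                "a_umami": a_umami(res, catalog),
            }
        )
        for rp in release_profile(res, config.min_len, config.max_len):
            released.setdefault(rp.peptide)
            profile_rows.append(
                {
                    "chain": chain.id,
                    "peptide": rp.peptide,
                    "length": len(rp.peptide),
                    "multiplicity": rp.multiplicity,
                    "positions": ";".join(f"{s}-{e}" for s, e in rp.positions),
                }
            )
    pd.DataFrame(digest_rows).to_csv(outdir / "digest_stats.tsv", sep="\t", index=False)
    pd.DataFrame(profile_rows).to_csv(outdir / "release_profile.tsv", sep="\t", index=False)

    unique_released = list(released)
    partition = novelty_screen(unique_released, catalog)
    pd.DataFrame(
        [{"peptide": p, "status": "known", "provenance": e.provenance} for p, e in partition.known]
        + [{"peptide": p, "status": "novel", "provenance": ""} for p in partition.novel]
    ).to_csv(outdir / "novelty.tsv", sep="\t", index=False)
    log.info("released %d unique peptides; %d known, %d novel",
             len(unique_released), len(partition.known), len(partition.novel))

    novel = list(partition.novel)
    phys = physchem_table(novel, tables)
    phys.to_csv(outdir / "physchem.tsv", sep="\t", index=False)

    criteria = FilterCriteria(**config.criteria)
    annotations = []
    if config.annotations:
        annotations = load_annotations(config.annotations)
    elif criteria.require_nontoxic or criteria.require_nonallergen:
        log.warning("no annotation table supplied; annotation-dependent criteria fail closed")
    fractions = dict(zip(phys["peptide"], phys["umami_fraction"]))
    report = apply_filters(novel, fractions, annotations, criteria)
    report.table.to_csv(outdir / "candidates.tsv", sep="\t", index=False)
    summary = summarize_stages(report)
    for stage in ("physchem_pass", "docked", "docking_pass", "sensory_pass"):
        log.info("stage %s: %d peptide(s)", stage, summary[stage])

    provenance = {
        "umamipep_version": __version__,
        "protease_fixture": pset.version,
        "catalog_version": catalog.version,
        "constants_version": tables.version,
        "criteria": asdict(criteria),
        "enzyme_selection": selected_label,
        "seed": config.seed,
        "chains": [c.id for c in chains],
    }
    (outdir / "summary.json").write_text(json.dumps({"stages": summary}, indent=2, sort_keys=True))
    (outdir / "provenance.json").write_text(json.dumps(provenance, indent=2, sort_keys=True))
    return outdir


def run_from_file(path: str | Path) -> Path:
    config, errors = validate_config(path)
    if errors:
        raise ConfigError("; ".join(errors))
    return run_pipeline(config)
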