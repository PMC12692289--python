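"""Known-umami-peptide catalog, A_umami, and the novelty screen.

The catalog is the counting source for the umami-fragment frequency
A_umami = a_umami / N: a released fragment counts toward a_umami iff its
full residue string is a catalog entry (exact match, with multiplicity —
not substring occurrence in the parent chain). The novelty screen advances
only peptides absent from the catalog.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from .digestion import DigestResult
from .sequence_io import AMINO_ACIDS

_AA_SET = frozenset(AMINO_ACIDS)

PROVENANCES = ("biopep", "literature")
DEFAULT_CATALOG_FIXTURE = "umami_catalog_v1.tsv"


class CatalogError(ValueError):
    pass


@dataclass(frozen=True)
class CatalogEntry:
    peptide: str
    provenance: str
    citation: str = ""

    def __post_init__(self) -> None:
        if not self.peptide or set(self.peptide) - _AA_SET:
            raise CatalogError(f"invalid catalog peptide {self.peptide!r}")
        if self.provenance not in PROVENANCES:
            raise CatalogError(
                f"peptide {self.peptide!r}: provenance must be one of {PROVENANCES}, "
                f"got {self.provenance!r}"
            )


@dataclass(frozen=True)
class UmamiCatalog:
    entries: tuple[CatalogEntry, ...]
    version: str = "unversioned"

    def __post_init__(self) -> None:
        peptides = [e.peptide for e in self.entries]
        if len(peptides) != len(set(peptides)):
            dupes = sorted({p for p in peptides if peptides.count(p) > 1})
            raise CatalogError(f"duplicate catalog peptide(s): {dupes}")

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, peptide: str) -> bool:
        return peptide in self._index()

    def _index(self) -> dict[str, CatalogEntry]:
        # tiny catalogs; rebuild on demand rather than caching on a frozen class
        return {e.peptide: e for e in self.entries}

    def get(self, peptide: str) -> CatalogEntry:
        return self._index()[peptide]


@dataclass(frozen=True)
class NoveltyPartition:
    """Released peptides split into catalog-known and novel."""

    known: tuple[tuple[str, CatalogEntry], ...]
    novel: tuple[str, ...]


def load_catalog(paths: str | Path | Sequence[str | Path] | None = None) -> UmamiCatalog:
    """Load and merge TSV catalog fixtures (peptide, provenance, citation).

    ``None`` loads the shipped fixture. Duplicate peptides across files with
    identical provenance are deduplicated silently; conflicting provenance
    is an error. Malformed rows report their line number.
    """
    if paths is None:
        texts = [
            (
                DEFAULT_CATALOG_FIXTURE,
                resources.files("umamipep.data").joinpath(DEFAULT_CATALOG_FIXTURE).read_text(),
            )
        ]
        version = "catalog-v1"
    else:
        if isinstance(paths, (str, Path)):
            paths = [paths]
        texts = [(str(p), Path(p).read_text()) for p in paths]
        version = "+".join(Path(p).stem for p in paths)
    merged: dict[str, CatalogEntry] = {}
    for label, text in texts:
        reader = csv.reader(text.splitlines(), delimiter="\t")
        for lineno, row in enumerate(reader, start=1):
            if not row or row[0].startswith("#") or row[0] == "peptide":
                continue
            if len(row) < 2:
                raise CatalogError(f"{label}:{lineno}: expected at least 2 columns, got {len(row)}")
            try:
                entry = CatalogEntry(
                    peptide=row[0].strip(),
                    provenance=row[1].strip(),
                    citation=row[2].strip() if len(row) > 2 else "",
                )
            except CatalogError as exc:
                raise CatalogError(f"{label}:{lineno}: {exc}") from exc
            prior = merged.get(entry.peptide)
            if prior is not None and prior.provenance != entry.provenance:
                raise CatalogError(
                    f"{label}:{lineno}: peptide {entry.peptide!r} already loaded with "
                    f"provenance {prior.provenance!r}, conflicts with {entry.provenance!r}"
                )
            merged.setdefault(entry.peptide, entry)
    return UmamiCatalog(entries=tuple(merged.values()), version=version)


def a_umami(result: DigestResult, catalog: UmamiCatalog) -> float:
    """Umami-fragment frequency: catalog fragments (with multiplicity) over N."""
    if result.n_residues < 1:
        raise CatalogError("empty chain")
    index = {e.peptide for e in catalog.entries}
    count = sum(1 for frag in result.fragments if frag.residues in index)
    return count / result.n_residues


def novelty_screen(peptides: Iterable[str], catalog: UmamiCatalog) -> NoveltyPartition:
    """Partition unique peptides into known (exact catalog match) and novel."""
    peptides = list(peptides)
    if len(peptides) != len(set(peptides)):
        raise CatalogError("novelty_screen expects unique peptides")
    known = []
    novel = []
    for p in peptides:
        if p in catalog:
            known.append((p, catalog.get(p)))
        else:
            novel.append(p)
    return NoveltyPartition(known=tuple(known), novel=tuple(novel))
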