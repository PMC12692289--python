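"""Protein sequence containers, FASTA I/O and pairwise global identity.

The twenty canonical one-letter residue codes are the working alphabet.
Ambiguity codes (B, Z, X, U, O, J) are rejected by default because the
downstream cleavage-rule engine is defined only on the canonical residues;
a permissive mode maps them to the sentinel ``*`` which never matches a
cleavage rule and always scores as a mismatch in alignments.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import Align, SeqIO

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)
AMBIGUOUS = frozenset("BZXUOJ")

#: sentinel residue substituted for ambiguity codes in permissive mode
SENTINEL = "*"


class SequenceError(ValueError):
    """Raised for malformed sequences or FASTA records."""


@dataclass(frozen=True)
class ProteinSequence:
    """An identified amino-acid chain.

    Parameters
    ----------
    id : str
        Accession or free-text identifier (FASTA header token before the
        first whitespace).
    residues : str
        Upper-case one-letter residue string over the 20-letter alphabet.
    description : str
        Remainder of the FASTA header, free text.
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise SequenceError(f"sequence {self.id!r}: empty residue string")
        for pos, ch in enumerate(self.residues, start=1):
            if ch not in _AA_SET and ch != SENTINEL:
                raise SequenceError(
                    f"sequence {self.id!r}: illegal residue {ch!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def length(self) -> int:
        """Residue count N (the denominator of the umami-fragment frequency)."""
        return len(self.residues)

    @property
    def n_bonds(self) -> int:
        """Total peptide-bond count D = N - 1."""
        return len(self.residues) - 1


@dataclass(frozen=True)
class IdentityResult:
    """Outcome of a pairwise global alignment.

    ``percent_identity`` is matches over aligned columns (gap columns
    included), on a 0-100 scale, and is symmetric in the two inputs.
    """

    percent_identity: float
    aligned_length: int
    matches: int
    parameters: dict = field(compare=False, default_factory=dict)


def _clean_residues(record_id: str, raw: str, permissive: bool) -> str:
    residues = raw.upper()
    out = []
    for pos, ch in enumerate(residues, start=1):
        if ch in _AA_SET:
            out.append(ch)
        elif ch in AMBIGUOUS and permissive:
            out.append(SENTINEL)
        else:
            raise SequenceError(
                f"record {record_id!r}: illegal residue {ch!r} at position {pos}"
            )
    return "".join(out)


def read_fasta(path: str | Path, permissive: bool = False) -> list[ProteinSequence]:
    """Read a (possibly wrapped) multi-record FASTA file.

    Returns one :class:`ProteinSequence` per record in file order. The header
    token before the first whitespace becomes the id. With
    ``permissive=True`` ambiguity codes are mapped to the ``*`` sentinel
    instead of raising.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise SequenceError(f"{path}: no FASTA records found")
    out = []
    for rec in records:
        residues = _clean_residues(rec.id, str(rec.seq), permissive)
        if not residues:
            raise SequenceError(f"record {rec.id!r}: empty sequence")
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        out.append(ProteinSequence(id=rec.id, residues=residues, description=desc))
    return out


def write_fasta(seqs: Iterable[ProteinSequence], path: str | Path, width: int = 60) -> None:
    """Write sequences as wrapped FASTA."""
    with open(path, "w") as fh:
        for s in seqs:
            header = f">{s.id}" + (f" {s.description}" if s.description else "")
            fh.write(header + "\n")
            for i in range(0, len(s.residues), width):
                fh.write(s.residues[i : i + width] + "\n")


def global_identity(
    a: ProteinSequence,
    b: ProteinSequence,
    match: float = 1.0,
    mismatch: float = 0.0,
    gap_open: float = -5.0,
    gap_extend: float = -1.0,
) -> IdentityResult:
    """Percent identity from an optimal end-to-end affine-gap alignment.

    Identity is counted as identical columns over all aligned columns,
    including gap columns. Among co-optimal alignments the aligner's first
    (deterministic) traceback is taken; the identity statistic is recorded
    together with the scoring parameters so alternative conventions can be
    audited. For near-identical chains the value is insensitive to the
    scheme.
    """
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    # sentinel residues from permissive parsing must never count as matches
    sa = a.residues
    sb = b.residues
    aln = aligner.align(sa, sb)[0]
    counts = aln.counts()
    matches = counts.identities
    if SENTINEL in sa or SENTINEL in sb:
        # recount columns by hand: sentinel-sentinel columns are not identities
        matches = 0
        ta, tb = aln[0], aln[1]
        for ca, cb in zip(ta, tb):
            if ca == cb and ca != "-" and ca != SENTINEL:
                matches += 1
    aligned_length = aln.length
    return IdentityResult(
        percent_identity=100.0 * matches / aligned_length,
        aligned_length=aligned_length,
        matches=matches,
        parameters={
            "match": match,
            "mismatch": mismatch,
            "gap_open": gap_open,
            "gap_extend": gap_extend,
            "denominator": "aligned_columns_including_gaps",
        },
    )
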