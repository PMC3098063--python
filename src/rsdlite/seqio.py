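"""Reading, sanitizing, and indexing protein genomes.

A *genome* here is a flat FASTA file of amino-acid sequences, one per
gene/protein.  Genomes are kept on disk as a directory named after the
organism (conventionally ``<organism>.aa``) containing a single cleaned
FASTA file, and in memory as an immutable :class:`GenomeDB`.

Record identifiers are sanitized so that they are safe to embed verbatim
in runner-file command lines and in file names: every character outside
``[A-Za-z0-9_.-]`` is replaced by an underscore and runs of underscores
are collapsed.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from types import MappingProxyType
from typing import Iterable, Mapping

from Bio.SeqIO.FastaIO import SimpleFastaParser

__all__ = [
    "ProteinSequence",
    "GenomeDB",
    "FastaParseError",
    "SequenceRecordError",
    "read_fasta",
    "write_fasta",
    "sanitize_name",
    "format_genome",
    "save_genome",
    "load_genome",
]

#: The 20 canonical residues, in the conventional PAML/dat-file order.
AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"

#: Residues accepted in input sequences ('X' marks an unknown residue).
ALLOWED_RESIDUES = frozenset(AMINO_ACIDS + "X")

# IUPAC ambiguity / rare residue codes that NCBI proteomes may contain.
# They carry too little information for distance estimation, so they are
# mapped to the generic unknown residue on read.
_AMBIGUOUS_TO_X = str.maketrans({c: "X" for c in "BZJUO"})


class FastaParseError(ValueError):
    """The file is not syntactically valid FASTA."""


class SequenceRecordError(ValueError):
    """A structurally valid record has unusable content."""


@dataclass(frozen=True)
class ProteinSequence:
    """An amino-acid sequence with a whitespace-free identifier."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id or re.search(r"\s", self.id):
            raise SequenceRecordError(
                f"invalid sequence id {self.id!r}: must be non-empty, no whitespace"
            )
        if not self.seq:
            raise SequenceRecordError(f"record {self.id!r} has an empty sequence")
        bad = set(self.seq) - ALLOWED_RESIDUES
        if bad:
            raise SequenceRecordError(
                f"record {self.id!r} contains invalid residues: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class GenomeDB:
    """A named, indexed, immutable collection of protein sequences."""

    name: str
    records: Mapping[str, ProteinSequence]
    total_residues: int = field(default=0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", MappingProxyType(dict(self.records)))
        total = sum(len(r) for r in self.records.values())
        object.__setattr__(self, "total_residues", total)
        if not self.records:
            raise ValueError(f"genome {self.name!r} has no records")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records.values())

    def __getitem__(self, rec_id: str) -> ProteinSequence:
        return self.records[rec_id]

    def __contains__(self, rec_id: str) -> bool:
        return rec_id in self.records


def _clean_seq(raw: str, rec_id: str) -> str:
    seq = raw.upper().replace(" ", "")
    if "*" in seq:
        warnings.warn(
            f"record {rec_id!r}: stripping {seq.count('*')} stop character(s)",
            stacklevel=3,
        )
        seq = seq.replace("*", "")
    return seq.translate(_AMBIGUOUS_TO_X)


def read_fasta(path: str | Path) -> list[ProteinSequence]:
    """Read protein records from a FASTA file, in file order.

    Sequences are uppercased; stop characters (``*``) are stripped with a
    warning; ambiguity codes (B, Z, J, U, O) become ``X``.  The record id
    is the first whitespace-delimited token of the header.

    Raises
    ------
    FastaParseError
        If sequence data precedes any ``>`` header (the offending line
        number is reported).
    SequenceRecordError
        If a header has no sequence, no id token, or invalid residues.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise FastaParseError(
                        f"{path}: line {lineno}: sequence data before any '>' header"
                    )
                break
        else:
            return []

    records: list[ProteinSequence] = []
    with open(path) as fh:
        for header, seq in SimpleFastaParser(fh):
            tokens = header.split()
            if not tokens:
                raise SequenceRecordError(f"{path}: header with no id token")
            rec_id = tokens[0]
            cleaned = _clean_seq(seq, rec_id)
            if not cleaned:
                raise SequenceRecordError(f"{path}: record {rec_id!r} has no sequence")
            records.append(ProteinSequence(rec_id, cleaned))
    return records


def write_fasta(records: Iterable[ProteinSequence], path: str | Path, width: int = 60) -> None:
    """Write records as multi-line FASTA (fixed line width, id-only headers)."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def sanitize_name(raw: str) -> str:
    """Make an identifier safe for command lines and file names.

    Every character outside ``[A-Za-z0-9_.-]`` becomes ``_`` and runs of
    underscores collapse to one.  Raises :class:`ValueError` when nothing
    recoverable remains (empty or all-underscore result).
    """
    if not raw:
        raise ValueError("cannot sanitize an empty name")
    clean = re.sub(r"[^A-Za-z0-9_.\-]", "_", raw)
    clean = re.sub(r"_{2,}", "_", clean)
    if not clean.strip("_"):
        raise ValueError(f"name {raw!r} sanitizes to nothing usable")
    return clean


def format_genome(records: Iterable[ProteinSequence], name: str) -> GenomeDB:
    """Sanitize ids, check uniqueness, and build an immutable genome database."""
    clean_name = sanitize_name(name)
    seen: dict[str, ProteinSequence] = {}
    collisions: list[str] = []
    for rec in records:
        rec_id = sanitize_name(rec.id)
        if rec_id in seen:
            collisions.append(rec_id)
        else:
            seen[rec_id] = ProteinSequence(rec_id, rec.seq)
    if collisions:
        raise ValueError(
            f"genome {clean_name!r}: duplicate ids after sanitization: {sorted(set(collisions))}"
        )
    if not seen:
        raise ValueError(f"genome {clean_name!r} has no records")
    return GenomeDB(name=clean_name, records=seen)


def save_genome(db: GenomeDB, parent: str | Path) -> Path:
    """Serialize a genome as ``<parent>/<name>/<name>.fasta`` (cleaned FASTA)."""
    folder = Path(parent) / db.name
    folder.mkdir(parents=True, exist_ok=True)
    out = folder / f"{db.name}.fasta"
    write_fasta(db, out)
    return folder


def load_genome(folder: str | Path) -> GenomeDB:
    """Load a genome previously written by :func:`save_genome`."""
    folder = Path(folder)
    name = folder.name
    fasta = folder / f"{name}.fasta"
    if not fasta.exists():
        raise FileNotFoundError(f"no genome FASTA at {fasta}")
    return format_genome(read_fasta(fasta), name)
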