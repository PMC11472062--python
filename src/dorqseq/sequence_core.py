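"""Sequence primitives, edit distance, and FASTA/FASTQ + tabular I/O.

Everything downstream works on a single canonical alphabet: uppercase DNA
``{A, C, G, T}``. tRNA references are frequently distributed as RNA; they are
converted on read. IUPAC ambiguity codes are rejected outright because the
probe-design pipeline compares concrete sequences by edit distance, and a
silently expanded ``N`` would corrupt every distance it touches.
"""

from __future__ import annotations

import csv
import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence, TextIO

import edlib
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "AmbiguousBaseError",
    "InvalidBaseError",
    "TRNAReference",
    "Read",
    "normalize_sequence",
    "reverse_complement",
    "levenshtein",
    "gc_fraction",
    "read_fasta_references",
    "write_fasta_references",
    "read_fastq",
    "write_fastq",
    "open_text",
]

DNA_ALPHABET = frozenset("ACGT")
IUPAC_AMBIGUITY = frozenset("NRYSWKMBDHV")
PHRED_OFFSET = 33  # Phred+33, the only encoding current Illumina emits

COMPARTMENTS = ("cytosolic", "mitochondrial")


class AmbiguousBaseError(ValueError):
    """Raised when a sequence contains an IUPAC ambiguity code (N, R, Y, ...)."""


class InvalidBaseError(ValueError):
    """Raised when a sequence contains a character with no nucleotide meaning."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TRNAReference:
    """One mature tRNA gene sequence, 5'->3', with its annotation.

    Parameters
    ----------
    id : str
        Unique identifier within a reference collection.
    organism : str
        Source organism (free text).
    compartment : str
        ``"cytosolic"`` or ``"mitochondrial"``; decides the probe dye.
    amino_acid : str
        One-letter amino-acid code of the charged residue.
    anticodon : str
        The 3-mer anticodon, DNA alphabet.
    sequence : str
        Mature sequence, normalized DNA, length >= 40.
    """

    id: str
    organism: str
    compartment: str
    amino_acid: str
    anticodon: str
    sequence: str

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise ValueError(
                f"compartment must be one of {COMPARTMENTS}, got {self.compartment!r}"
            )
        object.__setattr__(self, "sequence", normalize_sequence(self.sequence))
        if len(self.sequence) < 40:
            raise ValueError(
                f"reference {self.id!r} is {len(self.sequence)} nt; need >= 40"
            )


@dataclass(frozen=True)
class Read:
    """A sequencing read: sequence plus per-base Phred scores."""

    id: str
    sequence: str
    qualities: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.id!r}: {len(self.sequence)} bases vs "
                f"{len(self.qualities)} quality scores"
            )
        if any(q < 0 for q in self.qualities):
            raise ValueError(f"read {self.id!r}: negative Phred score")


# ---------------------------------------------------------------------------
# Core operations
# ---------------------------------------------------------------------------

_RNA_TO_DNA = str.maketrans("acgtuACGTU", "ACGTTACGTT")


def normalize_sequence(raw: str) -> str:
    """Uppercase and map U->T; reject anything outside {A,C,G,T,U}.

    IUPAC ambiguity codes raise :class:`AmbiguousBaseError`; any other
    character raises :class:`InvalidBaseError`.
    """
    seq = raw.translate(_RNA_TO_DNA)
    bad = set(seq) - DNA_ALPHABET
    if bad:
        ambiguous = {b for b in bad if b.upper() in IUPAC_AMBIGUITY}
        if ambiguous:
            raise AmbiguousBaseError(
                f"ambiguity codes not allowed: {sorted(ambiguous)}"
            )
        raise InvalidBaseError(f"non-nucleotide characters: {sorted(bad)}")
    return seq


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement of a normalized DNA sequence."""
    return str(Seq(seq).reverse_complement())


def levenshtein(a: str, b: str) -> int:
    """Levenshtein edit distance (unit-cost insertions/deletions/substitutions)."""
    if a == b:
        return 0
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


def gc_fraction(seq: str) -> float:
    """Fraction of G+C bases; 0.0 for the empty sequence."""
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


# ---------------------------------------------------------------------------
# I/O — FASTA references
# ---------------------------------------------------------------------------

def open_text(path: str | Path, mode: str = "rt") -> TextIO:
    """Open a text file, transparently handling ``.gz``."""
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)  # type: ignore[return-value]
    return open(path, mode)


def _parse_header(header: str) -> dict[str, str]:
    # rich convention: id|organism|compartment|aa|anticodon
    parts = header.split("|")
    if len(parts) == 5:
        return {
            "id": parts[0],
            "organism": parts[1],
            "compartment": parts[2],
            "amino_acid": parts[3],
            "anticodon": parts[4],
        }
    return {"id": parts[0]}


def _read_sidecar(path: str | Path) -> dict[str, dict[str, str]]:
    with open_text(path) as fh:
        rows = list(csv.DictReader(fh, delimiter="\t"))
    return {row["id"]: row for row in rows}


def read_fasta_references(
    path: str | Path, sidecar: str | Path | None = None
) -> list[TRNAReference]:
    """Read tRNA references from FASTA.

    Headers follow ``>id|organism|compartment|aa|anticodon``. Records whose
    header carries only an id fall back to annotations from a sidecar TSV
    (columns: id, organism, compartment, amino_acid, anticodon).
    """
    annotations = _read_sidecar(sidecar) if sidecar is not None else {}
    refs: list[TRNAReference] = []
    seen: set[str] = set()
    with open_text(path) as fh:
        for record in SeqIO.parse(fh, "fasta"):
            meta = _parse_header(record.description or record.id)
            if "compartment" not in meta:
                extra = annotations.get(meta["id"])
                if extra is None:
                    raise ValueError(
                        f"record {meta['id']!r} lacks annotation and no sidecar "
                        "entry was found"
                    )
                meta = {**extra, "id": meta["id"]}
            if meta["id"] in seen:
                raise ValueError(f"duplicate reference id {meta['id']!r}")
            seen.add(meta["id"])
            refs.append(
                TRNAReference(
                    id=meta["id"],
                    organism=meta.get("organism", ""),
                    compartment=meta["compartment"],
                    amino_acid=meta["amino_acid"],
                    anticodon=normalize_sequence(meta["anticodon"]),
                    sequence=str(record.seq),
                )
            )
    return refs


def write_fasta_references(refs: Iterable[TRNAReference], path: str | Path) -> None:
    records = [
        SeqRecord(
            Seq(r.sequence),
            id=f"{r.id}|{r.organism}|{r.compartment}|{r.amino_acid}|{r.anticodon}",
            description="",
        )
        for r in refs
    ]
    with open_text(path, "wt") as fh:
        SeqIO.write(records, fh, "fasta")


# ---------------------------------------------------------------------------
# I/O — FASTQ (Phred+33)
# ---------------------------------------------------------------------------

def read_fastq(path: str | Path) -> Iterator[Read]:
    """Iterate reads from a FASTQ file (gzip-transparent, Phred+33)."""
    with open_text(path) as fh:
        for record in SeqIO.parse(fh, "fastq"):
            yield Read(
                id=record.id,
                sequence=str(record.seq),
                qualities=tuple(record.letter_annotations["phred_quality"]),
            )


def write_fastq(reads: Iterable[Read], path: str | Path) -> None:
    """Write reads as FASTQ (gzip-transparent, Phred+33)."""
    with open_text(path, "wt") as fh:
        for read in reads:
            qual = "".join(chr(q + PHRED_OFFSET) for q in read.qualities)
            fh.write(f"@{read.id}\n{read.sequence}\n+\n{qual}\n")
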