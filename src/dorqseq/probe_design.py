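"""Design and validation of cDOQ hybridization probes from tRNA references.

A cDOQ ("cDNA Oligo for Quantification") targets the last 40 nt of a mature
tRNA: references whose 3' 40-mers fall within a Levenshtein distance below a
collapse threshold (default 6) are grouped into one isodecoder family, and the
family's probe carries the reverse complement of its representative 40-mer
flanked by the Illumina P5/P3 amplification adapters (87 nt total with the
default adapters). Cytosolic families are dyed 6-FAM, mitochondrial ones Cy5.

The minimum pairwise distance of the final recognition set is the quantity
that guarantees read-assignment specificity downstream; validation reports it
rather than enforcing it, because closely spaced families are a property of a
genome, not a software defect.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .sequence_core import (
    TRNAReference,
    gc_fraction,
    levenshtein,
    normalize_sequence,
    open_text,
    reverse_complement,
)

__all__ = [
    "P5_DEFAULT",
    "P3_DEFAULT",
    "DYE_CYTOSOLIC",
    "DYE_MITOCHONDRIAL",
    "SequenceTooShortError",
    "MixedCompartmentError",
    "Probe",
    "ProbeSet",
    "ValidationReport",
    "extract_3prime_region",
    "collapse_families",
    "build_probe",
    "design_probe_set",
    "validate_probe_set",
    "write_probe_tsv",
    "read_probe_tsv",
    "write_recognition_fasta",
]

P5_DEFAULT = "AGACGTGTGCTCTTCCGATCT"
P3_DEFAULT = "GATCGTCGGACTGTAGAACTCTGAAC"
RECOGNITION_LENGTH = 40
COLLAPSE_THRESHOLD_DEFAULT = 6

DYE_CYTOSOLIC = "6-FAM"
DYE_MITOCHONDRIAL = "Cy5"

AA_THREE_LETTER = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
}


class SequenceTooShortError(ValueError):
    """Reference shorter than the requested 3' region."""


class MixedCompartmentError(ValueError):
    """A family mixes cytosolic and mitochondrial references; no single dye fits."""


@dataclass(frozen=True)
class Probe:
    """One quantification oligo and the tRNA family it covers."""

    name: str
    compartment: str
    recognition: str  # 40-nt reverse complement of the family 3' region
    construct: str  # p5 + recognition + p3
    dye: str
    members: tuple[str, ...]

    @property
    def gc_fraction(self) -> float:
        return gc_fraction(self.recognition)


@dataclass
class ProbeSet:
    """A validated collection of probes sharing one adapter pair."""

    probes: list[Probe]
    p5: str = P5_DEFAULT
    p3: str = P3_DEFAULT
    collapse_threshold: int = COLLAPSE_THRESHOLD_DEFAULT

    def __post_init__(self) -> None:
        names = [p.name for p in self.probes]
        if len(set(names)) != len(names):
            raise ValueError("probe names must be unique")
        recs = [p.recognition for p in self.probes]
        if len(set(recs)) != len(recs):
            raise ValueError("recognition sequences must be unique")

    def __len__(self) -> int:
        return len(self.probes)

    def __iter__(self):
        return iter(self.probes)

    @property
    def names(self) -> list[str]:
        return [p.name for p in self.probes]

    @property
    def min_pairwise_distance(self) -> int | None:
        """Smallest Levenshtein distance between any two recognitions."""
        if len(self.probes) < 2:
            return None
        return min(
            levenshtein(a.recognition, b.recognition)
            for i, a in enumerate(self.probes)
            for b in self.probes[i + 1 :]
        )


@dataclass
class Family:
    """A collapsed isodecoder family: member ids plus one representative 40-mer."""

    members: tuple[str, ...]
    representative: str


@dataclass
class ValidationReport:
    """Specificity report for a probe set (report-only; never aborts design)."""

    min_pairwise_distance: int
    min_distance_pair: tuple[str, str]
    min_distance_fraction: float  # of the recognition length
    gc_fractions: dict[str, float]
    pairs_below_threshold: list[tuple[str, str, int]]
    passed: bool


# ---------------------------------------------------------------------------
# Design pipeline
# ---------------------------------------------------------------------------

def extract_3prime_region(
    ref: TRNAReference, length: int = RECOGNITION_LENGTH
) -> str:
    """Last ``length`` nucleotides of the mature sequence, 5'->3' preserved."""
    if len(ref.sequence) < length:
        raise SequenceTooShortError(
            f"reference {ref.id!r} is {len(ref.sequence)} nt; need >= {length}"
        )
    return ref.sequence[-length:]


def collapse_families(
    regions: Mapping[str, str], threshold: int = COLLAPSE_THRESHOLD_DEFAULT
) -> list[Family]:
    """Group 3' regions into families by single-linkage at distance < threshold.

    Families are the connected components of the graph joining pairs of
    regions whose Levenshtein distance is strictly below ``threshold`` — the
    unique order-independent realization of "collapsing into one species".
    The representative is the most frequent member sequence (ties broken
    lexicographically), maximizing exact-match capture of reads.

    Families are returned sorted by representative sequence, so the partition
    is a pure function of the input set.
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    lengths = {len(s) for s in regions.values()}
    if len(lengths) > 1:
        raise ValueError(f"regions must share one length, got {sorted(lengths)}")

    graph = nx.Graph()
    graph.add_nodes_from(regions)
    ids = sorted(regions)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            if levenshtein(regions[a], regions[b]) < threshold:
                graph.add_edge(a, b)

    families = []
    for component in nx.connected_components(graph):
        members = tuple(sorted(component))
        counts = Counter(regions[m] for m in members)
        top = max(counts.values())
        representative = min(s for s, c in counts.items() if c == top)
        families.append(Family(members=members, representative=representative))
    families.sort(key=lambda f: f.representative)
    return families


def build_probe(
    family: Family,
    name: str,
    compartment: str,
    p5: str = P5_DEFAULT,
    p3: str = P3_DEFAULT,
) -> Probe:
    """Assemble the oligo for one family: p5 + revcomp(region) + p3, dyed.

    With the default adapters (21 + 40 + 26 nt) the construct is 87 nt.
    """
    recognition = reverse_complement(family.representative)
    dye = DYE_CYTOSOLIC if compartment == "cytosolic" else DYE_MITOCHONDRIAL
    return Probe(
        name=name,
        compartment=compartment,
        recognition=recognition,
        construct=p5 + recognition + p3,
        dye=dye,
        members=family.members,
    )


def _family_name(refs_by_id: Mapping[str, TRNAReference], family: Family) -> str:
    # label by the amino acid + anticodon(s) of the members, e.g. ThrAGT
    rep_refs = [refs_by_id[m] for m in family.members]
    aas = sorted({r.amino_acid for r in rep_refs})
    anticodons = sorted({r.anticodon for r in rep_refs})
    aa_label = "/".join(AA_THREE_LETTER.get(a, a) for a in aas)
    return aa_label + "/".join(anticodons)


def design_probe_set(
    refs: Sequence[TRNAReference],
    threshold: int = COLLAPSE_THRESHOLD_DEFAULT,
    p5: str = P5_DEFAULT,
    p3: str = P3_DEFAULT,
    append_cca: bool = False,
) -> ProbeSet:
    """Full design pipeline: extract 3' 40-mers, collapse, build probes.

    ``append_cca`` adds the universal 3'-CCA to references lacking it, for
    genomic database entries that omit the post-transcriptional addition; the
    hybridization region must match the sequenced molecule, which carries CCA.

    Raises :class:`MixedCompartmentError` if a collapsed family spans both
    compartments (no single dye assignment would be valid).
    """
    if append_cca:
        refs = [
            r
            if r.sequence.endswith("CCA")
            else TRNAReference(
                id=r.id,
                organism=r.organism,
                compartment=r.compartment,
                amino_acid=r.amino_acid,
                anticodon=r.anticodon,
                sequence=r.sequence + "CCA",
            )
            for r in refs
        ]
    refs_by_id = {r.id: r for r in refs}
    if len(refs_by_id) != len(refs):
        raise ValueError("reference ids must be unique")
    regions = {r.id: extract_3prime_region(r) for r in refs}
    families = collapse_families(regions, threshold=threshold)

    probes = []
    used_names: Counter[str] = Counter()
    for family in families:
        compartments = {refs_by_id[m].compartment for m in family.members}
        if len(compartments) > 1:
            raise MixedCompartmentError(
                f"family {family.members} mixes compartments {sorted(compartments)}"
            )
        name = _family_name(refs_by_id, family)
        used_names[name] += 1
        if used_names[name] > 1:
            name = f"{name}.{used_names[name]}"
        probes.append(
            build_probe(family, name, compartments.pop(), p5=p5, p3=p3)
        )
    return ProbeSet(probes=probes, p5=p5, p3=p3, collapse_threshold=threshold)


def validate_probe_set(probe_set: ProbeSet) -> ValidationReport:
    """All-pairs distance audit of the recognitions.

    Fails (``passed=False``) if any pair sits below the collapse threshold;
    failure is reported, never raised, so a designer can inspect borderline
    genomes.
    """
    probes = probe_set.probes
    if len(probes) < 2:
        raise ValueError("validation needs at least 2 probes")
    min_dist = None
    min_pair = ("", "")
    below: list[tuple[str, str, int]] = []
    for i, a in enumerate(probes):
        for b in probes[i + 1 :]:
            d = levenshtein(a.recognition, b.recognition)
            if min_dist is None or d < min_dist:
                min_dist, min_pair = d, (a.name, b.name)
            if d < probe_set.collapse_threshold:
                below.append((a.name, b.name, d))
    assert min_dist is not None
    length = len(probes[0].recognition)
    return ValidationReport(
        min_pairwise_distance=min_dist,
        min_distance_pair=min_pair,
        min_distance_fraction=min_dist / length,
        gc_fractions={p.name: p.gc_fraction for p in probes},
        pairs_below_threshold=below,
        passed=not below,
    )


# ---------------------------------------------------------------------------
# Tabular / FASTA interchange
# ---------------------------------------------------------------------------

_TSV_COLUMNS = [
    "name",
    "compartment",
    "dye",
    "recognition",
    "construct",
    "members",
    "gc_fraction",
]


def write_probe_tsv(probe_set: ProbeSet, path: str | Path) -> None:
    """Probe table, fixed column order; adapters and threshold in # header lines."""
    with open_text(path, "wt") as fh:
        fh.write(f"#p5={probe_set.p5}\n")
        fh.write(f"#p3={probe_set.p3}\n")
        fh.write(f"#collapse_threshold={probe_set.collapse_threshold}\n")
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_TSV_COLUMNS)
        for p in probe_set.probes:
            writer.writerow(
                [
                    p.name,
                    p.compartment,
                    p.dye,
                    p.recognition,
                    p.construct,
                    ",".join(p.members),
                    f"{p.gc_fraction:.6f}",
                ]
            )


def read_probe_tsv(path: str | Path) -> ProbeSet:
    meta = {"p5": P5_DEFAULT, "p3": P3_DEFAULT, "collapse_threshold": "6"}
    rows: list[dict[str, str]] = []
    with open_text(path) as fh:
        header_line: list[str] | None = None
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line[1:].partition("=")
                meta[key] = value
                continue
            fields = line.split("\t")
            if header_line is None:
                header_line = fields
                continue
            rows.append(dict(zip(header_line, fields)))
    probes = [
        Probe(
            name=row["name"],
            compartment=row["compartment"],
            recognition=normalize_sequence(row["recognition"]),
            construct=normalize_sequence(row["construct"]),
            dye=row["dye"],
            members=tuple(row["members"].split(",")) if row["members"] else (),
        )
        for row in rows
    ]
    return ProbeSet(
        probes=probes,
        p5=meta["p5"],
        p3=meta["p3"],
        collapse_threshold=int(meta["collapse_threshold"]),
    )


def write_recognition_fasta(probe_set: ProbeSet, path: str | Path) -> None:
    """Recognition sequences as FASTA — the quantifier's reference set."""
    with open_text(path, "wt") as fh:
        for p in probe_set.probes:
            fh.write(f">{p.name}\n{p.recognition}\n")
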