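"""GenBank/FASTA/TSV readers and writers.

Internal coordinates are 0-based half-open everywhere; every user-facing
file (GenBank, TSV reports, truth tables) is 1-based inclusive.  GenBank
compound locations (join/complement) are flattened to their min..max span
with the strand preserved — islands are contiguous intervals, exon-level
precision is irrelevant here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq, UndefinedSequenceError
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .oup import sequence_pattern
from .sniffer import GenomicIsland

__all__ = [
    "Feature",
    "RepliconRecord",
    "read_genbank",
    "read_fasta",
    "read_replicon",
    "write_fasta",
    "write_genbank",
    "write_island",
    "read_island",
    "write_island_table",
    "to_one_based",
    "from_one_based",
]


def to_one_based(start: int, end: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive."""
    return start + 1, end


def from_one_based(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    return start - 1, end


@dataclass(frozen=True)
class Feature:
    start: int          # 0-based half-open
    end: int
    strand: str         # "+" or "-"
    type: str
    product: str


@dataclass
class RepliconRecord:
    accession: str
    description: str
    sequence: str
    features: list[Feature] = field(default_factory=list)
    lineage: str | None = None
    host_info: str | None = None

    def __post_init__(self):
        if not self.accession:
            raise ValueError("accession must be non-empty")


def read_genbank(path: str | Path) -> RepliconRecord:
    """Read one GenBank flat file into a :class:`RepliconRecord`."""
    try:
        rec = SeqIO.read(str(path), "genbank")
    except ValueError as exc:
        raise ValueError(f"{path}: not a readable GenBank flat file ({exc})") from exc
    try:
        sequence = str(rec.seq)
    except UndefinedSequenceError as exc:
        raise ValueError(f"{path}: GenBank record has no ORIGIN sequence") from exc
    if not sequence:
        raise ValueError(f"{path}: GenBank record has no ORIGIN sequence")

    feats = []
    for f in rec.features:
        if f.type == "source":
            continue
        try:
            start, end = int(f.location.start), int(f.location.end)
        except (AttributeError, TypeError):
            continue  # unparseable location: skip the feature
        strand = "-" if f.location.strand == -1 else "+"
        product = f.qualifiers.get("product", [""])[0]
        feats.append(Feature(start, end, strand, f.type, product))

    taxonomy = rec.annotations.get("taxonomy") or []
    organism = rec.annotations.get("organism", "")
    lineage = ";".join(list(taxonomy) + ([organism] if organism else [])) or None
    return RepliconRecord(
        accession=rec.id or rec.name,
        description=rec.description,
        sequence=sequence,
        features=feats,
        lineage=lineage,
    )


def read_fasta(path: str | Path) -> RepliconRecord:
    """Read the first record of a FASTA file."""
    try:
        rec = next(SeqIO.parse(str(path), "fasta"))
    except StopIteration:
        raise ValueError(f"{path}: no FASTA records found") from None
    return RepliconRecord(
        accession=rec.id, description=rec.description, sequence=str(rec.seq)
    )


def read_replicon(path: str | Path) -> RepliconRecord:
    """Read GenBank or FASTA, sniffing the format from the first byte."""
    path = Path(path)
    with open(path) as fh:
        first = fh.read(1)
    return read_fasta(path) if first == ">" else read_genbank(path)


def write_fasta(record: RepliconRecord, path: str | Path) -> None:
    rec = SeqRecord(Seq(record.sequence), id=record.accession, description=record.description)
    SeqIO.write([rec], str(path), "fasta")


def _taxonomy_parts(lineage: str | None) -> tuple[list[str], str]:
    if not lineage:
        return [], ""
    parts = lineage.split(";")
    return parts[:-1], parts[-1]


def write_genbank(record: RepliconRecord, path: str | Path) -> None:
    """Write a minimal, deterministic GenBank flat file (fixed date stamp)."""
    taxonomy, organism = _taxonomy_parts(record.lineage)
    rec = SeqRecord(
        Seq(record.sequence),
        id=record.accession,
        name=record.accession[:16],
        description=record.description,
        annotations={
            "molecule_type": "DNA",
            "topology": "linear",
            "date": "01-JAN-2000",
            "organism": organism,
            "taxonomy": taxonomy,
        },
    )
    rec.features.append(
        SeqFeature(
            FeatureLocation(0, len(record.sequence), strand=1),
            type="source",
            qualifiers={"organism": [organism] if organism else ["synthetic construct"]},
        )
    )
    for f in record.features:
        rec.features.append(
            SeqFeature(
                FeatureLocation(f.start, f.end, strand=-1 if f.strand == "-" else 1),
                type=f.type,
                qualifiers={"product": [f.product]} if f.product else {},
            )
        )
    SeqIO.write([rec], str(path), "genbank")


def write_island(island: GenomicIsland, path: str | Path) -> None:
    """Write one island as a GenBank record.

    The source feature carries the host accession and the island's
    original 1-based coordinates; features are remapped to island-local
    coordinates; a suspicious (rrn) island gets an asterisk in its
    definition line.
    """
    start1, end1 = to_one_based(island.start, island.end)
    desc = f"genomic island from {island.host_id} {start1}..{end1}"
    if island.suspicious_rrn:
        desc += " *"
    rec = SeqRecord(
        Seq(island.sequence),
        id=island.id.replace(":", "_"),
        name=f"GI_{island.host_id}"[:16].replace(":", "_"),
        description=desc,
        annotations={
            "molecule_type": "DNA",
            "topology": "linear",
            "date": "01-JAN-2000",
        },
    )
    rec.features.append(
        SeqFeature(
            FeatureLocation(0, island.length, strand=1),
            type="source",
            qualifiers={
                "note": [f"host={island.host_id};start={start1};end={end1}"],
                "db_xref": [f"host:{island.host_id}"],
            },
        )
    )
    for fs, fe, strand, product in island.features:
        s = max(fs, island.start) - island.start
        e = min(fe, island.end) - island.start
        if e <= s:
            continue
        rec.features.append(
            SeqFeature(
                FeatureLocation(s, e, strand=-1 if strand == "-" else 1),
                type="CDS",
                qualifiers={"product": [product]} if product else {},
            )
        )
    SeqIO.write([rec], str(path), "genbank")


def read_island(path: str | Path) -> GenomicIsland:
    """Read an island GenBank file written by :func:`write_island`."""
    rec = SeqIO.read(str(path), "genbank")
    sequence = str(rec.seq)
    host_id, start1, end1 = rec.id, 1, len(sequence)
    for f in rec.features:
        if f.type == "source":
            for note in f.qualifiers.get("note", []):
                fields = dict(
                    kv.split("=", 1) for kv in note.split(";") if "=" in kv
                )
                host_id = fields.get("host", host_id)
                start1 = int(fields.get("start", start1))
                end1 = int(fields.get("end", end1))
    start, end = from_one_based(start1, end1)
    feats = []
    for f in rec.features:
        if f.type == "source":
            continue
        strand = "-" if f.location.strand == -1 else "+"
        product = f.qualifiers.get("product", [""])[0]
        feats.append((int(f.location.start) + start, int(f.location.end) + start, strand, product))
    isl = GenomicIsland(
        host_id=host_id,
        start=start,
        end=end,
        sequence=sequence,
        pattern=sequence_pattern(sequence),
        mean_D=0.0,
        mean_V=0.0,
        suspicious_rrn=rec.description.rstrip().endswith("*"),
        features=feats,
    )
    from .sniffer import keyword_confirm

    isl.keyword_confirmed = keyword_confirm(feats)
    return isl


def write_island_table(islands, path: str | Path) -> pd.DataFrame:
    """TSV summary of islands (1-based inclusive coordinates)."""
    rows = []
    for isl in islands:
        s1, e1 = to_one_based(isl.start, isl.end)
        rows.append(
            (
                isl.host_id,
                s1,
                e1,
                isl.length,
                round(isl.mean_D, 4),
                round(isl.mean_V, 4),
                isl.suspicious_rrn,
                isl.keyword_confirmed,
            )
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "host_id",
            "start",
            "end",
            "length",
            "mean_D",
            "mean_V",
            "suspicious_rrn",
            "keyword_confirmed",
        ],
    )
    df.to_csv(path, sep="\t", index=False)
    return df
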