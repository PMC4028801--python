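"""Sequence input/output and coordinate bookkeeping.

Reads and writes GenBank flat files and FASTA, classifies records into the
five taxonomic buckets used to route candidates (bacteria & archaea,
eukaryotes, mitochondria, chloroplasts, other), and extracts oriented
candidate windows with flanking sequence while maintaining an exact
coordinate map back to the source record.

Internal coordinates are 0-based half-open throughout; GenBank-facing output
uses the standard 1-based inclusive convention.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord


class Organelle(str, Enum):
    NONE = "none"
    MITOCHONDRION = "mitochondrion"
    CHLOROPLAST = "chloroplast"


class TaxonBucket(str, Enum):
    """The five sets candidate records are divided into."""

    BACTERIA_ARCHAEA = "bacteria_archaea"
    EUKARYOTES = "eukaryotes"
    MITOCHONDRIA = "mitochondria"
    CHLOROPLASTS = "chloroplasts"
    OTHER = "other"


class GenBankParseError(ValueError):
    """A single GenBank block could not be parsed."""


@dataclass
class GenomicRecord:
    """One GenBank entry: sequence, taxonomy, and the original text."""

    accession: str
    version: str
    sequence: str
    taxonomy_lineage: list[str] = field(default_factory=list)
    organelle: Organelle = Organelle.NONE
    organism: str = ""
    raw_entry: str = ""

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError("record sequence must be non-empty")
        if not self.accession:
            raise ValueError("record accession must be non-empty")

    def __len__(self) -> int:
        return len(self.sequence)


_COMPLEMENT = str.maketrans(
    "ACGTUMRWSYKVHDBNacgtumrwsykvhdbn",
    "TGCAAKYWSRMBDHVNtgcaakywsrmbdhvn",
)


def revcomp(seq: str) -> str:
    """Reverse complement, preserving IUPAC ambiguity codes."""
    return seq.translate(_COMPLEMENT)[::-1]


def _split_genbank_blocks(text: str) -> list[str]:
    blocks = []
    current: list[str] = []
    for line in text.splitlines(keepends=True):
        current.append(line)
        if line.strip() == "//":
            blocks.append("".join(current))
            current = []
    tail = "".join(current)
    if tail.strip():
        blocks.append(tail)
    return blocks


def _parse_block(block: str) -> GenomicRecord:
    locus_match = re.search(r"^LOCUS\s+(\S+)\s+(\d+)\s+bp", block, re.M)
    if "ORIGIN" not in block:
        raise GenBankParseError("block has no ORIGIN section")
    try:
        rec = SeqIO.read(io.StringIO(block), "genbank")
    except Exception as exc:  # Biopython raises plain ValueError
        raise GenBankParseError(str(exc)) from exc
    seq = str(rec.seq).upper()
    if not seq:
        raise GenBankParseError(f"{rec.id}: empty sequence")
    if locus_match is not None:
        stated = int(locus_match.group(2))
        if stated != len(seq):
            raise GenBankParseError(
                f"{rec.id}: LOCUS states {stated} bp but sequence has {len(seq)}"
            )
    organelle = Organelle.NONE
    for feat in rec.features:
        if feat.type == "source" and "organelle" in feat.qualifiers:
            value = feat.qualifiers["organelle"][0].lower()
            if "mitochondri" in value:
                organelle = Organelle.MITOCHONDRION
            elif "chloroplast" in value or "plastid" in value:
                organelle = Organelle.CHLOROPLAST
    accession = rec.annotations.get("accessions", [rec.id.split(".")[0]])[0]
    version = rec.id if "." in rec.id else accession
    return GenomicRecord(
        accession=accession,
        version=version,
        sequence=seq,
        taxonomy_lineage=list(rec.annotations.get("taxonomy", [])),
        organelle=organelle,
        organism=rec.annotations.get("organism", ""),
        raw_entry=block,
    )


def read_genbank(text: str) -> list[GenomicRecord]:
    """Parse GenBank flat-file text into records, skipping malformed blocks.

    Use :func:`read_genbank_strict` to get per-block errors instead of
    silently dropping them.
    """
    records, _ = read_genbank_strict(text)
    return records


def read_genbank_strict(
    text: str,
) -> tuple[list[GenomicRecord], list[tuple[int, str]]]:
    """Parse GenBank text; malformed blocks become (index, message) errors
    and do not affect the remaining records."""
    records: list[GenomicRecord] = []
    errors: list[tuple[int, str]] = []
    for i, block in enumerate(_split_genbank_blocks(text)):
        try:
            records.append(_parse_block(block))
        except GenBankParseError as exc:
            errors.append((i, str(exc)))
    return records, errors


def write_genbank(records: Iterable[GenomicRecord]) -> str:
    """Serialize records as GenBank flat-file text (fixed date for
    reproducible output)."""
    out = io.StringIO()
    seqrecords = []
    for rec in records:
        sr = SeqRecord(
            Seq(rec.sequence),
            id=rec.version,
            name=rec.accession,
            description=rec.organism or rec.accession,
        )
        sr.annotations["molecule_type"] = "DNA"
        sr.annotations["topology"] = "linear"
        sr.annotations["date"] = "01-JAN-2000"
        sr.annotations["accessions"] = [rec.accession]
        sr.annotations["organism"] = rec.organism
        sr.annotations["source"] = rec.organism
        sr.annotations["taxonomy"] = list(rec.taxonomy_lineage)
        qualifiers = {"organism": [rec.organism]} if rec.organism else {}
        if rec.organelle is not Organelle.NONE:
            qualifiers["organelle"] = [rec.organelle.value]
        sr.features.append(
            SeqFeature(
                SimpleLocation(0, len(rec.sequence)), type="source",
                qualifiers=qualifiers,
            )
        )
        seqrecords.append(sr)
    SeqIO.write(seqrecords, out, "genbank")
    return out.getvalue()


def classify_taxon(record: GenomicRecord) -> TaxonBucket:
    """Assign a record to one of the five taxonomic buckets.

    Organelle qualifiers take precedence; otherwise the lineage root decides.
    Records without taxonomy go to OTHER.
    """
    if record.organelle is Organelle.MITOCHONDRION:
        return TaxonBucket.MITOCHONDRIA
    if record.organelle is Organelle.CHLOROPLAST:
        return TaxonBucket.CHLOROPLASTS
    if record.taxonomy_lineage:
        root = record.taxonomy_lineage[0].strip()
        if root in ("Bacteria", "Archaea"):
            return TaxonBucket.BACTERIA_ARCHAEA
        if root == "Eukaryota":
            return TaxonBucket.EUKARYOTES
    return TaxonBucket.OTHER


def bucket_records(
    records: Iterable[GenomicRecord],
) -> dict[TaxonBucket, list[GenomicRecord]]:
    buckets: dict[TaxonBucket, list[GenomicRecord]] = {b: [] for b in TaxonBucket}
    for rec in records:
        buckets[classify_taxon(rec)].append(rec)
    return buckets


def concatenate_bucket(records: Sequence[GenomicRecord]) -> str:
    """Concatenated GenBank text of a bucket (original entries verbatim when
    available, regenerated otherwise)."""
    parts = []
    for rec in records:
        parts.append(rec.raw_entry if rec.raw_entry else write_genbank([rec]))
    return "".join(parts)


@dataclass
class SequenceWindow:
    """A candidate region plus flanks, oriented so the IEP reads forward.

    ``source_interval`` is the covered [start, end) interval on the source
    forward strand; when ``source_strand`` is '-', ``window_seq`` is the
    reverse complement of that slice and window position 0 maps to source
    position ``end - 1``.
    """

    candidate_id: str
    source_accession: str
    window_seq: str
    source_interval: tuple[int, int]
    source_strand: str
    hit_interval_window: Optional[tuple[int, int]] = None

    def __len__(self) -> int:
        return len(self.window_seq)

    def to_source(self, window_pos: int) -> int:
        start, end = self.source_interval
        if not 0 <= window_pos < end - start:
            raise IndexError(f"window position {window_pos} out of range")
        if self.source_strand == "+":
            return start + window_pos
        return end - 1 - window_pos

    def to_window(self, source_pos: int) -> int:
        start, end = self.source_interval
        if not start <= source_pos < end:
            raise IndexError(f"source position {source_pos} outside window")
        if self.source_strand == "+":
            return source_pos - start
        return end - 1 - source_pos

    def interval_to_source(self, w_start: int, w_end: int) -> tuple[int, int]:
        """Map a window [start, end) interval to the source forward strand."""
        if w_end <= w_start:
            raise ValueError("empty interval")
        a = self.to_source(w_start)
        b = self.to_source(w_end - 1)
        return (min(a, b), max(a, b) + 1)


def extract_window(
    record: GenomicRecord,
    hit_interval: tuple[int, int],
    strand: str,
    flank_nt: int = 3000,
    candidate_id: Optional[str] = None,
) -> SequenceWindow:
    """Slice the hit plus up to ``flank_nt`` of flank on each side, oriented
    to the strand encoding the IEP; flanks are truncated silently at record
    ends."""
    start, end = hit_interval
    if end <= start:
        raise ValueError("empty hit interval")
    if start < 0 or end > len(record.sequence):
        raise ValueError("hit interval outside record")
    if strand not in "+-":
        raise ValueError(f"bad strand {strand!r}")
    w_start = max(0, start - flank_nt)
    w_end = min(len(record.sequence), end + flank_nt)
    raw = record.sequence[w_start:w_end]
    seq = raw if strand == "+" else revcomp(raw)
    window = SequenceWindow(
        candidate_id=candidate_id or f"{record.accession}:{start}-{end}({strand})",
        source_accession=record.accession,
        window_seq=seq,
        source_interval=(w_start, w_end),
        source_strand=strand,
    )
    if strand == "+":
        window.hit_interval_window = (start - w_start, end - w_start)
    else:
        window.hit_interval_window = (w_end - end, w_end - start)
    return window


def read_fasta(text: str) -> list[tuple[str, str]]:
    """(id, sequence) pairs from FASTA text."""
    out = []
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        out.append((rec.id, str(rec.seq).upper()))
    return out


def write_fasta(entries: Iterable[tuple[str, str]], width: int = 70) -> str:
    lines = []
    for name, seq in entries:
        lines.append(f">{name}")
        for i in range(0, len(seq), width):
            lines.append(seq[i : i + width])
    return "\n".join(lines) + "\n"
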