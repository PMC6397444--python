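"""Annotated-genome input/output and region bookkeeping.

Reads GenBank flat files into :class:`GenomeRecord`, partitions a chromosome
into gene / intergenic / unmodeled segments, and extracts the four region
sets that the scanner operates on: the whole genome, intergenic regions,
and the coding and template strands of protein-coding genes.

Coordinates are converted from GenBank 1-based inclusive to 0-based
half-open at the parser boundary; everything downstream uses 0-based
half-open intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .alphabet import encode, revcomp, sanitize


class GenomeParseError(ValueError):
    """Fatal problem with a genome file (missing sequence, bad coordinates)."""


@dataclass(frozen=True)
class CdsFeature:
    """A protein-coding feature in 0-based half-open genome coordinates."""

    start: int
    end: int
    strand: str  # '+' or '-'
    compound: bool = False
    label: str = ""
    parts: tuple[tuple[int, int], ...] = ()

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise GenomeParseError(
                f"bad CDS interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise GenomeParseError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenomeRecord:
    """An annotated chromosome: sequence over {A,C,G,T,N} plus CDS features."""

    id: str
    sequence: str
    circular: bool = False
    features: list[CdsFeature] = field(default_factory=list)

    def __post_init__(self):
        self.features = sorted(self.features, key=lambda f: (f.start, f.end))
        for f in self.features:
            if f.end > len(self.sequence):
                raise GenomeParseError(
                    f"CDS [{f.start},{f.end}) outside sequence of length "
                    f"{len(self.sequence)}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def codes(self) -> np.ndarray:
        return encode(self.sequence)


@dataclass(frozen=True)
class Segment:
    """One piece of the gene/intergenic decomposition of a chromosome."""

    start: int
    end: int
    klass: str  # 'gene' | 'intergenic' | 'unmodeled'
    strand: Optional[str] = None  # '+'/'-' for genes, None otherwise
    source_feature: Optional[int] = None  # index into GenomeRecord.features

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SegmentPartition:
    """Disjoint, sorted segments whose union is exactly [0, genome_length)."""

    segments: list[Segment]
    genome_length: int

    def __post_init__(self):
        pos = 0
        for s in self.segments:
            if s.start != pos or s.end <= s.start:
                raise ValueError("segments must tile [0, genome_length)")
            if s.klass == "gene" and s.strand not in "+-":
                raise ValueError("gene segments need a strand")
            pos = s.end
        if pos != self.genome_length:
            raise ValueError("segments do not cover the genome")

    def __iter__(self):
        return iter(self.segments)

    def __len__(self):
        return len(self.segments)

    def by_class(self, klass: str) -> list[Segment]:
        return [s for s in self.segments if s.klass == klass]

    def to_bed(self, path) -> None:
        """Write a BED-like TSV (chrom left blank-agnostic: start, end, klass, strand)."""
        with open(path, "w") as fh:
            fh.write("#start\tend\tklass\tstrand\n")
            for s in self.segments:
                fh.write(f"{s.start}\t{s.end}\t{s.klass}\t{s.strand or '.'}\n")


@dataclass(frozen=True)
class SeqEntry:
    """One sequence of a region set, with its genome provenance."""

    name: str
    sequence: str
    scan_mode: str  # 'both_strands' | 'given_strand_only'
    start: int
    end: int
    strand: str  # '+'/'-'; for both_strands entries this is the stored text strand


@dataclass
class SequenceSet:
    """Named collection of sequences extracted from one genome region mode."""

    name: str
    entries: list[SeqEntry]

    def __iter__(self):
        return iter(self.entries)

    def __len__(self):
        return len(self.entries)

    @property
    def scan_mode(self) -> str:
        return self.entries[0].scan_mode if self.entries else "both_strands"


REGION_MODES = ("genome", "intergenic", "coding", "template")


def read_genbank(path) -> GenomeRecord:
    """Read the first record of a GenBank flat file.

    The sequence is upper-cased with non-ACGT characters mapped to N.  All
    CDS features are captured; join/compound locations are flagged and carry
    their sub-intervals.
    """
    records = list(SeqIO.parse(str(path), "genbank"))
    if not records:
        raise GenomeParseError(f"no GenBank record found in {path}")
    if len(records) > 1:
        warnings.warn(
            f"{path}: {len(records)} records found; using the first only")
    rec = records[0]
    try:
        seq = str(rec.seq)
    except Exception as exc:  # undefined sequence (CONTIG-only record)
        raise GenomeParseError(f"{path}: no usable sequence: {exc}") from exc
    if not seq:
        raise GenomeParseError(f"{path}: record has no ORIGIN sequence block")
    features = []
    for feat in rec.features:
        if feat.type != "CDS" or feat.location is None:
            continue
        loc = feat.location
        compound = isinstance(loc, CompoundLocation) or len(loc.parts) > 1
        strand = "-" if loc.strand == -1 else "+"
        label = ""
        for key in ("locus_tag", "gene", "protein_id"):
            if key in feat.qualifiers:
                label = feat.qualifiers[key][0]
                break
        start, end = int(loc.start), int(loc.end)
        if end > len(seq) or start < 0:
            raise GenomeParseError(
                f"{path}: CDS [{start},{end}) outside sequence")
        parts = (tuple(sorted((int(p.start), int(p.end)) for p in loc.parts))
                 if compound else ())
        features.append(CdsFeature(start, end, strand, compound, label, parts))
    if not features:
        warnings.warn(f"{path}: no CDS features found")
    topology = rec.annotations.get("topology", "linear")
    return GenomeRecord(
        id=rec.id or rec.name,
        sequence=sanitize(seq),
        circular=(topology == "circular"),
        features=features,
    )


def write_genbank(genome: GenomeRecord, path) -> None:
    """Write a GenomeRecord as a GenBank flat file (round-trips with the reader)."""
    rec = SeqRecord(
        Seq(genome.sequence),
        id=genome.id,
        name=genome.id.split(".")[0][:16] or "chromosome",
        description="synthetic chromosome" if not genome.circular else "chromosome",
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if genome.circular else "linear",
        },
    )
    for f in genome.features:
        strand = -1 if f.strand == "-" else 1
        if f.compound and len(f.parts) > 1:
            loc = CompoundLocation(
                [SimpleLocation(s, e, strand) for s, e in f.parts])
        else:
            loc = SimpleLocation(f.start, f.end, strand)
        qualifiers = {"locus_tag": [f.label]} if f.label else {}
        rec.features.append(SeqFeature(loc, type="CDS", qualifiers=qualifiers))
    SeqIO.write([rec], str(path), "genbank")


def partition_genome(genome: GenomeRecord) -> SegmentPartition:
    """Decompose the chromosome into gene / intergenic / unmodeled segments.

    A CDS becomes a gene segment when it is non-compound, its length is a
    multiple of 3, and it does not overlap a previously accepted gene
    (earlier start wins whole).  The uncovered remainder of a rejected CDS,
    compound CDS, and CDS whose length is not divisible by 3 become
    unmodeled segments: the randomizer treats them like intergenic DNA, but
    they are still masked out of "intergenic" region scans.
    """
    n = genome.length
    # 0 = intergenic, 1 = gene, 2 = unmodeled
    label = np.zeros(n, dtype=np.int8)
    genes: list[tuple[int, int, str, int]] = []  # (start, end, strand, feat idx)
    last_gene_end = -1
    for idx, f in enumerate(genome.features):
        acceptable = (not f.compound) and f.length % 3 == 0
        if acceptable and f.start >= last_gene_end:
            genes.append((f.start, f.end, f.strand, idx))
            label[f.start:f.end] = 1
            last_gene_end = f.end
        else:
            for s, e in (f.parts or ((f.start, f.end),)):
                span = label[s:e]
                span[span == 0] = 2
    segments: list[Segment] = []

    def _fill_nongene(a: int, b: int) -> None:
        # split [a, b) into maximal runs of intergenic vs unmodeled
        pos = a
        while pos < b:
            k = label[pos]
            run = pos
            while run < b and label[run] == k:
                run += 1
            klass = "unmodeled" if k == 2 else "intergenic"
            segments.append(Segment(pos, run, klass))
            pos = run

    cursor = 0
    for s, e, strand, idx in genes:
        if cursor < s:
            _fill_nongene(cursor, s)
        segments.append(Segment(s, e, "gene", strand, idx))
        cursor = e
    if cursor < n:
        _fill_nongene(cursor, n)
    return SegmentPartition(segments, n)


def _gene_sense_text(genome_seq: str, seg: Segment) -> str:
    text = genome_seq[seg.start:seg.end]
    return revcomp(text) if seg.strand == "-" else text


def extract_region_set(
    genome: GenomeRecord, partition: SegmentPartition, mode: str
) -> SequenceSet:
    """Extract one of the four scanned region sets.

    genome:     one sequence, the whole chromosome, scanned on both strands.
    intergenic: one plus-strand sequence per intergenic segment, both strands.
    coding:     each gene's sense-strand text, scanned on that strand only.
    template:   reverse complement of each coding sequence, one strand only.
    """
    if mode not in REGION_MODES:
        raise ValueError(f"unknown region mode {mode!r}")
    seq = genome.sequence
    entries: list[SeqEntry] = []
    if mode == "genome":
        entries.append(SeqEntry(genome.id, seq, "both_strands", 0,
                                genome.length, "+"))
    elif mode == "intergenic":
        for i, seg in enumerate(partition.by_class("intergenic")):
            entries.append(SeqEntry(
                f"ig_{i:05d}", seq[seg.start:seg.end], "both_strands",
                seg.start, seg.end, "+"))
    else:
        for i, seg in enumerate(partition.by_class("gene")):
            sense = _gene_sense_text(seq, seg)
            text = sense if mode == "coding" else revcomp(sense)
            strand = seg.strand if mode == "coding" else (
                "-" if seg.strand == "+" else "+")
            entries.append(SeqEntry(
                f"gene_{i:05d}", text, "given_strand_only",
                seg.start, seg.end, strand))
    return SequenceSet(mode, entries)


def read_fasta(path) -> list[tuple[str, str]]:
    """Read a multi-FASTA file into (name, sequence) pairs."""
    return [(rec.id, sanitize(str(rec.seq)))
            for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(entries: Iterable[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for name, seq in entries:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")
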