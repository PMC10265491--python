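"""Sequence and annotation I/O with a fixed coordinate convention.

Every genomic coordinate handled by this package is 1-based and inclusive,
exactly as printed in GFF3 files; any half-open arithmetic is private to the
function that needs it.  A gene spanning ``start..end`` therefore has length
``end - start + 1``.

IUPAC ambiguity codes pass through I/O unchanged; downstream scoring treats
them as mismatches.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

# gap characters are allowed so aligned FASTA round-trips through the same reader
_DNA = set("ACGTUNRYSWKMBDHV-.")
_PROTEIN = set("ACDEFGHIKLMNPQRSTVWYXBZJUO*-.")

__all__ = [
    "GeneModel",
    "SeqCollection",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "extract_sequence",
    "reverse_complement",
]


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC codes handled)."""
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class GeneModel:
    """One annotated gene: coordinates, strand, CDS layout and chromosome rank.

    ``cds_segments`` are 1-based inclusive genomic intervals, sorted in
    genomic order; ``rank_index`` is the ordinal position of the gene along
    its chromosome among *all* annotated genes (used for intervening-gene
    counts in tandem-duplication calls).
    """

    gene_id: str
    chromosome: str
    strand: str
    start: int
    end: int
    cds_segments: tuple[tuple[int, int], ...]
    rank_index: int = 0

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: unknown strand {self.strand!r}")
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} > end {self.end}")
        prev_end = None
        for s, e in self.cds_segments:
            if s > e:
                raise ValueError(f"{self.gene_id}: CDS segment {s}..{e} inverted")
            if s < self.start or e > self.end:
                raise ValueError(
                    f"{self.gene_id}: CDS segment {s}..{e} outside gene span "
                    f"{self.start}..{self.end}"
                )
            if prev_end is not None and s <= prev_end:
                raise ValueError(f"{self.gene_id}: CDS segments overlap or unsorted")
            prev_end = e

    @property
    def span(self) -> int:
        """Genomic length, end − start + 1."""
        return self.end - self.start + 1

    @property
    def intron_count(self) -> int:
        return max(len(self.cds_segments) - 1, 0)

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_segments)


@dataclass
class SeqCollection:
    """Ordered id → sequence mapping with a declared alphabet ('dna'/'protein')."""

    records: dict[str, str]
    alphabet: str = "dna"

    def __post_init__(self) -> None:
        allowed = _DNA if self.alphabet == "dna" else _PROTEIN
        for rid, seq in self.records.items():
            if not seq:
                raise ValueError(f"empty sequence for record {rid!r}")
            bad = set(seq.upper()) - allowed
            if bad:
                raise ValueError(
                    f"record {rid!r}: characters {sorted(bad)} outside "
                    f"{self.alphabet} alphabet"
                )

    def __getitem__(self, rid: str) -> str:
        return self.records[rid]

    def __contains__(self, rid: str) -> bool:
        return rid in self.records

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def items(self):
        return self.records.items()


def read_fasta(path: str | Path, alphabet: str = "dna") -> SeqCollection:
    """Read a (possibly line-wrapped) FASTA file.

    Duplicate ids and empty sequences are hard errors; sequence case is
    preserved on read.
    """
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seq = str(rec.seq)
        if not seq:
            raise ValueError(f"empty sequence for FASTA id {rec.id!r} in {path}")
        records[rec.id] = seq
    return SeqCollection(records, alphabet=alphabet)


def write_fasta(collection: SeqCollection | Mapping[str, str], path: str | Path, width: int = 80) -> None:
    """Write sequences as multi-line FASTA (≤ ``width`` columns)."""
    items = collection.items() if hasattr(collection, "items") else collection
    recs = [SeqRecord(Seq(seq), id=rid, description="") for rid, seq in items]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Parse gene/mRNA/CDS features from a GFF3 file into GeneModels.

    Coordinates are kept 1-based inclusive.  ``rank_index`` is assigned by
    sorting gene starts per chromosome over all genes in the file.
    """
    db = gffutils.create_db(
        str(path), dbfn=":memory:", keep_order=True, merge_strategy="create_unique"
    )
    raw: list[dict] = []
    for gene in db.features_of_type("gene"):
        if gene.strand not in {"+", "-"}:
            raise ValueError(f"{gene.id}: unknown strand symbol {gene.strand!r}")
        segs = sorted(
            (c.start, c.end) for c in db.children(gene, featuretype="CDS")
        )
        for s, e in segs:
            if s < gene.start or e > gene.end:
                raise ValueError(
                    f"{gene.id}: CDS {s}..{e} outside parent gene span "
                    f"{gene.start}..{gene.end}"
                )
        raw.append(
            dict(
                gene_id=gene.id,
                chromosome=gene.seqid,
                strand=gene.strand,
                start=gene.start,
                end=gene.end,
                cds_segments=tuple(segs),
            )
        )
    # rank by start position within each chromosome
    by_chrom: dict[str, list[dict]] = {}
    for entry in raw:
        by_chrom.setdefault(entry["chromosome"], []).append(entry)
    models: list[GeneModel] = []
    for entries in by_chrom.values():
        for rank, entry in enumerate(sorted(entries, key=lambda d: d["start"])):
            models.append(GeneModel(rank_index=rank, **entry))
    models.sort(key=lambda g: (g.chromosome, g.start))
    return models


def write_gff3(models: Iterable[GeneModel], path: str | Path, source: str = "genefam") -> None:
    """Write GeneModels as a minimal gene/mRNA/CDS GFF3 file."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(models, key=lambda m: (m.chromosome, m.start)):
            base = f"{g.chromosome}\t{source}"
            fh.write(
                f"{base}\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            mrna = f"{g.gene_id}.1"
            fh.write(
                f"{base}\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={mrna};Parent={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.cds_segments, 1):
                phase = 0 if g.strand == "+" else 0
                fh.write(
                    f"{base}\tCDS\t{s}\t{e}\t.\t{g.strand}\t{phase}\t"
                    f"ID={mrna}.cds{i};Parent={mrna}\n"
                )


def extract_sequence(
    genome: SeqCollection,
    chromosome: str,
    start: int,
    end: int,
    strand: str = "+",
    on_out_of_range: str = "error",
) -> str:
    """Inclusive 1-based slice of a chromosome; minus strand reverse-complements.

    ``on_out_of_range`` is ``"error"`` (default) or ``"clip"`` (clip to the
    chromosome with a logged warning).
    """
    if chromosome not in genome:
        raise KeyError(f"chromosome {chromosome!r} not in genome")
    if start > end:
        raise ValueError(f"invalid range {start}..{end} (start > end)")
    chrom = genome[chromosome]
    if start < 1 or end > len(chrom):
        if on_out_of_range == "clip":
            clipped = (max(start, 1), min(end, len(chrom)))
            logger.warning(
                "range %d..%d clipped to %d..%d on %s",
                start, end, clipped[0], clipped[1], chromosome,
            )
            start, end = clipped
        else:
            raise ValueError(
                f"range {start}..{end} outside {chromosome} (length {len(chrom)})"
            )
    seq = chrom[start - 1 : end]
    return reverse_complement(seq) if strand == "-" else seq
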