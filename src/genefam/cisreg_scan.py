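"""Promoter extraction and cis-regulatory element scanning.

Promoters are the 2,000 bp immediately 5′ of the start codon,
strand-oriented.  Elements come from a curated dictionary of IUPAC consensus
motifs grouped into hormone / stress / development categories (a compact
stand-in for a full plant cis-element database; the shipped table covers the
elements commonly reported for stress-responsive gene families and is
user-extensible).  Both strands are scanned; IUPAC codes in a consensus
match their base sets, while ambiguity codes in the *sequence* count as
mismatches.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .io_formats import GeneModel, SeqCollection, extract_sequence, reverse_complement

logger = logging.getLogger(__name__)

CATEGORIES = ("hormone", "stress", "development")

IUPAC_DNA = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

__all__ = [
    "ElementDef",
    "ElementHit",
    "load_dictionary",
    "extract_promoter",
    "scan_elements",
    "categorize_counts",
]


@dataclass(frozen=True)
class ElementDef:
    name: str
    consensus: str
    category: str
    response: str

    def __post_init__(self) -> None:
        if not self.consensus:
            raise ValueError(f"element {self.name!r}: empty consensus")
        bad = set(self.consensus.upper()) - set(IUPAC_DNA)
        if bad:
            raise ValueError(
                f"element {self.name!r}: malformed IUPAC symbols {sorted(bad)}"
            )
        if self.category not in CATEGORIES:
            raise ValueError(
                f"element {self.name!r}: category {self.category!r} not in {CATEGORIES}"
            )


@dataclass(frozen=True)
class ElementHit:
    promoter_id: str
    element: str
    position: int  # 1-based start on the promoter forward strand
    strand: str


def load_dictionary(path: str | Path | None = None) -> list[ElementDef]:
    """Load the element dictionary TSV (packaged dictionary by default)."""
    if path is None:
        src = resources.files("genefam.data").joinpath("cis_elements.tsv")
        with resources.as_file(src) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    defs = [
        ElementDef(str(row["name"]), str(row["consensus"]).upper(),
                   str(row["category"]), str(row["response"]))
        for _, row in df.iterrows()
    ]
    names = [d.name for d in defs]
    if len(names) != len(set(names)):
        raise ValueError("duplicate element names in dictionary")
    return defs


def extract_promoter(
    gene: GeneModel, genome: SeqCollection, length: int = 2000
) -> str:
    """2 kb immediately 5′ of the start codon, oriented on the gene strand.

    Truncated at the chromosome edge with a logged warning.
    """
    chrom_len = len(genome[gene.chromosome])
    if gene.strand == "+":
        lo, hi = gene.start - length, gene.start - 1
    else:
        lo, hi = gene.end + 1, gene.end + length
    clipped_lo, clipped_hi = max(lo, 1), min(hi, chrom_len)
    if (clipped_lo, clipped_hi) != (lo, hi):
        logger.warning(
            "gene %s: promoter truncated to %d bp at the chromosome edge",
            gene.gene_id, max(clipped_hi - clipped_lo + 1, 0),
        )
    if clipped_lo > clipped_hi:
        return ""
    return extract_sequence(
        genome, gene.chromosome, clipped_lo, clipped_hi, strand=gene.strand
    )


def _matches_at(seq: str, motif: str, pos: int) -> bool:
    for off, code in enumerate(motif):
        base = seq[pos + off]
        if base not in "ACGT" or base not in IUPAC_DNA[code]:
            return False
    return True


def scan_elements(
    promoter: str,
    dictionary: Sequence[ElementDef],
    promoter_id: str = "",
) -> list[ElementHit]:
    """Find every (overlapping) element occurrence on both strands.

    A minus-strand hit is reported at the start of its footprint on the
    forward promoter coordinates.
    """
    seq = promoter.upper()
    hits: list[ElementHit] = []
    for elem in dictionary:
        for motif, strand in ((elem.consensus, "+"), (reverse_complement(elem.consensus), "-")):
            w = len(motif)
            for i in range(len(seq) - w + 1):
                if _matches_at(seq, motif, i):
                    hits.append(ElementHit(promoter_id, elem.name, i + 1, strand))
    hits.sort(key=lambda h: (h.promoter_id, h.position, h.element, h.strand))
    return hits


def categorize_counts(
    hits: Sequence[ElementHit], dictionary: Sequence[ElementDef]
) -> dict[str, pd.DataFrame]:
    """Per-promoter count tables by response label and by category.

    Returns ``{"by_response": ..., "by_category": ...}`` DataFrames indexed
    by promoter id, with every dictionary label present (zero-filled) and a
    family-level "total" row.
    """
    by_name = {d.name: d for d in dictionary}
    for h in hits:
        if h.element not in by_name:
            raise KeyError(f"hit names unknown element {h.element!r}")
    promoters = sorted({h.promoter_id for h in hits})
    responses = sorted({d.response for d in dictionary})
    resp = pd.DataFrame(0, index=promoters, columns=responses)
    cat = pd.DataFrame(0, index=promoters, columns=list(CATEGORIES))
    for h in hits:
        d = by_name[h.element]
        resp.loc[h.promoter_id, d.response] += 1
        cat.loc[h.promoter_id, d.category] += 1
    resp.loc["total"] = resp.sum(axis=0)
    cat.loc["total"] = cat.sum(axis=0)
    return {"by_response": resp, "by_category": cat}
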