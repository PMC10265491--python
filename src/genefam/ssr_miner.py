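"""Perfect-microsatellite (SSR) mining in the MISA style.

Di-, tri- and tetranucleotide perfect repeats are detected with minimum
repeat counts of 6, 5 and 5 respectively, over the gene region plus 2 kb of
flank on each side.  Motifs whose unit is itself periodic (e.g. "ATAT") are
suppressed in favour of the shorter unit; mononucleotide runs are not
searched, so pure homopolymers yield nothing.  Overlapping candidates are
resolved longest-first, then leftmost.  Consecutive SSRs separated by at
most 100 bp (MISA's default) merge into a compound SSR.  Motifs are reported
as found, without canonical rotation or strand collapsing; a normalization
helper is provided for statistics but is off by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

from .io_formats import GeneModel, SeqCollection, extract_sequence, reverse_complement

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = {2: 6, 3: 5, 4: 5}
UNIT_CLASS_NAMES = {2: "di", 3: "tri", 4: "tetra"}

__all__ = [
    "SSRRecord",
    "AnalysisWindow",
    "analysis_window",
    "find_ssrs",
    "merge_compound",
    "ssr_stats",
    "mine_gene",
    "canonical_motif",
]


@dataclass(frozen=True)
class SSRRecord:
    """One microsatellite, 1-based inclusive within the analysed sequence."""

    seq_id: str
    motif: str
    repeats: int
    start: int
    end: int
    region: str = ""  # upstream | genic | downstream (when region-mapped)
    compound_id: str = ""

    @property
    def unit_length(self) -> int:
        return len(self.motif)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class AnalysisWindow:
    """Strand-oriented upstream + genic + downstream sequence of one gene."""

    gene_id: str
    sequence: str
    upstream_len: int
    genic_len: int
    downstream_len: int

    def region_of(self, pos: int) -> str:
        """Region containing a 1-based window position."""
        if pos <= self.upstream_len:
            return "upstream"
        if pos <= self.upstream_len + self.genic_len:
            return "genic"
        return "downstream"


def _is_periodic(unit: str) -> bool:
    """True when the unit is a repetition of a shorter unit (e.g. ATAT)."""
    n = len(unit)
    for p in range(1, n):
        if n % p == 0 and unit == unit[:p] * (n // p):
            return True
    return False


def analysis_window(
    gene: GeneModel, genome: SeqCollection, flank: int = 2000
) -> AnalysisWindow:
    """Gene ± flank, oriented 5′→3′ on the gene's strand.

    For a minus-strand gene the window is the reverse complement of the
    genomic slice, so "upstream" lies at higher genomic coordinates.
    Flanks are truncated at chromosome edges with a log entry.
    """
    chrom_len = len(genome[gene.chromosome])
    lo = gene.start - flank
    hi = gene.end + flank
    if lo < 1 or hi > chrom_len:
        logger.info(
            "gene %s: flank truncated to chromosome bounds (%d..%d → %d..%d)",
            gene.gene_id, lo, hi, max(lo, 1), min(hi, chrom_len),
        )
        lo, hi = max(lo, 1), min(hi, chrom_len)
    seq = extract_sequence(genome, gene.chromosome, lo, hi, strand=gene.strand)
    left = gene.start - lo      # genomic bases before the gene
    right = hi - gene.end       # genomic bases after the gene
    up, down = (left, right) if gene.strand == "+" else (right, left)
    return AnalysisWindow(
        gene_id=gene.gene_id,
        sequence=seq,
        upstream_len=up,
        genic_len=gene.span,
        downstream_len=down,
    )


def find_ssrs(
    sequence: str,
    thresholds: Mapping[int, int] = DEFAULT_THRESHOLDS,
    seq_id: str = "",
) -> list[SSRRecord]:
    """Detect leftmost-maximal perfect repeats of unit length 2–4.

    Candidates are maximal runs (not left-extendable, partial units
    discarded); overlaps across classes resolve longest-first, then
    leftmost, then shortest unit.
    """
    seq = sequence.upper()
    n = len(seq)
    candidates: list[SSRRecord] = []
    for ulen, min_rep in sorted(thresholds.items()):
        i = 0
        while i + ulen * min_rep <= n:
            unit = seq[i : i + ulen]
            if _is_periodic(unit) or not set(unit) <= set("ACGT"):
                i += 1
                continue
            # leftmost: the run must not extend left with the same period
            if i > 0 and seq[i - 1] == seq[i + ulen - 1]:
                i += 1
                continue
            # extend right while periodicity holds
            j = i + ulen
            while j < n and seq[j] == seq[j - ulen]:
                j += 1
            count = (j - i) // ulen
            if count >= min_rep:
                candidates.append(
                    SSRRecord(
                        seq_id=seq_id,
                        motif=unit,
                        repeats=count,
                        start=i + 1,
                        end=i + ulen * count,
                    )
                )
                i = i + ulen * count  # jump past the reported repeat
            else:
                i += 1
    # longest-first, then leftmost, then shortest unit
    candidates.sort(key=lambda r: (-r.length, r.start, r.unit_length))
    chosen: list[SSRRecord] = []
    occupied: list[tuple[int, int]] = []
    for cand in candidates:
        if any(not (cand.end < s or cand.start > e) for s, e in occupied):
            continue
        chosen.append(cand)
        occupied.append((cand.start, cand.end))
    chosen.sort(key=lambda r: r.start)
    return chosen


def merge_compound(
    records: Sequence[SSRRecord], max_interruption: int = 100
) -> list[SSRRecord]:
    """Assign a shared compound_id to runs of SSRs separated by ≤ 100 bp."""
    out: list[SSRRecord] = []
    by_seq: dict[str, list[SSRRecord]] = {}
    for rec in records:
        by_seq.setdefault(rec.seq_id, []).append(rec)
    counter = 0
    for seq_id in sorted(by_seq):
        recs = sorted(by_seq[seq_id], key=lambda r: r.start)
        groups: list[list[SSRRecord]] = []
        for rec in recs:
            if groups and rec.start - groups[-1][-1].end - 1 <= max_interruption:
                groups[-1].append(rec)
            else:
                groups.append([rec])
        for group in groups:
            if len(group) > 1:
                counter += 1
                cid = f"compound{counter}"
                out.extend(replace(r, compound_id=cid) for r in group)
            else:
                out.append(group[0])
    out.sort(key=lambda r: (r.seq_id, r.start))
    return out


def canonical_motif(motif: str) -> str:
    """Lexicographic minimum over rotations and the reverse-complement strand."""
    variants = []
    for m in (motif, reverse_complement(motif)):
        variants.extend(m[i:] + m[:i] for i in range(len(m)))
    return min(variants)


def ssr_stats(records: Sequence[SSRRecord]) -> dict:
    """Counts and 2-dp percentages by unit length, repeat count and region.

    Two denominators are reported: the number of SSR occurrences and the
    number of distinct SSR types (unit motifs as found); class percentages
    use the type denominator, matching the published summary convention.
    """
    def _pct(counts: dict) -> dict:
        total = sum(counts.values())
        return {k: round(100.0 * v / total, 2) if total else 0.0 for k, v in counts.items()}

    unit_counts: dict[str, int] = {}
    repeat_counts: dict[int, int] = {}
    region_counts: dict[str, int] = {}
    types_by_unit: dict[str, set] = {}
    for rec in records:
        cls = UNIT_CLASS_NAMES.get(rec.unit_length, str(rec.unit_length))
        unit_counts[cls] = unit_counts.get(cls, 0) + 1
        repeat_counts[rec.repeats] = repeat_counts.get(rec.repeats, 0) + 1
        if rec.region:
            region_counts[rec.region] = region_counts.get(rec.region, 0) + 1
        types_by_unit.setdefault(cls, set()).add(rec.motif)
    type_counts = {cls: len(motifs) for cls, motifs in types_by_unit.items()}
    return dict(
        total=len(records),
        unit_counts=unit_counts,
        unit_percentages=_pct(unit_counts),
        type_counts=type_counts,
        type_percentages=_pct(type_counts),
        repeat_counts=repeat_counts,
        repeat_percentages=_pct(repeat_counts),
        region_counts=region_counts,
        region_percentages=_pct(region_counts),
        n_compound=len({r.compound_id for r in records if r.compound_id}),
    )


def mine_gene(
    gene: GeneModel,
    genome: SeqCollection,
    thresholds: Mapping[int, int] = DEFAULT_THRESHOLDS,
    flank: int = 2000,
    max_interruption: int = 100,
) -> list[SSRRecord]:
    """Full per-gene SSR mining: window, detection, regions, compounds.

    An SSR straddling a region boundary is attributed to the region
    containing its start.
    """
    window = analysis_window(gene, genome, flank=flank)
    records = [
        replace(rec, region=window.region_of(rec.start))
        for rec in find_ssrs(window.sequence, thresholds, seq_id=gene.gene_id)
    ]
    return merge_compound(records, max_interruption=max_interruption)
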