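"""Duplicate-pair detection, classification, NG86 Ka/Ks and clock dating.

A pair of family CDS is called a duplicate when a global alignment covers
more than 70% of the longer sequence and shows more than 70% identity over
the aligned region (the "70/70" rule).  Pairs on one chromosome separated by
at most five intervening genes and at most 100 kb start-to-start are tandem
duplicates; everything else is segmental.  Synonymous and nonsynonymous
substitution rates are estimated by the Nei–Gojobori (1986) counting method:
per-codon synonymous site fractions averaged over both sequences,
multiple-difference codons averaged over all minimal substitution paths, and
a Jukes–Cantor correction d = −(3/4)·ln(1 − 4p/3).  Ks converts to a
divergence time via T = Ks / (2λ) × 10⁻⁶ Mya with a clock rate λ of
6.1 × 10⁻⁹ substitutions per synonymous site per year.

Site-counting convention: a mutation that would create a stop codon counts
as nonsynonymous, so every codon contributes exactly 3 sites and
N + S = 3 × codon count.  Substitution paths passing through a stop codon
are excluded from the path average (unless every path is blocked, in which
case all paths are used).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .io_formats import GeneModel
from .seqprops import _CODON_TO_AA

CLOCK_RATE = 6.1e-9  # substitutions / synonymous site / year
_BASES = "ACGT"

__all__ = [
    "DuplicatePair",
    "KaKsSaturationError",
    "align_pair",
    "codon_align_pair",
    "find_duplicates",
    "classify_pair",
    "ng86_site_counts",
    "ng86_proportions",
    "kaks_ng86",
    "divergence_time",
    "duplication_report",
]


class KaKsSaturationError(ValueError):
    """Raised when p ≥ 3/4 and the Jukes–Cantor correction diverges."""


@dataclass
class DuplicatePair:
    """A duplicate gene pair with its alignment stats, type and date."""

    gene_a: str
    gene_b: str
    coverage: float
    similarity: float
    dup_type: str = ""
    ka: float = float("nan")
    ks: float = float("nan")
    t_mya: float = float("nan")
    saturated: bool = False

    @property
    def kaks_ratio(self) -> float:
        return self.ka / self.ks if self.ks > 0 else float("nan")


# ---------------------------------------------------------------------------
# pairwise alignment and the 70/70 rule

def _nucleotide_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -1
    aligner.open_gap_score = -4
    aligner.extend_gap_score = -1
    return aligner


def align_pair(seq_a: str, seq_b: str) -> tuple[float, float, tuple[str, str]]:
    """Globally align two CDS and report (coverage, similarity, aligned pair).

    coverage = columns where both sequences have a residue / length of the
    longer sequence; similarity = identical columns / columns where both
    sequences have a residue.  Scoring: match +2, mismatch −1, gap open −4,
    gap extend −1.
    """
    if not seq_a or not seq_b:
        raise ValueError("cannot align an empty sequence")
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    aln = _nucleotide_aligner().align(seq_a, seq_b)[0]
    ga, gb = aln[0], aln[1]
    both = sum(1 for x, y in zip(ga, gb) if x != "-" and y != "-")
    ident = sum(1 for x, y in zip(ga, gb) if x == y and x != "-")
    longer = max(len(seq_a), len(seq_b))
    coverage = both / longer
    similarity = ident / both if both else 0.0
    return coverage, similarity, (ga, gb)


def codon_align_pair(cds_a: str, cds_b: str) -> tuple[str, str]:
    """Gap-free codon alignment of two CDS, guided by a protein alignment.

    The translated products are aligned with BLOSUM62; each aligned residue
    pair maps back to its codon, and any codon opposite a gap is dropped
    whole.  Terminal stop codons are removed first.
    """
    from .seqprops import translate_cds

    pa, pb = translate_cds(cds_a), translate_cds(cds_b)
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10
    aligner.extend_gap_score = -0.5
    aln = aligner.align(pa, pb)[0]
    ga, gb = aln[0], aln[1]
    cds_a, cds_b = cds_a.upper(), cds_b.upper()
    ia = ib = 0
    cod_a: list[str] = []
    cod_b: list[str] = []
    for x, y in zip(ga, gb):
        if x != "-" and y != "-":
            cod_a.append(cds_a[3 * ia : 3 * ia + 3])
            cod_b.append(cds_b[3 * ib : 3 * ib + 3])
        if x != "-":
            ia += 1
        if y != "-":
            ib += 1
    return "".join(cod_a), "".join(cod_b)


def find_duplicates(
    cds: Mapping[str, str],
    coverage_min: float = 0.7,
    similarity_min: float = 0.7,
) -> list[DuplicatePair]:
    """Test all unordered pairs against the 70/70 rule."""
    ids = sorted(cds)
    pairs = []
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            cov, sim, _ = align_pair(cds[a], cds[b])
            if cov > coverage_min and sim > similarity_min:
                pairs.append(DuplicatePair(a, b, cov, sim))
    return pairs


def classify_pair(
    gene_a: str,
    gene_b: str,
    gene_models: Mapping[str, GeneModel],
    max_intervening: int = 5,
    max_distance: int = 100_000,
) -> str:
    """Tandem iff same chromosome, ≤5 intervening genes and ≤100 kb apart.

    Distance is measured start-to-start; intervening genes are counted over
    all annotated genes via their chromosome rank.
    """
    try:
        ga, gb = gene_models[gene_a], gene_models[gene_b]
    except KeyError as exc:
        raise KeyError(f"gene {exc.args[0]!r} missing from annotation") from exc
    if ga.chromosome != gb.chromosome:
        return "segmental"
    intervening = abs(ga.rank_index - gb.rank_index) - 1
    distance = abs(ga.start - gb.start)
    if intervening <= max_intervening and distance <= max_distance:
        return "tandem"
    return "segmental"


# ---------------------------------------------------------------------------
# NG86 counting

@lru_cache(maxsize=None)
def _syn_fraction(codon: str) -> float:
    """Number of synonymous sites in a codon (0..3).

    Each position contributes (synonymous single-nucleotide changes)/3;
    changes to stop codons count as nonsynonymous.
    """
    aa = _CODON_TO_AA[codon]
    if aa == "*":
        raise ValueError(f"stop codon {codon!r} in coding sequence")
    total = 0.0
    for pos in range(3):
        syn = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if _CODON_TO_AA[alt] == aa:
                syn += 1
        total += syn / 3.0
    return total


def ng86_site_counts(cds: str) -> tuple[float, float]:
    """(N, S) site counts for one sequence; N + S = 3 × codon count."""
    cds = cds.upper()
    if len(cds) % 3:
        raise ValueError("CDS length not divisible by 3")
    s = sum(_syn_fraction(cds[i : i + 3]) for i in range(0, len(cds), 3))
    return len(cds) - s, s


@lru_cache(maxsize=None)
def _codon_diff_counts(c1: str, c2: str) -> tuple[float, float]:
    """(Nd, Sd) for one codon pair, averaged over minimal substitution paths.

    Paths with a stop-codon intermediate are excluded; if every path is
    blocked the average runs over all paths instead.
    """
    diffs = [i for i in range(3) if c1[i] != c2[i]]
    if not diffs:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diffs):
        cur = c1
        nd = sd = 0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if _CODON_TO_AA[nxt] == "*":
                blocked = True
            if _CODON_TO_AA[nxt] == _CODON_TO_AA[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        paths.append((nd, sd, blocked))
    usable = [(nd, sd) for nd, sd, blocked in paths if not blocked]
    if not usable:
        usable = [(nd, sd) for nd, sd, _ in paths]
    nd = sum(p[0] for p in usable) / len(usable)
    sd = sum(p[1] for p in usable) / len(usable)
    return nd, sd


def ng86_proportions(cds_a: str, cds_b: str) -> dict[str, float]:
    """Raw NG86 quantities for a gap-free codon-aligned pair.

    Returns N, S (site counts averaged over both sequences), Nd, Sd
    (path-averaged differences) and the proportions pN = Nd/N, pS = Sd/S.
    """
    cds_a, cds_b = cds_a.upper(), cds_b.upper()
    if len(cds_a) != len(cds_b):
        raise ValueError("codon-aligned sequences must have equal length")
    if len(cds_a) % 3:
        raise ValueError("CDS length not divisible by 3")
    na, sa = ng86_site_counts(cds_a)
    nb, sb = ng86_site_counts(cds_b)
    n_sites, s_sites = (na + nb) / 2.0, (sa + sb) / 2.0
    nd = sd = 0.0
    for i in range(0, len(cds_a), 3):
        d_n, d_s = _codon_diff_counts(cds_a[i : i + 3], cds_b[i : i + 3])
        nd += d_n
        sd += d_s
    return dict(
        N=n_sites,
        S=s_sites,
        Nd=nd,
        Sd=sd,
        pN=nd / n_sites if n_sites else 0.0,
        pS=sd / s_sites if s_sites else 0.0,
    )


def _jukes_cantor(p: float) -> float:
    if p >= 0.75:
        raise KaKsSaturationError(f"proportion {p:.4f} ≥ 3/4: saturated")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def kaks_ng86(cds_a: str, cds_b: str) -> tuple[float, float]:
    """(Ka, Ks) by NG86 with Jukes–Cantor correction.

    Input must be a gap-free codon-aligned pair without internal stops.
    Raises :class:`KaKsSaturationError` when either proportion is ≥ 3/4.
    """
    q = ng86_proportions(cds_a, cds_b)
    return _jukes_cantor(q["pN"]), _jukes_cantor(q["pS"])


def divergence_time(ks: float, rate: float = CLOCK_RATE) -> float:
    """Molecular-clock date in Mya: T = Ks / (2·rate) × 10⁻⁶."""
    if ks < 0:
        raise ValueError(f"negative Ks {ks}")
    return ks / (2.0 * rate) * 1e-6


# ---------------------------------------------------------------------------
# pipeline assembly

def duplication_report(
    cds: Mapping[str, str],
    gene_models: Mapping[str, GeneModel],
    coverage_min: float = 0.7,
    similarity_min: float = 0.7,
    rate: float = CLOCK_RATE,
) -> list[DuplicatePair]:
    """Find, classify and date every duplicate pair in a family CDS set.

    Saturated pairs (p ≥ 3/4) keep their classification and are flagged
    undated.
    """
    pairs = find_duplicates(cds, coverage_min, similarity_min)
    for pair in pairs:
        pair.dup_type = classify_pair(pair.gene_a, pair.gene_b, gene_models)
        ca, cb = codon_align_pair(cds[pair.gene_a], cds[pair.gene_b])
        try:
            pair.ka, pair.ks = kaks_ng86(ca, cb)
            pair.t_mya = divergence_time(pair.ks, rate=rate)
        except KaKsSaturationError:
            pair.saturated = True
    return pairs


def pairs_table(pairs: Sequence[DuplicatePair]) -> "pandas.DataFrame":
    """TSV-ready table: pair, Ka, Ks, Ka/Ks, Mya (1 dp), type."""
    import pandas as pd

    return pd.DataFrame(
        [
            dict(
                pair=f"{p.gene_a}/{p.gene_b}",
                coverage=round(p.coverage, 3),
                similarity=round(p.similarity, 3),
                ka=round(p.ka, 3) if not p.saturated else float("nan"),
                ks=round(p.ks, 3) if not p.saturated else float("nan"),
                kaks=round(p.kaks_ratio, 3) if not p.saturated else float("nan"),
                mya=round(p.t_mya, 1) if not p.saturated else float("nan"),
                dup_type=p.dup_type,
                saturated=p.saturated,
            )
            for p in pairs
        ]
    )
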