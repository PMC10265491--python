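"""Family-member identification by position-specific scoring.

A profile (log-odds PSSM) is built from a seed alignment of the family
domain; each candidate protein is scored by its best ungapped window, and
significance is calibrated empirically against a decoy proteome sampled
from the background composition.  The empirical E-value is

    E(s) = (1 + #decoys scoring ≥ s) / n_decoys × proteome size,

so the default retention rule "no decoy reaches the score" corresponds to
E ≤ proteome_size / n_decoys — the desk-scale analogue of a stringent
homology-search E-value cutoff.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}
_GAP_CHARS = {"-", "."}

__all__ = ["Profile", "DomainHit", "build_profile", "score_best_window", "scan_proteome"]


@dataclass
class Profile:
    """Per-column log₂-odds scores over the 20 amino acids."""

    scores: np.ndarray  # (columns, 20)
    background: np.ndarray  # (20,)
    pseudocount: float

    @property
    def n_columns(self) -> int:
        return self.scores.shape[0]

    def max_score(self) -> float:
        """Score of the best possible sequence (sum of column maxima)."""
        return float(self.scores.max(axis=1).sum())


@dataclass(frozen=True)
class DomainHit:
    protein_id: str
    start: int  # 1-based, inclusive, protein coordinates
    end: int
    bitscore: float
    evalue: float


def build_profile(
    alignment: Sequence[str] | Mapping[str, str],
    pseudocount: float = 1.0,
    background: Sequence[float] | None = None,
) -> Profile:
    """Build a PSSM from an aligned seed family.

    Columns with more than 50% gaps are dropped.  Scores are
    log₂((counts + pseudocount·bg) / (n + pseudocount) / bg) with a uniform
    background by default.
    """
    seqs = list(alignment.values()) if hasattr(alignment, "values") else list(alignment)
    if len(seqs) < 2:
        raise ValueError("seed alignment needs at least 2 sequences")
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("ragged alignment: sequences differ in length")
    bg = np.full(20, 1.0 / 20) if background is None else np.asarray(background, float)
    if not np.isclose(bg.sum(), 1.0):
        raise ValueError("background frequencies must sum to 1")
    cols = []
    for c in range(length):
        column = [s[c].upper() for s in seqs]
        n_gap = sum(ch in _GAP_CHARS for ch in column)
        if n_gap * 2 > len(column):
            continue
        counts = np.zeros(20)
        n = 0
        for ch in column:
            if ch in _GAP_CHARS:
                continue
            idx = _AA_INDEX.get(ch)
            if idx is None:
                continue  # ambiguous residue: contributes nothing
            counts[idx] += 1
            n += 1
        probs = (counts + pseudocount * bg) / (n + pseudocount)
        cols.append(np.log2(probs / bg))
    if not cols:
        raise ValueError("alignment has no usable columns")
    return Profile(scores=np.vstack(cols), background=bg, pseudocount=pseudocount)


def _encode(seq: str) -> np.ndarray:
    """Map residues to alphabet indices; unknown/ambiguous symbols to -1."""
    return np.array([_AA_INDEX.get(ch, -1) for ch in seq.upper()], dtype=np.int64)


def score_best_window(profile: Profile, seq: str) -> tuple[float, int]:
    """Best ungapped window score and its 1-based start position.

    Residues outside the 20-letter alphabet score the column minimum
    (ambiguity counts against the match).
    """
    codes = _encode(seq)
    w = profile.n_columns
    n_windows = len(codes) - w + 1
    if n_windows < 1:
        raise ValueError("sequence shorter than profile")
    col_min = profile.scores.min(axis=1)
    totals = np.zeros(n_windows)
    for c in range(w):
        col_scores = profile.scores[c]
        idx = codes[c : c + n_windows]
        vals = np.where(idx >= 0, col_scores[np.clip(idx, 0, 19)], col_min[c])
        totals += vals
    best = int(np.argmax(totals))
    return float(totals[best]), best + 1


def _sample_decoys(
    profile: Profile,
    lengths: np.ndarray,
    freqs: np.ndarray,
    n_decoys: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Best-window null scores from composition-matched decoy proteins."""
    aa = np.array(list(AA_ORDER))
    scores = np.empty(n_decoys)
    picks = rng.choice(len(lengths), size=n_decoys)
    for i in range(n_decoys):
        L = int(lengths[picks[i]])
        seq = "".join(rng.choice(aa, size=L, p=freqs))
        scores[i], _ = score_best_window(profile, seq)
    return np.sort(scores)


def _proteome_composition(proteins: Mapping[str, str]) -> np.ndarray:
    """Empirical amino-acid frequencies of a proteome (smoothed)."""
    counts = np.ones(20)  # add-one smoothing
    for seq in proteins.values():
        for ch in seq.upper():
            idx = _AA_INDEX.get(ch)
            if idx is not None:
                counts[idx] += 1
    return counts / counts.sum()


def scan_proteome(
    proteins: Mapping[str, str],
    profile: Profile,
    n_decoys: int = 1000,
    rng_seed: int = 0,
    max_evalue: float | None = None,
) -> list[DomainHit]:
    """Score every protein and keep hits at the decoy-calibrated threshold.

    With the default ``max_evalue`` (proteome_size / n_decoys) a hit is kept
    exactly when no decoy matches or beats its score.  Proteins shorter than
    the profile are skipped with a log entry.  Deterministic under
    ``rng_seed``.
    """
    if n_decoys < 100:
        raise ValueError("n_decoys must be ≥ 100 for a usable null")
    rng = np.random.default_rng(rng_seed)
    eligible = {pid: s for pid, s in proteins.items() if len(s) >= profile.n_columns}
    for pid in proteins:
        if pid not in eligible:
            logger.info("protein %s shorter than profile (%d cols); skipped",
                        pid, profile.n_columns)
    if not eligible:
        return []
    lengths = np.array([len(s) for s in eligible.values()])
    freqs = _proteome_composition(proteins)
    null = _sample_decoys(profile, lengths, freqs, n_decoys, rng)
    n_prot = len(proteins)
    if max_evalue is None:
        max_evalue = n_prot / n_decoys
    hits = []
    for pid, seq in eligible.items():
        s, start = score_best_window(profile, seq)
        n_ge = int(len(null) - np.searchsorted(null, s, side="left"))
        evalue = (n_ge + 1) / n_decoys * n_prot
        if evalue <= max_evalue:
            hits.append(
                DomainHit(pid, start, start + profile.n_columns - 1, s, evalue)
            )
    hits.sort(key=lambda h: (h.evalue, -h.bitscore, h.protein_id))
    return hits
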