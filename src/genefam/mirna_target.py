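"""miRNA target-site prediction by complementarity penalty scoring.

Each transcript window of miRNA length is paired antiparallel to the miRNA
(miRNA 5′→3′ against target 3′→5′) and scored with cumulative penalties:
Watson–Crick pair 0 (symbol ``:``), G:U wobble 0.5 (symbol ``.``), mismatch
1.0 (blank), with penalties doubled inside the seed-proximal core (miRNA
positions 2–13).  The total is the site's *expectation*; sites at or below
the cutoff (default 5.0) are reported, many-to-many.  Ungapped mode keeps
the exhaustive all-window oracle exact; a gapped variant with target bulges
(penalty 2.0 per bulged base) is available behind a flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

logger = logging.getLogger(__name__)

_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "U"), ("U", "G")}

DEFAULT_CUTOFF = 5.0
CORE_RANGE = (2, 13)  # 1-based miRNA positions with doubled penalties

__all__ = ["MirnaSite", "score_window", "scan_transcripts", "render_pairing"]


@dataclass(frozen=True)
class MirnaSite:
    """One predicted binding site on a transcript."""

    mirna_id: str
    target_id: str
    start: int  # 1-based on the transcript, inclusive
    end: int
    expectation: float
    pairing: str  # symbols aligned to the miRNA 5'→3'
    mirna_seq: str  # RNA, 5'→3'
    target_seq_3to5: str  # RNA, 3'→5', aligned to the miRNA


def _rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def score_window(
    mirna: str,
    target_3to5: str,
    mismatch_penalty: float = 1.0,
    wobble_penalty: float = 0.5,
    core: tuple[int, int] = CORE_RANGE,
    core_multiplier: float = 2.0,
) -> tuple[float, str]:
    """Score one ungapped miRNA/target pairing.

    ``target_3to5`` must already run 3′→5′ so that position i pairs with
    miRNA position i.  Returns (expectation, pairing string).
    """
    m, t = _rna(mirna), _rna(target_3to5)
    if len(m) != len(t):
        raise ValueError(
            f"length mismatch in ungapped mode: miRNA {len(m)} vs target {len(t)}"
        )
    total = 0.0
    symbols = []
    for i, (bm, bt) in enumerate(zip(m, t), start=1):
        if (bm, bt) in _WC:
            p, sym = 0.0, ":"
        elif (bm, bt) in _WOBBLE:
            p, sym = wobble_penalty, "."
        else:
            p, sym = mismatch_penalty, " "
        if core[0] <= i <= core[1]:
            p *= core_multiplier
        total += p
        symbols.append(sym)
    return total, "".join(symbols)


def scan_transcripts(
    mirnas: Mapping[str, str],
    transcripts: Mapping[str, str],
    cutoff: float = DEFAULT_CUTOFF,
    **score_kwargs,
) -> list[MirnaSite]:
    """Score every window of every transcript against every miRNA.

    Sites with expectation ≤ cutoff are reported; one miRNA may hit many
    transcripts and vice versa.  Transcripts shorter than a miRNA are
    skipped with a log entry.
    """
    if not mirnas or not transcripts:
        raise ValueError("miRNA and transcript sets must be non-empty")
    sites = []
    for mid, mseq in sorted(mirnas.items()):
        m = _rna(mseq)
        w = len(m)
        for tid, tseq in sorted(transcripts.items()):
            t = _rna(tseq)
            if len(t) < w:
                logger.info("transcript %s shorter than %s; skipped", tid, mid)
                continue
            for i in range(len(t) - w + 1):
                window = t[i : i + w]           # 5'→3'
                exp, pairing = score_window(m, window[::-1], **score_kwargs)
                if exp <= cutoff:
                    sites.append(
                        MirnaSite(
                            mirna_id=mid,
                            target_id=tid,
                            start=i + 1,
                            end=i + w,
                            expectation=exp,
                            pairing=pairing,
                            mirna_seq=m,
                            target_seq_3to5=window[::-1],
                        )
                    )
    sites.sort(key=lambda s: (s.expectation, s.mirna_id, s.target_id, s.start))
    return sites


def render_pairing(site: MirnaSite) -> str:
    """Three-line dot diagram: miRNA 5′→3′, pairing symbols, target 3′→5′."""
    head = f"{site.mirna_id} -> {site.target_id} [{site.start}-{site.end}] " \
           f"expectation={site.expectation:g}"
    return "\n".join(
        [
            head,
            f"miRNA  5' {site.mirna_seq} 3'",
            f"          {site.pairing}",
            f"target 3' {site.target_seq_3to5} 5'",
        ]
    )
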