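"""Forged genomes, expression tables and miRNA sets with known ground truth.

Every pipeline stage is testable without downloads: the forge plants a
protein family (members embed a seed domain; background genes are sampled
from a smoothed order-3 Markov model fitted to the seed consensus, so
decoys share its composition but not the domain), duplicate gene pairs with
controlled synonymous/nonsynonymous divergence, microsatellites, promoter
cis-elements and miRNA binding sites, and writes a truth table recording
the expected call for each planted feature.

Default conditions mirror the characterization study the pipeline is built
for at desk scale: 12 family members, one tandem duplication (2 intervening
genes, 37 kb start-to-start) plus two segmental duplications on different
chromosomes, pair divergences back-computed from the published Ks/Ka values
via the Jukes–Cantor inversion, qPCR with 3 biological replicates, and a
genome of 6 chromosomes × 400 kb.

All randomness flows through one seeded generator per forge call; fixed
seeds give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .duplication import ng86_proportions
from .io_formats import GeneModel, SeqCollection, reverse_complement, write_fasta, write_gff3
from .seqprops import _CODON_TO_AA, translate_cds

_AA = "ACDEFGHIKLMNPQRSTVWY"
_BASES = "ACGT"
_AA_TO_CODONS: dict[str, list[str]] = {}
for _codon, _aa in sorted(_CODON_TO_AA.items()):
    if _aa != "*":
        _AA_TO_CODONS.setdefault(_aa, []).append(_codon)

__all__ = [
    "DuplicationEvent",
    "SsrPlanting",
    "ElementPlanting",
    "MirnaPlanting",
    "ForgeConfig",
    "ForgeResult",
    "forge_genome",
    "mutate_codons",
    "simulate_ct",
    "simulate_fpkm",
    "simulate_subfamilies",
    "make_seed_alignment",
]


# ---------------------------------------------------------------------------
# planting descriptors

@dataclass(frozen=True)
class DuplicationEvent:
    """One planted duplicate pair with its target NG86 divergence."""

    dup_type: str  # "tandem" | "segmental"
    target_ps: float = 0.2
    target_pn: float = 0.02
    intervening_genes: int = 2
    genomic_gap: int = 40_000  # start-to-start, tandem only

    def __post_init__(self) -> None:
        if self.dup_type not in {"tandem", "segmental"}:
            raise ValueError(f"unknown duplication type {self.dup_type!r}")
        for p in (self.target_ps, self.target_pn):
            if not 0.0 <= p < 0.7:
                raise ValueError(f"target proportion {p} outside [0, 0.7)")
        if self.intervening_genes < 0 or self.genomic_gap < 0:
            raise ValueError("negative planting parameters")


@dataclass(frozen=True)
class SsrPlanting:
    motif: str
    repeats: int
    region: str  # upstream | genic | downstream
    position: int | None = None  # auto-spaced when None
    member_index: int | None = None  # index into the non-duplicate members

    def __post_init__(self) -> None:
        if self.region not in {"upstream", "genic", "downstream"}:
            raise ValueError(f"unknown SSR region {self.region!r}")
        if not 2 <= len(self.motif) <= 4 or self.repeats < 1:
            raise ValueError("SSR unit length must be 2-4 with ≥1 repeat")


@dataclass(frozen=True)
class ElementPlanting:
    element: str
    position: int  # 1-based within the 2-kb promoter
    member_index: int | None = None


@dataclass(frozen=True)
class MirnaPlanting:
    mirna_id: str
    n_mismatches: int = 0
    n_wobbles: int = 0
    member_index: int | None = None
    site_position: int | None = None  # 1-based on the transcript


_DEFAULT_EVENTS = (
    DuplicationEvent("tandem", 0.695, 0.0375, intervening_genes=2, genomic_gap=37_000),
    DuplicationEvent("segmental", 0.649, 0.0355),
    DuplicationEvent("segmental", 0.660, 0.0310),
)
_DEFAULT_SSRS = (
    SsrPlanting("AT", 6, "upstream"),
    SsrPlanting("AG", 7, "downstream"),
    SsrPlanting("AAG", 5, "genic"),
    SsrPlanting("ATC", 5, "upstream"),
    SsrPlanting("AAAT", 5, "downstream"),
)
_DEFAULT_ELEMENT_NAMES = (
    "ABRE", "ABRE", "ABRE", "CGTCA-motif", "TGACG-motif", "TCA-element",
    "P-box", "GARE-motif", "ARE", "ARE", "MBS", "LTR", "TC-rich repeats",
    "CAT-box", "O2-site", "circadian",
)
_DEFAULT_ELEMENTS = tuple(
    ElementPlanting(name, 120 + 60 * i) for i, name in enumerate(_DEFAULT_ELEMENT_NAMES)
)
_DEFAULT_MIRNAS = (
    MirnaPlanting("syn-miR01"),
    MirnaPlanting("syn-miR02"),
    MirnaPlanting("syn-miR03"),
    MirnaPlanting("syn-miR04", n_mismatches=1),
    MirnaPlanting("syn-miR05", n_wobbles=1),
)

# Concrete bases for IUPAC codes when writing a planted element.
_IUPAC_PICK = {
    "A": "A", "C": "C", "G": "G", "T": "T", "R": "A", "Y": "C", "S": "G",
    "W": "A", "K": "G", "M": "A", "B": "C", "D": "A", "H": "A", "V": "A",
    "N": "A",
}


@dataclass(frozen=True)
class ForgeConfig:
    """Study conditions for one forged genome."""

    n_chromosomes: int = 6
    chromosome_length: int = 400_000
    n_background_genes: int = 48
    n_members: int = 12
    domain_length: int = 60
    seed_consensus: str | None = None
    duplication_events: tuple[DuplicationEvent, ...] = _DEFAULT_EVENTS
    ssr_plantings: tuple[SsrPlanting, ...] = _DEFAULT_SSRS
    element_plantings: tuple[ElementPlanting, ...] = _DEFAULT_ELEMENTS
    mirna_plantings: tuple[MirnaPlanting, ...] = _DEFAULT_MIRNAS
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_chromosomes", "chromosome_length", "n_background_genes",
                     "n_members", "domain_length"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        needed = 2 * len(self.duplication_events) + 1
        if self.n_members < needed:
            raise ValueError(
                f"n_members={self.n_members} too small for "
                f"{len(self.duplication_events)} duplication events (need ≥ {needed})"
            )


# ---------------------------------------------------------------------------
# sequence generators

def _random_dna(rng: np.random.Generator, length: int) -> str:
    arr = rng.integers(0, 4, size=length)
    return np.frombuffer(b"ACGT", dtype=np.uint8)[arr].tobytes().decode()


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(_AA), size=length))


def _mutate_protein(protein: str, rate: float, rng: np.random.Generator) -> str:
    out = list(protein)
    for i in range(len(out)):
        if rng.random() < rate:
            choices = [a for a in _AA if a != out[i]]
            out[i] = choices[int(rng.integers(len(choices)))]
    return "".join(out)


class _MarkovProteinModel:
    """Order-3 Markov model over amino acids with add-one smoothing.

    Fitted to the seed consensus so that background (decoy) proteins share
    its composition; unseen contexts fall back to the consensus residue
    composition.
    """

    def __init__(self, consensus: str, order: int = 3):
        self.order = order
        counts: dict[str, np.ndarray] = {}
        comp = np.ones(len(_AA))
        idx = {a: i for i, a in enumerate(_AA)}
        for i, aa in enumerate(consensus):
            if aa in idx:
                comp[idx[aa]] += 1
            if i >= order:
                ctx = consensus[i - order : i]
                vec = counts.setdefault(ctx, np.ones(len(_AA)))
                if aa in idx:
                    vec[idx[aa]] += 1
        self.composition = comp / comp.sum()
        self.contexts = {c: v / v.sum() for c, v in counts.items()}

    def sample(self, rng: np.random.Generator, length: int) -> str:
        out: list[str] = []
        aas = list(_AA)
        for _ in range(length):
            ctx = "".join(out[-self.order :])
            probs = self.contexts.get(ctx, self.composition)
            out.append(str(rng.choice(aas, p=probs)))
        return "".join(out)


def _reverse_translate(protein: str, rng: np.random.Generator) -> str:
    return "".join(
        _AA_TO_CODONS[aa][int(rng.integers(len(_AA_TO_CODONS[aa])))] for aa in protein
    )


def make_seed_alignment(
    consensus: str, n_seqs: int = 8, divergence: float = 0.10,
    rng: np.random.Generator | None = None,
) -> dict[str, str]:
    """Ungapped seed alignment: variants of the consensus at ~10% divergence."""
    rng = rng or np.random.default_rng(0)
    return {
        f"seed{i + 1}": _mutate_protein(consensus, divergence, rng)
        for i in range(n_seqs)
    }


# ---------------------------------------------------------------------------
# controlled codon evolution

def _synonymous_alternatives(codon: str) -> list[str]:
    aa = _CODON_TO_AA[codon]
    out = []
    for pos in range(3):
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if _CODON_TO_AA[alt] == aa:
                out.append(alt)
    return out


def _nonsynonymous_alternatives(codon: str) -> list[str]:
    aa = _CODON_TO_AA[codon]
    out = []
    for pos in range(3):
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if _CODON_TO_AA[alt] not in ("*", aa):
                out.append(alt)
    return out


def mutate_codons(
    cds: str,
    target_ps: float,
    target_pn: float,
    rng_seed: int | np.random.Generator = 0,
    tol: float = 0.01,
) -> str:
    """Substitute codons until NG86 proportions vs the input hit the targets.

    Applies single-nucleotide synonymous/nonsynonymous changes (never
    creating a stop) until the observed per-site proportions measured by
    NG86 counting against the original sequence are within ±``tol`` of
    (target_ps, target_pn).  Raises when a target is unreachable (e.g. any
    pS > 0 on a sequence without synonymous degrees of freedom).
    """
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    cds = cds.upper()
    if len(cds) % 3:
        raise ValueError("CDS length not divisible by 3")
    for p in (target_ps, target_pn):
        if not 0.0 <= p < 0.7:
            raise ValueError(f"target proportion {p} outside [0, 0.7)")
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    stop_tail = ""
    if codons and _CODON_TO_AA[codons[-1]] == "*":
        stop_tail = codons.pop()
    translate_cds("".join(codons) + (stop_tail or "TAA"))  # validates stops
    if not codons:
        raise ValueError("empty coding region")
    original = "".join(codons)
    current = list(codons)
    n = len(codons)
    max_attempts = 400 * n + 4000
    attempts = 0
    while True:
        q = ng86_proportions(original, "".join(current))
        d_ps = target_ps - q["pS"]
        d_pn = target_pn - q["pN"]
        if abs(d_ps) <= tol and abs(d_pn) <= tol:
            break
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                f"unreachable targets (pS={target_ps}, pN={target_pn}): "
                f"stalled at pS={q['pS']:.4f}, pN={q['pN']:.4f}"
            )
        if d_ps > tol or d_pn > tol:
            synonymous = d_ps >= d_pn
            changed = False
            for _ in range(50):
                i = int(rng.integers(n))
                alts = (
                    _synonymous_alternatives(current[i])
                    if synonymous
                    else _nonsynonymous_alternatives(current[i])
                )
                if alts:
                    current[i] = alts[int(rng.integers(len(alts)))]
                    changed = True
                    break
            if not changed:
                raise ValueError(
                    f"unreachable targets: no "
                    f"{'synonymous' if synonymous else 'nonsynonymous'} "
                    "degrees of freedom"
                )
        else:
            # overshoot: revert one diverged codon toward the original
            diverged = [i for i in range(n) if current[i] != original[3 * i : 3 * i + 3]]
            if not diverged:
                break
            i = diverged[int(rng.integers(len(diverged)))]
            current[i] = original[3 * i : 3 * i + 3]
    return "".join(current) + stop_tail


# ---------------------------------------------------------------------------
# genome forging

@dataclass
class _Gene:
    gene_id: str
    cds: str  # coding strand, incl. terminal stop
    genomic: str  # genomic-strand sequence of the gene body
    rel_segments: tuple[tuple[int, int], ...]  # CDS intervals within the gene body
    strand: str
    is_member: bool
    chromosome: int = -1
    start: int = 0  # genomic, 1-based

    @property
    def span(self) -> int:
        return len(self.genomic)

    @property
    def end(self) -> int:
        return self.start + self.span - 1


@dataclass
class ForgeResult:
    """In-memory forged dataset plus its ground truth."""

    genome: SeqCollection
    gene_models: list[GeneModel]
    cds: SeqCollection
    proteins: SeqCollection
    truth: pd.DataFrame
    seed_alignment: dict[str, str]
    mirnas: dict[str, str]
    config: ForgeConfig

    @property
    def member_ids(self) -> list[str]:
        return sorted(
            self.truth[self.truth["feature"] == "family_member"]["id"].tolist()
        )

    def models_by_id(self) -> dict[str, GeneModel]:
        return {g.gene_id: g for g in self.gene_models}

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fasta",
            "gff3": outdir / "genes.gff3",
            "cds": outdir / "cds.fasta",
            "proteins": outdir / "proteins.fasta",
            "seed_alignment": outdir / "seed_alignment.fasta",
            "mirnas": outdir / "mirnas.fasta",
            "truth": outdir / "truth.tsv",
        }
        write_fasta(self.genome, paths["genome"])
        write_gff3(self.gene_models, paths["gff3"])
        write_fasta(self.cds, paths["cds"])
        write_fasta(self.proteins, paths["proteins"])
        write_fasta(self.seed_alignment, paths["seed_alignment"])
        write_fasta(self.mirnas, paths["mirnas"])
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths


def _member_protein(
    consensus: str, bg_model: _MarkovProteinModel, rng: np.random.Generator,
    domain_divergence: float = 0.12,
) -> str:
    n_flank = int(rng.integers(100, 200))
    c_flank = int(rng.integers(100, 200))
    domain = _mutate_protein(consensus, domain_divergence, rng)
    return "M" + bg_model.sample(rng, n_flank) + domain + bg_model.sample(rng, c_flank)


def _write_block(arr: bytearray, start0: int, seq: str) -> None:
    arr[start0 : start0 + len(seq)] = seq.encode()


def _guard_base(avoid: str) -> str:
    for b in _BASES:
        if b != avoid.upper():
            return b
    raise AssertionError


def forge_genome(config: ForgeConfig = ForgeConfig(), outdir: str | Path | None = None) -> ForgeResult:
    """Forge a genome + annotation + proteome with a planted truth table.

    Deterministic under ``config.rng_seed``; writes the standard files when
    ``outdir`` is given.
    """
    rng = np.random.default_rng(config.rng_seed)
    consensus = config.seed_consensus or _random_protein(rng, config.domain_length)
    seed_aln = make_seed_alignment(consensus, rng=rng)
    bg_model = _MarkovProteinModel(consensus)

    events = config.duplication_events
    member_ids = [f"FAM{i + 1:02d}" for i in range(config.n_members)]
    event_pairs = [
        (member_ids[2 * k], member_ids[2 * k + 1]) for k in range(len(events))
    ]
    free_ids = member_ids[2 * len(events) :]

    # --- member coding sequences
    gene_cds: dict[str, str] = {}
    truth_rows: list[dict] = []
    for ev, (gid_a, gid_b) in zip(events, event_pairs):
        prot = _member_protein(consensus, bg_model, rng)
        cds_a = _reverse_translate(prot, rng) + "TAA"
        cds_b = mutate_codons(
            cds_a, ev.target_ps, ev.target_pn, rng_seed=int(rng.integers(2**31))
        )
        gene_cds[gid_a] = cds_a
        gene_cds[gid_b] = cds_b
        truth_rows.append(
            dict(
                feature="duplicate_pair", id=f"{gid_a}|{gid_b}", chromosome="",
                start=0, end=0, klass=ev.dup_type,
                detail=f"target_ps={ev.target_ps};target_pn={ev.target_pn}",
            )
        )
    # Free members must not spuriously pass the duplicate rule against any
    # other member (they share only the domain); borderline cases are
    # regenerated so the planted pair list is the complete truth.
    from .duplication import align_pair

    def _passes_7070(cds_a: str, cds_b: str) -> bool:
        cov, sim, _ = align_pair(cds_a, cds_b)
        return cov > 0.68 and sim > 0.68  # small margin below the 0.7 rule

    for gid in free_ids:
        for _ in range(20):
            prot = _member_protein(consensus, bg_model, rng)
            cand = _reverse_translate(prot, rng) + "TAA"
            if not any(_passes_7070(cand, other) for other in gene_cds.values()):
                break
        else:
            raise ValueError(f"could not forge a distinct free member for {gid}")
        gene_cds[gid] = cand

    bg_ids = [f"BG{i + 1:03d}" for i in range(config.n_background_genes)]
    for gid in bg_ids:
        prot = "M" + bg_model.sample(rng, int(rng.integers(150, 300)))
        gene_cds[gid] = _reverse_translate(prot, rng) + "TAA"

    # --- planting assignment (deterministic round-robin)
    ssr_by_member: dict[str, list[tuple[int, SsrPlanting]]] = {}
    for i, plant in enumerate(config.ssr_plantings):
        gid = free_ids[(plant.member_index if plant.member_index is not None else i) % len(free_ids)]
        ssr_by_member.setdefault(gid, []).append((i, plant))
    elem_by_member: dict[str, list[tuple[int, ElementPlanting]]] = {}
    for i, eplant in enumerate(config.element_plantings):
        gid = member_ids[(eplant.member_index if eplant.member_index is not None else i) % len(member_ids)]
        elem_by_member.setdefault(gid, []).append((i, eplant))

    # --- gene bodies (introns inserted for genic SSR plantings)
    genes: dict[str, _Gene] = {}
    genic_ssr_info: dict[str, list[tuple[SsrPlanting, int]]] = {}  # gid -> (plant, offset in gene body, 0-based)
    for gid, cds in gene_cds.items():
        is_member = gid.startswith("FAM")
        genic = [p for _, p in ssr_by_member.get(gid, []) if p.region == "genic"]
        if genic:
            half = (len(cds) // 3 // 2) * 3
            intron_core = _random_dna(rng, 496)
            intron = "GT" + intron_core + "AG"
            offsets = []
            arr = bytearray(intron.encode())
            for j, plant in enumerate(genic):
                block = plant.motif * plant.repeats
                off = 80 + j * (len(block) + 60)
                if off + len(block) + 2 > len(intron) - 2:
                    raise ValueError(
                        f"planting collision: genic SSRs overflow the intron of {gid}"
                    )
                _write_block(arr, off, block)
                arr[off - 1] = ord(_guard_base(plant.motif[-1]))
                arr[off + len(block)] = ord(_guard_base(plant.motif[0]))
                offsets.append(off)
            intron = arr.decode()
            body = cds[:half] + intron + cds[half:]
            segs = ((1, half), (half + len(intron) + 1, len(body)))
            genes[gid] = _Gene(gid, cds, body, segs, "+", is_member)
            genic_ssr_info[gid] = [
                (plant, half + off) for plant, off in zip(genic, offsets)
            ]
        else:
            strand = "+"
            body = cds
            if not is_member and rng.random() < 0.4:
                strand = "-"
                body = reverse_complement(cds)
            genes[gid] = _Gene(gid, cds, body, ((1, len(body)),), strand, is_member)

    # --- chromosome assignment
    n_chrom = config.n_chromosomes
    if n_chrom < 2 and any(ev.dup_type == "segmental" for ev in events):
        raise ValueError("segmental events need ≥ 2 chromosomes")
    chrom_blocks: list[list[list[str]]] = [[] for _ in range(n_chrom)]
    bg_pool = list(bg_ids)
    ci = 0
    for ev, (gid_a, gid_b) in zip(events, event_pairs):
        if ev.dup_type == "tandem":
            intervening = [bg_pool.pop(0) for _ in range(ev.intervening_genes)]
            chrom_blocks[ci % n_chrom].append(["TANDEM", gid_a, gid_b, *intervening])
            ci += 1
        else:
            chrom_blocks[ci % n_chrom].append([gid_a])
            chrom_blocks[(ci + 1) % n_chrom].append([gid_b])
            ci += 2
    for i, gid in enumerate(free_ids + bg_pool):
        chrom_blocks[(ci + i) % n_chrom].append([gid])

    # --- placement
    chrom_names = [f"chr{i + 1}" for i in range(n_chrom)]
    collisions: list[str] = []
    for c in range(n_chrom):
        cursor = 3000
        for block in chrom_blocks[c]:
            if block[0] == "TANDEM":
                gid_a, gid_b, *inter = block[1:]
                ev = events[[p for p, pair in enumerate(event_pairs)
                             if pair == (gid_a, gid_b)][0]]
                ga, gb = genes[gid_a], genes[gid_b]
                ga.chromosome, ga.start = c, cursor
                gb.chromosome, gb.start = c, cursor + ev.genomic_gap
                inner_start = cursor + ga.span + 2500
                inner_end = cursor + ev.genomic_gap - 2500
                pos = inner_start
                for gid in inter:
                    g = genes[gid]
                    if pos + g.span > inner_end:
                        collisions.append(
                            f"tandem block {gid_a}/{gid_b}: intervening gene {gid} "
                            f"does not fit in gap {ev.genomic_gap}"
                        )
                        break
                    g.chromosome, g.start = c, pos
                    pos += g.span + 2600
                cursor = gb.start + gb.span
            else:
                g = genes[block[0]]
                g.chromosome, g.start = c, cursor
                cursor = g.start + g.span
            cursor += 5000 + int(rng.integers(0, 2000))
        if cursor + 2500 > config.chromosome_length:
            collisions.append(
                f"{chrom_names[c]}: layout needs {cursor + 2500} bp, "
                f"chromosome is {config.chromosome_length} bp"
            )
    if collisions:
        raise ValueError("planting collisions:\n" + "\n".join(collisions))

    # --- assemble chromosomes
    arrays = [
        bytearray(_random_dna(rng, config.chromosome_length).encode())
        for _ in range(n_chrom)
    ]
    placed = sorted(genes.values(), key=lambda g: (g.chromosome, g.start))
    for g in placed:
        _write_block(arrays[g.chromosome], g.start - 1, g.genomic)

    occupied: dict[int, list[tuple[int, int, str]]] = {c: [] for c in range(n_chrom)}
    for g in placed:
        occupied[g.chromosome].append((g.start, g.end, g.gene_id))

    def _claim(c: int, s: int, e: int, what: str) -> None:
        for s0, e0, w0 in occupied[c]:
            if not (e < s0 or s > e0):
                collisions.append(f"{what} at {chrom_names[c]}:{s}-{e} overlaps {w0}")
        occupied[c].append((s, e, what))

    # --- flank plantings: promoter elements (consensus from the packaged dictionary)
    from .cisreg_scan import load_dictionary

    dictionary = {d.name: d for d in load_dictionary()}
    for gid, plants in sorted(elem_by_member.items()):
        g = genes[gid]
        for _, eplant in plants:
            if eplant.element not in dictionary:
                raise ValueError(f"unknown element {eplant.element!r} in plantings")
            motif = "".join(_IUPAC_PICK[ch] for ch in dictionary[eplant.element].consensus)
            p = eplant.position
            if not 1 <= p <= 2000 - len(motif) + 1:
                raise ValueError(
                    f"element position {p} outside the 2-kb promoter of {gid}"
                )
            if g.strand == "+":
                gp = g.start - 2000 + (p - 1)  # 1-based genomic
                _claim(g.chromosome, gp, gp + len(motif) - 1, f"element:{eplant.element}:{gid}")
                _write_block(arrays[g.chromosome], gp - 1, motif)
            else:
                gp = g.end + 2000 - (p - 1) - len(motif) + 1
                _claim(g.chromosome, gp, gp + len(motif) - 1, f"element:{eplant.element}:{gid}")
                _write_block(arrays[g.chromosome], gp - 1, reverse_complement(motif))
            truth_rows.append(
                dict(
                    feature="cis_element", id=gid, chromosome=chrom_names[g.chromosome],
                    start=p, end=p + len(motif) - 1, klass=eplant.element,
                    detail="strand=+",
                )
            )

    # --- flank plantings: upstream/downstream SSRs (members are '+' strand)
    up_i = down_i = 0
    for gid in sorted(ssr_by_member):
        g = genes[gid]
        for _, plant in ssr_by_member[gid]:
            if plant.region == "genic":
                continue
            block = plant.motif * plant.repeats
            if plant.region == "upstream":
                p = plant.position if plant.position is not None else 1500 + 45 * up_i
                up_i += 1
                gp = g.start - 2000 + (p - 1)
                wpos = p
            else:
                q = plant.position if plant.position is not None else 300 + 45 * down_i
                down_i += 1
                gp = g.end + q
                wpos = 2000 + g.span + q
            _claim(g.chromosome, gp - 1, gp + len(block), f"ssr:{plant.motif}:{gid}")
            arr = arrays[g.chromosome]
            _write_block(arr, gp - 1, block)
            arr[gp - 2] = ord(_guard_base(plant.motif[-1]))
            arr[gp - 1 + len(block)] = ord(_guard_base(plant.motif[0]))
            truth_rows.append(
                dict(
                    feature="ssr", id=gid, chromosome=chrom_names[g.chromosome],
                    start=wpos, end=wpos + len(block) - 1, klass=plant.region,
                    detail=f"motif={plant.motif};repeats={plant.repeats}",
                )
            )
    for gid, infos in sorted(genic_ssr_info.items()):
        g = genes[gid]
        for plant, off0 in infos:  # off0: 0-based offset within the gene body
            wpos = 2000 + off0 + 1
            truth_rows.append(
                dict(
                    feature="ssr", id=gid, chromosome=chrom_names[g.chromosome],
                    start=wpos, end=wpos + len(plant.motif) * plant.repeats - 1,
                    klass="genic",
                    detail=f"motif={plant.motif};repeats={plant.repeats}",
                )
            )
    if collisions:
        raise ValueError("planting collisions:\n" + "\n".join(collisions))

    # --- miRNA plantings (derived from transcripts; no genome edits)
    mirnas: dict[str, str] = {}
    for i, mplant in enumerate(config.mirna_plantings):
        gid = free_ids[(mplant.member_index if mplant.member_index is not None else i) % len(free_ids)]
        cds = gene_cds[gid]
        pos = mplant.site_position if mplant.site_position is not None else 30 + 30 * i
        length = 21
        if pos + length - 1 > len(cds):
            raise ValueError(f"miRNA site for {mplant.mirna_id} outside transcript {gid}")
        window = cds[pos - 1 : pos + length - 1]
        mirna = list(reverse_complement(window).replace("T", "U"))
        target_3to5 = window[::-1].replace("T", "U")
        expectation = 0.0
        mutable = [p for p in range(14, length + 1)]  # non-core, away from pos 1
        for k in range(mplant.n_mismatches):
            p = mutable[k]
            t = target_3to5[p - 1]
            for b in "ACGU":
                if b != mirna[p - 1] and (b, t) not in {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}:
                    mirna[p - 1] = b
                    break
            expectation += 1.0
        if mplant.n_wobbles:
            done = 0
            for p in mutable[mplant.n_mismatches :]:
                t = target_3to5[p - 1]
                if t == "U" and mirna[p - 1] == "A":
                    mirna[p - 1] = "G"
                elif t == "G" and mirna[p - 1] == "C":
                    mirna[p - 1] = "U"
                else:
                    continue
                expectation += 0.5
                done += 1
                if done == mplant.n_wobbles:
                    break
            if done < mplant.n_wobbles:
                raise ValueError(
                    f"no wobble-compatible position for {mplant.mirna_id} in {gid}"
                )
        mirnas[mplant.mirna_id] = "".join(mirna)
        truth_rows.append(
            dict(
                feature="mirna_site", id=f"{mplant.mirna_id}|{gid}", chromosome="",
                start=pos, end=pos + length - 1, klass="site",
                detail=f"expectation={expectation}",
            )
        )

    # --- outputs
    genome = SeqCollection(
        {chrom_names[c]: arrays[c].decode() for c in range(n_chrom)}, alphabet="dna"
    )
    models: list[GeneModel] = []
    per_chrom: dict[int, list[_Gene]] = {}
    for g in placed:
        per_chrom.setdefault(g.chromosome, []).append(g)
    for c, glist in per_chrom.items():
        for rank, g in enumerate(sorted(glist, key=lambda x: x.start)):
            models.append(
                GeneModel(
                    gene_id=g.gene_id,
                    chromosome=chrom_names[c],
                    strand=g.strand,
                    start=g.start,
                    end=g.end,
                    cds_segments=tuple(
                        (g.start + s - 1, g.start + e - 1) for s, e in g.rel_segments
                    ),
                    rank_index=rank,
                )
            )
    models.sort(key=lambda m: (m.chromosome, m.start))
    for gid in member_ids:
        g = genes[gid]
        truth_rows.append(
            dict(
                feature="family_member", id=gid, chromosome=chrom_names[g.chromosome],
                start=g.start, end=g.end, klass="member", detail="",
            )
        )
    truth = pd.DataFrame(
        truth_rows, columns=["feature", "id", "chromosome", "start", "end", "klass", "detail"]
    ).sort_values(["feature", "id", "start"], kind="stable").reset_index(drop=True)
    cds_coll = SeqCollection({gid: gene_cds[gid] for gid in sorted(gene_cds)}, "dna")
    proteins = SeqCollection(
        {gid: translate_cds(seq) for gid, seq in cds_coll.items()}, "protein"
    )
    result = ForgeResult(
        genome=genome,
        gene_models=models,
        cds=cds_coll,
        proteins=proteins,
        truth=truth,
        seed_alignment=seed_aln,
        mirnas=mirnas,
        config=config,
    )
    if outdir is not None:
        result.write(outdir)
    return result


# ---------------------------------------------------------------------------
# expression simulators

def simulate_ct(
    samples: Sequence[str],
    genes: Sequence[str],
    true_log2_fc: Mapping[str, Mapping[str, float]] | None,
    ref_genes: Sequence[str],
    sd: float = 0.2,
    n_reps: int = 3,
    rng_seed: int = 0,
    baseline_ct: float = 24.0,
    ref_baseline_ct: float = 20.0,
) -> pd.DataFrame:
    """Simulate a tidy qPCR Ct table with known fold changes.

    ``true_log2_fc[sample][gene]`` shifts the target's Ct by −fc cycles
    (so downstream RQ = 2^fc relative to a sample with fc 0); reference
    genes are flat in expectation across samples.  Gaussian noise with
    standard deviation ``sd`` cycles; requires ≥ 2 replicates.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be ≥ 2 (the downstream t-test needs replicates)")
    if sd < 0:
        raise ValueError("negative sd")
    rng = np.random.default_rng(rng_seed)
    fc = true_log2_fc or {}
    rows = []
    for sample in samples:
        for gene in list(genes) + list(ref_genes):
            for rep in range(1, n_reps + 1):
                if gene in ref_genes:
                    ct = ref_baseline_ct
                else:
                    ct = baseline_ct - float(fc.get(sample, {}).get(gene, 0.0))
                noise = float(rng.normal(0.0, sd)) if sd > 0 else 0.0
                rows.append(
                    dict(sample=sample, gene=gene, replicate=rep, ct=ct + noise)
                )
    return pd.DataFrame(rows)


def simulate_fpkm(
    genes: Sequence[str],
    conditions: Sequence[str],
    true_log2_fc: Mapping[str, Mapping[str, float]] | None = None,
    dispersion: float = 0.2,
    rng_seed: int = 0,
    base_mean: float = 20.0,
    zero_genes: Sequence[str] = (),
) -> pd.DataFrame:
    """Simulate a genes × conditions FPKM matrix with log-normal noise.

    Condition means are ``base_mean × 2^fc``; ``zero_genes`` stay at 0 in
    every condition (they map to the heatmap floor downstream).
    """
    if dispersion < 0:
        raise ValueError("negative dispersion")
    rng = np.random.default_rng(rng_seed)
    fc = true_log2_fc or {}
    data = {}
    for cond in conditions:
        col = []
        for gene in genes:
            if gene in set(zero_genes):
                col.append(0.0)
                continue
            mean = base_mean * 2.0 ** float(fc.get(cond, {}).get(gene, 0.0))
            noise = float(rng.normal(0.0, dispersion)) if dispersion > 0 else 0.0
            col.append(mean * float(np.exp(noise)))
        data[cond] = col
    return pd.DataFrame(data, index=list(genes))


def simulate_subfamilies(
    labels: Sequence[str] = ("C", "ER", "M", "Chl", "N"),
    n_refs: int = 2,
    n_queries: int = 2,
    length: int = 80,
    within_divergence: float = 0.05,
    rng_seed: int = 0,
) -> tuple[dict[str, str], dict[str, str], dict[str, str]]:
    """Aligned protein family evolved from one ancestor per subfamily.

    Returns (aligned sequences, reference labels, query truth labels).
    Members of a subfamily sit ``within_divergence`` from their ancestor;
    ancestors are independent, so between-subfamily distances are large.
    """
    rng = np.random.default_rng(rng_seed)
    aligned: dict[str, str] = {}
    references: dict[str, str] = {}
    queries: dict[str, str] = {}
    for label in labels:
        ancestor = _random_protein(rng, length)
        for i in range(n_refs):
            name = f"{label}_ref{i + 1}"
            aligned[name] = _mutate_protein(ancestor, within_divergence, rng)
            references[name] = label
        for i in range(n_queries):
            name = f"{label}_query{i + 1}"
            aligned[name] = _mutate_protein(ancestor, within_divergence, rng)
            queries[name] = label
    return aligned, references, queries
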