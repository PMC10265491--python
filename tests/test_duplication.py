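"""Duplicate detection (70/70 rule), tandem/segmental calls, NG86 and dating."""

import itertools
import math

import pytest

from conftest import random_cds
from genefam.duplication import (
    KaKsSaturationError,
    align_pair,
    classify_pair,
    codon_align_pair,
    divergence_time,
    find_duplicates,
    kaks_ng86,
    ng86_proportions,
    ng86_site_counts,
)
from genefam.io_formats import GeneModel
from genefam.seqprops import _CODON_TO_AA
from genefam.synthetic_data import mutate_codons

SENSE_CODONS = sorted(c for c, aa in _CODON_TO_AA.items() if aa != "*")


# --- independent oracles -----------------------------------------------------

def _gotoh_score(a, b, match=2, mismatch=-1, open_=-4, extend=-1):
    """Affine-gap global alignment score by explicit 3-state DP."""
    NEG = float("-inf")
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consume a)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consume b)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = open_ + extend * (i - 1)
    for j in range(1, m + 1):
        Y[0][j] = open_ + extend * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + open_, X[i - 1][j] + extend, Y[i - 1][j] + open_)
            Y[i][j] = max(M[i][j - 1] + open_, Y[i][j - 1] + extend, X[i][j - 1] + open_)
    return max(M[n][m], X[n][m], Y[n][m])


def _oracle_codon_pair(c1, c2):
    """(Nd, Sd) by brute-force enumeration of substitution orderings."""
    diffs = [i for i in range(3) if c1[i] != c2[i]]
    results = []
    for order in itertools.permutations(diffs):
        cur, nd, sd, ok = c1, 0, 0, True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if _CODON_TO_AA[nxt] == "*":
                ok = False
            if _CODON_TO_AA[nxt] == _CODON_TO_AA[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        results.append((nd, sd, ok))
    usable = [(nd, sd) for nd, sd, ok in results if ok] or [
        (nd, sd) for nd, sd, _ in results
    ]
    return (
        sum(r[0] for r in usable) / len(usable),
        sum(r[1] for r in usable) / len(usable),
    )


def oracle_proportions(a, b):
    """Independent NG86 pS/pN on a codon-aligned pair."""
    def sites(seq):
        s = 0.0
        for i in range(0, len(seq), 3):
            cod = seq[i : i + 3]
            for pos in range(3):
                for base in "ACGT":
                    if base != cod[pos]:
                        alt = cod[:pos] + base + cod[pos + 1 :]
                        if _CODON_TO_AA[alt] == _CODON_TO_AA[cod]:
                            s += 1 / 3
        return s

    S = (sites(a) + sites(b)) / 2
    N = len(a) - S
    nd = sd = 0.0
    for i in range(0, len(a), 3):
        d_n, d_s = _oracle_codon_pair(a[i : i + 3], b[i : i + 3])
        nd, sd = nd + d_n, sd + d_s
    return nd / N if N else 0.0, sd / S if S else 0.0


# --- alignment ---------------------------------------------------------------

class TestAlignPair:
    def test_identical_sequences(self):
        cov, sim, _ = align_pair("ATGATGATG", "ATGATGATG")
        assert cov == 1.0 and sim == 1.0

    def test_half_sequence_fails_coverage(self):
        a = "ATGGCTTGCAAAGGGTTTCCC"
        cov, sim, _ = align_pair(a, a[: len(a) // 2])
        assert cov == pytest.approx(0.5, abs=0.05)
        assert cov <= 0.7

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            align_pair("", "ATG")

    def test_matches_affine_dp_oracle_on_short_pairs(self, rng):
        from Bio import Align

        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score, aligner.mismatch_score = 2, -1
        aligner.open_gap_score, aligner.extend_gap_score = -4, -1
        for _ in range(40):
            a = "".join("ACGT"[int(rng.integers(4))] for _ in range(int(rng.integers(3, 21))))
            b = "".join("ACGT"[int(rng.integers(4))] for _ in range(int(rng.integers(3, 21))))
            assert aligner.score(a, b) == pytest.approx(_gotoh_score(a, b))


# --- NG86 --------------------------------------------------------------------

class TestNg86:
    def test_identical_sequences_zero(self):
        assert kaks_ng86("ATGGCT", "ATGGCT") == (0.0, 0.0)

    def test_fourfold_site_hand_count(self):
        # one synonymous change among four Gly codons: S=4, Sd=1, pS=1/4
        q = ng86_proportions("GGAGGAGGAGGA", "GGGGGAGGAGGA")
        assert (q["S"], q["Sd"], q["pS"], q["pN"]) == (4.0, 1.0, 0.25, 0.0)
        ka, ks = kaks_ng86("GGAGGAGGAGGA", "GGGGGAGGAGGA")
        assert ka == 0.0
        assert ks == pytest.approx(-0.75 * math.log(1 - 0.25 * 4 / 3), abs=1e-12)

    def test_symmetry(self, rng):
        a = random_cds(rng, 30, with_stop=False)
        b = mutate_codons(a, 0.1, 0.05, rng_seed=3)
        assert kaks_ng86(a, b) == kaks_ng86(b, a)

    def test_sites_sum_to_three_per_codon(self, rng):
        for _ in range(10):
            cds = random_cds(rng, int(rng.integers(5, 40)), with_stop=False)
            n, s = ng86_site_counts(cds)
            assert n + s == pytest.approx(len(cds))

    def test_matches_path_enumeration_oracle(self, rng):
        for _ in range(60):
            n_cod = int(rng.integers(2, 11))
            a = "".join(SENSE_CODONS[int(rng.integers(61))] for _ in range(n_cod))
            b = list(a)
            for _ in range(int(rng.integers(1, 4))):  # ≤3 differing positions
                pos = int(rng.integers(len(a)))
                cand = "ACGT"[int(rng.integers(4))]
                trial = b.copy()
                trial[pos] = cand
                cod_i = pos // 3
                if _CODON_TO_AA["".join(trial[3 * cod_i : 3 * cod_i + 3])] != "*":
                    b = trial
            b = "".join(b)
            q = ng86_proportions(a, b)
            pn_o, ps_o = oracle_proportions(a, b)
            assert q["pN"] == pytest.approx(pn_o, abs=1e-12)
            assert q["pS"] == pytest.approx(ps_o, abs=1e-12)

    def test_saturation_raises(self):
        # every codon differs at its fourfold site: pS = 1 ≥ 3/4
        a, b = "GGA" * 10, "GGG" * 10
        with pytest.raises(KaKsSaturationError):
            kaks_ng86(a, b)

    def test_codon_alignment_drops_gapped_codons(self):
        a = "ATGGCTAAGGGG"          # M A K G
        b = "ATGAAGGGG"             # M K G   (A deleted)
        ca, cb = codon_align_pair(a, b)
        assert len(ca) == len(cb) == 9
        assert ca == "ATGAAGGGG"


# --- classification and dating ----------------------------------------------

def _gm(gid, chrom, start, rank):
    return GeneModel(gid, chrom, "+", start, start + 999, ((start, start + 999),), rank)


class TestClassifyPair:
    def test_tandem_from_published_coordinates(self):
        # same chromosome, 2 intervening genes, ~37 kb start-to-start
        models = {
            "g3": _gm("g3", "chr9", 34_779_571, 10),
            "g5": _gm("g5", "chr9", 34_816_934, 13),
        }
        assert classify_pair("g3", "g5", models) == "tandem"

    def test_different_chromosomes_are_segmental(self):
        models = {"a": _gm("a", "chr4", 100, 0), "b": _gm("b", "chr9", 100, 0)}
        assert classify_pair("a", "b", models) == "segmental"

    def test_six_intervening_genes_are_segmental(self):
        models = {"a": _gm("a", "chr1", 1000, 0), "b": _gm("b", "chr1", 50_000, 7)}
        assert classify_pair("a", "b", models) == "segmental"

    def test_over_100kb_is_segmental(self):
        models = {"a": _gm("a", "chr1", 1000, 0), "b": _gm("b", "chr1", 150_000, 2)}
        assert classify_pair("a", "b", models) == "segmental"

    def test_order_independent(self):
        models = {"a": _gm("a", "chr1", 1000, 0), "b": _gm("b", "chr1", 20_000, 2)}
        assert classify_pair("a", "b", models) == classify_pair("b", "a", models)

    def test_missing_gene_raises(self):
        with pytest.raises(KeyError):
            classify_pair("a", "zz", {"a": _gm("a", "chr1", 1, 0)})


class TestDivergenceTime:
    @pytest.mark.parametrize("ks,mya", [(1.505, 123.4), (1.996, 163.6), (0.0, 0.0)])
    def test_printed_dates(self, ks, mya):
        assert round(divergence_time(ks), 1) == mya

    def test_negative_ks_rejected(self):
        with pytest.raises(ValueError):
            divergence_time(-0.1)

    def test_linear_in_ks(self):
        assert divergence_time(2.0) == pytest.approx(2 * divergence_time(1.0))


# --- pipeline-level ----------------------------------------------------------

class TestFindDuplicates:
    def test_single_gene_family_is_empty(self):
        assert find_duplicates({"a": "ATGGCTTAA"}) == []

    def test_forged_paralogs_found_and_unrelated_rejected(self, rng):
        ancestor = random_cds(rng, 150, with_stop=False)
        fam = {
            "p1": ancestor,
            "p2": mutate_codons(ancestor, 0.25, 0.02, rng_seed=1),
            "p3": mutate_codons(ancestor, 0.30, 0.03, rng_seed=2),
            "bg": random_cds(rng, 150, with_stop=False),
        }
        pairs = {(p.gene_a, p.gene_b) for p in find_duplicates(fam)}
        assert pairs == {("p1", "p2"), ("p1", "p3"), ("p2", "p3")}


class TestMutateCodons:
    def test_zero_targets_identity(self, rng):
        cds = random_cds(rng, 50)
        assert mutate_codons(cds, 0.0, 0.0, rng_seed=9) == cds

    def test_recovery_at_spec_point(self, rng):
        cds = random_cds(rng, 300, with_stop=False)
        out = mutate_codons(cds, 0.2, 0.02, rng_seed=7)
        q = ng86_proportions(cds, out)
        assert q["pS"] == pytest.approx(0.2, abs=0.01)
        assert q["pN"] == pytest.approx(0.02, abs=0.01)
        pn_o, ps_o = oracle_proportions(cds, out)
        assert ps_o == pytest.approx(0.2, abs=0.01)

    def test_atg_only_unreachable(self):
        with pytest.raises(ValueError, match="unreachable"):
            mutate_codons("ATG", 0.2, 0.0, rng_seed=0)

    def test_composition_preserves_frame_and_stops(self, rng):
        from genefam.seqprops import translate_cds

        cds = random_cds(rng, 80)
        for i in range(4):
            cds = mutate_codons(cds, 0.05, 0.01, rng_seed=i)
            assert len(cds) % 3 == 0
            translate_cds(cds)  # raises on internal stops
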