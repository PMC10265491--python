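"""Distance-based phylogeny and reference-anchored subfamily assignment.

A p-distance matrix over a multiple protein alignment feeds a
neighbor-joining (Saitou–Nei) agglomeration.  NJ is consistent on additive
distances, so synthetic families evolved from subfamily ancestors cluster
correctly.  Queries inherit the subcellular subfamily (C, ER, M, Chl, N) of
the majority of labelled references in their smallest containing clade with
at least one reference; ties stay unassigned.

Numerical policy: ties in the Q-criterion break deterministically by taxon
label order; a negative NJ branch length is floored at zero with the
deficit shifted to its sister branch.
"""

from __future__ import annotations

import io
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from skbio import TreeNode

__all__ = [
    "DistanceMatrix",
    "p_distance",
    "nj_tree",
    "assign_subfamilies",
    "bootstrap_splits",
]

SUBFAMILY_LABELS = ("C", "ER", "M", "Chl", "N")


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distances with a zero diagonal."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("distance matrix diagonal is not zero")
        if (self.values < -1e-12).any():
            raise ValueError("negative distances")

    def __len__(self) -> int:
        return len(self.labels)


def p_distance(aligned: Mapping[str, str]) -> DistanceMatrix:
    """Pairwise mismatch fraction over columns where both have residues."""
    labels = tuple(sorted(aligned))
    seqs = {k: aligned[k].upper() for k in labels}
    length = len(next(iter(seqs.values())))
    if any(len(s) != length for s in seqs.values()):
        raise ValueError("aligned sequences must have equal length")
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = seqs[labels[i]], seqs[labels[j]]
            shared = mismatch = 0
            for x, y in zip(a, b):
                if x == "-" or y == "-":
                    continue
                shared += 1
                if x != y:
                    mismatch += 1
            if shared == 0:
                raise ValueError(
                    f"no shared non-gap columns between {labels[i]!r} and {labels[j]!r}"
                )
            d[i, j] = d[j, i] = mismatch / shared
    return DistanceMatrix(labels, d)


def _fmt(x: float) -> str:
    return f"{x:.10g}"


def nj_tree(matrix: DistanceMatrix) -> str:
    """Neighbor-joining tree as newick text with branch lengths.

    Agglomerates by the Saitou–Nei Q-criterion down to a trifurcating
    (unrooted) root.  Deterministic: Q-ties break by the smallest taxon
    label in each cluster.
    """
    n = len(matrix)
    if n < 3:
        raise ValueError("NJ needs at least 3 taxa")
    d = {i: {} for i in range(n)}
    for i in range(n):
        for j in range(n):
            if i != j:
                d[i][j] = float(matrix.values[i, j])
    newick = {i: matrix.labels[i] for i in range(n)}
    minlab = {i: matrix.labels[i] for i in range(n)}  # tie-break key
    active = set(range(n))
    next_id = n
    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i][j] for j in active if j != i) for i in active}
        best = None
        for i in sorted(active):
            for j in sorted(active):
                if j <= i:
                    continue
                q = (m - 2) * d[i][j] - r[i] - r[j]
                key = (q, *sorted((minlab[i], minlab[j])))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        li = 0.5 * d[i][j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i][j] - li
        if li < 0:
            lj += li
            li = 0.0
        elif lj < 0:
            li += lj
            lj = 0.0
        u = next_id
        next_id += 1
        newick[u] = f"({newick[i]}:{_fmt(li)},{newick[j]}:{_fmt(lj)})"
        minlab[u] = min(minlab[i], minlab[j])
        d[u] = {}
        for k in active:
            if k in (i, j):
                continue
            dk = 0.5 * (d[i][k] + d[j][k] - d[i][j])
            d[u][k] = d[k][u] = dk
        active -= {i, j}
        active.add(u)
    a, b, c = sorted(active, key=lambda x: minlab[x])
    la = 0.5 * (d[a][b] + d[a][c] - d[b][c])
    lb = 0.5 * (d[a][b] + d[b][c] - d[a][c])
    lc = 0.5 * (d[a][c] + d[b][c] - d[a][b])
    la, lb, lc = (max(x, 0.0) for x in (la, lb, lc))
    return (
        f"({newick[a]}:{_fmt(la)},{newick[b]}:{_fmt(lb)},{newick[c]}:{_fmt(lc)});"
    )


def assign_subfamilies(
    newick: str, references: Mapping[str, str]
) -> dict[str, str]:
    """Label every query taxon by its nearest reference-bearing clade.

    Each query receives the majority label of the references inside its
    smallest containing clade that holds at least one reference; ties (or
    no reference anywhere above) give ``"unassigned"``.  References keep
    their own labels.

    NJ output is unrooted (a trifurcating root), so the tree is
    midpoint-rooted first; otherwise a subfamily straddling the arbitrary
    trifurcation would dissolve into the root.
    """
    tree = TreeNode.read(io.StringIO(newick), convert_underscores=False)
    try:
        tree = tree.root_at_midpoint()
    except Exception:  # zero-length or degenerate trees: keep the input rooting
        pass
    tips = {t.name for t in tree.tips()}
    missing = set(references) - tips
    if missing:
        raise ValueError(f"reference taxa absent from tree: {sorted(missing)}")
    assignment: dict[str, str] = {}
    for tip in tree.tips():
        if tip.name in references:
            assignment[tip.name] = references[tip.name]
            continue
        label = "unassigned"
        for anc in tip.ancestors():
            refs = [references[t.name] for t in anc.tips() if t.name in references]
            if refs:
                counts = Counter(refs).most_common()
                if len(counts) > 1 and counts[0][1] == counts[1][1]:
                    label = "unassigned"
                else:
                    label = counts[0][0]
                break
        assignment[tip.name] = label
    return assignment


def _splits(newick: str) -> set[frozenset]:
    tree = TreeNode.read(io.StringIO(newick), convert_underscores=False)
    all_tips = frozenset(t.name for t in tree.tips())
    out = set()
    for node in tree.non_tips():
        clade = frozenset(t.name for t in node.tips())
        if 1 < len(clade) < len(all_tips) - 1:
            out.add(min(clade, all_tips - clade, key=sorted))
    return out


def bootstrap_splits(
    aligned: Mapping[str, str], n_replicates: int = 100, rng_seed: int = 0
) -> dict[frozenset, float]:
    """Support of the NJ tree's internal splits under column resampling.

    Optional diagnostic (off by default in the pipeline): resamples
    alignment columns with replacement, rebuilds the NJ tree and reports
    the fraction of replicates containing each original split.
    """
    rng = np.random.default_rng(rng_seed)
    base = _splits(nj_tree(p_distance(aligned)))
    length = len(next(iter(aligned.values())))
    counts = Counter()
    for _ in range(n_replicates):
        cols = rng.integers(0, length, size=length)
        resampled = {k: "".join(v[c] for c in cols) for k, v in aligned.items()}
        try:
            rep = _splits(nj_tree(p_distance(resampled)))
        except ValueError:  # a replicate can lose all shared columns
            continue
        for split in base:
            if split in rep:
                counts[split] += 1
    return {split: counts[split] / n_replicates for split in base}
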