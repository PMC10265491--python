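"""Relative expression by 2^−ΔΔCT and log2(FPKM) heatmap matrices.

ΔCt is the target gene's threshold cycle minus the reference signal; with
two reference genes the reference signal is the arithmetic mean of their Ct
values (equivalent to the geometric mean of the linear quantities).  ΔΔCt
subtracts the calibrator sample's ΔCt, and RQ = 2^−ΔΔCt, so the calibrator
is exactly 1 by construction.  Significance comes from an equal-variance
two-tailed t-test on replicate-level ΔCt values against the calibrator,
flagged ``*`` at p < 0.05 and ``**`` at p < 0.01.

RNA-seq matrices are displayed as log2(FPKM) with hard clip bounds; zeros
map to the lower bound instead of −∞.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CtTable",
    "RelativeExpression",
    "read_ct_table",
    "delta_delta_ct",
    "significance",
    "log2_fpkm_matrix",
]


@dataclass
class CtTable:
    """Tidy qPCR Ct values with designated references and calibrator.

    ``data`` columns: sample, gene, replicate, ct.  Every (sample, gene)
    needs ≥ 2 replicates and 1–2 reference genes must be present in every
    sample.
    """

    data: pd.DataFrame
    reference_genes: tuple[str, ...]
    calibrator: str

    def __post_init__(self) -> None:
        required = {"sample", "gene", "replicate", "ct"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"Ct table missing columns {sorted(missing)}")
        if not 1 <= len(self.reference_genes) <= 2:
            raise ValueError("need 1 or 2 reference genes")
        if self.calibrator not in set(self.data["sample"]):
            raise ValueError(f"calibrator sample {self.calibrator!r} not in table")
        counts = self.data.groupby(["sample", "gene"])["ct"].count()
        if (counts < 2).any():
            bad = counts[counts < 2].index.tolist()
            raise ValueError(f"fewer than 2 replicates for {bad}")
        for sample, grp in self.data.groupby("sample"):
            present = set(grp["gene"])
            for ref in self.reference_genes:
                if ref not in present:
                    raise ValueError(
                        f"reference gene {ref!r} missing in sample {sample!r}"
                    )

    @property
    def target_genes(self) -> list[str]:
        return sorted(set(self.data["gene"]) - set(self.reference_genes))


@dataclass(frozen=True)
class RelativeExpression:
    """RQ = 2^−ΔΔCT for one gene in one sample, with its significance flag."""

    sample: str
    gene: str
    rq: float
    log2_rq: float
    p_value: float
    flag: str


def read_ct_table(
    path: str | Path, reference_genes: Sequence[str], calibrator: str
) -> CtTable:
    """Load a TSV with columns sample, gene, replicate, ct."""
    df = pd.read_csv(path, sep="\t")
    return CtTable(df, tuple(reference_genes), calibrator)


def _flag(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def significance(dct: Sequence[float], dct_calibrator: Sequence[float]) -> tuple[float, str]:
    """Two-sample equal-variance two-tailed t-test on replicate ΔCt values."""
    a = np.asarray(dct, float)
    b = np.asarray(dct_calibrator, float)
    if np.allclose(a.std(), 0) and np.allclose(b.std(), 0):
        p = 1.0 if math.isclose(a.mean(), b.mean()) else 0.0
    else:
        p = float(stats.ttest_ind(a, b, equal_var=True).pvalue)
        if math.isnan(p):
            p = 1.0
    return p, _flag(p)


def _replicate_dct(table: CtTable, sample: str, gene: str) -> np.ndarray:
    """Per-replicate ΔCt: target Ct − mean reference Ct, paired by replicate."""
    df = table.data
    sub = df[df["sample"] == sample]
    target = sub[sub["gene"] == gene].set_index("replicate")["ct"]
    ref = (
        sub[sub["gene"].isin(table.reference_genes)]
        .groupby("replicate")["ct"]
        .mean()
    )
    common = target.index.intersection(ref.index)
    if len(common) < 2:
        raise ValueError(
            f"fewer than 2 paired replicates for {gene!r} in sample {sample!r}"
        )
    return (target.loc[common] - ref.loc[common]).to_numpy()


def delta_delta_ct(table: CtTable) -> list[RelativeExpression]:
    """Relative quantification of every target gene in every sample.

    The mean-level ΔΔCt defines RQ; the replicate-level ΔCt sets feed the
    t-test against the calibrator.  The calibrator's own RQ is exactly 1
    and carries p = 1.
    """
    df = table.data
    results = []
    for gene in table.target_genes:
        cal_dct = _replicate_dct(table, table.calibrator, gene)
        cal_mean = float(cal_dct.mean())
        for sample in sorted(set(df["sample"])):
            if sample == table.calibrator:
                rq, p, flag = 1.0, 1.0, ""
            else:
                dct = _replicate_dct(table, sample, gene)
                ddct = float(dct.mean()) - cal_mean
                rq = 2.0 ** (-ddct)
                p, flag = significance(dct, cal_dct)
            results.append(
                RelativeExpression(
                    sample=sample,
                    gene=gene,
                    rq=rq,
                    log2_rq=math.log2(rq),
                    p_value=p,
                    flag=flag,
                )
            )
    return results


def expression_table(results: Sequence[RelativeExpression]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(sample=r.sample, gene=r.gene, rq=r.rq, log2_rq=r.log2_rq,
                 p=r.p_value, flag=r.flag)
            for r in results
        ]
    )


def log2_fpkm_matrix(
    fpkm: pd.DataFrame, lo: float = -4.0, hi: float = 10.0
) -> pd.DataFrame:
    """log2-transform an FPKM matrix and clip to display bounds [lo, hi].

    FPKM = 0 maps to the floor ``lo`` rather than −∞.  Monotone and
    idempotent under repeated application with the same bounds.
    """
    if lo >= hi:
        raise ValueError(f"clip bounds inverted: lo={lo} ≥ hi={hi}")
    values = fpkm.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("FPKM values must be non-negative")
    floored = np.maximum(values, 2.0 ** lo)
    clipped = np.clip(np.log2(floored), lo, hi)
    return pd.DataFrame(clipped, index=fpkm.index, columns=fpkm.columns)
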