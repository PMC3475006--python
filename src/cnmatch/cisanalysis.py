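"""Gene-wise cis-effect analysis of matched copy number / expression data.

A cis-effect is the influence of a gene's own DNA dosage on its expression.
For each row of a matched pair the association between the expression
signature and the assigned copy number signature (segmented data) is measured
by Spearman's rank correlation, with a two-sided p-value from the usual
t approximation, and Benjamini-Hochberg control of the false discovery rate
across genes. Rows whose copy number or expression signature is constant
across samples carry no rank information: their correlation is reported as
missing and they do not enter the BH denominator.

Matching procedures can be compared on the same data by counting, over the
genes matched by all of them, how often procedure A's cis-correlation
strictly exceeds procedure B's (:func:`pairwise_win_counts`); rank ties count
for neither procedure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import MatchedPair

__all__ = [
    "CisResult",
    "cis_correlations",
    "cis_frame",
    "pairwise_win_counts",
    "bh_adjust",
    "spearman_rows",
]


@dataclass(frozen=True)
class CisResult:
    """Per-gene cis association: Spearman rho, raw and BH-adjusted p-value."""

    gene_id: str
    rho: float
    p: float
    p_adj: float

    @property
    def missing(self) -> bool:
        return not np.isfinite(self.rho)


def spearman_rows(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Spearman correlation of two equal-shape matrices.

    Ranks use average ties (midranks); the p-value is the two-sided
    t-approximation on n-2 degrees of freedom, the same statistic
    ``scipy.stats.spearmanr`` reports. Rows containing missing values fall
    back to pairwise-complete scipy computation; rows where either vector is
    constant (zero rank variance) return missing rho and p.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    n_rows, n = x.shape
    rho = np.full(n_rows, np.nan)
    pval = np.full(n_rows, np.nan)
    finite = np.isfinite(x) & np.isfinite(y)
    clean = finite.all(axis=1)

    if clean.any():
        rx = stats.rankdata(x[clean], axis=1)
        ry = stats.rankdata(y[clean], axis=1)
        rx = rx - rx.mean(axis=1, keepdims=True)
        ry = ry - ry.mean(axis=1, keepdims=True)
        sx = np.sqrt((rx**2).sum(axis=1))
        sy = np.sqrt((ry**2).sum(axis=1))
        ok = (sx > 0) & (sy > 0)
        r = np.full(ok.shape, np.nan)
        with np.errstate(invalid="ignore", divide="ignore"):
            r[ok] = (rx * ry).sum(axis=1)[ok] / (sx[ok] * sy[ok])
        r = np.clip(r, -1.0, 1.0)
        p = np.full(ok.shape, np.nan)
        if n > 2:
            with np.errstate(invalid="ignore", divide="ignore"):
                t = r * np.sqrt((n - 2) / (1.0 - r**2))
            p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), n - 2)
            p[ok & (np.abs(r) >= 1.0)] = 0.0
        rho[clean] = r
        pval[clean] = p

    for i in np.flatnonzero(~clean):
        mask = finite[i]
        if mask.sum() < 3:
            continue
        xi, yi = x[i, mask], y[i, mask]
        if np.ptp(xi) == 0 or np.ptp(yi) == 0:
            continue
        res = stats.spearmanr(xi, yi)
        rho[i], pval[i] = res.statistic, res.pvalue
    return rho, pval


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, order-preserving with the input.

    Input p-values must lie in (0, 1]; the adjusted value of the i-th order
    statistic is min over j >= i of m * p(j) / j, capped at 1.
    """
    arr = np.asarray(list(p), dtype=float)
    if arr.size == 0:
        return arr
    if np.isnan(arr).any() or (arr <= 0).any() or (arr > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def cis_correlations(pair: MatchedPair) -> list[CisResult]:
    """Spearman cis-correlation per matched row, BH-adjusted across rows.

    Correlates each row's expression signature against its segmented copy
    number signature over samples (at least 3 required). Constant rows are
    reported with missing rho/p and are excluded from the BH denominator.
    """
    n_samples = len(pair.expression.samples)
    if n_samples < 3:
        raise ValueError(f"cis analysis needs >= 3 samples, got {n_samples}")
    rho, p = spearman_rows(pair.expression.expression, pair.cn_summary.segmented)
    p_adj = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        # BH treats exact zeros (perfect monotone association) as valid input
        adj = multipletests(np.clip(p[ok], 0.0, 1.0), method="fdr_bh")[1]
        p_adj[ok] = adj
    ids = pair.provenance["gene_id"].tolist()
    return [
        CisResult(ids[i], float(rho[i]), float(p[i]), float(p_adj[i]))
        for i in range(len(ids))
    ]


def cis_frame(pair: MatchedPair, alpha: float = 0.05) -> pd.DataFrame:
    """Tabular cis results with provenance and a significance flag at ``alpha``."""
    results = cis_correlations(pair)
    df = pair.provenance.copy()
    df["rho"] = [r.rho for r in results]
    df["p"] = [r.p for r in results]
    df["p_adj"] = [r.p_adj for r in results]
    df["significant"] = df["p_adj"] < alpha
    return df


def pairwise_win_counts(
    rho_by_procedure: Mapping[str, Mapping[str, float] | pd.Series],
    genes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Count, pairwise, how often one procedure out-correlates another.

    Restricted to genes with a non-missing correlation under every procedure
    (``genes`` narrows this further); ``counts.loc[A, B]`` is the number of
    genes where procedure A's rho strictly exceeds B's. Ties count for
    neither side, so ``counts.loc[A, B] + counts.loc[B, A] <= #genes``.
    """
    series = {
        name: pd.Series(vals, dtype=float).dropna()
        for name, vals in rho_by_procedure.items()
    }
    names = list(series)
    common: set[str] | None = None
    for s in series.values():
        idx = set(s.index)
        common = idx if common is None else common & idx
    common = common or set()
    if genes is not None:
        common &= set(genes)
    if not common:
        warnings.warn("no genes are matched by every procedure; win counts are empty")
        return pd.DataFrame(index=names, columns=names, dtype=float).iloc[0:0, 0:0]
    order = sorted(common)
    mat = np.vstack([series[n].loc[order].to_numpy() for n in names])
    counts = pd.DataFrame(0, index=names, columns=names, dtype=int)
    for a in range(len(names)):
        for b in range(len(names)):
            if a != b:
                counts.iloc[a, b] = int((mat[a] > mat[b]).sum())
    return counts
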