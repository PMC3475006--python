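"""Summarize matched copy number features into row-aligned paired datasets.

Given a :class:`~cnmatch.model.MatchMap`, these functions build the "matched
dataset": one copy number signature (a vector over samples) per matched
expression feature, row-aligned with the expression data and carrying full
provenance (which CN probes, which weights), so that genes recurring after
the split/expand extensions can be counted in multiple-testing corrections.

Two summaries of a multi-probe match are offered: the weighted mean
(:func:`weighted_summary`, the default for the *Any* procedures) and the
per-sample most aberrant signal (:func:`maximum_summary`). Two further
extensions rewrite the MatchMap itself before summarization:
:func:`split_at_breakpoints` partitions each matched set wherever any sample
segments differently between consecutive probes, and :func:`expand_to_single`
reduces every matched set to singletons. Neither changes which CN features a
gene is assigned — only how their data are combined.

Calls are categorical, so they are never averaged: the weighted summary
copies the calls of the dominant-weight feature (weight ties resolved per
sample toward the call nearest 0, then the smaller start).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model import (
    SEGMENT_ATOL,
    CopyNumberSet,
    ExpressionSet,
    FeatureAnnotation,
    MatchEntry,
    MatchMap,
    MatchedPair,
)

__all__ = [
    "weighted_summary",
    "maximum_summary",
    "split_at_breakpoints",
    "expand_to_single",
]


def _entry_order(entry: MatchEntry, cn: CopyNumberSet) -> np.ndarray:
    """Positions of the entry's CN features in (start, end, id) order."""
    return np.array(
        sorted(
            range(entry.size),
            key=lambda k: (
                cn.features[entry.cn_indices[k]].start,
                cn.features[entry.cn_indices[k]].end,
                cn.features[entry.cn_indices[k]].feature_id,
            ),
        ),
        dtype=int,
    )


def _weighted_mean_rows(values: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Per-sample weighted mean of a k x p block, excluding missing values.

    Weights attached to missing entries are dropped and the remainder
    renormalized per sample; a sample where every matched value is missing
    yields a missing output value.
    """
    finite = np.isfinite(values)
    wmat = np.where(finite, w[:, None], 0.0)
    wsum = wmat.sum(axis=0)
    out = np.full(values.shape[1], np.nan)
    ok = wsum > 0
    if ok.any():
        num = (wmat * np.where(finite, values, 0.0)).sum(axis=0)
        out[ok] = num[ok] / wsum[ok]
    return out


def _dominant_calls(entry: MatchEntry, cn: CopyNumberSet) -> np.ndarray:
    """Calls row of the largest-weight feature.

    Several features may tie for the largest weight (uniform label weights,
    equal overlap fractions). Calls vary by sample, so ties are resolved per
    sample: among the tied features, the call with the smallest magnitude is
    taken (the conservative choice), then the feature with the smaller start.
    """
    wmax = max(entry.weights)
    tied = [k for k, w in enumerate(entry.weights) if w >= wmax - 1e-12]
    order = _entry_order(entry, cn)
    tied_in_order = [k for k in order if k in set(tied)]
    rows = cn.calls[[entry.cn_indices[k] for k in tied_in_order]]
    if len(tied_in_order) == 1:
        return rows[0].copy()
    out = np.full(rows.shape[1], np.nan)
    for s in range(rows.shape[1]):
        col = rows[:, s]
        finite = np.flatnonzero(np.isfinite(col))
        if finite.size == 0:
            continue
        out[s] = col[finite[np.argmin(np.abs(col[finite]), )]]
    return out


def _provenance_frame(entries, cn: CopyNumberSet, ge: ExpressionSet) -> pd.DataFrame:
    rows = []
    for e in entries:
        rows.append(
            {
                "gene_id": ge.features[e.gene_index].feature_id,
                "cn_ids": "|".join(cn.features[i].feature_id for i in e.cn_indices),
                "weights": "|".join(format(w, ".10g") for w in e.weights),
                "n_cn_features": e.size,
            }
        )
    return pd.DataFrame(rows, columns=["gene_id", "cn_ids", "weights", "n_cn_features"])


def _assemble(
    entries, cn: CopyNumberSet, ge: ExpressionSet, normalized, segmented, calls
) -> MatchedPair:
    # Summary rows inherit the gene's own annotation: the summarized signature
    # is the dosage assigned *to the gene*, and genes recurring under the
    # split/expand extensions are distinguished by provenance, not coordinates.
    gene_feats = [ge.features[e.gene_index] for e in entries]
    feats = [
        FeatureAnnotation(f.feature_id, f.chromosome, f.start, f.end) for f in gene_feats
    ]
    n, p = len(entries), len(cn.samples)
    cn_summary = CopyNumberSet(
        features=feats,
        samples=cn.samples,
        normalized=np.asarray(normalized).reshape(n, p),
        segmented=np.asarray(segmented).reshape(n, p),
        calls=np.asarray(calls).reshape(n, p),
    )
    expression = ExpressionSet(
        features=feats,
        samples=ge.samples,
        expression=ge.expression[[e.gene_index for e in entries]].copy(),
    )
    return MatchedPair(cn_summary, expression, _provenance_frame(entries, cn, ge))


def weighted_summary(cn: CopyNumberSet, ge: ExpressionSet, m: MatchMap) -> MatchedPair:
    """Weighted-mean copy number signature per matched expression feature.

    The normalized and segmented rows of each entry are the weight-weighted
    means of the matched CN features' rows (missing values excluded with
    per-sample weight renormalization); the calls row is copied from the
    dominant-weight feature. Singleton entries reproduce the source rows
    exactly, and every output value lies within the range of the matched
    inputs (the mean is convex).
    """
    normalized, segmented, calls = [], [], []
    for e in m.entries:
        idx = list(e.cn_indices)
        w = np.asarray(e.weights)
        normalized.append(_weighted_mean_rows(cn.normalized[idx], w))
        segmented.append(_weighted_mean_rows(cn.segmented[idx], w))
        calls.append(_dominant_calls(e, cn))
    return _assemble(m.entries, cn, ge, normalized, segmented, calls)


def maximum_summary(cn: CopyNumberSet, ge: ExpressionSet, m: MatchMap) -> MatchedPair:
    """Most-aberrant copy number signature per matched expression feature.

    Per entry and per sample, the matched feature whose segmented value has
    the largest absolute deviation from zero is selected; its segmented,
    normalized and called values travel together. The resulting signature may
    draw on different features in different samples, increasing copy number
    variation (which can help cis-effect discovery at the price of more false
    positives). Ties break toward the smaller start coordinate.
    """
    normalized, segmented, calls = [], [], []
    for e in m.entries:
        order = _entry_order(e, cn)
        idx = [e.cn_indices[k] for k in order]
        seg = cn.segmented[idx]
        nrm = cn.normalized[idx]
        cal = cn.calls[idx]
        p = seg.shape[1]
        srow = np.full(p, np.nan)
        nrow = np.full(p, np.nan)
        crow = np.full(p, np.nan)
        absval = np.where(np.isfinite(seg), np.abs(seg), -np.inf)
        best = np.argmax(absval, axis=0)  # first max = smallest start
        for s in range(p):
            if np.isfinite(seg[best[s], s]):
                srow[s] = seg[best[s], s]
                nrow[s] = nrm[best[s], s]
                crow[s] = cal[best[s], s]
        segmented.append(srow)
        normalized.append(nrow)
        calls.append(crow)
    return _assemble(m.entries, cn, ge, normalized, segmented, calls)


def split_at_breakpoints(m: MatchMap, cn: CopyNumberSet) -> MatchMap:
    """Partition each matched set at every within-set breakpoint.

    A breakpoint sits between two genomically consecutive matched features
    whenever any sample's segmented values differ there. Each resulting part
    becomes its own entry for the same gene, with weights renormalized within
    the part — so a gene may appear multiple times afterwards, each time with
    the same expression signature but a different (internally breakpoint-free)
    copy number signature.
    """
    out = MatchMap(unmatched_genes=list(m.unmatched_genes), notes=list(m.notes))
    for e in m.entries:
        order = _entry_order(e, cn)
        idx = [e.cn_indices[k] for k in order]
        w = [e.weights[k] for k in order]
        parts: list[list[int]] = [[0]]
        for k in range(1, len(idx)):
            same = np.isclose(
                cn.segmented[idx[k - 1]],
                cn.segmented[idx[k]],
                rtol=0.0,
                atol=SEGMENT_ATOL,
                equal_nan=True,
            ).all()
            if same:
                parts[-1].append(k)
            else:
                parts.append([k])
        for part in parts:
            pw = np.asarray([w[k] for k in part])
            out.entries.append(
                MatchEntry(
                    e.gene_index,
                    tuple(idx[k] for k in part),
                    tuple(pw / pw.sum()),
                )
            )
    return out


def expand_to_single(m: MatchMap) -> MatchMap:
    """Split every matched set into singletons, one entry per CN feature.

    Each (gene, k features) entry becomes k weight-1 entries; the total entry
    count equals the sum of the original entry sizes. Idempotent on
    all-singleton inputs. The multiplicity correction downstream grows
    accordingly.
    """
    out = MatchMap(unmatched_genes=list(m.unmatched_genes), notes=list(m.notes))
    for e in m.entries:
        for i in e.cn_indices:
            out.entries.append(MatchEntry(e.gene_index, (i,), (1.0,)))
    return out
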