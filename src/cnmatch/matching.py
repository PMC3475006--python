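"""The six procedures matching copy number array features to expression features.

Each procedure answers the same question — which copy number (CN) probes carry
the dosage information for a given expression probe? — with a different use of
the annotation (and, for overlapPlus, the experimental data):

``match_label``
    join platforms through a shared descriptor set (e.g. gene symbols).
``match_distance``
    winner-takes-all: the CN probe whose midpoint is nearest the gene's.
``match_distance_any``
    all CN probes within a window of the gene midpoint, weighted
    reciprocally to distance (a moving-average along the genome).
``match_overlap``
    the CN probe with the largest overlap fraction (overlap bp / probe length).
``match_overlap_any``
    all CN probes with overlap fraction above a threshold, weights
    proportional to the fraction.
``match_overlap_plus``
    overlap matching, then dosage interpolation for genes in uncovered
    regions when no sample shows a breakpoint between the flanking probes.

All procedures return a :class:`~cnmatch.model.MatchMap` whose entry weights
sum to one, so downstream summarization is a plain weighted mean. Results are
independent of the input row order: candidate scans use (start, end, id) order
internally, and ties break toward the smallest start, then smallest end, then
lexicographic id.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np

from .model import (
    SEGMENT_ATOL,
    CopyNumberSet,
    ExpressionSet,
    FeatureAnnotation,
    MatchEntry,
    MatchMap,
)

__all__ = [
    "ConfigurationError",
    "match_label",
    "match_distance",
    "match_distance_any",
    "match_overlap",
    "match_overlap_any",
    "match_overlap_plus",
]

#: Distance beyond which a winner-takes-all match is flagged in the report.
DEFAULT_WARN_DISTANCE = 1_000_000.0


class ConfigurationError(ValueError):
    """Invalid procedure parameter (non-positive window/offset, missing data)."""


def _annotations(x) -> list[FeatureAnnotation]:
    if isinstance(x, (CopyNumberSet, ExpressionSet)):
        return x.features
    return list(x)


class _ChromIndex:
    """Per-chromosome candidate arrays in canonical (start, end, id) order."""

    def __init__(self, features: Sequence[FeatureAnnotation]):
        by_chrom: dict[str, list[int]] = {}
        for i, f in enumerate(features):
            by_chrom.setdefault(f.chromosome, []).append(i)
        self.groups: dict[str, dict[str, np.ndarray]] = {}
        for chrom, idx in by_chrom.items():
            idx.sort(key=lambda i: (features[i].start, features[i].end, features[i].feature_id))
            arr = np.array(idx, dtype=int)
            self.groups[chrom] = {
                "index": arr,
                "start": np.array([features[i].start for i in idx], dtype=float),
                "end": np.array([features[i].end for i in idx], dtype=float),
                "mid": np.array([features[i].midpoint for i in idx], dtype=float),
                "length": np.array([features[i].length for i in idx], dtype=float),
            }

    def get(self, chrom: str):
        return self.groups.get(chrom)


def _normalized(weights: np.ndarray) -> np.ndarray:
    return weights / weights.sum()


# ---------------------------------------------------------------------------
# label matching
# ---------------------------------------------------------------------------

def _descriptors(mapping: Mapping[str, object], key: str) -> set[str]:
    v = mapping.get(key)
    if v is None:
        return set()
    if isinstance(v, str):
        return {v}
    return set(v)


def match_label(
    cn_ids: Sequence[str],
    ge_ids: Sequence[str],
    cn_to_common: Mapping[str, object],
    ge_to_common: Mapping[str, object],
    *,
    cn_features: Sequence[FeatureAnnotation] | None = None,
    ge_features: Sequence[FeatureAnnotation] | None = None,
    strict_chromosome: bool = False,
) -> MatchMap:
    """Match platforms through a common descriptor set (e.g. gene symbols).

    Each platform's manufacturer IDs are mapped to common descriptors; a gene
    is matched, with uniform weights, to every CN feature sharing at least one
    descriptor with it. Maps may be partial and many-to-one. Because labels
    carry no positional information, a match may in principle cross
    chromosomes; pass annotation lists and ``strict_chromosome=True`` to
    discard cross-chromosome links.
    """
    if strict_chromosome and (cn_features is None or ge_features is None):
        raise ConfigurationError(
            "strict_chromosome requires cn_features and ge_features annotations"
        )
    # invert the CN map: descriptor -> CN feature positions
    desc_to_cn: dict[str, list[int]] = {}
    for j, cid in enumerate(cn_ids):
        for d in _descriptors(cn_to_common, cid):
            desc_to_cn.setdefault(d, []).append(j)

    result = MatchMap()
    for g, gid in enumerate(ge_ids):
        hits: set[int] = set()
        for d in _descriptors(ge_to_common, gid):
            hits.update(desc_to_cn.get(d, ()))
        if strict_chromosome:
            chrom = ge_features[g].chromosome
            hits = {j for j in hits if cn_features[j].chromosome == chrom}
        if not hits:
            result.unmatched_genes.append(g)
            continue
        idx = sorted(hits)
        w = np.full(len(idx), 1.0 / len(idx))
        result.entries.append(MatchEntry(g, tuple(idx), tuple(w)))
    return result


# ---------------------------------------------------------------------------
# distance matching
# ---------------------------------------------------------------------------

def match_distance(
    cn,
    ge,
    *,
    warn_distance: float = DEFAULT_WARN_DISTANCE,
) -> MatchMap:
    """Winner-takes-all midpoint matching.

    Every gene whose chromosome carries at least one CN feature is matched
    (weight 1) to the CN feature whose midpoint is nearest the gene midpoint;
    no maximum distance is imposed, but matches farther than ``warn_distance``
    (default 1 Mb) are flagged in ``MatchMap.notes``, since a cis-effect is
    not plausible across large genomic separations.
    """
    cn_feats, ge_feats = _annotations(cn), _annotations(ge)
    index = _ChromIndex(cn_feats)
    result = MatchMap()
    for g, gene in enumerate(ge_feats):
        grp = index.get(gene.chromosome)
        if grp is None:
            result.unmatched_genes.append(g)
            continue
        d = np.abs(grp["mid"] - gene.midpoint)
        best = int(np.argmin(d))  # first occurrence = smallest (start, end, id)
        result.entries.append(MatchEntry(g, (int(grp["index"][best]),), (1.0,)))
        if d[best] > warn_distance:
            result.notes.append(
                f"gene {gene.feature_id!r} matched to "
                f"{cn_feats[grp['index'][best]].feature_id!r} at "
                f"{d[best]:.0f} bp (> {warn_distance:.0f} bp warn threshold)"
            )
    return result


def match_distance_any(cn, ge, window: float, offset: float = 1.0) -> MatchMap:
    """Match every CN feature within ``window`` bp of the gene midpoint.

    Candidate CN features on the gene's chromosome with midpoint distance
    strictly below ``window`` are all matched; raw weights are reciprocal to
    ``distance + offset`` (the offset keeps a zero-distance feature's weight
    finite) and normalized to unit sum.
    """
    if not window > 0:
        raise ConfigurationError(f"window must be positive, got {window!r}")
    if not offset > 0:
        raise ConfigurationError(f"offset must be positive, got {offset!r}")
    cn_feats, ge_feats = _annotations(cn), _annotations(ge)
    index = _ChromIndex(cn_feats)
    result = MatchMap()
    for g, gene in enumerate(ge_feats):
        grp = index.get(gene.chromosome)
        if grp is None:
            result.unmatched_genes.append(g)
            continue
        d = np.abs(grp["mid"] - gene.midpoint)
        keep = d < window
        if not keep.any():
            result.unmatched_genes.append(g)
            continue
        w = _normalized(1.0 / (d[keep] + offset))
        result.entries.append(
            MatchEntry(g, tuple(int(i) for i in grp["index"][keep]), tuple(w))
        )
    return result


# ---------------------------------------------------------------------------
# overlap matching
# ---------------------------------------------------------------------------

def _overlap_fractions(grp, gene: FeatureAnnotation) -> np.ndarray:
    ov = np.minimum(grp["end"], gene.end) - np.maximum(grp["start"], gene.start) + 1.0
    return np.maximum(ov, 0.0) / grp["length"]


def match_overlap(cn, ge) -> MatchMap:
    """Match each gene to the CN feature with maximal overlap fraction.

    The overlap fraction is the number of shared basepairs divided by the CN
    probe's length. Genes whose best fraction is zero stay unmatched; ties at
    the maximum break toward the smallest start, then end, then id.
    """
    cn_feats, ge_feats = _annotations(cn), _annotations(ge)
    index = _ChromIndex(cn_feats)
    result = MatchMap()
    for g, gene in enumerate(ge_feats):
        grp = index.get(gene.chromosome)
        if grp is None:
            result.unmatched_genes.append(g)
            continue
        frac = _overlap_fractions(grp, gene)
        best = int(np.argmax(frac))
        if frac[best] <= 0.0:
            result.unmatched_genes.append(g)
            continue
        result.entries.append(MatchEntry(g, (int(grp["index"][best]),), (1.0,)))
    return result


def match_overlap_any(cn, ge, min_fraction: float = 0.0) -> MatchMap:
    """Match every CN feature overlapping the gene above a threshold.

    All CN features with overlap fraction strictly greater than
    ``min_fraction`` are matched, with weights proportional to the fraction
    (normalized to unit sum). With the default threshold 0 the matched *gene*
    set coincides with that of :func:`match_overlap`.
    """
    if not (0.0 <= min_fraction < 1.0):
        raise ConfigurationError(
            f"min_fraction must lie in [0, 1), got {min_fraction!r}"
        )
    cn_feats, ge_feats = _annotations(cn), _annotations(ge)
    index = _ChromIndex(cn_feats)
    result = MatchMap()
    for g, gene in enumerate(ge_feats):
        grp = index.get(gene.chromosome)
        if grp is None:
            result.unmatched_genes.append(g)
            continue
        frac = _overlap_fractions(grp, gene)
        keep = frac > min_fraction
        if not keep.any():
            result.unmatched_genes.append(g)
            continue
        w = _normalized(frac[keep])
        result.entries.append(
            MatchEntry(g, tuple(int(i) for i in grp["index"][keep]), tuple(w))
        )
    return result


def match_overlap_plus(cn: CopyNumberSet, ge) -> MatchMap:
    """Overlap matching plus breakpoint-checked dosage interpolation.

    Step one is plain overlap matching. For each gene left unmatched (its
    locus not covered by the CN platform), the nearest CN features strictly
    down- and upstream of the gene midpoint are located; if both exist and no
    sample shows a breakpoint between them — their segmented rows agree in
    every sample — the flanking dosage is interpolated to the gene: it is
    matched (weight 1) to the nearer flank. If any sample segments differently
    across the gap, the correct dosage is undecidable and the gene stays
    unmatched. A gene with only one flank (chromosome end) stays unmatched.

    Unlike the annotation-only procedures this step consults the segmented
    data, so the matching can differ between datasets from the same platform.
    """
    if not isinstance(cn, CopyNumberSet):
        raise ConfigurationError(
            "match_overlap_plus needs a CopyNumberSet (segmented data required)"
        )
    ge_feats = _annotations(ge)
    result = match_overlap(cn, ge_feats)
    index = _ChromIndex(cn.features)
    still_unmatched: list[int] = []
    for g in result.unmatched_genes:
        gene = ge_feats[g]
        grp = index.get(gene.chromosome)
        if grp is None:
            still_unmatched.append(g)
            continue
        delta = grp["mid"] - gene.midpoint
        down = np.flatnonzero(delta < 0)
        up = np.flatnonzero(delta > 0)
        if down.size == 0 or up.size == 0:
            still_unmatched.append(g)
            continue
        # nearest flank by midpoint; equal midpoints resolve to the first in
        # (start, end, id) order, probes being allowed to overlap each other
        mid = grp["mid"]
        lo = down[np.flatnonzero(mid[down] == mid[down].max())[0]]
        hi = up[np.flatnonzero(mid[up] == mid[up].min())[0]]
        row_lo = cn.segmented[grp["index"][lo]]
        row_hi = cn.segmented[grp["index"][hi]]
        if not np.isclose(row_lo, row_hi, rtol=0.0, atol=SEGMENT_ATOL, equal_nan=True).all():
            still_unmatched.append(g)  # breakpoint in at least one sample
            continue
        pick = lo if -delta[lo] <= delta[hi] else hi
        result.entries.append(MatchEntry(g, (int(grp["index"][pick]),), (1.0,)))
    result.unmatched_genes = still_unmatched
    result.entries.sort(key=lambda e: e.gene_index)
    return result
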