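"""Domain types and coordinate geometry shared by all matching procedures.

Conventions
-----------
Coordinates are 1-based and inclusive on both ends, the convention of array
annotation tables: a feature spanning ``start..end`` has length
``end - start + 1`` and a single-basepair feature has ``start == end``.
BED input (0-based, half-open) is converted at the I/O boundary, never here.

Chromosome labels are normalized once, on construction: an optional ``chr``
prefix is stripped and ``x``/``y``/``mt`` are uppercased, so ``chr14`` and
``14`` compare equal, as do ``chrX`` and ``X``.

Midpoints are kept as exact halves (a probe of even length has a ``.5``
midpoint); rounding would silently change tie outcomes downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "FeatureAnnotation",
    "CopyNumberSet",
    "ExpressionSet",
    "MatchEntry",
    "MatchMap",
    "MatchedPair",
    "normalize_chromosome",
    "chromosome_sort_key",
    "midpoint",
    "midpoint_distance",
    "overlap_bp",
    "overlap_fraction",
    "canonical_order",
]

#: Valid discrete copy number calls: double loss .. amplification.
CALL_LEVELS = (-2, -1, 0, 1, 2)

#: Absolute tolerance for "same segment" comparisons of segmented values.
#: Segmented profiles are piecewise constant, so equality is expected exactly;
#: the tolerance only guards float round-trips through text files.
SEGMENT_ATOL = 1e-8


def normalize_chromosome(label: str) -> str:
    """Normalize a chromosome label: strip ``chr`` prefix, uppercase X/Y/MT."""
    s = str(label).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    if s.lower() in ("x", "y", "mt", "m"):
        s = "MT" if s.lower() in ("mt", "m") else s.upper()
    return s


def chromosome_sort_key(label: str):
    """Sort key placing numeric chromosomes first (numerically), then X, Y, MT."""
    order = {"X": 23, "Y": 24, "MT": 25}
    if label.isdigit():
        return (0, int(label), "")
    if label in order:
        return (0, order[label], "")
    return (1, 0, label)


@dataclass(frozen=True)
class FeatureAnnotation:
    """One array probe or gene: identifier plus genomic interval.

    Parameters
    ----------
    feature_id : str
        Platform identifier (e.g. an Agilent probe name).
    chromosome : str
        Chromosome label; normalized on construction.
    start, end : int
        1-based inclusive basepair coordinates, ``1 <= start <= end``.
    """

    feature_id: str
    chromosome: str
    start: int
    end: int

    def __post_init__(self):
        object.__setattr__(self, "chromosome", normalize_chromosome(self.chromosome))
        object.__setattr__(self, "start", int(self.start))
        object.__setattr__(self, "end", int(self.end))
        if self.start < 1:
            raise ValueError(
                f"feature {self.feature_id!r}: start must be >= 1, got {self.start}"
            )
        if self.end < self.start:
            raise ValueError(
                f"feature {self.feature_id!r}: end ({self.end}) < start ({self.start})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


def midpoint(f: FeatureAnnotation) -> float:
    """Midpoint of a feature: mean of start and end positions (exact halves kept)."""
    return f.midpoint


def midpoint_distance(a: FeatureAnnotation, b: FeatureAnnotation) -> float:
    """Absolute distance between two features' midpoints, in bp. Symmetric."""
    return abs(a.midpoint - b.midpoint)


def overlap_bp(a: FeatureAnnotation, b: FeatureAnnotation) -> int:
    """Number of basepairs shared by two features; 0 on different chromosomes."""
    if a.chromosome != b.chromosome:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start) + 1)


def overlap_fraction(gene: FeatureAnnotation, cn: FeatureAnnotation) -> float:
    """Overlap of a gene and a copy number probe as a fraction of *probe* length.

    The denominator is always the copy number probe's length, never the
    gene's: a short probe fully inside a long gene scores 1.0.
    """
    return overlap_bp(gene, cn) / cn.length


def canonical_order(features: Sequence[FeatureAnnotation]) -> np.ndarray:
    """Indices that sort features by (chromosome, start, end, id).

    Applying the resulting permutation twice is a no-op on the sorted list
    (canonicalization is idempotent).
    """
    return np.array(
        sorted(
            range(len(features)),
            key=lambda i: (
                chromosome_sort_key(features[i].chromosome),
                features[i].start,
                features[i].end,
                features[i].feature_id,
            ),
        ),
        dtype=int,
    )


def _as_matrix(x, n_rows: int, n_cols: int, name: str, dtype=float) -> np.ndarray:
    m = np.asarray(x, dtype=dtype)
    if m.shape != (n_rows, n_cols):
        raise ValueError(f"{name} matrix has shape {m.shape}, expected ({n_rows}, {n_cols})")
    return m


@dataclass
class CopyNumberSet:
    """Copy number platform: annotation plus aligned normalized/segmented/calls.

    The three matrices are features x samples: ``normalized`` holds noisy log2
    ratios, ``segmented`` their piecewise-constant segmentation, and ``calls``
    the discretization into {-2,-1,0,1,2} (double loss .. amplification).
    """

    features: list[FeatureAnnotation]
    samples: list[str]
    normalized: np.ndarray
    segmented: np.ndarray
    calls: np.ndarray

    def __post_init__(self):
        n, p = len(self.features), len(self.samples)
        self.features = list(self.features)
        self.samples = [str(s) for s in self.samples]
        self.normalized = _as_matrix(self.normalized, n, p, "normalized")
        self.segmented = _as_matrix(self.segmented, n, p, "segmented")
        self.calls = _as_matrix(self.calls, n, p, "calls")
        finite = self.calls[np.isfinite(self.calls)]
        if finite.size and not np.isin(finite, CALL_LEVELS).all():
            bad = sorted(set(finite[~np.isin(finite, CALL_LEVELS)]))
            raise ValueError(f"calls matrix contains values outside {CALL_LEVELS}: {bad}")

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def feature_ids(self) -> list[str]:
        return [f.feature_id for f in self.features]

    def canonicalize(self) -> "CopyNumberSet":
        """Return a copy with features sorted by (chromosome, start, end, id)."""
        order = canonical_order(self.features)
        return CopyNumberSet(
            features=[self.features[i] for i in order],
            samples=self.samples,
            normalized=self.normalized[order],
            segmented=self.segmented[order],
            calls=self.calls[order],
        )

    def subset(self, indices: Iterable[int]) -> "CopyNumberSet":
        idx = np.asarray(list(indices), dtype=int)
        return CopyNumberSet(
            features=[self.features[i] for i in idx],
            samples=self.samples,
            normalized=self.normalized[idx],
            segmented=self.segmented[idx],
            calls=self.calls[idx],
        )


@dataclass
class ExpressionSet:
    """Expression platform: annotation plus one features x samples matrix."""

    features: list[FeatureAnnotation]
    samples: list[str]
    expression: np.ndarray

    def __post_init__(self):
        self.features = list(self.features)
        self.samples = [str(s) for s in self.samples]
        self.expression = _as_matrix(
            self.expression, len(self.features), len(self.samples), "expression"
        )

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def feature_ids(self) -> list[str]:
        return [f.feature_id for f in self.features]

    def canonicalize(self) -> "ExpressionSet":
        order = canonical_order(self.features)
        return ExpressionSet(
            features=[self.features[i] for i in order],
            samples=self.samples,
            expression=self.expression[order],
        )

    def subset(self, indices: Iterable[int]) -> "ExpressionSet":
        idx = np.asarray(list(indices), dtype=int)
        return ExpressionSet(
            features=[self.features[i] for i in idx],
            samples=self.samples,
            expression=self.expression[idx],
        )


@dataclass(frozen=True)
class MatchEntry:
    """One matched expression feature: CN feature indices plus unit-sum weights."""

    gene_index: int
    cn_indices: tuple[int, ...]
    weights: tuple[float, ...]

    def __post_init__(self):
        object.__setattr__(self, "cn_indices", tuple(int(i) for i in self.cn_indices))
        object.__setattr__(self, "weights", tuple(float(w) for w in self.weights))
        if len(self.cn_indices) == 0:
            raise ValueError("a match entry must contain at least one CN feature")
        if len(self.weights) != len(self.cn_indices):
            raise ValueError("weights and cn_indices must have equal length")
        if any(w <= 0 for w in self.weights):
            raise ValueError("all match weights must be strictly positive")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1, got {sum(self.weights)!r}")

    @property
    def size(self) -> int:
        return len(self.cn_indices)


@dataclass
class MatchMap:
    """Result of a matching procedure.

    ``entries`` hold, per matched expression feature, the indices of the CN
    features assigned to it and their normalized (unit-sum) weights.
    ``unmatched_genes`` are expression-feature indices no procedure step could
    match; ``notes`` carries procedure warnings (e.g. distant matches).
    Gene indices are unique across entries except after the breakpoint-split /
    expand-to-singletons extensions, where a gene may recur.
    """

    entries: list[MatchEntry] = field(default_factory=list)
    unmatched_genes: list[int] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def matched_gene_indices(self) -> list[int]:
        return [e.gene_index for e in self.entries]

    def matched_gene_set(self) -> set[int]:
        return set(e.gene_index for e in self.entries)


@dataclass
class MatchedPair:
    """Row-aligned (CN summary, expression) dataset ready for cis analysis.

    Row ``i`` of ``cn_summary`` and of ``expression`` refer to the same match
    entry. ``provenance`` is a pandas DataFrame with one row per entry:
    gene_id, matched cn_ids ('|'-separated), weights ('|'-separated), so
    downstream multiplicity corrections can count genes recurring under the
    split/expand extensions.
    """

    cn_summary: CopyNumberSet
    expression: ExpressionSet
    provenance: "object"  # pandas.DataFrame; untyped to keep pandas import lazy

    def __post_init__(self):
        if self.cn_summary.n_features != self.expression.n_features:
            raise ValueError(
                "cn_summary and expression must be row-aligned: "
                f"{self.cn_summary.n_features} vs {self.expression.n_features} rows"
            )

    @property
    def n_rows(self) -> int:
        return self.cn_summary.n_features
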