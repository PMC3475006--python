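"""Seeded generator of paired copy number / expression platforms.

The generator emulates the data model the matching procedures assume: a copy
number (aCGH) platform of non-overlapping probes laid out along chromosomes,
carrying piecewise-constant segmented log2 ratios (per-sample aberration
states over shared segment borders), noisy normalized ratios, and discrete
calls; and an expression platform of genes whose expression optionally
carries a cis dosage effect (a linear term in the local segmented value) for
a configurable fraction of genes. Ground truth — each gene's cis status and
the CN probes genomically overlapping it — is returned alongside.

Two probe layouts are available, mirroring the two array generations found
in real studies: short dense "oligo" probes (~60 bp, Agilent 244K-like) and
long sparse "bac" clones (~150 kb), whose midpoints can sit far from any
gene's midpoint and thereby defeat narrow-window distance matching.

All randomness flows from a single ``SimConfig.seed`` through one
``numpy.random.default_rng`` stream; identical configurations therefore
produce identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .matching import ConfigurationError
from .model import CopyNumberSet, ExpressionSet, FeatureAnnotation

__all__ = ["SimConfig", "simulate_platforms", "bac_like_config", "with_seed"]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a simulated paired-platform dataset.

    Defaults describe an oligo-era study: 4 chromosomes of 10 Mb, 2000 short
    CN probes (~20 kb spacing), 500 genes of median length 20 kb, 30 samples,
    8 copy number segments per chromosome with aberration levels on the log2
    scale (loss -0.45, normal 0, gain 0.45, amplification 0.9), measurement
    noise of 0.15 on the normalized ratios, and a cis-effect of slope 0.8 on
    30% of genes with expression noise 0.3.
    """

    n_chromosomes: int = 4
    chrom_length: int = 10_000_000
    n_cn_features: int = 2000
    probe_mode: str = "oligo"  # "oligo" (~60 bp) or "bac" (~150 kb)
    oligo_length: int = 60
    bac_length_mean: float = 150_000.0
    bac_length_sd: float = 15_000.0
    n_ge_features: int = 500
    gene_length_median: float = 20_000.0
    gene_length_sigma: float = 0.8  # lognormal shape
    n_samples: int = 30
    n_segments: int = 8
    segment_levels: tuple[float, ...] = (-0.45, 0.0, 0.45, 0.9)
    segment_probs: tuple[float, ...] = (0.15, 0.60, 0.20, 0.05)
    noise_sd: float = 0.15
    call_thresholds: tuple[float, float, float] = (-0.225, 0.225, 0.675)
    cis_fraction: float = 0.3
    beta: float = 0.8
    expression_baseline_mean: float = 7.0
    expression_baseline_sd: float = 1.0
    expression_noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self):
        for name in (
            "n_chromosomes",
            "chrom_length",
            "n_cn_features",
            "n_ge_features",
            "n_samples",
            "n_segments",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if not (0.0 <= self.cis_fraction <= 1.0):
            raise ConfigurationError("cis_fraction must lie in [0, 1]")
        if self.probe_mode not in ("oligo", "bac"):
            raise ConfigurationError("probe_mode must be 'oligo' or 'bac'")
        if len(self.segment_levels) != len(self.segment_probs):
            raise ConfigurationError("segment_levels and segment_probs length mismatch")
        if abs(sum(self.segment_probs) - 1.0) > 1e-9:
            raise ConfigurationError("segment_probs must sum to 1")


def bac_like_config(**overrides) -> SimConfig:
    """A sparse long-clone layout (BAC-era array): ~1.5 Mb probe spacing.

    Probe midpoints then typically sit hundreds of kilobases from gene
    midpoints, so narrow-window distance matching succeeds for only a small
    fraction of genes — the qualitative behaviour of early BAC datasets.
    """
    base = dict(
        n_chromosomes=2,
        chrom_length=30_000_000,
        n_cn_features=40,
        probe_mode="bac",
        n_ge_features=500,
    )
    base.update(overrides)
    return SimConfig(**base)


def _place_probes(cfg: SimConfig, rng: np.random.Generator) -> list[FeatureAnnotation]:
    """Non-overlapping sorted probes, one slot per probe along each chromosome."""
    per_chrom = _split_count(cfg.n_cn_features, cfg.n_chromosomes)
    features: list[FeatureAnnotation] = []
    counter = 0
    for c in range(cfg.n_chromosomes):
        n = per_chrom[c]
        if n == 0:
            continue
        spacing = cfg.chrom_length / n
        if cfg.probe_mode == "oligo":
            lengths = np.full(n, cfg.oligo_length, dtype=float)
        else:
            lengths = np.clip(
                rng.normal(cfg.bac_length_mean, cfg.bac_length_sd, size=n),
                1000.0,
                None,
            )
        if (lengths >= spacing).any():
            raise ConfigurationError(
                f"probe layout infeasible: longest probe ({lengths.max():.0f} bp) "
                f"does not fit the per-probe slot ({spacing:.0f} bp); "
                "reduce n_cn_features or probe length, or enlarge chrom_length"
            )
        slack = spacing - lengths
        starts = (np.arange(n) * spacing + rng.uniform(0.0, 1.0, size=n) * slack).astype(int) + 1
        ends = starts + lengths.astype(int) - 1
        for s, e in zip(starts, ends):
            counter += 1
            features.append(
                FeatureAnnotation(f"cn_{counter:05d}", str(c + 1), int(s), int(min(e, cfg.chrom_length)))
            )
    return features


def _place_genes(cfg: SimConfig, rng: np.random.Generator) -> list[FeatureAnnotation]:
    per_chrom = _split_count(cfg.n_ge_features, cfg.n_chromosomes)
    features: list[FeatureAnnotation] = []
    counter = 0
    max_len = cfg.chrom_length // 4
    for c in range(cfg.n_chromosomes):
        n = per_chrom[c]
        lengths = np.clip(
            rng.lognormal(np.log(cfg.gene_length_median), cfg.gene_length_sigma, size=n),
            200.0,
            max_len,
        ).astype(int)
        starts = rng.integers(1, cfg.chrom_length - lengths + 1)
        order = np.argsort(starts, kind="stable")
        for k in order:
            counter += 1
            features.append(
                FeatureAnnotation(
                    f"ge_{counter:05d}", str(c + 1), int(starts[k]), int(starts[k] + lengths[k] - 1)
                )
            )
    return features


def _split_count(total: int, parts: int) -> list[int]:
    base, rem = divmod(total, parts)
    return [base + (1 if i < rem else 0) for i in range(parts)]


def _segment_borders(cfg: SimConfig, rng: np.random.Generator) -> list[np.ndarray]:
    """Per chromosome: sorted interior borders (shared by all samples)."""
    borders = []
    for _ in range(cfg.n_chromosomes):
        if cfg.n_segments == 1:
            borders.append(np.array([], dtype=float))
        else:
            cuts = np.sort(rng.uniform(1, cfg.chrom_length, size=cfg.n_segments - 1))
            borders.append(cuts)
    return borders


def _segment_of(positions: np.ndarray, cuts: np.ndarray) -> np.ndarray:
    return np.searchsorted(cuts, positions, side="right")


def _call_matrix(segmented: np.ndarray, thresholds: Sequence[float]) -> np.ndarray:
    loss, gain, amp = thresholds
    calls = np.zeros_like(segmented)
    calls[segmented <= loss] = -1
    calls[segmented >= gain] = 1
    calls[segmented >= amp] = 2
    return calls


def simulate_platforms(
    cfg: SimConfig,
) -> tuple[CopyNumberSet, ExpressionSet, pd.DataFrame]:
    """Simulate a paired (copy number, expression) dataset with ground truth.

    Returns
    -------
    cn : CopyNumberSet
        Sorted non-overlapping probes; segmented rows piecewise constant over
        shared per-chromosome segment borders with per-sample aberration
        states; ``normalized = segmented + N(0, noise_sd)``; calls by
        thresholding the segmented values (loss/gain/amplification cutpoints;
        the double-loss level -2 is reserved but not emitted).
    ge : ExpressionSet
        Genes with ``expression = baseline + beta * segmented(own locus)``
        plus noise for cis genes, baseline plus noise otherwise.
    truth : pandas.DataFrame
        One row per gene: ``gene_id``, ``is_cis``, and ``true_cn_ids`` — the
        '|'-joined IDs of CN probes genomically overlapping the gene.
    """
    rng = np.random.default_rng(cfg.seed)
    samples = [f"sample_{i + 1:03d}" for i in range(cfg.n_samples)]

    probes = _place_probes(cfg, rng)
    genes = _place_genes(cfg, rng)
    borders = _segment_borders(cfg, rng)

    # per (chromosome, segment, sample): an aberration level
    levels = np.asarray(cfg.segment_levels)
    seg_state = rng.choice(
        len(levels),
        size=(cfg.n_chromosomes, cfg.n_segments, cfg.n_samples),
        p=np.asarray(cfg.segment_probs),
    )
    seg_level = levels[seg_state]  # (chrom, segment, sample)

    def dosage_rows(features: list[FeatureAnnotation]) -> np.ndarray:
        rows = np.empty((len(features), cfg.n_samples))
        for i, f in enumerate(features):
            c = int(f.chromosome) - 1
            s = int(_segment_of(np.array([f.midpoint]), borders[c])[0])
            rows[i] = seg_level[c, s]
        return rows

    segmented = dosage_rows(probes)
    normalized = segmented + rng.normal(0.0, cfg.noise_sd, size=segmented.shape)
    calls = _call_matrix(segmented, cfg.call_thresholds)
    cn = CopyNumberSet(probes, samples, normalized, segmented, calls)

    gene_dosage = dosage_rows(genes)
    n_cis = int(round(cfg.cis_fraction * len(genes)))
    cis_flags = np.zeros(len(genes), dtype=bool)
    cis_flags[rng.choice(len(genes), size=n_cis, replace=False)] = True
    baseline = rng.normal(
        cfg.expression_baseline_mean, cfg.expression_baseline_sd, size=len(genes)
    )
    expression = (
        baseline[:, None]
        + cfg.beta * gene_dosage * cis_flags[:, None]
        + rng.normal(0.0, cfg.expression_noise_sd, size=gene_dosage.shape)
    )
    ge = ExpressionSet(genes, samples, expression)

    truth = pd.DataFrame(
        {
            "gene_id": [g.feature_id for g in genes],
            "chromosome": [g.chromosome for g in genes],
            "start": [g.start for g in genes],
            "end": [g.end for g in genes],
            "is_cis": cis_flags,
            "true_cn_ids": [
                "|".join(
                    p.feature_id
                    for p in probes
                    if p.chromosome == g.chromosome
                    and min(p.end, g.end) >= max(p.start, g.start)
                )
                for g in genes
            ],
        }
    )
    return cn, ge, truth


def with_seed(cfg: SimConfig, seed: int) -> SimConfig:
    """Copy of a configuration with a different seed."""
    return replace(cfg, seed=seed)
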