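import numpy as np
import pytest

from cnmatch import CopyNumberSet, ExpressionSet, FeatureAnnotation, load_example_locus


@pytest.fixture(scope="session")
def example_locus():
    """The packaged chr14 worked-example locus: (gene, 25 CN probes)."""
    return load_example_locus()


def random_features(rng, n, prefix, n_chrom=2, span=1_000_000, max_length=50_000):
    """Random annotated features on `n_chrom` chromosomes, unsorted."""
    feats = []
    for i in range(n):
        chrom = str(rng.integers(1, n_chrom + 1))
        length = int(rng.integers(1, max_length + 1))
        start = int(rng.integers(1, span - length + 1))
        feats.append(FeatureAnnotation(f"{prefix}{i:04d}", chrom, start, start + length - 1))
    return feats


def random_instance(rng, n_probes=None, n_genes=None):
    """One random matching instance: (cn probes, genes), unsorted input order."""
    n_probes = n_probes or int(rng.integers(1, 201))
    n_genes = n_genes or int(rng.integers(1, 51))
    probes = random_features(rng, n_probes, "cn", max_length=5_000)
    genes = random_features(rng, n_genes, "ge", max_length=50_000)
    return probes, genes


def make_cn_set(features, n_samples=3, rng=None, seg_values=(-0.5, 0.0, 0.5)):
    """CopyNumberSet over given features with random low-cardinality segmented data.

    Segmented values are drawn from a small set so that equal and unequal
    flanking rows (breakpoints) both occur with useful probability.
    """
    rng = rng or np.random.default_rng(0)
    n = len(features)
    segmented = rng.choice(np.asarray(seg_values), size=(n, n_samples))
    normalized = segmented + rng.normal(0, 0.1, size=(n, n_samples))
    calls = np.sign(segmented)
    return CopyNumberSet(features, [f"s{i}" for i in range(n_samples)],
                         normalized, segmented, calls)


def make_ge_set(features, n_samples=3, rng=None):
    rng = rng or np.random.default_rng(1)
    expr = rng.normal(7.0, 1.0, size=(len(features), n_samples))
    return ExpressionSet(features, [f"s{i}" for i in range(n_samples)], expr)
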