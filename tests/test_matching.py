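"""Matching procedures against exhaustive oracles and the worked-example locus."""

import numpy as np
import pytest

from cnmatch import (
    ConfigurationError,
    FeatureAnnotation,
    match_distance,
    match_distance_any,
    match_label,
    match_overlap,
    match_overlap_any,
    match_overlap_plus,
    midpoint_distance,
    overlap_fraction,
)

from conftest import make_cn_set, random_instance


# ---------------------------------------------------------------------------
# naive exhaustive oracles (O(n*m), independent of the implementation)
# ---------------------------------------------------------------------------

def _tiebreak_key(f):
    return (f.start, f.end, f.feature_id)


def oracle_distance(probes, genes):
    out = {}
    for g, gene in enumerate(genes):
        cands = [(i, p) for i, p in enumerate(probes) if p.chromosome == gene.chromosome]
        if not cands:
            continue
        best = min(cands, key=lambda ip: (midpoint_distance(gene, ip[1]),) + _tiebreak_key(ip[1]))
        out[g] = {best[0]: 1.0}
    return out


def oracle_distance_any(probes, genes, window, offset=1.0):
    out = {}
    for g, gene in enumerate(genes):
        raw = {
            i: 1.0 / (midpoint_distance(gene, p) + offset)
            for i, p in enumerate(probes)
            if p.chromosome == gene.chromosome and midpoint_distance(gene, p) < window
        }
        if raw:
            total = sum(raw.values())
            out[g] = {i: w / total for i, w in raw.items()}
    return out


def oracle_overlap(probes, genes):
    out = {}
    for g, gene in enumerate(genes):
        cands = [
            (i, p) for i, p in enumerate(probes)
            if p.chromosome == gene.chromosome and overlap_fraction(gene, p) > 0
        ]
        if not cands:
            continue
        best = min(cands, key=lambda ip: (-overlap_fraction(gene, ip[1]),) + _tiebreak_key(ip[1]))
        out[g] = {best[0]: 1.0}
    return out


def oracle_overlap_any(probes, genes, min_fraction=0.0):
    out = {}
    for g, gene in enumerate(genes):
        raw = {
            i: overlap_fraction(gene, p)
            for i, p in enumerate(probes)
            if p.chromosome == gene.chromosome and overlap_fraction(gene, p) > min_fraction
        }
        if raw:
            total = sum(raw.values())
            out[g] = {i: w / total for i, w in raw.items()}
    return out


def oracle_overlap_plus(cn, genes):
    probes = cn.features
    out = oracle_overlap(probes, genes)
    for g, gene in enumerate(genes):
        if g in out:
            continue
        cands = [(i, p) for i, p in enumerate(probes) if p.chromosome == gene.chromosome]
        down = [(i, p) for i, p in cands if p.midpoint < gene.midpoint]
        up = [(i, p) for i, p in cands if p.midpoint > gene.midpoint]
        if not down or not up:
            continue
        lo_mid = max(p.midpoint for _, p in down)
        hi_mid = min(p.midpoint for _, p in up)
        lo = min((ip for ip in down if ip[1].midpoint == lo_mid),
                 key=lambda ip: _tiebreak_key(ip[1]))
        hi = min((ip for ip in up if ip[1].midpoint == hi_mid),
                 key=lambda ip: _tiebreak_key(ip[1]))
        if not np.allclose(cn.segmented[lo[0]], cn.segmented[hi[0]], rtol=0, atol=1e-8):
            continue
        d_lo = midpoint_distance(gene, lo[1])
        d_hi = midpoint_distance(gene, hi[1])
        out[g] = {lo[0] if d_lo <= d_hi else hi[0]: 1.0}
    return out


def as_dict(match_map):
    return {
        e.gene_index: dict(zip(e.cn_indices, e.weights)) for e in match_map.entries
    }


def assert_same_matching(result, expected):
    got = as_dict(result)
    assert got.keys() == expected.keys()
    for g in expected:
        assert got[g].keys() == expected[g].keys()
        for i, w in expected[g].items():
            assert got[g][i] == pytest.approx(w, abs=1e-12)


# ---------------------------------------------------------------------------
# oracle equivalence on random instances
# ---------------------------------------------------------------------------

N_ORACLE_INSTANCES = 40  # per procedure here; the full 200-instance sweep
# runs in the acceptance suite


@pytest.mark.parametrize("seed", range(N_ORACLE_INSTANCES))
def test_distance_matches_oracle(seed):
    rng = np.random.default_rng(seed)
    probes, genes = random_instance(rng)
    assert_same_matching(match_distance(probes, genes), oracle_distance(probes, genes))


@pytest.mark.parametrize("seed", range(N_ORACLE_INSTANCES))
def test_distance_any_matches_oracle(seed):
    rng = np.random.default_rng(100 + seed)
    probes, genes = random_instance(rng)
    window = float(rng.choice([1_000, 10_000, 100_000]))
    assert_same_matching(
        match_distance_any(probes, genes, window=window),
        oracle_distance_any(probes, genes, window),
    )


@pytest.mark.parametrize("seed", range(N_ORACLE_INSTANCES))
def test_overlap_matches_oracle(seed):
    rng = np.random.default_rng(200 + seed)
    probes, genes = random_instance(rng)
    assert_same_matching(match_overlap(probes, genes), oracle_overlap(probes, genes))


@pytest.mark.parametrize("seed", range(N_ORACLE_INSTANCES))
def test_overlap_any_matches_oracle(seed):
    rng = np.random.default_rng(300 + seed)
    probes, genes = random_instance(rng)
    frac = float(rng.choice([0.0, 0.1, 0.5]))
    assert_same_matching(
        match_overlap_any(probes, genes, min_fraction=frac),
        oracle_overlap_any(probes, genes, frac),
    )


@pytest.mark.parametrize("seed", range(N_ORACLE_INSTANCES))
def test_overlap_plus_matches_oracle(seed):
    rng = np.random.default_rng(400 + seed)
    probes, genes = random_instance(rng)
    cn = make_cn_set(probes, n_samples=2, rng=rng)
    assert_same_matching(match_overlap_plus(cn, genes), oracle_overlap_plus(cn, genes))


# ---------------------------------------------------------------------------
# worked-example locus
# ---------------------------------------------------------------------------

def test_example_locus_selections(example_locus):
    gene, probes = example_locus
    starts = lambda m: sorted(probes[i].start for i in m.entries[0].cn_indices)

    assert starts(match_distance(probes, [gene])) == [38609230]
    assert starts(match_overlap(probes, [gene])) == [38571564]
    assert starts(match_distance_any(probes, [gene], window=10_000)) == [
        38597108, 38602277, 38609230, 38614898,
    ]
    assert starts(match_distance_any(probes, [gene], window=100_000)) == sorted(
        p.start for p in probes
    )
    assert starts(match_overlap_any(probes, [gene])) == [
        38571564, 38581765, 38587626, 38597108, 38602277,
        38609230, 38614898, 38626492, 38631536, 38639169,
    ]
    # overlapPlus: overlap already matched the gene, so the result is identical
    cn = make_cn_set(probes, n_samples=2)
    assert starts(match_overlap_plus(cn, [gene])) == [38571564]


def test_example_locus_distance_any_weights_decrease_with_distance(example_locus):
    gene, probes = example_locus
    m = match_distance_any(probes, [gene], window=10_000)
    e = m.entries[0]
    dist = [midpoint_distance(gene, probes[i]) for i in e.cn_indices]
    order = np.argsort(dist)
    w = np.asarray(e.weights)[order]
    assert (np.diff(w) < 0).all()
    assert sum(e.weights) == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# procedure-specific behaviour
# ---------------------------------------------------------------------------

def test_distance_matches_every_gene_when_chromosome_covered():
    probe = [FeatureAnnotation("p", "5", 1000, 1059)]
    genes = [FeatureAnnotation(f"g{i}", "5", 10_000 * (i + 1), 10_000 * (i + 1) + 99)
             for i in range(10)]
    m = match_distance(probe, genes)
    assert m.matched_gene_set() == set(range(10))
    assert all(e.cn_indices == (0,) for e in m.entries)


def test_distance_reports_unmatched_chromosome_and_far_matches():
    probes = [FeatureAnnotation("p", "1", 100, 159)]
    genes = [
        FeatureAnnotation("near", "1", 200, 400),
        FeatureAnnotation("far", "1", 5_000_000, 5_000_200),
        FeatureAnnotation("off", "2", 100, 200),
    ]
    m = match_distance(probes, genes)
    assert m.unmatched_genes == [2]
    assert len(m.notes) == 1 and "far" in m.notes[0]


def test_distance_any_zero_distance_weight_before_normalization():
    probe = [FeatureAnnotation("p", "1", 100, 200)]
    gene = [FeatureAnnotation("g", "1", 100, 200)]  # identical midpoint
    m = match_distance_any(probe, gene, window=1_000, offset=1.0)
    assert m.entries[0].weights == (1.0,)  # raw 1/(0+1), alone in the window


@pytest.mark.parametrize("window,offset", [(0, 1), (-5, 1), (100, 0), (100, -1)])
def test_distance_any_rejects_bad_parameters(window, offset):
    with pytest.raises(ConfigurationError):
        match_distance_any([], [], window=window, offset=offset)


def test_overlap_any_rejects_bad_threshold():
    with pytest.raises(ConfigurationError):
        match_overlap_any([], [], min_fraction=1.0)


def test_overlap_empty_across_chromosomes():
    probes = [FeatureAnnotation("p", "1", 100, 200)]
    genes = [FeatureAnnotation("g", "2", 100, 200)]
    m = match_overlap(probes, genes)
    assert len(m) == 0 and m.unmatched_genes == [0]


def test_overlap_plus_interpolates_only_without_breakpoint():
    probes = [
        FeatureAnnotation("left", "1", 1_000, 1_059),
        FeatureAnnotation("right", "1", 9_000, 9_059),
    ]
    gene = [FeatureAnnotation("g", "1", 4_000, 4_500)]  # uncovered, nearer to left
    seg_equal = np.array([[0.5, 0.0], [0.5, 0.0]])
    seg_break = np.array([[0.5, 0.0], [0.5, 0.4]])  # one sample differs

    cn = make_cn_set(probes, n_samples=2)
    cn.segmented = seg_equal
    m = match_overlap_plus(cn, gene)
    assert as_dict(m) == {0: {0: 1.0}}  # matched to nearer flank

    cn.segmented = seg_break
    m = match_overlap_plus(cn, gene)
    assert len(m) == 0 and m.unmatched_genes == [0]


def test_overlap_plus_single_flank_stays_unmatched():
    probes = [FeatureAnnotation("only", "1", 1_000, 1_059)]
    gene = [FeatureAnnotation("g", "1", 5_000, 5_500)]
    cn = make_cn_set(probes, n_samples=2)
    m = match_overlap_plus(cn, gene)
    assert len(m) == 0 and m.unmatched_genes == [0]


def test_overlap_plus_requires_copynumber_set(example_locus):
    gene, probes = example_locus
    with pytest.raises(ConfigurationError):
        match_overlap_plus(probes, [gene])


# ---------------------------------------------------------------------------
# label matching
# ---------------------------------------------------------------------------

def test_label_one_to_one():
    m = match_label(["x"], ["A"], {"x": "GS1"}, {"A": "GS1"})
    assert as_dict(m) == {0: {0: 1.0}}


def test_label_many_to_one_uniform_weights():
    m = match_label(["x", "y"], ["A"], {"x": "GS1", "y": "GS1"}, {"A": "GS1"})
    assert as_dict(m) == {0: {0: 0.5, 1: 0.5}}


def test_label_disjoint_descriptors_unmatched():
    m = match_label(["x"], ["A"], {"x": "GS2"}, {"A": "GS1"})
    assert len(m) == 0 and m.unmatched_genes == [0]


def test_label_empty_maps_empty_result():
    m = match_label(["x"], ["A"], {}, {})
    assert len(m) == 0


def test_label_strict_chromosome_drops_cross_chromosome_links():
    cn_feats = [FeatureAnnotation("x", "1", 1, 10)]
    ge_feats = [FeatureAnnotation("A", "2", 1, 10)]
    loose = match_label(["x"], ["A"], {"x": "GS1"}, {"A": "GS1"})
    assert len(loose) == 1
    strict = match_label(
        ["x"], ["A"], {"x": "GS1"}, {"A": "GS1"},
        cn_features=cn_feats, ge_features=ge_feats, strict_chromosome=True,
    )
    assert len(strict) == 0


# ---------------------------------------------------------------------------
# cross-procedure invariants
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("seed", range(25))
def test_overlap_and_overlap_any_match_same_genes(seed):
    rng = np.random.default_rng(500 + seed)
    probes, genes = random_instance(rng)
    assert (
        match_overlap(probes, genes).matched_gene_set()
        == match_overlap_any(probes, genes, 0.0).matched_gene_set()
    )


@pytest.mark.parametrize("seed", range(25))
def test_overlap_matches_subset_of_overlap_plus(seed):
    rng = np.random.default_rng(600 + seed)
    probes, genes = random_instance(rng)
    cn = make_cn_set(probes, n_samples=2, rng=rng)
    assert match_overlap(probes, genes).matched_gene_set() <= \
        match_overlap_plus(cn, genes).matched_gene_set()


@pytest.mark.parametrize("seed", range(10))
def test_results_invariant_under_input_permutation(seed):
    rng = np.random.default_rng(700 + seed)
    probes, genes = random_instance(rng, n_probes=60, n_genes=20)
    perm = rng.permutation(len(probes))
    shuffled = [probes[i] for i in perm]

    def identity_map(m, feats):
        return {
            genes[e.gene_index].feature_id: {
                (feats[i].feature_id) : round(w, 12)
                for i, w in zip(e.cn_indices, e.weights)
            }
            for e in m.entries
        }

    for fn in (
        lambda cn, ge: match_distance(cn, ge),
        lambda cn, ge: match_distance_any(cn, ge, window=50_000),
        lambda cn, ge: match_overlap(cn, ge),
        lambda cn, ge: match_overlap_any(cn, ge),
    ):
        assert identity_map(fn(probes, genes), probes) == identity_map(
            fn(shuffled, genes), shuffled
        )
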