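# cnmatch

Matching of array CGH (aCGH) copy number features to gene or microRNA
expression features, for integrative genomic analysis.

## The problem

Cancer genomes carry copy number aberrations whose gene-dosage changes can
drive expression changes in the genes they span (*cis*-effects). Studying
this requires, for every expression probe, the copy number signature of its
locus — but when the two molecular levels are measured on different array
platforms, their features interrogate different genomic intervals and must
first be *matched*, and the data of multiply matched copy number probes must
be *summarized*. How this preprocessing is done is rarely reported, yet it
changes which genes enter the downstream analysis and, occasionally, their
results.

`cnmatch` is for bioinformaticians preparing paired copy-number/expression
datasets. It implements six matching procedures, three summarization
extensions, a gene-wise cis-correlation stage, and a seeded simulator of
paired platforms for validation.

## The procedures

Each expression feature (a "gene" $g$ with interval $[s_g, e_g]$ on a
chromosome) is assigned a set of copy number features $j$ with weights
$w_{gj}$, $\sum_j w_{gj} = 1$:

- **label** — both platforms' IDs are mapped to a common descriptor set
  (e.g. gene symbols); features sharing a descriptor match, weights uniform.
- **distance** — with midpoints $m = (s + e)/2$, the gene is matched to the
  single feature minimizing $|m_j - m_g|$ (winner-takes-all).
- **distanceAny** — all features with $|m_j - m_g| < w$ (window $w$) match,
  with weights $\propto 1/(|m_j - m_g| + \delta)$; the offset $\delta$
  (default 1 bp) keeps a zero-distance feature's weight finite.
- **overlap** — the gene is matched to the feature maximizing the overlap
  fraction $o_{gj} = \text{overlapping bp} / \text{length of CN probe } j$,
  provided it is positive.
- **overlapAny** — all features with $o_{gj}$ above a threshold match, with
  weights $\propto o_{gj}$.
- **overlapPlus** — overlap matching, then interpolation for genes in
  regions the CN platform does not cover: if no sample shows a breakpoint
  (a change in the segmented value) between the two flanking CN features,
  the nearer flank's dosage is assigned; otherwise the gene stays unmatched.

Multi-feature matches are summarized per sample by the weighted mean of the
normalized and segmented data (calls follow the dominant-weight feature), or
by three extensions: the most aberrant segmented signal per sample
(`maximum_summary`), splitting matched sets at within-set breakpoints
(`split_at_breakpoints`), or expanding them to singletons
(`expand_to_single`) — under the last two a gene may recur in the matched
dataset, which the provenance table records for multiplicity corrections.

Downstream, `cis_correlations` computes per-gene Spearman rank correlations
between expression and the segmented copy number signature, with
Benjamini–Hochberg FDR control, and `pairwise_win_counts` compares matching
procedures by counting which yields the higher cis-correlation per gene.

## Worked example

The package ships a real worked instance: expression probe `A_23_P140170`
(chr14:38,570,874–38,642,188, Agilent) with the 25 surrounding probes of an
Agilent 244K aCGH layout.

```python
import cnmatch as cm

gene, probes = cm.load_example_locus()
m = cm.match_distance(probes, [gene])
print(probes[m.entries[0].cn_indices[0]].start)   # 38609230
m = cm.match_overlap(probes, [gene])
print(probes[m.entries[0].cn_indices[0]].start)   # 38571564
m = cm.match_distance_any(probes, [gene], window=10_000)
print(sorted(probes[i].start for i in m.entries[0].cn_indices))
# [38597108, 38602277, 38609230, 38614898]
```

Distance matching picks the probe nearest the gene's midpoint (start
38,609,230); overlap matching picks the leftmost of the ten probes fully
contained in the gene (38,571,564, all tied at overlap fraction 1);
distanceAny with a 10 kb window keeps the four probes whose midpoints lie
within 10 kb of the gene's.

A full simulated pipeline:

```python
import cnmatch as cm

cn, ge, truth = cm.simulate_platforms(cm.SimConfig(seed=42))
pair = cm.weighted_summary(cn, ge, cm.match_overlap_any(cn, ge))
res = cm.cis_frame(pair)
print(len(pair.provenance), int(res["significant"].sum()))
```

With the default configuration (500 genes, 30 samples, a cis slope of 0.8 on
30% of genes) and seed 42 this matches 365 of 500 genes (1.88 CN probes per
gene on average) and finds 113 significant cis genes at BH-adjusted 0.05;
cis genes reach a mean |rho| of 0.64 versus 0.15 for non-cis genes.

The same workflow is available from the shell:

```sh
cnmatch simulate --seed 42 --out-dir sim/
cnmatch match --method overlapAny \
    --cn-annotation sim/cn_annotation.tsv --cn-normalized sim/cn_normalized.tsv \
    --cn-segmented sim/cn_segmented.tsv --cn-calls sim/cn_calls.tsv \
    --ge-annotation sim/ge_annotation.tsv --ge-expression sim/expression.tsv \
    --out-dir matched/
cnmatch cis --bundle matched/ --out cis.tsv
```

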