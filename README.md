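# spiralcompare

Cross-species comparison of developmental transcriptome time courses for
spiral-cleaving embryos.

Spiralian embryos (annelids, molluscs and relatives) share a famously
stereotyped early cleavage program, yet different lineages specify their
embryonic organiser at very different times.  `spiralcompare` implements the
computational side of asking what that means at the transcriptome level: given
two species' staged bulk RNA-seq time courses (oocyte → gastrula, in
replicates) and their orthology map, it quantifies when the two transcriptomes
are most similar, which temporal coexpression programs correspond across
species, and which orthologs have shifted their activation timing
(heterochrony).  It is aimed at evo-devo groups with matched developmental
RNA-seq in two species and an OrthoFinder run — everything downstream of the
expression matrices lives here.

## What it computes

- **Expression core** — TPM/count matrices bound to an ordered stage design;
  expressed-gene calls (stage-mean TPM > 2 by default, or a data-driven cutoff
  from the inflexion/valley of the log2 TPM density); replicate correlation,
  PCA variance decomposition, hierarchical sample grouping, optional log-space
  batch centering.
- **Differential expression** — a compact negative-binomial Wald stage for
  adjacent-stage contrasts: median-of-ratios size factors s_j, per-gene
  dispersion α̂ by method of moments shrunk toward a fitted mean–dispersion
  trend, LFC = log2((μ̂₁+½)/(μ̂₀+½)) with delta-method SE from
  Var(K) = μ + αμ², Benjamini–Hochberg adjustment, and a log2 fold-change
  call cutoff of 0.
- **Temporal clustering** — Mfuzz-style fuzzy c-means on z-scored stage-mean
  profiles, minimising Σᵢⱼ u(i,j)^m ‖xᵢ − cⱼ‖² with the Schwämmle–Jensen
  fuzzifier m; the cluster number k is chosen by the Calinski–Harabasz index on
  centroid-linkage hierarchical partitions; clusters get biological category
  labels (oocyte/zygote-specific, maternal decay, early/late zygotic,
  stage-specific, embryonic) from documented centroid-shape rules.
- **Stage divergence ("hourglass")** — for every stage pair across species,
  one-to-one ortholog stage-mean TPM vectors are quantile-transformed into
  probability distributions and compared with the Jensen–Shannon distance
  JSD(p,q) = √(½KL(p‖m) + ½KL(q‖m)), m = (p+q)/2, log base 2 — a metric on
  [0, 1].  The global minimum of the stage × stage matrix locates the most
  conserved (mid-developmental transition) period.
- **Heterochrony** — an ortholog's activation is the first stage whose mean
  TPM reaches the cutoff; activations are mapped across species on a
  stage-correspondence table (with excluded stages) and classified as
  `earlier_in_A` / `earlier_in_B` / `same` / `inactive` / `unscored`, with
  direction summaries and cluster-allocation tables.
- **Cluster correspondence** — orthogroup-level overlap between every cluster
  pair across species, upper-tail hypergeometric p-values, BH adjustment,
  −log10 tables; plus one-to-one ortholog cluster-flow contingency tables
  with percentages.
- **Annotation statistics** — upper-tail Fisher GO enrichment against a
  declared universe; KEGG-style pathway enrichment with the conventional
  p < 0.05 / q < 0.5 reporting filter; phylostratum composition per cluster
  and per-stage quantile-normalised age × stage expression summaries; codon
  usage per gene set and per-codon log2 frequency ratios between clusters.
- **Synthetic data** — a fully seeded two-species embryo-transcriptome
  generator with planted cluster structure, maternal decay waves, zygotic
  genome activation, a conservation peak at a configurable stage, planted
  activation shifts, phylostratum labels, GO signatures and codon bias — with
  a machine-readable truth table, so every stage of the pipeline is testable
  as a parameter-recovery problem without any downloads.

## Worked example

```python
from spiralcompare import SimulationConfig, generate_dataset
from spiralcompare.expression import stage_means, ThresholdSpec, expressed_counts_per_stage
from spiralcompare.clustering import standardize_profiles, select_k, fuzzy_cmeans, categorize_clusters
from spiralcompare.orthology import stage_divergence, min_divergence_profile
from spiralcompare.heterochrony import StageCorrespondence, call_heterochrony, shift_direction_summary

ds = generate_dataset(SimulationConfig(n_genes_per_species=2000, seed=42))
sm_a, sm_b = stage_means(ds.tpm_a), stage_means(ds.tpm_b)

print(expressed_counts_per_stage(ds.tpm_a, ThresholdSpec(2.0)).to_string())

z = standardize_profiles(sm_a)
k = select_k(z, seed=42)
fc = fuzzy_cmeans(z, k=k, seed=42)
print("chosen k =", k, "| categories:", sorted(categorize_clusters(fc).values()))

div = stage_divergence(sm_a, sm_b, ds.truth.pairs)
profile, argmin = min_divergence_profile(div)
print("most similar stage pair:", argmin, "| JSD =", round(div.raw.loc[argmin], 4))

corr = StageCorrespondence.positional(ds.truth.stages, ds.truth.stages)
calls = call_heterochrony(sm_a, sm_b, ds.truth.pairs[["orthogroup", "gene_a", "gene_b"]],
                          corr, ThresholdSpec(2.0, inclusive=True), ThresholdSpec(2.0, inclusive=True))
print(shift_direction_summary(calls).to_string())
```

prints

```
oocyte       600
zygote       602
2cell        922
4cell        692
8cell        965
16cell      1401
32cell      1401
64cell      1401
gastrula    1401
chosen k = 5 | categories: ['early_zygotic', 'embryonic', 'late_zygotic', 'maternal_decay', 'oocyte_zygote_specific']
most similar stage pair: ('gastrula', 'gastrula') | JSD = 0.0787
                n  percent_of_shifted
shift_class                          
earlier_in_A    4                1.65
earlier_in_B  238               98.35
same          958                 NaN
inactive        0                 NaN
unscored        0                 NaN
```

Reading the output: the expressed-gene series is flat through early cleavage
and rises from the 16-cell stage — the zygotic genome switching on; k = 5
temporal clusters are found and labelled; the stage-divergence minimum falls
on the gastrula/gastrula pair (the planted "hourglass waist"); and of the
ortholog pairs with an activation-timing shift, 98% activate earlier in
species B, matching the planted shift direction (20% of pairs displaced two
stages earlier in B).

The same pipeline runs end-to-end from one YAML config:

```bash
spiralcompare run --config run.yaml        # simulate/load → QC → DE → cluster → compare
spiralcompare simulate --out fixture/ --seed 1 --cds
spiralcompare compare --tpm-a a_tpm.tsv --design-a a_design.tsv \
    --tpm-b b_tpm.tsv --design-b b_design.tsv --orthogroups og.tsv --out cmp/
```

Every output table carries a provenance header (tool version, config hash,
seed), and identical config + seed reproduce the report bundle byte for byte.

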