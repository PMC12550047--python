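# Methods

This note documents the models and procedures implemented in
`spiralcompare`, the parameters that matter, the numerical choices, and what
the synthetic generator does and does not emulate.

## Expression model and expressed-gene calls

An `ExpressionMatrix` is a genes × samples table of non-negative abundances
tagged with its unit (`tpm` or `counts`) and bound to a `StageDesign` — an
ordered list of developmental stages plus a sample → (stage, replicate,
batch) map.  All stage-level analyses operate on stage means (the mean over
replicates), which is also the clustering input; per-replicate "expressed"
calls would be an alternative convention and can be emulated by passing a
single-replicate design.

A gene is *expressed* at a stage when its stage-mean TPM strictly exceeds
the cutoff (default 2 TPM).  Activation calls in the heterochrony module use
'≥' instead; both conventions appear in practice and are configurable via
`ThresholdSpec(inclusive=...)`.

`infer_activation_threshold` estimates a dataset-specific cutoff from the
density of log2 TPM over positive values: a Gaussian KDE (Silverman
bandwidth, 512-point grid over the observed range) is scanned right of the
mode for, in order of preference, (1) a local minimum whose right side
climbs by at least 5% — the noise/signal valley of a bimodal distribution —
or (2) the first sign change of the lightly smoothed second derivative —
the flank inflexion of an asymmetric unimodal distribution.  If neither
exists the fixed default (2 TPM) is returned with a fallback flag.  The
512-point grid and 9-point boxcar smoothing are reproducibility choices for
an otherwise under-determined "inflexion"; the method tag records which
path was taken.

Batch centering is deliberately simple: per gene, each batch's mean
log2(TPM+1) is shifted to the gene's grand mean and values are
inverse-transformed (clipped at zero).  For a two-batch design this is
equivalent to linear-model residualisation up to the intercept and avoids a
heavier dependency; it removes additive log-scale offsets only.

## Differential expression

The NB stage is a transparent approximation to the standard count-based
pipelines, sufficient to produce DEG lists for the comparative analyses:

- **Size factors**: median-of-ratios against the geometric-mean reference
  over genes positive in every sample.  When no such gene exists (fully
  stage-restricted transcriptomes), `method="poscounts"` pools ratios over
  positive entries only; `"auto"` falls back automatically.
- **Dispersion**: per-gene method of moments on normalized counts,
  α̂ = max(0, (s² − μ̄)/μ̄²), with the within-group variance pooled across
  stages, shrunk 50% toward a fitted trend α(μ) = a₀ + a₁/μ, then floored
  at 0.8× the trend.  The trend floor matters: at two replicates per group
  the moment estimator has ~2 degrees of freedom, and carrying its
  below-trend excursions into the Wald statistic makes the test
  anticonservative (empirically ~0.07 at nominal 0.05); with the floor the
  null rejection rate is 0.043–0.053 across seeds while the detection rate
  for 4-fold changes stays above 0.94.
- **Wald test**: LFC = log2((μ̂₁+½)/(μ̂₀+½)) on normalized group means;
  SE by the delta method from Var(K) = μ + αμ²; two-sided Gaussian p;
  independent filtering (mean normalized count ≥ 1) before BH.  The LFC
  call cutoff is 0 — any adjusted-significant change counts.

Not implemented, by design: Cox–Reid adjusted likelihoods, shrinkage LFC
estimators, outlier replacement, GLMs with covariates.

## Temporal clustering

Stage-mean profiles are z-scored per gene (constant genes dropped).  Fuzzy
c-means minimises Σ u^m‖x−c‖² by exact alternating updates; convergence is
declared when the largest centroid shift drops below 1e−6 (max 300
iterations), and both half-steps being exact minimisers makes the objective
non-increasing.  The fuzzifier defaults to the Schwämmle–Jensen estimate
m(N, D); hard assignments take the argmax membership when it reaches 0.5,
otherwise `unassigned`.  Initialisation is a deterministic 10-restart
k-means (k-means++ seeded) — a single k-means++ draw occasionally merges
the two maternal programs, and the restarts remove that failure mode while
keeping the determinism contract.

k is selected by the Calinski–Harabasz index computed on centroid-linkage
hierarchical partitions over k ∈ [2, 15] (ties → smallest k), mirroring the
common practice of choosing k with a hierarchical index and then running
the soft clustering at that k.  For large gene sets the index is evaluated
on a deterministic 2000-gene subsample; the CH optimum is stable under
subsampling of well-populated clusters.

Category rules (all thresholds in `CategoryRules`): a centroid peaking at
the last stage is `embryonic`; one that starts high (z > 0.5 at the first
stage) with its peak within the first two stages is maternal-type — split
into `oocyte_zygote_specific` if it drops below its mean by stage 2, else
`maternal_decay`; an interior peak with above-half-maximum width ≤ 2 stages
is `stage_specific:<stage>`; wider interior peaks are `early_zygotic` or
`late_zygotic` by peak position; near-flat centroids are `uncategorized`,
never guessed.  The "starts high" clause instead of "peaks first" is
deliberate: TPM is compositional, so genuinely decaying maternal
transcripts show a shallow realised peak a stage or two after the oocyte as
the rest of the pool clears.

## Cross-species divergence

For each stage pair, the one-to-one ortholog stage-mean TPM vectors
(ordered identically by pair) are converted to probability vectors by the
average-rank quantile transform r_i/Σr and compared with the
Jensen–Shannon distance (square root of the JS divergence, log base 2) — a
bounded metric, verified against its axioms by property tests.  Ranks
rather than raw quantile-mapped values make the statistic invariant to
monotone distortions of the TPM scale; average ranks resolve ties
deterministically.  The raw matrix is the quantity of record;
normalisation (whole-matrix min–max by default, row-wise optional) is a
display aid and, being monotone, preserves the global argmin.  Ties in the
argmin go to the earliest stage pair.

Cluster correspondence is tested in orthogroup units: the universe is the
set of orthogroups with at least one clustered gene in both species, a
cluster's set is the orthogroups containing any of its genes, and the
upper-tail hypergeometric p-value P[X ≥ overlap] is BH-adjusted over all
cluster pairs.  Counting orthogroups (not genes) is what lets one-to-many
and many-to-many relations aggregate cleanly.

## Heterochrony

Activation = first stage (in order) whose stage-mean TPM reaches the
cutoff; maternal presence at the first stage counts as activation there.
Cross-species comparison uses a `StageCorrespondence`: an ordered list of
matched stage pairs with optional per-species exclusions.  Activation is
evaluated on the matched stages only; a pair active only within excluded
stages is `unscored`, one never reaching the cutoff anywhere is
`inactive`.  Any matched-index offset ≥ 1 counts as a shift by default
(`min_offset` configurable; no minimum-offset convention is established in
the field).  Direction percentages are reported over shifted pairs only.
For the in-repo two-species runs the correspondence is positional over the
nine shared stages; cross-dataset runs must supply their own table.

## Annotation statistics

GO enrichment is the classic upper-tail Fisher exact test per term against
a declared universe; annotations are tested as given (no DAG propagation —
maps are assumed pre-propagated if that is desired).  KEGG-style pathway
enrichment reports pathways with unadjusted p < 0.05 and BH q < 0.5, the
q-value computed for reporting only.  Phylostratum summaries use an
ordered oldest → youngest stratum list; unmapped genes go to an explicit
`unassigned` stratum.  The age × stage heatmap input quantile-normalises
stage columns to the mean-of-sorted-columns reference (ties receive the
mean of their pooled reference values), then averages per stratum; ties in
the per-stratum argmax go to the earliest stage.  Codon usage is counted
per gene set from CDS (trailing partial codons trimmed with a warning,
codons containing non-ACGT skipped and tallied) and clusters are compared
by per-codon log2 ratios of global relative frequencies with a small
pseudocount.

## Synthetic data: what it emulates, and what it does not

The generator plants, per species, a set of cluster templates over nine
ordered stages (oocyte → gastrula): an oocyte/zygote-specific cluster
cleared immediately after fertilisation, a maternal-decay cluster cleared
by mid-cleavage (the two maternal waves), early- and late-zygotic clusters,
species-B-only stage-specific clusters at the 16-, 32- and 64-cell stages,
and a large embryonic cluster rising at gastrulation.  Per-gene profiles
are amplitude × template + a weak noise floor, with multiplicative
log-normal stage noise.  One-to-one ortholog pairs share amplitude, gene
length, and a latent noise field mixed by per-stage conservation weights
w(s) = 0.2 + 0.75·exp(−((s − peak)/1.8)²), maximal at the hourglass stage
(gastrula by default) — this is what plants the cross-species JSD minimum.
A configurable fraction of zygotic-onset pairs (default 20%) has the
species-B template displaced by the shift magnitude (default −2 stages,
i.e. earlier in B).  Counts are negative-binomial (gamma–Poisson) around
library-size-scaled expected values with dispersion α = 0.05 (typical bulk
RNA-seq); `dispersion = 0` produces deterministic rounded counts, giving
the noise-free contracts exact meaning.  TPM is re-derived from counts and
lengths, exactly as for real data.  Library sizes are drawn once per sample
slot and shared between species (a paired design).  Phylostratum labels
correlate with cluster age (the embryonic cluster is ancient-gene-heavy,
stage-specific clusters are >50% species-specific), half of the
stage-specific cluster genes are deliberately unannotated, each category
carries a planted GO signature, and oocyte-cluster genes use a skewed
synonymous-codon sampler.

Unstated-by-construction parameters (noise level, amplitude distribution,
floor magnitude, conservation-curve shape) were calibrated once so that
downstream recovery is neither trivial nor impossible, then frozen; the
defaults are the package's reference study conditions.  Two deliberate
scale conventions: the noise floor is specified on the realised-TPM scale
of the reference 5000-gene transcriptome and rescaled with the gene count
(TPM is compositional, so a fixed intent value would grow as 1/n), and
amplitudes are log-normal with median ≈ 50 intent units.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: read-level noise and mapping ambiguity
(simulation starts at counts), 3' bias and length-dependent quantification
error, constitutively expressed genes (every simulated gene is
stage-restricted, which is why the pseudo-reference size-factor path
exists), continuous developmental time and staging error, partial
conservation of cluster membership (pairs share their category by
construction), sequence evolution, and single-cell structure.  Recovery
rates here measure the correctness and calibration of the implementations
under the stated model, not field performance on real embryo time courses.

## Problem sizes and runtime

The recovery benchmarks run the generator at its default scale (2 × 5000
genes, 9 stages, 2 replicates) over 20 seeds for the hourglass and
clustering checks; differential-expression calibration uses one 5000-gene
null simulation and 50 × 50 planted 4-fold genes for power; the
hypergeometric oracle enumerates all ~6.4 × 10⁵ tables with universe ≤ 60
by exact integer arithmetic.  These sizes put the Monte-Carlo error of each
reported rate well below the margins being checked while keeping the whole
acceptance run under a minute on one CPU.

## Known limitations

- The NB Wald stage is not a DESeq2 clone; counts of DEGs will differ in
  detail from likelihood-ratio or shrinkage-based pipelines.
- Divergence-matrix normalisation is a documented stand-in (min–max);
  any monotone rescaling preserves the argmin, which is the quantity the
  biological conclusion rests on, but normalised values are not comparable
  across datasets processed with other conventions.
- Category labels are heuristics over centroid shapes; unusual profiles
  (e.g. bimodal in time) fall back to `uncategorized` or the nearest rule.
- Quantile-normalisation idempotence holds exactly on tie-free data; with
  heavy ties across differently tied columns it is approximate.
- The deactivation direction of heterochrony (off-switch timing) is out of
  scope, as is continuous-time alignment (e.g. dynamic time warping).
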