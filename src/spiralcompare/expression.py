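"""Expression-matrix model and sample-level QC for staged developmental time courses.

The central objects are :class:`StageDesign` (an ordered list of developmental
stages plus a sample -> (stage, replicate, batch) map) and
:class:`ExpressionMatrix` (a genes x samples abundance table tagged with its
unit, TPM or counts, and bound to a design).  On top of these the module
provides the expressed-gene definition (stage-mean TPM strictly above a
cutoff), data-driven activation-threshold inference from the shape of the
log2 TPM distribution, replicate correlation, PCA variance decomposition,
hierarchical sample grouping, and an optional per-batch log-space centering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import gaussian_kde


class ExpressionError(ValueError):
    """Raised for invalid expression matrices, designs or thresholds."""


# ---------------------------------------------------------------------------
# Designs and matrices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StageDesign:
    """Ordered stage labels and the sample -> (stage, replicate, batch) map.

    ``samples`` is indexed by sample name with columns ``stage``,
    ``replicate`` and ``batch``.  Stage order is total and given by
    ``stages``; every sample must map to exactly one listed stage.
    """

    stages: tuple[str, ...]
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"stage", "replicate", "batch"}
        missing = required - set(self.samples.columns)
        if missing:
            raise ExpressionError(f"design table lacks columns: {sorted(missing)}")
        unknown = set(self.samples["stage"]) - set(self.stages)
        if unknown:
            raise ExpressionError(f"design references unlisted stages: {sorted(unknown)}")
        if self.samples.index.duplicated().any():
            dups = self.samples.index[self.samples.index.duplicated()].tolist()
            raise ExpressionError(f"duplicate sample names in design: {dups}")

    def samples_for_stage(self, stage: str) -> list[str]:
        if stage not in self.stages:
            raise ExpressionError(f"unknown stage {stage!r}; stages are {list(self.stages)}")
        return list(self.samples.index[self.samples["stage"] == stage])

    def stage_index(self, stage: str) -> int:
        if stage not in self.stages:
            raise ExpressionError(f"unknown stage {stage!r}")
        return self.stages.index(stage)

    @classmethod
    def default(
        cls,
        stages: tuple[str, ...],
        n_replicates: int = 2,
        batch_by_replicate: bool = True,
    ) -> "StageDesign":
        """Full-factorial design with samples named ``<stage>_<rep>``."""
        rows = []
        for stage in stages:
            for rep in range(1, n_replicates + 1):
                rows.append(
                    {
                        "sample": f"{stage}_{rep}",
                        "stage": stage,
                        "replicate": rep,
                        "batch": f"rep{rep}" if batch_by_replicate else "batch1",
                    }
                )
        table = pd.DataFrame(rows).set_index("sample")
        return cls(stages=tuple(stages), samples=table)

    @classmethod
    def from_table(cls, path) -> "StageDesign":
        table = pd.read_csv(path, sep="\t", dtype={"sample": str, "stage": str})
        if table.empty:
            raise ExpressionError(f"empty design table: {path}")
        table = table.set_index("sample")
        if "batch" not in table.columns:
            table["batch"] = "batch1"
        if "replicate" not in table.columns:
            table["replicate"] = table.groupby("stage").cumcount() + 1
        stages = tuple(dict.fromkeys(table["stage"]))  # first-appearance order
        return cls(stages=stages, samples=table)

    def to_table(self, path) -> None:
        self.samples.reset_index().to_csv(path, sep="\t", index=False)


@dataclass
class ExpressionMatrix:
    """Genes x samples abundance table bound to a :class:`StageDesign`.

    ``unit`` is ``"tpm"`` or ``"counts"`` and is required before
    unit-specific operations (expressed-gene calls need TPM, size-factor
    normalisation needs counts).
    """

    values: pd.DataFrame
    unit: str
    design: StageDesign

    def __post_init__(self) -> None:
        if self.unit not in ("tpm", "counts"):
            raise ExpressionError(f"unit must be 'tpm' or 'counts', got {self.unit!r}")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ExpressionError(f"duplicate gene identifiers: {dups[:5]}")
        if (self.values.to_numpy() < 0).any():
            raise ExpressionError("expression matrix contains negative values")
        undeclared = [c for c in self.values.columns if c not in self.design.samples.index]
        if undeclared:
            raise ExpressionError(f"matrix columns missing from design: {undeclared}")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def sample_names(self) -> pd.Index:
        return self.values.columns

    def require_unit(self, unit: str) -> None:
        if self.unit != unit:
            raise ExpressionError(f"operation requires unit {unit!r}, matrix is {self.unit!r}")

    def subset_genes(self, genes) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(genes)], self.unit, self.design)


@dataclass(frozen=True)
class ThresholdSpec:
    """Expression cutoff on the TPM scale.

    ``method`` records how the cutoff was obtained: ``"fixed"`` (supplied) or
    ``"inflexion"`` (inferred from the log2 TPM density);
    ``fallback`` flags an inference that fell back to the fixed default.
    ``inclusive`` chooses '>=', used for activation calls; the expressed-gene
    definition always uses strict '>'.
    """

    cutoff: float = 2.0
    method: str = "fixed"
    inclusive: bool = False
    fallback: bool = False

    def __post_init__(self) -> None:
        if not self.cutoff > 0:
            raise ExpressionError(f"cutoff must be > 0, got {self.cutoff}")


def read_matrix(path, design_path, unit: str) -> ExpressionMatrix:
    """Read a TSV expression matrix (genes as rows) and validate it against a design."""
    design = StageDesign.from_table(design_path)
    try:
        table = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise ExpressionError(f"empty expression matrix: {path}") from exc
    if table.empty and table.columns.empty:
        raise ExpressionError(f"empty expression matrix: {path}")
    return ExpressionMatrix(values=table, unit=unit, design=design)


def write_matrix(m: ExpressionMatrix, path) -> None:
    m.values.to_csv(path, sep="\t", index_label="gene")


# ---------------------------------------------------------------------------
# Stage summaries and expressed-gene calls
# ---------------------------------------------------------------------------

def stage_means(m: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene mean abundance per stage (mean over replicates, stage order kept)."""
    cols = {}
    for stage in m.design.stages:
        samples = m.design.samples_for_stage(stage)
        present = [s for s in samples if s in m.values.columns]
        if not present:
            raise ExpressionError(f"stage {stage!r} has no samples in the matrix")
        cols[stage] = m.values[present].mean(axis=1)
    return pd.DataFrame(cols, index=m.genes)


def expressed_set(m: ExpressionMatrix, t: ThresholdSpec, stage: str) -> set[str]:
    """Genes whose stage-mean TPM exceeds the cutoff (strict '>')."""
    m.require_unit("tpm")
    m.design.stage_index(stage)  # validates the stage name
    means = stage_means(m)[stage]
    return set(means.index[means > t.cutoff])


def expressed_counts_per_stage(m: ExpressionMatrix, t: ThresholdSpec) -> pd.Series:
    """Number of expressed genes at each stage, in stage order."""
    m.require_unit("tpm")
    means = stage_means(m)
    counts = (means > t.cutoff).sum(axis=0)
    return pd.Series(counts, index=list(m.design.stages), name="expressed_genes")


def infer_activation_threshold(
    m: ExpressionMatrix,
    n_grid: int = 512,
    fallback_cutoff: float = 2.0,
) -> ThresholdSpec:
    """Infer an activation cutoff from the shape of the log2 TPM density.

    A Gaussian KDE (Silverman bandwidth) is fitted to log2 of the positive
    TPM values on a 512-point grid over their observed range.  The cutoff is
    2**x* where x* is, in order of preference: the first local minimum of
    the density right of its mode (the noise/signal valley, when the
    distribution is bimodal); otherwise the first sign change of the
    smoothed second derivative right of the mode — the inflexion where the
    right flank of an asymmetric unimodal distribution flattens out.  When
    neither exists the fixed default is returned with the fallback flag set.
    """
    m.require_unit("tpm")
    vals = m.values.to_numpy().ravel()
    pos = vals[vals > 0]
    if pos.size == 0:
        raise ExpressionError("cannot infer a threshold from an all-zero matrix")
    if pos.size < 1000:
        warnings.warn("fewer than 1000 positive values; inferred threshold may be unstable")
    x = np.log2(pos)
    if np.ptp(x) == 0:  # degenerate single-valued matrix
        return ThresholdSpec(cutoff=fallback_cutoff, method="fixed", fallback=True)
    grid = np.linspace(x.min(), x.max(), n_grid)
    kde = gaussian_kde(x, bw_method="silverman")
    dens = kde(grid)
    d2 = np.gradient(np.gradient(dens, grid), grid)
    # light smoothing of the curvature to suppress grid-level wiggles
    kernel = np.ones(9) / 9.0
    d2s = np.convolve(d2, kernel, mode="same")
    mode_i = int(np.argmax(dens))
    smooth = np.convolve(dens, kernel, mode="same")
    # bimodal path: first rising turn (local minimum) right of the mode,
    # requiring the density to climb appreciably afterwards
    for i in range(mode_i + 5, n_grid - 5):
        if smooth[i] <= smooth[i - 1] and smooth[i] < smooth[i + 1]:
            if smooth[i + 1 :].max() > 1.05 * smooth[i]:
                return ThresholdSpec(cutoff=float(2.0 ** grid[i]), method="inflexion")
            break
    sign = np.sign(d2s)
    for i in range(mode_i + 1, n_grid - 1):
        if sign[i] <= 0 and sign[i + 1] > 0:
            return ThresholdSpec(cutoff=float(2.0 ** grid[i]), method="inflexion")
    return ThresholdSpec(cutoff=fallback_cutoff, method="fixed", fallback=True)


# ---------------------------------------------------------------------------
# Sample-level QC
# ---------------------------------------------------------------------------

def sample_correlation(
    m: ExpressionMatrix, method: str = "pearson", log_offset: float = 1.0
) -> pd.DataFrame:
    """Sample x sample correlation of log-transformed abundances."""
    if m.values.shape[1] < 2:
        raise ExpressionError("sample correlation needs at least 2 samples")
    if method not in ("pearson", "spearman"):
        raise ExpressionError(f"unknown correlation method {method!r}")
    logged = np.log2(m.values + log_offset)
    return logged.corr(method=method)


def pca_variance_explained(m: ExpressionMatrix, n_components: int | None = None,
                           log_offset: float = 1.0) -> np.ndarray:
    """Proportions of variance explained by successive PCs over samples.

    Samples are observations, genes are features; log2(x + offset) values are
    gene-centered before the eigendecomposition.  Proportions are
    non-increasing and sum to 1 over the full rank.
    """
    if m.values.shape[1] < 2:
        raise ExpressionError("PCA needs at least 2 samples")
    logged = np.log2(m.values.to_numpy(dtype=float) + log_offset).T  # samples x genes
    centered = logged - logged.mean(axis=0)
    # economical SVD: rank <= n_samples - 1
    s = np.linalg.svd(centered, compute_uv=False)
    var = s**2
    total = var.sum()
    if total == 0:
        raise ExpressionError("zero total variance; PCA undefined")
    props = var / total
    rank = int(np.sum(var > var[0] * 1e-12))
    props = props[:rank]
    if n_components is not None:
        if n_components > props.size:
            warnings.warn(
                f"n_components={n_components} exceeds rank {props.size}; truncated"
            )
        props = props[:n_components]
    return props


def hierarchical_sample_groups(corr: pd.DataFrame, k: int) -> pd.Series:
    """Cut an average-linkage tree of distance 1 - correlation into k groups."""
    if corr.shape[0] != corr.shape[1] or not np.allclose(corr, corr.T, atol=1e-8):
        raise ExpressionError("correlation matrix must be square and symmetric")
    dist = 1.0 - corr.to_numpy(dtype=float)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    z = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(z, t=k, criterion="maxclust")
    return pd.Series(labels, index=corr.index, name="group")


def center_batches(m: ExpressionMatrix) -> ExpressionMatrix:
    """Remove additive batch offsets in log2(TPM+1) space.

    For each gene, each batch's mean log expression is shifted to the gene's
    grand mean; values are inverse-transformed and clipped at zero.  With a
    single batch this is the identity.
    """
    m.require_unit("tpm")
    batches = m.design.samples.loc[m.values.columns, "batch"]
    if batches.nunique() <= 1:
        return m
    logged = np.log2(m.values + 1.0)
    grand = logged.mean(axis=1)
    corrected = logged.copy()
    for batch in batches.unique():
        cols = batches.index[batches == batch]
        offset = logged[cols].mean(axis=1) - grand
        corrected[cols] = logged[cols].sub(offset, axis=0)
    out = (2.0**corrected - 1.0).clip(lower=0.0)
    return ExpressionMatrix(values=out, unit="tpm", design=m.design)


DEFAULT_STAGES: tuple[str, ...] = (
    "oocyte",
    "zygote",
    "2cell",
    "4cell",
    "8cell",
    "16cell",
    "32cell",
    "64cell",
    "gastrula",
)
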