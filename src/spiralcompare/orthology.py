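"""Orthology handling and cross-species stage-divergence analysis.

Two species' developmental time courses are compared through their
orthologs: one-to-one pairs feed a Jensen-Shannon distance (JSD) matrix
over all stage pairs — whose global minimum locates the most conserved
("phylotypic" / hourglass-waist) period — while the complete orthogroup
map feeds hypergeometric cluster-correspondence tests and an
ortholog cluster-flow contingency table.

The JSD here is the Endres–Schindelin metric: the square root of the
Jensen–Shannon divergence with base-2 logarithms, bounded in [0, 1].
Stage-mean TPM vectors over the shared orthologs are first converted to
probability distributions by an average-rank quantile transform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, rankdata
from statsmodels.stats.multitest import multipletests


class OrthologyError(ValueError):
    """Raised for malformed orthogroup maps or divergence inputs."""


# ---------------------------------------------------------------------------
# Orthogroup map
# ---------------------------------------------------------------------------

@dataclass
class OrthologyMap:
    """Orthogroups across two species, OrthoFinder style.

    ``groups`` maps an orthogroup id to a pair of gene lists (species A,
    species B).  A gene may appear in at most one orthogroup.  The derived
    one-to-one subset contains the groups with exactly one gene per species.
    """

    groups: dict[str, tuple[list[str], list[str]]]
    species_a: str = "SpeciesA"
    species_b: str = "SpeciesB"

    def __post_init__(self) -> None:
        for side in (0, 1):
            seen: set[str] = set()
            for og, genes in self.groups.items():
                for g in genes[side]:
                    if g in seen:
                        raise OrthologyError(f"gene {g!r} appears in more than one orthogroup")
                    seen.add(g)

    @property
    def one_to_one(self) -> pd.DataFrame:
        """DataFrame (orthogroup, gene_a, gene_b) of single-copy orthologs."""
        rows = [
            {"orthogroup": og, "gene_a": a[0], "gene_b": b[0]}
            for og, (a, b) in self.groups.items()
            if len(a) == 1 and len(b) == 1
        ]
        return pd.DataFrame(rows, columns=["orthogroup", "gene_a", "gene_b"])

    def gene_to_group(self, side: str) -> dict[str, str]:
        idx = 0 if side == "a" else 1
        return {g: og for og, genes in self.groups.items() for g in genes[idx]}


def read_orthogroups(path) -> OrthologyMap:
    """Parse an OrthoFinder-style Orthogroups.tsv (comma-separated gene lists)."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    if table.shape[1] < 3:
        raise OrthologyError(
            f"orthogroups table needs Orthogroup + two species columns, got {list(table.columns)}"
        )
    og_col, col_a, col_b = table.columns[:3]
    groups = {}
    for _, row in table.iterrows():
        split = lambda cell: (
            [] if pd.isna(cell) or not str(cell).strip()
            else [g.strip() for g in str(cell).split(",") if g.strip()]
        )
        groups[row[og_col]] = (split(row[col_a]), split(row[col_b]))
    return OrthologyMap(groups=groups, species_a=col_a, species_b=col_b)


def write_orthogroups(omap: OrthologyMap, path) -> None:
    rows = [
        {"Orthogroup": og, omap.species_a: ", ".join(a), omap.species_b: ", ".join(b)}
        for og, (a, b) in omap.groups.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Quantile transform and Jensen-Shannon distance
# ---------------------------------------------------------------------------

def quantile_transform(values) -> np.ndarray:
    """Rank-based probability vector: average ranks divided by their sum.

    Monotone transforms of the input leave the output unchanged; an
    all-identical vector maps to the uniform distribution.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise OrthologyError("quantile_transform expects a 1-D vector of length >= 2")
    ranks = rankdata(arr, method="average")
    return ranks / ranks.sum()


def jsd(p, q) -> float:
    """Jensen-Shannon distance sqrt(JS divergence), base-2 logs, in [0, 1]."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise OrthologyError(f"length mismatch: {p.shape} vs {q.shape}")
    for name, v in (("p", p), ("q", q)):
        if abs(v.sum() - 1.0) > 1e-6:
            raise OrthologyError(f"{name} is not normalized (sum {v.sum():.8f})")
        if (v < 0).any():
            raise OrthologyError(f"{name} has negative entries")
    m = 0.5 * (p + q)
    with np.errstate(divide="ignore", invalid="ignore"):
        kl_pm = np.where(p > 0, p * (np.log2(p) - np.log2(m)), 0.0).sum()
        kl_qm = np.where(q > 0, q * (np.log2(q) - np.log2(m)), 0.0).sum()
    return float(np.sqrt(max(0.5 * kl_pm + 0.5 * kl_qm, 0.0)))


@dataclass
class DivergenceMatrix:
    """Stage x stage Jensen-Shannon distances across two species."""

    raw: pd.DataFrame                      # rows: stages of A, cols: stages of B
    normalized: pd.DataFrame | None = None
    normalization: str = "none"

    def argmin_pair(self) -> tuple[str, str]:
        """Stage pair with the smallest raw distance (earliest pair on ties)."""
        arr = self.raw.to_numpy()
        i, j = np.unravel_index(np.argmin(arr), arr.shape)  # first (earliest) min
        return str(self.raw.index[i]), str(self.raw.columns[j])


def stage_divergence(
    stage_means_a: pd.DataFrame,
    stage_means_b: pd.DataFrame,
    pairs: pd.DataFrame,
) -> DivergenceMatrix:
    """Raw JSD between every pair of stages across species.

    ``stage_means_a``/``b`` are genes x stages TPM stage means;
    ``pairs`` holds one-to-one orthologs (columns gene_a, gene_b).  For each
    stage pair the two ortholog vectors (ordered identically by pair) are
    quantile-transformed and compared with :func:`jsd`.
    """
    if len(pairs) < 2:
        raise OrthologyError("need at least 2 shared one-to-one pairs")
    if len(pairs) < 50:
        warnings.warn("fewer than 50 one-to-one pairs; JSD estimates may be noisy")
    va = stage_means_a.loc[pairs["gene_a"]].to_numpy(dtype=float)
    vb = stage_means_b.loc[pairs["gene_b"]].to_numpy(dtype=float)
    pa = np.column_stack([quantile_transform(va[:, s]) for s in range(va.shape[1])])
    pb = np.column_stack([quantile_transform(vb[:, s]) for s in range(vb.shape[1])])
    out = np.empty((pa.shape[1], pb.shape[1]))
    for i in range(pa.shape[1]):
        for j in range(pb.shape[1]):
            out[i, j] = jsd(pa[:, i], pb[:, j])
    raw = pd.DataFrame(out, index=stage_means_a.columns, columns=stage_means_b.columns)
    return DivergenceMatrix(raw=raw)


def normalize_divergence(matrix: DivergenceMatrix, method: str = "minmax") -> DivergenceMatrix:
    """Rescale the raw matrix; min-max over the whole matrix by default.

    Both methods are monotone within their scope, so the global minimum
    location is preserved by the default whole-matrix scaling.
    """
    raw = matrix.raw
    if method == "minmax":
        lo, hi = raw.to_numpy().min(), raw.to_numpy().max()
        if hi == lo:
            warnings.warn("constant divergence matrix; normalized values set to 0")
            norm = raw * 0.0
        else:
            norm = (raw - lo) / (hi - lo)
    elif method == "rowwise":
        norm = raw.sub(raw.min(axis=1), axis=0)
        span = (raw.max(axis=1) - raw.min(axis=1)).replace(0, np.nan)
        norm = norm.div(span, axis=0).fillna(0.0)
    else:
        raise OrthologyError(f"unknown normalization method {method!r}")
    return DivergenceMatrix(raw=raw, normalized=norm, normalization=method)


def min_divergence_profile(matrix: DivergenceMatrix) -> tuple[pd.Series, tuple[str, str]]:
    """Per-A-stage minimum over B stages, plus the global argmin stage pair."""
    per_stage = matrix.raw.min(axis=1)
    per_stage.name = "min_jsd"
    return per_stage, matrix.argmin_pair()


# ---------------------------------------------------------------------------
# Cluster correspondence and ortholog flow
# ---------------------------------------------------------------------------

def cluster_overlap_tests(
    assignments_a: Mapping[str, str],
    assignments_b: Mapping[str, str],
    orthology: OrthologyMap,
) -> pd.DataFrame:
    """Hypergeometric orthogroup-overlap tests for every cluster pair.

    The universe is the set of orthogroups containing at least one clustered
    gene in *both* species; a cluster's orthogroup set comprises the groups
    containing at least one of its genes.  The upper-tail p-value
    P[X >= overlap] is BH-adjusted across all cluster pairs.
    """
    g2og_a = orthology.gene_to_group("a")
    g2og_b = orthology.gene_to_group("b")
    ogs_a: dict[str, set[str]] = {}
    ogs_b: dict[str, set[str]] = {}
    for gene, cl in assignments_a.items():
        og = g2og_a.get(gene)
        if og is not None:
            ogs_a.setdefault(str(cl), set()).add(og)
    for gene, cl in assignments_b.items():
        og = g2og_b.get(gene)
        if og is not None:
            ogs_b.setdefault(str(cl), set()).add(og)
    universe = set().union(*ogs_a.values(), set()) & set().union(*ogs_b.values(), set()) \
        if ogs_a and ogs_b else set()
    if not universe:
        raise OrthologyError("empty orthogroup universe: no cluster pair to test")
    n_universe = len(universe)
    rows = []
    for ca, set_a in sorted(ogs_a.items()):
        sa = set_a & universe
        for cb, set_b in sorted(ogs_b.items()):
            sb = set_b & universe
            overlap = len(sa & sb)
            p = float(hypergeom.sf(overlap - 1, n_universe, len(sa), len(sb)))
            rows.append(
                {
                    "cluster_a": ca,
                    "cluster_b": cb,
                    "overlap": overlap,
                    "size_a": len(sa),
                    "size_b": len(sb),
                    "universe": n_universe,
                    "p": min(p, 1.0),
                }
            )
    table = pd.DataFrame(rows)
    table["padj"] = multipletests(table["p"], method="fdr_bh")[1]
    with np.errstate(divide="ignore"):
        table["neg_log10_padj"] = -np.log10(table["padj"])
    return table


def ortholog_cluster_flow(
    pairs: pd.DataFrame,
    categories_a: Mapping[str, str],
    categories_b: Mapping[str, str],
    total: int | None = None,
) -> pd.DataFrame:
    """Contingency of one-to-one pairs by (category in A, category in B).

    Percentages are over the total number of one-to-one pairs (``total``
    defaults to ``len(pairs)``) and reported to 2 decimals, matching how
    ortholog cluster-flow ("alluvial") tables are usually summarised.
    """
    total = len(pairs) if total is None else total
    if total <= 0:
        raise OrthologyError("flow table needs a positive pair total")
    cat_a = pairs["gene_a"].map(lambda g: categories_a.get(g, "unassigned"))
    cat_b = pairs["gene_b"].map(lambda g: categories_b.get(g, "unassigned"))
    counts = (
        pd.crosstab(cat_a, cat_b)
        .stack()
        .rename("n_pairs")
        .reset_index()
        .rename(columns={"gene_a": "category_a", "gene_b": "category_b"})
    )
    counts = counts[counts["n_pairs"] > 0].reset_index(drop=True)
    counts["percent"] = (100.0 * counts["n_pairs"] / total).round(2)
    return counts
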