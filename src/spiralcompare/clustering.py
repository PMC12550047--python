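"""Soft temporal clustering of stage-mean expression profiles.

Implements the Mfuzz-style workflow: per-gene standardisation of stage-mean
profiles, fuzzy c-means with a data-driven fuzzifier (the Schwämmle–Jensen
estimate), cluster-number selection by the Calinski–Harabasz index computed
on centroid-linkage hierarchical clusters, hard assignment with a minimum
membership, and rule-based biological category labels (oocyte/zygote-
specific, maternal decay, early/late zygotic, stage-specific, embryonic).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans
from sklearn.metrics import calinski_harabasz_score


class ClusteringError(ValueError):
    """Raised for invalid clustering inputs."""


UNASSIGNED = "unassigned"
UNCATEGORIZED = "uncategorized"


@dataclass
class FuzzyClustering:
    """Fitted fuzzy c-means model over standardized stage profiles.

    ``membership`` (genes x k) rows sum to 1; ``hard`` maps each gene to the
    argmax cluster when its top membership reaches ``min_membership`` and to
    ``"unassigned"`` otherwise.  ``categories`` (cluster id -> label) is
    filled by :func:`categorize_clusters`.
    """

    k: int
    m: float
    membership: pd.DataFrame            # genes x cluster ids (ints as str)
    centroids: pd.DataFrame             # cluster ids x stages
    min_membership: float = 0.5
    objective: float = float("nan")
    n_iter: int = 0
    categories: dict[str, str] = field(default_factory=dict)

    @property
    def hard(self) -> pd.Series:
        best = self.membership.idxmax(axis=1)
        top = self.membership.max(axis=1)
        return pd.Series(
            np.where(top >= self.min_membership, best, UNASSIGNED),
            index=self.membership.index,
            name="cluster",
        )

    def hard_categories(self) -> pd.Series:
        """Hard assignment mapped through cluster category labels."""
        if not self.categories:
            raise ClusteringError("clusters have not been categorized yet")
        mapping = dict(self.categories)
        mapping[UNASSIGNED] = UNASSIGNED
        return self.hard.map(mapping).rename("category")


def standardize_profiles(stage_means: pd.DataFrame) -> pd.DataFrame:
    """Per-gene z-scores of stage means; zero-variance genes are dropped."""
    if stage_means.shape[1] < 2:
        raise ClusteringError("standardization needs at least 2 stages")
    mu = stage_means.mean(axis=1)
    sd = stage_means.std(axis=1, ddof=0)
    keep = sd > 0
    if (~keep).any():
        warnings.warn(f"dropping {(~keep).sum()} constant-profile genes")
    z = stage_means.loc[keep].sub(mu[keep], axis=0).div(sd[keep], axis=0)
    return z


def estimate_fuzzifier(n_genes: int, n_stages: int) -> float:
    """Schwämmle–Jensen fuzzifier estimate (Mfuzz's ``mestimate``); m > 1."""
    if n_genes < 2 or n_stages < 1:
        raise ClusteringError("need >= 2 genes and >= 1 stage to estimate a fuzzifier")
    N, D = float(n_genes), float(n_stages)
    return float(
        1.0
        + (1418.0 / N + 22.05) * D ** (-2.0)
        + (12.33 / N + 0.243) * D ** (-0.0406 * np.log(N) - 0.1134)
    )


def fuzzy_cmeans(
    z_profiles: pd.DataFrame,
    k: int,
    m: float | None = None,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 300,
    min_membership: float = 0.5,
) -> FuzzyClustering:
    """Fuzzy c-means on standardized profiles, k-means++ seeded, deterministic.

    Alternates exact centroid and membership updates for the objective
    sum_ij u_ij^m ||x_i - c_j||^2 until the largest centroid shift falls
    below ``tol``; both half-steps are exact minimisers, so the objective is
    non-increasing.
    """
    x = z_profiles.to_numpy(dtype=float)
    n, d = x.shape
    if k < 2:
        raise ClusteringError("k must be >= 2")
    if k > n:
        raise ClusteringError(f"k={k} exceeds number of genes {n}")
    if m is None:
        m = estimate_fuzzifier(n, d)
    if m <= 1:
        raise ClusteringError("fuzzifier m must be > 1")
    # deterministic initialisation: multi-restart k-means on top of k-means++
    # seeding, so the soft refinement starts from a stable hard partition
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(x)
    centroids = km.cluster_centers_.copy()
    u = np.empty((n, k))
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        d2 = ((x[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        zero = d2 <= 1e-300
        # memberships: u_ij = 1 / sum_l (d_ij / d_il)^(2/(m-1))
        with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
            ratio = d2[:, :, None] / d2[:, None, :]
            u = 1.0 / (ratio ** (1.0 / (m - 1.0))).sum(axis=2)
        if zero.any():
            rows = zero.any(axis=1)
            u[rows] = 0.0
            u[rows] = zero[rows] / zero[rows].sum(axis=1, keepdims=True)
        um = u**m
        new_centroids = (um.T @ x) / um.sum(axis=0)[:, None]
        shift = np.abs(new_centroids - centroids).max()
        centroids = new_centroids
        if shift < tol:
            break
    d2 = ((x[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    objective = float(((u**m) * d2).sum())
    ids = [str(j) for j in range(k)]
    return FuzzyClustering(
        k=k,
        m=float(m),
        membership=pd.DataFrame(u, index=z_profiles.index, columns=ids),
        centroids=pd.DataFrame(centroids, index=ids, columns=z_profiles.columns),
        min_membership=min_membership,
        objective=objective,
        n_iter=n_iter,
    )


def select_k(
    z_profiles: pd.DataFrame,
    k_range: tuple[int, int] = (2, 15),
    max_genes: int | None = 2000,
    seed: int = 0,
) -> int:
    """Pick k by the Calinski–Harabasz index on centroid-linkage hierarchies.

    For each candidate k the profiles are cut from a centroid-linkage tree on
    Euclidean distances and scored with the CH (between/within variance
    ratio) index; the argmax wins, ties going to the smallest k.  For large
    inputs a deterministic random subsample of ``max_genes`` profiles is
    scored — the CH optimum is stable under subsampling of well-populated
    clusters.
    """
    lo, hi = k_range
    n = len(z_profiles)
    if not (2 <= lo <= hi <= max(n - 1, 2)):
        raise ClusteringError(f"k_range {k_range} outside [2, n_genes-1]")
    x = z_profiles.to_numpy(dtype=float)
    if max_genes is not None and n > max_genes:
        idx = np.random.default_rng(seed).choice(n, size=max_genes, replace=False)
        x = x[np.sort(idx)]
    z = linkage(x, method="centroid")
    best_k, best_score = lo, -np.inf
    for k in range(lo, min(hi, len(x) - 1) + 1):
        labels = fcluster(z, t=k, criterion="maxclust")
        if len(np.unique(labels)) < 2:
            continue
        score = calinski_harabasz_score(x, labels)
        if score > best_score + 1e-12:
            best_k, best_score = k, score
    return best_k


# ---------------------------------------------------------------------------
# Category labelling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CategoryRules:
    """Thresholds for the rule-based centroid categorisation.

    ``flat_span``: a centroid whose z-range is below this is left
    uncategorized.  A profile is *maternal-type* when it starts high
    (first-stage z above ``early_start_z``) and peaks within the first
    ``early_peak_region`` stages — TPM is compositional, so decaying
    maternal transcripts can show a shallow realised peak a stage or two
    after the oocyte as the rest of the pool clears.  Maternal-type
    profiles that drop below their mean by ``early_cross_stage`` are
    oocyte/zygote-specific, later-decaying ones maternal decay.
    ``narrow_width``: an interior peak whose above-half-maximum width is at
    most this many stages is stage-specific rather than broadly zygotic.
    """

    flat_span: float = 0.5
    early_start_z: float = 0.5
    early_peak_region: int = 2
    early_cross_stage: int = 2
    narrow_width: int = 2


def categorize_profile(
    profile: np.ndarray, stages: tuple[str, ...], rules: CategoryRules = CategoryRules()
) -> str:
    """Category label for one mean profile (centroid or template)."""
    c = np.asarray(profile, dtype=float)
    n = c.size
    if np.ptp(c) < 1e-12:
        return UNCATEGORIZED
    z = (c - c.mean()) / c.std()
    if np.ptp(z) < rules.flat_span:
        return UNCATEGORIZED
    peak = int(np.argmax(z))
    if peak == n - 1:
        return "embryonic"
    if z[0] > rules.early_start_z and peak <= rules.early_peak_region:
        below = np.nonzero(z < 0)[0]
        cross = int(below[0]) if below.size else n
        return (
            "oocyte_zygote_specific" if cross <= rules.early_cross_stage else "maternal_decay"
        )
    shifted = z - z.min()
    width = int((shifted > 0.5 * shifted.max()).sum())
    if width <= rules.narrow_width:
        return f"stage_specific:{stages[peak]}"
    return "early_zygotic" if peak <= (n - 1) // 2 + 1 else "late_zygotic"


def categorize_clusters(
    clustering: FuzzyClustering,
    stages: tuple[str, ...] | None = None,
    rules: CategoryRules = CategoryRules(),
) -> dict[str, str]:
    """Label every cluster from its centroid shape; stored on the clustering."""
    stage_labels = tuple(stages or clustering.centroids.columns)
    labels = {
        cid: categorize_profile(clustering.centroids.loc[cid].to_numpy(), stage_labels, rules)
        for cid in clustering.centroids.index
    }
    clustering.categories = labels
    return labels
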