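"""Negative-binomial Wald tests for adjacent-stage differential expression.

A deliberately compact NB pipeline: median-of-ratios size factors,
method-of-moments gene dispersions shrunk halfway toward a fitted
mean-dispersion trend, a delta-method Wald test on the log2 fold change
between two stages, an independent low-count filter, and Benjamini-Hochberg
adjustment.  It produces DEG lists of the kind a DESeq2 run would, without
DESeq2's Cox-Reid likelihood machinery or shrinkage estimators — enough for
the comparative analyses downstream, and fully transparent.  The log2
fold-change cutoff for calling a gene differential is 0: any adjusted-
significant change counts.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expression import ExpressionMatrix, ExpressionError


def size_factors(counts: ExpressionMatrix, method: str = "ratio") -> pd.Series:
    """Median-of-ratios per-sample scale factors.

    ``method="ratio"``: factor_j = median over reference genes of
    count_gj / geometric-mean_g, restricted to genes with all-positive
    counts; raises when no such gene exists.  ``method="poscounts"``: the
    pseudo-reference variant for sparse matrices — the geometric mean is
    taken over positive counts only and ratios are pooled over positive
    entries.  ``method="auto"``: strict first, pseudo-reference fallback.
    """
    counts.require_unit("counts")
    x = counts.values.to_numpy(dtype=float)
    allpos = (x > 0).all(axis=1)
    if method not in ("ratio", "poscounts", "auto"):
        raise ExpressionError(f"unknown size-factor method {method!r}")
    if method == "ratio" or (method == "auto" and allpos.any()):
        if not allpos.any():
            raise ExpressionError(
                "no gene has positive counts in every sample; cannot form the "
                "median-of-ratios reference (use method='poscounts' for a "
                "pseudo-reference)"
            )
        ref = x[allpos]
        geo = np.exp(np.log(ref).mean(axis=1))
        factors = np.median(ref / geo[:, None], axis=0)
        return pd.Series(factors, index=counts.sample_names, name="size_factor")
    else:
        expressed = x[(x > 0).any(axis=1)]
        if expressed.size == 0:
            raise ExpressionError("all-zero count matrix")
        with np.errstate(divide="ignore"):
            logx = np.where(expressed > 0, np.log(expressed), np.nan)
        geo = np.exp(np.nanmean(logx, axis=1))
        ratios = expressed / geo[:, None]
        ratios = np.where(expressed > 0, ratios, np.nan)
        factors = np.nanmedian(ratios, axis=0)
    factors = factors / np.exp(np.mean(np.log(factors)))  # geometric mean 1
    return pd.Series(factors, index=counts.sample_names, name="size_factor")


def normalized_counts(counts: ExpressionMatrix, factors: pd.Series | None = None) -> pd.DataFrame:
    if factors is None:
        factors = size_factors(counts)
    return counts.values / factors


def estimate_dispersion(
    counts: ExpressionMatrix,
    factors: pd.Series | None = None,
    groups: pd.Series | None = None,
    shrink: float = 0.5,
    trend_floor: float = 0.8,
    floor: float = 1e-8,
) -> pd.Series:
    """Per-gene NB dispersion alpha (variance mu + alpha*mu^2).

    Method-of-moments on normalized counts, alpha_hat = max(0, (s^2 - mu) / mu^2)
    with the within-group variance pooled over ``groups`` (default: stages),
    shrunk ``shrink`` of the way toward a fitted mean-dispersion trend
    a0 + a1/mu, then floored at ``trend_floor`` times the trend: at the few
    residual degrees of freedom of a replicated time course, below-trend
    moment estimates are dominated by sampling noise, and carrying them into
    the Wald test makes it anticonservative.
    """
    counts.require_unit("counts")
    norm = normalized_counts(counts, factors)
    if groups is None:
        groups = counts.design.samples.loc[norm.columns, "stage"]
    sizes = groups.value_counts()
    if (sizes < 2).any():
        bad = sizes.index[sizes < 2].tolist()
        raise ExpressionError(f"dispersion needs >= 2 replicates per group; offenders: {bad}")
    x = norm.to_numpy(dtype=float)
    mu = x.mean(axis=1)
    # pooled within-group variance
    ss = np.zeros(len(norm))
    dof = 0
    for g in sizes.index:
        cols = [i for i, c in enumerate(norm.columns) if groups[c] == g]
        sub = x[:, cols]
        ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        dof += len(cols) - 1
    s2 = ss / dof
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(mu > 0, (s2 - mu) / mu**2, 0.0)
    raw = np.clip(raw, 0.0, None)
    # parametric trend alpha(mu) = a0 + a1/mu on informative genes
    ok = (mu > 1.0) & (raw > 0)
    if ok.sum() >= 10:
        A = np.column_stack([np.ones(ok.sum()), 1.0 / mu[ok]])
        coef, *_ = np.linalg.lstsq(A, raw[ok], rcond=None)
        a0, a1 = max(coef[0], 0.0), max(coef[1], 0.0)
    else:
        a0, a1 = float(np.median(raw[raw > 0])) if (raw > 0).any() else 0.0, 0.0
    with np.errstate(divide="ignore"):
        trend = a0 + a1 / np.where(mu > 0, mu, np.inf)
    alpha = (1.0 - shrink) * raw + shrink * trend
    alpha = np.maximum(alpha, trend_floor * trend)
    alpha = np.maximum(alpha, floor)
    return pd.Series(alpha, index=counts.genes, name="dispersion")


def nb_wald_pairwise(
    counts: ExpressionMatrix,
    stage_t: str,
    stage_t1: str,
    factors: pd.Series | None = None,
    dispersion: pd.Series | None = None,
    pseudocount: float = 0.5,
    min_mean_count: float = 1.0,
) -> pd.DataFrame:
    """Wald test of stage_t1 vs stage_t on normalized counts.

    Per gene: LFC = log2 of the ratio of group means (pseudocounted); the
    standard error follows from the NB variance mu + alpha*mu^2 by the delta
    method; the two-sided p-value is Gaussian.  Genes whose mean normalized
    count across both groups falls below ``min_mean_count`` are dropped
    before BH adjustment (independent filtering).
    """
    counts.require_unit("counts")
    if factors is None:
        factors = size_factors(counts)
    design = counts.design
    cols_t = [c for c in design.samples_for_stage(stage_t) if c in counts.sample_names]
    cols_t1 = [c for c in design.samples_for_stage(stage_t1) if c in counts.sample_names]
    if len(cols_t) < 2 or len(cols_t1) < 2:
        raise ExpressionError("both stages need >= 2 replicates for the Wald test")
    if dispersion is None:
        sub = ExpressionMatrix(counts.values[cols_t + cols_t1], "counts", design)
        dispersion = estimate_dispersion(sub, factors[cols_t + cols_t1])
    norm = normalized_counts(counts, factors)
    m0 = norm[cols_t].mean(axis=1).to_numpy()
    m1 = norm[cols_t1].mean(axis=1).to_numpy()
    alpha = dispersion.reindex(counts.genes).to_numpy()
    n0, n1 = len(cols_t), len(cols_t1)
    lfc = np.log2((m1 + pseudocount) / (m0 + pseudocount))
    v0 = (m0 + alpha * m0**2) / n0
    v1 = (m1 + alpha * m1**2) / n1
    ln2 = np.log(2.0)
    se = np.sqrt(v1 / (m1 + pseudocount) ** 2 + v0 / (m0 + pseudocount) ** 2) / ln2
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, lfc / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    table = pd.DataFrame(
        {
            "gene": counts.genes,
            "base_mean": (m0 * n0 + m1 * n1) / (n0 + n1),
            "lfc": lfc,
            "se": se,
            "p": p,
            "direction": np.where(lfc >= 0, "up", "down"),
        }
    ).set_index("gene")
    tested = table["base_mean"] >= min_mean_count
    if not tested.any():
        warnings.warn("no gene passes the independent low-count filter; empty DE result")
        return table.iloc[0:0].assign(padj=pd.Series(dtype=float))
    table = table[tested].copy()
    table["padj"] = bh_adjust(table["p"].to_numpy())
    return table


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, clipped to 1."""
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def deg_summary(
    results_by_transition: dict[str, pd.DataFrame], padj_cutoff: float = 0.05
) -> pd.DataFrame:
    """Up/down DEG counts per stage transition at |LFC| > 0 and padj < cutoff."""
    rows = []
    for transition, table in results_by_transition.items():
        if table.empty:
            rows.append({"transition": transition, "up": 0, "down": 0})
            continue
        sig = table[table["padj"] < padj_cutoff]
        rows.append(
            {
                "transition": transition,
                "up": int((sig["lfc"] > 0).sum()),
                "down": int((sig["lfc"] < 0).sum()),
            }
        )
    return pd.DataFrame(rows).set_index("transition")
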