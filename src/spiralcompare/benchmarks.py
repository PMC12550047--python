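"""Parameter-recovery benchmarks on the synthetic two-species generator.

Each function sets up the reference study conditions (the generator
defaults), runs the corresponding analysis module from scratch and scores
the result against the planted truth.  They are used both by the test
suite and by the repository's acceptance script, so every headline number
is produced by one shared, seedable code path.

Problem sizes: the recovery suites run the generator at its default scale
(2 x 5000 genes, 9 stages, 2 replicates) over 20 seeds; the differential-
expression calibration uses dedicated two-group simulations (5000 null
genes; 50 seeds x 50 planted 4-fold genes for power), sizes chosen so the
Monte-Carlo error on each rate is well below the margins of interest.
"""

from __future__ import annotations

import math
from itertools import product

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from sklearn.metrics import adjusted_rand_score

from .clustering import fuzzy_cmeans, select_k, standardize_profiles
from .de import nb_wald_pairwise
from .expression import ExpressionMatrix, StageDesign, ThresholdSpec, stage_means
from .heterochrony import StageCorrespondence, call_heterochrony, shift_direction_summary
from .orthology import (
    cluster_overlap_tests,
    jsd,
    min_divergence_profile,
    ortholog_cluster_flow,
    stage_divergence,
)
from .annotation import AnnotationMap, annotation_coverage
from .simulate import SimulationConfig, generate_dataset


def _seed_for(base: int, offset: int) -> int:
    return (base * 1000 + offset) % (2**31 - 1)


# ---------------------------------------------------------------------------
# Hourglass (JSD minimum) recovery
# ---------------------------------------------------------------------------

def hourglass_recovery(base_seed: int = 0, n_seeds: int = 20, **overrides) -> dict:
    """Fraction of seeds whose cross-species JSD argmin hits the planted stage."""
    correct = 0
    for i in range(n_seeds):
        ds = generate_dataset(SimulationConfig(seed=_seed_for(base_seed, i), **overrides))
        div = stage_divergence(stage_means(ds.tpm_a), stage_means(ds.tpm_b), ds.truth.pairs)
        _, argmin = min_divergence_profile(div)
        peak = ds.truth.stages[ds.truth.hourglass_peak_stage]
        correct += argmin == (peak, peak)
    return {"n_correct": correct, "n_seeds": n_seeds, "rate": correct / n_seeds}


# ---------------------------------------------------------------------------
# Clustering recovery
# ---------------------------------------------------------------------------

def clustering_recovery(base_seed: int = 0, n_seeds: int = 20, planted_k: int = 5,
                        **overrides) -> dict:
    """select_k and fuzzy-c-means assignment recovery on species A."""
    k_hits = 0
    aris = []
    row_dev = 0.0
    for i in range(n_seeds):
        seed = _seed_for(base_seed, i)
        ds = generate_dataset(SimulationConfig(seed=seed, **overrides))
        z = standardize_profiles(stage_means(ds.tpm_a))
        k = select_k(z, seed=seed)
        k_hits += k == planted_k
        fc = fuzzy_cmeans(z, k=k, seed=seed)
        row_dev = max(row_dev, float(np.abs(fc.membership.sum(axis=1) - 1.0).max()))
        hard = fc.hard
        assigned = hard.index[hard != "unassigned"]
        truth = pd.Series(ds.truth.cluster_a)
        aris.append(adjusted_rand_score(truth[assigned], hard[assigned]))
    return {
        "n_k_correct": k_hits,
        "n_seeds": n_seeds,
        "ari_mean": float(np.mean(aris)),
        "ari_min": float(np.min(aris)),
        "n_ari_ge_0.8": int(sum(a >= 0.8 for a in aris)),
        "membership_row_sum_max_dev": row_dev,
    }


# ---------------------------------------------------------------------------
# Heterochrony recovery
# ---------------------------------------------------------------------------

def heterochrony_recovery(seed: int = 0, **overrides) -> dict:
    """Sensitivity / FDR of shift calls and recovered direction proportions."""
    ds = generate_dataset(SimulationConfig(seed=seed, **overrides))
    corr = StageCorrespondence.positional(ds.truth.stages, ds.truth.stages)
    calls = call_heterochrony(
        stage_means(ds.tpm_a),
        stage_means(ds.tpm_b),
        ds.truth.pairs[["orthogroup", "gene_a", "gene_b"]],
        corr,
        threshold_a=ThresholdSpec(2.0, inclusive=True),
        threshold_b=ThresholdSpec(2.0, inclusive=True),
    )
    merged = calls.merge(
        ds.truth.pairs[["orthogroup", "shift_class"]],
        on="orthogroup",
        suffixes=("_called", "_true"),
    )
    shift_classes = ("earlier_in_A", "earlier_in_B")
    true_shift = merged["shift_class_true"].isin(shift_classes)
    called_shift = merged["shift_class_called"].isin(shift_classes)
    correct = (merged["shift_class_called"] == merged["shift_class_true"]) & true_shift
    sensitivity = float(correct.sum() / true_shift.sum())
    false_calls = (called_shift & ~correct).sum()
    fdr = float(false_calls / called_shift.sum()) if called_shift.any() else 0.0
    direction = shift_direction_summary(calls)
    truth_direction = shift_direction_summary(
        ds.truth.pairs.rename(columns={"shift_class": "shift_class"})
    )
    return {
        "n_pairs": len(calls),
        "n_planted_shifts": int(true_shift.sum()),
        "sensitivity": sensitivity,
        "fdr": fdr,
        "pct_earlier_in_B_called": float(direction.loc["earlier_in_B", "percent_of_shifted"]),
        "pct_earlier_in_B_planted": float(
            truth_direction.loc["earlier_in_B", "percent_of_shifted"]
        ),
    }


# ---------------------------------------------------------------------------
# Cluster correspondence
# ---------------------------------------------------------------------------

def correspondence_recovery(seed: int = 0, **overrides) -> dict:
    """Hypergeometric overlap tests on the planted cluster assignments."""
    ds = generate_dataset(SimulationConfig(seed=seed, **overrides))
    table = cluster_overlap_tests(ds.truth.cluster_a, ds.truth.cluster_b, ds.orthology)
    matched = set(ds.truth.matched_cluster_pairs)
    is_matched = [
        (a, b) in matched for a, b in zip(table["cluster_a"], table["cluster_b"])
    ]
    table = table.assign(matched=is_matched)
    return {
        "n_cluster_pairs": len(table),
        "matched_max_padj": float(table.loc[table["matched"], "padj"].max()),
        "unmatched_median_padj": float(table.loc[~table["matched"], "padj"].median()),
    }


# ---------------------------------------------------------------------------
# Differential expression calibration
# ---------------------------------------------------------------------------

def _two_group_counts(
    n_genes: int,
    mu_range: tuple[float, float],
    alpha: float,
    seed: int,
    lfc_genes: np.ndarray | None = None,
    fold: float = 4.0,
    n_rep: int = 2,
) -> ExpressionMatrix:
    rng = np.random.default_rng(seed)
    design = StageDesign.default(("s0", "s1"), n_rep)
    mu = rng.uniform(*mu_range, size=n_genes)
    mult = np.ones(n_genes)
    if lfc_genes is not None:
        mult[lfc_genes] = fold
    cols = {}
    for s in design.samples.index:
        m = mu * (mult if design.samples.loc[s, "stage"] == "s1" else 1.0)
        cols[s] = rng.poisson(rng.gamma(1.0 / alpha, alpha * m))
    frame = pd.DataFrame(cols, index=[f"g{i}" for i in range(n_genes)])
    return ExpressionMatrix(frame, "counts", design)


def de_type1_error(seed: int = 0, n_genes: int = 5000, alpha: float = 0.05) -> dict:
    """Fraction of raw p < 0.05 in an all-null NB simulation."""
    counts = _two_group_counts(n_genes, (20, 500), alpha, seed)
    res = nb_wald_pairwise(counts, "s0", "s1")
    return {"n_genes": len(res), "fraction_p_lt_0.05": float((res["p"] < 0.05).mean())}


def de_power(base_seed: int = 0, n_seeds: int = 50, n_genes: int = 2000,
             n_planted: int = 50, alpha: float = 0.05, fold: float = 4.0) -> dict:
    """Detection rate (BH padj < 0.05) of planted ``fold``-changes at n=2."""
    hits = total = 0
    for i in range(n_seeds):
        idx = np.arange(n_planted)
        counts = _two_group_counts(
            n_genes, (50, 200), alpha, _seed_for(base_seed, 500 + i), lfc_genes=idx, fold=fold
        )
        res = nb_wald_pairwise(counts, "s0", "s1")
        sig = set(res.index[res["padj"] < 0.05])
        hits += sum(f"g{i}" in sig for i in idx)
        total += n_planted
    return {"n_tests": total, "power": hits / total}


# ---------------------------------------------------------------------------
# Metric and oracle checks
# ---------------------------------------------------------------------------

def jsd_metric_check(seed: int = 0, n_triples: int = 1000, dim: int = 8) -> dict:
    """Symmetry, zero-iff-equal, range and triangle inequality on random triples."""
    rng = np.random.default_rng(seed)
    max_asym = max_tri_violation = 0.0
    max_val = 0.0
    min_self = 0.0
    for _ in range(n_triples):
        p, q, r = rng.dirichlet(np.ones(dim), size=3)
        dpq, dqp = jsd(p, q), jsd(q, p)
        dqr, dpr = jsd(q, r), jsd(p, r)
        max_asym = max(max_asym, abs(dpq - dqp))
        max_tri_violation = max(max_tri_violation, dpr - (dpq + dqr))
        max_val = max(max_val, dpq, dqr, dpr)
        min_self = max(min_self, jsd(p, p))
    return {
        "n_triples": n_triples,
        "max_asymmetry": max_asym,
        "max_triangle_violation": max_tri_violation,
        "max_value": max_val,
        "max_self_distance": min_self,
    }


def fisher_oracle_check(max_universe: int = 60) -> dict:
    """Upper-tail hypergeometric p vs exact integer enumeration, all tables N<=60."""
    comb = [[math.comb(n, k) for k in range(n + 1)] for n in range(max_universe + 1)]
    max_diff = 0.0
    n_tables = 0
    for n_uni in range(1, max_universe + 1):
        for n_term in range(0, n_uni + 1):
            for n_study in range(0, n_uni + 1):
                lo = max(0, n_term + n_study - n_uni)
                hi = min(n_term, n_study)
                denom = comb[n_uni][n_study]
                # exact upper-tail sums via integer arithmetic, from the top
                tail = 0
                exact = {}
                for k in range(hi, lo - 1, -1):
                    tail += comb[n_term][k] * comb[n_uni - n_term][n_study - k]
                    exact[k] = tail / denom
                ks = np.arange(lo, hi + 1)
                sf = hypergeom.sf(ks - 1, n_uni, n_term, n_study)
                for k, p in zip(ks, sf):
                    max_diff = max(max_diff, abs(p - exact[int(k)]))
                    n_tables += 1
    return {"n_tables": n_tables, "max_abs_diff": max_diff}


# ---------------------------------------------------------------------------
# Worked examples (printed-arithmetic contingency inputs)
# ---------------------------------------------------------------------------

def worked_examples() -> dict:
    """Percentages from the flow/summary operations on fixed contingency inputs."""
    out = {}

    def _flow_pct(n_cell: int, total: int, cat_a: str, cat_b: str) -> float:
        genes_a = [f"a{i}" for i in range(total)]
        genes_b = [f"b{i}" for i in range(total)]
        pairs = pd.DataFrame({"gene_a": genes_a, "gene_b": genes_b})
        cats_a = {g: (cat_a if i < n_cell else "other") for i, g in enumerate(genes_a)}
        cats_b = {g: (cat_b if i < n_cell else "other") for i, g in enumerate(genes_b)}
        flow = ortholog_cluster_flow(pairs, cats_a, cats_b)
        row = flow[(flow["category_a"] == cat_a) & (flow["category_b"] == cat_b)]
        return float(row["percent"].iloc[0])

    # cluster-membership share of a DEG list, via the same flow operation
    out["pct_down_degs_oocyte_specific"] = {
        "value": _flow_pct(168, 290, "oocyte_zygote_specific", "downregulated"),
        "n": 290,
    }
    out["pct_embryonic_a_maternal_in_b"] = {
        "value": _flow_pct(622, 7607, "embryonic", "maternal"), "n": 7607,
    }
    out["pct_embryonic_b_maternal_in_a"] = {
        "value": _flow_pct(859, 7607, "maternal", "embryonic"), "n": 7607,
    }

    def _coverage_pct(n_unann: int, size: int, cluster: str) -> float:
        genes = [f"g{i}" for i in range(size)]
        assignments = {g: cluster for g in genes}
        annotated = {g: {"GO:0000001"} for g in genes[n_unann:]}
        amap = AnnotationMap(gene_terms=annotated, universe=set(genes))
        cov = annotation_coverage(assignments, amap)
        return float(cov.loc[cluster, "percent_unannotated"])

    out["pct_unannotated_16cell_cluster"] = {
        "value": _coverage_pct(1040, 2310, "stage_specific:16cell"), "n": 2310,
    }
    out["pct_unannotated_32cell_cluster"] = {
        "value": _coverage_pct(1565, 3104, "stage_specific:32cell"), "n": 3104,
    }
    out["pct_unannotated_64cell_cluster"] = {
        "value": _coverage_pct(2161, 4841, "stage_specific:64cell"), "n": 4841,
    }

    calls = pd.DataFrame(
        {
            "gene_a": [f"tf{i}" for i in range(20)],
            "gene_b": [f"tg{i}" for i in range(20)],
            "shift_class": ["earlier_in_B"] * 17 + ["earlier_in_A"] * 3,
        }
    )
    direction = shift_direction_summary(calls)
    out["pct_tf_shifts_earlier_in_b"] = {
        "value": float(direction.loc["earlier_in_B", "percent_of_shifted"]), "n": 20,
    }
    return out


# ---------------------------------------------------------------------------
# End-to-end determinism
# ---------------------------------------------------------------------------

def determinism_check(seed: int = 0, tmpdir=None, n_genes: int = 800) -> dict:
    """Two identical pipeline runs must produce byte-identical summary JSON."""
    import tempfile
    from pathlib import Path

    from .pipeline import RunConfig, run_all

    base = Path(tmpdir) if tmpdir is not None else Path(tempfile.mkdtemp())
    blobs = []
    for tag in ("x", "y"):
        out = base / f"run_{tag}"
        run_all(RunConfig(seed=seed, outdir=str(out),
                          simulate={"n_genes_per_species": n_genes}))
        blobs.append((out / "summary.json").read_bytes())
    return {"identical": int(blobs[0] == blobs[1]), "n_genes": n_genes}
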