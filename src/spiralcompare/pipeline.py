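"""End-to-end orchestration: simulate/load -> QC -> DE -> cluster -> compare.

A single :class:`RunConfig` (YAML-loadable) drives the full comparison and
writes a reproducible report bundle: per-module TSV tables plus a
``summary.json`` with the headline quantities (expressed-gene series, DEG
counts per transition, chosen k and cluster categories per species, the
stage pair of minimal cross-species JSD, heterochrony direction
percentages, top enrichment terms).  Identical config + seed produce a
byte-identical summary; every output file carries a provenance header with
the tool version, config hash and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .expression import (
    ExpressionMatrix,
    StageDesign,
    ThresholdSpec,
    center_batches,
    expressed_counts_per_stage,
    hierarchical_sample_groups,
    pca_variance_explained,
    read_matrix,
    sample_correlation,
    stage_means,
)
from .de import deg_summary, nb_wald_pairwise, size_factors
from .clustering import categorize_clusters, fuzzy_cmeans, select_k, standardize_profiles
from .heterochrony import StageCorrespondence, call_heterochrony, shift_direction_summary
from .orthology import (
    OrthologyMap,
    cluster_overlap_tests,
    min_divergence_profile,
    normalize_divergence,
    read_orthogroups,
    stage_divergence,
)
from .simulate import SimulationConfig, generate_dataset

log = logging.getLogger("spiralcompare")


class ConfigError(ValueError):
    """Raised when a run configuration fails validation."""


_KNOWN_TOP_KEYS = {
    "seed", "outdir", "simulate", "inputs", "threshold", "de", "clustering",
    "heterochrony", "divergence",
}
_KNOWN_INPUT_KEYS = {
    "tpm_a", "counts_a", "design_a", "tpm_b", "counts_b", "design_b", "orthogroups",
}


@dataclass
class RunConfig:
    """Validated settings for one end-to-end run."""

    seed: int = 0
    outdir: str = "spiralcompare_out"
    simulate: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)
    threshold: dict = field(default_factory=dict)
    de: dict = field(default_factory=dict)
    clustering: dict = field(default_factory=dict)
    heterochrony: dict = field(default_factory=dict)
    divergence: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(open(path)) or {}
        errors = validate_config_dict(raw)
        if errors:
            raise ConfigError("; ".join(errors))
        return cls(**raw)

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload.pop("outdir", None)  # output location is not part of the analysis
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def validate_config_dict(raw: dict) -> list[str]:
    """All configuration problems at once, as human-readable strings."""
    errors = []
    if not isinstance(raw, dict):
        return ["configuration must be a mapping"]
    for key in raw:
        if key not in _KNOWN_TOP_KEYS:
            errors.append(f"unknown configuration key: {key!r}")
    seed = raw.get("seed", 0)
    if not isinstance(seed, int) or seed < 0:
        errors.append(f"seed must be a non-negative integer, got {seed!r}")
    inputs = raw.get("inputs") or {}
    for key, path in inputs.items():
        if key not in _KNOWN_INPUT_KEYS:
            errors.append(f"unknown input key: {key!r}")
        elif not Path(path).exists():
            errors.append(f"input file does not exist: {key}={path}")
    if not inputs and "simulate" not in raw:
        errors.append("either 'simulate' or 'inputs' must be provided")
    if inputs and not {"tpm_a", "tpm_b", "counts_a", "counts_b",
                       "design_a", "design_b", "orthogroups"} <= set(inputs):
        errors.append("file-driven runs need tpm/counts/design for both species and orthogroups")
    sim = raw.get("simulate") or {}
    if sim:
        valid = {f.name for f in dataclasses.fields(SimulationConfig)}
        for key in sim:
            if key not in valid:
                errors.append(f"unknown simulate parameter: {key!r}")
    return errors


def validate_config(path) -> list[str]:
    try:
        raw = yaml.safe_load(open(path)) or {}
    except yaml.YAMLError as exc:
        return [f"YAML parse error: {exc}"]
    return validate_config_dict(raw)


def _provenance(config: RunConfig) -> str:
    return f"# spiralcompare {__version__} config={config.config_hash()} seed={config.seed}"


def _write_tsv(df: pd.DataFrame, path: Path, config: RunConfig, index: bool = True) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance(config) + "\n")
        df.to_csv(fh, sep="\t", index=index)


def _load_inputs(config: RunConfig):
    inp = config.inputs
    tpm_a = read_matrix(inp["tpm_a"], inp["design_a"], "tpm")
    counts_a = read_matrix(inp["counts_a"], inp["design_a"], "counts")
    tpm_b = read_matrix(inp["tpm_b"], inp["design_b"], "tpm")
    counts_b = read_matrix(inp["counts_b"], inp["design_b"], "counts")
    orthology = read_orthogroups(inp["orthogroups"])
    return counts_a, tpm_a, counts_b, tpm_b, orthology, None


def run_all(config: RunConfig) -> dict:
    """Run the full pipeline and write the report bundle; returns the summary."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "tool_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
    }
    manifest: list[str] = []
    stage_name = "setup"
    try:
        # ---------------- data -------------------------------------------
        stage_name = "simulate" if config.simulate or not config.inputs else "load"
        if config.inputs:
            counts_a, tpm_a, counts_b, tpm_b, orthology, truth = _load_inputs(config)
        else:
            sim = SimulationConfig(**{**config.simulate, "seed": config.seed})
            counts_a, tpm_a, counts_b, tpm_b, orthology, truth = generate_dataset(sim)
        log.info("%s: A %s, B %s", stage_name, tpm_a.values.shape, tpm_b.values.shape)
        pairs = orthology.one_to_one
        threshold = ThresholdSpec(cutoff=float(config.threshold.get("cutoff", 2.0)))

        species = {"a": (counts_a, tpm_a), "b": (counts_b, tpm_b)}
        clusterings = {}
        for sp, (counts, tpm) in species.items():
            # ------------- QC -------------------------------------------
            stage_name = f"qc_{sp}"
            expressed = expressed_counts_per_stage(tpm, threshold)
            corr = sample_correlation(tpm)
            pca = pca_variance_explained(tpm, n_components=2)
            groups = hierarchical_sample_groups(corr, k=min(3, corr.shape[0]))
            _write_tsv(corr, outdir / f"sample_correlation_{sp}.tsv", config)
            _write_tsv(expressed.to_frame(), outdir / f"expressed_counts_{sp}.tsv", config)
            manifest += [f"sample_correlation_{sp}.tsv", f"expressed_counts_{sp}.tsv"]
            summary[f"expressed_genes_{sp}"] = {s: int(v) for s, v in expressed.items()}
            summary[f"pca_variance_percent_{sp}"] = [round(100 * float(v), 2) for v in pca]
            summary[f"sample_groups_{sp}"] = {s: int(g) for s, g in groups.items()}

            # ------------- DE -------------------------------------------
            stage_name = f"de_{sp}"
            factors = size_factors(counts, method="auto")
            stages = counts.design.stages
            results = {}
            for t, t1 in zip(stages[:-1], stages[1:]):
                results[f"{t}->{t1}"] = nb_wald_pairwise(counts, t, t1, factors=factors)
            degs = deg_summary(results, padj_cutoff=float(config.de.get("padj_cutoff", 0.05)))
            _write_tsv(degs, outdir / f"deg_counts_{sp}.tsv", config)
            manifest.append(f"deg_counts_{sp}.tsv")
            summary[f"deg_counts_{sp}"] = {
                tr: {"up": int(r["up"]), "down": int(r["down"])} for tr, r in degs.iterrows()
            }

            # ------------- clustering -----------------------------------
            stage_name = f"cluster_{sp}"
            centered = center_batches(tpm)
            z = standardize_profiles(stage_means(centered))
            k_setting = config.clustering.get("k", "auto")
            if k_setting == "auto":
                k_range = tuple(config.clustering.get("k_range", (2, 15)))
                k = select_k(z, k_range=k_range, seed=config.seed)
            else:
                k = int(k_setting)
            fc = fuzzy_cmeans(
                z,
                k=k,
                seed=config.seed,
                min_membership=float(config.clustering.get("min_membership", 0.5)),
            )
            categorize_clusters(fc)
            clusterings[sp] = fc
            _write_tsv(fc.membership, outdir / f"membership_{sp}.tsv", config)
            _write_tsv(fc.centroids, outdir / f"centroids_{sp}.tsv", config)
            manifest += [f"membership_{sp}.tsv", f"centroids_{sp}.tsv"]
            summary[f"clusters_{sp}"] = {"k": int(k), "categories": dict(sorted(fc.categories.items()))}

        # ---------------- cross-species comparison -----------------------
        stage_name = "divergence"
        sm_a = stage_means(tpm_a)
        sm_b = stage_means(tpm_b)
        div = stage_divergence(sm_a, sm_b, pairs)
        div = normalize_divergence(div, method=config.divergence.get("method", "minmax"))
        profile, argmin = min_divergence_profile(div)
        _write_tsv(div.raw, outdir / "jsd_raw.tsv", config)
        _write_tsv(div.normalized, outdir / "jsd_normalized.tsv", config)
        manifest += ["jsd_raw.tsv", "jsd_normalized.tsv"]
        summary["jsd_argmin_stage_pair"] = list(argmin)
        summary["jsd_min_profile"] = {s: round(float(v), 6) for s, v in profile.items()}

        stage_name = "cluster_overlap"
        overlap = cluster_overlap_tests(
            clusterings["a"].hard.drop(clusterings["a"].hard[clusterings["a"].hard == "unassigned"].index).to_dict(),
            clusterings["b"].hard.drop(clusterings["b"].hard[clusterings["b"].hard == "unassigned"].index).to_dict(),
            orthology,
        )
        _write_tsv(overlap, outdir / "cluster_overlap.tsv", config, index=False)
        manifest.append("cluster_overlap.tsv")
        best = overlap.nsmallest(3, "padj")
        summary["top_cluster_overlaps"] = [
            {
                "cluster_a": r.cluster_a,
                "cluster_b": r.cluster_b,
                "padj": float(f"{r.padj:.3e}"),
            }
            for r in best.itertuples()
        ]

        stage_name = "heterochrony"
        corr_table = StageCorrespondence.positional(tpm_a.design.stages, tpm_b.design.stages)
        calls = call_heterochrony(
            sm_a, sm_b, pairs, corr_table,
            threshold_a=ThresholdSpec(threshold.cutoff, inclusive=True),
            threshold_b=ThresholdSpec(threshold.cutoff, inclusive=True),
            min_offset=int(config.heterochrony.get("min_offset", 1)),
        )
        direction = shift_direction_summary(calls)
        _write_tsv(calls.set_index("orthogroup"), outdir / "heterochrony_calls.tsv", config)
        _write_tsv(direction, outdir / "heterochrony_direction.tsv", config)
        manifest += ["heterochrony_calls.tsv", "heterochrony_direction.tsv"]
        summary["heterochrony"] = {
            cl: {
                "n": int(direction.loc[cl, "n"]),
                "percent_of_shifted": None
                if pd.isna(direction.loc[cl, "percent_of_shifted"])
                else float(direction.loc[cl, "percent_of_shifted"]),
            }
            for cl in direction.index
        }
    except Exception as exc:
        (outdir / "MANIFEST.partial.txt").write_text("\n".join(manifest) + "\n")
        raise RuntimeError(
            f"pipeline failed at stage {stage_name!r}; partial outputs listed in "
            f"{outdir / 'MANIFEST.partial.txt'}"
        ) from exc

    (outdir / "MANIFEST.txt").write_text("\n".join(manifest + ["summary.json"]) + "\n")
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return summary
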