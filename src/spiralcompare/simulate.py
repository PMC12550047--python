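"""Synthetic two-species developmental transcriptome generator with planted truth.

The generator emulates the structure of a two-species embryonic time course
in spiral-cleaving annelids: nine ordered stages from oocyte to gastrula
sampled in replicate, maternal transcripts decaying in two waves (an
oocyte/zygote-specific cluster cleared immediately and a maternal-decay
cluster cleared by mid-cleavage), zygotic genome activation between the 2nd
and 4th cleavage, stage-specific clusters present only in species B, a
large embryonic cluster rising at gastrulation, cross-species conservation
of one-to-one ortholog profiles that peaks at a configurable "hourglass"
stage, planted heterochronic activation shifts, phylostratum labels
correlated with cluster age, planted GO signatures per cluster, and
codon-usage bias in oocyte-specific genes.

Every random quantity is drawn from one ``numpy`` generator seeded from the
config, so identical configs give byte-identical outputs.  A machine-
readable :class:`SyntheticTruth` records everything that was planted so the
downstream modules can be tested as parameter-recovery problems.

Scale convention: per-gene stage profiles are built in arbitrary
"expression intent" units (amplitude x template + a weak noise floor);
expected read counts allocate a sampled library size proportionally to
intent x gene length, and TPM is then re-derived from the counts and
lengths, exactly as for real data.  ``dispersion == 0`` produces
deterministic, noise-free counts (rounded expected values).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .expression import DEFAULT_STAGES, ExpressionMatrix, StageDesign
from .orthology import OrthologyMap, write_orthogroups


class SimulationConfigError(ValueError):
    """Raised when a SimulationConfig violates its invariants."""


# ---------------------------------------------------------------------------
# Cluster templates
# ---------------------------------------------------------------------------

# canonical profile shapes as (normalized stage position, level) control points
_TEMPLATE_KNOTS: dict[str, list[tuple[float, float]]] = {
    "oocyte_zygote_specific": [(0, 1), (0.125, 0.9), (0.25, 0.1), (0.35, 0.0), (1, 0)],
    "maternal_decay": [(0, 1), (0.125, 1), (0.25, 0.8), (0.375, 0.4), (0.5, 0.1), (0.6, 0.0), (1, 0)],
    "early_zygotic": [(0, 0), (0.2, 0), (0.25, 0.05), (0.375, 0.3), (0.5, 0.7),
                      (0.625, 1), (0.75, 0.9), (0.875, 0.6), (1, 0.3)],
    "late_zygotic": [(0, 0), (0.45, 0), (0.5, 0.05), (0.625, 0.3), (0.75, 0.6),
                     (0.875, 1), (1, 0.7)],
    "embryonic": [(0, 0), (0.55, 0), (0.625, 0.05), (0.75, 0.1), (0.875, 0.3), (1, 1)],
}

#: categories whose template activates after the first stage; only these can
#: carry a detectable activation shift
ZYGOTIC_CATEGORIES = ("early_zygotic", "late_zygotic", "embryonic")


def template_for(category: str, stages: tuple[str, ...]) -> np.ndarray:
    """Mean-profile template for a cluster category over the given stages."""
    n = len(stages)
    pos = np.linspace(0.0, 1.0, n)
    if category.startswith("stage_specific:"):
        stage = category.split(":", 1)[1]
        if stage not in stages:
            raise SimulationConfigError(f"stage-specific cluster names unknown stage {stage!r}")
        peak = stages.index(stage)
        tpl = np.zeros(n)
        tpl[peak] = 1.0
        if peak > 0:
            tpl[peak - 1] = 0.3
        if peak < n - 1:
            tpl[peak + 1] = 0.3
        return tpl
    if category not in _TEMPLATE_KNOTS:
        raise SimulationConfigError(f"unknown cluster category {category!r}")
    xs, ys = zip(*_TEMPLATE_KNOTS[category])
    return np.interp(pos, xs, ys)


def shifted_template(template: np.ndarray, shift: int) -> np.ndarray:
    """Displace a template along the stage axis; negative = earlier, edge-clipped."""
    n = template.size
    idx = np.clip(np.arange(n) - shift, 0, n - 1)
    return template[idx]


def categorize_template(template: np.ndarray, stages: tuple[str, ...]) -> str:
    """Rule-based category of a mean profile (same rules as cluster labelling)."""
    from .clustering import categorize_profile  # deferred: avoids import cycle

    return categorize_profile(np.asarray(template, dtype=float), stages)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClusterSpec:
    """One planted coexpression cluster: category label and gene count."""

    category: str
    size: int


def default_cluster_fractions_a() -> list[tuple[str, float]]:
    return [
        ("oocyte_zygote_specific", 0.12),
        ("maternal_decay", 0.18),
        ("early_zygotic", 0.16),
        ("late_zygotic", 0.14),
        ("embryonic", 0.40),
    ]


def default_cluster_fractions_b(stages: tuple[str, ...]) -> list[tuple[str, float]]:
    mid = [s for s in stages[5:-1]] or [stages[len(stages) // 2]]
    spec = [
        ("oocyte_zygote_specific", 0.10),
        ("maternal_decay", 0.18),
        ("early_zygotic", 0.20),
    ]
    stage_frac = {0: [], 1: [0.32], 2: [0.14, 0.18], 3: [0.08, 0.10, 0.14]}
    fracs = stage_frac.get(min(len(mid), 3), [0.08, 0.10, 0.14])
    for s, f in zip(mid[:3], fracs):
        spec.append((f"stage_specific:{s}", f))
    spec.append(("embryonic", round(1.0 - sum(f for _, f in spec), 10)))
    return spec


def _sizes_from_fractions(fracs: list[tuple[str, float]], n: int) -> list[ClusterSpec]:
    sizes = [int(round(f * n)) for _, f in fracs]
    sizes[-1] += n - sum(sizes)  # absorb rounding remainder in the last cluster
    return [ClusterSpec(cat, s) for (cat, _), s in zip(fracs, sizes)]


def default_conservation_curve(n_stages: int, peak: int) -> tuple[float, ...]:
    """Conservation weights in [0,1], rising to a maximum at the hourglass stage."""
    i = np.arange(n_stages)
    w = 0.2 + 0.75 * np.exp(-(((i - peak) / 1.8) ** 2))
    return tuple(float(x) for x in w)


@dataclass(frozen=True)
class SimulationConfig:
    """Generator settings; the defaults define the reference study conditions."""

    n_genes_per_species: int = 5000
    stages: tuple[str, ...] = DEFAULT_STAGES
    n_replicates: int = 2
    frac_one_to_one: float = 0.6
    cluster_spec_a: tuple[ClusterSpec, ...] | None = None
    cluster_spec_b: tuple[ClusterSpec, ...] | None = None
    hourglass_peak_stage: int = 8
    conservation_weight_curve: tuple[float, ...] | None = None
    frac_shifted: float = 0.2
    shift_magnitude: int = -2          # negative: species B activates earlier
    dispersion: float = 0.05           # NB dispersion alpha; 0 = deterministic counts
    profile_noise_sd: float = 0.25     # per-stage log-normal biological noise
    amplitude_log_mean: float = np.log(50.0)
    amplitude_log_sd: float = 0.8
    noise_floor_log_mean: float = np.log(0.01)
    noise_floor_log_sd: float = 0.5
    libsize_range: tuple[float, float] = (8e5, 1.2e6)
    frac_tf: float = 0.05
    frac_unannotated_stage_specific: float = 0.5
    seed: int = 0

    def resolved_cluster_spec(self, species: str) -> tuple[ClusterSpec, ...]:
        spec = self.cluster_spec_a if species == "a" else self.cluster_spec_b
        if spec is None:
            fracs = (
                default_cluster_fractions_a()
                if species == "a"
                else default_cluster_fractions_b(self.stages)
            )
            spec = tuple(_sizes_from_fractions(fracs, self.n_genes_per_species))
        return tuple(spec)

    def resolved_conservation_curve(self) -> np.ndarray:
        curve = self.conservation_weight_curve
        if curve is None:
            curve = default_conservation_curve(len(self.stages), self.hourglass_peak_stage)
        return np.asarray(curve, dtype=float)

    def validate(self) -> None:
        n = self.n_genes_per_species
        if not isinstance(n, (int, np.integer)) or n <= 0:
            raise SimulationConfigError(f"n_genes_per_species must be a positive integer, got {n!r}")
        if self.n_replicates < 1:
            raise SimulationConfigError("n_replicates must be >= 1")
        for name in ("frac_one_to_one", "frac_shifted", "frac_tf",
                     "frac_unannotated_stage_specific"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationConfigError(f"{name} must be in [0, 1], got {v}")
        for species in ("a", "b"):
            spec = self.resolved_cluster_spec(species)
            sizes = [c.size for c in spec]
            if any((not isinstance(s, (int, np.integer))) or s < 0 for s in sizes):
                raise SimulationConfigError(f"cluster sizes must be non-negative integers: {sizes}")
            if sum(sizes) != n:
                raise SimulationConfigError(
                    f"cluster sizes for species {species} sum to {sum(sizes)}, expected {n}"
                )
            for c in spec:
                template_for(c.category, self.stages)  # validates category names
        curve = self.resolved_conservation_curve()
        if curve.size != len(self.stages):
            raise SimulationConfigError(
                f"conservation_weight_curve length {curve.size} != n_stages {len(self.stages)}"
            )
        if (curve < 0).any() or (curve > 1).any():
            raise SimulationConfigError("conservation weights must lie in [0, 1]")
        if curve[self.hourglass_peak_stage] < curve.max():
            raise SimulationConfigError(
                "conservation_weight_curve must peak at hourglass_peak_stage"
            )
        if not 0 <= self.hourglass_peak_stage < len(self.stages):
            raise SimulationConfigError("hourglass_peak_stage out of range")
        if self.dispersion < 0:
            raise SimulationConfigError("dispersion must be >= 0")
        lo, hi = self.libsize_range
        if not (0 < lo <= hi):
            raise SimulationConfigError(f"invalid libsize_range {self.libsize_range}")
        if self.frac_one_to_one * n < 10:
            warnings.warn("fewer than 10 one-to-one pairs; downstream tests are underpowered")


# ---------------------------------------------------------------------------
# Truth record
# ---------------------------------------------------------------------------

# cluster category -> planted signature GO term (id, name)
GO_SIGNATURES: dict[str, tuple[str, str]] = {
    "oocyte_zygote_specific": ("GO:0008152", "metabolic process"),
    "maternal_decay": ("GO:0007049", "cell cycle"),
    "early_zygotic": ("GO:0008104", "protein localization"),
    "late_zygotic": ("GO:0035556", "intracellular signal transduction"),
    "stage_specific": ("GO:0007218", "neuropeptide signaling pathway"),
    "embryonic": ("GO:0006351", "DNA-templated transcription"),
}

BACKGROUND_GO_TERMS: list[tuple[str, str]] = [
    ("GO:0005515", "protein binding"),
    ("GO:0016020", "membrane"),
    ("GO:0005634", "nucleus"),
]

PHYLOSTRATA: tuple[str, ...] = (
    "Metazoa", "Bilateria", "Protostomia", "Spiralia", "species_specific"
)

# sampling weights over PHYLOSTRATA by cluster category class; the embryonic
# cluster is distinctly ancient-gene-heavy so that old strata peak at the
# gastrula, stage-specific clusters are dominated by species-specific genes
_STRATUM_WEIGHTS = {
    "stage_specific": (0.10, 0.10, 0.10, 0.10, 0.60),
    "oocyte_zygote_specific": (0.20, 0.20, 0.15, 0.15, 0.30),
    "embryonic": (0.42, 0.30, 0.10, 0.08, 0.10),
    "old_heavy": (0.28, 0.18, 0.20, 0.16, 0.18),
}


@dataclass
class SyntheticTruth:
    """Everything planted by the generator, for parameter-recovery tests."""

    cluster_a: dict[str, str]
    cluster_b: dict[str, str]
    pairs: pd.DataFrame            # orthogroup, gene_a, gene_b, shift_class, shift_magnitude
    matched_cluster_pairs: list[tuple[str, str]]
    phylostratum_a: dict[str, str]
    phylostratum_b: dict[str, str]
    go_a: dict[str, list[str]]
    go_b: dict[str, list[str]]
    go_term_names: dict[str, str]
    codon_bias_a: dict[str, bool]
    codon_bias_b: dict[str, bool]
    tf_a: list[str]
    tf_b: list[str]
    gene_length_a: dict[str, int]
    gene_length_b: dict[str, int]
    hourglass_peak_stage: int
    stages: tuple[str, ...]
    seed: int

    def shift_counts(self) -> pd.Series:
        return self.pairs["shift_class"].value_counts()

    def to_json(self, path) -> None:
        payload = {
            "cluster_a": self.cluster_a,
            "cluster_b": self.cluster_b,
            "pairs": self.pairs.to_dict(orient="list"),
            "matched_cluster_pairs": [list(p) for p in self.matched_cluster_pairs],
            "phylostratum_a": self.phylostratum_a,
            "phylostratum_b": self.phylostratum_b,
            "go_a": self.go_a,
            "go_b": self.go_b,
            "go_term_names": self.go_term_names,
            "codon_bias_a": self.codon_bias_a,
            "codon_bias_b": self.codon_bias_b,
            "tf_a": self.tf_a,
            "tf_b": self.tf_b,
            "gene_length_a": self.gene_length_a,
            "gene_length_b": self.gene_length_b,
            "hourglass_peak_stage": self.hourglass_peak_stage,
            "stages": list(self.stages),
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())
        payload["pairs"] = pd.DataFrame(payload["pairs"])[
            ["orthogroup", "gene_a", "gene_b", "shift_class", "shift_magnitude"]
        ]
        payload["matched_cluster_pairs"] = [tuple(p) for p in payload["matched_cluster_pairs"]]
        payload["stages"] = tuple(payload["stages"])
        return cls(**payload)


class SimulatedDataset(NamedTuple):
    counts_a: ExpressionMatrix
    tpm_a: ExpressionMatrix
    counts_b: ExpressionMatrix
    tpm_b: ExpressionMatrix
    orthology: OrthologyMap
    truth: SyntheticTruth


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _allocate_pairs(
    spec_a: tuple[ClusterSpec, ...],
    spec_b: tuple[ClusterSpec, ...],
    n_pairs: int,
) -> dict[str, int]:
    """Split the one-to-one pair budget over categories shared by both species."""
    sizes_a = {c.category: c.size for c in spec_a}
    sizes_b = {c.category: c.size for c in spec_b}
    shared = [c for c in sizes_a if c in sizes_b]
    caps = {c: min(sizes_a[c], sizes_b[c]) for c in shared}
    cap_total = sum(caps.values())
    if cap_total < n_pairs:
        raise SimulationConfigError(
            f"cannot place {n_pairs} one-to-one pairs: shared-category capacity is {cap_total}"
        )
    raw = {c: n_pairs * caps[c] / cap_total for c in shared}
    alloc = {c: int(np.floor(v)) for c, v in raw.items()}
    leftovers = sorted(shared, key=lambda c: raw[c] - alloc[c], reverse=True)
    for c in leftovers[: n_pairs - sum(alloc.values())]:
        alloc[c] += 1
    return alloc


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """Negative-binomial counts with variance mu + alpha*mu^2 (gamma-Poisson)."""
    if alpha == 0.0:
        return np.rint(mean).astype(np.int64)
    mean = np.clip(mean, 0.0, None)
    lam = rng.gamma(shape=1.0 / alpha, scale=alpha * np.where(mean > 0, mean, 1.0))
    lam = np.where(mean > 0, lam, 0.0)
    return rng.poisson(lam).astype(np.int64)


def generate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Simulate the full two-species dataset plus its ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    stages = config.stages
    n_stages = len(stages)
    n = config.n_genes_per_species
    spec_a = config.resolved_cluster_spec("a")
    spec_b = config.resolved_cluster_spec("b")
    weights = config.resolved_conservation_curve()

    genes_a = [f"A{i:05d}" for i in range(n)]
    genes_b = [f"B{i:05d}" for i in range(n)]
    cat_a: dict[str, str] = {}
    cat_b: dict[str, str] = {}
    by_cat_a: dict[str, list[str]] = {}
    by_cat_b: dict[str, list[str]] = {}
    i = 0
    for c in spec_a:
        block = genes_a[i : i + c.size]
        by_cat_a[c.category] = block
        cat_a.update({g: c.category for g in block})
        i += c.size
    i = 0
    for c in spec_b:
        block = genes_b[i : i + c.size]
        by_cat_b[c.category] = block
        cat_b.update({g: c.category for g in block})
        i += c.size

    # --- one-to-one pairing over shared categories -------------------------
    n_pairs = int(round(config.frac_one_to_one * n))
    alloc = _allocate_pairs(spec_a, spec_b, n_pairs)
    pair_rows = []
    for cat in alloc:
        for ga, gb in zip(by_cat_a[cat][: alloc[cat]], by_cat_b[cat][: alloc[cat]]):
            pair_rows.append({"gene_a": ga, "gene_b": gb, "category": cat})
    pairs = pd.DataFrame(pair_rows)
    pairs.insert(0, "orthogroup", [f"OG{i:07d}" for i in range(len(pairs))])

    # --- heterochronic shifts (zygotic-onset pairs only) -------------------
    n_shift = int(round(config.frac_shifted * len(pairs)))
    eligible = pairs.index[pairs["category"].isin(ZYGOTIC_CATEGORIES)].to_numpy()
    if n_shift > eligible.size:
        raise SimulationConfigError(
            f"frac_shifted needs {n_shift} zygotic-onset pairs, only {eligible.size} available"
        )
    shifted_idx = np.sort(rng.choice(eligible, size=n_shift, replace=False))
    shift = int(config.shift_magnitude)
    if shift < 0:
        shift_class = "earlier_in_B"
    elif shift > 0:
        shift_class = "earlier_in_A"
    else:
        shift_class = "same"
    pairs["shift_class"] = "same"
    pairs["shift_magnitude"] = 0
    if shift != 0:
        pairs.loc[shifted_idx, "shift_class"] = shift_class
        pairs.loc[shifted_idx, "shift_magnitude"] = shift

    # --- per-gene latent profiles ------------------------------------------
    templates = {c.category: template_for(c.category, stages) for c in spec_a + spec_b}
    tpl_a = np.vstack([templates[cat_a[g]] for g in genes_a])
    tpl_b = np.vstack([templates[cat_b[g]] for g in genes_b])
    idx_a = {g: i for i, g in enumerate(genes_a)}
    idx_b = {g: i for i, g in enumerate(genes_b)}
    for row in pairs.itertuples():
        if row.shift_magnitude != 0:
            tpl_b[idx_b[row.gene_b]] = shifted_template(
                templates[row.category], row.shift_magnitude
            )

    amp_a = rng.lognormal(config.amplitude_log_mean, config.amplitude_log_sd, size=n)
    amp_b = rng.lognormal(config.amplitude_log_mean, config.amplitude_log_sd, size=n)
    # the floor is calibrated on the realized-TPM scale of the reference
    # 5000-gene transcriptome; TPM is compositional, so the intent value
    # scales with n to keep the realized floor magnitude size-invariant
    floor_mean = config.noise_floor_log_mean + np.log(n / 5000.0)
    floor_a = rng.lognormal(floor_mean, config.noise_floor_log_sd, size=n)
    floor_b = rng.lognormal(floor_mean, config.noise_floor_log_sd, size=n)
    ia = pairs["gene_a"].map(idx_a).to_numpy()
    ib = pairs["gene_b"].map(idx_b).to_numpy()
    amp_b[ib] = amp_a[ia]          # conserved pairs share amplitude
    floor_b[ib] = floor_a[ia]

    z_a = rng.standard_normal((n, n_stages))
    z_b = rng.standard_normal((n, n_stages))
    z_shared = rng.standard_normal((len(pairs), n_stages))
    sqw = np.sqrt(weights)
    sq1w = np.sqrt(1.0 - weights)
    z_a[ia] = sqw * z_shared + sq1w * z_a[ia]
    z_b[ib] = sqw * z_shared + sq1w * z_b[ib]

    sd = config.profile_noise_sd
    q_a = (amp_a[:, None] * tpl_a + floor_a[:, None]) * np.exp(sd * z_a)
    q_b = (amp_b[:, None] * tpl_b + floor_b[:, None]) * np.exp(sd * z_b)

    # --- gene lengths (multiples of 3; shared within a pair) ---------------
    len_a = 3 * rng.integers(167, 1000, size=n)
    len_b = 3 * rng.integers(167, 1000, size=n)
    len_b[ib] = len_a[ia]

    # --- counts and TPM -----------------------------------------------------
    design = StageDesign.default(stages, config.n_replicates)
    # library sizes are drawn once per sample slot and shared by the two
    # species (a paired design); with zero dispersion and noise the
    # one-to-one submatrices are then exactly equal
    libsizes = rng.uniform(*config.libsize_range, size=len(design.samples))

    def _counts_and_tpm(q: np.ndarray, lengths: np.ndarray, genes: list[str]):
        lens_kb = lengths / 1000.0
        counts = np.empty((len(genes), len(design.samples)), dtype=np.int64)
        for j, sample in enumerate(design.samples.index):
            s = design.stage_index(design.samples.loc[sample, "stage"])
            share = q[:, s] * lens_kb
            mu = libsizes[j] * share / share.sum()
            counts[:, j] = _nb_draw(rng, mu, config.dispersion)
        rate = counts / lens_kb[:, None]
        tpm = rate / rate.sum(axis=0) * 1e6
        cols = list(design.samples.index)
        cm = ExpressionMatrix(
            pd.DataFrame(counts, index=genes, columns=cols), "counts", design
        )
        tm = ExpressionMatrix(
            pd.DataFrame(tpm, index=genes, columns=cols), "tpm", design
        )
        return cm, tm

    counts_a, tpm_a = _counts_and_tpm(q_a, len_a, genes_a)
    counts_b, tpm_b = _counts_and_tpm(q_b, len_b, genes_b)

    # --- orthogroups: one-to-one plus some multi-copy groups ---------------
    groups: dict[str, tuple[list[str], list[str]]] = {
        row.orthogroup: ([row.gene_a], [row.gene_b]) for row in pairs.itertuples()
    }
    og_i = len(groups)
    paired_a = set(pairs["gene_a"])
    paired_b = set(pairs["gene_b"])
    for cat in sorted(set(by_cat_a) & set(by_cat_b)):
        rest_a = [g for g in by_cat_a[cat] if g not in paired_a]
        rest_b = [g for g in by_cat_b[cat] if g not in paired_b]
        # use half of the leftovers for alternating 2:1 and 1:2 groups;
        # the remainder stays orthogroup-free (lineage-restricted genes)
        budget_a, budget_b = len(rest_a) // 2, len(rest_b) // 2
        flip = True
        while budget_a >= 2 and budget_b >= 2:
            if flip:
                groups[f"OG{og_i:07d}"] = ([rest_a.pop(), rest_a.pop()], [rest_b.pop()])
                budget_a, budget_b = budget_a - 2, budget_b - 1
            else:
                groups[f"OG{og_i:07d}"] = ([rest_a.pop()], [rest_b.pop(), rest_b.pop()])
                budget_a, budget_b = budget_a - 1, budget_b - 2
            og_i += 1
            flip = not flip
    orthology = OrthologyMap(groups=groups)

    # --- truth categories (shifted genes relabelled by realised profile) ---
    truth_cat_b = dict(cat_b)
    for row in pairs.itertuples():
        if row.shift_magnitude != 0:
            truth_cat_b[row.gene_b] = categorize_template(tpl_b[idx_b[row.gene_b]], stages)

    # --- phylostrata ---------------------------------------------------------
    def _strata(cats: dict[str, str]) -> dict[str, str]:
        out = {}
        for g, c in cats.items():
            if c.startswith("stage_specific:"):
                w = _STRATUM_WEIGHTS["stage_specific"]
            elif c in ("oocyte_zygote_specific", "embryonic"):
                w = _STRATUM_WEIGHTS[c]
            else:
                w = _STRATUM_WEIGHTS["old_heavy"]
            out[g] = PHYLOSTRATA[rng.choice(len(PHYLOSTRATA), p=w)]
        return out

    strata_a = _strata(cat_a)
    strata_b = _strata(truth_cat_b)

    # --- GO annotations ------------------------------------------------------
    term_names = {tid: name for tid, name in
                  list(GO_SIGNATURES.values()) + BACKGROUND_GO_TERMS}

    def _annotate(cats: dict[str, str]) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for g, c in cats.items():
            key = "stage_specific" if c.startswith("stage_specific:") else c
            if key == "stage_specific" and rng.random() < config.frac_unannotated_stage_specific:
                out[g] = []
                continue
            terms = []
            sig = GO_SIGNATURES[key][0]
            if rng.random() < 0.5:
                terms.append(sig)
            for tid, _ in BACKGROUND_GO_TERMS:
                if rng.random() < 0.25:
                    terms.append(tid)
            if not terms:  # deliberately unannotated genes are flagged above
                terms.append(BACKGROUND_GO_TERMS[0][0])
            out[g] = terms
        return out

    go_a = _annotate(cat_a)
    go_b = _annotate(truth_cat_b)

    # --- TF flags (pair-consistent) and codon bias ---------------------------
    tf_a = set(np.array(genes_a)[rng.random(n) < config.frac_tf])
    tf_b = set(np.array(genes_b)[rng.random(n) < config.frac_tf])
    for row in pairs.itertuples():
        if row.gene_a in tf_a:
            tf_b.add(row.gene_b)
        elif row.gene_b in tf_b:
            tf_a.add(row.gene_a)
    codon_bias_a = {g: cat_a[g] == "oocyte_zygote_specific" for g in genes_a}
    codon_bias_b = {g: truth_cat_b[g] == "oocyte_zygote_specific" for g in genes_b}

    truth = SyntheticTruth(
        cluster_a=cat_a,
        cluster_b=truth_cat_b,
        pairs=pairs[["orthogroup", "gene_a", "gene_b", "shift_class", "shift_magnitude"]],
        matched_cluster_pairs=[(c, c) for c in sorted(set(by_cat_a) & set(by_cat_b))],
        phylostratum_a=strata_a,
        phylostratum_b=strata_b,
        go_a=go_a,
        go_b=go_b,
        go_term_names=term_names,
        codon_bias_a=codon_bias_a,
        codon_bias_b=codon_bias_b,
        tf_a=sorted(tf_a),
        tf_b=sorted(tf_b),
        gene_length_a={g: int(l) for g, l in zip(genes_a, len_a)},
        gene_length_b={g: int(l) for g, l in zip(genes_b, len_b)},
        hourglass_peak_stage=config.hourglass_peak_stage,
        stages=stages,
        seed=config.seed,
    )
    return SimulatedDataset(counts_a, tpm_a, counts_b, tpm_b, orthology, truth)


# ---------------------------------------------------------------------------
# Coding sequences and fixture bundle
# ---------------------------------------------------------------------------

from Bio.Data.CodonTable import standard_dna_table  # noqa: E402

_SENSE_CODONS = sorted(standard_dna_table.forward_table)
_FAMILIES: dict[str, list[str]] = {}
for codon in _SENSE_CODONS:
    _FAMILIES.setdefault(standard_dna_table.forward_table[codon], []).append(codon)
#: one designated preferred codon per synonymous family (alphabetically first)
PREFERRED_CODONS: dict[str, str] = {aa: sorted(cods)[0] for aa, cods in _FAMILIES.items()}


def generate_cds(
    truth: SyntheticTruth, species: str, rng: np.random.Generator, bias: float = 0.6
) -> dict[str, str]:
    """Simulated CDS per gene: ATG ... TAA, sense codons only.

    Codon-bias-flagged genes draw each family's designated preferred codon
    with probability ``bias`` (uniform across families otherwise), so their
    preferred-codon frequency exceeds 1/#synonyms by construction.
    """
    lengths = truth.gene_length_a if species == "a" else truth.gene_length_b
    flags = truth.codon_bias_a if species == "a" else truth.codon_bias_b
    aas = sorted(_FAMILIES)
    out = {}
    for gene in sorted(lengths):
        n_codons = max(lengths[gene] // 3 - 2, 1)
        aa_seq = [aas[i] for i in rng.integers(0, len(aas), size=n_codons)]
        codons = []
        for aa in aa_seq:
            fam = _FAMILIES[aa]
            if flags.get(gene) and rng.random() < bias:
                codons.append(PREFERRED_CODONS[aa])
            else:
                codons.append(fam[rng.integers(0, len(fam))])
        out[gene] = "ATG" + "".join(codons) + "TAA"
    return out


def write_fixture_bundle(dataset: SimulatedDataset, directory, write_cds: bool = True,
                         cds_seed: int = 0) -> dict[str, Path]:
    """Write TSV matrices, design, orthogroups, annotations, CDS and truth JSON."""
    from .expression import write_matrix

    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create fixture directory {directory}: {exc}") from exc
    truth = dataset.truth
    paths: dict[str, Path] = {}

    def _put(key: str, name: str) -> Path:
        paths[key] = directory / name
        return paths[key]

    write_matrix(dataset.counts_a, _put("counts_a", "species_a_counts.tsv"))
    write_matrix(dataset.tpm_a, _put("tpm_a", "species_a_tpm.tsv"))
    write_matrix(dataset.counts_b, _put("counts_b", "species_b_counts.tsv"))
    write_matrix(dataset.tpm_b, _put("tpm_b", "species_b_tpm.tsv"))
    dataset.counts_a.design.to_table(_put("design_a", "species_a_design.tsv"))
    dataset.counts_b.design.to_table(_put("design_b", "species_b_design.tsv"))
    write_orthogroups(dataset.orthology, _put("orthogroups", "orthogroups.tsv"))

    for species, go in (("a", truth.go_a), ("b", truth.go_b)):
        rows = [{"gene": g, "term": t} for g in sorted(go) for t in go[g]]
        pd.DataFrame(rows, columns=["gene", "term"]).to_csv(
            _put(f"go_{species}", f"species_{species}_go.tsv"), sep="\t", index=False
        )
    for species, strata in (("a", truth.phylostratum_a), ("b", truth.phylostratum_b)):
        pd.DataFrame(
            [{"gene": g, "phylostratum": s} for g, s in sorted(strata.items())]
        ).to_csv(_put(f"strata_{species}", f"species_{species}_phylostrata.tsv"),
                 sep="\t", index=False)
    for species, tfs in (("a", truth.tf_a), ("b", truth.tf_b)):
        pd.DataFrame({"gene": tfs}).to_csv(
            _put(f"tf_{species}", f"species_{species}_tfs.tsv"), sep="\t", index=False
        )

    if write_cds:
        rng = np.random.default_rng(cds_seed)
        for species in ("a", "b"):
            cds = generate_cds(truth, species, rng)
            with open(_put(f"cds_{species}", f"species_{species}_cds.fasta"), "w") as fh:
                for gene, seq in cds.items():
                    fh.write(f">{gene}\n")
                    for k in range(0, len(seq), 70):
                        fh.write(seq[k : k + 70] + "\n")

    truth.to_json(_put("truth", "truth.json"))
    return paths
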