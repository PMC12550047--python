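"""Heterochronic-shift calling between two species' developmental time courses.

An ortholog's *activation* is the first stage at which its stage-mean TPM
reaches the expression cutoff ('>=' by convention; maternal presence at the
first stage counts as activation there).  Activations are compared across
species on a stage-correspondence table — an ordered list of matched stage
pairs, optionally with excluded stages that are dropped from both sides
before comparison — and each one-to-one pair is classified as
``earlier_in_A``, ``earlier_in_B``, ``same``, ``inactive`` (never reaching
the cutoff on matched stages in either species) or ``unscored`` (active
only within excluded stages).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .expression import ThresholdSpec


class HeterochronyError(ValueError):
    """Raised for invalid correspondences or call inputs."""


SHIFT_CLASSES = ("earlier_in_A", "earlier_in_B", "same", "inactive", "unscored")


@dataclass(frozen=True)
class StageCorrespondence:
    """Ordered matched stage pairs across species, with per-species exclusions."""

    matched: tuple[tuple[str, str], ...]
    excluded_a: tuple[str, ...] = ()
    excluded_b: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for side, excl in ((0, self.excluded_a), (1, self.excluded_b)):
            listed = [p[side] for p in self.matched]
            bad = set(excl) & set(listed)
            if bad:
                raise HeterochronyError(f"excluded stages also matched: {sorted(bad)}")

    @classmethod
    def positional(cls, stages_a: Iterable[str], stages_b: Iterable[str]) -> "StageCorrespondence":
        """Match equally long ordered stage lists position by position."""
        a, b = list(stages_a), list(stages_b)
        if len(a) != len(b):
            raise HeterochronyError(
                f"positional matching needs equal stage counts ({len(a)} vs {len(b)})"
            )
        return cls(matched=tuple(zip(a, b)))

    @classmethod
    def from_yaml(cls, path) -> "StageCorrespondence":
        spec = yaml.safe_load(open(path))
        return cls(
            matched=tuple((str(a), str(b)) for a, b in spec["matched"]),
            excluded_a=tuple(spec.get("excluded_a", [])),
            excluded_b=tuple(spec.get("excluded_b", [])),
        )


def activation_stage(
    profile: pd.Series, threshold: ThresholdSpec, stage_order: Iterable[str]
) -> str | None:
    """First stage (in order) whose mean TPM reaches the cutoff; None if never."""
    cutoff = threshold.cutoff
    for stage in stage_order:
        v = profile[stage]
        if v >= cutoff if threshold.inclusive else v > cutoff:
            return stage
    return None


def classify_shift(
    profile_a: pd.Series,
    profile_b: pd.Series,
    threshold_a: ThresholdSpec,
    threshold_b: ThresholdSpec,
    correspondence: StageCorrespondence,
    min_offset: int = 1,
) -> dict:
    """Classify one ortholog pair's activation-timing relationship.

    Activation is evaluated on the matched (non-excluded) stages of each
    species; a pair active only within excluded stages is ``unscored`` and a
    pair never reaching the cutoff anywhere is ``inactive``.  A shift needs
    a matched-index offset of at least ``min_offset``.
    """
    stages_a = [p[0] for p in correspondence.matched]
    stages_b = [p[1] for p in correspondence.matched]
    for stage in stages_a:
        if stage not in profile_a.index:
            raise HeterochronyError(f"stage {stage!r} missing from species-A profile")
    for stage in stages_b:
        if stage not in profile_b.index:
            raise HeterochronyError(f"stage {stage!r} missing from species-B profile")
    act_a = activation_stage(profile_a[stages_a], threshold_a, stages_a)
    act_b = activation_stage(profile_b[stages_b], threshold_b, stages_b)
    idx_a = stages_a.index(act_a) if act_a is not None else None
    idx_b = stages_b.index(act_b) if act_b is not None else None
    if idx_a is None or idx_b is None:
        # distinguish truly silent pairs from those active only in excluded stages
        def _active_excluded(profile, thr, excluded):
            return any(
                (profile[s] >= thr.cutoff if thr.inclusive else profile[s] > thr.cutoff)
                for s in excluded
                if s in profile.index
            )

        silent_a = idx_a is None and not _active_excluded(
            profile_a, threshold_a, correspondence.excluded_a
        )
        silent_b = idx_b is None and not _active_excluded(
            profile_b, threshold_b, correspondence.excluded_b
        )
        if (idx_a is None and not silent_a) or (idx_b is None and not silent_b):
            cls = "unscored"
        else:
            cls = "inactive"
    elif idx_a - idx_b >= min_offset:
        cls = "earlier_in_B"
    elif idx_b - idx_a >= min_offset:
        cls = "earlier_in_A"
    else:
        cls = "same"
    return {
        "activation_a": act_a,
        "activation_b": act_b,
        "index_a": idx_a,
        "index_b": idx_b,
        "shift_class": cls,
    }


def call_heterochrony(
    stage_means_a: pd.DataFrame,
    stage_means_b: pd.DataFrame,
    pairs: pd.DataFrame,
    correspondence: StageCorrespondence,
    threshold_a: ThresholdSpec | None = None,
    threshold_b: ThresholdSpec | None = None,
    min_offset: int = 1,
    tf_genes_a: set[str] | None = None,
    tf_genes_b: set[str] | None = None,
) -> pd.DataFrame:
    """Vectorised shift calls for every one-to-one pair.

    Thresholds default to TPM >= 2 in both species.  ``pairs`` has columns
    ``gene_a``/``gene_b`` (an ``orthogroup`` column is carried through).
    """
    thr_a = threshold_a or ThresholdSpec(2.0, inclusive=True)
    thr_b = threshold_b or ThresholdSpec(2.0, inclusive=True)
    stages_a = [p[0] for p in correspondence.matched]
    stages_b = [p[1] for p in correspondence.matched]
    for s in stages_a:
        if s not in stage_means_a.columns:
            raise HeterochronyError(f"stage {s!r} not in species-A stage means")
    for s in stages_b:
        if s not in stage_means_b.columns:
            raise HeterochronyError(f"stage {s!r} not in species-B stage means")

    def _first_hit(mat: np.ndarray, cutoff: float, inclusive: bool) -> np.ndarray:
        hit = mat >= cutoff if inclusive else mat > cutoff
        any_hit = hit.any(axis=1)
        first = np.where(any_hit, hit.argmax(axis=1), -1)
        return first

    va = stage_means_a.loc[pairs["gene_a"], stages_a].to_numpy(dtype=float)
    vb = stage_means_b.loc[pairs["gene_b"], stages_b].to_numpy(dtype=float)
    ia = _first_hit(va, thr_a.cutoff, thr_a.inclusive)
    ib = _first_hit(vb, thr_b.cutoff, thr_b.inclusive)

    def _excluded_hit(stage_means, genes, thr, excluded):
        cols = [s for s in excluded if s in stage_means.columns]
        if not cols:
            return np.zeros(len(genes), dtype=bool)
        v = stage_means.loc[genes, cols].to_numpy(dtype=float)
        return (v >= thr.cutoff if thr.inclusive else v > thr.cutoff).any(axis=1)

    excl_a = _excluded_hit(stage_means_a, pairs["gene_a"], thr_a, correspondence.excluded_a)
    excl_b = _excluded_hit(stage_means_b, pairs["gene_b"], thr_b, correspondence.excluded_b)

    cls = np.full(len(pairs), "same", dtype=object)
    diff = ia - ib
    cls[diff >= min_offset] = "earlier_in_B"
    cls[-diff >= min_offset] = "earlier_in_A"
    missing = (ia < 0) | (ib < 0)
    unscored = missing & (((ia < 0) & excl_a) | ((ib < 0) & excl_b))
    inactive = missing & ~unscored
    cls[inactive] = "inactive"
    cls[unscored] = "unscored"

    out = pairs.copy()
    out["activation_a"] = [stages_a[i] if i >= 0 else None for i in ia]
    out["activation_b"] = [stages_b[i] if i >= 0 else None for i in ib]
    out["index_a"] = np.where(ia >= 0, ia, -1)
    out["index_b"] = np.where(ib >= 0, ib, -1)
    out["shift_class"] = cls
    tf_a = tf_genes_a or set()
    tf_b = tf_genes_b or set()
    out["is_tf"] = out["gene_a"].isin(tf_a) | out["gene_b"].isin(tf_b)
    return out


def shift_direction_summary(calls: pd.DataFrame) -> pd.DataFrame:
    """Counts per class plus percentages over the shifted pairs only."""
    counts = calls["shift_class"].value_counts().reindex(SHIFT_CLASSES, fill_value=0)
    shifted = int(counts["earlier_in_A"] + counts["earlier_in_B"])
    rows = []
    for cl in SHIFT_CLASSES:
        pct = (
            round(100.0 * counts[cl] / shifted, 2)
            if shifted > 0 and cl in ("earlier_in_A", "earlier_in_B")
            else float("nan")
        )
        rows.append({"shift_class": cl, "n": int(counts[cl]), "percent_of_shifted": pct})
    return pd.DataFrame(rows).set_index("shift_class")


def shift_cluster_allocation(
    calls: pd.DataFrame,
    categories_a: Mapping[str, str],
    categories_b: Mapping[str, str],
) -> pd.DataFrame:
    """Distribution of shifted pairs over cluster categories, per species."""
    shifted = calls[calls["shift_class"].isin(("earlier_in_A", "earlier_in_B"))]
    rows = []
    for species, gene_col, cats in (
        ("A", "gene_a", categories_a),
        ("B", "gene_b", categories_b),
    ):
        if shifted.empty:
            continue
        counts = (
            shifted[gene_col].map(lambda g: cats.get(g, "unassigned")).value_counts()
        )
        for cat, n in counts.items():
            rows.append(
                {
                    "species": species,
                    "category": cat,
                    "n": int(n),
                    "percent": round(100.0 * n / len(shifted), 2),
                }
            )
    return pd.DataFrame(rows, columns=["species", "category", "n", "percent"])


def tf_subset(calls: pd.DataFrame, tf_genes: set[str]) -> pd.DataFrame:
    """Calls restricted to pairs where either gene is an annotated TF."""
    mask = calls["gene_a"].isin(tf_genes) | calls["gene_b"].isin(tf_genes)
    return calls[mask]
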