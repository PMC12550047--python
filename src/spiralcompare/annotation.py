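"""Functional-annotation statistics: enrichment, phylostratigraphy, codon usage.

GO enrichment is the classic upper-tail Fisher exact test per term against
a declared gene universe (annotations are used as given — no DAG
propagation).  KEGG pathway enrichment uses the same 2x2 upper tail with
the conventional reporting filter p < 0.05 and BH q < 0.5, where q is
computed for reporting only and the p-filter stays unadjusted.
Phylostratigraphy summarises cluster composition by gene age and, after
per-stage quantile normalisation, locates each age class's stage of
highest expression.  Codon usage is counted per gene set from CDS FASTA
and compared between clusters as per-codon log2 frequency ratios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Data.CodonTable import standard_dna_table
from scipy.stats import hypergeom, rankdata

from .de import bh_adjust


class AnnotationError(ValueError):
    """Raised for invalid annotation inputs."""


# ---------------------------------------------------------------------------
# Annotation maps
# ---------------------------------------------------------------------------

@dataclass
class AnnotationMap:
    """Gene -> term sets over a declared universe."""

    gene_terms: dict[str, set[str]]
    universe: set[str]
    term_names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        outside = set(self.gene_terms) - self.universe
        if outside:
            raise AnnotationError(
                f"annotated genes outside the universe: {sorted(outside)[:5]}"
            )

    @property
    def term_genes(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for gene, terms in self.gene_terms.items():
            for t in terms:
                out.setdefault(t, set()).add(gene)
        return out

    @classmethod
    def from_table(cls, path, universe: Iterable[str] | None = None) -> "AnnotationMap":
        table = pd.read_csv(path, sep="\t", dtype=str)
        if not {"gene", "term"} <= set(table.columns):
            raise AnnotationError("annotation table needs 'gene' and 'term' columns")
        gene_terms: dict[str, set[str]] = {}
        for row in table.itertuples():
            gene_terms.setdefault(row.gene, set()).add(row.term)
        uni = set(universe) if universe is not None else set(gene_terms)
        return cls(gene_terms=gene_terms, universe=uni)

    @classmethod
    def from_gmt(cls, path, universe: Iterable[str] | None = None) -> "AnnotationMap":
        gene_terms: dict[str, set[str]] = {}
        names: dict[str, str] = {}
        for line in open(path):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            term, name, *genes = parts
            names[term] = name
            for g in genes:
                if g:
                    gene_terms.setdefault(g, set()).add(term)
        uni = set(universe) if universe is not None else set(gene_terms)
        return cls(gene_terms=gene_terms, universe=uni, term_names=names)


# ---------------------------------------------------------------------------
# Enrichment
# ---------------------------------------------------------------------------

def fisher_enrichment(
    study_genes: Iterable[str],
    annotation: AnnotationMap,
    min_term_size: int = 1,
    top_n: int | None = None,
) -> pd.DataFrame:
    """Upper-tail Fisher exact enrichment of every term in the study set.

    The 2x2 table per term is (study&term, study-term, term-study, rest);
    the upper tail P[X >= overlap] is the hypergeometric survival function,
    identical to Fisher's exact test with alternative='greater'.
    """
    study = set(study_genes)
    if not study:
        raise AnnotationError("empty study set")
    stray = study - annotation.universe
    if stray:
        raise AnnotationError(f"study genes outside the universe: {sorted(stray)[:5]}")
    n_uni = len(annotation.universe)
    n_study = len(study)
    rows = []
    for term, genes in sorted(annotation.term_genes.items()):
        genes = genes & annotation.universe
        if len(genes) < min_term_size:
            continue
        overlap = len(study & genes)
        p = float(hypergeom.sf(overlap - 1, n_uni, len(genes), n_study))
        expected = n_study * len(genes) / n_uni
        rows.append(
            {
                "term": term,
                "name": annotation.term_names.get(term, ""),
                "study_count": overlap,
                "term_size": len(genes),
                "expected": expected,
                "fold": overlap / expected if expected > 0 else np.nan,
                "p": min(p, 1.0),
            }
        )
    table = pd.DataFrame(rows).sort_values(["p", "term"]).reset_index(drop=True)
    if top_n is not None:
        table = table.head(top_n)
    return table


def kegg_enrichment(
    study_genes: Iterable[str],
    pathway_map: AnnotationMap,
    p_cutoff: float = 0.05,
    q_cutoff: float = 0.5,
) -> pd.DataFrame:
    """Hypergeometric pathway enrichment filtered at p < 0.05 and BH q < 0.5.

    The q-value is computed across pathways for reporting; the p filter is
    applied to the unadjusted p, by convention.
    """
    table = fisher_enrichment(study_genes, pathway_map)
    if table.empty:
        return table.assign(q=pd.Series(dtype=float))
    table["q"] = bh_adjust(table["p"].to_numpy())
    keep = (table["p"] < p_cutoff) & (table["q"] < q_cutoff) & (table["study_count"] > 0)
    return table[keep].reset_index(drop=True)


def annotation_coverage(
    assignments: Mapping[str, str], annotation: AnnotationMap
) -> pd.DataFrame:
    """Per-cluster counts and percentages of genes without any annotation."""
    ser = pd.Series(dict(assignments), name="cluster")
    annotated = {g for g, terms in annotation.gene_terms.items() if terms}
    rows = []
    for cluster, genes in ser.groupby(ser).groups.items():
        n = len(genes)
        n_unann = sum(1 for g in genes if g not in annotated)
        rows.append(
            {
                "cluster": cluster,
                "n_genes": n,
                "n_unannotated": n_unann,
                "percent_unannotated": round(100.0 * n_unann / n, 2) if n else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("cluster")


# ---------------------------------------------------------------------------
# Phylostratigraphy
# ---------------------------------------------------------------------------

@dataclass
class PhylostratumMap:
    """Ordered gene-age classes (oldest -> youngest) and a gene -> stratum map."""

    strata: tuple[str, ...]
    gene_stratum: dict[str, str]

    def __post_init__(self) -> None:
        unknown = set(self.gene_stratum.values()) - set(self.strata)
        if unknown:
            raise AnnotationError(f"unlisted strata in map: {sorted(unknown)}")

    @classmethod
    def from_table(cls, path, strata: Iterable[str] | None = None) -> "PhylostratumMap":
        table = pd.read_csv(path, sep="\t", dtype=str)
        if not {"gene", "phylostratum"} <= set(table.columns):
            raise AnnotationError("phylostratum table needs 'gene' and 'phylostratum' columns")
        mapping = dict(zip(table["gene"], table["phylostratum"]))
        order = tuple(strata) if strata is not None else tuple(dict.fromkeys(table["phylostratum"]))
        return cls(strata=order, gene_stratum=mapping)


UNASSIGNED_STRATUM = "unassigned"


def phylostratum_composition(
    assignments: Mapping[str, str], strata: PhylostratumMap
) -> pd.DataFrame:
    """Cluster x stratum proportions (rows sum to 1; unmapped genes -> 'unassigned')."""
    ser = pd.Series(dict(assignments), name="cluster")
    stratum = ser.index.map(lambda g: strata.gene_stratum.get(g, UNASSIGNED_STRATUM))
    table = pd.crosstab(ser, stratum)
    cols = [s for s in strata.strata if s in table.columns]
    if UNASSIGNED_STRATUM in table.columns:
        cols.append(UNASSIGNED_STRATUM)
    table = table[cols]
    return table.div(table.sum(axis=1), axis=0)


def quantile_normalize_columns(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalise columns to the mean-of-sorted-columns reference.

    Ties within a column receive the mean of their pooled reference values;
    the operation is idempotent and makes sorted columns identical.
    """
    x = matrix.to_numpy(dtype=float)
    ref = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        order = np.argsort(x[:, j], kind="mergesort")
        sorted_col = x[order, j]
        grp = np.concatenate([[0], np.cumsum(sorted_col[1:] != sorted_col[:-1])])
        avg = np.bincount(grp, weights=ref) / np.bincount(grp)
        out[order, j] = avg[grp]
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def stratum_stage_expression(
    tpm_stage_means: pd.DataFrame, strata: PhylostratumMap
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-stratum mean expression per stage after per-stage quantile normalisation.

    Returns the stratum x stage summary and each stratum's argmax stage
    (first stage on ties).
    """
    qn = quantile_normalize_columns(tpm_stage_means)
    stratum = qn.index.map(lambda g: strata.gene_stratum.get(g, UNASSIGNED_STRATUM))
    summary = qn.groupby(stratum).mean()
    order = [s for s in strata.strata if s in summary.index]
    if UNASSIGNED_STRATUM in summary.index:
        order.append(UNASSIGNED_STRATUM)
    summary = summary.loc[order]
    argmax = summary.idxmax(axis=1)
    argmax.name = "peak_stage"
    return summary, argmax


# ---------------------------------------------------------------------------
# Codon usage
# ---------------------------------------------------------------------------

ALL_CODONS = tuple(sorted(standard_dna_table.forward_table) + sorted(standard_dna_table.stop_codons))

_FAMILY_OF = {c: standard_dna_table.forward_table[c] for c in standard_dna_table.forward_table}
for _c in standard_dna_table.stop_codons:
    _FAMILY_OF[_c] = "*"


@dataclass
class CodonUsageTable:
    """Pooled codon counts and frequencies for one gene set / cluster."""

    counts: pd.Series                      # indexed by the 64 codons
    source: str = ""
    n_sequences: int = 0
    n_skipped_codons: int = 0

    @property
    def frequencies(self) -> pd.Series:
        total = self.counts.sum()
        return self.counts / total if total > 0 else self.counts.astype(float)

    @property
    def family_frequencies(self) -> pd.Series:
        """Relative frequency of each codon within its synonymous family."""
        fam = pd.Series({c: _FAMILY_OF[c] for c in self.counts.index})
        sums = self.counts.groupby(fam).transform("sum")
        with np.errstate(invalid="ignore"):
            return (self.counts / sums).fillna(0.0)


def read_cds(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def codon_usage(
    sequences: Mapping[str, str], gene_set: Iterable[str] | None = None, source: str = ""
) -> CodonUsageTable:
    """Pooled codon counts over a gene set.

    A trailing incomplete codon is trimmed with a warning; codons containing
    characters outside ACGT are skipped and tallied.
    """
    genes = list(gene_set) if gene_set is not None else list(sequences)
    counts = pd.Series(0, index=list(ALL_CODONS), dtype=int)
    skipped = 0
    n_seq = 0
    trimmed = False
    valid = set("ACGT")
    for gene in genes:
        seq = sequences.get(gene)
        if seq is None:
            continue
        n_seq += 1
        seq = seq.upper()
        if len(seq) % 3:
            trimmed = True
            seq = seq[: len(seq) - len(seq) % 3]
        for i in range(0, len(seq), 3):
            codon = seq[i : i + 3]
            if set(codon) <= valid:
                counts[codon] += 1
            else:
                skipped += 1
    if trimmed:
        warnings.warn("trimmed incomplete trailing codons from some sequences")
    return CodonUsageTable(counts=counts, source=source, n_sequences=n_seq,
                           n_skipped_codons=skipped)


def codon_log2_ratio(
    table_a: CodonUsageTable, table_b: CodonUsageTable, pseudocount: float = 1e-6
) -> pd.DataFrame:
    """Per-codon log2 ratio of global relative frequencies (A over B), sorted."""
    fa = table_a.frequencies
    fb = table_b.frequencies
    ratio = np.log2((fa + pseudocount) / (fb + pseudocount))
    out = pd.DataFrame(
        {"freq_a": fa, "freq_b": fb, "log2_ratio": ratio}
    ).sort_values("log2_ratio")
    out.index.name = "codon"
    return out
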