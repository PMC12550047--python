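"""Enrichment statistics, phylostratigraphy summaries, codon usage."""

import numpy as np
import pandas as pd
import pytest

from spiralcompare.annotation import (
    AnnotationError,
    AnnotationMap,
    PhylostratumMap,
    annotation_coverage,
    codon_log2_ratio,
    codon_usage,
    fisher_enrichment,
    kegg_enrichment,
    phylostratum_composition,
    quantile_normalize_columns,
    stratum_stage_expression,
)
from spiralcompare.expression import DEFAULT_STAGES, stage_means
from spiralcompare.simulate import (
    GO_SIGNATURES,
    PHYLOSTRATA,
    SimulationConfig,
    generate_cds,
    generate_dataset,
)


def _map(gene_terms, universe=None):
    return AnnotationMap(
        gene_terms={g: set(t) for g, t in gene_terms.items()},
        universe=set(universe) if universe else set(gene_terms),
    )


class TestFisher:
    def test_exact_enumeration_example(self):
        universe = [f"g{i}" for i in range(10)]
        amap = _map({g: {"T"} for g in universe[:5]}, universe=universe)
        study = universe[:4] + [universe[9]]
        table = fisher_enrichment(study, amap)
        assert table.loc[table.term == "T", "p"].iloc[0] == pytest.approx(26 / 252, abs=1e-12)

    def test_study_equals_universe_all_p_one(self):
        universe = [f"g{i}" for i in range(8)]
        amap = _map({g: {"T1"} for g in universe[:3]} | {universe[4]: {"T2"}},
                    universe=universe)
        table = fisher_enrichment(universe, amap)
        np.testing.assert_allclose(table["p"], 1.0)

    def test_empty_study_errors(self):
        with pytest.raises(AnnotationError):
            fisher_enrichment([], _map({"g": {"T"}}))

    def test_planted_signature_ranked_first(self):
        """The planted cluster GO signature tops the enrichment of its cluster."""
        hits = 0
        for seed in range(20):
            ds = generate_dataset(SimulationConfig(n_genes_per_species=600, seed=100 + seed))
            truth = ds.truth
            amap = AnnotationMap(
                gene_terms={g: set(t) for g, t in truth.go_a.items() if t},
                universe=set(truth.go_a),
            )
            study = [g for g, c in truth.cluster_a.items() if c == "embryonic"]
            table = fisher_enrichment(study, amap)
            hits += table.iloc[0]["term"] == GO_SIGNATURES["embryonic"][0]
        assert hits >= 18


class TestKegg:
    def test_no_study_gene_in_any_pathway(self):
        amap = _map({"g1": {"path1"}}, universe=["g1", "g2"])
        table = kegg_enrichment(["g2"], amap)
        assert table.empty

    def test_single_pathway_equal_to_study(self):
        universe = [f"g{i}" for i in range(10)]
        gene_terms = {g: {"hit"} for g in universe[:3]}
        gene_terms.update({g: {"bg"} for g in universe[3:]})
        amap = _map(gene_terms, universe=universe)
        table = kegg_enrichment(universe[:3], amap)
        assert table.iloc[0]["term"] == "hit"

    def test_matches_fisher_on_same_table(self):
        universe = [f"g{i}" for i in range(30)]
        amap = _map({g: {"P"} for g in universe[:12]}, universe=universe)
        study = universe[6:16]
        fisher = fisher_enrichment(study, amap)
        kegg = kegg_enrichment(study, amap, p_cutoff=1.1, q_cutoff=1.1)
        assert kegg.loc[kegg.term == "P", "p"].iloc[0] == pytest.approx(
            fisher.loc[fisher.term == "P", "p"].iloc[0]
        )


class TestCoverage:
    @pytest.mark.parametrize(
        "n_unann,size,expected",
        [(1040, 2310, 45.02), (1565, 3104, 50.42), (2161, 4841, 44.64)],
    )
    def test_unannotated_percentages(self, n_unann, size, expected):
        genes = [f"g{i}" for i in range(size)]
        assignments = {g: "c" for g in genes}
        amap = AnnotationMap(
            gene_terms={g: {"T"} for g in genes[n_unann:]}, universe=set(genes)
        )
        cov = annotation_coverage(assignments, amap)
        assert cov.loc["c", "n_unannotated"] == n_unann
        assert cov.loc["c", "percent_unannotated"] == expected

    def test_half_of_stage_specific_cluster_unannotated(self, medium_dataset):
        truth = medium_dataset.truth
        amap = AnnotationMap(
            gene_terms={g: set(t) for g, t in truth.go_b.items() if t},
            universe=set(truth.go_b),
        )
        cov = annotation_coverage(truth.cluster_b, amap)
        ss = [c for c in cov.index if str(c).startswith("stage_specific:")]
        assert ss
        pct = cov.loc[ss, "percent_unannotated"]
        assert ((pct > 40) & (pct < 60)).all()


class TestPhylostrata:
    def test_single_stratum_proportion_one(self):
        pmap = PhylostratumMap(("old",), {"g1": "old", "g2": "old"})
        comp = phylostratum_composition({"g1": "c", "g2": "c"}, pmap)
        assert comp.loc["c", "old"] == 1.0

    def test_proportions_sum_to_one(self, small_dataset):
        truth = small_dataset.truth
        pmap = PhylostratumMap(PHYLOSTRATA, truth.phylostratum_a)
        comp = phylostratum_composition(truth.cluster_a, pmap)
        np.testing.assert_allclose(comp.sum(axis=1), 1.0)

    def test_young_genes_dominate_stage_specific_clusters(self, medium_dataset):
        truth = medium_dataset.truth
        pmap = PhylostratumMap(PHYLOSTRATA, truth.phylostratum_b)
        comp = phylostratum_composition(truth.cluster_b, pmap)
        ss = [c for c in comp.index if str(c).startswith("stage_specific:")]
        assert (comp.loc[ss, "species_specific"] > 0.5).all()

    def test_unmapped_genes_get_explicit_stratum(self):
        pmap = PhylostratumMap(("old",), {"g1": "old"})
        comp = phylostratum_composition({"g1": "c", "g2": "c"}, pmap)
        assert comp.loc["c", "unassigned"] == 0.5


class TestQuantileNormalization:
    def test_sorted_columns_identical_without_ties(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.random((50, 4)))
        qn = quantile_normalize_columns(m)
        ref = np.sort(qn.to_numpy(), axis=0)
        for j in range(1, 4):
            np.testing.assert_allclose(ref[:, j], ref[:, 0])

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        m = pd.DataFrame(rng.lognormal(size=(40, 5)))
        once = quantile_normalize_columns(m)
        twice = quantile_normalize_columns(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_uniform_matrix_flat_with_first_stage_argmax(self):
        sm = pd.DataFrame(np.ones((10, 3)), columns=["s0", "s1", "s2"])
        pmap = PhylostratumMap(("old",), {i: "old" for i in sm.index})
        summary, argmax = stratum_stage_expression(sm, pmap)
        assert summary.loc["old"].nunique() == 1
        assert argmax["old"] == "s0"

    def test_old_strata_peak_at_gastrula(self, medium_dataset):
        ds = medium_dataset
        pmap = PhylostratumMap(PHYLOSTRATA, ds.truth.phylostratum_a)
        summary, argmax = stratum_stage_expression(stage_means(ds.tpm_a), pmap)
        assert argmax["Metazoa"] == "gastrula"
        assert argmax["Bilateria"] == "gastrula"


class TestCodonUsage:
    def test_simple_counting(self):
        table = codon_usage({"g": "ATGATG"})
        assert table.counts["ATG"] == 2
        assert table.counts.drop("ATG").sum() == 0

    def test_empty_set_zero_table(self):
        table = codon_usage({"g": "ATGATG"}, gene_set=[])
        assert table.counts.sum() == 0

    def test_matches_sliding_window_oracle(self, small_dataset):
        rng = np.random.default_rng(0)
        seqs = generate_cds(small_dataset.truth, "a", rng)
        subset = dict(list(seqs.items())[:20])
        table = codon_usage(subset)
        oracle: dict[str, int] = {}
        for seq in subset.values():
            for i in range(0, len(seq) - 2, 3):
                oracle[seq[i : i + 3]] = oracle.get(seq[i : i + 3], 0) + 1
        for codon, n in oracle.items():
            assert table.counts[codon] == n

    def test_ambiguous_codons_skipped_and_tallied(self):
        with pytest.warns(UserWarning, match="trimmed"):
            table = codon_usage({"g": "ATGNNNGGGAA"})
        assert table.n_skipped_codons == 1
        assert table.counts["ATG"] == 1 and table.counts["GGG"] == 1

    def test_family_frequencies_sum_to_one(self):
        table = codon_usage({"g": "ATGGGAGGGGGAAAATTT"})
        fam = table.family_frequencies
        gly = [c for c in ("GGA", "GGC", "GGG", "GGT")]
        assert fam[gly].sum() == pytest.approx(1.0)


class TestCodonRatio:
    def test_identical_tables_all_zero(self):
        t = codon_usage({"g": "ATGCCGATG"})
        ratio = codon_log2_ratio(t, t)
        np.testing.assert_allclose(ratio["log2_ratio"], 0.0, atol=1e-9)

    def test_double_frequency_gives_plus_one(self):
        a = codon_usage({"g": "AAAAAACCC"})   # AAA x2, CCC x1
        b = codon_usage({"g": "AAACCCGGG"})   # each x1
        ratio = codon_log2_ratio(a, b, pseudocount=0.0)
        assert ratio.loc["AAA", "log2_ratio"] == pytest.approx(1.0)

    def test_biased_cluster_codons_stand_out(self, medium_dataset):
        """Oocyte-cluster preferred codons dominate the log2 ratio extremes."""
        truth = medium_dataset.truth
        rng = np.random.default_rng(3)
        seqs = generate_cds(truth, "a", rng)
        biased = [g for g, f in truth.codon_bias_a.items() if f]
        zygotic = [g for g, c in truth.cluster_a.items() if c == "embryonic"]
        ratio = codon_log2_ratio(
            codon_usage(seqs, biased[:150]), codon_usage(seqs, zygotic[:150])
        )
        from spiralcompare.simulate import PREFERRED_CODONS, _FAMILIES

        # within every synonymous family, the designated preferred codon is
        # the most enriched in the biased cluster
        for aa, fam in _FAMILIES.items():
            if len(fam) < 2:
                continue
            fam_ratios = ratio.loc[fam, "log2_ratio"]
            assert fam_ratios.idxmax() == PREFERRED_CODONS[aa]
        big_pref = [c for aa, c in PREFERRED_CODONS.items() if len(_FAMILIES[aa]) >= 4]
        assert ratio.loc[big_pref, "log2_ratio"].mean() > 1.0
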