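"""Phase partitioning, RT-expression integration, phase-ratio clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

import replitime as rt
from replitime.cycle import (
    PHASES,
    load_dna_replication_genes,
    partition_percentages,
)


def de_row(gene, phase, log2fc, fdr):
    return {"gene": gene, "phase": phase, "log2fc": log2fc, "fdr": fdr}


class TestPhasePartition:
    def test_es_only_counts_as_unique_s(self):
        de = pd.DataFrame([de_row("g1", "ES", 2.0, 0.01)]
                          + [de_row("g1", p, 0.1, 0.9) for p in ("G1", "LS", "G2M")])
        counts = rt.phase_partition(de)
        assert counts["unique_S"] == 1
        assert sum(counts.values()) == 1

    def test_all_pooled_phases_is_shared_all(self):
        de = pd.DataFrame([de_row("g1", p, 2.0, 0.01) for p in ("G1", "ES", "G2M")])
        counts = rt.phase_partition(de)
        assert counts["shared_all"] == 1

    def test_hand_counted_partition(self):
        rows = []
        # 3 genes unique to G1; 2 unique to S (one via ES, one via LS);
        # 1 unique to G2; 2 shared between two pooled phases; 2 shared all
        for g in ("a", "b", "c"):
            rows.append(de_row(g, "G1", 1.5, 0.01))
        rows.append(de_row("d", "ES", -2.0, 0.001))
        rows.append(de_row("e", "LS", 3.0, 0.04))
        rows.append(de_row("f", "G2M", 1.2, 0.02))
        for g in ("g", "h"):
            rows += [de_row(g, "G1", 2.0, 0.01), de_row(g, "LS", 2.0, 0.01)]
        for g in ("i", "j"):
            rows += [
                de_row(g, "G1", 2.0, 0.01),
                de_row(g, "ES", 2.0, 0.01),
                de_row(g, "G2M", 2.0, 0.01),
            ]
        counts = rt.phase_partition(pd.DataFrame(rows))
        assert counts == {
            "unique_G1": 3,
            "unique_S": 2,
            "unique_G2": 1,
            "shared_2_3": 2,
            "shared_all": 2,
        }
        assert sum(partition_percentages(counts).values()) == pytest.approx(100.0)

    def test_de_filter_is_twofold_and_fdr(self):
        de = pd.DataFrame(
            [
                de_row("weak_fc", "G1", 0.9, 0.001),   # below twofold
                de_row("weak_fdr", "G1", 3.0, 0.10),   # FDR too high
                de_row("ok", "G1", -1.1, 0.04),
            ]
        )
        counts = rt.phase_partition(de)
        assert sum(counts.values()) == 1

    def test_empty_warns(self):
        de = pd.DataFrame([de_row("g", "G1", 0.1, 0.9)])
        with pytest.warns(UserWarning):
            counts = rt.phase_partition(de)
        assert sum(counts.values()) == 0


def _diff_result(n=40, later_bins=(), earlier_bins=()):
    g = rt.BinGrid.from_chrom_sizes({"chr1": n * 50_000})
    a = np.full(n, 0.5)
    a[list(later_bins)] = 0.9
    a[list(earlier_bins)] = 0.1
    b = np.full(n, 0.5)
    return rt.call_differential(
        rt.RTProfile(g, a), rt.RTProfile(g, b), sigma=0.05
    )


class TestRTExpressionMatrix:
    def test_single_gene_region_value(self):
        diff = _diff_result(later_bins=[3])
        genes = pd.DataFrame(
            [{"chrom": "chr1", "start": 155_000, "end": 160_000, "gene": "g1"}]
        )
        de = pd.DataFrame([de_row("g1", p, 2.0 if p == "ES" else 0.0, 0.01) for p in PHASES])
        mat = rt.rt_expression_matrix(diff, de, genes)
        assert len(mat) == 1
        assert mat.loc[0, "ES"] == pytest.approx(2.0)
        assert mat.loc[0, "G1"] == pytest.approx(0.0)

    def test_region_without_tested_gene_excluded(self):
        diff = _diff_result(later_bins=[3, 10])
        genes = pd.DataFrame(
            [{"chrom": "chr1", "start": 155_000, "end": 160_000, "gene": "g1"}]
        )
        de = pd.DataFrame([de_row("g1", p, 1.0, 0.01) for p in PHASES])
        mat = rt.rt_expression_matrix(diff, de, genes)
        assert len(mat) == 1  # bin 10 has no gene

    def test_no_genes_raises(self):
        diff = _diff_result(later_bins=[3])
        with pytest.raises(ValueError, match="gene"):
            rt.rt_expression_matrix(diff, pd.DataFrame(), pd.DataFrame())

    def test_sign_concordant_simulation_gives_negative_correlation(self):
        # later-replicating regions seeded with downregulation must yield a
        # negative association between delta-RTI and mean logFC
        rng = np.random.default_rng(10)
        n = 60
        later = list(range(5, 20))
        earlier = list(range(30, 45))
        diff = _diff_result(n=n, later_bins=later, earlier_bins=earlier)
        cfg = rt.ExprSimConfig(n_genes=n, seed=3)
        sim = rt.simulate_phase_expression(cfg, grid=diff.grid, diff_call=diff.call)
        mat = rt.rt_expression_matrix(diff, sim["de"], sim["genes"])
        mean_fc = mat[list(PHASES)].mean(axis=1)
        rho = spearmanr(mat["delta"], mean_fc).statistic
        assert rho < -0.5
        assert mean_fc[mat["call"] == "later"].mean() < 0


class TestPhaseRatioMatrix:
    def _expr(self, levels_by_gene, lines=(("L1", "sub1"),)):
        rows = []
        for gene, levels in levels_by_gene.items():
            for line, sub in lines:
                for phase, v in zip(PHASES, levels):
                    rows.append(
                        {"gene": gene, "cell_line": line, "subgroup": sub,
                         "phase": phase, "fpkm": v}
                    )
        return pd.DataFrame(rows)

    def test_constant_expression_zero_ratios(self):
        mat, dropped = rt.phase_ratio_matrix(self._expr({"g": (5, 5, 5, 5)}))
        np.testing.assert_allclose(mat.to_numpy(), 0.0)
        assert dropped == []

    def test_doubling_each_phase(self):
        # doubling G1->ES->LS->G2M gives +1, +1, +1 then -3 on the return
        mat, _ = rt.phase_ratio_matrix(self._expr({"g": (10, 21, 43, 87)}), pseudocount=1.0)
        row = mat.iloc[0]
        assert row["sub1:G1->ES"] == pytest.approx(1.0)
        assert row["sub1:ES->LS"] == pytest.approx(1.0)
        assert row["sub1:LS->G2M"] == pytest.approx(1.0)
        assert row["sub1:G2M->G1"] == pytest.approx(-3.0)

    def test_circularity(self):
        rng = np.random.default_rng(11)
        levels = {f"g{i}": tuple(rng.uniform(0, 50, 4)) for i in range(10)}
        mat, _ = rt.phase_ratio_matrix(self._expr(levels))
        # the four transition ratios of each gene close the cycle exactly
        per_gene = mat[[c for c in mat.columns if c.startswith("sub1:")]].sum(axis=1)
        np.testing.assert_allclose(per_gene.to_numpy(), 0.0, atol=1e-12)

    def test_silent_gene_dropped(self):
        levels = {f"g{i}": (10, 12, 14, 16) for i in range(38)}
        levels["silent"] = (0, 0, 0, 0)
        gene_list = list(levels)
        assert len(gene_list) == 39
        mat, dropped = rt.phase_ratio_matrix(self._expr(levels), gene_list=gene_list)
        assert len(mat) == 38
        assert "silent" in dropped

    def test_absent_gene_reported_not_fatal(self):
        mat, dropped = rt.phase_ratio_matrix(
            self._expr({"g": (5, 5, 5, 5)}), gene_list=["g", "ghost"]
        )
        assert "ghost" in dropped
        assert len(mat) == 1

    def test_bundled_panel_has_39_genes(self):
        genes = load_dna_replication_genes()
        assert len(genes) == 39
        assert "PIF1" in genes


class TestClusterRatioGenes:
    def _two_archetype_matrix(self, n_per=10, noise=0.05, seed=12):
        rng = np.random.default_rng(seed)
        a = np.array([0.0, 2.0, 0.0, -2.0])   # up at ES->LS
        b = np.array([0.0, 0.0, -2.0, 2.0])   # up at G2->G1
        rows, names = [], []
        for i in range(n_per):
            rows.append(a + rng.normal(0, noise, 4))
            names.append(f"a{i}")
        for i in range(n_per):
            rows.append(b + rng.normal(0, noise, 4))
            names.append(f"b{i}")
        cols = [f"sub1:{p}->{q}" for p, q in
                (("G1", "ES"), ("ES", "LS"), ("LS", "G2M"), ("G2M", "G1"))]
        return pd.DataFrame(rows, index=names, columns=cols)

    def test_two_archetypes_recovered(self):
        mat = self._two_archetype_matrix()
        labels = rt.cluster_ratio_genes(mat, k=2)
        first = {labels[f"a{i}"] for i in range(10)}
        second = {labels[f"b{i}"] for i in range(10)}
        assert len(first) == 1 and len(second) == 1 and first != second

    def test_k_equals_n_gives_singletons(self):
        mat = self._two_archetype_matrix(n_per=3)
        labels = rt.cluster_ratio_genes(mat, k=6)
        assert labels.nunique() == 6

    def test_k_too_large_raises(self):
        mat = self._two_archetype_matrix(n_per=2)
        with pytest.raises(ValueError):
            rt.cluster_ratio_genes(mat, k=10)

    def test_duplicated_rows_co_cluster(self):
        mat = self._two_archetype_matrix()
        mat.loc["dup_of_a0"] = mat.loc["a0"]
        labels = rt.cluster_ratio_genes(mat, k=2)
        assert labels["dup_of_a0"] == labels["a0"]

    def test_permutation_stable(self):
        mat = self._two_archetype_matrix()
        labels = rt.cluster_ratio_genes(mat, k=2)
        shuffled = mat.sample(frac=1.0, random_state=4)
        labels2 = rt.cluster_ratio_genes(shuffled, k=2)
        assert (labels2.loc[labels.index] == labels).all()


class TestClusterPhaseProfiles:
    def _expr(self):
        rows = []
        for gene, levels in {"g1": (10, 20, 30, 40), "g2": (30, 40, 50, 60)}.items():
            for line in ("L1", "L2"):
                for phase, v in zip(PHASES, levels):
                    rows.append({"gene": gene, "cell_line": line, "subgroup": "sub1",
                                 "phase": phase, "fpkm": v})
        return pd.DataFrame(rows)

    def test_two_gene_mean(self):
        labels = pd.Series({"g1": 1, "g2": 1}, name="cluster")
        prof = rt.cluster_phase_profiles(self._expr(), labels)
        assert prof.loc[(1, "sub1"), "G1"] == pytest.approx(20.0)
        assert prof.loc[(1, "sub1"), "G2M"] == pytest.approx(50.0)

    def test_single_gene_cluster(self):
        labels = pd.Series({"g1": 1, "g2": 2}, name="cluster")
        prof = rt.cluster_phase_profiles(self._expr(), labels)
        assert prof.loc[(1, "sub1"), "ES"] == pytest.approx(20.0)

    def test_empty_cluster_warns(self):
        labels = pd.Series({"g1": 1, "g2": 1, "ghost": 3}, name="cluster")
        with pytest.warns(UserWarning, match="3"):
            rt.cluster_phase_profiles(self._expr(), labels)

    def test_subgroup_timing_shift_reproduced(self):
        # a cluster built to rise between G1 and ES in tumor lines but
        # between ES and LS in astrocytes shows the earlier upregulation
        rows = []
        profiles = {
            ("astro", "A1"): (10, 10, 40, 40),
            ("tumor", "T1"): (10, 40, 40, 40),
        }
        for (sub, line), levels in profiles.items():
            for phase, v in zip(PHASES, levels):
                rows.append({"gene": "g", "cell_line": line, "subgroup": sub,
                             "phase": phase, "fpkm": v})
        labels = pd.Series({"g": 1}, name="cluster")
        prof = rt.cluster_phase_profiles(pd.DataFrame(rows), labels)
        astro, tumor = prof.loc[(1, "astro")], prof.loc[(1, "tumor")]
        assert tumor["ES"] > tumor["G1"]          # early rise in tumor
        assert astro["ES"] == astro["G1"]         # astrocytes rise later
        assert astro["LS"] > astro["ES"]
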