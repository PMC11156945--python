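"""Transcriptome processing, co-expression clustering, gene-trait networks."""

import numpy as np
import pandas as pd
import pytest

from olfatau.exceptions import ParameterError, SchemaError
from olfatau.gene_coexpr import (
    cluster_genes,
    cluster_maps,
    coexpression,
    gene_trait_network,
    map_samples_to_regions,
    zscore_rows,
)
from olfatau.synthetic_data import ExpressionMatrix, ExpressionTruth, generate_expression


def _samples(donors, regions, genes, values):
    rows = []
    for d in donors:
        for r in regions:
            rows.append({"donor": d, "region": r, **{g: values[(d, r, g)] for g in genes}})
    return pd.DataFrame(rows)


class TestMapSamplesToRegions:
    def test_single_donor_single_sample_is_zscored_input(self):
        regions = ["lh_a", "lh_b", "rh_a", "rh_b"]
        vals = {("d1", r, "g1"): v for r, v in zip(regions, [1.0, 2.0, 3.0, 4.0])}
        expr = map_samples_to_regions(_samples(["d1"], regions, ["g1"], vals), ["g1"])
        expected = (np.array([1, 2, 3, 4]) - 2.5) / np.std([1, 2, 3, 4])
        np.testing.assert_allclose(expr.values.loc["g1", regions], expected)

    def test_duplicate_samples_leave_mean_unchanged(self):
        regions = ["lh_a", "lh_b", "rh_a", "rh_b"]
        vals = {("d1", r, "g1"): v for r, v in zip(regions, [1.0, 2.0, 3.0, 4.0])}
        s1 = _samples(["d1"], regions, ["g1"], vals)
        s2 = pd.concat([s1, s1.iloc[[0]]], ignore_index=True)
        e1 = map_samples_to_regions(s1, ["g1"])
        e2 = map_samples_to_regions(s2, ["g1"])
        pd.testing.assert_frame_equal(e1.values, e2.values)

    def test_cross_donor_median(self):
        regions = ["lh_a", "lh_b", "rh_a"]
        vals = {}
        for r, base in zip(regions, [1.0, 5.0, 9.0]):
            vals[("x1", r, "g1")] = base
            vals[("x2", r, "g1")] = base
            vals[("y", r, "g1")] = base + 100
        expr = map_samples_to_regions(_samples(["x1", "x2", "y"], regions, ["g1"], vals), ["g1"])
        # median of {x, x, y} is x; after z-scoring the profile matches x's
        expected = zscore_rows(pd.DataFrame([[1.0, 5.0, 9.0]], index=["g1"], columns=regions))
        np.testing.assert_allclose(expr.values.to_numpy(), expected.to_numpy())

    def test_missing_donor_column_rejected(self):
        with pytest.raises(SchemaError):
            map_samples_to_regions(pd.DataFrame({"region": ["a"], "g1": [1.0]}), ["g1"])


class TestCoexpression:
    def test_duplicated_gene_fully_correlated(self, rng):
        vals = rng.standard_normal((1, 20))
        frame = pd.DataFrame(np.vstack([vals, vals]), index=["g1", "g2"])
        expr = ExpressionMatrix(values=frame, region_meta=pd.DataFrame())
        assert coexpression(expr).loc["g1", "g2"] == pytest.approx(1.0)

    def test_negated_gene_anticorrelated(self, rng):
        vals = rng.standard_normal((1, 20))
        frame = pd.DataFrame(np.vstack([vals, -vals]), index=["g1", "g2"])
        expr = ExpressionMatrix(values=frame, region_meta=pd.DataFrame())
        assert coexpression(expr).loc["g1", "g2"] == pytest.approx(-1.0)

    def test_planted_blocks_have_higher_within_correlation(self):
        truth = ExpressionTruth(n_genes=80, k_clusters=4, within_cluster_corr=0.7, seed=2)
        expr = generate_expression(truth)
        c = coexpression(expr).to_numpy()
        labels = expr.truth_labels
        same = labels[:, None] == labels[None, :]
        off = ~np.eye(80, dtype=bool)
        assert c[same & off].mean() > c[~same].mean() + 0.3


class TestClusterGenes:
    def test_two_anticorrelated_blocks(self, rng):
        f = rng.standard_normal(30)
        genes = np.vstack([f + 0.05 * rng.standard_normal((10, 30)), -f + 0.05 * rng.standard_normal((10, 30))])
        frame = pd.DataFrame(genes, index=[f"g{i}" for i in range(20)])
        expr = ExpressionMatrix(values=frame, region_meta=pd.DataFrame())
        clusters = cluster_genes(coexpression(expr), k_range=range(2, 6))
        assert clusters.k == 2
        assert clusters.silhouette_by_k[2] > 0.9
        lab = clusters.labels.to_numpy()
        assert len(set(lab[:10])) == 1 and len(set(lab[10:])) == 1 and lab[0] != lab[-1]

    def test_gene_order_permutation_invariance(self):
        truth = ExpressionTruth(n_genes=60, k_clusters=3, within_cluster_corr=0.8, seed=4)
        expr = generate_expression(truth)
        c = coexpression(expr)
        perm = np.random.default_rng(0).permutation(60)
        c_perm = c.iloc[perm, perm]
        l1 = cluster_genes(c, k_range=range(2, 6)).labels
        l2 = cluster_genes(c_perm, k_range=range(2, 6)).labels
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(l1[c_perm.index], l2) == pytest.approx(1.0)

    def test_invalid_k_range_rejected(self):
        truth = ExpressionTruth(n_genes=20, k_clusters=2, within_cluster_corr=0.8, seed=0)
        c = coexpression(generate_expression(truth))
        with pytest.raises(ParameterError):
            cluster_genes(c, k_range=range(2, 25))


class TestClusterMaps:
    def test_per_hemisphere_zero_mean_unit_sd(self):
        truth = ExpressionTruth(n_genes=40, k_clusters=2, within_cluster_corr=0.8, seed=1)
        expr = generate_expression(truth)
        clusters = cluster_genes(coexpression(expr), k_range=range(2, 5))
        maps = cluster_maps(expr, clusters)
        hemi = expr.region_meta.set_index("region")["hemisphere"]
        for h in ("L", "R"):
            cols = [r for r in maps.columns if hemi[r] == h]
            np.testing.assert_allclose(maps[cols].mean(axis=1), 0, atol=1e-10)
            np.testing.assert_allclose(maps[cols].std(axis=1, ddof=0), 1, atol=1e-10)

    def test_hemisphere_shift_visible_before_rezscoring(self):
        truth = ExpressionTruth(
            n_genes=40, k_clusters=2, within_cluster_corr=0.8, hemisphere_shift={0: 2.0}, seed=1
        )
        expr = generate_expression(truth)
        meta = expr.region_meta.set_index("region")["hemisphere"]
        rows = expr.values.loc[expr.truth_labels == 0]
        right = [r for r in rows.columns if meta[r] == "R"]
        left = [r for r in rows.columns if meta[r] == "L"]
        assert rows[right].mean().mean() > rows[left].mean().mean() + 1.0

    def test_single_gene_cluster_map_is_that_row(self):
        truth = ExpressionTruth(n_genes=5, k_clusters=5, within_cluster_corr=0.5, seed=2)
        expr = generate_expression(truth)
        labels = pd.Series(range(5), index=expr.values.index, name="cluster")
        from olfatau.gene_coexpr import CoexprClusters

        clusters = CoexprClusters(labels=labels, k=5, silhouette_by_k={}, linkage="average")
        maps = cluster_maps(expr, clusters)
        hemi = expr.region_meta.set_index("region")["hemisphere"]
        row = expr.values.iloc[0].copy()
        for h in ("L", "R"):
            cols = [r for r in row.index if hemi[r] == h]
            row[cols] = (row[cols] - row[cols].mean()) / row[cols].std(ddof=0)
        np.testing.assert_allclose(maps.iloc[0], row, atol=1e-10)


class TestGeneTraitNetwork:
    DOMAINS = {"tau burden": "tau", "amyloid load": "amyloid"}

    def test_minimum_p_is_edge_weight(self):
        t = pd.DataFrame(
            {
                "gene": ["G1", "G1"],
                "trait": ["tau burden", "tau burden"],
                "p": [1e-8, 1e-6],
            }
        )
        net = gene_trait_network(t, self.DOMAINS)
        assert net.gene_trait["weight"].iloc[0] == 1e-8
        assert net.gene_domain.query("gene == 'G1' and domain == 'tau'")["weight"].iloc[0] == 1e-8

    def test_empty_table_empty_network(self):
        t = pd.DataFrame(columns=["gene", "trait", "p"])
        net = gene_trait_network(t, self.DOMAINS)
        assert net.gene_trait.empty and net.gene_domain.empty

    def test_catalog_bound_rejects_weak_associations(self):
        t = pd.DataFrame({"gene": ["G1", "G2"], "trait": ["tau burden"] * 2, "p": [1e-8, 1e-4]})
        net = gene_trait_network(t, self.DOMAINS)
        assert net.n_rejected == 1
        assert list(net.gene_trait["gene"]) == ["G1"]

    def test_hand_built_network_matches_manual_construction(self):
        t = pd.DataFrame(
            {
                "gene": ["G1", "G1", "G2", "G3", "G4", "G5"],
                "trait": [
                    "tau burden",
                    "amyloid load",
                    "tau burden",
                    "unrelated trait",
                    "amyloid load",
                    "tau burden",
                ],
                "p": [1e-9, 1e-7, 1e-6, 1e-10, 1e-8, 2e-6],
            }
        )
        net = gene_trait_network(t, self.DOMAINS)
        # G3's trait is outside the six domains -> dropped
        assert set(net.gene_domain["gene"]) == {"G1", "G2", "G4", "G5"}
        manual = {("G1", "tau"): 1e-9, ("G1", "amyloid"): 1e-7, ("G2", "tau"): 1e-6,
                  ("G4", "amyloid"): 1e-8, ("G5", "tau"): 2e-6}
        got = {(r.gene, r.domain): r.weight for r in net.gene_domain.itertuples()}
        assert got == manual


def test_zscore_idempotent_on_zscored_input(rng):
    frame = pd.DataFrame(rng.standard_normal((5, 30)))
    once = zscore_rows(frame)
    twice = zscore_rows(once)
    np.testing.assert_allclose(once.to_numpy(), twice.to_numpy(), atol=1e-12)
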