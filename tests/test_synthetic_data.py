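import json

import numpy as np
import pytest

from gapkit import (
    GridLayer,
    WorldConfig,
    fps_classify,
    grs,
    hcpc_clusters,
    make_ecoregions,
    make_env_layers,
    make_taxon,
    make_tree_and_traits,
    make_world,
    partition_counts,
    pca,
    srs,
    write_world,
)
from gapkit.eco_phylo import extract_env, phylo_covariance, read_newick
from gapkit.geodata import circular_buffer_range, read_ascii_grid
from gapkit.occurrences import coords_of, load_occurrences


def lag1_autocorr(values):
    a, b = values[:, :-1].ravel(), values[:, 1:].ravel()
    return np.corrcoef(a, b)[0, 1]


@pytest.fixture
def template():
    return GridLayer(np.zeros((40, 40)), -110.0, 45.0, 0.25)


class TestEnvLayers:
    def test_unit_correlation_length_is_white(self, template):
        rs = [
            lag1_autocorr(
                make_env_layers(1, template, 1, seed)["env_01"].values
            )
            for seed in range(20)
        ]
        assert abs(np.mean(rs)) < 0.1

    def test_large_correlation_length_is_smooth(self, template):
        rs = [
            lag1_autocorr(
                make_env_layers(1, template, 9, seed)["env_01"].values
            )
            for seed in range(20)
        ]
        assert np.mean(rs) > 0.5

    def test_standardized_per_layer(self, template):
        layers = make_env_layers(3, template, 5, 0)
        for layer in layers.values():
            assert layer.values.mean() == pytest.approx(0.0, abs=1e-10)
            assert layer.values.std() == pytest.approx(1.0, abs=1e-10)

    def test_collinearity_induces_correlation(self, template):
        free = make_env_layers(6, template, 5, 0, collinearity=0.0)
        tied = make_env_layers(6, template, 5, 0, collinearity=0.8, n_latent=1)
        def mean_abs_corr(layers):
            mats = [l.values.ravel() for l in layers.values()]
            cc = np.corrcoef(mats)
            return np.abs(cc[np.triu_indices_from(cc, 1)]).mean()
        assert mean_abs_corr(tied) > mean_abs_corr(free) + 0.3

    def test_deterministic_by_seed(self, template):
        a = make_env_layers(2, template, 5, 42)
        b = make_env_layers(2, template, 5, 42)
        for k in a:
            np.testing.assert_array_equal(a[k].values, b[k].values)

    def test_sub_cell_correlation_length_rejected(self, template):
        with pytest.raises(ValueError):
            make_env_layers(1, template, 0, 0)


class TestEcoregions:
    def test_single_class_constant_map(self, template):
        eco = make_ecoregions(template, 1, 0)
        assert set(np.unique(eco.values)) == {1.0}

    def test_all_classes_present(self, template):
        eco = make_ecoregions(template, 4, 3)
        assert set(np.unique(eco.values)) == {1.0, 2.0, 3.0, 4.0}

    def test_deterministic_by_seed(self, template):
        np.testing.assert_array_equal(
            make_ecoregions(template, 5, 9).values, make_ecoregions(template, 5, 9).values
        )

    def test_too_many_classes_rejected(self, template):
        with pytest.raises(ValueError):
            make_ecoregions(template, 40 * 40 + 1, 0)


class TestMakeTaxon:
    @pytest.fixture
    def env(self, template):
        return make_env_layers(2, template, 7, 1)

    def test_huge_breadth_is_nearly_uniform(self, env):
        truth, _ = make_taxon(
            "t", env, {"env_01": 0.0}, {"env_01": 1e6}, 10, 0.5, seed=0
        )
        vals = truth.true_suitability.values
        assert vals.min() > 0.999

    def test_narrow_niche_concentrates_occurrences(self, env):
        truth, recs = make_taxon(
            "t", env, {"env_01": 0.5}, {"env_01": 0.2}, 200, 0.5, seed=1
        )
        pts = [(r.lon, r.lat) for r in recs if r.has_coords]
        mat, _ = extract_env(pts, env)
        # sample mean of the occupied environment within 0.5 niche SD of center
        assert abs(mat["env_01"].mean() - 0.5) < 0.5 * 1.0

    def test_zero_germplasm_fraction_zeroes_srs(self, env):
        _, recs = make_taxon("t", env, {"env_01": 0.0}, {"env_01": 1.0}, 30, 0.0, seed=2)
        n_g, n_h, _, _ = partition_counts(recs, "t")
        assert srs(n_g, n_h) == 0.0

    def test_deterministic_by_seed(self, env):
        _, a = make_taxon("t", env, {"env_01": 0.0}, {"env_01": 1.0}, 20, 0.4, seed=7)
        _, b = make_taxon("t", env, {"env_01": 0.0}, {"env_01": 1.0}, 20, 0.4, seed=7)
        assert [(r.lon, r.lat, r.record_type) for r in a] == [
            (r.lon, r.lat, r.record_type) for r in b
        ]


class TestTreeAndTraits:
    def test_bm_tip_variance_matches_rate_times_depth(self):
        tree, traits = make_tree_and_traits(12, seed=6, n_traits=500, rate=2.0)
        depth = phylo_covariance(tree).to_numpy().diagonal().mean()
        tip_vars = traits.var(axis=1, ddof=1)
        assert tip_vars.mean() == pytest.approx(2.0 * depth, rel=0.10)

    def test_newick_roundtrip_lossless(self):
        tree, _ = make_tree_and_traits(10, seed=3)
        newick = tree.as_string(schema="newick", unquoted_underscores=True)
        back = read_newick(newick)
        assert sorted(l.taxon.label for l in back.leaf_node_iter()) == sorted(
            l.taxon.label for l in tree.leaf_node_iter()
        )
        np.testing.assert_allclose(
            phylo_covariance(back).to_numpy(), phylo_covariance(tree).to_numpy(), atol=1e-9
        )

    def test_same_seed_same_newick(self):
        a, _ = make_tree_and_traits(8, seed=4)
        b, _ = make_tree_and_traits(8, seed=4)
        assert a.as_string(schema="newick") == b.as_string(schema="newick")

    def test_ultrametric_within_tolerance(self):
        tree, _ = make_tree_and_traits(15, seed=2)
        depths = phylo_covariance(tree).to_numpy().diagonal()
        assert depths.max() - depths.min() < 1e-6


class TestWorld:
    def test_two_taxa_same_niche_same_seed_overlap_perfectly(self, template):
        env = make_env_layers(2, template, 7, 5)
        t1, _ = make_taxon("a", env, {"env_01": 0.0}, {"env_01": 1.0}, 20, 0.5, seed=9)
        t2, _ = make_taxon("b", env, {"env_01": 0.0}, {"env_01": 1.0}, 20, 0.5, seed=9)
        from gapkit import normalize_pair, schoener_d, hellinger_i

        p, q = normalize_pair(t1.true_suitability, t2.true_suitability)
        assert schoener_d(p, q) == pytest.approx(1.0)
        assert hellinger_i(p, q) == pytest.approx(1.0)

    def test_records_lie_inside_the_grid(self, small_world):
        tpl = small_world.template
        for r in small_world.records:
            if r.has_coords:
                assert tpl.cell_of(r.lon, r.lat) is not None

    def test_world_regeneration_is_bit_identical(self):
        cfg = WorldConfig(seed=5, n_taxa=4, n_rows=20, n_cols=20, n_env_layers=3,
                          n_occurrences=10, n_coordless=5)
        w1, w2 = make_world(cfg), make_world(cfg)
        assert w1.tree_newick == w2.tree_newick
        np.testing.assert_array_equal(w1.ecoregions.values, w2.ecoregions.values)
        assert [(r.record_id, r.lon, r.lat, r.record_type) for r in w1.records] == [
            (r.record_id, r.lon, r.lat, r.record_type) for r in w2.records
        ]

    def test_invalid_config_names_fields(self):
        with pytest.raises(ValueError, match="n_taxa"):
            WorldConfig(n_taxa=1).validate()

    def test_written_world_reads_back(self, tmp_path, small_world):
        out = write_world(small_world, tmp_path / "world")
        records = load_occurrences(out / "occ.csv")
        assert len(records) == len(small_world.records)
        eco = read_ascii_grid(out / "eco.asc")
        np.testing.assert_array_equal(eco.values, small_world.ecoregions.values)
        truth = json.loads((out / "truth.json").read_text())
        assert truth["config"]["n_taxa"] == small_world.config.n_taxa
        tree = read_newick(str(out / "tree.nwk"))
        assert len(list(tree.leaf_node_iter())) == small_world.config.n_taxa


class TestTruthRecovery:
    def test_disjoint_niches_land_in_distinct_clusters(self, template):
        """Taxa with separated niche centers on two variables should be
        recovered as distinct HCPC clusters in nearly every replicate."""
        hits = 0
        n_reps = 50
        for seed in range(n_reps):
            env = make_env_layers(2, template, 7, seed)
            centers = [(-1.2, -1.2), (1.2, 1.2)]
            pts, labels = [], []
            for i, (c1, c2) in enumerate(centers):
                _, recs = make_taxon(
                    f"t{i}", env,
                    {"env_01": c1, "env_02": c2},
                    {"env_01": 0.4, "env_02": 0.4},
                    25, 0.5, seed=seed * 10 + i,
                )
                pts += [(r.lon, r.lat) for r in recs]
                labels += [f"t{i}"] * len(recs)
            mats, kept = [], []
            mat, _ = extract_env(pts, env)
            res = pca(mat, standardize=False)
            assign = hcpc_clusters(res.scores.to_numpy(), labels, k=2, n_pcs=2)
            if assign.assignments["t0"] != assign.assignments["t1"]:
                hits += 1
        assert hits >= 0.9 * n_reps

    def test_zero_germplasm_taxon_is_high_priority(self, template):
        env = make_env_layers(1, template, 7, 2)
        truth, recs = make_taxon(
            "t", env, {"env_01": 0.0}, {"env_01": 1.0}, 30, 0.0, seed=3
        )
        n_g, n_h, _, _ = partition_counts(recs, "t")
        from gapkit.sdm_eval import binarize

        rng = binarize(truth.true_suitability, 0.5)
        gs = fps_classify("t", srs(n_g, n_h), 0.0, 0.0)
        assert gs.category == "HPS" and gs.fps <= 3.0
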