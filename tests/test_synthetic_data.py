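import json

import numpy as np
import pandas as pd
import pytest

import personet as pn
from personet._util import ConfigError


class TestConfigValidation:
    def test_profile_sizes_must_sum_to_subjects(self, tiny_cfg):
        cfg = pn.SynthConfig(**{**tiny_cfg.to_dict(), "n_subjects": 31})
        with pytest.raises(ConfigError, match="profile_sizes"):
            cfg.validate()

    @pytest.mark.parametrize("field,value,match", [
        ("noise_sd", 0.0, "noise_sd"),
        ("llps_fraction", 1.5, "llps_fraction"),
        ("n_biclusters", 0, "n_biclusters"),
        ("n_responsive", 10_000, "n_responsive"),
    ])
    def test_errors_name_the_offending_field(self, tiny_cfg, field, value, match):
        cfg = pn.SynthConfig(**{**tiny_cfg.to_dict(), field: value})
        with pytest.raises(ConfigError, match=match):
            cfg.validate()


class TestGenExpression:
    def test_shape_labels_and_planted_truth(self, tiny_cfg):
        matrix, labels, truth = pn.gen_expression(tiny_cfg)
        assert matrix.shape == (30, 120)
        assert len(labels) == 30
        counts = pd.Series(labels).value_counts().to_dict()
        assert counts == tiny_cfg.profile_sizes
        blocks = [set(b["genes"]) for b in truth["biclusters"].values()]
        for i, a in enumerate(blocks):  # gene blocks are disjoint
            for b in blocks[i + 1:]:
                assert a.isdisjoint(b)

    def test_cohort_scale_group_sizes(self):
        cfg = pn.SynthConfig(n_genes=1600, n_responsive=700,
                             bicluster_genes=100, rng_seed=0)
        matrix, labels, _ = pn.gen_expression(cfg)
        sizes = pd.Series(labels).value_counts()
        assert matrix.shape[0] == 459
        assert (sizes["creative"], sizes["organized"], sizes["unregulated"]) \
            == (125, 241, 93)
        assert sizes.sum() == 459

    def test_deterministic_given_seed(self, tiny_cfg):
        m1, l1, t1 = pn.gen_expression(tiny_cfg)
        m2, l2, t2 = pn.gen_expression(tiny_cfg)
        assert m1.equals(m2) and l1 == l2 and t1 == t2

    def test_zero_effect_still_returns_valid_matrix(self, tiny_cfg):
        cfg = pn.SynthConfig(**{**tiny_cfg.to_dict(), "bicluster_effect": 0.0})
        matrix, _, truth = pn.gen_expression(cfg)
        assert np.isfinite(matrix.to_numpy()).all()
        assert len(truth["biclusters"]) == cfg.n_biclusters

    def test_label_permutation_destroys_profile_effect(self):
        cfg = pn.SynthConfig(
            n_subjects=120,
            profile_sizes={"creative": 35, "organized": 55, "unregulated": 30},
            n_genes=600, n_responsive=150, n_biclusters=2,
            bicluster_genes=30, bicluster_subjects=40,
            profile_effect={"creative": 1.0, "organized": 0.5,
                            "unregulated": 0.0},
            rng_seed=5)
        matrix, labels, truth = pn.gen_expression(cfg)
        resp = matrix.loc[:, truth["responsive_genes"]]
        planted = pn.bootstrap_profile_anova(resp, labels, n_boot=10, seed=1)
        rng = np.random.default_rng(2)
        subjects = list(labels)
        fs = []
        for _ in range(20):
            perm = rng.permutation(subjects)
            shuffled = {s: labels[p] for s, p in zip(subjects, perm)}
            fs.append(pn.bootstrap_profile_anova(
                resp, shuffled, n_boot=5, seed=3).mean_F)
        assert planted.mean_F > 10 * max(np.mean(fs), 1e-9)


class TestGenAtlas:
    def test_enriched_set_mean_exceeds_background(self, tiny_cfg):
        cfg = pn.SynthConfig(**{**tiny_cfg.to_dict(),
                                "region_enrichment": {"S": ["R01"]}})
        genes = [f"G{i:06d}" for i in range(1, 121)]
        sets = {"S": genes[:15]}
        atlas = pn.gen_atlas(cfg, sets)
        in_set = atlas.loc[sets["S"], "R01"].mean()
        background = atlas.loc[genes[15:], "R01"].mean()
        assert in_set > background + 0.5 * cfg.region_effect

    def test_no_enrichment_regions_exchangeable(self, tiny_cfg):
        atlas = pn.gen_atlas(tiny_cfg, {})
        col_means = atlas.mean(axis=0)
        assert col_means.std() < 0.5  # all regions drawn from one law

    def test_unknown_set_or_region_rejected(self, tiny_cfg):
        cfg = pn.SynthConfig(**{**tiny_cfg.to_dict(),
                                "region_enrichment": {"ghost": ["R01"]}})
        with pytest.raises(ConfigError, match="ghost"):
            pn.gen_atlas(cfg, {})
        cfg = pn.SynthConfig(**{**tiny_cfg.to_dict(),
                                "region_enrichment": {"S": ["R99"]}})
        with pytest.raises(ConfigError, match="R99"):
            pn.gen_atlas(cfg, {"S": ["G000001"]})


class TestGenInteractions:
    def test_deterministic_given_seed(self, tiny_cfg):
        i1, l1, t1 = pn.gen_interactions(tiny_cfg)
        i2, l2, t2 = pn.gen_interactions(tiny_cfg)
        assert i1.edges.equals(i2.edges) and l1.equals(l2)
        assert t1["modules"] == t2["modules"]

    def test_all_seven_signatures_populated(self, interaction_bundle):
        interactions, _, truth = interaction_bundle
        for mid in (f"M{i}" for i in range(1, 8)):
            assert truth["modules"][mid], mid

    def test_seed_sets_connect_to_all_hub_genes(self, interaction_bundle):
        interactions, _, truth = interaction_bundle
        edges = interactions.edges
        for name, seeds in truth["seed_sets"].items():
            touched = set()
            seed_set = set(seeds)
            for row in edges.itertuples(index=False):
                if row.source in seed_set and row.target in truth["hub"]:
                    touched.add(row.target)
                if row.target in seed_set and row.source in truth["hub"]:
                    touched.add(row.source)
            assert touched == set(truth["hub"]), name

    def test_hub_disjoint_from_ordinary_gene_pool(self, tiny_cfg):
        cfg = pn.SynthConfig(**{**tiny_cfg.to_dict(),
                                "hub_mirnas": ("mir-A", "mir-A", "mir-B")})
        with pytest.raises(ConfigError):
            pn.gen_interactions(cfg)

    def test_planted_connector_survives_minimum_network(self):
        # connector on every seed-to-seed path must survive pruning
        rows = pd.DataFrame(
            [("s1", "hubX", "ppi"), ("hubX", "s2", "ppi"),
             ("s1", "leaf", "ppi")],
            columns=["source", "target", "layer"])
        net = pn.network_from_edges(rows, seeds=["s1", "s2"])
        minimal = pn.minimum_network(net)
        assert "hubX" in minimal.nodes and "leaf" not in minimal.nodes

    def test_truth_roundtrips_through_json(self, tmp_path, interaction_bundle):
        _, _, truth = interaction_bundle
        path = tmp_path / "truth.json"
        path.write_text(json.dumps(truth, sort_keys=True))
        assert json.loads(path.read_text()) == json.loads(
            json.dumps(truth, sort_keys=True))


class TestGenAnnotations:
    def test_llps_rate_matches_binomial_mean(self):
        cfg = pn.SynthConfig(n_genes=2000, n_responsive=1500, rng_seed=9)
        genes = [f"G{i}" for i in range(20_000)]
        ann = pn.gen_annotations(cfg, genes)
        rate = ann["llps_ht"].mean()
        # binomial sd at n=20000, p=0.157 is ~0.0026
        assert rate == pytest.approx(cfg.llps_fraction, abs=0.01)

    def test_zero_fraction_gives_empty_list(self, tiny_cfg):
        cfg = pn.SynthConfig(**{**tiny_cfg.to_dict(), "llps_fraction": 0.0})
        ann = pn.gen_annotations(cfg, [f"g{i}" for i in range(500)])
        assert not ann["llps_ht"].any()

    def test_exact_planting(self, tiny_cfg):
        genes = [f"g{i}" for i in range(100)]
        ann = pn.gen_annotations(tiny_cfg, genes,
                                 exact_llps=[(genes[:8], 5)])
        assert ann.loc[ann["gene"].isin(genes[:8]), "llps_ht"].sum() == 5

    def test_deterministic_given_seed(self, tiny_cfg):
        genes = [f"g{i}" for i in range(200)]
        a = pn.gen_annotations(tiny_cfg, genes)
        b = pn.gen_annotations(tiny_cfg, genes)
        assert a.equals(b)
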