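"""Generator correctness: planted effects, reproducibility, file contracts."""

import itertools

import numpy as np
import pandas as pd
import pytest

from immffl.assoc import spearman
from immffl.errors import ConfigurationError
from immffl.synthetic import (
    SimulationConfig,
    generate_counts,
    generate_edge_tables,
    generate_infiltration,
    generate_survival,
    write_simulated_dataset,
)
from immffl import survival as sv


def small_config(**kw):
    base = dict(
        n_genes=300, n_mirnas=40, n_tumor=20, n_normal=8, n_de_genes=30,
        n_de_mirnas=8, n_batches=2, seed=0,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestConfig:
    @pytest.mark.parametrize(
        "kw",
        [
            {"n_genes": 0},
            {"n_tumor": -1},
            {"n_de_genes": 500},
            {"dispersion": 0.0},
            {"censor_rate": 1.5},
            {"hub_size": 1000},
            {"infiltration_targets": [("G0001", "NKT", 1.5)]},
            {"planted_ffls": [("MIRX", "TF001", "G0001")]},
        ],
    )
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ConfigurationError):
            small_config(**kw)

    def test_planted_ids_exist_in_universe(self):
        cfg = small_config()
        genes, mirnas, tfs = (
            set(cfg.gene_ids()), set(cfg.mirna_ids()), set(cfg.tf_ids()),
        )
        for m, t, g in cfg.planted_ffls:
            assert m in mirnas and t in tfs and g in genes
        for g, _, _ in cfg.infiltration_targets:
            assert g in genes

    def test_yaml_round_trip(self, tmp_path):
        cfg = small_config(de_log2fc=2.5)
        cfg.to_yaml(tmp_path / "sim.yaml")
        again = SimulationConfig.from_yaml(tmp_path / "sim.yaml")
        assert again.to_dict() == cfg.to_dict()


class TestCounts:
    def test_null_fold_change_plants_nothing(self):
        res = generate_counts(small_config(de_log2fc=0.0, seed=3))
        assert (res.truth_mrna["true_log2fc"] == 0).all()
        assert (res.truth_mirna["true_log2fc"] == 0).all()

    def test_counts_are_nonnegative_integers_with_matching_annotations(self):
        res = generate_counts(small_config())
        for cohort in (res.mrna, res.mirna):
            vals = cohort.values.to_numpy()
            assert (vals >= 0).all()
            assert np.allclose(vals, np.round(vals))
            assert list(cohort.values.columns) == list(cohort.annotations.index)

    def test_planted_mean_log2fc_recovered(self):
        # ratio-of-group-means estimator on the raw count matrix
        cfg = SimulationConfig(
            n_genes=2000, n_mirnas=3, n_tumor=30, n_normal=30, n_de_genes=200,
            n_de_mirnas=0, de_log2fc=3.0, n_batches=1, planted_ffls=[],
            infiltration_targets=[], seed=7,
        )
        res = generate_counts(cfg)
        up = res.truth_mrna.loc[res.truth_mrna["true_log2fc"] > 0, "feature_id"]
        tumor = res.mrna.values[res.mrna.samples_in_group("tumor")]
        normal = res.mrna.values[res.mrna.samples_in_group("normal")]
        lfc = np.log2(tumor.loc[up].mean(axis=1) / normal.loc[up].mean(axis=1))
        assert abs(lfc.mean() - 3.0) < 0.2

    def test_same_seed_reproduces_identical_matrices(self):
        a = generate_counts(small_config(seed=11))
        b = generate_counts(small_config(seed=11))
        pd.testing.assert_frame_equal(a.mrna.values, b.mrna.values)
        pd.testing.assert_frame_equal(a.mirna.values, b.mirna.values)


class TestEdgeTables:
    @pytest.fixture
    def tables(self):
        cfg = small_config()
        return cfg, generate_edge_tables(cfg, generate_counts(cfg).truth_mrna)

    def test_planted_clique_fully_present_above_cutoff(self, tables):
        cfg, et = tables
        hubs = et.hub_genes
        pairs = {
            tuple(sorted(p)): s
            for p, s in zip(
                et.ppi[["a", "b"]].itertuples(index=False), et.ppi["score"]
            )
        }
        for a, b in itertools.combinations(sorted(hubs), 2):
            assert pairs[(a, b)] > 0.9

    def test_background_scores_capped(self, tables):
        _, et = tables
        hubset = set(et.hub_genes)
        bg = et.ppi[~(et.ppi["a"].isin(hubset) & et.ppi["b"].isin(hubset))]
        assert (bg["score"] <= 0.95).all()
        assert (bg["score"] >= 0.4).all()

    def test_planted_triples_have_all_three_edges(self, tables):
        cfg, et = tables
        edges = {
            (s, t, ty)
            for s, t, ty in et.regulatory[["source", "target", "type"]].itertuples(
                index=False
            )
        }
        for m, t, g in cfg.planted_ffls:
            assert (m, g, "mirna_mrna") in edges
            assert (m, t, "mirna_tf") in edges
            assert (t, g, "tf_mrna") in edges

    def test_immune_list_contains_hubs_and_gene_set_contains_hubs(self, tables):
        _, et = tables
        assert set(et.hub_genes) <= set(et.immune_genes)
        assert set(et.hub_genes) <= set(et.gene_sets.sets["HUB_COMPLEX"])


class TestSurvival:
    def _tumor_cohort(self, cfg):
        res = generate_counts(cfg)
        return res.mrna.subset_samples(res.mrna.samples_in_group("tumor"))

    def test_zero_censor_rate_gives_all_events(self):
        cfg = small_config(censor_rate=0.0)
        tab = generate_survival(cfg, self._tumor_cohort(cfg), "G0001")
        assert (tab["event"] == 1).all()

    def test_absent_marker_raises(self):
        cfg = small_config()
        with pytest.raises(KeyError):
            generate_survival(cfg, self._tumor_cohort(cfg), "NOPE")

    def test_negative_beta_shortens_low_expression_survival(self):
        cfg = SimulationConfig(
            n_genes=10, n_mirnas=3, n_tumor=800, n_normal=1, n_de_genes=0,
            n_de_mirnas=0, n_batches=1, planted_ffls=[], infiltration_targets=[],
            survival_beta=-0.5, censor_rate=0.2, seed=21,
        )
        cohort = self._tumor_cohort(cfg)
        tab = generate_survival(cfg, cohort, "G0001")
        expr = np.log2(cohort.values.loc["G0001"] + 1)
        groups = sv.dichotomize(expr, "median")
        merged = tab.set_index("sample_id").assign(group=groups.values).reset_index()
        _, med_low = sv.km_estimate(merged[merged["group"] == "low"])
        _, med_high = sv.km_estimate(merged[merged["group"] == "high"])
        assert med_low < med_high

    def test_censor_rate_approximately_respected(self):
        cfg = SimulationConfig(
            n_genes=10, n_mirnas=3, n_tumor=2000, n_normal=1, n_de_genes=0,
            n_de_mirnas=0, n_batches=1, planted_ffls=[], infiltration_targets=[],
            censor_rate=0.3, seed=5,
        )
        tab = generate_survival(cfg, self._tumor_cohort(cfg), "G0001")
        assert abs((1 - tab["event"]).mean() - 0.3) < 0.05


class TestInfiltration:
    def _cohort(self, targets, seed=4, n=400):
        cfg = SimulationConfig(
            n_genes=50, n_mirnas=3, n_tumor=n, n_normal=1, n_de_genes=0,
            n_de_mirnas=0, n_batches=1, planted_ffls=[],
            infiltration_targets=targets, seed=seed,
        )
        res = generate_counts(cfg)
        return cfg, res.mrna.subset_samples(res.mrna.samples_in_group("tumor"))

    def test_strong_target_recovered(self):
        cfg, cohort = self._cohort([("G0001", "NKT", 0.9)])
        infil = generate_infiltration(cfg, cohort)
        r = spearman(cohort.values.loc["G0001"].to_numpy(), infil["NKT"].to_numpy())
        assert abs(r.rho - 0.9) < 0.1

    def test_null_target_uncorrelated(self):
        cfg, cohort = self._cohort([("G0002", "CD8_T", 0.0)])
        infil = generate_infiltration(cfg, cohort)
        r = spearman(cohort.values.loc["G0002"].to_numpy(), infil["CD8_T"].to_numpy())
        assert abs(r.rho) < 0.15

    def test_fractions_bounded_and_purity_anticorrelated(self):
        cfg, cohort = self._cohort([("G0001", "NKT", 0.5)])
        infil = generate_infiltration(cfg, cohort)
        assert ((infil >= 0) & (infil <= 1)).all().all()
        cells = [c for c in infil.columns if c != "purity"]
        total = infil[cells].sum(axis=1)
        assert spearman(total.to_numpy(), infil["purity"].to_numpy()).rho < -0.5


class TestWriter:
    def test_dataset_files_written_and_byte_identical_on_rerun(self, tmp_path):
        cfg = small_config(seed=9)
        p1 = write_simulated_dataset(cfg, tmp_path / "a")
        p2 = write_simulated_dataset(small_config(seed=9), tmp_path / "b")
        assert set(p1) == set(p2)
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes(), key

    def test_truth_file_matches_planted_structure(self, tmp_path):
        import json

        cfg = small_config(seed=9)
        paths = write_simulated_dataset(cfg, tmp_path / "a")
        truth = json.loads(paths["truth"].read_text())
        assert truth["planted_ffls"] == [list(t) for t in cfg.planted_ffls]
        assert len(truth["de_genes"]) == cfg.n_de_genes
        assert truth["hub_genes"] == cfg.hub_genes()
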