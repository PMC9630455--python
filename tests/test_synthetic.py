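"""Synthetic generator: structure, moments, determinism, intermediates."""

import numpy as np
import pytest

import slideuq as s
from slideuq.errors import ConfigError, ContractError


class TestConfig:
    @pytest.mark.parametrize(
        "field,value",
        [
            ("passes", 1),
            ("clear_center_offset", 0.0),
            ("ambiguous_pass_sd", 0.01),  # below clear_pass_sd
            ("ambiguous_tile_fraction", 1.5),
            ("intermediate_slide_fraction", -0.1),
            ("class_ratio", (0, 3)),
        ],
    )
    def test_invalid_fields_named(self, field, value):
        cfg = s.SimulationConfig(**{field: value})
        with pytest.raises(ConfigError):
            cfg.validate()

    def test_ratio_slide_counts(self):
        assert s.SimulationConfig(
            n_slides_per_class=200, class_ratio=(1, 3)
        ).slides_per_class() == (67, 200)
        assert s.SimulationConfig(
            n_slides_per_class=200, class_ratio=(1, 10)
        ).slides_per_class() == (20, 200)
        assert s.SimulationConfig(
            n_slides_per_class=200, class_ratio=(10, 1)
        ).slides_per_class() == (200, 20)


class TestSimulateDataset:
    def test_noise_free_limit_all_correct(self):
        cfg = s.SimulationConfig(
            n_slides_per_class=4, tiles_per_slide=10, ambiguous_tile_fraction=0.0,
            clear_pass_sd=0.0, ambiguous_pass_sd=0.01,
            intermediate_slide_fraction=0.0, seed=2,
        )
        results = s.estimate_all(s.simulate_dataset(cfg).ensembles)
        assert all(r.sigma_hat == 0.0 for r in results)
        assert all(r.correct for r in results)

    def test_determinism(self):
        cfg = s.SimulationConfig(n_slides_per_class=5, tiles_per_slide=8, seed=42)
        a, b = s.simulate_dataset(cfg), s.simulate_dataset(cfg)
        assert a.tiles.equals(b.tiles)
        assert a.manifest.equals(b.manifest)
        for ea, eb in zip(a.ensembles, b.ensembles):
            assert ea == eb

    def test_ambiguous_tiles_have_higher_uncertainty(self):
        cfg = s.SimulationConfig(
            n_slides_per_class=50, tiles_per_slide=50,
            intermediate_slide_fraction=0.0, seed=7,
        )
        ds = s.simulate_dataset(cfg)
        results = s.estimate_all(ds.ensembles)
        amb = ds.tiles["is_ambiguous"].to_numpy()
        sig = np.array([r.sigma_hat for r in results])
        mean_amb, mean_clear = sig[amb].mean(), sig[~amb].mean()
        assert mean_amb > mean_clear
        # spreads consistent with the configured sds (clipping shrinks
        # the ambiguous spread somewhat; allow a generous band)
        assert mean_clear == pytest.approx(cfg.clear_pass_sd, rel=0.15)
        assert 0.5 * cfg.ambiguous_pass_sd < mean_amb <= cfg.ambiguous_pass_sd

    def test_mispredicted_tiles_have_higher_mean_uncertainty(self, small_dataset,
                                                             small_tile_results):
        sig = np.array([r.sigma_hat for r in small_tile_results])
        correct = np.array([r.correct for r in small_tile_results])
        assert sig[~correct].mean() > sig[correct].mean()

    def test_manifest_consistent_with_tiles(self, small_dataset):
        ds = small_dataset
        merged = ds.tiles.merge(ds.manifest, on="slide_id", suffixes=("", "_m"))
        assert (merged["label"] == merged["label_m"]).all()
        assert (merged["patient_id"] == merged["patient_id_m"]).all()
        inter = merged[merged["is_intermediate"]]
        assert inter["is_ambiguous"].all()

    def test_multi_slide_patients(self):
        cfg = s.SimulationConfig(
            n_slides_per_class=10, tiles_per_slide=4,
            multi_slide_patient_fraction=0.4, intermediate_slide_fraction=0.0,
            seed=3,
        )
        ds = s.simulate_dataset(cfg)
        sizes = ds.manifest.groupby("patient_id").size()
        assert (sizes > 1).any()
        # a patient's slides always share one label
        labels = ds.manifest.groupby("patient_id")["label"].nunique()
        assert (labels == 1).all()


class TestIntermediateSlides:
    def test_zero_count_is_identity(self, small_dataset):
        out = s.add_intermediate_slides(small_dataset, count=0)
        assert out is small_dataset

    def test_explicit_count_flagged(self, small_dataset):
        out = s.add_intermediate_slides(small_dataset, count=10,
                                        tiles_per_slide=30)
        added = out.manifest[out.manifest["slide_id"].str.startswith("SX_")]
        assert len(added) == 10
        assert added["is_intermediate"].all()
        assert set(added["label"]) <= {0, 1}
        new_tiles = out.tiles[out.tiles["slide_id"].str.startswith("SX_")]
        assert len(new_tiles) == 300
        assert new_tiles["is_ambiguous"].all()

    def test_fraction_against_final_total(self, small_dataset):
        n0 = len(small_dataset.manifest)
        out = s.add_intermediate_slides(small_dataset, fraction=0.5,
                                        tiles_per_slide=10)
        assert len(out.manifest) == 2 * n0

    def test_labels_uninformative_on_intermediates(self):
        """Slide predictions on random-label intermediate slides are
        independent of those labels (permutation-style check)."""
        cfg = s.SimulationConfig(n_slides_per_class=20, tiles_per_slide=40,
                                 intermediate_slide_fraction=0.0, seed=13)
        ds = s.add_intermediate_slides(s.simulate_dataset(cfg), count=40,
                                       tiles_per_slide=40, seed=13)
        results = s.estimate_all(ds.ensembles)
        inter_ids = set(ds.manifest.loc[ds.manifest["is_intermediate"], "slide_id"])
        slides = [x for x in s.aggregate_slides_nonuq(results)
                  if x.slide_id in inter_ids]
        preds = np.array([x.slide_prediction for x in slides])
        labels = np.array([x.label for x in slides])
        gap = abs(preds[labels == 1].mean() - preds[labels == 0].mean())
        assert gap < 0.05  # no association between random labels and predictions

    def test_intermediate_slides_dominate_slide_uncertainty(self, small_dataset):
        ds = s.add_intermediate_slides(small_dataset, count=20,
                                       tiles_per_slide=40, seed=5)
        results = s.estimate_all(ds.ensembles)
        slides = s.aggregate_slides_uq(results, s.HIGH_CONF_ALL)
        inter_ids = set(ds.manifest.loc[ds.manifest["is_intermediate"], "slide_id"])
        u_inter = [x.slide_uncertainty for x in slides if x.slide_id in inter_ids]
        u_ord = [x.slide_uncertainty for x in slides if x.slide_id not in inter_ids]
        assert min(u_inter) > max(u_ord)

    def test_bad_fraction_rejected(self, small_dataset):
        with pytest.raises(ConfigError):
            s.add_intermediate_slides(small_dataset, fraction=1.5)


class TestOraclePredictor:
    def test_deterministic_given_seed(self, small_dataset):
        ids = list(small_dataset.tiles["tile_id"].iloc[:50])
        p1 = s.oracle_predictor(small_dataset, seed=9).fit(ids)
        p2 = s.oracle_predictor(small_dataset, seed=9).fit(ids)
        assert p1.predict_ensemble(ids) == p2.predict_ensemble(ids)

    def test_batching_does_not_change_ensembles(self, small_dataset):
        ids = list(small_dataset.tiles["tile_id"].iloc[:40])
        p = s.oracle_predictor(small_dataset, seed=9).fit(ids)
        whole = p.predict_ensemble(ids)
        parts = p.predict_ensemble(ids[:13]) + p.predict_ensemble(ids[13:])
        assert whole == parts

    def test_degradation_disabled_ignores_training_size(self, small_dataset):
        ids = list(small_dataset.tiles["tile_id"].iloc[:30])
        p = s.oracle_predictor(small_dataset, seed=1)
        small = p.fit(ids[:5]).predict_ensemble(ids)
        large = p.fit(ids).predict_ensemble(ids)
        assert small == large

    def test_degradation_widens_uncertainty_for_small_training_sets(
        self, small_dataset
    ):
        ids = list(small_dataset.tiles["tile_id"])
        p = s.oracle_predictor(small_dataset, seed=1, degradation=0.25,
                               reference_train_size=1000)
        sig10 = np.mean([
            r.sigma_hat
            for r in s.estimate_all(p.fit(ids[:10]).predict_ensemble(ids[:300]))
        ])
        sig1000 = np.mean([
            r.sigma_hat
            for r in s.estimate_all(p.fit(ids[:1000]).predict_ensemble(ids[:300]))
        ])
        assert sig10 > sig1000

    def test_unknown_tile_rejected(self, small_dataset):
        p = s.oracle_predictor(small_dataset, seed=0)
        with pytest.raises(ContractError):
            p.predict_ensemble(["nope"])
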