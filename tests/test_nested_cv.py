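"""Fold planning, nested threshold derivation, and the experiment
runner, including the anti-leakage guarantees."""

import math

import pandas as pd
import pytest

import slideuq as s
from slideuq.errors import ConfigError, InsufficientDataError
from slideuq.nested_cv import _child_seed


def manifest(n_per_class, patients=None):
    rows = []
    for label in (0, 1):
        for i in range(n_per_class):
            sid = f"S{label}_{i:03d}"
            rows.append({
                "slide_id": sid,
                "patient_id": patients[sid] if patients else f"P_{sid}",
                "label": label,
            })
    return pd.DataFrame(rows)


class TestFoldPlan:
    def test_balanced_stratification(self):
        plan = s.make_fold_plan(manifest(15), k_outer=3, k_inner=5, seed=1)
        df = manifest(15).set_index("slide_id")
        for f in range(3):
            fold = [sid for sid, g in plan.outer_assignments.items() if g == f]
            assert len(fold) == 10
            assert sum(df.loc[sid, "label"] for sid in fold) == 5

    def test_inner_folds_partition_outer_training_sets(self):
        plan = s.make_fold_plan(manifest(15), k_outer=3, k_inner=5, seed=1)
        for f in range(3):
            train, val = plan.outer_split(f)
            section = plan.inner_section(f)
            assert set(section) == set(train)
            assert set(section.values()) == set(range(5))

    def test_determinism_and_input_order_invariance(self):
        m = manifest(20)
        p1 = s.make_fold_plan(m, seed=5)
        p2 = s.make_fold_plan(m.sample(frac=1.0, random_state=0), seed=5)
        assert p1.outer_assignments == p2.outer_assignments
        assert p1.inner_assignments == p2.inner_assignments
        p3 = s.make_fold_plan(m, seed=6)
        assert p3.outer_assignments != p1.outer_assignments

    def test_patient_grouping_never_straddles_folds(self):
        # pair slides into shared patients
        patients = {}
        for label in (0, 1):
            for i in range(30):
                sid = f"S{label}_{i:03d}"
                patients[sid] = f"P{label}_{i // 2:03d}"
        m = manifest(30, patients)
        plan = s.make_fold_plan(m, k_outer=3, k_inner=5, seed=2,
                                group_by_patient=True)
        by_patient = m.groupby("patient_id")["slide_id"].apply(list)
        for sids in by_patient:
            outs = {plan.outer_assignments[x] for x in sids}
            assert len(outs) == 1
            f_out = outs.pop()
            for f in range(3):
                if f == f_out:
                    continue
                inner = {plan.inner_assignments[(f, x)] for x in sids}
                assert len(inner) == 1

    def test_insufficient_slides_lists_counts(self):
        with pytest.raises(InsufficientDataError, match="per-class"):
            s.make_fold_plan(manifest(10), k_outer=3, k_inner=5, seed=0)

    def test_bad_k(self):
        with pytest.raises(ConfigError):
            s.make_fold_plan(manifest(20), k_outer=1, k_inner=5, seed=0)


@pytest.fixture(scope="module")
def nested_setup():
    cfg = s.SimulationConfig(n_slides_per_class=30, tiles_per_slide=30, seed=21)
    ds = s.simulate_dataset(cfg)
    plan = s.make_fold_plan(ds.manifest, k_outer=3, k_inner=5, seed=21)
    return ds, plan


class TestDeriveThresholdsNested:
    def test_min_max_combination_rule(self, nested_setup):
        ds, plan = nested_setup
        predictor = s.oracle_predictor(ds, seed=4)
        train, _ = plan.outer_split(0)
        tiles = ds.tiles[ds.tiles["slide_id"].isin(train)]
        rep = s.derive_thresholds_nested(tiles, plan.inner_section(0), predictor)
        finite_t = [x.optimum for x in rep.tile_searches if not x.is_degenerate]
        finite_s = [x.optimum for x in rep.slide_searches if not x.is_degenerate]
        if finite_t:
            assert rep.thresholds.theta_tile == min(finite_t)
            assert all(rep.thresholds.theta_tile <= v for v in finite_t)
        if finite_s:
            assert rep.thresholds.theta_slide == max(finite_s)
            assert all(rep.thresholds.theta_slide >= v for v in finite_s)

    def test_leakage_canary_poisoned_validation_tiles(self, nested_setup):
        """Thresholds must be identical whether or not outer-validation
        tiles are poisoned, proving validation data is never read."""
        ds, plan = nested_setup
        train, val = plan.outer_split(1)
        poisoned = ds.tiles.copy()
        mask = poisoned["slide_id"].isin(val)
        poisoned.loc[mask, "center"] = 0.987654
        poisoned.loc[mask, "pass_sd"] = 123.0
        ds_poisoned = s.SyntheticDataset(
            tiles=poisoned, manifest=ds.manifest, config=ds.config, seed=ds.seed
        )
        clean_rep = s.derive_thresholds_nested(
            ds.tiles[ds.tiles["slide_id"].isin(train)],
            plan.inner_section(1), s.oracle_predictor(ds, seed=8),
        )
        poisoned_rep = s.derive_thresholds_nested(
            ds_poisoned.tiles[ds_poisoned.tiles["slide_id"].isin(train)],
            plan.inner_section(1), s.oracle_predictor(ds_poisoned, seed=8),
        )
        assert clean_rep.thresholds.theta_tile == poisoned_rep.thresholds.theta_tile
        assert clean_rep.thresholds.theta_slide == poisoned_rep.thresholds.theta_slide
        assert (clean_rep.thresholds.inner_fold_theta_tile
                == poisoned_rep.thresholds.inner_fold_theta_tile)

    def test_degenerate_folds_fall_back_to_sentinels(self):
        """Noise-free, unambiguous data has no mispredictions anywhere:
        every inner fold is degenerate and both thresholds become the
        everything-high-confidence sentinel, with a warning."""
        cfg = s.SimulationConfig(
            n_slides_per_class=16, tiles_per_slide=10,
            ambiguous_tile_fraction=0.0, clear_pass_sd=0.001,
            ambiguous_pass_sd=0.01, intermediate_slide_fraction=0.0, seed=3,
        )
        ds = s.simulate_dataset(cfg)
        plan = s.make_fold_plan(ds.manifest, k_outer=3, k_inner=5, seed=3)
        rep = s.derive_thresholds_nested(
            ds.tiles[ds.tiles["slide_id"].isin(plan.outer_split(0)[0])],
            plan.inner_section(0), s.oracle_predictor(ds, seed=1),
        )
        assert rep.thresholds.theta_tile == math.inf
        assert rep.thresholds.theta_slide == math.inf
        assert rep.degenerate_tile_folds == 5
        assert any("degenerate" in w for w in rep.warnings)

    def test_separable_uncertainty_yields_perfect_held_out_accuracy(self):
        """With clear tiles far quieter than ambiguous ones, the nested
        thresholds give 100% accurate high-confidence tiles on the held
        out outer fold."""
        cfg = s.SimulationConfig(
            n_slides_per_class=20, tiles_per_slide=40,
            clear_pass_sd=0.01, ambiguous_pass_sd=0.3,
            intermediate_slide_fraction=0.1, seed=6,
        )
        ds = s.simulate_dataset(cfg)
        plan = s.make_fold_plan(ds.manifest, k_outer=3, k_inner=5, seed=6)
        predictor = s.oracle_predictor(ds, seed=2)
        train, val = plan.outer_split(0)
        rep = s.derive_thresholds_nested(
            ds.tiles[ds.tiles["slide_id"].isin(train)],
            plan.inner_section(0), predictor,
        )
        val_tiles = ds.tiles[ds.tiles["slide_id"].isin(val)]
        results = s.estimate_all(
            predictor.fit(list(ds.tiles["tile_id"])).predict_ensemble(
                list(val_tiles["tile_id"])
            )
        )
        high = [r for r in s.assign_tile_confidence(
            results, rep.thresholds.theta_tile) if r.confidence == "high"]
        assert high  # some tiles retained
        assert all(r.correct for r in high)


class TestExperimentRunner:
    @pytest.fixture(scope="class")
    @staticmethod
    def dataset():
        return s.simulate_dataset(
            s.SimulationConfig(n_slides_per_class=30, tiles_per_slide=30, seed=31)
        )

    def test_determinism_byte_identical_tables(self, dataset):
        cfg = s.ExperimentConfig(bootstrap_repeats=2, seed=9)
        r1 = s.run_crossval_experiment(dataset, cfg)
        r2 = s.run_crossval_experiment(dataset, cfg)
        assert r1.slides_table().to_csv(index=False) == r2.slides_table().to_csv(index=False)
        assert r1.reports_table().to_csv(index=False) == r2.reports_table().to_csv(index=False)

    def test_non_uq_mode_has_no_confidence_partition(self, dataset):
        cfg = s.ExperimentConfig(bootstrap_repeats=1, use_uq=False, seed=9)
        res = s.run_crossval_experiment(dataset, cfg)
        for fo in res.folds:
            assert fo.thresholds is None
            assert [r.cohort for r in fo.reports] == ["all"]
            assert all(x.confidence == "unset" for x in fo.slide_results)

    def test_every_validation_slide_appears_once_per_repeat(self, dataset):
        cfg = s.ExperimentConfig(bootstrap_repeats=2, seed=9)
        res = s.run_crossval_experiment(dataset, cfg)
        table = res.slides_table()
        for rep in (0, 1):
            ids = table.loc[table["repeat"] == rep, "slide_id"]
            assert ids.is_unique
            assert set(ids) == set(dataset.manifest["slide_id"])

    def test_unbalanced_ratios_complete_with_correct_counts(self):
        big = s.simulate_dataset(
            s.SimulationConfig(n_slides_per_class=60, tiles_per_slide=15, seed=33)
        )
        for ratio in ((1, 3), (1, 10)):
            cfg = s.ExperimentConfig(bootstrap_repeats=1, class_ratio=ratio,
                                     k_inner=2, seed=9)
            res = s.run_crossval_experiment(big, cfg)
            table = res.slides_table()
            ordinary = table[~table["slide_id"].str.startswith("SI_")]
            n0 = (ordinary["label"] == 0).sum()
            n1 = (ordinary["label"] == 1).sum()
            a, b = ratio
            scale = min(60 / a, 60 / b)
            assert n0 == int(scale * a) and n1 == int(scale * b)
            for fo in res.folds:
                assert {r.cohort for r in fo.reports} == {
                    "all", "high_confidence", "low_confidence"
                }

    def test_ratio_exhaustion_raises(self, dataset):
        cfg = s.ExperimentConfig(bootstrap_repeats=1, class_ratio=(1, 40), seed=9)
        with pytest.raises(InsufficientDataError):
            s.run_crossval_experiment(dataset, cfg)

    def test_config_from_dict_rejects_unknown_fields(self):
        with pytest.raises(ConfigError):
            s.ExperimentConfig.from_dict({"bogus": 1})
        cfg = s.ExperimentConfig.from_dict({"class_ratio": [1, 3], "seed": 2})
        assert cfg.class_ratio == (1, 3)


def test_child_seed_is_stable_and_bounded():
    a = _child_seed(7, 1, 2)
    assert a == _child_seed(7, 1, 2)
    assert 0 <= a < 2**31 - 1
    assert a != _child_seed(7, 2, 1)
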