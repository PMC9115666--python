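import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

from freshcube import experiment as ex
from freshcube import scene_sim as ss
from freshcube.core import InvalidParameterError, SampleRecord


@pytest.fixture(scope="module")
def tiny_params():
    return ss.ScenarioParams(height=24, width=24, temperatures=(4.0, 25.0),
                             days=(1, 12), n_replicates=4, n_outliers=0,
                             noise_sd=0.002, seed=11)


@pytest.fixture(scope="module")
def tiny_cfg():
    return ex.ExperimentConfig(downsample_budget=60, spice_m0=4,
                               max_fit_spectra=600, plsr_components=3,
                               seed=11)


@pytest.fixture(scope="module")
def tiny_prepared(tiny_params, tiny_cfg):
    records = ss.simulate_design(tiny_params)
    return ex.prepare_dataset(records, tiny_params, tiny_cfg)


class TestSplitFolds:
    def test_default_design_partition(self, default_params):
        records = ss.simulate_design(default_params)
        plan = ex.split_folds(records, seed=3)
        assert len(plan.groups) == 4
        assert all(len(g) == 12 for g in plan.groups)
        record_map = {r.sample_id: r for r in records}
        for group in plan.groups:
            conditions = {record_map[s].condition for s in group}
            assert len(conditions) == 12
        flat = [s for g in plan.groups for s in g]
        assert len(set(flat)) == 48

    def test_single_condition_four_reps(self):
        records = [SampleRecord(sample_id=f"r{i}", temperature=4.0, day=1,
                                replicate=i, glucosinolate=10.0)
                   for i in range(1, 5)]
        plan = ex.split_folds(records, seed=0)
        assert sorted(len(g) for g in plan.groups) == [1, 1, 1, 1]

    def test_same_seed_identical(self, default_params):
        records = ss.simulate_design(default_params)
        a = ex.split_folds(records, seed=9)
        b = ex.split_folds(records, seed=9)
        assert a.groups == b.groups and a.test_index == b.test_index

    def test_unbalanced_rejected(self, default_params):
        records = ss.simulate_design(default_params)[:-1]
        with pytest.raises(InvalidParameterError, match="unbalanced"):
            ex.split_folds(records, seed=0)


class TestRunCv:
    def test_gamma_grid_has_15_values(self):
        assert len(ex.GAMMA_GRID) == 15
        assert ex.GAMMA_GRID[0] == 10 and ex.GAMMA_GRID[-1] == 150

    def test_fit_bookkeeping(self, tiny_prepared, tiny_cfg):
        cv = ex.run_cv(tiny_prepared, "spice+mlr", "entire",
                       gamma_grid=[5.0, 10.0], n_reps=2, config=tiny_cfg,
                       seed=11)
        f = cv.frame()
        # n_reps x n_folds fits per gamma
        assert (f.groupby("gamma").size() == 2 * 3).all()

    def test_unknown_method_rejected(self, tiny_prepared, tiny_cfg):
        with pytest.raises(InvalidParameterError):
            ex.run_cv(tiny_prepared, "nope", "entire", config=tiny_cfg)

    def test_unknown_scenario_rejected(self, tiny_prepared, tiny_cfg):
        with pytest.raises(InvalidParameterError):
            ex.run_cv(tiny_prepared, "plsr", "sideways", config=tiny_cfg)

    def test_determinism(self, tiny_prepared, tiny_cfg):
        a = ex.run_cv(tiny_prepared, "plsr", "entire", n_reps=2,
                      config=tiny_cfg, seed=4)
        b = ex.run_cv(tiny_prepared, "plsr", "entire", n_reps=2,
                      config=tiny_cfg, seed=4)
        pd.testing.assert_frame_equal(a.frame(), b.frame())

    def test_test_group_never_trains(self, tiny_prepared, tiny_cfg):
        plan = ex.split_folds(tiny_prepared.records, seed=11)
        cv = ex.run_cv(tiny_prepared, "miace+mlr", "entire", n_reps=2,
                       config=tiny_cfg, plan=plan, seed=11)
        test_ids = set(plan.test_ids)
        for row in cv.rows:
            assert test_ids.isdisjoint(row["train_ids"])
            assert test_ids.isdisjoint(row["val_ids"])
            assert set(row["train_ids"]).isdisjoint(row["val_ids"])

    def test_aggregation_matches_manual_recompute(self, tiny_prepared,
                                                  tiny_cfg):
        cv = ex.run_cv(tiny_prepared, "plsr", "entire", n_reps=3,
                       config=tiny_cfg, seed=2)
        f = cv.frame()
        manual = f["val_rmse"].mean()
        assert cv.summary()["val_rmse_mean"].iloc[0] == pytest.approx(manual)
        rep0 = f[f["rep"] == 0]["test_rmse"].mean()
        got = cv.per_repetition().set_index("rep").loc[0, "test_rmse"]
        assert got == pytest.approx(rep0)


class TestSelectModel:
    def _cv(self, rows):
        cv = ex.CVResult(method="spice+mlr", scenario="entire")
        cv.rows = rows
        return cv

    def _row(self, gamma, val_rmse, val_r2=0.5, m=3):
        return {"rep": 0, "fold": 0, "gamma": gamma, "val_rmse": val_rmse,
                "val_r2": val_r2, "test_rmse": 1.0, "test_r2": 0.5, "m": m}

    def test_single_candidate(self):
        choice = ex.select_model(self._cv([self._row(10.0, 2.0)]))
        assert choice["gamma"] == 10.0

    def test_lowest_rmse_wins(self):
        rows = [self._row(10.0, 3.0), self._row(20.0, 1.5),
                self._row(30.0, 2.5)]
        assert ex.select_model(self._cv(rows))["gamma"] == 20.0

    def test_tie_breaks_on_r2(self):
        rows = [self._row(10.0, 2.0, val_r2=0.7),
                self._row(20.0, 2.0, val_r2=0.8)]
        assert ex.select_model(self._cv(rows))["gamma"] == 20.0

    def test_then_smaller_m_then_smaller_gamma(self):
        rows = [self._row(10.0, 2.0, val_r2=0.8, m=4),
                self._row(20.0, 2.0, val_r2=0.8, m=3),
                self._row(30.0, 2.0, val_r2=0.8, m=3)]
        assert ex.select_model(self._cv(rows))["gamma"] == 20.0

    def test_empty_rejected(self):
        with pytest.raises(InvalidParameterError):
            ex.select_model(self._cv([]))


class TestOutlierExperiment:
    def test_unknown_id_rejected(self, tiny_prepared, tiny_cfg):
        with pytest.raises(InvalidParameterError, match="unknown"):
            ex.outlier_experiment(tiny_prepared, ["ghost"], config=tiny_cfg)

    def test_capacity_error_on_shared_condition(self, tiny_prepared,
                                                tiny_cfg):
        recs = tiny_prepared.records
        same_cond = [r.sample_id for r in recs
                     if r.condition == recs[0].condition][:2]
        with pytest.raises(InvalidParameterError, match="capacity"):
            ex.outlier_experiment(tiny_prepared, same_cond, method="plsr",
                                  config=tiny_cfg)

    def test_zero_outliers_identical_to_baseline(self, tiny_prepared,
                                                 tiny_cfg):
        out = ex.outlier_experiment(tiny_prepared, [], method="plsr",
                                    n_reps=1, config=tiny_cfg, seed=3)
        pd.testing.assert_frame_equal(out["baseline"].frame(),
                                      out["moved"].frame())

    def test_moved_plan_contains_outliers(self, tiny_prepared, tiny_cfg):
        sid = tiny_prepared.records[0].sample_id
        out = ex.outlier_experiment(tiny_prepared, [sid], method="plsr",
                                    n_reps=1, config=tiny_cfg, seed=3)
        moved = out["moved_plan"]
        assert sid in moved.groups[moved.test_index]
        flat = sorted(s for g in moved.groups for s in g)
        base = sorted(s for g in out["baseline_plan"].groups for s in g)
        assert flat == base

    def test_training_error_drops_when_outliers_leave(self):
        params = ss.ScenarioParams(height=24, width=24, noise_sd=0.002,
                                   temperatures=(4.0, 25.0), days=(1, 12),
                                   n_outliers=2, seed=21)
        records = ss.simulate_design(params)
        outlier_ids = [r.sample_id for r in records if r.is_outlier]
        cfg = ex.ExperimentConfig(downsample_budget=60, plsr_components=3,
                                  seed=21)
        prepared = ex.prepare_dataset(records, params, cfg)
        out = ex.outlier_experiment(prepared, outlier_ids, method="plsr",
                                    n_reps=2, config=cfg, seed=21)
        base = out["baseline"].frame()["train_rmse"].mean()
        moved = out["moved"].frame()["train_rmse"].mean()
        assert moved < base


class TestMakeReport:
    def test_report_files(self, tiny_prepared, tiny_cfg, tmp_path):
        cv = ex.run_cv(tiny_prepared, "plsr", "entire", n_reps=1,
                       config=tiny_cfg, seed=1)
        sid = tiny_prepared.records[0].sample_id
        truth_mask = tiny_prepared.samples[sid].masks["entire"]
        values = np.clip(np.random.default_rng(0).random(truth_mask.shape), 0, 1)
        written = ex.make_report({("plsr", "entire"): cv}, str(tmp_path),
                                 maps={"demo": (values, truth_mask)})
        assert (tmp_path / "summary.csv").exists()
        assert (tmp_path / "map_demo.png").exists()
        hist = pd.read_csv(written["hist:demo"])
        assert hist["count"].sum() == truth_mask.count()

    def test_regeneration_identical(self, tiny_prepared, tiny_cfg, tmp_path):
        cv = ex.run_cv(tiny_prepared, "plsr", "entire", n_reps=1,
                       config=tiny_cfg, seed=1)
        a = tmp_path / "a"
        b = tmp_path / "b"
        ex.make_report({("plsr", "entire"): cv}, str(a))
        ex.make_report({("plsr", "entire"): cv}, str(b))
        assert (a / "summary.csv").read_bytes() == (b / "summary.csv").read_bytes()
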