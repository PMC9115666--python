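"""Evaluation orchestration: replicate-stratified splits, repeated 3-fold
cross-validation over the sparsity-parameter grid, model selection,
test-fold evaluation for both segmentation scenarios, and the
outlier-relocation experiment."""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import miace as miace_mod
from . import regress, segment, spice
from .core import (
    FeatureVector,
    InvalidParameterError,
    Mask,
    SampleRecord,
    SpectraMatrix,
)
from .preprocess import PreprocessConfig, preprocess_pipeline
from .spice import SpiceParams

__all__ = [
    "GAMMA_GRID",
    "METHODS",
    "SCENARIOS",
    "ExperimentConfig",
    "SplitPlan",
    "CVResult",
    "PreparedSample",
    "PreparedDataset",
    "prepare_sample",
    "prepare_dataset",
    "split_folds",
    "run_cv",
    "select_model",
    "outlier_experiment",
    "make_report",
]

log = logging.getLogger(__name__)

GAMMA_GRID: Tuple[int, ...] = tuple(range(10, 151, 10))
METHODS = ("spice+mlr", "miace+mlr", "plsr")
SCENARIOS = ("entire", "florets")


@dataclass(frozen=True)
class ExperimentConfig:
    downsample_budget: int = 5000
    close_radius: int = 2
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    spice_m0: int = 20
    spice_mu: float = 1e-4
    spice_tol: float = 1e-4
    spice_max_iter: int = 300
    max_fit_spectra: int = 2000
    miace_threshold: float = 50.0
    plsr_components: Optional[int] = None  # None -> inner CV
    n_folds: int = 3
    seed: int = 0


@dataclass
class SplitPlan:
    """Replicate-stratified partition into equally sized groups."""

    groups: List[List[str]]
    test_index: int
    seed: int

    @property
    def test_ids(self) -> List[str]:
        return list(self.groups[self.test_index])

    @property
    def trainval_ids(self) -> List[str]:
        out = []
        for i, grp in enumerate(self.groups):
            if i != self.test_index:
                out.extend(grp)
        return out


@dataclass
class CVResult:
    """Per-fit log rows plus aggregation helpers."""

    rows: List[dict] = field(default_factory=list)
    method: str = ""
    scenario: str = ""

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def summary(self) -> pd.DataFrame:
        f = self.frame()
        if f.empty:
            return f
        agg = f.groupby("gamma", dropna=False).agg(
            val_rmse_mean=("val_rmse", "mean"),
            val_rmse_sd=("val_rmse", "std"),
            val_r2_mean=("val_r2", "mean"),
            test_rmse_mean=("test_rmse", "mean"),
            test_rmse_sd=("test_rmse", "std"),
            test_r2_mean=("test_r2", "mean"),
            m_mean=("m", "mean"),
            n_fits=("val_rmse", "size"),
        )
        return agg.reset_index()

    def per_repetition(self, gamma=None) -> pd.DataFrame:
        f = self.frame()
        if gamma is not None:
            f = f[f["gamma"] == gamma]
        return f.groupby("rep").agg(
            val_rmse=("val_rmse", "mean"),
            val_r2=("val_r2", "mean"),
            test_rmse=("test_rmse", "mean"),
            test_r2=("test_r2", "mean"),
        ).reset_index()


@dataclass
class PreparedSample:
    """Everything downstream stages need for one sample."""

    record: SampleRecord
    spectra: Dict[str, SpectraMatrix]       # scenario -> down-sampled spectra
    mean_spectrum: Dict[str, np.ndarray]    # scenario -> mean preprocessed spectrum
    masks: Dict[str, Mask] = field(default_factory=dict)


@dataclass
class PreparedDataset:
    samples: Dict[str, PreparedSample]
    records: List[SampleRecord]

    def record_map(self) -> Dict[str, SampleRecord]:
        return {r.sample_id: r for r in self.records}


def prepare_sample(record: SampleRecord, raw, white, dark,
                   config: ExperimentConfig,
                   truth=None) -> PreparedSample:
    """Preprocess, segment and down-sample one sample.

    Foreground comes from 2-means plus morphological closing. The floret
    region comes from the seeded min-cut when ground truth provides seed
    locations, otherwise it falls back to the foreground (entire-sample
    scenario only).
    """
    cube, spectra = preprocess_pipeline(raw=raw, white=white, dark=dark,
                                        config=config.preprocess)
    fg = segment.kmeans_foreground(spectra, seed=config.seed)
    fg = segment.morphological_close(fg, radius=config.close_radius)
    masks = {"entire": fg}
    if truth is not None:
        floret_truth = truth.floret_mask.values.astype(bool)
        combined = fg.values.astype(bool) & floret_truth
        if combined.any():
            masks["florets"] = Mask(values=combined.astype(np.uint8),
                                    role="floret")
    if "florets" not in masks:
        masks["florets"] = Mask(values=fg.values.copy(), role="floret")

    out_spectra, out_means = {}, {}
    for scenario, mask in masks.items():
        sel = cube.to_spectra(mask=mask)
        from .preprocess import l2_normalize

        sel = l2_normalize(sel)
        down = segment.downsample_spectra(sel, budget=config.downsample_budget,
                                          seed=config.seed)
        out_spectra[scenario] = down
        out_means[scenario] = sel.values.mean(axis=0)
    return PreparedSample(record=record, spectra=out_spectra,
                          mean_spectrum=out_means, masks=masks)


def prepare_dataset(records: Sequence[SampleRecord], params,
                    config: Optional[ExperimentConfig] = None,
                    endmembers=None) -> PreparedDataset:
    """Render and prepare every sample of a synthetic design."""
    from .scene_sim import make_endmember_library, render_cube

    cfg = config or ExperimentConfig()
    endmembers = endmembers or make_endmember_library(params.grid(), params)
    samples = {}
    for record in records:
        raw, white, dark, truth = render_cube(record, params, endmembers)
        samples[record.sample_id] = prepare_sample(record, raw, white, dark,
                                                   cfg, truth=truth)
    return PreparedDataset(samples=samples, records=list(records))


def split_folds(design: Sequence[SampleRecord], seed: int = 0,
                test_index: Optional[int] = None) -> SplitPlan:
    """Assign one replicate per condition to each of n_replicate groups."""
    by_condition: Dict[tuple, List[SampleRecord]] = {}
    for r in design:
        by_condition.setdefault(r.condition, []).append(r)
    sizes = {len(v) for v in by_condition.values()}
    if len(sizes) != 1:
        raise InvalidParameterError(
            "unbalanced design: conditions have differing replicate counts"
        )
    n_groups = sizes.pop()
    rng = np.random.default_rng([seed, 7])
    groups: List[List[str]] = [[] for _ in range(n_groups)]
    for condition in sorted(by_condition):
        members = sorted(by_condition[condition], key=lambda r: r.replicate)
        perm = rng.permutation(n_groups)
        for g, member in zip(perm, members):
            groups[g].append(member.sample_id)
    if test_index is None:
        test_index = int(rng.integers(n_groups))
    return SplitPlan(groups=groups, test_index=test_index, seed=seed)


def _stratified_folds(records: Sequence[SampleRecord], n_folds: int,
                      rng: np.random.Generator) -> List[List[str]]:
    by_condition: Dict[tuple, List[SampleRecord]] = {}
    for r in records:
        by_condition.setdefault(r.condition, []).append(r)
    folds: List[List[str]] = [[] for _ in range(n_folds)]
    for condition in sorted(by_condition):
        members = sorted(by_condition[condition], key=lambda r: r.replicate)
        perm = rng.permutation(len(members))
        for pos, member_idx in enumerate(perm):
            folds[pos % n_folds].append(members[member_idx].sample_id)
    return folds


def _spice_features(prepared: PreparedDataset, train_ids, scenario, gamma,
                    config: ExperimentConfig, seed: int):
    rng = np.random.default_rng([seed, 13])
    pooled = np.vstack([prepared.samples[sid].spectra[scenario].values
                        for sid in train_ids])
    if pooled.shape[0] > config.max_fit_spectra:
        pick = rng.choice(pooled.shape[0], size=config.max_fit_spectra,
                          replace=False)
        pooled = pooled[pick]
    grid = next(iter(prepared.samples.values())).spectra[scenario].grid
    pooled_sm = SpectraMatrix(values=pooled, grid=grid)
    params = SpiceParams(gamma=gamma, m0=min(config.spice_m0,
                                             pooled.shape[0] - 1),
                         mu=config.spice_mu, tol=config.spice_tol,
                         max_iter=config.spice_max_iter, seed=seed)
    fit = spice.spice_fit(pooled_sm, params)

    m = fit.endmembers.n_endmembers

    def extract(sid: str) -> FeatureVector:
        sm = prepared.samples[sid].spectra[scenario]
        ab = spice.solve_abundances(sm, fit.endmembers)  # test-time FCLS
        feat = spice.abundance_feature(ab, sample_id=sid)
        if m >= 2:
            # abundances sum to one, so the last column is redundant in a
            # regression with intercept; drop it to keep the design full rank
            feat = FeatureVector(values=feat.values[:-1], sample_id=sid)
        return feat

    return extract, m


def _miace_features(prepared: PreparedDataset, train_ids, scenario,
                    config: ExperimentConfig, seed: int):
    samples = [(prepared.samples[sid].spectra[scenario],
                prepared.samples[sid].record.glucosinolate)
               for sid in train_ids]
    bags = miace_mod.make_bags(samples, threshold=config.miace_threshold,
                               sample_ids=list(train_ids))
    sig, whiten = miace_mod.miace_fit(
        bags, miace_mod.MiaceParams(threshold=config.miace_threshold,
                                    seed=seed))

    def extract(sid: str) -> FeatureVector:
        sm = prepared.samples[sid].spectra[scenario]
        return miace_mod.confidence_feature(sm, sig, whiten, sample_id=sid)

    return extract, 1


def run_cv(prepared: PreparedDataset, method: str, scenario: str = "entire",
           gamma_grid: Optional[Sequence[float]] = None, n_reps: int = 10,
           config: Optional[ExperimentConfig] = None,
           plan: Optional[SplitPlan] = None,
           seed: Optional[int] = None) -> CVResult:
    """Repeated stratified 3-fold cross-validation with a fixed test group.

    The test group never enters feature extraction or regression fits; the
    training/validation samples are reshuffled into folds every repetition.
    """
    if method not in METHODS:
        raise InvalidParameterError(f"unknown method '{method}'")
    if scenario not in SCENARIOS:
        raise InvalidParameterError(f"unknown scenario '{scenario}'")
    cfg = config or ExperimentConfig()
    seed = cfg.seed if seed is None else seed
    plan = plan or split_folds(prepared.records, seed=seed)
    record_map = prepared.record_map()
    test_ids = plan.test_ids
    trainval = [record_map[sid] for sid in plan.trainval_ids]
    if len(plan.groups) - 1 < cfg.n_folds:
        raise InvalidParameterError(
            f"need at least {cfg.n_folds} non-test groups, "
            f"got {len(plan.groups) - 1}"
        )
    gammas = list(gamma_grid) if (gamma_grid is not None) else (
        list(GAMMA_GRID) if method == "spice+mlr" else [None])
    if method != "spice+mlr":
        gammas = [None]

    result = CVResult(method=method, scenario=scenario)
    for rep in range(n_reps):
        rng = np.random.default_rng([seed, 1000 + rep])
        folds = _stratified_folds(trainval, cfg.n_folds, rng)
        for fold_i in range(cfg.n_folds):
            val_ids = folds[fold_i]
            train_ids = [sid for j, f in enumerate(folds) if j != fold_i
                         for sid in f]
            y_train = np.array([record_map[s].glucosinolate for s in train_ids])
            y_val = np.array([record_map[s].glucosinolate for s in val_ids])
            y_test = np.array([record_map[s].glucosinolate for s in test_ids])
            for gamma in gammas:
                fit_seed = int(np.random.default_rng(
                    [seed, rep, fold_i]).integers(2 ** 31))
                try:
                    row = _one_fit(prepared, method, scenario, gamma, cfg,
                                   fit_seed, train_ids, val_ids, test_ids,
                                   y_train, y_val, y_test)
                except ValueError as exc:
                    log.warning("fit failed (rep %d fold %d gamma %s): %s",
                                rep, fold_i, gamma, exc)
                    continue
                row.update({"rep": rep, "fold": fold_i, "gamma": gamma,
                            "method": method, "scenario": scenario,
                            "train_ids": tuple(train_ids),
                            "val_ids": tuple(val_ids)})
                result.rows.append(row)
    return result


def _one_fit(prepared, method, scenario, gamma, cfg, fit_seed,
             train_ids, val_ids, test_ids, y_train, y_val, y_test) -> dict:
    if method == "plsr":
        x = {sid: prepared.samples[sid].mean_spectrum[scenario]
             for sid in (*train_ids, *val_ids, *test_ids)}
        fit = regress.fit_plsr(np.vstack([x[s] for s in train_ids]), y_train,
                               n_components=cfg.plsr_components, seed=fit_seed)
        pred_val = regress.predict(fit, np.vstack([x[s] for s in val_ids]))
        pred_test = regress.predict(fit, np.vstack([x[s] for s in test_ids]))
        m = fit.n_components
    else:
        if method == "spice+mlr":
            extract, m = _spice_features(prepared, train_ids, scenario,
                                         gamma, cfg, fit_seed)
        else:
            extract, m = _miace_features(prepared, train_ids, scenario, cfg,
                                         fit_seed)
        feats = {sid: extract(sid)
                 for sid in (*train_ids, *val_ids, *test_ids)}
        fit = regress.fit_mlr([feats[s] for s in train_ids], y_train)
        pred_val = regress.predict(fit, [feats[s] for s in val_ids])
        pred_test = regress.predict(fit, [feats[s] for s in test_ids])
    val_rmse, val_r2 = regress.evaluate(
        regress.PredictionResult(measured=y_val, predicted=pred_val))
    test_rmse, test_r2 = regress.evaluate(
        regress.PredictionResult(measured=y_test, predicted=pred_test))
    return {"train_rmse": fit.rmse, "train_r2": fit.r2,
            "val_rmse": val_rmse, "val_r2": val_r2, "test_rmse": test_rmse,
            "test_r2": test_r2, "m": m,
            "f_statistic": fit.f_statistic, "p_value": fit.p_value}


def select_model(cv: CVResult) -> dict:
    """Pick the candidate with the lowest mean validation RMSE.

    Ties break by higher validation R-squared, then smaller retained M,
    then smaller gamma.
    """
    summary = cv.summary()
    if summary.empty:
        raise InvalidParameterError("empty CV result")
    summary = summary.copy()
    gamma_key = summary["gamma"].fillna(np.inf)
    order = summary.assign(_g=gamma_key).sort_values(
        by=["val_rmse_mean", "val_r2_mean", "m_mean", "_g"],
        ascending=[True, False, True, True],
        kind="mergesort",
    )
    best = order.iloc[0]
    gamma = best["gamma"]
    return {
        "method": cv.method,
        "scenario": cv.scenario,
        "gamma": None if pd.isna(gamma) else float(gamma),
        "val_rmse": float(best["val_rmse_mean"]),
        "val_r2": float(best["val_r2_mean"]),
        "test_rmse": float(best["test_rmse_mean"]),
        "test_r2": float(best["test_r2_mean"]),
        "m": float(best["m_mean"]),
    }


def outlier_experiment(prepared: PreparedDataset, outlier_ids: Sequence[str],
                       method: str = "spice+mlr", scenario: str = "entire",
                       gamma_grid: Optional[Sequence[float]] = None,
                       n_reps: int = 10,
                       config: Optional[ExperimentConfig] = None,
                       seed: int = 0) -> Dict[str, CVResult]:
    """Baseline CV versus CV with the listed samples forced into the test
    group (swapped with the test group's same-condition members)."""
    record_map = prepared.record_map()
    unknown = [sid for sid in outlier_ids if sid not in record_map]
    if unknown:
        raise InvalidParameterError(f"unknown outlier ids: {unknown}")
    plan = split_folds(prepared.records, seed=seed)
    baseline = run_cv(prepared, method, scenario, gamma_grid=gamma_grid,
                      n_reps=n_reps, config=config, plan=plan, seed=seed)

    conditions_seen = {}
    for sid in outlier_ids:
        cond = record_map[sid].condition
        if cond in conditions_seen:
            raise InvalidParameterError(
                "outliers exceed test-group capacity: two outliers share "
                f"condition {cond}"
            )
        conditions_seen[cond] = sid
    groups = [list(g) for g in plan.groups]
    test_group = groups[plan.test_index]
    for cond, sid in conditions_seen.items():
        if sid in test_group:
            continue
        # the test group holds exactly one member per condition: swap it out
        partner = next(s for s in test_group if record_map[s].condition == cond)
        src = next(i for i, g in enumerate(groups) if sid in g)
        groups[src][groups[src].index(sid)] = partner
        test_group[test_group.index(partner)] = sid
    moved_plan = SplitPlan(groups=groups, test_index=plan.test_index,
                           seed=plan.seed)
    moved = run_cv(prepared, method, scenario, gamma_grid=gamma_grid,
                   n_reps=n_reps, config=config, plan=moved_plan, seed=seed)
    return {"baseline": baseline, "moved": moved,
            "baseline_plan": plan, "moved_plan": moved_plan}


def make_report(cv_results: Dict[Tuple[str, str], CVResult], out_dir: str,
                maps: Optional[Dict[str, Tuple[np.ndarray, Mask]]] = None,
                signatures: Optional[pd.DataFrame] = None) -> Dict[str, str]:
    """Write summary CSVs (and optional map PNGs / signature tables)."""
    from . import cube_io

    os.makedirs(out_dir, exist_ok=True)
    written = {}
    rows = []
    for (method, scenario), cv in cv_results.items():
        chosen = select_model(cv)
        rows.append({"method": method, "scenario": scenario, **{
            k: v for k, v in chosen.items() if k not in ("method", "scenario")
        }})
        detail = cv.frame().drop(columns=["train_ids", "val_ids"],
                                 errors="ignore")
        path = os.path.join(out_dir, f"cv_{method.replace('+', '_')}_{scenario}.csv")
        detail.to_csv(path, index=False)
        written[f"cv:{method}:{scenario}"] = path
    summary_path = os.path.join(out_dir, "summary.csv")
    pd.DataFrame(rows).to_csv(summary_path, index=False)
    written["summary"] = summary_path
    if maps:
        for name, (values, mask) in maps.items():
            path = os.path.join(out_dir, f"map_{name}.png")
            cube_io.export_map(np.clip(values, 0.0, 1.0), mask, path)
            written[f"map:{name}"] = path
            hist, edges = np.histogram(values[mask.values.astype(bool)],
                                       bins=20, range=(0.0, 1.0))
            hist_path = os.path.join(out_dir, f"hist_{name}.csv")
            pd.DataFrame({"bin_lo": edges[:-1], "bin_hi": edges[1:],
                          "count": hist}).to_csv(hist_path, index=False)
            written[f"hist:{name}"] = hist_path
    if signatures is not None:
        sig_path = os.path.join(out_dir, "signatures.csv")
        signatures.to_csv(sig_path, index=False)
        written["signatures"] = sig_path
    return written
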