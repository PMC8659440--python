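"""End-to-end experiment: simulate -> pretreat -> select -> model -> map.

Mirrors the workflow of a stacked-fermentation calibration study: a
pretreatment comparison (full-spectrum PLS ranked by Rp) feeds the winning
pretreatment into per-component wavelength selection, PCA compression and
PLS/ELM/SVR calibration, evaluated with Rc/RMSECV/Rp/RMSEP/RPD; finally a
pixel-wise content map is rendered per fermentation level.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import preprocessing as pp
from . import regression as reg
from . import selection as sel
from . import synthetic as syn
from .mapping import background_mask, denoise_cube, predict_map, render_map
from .synthetic import ConfigurationError, MONOMERS, ParameterError

log = logging.getLogger(__name__)

DEFAULT_SELECTOR_MAP = {
    "total": "spa", "egc": "vcpa-ga", "ecg": "vcpa-ga",
    "c": "vcpa-iriv", "ec": "vcpa-iriv", "egcg": "vcpa-iriv",
}

#: Desk-scale search budgets; module-level algorithm defaults are larger.
DEFAULT_SELECTOR_PARAMS = {
    "spa": {"kmin": 6, "kmax": 16},
    "sfla": {"memeplexes": 5, "frogs_per": 10, "iterations": 30},
    "vcpa": {"n_bms": 150, "edf_loops": 6, "final_size": 40},
    "ga": {"population": 24, "generations": 30},
    "iriv": {"n_draws": 60, "max_rounds": 5},
}


@dataclass
class ExperimentConfig:
    """Complete, YAML-serialisable description of one experiment run."""

    seed: int = 0
    grid_start_nm: float = 400.0
    grid_end_nm: float = 960.0
    grid_bands: int = 401
    replicates: int = 10
    noise: dict = field(default_factory=dict)        # NoiseModel overrides
    nonlinearity: float = 0.0
    use_absorbance: bool = True
    pretreatments: list = field(default_factory=lambda: list(pp.ALL_METHODS))
    components: list = field(default_factory=lambda: list(syn.COMPONENTS))
    selector_map: dict = field(default_factory=lambda: dict(DEFAULT_SELECTOR_MAP))
    selector_params: dict = field(default_factory=lambda:
                                  {k: dict(v) for k, v in DEFAULT_SELECTOR_PARAMS.items()})
    models: list = field(default_factory=lambda: ["pls", "elm", "svr"])
    cal_fraction: float = 0.75
    rmsecv_folds: int = 10
    fitness_folds: int = 5
    max_pcs: int = 15
    # desk-scale tuning grids (octave steps); regression.default_*_grid()
    # provides the dense half-octave grids for a full search
    svr_c_grid: list = field(default_factory=lambda:
                             [float(2.0 ** k) for k in range(-2, 11)])
    svr_g_grid: list = field(default_factory=lambda:
                             [float(2.0 ** k) for k in range(-7, 2)])
    make_maps: bool = True
    map_size: int = 48
    map_component: str = "total"
    output_dir: str = "teaspec_run"

    def validate(self) -> None:
        if not self.models:
            raise ConfigurationError("model list is empty")
        unknown = set(self.models) - {"pls", "elm", "svr"}
        if unknown:
            raise ConfigurationError(f"unknown model(s) {sorted(unknown)}")
        for comp in self.components:
            if comp not in syn.COMPONENTS:
                raise ConfigurationError(f"unknown component {comp!r}")
            algo = self.selector_map.get(comp)
            if algo not in ("spa", "sfla", "vcpa", "vcpa-ga", "vcpa-iriv"):
                raise ConfigurationError(
                    f"component {comp!r} has no valid selector (got {algo!r})")
        if len(self.pretreatments) < 2:
            raise ConfigurationError("need at least 2 pretreatments to compare")
        if not 0 < self.cal_fraction < 1:
            raise ConfigurationError("cal_fraction must lie in (0, 1)")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ExperimentReport:
    """Pretreatment-comparison and model tables plus run provenance."""

    pretreatment_rows: pd.DataFrame
    model_rows: pd.DataFrame
    selections: dict
    provenance: dict


# ---------------------------------------------------------------------------
# Pretreatment comparison (full-spectrum PLS ranked by Rp)
# ---------------------------------------------------------------------------

def _pls_lv_by_rmsecv(X, y, folds, seed, cap):
    test_sets = sel._cv_folds(len(y), folds, seed)
    best = (np.inf, 1)
    cap = min(cap, X.shape[1], len(y) - max(len(t) for t in test_sets) - 1)
    for lv in range(1, max(cap, 1) + 1):
        rmse = sel._pls_cv_rmse(X, y, test_sets, max_components=lv)
        if rmse < best[0] - 1e-15:
            best = (rmse, lv)
    return best[1], best[0]


def compare_pretreatments(spectra: syn.SpectraSet, chem: syn.ChemTable,
                          component: str, split: sel.CalSplit,
                          folds: int = 5, chains=None, seed: int = 0,
                          max_lv: int = 10, use_absorbance: bool = True
                          ) -> pd.DataFrame:
    """Fit a full-spectrum PLS per pretreatment and rank by prediction-set Rp.

    A failing pretreatment is marked failed and the comparison continues.
    The returned frame has one row per method with PCs/Rc/RMSECV/Rp/RMSEP and
    a ``selected`` flag on the Rp argmax.
    """
    chains = chains if chains is not None else pp.standard_chains(
        to_absorbance=use_absorbance)
    if len(chains) < 2:
        raise ParameterError("need at least 2 pretreatments to compare")
    y_all = spectra.meta.merge(chem.data, on="sample_id", how="left",
                               suffixes=("", "_chem"))[component].to_numpy(float)
    cal_set = spectra.subset_rows(split.calibration)
    pred_set = spectra.subset_rows(split.prediction)
    ycal, ypred = y_all[split.calibration], y_all[split.prediction]
    rows = []
    for chain in chains:
        try:
            chain.fit(cal_set)
            Xc = chain.transform(cal_set).values
            Xp = chain.transform(pred_set).values
            lv, rmsecv = _pls_lv_by_rmsecv(Xc, ycal, folds, seed, max_lv)
            model = reg.pls_train(Xc, ycal, lv)
            ev = reg.evaluate_model(model, Xc, ycal, Xp, ypred,
                                    component=component, method=chain.method,
                                    n_variables=Xc.shape[1], pcs=lv,
                                    rmsecv=rmsecv)
            rows.append({"method": chain.method, "pcs": lv, "rc": ev.rc,
                         "rmsecv": rmsecv, "rp": ev.rp, "rmsep": ev.rmsep,
                         "failed": False})
        except Exception as exc:  # a broken pretreatment must not stop the run
            log.warning("pretreatment %s failed for %s: %s",
                        chain.method, component, exc)
            rows.append({"method": chain.method, "pcs": 0, "rc": np.nan,
                         "rmsecv": np.nan, "rp": -np.inf, "rmsep": np.nan,
                         "failed": True})
    df = pd.DataFrame(rows)
    df["selected"] = df["rp"] == df["rp"].max()
    # break exact ties deterministically: first method wins
    first = df.index[df["selected"]][0]
    df["selected"] = df.index == first
    df["rp"] = df["rp"].replace(-np.inf, np.nan)
    return df


# ---------------------------------------------------------------------------
# Selection dispatch
# ---------------------------------------------------------------------------

def _run_selector(algo: str, Xcal, ycal, grid, seed: int, params: dict,
                  fitness_folds: int) -> sel.SelectionResult:
    fitness = sel.SubsetFitness(Xcal, ycal, folds=fitness_folds, seed=seed)
    if algo == "spa":
        return sel.spa_select(Xcal, ycal, grid=grid, seed=seed,
                              folds=fitness_folds, **params.get("spa", {}))
    if algo == "sfla":
        return sel.sfla_select(Xcal, ycal, fitness, grid=grid, seed=seed,
                               **params.get("sfla", {}))
    vcpa = sel.vcpa_select(Xcal, ycal, fitness, grid=grid, seed=seed,
                           **params.get("vcpa", {}))
    if algo == "vcpa":
        return vcpa
    mode = "GA" if algo == "vcpa-ga" else "IRIV"
    refine_params = params.get("ga" if mode == "GA" else "iriv", {})
    return sel.refine_subset(Xcal, ycal, vcpa, mode, fitness,
                             refine_params, seed=seed, grid=grid)


# ---------------------------------------------------------------------------
# Full experiment
# ---------------------------------------------------------------------------

def run_experiment(cfg: ExperimentConfig) -> ExperimentReport:
    """Run the full pipeline deterministically from a config.

    Writes report_pretreatment.csv, report_models.csv, selection JSONs,
    content maps and run.log under ``cfg.output_dir``.  Prediction-set
    responses are only read at evaluation time; every model and statistic is
    fit on the calibration rows alone.
    """
    cfg.validate()
    os.makedirs(cfg.output_dir, exist_ok=True)
    handler = logging.FileHandler(os.path.join(cfg.output_dir, "run.log"), mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("teaspec")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    t_start = time.time()
    try:
        return _run_experiment(cfg, t_start)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run_experiment(cfg: ExperimentConfig, t_start: float) -> ExperimentReport:
    grid = syn.make_wavelength_grid(cfg.grid_start_nm, cfg.grid_end_nm,
                                    cfg.grid_bands)
    lib = syn.default_library(grid)
    noise = syn.NoiseModel(**{"seed": cfg.seed, **cfg.noise})
    chem = syn.simulate_kinetics()
    spectra = syn.simulate_spectra(chem, lib, noise, cfg.replicates,
                                   nonlinearity=cfg.nonlinearity)
    log.info("simulated %d spectra on %d bands (%.1fs)", spectra.n_samples,
             len(grid), time.time() - t_start)

    base = spectra.to_absorbance() if cfg.use_absorbance else spectra
    split = sel.kennard_stone(base.values, cfg.cal_fraction)
    y_table = spectra.meta.merge(chem.data, on="sample_id", how="left",
                                 suffixes=("", "_chem"))

    pretreat_rows, model_rows, selections = [], [], {}
    for component in cfg.components:
        t0 = time.time()
        y_all = y_table[component].to_numpy(float)
        ycal, ypred = y_all[split.calibration], y_all[split.prediction]

        chains = pp.standard_chains(cfg.pretreatments,
                                    to_absorbance=cfg.use_absorbance)
        cmp_df = compare_pretreatments(spectra, chem, component, split,
                                       folds=cfg.fitness_folds, chains=chains,
                                       seed=cfg.seed,
                                       use_absorbance=cfg.use_absorbance)
        cmp_df.insert(0, "component", component)
        pretreat_rows.append(cmp_df)
        winner = cmp_df.loc[cmp_df["selected"], "method"].iloc[0]
        chain = next(c for c in chains if c.method == winner)
        cal_set = spectra.subset_rows(split.calibration)
        chain.fit(cal_set)
        Xcal = chain.transform(cal_set).values
        Xpred = chain.transform(spectra.subset_rows(split.prediction)).values

        algo = cfg.selector_map[component]
        result = _run_selector(algo, Xcal, ycal, grid, cfg.seed,
                               cfg.selector_params, cfg.fitness_folds)
        selections[component] = {"result": result, "chain": chain,
                                 "pretreatment": winner}
        result.to_json(os.path.join(cfg.output_dir,
                                    f"selection_{component}.json"))
        log.info("%s: pretreatment=%s selector=%s bands=%d reduction=%.4f "
                 "(%.1fs)", component, winner, result.algorithm,
                 result.indices.size, result.data_reduction_ratio,
                 time.time() - t0)

        max_pcs = min(cfg.max_pcs, result.indices.size,
                      split.calibration.size - 1)
        cal_scores, pred_scores, pca = reg.pca_reduce(
            Xcal, Xpred, result.indices, max_pcs)
        selections[component]["pca"] = pca

        best = (-np.inf, None, None)
        for kind in cfg.models:
            kw = {}
            if kind == "svr":
                kw = {"c": 4.0, "g": 0.5}
            pcs, rmsecv = reg.choose_pcs_by_rmsecv(
                cal_scores, ycal, kind, folds=cfg.rmsecv_folds,
                seed=cfg.seed, **kw)
            Xc, Xp = cal_scores[:, :pcs], pred_scores[:, :pcs]
            if kind == "pls":
                model = reg.pls_train(Xc, ycal, n_lv=pcs)
            elif kind == "elm":
                model = reg.elm_train(Xc, ycal, seed=cfg.seed)
            else:
                model, c, g = reg.svr_train_tuned(
                    Xc, ycal, cfg.svr_c_grid, cfg.svr_g_grid,
                    folds=cfg.fitness_folds, seed=cfg.seed)
                log.info("%s SVR tuned: c=%.4g g=%.4g", component, c, g)
            ev = reg.evaluate_model(
                model, Xc, ycal, Xp, ypred, component=component,
                method=f"{result.algorithm}-{kind.upper()}",
                n_variables=result.indices.size, pcs=pcs, rmsecv=rmsecv)
            row = ev.as_row()
            row["pretreatment"] = winner
            row["data_reduction_ratio"] = result.data_reduction_ratio
            model_rows.append(row)
            if ev.rp > best[0]:
                best = (ev.rp, kind, (model, pcs))
        selections[component]["best_model"] = best

    pre_df = pd.concat(pretreat_rows, ignore_index=True)
    mod_df = pd.DataFrame(model_rows)
    pre_df.to_csv(os.path.join(cfg.output_dir, "report_pretreatment.csv"),
                  index=False, float_format="%.6g")
    mod_df.to_csv(os.path.join(cfg.output_dir, "report_models.csv"),
                  index=False, float_format="%.6g")

    if cfg.make_maps:
        _render_stage_maps(cfg, chem, lib, noise, selections)

    provenance = {"seed": cfg.seed, "config_digest": cfg.digest(),
                  "n_spectra": int(spectra.n_samples),
                  "n_calibration": int(split.calibration.size),
                  "n_prediction": int(split.prediction.size),
                  "quantity": "absorbance" if cfg.use_absorbance else "reflectance",
                  "runtime_s": round(time.time() - t_start, 2)}
    with open(os.path.join(cfg.output_dir, "provenance.json"), "w") as fh:
        json.dump(provenance, fh, indent=1, sort_keys=True)
    return ExperimentReport(pre_df, mod_df, selections, provenance)


#: Fermentation levels for the visual analysis: mild (2 h), moderate (4 h),
#: excessive (5 h), sampled from the lower layer.
MAP_STAGES = (("mild", 2.0), ("moderate", 4.0), ("excessive", 5.0))


def _render_stage_maps(cfg, chem, lib, noise, selections):
    component = cfg.map_component
    if component not in selections:
        log.warning("no trained model for map component %r", component)
        return
    bundle = selections[component]
    _, kind, (model, pcs) = bundle["best_model"]
    maps_dir = os.path.join(cfg.output_dir, "maps")
    os.makedirs(maps_dir, exist_ok=True)
    for stage, t in MAP_STAGES:
        row = chem.data[(chem.data.time_h == t) & (chem.data.layer == "lower")]
        if row.empty:
            continue
        cube, _truth = syn.simulate_cube(row.iloc[0], lib, noise,
                                         cfg.map_size, cfg.map_size,
                                         nonlinearity=cfg.nonlinearity)
        mask = background_mask(cube)
        cube = denoise_cube(cube, mask)
        pmap = predict_map(cube, mask, bundle["chain"], bundle["result"],
                           bundle["pca"], model, component=component,
                           n_pcs=pcs)
        render_map(pmap, os.path.join(maps_dir, f"{component}_{stage}.png"),
                   annotated_path=os.path.join(
                       maps_dir, f"{component}_{stage}_annotated.png"))
        log.info("map %s (%s, %g h): model=%s pcs=%d", component, stage, t,
                 kind, pcs)
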