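"""Configuration-driven orchestration of the full study workflow.

``run_experiment`` executes: simulate -> preprocess -> Kennard-Stone split
-> per-modality calibration -> the three fusion strategies -> PDS
calibration transfer of the coarse-mesh NIR onto the reference mesh -> a
structured report (the analogue of the study's results table).  Every
stochastic step derives from the single config seed, so a fixed config
yields a byte-identical report.
"""

from __future__ import annotations

import copy
import json
import logging
import time
from pathlib import Path

import numpy as np

from . import fusion as fus
from . import preprocess as pp
from .model import PLSCalibration, evaluate, fit_bpnn_baseline, fit_svm_baseline, kennard_stone_split
from .select import FeatureIndexSet, sipls_select, spa_select, uve_select, uve_spa_select
from .simulate import DesignConfig, SimulatedStudy, generate_dataset
from .spectra import SpectraSet, align_by_meta
from .transfer import PDSTransfer, WindowSpec, optimize_pds, select_standard_samples

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or unknown pipeline configuration."""


DEFAULT_CONFIG: dict = {
    "seed": None,  # required
    "design": {
        "n_concentrations": 21,
        "conc_min": 0.5,
        "conc_max": 20.0,
        "replicates": 3,
        "meshes": [80, 100, 120],
        # noise knobs default to the DesignConfig study conditions
        "noise_sd_frac": DesignConfig.noise_sd_frac,
        "scatter_sd": DesignConfig.scatter_sd,
        "baseline_jitter_frac": DesignConfig.baseline_jitter_frac,
        "aliquot_rel_sd": DesignConfig.aliquot_rel_sd,
        "interference_sd": DesignConfig.interference_sd,
        "matrix_covariate_sd": DesignConfig.matrix_covariate_sd,
    },
    "preprocess": {
        # study outcome: SG+SNV for NIR, MSC for MIR
        "nir": [["sg", {"window": 5, "polyorder": 3}], ["snv", {}]],
        "mir": [["msc", {}]],
    },
    "split": {"cal_fraction": 2.0 / 3.0},
    "features": {
        "method": "uve_spa",  # uve_spa | uve | spa | sipls | none
        "uve": {"n_lv": 6, "cutoff_factor": 1.0},
        # chain-length bounds bracketing the ~10-variable subsets this
        # selector typically lands on for adulterant quantification
        "spa": {"m_min": 5, "m_max": 15},
        "sipls": {"n_intervals": 20, "combo_size": 2},
    },
    "model": {"max_lv": 6, "cv_folds": 10},
    "baselines": False,  # also fit SVM / BPNN on the full-spectrum block
    "transfer": {
        "enabled": True,
        "widths": [3, 5, 7, 9, 11],
        "n_std_min": 1,
        "n_std_max": 17,
        "n_lv_local": 2,
        "optimize": True,
    },
    "output_dir": None,
}


def validate_config(cfg: dict) -> dict:
    """Merge a user config over the defaults, rejecting unknown keys."""

    def merge(defaults: dict, user: dict, path: str) -> dict:
        out = copy.deepcopy(defaults)
        for key, value in user.items():
            if key not in defaults:
                raise ConfigError(f"unknown config key {path + key!r}")
            if isinstance(defaults[key], dict) and isinstance(value, dict):
                out[key] = merge(defaults[key], value, path + key + ".")
            else:
                out[key] = copy.deepcopy(value)
        return out

    if not isinstance(cfg, dict):
        raise ConfigError("config must be a mapping")
    full = merge(DEFAULT_CONFIG, cfg, "")
    if full["seed"] is None:
        raise ConfigError("config requires an integer 'seed'")
    full["seed"] = int(full["seed"])
    if full["features"]["method"] not in ("uve_spa", "uve", "spa", "sipls", "none"):
        raise ConfigError(f"unknown feature method {full['features']['method']!r}")
    return full


def _design_from_config(cfg: dict) -> DesignConfig:
    d = cfg["design"]
    return DesignConfig(
        seed=cfg["seed"],
        concentrations=np.linspace(d["conc_min"], d["conc_max"],
                                   d["n_concentrations"]),
        replicates=d["replicates"],
        meshes=tuple(d["meshes"]),
        noise_sd_frac=d["noise_sd_frac"],
        scatter_sd=d["scatter_sd"],
        baseline_jitter_frac=d["baseline_jitter_frac"],
        aliquot_rel_sd=d["aliquot_rel_sd"],
        interference_sd=d["interference_sd"],
        matrix_covariate_sd=d["matrix_covariate_sd"],
    )


def _select_features(X: np.ndarray, y: np.ndarray, cfg: dict, seed: int,
                     modality: str) -> FeatureIndexSet | None:
    method = cfg["features"]["method"]
    if method == "none":
        return None
    uve_params = dict(cfg["features"]["uve"], seed=seed)
    spa_params = dict(cfg["features"]["spa"])
    if method == "uve_spa":
        return uve_spa_select(X, y, uve_params, spa_params, modality=modality)
    if method == "uve":
        return uve_select(X, y, modality=modality, **uve_params)
    if method == "spa":
        return spa_select(X, y, modality=modality, **spa_params)
    return sipls_select(X, y, modality=modality,
                        max_lv=cfg["model"]["max_lv"], **cfg["features"]["sipls"])


def _fit_eval(X_cal, y_cal, X_pred, y_pred, cfg):
    """Fit a PLS calibration and evaluate on the held-out block."""
    max_lv = min(cfg["model"]["max_lv"], X_cal.shape[1])
    res = PLSCalibration(X_cal, y_cal, max_lv=max_lv,
                         cv_folds=cfg["model"]["cv_folds"]).fit()
    report = evaluate(y_pred, res.predict(X_pred))
    return res, report


def _eval_dict(report) -> dict:
    return {"r2": round(float(report.r2), 10),
            "rmse": round(float(report.rmse), 10),
            "r2_cod": round(float(report.r2_cod), 10)}


def run_experiment(user_cfg: dict) -> dict:
    """Run the full study workflow for one configuration; return the report."""
    cfg = validate_config(user_cfg)
    seed = cfg["seed"]
    t0 = time.time()
    study = generate_dataset(_design_from_config(cfg))
    report: dict = {
        "config": _jsonable(cfg),
        "design": {
            "n_nir_samples_total": int(sum(s.n_samples for s in study.nir.values())),
            "n_mir_samples": int(study.mir.n_samples),
            "meshes": sorted(study.nir),
        },
        "results": {},
    }

    # ----- reference-mesh (master) workflow ---------------------------------
    master_mesh = max(study.nir)  # finest particle size
    nir_m, mir = align_by_meta(study.nir[master_mesh], study.mir)
    y_all = nir_m.concentrations
    split = kennard_stone_split(nir_m.absorbance, cfg["split"]["cal_fraction"])
    cal, pred = split.calibration_indices, split.prediction_indices
    report["split"] = {"n_calibration": int(cal.size), "n_prediction": int(pred.size)}
    y_cal, y_pred = y_all[cal], y_all[pred]

    nir_chain = pp.chain(_as_steps(cfg["preprocess"]["nir"]))
    mir_chain = pp.chain(_as_steps(cfg["preprocess"]["mir"]))
    nir_cal = nir_chain.fit(nir_m.take(cal))
    mir_cal = mir_chain.fit(mir.take(cal))
    nir_pred = nir_chain.apply(nir_m.take(pred))
    mir_pred = mir_chain.apply(mir.take(pred))

    # single-modality models at the reference mesh
    nir_model, nir_eval = _fit_eval(nir_cal.absorbance, y_cal,
                                    nir_pred.absorbance, y_pred, cfg)
    mir_model, mir_eval = _fit_eval(mir_cal.absorbance, y_cal,
                                    mir_pred.absorbance, y_pred, cfg)
    report["results"]["nir_single"] = dict(_eval_dict(nir_eval),
                                           n_lv=int(nir_model.n_lv))
    report["results"]["mir_single"] = dict(_eval_dict(mir_eval),
                                           n_lv=int(mir_model.n_lv))

    # single-NIR models at the coarser meshes (results-table analogue rows)
    for mesh in sorted(m for m in study.nir if m != master_mesh):
        s = study.nir[mesh]
        sp = kennard_stone_split(s.absorbance, cfg["split"]["cal_fraction"])
        ch = pp.chain(_as_steps(cfg["preprocess"]["nir"]))
        s_cal = ch.fit(s.take(sp.calibration_indices))
        s_pred = ch.apply(s.take(sp.prediction_indices))
        _, ev = _fit_eval(s_cal.absorbance, s.concentrations[sp.calibration_indices],
                          s_pred.absorbance, s.concentrations[sp.prediction_indices],
                          cfg)
        report["results"][f"nir_single_mesh{mesh}"] = _eval_dict(ev)

    # per-modality range normalization fitted on the calibration sets; both
    # fusion paths use it so the two instruments' scales meet without a jump
    norm_nir = pp.range_normalize_fit(nir_cal)
    norm_mir = pp.range_normalize_fit(mir_cal)

    # ----- full-spectrum fusion --------------------------------------------
    fused_cal = fus.fuse_full_spectrum(nir_cal, mir_cal, (norm_nir, norm_mir))
    fused_pred = fus.fuse_full_spectrum(nir_pred, mir_pred, (norm_nir, norm_mir))
    full_model, full_eval = _fit_eval(fused_cal, y_cal, fused_pred, y_pred, cfg)
    report["results"]["full_spectrum_fusion"] = dict(
        _eval_dict(full_eval), n_columns=int(fused_cal.shape[1]),
        n_lv=int(full_model.n_lv),
    )
    if cfg["baselines"]:
        svm = fit_svm_baseline(fused_cal, y_cal)
        report["results"]["full_spectrum_svm"] = _eval_dict(
            evaluate(y_pred, svm.predict(fused_pred)))
        bpnn = fit_bpnn_baseline(fused_cal, y_cal, seed=seed)
        report["results"]["full_spectrum_bpnn"] = _eval_dict(
            evaluate(y_pred, bpnn.predict(fused_pred)))

    # ----- feature-level fusion --------------------------------------------
    # selection and the fused model run on the range-normalized blocks so
    # neither modality dominates the fused regression by scale alone
    nir_cal_n = pp.range_normalize_apply(nir_cal, norm_nir)
    mir_cal_n = pp.range_normalize_apply(mir_cal, norm_mir)
    nir_pred_n = pp.range_normalize_apply(nir_pred, norm_nir)
    mir_pred_n = pp.range_normalize_apply(mir_pred, norm_mir)
    f_nir = _select_features(nir_cal_n.absorbance, y_cal, cfg, seed, "NIR")
    f_mir = _select_features(mir_cal_n.absorbance, y_cal, cfg, seed + 1, "MIR")
    feat_model = feat_eval = None
    if f_nir is not None and f_mir is not None:
        ff_cal = fus.fuse_feature_level(nir_cal_n, mir_cal_n, f_nir, f_mir)
        ff_pred = fus.fuse_feature_level(nir_pred_n, mir_pred_n, f_nir, f_mir)
        feat_model, feat_eval = _fit_eval(ff_cal, y_cal, ff_pred, y_pred, cfg)
        report["results"]["feature_level_fusion"] = dict(
            _eval_dict(feat_eval),
            n_nir_features=len(f_nir), n_mir_features=len(f_mir),
            n_lv=int(feat_model.n_lv),
        )
        report["features"] = {
            "nir": [int(i) for i in f_nir.indices],
            "mir": [int(i) for i in f_mir.indices],
            "method": cfg["features"]["method"],
        }

    # ----- decision-level fusion -------------------------------------------
    # criteria and the MLR combiner come from an internal 2:1 KS re-split of
    # the calibration set; the held-out prediction set is never touched
    inner = kennard_stone_split(nir_cal.absorbance, 2.0 / 3.0)
    itr, iva = inner.calibration_indices, inner.prediction_indices
    cols_nir = f_nir.indices if f_nir is not None else slice(None)
    cols_mir = f_mir.indices if f_mir is not None else slice(None)
    Xn, Xm = nir_cal_n.absorbance[:, cols_nir], mir_cal_n.absorbance[:, cols_mir]
    inner_nir, _ = _fit_eval(Xn[itr], y_cal[itr], Xn[iva], y_cal[iva], cfg)
    inner_mir, _ = _fit_eval(Xm[itr], y_cal[itr], Xm[iva], y_cal[iva], cfg)
    ev_n = evaluate(y_cal[iva], inner_nir.predict(Xn[iva]))
    ev_m = evaluate(y_cal[iva], inner_mir.predict(Xm[iva]))
    criteria = fus.CriteriaMatrix(
        values=np.array([[ev_n.r2, ev_n.rmse], [ev_m.r2, ev_m.rmse]]),
        benefit=(True, False),
    )
    weights = fus.entropy_topsis_weights(criteria)
    combiner = fus.fit_mlr_combiner(fus.PredictionSet(
        y_nir=inner_nir.predict(Xn[iva]), y_mir=inner_mir.predict(Xm[iva]),
        y_true=y_cal[iva],
    ))
    # final per-modality models on the full calibration set
    fin_nir, _ = _fit_eval(Xn, y_cal, Xn, y_cal, cfg)
    fin_mir, _ = _fit_eval(Xm, y_cal, Xm, y_cal, cfg)
    Xn_p = nir_pred_n.absorbance[:, cols_nir]
    Xm_p = mir_pred_n.absorbance[:, cols_mir]
    pset = fus.PredictionSet(y_nir=fin_nir.predict(Xn_p),
                             y_mir=fin_mir.predict(Xm_p), y_true=y_pred)
    report["results"]["decision_topsis"] = dict(
        _eval_dict(evaluate(y_pred, fus.combine_topsis(pset, weights))),
        weights={"n": round(weights.n, 10), "m": round(weights.m, 10)},
    )
    report["results"]["decision_mlr"] = dict(
        _eval_dict(evaluate(y_pred, fus.combine_mlr(pset, combiner))),
        coefficients={"b": round(combiner.b, 10), "k1": round(combiner.k1, 10),
                      "k2": round(combiner.k2, 10)},
    )

    # ----- PDS calibration transfer ----------------------------------------
    if cfg["transfer"]["enabled"] and feat_model is not None:
        report["transfer"] = {}
        tr = cfg["transfer"]

        def downstream(transferred: SpectraSet, y_val) -> float:
            """Score transferred slave NIR through the frozen fusion model."""
            pre = pp.range_normalize_apply(nir_chain.apply(transferred), norm_nir)
            a, b = align_by_meta(pre, mir_cal_n)
            block = fus.fuse_feature_level(a, b, f_nir, f_mir)
            resid = a.concentrations - feat_model.predict(block)
            return float(np.sqrt(np.mean(resid**2)))

        for mesh in sorted(m for m in study.nir if m != master_mesh):
            slave, _ = align_by_meta(study.nir[mesh], nir_m)
            # identical design -> alignment preserves the master row order
            slave_cal, slave_pred = slave.take(cal), slave.take(pred)
            entry: dict = {}
            if tr["optimize"]:
                search = optimize_pds(
                    nir_m.take(cal), slave_cal, y_cal, downstream,
                    widths=tuple(tr["widths"]),
                    n_std_range=range(tr["n_std_min"], tr["n_std_max"] + 1),
                    n_lv_local=tr["n_lv_local"],
                )
                width, n_std = search.best
                entry["grid"] = {
                    f"w{w}_s{s}": (None if not np.isfinite(v) else round(v, 10))
                    for (w, s), v in sorted(search.grid.items())
                }
            else:
                width, n_std = max(tr["widths"]), max(2, tr["n_std_min"])
            std_idx = select_standard_samples(nir_m.take(cal), n_std)
            t = PDSTransfer(
                nir_m.take(cal).take(std_idx), slave_cal.take(std_idx),
                WindowSpec.symmetric(width), tr["n_lv_local"],
            ).fit(standard_indices=std_idx)
            entry["window_width"] = int(width)
            entry["n_standards"] = int(n_std)
            entry["transferred"] = _eval_dict(_score_through_fusion(
                t.transform(slave_pred), nir_chain, norm_nir, mir_pred_n,
                f_nir, f_mir, feat_model))
            entry["untransferred"] = _eval_dict(_score_through_fusion(
                slave_pred, nir_chain, norm_nir, mir_pred_n, f_nir, f_mir,
                feat_model))
            report["transfer"][f"mesh{mesh}"] = entry

    logger.info("experiment finished in %.1f s", time.time() - t0)
    out_dir = cfg.get("output_dir")
    if out_dir:
        path = Path(out_dir)
        path.mkdir(parents=True, exist_ok=True)
        (path / "report.json").write_text(report_json(report))
        (path / "summary.txt").write_text(summarize(report))
    return report


def _score_through_fusion(slave_nir_raw: SpectraSet, nir_chain, norm_nir,
                          mir_pred_norm, f_nir, f_mir, feat_model):
    """Evaluate (possibly transferred) slave NIR through the frozen
    feature-level fusion model, fused with the unchanged reference-mesh MIR
    of the metadata-matched samples."""
    pre = pp.range_normalize_apply(nir_chain.apply(slave_nir_raw), norm_nir)
    a, b = align_by_meta(pre, mir_pred_norm)
    block = fus.fuse_feature_level(a, b, f_nir, f_mir)
    return evaluate(a.concentrations, feat_model.predict(block))


def _as_steps(spec_list) -> list[tuple[str, dict]]:
    steps = []
    for item in spec_list:
        if isinstance(item, str):
            steps.append((item, {}))
        else:
            name = item[0]
            params = item[1] if len(item) > 1 else {}
            steps.append((name, dict(params)))
    return steps


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj]
    return obj


def report_json(report: dict) -> str:
    """Canonical JSON serialization (sorted keys: byte-identical reruns)."""
    return json.dumps(_jsonable(report), indent=2, sort_keys=True)


def summarize(report: dict) -> str:
    """Human-readable results table."""
    lines = ["strategy                      R^2      RMSE", "-" * 46]
    for name, res in sorted(report.get("results", {}).items()):
        lines.append(f"{name:<28} {res['r2']:.4f}   {res['rmse']:.4f}")
    for mesh, entry in sorted(report.get("transfer", {}).items()):
        t, u = entry["transferred"], entry["untransferred"]
        lines.append(
            f"PDS {mesh} (w={entry['window_width']}, n={entry['n_standards']}): "
            f"R^2 {t['r2']:.4f} RMSE {t['rmse']:.4f} "
            f"(untransferred RMSE {u['rmse']:.4f})"
        )
    return "\n".join(lines) + "\n"
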