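"""End-to-end pipeline: simulate -> indices -> split/fit -> evaluate -> map.

Everything is driven by a :class:`PipelineConfig` that round-trips to
YAML; a SHA-256 hash of the canonical config is stamped into every
artifact so outputs are traceable to the exact configuration (and a
rerun with the same config is byte-identical).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .baselines import fit_ols, fit_pcr
from .errors import ParameterError
from .evaluation import (
    compare_models,
    correlation_matrix,
    render_markdown,
    score,
    split_samples,
    summary_table,
)
from .indices import VARIABLE_NAMES, build_variable_table, compute_index_grids
from .mapping import DEFAULT_BIN_EDGES, classify_gpc, export_map, predict_grid
from .pls import fit_pls, predict, press_curve, select_components, vip_scores
from .synthetic import SceneParams, generate_samples, generate_scene

logger = logging.getLogger(__name__)

#: the four indices identified as sensitive GPC predictors
DEFAULT_PREDICTORS = ("NDVI", "SIPI", "PSRI", "EVI")


@dataclass
class PipelineConfig:
    predictors: tuple = DEFAULT_PREDICTORS
    a_max: int = 10
    split_ratio: float = 0.6
    seed: int = 0
    accuracy: str = "relative"
    evi_variant: str = "paper"
    bin_edges: tuple = DEFAULT_BIN_EDGES
    lr_predictors: str = "same"  # "same" as PLS, or "all" 14 variables
    pcr_components: int = 5
    scene: SceneParams = field(default_factory=SceneParams)
    map_rows: int = 64
    map_cols: int = 64
    wheat_fraction: float = 0.6
    out_dir: str = "wheatgpc_run"

    def validate(self) -> None:
        self.scene.validate()
        unknown = [p for p in self.predictors if p not in VARIABLE_NAMES]
        if unknown:
            raise ParameterError(f"unknown predictor(s) {unknown}; choose from {VARIABLE_NAMES}")
        if self.a_max < 1:
            raise ParameterError(f"a_max must be >= 1, got {self.a_max}")
        if not (0.0 < self.split_ratio < 1.0):
            raise ParameterError(f"split_ratio must be in (0, 1), got {self.split_ratio}")
        if self.accuracy not in ("relative", "mae"):
            raise ParameterError(f"accuracy must be 'relative' or 'mae', got {self.accuracy!r}")
        if self.lr_predictors not in ("same", "all"):
            raise ParameterError(f"lr_predictors must be 'same' or 'all', got {self.lr_predictors!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["predictors"] = list(self.predictors)
        d["bin_edges"] = list(self.bin_edges)
        d["scene"] = self.scene.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kwargs = dict(d)
        if "predictors" in kwargs:
            kwargs["predictors"] = tuple(kwargs["predictors"])
        if "bin_edges" in kwargs:
            kwargs["bin_edges"] = tuple(kwargs["bin_edges"])
        if "scene" in kwargs and isinstance(kwargs["scene"], dict):
            kwargs["scene"] = SceneParams.from_dict(kwargs["scene"])
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    @property
    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _write_json(path: Path, obj: dict, cfg_hash: str) -> None:
    obj = {"config_hash": cfg_hash, **obj}
    path.write_text(json.dumps(obj, indent=2, sort_keys=True))


def _write_frame(path: Path, frame: pd.DataFrame, cfg_hash: str, index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash: {cfg_hash}\n")
        frame.to_csv(fh, index=index)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full pipeline on synthetic data; returns the artifact summary.

    Stages: sample generation, variable-table construction, 3:2 split,
    PRESS component selection and PLS fit, OLS/PCR baselines, scoring
    on both sets, model comparison, and gridded GPC map production.
    All artifacts are written under ``config.out_dir``.
    """
    config.validate()
    cfg_hash = config.config_hash
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    log = {"config_hash": cfg_hash, "stages": []}

    # -- simulate ------------------------------------------------------
    samples = generate_samples(config.scene)
    _write_frame(out / "samples.csv", samples, cfg_hash)
    log["stages"].append({"stage": "simulate", "n_samples": len(samples)})

    # -- indices -------------------------------------------------------
    table = build_variable_table(samples, evi_variant=config.evi_variant)
    table_path = out / "variables.csv"
    frame = table.data.copy()
    frame["gpc"] = table.y.to_numpy()
    _write_frame(table_path, frame, cfg_hash)
    log["stages"].append(
        {"stage": "indices", "n_rows": table.n, "n_excluded": table.n_excluded}
    )

    # -- split + summary + correlations -------------------------------
    split = split_samples(table.y, ratio=config.split_ratio, seed=config.seed)
    _write_json(
        out / "split.json",
        {
            "modeling_ids": split.modeling_ids.tolist(),
            "verification_ids": split.verification_ids.tolist(),
            "ratio": split.ratio,
            "seed": split.seed,
        },
        cfg_hash,
    )
    summary = summary_table(table.y, split)
    _write_frame(out / "gpc_summary.csv", summary, cfg_hash, index=True)
    (out / "gpc_summary.md").write_text(
        f"<!-- config_hash: {cfg_hash} -->\n"
        + render_markdown(summary.reset_index(names="set"))
        + "\n"
    )

    model_rows = split.modeling_ids
    verif_rows = split.verification_ids
    model_table = table.data.iloc[model_rows]
    y_model = table.y.to_numpy()[model_rows]
    y_verif = table.y.to_numpy()[verif_rows]

    from .indices import VariableTable

    screen = correlation_matrix(
        VariableTable(data=model_table.reset_index(drop=True),
                      y=pd.Series(y_model, name="gpc"))
    )
    _write_frame(out / "correlations.csv", screen.r, cfg_hash, index=True)
    log["stages"].append({"stage": "screen", "n_modeling": len(model_rows)})

    # -- PLS fit with PRESS selection ----------------------------------
    Xm = model_table[list(config.predictors)]
    Xv = table.data.iloc[verif_rows][list(config.predictors)]
    a_max = min(config.a_max, len(config.predictors))
    curve = press_curve(Xm, y_model, a_max=a_max)
    a_opt = select_components(curve)
    pls_model = fit_pls(Xm, y_model, a=a_opt)
    pls_model.save(out / "pls_model.json")
    _write_frame(out / "press_curve.csv", curve.to_frame(), cfg_hash)
    _write_frame(out / "vip.csv", vip_scores(pls_model).to_frame(), cfg_hash, index=True)
    log["stages"].append(
        {"stage": "fit", "a_max": a_max, "selected_components": a_opt,
         "press_min": float(curve.press.min())}
    )

    # -- baselines -----------------------------------------------------
    if config.lr_predictors == "all":
        Xm_lr = model_table[VARIABLE_NAMES]
        Xv_lr = table.data.iloc[verif_rows][VARIABLE_NAMES]
    else:
        Xm_lr, Xv_lr = Xm, Xv
    ols_model = fit_ols(Xm_lr, y_model)
    pcr_model = fit_pcr(
        model_table[VARIABLE_NAMES], y_model, n_components=config.pcr_components
    )
    ols_model.save(out / "lr_model.json")
    pcr_model.save(out / "pcr_model.json")

    # -- evaluate ------------------------------------------------------
    Xv_pcr = table.data.iloc[verif_rows][VARIABLE_NAMES]
    Xm_pcr = model_table[VARIABLE_NAMES]
    reports = {
        "PLS": {
            "modeling": score(y_model, predict(pls_model, Xm), config.accuracy, "modeling"),
            "verification": score(y_verif, predict(pls_model, Xv), config.accuracy, "verification"),
        },
        "LR": {
            "modeling": score(y_model, ols_model.predict(Xm_lr), config.accuracy, "modeling"),
            "verification": score(y_verif, ols_model.predict(Xv_lr), config.accuracy, "verification"),
        },
        "PCA": {
            "modeling": score(y_model, pcr_model.predict(Xm_pcr), config.accuracy, "modeling"),
            "verification": score(y_verif, pcr_model.predict(Xv_pcr), config.accuracy, "verification"),
        },
    }
    comparison = compare_models(reports)
    _write_json(
        out / "reports.json",
        {
            alg: {lab: rep.to_dict() for lab, rep in per_set.items()}
            for alg, per_set in reports.items()
        },
        cfg_hash,
    )
    _write_frame(out / "comparison.csv", comparison.table, cfg_hash)
    (out / "comparison.md").write_text(
        f"<!-- config_hash: {cfg_hash} -->\n" + render_markdown(comparison.table) + "\n"
    )
    _write_frame(out / "accuracy_deltas.csv", comparison.accuracy_deltas, cfg_hash)
    scatter = pd.DataFrame(
        {"set": "verification", "measured": y_verif, "predicted": predict(pls_model, Xv)}
    )
    _write_frame(out / "one_to_one.csv", scatter, cfg_hash)
    log["stages"].append({"stage": "evaluate", "algorithms": list(reports)})

    # -- map -----------------------------------------------------------
    band_grids, mask, _ = generate_scene(
        config.map_rows, config.map_cols, config.wheat_fraction, config.scene
    )
    index_grids = compute_index_grids(band_grids, mask, evi_variant=config.evi_variant)
    grid = predict_grid(pls_model, index_grids, mask)
    grid = classify_gpc(grid, bin_edges=config.bin_edges)
    map_paths = export_map(grid, out / "map", fmt="text")
    log["stages"].append(
        {"stage": "map", "valid_cells": grid.n_valid, "class_cells": grid.class_counts()}
    )

    _write_json(out / "run_log.json", log, cfg_hash)
    return {
        "config_hash": cfg_hash,
        "out_dir": str(out),
        "selected_components": a_opt,
        "press_min": float(curve.press.min()),
        "reports": reports,
        "comparison": comparison,
        "map_paths": {k: str(v) for k, v in map_paths.items()},
    }


def run_algorithm_comparison(
    params: SceneParams,
    seed: int | None = None,
    predictors: tuple = DEFAULT_PREDICTORS,
    a_max: int = 10,
    pcr_components: int = 5,
    split_ratio: float = 0.6,
    accuracy: str = "relative",
) -> dict:
    """Benchmark PLS vs LR vs PCR on one synthetic replicate.

    The three algorithms are configured the way the study frames its
    comparison: PLS runs on the full 14-variable candidate set with the
    component count selected at the PRESS minimum (candidate counts
    1..a_max); LR is ordinary least squares on the four sensitive
    indices (the full candidate set is exactly collinear — DVI is a
    linear identity in two bands — so unrestricted LR is infeasible by
    construction); PCR retains ``pcr_components`` principal components
    of all 14 variables.

    Returns per-algorithm FitReports for the modeling and verification
    sets plus the selected PLS component count.
    """
    samples = generate_samples(params)
    table = build_variable_table(samples)
    split = split_samples(table.y, ratio=split_ratio, seed=seed)
    y = table.y.to_numpy()
    ym, yv = y[split.modeling_ids], y[split.verification_ids]
    Xm, Xv = table.data.iloc[split.modeling_ids], table.data.iloc[split.verification_ids]

    curve = press_curve(Xm[VARIABLE_NAMES], ym, a_max=a_max)
    a_opt = select_components(curve)
    pls_model = fit_pls(Xm[VARIABLE_NAMES], ym, a=a_opt)
    ols_model = fit_ols(Xm[list(predictors)], ym)
    pcr_model = fit_pcr(Xm[VARIABLE_NAMES], ym, n_components=pcr_components)

    preds = {
        "PLS": (predict(pls_model, Xm[VARIABLE_NAMES]), predict(pls_model, Xv[VARIABLE_NAMES])),
        "LR": (ols_model.predict(Xm[list(predictors)]), ols_model.predict(Xv[list(predictors)])),
        "PCA": (pcr_model.predict(Xm[VARIABLE_NAMES]), pcr_model.predict(Xv[VARIABLE_NAMES])),
    }
    reports = {
        alg: {
            "modeling": score(ym, pm, accuracy, "modeling"),
            "verification": score(yv, pv, accuracy, "verification"),
        }
        for alg, (pm, pv) in preds.items()
    }
    return {"reports": reports, "selected_components": a_opt, "press_curve": curve}
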