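"""End-to-end orchestration: data -> filters -> segments -> features ->
selection -> classifiers, with deterministic artifacts and the ablation
variants (all features / MPSO only / Pearson only / full PMPSO).

One master seed in the config fans out to per-stage seeds by fixed offsets,
so every stage is independently reproducible.  The held-out test partition
is touched only by the final test-set evaluation, never by selection or
cross-validation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .evaluation import ModelSpec, kfold_cv, train_and_predict, confusion_matrix, metrics_from_confusion
from .features import ExtractionConfig, extract_feature_matrix
from .io import (
    FilterSpec,
    apply_filters,
    concat_segment_sets,
    read_bonn_record,
    save_segment_set,
    segment_record,
    split_segments,
)
from .selection import (
    FitnessSpec,
    SwarmConfig,
    feature_importance,
    pmpso,
    redundancy_filter,
    run_mpso,
    top_k,
)
from .synth import DEFAULT_CLASS_SPECS, gen_eeg_dataset

logger = logging.getLogger("pmpso")

ABLATION_MODES = ("full_pmpso", "mpso_only", "pearson_only", "none")

# per-stage seed offsets from the master seed
_SEED_SYNTH, _SEED_SPLIT, _SEED_SWARM, _SEED_EVAL = 0, 1, 2, 3


@dataclass
class PipelineConfig:
    """Everything one run needs; loadable from a single YAML file."""

    source: dict = field(default_factory=lambda: {"type": "synthetic", "n_per_class": 30})
    filter: FilterSpec = field(default_factory=FilterSpec)
    window_len: int = 1024
    overlap: int = 64
    fractions: tuple[float, float, float] = (0.9, 0.05, 0.05)
    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)
    swarm: SwarmConfig = field(default_factory=SwarmConfig)
    models: tuple[str, ...] = ("rf",)
    cv_folds: int = 10
    ablation: str = "full_pmpso"
    seed: int = 0
    output_dir: str = "pmpso_out"

    def __post_init__(self) -> None:
        if self.ablation not in ABLATION_MODES:
            raise ValueError(f"ablation must be one of {ABLATION_MODES}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kw: dict = {}
        for key in ("source", "window_len", "overlap", "models", "cv_folds",
                    "ablation", "seed", "output_dir"):
            if key in raw:
                kw[key] = raw[key]
        if "fractions" in raw:
            kw["fractions"] = tuple(raw["fractions"])
        if "filter" in raw:
            kw["filter"] = FilterSpec(**raw["filter"])
        if "extraction" in raw:
            ex = dict(raw["extraction"])
            if "bands" in ex:
                ex["bands"] = tuple(tuple(b) for b in ex["bands"])
            kw["extraction"] = ExtractionConfig(**ex)
        if "pmpso" in raw:
            sw = dict(raw["pmpso"])
            if "fitness" in sw:
                sw["fitness"] = FitnessSpec(**sw["fitness"])
            kw["swarm"] = SwarmConfig(**sw)
        if "models" in kw:
            kw["models"] = tuple(kw["models"])
        return cls(**kw)


def _load_records(cfg: PipelineConfig):
    src = cfg.source
    kind = src.get("type", "synthetic")
    if kind == "synthetic":
        return gen_eeg_dataset(
            n_per_class=src.get("n_per_class", 30),
            seed=cfg.seed + _SEED_SYNTH,
            amplitude_jitter=src.get("amplitude_jitter", 0.15),
        )
    if kind == "bonn":
        labels_csv = Path(src["labels"])
        base = labels_csv.parent
        table = pd.read_csv(labels_csv)
        return [
            read_bonn_record(base / row["file"], row["label"])
            for _, row in table.iterrows()
        ]
    raise ValueError(f"unknown source type {kind!r}")


def anova_ranking(features: pd.DataFrame, labels) -> list[str]:
    """Univariate ranking by the between/within class variance ratio
    (ANOVA F), used by the Pearson-only ablation which has no swarm stage."""
    from sklearn.feature_selection import f_classif

    F, _ = f_classif(features.to_numpy(), np.asarray(labels))
    F = np.nan_to_num(F, nan=0.0)
    order = np.argsort(-F, kind="stable")
    return [features.columns[j] for j in order]


def select_features(
    features: pd.DataFrame, labels, swarm: SwarmConfig, mode: str = "full_pmpso"
):
    """Apply one ablation variant; returns (subset names, details dict)."""
    names = list(features.columns)
    if mode == "none":
        return names, {"mode": mode}
    if mode == "pearson_only":
        ranked = anova_ranking(features, labels)
        subset, r_table = redundancy_filter(features, ranked, swarm.delta)
        return subset, {"mode": mode, "ranked": ranked,
                        "r_table": [[a, b, float(r)] for a, b, r in r_table]}
    if mode == "mpso_only":
        history, gbest = run_mpso(features, labels, swarm)
        imp = feature_importance(history, names)
        subset = top_k(imp, min(swarm.top_k, len(names)))
        return subset, {"mode": mode, "importance": imp,
                        "gbest_fitness": float(gbest["fitness"]),
                        "n_iters": int(gbest["n_iters"])}
    result = pmpso(features, labels, swarm)
    return result.final_subset, {"mode": mode, "result": result.to_dict()}


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage and write deterministic artifacts to the output dir.

    Returns a dict with the in-memory stage outputs (segments, features,
    subset, evaluation reports) and the manifest.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    logger.info("stage 1/5: loading and filtering records")
    try:
        records = [apply_filters(r, cfg.filter) for r in _load_records(cfg)]
    except Exception as e:
        raise RuntimeError(f"stage io_preprocess (load/filter) failed: {e}") from e

    logger.info("stage 2/5: segmentation and split")
    try:
        segsets = [segment_record(r, cfg.window_len, cfg.overlap) for r in records]
        allseg = concat_segment_sets([s for s in segsets if len(s)])
        train, val, test = split_segments(allseg, cfg.fractions, cfg.seed + _SEED_SPLIT)
        save_segment_set(train, out / "segments_train.csv")
    except Exception as e:
        raise RuntimeError(f"stage segmentation/split failed: {e}") from e

    logger.info("stage 3/5: feature extraction (%d train segments)", len(train))
    try:
        X_train, y_train = extract_feature_matrix(train, cfg.extraction)
        X_val, y_val = extract_feature_matrix(val, cfg.extraction)
        X_test, y_test = extract_feature_matrix(test, cfg.extraction)
        feat_out = X_train.copy()
        feat_out["label"] = y_train
        feat_out.to_csv(out / "features_train.csv", index=False)
    except Exception as e:
        raise RuntimeError(f"stage feature_extraction failed: {e}") from e

    logger.info("stage 4/5: feature selection (%s)", cfg.ablation)
    try:
        swarm = replace(cfg.swarm, seed=cfg.seed + _SEED_SWARM)
        subset, details = select_features(X_train, y_train, swarm, cfg.ablation)
        (out / "selection.json").write_text(json.dumps(
            {"subset": subset, **{k: v for k, v in details.items() if k != "result"},
             **({"result": details["result"]} if "result" in details else {})},
            indent=2))
        if "result" in details and details["result"].get("r_table"):
            pd.DataFrame(details["result"]["r_table"],
                         columns=["feature_X", "feature_Y", "r"]).to_csv(
                out / "r_table.csv", index=False)
    except Exception as e:
        raise RuntimeError(f"stage pmpso_select failed: {e}") from e

    logger.info("stage 5/5: classification (%s) on %d features", cfg.models, len(subset))
    reports = {}
    try:
        for kind in cfg.models:
            spec = ModelSpec(kind)
            rep = kfold_cv(X_train[subset], y_train, spec, k=cfg.cv_folds,
                           seed=cfg.seed + _SEED_EVAL)
            # held-out test evaluation: fit on train only, predict test
            pred = train_and_predict(spec, X_train[subset], y_train, X_test[subset],
                                     seed=cfg.seed + _SEED_EVAL)
            classes = list(rep.classes)
            enc = {c: i for i, c in enumerate(classes)}
            cm_test = confusion_matrix([enc[c] for c in y_test],
                                       [enc[c] for c in pred], len(classes))
            test_metrics = metrics_from_confusion(cm_test, "macro")
            payload = rep.to_dict()
            payload["test"] = {
                "confusion": cm_test.tolist(),
                "macro": {k: round(v, 2) for k, v in test_metrics.items()},
                "accuracy": round(100.0 * np.trace(cm_test) / max(cm_test.sum(), 1), 2),
            }
            (out / f"eval_{kind}.json").write_text(json.dumps(payload, indent=2))
            reports[kind] = rep
    except Exception as e:
        raise RuntimeError(f"stage classify_eval failed: {e}") from e

    manifest = {
        "version": __version__,
        "config_hash": config_hash(cfg),
        "seed": cfg.seed,
        "stage_seeds": {"synth": cfg.seed + _SEED_SYNTH, "split": cfg.seed + _SEED_SPLIT,
                        "swarm": cfg.seed + _SEED_SWARM, "eval": cfg.seed + _SEED_EVAL},
        "ablation": cfg.ablation,
        "n_segments": {"train": len(train), "val": len(val), "test": len(test)},
        "subset": subset,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {
        "train": (X_train, y_train),
        "val": (X_val, y_val),
        "test": (X_test, y_test),
        "subset": subset,
        "details": details,
        "reports": reports,
        "manifest": manifest,
    }


def config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_ablation(cfg: PipelineConfig) -> pd.DataFrame:
    """Run all four selection variants on the same data/seed; one row each
    with subset size and macro metrics of the first configured model."""
    rows = []
    for mode in ABLATION_MODES:
        sub_cfg = replace(cfg, ablation=mode,
                          output_dir=str(Path(cfg.output_dir) / mode))
        res = run_pipeline(sub_cfg)
        kind = cfg.models[0]
        rep = res["reports"][kind]
        rows.append({
            "variant": mode,
            "n_features": len(res["subset"]),
            "AC": round(rep.macro["AC"], 2),
            "SE": round(rep.macro["SE"], 2),
            "SP": round(rep.macro["SP"], 2),
            "F1": round(rep.macro["f1_paper"], 2),
            "pooled_accuracy": round(rep.micro_accuracy, 2),
        })
    table = pd.DataFrame(rows)
    Path(cfg.output_dir).mkdir(parents=True, exist_ok=True)
    table.to_csv(Path(cfg.output_dir) / "ablation.csv", index=False)
    return table


def compare_selectors(
    features: pd.DataFrame, labels, swarm: SwarmConfig,
    selectors: tuple[str, ...] = ("pmpso", "pso_baseline"),
) -> pd.DataFrame:
    """Compare the constricted two-stage selector against a baseline PSO
    (identical swarm, phi forced to 1, no Pearson stage)."""
    from .selection import FitnessEvaluator

    rows = []
    names = list(features.columns)
    fit = FitnessEvaluator(features.to_numpy(), np.asarray(labels), swarm.fitness)
    for sel in selectors:
        if sel == "pmpso":
            result = pmpso(features, labels, swarm)
            subset, n_iters = result.final_subset, result.n_iters
        elif sel == "pso_baseline":
            base = replace(swarm, constriction=False)
            history, gbest = run_mpso(features, labels, base)
            imp = feature_importance(history, names)
            subset = top_k(imp, min(base.top_k, len(names)))
            n_iters = gbest["n_iters"]
        else:
            raise ValueError(f"unknown selector {sel!r}")
        mask = np.array([n in set(subset) for n in names], dtype=int)
        acc, size = fit(mask)
        rows.append({"selector": sel, "subset_size": size,
                     "cv_accuracy": round(100 * acc, 2), "iterations": n_iters})
    return pd.DataFrame(rows)

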