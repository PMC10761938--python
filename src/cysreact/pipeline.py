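"""End-to-end pipeline: dataset -> encode -> select -> resample -> train ->
evaluate, with a run manifest so every artifact directory is replayable.

The stages mirror the predictor's design: assemble a balanced benchmark
(undersampling the unchanged pool), stratified 20% validation split,
feature encoding, per-task elastic-net feature selection, SMOTE-Tomek
rebalancing of the direction task's training split, training of the two
gated XGBoost stages, and evaluation of the hierarchical tri-classifier
(plus optional direct tri-classifier and baseline comparators).
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import metrics as M
from .encoders import EncoderConfig, encode_dataset, labels_series, write_feature_tsv
from .models import (
    HierarchicalModel,
    HyperparameterProtocol,
    run_baselines,
    train_direct_tri,
    train_direction,
    train_occurrence,
)
from .sampling import smote_tomek, stratified_split, write_split_manifest
from .seqdata import assemble_benchmark, load_records, read_labels_tsv
from .selection import select_features, write_selection_tsv
from .synthetic import SimulationConfig, simulate_proteome

DEFAULT_CONFIG: dict = {
    "seed": 42,
    "data": {
        "source": "simulate",
        "simulate": {
            "class_counts": [80, 290, 6357],
            "ps_enrichment": 0.5,
            "disorder_shift": 1.0,
            "pdis_shift": 1.0,
        },
        "fasta": None,
        "phospho": None,
        "iupred": None,
        "labels": None,
    },
    "benchmark": {"undersample": True},
    "split": {"fraction": 0.2},
    "encoder": {"window_length": 21, "cksaap_gaps": [0, 1], "ebgw_j": 5},
    "selection": {"enabled": True, "folds": 10, "scoring": "accuracy", "resampled": True},
    "resample": {"direction": True, "occurrence": False, "k": 5},
    "train": {"protocol": "fast"},
    "direct_tri": {"enabled": False},
    "baselines": {"enabled": False},
}


def _merge(base: dict, user: dict, path: str = "") -> None:
    unknown = set(user) - set(base)
    if unknown:
        where = f" under {path!r}" if path else ""
        raise ValueError(f"unknown config key(s){where}: {sorted(unknown)}")
    for key, val in user.items():
        if isinstance(val, dict) and isinstance(base[key], dict):
            _merge(base[key], val, f"{path}.{key}".lstrip("."))
        else:
            base[key] = val


def merge_config(user: dict | None) -> dict:
    """Overlay a user config on the defaults, recursively; unknown keys at
    any level are a schema violation and are reported by name."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if user:
        _merge(cfg, user)
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def load_config(path) -> dict:
    with open(path) as fh:
        return merge_config(yaml.safe_load(fh) or {})


def _load_dataset(cfg: dict):
    data = cfg["data"]
    if data["source"] == "simulate":
        sim = data["simulate"]
        sc = SimulationConfig(
            class_counts=tuple(sim["class_counts"]),
            ps_enrichment=sim["ps_enrichment"],
            disorder_shift=sim["disorder_shift"],
            pdis_shift=sim["pdis_shift"],
            seed=cfg["seed"],
        )
        return simulate_proteome(sc)
    if data["source"] == "files":
        records = load_records(data["fasta"], data["phospho"], data["iupred"])
        sites = read_labels_tsv(data["labels"])
        return records, sites
    raise ValueError(f"unknown data source {data['source']!r}")


def run_pipeline(config: dict | None = None, outdir=None, seed: int | None = None) -> dict:
    """Execute the full pipeline; returns the evaluation report dict.

    When ``outdir`` is given, stage artifacts (split manifest, selection
    tables, model directory, report JSON) are written there together with
    a run manifest; a rerun against an identical manifest short-circuits
    to the cached report.
    """
    cfg = merge_config(config)
    if seed is not None:
        cfg["seed"] = seed
    chash = config_hash(cfg)

    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        man_path = out / "manifest.json"
        rep_path = out / "report.json"
        if man_path.exists() and rep_path.exists():
            old = json.loads(man_path.read_text())
            if old.get("config_hash") == chash:
                return json.loads(rep_path.read_text())

    rng_seed = cfg["seed"]
    log: list[str] = []

    # --- dataset -----------------------------------------------------------
    records, sites = _load_dataset(cfg)
    log.append(f"dataset: {len(records)} proteins, {len(sites)} sites")
    if cfg["benchmark"]["undersample"]:
        sites = assemble_benchmark(sites, seed=rng_seed)
        log.append(f"benchmark: {len(sites)} sites after undersampling")

    # --- encode ------------------------------------------------------------
    enc = cfg["encoder"]
    enc_cfg = EncoderConfig(
        window_length=enc["window_length"],
        cksaap_gaps=tuple(enc["cksaap_gaps"]),
        ebgw_j=enc["ebgw_j"],
    )
    X = encode_dataset(sites, records, enc_cfg)
    y = labels_series(sites)
    log.append(f"encode: {X.shape[0]} x {X.shape[1]} feature matrix")

    # --- split -------------------------------------------------------------
    split = stratified_split(y.to_numpy(), cfg["split"]["fraction"], seed=rng_seed)
    X_tr, X_val = X.iloc[split.train], X.iloc[split.validation]
    y_tr, y_val = y.iloc[split.train], y.iloc[split.validation]
    log.append(f"split: {len(X_tr)} train / {len(X_val)} validation")

    # task labelings
    occ_tr, occ_val = (y_tr != 0).astype(int), (y_val != 0).astype(int)
    dir_tr_mask, dir_val_mask = y_tr != 0, y_val != 0
    dir_tr = (y_tr[dir_tr_mask] == 1).astype(int)
    dir_val = (y_val[dir_val_mask] == 1).astype(int)

    # --- resample (training data only) -------------------------------------
    k = cfg["resample"]["k"]
    if cfg["resample"]["occurrence"]:
        X_occ, y_occ = smote_tomek(X_tr, occ_tr.to_numpy(), seed=rng_seed, k=k)
        X_occ = pd.DataFrame(X_occ, columns=X.columns)
    else:
        X_occ, y_occ = X_tr, occ_tr.to_numpy()
    if cfg["resample"]["direction"]:
        X_dir, y_dir = smote_tomek(
            X_tr[dir_tr_mask], dir_tr.to_numpy(), seed=rng_seed, k=k
        )
        X_dir = pd.DataFrame(X_dir, columns=X.columns)
    else:
        X_dir, y_dir = X_tr[dir_tr_mask], dir_tr.to_numpy()
    log.append(f"resample: occurrence {len(X_occ)}, direction {len(X_dir)} rows")

    # --- feature selection (per task) ---------------------------------------
    sel_cfg = cfg["selection"]
    if sel_cfg["enabled"]:
        if sel_cfg["resampled"]:
            occ_sel_X, occ_sel_y = X_occ, y_occ
            dir_sel_X, dir_sel_y = X_dir, y_dir
        else:
            occ_sel_X, occ_sel_y = X_tr, occ_tr.to_numpy()
            dir_sel_X, dir_sel_y = X_tr[dir_tr_mask], dir_tr.to_numpy()
        occ_sel = select_features(
            occ_sel_X, occ_sel_y, folds=sel_cfg["folds"],
            seed=rng_seed, scoring=sel_cfg["scoring"],
        )
        dir_sel = select_features(
            dir_sel_X, dir_sel_y, folds=sel_cfg["folds"],
            seed=rng_seed, scoring=sel_cfg["scoring"],
        )
        occ_features = occ_sel.selected or list(X.columns)
        dir_features = dir_sel.selected or list(X.columns)
        log.append(
            f"selection: {len(occ_features)} occurrence / {len(dir_features)} direction features"
        )
    else:
        occ_sel = dir_sel = None
        occ_features = dir_features = list(X.columns)

    # --- train --------------------------------------------------------------
    protocol = (
        HyperparameterProtocol.fast()
        if cfg["train"]["protocol"] == "fast"
        else HyperparameterProtocol.default()
    )
    occ_clf, occ_man = train_occurrence(X_occ[occ_features], y_occ, protocol, rng_seed)
    dir_clf, dir_man = train_direction(X_dir[dir_features], y_dir, protocol, rng_seed)
    model = HierarchicalModel(
        occurrence_clf=occ_clf,
        direction_clf=dir_clf,
        occurrence_features=occ_features,
        direction_features=dir_features,
        manifest={"occurrence": occ_man, "direction": dir_man, "config_hash": chash},
    )

    # --- evaluate ------------------------------------------------------------
    proba = model.predict_proba(X_val)
    occ_pred = (proba["p_changed"] >= model.occurrence_cutoff).astype(int)
    occ_report = M.evaluation_report(
        occ_val.to_numpy(), occ_pred.to_numpy(), proba["p_changed"].to_numpy()
    )
    dir_proba = proba.loc[dir_val_mask.to_numpy(), "p_increased"]
    dir_pred = (dir_proba >= model.direction_cutoff).astype(int)
    dir_report = M.evaluation_report(
        dir_val.to_numpy(), dir_pred.to_numpy(), dir_proba.to_numpy()
    )
    tri_pred = model.predict_tri(X_val)
    tri_report = M.tri_metrics(M.confusion_tri(y_val.to_numpy(), tri_pred))

    report = {
        "config_hash": chash,
        "seed": rng_seed,
        "log": log,
        "occurrence": occ_report,
        "direction": dir_report,
        "hierarchical_tri": tri_report,
        "n_features": {"occurrence": len(occ_features), "direction": len(dir_features)},
    }

    if cfg["direct_tri"]["enabled"]:
        tri_clf = train_direct_tri(X_tr, y_tr.to_numpy(), protocol, rng_seed)
        tri_direct = tri_clf.predict(X_val.to_numpy()) - 1
        report["direct_tri"] = M.tri_metrics(
            M.confusion_tri(y_val.to_numpy(), tri_direct)
        )
    if cfg["baselines"]["enabled"]:
        table = run_baselines(
            X_occ[occ_features], y_occ, X_val[occ_features], occ_val, seed=rng_seed
        )
        report["baselines_occurrence"] = table.to_dict(orient="index")

    # --- persist -------------------------------------------------------------
    if out is not None:
        write_split_manifest(list(X.index), split, y.to_numpy(), out / "split.tsv")
        if occ_sel is not None:
            write_selection_tsv(occ_sel, out / "selection_occurrence.tsv")
            write_selection_tsv(dir_sel, out / "selection_direction.tsv")
        model.save(out / "model")
        write_feature_tsv(X_val, out / "features_validation.tsv")
        (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
        (out / "manifest.json").write_text(
            json.dumps({"config_hash": chash, "config": cfg}, indent=2, default=str)
        )
    return report
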