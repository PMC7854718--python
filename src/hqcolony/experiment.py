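"""End-to-end experiment orchestration.

One *dataset run* is a (cell line, well, feature set) triple pushed through
the whole chain: feature extraction -> ground truth (sFCM on the entropy
map, or the generator's true mask) -> pixel-table serialization ->
[1,255] normalization -> 0.2% sampling -> z-score standardization ->
80/20 split -> cross-validated grid search -> test metrics.  The default
full enumeration is 4 lines x 30 wells x 6 feature sets = 720 runs; the
config scales every axis down for smoke tests.
"""

from __future__ import annotations

import hashlib
import json
import warnings

import numpy as np
import pandas as pd

from . import dataset as ds
from .evaluation import grid_search
from .features import FEATURE_SETS, feature_map_stack
from .groundtruth import ground_truth_mask
from .synthetic import REGIMES, generate_cell_line_suite

__all__ = ["DEFAULT_CONFIG", "enumerate_runs", "run_dataset", "run_experiment"]

DEFAULT_CONFIG = {
    "regimes": list(REGIMES),          # the four cell-line-like regimes
    "n_wells": 30,
    "feature_sets": list(FEATURE_SETS),
    "objective": "balanced_accuracy",
    "sampling_fraction": 0.002,
    "dev_fraction": 0.8,
    "window": 5,
    "gray_levels": 256,
    "side": 301,
    "ground_truth": "sfcm",            # or "true" for the generator's mask
    "min_area": 50,
    "opening_radius": 1,
    "seed": 0,
    "param_grid": None,                # None -> the full HQC grid per kind
    "n_folds": 5,
}


def enumerate_runs(config: dict | None = None) -> list[dict]:
    """The (line, well, feature set) run descriptors for a config; the
    default enumerates 4 x 30 x 6 = 720 dataset runs."""
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    return [
        {"line": line, "well": well, "feature_set": fs}
        for line in cfg["regimes"]
        for well in range(cfg["n_wells"])
        for fs in cfg["feature_sets"]
    ]


def _feature_kind(feature_set: str) -> str:
    return "triplet" if len(FEATURE_SETS[feature_set]) == 3 else "scalar"


def prepare_tables(stack, mask, feature_set: str, fraction: float, dev_fraction: float,
                   seed: int, provenance: dict | None = None):
    """Serialize one well's maps + mask and run the pre-processing chain;
    returns (development, test) standardized pixel tables."""
    table = ds.serialize(stack.select(feature_set), mask, provenance=provenance)
    table = ds.normalize_range(table)
    table = ds.sample(table, fraction=fraction, seed=seed)
    table, _stats = ds.standardize(table)
    return ds.split(table, dev_fraction=dev_fraction, seed=seed)


def run_dataset(image, true_mask, feature_set: str, config: dict, seed: int,
                provenance: dict | None = None) -> dict:
    """One full dataset run; returns a record with the winning
    hyperparameters and test metrics."""
    cfg = {**DEFAULT_CONFIG, **config}
    stack = feature_map_stack(image, window=cfg["window"], L=cfg["gray_levels"])
    if cfg["ground_truth"] == "true":
        mask = np.asarray(true_mask)
    else:
        mask = ground_truth_mask(
            stack.maps["entropy"], min_area=cfg["min_area"],
            opening_radius=cfg["opening_radius"],
        )
    dev, test = prepare_tables(
        stack, mask, feature_set, cfg["sampling_fraction"], cfg["dev_fraction"], seed,
        provenance=provenance,
    )
    res = grid_search(
        dev, feature_set_kind=_feature_kind(feature_set), objective=cfg["objective"],
        seed=seed, param_grid=cfg["param_grid"], n_folds=cfg["n_folds"], test=test,
    )
    m = res.test_metrics
    return {
        "feature_set": feature_set,
        "seed": seed,
        "best_params": res.best_params,
        "mean_validation_score": res.best_score,
        "balanced_accuracy": m.balanced_accuracy,
        "auroc": m.auroc,
        "jaccard": m.jaccard,
        "dice": m.dice,
    }


def run_experiment(config: dict | None = None):
    """Run every enumerated dataset and aggregate mean +/- sd per
    (line, feature set).

    Returns ``(manifest, scores)``: a JSON-serializable manifest (config,
    per-run seeds and records, skip reasons, content hash) and a tidy
    DataFrame of per-run scores.  Identical configs give identical
    manifests.
    """
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    runs = enumerate_runs(cfg)
    master = np.random.SeedSequence(cfg["seed"])
    run_seeds = [int(s) for s in
                 master.generate_state(len(runs)) % np.uint32(2**31 - 1)]

    wells_cache: dict[str, list] = {}
    records, skipped = [], []
    for descriptor, run_seed in zip(runs, run_seeds):
        line = descriptor["line"]
        if line not in wells_cache:
            line_seed = int(
                np.random.SeedSequence([cfg["seed"], list(REGIMES).index(line)])
                .generate_state(1)[0] % np.uint32(2**31 - 1)
            )
            wells_cache[line] = generate_cell_line_suite(
                line, n_wells=cfg["n_wells"], seed=line_seed, side=cfg["side"]
            )
        image, true_mask, _spec = wells_cache[line][descriptor["well"]]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rec = run_dataset(
                    image, true_mask, descriptor["feature_set"], cfg, run_seed,
                    provenance={"line": line, "well": descriptor["well"]},
                )
            records.append({**descriptor, **rec})
        except Exception as exc:
            skipped.append({**descriptor, "reason": f"{type(exc).__name__}: {exc}"})

    scores = pd.DataFrame(records)
    aggregates = []
    if len(scores):
        grouped = scores.groupby(["line", "feature_set"])
        for (line, fs), g in grouped:
            aggregates.append(
                {
                    "line": line,
                    "feature_set": fs,
                    "n_runs": len(g),
                    "balanced_accuracy_mean": g["balanced_accuracy"].mean(),
                    "balanced_accuracy_sd": g["balanced_accuracy"].std(ddof=0),
                    "auroc_mean": g["auroc"].mean(),
                    "jaccard_mean": g["jaccard"].mean(),
                    "dice_mean": g["dice"].mean(),
                }
            )
    manifest = {
        "config": cfg,
        "n_runs": len(runs),
        "run_seeds": run_seeds,
        "records": records,
        "skipped": skipped,
        "aggregates": aggregates,
    }
    payload = json.dumps(manifest, sort_keys=True, default=str).encode()
    manifest["content_hash"] = hashlib.sha256(payload).hexdigest()
    return manifest, scores
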