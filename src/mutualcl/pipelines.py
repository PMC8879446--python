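"""Config-driven, reproducible pipelines: generate -> train -> evaluate.

These functions are the scripted surface of the package: each takes a
plain configuration mapping (loadable from YAML or JSON), validates it
(unknown keys are rejected), performs one stage, writes its artifacts
into an output directory together with an exact echo of the
configuration that produced them, and returns the in-memory result.
All randomness flows from the seeds recorded in the config, so rerunning
a stage with the same config reproduces its outputs.
"""

from __future__ import annotations

import json
import os
from dataclasses import fields as dc_fields
from typing import Mapping

import matplotlib
import numpy as np
import pandas as pd
import yaml

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402  (backend must be set first)

from .benchmark import default_benchmark, load_benchmark, write_benchmark
from .evaluation import VARIANTS, forgetting_curve, loss_comparison, tau_sweep
from .exceptions import ValidationError
from .losses import LOG_COLUMNS
from .trainer import RunHistory, TrainConfig, run_sequence

__all__ = [
    "load_config",
    "make_train_config",
    "resolve_benchmark",
    "generate",
    "train",
    "evaluate",
    "sweep_tau",
    "compare_losses",
]

_BENCHMARK_KEYS = {
    "path",
    "seed",
    "items_per_class",
    "noise_sigma",
    "image_size",
    "split_fraction",
}
_TOP_KEYS = {"benchmark", "train", "seeds", "taus", "variants"}
_TRAIN_KEYS = {f.name for f in dc_fields(TrainConfig)}


def load_config(path: str) -> dict:
    """Load a YAML (or JSON — a YAML subset) config file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, Mapping):
        raise ValidationError("config root must be a mapping")
    return validate_config(dict(cfg))


def validate_config(cfg: dict) -> dict:
    unknown = set(cfg) - _TOP_KEYS
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    bench = cfg.get("benchmark", {})
    if set(bench) - _BENCHMARK_KEYS:
        raise ValidationError(
            f"unknown benchmark keys: {sorted(set(bench) - _BENCHMARK_KEYS)}"
        )
    train = cfg.get("train", {})
    if set(train) - _TRAIN_KEYS:
        raise ValidationError(f"unknown train keys: {sorted(set(train) - _TRAIN_KEYS)}")
    return cfg


def make_train_config(cfg: dict) -> TrainConfig:
    train = dict(cfg.get("train", {}))
    if "hidden_dims" in train:
        train["hidden_dims"] = tuple(train["hidden_dims"])
    return TrainConfig(**train)


def resolve_benchmark(cfg: dict):
    bench = dict(cfg.get("benchmark", {}))
    path = bench.pop("path", None)
    if path is not None:
        return load_benchmark(path)
    return default_benchmark(**bench)


def _echo(cfg: dict, out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    with open(os.path.join(out_dir, "config.yaml"), "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def generate(cfg: dict, out_dir: str):
    """Render the synthetic benchmark to ``out_dir`` (PNGs + manifest.csv)."""
    validate_config(cfg)
    tasks = resolve_benchmark(cfg)
    _echo(cfg, out_dir)
    manifest = write_benchmark(tasks, out_dir)
    summary = pd.read_csv(manifest).groupby(["domain", "split", "class"]).size()
    return tasks, summary


def train(cfg: dict, out_dir: str) -> RunHistory:
    """Run the continual sequence and persist history, loss log and checkpoints."""
    validate_config(cfg)
    tasks = resolve_benchmark(cfg)
    config = make_train_config(cfg)
    history = run_sequence(tasks, config)
    _echo(cfg, out_dir)
    with open(os.path.join(out_dir, "history.json"), "w") as fh:
        json.dump(history.to_json(), fh, indent=1)
    pd.DataFrame(history.loss_log, columns=LOG_COLUMNS).to_csv(
        os.path.join(out_dir, "loss_log.csv"), index=False
    )
    ckpt = {
        f"layer{i}_{name}": arr
        for i, (w, b) in enumerate(zip(history.model.weights, history.model.biases))
        for name, arr in (("w", w), ("b", b))
    }
    np.savez(os.path.join(out_dir, "model_final.npz"), **ckpt)
    return history


def evaluate(history: RunHistory, out_dir: str) -> pd.DataFrame:
    """Write the per-increment metric report and forgetting drops as CSV."""
    curve = forgetting_curve(history)
    rows = []
    for entry, report in zip(history.entries, curve["series"]):
        rows.append(
            {
                "increment": entry["increment"],
                "domain": entry["domain"],
                **report.as_dict(),
                "items_in_memory": entry["items_in_memory"],
                "memory_reduction": entry["memory_reduction"],
            }
        )
    df = pd.DataFrame(rows)
    os.makedirs(out_dir, exist_ok=True)
    df.to_csv(os.path.join(out_dir, "metrics.csv"), index=False)
    with open(os.path.join(out_dir, "forgetting_drops.json"), "w") as fh:
        json.dump(curve["drops"], fh, indent=1)
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.plot(df["increment"], df["acc"], "o-", label="top-1 accuracy")
    ax.plot(df["increment"], df["f1"], "s--", label="macro F1")
    ax.set_xlabel("increment")
    ax.set_ylabel("score on cumulative test set")
    ax.set_ylim(0, 1)
    ax.legend()
    fig.tight_layout()
    fig.savefig(os.path.join(out_dir, "forgetting_curve.png"), dpi=120)
    plt.close(fig)
    return df


def sweep_tau(cfg: dict, out_dir: str) -> pd.DataFrame:
    """Temperature sweep; writes one CSV row per tau (mean/sd top-1 error)."""
    validate_config(cfg)
    tasks = resolve_benchmark(cfg)
    config = make_train_config(cfg)
    taus = cfg.get("taus", [0.5, 1.0, 1.5, 2.0, 5.0])
    seeds = cfg.get("seeds", [0, 1, 2])
    df = tau_sweep(taus, tasks, config, seeds)
    _echo(cfg, out_dir)
    df.to_csv(os.path.join(out_dir, "tau_sweep.csv"), index=False)
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.errorbar(df["tau"], df["mean_error"], yerr=df["sd_error"], fmt="o-")
    ax.set_xlabel(r"temperature $\tau$")
    ax.set_ylabel("top-1 test error")
    fig.tight_layout()
    fig.savefig(os.path.join(out_dir, "tau_sweep.png"), dpi=120)
    plt.close(fig)
    return df


def compare_losses(cfg: dict, out_dir: str) -> pd.DataFrame:
    """Loss-variant comparison table (one row per objective)."""
    validate_config(cfg)
    tasks = resolve_benchmark(cfg)
    config = make_train_config(cfg)
    variants = cfg.get("variants", list(VARIANTS))
    seeds = cfg.get("seeds", [0, 1, 2, 3, 4])
    df = loss_comparison(variants, tasks, config, seeds)
    _echo(cfg, out_dir)
    df.drop(columns=["per_seed"]).to_csv(
        os.path.join(out_dir, "loss_comparison.csv"), index=False
    )
    return df
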