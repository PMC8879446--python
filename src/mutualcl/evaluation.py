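"""Metrics and the experiment drivers (forgetting, transfer, ablations).

Multiclass performance is reported as top-1 accuracy plus macro-averaged
one-vs-rest sensitivity (TPR), specificity (TNR), precision (PPV) and
F1.  Macro averaging runs over classes present in the ground truth;
ratios with zero denominators resolve to 0 and are flagged rather than
dropped, so reports stay comparable across increments.

The experiment drivers re-run the continual trainer under controlled
variations: per-increment forgetting curves, the cross-domain
transferability grid, a temperature sweep, and the loss-variant
comparison (KL distillation vs. plain cross-entropy fine-tuning vs. the
continual objective with and without its mutual-distillation term).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "confusion_counts",
    "compute_metrics",
    "forgetting_curve",
    "transferability_matrix",
    "tau_sweep",
    "loss_comparison",
]


@dataclass
class ConfusionCounts:
    """One-vs-rest confusion tallies per registry class."""

    class_ids: list
    tp: np.ndarray
    fp: np.ndarray
    tn: np.ndarray
    fn: np.ndarray
    n: int


@dataclass
class MetricReport:
    acc: float
    tpr: float
    tnr: float
    ppv: float
    f1: float
    averaging: str
    per_class: dict
    undefined: dict  # class -> list of metric names that were 0/0

    def as_dict(self) -> dict:
        return {
            "acc": self.acc,
            "tpr": self.tpr,
            "tnr": self.tnr,
            "ppv": self.ppv,
            "f1": self.f1,
            "averaging": self.averaging,
        }


def confusion_counts(
    predictions: Sequence, truths: Sequence, registry: Sequence
) -> ConfusionCounts:
    """Per-class one-vs-rest TP/FP/TN/FN over aligned prediction/truth lists."""
    preds = list(predictions)
    trues = list(truths)
    if len(preds) != len(trues):
        raise ValidationError("predictions and truths differ in length")
    if not preds:
        raise ValidationError("empty prediction list")
    known = set(registry)
    for lab in (*preds, *trues):
        if lab not in known:
            raise ValidationError(f"label {lab!r} not in registry")
    classes = list(registry)
    index = {c: i for i, c in enumerate(classes)}
    n = len(preds)
    w = len(classes)
    tp = np.zeros(w, dtype=int)
    fp = np.zeros(w, dtype=int)
    fn = np.zeros(w, dtype=int)
    for p, t in zip(preds, trues):
        if p == t:
            tp[index[p]] += 1
        else:
            fp[index[p]] += 1
            fn[index[t]] += 1
    tn = n - tp - fp - fn
    return ConfusionCounts(class_ids=classes, tp=tp, fp=fp, tn=tn, fn=fn, n=n)


def _safe_ratio(num: float, den: float, flags: list, name: str) -> float:
    if den == 0:
        flags.append(name)
        return 0.0
    return num / den


def compute_metrics(counts: ConfusionCounts) -> MetricReport:
    """Top-1 accuracy plus macro TPR/TNR/PPV/F1 over truth-present classes."""
    if counts.n < 1:
        raise ValidationError("need at least one sample")
    per_class: dict = {}
    undefined: dict = {}
    present: list = []
    for j, cls in enumerate(counts.class_ids):
        flags: list = []
        tp, fp, tn, fn = (int(a[j]) for a in (counts.tp, counts.fp, counts.tn, counts.fn))
        tpr = _safe_ratio(tp, tp + fn, flags, "tpr")
        tnr = _safe_ratio(tn, tn + fp, flags, "tnr")
        ppv = _safe_ratio(tp, tp + fp, flags, "ppv")
        f1 = _safe_ratio(2 * ppv * tpr, ppv + tpr, flags, "f1")
        per_class[cls] = {"tpr": tpr, "tnr": tnr, "ppv": ppv, "f1": f1,
                          "tp": tp, "fp": fp, "tn": tn, "fn": fn}
        if flags:
            undefined[cls] = flags
        if tp + fn > 0:
            present.append(cls)
    if not present:
        raise ValidationError("no class present in the ground truth")
    acc = float(counts.tp.sum()) / counts.n
    macro = {
        m: float(np.mean([per_class[c][m] for c in present]))
        for m in ("tpr", "tnr", "ppv", "f1")
    }
    return MetricReport(
        acc=acc,
        tpr=macro["tpr"],
        tnr=macro["tnr"],
        ppv=macro["ppv"],
        f1=macro["f1"],
        averaging="macro",
        per_class=per_class,
        undefined=undefined,
    )


# ---------------------------------------------------------------------------
# experiment drivers


def forgetting_curve(history) -> dict:
    """Per-increment metric series on the cumulative test set, plus drops.

    Returns ``{"series": [MetricReport, ...], "drops": [...]}`` where
    ``drops[k]`` maps each class already known before increment ``k+1``
    to its per-class recall drop between consecutive increments
    (positive = forgetting).
    """
    if not getattr(history, "entries", None):
        raise ValidationError("empty run history")
    series: list[MetricReport] = []
    for e in history.entries:
        counts = confusion_counts(e["y_pred"], e["y_true"], history.registry)
        series.append(compute_metrics(counts))
    drops: list[dict] = []
    seen = set(history.entries[0]["classes_added"])
    for prev_r, cur_e, cur_r in zip(series, history.entries[1:], series[1:]):
        drops.append(
            {
                cls: prev_r.per_class[cls]["tpr"] - cur_r.per_class[cls]["tpr"]
                for cls in sorted(seen)
            }
        )
        seen |= set(cur_e["classes_added"])
    return {"series": series, "drops": drops}


def _base_name(qualified: str) -> str:
    return qualified.split("/", 1)[1] if "/" in qualified else qualified


def transferability_matrix(
    trained: Mapping[str, tuple],
    test_sets: Mapping[str, tuple],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Top-1 accuracy of each domain's model on every domain's test set.

    ``trained[domain] = (model, class_ids)`` and ``test_sets[domain] =
    (X, labels)``.  Labels are translated between registries by base
    class name (the part after the ``domain/`` prefix); a test class
    with no counterpart in a model's registry raises.

    Returns ``(accuracy_grid, counts_grid)`` where the second grid holds
    "n_correct/n_total" strings.
    """
    domains = list(test_sets)
    acc = pd.DataFrame(index=list(trained), columns=domains, dtype=float)
    cnt = pd.DataFrame(index=list(trained), columns=domains, dtype=object)
    for src, (model, class_ids) in trained.items():
        base_of = [_base_name(c) for c in class_ids]
        for dst in domains:
            x, labels = test_sets[dst]
            want = [_base_name(l) for l in labels]
            missing = set(want) - set(base_of)
            if missing:
                raise ValidationError(
                    f"model {src!r} cannot express classes {sorted(missing)}"
                )
            pred = model.predict(x)
            correct = sum(base_of[p] == t for p, t in zip(pred, want))
            acc.loc[src, dst] = correct / len(labels)
            cnt.loc[src, dst] = f"{correct}/{len(labels)}"
    return acc, cnt


def tau_sweep(
    taus: Sequence[float],
    benchmark,
    config,
    seeds: Sequence[int],
) -> pd.DataFrame:
    """Mean +/- sd final top-1 test *error* per temperature.

    Runs the full increment schedule once per (tau, seed); the reported
    error is ``1 - accuracy`` on the cumulative test set after the last
    increment, mirroring the temperature-ablation axes.
    """
    from .trainer import run_sequence

    if any(t <= 0 for t in taus):
        raise ValidationError("temperatures must be positive")
    rows = []
    for tau in taus:
        errs = []
        for seed in seeds:
            cfg = replace(config, temperature=float(tau), seed=int(seed))
            hist = run_sequence(benchmark, cfg)
            errs.append(1.0 - hist.final_accuracy())
        rows.append(
            {
                "tau": float(tau),
                "mean_error": float(np.mean(errs)),
                "sd_error": float(np.std(errs, ddof=1)) if len(errs) > 1 else 0.0,
                "n_seeds": len(errs),
            }
        )
    return pd.DataFrame(rows)


VARIANTS = ("kl_distill", "cross_entropy", "lcl", "lcl_no_md")


def _variant_config(variant: str, config):
    if variant == "lcl":
        return replace(config, objective="lcl", include_md=True)
    if variant == "lcl_no_md":
        return replace(config, objective="lcl", include_md=False)
    if variant == "cross_entropy":
        return replace(config, objective="ce")
    if variant == "kl_distill":
        return replace(config, objective="kl_distill")
    raise ValidationError(f"unknown variant {variant!r}")


def loss_comparison(
    variants: Sequence[str],
    benchmark,
    config,
    seeds: Sequence[int],
) -> pd.DataFrame:
    """Mean final cumulative-test accuracy per training objective.

    Each variant is trained on the identical benchmark and seed list:
    classic KL distillation, plain cross-entropy fine-tuning (no
    teacher, no exemplars), and the continual objective with and without
    its mutual-distillation term.
    """
    from .trainer import run_sequence

    if len(variants) < 1:
        raise ValidationError("need at least one variant")
    rows = []
    for variant in variants:
        accs = []
        for seed in seeds:
            cfg = replace(_variant_config(variant, config), seed=int(seed))
            hist = run_sequence(benchmark, cfg)
            accs.append(hist.final_accuracy())
        rows.append(
            {
                "loss": variant,
                "mean_accuracy": float(np.mean(accs)),
                "sd_accuracy": float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0,
                "per_seed": accs,
            }
        )
    return pd.DataFrame(rows)
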