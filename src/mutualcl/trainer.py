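"""Class-incremental training loop driven by the continual objective.

Protocol per increment:

1. the label space grows (existing class indices are never reordered)
   and the classifier head is widened for the new classes only;
2. a frozen snapshot of the previous model becomes the teacher — its
   temperature-softened outputs are the "old" stream;
3. each epoch, class priors and per-class Gaussian conditionals of the
   joint ``[teacher probs, student probs]`` representation are refitted
   on the union of retained exemplars and the new data (the fits are
   treated as constants within an epoch's steps);
4. batches minimize ``L_CL = L_N + L_MD + L_O`` with ADADELTA, exemplars
   contributing through the mutual-distillation term and new samples
   through the acquisition and coupling terms;
5. after training, a random per-class exemplar subset of the new data is
   retained for later increments.

The first increment has no teacher and degenerates to acquisition-only
training.  Baseline objectives ("ce" plain fine-tuning without teacher
or exemplars, and "kl_distill", classic soft-target distillation over
the teacher's classes) share the same loop for controlled comparisons.
Everything is serial numpy and bit-deterministic given the config seed.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from typing import Literal, Sequence

import numpy as np

from .exceptions import SnapshotError, ValidationError
from .gaussian_bayes import (
    ClassPrior,
    class_prior,
    fit_class_conditionals,
    class_posterior,
    posterior_point_gradient,
)
from .losses import (
    LabelIndicator,
    LossBreakdown,
    PROB_FLOOR,
    continual_loss,
    mutual_distillation_loss,
    new_knowledge_loss,
    old_knowledge_loss,
    soften,
    soften_jacobian_vector,
)
from .model import Adadelta, SoftmaxMLP

__all__ = [
    "LabelSpace",
    "TrainConfig",
    "TeacherSnapshot",
    "RunHistory",
    "snapshot_teacher",
    "expand_label_space",
    "select_exemplars",
    "train_increment",
    "run_sequence",
    "continual_batch",
]


@dataclass
class LabelSpace:
    """Ordered, strictly growing class registry."""

    class_ids: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)  # class -> increment index

    @property
    def width(self) -> int:
        return len(self.class_ids)

    def index(self, labels: Sequence) -> np.ndarray:
        lookup = {c: i for i, c in enumerate(self.class_ids)}
        try:
            return np.asarray([lookup[l] for l in labels], dtype=int)
        except KeyError as exc:
            raise ValidationError(f"label {exc.args[0]!r} not in label space") from exc


def expand_label_space(space: LabelSpace, new_classes: Sequence, increment: int = 0) -> LabelSpace:
    """Append ``new_classes``; existing entries keep their positions."""
    existing = set(space.class_ids)
    incoming = list(new_classes)
    if len(set(incoming)) != len(incoming) or existing & set(incoming):
        raise ValidationError("new classes must be distinct and disjoint from existing")
    return LabelSpace(
        class_ids=[*space.class_ids, *incoming],
        provenance={**space.provenance, **{c: increment for c in incoming}},
    )


@dataclass
class TrainConfig:
    """Hyperparameters of one continual run (defaults follow the published protocol)."""

    epochs: int = 20
    optimizer: str = "adadelta"
    batch_size: int = 16
    temperature: float = 2.0
    exemplars_per_class: int | None = 20  # None means unlimited
    ridge: float = 1e-4
    seed: int = 0
    include_md: bool = True
    md_scale_mode: Literal["inv_tau_sq", "none"] = "inv_tau_sq"
    objective: Literal["lcl", "ce", "kl_distill"] = "lcl"
    # The Gaussian precision scales like 1/ridge, so the coupling term's
    # point gradient can transiently explode before the per-epoch fits
    # settle; rows are clipped to this norm (None = exact gradients).
    md_point_grad_clip: float | None = 5.0
    hidden_dims: tuple = (64,)
    lr: float = 1.0
    rho: float = 0.95
    eps: float = 1e-6
    strict_determinism: bool = True  # backend is serial numpy; always deterministic

    def __post_init__(self) -> None:
        if self.epochs < 0:
            raise ValidationError("epochs must be >= 0")
        if self.temperature <= 0:
            raise ValidationError("temperature must be positive")
        if self.optimizer.lower() != "adadelta":
            raise ValidationError("only the adadelta optimizer is provided")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["hidden_dims"] = list(self.hidden_dims)
        d["exemplars_per_class"] = (
            None if self.exemplars_per_class is None else int(self.exemplars_per_class)
        )
        return d


@dataclass
class TeacherSnapshot:
    """Frozen copy of a trained model plus its label space at snapshot time."""

    model: SoftmaxMLP
    class_ids: list

    @property
    def width(self) -> int:
        return len(self.class_ids)

    def padded_probs(self, x: np.ndarray, temperature: float, width: int) -> np.ndarray:
        """Teacher's softened outputs zero-padded to the current label width.

        Padding columns carry exactly zero probability: the teacher assigns
        no mass to classes it never saw.
        """
        probs = soften(self.model.logits(x), temperature, stream="old").probs
        if width < probs.shape[1]:
            raise ValidationError("current width smaller than teacher width")
        out = np.zeros((probs.shape[0], width))
        out[:, : probs.shape[1]] = probs
        return out


def snapshot_teacher(model: SoftmaxMLP, space: LabelSpace) -> TeacherSnapshot:
    """Deep-copied, frozen replica of ``model``; idempotent."""
    if not getattr(model, "trained", False):
        raise SnapshotError("cannot snapshot an untrained model")
    frozen = model.copy()
    frozen.trained = True
    return TeacherSnapshot(model=frozen, class_ids=list(space.class_ids))


def select_exemplars(
    labels: Sequence,
    per_class_budget: int | None,
    seed: int,
) -> np.ndarray:
    """Indices of a uniform random per-class subset, deterministic given seed.

    ``per_class_budget=None`` (or any budget >= class size) keeps whole
    classes; budget 0 keeps nothing.
    """
    labels_arr = np.asarray(labels, dtype=object)
    if per_class_budget is None or math.isinf(per_class_budget):
        return np.arange(len(labels_arr))
    if per_class_budget < 0:
        raise ValidationError("per_class_budget must be >= 0")
    rng = np.random.default_rng(seed)
    keep: list[np.ndarray] = []
    for cls in dict.fromkeys(labels_arr):
        idx = np.flatnonzero(labels_arr == cls)
        k = min(int(per_class_budget), len(idx))
        if k:
            keep.append(np.sort(rng.choice(idx, size=k, replace=False)))
    return np.concatenate(keep) if keep else np.arange(0)


# ---------------------------------------------------------------------------
# loss-and-gradient kernel


def continual_batch(
    student_logits: np.ndarray,
    label_idx: np.ndarray,
    is_old: np.ndarray,
    teacher_probs: np.ndarray | None,
    teacher_width: int,
    conditionals: dict | None,
    prior: ClassPrior | None,
    config: TrainConfig,
) -> tuple[LossBreakdown, np.ndarray]:
    """Loss breakdown and d(L)/d(student logits) for one batch.

    The Gaussian conditionals, prior and teacher outputs are treated as
    constants; gradients flow through the student's temperature softmax
    only (including the student half of the joint representation inside
    the mutual-distillation posterior).
    """
    z = np.atleast_2d(np.asarray(student_logits, dtype=float))
    n, w = z.shape
    label_idx = np.asarray(label_idx, dtype=int)
    is_old = np.asarray(is_old, dtype=bool)
    tau = config.temperature
    onehot = LabelIndicator.from_indices(label_idx, w)

    if config.objective == "ce":
        p = soften(z, 1.0).probs
        l_n = new_knowledge_loss(onehot, soften(z, 1.0), n)
        d_z = (p - onehot.onehot) / n
        breakdown = continual_loss(l_n, 0.0, 0.0, 1.0, include_md=False)
        return breakdown, d_z

    if config.objective == "kl_distill":
        p1 = soften(z, 1.0).probs
        l_n = new_knowledge_loss(onehot, soften(z, 1.0), n)
        d_z = (p1 - onehot.onehot) / n
        l_distill = 0.0
        if teacher_probs is not None and teacher_width > 0:
            q_t = teacher_probs[:, :teacher_width]
            p_s = soften(z[:, :teacher_width], tau).probs
            ratio = np.where(
                q_t > 0,
                q_t * (np.log(np.maximum(q_t, PROB_FLOOR)) - np.log(np.maximum(p_s, PROB_FLOOR))),
                0.0,
            )
            l_distill = float(np.sum(ratio)) / n
            d_z[:, :teacher_width] += (p_s - q_t) / (n * tau)
        breakdown = continual_loss(l_n, 0.0, l_distill, tau, include_md=False)
        return breakdown, d_z

    # --- the continual objective ---
    soft_new = soften(z, tau, stream="new")
    p_new = soft_new.probs
    d_z = np.zeros_like(z)

    # acquisition over current-increment rows (exemplars feed L_MD only)
    new_rows = ~is_old
    l_n = 0.0
    if new_rows.any():
        l_n = new_knowledge_loss(
            LabelIndicator(onehot.onehot[new_rows]),
            soften(z[new_rows], tau),
            n,
        )
        d_z[new_rows] += (p_new[new_rows] - onehot.onehot[new_rows]) / (n * tau)

    l_o = 0.0
    l_md = 0.0
    if teacher_probs is not None:
        # retention: cross-entropy against the teacher's output, evaluated on
        # rows whose true class existed at snapshot time (the teacher has no
        # mass elsewhere).  Constant w.r.t. the student.
        known = label_idx < teacher_width
        if known.any():
            l_o = old_knowledge_loss(
                LabelIndicator(onehot.onehot[known]),
                soften_probs_passthrough(teacher_probs[known], tau),
                n,
            )
        if config.include_md and conditionals is not None and prior is not None:
            points = np.concatenate([teacher_probs, p_new], axis=1)
            table = class_posterior(conditionals, prior, points)
            old_t = LabelIndicator(onehot.onehot[is_old]) if is_old.any() else None
            new_t = LabelIndicator(onehot.onehot[new_rows])
            l_md = mutual_distillation_loss(
                old_t,
                new_t,
                _slice_table(table, is_old) if is_old.any() else None,
                _slice_table(table, new_rows),
                tau,
                scale_mode=config.md_scale_mode,
            )
            scale = 1.0 / tau**2 if config.md_scale_mode == "inv_tau_sq" else 1.0
            g_point = posterior_point_gradient(conditionals, prior, points, label_idx)
            if config.md_point_grad_clip is not None:
                norms = np.linalg.norm(g_point, axis=1, keepdims=True)
                g_point = g_point * np.minimum(
                    1.0, config.md_point_grad_clip / np.maximum(norms, 1e-12)
                )
            g_new_half = g_point[:, w:]
            d_z += soften_jacobian_vector(p_new, -scale * g_new_half, tau)

    breakdown = continual_loss(l_n, l_md, l_o, tau, include_md=config.include_md)
    if not np.isfinite(breakdown.l_cl):
        raise FloatingPointError(
            f"non-finite continual loss: {breakdown} (batch of {n} rows, "
            f"labels {np.unique(label_idx).tolist()})"
        )
    return breakdown, d_z


def soften_probs_passthrough(probs: np.ndarray, temperature: float):
    """Wrap an already-softened probability matrix as a SoftRepresentation."""
    from .losses import SoftRepresentation

    return SoftRepresentation(probs=probs, temperature=temperature, stream="old")


def _slice_table(table, mask):
    from .gaussian_bayes import PosteriorTable

    return PosteriorTable(
        log_likelihood=table.log_likelihood[mask],
        log_posterior=table.log_posterior[mask],
        class_ids=table.class_ids,
    )


# ---------------------------------------------------------------------------
# increment loop


def train_increment(
    model: SoftmaxMLP,
    teacher: TeacherSnapshot | None,
    new_x: np.ndarray,
    new_y_idx: np.ndarray,
    exemplar_x: np.ndarray | None,
    exemplar_y_idx: np.ndarray | None,
    space: LabelSpace,
    config: TrainConfig,
    increment: int = 0,
) -> tuple[SoftmaxMLP, list[dict]]:
    """Minimize the configured objective for ``config.epochs`` epochs.

    Mutates and returns ``model`` together with a per-step loss log
    (one row per batch: iteration, epoch, step, the four loss scalars
    and the temperature).  With ``epochs=0`` the model is returned
    bitwise unchanged and the log is empty.
    """
    new_x = np.atleast_2d(np.asarray(new_x, dtype=float))
    if new_x.shape[0] == 0:
        raise ValidationError("new_data must be non-empty")
    if config.epochs == 0:
        return model, []

    use_exemplars = (
        config.objective != "ce"
        and exemplar_x is not None
        and len(exemplar_x) > 0
    )
    if use_exemplars:
        union_x = np.concatenate([exemplar_x, new_x], axis=0)
        union_idx = np.concatenate([exemplar_y_idx, new_y_idx])
        union_old = np.concatenate(
            [np.ones(len(exemplar_x), bool), np.zeros(len(new_x), bool)]
        )
    else:
        union_x, union_idx = new_x, np.asarray(new_y_idx, dtype=int)
        union_old = np.zeros(len(new_x), bool)

    w = space.width
    tau = config.temperature
    use_teacher = teacher is not None and config.objective != "ce"
    teacher_probs_union = (
        teacher.padded_probs(union_x, tau, w) if use_teacher else None
    )
    teacher_width = teacher.width if use_teacher else 0

    optimizer = Adadelta(model.parameters(), rho=config.rho, eps=config.eps, lr=config.lr)
    rng = np.random.default_rng([config.seed, increment, 7])
    log: list[dict] = []
    union_labels = [space.class_ids[i] for i in union_idx]

    for epoch in range(config.epochs):
        conditionals = prior = None
        if use_teacher and config.objective == "lcl" and config.include_md:
            student_probs = soften(model.logits(union_x), tau).probs
            prior = class_prior(union_labels, registry=space.class_ids)
            conditionals = fit_class_conditionals(
                teacher_probs_union, student_probs, union_labels, ridge=config.ridge
            )
        order = rng.permutation(len(union_x))
        for step, start in enumerate(range(0, len(order), config.batch_size)):
            rows = order[start : start + config.batch_size]
            logits, cache = model.forward(union_x[rows])
            breakdown, d_logits = continual_batch(
                logits,
                union_idx[rows],
                union_old[rows],
                teacher_probs_union[rows] if teacher_probs_union is not None else None,
                teacher_width,
                conditionals,
                prior,
                config,
            )
            grads = model.backward(cache, d_logits)
            optimizer.step(model.parameters(), grads)
            log.append(breakdown.as_row(increment, epoch, step))
        model.trained = True
    return model, log


@dataclass
class RunHistory:
    """Per-increment record of a full continual run."""

    config: dict
    registry: list
    entries: list  # one dict per increment
    loss_log: list  # flat list of per-step loss rows
    model: SoftmaxMLP | None = None
    label_space: LabelSpace | None = None

    def to_json(self) -> dict:
        return {
            "config": self.config,
            "registry": [str(c) for c in self.registry],
            "entries": [
                {k: v for k, v in e.items() if k not in ("y_true", "y_pred")}
                | {
                    "y_true": [str(t) for t in e["y_true"]],
                    "y_pred": [str(p) for p in e["y_pred"]],
                }
                for e in self.entries
            ],
        }

    def final_accuracy(self) -> float:
        return self.entries[-1]["accuracy"]


def run_sequence(tasks, config: TrainConfig, keep_models: bool = False) -> RunHistory:
    """Drive the whole increment schedule and evaluate after each step.

    After every increment the model is evaluated on the cumulative test
    set of all classes seen so far; the history also accounts for memory
    (items held for training vs. the cumulative training-set size).
    """
    from .evaluation import compute_metrics, confusion_counts  # lazy: avoids cycle

    if not tasks.increments:
        raise ValidationError("task sequence has no increments")
    space = LabelSpace()
    model: SoftmaxMLP | None = None
    teacher: TeacherSnapshot | None = None
    ex_x: np.ndarray | None = None
    ex_y: np.ndarray | None = None
    entries: list[dict] = []
    loss_log: list[dict] = []
    cumulative_train = 0

    for k, inc in enumerate(tasks.increments):
        space = expand_label_space(space, inc.classes, increment=k)
        if model is None:
            model = SoftmaxMLP(
                input_dim=inc.train_x.shape[1],
                n_classes=space.width,
                hidden_dims=config.hidden_dims,
                seed=config.seed,
            )
        else:
            model.widen_head(space.width - model.n_classes)

        new_idx = space.index(inc.train_y)
        n_new = len(inc.train_x)
        use_ex = config.objective != "ce"
        n_memory = n_new + (len(ex_x) if (use_ex and ex_x is not None) else 0)
        cumulative_train += n_new

        model, log = train_increment(
            model,
            teacher if config.objective != "ce" else None,
            inc.train_x,
            new_idx,
            ex_x if use_ex else None,
            ex_y if use_ex else None,
            space,
            config,
            increment=k,
        )
        loss_log.extend(log)
        teacher = snapshot_teacher(model, space)

        if use_ex:
            keep = select_exemplars(
                inc.train_y, config.exemplars_per_class, seed=int(np.random.default_rng([config.seed, k, 11]).integers(2**31))
            )
            kept_x, kept_y = inc.train_x[keep], new_idx[keep]
            ex_x = kept_x if ex_x is None else np.concatenate([ex_x, kept_x])
            ex_y = kept_y if ex_y is None else np.concatenate([ex_y, kept_y])

        test_x, test_y = tasks.cumulative_test(k)
        pred_idx = model.predict(test_x)
        y_pred = [space.class_ids[i] for i in pred_idx]
        counts = confusion_counts(y_pred, test_y, space.class_ids)
        report = compute_metrics(counts)
        entries.append(
            {
                "increment": k,
                "domain": inc.domain,
                "classes_added": list(inc.classes),
                "n_train_new": n_new,
                "items_in_memory": n_memory,
                "cumulative_train_items": cumulative_train,
                "memory_reduction": 1.0 - n_memory / cumulative_train,
                "accuracy": report.acc,
                "macro_f1": report.f1,
                "macro_tpr": report.tpr,
                "macro_tnr": report.tnr,
                "macro_ppv": report.ppv,
                "y_true": list(test_y),
                "y_pred": y_pred,
                "registry_width": space.width,
                "model": model.copy() if keep_models else None,
            }
        )
    return RunHistory(
        config=config.to_dict(),
        registry=list(space.class_ids),
        entries=entries,
        loss_log=loss_log,
        model=model,
        label_space=space,
    )
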