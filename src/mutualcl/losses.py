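"""The continual-learning objective and its component losses.

The combined objective for one batch is

    L_CL = L_N + L_MD + L_O

where

* ``L_N`` (acquisition) is a KL divergence between the true new-task
  label distribution and the student's temperature-softened output,
  averaged over the batch;
* ``L_O`` (retention) is a categorical cross-entropy between the true
  labels and the teacher's ("old" stream) softened output;
* ``L_MD`` (mutual distillation) couples the two streams: it is the sum
  of two cross-entropies of the true labels against the Bayes class
  posterior of the joint representation ``[f_old(x), f_new(x)]`` — one
  sum over the ``n1`` retained old exemplars, one over the ``n2`` new
  samples — scaled by ``1/tau^2``.

The ``1/tau^2`` scale reproduces the published formula, which divides
both the one-hot indicator and the log-posterior by the temperature; the
alternative reading (no scale) is available via ``scale_mode="none"``.
All logarithms are natural; probabilities are floored at ``1e-12``
before any log so early-training one-hot outputs stay finite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .exceptions import ValidationError
from .gaussian_bayes import PosteriorTable

__all__ = [
    "PROB_FLOOR",
    "SoftRepresentation",
    "LabelIndicator",
    "IncrementBatch",
    "LossBreakdown",
    "soften",
    "soften_jacobian_vector",
    "mutual_distillation_loss",
    "old_knowledge_loss",
    "new_knowledge_loss",
    "continual_loss",
]

PROB_FLOOR = 1e-12

LOG_COLUMNS = ["iteration", "epoch", "step", "l_md", "l_o", "l_n", "l_cl", "temperature"]


@dataclass
class SoftRepresentation:
    """Row-stochastic probability matrix produced by a temperature softmax."""

    probs: np.ndarray
    temperature: float
    stream: Literal["old", "new"]
    class_ids: list | None = None

    def __post_init__(self) -> None:
        self.probs = np.atleast_2d(np.asarray(self.probs, dtype=float))
        if self.temperature <= 0:
            raise ValidationError("temperature must be positive")
        if np.any(self.probs < -1e-9):
            raise ValidationError("probabilities must be non-negative")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-6):
            raise ValidationError("rows must sum to 1 (within 1e-6)")


@dataclass
class LabelIndicator:
    """One-hot target matrix aligned with the label registry."""

    onehot: np.ndarray
    stream: Literal["old", "new"] = "new"

    def __post_init__(self) -> None:
        self.onehot = np.atleast_2d(np.asarray(self.onehot, dtype=float))
        if self.onehot.size and not np.all(
            np.isin(self.onehot, (0.0, 1.0))
        ):
            raise ValidationError("indicator entries must be 0 or 1")
        if self.onehot.shape[0] and not np.all(self.onehot.sum(axis=1) == 1):
            raise ValidationError("exactly one 1 per row required")

    @classmethod
    def from_indices(cls, indices: Sequence[int], width: int, stream="new"):
        idx = np.asarray(indices, dtype=int)
        onehot = np.zeros((len(idx), width))
        if len(idx):
            onehot[np.arange(len(idx)), idx] = 1.0
        return cls(onehot=onehot, stream=stream)


@dataclass
class IncrementBatch:
    """Bookkeeping for one optimization batch: n1 old exemplars, n2 new samples."""

    n_old: int
    n_new: int
    batch_size: int

    def __post_init__(self) -> None:
        if self.n_old < 0 or self.n_new < 1 or self.batch_size < 1:
            raise ValidationError("need n_old >= 0, n_new >= 1, batch_size >= 1")


@dataclass
class LossBreakdown:
    """The four scalars of one batch: L_MD, L_O, L_N and their sum L_CL."""

    l_md: float
    l_o: float
    l_n: float
    l_cl: float
    temperature: float

    def as_row(self, iteration: int, epoch: int, step: int) -> dict:
        return {
            "iteration": iteration,
            "epoch": epoch,
            "step": step,
            "l_md": self.l_md,
            "l_o": self.l_o,
            "l_n": self.l_n,
            "l_cl": self.l_cl,
            "temperature": self.temperature,
        }


def soften(
    logits: np.ndarray,
    temperature: float,
    stream: Literal["old", "new"] = "new",
    class_ids: list | None = None,
) -> SoftRepresentation:
    """Temperature softmax: ``p_ij = exp(z_ij / tau) / sum_k exp(z_ik / tau)``.

    Computed with row-max subtraction for numerical stability.  Large
    temperatures flatten the rows toward uniform; ``tau=1`` recovers the
    ordinary softmax.
    """
    if temperature <= 0:
        raise ValidationError("temperature must be positive")
    z = np.atleast_2d(np.asarray(logits, dtype=float))
    if not np.all(np.isfinite(z)):
        raise ValidationError("logits must be finite")
    scaled = z / temperature
    scaled = scaled - scaled.max(axis=1, keepdims=True)
    expz = np.exp(scaled)
    probs = expz / expz.sum(axis=1, keepdims=True)
    return SoftRepresentation(
        probs=probs, temperature=float(temperature), stream=stream, class_ids=class_ids
    )


def soften_jacobian_vector(probs: np.ndarray, grad_probs: np.ndarray, temperature: float) -> np.ndarray:
    """Back-propagate a gradient w.r.t. softmax outputs to the logits.

    For ``p = softmax(z / tau)`` the Jacobian-transpose product is
    ``(p * (g - <g, p>)) / tau`` applied row-wise.
    """
    inner = np.sum(grad_probs * probs, axis=1, keepdims=True)
    return probs * (grad_probs - inner) / temperature


def _floored_log(p: np.ndarray) -> np.ndarray:
    return np.log(np.maximum(p, PROB_FLOOR))


def mutual_distillation_loss(
    old_targets: LabelIndicator | None,
    new_targets: LabelIndicator,
    posterior_old_new: PosteriorTable | None,
    posterior_new_old: PosteriorTable,
    temperature: float,
    scale_mode: Literal["inv_tau_sq", "none"] = "inv_tau_sq",
) -> float:
    """Mutual distillation loss over one batch.

    ``-(scale) * [ sum_j sum_i old_onehot(j,i) log p(t_i | old,new)_j
                 + sum_j sum_i new_onehot(j,i) log p(t_i | new,old)_j ]``

    with ``scale = 1/tau^2`` by default.  The first sum runs over the
    old-exemplar rows (empty on the first increment), the second over the
    current-increment rows; each is a cross-entropy of the true label
    against the joint-representation class posterior.
    """
    if temperature <= 0:
        raise ValidationError("temperature must be positive")
    scale = 1.0 / temperature**2 if scale_mode == "inv_tau_sq" else 1.0

    def stream_term(targets: LabelIndicator | None, table: PosteriorTable | None) -> float:
        if targets is None or targets.onehot.shape[0] == 0:
            return 0.0
        if table is None:
            raise ValidationError("posterior table missing for a non-empty stream")
        onehot = targets.onehot
        if onehot.shape != table.log_posterior.shape:
            raise ValidationError(
                f"targets {onehot.shape} misaligned with posterior "
                f"{table.log_posterior.shape}"
            )
        picked = table.log_posterior[onehot.astype(bool)]
        if np.any(np.isneginf(picked)):
            warnings.warn(
                "one-hot target hit a zero-probability posterior column; "
                "L_MD is +inf",
                RuntimeWarning,
            )
            return np.inf
        return -float(np.sum(picked))

    total = stream_term(old_targets, posterior_old_new) + stream_term(
        new_targets, posterior_new_old
    )
    return scale * total


def old_knowledge_loss(
    new_targets: LabelIndicator,
    old_stream_probs: SoftRepresentation,
    batch_size: int,
) -> float:
    """Retention term: cross-entropy of true labels vs the old-stream output.

    ``-(1/bs) sum_i sum_j onehot(i,j) log old_probs(i,j)``.
    """
    onehot = new_targets.onehot
    probs = old_stream_probs.probs
    if onehot.shape != probs.shape:
        raise ValidationError(
            f"targets {onehot.shape} misaligned with probabilities {probs.shape}"
        )
    if batch_size < 1:
        raise ValidationError("batch_size must be >= 1")
    return -float(np.sum(onehot * _floored_log(probs))) / batch_size


def new_knowledge_loss(
    new_targets: np.ndarray | LabelIndicator,
    new_stream_probs: SoftRepresentation,
    batch_size: int,
) -> float:
    """Acquisition term: averaged KL divergence KL(target || student output).

    ``(1/bs) sum_i sum_j q(i,j) log( q(i,j) / p(i,j) )`` with the
    convention ``0 log(0/p) = 0``.  Targets may be one-hot (the usual
    case, where KL reduces to cross-entropy) or arbitrary row-stochastic
    soft targets.
    """
    q = new_targets.onehot if isinstance(new_targets, LabelIndicator) else np.atleast_2d(
        np.asarray(new_targets, dtype=float)
    )
    p = new_stream_probs.probs
    if q.shape != p.shape:
        raise ValidationError(f"targets {q.shape} misaligned with probabilities {p.shape}")
    if np.any(q < -1e-9) or not np.allclose(q.sum(axis=1), 1.0, atol=1e-6):
        raise ValidationError("target rows must be non-negative and sum to 1")
    if batch_size < 1:
        raise ValidationError("batch_size must be >= 1")
    ratio = np.where(q > 0, q * (_floored_log(q) - _floored_log(p)), 0.0)
    return float(np.sum(ratio)) / batch_size


def continual_loss(
    l_n: float,
    l_md: float,
    l_o: float,
    temperature: float,
    include_md: bool = True,
) -> LossBreakdown:
    """Combine the three terms into ``L_CL = L_N + L_MD + L_O``.

    With ``include_md=False`` the coupling term is ablated (set to 0), the
    configuration used to measure the contribution of mutual distillation.
    """
    l_md_eff = float(l_md) if include_md else 0.0
    return LossBreakdown(
        l_md=l_md_eff,
        l_o=float(l_o),
        l_n=float(l_n),
        l_cl=float(l_n) + l_md_eff + float(l_o),
        temperature=float(temperature),
    )
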