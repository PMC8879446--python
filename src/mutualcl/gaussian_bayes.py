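"""Class-conditional Gaussian modelling of joint old/new representations.

The continual objective couples the teacher ("old") and student ("new")
streams through the class posterior of their *joint* soft representation.
For a sample ``x`` the joint vector is the concatenation
``[f_old(x), f_new(x)]`` of the two temperature-softened probability
vectors.  Per class the joint is modelled with a single multivariate
Gaussian ``N(mu, Sigma)``; Bayes' rule with empirical class priors then
yields a posterior over classes for every sample.

For a Gaussian the joint density equals both chain-rule factorizations
``p(old | new, t) p(new | t)`` and ``p(new | old, t) p(old | t)``, so one
fit per class serves both directions of the coupling.

Soft representations live on the probability simplex, which makes the
sample covariance rank-deficient by construction; a diagonal ridge
(default ``1e-4``) is therefore always added before factorization.  All
densities and posteriors are computed in log space and exponentiated only
at reporting boundaries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.special import logsumexp

from .exceptions import (
    DegenerateCovarianceError,
    EmptySampleError,
    MissingClassError,
    ValidationError,
)

__all__ = [
    "GaussianSummary",
    "ClassPrior",
    "PosteriorTable",
    "fit_gaussian",
    "gaussian_log_density",
    "class_prior",
    "fit_class_conditionals",
    "class_posterior",
]

DEFAULT_RIDGE = 1e-4

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class GaussianSummary:
    """Mean/covariance summary of one class's joint representations.

    The ridge is stored separately from the raw sample covariance and only
    added to the diagonal when the density is evaluated, so the unbiased
    estimate itself is preserved.
    """

    mean: np.ndarray
    covariance: np.ndarray
    count: int
    ridge: float = DEFAULT_RIDGE
    _chol: np.ndarray | None = field(default=None, repr=False, compare=False)
    _logdet: float | None = field(default=None, repr=False, compare=False)

    @property
    def dim(self) -> int:
        return int(self.mean.shape[0])

    def effective_covariance(self) -> np.ndarray:
        return self.covariance + self.ridge * np.eye(self.dim)

    def _factorize(self) -> tuple[np.ndarray, float]:
        """Lower Cholesky factor and log-determinant of the effective covariance."""
        if self._chol is None:
            eff = self.effective_covariance()
            try:
                chol = np.linalg.cholesky(eff)
            except np.linalg.LinAlgError as exc:
                raise DegenerateCovarianceError(
                    "effective covariance is not positive definite; "
                    "increase the ridge"
                ) from exc
            self._chol = chol
            self._logdet = float(2.0 * np.sum(np.log(np.diag(chol))))
        return self._chol, self._logdet  # type: ignore[return-value]

    def log_density(self, points: np.ndarray) -> np.ndarray:
        """Log N(points | mean, covariance + ridge*I), vectorized over rows."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if pts.shape[1] != self.dim:
            raise ValidationError(
                f"point dimension {pts.shape[1]} != summary dimension {self.dim}"
            )
        chol, logdet = self._factorize()
        # Mahalanobis term via triangular solve; never form the inverse.
        z = solve_triangular(chol, (pts - self.mean).T, lower=True)
        maha = np.sum(z * z, axis=0)
        return -0.5 * (self.dim * _LOG_2PI + logdet + maha)

    def density_gradient(self, points: np.ndarray) -> np.ndarray:
        """Gradient of ``log_density`` with respect to each point (row-wise).

        d/dv log N(v | mu, S) = -S^{-1} (v - mu).
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        chol, _ = self._factorize()
        diff = (pts - self.mean).T
        sol = cho_solve((chol, True), diff)
        return -sol.T

    def to_json(self) -> dict:
        return {
            "mean": self.mean.tolist(),
            "covariance": self.covariance.tolist(),
            "count": int(self.count),
            "ridge": float(self.ridge),
        }

    @classmethod
    def from_json(cls, obj: Mapping) -> "GaussianSummary":
        return cls(
            mean=np.asarray(obj["mean"], dtype=float),
            covariance=np.asarray(obj["covariance"], dtype=float),
            count=int(obj["count"]),
            ridge=float(obj["ridge"]),
        )


@dataclass
class ClassPrior:
    """Empirical class prior p(t = t_i) = n_i / s_n."""

    class_ids: list
    counts: np.ndarray
    total: int

    @property
    def probs(self) -> np.ndarray:
        return self.counts / self.total

    def log_probs(self) -> np.ndarray:
        """Log prior; classes with zero count map to -inf."""
        with np.errstate(divide="ignore"):
            return np.log(self.probs)


@dataclass
class PosteriorTable:
    """Per-sample, per-class log-likelihoods and normalized log-posteriors."""

    log_likelihood: np.ndarray
    log_posterior: np.ndarray
    class_ids: list

    @property
    def posterior(self) -> np.ndarray:
        return np.exp(self.log_posterior)

    def to_json(self) -> dict:
        return {
            "log_likelihood": self.log_likelihood.tolist(),
            "log_posterior": self.log_posterior.tolist(),
            "class_ids": [str(c) for c in self.class_ids],
        }

    @classmethod
    def from_json(cls, obj: Mapping) -> "PosteriorTable":
        return cls(
            log_likelihood=np.asarray(obj["log_likelihood"], dtype=float),
            log_posterior=np.asarray(obj["log_posterior"], dtype=float),
            class_ids=list(obj["class_ids"]),
        )


def fit_gaussian(samples: np.ndarray, ridge: float = DEFAULT_RIDGE) -> GaussianSummary:
    """Fit mean and unbiased sample covariance to ``samples`` (n x d).

    With a single sample the covariance is the zero matrix and a positive
    ridge is required for the density to exist.
    """
    arr = np.atleast_2d(np.asarray(samples, dtype=float))
    if arr.size == 0 or arr.shape[0] == 0:
        raise EmptySampleError("cannot fit a Gaussian to zero samples")
    if not np.all(np.isfinite(arr)):
        raise ValidationError("samples contain non-finite entries")
    if ridge < 0:
        raise ValidationError("ridge must be non-negative")
    n, d = arr.shape
    mean = arr.mean(axis=0)
    if n >= 2:
        cov = np.cov(arr, rowvar=False, ddof=1).reshape(d, d)
    else:
        if ridge == 0:
            raise DegenerateCovarianceError(
                "a single sample with ridge=0 has no defined density"
            )
        cov = np.zeros((d, d))
    return GaussianSummary(mean=mean, covariance=cov, count=n, ridge=float(ridge))


def gaussian_log_density(point: np.ndarray, summary: GaussianSummary) -> float | np.ndarray:
    """Log multivariate-normal density of ``point`` under ``summary``.

    Accepts a single vector (returns a scalar) or an n x d matrix
    (returns a length-n array).
    """
    pt = np.asarray(point, dtype=float)
    single = pt.ndim == 1
    out = summary.log_density(pt)
    return float(out[0]) if single else out


def class_prior(labels: Sequence, registry: Sequence | None = None) -> ClassPrior:
    """Empirical prior over classes.

    Class order is first-seen order, optionally seeded by an explicit
    ``registry``: registry classes keep their positions (zero counts
    allowed), labels outside the registry are appended in first-seen order.
    """
    labels = list(labels)
    if not labels:
        raise ValidationError("label list is empty")
    order: list = list(registry) if registry is not None else []
    seen = set(order)
    for lab in labels:
        if lab not in seen:
            order.append(lab)
            seen.add(lab)
    index = {c: i for i, c in enumerate(order)}
    counts = np.zeros(len(order), dtype=int)
    for lab in labels:
        counts[index[lab]] += 1
    return ClassPrior(class_ids=order, counts=counts, total=len(labels))


def fit_class_conditionals(
    old_reps: np.ndarray,
    new_reps: np.ndarray,
    labels: Sequence,
    ridge: float = DEFAULT_RIDGE,
) -> dict:
    """One joint Gaussian per class on the concatenated representations.

    ``old_reps`` (n x w_old) and ``new_reps`` (n x w_new) must be
    row-aligned with ``labels``.  Classes are fitted on the concatenation
    ``[old, new]`` of their samples.
    """
    old = np.atleast_2d(np.asarray(old_reps, dtype=float))
    new = np.atleast_2d(np.asarray(new_reps, dtype=float))
    if old.shape[1] == 0 or new.shape[1] == 0:
        raise ValidationError("stream width must be >= 1")
    if old.shape[0] != new.shape[0] or old.shape[0] != len(labels):
        raise ValidationError("old_reps, new_reps and labels must be row-aligned")
    joint = np.concatenate([old, new], axis=1)
    labels_arr = np.asarray(labels, dtype=object)
    out: dict = {}
    for cls in dict.fromkeys(labels):  # first-seen order
        mask = labels_arr == cls
        if not mask.any():
            raise MissingClassError(cls)
        out[cls] = fit_gaussian(joint[mask], ridge=ridge)
    return out


def class_posterior(
    conditionals: Mapping,
    prior: ClassPrior,
    points: np.ndarray,
) -> PosteriorTable:
    """Bayes posterior over classes for each row of ``points``.

    ``log_posterior[i, j] = log_lik[i, j] + log prior_j - logsumexp_k(...)``,
    all in log space.  Classes with zero prior mass receive a -inf column
    and are skipped when evaluating conditionals (they may legitimately
    lack one).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    n = pts.shape[0]
    w = len(prior.class_ids)
    log_prior = prior.log_probs()
    log_lik = np.full((n, w), -np.inf)
    for j, cls in enumerate(prior.class_ids):
        if prior.counts[j] == 0:
            continue
        if cls not in conditionals:
            raise MissingClassError(cls)
        log_lik[:, j] = conditionals[cls].log_density(pts)
    joint = log_lik + log_prior[np.newaxis, :]
    norm = logsumexp(joint, axis=1, keepdims=True)
    log_post = joint - norm
    return PosteriorTable(
        log_likelihood=log_lik, log_posterior=log_post, class_ids=list(prior.class_ids)
    )


def posterior_point_gradient(
    conditionals: Mapping,
    prior: ClassPrior,
    points: np.ndarray,
    true_class_index: np.ndarray,
) -> np.ndarray:
    """Row-wise gradient of the true class's log-posterior w.r.t. the point.

    For sample i with true class c:
    ``d log p(c | v) / dv = s_c(v) - sum_k p(k | v) s_k(v)`` where
    ``s_k(v) = d log N(v | mu_k, Sigma_k) / dv``.  Used by the trainer to
    push joint representations toward their class-conditional mode while
    treating the fitted Gaussians as constants.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    n, d = pts.shape
    table = class_posterior(conditionals, prior, pts)
    post = table.posterior
    grads = np.zeros((n, len(prior.class_ids), d))
    for j, cls in enumerate(prior.class_ids):
        if prior.counts[j] == 0:
            continue
        grads[:, j, :] = conditionals[cls].density_gradient(pts)
    expected = np.einsum("nk,nkd->nd", post, grads)
    own = grads[np.arange(n), np.asarray(true_class_index, dtype=int), :]
    return own - expected


def conditionals_to_json(conditionals: Mapping) -> str:
    return json.dumps({str(k): v.to_json() for k, v in conditionals.items()})


def conditionals_from_json(payload: str) -> dict:
    raw = json.loads(payload)
    return {k: GaussianSummary.from_json(v) for k, v in raw.items()}
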