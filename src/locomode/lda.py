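"""Linear discriminant analysis, implemented from its defining formulas.

The classifier models each locomotion mode ``k`` as a Gaussian with its own
mean ``mu_k`` and a covariance ``Sigma`` pooled across classes.  The
discriminant score of window ``x`` is the linear function

    delta_k(x) = x^T Sigma^-1 mu_k - 1/2 mu_k^T Sigma^-1 mu_k + log pi_k

and the predicted mode is ``argmax_k delta_k(x)``, ties broken by the
canonical class order (W, CO, SS, COS, SSS; unknown labels after, sorted).

Because the feature space is wide relative to the number of training trials
(six features per channel over tens of channels versus tens of trials), the
pooled covariance is regularized by diagonal-target shrinkage

    Sigma_lambda = (1 - lambda) Sigma + lambda diag(Sigma),

default ``lambda = 0.01``.  Features are standardized (center/scale learned
on the training split only) before fitting, so channels in m/s^2, deg/s and
deg contribute on a common scale; priors default to uniform over the classes
present, since trial lengths — hence window counts — differ by task.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .core import TASKS

DEFAULT_SHRINKAGE = 0.01

#: floor applied to zero shrinkage-target diagonal entries (relative to the
#: largest one) so degenerate constant features cannot break positive
#: definiteness on otherwise valid input
_DIAG_FLOOR = 1e-12


@dataclass
class Standardizer:
    """Per-feature center/scale learned on the training split."""

    center: np.ndarray
    scale: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.center) / self.scale

    @classmethod
    def fit(cls, X: np.ndarray) -> "Standardizer":
        center = X.mean(axis=0)
        scale = X.std(axis=0)
        scale = np.where(scale > 0, scale, 1.0)
        return cls(center=center, scale=scale)


def canonical_class_order(labels) -> list:
    """Classes present, canonical task order first, unknown labels sorted after."""
    present = list(dict.fromkeys(labels))
    known = [c for c in TASKS if c in present]
    other = sorted((c for c in present if c not in TASKS), key=str)
    return known + other


@dataclass
class DiscriminantModel:
    """A fitted linear discriminant: class means, shrunk pooled covariance,
    its inverse, priors and the training standardizer.

    ``means`` and ``pooled_cov`` live in standardized feature space.
    """

    classes: list
    means: np.ndarray          # (K, p)
    pooled_cov: np.ndarray     # (p, p), after shrinkage
    precision: np.ndarray      # inverse of pooled_cov
    priors: np.ndarray         # (K,)
    shrinkage: float
    standardizer: Standardizer

    @property
    def n_features(self) -> int:
        return int(self.means.shape[1])

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "classes": [str(c) for c in self.classes],
            "means": self.means.tolist(),
            "pooled_cov": self.pooled_cov.tolist(),
            "priors": self.priors.tolist(),
            "shrinkage": self.shrinkage,
            "standardizer": {
                "center": self.standardizer.center.tolist(),
                "scale": self.standardizer.scale.tolist(),
            },
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "DiscriminantModel":
        cov = np.asarray(d["pooled_cov"], dtype=float)
        return cls(
            classes=list(d["classes"]),
            means=np.asarray(d["means"], dtype=float),
            pooled_cov=cov,
            precision=_invert_spd(cov, d["shrinkage"]),
            priors=np.asarray(d["priors"], dtype=float),
            shrinkage=float(d["shrinkage"]),
            standardizer=Standardizer(
                center=np.asarray(d["standardizer"]["center"], dtype=float),
                scale=np.asarray(d["standardizer"]["scale"], dtype=float),
            ),
        )

    @classmethod
    def from_json(cls, path) -> "DiscriminantModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def shrink_covariance(cov: np.ndarray, lam: float) -> np.ndarray:
    """Diagonal-target shrinkage ``(1 - lam) Sigma + lam diag(Sigma)``."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"shrinkage must lie in [0, 1], got {lam}")
    d = np.diag(cov).copy()
    floor = _DIAG_FLOOR * max(d.max(), 1.0)
    d = np.where(d > floor, d, floor)
    out = (1.0 - lam) * cov + lam * np.diag(d)
    # keep exact symmetry for the Cholesky factorization
    return (out + out.T) / 2.0


def _invert_spd(cov: np.ndarray, lam: float) -> np.ndarray:
    try:
        c, low = linalg.cho_factor(cov)
        return linalg.cho_solve((c, low), np.eye(cov.shape[0]))
    except linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "pooled covariance is singular (rank-deficient training data or a "
            "zero-variance feature); increase the shrinkage lambda above 0"
        ) from exc


def fit_lda(
    X: np.ndarray,
    y,
    shrinkage: float = DEFAULT_SHRINKAGE,
    priors: np.ndarray | None = None,
) -> DiscriminantModel:
    """Fit the discriminant on training windows.

    ``X`` is ``(n, p)``, ``y`` the per-window class labels.  The pooled
    within-class covariance uses the ``N - K`` denominator.  Priors default
    to uniform over the classes present.  Fitting is deterministic.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError(f"X shape {X.shape} does not match {y.shape[0]} labels")
    classes = canonical_class_order(y)
    if len(classes) < 2:
        raise ValueError(f"need >= 2 classes to fit a discriminant, got {classes}")
    std = Standardizer.fit(X)
    Z = std.transform(X)
    n, p = Z.shape
    K = len(classes)
    means = np.empty((K, p))
    scatter = np.zeros((p, p))
    for i, c in enumerate(classes):
        Zc = Z[y == c]
        if Zc.shape[0] < 2:
            raise ValueError(
                f"class {c!r} has {Zc.shape[0]} training window(s); "
                "need >= 2 per class"
            )
        means[i] = Zc.mean(axis=0)
        R = Zc - means[i]
        scatter += R.T @ R
    cov = shrink_covariance(scatter / (n - K), shrinkage)
    if priors is None:
        priors = np.full(K, 1.0 / K)
    else:
        priors = np.asarray(priors, dtype=float)
        if priors.shape != (K,) or not np.isclose(priors.sum(), 1.0):
            raise ValueError("priors must be one probability per class, summing to 1")
    return DiscriminantModel(
        classes=classes,
        means=means,
        pooled_cov=cov,
        precision=_invert_spd(cov, shrinkage),
        priors=priors,
        shrinkage=shrinkage,
        standardizer=std,
    )


def discriminant_scores(model: DiscriminantModel, X: np.ndarray) -> np.ndarray:
    """``delta_k(x)`` for every row and class; shape ``(n, K)``."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match model ({model.n_features})"
        )
    Z = model.standardizer.transform(X)
    W = model.precision @ model.means.T                     # (p, K)
    b = -0.5 * np.einsum("kp,pk->k", model.means, W) + np.log(model.priors)
    return Z @ W + b


def discriminant_score(model: DiscriminantModel, x: np.ndarray, k) -> float:
    """``delta_k(x)`` for one window and one class label."""
    return float(discriminant_scores(model, x)[0, model.classes.index(k)])


def predict(model: DiscriminantModel, X: np.ndarray) -> np.ndarray:
    """Predicted class per row; ties resolve to the earlier class in
    canonical order (argmax returns the first maximum)."""
    scores = discriminant_scores(model, X)
    idx = scores.argmax(axis=1)
    return np.asarray([model.classes[i] for i in idx], dtype=object)
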