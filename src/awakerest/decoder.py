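"""Sparse logistic-regression orientation decoder (automatic relevance
determination).

The classifier is a Bernoulli logistic regression with an independent
zero-mean Gaussian prior on each voxel weight, N(0, 1/alpha_j).  The
per-weight precisions alpha_j are learned from the data by iterating

* a MAP (Laplace) fit of the weights at fixed precisions, via
  Newton/IRLS on the penalized log-likelihood, and
* the MacKay evidence update alpha_j <- gamma_j / w_j^2, with
  gamma_j = 1 - alpha_j * Sigma_jj the effective number of well-determined
  parameters and Sigma the inverse Hessian at the MAP point.

Voxels whose precision exceeds ``prune_threshold`` are pruned: their
weights are set exactly to zero and they drop out of subsequent updates.
The surviving voxels are the "relevant" ones; the fit is deterministic
(weights start at zero, precisions at one) so no random seed is involved.

The bias is unpenalized.  Classes are encoded with the positive class
fixed at fit time, and all downstream "probability of orientation X"
queries select the proper column of :func:`predict_proba` rather than
refitting.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .preprocess import SampleMatrix

__all__ = [
    "ARDLogisticModel",
    "CVResult",
    "fit",
    "predict_proba",
    "prob_of",
    "cross_validate_loro",
    "combine_rois",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ARDLogisticModel:
    """A fitted sparse decoder.

    ``weights`` is full-length over the trained voxel set, with exact
    zeros for pruned voxels; ``relevance`` holds the final precision of
    every voxel (pruned voxels have relevance above the prune threshold);
    ``retained_index`` are the positions of voxels that survived pruning.
    ``class_labels`` is (negative class, positive class): the model's
    probability column 1 is P(positive class).
    """

    weights: np.ndarray
    bias: float
    relevance: np.ndarray
    retained_index: np.ndarray
    voxel_ids: np.ndarray
    class_labels: tuple
    n_iterations: int
    converged: bool

    @property
    def n_retained(self) -> int:
        return int(self.retained_index.size)

    def decision_function(self, data: np.ndarray) -> np.ndarray:
        data = np.asarray(data, dtype=float)
        return data @ self.weights + self.bias


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _map_fit(
    X: np.ndarray,
    y: np.ndarray,
    alpha: np.ndarray,
    w: np.ndarray,
    max_newton: int = 50,
    gtol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray]:
    """Newton/IRLS MAP fit at fixed precisions.

    ``X`` includes the bias column last; ``alpha`` has a zero entry for
    the bias.  Returns the MAP weights and the posterior covariance
    (inverse Hessian) at the mode.
    """
    n, d = X.shape
    A = np.diag(alpha)
    for _ in range(max_newton):
        p = _sigmoid(X @ w)
        g = X.T @ (y - p) - alpha * w
        if np.max(np.abs(g)) < gtol:
            break
        r = np.maximum(p * (1.0 - p), 1e-10)
        H = (X.T * r) @ X + A
        # damped Newton: halve the step while the objective worsens
        step = np.linalg.solve(H, g)
        obj0 = _penalized_nll(X, y, alpha, w)
        t = 1.0
        for _ in range(20):
            w_new = w + t * step
            if _penalized_nll(X, y, alpha, w_new) <= obj0 + 1e-12:
                break
            t *= 0.5
        w = w_new
    p = _sigmoid(X @ w)
    r = np.maximum(p * (1.0 - p), 1e-10)
    H = (X.T * r) @ X + np.diag(alpha)
    sigma = np.linalg.inv(H)
    return w, sigma


def _penalized_nll(X, y, alpha, w) -> float:
    z = X @ w
    # log(1 + exp(-|z|)) + max(0, -z*y') form, numerically stable
    ll = y @ z - np.sum(np.logaddexp(0.0, z))
    return -ll + 0.5 * float(alpha @ (w * w))


def fit(
    samples: SampleMatrix,
    prune_threshold: float = 1e8,
    tol: float = 1e-5,
    max_iter: int = 500,
    positive_label=None,
) -> ARDLogisticModel:
    """Fit the ARD logistic decoder to labeled trial samples.

    The positive class defaults to the lexicographically larger label
    (for the orientation labels "135"/"45" that makes "45" the positive
    class).  Raises on single-class input; if the evidence iteration does
    not converge within ``max_iter`` the model is returned with
    ``converged=False`` and a warning.
    """
    if samples.labels is None:
        raise ValueError("samples must carry class labels")
    classes = np.unique(samples.labels)
    if classes.size != 2:
        raise ValueError(f"need exactly 2 classes, got {classes.tolist()}")
    if positive_label is None:
        positive_label = classes[-1]
    elif positive_label not in classes:
        raise ValueError(f"positive_label {positive_label!r} not among {classes}")
    negative_label = classes[classes != positive_label][0]
    y = (samples.labels == positive_label).astype(float)
    if min(y.sum(), (1 - y).sum()) < 2:
        raise ValueError("need at least 2 samples per class")

    X_vox = np.asarray(samples.data, dtype=float)
    n, d = X_vox.shape
    X = np.hstack([X_vox, np.ones((n, 1))])

    # deterministic initialization: weights zero, precisions one
    alpha = np.ones(d + 1)
    alpha[-1] = 0.0  # unpenalized bias
    w = np.zeros(d + 1)
    active = np.ones(d + 1, dtype=bool)

    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        w_prev = w.copy()
        idx = np.flatnonzero(active)
        w_a, sigma = _map_fit(X[:, idx], y, alpha[idx], w[idx])
        w = np.zeros(d + 1)
        w[idx] = w_a

        # MacKay evidence update of the voxel precisions (bias excluded)
        gamma = 1.0 - alpha[idx] * np.diag(sigma)
        new_alpha = alpha.copy()
        vox = idx[idx < d]
        gv = gamma[idx < d]
        wv = w[vox]
        with np.errstate(divide="ignore", over="ignore"):
            new_alpha[vox] = np.where(
                wv * wv > 0, np.maximum(gv, 1e-12) / np.maximum(wv * wv, 1e-300),
                np.inf,
            )
        alpha = new_alpha

        # prune voxels whose precision exploded
        prune = active.copy()
        prune[:d] &= alpha[:d] > prune_threshold
        prune[-1] = False
        if prune.any():
            active[prune] = False
            w[prune] = 0.0
            alpha[prune] = np.inf

        if np.max(np.abs(w - w_prev)) < tol:
            converged = True
            break

    if not converged:
        warnings.warn(
            f"ARD decoder did not converge within {max_iter} iterations",
            RuntimeWarning,
            stacklevel=2,
        )

    retained = np.flatnonzero(active[:d])
    return ARDLogisticModel(
        weights=w[:d],
        bias=float(w[-1]),
        relevance=alpha[:d],
        retained_index=retained,
        voxel_ids=np.asarray(samples.voxel_ids),
        class_labels=(negative_label, positive_label),
        n_iterations=n_iter,
        converged=converged,
    )


def _align(model: ARDLogisticModel, samples: SampleMatrix) -> np.ndarray:
    """Columns of ``samples`` reordered to the model's voxel set."""
    if samples.n_voxels == model.voxel_ids.size and np.array_equal(
        samples.voxel_ids, model.voxel_ids
    ):
        return samples.data
    pos = {v: i for i, v in enumerate(samples.voxel_ids.tolist())}
    try:
        cols = [pos[v] for v in model.voxel_ids.tolist()]
    except KeyError as err:
        raise ValueError(
            f"sample voxel set is missing model voxel {err.args[0]!r}"
        ) from err
    return samples.data[:, cols]


def predict_proba(model: ARDLogisticModel, samples: SampleMatrix) -> np.ndarray:
    """Per-sample class probabilities, columns ordered as ``class_labels``.

    The sample voxel set must contain every voxel the model was trained
    on; the two columns sum to one.
    """
    X = _align(model, samples)
    p_pos = _sigmoid(model.decision_function(X))
    return np.column_stack([1.0 - p_pos, p_pos])


def prob_of(model: ARDLogisticModel, samples: SampleMatrix, label) -> np.ndarray:
    """Per-sample probability of a specific orientation label."""
    probs = predict_proba(model, samples)
    labels = list(model.class_labels)
    if label not in labels:
        raise ValueError(f"label {label!r} not among model classes {labels}")
    return probs[:, labels.index(label)]


@dataclass(frozen=True)
class CVResult:
    """Leave-one-run-out cross-validation of the decoder."""

    fold_run_ids: np.ndarray
    fold_accuracy: np.ndarray
    fold_probability: np.ndarray  # mean probability assigned to the true class
    single_class_folds: tuple = ()

    @property
    def n_folds(self) -> int:
        return int(self.fold_run_ids.size)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracy))

    @property
    def mean_probability(self) -> float:
        return float(np.mean(self.fold_probability))


def cross_validate_loro(samples: SampleMatrix, **fit_kwargs) -> CVResult:
    """Leave-one-run-out CV: retrain on all runs but one, test on that run.

    With the default ten-run design this is the study's 10-fold
    cross-validation.  A test run containing a single class is still
    scored but flagged in ``single_class_folds``.
    """
    runs = np.unique(samples.run_ids)
    if runs.size < 2:
        raise ValueError("need at least 2 runs for leave-one-run-out CV")
    accs, probs, flagged = [], [], []
    for run in runs:
        test = samples.run_ids == run
        train = SampleMatrix(
            data=samples.data[~test],
            labels=samples.labels[~test],
            run_ids=samples.run_ids[~test],
            voxel_ids=samples.voxel_ids,
        )
        model = fit(train, **fit_kwargs)
        test_m = SampleMatrix(
            data=samples.data[test],
            labels=samples.labels[test],
            run_ids=samples.run_ids[test],
            voxel_ids=samples.voxel_ids,
        )
        if np.unique(test_m.labels).size < 2:
            flagged.append(run)
        p = predict_proba(model, test_m)
        truth = (test_m.labels == model.class_labels[1]).astype(int)
        pred = (p[:, 1] >= 0.5).astype(int)
        accs.append(float(np.mean(pred == truth)))
        probs.append(float(np.mean(np.where(truth == 1, p[:, 1], p[:, 0]))))
    return CVResult(
        fold_run_ids=runs,
        fold_accuracy=np.array(accs),
        fold_probability=np.array(probs),
        single_class_folds=tuple(flagged),
    )


def combine_rois(roi_samples: dict[str, SampleMatrix] | list[SampleMatrix]) -> SampleMatrix:
    """Voxel-wise concatenation of ROI sample matrices (e.g. V1-V3).

    All ROIs must share the sample axis (labels and run ids); duplicate
    voxel ids are rejected.
    """
    mats = list(roi_samples.values()) if isinstance(roi_samples, dict) else list(roi_samples)
    if not mats:
        raise ValueError("need at least one ROI")
    first = mats[0]
    for m in mats[1:]:
        if m.n_samples != first.n_samples or not np.array_equal(
            m.run_ids, first.run_ids
        ):
            raise ValueError("ROIs disagree on the sample axis")
        same_labels = (m.labels is None) == (first.labels is None) and (
            m.labels is None or np.array_equal(m.labels, first.labels)
        )
        if not same_labels:
            raise ValueError("ROIs disagree on the sample labels")
    voxel_ids = np.concatenate([m.voxel_ids for m in mats])
    if np.unique(voxel_ids).size != voxel_ids.size:
        raise ValueError("duplicate voxel ids across ROIs")
    return SampleMatrix(
        data=np.hstack([m.data for m in mats]),
        labels=first.labels,
        run_ids=first.run_ids,
        voxel_ids=voxel_ids,
    )
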