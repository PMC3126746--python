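"""Sample classification from fitted model parameters.

Each fitted sample is reduced to a feature vector of joint prior state
proportions per pair class — omega[k1] * T[k1, k2] for every allowed joint
state, 4 + 9 + 9 + 6 = 28 values for a full model — and samples are
classified to the group minimizing a diagonal Mahalanobis distance,

    d(i, g) = sum_t (nu_ti - mu_tg)^2 / sigma^2_tg,

where mu_tg and sigma^2_tg are the per-feature empirical mean and variance
over group g's samples, excluding sample i itself when i belongs to g
(leave-one-out).  Diagonal covariance is deliberate: group sizes of about
six samples cannot support a full covariance estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .model_core import PAIR_CLASSES, SampleModel, allowed_states

_VAR_FLOOR = 1e-8  # guards division by zero for near-constant features


@dataclass
class FeatureVector:
    """Ordered per-pair-class mixture-proportion features of one sample."""

    sample_id: str
    names: list[str]
    values: np.ndarray


def model_feature_vector(sm: SampleModel, joint: bool = True) -> FeatureVector:
    """Mixture-proportion features of a fitted sample model.

    With ``joint=True`` (default) the features are the joint prior
    proportions omega[k1]*T[k1,k2] of every allowed joint state of every pair
    class; they sum to 1 within each class.  With ``joint=False`` only the
    initial-state proportions omega are used.
    """
    names: list[str] = []
    values: list[float] = []
    for pc in PAIR_CLASSES:
        if pc not in sm.pair_models:
            continue
        pm = sm.pair_models[pc]
        if joint:
            prior = pm.joint_prior()
            for i, k1 in enumerate(pm.states1):
                for j, k2 in enumerate(pm.states2):
                    names.append(f"{pc}:{k1}{k2}")
                    values.append(float(prior[i, j]))
        else:
            for i, k1 in enumerate(pm.states1):
                names.append(f"{pc}:{k1}")
                values.append(float(pm.omega_init[i]))
    return FeatureVector(sm.sample_id, names, np.asarray(values))


def features_to_frame(features: list[FeatureVector]) -> pd.DataFrame:
    """Stack feature vectors into a samples x features table."""
    if not features:
        raise ValueError("no feature vectors")
    names = features[0].names
    for f in features[1:]:
        if f.names != names:
            raise ValueError(
                f"feature name mismatch between samples "
                f"{features[0].sample_id} and {f.sample_id}"
            )
    return pd.DataFrame(
        [f.values for f in features],
        index=[f.sample_id for f in features],
        columns=names,
    )


def _group_moments(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    var = X.var(axis=0, ddof=1) if len(X) > 1 else np.zeros(X.shape[1])
    return mu, var


def _floored(var: np.ndarray) -> np.ndarray:
    if np.any(var < _VAR_FLOOR):
        warnings.warn(
            "near-zero within-group variance; flooring for Mahalanobis distance",
            stacklevel=3,
        )
    return np.maximum(var, _VAR_FLOOR)


def mahalanobis_loo_classify(
    features, labels
) -> tuple[np.ndarray, pd.DataFrame]:
    """Leave-one-out Mahalanobis classification of samples.

    ``features`` is a samples x features array/DataFrame or a list of
    :class:`FeatureVector`; ``labels`` the true group per sample.  Each
    sample is assigned to the group with the smallest diagonal Mahalanobis
    distance, recomputing its own group's mean and variance without it.
    Returns the predicted labels and a confusion matrix (rows = true,
    columns = predicted, groups in sorted label order; argmin ties break
    toward the first group in that order).
    """
    if isinstance(features, list) and features and isinstance(features[0], FeatureVector):
        features = features_to_frame(features)
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if X.shape[0] != len(y):
        raise ValueError("features and labels disagree on sample count")
    groups = np.array(sorted(pd.unique(y)))
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    counts = {g: int(np.sum(y == g)) for g in groups}
    for g, c in counts.items():
        if c < 3:
            warnings.warn(
                f"group {g!r} has only {c} samples; leave-one-out variance "
                "rests on fewer than 2 members",
                stacklevel=2,
            )

    n = X.shape[0]
    dist = np.empty((n, len(groups)))
    for gi, g in enumerate(groups):
        members = np.flatnonzero(y == g)
        Xg = X[members]
        mu_all, var_all = _group_moments(Xg)
        var_all = _floored(var_all)
        d = ((X - mu_all) ** 2 / var_all).sum(axis=1)
        # leave-one-out correction for the group's own members
        for i in members:
            others = Xg[members != i]
            mu, var = _group_moments(others)
            var = _floored(var)
            d[i] = float(((X[i] - mu) ** 2 / var).sum())
        dist[:, gi] = d

    pred = groups[np.argmin(dist, axis=1)]
    confusion = pd.DataFrame(0, index=groups, columns=groups)
    for t, p in zip(y, pred):
        confusion.loc[t, p] += 1
    return pred, confusion


class MahalanobisClassifier(BaseEstimator, ClassifierMixin):
    """Nearest-group classifier under diagonal Mahalanobis distance.

    ``fit`` stores per-group feature means and variances; ``predict``
    assigns each sample to the closest group.  For the transductive
    leave-one-out protocol on the training cohort itself use
    :meth:`loo_predict` (equivalent to :func:`mahalanobis_loo_classify`).

    Parameters
    ----------
    var_floor : float
        Lower bound applied to per-feature group variances.
    """

    def __init__(self, var_floor: float = _VAR_FLOOR):
        self.var_floor = var_floor

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != len(y):
            raise ValueError("X must be 2-D with one row per label")
        self.classes_ = np.array(sorted(pd.unique(y)))
        self.means_ = np.stack([X[y == g].mean(axis=0) for g in self.classes_])
        self.variances_ = np.stack(
            [
                np.maximum(
                    X[y == g].var(axis=0, ddof=1)
                    if np.sum(y == g) > 1
                    else np.zeros(X.shape[1]),
                    self.var_floor,
                )
                for g in self.classes_
            ]
        )
        self.X_, self.y_ = X, y
        return self

    def decision_distances(self, X) -> np.ndarray:
        check_is_fitted(self, "classes_")
        X = np.asarray(X, dtype=float)
        return np.stack(
            [
                ((X - self.means_[gi]) ** 2 / self.variances_[gi]).sum(axis=1)
                for gi in range(len(self.classes_))
            ],
            axis=1,
        )

    def predict(self, X):
        return self.classes_[np.argmin(self.decision_distances(X), axis=1)]

    def loo_predict(self):
        """Leave-one-out predictions for the training samples."""
        check_is_fitted(self, "classes_")
        pred, _ = mahalanobis_loo_classify(self.X_, self.y_)
        return pred
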