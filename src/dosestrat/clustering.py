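"""Bayesian Gaussian mixture stratification of the dose feature matrix.

Patients are standardized in feature space and fit with a 3-component
variational Bayesian Gaussian mixture (Dirichlet-process weight prior,
full covariances).  The high-dose (HD) component is the one whose members
have the highest average per-patient sum of organ mean doses, computed in
raw Gy; it is the candidate high-risk stratum.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.mixture import BayesianGaussianMixture

from .dose_features import DoseFeatureMatrix, FeatureSpec, mean_dose_sum

log = logging.getLogger("dosestrat")


@dataclass
class ClusterModel:
    """A fitted mixture over dose features plus the HD-component identity.

    Geometry (means/covariances) lives in standardized feature space;
    ``scaler_mean``/``scaler_scale`` map back to Gy.  HD identification is
    done in raw Gy via mean doses.
    """

    n_components: int
    feature_names: list[str]
    weights: np.ndarray
    means: np.ndarray
    covariances: np.ndarray
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    labels: pd.Series                      # patient -> component id
    seed: int
    hd_cluster: int | None = None
    cluster_mean_dose_sum: dict[int, float] = field(default_factory=dict)
    converged: bool = True
    _estimator: BayesianGaussianMixture | None = None

    # -- posterior machinery -------------------------------------------------
    def predict(self, x: np.ndarray) -> np.ndarray:
        """Component of maximum posterior responsibility (ties -> lower id)."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != len(self.feature_names):
            raise ValueError(
                f"feature dimension {x.shape[1]} != model dimension "
                f"{len(self.feature_names)}"
            )
        z = (x - self.scaler_mean) / self.scaler_scale
        resp = self._estimator.predict_proba(z)
        return np.argmax(resp, axis=1)

    def hd_membership(self) -> pd.Series:
        if self.hd_cluster is None:
            raise RuntimeError("HD cluster not identified yet")
        return (self.labels == self.hd_cluster).rename("hd")

    # -- serialization -------------------------------------------------------
    def to_json(self, path) -> None:
        payload = {
            "n_components": self.n_components,
            "feature_names": self.feature_names,
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "covariances": self.covariances.tolist(),
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_scale": self.scaler_scale.tolist(),
            "labels": {str(k): int(v) for k, v in self.labels.items()},
            "seed": self.seed,
            "hd_cluster": self.hd_cluster,
            "cluster_mean_dose_sum": {
                str(k): v for k, v in self.cluster_mean_dose_sum.items()
            },
            "converged": self.converged,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def fit_bgmm(
    features: DoseFeatureMatrix,
    k: int = 3,
    seed: int = 0,
    n_init: int = 5,
    reg_covar: float = 1e-4,
    max_iter: int = 500,
) -> ClusterModel:
    """Fit a k-component variational Bayesian GMM to the feature matrix.

    Features are standardized internally (mean 0, sd 1; constant columns
    get unit scale); the weight-concentration prior is 1/k with the
    Dirichlet-process parameterization, so superfluous components are
    suppressed rather than force-filled.  Deterministic given ``seed``.
    """
    x = features.values.to_numpy(dtype=float)
    n = x.shape[0]
    if k <= 0 or k > n:
        raise ValueError(f"k must be in 1..{n}, got {k}")
    if not np.all(np.isfinite(x)):
        raise ValueError("feature matrix contains non-finite values")
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    z = (x - mu) / sd
    est = BayesianGaussianMixture(
        n_components=k,
        covariance_type="full",
        reg_covar=reg_covar,
        n_init=n_init,
        max_iter=max_iter,
        weight_concentration_prior_type="dirichlet_process",
        weight_concentration_prior=1.0 / k,
        random_state=seed,
    )
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            est.fit(z)
        except ConvergenceWarning:
            converged = False
            log.warning("BGMM did not converge; keeping best-so-far model")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                est.fit(z)
    labels = pd.Series(est.predict(z), index=features.values.index, name="cluster")
    return ClusterModel(
        n_components=k,
        feature_names=features.feature_names,
        weights=est.weights_,
        means=est.means_,
        covariances=est.covariances_,
        scaler_mean=mu,
        scaler_scale=sd,
        labels=labels,
        seed=seed,
        converged=converged,
        _estimator=est,
    )


def assign(model: ClusterModel, x: np.ndarray) -> int:
    """Assign one feature vector to its maximum-posterior component."""
    return int(model.predict(np.atleast_2d(x))[0])


def identify_hd(
    model: ClusterModel,
    cohort,
    spec: FeatureSpec,
) -> int:
    """Identify the high-dose component.

    Per patient, the mean doses of the spec organs are summed; per
    component, that sum is averaged over members (so HD identity does not
    depend on cluster size); the argmax component is HD.  Empty components
    are excluded with a warning.  Populates ``model.cluster_mean_dose_sum``
    and ``model.hd_cluster``.
    """
    sums = mean_dose_sum(cohort, spec.organs).reindex(model.labels.index)
    if sums.isna().any():
        raise KeyError("mean dose sums missing for some labelled patients")
    by_cluster = sums.groupby(model.labels).mean()
    model.cluster_mean_dose_sum = {
        int(c) : float(v) for c, v in by_cluster.items()
    }
    present = by_cluster.index
    empty = sorted(set(range(model.n_components)) - set(int(c) for c in present))
    if empty:
        log.warning("components %s are empty; excluded from HD argmax", empty)
    model.hd_cluster = int(by_cluster.idxmax())
    return model.hd_cluster


def verify_hd_incidence(
    labels: pd.Series,
    hd_cluster: int,
    severe: pd.Series,
) -> dict:
    """Report whether the HD component also has the highest incidence of
    the severe late endpoint; per-component rates are returned alongside."""
    severe = severe.reindex(labels.index).astype(bool)
    rates = severe.groupby(labels).mean()
    top = rates.max()
    argmax = [int(c) for c in rates.index[rates == top]]
    return {
        "hd_cluster": int(hd_cluster),
        "incidence": {int(c): float(v) for c, v in rates.items()},
        "hd_has_max_incidence": hd_cluster in argmax and len(argmax) == 1,
        "tied": len(argmax) > 1,
    }
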