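"""Cross-validated comparison of cluster stratifications vs NTCP models.

Four risk models are scored per endpoint with stratified 5-fold CV:

* ``All`` — the 3-level mixture stratification; clusters are ranked within
  each training fold by their count of positive outcomes and test patients
  receive rank risks 1 / 0.5 / 0 (ties ranked by cluster mean dose).
* ``HD`` — membership in the high-dose cluster (risk 1 vs 0).
* ``SHD`` — membership in the rule-based simplified high-dose group.
* ``NTCP`` — a logistic model on clinical covariates plus organ mean
  doses, recalibrated on each training fold.

Clustering and rule mining are refit inside every training fold, so no
test information leaks into the stratification.  AUC-ROC (tie-aware) and
Matthews correlation (multi-level risks binarized at risk >= 1) are pooled
over folds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .clustering import fit_bgmm, identify_hd
from .dose_features import DoseFeatureMatrix, FeatureSpec
from .dvh_io import PatientDose
from .rule_mining import beam_search_rules
from .stats_tests import fit_logistic_mle

log = logging.getLogger("dosestrat")

MODEL_NAMES = ("All", "NTCP", "HD", "SHD")


# ----------------------------------------------------------------- metrics

def auc_roc(scores, outcomes) -> float:
    """Area under the ROC curve (Mann-Whitney form, 0.5 credit for ties)."""
    y = np.asarray(outcomes, dtype=bool)
    s = np.asarray(scores, dtype=float)
    if y.all() or not y.any():
        raise ValueError("AUC undefined: only one outcome class present")
    return float(roc_auc_score(y, s))


def mcc(pred, outcomes) -> float:
    """Matthews correlation coefficient of two binary vectors.

    Zero when any confusion-matrix margin is empty.
    """
    p = np.asarray(pred, dtype=bool)
    y = np.asarray(outcomes, dtype=bool)
    if p.shape != y.shape:
        raise ValueError("length mismatch")
    tp = float(np.count_nonzero(p & y))
    fp = float(np.count_nonzero(p & ~y))
    fn = float(np.count_nonzero(~p & y))
    tn = float(np.count_nonzero(~p & ~y))
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / np.sqrt(denom)


# ------------------------------------------------------------- risk scores

def rank_risk_scores(
    train_labels: pd.Series,
    train_outcomes,
    test_labels: pd.Series,
    cluster_mean_dose: dict[int, float],
) -> np.ndarray:
    """Rank-based risks for the 3-level stratification.

    Clusters are ordered by their training-fold count of positive outcomes
    (descending; ties broken by higher cluster mean dose) and mapped to
    risks 1, 0.5, 0 for ranks 1..3 (further ranks also 0).
    """
    y = np.asarray(train_outcomes, dtype=bool)
    counts: dict[int, int] = {}
    for cid in sorted(set(int(c) for c in train_labels)):
        counts[cid] = int(np.count_nonzero(y[(train_labels == cid).to_numpy()]))
    unseen = set(int(c) for c in test_labels) - set(counts)
    if unseen:
        raise ValueError(f"test clusters {sorted(unseen)} unseen in training")
    order = sorted(
        counts,
        key=lambda cid: (-counts[cid], -cluster_mean_dose.get(cid, 0.0), cid),
    )
    risk_of = {cid: ([1.0, 0.5] + [0.0] * len(order))[rank]
               for rank, cid in enumerate(order)}
    return np.asarray([risk_of[int(c)] for c in test_labels])


def fit_ntcp(design: pd.DataFrame, outcome):
    """Recalibrate the NTCP logistic model (covariates + organ mean doses)
    on training data; returns the fitted model."""
    return fit_logistic_mle(design, np.asarray(outcome, dtype=float))


# ---------------------------------------------------------------- CV types

@dataclass
class CohortBundle:
    """Everything one endpoint evaluation needs, aligned on patient id."""

    features: DoseFeatureMatrix          # cluster feature matrix
    cohort: list[PatientDose]            # lateralized DVHs (for HD id)
    spec: FeatureSpec
    ntcp_design: pd.DataFrame            # covariates + NTCP organ mean doses
    endpoint: pd.Series                  # binary outcome

    def __post_init__(self):
        idx = self.features.values.index
        self.ntcp_design = self.ntcp_design.loc[idx]
        self.endpoint = self.endpoint.loc[idx].astype(bool)
        byid = {p.patient_id: p for p in self.cohort}
        self.cohort = [byid[pid] for pid in idx]


@dataclass
class CVResult:
    """Pooled and per-fold AUC/MCC per model for one endpoint."""

    endpoint: str
    n_folds: int
    seed: int
    auc: dict[str, float] = field(default_factory=dict)
    mcc: dict[str, float] = field(default_factory=dict)
    fold_auc: dict[str, list[float]] = field(default_factory=dict)
    fold_mcc: dict[str, list[float]] = field(default_factory=dict)
    scores: dict[str, np.ndarray] = field(default_factory=dict)
    folds: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        """Report table: rows AUC/MCC, columns All/NTCP/HD/SHD."""
        return pd.DataFrame(
            {m: {"AUC": self.auc.get(m, np.nan), "MCC": self.mcc.get(m, np.nan)}
             for m in MODEL_NAMES}
        )


# ------------------------------------------------------------------- folds

def _stratified_folds(y: np.ndarray, k: int, seed: int):
    """Stratified k-fold index pairs; folds lacking positives are re-drawn
    with a new sub-seed, up to 10 attempts."""
    for attempt in range(10):
        skf = StratifiedKFold(n_splits=k, shuffle=True,
                              random_state=seed + 1000 * attempt)
        folds = list(skf.split(np.zeros_like(y), y))
        if all(y[tr].any() and y[te].any() and (~y[tr]).any()
               for tr, te in folds):
            return folds
    raise ValueError("could not draw stratified folds with positives in "
                     "every fold after 10 attempts")


def cross_validate(
    bundle: CohortBundle,
    endpoint_name: str,
    models=MODEL_NAMES,
    k: int = 5,
    seed: int = 0,
    frozen_clusters: bool = False,
    n_components: int = 3,
    beam_width: int = 25,
    max_depth: int = 2,
    n_init: int = 5,
) -> CVResult:
    """Stratified k-fold CV of the requested risk models on one endpoint.

    With ``frozen_clusters`` the mixture and rule set are fit once on the
    full cohort (the weaker, leak-prone variant kept for comparison);
    otherwise both are refit inside each training fold.  Scores are pooled
    across folds before computing AUC/MCC; per-fold values are retained.
    Deterministic given ``seed``.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    y = bundle.endpoint.to_numpy(dtype=bool)
    n = y.size
    folds = _stratified_folds(y, k, seed)
    sizes = sorted(len(te) for _, te in folds)
    assert sizes[-1] - sizes[0] <= 1

    frozen = None
    if frozen_clusters:
        model = fit_bgmm(bundle.features, k=n_components, seed=seed,
                         n_init=n_init)
        identify_hd(model, bundle.cohort, bundle.spec)
        rules = beam_search_rules(bundle.features, model.hd_membership(),
                                  beam_width=beam_width, max_depth=max_depth)
        frozen = (model, rules)

    scores = {m: np.full(n, np.nan) for m in models}
    fold_auc = {m: [] for m in models}
    fold_mcc = {m: [] for m in models}

    for fold_i, (tr, te) in enumerate(folds):
        tr_ids = bundle.features.values.index[tr]
        te_ids = bundle.features.values.index[te]
        feats_tr = DoseFeatureMatrix(bundle.features.values.loc[tr_ids])
        cohort_tr = [bundle.cohort[i] for i in tr]

        if frozen is not None:
            model, rules = frozen
        else:
            model = fit_bgmm(feats_tr, k=n_components,
                             seed=seed + 17 * fold_i, n_init=n_init)
            identify_hd(model, cohort_tr, bundle.spec)
            rules = beam_search_rules(feats_tr, model.hd_membership(),
                                      beam_width=beam_width,
                                      max_depth=max_depth)

        test_x = bundle.features.values.loc[te_ids].to_numpy()
        test_labels = pd.Series(model.predict(test_x), index=te_ids)
        train_labels = model.labels.reindex(tr_ids)
        if train_labels.isna().any():   # frozen model covers all patients
            train_labels = pd.Series(
                model.predict(bundle.features.values.loc[tr_ids].to_numpy()),
                index=tr_ids,
            )

        for m in models:
            if m == "All":
                s = rank_risk_scores(train_labels, y[tr], test_labels,
                                     model.cluster_mean_dose_sum)
            elif m == "HD":
                s = (test_labels == model.hd_cluster).to_numpy(float)
            elif m == "SHD":
                feats_te = DoseFeatureMatrix(bundle.features.values.loc[te_ids])
                s = rules.membership(feats_te).astype(float)
            elif m == "NTCP":
                fit = fit_ntcp(bundle.ntcp_design.loc[tr_ids], y[tr])
                s = fit.predict(bundle.ntcp_design.loc[te_ids])
            else:
                raise ValueError(f"unknown model {m!r}")
            scores[m][te] = s
            if y[te].any() and (~y[te]).any():
                fold_auc[m].append(auc_roc(s, y[te]))
                fold_mcc[m].append(mcc(_binarize(m, s), y[te]))

    result = CVResult(endpoint=endpoint_name, n_folds=k, seed=seed,
                      folds=folds)
    for m in models:
        result.auc[m] = auc_roc(scores[m], y)
        result.mcc[m] = mcc(_binarize(m, scores[m]), y)
        result.fold_auc[m] = fold_auc[m]
        result.fold_mcc[m] = fold_mcc[m]
        result.scores[m] = scores[m]
    return result


def _binarize(model_name: str, s: np.ndarray) -> np.ndarray:
    """Binary prediction for MCC: risk >= 1 for rank-based stratifications
    (HD membership), probability >= 0.5 for NTCP."""
    if model_name == "NTCP":
        return s >= 0.5
    return s >= 1.0


# ------------------------------------------------------- pipeline assembly

def assemble_bundle(
    cohort: list[PatientDose],
    clinical: pd.DataFrame,
    symptom_table,
    symptom: str,
    cfg: dict,
    endpoint: str = "late_severe",
    impute: bool = True,
    seed: int = 0,
):
    """Run the preprocessing pipeline and align everything on one index.

    Lateralizes paired organs, applies eligibility filtering and (optional)
    baseline imputation, derives the binary endpoint, builds the cluster
    feature matrix, the covariate indicators and the NTCP design
    (covariates + NTCP organ mean doses).  Returns
    (CohortBundle, EndpointTable, CovariateTable).
    """
    from .dose_features import build_feature_matrix, mean_dose
    from .dvh_io import lateralize_cohort
    from .outcomes import derive_endpoints, eligibility_filter, impute_baseline
    from .stats_tests import build_covariate_table

    spec = FeatureSpec.from_config(cfg, symptom)
    pairs = [tuple(p) for p in cfg["paired_organs"]]
    lat = lateralize_cohort(cohort, pairs)

    ocfg = cfg["outcomes"]
    retained, _ = eligibility_filter(
        symptom_table, symptom, min_completeness=ocfg["min_completeness"]
    )
    st = symptom_table
    if impute:
        imp = ocfg["imputer"]
        st = impute_baseline(
            st, seed=seed, hidden=tuple(imp["hidden"]),
            corruption=imp["corruption"], learning_rate=imp["learning_rate"],
            max_epochs=imp["max_epochs"], patience=imp["patience"],
        )
    st = type(st)(st.ratings.loc[retained],
                  None if st.imputed_mask is None
                  else st.imputed_mask.loc[retained])
    ep = derive_endpoints(st, symptom, threshold=ocfg["severe_threshold"])

    features = build_feature_matrix(lat, spec)
    cov = build_covariate_table(clinical, lat)

    ntcp_organs = cfg["ntcp_organs"][symptom]
    ntcp = cov.design().copy()
    byid = {p.patient_id: p for p in lat}
    for organ in ntcp_organs:
        ntcp[f"{organ}:mean"] = [
            mean_dose(byid[pid].curves[organ]) if organ in byid[pid].curves
            else np.nan
            for pid in ntcp.index
        ]
    ntcp = ntcp.dropna(axis=1, how="any")

    idx = features.values.index.intersection(ep.table.index)
    idx = idx.intersection(ntcp.index)
    y = ep.table.loc[idx, endpoint]
    keep = y.notna()
    idx = idx[keep.to_numpy()]
    bundle = CohortBundle(
        features=DoseFeatureMatrix(features.values.loc[idx]),
        cohort=[byid[pid] for pid in idx],
        spec=spec,
        ntcp_design=ntcp.loc[idx],
        endpoint=ep.table.loc[idx, endpoint].astype(bool),
    )
    return bundle, ep, cov
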