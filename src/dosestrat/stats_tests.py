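"""Association testing: LRTs over clinical covariates, chi-square tables,
Fisher odds ratios, and published dose-limit flags.

The central question is whether cluster membership carries information
about a late severe endpoint beyond clinical confounders.  A baseline
logistic model on the confounders is compared with an extended model that
adds cluster indicators via a likelihood-ratio test; odds ratios come from
the added coefficient, and Akaike/Bayesian information-criterion deltas
quantify fit net of parameter count (a BIC reduction of at least 6 is
conventionally read as strong evidence).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .dose_features import max_dose, mean_dose, volume_at_dose
from .dvh_io import PatientDose

log = logging.getLogger("dosestrat")

#: clinical confounder indicator columns used in baseline models
CONFOUNDERS = (
    "t34", "n2plus", "hpv_pos", "subsite_bot", "subsite_tonsil",
    "age_ge65", "ecog_1", "ecog_2", "parotid_limit",
)


# --------------------------------------------------------- covariate table

@dataclass
class CovariateTable:
    """Binary clinical indicators per patient, plus the raw fields."""

    indicators: pd.DataFrame
    raw: pd.DataFrame

    def design(self, columns=CONFOUNDERS) -> pd.DataFrame:
        cols = [c for c in columns if c in self.indicators.columns]
        return self.indicators[cols].astype(float)


def _stage_number(value) -> float:
    if pd.isna(value):
        return np.nan
    if isinstance(value, (int, float, np.integer, np.floating)):
        return float(value)
    digits = "".join(ch for ch in str(value) if ch.isdigit())
    return float(digits) if digits else np.nan


def build_covariate_table(
    clinical: pd.DataFrame,
    cohort: list[PatientDose] | None = None,
) -> CovariateTable:
    """Encode raw clinical fields as the confounder indicators.

    Expected raw columns: t_stage, n_stage, hpv ('positive'/'negative'/
    'unknown'), subsite ('BOT'/'tonsil'/other), age, ecog (0/1/2/'unknown'),
    optionally prior_surgery and modality.  Unknown ECOG and unknown HPV
    are reference-level (all indicators 0).  ``parotid_limit`` (mean dose
    > 20 Gy to both parotids or > 25 Gy to one) is computed from the DVH
    cohort when given.
    """
    idx = clinical.index.astype(str)
    ind = pd.DataFrame(index=idx)
    ind["t34"] = (clinical["t_stage"].map(_stage_number) > 2).fillna(False).astype(int).to_numpy()
    ind["n2plus"] = (clinical["n_stage"].map(_stage_number) > 1).fillna(False).astype(int).to_numpy()
    hpv = clinical["hpv"].astype(str).str.lower()
    ind["hpv_pos"] = hpv.isin(["positive", "pos", "+", "hpv+"]).astype(int).to_numpy()
    subsite = clinical["subsite"].astype(str).str.lower()
    ind["subsite_bot"] = (subsite == "bot").astype(int).to_numpy()
    ind["subsite_tonsil"] = (subsite == "tonsil").astype(int).to_numpy()
    ind["age_ge65"] = (clinical["age"] >= 65).astype(int).to_numpy()
    ecog = clinical["ecog"].map(_stage_number)
    ind["ecog_1"] = (ecog == 1).fillna(False).astype(int).to_numpy()
    ind["ecog_2"] = (ecog >= 2).fillna(False).astype(int).to_numpy()
    if cohort is not None:
        flags = {}
        for pdose in cohort:
            flag = dose_limit_flags(pdose).get("parotid")
            flags[pdose.patient_id] = 0 if flag is None else int(flag)
        ind["parotid_limit"] = pd.Series(flags).reindex(idx).fillna(0).astype(int)
    raw = clinical.copy()
    raw.index = idx
    return CovariateTable(indicators=ind, raw=raw)


# ------------------------------------------------------------ logistic MLE

@dataclass
class FittedLogit:
    """A converged logistic MLE: coefficients, log-likelihood, and the
    parameter count used by the information criteria."""

    params: pd.Series
    llf: float
    k: int                      # parameters incl. intercept and flat columns
    n: int
    columns: tuple[str, ...]    # design columns incl. dropped/flat, no const
    dropped: tuple[str, ...] = ()
    ridge: bool = False

    @property
    def aic(self) -> float:
        return 2 * self.k - 2 * self.llf

    @property
    def bic(self) -> float:
        return self.k * np.log(self.n) - 2 * self.llf

    def predict(self, design: pd.DataFrame) -> np.ndarray:
        x = sm.add_constant(design[list(self.params.index[1:])], has_constant="add")
        lin = x.to_numpy(dtype=float) @ self.params.to_numpy()
        return 1.0 / (1.0 + np.exp(-lin))


def _ridge_logit(x: np.ndarray, y: np.ndarray, alpha: float = 1e-6):
    """Newton iterations on an L2-penalized logistic likelihood (intercept
    unpenalized); returns (params, unpenalized llf)."""
    n, p = x.shape
    beta = np.zeros(p)
    pen = np.full(p, alpha)
    pen[0] = 0.0
    for _ in range(200):
        eta = np.clip(x @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1 - mu) + 1e-12
        grad = x.T @ (y - mu) - pen * beta
        hess = (x * w[:, None]).T @ x + np.diag(pen + 1e-12)
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    eta = np.clip(x @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    eps = 1e-12
    llf = float(np.sum(y * np.log(mu + eps) + (1 - y) * np.log(1 - mu + eps)))
    return beta, llf


def fit_logistic_mle(design: pd.DataFrame, y) -> FittedLogit:
    """Maximum-likelihood logistic regression with an intercept.

    Exact-collinear columns are dropped with a warning (they add no
    parameter); all-zero columns are kept as flat parameters (coefficient
    0, counted in k, no likelihood contribution).  Separation or
    non-convergence falls back to a lightly ridged fit (alpha 1e-6) with a
    warning.
    """
    y = np.asarray(y, dtype=float)
    design = design.astype(float)
    if design.shape[0] != y.size:
        raise ValueError("design/outcome length mismatch")
    all_cols = tuple(design.columns)

    zero_cols = [c for c in design.columns if (design[c] == 0).all()]
    work = design.drop(columns=zero_cols)

    # drop columns exactly collinear with earlier ones (or the intercept)
    kept: list[str] = []
    dropped: list[str] = []
    base = np.ones((design.shape[0], 1))
    for col in work.columns:
        cand = np.column_stack([base, work[kept + [col]].to_numpy()])
        if np.linalg.matrix_rank(cand) == cand.shape[1]:
            kept.append(col)
        else:
            dropped.append(col)
            log.warning("dropping aliased design column %r", col)

    x = sm.add_constant(work[kept], has_constant="add")
    xmat = x.to_numpy(dtype=float)
    ridge = False
    import warnings
    try:
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, xmat).fit(disp=0, maxiter=200)
        params = res.params
        llf = float(res.llf)
        if not res.mle_retvals.get("converged", True) or np.any(np.abs(params) > 30):
            raise RuntimeError("non-convergence or separation")
    except Exception:
        log.warning("logistic MLE unstable (separation?); ridge fallback 1e-6")
        params, llf = _ridge_logit(xmat, y)
        ridge = True

    coef = pd.Series(params, index=["const"] + kept)
    for col in zero_cols:
        coef[col] = 0.0
    k = 1 + len(kept) + len(zero_cols)
    return FittedLogit(
        params=coef, llf=llf, k=k, n=y.size,
        columns=all_cols, dropped=tuple(dropped), ridge=ridge,
    )


# ------------------------------------------------------------------- LRT

@dataclass
class LRTResult:
    statistic: float
    p_value: float
    df: int
    odds_ratio: float | None
    delta_aic: float
    delta_bic: float


def lrt_nested(base: FittedLogit, extended: FittedLogit) -> LRTResult:
    """Likelihood-ratio test of nested logistic models.

    Statistic 2(lnL_ext - lnL_base) on chi-square(df = added parameters);
    the odds ratio is the exponentiated coefficient of the single added
    column (absent for multi-column additions).  Deltas are extended minus
    base information criteria.
    """
    if base.n != extended.n:
        raise ValueError("models fit on different sample sizes")
    if not set(base.columns) <= set(extended.columns):
        raise ValueError("designs are not nested")
    df = extended.k - base.k
    if df < 0:
        raise ValueError("extended model has fewer parameters than base")
    stat = max(0.0, 2.0 * (extended.llf - base.llf))
    p = float(scipy.stats.chi2.sf(stat, df)) if df > 0 else 1.0
    added = [c for c in extended.columns if c not in base.columns]
    odds = None
    if len(added) == 1 and added[0] in extended.params.index:
        odds = float(np.exp(extended.params[added[0]]))
    return LRTResult(
        statistic=stat, p_value=p, df=df, odds_ratio=odds,
        delta_aic=extended.aic - base.aic,
        delta_bic=extended.bic - base.bic,
    )


def lrt_nested_linear(
    base_design: pd.DataFrame, ext_design: pd.DataFrame, y
) -> LRTResult:
    """Linear-outcome analogue (0-10 rating scale): OLS with an F-test for
    the added columns; deltas from the OLS information criteria."""
    if not set(base_design.columns) <= set(ext_design.columns):
        raise ValueError("designs are not nested")
    y = np.asarray(y, dtype=float)
    xb = sm.add_constant(base_design.astype(float), has_constant="add")
    xe = sm.add_constant(ext_design.astype(float), has_constant="add")
    rb = sm.OLS(y, xb).fit()
    re = sm.OLS(y, xe).fit()
    fstat, p, df = re.compare_f_test(rb)
    added = [c for c in ext_design.columns if c not in base_design.columns]
    coef = float(re.params[added[0]]) if len(added) == 1 else None
    return LRTResult(
        statistic=float(fstat), p_value=float(p), df=int(df),
        odds_ratio=coef,
        delta_aic=float(re.aic - rb.aic), delta_bic=float(re.bic - rb.bic),
    )


# ---------------------------------------------------- contingency testing

def chi2_cluster_covariates(
    membership, covariates: pd.DataFrame
) -> pd.DataFrame:
    """Pearson chi-square of every covariate column against membership.

    ``membership`` may be multi-level cluster labels or a binary SHD
    indicator.  Returns statistic, p, dof and a low-expected-count flag per
    covariate.
    """
    membership = pd.Series(membership)
    rows = {}
    for col in covariates.columns:
        tab = pd.crosstab(covariates[col].to_numpy(), membership.to_numpy())
        if tab.shape[0] < 2 or tab.shape[1] < 2:
            rows[col] = {"statistic": np.nan, "p_value": np.nan,
                         "dof": 0, "low_expected": False}
            continue
        res = scipy.stats.chi2_contingency(tab.to_numpy(), correction=False)
        low = bool((res.expected_freq < 1).any())
        if low:
            log.warning("chi2 for %r has expected cell counts < 1", col)
        rows[col] = {"statistic": float(res.statistic),
                     "p_value": float(res.pvalue),
                     "dof": int(res.dof), "low_expected": low}
    return pd.DataFrame(rows).T


def fisher_or(table) -> tuple[float, float]:
    """Sample odds ratio and two-sided Fisher exact p for a 2x2 table.

    OR is ad/bc with a 0.5 Haldane correction when any cell is zero; an
    empty margin leaves the OR undefined (NaN, logged).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    a, b = t[0]
    c, d = t[1]
    if min(a + b, c + d, a + c, b + d) == 0:
        log.warning("fisher_or: empty margin; OR undefined")
        odds = float("nan")
    else:
        if (t == 0).any():
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        odds = (a * d) / (b * c)
    _, p = scipy.stats.fisher_exact(t.astype(int), alternative="two-sided")
    return float(odds), float(p)


# ------------------------------------------------------- dose limit flags

def _family_curves(pdose: PatientDose, family: str) -> list:
    names = (f"left_{family}", f"right_{family}",
             f"ipsilateral_{family}", f"contralateral_{family}")
    return [pdose.curves[n] for n in names if n in pdose.curves]


def dose_limit_flags(pdose: PatientDose) -> dict[str, bool | None]:
    """Evaluate published organ dose limits for one patient.

    Volume readings ("V50 > 27") are percent-of-volume-at-dose; flags for
    organs without a curve are None (undefined) and logged.
    """
    flags: dict[str, bool | None] = {}

    def get(roi):
        return pdose.curves.get(roi)

    def simple(name, roi, fn):
        curve = get(roi)
        if curve is None:
            log.info("patient %s: ROI %r missing; limit %r undefined",
                     pdose.patient_id, roi, name)
            flags[name] = None
        else:
            flags[name] = bool(fn(curve))

    simple("spinal_cord", "spinal_cord", lambda c: max_dose(c) > 50)
    parotids = _family_curves(pdose, "parotid")
    if len(parotids) < 2:
        log.info("patient %s: < 2 parotid curves; parotid limit undefined",
                 pdose.patient_id)
        flags["parotid"] = None
    else:
        means = [mean_dose(c) for c in parotids]
        flags["parotid"] = bool(max(means) > 25 or min(means) > 20)
    simple("ipc", "ipc", lambda c: mean_dose(c) > 50)
    simple("ipc_2", "ipc", lambda c: mean_dose(c) > 60)
    simple("mpc", "mpc", lambda c: mean_dose(c) > 50)
    simple("mpc_2", "mpc", lambda c: mean_dose(c) > 60)
    simple("spc", "spc", lambda c: mean_dose(c) > 50)
    simple("spc_2", "spc", lambda c: mean_dose(c) > 60)
    simple("mandible", "mandible", lambda c: max_dose(c) > 70)
    simple("larynx", "larynx", lambda c: volume_at_dose(c, 50) > 27)
    simple("brachial_plexus", "brachial_plexus", lambda c: max_dose(c) > 60)
    simple(
        "esophagus", "esophagus",
        lambda c: (volume_at_dose(c, 35) > 50 or volume_at_dose(c, 50) > 40
                   or volume_at_dose(c, 70) > 20 or volume_at_dose(c, 60) > 30),
    )
    return flags


# ----------------------------------------------------------- report shape

def cluster_lrt_suite(
    y,
    covariates: pd.DataFrame,
    labels: pd.Series,
    cluster_order: list[int],
    shd_membership,
) -> pd.DataFrame:
    """LRT report rows for the All / HD / SHD stratifications of one outcome.

    'All' adds one indicator per non-reference cluster (lowest-dose cluster
    is reference, ``cluster_order`` low-to-high); 'HD' adds the high-dose
    indicator alone; 'SHD' the rule-based indicator.  Columns: p_value,
    odds_ratio, delta_aic, delta_bic.
    """
    y = np.asarray(y, dtype=float)
    base = fit_logistic_mle(covariates, y)
    out = {}

    hd = cluster_order[-1]
    ext_all = covariates.copy()
    for cid in cluster_order[1:]:
        ext_all[f"cluster_{cid}"] = (labels == cid).astype(float).to_numpy()
    res_all = lrt_nested(base, fit_logistic_mle(ext_all, y))
    out["All"] = {"p_value": res_all.p_value, "odds_ratio": np.nan,
                  "delta_aic": res_all.delta_aic, "delta_bic": res_all.delta_bic}

    ext_hd = covariates.copy()
    ext_hd["hd"] = (labels == hd).astype(float).to_numpy()
    res_hd = lrt_nested(base, fit_logistic_mle(ext_hd, y))
    out["HD"] = {"p_value": res_hd.p_value, "odds_ratio": res_hd.odds_ratio,
                 "delta_aic": res_hd.delta_aic, "delta_bic": res_hd.delta_bic}

    ext_shd = covariates.copy()
    ext_shd["shd"] = np.asarray(shd_membership, dtype=float)
    res_shd = lrt_nested(base, fit_logistic_mle(ext_shd, y))
    out["SHD"] = {"p_value": res_shd.p_value, "odds_ratio": res_shd.odds_ratio,
                  "delta_aic": res_shd.delta_aic, "delta_bic": res_shd.delta_bic}

    return pd.DataFrame(out).T[["p_value", "odds_ratio", "delta_aic", "delta_bic"]]
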