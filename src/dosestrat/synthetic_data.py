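"""Synthetic radiotherapy cohorts with planted dose-group structure.

The generator emulates the structure of an oropharyngeal-cancer cohort:
three latent dose groups (low / moderate / high) with spatially correlated
organ doses, paired left/right salivary glands with a higher-dose primary
side, clinical covariates enriched in the high group (more T4/N3, more
base-of-tongue primaries), and MDASI-style 0-10 symptom ratings whose
6-month severe endpoint follows a configured logistic model on dose
features and covariates.  Every quantity is deterministic given the seed,
and the planted truth is returned for recovery testing.

DVH curves use a logistic tail v(d) = 1/(1+exp(s(d-d50))) normalized to
v(0)=1 on a 1-Gy grid, with d50 solved by bisection so the curve's mean
dose hits a target.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .config import TIMEPOINTS
from .dose_features import dose_at_volume, max_dose, mean_dose
from .dvh_io import DVHCurve, PatientDose, lateralize

#: MDASI-style item names (emulation of a 28-item severity questionnaire)
SYMPTOM_NAMES = (
    "pain", "fatigue", "nausea", "sleep_disturbance", "distress",
    "shortness_of_breath", "memory", "appetite", "drowsiness", "drymouth",
    "sadness", "vomiting", "numbness", "mucus", "swallow", "choking",
    "voice", "skin", "constipation", "taste", "sores", "teeth_problems",
    "general_activity", "mood", "work", "relations", "walking", "enjoyment",
)

PAIRED_FAMILIES = ("parotid", "submandibular")

#: per-organ multiplier of the group base dose target
DEFAULT_ORGAN_FACTORS: dict[str, float] = {
    "parotid": 0.85,
    "submandibular": 1.0,
    "hard_palate": 0.9,
    "soft_palate": 0.85,
    "upper_lip": 0.4,
    "lower_lip": 0.35,
    "oral_cavity": 0.8,
    "mylogeniohyoid": 0.9,
    "tongue": 0.85,
    "larynx": 0.7,
    "supraglottic_larynx": 0.75,
    "esophagus": 0.5,
    "ipc": 0.8,
    "mpc": 0.8,
    "spc": 0.8,
    "cricopharyngeal": 0.7,
    "genioglossus": 0.8,
    "mandible": 0.9,
    "spinal_cord": 0.45,
    "brachial_plexus": 0.5,
}


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one synthetic cohort."""

    n_patients: int = 349
    seed: int = 0
    group_weights: tuple[float, float, float] = (0.35, 0.35, 0.30)
    group_mean_targets: tuple[float, float, float] = (20.0, 45.0, 70.0)
    dose_sd: float = 3.0
    inter_organ_correlation: float = 0.5      # shared latent loading
    lateral_asymmetry: float = 8.0            # primary-minus-contra Gy gap
    steepness: float = 0.15                   # DVH falloff
    organ_factors: dict = field(default_factory=lambda: dict(DEFAULT_ORGAN_FACTORS))
    symptom: str = "drymouth"
    outcome_intercept: float = -4.0
    outcome_coefficients: dict = field(default_factory=lambda: {
        "contralateral_submandibular:mean": 0.05,
        "ipsilateral_parotid:mean": 0.03,
        "t34": 0.3,
    })
    #: per-group probabilities (low, moderate, high)
    p_t4: tuple = (0.04, 0.08, 0.22)
    p_t3: tuple = (0.10, 0.14, 0.20)
    p_n2plus: tuple = (0.55, 0.60, 0.70)
    p_hpv_pos: tuple = (0.84, 0.82, 0.78)
    p_hpv_unknown: float = 0.12
    p_bot: tuple = (0.32, 0.45, 0.65)
    p_tonsil: tuple = (0.50, 0.42, 0.25)
    p_vmat_impt: tuple = (0.55, 0.62, 0.75)
    p_imrt: tuple = (0.30, 0.25, 0.15)
    p_surgery: tuple = (0.14, 0.10, 0.04)
    age_mean: tuple = (58.0, 59.0, 62.0)
    age_sd: float = 9.0
    p_ecog: tuple = (0.75, 0.18, 0.02, 0.05)  # 0 / 1 / 2 / unknown
    baseline_missing_rate: float = 0.17
    extra_missing_rate: float = 0.03
    grid_max: float = 80.0

    def validate(self) -> None:
        w = np.asarray(self.group_weights, dtype=float)
        if w.size != 3 or abs(w.sum() - 1.0) > 1e-9 or (w < 0).any():
            raise ValueError("group_weights must be 3 non-negative values summing to 1")
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        if not 0.0 <= self.inter_organ_correlation <= 1.0:
            raise ValueError("inter_organ_correlation must lie in [0, 1]")
        if any(t < 0 for t in self.group_mean_targets):
            raise ValueError("dose targets must be >= 0")
        for name in ("p_t4", "p_t3", "p_n2plus", "p_hpv_pos", "p_bot",
                     "p_tonsil", "p_vmat_impt", "p_imrt", "p_surgery"):
            vals = np.asarray(getattr(self, name), dtype=float)
            if ((vals < 0) | (vals > 1)).any():
                raise ValueError(f"{name} probabilities must lie in [0, 1]")
        for lo, hi in ((self.p_t3, self.p_t4), (self.p_tonsil, self.p_bot),
                       (self.p_imrt, self.p_vmat_impt)):
            if (np.asarray(lo) + np.asarray(hi) > 1.0).any():
                raise ValueError("per-group category probabilities exceed 1")
        if not 0 <= self.baseline_missing_rate <= 1:
            raise ValueError("baseline_missing_rate must lie in [0, 1]")


@dataclass
class SyntheticTruth:
    """Planted quantities for every generated patient."""

    table: pd.DataFrame     # group, p_outcome, baseline_missing,
                            # true_mean:<roi> columns

    @property
    def groups(self) -> pd.Series:
        return self.table["group"]

    def hd_patients(self) -> pd.Index:
        return self.table.index[self.table["group"] == 2]


# ----------------------------------------------------------------- curves

def _logistic_curves(grid: np.ndarray, s: np.ndarray, d50: np.ndarray) -> np.ndarray:
    """Rows of normalized logistic-tail curves v(d), v(0) = 1."""
    z = np.clip(s[:, None] * (grid[None, :] - d50[:, None]), -500, 500)
    v = 1.0 / (1.0 + np.exp(z))
    return v / v[:, :1]


def _solve_d50(targets: np.ndarray, s: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Vectorized bisection for the d50 hitting each target mean dose."""
    lo = np.full_like(targets, -250.0)
    hi = np.full_like(targets, grid[-1] + 400.0)
    for _ in range(50):
        mid = 0.5 * (lo + hi)
        means = np.trapezoid(_logistic_curves(grid, s, mid), grid, axis=1)
        under = means < targets
        lo = np.where(under, mid, lo)
        hi = np.where(under, hi, mid)
    return 0.5 * (lo + hi)


def generate_dvh(
    mean_target: float,
    steepness: float = 0.15,
    rng: np.random.Generator | None = None,
    grid_max: float = 80.0,
    tol: float = 0.5,
) -> DVHCurve:
    """A logistic-tail cumulative DVH whose mean dose hits ``mean_target``.

    v(d) = 1/(1+exp(s(d-d50))) normalized so v(0)=1, discretized on a 1-Gy
    grid; d50 is solved by bisection to within ``tol`` Gy of the target.
    A supplied rng jitters the falloff steepness (shape, not mean).
    Raises for targets beyond the grid maximum.
    """
    if mean_target < 0:
        raise ValueError("mean_target must be >= 0")
    if mean_target > grid_max - 1:
        raise ValueError(f"mean_target {mean_target} infeasible on a "
                         f"{grid_max} Gy grid")
    s = float(steepness)
    if rng is not None:
        s *= float(np.exp(rng.normal(0.0, 0.1)))
    s = max(s, 1e-3)
    if mean_target < 0.25:
        return DVHCurve("synthetic", np.array([0.0, 0.5]), np.array([1.0, 0.0]))
    grid = np.arange(0.0, grid_max + 1.0)
    d50 = _solve_d50(np.array([mean_target]), np.array([s]), grid)
    v = _logistic_curves(grid, np.array([s]), d50)[0]
    curve = DVHCurve("synthetic", grid, v).validate()
    achieved = float(np.trapezoid(curve.volume_fraction, curve.dose_grid))
    if abs(achieved - mean_target) > tol:
        raise ValueError(
            f"could not hit mean target {mean_target} (got {achieved:.2f})"
        )
    return curve


# ----------------------------------------------------------------- cohort

def _binom_p_for_severe(q: np.ndarray) -> np.ndarray:
    """Invert P(Binomial(10, p) > 4) = q via a dense monotone grid."""
    p_grid = np.linspace(0.0, 1.0, 2001)
    q_grid = scipy.stats.binom.sf(4, 10, p_grid)
    return np.interp(q, q_grid, p_grid)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def generate_cohort(
    cfg: CohortConfig,
) -> tuple[list[PatientDose], pd.DataFrame, "SymptomTable", SyntheticTruth]:
    """Generate (DVH cohort, raw clinical table, symptom table, truth).

    DVHs carry left_/right_ paired names (lateralization is the pipeline's
    job); the 6-month rating of the configured symptom is drawn as
    Binomial(10, p*) with p* inverted so that P(rating > 4) equals the
    configured logistic outcome probability.
    """
    from .outcomes import SymptomTable

    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_patients
    ids = [f"pt{i:04d}" for i in range(n)]

    empty_truth = pd.DataFrame(
        columns=["group", "p_outcome", "baseline_missing"], index=[]
    )
    if n == 0:
        cols = pd.MultiIndex.from_product(
            [list(TIMEPOINTS), sorted(SYMPTOM_NAMES)],
            names=["timepoint", "symptom"],
        )
        return ([], pd.DataFrame(), SymptomTable(pd.DataFrame(columns=cols)),
                SyntheticTruth(empty_truth))

    groups = rng.choice(3, size=n, p=np.asarray(cfg.group_weights))
    latent = rng.normal(0.0, 1.0, size=n)
    rho = cfg.inter_organ_correlation
    base = np.asarray(cfg.group_mean_targets)[groups]
    primary_left = rng.random(n) < 0.5

    organ_targets: dict[str, np.ndarray] = {}
    for organ, factor in cfg.organ_factors.items():
        noise = rng.normal(0.0, 1.0, size=n)
        shared = np.sqrt(rho) * latent + np.sqrt(1.0 - rho) * noise
        target = base * factor + cfg.dose_sd * shared
        if organ in PAIRED_FAMILIES:
            # per-patient, per-family gap so paired organs are correlated
            # but not deterministically offset
            gap = np.abs(rng.normal(cfg.lateral_asymmetry,
                                    cfg.lateral_asymmetry / 3.0, size=n))
            asym = gap / 2.0
            left = np.where(primary_left, target + asym, target - asym)
            right = np.where(primary_left, target - asym, target + asym)
            organ_targets[f"left_{organ}"] = np.clip(left, 0.0, cfg.grid_max - 2)
            organ_targets[f"right_{organ}"] = np.clip(right, 0.0, cfg.grid_max - 2)
        else:
            organ_targets[organ] = np.clip(target, 0.0, cfg.grid_max - 2)

    # solve all DVH midpoints in one vectorized bisection
    rois = list(organ_targets)
    tmat = np.stack([organ_targets[r] for r in rois], axis=1)  # n x rois
    smat = cfg.steepness * np.exp(rng.normal(0.0, 0.1, size=tmat.shape))
    smat = np.maximum(smat, 1e-3)
    grid = np.arange(0.0, cfg.grid_max + 1.0)
    flat_t = tmat.ravel()
    flat_s = smat.ravel()
    solvable = flat_t >= 0.25
    d50 = np.zeros_like(flat_t)
    d50[solvable] = _solve_d50(flat_t[solvable], flat_s[solvable], grid)
    vmat = _logistic_curves(grid, flat_s, d50)

    cohort: list[PatientDose] = []
    for i, pid in enumerate(ids):
        curves = {}
        for j, roi in enumerate(rois):
            flat = i * len(rois) + j
            if solvable[flat]:
                curve = DVHCurve(roi, grid, vmat[flat])
            else:
                curve = DVHCurve(roi, np.array([0.0, 0.5]),
                                 np.array([1.0, 0.0]))
            curves[roi] = curve
        cohort.append(PatientDose(patient_id=pid, curves=curves))

    # ---- covariates with group enrichment
    u = rng.random((n, 8))
    p_t4 = np.asarray(cfg.p_t4)[groups]
    p_t3 = np.asarray(cfg.p_t3)[groups]
    t_stage = np.where(u[:, 0] < p_t4, 4,
                       np.where(u[:, 0] < p_t4 + p_t3, 3,
                                np.where(u[:, 1] < 0.5, 2, 1)))
    n_stage = np.where(u[:, 2] < np.asarray(cfg.p_n2plus)[groups],
                       np.where(u[:, 3] < 0.25, 3, 2),
                       np.where(u[:, 3] < 0.5, 1, 0))
    hpv = np.where(
        u[:, 4] < cfg.p_hpv_unknown, "unknown",
        np.where(u[:, 5] < np.asarray(cfg.p_hpv_pos)[groups],
                 "positive", "negative"),
    )
    p_bot = np.asarray(cfg.p_bot)[groups]
    p_tonsil = np.asarray(cfg.p_tonsil)[groups]
    subsite = np.where(u[:, 6] < p_bot, "BOT",
                       np.where(u[:, 6] < p_bot + p_tonsil, "tonsil", "other"))
    p_vi = np.asarray(cfg.p_vmat_impt)[groups]
    p_im = np.asarray(cfg.p_imrt)[groups]
    modality = np.where(u[:, 7] < p_vi, "VMAT/IMPT",
                        np.where(u[:, 7] < p_vi + p_im, "IMRT", "other"))
    surgery = rng.random(n) < np.asarray(cfg.p_surgery)[groups]
    age = np.round(rng.normal(np.asarray(cfg.age_mean)[groups], cfg.age_sd))
    ecog_draw = rng.random(n)
    p0, p1, p2, _pu = cfg.p_ecog
    ecog = np.where(ecog_draw < p0, "0",
                    np.where(ecog_draw < p0 + p1, "1",
                             np.where(ecog_draw < p0 + p1 + p2, "2", "unknown")))
    clinical = pd.DataFrame({
        "t_stage": [f"T{t}" for t in t_stage],
        "n_stage": [f"N{v}" for v in n_stage],
        "hpv": hpv,
        "subsite": subsite,
        "modality": modality,
        "prior_surgery": surgery,
        "age": age,
        "ecog": ecog,
    }, index=pd.Index(ids, name="patient"))

    # ---- outcome probability from the configured logistic model
    lateralized = [
        lateralize(p, [(f"left_{f}", f"right_{f}") for f in PAIRED_FAMILIES])
        for p in cohort
    ]
    lin = np.full(n, cfg.outcome_intercept, dtype=float)
    for name, coef in cfg.outcome_coefficients.items():
        if ":" in name:
            organ, feat = name.split(":", 1)
            vals = np.empty(n)
            for i, p in enumerate(lateralized):
                curve = p.curves[organ]
                if feat == "mean":
                    vals[i] = mean_dose(curve)
                elif feat == "max":
                    vals[i] = max_dose(curve)
                elif feat.startswith("V"):
                    vals[i] = dose_at_volume(curve, float(feat[1:]))
                else:
                    raise ValueError(f"unknown dose feature {name!r}")
        elif name == "t34":
            vals = (t_stage > 2).astype(float)
        elif name == "n2plus":
            vals = (n_stage > 1).astype(float)
        elif name == "subsite_bot":
            vals = (subsite == "BOT").astype(float)
        elif name == "age_ge65":
            vals = (age >= 65).astype(float)
        else:
            raise ValueError(f"unknown outcome covariate {name!r}")
        lin += coef * np.asarray(vals, dtype=float)
    p_outcome = _sigmoid(lin)

    # ---- symptom ratings: low-rank latent structure + planted endpoint
    symptoms = sorted(SYMPTOM_NAMES)
    tps = list(TIMEPOINTS)
    frailty = rng.normal(0.0, 0.6, size=n)
    dose_z = (base - base.mean()) / max(base.std(), 1e-9)
    sym_offset = {s: o for s, o in zip(
        symptoms, rng.normal(-2.0, 0.4, size=len(symptoms)))}
    sym_doseload = {s: d for s, d in zip(
        symptoms, np.abs(rng.normal(0.4, 0.2, size=len(symptoms))))}
    tp_offset = {
        "baseline": -0.6, "week1": -0.2, "week2": 0.1, "week3": 0.35,
        "week4": 0.55, "week5": 0.7, "week6": 0.8, "week7": 0.85,
        "followup_6wk": 0.5, "followup_6mo": 0.2,
    }
    cols = pd.MultiIndex.from_product([tps, symptoms],
                                      names=["timepoint", "symptom"])
    ratings = pd.DataFrame(index=pd.Index(ids, name="patient"),
                           columns=cols, dtype=float)
    for tp in tps:
        for s in symptoms:
            if tp == "followup_6mo" and s == cfg.symptom:
                p_star = _binom_p_for_severe(p_outcome)
            else:
                p_star = _sigmoid(sym_offset[s] + tp_offset[tp]
                                  + frailty + sym_doseload[s] * dose_z)
            ratings[(tp, s)] = rng.binomial(10, p_star).astype(float)

    baseline_missing = rng.random(n) < cfg.baseline_missing_rate
    for s in symptoms:
        ratings.loc[baseline_missing, ("baseline", s)] = np.nan
    if cfg.extra_missing_rate > 0:
        during = [t for t in tps if t not in ("baseline", "followup_6mo")]
        for tp in during:
            for s in symptoms:
                drop = rng.random(n) < cfg.extra_missing_rate
                ratings.loc[drop, (tp, s)] = np.nan

    truth = pd.DataFrame({
        "group": groups,
        "p_outcome": p_outcome,
        "baseline_missing": baseline_missing,
    }, index=pd.Index(ids, name="patient"))
    for roi, targets in organ_targets.items():
        truth[f"true_mean:{roi}"] = targets

    return cohort, clinical, SymptomTable(ratings), SyntheticTruth(truth)
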