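"""DVH summary features and the per-symptom clustering feature matrix.

Two dual readings of "Vx" coexist in the radiotherapy literature and both
are provided here:

* :func:`dose_at_volume` — the dose (Gy) delivered to at least x% of the
  organ volume, i.e. the inverse of the cumulative DVH.  This is the
  feature used to vectorize patients for clustering (e.g. a drymouth
  patient is 5 organs x V25..V60 in 5% steps = 40 doses).
* :func:`volume_at_dose` — the percent of organ volume receiving at least
  d Gy, the QUANTEC-style reading used by published dose limits
  (e.g. larynx "V50 > 27" percent).

All interpolation is linear; beyond the last grid point the volume
fraction is taken as 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dvh_io import DVHCurve, PatientDose

log = logging.getLogger("dosestrat")


# ---------------------------------------------------------------- curve ops

def dose_at_volume(curve: DVHCurve, x_percent: float) -> float:
    """Largest dose d with volume_fraction(d) >= x_percent/100 (Gy).

    Returns 0 when less than x% of the organ receives any dose, so a rule
    like "contralateral parotid V45 > 0" reads as "more than 45% of the
    gland is irradiated".
    """
    if not 0 < x_percent <= 100:
        raise ValueError(f"x_percent must be in (0, 100], got {x_percent}")
    d, v = curve.dose_grid, curve.volume_fraction
    if d.size == 0:
        raise ValueError(f"{curve.roi_name}: empty curve")
    t = x_percent / 100.0
    above = np.flatnonzero(v >= t)
    if above.size == 0:
        return 0.0
    j = int(above[-1])
    if j == d.size - 1:
        return float(d[j])
    # v[j] >= t > v[j+1]: linear crossing inside the segment
    return float(d[j] + (v[j] - t) * (d[j + 1] - d[j]) / (v[j] - v[j + 1]))


def volume_at_dose(curve: DVHCurve, dose_gy: float) -> float:
    """Percent of organ volume receiving at least ``dose_gy`` Gy."""
    if dose_gy < 0:
        raise ValueError("dose must be non-negative")
    d, v = curve.dose_grid, curve.volume_fraction
    return float(100.0 * np.interp(dose_gy, d, v, left=v[0], right=0.0))


def mean_dose(curve: DVHCurve) -> float:
    """Volume-weighted mean dose (Gy): trapezoidal integral of the
    cumulative volume fraction over the dose support."""
    d, v = curve.dose_grid, curve.volume_fraction
    if d.size < 2:
        return 0.0
    return float(np.trapezoid(v, d))


def max_dose(curve: DVHCurve, eps_volume: float = 0.0) -> float:
    """Largest dose with volume_fraction > ``eps_volume`` (Gy)."""
    d, v = curve.dose_grid, curve.volume_fraction
    above = np.flatnonzero(v > eps_volume)
    if above.size == 0:
        return 0.0
    j = int(above[-1])
    if j == d.size - 1:
        return float(d[j])
    return float(d[j] + (v[j] - eps_volume) * (d[j + 1] - d[j]) / (v[j] - v[j + 1]))


# ------------------------------------------------------- feature assembly

@dataclass(frozen=True)
class FeatureSpec:
    """Which organs and which dose-at-volume window encode one symptom."""

    symptom: str
    organs: tuple[str, ...]
    vx_percent_lo: float = 25.0
    vx_percent_hi: float = 60.0
    vx_percent_step: float = 5.0

    def __post_init__(self):
        object.__setattr__(self, "organs", tuple(self.organs))
        if not self.organs:
            raise ValueError("organs must be non-empty")
        lo, hi, step = self.vx_percent_lo, self.vx_percent_hi, self.vx_percent_step
        if not (lo <= hi and step > 0):
            raise ValueError("require lo <= hi and step > 0")
        if abs(round((hi - lo) / step) - (hi - lo) / step) > 1e-9:
            raise ValueError("(hi - lo) must be an integer multiple of step")

    @property
    def vx_percents(self) -> np.ndarray:
        n = int(round((self.vx_percent_hi - self.vx_percent_lo) / self.vx_percent_step))
        return self.vx_percent_lo + self.vx_percent_step * np.arange(n + 1)

    @property
    def feature_names(self) -> list[str]:
        return [f"{o}:V{x:g}" for o in self.organs for x in self.vx_percents]

    @classmethod
    def from_config(cls, cfg: dict, symptom: str) -> "FeatureSpec":
        block = cfg["feature_specs"][symptom]
        return cls(
            symptom=symptom,
            organs=tuple(block["organs"]),
            vx_percent_lo=float(block["vx_percent_lo"]),
            vx_percent_hi=float(block["vx_percent_hi"]),
            vx_percent_step=float(block["vx_percent_step"]),
        )


@dataclass
class DoseFeatureMatrix:
    """Patients x dose features (Gy), with no missing values."""

    values: pd.DataFrame
    excluded: dict[str, str] = field(default_factory=dict)

    @property
    def patient_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    def to_csv(self, path) -> None:
        self.values.to_csv(path, index_label="patient")

    @classmethod
    def from_csv(cls, path) -> "DoseFeatureMatrix":
        return cls(pd.read_csv(path, index_col="patient"))


def build_feature_matrix(
    cohort,
    spec: FeatureSpec,
    extras: tuple[str, ...] = (),
    strict: bool = False,
) -> DoseFeatureMatrix:
    """Assemble the patients x features dose matrix for one symptom.

    Columns are organ-major, Vx ascending in x, with optional per-organ
    ``mean`` / ``max`` columns appended (``extras``).  Patients missing a
    spec organ are excluded with a logged reason (error under ``strict``).
    """
    bad = set(extras) - {"mean", "max"}
    if bad:
        raise ValueError(f"unknown extras {sorted(bad)}")
    percents = spec.vx_percents
    columns = [f"{o}:V{x:g}" for o in spec.organs for x in percents]
    columns += [f"{o}:{e}" for o in spec.organs for e in extras]
    rows, index, excluded = [], [], {}
    for pdose in cohort:
        missing = [o for o in spec.organs if o not in pdose.curves]
        if missing:
            msg = f"missing ROIs {missing}"
            if strict:
                raise KeyError(f"patient {pdose.patient_id}: {msg}")
            excluded[pdose.patient_id] = msg
            log.info("excluding patient %s: %s", pdose.patient_id, msg)
            continue
        row = []
        for organ in spec.organs:
            curve = pdose.curves[organ]
            row.extend(dose_at_volume(curve, x) for x in percents)
        for organ in spec.organs:
            curve = pdose.curves[organ]
            for e in extras:
                row.append(mean_dose(curve) if e == "mean" else max_dose(curve))
        rows.append(row)
        index.append(pdose.patient_id)
    values = pd.DataFrame(rows, index=pd.Index(index, name="patient"),
                          columns=columns, dtype=float)
    return DoseFeatureMatrix(values=values, excluded=excluded)


def mean_dose_sum(cohort, organs) -> pd.Series:
    """Per-patient sum of organ mean doses (Gy) over ``organs``."""
    out = {}
    for pdose in cohort:
        out[pdose.patient_id] = sum(
            mean_dose(pdose.curves[o]) for o in organs if o in pdose.curves
        )
    return pd.Series(out, name="mean_dose_sum")


def screen_vx_range(
    features: DoseFeatureMatrix,
    endpoints: pd.DataFrame,
    spec: FeatureSpec,
) -> tuple[FeatureSpec, float]:
    """Pick the contiguous Vx window most informative about late endpoints.

    ``features`` must span a wide Vx grid built from ``spec``.  Every
    contiguous sub-window [lo, hi] of the grid is scored by the mean over
    its features of the summed empirical mutual information (bits) between
    the median-dichotomized feature and each binary endpoint column; the
    best-scoring window is returned as a new FeatureSpec together with its
    score.  Exposed for reproducibility; shipped defaults are the
    per-symptom windows actually used.
    """
    from .rule_mining import mutual_information

    ep = endpoints.loc[features.values.index]
    percents = spec.vx_percents
    fmi = {}
    for name in features.feature_names:
        col = features.values[name].to_numpy()
        split = col > np.median(col)
        if split.all() or not split.any():
            fmi[name] = 0.0
            continue
        fmi[name] = sum(
            mutual_information(split, ep[c].to_numpy(dtype=bool))
            for c in ep.columns
        )
    best, best_score = None, -np.inf
    for i in range(len(percents)):
        for j in range(i, len(percents)):
            window = percents[i:j + 1]
            names = [f"{o}:V{x:g}" for o in spec.organs for x in window]
            score = float(np.mean([fmi[n] for n in names]))
            if score > best_score + 1e-12:
                best, best_score = (percents[i], percents[j]), score
    lo, hi = best
    return (
        FeatureSpec(spec.symptom, spec.organs, lo, hi, spec.vx_percent_step),
        best_score,
    )
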