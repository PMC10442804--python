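"""Reading, validating and lateralizing cumulative dose-volume histograms.

A cumulative DVH gives, for each dose level d, the fraction of an organ's
volume receiving at least d Gy.  Curves are stored on arbitrary ascending
dose grids with relative volume (fraction of the ROI); linear interpolation
is used between grid points and volume is taken as 0 beyond the last point.

Paired organs (parotid and submandibular glands) are encoded side-neutrally:
the side with the higher total mean dose over all paired organs is the
patient's single "primary" (ipsilateral) side, the other side contralateral.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger("dosestrat")


class DVHValidationError(ValueError):
    """A curve violates the cumulative-DVH invariants."""


class DVHFormatError(ValueError):
    """A DVH table is missing required columns or is otherwise malformed."""


@dataclass(frozen=True)
class DVHCurve:
    """One organ's cumulative DVH: ascending dose grid (Gy) and the
    non-increasing fraction of organ volume receiving at least each dose."""

    roi_name: str
    dose_grid: np.ndarray
    volume_fraction: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "dose_grid",
                           np.asarray(self.dose_grid, dtype=float))
        object.__setattr__(self, "volume_fraction",
                           np.asarray(self.volume_fraction, dtype=float))

    def validate(self, repair: bool = False) -> "DVHCurve":
        """Check (or, with ``repair``, enforce) the curve invariants.

        Returns a possibly repaired copy.  Non-monotone volume without
        ``repair`` raises :class:`DVHValidationError`.
        """
        d, v = self.dose_grid, self.volume_fraction
        if d.size == 0:
            raise DVHValidationError(f"{self.roi_name}: empty curve")
        if d.size != v.size:
            raise DVHValidationError(f"{self.roi_name}: grid/volume length mismatch")
        if not (np.all(np.isfinite(d)) and np.all(np.isfinite(v))):
            raise DVHValidationError(f"{self.roi_name}: non-finite values")
        if np.any(np.diff(d) <= 0):
            raise DVHValidationError(f"{self.roi_name}: dose grid not strictly increasing")
        if d[0] < 0:
            raise DVHValidationError(f"{self.roi_name}: negative dose")
        if np.any(v < -1e-12) or np.any(v > 1 + 1e-12):
            raise DVHValidationError(f"{self.roi_name}: volume fraction outside [0, 1]")
        v = np.clip(v, 0.0, 1.0)
        if np.any(np.diff(v) > 1e-12):
            if not repair:
                raise DVHValidationError(
                    f"{self.roi_name}: volume fraction increases along the dose grid"
                )
            # isotonic clip: running minimum makes the curve non-increasing
            v = np.minimum.accumulate(v)
        # a grid not starting at 0 means the whole volume is counted at
        # dose >= 0: prepend (0, 1).  A supplied (0, v<1) point is kept --
        # it encodes the fraction of the organ receiving any dose at all.
        if d[0] > 0:
            d = np.concatenate([[0.0], d])
            v = np.concatenate([[1.0], v])
        return DVHCurve(self.roi_name, d, v)


@dataclass
class PatientDose:
    """All DVH curves for one patient, keyed by (possibly lateralized) ROI."""

    patient_id: str
    curves: dict[str, DVHCurve] = field(default_factory=dict)

    def __contains__(self, roi: str) -> bool:
        return roi in self.curves

    def __getitem__(self, roi: str) -> DVHCurve:
        return self.curves[roi]


def normalize_roi(name: str, aliases: Mapping[str, str] | None = None) -> str:
    """Map a vendor ROI label to the canonical vocabulary.

    Exact alias matches win; otherwise the name is lower-cased with spaces
    and dashes collapsed to underscores, and passed through with a warning
    if still unrecognized by the alias map's value set.
    """
    aliases = aliases or {}
    if name in aliases:
        return aliases[name]
    canon = name.strip().lower().replace("-", "_").replace(" ", "_")
    if canon in aliases:
        return aliases[canon]
    known = set(aliases.values())
    if known and canon not in known:
        log.warning("unrecognized ROI %r passed through as %r", name, canon)
    return canon


def read_dvh_table(
    path,
    aliases: Mapping[str, str] | None = None,
    repair: bool = False,
    wide: bool = False,
) -> list[PatientDose]:
    """Read a DVH CSV into PatientDose records.

    Long format (default): columns patient, roi, dose_gy, volume_fraction.
    Wide format (``wide=True``): columns patient, dose_gy plus one volume
    column per ROI.  Volume given in percent (max > 1.5) is auto-rescaled
    to fractions.  Curves are sorted by dose and validated; non-monotone
    volume raises unless ``repair`` is set, in which case it is
    isotonically clipped.
    """
    df = pd.read_csv(path)
    if wide:
        for col in ("patient", "dose_gy"):
            if col not in df.columns:
                raise DVHFormatError(f"wide DVH table missing column {col!r}")
        df = df.melt(id_vars=["patient", "dose_gy"], var_name="roi",
                     value_name="volume_fraction").dropna(subset=["volume_fraction"])
    required = {"patient", "roi", "dose_gy", "volume_fraction"}
    missing = required - set(df.columns)
    if missing:
        raise DVHFormatError(f"DVH table missing columns: {sorted(missing)}")
    out: list[PatientDose] = []
    for pid, pgroup in df.groupby("patient", sort=True):
        pdose = PatientDose(patient_id=str(pid))
        for roi, g in pgroup.groupby("roi", sort=True):
            g = g.sort_values("dose_gy")
            dose = g["dose_gy"].to_numpy(dtype=float)
            vol = g["volume_fraction"].to_numpy(dtype=float)
            if vol.size and np.nanmax(vol) > 1.5:  # percent convention
                vol = vol / 100.0
            curve = DVHCurve(normalize_roi(str(roi), aliases), dose, vol)
            try:
                curve = curve.validate(repair=repair)
            except DVHValidationError as err:
                raise DVHValidationError(f"patient {pid}: {err}") from None
            pdose.curves[curve.roi_name] = curve
        out.append(pdose)
    return out


def write_dvh_table(cohort: Iterable[PatientDose], path) -> None:
    """Write a cohort back to the long-format CSV read by read_dvh_table."""
    rows = []
    for pdose in cohort:
        for roi, curve in pdose.curves.items():
            for d, v in zip(curve.dose_grid, curve.volume_fraction):
                rows.append((pdose.patient_id, roi, d, v))
    pd.DataFrame(rows, columns=["patient", "roi", "dose_gy", "volume_fraction"]) \
        .to_csv(path, index=False)


def _curve_mean_dose(curve: DVHCurve) -> float:
    # local trapezoid; dose_features.mean_dose is the public API
    if curve.dose_grid.size < 2:
        return 0.0
    return float(np.trapezoid(curve.volume_fraction, curve.dose_grid))


def _strip_side(roi: str) -> str:
    for prefix in ("left_", "right_"):
        if roi.startswith(prefix):
            return roi[len(prefix):]
    raise ValueError(f"ROI {roi!r} has no left_/right_ prefix")


def lateralize(
    pdose: PatientDose,
    pairs: Sequence[tuple[str, str]],
    allow_missing: bool = False,
) -> PatientDose:
    """Relabel paired left/right organs as ipsilateral/contralateral.

    One global primary side per patient: the side whose summed mean dose
    over all paired organs is higher becomes ipsilateral for every pair.
    Exact ties go to the left side.  Already-lateralized input is returned
    unchanged (idempotence).
    """
    pairs = [tuple(p) for p in pairs]
    families = {_strip_side(left) for left, _ in pairs}
    if all(
        f"ipsilateral_{fam}" in pdose.curves or f"contralateral_{fam}" in pdose.curves
        for fam in families
    ) and not any(
        left in pdose.curves or right in pdose.curves for left, right in pairs
    ):
        return pdose

    left_sum = right_sum = 0.0
    present_pairs: list[tuple[str, str]] = []
    for left, right in pairs:
        lh, rh = left in pdose.curves, right in pdose.curves
        if not (lh or rh):
            raise KeyError(
                f"patient {pdose.patient_id}: neither {left!r} nor {right!r} present"
            )
        if not (lh and rh):
            if not allow_missing:
                raise KeyError(
                    f"patient {pdose.patient_id}: missing one of {left!r}/{right!r}"
                )
            log.warning("patient %s: pair %s/%s incomplete", pdose.patient_id, left, right)
        if lh:
            left_sum += _curve_mean_dose(pdose.curves[left])
        if rh:
            right_sum += _curve_mean_dose(pdose.curves[right])
        present_pairs.append((left, right))

    primary_left = left_sum >= right_sum  # tie -> left
    curves: dict[str, DVHCurve] = {}
    sided = {name for pair in pairs for name in pair}
    for roi, curve in pdose.curves.items():
        if roi not in sided:
            curves[roi] = curve
    for left, right in present_pairs:
        fam = _strip_side(left)
        ipsi_src, contra_src = (left, right) if primary_left else (right, left)
        for label, src in (("ipsilateral", ipsi_src), ("contralateral", contra_src)):
            if src in pdose.curves:
                new_name = f"{label}_{fam}"
                curves[new_name] = replace(pdose.curves[src], roi_name=new_name)
    return PatientDose(patient_id=pdose.patient_id, curves=curves)


def lateralize_cohort(
    cohort: Iterable[PatientDose],
    pairs: Sequence[tuple[str, str]],
    allow_missing: bool = False,
) -> list[PatientDose]:
    return [lateralize(p, pairs, allow_missing=allow_missing) for p in cohort]
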