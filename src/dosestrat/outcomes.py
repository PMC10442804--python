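"""Longitudinal symptom ratings, eligibility, imputation and endpoints.

Ratings are 0-10 integer severities (MDASI-style) per patient, symptom and
timepoint (baseline, 7 weekly on-treatment ratings, 6-week and 6-month
follow-ups).  Analysis endpoints per symptom are binary: a 6-month rating
strictly above a severity threshold (default 4, "severe"), and a
change-from-baseline strictly above the same threshold.  Missing baselines
are filled by a denoising autoencoder trained on patients with complete
enough questionnaires; on-treatment ratings enter only as imputer inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.neural_network import MLPRegressor

from .config import LATE_TIMEPOINT, TIMEPOINTS

log = logging.getLogger("dosestrat")


@dataclass
class SymptomTable:
    """Patient x (timepoint, symptom) integer ratings in 0..10, NaN = missing.

    ``ratings`` columns are a 2-level MultiIndex (timepoint, symptom) with
    timepoints in protocol order.
    """

    ratings: pd.DataFrame
    imputed_mask: pd.DataFrame | None = None

    def __post_init__(self):
        cols = self.ratings.columns
        if cols.nlevels != 2:
            raise ValueError("ratings needs (timepoint, symptom) columns")
        tps = [t for t in TIMEPOINTS if t in cols.get_level_values(0)]
        self.ratings = self.ratings.reindex(
            columns=pd.MultiIndex.from_product(
                [tps, sorted(cols.get_level_values(1).unique())],
                names=["timepoint", "symptom"],
            )
        )
        vals = self.ratings.to_numpy(dtype=float)
        bad = vals[np.isfinite(vals)]
        if bad.size and (bad.min() < 0 or bad.max() > 10):
            raise ValueError("ratings must lie in 0..10")

    @property
    def symptoms(self) -> list[str]:
        return list(self.ratings.columns.get_level_values(1).unique())

    @property
    def timepoints(self) -> list[str]:
        return list(self.ratings.columns.get_level_values(0).unique())

    def completeness(self) -> pd.Series:
        """Fraction of items answered per patient across the whole window."""
        return self.ratings.notna().mean(axis=1).rename("completeness")

    def copy(self) -> "SymptomTable":
        return SymptomTable(
            self.ratings.copy(),
            None if self.imputed_mask is None else self.imputed_mask.copy(),
        )


def read_symptom_table(path) -> SymptomTable:
    """Read a long CSV (patient, timepoint, symptom, rating)."""
    df = pd.read_csv(path)
    required = {"patient", "timepoint", "symptom", "rating"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"symptom table missing columns: {sorted(missing)}")
    wide = df.pivot_table(
        index="patient", columns=["timepoint", "symptom"], values="rating",
        aggfunc="first",
    )
    wide.index = wide.index.astype(str)
    return SymptomTable(wide)


def write_symptom_table(st: SymptomTable, path) -> None:
    long = st.ratings.stack(["timepoint", "symptom"], future_stack=True)
    long = long.dropna().rename("rating").reset_index()
    long.columns = ["patient", "timepoint", "symptom", "rating"]
    long.to_csv(path, index=False)


def eligibility_filter(
    st: SymptomTable, symptom: str, min_completeness: float = 0.7
) -> tuple[list[str], dict[str, str]]:
    """Retain patients with enough answered items and a 6-month rating.

    Completeness is counted across all items in the whole observation
    window.  Returns (retained patient ids, exclusion reasons).
    """
    comp = st.completeness()
    late = st.ratings[(LATE_TIMEPOINT, symptom)]
    retained, excluded = [], {}
    for pid in st.ratings.index:
        if comp[pid] < min_completeness:
            excluded[str(pid)] = "completeness"
        elif pd.isna(late[pid]):
            excluded[str(pid)] = "no 6-month rating"
        else:
            retained.append(pid)
    for pid, reason in excluded.items():
        log.info("excluding patient %s: %s", pid, reason)
    return retained, excluded


@dataclass
class EndpointTable:
    """Per-patient binary endpoints for one symptom."""

    symptom: str
    table: pd.DataFrame = field(default_factory=pd.DataFrame)
    # columns: late_severe (bool), change_severe (boolean, NaN when no
    # baseline), baseline_imputed (bool)

    @property
    def late_severe(self) -> pd.Series:
        return self.table["late_severe"]

    @property
    def change_severe(self) -> pd.Series:
        return self.table["change_severe"]


# ---------------------------------------------------------------- imputer

def _corrupt(x: np.ndarray, rng: np.random.Generator, p: float) -> np.ndarray:
    """Multiplicative zeroing noise: each entry dropped to 0 with prob p."""
    keep = rng.random(x.shape) >= p
    return x * keep


def impute_baseline(
    st: SymptomTable,
    seed: int = 0,
    hidden: tuple[int, int] = (32, 16),
    corruption: float = 0.5,
    learning_rate: float = 1e-3,
    max_epochs: int = 2000,
    patience: int = 50,
    min_train: int = 30,
    n_corrupt_copies: int = 10,
    min_completeness: float = 0.7,
) -> SymptomTable:
    """Fill missing baseline ratings with a denoising autoencoder.

    The network input is every rating at every timepoint, scaled to [0,1]
    with missing entries as 0.  Training rows are patients with an observed
    baseline and at least ``min_completeness`` of all items; each is
    presented ``n_corrupt_copies`` times under Bernoulli zeroing corruption
    (zeroing probability drawn per copy, up to ``corruption``) with the
    uncorrupted vector as the regression target (two ReLU hidden layers,
    Adam, MSE, early stopping).  Predicted
    baselines are clipped to [0,10], rounded to integers, and written only
    into missing cells.  Deterministic given ``seed``.  With fewer than
    ``min_train`` trainable patients, falls back to per-symptom median
    imputation with a warning.
    """
    out = st.copy()
    baseline = out.ratings["baseline"]
    missing = baseline.isna()
    mask = pd.DataFrame(
        False, index=out.ratings.index, columns=out.ratings.columns
    )
    if not missing.to_numpy().any():
        out.imputed_mask = mask
        return out

    comp = out.completeness()
    has_baseline = baseline.notna().all(axis=1)
    train_ids = out.ratings.index[(comp >= min_completeness) & has_baseline]

    filled = out.ratings.copy()
    if len(train_ids) < min_train:
        log.warning(
            "only %d complete patients (< %d): median baseline imputation",
            len(train_ids), min_train,
        )
        med = baseline.median()
        for sym in baseline.columns:
            fill = 0.0 if pd.isna(med[sym]) else float(med[sym])
            col = ("baseline", sym)
            sel = out.ratings[col].isna()
            filled.loc[sel, col] = round(fill)
            mask.loc[sel, col] = True
        out.ratings = filled
        out.imputed_mask = mask
        return out

    rng = np.random.default_rng(seed)
    x_train = out.ratings.loc[train_ids].to_numpy(dtype=float)
    x_train = np.nan_to_num(x_train, nan=0.0) / 10.0
    # each presentation is corrupted at a level drawn up to ``corruption``,
    # so inference-time inputs (only a few cells missing) are in the
    # training distribution and the net cannot key on overall input scale
    x_aug = np.vstack([
        _corrupt(x_train, rng, rng.uniform(0.0, corruption))
        for _ in range(n_corrupt_copies)
    ])
    y_aug = np.vstack([x_train] * n_corrupt_copies)

    net = MLPRegressor(
        hidden_layer_sizes=tuple(hidden),
        activation="relu",
        solver="adam",
        learning_rate_init=learning_rate,
        max_iter=max_epochs,
        early_stopping=True,
        validation_fraction=0.1,
        n_iter_no_change=patience,
        random_state=int(rng.integers(2**31 - 1)),
    )
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence chatter
        net.fit(x_aug, y_aug)

    x_all = np.nan_to_num(out.ratings.to_numpy(dtype=float), nan=0.0) / 10.0
    pred = np.clip(net.predict(x_all) * 10.0, 0.0, 10.0)
    pred_df = pd.DataFrame(np.rint(pred), index=out.ratings.index,
                           columns=out.ratings.columns)
    for sym in baseline.columns:
        col = ("baseline", sym)
        sel = out.ratings[col].isna()
        filled.loc[sel, col] = pred_df.loc[sel, col]
        mask.loc[sel, col] = True
    out.ratings = filled
    out.imputed_mask = mask
    return out


def derive_endpoints(
    st: SymptomTable, symptom: str, threshold: int = 4
) -> EndpointTable:
    """Binary endpoints: 6-month rating > threshold, and change > threshold.

    ``change_severe`` is NaN (excluded downstream, logged) for patients
    still lacking a baseline after imputation.
    """
    late = st.ratings[(LATE_TIMEPOINT, symptom)]
    base = st.ratings[("baseline", symptom)]
    imputed = (
        st.imputed_mask[("baseline", symptom)]
        if st.imputed_mask is not None and ("baseline", symptom) in st.imputed_mask
        else pd.Series(False, index=st.ratings.index)
    )
    if late.isna().any():
        raise ValueError(
            "6-month ratings missing; apply eligibility_filter first"
        )
    change = late - base
    no_base = base.isna()
    if no_base.any():
        log.info("%d patients lack a baseline even after imputation; "
                 "change endpoint undefined for them", int(no_base.sum()))
    table = pd.DataFrame({
        "late_severe": late > threshold,
        "change_severe": (change > threshold).where(~no_base),
        "baseline_imputed": imputed.astype(bool),
    })
    return EndpointTable(symptom=symptom, table=table)
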