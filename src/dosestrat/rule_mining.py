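"""Distilling the high-dose cluster into dose-threshold rules.

The high-dose (HD) mixture component is approximated by a short conjunction
of exceedance rules ("feature > threshold Gy").  Candidate thresholds are
midpoints between consecutive observed values (quantile-thinned to a cap);
splits are scored by the plug-in empirical mutual information (bits) with
HD membership; a beam search over conjunctions (beam width 25, depth 2 by
default) returns the best rule set.  Patients exceeding all thresholds form
the simplified high-dose (SHD) group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .dose_features import DoseFeatureMatrix

log = logging.getLogger("dosestrat")


# ------------------------------------------------------------- primitives

def candidate_thresholds(values, max_candidates: int = 64) -> np.ndarray:
    """Midpoints between consecutive distinct sorted values.

    With more than ``max_candidates`` midpoints, exactly that many are kept
    at evenly spaced quantiles of the midpoint set.  Deterministic.
    """
    vals = np.unique(np.asarray(values, dtype=float))
    if vals.size < 2:
        return np.empty(0)
    mids = 0.5 * (vals[:-1] + vals[1:])
    if mids.size <= max_candidates:
        return mids
    return np.quantile(mids, np.linspace(0.0, 1.0, max_candidates))


def _mi_from_counts(n11, n10, n01, n00) -> float:
    return float(_mi_vec(np.asarray([n11], float), np.asarray([n10], float),
                         np.asarray([n01], float), np.asarray([n00], float))[0])


def _mi_vec(n11, n10, n01, n00):
    """Plug-in MI (bits) for vectors of 2x2 cell counts; 0*log0 := 0."""
    n = n11 + n10 + n01 + n00
    out = np.zeros_like(n11, dtype=float)
    ok = n > 0
    r1, r0 = n11 + n10, n01 + n00
    c1, c0 = n11 + n01, n10 + n00
    for cell, row, col in ((n11, r1, c1), (n10, r1, c0),
                           (n01, r0, c1), (n00, r0, c0)):
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(
                ok & (cell > 0),
                cell / n * np.log2(np.where(cell > 0, cell * n, 1.0)
                                   / np.where(row * col > 0, row * col, 1.0)),
                0.0,
            )
        out += term
    return out


def mutual_information(split, target) -> float:
    """Empirical mutual information (bits) between two binary vectors."""
    a = np.asarray(split, dtype=bool)
    b = np.asarray(target, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    n11 = np.count_nonzero(a & b)
    n10 = np.count_nonzero(a & ~b)
    n01 = np.count_nonzero(~a & b)
    n00 = a.size - n11 - n10 - n01
    return _mi_from_counts(n11, n10, n01, n00)


def _mi_many(masks: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """MI (bits) and recall of each column-mask of ``masks`` vs target y."""
    npos = float(np.count_nonzero(y))
    n = float(y.size)
    n11 = (masks & y[:, None]).sum(axis=0).astype(float)
    n1 = masks.sum(axis=0).astype(float)
    n10 = n1 - n11
    n01 = npos - n11
    n00 = n - n1 - npos + n11
    mi = _mi_vec(n11, n10, n01, n00)
    recall = n11 / npos if npos else np.zeros_like(n11)
    return mi, recall


# ------------------------------------------------------------------ types

@dataclass(frozen=True)
class Rule:
    """One exceedance split: feature value strictly above a dose threshold."""

    feature_name: str
    threshold: float
    direction: str = ">"

    def display(self, ndigits: int = 0) -> str:
        thr = round(self.threshold, ndigits)
        thr = int(thr) if ndigits == 0 else thr
        return f"{self.feature_name} > {thr}"


@dataclass
class RuleSet:
    """An ordered conjunction of rules plus its quality vs the HD labels.

    Membership is the AND over rules; an empty rule set has no members.
    """

    rules: tuple[Rule, ...]
    mi_bits: float = 0.0
    precision: float = 0.0
    recall: float = 0.0
    empty_shd: bool = False

    def membership(self, features: DoseFeatureMatrix) -> np.ndarray:
        n = len(features.patient_ids)
        if not self.rules:
            return np.zeros(n, dtype=bool)
        mask = np.ones(n, dtype=bool)
        for rule in self.rules:
            mask &= features.values[rule.feature_name].to_numpy() > rule.threshold
        return mask

    def to_yaml(self, path) -> None:
        payload = {
            "rules": [
                {"feature": r.feature_name, "threshold": float(r.threshold),
                 "direction": r.direction, "display": r.display()}
                for r in self.rules
            ],
            "mi_bits": float(self.mi_bits),
            "precision": float(self.precision),
            "recall": float(self.recall),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RuleSet":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        rules = tuple(
            Rule(r["feature"], float(r["threshold"]), r.get("direction", ">"))
            for r in payload["rules"]
        )
        return cls(rules, payload.get("mi_bits", 0.0),
                   payload.get("precision", 0.0), payload.get("recall", 0.0))


def rule_quality(
    rs: RuleSet, features: DoseFeatureMatrix, hd_labels
) -> tuple[float, float, float]:
    """(precision, recall, mi_bits) of the SHD group vs the HD labels."""
    if not rs.rules:
        raise ValueError("empty RuleSet")
    y = np.asarray(hd_labels, dtype=bool)
    shd = rs.membership(features)
    tp = np.count_nonzero(shd & y)
    fp = np.count_nonzero(shd & ~y)
    fn = np.count_nonzero(~shd & y)
    if tp + fp == 0:
        log.warning("SHD group is empty; precision reported as 0")
        precision = 0.0
    else:
        precision = tp / (tp + fp)
    recall = tp / (tp + fn) if tp + fn else 0.0
    return precision, recall, mutual_information(shd, y)


# ------------------------------------------------------------ beam search

def _sort_key(mi, recall, rules):
    # higher MI, then higher recall, then fewer rules, then lexicographic
    return (
        -mi,
        -recall,
        len(rules),
        tuple(r.feature_name for r in rules),
        tuple(r.threshold for r in rules),
    )


def beam_search_rules(
    features: DoseFeatureMatrix,
    hd_labels,
    beam_width: int = 25,
    max_depth: int = 2,
    max_thresholds: int = 64,
) -> RuleSet:
    """Find the threshold conjunction most informative about HD membership.

    Depth 1 scores every (feature, midpoint-threshold) split by MI with the
    HD labels and keeps the top ``beam_width``.  At each further depth,
    every beam conjunction is extended by one split whose candidate
    thresholds are recomputed on the sub-cohort already satisfying the
    conjunction; the MI of the full conjunction is scored on the whole
    cohort, and the global top ``beam_width`` conjunctions survive.  Search
    stops at ``max_depth`` or when no extension strictly increases MI.
    Ties break toward higher recall, then fewer rules, then lexicographic
    feature names.
    """
    if isinstance(hd_labels, pd.Series):
        hd_labels = hd_labels.reindex(features.values.index).to_numpy()
    y = np.asarray(hd_labels, dtype=bool)
    x = features.values.to_numpy(dtype=float)
    names = features.feature_names
    if y.size != x.shape[0]:
        raise ValueError("hd_labels length does not match feature matrix")
    if not (y.any() and (~y).any()):
        raise ValueError("need at least one HD-positive and one negative patient")

    def score_extensions(parent_rules, parent_mask):
        """All one-split extensions of a (possibly empty) conjunction."""
        sub = x[parent_mask]
        found = []
        for f_idx, name in enumerate(names):
            thrs = candidate_thresholds(sub[:, f_idx], max_thresholds)
            if thrs.size == 0:
                continue
            masks = parent_mask[:, None] & (x[:, f_idx:f_idx + 1] > thrs[None, :])
            mi, recall = _mi_many(masks, y)
            for t_idx, thr in enumerate(thrs):
                rules = parent_rules + (Rule(name, float(thr)),)
                found.append((mi[t_idx], recall[t_idx], rules))
        return found

    all_true = np.ones(y.size, dtype=bool)
    cands = score_extensions((), all_true)
    if not cands:
        log.warning("all feature columns constant; returning empty RuleSet")
        return RuleSet(rules=(), empty_shd=True)

    cands.sort(key=lambda c: _sort_key(*c))
    best = cands[0]
    beam = cands[:beam_width]

    def mask_of(rules):
        m = all_true.copy()
        for rule in rules:
            m &= x[:, names.index(rule.feature_name)] > rule.threshold
        return m

    for _depth in range(2, max_depth + 1):
        nxt = []
        for _mi, _rec, rules in beam:
            pmask = mask_of(rules)
            if not pmask.any():
                continue
            nxt.extend(score_extensions(rules, pmask))
        if not nxt:
            break
        nxt.sort(key=lambda c: _sort_key(*c))
        if nxt[0][0] <= best[0] + 1e-12:
            break  # no strict MI gain
        best = nxt[0]
        beam = nxt[:beam_width]

    mi, recall, rules = best
    rs = RuleSet(rules=rules)
    precision, recall_, mi_ = rule_quality(rs, features, hd_labels)
    rs.mi_bits = mi_
    rs.precision = precision
    rs.recall = recall_
    rs.empty_shd = not rs.membership(features).any()
    return rs
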