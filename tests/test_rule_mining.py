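"""Threshold candidates, mutual information, and the conjunction beam search."""

import numpy as np
import pandas as pd
import pytest

from dosestrat import (Rule, RuleSet, beam_search_rules, candidate_thresholds,
                       mutual_information, rule_quality)
from dosestrat.dose_features import DoseFeatureMatrix


def _matrix(x):
    return DoseFeatureMatrix(
        pd.DataFrame(np.asarray(x, dtype=float),
                     index=pd.Index([f"p{i}" for i in range(len(x))],
                                    name="patient"),
                     columns=[f"f{j}" for j in range(np.shape(x)[1])]))


# ------------------------------------------------------------- thresholds

class TestCandidateThresholds:
    def test_midpoints_of_distinct_values(self):
        np.testing.assert_allclose(candidate_thresholds([0, 10, 20]), [5, 15])
        np.testing.assert_allclose(candidate_thresholds([20, 0, 10, 10]), [5, 15])

    def test_constant_column_gives_none(self):
        assert candidate_thresholds([7, 7, 7]).size == 0
        assert candidate_thresholds([3.0]).size == 0

    def test_many_values_thinned_to_quantiles(self):
        vals = np.arange(1000, dtype=float)
        got = candidate_thresholds(vals, max_candidates=64)
        mids = (vals[:-1] + vals[1:]) / 2
        expected = np.quantile(mids, np.linspace(0, 1, 64))
        assert got.size == 64
        np.testing.assert_allclose(got, expected)


# ----------------------------------------------------- mutual information

def _mi_oracle(a, b):
    """Direct plug-in formula, independent of the package implementation."""
    a, b = np.asarray(a, bool), np.asarray(b, bool)
    n = a.size
    total = 0.0
    for av in (True, False):
        for bv in (True, False):
            pj = np.mean((a == av) & (b == bv))
            pa, pb = np.mean(a == av), np.mean(b == bv)
            if pj > 0:
                total += pj * np.log2(pj / (pa * pb))
    return total


class TestMutualInformation:
    def test_identical_balanced_split_is_one_bit(self):
        y = np.array([True] * 40 + [False] * 40)
        assert mutual_information(y, y) == pytest.approx(1.0, abs=1e-12)

    def test_independent_counts_are_zero_bits(self):
        # exact product form: counts (20, 20; 20, 20)
        a = np.array([True] * 40 + [False] * 40)
        b = np.tile([True, False], 40)
        assert mutual_information(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_2x2_closed_form(self):
        # counts (30, 10; 10, 30), n = 80:
        # MI = 0.75 log2(1.5) + 0.25 log2(0.5)
        a = np.array([True] * 40 + [False] * 40)
        b = np.array([True] * 30 + [False] * 10 + [True] * 10 + [False] * 30)
        expected = 0.75 * np.log2(1.5) - 0.25
        assert mutual_information(a, b) == pytest.approx(expected, abs=1e-12)
        assert mutual_information(a, b) == pytest.approx(_mi_oracle(a, b), abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mutual_information([True, False], [True])

    def test_matches_oracle_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a = rng.random(60) < rng.uniform(0.2, 0.8)
            b = rng.random(60) < rng.uniform(0.2, 0.8)
            assert mutual_information(a, b) == pytest.approx(
                _mi_oracle(a, b), abs=1e-12)


# ------------------------------------------------------------ beam search

def _exhaustive_best_mi(x, y, max_depth=2, cap=64):
    """Best conjunction MI by brute force over the same candidate space:
    depth-1 splits everywhere, depth-2 thresholds from each sub-cohort."""
    n, p = x.shape
    best1 = 0.0
    d1 = []
    for j in range(p):
        for t in candidate_thresholds(x[:, j], cap):
            mask = x[:, j] > t
            m = _mi_oracle(mask, y)
            d1.append((j, t, mask))
            best1 = max(best1, m)
    best = best1
    if max_depth >= 2:
        for j, t, mask in d1:
            if not mask.any():
                continue
            sub = x[mask]
            for j2 in range(p):
                for t2 in candidate_thresholds(sub[:, j2], cap):
                    m = _mi_oracle(mask & (x[:, j2] > t2), y)
                    if m > best + 1e-12:
                        best = m
    return best, best1


class TestBeamSearch:
    def test_depth1_equals_exhaustive_single_split(self):
        rng = np.random.default_rng(2)
        x = np.round(rng.uniform(0, 30, (150, 6)))
        y = (x[:, 2] + rng.normal(0, 3, 150)) > 18
        fm = _matrix(x)
        rs = beam_search_rules(fm, y, beam_width=25, max_depth=1)
        _, best1 = _exhaustive_best_mi(x, y, max_depth=1)
        assert rs.mi_bits == pytest.approx(best1, abs=1e-12)
        assert len(rs.rules) == 1

    def test_full_width_depth2_equals_exhaustive(self):
        rng = np.random.default_rng(3)
        x = np.round(rng.uniform(0, 20, (120, 4)))
        y = (x[:, 0] > 10) & (x[:, 1] > 8)
        fm = _matrix(x)
        n_splits = sum(candidate_thresholds(x[:, j]).size for j in range(4))
        rs = beam_search_rules(fm, y, beam_width=n_splits, max_depth=2)
        best, _ = _exhaustive_best_mi(x, y, max_depth=2)
        assert rs.mi_bits == pytest.approx(best, abs=1e-12)

    def test_planted_two_rule_conjunction_recovered_exactly(self):
        rng = np.random.default_rng(4)
        # integer-valued doses keep the candidate set below the thinning
        # cap, so the exact planted midpoints are searchable
        x = np.column_stack([
            np.round(rng.uniform(30, 70, 500)), np.round(rng.uniform(10, 50, 500)),
            np.round(rng.uniform(20, 60, 500)), np.round(rng.uniform(20, 60, 500)),
        ])
        y = (x[:, 0] > 50) & (x[:, 1] > 30)
        rs = beam_search_rules(_matrix(x), y)
        assert rs.precision == 1.0 and rs.recall == 1.0
        assert {r.feature_name for r in rs.rules} == {"f0", "f1"}

    def test_planted_single_threshold_yields_one_rule(self):
        rng = np.random.default_rng(5)
        x = np.round(rng.uniform(0, 100, (300, 5)) / 2) * 2
        y = x[:, 3] > 50
        rs = beam_search_rules(_matrix(x), y)
        # a second rule cannot strictly increase MI beyond the perfect split
        assert len(rs.rules) == 1
        assert rs.rules[0].feature_name == "f3"
        assert rs.precision == 1.0 and rs.recall == 1.0

    def test_conjunction_mi_at_least_depth1_prefix(self):
        rng = np.random.default_rng(6)
        x = rng.uniform(0, 60, (200, 6))
        y = (x[:, 0] > 30) & (x[:, 1] > 20)
        rs = beam_search_rules(_matrix(x), y)
        _, best1 = _exhaustive_best_mi(x, y, max_depth=1)
        assert rs.mi_bits >= best1 - 1e-12

    def test_constant_features_give_empty_ruleset(self, caplog):
        x = np.full((50, 3), 7.0)
        y = np.array([True] * 25 + [False] * 25)
        rs = beam_search_rules(_matrix(x), y)
        assert rs.rules == () and rs.empty_shd

    def test_single_class_labels_rejected(self):
        x = np.random.default_rng(0).uniform(0, 1, (20, 2))
        with pytest.raises(ValueError):
            beam_search_rules(_matrix(x), np.ones(20, dtype=bool))


class TestRuleQuality:
    def test_shd_equal_hd_gives_unit_precision_recall_and_entropy_mi(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(0, 100, (200, 3))
        y = x[:, 0] > 60
        rs = RuleSet(rules=(Rule("f0", 60.0),))
        prec, rec, mi = rule_quality(rs, _matrix(x), y)
        assert prec == 1.0 and rec == 1.0
        prev = y.mean()
        entropy = -(prev * np.log2(prev) + (1 - prev) * np.log2(1 - prev))
        assert mi == pytest.approx(entropy, abs=1e-12)

    def test_complement_shd_has_zero_precision_but_full_mi(self):
        x = np.column_stack([np.concatenate([np.full(50, 80.0), np.full(50, 10.0)])])
        y = x[:, 0] < 40  # SHD (f0 > 40) is exactly the complement, 50/50
        rs = RuleSet(rules=(Rule("f0", 40.0),))
        prec, rec, mi = rule_quality(rs, _matrix(x), y)
        assert prec == 0.0 and rec == 0.0
        assert mi == pytest.approx(1.0, abs=1e-12)

    def test_membership_reproduces_stored_quality(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(0, 60, (300, 5))
        y = (x[:, 0] > 30) & (x[:, 1] > 40)
        fm = _matrix(x)
        rs = beam_search_rules(fm, y)
        shd = rs.membership(fm)
        tp = np.sum(shd & y)
        assert rs.precision == tp / shd.sum()
        assert rs.recall == tp / y.sum()

    def test_empty_ruleset_rejected(self):
        with pytest.raises(ValueError):
            rule_quality(RuleSet(rules=()), _matrix(np.zeros((3, 1))),
                         np.array([True, False, True]))


def test_yaml_round_trip(tmp_path):
    rs = RuleSet(rules=(Rule("ipc:V50", 40.2), Rule("supraglottic_larynx:V60", 46.0)),
                 mi_bits=0.5, precision=0.9, recall=0.95)
    rs.to_yaml(tmp_path / "r.yaml")
    back = RuleSet.from_yaml(tmp_path / "r.yaml")
    assert back.rules == rs.rules
    assert back.precision == rs.precision
    assert back.rules[0].display() == "ipc:V50 > 40"
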