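"""Evaluation suite: AUROC oracle, bootstrap, averaging, calibration, cutoffs."""

import numpy as np
import pandas as pd
import pytest

from doepred._streams import stream
from doepred.evaluate import (auroc, bootstrap_ci, calibration, macro_micro,
                              optimal_cutoff, evaluation_report)


def pair_count_auroc(scores, labels):
    """O(n^2) oracle: fraction of (positive, negative) pairs ranked correctly."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_all_ties_half(self):
        assert auroc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auroc([0.1, 0.9], [1, 1])

    def test_matches_pair_count_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(10, 200))
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            scores = np.round(rng.normal(size=n), 2)  # coarse -> ties occur
            assert auroc(scores, labels) == pytest.approx(
                pair_count_auroc(scores, labels), abs=1e-12)

    def test_complement_symmetry(self, scored_sample):
        s, y = scored_sample
        assert auroc(-np.asarray(s), y) == pytest.approx(1 - auroc(s, y), abs=1e-12)

    def test_invariant_under_monotone_transform(self, scored_sample):
        s, y = scored_sample
        assert auroc(np.exp(np.asarray(s)), y) == pytest.approx(auroc(s, y), abs=1e-12)


class TestBootstrap:
    def test_constant_metric_zero_width(self, scored_sample):
        s, y = scored_sample
        point, lo, hi = bootstrap_ci(lambda a, b: 0.42, s, y, n_boot=50, seed=1)
        assert point == lo == hi == 0.42

    def test_fixed_seed_reproducible(self, scored_sample):
        s, y = scored_sample
        assert bootstrap_ci(auroc, s, y, n_boot=100, seed=3) == \
            bootstrap_ci(auroc, s, y, n_boot=100, seed=3)

    def test_reverse_percentile_formula_hand_oracle(self, scored_sample):
        """Replay the resample stream and apply the interval formula by hand."""
        s, y = scored_sample
        s = np.asarray(s, dtype=float)
        point, lo, hi = bootstrap_ci(auroc, s, y, n_boot=80, seed=9)
        rng = stream(9, "bootstrap")
        stats = []
        while len(stats) < 80:
            idx = rng.integers(len(s), size=len(s))
            if len(np.unique(np.asarray(y)[idx])) < 2:
                continue
            stats.append(auroc(s[idx], np.asarray(y)[idx]))
        q_lo, q_hi = np.quantile(stats, [0.025, 0.975])
        assert point == pytest.approx(auroc(s, y))
        assert lo == pytest.approx(2 * point - q_hi, abs=1e-12)
        assert hi == pytest.approx(2 * point - q_lo, abs=1e-12)

    def test_degenerate_resamples_redrawn(self):
        # 1 positive in 12: many resamples miss it and must be redrawn
        y = np.zeros(12, dtype=int)
        y[0] = 1
        s = np.linspace(0, 1, 12)
        point, lo, hi = bootstrap_ci(auroc, s, y, n_boot=50, seed=4)
        assert np.isfinite([point, lo, hi]).all()


class TestMacroMicro:
    def test_single_class_macro_equals_micro(self, scored_sample):
        s, y = scored_sample
        macro, micro = macro_micro({"only": (s, y)})
        assert macro == pytest.approx(micro)

    def test_identical_classes_equal(self, scored_sample):
        s, y = scored_sample
        macro, micro = macro_micro({"a": (s, y), "b": (s, y)})
        assert macro == pytest.approx(micro)

    def test_micro_equals_pooled_oracle(self, rng):
        per_class = {}
        pooled_s, pooled_y = [], []
        for cls in "abc":
            n = int(rng.integers(50, 150))
            y = rng.integers(0, 2, size=n)
            y[0], y[1] = 0, 1
            s = rng.normal(size=n) + 0.8 * y
            per_class[cls] = (s, y)
            pooled_s.append(s)
            pooled_y.append(y)
        macro, micro = macro_micro(per_class)
        assert micro == pytest.approx(auroc(np.concatenate(pooled_s), np.concatenate(pooled_y)))
        assert macro == pytest.approx(np.mean([auroc(s, y) for s, y in per_class.values()]))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            macro_micro({})


class TestCalibration:
    def test_perfectly_calibrated_groups(self):
        p, y = [], []
        for rate, n in ((0.15, 400), (0.45, 400), (0.85, 400)):
            p += [rate] * n
            y += [1] * int(rate * n) + [0] * (n - int(rate * n))
        res = calibration(np.array(p), np.array(y))
        assert res.slope == pytest.approx(1.0, abs=1e-9)
        assert res.intercept == pytest.approx(0.0, abs=1e-9)

    def test_single_bin_flagged(self):
        res = calibration(np.full(100, 0.5), np.r_[np.ones(50), np.zeros(50)])
        assert res.flagged and res.slope is None
        assert len(res.curve) == 1
        assert res.curve.iloc[0]["mean_predicted"] == pytest.approx(0.5)
        assert res.curve.iloc[0]["observed_rate"] == pytest.approx(0.5)

    def test_bin_counts_sum_to_n(self, rng):
        p = rng.random(500)
        y = (rng.random(500) < p).astype(int)
        res = calibration(p, y)
        assert res.curve["count"].sum() == 500

    def test_out_of_range_predictions_rejected(self):
        with pytest.raises(ValueError):
            calibration([1.2, 0.5], [1, 0])


def grid_cutoff_oracle(preds, labels, beta, n_grid=10_000):
    """Dense-grid scan over candidate thresholds."""
    preds = np.asarray(preds, dtype=float)
    labels = np.asarray(labels).astype(int)
    grid = np.unique(np.r_[np.linspace(preds.min(), preds.max(), n_grid), preds])
    best = (-1.0, None)
    b2 = beta * beta
    for t in grid:
        called = preds >= t
        tp = int((called & (labels == 1)).sum())
        if called.sum() == 0:
            continue
        prec = tp / called.sum()
        rec = tp / labels.sum()
        f = (1 + b2) * prec * rec / (b2 * prec + rec) if (prec + rec) else 0.0
        if f > best[0]:
            best = (f, t)
    return best[0]


class TestOptimalCutoff:
    def test_textbook_example(self):
        res = optimal_cutoff([0.1, 0.4, 0.6, 0.9], [0, 0, 1, 1], beta=1.0)
        assert res.threshold == 0.6 and res.f_beta == pytest.approx(1.0)
        assert res.precision == 1.0 and res.recall == 1.0

    def test_beta_to_zero_favors_precision(self, rng):
        p = rng.random(200)
        y = (p + rng.normal(scale=0.2, size=200) > 0.7).astype(int)
        y[np.argmax(p)] = 1  # a precision-1 threshold exists
        res = optimal_cutoff(p, y, beta=1e-6)
        assert res.precision == pytest.approx(1.0)

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError):
            optimal_cutoff([0.1, 0.9], [0, 0])

    def test_tie_breaks_to_smallest_threshold(self):
        # thresholds 0.9 and 0.8 both give F=1 when both top items are positive
        res = optimal_cutoff([0.1, 0.8, 0.9], [0, 1, 1], beta=1.0)
        assert res.threshold == 0.8

    @pytest.mark.parametrize("beta", [1.0, 0.2])
    def test_matches_dense_grid_oracle(self, rng, beta):
        for _ in range(50):
            n = int(rng.integers(10, 60))
            p = np.round(rng.random(n), 3)
            y = rng.integers(0, 2, size=n)
            y[int(rng.integers(n))] = 1
            res = optimal_cutoff(p, y, beta=beta)
            assert res.f_beta == pytest.approx(grid_cutoff_oracle(p, y, beta), abs=1e-12)

    def test_optimum_dominates_all_distinct_thresholds(self, rng):
        p = rng.random(100)
        y = rng.integers(0, 2, size=100)
        y[0] = 1
        res = optimal_cutoff(p, y, beta=0.5)
        for t in np.unique(p):
            called = p >= t
            tp = int((called & (y == 1)).sum())
            prec = tp / called.sum()
            rec = tp / y.sum()
            f = 1.25 * prec * rec / (0.25 * prec + rec) if (prec + rec) else 0.0
            assert res.f_beta >= f - 1e-12


def test_evaluation_report_structure(scored_sample, tmp_path):
    s, y = scored_sample
    p = 1 / (1 + np.exp(-np.asarray(s)))
    report = evaluation_report({"inhibitor": (p, y)}, beta=1.0, n_boot=50, seed=2)
    entry = report.per_class["inhibitor"]
    assert 0 <= entry["auroc"] <= 1
    assert entry["cutoff"]["beta"] == 1.0
    text = report.to_json(tmp_path / "report.json")
    assert (tmp_path / "report.json").read_text() == text
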