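"""Decoy-counting FDR arithmetic against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from psmrescore import (
    ThresholdStat,
    compute_threshold_stats,
    estimate_fdr,
    mean_sensitivity,
    select_threshold,
    sensitivity_curve,
    write_threshold_stats,
)

from conftest import labeled_dataset


def brute_force_fdr(labels, probs, t):
    """Independent oracle: literal filter-and-count of D_t/(N_t - D_t)."""
    acc = [(l, p) for l, p in zip(labels, probs) if p >= t]
    d_t = sum(1 for l, _ in acc if l == 0)
    n_t = len(acc)
    if n_t - d_t == 0:
        return 0.0 if d_t == 0 else 1.0
    return d_t / (n_t - d_t)


def test_one_decoy_per_hundred_targets_is_one_percent():
    labels = [1] * 100 + [0]
    probs = [0.9] * 100 + [0.9]
    assert estimate_fdr(labels, probs, 0.9) == pytest.approx(0.01)


def test_zero_numerator_is_zero():
    assert estimate_fdr([1, 1, 0], [0.9, 0.8, 0.1], 0.5) == 0.0


def test_only_decoys_accepted_caps_at_one():
    assert estimate_fdr([0, 1], [0.9, 0.1], 0.5) == 1.0


def test_empty_input_rejected():
    with pytest.raises(ValueError):
        estimate_fdr([], [], 0.5)


@settings(max_examples=300, derandomize=True)
@given(
    data=st.lists(
        st.tuples(st.integers(0, 1), st.floats(0, 1, allow_nan=False)),
        min_size=1, max_size=40,
    ),
    t=st.floats(0, 1, allow_nan=False),
)
def test_estimate_fdr_matches_brute_force(data, t):
    labels, probs = zip(*data)
    assert estimate_fdr(labels, probs, t) == pytest.approx(
        brute_force_fdr(labels, probs, t)
    )


class TestThresholdStats:
    def test_hand_enumeration(self):
        ds = labeled_dataset({1: [0.9, 0.7], 0: [0.8]})
        stats = compute_threshold_stats(ds)
        by_t = {s.threshold: s for s in stats}
        assert (by_t[0.9].tp, by_t[0.9].fp, by_t[0.9].est_fdr) == (1, 0, 0.0)
        assert (by_t[0.8].tp, by_t[0.8].fp, by_t[0.8].est_fdr) == (1, 1, 1.0)
        assert (by_t[0.7].tp, by_t[0.7].fp, by_t[0.7].est_fdr) == (2, 1, 0.5)
        # sentinel above the max accepts nothing
        assert stats[0].tp == stats[0].fp == 0
        assert stats[0].threshold > 0.9

    def test_tied_probabilities_collapse(self):
        ds = labeled_dataset({1: [0.5, 0.5], 0: [0.5]})
        stats = compute_threshold_stats(ds)
        assert len(stats) == 2  # sentinel + single operating point
        assert (stats[1].tp, stats[1].fp) == (2, 1)

    def test_counts_monotone_and_consistent_with_estimator(self, rng):
        n = 500
        labels = rng.integers(0, 2, n)
        probs = rng.random(n).round(2)  # force ties
        ds = labeled_dataset(
            {1: probs[labels == 1].tolist(), 0: probs[labels == 0].tolist()}
        )
        stats = compute_threshold_stats(ds)
        tps = [s.tp for s in stats]
        fps = [s.fp for s in stats]
        assert tps == sorted(tps) and fps == sorted(fps)  # decreasing threshold
        for s in stats[1:]:
            assert s.est_fdr == pytest.approx(
                brute_force_fdr(labels, probs, s.threshold)
            )
            assert s.tp + s.fn == int((labels == 1).sum())
            assert s.fp + s.tn == int((labels == 0).sum())

    def test_missing_probabilities_error(self):
        ds = labeled_dataset({1: [0.5]})
        with pytest.raises(ValueError, match="adjusted_prob"):
            compute_threshold_stats(ds, "adjusted_prob")


class TestSelectThreshold:
    def _stats(self, triples):
        return [
            ThresholdStat(threshold=t, tp=tp, fp=fp, tn=0, fn=0,
                          est_fdr=(0.0 if tp == 0 and fp == 0 else
                                   1.0 if tp == 0 else fp / tp))
            for t, tp, fp in triples
        ]

    def test_max_sensitivity_subject_to_fdr(self):
        ds = labeled_dataset({1: [0.9, 0.7], 0: [0.8]})
        sel = select_threshold(compute_threshold_stats(ds), 0.6)
        assert (sel.threshold, sel.tp, sel.est_fdr) == (0.7, 2, 0.5)

    def test_all_zero_fdr_picks_lowest_threshold(self):
        stats = self._stats([(0.9, 1, 0), (0.5, 3, 0), (0.2, 7, 0)])
        assert select_threshold(stats, 0.01).threshold == 0.2

    def test_tie_on_targets_prefers_higher_threshold(self):
        stats = self._stats([(0.9, 5, 0), (0.5, 5, 0)])
        assert select_threshold(stats, 0.01).threshold == 0.9

    def test_unreachable_fdr_returns_flagged_smallest(self):
        stats = self._stats([(0.9, 10, 1), (0.5, 20, 5)])  # fdrs 0.1, 0.25
        sel = select_threshold(stats, 0.01)
        assert sel.fallback and sel.est_fdr == pytest.approx(0.1)


class TestSensitivityCurve:
    def test_non_decreasing_on_synthetic_probs(self, rng):
        probs1 = np.clip(rng.normal(0.6, 0.2, 400), 0, 1)
        probs0 = np.clip(rng.normal(0.4, 0.2, 400), 0, 1)
        ds = labeled_dataset({1: probs1.tolist(), 0: probs0.tolist()})
        curve = sensitivity_curve(compute_threshold_stats(ds))
        counts = [c for _, c in curve]
        assert counts == sorted(counts)

    def test_matches_brute_force_maximization(self, rng):
        labels = rng.integers(0, 2, 300)
        probs = rng.random(300).round(2)
        ds = labeled_dataset(
            {1: probs[labels == 1].tolist(), 0: probs[labels == 0].tolist()}
        )
        stats = compute_threshold_stats(ds)
        for f, count in sensitivity_curve(stats):
            best = 0
            for t in np.unique(probs):
                if brute_force_fdr(labels, probs, t) <= f:
                    best = max(best, int(((probs >= t) & (labels == 1)).sum()))
            assert count == best


class TestMeanSensitivity:
    def test_constant_curve(self):
        stats = [ThresholdStat(0.5, 42, 0, 0, 0, 0.0)]
        assert mean_sensitivity(stats) == 42.0

    def test_equals_mean_of_curve(self, rng):
        probs1 = np.clip(rng.normal(0.7, 0.15, 200), 0, 1)
        probs0 = np.clip(rng.normal(0.3, 0.15, 200), 0, 1)
        ds = labeled_dataset({1: probs1.tolist(), 0: probs0.tolist()})
        stats = compute_threshold_stats(ds)
        curve = sensitivity_curve(stats)
        assert mean_sensitivity(stats) == pytest.approx(
            np.mean([c for _, c in curve])
        )


def test_stats_export_tsv(tmp_path):
    ds = labeled_dataset({1: [0.9, 0.7], 0: [0.8]})
    stats = compute_threshold_stats(ds)
    path = tmp_path / "stats.tsv"
    write_threshold_stats(stats, path)
    lines = path.read_text().strip().splitlines()
    assert lines[0].split("\t") == ["threshold", "tp", "fp", "tn", "fn", "est_fdr"]
    assert len(lines) == len(stats) + 1
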