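"""Change-point segmentation: trivial cases, brute-force oracle, properties."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from repliscope.segmentation import (
    MIN_SEGMENT_LEN,
    default_penalty,
    detect_steps,
    fit_piecewise,
    segment_rates,
)

# ---------------------------------------------------------------------------
# independent exhaustive-search oracle (enumerates all breakpoint placements)
# ---------------------------------------------------------------------------


def _oracle_cost(t, y, i, j, model):
    yy = y[i:j]
    if model == "constant":
        return float(np.sum((yy - yy.mean()) ** 2))
    tt = t[i:j]
    coeff = np.polyfit(tt, yy, 1)
    return float(np.sum((yy - np.polyval(coeff, tt)) ** 2))


def _compositions(n, min_size):
    """All orderings of segment lengths >= min_size summing to n."""
    if n == 0:
        yield ()
        return
    for first in range(min_size, n + 1):
        if n - first != 0 and n - first < min_size:
            continue
        for rest in _compositions(n - first, min_size):
            yield (first, *rest)


def oracle_segmentation(t, y, model, penalty, min_size=MIN_SEGMENT_LEN):
    n = len(y)
    best_cost, best_k, best_bkps = np.inf, np.inf, None
    cache = {}
    for comp in _compositions(n, min_size):
        edges = np.cumsum((0,) + comp)
        cost = penalty * (len(comp) - 1)
        for i, j in zip(edges[:-1], edges[1:]):
            key = (i, j)
            if key not in cache:
                cache[key] = _oracle_cost(t, y, i, j, model)
            cost += cache[key]
        k = len(comp) - 1
        if cost < best_cost - 1e-9 or (cost <= best_cost + 1e-9 and k < best_k):
            best_cost, best_k, best_bkps = cost, k, tuple(int(e) for e in edges[1:-1])
    return best_bkps, best_cost


# ---------------------------------------------------------------------------
# direct examples
# ---------------------------------------------------------------------------


def test_linear_trace_is_single_segment():
    t = np.arange(20.0)
    y = 0.58 * t + 1.0
    seg = fit_piecewise(t, y, model="linear")
    assert seg.breakpoints == ()
    rates = segment_rates(t, y, smooth=False)
    assert len(rates) == 1
    assert rates[0].rate_bp_s == pytest.approx(580.0, rel=1e-9)


def test_two_slope_trace_breakpoint_at_junction():
    t = np.arange(30.0)
    y = np.where(t < 15, 0.6 * t, 0.6 * 15)  # 600 bp/s then stalled
    seg = fit_piecewise(t, y, model="linear", penalty=0.5)
    assert len(seg.breakpoints) == 1
    assert abs(seg.breakpoints[0] - 15) <= 1


def test_constant_trace_has_no_steps():
    fit = detect_steps(np.arange(10.0), np.full(10, 3.3))
    assert fit.n_steps == 0
    assert fit.levels[0] == pytest.approx(3.3)


def test_simple_step_trace():
    fit = detect_steps(np.arange(6.0), np.array([1.0, 1, 1, 5, 5, 5]))
    assert list(fit.breakpoint_indices) == [3]
    assert fit.levels == pytest.approx([1.0, 5.0])
    assert fit.step_sizes() == pytest.approx([4.0])


def test_short_trace_returns_single_segment():
    t = np.arange(4.0)
    seg = fit_piecewise(t, np.array([0.0, 5.0, 1.0, 6.0]), model="linear")
    assert seg.breakpoints == ()


def test_rejects_bad_inputs():
    with pytest.raises(ValueError):
        fit_piecewise(np.arange(5.0), np.arange(6.0))
    with pytest.raises(ValueError):
        fit_piecewise(np.arange(10.0), np.arange(10.0), model="quadratic")
    with pytest.raises(ValueError):
        fit_piecewise(np.arange(10.0), np.arange(10.0), penalty=-1.0)


# ---------------------------------------------------------------------------
# oracle equivalence on noisy short traces
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("model", ["constant", "linear"])
def test_dp_matches_exhaustive_search(model):
    """DP optimum equals brute-force enumeration on traces of <= 30 samples."""
    rng = np.random.default_rng(42)
    for trial in range(25):
        n = int(rng.integers(8, 31))
        t = np.arange(float(n))
        k_true = int(rng.integers(1, 4))
        edges = np.sort(rng.choice(np.arange(3, n - 2), size=k_true, replace=False))
        y = np.zeros(n)
        level = 0.0
        start = 0
        for e in list(edges) + [n]:
            if model == "constant":
                y[start:e] = level
                level += rng.normal(0, 4)
            else:
                slope = rng.normal(0, 1)
                y[start:e] = y[start - 1] if start else 0.0
                y[start:e] = (y[start] if start else 0.0) + slope * np.arange(e - start)
            start = e
        y = y + rng.normal(0, 0.5, n)
        penalty = default_penalty(y, model)
        got = fit_piecewise(t, y, model=model, penalty=penalty)
        want_bkps, want_cost = oracle_segmentation(t, y, model, penalty)
        assert got.breakpoints == want_bkps, f"trial {trial}: {got.breakpoints} != {want_bkps}"
        assert got.total_cost == pytest.approx(want_cost, abs=1e-6)


# ---------------------------------------------------------------------------
# invariants
# ---------------------------------------------------------------------------


def test_objective_never_worse_than_single_segment():
    rng = np.random.default_rng(3)
    for _ in range(20):
        n = int(rng.integers(10, 60))
        y = np.cumsum(rng.normal(0, 1, n))
        t = np.arange(float(n))
        penalty = default_penalty(y)
        seg = fit_piecewise(t, y, model="linear", penalty=penalty)
        single = _oracle_cost(t, y, 0, n, "linear")
        assert seg.total_cost <= single + 1e-8


@pytest.mark.parametrize("model,n_segments", [("constant", 3), ("linear", 2)])
def test_breakpoint_recovery_under_noise(model, n_segments):
    """At SNR >= 5 and plateaus >= 5 samples, the true breakpoint count is
    recovered in >= 95% of seeded replicates."""
    rng = np.random.default_rng(7)
    sigma = 1.0
    hits = 0
    n_rep = 200
    for _ in range(n_rep):
        pieces = []
        for s in range(n_segments):
            length = int(rng.integers(6, 12))
            if model == "constant":
                pieces.append(np.full(length, 6.0 * s))  # gap 6 sigma
            else:
                slope = 3.0 if s % 2 == 0 else -3.0
                start = pieces[-1][-1] if pieces else 0.0
                pieces.append(start + slope * np.arange(1, length + 1))
        y = np.concatenate(pieces) + rng.normal(0, sigma, sum(len(p) for p in pieces))
        t = np.arange(float(len(y)))
        seg = fit_piecewise(t, y, model=model)
        if len(seg.breakpoints) == n_segments - 1:
            hits += 1
    assert hits / n_rep >= 0.95


def test_segment_rates_tile_time_span():
    rng = np.random.default_rng(11)
    t = np.arange(60.0)
    y = np.concatenate([0.58 * np.arange(30), 0.58 * 29 * np.ones(30)])
    y += rng.normal(0, 0.05, 60)
    segs = segment_rates(t, y)
    assert segs[0].start_s == 0.0
    assert segs[-1].end_s == 59.0
    for a, b in zip(segs[:-1], segs[1:]):
        assert b.start_index == a.end_index
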