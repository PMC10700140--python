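import numpy as np
import pytest
from scipy.stats import hypergeom

import boutwise as bw
from boutwise import cells as cm
from boutwise.microstructure import Bout


def _matrix(traces, rate=5.0):
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    n = traces.shape[1]
    return cm.CellMatrix(
        cell_ids=tuple(f"c{i}" for i in range(traces.shape[0])),
        traces=traces,
        time=np.arange(n) / rate,
        rate=rate,
    )


def _bout(start, end, n=10):
    return Bout(start, end, np.linspace(start, end, n), "photometry")


def test_zscore_formula_per_cell():
    rng = np.random.default_rng(0)
    base = rng.normal(10.0, 5.0, 500)
    base = 10.0 + (base - base.mean()) * (5.0 / base.std(ddof=1))
    trace = np.concatenate([base, [20.0]])
    out = cm.normalize_cell_traces(_matrix(trace), (0.0, 100.0))
    assert out.mu[0] == pytest.approx(10.0)
    assert out.sigma[0] == pytest.approx(5.0)
    assert out.z[0, -1] == pytest.approx(2.0)


def test_baseline_self_normalization_per_cell():
    rng = np.random.default_rng(1)
    out = cm.normalize_cell_traces(_matrix(rng.normal(size=(5, 400))), (0.0, 80.0))
    mask = out.window_mask((0.0, 80.0))
    for c in range(5):
        assert abs(out.z[c, mask].mean()) < 1e-9
        assert abs(out.z[c, mask].std(ddof=1) - 1.0) < 1e-9


def test_zero_variance_cell_excluded_not_fatal():
    rng = np.random.default_rng(2)
    traces = np.vstack([np.ones(400), rng.normal(size=400)])
    out = cm.normalize_cell_traces(_matrix(traces), (0.0, 80.0))
    assert out.excluded[0] and not out.excluded[1]
    assert np.isnan(out.z[0]).all()


def test_activation_threshold_is_inclusive():
    rng = np.random.default_rng(3)
    n = 1000
    base = rng.normal(0, 0.05, (2, n))
    t = np.arange(n) / 5.0
    resp = ((t >= 100.0) & (t < 115.0)).astype(float)
    traces = 50.0 + base + np.vstack([1.5 * resp, 0.5 * resp]) * 0.05
    out = cm.normalize_cell_traces(_matrix(traces), (0.0, 80.0))
    result = cm.classify_bout_responders(out, [_bout(100.0, 115.0)])
    assert bool(result.flags[0, 0]) is True  # ~1.5 z responder
    assert bool(result.flags[1, 0]) is False  # ~0.5 z stays below 1 z


def test_responder_fraction_within_binomial_interval():
    train = bw.generate_lick_train(4, bout_size_dist=("uniform_int", 40, 60), seed=5)
    ensemble, truth = bw.generate_cell_ensemble(100, 0.7, train=train, seed=5)
    out = cm.normalize_cell_traces(ensemble, (0.0, 600.0))
    bouts = bw.segment_bouts(train, "photometry")
    result = cm.classify_bout_responders(out, bouts)
    frac = result.activated_all_bouts.mean()
    assert 0.59 <= frac <= 0.81  # binomial 95% interval around 0.7 at n=100
    np.testing.assert_array_equal(result.activated_all_bouts, truth.responders["lick"])


def test_population_weighted_z_definitions():
    flags = np.ones((4, 3), dtype=bool)
    means = np.full((4, 3), 2.0)
    res = cm.ResponderResult(flags, means, flags.sum(axis=1), 1.0, 15.0, np.zeros(3, bool))
    assert cm.population_weighted_z(res) == pytest.approx(2.0)
    res_none = cm.ResponderResult(
        np.zeros((4, 3), bool), means, np.zeros(4, int), 1.0, 15.0, np.zeros(3, bool)
    )
    assert cm.population_weighted_z(res_none) == 0.0
    half_flags = np.vstack([np.ones((2, 3), bool), np.zeros((2, 3), bool)])
    res_half = cm.ResponderResult(
        half_flags, means, half_flags.sum(axis=1), 1.0, 15.0, np.zeros(3, bool)
    )
    assert cm.population_weighted_z(res_half) == pytest.approx(1.0)


def test_population_weighted_never_exceeds_activated_mean():
    rng = np.random.default_rng(6)
    flags = rng.random((30, 4)) < 0.5
    means = rng.normal(2.0, 0.5, (30, 4))
    res = cm.ResponderResult(flags, means, flags.sum(axis=1), 1.0, 15.0, np.zeros(4, bool))
    pw = cm.population_weighted_z(res)
    active = res.activated_all_bouts
    if active.any():
        assert pw <= np.nanmean(cm.mean_response(res)[active]) + 1e-12


def test_overlap_saturation_and_partition():
    a = np.full(10, 2.0)
    b = np.full(10, 3.0)
    res = cm.stimulus_overlap(a, b)
    assert res.counts["both"] == 10
    assert sum(res.counts.values()) == 10
    rng = np.random.default_rng(7)
    res2 = cm.stimulus_overlap(rng.normal(1, 1, 50), rng.normal(1, 1, 50))
    assert sum(res2.counts.values()) == 50
    assert res2.table.sum() == 50


def test_fisher_p_invariant_under_stimulus_swap():
    rng = np.random.default_rng(8)
    a, b = rng.normal(1, 1, 40), rng.normal(1, 1, 40)
    assert cm.stimulus_overlap(a, b).fisher_p == pytest.approx(
        cm.stimulus_overlap(b, a).fisher_p
    )


def enumerate_fisher_p(table):
    """Two-sided Fisher p by hypergeometric enumeration."""
    (a, b), (c, d) = table
    row1, col1, n = a + b, a + c, a + b + c + d
    rv = hypergeom(n, row1, col1)
    support = np.arange(max(0, row1 + col1 - n), min(row1, col1) + 1)
    pmf = rv.pmf(support)
    return float(pmf[pmf <= rv.pmf(a) * (1 + 1e-9)].sum())


def test_fisher_matches_enumeration_on_small_tables():
    rng = np.random.default_rng(9)
    for _ in range(50):
        a, b, c, d = rng.integers(0, 8, 4)
        if a + b + c + d == 0:
            continue
        responses_a = np.concatenate(
            [np.full(a + b, 2.0), np.full(c + d, 0.0)]
        )
        responses_b = np.concatenate(
            [np.full(a, 2.0), np.full(b, 0.0), np.full(c, 2.0), np.full(d, 0.0)]
        )
        if len(responses_a) < 2:
            continue
        res = cm.stimulus_overlap(responses_a, responses_b)
        assert res.fisher_p == pytest.approx(enumerate_fisher_p([[a, b], [c, d]]), abs=1e-9)


def test_overlap_requires_two_cells():
    with pytest.raises(ValueError, match="2 cells"):
        cm.stimulus_overlap(np.array([1.0]), np.array([1.0]))


def test_independent_stimuli_rarely_significant():
    train = bw.generate_lick_train(3, bout_size_dist=("uniform_int", 40, 60), seed=10)
    bouts = bw.segment_bouts(train, "photometry")
    sig = 0
    runs = 40
    for s in range(runs):
        ensemble, _ = bw.generate_cell_ensemble(
            60, 0.5, train=train, seed=1000 + s,
            injection_time=train.session_duration - 300.0,
            injection_responder_fraction=0.5,
        )
        out = cm.normalize_cell_traces(ensemble, (0.0, 600.0))
        result = cm.classify_bout_responders(out, bouts)
        lick_resp = cm.mean_response(result)
        inj_window = out.window_mask((train.session_duration - 300.0, train.session_duration))
        base = out.window_mask((0.0, 600.0))
        inj_resp = (
            np.nanmean(out.z[:, inj_window], axis=1)
        )
        res = cm.stimulus_overlap(lick_resp, inj_resp)
        if res.fisher_p < 0.05:
            sig += 1
    assert sig <= 0.15 * runs
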