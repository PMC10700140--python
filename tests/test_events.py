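import numpy as np
import pytest

import boutwise as bw
from boutwise import events
from boutwise.microstructure import Bout

from conftest import lick_train, make_trace


def _bout(start, end, n_licks, rule_set="photometry"):
    return Bout(start, end, np.linspace(start, end, n_licks), rule_set)


def exact_unit_baseline(n):
    """A +-c vector whose sample mean is 0 and sample SD (ddof=1) exactly 1."""
    base = np.resize([1.0, -1.0], n)
    return base * np.sqrt((n - 1) / (base**2).sum())


def test_bout_response_arithmetic():
    rate = 4.0
    z = np.concatenate([exact_unit_baseline(60), np.full(40, 2.0)])
    trace = make_trace(z, rate=rate)
    bout = _bout(15.0, 24.5, 10)
    (resp,) = events.bout_locked_response(trace, [bout], response_window=10.0)
    assert resp.z_per_bout == pytest.approx(2.0)
    assert resp.licks_in_window == 10
    assert resp.z_per_lick == pytest.approx(0.2)


def test_bout_response_null_case():
    rng = np.random.default_rng(0)
    trace = make_trace(rng.normal(size=400), rate=4.0)
    bout = _bout(50.0, 60.0, 20)
    (resp,) = events.bout_locked_response(trace, [bout])
    assert abs(resp.z_per_bout) < 1.0  # window mean stays near its own baseline


def test_consistency_identity_on_generated_session(phasic_trace4, default_train):
    bouts = bw.segment_bouts(default_train, "photometry")
    for r in events.bout_locked_response(phasic_trace4, bouts):
        if np.isfinite(r.z_per_lick):
            assert r.z_per_lick * r.licks_in_window == pytest.approx(r.z_per_bout, abs=1e-9)


def test_response_ranks_follow_true_amplitudes():
    from scipy.stats import spearmanr

    train = bw.generate_lick_train(
        10, bout_size_dist=("uniform_int", 60, 90), seed=31
    )
    amps = np.linspace(1.0, 6.0, 10)
    rng = np.random.default_rng(5)
    amps = rng.permutation(amps)
    raw, truth = bw.generate_photometry_session(
        train, params=bw.KernelParams(noise_sd=0.1), per_bout_amplitudes=amps,
        seed=32, rate=101.73,
    )
    trace = bw.zscore_trace(bw.fit_isosbestic_baseline(raw, (0.0, 600.0)))
    bouts = bw.segment_bouts(train, "photometry")
    zs = [r.z_per_bout for r in events.bout_locked_response(trace, bouts)]
    rho = spearmanr(zs, amps).statistic
    assert rho > 0.9


def test_size_bin_membership():
    responses = events.bout_locked_response(
        make_trace(np.concatenate([exact_unit_baseline(80), np.ones(200)]), rate=4.0),
        [_bout(25.0, 40.0, 30), _bout(45.0, 50.0, 4)],
    )
    bins = events.bin_by_bout_size(responses)
    assert np.isfinite(bins[(26, 50)])
    # the 4-lick bout falls below the smallest bin everywhere
    assert np.isnan(bins[(5, 25)]) and np.isnan(bins[(51, 75)])


def test_size_bin_mean():
    r1 = events.BoutResponse(_bout(0, 10, 30), 1.0, 0.1, 30, 0, 1, 10)
    r2 = events.BoutResponse(_bout(20, 30, 40), 3.0, 0.3, 40, 0, 1, 10)
    bins = events.bin_by_bout_size([r1, r2])
    assert bins[(26, 50)] == pytest.approx(0.2)


# --- crossing estimators on analytic PSTHs -------------------------------

GRID = np.arange(0.0, 40.0, 0.25)


def test_tau_exponential_rise_crossing():
    psth = 1.0 - np.exp(-GRID / 3.7)
    tau = events.estimate_rise_tau(GRID, psth)
    # analytic crossing of 63.8% of the max is at ~3.76 s for this extent;
    # the earliest grid point at or past it is 4.00 s
    assert tau.defined and tau.value == pytest.approx(4.00)


def test_tau_step_function():
    psth = np.where(GRID >= 2.0, 1.0, 0.0)
    assert events.estimate_rise_tau(GRID, psth).value == pytest.approx(2.0)


def test_tau_linear_ramp():
    grid = np.arange(0.0, 10.25, 0.25)
    tau = events.estimate_rise_tau(grid, grid / 10.0)
    assert tau.value == pytest.approx(6.5)  # first grid point >= 6.38 s


def test_tau_undefined_for_nonpositive_psth():
    assert not events.estimate_rise_tau(GRID, -np.ones_like(GRID)).defined


def test_lambda_exponential_decay_crossing():
    psth = np.exp(-GRID / 7.5)
    lam = events.estimate_decay_lambda(GRID, psth)
    assert lam.defined and lam.value == pytest.approx(7.5)  # crossing at 7.46 s


def test_lambda_instant_drop():
    psth = np.where(GRID == 0.0, 1.0, 0.0)
    assert events.estimate_decay_lambda(GRID, psth).value == pytest.approx(0.25)


def test_lambda_undefined_for_constant_trace():
    assert not events.estimate_decay_lambda(GRID, np.ones_like(GRID)).defined


def test_crossings_match_closed_form_within_one_grid_step():
    rng = np.random.default_rng(7)
    for _ in range(20):
        tau_true = rng.uniform(0.5, 9.0)
        lam_true = rng.uniform(1.0, 12.0)
        rise = 1.0 - np.exp(-GRID / tau_true)
        decay = np.exp(-GRID / lam_true)
        t_cross = tau_true * np.log((1 - 0.638 * (1 - np.exp(-GRID[-1] / tau_true))) ** -1)
        l_cross = lam_true * np.log(1 / 0.37)
        tau_hat = events.estimate_rise_tau(GRID, rise).value
        lam_hat = events.estimate_decay_lambda(GRID, decay).value
        assert 0 <= tau_hat - t_cross <= 0.25 + 1e-9
        assert 0 <= lam_hat - l_cross <= 0.25 + 1e-9


# --- slope, end-of-bout drop, early/late ---------------------------------

def test_bout_size_slope_recovery():
    rng = np.random.default_rng(11)
    sizes = rng.integers(10, 100, 50)
    responses = [
        events.BoutResponse(
            _bout(100.0 * i, 100.0 * i + 10, int(s)),
            0.05 * s + rng.normal(0, 0.01),
            np.nan, int(s), 0.0, 1.0, 10.0,
        )
        for i, s in enumerate(sizes)
    ]
    assert 0.045 <= events.bout_size_slope(responses) <= 0.055


def test_bout_size_slope_flat_relation():
    responses = [
        events.BoutResponse(_bout(100.0 * i, 100.0 * i + 10, s), 1.5, np.nan, s, 0, 1, 10)
        for i, s in enumerate([10, 20, 30, 40])
    ]
    assert events.bout_size_slope(responses) == pytest.approx(0.0, abs=1e-12)


def test_bout_size_slope_needs_two_distinct_sizes():
    r = events.BoutResponse(_bout(0, 10, 20), 1.0, 0.05, 20, 0, 1, 10)
    with pytest.raises(ValueError, match="distinct"):
        events.bout_size_slope([r])


def test_end_of_bout_drop_arithmetic():
    rate = 4.0
    z = np.zeros(400)
    t = np.arange(400) / rate
    z[(t >= 35.0) & (t < 50.0)] = 3.0  # pre-last-lick peak
    z[(t >= 50.0) & (t < 65.0)] = 1.0  # post mean
    trace = make_trace(z, rate=rate)
    (drop,) = events.end_of_bout_drop(trace, [_bout(30.0, 50.0, 40)])
    assert drop.drop == pytest.approx(-2.0)
    assert not drop.truncated


def test_end_of_bout_drop_nonpositive_on_flat_trace():
    trace = make_trace(np.full(400, 1.3), rate=4.0)
    (drop,) = events.end_of_bout_drop(trace, [_bout(30.0, 50.0, 40)])
    assert drop.drop <= 0.0


def test_end_of_bout_drop_stronger_for_fast_decay():
    def drop_for(lam):
        train = bw.generate_lick_train(4, bout_size_dist=("uniform_int", 80, 100),
                                       inter_bout_gap_dist=("uniform", 80, 100), seed=13)
        raw, _ = bw.generate_photometry_session(
            train, params=bw.KernelParams(lambda_decay=lam, noise_sd=0.05),
            seed=14, rate=101.73,
        )
        trace = bw.zscore_trace(bw.fit_isosbestic_baseline(raw, (0.0, 600.0)))
        bouts = bw.segment_bouts(train, "photometry")
        return np.mean([d.drop for d in events.end_of_bout_drop(trace, bouts)])

    fast, slow = drop_for(7.5), drop_for(60.0)
    assert fast < 0
    assert fast < slow


def test_split_early_late_boundary_is_half_open():
    trace = make_trace(np.zeros(8000), rate=4.0)
    at_boundary = _bout(900.0, 910.0, 10)
    early_bout = _bout(100.0, 110.0, 10)
    early, late = events.split_early_late(trace, [early_bout, at_boundary])
    assert early.n_bouts == 1 and late.n_bouts == 1
    assert late.responses[0].bout.start == pytest.approx(900.0)


def test_split_early_late_empty_half_flagged():
    trace = make_trace(np.zeros(8000), rate=4.0)
    early, late = events.split_early_late(trace, [_bout(100.0, 110.0, 10)])
    assert not early.empty
    assert late.empty and np.isnan(late.mean_z_per_bout)


def test_kinetics_on_generated_session_recover_defaults():
    train = bw.generate_lick_train(
        8, bout_size_dist=("uniform_int", 150, 200),
        inter_bout_gap_dist=("uniform", 60, 80), seed=17,
    )
    raw, _ = bw.generate_photometry_session(train, seed=18)
    trace = bw.resample_and_smooth(
        bw.zscore_trace(bw.fit_isosbestic_baseline(raw, (0.0, 600.0))), target_rate=4.0
    )
    bouts = bw.segment_bouts(train, "photometry")
    tau = events.rise_kinetics(trace, bouts)
    lam = events.decay_kinetics(trace, bouts)
    assert tau.value == pytest.approx(3.7, abs=0.5)
    assert lam.value == pytest.approx(7.5, abs=1.0)
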