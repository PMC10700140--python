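"""Synthetic sessions with known ground truth.

Every analysis stage in this package is testable without animal data because
this module generates the three raw inputs — lick trains, two-channel
photometry and per-neuron calcium matrices — from explicit, recoverable
parameters:

* lick trains are bout-structured, with within-bout interlick intervals
  drawn from a two-component lognormal mixture truncated to (0, 1] s
  (the bimodal ILI structure seen in rodent licking);
* the calcium response is an asymmetric exponential bout envelope: while
  the animal licks, activity rises toward the bout amplitude with time
  constant ``tau_rise``; after the last lick it decays with ``lambda_decay``.
  These are therefore exactly the constants the 63.8%/37% crossing
  estimators should recover;
* slow post-ingestive ramps are driven by delayed cumulative intake or
  infusion volume, saturating and then low-pass filtered so that a step
  drive reaches half its plateau ``ramp_t50`` minutes later;
* both photometry channels share an exponential bleaching baseline and a
  band-limited motion artifact (with a channel gain ratio), which is what
  the isosbestic regression is built to remove.  The reference channel
  carries no response component.

Determinism: identical (params, seed) regenerate bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .io import EventTrain, RawPhotometry, SessionProtocol

__all__ = [
    "KernelParams",
    "GroundTruth",
    "generate_lick_train",
    "generate_photometry_session",
    "generate_cell_ensemble",
    "response_envelope",
]

#: reference channel picks up this fraction of the shared artifact/bleach
REFERENCE_GAIN = 0.7
SIGNAL_BASELINE = 100.0
REFERENCE_BASELINE = 80.0


@dataclass(frozen=True)
class KernelParams:
    """Ground-truth response parameters of a synthetic session.

    Defaults are the conditions this package is meant to reproduce: fast
    lick-locked transients with tau_rise = 3.7 s and lambda_decay = 7.5 s at
    ~3.5 z amplitude, and (when enabled) post-ingestive ramps with ~3.5 min
    latency that keep building for many minutes after intake stops.
    Noise/artifact/bleach magnitudes are modelling choices (none are
    measured quantities) picked so that estimators are exercised at
    realistic signal-to-noise.
    """

    tau_rise: float = 3.7  # s
    lambda_decay: float = 7.5  # s
    amplitude: float = 3.5  # z units
    ramp_latency: float = 3.5  # min
    ramp_t50: float = 16.0  # min, half-rise lag of the post-ingestive ramp
    ramp_amplitude: float = 0.0  # z units
    ramp_v_ref: float = 1.5  # ml of intake at which the ramp drive saturates
    lick_volume_ul: float = 2.0  # ul ingested per lick
    noise_sd: float = 0.1  # channel units (and hence ~1 z unit per noise_sd)
    artifact_amplitude: float = 0.5  # channel units, shared across channels
    bleach_amplitude: float = 20.0  # channel units
    bleach_time_constant: float = 1200.0  # s

    def __post_init__(self) -> None:
        for name in ("tau_rise", "lambda_decay", "ramp_t50", "bleach_time_constant"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("amplitude", "ramp_amplitude", "noise_sd", "artifact_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually used, for recovery tests."""

    params: KernelParams
    seed: int
    per_bout_amplitudes: np.ndarray | None = None  # z units, per generated bout
    bout_intervals: tuple[tuple[float, float], ...] = ()
    response_z: np.ndarray | None = None  # response component in z units
    ramp_z: np.ndarray | None = None
    artifact: np.ndarray | None = None  # shared artifact, channel units
    responders: dict | None = None  # class name -> boolean array per cell


# ---------------------------------------------------------------------------
# distributions

def _sample(spec, rng: np.random.Generator, size: int) -> np.ndarray:
    """Sample from a small declarative distribution spec.

    Specs: ("constant", v) | ("uniform", lo, hi) | ("uniform_int", lo, hi).
    """
    kind = spec[0]
    if kind == "constant":
        return np.full(size, float(spec[1]))
    if kind == "uniform":
        return rng.uniform(spec[1], spec[2], size)
    if kind == "uniform_int":
        return rng.integers(int(spec[1]), int(spec[2]) + 1, size).astype(float)
    raise ValueError(f"unknown distribution spec {spec!r}")


def _dist_min(spec) -> float:
    if spec[0] == "constant":
        return float(spec[1])
    return float(spec[1])


# ---------------------------------------------------------------------------
# lick trains

def generate_lick_train(
    n_bouts: int,
    bout_size_dist=("uniform_int", 20, 120),
    ili_modes: tuple[float, float] = (0.13, 0.35),
    ili_weights: tuple[float, float] = (0.8, 0.2),
    ili_log_sd: float = 0.15,
    inter_bout_gap_dist=("uniform", 25.0, 45.0),
    start_time: float = 600.0,
    session_tail: float = 120.0,
    min_bout_duration: float = 4.5,
    seed: int = 0,
    source: str = "b1",
) -> EventTrain:
    """Generate a bout-structured lick train whose photometry-rule
    re-segmentation yields exactly ``n_bouts`` bouts.

    Within-bout ILIs come from a two-component lognormal mixture with median
    interval ``ili_modes`` (seconds, both in (0, 1)) truncated to (0, 1].
    Bouts shorter than ``min_bout_duration`` are extended with extra licks
    so every generated bout survives the 4-s minimum-duration rule, and
    inter-bout gaps must be guaranteed >= 20 s.
    """
    if n_bouts < 0:
        raise ValueError("n_bouts must be non-negative")
    if not all(0 < m < 1 for m in ili_modes):
        raise ValueError("ILI mode means must lie in (0, 1) s")
    if _dist_min(inter_bout_gap_dist) < 20.0:
        raise ValueError(
            "inter-bout gap distribution must guarantee gaps >= 20 s so that the "
            "photometry rule set separates the requested bouts"
        )
    rng = np.random.default_rng(seed)
    if n_bouts == 0:
        return EventTrain(
            np.empty(0), np.empty(0, object), np.empty(0, object), start_time + session_tail
        )

    def draw_ili(n: int) -> np.ndarray:
        comp = rng.random(n) < ili_weights[0]
        mu = np.where(comp, math.log(ili_modes[0]), math.log(ili_modes[1]))
        ili = np.exp(rng.normal(mu, ili_log_sd))
        return np.clip(ili, 1e-3, 1.0)

    sizes = _sample(bout_size_dist, rng, n_bouts).astype(int)
    gaps = _sample(inter_bout_gap_dist, rng, n_bouts)
    times: list[float] = []
    t = start_time
    for i in range(n_bouts):
        t += gaps[i]
        bout = [t]
        ilis = list(draw_ili(max(sizes[i] - 1, 0)))
        while sum(ilis) < min_bout_duration:
            ilis.extend(draw_ili(1))
        bout.extend(t + np.cumsum(ilis))
        times.extend(bout)
        t = bout[-1]
    ts = np.asarray(times)
    return EventTrain(
        ts,
        np.full(len(ts), "lick", dtype=object),
        np.full(len(ts), source, dtype=object),
        session_duration=float(ts[-1] + session_tail),
    )


# ---------------------------------------------------------------------------
# response envelope

def _merge_runs(lick_times: np.ndarray, max_gap: float = 5.0) -> list[tuple[float, float]]:
    if len(lick_times) == 0:
        return []
    cuts = np.flatnonzero(np.diff(lick_times) > max_gap) + 1
    return [(g[0], g[-1]) for g in np.split(lick_times, cuts)]


def response_envelope(
    time: np.ndarray,
    lick_times: np.ndarray,
    tau_rise: float,
    lambda_decay: float,
    amplitudes=None,
    run_gap: float = 5.0,
) -> tuple[np.ndarray, list[tuple[float, float]]]:
    """Asymmetric exponential envelope of the lick-locked response.

    While a bout is in progress (between its first and last lick) the
    envelope relaxes toward the bout amplitude with time constant
    ``tau_rise``; outside bouts it decays with ``lambda_decay``.  The
    envelope is identically zero before the first lick (conservation).

    Returns the envelope (peak-normalised to the per-bout amplitudes, which
    default to 1) and the list of (start, end) bout intervals used.
    """
    runs = _merge_runs(np.asarray(lick_times, dtype=float), run_gap)
    if amplitudes is None:
        amplitudes = np.ones(len(runs))
    amplitudes = np.asarray(amplitudes, dtype=float)
    if len(amplitudes) != len(runs):
        raise ValueError("one amplitude per bout is required")
    env = np.zeros_like(time, dtype=float)
    x = 0.0
    t_prev = time[0] if len(time) else 0.0
    for (on, off), amp in zip(runs, amplitudes):
        # free decay from the previous state up to this bout's onset
        mask = (time >= t_prev) & (time < on)
        env[mask] = x * np.exp(-(time[mask] - t_prev) / lambda_decay)
        x = x * math.exp(-max(on - t_prev, 0.0) / lambda_decay)
        # rise toward amp during the bout
        mask = (time >= on) & (time <= off)
        env[mask] = amp + (x - amp) * np.exp(-(time[mask] - on) / tau_rise)
        x = amp + (x - amp) * math.exp(-max(off - on, 0.0) / tau_rise)
        t_prev = off
    mask = time >= t_prev
    if len(runs):
        env[mask] = x * np.exp(-(time[mask] - t_prev) / lambda_decay)
    return env, runs


def _cumulative_volume_ml(
    time: np.ndarray, train: EventTrain, protocol: SessionProtocol | None, lick_volume_ul: float
) -> np.ndarray:
    v = np.searchsorted(train.timestamps, time, side="right") * lick_volume_ul / 1000.0
    if protocol is not None:
        for ep in protocol.infusion_epochs:
            elapsed = np.clip(time - ep.start, 0.0, ep.end - ep.start)
            v = v + ep.rate * elapsed / 60.0 / 1000.0  # ul/min over seconds -> ml
    return v


def _ramp_component(
    time: np.ndarray, train: EventTrain, protocol: SessionProtocol | None, params: KernelParams
) -> np.ndarray:
    """Post-ingestive ramp in z units: saturating function of delayed
    cumulative volume, low-pass filtered with a lag whose step response
    reaches 50% at ``ramp_t50`` minutes."""
    if params.ramp_amplitude == 0:
        return np.zeros_like(time)
    latency_s = params.ramp_latency * 60.0
    v_delayed = _cumulative_volume_ml(time - latency_s, train, protocol, params.lick_volume_ul)
    v_delayed[time < latency_s] = 0.0
    drive = 1.0 - np.exp(-v_delayed / params.ramp_v_ref * math.log(2) * 2)
    theta = params.ramp_t50 * 60.0 / math.log(2)
    dt = float(np.median(np.diff(time))) if len(time) > 1 else 1.0
    alpha = 1.0 - math.exp(-dt / theta)
    from scipy.signal import lfilter

    ramp = lfilter([alpha], [1.0, -(1.0 - alpha)], drive)
    return params.ramp_amplitude * ramp


def _band_limited_noise(rng: np.random.Generator, n: int, rate: float, sd: float) -> np.ndarray:
    """Zero-mean artifact with ~0.5 s correlation time, scaled to ``sd``."""
    if sd == 0 or n == 0:
        return np.zeros(n)
    raw = gaussian_filter1d(rng.standard_normal(n), sigma=max(0.5 * rate, 1.0))
    raw -= raw.mean()
    s = raw.std()
    return raw * (sd / s) if s > 0 else raw


def generate_photometry_session(
    train: EventTrain,
    protocol: SessionProtocol | None = None,
    params: KernelParams = KernelParams(),
    seed: int = 0,
    rate: float = 1017.3,
    per_bout_amplitudes=None,
) -> tuple[RawPhotometry, GroundTruth]:
    """Simulate a two-channel photometry recording of the session.

    The default sampling rate is the demodulated acquisition rate of the
    emulated rig (1017.3 Hz); analyses downsample to 4 Hz, and that block
    averaging is what gives the 4-Hz z-trace its low noise floor.

    signal    = baseline + bleach + artifact + response + noise
    reference = baseline + gain * (bleach + artifact) + noise

    The response component (lick-locked envelope plus post-ingestive ramp)
    is expressed in z units of the noise floor, i.e. its raw magnitude is
    ``z * noise_sd`` channel units, so that after isosbestic normalization
    the recovered z-score matches the ground-truth amplitude.
    """
    if len(train) and train.timestamps[-1] > train.session_duration:
        raise ValueError("train exceeds its session duration")
    if rate < 2.0 / params.tau_rise:
        import warnings

        warnings.warn("sampling rate too low to resolve tau_rise", stacklevel=2)
    rng = np.random.default_rng(seed)
    n = int(round(train.session_duration * rate)) + 1
    time = np.arange(n) / rate

    if per_bout_amplitudes is None:
        n_runs = len(_merge_runs(train.timestamps))
        per_bout_amplitudes = np.full(n_runs, params.amplitude)
    env, runs = response_envelope(
        time, train.timestamps, params.tau_rise, params.lambda_decay, per_bout_amplitudes
    )
    ramp_z = _ramp_component(time, train, protocol, params)
    response_z = env + ramp_z
    scale = params.noise_sd if params.noise_sd > 0 else 1.0
    response_raw = response_z * scale

    bleach = params.bleach_amplitude * np.exp(-time / params.bleach_time_constant)
    artifact = _band_limited_noise(rng, n, rate, params.artifact_amplitude)
    shared = bleach + artifact
    # the demodulated isosbestic channel is modelled with a smaller
    # independent-noise floor so that the z-scale of the regressed residual
    # stays within a few percent of the ground-truth amplitude
    signal = SIGNAL_BASELINE + shared + response_raw + rng.normal(0, params.noise_sd, n)
    reference = (
        REFERENCE_BASELINE
        + REFERENCE_GAIN * shared
        + rng.normal(0, 0.2 * params.noise_sd, n)
    )

    raw = RawPhotometry(time=time, signal=signal, reference=reference, rate=rate)
    truth = GroundTruth(
        params=params,
        seed=seed,
        per_bout_amplitudes=np.asarray(per_bout_amplitudes, dtype=float),
        bout_intervals=tuple(runs),
        response_z=response_z,
        ramp_z=ramp_z,
        artifact=artifact,
    )
    return raw, truth


# ---------------------------------------------------------------------------
# single-cell ensembles

def generate_cell_ensemble(
    n_cells: int,
    responder_fraction: float,
    params: KernelParams = KernelParams(),
    train: EventTrain | None = None,
    seed: int = 0,
    rate: float = 5.0,
    injection_time: float | None = None,
    injection_responder_fraction: float | None = None,
    injection_amplitude: float | None = None,
):
    """Generate a heterogeneous single-cell ensemble.

    Each cell is independently flagged as a lick responder with probability
    ``responder_fraction``; responders carry the bout-locked envelope at the
    kernel amplitude, non-responders only noise.  If ``injection_time`` is
    given, a second stimulus class ("injection": a sustained post-injection
    step with slow rise) is assigned independently with probability
    ``injection_responder_fraction``.

    Returns ``(CellMatrix, GroundTruth)``; responder flags live in
    ``GroundTruth.responders`` under keys ``"lick"`` and ``"injection"``.
    """
    from .cells import CellMatrix

    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if not 0.0 <= responder_fraction <= 1.0:
        raise ValueError("responder_fraction must lie in [0, 1]")
    if train is None:
        train = generate_lick_train(4, seed=seed)
    rng = np.random.default_rng(seed)
    n = int(round(train.session_duration * rate)) + 1
    time = np.arange(n) / rate
    env, _ = response_envelope(time, train.timestamps, params.tau_rise, params.lambda_decay)

    responders = {"lick": rng.random(n_cells) < responder_fraction}
    scale = params.noise_sd if params.noise_sd > 0 else 1.0
    components = [params.amplitude * scale * env]
    flags_list = [responders["lick"]]
    if injection_time is not None:
        frac_b = injection_responder_fraction if injection_responder_fraction is not None else 0.5
        amp_b = injection_amplitude if injection_amplitude is not None else params.amplitude
        responders["injection"] = rng.random(n_cells) < frac_b
        step = np.where(time >= injection_time, 1.0 - np.exp(-np.clip(time - injection_time, 0, None) / 60.0), 0.0)
        components.append(amp_b * scale * step)
        flags_list.append(responders["injection"])

    traces = np.empty((n_cells, n))
    for c in range(n_cells):
        tr = 50.0 + rng.normal(0, params.noise_sd, n)
        for comp, flags in zip(components, flags_list):
            if flags[c]:
                tr = tr + comp
        traces[c] = tr
    cells = CellMatrix(
        cell_ids=tuple(f"cell{c:03d}" for c in range(n_cells)),
        traces=traces,
        time=time,
        rate=rate,
    )
    truth = GroundTruth(params=params, seed=seed, responders=responders)
    return cells, truth
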