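"""Extraction of electrophysiological observables from multichannel recordings.

Given a voltage recording (simulated or loaded from CSV) this module detects
spike events against a robust running-median baseline, fits the
biexponential spike waveform and the single-exponential relaxation model,
segments long recordings into the initial / transitional / late phases,
summarizes each channel (steady state, drift, spike rates, polarization
band) and classifies the recording's morphology from rule scores.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize

from .errors import InsufficientDataError, InvalidParameterError
from .sim_dynamics import (
    Recording,
    RelaxationParams,
    SpikeShape,
    render_spike,
)

logger = logging.getLogger("gfdkit.ephys_analysis")

#: Running-median baseline window, samples (odd).
BASELINE_WINDOW = 601
#: Detection threshold in robust noise sd units.
DEFAULT_THRESHOLD_K = 5.0
#: Minimum separation between detected events, s.  Small by design: on the
#: 1 Hz recording grid an event is a contiguous supra-threshold run, and the
#: 0.6 Hz pacemaker train must not be merged on finer grids.
DEFAULT_DETECT_REFRACTORY_S = 0.4
#: MAD -> Gaussian sd consistency factor.
MAD_SCALE = 1.4826

#: Polarization-band thresholds (mV), separating the reported fiber bands
#: (+40..+65 / -10..+30 / -60..-90).
BAND_POSITIVE_MV = 35.0
BAND_NEGATIVE_MV = -50.0


@dataclass(frozen=True)
class SpikeEvent:
    """One detected spike: onset time, peak deviation, polarity, half-width."""

    time: float
    amplitude: float
    polarity: str           # "up" | "down"
    width: float

    def __post_init__(self) -> None:
        if not self.amplitude > 0:
            raise InvalidParameterError("amplitude must be > 0")
        if not self.width > 0:
            raise InvalidParameterError("width must be > 0")


@dataclass(frozen=True)
class PhaseSegmentation:
    """Ordered phase boundaries (s) and their labels, in time order."""

    boundaries: tuple[float, ...]
    labels: tuple[str, ...]
    span: tuple[float, float]
    confident: bool = True

    def __post_init__(self) -> None:
        b = self.boundaries
        if any(y <= x for x, y in zip(b, b[1:])):
            raise InvalidParameterError("boundaries must be strictly increasing")
        lo, hi = self.span
        if any(not (lo < x < hi) for x in b):
            raise InvalidParameterError("boundaries must lie inside the recording span")
        if len(self.labels) != len(b) + 1:
            raise InvalidParameterError("need one label per phase")

    def intervals(self) -> list[tuple[str, float, float]]:
        edges = [self.span[0], *self.boundaries, self.span[1]]
        return [(lab, s, e) for lab, s, e in zip(self.labels, edges, edges[1:])]


@dataclass(frozen=True)
class ChannelSummary:
    """Descriptive per-channel statistics used by the morphology rules."""

    name: str
    steady_state: float                 # mean over the final window, mV
    drift: float                        # net change across the drift window, mV
    spike_rate: dict = field(default_factory=dict)   # per-phase + "overall", Hz
    range: tuple[float, float] = (0.0, 0.0)
    band: str = "neutral"               # positive | neutral | negative

    def __post_init__(self) -> None:
        lo, hi = self.range
        if not (lo <= self.steady_state <= hi):
            raise InvalidParameterError("steady state outside channel range")


@dataclass(frozen=True)
class MorphologyCall:
    """Classification outcome: winning label plus normalized rule scores."""

    label: str
    scores: dict

    def __post_init__(self) -> None:
        total = sum(self.scores.values())
        if total > 0 and not math.isclose(total, 1.0, rel_tol=1e-9):
            raise InvalidParameterError("scores must be normalized to sum 1")


def _resolve_call(scores: dict[str, float]) -> MorphologyCall:
    total = sum(scores.values())
    if total <= 0:
        norm = {k: 1.0 / len(scores) for k in scores}
    else:
        norm = {k: v / total for k, v in scores.items()}
    best = max(norm.values())
    # deterministic lexicographic tie-break
    label = min(k for k, v in norm.items() if math.isclose(v, best, rel_tol=1e-12))
    return MorphologyCall(label=label, scores=norm)


# ---------------------------------------------------------------------------
# Spike detection
# ---------------------------------------------------------------------------

def detect_spikes(
    trace: np.ndarray,
    fs: float = 1.0,
    threshold_k: float = DEFAULT_THRESHOLD_K,
    refractory_s: float = DEFAULT_DETECT_REFRACTORY_S,
    times: np.ndarray | None = None,
) -> list[SpikeEvent]:
    """Detect spikes as excursions from a running-median baseline.

    The baseline is a 601-sample running median; the noise scale is the
    MAD-based robust sd of the residual.  Samples with |residual| above
    ``threshold_k`` times that scale are grouped into events (contiguous
    runs, merged when separated by less than ``refractory_s``); each event
    reports its onset time, peak |residual| amplitude, polarity and time
    above half amplitude.  Detection is invariant to constant offsets.
    """
    if threshold_k <= 0:
        raise InvalidParameterError("threshold_k must be > 0")
    y = np.asarray(trace, dtype=float)
    if y.size < BASELINE_WINDOW:
        raise InsufficientDataError(
            f"trace has {y.size} samples; needs >= {BASELINE_WINDOW} for the baseline"
        )
    if times is None:
        times = np.arange(y.size) / fs
    baseline = ndimage.median_filter(y, size=BASELINE_WINDOW, mode="nearest")
    resid = y - baseline
    scale = MAD_SCALE * np.median(np.abs(resid - np.median(resid)))
    if scale <= 0:
        return []
    above = np.abs(resid) > threshold_k * scale
    if not above.any():
        return []

    # contiguous runs of supra-threshold samples
    idx = np.flatnonzero(above)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    ends = np.concatenate((idx[breaks], [idx[-1]]))

    # merge runs separated by less than the refractory period
    merged: list[tuple[int, int]] = []
    for s, e in zip(starts, ends):
        if merged and (times[s] - times[merged[-1][1]]) < refractory_s:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))

    dt = 1.0 / fs
    events: list[SpikeEvent] = []
    for s, e in merged:
        seg = resid[s:e + 1]
        peak_local = int(np.argmax(np.abs(seg)))
        amp = float(abs(seg[peak_local]))
        half = amp / 2.0
        width = float(np.count_nonzero(np.abs(seg) >= half)) * dt
        events.append(SpikeEvent(
            time=float(times[s]),
            amplitude=amp,
            polarity="up" if seg[peak_local] > 0 else "down",
            width=max(width, dt),
        ))
    return events


# ---------------------------------------------------------------------------
# Waveform / relaxation fitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpikeFit:
    """Result of a biexponential waveform fit."""

    shape: SpikeShape | None
    residual_norm: float
    success: bool
    censored_rise: bool = False
    message: str = ""


@dataclass(frozen=True)
class RelaxationFit:
    """Result of a single-exponential relaxation fit."""

    params: RelaxationParams | None
    residual_norm: float
    success: bool
    low_quality: bool = False
    message: str = ""


def _spike_model(t, baseline, amp, tau_rise, tau_decay, t0):
    dt = np.maximum(t - t0, 0.0)
    return baseline + amp * np.where(
        t >= t0, np.exp(-dt / tau_decay) - np.exp(-dt / tau_rise), 0.0
    )


def fit_spike_waveform(
    segment: np.ndarray,
    fs: float,
    init: SpikeShape | None = None,
    times: np.ndarray | None = None,
    max_restarts: int = 3,
) -> SpikeFit:
    """Least-squares fit of the biexponential spike model to one event segment.

    The fitted parameters are reported in the canonical tau_rise < tau_decay
    labeling (the model is invariant under swapping the constants and
    negating the amplitude).  tau_rise is bounded below by one sample; a fit
    pinned at that bound is reported as censored, since a 1 Hz recording
    cannot resolve millisecond-scale rise times.  Non-convergence yields a
    failed SpikeFit, not an exception.
    """
    y = np.asarray(segment, dtype=float)
    if times is None:
        times = np.arange(y.size) / fs
    t = np.asarray(times, dtype=float)
    if y.size < 10:
        return SpikeFit(None, math.inf, False, message="fewer than 10 samples")

    dt = 1.0 / fs
    span = float(t[-1] - t[0])
    ptp = float(np.ptp(y))
    if ptp <= 0:
        return SpikeFit(
            SpikeShape(float(y[0]), 0.0, dt, 2 * dt, float(t[0])),
            0.0, False, message="flat segment (amplitude ~ 0)",
        )

    def heuristics() -> tuple[float, float, float, float, float]:
        base = float(np.median(y[: max(3, y.size // 10)]))
        k = int(np.argmax(np.abs(y - base)))
        amp = (y[k] - base) / 0.6
        t0 = float(t[max(k - 2, 0)])
        return base, float(amp), dt, max(5 * dt, span / 10), t0

    guesses = []
    if init is not None:
        guesses.append((init.baseline, init.amplitude, init.tau_rise, init.tau_decay, init.t0))
    guesses.append(heuristics())
    b0, a0, tr0, td0, t00 = guesses[-1]
    guesses.append((b0, a0, 2 * dt, max(10 * dt, span / 4), t00))

    lo = [-np.inf, -np.inf, dt, dt, t[0] - span]
    hi = [np.inf, np.inf, 10 * span, 10 * span, t[-1]]
    best = None
    for trial, g in enumerate(guesses[: max_restarts + 1]):
        p0 = np.clip(np.asarray(g, dtype=float), lo, hi)
        if p0[2] == p0[3]:
            p0[3] *= 2
        try:
            res = optimize.least_squares(
                lambda p: _spike_model(t, *p) - y, p0, bounds=(lo, hi),
                xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
        except Exception as exc:  # pragma: no cover - defensive
            logger.debug("spike fit trial %d raised %s", trial, exc)
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not np.isfinite(best.cost):
        return SpikeFit(None, math.inf, False, message="no fit converged")

    base, amp, tr, td, t0 = best.x
    if tr > td:  # canonical labeling
        tr, td, amp = td, tr, -amp
    if math.isclose(tr, td, rel_tol=1e-9):
        td = tr * (1 + 1e-6)
    shape = SpikeShape(float(base), float(amp), float(tr), float(td), float(t0))
    censored = tr <= dt * 1.001
    resid = float(np.sqrt(2 * best.cost))
    flat = abs(amp) * shape.peak_factor < 3 * resid / math.sqrt(y.size)
    return SpikeFit(shape, resid, success=not flat, censored_rise=censored,
                    message="amplitude indistinguishable from noise" if flat else "")


def fit_relaxation(
    trace: np.ndarray,
    times: np.ndarray,
) -> RelaxationFit:
    """Least-squares fit of v_inf + dv exp(-t/tau) to a trace.

    Initialization from the endpoints: v_inf from the final 10% mean, dv
    from the first sample, tau from the time to cover 1 - 1/e of the span.
    A non-monotone trace that fits poorly is flagged low-quality rather than
    rejected.
    """
    y = np.asarray(trace, dtype=float)
    t = np.asarray(times, dtype=float)
    if y.size < 10:
        raise InsufficientDataError("relaxation fit needs >= 10 samples")
    t = t - t[0]

    v_inf0 = float(np.mean(y[-max(1, y.size // 10):]))
    dv0 = float(y[0] - v_inf0)
    if abs(dv0) < 1e-12:
        # constant trace: the model degenerates to its asymptote
        resid = float(np.linalg.norm(y - v_inf0))
        params = RelaxationParams(v_inf=v_inf0, dv=0.0, tau=max(float(t[-1]), 1.0))
        return RelaxationFit(params, resid, True)
    crossing = np.flatnonzero(np.abs(y - v_inf0) <= abs(dv0) / math.e)
    tau0 = float(t[crossing[0]]) if crossing.size else float(t[-1] / 3)
    tau0 = max(tau0, float(t[1]))

    def model(tt, v_inf, dv, tau):
        return v_inf + dv * np.exp(-tt / tau)

    try:
        popt, _ = optimize.curve_fit(
            model, t, y, p0=(v_inf0, dv0, tau0),
            bounds=([-np.inf, -np.inf, 1e-9], [np.inf, np.inf, np.inf]),
            maxfev=20000, xtol=1e-14, ftol=1e-14,
        )
    except Exception as exc:
        return RelaxationFit(None, math.inf, False, message=f"no convergence: {exc}")
    resid = float(np.linalg.norm(model(t, *popt) - y))
    var = float(np.var(y)) * y.size
    low_quality = var > 0 and (1.0 - resid**2 / var) < 0.2
    params = RelaxationParams(v_inf=float(popt[0]), dv=float(popt[1]), tau=float(popt[2]))
    return RelaxationFit(params, resid, True, low_quality=low_quality)


# ---------------------------------------------------------------------------
# Phase segmentation
# ---------------------------------------------------------------------------

def _best_split(profile: np.ndarray) -> tuple[int, float]:
    """Best single change-point by SSE reduction; returns (index, gain)."""
    n = profile.size
    total = float(np.sum((profile - profile.mean()) ** 2))
    best_i, best_cost = -1, math.inf
    for i in range(2, n - 1):
        left, right = profile[:i], profile[i:]
        cost = float(np.sum((left - left.mean()) ** 2) + np.sum((right - right.mean()) ** 2))
        if cost < best_cost:
            best_i, best_cost = i, cost
    gain = 0.0 if total <= 0 else (total - best_cost) / total
    return best_i, gain


def _split_is_significant(profile: np.ndarray, gain: float,
                          n_perm: int = 199, alpha: float = 0.01) -> bool:
    """Permutation test for a change-point: the observed SSE-reduction gain
    must beat the (1 - alpha) quantile of gains on shuffled profiles.

    An exchangeable (orderless) profile passes at rate ~alpha, so shuffled
    recordings essentially never acquire confident boundaries."""
    if profile.size < 6 or gain <= 0:
        return False
    rng = np.random.default_rng(0)  # fixed: segmentation stays deterministic
    perm_gains = np.empty(n_perm)
    for k in range(n_perm):
        perm_gains[k] = _best_split(rng.permutation(profile))[1]
    return gain > float(np.quantile(perm_gains, 1.0 - alpha))


def segment_phases(
    recording: Recording,
    window_s: float = 5000.0,
    threshold_k: float = DEFAULT_THRESHOLD_K,
    min_gain: float = 0.1,
) -> PhaseSegmentation:
    """Segment a recording into initial / transitional / late phases.

    Spike counts per window (summed over channels) form a rate profile; if
    the recording carries too few spikes to segment, the windowed variance
    profile is used instead.  The two largest change-points from binary
    segmentation become the phase boundaries; if no split clears the
    ``min_gain`` SSE-reduction threshold a single-phase segmentation is
    returned flagged as not confident.
    """
    t = recording.times
    span = (float(t[0]), float(t[-1]))
    n_win = int(recording.duration // window_s)
    if n_win < 3:
        raise InsufficientDataError("recording shorter than 3 windows")
    fs = 1.0 / recording.sample_interval
    edges = t[0] + window_s * np.arange(n_win + 1)

    rate = np.zeros(n_win)
    variance = np.zeros(n_win)
    for trace in recording.channels.values():
        try:
            events = detect_spikes(trace, fs=fs, threshold_k=threshold_k, times=t)
        except InsufficientDataError:
            events = []
        if events:
            ev_t = np.asarray([e.time for e in events])
            rate += np.histogram(ev_t, bins=edges)[0]
        samples_per_win = int(window_s * fs)
        for w in range(n_win):
            seg = trace[w * samples_per_win:(w + 1) * samples_per_win]
            variance[w] += float(np.var(seg))
    rate /= window_s * len(recording.channels)
    variance /= len(recording.channels)

    profile = rate if rate.sum() * recording.duration >= 10 else np.sqrt(variance)

    i1, gain1 = _best_split(profile)
    if i1 < 0 or gain1 < min_gain or not _split_is_significant(profile, gain1):
        return PhaseSegmentation((), ("single",), span, confident=False)
    # second split: best split of either side of the first boundary
    cands = []
    left, right = profile[:i1], profile[i1:]
    if left.size >= 6:
        j, gn = _best_split(left)
        if j > 0 and _split_is_significant(left, gn):
            cands.append((j, gn))
    if right.size >= 6:
        j, gn = _best_split(right)
        if j > 0 and _split_is_significant(right, gn):
            cands.append((i1 + j, gn))
    if not cands:
        b = float(edges[i1])
        return PhaseSegmentation((b,), ("initial", "late"), span, confident=True)
    i2, gain2 = max(cands, key=lambda c: c[1])
    if gain2 < min_gain:
        b = float(edges[i1])
        return PhaseSegmentation((b,), ("initial", "late"), span, confident=True)
    b1, b2 = sorted((float(edges[i1]), float(edges[i2])))
    return PhaseSegmentation(
        (b1, b2), ("initial", "transitional", "late"), span, confident=True
    )


# ---------------------------------------------------------------------------
# Channel summaries and morphology classification
# ---------------------------------------------------------------------------

def summarize_channels(
    recording: Recording,
    segmentation: PhaseSegmentation | None = None,
    final_window_s: float = 10_000.0,
    threshold_k: float = DEFAULT_THRESHOLD_K,
) -> list[ChannelSummary]:
    """Per-channel steady state, drift, per-phase spike rate, range and band.

    steady_state is the mean over the final ``final_window_s`` (clipped to
    the recording length); drift is the change between the means of the two
    most recent windows of length max(final_window_s, T/8), which captures
    whether a channel is still moving at the end of the recording.
    """
    t = recording.times
    fs = 1.0 / recording.sample_interval
    T = recording.duration
    w_final = min(final_window_s, T / 2)
    w_drift = min(max(final_window_s, T / 8), T / 2)

    intervals = segmentation.intervals() if segmentation is not None else [
        ("overall", float(t[0]), float(t[-1]))
    ]
    summaries = []
    for name, trace in recording.channels.items():
        final_mask = t >= t[-1] - w_final
        steady = float(np.mean(trace[final_mask]))
        last = trace[t >= t[-1] - w_drift]
        prev = trace[(t >= t[-1] - 2 * w_drift) & (t < t[-1] - w_drift)]
        drift = float(np.mean(last) - np.mean(prev)) if prev.size else 0.0
        try:
            events = detect_spikes(trace, fs=fs, threshold_k=threshold_k, times=t)
        except InsufficientDataError:
            events = []
        ev_t = np.asarray([e.time for e in events])
        rates = {"overall": float(ev_t.size / T)}
        for lab, s, e in intervals:
            dur = e - s
            rates[lab] = float(np.count_nonzero((ev_t >= s) & (ev_t < e)) / dur) if dur > 0 else 0.0
        lo, hi = float(trace.min()), float(trace.max())
        band = ("positive" if steady > BAND_POSITIVE_MV
                else "negative" if steady < BAND_NEGATIVE_MV else "neutral")
        summaries.append(ChannelSummary(
            name=name, steady_state=steady, drift=drift,
            spike_rate=rates, range=(lo, hi), band=band,
        ))
    return summaries


def classify_morphology(summaries: list[ChannelSummary]) -> MorphologyCall:
    """Rule-based morphology call from channel summaries.

    Soft rule scores, each in [0, 1], normalized to sum 1:

    * microspheres — most channels spike and the late-phase steady states
      spread widely;
    * fibers — essentially no spikes, wide stable polarization bands, and
      no residual drift at the end of the recording;
    * mixture — spiking and silent channels coexist with steady states
      inside the mixed-network envelope (about -40..+45 mV);
    * control — no spikes and at least one channel still drifting
      monotonically at the end (or nothing happening at all, the documented
      lexicographic tie-break).
    """
    if not summaries:
        raise InsufficientDataError("need at least one channel summary")
    rates = np.asarray([s.spike_rate.get("overall", 0.0) for s in summaries])
    steady = np.asarray([s.steady_state for s in summaries])
    drifts = np.asarray([abs(s.drift) for s in summaries])

    mean_rate = float(rates.mean())
    f_spiking = float(np.mean(rates > 0.003))
    spread = float(steady.max() - steady.min()) if steady.size > 1 else 0.0

    spiky = min(mean_rate / 0.03, 1.0)
    banded = min(spread / 80.0, 1.0)
    drifty = min(float(drifts.max()) / 8.0, 1.0)
    envelope = float(np.mean((steady >= -45.0) & (steady <= 50.0)))

    scores = {
        "microspheres": spiky * (0.4 + 0.6 * banded),
        "fibers": (1.0 - spiky) * banded * (1.0 - drifty),
        "mixture": 4.0 * f_spiking * (1.0 - f_spiking) * envelope,
        "control": (1.0 - spiky) * drifty,
    }
    return _resolve_call(scores)
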