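"""Forward models of proteinoid electrical activity and the synthetic-recording generator.

Glu-Phe-Asp (GFD) proteinoid assemblies produce morphology-dependent
extracellular potentials: microspheres emit rapid, action-potential-like
spikes; fibrillar networks drift slowly and carry quasi-periodic slow waves;
50:50 mixtures settle into stable heterogeneous voltage zones.  This module
renders the elementary waveforms (exponential relaxation, biexponential
spikes, leaky-membrane and bistable double-well dynamics, Nernst-Planck
flux) and composes them into full multichannel recordings, one regime per
electrode channel, with every source of randomness controlled by a single
root seed.

Units throughout: potentials mV, time s, capacitance uF, conductance uS,
current uA, diffusion um^2/s.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.signal import lfilter

from .errors import ConfigurationError, InvalidParameterError, StabilityError

logger = logging.getLogger("gfdkit.sim_dynamics")

#: Faraday constant, C/mol.
FARADAY = 96485.0
#: Molar gas constant, J/(mol K).
GAS_CONSTANT = 8.314

#: Recording-grid spacing of the data logger, s (1 sample per second).
DEFAULT_SAMPLE_INTERVAL_S = 1.0
#: Internal integration step used before decimation to the recording grid, s.
DEFAULT_INTERNAL_STEP_S = 0.1
#: Absolute dead time between emitted spikes in threshold_spiker mode, s.
DEFAULT_REFRACTORY_S = 2.0
#: Dead time used by the pacemaker mode, s.  A 0.6 Hz pacemaker cannot run
#: under a 2 s dead time (mean interval 1.67 s), so its dead time is shorter.
PACEMAKER_REFRACTORY_S = 1.0

MORPHOLOGIES = ("microsphere", "fiber", "mixture", "control")
CHANNEL_MODES = ("threshold_spiker", "bistable", "pacemaker", "drift", "slow_wave", "banded")


# ---------------------------------------------------------------------------
# Parameter bundles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RelaxationParams:
    """Single-exponential relaxation V(t) = v_inf + dv * exp(-t / tau).

    v_inf is the steady-state potential (mV), dv the initial deviation from
    it (mV), tau the relaxation time constant (s).
    """

    v_inf: float
    dv: float
    tau: float

    def __post_init__(self) -> None:
        if not self.tau > 0:
            raise InvalidParameterError(f"tau must be > 0, got {self.tau}")


@dataclass(frozen=True)
class SpikeShape:
    """Biexponential spike waveform parameters.

    For t >= t0 the deviation from baseline is
    ``amplitude * (exp(-(t-t0)/tau_decay) - exp(-(t-t0)/tau_rise))`` with
    tau_rise < tau_decay, so a positive amplitude gives a positive-going
    spike with a quick rise and a gradual decay.
    """

    baseline: float
    amplitude: float
    tau_rise: float
    tau_decay: float
    t0: float

    def __post_init__(self) -> None:
        if not (self.tau_rise > 0 and self.tau_decay > 0):
            raise InvalidParameterError("rise/decay constants must be > 0")
        if self.tau_rise == self.tau_decay:
            raise InvalidParameterError("tau_rise == tau_decay is degenerate")
        if not math.isfinite(self.amplitude):
            raise InvalidParameterError("amplitude must be finite")

    @property
    def peak_time(self) -> float:
        """Time after onset at which the biexponential difference peaks."""
        tr, td = self.tau_rise, self.tau_decay
        return math.log(td / tr) * tr * td / (td - tr)

    @property
    def peak_factor(self) -> float:
        """Peak value of |exp(-t/tau_decay) - exp(-t/tau_rise)| (unit amplitude)."""
        tp = self.peak_time
        return abs(math.exp(-tp / self.tau_decay) - math.exp(-tp / self.tau_rise))


@dataclass(frozen=True)
class MembraneParams:
    """Leaky-membrane parameters: cm dV/dt = -g_ion (V - v_eq) + i_ion(t).

    ``i_ion`` is a piecewise-constant stimulus schedule given as a sequence
    of (start_time_s, current_uA) pairs; each current holds until the next
    start time.
    """

    cm: float
    g_ion: float
    v_eq: float
    i_ion: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        if not self.cm > 0:
            raise InvalidParameterError("cm must be > 0")
        if self.g_ion < 0:
            raise InvalidParameterError("g_ion must be >= 0")
        starts = [t for t, _ in self.i_ion]
        if sorted(starts) != starts:
            raise InvalidParameterError("i_ion schedule must be time-ordered")


@dataclass(frozen=True)
class BistableParams:
    """Double-well drift dV = -alpha V (V - v1)(V - v2) dt + sigma dW.

    alpha (mV^-2 s^-1) sets the transition rate, v1/v2 are the stable
    potentials (mV), sigma the white-noise intensity (mV s^-1/2).
    """

    alpha: float
    v1: float
    v2: float
    sigma: float

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise InvalidParameterError("alpha must be > 0")
        if self.v1 == self.v2:
            raise InvalidParameterError("v1 and v2 must differ")
        if self.sigma < 0:
            raise InvalidParameterError("sigma must be >= 0")


@dataclass(frozen=True)
class NernstPlanckInputs:
    """Pointwise inputs for the radial Nernst-Planck flux evaluation."""

    d_coeff: float        # um^2/s
    conc: float           # mol/m^3
    dconc_dr: float       # (mol/m^3) per um
    dv_dr: float          # mV per um
    z_charge: float       # ion valence
    temperature: float    # K

    def __post_init__(self) -> None:
        if not self.d_coeff > 0:
            raise InvalidParameterError("d_coeff must be > 0")
        if not self.temperature > 0:
            raise InvalidParameterError("temperature must be > 0")


@dataclass(frozen=True)
class Phase:
    """One interval of a channel's phase schedule.

    rate_hz is the spike emission rate inside the interval, amp_range the
    (low, high) target peak amplitudes in mV, band an optional (low, high)
    target potential band for the baseline during the phase.
    """

    start: float
    end: float
    rate_hz: float = 0.0
    amp_range: tuple[float, float] = (0.0, 0.0)
    band: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise InvalidParameterError("phase end must exceed start")
        if self.rate_hz < 0:
            raise InvalidParameterError("spike rates must be >= 0")


@dataclass(frozen=True)
class ChannelRegime:
    """What one electrode channel does: morphology, dynamic mode, schedule."""

    morphology: str
    mode: str
    phase_schedule: tuple[Phase, ...] = ()
    steady_target: float = 0.0
    v_start: float | None = None
    tau_s: float | None = None
    options: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.morphology not in MORPHOLOGIES:
            raise ConfigurationError(f"unknown morphology {self.morphology!r}")
        if self.mode not in CHANNEL_MODES:
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        phases = self.phase_schedule
        for a, b in zip(phases, phases[1:]):
            if b.start < a.end:
                raise ConfigurationError(
                    f"phase schedule overlaps: [{a.start},{a.end}) and [{b.start},{b.end})"
                )


@dataclass(frozen=True)
class ModulationFactors:
    """Environmental modifiers of spike probability.

    Each factor scales the emission rate multiplicatively and monotonically:
    higher ionic strength, warmer temperature, lower pH and more divalent
    cations all increase the rate.  The functional forms are linear clamps;
    at the defaults the multiplier is exactly 1.
    """

    ionic_strength_scale: float = 1.0
    temperature_c: float = 25.0
    ph: float = 7.0
    divalent_mM: float = 0.0

    def __post_init__(self) -> None:
        vals = (self.ionic_strength_scale, self.temperature_c, self.ph, self.divalent_mM)
        if not all(math.isfinite(v) for v in vals):
            raise InvalidParameterError("modulation factors must be finite")
        if self.ionic_strength_scale < 0:
            raise InvalidParameterError("ionic_strength_scale must be >= 0")

    def rate_multiplier(self) -> float:
        f_temp = np.clip(1.0 + 0.04 * (self.temperature_c - 25.0), 0.1, 3.0)
        f_ph = np.clip(1.0 + 0.15 * (7.0 - self.ph), 0.1, 3.0)
        f_div = np.clip(1.0 + 0.10 * self.divalent_mM, 1.0, 3.0)
        return float(self.ionic_strength_scale * f_temp * f_ph * f_div)


@dataclass
class Recording:
    """A uniformly sampled multichannel voltage recording.

    ``channels`` maps channel label -> trace (mV) on the common ``times``
    grid; ``meta`` carries morphology, seed, internal step and modulation.
    """

    times: np.ndarray
    channels: dict[str, np.ndarray]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1 or t.size < 2:
            raise InvalidParameterError("times must be a 1-D grid with >= 2 samples")
        dt = np.diff(t)
        if not (np.all(dt > 0) and np.allclose(dt, dt[0], rtol=1e-9, atol=1e-9)):
            raise InvalidParameterError("times must be strictly increasing and uniform")
        self.times = t
        for name, trace in self.channels.items():
            trace = np.asarray(trace, dtype=float)
            if trace.shape != t.shape:
                raise InvalidParameterError(f"channel {name!r} length mismatch")
            self.channels[name] = trace

    @property
    def sample_interval(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])


# ---------------------------------------------------------------------------
# Elementary traces
# ---------------------------------------------------------------------------

def relaxation_trace(params: RelaxationParams, times: np.ndarray) -> np.ndarray:
    """Evaluate the exponential relaxation v_inf + dv * exp(-t/tau) on a grid."""
    t = np.asarray(times, dtype=float)
    if t.size and t.min() < 0:
        raise InvalidParameterError("times must be >= 0")
    return params.v_inf + params.dv * np.exp(-t / params.tau)


def render_spike(
    shape: SpikeShape,
    times: np.ndarray,
    convention: str = "decay_minus_rise",
) -> np.ndarray:
    """Render a biexponential spike gated by the Heaviside step at t0.

    ``convention`` selects the ordering of the exponential difference;
    the default ("decay_minus_rise") makes a positive amplitude a
    positive-going spike when tau_rise < tau_decay.
    """
    t = np.asarray(times, dtype=float)
    dt = t - shape.t0
    gate = dt >= 0
    dtp = np.where(gate, dt, 0.0)
    diff = np.exp(-dtp / shape.tau_decay) - np.exp(-dtp / shape.tau_rise)
    if convention == "rise_minus_decay":
        diff = -diff
    elif convention != "decay_minus_rise":
        raise ConfigurationError(f"unknown spike convention {convention!r}")
    return shape.baseline + shape.amplitude * np.where(gate, diff, 0.0)


def simulate_membrane(
    params: MembraneParams,
    v0: float,
    times: np.ndarray,
    seed: int | None = None,
    noise_sigma: float = 0.0,
) -> np.ndarray:
    """Forward-Euler integration of the leaky-membrane equation on a uniform grid.

    With i_ion == 0 the trace relaxes exponentially towards v_eq with time
    constant cm/g_ion (to first order in the step).  Optional additive
    Gaussian noise (noise_sigma, mV s^-1/2) enters as Wiener increments.
    The explicit scheme requires dt < 2 cm / g_ion.
    """
    t = np.asarray(times, dtype=float)
    if t.size < 2:
        raise InvalidParameterError("need at least two grid points")
    dt = float(t[1] - t[0])
    if not np.allclose(np.diff(t), dt, rtol=1e-9, atol=1e-12):
        raise InvalidParameterError("grid must be uniform")
    if params.g_ion > 0 and dt >= 2.0 * params.cm / params.g_ion:
        raise StabilityError(
            f"dt={dt} s violates explicit-Euler stability (needs dt < {2 * params.cm / params.g_ion} s)"
        )
    n = t.size
    a = 1.0 - dt * params.g_ion / params.cm

    current = np.zeros(n)
    for start, value in params.i_ion:
        current[t >= start] = value
    drive = (dt / params.cm) * (params.g_ion * params.v_eq + current)

    u = np.empty(n)
    u[0] = v0
    u[1:] = drive[:-1]
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        u[1:] += noise_sigma * math.sqrt(dt) * rng.standard_normal(n - 1)
    # V_n = a V_{n-1} + u_n is an AR(1) recursion; lfilter evaluates it exactly.
    return lfilter([1.0], [1.0, -a], u)


def simulate_bistable(
    params: BistableParams,
    v0: float,
    times: np.ndarray,
    seed: int | None = None,
) -> np.ndarray:
    """Euler-Maruyama integration of the double-well SDE.

    With sigma = 0 trajectories converge to v1 or v2 from any start except
    the unstable root at 0 (and the roots themselves, which are fixed).
    """
    t = np.asarray(times, dtype=float)
    if t.size < 2:
        raise InvalidParameterError("need at least two grid points")
    dt = float(t[1] - t[0])
    if not np.allclose(np.diff(t), dt, rtol=1e-9, atol=1e-12):
        raise InvalidParameterError("grid must be uniform")
    n = t.size
    out = np.empty(n)
    out[0] = v0
    if params.sigma > 0:
        rng = np.random.default_rng(seed)
        noise = params.sigma * math.sqrt(dt) * rng.standard_normal(n - 1)
    else:
        noise = np.zeros(n - 1)
    alpha, v1, v2 = params.alpha, params.v1, params.v2
    v = v0
    # The cubic drift is stiff far from the wells; substep each grid interval
    # so the explicit update stays well inside its stability region.
    stiff_scale = abs(v1) + abs(v2)
    for i in range(1, n):
        slope = alpha * (3 * v * v + 2 * abs(v) * stiff_scale + abs(v1 * v2))
        m = min(10000, int(dt * slope / 0.5) + 1)
        h = dt / m
        for _ in range(m):
            v = v + h * (-alpha * v * (v - v1) * (v - v2))
        v += noise[i - 1]
        out[i] = v
    return out


def nernst_planck_flux(inp: NernstPlanckInputs) -> float:
    """Pointwise radial Nernst-Planck flux, mol um^-2 s^-1.

    J = -D dC/dr + (z F / R T) D C dV/dr.  Unit bookkeeping: with D in
    um^2/s, C in mol/m^3 and radial gradients per um, the bracket comes out
    in mol um / (m^3 s); one m^3 is 1e18 um^3, hence the 1e-18 prefactor.
    The potential gradient is given in mV/um, hence the 1e-3 V/mV factor in
    the electromigration term.
    """
    drift_coeff = inp.z_charge * FARADAY * 1e-3 / (GAS_CONSTANT * inp.temperature)
    bracket = -inp.d_coeff * inp.dconc_dr + drift_coeff * inp.d_coeff * inp.conc * inp.dv_dr
    return 1e-18 * bracket


# ---------------------------------------------------------------------------
# Spike trains
# ---------------------------------------------------------------------------

def draw_spike_times(
    rate_hz: float,
    t_start: float,
    t_end: float,
    dead_time_s: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw spike onset times on [t_start, t_end) as a renewal process.

    Intervals are dead_time + Exp(mean 1/rate - dead_time), so the realized
    mean rate equals ``rate_hz`` exactly while enforcing an absolute
    refractory period.  Rates at or above 1/dead_time saturate to back-to-
    back dead times.
    """
    if rate_hz <= 0 or t_end <= t_start:
        return np.empty(0)
    mean_exp = max(1.0 / rate_hz - dead_time_s, 1e-9)
    span = t_end - t_start
    times: list[float] = []
    # first onset: stationary-ish start, offset by a fresh interval
    t = t_start + rng.exponential(1.0 / rate_hz)
    while t < t_end:
        times.append(t)
        t += dead_time_s + rng.exponential(mean_exp)
        if len(times) > int(span * rate_hz * 10 + 1000):  # safety valve
            break
    return np.asarray(times)


def _add_spikes(
    trace: np.ndarray,
    t_grid: np.ndarray,
    onsets: np.ndarray,
    peak_amps: np.ndarray,
    tau_rise: float,
    tau_decay: float,
) -> None:
    """Add biexponential spikes in place; peak_amps are realized peak heights."""
    if onsets.size == 0:
        return
    dt = t_grid[1] - t_grid[0]
    ref = SpikeShape(0.0, 1.0, tau_rise, tau_decay, 0.0)
    scale = 1.0 / ref.peak_factor
    span = int(math.ceil((ref.peak_time + 8.0 * tau_decay) / dt))
    t0_grid = t_grid[0]
    for t0, amp in zip(onsets, peak_amps):
        i0 = int(math.ceil((t0 - t0_grid) / dt))
        i1 = min(i0 + span, t_grid.size)
        if i0 >= t_grid.size:
            continue
        local = t_grid[i0:i1] - t0
        trace[i0:i1] += amp * scale * (
            np.exp(-local / tau_decay) - np.exp(-local / tau_rise)
        )


def _ar1_noise(n: int, dt: float, sigma: float, tau: float, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean Ornstein-Uhlenbeck-style noise with stationary sd ``sigma``."""
    if sigma <= 0:
        return np.zeros(n)
    a = math.exp(-dt / tau)
    innov = sigma * math.sqrt(1 - a * a) * rng.standard_normal(n)
    innov[0] = sigma * rng.standard_normal()
    return lfilter([1.0], [1.0, -a], innov)


# ---------------------------------------------------------------------------
# Channel simulators
# ---------------------------------------------------------------------------

def _internal_grid(times: np.ndarray, internal_step: float | None) -> tuple[np.ndarray, int]:
    """Build the fine integration grid and the decimation stride."""
    t = np.asarray(times, dtype=float)
    dt_rec = float(t[1] - t[0])
    if internal_step is None or internal_step >= dt_rec:
        return t, 1
    stride = int(round(dt_rec / internal_step))
    if not math.isclose(stride * internal_step, dt_rec, rel_tol=1e-9):
        raise ConfigurationError("sample interval must be a multiple of the internal step")
    fine = t[0] + internal_step * np.arange((t.size - 1) * stride + 1)
    return fine, stride


def simulate_microsphere_channel(
    regime: ChannelRegime,
    mod: ModulationFactors | None,
    times: np.ndarray,
    seed: int | None,
    internal_step: float | None = DEFAULT_INTERNAL_STEP_S,
) -> np.ndarray:
    """Simulate one microsphere-dominated channel on the recording grid.

    Modes: ``threshold_spiker`` (slow leaky-membrane accumulation plus
    stochastic spikes at the phase-schedule rates), ``pacemaker``
    (homogeneous small-amplitude spike train, 0.6 Hz / 1-2 mV by default)
    and ``bistable`` (double-well switching around the channel baseline).
    The trace is integrated on a fine internal grid and decimated.
    """
    if regime.morphology not in ("microsphere", "mixture"):
        raise ConfigurationError(
            f"microsphere simulator got morphology {regime.morphology!r}"
        )
    if regime.mode not in ("threshold_spiker", "bistable", "pacemaker"):
        raise ConfigurationError(f"mode {regime.mode!r} is not a microsphere mode")
    mod = mod or ModulationFactors()
    rng = np.random.default_rng(seed)
    fine, stride = _internal_grid(times, internal_step)
    dt = float(fine[1] - fine[0]) if fine.size > 1 else DEFAULT_INTERNAL_STEP_S
    opts = regime.options
    noise_sigma = float(opts.get("noise_sigma_mv", 0.2))
    rate_scale = mod.rate_multiplier()

    if regime.mode == "bistable":
        half = float(opts.get("swing_mv", 9.0)) / 2.0
        params = BistableParams(
            alpha=float(opts.get("alpha", 0.005)),
            v1=-half,
            v2=half,
            sigma=float(opts.get("sigma", 1.0)),
        )
        v0 = float(opts.get("v0", params.v2))
        trace = regime.steady_target + simulate_bistable(
            params, v0, fine, seed=rng.integers(2**31)
        )
        return trace[::stride].copy()

    if regime.mode == "pacemaker":
        rate = float(opts.get("rate_hz", 0.6)) * rate_scale
        amp_lo, amp_hi = opts.get("amp_range_mv", (1.0, 2.0))
        baseline = regime.steady_target if regime.steady_target else -39.0
        trace = np.full(fine.size, float(baseline))
        # slow baseline wander (Channel-H style, a few mV over minutes)
        wander = float(opts.get("wander_mv", 2.0))
        if wander > 0:
            period = float(opts.get("wander_period_s", 900.0))
            trace += wander * np.sin(2 * np.pi * fine / period)
        trace += _ar1_noise(fine.size, dt, float(opts.get("noise_sigma_mv", 0.1)), 5.0, rng)
        onsets = draw_spike_times(
            rate, fine[0], fine[-1], PACEMAKER_REFRACTORY_S, rng
        )
        amps = rng.uniform(amp_lo, amp_hi, onsets.size)
        _add_spikes(
            trace, fine, onsets, amps,
            tau_rise=float(opts.get("tau_rise_s", 0.05)),
            tau_decay=float(opts.get("tau_decay_s", 0.15)),
        )
        return trace[::stride].copy()

    # threshold_spiker: baseline follows leaky-membrane dynamics between the
    # per-phase band targets; spikes ride on top as a refractory renewal train.
    phases = regime.phase_schedule
    if not phases:
        raise ConfigurationError("threshold_spiker needs a phase schedule")
    cm = float(opts.get("cm_uf", 1.0))
    g_ion = float(opts.get("g_ion_us", 0.01))
    v_eq = 0.0
    schedule = []
    for ph in phases:
        target = regime.steady_target
        if ph.band is not None:
            target = 0.5 * (ph.band[0] + ph.band[1])
        schedule.append((ph.start, g_ion * (target - v_eq)))
    params = MembraneParams(cm=cm, g_ion=g_ion, v_eq=v_eq, i_ion=tuple(schedule))
    v0 = regime.v_start
    if v0 is None:
        v0 = schedule[0][1] / g_ion
    trace = simulate_membrane(params, float(v0), fine)
    trace += _ar1_noise(fine.size, dt, noise_sigma, 10.0, rng)

    tau_rise = float(opts.get("tau_rise_s", 0.2))
    tau_decay = float(opts.get("tau_decay_s", 1.0))
    dead = float(opts.get("refractory_s", DEFAULT_REFRACTORY_S))
    polarity = float(opts.get("polarity", 1.0))
    for ph in phases:
        onsets = draw_spike_times(ph.rate_hz * rate_scale, ph.start, min(ph.end, fine[-1]), dead, rng)
        amps = polarity * rng.uniform(ph.amp_range[0], ph.amp_range[1], onsets.size)
        _add_spikes(trace, fine, onsets, amps, tau_rise, tau_decay)
    return trace[::stride].copy()


def simulate_fiber_channel(
    regime: ChannelRegime,
    times: np.ndarray,
    seed: int | None,
    internal_step: float | None = None,
) -> np.ndarray:
    """Simulate one fiber-dominated channel on the recording grid.

    Modes: ``drift`` (exponential approach to the steady target with
    0.5-1.0 mV micro-oscillations), ``slow_wave`` (asymmetric quasi-periodic
    waves, 3-5 mV peak-to-peak, troughs every 5,000-10,000 s) and ``banded``
    (three-phase transient -> transition -> equilibrium-band trajectory).
    Fiber dynamics are slow, so the default integration grid is the
    recording grid itself.
    """
    if regime.morphology not in ("fiber", "mixture", "control"):
        raise ConfigurationError(f"fiber simulator got morphology {regime.morphology!r}")
    if regime.mode not in ("drift", "slow_wave", "banded"):
        raise ConfigurationError(f"mode {regime.mode!r} is not a fiber mode")
    rng = np.random.default_rng(seed)
    fine, stride = _internal_grid(times, internal_step)
    t_rel = fine - fine[0]
    dt = float(fine[1] - fine[0])
    span = float(fine[-1] - fine[0])
    opts = regime.options
    noise_sigma = float(opts.get("noise_sigma_mv", 0.05))

    if regime.mode == "drift":
        v_start = regime.v_start if regime.v_start is not None else regime.steady_target
        tau = regime.tau_s or span / 5.0
        trace = relaxation_trace(
            RelaxationParams(regime.steady_target, v_start - regime.steady_target, tau),
            t_rel,
        )
        osc = float(opts.get("osc_amp_mv", 0.5))
        if osc > 0:
            # two incommensurate tones, zero at t=0, realizing the 0.5-1 mV ripple
            trace += 0.5 * osc * np.sin(2 * np.pi * t_rel / 610.0)
            trace += 0.25 * osc * np.sin(2 * np.pi * t_rel / 131.0)
        trace += _ar1_noise(fine.size, dt, noise_sigma,
                            float(opts.get("noise_tau_s", 30.0)), rng)
        return trace[::stride].copy()

    if regime.mode == "slow_wave":
        period0 = float(opts.get("wave_period_s", 7500.0))
        p2p_lo, p2p_hi = opts.get("p2p_range_mv", (3.0, 5.0))
        frac_fall = float(opts.get("fall_fraction", 0.8))
        baseline = regime.steady_target if regime.steady_target else 49.5
        trace = np.full(fine.size, float(baseline))
        t = 0.0
        while t < span:
            period = float(np.clip(period0 * rng.uniform(0.85, 1.15), 5000.0, 10000.0))
            p2p = rng.uniform(p2p_lo, p2p_hi)
            i0 = int(t / dt)
            i1 = min(int((t + period) / dt), fine.size)
            if i1 <= i0:
                break
            u = (t_rel[i0:i1] - t) / period  # cycle phase in [0,1)
            wave = np.where(
                u < frac_fall,
                0.5 * p2p - p2p * (u / frac_fall),          # gradual descent
                -0.5 * p2p + p2p * (u - frac_fall) / (1 - frac_fall),  # rapid rise
            )
            trace[i0:i1] += wave
            t += period
        trace += _ar1_noise(fine.size, dt, noise_sigma, 60.0, rng)
        return trace[::stride].copy()

    # banded: large initial transient relaxing into the equilibrium band.
    phases = regime.phase_schedule
    if not phases:
        raise ConfigurationError("banded mode needs a three-phase schedule")
    transition_end = phases[1].end if len(phases) > 1 else span / 3.0
    v_start = regime.v_start
    if v_start is None:
        v_start = regime.steady_target + float(opts.get("transient_amp_mv", 100.0))
    tau = regime.tau_s or transition_end / 4.0
    trace = relaxation_trace(
        RelaxationParams(regime.steady_target, v_start - regime.steady_target, tau), t_rel
    )
    osc = float(opts.get("osc_amp_mv", 0.8))
    if osc > 0:
        trace += 0.5 * osc * np.sin(2 * np.pi * t_rel / 2100.0)
    trace += _ar1_noise(fine.size, dt, float(opts.get("noise_sigma_mv", 0.15)), 60.0, rng)
    return trace[::stride].copy()


# ---------------------------------------------------------------------------
# Whole-recording composition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RecordingConfig:
    """Experiment description for :func:`simulate_recording`."""

    morphology: str
    duration_s: float
    channels: tuple[ChannelRegime, ...]
    labels: tuple[str, ...]
    sample_interval_s: float = DEFAULT_SAMPLE_INTERVAL_S
    internal_step_s: float = DEFAULT_INTERNAL_STEP_S
    modulation: ModulationFactors = field(default_factory=ModulationFactors)

    def __post_init__(self) -> None:
        if self.morphology not in MORPHOLOGIES:
            raise ConfigurationError(f"unknown morphology {self.morphology!r}")
        if not self.duration_s > 0:
            raise ConfigurationError("duration must be > 0")
        if len(self.channels) < 1:
            raise ConfigurationError("need at least one channel")
        if len(self.labels) != len(self.channels):
            raise ConfigurationError("labels/channels length mismatch")


def _three_phase(duration: float, rates, amps, bands) -> tuple[Phase, ...]:
    """Initial/transitional/late schedule at the canonical 2/9 and 2/3 fractions."""
    b1, b2 = duration * 2.0 / 9.0, duration * 2.0 / 3.0
    edges = [(0.0, b1), (b1, b2), (b2, duration)]
    return tuple(
        Phase(s, e, rate_hz=r, amp_range=a, band=b)
        for (s, e), r, a, b in zip(edges, rates, amps, bands)
    )


def default_config(
    morphology: str,
    duration_s: float | None = None,
    n_channels: int | None = None,
    modulation: ModulationFactors | None = None,
    sample_interval_s: float = DEFAULT_SAMPLE_INTERVAL_S,
    internal_step_s: float = DEFAULT_INTERNAL_STEP_S,
) -> RecordingConfig:
    """Build the default per-morphology experiment configuration.

    Defaults emulate the reported regimes: microsphere recordings run three
    phases (high-rate spiking at 5-15 mV, a 0.1-0.2 Hz transitional phase,
    then a late phase spreading over -70..+110 mV) with one bistable and one
    pacemaker channel; fiber recordings relax from large transients into
    stable polarization bands (+40..+65 / -10..+30 / -60..-90 mV); mixtures
    stabilize all channels inside -40..+45 mV after the first ~10,000 s;
    the control produces spike-free drifts only.
    """
    if morphology == "microsphere":
        duration = duration_s or 180_000.0
        n = n_channels or 8
        late_targets = np.linspace(-70.0, 110.0, n)
        regimes, labels = [], []
        rates = (0.4, 0.15, 0.05)
        for i in range(n):
            label = f"Ch{chr(ord('A') + i)}"
            labels.append(label)
            if n >= 6 and i == 4:          # Channel-E-style bistable switcher
                regimes.append(ChannelRegime(
                    morphology="microsphere", mode="bistable",
                    steady_target=float(late_targets[i]),
                ))
                continue
            if n >= 8 and i == 7:          # Channel-H-style pacemaker
                regimes.append(ChannelRegime(
                    morphology="microsphere", mode="pacemaker", steady_target=-39.0,
                ))
                continue
            bands = (
                (-10.0, 10.0),
                (late_targets[i] * 0.5 - 5.0, late_targets[i] * 0.5 + 5.0),
                (late_targets[i] - 2.0, late_targets[i] + 2.0),
            )
            amps = ((5.0, 15.0), (5.0, 15.0), (2.0, 8.0))
            regimes.append(ChannelRegime(
                morphology="microsphere", mode="threshold_spiker",
                phase_schedule=_three_phase(duration, rates, amps, bands),
                steady_target=float(late_targets[i]),
            ))
    elif morphology == "fiber":
        duration = duration_s or 360_000.0
        n = n_channels or 8
        # Polarization bands: positive C/E/F, neutral A/B/H, negative G.
        targets = [10.0, 25.0, 48.0, 30.0, 55.0, 63.0, -75.0, -5.0][:n]
        transients = [60.0, 80.0, 120.0, 200.0, 90.0, 100.0, -160.0, 70.0][:n]
        b1, b2 = duration * 5.0 / 36.0, duration * 15.0 / 36.0
        schedule = (
            Phase(0.0, b1, band=None),
            Phase(b1, b2, band=None),
            Phase(b2, duration, band=None),
        )
        regimes, labels = [], []
        for i in range(n):
            labels.append(f"Ch{chr(ord('A') + i)}")
            regimes.append(ChannelRegime(
                morphology="fiber", mode="banded",
                phase_schedule=schedule,
                steady_target=targets[i % len(targets)],
                v_start=targets[i % len(targets)] + transients[i % len(transients)],
            ))
    elif morphology == "mixture":
        duration = duration_s or 60_000.0
        n = n_channels or 9
        targets = np.linspace(-38.0, 43.0, n)
        regimes, labels = [], []
        for i in range(n):
            labels.append(f"Ch{chr(ord('A') + i)}")
            tgt = float(targets[::-1][i] if i % 2 else targets[i])
            if i % 2 == 0:
                # microsphere-dominated zone: modest spiking on a settling baseline
                schedule = (
                    Phase(0.0, duration / 6.0, rate_hz=0.03, amp_range=(2.0, 6.0),
                          band=(tgt - 12.0, tgt + 12.0)),
                    Phase(duration / 6.0, duration, rate_hz=0.02, amp_range=(2.0, 6.0),
                          band=(tgt - 1.0, tgt + 1.0)),
                )
                regimes.append(ChannelRegime(
                    morphology="mixture", mode="threshold_spiker",
                    phase_schedule=schedule, steady_target=tgt,
                    v_start=tgt + (15.0 if tgt < 0 else -15.0),
                    options={"g_ion_us": 0.0004},   # cm/g = 2500 s settling
                ))
            else:
                regimes.append(ChannelRegime(
                    morphology="mixture", mode="drift",
                    steady_target=tgt,
                    v_start=tgt + (20.0 if tgt < 0 else -20.0),
                    tau_s=2500.0,
                    options={"osc_amp_mv": 0.6, "noise_sigma_mv": 0.1},
                ))
    elif morphology == "control":
        duration = duration_s or 175_000.0
        n = n_channels or 8
        starts = [30.0, -10.0, 15.0, 75.0, -20.0, 25.0, -100.0, 5.0][:n]
        targets = [10.0, -25.0, 0.0, 20.0, -35.0, 8.0, -100.0, -12.0][:n]
        regimes, labels = [], []
        for i in range(n):
            labels.append(f"Ch{chr(ord('A') + i)}")
            regimes.append(ChannelRegime(
                morphology="control", mode="drift",
                steady_target=targets[i % len(targets)],
                v_start=starts[i % len(starts)],
                tau_s=duration / 2.0,
                options={"osc_amp_mv": 0.0, "noise_sigma_mv": 0.25, "noise_tau_s": 2.0},
            ))
    else:
        raise ConfigurationError(f"unknown morphology {morphology!r}")

    return RecordingConfig(
        morphology=morphology,
        duration_s=duration,
        channels=tuple(regimes),
        labels=tuple(labels),
        sample_interval_s=sample_interval_s,
        internal_step_s=internal_step_s,
        modulation=modulation or ModulationFactors(),
    )


def simulate_recording(config: RecordingConfig, seed: int = 0) -> Recording:
    """Compose per-channel simulators into a full multichannel Recording.

    Channel i uses the deterministic child seed ``seed + i`` so channels are
    independent but the whole recording is reproducible bit-for-bit.
    """
    times = np.arange(0.0, config.duration_s + 0.5 * config.sample_interval_s,
                      config.sample_interval_s)
    channels: dict[str, np.ndarray] = {}
    for i, (label, regime) in enumerate(zip(config.labels, config.channels)):
        child = seed + i
        if regime.mode in ("threshold_spiker", "bistable", "pacemaker"):
            trace = simulate_microsphere_channel(
                regime, config.modulation, times, child,
                internal_step=config.internal_step_s,
            )
        else:
            trace = simulate_fiber_channel(regime, times, child)
        channels[label] = trace
        logger.debug("simulated %s (%s/%s)", label, regime.morphology, regime.mode)
    meta = {
        "morphology": config.morphology,
        "seed": seed,
        "internal_step_s": config.internal_step_s,
        "sample_interval_s": config.sample_interval_s,
        "duration_s": config.duration_s,
        "modulation": {
            "ionic_strength_scale": config.modulation.ionic_strength_scale,
            "temperature_c": config.modulation.temperature_c,
            "ph": config.modulation.ph,
            "divalent_mM": config.modulation.divalent_mM,
        },
    }
    return Recording(times=times, channels=channels, meta=meta)
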