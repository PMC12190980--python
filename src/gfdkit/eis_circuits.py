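"""Equivalent-circuit impedance models and electrochemical stream statistics.

The three GFD morphologies map onto three textbook equivalent circuits: a
pure resistor (fibers, Z = R), a series RC (the 50:50 mixture,
Z = R + 1/(jwC)) and a parallel RC (microspheres, Z = R / (1 + jwRC)).
This module synthesizes spectra from those models, fits them back by
complex least squares, extracts the series capacitance Cs = -1/(w Im Z),
and generates / summarizes 1 Hz electrochemical streams (impedance,
capacitance, DC resistance) with the reported per-morphology statistics.

Units: frequency Hz (angular frequency computed internally), impedance Ohm,
capacitance uF, DC resistance mOhm, time s.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .errors import ConfigurationError, InvalidParameterError, UndefinedCapacitanceError

logger = logging.getLogger("gfdkit.eis_circuits")

CIRCUIT_KINDS = ("resistor", "series_rc", "parallel_rc")

#: Reported per-morphology statistics of the 1000 s electrochemical streams:
#: mean/std/min/max/median for impedance (Ohm) and capacitance (uF), plus
#: slope (mOhm/s) for the DC-resistance stream.
STREAM_PROFILES: dict[str, dict] = {
    "fibers": {
        "z_ohm": dict(mean=209.400, std=0.286, min=208.349, max=210.225, median=209.401),
        "cs_uf": dict(mean=9.912, std=0.171, min=9.436, max=10.434, median=9.898),
        "idc_mohm": dict(mean=163067.613, std=9253.064, min=157464.172,
                         max=212725.067, median=159023.422, slope=-26.613),
    },
    "mixture": {
        "z_ohm": dict(mean=404.235, std=1.091, min=400.544, max=408.045, median=404.226),
        "cs_uf": dict(mean=3.328, std=0.076, min=3.062, max=3.601, median=3.326),
        "idc_mohm": dict(mean=60424.487, std=1293.986, min=59054.138,
                         max=67298.653, median=59998.276, slope=-4.707),
    },
    "microspheres": {
        "z_ohm": dict(mean=6646.282, std=178.664, min=6346.610, max=7038.241, median=6620.197),
        "cs_uf": dict(mean=1.926, std=5.735, min=0.633, max=162.514, median=1.452),
        "idc_mohm": dict(mean=15830.739, std=652.514, min=14643.011,
                         max=18024.274, median=16000.094, slope=-2.483),
    },
}


@dataclass(frozen=True)
class CircuitModel:
    """Equivalent circuit: kind plus resistance (Ohm) and capacitance (uF)."""

    kind: str
    r: float
    c: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in CIRCUIT_KINDS:
            raise ConfigurationError(f"unknown circuit kind {self.kind!r}")
        if not self.r > 0:
            raise InvalidParameterError("r must be > 0")
        if self.kind == "resistor":
            if self.c is not None:
                raise InvalidParameterError("a pure resistor has no capacitance")
        else:
            if self.c is None or not self.c > 0:
                raise InvalidParameterError("c must be > 0 for RC circuits")


@dataclass(frozen=True)
class Spectrum:
    """Complex impedance (Ohm) on a strictly increasing frequency grid (Hz)."""

    freqs: np.ndarray
    z: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        z = np.asarray(self.z, dtype=complex)
        if f.shape != z.shape:
            raise InvalidParameterError("freqs/z length mismatch")
        if f.size and not (np.all(f > 0) and np.all(np.diff(f) > 0)):
            raise InvalidParameterError("freqs must be positive and strictly increasing")
        object.__setattr__(self, "freqs", f)
        object.__setattr__(self, "z", z)


@dataclass(frozen=True)
class ElectroTimeSeries:
    """Electrochemical measurement streams (t s, Z Ohm, Cs uF, Idc mOhm)."""

    t: np.ndarray
    z_ohm: np.ndarray
    cs_uf: np.ndarray
    idc_mohm: np.ndarray

    def __post_init__(self) -> None:
        arrays = [np.asarray(a, dtype=float) for a in (self.t, self.z_ohm, self.cs_uf, self.idc_mohm)]
        n = arrays[0].size
        if any(a.size != n for a in arrays):
            raise InvalidParameterError("stream lengths differ")
        if n > 1 and not np.all(np.diff(arrays[0]) > 0):
            raise InvalidParameterError("t must be increasing")
        for name, a in zip(("t", "z_ohm", "cs_uf", "idc_mohm"), arrays):
            object.__setattr__(self, name, a)


@dataclass(frozen=True)
class QuantityStats:
    mean: float
    std: float
    min: float
    max: float
    median: float
    slope: float | None = None

    def __post_init__(self) -> None:
        if not (self.min <= self.median <= self.max):
            raise InvalidParameterError("min <= median <= max violated")


@dataclass(frozen=True)
class SummaryStats:
    """Per-stream descriptive statistics in the reported table layout."""

    z_ohm: QuantityStats
    cs_uf: QuantityStats
    idc_mohm: QuantityStats


@dataclass(frozen=True)
class CircuitFit:
    """Fitted circuit plus residual norm and diagnostic flags."""

    model: CircuitModel | None
    residual_norm: float
    success: bool
    flags: tuple[str, ...] = ()
    message: str = ""


# ---------------------------------------------------------------------------
# Forward models
# ---------------------------------------------------------------------------

def circuit_impedance(model: CircuitModel, freq) -> np.ndarray | complex:
    """Complex impedance of the circuit at frequency ``freq`` (Hz)."""
    f = np.asarray(freq, dtype=float)
    if np.any(f <= 0):
        raise InvalidParameterError("freq must be > 0")
    omega = 2.0 * np.pi * f
    if model.kind == "resistor":
        z = np.broadcast_to(model.r + 0j, f.shape).copy()
    elif model.kind == "parallel_rc":
        c_farad = model.c * 1e-6
        z = model.r / (1.0 + 1j * omega * model.r * c_farad)
    else:  # series_rc
        c_farad = model.c * 1e-6
        z = model.r + 1.0 / (1j * omega * c_farad)
    return z if np.ndim(freq) else complex(z)


def default_freq_grid(n: int = 50, f_min: float = 1.0, f_max: float = 1e6) -> np.ndarray:
    """Log-spaced frequency grid (default 50 points over 1 Hz .. 1 MHz)."""
    return np.logspace(math.log10(f_min), math.log10(f_max), n)


def synth_spectrum(
    model: CircuitModel,
    freqs: np.ndarray | None = None,
    noise_rel: float = 0.0,
    seed: int | None = None,
) -> Spectrum:
    """Forward-model spectrum with optional proportional complex noise."""
    if noise_rel < 0:
        raise InvalidParameterError("noise_rel must be >= 0")
    f = default_freq_grid() if freqs is None else np.asarray(freqs, dtype=float)
    z = np.asarray(circuit_impedance(model, f), dtype=complex)
    if noise_rel > 0:
        rng = np.random.default_rng(seed)
        mag = np.abs(z)
        z = z + noise_rel * mag * (
            rng.standard_normal(f.size) + 1j * rng.standard_normal(f.size)
        )
    return Spectrum(freqs=f, z=z)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _pack_residual(z_model: np.ndarray, z_data: np.ndarray) -> np.ndarray:
    """Stacked real/imag residuals with relative (1/|z|) weighting."""
    w = 1.0 / np.maximum(np.abs(z_data), 1e-300)
    d = (z_model - z_data) * w
    return np.concatenate([d.real, d.imag])


def fit_circuit(
    spectrum: Spectrum,
    kind: str,
    init: CircuitModel | None = None,
) -> CircuitFit:
    """Complex least-squares fit of one circuit kind to a spectrum.

    Initialization: R0 from the low-frequency |Z| (parallel RC, resistor) or
    the high-frequency |Z| (series RC); C0 from the frequency of maximum
    -Im Z.  Parameters are fitted in log space so kilo-ohm and ohm spectra
    behave identically.  A capacitance pinned at its bounds (e.g. when an RC
    model is forced onto a purely resistive spectrum) is flagged.
    """
    if kind not in CIRCUIT_KINDS:
        raise ConfigurationError(f"unknown circuit kind {kind!r}")
    f = spectrum.freqs
    z = spectrum.z
    if kind != "resistor" and f.size < 4:
        raise InvalidParameterError("RC fits need at least 4 frequencies")
    if f.size < 1:
        raise InvalidParameterError("empty spectrum")

    if kind == "resistor":
        # weighted scalar least squares has a closed form on the real part
        r_hat = float(np.mean(np.abs(z)))
        try:
            res = optimize.least_squares(
                lambda p: _pack_residual(np.full(f.size, math.exp(p[0]) + 0j), z),
                [math.log(max(r_hat, 1e-12))],
            )
        except Exception as exc:
            return CircuitFit(None, math.inf, False, message=str(exc))
        model = CircuitModel("resistor", math.exp(float(res.x[0])))
        return CircuitFit(model, float(np.linalg.norm(res.fun)), True)

    if init is not None:
        r0, c0 = init.r, init.c or 1.0
    else:
        neg_im = -z.imag
        k = int(np.argmax(neg_im))
        f_peak = f[k] if neg_im[k] > 0 else math.sqrt(f[0] * f[-1])
        if kind == "parallel_rc":
            r0 = float(np.abs(z[0]))
            c0 = 1e6 / (2 * math.pi * f_peak * r0)
        else:
            r0 = float(np.abs(z[-1]))
            im0 = z.imag[0]
            c0 = (-1e6 / (2 * math.pi * f[0] * im0)) if im0 < 0 else 1.0
    r0 = max(r0, 1e-9)
    c0 = max(c0, 1e-9)

    log_bounds = ([math.log(1e-9), math.log(1e-12)], [math.log(1e12), math.log(1e9)])

    def resid(p):
        model = CircuitModel(kind, math.exp(p[0]), math.exp(p[1]))
        return _pack_residual(np.asarray(circuit_impedance(model, f)), z)

    try:
        res = optimize.least_squares(
            resid, [math.log(r0), math.log(c0)], bounds=log_bounds,
            xtol=1e-15, ftol=1e-15, gtol=1e-15,
        )
    except Exception as exc:
        return CircuitFit(None, math.inf, False, message=str(exc))
    r_fit, c_fit = math.exp(float(res.x[0])), math.exp(float(res.x[1]))
    flags = []
    if c_fit >= math.exp(log_bounds[1][1]) * 0.9 or c_fit <= math.exp(log_bounds[0][1]) * 1.1:
        flags.append("capacitance_at_bound")
    model = CircuitModel(kind, r_fit, c_fit)
    return CircuitFit(model, float(np.linalg.norm(res.fun)), res.success,
                      flags=tuple(flags))


def series_capacitance(z: complex, freq: float) -> float:
    """Series capacitance Cs = -1/(2 pi f Im Z), returned in uF."""
    if freq <= 0:
        raise InvalidParameterError("freq must be > 0")
    im = complex(z).imag
    if im == 0:
        raise UndefinedCapacitanceError("Im Z = 0: series capacitance undefined")
    return -1e6 / (2.0 * math.pi * freq * im)


# ---------------------------------------------------------------------------
# Streams
# ---------------------------------------------------------------------------

def summarize_timeseries(ts: ElectroTimeSeries) -> SummaryStats:
    """Mean/std(ddof=1)/min/max/median per stream; OLS slope for Idc (mOhm/s)."""
    if ts.t.size < 2:
        raise InvalidParameterError("need at least 2 samples")

    def q(a: np.ndarray, slope: bool = False) -> QuantityStats:
        return QuantityStats(
            mean=float(np.mean(a)), std=float(np.std(a, ddof=1)),
            min=float(np.min(a)), max=float(np.max(a)), median=float(np.median(a)),
            slope=float(np.polyfit(ts.t, a, 1)[0]) if slope else None,
        )

    return SummaryStats(z_ohm=q(ts.z_ohm), cs_uf=q(ts.cs_uf), idc_mohm=q(ts.idc_mohm, slope=True))


def _truncated_normal(mean, std, lo, hi, n, rng) -> np.ndarray:
    if std <= 0:
        return np.full(n, float(mean))
    a, b = (lo - mean) / std, (hi - mean) / std
    return stats.truncnorm.rvs(a, b, loc=mean, scale=std, size=n, random_state=rng)


def synth_timeseries(profile: str, n: int = 1000, seed: int | None = None) -> ElectroTimeSeries:
    """Synthesize a 1 Hz electrochemical stream matching a morphology profile.

    Z and Cs are truncated Gaussians at the profile's mean/std clipped to the
    printed min/max; the microsphere Cs stream instead fluctuates tightly
    around its median and adds rare large positive excursions (transient
    charge-buildup spikes, up to the printed 162.514 uF extreme) so the
    median stays low while the mean and max are pulled up.  Idc carries the
    printed linear trend plus residual noise, clipped to the printed range.
    """
    if profile not in STREAM_PROFILES:
        raise ConfigurationError(f"unknown profile {profile!r}; expected one of {list(STREAM_PROFILES)}")
    spec = STREAM_PROFILES[profile]
    rng = np.random.default_rng(seed)
    t = np.arange(n, dtype=float)
    if n == 0:
        empty = np.empty(0)
        return ElectroTimeSeries(empty, empty.copy(), empty.copy(), empty.copy())

    zs = spec["z_ohm"]
    z = _truncated_normal(zs["mean"], zs["std"], zs["min"], zs["max"], n, rng)

    cs_spec = spec["cs_uf"]
    if profile == "microspheres":
        cs = _truncated_normal(cs_spec["median"], 0.35, cs_spec["min"], 3.5, n, rng)
        n_spikes = max(1, n // 250)
        pos = rng.choice(n, size=n_spikes, replace=False)
        cs[pos] = rng.uniform(40.0, cs_spec["max"], n_spikes)
    else:
        cs = _truncated_normal(cs_spec["mean"], cs_spec["std"], cs_spec["min"], cs_spec["max"], n, rng)

    idc_spec = spec["idc_mohm"]
    slope = idc_spec["slope"]
    intercept = idc_spec["mean"] - slope * float(np.mean(t))
    trend_var = slope**2 * float(np.var(t))
    resid_sd = math.sqrt(max(idc_spec["std"] ** 2 - trend_var, (0.01 * idc_spec["std"]) ** 2))
    # The Idc stream is not clipped: a sustained linear trend at the printed
    # slope necessarily exceeds the printed extremes, so the trend (and the
    # mean/std) takes precedence over the min/max for this stream.
    idc = intercept + slope * t + resid_sd * rng.standard_normal(n)

    return ElectroTimeSeries(t=t, z_ohm=z, cs_uf=cs, idc_mohm=idc)
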