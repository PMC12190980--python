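"""Synthetic Raman / UV-Vis spectra and rule-based morphology fingerprints.

Raman: fibers show many sharp bands (strongest at 1000 cm^-1, amide III at
1250, amide I at 1650) on a flat baseline; microspheres show a smooth,
broadened profile with a broad ~350 cm^-1 bump and a continuous intensity
decline from 500 to 2000 cm^-1; the 50:50 mixture is intermediate, with a
step-like increase near 750 cm^-1 and a rising baseline beyond 1700.

UV-Vis: all morphologies share the aromatic pi-pi* absorption edge at
350-375 nm; microspheres add a sharp 410 nm band, a broad 570-630 nm band
and a weak 750 nm feature; fibers decay to low absorbance beyond ~400 nm;
the mixture switches to near-complete transparency beyond ~375 nm.

Peak detection runs on a rolling-ball-corrected spectrum, and the
classifier scores each morphology by the fraction of its expected features
that are present.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

from .errors import ConfigurationError, InvalidParameterError
from .ephys_analysis import MorphologyCall, _resolve_call

logger = logging.getLogger("gfdkit.spectra_fingerprints")

MODALITIES = ("raman", "uvvis")
SPECTRUM_MORPHOLOGIES = ("microspheres", "fibers", "mixture")

#: Gaussian FWHM defaults (axis units) realizing the sharp/broad dichotomy.
FIBER_FWHM = 15.0
MICROSPHERE_FWHM = 80.0
MIXTURE_FWHM = 40.0

#: Rolling-ball baseline window, in axis units.
BASELINE_WINDOW_AXIS = 200.0


@dataclass(frozen=True)
class OpticalSpectrum:
    """Intensity vs wavenumber (cm^-1, Raman) or wavelength (nm, UV-Vis)."""

    axis: np.ndarray
    intensity: np.ndarray
    modality: str

    def __post_init__(self) -> None:
        x = np.asarray(self.axis, dtype=float)
        y = np.asarray(self.intensity, dtype=float)
        if x.shape != y.shape:
            raise InvalidParameterError("axis/intensity length mismatch")
        if x.size > 1 and not np.all(np.diff(x) > 0):
            raise InvalidParameterError("axis must be strictly increasing")
        if self.modality not in MODALITIES:
            raise ConfigurationError(f"unknown modality {self.modality!r}")
        object.__setattr__(self, "axis", x)
        object.__setattr__(self, "intensity", y)

    def value_near(self, x0: float, halfwidth: float = 10.0) -> float:
        """Mean intensity inside [x0 - halfwidth, x0 + halfwidth]."""
        mask = np.abs(self.axis - x0) <= halfwidth
        return float(np.mean(self.intensity[mask])) if mask.any() else 0.0


@dataclass(frozen=True)
class PeakList:
    """Detected peaks: positions (axis units), heights, FWHM widths, prominences."""

    positions: np.ndarray
    heights: np.ndarray
    widths: np.ndarray
    prominences: np.ndarray

    def __post_init__(self) -> None:
        arrays = [np.asarray(a, dtype=float)
                  for a in (self.positions, self.heights, self.widths, self.prominences)]
        if len({a.size for a in arrays}) > 1:
            raise InvalidParameterError("peak attribute lengths differ")
        for name, a in zip(("positions", "heights", "widths", "prominences"), arrays):
            object.__setattr__(self, name, a)

    def __len__(self) -> int:
        return self.positions.size

    def near(self, x0: float, tol: float) -> bool:
        return bool(np.any(np.abs(self.positions - x0) <= tol))


@dataclass(frozen=True)
class FingerprintRules:
    """Expected spectral features per morphology.

    Raman peak positions follow the reported band table (fibers ~500, 650,
    1000, 1250, 1650 cm^-1); tolerances and the sharp/broad width threshold
    separate the fiber and microsphere profiles; UV-Vis rules encode the
    350-375 nm edge, the microsphere 410 / 570-630 / 750 nm bands and the
    mixture's transparency beyond ~400 nm.
    """

    raman_fiber_peaks: tuple[float, ...] = (500.0, 650.0, 1000.0, 1250.0, 1650.0)
    raman_peak_tol: float = 15.0
    sharp_width_max: float = 40.0
    raman_step_position: float = 750.0
    uv_edge_window: tuple[float, float] = (350.0, 375.0)
    uv_micro_bands: tuple[float, ...] = (410.0, 600.0, 750.0)
    uv_band_tol: float = 12.0
    uv_transparency_max: float = 0.02
    uv_transparent_beyond: float = 400.0

    def __post_init__(self) -> None:
        if self.raman_peak_tol <= 0 or self.uv_band_tol <= 0:
            raise InvalidParameterError("tolerances must be > 0")


def _gauss(x: np.ndarray, center: float, fwhm: float, height: float) -> np.ndarray:
    sigma = fwhm / 2.3548200450309493
    return height * np.exp(-0.5 * ((x - center) / sigma) ** 2)


def _sigmoid(x: np.ndarray, center: float, width: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-(x - center) / width))


# ---------------------------------------------------------------------------
# Synthesis
# ---------------------------------------------------------------------------

def synth_optical(
    morphology: str,
    modality: str,
    noise: float = 0.0,
    seed: int | None = None,
    axis: np.ndarray | None = None,
) -> OpticalSpectrum:
    """Synthesize a morphology-specific Raman or UV-Vis spectrum.

    ``noise`` is the relative (fraction of the maximum intensity) sd of
    additive Gaussian noise.  Intensities are arbitrary units, floored at 0.
    """
    if morphology not in SPECTRUM_MORPHOLOGIES:
        raise ConfigurationError(f"unknown morphology {morphology!r}")
    if modality not in MODALITIES:
        raise ConfigurationError(f"unknown modality {modality!r}")

    if modality == "raman":
        x = np.arange(100.0, 2000.0) if axis is None else np.asarray(axis, dtype=float)
        y = np.zeros_like(x)
        if morphology == "fibers":
            y += 0.05
            heights = {500.0: 0.55, 650.0: 0.50, 1000.0: 1.00, 1250.0: 0.70, 1650.0: 0.65}
            for pos, h in heights.items():
                y += _gauss(x, pos, FIBER_FWHM, h)
            for pos, h in ((250.0, 0.30), (850.0, 0.25), (1100.0, 0.28),
                           (1450.0, 0.25), (1750.0, 0.22)):
                y += _gauss(x, pos, FIBER_FWHM, h)
        elif morphology == "microspheres":
            # smooth profile: broad ~350 bump, monotone decline 500 -> 2000
            y += 0.9 * _sigmoid(-x, -500.0, 120.0) + 0.25
            y += np.where(x > 500.0, 0.65 * (2000.0 - x) / 1500.0, 0.65)
            y += _gauss(x, 350.0, 300.0, 0.55)
            y += _gauss(x, 1250.0, MICROSPHERE_FWHM, 0.07)
            y += _gauss(x, 1650.0, MICROSPHERE_FWHM, 0.07)
        else:  # mixture
            y += 0.15 + 0.45 * _sigmoid(x, 750.0, 18.0)          # step near 750
            y += np.where(x > 1700.0, 0.002 * (x - 1700.0), 0.0)  # rising tail
            for pos, h in ((750.0, 0.18), (1250.0, 0.25), (1650.0, 0.22)):
                y += _gauss(x, pos, MIXTURE_FWHM, h)
    else:
        x = np.arange(350.0, 1051.0) if axis is None else np.asarray(axis, dtype=float)
        edge_mid = 365.0
        if morphology == "microspheres":
            y = 1.4 * (1.0 - _sigmoid(x, edge_mid, 6.0)) + 0.12 * (1.0 - _sigmoid(x, 900.0, 80.0))
            y += _gauss(x, 410.0, 12.0, 0.95)
            y += _gauss(x, 600.0, 70.0, 0.45)
            y += _gauss(x, 750.0, 35.0, 0.15)
        elif morphology == "fibers":
            y = 1.4 * (1.0 - _sigmoid(x, edge_mid, 6.0))
            y += 0.10 * np.exp(-(x - 375.0) / 250.0) * _sigmoid(x, 375.0, 4.0)
        else:  # mixture: sharpest cutoff, transparent beyond ~375-400 nm
            y = 1.5 * (1.0 - _sigmoid(x, 372.0, 2.5))
            y += 0.004

    if noise > 0:
        rng = np.random.default_rng(seed)
        y = y + noise * float(np.max(y)) * rng.standard_normal(x.size)
    return OpticalSpectrum(axis=x, intensity=np.maximum(y, 0.0), modality=modality)


# ---------------------------------------------------------------------------
# Peak detection
# ---------------------------------------------------------------------------

def rolling_ball_baseline(spectrum: OpticalSpectrum,
                          window_axis: float = BASELINE_WINDOW_AXIS) -> np.ndarray:
    """Rolling-minimum + smoothing baseline estimate (a 1-D rolling ball)."""
    x, y = spectrum.axis, spectrum.intensity
    step = float(np.median(np.diff(x))) if x.size > 1 else 1.0
    w = max(3, int(round(window_axis / step)) | 1)
    floor = ndimage.minimum_filter1d(y, size=w, mode="nearest")
    return ndimage.uniform_filter1d(floor, size=w, mode="nearest")


def detect_peaks(
    spectrum: OpticalSpectrum,
    prominence_min: float,
    width_max: float | None = None,
    smooth_window: int | None = None,
) -> PeakList:
    """Local maxima above a prominence threshold after baseline subtraction.

    The baseline-corrected signal is lightly Savitzky-Golay smoothed
    (quadratic, ~9 samples by default) before peak picking, which
    suppresses single-sample noise maxima without moving band positions.
    Widths are measured at half prominence and returned in axis units.
    Positions are invariant to constant offsets and uniform scaling of the
    intensity (prominences scale with the data).
    """
    if prominence_min <= 0:
        raise InvalidParameterError("prominence_min must be > 0")
    x, y = spectrum.axis, spectrum.intensity
    corrected = y - rolling_ball_baseline(spectrum)
    if smooth_window is None:
        smooth_window = 9
    if smooth_window >= 5 and corrected.size > smooth_window:
        corrected = signal.savgol_filter(corrected, smooth_window | 1, 2)
    step = float(np.median(np.diff(x))) if x.size > 1 else 1.0
    idx, props = signal.find_peaks(corrected, prominence=prominence_min)
    if idx.size == 0:
        z = np.empty(0)
        return PeakList(z, z.copy(), z.copy(), z.copy())
    widths_samples = signal.peak_widths(corrected, idx, rel_height=0.5)[0]
    widths = widths_samples * step
    keep = np.ones(idx.size, dtype=bool)
    if width_max is not None:
        keep = widths <= width_max
    return PeakList(
        positions=x[idx][keep],
        heights=corrected[idx][keep],
        widths=widths[keep],
        prominences=props["prominences"][keep],
    )


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def _classify_raman(peaks: PeakList, spec: OpticalSpectrum,
                    rules: FingerprintRules) -> dict[str, float]:
    tol = rules.raman_peak_tol
    sharp = peaks.widths <= rules.sharp_width_max if len(peaks) else np.empty(0, dtype=bool)
    n_sharp = int(np.count_nonzero(sharp))

    decline = spec.value_near(600.0, 50.0) - spec.value_near(1900.0, 50.0)
    scale = max(float(np.ptp(spec.intensity)), 1e-12)

    fiber_hits = sum(peaks.near(p, tol) for p in rules.raman_fiber_peaks)
    fibers = (fiber_hits + (n_sharp >= 4)) / (len(rules.raman_fiber_peaks) + 1)

    low_bump = spec.value_near(350.0, 50.0) - spec.value_near(150.0, 30.0)
    micro = (
        (n_sharp <= 2)
        + (decline > 0.15 * scale)
        + (low_bump > 0.0)
    ) / 3.0

    step = spec.value_near(850.0, 80.0) - spec.value_near(600.0, 80.0)
    tail = spec.value_near(1950.0, 40.0) - spec.value_near(1750.0, 40.0)
    mixture = (
        (step > 0.05 * scale)
        + (tail > 0.0)
        + peaks.near(1250.0, 2 * tol)
        + (1 <= n_sharp <= 6)
    ) / 4.0
    return {"fibers": float(fibers), "microspheres": float(micro), "mixture": float(mixture)}


def _classify_uvvis(peaks: PeakList, spec: OpticalSpectrum,
                    rules: FingerprintRules) -> dict[str, float]:
    tol = rules.uv_band_tol
    lo, hi = rules.uv_edge_window
    has_edge = spec.value_near(lo + 3.0, 3.0) > 3.0 * spec.value_near(500.0, 30.0) + 0.05
    beyond = spec.axis > rules.uv_transparent_beyond
    tail_mean = float(np.mean(spec.intensity[beyond])) if beyond.any() else 0.0
    far_peaks = peaks.positions[peaks.positions > 430.0] if len(peaks) else np.empty(0)

    micro = (
        (peaks.near(410.0, max(tol, 8.0)) if len(peaks) else False)
        + (bool(np.any((peaks.positions >= 560.0) & (peaks.positions <= 640.0))) if len(peaks) else False)
        + ((peaks.near(750.0, 25.0)) if len(peaks) else False)
        + (tail_mean > 0.05)
    ) / 4.0

    fibers = (
        has_edge
        + (far_peaks.size == 0)
        + (rules.uv_transparency_max < tail_mean <= 0.2)
    ) / 3.0

    mixture = (
        has_edge
        + (far_peaks.size == 0)
        + (tail_mean <= rules.uv_transparency_max)
    ) / 3.0
    return {"fibers": float(fibers), "microspheres": float(micro), "mixture": float(mixture)}


def classify_spectrum(
    peaks: PeakList,
    spectrum: OpticalSpectrum,
    rules: FingerprintRules | None = None,
) -> MorphologyCall:
    """Score each morphology by its matched expected features and call the winner.

    Scores are fractions of matched features, normalized to sum 1; ties
    break lexicographically.  An empty peak list on a declining profile is
    the microsphere signature (smooth spectral profile).
    """
    rules = rules or FingerprintRules()
    if spectrum.modality == "raman":
        scores = _classify_raman(peaks, spectrum, rules)
    else:
        scores = _classify_uvvis(peaks, spectrum, rules)
    return _resolve_call(scores)


def default_prominence(spectrum: OpticalSpectrum) -> float:
    """Prominence threshold: 4% of the dynamic range, floored at 4x the
    point-to-point noise scale (robust sd of the first difference)."""
    y = spectrum.intensity
    noise_sd = 1.4826 * float(np.median(np.abs(np.diff(y)))) / math.sqrt(2.0) if y.size > 1 else 0.0
    return max(0.04 * float(np.ptp(y)), 4.0 * noise_sd, 1e-9)
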