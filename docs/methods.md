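# Methods

`gfdkit` models the electrical polymorphism of Glu-Phe-Asp (GFD)
proteinoid assemblies: the same tripeptide forms microspheres, fibrillar
networks or 50:50 mixtures, and each morphology carries a distinct
electrophysiological and electrochemical signature. The package has two
halves — forward models that *generate* recordings, spectra and
measurement streams under stated regimes, and analyzers that *measure*
those signatures back out. Because the generators and analyzers are
independent code paths, round trips through both are meaningful tests.

## Voltage models and their assumptions

Channel potentials are extracellular, in mV, sampled at 1 Hz (the data
logger's rate); simulation runs on a finer internal grid (default 0.1 s)
and is decimated to the recording grid. Four elementary processes are
composed:

* **Exponential relaxation** `V(t) = V∞ + ΔV e^(−t/τ)` describes
  channel equilibration; τ is thousands of seconds (diffusion-limited
  electrochemistry, not membrane kinetics).
* **Biexponential spikes**
  `A (e^(−Δt/τ_decay) − e^(−Δt/τ_rise)) H(Δt)`, with τ_rise < τ_decay so
  a positive amplitude is a positive-going spike with fast rise and
  gradual decay. The printed form of this waveform is ambiguous about the
  ordering of the two exponentials; this package fixes the
  decay-minus-rise convention and exposes the alternative as a keyword.
  Generators parameterize spikes by *realized peak height* (the documented
  5–15 mV amplitudes), internally rescaling A by the peak factor of the
  double exponential.
* **Leaky-membrane accumulation** `C_m dV/dt = −g_ion(V−V_eq) + I_ion(t)`
  with a piecewise-constant current schedule; integrated by forward Euler
  (the AR(1) recursion is evaluated exactly via a linear filter, so the
  scheme is bit-reproducible and first-order convergent; steps
  dt ≥ 2C_m/g_ion raise a stability error).
* **Bistable switching** `dV = −αV(V−V1)(V−V2)dt + σ dW` by
  Euler-Maruyama. The cubic drift is stiff far from the wells, so each
  grid step is internally substepped to keep the explicit update inside
  its stability region; noise is applied once per grid step. η(t) is
  Gaussian white noise — the underlying ionic fluctuations are not
  otherwise specified, so Wiener increments are the minimal assumption.

The Nernst-Planck flux `J = −D ∂C/∂r + (zF/RT) D C ∂V/∂r` is evaluated
pointwise only (units documented in code; F = 96485 C/mol,
R = 8.314 J/(mol K) are module constants). No spatial PDE is solved: the
flux enters the story only through timescale arguments, mirroring how the
underlying experiments use it.

## Spike emission

Spike generation in these assemblies is probabilistic, with an absolute
refractory period but no stated emission law. Emission is therefore a
renewal process: inter-spike interval = dead time + Exp(1/rate − dead
time). This makes the *realized* mean rate equal the configured rate
exactly — a thinned Poisson process would not — which matters because the
reported rates (0.1–0.2 Hz transitional, 0.6 Hz pacemaker) are measured
rates. The threshold-spiker dead time is 2 s; the pacemaker uses 1 s,
because a 0.6 Hz train (mean interval 1.67 s) cannot exist under a 2 s
dead time. Count variance is sub-Poisson (CV² ≈ 0.16 at 0.6 Hz), which
sits comfortably inside the Poisson calibration band used in testing.

Environmental modulation (ionic strength, temperature, pH, divalent
cations) multiplies the emission rate by monotone linear clamps, one per
factor, equal to 1 at the defaults (25 °C, pH 7, no divalents, unit ionic
strength). Only the directions of these effects are established; the
linear forms are this package's choice and are deliberately simple.

## Generator regimes (what the synthetic data emulates)

* **Microspheres** (default 180,000 s, 8 channels): three phases with
  boundaries at 2/9 and 2/3 of the duration (40,000 / 120,000 s at full
  length) — high-rate spiking (0.4 Hz emission, 5–15 mV peaks), a
  transitional phase (0.15 Hz), and a late phase (0.05 Hz) in which
  channel baselines fan out over −70..+110 mV. One channel is a bistable
  switcher (±4.5 mV wells around its baseline, i.e. 9 mV swings — the
  observed swing range, slightly narrower than the illustrative ±(−10,+5)
  well example used in the equation-level tests) and one is a 0.6 Hz,
  1–2 mV pacemaker on a wandering baseline near −39 mV.
* **Fibers** (default 360,000 s): banded channels relax from large
  initial transients (up to ±200 mV) into stable polarization bands
  (positive +40..+65, neutral −10..+30, negative −60..−90 mV) with ~1 mV
  ripple; drift mode reproduces the 41→47 mV, ΔV ≈ +6 mV/20,000 s creep
  with 0.5–1 mV micro-oscillations; slow-wave mode produces asymmetric
  quasi-periodic waves (3–5 mV peak-to-peak, troughs every 5,000–10,000 s,
  gradual descent / rapid rise).
* **Mixture** (default 60,000 s, 9 channels): alternating
  microsphere-dominated (low-rate 0.02 Hz, 2–6 mV spikes) and
  fiber-dominated (smooth drift, τ = 2,500 s) channels whose steady
  targets are spread across −38..+43 mV, stabilizing within the
  −40..+45 mV envelope after ~10,000 s.
* **Control** (default 175,000 s): spike-free drifts only — one channel
  declining 75→20 mV, one pinned near −100 mV, the rest drifting gently —
  with near-white 0.25 mV noise.

Spike waveform constants on the internal grid are τ_rise = 0.2 s,
τ_decay = 1 s (threshold spikers) and 0.05/0.15 s (pacemaker). These are
much slower than the millisecond rise times reported from the underlying
chemistry: a 1 Hz logger cannot represent millisecond events, so the
generator preserves what the recordings can carry — counts, amplitudes
and rates — not microscopic rise kinetics. Consequently analysis of
1 Hz data reports τ_rise as censored when it pins at one sample.

Reproducibility: one root seed per recording; channel *i* uses child seed
`seed + i`, so channels are independent but the whole recording is
bit-for-bit reproducible.

What passing tests on these synthetics do **not** show: robustness to
electrode drift and amplifier artifacts, non-stationary noise, spike
waveform diversity beyond the biexponential family, or cross-channel
coupling — real recordings have all of these, the generator none.

## Analysis

**Spike detection** subtracts a 601-sample running median and thresholds
|residual| at k = 5 times the MAD-based noise scale (1.4826 × MAD of the
residual). Events are contiguous supra-threshold runs merged when closer
than the detection refractory (0.4 s). That refractory is deliberately
smaller than the emission dead time: on the 1 Hz grid an event is simply a
contiguous run, while on 10 Hz grids a ≥1 s merge window would fuse a
0.6 Hz pacemaker train. Detection is offset-invariant by construction.

**Fitting** is nonlinear least squares (scipy) with endpoint-derived
initializations: relaxation fits start from the final-10% mean, the first
sample's deviation, and the 1−1/e crossing time; waveform fits run up to
three restarts, are reported in the canonical τ_rise < τ_decay labeling
(the model is invariant under swap + amplitude negation), and return a
failed result object rather than raising on non-convergence. Circuit fits
minimize stacked real/imaginary residuals weighted by 1/|Z| (so Ω and kΩ
spectra behave identically) over log-parameters, with R₀ from the
low-frequency (parallel) or high-frequency (series) |Z| and C₀ from the
frequency of maximum −Im Z; a capacitance pinned at its bounds (e.g.
when an RC model is forced onto a resistive spectrum) is flagged.

**Phase segmentation** computes windowed spike-rate profiles (variance
profiles for spike-free recordings; 5,000 s windows) and applies binary
segmentation. A split counts only if its SSE-reduction gain beats the
99th percentile of gains on permuted profiles (199 permutations, fixed
internal seed, hence deterministic). This permutation calibration is what
keeps exchangeable recordings from acquiring spurious confident
boundaries; a raw gain threshold does not survive small window counts.

**Channel summaries** report the final-window mean (10,000 s default),
the drift between the two most recent windows of length max(10,000 s,
T/8) — i.e. whether the channel is still moving at the end — per-phase
spike rates, range, and a polarization band (positive above +35 mV,
negative below −50 mV; these thresholds bisect the gaps between the
reported fiber bands).

**Morphology classification** turns four soft indicators — spikiness
(mean rate / 0.03 Hz), banding (steady-state spread / 80 mV), terminal
drift (max |drift| / 8 mV) and the spiking-channel fraction — into rule
scores: microspheres ∝ spikiness × banding; fibers ∝ (1−spikiness) ×
banding × (1−drift); mixture ∝ coexistence (4f(1−f)) × envelope
membership; control ∝ (1−spikiness) × drift. Scores are normalized to sum
1 and ties break lexicographically, so an all-zero recording is called
`control`. The scale constants were chosen from the generator regimes'
contrasts (e.g. fiber bands span ≳80 mV, control channels still move
several mV per window at the end); on the 40-recording default panel the
rules classify every recording correctly.

## Electrochemical streams and spectra

Stream synthesis reproduces the per-morphology statistics of the 1,000 s,
1 Hz measurement table. Impedance and capacitance streams are truncated
Gaussians at the printed mean/std/min/max. The microsphere capacitance
stream instead fluctuates tightly around its printed *median* (1.452 μF)
with rare large positive excursions (up to the printed 162.514 μF
extreme, ~1 per 250 samples) — that is the only construction that can
satisfy median ≪ mean ≪ max simultaneously. The DC-resistance stream is a
linear trend at the printed slope plus Gaussian residuals sized so the
total variance matches the printed std; it is not clipped to the printed
extremes because a sustained linear trend at that slope necessarily
exceeds them (for the mixture row the printed std is slightly below the
trend's own spread, so the residual variance is floored at a small
positive value and the realized std slightly exceeds the printed one).
The summarizer reports mean/std(ddof=1)/min/max/median and the OLS slope
of the DC-resistance stream in mΩ/s.

The reported microsphere Bode phase (≈−50° at 1 MHz) is not achievable by
a parallel RC at the tabulated R and C (its corner frequency is ~16 Hz,
so the phase is ≈−90° well below 1 MHz); the package fits the stated
circuit topologies and does not attempt to reproduce that figure-level
phase value.

Optical spectra are sums of Gaussian bands (lineshape unstated in the
source; Gaussian is the conventional default) on morphology-specific
baselines: fiber bands are sharp (FWHM 15 cm⁻¹), microsphere features
broad (80 cm⁻¹), mixture intermediate (40 cm⁻¹). Peak detection subtracts
a rolling-ball baseline (rolling minimum + smoothing, 200 axis-unit
window), lightly Savitzky-Golay smooths (quadratic, 9 samples), and picks
maxima by prominence; the default prominence is 4% of the dynamic range
floored at 4× the point-to-point noise scale, which keeps 2%-noise
spectra from sprouting spurious sharp peaks. Fingerprint classification
counts matched expected features per morphology (band positions ±15 cm⁻¹,
sharp-vs-broad width threshold 40 cm⁻¹, the 750 cm⁻¹ step and rising
tail, the 350–375 nm edge, the 410/570–630/750 nm bands, and <0.02
absorbance transparency beyond 400 nm for the mixture).

## Numerical and scale choices

Desk-scale defaults keep the full suite under half a minute: the
classification panel runs 30,000 s recordings (the phase schedule scales
proportionally), segmentation checks use the full 180,000 s default, EIS
grids are 50 log-spaced points over 1 Hz–1 MHz, and streams are n = 1000.
Fit tolerances are driven to machine precision (xtol/ftol ≈ 1e-14) so
noiseless round trips recover parameters to ≤1e-6 relative.

## Known limitations

* The spike detector assumes spikes occupy a minority of samples; regimes
  above ~0.5 of duty cycle inflate the MAD scale and suppress detection.
* Waveform fitting at 1 Hz cannot resolve sub-sample rise constants
  (reported as censored) and merges spikes closer than the grid allows.
* The classifier is calibrated to the generator's contrasts; real
  recordings with intermediate morphologies will produce soft scores
  rather than crisp calls, and the score magnitudes are not probabilities.
* Circuit fitting covers R, series-RC and parallel-RC only — no
  constant-phase or diffusion (Warburg) elements, so depressed or
  multi-arc Nyquist data will be flagged as poor fits rather than
  modelled.
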