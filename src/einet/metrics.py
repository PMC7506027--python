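"""Summary statistics: spike coherence, firing rates, power spectra.

Spike coherence is the normalized binned cross-correlation of two spike
trains: responses are reduced to 20 ms indicator bins and

    C = sum(X_i X_j) / sqrt(sum(X_i^2) * sum(X_j^2)),

so ``C = 1`` for identical binned trains and ``C = 0`` for bin-disjoint
ones (the square-rooted denominator is what makes these calibration
points exact; note that for *dense* independent trains the expectation
of C is about the per-bin firing probability, not 0, so raw C is
reported without baseline subtraction).  Coherence of a network is the
mean over randomly sampled excitatory pairs.

Single-cell power spectra follow the first-order low-pass response of a
decoupled cell: a Lorentzian envelope ``a^2/(a^2 + w^2)`` multiplying
the flat intrinsic-noise level ``D`` plus a waveform-specific stimulus
term (flat for white-limit noise, an equidistant comb for pulse trains,
an ``n^2``-weighted comb for biphasic pairs, a single line for a
sinusoid).  The half-power point of the noise-only envelope sits at the
rate constant, which is why the faster inhibitory population passes —
and responds to — a wider stimulus band than the excitatory one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
from scipy import signal as sps
from scipy.optimize import brentq

from .simulation import SpikeRaster
from .waveforms import StimulusSpec

__all__ = [
    "CoherenceConfig",
    "SpectrumResult",
    "bin_spikes",
    "coherence_of_trains",
    "spike_coherence",
    "mean_firing_rate",
    "psd_analytic",
    "psd_empirical",
    "half_power_frequency",
]


@dataclass(frozen=True)
class CoherenceConfig:
    bin_ms: float = 20.0
    n_pairs: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bin_ms <= 0:
            raise ValueError("bin_ms must be positive")
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be at least 1")


def bin_spikes(spike_times, bin_ms: float, t0: float, t1: float) -> np.ndarray:
    """Indicator per bin ``[t0 + k*bin, t0 + (k+1)*bin)``; last partial bin dropped."""
    if t1 <= t0:
        raise ValueError("require t1 > t0")
    if bin_ms <= 0:
        raise ValueError("bin_ms must be positive")
    n_bins = int(np.floor((t1 - t0) / bin_ms))
    out = np.zeros(n_bins, dtype=np.uint8)
    t = np.asarray(spike_times, dtype=float)
    t = t[(t >= t0) & (t < t0 + n_bins * bin_ms)]
    if t.size:
        out[((t - t0) // bin_ms).astype(int)] = 1
    return out


def coherence_of_trains(x: np.ndarray, y: np.ndarray) -> float:
    """Normalized cross-correlation of two binned indicator trains."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("binned trains must have equal length")
    denom = np.sqrt(x.sum() * y.sum())  # X^2 = X for indicators
    if denom == 0:
        return 0.0
    return float((x * y).sum() / denom)


def spike_coherence(raster: SpikeRaster, config: CoherenceConfig,
                    window: tuple[float, float]) -> float:
    """Mean pairwise coherence over sampled excitatory pairs.

    Pairs in which either binned train is empty are resampled (they
    carry no normalizable signal); if no occupied train exists at all
    the coherence is 0.  Deterministic given ``config.seed``.
    """
    t0, t1 = window
    if t1 - t0 < 2 * config.bin_ms:
        raise ValueError("window must span at least two bins")
    n_e = raster.n_cells("e")
    if n_e < 2:
        raise ValueError("need at least two excitatory cells")
    rng = np.random.default_rng(config.seed)

    cache: dict[int, np.ndarray] = {}

    def train(cell: int) -> np.ndarray:
        if cell not in cache:
            cache[cell] = bin_spikes(raster.spike_times("e", cell),
                                     config.bin_ms, t0, t1)
        return cache[cell]

    vals = []
    attempts = 0
    max_attempts = 50 * config.n_pairs
    while len(vals) < config.n_pairs and attempts < max_attempts:
        attempts += 1
        i, j = rng.choice(n_e, size=2, replace=False)
        xi, xj = train(int(i)), train(int(j))
        if xi.sum() == 0 or xj.sum() == 0:
            continue
        vals.append(coherence_of_trains(xi, xj))
    if not vals:
        return 0.0
    return float(np.mean(vals))


def mean_firing_rate(raster: SpikeRaster, population: str,
                     window: tuple[float, float]) -> float:
    """Population firing rate in Hz: spikes / (N_pop * window length)."""
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("window length must be positive")
    n = raster.n_cells(population)
    count = raster.count_in(population, t0, t1)
    return count / (n * (t1 - t0) * 1e-3)


@dataclass
class SpectrumResult:
    """Per-frequency power on the grid ``omega_n = 2*pi*n/T``."""

    frequencies: np.ndarray  # Hz
    power_e: np.ndarray
    power_i: np.ndarray | None
    T: float  # observation length, s
    spec: StimulusSpec | None = None
    envelope_e: Callable[[float], float] | None = field(default=None, repr=False)
    envelope_i: Callable[[float], float] | None = field(default=None, repr=False)

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd
        d = {"freq_hz": self.frequencies, "power_e": self.power_e}
        if self.power_i is not None:
            d["power_i"] = self.power_i
        pd.DataFrame(d).to_csv(path, index=False)


def _lorentzian(a: float, omega: np.ndarray) -> np.ndarray:
    return a * a / (a * a + omega * omega)


def _stimulus_term(spec: StimulusSpec, omega: np.ndarray, n: np.ndarray,
                   T: float, D: float, tau_gap: float) -> np.ndarray:
    """Additive spectral content ``D + |S_n|^2`` per waveform family."""
    if spec.family in ("none",):
        return np.full_like(omega, D)
    if spec.family == "ou_noise":
        # white-noise limit: flat level D + D_s
        return np.full_like(omega, D + spec.D_s)
    k = spec.f_s * T  # line index of the repetition frequency
    if abs(k - round(k)) > 1e-9:
        raise ValueError(
            f"f_s*T = {k:g} must be an integer so spectral lines land on "
            "the frequency grid")
    k = int(round(k))
    omega_s = 2.0 * np.pi * spec.f_s
    if spec.family == "sinusoid":
        comb = (n == k).astype(float)  # delta_{n,k}; single off-zero line
        return D + T * spec.S0 ** 2 / 4.0 * comb
    on_comb = (n % k == 0).astype(float)
    comb = 2.0 * on_comb  # delta_{n,lk} + delta_{-n,lk} summed over l
    if spec.family == "pulse":
        return D + T * spec.S0 ** 2 * (omega_s / (4.0 * np.pi) * comb + 1.0 / T) ** 2
    if spec.family == "biphasic":
        return (D + spec.S0 ** 2 * omega_s ** 2 * tau_gap ** 2
                / (4.0 * T) * n.astype(float) ** 2 * comb)
    raise ValueError(f"unsupported family {spec.family!r}")


def psd_analytic(spec: StimulusSpec, a_e: float, a_i: float, D: float,
                 T: float, f_max: float = 500.0,
                 tau_gap: float = 0.002) -> SpectrumResult:
    """Closed-form single-cell power spectrum for both populations.

    Evaluates the family-specific spectral content on the discrete grid
    ``omega_n = 2*pi*n/T`` and multiplies by each population's
    Lorentzian envelope.  ``tau_gap`` (s) is the separation of the two
    phases of a biphasic pair.  Periodic families require ``f_s * T``
    to be an integer so the spectral lines land on grid points.
    """
    if T <= 0:
        raise ValueError("T must be positive")
    n = np.arange(0, int(np.floor(f_max * T)) + 1)
    omega = 2.0 * np.pi * n / T
    content = _stimulus_term(spec, omega, n, T, D, tau_gap)
    power_e = _lorentzian(a_e, omega) * content
    power_i = _lorentzian(a_i, omega) * content

    def _envelope(a: float) -> Callable[[float], float]:
        # smooth (line-free) part of the spectrum: the noise Lorentzian
        level = D + (spec.D_s if spec.family == "ou_noise" else 0.0)
        return lambda w: a * a / (a * a + w * w) * level

    has_lines = spec.family in ("pulse", "biphasic", "sinusoid")
    return SpectrumResult(frequencies=omega / (2.0 * np.pi),
                          power_e=power_e, power_i=power_i, T=T, spec=spec,
                          envelope_e=None if has_lines else _envelope(a_e),
                          envelope_i=None if has_lines else _envelope(a_i))


def psd_empirical(trace, dt_ms: float, n_segments: int = 1) -> SpectrumResult:
    """Averaged periodogram of a trace on the ``omega_n = 2*pi*n/T`` grid.

    Returns a one-sided density per Hz (so that ``sum(power) * df``
    equals the trace variance — Parseval).  For a decoupled cell driven
    by white noise of flat spectral level D this estimates twice the
    closed-form spectrum of :func:`psd_analytic` (one-sided-per-Hz
    versus the symmetric-grid convention); callers comparing the two
    should divide by :data:`EMPIRICAL_TO_ANALYTIC`.
    """
    x = np.asarray(trace, dtype=float)
    if x.size < 2:
        raise ValueError("trace too short")
    fs = 1000.0 / dt_ms
    nperseg = x.size // max(1, n_segments)
    freqs, power = sps.welch(x, fs=fs, window="boxcar", nperseg=nperseg,
                             noverlap=0, detrend="constant",
                             scaling="density")
    T = nperseg / fs
    return SpectrumResult(frequencies=freqs, power_e=power, power_i=None, T=T)


# ratio between psd_empirical's one-sided per-Hz density and the
# closed-form grid convention of psd_analytic, for the same process
EMPIRICAL_TO_ANALYTIC = 2.0


def half_power_frequency(spectrum: SpectrumResult, population: str = "e",
                         w_max: float = 1e6) -> float:
    """Frequency at which the smooth envelope drops to half its zero value.

    For a Lorentzian ``a^2/(a^2+w^2)`` envelope this is exactly the
    rate constant ``a`` (in the same units as ``a``).  Requires a
    noise-only spectrum: comb spectra have no monotone envelope and are
    rejected.
    """
    env = spectrum.envelope_e if population == "e" else spectrum.envelope_i
    if env is None:
        power = spectrum.power_e if population == "e" else spectrum.power_i
        if power is None:
            raise ValueError(f"spectrum has no data for population {population!r}")
        if np.any(np.diff(power) > 0):
            raise ValueError(
                "non-monotone spectrum (stimulus lines present); half-power "
                "is defined on the noise-only envelope")
        omega = 2.0 * np.pi * spectrum.frequencies
        half = 0.5 * power[0]
        k = int(np.searchsorted(-power, -half))
        if k == 0 or k >= len(power):
            raise ValueError("half-power point outside the sampled grid")
        # linear interpolation between the bracketing grid points
        w0, w1 = omega[k - 1], omega[k]
        p0, p1 = power[k - 1], power[k]
        return float(w0 + (half - p0) * (w1 - w0) / (p1 - p0))
    p0 = env(0.0)
    if not np.isfinite(p0) or p0 <= 0:
        raise ValueError("envelope has no finite positive zero-frequency value")
    g = lambda w: env(w) / p0 - 0.5
    return float(brentq(g, 0.0, w_max, xtol=1e-12, rtol=1e-14))
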