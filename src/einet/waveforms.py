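"""Discrete-time global stimulation traces.

Four waveform families are supported, mirroring common open-loop
neurostimulation paradigms:

``pulse``
    Periodic single-step pulses of amplitude ``S0`` (negative ``S0``
    gives an inhibitory pulse train).
``biphasic``
    Charge-balanced pairs: ``+S0`` at each period start and ``-S0`` two
    steps later, so the train has zero net mean.
``sinusoid``
    ``S0 * sin(2*pi*f_s*t)``.
``ou_noise``
    Low-pass-filtered Gaussian noise: an Ornstein-Uhlenbeck process
    ``tau dS/dt = -S + sqrt(2 D_s) eta`` with cutoff ``f_c = 1/tau``,
    zero mean and stationary variance ``D_s * f_c``.

A pulse is the amplitude held for exactly one integration step (the
discrete delta convention ``delta(0) = 1``), not an impulse scaled by
``1/dt``.  Pulse placement uses the rounded integer period
``round((1000/f_s)/dt)`` steps, and the frequency actually realized by
that rounding is what downstream sweeps report.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "StimulusSpec",
    "StimulusTrace",
    "make_pulse_train",
    "make_biphasic_train",
    "make_sinusoid",
    "make_ou_noise",
    "compile_stimulus",
    "waveform_mean",
]

_FAMILIES = ("none", "ou_noise", "pulse", "biphasic", "sinusoid")

# offset of the negative phase of a biphasic pair, in integration steps
BIPHASIC_OFFSET_STEPS = 2


@dataclass(frozen=True)
class StimulusSpec:
    """Waveform family plus its amplitude/frequency/noise parameters."""

    family: str = "none"
    S0: float = 0.0
    f_s: float | None = None   # Hz, periodic families
    D_s: float = 0.0           # ou_noise only
    f_c: float | None = None   # Hz, ou_noise only
    seed: int | None = None    # ou_noise only

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown waveform family {self.family!r}")
        if self.family in ("pulse", "biphasic", "sinusoid"):
            if self.f_s is None or self.f_s <= 0:
                raise ValueError(f"{self.family} requires f_s > 0")
        if self.family == "ou_noise":
            if self.D_s < 0:
                raise ValueError("ou_noise requires D_s >= 0")
            if self.f_c is None or self.f_c <= 0:
                raise ValueError("ou_noise requires f_c > 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusSpec":
        return cls(**d)

    def replace(self, **kwargs) -> "StimulusSpec":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class StimulusTrace:
    """A compiled stimulus: one value per integration step."""

    values: np.ndarray
    dt: float  # ms
    spec: StimulusSpec

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if not np.all(np.isfinite(self.values)):
            raise ValueError("stimulus trace contains non-finite values")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(len(self.values)) * self.dt

    def to_csv(self, path: str | Path) -> None:
        arr = np.column_stack([self.times_ms, self.values])
        np.savetxt(path, arr, delimiter=",", header="time_ms,value", comments="")


def _period_steps(f_s: float, dt: float) -> int:
    period_ms = 1000.0 / f_s
    if period_ms < dt:
        raise ValueError(
            f"period {period_ms:g} ms of f_s={f_s:g} Hz is shorter than dt={dt:g} ms")
    return max(1, int(round(period_ms / dt)))


def realized_frequency(f_s: float, dt: float) -> float:
    """Frequency actually produced by integer-period rounding (Hz)."""
    return 1000.0 / (_period_steps(f_s, dt) * dt)


def make_pulse_train(spec: StimulusSpec, n_steps: int, dt: float) -> StimulusTrace:
    """Amplitude ``S0`` on exactly one step per period, zero elsewhere."""
    if spec.family != "pulse":
        raise ValueError("spec.family must be 'pulse'")
    period = _period_steps(spec.f_s, dt)
    values = np.zeros(n_steps)
    values[np.arange(0, n_steps, period)] = spec.S0
    return StimulusTrace(values, dt, spec)


def make_biphasic_train(spec: StimulusSpec, n_steps: int, dt: float) -> StimulusTrace:
    """``+S0`` at period starts and ``-S0`` two steps later (zero net mean)."""
    if spec.family != "biphasic":
        raise ValueError("spec.family must be 'biphasic'")
    period = _period_steps(spec.f_s, dt)
    if period < BIPHASIC_OFFSET_STEPS + 1:
        raise ValueError(
            f"period of {period} steps cannot host a biphasic pulse pair")
    values = np.zeros(n_steps)
    starts = np.arange(0, n_steps, period)
    values[starts] += spec.S0
    neg = starts + BIPHASIC_OFFSET_STEPS
    values[neg[neg < n_steps]] -= spec.S0
    return StimulusTrace(values, dt, spec)


def make_sinusoid(spec: StimulusSpec, n_steps: int, dt: float) -> StimulusTrace:
    """``S0*sin(2*pi*f_s*t)`` sampled at ``t = k*dt``."""
    if spec.family != "sinusoid":
        raise ValueError("spec.family must be 'sinusoid'")
    t = np.arange(n_steps) * dt * 1e-3  # s
    values = spec.S0 * np.sin(2.0 * np.pi * spec.f_s * t)
    return StimulusTrace(values, dt, spec)


def make_ou_noise(spec: StimulusSpec, n_steps: int, dt: float,
                  rng: np.random.Generator | None = None) -> StimulusTrace:
    """Stationary Ornstein-Uhlenbeck trace with variance ``D_s * f_c``.

    Uses the exact discretization (exponential decay factor plus an
    exact-variance Gaussian increment), which is free of time-step bias
    in the stationary variance.  Reproducible given ``spec.seed`` (or a
    caller-supplied generator, which takes precedence).
    """
    if spec.family != "ou_noise":
        raise ValueError("spec.family must be 'ou_noise'")
    tau = 1.0 / spec.f_c  # s
    dt_s = dt * 1e-3
    if dt_s >= tau:
        raise ValueError(
            f"dt={dt:g} ms is not smaller than tau={tau * 1e3:g} ms; "
            "the cutoff is unresolvable at this step")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    var = spec.D_s * spec.f_c
    alpha = np.exp(-dt_s / tau)
    sigma_step = np.sqrt(var * (1.0 - alpha * alpha))
    z = rng.standard_normal(n_steps)
    values = np.empty(n_steps)
    s = np.sqrt(var) * z[0]  # stationary initial condition
    values[0] = s
    for n in range(1, n_steps):
        s = alpha * s + sigma_step * z[n]
        values[n] = s
    return StimulusTrace(values, dt, spec)


def make_ou_noise_euler(spec: StimulusSpec, n_steps: int, dt: float,
                        rng: np.random.Generator | None = None) -> StimulusTrace:
    """Plain Euler-Maruyama variant of :func:`make_ou_noise`.

    Kept as a cross-check: it carries an O(dt/tau) bias in the
    stationary variance that the exact discretization does not.
    """
    if spec.family != "ou_noise":
        raise ValueError("spec.family must be 'ou_noise'")
    tau = 1.0 / spec.f_c
    dt_s = dt * 1e-3
    if dt_s >= tau:
        raise ValueError("dt must be smaller than tau")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    z = rng.standard_normal(n_steps)
    values = np.empty(n_steps)
    s = np.sqrt(spec.D_s * spec.f_c) * z[0]
    values[0] = s
    coef = np.sqrt(2.0 * spec.D_s * dt_s) / tau
    for n in range(1, n_steps):
        s = s + dt_s / tau * (-s) + coef * z[n]
        values[n] = s
    return StimulusTrace(values, dt, spec)


def compile_stimulus(spec: StimulusSpec, n_steps: int, dt: float,
                     rng: np.random.Generator | None = None) -> StimulusTrace:
    """Compile a :class:`StimulusSpec` into a trace of ``n_steps`` values."""
    if spec.family == "none":
        return StimulusTrace(np.zeros(n_steps), dt, spec)
    if spec.family == "pulse":
        return make_pulse_train(spec, n_steps, dt)
    if spec.family == "biphasic":
        return make_biphasic_train(spec, n_steps, dt)
    if spec.family == "sinusoid":
        return make_sinusoid(spec, n_steps, dt)
    if spec.family == "ou_noise":
        return make_ou_noise(spec, n_steps, dt, rng)
    raise ValueError(f"unknown family {spec.family!r}")


def waveform_mean(trace: StimulusTrace) -> float:
    """Time-average ``mu_s`` of the trace (the drive offset it adds)."""
    if len(trace) == 0:
        raise ValueError("empty stimulus trace")
    return float(np.mean(trace.values))
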