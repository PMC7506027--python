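"""Model constants and the instantaneous firing-probability function.

The network couples an excitatory and an inhibitory population of
stochastic rate neurons.  Each cell carries a membrane-like activity
variable ``u`` that relaxes with rate constant ``a`` towards the sum of
its synaptic, baseline and stimulation inputs, and emits spikes as a
Bernoulli process with per-step probability ``f[u]``, where ``f`` is a
sharp sigmoid.  All model symbols live in :class:`NetworkParams`, which
is the single source of truth shared by the spiking simulator and the
mean-field analysis.

Units
-----
Rate constants ``a_e``, ``a_i`` are in Hz, the integration step ``dt``
in milliseconds; internal time arithmetic converts to seconds once (see
:attr:`NetworkParams.dt_s`).  Membrane activity, synaptic weights and
drives are dimensionless "membrane units".  The intrinsic noise variance
``D`` is expressed so that a decoupled cell's stationary membrane
variance equals ``D`` (see :mod:`einet.simulation`).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from scipy.special import expit

__all__ = [
    "NetworkParams",
    "Protocol",
    "firing_prob",
    "firing_prob_slope",
]

@dataclass(frozen=True)
class NetworkParams:
    """All constants of the two-population network.

    Defaults are the reference parameter set of the model: an 800/200
    excitatory/inhibitory network with strong E->I coupling, strong
    I->E feedback and weak I->I self-inhibition.  Inhibitory weights
    carry their sign in the value: the simulator adds weighted spike
    counts without extra negation.
    """

    N_e: int = 800
    N_i: int = 200
    beta: float = 300.0
    h: float = 0.0
    a_e: float = 100.0
    a_i: float = 200.0
    w_ee: float = 1.60
    w_ei: float = 3.00
    w_ie: float = -4.70
    w_ii: float = -0.13
    I_e: float = -0.25
    I_i: float = -0.50
    D: float = 0.01
    dt: float = 1.0  # ms

    def __post_init__(self) -> None:
        if self.N_e <= 0 or self.N_i <= 0:
            raise ValueError("population sizes must be positive")
        if self.a_e <= 0 or self.a_i <= 0:
            raise ValueError("rate constants must be positive")
        if self.beta <= 0:
            raise ValueError("sigmoid gain beta must be positive")
        if self.dt <= 0:
            raise ValueError("integration step dt must be positive")
        if self.D < 0:
            raise ValueError("noise variance D must be nonnegative")
        for name in ("beta", "h", "a_e", "a_i", "w_ee", "w_ei", "w_ie",
                     "w_ii", "I_e", "I_i", "D", "dt"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"parameter {name} must be finite")

    @property
    def dt_s(self) -> float:
        """Integration step in seconds."""
        return self.dt * 1e-3

    def replace(self, **kwargs) -> "NetworkParams":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkParams":
        return cls(**d)

    def save(self, path: str | Path) -> None:
        """Write the parameters as a flat YAML mapping (symbol -> value)."""
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path: str | Path) -> "NetworkParams":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass(frozen=True)
class Protocol:
    """Timing of a simulation run and of the tonic-drive step.

    The tonic excitatory drive is ``Io_pre`` before ``t_step`` and
    ``Io_post`` afterwards.  ``burn_in`` is discarded before any
    measurement; metrics use the final ``measure_window`` milliseconds
    of each epoch.
    """

    t_total: float = 2000.0  # ms
    t_step: float = 1000.0   # ms
    Io_pre: float = 0.0
    Io_post: float = 0.1
    burn_in: float = 500.0   # ms
    measure_window: float = 800.0  # ms
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.t_step <= self.t_total:
            raise ValueError("require 0 <= t_step <= t_total")
        if not self.burn_in < self.t_step:
            raise ValueError("burn_in must precede the drive step")
        if self.measure_window > self.t_total - self.t_step:
            raise ValueError("measure_window exceeds the post-step epoch")

    def n_steps(self, dt: float) -> int:
        return int(round(self.t_total / dt))

    def step_index(self, dt: float) -> int:
        return int(round(self.t_step / dt))

    def replace(self, **kwargs) -> "Protocol":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "Protocol":
        return cls(**d)


def firing_prob(u, params: NetworkParams | None = None, *,
                beta: float | None = None, h: float | None = None):
    """Instantaneous firing probability ``f[u] = 1/(1+exp(-beta(u-h)))``.

    Strictly increasing in ``u``, mapping the real line onto (0, 1);
    evaluated through the numerically exact logistic, which saturates
    cleanly to 0.0/1.0 in the float tails.  Accepts scalars or arrays.
    ``beta``/``h`` override the values in ``params`` (both default to
    the reference parameter set).
    """
    if params is None:
        params = NetworkParams()
    b = params.beta if beta is None else beta
    th = params.h if h is None else h
    out = expit(b * (np.asarray(u, dtype=float) - th))
    return float(out) if np.isscalar(u) or np.ndim(u) == 0 else out


def firing_prob_slope(u, params: NetworkParams | None = None, *,
                      beta: float | None = None, h: float | None = None):
    """Analytic derivative ``f'[u] = beta * f * (1 - f)``."""
    if params is None:
        params = NetworkParams()
    b = params.beta if beta is None else beta
    fval = firing_prob(u, params, beta=beta, h=h)
    return b * fval * (1.0 - fval)
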