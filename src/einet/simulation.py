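"""Stochastic spiking simulation of the two-population network.

Each cell's membrane activity follows an Euler-Maruyama update

    u <- u + a*dt*(-u + syn + I + I_o(t) + S(t)) + sqrt(2*a*D*dt) * z

with ``z`` an independent standard normal per cell and step, and emits a
spike with probability ``f[u]`` (per-step Bernoulli).  A spike
contributes exactly 1 to the next step's synaptic sum, so the
time-average of a cell's spike indicator equals the time-average of
``f[u]`` — the diffusion approximation under which the mean-field
reduction of :mod:`einet.meanfield` follows without extra constants.

The noise increment ``sqrt(2*a*D*dt)`` makes the stationary membrane
variance of a decoupled cell equal ``D`` for both populations,
matching the deviation law ``N(0, D)`` used by the mean-field transfer
functions (see ``docs/methods.md`` for why this calibration, rather
than a rate-scaled variance, is the one consistent with the model's
bifurcation structure).

Coupling is homogeneous all-to-all (self-connections included): the
synaptic drive to every excitatory cell is
``w_ee * (E spike count)/N_e + w_ie * (I spike count)/N_i`` and
analogously for inhibitory cells, with the signed weights used as-is.
The tonic drive ``I_o(t)`` enters the excitatory equation only; the
global stimulus ``S(t)`` enters both.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .model import NetworkParams, Protocol, firing_prob
from .waveforms import StimulusSpec, StimulusTrace, compile_stimulus

__all__ = ["SpikeRaster", "SimResult", "simulate", "population_mean_traces"]

# refuse to allocate more than this for optional per-cell traces
DEFAULT_TRACE_MEMORY_CAP_BYTES = 2 * 1024**3


@dataclass
class SpikeRaster:
    """Spike times of every cell, stored as parallel step/cell arrays."""

    dt: float  # ms
    n_e: int
    n_i: int
    steps_e: np.ndarray  # step index of each excitatory spike
    cells_e: np.ndarray  # cell index of each excitatory spike
    steps_i: np.ndarray
    cells_i: np.ndarray

    def _pop(self, population: str) -> tuple[np.ndarray, np.ndarray, int]:
        if population == "e":
            return self.steps_e, self.cells_e, self.n_e
        if population == "i":
            return self.steps_i, self.cells_i, self.n_i
        raise ValueError("population must be 'e' or 'i'")

    def n_cells(self, population: str) -> int:
        return self._pop(population)[2]

    def spike_times(self, population: str, cell: int) -> np.ndarray:
        """Sorted spike times (ms) of one cell."""
        steps, cells, n = self._pop(population)
        if not 0 <= cell < n:
            raise IndexError(f"cell {cell} out of range for population {population!r}")
        return np.sort(steps[cells == cell]) * self.dt

    def count_in(self, population: str, t0: float, t1: float) -> int:
        """Total spikes of a population in the window [t0, t1) ms."""
        steps, _, _ = self._pop(population)
        t = steps * self.dt
        return int(np.count_nonzero((t >= t0) & (t < t1)))

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("cell_id\tpopulation\tspike_time_ms\n")
            for steps, cells, pop in ((self.steps_e, self.cells_e, "e"),
                                      (self.steps_i, self.cells_i, "i")):
                for s, c in zip(steps, cells):
                    fh.write(f"{c}\t{pop}\t{s * self.dt:g}\n")


@dataclass
class SimResult:
    """Full output of one simulation run."""

    u_e_mean: np.ndarray
    u_i_mean: np.ndarray
    raster: SpikeRaster
    stimulus: StimulusTrace
    params: NetworkParams
    protocol: Protocol
    seed: int
    u_e_cells: np.ndarray | None = field(default=None, repr=False)
    u_i_cells: np.ndarray | None = field(default=None, repr=False)

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(len(self.u_e_mean)) * self.params.dt

    def traces_to_csv(self, path: str | Path) -> None:
        arr = np.column_stack([self.times_ms, self.u_e_mean, self.u_i_mean,
                               self.stimulus.values])
        np.savetxt(path, arr, delimiter=",",
                   header="time_ms,u_e_mean,u_i_mean,stimulus", comments="")


def simulate(params: NetworkParams, protocol: Protocol,
             stim: StimulusSpec | None = None, *,
             u0_e=None, u0_i=None,
             keep_cell_traces: bool = False,
             memory_cap_bytes: int = DEFAULT_TRACE_MEMORY_CAP_BYTES) -> SimResult:
    """Integrate the network for ``protocol.t_total`` ms.

    Bitwise reproducible for fixed ``(params, protocol, stim)``: the
    protocol seed spawns one generator per population plus one for the
    stimulus, and all draws are vectorized in fixed cell order.
    ``u0_e``/``u0_i`` override the default stationary initial
    conditions (scalar or per-cell array).
    """
    if stim is None:
        stim = StimulusSpec(family="none")
    dt_s = params.dt_s
    for a, pop in ((params.a_e, "a_e"), (params.a_i, "a_i")):
        if a * dt_s >= 1.0:
            raise ValueError(
                f"dt*{pop} = {a * dt_s:g} >= 1: explicit scheme unstable")
    n_steps = protocol.n_steps(params.dt)
    step_idx = protocol.step_index(params.dt)

    if keep_cell_traces:
        need = 8 * n_steps * (params.N_e + params.N_i)
        if need > memory_cap_bytes:
            raise MemoryError(
                f"per-cell traces need {need} bytes > cap {memory_cap_bytes}")

    ss = np.random.SeedSequence(protocol.seed)
    child_e, child_i, child_s = ss.spawn(3)
    rng_e = np.random.default_rng(child_e)
    rng_i = np.random.default_rng(child_i)
    rng_s = np.random.default_rng(child_s)

    stim_trace = compile_stimulus(stim, n_steps, params.dt, rng_s)
    S = stim_trace.values

    a_e, a_i = params.a_e, params.a_i
    # per-step noise scale 2*a*D*dt with the finite-step factor
    # (1 - a*dt/2) removing the Euler bias, so the stationary deviation
    # variance of a decoupled cell is exactly D at any step size
    sig_e = np.sqrt(2.0 * a_e * params.D * dt_s * (1.0 - a_e * dt_s / 2.0))
    sig_i = np.sqrt(2.0 * a_i * params.D * dt_s * (1.0 - a_i * dt_s / 2.0))
    sqrtD = np.sqrt(params.D)

    # stationary initial conditions for the deviation law N(0, D)
    u_e = (sqrtD * rng_e.standard_normal(params.N_e) if u0_e is None
           else np.broadcast_to(np.asarray(u0_e, dtype=float),
                                (params.N_e,)).copy())
    u_i = (sqrtD * rng_i.standard_normal(params.N_i) if u0_i is None
           else np.broadcast_to(np.asarray(u0_i, dtype=float),
                                (params.N_i,)).copy())
    sp_e = rng_e.random(params.N_e) < firing_prob(u_e, params)
    sp_i = rng_i.random(params.N_i) < firing_prob(u_i, params)

    u_e_mean = np.empty(n_steps)
    u_i_mean = np.empty(n_steps)
    steps_e: list[np.ndarray] = []
    cells_e: list[np.ndarray] = []
    steps_i: list[np.ndarray] = []
    cells_i: list[np.ndarray] = []
    if keep_cell_traces:
        u_e_cells = np.empty((n_steps, params.N_e))
        u_i_cells = np.empty((n_steps, params.N_i))

    for n in range(n_steps):
        # spikes emitted at step n-1 drive step n
        frac_e = sp_e.sum() / params.N_e
        frac_i = sp_i.sum() / params.N_i
        syn_e = params.w_ee * frac_e + params.w_ie * frac_i
        syn_i = params.w_ei * frac_e + params.w_ii * frac_i
        Io = protocol.Io_pre if n < step_idx else protocol.Io_post
        u_e = (u_e + a_e * dt_s * (-u_e + syn_e + params.I_e + Io + S[n])
               + sig_e * rng_e.standard_normal(params.N_e))
        u_i = (u_i + a_i * dt_s * (-u_i + syn_i + params.I_i + S[n])
               + sig_i * rng_i.standard_normal(params.N_i))
        sp_e = rng_e.random(params.N_e) < firing_prob(u_e, params)
        sp_i = rng_i.random(params.N_i) < firing_prob(u_i, params)

        u_e_mean[n] = u_e.mean()
        u_i_mean[n] = u_i.mean()
        if keep_cell_traces:
            u_e_cells[n] = u_e
            u_i_cells[n] = u_i
        idx = np.nonzero(sp_e)[0]
        if idx.size:
            steps_e.append(np.full(idx.size, n, dtype=np.int64))
            cells_e.append(idx.astype(np.int64))
        idx = np.nonzero(sp_i)[0]
        if idx.size:
            steps_i.append(np.full(idx.size, n, dtype=np.int64))
            cells_i.append(idx.astype(np.int64))

    def _cat(parts):
        return np.concatenate(parts) if parts else np.empty(0, dtype=np.int64)

    raster = SpikeRaster(dt=params.dt, n_e=params.N_e, n_i=params.N_i,
                         steps_e=_cat(steps_e), cells_e=_cat(cells_e),
                         steps_i=_cat(steps_i), cells_i=_cat(cells_i))
    return SimResult(u_e_mean=u_e_mean, u_i_mean=u_i_mean, raster=raster,
                     stimulus=stim_trace, params=params, protocol=protocol,
                     seed=protocol.seed,
                     u_e_cells=u_e_cells if keep_cell_traces else None,
                     u_i_cells=u_i_cells if keep_cell_traces else None)


def population_mean_traces(result: SimResult,
                           window: tuple[float, float]) -> tuple[float, float]:
    """Time-and-population average of u over a window [t0, t1) in ms."""
    t0, t1 = window
    dt = result.params.dt
    i0, i1 = int(round(t0 / dt)), int(round(t1 / dt))
    if not 0 <= i0 < i1 <= len(result.u_e_mean):
        raise ValueError(f"window {window} outside the simulation or empty")
    return (float(result.u_e_mean[i0:i1].mean()),
            float(result.u_i_mean[i0:i1].mean()))
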