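"""Stochastic mean-field reduction and stability analysis.

Averaging the spiking network over cells and over the fast fluctuations
yields a two-dimensional system for the population means
``(u_e, u_i)``.  The sigmoid of each cell is replaced by the *effective
transfer function* — the sigmoid convolved with the stationary Gaussian
law of the noise-driven membrane deviations:

    F[u] = E_v f[u + v],   v ~ N(0, Dbar).

For a sharp sigmoid this convolution is the Gaussian CDF
``F[u] = (1 + erf(u / sqrt(2 Dbar))) / 2``; noise therefore *linearizes*
the response, and large enough ``Dbar`` removes the fold (saddle-node
pair) responsible for multistability and abrupt, seizure-like jumps.

Steady states solve

    u_e = w_ee F_e[u_e] + w_ie F_i[u_i] + I_e + I_o
    u_i = w_ei F_e[u_e] + w_ii F_i[u_i] + I_i

and their stability follows from the rate-scaled Jacobian

    J = [[a_e(-1 + w_ee R_e),  a_e w_ie R_i],
         [a_i w_ei R_e,        a_i(-1 + w_ii R_i)]]

with ``R = F'`` evaluated at the steady state.  Eigenvalues are
computed both in closed form and by direct eigendecomposition; any
disagreement is a hard error (an implementation bug trap, since the
two must be identical).

Deviation variances
-------------------
The intrinsic deviation variance is ``Dbar = D`` for both populations,
matching the simulator's noise calibration (see ``docs/methods.md``).
A global low-pass-noise stimulus with variance parameter ``D_s`` and
cutoff ``f_c`` adds ``a * D_s * f_c / (a + f_c)``: the white-noise
limit ``f_c -> infinity`` gives the maximal extra variance ``a * D_s``
while ``f_c -> 0`` contributes nothing.  Periodic stimuli enter the
mean-field only through their time-average ``mu_s`` as a common drive
offset; their effect beyond that is studied by direct simulation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from scipy.optimize import brentq
from scipy.special import erf

from .model import NetworkParams, firing_prob

__all__ = [
    "EffectiveNoise",
    "Equilibrium",
    "BifurcationDiagram",
    "effective_noise_variance",
    "deviation_variance",
    "effective_transfer",
    "effective_transfer_slope",
    "effective_transfer_quad",
    "find_equilibria",
    "closed_form_eigenvalues",
    "linear_stability",
    "bifurcation_sweep",
]

RESIDUAL_TOL = 1e-10
MERGE_TOL = 1e-6
EIG_AGREE_RTOL = 1e-9


def effective_noise_variance(a: float, D: float, D_s: float = 0.0,
                             f_c: float = 0.0) -> float:
    """Rate-scaled effective variance ``a*D + a*D_s*f_c/(a + f_c)``.

    This is the variance of the membrane deviations when the
    continuous-time intrinsic noise enters the rate-normalized equation
    as white noise of variance ``D`` (stationary variance ``a*D``),
    plus the exact contribution of a global Ornstein-Uhlenbeck stimulus
    low-pass filtered by the membrane.  With ``D_s = 0`` it reduces to
    ``a*D``.
    """
    if a <= 0:
        raise ValueError("rate constant must be positive")
    if D < 0 or D_s < 0 or f_c < 0:
        raise ValueError("variances and cutoff must be nonnegative")
    extr = a * D_s * f_c / (a + f_c) if f_c > 0 else 0.0
    return a * D + extr


def deviation_variance(a: float, D: float, D_s: float = 0.0,
                       f_c: float = 0.0) -> float:
    """Deviation variance matching the simulator's noise calibration.

    The simulator's intrinsic increments give a stationary membrane
    variance of ``D`` for both populations; the extrinsic-noise term is
    the same membrane-filtered Ornstein-Uhlenbeck contribution as in
    :func:`effective_noise_variance`.  This is the variance the
    equilibrium and stability computations use.
    """
    if a <= 0:
        raise ValueError("rate constant must be positive")
    if D < 0 or D_s < 0 or f_c < 0:
        raise ValueError("variances and cutoff must be nonnegative")
    extr = a * D_s * f_c / (a + f_c) if f_c > 0 else 0.0
    return D + extr


@dataclass(frozen=True)
class EffectiveNoise:
    """Per-population deviation variances entering the smoothed transfer."""

    Dbar_e: float
    Dbar_i: float

    def __post_init__(self) -> None:
        if self.Dbar_e <= 0 or self.Dbar_i <= 0:
            raise ValueError("effective variances must be positive")

    @classmethod
    def from_network(cls, params: NetworkParams, D_s: float = 0.0,
                     f_c: float = 0.0) -> "EffectiveNoise":
        return cls(deviation_variance(params.a_e, params.D, D_s, f_c),
                   deviation_variance(params.a_i, params.D, D_s, f_c))


def effective_transfer(u, Dbar: float):
    """Noise-smoothed transfer ``F[u] = (1 + erf(u/sqrt(2 Dbar)))/2``."""
    if Dbar <= 0:
        raise ValueError("Dbar must be positive")
    return 0.5 * (1.0 + erf(np.asarray(u, dtype=float) / np.sqrt(2.0 * Dbar)))


def effective_transfer_slope(u, Dbar: float):
    """Slope ``R[u] = F'[u]``: the normal density with variance Dbar."""
    if Dbar <= 0:
        raise ValueError("Dbar must be positive")
    u = np.asarray(u, dtype=float)
    return np.exp(-u * u / (2.0 * Dbar)) / np.sqrt(2.0 * np.pi * Dbar)


def effective_transfer_quad(u, Dbar: float, beta: float = 300.0,
                            n_nodes: int = 200):
    """Finite-gain transfer by direct quadrature of the convolution.

    Integrates the logistic sigmoid of gain ``beta`` against
    ``N(0, Dbar)`` with composite Gauss-Legendre panels split at the
    sigmoid's transition layer (whose width ``~1/beta`` would otherwise
    defeat any fixed global rule); converges to
    :func:`effective_transfer` as ``beta -> infinity``.  Serves as the
    independent oracle for the closed form.
    """
    if Dbar <= 0:
        raise ValueError("Dbar must be positive")
    nodes, weights = np.polynomial.legendre.leggauss(n_nodes)  # on [-1, 1]
    sigma = np.sqrt(Dbar)
    L = 10.0 * sigma
    layer = 80.0 / beta  # transition-layer half-width to isolate
    u = np.atleast_1d(np.asarray(u, dtype=float))
    out = np.empty(u.shape)
    norm = 1.0 / np.sqrt(2.0 * np.pi * Dbar)
    for k, uk in enumerate(u):
        t = -uk  # the sigmoid of f[u+v] switches at v = -u
        brk = np.unique(np.clip([-L, t - layer, t + layer, L], -L, L))
        total = 0.0
        for a, b in zip(brk[:-1], brk[1:]):
            if b <= a:
                continue
            v = 0.5 * (b - a) * nodes + 0.5 * (a + b)
            g = (firing_prob(uk + v, beta=beta, h=0.0)
                 * norm * np.exp(-v * v / (2.0 * Dbar)))
            total += 0.5 * (b - a) * np.dot(weights, g)
        out[k] = total
    return out if out.size > 1 else float(out[0])


@dataclass
class Equilibrium:
    """A mean-field steady state with its linear-stability annotation."""

    u_e: float
    u_i: float
    I_o: float
    stability: str = "unknown"  # "stable" | "unstable"
    damping: float = np.nan     # Re(lambda), 1/s
    eigfreq: float = np.nan     # |Im(lambda)|, rad/s

    @property
    def eigfreq_hz(self) -> float:
        return self.eigfreq / (2.0 * np.pi)


def _solve_u_i(u_e: float, params: NetworkParams, noise: EffectiveNoise,
               xtol: float = 1e-14) -> float:
    """Unique root of the inhibitory steady-state equation at fixed u_e.

    With ``w_ii <= 0`` the map ``u_i - w_ii F_i[u_i]`` is strictly
    increasing, so the root is unique and bracketed by
    ``[rhs + w_ii, rhs]``.
    """
    rhs = params.w_ei * float(effective_transfer(u_e, noise.Dbar_e)) + params.I_i
    lo = rhs + min(params.w_ii, 0.0) - 1e-9
    hi = rhs + max(-params.w_ii, 0.0) + 1e-9

    def g(u_i: float) -> float:
        return u_i - params.w_ii * float(effective_transfer(u_i, noise.Dbar_i)) - rhs

    return brentq(g, lo, hi, xtol=xtol)


def _solve_u_i_grid(u_e: np.ndarray, params: NetworkParams,
                    noise: EffectiveNoise) -> np.ndarray:
    """Vectorized Newton version of :func:`_solve_u_i` for dense scans."""
    rhs = params.w_ei * effective_transfer(u_e, noise.Dbar_e) + params.I_i
    u_i = rhs + 0.5 * params.w_ii
    for _ in range(100):
        g = u_i - params.w_ii * effective_transfer(u_i, noise.Dbar_i) - rhs
        gp = 1.0 - params.w_ii * effective_transfer_slope(u_i, noise.Dbar_i)
        step = g / gp
        u_i = u_i - step
        if np.max(np.abs(step)) < 1e-13:
            break
    return u_i


def _scalar_residual(u_e: float, I_o: float, params: NetworkParams,
                     noise: EffectiveNoise) -> float:
    u_i = _solve_u_i(u_e, params, noise)
    return (params.w_ee * float(effective_transfer(u_e, noise.Dbar_e))
            + params.w_ie * float(effective_transfer(u_i, noise.Dbar_i))
            + params.I_e + I_o - u_e)


def _default_range(params: NetworkParams, I_o: float,
                   noise: EffectiveNoise) -> tuple[float, float]:
    pad = 6.0 * np.sqrt(max(noise.Dbar_e, noise.Dbar_i))
    drive = params.I_e + I_o
    lo = drive + min(params.w_ee, 0.0) + min(params.w_ie, 0.0) - pad
    hi = drive + max(params.w_ee, 0.0) + max(params.w_ie, 0.0) + pad
    return lo, hi


def find_equilibria(params: NetworkParams, I_o: float, noise: EffectiveNoise,
                    u_range: tuple[float, float] | None = None,
                    n_grid: int = 20_000, *,
                    with_stability: bool = True) -> list[Equilibrium]:
    """All real steady states at drive ``I_o``, sorted by ``u_e``.

    Scans the scalar excitatory residual (after eliminating ``u_i``,
    which is unique for ``w_ii <= 0``) on a dense bracketing grid and
    polishes each sign change with Brent's method.  The grid must be
    dense enough to separate the root pair near a fold; the default
    resolves pairs down to a few 1e-4 in ``u_e``, well below the
    separation at the interval-refinement tolerance of the sweeps.
    """
    if u_range is None:
        u_range = _default_range(params, I_o, noise)
    grid = np.linspace(u_range[0], u_range[1], n_grid)
    u_i_grid = _solve_u_i_grid(grid, params, noise)
    res = (params.w_ee * effective_transfer(grid, noise.Dbar_e)
           + params.w_ie * effective_transfer(u_i_grid, noise.Dbar_i)
           + params.I_e + I_o - grid)
    if not (res[0] > 0 and res[-1] < 0):
        raise RuntimeError(
            "scan range does not bracket the bounded fixed-point structure; "
            "widen u_range")
    roots: list[float] = []
    sign = np.sign(res)
    for k in np.nonzero(sign[:-1] * sign[1:] < 0)[0]:
        r = brentq(_scalar_residual, grid[k], grid[k + 1],
                   args=(I_o, params, noise), xtol=1e-13)
        if not roots or abs(r - roots[-1]) > MERGE_TOL:
            roots.append(r)
    for k in np.nonzero(res == 0.0)[0]:  # exact grid hits
        r = grid[k]
        if all(abs(r - x) > MERGE_TOL for x in roots):
            roots.append(r)
    roots.sort()
    out = []
    for r in roots:
        u_i = _solve_u_i(r, params, noise)
        resid_e = abs(_scalar_residual(r, I_o, params, noise))
        if resid_e > RESIDUAL_TOL:
            raise RuntimeError(f"unpolished root at u_e={r}: residual {resid_e}")
        eq = Equilibrium(u_e=r, u_i=u_i, I_o=I_o)
        if with_stability:
            linear_stability(params, eq, noise)
        out.append(eq)
    return out


def _jacobian(params: NetworkParams, eq: Equilibrium,
              noise: EffectiveNoise) -> np.ndarray:
    R_e = float(effective_transfer_slope(eq.u_e, noise.Dbar_e))
    R_i = float(effective_transfer_slope(eq.u_i, noise.Dbar_i))
    return np.array([
        [params.a_e * (-1.0 + params.w_ee * R_e), params.a_e * params.w_ie * R_i],
        [params.a_i * params.w_ei * R_e, params.a_i * (-1.0 + params.w_ii * R_i)],
    ])


def closed_form_eigenvalues(params: NetworkParams, R_e: float,
                            R_i: float) -> tuple[complex, complex]:
    """Eigenvalues ``lambda_pm = G/2 +- sqrt(H)/2`` of the rate-scaled Jacobian.

    ``G`` is the trace and ``H`` the discriminant ``G^2 - 4 det``,
    written out in the model's weight/slope symbols.
    """
    a_e, a_i = params.a_e, params.a_i
    w_ee, w_ei, w_ie, w_ii = params.w_ee, params.w_ei, params.w_ie, params.w_ii
    G = w_ee * R_e * a_e + w_ii * R_i * a_i - (a_e + a_i)
    H = ((w_ee * R_e * a_e) ** 2 + (w_ii * R_i * a_i) ** 2
         - 2.0 * a_e * a_i * R_e * R_i * w_ee * w_ii
         + 4.0 * a_e * a_i * R_e * R_i * w_ei * w_ie
         - 2.0 * a_e ** 2 * R_e * w_ee + 2.0 * a_e * a_i * R_e * w_ee
         + 2.0 * a_e * a_i * R_i * w_ii - 2.0 * a_i ** 2 * R_i * w_ii
         - 2.0 * a_e * a_i + a_i ** 2 + a_e ** 2)
    sq = np.emath.sqrt(H)
    return (complex(0.5 * G + 0.5 * sq), complex(0.5 * G - 0.5 * sq))


def linear_stability(params: NetworkParams, eq: Equilibrium,
                     noise: EffectiveNoise) -> tuple[float, float, str]:
    """Damping rate, eigenfrequency and stability label of a steady state.

    Computes the leading eigenvalue twice — closed form and numeric
    eigendecomposition — and raises if they disagree beyond
    ``EIG_AGREE_RTOL`` (relative).  Mutates ``eq`` in place with the
    result and also returns it.
    """
    R_e = float(effective_transfer_slope(eq.u_e, noise.Dbar_e))
    R_i = float(effective_transfer_slope(eq.u_i, noise.Dbar_i))
    lam_closed = closed_form_eigenvalues(params, R_e, R_i)
    lam_num = np.linalg.eigvals(_jacobian(params, eq, noise))
    # pair by real part, then imaginary part
    key = lambda z: (np.real(z), np.imag(z))
    lc = sorted(lam_closed, key=key)
    ln = sorted(lam_num, key=key)
    scale = max(abs(lc[0]), abs(lc[1]), 1.0)
    for c, m in zip(lc, ln):
        if abs(c - m) > EIG_AGREE_RTOL * scale:
            raise AssertionError(
                f"closed-form eigenvalues {lc} disagree with "
                f"eigendecomposition {ln}")
    lead = max(lam_closed, key=lambda z: z.real)
    damping = float(lead.real)
    eigfreq = float(abs(lead.imag))
    stability = "stable" if damping < 0 else "unstable"
    eq.damping = damping
    eq.eigfreq = eigfreq
    eq.stability = stability
    return damping, eigfreq, stability


@dataclass
class BifurcationDiagram:
    """Equilibria over a drive grid, with the multistable interval."""

    drives: np.ndarray
    equilibria: list[list[Equilibrium]]
    multistable_interval: tuple[float, float] | None
    noise: EffectiveNoise
    params: NetworkParams = field(repr=False, default=None)

    @property
    def interval_width(self) -> float:
        if self.multistable_interval is None:
            return 0.0
        lo, hi = self.multistable_interval
        return hi - lo

    def to_rows(self) -> list[dict]:
        rows = []
        for I_o, eqs in zip(self.drives, self.equilibria):
            for b, eq in enumerate(eqs):
                rows.append({
                    "I_o": float(I_o), "branch_id": b,
                    "u_e": eq.u_e, "u_i": eq.u_i,
                    "damping": eq.damping, "eigfreq_hz": eq.eigfreq_hz,
                    "stable": eq.stability == "stable",
                })
        return rows

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd
        pd.DataFrame(self.to_rows()).to_csv(path, index=False)

    def summary(self) -> dict:
        return {
            "multistable_interval": (list(self.multistable_interval)
                                     if self.multistable_interval else None),
            "interval_width": self.interval_width,
            "Dbar_e": self.noise.Dbar_e,
            "Dbar_i": self.noise.Dbar_i,
            "n_drives": int(len(self.drives)),
        }

    def summary_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2)


def _count_equilibria(params: NetworkParams, I_o: float,
                      noise: EffectiveNoise, n_grid: int) -> int:
    return len(find_equilibria(params, I_o, noise, n_grid=n_grid,
                               with_stability=False))


def bifurcation_sweep(params: NetworkParams, noise: EffectiveNoise,
                      drive_grid, n_grid: int = 20_000,
                      refine_tol: float = 1e-4) -> BifurcationDiagram:
    """Equilibria and stability at each drive, plus the multistable interval.

    The interval is the extent of drives carrying at least three
    coexisting equilibria; its endpoints are refined by bisection
    between neighbouring grid points to ``refine_tol`` in the drive.
    """
    drives = np.asarray(sorted(drive_grid), dtype=float)
    all_eqs: list[list[Equilibrium]] = []
    counts = np.empty(len(drives), dtype=int)
    for k, I_o in enumerate(drives):
        eqs = find_equilibria(params, float(I_o), noise, n_grid=n_grid)
        all_eqs.append(eqs)
        counts[k] = len(eqs)

    multi = np.nonzero(counts >= 3)[0]
    interval = None
    if multi.size:
        lo_idx, hi_idx = multi[0], multi[-1]
        lo = float(drives[lo_idx])
        hi = float(drives[hi_idx])

        def bisect(a: float, b: float, want_multi_at_b: bool) -> float:
            # invariant: exactly one of a, b sits inside the interval
            while b - a > refine_tol:
                m = 0.5 * (a + b)
                is_multi = _count_equilibria(params, m, noise, n_grid) >= 3
                if is_multi == want_multi_at_b:
                    b = m
                else:
                    a = m
            return 0.5 * (a + b)

        if lo_idx > 0:
            lo = bisect(float(drives[lo_idx - 1]), lo, want_multi_at_b=True)
        if hi_idx < len(drives) - 1:
            hi = bisect(hi, float(drives[hi_idx + 1]), want_multi_at_b=False)
        interval = (lo, hi)

    return BifurcationDiagram(drives=drives, equilibria=all_eqs,
                              multistable_interval=interval, noise=noise,
                              params=params)
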