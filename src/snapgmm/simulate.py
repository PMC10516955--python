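"""Evolve populations of single cells under mass-action dynamics.

Every cell is an independent well-mixed reactor: its state vector is
integrated from its own initial condition with no cross-cell coupling.
Deterministic kinetics use one of three interchangeable routes:

``exact``
    closed-form affine propagation ``x(t) = e^{At} x0 + psi(t)`` via the
    matrix exponential of the augmented system — available only when all
    reactions have order <= 1, in which case it is the exact solution;
``rk45``
    an adaptive Dormand–Prince 4(5) integrator compiled with numba,
    looping over cells (the hot path for nonlinear networks);
``lsoda``
    scipy's stiff-capable LSODA, applied to chunks of cells at a time.

``method="auto"`` (the default) picks ``exact`` for purely zero/first
order networks and ``rk45`` otherwise.  Stochastic kinetics use the
Gillespie direct method with one independent random substream per cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from .bngl import ReactionNetwork
from ._kernels import rk45_population

__all__ = ["EvolvedPopulation", "evolve_cells", "evolve_cells_ssa", "SimulationError"]

DEFAULT_RTOL = 1e-6
DEFAULT_ATOL = 1e-9
#: chunk size for the LSODA route (cells integrated as one flattened system)
LSODA_CHUNK = 64


class SimulationError(RuntimeError):
    pass


@dataclass
class EvolvedPopulation:
    """All cells of one population evolved to a single time point."""

    time: float
    states: np.ndarray  # n x p, row i = cell i at `time`


def _check_inputs(net: ReactionNetwork, theta, x0, times):
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (net.n_parameters,):
        raise ValueError(
            f"theta has shape {theta.shape}, expected ({net.n_parameters},)"
        )
    if (theta < 0).any():
        raise ValueError("negative rate constants are not allowed")
    x0 = np.asarray(x0, dtype=float)
    if x0.ndim != 2 or x0.shape[1] != net.n_species:
        raise ValueError(
            f"x0 has shape {x0.shape}, expected (n_cells, {net.n_species})"
        )
    times = [float(t) for t in times]
    if any(t < 0 for t in times):
        raise ValueError("times must be nonnegative")
    if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
        raise ValueError("times must be sorted ascending")
    return theta, x0, times


def _exact_linear(net, theta, x0, times):
    p = net.n_species
    A, b = net.affine_dynamics(theta)
    M = np.zeros((p + 1, p + 1))
    M[:p, :p] = A
    M[:p, p] = b
    out = []
    for t in times:
        if t == 0.0:
            out.append(EvolvedPopulation(0.0, x0.copy()))
            continue
        Pt = expm(M * t)
        phi, psi = Pt[:p, :p], Pt[:p, p]
        states = x0 @ phi.T + psi
        out.append(EvolvedPopulation(t, np.maximum(states, 0.0)))
    return out


_STATUS_MSG = {
    1: "step size underflow",
    2: "negative excursion below tolerance",
    3: "step budget exceeded (dynamics too fast; raise max_steps or use lsoda)",
}


def _rk45(net, theta, x0, times, rtol, atol, max_steps):
    k = net.reaction_rates(theta)
    states, status = rk45_population(
        np.ascontiguousarray(x0),
        np.array(times, dtype=np.float64),
        k,
        net.reactant_matrix,
        net.S,
        rtol,
        atol,
        _negative_floor(x0, rtol),
        max_steps,
    )
    bad = np.nonzero(status)[0]
    if bad.size:
        raise SimulationError(
            f"integration failed for cell {bad[0]}: "
            f"{_STATUS_MSG.get(int(status[bad[0]]), 'unknown failure')}"
        )
    return [EvolvedPopulation(t, np.maximum(states[i], 0.0))
            for i, t in enumerate(times)]


def _negative_floor(x0, rtol) -> float:
    # abort threshold for negative excursions, relative to data scale
    return -1e-6 * max(1.0, float(np.max(np.abs(x0), initial=0.0)))


def _lsoda(net, theta, x0, times, rtol, atol):
    n, p = x0.shape
    k = net.reaction_rates(theta)
    R, S = net.reactant_matrix, net.S
    floor = _negative_floor(x0, rtol)
    t_end = times[-1]
    out = np.empty((len(times), n, p))
    for lo in range(0, n, LSODA_CHUNK):
        hi = min(lo + LSODA_CHUNK, n)
        block = x0[lo:hi]
        nb = hi - lo

        def rhs(t, y):
            x = y.reshape(nb, p)
            v = np.tile(k, (nb, 1))
            for r in range(len(k)):
                for i in np.nonzero(R[r])[0]:
                    v[:, r] *= x[:, i] ** R[r, i]
            return (v @ S.T).ravel()

        if t_end == 0.0:
            sol_y = np.repeat(block.ravel()[None, :], len(times), axis=0)
        else:
            sol = solve_ivp(
                rhs, (0.0, t_end), block.ravel(), method="LSODA",
                t_eval=times, rtol=rtol, atol=atol,
            )
            if not sol.success:
                raise SimulationError(
                    f"LSODA failed for cells {lo}..{hi - 1}: {sol.message}"
                )
            sol_y = sol.y.T
        for j in range(len(times)):
            out[j, lo:hi] = sol_y[j].reshape(nb, p)
    if out.min() < floor:
        raise SimulationError(
            f"negative excursion {out.min():.3g} below tolerance {floor:.3g}"
        )
    return [EvolvedPopulation(t, np.maximum(out[j], 0.0))
            for j, t in enumerate(times)]


def evolve_cells(
    net: ReactionNetwork,
    theta,
    x0,
    times,
    method: str = "auto",
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    max_steps: int = 20_000,
) -> list[EvolvedPopulation]:
    """Deterministically evolve each cell in ``x0`` to every time in ``times``.

    Parameters
    ----------
    net : the reaction network.
    theta : full parameter vector (length ``net.n_parameters``).
    x0 : n x p matrix of per-cell initial abundances.
    times : sorted nonnegative times; ``t=0`` returns ``x0`` unchanged.
    method : ``auto`` | ``exact`` | ``rk45`` | ``lsoda``.
    max_steps : per-cell adaptive step budget for the ``rk45`` route;
        exceeding it raises :class:`SimulationError` (optimizers treat
        that as an infinite-cost evaluation).
    """
    theta, x0, times = _check_inputs(net, theta, x0, times)
    if not times:
        return []
    if method == "auto":
        method = "exact" if net.is_linear else "rk45"
    if method == "exact":
        return _exact_linear(net, theta, x0, times)
    if method == "rk45":
        return _rk45(net, theta, x0, times, rtol, atol, max_steps)
    if method == "lsoda":
        return _lsoda(net, theta, x0, times, rtol, atol)
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# stochastic kinetics

def _ssa_propensities(k, R, x):
    # falling-factorial combinatorics: c identical reactant molecules
    # contribute x(x-1)...(x-c+1)/c!
    m = len(k)
    a = k.astype(float).copy()
    for r in range(m):
        for i in np.nonzero(R[r])[0]:
            c = R[r, i]
            if c == 1:
                a[r] *= x[i]
            else:
                a[r] *= x[i] * (x[i] - 1) / 2.0
    return a


def evolve_cells_ssa(
    net: ReactionNetwork, theta, x0, times, seed: int
) -> list[EvolvedPopulation]:
    """Gillespie direct-method evolution of every cell to each time.

    Each cell draws from its own substream (``SeedSequence(seed)`` child
    ``i`` for cell ``i``), so results are reproducible and independent of
    iteration order.  States are sampled piecewise-constantly: the state
    reported at time t is the state after the last firing before t.
    """
    theta, x0f, times = _check_inputs(net, theta, x0, times)
    if not np.array_equal(x0f, np.round(x0f)):
        raise ValueError("SSA requires integer-valued initial abundances")
    x0i = x0f.astype(np.int64)
    n, p = x0i.shape
    if not times:
        return []
    k = net.reaction_rates(theta)
    R = net.reactant_matrix
    Sint = net.S.astype(np.int64).T  # reactions x species net change
    children = np.random.SeedSequence(seed).spawn(n)
    out = np.empty((len(times), n, p), dtype=np.int64)
    for c in range(n):
        rng = np.random.Generator(np.random.PCG64(children[c]))
        x = x0i[c].copy()
        t = 0.0
        ti = 0
        while ti < len(times):
            a = _ssa_propensities(k, R, x)
            a0 = a.sum()
            if a0 <= 0.0:
                break
            t_next = t + rng.exponential(1.0 / a0)
            while ti < len(times) and times[ti] < t_next:
                out[ti, c] = x
                ti += 1
            if ti >= len(times):
                break
            t = t_next
            r = int(np.searchsorted(np.cumsum(a), rng.random() * a0))
            r = min(r, len(k) - 1)
            x = x + Sint[r]
        while ti < len(times):
            out[ti, c] = x
            ti += 1
    return [EvolvedPopulation(t, out[j].copy()) for j, t in enumerate(times)]
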