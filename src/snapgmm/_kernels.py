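"""Numba-compiled Dormand–Prince 4(5) integrator for cell populations.

One small ODE system per cell, integrated independently with adaptive
step control (error norm scaled by ``atol + rtol*|y|``).  Mass-action
right-hand sides walk a sparse encoding of the reactant multiplicities
and net stoichiometry, so any network with reaction order <= 2 is
supported without code generation.
"""

import numpy as np
from numba import njit

# Dormand–Prince 5(4) tableau: row s holds the stage-s coefficients
# (row 6 equals the 5th-order weights, the FSAL property).
_A = np.array([
    [0.0, 0.0, 0.0, 0.0, 0.0, 0.0],
    [1 / 5, 0.0, 0.0, 0.0, 0.0, 0.0],
    [3 / 40, 9 / 40, 0.0, 0.0, 0.0, 0.0],
    [44 / 45, -56 / 15, 32 / 9, 0.0, 0.0, 0.0],
    [19372 / 6561, -25360 / 2187, 64448 / 6561, -212 / 729, 0.0, 0.0],
    [9017 / 3168, -355 / 33, 46732 / 5247, 49 / 176, -5103 / 18656, 0.0],
    [35 / 384, 0.0, 500 / 1113, 125 / 192, -2187 / 6784, 11 / 84],
])
# embedded 4th-order weights (7 stages)
_B4 = np.array([5179 / 57600, 0.0, 7571 / 16695, 393 / 640,
                -92097 / 339200, 187 / 2100, 1 / 40])


def _sparse_structure(R, S):
    """Flatten reactant multiplicities and net stoichiometry into CSR-like
    index arrays so the RHS touches only the species each reaction uses."""
    m, p = R.shape
    r_ptr = [0]
    r_idx, r_cnt = [], []
    s_ptr = [0]
    s_idx, s_val = [], []
    for r in range(m):
        for i in range(p):
            if R[r, i]:
                r_idx.append(i)
                r_cnt.append(int(R[r, i]))
        r_ptr.append(len(r_idx))
        for i in range(p):
            if S[i, r] != 0.0:
                s_idx.append(i)
                s_val.append(float(S[i, r]))
        s_ptr.append(len(s_idx))
    return (
        np.asarray(r_ptr, np.int64), np.asarray(r_idx, np.int64),
        np.asarray(r_cnt, np.int64), np.asarray(s_ptr, np.int64),
        np.asarray(s_idx, np.int64), np.asarray(s_val, np.float64),
    )


@njit(cache=True, inline="always")
def _rhs(x, k, r_ptr, r_idx, r_cnt, s_ptr, s_idx, s_val, dx):
    p = x.shape[0]
    m = k.shape[0]
    for i in range(p):
        dx[i] = 0.0
    for r in range(m):
        a = k[r]
        for j in range(r_ptr[r], r_ptr[r + 1]):
            xi = x[r_idx[j]]
            if r_cnt[j] == 1:
                a *= xi
            else:
                a *= xi * xi
        for j in range(s_ptr[r], s_ptr[r + 1]):
            dx[s_idx[j]] += s_val[j] * a
    return dx


@njit(cache=True)
def _integrate_cell(y, times, k, r_ptr, r_idx, r_cnt, s_ptr, s_idx, s_val,
                    rtol, atol, floor, max_steps, out, A, B4):
    """Integrate one cell through all requested (sorted) times.

    Returns status: 0 ok, 1 step-size failure, 2 negative excursion
    below `floor`, 3 step budget exceeded (dynamics too fast for the
    budget -- callers treat the whole evaluation as failed).
    """
    p = y.shape[0]
    T = times.shape[0]
    K = np.empty((7, p))
    ytmp = np.empty(p)
    t = 0.0
    ti = 0
    while ti < T and times[ti] <= t:
        for i in range(p):
            out[ti, i] = y[i]
        ti += 1
    if ti >= T:
        return 0
    t_end = times[T - 1]
    # initial step heuristic (Hairer-Norsett-Wanner style, simplified)
    _rhs(y, k, r_ptr, r_idx, r_cnt, s_ptr, s_idx, s_val, K[0])
    d0 = 0.0
    d1 = 0.0
    for i in range(p):
        sc = atol + rtol * abs(y[i])
        d0 += (y[i] / sc) ** 2
        d1 += (K[0, i] / sc) ** 2
    d0 = np.sqrt(d0 / p)
    d1 = np.sqrt(d1 / p)
    if d0 < 1e-5 or d1 < 1e-5:
        h = 1e-6 * max(1.0, t_end)
    else:
        h = 0.01 * d0 / d1
    if h > t_end:
        h = t_end
    n_reject = 0
    n_steps = 0
    while ti < T:
        n_steps += 1
        if n_steps > max_steps:
            return 3
        if h < 1e-14 * max(1.0, t):
            return 1
        clipped = t + h >= times[ti]
        h_use = times[ti] - t if clipped else h
        _rhs(y, k, r_ptr, r_idx, r_cnt, s_ptr, s_idx, s_val, K[0])
        for s in range(1, 7):
            n_prev = s if s < 6 else 6
            for i in range(p):
                acc = 0.0
                for j in range(n_prev):
                    acc += A[s, j] * K[j, i]
                ytmp[i] = y[i] + h_use * acc
            _rhs(ytmp, k, r_ptr, r_idx, r_cnt, s_ptr, s_idx, s_val, K[s])
        # after stage 6, ytmp holds the 5th-order solution
        err = 0.0
        for i in range(p):
            acc4 = 0.0
            for j in range(7):
                acc4 += B4[j] * K[j, i]
            y4i = y[i] + h_use * acc4
            sc = atol + rtol * max(abs(y[i]), abs(ytmp[i]))
            e = (ytmp[i] - y4i) / sc
            err += e * e
        err = np.sqrt(err / p)
        if err <= 1.0:
            t = times[ti] if clipped else t + h_use
            for i in range(p):
                y[i] = ytmp[i]
                if y[i] < floor:
                    return 2
            while ti < T and times[ti] <= t:
                for i in range(p):
                    out[ti, i] = y[i]
                ti += 1
            if err == 0.0:
                fac = 5.0
            else:
                fac = 0.9 * err ** (-0.2)
                if fac > 5.0:
                    fac = 5.0
                elif fac < 0.2:
                    fac = 0.2
            h_new = h_use * fac
            if clipped and h_new < h:
                h_new = h  # do not let an output-clipped step shrink h
            h = h_new
            n_reject = 0
        else:
            fac = 0.9 * err ** (-0.2)
            if fac < 0.1:
                fac = 0.1
            h = h_use * fac
            n_reject += 1
            if n_reject > 60:
                return 1
    return 0


@njit(cache=True)
def _rk45_population_impl(x0, times, k, r_ptr, r_idx, r_cnt, s_ptr, s_idx,
                          s_val, rtol, atol, floor, max_steps, A, B4):
    n, p = x0.shape
    T = times.shape[0]
    out = np.empty((T, n, p))
    status = np.zeros(n, dtype=np.int64)
    cell_out = np.empty((T, p))
    y = np.empty(p)
    for c in range(n):
        for i in range(p):
            y[i] = x0[c, i]
        st = _integrate_cell(y, times, k, r_ptr, r_idx, r_cnt, s_ptr,
                             s_idx, s_val, rtol, atol, floor, max_steps,
                             cell_out, A, B4)
        status[c] = st
        if st != 0:
            break  # fail fast: one bad cell voids the evaluation
        for t in range(T):
            for i in range(p):
                out[t, c, i] = cell_out[t, i]
    return out, status


def rk45_population(x0, times, k, R, S, rtol, atol, floor, max_steps=20000):
    """Integrate every cell (row of x0) to each requested time.

    Returns (states, status): states has shape (T, n, p); status is a
    per-cell code (0 ok, 1 step failure, 2 negative excursion, 3 step
    budget exceeded).  On the first nonzero status the remaining cells
    are skipped.
    """
    sparse = _sparse_structure(np.asarray(R, np.int64), np.asarray(S, np.float64))
    return _rk45_population_impl(
        np.asarray(x0, np.float64), np.asarray(times, np.float64),
        np.asarray(k, np.float64), *sparse,
        float(rtol), float(atol), float(floor), int(max_steps), _A, _B4,
    )
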