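"""Global-best Particle Swarm Optimization over a bounded box.

The swarm follows the classic update
``v <- w*v + c1*r1*(pbest - x) + c2*r2*(gbest - x)`` with fresh uniform
r1, r2 per dimension, fixed inertia, and reflecting boundaries (position
folded back into the box, velocity sign flipped).  Rate constants span
orders of magnitude, so the search is run in log10-transformed
coordinates by default; non-finite objective values are treated as +inf
so failed model evaluations are survivable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["PSOConfig", "PSOResult", "pso_minimize", "run_replicates"]


@dataclass
class PSOConfig:
    """Hyperparameters of one PSO run.

    The five tunables are the swarm size, the number of steps, and the
    three movement coefficients (inertia, cognitive, social).
    """

    bounds: list[tuple[float, float]]
    n_particles: int = 150
    n_steps: int = 100
    inertia: float = 0.7
    cognitive: float = 1.5
    social: float = 1.5
    seed: int = 0
    search_space: str = "log10"  # or "linear"

    def __post_init__(self):
        if self.n_particles < 1 or self.n_steps < 0:
            raise ValueError("need n_particles >= 1 and n_steps >= 0")
        if self.search_space not in ("linear", "log10"):
            raise ValueError(f"unknown search space {self.search_space!r}")
        for lo, hi in self.bounds:
            if not lo < hi:
                raise ValueError(f"invalid bounds ({lo}, {hi}): need low < high")
            if self.search_space == "log10" and lo <= 0:
                raise ValueError(
                    f"log10 search requires positive bounds, got low={lo}"
                )

    @property
    def ndim(self) -> int:
        return len(self.bounds)


@dataclass
class PSOResult:
    best_x: np.ndarray
    best_f: float
    history: np.ndarray  # global best after initialization and each step
    n_evals: int


def _reflect(x: np.ndarray, v: np.ndarray, lo: np.ndarray, hi: np.ndarray):
    """Fold positions back into [lo, hi], flipping velocity where they left."""
    for _ in range(64):  # a huge velocity may need several folds
        below = x < lo
        above = x > hi
        if not (below.any() or above.any()):
            break
        x = np.where(below, 2 * lo - x, x)
        x = np.where(above, 2 * hi - x, x)
        v = np.where(below | above, -v, v)
    np.clip(x, lo, hi, out=x)
    return x, v


def pso_minimize(objective, config: PSOConfig) -> PSOResult:
    """Minimize ``objective`` (vector -> real) over the configured box.

    Fully reproducible from ``config.seed``; returns the best point over
    all ``n_particles * (n_steps + 1)`` evaluations together with the
    per-step global-best history.
    """
    rng = np.random.default_rng(config.seed)
    d = config.ndim
    lo = np.array([b[0] for b in config.bounds], dtype=float)
    hi = np.array([b[1] for b in config.bounds], dtype=float)
    log = config.search_space == "log10"
    if log:
        lo, hi = np.log10(lo), np.log10(hi)

    def f(z):
        x = 10.0 ** z if log else z
        val = objective(x)
        return val if np.isfinite(val) else np.inf

    x = rng.uniform(lo, hi, size=(config.n_particles, d))
    span = hi - lo
    v = rng.uniform(-span, span, size=(config.n_particles, d)) * 0.1
    fvals = np.array([f(xi) for xi in x])
    pbest_x = x.copy()
    pbest_f = fvals.copy()
    g = int(np.argmin(pbest_f))
    gbest_x = pbest_x[g].copy()
    gbest_f = float(pbest_f[g])
    history = [gbest_f]
    n_evals = config.n_particles

    for _ in range(config.n_steps):
        r1 = rng.random((config.n_particles, d))
        r2 = rng.random((config.n_particles, d))
        v = (config.inertia * v
             + config.cognitive * r1 * (pbest_x - x)
             + config.social * r2 * (gbest_x[None, :] - x))
        x = x + v
        for i in range(config.n_particles):
            x[i], v[i] = _reflect(x[i], v[i], lo, hi)
            fi = f(x[i])
            n_evals += 1
            if fi < pbest_f[i]:
                pbest_f[i] = fi
                pbest_x[i] = x[i]
                if fi < gbest_f:
                    gbest_f = float(fi)
                    gbest_x = x[i].copy()
        history.append(gbest_f)

    best_x = 10.0 ** gbest_x if log else gbest_x.copy()
    return PSOResult(best_x=best_x, best_f=gbest_f,
                     history=np.array(history), n_evals=n_evals)


def replicate_seed(master_seed: int, r: int) -> int:
    """Deterministic, well-separated per-replicate seed below 2**31."""
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=(int(r),))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def run_replicates(objective, config: PSOConfig, n_replicates: int,
                   master_seed: int) -> list[PSOResult]:
    """Independent PSO runs whose seeds derive from (master_seed, replicate).

    Replicates are order-insensitive: replicate r always gets the same
    derived seed regardless of how many replicates are requested.
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    results = []
    for r in range(n_replicates):
        cfg = replace(config, seed=replicate_seed(master_seed, r))
        results.append(pso_minimize(objective, cfg))
    return results
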