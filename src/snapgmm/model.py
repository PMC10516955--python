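"""End-to-end estimation: a model object over (network, dataset) and a
results object carrying estimates, uncertainties and diagnostics.

:class:`SnapshotGMM` holds a reaction network and a snapshot dataset,
precomputes the per-time GMM weight blocks from the observed cells, and
exposes the GMM cost as a function of the free parameters.  ``fit()``
runs replicated particle-swarm minimizations and returns a
:class:`SnapshotGMMResults` whose point estimate is the lowest-cost
replicate and whose confidence intervals are empirical percentiles over
the replicate estimates.  Forecasting, observed-vs-predicted fit
reports and pairwise cost-contour identifiability maps hang off these
two objects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bngl import ReactionNetwork
from .io import SnapshotDataset
from .moments import (
    MomentLevel,
    MomentVector,
    compute_moments,
    gmm_cost,
    moment_length,
    weight_from_data,
)
from .pso import PSOConfig, PSOResult, run_replicates
from .simulate import evolve_cells, evolve_cells_ssa

logger = logging.getLogger(__name__)

__all__ = [
    "SnapshotGMM",
    "SnapshotGMMResults",
    "ContourGrid",
    "confidence_intervals",
    "forecast",
]

_LOG_COST_EPS = 1e-300


def confidence_intervals(replicate_estimates, alpha: float = 0.05):
    """Per-parameter empirical percentile interval over replicate estimates.

    Returns ``(ci_low, ci_high)`` at levels (alpha/2, 1 - alpha/2) with
    linear interpolation; requires at least two replicates.
    """
    reps = np.asarray(replicate_estimates, dtype=float)
    if reps.ndim != 2 or reps.shape[0] < 2:
        raise ValueError("need a replicates-by-parameters matrix with >= 2 rows")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    lo = np.percentile(reps, 100 * alpha / 2, axis=0)
    hi = np.percentile(reps, 100 * (1 - alpha / 2), axis=0)
    return lo, hi


def forecast(
    net: ReactionNetwork,
    theta_full,
    x0,
    times,
    level: MomentLevel = MomentLevel.FULL,
    dynamics: str = "ode",
    method: str = "auto",
    ssa_seed: int = 0,
    max_steps: int = 20_000,
    rtol: float | None = None,
    atol: float | None = None,
) -> list[tuple[float, MomentVector]]:
    """Model-predicted moments at arbitrary (possibly future) times."""
    level = MomentLevel.from_config(level)
    times = sorted(float(t) for t in times)
    if any(t < 0 for t in times):
        raise ValueError("forecast times must be nonnegative")
    tol = {}
    if rtol is not None:
        tol["rtol"] = rtol
    if atol is not None:
        tol["atol"] = atol
    if dynamics == "ode":
        pops = evolve_cells(net, theta_full, x0, times, method=method,
                            max_steps=max_steps, **tol)
    elif dynamics == "ssa":
        pops = evolve_cells_ssa(net, theta_full, x0, times, seed=ssa_seed)
    else:
        raise ValueError(f"unknown dynamics {dynamics!r}")
    return [(pop.time, compute_moments(pop.states, level, net.species))
            for pop in pops]


@dataclass
class ContourGrid:
    """log10 GMM cost on a 2-D lattice of one parameter pair."""

    param_x: str
    param_y: str
    x_values: np.ndarray
    y_values: np.ndarray
    log_cost: np.ndarray  # shape (len(y_values), len(x_values))
    fixed_theta: np.ndarray

    def argmin_cell(self) -> tuple[int, int]:
        """(row, col) of the minimum log-cost cell."""
        return tuple(np.unravel_index(np.argmin(self.log_cost), self.log_cost.shape))

    def n_cells_within(self, delta: float = 1.0) -> int:
        """Number of cells within ``delta`` log10 units of the grid minimum.

        A large count signals a flat or striped cost valley — parameter
        combinations the data cannot distinguish.
        """
        return int((self.log_cost <= self.log_cost.min() + delta).sum())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (x, y, self.log_cost[iy, ix])
            for iy, y in enumerate(self.y_values)
            for ix, x in enumerate(self.x_values)
        ]
        return pd.DataFrame(rows, columns=[self.param_x, self.param_y, "log10_cost"])


class SnapshotGMM:
    """GMM moment-matching model for a reaction network and snapshot data.

    Parameters
    ----------
    network : parsed reaction network; its free parameters are estimated.
    dataset : filtered snapshot data (initial cells plus observations).
    level : which moments enter the cost (means / +variances / full).
    weight_method : 'inverse_cov' (default), 'diagonal' or 'identity'.
    dynamics : 'ode' (deterministic) or 'ssa' (stochastic kinetics).
    solver : ODE route passed to the simulator ('auto', 'exact', 'rk45',
        'lsoda').
    """

    def __init__(
        self,
        network: ReactionNetwork,
        dataset: SnapshotDataset,
        level: MomentLevel = MomentLevel.FULL,
        weight_method: str = "inverse_cov",
        ridge: float | None = None,
        dynamics: str = "ode",
        solver: str = "auto",
        ssa_seed: int = 0,
    ):
        if dataset.n_species != network.n_species:
            raise ValueError(
                f"dataset has {dataset.n_species} columns but the model has "
                f"{network.n_species} species"
            )
        if network.n_free < 1:
            raise ValueError("model has no free parameters to estimate")
        self.network = network
        self.dataset = dataset
        self.level = MomentLevel.from_config(level)
        self.weight_method = weight_method
        self.dynamics = dynamics
        self.solver = solver
        self.ssa_seed = ssa_seed
        # one weight block and one observed moment vector per time point,
        # both held fixed during optimization (one-step GMM)
        self.weights = [
            weight_from_data(y, self.level, weight_method, ridge)
            for _, y in dataset.observations
        ]
        self.observed_moments = [
            compute_moments(y, self.level, network.species)
            for _, y in dataset.observations
        ]

    # -- objective ----------------------------------------------------

    #: two-stage integration policy: while *optimizing*, integrate at a
    #: looser tolerance with a per-cell step budget so particles in absurd
    #: rate regions (ultra-fast dynamics the data could never support)
    #: fail fast and score +inf instead of stalling the swarm; reported
    #: predictions always use the tight default tolerance
    objective_max_steps: int = 500
    objective_rtol: float = 1e-4
    objective_atol: float = 1e-7

    def predicted_moments(self, theta_full,
                          max_steps: int = 20_000) -> list[tuple[float, MomentVector]]:
        return forecast(
            self.network, theta_full, self.dataset.x0, self.dataset.times,
            self.level, self.dynamics, self.solver, self.ssa_seed,
            max_steps=max_steps,
        )

    def cost(self, free_values) -> float:
        """GMM cost at a free-parameter vector (block-diagonal over times).

        Evaluated with the looser objective-stage integration policy;
        :meth:`cost_at_full_theta` uses the tight reporting tolerance.
        """
        theta = self.network.assemble_full_theta(free_values)
        try:
            preds = forecast(
                self.network, theta, self.dataset.x0, self.dataset.times,
                self.level, self.dynamics, self.solver, self.ssa_seed,
                max_steps=self.objective_max_steps,
                rtol=self.objective_rtol, atol=self.objective_atol,
            )
        except Exception as e:  # failed integrations are survivable
            logger.debug("simulation failed at theta=%s: %s", theta, e)
            return np.inf
        return sum(
            gmm_cost(pred, obs, w)
            for (_, pred), obs, w in zip(preds, self.observed_moments, self.weights)
        )

    def cost_at_full_theta(self, theta_full) -> float:
        preds = self.predicted_moments(theta_full)
        return sum(
            gmm_cost(pred, obs, w)
            for (_, pred), obs, w in zip(preds, self.observed_moments, self.weights)
        )

    # -- fitting ------------------------------------------------------

    def fit(
        self,
        n_particles: int = 150,
        n_steps: int = 100,
        n_replicates: int = 1,
        seed: int = 0,
        inertia: float = 0.7,
        cognitive: float = 1.5,
        social: float = 1.5,
        search_space: str = "log10",
        bounds: list[tuple[float, float]] | None = None,
        alpha: float = 0.05,
    ) -> "SnapshotGMMResults":
        """Replicated PSO minimization of the GMM cost.

        Each replicate runs an independent swarm from a seed derived from
        ``(seed, replicate)``.  The point estimate is the lowest-cost
        replicate; percentile confidence intervals require
        ``n_replicates >= 2``.
        """
        if bounds is None:
            bounds = self.network.free_bounds()
        config = PSOConfig(
            bounds=bounds, n_particles=n_particles, n_steps=n_steps,
            inertia=inertia, cognitive=cognitive, social=social,
            search_space=search_space,
        )
        results = run_replicates(self.cost, config, n_replicates, seed)
        reps = np.vstack([r.best_x for r in results])
        costs = np.array([r.best_f for r in results])
        best = int(np.argmin(costs))
        point = reps[best].copy()
        ci_low = ci_high = None
        if n_replicates >= 2:
            ci_low, ci_high = confidence_intervals(reps, alpha)
            # the reported interval always contains the point estimate
            # (the lowest-cost replicate can be a percentile extreme)
            ci_low = np.minimum(ci_low, point)
            ci_high = np.maximum(ci_high, point)
        theta_hat = self.network.assemble_full_theta(point)
        predicted = self.predicted_moments(theta_hat)
        return SnapshotGMMResults(
            model=self,
            free_names=self.network.free_names,
            point_estimate=point,
            replicate_estimates=reps,
            replicate_costs=costs,
            ci_low=ci_low,
            ci_high=ci_high,
            alpha=alpha,
            best_cost=float(costs[best]),
            predicted_moments=predicted,
            level=self.level,
            pso_results=results,
        )

    # -- identifiability diagnostics ----------------------------------

    def cost_contour(
        self,
        param_x: str,
        param_y: str,
        x_range: tuple[float, float],
        y_range: tuple[float, float],
        n_grid: int = 41,
        fixed_theta=None,
        log_axes: bool = True,
    ) -> ContourGrid:
        """log10 GMM cost on an ``n_grid x n_grid`` lattice of one pair.

        All other parameters are held at ``fixed_theta`` (default: the
        model file values, i.e. the ground truth in synthetic studies).
        Flat or striped low-cost regions reveal parameter combinations
        the snapshot moments cannot identify.
        """
        if param_x == param_y:
            raise ValueError("param_x and param_y must differ")
        net = self.network
        ix = net.parameter_index(param_x)
        iy = net.parameter_index(param_y)
        theta0 = (np.asarray(fixed_theta, float).copy()
                  if fixed_theta is not None else net.theta_file())
        if theta0.shape != (net.n_parameters,):
            raise ValueError("fixed_theta must be a full parameter vector")
        if n_grid < 1:
            raise ValueError("n_grid must be >= 1")
        if log_axes:
            if x_range[0] <= 0 or y_range[0] <= 0:
                raise ValueError("log axes need positive ranges")
            xs = np.logspace(np.log10(x_range[0]), np.log10(x_range[1]), n_grid)
            ys = np.logspace(np.log10(y_range[0]), np.log10(y_range[1]), n_grid)
        else:
            xs = np.linspace(x_range[0], x_range[1], n_grid)
            ys = np.linspace(y_range[0], y_range[1], n_grid)
        grid = np.empty((n_grid, n_grid))
        for iyv, yv in enumerate(ys):
            for ixv, xv in enumerate(xs):
                theta = theta0.copy()
                theta[ix] = xv
                theta[iy] = yv
                c = self.cost_at_full_theta(theta)
                grid[iyv, ixv] = np.log10(max(c, _LOG_COST_EPS))
        return ContourGrid(param_x, param_y, xs, ys, grid, theta0)


@dataclass
class SnapshotGMMResults:
    """Estimates, uncertainties and diagnostics from :meth:`SnapshotGMM.fit`."""

    model: SnapshotGMM
    free_names: list[str]
    point_estimate: np.ndarray
    replicate_estimates: np.ndarray
    replicate_costs: np.ndarray
    ci_low: np.ndarray | None
    ci_high: np.ndarray | None
    alpha: float
    best_cost: float
    predicted_moments: list[tuple[float, MomentVector]]
    level: MomentLevel
    pso_results: list[PSOResult] = field(repr=False, default_factory=list)

    @property
    def params(self) -> pd.Series:
        return pd.Series(self.point_estimate, index=self.free_names)

    @property
    def theta_full(self) -> np.ndarray:
        """Full parameter vector at the point estimate (fixed values kept)."""
        return self.model.network.assemble_full_theta(self.point_estimate)

    @property
    def n_replicates(self) -> int:
        return self.replicate_estimates.shape[0]

    def conf_int(self, alpha: float | None = None) -> pd.DataFrame:
        if self.n_replicates < 2:
            raise ValueError("confidence intervals need >= 2 replicates")
        if alpha is None or alpha == self.alpha:
            lo, hi = self.ci_low, self.ci_high
        else:
            lo, hi = confidence_intervals(self.replicate_estimates, alpha)
        return pd.DataFrame({"ci_low": lo, "ci_high": hi}, index=self.free_names)

    # -- diagnostics ---------------------------------------------------

    def forecast(self, times, dynamics: str | None = None):
        """Predicted moments at arbitrary times using the fitted parameters.

        Uses the same initial cells as the fit; at an observed time this
        reproduces the fit's predicted moments exactly.
        """
        return forecast(
            self.model.network, self.theta_full, self.model.dataset.x0,
            times, self.level,
            dynamics or self.model.dynamics, self.model.solver,
            self.model.ssa_seed,
        )

    def fit_report(self) -> pd.DataFrame:
        """Observed vs predicted value for every moment at every time."""
        rows = []
        for (t, pred), obs in zip(self.predicted_moments,
                                  self.model.observed_moments):
            for lab, o, pr in zip(obs.labels, obs.values, pred.values):
                rows.append((t, lab, lab.split(":", 1)[0], o, pr))
        return pd.DataFrame(
            rows, columns=["time", "label", "class", "observed", "predicted"]
        )

    def fit_slopes(self) -> pd.Series:
        """Least-squares slope through the origin of observed on predicted,
        one per moment class; slopes near 1 indicate good moment fits."""
        rep = self.fit_report()
        slopes = {}
        for cls, grp in rep.groupby("class", sort=False):
            x = grp["predicted"].to_numpy()
            y = grp["observed"].to_numpy()
            denom = float(x @ x)
            slopes[cls] = float(x @ y) / denom if denom > 0 else np.nan
        return pd.Series(slopes)

    def plot_fit(self, path=None, ax=None):
        """Observed = predicted scatter with the identity line."""
        import matplotlib
        if path is not None:
            matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        rep = self.fit_report()
        if ax is None:
            fig, ax = plt.subplots(figsize=(5, 5))
        else:
            fig = ax.figure
        for cls, marker in (("mean", "o"), ("var", "s"), ("cov", "^")):
            grp = rep[rep["class"] == cls]
            if len(grp):
                ax.scatter(grp["predicted"], grp["observed"], s=18,
                           marker=marker, label=cls, alpha=0.7)
        lims = [rep[["observed", "predicted"]].min().min(),
                rep[["observed", "predicted"]].max().max()]
        ax.plot(lims, lims, "k--", lw=1, label="observed = predicted")
        ax.set_xlabel("predicted moment")
        ax.set_ylabel("observed moment")
        ax.legend(fontsize=8)
        if path is not None:
            fig.savefig(path, dpi=150, bbox_inches="tight")
            plt.close(fig)
        return ax

    def summary(self) -> str:
        """Human-readable fit summary table."""
        net = self.model.network
        lines = [
            "GMM snapshot fit",
            "=" * 60,
            f"species:            {net.n_species}",
            f"observed times:     {self.model.dataset.times}",
            f"moment level:       {self.level.name} "
            f"({moment_length(net.n_species, self.level)} per time)",
            f"replicates:         {self.n_replicates}",
            f"best GMM cost:      {self.best_cost:.6g}",
            "-" * 60,
        ]
        header = f"{'parameter':<12}{'estimate':>12}"
        if self.ci_low is not None:
            pct = 100 * (1 - self.alpha)
            header += f"{f'{pct:g}% CI low':>14}{f'{pct:g}% CI high':>14}"
        lines.append(header)
        for j, name in enumerate(self.free_names):
            row = f"{name:<12}{self.point_estimate[j]:>12.5g}"
            if self.ci_low is not None:
                row += f"{self.ci_low[j]:>14.5g}{self.ci_high[j]:>14.5g}"
            lines.append(row)
        fixed = [p for p in net.parameters if p.fixed]
        for p in fixed:
            lines.append(f"{p.name:<12}{p.value:>12.5g}{'(fixed)':>14}")
        lines.append("-" * 60)
        slopes = self.fit_slopes()
        lines.append(
            "observed-vs-predicted slopes: "
            + ", ".join(f"{c}={s:.4f}" for c, s in slopes.items())
        )
        return "\n".join(lines)
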