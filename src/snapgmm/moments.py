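"""Sample moments, GMM weight matrices, and the GMM cost.

The moment vector at one time stacks, in fixed order: all species means,
then all variances (sample, 1/(n-1)), then all pairwise covariances in
lexicographic (i, j) pair order with i < j.  Three nested levels are
supported: means only; means and variances; the full vector.

The GMM weight is built per time point from the observed cells: each
cell contributes a vector u_c (its abundances, squared deviations and
cross-deviations), and the weight block is the regularized inverse of
``cov(u_c)/n`` — the estimated covariance of the sample moment vector —
so moments measured with larger sampling fluctuation count less.
Cells at different times are disjoint, so the weight across times is
block diagonal and the total cost is a sum over time points.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass

import numpy as np

from .bngl import ReactionNetwork
from .io import SnapshotDataset
from .simulate import evolve_cells, evolve_cells_ssa

logger = logging.getLogger(__name__)

__all__ = [
    "MomentLevel",
    "MomentVector",
    "moment_length",
    "moment_labels",
    "compute_moments",
    "weight_from_data",
    "gmm_cost",
    "total_cost",
]


class MomentLevel(enum.Enum):
    """Which sample moments enter the GMM cost."""

    MEANS = 1
    MEANS_VARS = 2
    FULL = 3

    @classmethod
    def from_config(cls, value) -> "MomentLevel":
        if isinstance(value, cls):
            return value
        try:
            return cls(int(value))
        except (ValueError, TypeError):
            raise ValueError(
                f"moment level must be 1 (means), 2 (means+variances) or "
                f"3 (full), got {value!r}"
            )


def moment_length(p: int, level: MomentLevel) -> int:
    """Length of the stacked moment vector for ``p`` species."""
    if p < 1:
        raise ValueError("need at least one species")
    level = MomentLevel.from_config(level)
    if level is MomentLevel.MEANS:
        return p
    if level is MomentLevel.MEANS_VARS:
        return 2 * p
    return p * (p + 3) // 2


def moment_labels(species: list[str], level: MomentLevel) -> list[str]:
    level = MomentLevel.from_config(level)
    labels = [f"mean:{s}" for s in species]
    if level is MomentLevel.MEANS:
        return labels
    labels += [f"var:{s}" for s in species]
    if level is MomentLevel.MEANS_VARS:
        return labels
    p = len(species)
    for i in range(p):
        for j in range(i + 1, p):
            labels.append(f"cov:{species[i]}:{species[j]}")
    return labels


@dataclass
class MomentVector:
    level: MomentLevel
    labels: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.labels) != self.values.size:
            raise ValueError("labels and values length mismatch")

    @property
    def classes(self) -> np.ndarray:
        """Per-entry moment class: 'mean' | 'var' | 'cov'."""
        return np.array([lab.split(":", 1)[0] for lab in self.labels])


def compute_moments(
    m: np.ndarray, level: MomentLevel, species: list[str] | None = None
) -> MomentVector:
    """Stacked sample moments of an n x p abundance matrix (n >= 2)."""
    level = MomentLevel.from_config(level)
    m = np.asarray(m, dtype=float)
    if m.ndim != 2:
        raise ValueError("expected a 2-D cells-by-species matrix")
    n, p = m.shape
    if n < 2:
        raise ValueError("at least 2 cells are required to form moments")
    if species is None:
        species = [f"s{i + 1}" for i in range(p)]
    vals = [m.mean(axis=0)]
    if level is not MomentLevel.MEANS:
        cov = np.cov(m, rowvar=False, ddof=1).reshape(p, p)
        vals.append(np.diag(cov))
        if level is MomentLevel.FULL:
            iu = np.triu_indices(p, k=1)
            vals.append(cov[iu])
    return MomentVector(level, moment_labels(species, level), np.concatenate(vals))


def _contributions(m: np.ndarray, level: MomentLevel) -> np.ndarray:
    """Per-cell moment contribution vectors u_c (n x L)."""
    n, p = m.shape
    cols = [m]
    if level is not MomentLevel.MEANS:
        d = m - m.mean(axis=0, keepdims=True)
        cols.append(d * d)
        if level is MomentLevel.FULL:
            iu, ju = np.triu_indices(p, k=1)
            cols.append(d[:, iu] * d[:, ju])
    return np.hstack(cols)


def weight_from_data(
    y: np.ndarray,
    level: MomentLevel,
    method: str = "inverse_cov",
    ridge: float | None = None,
) -> np.ndarray:
    """One GMM weight block estimated from the observed cells at one time.

    ``inverse_cov`` inverts the (ridge-regularized) covariance of the
    sample moment vector, ``cov(u_c)/n``; ``diagonal`` keeps only its
    diagonal; ``identity`` returns I.  When there are too few cells to
    estimate a full covariance (n < L + 1) the method falls back to
    ``diagonal`` with a logged warning.
    """
    level = MomentLevel.from_config(level)
    y = np.asarray(y, dtype=float)
    n, p = y.shape
    L = moment_length(p, level)
    if method == "identity":
        return np.eye(L)
    if method not in ("diagonal", "inverse_cov"):
        raise ValueError(f"unknown weight method {method!r}")
    if method == "inverse_cov" and n < L + 1:
        logger.warning(
            "only %d cells for a %d-moment vector; falling back to the "
            "diagonal weight", n, L,
        )
        method = "diagonal"
    u = _contributions(y, level)
    sigma = np.cov(u, rowvar=False, ddof=1).reshape(L, L) / n
    if ridge is None:
        ridge = 1e-6 * np.trace(sigma) / L
    if method == "diagonal":
        d = np.diag(sigma) + ridge
        if (d <= 0).any():
            raise np.linalg.LinAlgError("degenerate moment variances")
        return np.diag(1.0 / d)
    sigma = sigma + ridge * np.eye(L)
    try:
        w = np.linalg.inv(sigma)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError(
            "moment covariance singular even after ridge regularization"
        )
    return 0.5 * (w + w.T)


def gmm_cost(pred: MomentVector, obs: MomentVector, w: np.ndarray) -> float:
    """Quadratic form g' W g with g = predicted - observed moments."""
    if pred.labels != obs.labels:
        raise ValueError("predicted and observed moment labels differ")
    g = pred.values - obs.values
    w = np.asarray(w, dtype=float)
    if w.shape != (g.size, g.size):
        raise ValueError(f"weight block has shape {w.shape}, expected {(g.size,) * 2}")
    return float(g @ w @ g)


def total_cost(
    net: ReactionNetwork,
    free_values,
    dataset: SnapshotDataset,
    level: MomentLevel,
    weights: list[np.ndarray],
    dynamics: str = "ode",
    method: str = "auto",
    ssa_seed: int = 0,
) -> float:
    """GMM cost summed over observed time points.

    Evolves the dataset's initial cells to every observed time under the
    full theta assembled from ``free_values`` and compares predicted to
    observed moments, one weight block per time.
    """
    level = MomentLevel.from_config(level)
    times = dataset.times
    if len(weights) != len(times):
        raise ValueError("need one weight block per observed time")
    theta = net.assemble_full_theta(free_values)
    if dynamics == "ode":
        evolved = evolve_cells(net, theta, dataset.x0, times, method=method)
    elif dynamics == "ssa":
        evolved = evolve_cells_ssa(net, theta, dataset.x0, times, seed=ssa_seed)
    else:
        raise ValueError(f"unknown dynamics {dynamics!r}")
    cost = 0.0
    for (t, y), pop, w in zip(dataset.observations, evolved, weights):
        pred = compute_moments(pop.states, level, net.species)
        obs = compute_moments(y, level, net.species)
        cost += gmm_cost(pred, obs, w)
    return cost
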