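"""Synthetic snapshot datasets with the structure of mass-cytometry data.

Real snapshot measurements are destructive: a cell observed at one time
cannot be observed at another, so the initial cells ``X`` and every
observed cohort ``Y_t`` are disjoint draws from the same population.
The generator emulates exactly that: per-species lognormal initial
abundances (widely reported for single-cell protein levels), one fresh
cohort per observed time evolved under a ground-truth model, and an
optional additive Gaussian artifact that pushes some entries negative
the way zero-spreading preprocessing does in CyTOF pipelines.

Four small fixture models are bundled (reconstructed topologies; their
rate values are this package's own frozen choices):

``linear6``
    six species in a linear chain of first-order conversions ending in
    decay — a fully identifiable reference model;
``msn2``
    a five-species gene-regulatory motif (transcription-factor/promoter
    binding, transcription, translation, decay) with the protein birth
    and death rates fixed, leaving four free parameters;
``vav1``
    six-species phosphorylation/dephosphorylation kinetics of Vav1 by
    the kinase Syk and the phosphatase SHP1, a zero-order
    ultrasensitivity-style cycle with known identifiability problems;
``cd8_chain``
    a four-protein signal-relay chain (pCD3z -> pSLP76 -> pErk -> pS6)
    with constant pCD3z production, catalytic first-order activations
    and one shared decay rate — five rate constants in total.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .bngl import ReactionNetwork, parse_bngl
from .io import SnapshotDataset, filter_nonnegative, write_matrix_csv
from .simulate import evolve_cells, evolve_cells_ssa

__all__ = [
    "SyntheticSpec",
    "SyntheticDataset",
    "sample_lognormal_cells",
    "generate",
    "fixture_network",
    "fixture_spec",
    "FIXTURE_NAMES",
]

_LINEAR6_BNGL = """\
begin model
begin parameters
  k1 0.98
  k2 0.3497
  k3 0.1422
  k4 0.6415
  k5 0.0708
  k6 0.1301
end parameters
begin species
  X1 1
  X2 1
  X3 1
  X4 1
  X5 1
  X6 1
end species
begin reaction rules
  X1 -> X2 k1
  X2 -> X3 k2
  X3 -> X4 k3
  X4 -> X5 k4
  X5 -> X6 k5
  X6 -> 0 k6
end reaction rules
end model
"""

_MSN2_BNGL = """\
begin model
begin parameters
  kon 0.0527
  koff 0.1395
  ktr 0.6437
  kdm 0.3253
  pb 0.2697
  pd 0.0967
end parameters
begin species
  T2 1
  D 1
  DT 1
  m 1
  P 1
end species
begin reaction rules
  D + T2 -> DT kon
  DT -> D + T2 koff
  DT -> DT + m ktr
  m -> 0 kdm
  m -> m + P pb
  P -> 0 pd
end reaction rules
end model
"""

_VAV1_BNGL = """\
begin model
begin parameters
  k1 0.4725
  k2 0.4285
  k3 0.4368
  k4 0.651
  k5 0.1113
  k6 0.6396
end parameters
begin species
  Syk 1
  Vav1 1
  SykVav1 1
  SHP1 1
  SHP1pVav1 1
  pVav1 1
end species
begin reaction rules
  Syk + Vav1 -> SykVav1 k1
  SykVav1 -> Syk + Vav1 k2
  SykVav1 -> Syk + pVav1 k3
  SHP1 + pVav1 -> SHP1pVav1 k4
  SHP1pVav1 -> SHP1 + pVav1 k5
  SHP1pVav1 -> SHP1 + Vav1 k6
end reaction rules
end model
"""

_CD8_BNGL = """\
begin model
begin parameters
  k1 0.0546
  k2 0.1229
  k3 0.4557
  k4 0.0614
  k5 0.055
end parameters
begin species
  pCD3z 1
  pSLP76 1
  pErk 1
  pS6 1
end species
begin reaction rules
  0 -> pCD3z k1
  pCD3z -> pCD3z + pSLP76 k2
  pSLP76 -> pSLP76 + pErk k3
  pErk -> pErk + pS6 k4
  pCD3z -> 0 k5
  pSLP76 -> 0 k5
  pErk -> 0 k5
  pS6 -> 0 k5
end reaction rules
end model
"""

# per-fixture: (bngl text, fixed params, observed times, snapshot sizes,
# lognormal log-space location per species).  The Vav1 cycle operates in
# the zero-order ultrasensitivity regime, so its substrate pools (Vav1,
# pVav1) are drawn far more abundant than its enzyme pools (Syk, SHP1)
# and complexes.
_FIXTURES = {
    "linear6": (_LINEAR6_BNGL, (), [1.5], [10_000, 10_000], 1.0),
    "msn2": (_MSN2_BNGL, ("pb", "pd"), [1.0, 5.0], [10_000, 10_000, 10_000], 1.0),
    "vav1": (_VAV1_BNGL, (), [0.5, 2.0], [5_000, 5_000, 5_000],
             [np.log(2.0), np.log(40.0), 0.0, np.log(2.0), 0.0, np.log(10.0)]),
    "cd8_chain": (_CD8_BNGL, (), [1.0, 2.0], [719, 719, 653], 1.0),
}
FIXTURE_NAMES = tuple(_FIXTURES)

#: default lognormal initial-condition parameters (log-space location and
#: scale): median abundance e ~ 2.7 per species with ~40% cell-to-cell
#: variation
DEFAULT_IC_MU = 1.0
DEFAULT_IC_SIGMA = 0.4


def fixture_network(name: str) -> ReactionNetwork:
    """One of the bundled fixture models, with its fixed flags applied."""
    try:
        text, fixed, _, _, _ = _FIXTURES[name]
    except KeyError:
        raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    net = parse_bngl(text)
    if fixed:
        net.fix(*fixed)
    return net


@dataclass
class SyntheticSpec:
    """Everything needed to generate one synthetic snapshot dataset.

    ``n_per_snapshot`` lists the cell count for X followed by one count
    per observed time; ``negative_artifact_sd`` adds Gaussian noise of
    that standard deviation to the observed matrices (0 disables).
    """

    network: ReactionNetwork
    truth_theta: np.ndarray
    times: list[float]
    n_per_snapshot: list[int]
    ic_mu: np.ndarray | float = DEFAULT_IC_MU
    ic_sigma: np.ndarray | float = DEFAULT_IC_SIGMA
    seed: int = 0
    dynamics: str = "ode"
    negative_artifact_sd: float = 0.0

    def __post_init__(self):
        p = self.network.n_species
        self.truth_theta = np.asarray(self.truth_theta, dtype=float)
        if self.truth_theta.shape != (self.network.n_parameters,):
            raise ValueError("truth_theta must be a full parameter vector")
        self.ic_mu = np.broadcast_to(np.asarray(self.ic_mu, float), (p,)).copy()
        self.ic_sigma = np.broadcast_to(np.asarray(self.ic_sigma, float), (p,)).copy()
        if (self.ic_sigma < 0).any():
            raise ValueError("ic_sigma must be nonnegative")
        if len(self.n_per_snapshot) != len(self.times) + 1:
            raise ValueError(
                "n_per_snapshot needs one entry for X plus one per observed time"
            )
        if any(n < 2 for n in self.n_per_snapshot):
            raise ValueError("every snapshot needs at least 2 cells")
        if any(t <= 0 for t in self.times):
            raise ValueError("observed times must be positive")
        if any(t2 <= t1 for t1, t2 in zip(self.times, self.times[1:])):
            raise ValueError("times must be strictly increasing")
        if self.negative_artifact_sd < 0:
            raise ValueError("negative_artifact_sd must be >= 0")


def fixture_spec(name: str, seed: int = 0, n_per_snapshot=None,
                 times=None, **kwargs) -> SyntheticSpec:
    """A ready-to-run :class:`SyntheticSpec` for one fixture model.

    Defaults reproduce the bundled study conditions (snapshot sizes and
    observation times); both can be overridden for smaller runs.
    """
    net = fixture_network(name)
    _, _, default_times, default_n, default_mu = _FIXTURES[name]
    times = list(default_times) if times is None else list(times)
    if n_per_snapshot is None:
        if times == list(default_times):
            n_per_snapshot = list(default_n)
        else:
            n_per_snapshot = [default_n[0]] * (len(times) + 1)
    kwargs.setdefault("ic_mu", default_mu)
    return SyntheticSpec(
        network=net, truth_theta=net.theta_file(), times=times,
        n_per_snapshot=list(n_per_snapshot), seed=seed, **kwargs,
    )


@dataclass
class SyntheticDataset:
    """A generated dataset plus the hidden ground truth (testing only)."""

    dataset: SnapshotDataset
    truth_theta: np.ndarray
    hidden_initial_conditions: list[np.ndarray]  # progenitors of each Y_t
    raw_observations: list[np.ndarray]  # pre-filter Y matrices (with artifacts)
    n_dropped: list[int]


def sample_lognormal_cells(mu, sigma, n: int, seed) -> np.ndarray:
    """n cells of independent per-species lognormal abundances.

    Entry (c, i) is exp(z) with z ~ Normal(mu_i, sigma_i^2).  ``seed``
    may be an int or a numpy SeedSequence/Generator.
    """
    if n < 2:
        raise ValueError("need at least 2 cells")
    rng = np.random.default_rng(seed)
    mu = np.atleast_1d(np.asarray(mu, float))
    sigma = np.atleast_1d(np.asarray(sigma, float))
    z = rng.normal(mu, sigma, size=(n, mu.size))
    return np.exp(z)


def generate(spec: SyntheticSpec, out_dir=None) -> SyntheticDataset:
    """Generate a snapshot dataset under a ground-truth model.

    X and every per-time cohort are drawn from independent random
    substreams (children of ``SeedSequence(spec.seed)``), so the draws
    are pairwise disjoint and each cohort is reproducible on its own.
    Each cohort is evolved only to its own observation time; only the
    evolved states are recorded as Y.  When ``out_dir`` is given the
    X/Y/times.csv directory layout read by :func:`snapgmm.io.load_dataset`
    is written there.
    """
    net = spec.network
    T = len(spec.times)
    ss = np.random.SeedSequence(spec.seed)
    children = ss.spawn(2 * T + 1)
    x_child, cohort_children, noise_children = (
        children[0], children[1:1 + T], children[1 + T:]
    )

    def draw(child, n):
        cells = sample_lognormal_cells(spec.ic_mu, spec.ic_sigma, n, child)
        if spec.dynamics == "ssa":
            cells = np.maximum(np.round(cells), 0.0)
        return cells

    x0 = draw(x_child, spec.n_per_snapshot[0])

    hidden_ics, raw_obs, observations, n_dropped = [], [], [], []
    for i, t in enumerate(spec.times):
        cohort = draw(cohort_children[i], spec.n_per_snapshot[1 + i])
        hidden_ics.append(cohort)
        if spec.dynamics == "ode":
            pop = evolve_cells(net, spec.truth_theta, cohort, [t])[0]
        elif spec.dynamics == "ssa":
            seed_i = int(cohort_children[i].generate_state(1)[0] % (2**31))
            pop = evolve_cells_ssa(net, spec.truth_theta, cohort, [t],
                                   seed=seed_i)[0]
        else:
            raise ValueError(f"unknown dynamics {spec.dynamics!r}")
        y = np.asarray(pop.states, dtype=float)
        if spec.negative_artifact_sd > 0:
            noise_rng = np.random.default_rng(noise_children[i])
            y = y + noise_rng.normal(0.0, spec.negative_artifact_sd, y.shape)
        raw_obs.append(y)
        y_clean, dropped = filter_nonnegative(y)
        n_dropped.append(dropped)
        observations.append((t, y_clean))

    dataset = SnapshotDataset(x0=x0, observations=observations,
                              species_order=list(net.species))

    if out_dir is not None:
        out_dir = Path(out_dir)
        (out_dir / "X").mkdir(parents=True, exist_ok=True)
        (out_dir / "Y").mkdir(parents=True, exist_ok=True)
        write_matrix_csv(out_dir / "X" / "x0.csv", x0)
        for i, (t, y) in enumerate(zip(spec.times, raw_obs)):
            write_matrix_csv(out_dir / "Y" / f"y{i:02d}.csv", y)
        with open(out_dir / "times.csv", "w", encoding="utf-8") as fh:
            for t in spec.times:
                fh.write(f"{t:.17g}\n")

    return SyntheticDataset(
        dataset=dataset, truth_theta=spec.truth_theta.copy(),
        hidden_initial_conditions=hidden_ics, raw_observations=raw_obs,
        n_dropped=n_dropped,
    )
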