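"""Reaction networks and a parser for a plain-species subset of BNGL.

The dialect understood here covers mass-action models whose species are
simple names (no molecule components, bonds or compartments): a
``parameters`` block of ``name value`` pairs, a ``species`` (or
``seed species``) block, and a ``reaction rules`` block of elementary
unidirectional (``->``) or reversible (``<->``) rules with total reactant
order at most two.  ``observables`` and ``actions`` blocks are accepted
and ignored.  Reversible rules are expanded into two irreversible
reactions at parse time.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Parameter",
    "Reaction",
    "ReactionNetwork",
    "BNGLParseError",
    "parse_bngl",
    "mass_action_derivative",
    "stoichiometry_matrix",
    "assemble_full_theta",
]

#: default half-width of parameter search boxes, in decades around the
#: file value, used when no explicit bounds are configured
DEFAULT_BOUND_DECADES = 3.0


class BNGLParseError(ValueError):
    """Raised on malformed model text; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass
class Parameter:
    """A rate constant with an optional fixed flag and search bounds.

    Units are 1/time for zero- and first-order reactions and
    1/(abundance*time) for bimolecular ones; the package never rescales
    units.  Bounds default to ``value * 10**(+-DEFAULT_BOUND_DECADES)``.
    """

    name: str
    value: float
    fixed: bool = False
    lower: float | None = None
    upper: float | None = None

    def __post_init__(self):
        if self.value < 0:
            raise ValueError(f"parameter {self.name!r}: negative value {self.value}")
        if self.lower is None:
            base = self.value if self.value > 0 else 1.0
            self.lower = base * 10.0 ** (-DEFAULT_BOUND_DECADES)
        if self.upper is None:
            base = self.value if self.value > 0 else 1.0
            self.upper = base * 10.0 ** (+DEFAULT_BOUND_DECADES)
        if not self.fixed and not (self.lower <= self.value <= self.upper):
            raise ValueError(
                f"parameter {self.name!r}: value {self.value} outside "
                f"bounds [{self.lower}, {self.upper}]"
            )


@dataclass
class Reaction:
    """One irreversible mass-action reaction.

    Stoichiometries map species name -> positive integer multiplicity;
    ``rate_param`` names the governing rate constant.
    """

    reactants: dict[str, int]
    products: dict[str, int]
    rate_param: str

    @property
    def order(self) -> int:
        return sum(self.reactants.values())

    def __post_init__(self):
        if not self.reactants and not self.products:
            raise ValueError("reaction with empty reactant and product sides")
        if self.order > 2:
            raise ValueError(
                f"reaction order {self.order} > 2 not supported "
                f"(reactants: {self.reactants})"
            )


class ReactionNetwork:
    """A validated mass-action reaction network.

    Parameters
    ----------
    species : ordered species names (defines the column meaning of every
        abundance matrix in the package).
    reactions : list of :class:`Reaction`.
    parameters : ordered list of :class:`Parameter`; the order defines the
        layout of the full parameter vector theta.
    initial_values : per-species file initial values (informational; a
        supplied X matrix always wins as the initial-condition source).
    """

    def __init__(
        self,
        species: list[str],
        reactions: list[Reaction],
        parameters: list[Parameter],
        initial_values: dict[str, float] | None = None,
    ):
        self.species = list(species)
        self.reactions = list(reactions)
        self.parameters = list(parameters)
        self.initial_values = dict(initial_values or {})
        self._validate()
        self._index = {s: i for i, s in enumerate(self.species)}
        self._pindex = {p.name: i for i, p in enumerate(self.parameters)}
        # dense reaction arrays used by the simulators
        p, m = self.n_species, self.n_reactions
        self.reactant_matrix = np.zeros((m, p), dtype=np.int64)
        self.product_matrix = np.zeros((m, p), dtype=np.int64)
        for r, rx in enumerate(self.reactions):
            for s, c in rx.reactants.items():
                self.reactant_matrix[r, self._index[s]] = c
            for s, c in rx.products.items():
                self.product_matrix[r, self._index[s]] = c
        #: index into the parameter vector for each reaction
        self.rate_index = np.array(
            [self._pindex[rx.rate_param] for rx in self.reactions], dtype=np.int64
        )
        #: stoichiometry matrix S (species x reactions)
        self.S = (self.product_matrix - self.reactant_matrix).T.astype(np.float64)

    # -- bookkeeping -------------------------------------------------

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def n_parameters(self) -> int:
        return len(self.parameters)

    @property
    def free_parameters(self) -> list[Parameter]:
        return [p for p in self.parameters if not p.fixed]

    @property
    def free_names(self) -> list[str]:
        return [p.name for p in self.free_parameters]

    @property
    def n_free(self) -> int:
        return len(self.free_parameters)

    def theta_file(self) -> np.ndarray:
        """Full parameter vector as declared in the model file."""
        return np.array([p.value for p in self.parameters], dtype=float)

    def free_values(self) -> np.ndarray:
        return np.array([p.value for p in self.free_parameters], dtype=float)

    def free_bounds(self) -> list[tuple[float, float]]:
        return [(p.lower, p.upper) for p in self.free_parameters]

    def parameter(self, name: str) -> Parameter:
        return self.parameters[self._pindex[name]]

    def parameter_index(self, name: str) -> int:
        return self._pindex[name]

    def species_index(self, name: str) -> int:
        return self._index[name]

    def fix(self, *names: str, values: dict[str, float] | None = None) -> "ReactionNetwork":
        """Mark parameters as fixed (in place); optionally override values."""
        for n in names:
            self.parameter(n).fixed = True
        for n, v in (values or {}).items():
            self.parameter(n).value = float(v)
        return self

    @property
    def is_linear(self) -> bool:
        """True when every reaction has total order <= 1, so the population
        dynamics are an affine ODE solvable by a matrix exponential."""
        return bool((self.reactant_matrix.sum(axis=1) <= 1).all())

    # -- validation and theta assembly -------------------------------

    def _validate(self) -> None:
        names = [s for s in self.species]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate species names: {dup}")
        pnames = [p.name for p in self.parameters]
        if len(set(pnames)) != len(pnames):
            dup = sorted({n for n in pnames if pnames.count(n) > 1})
            raise ValueError(f"duplicate parameter names: {dup}")
        declared = set(names)
        pset = set(pnames)
        referenced: set[str] = set()
        for rx in self.reactions:
            for s in (*rx.reactants, *rx.products):
                if s not in declared:
                    raise ValueError(f"reaction references undeclared species {s!r}")
            if rx.rate_param not in pset:
                raise ValueError(
                    f"reaction references undeclared parameter {rx.rate_param!r}"
                )
            referenced.add(rx.rate_param)
        unused = pset - referenced
        if unused:
            raise ValueError(f"parameters not referenced by any reaction: {sorted(unused)}")

    def assemble_full_theta(self, free_values) -> np.ndarray:
        """Merge a free-parameter subvector into the full theta vector.

        Fixed parameters keep their file values; free parameters are
        overwritten in declaration order.
        """
        free_values = np.asarray(free_values, dtype=float)
        if free_values.shape != (self.n_free,):
            raise ValueError(
                f"expected {self.n_free} free values, got shape {free_values.shape}"
            )
        theta = self.theta_file()
        j = 0
        for i, p in enumerate(self.parameters):
            if not p.fixed:
                theta[i] = free_values[j]
                j += 1
        return theta

    # -- dynamics -----------------------------------------------------

    def reaction_rates(self, theta: np.ndarray) -> np.ndarray:
        """Per-reaction rate constants for a full parameter vector."""
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.n_parameters,):
            raise ValueError(
                f"theta has shape {theta.shape}, expected ({self.n_parameters},)"
            )
        return theta[self.rate_index]

    def propensities(self, theta: np.ndarray, state: np.ndarray) -> np.ndarray:
        """Mass-action rates v_r = k_r * prod_i x_i^c_ri for one state."""
        k = self.reaction_rates(theta)
        x = np.asarray(state, dtype=float)
        if x.shape != (self.n_species,):
            raise ValueError(f"state has shape {x.shape}, expected ({self.n_species},)")
        v = k.copy()
        for r in range(self.n_reactions):
            row = self.reactant_matrix[r]
            for i in np.nonzero(row)[0]:
                v[r] *= x[i] ** row[i]
        return v

    def derivative(self, theta: np.ndarray, state: np.ndarray) -> np.ndarray:
        """dx/dt = S v(x) under mass-action kinetics."""
        return self.S @ self.propensities(theta, state)

    def affine_dynamics(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(A, b) with dx/dt = A x + b; only valid when :attr:`is_linear`."""
        if not self.is_linear:
            raise ValueError("network has reactions of order > 1")
        k = self.reaction_rates(theta)
        p = self.n_species
        A = np.zeros((p, p))
        b = np.zeros(p)
        for r in range(self.n_reactions):
            row = self.reactant_matrix[r]
            nz = np.nonzero(row)[0]
            if nz.size == 0:
                b += self.S[:, r] * k[r]
            else:
                A[:, nz[0]] += self.S[:, r] * k[r]
        return A, b

    # -- serialization ------------------------------------------------

    def to_bngl(self) -> str:
        """Canonical serializer for the same BNGL subset the parser reads."""
        out = ["begin model", "begin parameters"]
        for p in self.parameters:
            out.append(f"  {p.name} {p.value:.17g}")
        out.append("end parameters")
        out.append("begin species")
        for s in self.species:
            out.append(f"  {s} {self.initial_values.get(s, 0.0):.17g}")
        out.append("end species")
        out.append("begin reaction rules")
        for rx in self.reactions:
            out.append(f"  {_side(rx.reactants)} -> {_side(rx.products)} {rx.rate_param}")
        out.append("end reaction rules")
        out.append("end model")
        return "\n".join(out) + "\n"

    def __repr__(self) -> str:
        return (
            f"<ReactionNetwork {self.n_species} species, {self.n_reactions} "
            f"reactions, {self.n_parameters} parameters ({self.n_free} free)>"
        )


def _side(stoich: dict[str, int]) -> str:
    if not stoich:
        return "0"
    terms = []
    for s, c in stoich.items():
        terms.extend([s] * c)
    return " + ".join(terms)


# ---------------------------------------------------------------------------
# parser

_NAME_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")
_UNSUPPORTED = re.compile(r"[()!@%]|::")
_BLOCK_ALIASES = {
    "parameters": "parameters",
    "species": "species",
    "seed species": "species",
    "reaction rules": "rules",
    "molecule types": "unsupported",
    "compartments": "unsupported",
    "functions": "unsupported",
    "energy patterns": "unsupported",
    "observables": "ignored",
    "actions": "ignored",
    "model": "model",
}


def _strip_comment(line: str) -> str:
    return line.split("#", 1)[0].rstrip()


def _parse_species_term(tok: str, lineno: int) -> str:
    if _UNSUPPORTED.search(tok):
        raise BNGLParseError(
            f"unsupported BNGL construct in species {tok!r} "
            "(components, bonds and compartments are not supported)",
            lineno,
        )
    if not _NAME_RE.match(tok):
        raise BNGLParseError(f"invalid species name {tok!r}", lineno)
    return tok


def _parse_side(text: str, lineno: int) -> dict[str, int]:
    text = text.strip()
    stoich: dict[str, int] = {}
    if text in ("0", "∅", ""):
        return stoich
    for term in (t.strip() for t in text.split("+")):
        if not term:
            raise BNGLParseError("empty reactant/product term", lineno)
        mult = 1
        m = re.match(r"^(\d+)\s*\*?\s*(.+)$", term)
        if m:
            mult = int(m.group(1))
            term = m.group(2).strip()
        name = _parse_species_term(term, lineno)
        stoich[name] = stoich.get(name, 0) + mult
    return stoich


def parse_bngl(text: str) -> ReactionNetwork:
    """Parse a BNGL-subset model string into a :class:`ReactionNetwork`.

    Raises :class:`BNGLParseError` with the offending line number for
    syntax errors and unsupported constructs; plain ``ValueError`` for
    semantic problems (undeclared references, duplicates).
    """
    parameters: list[Parameter] = []
    species: list[str] = []
    initial_values: dict[str, float] = {}
    reactions: list[Reaction] = []
    seen_blocks: set[str] = set()

    block: str | None = None
    block_name: str | None = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = _strip_comment(raw).strip()
        if not line:
            continue
        low = line.lower()
        if low.startswith("begin "):
            name = low[len("begin "):].strip()
            kind = _BLOCK_ALIASES.get(name)
            if kind is None:
                raise BNGLParseError(f"unknown block {name!r}", lineno)
            if kind == "unsupported":
                raise BNGLParseError(f"unsupported BNGL block {name!r}", lineno)
            if kind == "model":
                continue
            if block is not None:
                raise BNGLParseError(f"nested block {name!r}", lineno)
            if kind == "ignored":
                logger.info("ignoring BNGL block %r (line %d)", name, lineno)
            block, block_name = kind, name
            seen_blocks.add(kind)
            continue
        if low.startswith("end "):
            name = low[len("end "):].strip()
            if _BLOCK_ALIASES.get(name) == "model":
                continue
            if block is None or name != block_name:
                raise BNGLParseError(f"unexpected 'end {name}'", lineno)
            block = block_name = None
            continue
        if block is None:
            raise BNGLParseError(f"statement outside any block: {line!r}", lineno)
        if block == "ignored":
            continue
        tokens = line.split()
        # BNGL permits a leading integer index on block lines
        if len(tokens) >= 2 and tokens[0].isdigit() and block in ("parameters", "species"):
            tokens = tokens[1:]
        if block == "parameters":
            if len(tokens) != 2:
                raise BNGLParseError(f"expected 'name value', got {line!r}", lineno)
            name, val = tokens
            if not _NAME_RE.match(name):
                raise BNGLParseError(f"invalid parameter name {name!r}", lineno)
            try:
                value = float(val)
            except ValueError:
                raise BNGLParseError(f"non-numeric parameter value {val!r}", lineno)
            if not math.isfinite(value) or value < 0:
                raise BNGLParseError(f"parameter value must be finite and >= 0", lineno)
            if any(p.name == name for p in parameters):
                raise BNGLParseError(f"duplicate parameter {name!r}", lineno)
            parameters.append(Parameter(name, value))
        elif block == "species":
            if len(tokens) not in (1, 2):
                raise BNGLParseError(f"expected 'species [initial]', got {line!r}", lineno)
            name = _parse_species_term(tokens[0], lineno)
            if name in species:
                raise BNGLParseError(f"duplicate species {name!r}", lineno)
            species.append(name)
            if len(tokens) == 2:
                try:
                    initial_values[name] = float(tokens[1])
                except ValueError:
                    raise BNGLParseError(
                        f"non-numeric initial value {tokens[1]!r}", lineno
                    )
        else:  # reaction rules
            body = line
            m = re.match(r"^[A-Za-z_][A-Za-z0-9_]*\s*:\s*(.*)$", body)
            if m:  # optional rule label
                body = m.group(1)
            reversible = "<->" in body
            arrow = "<->" if reversible else "->"
            if arrow not in body:
                raise BNGLParseError(f"rule without '->': {line!r}", lineno)
            lhs_text, rhs_text = body.split(arrow, 1)
            if reversible:
                # "products kf, kr": the comma separates the two rates
                comma_parts = [s.strip() for s in rhs_text.split(",")]
                if len(comma_parts) != 2 or not comma_parts[1]:
                    raise BNGLParseError(
                        f"reversible rule needs two rate constants 'kf, kr': {line!r}",
                        lineno,
                    )
                head = comma_parts[0].rsplit(None, 1)
                if len(head) != 2:
                    raise BNGLParseError(
                        f"rule missing rate constant: {line!r}", lineno
                    )
                prod_text, kf = head
                rates = [kf, comma_parts[1]]
            else:
                rhs_tokens = rhs_text.strip().rsplit(None, 1)
                if len(rhs_tokens) != 2:
                    raise BNGLParseError(
                        f"rule missing rate constant: {line!r}", lineno
                    )
                prod_text, rate_text = rhs_tokens
                if "," in rate_text:
                    raise BNGLParseError(
                        f"irreversible rule takes a single rate constant: {line!r}",
                        lineno,
                    )
                rates = [rate_text.strip()]
            for rname in rates:
                if not _NAME_RE.match(rname):
                    raise BNGLParseError(f"invalid rate constant name {rname!r}", lineno)
            lhs = _parse_side(lhs_text, lineno)
            rhs = _parse_side(prod_text, lineno)
            try:
                reactions.append(Reaction(lhs, rhs, rates[0]))
                if reversible:
                    reactions.append(Reaction(dict(rhs), dict(lhs), rates[1]))
            except ValueError as e:
                raise BNGLParseError(str(e), lineno)

    if block is not None:
        raise BNGLParseError(f"unterminated block {block_name!r}")
    for required in ("parameters", "species"):
        if required not in seen_blocks:
            raise BNGLParseError(f"missing '{required}' block")
    if not reactions:
        raise BNGLParseError("missing or empty 'reaction rules' block")
    return ReactionNetwork(species, reactions, parameters, initial_values)


# ---------------------------------------------------------------------------
# functional wrappers mirroring the network methods

def mass_action_derivative(net: ReactionNetwork, theta, state) -> np.ndarray:
    """dx/dt = S v(x) for one state vector under mass-action kinetics."""
    return net.derivative(np.asarray(theta, float), np.asarray(state, float))


def stoichiometry_matrix(net: ReactionNetwork) -> np.ndarray:
    """Net stoichiometry S (species x reactions): products - reactants."""
    return net.S.copy()


def assemble_full_theta(net: ReactionNetwork, free_values) -> np.ndarray:
    return net.assemble_full_theta(free_values)
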