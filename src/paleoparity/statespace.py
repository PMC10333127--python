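"""State spaces, generator matrices and cost matrices for amniote reproduction characters.

Two hierarchically dependent characters are modelled: reproduction mode
(oviparous / viviparous) and eggshell mineralization (membrane / parchment /
rigid).  Eggshell is unobservable in viviparous taxa, so the two characters
are amalgamated into a single structured Markov model (SMM) over six states,
three of which carry a hidden eggshell component:

    index = 3 * reproduction + shell,  with  O=0, V=1  and  m=0, p=1, r=2

giving the ordering ``O*m, O*p, O*r, V*m, V*p, V*r``.  This ordering makes the
independent-characters generator literally the Kronecker sum of the two
component generators (see :func:`build_generator`).

Dependency flavours
-------------------
``_ind``
    the two components evolve independently, except that simultaneous changes
    of both components in one jump are prohibited (structural zeros).
``_sw``
    "switch-on" dependency: the eggshell component can change only while
    reproduction mode is oviparous; the viviparous-background shell
    transitions are additional structural zeros.

Rate parametrizations (crossed with _ind/_sw to give eight SMMs):

=======  ==  ==================================================================
ER       1   every allowed transition shares a single rate
CER      2   one rate per component character
CSYM     4   1 symmetric reproduction rate + 3 symmetric shell rates
CARD     8   2 reproduction rates + 6 shell rates, all different
=======  ==  ==================================================================

The binary extended-embryo-retention (EER) character gets its own two-state
models, ``EER_ER`` (1 rate) and ``EER_ARD`` (2 rates).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

REPRODUCTION_STATES = ("oviparous", "viviparous")
SHELL_STATES = ("membrane", "parchment", "rigid")
EER_STATES = ("absent", "present")

SMM_MODELS = (
    "ER_ind", "ER_sw",
    "CER_ind", "CER_sw",
    "CSYM_ind", "CSYM_sw",
    "CARD_ind", "CARD_sw",
)
EER_MODELS = ("EER_ER", "EER_ARD")
ALL_MODELS = SMM_MODELS + EER_MODELS


class CodingError(ValueError):
    """Raised for contradictory or empty character codings."""


@dataclass(frozen=True)
class AmalgamatedSpace:
    """The six-state amalgamated space for reproduction mode x eggshell."""

    states: tuple[tuple[str, str], ...]

    @property
    def n(self) -> int:
        return len(self.states)

    @property
    def labels(self) -> tuple[str, ...]:
        # hidden (unobservable) shell components of viviparous states marked *
        return tuple(
            f"{r[0].upper()}·{s}" + ("*" if r == "viviparous" else "")
            for r, s in self.states
        )

    def index(self, reproduction: str, shell: str) -> int:
        return self.states.index((reproduction, shell))

    def decode(self, idx: int) -> tuple[str, str]:
        return self.states[idx]


def build_space() -> AmalgamatedSpace:
    """Build the amalgamated 6-state space with the documented fixed ordering.

    ``index = 3*(O=0, V=1) + (membrane=0, parchment=1, rigid=2)``.
    """
    states = tuple(
        (r, s) for r in REPRODUCTION_STATES for s in SHELL_STATES
    )
    return AmalgamatedSpace(states=states)


@dataclass(frozen=True)
class CharacterCoding:
    """Observed (possibly ambiguous) states of one taxon.

    ``reproduction`` and ``eer`` are non-empty subsets of their state sets;
    ``eggshell`` is a non-empty subset of the shell states or ``None`` for
    inapplicable ('-', the coding of viviparous taxa whose eggshell component
    is unobservable).  Unknown ('?') is encoded as the full subset.
    """

    taxon: str
    reproduction: frozenset[str]
    eggshell: frozenset[str] | None
    eer: frozenset[str] = frozenset(EER_STATES)

    def __post_init__(self) -> None:
        if not self.reproduction or not self.reproduction <= set(REPRODUCTION_STATES):
            raise CodingError(f"{self.taxon}: bad reproduction set {set(self.reproduction)}")
        if self.eggshell is not None and (
            not self.eggshell or not self.eggshell <= set(SHELL_STATES)
        ):
            raise CodingError(f"{self.taxon}: bad eggshell set {set(self.eggshell)}")
        if not self.eer or not self.eer <= set(EER_STATES):
            raise CodingError(f"{self.taxon}: bad EER set {set(self.eer)}")
        if self.reproduction == {"oviparous"} and self.eggshell is None:
            raise CodingError(
                f"{self.taxon}: oviparous with inapplicable eggshell is contradictory"
            )


def parse_coding(taxon: str, reproduction: str, eggshell: str, eer: str = "?") -> CharacterCoding:
    """Parse the CSV cell conventions: '/'-separated sets, '-' inapplicable, '?' unknown."""

    def parse_set(cell: str, full: tuple[str, ...]) -> frozenset[str]:
        cell = cell.strip()
        if cell == "?" or cell == "":
            return frozenset(full)
        return frozenset(part.strip() for part in cell.split("/"))

    shell_cell = eggshell.strip()
    shell = None if shell_cell == "-" else parse_set(shell_cell, SHELL_STATES)
    return CharacterCoding(
        taxon=taxon,
        reproduction=parse_set(reproduction, REPRODUCTION_STATES),
        eggshell=shell,
        eer=parse_set(eer, EER_STATES),
    )


def compatible_states(coding: CharacterCoding, space: AmalgamatedSpace | None = None) -> list[int]:
    """Amalgamated state indices compatible with an observation.

    Viviparous taxa are compatible with every hidden shell component;
    oviparous taxa with the observed shell subset (inapplicable shell rules
    the oviparous states out).
    """
    space = space or build_space()
    out = []
    for i, (r, s) in enumerate(space.states):
        if r not in coding.reproduction:
            continue
        if r == "viviparous":
            out.append(i)  # shell component hidden, all compatible
        elif coding.eggshell is not None and s in coding.eggshell:
            out.append(i)
    if not out:
        raise CodingError(f"{coding.taxon}: no amalgamated state compatible with coding")
    return out


def tip_prior(coding: CharacterCoding, space: AmalgamatedSpace | None = None) -> np.ndarray:
    """Probability vector over amalgamated states: uniform over compatible states."""
    space = space or build_space()
    idx = compatible_states(coding, space)
    vec = np.zeros(space.n)
    vec[idx] = 1.0 / len(idx)
    return vec


def contrast_row(coding: CharacterCoding, space: AmalgamatedSpace | None = None) -> np.ndarray:
    """0/1 membership over amalgamated states, the parsimony counterpart of tip_prior."""
    space = space or build_space()
    vec = np.zeros((space or build_space()).n, dtype=bool)
    vec[compatible_states(coding, space)] = True
    return vec


def eer_tip_prior(coding: CharacterCoding) -> np.ndarray:
    vec = np.zeros(2)
    for i, s in enumerate(EER_STATES):
        if s in coding.eer:
            vec[i] = 1.0
    return vec / vec.sum()


def eer_contrast_row(coding: CharacterCoding) -> np.ndarray:
    return np.array([s in coding.eer for s in EER_STATES], dtype=bool)


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneratorSpec:
    """Parametrized rate-matrix skeleton for one model.

    ``param_index[i, j]`` gives the free-parameter id (0..k-1) governing the
    i→j transition, or -1 for structural zeros and the diagonal.
    """

    name: str
    n_states: int
    k: int
    param_index: np.ndarray = field(repr=False)

    def bind(self, rates: np.ndarray) -> np.ndarray:
        """Bind positive rates to the skeleton, returning a proper generator."""
        rates = np.asarray(rates, dtype=float)
        if rates.shape != (self.k,):
            raise ValueError(f"{self.name}: expected {self.k} rates, got {rates.shape}")
        if np.any(rates <= 0):
            raise ValueError(f"{self.name}: rates must be strictly positive")
        q = np.zeros((self.n_states, self.n_states))
        mask = self.param_index >= 0
        q[mask] = rates[self.param_index[mask]]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        return q


def bind_rates(spec: GeneratorSpec, rates) -> np.ndarray:
    return spec.bind(np.asarray(rates, dtype=float))


def _shell_param(scheme: str, a: int, b: int) -> int:
    """Free-parameter id of the shell transition a→b under a component scheme.

    Ids are local to the shell component; callers offset them past the
    reproduction-component ids.
    """
    if scheme == "ER":
        return 0
    if scheme == "CER":
        return 0
    if scheme == "CSYM":
        # unordered pairs (m,p)=0, (m,r)=1, (p,r)=2
        pairs = {frozenset((0, 1)): 0, frozenset((0, 2)): 1, frozenset((1, 2)): 2}
        return pairs[frozenset((a, b))]
    if scheme == "CARD":
        order = [(0, 1), (1, 0), (0, 2), (2, 0), (1, 2), (2, 1)]
        return order.index((a, b))
    raise ValueError(scheme)


def build_generator(model_name: str) -> GeneratorSpec:
    """Build the generator skeleton for any of the ten models.

    SMM skeletons only ever allow single-component moves (simultaneous changes
    of reproduction mode and eggshell are structural zeros); ``_sw`` variants
    additionally zero the shell transitions in the viviparous background.
    """
    if model_name in EER_MODELS:
        pi = -np.ones((2, 2), dtype=int)
        if model_name == "EER_ER":
            pi[0, 1] = pi[1, 0] = 0
            k = 1
        else:  # EER_ARD
            pi[0, 1], pi[1, 0] = 0, 1
            k = 2
        return GeneratorSpec(model_name, 2, k, pi)

    if model_name not in SMM_MODELS:
        raise ValueError(f"unknown model {model_name!r}; known: {ALL_MODELS}")

    scheme, dep = model_name.rsplit("_", 1)
    space = build_space()
    n = space.n
    pi = -np.ones((n, n), dtype=int)

    # free-parameter layout: reproduction ids first, then shell ids
    if scheme == "ER":
        n_repro, rp = 1, {(0, 1): 0, (1, 0): 0}
        shell_scheme, n_shell, shell_offset = "ER", 0, 0  # shares id 0
    elif scheme == "CER":
        n_repro, rp = 1, {(0, 1): 0, (1, 0): 0}
        shell_scheme, n_shell, shell_offset = "CER", 1, 1
    elif scheme == "CSYM":
        n_repro, rp = 1, {(0, 1): 0, (1, 0): 0}
        shell_scheme, n_shell, shell_offset = "CSYM", 3, 1
    elif scheme == "CARD":
        n_repro, rp = 2, {(0, 1): 0, (1, 0): 1}
        shell_scheme, n_shell, shell_offset = "CARD", 6, 2
    else:
        raise ValueError(model_name)

    for i, (ri, si) in enumerate(space.states):
        r_i, s_i = REPRODUCTION_STATES.index(ri), SHELL_STATES.index(si)
        for j, (rj, sj) in enumerate(space.states):
            if i == j:
                continue
            r_j, s_j = REPRODUCTION_STATES.index(rj), SHELL_STATES.index(sj)
            if r_i != r_j and s_i != s_j:
                continue  # simultaneous two-component change: structural zero
            if r_i != r_j:
                pi[i, j] = rp[(r_i, r_j)]
            else:
                if dep == "sw" and ri == "viviparous":
                    continue  # shell frozen in the viviparous background
                pi[i, j] = shell_offset + _shell_param(shell_scheme, s_i, s_j)

    k = max(n_repro, 1) if scheme == "ER" else n_repro + n_shell
    return GeneratorSpec(model_name, n, k, pi)


# ---------------------------------------------------------------------------
# Parsimony cost and contrast matrices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CostMatrix:
    """Square Sankoff step-cost table over amalgamated states."""

    costs: np.ndarray
    forbidden_cost: float

    def __post_init__(self) -> None:
        c = self.costs
        if c.shape[0] != c.shape[1] or np.any(np.diag(c) != 0) or np.any(c < 0):
            raise ValueError("cost matrix must be square, zero-diagonal, non-negative")


def build_cost_matrix(dependency: str = "ind", forbidden_cost: float = 100.0) -> CostMatrix:
    """Sankoff cost matrix over the six amalgamated states.

    ``free``: every move costs 1.  ``ind``: single-component moves cost 1,
    simultaneous two-component moves cost ``forbidden_cost``.  ``sw``: as
    ``ind`` but viviparous-background shell changes also cost
    ``forbidden_cost`` — high enough (default 100) to make such steps
    practically impossible in a most-parsimonious reconstruction.
    """
    if forbidden_cost <= 0:
        raise ValueError("forbidden_cost must be positive")
    if dependency not in ("free", "ind", "sw"):
        raise ValueError(f"dependency must be free/ind/sw, got {dependency!r}")
    space = build_space()
    n = space.n
    costs = np.ones((n, n))
    np.fill_diagonal(costs, 0.0)
    if dependency != "free":
        for i, (ri, si) in enumerate(space.states):
            for j, (rj, sj) in enumerate(space.states):
                if i == j:
                    continue
                if ri != rj and si != sj:
                    costs[i, j] = forbidden_cost
                elif dependency == "sw" and ri == rj == "viviparous":
                    costs[i, j] = forbidden_cost
    return CostMatrix(costs=costs, forbidden_cost=forbidden_cost)


def stationary_distribution(q: np.ndarray) -> np.ndarray:
    """Stationary distribution of a generator (null vector of Q^T)."""
    n = q.shape[0]
    a = np.vstack([q.T, np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(a, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def is_reversible(q: np.ndarray, tol: float = 1e-9) -> bool:
    """Detailed-balance check pi_i q_ij = pi_j q_ji under the stationary law."""
    pi = stationary_distribution(q)
    flow = pi[:, None] * q
    return bool(np.allclose(flow, flow.T, atol=tol * max(1.0, np.abs(q).max())))
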