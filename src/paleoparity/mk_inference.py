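"""Mk/SMM likelihoods, maximum-likelihood rate fitting, marginal ancestral states.

The engine is Felsenstein pruning over a time tree with a continuous-time
Markov generator Q: per-edge transition probabilities are exp(Q t) and tip
observations enter as probability vectors (``tip_priors``), which is how
ambiguous codings and the hidden eggshell component of viviparous taxa are
expressed.  Several independent characters sharing the tree and Q can be
evaluated in one vectorized pass.

Marginal ancestral states are available through two routes:

``no_reroot``
    a single upward-downward (outside-inside) recursion that conditions every
    node on all tips; valid for any generator, including the non-reversible
    all-rates-different models.
``reroot``
    each node is made the root of a rerooted copy of the tree and its marginal
    is read off the root partials; only valid for time-reversible generators
    (an error names the offending matrix otherwise).

Node-state constraints ("node fossilization") zero the partial likelihood of
disallowed states at a named clade's ancestor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import minimize

from .statespace import GeneratorSpec, is_reversible, stationary_distribution
from .treetime import TimeTree


class ZeroLikelihoodError(ValueError):
    """The data (or a node constraint) has probability zero under the model."""


def _validate_generator(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    if q.ndim != 2 or q.shape[0] != q.shape[1]:
        raise ValueError("generator must be square")
    off = q.copy()
    np.fill_diagonal(off, 0.0)
    if np.any(off < -1e-12):
        raise ValueError("generator has negative off-diagonal entries")
    if np.any(np.abs(q.sum(axis=1)) > 1e-8 * max(1.0, np.abs(q).max())):
        raise ValueError("generator rows must sum to zero")
    return q


def _resolve_root_prior(root_prior, q: np.ndarray) -> np.ndarray:
    n = q.shape[0]
    if isinstance(root_prior, str):
        if root_prior == "flat":
            return np.full(n, 1.0 / n)
        if root_prior == "stationary":
            return stationary_distribution(q)
        raise ValueError(f"root_prior must be 'flat', 'stationary' or a vector, got {root_prior!r}")
    vec = np.asarray(root_prior, dtype=float)
    if vec.shape != (n,) or np.any(vec < 0) or not np.isclose(vec.sum(), 1.0):
        raise ValueError("custom root prior must be a probability vector over states")
    return vec


def _tip_matrix(tip_priors: dict[str, np.ndarray], label: str, n: int) -> np.ndarray:
    if label not in tip_priors:
        raise KeyError(f"no tip prior for taxon {label!r}")
    vec = np.atleast_2d(np.asarray(tip_priors[label], dtype=float))
    if vec.shape[1] != n:
        raise ValueError(f"tip prior for {label!r} has {vec.shape[1]} states, expected {n}")
    return vec


def _constraint_masks(tree: TimeTree, constraints, n: int):
    """Map dendropy nodes to 0/1 masks from clade-addressed constraints."""
    if not constraints:
        return {}
    cmap = tree.clade_map()
    masks = {}
    for clade, allowed in constraints.items():
        clade = frozenset(clade)
        if clade not in cmap:
            raise KeyError(f"no node with tip set {sorted(clade)}")
        allowed = list(allowed)
        if not allowed:
            raise ValueError("constraint allowed-state set must be non-empty")
        mask = np.zeros(n)
        mask[allowed] = 1.0
        masks[cmap[clade]] = mask
    return masks


def _uppass(tree: TimeTree, tip_priors, q, constraints=None):
    """Scaled upward partials per node: (C, S) arrays plus per-character log scalers."""
    n = q.shape[0]
    masks = _constraint_masks(tree, constraints, n)
    pcache: dict[float, np.ndarray] = {}

    def pmat(t: float) -> np.ndarray:
        key = round(float(t), 15)
        if key not in pcache:
            if t < 0:
                raise ValueError("negative edge duration")
            pcache[key] = expm(q * t)
        return pcache[key]

    up: dict = {}
    logscale: dict = {}
    for nd in tree.dtree.postorder_node_iter():
        if nd.is_leaf():
            part = _tip_matrix(tip_priors, nd.taxon.label, n).copy()
            ls = np.zeros(part.shape[0])
        else:
            part = None
            ls = None
            for c in nd.child_nodes():
                contrib = up[c] @ pmat(c.edge.length).T
                part = contrib if part is None else part * contrib
                ls = logscale[c] if ls is None else ls + logscale[c]
        if nd in masks:
            part = part * masks[nd]
        scale = part.max(axis=1)
        safe = np.where(scale > 0, scale, 1.0)
        up[nd] = part / safe[:, None]
        logscale[nd] = ls + np.where(scale > 0, np.log(safe), -np.inf)
    return up, logscale, pmat


def prune_loglik(tree: TimeTree, tip_priors: dict[str, np.ndarray], q,
                 root_prior="flat", constraints=None) -> float:
    """Log-likelihood of the tip data under generator ``q`` by pruning.

    ``tip_priors`` maps taxon to a state-probability vector, or to a
    (characters x states) array for several independent characters, in which
    case the per-character log-likelihoods are summed.  Returns ``-inf`` when
    the data (e.g. under a node constraint) has probability zero.
    """
    q = _validate_generator(q)
    prior = _resolve_root_prior(root_prior, q)
    up, logscale, _ = _uppass(tree, tip_priors, q, constraints)
    root = tree.dtree.seed_node
    lik = up[root] @ prior
    with np.errstate(divide="ignore"):
        ll = np.log(lik) + logscale[root]
    return float(ll.sum())


def prune_loglik_per_character(tree, tip_priors, q, root_prior="flat", constraints=None):
    """Per-character log-likelihood vector (see :func:`prune_loglik`)."""
    q = _validate_generator(q)
    prior = _resolve_root_prior(root_prior, q)
    up, logscale, _ = _uppass(tree, tip_priors, q, constraints)
    root = tree.dtree.seed_node
    with np.errstate(divide="ignore"):
        return np.log(up[root] @ prior) + logscale[root]


@dataclass
class NodeMarginals:
    """Marginal state probabilities per internal node, addressed by clade."""

    marginals: dict[frozenset, np.ndarray]
    state_labels: tuple[str, ...] | None = None

    def __getitem__(self, clade) -> np.ndarray:
        return self.marginals[frozenset(clade)]

    def __iter__(self):
        return iter(self.marginals.items())

    def table(self) -> pd.DataFrame:
        rows = []
        for clade, vec in self.marginals.items():
            v = np.atleast_2d(vec)[0] if np.asarray(vec).ndim > 1 else vec
            rows.append({"clade": "|".join(sorted(clade)), "n_tips": len(clade),
                         **{(self.state_labels[i] if self.state_labels else f"state_{i}"): p
                            for i, p in enumerate(np.asarray(v))}})
        return pd.DataFrame(rows).sort_values("n_tips", ascending=False).reset_index(drop=True)

    def to_tsv(self, path) -> None:
        self.table().to_csv(path, sep="\t", index=False)


def marginal_asr(tree: TimeTree, tip_priors, q, root_prior="flat",
                 method: str = "no_reroot", constraints=None,
                 state_labels=None) -> NodeMarginals:
    """Marginal ancestral state probabilities at every internal node.

    Rows sum to one; states disallowed by a constraint get exactly zero mass.
    """
    q = _validate_generator(q)
    prior = _resolve_root_prior(root_prior, q)
    if method == "no_reroot":
        margs = _asr_updown(tree, tip_priors, q, prior, constraints)
    elif method == "reroot":
        if not is_reversible(q):
            raise ValueError(
                "reroot marginals require a time-reversible generator; "
                f"this matrix is not reversible:\n{np.array_str(q, precision=4)}"
            )
        margs = _asr_reroot(tree, tip_priors, q, prior, constraints)
    else:
        raise ValueError(f"method must be no_reroot or reroot, got {method!r}")
    squeeze = np.asarray(next(iter(tip_priors.values()))).ndim == 1
    out = {}
    for clade, m in margs.items():
        tot = m.sum(axis=1, keepdims=True)
        if np.any(tot <= 0):
            raise ZeroLikelihoodError(
                f"zero likelihood at node {sorted(clade)[:3]}...; "
                "check node constraints against the data"
            )
        m = m / tot
        out[clade] = m[0] if squeeze else m
    return NodeMarginals(out, tuple(state_labels) if state_labels else None)


def _asr_updown(tree, tip_priors, q, prior, constraints):
    n = q.shape[0]
    up, _, pmat = _uppass(tree, tip_priors, q, constraints)
    masks = _constraint_masks(tree, constraints, n)
    root = tree.dtree.seed_node
    down = {root: np.broadcast_to(prior, up[root].shape).copy()}
    margs = {}
    for nd in tree.dtree.preorder_node_iter():
        if not nd.is_leaf():
            margs[tree.clade_of(nd)] = up[nd] * down[nd]
        # effective outside message passed to children includes this node's mask
        d_eff = down[nd] * masks[nd] if nd in masks else down[nd]
        children = nd.child_nodes()
        if not children:
            continue
        upP = [up[c] @ pmat(c.edge.length).T for c in children]
        for i, c in enumerate(children):
            sib = d_eff.copy()
            for j, other in enumerate(children):
                if j != i:
                    sib = sib * upP[j]
            dvec = sib @ pmat(c.edge.length)
            mx = dvec.max(axis=1, keepdims=True)
            down[c] = dvec / np.where(mx > 0, mx, 1.0)
    return margs


def _asr_reroot(tree, tip_priors, q, prior, constraints):
    """Marginals by literally rerooting the (undirected) tree at each node."""
    n = q.shape[0]
    masks = _constraint_masks(tree, constraints, n)
    # undirected adjacency with durations
    adj: dict = {}
    for nd in tree.dtree.preorder_node_iter():
        for c in nd.child_nodes():
            adj.setdefault(nd, []).append((c, c.edge.length))
            adj.setdefault(c, []).append((nd, c.edge.length))
    pcache: dict[float, np.ndarray] = {}

    def pmat(t):
        key = round(float(t), 15)
        if key not in pcache:
            pcache[key] = expm(q * t)
        return pcache[key]

    nchar = np.atleast_2d(np.asarray(next(iter(tip_priors.values())))).shape[0]

    def up_from(node, parent):
        if node.is_leaf():
            part = _tip_matrix(tip_priors, node.taxon.label, n).copy()
        else:
            part = np.ones((nchar, n))
            for nb, t in adj[node]:
                if nb is parent:
                    continue
                part = part * (up_from(nb, node) @ pmat(t).T)
        if node in masks:
            part = part * masks[node]
        mx = part.max(axis=1, keepdims=True)
        return part / np.where(mx > 0, mx, 1.0)

    margs = {}
    for nd in tree.dtree.preorder_node_iter():
        if nd.is_leaf():
            continue
        margs[tree.clade_of(nd)] = up_from(nd, None) * prior
    return margs


# ---------------------------------------------------------------------------
# Maximum-likelihood fitting
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Outcome of one ML fit: rates, log-likelihood and AIC for model choice."""

    model: str
    rates: np.ndarray
    loglik: float
    k: int
    aic: float
    converged: bool
    at_bound: bool
    n_restarts: int
    restart_logliks: list[float] = field(default_factory=list)
    seed: object = None
    root_prior: str = "flat"

    def to_dict(self) -> dict:
        return {
            "model": self.model, "rates": list(map(float, self.rates)),
            "loglik": float(self.loglik), "k": self.k, "aic": float(self.aic),
            "converged": self.converged, "at_bound": self.at_bound,
            "n_restarts": self.n_restarts,
            "restart_logliks": list(map(float, self.restart_logliks)),
            "seed": self.seed, "root_prior": self.root_prior,
        }


def fit_mk(tree: TimeTree, tip_priors, spec: GeneratorSpec, n_restarts: int = 10,
           max_iter: int = 500, seed=None, root_prior="flat", constraints=None,
           bounds: tuple[float, float] = (1e-8, 1e3)) -> FitResult:
    """Fit a model's transition rates by maximum likelihood with restarts.

    Optimization runs over log-rates with L-BFGS-B inside ``bounds`` (sized
    for trees rescaled to height 1).  The first restart starts at rate 1 for
    every parameter; the rest start log-uniform on [1e-3, 1e2].  The best
    restart is returned; all restart log-likelihoods are recorded.
    """
    if n_restarts < 1:
        raise ValueError("need at least one restart")
    rng = np.random.default_rng(seed)
    lo, hi = np.log(bounds[0]), np.log(bounds[1])

    def nll(logr):
        ll = prune_loglik(tree, tip_priors, spec.bind(np.exp(logr)),
                          root_prior=root_prior, constraints=constraints)
        return -ll if np.isfinite(ll) else 1e300

    best = None
    restart_lls, any_ok = [], False
    for i in range(n_restarts):
        x0 = (np.zeros(spec.k) if i == 0
              else rng.uniform(np.log(1e-3), np.log(1e2), size=spec.k))
        res = minimize(nll, x0, method="L-BFGS-B",
                       bounds=[(lo, hi)] * spec.k,
                       options={"maxiter": max_iter})
        restart_lls.append(-float(res.fun))
        any_ok = any_ok or bool(res.success)
        if best is None or -res.fun > -best.fun + 1e-12:
            best = res

    rates = np.exp(best.x)
    ll = -float(best.fun)
    at_bound = bool(np.any(best.x <= lo + 1e-6) or np.any(best.x >= hi - 1e-6))
    return FitResult(
        model=spec.name, rates=rates, loglik=ll, k=spec.k,
        aic=2 * spec.k - 2 * ll, converged=any_ok, at_bound=at_bound,
        n_restarts=n_restarts, restart_logliks=restart_lls, seed=seed,
        root_prior=root_prior if isinstance(root_prior, str) else "custom",
    )
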