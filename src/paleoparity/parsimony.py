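"""Maximum-parsimony ancestral reconstruction with and without cost matrices.

Two engines:

* :func:`sankoff` — dynamic programming over arbitrary step-cost matrices
  (MPR): an up-pass of minimal subtree costs and a down-pass that returns, for
  every node, the full set of states attained in at least one globally minimal
  reconstruction, plus the fraction of minimal reconstructions per state.
  Cost matrices express character dependency: forbidden steps (simultaneous
  two-component changes; viviparous-background eggshell changes under the
  switch-on model) carry a prohibitively large step cost.
* :func:`acctran` — Fitch/Hartigan counting with the accelerated-transformation
  convention: a single state per node, changes placed on the rootward-most
  eligible edge, ties among replacement states broken by lowest state index.

Branch lengths are ignored throughout (standard MP on a topology), even
though the inputs are time trees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .statespace import (
    CharacterCoding,
    CostMatrix,
    build_cost_matrix,
    build_space,
    contrast_row,
    eer_contrast_row,
)
from .treetime import TimeTree

_INF = np.inf


@dataclass
class ParsimonyResult:
    """Minimal total cost plus per-node minimal-state sets (by clade)."""

    method: str
    total_cost: float
    node_states: dict[frozenset, frozenset]
    state_freq: dict[frozenset, np.ndarray] | None = None
    state_labels: tuple[str, ...] | None = None

    def table(self) -> pd.DataFrame:
        rows = []
        for clade, states in self.node_states.items():
            rows.append({
                "clade": "|".join(sorted(clade)),
                "n_tips": len(clade),
                "states": ",".join(str(s) for s in sorted(states)),
            })
        return pd.DataFrame(rows).sort_values("n_tips", ascending=False).reset_index(drop=True)


def _tip_rows(tree: TimeTree, rows: dict[str, np.ndarray], n: int) -> None:
    for label in tree.leaf_labels():
        if label not in rows:
            raise KeyError(f"no contrast row for taxon {label!r}")
        row = np.asarray(rows[label], dtype=bool)
        if row.shape != (n,):
            raise ValueError(f"contrast row for {label!r} has wrong length")
        if not row.any():
            raise ValueError(f"contrast row for {label!r} allows no state")


def sankoff(tree: TimeTree, rows: dict[str, np.ndarray], cost: CostMatrix,
            state_labels=None) -> ParsimonyResult:
    """Sankoff MPR: minimal cost and all per-node states attaining it.

    ``state_freq`` gives, per node, the fraction of distinct globally minimal
    reconstructions in which each state occurs (counted exactly by min-plus
    dynamic programming with multiplicities).
    """
    c = cost.costs
    n = c.shape[0]
    _tip_rows(tree, rows, n)

    # up-pass: S[v][s] = minimal subtree cost given state s; N = count of minima
    S: dict = {}
    N: dict = {}
    child_choices: dict = {}
    for nd in tree.dtree.postorder_node_iter():
        if nd.is_leaf():
            row = np.asarray(rows[nd.taxon.label], dtype=bool)
            S[nd] = np.where(row, 0.0, _INF)
            N[nd] = np.where(row, 1.0, 0.0)
            continue
        s_v = np.zeros(n)
        n_v = np.ones(n)
        for ch in nd.child_nodes():
            # move[s, t] = cost of assigning t to child given s at nd
            move = c + S[ch][None, :]
            m_ch = move.min(axis=1)
            choice = move <= m_ch[:, None] + 1e-9
            cnt = (choice * N[ch][None, :]).sum(axis=1)
            child_choices[(nd, ch)] = (m_ch, choice)
            s_v = s_v + m_ch
            n_v = n_v * cnt
        S[nd] = s_v
        N[nd] = n_v

    root = tree.dtree.seed_node
    total = float(S[root].min())
    if not np.isfinite(total):
        raise ValueError("no admissible reconstruction (all tip rows conflict)")

    # down-pass: D[v][s] = minimal cost of the rest of the tree given s at v,
    # O[v][s] = count of minimal outside completions
    D: dict = {root: np.zeros(n)}
    O: dict = {root: np.ones(n)}
    node_states: dict[frozenset, frozenset] = {}
    state_freq: dict[frozenset, np.ndarray] = {}
    for nd in tree.dtree.preorder_node_iter():
        full = D[nd] + S[nd]
        minimal = full <= total + 1e-9
        counts = np.where(minimal, O[nd] * N[nd], 0.0)
        clade = tree.clade_of(nd)
        node_states[clade] = frozenset(int(i) for i in np.flatnonzero(minimal))
        state_freq[clade] = counts / counts.sum()
        children = nd.child_nodes()
        for ch in children:
            # outside cost for child: D at nd + siblings' minima + step cost
            base = D[nd].copy()
            base_cnt = O[nd].copy()
            for other in children:
                if other is ch:
                    continue
                m_o, choice_o = child_choices[(nd, other)]
                base = base + m_o
                base_cnt = base_cnt * (choice_o * N[other][None, :]).sum(axis=1)
            tot_ch = base[:, None] + c  # [s_parent, t_child]
            D[ch] = tot_ch.min(axis=0)
            pick = tot_ch <= D[ch][None, :] + 1e-9
            O[ch] = (pick * base_cnt[:, None]).sum(axis=0)

    return ParsimonyResult(
        method=f"MPR(forbidden={cost.forbidden_cost:g})",
        total_cost=total,
        node_states=node_states,
        state_freq=state_freq,
        state_labels=tuple(state_labels) if state_labels else None,
    )


def acctran(tree: TimeTree, rows: dict[str, np.ndarray], state_labels=None) -> ParsimonyResult:
    """Fitch/Hartigan parsimony with the ACCTRAN resolution convention.

    Up-pass (Hartigan, valid on polytomies): the preliminary set holds the
    states most frequent among child preliminary sets; each up-pass event adds
    (children − max frequency) changes.  Down-pass: the root takes the
    lowest-index preliminary state; a child keeps the parental state when it is
    in the child's preliminary set, otherwise the change happens on this —
    the rootward-most eligible — edge and the lowest-index preliminary state
    is taken.
    """
    n = len(next(iter(rows.values())))
    _tip_rows(tree, rows, n)

    prelim: dict = {}
    cost = 0.0
    for nd in tree.dtree.postorder_node_iter():
        if nd.is_leaf():
            prelim[nd] = np.asarray(rows[nd.taxon.label], dtype=bool)
            continue
        counts = np.zeros(n)
        for ch in nd.child_nodes():
            counts += prelim[ch]
        kmax = counts.max()
        prelim[nd] = counts >= kmax
        cost += len(nd.child_nodes()) - kmax

    root = tree.dtree.seed_node
    final: dict = {root: int(np.flatnonzero(prelim[root])[0])}
    for nd in tree.dtree.preorder_node_iter():
        for ch in nd.child_nodes():
            ps = final[nd]
            final[ch] = ps if prelim[ch][ps] else int(np.flatnonzero(prelim[ch])[0])

    node_states = {}
    for nd in tree.dtree.preorder_node_iter():
        if not nd.is_leaf():
            node_states[tree.clade_of(nd)] = frozenset([final[nd]])
    return ParsimonyResult(
        method="ACCTRAN",
        total_cost=float(cost),
        node_states=node_states,
        state_labels=tuple(state_labels) if state_labels else None,
    )


def parsimony_suite(tree: TimeTree, codings: list[CharacterCoding],
                    forbidden_cost: float = 100.0) -> dict[str, ParsimonyResult]:
    """The parsimony battery: ACCTRAN, MPR_ind and MPR_sw over the amalgamated
    character, plus ACCTRAN over the binary EER character."""
    space = build_space()
    amal_rows = {cd.taxon: contrast_row(cd, space) for cd in codings}
    eer_rows = {cd.taxon: eer_contrast_row(cd) for cd in codings}
    return {
        "ACCTRAN": acctran(tree, amal_rows, state_labels=space.labels),
        "MPR_ind": sankoff(tree, amal_rows, build_cost_matrix("ind", forbidden_cost),
                           state_labels=space.labels),
        "MPR_sw": sankoff(tree, amal_rows, build_cost_matrix("sw", forbidden_cost),
                          state_labels=space.labels),
        "EER_ACCTRAN": acctran(tree, eer_rows, state_labels=("absent", "present")),
    }
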