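"""Synthetic trees, stratigraphic intervals and trait histories with known truth.

Everything the pipeline consumes can be generated here: birth–death trees that
retain extinct lineages as fossil tips, FAD/LAD occurrence intervals around
the true tip ages, exact (Gillespie) realizations of any of the structured
Markov models along the tree, the observation-masking rule that hides the
eggshell component of viviparous tips, and a realistic amniote-shaped fixture
(80 taxa, 59 of them extinct, in fixed clade blocks, plus two outgroups
dropped before ancestral-state work).

Because every history records its full jump chain and true node states,
inference can be scored against the truth (:func:`recovery_experiment`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .statespace import (
    CharacterCoding,
    GeneratorSpec,
    build_generator,
    build_space,
    EER_STATES,
)
from .treetime import OccurrenceInterval, TimeTree


# ---------------------------------------------------------------------------
# Trees and intervals
# ---------------------------------------------------------------------------

def simulate_tree(birth: float = 0.05, death: float = 0.02, tip_target: int = 32,
                  seed=None, max_tries: int = 100) -> TimeTree:
    """Forward birth–death simulation keeping extinct lineages as fossil tips.

    Time runs in Myr; the simulation stops when ``tip_target`` lineages are
    simultaneously alive, extant tips sit at age 0 and extinct tips at their
    extinction ages.  Defaults (birth 0.05, death 0.02 per lineage per Myr)
    give trees a few hundred Myr deep with a majority of fossil tips, the age
    structure of a mostly extinct amniote sample.
    """
    if birth <= 0 or death < 0:
        raise ValueError("need birth > 0 and death >= 0")
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        tree = _try_birth_death(birth, death, tip_target, rng)
        if tree is not None:
            return tree
    raise RuntimeError(f"tree extinct in all {max_tries} attempts; raise birth/death ratio")


def _try_birth_death(birth, death, tip_target, rng):
    taxa = dendropy.TaxonNamespace()
    dtree = dendropy.Tree(taxon_namespace=taxa)
    root = dtree.seed_node

    def new_node(parent, t0):
        nd = dendropy.Node()
        nd.birth_time = t0
        parent.add_child(nd)
        return nd

    root.birth_time = 0.0
    if tip_target < 2:
        raise ValueError("tip_target must be >= 2")
    alive = [new_node(root, 0.0), new_node(root, 0.0)]
    t = 0.0
    extinct: list[tuple[dendropy.Node, float]] = []
    while len(alive) < tip_target:
        if not alive:
            return None
        rate = (birth + death) * len(alive)
        t += rng.exponential(1.0 / rate)
        nd = alive[rng.integers(len(alive))]
        if rng.random() < birth / (birth + death):
            alive.remove(nd)
            alive.extend([new_node(nd, t), new_node(nd, t)])
            nd.death_time = t
        else:
            alive.remove(nd)
            extinct.append((nd, t))
            nd.death_time = t
    t_end = t
    for nd in alive:
        nd.death_time = t_end

    # every extinct lineage is retained as a fossil tip
    tip_ages = {}
    idx = 0
    for nd in dtree.leaf_node_iter():
        idx += 1
        label = f"t{idx}"
        nd.taxon = taxa.new_taxon(label)
        tip_ages[label] = t_end - nd.death_time
    for nd in dtree.preorder_node_iter():
        if nd.parent_node is not None:
            nd.edge.length = nd.death_time - nd.birth_time
    dtree.seed_node.edge.length = None
    return TimeTree(dtree, tip_ages)


def make_intervals(tree: TimeTree, window: float = 5.0, seed=None) -> list[OccurrenceInterval]:
    """FAD/LAD intervals that bracket each fossil tip's true age.

    ``window`` (Myr) bounds the one-sided widths drawn uniformly; extant tips
    (true age 0) get fad = lad = 0.
    """
    if window < 0:
        raise ValueError("window must be non-negative")
    rng = np.random.default_rng(seed)
    out = []
    for taxon, age in sorted(tree.tip_ages.items()):
        if age == 0:
            out.append(OccurrenceInterval(taxon, 0.0, 0.0, extant=True))
        else:
            fad = age + rng.uniform(0, window)
            lad = max(age - rng.uniform(0, window), 0.0)
            out.append(OccurrenceInterval(taxon, fad, lad, extant=False))
    return out


# ---------------------------------------------------------------------------
# Trait histories
# ---------------------------------------------------------------------------

@dataclass
class SimulatedHistory:
    """A realized trait history: true states everywhere plus the jump chain."""

    tip_states: dict[str, int]
    node_states: dict[frozenset, int]
    jumps: list[tuple[frozenset, float, int, int]]  # (child clade, time-from-parent, from, to)
    root_state: int
    seed: object = None


def simulate_history(tree: TimeTree, q: np.ndarray, root_state=None,
                     root_prior=None, seed=None) -> SimulatedHistory:
    """Exact Gillespie simulation of a CTMC along every edge of a time tree."""
    q = np.asarray(q, dtype=float)
    n = q.shape[0]
    rng = np.random.default_rng(seed)
    if root_state is None:
        p = np.full(n, 1.0 / n) if root_prior is None else np.asarray(root_prior, float)
        root_state = int(rng.choice(n, p=p / p.sum()))

    node_states: dict[frozenset, int] = {}
    tip_states: dict[str, int] = {}
    jumps = []
    state_at: dict = {tree.dtree.seed_node: root_state}
    for nd in tree.dtree.preorder_node_iter():
        s = state_at[nd]
        if nd.is_leaf():
            tip_states[nd.taxon.label] = s
        else:
            node_states[tree.clade_of(nd)] = s
        for ch in nd.child_nodes():
            t_total = ch.edge.length
            cur, t = s, 0.0
            clade = tree.clade_of(ch)
            while True:
                out_rate = -q[cur, cur]
                if out_rate <= 0:
                    break
                t += rng.exponential(1.0 / out_rate)
                if t >= t_total:
                    break
                probs = q[cur].copy()
                probs[cur] = 0.0
                probs = probs / probs.sum()
                nxt = int(rng.choice(n, p=probs))
                jumps.append((clade, t, cur, nxt))
                cur = nxt
            state_at[ch] = cur
    return SimulatedHistory(tip_states=tip_states, node_states=node_states,
                            jumps=jumps, root_state=root_state, seed=seed)


DEFAULT_EER_MAP = {  # amalgamated state index -> EER state; viviparity implies EER
    0: "absent", 1: "absent", 2: "absent", 3: "present", 4: "present", 5: "present",
}


def mask_observation(true_state: int, ambiguity_rate: float = 0.0, seed=None,
                     taxon: str = "tip", eer_state: str | None = None,
                     eer_map: dict[int, str] = DEFAULT_EER_MAP) -> CharacterCoding:
    """Turn a true amalgamated tip state into an observed coding.

    Viviparous states are coded reproduction = viviparous with eggshell
    inapplicable ('-'), oviparous states keep their observed shell.  With
    probability ``ambiguity_rate`` the tip instead becomes fully unknown
    (both characters '?').  EER comes from ``eer_state`` if supplied (the
    independent-character mode), else from the deterministic state map.
    """
    space = build_space()
    rng = np.random.default_rng(seed)
    eer = frozenset([eer_state if eer_state is not None else eer_map[true_state]])
    if rng.random() < ambiguity_rate:
        return CharacterCoding(taxon, frozenset(("oviparous", "viviparous")),
                               frozenset(("membrane", "parchment", "rigid")),
                               frozenset(EER_STATES))
    repro, shell = space.decode(true_state)
    if repro == "viviparous":
        return CharacterCoding(taxon, frozenset([repro]), None, eer)
    return CharacterCoding(taxon, frozenset([repro]), frozenset([shell]), eer)


# ---------------------------------------------------------------------------
# Synthetic amniote fixture
# ---------------------------------------------------------------------------

#: clade blocks of the synthetic amniote sample: (name, n_extinct, n_extant)
FIXTURE_BLOCKS = (
    ("Mammalia", 6, 4),
    ("Mesosauridae", 1, 0),
    ("Testudinata", 6, 3),
    ("Ichthyosauria", 13, 0),
    ("Sauropterygia", 5, 0),
    ("Rhynchocephalia", 0, 1),
    ("Squamata", 4, 6),
    ("Choristodera", 3, 0),
    ("Protorosauria", 1, 0),
    ("Crocodylia", 2, 2),
    ("Pterosauria", 4, 0),
    ("Dinosauria", 13, 0),
    ("Aves", 1, 5),
)
OUTGROUP_TAXA = ("Outgroup_1", "Outgroup_2")


@dataclass
class SimulatedDataset:
    """A fully known synthetic dataset shaped like a real fossil-amniote table."""

    tree: TimeTree                      # ingroup time tree (truth)
    tree_with_outgroups: TimeTree
    node_states: dict[frozenset, int]   # true amalgamated states, ingroup nodes
    tip_states: dict[str, int]
    codings: list[CharacterCoding]      # one row per ingroup taxon
    intervals: list[OccurrenceInterval]
    clades: dict[str, list[str]]
    model: str
    rates: np.ndarray
    seed: object = None
    ambiguous_taxon: str | None = None

    @property
    def taxa(self) -> list[str]:
        return [c.taxon for c in self.codings]

    @property
    def n_extinct(self) -> int:
        return sum(1 for c in self.codings
                   if not any(iv.taxon == c.taxon and iv.extant for iv in self.intervals))


def _random_clade_topology(labels, rng) -> str:
    """Random rooted bifurcating Newick over the given labels."""
    nodes = list(labels)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b})")
    return nodes[0]


#: generating model and rates of the fixture: switch-on dependency with one
#: reproduction rate and one shell rate, in events per Myr on a ~340 Myr tree
FIXTURE_MODEL = "CER_sw"
FIXTURE_RATES = np.array([0.004, 0.008])


def amniote_fixture(seed: int = 0, ambiguity_rate: float = 0.05) -> SimulatedDataset:
    """Generate the synthetic amniote dataset: 80 taxa (59 extinct, 21 extant).

    The topology nests random bifurcating blocks for each clade in a fixed
    amniote-like backbone, with two outgroup taxa outside the ingroup (removed
    before any ancestral-state work, the standard protocol).  Node ages
    descend geometrically from a ~340 Myr root; the amalgamated character
    evolves under the ``CER_sw`` model from an oviparous, parchment-shelled
    root; EER evolves independently as a binary character; viviparous tips are
    masked to eggshell-inapplicable; one mesosaur-style tip is coded
    ambiguously as either viviparous or oviparous with membrane-shelled eggs.
    """
    rng = np.random.default_rng(seed)
    labels: dict[str, list[str]] = {}
    extant: set[str] = set()
    for name, n_ext, n_liv in FIXTURE_BLOCKS:
        block = [f"{name}_f{i+1}" for i in range(n_ext)] + \
                [f"{name}_x{i+1}" for i in range(n_liv)]
        labels[name] = block
        extant.update(f"{name}_x{i+1}" for i in range(n_liv))

    def blk(name):
        ls = labels[name]
        return ls[0] if len(ls) == 1 else _random_clade_topology(ls, rng)

    lepidosauria = f"({blk('Rhynchocephalia')},{blk('Squamata')})"
    marine = f"({blk('Ichthyosauria')},{blk('Sauropterygia')})"
    archosauria = f"(({blk('Crocodylia')},({blk('Dinosauria')},{blk('Aves')})),{blk('Pterosauria')})"
    archosauromorpha = f"(({blk('Choristodera')},{blk('Protorosauria')}),{archosauria})"
    diapsida = f"(({marine},{blk('Testudinata')}),({lepidosauria},{archosauromorpha}))"
    amniota = f"({blk('Mammalia')},({blk('Mesosauridae')},{diapsida}))"
    newick = f"({OUTGROUP_TAXA[0]},({OUTGROUP_TAXA[1]},{amniota}));"

    full = TimeTree.from_newick(newick)
    # geometric age cascade from a Carboniferous-age root
    ages: dict = {}
    root = full.dtree.seed_node
    ages[root] = 340.0
    for nd in full.dtree.preorder_node_iter():
        if nd is root:
            continue
        pa = ages[nd.parent_node]
        if nd.is_leaf():
            ages[nd] = 0.0 if nd.taxon.label in extant else pa * rng.uniform(0.3, 0.9)
        else:
            ages[nd] = pa * rng.uniform(0.6, 0.95)
    full.tip_ages = {lf.taxon.label: ages[lf] for lf in full.dtree.leaf_node_iter()}
    full._set_ages(ages)

    from .treetime import drop_taxa  # local import to avoid cycle at module load
    ingroup = drop_taxa(full, OUTGROUP_TAXA)

    spec = build_generator(FIXTURE_MODEL)
    q = spec.bind(FIXTURE_RATES)
    space = build_space()
    root_state = space.index("oviparous", "parchment")
    hist = simulate_history(ingroup, q, root_state=root_state,
                            seed=int(rng.integers(2**31)))
    eer_q = build_generator("EER_ER").bind(np.array([0.003]))
    eer_hist = simulate_history(ingroup, eer_q, root_state=0,
                                seed=int(rng.integers(2**31)))

    mesosaur = labels["Mesosauridae"][0]
    codings = []
    for taxon in sorted(ingroup.leaf_labels()):
        if taxon == mesosaur:
            # either viviparous, or oviparous with membrane-shelled eggs
            codings.append(CharacterCoding(
                taxon, frozenset(("oviparous", "viviparous")),
                frozenset(["membrane"]),
                frozenset([EER_STATES[eer_hist.tip_states[taxon]]])))
            continue
        codings.append(mask_observation(
            hist.tip_states[taxon], ambiguity_rate=ambiguity_rate,
            seed=int(rng.integers(2**31)), taxon=taxon,
            eer_state=EER_STATES[eer_hist.tip_states[taxon]]))

    intervals = make_intervals(ingroup, window=5.0, seed=int(rng.integers(2**31)))
    clades = {name: ls for name, ls in labels.items()}
    clades["Amniota"] = sorted(ingroup.leaf_labels())
    clades["Lepidosauria"] = labels["Rhynchocephalia"] + labels["Squamata"]
    return SimulatedDataset(
        tree=ingroup, tree_with_outgroups=full,
        node_states=hist.node_states, tip_states=hist.tip_states,
        codings=codings, intervals=intervals, clades=clades,
        model=FIXTURE_MODEL, rates=FIXTURE_RATES.copy(), seed=seed,
        ambiguous_taxon=mesosaur,
    )


# ---------------------------------------------------------------------------
# Recovery harness
# ---------------------------------------------------------------------------

def recovery_experiment(model: str = "ER_ind", rates=(0.25,), tree_size: int = 64,
                        n_chars: int = 500, seed=None,
                        birth: float = 0.06, death: float = 0.02) -> dict:
    """Simulate, mask, time-scale, fit and reconstruct; score against the truth.

    One birth–death tree of ``tree_size`` tips is drawn, rescaled to unit
    height, and ``n_chars`` independent characters are evolved under the named
    model.  The model is refit by ML on the masked observations and marginal
    ancestral states are computed at the fitted rates; reported are the rate
    estimates, their relative errors, and the frequency with which the
    maximum-marginal root state equals the true simulated root state.
    """
    from .mk_inference import fit_mk, marginal_asr  # deferred: avoid import cycle
    from .statespace import tip_prior
    from .treetime import rescale_tree

    rng = np.random.default_rng(seed)
    rates = np.asarray(rates, dtype=float)
    spec = build_generator(model)
    if rates.shape != (spec.k,):
        raise ValueError(f"{model} needs {spec.k} rates")
    tree = simulate_tree(birth, death, tree_size, seed=int(rng.integers(2**31)))
    tree = rescale_tree(tree, "unit_height")
    q = spec.bind(rates)

    histories = [simulate_history(tree, q, seed=int(rng.integers(2**31)))
                 for _ in range(n_chars)]
    # observed tip priors: (n_chars, n_states) per taxon after masking
    tip_priors: dict[str, np.ndarray] = {}
    for taxon in tree.leaf_labels():
        mat = np.zeros((n_chars, spec.n_states))
        for ci, h in enumerate(histories):
            if spec.n_states == 6:
                coding = mask_observation(h.tip_states[taxon], 0.0, taxon=taxon)
                mat[ci] = tip_prior(coding)
            else:
                mat[ci, h.tip_states[taxon]] = 1.0
        tip_priors[taxon] = mat

    fit = fit_mk(tree, tip_priors, spec, n_restarts=4, max_iter=500,
                 seed=int(rng.integers(2**31)))
    q_hat = spec.bind(fit.rates)
    margs = marginal_asr(tree, tip_priors, q_hat)
    root_clade = frozenset(tree.leaf_labels())
    root_marg = np.atleast_2d(margs[root_clade])
    true_roots = np.array([h.root_state for h in histories])
    top = root_marg.argmax(axis=1)
    strict = (top == true_roots).mean()
    if spec.n_states == 6:
        # the eggshell component of a viviparous root is structurally hidden
        # (every tip masks it), so recovery is scored on the observable
        # components: reproduction always, eggshell only for oviparous roots
        same_repro = (top // 3) == (true_roots // 3)
        recovered = np.where(true_roots < 3, top == true_roots, same_repro).mean()
    else:
        recovered = strict

    rel_err = np.abs(fit.rates - rates) / rates
    return {
        "model": model,
        "true_rates": rates,
        "rates_hat": fit.rates,
        "relative_error": rel_err,
        "rate_rmse": float(np.sqrt(np.mean((fit.rates - rates) ** 2))),
        "root_recovery_frequency": float(recovered),
        "root_recovery_strict": float(strict),
        "loglik": fit.loglik,
        "n_chars": n_chars,
        "tree_size": tree_size,
        "seed": seed,
    }
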