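"""Time-scaled trees: I/O, a posteriori time-scaling, calibrations, tree surgery.

Trees are rooted; ages are in Myr before present (larger = older) and edges
store non-negative durations, matching the semantics of stratigraphic first
and last appearance dates (FAD/LAD).  A topology with sampled tip ages is
turned into a time tree by one of two a posteriori time-scaling methods:

``mbl``
    node ages are initialised at the oldest descendant tip age, then ancestors
    are pushed back until every edge lasts at least ``vartime`` Myr.
``equal``
    the root is extended back by ``vartime`` and zero-duration edges acquire
    positive duration by taking an equal share of the span down from the
    nearest ancestral positive-duration edge.

Both leave tip ages untouched and are deterministic given tip ages; the only
random element of a tree sample is the uniform draw of each tip age from its
[LAD, FAD] interval.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

_ZERO = 1e-12


@dataclass(frozen=True)
class OccurrenceInterval:
    """Stratigraphic range of one taxon: FAD >= LAD >= 0, ages in Myr."""

    taxon: str
    fad: float
    lad: float
    extant: bool = False

    def __post_init__(self) -> None:
        if not (self.fad >= self.lad >= 0):
            raise ValueError(f"{self.taxon}: need fad >= lad >= 0, got {self.fad}, {self.lad}")


def read_occurrences(path) -> list[OccurrenceInterval]:
    """Read an occurrence CSV with columns taxon, fad, lad, extant."""
    df = pd.read_csv(path)
    required = {"taxon", "fad", "lad", "extant"}
    if not required <= set(df.columns):
        raise ValueError(f"occurrence CSV needs columns {sorted(required)}")
    return [
        OccurrenceInterval(str(r.taxon), float(r.fad), float(r.lad), bool(r.extant))
        for r in df.itertuples()
    ]


def write_occurrences(intervals: list[OccurrenceInterval], path) -> None:
    pd.DataFrame(
        [(iv.taxon, iv.fad, iv.lad, iv.extant) for iv in intervals],
        columns=["taxon", "fad", "lad", "extant"],
    ).to_csv(path, index=False)


class TimeTree:
    """A rooted tree whose edges carry durations (Myr) and tips carry ages.

    Node ages are derived: age(tip) comes from ``tip_ages`` (default 0,
    i.e. extant) and age(internal) = max over children of child age plus the
    child edge's duration.
    """

    def __init__(self, dtree: dendropy.Tree, tip_ages: dict[str, float] | None = None):
        self.dtree = dtree
        labels = self.leaf_labels()
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate tip labels: {dupes}")
        self.tip_ages: dict[str, float] = {l: 0.0 for l in labels}
        if tip_ages:
            unknown = set(tip_ages) - set(labels)
            if unknown:
                raise KeyError(f"tip ages for taxa not in tree: {sorted(unknown)}")
            self.tip_ages.update({k: float(v) for k, v in tip_ages.items()})

    # -- construction ------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str, tip_ages: dict[str, float] | None = None) -> "TimeTree":
        dtree = _parse(io.StringIO(newick), "newick")
        return cls(dtree, tip_ages)

    def copy(self) -> "TimeTree":
        return TimeTree(self.dtree.clone(depth=1), dict(self.tip_ages))

    # -- queries -----------------------------------------------------------

    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.dtree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self.dtree.leaf_nodes())

    def has_lengths(self) -> bool:
        return all(
            nd.edge.length is not None
            for nd in self.dtree.preorder_node_iter()
            if nd.parent_node is not None
        )

    def node_ages(self) -> dict[dendropy.Node, float]:
        """Per-node age in Myr before present, derived from durations + tip ages."""
        if not self.has_lengths():
            raise ValueError("tree has no edge durations; time-scale it first")
        ages: dict[dendropy.Node, float] = {}
        for nd in self.dtree.postorder_node_iter():
            if nd.is_leaf():
                ages[nd] = self.tip_ages[nd.taxon.label]
            else:
                ages[nd] = max(ages[c] + c.edge.length for c in nd.child_nodes())
        return ages

    def height(self) -> float:
        """Maximum root-to-tip path length (root age minus youngest tip age)."""
        ages = self.node_ages()
        root_age = ages[self.dtree.seed_node]
        return root_age - min(self.tip_ages.values())

    def edge_durations(self) -> dict[frozenset, float]:
        """Durations keyed by the clade (tip-label set) below each edge."""
        out = {}
        for nd in self.dtree.postorder_node_iter():
            if nd.parent_node is not None:
                out[self.clade_of(nd)] = float(nd.edge.length)
        return out

    def clade_of(self, node: dendropy.Node) -> frozenset:
        return frozenset(lf.taxon.label for lf in node.leaf_iter())

    def clade_map(self) -> dict[frozenset, dendropy.Node]:
        return {self.clade_of(nd): nd for nd in self.dtree.postorder_node_iter()}

    def mrca(self, labels) -> dendropy.Node:
        labels = set(labels)
        for nd in self.dtree.postorder_node_iter():
            if labels <= self.clade_of(nd):
                return nd
        raise KeyError(f"no node contains {sorted(labels)}")

    # -- output ------------------------------------------------------------

    def as_newick(self) -> str:
        return self.dtree.as_string(schema="newick", suppress_rooting=True).strip()

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.as_newick() + "\n")

    def _set_ages(self, ages: dict[dendropy.Node, float]) -> None:
        """Write edge durations from a consistent node-age assignment."""
        for nd in self.dtree.preorder_node_iter():
            if nd.parent_node is not None:
                nd.edge.length = ages[nd.parent_node] - ages[nd]
        self.dtree.seed_node.edge.length = None


def _parse(src, schema: str) -> dendropy.Tree:
    try:
        return dendropy.Tree.get(
            file=src, schema=schema, preserve_underscores=True, rooting="force-rooted"
        )
    except Exception as exc:  # dendropy raises several error types
        raise ValueError(f"malformed {schema} tree: {exc}") from exc


def read_tree(path, format: str = "newick", tip_ages: dict[str, float] | None = None) -> TimeTree:
    """Read a rooted tree from Newick or a NEXUS trees block."""
    if format not in ("newick", "nexus"):
        raise ValueError(f"format must be newick or nexus, got {format!r}")
    with open(path) as fh:
        return TimeTree(_parse(fh, format), tip_ages)


# ---------------------------------------------------------------------------
# Tip-date sampling and time-scaling
# ---------------------------------------------------------------------------

def sample_tip_dates(intervals, seed=None) -> dict[str, float]:
    """Draw each tip age uniformly on [LAD, FAD]; extant taxa at 0."""
    rng = np.random.default_rng(seed)
    ages = {}
    for iv in intervals:
        if iv.extant and iv.fad == iv.lad == 0:
            ages[iv.taxon] = 0.0
        else:
            ages[iv.taxon] = float(rng.uniform(iv.lad, iv.fad))
    return ages


def _require_tip_ages(tree: TimeTree, tip_ages: dict[str, float] | None) -> dict[str, float]:
    ages = dict(tree.tip_ages)
    if tip_ages:
        ages.update(tip_ages)
    missing = set(tree.leaf_labels()) - set(ages)
    if missing:
        raise KeyError(f"no age for tips {sorted(missing)}")
    return ages


def _naive_ages(tree: TimeTree, tip_ages: dict[str, float]) -> dict[dendropy.Node, float]:
    ages: dict[dendropy.Node, float] = {}
    for nd in tree.dtree.postorder_node_iter():
        if nd.is_leaf():
            ages[nd] = tip_ages[nd.taxon.label]
        else:
            ages[nd] = max(ages[c] for c in nd.child_nodes())
    return ages


def timescale_mbl(tree: TimeTree, tip_ages: dict[str, float] | None = None,
                  vartime: float = 1.0) -> TimeTree:
    """Minimum-branch-length time-scaling.

    Node ages start at the oldest descendant tip age; a tips-to-root pass then
    pushes each ancestor back until every edge lasts at least ``vartime``.
    """
    if vartime <= 0:
        raise ValueError("vartime must be positive")
    out = tree.copy()
    ages = _require_tip_ages(out, tip_ages)
    out.tip_ages = {l: ages[l] for l in out.leaf_labels()}
    node_age = _naive_ages(out, out.tip_ages)
    for nd in out.dtree.postorder_node_iter():
        if not nd.is_leaf():
            node_age[nd] = max(node_age[nd],
                               max(node_age[c] + vartime for c in nd.child_nodes()))
    out._set_ages(node_age)
    return out


def timescale_equal(tree: TimeTree, tip_ages: dict[str, float] | None = None,
                    vartime: float = 1.0) -> TimeTree:
    """Equal-share time-scaling.

    The root is pushed back by ``vartime``; each zero-duration edge then takes
    an equal share of the span from the nearest ancestral positive-duration
    edge down through the run of tied nodes.  All durations end positive and
    the root age equals the naive root age plus ``vartime``.
    """
    if vartime <= 0:
        raise ValueError("vartime must be positive")
    out = tree.copy()
    ages = _require_tip_ages(out, tip_ages)
    out.tip_ages = {l: ages[l] for l in out.leaf_labels()}
    node_age = _naive_ages(out, out.tip_ages)
    root = out.dtree.seed_node
    node_age[root] += vartime

    for v in out.dtree.preorder_node_iter():
        u = v.parent_node
        if u is None or node_age[u] - node_age[v] > _ZERO:
            continue
        # maximal run of tied nodes descending through v
        chain = [u, v]
        x = v
        while not x.is_leaf():
            tied = [c for c in x.child_nodes() if node_age[x] - node_age[c] <= _ZERO]
            if not tied:
                break
            x = tied[0]
            chain.append(x)
        if u.parent_node is not None:
            # donor edge above the parent is positive (fixed by top-down order);
            # split its span equally over itself and the run of zero edges
            top = u.parent_node
            movable = chain[:-1]  # u and interior nodes move older
        else:
            # parent is the root, already extended back by vartime
            top = u
            movable = chain[1:-1]
        span = node_age[top] - node_age[chain[-1]]
        m = len(movable) + 1  # edges sharing the span
        for i, nd in enumerate(movable, start=1):
            node_age[nd] = node_age[top] - (span / m) * i
    out._set_ages(node_age)
    return out


def rescale_tree(tree: TimeTree, mode: str = "unit_height", target: float | None = None) -> TimeTree:
    """Linearly rescale durations: to total height 1, or to a mean edge duration.

    Relative proportions are preserved; tip ages scale by the same factor so
    the tree remains internally consistent.
    """
    out = tree.copy()
    if mode == "unit_height":
        h = out.height()
        if h <= 0:
            raise ValueError("cannot rescale a zero-height tree")
        factor = 1.0 / h
    elif mode == "mean_bl":
        if target is None or target <= 0:
            raise ValueError("mean_bl rescaling needs a positive target")
        lengths = [nd.edge.length for nd in out.dtree.preorder_node_iter()
                   if nd.parent_node is not None]
        mean = float(np.mean(lengths))
        if mean <= 0:
            raise ValueError("cannot rescale a zero-length tree")
        factor = target / mean
    else:
        raise ValueError(f"mode must be unit_height or mean_bl, got {mode!r}")
    for nd in out.dtree.preorder_node_iter():
        if nd.parent_node is not None:
            nd.edge.length *= factor
    out.tip_ages = {k: v * factor for k, v in out.tip_ages.items()}
    return out


def anchor_ages(tree: TimeTree, anchor_taxon: str, anchor_age: float) -> TimeTree:
    """Affinely shift all ages so the anchor tip sits at its stated absolute age."""
    out = tree.copy()
    if anchor_taxon not in out.tip_ages:
        raise KeyError(f"anchor taxon {anchor_taxon!r} not in tree")
    shift = anchor_age - out.tip_ages[anchor_taxon]
    out.tip_ages = {k: v + shift for k, v in out.tip_ages.items()}
    return out


def sample_timescaled_trees(tree: TimeTree, intervals, method: str = "mbl",
                            vartime: float = 1.0, n_trees: int = 100,
                            seed=None) -> list[TimeTree]:
    """Generate a sample of time-scaled trees by resampling tip dates.

    Tip-date sampling is the only random element; the scalers themselves are
    deterministic.  Seeds for each draw derive from ``seed``.
    """
    scaler = {"mbl": timescale_mbl, "equal": timescale_equal}[method]
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_trees):
        ages = sample_tip_dates(intervals, rng)
        out.append(scaler(tree, ages, vartime))
    return out


# ---------------------------------------------------------------------------
# Calibration priors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CalibrationPrior:
    """Offset gamma node-calibration prior.

    Parametrized by shape, a hard minimum age (offset) and the prior standard
    deviation; scale = sd / sqrt(shape), so the distribution's s.d. equals
    ``sd`` and its mean is offset + shape * scale = offset + sqrt(shape) * sd.
    """

    shape: float
    offset: float
    sd: float

    def __post_init__(self) -> None:
        if self.shape <= 0 or self.sd <= 0:
            raise ValueError("shape and sd must be positive")

    @property
    def scale(self) -> float:
        return self.sd / np.sqrt(self.shape)

    @property
    def mean(self) -> float:
        return self.offset + self.shape * self.scale

    def _dist(self):
        return stats.gamma(self.shape, loc=self.offset, scale=self.scale)

    def pdf(self, x) -> np.ndarray:
        return self._dist().pdf(x)

    def sample(self, n: int, seed=None) -> np.ndarray:
        return self._dist().rvs(size=n, random_state=np.random.default_rng(seed))


def gamma_calibration(shape: float, offset: float, sd: float) -> CalibrationPrior:
    """Construct an offset gamma calibration prior (shape 3 in this pipeline)."""
    return CalibrationPrior(shape=shape, offset=offset, sd=sd)


# ---------------------------------------------------------------------------
# Tree surgery for robustness experiments
# ---------------------------------------------------------------------------

def drop_taxa(tree: TimeTree, taxa) -> TimeTree:
    """Remove tips; degree-2 nodes are suppressed with durations summed."""
    taxa = set(taxa)
    missing = taxa - set(tree.leaf_labels())
    if missing:
        raise KeyError(f"taxa not in tree: {sorted(missing)}")
    if len(taxa) >= tree.n_tips - 1:
        raise ValueError("cannot drop all but one tip")
    out = tree.copy()
    out.dtree.prune_taxa_with_labels(sorted(taxa), suppress_unifurcations=True)
    out.dtree.purge_taxon_namespace()
    out.tip_ages = {k: v for k, v in out.tip_ages.items() if k not in taxa}
    return out


def reattach_clade(tree: TimeTree, clade_tips, new_sister) -> TimeTree:
    """Detach a monophyletic clade and reattach it as sister to another taxon/clade.

    A topology operation: edge durations are discarded (the result is meant to
    be re-time-scaled).  The moved subtree is preserved intact.
    """
    clade_tips = frozenset(clade_tips)
    sister_tips = frozenset([new_sister] if isinstance(new_sister, str) else new_sister)
    if sister_tips & clade_tips:
        raise ValueError("new sister must lie outside the moved clade")
    out = tree.copy()
    for nd in out.dtree.preorder_node_iter():
        nd.edge.length = None

    cmap = out.clade_map()
    if clade_tips not in cmap:
        raise ValueError(f"clade {sorted(clade_tips)} is not monophyletic in this tree")
    clade = cmap[clade_tips]

    parent = clade.parent_node
    if parent is None:
        raise ValueError("cannot move the whole tree")
    parent.remove_child(clade)
    # suppress the resulting unifurcation
    if parent.num_child_nodes() == 1:
        only = parent.child_nodes()[0]
        grand = parent.parent_node
        parent.remove_child(only)
        if grand is None:
            out.dtree.seed_node = only
            only.parent_node = None
        else:
            grand.remove_child(parent)
            grand.add_child(only)

    cmap = out.clade_map()
    if sister_tips not in cmap:
        raise ValueError(f"sister {sorted(sister_tips)} is not a tip/monophyletic clade")
    sister = cmap[sister_tips]
    sparent = sister.parent_node
    joint = dendropy.Node()
    if sparent is None:
        out.dtree.seed_node = joint
    else:
        sparent.remove_child(sister)
        sparent.add_child(joint)
    joint.add_child(sister)
    joint.add_child(clade)
    out.dtree.update_bipartitions(suppress_unifurcations=True)
    return TimeTree(out.dtree, None)


def consensus_edge_lengths(trees: list[TimeTree]) -> TimeTree:
    """Average edge durations across a sample of trees sharing one topology."""
    if not trees:
        raise ValueError("empty tree sample")
    ref = trees[0]
    ref_clades = set(ref.edge_durations())
    sums = {c: 0.0 for c in ref_clades}
    for t in trees:
        durs = t.edge_durations()
        if set(durs) != ref_clades:
            raise ValueError("trees do not share a topology")
        for c, d in durs.items():
            sums[c] += d
    out = ref.copy()
    n = len(trees)
    for nd in out.dtree.postorder_node_iter():
        if nd.parent_node is not None:
            nd.edge.length = sums[out.clade_of(nd)] / n
    out.tip_ages = {
        l: float(np.mean([t.tip_ages[l] for t in trees])) for l in ref.leaf_labels()
    }
    return out
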