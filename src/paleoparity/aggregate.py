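"""Model selection, multi-tree aggregation and the exhaustive analysis grid.

AIC selects among the fitted models; the "near-best" set collects every model
within 2 AIC units of the best, and reported ancestral-state summaries span
that set as a min–max range around the mean marginal across the tree sample
(the style of result such analyses print, e.g. "viviparity: 99.5–100%").

Clades are addressed by tip-label sets, never node indices, so summaries
survive tree-sample variation and re-serialization.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .mk_inference import FitResult, NodeMarginals, fit_mk, marginal_asr
from .statespace import build_generator, build_space, tip_prior, eer_tip_prior
from .treetime import TimeTree, rescale_tree

AIC_NEAR_BEST_DELTA = 2.0


@dataclass
class ModelComparison:
    """Per-model fits, the best model, and the near-best (ΔAIC < 2) set."""

    fits: dict[str, FitResult]
    best: str
    near_best: list[str]

    def table(self) -> pd.DataFrame:
        rows = [{"model": m, "k": f.k, "loglik": f.loglik, "aic": f.aic,
                 "delta_aic": f.aic - self.fits[self.best].aic,
                 "near_best": m in self.near_best}
                for m, f in sorted(self.fits.items(), key=lambda kv: kv[1].aic)]
        return pd.DataFrame(rows)


def aic_select(fits) -> ModelComparison:
    """Rank fits by AIC; near-best = models with AIC − min(AIC) < 2."""
    if not fits:
        raise ValueError("no fits to select among")
    fit_map = {f.model: f for f in fits} if not isinstance(fits, dict) else dict(fits)
    best = min(fit_map, key=lambda m: fit_map[m].aic)
    near = [m for m, f in fit_map.items()
            if f.aic - fit_map[best].aic < AIC_NEAR_BEST_DELTA]
    near.sort(key=lambda m: fit_map[m].aic)
    return ModelComparison(fits=fit_map, best=best, near_best=near)


@dataclass
class AncestralSummary:
    """Per-clade mean marginal states across trees, with per-state ranges
    across a model set."""

    clade_means: dict[str, np.ndarray]              # clade name -> mean vector
    clade_ranges: dict[str, np.ndarray] | None = None  # clade -> (2, S) min/max
    state_labels: tuple[str, ...] | None = None
    n_trees: int = 0
    models: list[str] = field(default_factory=list)

    def percent(self, clade: str, state: int) -> str:
        """Format one cell the way results are quoted, e.g. '99.5–100%'."""
        if self.clade_ranges is None:
            return f"{100 * self.clade_means[clade][state]:.1f}%"
        lo, hi = self.clade_ranges[clade][:, state] * 100
        return f"{lo:.1f}–{hi:.1f}%"

    def table(self) -> pd.DataFrame:
        labels = self.state_labels or tuple(
            f"state_{i}" for i in range(len(next(iter(self.clade_means.values())))))
        rows = []
        for clade, vec in self.clade_means.items():
            row = {"clade": clade}
            for i, lab in enumerate(labels):
                row[lab] = vec[i]
                if self.clade_ranges is not None:
                    row[f"{lab}_min"] = self.clade_ranges[clade][0, i]
                    row[f"{lab}_max"] = self.clade_ranges[clade][1, i]
            rows.append(row)
        return pd.DataFrame(rows)


def aggregate_marginals(per_tree: list[NodeMarginals], clades: dict[str, list[str]],
                        state_labels=None) -> AncestralSummary:
    """Node-wise arithmetic mean of marginals across a tree sample.

    All trees must share the topology (clades are located by tip set); a clade
    missing from the marginals raises.
    """
    if not per_tree:
        raise ValueError("no marginals to aggregate")
    means = {}
    for name, tips in clades.items():
        key = frozenset(tips)
        try:
            vecs = [np.asarray(m[key]) for m in per_tree]
        except KeyError:
            raise KeyError(f"clade {name!r} (tips {sorted(tips)[:4]}...) not in topology")
        means[name] = np.mean(vecs, axis=0)
    labels = state_labels or per_tree[0].state_labels
    return AncestralSummary(clade_means=means, state_labels=labels,
                            n_trees=len(per_tree))


def summarize_model_range(per_model: dict[str, AncestralSummary]) -> AncestralSummary:
    """Combine summaries of several models into per-state min–max ranges.

    Feed it the near-best model set for headline ranges, or all fitted models
    for sensitivity reporting.
    """
    if not per_model:
        raise ValueError("no model summaries")
    models = sorted(per_model)
    first = per_model[models[0]]
    means, ranges = {}, {}
    for clade in first.clade_means:
        stack = np.stack([per_model[m].clade_means[clade] for m in models])
        means[clade] = stack.mean(axis=0)
        ranges[clade] = np.stack([stack.min(axis=0), stack.max(axis=0)])
    return AncestralSummary(clade_means=means, clade_ranges=ranges,
                            state_labels=first.state_labels,
                            n_trees=first.n_trees, models=models)


# ---------------------------------------------------------------------------
# The analysis grid
# ---------------------------------------------------------------------------

@dataclass
class GridConfig:
    """One multiplicative analysis grid: tree samples x models x methods.

    ``tree_samples`` maps a scaling label (e.g. 'mbl', 'equal') to a list of
    time trees sharing the topology; ``exclusions`` maps a variant label to
    taxa dropped before analysis ('' / empty list = full data).
    """

    tree_samples: dict[str, list[TimeTree]]
    codings: list
    clades: dict[str, list[str]]
    models: list[str] = field(default_factory=lambda: ["ER_ind", "ER_sw"])
    methods: list[str] = field(default_factory=lambda: ["ml"])
    exclusions: dict[str, list[str]] = field(default_factory=lambda: {"all_taxa": []})
    n_restarts: int = 4
    max_iter: int = 500
    seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps({
            "scalings": sorted(self.tree_samples),
            "n_trees": {k: len(v) for k, v in self.tree_samples.items()},
            "models": self.models, "methods": self.methods,
            "exclusions": {k: sorted(v) for k, v in self.exclusions.items()},
            "taxa": sorted(c.taxon for c in self.codings),
            "n_restarts": self.n_restarts, "max_iter": self.max_iter,
            "seed": self.seed,
        }, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_grid(config: GridConfig, out_dir=None) -> pd.DataFrame:
    """Execute every grid cell; archive per-cell JSON; resume on rerun.

    A cell is one (scaling, exclusion, model, method): ML cells fit the model
    on every tree of the sample and average marginals; MP cells run the
    parsimony battery per tree.  Failures are recorded (column ``error``) and
    the grid continues.  With ``out_dir`` given, finished cells found on disk
    are not recomputed.
    """
    from .parsimony import parsimony_suite  # deferred import

    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    space = build_space()
    rows = []
    rng = np.random.default_rng(config.seed)
    for scaling, trees in sorted(config.tree_samples.items()):
        for excl_name, dropped in sorted(config.exclusions.items()):
            use_codings = [c for c in config.codings if c.taxon not in set(dropped)]
            use_trees = trees
            if dropped:
                from .treetime import drop_taxa
                use_trees = [drop_taxa(t, dropped) for t in trees]
            priors = {c.taxon: tip_prior(c, space) for c in use_codings}
            eer_priors = {c.taxon: eer_tip_prior(c) for c in use_codings}
            for model in config.models:
                for method in config.methods:
                    cell_id = f"{scaling}.{excl_name}.{model}.{method}"
                    cell_seed = int(rng.integers(2**31))
                    cell_file = (out_path / f"{chash}.{cell_id}.json"
                                 if out_path is not None else None)
                    if cell_file is not None and cell_file.exists():
                        rows.append(json.loads(cell_file.read_text()))
                        continue
                    record = {"cell": cell_id, "config_hash": chash,
                              "seed": cell_seed, "n_trees": len(use_trees),
                              "error": ""}
                    try:
                        record.update(_run_cell(use_trees, model, method, priors,
                                                eer_priors, use_codings,
                                                config, cell_seed))
                    except Exception as exc:  # grid continues past cell failures
                        record["error"] = f"{type(exc).__name__}: {exc}"
                    rows.append(record)
                    if cell_file is not None:
                        cell_file.write_text(json.dumps(record, sort_keys=True))
    df = pd.DataFrame(rows)
    df = df.reindex(sorted(df.columns), axis=1).sort_values("cell").reset_index(drop=True)
    if out_path is not None:
        df.to_csv(out_path / f"{chash}.summary.tsv", sep="\t", index=False)
    return df


def _run_cell(trees, model, method, priors, eer_priors, codings, config, cell_seed):
    spec = build_generator(model)
    use_priors = eer_priors if model.startswith("EER") else priors
    if method == "ml":
        logliks, aics = [], []
        for tree in trees:
            t1 = rescale_tree(tree, "unit_height")
            fit = fit_mk(t1, use_priors, spec, n_restarts=config.n_restarts,
                         max_iter=config.max_iter, seed=cell_seed)
            logliks.append(fit.loglik)
            aics.append(fit.aic)
        return {"mean_loglik": float(np.mean(logliks)),
                "mean_aic": float(np.mean(aics)), "k": spec.k}
    if method == "mp":
        from .parsimony import parsimony_suite
        key = "EER_ACCTRAN" if model.startswith("EER") else \
            ("MPR_sw" if model.endswith("_sw") else "MPR_ind")
        costs = [parsimony_suite(tree, codings)[key].total_cost for tree in trees]
        return {"mean_cost": float(np.mean(costs)), "parsimony_model": key}
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# Minimal plotting
# ---------------------------------------------------------------------------

def plot_node_pies(tree: TimeTree, marginals: NodeMarginals, ax=None, colors=None):
    """Basic time-tree plot with marginal-state pies at internal nodes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 0.3 * tree.n_tips + 1))
    ages = tree.node_ages()
    ys: dict = {}
    for i, lf in enumerate(tree.dtree.leaf_node_iter()):
        ys[lf] = i
    for nd in tree.dtree.postorder_node_iter():
        if not nd.is_leaf():
            ys[nd] = np.mean([ys[c] for c in nd.child_nodes()])
    for nd in tree.dtree.preorder_node_iter():
        if nd.parent_node is not None:
            ax.plot([-ages[nd.parent_node], -ages[nd]], [ys[nd], ys[nd]], c="k", lw=0.8)
            ax.plot([-ages[nd.parent_node]] * 2, [ys[nd.parent_node], ys[nd]],
                    c="k", lw=0.8)
        if nd.is_leaf():
            ax.text(-ages[nd], ys[nd], " " + nd.taxon.label, va="center", fontsize=7)
    n_states = len(next(iter(marginals.marginals.values())))
    colors = colors or plt.get_cmap("tab10").colors[:n_states]
    span = max(a for a in ages.values()) or 1.0
    for clade, vec in marginals.marginals.items():
        nd = tree.clade_map()[clade]
        start = 0.0
        for s, p in enumerate(np.asarray(vec)):
            ax.add_patch(plt.matplotlib.patches.Wedge(
                (-ages[nd], ys[nd]), 0.012 * span, 360 * start, 360 * (start + p),
                color=colors[s], zorder=3))
            start += p
    ax.set_xlabel("age (Myr before present)")
    ax.set_yticks([])
    return ax
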