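"""Fixed-dimension Bayesian inference for the SMM and EER models.

Metropolis–Hastings over transition rates (multiplicative log-scale
proposals), stepping-stone estimation of the marginal likelihood, effective
sample sizes and log Bayes factors.  Single-rate models (ER_ind, ER_sw,
EER_ER) take a uniform(0, 10) rate prior;
multi-rate models take independent exponential priors with mean 10, a
fixed-prior simplification of the hierarchical exponential hyperprior
(recorded in every trace's metadata).

The sampler is fixed-dimension: the model set itself carries the rate
partitions, so reverse-jump moves over partitions are unnecessary for model
comparison by marginal likelihood, and the chain remains easy to verify
against closed forms and quadrature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import arviz as az
import numpy as np

from .mk_inference import marginal_asr, prune_loglik, NodeMarginals
from .statespace import GeneratorSpec
from .treetime import TimeTree

PRIOR_NOTE = (
    "fixed-dimension MH; multi-rate priors simplified to iid exponential(mean 10) "
    "in place of a hierarchical exponential hyperprior"
)


@dataclass(frozen=True)
class PriorSpec:
    """Independent per-rate prior: 'uniform' on (0, bound) or 'exponential' mean."""

    kind: str
    param: float  # upper bound (uniform) or mean (exponential)
    k: int

    def logpdf(self, rates: np.ndarray) -> float:
        rates = np.asarray(rates, dtype=float)
        if np.any(rates <= 0):
            return -np.inf
        if self.kind == "uniform":
            if np.any(rates >= self.param):
                return -np.inf
            return -self.k * np.log(self.param)
        if self.kind == "exponential":
            return float(-self.k * np.log(self.param) - rates.sum() / self.param)
        raise ValueError(self.kind)

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "uniform":
            return rng.uniform(0, self.param, size=self.k)
        return rng.exponential(self.param, size=self.k)

    @property
    def mean(self) -> float:
        return self.param / 2 if self.kind == "uniform" else self.param


def make_priors(spec: GeneratorSpec) -> PriorSpec:
    """Transition-rate prior for a model: uniform(0,10) if single-rate, else
    exponential(mean 10) per rate."""
    if spec.k == 1:
        return PriorSpec("uniform", 10.0, 1)
    return PriorSpec("exponential", 10.0, spec.k)


@dataclass
class McmcConfig:
    """Chain settings.  Full-scale production values are 11,000,000 iterations,
    sampling every 10,000, 1,000,000 burn-in and 3 chains; the defaults here
    are scaled down for desk-size analyses."""

    iterations: int = 20000
    sample_interval: int = 10
    burn_in: int = 2000
    chains: int = 1
    step_sd: float = 0.5
    seed: object = None

    FULL_SCALE = dict(iterations=11_000_000, sample_interval=10_000,
                       burn_in=1_000_000, chains=3)

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in < self.iterations):
            raise ValueError("need 0 <= burn_in < iterations")


@dataclass
class McmcTrace:
    rates: np.ndarray          # (n_samples, k)
    logliks: np.ndarray        # (n_samples,)
    acceptance_rate: float
    seed: object
    model: str
    note: str = PRIOR_NOTE


def _loglik_fn(tree, tip_priors, spec, root_prior, constraints):
    if tip_priors is None:  # flat likelihood: prior-only target
        return lambda rates: 0.0
    return lambda rates: prune_loglik(tree, tip_priors, spec.bind(rates),
                                      root_prior=root_prior, constraints=constraints)


def _mh_chain(loglik, prior: PriorSpec, config: McmcConfig, rng,
              power: float = 1.0, init: np.ndarray | None = None,
              max_init_tries: int = 100):
    """Core MH loop on log-rates with multiplicative proposals.

    The target is power * loglik + logprior (power posteriors feed the
    stepping-stone sampler).  Returns (samples, logliks, acceptance, final state).
    """
    k = prior.k
    if init is None:
        for _ in range(max_init_tries):
            cand = prior.sample(rng)
            if np.isfinite(loglik(cand)) or power == 0.0:
                init = cand
                break
        else:
            raise RuntimeError("could not find a starting point with positive likelihood")
    x = np.asarray(init, dtype=float)
    ll = loglik(x)
    lp = prior.logpdf(x)
    samples, lls = [], []
    accepted = 0
    for it in range(1, config.iterations + 1):
        prop = x * np.exp(rng.normal(0.0, config.step_sd, size=k))
        lp_prop = prior.logpdf(prop)
        if np.isfinite(lp_prop):
            ll_prop = loglik(prop)
            # multiplicative proposal: Jacobian term sum(log prop - log x)
            log_alpha = (power * ll_prop + lp_prop) - (power * ll + lp) \
                + float(np.sum(np.log(prop) - np.log(x)))
            if np.log(rng.random()) < log_alpha:
                x, ll, lp = prop, ll_prop, lp_prop
                accepted += 1
        if it > config.burn_in and (it - config.burn_in) % config.sample_interval == 0:
            samples.append(x.copy())
            lls.append(ll)
    return np.array(samples), np.array(lls), accepted / config.iterations, x


def run_mcmc(tree: TimeTree | None, tip_priors, spec: GeneratorSpec,
             config: McmcConfig | None = None, constraints=None,
             root_prior="flat", prior: PriorSpec | None = None) -> McmcTrace:
    """Sample the posterior over a model's transition rates.

    ``tip_priors=None`` gives a flat likelihood (posterior = prior), the
    standard sanity check.  Trees should be rescaled to a mean branch length
    of 0.01 before full-scale runs so rates sit well inside the prior.
    """
    config = config or McmcConfig()
    prior = prior or make_priors(spec)
    rng = np.random.default_rng(config.seed)
    loglik = _loglik_fn(tree, tip_priors, spec, root_prior, constraints)
    samples, lls, acc, _ = _mh_chain(loglik, prior, config, rng)
    return McmcTrace(rates=samples, logliks=lls, acceptance_rate=acc,
                     seed=config.seed, model=spec.name)


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------

def ess(trace, combined: bool = False) -> float:
    """Autocorrelation-based effective sample size.

    ``trace`` is a 1-D array (one chain) or 2-D (chains x draws) with
    ``combined=True``.  A constant trace has no information; its ESS is
    reported as 1 with a warning.
    """
    arr = np.asarray(trace, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    elif not combined:
        raise ValueError("pass combined=True for multi-chain input")
    if np.allclose(arr, arr.flat[0]):
        warnings.warn("constant trace: ESS undefined, reporting minimal value 1")
        return 1.0
    return float(az.ess(az.convert_to_dataset(arr))["x"].values)


# ---------------------------------------------------------------------------
# Marginal likelihood and model comparison
# ---------------------------------------------------------------------------

@dataclass
class SteppingStoneResult:
    powers: np.ndarray          # strictly increasing in (0, 1]
    contributions: np.ndarray   # per-stone log ratio estimates
    log_marginal_likelihood: float
    seed: object
    model: str | None = None


def stepping_stone(tree: TimeTree | None, tip_priors, spec: GeneratorSpec,
                   n_stones: int = 32, iters_per_stone: int = 2000, seed=None,
                   root_prior="flat", constraints=None,
                   prior: PriorSpec | None = None, step_sd: float = 0.5,
                   alpha: float = 0.4) -> SteppingStoneResult:
    """Stepping-stone estimate of the log marginal likelihood.

    Powers sit at quantiles of Beta(alpha, 1) (alpha = 0.4, the standard
    choice, clustering stones near the prior).  Each stone reuses the previous
    stone's final state, runs a short burn-in, and contributes
    log mean exp((beta_j - beta_{j-1}) * logL) under the beta_{j-1} power
    posterior.  ``tip_priors=None`` means likelihood ≡ 1, whose true log
    marginal likelihood is 0.
    """
    if n_stones < 2:
        raise ValueError("need at least 2 stones")
    prior = prior or make_priors(spec)
    rng = np.random.default_rng(seed)
    loglik = _loglik_fn(tree, tip_priors, spec, root_prior, constraints)
    powers = (np.arange(n_stones + 1) / n_stones) ** (1.0 / alpha)

    burn = max(iters_per_stone // 5, 1)
    cfg = McmcConfig(iterations=iters_per_stone + burn, sample_interval=1,
                     burn_in=burn, step_sd=step_sd)
    contributions = np.zeros(n_stones)
    state = prior.sample(rng)
    for j in range(n_stones):
        beta_prev, beta = powers[j], powers[j + 1]
        samples, lls, _, state = _mh_chain(loglik, prior, cfg, rng,
                                           power=beta_prev, init=state)
        delta = (beta - beta_prev) * lls
        if not np.all(np.isfinite(delta)):
            raise FloatingPointError(f"non-finite contribution at stone {j}")
        m = delta.max()
        contributions[j] = m + np.log(np.mean(np.exp(delta - m)))
    return SteppingStoneResult(
        powers=powers[1:], contributions=contributions,
        log_marginal_likelihood=float(contributions.sum()),
        seed=seed, model=spec.name,
    )


def log_bf(lnml_complex: float, lnml_simple: float) -> float:
    """Log Bayes factor, 2 * (lnML_complex − lnML_simple).

    The simple comparators in this pipeline are ER_sw for the amalgamated
    models and EER_ER for the EER models.
    """
    return 2.0 * (lnml_complex - lnml_simple)


def posterior_asr(trace: McmcTrace, tree: TimeTree, tip_priors,
                  spec: GeneratorSpec, root_prior="flat", constraints=None,
                  thin: int = 1) -> NodeMarginals:
    """Posterior-mean marginal ancestral states: per-sample marginals averaged
    over the (optionally thinned) post-burn-in trace."""
    if len(trace.rates) == 0:
        raise ValueError("empty trace")
    used = trace.rates[::thin]
    acc: dict[frozenset, np.ndarray] = {}
    labels = None
    for rates in used:
        m = marginal_asr(tree, tip_priors, spec.bind(rates),
                         root_prior=root_prior, constraints=constraints)
        labels = m.state_labels
        for clade, vec in m.marginals.items():
            acc[clade] = acc.get(clade, 0.0) + vec
    out = {clade: vec / len(used) for clade, vec in acc.items()}
    return NodeMarginals(out, labels)


def combine_traces(traces: list[McmcTrace]) -> McmcTrace:
    """Pool post-burn-in samples of independent chains of the same model."""
    if len({t.model for t in traces}) != 1:
        raise ValueError("traces come from different models")
    return McmcTrace(
        rates=np.concatenate([t.rates for t in traces]),
        logliks=np.concatenate([t.logliks for t in traces]),
        acceptance_rate=float(np.mean([t.acceptance_rate for t in traces])),
        seed=[t.seed for t in traces],
        model=traces[0].model,
    )
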