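"""Metropolis-coupled MCMC over fossil attachment, branch lengths and
gamma shape, with the backbone topology held fixed.

The state of one chain is (attachment edge, backbone branch lengths,
pendant branch length, gamma shape α).  Moves:

  (a) re-attachment — propose a uniformly random backbone edge, re-split
      it at its midpoint, keep the pendant length (symmetric proposal);
  (b) branch-length scaler — multiply one random length (a backbone edge
      or the pendant) by exp(δ(u - 1/2));
  (c) α scaler — the same multiplier kernel on the gamma shape.

Acceptance uses the Metropolis ratio on prior x likelihood^β with the
incremental heating β_i = 1/(1 + λ(i-1)); one swap between a random
adjacent chain pair is attempted every generation; only the cold chain
is recorded.  Priors: uniform over attachment edges, iid exponential on
branch lengths, exponential on α.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .matrices import CharacterMatrix, validate_compatibility
from .mk import MkParams, matrix_log_likelihood
from .splits import splits_from_attachment
from .trees import EdgeRef, Phylogeny

__all__ = [
    "SamplerConfig",
    "TraceSet",
    "RunTrace",
    "Sample",
    "PosteriorSample",
    "chain_temperature",
    "mcmc_run",
    "combine_runs",
    "placement_posterior",
    "asdsf",
    "mc_standard_error",
]

#: study-scale generation count; tests and smoke runs use TEST_GENERATIONS
STUDY_GENERATIONS = 1_000_000
TEST_GENERATIONS = 10_000


@dataclass(frozen=True)
class SamplerConfig:
    """Run design and priors; the defaults reproduce the study design
    (2 runs x 4 chains, one cold, 10^6 generations, 25% burn-in)."""

    n_generations: int = STUDY_GENERATIONS
    n_runs: int = 2
    n_chains: int = 4
    heating_lambda: float = 0.1
    sample_every: int = 100
    burn_in_fraction: float = 0.25
    seed: int = 0
    # priors
    branch_length_rate: float = 10.0   # exponential prior rate on lengths
    alpha_rate: float = 1.0            # exponential prior rate on gamma shape
    # proposal tuning (fixed, no auto-tuning)
    multiplier_delta: float = 2.0 * math.log(1.5)
    # model
    n_rate_categories: int = 4
    ascertainment: str = "variable"    # "variable" or "none"
    # initial values
    initial_pendant_length: float = 0.1
    initial_alpha: float = 1.0
    # restrictions (diagnostics / validation runs)
    prior_only: bool = False
    sample_lengths: bool = True
    sample_alpha: bool = True

    def __post_init__(self):
        if self.n_generations < 1 or self.n_runs < 1 or self.n_chains < 1:
            raise ValueError("counts must be positive")
        if self.heating_lambda <= 0:
            raise ValueError("heating_lambda must be positive")
        if self.multiplier_delta <= 0:
            raise ValueError("multiplier_delta must be positive")
        if not 0.0 <= self.burn_in_fraction < 1.0:
            raise ValueError("burn_in_fraction must lie in [0, 1)")
        if self.sample_every < 1:
            raise ValueError("sample_every must be >= 1")

    @classmethod
    def test_scale(cls, **overrides) -> "SamplerConfig":
        """Small-run defaults for tests and smoke checks."""
        overrides.setdefault("n_generations", TEST_GENERATIONS)
        overrides.setdefault("sample_every", 10)
        return cls(**overrides)


def chain_temperature(i: int, lam: float) -> float:
    """Inverse temperature β_i = 1/(1+λ(i-1)) of chain i (1-based; chain 1
    is cold with β = 1)."""
    if i < 1:
        raise ValueError("chain index is 1-based")
    if lam <= 0:
        raise ValueError("lambda must be positive")
    return 1.0 / (1.0 + lam * (i - 1))


@dataclass(frozen=True)
class Sample:
    generation: int
    edge: EdgeRef
    lengths: tuple       # backbone edge lengths, in TraceSet.edge_order
    pendant_length: float
    alpha: float
    log_posterior: float


@dataclass(frozen=True)
class RunTrace:
    samples: tuple
    swap_attempts: int
    swap_accepts: int


@dataclass(frozen=True)
class TraceSet:
    runs: tuple            # of RunTrace
    edge_order: tuple      # of EdgeRef, fixing the meaning of Sample.lengths
    config: SamplerConfig
    backbone: Phylogeny
    fossil: str


@dataclass(frozen=True)
class PosteriorSample:
    samples: tuple         # pooled post-burn-in Samples
    edge_order: tuple
    backbone: Phylogeny
    fossil: str


class _ChainState:
    __slots__ = ("edge_idx", "lengths", "pendant", "alpha", "log_lik", "log_prior")

    def __init__(self, edge_idx, lengths, pendant, alpha, log_lik, log_prior):
        self.edge_idx = edge_idx
        self.lengths = lengths
        self.pendant = pendant
        self.alpha = alpha
        self.log_lik = log_lik
        self.log_prior = log_prior

    def copy(self):
        return _ChainState(self.edge_idx, self.lengths.copy(), self.pendant,
                           self.alpha, self.log_lik, self.log_prior)


class _Model:
    """Likelihood/prior evaluator bound to one (backbone, matrix, fossil)."""

    def __init__(self, backbone: Phylogeny, m: CharacterMatrix, fossil: str,
                 config: SamplerConfig):
        self.backbone = backbone.copy()
        self.m = m
        self.fossil = fossil
        self.config = config
        self.edge_order = tuple(self.backbone.edge_splits().keys())
        self._node_of = self.backbone.edge_splits()

    def log_likelihood(self, st: _ChainState) -> float:
        if self.config.prior_only:
            return 0.0
        for e, x in zip(self.edge_order, st.lengths):
            self.backbone.blen[self._node_of[e]] = float(x)
        tree = self.backbone.attach_leaf(self.edge_order[st.edge_idx],
                                         self.fossil,
                                         pendant_length=st.pendant,
                                         split_fraction=0.5)
        params = MkParams(gamma_shape=st.alpha,
                          n_rate_categories=self.config.n_rate_categories)
        return matrix_log_likelihood(
            tree, self.m, params,
            correct_for_variable=self.config.ascertainment == "variable")

    def log_prior(self, st: _ChainState) -> float:
        c = self.config
        n = len(st.lengths)
        lp = n * math.log(c.branch_length_rate) - c.branch_length_rate * float(st.lengths.sum())
        lp += math.log(c.branch_length_rate) - c.branch_length_rate * st.pendant
        lp += math.log(c.alpha_rate) - c.alpha_rate * st.alpha
        lp -= math.log(len(self.edge_order))  # uniform over attachment edges
        return lp


def _run_one(model: _Model, config: SamplerConfig, rng: np.random.Generator,
             init_lengths: np.ndarray) -> RunTrace:
    n_edges = len(model.edge_order)
    betas = [chain_temperature(i + 1, config.heating_lambda)
             for i in range(config.n_chains)]

    chains = []
    for _ in range(config.n_chains):
        st = _ChainState(
            edge_idx=int(rng.integers(n_edges)),
            lengths=init_lengths.copy(),
            pendant=config.initial_pendant_length,
            alpha=config.initial_alpha,
            log_lik=0.0, log_prior=0.0)
        st.log_lik = model.log_likelihood(st)
        st.log_prior = model.log_prior(st)
        chains.append(st)

    moves = ["reattach"]
    if config.sample_lengths:
        moves.append("scale_length")
    if config.sample_alpha:
        moves.append("scale_alpha")

    samples = []
    swap_attempts = swap_accepts = 0
    delta = config.multiplier_delta
    for gen in range(1, config.n_generations + 1):
        for ci, st in enumerate(chains):
            beta = betas[ci]
            move = moves[int(rng.integers(len(moves)))]
            if move == "reattach":
                prop = st.copy()
                prop.edge_idx = int(rng.integers(n_edges))
                prop.log_lik = model.log_likelihood(prop)
                log_r = beta * (prop.log_lik - st.log_lik)
                log_hastings = 0.0
            elif move == "scale_length":
                prop = st.copy()
                j = int(rng.integers(n_edges + 1))
                mult = math.exp(delta * (rng.random() - 0.5))
                if j < n_edges:
                    prop.lengths[j] *= mult
                else:
                    prop.pendant *= mult
                prop.log_lik = model.log_likelihood(prop)
                prop.log_prior = model.log_prior(prop)
                log_hastings = math.log(mult)
                log_r = (beta * (prop.log_lik - st.log_lik)
                         + (prop.log_prior - st.log_prior) + log_hastings)
            else:  # scale_alpha
                prop = st.copy()
                mult = math.exp(delta * (rng.random() - 0.5))
                prop.alpha *= mult
                prop.log_lik = model.log_likelihood(prop)
                prop.log_prior = model.log_prior(prop)
                log_hastings = math.log(mult)
                log_r = (beta * (prop.log_lik - st.log_lik)
                         + (prop.log_prior - st.log_prior) + log_hastings)
            if log_r >= 0 or rng.random() < math.exp(log_r):
                chains[ci] = prop

        if config.n_chains > 1:
            a = int(rng.integers(config.n_chains - 1))
            b = a + 1
            swap_attempts += 1
            log_r = (betas[a] - betas[b]) * (chains[b].log_lik - chains[a].log_lik)
            if log_r >= 0 or rng.random() < math.exp(log_r):
                chains[a], chains[b] = chains[b], chains[a]
                swap_accepts += 1

        if gen % config.sample_every == 0:
            cold = chains[0]
            samples.append(Sample(
                generation=gen,
                edge=model.edge_order[cold.edge_idx],
                lengths=tuple(float(x) for x in cold.lengths),
                pendant_length=cold.pendant,
                alpha=cold.alpha,
                log_posterior=cold.log_prior + cold.log_lik,
            ))
    return RunTrace(samples=tuple(samples), swap_attempts=swap_attempts,
                    swap_accepts=swap_accepts)


def mcmc_run(backbone: Phylogeny, m: CharacterMatrix, fossil: str,
             config: SamplerConfig) -> TraceSet:
    """Run ``config.n_runs`` independent MC³ samplers; reproducible given
    ``config.seed``.

    Backbone branch lengths are free parameters (the backbone constrains
    topology only); absent lengths are initialised at 0.1.
    """
    report = validate_compatibility(m, backbone, fossil)
    if not report.ok:
        raise ValueError("matrix/backbone/fossil mismatch: " + "; ".join(report.messages))
    model = _Model(backbone, m, fossil, config)
    init = np.array([backbone.edge_lengths()[e] if backbone.has_lengths else 0.1
                     for e in model.edge_order], dtype=float)
    init = np.where(init <= 0, 1e-6, init)
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_runs)
    runs = tuple(_run_one(model, config, np.random.default_rng(s), init)
                 for s in seeds)
    return TraceSet(runs=runs, edge_order=model.edge_order, config=config,
                    backbone=backbone.copy(), fossil=fossil)


def combine_runs(traces: TraceSet,
                 burn_in_fraction: Optional[float] = None) -> PosteriorSample:
    """Drop the first ``ceil(fraction * n)`` samples of each run and pool
    the remainder."""
    frac = traces.config.burn_in_fraction if burn_in_fraction is None else burn_in_fraction
    if not 0.0 <= frac < 1.0:
        raise ValueError("burn-in fraction must lie in [0, 1)")
    pooled = []
    for run in traces.runs:
        drop = math.ceil(frac * len(run.samples))
        pooled.extend(run.samples[drop:])
    return PosteriorSample(samples=tuple(pooled), edge_order=traces.edge_order,
                           backbone=traces.backbone, fossil=traces.fossil)


def placement_posterior(samples: PosteriorSample) -> dict:
    """Posterior probability of each attachment edge (relative frequency
    among retained samples; every backbone edge gets an entry)."""
    if not samples.samples:
        raise ValueError("empty posterior sample")
    counts = {e: 0 for e in samples.edge_order}
    for s in samples.samples:
        counts[s.edge] += 1
    n = len(samples.samples)
    return {e: c / n for e, c in counts.items()}


def _run_split_frequencies(traces: TraceSet, run: RunTrace,
                           burn_in_fraction: float, cache: dict) -> dict:
    drop = math.ceil(burn_in_fraction * len(run.samples))
    kept = run.samples[drop:]
    freqs: dict = {}
    for s in kept:
        for split in splits_from_attachment(traces.backbone, s.edge,
                                            traces.fossil, _cache=cache):
            freqs[split] = freqs.get(split, 0.0) + 1.0 / len(kept)
    return freqs


def asdsf(traces: TraceSet, burn_in_fraction: Optional[float] = None,
          min_frequency: float = 0.1) -> float:
    """Average standard deviation of split frequencies across runs.

    Averages, over every split exceeding ``min_frequency`` in at least one
    run, the sample standard deviation (ddof=1) of its frequency across
    runs.  Zero when runs agree exactly; the standard two-run convergence
    diagnostic."""
    if len(traces.runs) < 2:
        raise ValueError("ASDSF needs at least two runs")
    frac = traces.config.burn_in_fraction if burn_in_fraction is None else burn_in_fraction
    cache: dict = {}
    per_run = [_run_split_frequencies(traces, r, frac, cache) for r in traces.runs]
    splits = {s for freqs in per_run for s, f in freqs.items() if f > min_frequency}
    if not splits:
        return 0.0
    sds = [float(np.std([freqs.get(s, 0.0) for freqs in per_run], ddof=1))
           for s in sorted(splits, key=sorted)]
    return float(np.mean(sds))


def mc_standard_error(indicator: np.ndarray, n_batches: int = 50) -> float:
    """Monte-Carlo standard error of a mean of (autocorrelated) draws by
    the batch-means method."""
    x = np.asarray(indicator, dtype=float)
    n = len(x) // n_batches * n_batches
    if n < n_batches:
        raise ValueError("too few draws for batch means")
    batches = x[:n].reshape(n_batches, -1).mean(axis=1)
    return float(batches.std(ddof=1) / math.sqrt(n_batches))
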