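"""Mk model likelihood for discrete morphological characters.

The Mk model (Lewis 2001) is a continuous-time Markov chain with k
states, equal exchange rates and uniform stationary frequencies; its
transition probabilities have the closed form

    P_same(t) = 1/k + (k-1)/k * exp(-k r t / (k-1))
    P_diff(t) = 1/k -   1/k   * exp(-k r t / (k-1))

with branch length t in expected changes per character at rate r = 1.
Among-character rate variation uses the discrete-gamma approximation
(equal-probability categories, category rate = mean of its quantile bin,
renormalised to average exactly 1).  Because invariant morphological
characters are never scored, the likelihood can condition each character
on being variable (the "Mkv" ascertainment correction): the character
likelihood is divided by one minus the summed probability of the k
constant patterns.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from .matrices import CharacterMatrix
from .trees import Phylogeny

__all__ = [
    "MkParams",
    "mk_transition",
    "gamma_rates",
    "character_likelihood",
    "matrix_log_likelihood",
]


@dataclass(frozen=True)
class MkParams:
    """Rate-variation parameters shared by all characters.

    gamma_shape -- shape α of the gamma rate distribution (mean fixed at 1)
    n_rate_categories -- number of discrete-gamma categories (1 = no variation)
    """

    gamma_shape: float = 1.0
    n_rate_categories: int = 4

    def __post_init__(self):
        if self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be positive")
        if self.n_rate_categories < 1:
            raise ValueError("need at least one rate category")


def mk_transition(k: int, t: float, rate: float = 1.0) -> np.ndarray:
    """k x k Mk transition probability matrix over a branch of length t."""
    if k < 2:
        raise ValueError("Mk needs k >= 2 states")
    if t < 0:
        raise ValueError("branch length must be nonnegative")
    e = np.exp(-k * rate * t / (k - 1))
    p_diff = (1.0 - e) / k
    return np.full((k, k), p_diff) + np.eye(k) * e



@lru_cache(maxsize=256)
def _gamma_rates_cached(alpha: float, ncat: int) -> tuple:
    bounds = gamma_dist.ppf(np.arange(ncat + 1) / ncat, alpha, scale=1.0 / alpha)
    # E[X; X<q] for X ~ Gamma(α, rate α) is the regularised incomplete
    # gamma with shape α+1 evaluated at αq
    cum = gammainc(alpha + 1.0, alpha * bounds[1:-1])
    mass = np.diff(np.concatenate([[0.0], cum, [1.0]]))
    rates = ncat * mass
    return tuple(rates / rates.mean())


def gamma_rates(alpha: float, ncat: int) -> np.ndarray:
    """Discrete-gamma category rates (mean of each equal-probability
    quantile bin of Gamma(α, mean 1)), renormalised to average exactly 1."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if ncat < 1:
        raise ValueError("ncat must be >= 1")
    if ncat == 1:
        return np.ones(1)
    return np.array(_gamma_rates_cached(float(alpha), int(ncat)))


def _pruned_likelihoods(tree: Phylogeny, leaf_indicators: dict, k: int,
                        rates: np.ndarray) -> np.ndarray:
    """Per-character likelihoods by Felsenstein pruning, averaged over rate
    categories, with uniform 1/k root frequencies.

    leaf_indicators maps leaf label -> array (n_chars, k) of 0/1 partials.
    Works on the trifurcating canonical rooting (reversibility makes the
    rooting irrelevant).  Exploits the Mk transition structure
    ``P v = P_diff * sum(v) + e * v`` so no matrix products are formed.
    """
    e_cat = np.empty(len(rates))
    partial: dict[int, np.ndarray] = {}
    for v in tree.postorder():
        kids = tree.children[v]
        if not kids:
            lab = tree.label[v]
            if lab not in leaf_indicators:
                raise KeyError(f"leaf {lab!r} has no character data")
            partial[v] = leaf_indicators[lab][None, :, :]  # broadcast over cats
            continue
        part = None
        for c in kids:
            t_len = tree.blen[c]
            if t_len is None:
                raise ValueError("tree is missing a branch length")
            np.exp(-k * rates * t_len / (k - 1), out=e_cat)
            e = e_cat[:, None, None]
            child = partial.pop(c)
            term = ((1.0 - e) / k) * child.sum(axis=2, keepdims=True) + e * child
            part = term if part is None else part * term
        partial[v] = part
    root = partial[tree.root]
    return (root.sum(axis=2) / k).mean(axis=0)


def _leaf_indicators(column_sets: dict, k: int) -> dict:
    """Stack single-character state sets into (1, k) indicator arrays."""
    out = {}
    for lab, cells in column_sets.items():
        arr = np.zeros((len(cells), k))
        for j, cell in enumerate(cells):
            for s in cell:
                arr[j, s] = 1.0
        out[lab] = arr
    return out


def character_likelihood(tree: Phylogeny, cell_states: dict, k: int,
                         params: MkParams) -> float:
    """Likelihood of a single character (leaf label -> state set)."""
    rates = gamma_rates(params.gamma_shape, params.n_rate_categories)
    ind = _leaf_indicators({lab: [frozenset(s)] for lab, s in cell_states.items()}, k)
    return float(_pruned_likelihoods(tree, ind, k, rates)[0])


def constant_pattern_probability(tree: Phylogeny, k: int,
                                 params: MkParams) -> float:
    """Summed probability of the k all-constant leaf patterns — the Mkv
    ascertainment term."""
    rates = gamma_rates(params.gamma_shape, params.n_rate_categories)
    labels = tree.leaf_labels()
    ind = _leaf_indicators(
        {lab: [frozenset([s]) for s in range(k)] for lab in labels}, k)
    return float(_pruned_likelihoods(tree, ind, k, rates).sum())


def matrix_log_likelihood(tree: Phylogeny, m: CharacterMatrix, params: MkParams,
                          correct_for_variable: bool = True) -> float:
    """Log-likelihood of the whole matrix; characters are independent and
    share one branch-length set and one gamma shape.

    With ``correct_for_variable`` each character's likelihood is divided
    by the probability that a character of its state-space size is
    variable on this tree (conditioning on observing only variable
    characters).  Characters of different k are handled independently.
    """
    if not tree.has_lengths:
        raise ValueError("tree is missing branch lengths")
    rates = gamma_rates(params.gamma_shape, params.n_rate_categories)
    total = 0.0
    by_k: dict[int, list[int]] = {}
    for j, k in enumerate(m.state_space):
        by_k.setdefault(k, []).append(j)
    for k, char_idx in by_k.items():
        # append the k constant patterns so the ascertainment term comes
        # out of the same pruning sweep as the data
        ind = _leaf_indicators(
            {lab: [m.rows[lab][j] for j in char_idx]
             + [frozenset([s]) for s in range(k)] for lab in m.taxa}, k)
        liks_all = _pruned_likelihoods(tree, ind, k, rates)
        liks, const = liks_all[:len(char_idx)], liks_all[len(char_idx):]
        if np.any(liks <= 0):
            raise ValueError("zero character likelihood (impossible data?)")
        if correct_for_variable:
            denom = 1.0 - float(const.sum())
            if denom <= 0:
                raise ValueError("nonpositive ascertainment denominator "
                                 "(numerical failure)")
            total += float(np.log(liks).sum()) - len(char_idx) * np.log(denom)
        else:
            total += float(np.log(liks).sum())
    return total
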