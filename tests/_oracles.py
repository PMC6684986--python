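"""Independent oracles and random-instance generators for the test suite.

Everything here is deliberately brute force — exhaustive enumeration over
internal-node state assignments, matrix exponentials, quadrature — and
shares no code path with the implementation it checks.
"""

from itertools import product

import numpy as np
from scipy.linalg import expm

from fossilplace.matrices import CharacterMatrix
from fossilplace.trees import Phylogeny, TaxonSet


def random_tree(rng: np.random.Generator, labels, with_lengths=True) -> Phylogeny:
    """Random unrooted binary topology by sequential attachment to a
    uniformly chosen edge (independent re-implementation)."""
    labels = list(labels)
    t = Phylogeny()
    root = t._new_node(None)
    for lab in labels[:3]:
        t._new_node(root, lab)
    for lab in labels[3:]:
        edges = list(t.edge_splits().keys())
        t = t.attach_leaf(edges[int(rng.integers(len(edges)))], lab,
                          pendant_length=None)
    if with_lengths:
        for v in t.children:
            if v != t.root:
                t.blen[v] = float(rng.uniform(0.05, 1.0))
    return t


def random_matrix(rng: np.random.Generator, labels, n_chars, max_k=3,
                  missing_p=0.1, poly_p=0.1) -> CharacterMatrix:
    ks = tuple(int(rng.integers(2, max_k + 1)) for _ in range(n_chars))
    rows = {}
    for lab in labels:
        cells = []
        for k in ks:
            u = rng.random()
            if u < missing_p:
                cells.append(frozenset(range(k)))
            elif u < missing_p + poly_p and k > 2:
                cells.append(frozenset(rng.choice(k, size=2, replace=False).tolist()))
            else:
                cells.append(frozenset([int(rng.integers(k))]))
        rows[lab] = tuple(cells)
    return CharacterMatrix(taxa=TaxonSet(labels), rows=rows, state_space=ks)


def brute_fitch(tree: Phylogeny, m: CharacterMatrix) -> int:
    """Minimum state changes by exhaustive minimisation over every
    assignment of states to internal nodes (and leaf-state choices are
    implied by taking the cheapest member of each leaf's set)."""
    internal = [v for v in tree.children if tree.children[v]]
    total = 0
    for j, k in enumerate(m.state_space):
        best = None
        for assign in product(range(k), repeat=len(internal)):
            states = dict(zip(internal, assign))
            cost = 0
            for v in tree.children:
                if v == tree.root:
                    continue
                p = states[tree.parent[v]]
                if tree.children[v]:
                    cost += int(states[v] != p)
                else:
                    cost += int(p not in m.rows[tree.label[v]][j])
            best = cost if best is None else min(best, cost)
        total += best
    return total


def mk_rate_matrix(k: int) -> np.ndarray:
    """Normalised Mk generator (unit expected changes per unit time)."""
    return (np.ones((k, k)) - k * np.eye(k)) / (k - 1)


def brute_character_likelihood(tree: Phylogeny, cell_states: dict, k: int,
                               rates) -> float:
    """Exhaustive sum over internal-node states x rate categories, with
    transition probabilities from scipy's matrix exponential."""
    internal = [v for v in tree.children if tree.children[v]]
    leaves = [v for v in tree.children if not tree.children[v]]
    total = 0.0
    for r in rates:
        P = {v: expm(mk_rate_matrix(k) * tree.blen[v] * r)
             for v in tree.children if v != tree.root}
        s = 0.0
        for assign in product(range(k), repeat=len(internal)):
            states = dict(zip(internal, assign))
            term = 1.0 / k  # uniform root frequency
            for v in internal:
                if v != tree.root:
                    term *= P[v][states[tree.parent[v]], states[v]]
            for v in leaves:
                p = states[tree.parent[v]]
                term *= sum(P[v][p, s_leaf]
                            for s_leaf in cell_states[tree.label[v]])
            s += term
        total += s / len(rates)
    return total
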