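"""Synthetic backbones and character matrices with a known fossil
attachment.

Matrices are generated under the same Mk(+gamma) model the likelihood
machinery assumes — uniform root state, per-character gamma rate
(continuous by default, optionally the discrete categories used in
inference) — on a random backbone with the fossil attached at a known
edge, then degraded with uniformly random missing cells.  Defaults
mirror the shape of the study system: 10 extant cycad genera plus one
fossil, 15 unordered characters with 2-3 states.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .matrices import CharacterMatrix
from .mk import gamma_rates
from .parsimony import attach_fossil
from .trees import EdgeRef, Phylogeny, TaxonSet

__all__ = [
    "SimulationSpec",
    "random_backbone",
    "simulate_matrix",
    "study_like_fixture",
    "EXTANT_CYCAD_GENERA",
]

#: the ten living cycad genera (fixture naming only)
EXTANT_CYCAD_GENERA = (
    "Bowenia", "Ceratozamia", "Cycas", "Dioon", "Encephalartos",
    "Lepidozamia", "Macrozamia", "Microcycas", "Stangeria", "Zamia",
)

MEAN_EDGE_LENGTH = 0.3


@dataclass(frozen=True)
class SimulationSpec:
    """Study-shaped simulation settings (11 taxa x 15 characters)."""

    n_extant: int = 10
    n_chars: int = 15
    state_counts: Optional[tuple] = None  # per-char k; default mix of 2s and 3s
    gamma_shape: float = 1.0
    true_attachment: Optional[EdgeRef] = None  # default: drawn from seed
    pendant_length: float = 0.1
    missing_fraction: float = 0.05
    polymorphic_fraction: float = 0.0
    condition_on_variable: bool = True
    discrete_rates: int = 0       # 0 = continuous gamma rates; else n categories
    fossil_label: str = "Dioonopsis"
    seed: int = 0

    def resolved_state_counts(self) -> tuple:
        if self.state_counts is not None:
            if len(self.state_counts) != self.n_chars:
                raise ValueError("state_counts length must equal n_chars")
            return tuple(self.state_counts)
        # alternating binary/ternary characters
        return tuple(2 if j % 2 == 0 else 3 for j in range(self.n_chars))

    def __post_init__(self):
        if not 0.0 <= self.missing_fraction < 1.0:
            raise ValueError("missing_fraction must lie in [0, 1)")
        if not 0.0 <= self.polymorphic_fraction < 1.0:
            raise ValueError("polymorphic_fraction must lie in [0, 1)")
        if self.pendant_length <= 0:
            raise ValueError("pendant_length must be positive")


def random_backbone(n_extant: int, seed: int,
                    labels: Optional[tuple] = None) -> Phylogeny:
    """Uniformly random labelled unrooted binary topology with iid
    exponential (mean 0.3) edge lengths.

    Built by sequential leaf addition to a uniformly chosen edge, which
    samples labelled topologies uniformly."""
    if n_extant < 4:
        raise ValueError("need at least 4 extant taxa")
    if labels is None:
        labels = tuple(f"T{i + 1}" for i in range(n_extant))
    if len(labels) != n_extant:
        raise ValueError("labels length must equal n_extant")
    rng = np.random.default_rng(seed)
    order = list(labels)  # insertion order fixed; randomness is in edge choice

    t = Phylogeny()
    root = t._new_node(None)
    for lab in order[:3]:
        t._new_node(root, lab)
    for lab in order[3:]:
        edges = list(t.edge_splits().keys())
        edge = edges[int(rng.integers(len(edges)))]
        t = t.attach_leaf(edge, lab, pendant_length=None)
    for v in t.children:
        if v != t.root:
            t.blen[v] = float(rng.exponential(MEAN_EDGE_LENGTH))
    return t


def _simulate_states(tree: Phylogeny, k: int, rate: float,
                     rng: np.random.Generator) -> dict:
    """Evolve one character down the tree; returns leaf label -> state."""
    states: dict[int, int] = {tree.root: int(rng.integers(k))}
    out: dict[str, int] = {}
    for v in tree.postorder()[::-1]:  # preorder
        if v == tree.root:
            pass
        else:
            t_len = tree.blen[v]
            parent_state = states[tree.parent[v]]
            e = np.exp(-k * rate * t_len / (k - 1))
            if rng.random() < e:
                states[v] = parent_state
            else:
                states[v] = int(rng.integers(k))  # uniform, incl. parent state
        if not tree.children[v]:
            out[tree.label[v]] = states[v]
    return out


def simulate_matrix(spec: SimulationSpec, backbone: Phylogeny,
                    max_retries: int = 1000) -> CharacterMatrix:
    """Simulate a fossil-inclusive matrix under Mk(+gamma) on the backbone
    with the fossil attached at ``spec.true_attachment``.

    Constant characters are redrawn (up to ``max_retries`` per character)
    when ``condition_on_variable`` is set, mirroring the ascertainment
    assumption of the corrected likelihood; afterwards a
    ``missing_fraction`` of cells is masked to the full state set (and,
    optionally, a ``polymorphic_fraction`` widened by one extra state)."""
    rng = np.random.default_rng(spec.seed)
    if spec.true_attachment is None:
        raise ValueError("spec.true_attachment must name a backbone edge")
    tree = attach_fossil(backbone, spec.true_attachment, spec.fossil_label,
                         pendant_length=spec.pendant_length)
    state_counts = spec.resolved_state_counts()
    taxa = TaxonSet(tree.leaf_labels())

    columns = []
    for k in state_counts:
        for attempt in range(max_retries + 1):
            if spec.discrete_rates:
                cats = gamma_rates(spec.gamma_shape, spec.discrete_rates)
                rate = float(cats[int(rng.integers(len(cats)))])
            else:
                rate = float(rng.gamma(spec.gamma_shape, 1.0 / spec.gamma_shape))
            col = _simulate_states(tree, k, rate, rng)
            if not spec.condition_on_variable or len(set(col.values())) > 1:
                break
        else:
            raise RuntimeError(
                "could not simulate a variable character "
                f"(k={k}) in {max_retries} tries — branch lengths too short?")
        columns.append(col)

    rows = {}
    for lab in taxa:
        cells = []
        for j, col in enumerate(columns):
            k = state_counts[j]
            u = rng.random()
            if u < spec.missing_fraction:
                cells.append(frozenset(range(k)))
            elif u < spec.missing_fraction + spec.polymorphic_fraction:
                extra = int(rng.integers(k))
                cells.append(frozenset({col[lab], extra} if extra != col[lab]
                                       else {col[lab], (col[lab] + 1) % k}))
            else:
                cells.append(frozenset([col[lab]]))
        rows[lab] = tuple(cells)
    return CharacterMatrix(taxa=taxa, rows=rows, state_space=state_counts)


def study_like_fixture(seed: int, n_chars: int = 15,
                       missing_fraction: float = 0.05,
                       pendant_length: float = 0.1):
    """A study-shaped synthetic instance: a random backbone over the ten
    extant cycad genera, a fossil named Dioonopsis attached at a random
    edge, and a simulated 11 x ``n_chars`` matrix.

    Returns ``(backbone, matrix, true_edge)``."""
    rng = np.random.default_rng(seed)
    backbone = random_backbone(10, int(rng.integers(2 ** 31)),
                               labels=EXTANT_CYCAD_GENERA)
    edges = sorted(backbone.edge_splits().keys(), key=sorted)
    true_edge = edges[int(rng.integers(len(edges)))]
    spec = SimulationSpec(n_chars=n_chars, missing_fraction=missing_fraction,
                          true_attachment=true_edge,
                          pendant_length=pendant_length,
                          seed=int(rng.integers(2 ** 31)))
    matrix = simulate_matrix(spec, backbone)
    return backbone, matrix, true_edge
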