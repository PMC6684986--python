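"""Fitch parsimony scoring and exhaustive fossil placement.

With a fixed backbone topology and a single free taxon, the trees
compatible with the backbone constraint correspond one-to-one with the
2L-3 edges of the unrooted backbone, so "exhaustive enumeration of
compatible trees" reduces to scoring every attachment edge.  State sets
(missing/polymorphic cells) enter the Fitch pass directly as leaf sets,
which still yields the true minimum number of unordered changes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matrices import CharacterMatrix, validate_compatibility
from .splits import tree_to_splits
from .trees import EdgeRef, Phylogeny

__all__ = [
    "fitch_steps",
    "attach_fossil",
    "placement_profile",
    "bootstrap_placements",
    "PlacementProfile",
    "BootstrapSummary",
]

DEFAULT_PENDANT_LENGTH = 0.1


def _column_masks(m: CharacterMatrix) -> dict:
    """Per-taxon bitmask tuples, one mask per character (bit i = state i)."""
    out = {}
    for t in m.taxa:
        out[t] = tuple(sum(1 << s for s in cell) for cell in m.rows[t])
    return out


def _fitch_count(tree: Phylogeny, masks: dict, n_chars: int) -> int:
    """Total Fitch steps over all characters via one postorder sweep.

    At each internal node child sets are folded pairwise: intersection if
    non-empty, else union at the cost of one step.  A trifurcating root is
    folded sequentially, which equals rooting along its third edge.
    """
    steps = 0
    node_masks: dict[int, list[int]] = {}
    for v in tree.postorder():
        kids = tree.children[v]
        if not kids:
            label = tree.label[v]
            if label not in masks:
                raise KeyError(f"leaf {label!r} has no matrix row")
            node_masks[v] = list(masks[label])
            continue
        acc = node_masks.pop(kids[0])
        for c in kids[1:]:
            other = node_masks.pop(c)
            for j in range(n_chars):
                inter = acc[j] & other[j]
                if inter:
                    acc[j] = inter
                else:
                    acc[j] = acc[j] | other[j]
                    steps += 1
        node_masks[v] = acc
    return steps


def fitch_steps(tree: Phylogeny, m: CharacterMatrix) -> int:
    """Minimum number of unordered state changes of the whole matrix on the
    tree (sum over characters); invariant under rerooting."""
    for label in tree.leaf_labels():
        if label not in m.rows:
            raise KeyError(f"leaf {label!r} has no matrix row")
    return _fitch_count(tree, _column_masks(m), m.n_chars)


def attach_fossil(backbone: Phylogeny, edge: EdgeRef, fossil: str,
                  pendant_length: float = DEFAULT_PENDANT_LENGTH) -> Phylogeny:
    """New tree with ``edge`` subdivided at its midpoint and a pendant leaf
    named ``fossil``; the backbone is left unmodified."""
    return backbone.attach_leaf(edge, fossil, pendant_length=pendant_length,
                                split_fraction=0.5)


@dataclass(frozen=True)
class PlacementProfile:
    """Parsimony steps for every possible attachment of the fossil."""

    edge_steps: dict  # EdgeRef -> int
    min_steps: int
    mp_edges: frozenset  # EdgeRefs attaining min_steps

    @classmethod
    def from_steps(cls, edge_steps: dict) -> "PlacementProfile":
        lo = min(edge_steps.values())
        return cls(edge_steps=dict(edge_steps), min_steps=lo,
                   mp_edges=frozenset(e for e, s in edge_steps.items() if s == lo))

    def margin(self, edge: EdgeRef) -> int:
        """Extra steps of ``edge`` relative to the most parsimonious placement."""
        return self.edge_steps[edge] - self.min_steps


def placement_profile(backbone: Phylogeny, m: CharacterMatrix,
                      fossil: str) -> PlacementProfile:
    """Score the fossil's attachment at every backbone edge.

    Equivalent to scoring every binary tree compatible with the backbone
    constraint, since each compatible tree is one attachment.
    """
    report = validate_compatibility(m, backbone, fossil)
    if not report.ok:
        raise ValueError("matrix/backbone/fossil mismatch: " + "; ".join(report.messages))
    masks = _column_masks(m)
    edge_steps = {}
    for edge in backbone.edge_splits():
        tree = attach_fossil(backbone, edge, fossil)
        edge_steps[edge] = _fitch_count(tree, masks, m.n_chars)
    return PlacementProfile.from_steps(edge_steps)


@dataclass(frozen=True)
class BootstrapSummary:
    """Character-resampling bootstrap of the constrained placement search."""

    n_replicates: int
    seed: int
    placement_support: dict  # EdgeRef -> fraction of replicate weight
    split_support: dict      # Split -> fraction of replicate weight


def bootstrap_replicate_indices(n_chars: int, n_replicates: int,
                                seed: int) -> np.ndarray:
    """The resampled character indices for each replicate; exposed so the
    resampling scheme is reproducible and externally checkable."""
    rng = np.random.default_rng(seed)
    return rng.integers(0, n_chars, size=(n_replicates, n_chars))


def bootstrap_placements(backbone: Phylogeny, m: CharacterMatrix, fossil: str,
                         n_replicates: int, seed: int) -> BootstrapSummary:
    """Resample the characters with replacement ``n_replicates`` times and
    re-run the exhaustive placement scoring on each pseudo-matrix.

    Tied most-parsimonious placements within a replicate share that
    replicate's unit weight equally, so placement support sums to 1 over
    edges.  Split support aggregates all splits of each replicate's MP
    trees (backbone + attached fossil) with the same fractional weights.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    report = validate_compatibility(m, backbone, fossil)
    if not report.ok:
        raise ValueError("matrix/backbone/fossil mismatch: " + "; ".join(report.messages))

    edges = list(backbone.edge_splits())
    attached = {e: attach_fossil(backbone, e, fossil) for e in edges}
    attached_splits = {e: tree_to_splits(attached[e]) for e in edges}

    placement = {e: 0.0 for e in edges}
    split_support: dict = {}
    for indices in bootstrap_replicate_indices(m.n_chars, n_replicates, seed):
        rep = m.select_chars(list(indices))
        masks = _column_masks(rep)
        steps = {e: _fitch_count(attached[e], masks, rep.n_chars) for e in edges}
        lo = min(steps.values())
        mp = [e for e in edges if steps[e] == lo]
        w = 1.0 / (len(mp) * n_replicates)
        for e in mp:
            placement[e] += w
            for s in attached_splits[e]:
                split_support[s] = split_support.get(s, 0.0) + w
    return BootstrapSummary(n_replicates=n_replicates, seed=seed,
                            placement_support=placement, split_support=split_support)
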