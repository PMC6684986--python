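"""Bipartitions (splits), split frequencies, cutoff filtering and
SplitsTree-compatible NEXUS output.

A split is the bipartition of the taxon set induced by removing one tree
edge, canonicalised as the side not containing the smallest label (see
:func:`fossilplace.trees.canonical_split`).  Aggregating splits over a
sample of trees (bootstrap MP trees, posterior attachment samples) and
keeping those above a frequency cutoff yields the split set of a
consensus network; drawing the network itself is left to a splits-graph
viewer, which this module feeds via a SPLITS-block NEXUS file.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional, Sequence

from .trees import EdgeRef, Phylogeny, TaxonSet, canonical_split

__all__ = [
    "Split",
    "WeightedSplitSet",
    "tree_to_splits",
    "split_frequencies",
    "filter_splits",
    "write_splits_nexus",
    "read_splits_nexus",
    "split_to_bitmask",
    "bitmask_to_split",
]

#: Splits share the canonical frozenset-of-labels representation of EdgeRef.
Split = EdgeRef


def split_to_bitmask(split: Split, taxa: TaxonSet) -> int:
    """Encode a split as a bitmask over the TaxonSet order (bit i = taxon i)."""
    return sum(1 << taxa.index(t) for t in split)


def bitmask_to_split(mask: int, taxa: TaxonSet) -> Split:
    side = [t for i, t in enumerate(taxa) if mask >> i & 1]
    return canonical_split(side, taxa.labels)


def tree_to_splits(t: Phylogeny) -> frozenset:
    """The non-trivial splits of a tree, one per internal edge.

    Trees with fewer than four leaves have none.  Multifurcating nodes are
    allowed; they simply contribute fewer splits.
    """
    labels = frozenset(t.leaf_labels())
    n = len(labels)
    if n < 4:
        return frozenset()
    below = t.leaves_below()
    out = set()
    for v in t.children:
        if v == t.root:
            continue
        side = below[v]
        if 2 <= len(side) <= n - 2:
            out.add(canonical_split(side, labels))
    return frozenset(out)


def split_frequencies(trees: Sequence[Phylogeny],
                      weights: Optional[Sequence[float]] = None) -> dict:
    """Weighted fraction of source trees containing each non-trivial split.

    ``weights`` default to 1 per tree and are normalised by their sum, so
    fractionally weighted samples (e.g. tied bootstrap MP trees) are
    supported directly.
    """
    trees = list(trees)
    if not trees:
        raise ValueError("no trees given")
    taxa = frozenset(trees[0].leaf_labels())
    if weights is None:
        weights = [1.0] * len(trees)
    if len(weights) != len(trees):
        raise ValueError("weights/trees length mismatch")
    total = float(sum(weights))
    freqs: dict = {}
    for t, w in zip(trees, weights):
        if frozenset(t.leaf_labels()) != taxa:
            raise ValueError("trees are not all on the same taxon set")
        for s in tree_to_splits(t):
            freqs[s] = freqs.get(s, 0.0) + w / total
    return freqs


@dataclass(frozen=True)
class WeightedSplitSet:
    """Non-trivial splits retained at or above a frequency cutoff."""

    frequencies: dict  # Split -> frequency in [0, 1]
    n_source_trees: int
    cutoff: float

    def top(self, n: int = 2) -> list:
        """The n highest-frequency splits, strongest first."""
        ranked = sorted(self.frequencies.items(),
                        key=lambda kv: (-kv[1], sorted(kv[0])))
        return ranked[:n]


def filter_splits(freqs: dict, cutoff: float,
                  n_source_trees: int = 0) -> WeightedSplitSet:
    """Keep splits whose frequency is >= cutoff (inclusive boundary)."""
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError("cutoff must lie in [0, 1]")
    kept = {s: f for s, f in freqs.items() if f >= cutoff}
    return WeightedSplitSet(frequencies=kept, n_source_trees=n_source_trees,
                            cutoff=cutoff)


def write_splits_nexus(s: WeightedSplitSet, taxa: TaxonSet) -> str:
    """NEXUS TAXA + SPLITS blocks loadable by SplitsTree.

    Each split row lists the 1-based indices of the side containing the
    first taxon, preceded by its weight (the frequency).
    """
    lines = [
        "#NEXUS",
        "BEGIN TAXA;",
        f"DIMENSIONS NTAX={len(taxa)};",
        "TAXLABELS " + " ".join(f"'{t}'" for t in taxa) + ";",
        "END;",
        "BEGIN SPLITS;",
        f"DIMENSIONS NTAX={len(taxa)} NSPLITS={len(s.frequencies)};",
        "FORMAT LABELS=NO WEIGHTS=YES;",
        "MATRIX",
    ]
    ranked = sorted(s.frequencies.items(), key=lambda kv: (-kv[1], sorted(kv[0])))
    for i, (split, freq) in enumerate(ranked, start=1):
        side = set(split)
        if taxa.labels[0] not in side:
            side = set(taxa.labels) - side
        idx = sorted(taxa.index(t) + 1 for t in side)
        lines.append(f"[{i}] {freq!r} " + " ".join(str(j) for j in idx) + ",")
    lines += [";", "END;", ""]
    return "\n".join(lines)


def read_splits_nexus(source: str) -> tuple:
    """Internal reader for the files written above; returns
    ``(WeightedSplitSet, TaxonSet)`` (used for round-trip checks)."""
    tm = re.search(r"TAXLABELS\s+(.*?);", source, re.DOTALL | re.IGNORECASE)
    if not tm:
        raise ValueError("no TAXLABELS statement")
    labels = re.findall(r"'([^']*)'|(\S+)", tm.group(1))
    taxa = TaxonSet([a or b for a, b in labels])
    mm = re.search(r"BEGIN SPLITS;.*?MATRIX\s*(.*?);", source,
                   re.DOTALL | re.IGNORECASE)
    if not mm:
        raise ValueError("no SPLITS matrix")
    freqs: dict = {}
    for line in mm.group(1).splitlines():
        line = re.sub(r"\[.*?\]", "", line).strip().rstrip(",")
        if not line:
            continue
        parts = line.split()
        weight = float(parts[0])
        side = [taxa.labels[int(j) - 1] for j in parts[1:]]
        freqs[canonical_split(side, taxa.labels)] = weight
    n = re.search(r"NSPLITS\s*=\s*(\d+)", source, re.IGNORECASE)
    if n and int(n.group(1)) != len(freqs):
        raise ValueError("NSPLITS does not match matrix rows")
    return WeightedSplitSet(frequencies=freqs, n_source_trees=0, cutoff=0.0), taxa


def render_split(split: Split, taxa: TaxonSet) -> str:
    """Human-readable 'A,B|C,D' rendering in TaxonSet order."""
    side = [t for t in taxa if t in split]
    rest = [t for t in taxa if t not in split]
    return ",".join(side) + "|" + ",".join(rest)


def splits_from_attachment(backbone: Phylogeny, edge: EdgeRef, fossil: str,
                           _cache: Optional[dict] = None) -> frozenset:
    """Splits of the full tree implied by attaching the fossil at ``edge`` —
    the shared code path by which posterior samples and bootstrap MP trees
    are turned into split sets."""
    if _cache is not None and edge in _cache:
        return _cache[edge]
    tree = backbone.attach_leaf(edge, fossil, pendant_length=None)
    out = tree_to_splits(tree)
    if _cache is not None:
        _cache[edge] = out
    return out
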