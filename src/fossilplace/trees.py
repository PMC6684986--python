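"""Phylogeny data model and Newick input/output.

Trees are unrooted in meaning but stored with an arbitrary rooting: a
"canonical" rooting places the root at an internal node with three
children, so every non-root node corresponds one-to-one with an edge of
the unrooted tree (2L-3 edges for L leaves).  An edge is identified
across rerootings by the bipartition (split) of the leaf set it induces;
splits are canonicalised as the side *not* containing the
lexicographically smallest leaf label.
"""

from __future__ import annotations

from typing import Iterable, Iterator, Optional

import dendropy

__all__ = [
    "TaxonSet",
    "Phylogeny",
    "EdgeRef",
    "canonical_split",
    "read_newick",
    "write_newick",
]

#: An edge of an unrooted tree, named by the split it induces: the frozen
#: set of leaf labels on the side not containing the smallest label.
EdgeRef = frozenset


def normalize_label(label: str) -> str:
    """Trim whitespace and unify underscores with spaces (Newick dialect)."""
    return label.strip().replace("_", " ")


class TaxonSet:
    """Ordered collection of unique taxon labels.

    The order is stable and defines bit positions when splits are encoded
    as bitmasks (see :mod:`fossilplace.splits`).
    """

    def __init__(self, labels: Iterable[str]):
        labels = [normalize_label(l) for l in labels]
        if any(not l for l in labels):
            raise ValueError("empty taxon label")
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate taxon labels: {dupes}")
        self.labels: tuple[str, ...] = tuple(labels)

    def __len__(self) -> int:
        return len(self.labels)

    def __iter__(self) -> Iterator[str]:
        return iter(self.labels)

    def __contains__(self, label: str) -> bool:
        return label in self.labels

    def __eq__(self, other) -> bool:
        return isinstance(other, TaxonSet) and set(self.labels) == set(other.labels)

    def __hash__(self):
        return hash(frozenset(self.labels))

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def __repr__(self) -> str:
        return f"TaxonSet({list(self.labels)!r})"


def canonical_split(side: Iterable[str], all_labels: Iterable[str]) -> EdgeRef:
    """Canonical form of a bipartition: the side without the smallest label."""
    side = frozenset(side)
    all_labels = frozenset(all_labels)
    if not side or side == all_labels:
        raise ValueError("split side must be a proper non-empty subset")
    ref = min(all_labels)
    return frozenset(all_labels - side) if ref in side else side


class Phylogeny:
    """Binary tree over labelled leaves with optional branch lengths.

    Internal representation: integer node ids, ``parent``/``children``
    maps, leaf ``label`` map and ``blen[v]`` = length of the edge above
    ``v`` (``None`` when the tree carries no lengths).
    """

    def __init__(self):
        self.root: int = 0
        self.children: dict[int, list[int]] = {}
        self.parent: dict[int, Optional[int]] = {}
        self.label: dict[int, str] = {}
        self.blen: dict[int, Optional[float]] = {}
        self._next_id = 0

    # -- construction -------------------------------------------------

    def _new_node(self, parent: Optional[int], label: Optional[str] = None,
                  blen: Optional[float] = None) -> int:
        v = self._next_id
        self._next_id += 1
        self.children[v] = []
        self.parent[v] = parent
        self.blen[v] = blen
        if parent is not None:
            self.children[parent].append(v)
        if label is not None:
            self.label[v] = label
        return v

    @classmethod
    def from_dendropy(cls, dtree: "dendropy.Tree") -> "Phylogeny":
        t = cls()
        seen: set[str] = set()
        node_map: dict = {}

        def visit(dnode, parent):
            lab = None
            if dnode.is_leaf():
                if dnode.taxon is None or not str(dnode.taxon.label).strip():
                    raise ValueError("unlabelled leaf in tree")
                lab = normalize_label(str(dnode.taxon.label))
                if lab in seen:
                    raise ValueError(f"duplicate leaf label: {lab!r}")
                seen.add(lab)
            v = t._new_node(parent, lab, dnode.edge.length)
            node_map[dnode] = v
            for child in dnode.child_nodes():
                visit(child, v)

        visit(dtree.seed_node, None)
        t.blen[t.root] = None
        t._canonicalize()
        return t

    def _canonicalize(self) -> None:
        """Suppress a degree-2 root so the rooting is trifurcating."""
        while len(self.children[self.root]) == 1:
            # degenerate chain above: splice
            (only,) = self.children[self.root]
            del self.children[self.root], self.parent[self.root], self.blen[self.root]
            self.parent[only] = None
            self.blen[only] = None
            self.root = only
        if len(self.children[self.root]) == 2 and len(self.leaf_nodes()) >= 3:
            a, b = self.children[self.root]
            # pick an internal child to become the new root
            new_root, other = (a, b) if self.children[a] else (b, a)
            if not self.children[new_root]:
                return  # two-leaf tree: leave as is
            la, lb = self.blen[a], self.blen[b]
            merged = None if (la is None or lb is None) else la + lb
            old_root = self.root
            del self.children[old_root], self.parent[old_root], self.blen[old_root]
            self.parent[new_root] = None
            self.blen[new_root] = None
            self.parent[other] = new_root
            self.blen[other] = merged
            self.children[new_root].append(other)
            self.root = new_root

    def copy(self) -> "Phylogeny":
        t = Phylogeny()
        t.root = self.root
        t.children = {v: list(c) for v, c in self.children.items()}
        t.parent = dict(self.parent)
        t.label = dict(self.label)
        t.blen = dict(self.blen)
        t._next_id = self._next_id
        return t

    # -- queries ------------------------------------------------------

    def leaf_nodes(self) -> list[int]:
        return [v for v in self.children if not self.children[v]]

    def leaf_labels(self) -> list[str]:
        return sorted(self.label[v] for v in self.leaf_nodes())

    def taxa(self) -> TaxonSet:
        return TaxonSet(self.leaf_labels())

    @property
    def has_lengths(self) -> bool:
        return all(self.blen[v] is not None for v in self.children if v != self.root)

    def postorder(self) -> list[int]:
        order, stack = [], [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(self.children[v])
        order.reverse()
        return order

    def n_edges(self) -> int:
        return len(self.children) - 1

    def leaves_below(self) -> dict[int, frozenset]:
        below: dict[int, frozenset] = {}
        for v in self.postorder():
            if not self.children[v]:
                below[v] = frozenset([self.label[v]])
            else:
                s = frozenset()
                for c in self.children[v]:
                    s |= below[c]
                below[v] = s
        return below

    def edge_splits(self) -> dict[EdgeRef, int]:
        """Map each unrooted edge (as a canonical split) to its lower node.

        Includes trivial (single-leaf) splits: those name terminal edges.
        """
        labels = frozenset(self.leaf_labels())
        below = self.leaves_below()
        out: dict[EdgeRef, int] = {}
        for v in self.children:
            if v == self.root:
                continue
            out[canonical_split(below[v], labels)] = v
        return out

    def edge_lengths(self) -> dict[EdgeRef, Optional[float]]:
        return {s: self.blen[v] for s, v in self.edge_splits().items()}

    # -- surgery -------------------------------------------------------

    def attach_leaf(self, edge: EdgeRef, label: str, pendant_length: Optional[float] = 0.1,
                    split_fraction: float = 0.5) -> "Phylogeny":
        """Return a new tree with ``edge`` subdivided and a pendant leaf added."""
        label = normalize_label(label)
        if label in self.label.values():
            raise ValueError(f"leaf label already present: {label!r}")
        t = self.copy()
        splits = t.edge_splits()
        if edge not in splits:
            raise KeyError(f"edge not in tree: {sorted(edge)}")
        v = splits[edge]
        p = t.parent[v]
        t_len = t.blen[v]
        u = t._new_node(None)
        # insert u between p and v
        t.children[p][t.children[p].index(v)] = u
        t.parent[u] = p
        t.parent[v] = u
        t.children[u] = [v]
        if t_len is None:
            t.blen[u] = None
        else:
            t.blen[u] = t_len * (1.0 - split_fraction)
            t.blen[v] = t_len * split_fraction
        t._new_node(u, label, pendant_length if t.has_lengths or t_len is not None else None)
        return t

    def remove_leaf(self, label: str) -> "Phylogeny":
        """Return a new tree with leaf ``label`` removed and its degree-2
        parent suppressed (lengths of the merged edges summed)."""
        label = normalize_label(label)
        t = self.copy()
        w = next((v for v, l in t.label.items() if l == label), None)
        if w is None:
            raise KeyError(f"no leaf labelled {label!r}")
        u = t.parent[w]
        t.children[u].remove(w)
        del t.children[w], t.parent[w], t.blen[w], t.label[w]
        if u == t.root:
            t._canonicalize()
        elif len(t.children[u]) == 1:
            (c,) = t.children[u]
            p = t.parent[u]
            t.children[p][t.children[p].index(u)] = c
            t.parent[c] = p
            lu, lc = t.blen[u], t.blen[c]
            t.blen[c] = None if (lu is None or lc is None) else lu + lc
            del t.children[u], t.parent[u], t.blen[u]
        return t

    def reroot_at(self, node: int) -> "Phylogeny":
        """Re-hang the tree so ``node`` (an internal node) becomes the root."""
        if not self.children.get(node):
            raise ValueError("can only reroot at an internal node")
        t = self.copy()
        path = [node]
        while t.parent[path[-1]] is not None:
            path.append(t.parent[path[-1]])
        orig_blen = {v: t.blen[v] for v in path}
        for child, par in zip(path[:-1], path[1:]):
            # reverse edge par -> child
            t.children[par].remove(child)
            t.children[child].append(par)
            t.parent[par] = child
            t.blen[par] = orig_blen[child]
        t.parent[node] = None
        t.blen[node] = None
        t.root = node
        return t

    # -- serialization -------------------------------------------------

    def newick(self) -> str:
        def render(v: int) -> str:
            if not self.children[v]:
                body = self.label[v].replace(" ", "_")
            else:
                body = "(" + ",".join(render(c) for c in self.children[v]) + ")"
            if v != self.root and self.blen[v] is not None:
                body += f":{self.blen[v]!r}"
            return body

        return render(self.root) + ";"

    def __repr__(self) -> str:
        return f"Phylogeny({self.newick()!r})"


def read_newick(source: str) -> Phylogeny:
    """Parse a Newick string (or text stream contents) into a Phylogeny."""
    try:
        dtree = dendropy.Tree.get(
            data=source, schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=False,
        )
    except Exception as exc:  # dendropy raises assorted error classes
        raise ValueError(f"Newick parse error: {exc}") from exc
    return Phylogeny.from_dendropy(dtree)


def write_newick(tree: Phylogeny) -> str:
    """Serialize to Newick; re-reading preserves the unrooted topology and
    branch lengths exactly (lengths are written at full precision)."""
    return tree.newick()
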