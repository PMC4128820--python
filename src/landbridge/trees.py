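"""Rooted, time-scaled genealogies.

A :class:`TimeTree` is a binary rooted tree whose node ages are measured in
years before present (BP); extant samples sit at age 0 and ages increase
towards the root.  Internally the tree is stored in flat arrays (parent
pointers and ages) because the MCMC kernel mutates trees millions of times;
conversion to and from dendropy trees happens only at the I/O boundary.

Node indexing convention: for ``n`` tips, nodes ``0 .. n-1`` are tips (in the
order of ``labels``) and ``n .. 2n-2`` are internal nodes.  Exactly one node
has parent ``-1`` (the root).
"""

from __future__ import annotations

from typing import Iterable, Sequence

import dendropy
import numpy as np

from .errors import InvalidInputError

__all__ = ["TimeTree"]


class TimeTree:
    def __init__(self, parent: np.ndarray, ages: np.ndarray, labels: Sequence[str]):
        parent = np.asarray(parent, dtype=np.int64)
        ages = np.asarray(ages, dtype=float)
        n_nodes = parent.shape[0]
        if n_nodes % 2 == 0 or n_nodes < 3:
            raise InvalidInputError(
                f"a binary rooted tree has an odd node count >= 3, got {n_nodes}"
            )
        self.n_tips = (n_nodes + 1) // 2
        if len(labels) != self.n_tips:
            raise InvalidInputError(
                f"expected {self.n_tips} tip labels, got {len(labels)}"
            )
        self.parent = parent
        self.ages = ages
        self.labels = list(labels)
        self._tip_index = {lab: i for i, lab in enumerate(self.labels)}
        if len(self._tip_index) != self.n_tips:
            raise InvalidInputError("tip labels must be unique")
        self.validate()

    # ------------------------------------------------------------------ basic
    @property
    def n_nodes(self) -> int:
        return 2 * self.n_tips - 1

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent < 0)[0])

    @property
    def root_age(self) -> float:
        return float(self.ages[self.root])

    def children(self) -> list[list[int]]:
        ch: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i, p in enumerate(self.parent):
            if p >= 0:
                ch[p].append(i)
        return ch

    def postorder(self) -> list[int]:
        """Node indices, children always before parents."""
        order = np.argsort(self.ages, kind="stable")
        return [int(i) for i in order]

    def branch_lengths(self) -> np.ndarray:
        """Duration in years of the branch above each non-root node."""
        bl = np.zeros(self.n_nodes)
        nz = self.parent >= 0
        bl[nz] = self.ages[self.parent[nz]] - self.ages[nz]
        return bl

    def total_branch_length(self) -> float:
        return float(self.branch_lengths().sum())

    def coalescent_times(self) -> np.ndarray:
        """Ascending ages of the n-1 internal nodes."""
        return np.sort(self.ages[self.n_tips:])

    def copy(self) -> "TimeTree":
        return TimeTree(self.parent.copy(), self.ages.copy(), list(self.labels))

    def validate(self) -> None:
        n = self.n_tips
        if np.count_nonzero(self.parent < 0) != 1:
            raise InvalidInputError("tree must have exactly one root")
        counts = np.bincount(self.parent[self.parent >= 0], minlength=self.n_nodes)
        if np.any(counts[:n] != 0) or np.any(counts[n:] != 2):
            raise InvalidInputError("tree must be binary with tips as leaves")
        if np.any(self.ages[:n] != 0.0):
            raise InvalidInputError("tip ages must all be 0 (contemporaneous tips)")
        nz = self.parent >= 0
        if np.any(self.ages[self.parent[nz]] <= self.ages[nz]):
            raise InvalidInputError("every parent must be strictly older than its children")

    # -------------------------------------------------------------- set logic
    def tip_indices(self, taxa: Iterable[str]) -> np.ndarray:
        idx = []
        for t in taxa:
            if t not in self._tip_index:
                raise InvalidInputError(f"unknown taxon {t!r}")
            idx.append(self._tip_index[t])
        if not idx:
            raise InvalidInputError("taxon set is empty")
        return np.asarray(sorted(set(idx)), dtype=np.int64)

    def mrca(self, taxa: Iterable[str]) -> int:
        """Index of the most recent common ancestor of a taxon set."""
        idx = self.tip_indices(taxa)
        if len(idx) == 1:
            return int(idx[0])
        # walk up from the oldest candidate until all taxa are descendants
        masks = self._descendant_masks()
        want = np.zeros(self.n_tips, dtype=bool)
        want[idx] = True
        node = int(idx[0])
        while not np.all(want <= masks[node]):
            node = int(self.parent[node])
        return node

    def is_monophyletic(self, taxa: Iterable[str]) -> bool:
        idx = self.tip_indices(taxa)
        m = self.mrca(self.labels[i] for i in idx)
        return int(self._descendant_masks()[m].sum()) == len(idx)

    def _descendant_masks(self) -> np.ndarray:
        """(n_nodes, n_tips) boolean descendant-tip masks."""
        masks = np.zeros((self.n_nodes, self.n_tips), dtype=bool)
        masks[np.arange(self.n_tips), np.arange(self.n_tips)] = True
        for i in self.postorder():
            p = self.parent[i]
            if p >= 0:
                masks[p] |= masks[i]
        return masks

    def clades(self) -> dict[int, frozenset[str]]:
        """Map internal node index -> frozenset of descendant tip labels."""
        masks = self._descendant_masks()
        out = {}
        for i in range(self.n_tips, self.n_nodes):
            out[i] = frozenset(self.labels[j] for j in np.flatnonzero(masks[i]))
        return out

    # --------------------------------------------------------------------- IO
    def to_dendropy(self, taxon_namespace: dendropy.TaxonNamespace | None = None) -> dendropy.Tree:
        tns = taxon_namespace or dendropy.TaxonNamespace(self.labels)
        tree = dendropy.Tree(taxon_namespace=tns)
        nodes = {}
        for i in range(self.n_nodes):
            nd = dendropy.Node()
            if i < self.n_tips:
                nd.taxon = tns.get_taxon(self.labels[i])
            nodes[i] = nd
        for i, p in enumerate(self.parent):
            if p >= 0:
                nodes[int(p)].add_child(nodes[i])
                nodes[i].edge.length = float(self.ages[p] - self.ages[i])
        tree.seed_node = nodes[self.root]
        return tree

    def to_newick(self) -> str:
        return self.to_dendropy().as_string(schema="newick", suppress_rooting=True).strip()

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "TimeTree":
        leaves = [lf for lf in tree.leaf_node_iter()]
        labels = []
        for lf in leaves:
            labels.append(lf.taxon.label if lf.taxon is not None else str(id(lf)))
        n = len(labels)
        index = {}
        for i, lf in enumerate(leaves):
            index[id(lf)] = i
        internals = [nd for nd in tree.preorder_node_iter() if not nd.is_leaf()]
        for j, nd in enumerate(internals):
            index[id(nd)] = n + j
        n_nodes = 2 * n - 1
        if n + len(internals) != n_nodes:
            raise InvalidInputError("tree is not strictly binary")
        depth = {id(tree.seed_node): 0.0}
        for nd in tree.preorder_node_iter():
            if nd.parent_node is not None:
                if nd.edge.length is None:
                    raise InvalidInputError(
                        "time tree requires branch lengths on every edge"
                    )
                depth[id(nd)] = depth[id(nd.parent_node)] + float(nd.edge.length)
        root_age = max(depth[id(lf)] for lf in leaves)
        parent = np.full(n_nodes, -1, dtype=np.int64)
        ages = np.zeros(n_nodes)
        for nd in tree.preorder_node_iter():
            i = index[id(nd)]
            ages[i] = root_age - depth[id(nd)]
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
        ages[:n] = 0.0  # contemporaneous-tip convention; caller may check ultrametricity
        return cls(parent, ages, labels)

    @classmethod
    def from_newick(cls, newick: str) -> "TimeTree":
        try:
            tree = dendropy.Tree.get(
                data=newick, schema="newick", suppress_internal_node_taxa=True
            )
        except Exception as exc:  # dendropy reports the character position itself
            raise InvalidInputError(f"unparseable newick string: {exc}") from exc
        return cls.from_dendropy(tree)

    def is_ultrametric(self, rtol: float = 1e-6) -> bool:
        d = self.to_dendropy()
        depths = []
        depth = {id(d.seed_node): 0.0}
        for nd in d.preorder_node_iter():
            if nd.parent_node is not None:
                depth[id(nd)] = depth[id(nd.parent_node)] + float(nd.edge.length or 0.0)
            if nd.is_leaf():
                depths.append(depth[id(nd)])
        depths = np.asarray(depths)
        scale = max(depths.max(), 1e-300)
        return bool((depths.max() - depths.min()) / scale <= rtol)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<TimeTree n_tips={self.n_tips} root_age={self.root_age:.1f}>"
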