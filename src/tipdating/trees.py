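"""Rooted, dated binary trees with heterochronous tips.

A :class:`TimeTree` stores node ages in years before present (BP), so a
branch's duration is simply ``age[parent] - age[child]``.  Tips occupy node
indices ``0 .. n_tips-1`` in the order of ``labels``; internal nodes follow.
Every internal node must be strictly older than each of its children.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TimeTree", "parse_newick", "tree_to_newick"]


@dataclass
class TimeTree:
    labels: list[str]
    parent: np.ndarray  # int64, -1 at the root
    left: np.ndarray    # int64, -1 at tips
    right: np.ndarray   # int64, -1 at tips
    age: np.ndarray     # float64, years BP
    root: int
    _postorder: np.ndarray | None = field(default=None, repr=False, compare=False)

    # ------------------------------------------------------------------ basics
    @property
    def n_tips(self) -> int:
        return len(self.labels)

    @property
    def n_nodes(self) -> int:
        return len(self.age)

    def is_tip(self, node: int) -> bool:
        return node < self.n_tips

    def children(self, node: int) -> tuple[int, int]:
        return int(self.left[node]), int(self.right[node])

    def copy(self) -> "TimeTree":
        return TimeTree(
            labels=self.labels,
            parent=self.parent.copy(),
            left=self.left.copy(),
            right=self.right.copy(),
            age=self.age.copy(),
            root=self.root,
            _postorder=self._postorder,
        )

    def invalidate(self) -> None:
        """Call after any topology change; cached traversals are discarded."""
        self._postorder = None

    # -------------------------------------------------------------- traversal
    def postorder(self) -> np.ndarray:
        """Indices of all nodes, children before parents (iterative)."""
        if self._postorder is not None:
            return self._postorder
        order = np.empty(self.n_nodes, dtype=np.int64)
        stack = [(self.root, False)]
        k = 0
        while stack:
            node, done = stack.pop()
            if done or self.is_tip(node):
                order[k] = node
                k += 1
            else:
                stack.append((node, True))
                stack.append((int(self.right[node]), False))
                stack.append((int(self.left[node]), False))
        self._postorder = order
        return order

    def tip_ages(self) -> dict[str, float]:
        return {lab: float(self.age[i]) for i, lab in enumerate(self.labels)}

    def clade_bitmask(self) -> dict[int, int]:
        """Per node, an integer bitmask of descendant tip indices."""
        masks: dict[int, int] = {}
        for node in self.postorder():
            node = int(node)
            if self.is_tip(node):
                masks[node] = 1 << node
            else:
                masks[node] = masks[int(self.left[node])] | masks[int(self.right[node])]
        return masks

    def mrca(self, tip_labels: list[str]) -> int:
        want = 0
        index = {lab: i for i, lab in enumerate(self.labels)}
        for lab in tip_labels:
            want |= 1 << index[lab]
        best, best_size = self.root, self.n_tips + 1
        masks = self.clade_bitmask()
        for node, mask in masks.items():
            if mask & want == want:
                size = bin(mask).count("1")
                if size < best_size:
                    best, best_size = node, size
        return best

    # ------------------------------------------------------------- validation
    def validate(self, tip_ages: dict[str, float] | None = None, atol: float = 1e-6) -> None:
        if self.n_nodes != 2 * self.n_tips - 1:
            raise ValueError("tree is not binary")
        for node in range(self.n_nodes):
            if node == self.root:
                if self.parent[node] != -1:
                    raise ValueError("root has a parent")
                continue
            p = int(self.parent[node])
            if self.age[p] <= self.age[node]:
                raise ValueError(
                    f"node {node} (age {self.age[node]}) not younger than parent "
                    f"{p} (age {self.age[p]})"
                )
        if np.any(self.age < 0):
            raise ValueError("negative node age")
        if tip_ages is not None:
            for i, lab in enumerate(self.labels):
                if abs(self.age[i] - tip_ages[lab]) > atol:
                    raise ValueError(f"tip {lab} age mismatch")

    def is_valid(self) -> bool:
        try:
            self.validate()
            return True
        except ValueError:
            return False


# ---------------------------------------------------------------------- newick
def tree_to_newick(tree: TimeTree, fmt: str = ".17g") -> str:
    """Serialize with branch lengths in years (parent age minus child age)."""

    def rec(node: int) -> str:
        if tree.is_tip(node):
            body = tree.labels[node]
        else:
            body = f"({rec(int(tree.left[node]))},{rec(int(tree.right[node]))})"
        if node == tree.root:
            return body
        bl = tree.age[int(tree.parent[node])] - tree.age[node]
        return f"{body}:{format(bl, fmt)}"

    import sys

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 10 * tree.n_nodes + 100))
    try:
        return rec(tree.root) + ";"
    finally:
        sys.setrecursionlimit(old)


def parse_newick(
    text: str,
    tip_ages: dict[str, float] | None = None,
    atol: float = 1e-6,
) -> TimeTree:
    """Parse a binary Newick string into a :class:`TimeTree`.

    Node ages are reconstructed from branch lengths: with ``tip_ages`` given,
    every tip must satisfy ``tip_age + depth = root_age`` for a common root
    age (checked to ``atol`` relative tolerance); without, the deepest tip is
    anchored at age 0.
    """
    import dendropy

    dtree = dendropy.Tree.get(data=text, schema="newick")
    dnodes = list(dtree.preorder_node_iter())
    for nd in dnodes:
        nch = len(nd.child_nodes())
        if nch not in (0, 2):
            raise ValueError("non-binary node in Newick input")
        if nd.edge.length is not None and nd.edge.length < 0:
            raise ValueError("negative branch length")

    tips = [nd for nd in dtree.leaf_node_iter()]
    labels = [nd.taxon.label for nd in tips]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate tip labels")
    n_tips = len(labels)
    n_nodes = 2 * n_tips - 1

    index: dict[int, int] = {}
    next_internal = n_tips
    for nd in dnodes:
        if nd.is_leaf():
            index[id(nd)] = labels.index(nd.taxon.label)
        else:
            index[id(nd)] = next_internal
            next_internal += 1

    parent = np.full(n_nodes, -1, dtype=np.int64)
    left = np.full(n_nodes, -1, dtype=np.int64)
    right = np.full(n_nodes, -1, dtype=np.int64)
    depth = np.zeros(n_nodes)
    for nd in dnodes:
        i = index[id(nd)]
        if nd.parent_node is not None:
            depth[i] = depth[index[id(nd.parent_node)]] + (nd.edge.length or 0.0)
        ch = nd.child_nodes()
        if ch:
            left[i], right[i] = index[id(ch[0])], index[id(ch[1])]
            parent[index[id(ch[0])]] = i
            parent[index[id(ch[1])]] = i

    root = index[id(dtree.seed_node)]
    if tip_ages is None:
        root_age = float(np.max(depth[:n_tips]))
    else:
        implied = np.array([tip_ages[lab] + depth[i] for i, lab in enumerate(labels)])
        root_age = float(np.mean(implied))
        scale = max(abs(root_age), 1.0)
        if np.max(np.abs(implied - root_age)) > atol * scale:
            raise ValueError("tip ages and branch lengths imply inconsistent root ages")
    age = root_age - depth
    tree = TimeTree(labels=labels, parent=parent, left=left, right=right, age=age, root=root)
    tree.validate()
    return tree
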