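"""Rooted, time-calibrated phylogenies.

Trees are parsed and written with :mod:`dendropy` and converted to a flat
array representation (preorder node list, parent pointers, branch lengths)
that the likelihood code can traverse cheaply.  Branch lengths are in million
years throughout; all model code assumes the tree is ultrametric.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = ["Phylogeny", "parse_newick", "write_newick", "TreeError"]


class TreeError(ValueError):
    """Raised for malformed or unsupported tree input."""


@dataclass
class Phylogeny:
    """A rooted phylogeny in flat-array form.

    Nodes are stored in preorder (root first); ``parent[i]`` is the preorder
    index of node ``i``'s parent (-1 for the root) and ``blen[i]`` the length
    of the branch subtending node ``i`` (0 for the root).  Every edge is
    addressable by the key of its child node: the tip label for terminal
    edges, an autogenerated ``"n<k>"`` label for unlabeled internal edges.
    """

    parent: np.ndarray            # (N,) int, -1 at root
    blen: np.ndarray              # (N,) float, million years
    node_keys: list[str]          # (N,) edge key of the branch above each node
    tip_index: dict[str, int]     # tip label -> preorder node index
    ultrametric_rtol: float = 1e-6
    _depth: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        n = len(self.parent)
        if n == 0 or self.parent[0] != -1 or np.any(self.parent[1:] < 0):
            raise TreeError("tree must be rooted with nodes in preorder")
        if np.any(self.blen < 0):
            raise TreeError("negative branch length")
        labels = list(self.tip_index)
        if len(set(labels)) != len(labels) or any(not s for s in labels):
            raise TreeError("tip labels must be unique and non-empty")
        depth = np.zeros(n)
        for i in range(1, n):
            depth[i] = depth[self.parent[i]] + self.blen[i]
        self._depth = depth
        h = self.height
        tip_depths = depth[list(self.tip_index.values())]
        if h > 0 and np.any(np.abs(tip_depths - h) > self.ultrametric_rtol * h):
            raise TreeError(
                "tree is not ultrametric within relative tolerance "
                f"{self.ultrametric_rtol:g}: tip depths {tip_depths}"
            )

    # -- basic accessors ---------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def tips(self) -> list[str]:
        """Tip labels, sorted for a stable species ordering."""
        return sorted(self.tip_index)

    @property
    def n_tips(self) -> int:
        return len(self.tip_index)

    @property
    def height(self) -> float:
        """Root-to-tip height (the age of the root), in million years."""
        return float(max(self._depth[i] for i in self.tip_index.values()))

    @property
    def edge_keys(self) -> list[str]:
        """Keys of all edges (children of the root included), root excluded."""
        return self.node_keys[1:]

    def depth(self, node: int) -> float:
        """Distance from the root to ``node``."""
        return float(self._depth[node])

    def node_of(self, key: str) -> int:
        """Preorder index of the node whose subtending edge has ``key``."""
        try:
            return self.node_keys.index(key)
        except ValueError:
            raise TreeError(f"no edge with key {key!r}") from None

    def is_tip_edge(self, key: str) -> bool:
        return key in self.tip_index

    # -- derived structure -------------------------------------------------

    def mrca_depth_matrix(self) -> np.ndarray:
        """(S, S) matrix of root-to-MRCA distances for tip pairs.

        Tips are ordered as in :attr:`tips`; the diagonal holds tip depths.
        """
        tips = self.tips
        s = len(tips)
        # ancestor sets per tip (including the tip itself)
        anc: list[dict[int, float]] = []
        for lab in tips:
            chain = {}
            i = self.tip_index[lab]
            while i != -1:
                chain[i] = self._depth[i]
                i = self.parent[i]
            anc.append(chain)
        out = np.zeros((s, s))
        for a in range(s):
            for b in range(s):
                shared = anc[a].keys() & anc[b].keys()
                out[a, b] = max(anc[a][i] for i in shared)
        return out

    def pair_divergence_times(self) -> np.ndarray:
        """(S, S) matrix of times since the MRCA of each tip pair (T_ij)."""
        md = self.mrca_depth_matrix()
        h = self.height
        out = h - md
        np.fill_diagonal(out, 0.0)
        return out

    def path_edges(self, tip: str) -> list[int]:
        """Preorder node indices of the edges on the root-to-tip path."""
        out = []
        i = self.tip_index[tip]
        while i != 0:
            out.append(i)
            i = self.parent[i]
        out.reverse()
        return out


def _from_dendropy(tree: dendropy.Tree, rtol: float = 1e-6) -> Phylogeny:
    root = tree.seed_node
    order = list(root.preorder_iter())
    index = {id(nd): i for i, nd in enumerate(order)}
    parent = np.empty(len(order), dtype=np.int64)
    blen = np.zeros(len(order))
    node_keys: list[str] = []
    tip_index: dict[str, int] = {}
    auto = 0
    for i, nd in enumerate(order):
        if nd is root:
            parent[i] = -1
            node_keys.append("root")
            continue
        parent[i] = index[id(nd.parent_node)]
        if nd.edge.length is None:
            raise TreeError(
                f"missing branch length on edge above node #{i}; "
                "branch lengths are required on every edge"
            )
        blen[i] = float(nd.edge.length)
        if nd.is_leaf():
            if nd.taxon is None or not nd.taxon.label:
                raise TreeError("unlabeled tip")
            lab = nd.taxon.label
            tip_index[lab] = i
            node_keys.append(lab)
        elif nd.label:
            node_keys.append(nd.label)
        else:
            auto += 1
            node_keys.append(f"n{auto}")
    return Phylogeny(parent=parent, blen=blen, node_keys=node_keys,
                     tip_index=tip_index, ultrametric_rtol=rtol)


def parse_newick(text: str, ultrametric_rtol: float = 1e-6,
                 require_ultrametric: bool = True) -> Phylogeny:
    """Parse a rooted Newick string with branch lengths into a Phylogeny.

    The tree must carry a branch length on every edge (a missing length is an
    error, never silently defaulted) and, unless ``require_ultrametric`` is
    switched off, must be ultrametric within ``ultrametric_rtol`` relative to
    the root height.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            rooting="force-rooted",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise TreeError(f"malformed Newick: {exc}") from exc
    rtol = ultrametric_rtol if require_ultrametric else np.inf
    return _from_dendropy(tree, rtol=rtol)


def write_newick(tree: Phylogeny) -> str:
    """Serialize back to Newick; round-trips branch lengths via repr."""
    children: dict[int, list[int]] = {}
    for i in range(1, tree.n_nodes):
        children.setdefault(int(tree.parent[i]), []).append(i)

    def render(i: int) -> str:
        kids = children.get(i, [])
        if not kids:
            core = tree.node_keys[i]
        else:
            core = "(" + ",".join(render(k) for k in kids) + ")"
        if i == 0:
            return core + ":0"
        return f"{core}:{float(tree.blen[i])!r}"

    return render(0) + ";"
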