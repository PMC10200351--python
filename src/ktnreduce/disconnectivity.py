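"""Effective free energies and disconnectivity graphs for reduced networks.

A GT-reduced chain has no literal potential energy, but its renormalized
stationary distribution and rates define an effective free-energy surface at
temperature T (k_B = h = 1):

    f_w      = -T ln(pi'_w)
    f+_ww'   = f_w' - T ln(B'_ww' / tau'_w') + T ln(T)

for each connected pair; B'_ww'/tau'_w' is the renormalized rate constant
K'_ww'.  The reverse-direction form f_w - T ln(B'_w'w / tau'_w) + T ln T is
equal whenever the chain satisfies detailed balance with pi', and both are
computed and checked.  The
transition-state free energy is defined precisely so that
K'_w'w = T exp(-(f+ - f_w)/T) reproduces the renormalized rate.

The disconnectivity tree groups minima into superbasins: at each threshold
level the superbasins are the connected components of the subgraph whose
transition states lie at or below the threshold, and the tree records the
merges bottom-up.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ktn_model import KTNValidationError

__all__ = [
    "FreeEnergyGraph",
    "TreeNode",
    "effective_free_energies",
    "disconnectivity_tree",
    "monotonic_sequence_minima",
    "reconstructed_rates",
    "superbasin_count",
    "leaf_layout",
    "render_tree",
]


@dataclass
class FreeEnergyGraph:
    """Effective free energies of retained nodes and their transition states."""

    f: np.ndarray            # per-node effective free energy
    edges: np.ndarray        # (m, 2) node-index pairs
    f_ts: np.ndarray         # per-edge transition-state free energy
    temperature: float
    node_ids: np.ndarray | None = None


@dataclass
class TreeNode:
    """Superbasin node of a disconnectivity tree.

    Leaves carry ``leaf`` (a minimum's index) and merge nodes carry the
    threshold ``level`` at which their children became connected.
    """

    level: float
    children: list = field(default_factory=list)
    leaf: int | None = None

    @property
    def is_leaf(self) -> bool:
        return self.leaf is not None

    def leaves(self) -> list:
        if self.is_leaf:
            return [self.leaf]
        out = []
        for ch in self.children:
            out.extend(ch.leaves())
        return out

    def size(self) -> int:
        return len(self.leaves())


def effective_free_energies(reduced, temperature: float) -> FreeEnergyGraph:
    """Effective free-energy surface of a reduced (or any B/tau/pi) network.

    Both directional forms of the transition-state free energy are computed
    and must agree to 1e-10 (they coincide iff detailed balance holds with
    the renormalized stationary distribution).  The defining rate
    round trip T exp(-(f+ - f_w)/T) = B'_w'w / tau'_w is exact by
    construction.  Edges with zero branching probability are omitted.
    """
    T = float(temperature)
    B, tau, pi = reduced.B, reduced.tau, reduced.pi
    n = B.shape[0]
    f = -T * np.log(pi)
    pairs = []
    fts = []
    for a in range(n):
        for b in range(a + 1, n):
            if B[a, b] <= 0 or B[b, a] <= 0:
                continue
            # via the b -> a rate and via the a -> b rate
            f_ab = f[b] - T * np.log(B[a, b] / tau[b]) + T * np.log(T)
            f_ba = f[a] - T * np.log(B[b, a] / tau[a]) + T * np.log(T)
            scale = max(abs(f_ab), abs(f_ba), 1.0)
            if abs(f_ab - f_ba) > 1e-10 * scale:
                raise KTNValidationError(
                    f"directional transition-state free energies disagree on edge "
                    f"({a}, {b}): {f_ab!r} vs {f_ba!r}; detailed balance violated"
                )
            pairs.append((a, b))
            fts.append(0.5 * (f_ab + f_ba))
    return FreeEnergyGraph(
        f=f,
        edges=np.array(pairs, dtype=int).reshape(-1, 2),
        f_ts=np.array(fts),
        temperature=T,
        node_ids=getattr(reduced, "node_ids", None),
    )


def reconstructed_rates(graph: FreeEnergyGraph):
    """Rates implied by the free-energy surface: K_w'w = T exp(-(f+ - f_w)/T).

    Returns (log_fwd, log_bwd) per edge — the rate out of the first and
    second endpoint respectively — for round-trip validation against the
    renormalized rates.
    """
    T = graph.temperature
    fa = graph.f[graph.edges[:, 0]]
    fb = graph.f[graph.edges[:, 1]]
    log_fwd = np.log(T) - (graph.f_ts - fa) / T
    log_bwd = np.log(T) - (graph.f_ts - fb) / T
    return log_fwd, log_bwd


def disconnectivity_tree(f, edges, f_ts, levels) -> TreeNode:
    """Build a superbasin tree from node and transition-state energies.

    At each threshold the superbasins are connected components of the
    subgraph with f_ts <= threshold; merges are recorded bottom-up.  Children
    of each merge node are ordered by basin size (descending), ties by the
    smallest contained minimum index, which gives a deterministic layout.
    Thresholds must be strictly increasing and span the transition states; a
    virtual root above the last level joins any remaining components.
    """
    f = np.asarray(f, dtype=float)
    edges = np.asarray(edges, dtype=int).reshape(-1, 2)
    f_ts = np.asarray(f_ts, dtype=float)
    levels = np.asarray(levels, dtype=float)
    if levels.size and np.any(np.diff(levels) <= 0):
        raise KTNValidationError("threshold levels must be strictly increasing")
    n = f.size
    trees: dict[int, TreeNode] = {i: TreeNode(level=f[i], leaf=i) for i in range(n)}
    all_levels = list(levels)
    if not all_levels or (f_ts.size and all_levels[-1] < f_ts.max()):
        all_levels.append(float(f_ts.max()) if f_ts.size else 0.0)
    for lev in all_levels:
        parent = list(range(n))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for a, b in edges[f_ts <= lev]:
            ra, rb = find(int(a)), find(int(b))
            if ra != rb:
                parent[rb] = ra
        groups: dict[int, list[int]] = {}
        for key in trees:
            groups.setdefault(find(key), []).append(key)
        for keys in groups.values():
            if len(keys) > 1:
                node = TreeNode(level=float(lev))
                node.children = sorted(
                    (trees.pop(k) for k in keys),
                    key=lambda c: (-c.size(), min(c.leaves())),
                )
                trees[min(keys)] = node
    remaining = [trees[k] for k in sorted(trees)]
    if len(remaining) == 1:
        return remaining[0]
    root = TreeNode(level=float(all_levels[-1]))
    root.children = sorted(remaining, key=lambda c: (-c.size(), min(c.leaves())))
    return root


def superbasin_count(n: int, edges, f_ts, threshold: float) -> int:
    """Number of superbasins (connected components with f_ts <= threshold)."""
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components

    edges = np.asarray(edges, dtype=int).reshape(-1, 2)
    f_ts = np.asarray(f_ts, dtype=float)
    keep = edges[f_ts <= threshold]
    adj = coo_matrix(
        (np.ones(len(keep)), (keep[:, 0], keep[:, 1])), shape=(n, n)
    )
    ncomp, _ = connected_components(adj, directed=False)
    return int(ncomp)


def leaf_layout(tree: TreeNode):
    """Deterministic x-positions for plotting: in-order leaf traversal."""
    leaves = tree.leaves()
    return {leaf: x for x, leaf in enumerate(leaves)}


def monotonic_sequence_minima(K_or_net, energies) -> np.ndarray:
    """Minima with no directly connected lower-energy neighbour.

    A node survives iff its energy is strictly below every neighbour's;
    exact ties are resolved by index, so exactly one of an energy-tied
    connected pair is kept.
    """
    K = getattr(K_or_net, "K", K_or_net)
    K = np.asarray(K)
    f = np.asarray(energies, dtype=float)
    n = f.size
    keep = []
    for i in range(n):
        nbrs = np.flatnonzero((K[:, i] > 0) | (K[i, :] > 0))
        nbrs = nbrs[nbrs != i]
        lower = (f[nbrs] < f[i]) | ((f[nbrs] == f[i]) & (nbrs < i))
        if not np.any(lower):
            keep.append(i)
    return np.array(keep, dtype=int)


def render_tree(tree: TreeNode, node_ids=None, indent: str = "  ") -> str:
    """Indented text rendering of a disconnectivity tree."""
    lines = []

    def walk(node: TreeNode, depth: int):
        if node.is_leaf:
            label = node.leaf if node_ids is None else node_ids[node.leaf]
            lines.append(f"{indent * depth}min {label}  f={node.level:.6g}")
        else:
            lines.append(f"{indent * depth}merge @ {node.level:.6g} ({node.size()} minima)")
            for ch in node.children:
                walk(ch, depth + 1)

    walk(tree, 0)
    return "\n".join(lines)
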