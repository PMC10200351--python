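"""Stochastic trajectory generation and ensemble observables.

Two samplers are provided: the standard rejection-free kinetic Monte Carlo
(kMC) algorithm — draw the next state from the current column of the
branching matrix B and an exponential waiting time with the node's mean —
and an absorbing-Markov-chain basin-escape sampler that treats the escape
from a whole metastable community as a single draw.

On GT-reduced networks columns of B can carry self-loops.  Rather than
iterating self-jumps, the number of consecutive visits is folded into a
geometric draw and the total dwell into a single gamma draw, which preserves
both the mean and the distribution of the occupation time.

Each trajectory gets its own generator seeded as (seed, trajectory index),
so ensembles are reproducible and order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ktn_model import CommunityPartition, KTNValidationError, RateNetwork
from .graph_transform import reduce_network

__all__ = [
    "Trajectory",
    "TrajectoryEnsemble",
    "kmc_trajectory",
    "simulate_ensemble",
    "BasinEscape",
    "basin_escape_sample",
    "occupation_probability",
    "empirical_fpt",
]


@dataclass
class Trajectory:
    nodes: np.ndarray   # visited states (internal indices)
    times: np.ndarray   # cumulative arrival times, times[0] == 0


@dataclass
class TrajectoryEnsemble:
    trajectories: list
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.trajectories)


class _JumpTable:
    """Per-column alias of off-diagonal jump targets, cumulative weights and
    self-loop probabilities, shared across trajectories."""

    def __init__(self, B: np.ndarray, tau: np.ndarray):
        n = B.shape[0]
        self.tau = np.asarray(tau, dtype=float)
        self.targets = []
        self.cum = []
        self.p_self = np.empty(n)
        for j in range(n):
            col = B[:, j].copy()
            self_p = col[j]
            col[j] = 0.0
            tgt = np.flatnonzero(col)
            w = col[tgt]
            s = w.sum()
            if s <= 0:
                self.targets.append(None)
                self.cum.append(None)
                self.p_self[j] = 1.0
                continue
            self.targets.append(tgt)
            self.cum.append(np.cumsum(w / s))
            # renormalize so self-loop + jumps account for the full column
            self.p_self[j] = self_p / (self_p + s)

    def step(self, j: int, rng: np.random.Generator):
        """One effective jump out of j: (next node, dwell time)."""
        tgt = self.targets[j]
        if tgt is None:
            raise KTNValidationError(f"node {j} has zero escape probability")
        # visits ~ Geometric(1 - p_self); dwell = sum of that many exponentials
        p_leave = 1.0 - self.p_self[j]
        visits = rng.geometric(p_leave) if self.p_self[j] > 0 else 1
        dwell = rng.gamma(visits, self.tau[j])
        nxt = tgt[np.searchsorted(self.cum[j], rng.random())]
        return int(nxt), float(dwell)


def kmc_trajectory(
    net,
    start: int,
    *,
    max_time: float | None = None,
    target=None,
    rng: np.random.Generator | int | None = None,
    table: _JumpTable | None = None,
) -> Trajectory:
    """Sample one rejection-free kMC trajectory.

    Stops on first entry into ``target`` (a node set) or when the next jump
    would exceed ``max_time`` (the final state then remains occupied).  At
    least one stop condition must be given.
    """
    if max_time is None and target is None:
        raise ValueError("need a max_time or a target set")
    rng = np.random.default_rng(rng)
    target_set = set(int(t) for t in np.atleast_1d(target)) if target is not None else set()
    if table is None:
        table = _JumpTable(net.B, net.tau)
    nodes = [int(start)]
    times = [0.0]
    t = 0.0
    cur = int(start)
    while cur not in target_set:
        if max_time is not None and t >= max_time:
            break
        nxt, dwell = table.step(cur, rng)
        t += dwell
        if max_time is not None and t > max_time:
            break
        cur = nxt
        nodes.append(cur)
        times.append(t)
    return Trajectory(np.array(nodes, dtype=int), np.array(times))


def simulate_ensemble(
    net,
    n_traj: int,
    p0,
    *,
    max_time: float | None = None,
    target=None,
    seed: int = 0,
    metadata: dict | None = None,
) -> TrajectoryEnsemble:
    """Sample an ensemble of kMC trajectories.

    ``p0`` is an :class:`~ktnreduce.spectral_fpt.InitialDistribution`, a
    probability vector over all nodes, or a single start node.  Trajectory i
    uses the generator seeded with (seed, i).
    """
    table = _JumpTable(net.B, net.tau)
    n = net.B.shape[0]
    if np.isscalar(p0):
        starts = np.full(n_traj, int(p0))
    else:
        if hasattr(p0, "as_vector"):
            vec = p0.as_vector(n)
        else:
            vec = np.asarray(p0, dtype=float)
        vec = vec / vec.sum()
        starts = np.random.default_rng([seed, 2**31 - 1]).choice(n, size=n_traj, p=vec)
    trajs = [
        kmc_trajectory(
            net, starts[i], max_time=max_time, target=target,
            rng=np.random.default_rng([seed, i]), table=table,
        )
        for i in range(n_traj)
    ]
    meta = {"seed": seed, "n_traj": n_traj, "max_time": max_time}
    meta.update(metadata or {})
    return TrajectoryEnsemble(trajs, meta)


@dataclass
class BasinEscape:
    """Precomputed single-draw escape statistics for one community and start node.

    GT eliminates every community state except the start; the remaining
    column of the renormalized branching matrix gives the absorption
    probabilities onto the external neighbours, and the renormalized waiting
    time divided by the per-visit leave probability is the exact mean escape
    time.  The escape time is drawn as a single exponential with that mean —
    exact in mean, and the correct shape in the metastable limit where the
    escape is dominated by one slow mode.
    """

    exit_nodes: np.ndarray
    exit_probs: np.ndarray
    mean_escape_time: float

    def sample(self, rng: np.random.Generator):
        node = rng.choice(self.exit_nodes, p=self.exit_probs)
        return int(node), float(rng.exponential(self.mean_escape_time))


def prepare_basin_escape(
    net: RateNetwork, partition: CommunityPartition, community, start: int
) -> BasinEscape:
    members = partition.communities[community]
    if start not in members:
        raise KTNValidationError(
            f"start node {start} is not in community {community!r}"
        )
    Z = np.setdiff1d(members, [start])
    red = reduce_network(net, Z) if Z.size else None
    if red is None:
        B, tau = net.B, net.tau
        pos = start
        kept = np.arange(net.n)
    else:
        B, tau = red.B, red.tau
        kept = red.retained
        pos = int(np.flatnonzero(kept == start)[0])
    col = B[:, pos].copy()
    self_p = col[pos]
    col[pos] = 0.0
    leave = col.sum()
    if leave <= 0:
        raise KTNValidationError(f"community {community!r} has no escape")
    mean_t = tau[pos] / leave
    return BasinEscape(
        exit_nodes=kept[np.flatnonzero(col)],
        exit_probs=col[np.flatnonzero(col)] / leave,
        mean_escape_time=float(mean_t),
    )


def basin_escape_sample(
    net: RateNetwork,
    partition: CommunityPartition,
    community,
    start: int,
    rng: np.random.Generator | int | None = None,
):
    """Draw (exit node, escape time) for one basin escape; see :class:`BasinEscape`."""
    rng = np.random.default_rng(rng)
    return prepare_basin_escape(net, partition, community, start).sample(rng)


def occupation_probability(
    ens: TrajectoryEnsemble,
    partition_labels,
    time_grid: np.ndarray,
):
    """Fraction of trajectories occupying each community at each grid time.

    ``partition_labels`` is a :class:`CommunityPartition` or a per-node label
    array (for reduced networks, pass labels of the retained nodes in
    retained order).  Returns (community labels, array of shape
    (n_times, n_communities)); rows sum to one.  Trajectories censored before
    a grid time are held at their final state.
    """
    labels = (
        partition_labels.labels
        if isinstance(partition_labels, CommunityPartition)
        else np.asarray(partition_labels)
    )
    comm_labels = np.unique(labels)
    pos_of = {lab: k for k, lab in enumerate(comm_labels)}
    counts = np.zeros((len(time_grid), comm_labels.size))
    for traj in ens.trajectories:
        idx = np.searchsorted(traj.times, time_grid, side="right") - 1
        idx = np.clip(idx, 0, len(traj.nodes) - 1)
        at = labels[traj.nodes[idx]]
        for r, lab in enumerate(at):
            counts[r, pos_of[lab]] += 1
    return comm_labels, counts / len(ens.trajectories)


def empirical_fpt(
    ens: TrajectoryEnsemble,
    target,
    bins: int | np.ndarray = 50,
):
    """Histogram of ln(first-passage time) into a target node set.

    Returns (bin_edges_in_y, counts, n_censored, fpts); trajectories that
    never reach the target contribute to the censored count only.
    """
    target_set = set(int(t) for t in np.atleast_1d(target))
    fpts = []
    censored = 0
    for traj in ens.trajectories:
        hit = np.flatnonzero(np.isin(traj.nodes, list(target_set)))
        if hit.size:
            fpts.append(traj.times[hit[0]])
        else:
            censored += 1
    if not fpts:
        raise KTNValidationError("every trajectory was censored before the target")
    y = np.log(np.array(fpts))
    counts, edges = np.histogram(y, bins=bins)
    return edges, counts, censored, np.array(fpts)
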