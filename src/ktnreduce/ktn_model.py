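"""Core data model for continuous-time Markov chains on kinetic transition networks.

A kinetic transition network (KTN) is a weighted graph whose nodes are discrete
states (e.g. potential-energy minima) and whose edges carry pairwise transition
rates.  The chain is held column-oriented: ``K[i, j]`` is the rate for the jump
``j -> i``, the mean waiting time of node ``j`` is ``tau[j] = 1 / sum_g K[g, j]``,
the branching (jump) matrix is ``B = K D^-1`` with ``D = diag(1/tau)``, and the
generator is ``Q = K - D``.  Columns of ``B`` sum to one and columns of ``Q``
sum to zero, so total occupation probability is conserved under
``dP/dt = Q P``.

Node ids are 1-based (or arbitrary integer labels) in files and 0-based
contiguous internally; the mapping is kept on the network object and used for
all output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import null_space
from scipy.special import logsumexp

__all__ = [
    "KTNValidationError",
    "NonErgodicError",
    "PrecisionLossError",
    "RateNetwork",
    "CommunityPartition",
    "load_network",
    "write_network",
    "read_discotress",
    "read_communities",
    "stationary_distribution",
    "build_partition",
    "check_detailed_balance",
]

#: pairwise flux residual below which a chain is flagged reversible
REVERSIBLE_TOL = 1e-10


class KTNValidationError(ValueError):
    """Raised when an input network violates a structural requirement."""


class NonErgodicError(KTNValidationError):
    """Raised when the chain has no unique stationary distribution."""


class PrecisionLossError(RuntimeError):
    """Raised when finite-precision cancellation invalidates a result."""


@dataclass
class RateNetwork:
    """A reversible (or general) CTMC with all derived quantities.

    Attributes
    ----------
    K : (n, n) ndarray
        Transition rates, ``K[i, j]`` = rate j -> i, zero diagonal.
    tau : (n,) ndarray
        Mean waiting times ``tau[j] = 1 / sum_g K[g, j]``.
    B : (n, n) ndarray
        Column-stochastic branching matrix ``B = K D^-1``.
    Q : (n, n) ndarray
        Rate (generator) matrix ``Q = K - D``; column sums vanish.
    pi : (n,) ndarray
        Stationary distribution, ``Q pi = 0``, ``sum(pi) = 1``.
    node_ids : (n,) ndarray
        Original file labels; ``node_ids[i]`` is the label of internal node i.
    energies : (n,) ndarray or None
        Node energies E_i in units with k_B = 1 (``pi ~ exp(-E/T)``).
    temperature : float
    reversible : bool
        True when the maximum relative detailed-balance residual is below
        ``REVERSIBLE_TOL``.
    """

    K: np.ndarray
    tau: np.ndarray
    B: np.ndarray
    Q: np.ndarray
    pi: np.ndarray
    node_ids: np.ndarray
    energies: np.ndarray | None = None
    temperature: float = 1.0
    reversible: bool = False
    balance_residual: float = field(default=np.nan)

    @property
    def n(self) -> int:
        return self.K.shape[0]

    def index_of(self, label) -> int:
        """Internal index of an original node label."""
        hits = np.flatnonzero(self.node_ids == label)
        if hits.size != 1:
            raise KeyError(f"unknown node label {label!r}")
        return int(hits[0])

    @classmethod
    def from_rates(
        cls,
        K: np.ndarray,
        energies: np.ndarray | None = None,
        temperature: float = 1.0,
        node_ids: np.ndarray | None = None,
        pi: np.ndarray | None = None,
    ) -> "RateNetwork":
        """Build a network from a rate matrix, populating derived fields."""
        K = np.asarray(K, dtype=float).copy()
        n = K.shape[0]
        if K.shape != (n, n):
            raise KTNValidationError("rate matrix must be square")
        np.fill_diagonal(K, 0.0)
        if np.any(K < 0):
            raise KTNValidationError("negative transition rate")
        esc = K.sum(axis=0)
        if np.any(esc <= 0):
            dead = np.flatnonzero(esc <= 0)
            raise KTNValidationError(f"nodes with zero escape rate: {dead.tolist()}")
        tau = 1.0 / esc
        B = K * tau[None, :]
        Q = K - np.diag(esc)
        net = cls(
            K=K,
            tau=tau,
            B=B,
            Q=Q,
            pi=np.empty(n),
            node_ids=np.arange(1, n + 1) if node_ids is None else np.asarray(node_ids),
            energies=None if energies is None else np.asarray(energies, dtype=float),
            temperature=float(temperature),
        )
        net.pi = pi if pi is not None else stationary_distribution(net)
        check_detailed_balance(net)
        return net


@dataclass
class CommunityPartition:
    """Non-overlapping partition of the nodes into communities.

    ``labels[i]`` is the community of internal node i (the participation
    function).  ``boundary[X]`` holds the nodes of X with at least one edge to
    a different community — the states mediating all inter-community flux —
    and ``interior[X]`` the complement within X.  ``b0[X]`` is the node of
    maximal stationary probability in X (ties broken by smallest internal id).
    """

    labels: np.ndarray
    communities: dict
    boundary: dict
    interior: dict
    b0: dict

    @property
    def community_labels(self) -> list:
        return list(self.communities)

    def nodes(self, label) -> np.ndarray:
        return self.communities[label]

    def retained_nodes(self) -> np.ndarray:
        """Union over communities of boundary nodes plus the pi-maximum node."""
        keep: set[int] = set()
        for lab in self.communities:
            keep.update(int(x) for x in self.boundary[lab])
            keep.add(int(self.b0[lab]))
        return np.array(sorted(keep), dtype=int)


# ---------------------------------------------------------------------------
# stationary distribution and detailed balance
# ---------------------------------------------------------------------------

def stationary_distribution(net: RateNetwork) -> np.ndarray:
    """Stationary distribution pi with Q pi = 0 and sum(pi) = 1.

    When node energies are available pi is computed in log space as the
    Boltzmann distribution exp(-E_i/T) / Z (robust at low temperature) and
    cross-checked against the null-space condition Q pi = 0.  Otherwise pi is
    the one-dimensional null space of Q.
    """
    if net.energies is not None:
        logw = -net.energies / net.temperature
        pi = np.exp(logw - logsumexp(logw))
        resid = np.max(np.abs(net.Q @ pi)) / max(np.max(net.K.sum(axis=0) * pi), 1e-300)
        if resid > 1e-8:
            raise NonErgodicError(
                f"Boltzmann weights are not stationary (residual {resid:.2e}); "
                "energies inconsistent with the rates"
            )
        return pi
    if net.n == 2:
        # closed form; makes the pairwise flux identity exact in floating point
        pi = np.array([net.K[0, 1], net.K[1, 0]])
        return pi / pi.sum()
    ns = null_space(net.Q)
    if ns.shape[1] != 1:
        raise NonErgodicError(
            f"zero eigenvalue of Q has multiplicity {ns.shape[1]}; chain is not ergodic"
        )
    pi = ns[:, 0]
    pi = pi / pi.sum()
    if np.any(pi <= 0):
        raise NonErgodicError("stationary distribution has non-positive entries")
    return pi


def check_detailed_balance(net: RateNetwork) -> float:
    """Maximum relative pairwise flux residual max |K_ji pi_i - K_ij pi_j| / max flux.

    Sets ``net.reversible`` to True iff the residual is at most 1e-10.  A
    two-state chain always returns exactly zero.
    """
    F = net.K * net.pi[None, :]  # F[i, j] = flux j -> i
    fmax = F.max()
    if fmax == 0:
        net.balance_residual = 0.0
        net.reversible = True
        return 0.0
    resid = float(np.max(np.abs(F - F.T)) / fmax)
    net.balance_residual = resid
    net.reversible = resid <= REVERSIBLE_TOL
    return resid


# ---------------------------------------------------------------------------
# partitions
# ---------------------------------------------------------------------------

def build_partition(net: RateNetwork, assignment) -> CommunityPartition:
    """Build a :class:`CommunityPartition` from a node -> label assignment.

    ``assignment`` is an array of labels over internal nodes, or a mapping
    from original node label to community.  Boundary status is read off the
    nonzero structure of K; ``b0`` is the argmax of pi over the whole
    community (boundary included), ties broken by smallest internal id.
    """
    if isinstance(assignment, dict):
        labels = np.array([assignment[lab] for lab in net.node_ids])
    else:
        labels = np.asarray(assignment)
    if labels.shape[0] != net.n:
        raise KTNValidationError(
            f"assignment covers {labels.shape[0]} nodes, network has {net.n}"
        )
    adj = net.K > 0
    communities: dict = {}
    boundary: dict = {}
    interior: dict = {}
    b0: dict = {}
    for lab in np.unique(labels):
        members = np.flatnonzero(labels == lab)
        if members.size == 0:
            raise KTNValidationError(f"community {lab!r} is empty")
        # a node is boundary iff it touches any node with a different label
        outside = labels != lab
        is_boundary = adj[outside][:, members].any(axis=0)
        communities[lab] = members
        boundary[lab] = members[is_boundary]
        interior[lab] = members[~is_boundary]
        # argmax of pi with floating-point ties resolved to the smallest id
        vals = net.pi[members]
        tied = members[vals >= vals.max() * (1.0 - 1e-12)]
        b0[lab] = int(tied.min())
    return CommunityPartition(labels, communities, boundary, interior, b0)


def read_communities(path) -> np.ndarray:
    """Read one community label per line; line n is node n of the node table."""
    with open(path) as fh:
        return np.array([line.split()[0] for line in fh if line.strip()])


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def _connected_components(K: np.ndarray) -> list[np.ndarray]:
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    ncomp, lab = connected_components(csr_matrix(K != 0), directed=False)
    return [np.flatnonzero(lab == c) for c in range(ncomp)]


def load_network(
    node_table,
    edge_table,
    temperature: float = 1.0,
    dialect: str = "linear",
) -> RateNetwork:
    """Load a network from a node table and an edge table (TSV with headers).

    nodes.tsv has columns ``id`` and either ``energy`` or ``log_stat_prob``.
    edges.tsv has columns ``i  j  rate_ij  rate_ji`` where column 3 is the
    rate i -> j and column 4 the rate j -> i; in the ``log`` dialect the rate
    columns are named ``log_rate_ij`` / ``log_rate_ji`` and hold natural logs
    (this survives magnitudes like exp(-E/T) at low temperature).
    """
    nodes = pd.read_csv(node_table, sep=r"\s+", float_precision="round_trip")
    edges = pd.read_csv(edge_table, sep=r"\s+", float_precision="round_trip")
    ids = nodes["id"].to_numpy()
    if np.unique(ids).size != ids.size:
        raise KTNValidationError("duplicate node id in node table")
    index = {lab: k for k, lab in enumerate(ids)}
    n = len(ids)

    if dialect == "log":
        fwd = np.exp(edges["log_rate_ij"].to_numpy(dtype=float))
        bwd = np.exp(edges["log_rate_ji"].to_numpy(dtype=float))
    elif dialect == "linear":
        fwd = edges["rate_ij"].to_numpy(dtype=float)
        bwd = edges["rate_ji"].to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    K = np.zeros((n, n))
    seen: set[tuple] = set()
    for row, (a, b) in enumerate(zip(edges["i"], edges["j"])):
        if a not in index or b not in index:
            missing = a if a not in index else b
            raise KTNValidationError(f"edge ({a}, {b}) references undeclared node {missing}")
        if a == b:
            raise KTNValidationError(f"self-edge on node {a}")
        key = (min(a, b), max(a, b))
        if key in seen:
            raise KTNValidationError(f"duplicate edge between nodes {key[0]} and {key[1]}")
        seen.add(key)
        if fwd[row] <= 0 or bwd[row] <= 0:
            raise KTNValidationError(f"nonpositive rate on edge ({a}, {b})")
        ia, ib = index[a], index[b]
        K[ib, ia] = fwd[row]  # rate a -> b
        K[ia, ib] = bwd[row]
    comps = _connected_components(K)
    if len(comps) > 1:
        sizes = [c.size for c in comps]
        raise KTNValidationError(
            f"network is disconnected: {len(comps)} components of sizes {sizes}"
        )

    energies = None
    pi = None
    if "energy" in nodes.columns:
        energies = nodes["energy"].to_numpy(dtype=float)
    elif "log_stat_prob" in nodes.columns:
        lp = nodes["log_stat_prob"].to_numpy(dtype=float)
        # treat ln pi as an effective energy surface: E = -T ln pi
        energies = -temperature * lp
        pi = np.exp(lp - logsumexp(lp))
    else:
        raise KTNValidationError("node table needs an 'energy' or 'log_stat_prob' column")
    return RateNetwork.from_rates(
        K, energies=energies, temperature=temperature, node_ids=ids, pi=pi
    )


def write_network(net: RateNetwork, nodes_path, edges_path, dialect: str = "linear") -> None:
    """Write nodes.tsv / edges.tsv; inverse of :func:`load_network`."""
    with open(nodes_path, "w") as fh:
        if net.energies is not None:
            fh.write("id\tenergy\n")
            for lab, e in zip(net.node_ids, net.energies):
                fh.write(f"{lab}\t{e:.17g}\n")
        else:
            fh.write("id\tlog_stat_prob\n")
            for lab, p in zip(net.node_ids, net.pi):
                fh.write(f"{lab}\t{np.log(p):.17g}\n")
    cols = ("rate_ij", "rate_ji") if dialect == "linear" else ("log_rate_ij", "log_rate_ji")
    with open(edges_path, "w") as fh:
        fh.write(f"i\tj\t{cols[0]}\t{cols[1]}\n")
        n = net.n
        for a in range(n):
            for b in range(a + 1, n):
                kf, kb = net.K[b, a], net.K[a, b]  # a->b, b->a
                if kf == 0 and kb == 0:
                    continue
                if dialect == "log":
                    fh.write(
                        f"{net.node_ids[a]}\t{net.node_ids[b]}\t"
                        f"{np.log(kf):.17g}\t{np.log(kb):.17g}\n"
                    )
                else:
                    fh.write(f"{net.node_ids[a]}\t{net.node_ids[b]}\t{kf:.17g}\t{kb:.17g}\n")


def read_discotress(stat_prob_path, ts_conns_path, ts_weights_path,
                    temperature: float = 1.0) -> RateNetwork:
    """Read the three-file convention stat_prob.dat / ts_conns.dat / ts_weights.dat.

    stat_prob.dat holds log stationary probabilities, one per node;
    ts_conns.dat holds the 1-based endpoints of each bidirectional edge; and
    ts_weights.dat holds log transition rates in edge order, two lines per
    edge (first the rate from the first endpoint to the second, then the
    reverse).
    """
    lp = np.loadtxt(stat_prob_path, dtype=float, ndmin=1)
    conns = np.loadtxt(ts_conns_path, dtype=int, ndmin=2)
    logk = np.loadtxt(ts_weights_path, dtype=float, ndmin=1)
    if logk.size != 2 * conns.shape[0]:
        raise KTNValidationError("ts_weights.dat must hold two lines per edge")
    n = lp.size
    K = np.zeros((n, n))
    for e, (a, b) in enumerate(conns):
        ia, ib = a - 1, b - 1
        if not (0 <= ia < n and 0 <= ib < n):
            raise KTNValidationError(f"edge ({a}, {b}) references undeclared node")
        K[ib, ia] = np.exp(logk[2 * e])      # a -> b
        K[ia, ib] = np.exp(logk[2 * e + 1])  # b -> a
    pi = np.exp(lp - logsumexp(lp))
    return RateNetwork.from_rates(
        K,
        energies=-temperature * lp,
        temperature=temperature,
        node_ids=np.arange(1, n + 1),
        pi=pi,
    )
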