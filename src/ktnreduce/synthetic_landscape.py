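"""Generator of multi-community model networks on a 2D multi-well potential.

The generator emulates a molecular energy landscape discretized as a kinetic
transition network: wells laid out on a grid (default 3x3, nine principal
communities), ~110 nodes per well placed around the well centre, node energy
given by the well base plus a quadratic confinement term plus noise, a
Poisson-like degree distribution obtained by sampling intra-well edges with
distance-decaying probability (connectivity enforced through a minimum
spanning tree), and inter-well edges between the closest node pairs of
adjacent wells — those endpoints are the ground-truth boundary nodes.

Every edge carries a shared transition-state energy
E+_ij = max(E_i, E_j) + barrier, with barriers drawn as a configurable
minimum plus an exponential; rates follow the Arrhenius form
K_ij = nu * exp(-(E+_ij - E_j) / T) (rate j -> i), so detailed balance with
pi ~ exp(-E/T) holds exactly by construction.  Inter-well barriers are drawn
larger than intra-well ones, making the communities metastable, increasingly
so as T falls.  Units have k_B = h = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import pdist, squareform

from .ktn_model import (
    CommunityPartition,
    KTNValidationError,
    RateNetwork,
    build_partition,
)

__all__ = [
    "LandscapeConfig",
    "generate",
    "arrhenius_rates",
    "metastability_report",
    "random_reversible_network",
]


@dataclass
class LandscapeConfig:
    """Parameters of the multi-well landscape generator.

    Energies are in units of k_B T at T = 1; times in units of the inverse
    attempt frequency.  ``intra_barrier_scale`` / ``inter_barrier_scale`` are
    the mean *added* barrier heights above the higher of the two endpoint
    energies; ``*_barrier_min`` are hard floors on the draw.
    """

    grid: tuple = (3, 3)
    nodes_per_community: int = 110
    target_mean_degree: float = 8.7
    well_depth_range: tuple = (-2.0, 0.0)
    intra_barrier_scale: float = 1.0
    inter_barrier_scale: float = 3.0
    intra_barrier_min: float = 0.1
    inter_barrier_min: float = 3.0
    temperature: float = 1.0
    prefactor: float = 1.0
    seed: int = 0
    well_spacing: float = 1.0
    position_sigma: float = 0.18
    curvature: float = 30.0
    energy_noise: float = 0.3
    inter_edges_per_pair: int = 8

    def __post_init__(self):
        if self.intra_barrier_scale <= 0 or self.inter_barrier_scale <= 0:
            raise KTNValidationError("barrier scales must be positive")
        if self.inter_barrier_scale < self.intra_barrier_scale:
            raise KTNValidationError(
                "inter-community barriers must be at least as large as "
                "intra-community barriers (metastability by construction)"
            )


def arrhenius_rates(E, edges, E_ts, temperature: float, prefactor: float = 1.0):
    """Log Arrhenius rates for each edge through a shared transition state.

    For edge (i, j) with transition-state energy E+_ij >= max(E_i, E_j):
    ln k(i->j) = ln nu - (E+_ij - E_i)/T and ln k(j->i) = ln nu -
    (E+_ij - E_j)/T.  Returned in log form so deep barriers never underflow;
    detailed balance with pi ~ exp(-E/T) is an algebraic identity of this
    form.  Raises when a transition state lies below either endpoint.
    """
    E = np.asarray(E, dtype=float)
    edges = np.asarray(edges, dtype=int)
    E_ts = np.asarray(E_ts, dtype=float)
    Ei = E[edges[:, 0]]
    Ej = E[edges[:, 1]]
    if np.any(E_ts < np.maximum(Ei, Ej) - 1e-12):
        bad = np.flatnonzero(E_ts < np.maximum(Ei, Ej) - 1e-12)
        raise KTNValidationError(
            f"transition-state energy below an endpoint on edges {bad.tolist()}"
        )
    lognu = np.log(prefactor)
    log_fwd = lognu - (E_ts - Ei) / temperature  # i -> j
    log_bwd = lognu - (E_ts - Ej) / temperature  # j -> i
    return log_fwd, log_bwd


def _intra_edges(pos: np.ndarray, m_target: int, rng: np.random.Generator,
                 length_scale: float) -> set:
    """Exactly m_target distance-weighted pairs including an MST for connectivity."""
    n = pos.shape[0]
    d = squareform(pdist(pos))
    mst = minimum_spanning_tree(csr_matrix(d)).tocoo()
    edges = {
        (min(int(a), int(b)), max(int(a), int(b))) for a, b in zip(mst.row, mst.col)
    }
    iu = np.triu_indices(n, k=1)
    in_tree = np.array([(int(a), int(b)) in edges for a, b in zip(*iu)])
    w = np.exp(-(d[iu] ** 2) / (2 * length_scale**2))
    w[in_tree] = 0.0
    extra = min(m_target - len(edges), int(np.count_nonzero(w)))
    if extra > 0:
        chosen = rng.choice(iu[0].size, size=extra, replace=False, p=w / w.sum())
        edges.update((int(iu[0][k]), int(iu[1][k])) for k in chosen)
    return edges


def generate(cfg: LandscapeConfig):
    """Build (RateNetwork, CommunityPartition) for the configured landscape."""
    rng = np.random.default_rng(cfg.seed)
    rows, cols = cfg.grid
    n_comm = rows * cols
    npc = cfg.nodes_per_community
    n = n_comm * npc

    centres = np.array(
        [(c * cfg.well_spacing, r * cfg.well_spacing) for r in range(rows) for c in range(cols)]
    )
    bases = rng.uniform(*cfg.well_depth_range, size=n_comm)
    labels = np.repeat(np.arange(n_comm), npc)
    pos = np.empty((n, 2))
    E = np.empty(n)
    for c in range(n_comm):
        sl = slice(c * npc, (c + 1) * npc)
        p = rng.normal(centres[c], cfg.position_sigma, size=(npc, 2))
        r2 = np.sum((p - centres[c]) ** 2, axis=1)
        pos[sl] = p
        E[sl] = bases[c] + cfg.curvature * r2 + rng.normal(0, cfg.energy_noise, npc)

    # intra-community edges: distance-weighted random pairs + spanning tree
    m_per_comm = int(round(cfg.target_mean_degree * npc / 2))
    if m_per_comm > npc * (npc - 1) // 2:
        raise KTNValidationError(
            f"target mean degree {cfg.target_mean_degree} unreachable with "
            f"{npc} nodes per community"
        )
    edges: list[tuple[int, int]] = []
    kinds: list[str] = []
    for c in range(n_comm):
        off = c * npc
        for a, b in _intra_edges(pos[off : off + npc], m_per_comm, rng,
                                 cfg.position_sigma):
            edges.append((off + a, off + b))
            kinds.append("intra")

    # inter-community edges between nearest node pairs of grid-adjacent wells
    def adjacent(c1, c2):
        r1, k1 = divmod(c1, cols)
        r2, k2 = divmod(c2, cols)
        return abs(r1 - r2) + abs(k1 - k2) == 1

    for c1 in range(n_comm):
        for c2 in range(c1 + 1, n_comm):
            if not adjacent(c1, c2):
                continue
            i1 = np.arange(c1 * npc, (c1 + 1) * npc)
            i2 = np.arange(c2 * npc, (c2 + 1) * npc)
            d = np.linalg.norm(pos[i1][:, None, :] - pos[i2][None, :, :], axis=2)
            # nearest cross pairs with distinct endpoints: these nodes become
            # the ground-truth boundary set between the two wells
            used1: set[int] = set()
            used2: set[int] = set()
            for flat in np.argsort(d, axis=None):
                if len(used1) >= cfg.inter_edges_per_pair:
                    break
                a, b = np.unravel_index(flat, d.shape)
                if int(a) in used1 or int(b) in used2:
                    continue
                used1.add(int(a))
                used2.add(int(b))
                edges.append((int(i1[a]), int(i2[b])))
                kinds.append("inter")

    edges_arr = np.array(edges, dtype=int)
    kinds_arr = np.array(kinds)
    barrier = np.where(
        kinds_arr == "intra",
        cfg.intra_barrier_min + rng.exponential(cfg.intra_barrier_scale, len(edges)),
        cfg.inter_barrier_min + rng.exponential(cfg.inter_barrier_scale, len(edges)),
    )
    E_ts = np.maximum(E[edges_arr[:, 0]], E[edges_arr[:, 1]]) + barrier
    log_fwd, log_bwd = arrhenius_rates(
        E, edges_arr, E_ts, cfg.temperature, cfg.prefactor
    )
    K = np.zeros((n, n))
    K[edges_arr[:, 1], edges_arr[:, 0]] = np.exp(log_fwd)  # i -> j
    K[edges_arr[:, 0], edges_arr[:, 1]] = np.exp(log_bwd)  # j -> i
    net = RateNetwork.from_rates(
        K, energies=E, temperature=cfg.temperature,
        node_ids=np.arange(1, n + 1),
    )
    partition = build_partition(net, labels)
    return net, partition


def metastability_report(net: RateNetwork, partition: CommunityPartition):
    """Per-community mixing time, slowest escape rate and mean escape time.

    Returns a DataFrame with one row per community: tau_m, lambda0,
    lambda0*tau_m (the metastability ratio, << 1 for strongly metastable
    communities) and the mean escape time 1/lambda0 from the quasi-stationary
    state.  A community covering the whole network has no escape and reports
    infinities.
    """
    import pandas as pd

    from .spectral_fpt import mixing_time

    rows = []
    for lab in partition.communities:
        members = partition.communities[lab]
        if members.size == net.n:
            rows.append(
                {"community": lab, "tau_m": np.inf, "lambda0": 0.0,
                 "metastability": 0.0, "mean_escape_time": np.inf}
            )
            continue
        info = mixing_time(net, members)
        rows.append(
            {
                "community": lab,
                "tau_m": info.tau_m,
                "lambda0": info.lambda0,
                "metastability": info.metastability,
                "mean_escape_time": 1.0 / info.lambda0 if info.lambda0 > 0 else np.inf,
            }
        )
    return pd.DataFrame(rows).set_index("community")


def random_reversible_network(
    n: int,
    seed: int = 0,
    mean_degree: float = 4.0,
    barrier_scale: float = 1.0,
    temperature: float = 1.0,
) -> RateNetwork:
    """Small random reversible test network with Arrhenius rates.

    Random energies, an Erdos-Renyi edge set augmented with a random spanning
    tree for connectivity, and exponential barriers; detailed balance holds
    by construction.  Intended for property tests and cross-checks.
    """
    rng = np.random.default_rng(seed)
    E = rng.uniform(-1.0, 1.0, n)
    iu = np.triu_indices(n, k=1)
    p_edge = min(mean_degree / max(n - 1, 1), 1.0)
    mask = rng.random(iu[0].size) < p_edge
    edge_set = {(int(a), int(b)) for a, b in zip(iu[0][mask], iu[1][mask])}
    perm = rng.permutation(n)
    edge_set.update(
        (min(int(perm[k]), int(perm[k + 1])), max(int(perm[k]), int(perm[k + 1])))
        for k in range(n - 1)
    )
    edges = np.array(sorted(edge_set), dtype=int)
    barrier = 0.1 + rng.exponential(barrier_scale, len(edges))
    E_ts = np.maximum(E[edges[:, 0]], E[edges[:, 1]]) + barrier
    log_fwd, log_bwd = arrhenius_rates(E, edges, E_ts, temperature)
    K = np.zeros((n, n))
    K[edges[:, 1], edges[:, 0]] = np.exp(log_fwd)
    K[edges[:, 0], edges[:, 1]] = np.exp(log_bwd)
    return RateNetwork.from_rates(K, energies=E, temperature=temperature)
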