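"""First-passage and first-escape time distributions via absorbing subsystems.

For a target set A and non-absorbing set S = Omega \\ A, the sub-generator
Q_S (whose diagonal keeps the full escape rates, including jumps into A)
governs dP_S/dt = Q_S P_S, and every trajectory is eventually absorbed.  With
reversed-sign eigenvalues lambda_l > 0 and biorthonormal right/left
eigenvectors w^R_l, w^L_l, the first-passage time density from an initial
distribution P_S(0) is the mode sum

    p(t) = sum_l lambda_l exp(-lambda_l t) c_l,
    c_l  = (1 . w^R_l) (w^L_l . P_S(0)),

with log-time density P(y) = sum_l lambda_l exp(y - lambda_l e^y) c_l for
y = ln t.  The mode weights sum to one; wild cancellation among them is the
finite-precision failure mode of ill-conditioned chains, and the evaluators
abort with a diagnostic rather than return garbage.

Reversible chains are diagonalized through the symmetric similarity
transform diag(pi^-1/2) Q_S diag(pi^1/2), which guarantees a real spectrum
and better conditioning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import breadth_first_order

from .ktn_model import (
    CommunityPartition,
    KTNValidationError,
    PrecisionLossError,
    RateNetwork,
)

__all__ = [
    "AbsorbingSubsystem",
    "FPTDistribution",
    "InitialDistribution",
    "MixingInfo",
    "absorbing_subsystem",
    "fpt_distribution",
    "mfpt",
    "mixing_time",
    "make_initial",
    "escape_time_distribution",
]

#: mode weights must sum to one within this tolerance, and no single weight
#: may exceed 1e3 in magnitude, else the eigendecomposition has lost precision
WEIGHT_SUM_TOL = 1e-6
WEIGHT_MAG_LIMIT = 1e3


@dataclass
class AbsorbingSubsystem:
    """Eigensystem of the sub-generator Q_S for a first-passage problem.

    ``S`` holds the internal indices of the non-absorbing states (ascending);
    ``A`` the absorbing targets.  ``G`` is the fundamental (Green's) matrix
    [I_S - B_SS]^-1 whose (s, s') entry is the expected number of visits to s
    starting from s' before absorption.
    """

    S: np.ndarray
    A: np.ndarray
    Q_S: np.ndarray
    B_SS: np.ndarray
    tau_S: np.ndarray
    G: np.ndarray
    lam: np.ndarray          # reversed-sign eigenvalues, ascending, all > 0
    WR: np.ndarray           # columns are right eigenvectors
    WL: np.ndarray           # rows are left eigenvectors, WL @ WR = I

    def position(self, node: int) -> int:
        hits = np.flatnonzero(self.S == node)
        if hits.size != 1:
            raise KeyError(f"node {node} is not in the non-absorbing set")
        return int(hits[0])


@dataclass
class FPTDistribution:
    """Spectral first-passage time distribution p(t) = sum_l lambda_l c_l e^(-lambda_l t).

    ``time_shift`` is an additive offset applied to the time axis (used for
    mixed initial distributions that are first evolved for a mixing time).
    """

    lam: np.ndarray
    c: np.ndarray
    time_shift: float = 0.0

    @property
    def mean(self) -> float:
        return float(self.time_shift + np.sum(self.c / self.lam))

    @property
    def weight_sum(self) -> float:
        return float(np.sum(self.c))

    def pdf(self, t):
        scalar = np.isscalar(t)
        t = np.atleast_1d(np.asarray(t, dtype=float)) - self.time_shift
        out = np.zeros_like(t)
        pos = t >= 0
        out[pos] = np.einsum(
            "l,l,lk->k", self.lam, self.c, np.exp(-np.outer(self.lam, t[pos]))
        )
        return float(out[0]) if scalar else out

    def cdf(self, t):
        scalar = np.isscalar(t)
        t = np.atleast_1d(np.asarray(t, dtype=float)) - self.time_shift
        out = np.zeros_like(t)
        pos = t >= 0
        out[pos] = 1.0 - np.einsum(
            "l,lk->k", self.c, np.exp(-np.outer(self.lam, t[pos]))
        )
        out = np.clip(out, 0.0, 1.0)
        return float(out[0]) if scalar else out

    def log_time_density(self, y) -> np.ndarray:
        """Density of y = ln t: P(y) = sum_l lambda_l e^(y - lambda_l e^y) c_l."""
        y = np.asarray(y, dtype=float)
        t = np.exp(y)
        return self.pdf(t + self.time_shift) * t

    def grid(self, n: int = 400, span: tuple[float, float] = (1e-2, 1e2)) -> np.ndarray:
        """Log-spaced evaluation grid spanning [span0/lam_max, span1/lam_min]."""
        lo = span[0] / self.lam.max()
        hi = span[1] / self.lam.min()
        return self.time_shift + np.geomspace(lo, hi, n)

    def evaluate(self, t=None):
        """Return (t, p(t), y, P(y)) on the default or a supplied grid."""
        if t is None:
            t = self.grid()
        y = np.log(np.maximum(t - self.time_shift, 1e-300)) if self.time_shift else np.log(t)
        return t, self.pdf(t), y, self.log_time_density(y)


@dataclass
class InitialDistribution:
    """Initial probability vector supported on one community.

    kind is one of Boltz (local Boltzmann), Min (delta at the pi-maximum
    node b0), Uni (uniform over the community) or Mix (uniform, evolved for
    one mixing time conditional on remaining in the community, then
    renormalized; downstream distributions are shifted by that mixing time).
    """

    kind: str
    nodes: np.ndarray        # internal indices carrying the probability
    p: np.ndarray            # weights over `nodes`, nonnegative, sum 1
    time_shift: float = 0.0

    def as_vector(self, n: int) -> np.ndarray:
        v = np.zeros(n)
        v[self.nodes] = self.p
        return v


@dataclass
class MixingInfo:
    """Mixing time and quasi-stationary distribution of a node set with escape."""

    tau_m: float
    lambda0: float
    lambda1: float
    qsd: np.ndarray
    metastability: float = field(init=False)

    def __post_init__(self):
        self.metastability = self.lambda0 * self.tau_m


# ---------------------------------------------------------------------------
# subsystem construction and eigendecomposition
# ---------------------------------------------------------------------------

def _sub_generator(net, S: np.ndarray) -> np.ndarray:
    """Q_S: restriction of Q to S; the diagonal keeps the full escape rates."""
    return net.Q[np.ix_(S, S)].copy()


def _is_reversible(net) -> bool:
    rev = getattr(net, "reversible", None)
    if rev is not None:
        return bool(rev)
    # reduced networks: detailed-balance closure of the renormalized fluxes
    F = net.B * (net.pi / net.tau)[None, :]
    fmax = F.max()
    return fmax > 0 and np.max(np.abs(F - F.T)) <= 1e-10 * fmax


def _eigensystem(net, S: np.ndarray, Q_S: np.ndarray):
    """Reversed-sign eigensystem with biorthonormal left/right vectors."""
    pi_S = net.pi[S]
    if _is_reversible(net) and np.all(pi_S > 0):
        sq = np.sqrt(pi_S)
        M = Q_S * (sq[None, :] / sq[:, None])
        M = 0.5 * (M + M.T)
        mu, U = scipy.linalg.eigh(M)      # ascending in mu, all <= 0
        order = np.argsort(-mu)           # ascending lambda = -mu
        lam = (-mu)[order]
        U = U[:, order]
        WR = U * sq[:, None]
        WL = (U / sq[:, None]).T
    else:
        mu, VL, VR = scipy.linalg.eig(Q_S, left=True, right=True)
        order = np.argsort(-mu.real)
        lam = -mu.real[order]
        VR = VR[:, order].real
        VL = VL[:, order].real
        norms = np.einsum("ij,ij->j", VL, VR)
        WR = VR
        WL = (VL / norms[None, :]).T
    return lam, WR, WL


def absorbing_subsystem(net, A) -> AbsorbingSubsystem:
    """Set up the first-passage problem into target set A.

    Raises when some non-absorbing node cannot reach A (the FPT would be
    infinite), naming the trapped nodes.
    """
    A = np.asarray(sorted(int(a) for a in np.atleast_1d(A)), dtype=int)
    if A.size == 0:
        raise KTNValidationError("target set is empty")
    n = net.K.shape[0]
    S = np.setdiff1d(np.arange(n), A)
    if S.size == 0:
        raise KTNValidationError("non-absorbing set is empty")
    # nodes that can reach A: BFS from A along reversed edges; K[i, j] > 0 is
    # the jump j -> i, so following rows of (K > 0) walks j <- i backwards
    adj = csr_matrix(net.K > 0)
    reach = np.zeros(n, dtype=bool)
    for a in A:
        if not reach[a]:
            order_ = breadth_first_order(adj, a, return_predecessors=False)
            reach[order_] = True
    trapped = S[~reach[S]]
    if trapped.size:
        raise KTNValidationError(
            f"nodes with no path to the target: {trapped.tolist()}"
        )
    Q_S = _sub_generator(net, S)
    B_SS = net.B[np.ix_(S, S)]
    G = scipy.linalg.solve(np.eye(S.size) - B_SS, np.eye(S.size))
    lam, WR, WL = _eigensystem(net, S, Q_S)
    if np.any(lam <= 0):
        raise PrecisionLossError(
            "non-positive decay rate in the absorbing subsystem; the problem "
            "is too ill-conditioned for eigendecomposition"
        )
    return AbsorbingSubsystem(
        S=S, A=A, Q_S=Q_S, B_SS=B_SS, tau_S=net.tau[S], G=G,
        lam=lam, WR=WR, WL=WL,
    )


# ---------------------------------------------------------------------------
# distributions and means
# ---------------------------------------------------------------------------

def _p0_on_S(sub: AbsorbingSubsystem, p0) -> np.ndarray:
    if isinstance(p0, InitialDistribution):
        full = np.zeros(int(max(sub.S.max(), p0.nodes.max())) + 1)
        full[p0.nodes] = p0.p
        if not np.isclose(full[sub.S].sum(), 1.0, atol=1e-9):
            raise KTNValidationError("initial distribution not supported on S")
        return full[sub.S], p0.time_shift
    p0 = np.asarray(p0, dtype=float)
    if p0.size == sub.S.size:
        return p0, 0.0
    raise KTNValidationError("initial vector must have |S| entries")


def fpt_distribution(sub: AbsorbingSubsystem, p0) -> FPTDistribution:
    """Spectral FPT distribution from an initial distribution on S.

    Mode weights c_l = (1 . w^R_l)(w^L_l . P_S(0)) are checked for
    completeness (sum to 1) and for wild cancellation before returning.
    """
    vec, shift = _p0_on_S(sub, p0)
    c = (sub.WR.sum(axis=0)) * (sub.WL @ vec)
    total = c.sum()
    if abs(total - 1.0) > WEIGHT_SUM_TOL:
        raise PrecisionLossError(
            f"spectral mode weights sum to {total:.6g}, not 1: eigendecomposition "
            "has lost precision (consider the GT route instead)"
        )
    if np.max(np.abs(c)) > WEIGHT_MAG_LIMIT:
        raise PrecisionLossError(
            "spectral mode weight exceeds 1e3 in magnitude: wild cancellation; "
            "the subsystem is too ill-conditioned"
        )
    return FPTDistribution(lam=sub.lam, c=c, time_shift=shift)


def mfpt(sub: AbsorbingSubsystem, p0) -> float:
    """Mean first-passage time tau_S G_S P_S(0) by linear solve.

    Cross-checked against the spectral mean sum_l c_l/lambda_l; disagreement
    beyond 1e-6 relative triggers a warning recommending the GT route.
    """
    vec, shift = _p0_on_S(sub, p0)
    x = scipy.linalg.solve((np.eye(sub.S.size) - sub.B_SS).T, sub.tau_S)
    value = float(x @ vec) + shift
    try:
        spectral = fpt_distribution(sub, p0).mean
    except PrecisionLossError:
        spectral = None
    if spectral is not None and abs(spectral - value) > 1e-6 * abs(value):
        warnings.warn(
            f"spectral mean {spectral:.8g} disagrees with linear-solve MFPT "
            f"{value:.8g}; the eigendecomposition is unreliable — use the GT route",
            RuntimeWarning,
        )
    return value


def mixing_time(net, X) -> MixingInfo:
    """Mixing time tau_m = 1/(lambda1 - lambda0) of a node set X with escape.

    lambda0 < lambda1 are the two smallest reversed-sign eigenvalues of Q_X
    (escape out of X included on the diagonal).  The quasi-stationary
    distribution is the dominant right eigenvector normalized to unit sum;
    ``metastability`` = lambda0 * tau_m is small in the metastable regime.
    """
    X = np.asarray(sorted(int(x) for x in np.atleast_1d(X)), dtype=int)
    if X.size < 2:
        raise KTNValidationError("mixing time needs at least two states")
    Q_X = _sub_generator(net, X)
    lam, WR, _ = _eigensystem(net, X, Q_X)
    lam0, lam1 = lam[0], lam[1]
    if lam1 - lam0 <= 1e-14 * max(lam1, 1.0):
        raise KTNValidationError("degenerate slowest eigenvalues; mixing time undefined")
    qsd = WR[:, 0]
    qsd = np.abs(qsd)
    qsd = qsd / qsd.sum()
    return MixingInfo(tau_m=1.0 / (lam1 - lam0), lambda0=float(lam0),
                      lambda1=float(lam1), qsd=qsd)


def make_initial(kind: str, net, partition: CommunityPartition, community,
                 tau_m: float | None = None) -> InitialDistribution:
    """Build one of the four initial distributions on a community.

    Boltz: stationary distribution restricted to the community, renormalized.
    Min:   delta at the community's pi-maximum node b0.
    Uni:   uniform over the community.
    Mix:   uniform density evolved for one mixing time under Q_X (conditional
           on not escaping), renormalized; the mixing time is recorded as a
           time shift for downstream distributions.
    """
    kind_l = kind.lower()
    members = partition.communities[community]
    if kind_l == "boltz":
        w = net.pi[members]
        return InitialDistribution("Boltz", members, w / w.sum())
    if kind_l == "min":
        b0 = partition.b0[community]
        return InitialDistribution("Min", np.array([b0]), np.array([1.0]))
    if kind_l == "uni":
        return InitialDistribution(
            "Uni", members, np.full(members.size, 1.0 / members.size)
        )
    if kind_l == "mix":
        if tau_m is None:
            tau_m = mixing_time(net, members).tau_m
        Q_X = _sub_generator(net, members)
        lam, WR, WL = _eigensystem(net, members, Q_X)
        if np.any(lam <= 0):
            raise PrecisionLossError(
                "community eigendecomposition failed; use Boltz instead of Mix"
            )
        p0 = np.full(members.size, 1.0 / members.size)
        amp = np.exp(-tau_m * lam) * (WL @ p0)
        if np.max(np.abs(amp)) > WEIGHT_MAG_LIMIT:
            raise PrecisionLossError(
                "ill-conditioned community propagation; use Boltz instead of Mix"
            )
        p = WR @ amp
        p = np.clip(p, 0.0, None)
        if p.sum() <= 0:
            raise PrecisionLossError(
                "propagated density vanished; use Boltz instead of Mix"
            )
        return InitialDistribution("Mix", members, p / p.sum(), time_shift=float(tau_m))
    raise ValueError(f"unknown initial-distribution kind {kind!r}")


def escape_time_distribution(net, partition: CommunityPartition, community,
                             p0) -> FPTDistribution:
    """First-escape time distribution from a community (absorb its complement)."""
    members = partition.communities[community]
    n = net.K.shape[0]
    A = np.setdiff1d(np.arange(n), members)
    if A.size == 0:
        raise KTNValidationError("community covers the whole network; no escape")
    sub = absorbing_subsystem(net, A)
    if isinstance(p0, str):
        p0 = make_initial(p0, net, partition, community)
    return fpt_distribution(sub, p0)
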