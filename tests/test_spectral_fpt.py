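"""Spectral first-passage analysis: eigensystems, distributions, mixing times."""

import numpy as np
import pytest

import ktnreduce as kr
from ktnreduce.ktn_model import KTNValidationError

GOLDEN_LAMBDAS = ((3 - np.sqrt(5)) / 2, (3 + np.sqrt(5)) / 2)


class TestAbsorbingSubsystem:
    def test_chain_eigenvalues(self, chain3):
        sub = kr.absorbing_subsystem(chain3, [2])
        np.testing.assert_allclose(sub.lam, GOLDEN_LAMBDAS, atol=1e-12)

    def test_chain_fundamental_matrix(self, chain3):
        sub = kr.absorbing_subsystem(chain3, [2])
        np.testing.assert_allclose(sub.G, [[2.0, 1.0], [2.0, 2.0]], atol=1e-12)

    def test_single_state_scalar_case(self):
        K = np.array([[0.0, 2.0], [2.0, 0.0]])
        net = kr.RateNetwork.from_rates(K)
        sub = kr.absorbing_subsystem(net, [1])
        np.testing.assert_allclose(sub.lam, [2.0])
        np.testing.assert_allclose(sub.G, [[1.0]])

    def test_fundamental_matrix_counts_visits(self, chain3):
        """G entries equal mean visit counts measured by simulation."""
        sub = kr.absorbing_subsystem(chain3, [2])
        rng = np.random.default_rng(0)
        visits = np.zeros(2)
        n_traj = 4000
        for _ in range(n_traj):
            traj = kr.kmc_trajectory(chain3, 0, target=[2], rng=rng)
            for s in (0, 1):
                visits[s] += np.count_nonzero(traj.nodes == s)
        est = visits / n_traj
        se = np.sqrt(np.array([8.0, 6.0]) / n_traj)  # loose variance bounds
        assert np.all(np.abs(est - sub.G[:, 0]) < 4 * se)

    def test_biorthonormality(self):
        net = kr.random_reversible_network(12, seed=5)
        sub = kr.absorbing_subsystem(net, [0, 7])
        np.testing.assert_allclose(sub.WL @ sub.WR, np.eye(10), atol=1e-9)

    def test_trapped_nodes_reported(self):
        # directed chain: 0 <-> 1 -> 2 <-> 3; from {2, 3} there is no path to 0
        class _Fake:
            pass

        K = np.zeros((4, 4))
        K[1, 0] = K[0, 1] = 1.0
        K[2, 1] = 1.0
        K[3, 2] = K[2, 3] = 1.0
        net = _Fake()
        esc = K.sum(axis=0)
        net.K = K
        net.tau = 1.0 / esc
        net.B = K / esc
        net.Q = K - np.diag(esc)
        net.pi = np.full(4, 0.25)
        net.reversible = False
        with pytest.raises(KTNValidationError, match=r"\[2, 3\]"):
            kr.absorbing_subsystem(net, [0])


class TestFPTDistribution:
    def test_single_state_exponential(self):
        K = np.array([[0.0, 1.7], [1.7, 0.0]])
        net = kr.RateNetwork.from_rates(K)
        sub = kr.absorbing_subsystem(net, [1])
        d = kr.fpt_distribution(sub, np.array([1.0]))
        t = np.linspace(0.01, 3.0, 50)
        np.testing.assert_allclose(d.pdf(t), 1.7 * np.exp(-1.7 * t), rtol=1e-10)

    def test_chain_mean_is_three(self, chain3):
        sub = kr.absorbing_subsystem(chain3, [2])
        d = kr.fpt_distribution(sub, np.array([1.0, 0.0]))
        assert d.mean == pytest.approx(3.0, rel=1e-12)
        assert d.weight_sum == pytest.approx(1.0, abs=1e-10)

    def test_weights_complete_on_random_networks(self):
        for seed in range(5):
            net = kr.random_reversible_network(15, seed=seed)
            sub = kr.absorbing_subsystem(net, [0])
            p0 = np.zeros(14)
            p0[5] = 1.0
            d = kr.fpt_distribution(sub, p0)
            assert abs(d.weight_sum - 1.0) <= 1e-8

    def test_log_time_density_normalized(self, chain3):
        sub = kr.absorbing_subsystem(chain3, [2])
        d = kr.fpt_distribution(sub, np.array([1.0, 0.0]))
        y = np.linspace(np.log(1e-6 / d.lam.max()), np.log(50.0 / d.lam.min()), 20000)
        mass = np.trapezoid(d.log_time_density(y), y)
        assert mass == pytest.approx(1.0, abs=1e-6)

    def test_density_nonnegative_on_grid(self, chain3):
        sub = kr.absorbing_subsystem(chain3, [2])
        d = kr.fpt_distribution(sub, np.array([0.5, 0.5]))
        assert np.all(d.pdf(d.grid()) >= 0)


class TestMFPT:
    def test_chain_hand_solve(self, chain3):
        # t1 = 1 + t2, t2 = 1/2 + t1/2 gives t1 = 3
        sub = kr.absorbing_subsystem(chain3, [2])
        assert kr.mfpt(sub, np.array([1.0, 0.0])) == pytest.approx(3.0, rel=1e-12)

    def test_adjacent_single_edge(self):
        K = np.array([[0.0, 0.25], [0.25, 0.0]])
        net = kr.RateNetwork.from_rates(K)
        sub = kr.absorbing_subsystem(net, [1])
        assert kr.mfpt(sub, np.array([1.0])) == pytest.approx(4.0)

    def test_agrees_with_gt_route(self, metastable_net):
        net, part = metastable_net
        A = part.communities[0]
        b = part.b0[2]
        sub = kr.absorbing_subsystem(net, A)
        v = np.zeros(net.n)
        v[b] = 1.0
        linear = kr.mfpt(sub, v[sub.S])
        assert kr.gt_mfpt(net, A, b) == pytest.approx(linear, rel=1e-8)


class TestMixingTime:
    def test_two_state_with_escape(self):
        # X = two symmetric states, internal rate a, escape eps each
        a, eps = 1.5, 0.01
        K = np.zeros((3, 3))
        K[0, 1] = K[1, 0] = a
        K[2, 0] = K[2, 1] = eps
        K[0, 2] = K[1, 2] = 1.0  # return edges keep the chain ergodic
        net = kr.RateNetwork.from_rates(K)
        info = kr.mixing_time(net, [0, 1])
        assert info.lambda0 == pytest.approx(eps, rel=1e-10)
        assert info.lambda1 == pytest.approx(2 * a + eps, rel=1e-10)
        assert info.tau_m == pytest.approx(1 / (2 * a), rel=1e-10)

    def test_chain_mixing_time_and_qsd(self, chain3):
        info = kr.mixing_time(chain3, [0, 1])
        assert info.tau_m == pytest.approx(1 / np.sqrt(5), rel=1e-10)
        np.testing.assert_allclose(
            info.qsd, [(np.sqrt(5) - 1) / 2, (3 - np.sqrt(5)) / 2], atol=1e-8
        )

    def test_qsd_tends_to_local_equilibrium(self):
        # eps -> 0: quasi-stationary distribution -> pi restricted to X
        a = 1.0
        for eps, tol in [(1e-2, 1e-2), (1e-5, 1e-5)]:
            K = np.zeros((3, 3))
            K[0, 1] = K[1, 0] = a
            K[2, 0] = K[2, 1] = eps
            K[0, 2] = K[1, 2] = 1.0
            net = kr.RateNetwork.from_rates(K)
            info = kr.mixing_time(net, [0, 1])
            np.testing.assert_allclose(info.qsd, [0.5, 0.5], atol=tol)

    def test_needs_two_states(self, chain3):
        with pytest.raises(KTNValidationError):
            kr.mixing_time(chain3, [0])


class TestInitialDistributions:
    @pytest.fixture
    def small_partition(self, metastable_net):
        return metastable_net

    def test_min_is_delta_at_b0(self, small_partition):
        net, part = small_partition
        d = kr.make_initial("min", net, part, 0)
        assert d.nodes.size == 1 and d.nodes[0] == part.b0[0]
        assert d.p[0] == 1.0

    def test_boltz_restricted_stationary(self, small_partition):
        net, part = small_partition
        d = kr.make_initial("boltz", net, part, 1)
        members = part.communities[1]
        np.testing.assert_allclose(d.p, net.pi[members] / net.pi[members].sum())

    def test_mix_with_zero_time_is_uniform(self, small_partition):
        net, part = small_partition
        d = kr.make_initial("mix", net, part, 2, tau_m=0.0)
        np.testing.assert_allclose(d.p, 1.0 / part.communities[2].size, atol=1e-12)

    def test_mix_long_time_limit_is_qsd(self, small_partition):
        net, part = small_partition
        members = part.communities[3]
        info = kr.mixing_time(net, members)
        d = kr.make_initial("mix", net, part, 3, tau_m=200 * info.tau_m)
        np.testing.assert_allclose(d.p, info.qsd, atol=1e-6)

    def test_all_kinds_normalized(self, small_partition):
        net, part = small_partition
        for kind in ("boltz", "min", "uni", "mix"):
            d = kr.make_initial(kind, net, part, 0)
            assert d.p.sum() == pytest.approx(1.0, abs=1e-10)
            assert np.all(d.p >= 0)


class TestEscapeDistributions:
    def test_single_node_community_exponential(self):
        K = np.array([[0.0, 0.5], [0.5, 0.0]])
        net = kr.RateNetwork.from_rates(K)
        part = kr.build_partition(net, np.array([0, 1]))
        p0 = kr.make_initial("uni", net, part, 0)
        d = kr.escape_time_distribution(net, part, 0, p0)
        t = np.linspace(0.1, 10, 30)
        np.testing.assert_allclose(d.pdf(t), 0.5 * np.exp(-0.5 * t), rtol=1e-10)

    def test_boltz_and_min_agree_under_metastability(self, metastable_net):
        """Strong metastability makes escape insensitive to the start distribution."""
        net, part = metastable_net
        rep = kr.metastability_report(net, part)
        lab = rep["metastability"].idxmin()
        d_b = kr.escape_time_distribution(net, part, lab, kr.make_initial("boltz", net, part, lab))
        d_m = kr.escape_time_distribution(net, part, lab, kr.make_initial("min", net, part, lab))
        y = np.linspace(np.log(1e-2 / d_b.lam.max()), np.log(1e2 / d_b.lam.min()), 2000)
        peak = d_b.log_time_density(y).max()
        sup = np.max(np.abs(d_b.log_time_density(y) - d_m.log_time_density(y)))
        assert sup < 1e-2 * peak

    def test_uniform_start_escapes_faster_at_short_time(self, metastable_net):
        """Boundary-node starting weight in Uni produces excess short-time escape."""
        net, part = metastable_net
        d_u = kr.escape_time_distribution(net, part, 0, kr.make_initial("uni", net, part, 0))
        d_b = kr.escape_time_distribution(net, part, 0, kr.make_initial("boltz", net, part, 0))
        assert d_u.pdf(0.0) > d_b.pdf(0.0)
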