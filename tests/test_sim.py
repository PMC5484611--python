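"""Glauber-dynamics simulator and cyclostationary estimators."""

import numpy as np
import pytest
from scipy import stats

import oscibin as ob
from oscibin.core import DriveSpec


def make_uncoupled_spec(n=400, m_target=0.2, sigma=1.0, tau=10.0):
    """Independent neurons whose activation probability is exactly m_target."""
    from scipy.special import erfcinv

    theta = float(np.sqrt(2) * sigma * erfcinv(2 * m_target))
    return ob.NetworkSpec(
        populations=(ob.Population("A", n, sigma_noise=sigma, theta=theta),),
        p=[[0.0]],
        J=[[0.0]],
        tau=tau,
    )


@pytest.fixture(scope="module")
def quarter_single_net(quarter_single_spec):
    return ob.build_network(quarter_single_spec, seed=42)


@pytest.fixture(scope="module")
def single_trials(quarter_single_spec, quarter_single_net):
    """20 undriven trials of the quarter-size single-I network."""
    drive = DriveSpec(h_ext=0.0, f=5.0)  # phase-folding reference only
    dur = ob.transient_length(quarter_single_spec.tau, drive.period) + 10.2 * drive.period
    return [
        ob.simulate(quarter_single_net, drive, dur, seed=100 + r) for r in range(20)
    ], drive


@pytest.fixture(scope="module")
def single_est(single_trials, quarter_single_spec):
    trials, drive = single_trials
    return ob.cyclostationary_stats(
        trials, quarter_single_spec, drive, n_bins=20, pair_subsample=20000, seed=7
    )


@pytest.fixture(scope="module")
def bio_driven_est(quarter_bio_spec):
    """Driven quarter-size biological network, 30 trials at 80 Hz."""
    drive = DriveSpec(h_ext=1.0, f=80.0)
    net = ob.build_network(quarter_bio_spec, seed=77)
    dur = ob.transient_length(quarter_bio_spec.tau, drive.period) + 40.2 * drive.period
    trials = [ob.simulate(net, drive, dur, seed=800 + r) for r in range(30)]
    return ob.cyclostationary_stats(
        trials, quarter_bio_spec, drive, n_bins=20, pair_subsample=20000, seed=3
    )


class TestBuildNetwork:
    def test_zero_indegree_gives_empty_adjacency(self):
        spec = make_uncoupled_spec(n=50)
        net = ob.build_network(spec, seed=0)
        assert net.indices.size == 0

    def test_exact_in_degree(self, quarter_single_net):
        deg = quarter_single_net.in_degrees()
        assert np.all(deg[:, 0] == 125)

    def test_no_self_connections_or_duplicates(self):
        spec = ob.NetworkSpec(
            populations=(ob.Population("A", 40, sigma_noise=1.0, theta=0.0),),
            p=[[0.5]],
            J=[[-1.0]],
            tau=10.0,
        )
        net = ob.build_network(spec, seed=3)
        senders = np.repeat(np.arange(40), np.diff(net.indptr))
        assert not np.any(senders == net.indices)
        edges = set(zip(senders.tolist(), net.indices.tolist()))
        assert len(edges) == senders.size  # no duplicate edges

    def test_mean_out_degree_equals_in_degree(self):
        spec = ob.NetworkSpec(
            populations=(ob.Population("A", 200, sigma_noise=1.0, theta=0.0),),
            p=[[0.15]],
            J=[[-1.0]],
            tau=10.0,
        )
        net = ob.build_network(spec, seed=5)
        out_deg = np.diff(net.indptr)
        assert out_deg.mean() == pytest.approx(spec.K[0, 0], rel=1e-12)
        # out-degrees are binomial-like: spread consistent with that scale
        assert 0.3 * np.sqrt(spec.K[0, 0]) < out_deg.std() < 3 * np.sqrt(spec.K[0, 0])

    def test_oversized_in_degree_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            spec = ob.NetworkSpec(
                populations=(ob.Population("A", 10, sigma_noise=1.0, theta=0.0),),
                p=[[1.0]],
                J=[[-1.0]],
                tau=10.0,
            )
            ob.build_network(spec, seed=0)

    def test_deterministic_given_seed(self, quarter_single_spec):
        n1 = ob.build_network(quarter_single_spec, seed=9)
        n2 = ob.build_network(quarter_single_spec, seed=9)
        assert np.array_equal(n1.indices, n2.indices)
        assert np.array_equal(n1.indptr, n2.indptr)


class TestSimulate:
    def test_identical_seeds_identical_event_streams(self, quarter_single_net):
        drive = DriveSpec(h_ext=1.0, f=20.0)
        t1 = ob.simulate(quarter_single_net, drive, 100.0, seed=7)
        t2 = ob.simulate(quarter_single_net, drive, 100.0, seed=7)
        assert np.array_equal(t1.t, t2.t)
        assert np.array_equal(t1.neuron, t2.neuron)
        assert np.array_equal(t1.state, t2.state)

    def test_event_count_poisson(self, quarter_single_net):
        spec = quarter_single_net.spec
        tr = ob.simulate(quarter_single_net, DriveSpec(), 400.0, seed=3)
        expect = 400.0 * quarter_single_net.n_neurons / spec.tau
        assert abs(tr.t.size - expect) < 5 * np.sqrt(expect)

    def test_update_intervals_exponential(self):
        spec = make_uncoupled_spec(n=100, tau=10.0)
        net = ob.build_network(spec, seed=0)
        tr = ob.simulate(net, DriveSpec(), duration=11000.0, seed=11)
        # pool inter-update intervals of all neurons: thinned Poisson with
        # mean tau per neuron
        ivals = np.concatenate([tr.update_intervals(i) for i in range(100)])
        assert ivals.size > 1e4
        res = stats.kstest(ivals, "expon", args=(0, spec.tau))
        assert res.pvalue > 0.01

    def test_independent_neurons_reach_target_activity(self):
        spec = make_uncoupled_spec(n=400, m_target=0.2)
        net = ob.build_network(spec, seed=0)
        tr = ob.simulate(net, DriveSpec(), duration=2000.0, seed=21,
                         init_m=np.array([0.2]))
        snaps = tr.states_at(np.arange(300.0, 2000.0, 25.0))
        m_hat = snaps.mean()
        n_samp = snaps.size  # nearly independent Bernoulli draws
        se = np.sqrt(0.2 * 0.8 / n_samp) * 2  # allow residual correlation
        assert abs(m_hat - 0.2) < 3 * se

    def test_fixed_step_mode_agrees(self, quarter_single_spec, quarter_single_net):
        tr = ob.simulate(
            quarter_single_net, DriveSpec(), 600.0, seed=13, step_mode="fixed"
        )
        m_hat = tr.states_at(np.arange(200.0, 600.0, 10.0)).mean()
        assert abs(m_hat - 0.3) < 0.01

    def test_single_population_mean_matches_theory(self, single_est,
                                                   quarter_single_st):
        ta = single_est.time_average()
        assert abs(ta["m"][0] - quarter_single_st.m[0]) < 4 * ta["m_se"][0]


class TestCyclostationaryStats:
    def test_needs_ensemble(self, single_trials, quarter_single_spec):
        trials, drive = single_trials
        with pytest.raises(ValueError, match="2 trials"):
            ob.cyclostationary_stats(trials[:1], quarter_single_spec, drive)

    def test_independent_neurons_uncorrelated(self):
        spec = make_uncoupled_spec(n=300, m_target=0.2)
        net = ob.build_network(spec, seed=0)
        drive = DriveSpec(h_ext=0.0, f=10.0)
        dur = ob.transient_length(spec.tau, drive.period) + 12.2 * drive.period
        trials = [ob.simulate(net, drive, dur, seed=400 + r,
                              init_m=np.array([0.2])) for r in range(20)]
        est = ob.cyclostationary_stats(trials, spec, drive, n_bins=30,
                                       pair_subsample=5000, seed=1)
        # covariance consistent with zero in at least 95% of bins
        frac = np.mean(np.abs(est.c[:, 0, 0]) < 3 * est.c_se[:, 0, 0])
        assert frac >= 0.95
        # binary identity a = m (1 - m) within errors
        resid = np.abs(est.a[:, 0] - est.m[:, 0] * (1 - est.m[:, 0]))
        assert np.all(resid < 3 * np.maximum(est.a_se[:, 0], 1e-4))

    def test_covariance_matches_theory_sign_and_magnitude(
        self, single_est, quarter_single_st
    ):
        ta = single_est.time_average()
        c_th = quarter_single_st.c[0, 0]
        assert abs(ta["c"][0] - c_th) < 4 * ta["c_se"][0]
        assert ta["c"][0] < 0  # suppression by inhibitory feedback
        assert 0.2 < ta["c"][0] / c_th < 5.0  # order of magnitude

    def test_biological_quarter_scale_matches_theory(self, quarter_bio_spec,
                                                     quarter_bio_st):
        net = ob.build_network(quarter_bio_spec, seed=50)
        drive = DriveSpec(h_ext=0.0, f=10.0)
        dur = ob.transient_length(quarter_bio_spec.tau, drive.period) + 12.2 * drive.period
        trials = [ob.simulate(net, drive, dur, seed=600 + r) for r in range(12)]
        est = ob.cyclostationary_stats(trials, quarter_bio_spec, drive,
                                       n_bins=15, pair_subsample=10000, seed=2)
        ta = est.time_average()
        for i in range(2):
            assert abs(ta["m"][i] - quarter_bio_st.m[i]) < 4 * ta["m_se"][i]
        assert abs(ta["c"][0, 0] - quarter_bio_st.c[0, 0]) < 4 * ta["c_se"][0, 0]

    def test_driven_covariance_harmonic_matches_linear_response(
        self, bio_driven_est, quarter_bio_st
    ):
        est = bio_driven_est
        drive = est.drive
        lr = ob.covariance_response(drive.omega, quarter_bio_st, drive.h_ext)
        X1 = est.harmonic("c", 1)[0, 0]
        # SE of the harmonic coefficient from the per-bin standard errors
        se = 2.0 * np.sqrt(np.mean(est.c_se[:, 0, 0] ** 2) / est.phase.size)
        assert abs(abs(X1) - abs(lr.C1[0, 0])) < 3 * np.sqrt(2) * se
        # mean modulation tracks the theory as well
        M1 = est.harmonic("m", 1)
        assert abs(M1[0]) == pytest.approx(abs(lr.M1[0]), rel=0.25)

    def test_gaussian_input_statistics(self):
        # noise level matched to the network-generated fluctuation: the
        # per-update input distribution is close to the Gaussian the theory
        # assumes
        base = ob.load_preset("single_inhibitory", calibrate=False).scaled(0.25)
        sigma_net = np.sqrt(125 * 0.3 * 0.7)  # K J^2 m (1-m)
        import dataclasses

        pops = (dataclasses.replace(base.populations[0], sigma_noise=sigma_net),)
        spec = ob.calibrated(dataclasses.replace(base, populations=pops))
        st = ob.solve_stationary(spec)
        net = ob.build_network(spec, seed=123)
        duration = 1.4e5 * spec.tau / net.n_neurons  # >1e5 usable events
        tr = ob.simulate(net, DriveSpec(), duration, seed=9, record_inputs=True)
        inputs = tr.inputs[tr.t > 20 * spec.tau][:100000]
        assert inputs.size >= 90000
        res = stats.kstest(inputs, "norm", args=(st.mu[0], st.sigma[0]))
        assert res.pvalue > 0.01


class TestPopulationEllipse:
    @staticmethod
    def _make_estimate(spec, c_pop_block, center):
        # minimal synthetic estimate with one bin
        npop = spec.n
        c_pop = np.zeros((1, npop, npop))
        c_pop[0, :2, :2] = c_pop_block
        m = np.zeros((1, npop))
        m[0, :2] = center
        z = np.zeros((1, npop))
        return ob.CyclostatEstimate(
            spec=spec, drive=DriveSpec(h_ext=0, f=10), phase=np.array([0.0]),
            m=m, m_se=z, a=z, a_se=z,
            c=np.zeros((1, npop, npop)), c_se=np.zeros((1, npop, npop)),
            c_pop=c_pop, n_trials=2, n_cycles=5, n_pairs=0,
        )

    def test_diagonal_covariance_axis_aligned(self, bio_spec):
        est = self._make_estimate(bio_spec, np.diag([4e-4, 1e-4]), [0.1, 0.3])
        ell = ob.population_ellipse(est, 0)
        assert ell.half_lengths == pytest.approx([2e-2, 1e-2])
        assert abs(ell.axes[0, 0]) == pytest.approx(1.0)

    def test_positive_cross_covariance_tilts_axes(self, bio_spec):
        est = self._make_estimate(
            bio_spec, np.array([[2.0, 1.0], [1.0, 2.0]]) * 1e-4, [0.1, 0.3]
        )
        ell = ob.population_ellipse(est, 0)
        # principal axis along the diagonal, not along a coordinate axis
        assert abs(ell.axes[0, 0]) == pytest.approx(np.sqrt(0.5), rel=1e-9)

    def test_full_ellipse_encloses_variance_only_ellipse(self, bio_spec):
        var = np.diag([3e-4, 2e-4])
        cov = np.array([[1.0, 0.8], [0.8, 1.0]]) * 1e-4  # PSD, nonnegative
        est_var = self._make_estimate(bio_spec, var, [0.1, 0.3])
        est_full = self._make_estimate(bio_spec, var + cov, [0.1, 0.3])
        b_var = ob.population_ellipse(est_var, 0).boundary(72)
        b_full = ob.population_ellipse(est_full, 0).boundary(72)
        r_var = np.linalg.norm(b_var - np.array([[0.1], [0.3]]), axis=0)
        r_full = np.linalg.norm(b_full - np.array([[0.1], [0.3]]), axis=0)
        # radius of the full ellipse exceeds the variance-only one in every
        # direction (check via support: min over directions of the ratio of
        # the quadratic forms)
        dirs = np.stack([np.cos(np.linspace(0, np.pi, 60)),
                         np.sin(np.linspace(0, np.pi, 60))])
        q_var = np.einsum("dn,de,en->n", dirs, var, dirs)
        q_full = np.einsum("dn,de,en->n", dirs, var + cov, dirs)
        assert np.all(q_full >= q_var)
        assert r_full.max() > r_var.max()

    def test_singular_covariance_rejected(self, bio_spec):
        est = self._make_estimate(bio_spec, np.zeros((2, 2)), [0.1, 0.3])
        with pytest.raises(ob.DegenerateEllipseError):
            ob.population_ellipse(est, 0)

    def test_ellipse_from_simulated_network(self, bio_driven_est, quarter_bio_st):
        # error ellipse of the driven EI network: well-defined in most phase
        # bins, with the principal half-length set by the dominant
        # population variance a_I / N_I
        expect = np.sqrt(
            np.max(np.linalg.eigvalsh(quarter_bio_st.c_total[:2, :2]))
        )
        lengths = []
        n_ok = 0
        for b in range(bio_driven_est.phase.size):
            try:
                ell = ob.population_ellipse(bio_driven_est, b)
            except ob.DegenerateEllipseError:
                continue
            n_ok += 1
            lengths.append(ell.half_lengths[0])
        assert n_ok >= 0.8 * bio_driven_est.phase.size
        assert 0.5 * expect < np.median(lengths) < 2.0 * expect
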