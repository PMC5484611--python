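"""Event-driven Monte-Carlo simulation of the binary network.

Asynchronous stochastic (Glauber) dynamics: global update events form a
Poisson process of rate ``N / tau``; at each event one uniformly chosen
neuron is set active iff its summed recurrent input plus drive plus a fresh
Gaussian noise draw exceeds its threshold.  Clamped (external) neurons are
set active with their fixed probability, independent of input.  This
event-driven scheme realizes the infinitesimal-update limit without
discretization bias; a fixed-step variant (``dt = tau / N``) is provided
for cross-checking.

Cyclostationary statistics are estimated by folding time onto the drive
phase: per phase bin, means and single-unit variances pool cycles and
trials, while pairwise covariances are estimated across realizations
(trial x cycle) on a fixed random subsample of ordered neuron pairs.
The hot loops compile with numba when available and fall back to NumPy
otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import DriveSpec, NetworkSpec
from .dynamics import transient_length

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(fn):
            return fn

        return wrap

__all__ = [
    "CyclostatEstimate",
    "DegenerateEllipseError",
    "EllipseParams",
    "Network",
    "StateTrajectory",
    "build_network",
    "cyclostationary_stats",
    "population_ellipse",
    "simulate",
]


class DegenerateEllipseError(np.linalg.LinAlgError):
    """The population covariance matrix is singular or not PSD."""


# ---------------------------------------------------------------------------
# Network realization
# ---------------------------------------------------------------------------


@dataclass
class Network:
    """One random realization of the connectivity.

    Stores the outgoing adjacency in CSR form (``indptr``/``indices`` over
    sender neurons, ``weights`` per edge) so that a state flip of neuron
    ``j`` updates the inputs of its targets in one pass.  Every neuron of
    population ``alpha`` has exactly ``K[alpha, beta]`` distinct inputs
    from population ``beta`` (self-connections excluded).
    """

    spec: NetworkSpec
    pop_of: np.ndarray      # population index per neuron
    indptr: np.ndarray      # outgoing CSR
    indices: np.ndarray
    weights: np.ndarray
    seed: int

    @property
    def n_neurons(self) -> int:
        return self.pop_of.size

    @property
    def pop_slices(self) -> list[slice]:
        off = np.concatenate([[0], np.cumsum(self.spec.N).astype(int)])
        return [slice(off[i], off[i + 1]) for i in range(self.spec.n)]

    def in_degrees(self) -> np.ndarray:
        """Per-neuron, per-sending-population in-degree (for validation)."""
        n_pops = self.spec.n
        deg = np.zeros((self.n_neurons, n_pops), dtype=int)
        senders = np.repeat(
            np.arange(self.n_neurons), np.diff(self.indptr)
        )
        np.add.at(deg, (self.indices, self.pop_of[senders]), 1)
        return deg


def build_network(spec: NetworkSpec, seed: int) -> Network:
    """Sample a fixed-in-degree random network.

    For every receiving neuron the ``K[alpha, beta]`` senders are drawn
    uniformly without replacement from population ``beta`` (excluding the
    neuron itself).  Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    N = spec.N.astype(int)
    K = spec.K
    n_total = int(N.sum())
    offsets = np.concatenate([[0], np.cumsum(N)])
    pop_of = np.repeat(np.arange(spec.n), N).astype(np.int32)

    for a in range(spec.n):
        for b in range(spec.n):
            avail = N[b] - (1 if a == b else 0)
            if K[a, b] > avail:
                raise ValueError(
                    f"in-degree K[{a},{b}] = {K[a, b]} exceeds available "
                    f"senders ({avail})"
                )

    # receiver-major edge lists, then convert to sender-major CSR
    rec_list: list[np.ndarray] = []
    send_list: list[np.ndarray] = []
    w_list: list[np.ndarray] = []
    for a in range(spec.n):
        for i in range(offsets[a], offsets[a + 1]):
            for b in range(spec.n):
                k = K[a, b]
                if k == 0:
                    continue
                pool = N[b]
                if a == b:
                    # uniform K-subset of the population excluding neuron i
                    local = rng.choice(pool - 1, size=k, replace=False)
                    local[local >= i - offsets[b]] += 1
                    senders = local + offsets[b]
                else:
                    senders = rng.choice(pool, size=k, replace=False) + offsets[b]
                send_list.append(senders.astype(np.int64))
                rec_list.append(np.full(k, i, dtype=np.int64))
                w_list.append(np.full(k, spec.J[a, b]))
    if send_list:
        senders = np.concatenate(send_list)
        receivers = np.concatenate(rec_list)
        weights = np.concatenate(w_list)
    else:
        senders = np.empty(0, dtype=np.int64)
        receivers = np.empty(0, dtype=np.int64)
        weights = np.empty(0)

    order = np.argsort(senders, kind="stable")
    senders = senders[order]
    receivers = receivers[order].astype(np.int64)
    weights = weights[order]
    indptr = np.zeros(n_total + 1, dtype=np.int64)
    np.add.at(indptr, senders + 1, 1)
    indptr = np.cumsum(indptr)
    return Network(
        spec=spec, pop_of=pop_of, indptr=indptr,
        indices=receivers, weights=weights, seed=int(seed),
    )


# ---------------------------------------------------------------------------
# Glauber dynamics kernel
# ---------------------------------------------------------------------------


@njit(cache=False)
def _glauber_kernel(
    n, hin, ev_t, ev_i, ev_s, inputs,
    indptr, indices, weights, pop_of,
    theta, sig, clamped, m_clamp,
    hext, omega, seed, record_inputs,
):
    np.random.seed(seed)
    n_ev = ev_t.size
    n_neurons = n.size
    for k in range(n_ev):
        t = ev_t[k]
        i = np.random.randint(0, n_neurons)
        p = pop_of[i]
        if clamped[p]:
            new = 1 if np.random.random() < m_clamp[p] else 0
        else:
            x = hin[i] + sig[p] * np.random.standard_normal()
            if record_inputs:
                inputs[k] = x
            x += hext * np.sin(omega * t)
            new = 1 if x >= theta[p] else 0
        ev_i[k] = i
        ev_s[k] = new
        if new != n[i]:
            d = 1.0 if new == 1 else -1.0
            n[i] = new
            for jj in range(indptr[i], indptr[i + 1]):
                hin[indices[jj]] += weights[jj] * d


@njit(cache=False)
def _replay_kernel(n0, ev_t, ev_i, ev_s, cut, out):
    cur = n0.copy()
    prev = 0
    for s in range(cut.size):
        stop = cut[s]
        for k in range(prev, stop):
            cur[ev_i[k]] = ev_s[k]
        out[s] = cur
        prev = stop


def _replay_py(n0, ev_i, ev_s, cut, out):
    cur = n0.copy()
    prev = 0
    for s in range(cut.size):
        stop = cut[s]
        if stop > prev:
            cur[ev_i[prev:stop]] = ev_s[prev:stop]
        out[s] = cur
        prev = stop


@dataclass
class StateTrajectory:
    """Event record of one simulated trial.

    ``t`` holds the (strictly increasing) update-event times in ms, and
    ``neuron``/``state`` the updated neuron and its new state — all update
    events are recorded, whether or not the state changed, so the expected
    event count is ``duration N / tau``.
    """

    t: np.ndarray
    neuron: np.ndarray
    state: np.ndarray
    n0: np.ndarray
    duration: float
    drive: DriveSpec
    seed: int
    inputs: np.ndarray | None = None

    @property
    def n_neurons(self) -> int:
        return self.n0.size

    def states_at(self, times: np.ndarray) -> np.ndarray:
        """Network state (0/1 per neuron) at each requested time."""
        times = np.asarray(times, dtype=float)
        if np.any(np.diff(times) < 0):
            raise ValueError("sample times must be sorted")
        cut = np.searchsorted(self.t, times, side="right").astype(np.int64)
        out = np.empty((times.size, self.n_neurons), dtype=np.uint8)
        if HAVE_NUMBA:
            _replay_kernel(self.n0, self.t, self.neuron, self.state, cut, out)
        else:
            _replay_py(self.n0, self.neuron, self.state, cut, out)
        return out

    def update_intervals(self, neuron_id: int) -> np.ndarray:
        """Inter-update intervals of one neuron (ms); exponential with
        mean tau by construction."""
        return np.diff(self.t[self.neuron == neuron_id])


def simulate(
    net: Network,
    drive: DriveSpec,
    duration: float,
    seed: int,
    init_m: np.ndarray | None = None,
    record_inputs: bool = False,
    step_mode: str = "event",
) -> StateTrajectory:
    """Run Glauber dynamics on one network realization.

    Parameters
    ----------
    duration:
        Simulated time in ms.
    init_m:
        Initial activation probability per population; defaults to the
        calibration targets (clamped means for clamped populations).
    record_inputs:
        Also record, per update event of a dynamic neuron, the summed
        recurrent input plus noise (used to check the Gaussian-input
        approximation).
    step_mode:
        ``"event"`` draws exponential waiting times (rate ``N / tau``);
        ``"fixed"`` uses a regular grid with step ``tau / N``, for
        cross-checking the event-driven scheme.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    spec = net.spec
    ss = np.random.SeedSequence(seed)
    s_times, s_kernel, s_init = ss.spawn(3)
    rng_t = np.random.default_rng(s_times)
    rng_init = np.random.default_rng(s_init)

    n_total = net.n_neurons
    rate = n_total / spec.tau  # events per ms
    if step_mode == "event":
        mean_ev = duration * rate
        cap = int(mean_ev + 10.0 * np.sqrt(mean_ev) + 100)
        ev_t = np.cumsum(rng_t.exponential(1.0 / rate, size=cap))
        while ev_t[-1] < duration:  # pragma: no cover - vanishing probability
            extra = np.cumsum(rng_t.exponential(1.0 / rate, size=cap // 4)) + ev_t[-1]
            ev_t = np.concatenate([ev_t, extra])
        ev_t = ev_t[ev_t < duration]
    elif step_mode == "fixed":
        dt = spec.tau / n_total
        ev_t = np.arange(1, int(duration / dt) + 1) * dt
        ev_t = ev_t[ev_t < duration]
    else:
        raise ValueError("step_mode must be 'event' or 'fixed'")

    if init_m is None:
        full = spec.m_clamped.copy()
        tgt = spec.target_m
        full[spec.dynamic] = np.where(np.isnan(tgt), 0.5, tgt)
    else:
        full = np.asarray(init_m, dtype=float)
    n0 = (rng_init.random(n_total) < full[net.pop_of]).astype(np.uint8)

    # initial summed recurrent input per neuron
    hin = np.zeros(n_total)
    senders = np.repeat(np.arange(n_total), np.diff(net.indptr))
    active = n0[senders] == 1
    if np.any(active):
        hin = np.bincount(
            net.indices[active], weights=net.weights[active], minlength=n_total
        ).astype(float)

    theta = np.where(np.isnan(spec.theta), 0.0, spec.theta)
    sig = spec.sigma_noise
    clamped = spec.clamped
    m_clamp = np.where(np.isnan(spec.m_clamped), 0.0, spec.m_clamped)
    if np.any(~clamped) and np.any(np.isnan(spec.theta[~clamped])):
        raise ValueError("dynamic populations need calibrated thresholds")

    n_ev = ev_t.size
    ev_i = np.empty(n_ev, dtype=np.int64)
    ev_s = np.empty(n_ev, dtype=np.uint8)
    inputs = np.empty(n_ev if record_inputs else 0)
    n_state = n0.copy()
    kernel_seed = int(s_kernel.generate_state(1, dtype=np.uint32)[0] % (2**31 - 1))

    args = (
        n_state, hin, ev_t, ev_i, ev_s, inputs,
        net.indptr, net.indices, net.weights, net.pop_of,
        theta, sig, clamped, m_clamp,
        float(drive.h_ext), float(drive.omega), kernel_seed, record_inputs,
    )
    if HAVE_NUMBA:
        _glauber_kernel(*args)
    else:
        _glauber_py(*args)

    return StateTrajectory(
        t=ev_t, neuron=ev_i, state=ev_s, n0=n0, duration=float(duration),
        drive=drive, seed=int(seed),
        inputs=inputs if record_inputs else None,
    )


def _glauber_py(
    n, hin, ev_t, ev_i, ev_s, inputs,
    indptr, indices, weights, pop_of,
    theta, sig, clamped, m_clamp,
    hext, omega, seed, record_inputs,
):
    # NumPy fallback mirroring the compiled kernel (slower, same semantics)
    np.random.seed(seed)
    n_neurons = n.size
    for k in range(ev_t.size):
        t = ev_t[k]
        i = np.random.randint(0, n_neurons)
        p = pop_of[i]
        if clamped[p]:
            new = 1 if np.random.random() < m_clamp[p] else 0
        else:
            x = hin[i] + sig[p] * np.random.standard_normal()
            if record_inputs:
                inputs[k] = x
            x += hext * np.sin(omega * t)
            new = 1 if x >= theta[p] else 0
        ev_i[k] = i
        ev_s[k] = new
        if new != n[i]:
            d = 1.0 if new == 1 else -1.0
            n[i] = new
            sl = slice(indptr[i], indptr[i + 1])
            np.add.at(hin, indices[sl], weights[sl] * d)


# ---------------------------------------------------------------------------
# Cyclostationary estimation
# ---------------------------------------------------------------------------


@dataclass
class CyclostatEstimate:
    """Phase-binned ensemble statistics of simulated trials.

    ``phase`` holds the bin centers in [0, 2 pi); all per-bin arrays are
    indexed ``[bin, population]`` (covariances ``[bin, pop, pop]``).
    Standard errors stem from the across-trial spread of per-trial
    estimates.  ``c_pop = c + diag(a / N)`` is the covariance matrix of the
    population-averaged activity used for the error ellipse.
    """

    spec: NetworkSpec
    drive: DriveSpec
    phase: np.ndarray
    m: np.ndarray
    m_se: np.ndarray
    a: np.ndarray
    a_se: np.ndarray
    c: np.ndarray
    c_se: np.ndarray
    c_pop: np.ndarray
    n_trials: int
    n_cycles: int
    n_pairs: int

    def time_average(self) -> dict:
        """Phase-averaged statistics (for comparison with the stationary
        theory); SEs shrink with the number of (nearly independent) bins."""
        nb = self.phase.size
        return {
            "m": self.m.mean(axis=0),
            "m_se": np.sqrt((self.m_se**2).mean(axis=0) / nb),
            "a": self.a.mean(axis=0),
            "a_se": np.sqrt((self.a_se**2).mean(axis=0) / nb),
            "c": self.c.mean(axis=0),
            "c_se": np.sqrt((self.c_se**2).mean(axis=0) / nb),
        }

    def harmonic(self, quantity: str, order: int = 1) -> np.ndarray:
        """Fourier coefficient of a phase-binned quantity over the cycle.

        Same sine convention as the theory: ``x(phi) = X0 +
        sum_k Im(Xk exp(i k phi))``.
        """
        x = getattr(self, quantity)
        if order == 0:
            return x.mean(axis=0)
        w = np.exp(-1j * order * self.phase)
        shape = (self.phase.size,) + (1,) * (x.ndim - 1)
        return 2j * (x * w.reshape(shape)).mean(axis=0)


def _sample_pairs(rng, idx_a, idx_b, n_pairs, same_pop):
    ii = rng.choice(idx_a, size=n_pairs, replace=True)
    jj = rng.choice(idx_b, size=n_pairs, replace=True)
    if same_pop:
        bad = ii == jj
        while np.any(bad):
            jj[bad] = rng.choice(idx_b, size=int(bad.sum()), replace=True)
            bad = ii == jj
    return ii, jj


def cyclostationary_stats(
    trials: list[StateTrajectory],
    spec: NetworkSpec,
    drive: DriveSpec,
    n_bins: int = 30,
    pair_subsample: int = 2000,
    seed: int = 0,
) -> CyclostatEstimate:
    """Estimate phase-resolved moments from an ensemble of trials.

    Time is folded onto the drive phase with ``n_bins`` bins after
    discarding the transient.  Means pool neurons, cycles and trials.
    Variances and pairwise covariances are estimated across realizations
    (trial x cycle, unbiased divisor); covariances average a fixed random
    subsample of ordered pairs per population block.  Requires at least
    two trials (the covariance needs an ensemble) and five usable cycles.
    """
    if len(trials) < 2:
        raise ValueError("cyclostationary covariance needs >= 2 trials")
    if drive.f <= 0:
        raise ValueError("phase folding requires a finite drive frequency")
    period = drive.period
    t_cut = transient_length(spec.tau, period)
    c0 = int(np.ceil(t_cut / period - 1e-9))
    n_cyc = min(
        int(np.floor(tr.duration / period - 1e-9)) - c0 for tr in trials
    )
    if n_cyc < 5:
        raise InsufficientCycles(
            f"only {n_cyc} usable cycles after the transient; need >= 5"
        )

    phase = (np.arange(n_bins) + 0.5) * 2.0 * np.pi / n_bins
    t_in_cycle = phase / (2.0 * np.pi) * period
    times = (
        (np.arange(c0, c0 + n_cyc) * period)[:, None] + t_in_cycle[None, :]
    ).ravel()

    n_total = trials[0].n_neurons
    X = np.empty((len(trials), n_cyc, n_bins, n_total), dtype=np.uint8)
    for r, tr in enumerate(trials):
        if tr.n_neurons != n_total:
            raise ValueError("trials stem from differently sized networks")
        X[r] = tr.states_at(times).reshape(n_cyc, n_bins, n_total)

    R = len(trials)
    npop = spec.n
    off = np.concatenate([[0], np.cumsum(spec.N).astype(int)])
    pops = [np.arange(off[i], off[i + 1]) for i in range(npop)]
    rng = np.random.default_rng(seed)

    m = np.empty((n_bins, npop))
    m_se = np.empty((n_bins, npop))
    a = np.empty((n_bins, npop))
    a_se = np.empty((n_bins, npop))
    c = np.empty((n_bins, npop, npop))
    c_se = np.empty((n_bins, npop, npop))

    Xf = X.astype(np.float32)
    n_real = R * n_cyc
    # per-neuron means over realizations, per bin
    mean_bn = Xf.reshape(n_real, n_bins, n_total).mean(axis=0)

    for p, idx in enumerate(pops):
        blk = Xf[..., idx]                      # (R, cyc, bins, Np)
        m[:, p] = blk.mean(axis=(0, 1, 3))
        trial_m = blk.mean(axis=(1, 3))         # (R, bins)
        m_se[:, p] = trial_m.std(axis=0, ddof=1) / np.sqrt(R)
        centered = blk - mean_bn[None, None, :, idx]
        var_bn = (centered**2).reshape(n_real, n_bins, -1).sum(axis=0) / (
            n_real - 1
        )
        a[:, p] = var_bn.mean(axis=1)
        trial_v = (centered**2).mean(axis=(1, 3)) * n_cyc * R / (n_real - 1)
        a_se[:, p] = trial_v.std(axis=0, ddof=1) / np.sqrt(R)

    Xc = (Xf - mean_bn[None, None]).reshape(n_real, n_bins, n_total)
    for pa in range(npop):
        for pb in range(pa, npop):
            if spec.populations[pa].clamped and spec.populations[pb].clamped:
                # independent Bernoulli units: covariance identically zero
                c[:, pa, pb] = c[:, pb, pa] = 0.0
                c_se[:, pa, pb] = c_se[:, pb, pa] = 0.0
                continue
            ii, jj = _sample_pairs(
                rng, pops[pa], pops[pb], pair_subsample, pa == pb
            )
            for b in range(n_bins):
                prod = Xc[:, b, ii] * Xc[:, b, jj]       # (n_real, P)
                est = prod.mean(axis=1).sum() / (n_real - 1)
                trial_est = (
                    prod.reshape(R, n_cyc, -1).mean(axis=(1, 2))
                    * n_real / (n_real - 1)
                )
                se = trial_est.std(ddof=1) / np.sqrt(R)
                c[b, pa, pb] = c[b, pb, pa] = est
                c_se[b, pa, pb] = c_se[b, pb, pa] = se

    c_pop = c + np.einsum(
        "bp,pq->bpq", a / spec.N[None, :], np.eye(npop)
    )
    return CyclostatEstimate(
        spec=spec, drive=drive, phase=phase,
        m=m, m_se=m_se, a=a, a_se=a_se, c=c, c_se=c_se, c_pop=c_pop,
        n_trials=R, n_cycles=n_cyc, n_pairs=pair_subsample,
    )


class InsufficientCycles(ValueError):
    """Fewer than five usable drive cycles after the transient."""


# ---------------------------------------------------------------------------
# Population error ellipse
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EllipseParams:
    """One-standard-deviation ellipse of the population activity.

    ``center`` is the mean activity of the dynamic populations, ``axes``
    the principal directions (columns) and ``half_lengths`` the square
    roots of the eigenvalues of ``c_pop``, in descending order.
    """

    center: np.ndarray
    axes: np.ndarray
    half_lengths: np.ndarray

    def boundary(self, n_points: int = 100) -> np.ndarray:
        """Points on the ellipse ``dm^T c_pop^{-1} dm = 1``."""
        t = np.linspace(0.0, 2.0 * np.pi, n_points)
        circ = np.stack([np.cos(t), np.sin(t)])
        return (
            self.center[:, None] + self.axes @ (self.half_lengths[:, None] * circ)
        )


def population_ellipse(est: CyclostatEstimate, bin_index: int) -> EllipseParams:
    """Error ellipse of the population-averaged activity at one phase bin.

    Diagonalizes the dynamic-population block of ``c_pop``; the ellipse
    ``dm^T c_pop^{-1} dm = 1`` has the eigenvectors as axes and the square
    roots of the eigenvalues as half-lengths.  Tilted axes indicate a
    nonzero cross-population covariance.
    """
    dyn = np.where(est.spec.dynamic)[0]
    C = est.c_pop[bin_index][np.ix_(dyn, dyn)]
    center = est.m[bin_index, dyn]
    vals, vecs = np.linalg.eigh(0.5 * (C + C.T))
    if np.min(vals) <= 1e-15 * max(np.max(np.abs(vals)), 1e-300):
        raise DegenerateEllipseError(
            "population covariance is singular; the ellipse is degenerate"
        )
    order = np.argsort(vals)[::-1]
    return EllipseParams(
        center=center,
        axes=vecs[:, order],
        half_lengths=np.sqrt(vals[order]),
    )
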