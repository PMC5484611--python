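"""Core types and transfer functions for population-level binary-network models.

A recurrent network of binary (0/1) neurons is described at the population
level by mean activities ``m``, single-unit variances ``a = m (1 - m)`` and
population-averaged pairwise covariances ``c``.  Under a Gaussian
approximation of the summed synaptic input, the expected activation of a
neuron with threshold ``theta`` receiving input of mean ``mu`` and standard
deviation ``sigma`` is the complementary-error-function gain
:func:`gain_phi`.  Its derivatives with respect to the mean input,
:func:`susceptibility` and :func:`dsusceptibility_dmu`, are the single-unit
linear gain and its curvature; together with the input moments
(:func:`input_moments`) they are the building blocks of both the stationary
self-consistency equations and the linear response to a weak periodic
drive.

Units
-----
Time is measured in milliseconds, user-facing frequencies in Hz.  Synaptic
weights, thresholds, noise amplitudes and input moments share one arbitrary
"input unit".  Mean activities are dimensionless occupation probabilities in
``[0, 1]``; firing rates are reported as ``nu = m / tau`` (converted
explicitly from 1/ms to Hz where needed).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import special

__all__ = [
    "ConvergenceError",
    "DriveSpec",
    "InputMoments",
    "MomentState",
    "NetworkSpec",
    "Population",
    "calibrate_thresholds",
    "calibrated",
    "dsusceptibility_dmu",
    "gain_phi",
    "input_moments",
    "stationary_covariance",
    "susceptibility",
]

_SQRT2 = np.sqrt(2.0)
_SQRT2PI = np.sqrt(2.0 * np.pi)


class ConvergenceError(RuntimeError):
    """A self-consistent iteration did not reach its tolerance."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Population:
    """One homogeneous population of binary neurons.

    Parameters
    ----------
    name:
        Label, e.g. ``"E"``, ``"I"`` or ``"X"``.
    size:
        Number of neurons ``N`` (>= 1).
    sigma_noise:
        Standard deviation of the Gaussian noise added to the input of each
        neuron at every update (input units, >= 0).  Ignored for clamped
        populations.
    theta:
        Activation threshold (input units).  ``None`` until calibrated.
        Only meaningful for dynamic populations.
    m_clamped:
        If set, the population is *clamped* (external): its neurons are
        active with this fixed probability and receive no recurrent input.
    target_m:
        Desired stationary mean activity used by threshold calibration.
    """

    name: str
    size: int
    sigma_noise: float = 0.0
    theta: float | None = None
    m_clamped: float | None = None
    target_m: float | None = None

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError(f"population {self.name!r}: size must be >= 1")
        if self.sigma_noise < 0:
            raise ValueError(f"population {self.name!r}: sigma_noise must be >= 0")
        if self.m_clamped is not None:
            if not 0.0 < self.m_clamped < 1.0:
                raise ValueError(
                    f"population {self.name!r}: m_clamped must lie in (0, 1)"
                )
            if self.theta is not None:
                raise ValueError(
                    f"population {self.name!r}: clamped populations carry no threshold"
                )
        if self.target_m is not None and not 0.0 < self.target_m < 1.0:
            raise ValueError(f"population {self.name!r}: target_m must lie in (0, 1)")

    @property
    def clamped(self) -> bool:
        return self.m_clamped is not None


@dataclass(frozen=True, eq=False)
class NetworkSpec:
    """Population-level parameters of a random binary network.

    The connectivity is an Erdos-Renyi-like random graph with fixed
    in-degree: every neuron of population ``alpha`` receives exactly
    ``K[alpha, beta] = round(p[alpha, beta] * N[beta])`` synapses of weight
    ``J[alpha, beta]`` from population ``beta``.

    Parameters
    ----------
    populations:
        Ordered tuple of :class:`Population`.
    p:
        Connection probabilities, ``p[a, b]`` from population ``b`` onto a
        neuron of population ``a``; rows of clamped populations must be 0.
    J:
        Synaptic weights (input units), same orientation as ``p``.  Each
        sending population has a single weight sign (Dale's law at the
        population level).
    tau:
        Update time constant in milliseconds.
    """

    populations: tuple[Population, ...]
    p: np.ndarray
    J: np.ndarray
    tau: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "populations", tuple(self.populations))
        p = np.array(self.p, dtype=float)
        J = np.array(self.J, dtype=float)
        n = len(self.populations)
        if p.shape != (n, n) or J.shape != (n, n):
            raise ValueError(f"p and J must have shape ({n}, {n})")
        object.__setattr__(self, "p", p)
        object.__setattr__(self, "J", J)
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("connection probabilities must lie in [0, 1]")
        for i, pop in enumerate(self.populations):
            if pop.clamped and np.any(p[i] != 0):
                raise ValueError(
                    f"clamped population {pop.name!r} must have a zero in-degree row"
                )
        # one weight sign per sending population, where connections exist
        K = self.K
        for b in range(n):
            w = J[:, b][K[:, b] > 0]
            if w.size and not (np.all(w >= 0) or np.all(w <= 0)):
                raise ValueError(
                    f"weights from population {self.populations[b].name!r} mix signs"
                )

    def __eq__(self, other) -> bool:
        if not isinstance(other, NetworkSpec):
            return NotImplemented
        return (
            self.populations == other.populations
            and np.array_equal(self.p, other.p)
            and np.array_equal(self.J, other.J)
            and self.tau == other.tau
        )

    # -- derived arrays ----------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.populations)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(pop.name for pop in self.populations)

    @property
    def N(self) -> np.ndarray:
        return np.array([pop.size for pop in self.populations], dtype=float)

    @property
    def clamped(self) -> np.ndarray:
        return np.array([pop.clamped for pop in self.populations])

    @property
    def dynamic(self) -> np.ndarray:
        return ~self.clamped

    @property
    def K(self) -> np.ndarray:
        """Fixed in-degrees ``round(p[a, b] * N[b])`` (integer array)."""
        K = np.rint(self.p * self.N[None, :]).astype(int)
        if np.any(K > self.N[None, :].astype(int)):
            raise ValueError("in-degree K exceeds sending population size")
        return K

    @property
    def T(self) -> np.ndarray:
        """Total-weight matrix ``T = K * J`` (Hadamard product)."""
        return self.K * self.J

    @property
    def sigma_noise(self) -> np.ndarray:
        return np.array([pop.sigma_noise for pop in self.populations], dtype=float)

    @property
    def theta(self) -> np.ndarray:
        """Thresholds; NaN for clamped or uncalibrated populations."""
        return np.array(
            [np.nan if pop.theta is None else pop.theta for pop in self.populations],
            dtype=float,
        )

    @property
    def m_clamped(self) -> np.ndarray:
        return np.array(
            [np.nan if pop.m_clamped is None else pop.m_clamped
             for pop in self.populations],
            dtype=float,
        )

    @property
    def target_m(self) -> np.ndarray:
        """Calibration targets of the dynamic populations (NaN if unset)."""
        return np.array(
            [np.nan if pop.target_m is None else pop.target_m
             for pop in self.populations if not pop.clamped],
            dtype=float,
        )

    @property
    def has_thresholds(self) -> bool:
        return all(pop.clamped or pop.theta is not None for pop in self.populations)

    # -- constructors ------------------------------------------------------

    def with_thresholds(self, theta_dynamic: np.ndarray) -> "NetworkSpec":
        """Return a copy with thresholds assigned to the dynamic populations."""
        theta_dynamic = np.asarray(theta_dynamic, dtype=float)
        pops = []
        it = iter(theta_dynamic)
        for pop in self.populations:
            if pop.clamped:
                pops.append(pop)
            else:
                pops.append(dataclasses.replace(pop, theta=float(next(it))))
        return dataclasses.replace(self, populations=tuple(pops))

    def scaled(self, factor: float) -> "NetworkSpec":
        """Return a size-scaled copy (same p, J, tau; thresholds dropped).

        In-degrees follow the scaled sizes through ``K = round(p N)``; the
        thresholds must be recalibrated for the new size, so they are reset.
        """
        pops = [
            dataclasses.replace(
                pop, size=max(1, int(round(pop.size * factor))), theta=None
            )
            for pop in self.populations
        ]
        return dataclasses.replace(self, populations=tuple(pops))

    def full_m(self, m_dynamic: np.ndarray) -> np.ndarray:
        """Expand a dynamic-population vector to all populations."""
        m = self.m_clamped.copy()
        m[self.dynamic] = np.asarray(m_dynamic, dtype=float)
        return m


@dataclass(frozen=True)
class DriveSpec:
    """Global sinusoidal drive ``h_ext * sin(omega t)`` applied to every
    dynamic neuron.

    ``h_ext`` is the amplitude in input units and ``f`` the frequency in Hz;
    the angular frequency ``omega`` is converted to rad/ms internally.
    """

    h_ext: float = 0.0
    f: float = 0.0

    def __post_init__(self) -> None:
        if self.h_ext < 0:
            raise ValueError("h_ext must be >= 0")
        if self.f < 0:
            raise ValueError("f must be >= 0")

    @property
    def omega(self) -> float:
        """Angular frequency in rad/ms."""
        return 2.0 * np.pi * self.f / 1000.0

    @property
    def period(self) -> float:
        """Drive period in ms (inf for f = 0)."""
        return np.inf if self.f == 0 else 1000.0 / self.f


@dataclass
class MomentState:
    """Population means and zero-lag covariances at one instant.

    ``m`` is the vector of mean activities, ``c`` the symmetric matrix of
    population-averaged pairwise covariances.  The single-unit variance
    ``a = m (1 - m)`` is derived.  Covariances between neurons of a clamped
    population vanish (independent Bernoulli units).
    """

    m: np.ndarray
    c: np.ndarray

    def __post_init__(self) -> None:
        self.m = np.asarray(self.m, dtype=float)
        self.c = np.asarray(self.c, dtype=float)
        n = self.m.size
        if self.c.shape != (n, n):
            raise ValueError("c must be square and match m")
        if np.any(self.m < -1e-9) or np.any(self.m > 1 + 1e-9):
            raise ValueError("mean activities must lie in [0, 1]")
        if not np.allclose(self.c, self.c.T, atol=1e-10, rtol=0.0):
            raise ValueError("covariance matrix must be symmetric")

    @property
    def a(self) -> np.ndarray:
        return self.m * (1.0 - self.m)

    @classmethod
    def uncorrelated(cls, m: np.ndarray) -> "MomentState":
        m = np.asarray(m, dtype=float)
        return cls(m, np.zeros((m.size, m.size)))


@dataclass(frozen=True)
class InputMoments:
    """Gaussian moments of the summed input per population.

    ``sigma_network`` is the part of the input fluctuation generated by the
    network (pairwise covariances plus single-unit variances of the
    senders); ``sigma**2 = sigma_network**2 + sigma_noise**2``.
    ``sigma_independent`` keeps only the sender Bernoulli variances
    ``(K * J^2) a`` — the width the input distribution would have for
    independently active senders (the convolved-binomial width), which is
    the conventional headline number for the network-generated noise
    level.
    """

    mu: np.ndarray
    sigma: np.ndarray
    sigma_network: np.ndarray
    sigma_independent: np.ndarray


# ---------------------------------------------------------------------------
# Transfer functions
# ---------------------------------------------------------------------------


def _check_sigma(sigma) -> np.ndarray:
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be > 0")
    return sigma


def gain_phi(mu, sigma, theta):
    """Expected activation of a threshold unit with Gaussian input.

    ``phi(mu, sigma, theta) = erfc((theta - mu) / (sqrt(2) sigma)) / 2`` is
    the probability that a Gaussian input of mean ``mu`` and SD ``sigma``
    exceeds the threshold ``theta``.  Smooth and strictly increasing in
    ``mu``.
    """
    sigma = _check_sigma(sigma)
    return 0.5 * special.erfc((np.asarray(theta) - np.asarray(mu)) / (_SQRT2 * sigma))


def susceptibility(mu, sigma, theta):
    """Single-unit linear gain ``S = d phi / d mu`` (per input unit).

    A Gaussian bump, maximal at ``mu = theta`` where it equals
    ``1 / (sqrt(2 pi) sigma)``.
    """
    sigma = _check_sigma(sigma)
    z = (np.asarray(mu) - np.asarray(theta)) / sigma
    return np.exp(-0.5 * z * z) / (_SQRT2PI * sigma)


def dsusceptibility_dmu(mu, sigma, theta):
    """Curvature ``dS/dmu = ((theta - mu) / sigma^2) S`` (per input unit^2)."""
    sigma = _check_sigma(sigma)
    return (np.asarray(theta) - np.asarray(mu)) / sigma**2 * susceptibility(
        mu, sigma, theta
    )


def input_moments(
    state: MomentState, spec: NetworkSpec, external_input: float = 0.0
) -> InputMoments:
    """Gaussian moments of the summed synaptic input per population.

    ``mu = T m + external_input`` and
    ``sigma_network^2 = diag(T c T^t) + (K * J^2) a`` with ``T = K * J``:
    the first term collects pairwise covariances among the senders, the
    second their Bernoulli variances.  The external noise adds in
    quadrature.
    """
    if state.m.size != spec.n:
        raise ValueError("state dimension does not match the network spec")
    T = spec.T
    m = state.m
    mu = T @ m + external_input
    var_pairs = np.einsum("ab,bc,ac->a", T, state.c, T)
    var_auto = (spec.K * spec.J**2) @ state.a
    var_net = var_pairs + var_auto
    # tiny negative values can arise from cancellation in the pair term
    var_net = np.maximum(var_net, 0.0)
    sigma_network = np.sqrt(var_net)
    sigma = np.sqrt(var_net + spec.sigma_noise**2)
    return InputMoments(
        mu=mu,
        sigma=sigma,
        sigma_network=sigma_network,
        sigma_independent=np.sqrt(var_auto),
    )


# ---------------------------------------------------------------------------
# Stationary covariance (linear solve) and threshold calibration
# ---------------------------------------------------------------------------


def stationary_covariance(W: np.ndarray, a: np.ndarray, N: np.ndarray) -> np.ndarray:
    """Solve ``2 c = W (c + diag(a/N)) + transpose`` for ``c``.

    This is the fixed point of the linearized covariance dynamics given the
    effective connectivity ``W`` and the single-unit variances ``a``.  The
    equation is solved exactly in the eigenbasis of ``W`` (componentwise
    division by ``2 - lambda_i - lambda_j``); for ill-conditioned
    eigenvector matrices it falls back to a Schur-based Sylvester solve.
    """
    D = np.diag(np.asarray(a, dtype=float) / np.asarray(N, dtype=float))
    B = W @ D
    B = B + B.T
    lam, U = np.linalg.eig(W)
    if np.linalg.cond(U) < 1e10:
        Uinv = np.linalg.inv(U)
        Bt = Uinv @ B @ Uinv.T
        denom = 2.0 - lam[:, None] - lam[None, :]
        c = U @ (Bt / denom) @ U.T
        c = c.real
    else:  # defective or near-defective W
        from scipy.linalg import solve_sylvester

        # 2c - Wc - cW^T = B  <=>  (2I - W) c + c (-W^T) = B
        c = solve_sylvester(2.0 * np.eye(W.shape[0]) - W, -W.T, B)
    return 0.5 * (c + c.T)


def calibrate_thresholds(
    target_m: np.ndarray,
    spec: NetworkSpec,
    *,
    tol: float = 1e-12,
    damping: float = 0.5,
    max_iter: int = 10_000,
) -> np.ndarray:
    """Thresholds that put the stationary means at ``target_m``.

    Inverts the stationarity condition ``phi(mu, sigma, theta) = m`` via
    ``theta = mu + sqrt(2) sigma erfcinv(2 m)``.  Because ``sigma`` depends
    on the stationary covariances, which in turn depend on the thresholds,
    the covariance part is iterated to self-consistency at fixed means
    before the thresholds are read off.  Note that at fixed target means the
    susceptibility ``S = exp(-erfcinv(2m)^2) / (sqrt(2 pi) sigma)`` does not
    depend on ``theta`` explicitly, so the joint fixed point reduces to an
    iteration over the covariance matrix alone.

    Parameters
    ----------
    target_m:
        Desired stationary means of the *dynamic* populations, each in
        (0, 1).
    spec:
        Network specification; thresholds may be unset.

    Returns
    -------
    ndarray
        Thresholds for the dynamic populations, in population order.
    """
    target_m = np.atleast_1d(np.asarray(target_m, dtype=float))
    dyn = spec.dynamic
    if target_m.size != int(dyn.sum()):
        raise ValueError("need one target mean per dynamic population")
    if np.any(target_m <= 0) or np.any(target_m >= 1):
        raise ValueError("target means must lie in (0, 1)")

    m = spec.full_m(target_m)
    a = m * (1.0 - m)
    z = _SQRT2 * special.erfcinv(2.0 * target_m)  # (theta - mu) / sigma
    s_peak = np.exp(-0.5 * z * z) / _SQRT2PI      # S * sigma at the fixed point
    N = spec.N
    T = spec.T

    c = np.zeros((spec.n, spec.n))
    im = input_moments(MomentState(m, c), spec)
    for _ in range(max_iter):
        S = np.zeros(spec.n)
        S[dyn] = s_peak / im.sigma[dyn]
        W = S[:, None] * T
        c_new = stationary_covariance(W, a, N)
        delta = np.max(np.abs(c_new - c))
        c = c + damping * (c_new - c)
        im = input_moments(MomentState(m, c), spec)
        if delta < tol * max(1.0, np.max(np.abs(c))):
            break
    else:
        raise ConvergenceError(
            "threshold calibration did not converge", residual=float(delta)
        )
    theta = im.mu[dyn] + z * im.sigma[dyn]
    # self-consistency check: phi at the calibrated point reproduces target_m
    resid = np.max(
        np.abs(gain_phi(im.mu[dyn], im.sigma[dyn], theta) - target_m)
    )
    if resid > 1e-10:
        raise ConvergenceError("calibration residual too large", residual=float(resid))
    return theta


def calibrated(spec: NetworkSpec, **kwargs) -> NetworkSpec:
    """Return ``spec`` with thresholds calibrated to its population targets."""
    targets = spec.target_m
    if np.any(np.isnan(targets)):
        raise ValueError("all dynamic populations need a target_m for calibration")
    return spec.with_thresholds(calibrate_thresholds(targets, spec, **kwargs))
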