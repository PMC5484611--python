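"""Numerical integration of the full mean-field moment ODEs.

The coupled population equations

``tau dm/dt = -m + phi(mu(m, h sin(omega t)), sigma(m, c))``
``tau dc/dt = -2c + W(t) (c + diag(a/N)) + [W(t) (c + diag(a/N))]^T``

with ``W(t) = S(mu(t), sigma(t)) * K * J`` are integrated without
linearization; the gain and susceptibility are evaluated at the
instantaneous input moments.  Harmonics of the resulting cyclostationary
trajectories are extracted by projection onto ``exp(-i k omega t)`` over an
integer number of drive periods after discarding the transient.

The covariance contribution to the input width ``sigma`` can be kept
time-dependent (``sigma_dynamics="full"``, the default) or frozen at its
stationary value (``"frozen"``), which mimics the approximation used by the
analytic linear-response layer and is the right mode for cross-validating
it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .core import DriveSpec, MomentState, NetworkSpec, gain_phi, susceptibility
from .stationary import solve_stationary

__all__ = [
    "HarmonicSet",
    "InsufficientDataError",
    "MomentTrajectory",
    "extract_harmonics",
    "integrate_moments",
    "transient_length",
]


class InsufficientDataError(ValueError):
    """Trajectory too short for the requested analysis."""


def transient_length(tau: float, period: float) -> float:
    """Length of the discarded initial transient: ``max(20 tau, 2 periods)``."""
    if np.isfinite(period):
        return max(20.0 * tau, 2.0 * period)
    return 20.0 * tau


@dataclass
class MomentTrajectory:
    """Time-resolved population moments under periodic drive.

    ``m`` has shape ``(nt, n_pops)`` and ``c`` shape ``(nt, n_pops,
    n_pops)`` with ``c[k]`` symmetric.  The time grid is uniform, in ms.
    """

    t: np.ndarray
    m: np.ndarray
    c: np.ndarray
    drive: DriveSpec
    spec: NetworkSpec

    def state_at(self, index: int) -> MomentState:
        return MomentState(self.m[index].copy(), self.c[index].copy())


@dataclass
class HarmonicSet:
    """Fourier coefficients of a cyclostationary trajectory.

    Convention: ``x(t) = X0 + sum_k Im(Xk exp(i k omega t))`` so a pure
    input-following component ``beta sin(omega t)`` has ``X1 = beta`` with
    phase 0, and ``beta cos(omega t)`` has ``X1 = i beta`` (phase +pi/2).

    ``mean_coeffs[k]`` is the order-``k`` coefficient vector of the means
    (order 0 is real); ``cov_coeffs[k]`` the coefficient matrix of the
    covariances.
    """

    orders: np.ndarray
    mean_coeffs: np.ndarray  # (max_order+1, n) complex
    cov_coeffs: np.ndarray   # (max_order+1, n, n) complex
    drive: DriveSpec

    def mean_amplitude(self, order: int) -> np.ndarray:
        return np.abs(self.mean_coeffs[order])

    def mean_phase(self, order: int) -> np.ndarray:
        return np.angle(self.mean_coeffs[order])

    def cov_amplitude(self, order: int) -> np.ndarray:
        return np.abs(self.cov_coeffs[order])

    def cov_phase(self, order: int) -> np.ndarray:
        return np.angle(self.cov_coeffs[order])


def _pack(m_dyn: np.ndarray, c: np.ndarray, iu: tuple) -> np.ndarray:
    return np.concatenate([m_dyn, c[iu]])


def _unpack(y: np.ndarray, n_dyn: int, n: int, iu: tuple) -> tuple[np.ndarray, np.ndarray]:
    c = np.zeros((n, n))
    c[iu] = y[n_dyn:]
    c = c + c.T - np.diag(np.diag(c))
    return y[:n_dyn], c


def integrate_moments(
    spec: NetworkSpec,
    drive: DriveSpec,
    t_end: float | None = None,
    init: MomentState | None = None,
    *,
    n_periods: int | None = None,
    sigma_dynamics: str = "full",
    samples_per_period: int = 64,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
) -> MomentTrajectory:
    """Integrate the full moment ODEs under sinusoidal drive.

    The state vector packs the dynamic means and the upper triangle of the
    covariance matrix, so symmetry is enforced structurally.  Clamped
    populations are held at their fixed mean.

    Parameters
    ----------
    t_end:
        Integration length in ms.  Alternatively give ``n_periods``; if
        neither is set, the transient plus eight drive periods are used.
    init:
        Initial moments; defaults to the stationary state.
    sigma_dynamics:
        ``"full"`` evaluates the input width from the instantaneous
        ``(m, c)``; ``"frozen"`` keeps it at its stationary value.
    samples_per_period:
        Output grid resolution (per drive period, or per ``20 tau`` when
        undriven).
    """
    if sigma_dynamics not in ("full", "frozen"):
        raise ValueError("sigma_dynamics must be 'full' or 'frozen'")
    period = drive.period
    if t_end is None:
        if np.isfinite(period):
            n_per = n_periods if n_periods is not None else (
                int(np.ceil(transient_length(spec.tau, period) / period)) + 8
            )
            t_end = n_per * period
        else:
            t_end = 40.0 * spec.tau
    if t_end <= 0:
        raise ValueError("t_end must be > 0")

    st = None
    if init is None or sigma_dynamics == "frozen":
        st = solve_stationary(spec)
    if init is None:
        init = st.state
    sigma_frozen = st.sigma.copy() if sigma_dynamics == "frozen" else None

    n = spec.n
    dyn = spec.dynamic
    n_dyn = int(dyn.sum())
    iu = np.triu_indices(n)
    theta_d = spec.theta[dyn]
    N = spec.N
    T = spec.T
    tau = spec.tau
    h, omega = drive.h_ext, drive.omega
    m_full = spec.m_clamped.copy()

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        m_dyn, c = _unpack(y, n_dyn, n, iu)
        m = m_full.copy()
        m[dyn] = m_dyn
        if np.any(m_dyn < -1e-6) or np.any(m_dyn > 1.0 + 1e-6):
            raise RuntimeError(
                f"mean activity left [0, 1] at t = {t:.3f} ms (model violation)"
            )
        a = m * (1.0 - m)
        ext = h * np.sin(omega * t)
        # input moments computed inline (avoids validation in the hot loop)
        mu = T @ m + ext
        if sigma_frozen is None:
            var = np.einsum("ab,bc,ac->a", T, c, T) + (spec.K * spec.J**2) @ a
            sigma = np.sqrt(np.maximum(var, 0.0) + spec.sigma_noise**2)
        else:
            sigma = sigma_frozen
        phi = gain_phi(mu[dyn], sigma[dyn], theta_d)
        S = np.zeros(n)
        S[dyn] = susceptibility(mu[dyn], sigma[dyn], theta_d)
        M = (S[:, None] * T) @ (c + np.diag(a / N))
        dc = (-2.0 * c + M + M.T) / tau
        dm = (phi - m_dyn) / tau
        return _pack(dm, dc, iu)

    if np.isfinite(period):
        dt = period / samples_per_period
    else:
        dt = 20.0 * tau / samples_per_period
    n_steps = int(round(t_end / dt))
    t_eval = np.arange(n_steps + 1) * dt

    y0 = _pack(init.m[dyn], init.c, iu)
    sol = solve_ivp(
        rhs, (0.0, float(t_eval[-1])), y0, t_eval=t_eval,
        method=method, rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"moment-ODE integration failed: {sol.message}")

    nt = sol.t.size
    m_out = np.empty((nt, n))
    c_out = np.empty((nt, n, n))
    for k in range(nt):
        m_dyn, c = _unpack(sol.y[:, k], n_dyn, n, iu)
        m_out[k] = m_full
        m_out[k, dyn] = m_dyn
        c_out[k] = c
    if np.any(m_out < -1e-6) or np.any(m_out > 1.0 + 1e-6):
        raise RuntimeError("mean activity left [0, 1] (model violation)")
    return MomentTrajectory(t=sol.t, m=m_out, c=c_out, drive=drive, spec=spec)


def extract_harmonics(
    traj: MomentTrajectory,
    drive: DriveSpec | None = None,
    max_order: int = 2,
) -> HarmonicSet:
    """Project a cyclostationary trajectory onto drive harmonics 0..max_order.

    Discards the initial transient (``max(20 tau, 2 periods)``), keeps an
    integer number of complete periods (at least five are required) and
    computes ``Xk = 2i <x(t) exp(-i k omega t)>`` for ``k >= 1`` and
    ``X0 = <x>`` by the rectangle rule, which is spectrally accurate on the
    uniform grid.
    """
    drive = drive if drive is not None else traj.drive
    if drive.f <= 0:
        raise ValueError("harmonic extraction requires a finite drive frequency")
    period = drive.period
    omega = drive.omega
    t = traj.t
    dt = t[1] - t[0]
    if not np.allclose(np.diff(t), dt, rtol=0.0, atol=1e-9 * dt):
        raise ValueError("harmonic extraction requires a uniform time grid")
    spp = period / dt
    if abs(spp - round(spp)) > 1e-6:
        raise ValueError("time grid must subdivide the drive period evenly")
    spp = int(round(spp))

    t_cut = transient_length(traj.spec.tau, period)
    i0 = int(np.ceil(t_cut / dt - 1e-9))
    n_per = (t.size - i0 - 1) // spp
    if n_per < 5:
        raise InsufficientDataError(
            f"only {n_per} full periods after the transient; need >= 5"
        )
    sel = slice(i0, i0 + n_per * spp)
    ts = t[sel]

    orders = np.arange(max_order + 1)
    n = traj.spec.n
    mean_coeffs = np.zeros((max_order + 1, n), dtype=complex)
    cov_coeffs = np.zeros((max_order + 1, n, n), dtype=complex)
    for k in orders:
        if k == 0:
            mean_coeffs[0] = traj.m[sel].mean(axis=0)
            cov_coeffs[0] = traj.c[sel].mean(axis=0)
        else:
            w = np.exp(-1j * k * omega * ts)
            mean_coeffs[k] = 2j * (traj.m[sel] * w[:, None]).mean(axis=0)
            cov_coeffs[k] = 2j * (traj.c[sel] * w[:, None, None]).mean(axis=0)
    return HarmonicSet(orders=orders, mean_coeffs=mean_coeffs,
                       cov_coeffs=cov_coeffs, drive=drive)
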