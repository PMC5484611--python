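"""Self-consistent stationary state of the mean-field moment equations.

Without drive, the population means satisfy ``m = phi(mu(m), sigma(m, c))``
and the covariances the linear relation
``2 c = W (c + diag(a/N)) + transpose`` with the effective connectivity
``W[a, b] = S_a K[a, b] J[a, b]`` (susceptibility-weighted anatomical
connectivity).  Both are solved jointly by damped fixed-point iteration;
the covariance equation is solved exactly at every step.  The eigensystem
of ``W`` governs stability (``max Re(lambda) < 1``) and is reused by the
linear-response layer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import (
    ConvergenceError,
    MomentState,
    NetworkSpec,
    gain_phi,
    input_moments,
    stationary_covariance,
    susceptibility,
)

__all__ = ["DefectiveMatrixError", "StationaryState", "eigensystem", "solve_stationary"]


class DefectiveMatrixError(np.linalg.LinAlgError):
    """The effective connectivity is (numerically) not diagonalizable."""


def eigensystem(W: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Eigendecomposition ``W = U diag(lam) U^-1`` of the effective
    connectivity.

    Eigenpairs are ordered by descending real part (conjugate pairs end up
    adjacent).  Raises :class:`DefectiveMatrixError` when the eigenvector
    matrix is too ill-conditioned for the linear-response formulas, which
    require diagonalizability.
    """
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("W must be square")
    lam, U = np.linalg.eig(W)
    order = np.lexsort((-lam.imag, -lam.real))
    lam = lam[order]
    U = U[:, order]
    cond = np.linalg.cond(U)
    if not np.isfinite(cond) or cond > 1e12:
        raise DefectiveMatrixError(
            f"eigenvector matrix condition number {cond:.3g} exceeds 1e12"
        )
    Uinv = np.linalg.inv(U)
    scale = max(1.0, float(np.max(np.abs(W))))
    resid = np.max(np.abs(U @ np.diag(lam) @ Uinv - W)) / scale
    if resid > 1e-10:
        raise DefectiveMatrixError(f"eigendecomposition residual {resid:.3g} > 1e-10")
    return U, lam, Uinv


@dataclass
class StationaryState:
    """Stationary moments and the linearization around them.

    Attributes
    ----------
    m, a, c:
        Stationary means, single-unit variances and pairwise covariances.
    mu, sigma, sigma_network:
        Input moments at the fixed point.
    S:
        Susceptibilities ``S(mu, sigma, theta)`` (zero for clamped
        populations).
    W:
        Effective connectivity ``S * K * J``; rows of clamped populations
        are zero, contributing "trivial" zero eigenvalues.
    U, lam, Uinv:
        Eigensystem of ``W``, ordered by descending real part.
    """

    spec: NetworkSpec
    m: np.ndarray
    c: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray
    sigma_network: np.ndarray
    sigma_independent: np.ndarray
    S: np.ndarray
    W: np.ndarray
    U: np.ndarray
    lam: np.ndarray
    Uinv: np.ndarray
    residual: float = 0.0

    @property
    def a(self) -> np.ndarray:
        return self.m * (1.0 - self.m)

    @property
    def c_total(self) -> np.ndarray:
        """``c + diag(a / N)``: pairwise plus population-variance part."""
        return self.c + np.diag(self.a / self.spec.N)

    @property
    def max_real_eig(self) -> float:
        return float(np.max(self.lam.real))

    @property
    def stable(self) -> bool:
        return self.max_real_eig < 1.0

    @property
    def state(self) -> MomentState:
        return MomentState(self.m.copy(), self.c.copy())

    @property
    def rates_hz(self) -> np.ndarray:
        """Stationary firing rates ``nu = m / tau`` in Hz."""
        return self.m / self.spec.tau * 1000.0


def _root_polish(
    spec: NetworkSpec, m: np.ndarray, c: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Solve the joint fixed-point residual with a hybrid Newton method."""
    from scipy.optimize import root

    dyn = spec.dynamic
    theta = spec.theta
    n = spec.n
    iu = np.triu_indices(n)
    m_full = spec.m_clamped.copy()

    def unpack(y):
        mf = m_full.copy()
        mf[dyn] = y[: int(dyn.sum())]
        cm = np.zeros((n, n))
        cm[iu] = y[int(dyn.sum()):]
        cm = cm + cm.T - np.diag(np.diag(cm))
        return mf, cm

    def residual(y):
        mf, cm = unpack(y)
        mc = np.clip(mf, 0.0, 1.0)
        a = mc * (1.0 - mc)
        im = input_moments(MomentState(mc, cm), spec)
        phi = mf.copy()
        phi[dyn] = gain_phi(im.mu[dyn], im.sigma[dyn], theta[dyn])
        S = np.zeros(n)
        S[dyn] = susceptibility(im.mu[dyn], im.sigma[dyn], theta[dyn])
        c_fix = stationary_covariance(S[:, None] * spec.T, a, spec.N)
        return np.concatenate([(phi - mf)[dyn], (c_fix - cm)[iu]])

    y0 = np.concatenate([m[dyn], c[iu]])
    sol = root(residual, y0, method="hybr", tol=1e-13)
    m_out, c_out = unpack(sol.x)
    resid = float(np.max(np.abs(residual(sol.x))))
    return m_out, 0.5 * (c_out + c_out.T), resid


def solve_stationary(
    spec: NetworkSpec,
    m0: np.ndarray | None = None,
    *,
    tol: float = 1e-12,
    damping: float = 0.5,
    max_iter: int = 10_000,
) -> StationaryState:
    """Solve the stationary mean-field equations self-consistently.

    Damped fixed-point iteration on the means combined with an exact linear
    solve of the covariance relation at every step.  Converged when both
    the gain residual ``|phi(m) - m|`` and the covariance residual fall
    below ``tol``.

    Parameters
    ----------
    spec:
        Complete network specification (thresholds set).
    m0:
        Optional initial means for the dynamic populations; defaults to the
        calibration targets where available, else 0.5.

    Raises
    ------
    ConvergenceError
        If the iteration does not converge.  A stationary state with
        ``max Re(lambda) >= 1`` is returned with a warning (it is a fixed
        point but linearly unstable).
    """
    if not spec.has_thresholds:
        raise ValueError("spec has uncalibrated thresholds; run calibrate first")
    dyn = spec.dynamic
    theta = spec.theta
    N = spec.N
    T = spec.T

    m = spec.m_clamped.copy()
    if m0 is not None:
        m[dyn] = np.asarray(m0, dtype=float)
    else:
        targets = spec.target_m
        m[dyn] = np.where(np.isnan(targets), 0.5, targets)
    c = np.zeros((spec.n, spec.n))

    resid = np.inf
    for _ in range(max_iter):
        a = m * (1.0 - m)
        im = input_moments(MomentState(m, c), spec)
        phi = m.copy()
        phi[dyn] = gain_phi(im.mu[dyn], im.sigma[dyn], theta[dyn])
        S = np.zeros(spec.n)
        S[dyn] = susceptibility(im.mu[dyn], im.sigma[dyn], theta[dyn])
        W = S[:, None] * T
        c_fix = stationary_covariance(W, a, N)
        resid = max(
            float(np.max(np.abs(phi - m))), float(np.max(np.abs(c_fix - c)))
        )
        # damped update m <- m + alpha (phi - m): the linearization factor of
        # the map is 1 + alpha (lambda - 1), so strong negative feedback
        # (lambda << 0) requires a small step; cap alpha accordingly.
        lam_w = np.linalg.eigvals(W)
        denom = np.abs(1.0 - lam_w) ** 2
        safe = np.where(lam_w.real < 1.0, 2.0 * (1.0 - lam_w.real) / denom, np.inf)
        alpha = min(damping, 0.9 * float(np.min(safe)))
        m = m + alpha * (phi - m)
        c = c + alpha * (c_fix - c)
        if resid < tol:
            break
    else:
        # far initializations can make the damped map cycle; finish with a
        # Newton-type root solve from the last iterate
        m, c, resid = _root_polish(spec, m, c)
        if resid > 1e-10:
            raise ConvergenceError(
                f"stationary solver did not converge (residual {resid:.3g})",
                residual=resid,
            )

    a = m * (1.0 - m)
    im = input_moments(MomentState(m, c), spec)
    S = np.zeros(spec.n)
    S[dyn] = susceptibility(im.mu[dyn], im.sigma[dyn], theta[dyn])
    W = S[:, None] * T
    U, lam, Uinv = eigensystem(W)
    st = StationaryState(
        spec=spec,
        m=m,
        c=c,
        mu=im.mu,
        sigma=im.sigma,
        sigma_network=im.sigma_network,
        sigma_independent=im.sigma_independent,
        S=S,
        W=W,
        U=U,
        lam=lam,
        Uinv=Uinv,
        residual=resid,
    )
    if not st.stable:
        warnings.warn(
            f"stationary state is linearly unstable: max Re(lambda) = "
            f"{st.max_real_eig:.4g} >= 1",
            RuntimeWarning,
            stacklevel=2,
        )
    return st
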