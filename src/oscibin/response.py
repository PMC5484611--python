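"""Closed-form linear response of means and covariances to sinusoidal drive.

For a weak global drive ``h_ext sin(omega t)`` the cyclostationary
deviations from the stationary state are, to first order,
``delta_m(t) = Im(M1 exp(i omega t))`` and
``delta_c(t) = Im(C1 exp(i omega t))``.  The mean response ``M1`` is a
first-order low-pass filter of the drive through the eigenmodes of the
effective connectivity ``W``.  The covariance response ``C1`` decomposes
additively into three mechanistic terms:

* the **direct-drive** term (``S_h``): the external input modulates the
  susceptibility of the receiving neurons (once low-pass filtered);
* the **recurrent-drive** term (``S_m``): the oscillating mean activity fed
  back through the network modulates the susceptibility (twice filtered);
* the **modulated-autocovariances** term (``a``): the time-varying
  single-unit variances ``a(t) = m(t)(1 - m(t))`` drive the pairwise
  covariances (twice filtered).

The analytic layer neglects the modulation of the input width ``sigma``;
:func:`delta_sigma_validity` reports the ratio that justifies this and a
warning is emitted when it is small.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import special

from .core import NetworkSpec, dsusceptibility_dmu
from .stationary import StationaryState

__all__ = [
    "LinearResponse",
    "amp_phase",
    "covariance_response",
    "delta_sigma_validity",
    "frequency_grid",
    "mean_response",
    "rate_modulation_sweep",
    "resonance_frequencies",
]


@dataclass
class LinearResponse:
    """First-harmonic amplitudes of means and covariances.

    Complex amplitudes in the sine convention ``x(t) = Im(X exp(i omega t))``
    (phase 0 means in phase with the drive ``h_ext sin(omega t)``).  ``C1``
    is the exact sum of the three decomposition terms.
    """

    omega: float  # rad/ms
    h_ext: float
    M1: np.ndarray          # complex vector, one entry per population
    C1: np.ndarray          # complex symmetric matrix
    C1_direct: np.ndarray   # S_h-term
    C1_recurrent: np.ndarray  # S_m-term
    C1_autocov: np.ndarray  # a-term
    T: np.ndarray           # K * J
    V: np.ndarray           # dS/dmu weighted connectivity

    @property
    def f(self) -> float:
        """Drive frequency in Hz."""
        return self.omega / (2.0 * np.pi) * 1000.0


def amp_phase(X) -> tuple[np.ndarray, np.ndarray]:
    """Amplitude and principal-value phase of a complex coefficient.

    Under the sine convention phase 0 is in phase with the drive and
    negative phases lag behind it.  No unwrapping is performed.
    """
    X = np.asarray(X)
    return np.abs(X), np.angle(X)


def mean_response(omega: float, st: StationaryState, h_ext: float) -> np.ndarray:
    """First harmonic ``M1`` of the mean activities.

    In the eigenbasis of ``W`` every mode is a first-order low-pass filter:
    ``M1 = U diag(1 / (1 - lambda + i tau omega)) U^-1 S h_ext``.  For
    ``omega -> 0`` this reduces to the quasi-static ``(1 - W)^-1 S h_ext``;
    for large ``omega`` the amplitude decays like ``1 / (tau omega)``.
    """
    tw = st.spec.tau * omega
    g = (st.Uinv @ st.S) * h_ext / (1.0 - st.lam + 1j * tw)
    return st.U @ g


def _modes_solve(
    R: np.ndarray, st: StationaryState, tw: float
) -> np.ndarray:
    """Solve ``(i tau omega + 2) C - W C - C W^T = R + R^T`` in the
    eigenbasis of W and return the symmetrized complex solution."""
    Rs = R + R.T
    Rt = st.Uinv @ Rs @ st.Uinv.T
    denom = 2.0 + 1j * tw - st.lam[:, None] - st.lam[None, :]
    C = st.U @ (Rt / denom) @ st.U.T
    scale = max(1.0, float(np.max(np.abs(C))))
    asym = float(np.max(np.abs(C - C.T))) / scale
    if asym > 1e-10:
        raise np.linalg.LinAlgError(
            f"covariance response asymmetry {asym:.3g} exceeds 1e-10"
        )
    return 0.5 * (C + C.T)


def covariance_response(
    omega: float, st: StationaryState, h_ext: float
) -> LinearResponse:
    """First harmonic ``C1`` of the pairwise covariances with its three-term
    decomposition.

    The linearized covariance dynamics
    ``tau d(dc)/dt + 2 dc - W dc - (W dc)^T = R(t) + R(t)^T`` is solved in
    the eigenbasis of ``W`` for a complex-exponential ansatz; each mode
    carries the factor ``1 / (2 - lambda_i - lambda_j + i tau omega)``.
    The inhomogeneity splits into the direct-drive, recurrent-drive and
    modulated-autocovariances parts, which are solved separately and
    returned individually; their sum is ``C1`` by construction.
    """
    spec = st.spec
    tw = spec.tau * omega
    dyn = spec.dynamic
    ratios = delta_sigma_validity(st)
    if np.min(ratios) < 3.0:
        warnings.warn(
            "input fluctuations are small: the neglected sigma-modulation may "
            f"matter (validity ratio {np.min(ratios):.2f} < 3)",
            RuntimeWarning,
            stacklevel=2,
        )

    M1 = mean_response(omega, st, h_ext)
    T = spec.T
    dS = np.zeros(spec.n)
    dS[dyn] = dsusceptibility_dmu(st.mu[dyn], st.sigma[dyn], spec.theta[dyn])
    V = dS[:, None] * T
    ct = st.c_total

    Vc = V @ ct
    R_direct = h_ext * Vc                        # delta_mu = h_ext for all
    R_recurrent = (T @ M1)[:, None] * Vc         # delta_mu = T delta_m
    R_autocov = st.W * ((1.0 - 2.0 * st.m) / spec.N * M1)[None, :]

    C_sh = _modes_solve(R_direct, st, tw)
    C_sm = _modes_solve(R_recurrent, st, tw)
    C_a = _modes_solve(R_autocov, st, tw)
    return LinearResponse(
        omega=omega,
        h_ext=h_ext,
        M1=M1,
        C1=C_sh + C_sm + C_a,
        C1_direct=C_sh,
        C1_recurrent=C_sm,
        C1_autocov=C_a,
        T=T,
        V=V,
    )


def resonance_frequencies(
    st: StationaryState, include_covariance_modes: bool = False
) -> np.ndarray:
    """Resonance frequencies of the mean activities in Hz.

    Each complex-conjugate eigenvalue pair of ``W`` contributes one
    resonance at ``f_res = |Im(lambda)| / (2 pi tau)``.  With
    ``include_covariance_modes`` the doubled frequencies ``2 f_res``,
    relevant for the covariance modes (their kernel involves sums of two
    eigenvalues), are appended.  Empty for purely real spectra.
    """
    imag = st.lam.imag
    pos = np.sort(imag[imag > 1e-12])
    fres = pos / (2.0 * np.pi * st.spec.tau) * 1000.0
    if include_covariance_modes:
        fres = np.concatenate([fres, 2.0 * fres])
    return fres


def delta_sigma_validity(st: StationaryState) -> np.ndarray:
    """Validity ratio for neglecting the modulation of the input width.

    Returns, per dynamic population, ``sqrt(2) erfcinv(2 m) / S`` — the
    ratio ``sigma dS/dmu / S`` of the kept susceptibility-modulation
    prefactor to the dropped width-modulation prefactor (per one input
    unit).  The approximation is good when this is large (roughly > 3),
    which holds whenever the input fluctuations are not too small.
    """
    dyn = st.spec.dynamic
    m = st.m[dyn]
    num = np.abs(np.sqrt(2.0) * special.erfcinv(2.0 * m))
    return num / st.S[dyn]


def frequency_grid(fmin: float = 1.0, fmax: float = 1000.0, n: int = 60) -> np.ndarray:
    """Logarithmic frequency grid in Hz (default 60 points, 1-1000 Hz)."""
    if n < 1 or fmin <= 0 or fmax < fmin:
        raise ValueError("need fmax >= fmin > 0 and n >= 1")
    return np.logspace(np.log10(fmin), np.log10(fmax), n)


def rate_modulation_sweep(
    st: StationaryState, h_ext: float, f_grid: np.ndarray
) -> np.ndarray:
    """Amplitude of the rate modulation ``|M1| / tau`` in Hz per frequency.

    Returns an array of shape ``(len(f_grid), n_populations)`` holding the
    full (sine-amplitude) modulation of the firing rate ``nu = m / tau``.
    """
    out = np.empty((len(f_grid), st.spec.n))
    for k, f in enumerate(np.asarray(f_grid, dtype=float)):
        omega = 2.0 * np.pi * f / 1000.0
        out[k] = np.abs(mean_response(omega, st, h_ext)) / st.spec.tau * 1000.0
    return out
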