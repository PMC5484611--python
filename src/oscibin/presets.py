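"""Ready-made network configurations.

Three presets cover the standard study conditions for periodically driven
balanced binary networks:

``single_inhibitory``
    One inhibitory population (N = 5000, p = 0.1, J = -1) at mean activity
    0.3 with external noise equal to the network-generated input
    fluctuation (sigma ~ 10.2).  The minimal self-stabilizing network.

``homogeneous_ei``
    Excitatory and inhibitory populations with identical inputs plus a
    clamped external excitatory population (N = 8192 each, p = 0.2,
    m = 0.11, m_X = 0.25).  The synaptic weights of this preset are
    representative placeholders (the setting is conventionally run with
    weights from a companion study that are not fixed here); treat its
    quantitative output accordingly.

``biological_ei``
    An EI network parameterized after layer 2/3 of mouse barrel cortex:
    connection probabilities, E/I population fractions, tau = 2.5 ms and
    target rates 18 Hz (E) / 108 Hz (I), i.e. mean activities
    m = tau * nu = 0.045 / 0.27.  External drive beyond the global
    sinusoid is absorbed into the calibrated thresholds.  Its effective
    connectivity has a complex-conjugate eigenvalue pair, hence a genuine
    resonance of the mean activities.
"""

from __future__ import annotations

import numpy as np

from .core import NetworkSpec, Population, calibrated

__all__ = ["PRESETS", "biological_ei", "homogeneous_ei", "load_preset", "single_inhibitory"]


def single_inhibitory() -> NetworkSpec:
    """Single inhibitory population; noise matched to the network SD."""
    sigma_system = np.sqrt((-1.0) ** 2 * 0.1 * 5000 * 0.3 * 0.7)  # ~10.25
    return NetworkSpec(
        populations=(
            Population("I", 5000, sigma_noise=sigma_system, target_m=0.3),
        ),
        p=[[0.1]],
        J=[[-1.0]],
        tau=10.0,
    )


def homogeneous_ei() -> NetworkSpec:
    """EI network with identical inputs plus a clamped external population.

    Weights are placeholders chosen to give an inhibition-dominated
    balanced state; they are not constrained by measurements.
    """
    p = 0.2
    j_e, j_i, j_x = 0.1, -0.5, 0.1
    return NetworkSpec(
        populations=(
            Population("E", 8192, sigma_noise=10.0, target_m=0.11),
            Population("I", 8192, sigma_noise=10.0, target_m=0.11),
            Population("X", 8192, m_clamped=0.25),
        ),
        p=[[p, p, p], [p, p, p], [0.0, 0.0, 0.0]],
        J=[[j_e, j_i, j_x], [j_e, j_i, j_x], [0.0, 0.0, 0.0]],
        tau=10.0,
    )


def biological_ei() -> NetworkSpec:
    """EI network with measured cortical (layer 2/3) parameters."""
    return NetworkSpec(
        populations=(
            Population("E", 1691, sigma_noise=10.0, target_m=0.045),
            Population("I", 230, sigma_noise=10.0, target_m=0.27),
        ),
        p=[[0.168, 0.5], [0.327, 0.36]],
        J=[[0.37, -0.52], [0.82, -0.54]],
        tau=2.5,
    )


PRESETS = {
    "single_inhibitory": single_inhibitory,
    "homogeneous_ei": homogeneous_ei,
    "biological_ei": biological_ei,
}


def load_preset(name: str, calibrate: bool = True) -> NetworkSpec:
    """Load a preset by name, optionally with calibrated thresholds."""
    try:
        spec = PRESETS[name]()
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
    return calibrated(spec) if calibrate else spec
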