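"""JSON (de)serialization of network and drive configurations.

Schema (all keys required unless noted)::

    {
      "tau_ms": 2.5,
      "populations": [
        {"name": "E", "size": 1691, "kind": "dynamic",
         "sigma_noise": 10.0,          # input units
         "theta": 12.3,                # input units; null if uncalibrated
         "target_m": 0.045},           # optional calibration target
        {"name": "X", "size": 8192, "kind": "clamped",
         "m_clamped": 0.25}
      ],
      "connection_probability": [[...], ...],   # p[receiver][sender]
      "synaptic_weight": [[...], ...],          # J[receiver][sender], input units
      "drive": {"h_ext": 1.0, "f_hz": 80.0}     # optional
    }

Round trip ``spec -> JSON -> spec`` is the identity.  ``config_hash`` gives
a short digest of the canonical JSON for reproducibility headers.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from .core import DriveSpec, NetworkSpec, Population

__all__ = [
    "config_hash",
    "drive_from_dict",
    "drive_to_dict",
    "load_config",
    "save_config",
    "spec_from_dict",
    "spec_to_dict",
]


def spec_to_dict(spec: NetworkSpec) -> dict:
    pops = []
    for pop in spec.populations:
        d: dict = {"name": pop.name, "size": pop.size}
        if pop.clamped:
            d["kind"] = "clamped"
            d["m_clamped"] = pop.m_clamped
        else:
            d["kind"] = "dynamic"
            d["sigma_noise"] = pop.sigma_noise
            d["theta"] = pop.theta
            if pop.target_m is not None:
                d["target_m"] = pop.target_m
        pops.append(d)
    return {
        "tau_ms": spec.tau,
        "populations": pops,
        "connection_probability": spec.p.tolist(),
        "synaptic_weight": spec.J.tolist(),
    }


def spec_from_dict(d: dict) -> NetworkSpec:
    pops = []
    for pd in d["populations"]:
        if pd.get("kind", "dynamic") == "clamped":
            pops.append(
                Population(pd["name"], int(pd["size"]), m_clamped=pd["m_clamped"])
            )
        else:
            pops.append(
                Population(
                    pd["name"],
                    int(pd["size"]),
                    sigma_noise=float(pd.get("sigma_noise", 0.0)),
                    theta=pd.get("theta"),
                    target_m=pd.get("target_m"),
                )
            )
    return NetworkSpec(
        populations=tuple(pops),
        p=np.array(d["connection_probability"], dtype=float),
        J=np.array(d["synaptic_weight"], dtype=float),
        tau=float(d["tau_ms"]),
    )


def drive_to_dict(drive: DriveSpec) -> dict:
    return {"h_ext": drive.h_ext, "f_hz": drive.f}


def drive_from_dict(d: dict) -> DriveSpec:
    return DriveSpec(h_ext=float(d.get("h_ext", 0.0)), f=float(d.get("f_hz", 0.0)))


def save_config(
    spec: NetworkSpec, path: str | Path, drive: DriveSpec | None = None
) -> None:
    d = spec_to_dict(spec)
    if drive is not None:
        d["drive"] = drive_to_dict(drive)
    Path(path).write_text(json.dumps(d, indent=2) + "\n")


def load_config(path: str | Path) -> tuple[NetworkSpec, DriveSpec | None]:
    d = json.loads(Path(path).read_text())
    drive = drive_from_dict(d["drive"]) if "drive" in d else None
    return spec_from_dict(d), drive


def config_hash(spec: NetworkSpec) -> str:
    """Short stable digest of the canonical configuration JSON."""
    payload = json.dumps(spec_to_dict(spec), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]
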