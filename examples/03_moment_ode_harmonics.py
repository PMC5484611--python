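"""Full moment-ODE integration and its Fourier harmonics.

Integrates the nonlinear mean-field equations for the driven EI network,
extracts harmonics 0-2 of the cyclostationary solution and compares the
first harmonic with the closed-form linear response.
"""

import numpy as np

import oscibin as ob
from oscibin.core import DriveSpec

spec = ob.load_preset("biological_ei")
st = ob.solve_stationary(spec)
drive = DriveSpec(h_ext=1.0, f=80.0)

traj = ob.integrate_moments(spec, drive)
hs = ob.extract_harmonics(traj)

print(f"drive: h_ext = {drive.h_ext}, f = {drive.f} Hz")
for k in hs.orders:
    print(f"harmonic {k}: |m| components =",
          np.round(np.abs(hs.mean_coeffs[k]), 5))
ratio = hs.mean_amplitude(2) / hs.mean_amplitude(1)
print("second/first harmonic ratio:", np.round(ratio, 3),
      " -> the response is dominated by the linear part")

m1 = ob.mean_response(drive.omega, st, drive.h_ext)
rel = np.abs(hs.mean_amplitude(1) - np.abs(m1)) / np.abs(m1)
print("relative deviation of |X1| from linear response:", np.round(rel, 4),
      " (the small residual is the sigma-modulation the analytics neglect)")
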