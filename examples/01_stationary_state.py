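"""Self-consistent stationary state of the cortically parameterized EI network.

Calibrates thresholds to the target rates (18 Hz excitatory, 108 Hz
inhibitory), solves the coupled mean/covariance fixed point and prints the
quantities that characterize the balanced state.
"""

import numpy as np

import oscibin as ob

spec = ob.load_preset("biological_ei")
st = ob.solve_stationary(spec)

print("population means m:", np.round(st.m, 4), "(occupation probabilities)")
print("firing rates nu = m/tau:", np.round(st.rates_hz, 1), "Hz")
print("input mean mu:", np.round(st.mu, 3), "and width sigma:", np.round(st.sigma, 3))
print("network-generated input SD:", np.round(st.sigma_independent, 3),
      " <- fluctuations the recurrent network itself produces")
print("pairwise covariances c:\n", st.c,
      "\n  (O(1/N): inhibition suppresses shared fluctuations)")
print("effective-connectivity eigenvalues:", np.round(st.lam, 3),
      " -> stable" if st.stable else " -> UNSTABLE")
fres = ob.resonance_frequencies(st)
print("resonance of the mean activities at", np.round(fres, 1),
      "Hz (from the imaginary part of the eigenvalue pair)")
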