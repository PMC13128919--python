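"""Real-time TDHF absorption spectrum of H2.

Excites the converged ground state with a weak Gaussian field pulse,
propagates the density matrix for 500 a.u. (12.1 fs), Fourier-transforms
the induced dipole and applies the empirical 1.335 rescaling.
"""

import numpy as np

from lobehf import (PropagationConfig, PulseSpec, ScreeningConfig, propagate,
                    rescale_spectrum, scf_solve, spectrum_from_trace)
from lobehf.fixtures import make_named_small

state = scf_solve(make_named_small("H2"),
                  screening_cfg=ScreeningConfig.spectra_defaults())
cfg = PropagationConfig()  # 2000 steps x 0.25 a.u.
trace = propagate(state, PulseSpec(polarization=[0, 0, 1.0]), cfg)
spec = spectrum_from_trace(trace, cfg)
peak_raw = spec.energies[int(np.argmax(spec.intensities))]
rescaled = rescale_spectrum(spec)
peak = rescaled.energies[int(np.argmax(rescaled.intensities))]

print(f"Tr(PS) drift over the run : {trace.trace_drift:.2e}")
print(f"strongest transition      : {peak_raw:.2f} eV (raw TDHF)")
print(f"rescaled by 1.335         : {peak:.2f} eV")
print("\nThe raw peak is the minimal-basis TDHF sigma->sigma* excitation;")
print("the rescaling maps systematically overestimated TDHF energies onto")
print("the experimental scale.")
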