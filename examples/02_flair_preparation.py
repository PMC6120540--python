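"""Simulate the magnetization preparation: T2-prep, inversion, CSF nulling.

Runs the Bloch/EPG chain of one repetition to steady state for CSF and
average brain tissue, then compares the off-resonance robustness of the
2- and 4-refocusing-pulse T2-prep variants at low transmit amplitude.
"""

import numpy as np

from dscflair import BRAIN, CSF, steady_state, t2prep

for tissue in (CSF, BRAIN):
    ss = steady_state(tissue, b1_scale=1.0, b0_off=0.0, tol=0.01)
    print(f"{tissue.name:5s}: steady state after {ss.n_periods_to_converge} "
          f"periods, Mz entering readout = {float(ss.mz_at_readout):+.4f}")
# CSF should be near zero (nulled by the inversion delay); brain tissue
# should be substantially recovered, carrying the image signal.

b0 = np.linspace(-300, 300, 121)
for n in (2, 4):
    mz = t2prep(n, 0.1, CSF, b1_scale=0.4, b0_off=b0)
    tv = np.sum(np.abs(np.diff(mz)))
    print(f"{n}-pulse T2-prep, CSF at 40% B1: Mz total variation over "
          f"+/-300 Hz = {tv:.1f}")
# The 2-pulse module oscillates far more with off-resonance: this is the
# mechanism behind the fringe-like CSF artefacts it produces in images.
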