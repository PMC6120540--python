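"""Build the FLAIR readout train and compute its ideal target signal.

The target is the echo train the sequence would produce with a perfectly
uniform transmitter for the reference brain tissue (T1 = 1.5 s,
T2 = 50 ms): it is the behaviour every voxel should be driven toward.
"""

import numpy as np

from dscflair import build_base_train, channel_powers, target_signal, PowerModel

train = build_base_train()  # 192 pulses, ramp to a constant 50 deg, 3 ms spacing
T = target_signal(train, T1ref=1.5, T2ref=0.05)

print(f"train: {train.n_pulses} pulses, {train.n_echoes} echoes, "
      f"TR {train.TR} s, TI {train.TI*1e3:.0f} ms")
print(f"flip angles (deg): excitation {train.flips_deg[0]:.0f}, "
      f"ramp {np.round(train.flips_deg[1:6], 1)} ... constant "
      f"{train.flips_deg[-1]:.0f}")
print(f"target signal: echo 1 = {T[0]:.3f}, centre echo "
      f"({train.center_echo_index}) = {T[train.center_echo_index-1]:.4f}, "
      f"last = {T[-1]:.4f}  (units of M0)")

rep = channel_powers(np.ones((train.n_pulses, 8)), train, PowerModel())
print(f"quadrature drive power: max avg {rep.max_avg:.3f} W/channel "
      f"(limit {rep.P_avg}), max peak {rep.max_peak:.1f} W (limit {rep.P_peak})")
# The centre-echo target (~0.05 M0) is what the shim optimization tries to
# realize uniformly over the brain despite B1+ inhomogeneity.
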