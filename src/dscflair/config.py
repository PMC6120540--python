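"""YAML configuration for sequence, power and optimization parameters.

Schema (all keys optional; defaults are the modelled protocol):

.. code-block:: yaml

    sequence:
      n_pulses: 192            # pulses in the echo train (incl. excitation)
      const_angle: 50.0        # constant refocusing flip, degrees
      ramp_length: 13          # pulses in the initial flip-angle ramp
      ramp_start_angle: 140.0  # first refocusing flip, degrees
      echo_spacing_ms: 3.0
      TR_s: 8.0
      TI_ms: 2250.0
      center_echo_index: 100   # 1-based echo at the centre of k-space
      pulse_duration_ms: 0.8
    power:
      A_W_per_uT2: 0.35
      P_avg_W: 1.0
      P_peak_W: 85.0
      mp_power_offset_W: 0.34  # 0.15 for the 2-pulse T2-prep
    optimization:
      individual: 13           # individually shimmed leading pulses
      blocks: [60, 60, 59]     # block-shimmed remainder (N_s = 13 + 3)
      T1ref_s: 1.5
      T2ref_s: 0.05
      weight_floor: 0.0
      init_amplitude: 0.6
      maxiter: 120
      max_opt_voxels: 250
      K_opt: 48
      shim_excitation: true
"""

from __future__ import annotations

from dataclasses import dataclass

import yaml

from .sequence import PowerModel, PulseTrain, build_base_train
from .shim import DSCConfig

__all__ = ["load_config", "RunConfig"]


@dataclass
class RunConfig:
    train: PulseTrain
    power: PowerModel
    dsc: DSCConfig


def _train_from_dict(d: dict) -> PulseTrain:
    return build_base_train(
        n_pulses=int(d.get("n_pulses", 192)),
        const_angle=float(d.get("const_angle", 50.0)),
        ramp_length=int(d.get("ramp_length", 13)),
        echo_spacing=float(d.get("echo_spacing_ms", 3.0)) * 1e-3,
        TR=float(d.get("TR_s", 8.0)),
        TI=float(d.get("TI_ms", 2250.0)) * 1e-3,
        ramp_start_angle=float(d.get("ramp_start_angle", 140.0)),
        pulse_duration=float(d.get("pulse_duration_ms", 0.8)) * 1e-3,
        center_echo_index=int(d.get("center_echo_index", 100)),
    )


def load_config(path: str = None) -> RunConfig:
    """Load a YAML run configuration (or the protocol defaults)."""
    raw = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    seq = raw.get("sequence", {})
    pw = raw.get("power", {})
    op = raw.get("optimization", {})
    train = _train_from_dict(seq)
    power = PowerModel(
        A=float(pw.get("A_W_per_uT2", 0.35)),
        P_avg=float(pw.get("P_avg_W", 1.0)),
        P_peak=float(pw.get("P_peak_W", 85.0)),
        mp_power_offset=float(pw.get("mp_power_offset_W", 0.34)),
    )
    dsc = DSCConfig(
        individual=int(op.get("individual", 13)),
        blocks=tuple(op.get("blocks", (60, 60, 59))),
        T1ref=float(op.get("T1ref_s", 1.5)),
        T2ref=float(op.get("T2ref_s", 0.05)),
        weight_floor=float(op.get("weight_floor", 0.0)),
        init_amplitude=float(op.get("init_amplitude", 0.6)),
        maxiter=int(op.get("maxiter", 120)),
        max_opt_voxels=int(op.get("max_opt_voxels", 250)),
        K_opt=int(op.get("K_opt", 48)),
        shim_excitation=bool(op.get("shim_excitation", True)),
    )
    return RunConfig(train=train, power=power, dsc=dsc)
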