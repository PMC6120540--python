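"""FLAIR base sequence: echo train, pulse amplitudes and the RF power model.

The base sequence is a 3D fast-spin-echo readout: one excitation pulse
followed by a long train of refocusing pulses whose flip angles ramp down
quickly to a constant value (50 degrees for the protocol modelled here).
Low constant refocusing angles keep RF power manageable and allow very long
echo trains, at the price of making the signal sensitive to transmit (B1+)
inhomogeneity -- which is what dynamic RF shimming then corrects.

All RF power bookkeeping used by the shim optimization constraints lives
here: for a pulse with peak amplitude ``b`` (uT) driven through channel
weight ``w``, the instantaneous per-channel power is ``|w b|^2 A`` and the
time-averaged power over the repetition time is
``sum_j |w_jk b_j|^2 t_RMS,j A / TR``, with ``A`` the coil/amplifier power
conversion factor in W/uT^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GAMMA_UT",
    "RFPulse",
    "PulseTrain",
    "PowerModel",
    "PowerReport",
    "build_base_train",
    "peak_b1_from_flip",
    "channel_powers",
]

#: Proton gyromagnetic ratio in rad s^-1 uT^-1 (2*pi*42.577 Hz/uT).
GAMMA_UT = 2.0 * np.pi * 42.577


def peak_b1_from_flip(flip_deg: float, duration_s: float) -> float:
    """Peak B1 amplitude (uT) of a hard pulse with the given flip and duration.

    For a rectangular pulse the flip angle is ``gamma * b * duration``, so
    ``b = flip_rad / (gamma * duration)``.

    Parameters
    ----------
    flip_deg : flip angle in degrees.
    duration_s : pulse duration in seconds; must be positive.
    """
    if duration_s <= 0:
        raise ValueError(f"pulse duration must be positive, got {duration_s}")
    return float(np.deg2rad(abs(flip_deg)) / (GAMMA_UT * duration_s))


@dataclass(frozen=True)
class RFPulse:
    """A single RF pulse of the readout train.

    ``peak_b1`` is the nominal peak amplitude in uT (the quantity the power
    constraints act on) and ``t_rms = integral p^2(t) dt / b^2`` relates pulse
    shape to deposited power; for a hard (rect) pulse ``t_rms == duration``.
    """

    flip: float  # degrees
    phase: float  # degrees
    duration: float  # seconds
    shape: str = "hard"  # {"hard", "sech"}
    peak_b1: float = None  # uT; computed for hard pulses when omitted
    t_rms: float = None  # seconds

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("RFPulse duration must be positive")
        if self.shape not in ("hard", "sech"):
            raise ValueError(f"unknown pulse shape {self.shape!r}")
        if self.peak_b1 is None:
            if self.shape != "hard":
                raise ValueError("peak_b1 must be given for non-hard pulses")
            object.__setattr__(
                self, "peak_b1", peak_b1_from_flip(self.flip, self.duration)
            )
        if self.t_rms is None:
            # hard pulse: p(t) = b over the full duration
            object.__setattr__(
                self, "t_rms", self.duration if self.shape == "hard" else self.duration
            )
        if self.peak_b1 < 0:
            raise ValueError("peak_b1 must be non-negative")
        if self.t_rms > self.duration + 1e-12:
            raise ValueError("t_rms cannot exceed the pulse duration")


@dataclass(frozen=True)
class PulseTrain:
    """Ordered readout pulses plus sequence timings.

    Pulse 0 is the excitation, pulses 1..N_p-1 are refocusing pulses; each
    refocusing interval produces one echo, so ``n_echoes = n_pulses - 1``.
    ``center_echo_index`` is the 1-based echo number acquired at the centre of
    k-space (echo 100 for the modelled protocol).
    """

    pulses: tuple
    echo_spacing: float  # seconds
    TR: float  # seconds
    TI: float  # seconds
    center_echo_index: int = 100

    def __post_init__(self):
        if self.echo_spacing <= 0:
            raise ValueError("echo_spacing must be positive")
        if not (0 < self.TI < self.TR):
            raise ValueError("require 0 < TI < TR")
        if not (1 <= self.center_echo_index <= len(self.pulses) - 1):
            raise ValueError("center_echo_index must lie within the echo train")

    @property
    def n_pulses(self) -> int:
        return len(self.pulses)

    @property
    def n_echoes(self) -> int:
        return len(self.pulses) - 1

    @property
    def flips_deg(self) -> np.ndarray:
        return np.array([p.flip for p in self.pulses])

    @property
    def phases_deg(self) -> np.ndarray:
        return np.array([p.phase for p in self.pulses])

    @property
    def peak_b1s(self) -> np.ndarray:
        """Nominal peak amplitude b_j of every pulse, in uT."""
        return np.array([p.peak_b1 for p in self.pulses])

    @property
    def t_rms(self) -> np.ndarray:
        return np.array([p.t_rms for p in self.pulses])

    @property
    def readout_duration(self) -> float:
        """Time from excitation to the last echo, in seconds."""
        return self.n_echoes * self.echo_spacing


@dataclass(frozen=True)
class PowerModel:
    """Per-channel RF power limits and the power conversion factor.

    ``mp_power_offset`` is the average-power contribution of the magnetization
    preparation module (T2-prep + inversion), which is transmitted in
    quadrature and therefore eats into the average-power budget available to
    the readout train on every channel.
    """

    A: float = 0.35  # W/uT^2
    P_avg: float = 1.0  # W per channel
    P_peak: float = 85.0  # W per channel
    mp_power_offset: float = 0.34  # W per channel (4-pulse T2-prep default)

    def __post_init__(self):
        if self.A <= 0:
            raise ValueError("power conversion factor A must be positive")
        if not (0 <= self.mp_power_offset < self.P_avg):
            raise ValueError("mp_power_offset must lie in [0, P_avg)")
        if self.P_peak < self.P_avg:
            raise ValueError("P_peak must be >= P_avg")


@dataclass
class PowerReport:
    """Evaluated per-channel powers against the limits."""

    avg_per_channel: np.ndarray  # (N_c,) W, including mp offset if requested
    peak: np.ndarray  # (N_p, N_c) W
    P_avg: float
    P_peak: float
    includes_prep_offset: bool = True
    margin: float = 1e-9

    @property
    def max_avg(self) -> float:
        return float(np.max(self.avg_per_channel))

    @property
    def max_peak(self) -> float:
        return float(np.max(self.peak))

    @property
    def avg_ok(self) -> bool:
        return bool(self.max_avg <= self.P_avg * (1 + self.margin))

    @property
    def peak_ok(self) -> bool:
        return bool(self.max_peak <= self.P_peak * (1 + self.margin))

    @property
    def feasible(self) -> bool:
        return self.avg_ok and self.peak_ok


def build_base_train(
    n_pulses: int = 192,
    const_angle: float = 50.0,
    ramp_length: int = 13,
    echo_spacing: float = 3e-3,
    TR: float = 8.0,
    TI: float = 2.25,
    *,
    ramp_start_angle: float = 140.0,
    pulse_duration: float = 0.8e-3,
    excitation_flip: float = 90.0,
    center_echo_index: int = 100,
) -> PulseTrain:
    """Build the variable-flip-angle FSE readout train.

    The excitation is a 90 degree pulse with its phase 90 degrees offset from
    the refocusing axis (CPMG convention: refocusing about x / phase 0,
    excitation about y / phase 90).  Refocusing flips decrease geometrically
    from ``ramp_start_angle`` down to ``const_angle`` over the first
    ``ramp_length`` refocusing pulses and stay constant thereafter, so for the
    default protocol pulses 14..192 (1-based) are all at 50 degrees.

    All readout pulses are modelled as hard pulses of 0.8 ms duration.
    """
    if n_pulses <= 1:
        raise ValueError("n_pulses must exceed 1 (excitation + refocusing)")
    if not (0 < const_angle <= 180):
        raise ValueError("const_angle must lie in (0, 180]")
    if not (0 <= ramp_length <= n_pulses - 1):
        raise ValueError("ramp_length must lie in [0, n_pulses - 1]")
    if ramp_length > 0 and ramp_start_angle < const_angle:
        raise ValueError("ramp_start_angle must be >= const_angle")

    pulses = [
        RFPulse(flip=excitation_flip, phase=90.0, duration=pulse_duration)
    ]
    n_refoc = n_pulses - 1
    flips = np.full(n_refoc, const_angle)
    if ramp_length > 0:
        # geometric descent reaching const_angle at refocusing pulse
        # `ramp_length` (i.e. train pulse ramp_length + 1, 1-based)
        r = np.arange(1, ramp_length + 1)
        flips[:ramp_length] = ramp_start_angle * (
            const_angle / ramp_start_angle
        ) ** (r / ramp_length)
    for f in flips:
        pulses.append(RFPulse(flip=float(f), phase=0.0, duration=pulse_duration))
    return PulseTrain(
        pulses=tuple(pulses),
        echo_spacing=echo_spacing,
        TR=TR,
        TI=TI,
        center_echo_index=min(center_echo_index, n_pulses - 1),
    )


def channel_powers(
    w: np.ndarray,
    train: PulseTrain,
    pm: PowerModel,
    *,
    include_prep_offset: bool = True,
) -> PowerReport:
    """Evaluate per-channel average and per-pulse peak RF power for a shim set.

    Parameters
    ----------
    w : complex array (N_p, N_c)
        Per-pulse, per-channel shim weights (one row per pulse of ``train``).
    include_prep_offset : bool
        Add the preparation-module average power contribution to each channel.

    Returns
    -------
    PowerReport with
    ``avg_k = sum_j |w_jk b_j|^2 t_RMS,j A / TR (+ offset)`` and
    ``peak_jk = |w_jk b_j|^2 A``.
    """
    w = np.asarray(w)
    if w.ndim != 2 or w.shape[0] != train.n_pulses:
        raise ValueError(
            f"shim matrix shape {w.shape} does not match train with "
            f"{train.n_pulses} pulses"
        )
    b = train.peak_b1s[:, None]  # (N_p, 1)
    t_rms = train.t_rms[:, None]
    amp2 = np.abs(w) ** 2 * b**2  # |w_jk b_j|^2
    peak = amp2 * pm.A
    avg = (amp2 * t_rms).sum(axis=0) * pm.A / train.TR
    if include_prep_offset:
        avg = avg + pm.mp_power_offset
    return PowerReport(
        avg_per_channel=avg,
        peak=peak,
        P_avg=pm.P_avg,
        P_peak=pm.P_peak,
        includes_prep_offset=include_prep_offset,
    )
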