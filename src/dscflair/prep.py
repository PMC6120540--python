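"""Bloch simulation of the FLAIR magnetization preparation.

The sequence prepares magnetization before the FSE readout with a T2-prep
module (hard 90 degree tip-down, 2 or 4 adiabatic hyperbolic-secant
refocusing pulses, hard 90 degree tip-up) followed by an adiabatic
inversion and an inversion delay TI chosen to null CSF.  T2-prep converts
the large T2 difference between CSF (T2 ~ 2 s) and brain tissue
(T2 ~ 50 ms) into a longitudinal difference: brain magnetization is heavily
T2-crushed before inversion, so it starts its recovery closer to zero and
has recovered much further than CSF by the time the readout begins.

Adiabatic pulses only behave ideally above a B1 threshold, so the whole
preparation is simulated with single-isochromat Bloch integration over a
grid of relative transmit amplitude (b1_scale) and off-resonance (b0_off),
chained with the EPG readout of :mod:`dscflair.epg` over repeated TR
periods until a steady state is reached.  Perfect spoiling of transverse
magnetization between the preparation and readout modules is assumed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .epg import _run_train
from .sequence import GAMMA_UT, PulseTrain, build_base_train

__all__ = [
    "SechPulse",
    "TissueParams",
    "PrepResult",
    "PeriodResult",
    "PrepConfig",
    "CSF",
    "BRAIN",
    "sech_waveform",
    "bloch_run",
    "t2prep",
    "adiabatic_inversion",
    "flair_period",
    "steady_state",
    "prep_grid",
]


@dataclass(frozen=True)
class SechPulse:
    """Amplitude/frequency-modulated hyperbolic-secant pulse.

    ``truncation`` is beta * duration / 2; the default 5.3 puts the edge
    amplitude at about 1% of the peak, a standard full-passage choice.
    """

    duration: float  # s
    peak_b1: float = 15.0  # uT
    max_freq_mod: float = 706.0  # Hz
    truncation: float = 5.3
    dt: float = 5e-6  # s, integration step

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.max_freq_mod < 0:
            raise ValueError("max_freq_mod must be non-negative")
        if self.dt > self.duration / 100:
            raise ValueError(
                "integration step too coarse: require dt <= duration/100"
            )

    @property
    def beta(self) -> float:
        return 2.0 * self.truncation / self.duration


#: Refocusing pulse of the T2-prep module (duration 9 ms, 15 uT, 706 Hz).
T2PREP_REFOCUS = SechPulse(duration=9e-3, peak_b1=15.0, max_freq_mod=706.0)
#: Inversion pulse (duration 17.1 ms, 15 uT, 700 Hz).
INVERSION_PULSE = SechPulse(duration=17.1e-3, peak_b1=15.0, max_freq_mod=700.0)


@dataclass(frozen=True)
class TissueParams:
    T1: float  # s
    T2: float  # s
    name: str = ""

    def __post_init__(self):
        if not (self.T1 >= self.T2 > 0):
            raise ValueError("require T1 >= T2 > 0")


CSF = TissueParams(T1=4.3, T2=2.0, name="CSF")
BRAIN = TissueParams(T1=1.5, T2=0.05, name="brain")


def sech_waveform(p: SechPulse):
    """Sampled amplitude (uT) and frequency offset (Hz) of a sech pulse.

    ``b1(t) = peak_b1 * sech(beta t)`` and ``f(t) = -max_freq_mod *
    tanh(beta t)`` for t in [-duration/2, +duration/2]; the amplitude is an
    even and the frequency an odd function of t.
    """
    n = max(int(np.ceil(p.duration / p.dt)), 100)
    t = (np.arange(n) + 0.5) / n * p.duration - p.duration / 2
    amp = p.peak_b1 / np.cosh(p.beta * t)
    freq = -p.max_freq_mod * np.tanh(p.beta * t)
    return t, amp, freq


def _rodrigues_apply(M, nx, ny, nz, angle):
    """Rotate vectors M (..., 3) by ``angle`` about unit axes (nx, ny, nz)."""
    c = np.cos(angle)
    s = np.sin(angle)
    C = 1.0 - c
    mx, my, mz = M[..., 0], M[..., 1], M[..., 2]
    dot = nx * mx + ny * my + nz * mz
    cx = ny * mz - nz * my
    cy = nz * mx - nx * mz
    cz = nx * my - ny * mx
    out = np.empty_like(M)
    out[..., 0] = mx * c + cx * s + nx * dot * C
    out[..., 1] = my * c + cy * s + ny * dot * C
    out[..., 2] = mz * c + cz * s + nz * dot * C
    return out


def bloch_run(
    waveform,
    b1_scale,
    b0_off,
    tissue: TissueParams,
    m_in,
    *,
    relaxation: bool = True,
) -> np.ndarray:
    """Integrate the Bloch equations through a sampled RF waveform.

    The frequency modulation is realised as a phase modulation in the fixed
    rotating frame (phase = cumulative integral of the frequency offset), so
    the simulation is exact up to the piecewise-constant step.  ``b1_scale``
    and ``b0_off`` may be scalars or arrays broadcast against ``m_in``
    (..., 3); relaxation is interleaved per step.
    """
    t, amp, freq = waveform
    dt = float(t[1] - t[0])
    b1_scale = np.asarray(b1_scale, dtype=float)
    b0_off = np.asarray(b0_off, dtype=float)
    m_in = np.asarray(m_in, dtype=float)
    shape = np.broadcast_shapes(m_in.shape[:-1], b1_scale.shape, b0_off.shape)
    M = np.empty(shape + (3,))
    M[:] = m_in
    # RF phase from the frequency modulation (midpoint samples)
    phase = 2 * np.pi * (np.cumsum(freq) - freq / 2) * dt
    wz = 2 * np.pi * b0_off
    if relaxation:
        e1 = np.exp(-dt / tissue.T1)
        e2 = np.exp(-dt / tissue.T2)
    for i in range(len(t)):
        w1 = GAMMA_UT * b1_scale * amp[i]  # rad/s
        bx = w1 * np.cos(phase[i])
        by = w1 * np.sin(phase[i])
        wmag = np.sqrt(bx**2 + by**2 + wz**2)
        safe = np.where(wmag > 0, wmag, 1.0)
        M = _rodrigues_apply(M, bx / safe, by / safe, wz / safe, wmag * dt)
        if relaxation:
            M[..., 0] *= e2
            M[..., 1] *= e2
            M[..., 2] = M[..., 2] * e1 + (1 - e1)
    return M


def _free_precession(M, duration, b0_off, tissue, relaxation=True):
    """Relaxation + off-resonance precession with no RF."""
    if duration <= 0:
        return M
    b0_off = np.asarray(b0_off, dtype=float)
    ang = 2 * np.pi * b0_off * duration
    mxy = (M[..., 0] + 1j * M[..., 1]) * np.exp(1j * ang)
    out = M.copy()
    if relaxation:
        mxy = mxy * np.exp(-duration / tissue.T2)
        out[..., 2] = 1 + (M[..., 2] - 1) * np.exp(-duration / tissue.T1)
    out[..., 0], out[..., 1] = mxy.real, mxy.imag
    return out


def _hard_rotation(M, flip_deg, phase_deg, b1_scale):
    """Instantaneous hard pulse; the achieved flip scales with local B1."""
    flip = np.deg2rad(flip_deg) * np.asarray(b1_scale, dtype=float)
    phi = np.deg2rad(phase_deg)
    return _rodrigues_apply(
        M, np.cos(phi), np.sin(phi), 0.0 * flip, flip
    )


def t2prep(
    n_refoc: int,
    total_duration: float,
    tissue: TissueParams,
    b1_scale=1.0,
    b0_off=0.0,
    *,
    mz_in=1.0,
    pulse: SechPulse = T2PREP_REFOCUS,
    relaxation: bool = True,
    ideal_pulses: bool = False,
) -> np.ndarray:
    """Longitudinal magnetization after the T2-preparation module.

    Simulates hard 90 tip-down (about +y), ``n_refoc`` evenly spaced
    adiabatic refocusing pulses (CPMG spacing tau/2n, tau/n, ..., tau/2n),
    and a hard -90 tip-up; transverse magnetization remaining afterwards is
    assumed perfectly spoiled, so only Mz is returned.

    With ``ideal_pulses`` the refocusing pulses are replaced by instantaneous
    perfect 180s (and the 90s are exact), giving the closed-form limit
    ``Mz_out = Mz_in * exp(-total_duration / T2)``.
    """
    if n_refoc not in (2, 4):
        raise ValueError("n_refoc must be 2 or 4")
    if total_duration <= n_refoc * pulse.duration:
        raise ValueError("total_duration must exceed the refocusing pulses")
    b1_scale = np.asarray(b1_scale, dtype=float)
    b0_off = np.asarray(b0_off, dtype=float)
    shape = np.broadcast_shapes(b1_scale.shape, b0_off.shape,
                                np.asarray(mz_in, dtype=float).shape)
    M = np.zeros(shape + (3,))
    M[..., 2] = mz_in
    tau = total_duration
    gap_half = tau / (2 * n_refoc)
    gap_full = tau / n_refoc
    wf = sech_waveform(pulse)
    # pulse "centres" follow the CPMG spacing; the adiabatic pulse duration
    # is taken out of the adjacent free intervals symmetrically (ideal
    # instantaneous pulses consume no time)
    dur = 0.0 if ideal_pulses else pulse.duration
    scl = 1.0 if ideal_pulses else b1_scale
    M = _hard_rotation(M, 90.0, 90.0, scl)  # tip-down about +y: z -> x
    for i in range(n_refoc):
        gap = gap_half if i == 0 else gap_full
        free = gap - dur / 2 - (0 if i == 0 else dur / 2)
        M = _free_precession(M, max(free, 0.0), b0_off, tissue, relaxation)
        if ideal_pulses:
            M = _hard_rotation(M, 180.0, 0.0, 1.0)
        else:
            M = bloch_run(wf, b1_scale, b0_off, tissue, M, relaxation=relaxation)
    M = _free_precession(
        M, max(gap_half - dur / 2, 0.0), b0_off, tissue, relaxation
    )
    M = _hard_rotation(M, -90.0, 90.0, scl)  # tip-up: x -> z
    return M[..., 2]


def adiabatic_inversion(
    b1_scale=1.0,
    b0_off=0.0,
    tissue: TissueParams = CSF,
    mz_in=1.0,
    *,
    pulse: SechPulse = INVERSION_PULSE,
    relaxation: bool = True,
) -> np.ndarray:
    """Mz after the adiabatic sech inversion (transverse spoiled)."""
    b1_scale = np.asarray(b1_scale, dtype=float)
    b0_off = np.asarray(b0_off, dtype=float)
    shape = np.broadcast_shapes(b1_scale.shape, b0_off.shape,
                                np.asarray(mz_in, dtype=float).shape)
    M = np.zeros(shape + (3,))
    M[..., 2] = mz_in
    M = bloch_run(sech_waveform(pulse), b1_scale, b0_off, tissue, M,
                  relaxation=relaxation)
    return M[..., 2]


@dataclass(frozen=True)
class PrepConfig:
    """Timing and structure of the preparation module within one TR."""

    n_refoc: int = 4
    t2prep_duration: float = 0.1  # s (vendor value unpublished)
    refocus_pulse: SechPulse = T2PREP_REFOCUS
    inversion_pulse: SechPulse = INVERSION_PULSE
    ideal_pulses: bool = False


@dataclass
class PeriodResult:
    mz_pre_inversion: np.ndarray
    mz_at_readout: np.ndarray
    mz_end: np.ndarray
    center_echo: np.ndarray


@dataclass
class PrepResult:
    """Steady-state longitudinal magnetization entering the readout.

    ``n_periods_to_converge`` counts the periods after which one additional
    period changes the pre-inversion Mz by less than the tolerance.
    """

    mz_at_readout: np.ndarray
    n_periods_to_converge: int
    mz_pre_inversion: np.ndarray = None
    center_echo: np.ndarray = None


def flair_period(
    tissue: TissueParams,
    b1_scale=1.0,
    b0_off=0.0,
    mz_in=1.0,
    *,
    train: PulseTrain = None,
    prep: PrepConfig = PrepConfig(),
    relaxation: bool = True,
    include_readout: bool = True,
) -> PeriodResult:
    """One full FLAIR period: T2-prep, inversion, TI recovery, FSE readout,
    and free recovery to the end of TR.

    TI is measured from the centre of the inversion pulse to the excitation
    pulse.  The readout consumes transverse magnetization (spoiled at the
    end) while the longitudinal state evolves under the EPG Z-state
    trajectory; its duration is ``n_echoes * echo_spacing``.
    """
    if train is None:
        train = build_base_train()
    b1_scale = np.asarray(b1_scale, dtype=float)
    b0_off = np.asarray(b0_off, dtype=float)
    shape = np.broadcast_shapes(b1_scale.shape, b0_off.shape,
                                np.asarray(mz_in, dtype=float).shape)
    inv_dur = prep.inversion_pulse.duration
    readout_dur = train.readout_duration
    rest = train.TR - prep.t2prep_duration - inv_dur / 2 - train.TI - readout_dur
    if rest < 0:
        raise ValueError("TI + readout duration exceed TR")

    mz_pre = t2prep(
        prep.n_refoc, prep.t2prep_duration, tissue, b1_scale, b0_off,
        mz_in=mz_in, pulse=prep.refocus_pulse, relaxation=relaxation,
        ideal_pulses=prep.ideal_pulses,
    )
    if prep.ideal_pulses:
        mz_inv = -np.broadcast_to(mz_pre, shape)
    else:
        mz_inv = adiabatic_inversion(
            b1_scale, b0_off, tissue, mz_pre,
            pulse=prep.inversion_pulse, relaxation=relaxation,
        )
    t_rec = train.TI - inv_dur / 2
    if relaxation:
        mz_rd = 1 + (mz_inv - 1) * np.exp(-t_rec / tissue.T1)
    else:
        mz_rd = mz_inv
    # EPG readout: flips scale with the local B1; B0 is irrelevant for the
    # short broadband readout pulses
    if include_readout:
        flat_b1 = np.broadcast_to(b1_scale, shape).ravel()
        flat_z0 = np.broadcast_to(mz_rd, shape).ravel()
        T1 = tissue.T1 if relaxation else 1e12
        T2 = tissue.T2 if relaxation else 1e12
        flips = np.deg2rad(train.flips_deg)[:, None] * flat_b1[None, :]
        phases = np.broadcast_to(
            np.deg2rad(train.phases_deg)[:, None], flips.shape
        )
        echoes, z_end, _ = _run_train(
            flips, phases, train.echo_spacing, T1, T2, z0=flat_z0,
        )
        center = np.abs(echoes[:, train.center_echo_index - 1]).reshape(shape)
        z_end = z_end.reshape(shape)
    else:
        center = np.zeros(shape)
        z_end = np.broadcast_to(mz_rd, shape)
    if relaxation:
        mz_end = 1 + (z_end - 1) * np.exp(-rest / tissue.T1)
    else:
        mz_end = z_end
    return PeriodResult(
        mz_pre_inversion=np.broadcast_to(mz_pre, shape),
        mz_at_readout=np.broadcast_to(mz_rd, shape),
        mz_end=mz_end,
        center_echo=center,
    )


def steady_state(
    tissue: TissueParams,
    b1_scale=1.0,
    b0_off=0.0,
    tol: float = 0.01,
    *,
    train: PulseTrain = None,
    prep: PrepConfig = PrepConfig(),
    max_periods: int = 20,
) -> PrepResult:
    """Cycle FLAIR periods from thermal equilibrium to steady state.

    Convergence is declared when the pre-inversion Mz of one further period
    differs (relatively) by less than ``tol`` from the previous period;
    ``n_periods_to_converge`` is the number of periods needed to reach that
    reproducible state.
    """
    if not (0 < tol <= 0.1):
        raise ValueError("tol must lie in (0, 0.1]")
    mz = np.asarray(1.0 + 0.0 * (np.asarray(b1_scale, float)
                                 * np.asarray(b0_off, float)))
    prev = None
    last = None
    for n in range(1, max_periods + 1):
        res = flair_period(
            tissue, b1_scale, b0_off, mz, train=train, prep=prep
        )
        p = np.asarray(res.mz_pre_inversion, dtype=float)
        if prev is not None:
            denom = np.maximum(np.abs(prev), 1e-9)
            if np.max(np.abs(p - prev) / denom) < tol:
                return PrepResult(
                    mz_at_readout=res.mz_at_readout,
                    n_periods_to_converge=n - 1,
                    mz_pre_inversion=p,
                    center_echo=res.center_echo,
                )
        prev = p
        mz = res.mz_end
        last = res
    raise RuntimeError(
        f"steady state not reached within {max_periods} periods"
    )


def prep_grid(
    tissue: TissueParams,
    b1_scales,
    b0_offs,
    n_refoc: int = 4,
    *,
    train: PulseTrain = None,
    prep: PrepConfig = None,
    tol: float = 0.01,
):
    """Steady-state Mz entering the readout over a (B1 scale, B0 offset) grid.

    Returns ``(mz_at_readout, center_echo)`` matrices of shape
    ``(len(b1_scales), len(b0_offs))``; the centre-echo map is the signal at
    the centre of k-space simulated from the converged preparation state,
    i.e. the quantity imaging actually sees.
    """
    b1_scales = np.atleast_1d(np.asarray(b1_scales, dtype=float))
    b0_offs = np.atleast_1d(np.asarray(b0_offs, dtype=float))
    if b1_scales.size == 0 or b0_offs.size == 0:
        raise ValueError("grids must be non-empty")
    if prep is None:
        prep = PrepConfig(n_refoc=n_refoc)
    B1, B0 = np.meshgrid(b1_scales, b0_offs, indexing="ij")
    res = steady_state(tissue, B1, B0, tol, train=train, prep=prep)
    return np.asarray(res.mz_at_readout), np.asarray(res.center_echo)
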