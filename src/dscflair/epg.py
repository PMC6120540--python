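"""Extended phase graph (EPG) engine for the FSE readout.

The echo train is simulated in the configuration-state basis
``(F+_n, F-_n, Z_n)``: RF pulses mix the three states of each dephasing
order n through the standard rotation matrix, crusher gradients shift the
transverse orders by one, and relaxation scales the states between pulses.
Evaluating the same recursion per voxel with the local complex transmit
scaling ``sum_k w_jk S_k(r)`` gives the spatially resolved (SR-EPG) forward
model ``I = f(w, S, a, T1ref, T2ref)`` whose order-0 transverse magnitude at
each echo time is the predicted echo amplitude.

Static field (B0) inhomogeneity is deliberately not part of the readout
model: the readout pulses are sub-millisecond and therefore broadband
compared to realistic off-resonance, so B0 only matters in the (much longer)
adiabatic preparation pulses handled by :mod:`dscflair.prep`.

The module also provides the adjoint-state gradient of the shim-optimization
cost through the full EPG recursion, and an independent Bloch isochromat
ensemble oracle used to validate the engine.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sequence import PulseTrain

__all__ = [
    "EPGState",
    "SignalPrediction",
    "epg_rf",
    "epg_evolve",
    "epg_shift",
    "simulate_echo_train",
    "forward_model",
    "target_signal",
    "bloch_ensemble_oracle",
    "epg_cost_and_grad",
]


# ---------------------------------------------------------------------------
# single-state operators (reference implementation, unit-test surface)
# ---------------------------------------------------------------------------


@dataclass
class EPGState:
    """EPG configuration state over orders 0..K.

    ``Fminus[n]`` stores the conjugate convention ``conj(F_{-n})`` so that
    ``Fminus[0] == conj(Fplus[0])`` at all times.
    """

    Fplus: np.ndarray
    Fminus: np.ndarray
    Z: np.ndarray
    M0: float = 1.0

    @classmethod
    def equilibrium(cls, K: int, M0: float = 1.0, z0: float = None) -> "EPGState":
        Fp = np.zeros(K + 1, dtype=complex)
        Fm = np.zeros(K + 1, dtype=complex)
        Z = np.zeros(K + 1, dtype=complex)
        Z[0] = M0 if z0 is None else z0
        return cls(Fp, Fm, Z, M0)

    def copy(self) -> "EPGState":
        return EPGState(self.Fplus.copy(), self.Fminus.copy(), self.Z.copy(), self.M0)


def _rf_matrix(alpha_rad, phi_rad):
    """Entries of the EPG RF mixing matrix T(alpha, phi).

    Acts on the column (F+_n, F-_n, Z_n) identically for every order n; each
    entry may be an array (broadcast over voxels).
    """
    c2 = np.cos(alpha_rad / 2) ** 2
    s2 = np.sin(alpha_rad / 2) ** 2
    sa = np.sin(alpha_rad)
    ca = np.cos(alpha_rad)
    ep = np.exp(1j * phi_rad)
    em = np.conj(ep)
    return (
        c2, s2 * ep**2, -1j * ep * sa,
        s2 * em**2, c2, 1j * em * sa,
        -0.5j * em * sa, 0.5j * ep * sa, ca,
    )


def epg_rf(state: EPGState, alpha_deg: float, phi_deg: float) -> EPGState:
    """Apply an RF rotation of flip ``alpha`` about an axis at phase ``phi``."""
    out = state.copy()
    T = _rf_matrix(np.deg2rad(alpha_deg), np.deg2rad(phi_deg))
    Fp, Fm, Z = state.Fplus, state.Fminus, state.Z
    out.Fplus = T[0] * Fp + T[1] * Fm + T[2] * Z
    out.Fminus = T[3] * Fp + T[4] * Fm + T[5] * Z
    out.Z = T[6] * Fp + T[7] * Fm + T[8] * Z
    return out


def epg_evolve(state: EPGState, dt: float, T1: float, T2: float) -> EPGState:
    """Relaxation over ``dt``: F states decay with T2, Z states with T1 and
    the order-0 longitudinal state recovers toward M0."""
    if dt < 0:
        raise ValueError("dt must be non-negative")
    if T1 <= 0 or T2 <= 0:
        raise ValueError("relaxation times must be positive")
    out = state.copy()
    e1 = np.exp(-dt / T1)
    e2 = np.exp(-dt / T2)
    out.Fplus = state.Fplus * e2
    out.Fminus = state.Fminus * e2
    out.Z = state.Z * e1
    out.Z[0] += state.M0 * (1 - e1)
    return out


def epg_shift(state: EPGState) -> EPGState:
    """Crusher gradient: dephase the transverse states by one order."""
    out = state.copy()
    out.Fplus[1:] = state.Fplus[:-1]
    out.Fminus[:-1] = state.Fminus[1:]
    out.Fminus[-1] = 0.0
    out.Fplus[0] = np.conj(out.Fminus[0])
    return out


# ---------------------------------------------------------------------------
# vectorized train kernel
# ---------------------------------------------------------------------------


def _relax(Fp, Fm, Z, e1, e2, M0):
    Fp *= e2
    Fm *= e2
    Z *= e1
    Z[0] += M0 * (1 - e1)


def _shift(Fp, Fm, Z):
    Fp[1:] = Fp[:-1]
    Fm[:-1] = Fm[1:]
    Fm[-1] = 0.0
    Fp[0] = np.conj(Fm[0])


def _apply_rf(Fp, Fm, Z, T):
    nFp = T[0] * Fp + T[1] * Fm + T[2] * Z
    nFm = T[3] * Fp + T[4] * Fm + T[5] * Z
    nZ = T[6] * Fp + T[7] * Fm + T[8] * Z
    return nFp, nFm, nZ


def _run_train(
    flips_rad: np.ndarray,
    phases_rad: np.ndarray,
    echo_spacing: float,
    T1: float,
    T2: float,
    z0: np.ndarray,
    M0: float = 1.0,
    K: int = None,
    checkpoints: bool = False,
):
    """Vectorized EPG recursion over a batch of voxels.

    ``flips_rad``/``phases_rad`` have shape (N_p, V).  Returns complex echoes
    (V, N_p-1), the final order-0 longitudinal magnetization (V,), and, when
    ``checkpoints`` is set, the states recorded immediately before every RF
    pulse (for the adjoint sweep).
    """
    n_pulses, V = flips_rad.shape
    if K is None:
        K = n_pulses
    e1 = np.exp(-echo_spacing / 2 / T1)
    e2 = np.exp(-echo_spacing / 2 / T2)
    Fp = np.zeros((K + 1, V), dtype=complex)
    Fm = np.zeros((K + 1, V), dtype=complex)
    Z = np.zeros((K + 1, V), dtype=complex)
    Z[0] = z0
    echoes = np.zeros((V, n_pulses - 1), dtype=complex)
    saved = [] if checkpoints else None
    for j in range(n_pulses):
        if j > 0:
            _relax(Fp, Fm, Z, e1, e2, M0)
            _shift(Fp, Fm, Z)
        if checkpoints:
            saved.append((Fp.copy(), Fm.copy(), Z.copy()))
        T = _rf_matrix(flips_rad[j], phases_rad[j])
        Fp, Fm, Z = _apply_rf(Fp, Fm, Z, T)
        if j > 0:
            _relax(Fp, Fm, Z, e1, e2, M0)
            _shift(Fp, Fm, Z)
            echoes[:, j - 1] = Fp[0]
    z_end = Z[0].real.copy()
    return echoes, z_end, saved


# ---------------------------------------------------------------------------
# public simulation API
# ---------------------------------------------------------------------------


@dataclass
class SignalPrediction:
    """Predicted echo magnitudes over masked voxels and the spatial target."""

    I: np.ndarray  # (N_voxels, N_echoes), real magnitudes in M0 units
    T: np.ndarray  # (N_echoes,), target (constant over space)

    @property
    def n_voxels(self) -> int:
        return self.I.shape[0]

    @property
    def n_echoes(self) -> int:
        return self.I.shape[1]


def _train_angles(train: PulseTrain, scale: np.ndarray):
    """Effective flips/phases for a (N_p, V) complex per-pulse scaling."""
    flips = np.deg2rad(train.flips_deg)[:, None] * np.abs(scale)
    phases = np.deg2rad(train.phases_deg)[:, None] + np.angle(scale)
    return flips, phases


def simulate_echo_train(
    train: PulseTrain,
    scale,
    T1: float,
    T2: float,
    z0: float = 1.0,
    *,
    M0: float = 1.0,
    K: int = None,
    return_final_z: bool = False,
) -> np.ndarray:
    """Echo magnitudes of a single voxel under per-pulse complex scalings.

    Pulse j is applied with flip ``a_j * |scale_j|`` and phase
    ``base_phase_j + arg(scale_j)``; each echo period relaxes and dephases
    over half the echo spacing on either side of the refocusing pulse, and
    the echo is the magnitude of the order-0 transverse state.

    ``scale`` may be a scalar (applied to every pulse) or a length-N_p
    complex vector.  ``z0`` is the longitudinal magnetization entering the
    train (e.g. from the FLAIR preparation), in units of M0.
    """
    scale = np.asarray(scale, dtype=complex)
    if scale.ndim == 0:
        scale = np.full(train.n_pulses, complex(scale))
    if scale.shape != (train.n_pulses,):
        raise ValueError(
            f"scale has shape {scale.shape}, expected ({train.n_pulses},)"
        )
    flips, phases = _train_angles(train, scale[:, None])
    echoes, z_end, _ = _run_train(
        flips, phases, train.echo_spacing, T1, T2,
        z0=np.array([z0], dtype=float), M0=M0, K=K,
    )
    mags = np.abs(echoes[0])
    if return_final_z:
        return mags, float(z_end[0])
    return mags


def target_signal(
    train: PulseTrain, T1ref: float, T2ref: float, z0: float = 1.0, *, K: int = None
) -> np.ndarray:
    """Ideal-conditions target ``T = f(1, 1, a, T1ref, T2ref)``.

    The target is the echo train of a uniform single-channel transmitter at
    nominal amplitude; it is constant over space by construction.  ``z0`` is
    the starting longitudinal magnetization for the reference tissue (1 when
    the preparation module is bypassed).
    """
    return simulate_echo_train(train, 1.0, T1ref, T2ref, z0=z0, K=K)


def forward_model(
    w: np.ndarray,
    fields,
    train: PulseTrain,
    T1ref: float,
    T2ref: float,
    z0=None,
    *,
    K: int = None,
) -> SignalPrediction:
    """SR-EPG forward model over the masked voxels of a field map.

    Per masked voxel i, the complex per-pulse transmit scaling is
    ``scale_ij = sum_k w_jk S_ik`` and the echo magnitudes follow from the
    EPG recursion with the reference relaxation times.  B0 is not an input:
    the readout pulses are broadband relative to realistic off-resonance.

    Parameters
    ----------
    w : complex (N_p, N_c) per-pulse shim weights (or a ShimSchedule).
    fields : object with an ``S`` attribute, complex (N_voxels, N_c), or a
        bare complex array of that shape.
    z0 : per-voxel starting longitudinal magnetization (default 1).
    """
    w = np.asarray(getattr(w, "w", w), dtype=complex)
    S = np.asarray(getattr(fields, "S", fields), dtype=complex)
    if w.ndim != 2 or w.shape[0] != train.n_pulses:
        raise ValueError(
            f"shim matrix shape {w.shape} does not match {train.n_pulses} pulses"
        )
    if S.ndim != 2 or S.shape[1] != w.shape[1]:
        raise ValueError(
            f"sensitivity matrix shape {S.shape} does not match "
            f"{w.shape[1]} channels"
        )
    V = S.shape[0]
    if z0 is None:
        z0 = np.ones(V)
    z0 = np.broadcast_to(np.asarray(z0, dtype=float), (V,))
    scale = S @ w.T  # (V, N_p)
    flips, phases = _train_angles(train, scale.T)
    echoes, _, _ = _run_train(
        flips, phases, train.echo_spacing, T1ref, T2ref, z0=z0, K=K
    )
    T = target_signal(train, T1ref, T2ref, K=K)
    return SignalPrediction(I=np.abs(echoes), T=T)


# ---------------------------------------------------------------------------
# Bloch isochromat ensemble oracle
# ---------------------------------------------------------------------------


def _rot_axis_xy(alpha_rad, phi_rad):
    """Right-handed 3x3 rotation by alpha about the in-plane axis at phase phi."""
    n = np.array([np.cos(phi_rad), np.sin(phi_rad), 0.0])
    c, s = np.cos(alpha_rad), np.sin(alpha_rad)
    C = 1 - c
    x, y, z = n
    return np.array(
        [
            [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
            [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
            [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
        ]
    )


def bloch_ensemble_oracle(
    train: PulseTrain,
    scale,
    T1: float,
    T2: float,
    n_isochromats: int = 1024,
    z0: float = 1.0,
    M0: float = 1.0,
) -> np.ndarray:
    """Echo magnitudes from a hard-pulse Bloch simulation of a dephasing
    ensemble; converges to the EPG result as the ensemble grows.

    Isochromats span one full cycle (2*pi) of crusher-induced dephasing per
    half echo period, mirroring the EPG shift operator.  This is a deliberate
    re-derivation of the signal in a different basis (magnetization vectors
    rotated by Rodrigues matrices) used to validate the EPG engine; a single
    isochromat does not reproduce the EPG signal because it carries no
    configuration dephasing.
    """
    scale = np.asarray(scale, dtype=complex)
    if scale.ndim == 0:
        scale = np.full(train.n_pulses, complex(scale))
    theta = 2 * np.pi * np.arange(n_isochromats) / n_isochromats
    rot_phase = np.exp(1j * theta)
    M = np.zeros((n_isochromats, 3))
    M[:, 2] = z0
    e1 = np.exp(-train.echo_spacing / 2 / T1)
    e2 = np.exp(-train.echo_spacing / 2 / T2)
    flips = np.deg2rad(train.flips_deg) * np.abs(scale)
    phases = np.deg2rad(train.phases_deg) + np.angle(scale)

    def relax_and_dephase():
        mxy = (M[:, 0] + 1j * M[:, 1]) * e2 * rot_phase
        M[:, 0], M[:, 1] = mxy.real, mxy.imag
        M[:, 2] = M[:, 2] * e1 + M0 * (1 - e1)

    echoes = np.zeros(train.n_echoes)
    for j in range(train.n_pulses):
        if j > 0:
            relax_and_dephase()
        M[:] = M @ _rot_axis_xy(flips[j], phases[j]).T
        if j > 0:
            relax_and_dephase()
            echoes[j - 1] = np.abs(np.mean(M[:, 0] + 1j * M[:, 1]))
    return echoes


# ---------------------------------------------------------------------------
# adjoint-state gradient of the shim cost
# ---------------------------------------------------------------------------


def _rf_matrix_derivs(alpha_rad, phi_rad):
    """d T / d alpha and d T / d phi, entrywise (broadcastable)."""
    sa = np.sin(alpha_rad)
    ca = np.cos(alpha_rad)
    half = np.sin(alpha_rad / 2) * np.cos(alpha_rad / 2)  # = sin(alpha)/2
    s2 = np.sin(alpha_rad / 2) ** 2
    ep = np.exp(1j * phi_rad)
    em = np.conj(ep)
    dTa = (
        -half, half * ep**2, -1j * ep * ca,
        half * em**2, -half, 1j * em * ca,
        -0.5j * em * ca, 0.5j * ep * ca, -sa,
    )
    dTp = (
        np.zeros_like(ep), 2j * s2 * ep**2, ep * sa,
        -2j * s2 * em**2, np.zeros_like(ep), em * sa,
        -0.5 * em * sa, -0.5 * ep * sa, np.zeros_like(ep),
    )
    return dTa, dTp


def _adj_shift(lFp, lFm, lZ):
    nFp = np.zeros_like(lFp)
    nFm = np.zeros_like(lFm)
    nFp[:-1] = lFp[1:]
    nFm[1:] = lFm[:-1]
    nFm[1] += np.conj(lFp[0])
    return nFp, nFm, lZ


def _adj_relax(lFp, lFm, lZ, e1, e2):
    return lFp * e2, lFm * e2, lZ * e1


def _adj_rf(lFp, lFm, lZ, T):
    # real-adjoint of the complex-linear RF mixing = conjugate transpose
    nFp = np.conj(T[0]) * lFp + np.conj(T[3]) * lFm + np.conj(T[6]) * lZ
    nFm = np.conj(T[1]) * lFp + np.conj(T[4]) * lFm + np.conj(T[7]) * lZ
    nZ = np.conj(T[2]) * lFp + np.conj(T[5]) * lFm + np.conj(T[8]) * lZ
    return nFp, nFm, nZ


def _pair(lam3, vec3):
    """Real inner product Re<lambda, x> summed over orders, per voxel."""
    out = 0.0
    for l, v in zip(lam3, vec3):
        out = out + np.sum((np.conj(l) * v).real, axis=0)
    return out


def epg_cost_and_grad(
    w: np.ndarray,
    S: np.ndarray,
    train: PulseTrain,
    T1ref: float,
    T2ref: float,
    C: np.ndarray,
    *,
    z0=None,
    K: int = None,
    mapping: np.ndarray = None,
):
    """Weighted least-squares signal cost and its exact gradient.

    Cost is ``sum_ij (C_j * (|I_ij| - T_j))**2`` with I the SR-EPG echo
    magnitudes for shims ``w`` (N_p, N_c) on sensitivities ``S``
    (N_voxels, N_c).  The gradient is computed by an adjoint (reverse) sweep
    of the EPG recursion, treating every operator as a real-linear map on the
    stacked configuration states, and is returned as a complex array packing
    ``d/d Re(w) + 1j * d/d Im(w)``.

    When ``mapping`` (length N_p, values in 0..N_s-1) is given, the gradient
    is accumulated onto the reduced shim rows and has shape (N_s, N_c).
    """
    w = np.asarray(w, dtype=complex)
    S = np.asarray(S, dtype=complex)
    n_pulses, n_ch = w.shape
    V = S.shape[0]
    if K is None:
        K = n_pulses
    if z0 is None:
        z0 = np.ones(V)
    z0 = np.broadcast_to(np.asarray(z0, dtype=float), (V,))
    C = np.asarray(C, dtype=float)
    a_rad = np.deg2rad(train.flips_deg)
    phi0 = np.deg2rad(train.phases_deg)
    e1 = np.exp(-train.echo_spacing / 2 / T1ref)
    e2 = np.exp(-train.echo_spacing / 2 / T2ref)

    scale = S @ w.T  # (V, N_p)
    flips = a_rad[:, None] * np.abs(scale.T)
    phases = phi0[:, None] + np.angle(scale.T)
    echoes, _, saved = _run_train(
        flips, phases, train.echo_spacing, T1ref, T2ref, z0=z0, K=K,
        checkpoints=True,
    )
    T_target = target_signal(train, T1ref, T2ref, K=K)
    mags = np.abs(echoes)
    resid = mags - T_target[None, :]
    cost = float(np.sum((C[None, :] * resid) ** 2))

    # seeds d cost / d echo (packed complex), guarding the |e| = 0 point
    safe = np.where(mags > 0, mags, 1.0)
    seeds = 2.0 * C[None, :] ** 2 * resid * echoes / safe  # (V, N_e)

    lFp = np.zeros((K + 1, V), dtype=complex)
    lFm = np.zeros((K + 1, V), dtype=complex)
    lZ = np.zeros((K + 1, V), dtype=complex)
    G = np.zeros((n_pulses, V), dtype=complex)  # packed grad wrt scale_ij

    for j in range(n_pulses - 1, -1, -1):
        if j > 0:
            lFp[0] += seeds[:, j - 1]
            lFp, lFm, lZ = _adj_shift(lFp, lFm, lZ)
            lFp, lFm, lZ = _adj_relax(lFp, lFm, lZ, e1, e2)
        Tj = _rf_matrix(flips[j], phases[j])
        dTa, dTp = _rf_matrix_derivs(flips[j], phases[j])
        x = saved[j]
        dxa = _apply_rf(*x, dTa)
        dxp = _apply_rf(*x, dTp)
        g_alpha = _pair((lFp, lFm, lZ), dxa)
        g_phi = _pair((lFp, lFm, lZ), dxp)
        u = scale[:, j]
        au = np.abs(u)
        ok = au > 1e-300
        inv = np.where(ok, 1.0 / np.where(ok, au, 1.0), 0.0)
        gre = g_alpha * a_rad[j] * u.real * inv - g_phi * u.imag * inv**2
        gim = g_alpha * a_rad[j] * u.imag * inv + g_phi * u.real * inv**2
        G[j] = gre + 1j * gim
        lFp, lFm, lZ = _adj_rf(lFp, lFm, lZ, Tj)
        if j > 0:
            lFp, lFm, lZ = _adj_shift(lFp, lFm, lZ)
            lFp, lFm, lZ = _adj_relax(lFp, lFm, lZ, e1, e2)

    # chain rule through scale_ij = sum_k w_jk S_ik
    grad_full = G @ np.conj(S)  # (N_p, N_c)
    if mapping is None:
        return cost, grad_full
    mapping = np.asarray(mapping)
    n_s = int(mapping.max()) + 1
    grad_red = np.zeros((n_s, n_ch), dtype=complex)
    np.add.at(grad_red, mapping, grad_full)
    return cost, grad_red
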