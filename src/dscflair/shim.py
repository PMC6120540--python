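"""Dynamic (per-pulse) and static RF shim optimization.

Direct signal control (DSC) chooses complex channel weightings ``w_jk`` for
every pulse ``j`` of the echo train so that the SR-EPG predicted echo
amplitudes approach the ideal-conditions target everywhere in the brain:

    min_w  sum_ij || C_ij o (I_ij - T_ij) ||_2^2
    s.t.   sum_j |w_jk b_j|^2 t_RMS,j A / TR <= P_avg  (per channel)
           |w_jk b_j|^2 A <= P_peak                    (per pulse, channel)

The number of free shim settings is reduced by mapping pulses onto N_s
reduced rows (individually shimmed early pulses, then large blocks), the
echo weighting C ramps linearly to a maximum at the centre-of-k-space echo,
and the optimization starts from a uniformly scaled quadrature drive (all
entries 0.6) to stay clear of the power constraints early on.

Besides the per-subject DSC solve this module provides the universal
(multi-subject) variant, the static magnitude-least-squares shim baseline
(variable exchange), and the quadrature reference drive.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np
from scipy import optimize

from .epg import epg_cost_and_grad, forward_model, target_signal
from .sequence import PowerModel, PowerReport, PulseTrain, channel_powers

__all__ = [
    "ShimSchedule",
    "EchoWeighting",
    "DSCSolution",
    "DSCConfig",
    "build_mapping",
    "build_echo_weighting",
    "dsc_cost",
    "dsc_optimize",
    "universal_optimize",
    "static_mls_shim",
    "quadrature_solution",
    "save_solution",
    "load_solution",
]


# ---------------------------------------------------------------------------
# shim parameterization
# ---------------------------------------------------------------------------


def build_mapping(n_pulses: int, individual: int = 13, blocks=(60, 60, 59)) -> np.ndarray:
    """Assign each pulse to one reduced shim row.

    The first ``individual`` pulses get their own row; the remaining pulses
    are grouped into consecutive ``blocks``.  Returns an integer array of
    length ``n_pulses`` with values in ``0..N_s-1`` where
    ``N_s = individual + len(blocks)``.
    """
    blocks = tuple(int(b) for b in blocks)
    if individual < 0 or any(b <= 0 for b in blocks):
        raise ValueError("individual must be >= 0 and blocks positive")
    if individual + sum(blocks) != n_pulses:
        raise ValueError(
            f"mapping covers {individual + sum(blocks)} pulses, train has {n_pulses}"
        )
    parts = [np.arange(individual)]
    for i, b in enumerate(blocks):
        parts.append(np.full(b, individual + i))
    return np.concatenate(parts).astype(int)


@dataclass
class ShimSchedule:
    """Per-pulse shim weights with their reduced parameterization."""

    w_reduced: np.ndarray  # (N_s, N_c) complex
    mapping: np.ndarray  # (N_p,) int, pulse -> reduced row

    def __post_init__(self):
        self.w_reduced = np.asarray(self.w_reduced, dtype=complex)
        self.mapping = np.asarray(self.mapping, dtype=int)
        if self.mapping.min() < 0 or self.mapping.max() >= self.w_reduced.shape[0]:
            raise ValueError("mapping indexes outside the reduced rows")

    @property
    def w(self) -> np.ndarray:
        """Expanded weights, complex (N_p, N_c)."""
        return self.w_reduced[self.mapping]

    @property
    def n_pulses(self) -> int:
        return self.mapping.size

    @property
    def n_channels(self) -> int:
        return self.w_reduced.shape[1]

    @property
    def n_reduced(self) -> int:
        return self.w_reduced.shape[0]


def quadrature_solution(n_pulses: int, n_channels: int = 8) -> ShimSchedule:
    """Nominal quadrature drive: every weight equal to 1."""
    return ShimSchedule(
        w_reduced=np.ones((1, n_channels), dtype=complex),
        mapping=np.zeros(n_pulses, dtype=int),
    )


@dataclass
class EchoWeighting:
    """Echo-domain weighting C, spatially uniform (a vector over echoes)."""

    C: np.ndarray

    def __post_init__(self):
        self.C = np.asarray(self.C, dtype=float)
        if (self.C < 0).any():
            raise ValueError("echo weighting must be non-negative")


def build_echo_weighting(
    n_echoes: int, center: int = 100, floor: float = 0.0
) -> EchoWeighting:
    """Linear ramp up to 1 at the centre-of-k-space echo and back down.

    ``center`` is 1-based.  ``floor`` is the weight at the first and last
    echoes; 1 would make the weighting meaningless (uniform), so it must be
    strictly below 1.
    """
    if not (1 <= center <= n_echoes):
        raise ValueError("center echo outside the train")
    if not (0 <= floor < 1):
        raise ValueError("floor must lie in [0, 1)")
    C = np.empty(n_echoes)
    idx = np.arange(1, n_echoes + 1, dtype=float)
    up = idx <= center
    C[up] = floor + (1 - floor) * (idx[up] - 1) / max(center - 1, 1)
    C[~up] = floor + (1 - floor) * (n_echoes - idx[~up]) / max(n_echoes - center, 1)
    return EchoWeighting(C=C)


# ---------------------------------------------------------------------------
# cost and constraints
# ---------------------------------------------------------------------------


def dsc_cost(
    w_reduced: np.ndarray,
    fields,
    train: PulseTrain,
    T1ref: float,
    T2ref: float,
    C,
    *,
    mapping: np.ndarray = None,
    K: int = None,
) -> float:
    """Weighted squared deviation of predicted echoes from the target.

    ``sum_ij (C_j * (I_ij - T_j))^2`` with I from the SR-EPG forward model
    for the expanded shims.
    """
    w_reduced = np.asarray(w_reduced, dtype=complex)
    if mapping is None:
        mapping = np.zeros(train.n_pulses, dtype=int) if w_reduced.shape[0] == 1 \
            else np.arange(train.n_pulses)
    sched = ShimSchedule(w_reduced=w_reduced, mapping=mapping)
    C = np.asarray(getattr(C, "C", C), dtype=float)
    pred = forward_model(sched.w, fields, train, T1ref, T2ref, K=K)
    return float(np.sum((C[None, :] * (pred.I - pred.T[None, :])) ** 2))


def _pack(w):  # complex (N_s, N_c) -> real vector
    return np.concatenate([w.real.ravel(), w.imag.ravel()])


def _unpack(x, shape):
    half = x.size // 2
    return x[:half].reshape(shape) + 1j * x[half:].reshape(shape)


def _constraint_coeffs(train: PulseTrain, pm: PowerModel, mapping: np.ndarray):
    """Per-reduced-row quadratic coefficients of the two power constraints."""
    b2 = train.peak_b1s**2
    t = train.t_rms
    n_s = int(mapping.max()) + 1
    avg_row = np.zeros(n_s)  # sum_{j in s} b_j^2 t_j * A / TR
    peak_row = np.zeros(n_s)  # max_{j in s} b_j^2 * A
    for s in range(n_s):
        sel = mapping == s
        avg_row[s] = (b2[sel] * t[sel]).sum() * pm.A / train.TR
        peak_row[s] = b2[sel].max() * pm.A
    return avg_row, peak_row


@dataclass
class DSCConfig:
    """Optimization configuration (desk-scale defaults).

    ``subsample`` thins the masked voxels used *inside* the optimization for
    speed; predictions and metrics always use the full mask.  ``K_opt``
    truncates the EPG order during optimization only.
    """

    individual: int = 13
    blocks: tuple = (60, 60, 59)
    T1ref: float = 1.5
    T2ref: float = 0.05
    weight_floor: float = 0.0
    init_amplitude: float = 0.6
    maxiter: int = 120
    cost_rtol: float = 1e-6
    subsample: int = 1
    max_opt_voxels: int = 250
    K_opt: int = 48
    shim_excitation: bool = True  # excitation pulse is shimmed too


@dataclass
class DSCSolution:
    schedule: ShimSchedule
    cost_history: np.ndarray
    power_report: PowerReport
    converged: bool
    initial_cost: float = None
    final_cost: float = None

    @property
    def w(self):
        return self.schedule.w


def _opt_voxels(S: np.ndarray, cfg: DSCConfig) -> np.ndarray:
    step = max(int(cfg.subsample), 1)
    Ssub = S[::step]
    if cfg.max_opt_voxels and Ssub.shape[0] > cfg.max_opt_voxels:
        stride = int(np.ceil(Ssub.shape[0] / cfg.max_opt_voxels))
        Ssub = Ssub[::stride]
    return Ssub


def dsc_optimize(
    fields,
    train: PulseTrain,
    pm: PowerModel,
    config: DSCConfig = None,
) -> DSCSolution:
    """Direct signal control: power-constrained dynamic shim optimization.

    Minimizes :func:`dsc_cost` over the real and imaginary parts of the
    reduced shim matrix with scipy's interior-point style ``trust-constr``
    solver, exact adjoint gradients, and the two per-channel power
    constraints (the preparation-module average power offset is subtracted
    from the available average-power budget).  The returned solution is
    projected to strict feasibility and always has final cost <= the cost at
    the scaled-quadrature initialization.
    """
    cfg = config or DSCConfig()
    S_full = np.asarray(getattr(fields, "S", fields), dtype=complex)
    if S_full.ndim != 2 or S_full.shape[0] < 1:
        raise ValueError("need a (N_voxels, N_channels) sensitivity matrix")
    n_ch = S_full.shape[1]
    mapping = build_mapping(train.n_pulses, cfg.individual, cfg.blocks)
    n_s = int(mapping.max()) + 1
    C = build_echo_weighting(
        train.n_echoes, train.center_echo_index, cfg.weight_floor
    ).C
    S = _opt_voxels(S_full, cfg)

    avg_row, peak_row = _constraint_coeffs(train, pm, mapping)
    avg_budget = pm.P_avg - pm.mp_power_offset
    if avg_budget <= 0:
        raise ValueError("MP power offset exhausts the average power budget")

    shape = (n_s, n_ch)

    exc_row = int(mapping[0])

    def cost_grad(x):
        w = _unpack(x, shape)
        if not cfg.shim_excitation:
            w = w.copy()
            w[exc_row] = 1.0  # excitation pinned at quadrature
        c, g = epg_cost_and_grad(
            w[mapping], S, train, cfg.T1ref, cfg.T2ref, C,
            K=cfg.K_opt, mapping=mapping,
        )
        if not cfg.shim_excitation:
            g[exc_row] = 0.0
        return c, _pack(g)

    # per-channel average power: sum_s |w_sk|^2 avg_row_s <= budget
    def f_avg(x):
        w2 = np.abs(_unpack(x, shape)) ** 2
        return avg_row @ w2  # (N_c,)

    def jac_avg(x):
        w = _unpack(x, shape)
        J = np.zeros((n_ch, x.size))
        half = x.size // 2
        for k in range(n_ch):
            gr = np.zeros(shape)
            gr[:, k] = 2 * avg_row * w.real[:, k]
            gi = np.zeros(shape)
            gi[:, k] = 2 * avg_row * w.imag[:, k]
            J[k, :half] = gr.ravel()
            J[k, half:] = gi.ravel()
        return J

    # per-pulse peak power reduces to per-row caps: |w_sk|^2 peak_row_s <= P_peak
    def f_peak(x):
        w2 = np.abs(_unpack(x, shape)) ** 2
        return (peak_row[:, None] * w2).ravel()

    def jac_peak(x):
        w = _unpack(x, shape)
        half = x.size // 2
        n = n_s * n_ch
        J = np.zeros((n, x.size))
        diag = (2 * peak_row[:, None] * w.real).ravel()
        J[np.arange(n), np.arange(n)] = diag
        diag_i = (2 * peak_row[:, None] * w.imag).ravel()
        J[np.arange(n), half + np.arange(n)] = diag_i
        return J

    w0 = np.full(shape, cfg.init_amplitude, dtype=complex)
    # auto-rescale an infeasible start (can only happen with tight limits)
    scale_cap = np.inf
    if (avg_row @ (np.abs(w0) ** 2).max(axis=1)).max() > 0:
        worst_avg = (avg_row.sum() * cfg.init_amplitude**2)
        if worst_avg > avg_budget:
            scale_cap = np.sqrt(avg_budget / worst_avg) * 0.99
    worst_peak = peak_row.max() * cfg.init_amplitude**2
    if worst_peak > pm.P_peak:
        scale_cap = min(scale_cap, np.sqrt(pm.P_peak / worst_peak) * 0.99)
    if np.isfinite(scale_cap):
        w0 = w0 * scale_cap
    x0 = _pack(w0)

    history = []

    def cb(x, state=None):
        history.append(float(state.fun) if state is not None else np.nan)

    constraints = [
        optimize.NonlinearConstraint(f_avg, -np.inf, avg_budget, jac=jac_avg),
        optimize.NonlinearConstraint(f_peak, -np.inf, pm.P_peak, jac=jac_peak),
    ]
    c0 = cost_grad(x0)[0]
    res = optimize.minimize(
        cost_grad, x0, jac=True, method="trust-constr",
        constraints=constraints,
        options={"maxiter": cfg.maxiter, "xtol": 1e-10, "gtol": 1e-8,
                 "verbose": 0},
        callback=cb,
    )
    w_opt = _unpack(res.x, shape)
    if not cfg.shim_excitation:
        w_opt[exc_row] = 1.0

    # strict feasibility projection: scale any offending row/column down
    w2 = np.abs(w_opt) ** 2
    over_peak = peak_row[:, None] * w2 / pm.P_peak
    fac = np.sqrt(np.maximum(over_peak, 1.0))
    w_opt = w_opt / fac
    avg_now = avg_row @ (np.abs(w_opt) ** 2)
    over = np.sqrt(np.maximum(avg_now / avg_budget, 1.0))
    w_opt = w_opt / over[None, :]

    sched = ShimSchedule(w_reduced=w_opt, mapping=mapping)
    final = dsc_cost(
        w_opt, S, train, cfg.T1ref, cfg.T2ref, C, mapping=mapping, K=cfg.K_opt
    )
    if final > c0:  # never return worse than the initialization
        sched = ShimSchedule(
            w_reduced=_unpack(x0, shape), mapping=mapping
        )
        final = c0
    report = channel_powers(sched.w, train, pm)
    return DSCSolution(
        schedule=sched,
        cost_history=np.array([c0] + history + [final]),
        power_report=report,
        converged=bool(res.status in (1, 2)),
        initial_cost=c0,
        final_cost=final,
    )


def universal_optimize(
    fields_list,
    train: PulseTrain,
    pm: PowerModel,
    config: DSCConfig = None,
) -> DSCSolution:
    """Universal DSC solution over a group of subjects.

    Identical to :func:`dsc_optimize` with the subjects' sensitivity maps
    concatenated into one large voxel set, so the least-squares error is
    minimized over the whole group.
    """
    if len(fields_list) < 1:
        raise ValueError("need at least one subject")
    mats = [np.asarray(getattr(f, "S", f), dtype=complex) for f in fields_list]
    n_ch = {m.shape[1] for m in mats}
    if len(n_ch) != 1:
        raise ValueError("subjects disagree on channel count")
    cfg = config or DSCConfig()
    # thin each subject before concatenating so every subject keeps the same
    # relative weight in the pooled cost
    per = max(cfg.max_opt_voxels // len(mats), 8) if cfg.max_opt_voxels else None
    thinned = []
    for m in mats:
        msub = m[:: max(int(cfg.subsample), 1)]
        if per and msub.shape[0] > per:
            msub = msub[:: int(np.ceil(msub.shape[0] / per))]
        thinned.append(msub)
    S = np.vstack(thinned)
    from dataclasses import replace

    cfg_all = replace(cfg, subsample=1, max_opt_voxels=0)
    return dsc_optimize(S, train, pm, cfg_all)


# ---------------------------------------------------------------------------
# static magnitude least squares shim
# ---------------------------------------------------------------------------


def static_mls_shim(
    fields,
    train: PulseTrain,
    pm: PowerModel,
    *,
    target: float = None,
    n_exchanges: int = 30,
    tol: float = 1e-8,
) -> ShimSchedule:
    """Static RF shim via constrained magnitude least squares.

    One complex weight per channel, applied to every pulse.  The variable
    exchange method alternates (a) setting the per-voxel phase target to the
    phase of the current combined field and (b) solving the resulting
    phase-fixed least-squares problem under the per-channel power limits,
    which for a static shim reduce to amplitude caps ``|w_k| <= r``.  The
    magnitude target defaults to the mean quadrature combination over the
    mask.
    """
    S = np.asarray(getattr(fields, "S", fields), dtype=complex)
    if S.ndim != 2 or S.shape[0] < 1:
        raise ValueError("need a (N_voxels, N_channels) sensitivity matrix")
    if not np.any(np.abs(S) > 0):
        raise ValueError("all-zero sensitivities: static shim undefined")
    V, n_ch = S.shape
    if target is None:
        target = float(np.mean(np.abs(S.sum(axis=1))))

    b2t = (train.peak_b1s**2 * train.t_rms).sum()
    r_avg = np.sqrt((pm.P_avg - pm.mp_power_offset) * train.TR / (pm.A * b2t))
    r_peak = np.sqrt(pm.P_peak / (pm.A * train.peak_b1s.max() ** 2))
    r = min(r_avg, r_peak)

    w = np.full(n_ch, min(1.0, 0.999 * r), dtype=complex)

    def mls_objective(wc):
        return float(np.sum((np.abs(S @ wc) - target) ** 2))

    def solve_phase_fixed(z, w_start):
        """min_w sum |S w - target*z|^2  s.t. |w_k| <= r  (convex)."""
        rhs = target * z

        def fg(x):
            wc = x[:n_ch] + 1j * x[n_ch:]
            res = S @ wc - rhs
            f = float(np.sum(np.abs(res) ** 2))
            g = 2 * (S.conj().T @ res)
            return f, np.concatenate([g.real, g.imag])

        cons = [
            optimize.NonlinearConstraint(
                lambda x: x[:n_ch] ** 2 + x[n_ch:] ** 2, -np.inf, r**2,
                jac=lambda x: np.hstack(
                    [np.diag(2 * x[:n_ch]), np.diag(2 * x[n_ch:])]
                ),
            )
        ]
        x0 = np.concatenate([w_start.real, w_start.imag])
        res = optimize.minimize(
            fg, x0, jac=True, method="SLSQP",
            constraints=[{"type": "ineq",
                          "fun": lambda x: r**2 - (x[:n_ch] ** 2 + x[n_ch:] ** 2)}],
            options={"maxiter": 200, "ftol": 1e-12},
        )
        return res.x[:n_ch] + 1j * res.x[n_ch:]

    prev = mls_objective(w)
    for _ in range(n_exchanges):
        combined = S @ w
        z = np.where(np.abs(combined) > 0, combined / np.abs(np.where(
            np.abs(combined) > 0, combined, 1.0)), 1.0)
        w_new = solve_phase_fixed(z, w)
        new = mls_objective(w_new)
        if new <= prev + 1e-15:
            w = w_new
        if abs(prev - new) <= tol * max(prev, 1e-30):
            prev = min(prev, new)
            break
        prev = min(prev, new)
    return ShimSchedule(
        w_reduced=w[None, :], mapping=np.zeros(train.n_pulses, dtype=int)
    )


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def save_solution(path: str, sol: DSCSolution) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("w", data=sol.schedule.w)
        f.create_dataset("w_reduced", data=sol.schedule.w_reduced)
        f.create_dataset("mapping", data=sol.schedule.mapping)
        f.create_dataset("cost_history", data=sol.cost_history)
        f.create_dataset("avg_per_channel", data=sol.power_report.avg_per_channel)
        f.create_dataset("peak", data=sol.power_report.peak)
        f.attrs["P_avg"] = sol.power_report.P_avg
        f.attrs["P_peak"] = sol.power_report.P_peak
        f.attrs["converged"] = sol.converged
        f.attrs["initial_cost"] = sol.initial_cost or np.nan
        f.attrs["final_cost"] = sol.final_cost or np.nan


def load_solution(path: str) -> DSCSolution:
    with h5py.File(path, "r") as f:
        sched = ShimSchedule(
            w_reduced=f["w_reduced"][()], mapping=f["mapping"][()]
        )
        report = PowerReport(
            avg_per_channel=f["avg_per_channel"][()],
            peak=f["peak"][()],
            P_avg=float(f.attrs["P_avg"]),
            P_peak=float(f.attrs["P_peak"]),
        )
        return DSCSolution(
            schedule=sched,
            cost_history=f["cost_history"][()],
            power_report=report,
            converged=bool(f.attrs["converged"]),
            initial_cost=float(f.attrs["initial_cost"]),
            final_cost=float(f.attrs["final_cost"]),
        )
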