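"""Synthetic 7T head-array field maps.

Generates 8-channel complex transmit sensitivity maps, smooth B0 maps and a
brain mask with the qualitative structure of measured 7T head-coil data:
the quadrature (all-ones) combination is bright at the centre of the brain
where the channel fields add coherently, and loses magnitude peripherally
and in an inferior-posterior "cerebellum-like" region where destructive
interference and coil coverage produce the characteristic B1+ dropout.

The channel model is phenomenological -- Gaussian-lobed amplitudes around
azimuthal port positions with propagation-like phase advance -- rather than
an electromagnetic simulation; only the statistical structure matters for
exercising the shim optimization.  Everything is deterministic given the
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .fields import FieldModel

__all__ = ["SynthConfig", "synth_b1", "synth_b0", "synth_fields", "synth_cohort"]


@dataclass(frozen=True)
class SynthConfig:
    grid_shape: tuple = (24, 24, 24)
    voxel_size: float = 8.0  # mm
    n_channels: int = 8
    seed: int = 1
    #: target minimum of the quadrature |B1+| inside the mask, relative to
    #: the value at the mask centroid
    dropout_depth: float = 0.35
    b0_range: float = 300.0  # Hz
    head_scale: float = 1.0
    channel_gains: np.ndarray = None

    def __post_init__(self):
        if min(self.grid_shape) < 8:
            raise ValueError("grid_shape must be at least 8 in every axis")
        if self.n_channels < 2:
            raise ValueError("need at least 2 channels")
        if not (0 < self.dropout_depth < 1):
            raise ValueError("dropout_depth must lie in (0, 1)")


def _grid_coords(cfg: SynthConfig):
    nx, ny, nz = cfg.grid_shape
    x, y, z = np.meshgrid(
        np.arange(nx) - (nx - 1) / 2,
        np.arange(ny) - (ny - 1) / 2,
        np.arange(nz) - (nz - 1) / 2,
        indexing="ij",
    )
    return x, y, z


def _head_mask(cfg: SynthConfig):
    """Ellipsoidal head mask (single connected component by construction)."""
    x, y, z = _grid_coords(cfg)
    nx, ny, nz = cfg.grid_shape
    ax = 0.38 * nx * cfg.head_scale
    ay = 0.42 * ny * cfg.head_scale
    az = 0.40 * nz * cfg.head_scale
    return (x / ax) ** 2 + (y / ay) ** 2 + (z / az) ** 2 <= 1.0


def synth_b1(cfg: SynthConfig) -> FieldModel:
    """Synthesize the multi-channel sensitivity maps, B0 map and mask.

    Channels sit azimuthally around the head; each amplitude decays with
    distance from its port and the phase advances with propagation depth.
    The maps are normalized so the quadrature combination has magnitude 1 at
    the mask centroid, then an inferior-posterior attenuation bump is
    calibrated so the in-mask minimum of the quadrature magnitude is close
    to ``cfg.dropout_depth`` of the central value.
    """
    rng = np.random.default_rng(cfg.seed)
    x, y, z = _grid_coords(cfg)
    nx, ny, nz = cfg.grid_shape
    mask = _head_mask(cfg)
    R = 0.55 * max(nx, ny) * cfg.head_scale  # coil ring radius, voxels

    gains = (
        np.ones(cfg.n_channels)
        if cfg.channel_gains is None
        else np.asarray(cfg.channel_gains, dtype=float)
    )
    # per-channel smooth random perturbation (low-order harmonics)
    pert_amp = rng.normal(0.0, 0.03, (cfg.n_channels, 3))
    pert_phase = rng.normal(0.0, 0.10, (cfg.n_channels, 3))

    kappa = 0.45 / R  # phase advance per voxel of depth (rad)
    sigma = 0.95 * R
    s_maps = np.zeros(cfg.grid_shape + (cfg.n_channels,), dtype=complex)
    d_center = np.full(cfg.n_channels, np.nan)
    for k in range(cfg.n_channels):
        theta = 2 * np.pi * k / cfg.n_channels
        px, py = R * np.cos(theta), R * np.sin(theta)
        # ports sit on the z=0 ring; sensitivity decays away from the ring
        # plane faster than in-plane (loop coil falloff)
        d = np.sqrt((x - px) ** 2 + (y - py) ** 2 + (0.85 * z) ** 2)
        d_center[k] = np.sqrt(px**2 + py**2)
        amp = gains[k] * np.exp(-(d**2) / (2 * sigma**2))
        amp = amp * (
            1.0
            + pert_amp[k, 0] * np.sin(np.pi * x / nx)
            + pert_amp[k, 1] * np.sin(np.pi * y / ny)
            + pert_amp[k, 2] * np.sin(np.pi * z / nz)
        )
        phase = kappa * (d - d_center[k]) * R / sigma * 2.2 + (
            pert_phase[k, 0] * np.sin(np.pi * x / nx)
            + pert_phase[k, 1] * np.sin(np.pi * y / ny)
            + pert_phase[k, 2] * np.sin(np.pi * z / nz)
        )
        s_maps[..., k] = amp * np.exp(1j * phase)

    # constructive-interference envelope: the combined field of a
    # circumferential array peaks at the head centre at 7T
    nxs, nys, nzs = 0.38 * nx, 0.42 * ny, 0.40 * nz
    u2 = (x / (nxs * cfg.head_scale)) ** 2 + (y / (nys * cfg.head_scale)) ** 2 \
        + (z / (nzs * cfg.head_scale)) ** 2
    s_maps *= np.exp(-u2 / (2 * 0.85**2))[..., None]

    # calibrate: quadrature magnitude = 1 at the mask centroid
    ijk = np.argwhere(mask)
    centroid = tuple(np.round(ijk.mean(axis=0)).astype(int))
    quad = np.abs(s_maps.sum(axis=-1))
    s_maps /= quad[centroid]
    quad = np.abs(s_maps.sum(axis=-1))

    # inferior-posterior "cerebellum-like" dropout: a destructive
    # interference null.  Inside a smooth bump the channel phases are
    # twisted apart (offset proportional to channel index) so the
    # quadrature combination collapses while the individual channel
    # amplitudes survive -- which is what makes the region recoverable by
    # re-phasing, as for real 7T interference dropouts.  The twist strength
    # is calibrated by bisection so the in-mask minimum of the quadrature
    # magnitude lands at dropout_depth relative to the centroid value.
    cb = np.array([-0.22 * nx, 0.0, -0.28 * nz])  # x: posterior, z: inferior
    r2 = ((x - cb[0]) ** 2 + (y - cb[1]) ** 2 + (z - cb[2]) ** 2) / (
        0.14 * nx * ny
    )
    bump = np.exp(-r2)
    k_idx = np.arange(cfg.n_channels)
    frac = (k_idx - (cfg.n_channels - 1) / 2) / cfg.n_channels

    # mild common-mode shading (coil coverage loss), applied before the
    # twist calibration so the target minimum is hit exactly
    s_maps = s_maps * (1.0 - 0.12 * bump)[..., None]

    def _twisted(gamma):
        twist = gamma * bump[..., None] * (2 * np.pi * frac)
        return s_maps * np.exp(1j * twist)

    def _min_ratio(gamma):
        qa = np.abs(_twisted(gamma).sum(axis=-1))
        return qa[mask].min() / qa[centroid]

    if _min_ratio(0.0) > cfg.dropout_depth:
        lo, hi = 0.0, 1.0
        while _min_ratio(hi) > cfg.dropout_depth and hi < 4.0:
            hi *= 1.5
        for _ in range(40):
            mid = (lo + hi) / 2
            if _min_ratio(mid) > cfg.dropout_depth:
                lo = mid
            else:
                hi = mid
        s_maps = _twisted((lo + hi) / 2)

    # re-normalize the centroid (the bump tail barely reaches it)
    quad = np.abs(s_maps.sum(axis=-1))
    s_maps /= quad[centroid]

    affine = np.diag([cfg.voxel_size] * 3 + [1.0])
    affine[:3, 3] = -cfg.voxel_size * (np.array(cfg.grid_shape) - 1) / 2
    return FieldModel(
        s_maps=s_maps,
        b0_map=synth_b0(cfg),
        mask=mask,
        affine=affine,
        subject_id=f"synth-{cfg.seed}",
    )


def synth_b0(cfg: SynthConfig) -> np.ndarray:
    """Smooth off-resonance map in Hz.

    A low-order polynomial background plus one or two localized offset blobs
    near the inferior-frontal mask boundary (air-tissue interface region),
    clamped to +/- ``cfg.b0_range``.
    """
    rng = np.random.default_rng(cfg.seed + 104729)
    x, y, z = _grid_coords(cfg)
    nx, ny, nz = cfg.grid_shape
    xn, yn, zn = x / nx, y / ny, z / nz
    coeffs = rng.normal(0.0, 1.0, 6)
    background = 0.15 * cfg.b0_range * (
        coeffs[0] * xn + coeffs[1] * yn + coeffs[2] * zn
        + coeffs[3] * xn * yn + coeffs[4] * (zn**2 - 1 / 12) + coeffs[5] * xn * zn
    )
    b0 = background.copy()
    n_blobs = 1 + int(rng.integers(0, 2))
    for _ in range(n_blobs):
        # inferior-frontal: +x (anterior), -z (inferior), near the boundary
        cx = (0.28 + 0.06 * rng.random()) * nx
        cy = rng.normal(0.0, 0.08) * ny
        cz = -(0.25 + 0.08 * rng.random()) * nz
        width2 = (0.055 * nx * nz) * (0.8 + 0.4 * rng.random())
        amp = rng.choice([-1.0, 1.0]) * (0.6 + 0.3 * rng.random()) * cfg.b0_range
        b0 += amp * np.exp(-(((x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2) / width2))
    return np.clip(b0, -cfg.b0_range, cfg.b0_range)


def synth_fields(cfg: SynthConfig = SynthConfig()) -> FieldModel:
    """Alias for :func:`synth_b1` (returns the complete field model)."""
    return synth_b1(cfg)


def synth_cohort(n_subjects: int, base_cfg: SynthConfig = SynthConfig()):
    """A cohort of per-subject field models with anatomical/coil variation.

    Head size varies by +/-10%, per-channel gains by +/-15%, and the dropout
    depth jitters around the base value; subject seeds are derived from the
    base seed so regeneration is exact.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be at least 1")
    out = []
    for s in range(n_subjects):
        rng = np.random.default_rng(base_cfg.seed * 1000 + s)
        cfg = replace(
            base_cfg,
            seed=base_cfg.seed * 1000 + s,
            head_scale=float(base_cfg.head_scale * (1 + rng.uniform(-0.10, 0.10))),
            channel_gains=1 + rng.uniform(-0.15, 0.15, base_cfg.n_channels),
            dropout_depth=float(
                np.clip(base_cfg.dropout_depth + rng.uniform(-0.05, 0.05), 0.05, 0.95)
            ),
        )
        fm = synth_b1(cfg)
        fm.subject_id = f"synth-{base_cfg.seed}-s{s}"
        out.append(fm)
    return out
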