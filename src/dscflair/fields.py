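"""Per-voxel field data: multi-channel transmit sensitivities, B0 and mask.

Volumes are held on their 3D grid together with a NIfTI affine; the
optimization-facing view (``S``, ``b0``, ``coords``) exposes only the masked
voxels.  Sensitivities are dimensionless complex factors relative to the
reference B1+, calibrated such that the all-ones (quadrature) channel
combination has unit magnitude at the mask centroid.

On disk a field model is a directory of uncompressed NIfTI volumes:
``b1_mag.nii`` / ``b1_phase.nii`` (4D, one volume per channel, phase in
radians), ``b0.nii`` (Hz) and ``mask.nii`` (bytes).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["FieldModel"]


@dataclass
class FieldModel:
    """Complex channel sensitivities, off-resonance and brain mask on a grid."""

    s_maps: np.ndarray  # (nx, ny, nz, n_channels) complex
    b0_map: np.ndarray  # (nx, ny, nz) Hz
    mask: np.ndarray  # (nx, ny, nz) bool
    affine: np.ndarray = None
    subject_id: str = ""

    def __post_init__(self):
        self.s_maps = np.asarray(self.s_maps, dtype=complex)
        self.b0_map = np.asarray(self.b0_map, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.affine is None:
            self.affine = np.eye(4)
        if self.s_maps.shape[:3] != self.mask.shape:
            raise ValueError("sensitivity and mask grids disagree")
        if self.b0_map.shape != self.mask.shape:
            raise ValueError("b0 and mask grids disagree")
        if not self.mask.any():
            raise ValueError("mask is empty")
        masked = self.s_maps[self.mask]
        if not (np.isfinite(masked).all() and
                np.isfinite(self.b0_map[self.mask]).all()):
            raise ValueError("non-finite field values inside the mask")

    @property
    def n_channels(self) -> int:
        return self.s_maps.shape[3]

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def S(self) -> np.ndarray:
        """Masked sensitivities, complex (N_voxels, N_channels)."""
        return self.s_maps[self.mask]

    @property
    def b0(self) -> np.ndarray:
        """Masked off-resonance in Hz, (N_voxels,)."""
        return self.b0_map[self.mask]

    @property
    def coords(self) -> np.ndarray:
        """World-space coordinates (mm) of the masked voxels, (N_voxels, 3)."""
        ijk = np.argwhere(self.mask)
        hom = np.c_[ijk, np.ones(len(ijk))]
        return (hom @ self.affine.T)[:, :3]

    @property
    def quadrature(self) -> np.ndarray:
        """Magnitude of the all-ones channel combination over the mask."""
        return np.abs(self.S.sum(axis=1))

    def subsample(self, step: int) -> np.ndarray:
        """Masked sensitivities of every ``step``-th voxel (optimization aid)."""
        return self.S[::max(int(step), 1)]

    # -- NIfTI round trip ---------------------------------------------------

    def save(self, directory: str) -> None:
        os.makedirs(directory, exist_ok=True)
        aff = self.affine

        def _w(name, data):
            nib.save(nib.Nifti1Image(np.asarray(data), aff),
                     os.path.join(directory, name))

        _w("b1_mag.nii", np.abs(self.s_maps).astype(np.float64))
        _w("b1_phase.nii", np.angle(self.s_maps).astype(np.float64))
        _w("b0.nii", self.b0_map)
        _w("mask.nii", self.mask.astype(np.uint8))

    @classmethod
    def load(cls, directory: str, subject_id: str = "") -> "FieldModel":
        def _r(name):
            return nib.load(os.path.join(directory, name))

        mag = _r("b1_mag.nii")
        phase = np.asarray(_r("b1_phase.nii").dataobj)
        s_maps = np.asarray(mag.dataobj) * np.exp(1j * phase)
        return cls(
            s_maps=s_maps,
            b0_map=np.asarray(_r("b0.nii").dataobj),
            mask=np.asarray(_r("mask.nii").dataobj) > 0,
            affine=mag.affine,
            subject_id=subject_id or os.path.basename(directory.rstrip("/")),
        )
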