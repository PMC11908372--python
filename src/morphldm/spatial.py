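"""Displacement fields and the differentiable warp.

A deformation ``v = Id + u`` is stored by its displacement part ``u``, a
3-channel grid in voxel units (channel d displaces along axis d). Applying
``v`` to a volume means sampling the volume at the displaced positions,
``out(p) = vol(p + u(p))`` — the grid-sampler / spatial-transformer of
learning-based registration. The regularizer penalises displacement
magnitude and its spatial gradient,

    R(v) = alpha * mean_p |u(p)|^2 + beta * mean_p |grad u(p)|^2,

with forward finite differences and a per-voxel mean (not sum) convention
so the weights are resolution independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn.functional import grid_sample_numpy

__all__ = ["Volume", "DisplacementField", "identity_field", "warp",
           "displacement_regularizer", "jacobian_determinant"]


@dataclass
class Volume:
    """Single-channel 3D intensity grid with voxel spacing in mm."""

    intensities: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 3:
            raise ValueError(
                f"Volume expects a 3D grid, got shape {self.intensities.shape}"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("Volume intensities must be finite")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    @property
    def voxel_volume(self) -> float:
        """mm^3 per voxel."""
        return float(np.prod(self.spacing))


@dataclass
class DisplacementField:
    """Voxel-unit displacement u of a deformation v = Id + u.

    u has shape (3, D, H, W); u[d] displaces along axis d.
    """

    u: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.u = np.asarray(self.u, dtype=float)
        if self.u.ndim != 4 or self.u.shape[0] != 3:
            raise ValueError(
                f"DisplacementField expects (3, D, H, W), got {self.u.shape}"
            )
        if not np.all(np.isfinite(self.u)):
            raise ValueError("displacement field must be finite")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.u.shape[1:]


def identity_field(grid_shape: tuple[int, int, int],
                   spacing=(1.0, 1.0, 1.0)) -> DisplacementField:
    """The identity deformation: u = 0 everywhere."""
    grid_shape = tuple(int(s) for s in grid_shape)
    if len(grid_shape) != 3 or any(s < 1 for s in grid_shape):
        raise ValueError(f"invalid grid shape {grid_shape}")
    return DisplacementField(np.zeros((3,) + grid_shape), spacing=spacing)


def warp(volume: Volume, displacement: DisplacementField,
         interpolation: str = "trilinear", padding_mode: str = "border") -> Volume:
    """Apply v = Id + u to a volume: out(p) = volume(p + u(p)).

    Trilinear interpolation for intensity images; nearest for label maps.
    """
    if volume.shape != displacement.grid_shape:
        raise ValueError(
            f"volume shape {volume.shape} does not match field grid "
            f"{displacement.grid_shape}"
        )
    out = grid_sample_numpy(volume.intensities, displacement.u,
                            interpolation=interpolation,
                            padding_mode=padding_mode)
    return Volume(out, spacing=volume.spacing, affine=volume.affine)


def _forward_diff(a: np.ndarray, axis: int) -> np.ndarray:
    """Forward difference with replicated edge (last slice difference = 0)."""
    d = np.zeros_like(a)
    sl_hi = [slice(None)] * a.ndim
    sl_lo = [slice(None)] * a.ndim
    sl_out = [slice(None)] * a.ndim
    sl_hi[axis] = slice(1, None)
    sl_lo[axis] = slice(None, -1)
    sl_out[axis] = slice(None, -1)
    d[tuple(sl_out)] = a[tuple(sl_hi)] - a[tuple(sl_lo)]
    return d


def displacement_regularizer(displacement: DisplacementField,
                             alpha: float = 5.0, beta: float = 1.0) -> dict:
    """R(v) = alpha*mean(|u|^2) + beta*mean(|grad u|^2).

    Returns the total and both components. Means are per voxel of the
    squared vector norm (channels and, for the gradient term, derivative
    axes are summed), so a unit constant displacement along one axis has
    magnitude component exactly 1 regardless of grid size. The gradient
    uses forward differences with a replicated edge.
    """
    if alpha < 0 or beta < 0:
        raise ValueError("regularizer weights must be nonnegative")
    u = displacement.u
    n_vox = u[0].size
    magnitude = float(np.sum(u ** 2) / n_vox)
    grad_sq = 0.0
    for axis in range(1, 4):
        d = _forward_diff(u, axis)
        grad_sq += np.sum(d ** 2)
    gradient = float(grad_sq / n_vox)
    return {
        "total": alpha * magnitude + beta * gradient,
        "magnitude": magnitude,
        "gradient": gradient,
    }


def jacobian_determinant(displacement: DisplacementField) -> dict:
    """Per-voxel det(grad(Id + u)) by forward finite differences.

    Returns the determinant grid and the fraction of nonpositive values
    (folding diagnostic). Determinants near 1 indicate a gentle,
    volume-preserving deformation.
    """
    u = displacement.u
    if min(u.shape[1:]) < 2:
        raise ValueError("jacobian needs at least 2 voxels per axis")
    J = np.zeros(u.shape[1:] + (3, 3))
    for d in range(3):
        for axis in range(3):
            J[..., d, axis] = _forward_diff(u[d], axis)
        J[..., d, d] += 1.0
    det = np.linalg.det(J)
    return {
        "determinant": det,
        "fraction_nonpositive": float(np.mean(det <= 0.0)),
    }
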