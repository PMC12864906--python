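"""Green-Lagrange strain from a dense displacement field.

Given the displacement gradient H = grad(u), the deformation gradient is
F = I + H and the Green-Lagrange strain

    E = (Fᵀ F − I) / 2 = (H + Hᵀ + Hᵀ H) / 2 .

Unlike the small-strain (infinitesimal) tensor, E vanishes identically for
any finite rigid motion, which is what makes it the right measure for the
large abdominal-wall deformations seen under Valsalva. The scalar that is
visualised and thresholded downstream is the maximum principal strain, the
largest eigenvalue of E at each voxel.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .core import GridRaster
from .registration import DisplacementField


@dataclass
class StrainField(GridRaster):
    """Per-voxel symmetric Green-Lagrange tensors and principal strain.

    ``boundary`` flags the one-voxel outer shell where the gradient falls
    back to one-sided differences; hotspots there are suspect and the flag
    propagates into reports.
    """

    max_principal: np.ndarray = None
    boundary: np.ndarray = None
    provenance: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.voxels.ndim != 5 or self.voxels.shape[3:] != (3, 3):
            raise ValueError(f"strain tensors must have shape (nx,ny,nz,3,3), got {self.voxels.shape}")
        if self.max_principal is None:
            self.max_principal = max_principal_strain(self.voxels)
        if self.boundary is None:
            self.boundary = boundary_shell(self.shape)

    @property
    def tensors(self) -> np.ndarray:
        return self.voxels


def boundary_shell(shape: tuple[int, int, int]) -> np.ndarray:
    b = np.zeros(shape, dtype=bool)
    b[[0, -1], :, :] = True
    b[:, [0, -1], :] = True
    b[:, :, [0, -1]] = True
    return b


def displacement_gradient(field: DisplacementField) -> np.ndarray:
    """Displacement gradient H[..., i, j] = du_i/dx_j (dimensionless).

    Second-order central differences scaled by the grid spacing; boundary
    planes use second-order one-sided differences. Requires at least three
    voxels per axis.
    """
    if any(n < 3 for n in field.shape):
        raise ValueError(f"gradient needs >= 3 voxels per axis, got shape {field.shape}")
    grad = np.empty(field.shape + (3, 3))
    for i in range(3):
        derivs = np.gradient(field.voxels[..., i], *field.spacing, edge_order=2)
        for j in range(3):
            grad[..., i, j] = derivs[j]
    return grad


def green_lagrange(grad: np.ndarray, like: GridRaster | None = None) -> StrainField | np.ndarray:
    """Green-Lagrange strain E = ((I+H)ᵀ(I+H) − I)/2 from a gradient field.

    Accepts any array of 3×3 matrices. With ``like`` (grid metadata donor)
    the result is wrapped as a :class:`StrainField`; otherwise the raw
    tensor array is returned.
    """
    grad = np.asarray(grad, dtype=float)
    if not np.isfinite(grad).all():
        raise ValueError("displacement gradient contains non-finite entries")
    ht = np.swapaxes(grad, -1, -2)
    e = 0.5 * (grad + ht + ht @ grad)
    e = 0.5 * (e + np.swapaxes(e, -1, -2))  # enforce exact symmetry against round-off
    if like is None:
        return e
    return StrainField(voxels=e, spacing=like.spacing, origin=like.origin, axis_codes=like.axis_codes)


def strain_from_field(field: DisplacementField) -> StrainField:
    """Convenience: displacement field -> Green-Lagrange strain field."""
    return green_lagrange(displacement_gradient(field), like=field)


def max_principal_strain(tensors: np.ndarray, atol_sym: float = 1e-8) -> np.ndarray:
    """Largest eigenvalue of each symmetric 3×3 tensor.

    Uses the closed-form trigonometric solution for symmetric 3×3
    matrices, fully vectorised; isotropic tensors are handled by the
    ``p -> 0`` limit.
    """
    t = np.asarray(tensors, dtype=float)
    if t.shape[-2:] != (3, 3):
        raise ValueError(f"expected trailing 3x3 matrices, got shape {t.shape}")
    asym = np.max(np.abs(t - np.swapaxes(t, -1, -2)))
    if asym > atol_sym:
        raise ValueError(f"tensor asymmetry {asym:.3e} exceeds tolerance {atol_sym:.0e}")

    a11, a22, a33 = t[..., 0, 0], t[..., 1, 1], t[..., 2, 2]
    a12, a13, a23 = t[..., 0, 1], t[..., 0, 2], t[..., 1, 2]
    q = (a11 + a22 + a33) / 3.0
    p2 = (a11 - q) ** 2 + (a22 - q) ** 2 + (a33 - q) ** 2 + 2.0 * (
        a12**2 + a13**2 + a23**2
    )
    p = np.sqrt(p2 / 6.0)

    safe_p = np.where(p > 0, p, 1.0)
    b11, b22, b33 = (a11 - q) / safe_p, (a22 - q) / safe_p, (a33 - q) / safe_p
    b12, b13, b23 = a12 / safe_p, a13 / safe_p, a23 / safe_p
    detb = (
        b11 * (b22 * b33 - b23**2)
        - b12 * (b12 * b33 - b23 * b13)
        + b13 * (b12 * b23 - b22 * b13)
    )
    r = np.clip(detb / 2.0, -1.0, 1.0)
    phi = np.arccos(r) / 3.0
    lam_max = q + 2.0 * p * np.cos(phi)
    return np.where(p > 0, lam_max, q)
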