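"""NIfTI input/output, resampling and affine alignment.

All volumes carry a 4x4 voxel-to-world affine (RAS+ millimetres); voxel
indices are 0-based, world coordinates, centroids and volumes are always
reported in world units (mm, cm^3).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage, optimize


class VolumeError(ValueError):
    """Raised for malformed volumes or files."""


@dataclass
class Volume3D:
    """A 3D scalar grid with world geometry.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Voxel intensities (arbitrary T2* units for MR volumes).
    affine : ndarray, shape (4, 4)
        Voxel index -> world (RAS+ mm) map.
    description : str
        Free-text provenance.
    """

    data: np.ndarray
    affine: np.ndarray
    description: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise VolumeError(
                f"expected a 3D volume, got {self.data.ndim} dimensions"
            )
        if self.affine.shape != (4, 4):
            raise VolumeError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise VolumeError("affine is singular")
        if not np.all(np.isfinite(self.data)):
            raise VolumeError("volume contains non-finite voxels")
        if np.any(self.spacing_mm <= 0):
            raise VolumeError("voxel spacing must be strictly positive")

    @property
    def spacing_mm(self) -> np.ndarray:
        """Voxel edge lengths in mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def index_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map voxel indices (n, 3) to world mm coordinates."""
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return (self.affine[:3, :3] @ ijk.T).T + self.affine[:3, 3]

    def world_to_index(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        inv = np.linalg.inv(self.affine)
        return (inv[:3, :3] @ xyz.T).T + inv[:3, 3]

    def copy(self, data: np.ndarray | None = None) -> "Volume3D":
        return Volume3D(
            data=self.data.copy() if data is None else data,
            affine=self.affine.copy(),
            description=self.description,
        )


@dataclass
class RigidAffineTransform:
    """World-mm to world-mm affine map (subject -> template)."""

    matrix: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (4, 4):
            raise VolumeError("transform matrix must be 4x4")
        if np.linalg.det(self.matrix[:3, :3]) <= 0:
            raise VolumeError("transform must be orientation preserving")

    def inverse(self) -> "RigidAffineTransform":
        return RigidAffineTransform(np.linalg.inv(self.matrix))

    def apply_points(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        return (self.matrix[:3, :3] @ xyz.T).T + self.matrix[:3, 3]


def read_volume(path) -> Volume3D:
    """Read a NIfTI-1 volume (.nii or .nii.gz).

    Raises
    ------
    VolumeError
        If the file is missing, not 3D, or contains non-finite voxels.
    """
    try:
        img = nib.load(str(path))
    except FileNotFoundError as exc:
        raise VolumeError(f"no such file: {path}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise VolumeError(
            f"{path}: expected a 3D image, file has {data.ndim} dimensions"
        )
    return Volume3D(
        data=np.asarray(data, dtype=np.float32),
        affine=np.asarray(img.affine, dtype=float),
        description=str(path),
    )


def write_volume(vol: Volume3D, path) -> None:
    """Write a volume as NIfTI-1 (gzip chosen by file extension)."""
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32), vol.affine)
    img.header.set_xyzt_units("mm")
    nib.save(img, str(path))


def _world_bounds(vol: Volume3D) -> tuple[np.ndarray, np.ndarray]:
    """Axis-aligned world bounding box of the voxel centres."""
    n = np.array(vol.shape) - 1
    corners = np.array(
        [[i, j, k] for i in (0, n[0]) for j in (0, n[1]) for k in (0, n[2])],
        dtype=float,
    )
    world = vol.index_to_world(corners)
    return world.min(axis=0), world.max(axis=0)


def resample_isotropic(
    vol: Volume3D, spacing: float = 1.5, order: str = "linear"
) -> Volume3D:
    """Resample to an isotropic grid aligned with the world axes.

    The output grid covers the input's world bounding box; intensities are
    interpolated linearly, masks/labels with nearest neighbour.
    """
    if spacing <= 0:
        raise VolumeError("spacing must be positive")
    interp = {"linear": 1, "nearest": 0}.get(order)
    if interp is None:
        raise VolumeError(f"unknown interpolation order {order!r}")
    lo, hi = _world_bounds(vol)
    n_out = np.maximum(1, np.floor((hi - lo) / spacing + 0.5).astype(int) + 1)
    out_affine = np.eye(4)
    out_affine[:3, :3] = np.diag([spacing] * 3)
    out_affine[:3, 3] = lo
    # voxel coords of the output grid in the input volume
    chain = np.linalg.inv(vol.affine) @ out_affine
    grid = np.indices(tuple(n_out), dtype=np.float32).reshape(3, -1)
    src = chain[:3, :3].astype(np.float32) @ grid + chain[:3, 3:4].astype(
        np.float32
    )
    out = ndimage.map_coordinates(
        np.asarray(vol.data, dtype=np.float32),
        src,
        order=interp,
        mode="nearest",  # the output grid lies inside the input bounding box
    ).reshape(tuple(n_out))
    return Volume3D(out, out_affine, description=vol.description)


def resample_like(
    vol: Volume3D,
    reference: Volume3D,
    order: str = "linear",
    transform: RigidAffineTransform | None = None,
) -> Volume3D:
    """Resample ``vol`` onto ``reference``'s grid, optionally through a
    world-to-world transform mapping ``vol`` space into reference space."""
    interp = {"linear": 1, "nearest": 0}[order]
    world_map = np.eye(4) if transform is None else np.linalg.inv(transform.matrix)
    chain = np.linalg.inv(vol.affine) @ world_map @ reference.affine
    grid = np.indices(reference.shape, dtype=np.float32).reshape(3, -1)
    src = chain[:3, :3].astype(np.float32) @ grid + chain[:3, 3:4].astype(
        np.float32
    )
    out = ndimage.map_coordinates(
        np.asarray(vol.data, dtype=np.float32),
        src,
        order=interp,
        mode="constant",
        cval=0.0,
    ).reshape(reference.shape)
    return Volume3D(out, reference.affine.copy(), description=vol.description)


def _params_to_matrix(p: np.ndarray, centre: np.ndarray) -> np.ndarray:
    """12-parameter affine: translation, rotation (deg), log-scale, shear,
    composed about ``centre``."""
    t = p[0:3]
    rx, ry, rz = np.deg2rad(p[3:6])
    s = np.exp(p[6:9]) if len(p) > 6 else np.ones(3)
    h = p[9:12] if len(p) > 9 else np.zeros(3)
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    Sh = np.array([[1, h[0], h[1]], [0, 1, h[2]], [0, 0, 1]])
    A = Rz @ Ry @ Rx @ Sh @ np.diag(s)
    M = np.eye(4)
    M[:3, :3] = A
    M[:3, 3] = t + centre - A @ centre
    return M


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)))


def _nmi(a: np.ndarray, b: np.ndarray, bins: int = 32) -> float:
    """Normalised mutual information (H(a)+H(b))/H(a,b)."""
    hist, _, _ = np.histogram2d(a, b, bins=bins)
    joint = hist / max(hist.sum(), 1.0)
    ha = _entropy(joint.sum(axis=1))
    hb = _entropy(joint.sum(axis=0))
    hab = _entropy(joint.ravel())
    if hab == 0:
        return 2.0
    return (ha + hb) / hab


def align_to_template(
    subject: Volume3D,
    template: Volume3D,
    working_spacing: float = 2.0,
) -> RigidAffineTransform:
    """Estimate the 12-parameter affine mapping subject world coordinates
    into template world coordinates by maximising normalised mutual
    information.

    Optimisation is staged (rigid then full affine) with Powell's method on
    volumes downsampled to ``working_spacing`` mm.

    Raises
    ------
    VolumeError
        If the optimiser fails to improve on the identity transform.
    """
    sub = resample_isotropic(subject, working_spacing)
    tpl = resample_isotropic(template, working_spacing)
    tpl_data = np.asarray(tpl.data, dtype=np.float32)
    centre = 0.5 * (np.array(_world_bounds(template)).sum(axis=0))

    def cost(p: np.ndarray) -> float:
        M = _params_to_matrix(np.asarray(p, dtype=float), centre)
        moved = resample_like(
            sub, tpl, order="linear", transform=RigidAffineTransform(M)
        )
        return -_nmi(tpl_data.ravel(), moved.data.ravel())

    x0 = np.zeros(6)
    res = optimize.minimize(
        cost, x0, method="Powell", options={"xtol": 1e-3, "ftol": 1e-6}
    )
    x = np.concatenate([res.x, np.zeros(6)])
    res2 = optimize.minimize(
        cost, x, method="Powell", options={"xtol": 1e-3, "ftol": 1e-6}
    )
    best = res2 if res2.fun <= res.fun else res
    if best.fun > cost(np.zeros(12)) + 1e-9:
        raise VolumeError(
            f"affine alignment failed to improve NMI (final metric {-best.fun:.4f})"
        )
    p = np.asarray(best.x, dtype=float)
    if p.size < 12:
        p = np.concatenate([p, np.zeros(12 - p.size)])
    return RigidAffineTransform(_params_to_matrix(p, centre))
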