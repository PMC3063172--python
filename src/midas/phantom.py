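"""Synthetic GRE T2* phantom generator.

Builds seedable 3D volumes that emulate a standard clinical T2*-weighted
acquisition (anisotropic 0.938 x 0.938 x 6.5 mm voxels: 5 mm slices plus a
1.5 mm gap, intensity averaged over the full 6.5 mm cell) together with
exact ground truth.  The head is modelled as nested ellipsoids — scalp
shell > skull shell > brain parenchyma > ventricular CSF — with per-tissue
mean intensities reproducing the T2* ordering seen clinically: CSF bright,
grey/white matter intermediate, microbleeds and skull dark.

Microbleeds are inserted as spheres with partial-volume weighting on the
anisotropic grid; common mimics (air-bone edge bands, vessel flow voids,
macrobleeds) are available as primitives.  Everything is deterministic
given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .io import Volume3D, write_volume

#: generative tissue labels
LABELS = {
    "background": 0,
    "scalp": 1,
    "skull": 2,
    "gwm": 3,
    "csf": 4,
    "cmb": 5,
    "mimic": 6,
}

#: default mean T2* intensities (arbitrary units); CSF > GWM > 2 * CMB
DEFAULT_TISSUE_MEANS = {
    "background": 5.0,
    "scalp": 120.0,
    "skull": 25.0,
    "gwm": 100.0,
    "csf": 180.0,
}

#: region codes used by the detection report
REGION_CODES = {"none": 0, "lobar": 1, "deep": 2, "infratentorial": 3}

# head geometry as fractions of the half field of view, so phantoms scale
# with the requested grid
_SCALP_FRAC = (0.97, 0.97, 0.99)
_SKULL_FRAC = (0.90, 0.90, 0.92)
_BRAIN_FRAC = (0.80, 0.80, 0.82)
_VENT_FRAC = (0.22, 0.30, 0.18)
_DEEP_FRAC = 0.38  # brain-relative radius bounding the deep region
_INFRA_FRAC = 0.55  # z below -0.55 * brain semi-axis is infratentorial


class PhantomError(ValueError):
    """Raised for invalid phantom specifications."""


@dataclass
class CMBSpec:
    """One synthetic microbleed: a dark sphere inside the parenchyma."""

    centre_mm: tuple[float, float, float]
    diameter_mm: float
    intensity_fraction: float = 0.3
    region_label: str = "lobar"


@dataclass
class PhantomSpec:
    """Parameters of one synthetic subject.

    ``voxel_size_mm`` defaults to the clinical acquisition geometry
    (0.938 x 0.938 x 6.5 mm).  Microbleed diameters must lie in the 2-10 mm
    range of definite microbleeds and their intensity fraction below 0.5 so
    that lesions stay darker than half the parenchyma, consistent with the
    segmentation constraint.
    """

    grid_shape: tuple[int, int, int] = (154, 154, 23)
    voxel_size_mm: tuple[float, float, float] = (0.938, 0.938, 6.5)
    tissue_means: dict = field(default_factory=lambda: dict(DEFAULT_TISSUE_MEANS))
    noise_sigma: float = 0.0
    bias_amplitude: float = 0.0
    cmb_list: list = field(default_factory=list)
    mimic_list: list = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.voxel_size_mm):
            raise PhantomError("voxel size must be strictly positive")
        if any(n < 1 for n in self.grid_shape):
            raise PhantomError("grid shape must be positive")
        if self.noise_sigma < 0 or self.bias_amplitude < 0:
            raise PhantomError("noise and bias amplitudes must be >= 0")
        for cmb in self.cmb_list:
            if not (2.0 <= cmb.diameter_mm <= 10.0):
                raise PhantomError(
                    f"CMB diameter {cmb.diameter_mm} mm outside the 2-10 mm range"
                )
            if not (0.0 < cmb.intensity_fraction < 0.5):
                raise PhantomError(
                    "CMB intensity_fraction must lie in (0, 0.5)"
                )


@dataclass
class LesionRecord:
    centre_mm: tuple[float, float, float]
    diameter_mm: float
    volume_cm3: float
    region_label: str
    n_voxels: int
    sub_voxel: bool


@dataclass
class GroundTruth:
    """Exact generative truth for one phantom."""

    cmb_mask: Volume3D
    tissue_label_map: Volume3D
    lesions: list
    bias_field: Volume3D | None = None

    def to_json(self) -> str:
        return json.dumps(
            [
                {
                    "centre_mm": list(les.centre_mm),
                    "diameter_mm": les.diameter_mm,
                    "volume_cm3": les.volume_cm3,
                    "region_label": les.region_label,
                    "n_voxels": les.n_voxels,
                    "sub_voxel": les.sub_voxel,
                }
                for les in self.lesions
            ],
            indent=2,
        )


@dataclass
class BiasFieldTruth:
    field: Volume3D
    coefficients: np.ndarray


# ---------------------------------------------------------------------------
# geometry helpers


def _affine(spec: PhantomSpec) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spec.voxel_size_mm)
    return aff


def _grid_mm(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Voxel-centre coordinates in mm relative to the grid centre."""
    out = []
    for n, s in zip(spec.grid_shape, spec.voxel_size_mm):
        out.append((np.arange(n) - (n - 1) / 2.0) * s)
    return tuple(np.asarray(a, dtype=np.float32) for a in out)


def _half_extent(spec: PhantomSpec) -> np.ndarray:
    return np.array(
        [n * s / 2.0 for n, s in zip(spec.grid_shape, spec.voxel_size_mm)]
    )


def brain_semi_axes(spec: PhantomSpec) -> np.ndarray:
    """Semi-axes (mm) of the brain ellipsoid for this grid."""
    return _half_extent(spec) * np.asarray(_BRAIN_FRAC)


def _ellipsoid(spec: PhantomSpec, semi: np.ndarray) -> np.ndarray:
    x, y, z = _grid_mm(spec)
    r2 = (
        (x[:, None, None] / semi[0]) ** 2
        + (y[None, :, None] / semi[1]) ** 2
        + (z[None, None, :] / semi[2]) ** 2
    )
    return r2 <= 1.0


def tissue_labels(spec: PhantomSpec) -> np.ndarray:
    """Generative tissue label volume (no lesions)."""
    half = _half_extent(spec)
    lab = np.full(spec.grid_shape, LABELS["background"], dtype=np.int16)
    lab[_ellipsoid(spec, half * np.asarray(_SCALP_FRAC))] = LABELS["scalp"]
    lab[_ellipsoid(spec, half * np.asarray(_SKULL_FRAC))] = LABELS["skull"]
    lab[_ellipsoid(spec, brain_semi_axes(spec))] = LABELS["gwm"]
    lab[_ellipsoid(spec, half * np.asarray(_VENT_FRAC))] = LABELS["csf"]
    return lab


def region_label_volume(spec: PhantomSpec) -> Volume3D:
    """Lobar / deep / infratentorial label volume matching the phantom.

    Deep = a central ellipsoid around the ventricles; infratentorial = the
    inferior cap of the brain; lobar = the remaining parenchyma.
    """
    semi = brain_semi_axes(spec)
    x, y, z = _grid_mm(spec)
    brain = _ellipsoid(spec, semi)
    r2 = (
        (x[:, None, None] / semi[0]) ** 2
        + (y[None, :, None] / semi[1]) ** 2
        + (z[None, None, :] / semi[2]) ** 2
    )
    lab = np.zeros(spec.grid_shape, dtype=np.int16)
    lab[brain] = REGION_CODES["lobar"]
    deep = brain & (r2 <= _DEEP_FRAC**2)
    lab[deep] = REGION_CODES["deep"]
    infra = brain & (z[None, None, :] < -_INFRA_FRAC * semi[2])
    lab[infra] = REGION_CODES["infratentorial"]
    return Volume3D(lab.astype(np.float32), _affine(spec), "region labels")


def _centre_world(spec: PhantomSpec, centre_mm) -> np.ndarray:
    """Convert a centre given relative to the head centre into world mm of
    the phantom affine (index * spacing)."""
    half0 = np.array(
        [(n - 1) * s / 2.0 for n, s in zip(spec.grid_shape, spec.voxel_size_mm)]
    )
    return np.asarray(centre_mm, dtype=float) + half0


# ---------------------------------------------------------------------------
# lesion insertion


def _sphere_occupancy(
    shape: tuple[int, int, int],
    spacing: np.ndarray,
    centre_vox: np.ndarray,
    radius_mm: float,
    supersample: int | None = None,
) -> tuple[tuple, np.ndarray]:
    """Fractional sphere occupancy of each voxel near the sphere.

    Returns (index arrays, occupancy in [0, 1]) for voxels with non-zero
    occupancy, computed by subdividing each candidate voxel into subcells.
    """
    spacing = np.asarray(spacing, dtype=float)
    lo = np.maximum(0, np.floor(centre_vox - radius_mm / spacing - 1).astype(int))
    hi = np.minimum(
        np.array(shape) - 1,
        np.ceil(centre_vox + radius_mm / spacing + 1).astype(int),
    )
    if np.any(lo > hi):
        return (np.array([], int),) * 3, np.array([])
    sub = (
        np.maximum(2, np.minimum(12, np.ceil(spacing / 0.45).astype(int)))
        if supersample is None
        else np.full(3, supersample, int)
    )
    axes_idx = [np.arange(lo[d], hi[d] + 1) for d in range(3)]
    # subcell centre offsets (voxel units) per axis
    offs = [
        (np.arange(sub[d]) + 0.5) / sub[d] - 0.5 for d in range(3)
    ]
    # distances in mm for every (voxel, subcell) combination, per axis
    dist2 = []
    for d in range(3):
        pos = (axes_idx[d][:, None] + offs[d][None, :] - centre_vox[d]) * spacing[d]
        dist2.append(pos**2)
    # accumulate occupancy: sum over subcells of inside-sphere indicator
    r2 = radius_mm**2
    d2 = (
        dist2[0][:, None, None, :, None, None]
        + dist2[1][None, :, None, None, :, None]
        + dist2[2][None, None, :, None, None, :]
    )
    inside = d2 <= r2
    occ = inside.reshape(
        len(axes_idx[0]), len(axes_idx[1]), len(axes_idx[2]), -1
    ).mean(axis=-1)
    nz = np.nonzero(occ > 0)
    idx = tuple(axes_idx[d][nz[d]] for d in range(3))
    return idx, occ[nz]


def insert_cmb(
    vol: Volume3D,
    centre_mm,
    diameter_mm: float,
    intensity_fraction: float,
) -> Volume3D:
    """Insert one spherical hypointensity with partial-volume weighting.

    Voxel intensities inside the sphere are multiplied towards
    ``intensity_fraction`` of their local value, weighted by the voxel's
    fractional sphere occupancy:  v' = v * (1 - occ * (1 - f)).
    """
    if diameter_mm <= 0:
        raise PhantomError("CMB diameter must be positive")
    if not (0.0 < intensity_fraction <= 1.0):
        raise PhantomError("intensity_fraction must lie in (0, 1]")
    out = vol.copy()
    centre_vox = vol.world_to_index(np.asarray(centre_mm, dtype=float))[0]
    idx, occ = _sphere_occupancy(
        vol.shape, vol.spacing_mm, centre_vox, diameter_mm / 2.0
    )
    if len(occ):
        out.data[idx] = out.data[idx] * (1.0 - occ * (1.0 - intensity_fraction))
    return out


# ---------------------------------------------------------------------------
# bias field


def _poly_basis(shape, order: int = 2) -> np.ndarray:
    """Monomial basis (n_terms, *shape) on coordinates normalised to [-1, 1]."""
    coords = [
        (2.0 * np.arange(n) / max(n - 1, 1) - 1.0).astype(np.float32)
        for n in shape
    ]
    X = coords[0][:, None, None]
    Y = coords[1][None, :, None]
    Z = coords[2][None, None, :]
    terms = []
    for i in range(order + 1):
        for j in range(order + 1 - i):
            for k in range(order + 1 - i - j):
                terms.append((X**i) * (Y**j) * (Z**k) * np.ones(shape, np.float32))
    return np.stack(terms)


def apply_bias_field(
    vol: Volume3D,
    amplitude: float,
    seed: int,
    mask: np.ndarray | None = None,
) -> tuple[Volume3D, BiasFieldTruth]:
    """Multiply by a smooth random field exp(f).

    ``f`` is a random second-order 3D polynomial, mean-centred over ``mask``
    (the brain, when supplied) and scaled so that the maximum of
    ``|field - 1|`` over the grid equals ``amplitude`` exactly.
    """
    if amplitude < 0:
        raise PhantomError("bias amplitude must be >= 0")
    ones = np.ones(vol.shape, dtype=np.float32)
    if amplitude == 0:
        truth = BiasFieldTruth(
            Volume3D(ones, vol.affine.copy(), "bias field"), np.zeros(9)
        )
        return vol.copy(), truth
    rng = np.random.default_rng(seed)
    basis = _poly_basis(vol.shape, order=2)[1:]  # drop the constant term
    coeff = rng.standard_normal(basis.shape[0])
    f = np.tensordot(coeff, basis, axes=(0, 0)).astype(np.float64)
    m = np.ones(vol.shape, bool) if mask is None else np.asarray(mask, bool)
    f -= f[m].mean()
    fmax, fmin = float(f.max()), float(f.min())

    def overshoot(s: float) -> float:
        return max(np.expm1(s * fmax), -np.expm1(s * fmin)) - amplitude

    from scipy.optimize import brentq

    hi = 1.0
    while overshoot(hi) < 0:
        hi *= 2.0
    s = brentq(overshoot, 0.0, hi, xtol=1e-12)
    fld = np.exp(s * f).astype(np.float32)
    out = vol.copy(data=(vol.data * fld).astype(np.float32))
    truth = BiasFieldTruth(
        Volume3D(fld, vol.affine.copy(), "bias field"), s * coeff
    )
    return out, truth


# ---------------------------------------------------------------------------
# mimics


def _apply_mimics(spec: PhantomSpec, data: np.ndarray, labels: np.ndarray) -> None:
    """Paint artefact primitives into the intensity volume in place."""
    x, y, z = _grid_mm(spec)
    semi = brain_semi_axes(spec)
    for mimic in spec.mimic_list:
        kind = mimic["kind"]
        frac = float(mimic.get("intensity_fraction", 0.3))
        if kind == "edge_band":
            # air-bone susceptibility band at the inferior brain edge
            thick = float(mimic.get("thickness_mm", 6.0))
            r2 = (
                (x[:, None, None] / semi[0]) ** 2
                + (y[None, :, None] / semi[1]) ** 2
                + (z[None, None, :] / semi[2]) ** 2
            )
            band = (
                (r2 <= 1.0)
                & (r2 >= (1.0 - thick / semi.mean()) ** 2)
                & (z[None, None, :] < -0.3 * semi[2])
            )
            data[band] *= frac
            labels[band & (labels == LABELS["gwm"])] = LABELS["mimic"]
        elif kind == "vessel":
            # straight dark tube (flow void) through the parenchyma
            p0 = np.asarray(mimic.get("start_mm", (-30.0, 0.0, 0.0)))
            p1 = np.asarray(mimic.get("end_mm", (30.0, 10.0, 5.0)))
            radius = float(mimic.get("radius_mm", 1.2))
            pts = np.stack(
                np.meshgrid(x, y, z, indexing="ij"), axis=-1
            ).reshape(-1, 3)
            d = p1 - p0
            t = np.clip(((pts - p0) @ d) / (d @ d), 0.0, 1.0)
            dist = np.linalg.norm(pts - (p0 + t[:, None] * d), axis=1)
            tube = (dist <= radius).reshape(spec.grid_shape)
            inside = tube & (labels == LABELS["gwm"])
            data[inside] *= frac
            labels[inside] = LABELS["mimic"]
        elif kind == "macrobleed":
            centre = np.asarray(mimic.get("centre_mm", (0.0, 0.0, 0.0)))
            diameter = float(mimic.get("diameter_mm", 12.0))
            r2 = (
                (x[:, None, None] - centre[0]) ** 2
                + (y[None, :, None] - centre[1]) ** 2
                + (z[None, None, :] - centre[2]) ** 2
            )
            blob = (r2 <= (diameter / 2.0) ** 2) & (labels == LABELS["gwm"])
            data[blob] *= frac
            labels[blob] = LABELS["mimic"]
        else:
            raise PhantomError(f"unknown mimic kind {kind!r}")


# ---------------------------------------------------------------------------
# phantom assembly


def make_phantom(spec: PhantomSpec) -> tuple[Volume3D, GroundTruth]:
    """Generate one synthetic T2* volume with its ground truth.

    Lesion centres are given in mm relative to the head centre.  A lesion
    centre outside the brain ellipsoid is rejected with a diagnostic.
    Bias is applied before noise; both derive from ``spec.seed``.
    """
    affine = _affine(spec)
    labels = tissue_labels(spec)
    label_names = {v: k for k, v in LABELS.items()}
    data = np.empty(spec.grid_shape, dtype=np.float32)
    for name, mean in spec.tissue_means.items():
        data[labels == LABELS[name]] = mean

    _apply_mimics(spec, data, labels)

    semi = brain_semi_axes(spec)
    vol = Volume3D(data, affine, f"phantom seed={spec.seed}")
    cmb_mask = np.zeros(spec.grid_shape, dtype=bool)
    lesions: list[LesionRecord] = []
    voxvol_cm3 = vol.voxel_volume_mm3 / 1000.0
    for cmb in spec.cmb_list:
        c = np.asarray(cmb.centre_mm, dtype=float)
        if np.sum((c / semi) ** 2) > 1.0:
            raise PhantomError(
                f"CMB centre {tuple(c)} mm lies outside the brain ellipsoid "
                f"(semi-axes {np.round(semi, 1).tolist()} mm)"
            )
        world = _centre_world(spec, cmb.centre_mm)
        centre_vox = vol.world_to_index(world)[0]
        idx, occ = _sphere_occupancy(
            vol.shape, vol.spacing_mm, centre_vox, cmb.diameter_mm / 2.0
        )
        vol.data[idx] *= 1.0 - occ * (1.0 - cmb.intensity_fraction)
        # ground-truth mask: voxels at least half covered by the sphere; a
        # lesion whose partial-volume amplitude stays below half the local
        # contrast everywhere is recorded as sub-voxel
        core = occ >= 0.5
        sub_voxel = not np.any(occ * (1.0 - cmb.intensity_fraction) >= 0.5 * (1.0 - cmb.intensity_fraction))
        mask_idx = tuple(a[core] for a in idx)
        cmb_mask[mask_idx] = True
        labels[mask_idx] = LABELS["cmb"]
        lesions.append(
            LesionRecord(
                centre_mm=tuple(np.asarray(world, float)),
                diameter_mm=cmb.diameter_mm,
                volume_cm3=int(core.sum()) * voxvol_cm3,
                region_label=cmb.region_label,
                n_voxels=int(core.sum()),
                sub_voxel=sub_voxel or not np.any(core),
            )
        )

    bias_truth = None
    if spec.bias_amplitude > 0:
        brain = labels >= LABELS["gwm"]
        vol, bias_truth = apply_bias_field(
            vol, spec.bias_amplitude, seed=spec.seed + 7919, mask=brain
        )
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        vol.data += rng.normal(
            0.0, spec.noise_sigma, size=spec.grid_shape
        ).astype(np.float32)

    gt = GroundTruth(
        cmb_mask=Volume3D(cmb_mask.astype(np.float32), affine, "cmb truth"),
        tissue_label_map=Volume3D(
            labels.astype(np.float32), affine, "tissue labels"
        ),
        lesions=lesions,
        bias_field=None if bias_truth is None else bias_truth.field,
    )
    gt.label_names = label_names
    return vol, gt


def sample_lobar_cmbs(
    spec: PhantomSpec,
    n: int,
    rng: np.random.Generator,
    diameter_range: tuple[float, float] = (4.0, 8.0),
    intensity_fraction: float = 0.3,
) -> list[CMBSpec]:
    """Draw ``n`` non-overlapping lobar lesion positions for this geometry.

    Centres land in the lobar shell (radius fraction 0.45-0.70 of the brain
    ellipsoid, above the infratentorial cut), clear of the ventricles and
    skull.
    """
    semi = brain_semi_axes(spec)
    out: list[CMBSpec] = []
    guard = 0
    while len(out) < n:
        guard += 1
        if guard > 2000:
            raise PhantomError("could not place the requested lesions")
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        rad = rng.uniform(0.45, 0.70)
        c = u * rad * semi
        if c[2] < -0.45 * semi[2]:  # stay clear of the infratentorial cap
            continue
        d = rng.uniform(*diameter_range)
        if any(
            np.linalg.norm(np.asarray(o.centre_mm) - c) < (o.diameter_mm + d)
            for o in out
        ):
            continue
        out.append(
            CMBSpec(
                centre_mm=tuple(c),
                diameter_mm=float(d),
                intensity_fraction=intensity_fraction,
                region_label="lobar",
            )
        )
    return out


def clinical_spec(seed: int = 0, **kwargs) -> PhantomSpec:
    """PhantomSpec with the clinical anisotropic acquisition geometry."""
    return PhantomSpec(seed=seed, **kwargs)


def isotropic_spec(seed: int = 0, spacing: float = 1.5, **kwargs) -> PhantomSpec:
    """PhantomSpec on an isotropic research-style grid."""
    n = int(round(144.0 / spacing))
    return PhantomSpec(
        grid_shape=(n, n, n),
        voxel_size_mm=(spacing, spacing, spacing),
        seed=seed,
        **kwargs,
    )


def save_phantom(vol: Volume3D, gt: GroundTruth, out_dir) -> None:
    """Write the phantom, truth mask, label map and lesion table."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_volume(vol, out / "t2star.nii.gz")
    write_volume(gt.cmb_mask, out / "cmb_truth.nii.gz")
    write_volume(gt.tissue_label_map, out / "tissue_labels.nii.gz")
    (out / "lesions.json").write_text(gt.to_json())
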