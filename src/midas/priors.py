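"""Six-class tissue prior construction and refinement.

The segmentation uses six spatial priors on the working grid: GWM (grey and
white matter merged — T2* barely separates them), CSF, the empirical CMB
"extra" class, skull (dark voxels around the brain), scalp, and background
("other").  The CMB prior starts flat (0.1 inside the brain, 0 outside:
microbleeds may appear anywhere in the parenchyma) and is replaced between
iterations by the cleaned first-pass posterior.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io import Volume3D

CLASS_NAMES = ("gwm", "csf", "cmb", "skull", "scalp", "other")


class PriorError(ValueError):
    pass


@dataclass
class TissuePriorSet:
    """Aligned per-voxel probabilities for the six tissue classes.

    Invariants: probabilities in [0, 1], per-voxel sum 1 (within 1e-6), and
    the CMB prior identically zero outside ``brain_mask``.
    """

    maps: dict
    brain_mask: np.ndarray
    affine: np.ndarray
    floor: float = 1e-6

    def __post_init__(self) -> None:
        missing = set(CLASS_NAMES) - set(self.maps)
        if missing:
            raise PriorError(f"missing prior classes: {sorted(missing)}")
        shapes = {m.shape for m in self.maps.values()}
        if len(shapes) != 1 or self.brain_mask.shape not in shapes:
            raise PriorError("prior maps are not on a common grid")

    @property
    def shape(self):
        return self.brain_mask.shape

    def stack(self) -> np.ndarray:
        """(6, nx, ny, nz) array in CLASS_NAMES order."""
        return np.stack([self.maps[k] for k in CLASS_NAMES])

    def copy(self) -> "TissuePriorSet":
        return TissuePriorSet(
            maps={k: v.copy() for k, v in self.maps.items()},
            brain_mask=self.brain_mask.copy(),
            affine=self.affine.copy(),
            floor=self.floor,
        )


def _renormalise(stack: np.ndarray, supports: np.ndarray, floor: float) -> np.ndarray:
    """Apply the probability floor inside each class's support and rescale
    every voxel to sum exactly 1.  Idempotent."""
    stack = np.clip(stack, 0.0, None)
    stack = np.where(supports & (stack < floor), floor, stack)
    stack = np.where(~supports, 0.0, stack)
    total = stack.sum(axis=0)
    total = np.where(total <= 0, 1.0, total)
    return stack / total


def build_prior_set(
    gm: Volume3D,
    wm: Volume3D,
    csf: Volume3D,
    skull: Volume3D,
    scalp: Volume3D,
    brain_mask: np.ndarray,
    cmb_prior_value: float = 0.1,
    floor: float = 1e-6,
) -> TissuePriorSet:
    """Assemble the six-class prior set from anatomical maps.

    GWM is the sum of the GM and WM priors; the CMB prior is flat
    (``cmb_prior_value``) inside the brain mask and zero outside; "other"
    takes the per-voxel complement.  All six are then renormalised to sum 1
    per voxel with a small probability floor inside each class's support.
    """
    vols = dict(gm=gm, wm=wm, csf=csf, skull=skull, scalp=scalp)
    shapes = {tuple(v.shape) for v in vols.values()}
    if len(shapes) != 1:
        raise PriorError("input prior maps are on different grids")
    for name, v in vols.items():
        if np.any(v.data < 0) or np.any(v.data > 1 + 1e-6):
            raise PriorError(f"{name} prior has values outside [0, 1]")
    brain_mask = np.asarray(brain_mask, bool)
    if brain_mask.shape != gm.data.shape:
        raise PriorError("brain mask grid does not match the priors")

    gwm = np.clip(gm.data + wm.data, 0.0, 1.0).astype(np.float64)
    cmb = np.where(brain_mask, cmb_prior_value, 0.0)
    partial = np.stack(
        [gwm, csf.data.astype(np.float64), cmb,
         skull.data.astype(np.float64), scalp.data.astype(np.float64)]
    )
    other = np.clip(1.0 - partial.sum(axis=0), 0.0, 1.0)
    stack = np.concatenate([partial[:2], partial[2:3], partial[3:], other[None]])
    # order: gwm, csf, cmb, skull, scalp, other
    supports = np.stack(
        [
            stack[0] > 0,
            stack[1] > 0,
            brain_mask,
            stack[3] > 0,
            stack[4] > 0,
            np.ones_like(brain_mask),
        ]
    )
    stack = _renormalise(stack, supports, floor)
    return TissuePriorSet(
        maps={k: stack[i] for i, k in enumerate(CLASS_NAMES)},
        brain_mask=brain_mask,
        affine=gm.affine.copy(),
        floor=floor,
    )


def refine_cmb_prior(
    priors: TissuePriorSet, cleaned_cmb_map: Volume3D | np.ndarray
) -> TissuePriorSet:
    """Second-iteration priors: swap in the cleaned CMB map.

    The CMB class is replaced by the cleaned (probabilistic) map; the other
    five classes are unchanged and the set is renormalised per voxel.
    Voxels where the cleaned map is zero get a hard-zero CMB prior, so the
    second pass can never introduce candidate territory the first pass did
    not propose — it is strictly more specific.
    """
    cleaned = np.asarray(
        cleaned_cmb_map.data
        if isinstance(cleaned_cmb_map, Volume3D)
        else cleaned_cmb_map,
        dtype=np.float64,
    )
    if cleaned.shape != priors.shape:
        raise PriorError("cleaned CMB map grid does not match the priors")
    if np.any(cleaned < 0) or np.any(cleaned > 1 + 1e-6):
        raise PriorError("cleaned CMB map must lie in [0, 1]")
    cleaned = np.where(priors.brain_mask, cleaned, 0.0)
    stack = priors.stack().astype(np.float64)
    icmb = CLASS_NAMES.index("cmb")
    stack[icmb] = cleaned
    supports = np.stack(
        [m > 0 for m in stack[:icmb]]
        + [cleaned > 0]
        + [m > 0 for m in stack[icmb + 1 : -1]]
        + [np.ones(priors.shape, bool)]
    )
    stack = _renormalise(stack, supports, priors.floor)
    return TissuePriorSet(
        maps={k: stack[i] for i, k in enumerate(CLASS_NAMES)},
        brain_mask=priors.brain_mask.copy(),
        affine=priors.affine.copy(),
        floor=priors.floor,
    )


@dataclass
class PriorReport:
    checks: dict = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return all(self.checks.values())

    def failures(self) -> list:
        return [k for k, v in self.checks.items() if not v]


def validate_priors(priors: TissuePriorSet) -> PriorReport:
    """Check every prior-set invariant; returns a pass/fail report."""
    stack = priors.stack()
    rep = PriorReport()
    rep.checks["values_in_unit_interval"] = bool(
        np.all(stack >= 0) and np.all(stack <= 1 + 1e-9)
    )
    rep.checks["per_voxel_sum_is_one"] = bool(
        np.all(np.abs(stack.sum(axis=0) - 1.0) <= 1e-6)
    )
    rep.checks["cmb_zero_outside_brain"] = bool(
        np.all(priors.maps["cmb"][~priors.brain_mask] == 0)
    )
    rep.checks["finite"] = bool(np.all(np.isfinite(stack)))
    return rep


def priors_from_labels(
    label_map: Volume3D,
    label_codes: dict | None = None,
    fwhm_mm: float = 8.0,
    cmb_prior_value: float = 0.1,
    floor: float = 1e-6,
) -> TissuePriorSet:
    """Build a prior set from a generative tissue label volume.

    Binary per-class maps are smoothed with a Gaussian kernel of the given
    FWHM (mm), emulating population-average template priors; the CMB prior
    is flat inside the brain.  Used with phantom label maps so the pipeline
    is testable without shipped templates.  Lesion/mimic labels are folded
    into parenchyma — the priors must not know the lesions.
    """
    from .phantom import LABELS as PHANTOM_LABELS

    codes = dict(PHANTOM_LABELS if label_codes is None else label_codes)
    lab = np.asarray(label_map.data)
    spacing = label_map.spacing_mm
    sigma_vox = (fwhm_mm / 2.3548) / spacing

    def smooth(binary: np.ndarray) -> Volume3D:
        sm = ndimage.gaussian_filter(binary.astype(np.float32), sigma_vox)
        return Volume3D(np.clip(sm, 0, 1), label_map.affine.copy())

    parenchyma = (lab == codes["gwm"])
    for extra in ("cmb", "mimic"):
        if extra in codes:
            parenchyma |= lab == codes[extra]
    csf_bin = lab == codes["csf"]
    brain_mask = parenchyma | csf_bin
    zeros = Volume3D(
        np.zeros(lab.shape, np.float32), label_map.affine.copy()
    )
    return build_prior_set(
        gm=smooth(parenchyma),
        wm=zeros,
        csf=smooth(csf_bin),
        skull=smooth(lab == codes["skull"]),
        scalp=smooth(lab == codes["scalp"]),
        brain_mask=brain_mask,
        cmb_prior_value=cmb_prior_value,
        floor=floor,
    )


def save_priors(priors: TissuePriorSet, out_dir) -> None:
    """Write the six maps as NIfTI plus a JSON manifest naming the classes."""
    import json
    from pathlib import Path

    from .io import write_volume

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name in CLASS_NAMES:
        write_volume(
            Volume3D(priors.maps[name].astype(np.float32), priors.affine),
            out / f"prior_{name}.nii.gz",
        )
    write_volume(
        Volume3D(priors.brain_mask.astype(np.float32), priors.affine),
        out / "brain_mask.nii.gz",
    )
    (out / "manifest.json").write_text(
        json.dumps({"classes": list(CLASS_NAMES), "floor": priors.floor})
    )


def load_priors(in_dir) -> TissuePriorSet:
    import json
    from pathlib import Path

    from .io import read_volume

    src = Path(in_dir)
    manifest = json.loads((src / "manifest.json").read_text())
    maps = {}
    affine = None
    for name in manifest["classes"]:
        vol = read_volume(src / f"prior_{name}.nii.gz")
        maps[name] = np.asarray(vol.data, dtype=np.float64)
        affine = vol.affine
    brain = read_volume(src / "brain_mask.nii.gz").data > 0.5
    stack = np.stack([maps[k] for k in CLASS_NAMES])
    supports = stack > 0
    supports[-1] = True
    stack = _renormalise(stack, supports, manifest.get("floor", 1e-6))
    return TissuePriorSet(
        maps={k: stack[i] for i, k in enumerate(CLASS_NAMES)},
        brain_mask=brain,
        affine=affine,
        floor=manifest.get("floor", 1e-6),
    )
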