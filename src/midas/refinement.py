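"""Morphological refinement of the first-pass CMB posterior.

The candidate map is cleaned in a fixed order: binarisation (0.2
threshold), connected-component labelling (26-connectivity), size
filtering (at least 2 contiguous voxels, at most 0.675 cm^3 — a cylinder
two slices high by 8 mm diameter, the upper bound separating microbleeds
from macrobleeds), skull masking, exclusion of CSF voxels and their
nearest neighbours, and finally removal of components overlapping the
control-derived artefact mask.  Every discarded candidate carries exactly
one discard reason, so the report is a complete audit trail.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .io import Volume3D

DISCARD_REASONS = (
    "too_large",
    "too_small",
    "skull",
    "csf_neighbour",
    "artefact_mask",
)

_STRUCT_26 = np.ones((3, 3, 3), bool)
_STRUCT_6 = ndimage.generate_binary_structure(3, 1)


@dataclass
class CMBComponent:
    """One connected candidate lesion."""

    id: int
    voxels: np.ndarray  # (n, 3) integer indices
    volume_cm3: float
    centroid_mm: np.ndarray
    peak_posterior: float
    bbox: tuple  # ((i0, i1), (j0, j1), (k0, k1)) inclusive
    region: str | None = None
    discard_reason: str | None = None

    @property
    def n_voxels(self) -> int:
        return int(len(self.voxels))

    @property
    def kept(self) -> bool:
        return self.discard_reason is None


@dataclass
class ArtefactMask:
    """Union of pipeline detections over healthy controls, marking
    recurrent false-positive territory (air-bone interfaces etc.)."""

    mask: np.ndarray
    affine: np.ndarray
    provenance: list = field(default_factory=list)

    @classmethod
    def empty(cls, shape, affine) -> "ArtefactMask":
        return cls(np.zeros(shape, bool), np.asarray(affine, float), [])

    def union(self, other_mask: np.ndarray, control_id: str) -> "ArtefactMask":
        return ArtefactMask(
            self.mask | np.asarray(other_mask, bool),
            self.affine,
            self.provenance + [control_id],
        )


def binarise_posterior(
    cmb_posterior: Volume3D | np.ndarray, threshold: float = 0.2
) -> np.ndarray:
    """Inclusive threshold: a voxel is a candidate iff posterior >= t."""
    data = (
        cmb_posterior.data
        if isinstance(cmb_posterior, Volume3D)
        else np.asarray(cmb_posterior)
    )
    if np.any(data < -1e-9) or np.any(data > 1 + 1e-6):
        raise ValueError("posterior values must lie in [0, 1]")
    return data >= threshold


def _measure(
    ids: np.ndarray,
    voxels: np.ndarray,
    affine: np.ndarray,
    posterior: np.ndarray | None,
) -> CMBComponent:
    vox_vol_cm3 = abs(np.linalg.det(affine[:3, :3])) / 1000.0
    centroid_vox = voxels.mean(axis=0)
    centroid_mm = affine[:3, :3] @ centroid_vox + affine[:3, 3]
    peak = (
        float(posterior[tuple(voxels.T)].max()) if posterior is not None else 1.0
    )
    bbox = tuple(
        (int(voxels[:, d].min()), int(voxels[:, d].max())) for d in range(3)
    )
    return CMBComponent(
        id=int(ids),
        voxels=voxels,
        volume_cm3=float(len(voxels) * vox_vol_cm3),
        centroid_mm=np.asarray(centroid_mm, float),
        peak_posterior=peak,
        bbox=bbox,
    )


def label_components(
    mask: np.ndarray,
    affine: np.ndarray,
    posterior: np.ndarray | None = None,
    connectivity: int = 26,
    start_id: int = 1,
) -> list:
    """Maximal connected components of a binary mask.

    Volumes (cm^3) and centroids (world mm) are computed from the affine;
    ``peak_posterior`` is read from ``posterior`` when given.
    """
    struct = {26: _STRUCT_26, 6: _STRUCT_6}.get(connectivity)
    if struct is None:
        raise ValueError("connectivity must be 6 or 26")
    lab, n = ndimage.label(np.asarray(mask, bool), structure=struct)
    comps = []
    if n:
        objects = ndimage.find_objects(lab)
        for i, sl in enumerate(objects, start=1):
            local = np.argwhere(lab[sl] == i)
            offset = np.array([s.start for s in sl])
            comps.append(
                _measure(
                    start_id + i - 1, local + offset, np.asarray(affine), posterior
                )
            )
    return comps


def filter_by_size(
    components: list,
    min_voxels: int = 2,
    max_volume_cm3: float = 0.675,
) -> list:
    """Granulometric size filter.

    Components strictly larger than ``max_volume_cm3`` are marked
    ``too_large`` (macrobleed territory); components with fewer than
    ``min_voxels`` voxels are marked ``too_small``.
    """
    out = []
    for c in components:
        if not c.kept:
            out.append(c)
        elif c.volume_cm3 > max_volume_cm3:
            out.append(replace(c, discard_reason="too_large"))
        elif c.n_voxels < min_voxels:
            out.append(replace(c, discard_reason="too_small"))
        else:
            out.append(c)
    return out


def _remove_voxels(
    components: list,
    removal: np.ndarray,
    reason: str,
    affine: np.ndarray,
    posterior: np.ndarray | None,
    connectivity: int = 26,
) -> list:
    """Subtract a removal mask from kept components.

    A component emptied by the subtraction is discarded with ``reason``;
    a partially overlapping component keeps its surviving voxels, which
    are re-labelled (they may split) and re-measured.
    """
    out = []
    next_id = max((c.id for c in components), default=0) + 1
    for c in components:
        if not c.kept:
            out.append(c)
            continue
        hit = removal[tuple(c.voxels.T)]
        if not hit.any():
            out.append(c)
            continue
        if hit.all():
            out.append(replace(c, discard_reason=reason))
            continue
        # rebuild the surviving part within the component bounding box
        keep_vox = c.voxels[~hit]
        sub = np.zeros(removal.shape, bool)
        sub[tuple(keep_vox.T)] = True
        pieces = label_components(
            sub, affine, posterior, connectivity, start_id=c.id
        )
        for j, p in enumerate(pieces):
            out.append(replace(p, id=c.id if j == 0 else next_id))
            if j > 0:
                next_id += 1
    return out


def mask_skull(
    components: list,
    skull_posterior: np.ndarray,
    affine: np.ndarray,
    cmb_posterior: np.ndarray | None = None,
    threshold: float = 0.5,
    connectivity: int = 26,
) -> list:
    """Remove voxels inside the skull class (posterior >= threshold);
    components fully inside the skull territory are discarded."""
    removal = np.asarray(skull_posterior) >= threshold
    return _remove_voxels(
        components, removal, "skull", affine, cmb_posterior, connectivity
    )


def exclude_csf_neighbours(
    components: list,
    csf_posterior: np.ndarray,
    affine: np.ndarray,
    cmb_posterior: np.ndarray | None = None,
    threshold: float = 0.5,
    neighbour_connectivity: int = 6,
    connectivity: int = 26,
) -> list:
    """Remove voxels with high CSF probability (> threshold, strict) and
    their nearest neighbours (one dilation, 6-connected by default)."""
    struct = _STRUCT_6 if neighbour_connectivity == 6 else _STRUCT_26
    csf = np.asarray(csf_posterior) > threshold
    removal = ndimage.binary_dilation(csf, structure=struct)
    return _remove_voxels(
        components, removal, "csf_neighbour", affine, cmb_posterior, connectivity
    )


def apply_artefact_mask(components: list, mask: ArtefactMask) -> list:
    """Discard any component sharing at least one voxel with the artefact
    mask (whole-component discard)."""
    out = []
    for c in components:
        if c.kept and mask.mask[tuple(c.voxels.T)].any():
            out.append(replace(c, discard_reason="artefact_mask"))
        else:
            out.append(c)
    return out


def components_to_mask(
    components: list, shape, kept_only: bool = True
) -> np.ndarray:
    out = np.zeros(shape, bool)
    for c in components:
        if c.kept or not kept_only:
            out[tuple(c.voxels.T)] = True
    return out


def cleaned_posterior_map(
    components: list, cmb_posterior: np.ndarray
) -> np.ndarray:
    """CMB posterior restricted to surviving components (probabilistic,
    not binarised) — the second-iteration empirical prior."""
    keep = components_to_mask(components, cmb_posterior.shape)
    return np.where(keep, cmb_posterior, 0.0)


def refine_candidates(
    cmb_posterior: np.ndarray,
    skull_posterior: np.ndarray,
    csf_posterior: np.ndarray,
    affine: np.ndarray,
    artefact_mask: ArtefactMask | None = None,
    binarise_threshold: float = 0.2,
    min_voxels: int = 2,
    max_volume_cm3: float = 0.675,
    skull_threshold: float = 0.5,
    csf_threshold: float = 0.5,
    connectivity: int = 26,
    neighbour_connectivity: int = 6,
) -> tuple[list, np.ndarray]:
    """Full refinement cascade in the fixed order: binarise -> label ->
    size filter -> skull mask -> CSF-neighbour exclusion -> artefact mask.

    Returns the audited component list and the cleaned probabilistic CMB
    map for the second iteration.
    """
    mask = binarise_posterior(cmb_posterior, binarise_threshold)
    comps = label_components(
        mask, affine, posterior=cmb_posterior, connectivity=connectivity
    )
    comps = filter_by_size(comps, min_voxels, max_volume_cm3)
    comps = mask_skull(
        comps, skull_posterior, affine, cmb_posterior, skull_threshold,
        connectivity,
    )
    comps = exclude_csf_neighbours(
        comps, csf_posterior, affine, cmb_posterior, csf_threshold,
        neighbour_connectivity, connectivity,
    )
    # masking can shrink survivors below the size bounds; re-check
    comps = filter_by_size(comps, min_voxels, max_volume_cm3)
    if artefact_mask is not None and artefact_mask.mask.any():
        comps = apply_artefact_mask(comps, artefact_mask)
    cleaned = cleaned_posterior_map(comps, np.asarray(cmb_posterior))
    return comps, cleaned


def build_artefact_mask(
    control_volumes: list,
    priors,
    config=None,
    control_ids: list | None = None,
) -> ArtefactMask:
    """Union of detected CMB voxels over healthy controls.

    The full two-iteration pipeline (all filters except the artefact-mask
    step itself) is run per control; any voxel detected in any control is
    added to the mask.  Union-monotone: adding a control never removes
    voxels.
    """
    from .pipeline import MidasConfig, run_midas

    config = config or MidasConfig()
    ids = control_ids or [f"control_{i}" for i in range(len(control_volumes))]
    mask = None
    affine = None
    prov = []
    for vol, cid in zip(control_volumes, ids):
        report = run_midas(vol, priors, artefact_mask=None, config=config)
        detected = report.final_cmb_mask
        if mask is None:
            mask = np.zeros(detected.shape, bool)
            affine = report.affine
        mask |= detected
        prov.append(cid)
    if mask is None:  # no controls: an empty mask on the prior grid
        return ArtefactMask.empty(priors.shape, priors.affine)
    return ArtefactMask(mask, affine, prov)
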