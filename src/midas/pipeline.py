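"""Two-iteration MIDAS orchestration.

Per subject: resample to the isotropic working grid, first constrained
mixture fit with the flat CMB prior, morphological refinement of the CMB
posterior, substitution of the cleaned map as the second-iteration CMB
prior, second fit, final 0.5 threshold on the second-pass CMB posterior,
re-labelling and size re-filtering, then per-region counts.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .io import Volume3D, resample_isotropic, resample_like
from .priors import CLASS_NAMES, TissuePriorSet, refine_cmb_prior
from .refinement import (
    ArtefactMask,
    binarise_posterior,
    components_to_mask,
    filter_by_size,
    label_components,
    refine_candidates,
)
from .segmentation import (
    ConstrainedGaussianMixture,
    EMConfig,
    MixtureModel,
    DEFAULT_N_GAUSSIANS,
)

REGION_NAMES = {0: "none", 1: "lobar", 2: "deep", 3: "infratentorial"}


@dataclass
class MidasConfig:
    """Every tunable constant of the detection pipeline."""

    working_spacing_mm: float = 1.5
    n_gaussians: dict = field(default_factory=lambda: dict(DEFAULT_N_GAUSSIANS))
    cmb_prior_value: float = 0.1
    binarise_threshold: float = 0.2
    min_voxels: int = 2
    max_volume_cm3: float = 0.675
    final_threshold: float = 0.5
    skull_threshold: float = 0.5
    csf_threshold: float = 0.5
    connectivity: int = 26
    neighbour_connectivity: int = 6
    em_tol: float = 1e-5
    em_max_iter: int = 100
    bias: bool = True
    bias_order: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name, lo, hi in (
            ("binarise_threshold", 0.0, 1.0),
            ("final_threshold", 0.0, 1.0),
            ("skull_threshold", 0.0, 1.0),
            ("csf_threshold", 0.0, 1.0),
            ("cmb_prior_value", 0.0, 1.0),
        ):
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if self.working_spacing_mm <= 0 or self.max_volume_cm3 <= 0:
            raise ValueError("spacings and volume bounds must be positive")

    def em_config(self) -> EMConfig:
        return EMConfig(
            n_gaussians=dict(self.n_gaussians),
            tol=self.em_tol,
            max_iter=self.em_max_iter,
            bias=self.bias,
            bias_order=self.bias_order,
        )

    def to_dict(self) -> dict:
        return asdict(self)


class PipelineError(RuntimeError):
    pass


@dataclass
class DetectionReport:
    """Final per-subject detection output with a full audit trail."""

    subject_id: str
    survivors: list  # final CMBComponents (second pass)
    first_pass: list  # all first-pass candidates with status
    region_counts: dict
    config: dict
    affine: np.ndarray
    shape: tuple
    runtime_s: float = 0.0
    final_cmb_mask: np.ndarray | None = None
    models: dict = field(default_factory=dict)

    @property
    def n_cmb(self) -> int:
        return len(self.survivors)

    @property
    def multi_cmb(self) -> bool:
        """Two or more surviving lobar microbleeds."""
        return self.region_counts.get("lobar", 0) >= 2

    def discards(self) -> list:
        return [c for c in self.first_pass if not c.kept]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for stage, comps in (("final", self.survivors), ("first_pass", self.first_pass)):
            for c in comps:
                rows.append(
                    {
                        "stage": stage,
                        "id": c.id,
                        "x_mm": c.centroid_mm[0],
                        "y_mm": c.centroid_mm[1],
                        "z_mm": c.centroid_mm[2],
                        "volume_cm3": c.volume_cm3,
                        "n_voxels": c.n_voxels,
                        "peak_posterior": c.peak_posterior,
                        "region": c.region or "none",
                        "status": "kept" if c.kept else "discarded",
                        "discard_reason": c.discard_reason or "",
                    }
                )
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        return json.dumps(
            {
                "subject_id": self.subject_id,
                "n_cmb": self.n_cmb,
                "region_counts": self.region_counts,
                "multi_cmb": self.multi_cmb,
                "runtime_s": self.runtime_s,
                "config": self.config,
                "components": self.to_dataframe().to_dict(orient="records"),
            },
            indent=2,
        )

    def summary(self) -> str:
        lines = [
            f"MIDAS detection report — subject {self.subject_id}",
            "=" * 56,
            f"surviving microbleeds: {self.n_cmb}",
            "  "
            + "  ".join(
                f"{k}: {v}" for k, v in sorted(self.region_counts.items())
            ),
            f"multiple (>=2) lobar microbleeds: {self.multi_cmb}",
            f"first-pass candidates: {len(self.first_pass)} "
            f"(kept {sum(c.kept for c in self.first_pass)})",
        ]
        reasons = {}
        for c in self.discards():
            reasons[c.discard_reason] = reasons.get(c.discard_reason, 0) + 1
        if reasons:
            lines.append(
                "discards: "
                + ", ".join(f"{k}={v}" for k, v in sorted(reasons.items()))
            )
        lines.append(f"runtime: {self.runtime_s:.1f} s")
        return "\n".join(lines)

    def save(self, out_dir) -> None:
        from pathlib import Path

        from .io import write_volume

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(self.to_json())
        self.to_dataframe().to_csv(out / "components.tsv", sep="\t", index=False)
        if self.final_cmb_mask is not None:
            write_volume(
                Volume3D(self.final_cmb_mask.astype(np.float32), self.affine),
                out / "cmb_map.nii.gz",
            )


def _resample_priors_like(
    priors: TissuePriorSet, reference: Volume3D
) -> TissuePriorSet:
    """Bring a prior set onto the reference grid: linear interpolation for
    probabilities (then per-voxel renormalisation), nearest for the mask."""
    from .priors import _renormalise

    maps = {}
    for name in CLASS_NAMES:
        maps[name] = resample_like(
            Volume3D(priors.maps[name].astype(np.float32), priors.affine),
            reference,
            order="linear",
        ).data.astype(np.float64)
    brain = (
        resample_like(
            Volume3D(priors.brain_mask.astype(np.float32), priors.affine),
            reference,
            order="nearest",
        ).data
        > 0.5
    )
    stack = np.stack([maps[k] for k in CLASS_NAMES])
    stack[CLASS_NAMES.index("cmb")] *= brain
    supports = stack > 0
    supports[-1] = True
    stack = _renormalise(stack, supports, priors.floor)
    return TissuePriorSet(
        maps={k: stack[i] for i, k in enumerate(CLASS_NAMES)},
        brain_mask=brain,
        affine=reference.affine.copy(),
        floor=priors.floor,
    )


def summarise_by_region(
    components: list, region_labels: Volume3D | None
) -> dict:
    """Assign each surviving component the region of its centroid voxel
    and count per region.  Components whose centroid falls outside the
    labelled brain get region "none"."""
    counts = {"lobar": 0, "deep": 0, "infratentorial": 0, "none": 0}
    for c in components:
        if not c.kept:
            continue
        region = "none"
        if region_labels is not None:
            idx = np.round(
                region_labels.world_to_index(c.centroid_mm)[0]
            ).astype(int)
            if np.all(idx >= 0) and np.all(idx < np.array(region_labels.shape)):
                code = int(region_labels.data[tuple(idx)])
                region = REGION_NAMES.get(code, "none")
        c.region = region
        counts[region] += 1
    return counts


def run_midas(
    t2star: Volume3D,
    priors: TissuePriorSet,
    artefact_mask: ArtefactMask | None = None,
    region_labels: Volume3D | None = None,
    config: MidasConfig | None = None,
    subject_id: str = "subject",
) -> DetectionReport:
    """Run the full two-iteration detection on one subject."""
    config = config or MidasConfig()
    t0 = time.time()

    # (1) isotropic working grid
    work = resample_isotropic(t2star, config.working_spacing_mm, order="linear")
    if tuple(priors.shape) != tuple(work.shape) or not np.allclose(
        priors.affine, work.affine
    ):
        priors_w = _resample_priors_like(priors, work)
    else:
        priors_w = priors
    if priors_w.brain_mask.sum() == 0:
        raise PipelineError("empty brain mask on the working grid")

    mask_w = None
    if artefact_mask is not None and artefact_mask.mask.any():
        mask_data = resample_like(
            Volume3D(
                artefact_mask.mask.astype(np.float32), artefact_mask.affine
            ),
            work,
            order="nearest",
        ).data > 0.5
        mask_w = ArtefactMask(mask_data, work.affine, artefact_mask.provenance)

    em_cfg = config.em_config()

    # (2) first pass: flat empirical CMB prior
    first = ConstrainedGaussianMixture(work, priors_w, em_cfg).fit()

    # (3) refinement cascade on the first-pass CMB posterior
    candidates, cleaned = refine_candidates(
        first.posteriors.maps["cmb"],
        first.posteriors.maps["skull"],
        first.posteriors.maps["csf"],
        work.affine,
        artefact_mask=mask_w,
        binarise_threshold=config.binarise_threshold,
        min_voxels=config.min_voxels,
        max_volume_cm3=config.max_volume_cm3,
        skull_threshold=config.skull_threshold,
        csf_threshold=config.csf_threshold,
        connectivity=config.connectivity,
        neighbour_connectivity=config.neighbour_connectivity,
    )

    # (4) refined subject-specific prior; (5) second pass (warm start)
    if cleaned.any():
        priors2 = refine_cmb_prior(priors_w, cleaned)
        second = ConstrainedGaussianMixture(work, priors2, em_cfg).fit(
            init_model=first.mixture
        )
        cmb_post2 = second.posteriors.maps["cmb"]
        second_model = second.mixture
    else:  # nothing survived: the second pass cannot invent lesions
        cmb_post2 = np.zeros(work.shape)
        second_model = None

    # (6) final threshold, re-label, re-apply the size filter
    final_mask = binarise_posterior(cmb_post2, config.final_threshold)
    finals = label_components(
        final_mask,
        work.affine,
        posterior=cmb_post2,
        connectivity=config.connectivity,
    )
    finals = filter_by_size(finals, config.min_voxels, config.max_volume_cm3)
    survivors = [c for c in finals if c.kept]

    # (7) per-region counts at the surviving centroids
    regions_w = None
    if region_labels is not None:
        regions_w = resample_like(region_labels, work, order="nearest")
    counts = summarise_by_region(survivors, regions_w)

    report = DetectionReport(
        subject_id=subject_id,
        survivors=survivors,
        first_pass=candidates,
        region_counts=counts,
        config=config.to_dict(),
        affine=work.affine,
        shape=tuple(work.shape),
        runtime_s=time.time() - t0,
        final_cmb_mask=components_to_mask(survivors, work.shape),
        models={
            "first_pass": first.mixture,
            "second_pass": second_model,
        },
    )
    return report


class MidasModel:
    """Model-style interface to the detection pipeline.

    ``MidasModel(t2star, priors, ...).fit()`` returns the
    :class:`DetectionReport` for the subject.
    """

    def __init__(
        self,
        t2star: Volume3D,
        priors: TissuePriorSet,
        artefact_mask: ArtefactMask | None = None,
        region_labels: Volume3D | None = None,
        config: MidasConfig | None = None,
        subject_id: str = "subject",
    ):
        self.t2star = t2star
        self.priors = priors
        self.artefact_mask = artefact_mask
        self.region_labels = region_labels
        self.config = config or MidasConfig()
        self.subject_id = subject_id

    def fit(self) -> DetectionReport:
        return run_midas(
            self.t2star,
            self.priors,
            self.artefact_mask,
            self.region_labels,
            self.config,
            self.subject_id,
        )
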