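"""MIDAS — microbleed detection by automated segmentation of GRE T2* MRI.

The package detects cerebral microbleeds as an explicit "extra" tissue
class inside a prior-weighted constrained Gaussian-mixture segmentation,
cleans the candidates with a fixed morphological cascade, re-segments
with the refined subject-specific prior, and reports per-region lesion
counts with agreement statistics against manual ratings.
"""

from .io import (
    RigidAffineTransform,
    Volume3D,
    align_to_template,
    read_volume,
    resample_isotropic,
    resample_like,
    write_volume,
)
from .phantom import (
    CMBSpec,
    GroundTruth,
    PhantomSpec,
    apply_bias_field,
    insert_cmb,
    make_phantom,
    region_label_volume,
    sample_lobar_cmbs,
)
from .priors import (
    TissuePriorSet,
    build_prior_set,
    priors_from_labels,
    refine_cmb_prior,
    validate_priors,
)
from .segmentation import (
    ConstrainedGaussianMixture,
    EMConfig,
    MixtureModel,
    SegmentationResults,
    constrain_means,
    estimate_bias,
    fit_constrained_mixture,
)
from .refinement import (
    ArtefactMask,
    CMBComponent,
    apply_artefact_mask,
    binarise_posterior,
    build_artefact_mask,
    exclude_csf_neighbours,
    filter_by_size,
    label_components,
    mask_skull,
    refine_candidates,
)
from .pipeline import (
    DetectionReport,
    MidasConfig,
    MidasModel,
    run_midas,
    summarise_by_region,
)
from .agreement import (
    MatchResult,
    agreement_summary,
    cohen_kappa,
    icc_counts,
    interpret_kappa,
    match_detections,
)

__version__ = "0.1.0"
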