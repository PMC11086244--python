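"""iriscap: capacity bounds for iris-texture biometrics via AR spectral models.

Each iris class is encoded as a stationary Gaussian auto-regressive process;
class distances are Whittle log-likelihood ratios / spectral relative
entropies; the cross-class (imposter) score distribution is fitted with an
Erlang family whose parameters (K, P) feed sphere-packing and
Daugman-style enrollment bounds on the maximum supportable population.
"""

from .ar import (
    AICCurve,
    ARModel,
    PowerSpectrum,
    aic_sweep,
    ar_autocovariance,
    ar_psd,
    burg_fit,
    random_stable_ar,
    sample_spectral_realizations,
    select_order,
    simulate_ar,
)
from .capacity import (
    CapacityResult,
    enrollment_capacity,
    enrollment_table,
    error_to_enroll,
    fmr_continuous,
    fmr_unit_grid,
    sphere_packing_capacity,
    sphere_packing_table,
)
from .detection import (
    ErlangComponentParams,
    PairStatistic,
    decide,
    erlang_component_params,
    exact_gaussian_llr,
    pairwise_error_mc,
    periodogram,
    relative_entropy,
    sample_lambda_component,
    union_bound,
    whittle_llr,
)
from .errors import DegenerateSignalError, GridMismatchError, IrisCapError, StabilityError
from .imposter import (
    ImposterFit,
    ImposterHistogram,
    enrollment_spectrum,
    erlang_pdf,
    fit_erlang_lsq,
    imposter_scores,
    sample_erlang,
)
from .pipeline import CohortSpec, PipelineResult, RunConfig, generate_cohort, run_pipeline
from .preprocess import (
    GaborParams,
    NormalizedIrisImage,
    VectorizedIris,
    gabor_filter,
    gabor_kernel,
    inner_half_crop,
    inverse_zigzag,
    load_normalized_image,
    preprocess_image,
    vectorize,
    zigzag_scan,
)

__version__ = "0.1.0"
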