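"""treburden: rare tandem-repeat-expansion calling and case-control burden analysis."""

__version__ = "0.1.0"

from .calling import (  # noqa: F401
    NOISE,
    CallParams,
    LocusMotifProfile,
    TRECall,
    call_expansions,
    canonical_motif,
    classify_cpg,
    dbscan_1d,
    merge_regions,
    rarity_filter,
)
from .meta import (  # noqa: F401
    MetaResult,
    PowerResult,
    StudyEffect,
    analytic_power,
    meta_fixed,
    power_sim,
)
from .simulate import (  # noqa: F401
    AnnotationBundle,
    CohortSim,
    SimConfig,
    SyntheticTruth,
    simulate_annotations,
    simulate_cohort,
)
from .stats import (  # noqa: F401
    BurdenResult,
    CarrierExcessResult,
    bh_adjust,
    burden_test,
    carrier_excess,
    compute_pcs,
    constraint_compare,
    normalize_irr,
    select_covariate_pcs,
    wilcoxon_rank_sum,
)


def __getattr__(name):
    # pipeline imports treburden.__version__; expose it lazily to avoid a cycle
    if name in ("AnalysisParams", "AnalysisResult", "RunConfig", "analyze_cohort", "run_pipeline"):
        from . import pipeline

        return getattr(pipeline, name)
    raise AttributeError(name)
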