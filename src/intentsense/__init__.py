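"""intentsense: modular, time-segmented multi-modal intent sensing.

Per-sensor sequence classifiers (five IMUs + one microphone) cast a
class vote at every overlapping 500 ms time window; votes are fused
across sensors and time either by a confusion-matrix-weighted Bayes rule
or by majority voting, yielding an intent posterior that sharpens as the
activity unfolds.  A seeded synthetic cohort generator emulating a
patient/control study population makes the whole pipeline testable end
to end.
"""

from .config import (
    ACTIVITIES,
    ALL_SENSORS,
    FUSION_METHODS,
    IMU_STREAMS,
    GeneratorConfig,
    PipelineConfig,
    load_config,
)
from .evaluation import run_loso, spearman_monotonicity
from .fusion import FusionConfig, bayes_fuse, majority_vote, naive_upper_bound
from .model import IntentSensingModel, IntentSensingResults
from .synthetic import generate_cohort, generate_cohort_dataset, generate_trial

__version__ = "0.1.0"

__all__ = [
    "ACTIVITIES",
    "ALL_SENSORS",
    "FUSION_METHODS",
    "IMU_STREAMS",
    "GeneratorConfig",
    "PipelineConfig",
    "load_config",
    "run_loso",
    "spearman_monotonicity",
    "FusionConfig",
    "bayes_fuse",
    "majority_vote",
    "naive_upper_bound",
    "IntentSensingModel",
    "IntentSensingResults",
    "generate_cohort",
    "generate_cohort_dataset",
    "generate_trial",
    "__version__",
]
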