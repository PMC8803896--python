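"""aoxpred: antioxidant-protein classification from sequence.

Sequence-derived feature encoders (188D physicochemical descriptor and
k-spaced amino-acid pair composition), MRMD feature selection, majority-
class undersampling, and a random-forest classifier with a confusion-
matrix/AUC evaluation suite — runnable end-to-end on synthetic data.
"""

from .sequence_io import (
    ALPHABET,
    LabeledDataset,
    ProteinSequence,
    read_fasta,
    split_dataset,
    validate_sequence,
    write_fasta,
)
from .feature_matrix import FeatureMatrix
from .features_188d import (
    GROUPING_TABLES,
    GroupingTable,
    aac,
    ctd_property,
    extract_188d,
    feature_names_188d,
)
from .features_cksaap import (
    cksaap,
    combined_feature_names,
    encode_dataset,
    encode_sequences,
    extract_combined,
)
from .mrmd import MRMDRanking, SubsetSelection, max_distance, max_relevance, rank_features, select_subset
from .sampling import SamplingConfig, random_undersample
from .classify_eval import (
    ConfusionCounts,
    MetricsReport,
    TrainedModel,
    confusion_metrics,
    cross_validate,
    metrics_report,
    predict_score,
    roc_auc,
    train,
)
from .synthetic import SyntheticSpec, generate, worked_example
from .pipeline import FeatureSpec, PipelineConfig, run_pipeline, predict_fasta

__version__ = "0.1.0"
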