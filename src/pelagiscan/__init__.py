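"""pelagiscan: spatial-spectral classification of pelagic fish species from
VIS-NIR hyperspectral cubes.

Pipeline: ENVI cube I/O and white-reference reflectance calibration ->
per-fish segmentation -> whole-body / random-RoI spectral signatures and
camera-emulated RGB rendering -> geometric + spectral augmentation with
class balancing -> a two-channel (spatial + spectral) CNN with linear-SVM
baselines -> cross-validated metrics and Wilcoxon model comparison.  A
synthetic scene generator makes the whole chain runnable without any
measured data.
"""

from .hypercube import (
    Hypercube,
    ReferenceFrame,
    calibrate_reflectance,
    nominal_wavelengths,
    read_envi,
    write_envi,
)
from .segmentation import FishMask, choose_contrast_band, crop_fish, segment_fish
from .signatures import (
    RoiSet,
    SignatureSet,
    SpectralSignature,
    resample_signature,
    roi_signatures,
    sample_rois,
    whole_body_signature,
)
from .rgb import (
    ProjectionMatrix,
    RGBImage,
    SensitivityMatrix,
    build_projection_matrix,
    default_sensitivity,
    load_sensitivity,
    render_rgb,
)
from .augment import (
    AugmentRanges,
    Dataset,
    Sample,
    SourceFish,
    augment_image,
    balance_dataset,
    standardize_image,
)
from .classifiers import (
    CNNConfig,
    CNNModel,
    HOGParams,
    SVMBaseline,
    TrainConfig,
    build_cnn,
    hog_features,
    predict,
    train_cnn,
    train_svm,
)
from .evaluation import (
    ConfusionMatrix,
    CVReport,
    MetricsReport,
    confusion_matrix,
    kfold_cv,
    learning_curve,
    metrics,
    wilcoxon_compare,
    zero_one_loss,
)
from .synth import (
    SceneSpec,
    SpeciesTemplate,
    default_templates,
    generate_experiment,
    generate_scene,
)
from .pipeline import RunConfig, run_full_experiment

__version__ = "0.1.0"
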