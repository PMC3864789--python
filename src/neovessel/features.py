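"""Assembly of the 75-value per-image feature vector.

Order is fixed: 17 statistical-texture features, then 50 higher-order-
spectra features (five statistics at each of ten projection angles),
then 8 fractal features.  ``FundusFeatureExtractor`` wraps the whole
preprocessing + extraction chain as a stateless scikit-learn
transformer over a list of RGB images.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .fractal import FRACTAL_FEATURE_NAMES, fractal_vector
from .hos import hos_feature_names, hos_vector
from .preprocess import PreprocessConfig, preprocess_image
from .texture import STA_FEATURE_NAMES, sta_vector

__all__ = ["FEATURE_NAMES", "extract_features", "extract_table",
           "FundusFeatureExtractor"]

FEATURE_NAMES: tuple[str, ...] = (
    STA_FEATURE_NAMES + hos_feature_names() + FRACTAL_FEATURE_NAMES
)
N_STA = len(STA_FEATURE_NAMES)            # 17
N_HOS = len(hos_feature_names())          # 50
N_FRACTAL = len(FRACTAL_FEATURE_NAMES)    # 8


def extract_features(rgb: np.ndarray,
                     config: PreprocessConfig | None = None) -> np.ndarray:
    """Preprocess one RGB fundus image and return its 75 features."""
    res = preprocess_image(rgb, config)
    sta = sta_vector(res.gray)
    hos = hos_vector(res.gray)
    fa = fractal_vector(res.gray, res.mask)
    vec = np.concatenate([sta, hos, fa])
    assert vec.size == len(FEATURE_NAMES)
    return vec


def extract_table(images, labels=None,
                  config: PreprocessConfig | None = None) -> pd.DataFrame:
    """Feature table for a list of images; adds a ``label`` column when
    labels are given."""
    rows = [extract_features(img, config) for img in images]
    table = pd.DataFrame(rows, columns=list(FEATURE_NAMES))
    if labels is not None:
        table["label"] = np.asarray(labels, dtype=int)
    return table


class FundusFeatureExtractor(BaseEstimator, TransformerMixin):
    """Stateless transformer: list of RGB images -> (n, 75) array.

    Parameters mirror :class:`~neovessel.preprocess.PreprocessConfig`;
    ``small_images=True`` selects the scale-adapted preprocessing used
    for ~200 px imagery.
    """

    def __init__(self, small_images: bool = False):
        self.small_images = small_images

    def _config(self) -> PreprocessConfig:
        return (PreprocessConfig.for_small_images() if self.small_images
                else PreprocessConfig())

    def fit(self, X, y=None):
        self.n_features_in_ = 1  # images, not columns
        self.feature_names_out_ = list(FEATURE_NAMES)
        return self

    def transform(self, X) -> np.ndarray:
        cfg = self._config()
        return np.vstack([extract_features(img, cfg) for img in X])

    def get_feature_names_out(self, input_features=None):
        return np.asarray(FEATURE_NAMES, dtype=object)
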