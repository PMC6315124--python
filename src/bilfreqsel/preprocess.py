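"""Expression filtering and log transformation ahead of feature selection.

Genes are kept when their mean FPKM across all samples is strictly above a
threshold (default 0.01), then values are mapped to log2(FPKM + pseudocount)
with a 0.01 pseudocount.  Filtering uses raw FPKM; the transform is applied
afterwards, so the two operations commute on the retained genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .datatypes import ExpressionMatrix, InvalidParameterError, ValidationError


@dataclass
class PreprocessConfig:
    min_mean_fpkm: float = 0.01
    pseudocount: float = 0.01
    log_base: float = 2.0

    def __post_init__(self) -> None:
        if self.pseudocount <= 0:
            raise InvalidParameterError("pseudocount must be positive")
        if self.min_mean_fpkm < 0:
            raise InvalidParameterError("min_mean_fpkm must be nonnegative")


def filter_low_expression(
    expr: ExpressionMatrix, config: PreprocessConfig = PreprocessConfig()
) -> ExpressionMatrix:
    """Keep genes whose mean FPKM is strictly greater than the threshold."""
    means = expr.values.mean(axis=1)
    keep = means > config.min_mean_fpkm
    if not keep.any():
        warnings.warn("expression filter removed every gene")
        empty = expr.values.loc[keep]
        out = ExpressionMatrix.__new__(ExpressionMatrix)
        out.values = empty  # bypass the non-empty invariant for this edge case
        return out
    return ExpressionMatrix(expr.values.loc[keep])


def log_transform(
    expr: ExpressionMatrix | pd.DataFrame,
    config: PreprocessConfig = PreprocessConfig(),
) -> pd.DataFrame:
    """log2(FPKM + pseudocount), elementwise; shape and labels preserved."""
    values = expr.values if isinstance(expr, ExpressionMatrix) else expr
    arr = values.to_numpy(float)
    if np.any(arr < 0):
        raise ValidationError("negative FPKM value passed to log_transform")
    out = np.log(arr + config.pseudocount) / np.log(config.log_base)
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def preprocess(
    expr: ExpressionMatrix, config: PreprocessConfig = PreprocessConfig()
) -> pd.DataFrame:
    """Filter then log-transform; returns a genes x samples log2 DataFrame."""
    return log_transform(filter_low_expression(expr, config), config)


class LowExpressionFilter(SelectorMixin, BaseEstimator):
    """Feature selector dropping genes at or below a mean-FPKM threshold.

    Operates on samples x genes arrays (scikit-learn orientation).
    """

    def __init__(self, min_mean_fpkm: float = 0.01):
        self.min_mean_fpkm = min_mean_fpkm

    def fit(self, X, y=None):
        X = check_array(X, ensure_min_samples=1)
        self.means_ = X.mean(axis=0)
        self.n_features_in_ = X.shape[1]
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "means_")
        return self.means_ > self.min_mean_fpkm


class Log2FpkmTransformer(TransformerMixin, BaseEstimator):
    """Stateless log2(x + pseudocount) transform for FPKM arrays."""

    def __init__(self, pseudocount: float = 0.01):
        self.pseudocount = pseudocount

    def fit(self, X, y=None):
        if self.pseudocount <= 0:
            raise InvalidParameterError("pseudocount must be positive")
        X = check_array(X)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "n_features_in_")
        X = check_array(X)
        if np.any(X < 0):
            raise ValidationError("negative values passed to Log2FpkmTransformer")
        return np.log2(X + self.pseudocount)
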