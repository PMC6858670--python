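"""Zero handling and log-ratio transformation of count compositions.

Sequencing count vectors carry only relative information, so analysis
happens in log-ratio space.  Because the logarithm is undefined at zero,
counts are first mapped to strictly positive compositions either by
count-zero-multiplicative (CZM) replacement — zeros receive a small
proportion tied to sequencing depth, non-zeros shrink multiplicatively so
their ratios are untouched — or by a uniform pseudocount.  The centered
log-ratio (CLR) transform then maps each composition to a zero-sum real
vector in which Euclidean geometry is meaningful; the Euclidean distance
between CLR vectors is the Aitchison distance.

All logarithms are base 2, matching the fold-change convention of the
differential-abundance statistics downstream; the base is exposed where it
matters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

__all__ = [
    "impute_zeros_czm",
    "impute_zeros_pseudocount",
    "clr",
    "clr_matrix",
    "aitchison_distance",
    "ClrMatrix",
    "CZMImputer",
    "PseudocountImputer",
    "CLRTransformer",
]


@dataclass
class ClrMatrix:
    """CLR-transformed values, features x samples, with identifiers.

    Every sample's CLR vector sums to zero (to 1e-9); ``log_base`` records
    the logarithm base used (2 throughout this package).
    """

    values: pd.DataFrame
    log_base: float = 2.0

    def __post_init__(self) -> None:
        sums = self.values.sum(axis=0).to_numpy()
        if self.values.shape[0] >= 2 and np.abs(sums).max() > 1e-9 * max(
            1.0, np.abs(self.values.to_numpy()).max()
        ):
            raise ValueError("CLR columns must sum to zero")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="feature_id")


def impute_zeros_czm(counts, frac: float = 0.65):
    """Count-zero-multiplicative replacement for one sample's count vector.

    With total depth ``n`` and ``Z`` zero cells, each zero receives the
    proportion ``delta = frac / (n + 1)`` and each non-zero count ``x_j``
    becomes ``(x_j / n) * (1 - Z * delta)``, so the output is a composition
    summing to one and the ratios between non-zero parts are preserved
    exactly.

    Parameters
    ----------
    counts : 1-D array of non-negative numbers
    frac : float in (0, 1], default 0.65
        Fraction of the detection limit ``1 / (n + 1)`` assigned to zeros.
    """
    x = np.asarray(counts, dtype=float)
    if x.ndim != 1:
        raise ValueError("impute_zeros_czm operates on one sample (1-D) at a time")
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    if not 0 < frac <= 1:
        raise ValueError("frac must lie in (0, 1]")
    n = x.sum()
    if n <= 0:
        raise ValueError("all-zero sample: no composition can be recovered")
    zeros = x == 0
    n_zero = int(zeros.sum())
    delta = frac / (n + 1.0)
    shrink = 1.0 - n_zero * delta
    if shrink <= 0:
        raise ValueError(
            f"{n_zero} zeros at depth {n:g}: imputed mass Z*delta >= 1; "
            "filter low-count samples/features before zero replacement"
        )
    out = np.where(zeros, delta, x / n * shrink)
    return out


def impute_zeros_pseudocount(counts, pseudo: float = 0.5):
    """Add a uniform pseudocount to every cell of a count array.

    Quick zero removal for the log-ratio transform; unlike CZM it perturbs
    the ratios between observed counts slightly.
    """
    if pseudo <= 0:
        raise ValueError("pseudo must be positive")
    x = np.asarray(counts, dtype=float)
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    return x + pseudo


def clr(parts, base: float = 2.0, axis: int | None = None):
    """Centered log-ratio transform of strictly positive parts.

    ``clr(x)_j = log(x_j) - mean_j log(x_j)`` (log base 2 by default).  The
    result sums to zero and is invariant to positive rescaling of the
    input.  For a 2-D array pass ``axis`` to select the dimension holding
    the parts of one composition (``axis=0`` for features x samples).
    """
    x = np.asarray(parts, dtype=float)
    if (x <= 0).any():
        raise ValueError(
            "clr requires strictly positive parts; apply zero handling first"
        )
    if x.ndim == 1:
        if x.size < 2:
            raise ValueError("clr needs at least two parts")
        logs = np.log(x) / np.log(base)
        return logs - logs.mean()
    if axis is None:
        raise ValueError("pass axis= for 2-D input")
    logs = np.log(x) / np.log(base)
    return logs - logs.mean(axis=axis, keepdims=True)


def clr_matrix(positive: pd.DataFrame, base: float = 2.0) -> ClrMatrix:
    """CLR-transform a features x samples matrix of positive values."""
    vals = clr(positive.to_numpy(), base=base, axis=0)
    return ClrMatrix(
        pd.DataFrame(vals, index=positive.index, columns=positive.columns),
        log_base=base,
    )


def aitchison_distance(x, y, base: float = 2.0) -> float:
    """Aitchison distance: Euclidean norm of ``clr(x) - clr(y)``.

    Symmetric, zero iff the two compositions are proportional, and
    invariant to element-wise perturbation by a common positive vector.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    return float(np.linalg.norm(clr(x, base=base) - clr(y, base=base)))


# ---------------------------------------------------------------------------
# sklearn-style transformers (X is samples x features, the sklearn layout)
# ---------------------------------------------------------------------------

class CZMImputer(TransformerMixin, BaseEstimator):
    """Count-zero-multiplicative replacement as a stateless transformer.

    Operates row-wise (each row of X is one sample's count vector) and
    returns compositions summing to one.  Composes with
    :class:`CLRTransformer` in a sklearn ``Pipeline``.
    """

    def __init__(self, frac: float = 0.65):
        self.frac = frac

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "n_features_in_")
        X = check_array(X, dtype=float)
        return np.vstack([impute_zeros_czm(row, frac=self.frac) for row in X])


class PseudocountImputer(TransformerMixin, BaseEstimator):
    """Uniform-pseudocount zero replacement as a stateless transformer."""

    def __init__(self, pseudo: float = 0.5):
        self.pseudo = pseudo

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "n_features_in_")
        X = check_array(X, dtype=float)
        return impute_zeros_pseudocount(X, pseudo=self.pseudo)


class CLRTransformer(TransformerMixin, BaseEstimator):
    """Row-wise centered log-ratio transform (sklearn transformer)."""

    def __init__(self, base: float = 2.0):
        self.base = base

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "n_features_in_")
        X = check_array(X, dtype=float)
        return clr(X, base=self.base, axis=1)
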