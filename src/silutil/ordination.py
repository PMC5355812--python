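"""Ordination and supporting statistics for aligned proxy matrices.

The screening convention in palaeoecology: run a detrended correspondence
analysis first and look at the axis-1 gradient length in standard-deviation
(SD) units of turnover.  Short gradients (< 1.5 SD) mean variables respond
approximately linearly along the latent gradient, so a linear method —
principal components analysis on standardized variables — is appropriate;
long gradients (> 2 SD) indicate unimodal turnover.

The correspondence analysis here is the classical chi-square SVD; axis-1
scores are converted to SD units by rescaling with the mean within-sample
variance of the species (column) scores, the linearized form of Hill's
rescaling.  Detrending-by-segments only alters axes >= 2 and so does not
affect the axis-1 gradient length.  Rare columns can be down-weighted in
the usual way (weights proportional to frequency below a fifth of the
commonest column).  Columns containing negative values are shifted up by
their minimum before the chi-square decomposition (logged); already
non-negative columns keep their baseline, since subtracting it would
manufacture compositional contrast the data do not have.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("silutil")

__all__ = [
    "OrdinationResult",
    "DCAScreen",
    "RegressionResult",
    "dca_gradient_length",
    "pca_with_scaling",
    "regress_adjusted_r2",
    "trend_test",
]


@dataclass
class OrdinationResult:
    """Eigen-structure of an ordination, biplot-ready."""

    method: str
    eigenvalues: np.ndarray
    axis_variance_fractions: np.ndarray
    variable_loadings: pd.DataFrame  # variables x axes
    sample_scores: pd.DataFrame  # samples x axes
    gradient_length_sd: float | None = None


@dataclass(frozen=True)
class DCAScreen:
    """Axis-1 gradient length and the linear/unimodal verdict."""

    gradient_length_sd: float
    threshold: float
    column_shifts: dict[str, float]

    @property
    def is_linear(self) -> bool:
        return self.gradient_length_sd < self.threshold


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r2: float
    adjusted_r2: float
    p_value: float
    n: int


def _drop_constant_columns(df: pd.DataFrame) -> pd.DataFrame:
    const = [c for c in df.columns if np.ptp(df[c].to_numpy()) == 0]
    if const:
        logger.warning("dropping constant column(s): %s", ", ".join(map(str, const)))
        df = df.drop(columns=const)
    return df


def dca_gradient_length(
    matrix,
    threshold: float = 1.5,
    downweight: bool = True,
) -> DCAScreen:
    """Axis-1 gradient length (SD units) of a correspondence analysis.

    ``matrix`` is a DataFrame (or :class:`~silutil.alignment.AlignedMatrix`)
    of samples x variables with >= 3 rows.  Negative columns are shifted to
    non-negative by their minimum (logged in ``column_shifts``); constant
    columns are dropped with a warning.  Returns the gradient length and
    the verdict against ``threshold`` (1.5 SD by default).
    """
    df = getattr(matrix, "data", matrix)
    if len(df) < 3:
        raise ValueError("need at least 3 rows for a DCA screen")
    df = _drop_constant_columns(pd.DataFrame(df).astype(float))
    shifts = {}
    Y = df.to_numpy().copy()
    for j, c in enumerate(df.columns):
        mn = Y[:, j].min()
        if mn < 0:
            shifts[str(c)] = -mn
            Y[:, j] = Y[:, j] - mn
            logger.info("column %s shifted by %+.4g to be non-negative", c, -mn)
    # drop empty rows/columns (possible after shifting created zeros)
    Y = Y[Y.sum(axis=1) > 0][:, Y.sum(axis=0) > 0]
    if Y.shape[0] < 2 or Y.shape[1] < 2:
        return DCAScreen(0.0, threshold, shifts)
    if downweight:
        freq = Y.sum(axis=0)
        cap = freq.max() / 5.0
        w = np.where(freq < cap, freq / cap, 1.0)
        Y = Y * w
    T = Y.sum()
    P = Y / T
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, s, _ = np.linalg.svd(S, full_matrices=False)
    if s.size == 0 or s[0] < 1e-12:
        return DCAScreen(0.0, threshold, shifts)
    x = U[:, 0] / np.sqrt(r)  # axis-1 row scores
    u = (P.T @ x) / c  # column scores: weighted averages of row scores
    xs = (P @ u) / r  # row scores: weighted averages of column scores
    # mean within-sample variance of column scores -> SD unit
    within = ((P / r[:, None]) * (u[None, :] - xs[:, None]) ** 2).sum(axis=1)
    V = float((r * within).sum())
    if V <= 0:
        return DCAScreen(0.0, threshold, shifts)
    length = float((xs.max() - xs.min()) / np.sqrt(V))
    return DCAScreen(length, threshold, shifts)


def pca_with_scaling(matrix) -> OrdinationResult:
    """PCA of variables centered and scaled to unit variance.

    Eigen-decomposition of the correlation structure; the eigenvalues of k
    standardized variables sum to k.  Axis signs are fixed by flipping each
    axis so its largest-magnitude loading is positive, making results
    platform-independent.  Refuses fewer than 3 rows; constant columns are
    dropped with a warning and at least 2 variables must remain.
    """
    df = getattr(matrix, "data", matrix)
    df = pd.DataFrame(df).astype(float)
    if len(df) < 3:
        raise ValueError("need at least 3 rows for PCA")
    df = _drop_constant_columns(df)
    if df.shape[1] < 2:
        raise ValueError("need at least 2 non-constant variables for PCA")
    X = df.to_numpy()
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    R = np.corrcoef(X, rowvar=False)
    evals, evecs = np.linalg.eigh(R)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    for a in range(evecs.shape[1]):
        j = np.argmax(np.abs(evecs[:, a]))
        if evecs[j, a] < 0:
            evecs[:, a] = -evecs[:, a]
    scores = Z @ evecs
    axes = [f"PC{i + 1}" for i in range(len(evals))]
    return OrdinationResult(
        method="PCA",
        eigenvalues=evals,
        axis_variance_fractions=evals / evals.sum(),
        variable_loadings=pd.DataFrame(evecs, index=df.columns, columns=axes),
        sample_scores=pd.DataFrame(scores, index=df.index, columns=axes),
    )


def regress_adjusted_r2(x, y) -> RegressionResult:
    """OLS of y on x with the small-sample adjusted R-squared.

    ``adjusted R2 = 1 - (1 - R2) * (n - 1) / (n - 2)``; the p-value is the
    two-sided test on the slope.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need n >= 3 for a slope test")
    if np.ptp(x) == 0:
        raise ValueError("x has zero variance")
    res = stats.linregress(x, y)
    r2 = res.rvalue**2
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(r2),
        adjusted_r2=float(adj),
        p_value=float(res.pvalue),
        n=int(n),
    )


def trend_test(values, ages) -> tuple[float, float]:
    """Long-term linear trend of a series against age.

    Returns ``(slope, p_value)`` from OLS of value on age (kyr BP), with the
    two-sided slope test.  Sign convention: ages grow into the past, so a
    decline toward the present is a *positive* slope against age.  A
    constant series returns (0.0, 1.0).
    """
    v = np.asarray(values, dtype=float)
    a = np.asarray(ages, dtype=float)
    if v.size < 4:
        raise ValueError("need at least 4 samples for a trend test")
    if np.ptp(v) == 0:
        return 0.0, 1.0
    res = stats.linregress(a, v)
    return float(res.slope), float(res.pvalue)
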