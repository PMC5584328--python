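"""Per-sample quadratic (second-order OLS) correction of log expression.

For each sample the model

    y_i = beta0 + beta1 * x_i + beta2 * x_i^2 + eps_i

is fitted by ordinary least squares over the invariant genes, where x_i is
the gene's log2 abundance in that sample and y_i its log2 abundance averaged
over all samples. Every gene k in the sample is then mapped through the
fitted parabola, yhat_k = b0 + b1 x_k + b2 x_k^2, pulling the sample onto
the cross-sample consensus while allowing a smooth, intensity-dependent
(hence non-linear) correction that a single scaling factor cannot express.
The coefficients differ per sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, log_transform

__all__ = [
    "QuadraticFit",
    "NormalizedMatrix",
    "fit_quadratic",
    "normalize_sample",
    "normalize_matrix",
    "back_transform",
]

# relative condition-number ceiling for the 3x3 normal equations
_MAX_CONDITION = 1e12


@dataclass
class QuadraticFit:
    """OLS fit of y = b0 + b1 x + b2 x^2 for one sample.

    ``residual_ss`` is Q = sum (y_i - yhat(x_i))^2. ``monotone_in_range``
    is False when the parabola's vertex -b1/(2 b2) falls inside the span of
    the fitted x values, i.e. the mapping reverses gene order locally.
    """

    sample_id: str
    beta: tuple[float, float, float]
    residual_ss: float
    n_fit: int
    fit_x: np.ndarray
    fit_y: np.ndarray
    x_range: tuple[float, float]
    monotone_in_range: bool

    def predict(self, x: np.ndarray) -> np.ndarray:
        b0, b1, b2 = self.beta
        x = np.asarray(x, dtype=float)
        return b0 + b1 * x + b2 * x * x

    @property
    def residuals(self) -> np.ndarray:
        return self.fit_y - self.predict(self.fit_x)


@dataclass
class NormalizedMatrix:
    """Corrected log2 values plus a linear-scale matrix for downstream tools.

    ``corrected_counts`` is real-valued (not rounded); entries whose raw
    input was exactly zero stay zero there, while ``corrected_log`` records
    the mapped value for diagnostics.
    """

    corrected_log: pd.DataFrame
    corrected_counts: pd.DataFrame
    fits: dict[str, QuadraticFit]
    pseudocount: float
    n_extrapolated: dict[str, int]


def fit_quadratic(x, y, sample_id: str = "") -> QuadraticFit:
    """OLS estimate beta = (X^T X)^{-1} X^T Y with design columns (1, x, x^2).

    Needs at least three points with at least three distinct x values (a
    parabola has three parameters). A numerically singular design raises,
    advising more invariant genes.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < 3 or len(np.unique(x)) < 3:
        raise ValueError(
            f"quadratic fit{' for sample ' + sample_id if sample_id else ''} "
            "needs >= 3 points with >= 3 distinct x values"
        )
    X = np.column_stack([np.ones_like(x), x, x * x])
    gram = X.T @ X
    if np.linalg.cond(gram) > _MAX_CONDITION:
        raise ValueError(
            f"near-singular design{' for sample ' + sample_id if sample_id else ''} "
            "(x values too clustered); supply more invariant genes spanning "
            "a wider expression range"
        )
    beta = np.linalg.solve(gram, X.T @ y)
    resid = y - X @ beta
    q = float(resid @ resid)

    lo, hi = float(x.min()), float(x.max())
    b0, b1, b2 = (float(v) for v in beta)
    monotone = True
    if b2 != 0.0:
        vertex = -b1 / (2.0 * b2)
        monotone = not (lo < vertex < hi)
    fit = QuadraticFit(
        sample_id=sample_id,
        beta=(b0, b1, b2),
        residual_ss=q,
        n_fit=len(x),
        fit_x=x,
        fit_y=y,
        x_range=(lo, hi),
        monotone_in_range=monotone,
    )
    if not monotone:
        warnings.warn(
            f"fitted parabola for sample {sample_id or '?'} is non-monotone "
            "inside the invariant-gene range; gene order is locally reversed"
        )
    return fit


def normalize_sample(log_values, fit: QuadraticFit) -> np.ndarray:
    """Map every gene's log value through the fitted parabola.

    Values outside the invariant genes' x-range are extrapolated; callers
    that need the extrapolation count use ``count_extrapolated``.
    """
    return fit.predict(np.asarray(log_values, dtype=float))


def count_extrapolated(log_values, fit: QuadraticFit) -> int:
    lo, hi = fit.x_range
    v = np.asarray(log_values, dtype=float)
    return int(np.sum((v < lo) | (v > hi)))


def normalize_matrix(
    matrix: ExpressionMatrix,
    invariant_gene_ids,
    pseudocount: float = 1.0,
) -> NormalizedMatrix:
    """Fit and apply the per-sample quadratic correction.

    For each sample s, x_i = log2(expr[i, s] + pseudocount) over the
    invariant genes and y_i = the mean over all samples of
    log2(expr[i, .] + pseudocount); after fitting, *all* genes of the
    sample are mapped through the parabola.
    """
    invariant_gene_ids = list(invariant_gene_ids)
    missing = [g for g in invariant_gene_ids if g not in matrix.data.index]
    if missing:
        raise ValueError(f"invariant gene(s) not in matrix: {missing[:5]}")
    logm = log_transform(matrix, pseudocount).data
    y_target = logm.loc[invariant_gene_ids].mean(axis=1).to_numpy()

    corrected = {}
    fits: dict[str, QuadraticFit] = {}
    n_extrap: dict[str, int] = {}
    for sample in matrix.sample_ids:
        x = logm.loc[invariant_gene_ids, sample].to_numpy()
        try:
            fit = fit_quadratic(x, y_target, sample_id=str(sample))
        except ValueError as err:
            raise ValueError(f"sample {sample!r}: {err}") from err
        col = logm[sample].to_numpy()
        corrected[sample] = normalize_sample(col, fit)
        n_extrap[sample] = count_extrapolated(col, fit)
        fits[sample] = fit

    corrected_log = pd.DataFrame(corrected, index=matrix.data.index)
    corrected_log = corrected_log[matrix.sample_ids]
    counts = back_transform(corrected_log, matrix, pseudocount)
    return NormalizedMatrix(corrected_log, counts, fits, pseudocount, n_extrap)


def back_transform(
    corrected_log: pd.DataFrame, raw: ExpressionMatrix, pseudocount: float = 1.0
) -> pd.DataFrame:
    """Invert the log: value = max(0, 2^corrected_log - pseudocount).

    Genes observed at exactly zero stay zero (the fit must not invent
    abundance). Values are left real-valued; tools demanding integer
    counts must round explicitly.
    """
    if corrected_log.shape != raw.data.shape:
        raise ValueError("corrected_log and raw matrix shapes differ")
    lin = np.maximum(0.0, np.exp2(corrected_log.to_numpy()) - pseudocount)
    lin[raw.data.to_numpy() == 0] = 0.0
    return pd.DataFrame(lin, index=corrected_log.index, columns=corrected_log.columns)
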