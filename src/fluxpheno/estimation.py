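"""Least-squares estimation of carbon-flux dates and its validation.

The final models regress an observed CFP date on the satellite LSP date
plus zero or more selected climate drivers, per biome and metric. Fits are
evaluated in-sample (R-squared, RMSE with divisor n, bias, overall F-test)
and by leave-one-out cross-validation; the LOOCV R-squared is the squared
correlation between observed dates and held-out predictions (1 - SSE/SST
is reported alongside).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import statsmodels.api as sm

from .errors import CollinearityError, FoldError, PairingError, ParameterError

#: Matrix rank is decided against this relative tolerance times the largest
#: singular value; well below it the design is reported collinear.
_RANK_RTOL = 1e-10


@dataclass
class RegressionResult:
    """An OLS fit of a CFP date on its predictors."""

    predictor_names: list
    coefficients: np.ndarray        # [intercept, *slopes]
    std_errors: np.ndarray
    r_squared: float                # fraction in [0, 1]
    rmse: float                     # days, divisor n
    bias: float                     # mean(predicted - observed), days
    f_p_value: float
    n: int
    fitted: np.ndarray = field(default=None, repr=False)
    residuals: np.ndarray = field(default=None, repr=False)

    @property
    def r_squared_percent(self) -> float:
        """R-squared on the percentage scale used in reporting tables."""
        return 100.0 * self.r_squared

    @property
    def significant(self) -> bool:
        return self.f_p_value < 0.05


@dataclass
class CrossValidationResult:
    """Leave-one-out predictions paired with the in-sample fit."""

    predictions: np.ndarray
    r_squared: float          # squared correlation observed vs held-out
    r_squared_sse: float      # 1 - SSE/SST variant
    rmse: float
    bias: float
    in_sample: RegressionResult


def _design(predictors, n: Optional[int] = None) -> tuple[np.ndarray, list]:
    """Build (X with intercept, names) from a mapping or 2-D array."""
    if isinstance(predictors, dict):
        names = list(predictors)
        cols = [np.asarray(predictors[k], dtype=float) for k in names]
        X = np.column_stack(cols) if cols else np.empty((n or 0, 0))
    else:
        X = np.asarray(predictors, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = [f"x{i}" for i in range(X.shape[1])]
    return sm.add_constant(X, has_constant="add"), names


def fit_cfp_model(observed, predictors) -> RegressionResult:
    """Ordinary least squares of observed dates on the predictor set.

    ``predictors`` is a mapping name -> vector (or a 2-D array). Raises
    :class:`CollinearityError` on a rank-deficient design and
    :class:`ParameterError` when n < p + 2.
    """
    y = np.asarray(observed, dtype=float)
    X, names = _design(predictors, n=len(y))
    n, p1 = X.shape
    if len(y) != n:
        raise PairingError("observed and predictors have different lengths")
    if n < p1 + 1:
        raise ParameterError(f"need n >= {p1 + 1} observations, got {n}")
    sv = np.linalg.svd(X, compute_uv=False)
    if sv[-1] <= _RANK_RTOL * sv[0]:
        raise CollinearityError(f"rank-deficient design over predictors {names}")
    model = sm.OLS(y, X).fit()
    fitted = np.asarray(model.fittedvalues)
    resid = y - fitted
    return RegressionResult(
        predictor_names=names,
        coefficients=np.asarray(model.params),
        std_errors=np.asarray(model.bse),
        r_squared=float(model.rsquared),
        rmse=float(np.sqrt(np.mean(resid ** 2))),
        bias=float(np.mean(fitted - y)),
        f_p_value=float(model.f_pvalue),
        n=n,
        fitted=fitted,
        residuals=resid,
    )


def loocv(observed, predictors) -> CrossValidationResult:
    """Leave-one-out cross-validation by explicit refitting.

    Each site-year is predicted from the model fitted on the remaining
    n - 1 (this matches the PRESS/hat-matrix closed form for linear
    models, which the test-suite uses as its independent check).
    """
    y = np.asarray(observed, dtype=float)
    X, _names = _design(predictors, n=len(y))
    n, p1 = X.shape
    if n < p1 + 2:
        raise ParameterError(f"LOOCV needs n >= {p1 + 2}, got {n}")
    in_sample = fit_cfp_model(observed, predictors)

    preds = np.empty(n)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        Xi, yi = X[mask], y[mask]
        sv = np.linalg.svd(Xi, compute_uv=False)
        if sv[-1] <= _RANK_RTOL * sv[0]:
            raise FoldError(f"leave-one-out fold {i} is rank-deficient")
        beta, *_ = np.linalg.lstsq(Xi, yi, rcond=None)
        preds[i] = X[i] @ beta
        mask[i] = True

    resid = preds - y
    sst = float(np.sum((y - y.mean()) ** 2))
    r2_sse = 1.0 - float(np.sum(resid ** 2)) / sst if sst > 0 else float("nan")
    if np.std(preds) > 0 and np.std(y) > 0:
        r2_corr = float(np.corrcoef(y, preds)[0, 1] ** 2)
    else:
        r2_corr = float("nan")
    return CrossValidationResult(
        predictions=preds,
        r_squared=r2_corr,
        r_squared_sse=r2_sse,
        rmse=float(np.sqrt(np.mean(resid ** 2))),
        bias=float(np.mean(resid)),
        in_sample=in_sample,
    )


def evaluate_dates(reference, candidate) -> tuple[float, float, float]:
    """(R-squared, RMSE in days, bias in days) between paired date vectors.

    R-squared is from the least-squares fit of reference on candidate
    (equivalently the squared correlation); RMSE and bias are computed on
    the raw differences candidate - reference, so a candidate running
    systematically early shows bias < 0.
    """
    ref = np.asarray(reference, dtype=float)
    cand = np.asarray(candidate, dtype=float)
    if ref.shape != cand.shape:
        raise PairingError(f"length mismatch: {ref.shape} vs {cand.shape}")
    if len(ref) < 3:
        raise ParameterError("need at least 3 pairs")
    diff = cand - ref
    rmse = float(np.sqrt(np.mean(diff ** 2)))
    bias = float(np.mean(diff))
    if np.std(ref) == 0 or np.std(cand) == 0:
        r2 = 1.0 if np.allclose(diff, diff[0]) else 0.0
    else:
        r2 = float(np.corrcoef(ref, cand)[0, 1] ** 2)
    return r2, rmse, bias
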