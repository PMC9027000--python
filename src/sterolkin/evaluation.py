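"""Model-performance metrics and the elliptical joint confidence region test.

Metrics follow the predictive-modelling conventions: besides R2, MAE and
RMSE, the multiplicative bias factor B_f and accuracy factor A_f (base-10
logs of predicted/observed ratios) and the signed/absolute mean relative
percentage errors MRPE/MAPE.  The sign convention puts over-prediction at
negative MRPE and B_f slightly above 1.

The EJCR test regresses predicted on observed by OLS and asks whether the
ideal point (intercept 0, slope 1) falls inside the joint (1-alpha)
confidence ellipse {b : (b - b_hat)' X'X (b - b_hat) <= 2 s^2 F(1-alpha; 2, n-2)}.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import DataError

__all__ = ["MetricReport", "EJCRResult", "compute_metrics", "ejcr_test"]


@dataclass(frozen=True)
class MetricReport:
    """Validation indices for one (observed, predicted) pair set.

    ``bf_af_defined`` is False when any prediction is non-positive, in which
    case ``bf`` and ``af`` are NaN.  ``r2`` is the coefficient of
    determination 1 - SS_res/SS_tot and may be negative for very poor models.
    """

    r2: float
    mae: float
    rmse: float
    mrpe: float
    bf: float
    mape: float
    af: float
    n: int
    bf_af_defined: bool = True

    def to_dict(self) -> dict:
        return {
            "R2": self.r2,
            "MAE": self.mae,
            "RMSE": self.rmse,
            "MRPE_percent": self.mrpe,
            "Bf": self.bf,
            "MAPE_percent": self.mape,
            "Af": self.af,
            "n": self.n,
            "bf_af_defined": self.bf_af_defined,
        }


def compute_metrics(observed: np.ndarray, predicted: np.ndarray) -> MetricReport:
    """Compute R2, MAE, RMSE, MRPE, B_f, MAPE and A_f.

    MAE  = mean |obs - pred|
    RMSE = sqrt(mean (obs - pred)^2)
    B_f  = 10^(mean log10(pred/obs))
    MRPE = mean ((obs - pred)/obs) * 100   (over-prediction -> negative)
    A_f  = 10^(mean |log10(pred/obs)|)
    MAPE = mean |(obs - pred)/obs| * 100

    Observed values must be strictly positive.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError(f"shape mismatch: observed {obs.shape} vs predicted {pred.shape}")
    n = obs.size
    if n < 2:
        raise DataError(f"need at least 2 pairs, got {n}")
    if np.any(obs <= 0):
        raise DataError("observed values must be strictly positive")

    diff = obs - pred
    mae = float(np.mean(np.abs(diff)))
    rmse = float(np.sqrt(np.mean(np.square(diff))))
    rel = diff / obs
    mrpe = float(np.mean(rel) * 100.0)
    mape = float(np.mean(np.abs(rel)) * 100.0)
    ss_tot = float(np.sum(np.square(obs - obs.mean())))
    ss_res = float(np.sum(np.square(diff)))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else -math.inf)

    if np.any(pred <= 0):
        bf, af, defined = float("nan"), float("nan"), False
    else:
        logs = np.log10(pred / obs)
        bf = float(10.0 ** np.mean(logs))
        af = float(10.0 ** np.mean(np.abs(logs)))
        defined = True

    return MetricReport(r2=r2, mae=mae, rmse=rmse, mrpe=mrpe, bf=bf, mape=mape, af=af, n=n, bf_af_defined=defined)


@dataclass(frozen=True)
class EJCRResult:
    """Joint slope-intercept confidence-region outcome for predicted ~ observed."""

    intercept: float
    slope: float
    xtx: np.ndarray  # 2x2 cross-product matrix of [1, observed]
    residual_variance: float
    f_critical: float
    confidence: float
    contains_ideal: bool
    n: int
    #: semi-axis lengths of the ellipse (0.0 when residual variance is zero)
    semi_axes: tuple[float, float]
    #: unit vectors (rows) spanning the principal axes in (intercept, slope) space
    axis_directions: np.ndarray

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "slope": self.slope,
            "residual_variance": self.residual_variance,
            "f_critical": self.f_critical,
            "confidence": self.confidence,
            "contains_ideal": self.contains_ideal,
            "n": self.n,
            "semi_axes": list(self.semi_axes),
        }


_IDEAL = np.array([0.0, 1.0])  # intercept 0, slope 1

# residual variance below this (relative) threshold is treated as exactly zero
_ZERO_VAR_RTOL = 1e-20


def ejcr_test(observed: np.ndarray, predicted: np.ndarray, confidence: float = 0.95) -> EJCRResult:
    """OLS of predicted on observed plus the joint confidence-ellipse check.

    The ideal (intercept, slope) = (0, 1) is inside the region iff

        (ideal - b_hat)' X'X (ideal - b_hat) <= 2 s^2 F(confidence; 2, n-2)

    Zero residual variance degenerates the ellipse to a point: the ideal is
    then contained iff the estimate equals (0, 1) exactly.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError(f"shape mismatch: observed {obs.shape} vs predicted {pred.shape}")
    n = obs.size
    if n < 3:
        raise DataError(f"EJCR needs at least 3 pairs, got {n}")
    if np.ptp(obs) == 0:
        raise DataError("observed values are all equal; the regression is degenerate")
    if not 0.0 < confidence < 1.0:
        raise ValueError(f"confidence must be in (0, 1), got {confidence}")

    x = np.column_stack([np.ones(n), obs])
    beta, *_ = np.linalg.lstsq(x, pred, rcond=None)
    resid = pred - x @ beta
    s2 = float(resid @ resid) / (n - 2)
    xtx = x.T @ x
    f_crit = float(stats.f.ppf(confidence, 2, n - 2))

    scale = max(1.0, float(np.mean(np.square(pred))))
    if s2 <= _ZERO_VAR_RTOL * scale:
        s2 = 0.0
        contains = bool(np.allclose(beta, _IDEAL, rtol=0.0, atol=1e-10))
        semi_axes = (0.0, 0.0)
        eigvec = np.eye(2)
    else:
        d = _IDEAL - beta
        contains = bool(d @ xtx @ d <= 2.0 * s2 * f_crit)
        eigval, eigvec = np.linalg.eigh(xtx)
        c = 2.0 * s2 * f_crit
        semi = np.sqrt(c / eigval)  # largest semi-axis along smallest eigenvalue
        semi_axes = (float(semi[0]), float(semi[1]))
        eigvec = eigvec.T

    return EJCRResult(
        intercept=float(beta[0]),
        slope=float(beta[1]),
        xtx=xtx,
        residual_variance=s2,
        f_critical=f_crit,
        confidence=confidence,
        contains_ideal=contains,
        n=n,
        semi_axes=semi_axes,
        axis_directions=eigvec,
    )
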