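"""Second-order response-surface regression of phytosterol content.

The model is the full 10-term quadratic in (a_w, T, tau):

    y = b0 + b1*aw + b2*aw^2 + b3*T + b4*T^2 + b5*tau + b6*tau^2
        + b7*aw*T + b8*aw*tau + b9*T*tau

fitted by ordinary least squares on the *unscaled* predictors so that the
coefficients are directly comparable to the published reference values.  The
solver uses an orthogonal factorization (never the normal equations): the
squared-term columns make the raw design matrix ill-conditioned.
"""

from __future__ import annotations

import json
from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.linalg import solve_triangular

from .exceptions import DataError, RankDeficiencyError
from .synthetic_data import DegradationDataset, StorageCondition

__all__ = [
    "RSRCoefficients",
    "RSRFit",
    "REFERENCE_COEFFICIENTS",
    "COEFFICIENT_NAMES",
    "TERM_NAMES",
    "design_row",
    "design_matrix",
    "predict_rsr",
    "fit_rsr",
    "fit_response_surface",
]

COEFFICIENT_NAMES = (
    "beta0",
    "beta_aw",
    "beta_aw2",
    "beta_T",
    "beta_T2",
    "beta_tau",
    "beta_tau2",
    "beta_awT",
    "beta_awTau",
    "beta_TTau",
)

#: Human-readable term labels in design-column order.
TERM_NAMES = ("intercept", "aw", "aw^2", "T", "T^2", "tau", "tau^2", "aw*T", "aw*tau", "T*tau")

N_TERMS = 10


@dataclass(frozen=True)
class RSRCoefficients:
    """The 10 coefficients of the quadratic response surface (mg g^-1 units)."""

    beta0: float
    beta_aw: float
    beta_aw2: float
    beta_T: float
    beta_T2: float
    beta_tau: float
    beta_tau2: float
    beta_awT: float
    beta_awTau: float
    beta_TTau: float

    def __post_init__(self) -> None:
        for name in COEFFICIENT_NAMES:
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"coefficient {name} is not finite: {v}")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in COEFFICIENT_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values: Sequence[float]) -> "RSRCoefficients":
        values = np.asarray(values, dtype=float)
        if values.shape != (N_TERMS,):
            raise ValueError(f"expected {N_TERMS} coefficients, got shape {values.shape}")
        return cls(*(float(v) for v in values))


#: Published reference coefficient set, stored exactly as printed (4 d.p.).
REFERENCE_COEFFICIENTS = RSRCoefficients(
    beta0=-55.1677,
    beta_aw=132.8619,
    beta_aw2=-69.4989,
    beta_T=0.9326,
    beta_T2=-0.0037,
    beta_tau=0.2277,
    beta_tau2=0.0001,
    beta_awT=-1.0046,
    beta_awTau=-0.2870,
    beta_TTau=-0.0013,
)


def design_row(condition: StorageCondition) -> np.ndarray:
    """The 10-element regressor row [1, aw, aw^2, T, T^2, tau, tau^2, aw*T, aw*tau, T*tau]."""
    a, t, tau = condition.water_activity, condition.temperature, condition.time
    return np.array([1.0, a, a * a, t, t * t, tau, tau * tau, a * t, a * tau, t * tau])


def design_matrix(conditions: Sequence[StorageCondition] | np.ndarray) -> np.ndarray:
    """Stack design rows for a sequence of conditions (or an (n, 3) array of
    (a_w, T, tau) triples)."""
    if isinstance(conditions, np.ndarray):
        x = np.asarray(conditions, dtype=float)
        if x.ndim != 2 or x.shape[1] != 3:
            raise ValueError(f"expected an (n, 3) array of (aw, T, tau), got {x.shape}")
        a, t, tau = x[:, 0], x[:, 1], x[:, 2]
        return np.column_stack(
            [np.ones(len(x)), a, a * a, t, t * t, tau, tau * tau, a * t, a * tau, t * tau]
        )
    return np.array([design_row(c) for c in conditions])


def predict_rsr(
    coefficients: RSRCoefficients, conditions: Sequence[StorageCondition] | np.ndarray
) -> np.ndarray:
    """Evaluate the surface at each condition.  Negative predictions are
    returned as-is; validity flagging is the caller's concern."""
    return design_matrix(conditions) @ coefficients.as_array()


@dataclass(frozen=True)
class RSRFit:
    """An OLS fit of the quadratic surface with standard inference.

    ``p_values`` come from two-sided t-tests with ``n - 10`` degrees of
    freedom; ``residual_standard_error`` is the unbiased sigma-hat;
    ``correlation_R`` is the Pearson correlation of fitted vs observed.
    """

    coefficients: RSRCoefficients
    standard_errors: np.ndarray
    p_values: np.ndarray
    residual_standard_error: float
    correlation_R: float
    n: int
    roles: tuple[str, ...]

    def predict(self, conditions) -> np.ndarray:
        return predict_rsr(self.coefficients, conditions)

    def to_dict(self) -> dict:
        return {
            "coefficients": {n: getattr(self.coefficients, n) for n in COEFFICIENT_NAMES},
            "standard_errors": dict(zip(COEFFICIENT_NAMES, map(float, self.standard_errors))),
            "p_values": dict(zip(COEFFICIENT_NAMES, map(float, self.p_values))),
            "residual_standard_error": float(self.residual_standard_error),
            "correlation_R": float(self.correlation_R),
            "n": int(self.n),
            "roles": list(self.roles),
        }

    def save_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_dict(cls, d: dict) -> "RSRFit":
        return cls(
            coefficients=RSRCoefficients(**d["coefficients"]),
            standard_errors=np.array([d["standard_errors"][n] for n in COEFFICIENT_NAMES]),
            p_values=np.array([d["p_values"][n] for n in COEFFICIENT_NAMES]),
            residual_standard_error=float(d["residual_standard_error"]),
            correlation_R=float(d["correlation_R"]),
            n=int(d["n"]),
            roles=tuple(d["roles"]),
        )

    @classmethod
    def load_json(cls, path) -> "RSRFit":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def _name_deficient_column(x: np.ndarray) -> str:
    # first column (in term order) lying in the span of its predecessors
    for j in range(1, x.shape[1]):
        prev, col = x[:, :j], x[:, j]
        resid = col - prev @ np.linalg.lstsq(prev, col, rcond=None)[0]
        if np.linalg.norm(resid) <= 1e-8 * max(np.linalg.norm(col), 1.0):
            return TERM_NAMES[j]
    return "unknown"


def fit_response_surface(
    x: np.ndarray, y: np.ndarray, roles: tuple[str, ...] = ()
) -> RSRFit:
    """OLS fit of the 10-term surface to (a_w, T, tau) rows ``x`` and targets ``y``.

    Raises :class:`DataError` for fewer than 11 rows and
    :class:`RankDeficiencyError` (naming the deficient term) when the design
    matrix is not full rank.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < N_TERMS + 1:
        raise DataError(f"need at least {N_TERMS + 1} rows to fit the surface, got {n}")
    xm = design_matrix(x)

    if np.linalg.matrix_rank(xm) < N_TERMS:
        raise RankDeficiencyError(
            f"design matrix is rank-deficient: column '{_name_deficient_column(xm)}' "
            "is collinear with preceding terms"
        )

    # QR solve; cov(beta) = s^2 (R^T R)^{-1}
    q, r = np.linalg.qr(xm)
    beta = solve_triangular(r, q.T @ y)
    fitted = xm @ beta
    resid = y - fitted
    dof = n - N_TERMS
    s2 = float(resid @ resid) / dof
    r_inv = solve_triangular(r, np.eye(N_TERMS))
    cov = s2 * (r_inv @ r_inv.T)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    pvals = 2.0 * stats.t.sf(np.abs(tvals), dof)

    if np.std(fitted) == 0 or np.std(y) == 0:
        corr = 1.0 if np.allclose(fitted, y) else 0.0
    else:
        corr = float(np.corrcoef(fitted, y)[0, 1])

    return RSRFit(
        coefficients=RSRCoefficients.from_array(beta),
        standard_errors=se,
        p_values=pvals,
        residual_standard_error=float(np.sqrt(s2)),
        correlation_R=corr,
        n=n,
        roles=roles,
    )


def fit_rsr(
    dataset: DegradationDataset,
    roles: Sequence[str] | None = ("learning", "test", "unassigned"),
) -> RSRFit:
    """Fit the surface to the rows matching ``roles``.

    The default role filter selects the building data (everything that is not
    held out for validation), whether or not the learning/test split has been
    applied.  Pass ``roles=None`` to fit on every row.
    """
    x, y = dataset.arrays(roles)
    used = tuple(roles) if roles is not None else ("all",)
    return fit_response_surface(x, y, roles=used)
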