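"""Small feed-forward regressors (MLP 3-H-1 and RBF 3-H-1) with topology search.

Both network types take (a_w, T, tau) and return phytosterol content.  Inputs
and target are min-max scaled to [0, 1] using learning-set bounds; all errors
are mean squared errors on the *scaled* target, so they are comparable across
topologies but not across differently scaled datasets.

MLPs are trained by BFGS on the scaled learning MSE with an early-stopping
snapshot at the best test error seen.  RBF networks use k-means centers, a
nearest-center width heuristic and a ridge-regularised linear output layer.
The topology search trains many restarts per topology, records the mean
learning/test/validation error curves, and selects the single network with
the lowest weighted error, where the weights are the learning/test/validation
shares of the dataset.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .exceptions import DataError, TrainingError
from .synthetic_data import DegradationDataset

__all__ = [
    "MLP_ACTIVATIONS",
    "NetworkSpec",
    "TrainedNetwork",
    "SearchResult",
    "activation",
    "count_parameters",
    "estimate_hidden_nodes",
    "forward",
    "train_mlp",
    "train_rbf",
    "architecture_search",
    "mlp_grid",
    "rbf_grid",
]

MLP_ACTIVATIONS = ("linear", "logistic", "exponential", "tanh")
_ALL_ACTIVATIONS = MLP_ACTIVATIONS + ("gaussian",)

# guard for the exponential activation: e^x overflows float64 near x = 710
_EXP_CLIP = 60.0


def activation(kind: str, x):
    """Evaluate an activation function elementwise.

    linear: x; logistic: 1/(1+e^-x); exponential: e^x; tanh; gaussian: e^(-x^2).
    """
    x = np.asarray(x, dtype=float)
    if kind == "linear":
        return x + 0.0
    if kind == "logistic":
        return 1.0 / (1.0 + np.exp(-np.clip(x, -_EXP_CLIP, _EXP_CLIP)))
    if kind == "exponential":
        return np.exp(np.clip(x, -_EXP_CLIP, _EXP_CLIP))
    if kind == "tanh":
        return np.tanh(x)
    if kind == "gaussian":
        return np.exp(-np.square(x))
    raise ValueError(f"unknown activation {kind!r}; expected one of {_ALL_ACTIVATIONS}")


def _activation_and_derivative(kind: str, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    h = activation(kind, x)
    if kind == "linear":
        return h, np.ones_like(h)
    if kind == "logistic":
        return h, h * (1.0 - h)
    if kind == "exponential":
        return h, h
    if kind == "tanh":
        return h, 1.0 - h * h
    raise ValueError(f"no derivative for activation {kind!r}")


@dataclass(frozen=True)
class NetworkSpec:
    """Topology of a 3-H-1 regressor: type, hidden size and activations."""

    network_type: str  # "mlp" or "rbf"
    n_hidden: int
    hidden_activation: str = "logistic"
    n_input: int = 3
    n_output: int = 1
    output_activation: str = "linear"

    def __post_init__(self) -> None:
        if self.network_type not in ("mlp", "rbf"):
            raise ValueError(f"network_type must be 'mlp' or 'rbf', got {self.network_type!r}")
        if self.n_hidden < 1:
            raise ValueError(f"n_hidden must be >= 1, got {self.n_hidden}")
        if self.output_activation != "linear":
            raise ValueError("the output layer is linear in regression mode")
        if self.network_type == "mlp" and self.hidden_activation not in MLP_ACTIVATIONS:
            raise ValueError(
                f"MLP hidden activation must be one of {MLP_ACTIVATIONS}, "
                f"got {self.hidden_activation!r}"
            )
        if self.network_type == "rbf" and self.hidden_activation != "gaussian":
            raise ValueError("RBF hidden activation must be 'gaussian'")

    @property
    def label(self) -> str:
        return f"{self.network_type.upper()} {self.n_input}-{self.n_hidden}-{self.n_output} ({self.hidden_activation})"


def count_parameters(spec: NetworkSpec) -> int:
    """Number of free parameters: N_in*N_h + N_h + N_out*N_h + N_out for an
    MLP; centers + widths + output weights + bias for an RBF."""
    h = spec.n_hidden
    if spec.network_type == "mlp":
        return spec.n_input * h + h + spec.n_output * h + spec.n_output
    return spec.n_input * h + h + spec.n_output * h + spec.n_output  # same count: H centers*3 + H widths + H weights + 1


def estimate_hidden_nodes(L: int, n_in: int = 3, n_out: int = 1) -> float:
    """Rule-of-thumb hidden-layer size assuming five learning cases per model
    parameter: N_h = (L - 5*N_out) / (5*(N_in + 1 + N_out)).

    Returns the raw (generally non-integer) value; callers round.
    """
    if L <= 5 * n_out:
        raise ValueError(f"need more than {5 * n_out} learning cases, got {L}")
    return (L - 5.0 * n_out) / (5.0 * (n_in + 1 + n_out))


@dataclass
class TrainedNetwork:
    """A fitted 3-H-1 network plus its scaling bounds and per-set errors.

    ``errors`` holds MSE on the scaled target for the learning/test/validation
    sets (``None`` when a set was not supplied).
    """

    spec: NetworkSpec
    output_weights: np.ndarray  # (H,)
    output_bias: float
    x_min: np.ndarray  # (3,)
    x_max: np.ndarray  # (3,)
    y_min: float
    y_max: float
    init_seed: int
    hidden_weights: np.ndarray | None = None  # MLP: (3, H)
    hidden_biases: np.ndarray | None = None  # MLP: (H,)
    centers: np.ndarray | None = None  # RBF: (H, 3)
    widths: np.ndarray | None = None  # RBF: (H,)
    errors: dict = field(default_factory=dict)

    # -- scaling ---------------------------------------------------------
    def _x_range(self) -> np.ndarray:
        rng = self.x_max - self.x_min
        return np.where(rng == 0, 1.0, rng)

    def _y_range(self) -> float:
        rng = self.y_max - self.y_min
        return rng if rng != 0 else 1.0

    def scale_x(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.x_min) / self._x_range()

    def scale_y(self, y: np.ndarray) -> np.ndarray:
        return (np.asarray(y, dtype=float) - self.y_min) / self._y_range()

    def unscale_y(self, ys: np.ndarray) -> np.ndarray:
        return np.asarray(ys, dtype=float) * self._y_range() + self.y_min

    # -- forward pass ----------------------------------------------------
    def forward_scaled(self, xs: np.ndarray) -> np.ndarray:
        """Scaled-space forward pass on already-scaled inputs."""
        if self.spec.network_type == "mlp":
            h = activation(self.spec.hidden_activation, xs @ self.hidden_weights + self.hidden_biases)
        else:
            d2 = np.square(xs[:, None, :] - self.centers[None, :, :]).sum(axis=2)
            h = np.exp(-d2 / (2.0 * np.square(self.widths)))
        return h @ self.output_weights + self.output_bias

    def predict(self, x: np.ndarray, return_flags: bool = False):
        """Predict phytosterol content (mg g^-1) for raw (a_w, T, tau) rows.

        With ``return_flags=True`` also returns a boolean extrapolation flag
        per row (input outside the stored scaling bounds).
        """
        x = np.atleast_2d(np.asarray(x, dtype=float))
        y = self.unscale_y(self.forward_scaled(self.scale_x(x)))
        if not return_flags:
            return y
        flags = ((x < self.x_min) | (x > self.x_max)).any(axis=1)
        return y, flags

    def mse(self, x: np.ndarray, y: np.ndarray) -> float:
        """MSE on the scaled target for raw inputs/targets."""
        pred = self.forward_scaled(self.scale_x(np.atleast_2d(x)))
        return float(np.mean(np.square(pred - self.scale_y(y))))

    def weighted_error(self, weights: Sequence[float]) -> float:
        wl, wt, wv = weights
        total = wl * (self.errors.get("learning") or 0.0)
        total += wt * (self.errors.get("test") or 0.0)
        total += wv * (self.errors.get("validation") or 0.0)
        return float(total)

    # -- serialisation ---------------------------------------------------
    def to_dict(self) -> dict:
        def arr(a):
            return None if a is None else np.asarray(a).tolist()

        return {
            "spec": {
                "network_type": self.spec.network_type,
                "n_hidden": self.spec.n_hidden,
                "hidden_activation": self.spec.hidden_activation,
                "n_input": self.spec.n_input,
                "n_output": self.spec.n_output,
            },
            "output_weights": arr(self.output_weights),
            "output_bias": float(self.output_bias),
            "x_min": arr(self.x_min),
            "x_max": arr(self.x_max),
            "y_min": float(self.y_min),
            "y_max": float(self.y_max),
            "init_seed": int(self.init_seed),
            "hidden_weights": arr(self.hidden_weights),
            "hidden_biases": arr(self.hidden_biases),
            "centers": arr(self.centers),
            "widths": arr(self.widths),
            "errors": {k: (None if v is None else float(v)) for k, v in self.errors.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrainedNetwork":
        def arr(a, shape2d=False):
            return None if a is None else np.asarray(a, dtype=float)

        return cls(
            spec=NetworkSpec(**d["spec"]),
            output_weights=np.asarray(d["output_weights"], dtype=float),
            output_bias=float(d["output_bias"]),
            x_min=np.asarray(d["x_min"], dtype=float),
            x_max=np.asarray(d["x_max"], dtype=float),
            y_min=float(d["y_min"]),
            y_max=float(d["y_max"]),
            init_seed=int(d["init_seed"]),
            hidden_weights=arr(d["hidden_weights"]),
            hidden_biases=arr(d["hidden_biases"]),
            centers=arr(d["centers"]),
            widths=arr(d["widths"]),
            errors=dict(d["errors"]),
        )

    def save_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def load_json(cls, path) -> "TrainedNetwork":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def forward(net: TrainedNetwork, x, return_flags: bool = False):
    """Functional alias for :meth:`TrainedNetwork.predict`."""
    return net.predict(x, return_flags=return_flags)


# ---------------------------------------------------------------------------
# MLP training
# ---------------------------------------------------------------------------


def _pack(w1: np.ndarray, b1: np.ndarray, w2: np.ndarray, b2: float) -> np.ndarray:
    return np.concatenate([w1.ravel(), b1, w2, [b2]])


def _unpack(theta: np.ndarray, n_in: int, h: int):
    w1 = theta[: n_in * h].reshape(n_in, h)
    b1 = theta[n_in * h : n_in * h + h]
    w2 = theta[n_in * h + h : n_in * h + 2 * h]
    b2 = theta[-1]
    return w1, b1, w2, b2


def _mlp_loss_grad(theta, xs, ys, kind, n_in, h):
    w1, b1, w2, b2 = _unpack(theta, n_in, h)
    z = xs @ w1 + b1
    a, da = _activation_and_derivative(kind, z)
    pred = a @ w2 + b2
    r = pred - ys
    n = len(ys)
    loss = float(r @ r) / n
    gpred = 2.0 * r / n
    gb2 = gpred.sum()
    gw2 = a.T @ gpred
    gz = np.outer(gpred, w2) * da
    gw1 = xs.T @ gz
    gb1 = gz.sum(axis=0)
    return loss, _pack(gw1, gb1, gw2, gb2)


def train_mlp(
    spec: NetworkSpec,
    x_learn: np.ndarray,
    y_learn: np.ndarray,
    x_test: np.ndarray | None = None,
    y_test: np.ndarray | None = None,
    init_seed: int = 0,
    max_iterations: int = 200,
) -> TrainedNetwork:
    """Train an MLP by BFGS on the scaled learning MSE.

    Inputs and target are min-max scaled to [0, 1] with learning-set bounds.
    Weights start uniform on [-0.5, 0.5] drawn from ``init_seed``.  When a
    test set is given, the test error is evaluated after every iteration and
    the parameters with the best test error seen are returned (early-stopping
    snapshot); otherwise the final parameters are returned.
    ``max_iterations=0`` returns the untrained initial network.
    """
    if spec.network_type != "mlp":
        raise ValueError("train_mlp requires an MLP spec")
    x_learn = np.atleast_2d(np.asarray(x_learn, dtype=float))
    y_learn = np.asarray(y_learn, dtype=float)
    if len(y_learn) == 0:
        raise DataError("learning set is empty")

    net = TrainedNetwork(
        spec=spec,
        output_weights=np.zeros(spec.n_hidden),
        output_bias=0.0,
        x_min=x_learn.min(axis=0),
        x_max=x_learn.max(axis=0),
        y_min=float(y_learn.min()),
        y_max=float(y_learn.max()),
        init_seed=init_seed,
    )
    xs = net.scale_x(x_learn)
    ys = net.scale_y(y_learn)
    has_test = x_test is not None and y_test is not None and len(np.atleast_1d(y_test)) > 0
    if has_test:
        xts = net.scale_x(np.atleast_2d(np.asarray(x_test, dtype=float)))
        yts = net.scale_y(np.asarray(y_test, dtype=float))

    rng = np.random.default_rng(init_seed)
    n_in, h = spec.n_input, spec.n_hidden
    theta0 = rng.uniform(-0.5, 0.5, size=count_parameters(spec))
    kind = spec.hidden_activation

    def test_error(theta):
        w1, b1, w2, b2 = _unpack(theta, n_in, h)
        pred = activation(kind, xts @ w1 + b1) @ w2 + b2
        return float(np.mean(np.square(pred - yts)))

    if max_iterations > 0:
        best = {"err": test_error(theta0) if has_test else np.inf, "theta": theta0.copy()}

        def callback(theta):
            if has_test:
                err = test_error(theta)
                if err < best["err"]:
                    best["err"] = err
                    best["theta"] = theta.copy()

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # BFGS line-search warnings on flat regions
            result = minimize(
                _mlp_loss_grad,
                theta0,
                args=(xs, ys, kind, n_in, h),
                method="BFGS",
                jac=True,
                callback=callback,
                options={"maxiter": max_iterations, "gtol": 1e-8},
            )
        theta = best["theta"] if has_test else result.x
        if not has_test and not np.all(np.isfinite(theta)):
            theta = theta0  # fall back rather than return garbage
    else:
        theta = theta0

    if not np.all(np.isfinite(theta)):
        raise TrainingError(f"MLP training produced non-finite parameters (init_seed={init_seed})")

    w1, b1, w2, b2 = _unpack(theta, n_in, h)
    net.hidden_weights = w1
    net.hidden_biases = b1
    net.output_weights = w2
    net.output_bias = float(b2)
    net.errors = {
        "learning": net.mse(x_learn, y_learn),
        "test": net.mse(x_test, y_test) if has_test else None,
        "validation": None,
    }
    if not np.isfinite(net.errors["learning"]):
        raise TrainingError(f"MLP training diverged (init_seed={init_seed})")
    return net


# ---------------------------------------------------------------------------
# RBF training
# ---------------------------------------------------------------------------


def _kmeans_centers(xs: np.ndarray, k: int, seed: int) -> np.ndarray:
    from sklearn.cluster import KMeans

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # duplicate points can yield < k distinct clusters
        km = KMeans(n_clusters=k, n_init=4, random_state=seed).fit(xs)
    return km.cluster_centers_


def train_rbf(
    spec: NetworkSpec,
    x_learn: np.ndarray,
    y_learn: np.ndarray,
    x_test: np.ndarray | None = None,
    y_test: np.ndarray | None = None,
    init_seed: int = 0,
    width_neighbors: int = 2,
    width_scale: float = 1.0,
    ridge: float = 1e-8,
) -> TrainedNetwork:
    """Fit an RBF network: seeded k-means centers on the scaled inputs, widths
    from the mean distance to the ``width_neighbors`` nearest other centers
    (times ``width_scale``), and a ridge-regularised linear output layer."""
    if spec.network_type != "rbf":
        raise ValueError("train_rbf requires an RBF spec")
    x_learn = np.atleast_2d(np.asarray(x_learn, dtype=float))
    y_learn = np.asarray(y_learn, dtype=float)
    if spec.n_hidden > len(y_learn):
        raise DataError(
            f"n_hidden={spec.n_hidden} exceeds the number of learning rows ({len(y_learn)})"
        )

    net = TrainedNetwork(
        spec=spec,
        output_weights=np.zeros(spec.n_hidden),
        output_bias=0.0,
        x_min=x_learn.min(axis=0),
        x_max=x_learn.max(axis=0),
        y_min=float(y_learn.min()),
        y_max=float(y_learn.max()),
        init_seed=init_seed,
    )
    xs = net.scale_x(x_learn)
    ys = net.scale_y(y_learn)

    centers = _kmeans_centers(xs, spec.n_hidden, init_seed)
    h = spec.n_hidden
    if h > 1:
        dists = np.sqrt(np.square(centers[:, None, :] - centers[None, :, :]).sum(axis=2))
        np.fill_diagonal(dists, np.inf)
        p = min(width_neighbors, h - 1)
        widths = np.sort(dists, axis=1)[:, :p].mean(axis=1)
    else:
        widths = np.array([np.sqrt(np.square(xs - centers[0]).sum(axis=1)).mean()])
    widths = np.maximum(widths * width_scale, 1e-8)

    d2 = np.square(xs[:, None, :] - centers[None, :, :]).sum(axis=2)
    phi = np.exp(-d2 / (2.0 * np.square(widths)))
    a = np.column_stack([phi, np.ones(len(xs))])
    gram = a.T @ a + ridge * np.eye(h + 1)
    coef = np.linalg.solve(gram, a.T @ ys)

    net.centers = centers
    net.widths = widths
    net.output_weights = coef[:h]
    net.output_bias = float(coef[h])
    has_test = x_test is not None and y_test is not None and len(np.atleast_1d(y_test)) > 0
    net.errors = {
        "learning": net.mse(x_learn, y_learn),
        "test": net.mse(x_test, y_test) if has_test else None,
        "validation": None,
    }
    return net


# ---------------------------------------------------------------------------
# Topology grid search
# ---------------------------------------------------------------------------


def mlp_grid(
    hidden: Sequence[int] = range(2, 17), activations: Sequence[str] = ("logistic", "tanh", "exponential")
) -> list[NetworkSpec]:
    """MLP topology grid: hidden sizes crossed with hidden activations."""
    return [NetworkSpec("mlp", h, act) for act in activations for h in hidden]


def rbf_grid(hidden: Sequence[int] = range(2, 51)) -> list[NetworkSpec]:
    """RBF topology grid over hidden sizes (gaussian activation)."""
    return [NetworkSpec("rbf", h, "gaussian") for h in hidden]


@dataclass
class SearchResult:
    """Outcome of a topology grid search.

    ``curves`` holds the per-topology mean learning/test/validation errors
    over restarts; ``best`` is the single trained network minimising the
    share-weighted error, ties broken by fewer hidden nodes then lower
    validation error.
    """

    grid: list[NetworkSpec]
    restarts: int
    weights: tuple[float, float, float]
    curves: pd.DataFrame
    best: TrainedNetwork
    best_weighted_error: float
    L: int
    estimated_hidden: float

    def to_dict(self) -> dict:
        return {
            "restarts": self.restarts,
            "weights": list(self.weights),
            "curves": self.curves.to_dict(orient="list"),
            "best": self.best.to_dict(),
            "best_weighted_error": float(self.best_weighted_error),
            "L": int(self.L),
            "estimated_hidden": float(self.estimated_hidden),
        }


def architecture_search(
    dataset: DegradationDataset,
    grid: Sequence[NetworkSpec],
    restarts: int = 25,
    base_seed: int = 0,
    max_iterations: int = 200,
) -> SearchResult:
    """Train ``restarts`` networks per topology and pick the best one.

    Selection weights are the learning/test/validation shares of the dataset;
    the winner minimises ``w_l*E_l + w_t*E_t + w_v*E_v`` over every trained
    network.  Seeds are derived as ``base_seed + topology_index*restarts +
    restart_index`` so runs are reproducible and restarts independent.
    """
    if not grid:
        raise ValueError("topology grid is empty")
    if restarts < 1:
        raise ValueError(f"restarts must be >= 1, got {restarts}")
    counts = dataset.role_counts()
    if counts["unassigned"]:
        raise DataError("dataset must be fully role-assigned before the search")

    x_learn, y_learn = dataset.arrays(["learning"])
    x_test, y_test = dataset.arrays(["test"])
    x_valid, y_valid = dataset.arrays(["validation"])
    n = dataset.n
    weights = (counts["learning"] / n, counts["test"] / n, counts["validation"] / n)
    L = counts["learning"]

    best_net: TrainedNetwork | None = None
    best_key: tuple | None = None
    rows = []
    for ti, spec in enumerate(grid):
        errs = {"learning": [], "test": [], "validation": []}
        for r in range(restarts):
            seed = base_seed + ti * restarts + r
            if spec.network_type == "mlp":
                net = train_mlp(
                    spec, x_learn, y_learn, x_test, y_test,
                    init_seed=seed, max_iterations=max_iterations,
                )
            else:
                h = min(spec.n_hidden, len(y_learn))
                eff_spec = spec if h == spec.n_hidden else NetworkSpec("rbf", h, "gaussian")
                net = train_rbf(eff_spec, x_learn, y_learn, x_test, y_test, init_seed=seed)
            if len(y_valid):
                net.errors["validation"] = net.mse(x_valid, y_valid)
            for k in errs:
                errs[k].append(net.errors[k] if net.errors[k] is not None else np.nan)
            werr = net.weighted_error(weights)
            key = (werr, net.spec.n_hidden, net.errors.get("validation") or np.inf)
            if best_key is None or key < best_key:
                best_key = key
                best_net = net
        rows.append(
            {
                "network_type": spec.network_type,
                "n_hidden": spec.n_hidden,
                "hidden_activation": spec.hidden_activation,
                "mean_learning_error": float(np.nanmean(errs["learning"])),
                "mean_test_error": float(np.nanmean(errs["test"])) if counts["test"] else np.nan,
                "mean_validation_error": float(np.nanmean(errs["validation"]))
                if counts["validation"]
                else np.nan,
            }
        )

    return SearchResult(
        grid=list(grid),
        restarts=restarts,
        weights=weights,
        curves=pd.DataFrame(rows),
        best=best_net,
        best_weighted_error=float(best_key[0]),
        L=L,
        estimated_hidden=estimate_hidden_nodes(L) if L > 5 else float("nan"),
    )
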