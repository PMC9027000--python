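"""Synthetic storage-experiment data generation and data-role splitting.

The generator emulates a factorial storage design: temperature levels crossed
with water-activity levels, each experiment sampled at regular intervals over
its storage duration, with replicate phytosterol determinations per sampling
time.  Phytosterol content is drawn from a quadratic degradation surface plus
additive Gaussian noise, so every downstream modelling stage can be exercised
without any external data.
"""

from __future__ import annotations

import math
from collections.abc import Callable, Iterable, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DataError, DesignError, GenerationError, StateError

__all__ = [
    "StorageCondition",
    "ExperimentPlan",
    "StorageDesign",
    "DegradationDataset",
    "RoleShares",
    "build_storage_design",
    "default_design",
    "tabulated_design",
    "simulate_degradation",
    "split_learning_test",
    "set_shares",
    "DEFAULT_TEMPERATURES",
    "DEFAULT_WATER_ACTIVITIES",
    "DEFAULT_VALIDATION_CONDITIONS",
    "PS_FLOOR",
]

#: Default factorial levels (4 temperatures x 4 water activities).
DEFAULT_TEMPERATURES: tuple[float, ...] = (12.0, 18.0, 24.0, 30.0)
DEFAULT_WATER_ACTIVITIES: tuple[float, ...] = (0.75, 0.80, 0.85, 0.90)

#: Default conditions reserved for external validation (one per temperature,
#: mirroring the published experiment-type pattern on the default levels).
DEFAULT_VALIDATION_CONDITIONS: tuple[tuple[float, float], ...] = (
    (12.0, 0.85),
    (18.0, 0.80),
    (24.0, 0.85),
    (30.0, 0.80),
)

#: Per-temperature water-activity levels of the tabulated (non-crossed) preset,
#: with the validation conditions marked separately below.
TABULATED_WATER_ACTIVITIES: dict[float, tuple[float, ...]] = {
    12.0: (0.76, 0.80, 0.86, 0.90),
    18.0: (0.76, 0.80, 0.86, 0.90),
    24.0: (0.75, 0.81, 0.85, 0.90),
    30.0: (0.75, 0.80, 0.84, 0.90),
}
TABULATED_VALIDATION_CONDITIONS: tuple[tuple[float, float], ...] = (
    (12.0, 0.86),
    (18.0, 0.80),
    (24.0, 0.85),
    (30.0, 0.80),
)

#: Storage lasts 72 days for low water activities and 48 days for high ones.
LONG_DURATION = 72.0
SHORT_DURATION = 48.0
AW_DURATION_THRESHOLD = 0.81

#: Truncation floor keeping phytosterol content strictly positive (mg g^-1).
PS_FLOOR = 1e-6

ROLES = ("learning", "test", "validation", "unassigned")

CSV_COLUMNS = [
    "experiment_id",
    "temperature_C",
    "water_activity",
    "time_days",
    "replicate",
    "ps_mg_per_g",
    "role",
]


def default_duration_rule(water_activity: float) -> float:
    """72-day storage for a_w <= 0.81, 48-day storage otherwise."""
    return LONG_DURATION if water_activity <= AW_DURATION_THRESHOLD else SHORT_DURATION


@dataclass(frozen=True)
class StorageCondition:
    """One (water activity, temperature, time) point — the model inputs."""

    water_activity: float
    temperature: float
    time: float

    def __post_init__(self) -> None:
        if not 0.0 < self.water_activity < 1.0:
            raise ValueError(f"water_activity must be in (0, 1), got {self.water_activity}")
        if self.time < 0.0:
            raise ValueError(f"time must be non-negative, got {self.time}")


@dataclass(frozen=True)
class ExperimentPlan:
    """A single storage experiment: constant (T, a_w), sampled over time."""

    experiment_id: str
    temperature: float
    water_activity: float
    duration: float
    purpose: str  # "build" or "validation"

    def __post_init__(self) -> None:
        if self.purpose not in ("build", "validation"):
            raise ValueError(f"purpose must be 'build' or 'validation', got {self.purpose!r}")


@dataclass(frozen=True)
class StorageDesign:
    """A set of storage experiments with a common sampling schedule."""

    experiments: tuple[ExperimentPlan, ...]
    sampling_interval: float
    replicates: int

    def sampling_times(self, experiment: ExperimentPlan) -> np.ndarray:
        """Times 0, h, 2h, ... up to and including the experiment duration."""
        n_steps = int(math.floor(experiment.duration / self.sampling_interval + 1e-9))
        return np.arange(n_steps + 1) * self.sampling_interval

    @property
    def n_rows(self) -> int:
        return sum(len(self.sampling_times(e)) * self.replicates for e in self.experiments)

    @property
    def build_experiments(self) -> tuple[ExperimentPlan, ...]:
        return tuple(e for e in self.experiments if e.purpose == "build")

    @property
    def validation_experiments(self) -> tuple[ExperimentPlan, ...]:
        return tuple(e for e in self.experiments if e.purpose == "validation")


def _is_validation(
    temperature: float, water_activity: float, validation_conditions: Iterable[tuple[float, float]]
) -> bool:
    return any(
        math.isclose(temperature, t, abs_tol=1e-9) and math.isclose(water_activity, a, abs_tol=1e-9)
        for t, a in validation_conditions
    )


def build_storage_design(
    temperatures: Sequence[float] = DEFAULT_TEMPERATURES,
    water_activities: Sequence[float] = DEFAULT_WATER_ACTIVITIES,
    sampling_interval: float = 6.0,
    replicates: int = 3,
    validation_conditions: Sequence[tuple[float, float]] = (),
    duration_rule: Callable[[float], float] = default_duration_rule,
) -> StorageDesign:
    """Cross temperature and water-activity levels into a storage design.

    Each (T, a_w) pair becomes one experiment whose duration follows
    ``duration_rule`` (default: 72 days for a_w <= 0.81, else 48 days).
    Conditions listed in ``validation_conditions`` are labelled for external
    validation; they must occur in the crossed grid.
    """
    if not temperatures or not water_activities:
        raise ValueError("temperatures and water_activities must be non-empty")
    if sampling_interval <= 0:
        raise ValueError(f"sampling_interval must be positive, got {sampling_interval}")
    if replicates < 1:
        raise ValueError(f"replicates must be >= 1, got {replicates}")

    pairs = [(t, a) for t in temperatures for a in water_activities]
    for cond in validation_conditions:
        if not any(_is_validation(t, a, [cond]) for t, a in pairs):
            raise DesignError(f"validation condition {cond} is not in the crossed design")

    experiments = []
    for i, (t, a) in enumerate(pairs, start=1):
        purpose = "validation" if _is_validation(t, a, validation_conditions) else "build"
        experiments.append(
            ExperimentPlan(
                experiment_id=f"E{i:02d}",
                temperature=float(t),
                water_activity=float(a),
                duration=float(duration_rule(a)),
                purpose=purpose,
            )
        )
    return StorageDesign(tuple(experiments), float(sampling_interval), int(replicates))


def default_design(sampling_interval: float = 6.0, replicates: int = 3) -> StorageDesign:
    """The default 16-experiment design: 12 build + 4 validation."""
    return build_storage_design(
        DEFAULT_TEMPERATURES,
        DEFAULT_WATER_ACTIVITIES,
        sampling_interval=sampling_interval,
        replicates=replicates,
        validation_conditions=DEFAULT_VALIDATION_CONDITIONS,
    )


def tabulated_design(sampling_interval: float = 6.0, replicates: int = 3) -> StorageDesign:
    """Preset using the exact per-temperature water-activity levels (non-crossed)."""
    if sampling_interval <= 0:
        raise ValueError(f"sampling_interval must be positive, got {sampling_interval}")
    if replicates < 1:
        raise ValueError(f"replicates must be >= 1, got {replicates}")
    experiments = []
    i = 1
    for t, aws in TABULATED_WATER_ACTIVITIES.items():
        for a in aws:
            purpose = (
                "validation" if _is_validation(t, a, TABULATED_VALIDATION_CONDITIONS) else "build"
            )
            experiments.append(
                ExperimentPlan(f"E{i:02d}", t, a, default_duration_rule(a), purpose)
            )
            i += 1
    return StorageDesign(tuple(experiments), float(sampling_interval), int(replicates))


@dataclass
class DegradationDataset:
    """Labelled degradation observations: one row per replicate measurement.

    Backed by a :class:`pandas.DataFrame` with the canonical column schema
    ``experiment_id, temperature_C, water_activity, time_days, replicate,
    ps_mg_per_g, role``.
    """

    df: pd.DataFrame = field(repr=False)
    seed: int | None = None

    def __post_init__(self) -> None:
        missing = [c for c in CSV_COLUMNS if c not in self.df.columns]
        if missing:
            raise DataError(f"dataset is missing columns: {missing}")
        self.df = self.df[CSV_COLUMNS].reset_index(drop=True)
        if (self.df["ps_mg_per_g"] <= 0).any():
            raise DataError("phytosterol content must be strictly positive in every row")
        bad = set(self.df["role"]) - set(ROLES)
        if bad:
            raise DataError(f"unknown roles: {sorted(bad)}")

    @property
    def n(self) -> int:
        return len(self.df)

    def role_counts(self) -> dict[str, int]:
        counts = self.df["role"].value_counts().to_dict()
        return {r: int(counts.get(r, 0)) for r in ROLES}

    def rows(self, roles: Sequence[str] | None = None) -> pd.DataFrame:
        if roles is None:
            return self.df
        return self.df[self.df["role"].isin(roles)]

    def arrays(self, roles: Sequence[str] | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Feature matrix (a_w, T, tau) and target vector for the given roles."""
        sub = self.rows(roles)
        x = sub[["water_activity", "temperature_C", "time_days"]].to_numpy(dtype=float)
        y = sub["ps_mg_per_g"].to_numpy(dtype=float)
        return x, y

    def conditions(self, roles: Sequence[str] | None = None) -> list[StorageCondition]:
        x, _ = self.arrays(roles)
        return [StorageCondition(a, t, tau) for a, t, tau in x]

    def copy(self) -> "DegradationDataset":
        return DegradationDataset(self.df.copy(), seed=self.seed)

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "DegradationDataset":
        df = pd.read_csv(path, dtype={"experiment_id": str, "role": str})
        return cls(df)


def simulate_degradation(
    design: StorageDesign,
    coefficients,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> DegradationDataset:
    """Simulate phytosterol measurements over a storage design.

    Each row's content is the quadratic-surface value at its condition plus
    Gaussian noise with standard deviation ``noise_sd`` (mg g^-1), truncated
    below at :data:`PS_FLOOR`.  The same seed always yields the same dataset.

    Raises
    ------
    GenerationError
        If the noise-free surface is non-positive anywhere in the design
        (the design lies outside the model's validity region).
    """
    from .rsr import predict_rsr  # local import to avoid a cycle

    if noise_sd < 0:
        raise ValueError(f"noise_sd must be non-negative, got {noise_sd}")

    records: list[tuple] = []
    conditions: list[StorageCondition] = []
    for exp in design.experiments:
        role = "validation" if exp.purpose == "validation" else "unassigned"
        for tau in design.sampling_times(exp):
            for rep in range(1, design.replicates + 1):
                records.append(
                    (exp.experiment_id, exp.temperature, exp.water_activity, float(tau), rep, role)
                )
                conditions.append(StorageCondition(exp.water_activity, exp.temperature, float(tau)))

    surface = predict_rsr(coefficients, conditions)
    if np.any(surface <= 0):
        i = int(np.argmin(surface))
        raise GenerationError(
            "degradation surface is non-positive at "
            f"(a_w={conditions[i].water_activity}, T={conditions[i].temperature}, "
            f"tau={conditions[i].time}): {surface[i]:.4f} mg/g — design outside model validity"
        )

    rng = np.random.default_rng(seed)
    ps = surface + rng.normal(0.0, noise_sd, size=len(surface))
    ps = np.maximum(ps, PS_FLOOR)

    df = pd.DataFrame.from_records(
        records,
        columns=["experiment_id", "temperature_C", "water_activity", "time_days", "replicate", "role"],
    )
    df.insert(5, "ps_mg_per_g", ps)
    return DegradationDataset(df, seed=seed)


def split_learning_test(
    dataset: DegradationDataset, learning_fraction: float = 0.7, seed: int = 0
) -> DegradationDataset:
    """Assign build rows to the learning/test roles at the given ratio.

    Replicate measurements of the same sample (same experiment and sampling
    time) are kept together: the split is drawn over replicate groups, with
    the test side rounded up to the nearest whole group and learning taking
    the remainder.  Rows already labelled ``validation`` are untouched.

    With 351 build rows in triplicate groups (117 groups) and a learning
    fraction of 0.70 this yields 243 learning and 108 test rows.
    """
    if not 0.0 < learning_fraction <= 1.0:
        raise ValueError(f"learning_fraction must be in (0, 1], got {learning_fraction}")
    build_mask = dataset.df["role"] != "validation"
    if (dataset.df.loc[build_mask, "role"] != "unassigned").any():
        raise StateError("build rows already have learning/test roles assigned")

    out = dataset.copy()
    groups = (
        out.df.loc[build_mask, ["experiment_id", "time_days"]]
        .drop_duplicates()
        .sort_values(["experiment_id", "time_days"])
        .to_records(index=False)
    )
    n_groups = len(groups)
    n_test = int(math.ceil((1.0 - learning_fraction) * n_groups - 1e-9))

    rng = np.random.default_rng(seed)
    order = rng.permutation(n_groups)
    test_groups = {tuple(groups[i]) for i in order[:n_test]}

    keys = list(zip(out.df["experiment_id"], out.df["time_days"]))
    new_roles = [
        role
        if role == "validation"
        else ("test" if key in test_groups else "learning")
        for role, key in zip(out.df["role"], keys)
    ]
    out.df["role"] = new_roles
    out.seed = seed
    return out


class RoleShares(tuple):
    """(learning, test, validation) fractions of a fully labelled dataset."""

    __slots__ = ()

    def __new__(cls, learning: float, test: float, validation: float):
        return super().__new__(cls, (learning, test, validation))

    @property
    def learning(self) -> float:
        return self[0]

    @property
    def test(self) -> float:
        return self[1]

    @property
    def validation(self) -> float:
        return self[2]


def set_shares(dataset: DegradationDataset) -> RoleShares:
    """Fractions of rows per role.  The validation share is the residual
    1 - learning - test so the three always sum to one exactly."""
    counts = dataset.role_counts()
    if counts["unassigned"]:
        raise StateError("dataset has unassigned rows; split it before computing shares")
    n = dataset.n
    if n == 0:
        raise DataError("dataset is empty")
    learning = counts["learning"] / n
    test = counts["test"] / n
    return RoleShares(learning, test, 1.0 - learning - test)
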