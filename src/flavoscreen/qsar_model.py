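"""MLR-QSAR fitting, GA descriptor selection and validation statistics.

Houses the two published regression equations (2D and 3D descriptor sets)
as immutable models, ordinary-least-squares fitting with leave-one-out
cross-validation, the nine-metric validation report, and a seeded genetic
algorithm for fixed-size descriptor-subset selection.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Callable, Mapping, Optional, Sequence

import numpy as np

from .compound_io import CompoundSet
from .descriptors_2d import DescriptorTable

__all__ = [
    "MLRModel",
    "ValidationReport",
    "GAConfig",
    "SingularDesignError",
    "fit_mlr",
    "predict",
    "published_model_2d",
    "published_model_3d",
    "train_test_split",
    "loo_cv",
    "validation_report",
    "ga_select",
    "residual",
]


class SingularDesignError(ValueError):
    """The design matrix is rank-deficient (exactly collinear columns)."""


@dataclass(frozen=True)
class MLRModel:
    intercept: float
    coefficients: Mapping[str, float]

    def __post_init__(self) -> None:
        if not self.coefficients:
            raise ValueError("model must have at least one coefficient")
        object.__setattr__(
            self, "coefficients", MappingProxyType(dict(self.coefficients))
        )

    @property
    def names(self) -> list[str]:
        return list(self.coefficients)

    def to_json(self) -> str:
        return json.dumps(
            {"intercept": self.intercept, "coefficients": dict(self.coefficients)},
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "MLRModel":
        obj = json.loads(text)
        return cls(intercept=obj["intercept"], coefficients=obj["coefficients"])


def published_model_2d() -> MLRModel:
    """The published 2D-descriptor equation (exact printed coefficients)."""
    return MLRModel(
        intercept=4.12506,
        coefficients={
            "MIC1": -0.15599,
            "ATS4v": -0.00011,
            "AATS7m": 0.05492,
            "CIC3": 3.06615,
            "minssCH2": -3.00189,
        },
    )


def published_model_3d() -> MLRModel:
    """The published 3D-descriptor equation (descriptors supplied externally)."""
    return MLRModel(
        intercept=8.97844,
        coefficients={
            "LOBMAX": 0.49135,
            "RDF35i": -0.03043,
            "TDB10i": 0.00505,
            "TDB9i": -0.01383,
            "TDB6m": 0.01155,
        },
    )


def _design(X: DescriptorTable | np.ndarray, names: Optional[Sequence[str]] = None):
    if isinstance(X, DescriptorTable):
        if names is not None:
            X = X.select(list(names))
        return X.values, list(X.names)
    arr = np.asarray(X, dtype=float)
    if names is None:
        names = [f"x{i+1}" for i in range(arr.shape[1])]
    return arr, list(names)


def fit_mlr(
    X: DescriptorTable | np.ndarray,
    y: Sequence[float],
    names: Optional[Sequence[str]] = None,
) -> MLRModel:
    """Ordinary least squares with intercept."""
    arr, names = _design(X, names)
    y = np.asarray(y, dtype=float)
    n, p = arr.shape
    if n <= p + 1:
        raise ValueError(f"insufficient data: n={n} rows for p={p} descriptors")
    if np.isnan(arr).any() or np.isnan(y).any():
        raise ValueError("design matrix or response contains missing values")
    design = np.column_stack([np.ones(n), arr])
    if np.linalg.matrix_rank(design) < p + 1:
        raise SingularDesignError("design matrix is rank-deficient")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return MLRModel(intercept=float(beta[0]), coefficients=dict(zip(names, beta[1:])))


def predict(model: MLRModel, data) -> np.ndarray | float:
    """Evaluate intercept + sum(coef * value) on a mapping, table or array."""
    if isinstance(data, Mapping):
        missing = [k for k in model.coefficients if k not in data]
        if missing:
            raise KeyError(f"missing descriptors: {missing}")
        return model.intercept + sum(
            coef * float(data[name]) for name, coef in model.coefficients.items()
        )
    if isinstance(data, DescriptorTable):
        sub = data.select(model.names)
        coefs = np.array([model.coefficients[n] for n in model.names])
        return model.intercept + sub.values @ coefs
    arr = np.asarray(data, dtype=float)
    coefs = np.array(list(model.coefficients.values()))
    return model.intercept + arr @ coefs


def train_test_split(
    compounds: CompoundSet, fraction: float = 0.8, seed: int = 0
) -> tuple[CompoundSet, CompoundSet]:
    """Seeded random split; the training side rounds up (27 -> 22/5)."""
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    n = len(compounds)
    if n < 2:
        raise ValueError("need at least two compounds to split")
    n_train = int(math.ceil(fraction * n))
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    ids = compounds.ids
    train_ids = sorted((ids[i] for i in order[:n_train]), key=ids.index)
    val_ids = sorted((ids[i] for i in order[n_train:]), key=ids.index)
    return (
        compounds.subset(train_ids, provenance=f"train split (seed={seed})"),
        compounds.subset(val_ids, provenance=f"validation split (seed={seed})"),
    )


def loo_cv(
    X: DescriptorTable | np.ndarray,
    y: Sequence[float],
    fit: Callable = fit_mlr,
) -> tuple[np.ndarray, float, float]:
    """Brute-force leave-one-out CV: (predictions, PRESS, Q2)."""
    arr, names = _design(X)
    y = np.asarray(y, dtype=float)
    n = len(y)
    preds = np.empty(n)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        try:
            model = fit(arr[mask], y[mask], names=names)
        except SingularDesignError as exc:
            raise SingularDesignError(
                f"singular design when leaving out observation {i}"
            ) from exc
        finally:
            mask[i] = True
        preds[i] = predict(model, arr[i])
    press = float(np.sum((y - preds) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    return preds, press, 1.0 - press / tss


@dataclass(frozen=True)
class ValidationReport:
    q2_loo: float
    r2_fitting: float
    r2_adjusted: float
    rss: float
    press: float
    sdec: float
    sdep: float
    mse: float
    mae: float
    n_train: int
    n_validation: int
    p: int

    _METRIC_NAMES = (
        ("Q2_LOO", "q2_loo"),
        ("R2 fitting", "r2_fitting"),
        ("R2 adjusted", "r2_adjusted"),
        ("RSS", "rss"),
        ("PRESS", "press"),
        ("SDEC", "sdec"),
        ("SDEP", "sdep"),
        ("MSE", "mse"),
        ("MAE", "mae"),
    )

    def to_csv(self, stream) -> None:
        stream.write("metric,value\n")
        for label, attr in self._METRIC_NAMES:
            stream.write(f"{label},{getattr(self, attr)}\n")


def adjusted_r2(r2: float, n: int, p: int) -> float:
    if n - p - 1 <= 0:
        raise ValueError("adjusted R2 undefined: n - p - 1 <= 0")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def validation_report(
    y_train: Sequence[float],
    yhat_train: Sequence[float],
    loo_predictions: Sequence[float],
    y_val: Sequence[float],
    yhat_val: Sequence[float],
    p: int,
) -> ValidationReport:
    """The nine fit/cross-validation statistics.

    RSS, R2, adjusted R2, SDEC and (via LOO) PRESS, Q2, SDEP are training
    quantities; MSE and MAE are computed on the validation set.
    """
    y_train = np.asarray(y_train, dtype=float)
    yhat_train = np.asarray(yhat_train, dtype=float)
    loo_predictions = np.asarray(loo_predictions, dtype=float)
    y_val = np.asarray(y_val, dtype=float)
    yhat_val = np.asarray(yhat_val, dtype=float)
    if not (len(y_train) == len(yhat_train) == len(loo_predictions)):
        raise ValueError("training vectors have inconsistent lengths")
    if len(y_val) != len(yhat_val):
        raise ValueError("validation vectors have inconsistent lengths")
    n = len(y_train)
    tss = float(np.sum((y_train - y_train.mean()) ** 2))
    if tss == 0.0:
        raise ValueError("zero training variance: R2 undefined")
    rss = float(np.sum((y_train - yhat_train) ** 2))
    press = float(np.sum((y_train - loo_predictions) ** 2))
    r2 = 1.0 - rss / tss
    return ValidationReport(
        q2_loo=1.0 - press / tss,
        r2_fitting=r2,
        r2_adjusted=adjusted_r2(r2, n, p),
        rss=rss,
        press=press,
        sdec=math.sqrt(rss / n),
        sdep=math.sqrt(press / n),
        mse=float(np.mean((y_val - yhat_val) ** 2)) if len(y_val) else float("nan"),
        mae=float(np.mean(np.abs(y_val - yhat_val))) if len(y_val) else float("nan"),
        n_train=n,
        n_validation=len(y_val),
        p=p,
    )


@dataclass(frozen=True)
class GAConfig:
    population: int = 50
    generations: int = 100
    subset_size: int = 5
    crossover_rate: float = 0.8
    mutation_rate: float = 0.1
    elitism: int = 2
    fitness: str = "q2_loo"  # or "r2_adjusted"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.crossover_rate <= 1.0 and 0.0 < self.mutation_rate <= 1.0):
            raise ValueError("rates must lie in (0, 1]")
        if self.elitism >= self.population:
            raise ValueError("elitism must be smaller than the population")
        if self.subset_size < 1:
            raise ValueError("subset size must be >= 1")
        if self.fitness not in ("q2_loo", "r2_adjusted"):
            raise ValueError(f"unknown fitness {self.fitness!r}")


def _subset_fitness(
    arr: np.ndarray, y: np.ndarray, subset: tuple[int, ...], fitness: str
) -> float:
    Xs = arr[:, list(subset)]
    try:
        model = fit_mlr(Xs, y)
    except (SingularDesignError, ValueError):
        return -np.inf
    if fitness == "q2_loo":
        try:
            _, _, q2 = loo_cv(Xs, y)
        except SingularDesignError:
            return -np.inf
        return q2
    yhat = predict(model, Xs)
    r2 = 1.0 - np.sum((y - yhat) ** 2) / np.sum((y - np.mean(y)) ** 2)
    return adjusted_r2(r2, len(y), Xs.shape[1])


def ga_select(
    table: DescriptorTable,
    y: Sequence[float],
    config: GAConfig = GAConfig(),
) -> tuple[list[str], MLRModel, list[float]]:
    """GA over fixed-size descriptor subsets.

    Chromosome = k-subset of column indices; tournament selection, uniform
    crossover repaired to size k, point mutation swapping one member, and
    elitism (so the best fitness trace is non-decreasing).  Deterministic
    for a given config seed.  Returns (names, refit model, fitness trace).
    """
    y = np.asarray(y, dtype=float)
    arr = table.values
    names = table.names
    n, p_total = arr.shape
    k = config.subset_size
    if p_total == 0:
        raise ValueError("empty descriptor table")
    if k >= n - 2:
        raise ValueError(f"subset size {k} too large for n={n} observations")
    if k > p_total:
        raise ValueError(f"subset size {k} exceeds {p_total} available descriptors")
    rng = np.random.default_rng(config.seed)
    cache: dict[tuple[int, ...], float] = {}

    def fit_of(subset: tuple[int, ...]) -> float:
        if subset not in cache:
            cache[subset] = _subset_fitness(arr, y, subset, config.fitness)
        return cache[subset]

    pop = [
        tuple(sorted(rng.choice(p_total, size=k, replace=False)))
        for _ in range(config.population)
    ]
    trace: list[float] = []
    best: tuple[float, tuple[int, ...]] = (-np.inf, pop[0])
    for _ in range(config.generations):
        scored = sorted(((fit_of(s), s) for s in pop), reverse=True)
        if scored[0][0] > best[0]:
            best = scored[0]
        trace.append(best[0])
        elite = [s for _, s in scored[: config.elitism]]
        children: list[tuple[int, ...]] = []
        while len(children) < config.population - config.elitism:
            pa = _tournament(scored, rng)
            pb = _tournament(scored, rng)
            if rng.random() < config.crossover_rate:
                child = _crossover(pa, pb, k, p_total, rng)
            else:
                child = pa
            if rng.random() < config.mutation_rate:
                child = _mutate(child, p_total, rng)
            children.append(child)
        pop = elite + children
    final = sorted(((fit_of(s), s) for s in pop), reverse=True)
    if final[0][0] > best[0]:
        best = final[0]
    chosen = [names[i] for i in best[1]]
    model = fit_mlr(arr[:, list(best[1])], y, names=chosen)
    return chosen, model, trace


def _tournament(scored, rng, size: int = 3) -> tuple[int, ...]:
    picks = rng.integers(0, len(scored), size=size)
    return max((scored[i] for i in picks), key=lambda t: t[0])[1]


def _crossover(pa, pb, k, p_total, rng) -> tuple[int, ...]:
    pool = sorted(set(pa) | set(pb))
    if len(pool) <= k:
        pool = pool + [g for g in range(p_total) if g not in pool]
    return tuple(sorted(rng.choice(pool, size=k, replace=False)))


def _mutate(subset, p_total, rng) -> tuple[int, ...]:
    outside = [g for g in range(p_total) if g not in subset]
    if not outside:
        return subset
    members = list(subset)
    members[rng.integers(0, len(members))] = outside[rng.integers(0, len(outside))]
    return tuple(sorted(set(members))) if len(set(members)) == len(members) else subset


def residual(cid: int, model_kind: str = "2d") -> float:
    """Printed Table residual (experimental minus predicted) for a reference CID."""
    from .compound_io import load_reference_predictions

    if model_kind not in ("2d", "3d"):
        raise ValueError(f"model kind must be '2d' or '3d', got {model_kind!r}")
    for row in load_reference_predictions():
        if row["cid"] == cid:
            return row[f"residual_{model_kind}"]
    raise KeyError(f"unknown reference compound CID {cid}")
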