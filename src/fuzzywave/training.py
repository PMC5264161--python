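"""Hybrid GA + gradient-descent training of the FWNN, and the GA-NN baseline.

The training scheme runs a real-coded genetic algorithm (global search over
all five parameter groups) and hands the best individual to full-batch plain
gradient descent for local refinement.  Default GA hyperparameters follow the
study configuration (population 100, crossover rate 0.3, per-gene mutation
rate 0.09, 200 generations).

All operations work on scaled data: ``X`` an ``(N, n)`` array of inputs and
``y`` an ``(N,)`` target vector, both in the space produced by
:mod:`fuzzywave.dataio` scaling.  Every stochastic operation takes an explicit
seed and is bit-reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from . import metrics as _metrics
from .errors import ConfigError, DegenerateActivationError, SchemaError, TrainingDivergedError
from .fwnn import AGGREGATIONS, FWNNParameters, WAVELETS, _aggregate, _layers, batch_predict

log = logging.getLogger(__name__)

__all__ = [
    "GAConfig",
    "GDConfig",
    "InitRanges",
    "TrainingReport",
    "BaselineNNParameters",
    "encode",
    "decode",
    "fitness",
    "ga_optimize",
    "gd_gradients",
    "gd_train",
    "hybrid_train",
    "baseline_nn_train",
]

PARAM_GROUPS = ("centers", "spreads", "dilations", "translations", "weights")

#: divisor-safety floor applied by decode to spreads and dilations
_DIVISOR_FLOOR = 1e-6


@dataclass
class InitRanges:
    """Per-group (low, high) initialization ranges for the GA.

    Spreads and dilations are drawn from the positive range and then given a
    random sign (both enter the model through even functions).  The defaults
    bracket the magnitudes seen in the packaged reference parameter set.
    """

    centers: tuple[float, float] = (-2.0, 2.0)
    spreads: tuple[float, float] = (0.1, 3.0)
    dilations: tuple[float, float] = (0.1, 3.0)
    translations: tuple[float, float] = (-2.0, 2.0)
    weights: tuple[float, float] = (-3.0, 3.0)

    #: groups whose draws get a random sign
    signed_groups: tuple[str, ...] = ("spreads", "dilations")


@dataclass
class GAConfig:
    population_size: int = 100
    crossover_rate: float = 0.3
    mutation_rate: float = 0.09
    max_generations: int = 200
    elitism_count: int = 2
    seed: int = 0
    init_ranges: InitRanges = field(default_factory=InitRanges)

    def validate(self) -> None:
        if self.population_size < 2:
            raise ConfigError("population_size must be >= 2")
        for name in ("crossover_rate", "mutation_rate"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be a probability in [0, 1]")
        if self.elitism_count < 1:
            raise ConfigError("elitism_count must be >= 1")
        if self.elitism_count >= self.population_size:
            raise ConfigError("elitism_count must be < population_size")
        if self.max_generations < 0:
            raise ConfigError("max_generations must be >= 0")


@dataclass
class GDConfig:
    learning_rate: float = 0.01
    max_epochs: int = 500
    target_error: float = 1e-4
    gradient_mode: str = "analytic"

    def validate(self) -> None:
        if self.learning_rate <= 0:
            raise ConfigError("learning_rate must be > 0")
        if self.target_error < 0:
            raise ConfigError("target_error must be >= 0")
        if self.gradient_mode not in ("analytic", "numeric"):
            raise ConfigError("gradient_mode must be 'analytic' or 'numeric'")


@dataclass
class TrainingReport:
    """Everything a training run produced: traces, final model, metrics."""

    ga_best_fitness_per_generation: list[float]
    gd_train_mse_per_epoch: list[float]
    final_params: object  # FWNNParameters or BaselineNNParameters
    train_metrics: "_metrics.Metrics"
    test_metrics: "_metrics.Metrics | None"
    seed: int

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "ga_best_fitness_per_generation": list(self.ga_best_fitness_per_generation),
            "gd_train_mse_per_epoch": list(self.gd_train_mse_per_epoch),
            "final_params": self.final_params.to_dict(),
            "train_metrics": self.train_metrics.to_dict(),
            "test_metrics": self.test_metrics.to_dict() if self.test_metrics else None,
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)


# ----------------------------------------------------------------------
# chromosome <-> parameters
# ----------------------------------------------------------------------

def chromosome_length(n_inputs: int, n_rules: int) -> int:
    return n_rules * 4 * n_inputs + n_rules


def encode(params: FWNNParameters) -> np.ndarray:
    """Flatten to a real vector: centers, spreads, dilations, translations
    (each row-major), then weights."""
    return np.concatenate(
        [
            params.centers.ravel(),
            params.spreads.ravel(),
            params.dilations.ravel(),
            params.translations.ravel(),
            params.weights,
        ]
    )


def decode(
    chromosome,
    n_inputs: int,
    n_rules: int,
    wavelet: str = "mexican_hat",
    aggregation: str = "normalized",
) -> FWNNParameters:
    """Inverse of :func:`encode`.

    Spread/dilation genes with magnitude below 1e-6 are clamped to +/-1e-6
    (they are divisors in the model); zeros clamp to +1e-6.
    """
    chrom = np.asarray(chromosome, dtype=float)
    expected = chromosome_length(n_inputs, n_rules)
    if chrom.shape != (expected,):
        raise SchemaError(
            f"chromosome has shape {chrom.shape}, expected ({expected},) for "
            f"{n_rules} rules x {n_inputs} inputs"
        )
    m = n_rules * n_inputs
    blocks = [chrom[k * m : (k + 1) * m].reshape(n_rules, n_inputs) for k in range(4)]
    weights = chrom[4 * m :].copy()

    def _clamp(a: np.ndarray) -> np.ndarray:
        a = a.copy()
        small = np.abs(a) < _DIVISOR_FLOOR
        a[small] = np.where(a[small] >= 0.0, _DIVISOR_FLOOR, -_DIVISOR_FLOOR)
        return a

    return FWNNParameters(
        centers=blocks[0],
        spreads=_clamp(blocks[1]),
        dilations=_clamp(blocks[2]),
        translations=blocks[3],
        weights=weights,
        wavelet=wavelet,
        aggregation=aggregation,
    )


# ----------------------------------------------------------------------
# fitness
# ----------------------------------------------------------------------

def fitness(
    chromosome,
    X: np.ndarray,
    y: np.ndarray,
    n_rules: int,
    aggregation: str = "normalized",
    wavelet: str = "mexican_hat",
) -> float:
    """GA fitness ``1 / (1 + MSE)`` in (0, 1]; degenerate or non-finite
    predictions score 0 so the search simply discards such individuals."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    params = decode(chromosome, X.shape[1], n_rules, wavelet=wavelet, aggregation=aggregation)
    try:
        pred = batch_predict(params, X, aggregation=aggregation)
    except DegenerateActivationError:
        return 0.0
    mse = float(np.mean((pred - y) ** 2))
    if not np.isfinite(mse):
        return 0.0
    return 1.0 / (1.0 + mse)


# ----------------------------------------------------------------------
# genetic algorithm
# ----------------------------------------------------------------------

def _gene_bounds_fwnn(n_inputs: int, n_rules: int, ranges: InitRanges):
    """Per-gene (low, high, signed) arrays following the encode layout."""
    m = n_inputs * n_rules
    low, high, signed = [], [], []
    for group, size in zip(PARAM_GROUPS, (m, m, m, m, n_rules)):
        lo, hi = getattr(ranges, group)
        low += [lo] * size
        high += [hi] * size
        signed += [group in ranges.signed_groups] * size
    return np.array(low), np.array(high), np.array(signed, dtype=bool)


def _ga_loop(eval_fn, low, high, signed, config: GAConfig):
    """Generic real-coded GA: tournament(2) selection, arithmetic crossover,
    per-gene Gaussian mutation (sd = 10% of the init range), elitism.

    Returns (best chromosome ever, best-fitness-per-generation trace)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    L = low.size
    pop_n = config.population_size
    mut_sd = 0.1 * (high - low)

    pop = rng.uniform(low, high, size=(pop_n, L))
    if signed.any():
        flips = rng.choice([-1.0, 1.0], size=(pop_n, signed.sum()))
        pop[:, signed] *= flips
    fit = np.array([eval_fn(ind) for ind in pop])

    best_idx = int(np.argmax(fit))
    best = pop[best_idx].copy()
    best_fit = float(fit[best_idx])
    trace: list[float] = []

    for _gen in range(config.max_generations):
        order = np.argsort(-fit, kind="stable")
        children = [pop[i].copy() for i in order[: config.elitism_count]]
        while len(children) < pop_n:
            picks = rng.integers(0, pop_n, size=4)
            p1 = pop[picks[0]] if fit[picks[0]] >= fit[picks[1]] else pop[picks[1]]
            p2 = pop[picks[2]] if fit[picks[2]] >= fit[picks[3]] else pop[picks[3]]
            if rng.random() < config.crossover_rate:
                alpha = rng.random(L)
                c1 = alpha * p1 + (1.0 - alpha) * p2
                c2 = (1.0 - alpha) * p1 + alpha * p2
            else:
                c1, c2 = p1.copy(), p2.copy()
            for child in (c1, c2):
                mask = rng.random(L) < config.mutation_rate
                if mask.any():
                    child[mask] += rng.normal(0.0, mut_sd[mask])
                if len(children) < pop_n:
                    children.append(child)
        pop = np.asarray(children)
        fit = np.array([eval_fn(ind) for ind in pop])
        gen_best = int(np.argmax(fit))
        if fit[gen_best] > best_fit:
            best_fit = float(fit[gen_best])
            best = pop[gen_best].copy()
        trace.append(best_fit)

    return best, trace


def ga_optimize(
    X: np.ndarray,
    y: np.ndarray,
    n_rules: int,
    config: GAConfig | None = None,
    aggregation: str = "normalized",
    wavelet: str = "mexican_hat",
):
    """GA stage: global search over all FWNN parameters.

    Returns ``(best_chromosome, best_fitness_per_generation)``; the trace is
    non-decreasing by construction (elitism + best-so-far bookkeeping).
    """
    config = config or GAConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ConfigError("ga_optimize requires a nonempty 2-D training set")
    low, high, signed = _gene_bounds_fwnn(X.shape[1], n_rules, config.init_ranges)

    def _eval(chrom):
        return fitness(chrom, X, y, n_rules, aggregation=aggregation, wavelet=wavelet)

    return _ga_loop(_eval, low, high, signed, config)


# ----------------------------------------------------------------------
# gradients / gradient descent
# ----------------------------------------------------------------------

def _leave_one_out_product(psi: np.ndarray) -> np.ndarray:
    # psi: (N, R, n) -> P[..., i] = prod over k != i of psi[..., k].
    # Explicit exclusion (not division) so zeros of the wavelet are safe.
    n = psi.shape[2]
    P = np.empty_like(psi)
    for i in range(n):
        P[:, :, i] = np.prod(np.delete(psi, i, axis=2), axis=2)
    return P


def _mse_and_gradients(params: FWNNParameters, X: np.ndarray, y: np.ndarray, aggregation: str):
    """Mean squared error over the batch and its gradient w.r.t. every
    parameter group, for the current wavelet family and aggregation mode."""
    _, dpsi_fn = WAVELETS[params.wavelet]
    N = X.shape[0]
    F, mu, z, psi, psihat = _layers(params, X)
    Psi = psi.prod(axis=2)  # (N, R)
    yhat = _aggregate(mu, psihat, aggregation)
    resid = yhat - y
    mse = float(np.mean(resid**2))
    d = 2.0 * resid / N  # dMSE/dyhat_k

    if aggregation == "normalized":
        S = mu.sum(axis=1)
        g_w = (d[:, None] * mu * Psi / S[:, None]).sum(axis=0)
        dmu = d[:, None] * (psihat - yhat[:, None]) / S[:, None]
        dPsi = d[:, None] * mu * params.weights[None, :] / S[:, None]
    else:
        g_w = (d[:, None] * mu * Psi).sum(axis=0)
        dmu = d[:, None] * psihat
        dPsi = d[:, None] * mu * params.weights[None, :]

    diff = X[:, None, :] - params.centers[None, :, :]
    sig2 = np.square(params.spreads)
    common = (dmu * mu)[:, :, None]
    g_c = (common * diff / sig2[None, :, :]).sum(axis=0)
    g_s = (common * np.square(diff) / (sig2 * params.spreads)[None, :, :]).sum(axis=0)

    P = _leave_one_out_product(psi)
    dz = dPsi[:, :, None] * P * dpsi_fn(z)
    g_b = (dz * (-1.0 / params.dilations)[None, :, :]).sum(axis=0)
    g_a = (dz * (-z / params.dilations[None, :, :])).sum(axis=0)

    grads = {
        "centers": g_c,
        "spreads": g_s,
        "dilations": g_a,
        "translations": g_b,
        "weights": g_w,
    }
    return mse, grads


def _numeric_gradients(params: FWNNParameters, X, y, aggregation, h: float = 1e-6):
    """Central finite differences of the batch MSE; the slow fallback mode."""
    chrom = encode(params)

    def loss(c):
        p = decode(c, params.n_inputs, params.n_rules, params.wavelet, aggregation)
        pred = batch_predict(p, X, aggregation=aggregation)
        return float(np.mean((pred - y) ** 2))

    g = np.empty_like(chrom)
    for k in range(chrom.size):
        cp, cm = chrom.copy(), chrom.copy()
        cp[k] += h
        cm[k] -= h
        g[k] = (loss(cp) - loss(cm)) / (2 * h)
    m = params.n_rules * params.n_inputs
    shape = (params.n_rules, params.n_inputs)
    return {
        "centers": g[:m].reshape(shape),
        "spreads": g[m : 2 * m].reshape(shape),
        "dilations": g[2 * m : 3 * m].reshape(shape),
        "translations": g[3 * m : 4 * m].reshape(shape),
        "weights": g[4 * m :],
    }


def gd_gradients(params: FWNNParameters, x, y_target: float, aggregation: str | None = None):
    """Analytic gradient of the squared error ``(yhat - y)**2`` for one sample,
    w.r.t. every parameter group.  Returns a dict keyed by group name."""
    mode = aggregation or params.aggregation
    x = np.asarray(x, dtype=float)
    _, grads = _mse_and_gradients(params, x[None, :], np.asarray([y_target], dtype=float), mode)
    return grads


def gd_train(
    params: FWNNParameters,
    X: np.ndarray,
    y: np.ndarray,
    config: GDConfig | None = None,
    aggregation: str | None = None,
    groups: tuple[str, ...] = PARAM_GROUPS,
):
    """Full-batch plain gradient descent on the training MSE.

    Stops at ``max_epochs`` or as soon as the train MSE falls to
    ``target_error``.  ``groups`` restricts which parameter groups are updated
    (all by default).  Returns ``(refined_params, per_epoch_train_mse)``; the
    trace records the MSE at the start of each epoch.
    """
    config = config or GDConfig()
    config.validate()
    unknown = set(groups) - set(PARAM_GROUPS)
    if unknown:
        raise ConfigError(f"unknown parameter groups {sorted(unknown)}")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    mode = aggregation or params.aggregation
    p = params.copy()
    trace: list[float] = []
    for epoch in range(config.max_epochs):
        if config.gradient_mode == "analytic":
            mse, grads = _mse_and_gradients(p, X, y, mode)
        else:
            pred = batch_predict(p, X, aggregation=mode)
            mse = float(np.mean((pred - y) ** 2))
            grads = _numeric_gradients(p, X, y, mode)
        if not np.isfinite(mse):
            raise TrainingDivergedError(f"non-finite training loss at epoch {epoch}")
        trace.append(mse)
        if mse <= config.target_error:
            break
        for name in groups:
            arr = getattr(p, name)
            arr -= config.learning_rate * grads[name]
        # keep divisors away from zero after the step
        for name in ("spreads", "dilations"):
            arr = getattr(p, name)
            small = np.abs(arr) < _DIVISOR_FLOOR
            if small.any():
                arr[small] = np.where(arr[small] >= 0, _DIVISOR_FLOOR, -_DIVISOR_FLOOR)
    return p, trace


# ----------------------------------------------------------------------
# hybrid trainer
# ----------------------------------------------------------------------

def _as_xy(split) -> tuple[np.ndarray, np.ndarray]:
    X, y = split
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.shape[0]:
        raise SchemaError("expected (X, y) with X (N, n) and y (N,)")
    return X, y


def hybrid_train(
    train,
    test=None,
    n_rules: int = 8,
    ga_config: GAConfig | None = None,
    gd_config: GDConfig | None = None,
    aggregation: str = "normalized",
    wavelet: str = "mexican_hat",
) -> TrainingReport:
    """GA global search followed by gradient-descent refinement.

    ``train``/``test`` are ``(X, y)`` pairs in scaled space.  The report
    carries both stage traces, the final parameters and train/test metrics
    (computed in the scaled space the trainer sees).
    """
    ga_config = ga_config or GAConfig()
    gd_config = gd_config or GDConfig()
    X_tr, y_tr = _as_xy(train)
    best, ga_trace = ga_optimize(
        X_tr, y_tr, n_rules, ga_config, aggregation=aggregation, wavelet=wavelet
    )
    params = decode(best, X_tr.shape[1], n_rules, wavelet=wavelet, aggregation=aggregation)
    params, gd_trace = gd_train(params, X_tr, y_tr, gd_config, aggregation=aggregation)

    train_m = _metrics.compute_metrics(y_tr, batch_predict(params, X_tr, aggregation=aggregation))
    test_m = None
    if test is not None:
        X_te, y_te = _as_xy(test)
        test_m = _metrics.compute_metrics(y_te, batch_predict(params, X_te, aggregation=aggregation))
    return TrainingReport(
        ga_best_fitness_per_generation=ga_trace,
        gd_train_mse_per_epoch=gd_trace,
        final_params=params,
        train_metrics=train_m,
        test_metrics=test_m,
        seed=ga_config.seed,
    )


# ----------------------------------------------------------------------
# GA-NN baseline (comparison harness only)
# ----------------------------------------------------------------------

@dataclass
class BaselineNNParameters:
    """Single-hidden-layer perceptron: tanh hidden units, linear output.

    With ``hidden_units == 0`` the model is purely linear,
    ``y = v . x + b0`` (ordinary linear regression reachable by the same
    training schedule).
    """

    hidden_weights: np.ndarray  # (h, n); empty when h == 0
    hidden_bias: np.ndarray  # (h,)
    output_weights: np.ndarray  # (h,) or (n,) when h == 0
    output_bias: float

    @property
    def hidden_units(self) -> int:
        return self.hidden_weights.shape[0]

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.hidden_units == 0:
            return X @ self.output_weights + self.output_bias
        H = np.tanh(X @ self.hidden_weights.T + self.hidden_bias)
        return H @ self.output_weights + self.output_bias

    def to_dict(self) -> dict:
        return {
            "hidden_units": self.hidden_units,
            "hidden_weights": self.hidden_weights.tolist(),
            "hidden_bias": self.hidden_bias.tolist(),
            "output_weights": self.output_weights.tolist(),
            "output_bias": self.output_bias,
        }


def _nn_decode(chrom: np.ndarray, n: int, h: int) -> BaselineNNParameters:
    if h == 0:
        return BaselineNNParameters(
            hidden_weights=np.empty((0, n)),
            hidden_bias=np.empty(0),
            output_weights=chrom[:n].copy(),
            output_bias=float(chrom[n]),
        )
    W = chrom[: h * n].reshape(h, n)
    b = chrom[h * n : h * n + h]
    v = chrom[h * n + h : h * n + 2 * h]
    return BaselineNNParameters(
        hidden_weights=W.copy(),
        hidden_bias=b.copy(),
        output_weights=v.copy(),
        output_bias=float(chrom[-1]),
    )


def _nn_encode(p: BaselineNNParameters) -> np.ndarray:
    return np.concatenate(
        [p.hidden_weights.ravel(), p.hidden_bias, p.output_weights, [p.output_bias]]
    )


def _nn_mse_and_gradients(p: BaselineNNParameters, X, y):
    N = X.shape[0]
    if p.hidden_units == 0:
        yhat = X @ p.output_weights + p.output_bias
        d = 2.0 * (yhat - y) / N
        return (
            float(np.mean((yhat - y) ** 2)),
            {"hidden_weights": np.empty((0, X.shape[1])), "hidden_bias": np.empty(0),
             "output_weights": X.T @ d, "output_bias": float(d.sum())},
        )
    pre = X @ p.hidden_weights.T + p.hidden_bias
    H = np.tanh(pre)
    yhat = H @ p.output_weights + p.output_bias
    d = 2.0 * (yhat - y) / N
    dpre = (d[:, None] * p.output_weights[None, :]) * (1.0 - H**2)
    return (
        float(np.mean((yhat - y) ** 2)),
        {"hidden_weights": dpre.T @ X, "hidden_bias": dpre.sum(axis=0),
         "output_weights": H.T @ d, "output_bias": float(d.sum())},
    )


def baseline_nn_train(
    train,
    test=None,
    hidden_units: int = 6,
    ga_config: GAConfig | None = None,
    gd_config: GDConfig | None = None,
) -> TrainingReport:
    """Train the GA-NN comparison baseline with the identical GA -> GD schedule."""
    if hidden_units < 0:
        raise ConfigError("hidden_units must be >= 0")
    ga_config = ga_config or GAConfig()
    gd_config = gd_config or GDConfig()
    ga_config.validate()
    gd_config.validate()
    X_tr, y_tr = _as_xy(train)
    n = X_tr.shape[1]
    L = n + 1 if hidden_units == 0 else hidden_units * (n + 2) + 1
    low = np.full(L, -2.0)
    high = np.full(L, 2.0)
    signed = np.zeros(L, dtype=bool)

    def _eval(chrom):
        pred = _nn_decode(chrom, n, hidden_units).predict(X_tr)
        mse = float(np.mean((pred - y_tr) ** 2))
        return 0.0 if not np.isfinite(mse) else 1.0 / (1.0 + mse)

    best, ga_trace = _ga_loop(_eval, low, high, signed, ga_config)

    p = _nn_decode(best, n, hidden_units)
    gd_trace: list[float] = []
    for epoch in range(gd_config.max_epochs):
        mse, grads = _nn_mse_and_gradients(p, X_tr, y_tr)
        if not np.isfinite(mse):
            raise TrainingDivergedError(f"non-finite baseline loss at epoch {epoch}")
        gd_trace.append(mse)
        if mse <= gd_config.target_error:
            break
        if hidden_units:
            p.hidden_weights -= gd_config.learning_rate * grads["hidden_weights"]
            p.hidden_bias -= gd_config.learning_rate * grads["hidden_bias"]
        p.output_weights -= gd_config.learning_rate * grads["output_weights"]
        p.output_bias -= gd_config.learning_rate * grads["output_bias"]

    train_m = _metrics.compute_metrics(y_tr, p.predict(X_tr))
    test_m = None
    if test is not None:
        X_te, y_te = _as_xy(test)
        test_m = _metrics.compute_metrics(y_te, p.predict(X_te))
    return TrainingReport(
        ga_best_fitness_per_generation=ga_trace,
        gd_train_mse_per_epoch=gd_trace,
        final_params=p,
        train_metrics=train_m,
        test_metrics=test_m,
        seed=ga_config.seed,
    )
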