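"""Width-1 bottleneck autoencoder for composite scoring.

The network distills an 8-measure standardized battery into a single
latent score (the activation of the central neuron) and reconstructs the
battery from it.  Layer order is

    input(8) -> dense(hidden, act) -> dropout -> dense(1, linear)
             -> dropout -> dense(hidden, act) -> dense(8, linear)

with the encoder and decoder sharing the hidden width and activation.
Training is full-batch gradient descent with Adam on the mean squared
reconstruction error; dropout is active only during training, so scoring
and reconstruction are deterministic functions of a trained model.

Model quality is summarized by the explained-variance fraction
1 - (mean per-measure residual sample variance) / (mean per-measure total
sample variance), and by the raw mean residual variance itself
(s^2 = 1/(n-1) * sum((x - x')^2) per measure, averaged over measures).

Implemented directly on numpy (forward pass, backpropagation, Adam);
the networks involved are tiny, so a full-batch closed loop is both the
simplest and the fastest option at this scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .cohort import StandardizedMatrix
from .errors import (
    BatteryMismatchError,
    ConfigError,
    DivergenceError,
    InsufficientDataError,
)

__all__ = [
    "AEArchitecture",
    "TrainingConfig",
    "TrainedAE",
    "EvalResult",
    "train_ae",
    "encode",
    "decode",
    "reconstruct",
    "explained_variance",
    "reconstruction_error",
    "evaluate_cv",
    "grid_search",
    "GRID_ACTIVATIONS",
    "GRID_WIDTHS",
]

# hyper-parameter grid: activations x hidden widths
GRID_ACTIVATIONS = ("relu", "tanh", "sigmoid", "linear")
GRID_WIDTHS = (10, 12, 16, 24, 32)

_ACTIVATIONS: dict[str, tuple[Callable, Callable]] = {
    "relu": (lambda x: np.maximum(x, 0.0), lambda x, a: (x > 0).astype(float)),
    "tanh": (np.tanh, lambda x, a: 1.0 - a**2),
    "sigmoid": (
        lambda x: 1.0 / (1.0 + np.exp(-x)),
        lambda x, a: a * (1.0 - a),
    ),
    "linear": (lambda x: x, lambda x, a: np.ones_like(x)),
}


@dataclass(frozen=True)
class AEArchitecture:
    """Shape and activations of the bottleneck autoencoder."""

    input_width: int = 8
    hidden_width: int = 24
    bottleneck_width: int = 1
    hidden_activation: str = "relu"
    dropout_rate: float = 0.4

    def __post_init__(self) -> None:
        if self.hidden_activation not in _ACTIVATIONS:
            raise ConfigError(
                f"unknown activation {self.hidden_activation!r}; choose from "
                f"{sorted(_ACTIVATIONS)}"
            )
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ConfigError("dropout_rate must be in [0, 1)")
        if self.bottleneck_width != 1:
            raise ConfigError("composite scoring requires bottleneck_width 1")
        if self.hidden_width < 1 or self.input_width < 1:
            raise ConfigError("layer widths must be positive")


@dataclass(frozen=True)
class TrainingConfig:
    """Full-batch Adam training configuration.

    ``patience``/``min_delta`` give optional plateau early stopping on the
    (dropout-free) training loss; ``patience=None`` disables it.
    ``scaler_policy`` controls cross-validation scaling: ``"train"``
    re-fits the z-scaler on each run's training rows only (leakage-safe),
    ``"all"`` keeps the incoming standardization.
    """

    learning_rate: float = 0.01
    epochs: int = 2000
    seed: int = 0
    patience: int | None = 200
    min_delta: float = 1e-5
    scaler_policy: str = "train"

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ConfigError("epochs must be >= 1")
        if not self.learning_rate > 0:
            raise ConfigError("learning_rate must be > 0")
        if self.scaler_policy not in ("train", "all"):
            raise ConfigError("scaler_policy must be 'train' or 'all'")


@dataclass
class TrainedAE:
    """A trained autoencoder: weights, loss trace and provenance."""

    architecture: AEArchitecture
    weights: dict[str, np.ndarray]
    loss_trace: np.ndarray
    seed: int

    @property
    def final_loss(self) -> float:
        return float(self.loss_trace[-1])


@dataclass
class EvalResult:
    """Cross-validated model quality.

    ``explained_variance_fraction`` and ``reconstruction_error`` are means
    over the two held-out runs; ``runs`` holds the per-run values.
    """

    explained_variance_fraction: float
    reconstruction_error: float
    runs: list[dict]


def _as_matrix(data: StandardizedMatrix | np.ndarray) -> np.ndarray:
    x = data.matrix if isinstance(data, StandardizedMatrix) else np.asarray(data)
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise BatteryMismatchError("expected a 2-D records x measures matrix")
    return x


def _init_weights(arch: AEArchitecture, rng: np.random.Generator) -> dict:
    """Uniform fan-in initialization: U(-1/sqrt(fan_in), 1/sqrt(fan_in))."""
    shapes = [
        ("W1", (arch.input_width, arch.hidden_width)),
        ("b1", (arch.hidden_width,)),
        ("W2", (arch.hidden_width, arch.bottleneck_width)),
        ("b2", (arch.bottleneck_width,)),
        ("W3", (arch.bottleneck_width, arch.hidden_width)),
        ("b3", (arch.hidden_width,)),
        ("W4", (arch.hidden_width, arch.input_width)),
        ("b4", (arch.input_width,)),
    ]
    fan_in = {
        "W1": arch.input_width, "b1": arch.input_width,
        "W2": arch.hidden_width, "b2": arch.hidden_width,
        "W3": arch.bottleneck_width, "b3": arch.bottleneck_width,
        "W4": arch.hidden_width, "b4": arch.hidden_width,
    }
    weights = {}
    for name, shape in shapes:
        bound = 1.0 / math.sqrt(fan_in[name])
        weights[name] = rng.uniform(-bound, bound, size=shape)
    return weights


def _forward(
    x: np.ndarray,
    w: dict,
    arch: AEArchitecture,
    rng: np.random.Generator | None = None,
) -> dict:
    """One forward pass.  With ``rng`` given, dropout is applied (training
    mode, inverted scaling); without it the pass is deterministic."""
    act, _ = _ACTIVATIONS[arch.hidden_activation]
    p = arch.dropout_rate
    cache: dict = {"x": x}
    cache["a1_pre"] = x @ w["W1"] + w["b1"]
    cache["a1"] = act(cache["a1_pre"])
    if rng is not None and p > 0:
        cache["m1"] = (rng.random(cache["a1"].shape) >= p) / (1.0 - p)
        d1 = cache["a1"] * cache["m1"]
    else:
        cache["m1"] = None
        d1 = cache["a1"]
    cache["d1"] = d1
    cache["z"] = d1 @ w["W2"] + w["b2"]            # bottleneck, linear
    if rng is not None and p > 0:
        cache["m2"] = (rng.random(cache["z"].shape) >= p) / (1.0 - p)
        d2 = cache["z"] * cache["m2"]
    else:
        cache["m2"] = None
        d2 = cache["z"]
    cache["d2"] = d2
    cache["a3_pre"] = d2 @ w["W3"] + w["b3"]
    cache["a3"] = act(cache["a3_pre"])
    cache["y"] = cache["a3"] @ w["W4"] + w["b4"]
    return cache


def _backward(cache: dict, w: dict, arch: AEArchitecture) -> dict:
    _, dact = _ACTIVATIONS[arch.hidden_activation]
    x, y = cache["x"], cache["y"]
    n_entries = x.size
    g: dict = {}
    dy = 2.0 * (y - x) / n_entries
    g["W4"] = cache["a3"].T @ dy
    g["b4"] = dy.sum(axis=0)
    da3 = dy @ w["W4"].T
    da3_pre = da3 * dact(cache["a3_pre"], cache["a3"])
    g["W3"] = cache["d2"].T @ da3_pre
    g["b3"] = da3_pre.sum(axis=0)
    dd2 = da3_pre @ w["W3"].T
    dz = dd2 * cache["m2"] if cache["m2"] is not None else dd2
    g["W2"] = cache["d1"].T @ dz
    g["b2"] = dz.sum(axis=0)
    dd1 = dz @ w["W2"].T
    da1 = dd1 * cache["m1"] if cache["m1"] is not None else dd1
    da1_pre = da1 * dact(cache["a1_pre"], cache["a1"])
    g["W1"] = x.T @ da1_pre
    g["b1"] = da1_pre.sum(axis=0)
    return g


def _mse(x: np.ndarray, y: np.ndarray) -> float:
    return float(np.mean((x - y) ** 2))


def train_ae(
    data: StandardizedMatrix | np.ndarray,
    arch: AEArchitecture | None = None,
    cfg: TrainingConfig | None = None,
) -> TrainedAE:
    """Train the bottleneck autoencoder by full-batch Adam on MSE.

    The loss trace records the dropout-free reconstruction MSE once per
    epoch, so the trace (and the early-stopping rule it drives) is free of
    dropout noise.  Identical (data, arch, cfg) give bit-identical models.
    """
    arch = arch if arch is not None else AEArchitecture()
    cfg = cfg if cfg is not None else TrainingConfig()
    x = _as_matrix(data)
    if x.shape[1] != arch.input_width:
        raise BatteryMismatchError(
            f"architecture expects {arch.input_width} measures, "
            f"data has {x.shape[1]}"
        )
    if x.shape[0] < 2:
        raise InsufficientDataError("training requires at least 2 records")

    rng = np.random.default_rng(cfg.seed)
    w = _init_weights(arch, rng)

    # Adam state
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    m = {k: np.zeros_like(v) for k, v in w.items()}
    v = {k: np.zeros_like(v_) for k, v_ in w.items()}

    trace = []
    best = math.inf
    since_best = 0
    for epoch in range(cfg.epochs):
        clean = _forward(x, w, arch, rng=None)
        loss = _mse(x, clean["y"])
        if not math.isfinite(loss):
            raise DivergenceError(
                f"non-finite loss at epoch {epoch}; try a lower learning rate"
            )
        trace.append(loss)
        if cfg.patience is not None:
            if loss < best - cfg.min_delta:
                best, since_best = loss, 0
            else:
                since_best += 1
                if since_best >= cfg.patience:
                    break
        cache = _forward(x, w, arch, rng=rng)
        grads = _backward(cache, w, arch)
        t = epoch + 1
        for k in w:
            m[k] = beta1 * m[k] + (1 - beta1) * grads[k]
            v[k] = beta2 * v[k] + (1 - beta2) * grads[k] ** 2
            m_hat = m[k] / (1 - beta1**t)
            v_hat = v[k] / (1 - beta2**t)
            w[k] = w[k] - cfg.learning_rate * m_hat / (np.sqrt(v_hat) + eps)

    final = _mse(x, _forward(x, w, arch, rng=None)["y"])
    if not math.isfinite(final):
        raise DivergenceError("non-finite final loss; try a lower learning rate")
    trace.append(final)
    return TrainedAE(
        architecture=arch, weights=w, loss_trace=np.array(trace), seed=cfg.seed
    )


def encode(model: TrainedAE, data: StandardizedMatrix | np.ndarray) -> np.ndarray:
    """Raw composite scores: the bottleneck activation, one per record.

    Inference mode — dropout inactive, fully deterministic.
    """
    x = _as_matrix(data)
    if x.shape[1] != model.architecture.input_width:
        raise BatteryMismatchError(
            f"model expects {model.architecture.input_width} measures, "
            f"data has {x.shape[1]}"
        )
    cache = _forward(x, model.weights, model.architecture, rng=None)
    return cache["z"][:, 0]


def decode(model: TrainedAE, codes: np.ndarray) -> np.ndarray:
    """Map bottleneck scores back to the 8-measure space."""
    z = np.asarray(codes, dtype=float).reshape(-1, 1)
    act, _ = _ACTIVATIONS[model.architecture.hidden_activation]
    w = model.weights
    a3 = act(z @ w["W3"] + w["b3"])
    return a3 @ w["W4"] + w["b4"]


def reconstruct(
    model: TrainedAE, data: StandardizedMatrix | np.ndarray
) -> np.ndarray:
    """Autoencoder reconstruction of every record (decode ∘ encode)."""
    return decode(model, encode(model, data))


def reconstruction_error(x: np.ndarray, x_reconstructed: np.ndarray) -> float:
    """Mean over measures of the per-measure residual sample variance
    s^2 = 1/(n-1) * sum((x - x')^2)."""
    x = np.asarray(x, dtype=float)
    xr = np.asarray(x_reconstructed, dtype=float)
    if x.shape != xr.shape:
        raise BatteryMismatchError("x and reconstruction must share a shape")
    n = x.shape[0]
    if n < 2:
        raise InsufficientDataError("residual variance undefined for n < 2")
    resid = ((x - xr) ** 2).sum(axis=0) / (n - 1)
    return float(resid.mean())


def explained_variance(x: np.ndarray, x_reconstructed: np.ndarray) -> float:
    """Fraction of battery variance captured by the reconstruction.

    1 - (mean per-measure residual sample variance) /
        (mean per-measure total sample variance of x);
    1.0 iff the reconstruction is perfect, <= 1 always, and 0 for the
    null predictor that returns each measure's mean.
    """
    x = np.asarray(x, dtype=float)
    xr = np.asarray(x_reconstructed, dtype=float)
    if x.shape != xr.shape:
        raise BatteryMismatchError("x and reconstruction must share a shape")
    if x.shape[0] < 2:
        raise InsufficientDataError("variance undefined for n < 2")
    n = x.shape[0]
    resid = ((x - xr) ** 2).sum(axis=0) / (n - 1)
    total = x.var(axis=0, ddof=1)
    return float(1.0 - resid.mean() / total.mean())


def _derive_seeds(seed: int, n: int) -> list[int]:
    """Deterministic child seeds (< 2^31) from one master seed."""
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s & 0x7FFFFFFF) for s in state]


def evaluate_cv(
    data: StandardizedMatrix | np.ndarray,
    arch: AEArchitecture | None = None,
    cfg: TrainingConfig | None = None,
) -> EvalResult:
    """Two hold-out runs with completely disjoint test sets.

    Each run holds out ceil(10%) of the records; the two test sets are
    drawn from one seeded permutation so they never intersect.  Under the
    default ``scaler_policy="train"`` the z-scaler is re-fitted on each
    run's training rows only and applied to its test rows.
    """
    arch = arch if arch is not None else AEArchitecture()
    cfg = cfg if cfg is not None else TrainingConfig()
    x = _as_matrix(data)
    n = x.shape[0]
    if n < 4:
        raise InsufficientDataError(
            "cross-validation needs >= 4 records for two disjoint test sets"
        )
    m = math.ceil(0.1 * n)
    if 2 * m > n - 2:
        raise InsufficientDataError(
            f"cannot carve two disjoint test sets of {m} from {n} records"
        )
    split_seed, seed_a, seed_b = _derive_seeds(cfg.seed, 3)
    perm = np.random.default_rng(split_seed).permutation(n)
    test_sets = [perm[:m], perm[m:2 * m]]
    assert len(set(test_sets[0]) & set(test_sets[1])) == 0

    runs = []
    for run_idx, (test_idx, run_seed) in enumerate(
        zip(test_sets, (seed_a, seed_b))
    ):
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        x_train, x_test = x[train_idx], x[test_idx]
        if cfg.scaler_policy == "train":
            mu = x_train.mean(axis=0)
            sd = x_train.std(axis=0, ddof=1)
            if not np.all(sd > 0):
                raise InsufficientDataError(
                    "zero-variance measure on a training split"
                )
            x_train = (x_train - mu) / sd
            x_test = (x_test - mu) / sd
        model = train_ae(x_train, arch, replace(cfg, seed=run_seed))
        recon_train = reconstruct(model, x_train)
        recon_test = reconstruct(model, x_test)
        runs.append(
            {
                "run": run_idx,
                "test_indices": test_idx.tolist(),
                "train_ev": explained_variance(x_train, recon_train),
                "test_ev": explained_variance(x_test, recon_test),
                "test_reconstruction_error": reconstruction_error(
                    x_test, recon_test
                ),
                "final_loss": model.final_loss,
                "seed": run_seed,
            }
        )
    return EvalResult(
        explained_variance_fraction=float(
            np.mean([r["test_ev"] for r in runs])
        ),
        reconstruction_error=float(
            np.mean([r["test_reconstruction_error"] for r in runs])
        ),
        runs=runs,
    )


def grid_search(
    data: StandardizedMatrix | np.ndarray,
    cfg: TrainingConfig | None = None,
    activations: Sequence[str] = GRID_ACTIVATIONS,
    widths: Sequence[int] = GRID_WIDTHS,
) -> tuple[AEArchitecture, EvalResult, pd.DataFrame]:
    """Exhaustive hyper-parameter search over activations x hidden widths.

    Every configuration is scored with :func:`evaluate_cv` on the same
    seeded splits; the winner maximizes mean test explained variance, with
    exact ties broken by position in the (activation, width) lists.
    Returns (best architecture, its EvalResult, the full results table).
    """
    cfg = cfg if cfg is not None else TrainingConfig()
    rows = []
    best: tuple[AEArchitecture, EvalResult] | None = None
    for act in activations:
        for width in widths:
            arch = AEArchitecture(hidden_activation=act, hidden_width=width)
            result = evaluate_cv(data, arch, cfg)
            rows.append(
                {
                    "activation": act,
                    "hidden_width": width,
                    "mean_test_ev": result.explained_variance_fraction,
                    "mean_reconstruction_error": result.reconstruction_error,
                }
            )
            if (
                best is None
                or result.explained_variance_fraction
                > best[1].explained_variance_fraction
            ):
                best = (arch, result)
    assert best is not None
    return best[0], best[1], pd.DataFrame(rows)
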