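"""GA-initialized backpropagation network with climate-factor sensitivity.

A fully connected feed-forward network with logistic-sigmoid (logsig)
activations on every non-input layer, default topology 8-50-30-1, maps
min-max scaled climate factors (inputs scaled to [0.10, 0.90]) to a
min-max scaled response.  A real-coded genetic algorithm first searches
weight space globally (tournament selection, arithmetic crossover,
Gaussian mutation, elitism of one); batch gradient descent with
momentum and a multiplicative learning-rate schedule then fine-tunes
from the GA's best chromosome.  Training stops once the summed squared
per-sample error falls below delta^2 * N and the mean absolute error
below 0.02 on the scaled outputs.

Factor importance is measured by one-at-a-time central-difference
perturbation of the trained network, normalized to sum to one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

__all__ = [
    "GAConfig",
    "BPConfig",
    "NetworkConfig",
    "ScalingParams",
    "TrainedNetwork",
    "SensitivityProfile",
    "TrainingDivergedError",
    "scale_minmax",
    "forward",
    "flatten_weights",
    "unflatten_weights",
    "init_weights",
    "ga_optimize",
    "bp_train",
    "check_convergence",
    "sensitivity",
    "fit_gabp",
]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class GAConfig:
    """Genetic-algorithm hyperparameters for weight pre-optimization."""

    population: int = 40
    generations: int = 100
    crossover_p: float = 0.8
    mutation_p: float = 0.05
    mutation_sd: float = 0.1
    tournament_size: int = 2
    init_scale: float = 0.5  # uniform(-s, s) chromosome initialization

    def validate(self) -> None:
        if self.population < 2:
            raise ValueError("GA population must be at least 2")
        if self.generations < 0:
            raise ValueError("generations must be non-negative")
        for p in (self.crossover_p, self.mutation_p):
            if not 0.0 <= p <= 1.0:
                raise ValueError("GA probabilities must lie in [0, 1]")


@dataclass
class BPConfig:
    """Backpropagation hyperparameters (gradient descent with momentum
    and multiplicative learning-rate adaptation)."""

    learning_rate: float = 0.05
    momentum: float = 0.9
    lr_up: float = 1.05
    lr_down: float = 0.7
    max_epochs: int = 5000
    max_perf_inc: float = 1.04  # reject steps inflating SSE beyond this ratio
    lr_min: float = 1e-3  # floor keeps the multiplicative schedule alive on plateaus

    def validate(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning rate must be non-negative")
        if not 0.0 <= self.momentum < 1.0:
            raise ValueError("momentum must lie in [0, 1)")
        if self.max_epochs < 0:
            raise ValueError("max_epochs must be non-negative")


@dataclass
class NetworkConfig:
    """Full model specification: topology, scaling bounds, GA/BP settings,
    the per-sample error tolerance delta, and the master seed."""

    layer_sizes: list[int] = field(default_factory=lambda: [8, 50, 30, 1])
    input_range: tuple[float, float] = (0.10, 0.90)
    ga: GAConfig = field(default_factory=GAConfig)
    bp: BPConfig = field(default_factory=BPConfig)
    delta: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if len(self.layer_sizes) < 2 or any(s < 1 for s in self.layer_sizes):
            raise ValueError("layer_sizes must be >= 2 positive integers")
        if self.layer_sizes[-1] != 1:
            raise ValueError("output layer must have a single unit")
        lo, hi = self.input_range
        if not lo < hi:
            raise ValueError("input_range must be increasing")
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        self.ga.validate()
        self.bp.validate()

    def to_dict(self) -> dict:
        d = asdict(self)
        d["input_range"] = list(self.input_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        d = dict(d)
        if "ga" in d:
            d["ga"] = GAConfig(**d["ga"])
        if "bp" in d:
            d["bp"] = BPConfig(**d["bp"])
        if "input_range" in d:
            d["input_range"] = tuple(d["input_range"])
        return cls(**d)


class TrainingDivergedError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Scaling
# ---------------------------------------------------------------------------


@dataclass
class ScalingParams:
    """Per-feature min-max affine map onto [lo, hi].

    Constant features cannot be ranged; they map to the midpoint and are
    flagged in ``constant_mask``.
    """

    mins: np.ndarray
    maxs: np.ndarray
    lo: float = 0.10
    hi: float = 0.90

    @property
    def constant_mask(self) -> np.ndarray:
        return self.maxs == self.mins

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, float))
        span = np.where(self.constant_mask, 1.0, self.maxs - self.mins)
        out = self.lo + (X - self.mins) * (self.hi - self.lo) / span
        out[:, self.constant_mask] = (self.lo + self.hi) / 2.0
        return out

    def inverse(self, Xs: np.ndarray) -> np.ndarray:
        Xs = np.atleast_2d(np.asarray(Xs, float))
        span = np.where(self.constant_mask, 1.0, self.maxs - self.mins)
        out = self.mins + (Xs - self.lo) * span / (self.hi - self.lo)
        out[:, self.constant_mask] = self.mins[self.constant_mask]
        return out


def scale_minmax(
    X: np.ndarray, lo: float = 0.10, hi: float = 0.90
) -> tuple[np.ndarray, ScalingParams]:
    """Map each feature affinely so its min goes to ``lo`` and max to ``hi``.

    Constant features are flagged and mapped to the midpoint.  Requires
    at least two rows; the returned :class:`ScalingParams` inverts the
    map exactly.
    """
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] < 2:
        raise ValueError("min-max scaling needs at least 2 rows")
    params = ScalingParams(mins=X.min(axis=0), maxs=X.max(axis=0), lo=lo, hi=hi)
    if params.constant_mask.any():
        warnings.warn("constant feature(s) mapped to the scaling midpoint", stacklevel=2)
    return params.transform(X), params


# ---------------------------------------------------------------------------
# Network forward / backward
# ---------------------------------------------------------------------------

Weights = list[tuple[np.ndarray, np.ndarray]]  # [(W (n_in, n_out), b (n_out,)), ...]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    # numerically safe logsig
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _forward_all(weights: Weights, X: np.ndarray) -> list[np.ndarray]:
    """Activations per layer (input first), logsig on every hidden/output layer."""
    acts = [np.atleast_2d(np.asarray(X, float))]
    for W, b in weights:
        acts.append(_sigmoid(acts[-1] @ W + b))
    return acts


def forward(weights: "Weights | TrainedNetwork", x: np.ndarray) -> np.ndarray:
    """Network output(s) in (0, 1) for scaled input vector(s) ``x``."""
    if isinstance(weights, TrainedNetwork):
        weights = weights.weights
    x = np.atleast_2d(np.asarray(x, float))
    if x.shape[1] != weights[0][0].shape[0]:
        raise ValueError(
            f"input has {x.shape[1]} features, network expects {weights[0][0].shape[0]}"
        )
    return _forward_all(weights, x)[-1][:, 0]


def _shapes(layer_sizes: Sequence[int]) -> list[tuple[int, int]]:
    return [(layer_sizes[i], layer_sizes[i + 1]) for i in range(len(layer_sizes) - 1)]


def n_parameters(layer_sizes: Sequence[int]) -> int:
    return sum(ni * no + no for ni, no in _shapes(layer_sizes))


def flatten_weights(weights: Weights) -> np.ndarray:
    return np.concatenate([np.concatenate([W.ravel(), b]) for W, b in weights])


def unflatten_weights(vec: np.ndarray, layer_sizes: Sequence[int]) -> Weights:
    vec = np.asarray(vec, float)
    if vec.size != n_parameters(layer_sizes):
        raise ValueError("weight vector length does not match topology")
    out: Weights = []
    i = 0
    for ni, no in _shapes(layer_sizes):
        W = vec[i : i + ni * no].reshape(ni, no)
        i += ni * no
        b = vec[i : i + no]
        i += no
        out.append((W.copy(), b.copy()))
    return out


def init_weights(layer_sizes: Sequence[int], rng: np.random.Generator,
                 scale: float = 0.5) -> np.ndarray:
    """Random flat chromosome, uniform(-scale, scale)."""
    return rng.uniform(-scale, scale, n_parameters(layer_sizes))


def _sse(weights: Weights, X: np.ndarray, y: np.ndarray) -> float:
    pred = _forward_all(weights, X)[-1][:, 0]
    return float(np.sum((pred - y) ** 2))


def _gradients(weights: Weights, X: np.ndarray, y: np.ndarray) -> tuple[Weights, float]:
    """Gradient of MSE w.r.t. all weights/biases, plus the current SSE."""
    acts = _forward_all(weights, X)
    pred = acts[-1][:, 0]
    n = X.shape[0]
    sse = float(np.sum((pred - y) ** 2))
    # dMSE/dpred = 2 (pred - y) / n ; chain through logsig a(1-a)
    delta = (2.0 * (acts[-1] - y[:, None]) / n) * acts[-1] * (1.0 - acts[-1])
    grads: Weights = [None] * len(weights)  # type: ignore[list-item]
    for l in range(len(weights) - 1, -1, -1):
        W, _ = weights[l]
        grads[l] = (acts[l].T @ delta, delta.sum(axis=0))
        if l > 0:
            delta = (delta @ W.T) * acts[l] * (1.0 - acts[l])
    return grads, sse


# ---------------------------------------------------------------------------
# Convergence
# ---------------------------------------------------------------------------


def check_convergence(errors: np.ndarray, delta: float, n: int) -> bool:
    """Training stop rule on scaled per-sample output errors.

    True iff the summed squared error is strictly below ``delta**2 * n``
    and the mean absolute error is below 0.02.
    """
    errors = np.asarray(errors, float)
    if errors.size == 0:
        raise ValueError("errors must be non-empty")
    if errors.size != n:
        raise ValueError("n must equal the number of per-sample errors")
    sse = float(np.sum(errors**2))
    mae = float(np.mean(np.abs(errors)))
    return sse < delta**2 * n and mae < 0.02


# ---------------------------------------------------------------------------
# Genetic algorithm
# ---------------------------------------------------------------------------


@dataclass
class GAResult:
    best_vector: np.ndarray
    best_sse: float
    fitness_trace: list[float]  # best fitness per generation (incl. initial)


def ga_optimize(
    X: np.ndarray,
    y: np.ndarray,
    config: NetworkConfig,
    rng: np.random.Generator | None = None,
) -> GAResult:
    """Globally pre-optimize the weight chromosome.

    Fitness is 1/(1 + SSE) on the scaled training set.  Tournament
    selection, per-gene arithmetic crossover, additive Gaussian
    mutation, elitism of one.  The best-per-generation fitness trace is
    non-decreasing by construction.
    """
    config.validate()
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float).ravel()
    if X.shape[0] == 0:
        raise ValueError("training set must be non-empty")
    ga = config.ga
    rng = rng if rng is not None else np.random.default_rng(config.seed)

    dim = n_parameters(config.layer_sizes)
    pop = rng.uniform(-ga.init_scale, ga.init_scale, (ga.population, dim))
    sse = np.array(
        [_sse(unflatten_weights(ind, config.layer_sizes), X, y) for ind in pop]
    )
    fitness = 1.0 / (1.0 + sse)
    trace = [float(fitness.max())]

    for _ in range(ga.generations):
        elite = int(np.argmax(fitness))
        children = np.empty_like(pop)
        children[0] = pop[elite]
        for i in range(1, ga.population):
            # tournament selection of two parents
            parents = []
            for _k in range(2):
                contenders = rng.integers(0, ga.population, ga.tournament_size)
                parents.append(pop[contenders[np.argmax(fitness[contenders])]])
            p1, p2 = parents
            if rng.random() < ga.crossover_p:
                u = rng.random(dim)
                child = u * p1 + (1.0 - u) * p2
            else:
                child = p1.copy()
            mask = rng.random(dim) < ga.mutation_p
            child = child + mask * rng.normal(0.0, ga.mutation_sd, dim)
            children[i] = child
        pop = children
        sse = np.array(
            [_sse(unflatten_weights(ind, config.layer_sizes), X, y) for ind in pop]
        )
        fitness = 1.0 / (1.0 + sse)
        trace.append(max(trace[-1], float(fitness.max())))

    best = int(np.argmax(fitness))
    best_sse = float(sse[best])
    # elitism guarantees the final population holds the best-of-run
    return GAResult(best_vector=pop[best].copy(), best_sse=best_sse, fitness_trace=trace)


# ---------------------------------------------------------------------------
# Backpropagation
# ---------------------------------------------------------------------------


@dataclass
class TrainedNetwork:
    """Trained weights plus the scaling maps needed to use raw units."""

    weights: Weights
    config: NetworkConfig
    x_scaler: ScalingParams | None = None
    y_scaler: ScalingParams | None = None
    error_trace: list[float] = field(default_factory=list)  # SSE per epoch
    ga_trace: list[float] = field(default_factory=list)
    converged: bool = False
    epochs: int = 0

    def predict_scaled(self, Xs: np.ndarray) -> np.ndarray:
        return forward(self.weights, Xs)

    def predict(self, X_raw: np.ndarray) -> np.ndarray:
        if self.x_scaler is None or self.y_scaler is None:
            raise ValueError("network has no attached scalers; use predict_scaled")
        ys = self.predict_scaled(self.x_scaler.transform(X_raw))
        return self.y_scaler.inverse(ys[:, None])[:, 0]

    def mae_scaled(self, Xs: np.ndarray, ys: np.ndarray) -> float:
        return float(np.mean(np.abs(self.predict_scaled(Xs) - np.ravel(ys))))


def bp_train(
    init_weights_vec: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    config: NetworkConfig,
) -> TrainedNetwork:
    """Batch gradient descent with momentum from an initial chromosome.

    The learning rate is multiplied by ``lr_up`` after an epoch that
    reduces the SSE and by ``lr_down`` otherwise; a step inflating the
    SSE beyond ``max_perf_inc`` times its previous value is rejected and
    the momentum reset, which keeps the adaptive schedule stable.  A
    floor of ``lr_min`` (inactive when the initial rate is zero) stops
    the rate from decaying to nothing on error plateaus.  Training
    stops at :func:`check_convergence` or ``max_epochs``.
    """
    config.validate()
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float).ravel()
    bp = config.bp

    weights = unflatten_weights(np.asarray(init_weights_vec, float), config.layer_sizes)
    velocity: Weights = [(np.zeros_like(W), np.zeros_like(b)) for W, b in weights]
    lr = bp.learning_rate
    n = X.shape[0]

    sse = _sse(weights, X, y)
    trace = [sse]
    converged = False
    epoch = 0
    for epoch in range(1, bp.max_epochs + 1):
        grads, _ = _gradients(weights, X, y)
        if any(not np.all(np.isfinite(g)) for gW, gb in grads for g in (gW, gb)):
            raise TrainingDivergedError(f"non-finite gradients at epoch {epoch}")
        proposal: Weights = []
        new_velocity: Weights = []
        for (W, b), (vW, vb), (gW, gb) in zip(weights, velocity, grads):
            nvW = bp.momentum * vW - lr * gW
            nvb = bp.momentum * vb - lr * gb
            proposal.append((W + nvW, b + nvb))
            new_velocity.append((nvW, nvb))
        new_sse = _sse(proposal, X, y)
        if not np.isfinite(new_sse):
            raise TrainingDivergedError(f"non-finite error at epoch {epoch}")

        if new_sse > sse * bp.max_perf_inc:
            # reject the step entirely; cool down
            lr *= bp.lr_down
            velocity = [(np.zeros_like(W), np.zeros_like(b)) for W, b in weights]
            trace.append(sse)
        else:
            weights = proposal
            velocity = new_velocity
            if new_sse < sse:
                lr *= bp.lr_up
            else:
                lr *= bp.lr_down
            sse = new_sse
            trace.append(sse)
        if bp.learning_rate > 0:
            lr = max(lr, bp.lr_min)

        pred = _forward_all(weights, X)[-1][:, 0]
        if check_convergence(pred - y, config.delta, n):
            converged = True
            break

    return TrainedNetwork(
        weights=weights,
        config=config,
        error_trace=trace,
        converged=converged,
        epochs=epoch,
    )


# ---------------------------------------------------------------------------
# Sensitivity analysis
# ---------------------------------------------------------------------------


@dataclass
class SensitivityProfile:
    """Normalized one-at-a-time factor importances (sum to 1)."""

    response: str
    factors: list[str]
    values: np.ndarray
    perturbation: float

    def ranking(self) -> list[str]:
        order = np.argsort(-self.values)
        return [self.factors[i] for i in order]

    def top_factor(self) -> str:
        return self.factors[int(np.argmax(self.values))]


def sensitivity(
    net: TrainedNetwork,
    X_scaled: np.ndarray,
    perturbation: float = 0.10,
    factors: Sequence[str] | None = None,
    response: str = "response",
) -> SensitivityProfile:
    """One-at-a-time central-difference sensitivity on the trained net.

    For each input factor j, s_j = mean over training samples of
    |f(x + d e_j) - f(x - d e_j)| / (2 d) with d = ``perturbation``
    times the scaled input span; the profile is normalized to sum to 1.
    """
    if perturbation <= 0:
        raise ValueError("perturbation must be positive")
    X_scaled = np.atleast_2d(np.asarray(X_scaled, float))
    if X_scaled.shape[0] == 0:
        raise ValueError("X must be non-empty")
    lo, hi = net.config.input_range
    d = perturbation * (hi - lo)
    nfac = X_scaled.shape[1]
    vals = np.empty(nfac)
    for j in range(nfac):
        up = X_scaled.copy()
        dn = X_scaled.copy()
        up[:, j] += d
        dn[:, j] -= d
        vals[j] = np.mean(np.abs(forward(net.weights, up) - forward(net.weights, dn))) / (
            2.0 * d
        )
    total = vals.sum()
    vals = vals / total if total > 0 else np.full(nfac, 1.0 / nfac)
    if factors is None:
        factors = [f"x{j}" for j in range(nfac)]
    return SensitivityProfile(
        response=response, factors=list(factors), values=vals, perturbation=perturbation
    )


# ---------------------------------------------------------------------------
# End-to-end fit
# ---------------------------------------------------------------------------


def fit_gabp(
    X_raw: np.ndarray,
    y_raw: np.ndarray,
    config: NetworkConfig | None = None,
) -> TrainedNetwork:
    """Scale inputs/outputs, GA pre-optimize, then backpropagate.

    Inputs and outputs are min-max scaled to ``config.input_range``
    (outputs must live inside the logsig range, so they share the same
    bounds).  With fewer than 20 samples a small-sample warning is
    emitted: the fit is a training-set fit only.
    """
    config = config or NetworkConfig()
    config.validate()
    X_raw = np.atleast_2d(np.asarray(X_raw, float))
    y_raw = np.asarray(y_raw, float).ravel()
    if X_raw.shape[1] != config.layer_sizes[0]:
        raise ValueError(
            f"data has {X_raw.shape[1]} factors but topology expects {config.layer_sizes[0]}"
        )
    if X_raw.shape[0] < 20:
        warnings.warn(
            "fewer than 20 samples: no train/test split is possible and the "
            "reported fit is a training-set fit only",
            stacklevel=2,
        )
    lo, hi = config.input_range
    Xs, xscale = scale_minmax(X_raw, lo, hi)
    ys_mat, yscale = scale_minmax(y_raw[:, None], lo, hi)
    ys = ys_mat[:, 0]

    rng = np.random.default_rng(config.seed)
    ga = ga_optimize(Xs, ys, config, rng)
    net = bp_train(ga.best_vector, Xs, ys, config)
    net.x_scaler = xscale
    net.y_scaler = yscale
    net.ga_trace = ga.fitness_trace
    return net
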