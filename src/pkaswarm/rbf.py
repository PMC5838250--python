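"""Gaussian RBF network trained by swarm optimization.

The network has one hidden layer of Gaussian units

    g_i(x) = exp(-||x - c_i||^2 / sigma_i^2)

and a linear output layer ``o = sum_h W[h, o] g_h(x) + B[o]``.  Training is
*not* gradient-based: all parameters (output weights, biases, centers and
per-node spreads) are flattened into a single particle vector and fitted by
minimizing training mean squared error with the CSAPSO-EDCD optimizer.

The particle layout is, in order: output weights (c*p), output biases (p),
centers (c*m_in, row-major per hidden node), then log-spreads (c).  Spreads
travel through the particle as log(sigma) so any decoded network has
strictly positive spreads.

Features are z-scored per column with training-set statistics; the same
constants are applied at prediction time and stored with the model.

`RBFRegression` / `RBFRegressionResults` present the workflow in the usual
model/results style: build the model from arrays or a DataFrame, call
``fit()``, inspect ``summary()``, ``predict()`` and ``evaluate()``.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import optimizer as opt
from .metrics import EvaluationReport

__all__ = [
    "NetworkShape",
    "RBFNetwork",
    "hidden_node_formula",
    "gaussian_basis",
    "encode_particle",
    "decode_particle",
    "particle_length",
    "particle_bounds",
    "mse_fitness",
    "train",
    "heuristic_hidden_search",
    "RBFRegression",
    "RBFRegressionResults",
]


@dataclass(frozen=True)
class NetworkShape:
    """Layer sizes (inputs m, hidden c, outputs p) of an RBF network."""

    n_inputs: int
    n_hidden: int
    n_outputs: int = 1

    def __post_init__(self) -> None:
        if min(self.n_inputs, self.n_hidden, self.n_outputs) < 1:
            raise ValueError("all layer sizes must be >= 1")


def hidden_node_formula(n_inputs: int, n_outputs: int = 1) -> int:
    """Rule-of-thumb hidden layer size ``floor(2*sqrt(m*n) + 1)``.

    ``m`` and ``n`` are the input and output layer sizes.  The floor
    rounding reproduces the conventional result of 5 hidden nodes for a
    5-input, 1-output network (raw value 5.47).
    """
    if n_inputs < 1 or n_outputs < 1:
        raise ValueError("layer sizes must be >= 1")
    return math.floor(2.0 * math.sqrt(n_inputs * n_outputs) + 1.0)


def gaussian_basis(x, center, sigma: float) -> float:
    """Gaussian basis activation ``exp(-||x - c||^2 / sigma^2)`` in (0, 1]."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    xv = np.asarray(x, dtype=float)
    cv = np.asarray(center, dtype=float)
    if xv.shape != cv.shape:
        raise ValueError("x and center must share dimension")
    return float(np.exp(-np.sum((xv - cv) ** 2) / sigma**2))


def _gram(X: np.ndarray, centers: np.ndarray, spreads: np.ndarray) -> np.ndarray:
    """Hidden-layer activation matrix (n_samples, n_hidden)."""
    # squared distances via the expansion trick; one shared path so the
    # training objective and predict() agree to the last bit
    x_sq = np.sum(X**2, axis=1)[:, None]
    c_sq = np.sum(centers**2, axis=1)[None, :]
    d2 = x_sq - 2.0 * (X @ centers.T) + c_sq
    np.maximum(d2, 0.0, out=d2)
    return np.exp(-d2 / spreads[None, :] ** 2)


class RBFNetwork:
    """A concrete Gaussian RBF network: centers, spreads, weights, biases.

    Optionally carries the feature standardization constants (``x_mean``,
    ``x_std``) so that `predict` accepts raw descriptor values.
    """

    def __init__(
        self,
        centers,
        spreads,
        weights,
        biases,
        x_mean=None,
        x_std=None,
    ) -> None:
        self.centers = np.atleast_2d(np.asarray(centers, dtype=float))
        self.spreads = np.asarray(spreads, dtype=float).ravel()
        self.weights = np.atleast_2d(np.asarray(weights, dtype=float))
        self.biases = np.asarray(biases, dtype=float).ravel()
        c, m_in = self.centers.shape
        if self.spreads.shape != (c,):
            raise ValueError("need one spread per hidden node")
        if np.any(self.spreads <= 0):
            raise ValueError("spreads must be strictly positive")
        if self.weights.shape[0] != c:
            raise ValueError("weights must have one row per hidden node")
        if self.biases.shape != (self.weights.shape[1],):
            raise ValueError("need one bias per output")
        self.x_mean = None if x_mean is None else np.asarray(x_mean, dtype=float).ravel()
        self.x_std = None if x_std is None else np.asarray(x_std, dtype=float).ravel()

    @property
    def shape(self) -> NetworkShape:
        c, m_in = self.centers.shape
        return NetworkShape(m_in, c, self.weights.shape[1])

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        if self.x_mean is None:
            return X
        return (X - self.x_mean) / self.x_std

    def predict(self, X) -> np.ndarray:
        """Predict outputs for a (n, m_in) matrix; (n,) for single-output nets."""
        Xv = np.atleast_2d(np.asarray(X, dtype=float))
        if Xv.shape[1] != self.centers.shape[1]:
            raise ValueError(
                f"feature count mismatch: network expects {self.centers.shape[1]}, "
                f"got {Xv.shape[1]}"
            )
        G = _gram(self._standardize(Xv), self.centers, self.spreads)
        out = G @ self.weights + self.biases
        if out.shape[1] == 1:
            return out[:, 0]
        return out

    def forward(self, x) -> np.ndarray:
        """Outputs for a single feature vector (length p)."""
        return np.atleast_1d(self.predict(np.asarray(x, dtype=float).reshape(1, -1)))

    # -- serialization ------------------------------------------------------

    def to_json(self, path=None) -> str:
        payload = {
            "shape": dataclasses.asdict(self.shape),
            "centers": self.centers.tolist(),
            "spreads": self.spreads.tolist(),
            "weights": self.weights.tolist(),
            "biases": self.biases.tolist(),
            "x_mean": None if self.x_mean is None else self.x_mean.tolist(),
            "x_std": None if self.x_std is None else self.x_std.tolist(),
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "RBFNetwork":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        return cls(
            centers=payload["centers"],
            spreads=payload["spreads"],
            weights=payload["weights"],
            biases=payload["biases"],
            x_mean=payload.get("x_mean"),
            x_std=payload.get("x_std"),
        )


# ---------------------------------------------------------------------------
# particle encoding
# ---------------------------------------------------------------------------


def particle_length(shape: NetworkShape) -> int:
    c, m_in, p = shape.n_hidden, shape.n_inputs, shape.n_outputs
    return c * p + p + c * m_in + c


def encode_particle(net: RBFNetwork) -> np.ndarray:
    """Flatten a network into the optimizer's particle vector.

    Order: weights, biases, centers, log-spreads.
    """
    return np.concatenate(
        [
            net.weights.ravel(),
            net.biases,
            net.centers.ravel(),
            np.log(net.spreads),
        ]
    )


def decode_particle(
    vector, shape: NetworkShape, x_mean=None, x_std=None
) -> RBFNetwork:
    """Rebuild a network from a particle vector (inverse of `encode_particle`)."""
    vec = np.asarray(vector, dtype=float).ravel()
    expected = particle_length(shape)
    if vec.size != expected:
        raise ValueError(
            f"particle length {vec.size} does not match shape {shape}: "
            f"expected {expected}"
        )
    c, m_in, p = shape.n_hidden, shape.n_inputs, shape.n_outputs
    i = 0
    weights = vec[i : i + c * p].reshape(c, p)
    i += c * p
    biases = vec[i : i + p]
    i += p
    centers = vec[i : i + c * m_in].reshape(c, m_in)
    i += c * m_in
    spreads = np.exp(vec[i : i + c])
    return RBFNetwork(centers, spreads, weights, biases, x_mean=x_mean, x_std=x_std)


def particle_bounds(
    shape: NetworkShape,
    weight_bound: float = 10.0,
    center_bound: float = 3.0,
    spread_range: tuple[float, float] = (0.1, 10.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Search-box bounds for each particle coordinate.

    Weights/biases in [-10, 10], centers in [-3, 3] (z-scored feature
    space), log-spreads in [log 0.1, log 10].
    """
    c, m_in, p = shape.n_hidden, shape.n_inputs, shape.n_outputs
    lo = np.concatenate(
        [
            np.full(c * p + p, -weight_bound),
            np.full(c * m_in, -center_bound),
            np.full(c, math.log(spread_range[0])),
        ]
    )
    hi = np.concatenate(
        [
            np.full(c * p + p, weight_bound),
            np.full(c * m_in, center_bound),
            np.full(c, math.log(spread_range[1])),
        ]
    )
    return lo, hi


def mse_fitness(net: RBFNetwork, X, y) -> float:
    """Mean squared prediction error of a network on (X, y)."""
    Xv = np.atleast_2d(np.asarray(X, dtype=float))
    yv = np.asarray(y, dtype=float)
    if Xv.shape[0] == 0:
        raise ValueError("mse_fitness needs at least one sample")
    if Xv.shape[0] != yv.shape[0]:
        raise ValueError("X row count must match y length")
    pred = net.predict(Xv)
    return float(np.mean((pred - yv.reshape(pred.shape)) ** 2))


def _training_objective(Xs: np.ndarray, y: np.ndarray, shape: NetworkShape):
    """Particle-matrix -> training-MSE closure over standardized features.

    Vectorized over the whole swarm: the argument is an (n_particles, dim)
    matrix and the return an (n_particles,) MSE vector, so one optimizer
    iteration costs a handful of einsums instead of a Python loop.
    """
    c, m_in, p = shape.n_hidden, shape.n_inputs, shape.n_outputs
    n_w, n_b, n_c = c * p, p, c * m_in
    yv = y.reshape(-1, p)
    x_sq = np.sum(Xs**2, axis=1)  # (n,)

    def objective(P: np.ndarray) -> np.ndarray:
        P = np.atleast_2d(P)
        W = P[:, :n_w].reshape(-1, c, p)
        B = P[:, n_w : n_w + n_b]
        C = P[:, n_w + n_b : n_w + n_b + n_c].reshape(-1, c, m_in)
        S = np.exp(P[:, n_w + n_b + n_c :])
        d2 = (
            x_sq[None, :, None]
            - 2.0 * np.einsum("nd,kcd->knc", Xs, C)
            + np.sum(C**2, axis=2)[:, None, :]
        )
        np.maximum(d2, 0.0, out=d2)
        G = np.exp(-d2 / S[:, None, :] ** 2)
        pred = np.einsum("knc,kcp->knp", G, W) + B[:, None, :]
        return np.mean((pred - yv[None, :, :]) ** 2, axis=(1, 2))

    return objective


def _fit_standardizer(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std = np.where(std < 1e-12, 1.0, std)
    return mean, std


def _anchor_particles(
    Xs: np.ndarray, y: np.ndarray, shape: NetworkShape, n_anchors: int, seed: int
) -> np.ndarray:
    """Data-informed initial particles: centers at sample points, bias near
    mean(y), weights on the scale of the target spread.

    Standard RBF initialization practice, applied to half the swarm; the
    remaining particles start uniformly in the search box so the anchors
    bias, but do not constrain, the search.
    """
    c, m_in, p = shape.n_hidden, shape.n_inputs, shape.n_outputs
    rng = np.random.default_rng(seed + 999331)
    y_sd = float(np.std(y)) or 1.0
    w_scale = max(1.0, 3.0 * y_sd)
    anchors = np.empty((n_anchors, particle_length(shape)))
    for i in range(n_anchors):
        w = rng.uniform(-w_scale, w_scale, c * p)
        b = np.full(p, float(np.mean(y))) + rng.normal(0.0, 0.3 * y_sd, p)
        n = Xs.shape[0]
        rows = rng.choice(n, size=c, replace=c > n)
        centers = Xs[rows] + rng.normal(0.0, 0.1, (c, m_in))
        log_spreads = rng.uniform(math.log(0.5), math.log(2.0), c)
        anchors[i] = np.concatenate([w, b, centers.ravel(), log_spreads])
    return anchors


def train(
    X,
    y,
    shape: NetworkShape,
    config: Optional[opt.OptimizerConfig] = None,
    seed: int = 0,
    standardize: bool = True,
    method: str = "csapso-edcd",
) -> tuple[RBFNetwork, pd.DataFrame]:
    """Fit an RBF network to (X, y) by swarm-optimizing its particle vector.

    ``method`` selects the trainer: ``"csapso-edcd"`` (entropy-driven chaotic
    swarm, the default), ``"pso"`` (classical randomized PSO baseline) or
    ``"random"`` (uniform random search at the same evaluation budget).
    Returns the decoded best network (carrying the standardization
    constants) and the optimizer trace.
    """
    Xv = np.atleast_2d(np.asarray(X, dtype=float))
    yv = np.asarray(y, dtype=float)
    if Xv.shape[0] != yv.shape[0]:
        raise ValueError("X row count must match y length")
    if Xv.shape[1] != shape.n_inputs:
        raise ValueError(
            f"X has {Xv.shape[1]} features but shape expects {shape.n_inputs}"
        )
    if standardize:
        x_mean, x_std = _fit_standardizer(Xv)
        Xs = (Xv - x_mean) / x_std
    else:
        x_mean = x_std = None
        Xs = Xv

    base = config if config is not None else opt.OptimizerConfig()
    lo, hi = particle_bounds(shape)
    run_cfg = dataclasses.replace(base, bounds=(lo, hi), seed=seed)
    objective = _training_objective(Xs, yv, shape)
    anchors = _anchor_particles(Xs, yv, shape, n_anchors=run_cfg.m // 2, seed=seed)

    if method == "csapso-edcd":
        result = opt.optimize(
            objective, run_cfg, dim=lo.size, init_positions=anchors, vectorized=True
        )
    elif method == "pso":
        result = opt.optimize(
            objective,
            opt.plain_pso_config(base=run_cfg),
            dim=lo.size,
            init_positions=anchors,
            vectorized=True,
        )
    elif method == "random":
        result = opt.random_search(objective, run_cfg, dim=lo.size, vectorized=True)
    else:
        raise ValueError(f"unknown training method {method!r}")

    net = decode_particle(result.best_position, shape, x_mean=x_mean, x_std=x_std)
    return net, result.trace


def heuristic_hidden_search(
    X,
    y,
    candidates: Sequence[int] = range(3, 14),
    config: Optional[opt.OptimizerConfig] = None,
    seed: int = 0,
    cv: int = 5,
) -> tuple[int, pd.Series]:
    """Pick the hidden-layer size by cross-validated MSE over candidates.

    Trains one network per candidate size per fold (fixed seed per
    candidate) and applies the one-standard-error parsimony rule: among the
    candidates whose mean validation MSE lies within one standard error of
    the minimum, the smallest is returned.  The raw CV-MSE curve noise in
    the candidate direction otherwise makes the plain argmin unstable, and
    the rule breaks exact ties toward fewer nodes as a special case.  A
    training failure records +inf for that candidate and the search
    continues.  Returns ``(best_size, cv_mse_curve)``.
    """
    from sklearn.model_selection import KFold

    candidates = sorted(set(candidates))
    if not candidates:
        raise ValueError("candidates must be non-empty")
    Xv = np.atleast_2d(np.asarray(X, dtype=float))
    yv = np.asarray(y, dtype=float)
    if Xv.shape[0] < cv:
        raise ValueError(f"need at least {cv} samples for {cv}-fold validation")

    curve: dict[int, float] = {}
    stderr: dict[int, float] = {}
    splitter = KFold(n_splits=cv, shuffle=True, random_state=seed)
    folds = list(splitter.split(Xv))
    for c in candidates:
        shape = NetworkShape(Xv.shape[1], c, 1)
        try:
            fold_mse = []
            for tr, va in folds:
                net, _ = train(Xv[tr], yv[tr], shape, config=config, seed=seed + c)
                fold_mse.append(mse_fitness(net, Xv[va], yv[va]))
            curve[c] = float(np.mean(fold_mse))
            stderr[c] = float(np.std(fold_mse, ddof=1) / math.sqrt(cv)) if cv > 1 else 0.0
        except Exception:
            curve[c] = math.inf
            stderr[c] = math.inf
    series = pd.Series(curve, name="cv_mse")
    argmin = min(candidates, key=lambda c: (curve[c], c))
    if not math.isfinite(curve[argmin]):
        return argmin, series
    threshold = curve[argmin] + stderr[argmin]
    best = min(c for c in candidates if curve[c] <= threshold)
    return best, series


# ---------------------------------------------------------------------------
# model / results interface
# ---------------------------------------------------------------------------


class RBFRegression:
    """RBF-network regression model in the model/results style.

    Parameters
    ----------
    endog
        Target vector (e.g. experimental pKa values).
    exog
        Feature matrix, one row per compound (e.g. molecular descriptors).
    n_hidden
        Hidden-layer size; defaults to the ``2*sqrt(m*n)+1`` formula.
    feature_names
        Optional column labels, kept for the summary.
    """

    def __init__(self, endog, exog, n_hidden: Optional[int] = None, feature_names=None):
        self.endog = np.asarray(endog, dtype=float).ravel()
        self.exog = np.atleast_2d(np.asarray(exog, dtype=float))
        if self.exog.shape[0] != self.endog.size:
            raise ValueError("endog and exog must have the same number of rows")
        if n_hidden is None:
            n_hidden = hidden_node_formula(self.exog.shape[1], 1)
        self.shape = NetworkShape(self.exog.shape[1], n_hidden, 1)
        self.feature_names = (
            list(feature_names)
            if feature_names is not None
            else [f"x{j}" for j in range(self.exog.shape[1])]
        )

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        target: Optional[str] = None,
        id_column: Optional[str] = None,
        n_hidden: Optional[int] = None,
    ) -> "RBFRegression":
        """Build from a DataFrame (first column id, last column target, by
        convention; override with ``id_column`` / ``target``)."""
        df = frame.copy()
        if id_column is None and df.columns.size and df.iloc[:, 0].dtype == object:
            id_column = df.columns[0]
        if id_column is not None:
            df = df.drop(columns=[id_column])
        if target is None:
            target = df.columns[-1]
        y = df[target].to_numpy(dtype=float)
        Xdf = df.drop(columns=[target])
        return cls(y, Xdf.to_numpy(dtype=float), n_hidden=n_hidden,
                   feature_names=list(Xdf.columns))

    def fit(
        self,
        config: Optional[opt.OptimizerConfig] = None,
        seed: int = 0,
        method: str = "csapso-edcd",
    ) -> "RBFRegressionResults":
        net, trace = train(
            self.exog, self.endog, self.shape, config=config, seed=seed, method=method
        )
        return RBFRegressionResults(self, net, trace, method=method, seed=seed)


class RBFRegressionResults:
    """Fitted RBF regression: network, optimizer trace and diagnostics."""

    def __init__(self, model: RBFRegression, network: RBFNetwork,
                 trace: pd.DataFrame, method: str, seed: int):
        self.model = model
        self.network = network
        self.trace = trace
        self.method = method
        self.seed = seed
        self.mse_train = mse_fitness(network, model.exog, model.endog)

    @property
    def params(self) -> np.ndarray:
        """The flattened particle vector of the fitted network."""
        return encode_particle(self.network)

    def predict(self, exog=None) -> np.ndarray:
        X = self.model.exog if exog is None else exog
        return self.network.predict(X)

    def evaluate(self, exog=None, endog=None) -> EvaluationReport:
        """Accuracy statistics on the training set or on held-out data."""
        if (exog is None) != (endog is None):
            raise ValueError("provide both exog and endog, or neither")
        X = self.model.exog if exog is None else exog
        y = self.model.endog if endog is None else np.asarray(endog, dtype=float)
        return EvaluationReport.from_predictions(y, self.network.predict(X))

    def save(self, path) -> None:
        self.network.to_json(path)

    def summary(self) -> str:
        rep = self.evaluate()
        s = self.model.shape
        lines = [
            "RBF Regression Results",
            "=" * 46,
            f"{'No. observations:':<26}{self.model.endog.size}",
            f"{'Network structure:':<26}{s.n_inputs}-{s.n_hidden}-{s.n_outputs}",
            f"{'Trainer:':<26}{self.method}",
            f"{'Seed:':<26}{self.seed}",
            f"{'Iterations run:':<26}{len(self.trace)}",
            f"{'Training MSE:':<26}{self.mse_train:.6g}",
            f"{'Training AARD:':<26}{rep.aard:.4f}",
            f"{'Training RMSEP:':<26}{rep.rmsep:.4f}",
            f"{'Training R^2:':<26}{rep.r2:.4f}",
            "=" * 46,
        ]
        return "\n".join(lines)
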