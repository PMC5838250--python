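"""Wrapper descriptor-subset selection driven by the swarm optimizer.

Each particle lives in the unit cube [0, 1]^D; coordinates above a threshold
(default 0.5) switch the corresponding descriptor on.  The fitness of a
subset is the cross-validated MSE of a fast inner model (multiple linear
regression by default) on the masked columns, plus a sparsity penalty
``alpha * n_selected / D`` (``alpha`` defaulting to 0.1 * var(target)).
The final QSAR model is still an RBF network trained on the selected subset;
the linear inner model only keeps the wrapper affordable.

Two anchor particles are injected into the initial population: the
all-features mask and a random five-feature mask.  Because the global best
is monotone, the returned subset is never worse (on the same folds) than
using every descriptor.

No multiple-testing control is applied: the selection is an optimization,
not an inference procedure.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from . import optimizer as opt

__all__ = [
    "SelectionProblem",
    "SelectionResult",
    "decode_subset",
    "selection_fitness",
    "select_descriptors",
    "DescriptorSelector",
]


@dataclass
class SelectionProblem:
    """A descriptor-selection task: feature matrix, target and labels."""

    feature_matrix: np.ndarray
    target: np.ndarray
    descriptor_names: list[str]
    max_subset: Optional[int] = None
    inner_cv_folds: int = 5

    def __post_init__(self) -> None:
        self.feature_matrix = np.atleast_2d(np.asarray(self.feature_matrix, dtype=float))
        self.target = np.asarray(self.target, dtype=float).ravel()
        if self.feature_matrix.shape[0] != self.target.size:
            raise ValueError("feature matrix row count must match target length")
        if len(self.descriptor_names) != self.feature_matrix.shape[1]:
            raise ValueError("descriptor_names length must match column count")

    @property
    def n_descriptors(self) -> int:
        return self.feature_matrix.shape[1]

    @classmethod
    def from_dataframe(
        cls, frame: pd.DataFrame, target: Optional[str] = None,
        id_column: Optional[str] = None, **kwargs
    ) -> "SelectionProblem":
        df = frame.copy()
        if id_column is None and df.columns.size and df.iloc[:, 0].dtype == object:
            id_column = df.columns[0]
        if id_column is not None:
            df = df.drop(columns=[id_column])
        if target is None:
            target = df.columns[-1]
        y = df[target].to_numpy(dtype=float)
        Xdf = df.drop(columns=[target])
        return cls(Xdf.to_numpy(dtype=float), y, list(Xdf.columns), **kwargs)


@dataclass
class SelectionResult:
    """Outcome of a selection run."""

    selected_names: list[str]
    mask: np.ndarray
    fitness: float
    trace: pd.DataFrame


def decode_subset(
    position, threshold: float = 0.5, max_subset: Optional[int] = None
) -> np.ndarray:
    """Threshold a continuous position in [0, 1]^D into a boolean mask.

    An empty mask is rescued by forcing on the single largest coordinate;
    a ``max_subset`` cap keeps only the top coordinates by value.
    """
    pos = np.asarray(position, dtype=float).ravel()
    if pos.size < 1:
        raise ValueError("position must have at least one coordinate")
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    mask = pos > threshold
    if not mask.any():
        mask = np.zeros(pos.size, dtype=bool)
        mask[int(np.argmax(pos))] = True
    if max_subset is not None and mask.sum() > max_subset:
        order = np.argsort(-pos)  # stable: ties keep lower index
        keep = order[:max_subset]
        mask = np.zeros(pos.size, dtype=bool)
        mask[keep] = True
    return mask


def _cv_mse_linear(X: np.ndarray, y: np.ndarray, folds: int, seed: int) -> float:
    """K-fold CV MSE of ordinary least squares with intercept on (X, y)."""
    from sklearn.model_selection import KFold

    mses = []
    for tr, va in KFold(n_splits=folds, shuffle=True, random_state=seed).split(X):
        A = np.column_stack([np.ones(tr.size), X[tr]])
        coef, *_ = np.linalg.lstsq(A, y[tr], rcond=None)
        Av = np.column_stack([np.ones(va.size), X[va]])
        pred = Av @ coef
        mses.append(float(np.mean((pred - y[va]) ** 2)))
    return float(np.mean(mses))


def selection_fitness(
    mask,
    problem: SelectionProblem,
    alpha: Optional[float] = None,
    cv_seed: int = 0,
    inner: Optional[Callable[[np.ndarray, np.ndarray], float]] = None,
) -> float:
    """Penalized cross-validated error of one descriptor subset (lower = better).

    ``inner(X_masked, y) -> cv_mse`` may be supplied to swap the inner model
    (e.g. a small RBF network, or an exact oracle in tests); the default is
    seeded K-fold linear regression.
    """
    m = np.asarray(mask, dtype=bool).ravel()
    if m.size != problem.n_descriptors:
        raise ValueError("mask length must match descriptor count")
    k = int(m.sum())
    if k < 1:
        raise ValueError("mask must select at least one descriptor")
    if alpha is None:
        alpha = 0.1 * float(np.var(problem.target))
    Xm = problem.feature_matrix[:, m]
    if inner is None:
        cv_mse = _cv_mse_linear(Xm, problem.target, problem.inner_cv_folds, cv_seed)
    else:
        cv_mse = float(inner(Xm, problem.target))
    return cv_mse + alpha * k / problem.n_descriptors


def select_descriptors(
    problem: SelectionProblem,
    config: Optional[opt.OptimizerConfig] = None,
    seed: int = 0,
    threshold: float = 0.5,
    alpha: Optional[float] = None,
    inner: Optional[Callable[[np.ndarray, np.ndarray], float]] = None,
) -> SelectionResult:
    """Search descriptor subsets with the CSAPSO-EDCD optimizer.

    Returns the best mask's descriptor names (in original column order), the
    mask, its penalized fitness and the optimizer trace.  Reproducible given
    ``seed`` (the same seed fixes both the swarm and the CV folds).
    """
    D = problem.n_descriptors
    base = config if config is not None else opt.OptimizerConfig()
    run_cfg = dataclasses.replace(base, bounds=(0.0, 1.0), seed=seed)

    def objective(pos: np.ndarray) -> float:
        mask = decode_subset(pos, threshold=threshold, max_subset=problem.max_subset)
        return selection_fitness(mask, problem, alpha=alpha, cv_seed=seed, inner=inner)

    # anchor particles: all-features, and a random 5-feature subset
    anchor_rng = np.random.default_rng(seed + 104729)
    anchors = np.full((2, D), 0.1)
    anchors[0, :] = 0.9
    chosen = anchor_rng.choice(D, size=min(5, D), replace=False)
    anchors[1, chosen] = 0.9

    result = opt.optimize(objective, run_cfg, dim=D, init_positions=anchors)
    mask = decode_subset(result.best_position, threshold=threshold,
                         max_subset=problem.max_subset)
    names = [n for n, keep in zip(problem.descriptor_names, mask) if keep]
    return SelectionResult(
        selected_names=names,
        mask=mask,
        fitness=result.best_fitness,
        trace=result.trace,
    )


class DescriptorSelector:
    """Thin model-style wrapper around :func:`select_descriptors`."""

    def __init__(self, problem: SelectionProblem, threshold: float = 0.5,
                 alpha: Optional[float] = None):
        self.problem = problem
        self.threshold = threshold
        self.alpha = alpha

    def fit(self, config: Optional[opt.OptimizerConfig] = None, seed: int = 0
            ) -> SelectionResult:
        return select_descriptors(
            self.problem, config=config, seed=seed,
            threshold=self.threshold, alpha=self.alpha,
        )
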