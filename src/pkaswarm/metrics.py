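"""Regression accuracy statistics for pKa prediction models.

Three statistics are used throughout the package to judge a trained model
against experimental pKa values:

* **AARD** — absolute average relative deviation, ``mean(|ŷ - y| / y)``.
  The denominator is the *signed* experimental value; a zero experimental
  value makes the statistic undefined and is rejected rather than skipped.
* **RMSEP** — root mean square error of prediction, in pKa units.
* **R²** — the squared Pearson correlation between experimental and
  predicted values.  Note this is the correlation form, not
  ``1 - SSE/SST``; the two differ for biased predictors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["aard", "rmsep", "r_squared", "EvaluationReport"]


def _pair(y_true, y_pred) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(y_true, dtype=float).ravel()
    p = np.asarray(y_pred, dtype=float).ravel()
    if t.shape != p.shape:
        raise ValueError(
            f"length mismatch: y_true has {t.size} entries, y_pred has {p.size}"
        )
    if t.size == 0:
        raise ValueError("empty input: need at least one (true, predicted) pair")
    return t, p


def aard(y_true, y_pred) -> float:
    """Absolute average relative deviation ``mean(|ŷ_i - y_i| / y_i)``.

    Raises ``ValueError`` if any experimental value is exactly zero (the
    relative deviation is undefined there).
    """
    t, p = _pair(y_true, y_pred)
    zeros = np.flatnonzero(t == 0.0)
    if zeros.size:
        raise ValueError(f"aard undefined: y_true is zero at index {zeros[0]}")
    return float(np.mean(np.abs(p - t) / t))


def rmsep(y_true, y_pred) -> float:
    """Root mean square error of prediction, ``sqrt(mean((y_i - ŷ_i)^2))``."""
    t, p = _pair(y_true, y_pred)
    return float(np.sqrt(np.mean((t - p) ** 2)))


def r_squared(y_true, y_pred) -> float:
    """Squared Pearson correlation between experimental and predicted values.

    Requires at least two samples and non-constant vectors on both sides;
    a constant vector makes the correlation undefined.
    """
    t, p = _pair(y_true, y_pred)
    if t.size < 2:
        raise ValueError("r_squared needs at least 2 samples")
    dt = t - t.mean()
    dp = p - p.mean()
    sst = float(np.sum(dt**2))
    ssp = float(np.sum(dp**2))
    if sst == 0.0 or ssp == 0.0:
        raise ValueError("r_squared undefined for a constant vector")
    cov = float(np.sum(dt * dp))
    return cov**2 / (sst * ssp)


@dataclass(frozen=True)
class EvaluationReport:
    """Bundle of the three accuracy statistics for one (true, predicted) pairing."""

    aard: float
    rmsep: float
    r2: float
    n: int

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "EvaluationReport":
        t, p = _pair(y_true, y_pred)
        return cls(aard=aard(t, p), rmsep=rmsep(t, p), r2=r_squared(t, p), n=t.size)

    def to_csv_line(self, header: bool = False) -> str:
        line = f"{self.aard:.6g},{self.rmsep:.6g},{self.r2:.6g},{self.n}"
        if header:
            return "aard,rmsep,r2,n\n" + line
        return line

    def __str__(self) -> str:  # pretty, Table-style layout
        return (
            f"n = {self.n}\n"
            f"AARD  = {self.aard:.4f}\n"
            f"RMSEP = {self.rmsep:.4f}\n"
            f"R^2   = {self.r2:.4f}"
        )
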