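"""Bundled experimental pKa tables, the 70/30 split, and synthetic generators.

Two curated compound tables ship with the package:

* ``main`` — 74 neutral and basic drugs with experimental pKa values, the
  modelling database (70% training / 30% testing by seeded random split,
  which for 74 compounds gives the conventional 52/22 partition);
* ``additional`` — 20 further compounds used purely as an external
  validation set.

The exact historical train/test partition of the main table was never
published, so the split here is seeded-random: ``random_split`` uses a
named PRNG (NumPy ``default_rng``, PCG64) with integer seeding and is
therefore stable across platforms.

The synthetic generators produce (a) regression targets from a known RBF
surface plus Gaussian noise, for trainer-recovery tests, and (b) feature
matrices with a planted informative subset, for selection-recovery tests.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass
from importlib import resources
from typing import Optional

import numpy as np
import pandas as pd

from .rbf import RBFNetwork
from .selection import SelectionProblem

__all__ = [
    "CompoundRecord",
    "SplitSpec",
    "CorruptedFixtureError",
    "load_dataset",
    "load_dataframe",
    "load_smiles_sidecar",
    "random_split",
    "synth_rbf_regression",
    "synth_selection_problem",
]

_FIXTURES = {
    "main": (
        "drugs_main.csv",
        "0d2054d4d578313c0428c1430dd31b1f3da74973a221113f6c573d589ab3dca1",
    ),
    "additional": (
        "drugs_additional.csv",
        "0970b26f3825c6fb1af5c89e665039bd922df069a762a55af94a771be3a7eef2",
    ),
}


class CorruptedFixtureError(RuntimeError):
    """A bundled data file does not match its recorded checksum."""


@dataclass
class CompoundRecord:
    """One compound: name, experimental pKa, optional descriptors/structure."""

    name: str
    pka_exp: float
    descriptors: Optional[np.ndarray] = None
    smiles: Optional[str] = None


@dataclass(frozen=True)
class SplitSpec:
    """Train/test split specification (fraction and PRNG seed)."""

    train_fraction: float = 0.70
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must lie in (0, 1)")


def _fixture_bytes(filename: str, sha256: str) -> bytes:
    raw = resources.files("pkaswarm.data").joinpath(filename).read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != sha256:
        raise CorruptedFixtureError(
            f"fixture {filename} checksum mismatch: expected {sha256}, got {digest}"
        )
    return raw


def load_dataframe(which: str) -> pd.DataFrame:
    """Load a bundled table ('main' or 'additional') as a DataFrame."""
    if which not in _FIXTURES:
        raise ValueError(f"unknown dataset {which!r}; choose from {sorted(_FIXTURES)}")
    filename, sha = _FIXTURES[which]
    from io import BytesIO

    return pd.read_csv(BytesIO(_fixture_bytes(filename, sha)))


def load_dataset(which: str) -> list[CompoundRecord]:
    """Load a bundled table as a list of `CompoundRecord`.

    ``main`` yields 74 records, ``additional`` 20; values are the printed
    experimental pKa values, verified against a checksum on every load.
    """
    df = load_dataframe(which)
    return [CompoundRecord(name=row["name"], pka_exp=float(row["pka_exp"]))
            for _, row in df.iterrows()]


def load_smiles_sidecar() -> pd.DataFrame:
    """Curated best-effort SMILES for a subset of the bundled compounds.

    Structures are drawn in their neutral form; descriptor values computed
    from them are approximations and are not asserted against any external
    descriptor table.
    """
    path = resources.files("pkaswarm.data").joinpath("smiles_sidecar.csv")
    from io import BytesIO

    return pd.read_csv(BytesIO(path.read_bytes()))


def random_split(records, spec: SplitSpec = SplitSpec()):
    """Seeded random partition into (train, test) lists.

    The training size is ``floor(fraction * N + 0.5)`` (round half up), so
    the 74-compound table splits 52/22 at the default 70%.  The partition is
    disjoint, exhaustive and identical for identical seeds.
    """
    records = list(records)
    n = len(records)
    if n < 2:
        raise ValueError("need at least 2 records to split")
    n_train = int(math.floor(spec.train_fraction * n + 0.5))
    n_train = min(max(n_train, 1), n - 1)
    perm = np.random.default_rng(spec.seed).permutation(n)
    train = [records[i] for i in perm[:n_train]]
    test = [records[i] for i in perm[n_train:]]
    return train, test


def synth_rbf_regression(
    n_samples: int,
    n_features: int,
    n_centers: int,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, RBFNetwork]:
    """Regression data from a randomly parameterized Gaussian RBF surface.

    Features are uniform in the cube [-2, 2]^d; the target is the response
    of a random ``n_centers``-node RBF network (centers in the same cube,
    spreads in [0.6, 1.6], weights in [-2, 2]) plus N(0, noise_sd²) noise.
    Returns ``(X, y, true_network)`` so recovery tests can compare against
    the generating parameters.  Deterministic given ``seed``.
    """
    if min(n_samples, n_features, n_centers) < 1:
        raise ValueError("all counts must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    X = rng.uniform(-2.0, 2.0, size=(n_samples, n_features))
    centers = rng.uniform(-2.0, 2.0, size=(n_centers, n_features))
    spreads = rng.uniform(0.6, 1.6, size=n_centers)
    weights = rng.uniform(-2.0, 2.0, size=(n_centers, 1))
    biases = rng.uniform(-1.0, 1.0, size=1)
    net = RBFNetwork(centers, spreads, weights, biases)
    y = net.predict(X)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=n_samples)
    return X, y, net


def synth_selection_problem(
    n_samples: int,
    n_informative: int,
    n_noise: int,
    effect_sizes=None,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[SelectionProblem, np.ndarray]:
    """Selection task with a planted linear support.

    All columns are independent N(0, 1); the target is a linear combination
    of ``n_informative`` randomly placed columns (coefficients
    ``effect_sizes``, default all 1) plus N(0, noise_sd²) noise.  Returns
    ``(problem, support)`` where ``support`` holds the informative column
    indices in ascending order.
    """
    if n_informative < 1:
        raise ValueError("n_informative must be >= 1")
    if n_noise < 0:
        raise ValueError("n_noise must be >= 0")
    d = n_informative + n_noise
    if effect_sizes is None:
        effect_sizes = np.ones(n_informative)
    effect_sizes = np.asarray(effect_sizes, dtype=float).ravel()
    if effect_sizes.size != n_informative:
        raise ValueError("effect_sizes length must equal n_informative")
    rng = np.random.default_rng(seed)
    X = rng.normal(0.0, 1.0, size=(n_samples, d))
    support = np.sort(rng.choice(d, size=n_informative, replace=False))
    y = X[:, support] @ effect_sizes
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=n_samples)
    names = [f"d{j}" for j in range(d)]
    problem = SelectionProblem(X, y, names)
    return problem, support
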