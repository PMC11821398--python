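"""Per-class multivariate Gaussian models and Monte-Carlo samplers.

Each oil class is modeled as a multivariate normal distribution over the
schema's features: the empirical mean vector locates the class centroid
and the empirical covariance matrix preserves the variances of, and the
correlations between, the compositional features.  Monte-Carlo draws
from this model are the data-augmentation engine of the package.

With a handful of observed samples and dozens of features the sample
covariance is singular; sampling therefore goes through an
eigendecomposition with negative eigenvalues clipped at zero, which is
the standard well-defined contract for drawing from a degenerate
Gaussian.

An independent-marginal sampler (diagonal covariance only) is provided
as a deliberately weaker comparison generator: it matches every
univariate marginal but destroys the between-feature correlations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .data import CompositionTable

SYMMETRY_TOL = 1e-10
PSD_TOL = 1e-8

MC_TAG = "mc"
INDEPENDENT_TAG = "independent-marginal"


class NonPSDError(ValueError):
    """Covariance matrix has an eigenvalue below tolerance."""


@dataclass(frozen=True)
class ClassDistribution:
    """Fitted Gaussian model of one oil class.

    Attributes
    ----------
    label : class name (e.g. ``"CO"``).
    mu : mean vector, length ``k``, in % units.
    sigma : ``k x k`` covariance matrix, %^2 units; symmetric PSD up to
        numerical noise.
    n_source : number of observed samples behind the fit (0 when the
        distribution is constructed rather than fitted).
    """

    label: str
    mu: np.ndarray
    sigma: np.ndarray
    n_source: int = 0

    def __post_init__(self):
        mu = np.asarray(self.mu, dtype=float)
        sigma = np.asarray(self.sigma, dtype=float)
        if mu.ndim != 1 or sigma.shape != (mu.size, mu.size):
            raise ValueError("mu must be length-k and sigma k x k")
        scale = max(np.abs(sigma).max(), 1.0)
        if np.abs(sigma - sigma.T).max() > SYMMETRY_TOL * scale:
            raise ValueError("sigma is not symmetric")
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "sigma", (sigma + sigma.T) / 2.0)

    @property
    def k(self) -> int:
        return self.mu.size

    # -- serialization ----------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "label": self.label,
                    "mu": self.mu.tolist(),
                    "sigma": self.sigma.tolist(),
                    "n_source": self.n_source,
                },
                indent=1,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "ClassDistribution":
        d = json.loads(Path(path).read_text())
        return cls(d["label"], np.array(d["mu"]), np.array(d["sigma"]), d["n_source"])


@dataclass(frozen=True)
class LabeledSimDataset:
    """Simulated n x k feature matrix carrying one class label."""

    label: str
    data: np.ndarray
    generator_tag: str
    seed: int

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2 or data.shape[0] < 1:
            raise ValueError("data must be a non-empty n x k matrix")
        if np.isnan(data).any():
            raise ValueError("simulated data must have no missing entries")
        object.__setattr__(self, "data", data)

    @property
    def n(self) -> int:
        return self.data.shape[0]


def fit_class_distribution(
    table: CompositionTable, label: Optional[str] = None
) -> ClassDistribution:
    """Fit mean vector and sample covariance (n-1 denominator) to a class.

    The table must be preprocessed (no flagged entries remaining; run
    :func:`oilauth.data.average_replicates` first) and contain at least
    two samples with the given label (defaults to the table's single
    label).
    """
    if label is None:
        labels = set(table.labels())
        if len(labels) != 1:
            raise ValueError(f"table has labels {sorted(labels)}; pass one explicitly")
        label = labels.pop()
    sub = table.subset(label)
    if sub.has_flags:
        raise ValueError("table still contains flagged entries; average replicates first")
    X = sub.matrix()
    if X.shape[0] < 2:
        raise ValueError(
            f"need >= 2 samples for label {label!r}, got {X.shape[0]}"
        )
    mu = X.mean(axis=0)
    sigma = np.cov(X, rowvar=False, ddof=1)
    return ClassDistribution(label, mu, np.atleast_2d(sigma), n_source=X.shape[0])


def fit_from_matrix(X: np.ndarray, label: str) -> ClassDistribution:
    """Moment fit straight from an n x k matrix (same estimators)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need an n x k matrix with n >= 2")
    return ClassDistribution(
        label, X.mean(axis=0), np.atleast_2d(np.cov(X, rowvar=False, ddof=1)),
        n_source=X.shape[0],
    )


def _sampling_root(sigma: np.ndarray) -> np.ndarray:
    """Matrix A with A A^T = sigma via eigendecomposition.

    Negative eigenvalues within PSD_TOL (relative) are clipped to zero so
    singular covariances sample on their support; anything more negative
    is an error.
    """
    w, V = np.linalg.eigh(sigma)
    scale = max(w.max(initial=0.0), 1.0)
    if w.min(initial=0.0) < -PSD_TOL * scale:
        raise NonPSDError(
            f"covariance not PSD: most negative eigenvalue {w.min():.3e}"
        )
    return V * np.sqrt(np.clip(w, 0.0, None))


def mc_sample(
    dist: ClassDistribution,
    n: int,
    seed: int,
    clip_nonnegative: bool = False,
) -> LabeledSimDataset:
    """Draw ``n`` Monte-Carlo samples from the class Gaussian.

    ``clip_nonnegative`` truncates negative entries at zero after
    sampling (compositions cannot be negative); off by default so that
    the simulated data follow the stated multivariate normal exactly.
    Deterministic given ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    A = _sampling_root(dist.sigma)
    rng = np.random.default_rng(seed)
    X = dist.mu + rng.standard_normal((n, dist.k)) @ A.T
    if clip_nonnegative:
        np.clip(X, 0.0, None, out=X)
    return LabeledSimDataset(dist.label, X, MC_TAG, seed)


def baseline_independent_sample(
    dist: ClassDistribution,
    n: int,
    seed: int,
    clip_nonnegative: bool = False,
) -> LabeledSimDataset:
    """Sample each feature independently from its univariate marginal.

    Matches the per-feature means and variances of ``dist`` but ignores
    all off-diagonal covariance — the information the full Monte-Carlo
    sampler is designed to preserve.  Serves as the weaker comparison
    generator in divergence benchmarks.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    var = np.diag(dist.sigma)
    if var.min() < -PSD_TOL:
        raise NonPSDError(f"negative marginal variance {var.min():.3e}")
    rng = np.random.default_rng(seed)
    X = dist.mu + rng.standard_normal((n, dist.k)) * np.sqrt(np.clip(var, 0.0, None))
    if clip_nonnegative:
        np.clip(X, 0.0, None, out=X)
    return LabeledSimDataset(dist.label, X, INDEPENDENT_TAG, seed)


def save_sim_dataset(
    ds: LabeledSimDataset,
    path: str | Path,
    feature_names: Optional[list[str]] = None,
) -> None:
    """Write a simulated dataset as CSV (features + label/tag columns)."""
    import pandas as pd

    names = feature_names or [f"f{i}" for i in range(ds.data.shape[1])]
    df = pd.DataFrame(ds.data, columns=names)
    df["class_label"] = ds.label
    df["generator_tag"] = ds.generator_tag
    df["seed"] = ds.seed
    df.to_csv(path, index=False)


def load_sim_dataset(path: str | Path) -> LabeledSimDataset:
    """Read a dataset written by :func:`save_sim_dataset`."""
    import pandas as pd

    df = pd.read_csv(path)
    meta = {"class_label", "generator_tag", "seed"}
    feats = [c for c in df.columns if c not in meta]
    label = str(df["class_label"].iloc[0])
    tag = str(df["generator_tag"].iloc[0])
    seed = int(df["seed"].iloc[0])
    return LabeledSimDataset(label, df[feats].to_numpy(float), tag, seed)
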