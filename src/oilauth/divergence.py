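"""Gaussian Kullback-Leibler divergence and generator benchmarking.

Simulation fidelity is scored with the closed-form KL divergence
between two multivariate normals,

    D(N0 || N1) = 1/2 [ tr(S1^-1 S0) + (m1-m0)^T S1^-1 (m1-m0)
                        - k + ln(det S1 / det S0) ],

where N0 = (m0, S0) is the *simulated* distribution and N1 = (m1, S1)
the *observed* one.  The divergence is non-negative, zero exactly when
the distributions coincide, and grows as the simulated distribution
drifts from the observed one.

Empirical covariances of small compositional datasets are singular, so
both matrices receive the same deterministic diagonal ridge before the
divergence is evaluated; sharing the ridge preserves the identity law
D(d, d) = 0.  All linear algebra goes through Cholesky factorizations —
no explicit inverses, no raw determinants — so k = 37 poses no
overflow or conditioning problem.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg

from .data import CompositionTable
from .generators import (
    ClassDistribution,
    LabeledSimDataset,
    fit_class_distribution,
    fit_from_matrix,
)

DEFAULT_EPSILON = 1e-6

#: A generator is any callable (dist, n, seed) -> LabeledSimDataset.
Generator = Callable[[ClassDistribution, int, int], LabeledSimDataset]


@dataclass(frozen=True)
class KLDResult:
    """KL divergence of a simulated Gaussian from an observed one."""

    value: float          # nats
    epsilon_used: float   # relative ridge magnitude applied to both matrices
    k: int                # dimension
    direction: str = "simulated||observed"


def regularize_covariance(sigma: np.ndarray, epsilon: float) -> np.ndarray:
    """Add a deterministic diagonal ridge to make ``sigma`` invertible.

    Returns ``sigma + epsilon * scale * I`` with ``scale`` the mean of
    the diagonal (1.0 if that mean is zero), so the ridge is relative to
    the matrix's own variance scale.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    sigma = np.asarray(sigma, dtype=float)
    if sigma.ndim != 2 or sigma.shape[0] != sigma.shape[1]:
        raise ValueError("sigma must be square")
    scale = max(np.abs(sigma).max(), 1.0)
    if np.abs(sigma - sigma.T).max() > 1e-8 * scale:
        raise ValueError("sigma is not symmetric")
    diag_mean = float(np.trace(sigma)) / sigma.shape[0]
    ridge = epsilon * (diag_mean if diag_mean != 0.0 else 1.0)
    return sigma + ridge * np.eye(sigma.shape[0])


def _chol_logdet(sigma: np.ndarray):
    """Cholesky factor and log-determinant of a symmetric PD matrix."""
    c, low = linalg.cho_factor(sigma, lower=True, check_finite=False)
    logdet = 2.0 * float(np.sum(np.log(np.diag(c))))
    return (c, low), logdet


def gaussian_kld(
    sim: ClassDistribution,
    obs: ClassDistribution,
    epsilon: float = DEFAULT_EPSILON,
) -> KLDResult:
    """Closed-form KL divergence D(simulated || observed) in nats.

    Both covariances are regularized with the same relative ridge
    ``epsilon`` before evaluation, so identical inputs give exactly 0.
    """
    if sim.k != obs.k:
        raise ValueError(f"dimension mismatch: sim k={sim.k}, obs k={obs.k}")
    k = sim.k
    s0 = regularize_covariance(sim.sigma, epsilon)
    s1 = regularize_covariance(obs.sigma, epsilon)
    try:
        f1, logdet1 = _chol_logdet(s1)
        _, logdet0 = _chol_logdet(s0)
    except linalg.LinAlgError as e:
        raise FloatingPointError(
            f"Cholesky factorization failed after regularization "
            f"(epsilon={epsilon}); try a larger epsilon"
        ) from e
    trace_term = float(np.trace(linalg.cho_solve(f1, s0, check_finite=False)))
    d = obs.mu - sim.mu
    maha = float(d @ linalg.cho_solve(f1, d, check_finite=False))
    value = 0.5 * (trace_term + maha - k + logdet1 - logdet0)
    return KLDResult(value=value, epsilon_used=epsilon, k=k)


def fit_and_score_generator(
    observed: CompositionTable,
    simulated: LabeledSimDataset,
    epsilon: float = DEFAULT_EPSILON,
) -> KLDResult:
    """Fit Gaussians to observed and simulated data, then score the KLD.

    Both sides go through the same moment estimators (mean, n-1 sample
    covariance), so an exact copy of the observed rows scores 0.
    """
    obs_dist = fit_class_distribution(observed, simulated.label)
    sim_dist = fit_from_matrix(simulated.data, simulated.label)
    if sim_dist.k != obs_dist.k:
        raise ValueError(
            f"dimension mismatch: simulated k={sim_dist.k}, observed k={obs_dist.k}"
        )
    return gaussian_kld(sim_dist, obs_dist, epsilon)


def compare_generators(
    observed: Mapping[str, CompositionTable],
    generators: Mapping[str, Generator],
    sizes: Sequence[int],
    epsilon: float = DEFAULT_EPSILON,
    seed: int = 0,
) -> pd.DataFrame:
    """Score every (generator, size, class) cell of a comparison grid.

    For each oil class the observed table is fitted once; each generator
    then simulates each requested size from that fit and is scored by
    :func:`fit_and_score_generator`.  Returns a tidy DataFrame with
    columns ``generator_tag``, ``n_simulated``, ``class``, ``kld_value``
    — one row per requested combination.
    """
    if not sizes:
        raise ValueError("sizes must be non-empty")
    rows = []
    for ci, (label, table) in enumerate(observed.items()):
        dist = fit_class_distribution(table, label)
        for gi, (tag, gen) in enumerate(generators.items()):
            for si, n in enumerate(sizes):
                sub_seed = (seed + 1_000_003 * ci + 1_009 * gi + si) % (2**31)
                sim = gen(dist, int(n), sub_seed)
                res = fit_and_score_generator(table, sim, epsilon)
                rows.append(
                    {
                        "generator_tag": tag,
                        "n_simulated": int(n),
                        "class": label,
                        "kld_value": res.value,
                    }
                )
    return pd.DataFrame(rows, columns=["generator_tag", "n_simulated", "class", "kld_value"])
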