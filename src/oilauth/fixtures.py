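"""Self-contained synthetic stand-ins for measured oil-composition data.

The package's downstream stages (distribution fitting, Monte-Carlo
augmentation, divergence scoring, mixture synthesis, classification)
need observed pure-oil tables and known ground-truth distributions to
be testable without any external download.  This module builds them:

* ground-truth Gaussians for cactus seed oil (CO) and refined sunflower
  oil (SO) whose means come from published composition ranges for the
  major analytes (e.g. CO linoleic acid 54.6-65.4 %, SO oleic acid
  28.5-32.7 %, CO gamma-tocopherol 92-97 %, SO alpha-tocopherol
  96-97 %), padded with plausible ranges for the minor analytes;
* "observed" tables emulating the study design of 27 CO and 10 SO
  measured samples;
* physically-mixed validation samples at the five adulteration levels
  (1, 3, 5, 7, 9 % by mass), 33 rows by default.

Covariance construction: standard deviations are a fixed coefficient of
variation of each mean (floored for trace analytes, capped at half the
stated range), correlations follow a one-factor model with a single
off-diagonal rho, and each block is closed with the oblique projection
M = I - w 1^T (w proportional to the block's standard deviations) so
that within-sample block sums stay at exactly 100 % and the closure
correction is absorbed by the dominant analytes rather than the trace
ones.  The projection makes the covariance singular — exactly the
property empirical percent-of-total covariances have — which
downstream code must (and does) handle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .data import CompositionSample, CompositionTable, write_composition_table
from .generators import ClassDistribution, mc_sample
from .mixtures import CO_LABEL, DEFAULT_RATIOS, SO_LABEL, blend_rows, ratio_label
from .schema import FeatureSchema

# ---------------------------------------------------------------------------
# Canonical 37-feature schema: 12 fatty acids, 21 triacylglycerols,
# 4 tocochromanols.  TAG names follow the Pa/St/Ol/Li/Ln monomer shorthand
# (palmitic, stearic, oleic, linoleic, linolenic).

_FA = (
    "palmitic", "palmitoleic", "margaric", "stearic", "oleic", "vaccenic",
    "linoleic", "alpha_linolenic", "arachidic", "gondoic", "behenic",
    "lignoceric",
)
_TAG = (
    "LiLiLi", "PaLiLi", "LiLiOl", "OlLiOl", "PaLiOl", "OlOlOl", "PaOlOl",
    "PaPaLi", "StLiLi", "StOlLi", "StOlOl", "PaOlPa", "LiLiLn", "PaLiLn",
    "OlLiLn", "PaPaOl", "StStOl", "PaLiSt", "StLiSt", "OlOlLn", "PaPaPa",
)
_TOCO = ("alpha_tocopherol", "beta_tocopherol", "gamma_tocopherol",
         "delta_tocopherol")


def canonical_schema() -> FeatureSchema:
    """The default 37-feature schema used by all fixtures."""
    block_of = {n: "FA" for n in _FA}
    block_of.update({n: "TAG" for n in _TAG})
    block_of.update({n: "TOCO" for n in _TOCO})
    return FeatureSchema(_FA + _TAG + _TOCO, block_of)


# Per-class (low, high) composition ranges in %.  Majors for FA and all
# tocochromanols reflect published ranges for Moroccan cactus seed oil and
# refined sunflower oil; minors and TAG species are plausible synthetic
# stand-ins (no claim of chemical realism).
CO_RANGES: dict[str, tuple[float, float]] = {
    "palmitic": (11.4, 12.9), "palmitoleic": (0.5, 1.0),
    "margaric": (0.05, 0.15), "stearic": (2.5, 3.5), "oleic": (13.0, 23.0),
    "vaccenic": (0.5, 1.2), "linoleic": (54.6, 65.4),
    "alpha_linolenic": (0.2, 0.5), "arachidic": (0.2, 0.5),
    "gondoic": (0.1, 0.3), "behenic": (0.1, 0.3), "lignoceric": (0.05, 0.2),
    "LiLiLi": (28.0, 36.0), "PaLiLi": (12.0, 18.0), "LiLiOl": (16.0, 22.0),
    "OlLiOl": (5.0, 9.0), "PaLiOl": (6.0, 10.0), "OlOlOl": (1.0, 3.0),
    "PaOlOl": (1.0, 3.0), "PaPaLi": (2.0, 4.0), "StLiLi": (2.0, 4.0),
    "StOlLi": (1.0, 2.0), "StOlOl": (0.2, 0.8), "PaOlPa": (0.5, 1.5),
    "LiLiLn": (0.5, 1.5), "PaLiLn": (0.3, 0.8), "OlLiLn": (0.2, 0.6),
    "PaPaOl": (0.3, 0.8), "StStOl": (0.05, 0.2), "PaLiSt": (0.5, 1.5),
    "StLiSt": (0.05, 0.2), "OlOlLn": (0.05, 0.2), "PaPaPa": (0.02, 0.1),
    "alpha_tocopherol": (0.0, 4.0), "beta_tocopherol": (0.0, 1.0),
    "gamma_tocopherol": (92.0, 97.0), "delta_tocopherol": (0.0, 2.0),
}

SO_RANGES: dict[str, tuple[float, float]] = {
    "palmitic": (5.6, 6.9), "palmitoleic": (0.1, 0.3),
    "margaric": (0.03, 0.1), "stearic": (3.0, 4.5), "oleic": (28.5, 32.7),
    "vaccenic": (0.5, 1.0), "linoleic": (54.6, 59.1),
    "alpha_linolenic": (0.1, 0.3), "arachidic": (0.2, 0.4),
    "gondoic": (0.1, 0.3), "behenic": (0.6, 0.9), "lignoceric": (0.2, 0.4),
    "LiLiLi": (18.0, 26.0), "PaLiLi": (6.0, 10.0), "LiLiOl": (20.0, 26.0),
    "OlLiOl": (12.0, 16.0), "PaLiOl": (4.0, 7.0), "OlOlOl": (3.0, 6.0),
    "PaOlOl": (2.0, 4.0), "PaPaLi": (0.5, 1.5), "StLiLi": (2.0, 4.0),
    "StOlLi": (2.0, 4.0), "StOlOl": (1.0, 2.0), "PaOlPa": (0.2, 0.8),
    "LiLiLn": (0.1, 0.5), "PaLiLn": (0.05, 0.3), "OlLiLn": (0.05, 0.3),
    "PaPaOl": (0.2, 0.6), "StStOl": (0.1, 0.4), "PaLiSt": (0.3, 1.0),
    "StLiSt": (0.1, 0.4), "OlOlLn": (0.05, 0.3), "PaPaPa": (0.02, 0.1),
    "alpha_tocopherol": (96.0, 97.0), "beta_tocopherol": (0.0, 1.0),
    "gamma_tocopherol": (0.0, 4.0), "delta_tocopherol": (0.0, 1.0),
}

#: Study-design sample counts for the "observed" fixture tables.
N_OBSERVED_CO = 27
N_OBSERVED_SO = 10
#: Number of physically-mixed validation samples in the study design.
N_REAL_WORLD = 33


@dataclass(frozen=True)
class GroundTruthSpec:
    """Parameters of the synthetic ground truth.

    rho is the shared off-diagonal correlation of the one-factor model,
    cv the coefficient of variation setting each feature's standard
    deviation (sd_i = cv * max(mu_i, sd_floor), capped at half the
    feature's stated range so the spread never exceeds what the ranges
    assert), and sd_floor keeps trace analytes from becoming exactly
    constant.
    """

    schema: FeatureSchema = field(default_factory=canonical_schema)
    ranges: Mapping[str, Mapping[str, tuple[float, float]]] = field(
        default_factory=lambda: {CO_LABEL: CO_RANGES, SO_LABEL: SO_RANGES}
    )
    rho: float = 0.3
    cv: float = 0.08
    sd_floor: float = 0.02
    seed: int = 20270101

    def __post_init__(self):
        if not (0.0 <= self.rho < 1.0):
            raise ValueError("rho must lie in [0, 1)")
        if self.cv <= 0:
            raise ValueError("cv must be > 0")
        for label, ranges in self.ranges.items():
            missing = [n for n in self.schema.feature_names if n not in ranges]
            if missing:
                raise ValueError(f"class {label!r} lacks ranges for {missing}")
            for name, (lo, hi) in ranges.items():
                if lo > hi:
                    raise ValueError(f"{label}/{name}: low {lo} > high {hi}")


@dataclass
class FixtureBundle:
    """Everything a downstream stage needs, generated from one seed."""

    schema: FeatureSchema
    spec: GroundTruthSpec
    ground_truth: dict[str, ClassDistribution]
    observed_co: CompositionTable
    observed_so: CompositionTable
    real_world_mixtures: CompositionTable


def _block_midpoint_means(
    schema: FeatureSchema, ranges: Mapping[str, tuple[float, float]]
) -> np.ndarray:
    """Range midpoints, renormalized so each block sums to 100 %."""
    mu = np.array(
        [(ranges[n][0] + ranges[n][1]) / 2.0 for n in schema.feature_names]
    )
    for idx in schema.block_slices().values():
        if idx:
            mu[idx] *= 100.0 / mu[idx].sum()
    return mu


def build_ground_truth(spec: GroundTruthSpec) -> dict[str, ClassDistribution]:
    """Construct the per-class ground-truth Gaussians.

    mu: block-renormalized range midpoints.  Sigma: one-factor
    correlation (off-diagonal rho) scaled by cv-proportional standard
    deviations, then closed within each block with M = I - w 1^T
    (w = sd / sum(sd) over the block) so block sums are invariant under
    sampling.  The closure makes Sigma singular by construction,
    matching the rank deficiency of real percent-of-total covariance
    matrices.
    """
    k = spec.schema.n_features
    R = np.full((k, k), spec.rho)
    np.fill_diagonal(R, 1.0)

    out = {}
    for label, ranges in spec.ranges.items():
        mu = _block_midpoint_means(spec.schema, ranges)
        sd = spec.cv * np.maximum(mu, spec.sd_floor)
        half_range = np.array(
            [(ranges[n][1] - ranges[n][0]) / 2.0 for n in spec.schema.feature_names]
        )
        sd = np.minimum(sd, np.maximum(half_range, spec.sd_floor))
        C = (sd[:, None] * R) * sd[None, :]
        # sd-weighted closure projector, block-diagonal
        M = np.eye(k)
        for idx in spec.schema.block_slices().values():
            if not idx:
                continue
            idx = np.asarray(idx)
            w = sd[idx] / sd[idx].sum()
            M[np.ix_(idx, idx)] -= np.outer(w, np.ones(len(idx)))
        sigma = M @ C @ M.T
        out[label] = ClassDistribution(label, mu, (sigma + sigma.T) / 2.0)
    return out


def sample_observed(
    dist: ClassDistribution,
    schema: FeatureSchema,
    n: int,
    seed: int,
    id_prefix: Optional[str] = None,
) -> CompositionTable:
    """Emulate ``n`` measured samples of one pure oil.

    Monte-Carlo draws with non-negativity clipping (real compositions
    cannot be negative), labeled and numbered like the study's samples
    (CO1 ... CO27, SO1 ... SO10).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    sim = mc_sample(dist, n, seed, clip_nonnegative=True)
    prefix = id_prefix if id_prefix is not None else dist.label
    samples = [
        CompositionSample.from_values(f"{prefix}{i + 1}", dist.label, row)
        for i, row in enumerate(sim.data)
    ]
    return CompositionTable(schema, samples)


def _largest_remainder_counts(n_total: int, n_parts: int) -> list[int]:
    base, rem = divmod(n_total, n_parts)
    counts = [base] * n_parts
    for i in range(rem):
        counts[i] += 1
    return counts


def make_real_world_mixtures(
    co_table: CompositionTable,
    so_table: CompositionTable,
    ratios: Sequence[float] = DEFAULT_RATIOS,
    n_total: int = N_REAL_WORLD,
    seed: int = 0,
) -> CompositionTable:
    """Emulate physically prepared adulterated samples.

    Each output row blends one randomly chosen CO sample with one
    randomly chosen SO sample at one of the given mass-fraction ratios;
    every ratio is represented, with row counts split by largest
    remainder.  Rows are labeled by ratio class (e.g. ``"95:5"``).
    """
    if len(co_table) == 0 or len(so_table) == 0:
        raise ValueError("input tables must be non-empty")
    if co_table.schema.feature_names != so_table.schema.feature_names:
        raise ValueError("tables must share a schema")
    if not all(0.0 < r < 1.0 for r in ratios):
        raise ValueError("ratios must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    co_m, so_m = co_table.matrix(), so_table.matrix()
    counts = _largest_remainder_counts(n_total, len(ratios))
    samples = []
    i_out = 0
    for r, cnt in zip(ratios, counts):
        for _ in range(cnt):
            ci = rng.integers(len(co_table))
            si = rng.integers(len(so_table))
            row = blend_rows(co_m[ci], so_m[si], r)
            i_out += 1
            samples.append(
                CompositionSample.from_values(f"MIX{i_out}", ratio_label(r), row)
            )
    return CompositionTable(co_table.schema, samples)


def make_fixture_bundle(spec: Optional[GroundTruthSpec] = None) -> FixtureBundle:
    """Build the full fixture bundle from one spec (default study design)."""
    spec = spec or GroundTruthSpec()
    gt = build_ground_truth(spec)
    obs_co = sample_observed(
        gt[CO_LABEL], spec.schema, N_OBSERVED_CO, seed=spec.seed
    )
    obs_so = sample_observed(
        gt[SO_LABEL], spec.schema, N_OBSERVED_SO, seed=spec.seed + 1
    )
    mixtures = make_real_world_mixtures(
        obs_co, obs_so, DEFAULT_RATIOS, N_REAL_WORLD, seed=spec.seed + 2
    )
    return FixtureBundle(spec.schema, spec, gt, obs_co, obs_so, mixtures)


def save_bundle(bundle: FixtureBundle, outdir: str | Path) -> dict:
    """Write the bundle as CSVs plus a JSON manifest of ground truth.

    The manifest records the true means and covariances so that
    parameter-recovery tests (and users) can compare fitted models
    against the generating truth.  Returns the manifest dict.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_composition_table(bundle.observed_co, outdir / "observed_co.csv")
    write_composition_table(bundle.observed_so, outdir / "observed_so.csv")
    write_composition_table(
        bundle.real_world_mixtures, outdir / "real_world_mixtures.csv"
    )
    bundle.schema.save(outdir / "schema.json")
    manifest = {
        "seed": bundle.spec.seed,
        "rho": bundle.spec.rho,
        "cv": bundle.spec.cv,
        "sd_floor": bundle.spec.sd_floor,
        "classes": {
            label: {
                "mu": d.mu.tolist(),
                "sigma": d.sigma.tolist(),
            }
            for label, d in bundle.ground_truth.items()
        },
        "files": {
            "observed_co": "observed_co.csv",
            "observed_so": "observed_so.csv",
            "real_world_mixtures": "real_world_mixtures.csv",
            "schema": "schema.json",
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
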