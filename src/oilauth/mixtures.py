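"""Weighted-sum mixture synthesis: the 7-class training corpus.

Adulteration of an expensive oil (CO) with a cheap one (SO) at mass
fraction r is modeled feature-wise as the linear blend

    mixture = (1 - r) * CO + r * SO,

applied directly to the percentage features.  The default design covers
pure CO, pure SO and five low adulteration levels (1, 3, 5, 7, 9 %),
giving seven classes with equal numbers of simulated samples each.

Mixture rows are built from *fresh*, index-paired, independent
Monte-Carlo draws of the two pure-oil distributions, so the ratio-r
class has mean (1-r) mu_CO + r mu_SO and covariance
(1-r)^2 Sigma_CO + r^2 Sigma_SO.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .generators import ClassDistribution, LabeledSimDataset, mc_sample

DEFAULT_RATIOS = (0.01, 0.03, 0.05, 0.07, 0.09)

CO_LABEL = "CO"
SO_LABEL = "SO"


def ratio_label(ratio: float) -> str:
    """Class label for an adulteration fraction, e.g. 0.05 -> '95:5'."""
    pct = 100.0 * ratio
    if abs(pct - round(pct)) < 1e-9:
        pct_str = str(int(round(pct)))
        co_str = str(int(round(100 - pct)))
    else:
        pct_str = f"{pct:g}"
        co_str = f"{100 - pct:g}"
    return f"{co_str}:{pct_str}"


@dataclass(frozen=True)
class MixtureDesign:
    """Class layout of the training corpus.

    ``ratios`` are the adulteration mass fractions, strictly increasing
    in (0, 1); the class list is pure CO, one class per ratio, pure SO —
    the natural low-to-high adulteration reading order.
    """

    ratios: tuple[float, ...] = DEFAULT_RATIOS
    n_per_class: int = 1000

    def __post_init__(self):
        r = self.ratios
        if not r:
            raise ValueError("need at least one ratio")
        if any(not (0.0 < x < 1.0) for x in r):
            raise ValueError("ratios must lie strictly between 0 and 1")
        if any(b <= a for a, b in zip(r, r[1:])):
            raise ValueError("ratios must be strictly increasing with no duplicates")
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        object.__setattr__(self, "ratios", tuple(float(x) for x in r))

    @property
    def class_labels(self) -> tuple[str, ...]:
        return (CO_LABEL, *[ratio_label(r) for r in self.ratios], SO_LABEL)

    @property
    def n_classes(self) -> int:
        return len(self.ratios) + 2

    def ratio_percent_of(self) -> dict[str, float]:
        """Adulteration % per class: pure CO = 0, pure SO = 100."""
        out = {CO_LABEL: 0.0, SO_LABEL: 100.0}
        out.update({ratio_label(r): 100.0 * r for r in self.ratios})
        return out


def blend_rows(
    co_row: np.ndarray, so_row: np.ndarray, ratio: float
) -> np.ndarray:
    """Element-wise weighted sum (1-ratio)*co + ratio*so."""
    co = np.asarray(co_row, dtype=float)
    so = np.asarray(so_row, dtype=float)
    if co.shape != so.shape:
        raise ValueError(f"shape mismatch: {co.shape} vs {so.shape}")
    if not (0.0 <= ratio <= 1.0):
        raise ValueError("ratio must be in [0, 1]")
    return (1.0 - ratio) * co + ratio * so


def build_training_corpus(
    co_dist: ClassDistribution,
    so_dist: ClassDistribution,
    design: MixtureDesign,
    seed: int,
    clip_nonnegative: bool = False,
) -> list[LabeledSimDataset]:
    """Simulate the full labeled corpus of the mixture design.

    Emits one dataset per class, in ``design.class_labels`` order, each
    with exactly ``design.n_per_class`` rows.  The pure classes are
    direct Monte-Carlo draws; each mixture class blends fresh CO and SO
    draws one-to-one by index.  Deterministic given ``seed``.
    """
    if co_dist.k != so_dist.k:
        raise ValueError("CO and SO distributions must share dimension")
    n = design.n_per_class
    datasets = []
    sub = lambda i: (seed + 7919 * i) % (2**31)  # noqa: E731 - per-class seed stream

    pure_co = mc_sample(co_dist, n, sub(0), clip_nonnegative)
    datasets.append(LabeledSimDataset(CO_LABEL, pure_co.data, pure_co.generator_tag, sub(0)))
    for i, r in enumerate(design.ratios):
        co_draw = mc_sample(co_dist, n, sub(2 * i + 1), clip_nonnegative)
        so_draw = mc_sample(so_dist, n, sub(2 * i + 2), clip_nonnegative)
        blended = blend_rows(co_draw.data, so_draw.data, r)
        datasets.append(
            LabeledSimDataset(ratio_label(r), blended, "mc-blend", sub(2 * i + 1))
        )
    last = sub(2 * len(design.ratios) + 1)
    pure_so = mc_sample(so_dist, n, last, clip_nonnegative)
    datasets.append(LabeledSimDataset(SO_LABEL, pure_so.data, pure_so.generator_tag, last))
    return datasets
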