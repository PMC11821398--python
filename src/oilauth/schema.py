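"""Feature schema for oil-composition tables.

An oil sample is described by three blocks of compositional features,
each expressed as a percentage of its block total:

* ``FA``   — fatty acids, % of total fatty acids (GC-FID of methyl esters),
* ``TAG``  — triacylglycerols, % of total TAG peak area (GC-FID),
* ``TOCO`` — tocochromanols, % of total tocochromanol content (HPLC-FLD).

The schema fixes the order and block membership of every feature; it is
the coordinate system shared by tables, fitted distributions, simulated
datasets and classifiers.  The default configuration carries 37 features.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

BLOCKS = ("FA", "TAG", "TOCO")

#: Columns that are metadata, not features, in a composition CSV.
ID_COLUMN = "sample_id"
LABEL_COLUMN = "class_label"
REPLICATE_COLUMN = "replicate_id"
META_COLUMNS = (ID_COLUMN, LABEL_COLUMN, REPLICATE_COLUMN)


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered feature vocabulary with block assignment.

    Parameters
    ----------
    feature_names
        Unique, non-empty identifiers, in column order.
    block_of
        Map feature name -> block, one of :data:`BLOCKS`.
    """

    feature_names: tuple[str, ...]
    block_of: Mapping[str, str] = field(repr=False)

    def __init__(self, feature_names: Sequence[str], block_of: Mapping[str, str]):
        names = tuple(feature_names)
        if len(names) != len(set(names)):
            raise ValueError("feature names must be unique")
        if any(not n for n in names):
            raise ValueError("feature names must be non-empty")
        missing = [n for n in names if n not in block_of]
        if missing:
            raise ValueError(f"features without block assignment: {missing}")
        bad = {n: b for n, b in block_of.items() if b not in BLOCKS}
        if bad:
            raise ValueError(f"unknown blocks {bad}; expected one of {BLOCKS}")
        object.__setattr__(self, "feature_names", names)
        object.__setattr__(self, "block_of", dict(block_of))

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def features_in_block(self, block: str) -> list[str]:
        return [n for n in self.feature_names if self.block_of[n] == block]

    def block_slices(self) -> dict[str, list[int]]:
        """Indices of each block's features, in schema order."""
        out: dict[str, list[int]] = {b: [] for b in BLOCKS}
        for i, name in enumerate(self.feature_names):
            out[self.block_of[name]].append(i)
        return out

    def index_of(self, name: str) -> int:
        try:
            return self.feature_names.index(name)
        except ValueError:
            raise KeyError(f"unknown feature {name!r}") from None

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "features": [
                {"name": n, "block": self.block_of[n]} for n in self.feature_names
            ]
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "FeatureSchema":
        feats = d["features"]
        return cls(
            [f["name"] for f in feats], {f["name"]: f["block"] for f in feats}
        )

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=1)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict(), sort_keys=False)
        )
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "FeatureSchema":
        path = Path(path)
        text = path.read_text()
        d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(d)
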