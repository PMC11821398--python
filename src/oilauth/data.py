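"""Composition tables: read/write/validate CSV data and preprocessing.

A table holds one row per (sample, replicate) with a value for every
schema feature.  Individual entries may instead carry a *flag*: the
measurement was below the limit of quantification (LOQ) or the analyte
was not detected (ND).  Flags are preserved losslessly through I/O and
only converted to zero at replicate-averaging time, which is the
preprocessing step used before any distribution fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .schema import (
    FeatureSchema,
    ID_COLUMN,
    LABEL_COLUMN,
    META_COLUMNS,
    REPLICATE_COLUMN,
)

#: Cell tokens interpreted as below-LOQ / not-detected.
DEFAULT_FLAG_TOKENS = ("ND", "<LOQ", "")
#: Token used when writing flagged entries back to CSV.
DEFAULT_FLAG_OUT = "ND"


class SchemaMismatchError(ValueError):
    """CSV columns do not match the expected feature schema."""


class TableParseError(ValueError):
    """A cell could not be parsed as a number or known flag."""


@dataclass(frozen=True)
class CompositionSample:
    """One measured row: id, class label, optional replicate, feature values.

    ``values`` holds NaN where ``flags`` carries a token; all unflagged
    values must be non-negative percentages.
    """

    sample_id: str
    class_label: str
    values: np.ndarray
    flags: tuple[Optional[str], ...]
    replicate_id: Optional[str] = None

    def __post_init__(self):
        object.__setattr__(
            self, "values", np.asarray(self.values, dtype=float)
        )
        if self.values.ndim != 1:
            raise ValueError("values must be a 1-D vector")
        if len(self.flags) != self.values.size:
            raise ValueError("flags length must equal values length")

    @classmethod
    def from_values(
        cls,
        sample_id: str,
        class_label: str,
        values: Sequence[float],
        replicate_id: Optional[str] = None,
    ) -> "CompositionSample":
        vals = np.asarray(values, dtype=float)
        return cls(sample_id, class_label, vals, (None,) * vals.size, replicate_id)


@dataclass
class CompositionTable:
    """Labeled samples x features matrix sharing one schema."""

    schema: FeatureSchema
    samples: list[CompositionSample] = field(default_factory=list)

    def __post_init__(self):
        k = self.schema.n_features
        seen = set()
        for s in self.samples:
            if s.values.size != k:
                raise ValueError(
                    f"sample {s.sample_id!r} has {s.values.size} values, "
                    f"schema expects {k}"
                )
            key = (s.sample_id, s.replicate_id)
            if key in seen:
                raise ValueError(f"duplicate sample/replicate pair {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def has_flags(self) -> bool:
        return any(f is not None for s in self.samples for f in s.flags)

    def matrix(self) -> np.ndarray:
        """n x k float matrix; flagged entries are NaN."""
        if not self.samples:
            return np.empty((0, self.schema.n_features))
        return np.vstack([s.values for s in self.samples])

    def labels(self) -> list[str]:
        return [s.class_label for s in self.samples]

    def subset(self, label: str) -> "CompositionTable":
        return CompositionTable(
            self.schema, [s for s in self.samples if s.class_label == label]
        )

    def to_dataframe(self, flag_token: str = DEFAULT_FLAG_OUT) -> pd.DataFrame:
        rows = []
        for s in self.samples:
            row: dict = {ID_COLUMN: s.sample_id, LABEL_COLUMN: s.class_label}
            if s.replicate_id is not None:
                row[REPLICATE_COLUMN] = s.replicate_id
            for name, v, fl in zip(self.schema.feature_names, s.values, s.flags):
                row[name] = flag_token if fl is not None else v
            rows.append(row)
        cols = [ID_COLUMN, LABEL_COLUMN]
        if any(s.replicate_id is not None for s in self.samples):
            cols.append(REPLICATE_COLUMN)
        cols += list(self.schema.feature_names)
        return pd.DataFrame(rows, columns=cols)


@dataclass(frozen=True)
class ValidationIssue:
    sample_id: str
    rule: str
    detail: str


@dataclass(frozen=True)
class ValidationReport:
    issues: tuple[ValidationIssue, ...]

    @property
    def passed(self) -> bool:
        return not self.issues


def read_composition_table(
    path: str | Path,
    schema: FeatureSchema,
    flag_tokens: Iterable[str] = DEFAULT_FLAG_TOKENS,
) -> CompositionTable:
    """Read a CSV composition table against ``schema``.

    The file must contain ``sample_id``, ``class_label``, optionally
    ``replicate_id``, and exactly the schema's feature columns.  Cells
    equal to one of ``flag_tokens`` become flagged (below-LOQ / ND)
    entries; everything else must parse as a number.
    """
    path = Path(path)
    tokens = set(flag_tokens)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    cols = set(df.columns)
    missing = [n for n in schema.feature_names if n not in cols]
    if missing:
        raise SchemaMismatchError(f"missing feature column(s): {missing}")
    unknown = [
        c for c in df.columns if c not in schema.feature_names and c not in META_COLUMNS
    ]
    if unknown:
        raise SchemaMismatchError(f"unknown column(s): {unknown}")
    for meta in (ID_COLUMN, LABEL_COLUMN):
        if meta not in cols:
            raise SchemaMismatchError(f"missing required column {meta!r}")
    has_rep = REPLICATE_COLUMN in cols

    samples = []
    for i, row in df.iterrows():
        values = np.empty(schema.n_features)
        flags: list[Optional[str]] = []
        for j, name in enumerate(schema.feature_names):
            cell = row[name].strip()
            if cell in tokens:
                values[j] = np.nan
                flags.append(cell if cell else DEFAULT_FLAG_OUT)
                continue
            try:
                values[j] = float(cell)
            except ValueError:
                raise TableParseError(
                    f"row {i}, column {name!r}: cannot parse {cell!r}"
                ) from None
            flags.append(None)
        rep = row[REPLICATE_COLUMN] if has_rep else None
        rep = rep if rep not in (None, "") else None
        samples.append(
            CompositionSample(
                row[ID_COLUMN], row[LABEL_COLUMN], values, tuple(flags), rep
            )
        )
    return CompositionTable(schema, samples)


def write_composition_table(
    table: CompositionTable,
    path: str | Path,
    flag_token: str = DEFAULT_FLAG_OUT,
) -> None:
    """Write a table as CSV, round-trippable by :func:`read_composition_table`.

    Numeric cells are written with Python ``repr`` (shortest string that
    parses back to the same float), so write-then-read reproduces the
    table exactly.
    """
    df = table.to_dataframe(flag_token=flag_token)
    for col in table.schema.feature_names:
        df[col] = df[col].map(lambda v: v if isinstance(v, str) else repr(float(v)))
    df.to_csv(path, index=False)


def validate_table(
    table: CompositionTable, block_sum_tolerance: float = 5.0
) -> ValidationReport:
    """Report structural issues: negative values and open block sums.

    Each compositional block should sum to ~100 % within a sample;
    deviations beyond ``block_sum_tolerance`` percentage points are
    reported.  Flagged entries count as 0 toward block sums and are
    exempt from the negativity rule.  Report-only: never raises.
    """
    issues: list[ValidationIssue] = []
    blocks = table.schema.block_slices()
    for s in table.samples:
        for name, v, fl in zip(table.schema.feature_names, s.values, s.flags):
            if fl is None and v < 0:
                issues.append(
                    ValidationIssue(s.sample_id, "negative-value", f"{name} = {v}")
                )
        for block, idx in blocks.items():
            if not idx:
                continue
            total = np.nansum(s.values[idx])
            if abs(total - 100.0) > block_sum_tolerance:
                issues.append(
                    ValidationIssue(
                        s.sample_id,
                        "block-sum",
                        f"{block} block sums to {total:.4g}, expected 100 "
                        f"+/- {block_sum_tolerance}",
                    )
                )
    return ValidationReport(tuple(issues))


def average_replicates(table: CompositionTable) -> CompositionTable:
    """Collapse replicates to one row per sample_id by arithmetic mean.

    Flagged (below-LOQ / not-detected) entries are replaced by zero
    before averaging, mirroring routine practice for compositional
    reporting.  Class labels must agree across a sample's replicates.
    Idempotent: a table without replicates passes through with flags
    zeroed.
    """
    order: list[str] = []
    groups: dict[str, list[CompositionSample]] = {}
    for s in table.samples:
        if s.sample_id not in groups:
            order.append(s.sample_id)
            groups[s.sample_id] = []
        groups[s.sample_id].append(s)

    out = []
    k = table.schema.n_features
    for sid in order:
        reps = groups[sid]
        labels = {s.class_label for s in reps}
        if len(labels) > 1:
            raise ValueError(
                f"sample {sid!r} has conflicting class labels {sorted(labels)}"
            )
        vals = np.vstack([np.nan_to_num(s.values, nan=0.0) for s in reps])
        out.append(
            CompositionSample(
                sid, reps[0].class_label, vals.mean(axis=0), (None,) * k, None
            )
        )
    return CompositionTable(table.schema, out)
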