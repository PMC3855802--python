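"""Record filtering, manual discretisation and explicit missing-state encoding.

The pre-processing mirrors how national audit registries are prepared for
categorical modelling: drop records by configurable exclusion rules (e.g. a
diagnosis outside the study population, a vanishingly rare treatment, or a
null outcome), bin the few continuous fields at clinically meaningful
cut-points, and replace every remaining null with an explicit
``"Unknown/Missing"`` category while recording the original nullness in a
mask.  The mask restricted to the predictor columns is the binary *indicator
matrix* used to test whether missingness itself predicts the outcome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .data_model import (
    MISSING_LABEL,
    ConfigurationError,
    Dataset,
    VariableSpec,
)


@dataclass(frozen=True)
class DiscretisationRule:
    """Bin a continuous field into labelled intervals.

    ``cut_points`` are strictly increasing; ``labels`` has one more entry than
    cut_points.  Intervals are left-closed / right-open: a value equal to a
    cut-point falls into the interval starting at that cut-point.
    """

    variable: str
    cut_points: tuple
    labels: tuple

    def __post_init__(self):
        object.__setattr__(self, "cut_points", tuple(float(c) for c in self.cut_points))
        object.__setattr__(self, "labels", tuple(self.labels))
        if list(self.cut_points) != sorted(set(self.cut_points)):
            raise ConfigurationError(f"{self.variable}: cut points must strictly increase")
        if len(self.labels) != len(self.cut_points) + 1:
            raise ConfigurationError(f"{self.variable}: need len(cuts)+1 labels")
        if len(set(self.labels)) != len(self.labels):
            raise ConfigurationError(f"{self.variable}: duplicate labels")


def discretise(value, rule: DiscretisationRule) -> str:
    """Interval label for ``value``; null (None/NaN) maps to the sentinel."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return MISSING_LABEL
    value = float(value)
    if not math.isfinite(value):
        raise ValueError(f"{rule.variable}: non-finite value {value}")
    # right=False: cuts[i-1] <= v < cuts[i]  (left-closed, right-open)
    return rule.labels[int(np.digitize(value, rule.cut_points, right=False))]


def discretise_column(values: Sequence, rule: DiscretisationRule) -> list:
    return [discretise(v, rule) for v in values]


@dataclass(frozen=True)
class ExclusionRule:
    """Drop records by state membership or by nullness of a column.

    ``drop_states`` removes rows whose cell in ``column`` holds one of the
    listed labels; ``drop_null=True`` removes rows whose cell was originally
    null (mask == 0).
    """

    column: str
    drop_states: tuple = ()
    drop_null: bool = False
    name: Optional[str] = None

    def label(self) -> str:
        if self.name:
            return self.name
        if self.drop_null:
            return f"{self.column} is null"
        return f"{self.column} in {list(self.drop_states)}"


def filter_records(raw: Dataset, exclusion_rules: Sequence[ExclusionRule]):
    """Apply exclusion rules; return (filtered dataset, per-rule removal counts).

    A removed row is attributed to the first rule it violates, so the counts
    are disjoint and sum to the number of rows dropped.
    """
    removed = np.zeros(raw.n, dtype=bool)
    counts = {}
    for rule in exclusion_rules:
        j = raw.index(rule.column)  # ConfigurationError on unknown column
        spec = raw.variables[j]
        hit = np.zeros(raw.n, dtype=bool)
        if rule.drop_states:
            drop_idx = [spec.index_of(s) for s in rule.drop_states]
            hit |= np.isin(raw.records[:, j], drop_idx)
        if rule.drop_null:
            hit |= raw.mask[:, j] == 0
        fresh = hit & ~removed
        counts[rule.label()] = int(fresh.sum())
        removed |= hit
    keep = ~removed
    if not keep.any():
        raise ValueError("all records removed by exclusion rules")
    return raw.subset(np.flatnonzero(keep)), counts


def encode_missing(frame: pd.DataFrame, specs: Sequence[VariableSpec]) -> Dataset:
    """Encode a label-valued DataFrame into a Dataset, replacing nulls with the
    explicit sentinel state.

    ``specs`` describe the non-sentinel state spaces; the sentinel is appended
    (and ``has_missing_state`` flagged) only for columns that actually contain
    nulls — fully observed columns keep their spec unchanged.
    """
    specs = list(specs)
    if list(frame.columns) != [s.name for s in specs]:
        raise ConfigurationError("frame columns must match specs, in order")
    out_specs, columns, mask_cols = [], [], []
    for s in specs:
        col = frame[s.name]
        null = col.isna().to_numpy()
        if null.any() and not s.has_missing_state:
            s = s.with_missing_state()
        out_specs.append(s)
        lookup = {lab: i for i, lab in enumerate(s.states)}
        enc = np.empty(len(frame), dtype=np.int64)
        for i, (v, isnull) in enumerate(zip(col.to_numpy(), null)):
            if isnull:
                enc[i] = s.missing_index
            else:
                try:
                    enc[i] = lookup[v]
                except KeyError:
                    raise ConfigurationError(
                        f"{s.name}: unknown state {v!r}"
                    ) from None
        columns.append(enc)
        mask_cols.append((~null).astype(np.int8))
    return Dataset(out_specs, np.column_stack(columns), np.column_stack(mask_cols))


def indicator_matrix(data: Dataset, outcome: str) -> Dataset:
    """Binary observed/missing dataset over the predictor columns, with the
    outcome column passed through unchanged.

    Each predictor becomes a two-state variable ("Missing", "Observed") whose
    value is the original mask entry.  The outcome must be fully observed.
    """
    j_out = data.index(outcome)
    if (data.mask[:, j_out] == 0).any():
        raise ValueError("outcome column contains nulls; filter records first")
    specs, cols = [], []
    for j, v in enumerate(data.variables):
        if j == j_out:
            specs.append(v)
            cols.append(data.records[:, j])
        else:
            specs.append(
                VariableSpec(v.name, ("Missing", "Observed"), False, v.tier)
            )
            cols.append(data.mask[:, j].astype(np.int64))
    return Dataset(specs, np.column_stack(cols))
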