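"""Expression normalisation and repeat-family aggregation.

Counts are normalised to counts-per-million (CPM, library-size scaling) or
transcripts-per-million (TPM, length-rate scaling); both make every sample
column sum to 1e6.  Repeat transcripts are then summed to TE-type or
TE-class level *in linear units* -- abundances add, log abundances do not --
and only afterwards log-transformed for display (log10(1 + CPM) by
convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import (
    ExpressionMatrix,
    TEAnnotation,
    ValidationError,
    LOG_UNITS,
)

logger = logging.getLogger("retroscope")

SCALE = 1e6


def to_cpm(m: ExpressionMatrix) -> ExpressionMatrix:
    """Counts per million: cpm[f, s] = count[f, s] / libsize[s] * 1e6."""
    if m.unit != "count":
        raise ValidationError(f"to_cpm expects unit=count, got {m.unit}")
    lib = m.values.sum(axis=0)
    zero = lib[lib == 0]
    if len(zero):
        raise ValidationError(f"zero library size for samples: {list(zero.index)}")
    return ExpressionMatrix(m.values / lib * SCALE, unit="CPM")


def to_tpm(m: ExpressionMatrix, ann: TEAnnotation) -> ExpressionMatrix:
    """Transcripts per million: length-normalised read rates rescaled so each
    sample sums to 1e6."""
    if m.unit != "count":
        raise ValidationError(f"to_tpm expects unit=count, got {m.unit}")
    lengths = ann.lengths()
    missing = [f for f in m.feature_ids if f not in lengths.index]
    if missing:
        raise ValidationError(f"features lacking effective_length: {missing}")
    rate = m.values.div(lengths.loc[m.feature_ids].to_numpy(), axis=0)
    denom = rate.sum(axis=0)
    zero = denom[denom == 0]
    if len(zero):
        raise ValidationError(f"zero total rate for samples: {list(zero.index)}")
    return ExpressionMatrix(rate / denom * SCALE, unit="TPM")


def log_transform(m: ExpressionMatrix, base: float = 10.0,
                  pseudocount: float = 1.0) -> ExpressionMatrix:
    """value -> log_base(pseudocount + value); tags the unit as a log unit."""
    if m.unit in LOG_UNITS:
        raise ValidationError(f"matrix already log-transformed (unit={m.unit})")
    if m.unit == "count":
        raise ValidationError("log_transform expects CPM or TPM, not raw counts")
    out = np.log(pseudocount + m.values) / np.log(base)
    return ExpressionMatrix(out, unit="log" + m.unit, log_base=float(base),
                            pseudocount=float(pseudocount))


def inverse_log_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """Invert :func:`log_transform` (used for round-trip checking)."""
    if m.unit not in LOG_UNITS:
        raise ValidationError(f"matrix is not log-transformed (unit={m.unit})")
    lin = np.power(m.log_base, m.values) - (m.pseudocount or 0.0)
    return ExpressionMatrix(lin.clip(lower=0), unit=m.unit[3:])


@dataclass
class AggregatedTEMatrix:
    """TE types (or classes) x samples abundance matrix.

    ``level`` records whether rows are TE types or TE classes;
    ``parent_map`` carries the type -> class taxonomy used.
    """

    values: pd.DataFrame
    unit: str
    level: str  # "type" | "class"
    parent_map: dict[str, str]
    log_base: float | None = None
    pseudocount: float | None = None

    def __post_init__(self) -> None:
        if self.level not in ("type", "class"):
            raise ValidationError(f"level must be 'type' or 'class', got {self.level!r}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def log_transform(self, base: float = 10.0,
                      pseudocount: float = 1.0) -> "AggregatedTEMatrix":
        if self.unit in LOG_UNITS:
            raise ValidationError("already log-transformed")
        out = np.log(pseudocount + self.values) / np.log(base)
        return AggregatedTEMatrix(out, "log" + self.unit, self.level,
                                  self.parent_map, float(base), float(pseudocount))

    def to_frame(self) -> pd.DataFrame:
        out = self.values.copy()
        if self.level == "type":
            out.insert(0, "te_class", [self.parent_map[t] for t in out.index])
            out.insert(0, "te_type", out.index)
        else:
            out.insert(0, "te_class", out.index)
        return out.reset_index(drop=True)


def aggregate_te(m: ExpressionMatrix, ann: TEAnnotation,
                 level: str = "type") -> AggregatedTEMatrix:
    """Sum repeat-transcript abundance to TE-type or TE-class rows.

    Requires a linear unit (CPM/TPM): aggregation happens before any log
    transform.  Coding and unannotated features are excluded; exclusions are
    logged, never silent.
    """
    if m.unit in LOG_UNITS:
        raise ValidationError("aggregate in linear units (CPM/TPM) before log transform")
    if level not in ("type", "class"):
        raise ValidationError(f"level must be 'type' or 'class', got {level!r}")
    rep = ann.repeat_features().set_index("feature_id")
    members = [f for f in m.feature_ids if f in rep.index]
    excluded = len(m.feature_ids) - len(members)
    if excluded:
        logger.info("aggregate_te: excluding %d non-repeat/unannotated features", excluded)
    parent_map = ann.type_to_class()
    key_col = "te_type" if level == "type" else "te_class"
    keys = rep.loc[members, key_col]
    agg = m.values.loc[members].groupby(keys.to_numpy()).sum()
    agg = agg.sort_index()
    return AggregatedTEMatrix(agg, m.unit, level, parent_map)


def classes_from_types(types: AggregatedTEMatrix) -> AggregatedTEMatrix:
    """Roll a type-level aggregate up to class level via its parent_map."""
    if types.level != "type":
        raise ValidationError("expected a type-level aggregate")
    missing = [t for t in types.values.index if t not in types.parent_map]
    if missing:
        raise ValidationError(f"te_types missing from parent_map: {missing}")
    keys = [types.parent_map[t] for t in types.values.index]
    agg = types.values.groupby(np.asarray(keys)).sum().sort_index()
    return AggregatedTEMatrix(agg, types.unit, "class", types.parent_map,
                              types.log_base, types.pseudocount)


def write_aggregated(agg: AggregatedTEMatrix, path) -> None:
    agg.to_frame().to_csv(path, sep="\t", index=False)
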