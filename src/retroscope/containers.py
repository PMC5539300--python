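"""Core in-memory containers shared by every analysis stage.

An :class:`ExpressionMatrix` is a features x samples table tagged with the
unit it carries (raw counts, CPM, TPM, or a log transform thereof), so that
downstream operations can refuse inputs on the wrong scale.  The remaining
containers hold sample metadata (group and patient pairing), the two-level
transposable-element taxonomy (type within class), and named gene sets.

All containers validate their invariants on construction and raise
:class:`ValidationError` with an explicit message naming the offending
entries -- there are no silent drops anywhere in the pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("retroscope")

#: Units an ExpressionMatrix may carry.
UNITS = ("count", "CPM", "TPM", "logCPM", "logTPM")
LOG_UNITS = ("logCPM", "logTPM")

REPEAT = "repeat"
CODING = "coding"


class ValidationError(ValueError):
    """An input violated a container invariant."""


def _duplicates(items) -> list:
    s = pd.Series(list(items))
    return sorted(s[s.duplicated()].unique().tolist())


@dataclass
class ExpressionMatrix:
    """Features x samples expression values with an explicit unit tag.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows are features, columns are samples.
    unit : str
        One of ``count``, ``CPM``, ``TPM``, ``logCPM``, ``logTPM``.
    log_base : float, optional
        Base of the log transform for log units (2 or 10).
    pseudocount : float, optional
        Pseudocount used by the log transform, recorded for invertibility.
    """

    values: pd.DataFrame
    unit: str = "count"
    log_base: float | None = None
    pseudocount: float | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        if self.unit not in UNITS:
            raise ValidationError(f"unknown unit {self.unit!r}; expected one of {UNITS}")
        dup_f = _duplicates(self.values.index)
        if dup_f:
            raise ValidationError(f"duplicate feature IDs: {dup_f}")
        dup_s = _duplicates(self.values.columns)
        if dup_s:
            raise ValidationError(f"duplicate sample IDs: {dup_s}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("expression values must be numeric")
        if np.isnan(arr).any():
            raise ValidationError("expression values contain NaN")
        if self.unit not in LOG_UNITS and (arr < 0).any():
            r, c = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative value at feature {self.values.index[r]!r}, "
                f"sample {self.values.columns[c]!r} (unit={self.unit})"
            )
        if self.unit in LOG_UNITS and self.log_base is None:
            self.log_base = 10.0

    # -- convenience -----------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_features(self, ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(ids)], self.unit,
                                self.log_base, self.pseudocount)

    def subset_samples(self, ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[list(ids)], self.unit,
                                self.log_base, self.pseudocount)


@dataclass
class SampleMetadata:
    """Per-sample design information: group label and patient pairing key."""

    table: pd.DataFrame  # columns: sample_id, group, patient_id

    REQUIRED = ("sample_id", "group", "patient_id")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValidationError(f"sample metadata missing columns: {missing}")
        t = self.table.copy()
        t["sample_id"] = t["sample_id"].astype(str)
        t["group"] = t["group"].astype(str)
        t["patient_id"] = t["patient_id"].fillna("").astype(str)
        dup = _duplicates(t["sample_id"])
        if dup:
            raise ValidationError(f"duplicate sample IDs in metadata: {dup}")
        paired = t[t["patient_id"] != ""]
        dup_pg = paired[paired.duplicated(["patient_id", "group"], keep=False)]
        if len(dup_pg):
            pairs = sorted(set(map(tuple, dup_pg[["patient_id", "group"]].values)))
            raise ValidationError(f"(patient_id, group) pairs occur more than once: {pairs}")
        self.table = t.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def groups(self) -> list[str]:
        return sorted(self.table["group"].unique())

    def samples_in_group(self, group: str) -> list[str]:
        return list(self.table.loc[self.table["group"] == group, "sample_id"])

    def group_of(self) -> pd.Series:
        return self.table.set_index("sample_id")["group"]

    def patient_of(self) -> pd.Series:
        return self.table.set_index("sample_id")["patient_id"]


@dataclass
class TEAnnotation:
    """Feature annotation: repeat transcripts carry a (TE type, TE class)
    pair from a two-level taxonomy; coding features carry a gene symbol.
    Every feature used for TPM carries a positive effective length in bases.
    """

    table: pd.DataFrame  # feature_id, kind, te_type, te_class, gene_symbol, effective_length

    COLUMNS = ("feature_id", "kind", "te_type", "te_class", "gene_symbol", "effective_length")

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.table.columns]
        if missing:
            raise ValidationError(f"annotation missing columns: {missing}")
        t = self.table.copy()
        for c in ("feature_id", "kind", "te_type", "te_class", "gene_symbol"):
            t[c] = t[c].fillna("").astype(str)
        dup = _duplicates(t["feature_id"])
        if dup:
            raise ValidationError(f"duplicate feature IDs in annotation: {dup}")
        bad_kind = sorted(set(t["kind"]) - {REPEAT, CODING})
        if bad_kind:
            raise ValidationError(f"unknown feature kinds: {bad_kind}")
        rep = t[t["kind"] == REPEAT]
        if ((rep["te_type"] == "") | (rep["te_class"] == "")).any():
            bad = rep.loc[(rep["te_type"] == "") | (rep["te_class"] == ""), "feature_id"]
            raise ValidationError(f"repeat features lacking te_type/te_class: {sorted(bad)}")
        cod = t[t["kind"] == CODING]
        if (cod["gene_symbol"] == "").any():
            bad = cod.loc[cod["gene_symbol"] == "", "feature_id"]
            raise ValidationError(f"coding features lacking gene_symbol: {sorted(bad)}")
        lengths = pd.to_numeric(t["effective_length"], errors="coerce")
        if lengths.isna().any() or (lengths <= 0).any():
            bad = t.loc[lengths.isna() | (lengths <= 0), "feature_id"]
            raise ValidationError(f"non-positive effective_length for: {sorted(bad)}")
        t["effective_length"] = lengths.astype(float)
        # each te_type maps to exactly one te_class
        tmap = rep.groupby("te_type")["te_class"].nunique()
        bad_types = sorted(tmap[tmap > 1].index)
        if bad_types:
            raise ValidationError(
                f"te_type assigned to more than one te_class: {bad_types}")
        self.table = t.reset_index(drop=True)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.table["feature_id"])

    def lookup(self, feature_id: str) -> pd.Series:
        row = self.table[self.table["feature_id"] == feature_id]
        if row.empty:
            raise KeyError(feature_id)
        return row.iloc[0]

    def type_to_class(self) -> dict[str, str]:
        rep = self.table[self.table["kind"] == REPEAT]
        return dict(rep.groupby("te_type")["te_class"].first())

    def repeat_features(self) -> pd.DataFrame:
        return self.table[self.table["kind"] == REPEAT]

    def coding_features(self) -> pd.DataFrame:
        return self.table[self.table["kind"] == CODING]

    def symbol_of(self) -> pd.Series:
        cod = self.coding_features()
        return cod.set_index("feature_id")["gene_symbol"]

    def lengths(self) -> pd.Series:
        return self.table.set_index("feature_id")["effective_length"]

    def unannotated(self, matrix: ExpressionMatrix) -> list[str]:
        """Features of ``matrix`` absent from this annotation (reported, never
        silently dropped)."""
        known = set(self.table["feature_id"])
        return [f for f in matrix.feature_ids if f not in known]


@dataclass
class GeneSetCollection:
    """Named gene sets (MSigDB-style) with per-set provenance strings."""

    sets: dict[str, frozenset[str]] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, frozenset] = {}
        for name, members in self.sets.items():
            members = frozenset(map(str, members))
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")
            clean[name] = members
        self.sets = clean
        for name in self.sets:
            self.provenance.setdefault(name, "")

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)
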