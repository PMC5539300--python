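"""Readers and writers for the external formats the pipeline touches.

Counts travel as features x samples TSV (header row of sample IDs, first
column ``feature_id``) or as MatrixMarket ``.mtx`` with ``features.tsv`` /
``samples.tsv`` sidecars.  Gene sets use the MSigDB GMT interchange format.
Annotation and sample metadata are plain TSV.  All TSVs are tab-separated
UTF-8; lines starting with ``#`` are treated as comments and skipped.

Every reader returns a validated container from :mod:`retroscope.containers`;
read after write is the identity for all of them.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .containers import (
    ExpressionMatrix,
    GeneSetCollection,
    SampleMetadata,
    TEAnnotation,
    ValidationError,
    _duplicates,
)

logger = logging.getLogger("retroscope")

#: Default two-level TE taxonomy shipped with the package.  The full
#: 68-type canonical table is not redistributable; this file covers the
#: types named throughout the analyses (see data/te_taxonomy.tsv header).
DEFAULT_TAXONOMY_PATH = Path(__file__).parent / "data" / "te_taxonomy.tsv"


class ParseError(ValueError):
    """A file could not be parsed; the message carries the location."""


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str,
                       keep_default_na=False, na_values=[])


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def read_counts(path, format: str = "tsv") -> ExpressionMatrix:
    """Read a counts matrix (``tsv`` or ``mtx``) as unit=count.

    For ``mtx``, ``features.tsv`` and ``samples.tsv`` sidecars (one ID per
    line) must sit next to the matrix file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        df = _read_tsv(path)
        if df.columns[0] != "feature_id":
            raise ParseError(
                f"{path}: first column header must be 'feature_id', got {df.columns[0]!r}")
        dup = _duplicates(df["feature_id"])
        if dup:
            raise ValidationError(f"{path}: duplicate feature IDs: {dup}")
        feats = df["feature_id"].tolist()
        body = df.drop(columns="feature_id")
        values = pd.DataFrame(index=feats, columns=body.columns, dtype=float)
        for col in body.columns:
            parsed = pd.to_numeric(body[col], errors="coerce")
            if parsed.isna().any():
                row = int(np.argmax(parsed.isna().to_numpy()))
                raise ParseError(
                    f"{path}: non-numeric count at feature {feats[row]!r}, sample {col!r}")
            if (parsed < 0).any():
                row = int(np.argmax((parsed < 0).to_numpy()))
                raise ParseError(
                    f"{path}: negative count at feature {feats[row]!r}, sample {col!r}")
            values[col] = parsed.to_numpy()
        return ExpressionMatrix(values, unit="count")
    if format == "mtx":
        feats = [l for l in Path(path.parent / "features.tsv").read_text().splitlines() if l]
        samples = [l for l in Path(path.parent / "samples.tsv").read_text().splitlines() if l]
        mat = scipy.io.mmread(path)
        arr = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float)
        if arr.shape != (len(feats), len(samples)):
            raise ParseError(
                f"{path}: matrix shape {arr.shape} does not match sidecars "
                f"({len(feats)} features, {len(samples)} samples)")
        if (arr < 0).any():
            r, c = np.argwhere(arr < 0)[0]
            raise ParseError(f"{path}: negative count at feature {feats[r]!r}, sample {samples[c]!r}")
        return ExpressionMatrix(pd.DataFrame(arr, index=feats, columns=samples), unit="count")
    raise ValueError(f"unknown counts format {format!r}; expected 'tsv' or 'mtx'")


def write_counts(m: ExpressionMatrix, path, format: str = "tsv") -> None:
    """Write an expression matrix; inverse of :func:`read_counts`."""
    path = Path(path)
    if format == "tsv":
        out = m.values.copy()
        out.insert(0, "feature_id", m.feature_ids)
        # integer-valued matrices round-trip bitwise through integer text
        vals = m.values.to_numpy()
        if m.unit == "count" and np.array_equal(vals, np.round(vals)):
            for c in m.sample_ids:
                out[c] = out[c].astype(np.int64)
        out.to_csv(path, sep="\t", index=False)
    elif format == "mtx":
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(m.values.to_numpy()))
        (path.parent / "features.tsv").write_text("\n".join(m.feature_ids) + "\n")
        (path.parent / "samples.tsv").write_text("\n".join(m.sample_ids) + "\n")
    else:
        raise ValueError(f"unknown counts format {format!r}")


# ---------------------------------------------------------------------------
# annotation / metadata
# ---------------------------------------------------------------------------

def read_te_annotation(path) -> TEAnnotation:
    """Read the feature annotation TSV and validate the TE taxonomy
    (each te_type under exactly one te_class, positive effective lengths)."""
    df = _read_tsv(path)
    return TEAnnotation(df)


def write_te_annotation(ann: TEAnnotation, path) -> None:
    out = ann.table.copy()
    out["effective_length"] = out["effective_length"].map(
        lambda x: f"{int(x)}" if float(x).is_integer() else repr(float(x)))
    out.to_csv(path, sep="\t", index=False)


def default_te_annotation() -> TEAnnotation:
    """The packaged default two-level TE taxonomy as a (length-less=1bp
    placeholder) annotation table of one pseudo-feature per TE type."""
    tax = read_te_taxonomy(DEFAULT_TAXONOMY_PATH)
    rows = [{"feature_id": t, "kind": "repeat", "te_type": t, "te_class": c,
             "gene_symbol": "", "effective_length": 1.0}
            for t, c in tax.items()]
    return TEAnnotation(pd.DataFrame(rows))


def read_te_taxonomy(path=DEFAULT_TAXONOMY_PATH) -> dict[str, str]:
    """Read a two-column te_type -> te_class table; rejects a type mapped to
    two classes."""
    df = _read_tsv(path)
    if list(df.columns[:2]) != ["te_type", "te_class"]:
        raise ParseError(f"{path}: expected columns te_type, te_class")
    seen: dict[str, str] = {}
    for _, row in df.iterrows():
        t, c = row["te_type"], row["te_class"]
        if t in seen and seen[t] != c:
            raise ValidationError(
                f"te_type {t!r} assigned to classes {seen[t]!r} and {c!r}")
        seen[t] = c
    return seen


def read_sample_metadata(path) -> SampleMetadata:
    return SampleMetadata(_read_tsv(path))


def write_sample_metadata(meta: SampleMetadata, path) -> None:
    meta.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------

def read_gmt(path) -> GeneSetCollection:
    """Read gene sets from GMT (one set per line: name, description,
    members...).  Duplicate symbols within a line are deduplicated with a
    logged warning; an empty file yields an empty collection."""
    sets: dict[str, frozenset] = {}
    prov: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ParseError(
                f"{path}:{lineno}: GMT line has {len(fields)} fields, expected >= 3")
        name, desc, *members = fields
        members = [m for m in members if m]
        if len(set(members)) < len(members):
            dups = _duplicates(members)
            logger.warning("GMT set %r (line %d): duplicate symbols %s deduplicated",
                           name, lineno, dups)
        sets[name] = frozenset(members)
        prov[name] = desc
    return GeneSetCollection(sets, prov)


def write_gmt(col: GeneSetCollection, path) -> None:
    lines = []
    for name in col.names():
        members = sorted(col[name])
        lines.append("\t".join([name, col.provenance.get(name, "")] + members))
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
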