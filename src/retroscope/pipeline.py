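"""End-to-end orchestration: read -> normalise/aggregate -> differential
expression (TE transcripts, TE types, coding genes) -> gene-set enrichment
-> co-expression modules -> module x TE-type association -> concordance
chi-square, with seeded determinism and a machine-readable report.

The report JSON is versioned and fully reproducible: every number in it can
be recomputed by running the corresponding module operation in isolation
with the same seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as rio
from .containers import ExpressionMatrix, ValidationError
from .de import Contrast, DifferentialExpression, TE_REGULATOR_PANEL
from .enrichment import CompetitiveEnrichment
from .networks import (
    CoexpressionNetwork,
    ConcordanceError,
    concordance_chi2,
    correlate_te,
    module_direction,
)
from .quant import aggregate_te, classes_from_types, log_transform, to_cpm, to_tpm
from .simulate import default_scenario, simulate, write_fixture

logger = logging.getLogger("retroscope")

REPORT_SCHEMA_VERSION = "1.0"


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    counts: str
    metadata: str
    annotation: str
    gene_sets: str | None = None
    contrasts: list[Contrast] = field(default_factory=list)
    primary_contrast: int = 0
    de_fdr_alpha: float = 0.05
    cell_alpha: float = 0.05
    enrichment_alpha: float = 0.05   # display stars at alpha/2 = 0.025
    n_perm: int = 1000
    seed: int = 0
    min_module_size: int = 30
    n_modules: int | str = "auto"
    min_total_count: int = 10
    output_dir: str = "retroscope_out"


def load_config(path) -> PipelineConfig:
    """Parse a YAML pipeline config (see :func:`validate_config`)."""
    try:
        raw = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as err:
        raise ValidationError(f"cannot parse config {path}: {err}") from err
    if not isinstance(raw, dict):
        raise ValidationError(f"config {path} is not a mapping")
    inputs = raw.get("inputs", {})
    alpha = raw.get("alpha", {})
    modules = raw.get("modules", {})
    contrasts = [Contrast(c["group_a"], c["group_b"], bool(c.get("paired", False)))
                 for c in raw.get("contrasts", [])]
    return PipelineConfig(
        counts=inputs.get("counts", ""),
        metadata=inputs.get("metadata", ""),
        annotation=inputs.get("annotation", ""),
        gene_sets=inputs.get("gene_sets"),
        contrasts=contrasts,
        primary_contrast=int(raw.get("primary_contrast", 0)),
        de_fdr_alpha=float(alpha.get("de_fdr", 0.05)),
        cell_alpha=float(alpha.get("cell", 0.05)),
        enrichment_alpha=float(alpha.get("enrichment_familywise", 0.05)),
        n_perm=int(raw.get("n_perm", 1000)),
        seed=int(raw.get("seed", 0)),
        min_module_size=int(modules.get("min_module_size", 30)),
        n_modules=modules.get("n_modules", "auto"),
        min_total_count=int(raw.get("min_total_count", 10)),
        output_dir=str(raw.get("output_dir", "retroscope_out")),
    )


def validate_config(config: PipelineConfig | str | Path) -> list[str]:
    """Collect *all* violations of a config, not just the first."""
    if not isinstance(config, PipelineConfig):
        config = load_config(config)
    errs = []
    for name in ("counts", "metadata", "annotation"):
        p = getattr(config, name)
        if not p:
            errs.append(f"inputs.{name} is required")
        elif not Path(p).exists():
            errs.append(f"inputs.{name}: file not found: {p}")
    if config.gene_sets and not Path(config.gene_sets).exists():
        errs.append(f"inputs.gene_sets: file not found: {config.gene_sets}")
    if not config.contrasts:
        errs.append("at least one contrast is required")
    for name in ("de_fdr_alpha", "cell_alpha", "enrichment_alpha"):
        a = getattr(config, name)
        if not (0.0 < a < 1.0):
            errs.append(f"{name} must lie in (0, 1), got {a}")
    if config.n_perm < 1:
        errs.append(f"n_perm must be >= 1, got {config.n_perm}")
    if config.min_module_size < 2:
        errs.append(f"min_module_size must be >= 2, got {config.min_module_size}")
    if config.n_modules != "auto":
        try:
            if int(config.n_modules) < 1:
                errs.append("n_modules must be >= 1 or 'auto'")
        except (TypeError, ValueError):
            errs.append(f"n_modules must be an integer or 'auto', got {config.n_modules!r}")
    if not (0 <= config.primary_contrast < max(len(config.contrasts), 1)):
        errs.append(f"primary_contrast index {config.primary_contrast} out of range")
    return errs


# ---------------------------------------------------------------------------

def _round_floats(obj, ndigits: int = 10):
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (float, np.floating)):
        x = float(obj)
        return None if np.isnan(x) else round(x, ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def _counts_by_te_type(counts: ExpressionMatrix, ann) -> ExpressionMatrix:
    rep = ann.repeat_features().set_index("feature_id")
    members = [f for f in counts.feature_ids if f in rep.index]
    keys = rep.loc[members, "te_type"]
    agg = counts.values.loc[members].groupby(keys.to_numpy()).sum().sort_index()
    return ExpressionMatrix(agg, unit="count")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns the report dict (also written to
    ``report.json`` with a MANIFEST recording per-stage completion)."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    report: dict = {"schema_version": REPORT_SCHEMA_VERSION, "seed": config.seed}
    stage = "read"
    try:
        counts = rio.read_counts(config.counts)
        meta = rio.read_sample_metadata(config.metadata)
        ann = rio.read_te_annotation(config.annotation)
        gene_sets = rio.read_gmt(config.gene_sets) if config.gene_sets else None
        unannotated = ann.unannotated(counts)
        if unannotated:
            logger.warning("%d features not in annotation (retained for coding "
                           "analyses only)", len(unannotated))
        report["n_features"] = counts.shape[0]
        report["n_samples"] = counts.shape[1]
        report["n_unannotated"] = len(unannotated)
        manifest[stage] = "ok"

        stage = "quantify"
        cpm = to_cpm(counts)
        try:
            tpm = to_tpm(counts.subset_features(
                [f for f in counts.feature_ids if f not in unannotated]), ann)
        except ValidationError as err:
            logger.warning("TPM unavailable: %s", err)
            tpm = None
        repeat_ids = [f for f in counts.feature_ids
                      if f in set(ann.repeat_features()["feature_id"])]
        coding_ids = [f for f in counts.feature_ids
                      if f in set(ann.coding_features()["feature_id"])]
        has_te = len(repeat_ids) > 0
        if has_te:
            te_types_cpm = aggregate_te(cpm, ann, level="type")
            te_classes_cpm = classes_from_types(te_types_cpm)
            from .quant import write_aggregated
            write_aggregated(te_types_cpm.log_transform(), outdir / "te_type_log10cpm.tsv")
            write_aggregated(te_classes_cpm.log_transform(), outdir / "te_class_log10cpm.tsv")
            if tpm is not None:
                write_aggregated(aggregate_te(tpm, ann, level="type").log_transform(),
                                 outdir / "te_type_log10tpm.tsv")
            report["te_types"] = list(te_types_cpm.values.index)
        else:
            report["te_types"] = []
        manifest[stage] = "ok"

        stage = "de"
        library_size = counts.values.sum(axis=0)
        coding_de = {}
        report["contrasts"] = {}
        for ci, contrast in enumerate(config.contrasts):
            entry: dict = {}
            cm = counts.subset_features(coding_ids) if coding_ids else None
            if cm is not None:
                res_coding = DifferentialExpression(
                    cm, meta, contrast, min_total_count=config.min_total_count,
                    library_size=library_size).fit()
                res_coding.to_tsv(outdir / f"de_coding_{contrast.label}.tsv")
                coding_de[ci] = res_coding
                panel, missing = res_coding.regulator_panel(
                    TE_REGULATOR_PANEL, ann, alpha=config.cell_alpha)
                entry["regulator_panel"] = {
                    row["gene_symbol"]: {"logFC": row["logFC"], "p": row["p"],
                                         "significant": bool(row["significant"])}
                    for _, row in panel.iterrows()}
                entry["regulator_panel_missing"] = missing
            if has_te:
                res_te = DifferentialExpression(
                    counts.subset_features(repeat_ids), meta, contrast,
                    min_total_count=config.min_total_count,
                    library_size=library_size).fit()
                res_te.to_tsv(outdir / f"de_te_transcripts_{contrast.label}.tsv")
                qs = res_te.lfc_quantiles(alpha=config.de_fdr_alpha)
                entry["te_transcript_abs_logfc_quantiles"] = {
                    f"{p:g}": v for p, v in zip(qs.probs, qs.values)}
                entry["n_te_transcripts_de"] = qs.n_features
                qs_all = res_te.lfc_quantiles(only_significant=False)
                entry["te_transcript_abs_logfc_quantiles_all"] = {
                    f"{p:g}": v for p, v in zip(qs_all.probs, qs_all.values)}
                type_counts = _counts_by_te_type(counts, ann)
                res_types = DifferentialExpression(
                    type_counts, meta, contrast, min_total_count=0,
                    library_size=library_size).fit()
                res_types.to_tsv(outdir / f"de_te_types_{contrast.label}.tsv")
                ttab = res_types.table.set_index("feature_id")
                med = _median_transcript_logfc(res_te, ann)
                entry["te_type_logfc"] = {
                    t: {"logFC": ttab.loc[t, "logFC"], "p": ttab.loc[t, "p"],
                        "fdr": ttab.loc[t, "fdr"],
                        "median_transcript_logFC": med.get(t)}
                    for t in ttab.index}
            report["contrasts"][contrast.label] = entry
        manifest[stage] = "ok" if config.contrasts else "skipped"

        stage = "enrich"
        primary = config.contrasts[config.primary_contrast]
        if gene_sets is not None and len(gene_sets) and config.primary_contrast in coding_de:
            sym_of = dict(ann.symbol_of())
            enr = CompetitiveEnrichment(
                coding_de[config.primary_contrast], gene_sets, sym_of).fit(
                n_perm=config.n_perm, seed=config.seed,
                alpha=config.enrichment_alpha)
            enr.to_tsv(outdir / f"enrichment_{primary.label}.tsv")
            report["enrichment"] = {
                r.set_name: {"direction": r.direction, "score": r.score,
                             "p": r.p, "p_bonf": r.p_bonf,
                             "n_genes_used": r.n_genes_used,
                             "significant": bool(r.significant)}
                for r in enr.results}
            manifest[stage] = "ok"
        else:
            manifest[stage] = "skipped"

        stage = "modules"
        if coding_ids and len(coding_ids) >= config.min_module_size:
            log2cpm = log_transform(to_cpm(counts.subset_features(coding_ids)),
                                    base=2.0)
            net = CoexpressionNetwork(
                log2cpm, min_module_size=config.min_module_size,
                n_modules=config.n_modules).fit()
            if config.primary_contrast in coding_de:
                net = module_direction(net, coding_de[config.primary_contrast],
                                       alpha=config.cell_alpha,
                                       n_perm=config.n_perm, seed=config.seed)
            net.assignment.rename("module").to_csv(
                outdir / "module_assignment.tsv", sep="\t",
                index_label="feature_id")
            report["modules"] = {
                "n_modules": net.n_modules,
                "sizes": {str(k): int(v) for k, v in net.sizes().items()},
                "direction": {str(k): v for k, v in net.direction.items()},
                "cut_height": net.cut_height,
            }
            manifest[stage] = "ok"
        else:
            net = None
            manifest[stage] = "skipped"

        stage = "associate"
        if net is not None and has_te and counts.shape[1] >= 4:
            te_log10 = aggregate_te(cpm, ann, level="type").log_transform()
            assoc = correlate_te(net.eigengene, te_log10, alpha=config.cell_alpha)
            assoc.to_long_frame().to_csv(outdir / "association_table.tsv",
                                         sep="\t", index=False)
            report["association"] = {
                "n_significant_cells": int(assoc.sig.to_numpy().sum()),
                "r": {str(m): {t: assoc.r.loc[m, t] for t in assoc.r.columns}
                      for m in assoc.r.index},
                "sig": {str(m): {t: bool(assoc.sig.loc[m, t])
                                 for t in assoc.sig.columns}
                        for m in assoc.sig.index},
            }
            manifest[stage] = "ok"

            stage = "concordance"
            try:
                assoc = concordance_chi2(assoc, net)
                report["concordance"] = {
                    "contingency": {r: {c: int(assoc.contingency.loc[r, c])
                                        for c in assoc.contingency.columns}
                                    for r in assoc.contingency.index},
                    "chi2": assoc.chi2, "chi2_p": assoc.chi2_p,
                    "fisher_p": assoc.fisher_p,
                }
                manifest[stage] = "ok"
            except (ConcordanceError, ValidationError) as err:
                logger.warning("concordance test unavailable: %s", err)
                report["concordance"] = {"error": str(err)}
                manifest[stage] = f"skipped: {err}"
            (outdir / "concordance.json").write_text(
                json.dumps(_round_floats(report.get("concordance", {})),
                           indent=1, sort_keys=True))
        else:
            manifest["associate"] = "skipped"
            manifest["concordance"] = "skipped"
    except Exception as err:  # abort with stage name, retain partial outputs
        manifest[stage] = f"failed: {err}"
        (outdir / "MANIFEST.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True))
        if isinstance(err, PipelineError):
            raise
        raise PipelineError(stage, err) from err

    report = _round_floats(report)
    (outdir / "report.json").write_text(
        json.dumps(report, indent=1, sort_keys=True))
    (outdir / "MANIFEST.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True))
    return report


def _median_transcript_logfc(res_te, ann) -> dict[str, float]:
    rep = ann.repeat_features().set_index("feature_id")["te_type"]
    tab = res_te.table
    types = tab["feature_id"].map(rep)
    return tab.groupby(types.to_numpy())["logFC"].median().to_dict()


# ---------------------------------------------------------------------------
# demo
# ---------------------------------------------------------------------------

def run_demo(output_dir, seed: int = 0, n_perm: int = 1000) -> dict:
    """Generate the default synthetic AML scenario and run the full
    pipeline on it: the single-command end-to-end demonstration."""
    output_dir = Path(output_dir)
    fixture_dir = output_dir / "fixture"
    bundle = simulate(default_scenario(seed=seed))
    paths = write_fixture(bundle, fixture_dir)
    config = PipelineConfig(
        counts=str(paths["counts"]),
        metadata=str(paths["metadata"]),
        annotation=str(paths["annotation"]),
        gene_sets=str(paths["gene_sets"]),
        contrasts=[Contrast("LSC", "pHSC", paired=True),
                   Contrast("LSC", "Blast", paired=True)],
        primary_contrast=1,
        n_perm=n_perm,
        seed=seed,
        min_module_size=30,
        output_dir=str(output_dir),
    )
    errs = validate_config(config)
    if errs:
        raise ValidationError("; ".join(errs))
    return run_pipeline(config)
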