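"""Synthetic count data with the statistical structure the pipeline assumes.

The generator plants, on the log2 scale:

* a paired multi-fraction design (default: 7 patients x pHSC/LSC/Blast) or
  an unpaired two-group design, with per-patient random offsets;
* negative-binomial counts (variance = mu + dispersion * mu^2);
* TE-type-specific suppression in a chosen group (e.g. Alu down in LSC);
* block-structured coding-gene co-expression driven by latent module
  factors with positive loadings;
* latent coupling between module factors and TE-type abundance, the
  structure the concordance chi-square is designed to detect;
* named immune/inflammation gene sets populated from chosen modules.

Everything is seeded and reproducible; a :class:`SimTruth` record carries
the planted effects so every analysis stage can be checked against ground
truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    ExpressionMatrix,
    GeneSetCollection,
    SampleMetadata,
    TEAnnotation,
    ValidationError,
)
from . import io as rio

#: TE types analysed throughout (each under its class), the qualitative
#: suppression pattern (log2 effects in the LSC fraction), and the
#: module-factor coupling signs used by the default scenario.
STUDY_TE_TYPES = {
    "Alu": "SINE", "MIR": "SINE", "L1": "LINE", "L2": "LINE",
    "ERV1": "LTR", "ERV3": "LTR", "ERVK": "LTR", "ERVL": "LTR",
    "Endogenous Retrovirus": "LTR", "LTR Retrotransposon": "LTR",
    "SAT": "Satellite",
}
LSC_SUPPRESSED_TYPES = ("Alu", "ERV3", "ERVK", "ERVL", "LTR Retrotransposon")
IMMUNE_POSITIVE_TYPES = ("Alu", "ERVL", "ERVK", "LTR Retrotransposon")
IMMUNE_NEGATIVE_TYPES = ("ERV1", "L1", "SAT")

#: Coupled types for the two-group concordance scenario: the SINE/LTR-class
#: types ride positively with immune-activated modules, the autonomous
#: LINE-class types (and ERV1) negatively -- mirrored for immune-suppressed
#: modules.  Extends the core pattern to class-mates so the concordance
#: table has enough cells to be informative.
CONCORDANCE_POSITIVE_TYPES = (
    "Alu", "ERVL", "ERVK", "LTR Retrotransposon", "ERV3",
    "Endogenous Retrovirus", "MIR", "L2", "ERVL-MaLR", "Gypsy", "Copia",
    "DIRS", "FLAM", "FRAM", "Deu", "tRNA",
)
CONCORDANCE_NEGATIVE_TYPES = ("ERV1", "L1", "CR1", "RTE")


@dataclass
class SimConfig:
    """Generator parameters; defaults mirror the AML fraction study design."""

    n_patients: int = 7
    groups: tuple[str, ...] = ("pHSC", "LSC", "Blast")
    paired: bool = True
    n_coding: int = 2000
    n_repeat: int = 500
    te_types: dict[str, str] = field(default_factory=lambda: dict(STUDY_TE_TYPES))
    nb_dispersion: float = 0.1
    baseline_log_mean_range: tuple[float, float] = (3.0, 8.0)
    te_suppression: dict[str, tuple[str, float]] = field(default_factory=dict)
    n_modules: int = 8
    module_size: int = 60
    factor_loading_sd: float = 1.0
    noise_sd: float = 0.3
    coupling: list[tuple[int, str, int, float]] = field(default_factory=list)
    module_group_effects: dict[int, dict[str, float]] = field(default_factory=dict)
    gene_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    immune_set_spec: dict[str, list[int]] = field(default_factory=dict)
    patient_effect_sd: float = 0.25
    # (src, dst) module pairs whose genes share baselines and loadings:
    # with linearly-balanced opposite group effects this makes the expected
    # library size exactly group-independent, so CPM cannot leak module
    # activity into unrelated features (see docs/methods.md).
    mirrored_module_pairs: list[tuple[int, int]] = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        errs = []
        for name in ("n_patients", "n_coding", "n_repeat", "n_modules", "module_size"):
            if getattr(self, name) <= 0:
                errs.append(f"{name} must be positive")
        if len(self.groups) < 2:
            errs.append("need at least 2 groups")
        if self.nb_dispersion < 0:
            errs.append("nb_dispersion must be >= 0")
        if self.n_modules * self.module_size > self.n_coding:
            errs.append("n_modules * module_size exceeds n_coding")
        for t, (g, _) in self.te_suppression.items():
            if t not in self.te_types:
                errs.append(f"te_suppression references unknown te_type {t!r}")
            if g not in self.groups:
                errs.append(f"te_suppression references unknown group {g!r}")
        for k, t, sign, strength in self.coupling:
            if not (1 <= k <= self.n_modules):
                errs.append(f"coupling references module {k} out of range")
            if t not in self.te_types:
                errs.append(f"coupling references unknown te_type {t!r}")
            if sign not in (-1, 1):
                errs.append(f"coupling sign must be +-1, got {sign}")
            if not (0 <= strength <= 1):
                errs.append(f"coupling strength must lie in [0, 1], got {strength}")
        for k, effs in self.module_group_effects.items():
            if not (1 <= k <= self.n_modules):
                errs.append(f"module_group_effects references module {k} out of range")
            for g in effs:
                if g not in self.groups:
                    errs.append(f"module_group_effects references unknown group {g!r}")
        for name, mods in self.immune_set_spec.items():
            for k in mods:
                if not (1 <= k <= self.n_modules):
                    errs.append(f"immune set {name!r} references module {k} out of range")
        for src, dst in self.mirrored_module_pairs:
            if not (1 <= src <= self.n_modules and 1 <= dst <= self.n_modules):
                errs.append(f"mirrored pair ({src}, {dst}) out of module range")
            elif src == dst:
                errs.append(f"mirrored pair ({src}, {dst}) must name two modules")
        if errs:
            raise ValidationError("; ".join(errs))


@dataclass
class SimTruth:
    """Planted ground truth for recovery tests."""

    group_effects: pd.DataFrame          # features x groups, log2 effects
    module_assignment: pd.Series         # coding gene -> module (0 = background)
    te_type_of: pd.Series                # repeat feature -> te_type
    coupling: list[tuple[int, str, int, float]]
    module_direction: dict[int, dict[str, int]]  # module -> {"a_vs_b": sign}

    def true_logfc(self, group_a: str, group_b: str) -> pd.Series:
        return self.group_effects[group_a] - self.group_effects[group_b]

    def coupling_sign(self, module: int, te_type: str) -> int:
        for k, t, sign, strength in self.coupling:
            if k == module and t == te_type and strength > 0:
                return sign
        return 0

    def to_json_dict(self) -> dict:
        return {
            "group_effects": {f: {g: float(v) for g, v in row.items()}
                              for f, row in self.group_effects.iterrows()},
            "module_assignment": {g: int(m) for g, m in self.module_assignment.items()},
            "te_type_of": dict(self.te_type_of),
            "coupling": [list(c) for c in self.coupling],
            "module_direction": {str(k): v for k, v in self.module_direction.items()},
        }


@dataclass
class SimBundle:
    counts: ExpressionMatrix
    metadata: SampleMetadata
    annotation: TEAnnotation
    gene_sets: GeneSetCollection
    truth: SimTruth
    config: SimConfig


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Counts with variance mu + dispersion * mu^2 (Poisson when dispersion=0)."""
    if dispersion <= 1e-12:
        return rng.poisson(mu)
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + mu))


def simulate(config: SimConfig) -> SimBundle:
    """Draw a full dataset (counts, metadata, annotation, gene sets, truth)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    groups = list(config.groups)

    # ---- samples -------------------------------------------------------
    sample_ids, sample_group, sample_patient = [], [], []
    if config.paired:
        patients = [f"P{p + 1:02d}" for p in range(config.n_patients)]
        for pat in patients:
            for g in groups:
                sample_ids.append(f"{pat}_{g}")
                sample_group.append(g)
                sample_patient.append(pat)
    else:
        i = 0
        for g in groups:
            for _ in range(config.n_patients):
                i += 1
                pat = f"P{i:03d}"
                sample_ids.append(f"{pat}_{g}")
                sample_group.append(g)
                sample_patient.append(pat)
    n_samples = len(sample_ids)
    meta = SampleMetadata(pd.DataFrame({
        "sample_id": sample_ids, "group": sample_group, "patient_id": sample_patient}))

    patient_offset = {}
    for pat in dict.fromkeys(sample_patient):
        patient_offset[pat] = rng.normal(0.0, config.patient_effect_sd)
    offsets = np.array([patient_offset[p] for p in sample_patient])
    group_idx = {g: np.array([sg == g for sg in sample_group]) for g in groups}

    # ---- latent module factors ----------------------------------------
    factors = rng.standard_normal((config.n_modules, n_samples))

    lo, hi = config.baseline_log_mean_range

    # ---- coding genes --------------------------------------------------
    gene_ids, assignment, loadings = [], [], []
    for k in range(1, config.n_modules + 1):
        for i in range(config.module_size):
            gene_ids.append(f"GM{k:02d}_{i + 1:03d}")
            assignment.append(k)
            # positive loadings keep a module's genes mutually correlated
            loadings.append(abs(rng.normal(config.factor_loading_sd,
                                           config.factor_loading_sd / 4.0)))
    n_bg = config.n_coding - len(gene_ids)
    for i in range(n_bg):
        gene_ids.append(f"G{i + 1:05d}")
        assignment.append(0)
        loadings.append(0.0)
    extra = list(config.gene_effects)
    gene_ids += extra
    assignment += [0] * len(extra)
    loadings += [0.0] * len(extra)

    n_genes = len(gene_ids)
    loadings = np.asarray(loadings, dtype=float)
    baseline_g = rng.uniform(lo, hi, size=n_genes)
    for src, dst in config.mirrored_module_pairs:
        s = slice((src - 1) * config.module_size, src * config.module_size)
        d = slice((dst - 1) * config.module_size, dst * config.module_size)
        baseline_g[d] = baseline_g[s]
        loadings[d] = loadings[s]
    gene_group_eff = np.zeros((n_genes, len(groups)))
    for gi, (gene, mod) in enumerate(zip(gene_ids, assignment)):
        effs = config.module_group_effects.get(mod, {})
        for g, e in effs.items():
            gene_group_eff[gi, groups.index(g)] = e
        if gene in config.gene_effects:
            for g, e in config.gene_effects[gene].items():
                gene_group_eff[gi, groups.index(g)] = e

    log2_mu_genes = np.tile(baseline_g[:, None], (1, n_samples))
    for gi, mod in enumerate(assignment):
        if mod > 0:
            log2_mu_genes[gi] += loadings[gi] * factors[mod - 1]
    log2_mu_genes += offsets[None, :]
    for g in groups:
        log2_mu_genes[:, group_idx[g]] += gene_group_eff[:, [groups.index(g)]]
    log2_mu_genes += rng.normal(0.0, config.noise_sd, size=log2_mu_genes.shape)

    # ---- TE transcripts ------------------------------------------------
    te_types = list(config.te_types)
    te_ids, te_type_of = [], []
    for i in range(config.n_repeat):
        t = te_types[i % len(te_types)]
        te_ids.append(f"TE_{t.replace(' ', '')}_{i + 1:04d}")
        te_type_of.append(t)
    baseline_t = rng.uniform(lo, hi, size=config.n_repeat)
    coupling_of: dict[str, list[tuple[int, float]]] = {t: [] for t in te_types}
    for k, t, sign, strength in config.coupling:
        coupling_of[t].append((k, sign * strength))

    log2_mu_te = np.tile(baseline_t[:, None], (1, n_samples))
    te_group_eff = np.zeros((config.n_repeat, len(groups)))
    for ti, t in enumerate(te_type_of):
        for k, w in coupling_of[t]:
            log2_mu_te[ti] += w * factors[k - 1]
        if t in config.te_suppression:
            g, eff = config.te_suppression[t]
            log2_mu_te[ti, group_idx[g]] += eff
            te_group_eff[ti, groups.index(g)] = eff
    log2_mu_te += offsets[None, :]
    log2_mu_te += rng.normal(0.0, config.noise_sd, size=log2_mu_te.shape)

    # ---- counts --------------------------------------------------------
    mu = np.vstack([np.power(2.0, log2_mu_genes), np.power(2.0, log2_mu_te)])
    counts = _nb_draw(rng, mu, config.nb_dispersion).astype(np.int64)
    feature_ids = gene_ids + te_ids
    matrix = ExpressionMatrix(
        pd.DataFrame(counts, index=feature_ids, columns=sample_ids), unit="count")

    # ---- annotation ----------------------------------------------------
    rows = []
    gene_lengths = rng.integers(500, 5001, size=n_genes)
    te_lengths = rng.integers(300, 6001, size=config.n_repeat)
    for gid, length in zip(gene_ids, gene_lengths):
        rows.append({"feature_id": gid, "kind": "coding", "te_type": "",
                     "te_class": "", "gene_symbol": gid,
                     "effective_length": float(length)})
    for tid, t, length in zip(te_ids, te_type_of, te_lengths):
        rows.append({"feature_id": tid, "kind": "repeat", "te_type": t,
                     "te_class": config.te_types[t], "gene_symbol": "",
                     "effective_length": float(length)})
    ann = TEAnnotation(pd.DataFrame(rows))

    # ---- gene sets -----------------------------------------------------
    sets, prov = {}, {}
    assign_series = pd.Series(assignment, index=gene_ids, name="module")
    for name, mods in config.immune_set_spec.items():
        members = [g for g, m in assign_series.items() if m in mods]
        if members:
            sets[name] = frozenset(members)
            prov[name] = f"synthetic: genes of modules {sorted(mods)}"
    gene_sets = GeneSetCollection(sets, prov)

    # ---- truth ---------------------------------------------------------
    group_effects = pd.DataFrame(
        np.vstack([gene_group_eff, te_group_eff]),
        index=feature_ids, columns=groups)
    module_direction: dict[int, dict[str, int]] = {}
    for k in range(1, config.n_modules + 1):
        effs = config.module_group_effects.get(k, {})
        dirs = {}
        for a in groups:
            for b in groups:
                if a == b:
                    continue
                diff = effs.get(a, 0.0) - effs.get(b, 0.0)
                dirs[f"{a}_vs_{b}"] = int(np.sign(diff))
        module_direction[k] = dirs
    truth = SimTruth(group_effects, assign_series,
                     pd.Series(te_type_of, index=te_ids, name="te_type"),
                     [tuple(c) for c in config.coupling], module_direction)
    return SimBundle(matrix, meta, ann, gene_sets, truth, config)


# ---------------------------------------------------------------------------
# canned scenarios
# ---------------------------------------------------------------------------

def default_scenario(seed: int = 0, **overrides) -> SimConfig:
    """The AML fraction scenario: 7 paired patients x pHSC/LSC/Blast,
    Alu/ERV3/ERVK/ERVL/LTR retrotransposon suppression in LSC, immune
    modules activated in Blast and coupled to TE types (SINE/LTR-class
    types positively, ERV1/L1 negatively)."""
    # Coupling strength 0.35: TE types share the latent factors, so at 7
    # samples per fraction the chance group-imbalance of a factor adds
    # ~2 * strength * sqrt(2/7) log2 units of type-level noise; 0.35 keeps
    # the module-TE association visible while leaving the planted -1
    # suppression dominant (a sign flip is a <1% event per type).
    w = 0.35
    coupling = []
    for k in (1, 2):          # immune-activated modules carry the coupling
        coupling += [(k, t, +1, w) for t in IMMUNE_POSITIVE_TYPES]
        coupling += [(k, t, -1, w) for t in IMMUNE_NEGATIVE_TYPES]
    for k in (5, 6):          # immune-suppressed modules mirror it
        coupling += [(k, "ERV1", +1, w)]
        coupling += [(k, t, -1, w) for t in ("Alu", "ERV3", "ERVL",
                                             "LTR Retrotransposon")]
    cfg = SimConfig(
        te_suppression={t: ("LSC", -1.0) for t in LSC_SUPPRESSED_TYPES},
        coupling=coupling,
        module_group_effects={
            **{k: {"Blast": 0.8} for k in (1, 2, 3, 4)},
            **{k: {"Blast": -0.8} for k in (5, 6, 7, 8)},
        },
        gene_effects={
            # EVI-1-like regulator high in pHSC; autophagy/helicase panel up in LSC
            "MECOM": {"pHSC": 2.2},
            "ATG5": {"LSC": 1.0}, "KIAA0430": {"LSC": 1.0},
            "LAMP2": {"LSC": 0.8}, "HSP90AA1": {"LSC": 0.8},
            "DHX15": {"LSC": 1.0},
        },
        immune_set_spec={"IMMUNE_COMBINED": [1, 2, 3, 4],
                         "INFLAMMATION_COMBINED": [3, 4]},
        seed=seed,
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    cfg.validate()
    return cfg


def null_scenario(seed: int = 0, **overrides) -> SimConfig:
    """The default design with every planted structure removed -- no TE
    suppression, no group effects, no named-gene effects, no module factors
    or TE coupling: independent null features, the reference condition for
    false-positive-rate calibration of the differential tests."""
    kwargs = dict(te_suppression={}, module_group_effects={}, gene_effects={},
                  coupling=[], factor_loading_sd=0.0)
    kwargs.update(overrides)
    return default_scenario(seed=seed, **kwargs)


def recovery_scenario(seed: int = 0, **overrides) -> SimConfig:
    """The default design with the TE-module coupling switched off, used to
    measure recovery of the planted TE suppression: shared latent factors
    are a confounder the paired design cannot remove, so the estimator is
    assessed without them."""
    return default_scenario(seed=seed, coupling=[], **overrides)


def two_group_scenario(seed: int = 0, coupled: bool = True,
                       n_per_group: int = 10, **overrides) -> SimConfig:
    """Unpaired two-group design (MDS-like low/high risk) built for the
    concordance analyses: ``n_per_group`` samples per group, 12 modules of
    which two are immune-activated and two immune-suppressed in the low
    group, and the full shipped taxonomy of TE types.

    ``coupled=False`` removes the module-TE coupling (the generator's null
    for the concordance test) while keeping everything else identical.

    Three design constraints keep the realised null faithful to its premise
    (TE expression independent of module activity) through the CPM step:

    * group effects are composition-neutral on the *linear* scale (an up
      effect of +0.3 is paired with log2(2 - 2^0.3) on the mirrored module,
      whose genes share baselines and loadings), so the expected library
      size is identical in both groups;
    * group effects are small relative to factor loadings, so eigengenes
      track their latent factor rather than the group axis -- strongly
      group-aligned eigengenes would share the group dimension and violate
      the cell-independence the concordance chi-square relies on;
    * module genes are a modest fraction of a diffuse library (360 of 2240
      features), so per-sample library noise -- a common divisor that every
      CPM profile shares -- stays small, as in real sequencing libraries.
    """
    taxonomy = rio.read_te_taxonomy()
    pairs = [(1, 7), (2, 8)]
    coupling = []
    if coupled:
        for i, t in enumerate(CONCORDANCE_POSITIVE_TYPES + CONCORDANCE_NEGATIVE_TYPES):
            k, km = pairs[i % 2]
            sign = +1 if t in CONCORDANCE_POSITIVE_TYPES else -1
            coupling += [(k, t, sign, 0.6), (km, t, -sign, 0.6)]
    up = 0.3
    down = float(np.log2(2.0 - 2.0 ** up))
    cfg = SimConfig(
        n_patients=n_per_group,
        groups=("low", "high"),
        paired=False,
        n_coding=2000,
        n_repeat=240,
        te_types=taxonomy,
        n_modules=12,
        module_size=30,
        factor_loading_sd=0.5,
        coupling=coupling,
        module_group_effects={1: {"low": up}, 2: {"low": up},
                              7: {"low": down}, 8: {"low": down}},
        mirrored_module_pairs=list(pairs),
        immune_set_spec={"IMMUNE_COMBINED": [1, 2]},
        # the null premise is TE _|_ module activity; a shared patient
        # offset would be a common cause, so it is off here
        patient_effect_sd=0.0,
        seed=seed,
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# fixtures on disk
# ---------------------------------------------------------------------------

def write_fixture(bundle: SimBundle, directory) -> dict[str, Path]:
    """Write counts/metadata/annotation/GMT/truth to ``directory``; reading
    back through :mod:`retroscope.io` reproduces the bundle exactly."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": directory / "counts.tsv",
        "metadata": directory / "metadata.tsv",
        "annotation": directory / "annotation.tsv",
        "gene_sets": directory / "gene_sets.gmt",
        "truth": directory / "truth.json",
    }
    rio.write_counts(bundle.counts, paths["counts"])
    rio.write_sample_metadata(bundle.metadata, paths["metadata"])
    rio.write_te_annotation(bundle.annotation, paths["annotation"])
    rio.write_gmt(bundle.gene_sets, paths["gene_sets"])
    cfg = asdict(bundle.config)
    cfg["groups"] = list(cfg["groups"])
    cfg["baseline_log_mean_range"] = list(cfg["baseline_log_mean_range"])
    paths["truth"].write_text(json.dumps(
        {"config": cfg, "truth": bundle.truth.to_json_dict()},
        indent=1, sort_keys=True))
    return paths
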