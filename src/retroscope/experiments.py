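"""Simulation experiments that characterise the pipeline's statistics:
false-positive-rate calibration of the moderated t, recovery of planted TE
suppression, module recovery, and calibration/power of the concordance
chi-square.  Each experiment generates data from a canned scenario, runs
the corresponding analysis stage, and reports a summary number.

The concordance experiments use the generator's *true* module assignment
and directional labels (both carried in :class:`~retroscope.simulate.SimTruth`)
rather than re-detecting them: they characterise the association statistic
itself, with the upstream detection steps validated separately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, ValidationError
from .de import Contrast, DifferentialExpression
from .networks import (
    ACTIVATED,
    ConcordanceError,
    ModuleResults,
    NONE,
    SUPPRESSED,
    concordance_chi2,
    correlate_te,
    detect_modules,
    eigengene,
)
from .quant import aggregate_te, to_cpm
from .simulate import (
    SimBundle,
    default_scenario,
    null_scenario,
    recovery_scenario,
    simulate,
    two_group_scenario,
)


def _te_ids(bundle: SimBundle) -> list[str]:
    rep = set(bundle.annotation.repeat_features()["feature_id"])
    return [f for f in bundle.counts.feature_ids if f in rep]


def _coding_ids(bundle: SimBundle) -> list[str]:
    cod = set(bundle.annotation.coding_features()["feature_id"])
    return [f for f in bundle.counts.feature_ids if f in cod]


# ---------------------------------------------------------------------------
# moderated-t calibration and recovery
# ---------------------------------------------------------------------------

def de_null_pvalue_fraction(seed: int, alpha: float = 0.05,
                            contrast: Contrast | None = None) -> float:
    """Fraction of features with p <= alpha on one null-generator dataset
    (no planted structure); should sit near alpha."""
    bundle = simulate(null_scenario(seed=seed))
    contrast = contrast or Contrast("LSC", "pHSC", paired=True)
    res = DifferentialExpression(bundle.counts, bundle.metadata, contrast).fit()
    return float((res.table["p"] <= alpha).mean())


def de_null_calibration(n_reps: int = 50, alpha: float = 0.05,
                        seed0: int = 0) -> dict:
    """Mean null p<=alpha fraction over replicates, with its Monte-Carlo
    standard error estimated from the replicate spread."""
    fracs = np.array([de_null_pvalue_fraction(seed0 + i, alpha)
                      for i in range(n_reps)])
    return {"mean": float(fracs.mean()),
            "mc_se": float(fracs.std(ddof=1) / np.sqrt(n_reps)),
            "alpha": alpha, "n_reps": n_reps}


def te_suppression_recovery(seed: int, te_type: str = "Alu",
                            contrast: Contrast | None = None) -> float:
    """Median estimated log2FC over transcripts of ``te_type`` on one
    recovery-scenario dataset (planted suppression, no coupling)."""
    bundle = simulate(recovery_scenario(seed=seed))
    contrast = contrast or Contrast("LSC", "pHSC", paired=True)
    lib = bundle.counts.values.sum(axis=0)
    res = DifferentialExpression(
        bundle.counts.subset_features(_te_ids(bundle)), bundle.metadata,
        contrast, library_size=lib).fit()
    types = bundle.annotation.repeat_features().set_index("feature_id")["te_type"]
    tab = res.table.set_index("feature_id")
    med = tab.groupby(tab.index.map(types))["logFC"].median()
    return float(med[te_type])


def suppression_recovery_medians(n_seeds: int = 20, te_type: str = "Alu",
                                 seed0: int = 0) -> np.ndarray:
    return np.array([te_suppression_recovery(seed0 + i, te_type)
                     for i in range(n_seeds)])


# ---------------------------------------------------------------------------
# module recovery
# ---------------------------------------------------------------------------

def module_recovery_ari(seed: int, n_modules: int = 4, module_size: int = 50,
                        min_module_size: int = 25) -> float:
    """Adjusted Rand index between detected and planted modules on a
    strongly blocked scenario (loading sd far above noise sd)."""
    cfg = default_scenario(
        seed=seed, n_modules=n_modules, module_size=module_size,
        n_coding=n_modules * module_size, n_repeat=50,
        factor_loading_sd=1.0, noise_sd=0.2,
        coupling=[], te_suppression={}, module_group_effects={},
        gene_effects={}, immune_set_spec={})
    bundle = simulate(cfg)
    coding = _coding_ids(bundle)
    cpm = to_cpm(bundle.counts)
    log2cpm = ExpressionMatrix(np.log2(1.0 + cpm.values.loc[coding]),
                               unit="logCPM", log_base=2)
    detected = detect_modules(log2cpm, min_module_size=min_module_size)
    truth = bundle.truth.module_assignment.loc[coding]
    return adjusted_rand_index(truth.to_numpy(), detected.assignment.to_numpy())


def adjusted_rand_index(a, b) -> float:
    """Adjusted Rand index between two labelings (permutation-invariant)."""
    a = pd.Categorical(a).codes
    b = pd.Categorical(b).codes
    n = len(a)
    ct = pd.crosstab(pd.Series(a), pd.Series(b)).to_numpy()
    comb = lambda x: x * (x - 1) / 2.0
    sum_ij = comb(ct.astype(float)).sum()
    ai = comb(ct.sum(axis=1).astype(float)).sum()
    bj = comb(ct.sum(axis=0).astype(float)).sum()
    expected = ai * bj / comb(float(n))
    max_index = 0.5 * (ai + bj)
    if max_index == expected:
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


# ---------------------------------------------------------------------------
# concordance chi-square calibration and power
# ---------------------------------------------------------------------------

@dataclass
class ConcordanceOutcome:
    rejected: bool
    chi2: float
    chi2_p: float
    n_sig_cells: int
    testable: bool


def concordance_replicate(seed: int, coupled: bool,
                          alpha: float = 0.05) -> ConcordanceOutcome:
    """One concordance experiment: simulate the two-group scenario, build
    eigengenes from the true module assignment, correlate against TE types,
    attach the true directional labels, and run the chi-square.

    A replicate whose contingency table cannot be tested (no significant
    cells, or a zero margin) counts as a non-rejection.
    """
    bundle = simulate(two_group_scenario(seed=seed, coupled=coupled))
    contrast_key = "low_vs_high"
    cpm = to_cpm(bundle.counts)
    coding = _coding_ids(bundle)
    log2cpm = ExpressionMatrix(np.log2(1.0 + cpm.values.loc[coding]),
                               unit="logCPM", log_base=2)
    assignment = bundle.truth.module_assignment.loc[coding]
    eig = eigengene(log2cpm, assignment)
    mods = ModuleResults(assignment, eig)
    mods.direction = {
        k: (ACTIVATED if d.get(contrast_key, 0) > 0
            else SUPPRESSED if d.get(contrast_key, 0) < 0 else NONE)
        for k, d in bundle.truth.module_direction.items()}
    mods.direction_contrast = contrast_key
    te_log10 = aggregate_te(cpm, bundle.annotation, level="type").log_transform()
    assoc = correlate_te(eig, te_log10, alpha=alpha)
    try:
        assoc = concordance_chi2(assoc, mods)
    except (ConcordanceError, ValidationError):
        n_sig = int(assoc.sig.to_numpy().sum())
        return ConcordanceOutcome(False, np.nan, np.nan, n_sig, False)
    return ConcordanceOutcome(bool(assoc.chi2_p <= alpha), assoc.chi2,
                              assoc.chi2_p,
                              int(assoc.contingency.to_numpy().sum()), True)


def concordance_rejection_rate(n_reps: int, coupled: bool, seed0: int = 0,
                               alpha: float = 0.05) -> dict:
    out = [concordance_replicate(seed0 + i, coupled, alpha)
           for i in range(n_reps)]
    rate = float(np.mean([o.rejected for o in out]))
    return {"rate": rate,
            "mc_se": float(np.sqrt(rate * (1 - rate) / n_reps)),
            "n_reps": n_reps, "coupled": coupled,
            "untestable": int(sum(not o.testable for o in out))}
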