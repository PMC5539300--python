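"""Competitive gene-set enrichment on moderated-t statistics.

The set score is the mean moderated t of member genes; its null is the
distribution of the same score over random same-size gene subsets drawn
without replacement from all tested features.  With cohorts as small as a
handful of paired patients, sample permutation is too coarse to give stable
p-values, so the competitive (random-set) null is used throughout.  The
two-sided p-value uses the standard +1 correction:

    p = (1 + #{ |null| >= |score| }) / (1 + n_perm)

Family-wise control is Bonferroni; the display convention stars sets with
p below alpha/2 (0.025 at the default alpha of 0.05).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import GeneSetCollection, ValidationError
from .de import DEResults

logger = logging.getLogger("retroscope")

MIN_MEMBERS = 5


def combine_sets(col: GeneSetCollection, names, combined_name: str | None = None
                 ) -> tuple[str, frozenset[str]]:
    """Union the named sets into one combined set (e.g. the 335-gene immune
    set from 17 canonical pathways, or the 649-gene inflammation set).

    Returns (name, members); provenance is the sorted source-set names.
    """
    names = list(names)
    missing = [n for n in names if n not in col]
    if missing:
        raise ValidationError(f"gene sets not in collection: {missing}")
    members: frozenset[str] = frozenset().union(*(col[n] for n in names))
    name = combined_name or ("combined:" + "+".join(names))
    return name, members


@dataclass
class EnrichmentResult:
    set_name: str
    direction: str            # "up_in_a" | "down_in_a"
    score: float              # mean moderated-t over member genes
    p: float
    n_genes_used: int
    p_bonf: float = np.nan
    significant: bool = False

    def to_dict(self) -> dict:
        return {
            "set_name": self.set_name, "direction": self.direction,
            "score": self.score, "p": self.p, "p_bonf": self.p_bonf,
            "n_genes_used": self.n_genes_used, "significant": self.significant,
        }


def competitive_test(res: DEResults, members, n_perm: int = 1000,
                     seed: int | np.random.Generator = 0,
                     set_name: str = "", symbol_of: dict | None = None,
                     min_members: int = MIN_MEMBERS) -> EnrichmentResult:
    """Competitive permutation test of one gene set against random sets.

    ``symbol_of`` optionally maps feature IDs to gene symbols so GMT symbol
    sets can be matched against feature-indexed DE results.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = res.table["t_mod"].to_numpy()
    ids = res.table["feature_id"].to_numpy()
    labels = np.array([symbol_of.get(f, f) for f in ids]) if symbol_of else ids
    members = set(members)
    in_set = np.isin(labels, list(members))
    k = int(in_set.sum())
    if k < min_members:
        raise ValidationError(
            f"gene set {set_name or '<unnamed>'!r}: only {k} members present "
            f"among tested features (need >= {min_members})")
    score = float(t[in_set].mean())
    n = len(t)
    if k == n:
        null = np.full(n_perm, score)
    else:
        # canonical order: the realised null draws (hence p) depend only on
        # the multiset of statistics, not on input feature order
        t_sorted = t[np.argsort(labels, kind="mergesort")]
        keys = rng.random((n_perm, n))
        idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
        null = t_sorted[idx].mean(axis=1)
    p = (1.0 + np.count_nonzero(np.abs(null) >= abs(score))) / (1.0 + n_perm)
    direction = "up_in_a" if score >= 0 else "down_in_a"
    return EnrichmentResult(set_name, direction, score, float(p), k)


def bonferroni(results: list[EnrichmentResult], alpha: float = 0.05
               ) -> list[EnrichmentResult]:
    """Annotate p_bonf = min(1, p * k) and star sets with p < alpha/2
    (the two-sided display convention)."""
    if not results:
        raise ValidationError("bonferroni requires at least one result")
    k = len(results)
    for r in results:
        r.p_bonf = min(1.0, r.p * k)
        r.significant = r.p < alpha / 2.0
    return results


class CompetitiveEnrichment:
    """Model object: test every set of a collection against DE results.

    ``fit`` returns an :class:`EnrichmentResults` table with Bonferroni
    annotation.
    """

    def __init__(self, de_results: DEResults, collection: GeneSetCollection,
                 symbol_of: dict | None = None):
        self.de_results = de_results
        self.collection = collection
        self.symbol_of = symbol_of

    def fit(self, n_perm: int = 1000, seed: int = 0, alpha: float = 0.05
            ) -> "EnrichmentResults":
        rng = np.random.default_rng(seed)
        out, skipped = [], []
        for name in self.collection.names():
            try:
                out.append(competitive_test(
                    self.de_results, self.collection[name], n_perm, rng,
                    set_name=name, symbol_of=self.symbol_of))
            except ValidationError as err:
                logger.warning("skipping set %r: %s", name, err)
                skipped.append(name)
        if out:
            bonferroni(out, alpha)
        return EnrichmentResults(out, skipped, alpha, n_perm,
                                 self.de_results.contrast.label)


@dataclass
class EnrichmentResults:
    results: list[EnrichmentResult]
    skipped: list[str]
    alpha: float
    n_perm: int
    contrast: str

    def to_frame(self) -> pd.DataFrame:
        cols = ["set_name", "direction", "score", "p", "p_bonf",
                "n_genes_used", "significant"]
        return pd.DataFrame([r.to_dict() for r in self.results], columns=cols)

    def summary(self) -> str:
        lines = [
            "Competitive gene-set enrichment",
            "=" * 60,
            f"contrast: {self.contrast}   permutations: {self.n_perm}   "
            f"display threshold: p < {self.alpha / 2:g}",
        ]
        if self.skipped:
            lines.append(f"skipped (too few members): {self.skipped}")
        lines.append("-" * 60)
        frame = self.to_frame()
        if not frame.empty:
            frame = frame.assign(star=np.where(frame["significant"], "*", ""))
        lines.append(frame.to_string(index=False, float_format=lambda x: f"{x:.4g}"))
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)
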