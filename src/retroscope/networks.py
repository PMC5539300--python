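"""Coding-gene co-expression modules and their association with TE types.

Genes are standardised across samples, clustered by average-linkage
agglomeration on Euclidean distances, and the tree is cut at the smallest
height yielding the requested number of clusters of at least
``min_module_size`` genes (clusters below that size go to module 0,
"unassigned").  Each module is summarised by its eigengene -- the first
principal-component score of the standardised member genes, unit variance
across samples, sign oriented so the mean gene loading is positive (the
WGCNA convention).

Eigengenes are Pearson-correlated against TE-type abundance profiles; each
module additionally receives an immune-activity *direction* from a
competitive gene-set test of its members on a two-group contrast.  The
global concordance question -- do immune-activated modules correlate
positively with the same TE types that immune-suppressed modules correlate
negatively with? -- is answered by a 2x2 chi-square on the signs of the
significant correlation cells, split by module direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage

from .containers import ExpressionMatrix, ValidationError
from .de import DEResults
from .enrichment import competitive_test
from .quant import AggregatedTEMatrix

logger = logging.getLogger("retroscope")

ACTIVATED = "activated_in_a"
SUPPRESSED = "suppressed_in_a"
NONE = "none"


class ConcordanceError(ValidationError):
    """The 2x2 concordance table has a zero margin; the chi-square statistic
    is undefined -- use the Fisher exact fallback."""


def _standardize(values: pd.DataFrame) -> pd.DataFrame:
    """Per-row standardisation (mean 0, sample variance 1, ddof=1);
    zero-variance rows become all-zero."""
    mu = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    z = values.sub(mu, axis=0).div(sd.where(sd > 0, 1.0), axis=0)
    return z


@dataclass
class ModuleResults:
    """Fitted module structure: assignment, eigengenes, immune directions."""

    assignment: pd.Series            # gene -> module id (0 = unassigned)
    eigengene: pd.DataFrame          # modules (1..K) x samples
    direction: dict[int, str] = field(default_factory=dict)
    direction_contrast: str = ""
    cut_height: float = np.nan
    min_module_size: int = 0

    @property
    def n_modules(self) -> int:
        return int((self.assignment.max()) if len(self.assignment) else 0)

    def sizes(self) -> pd.Series:
        return self.assignment[self.assignment > 0].value_counts().sort_index()

    def genes_in(self, module: int) -> list[str]:
        return list(self.assignment.index[self.assignment == module])

    def directional_modules(self) -> list[int]:
        return [m for m, d in self.direction.items() if d != NONE]

    def summary(self) -> str:
        sizes = self.sizes()
        lines = [
            "Co-expression modules",
            "=" * 60,
            f"genes: {len(self.assignment)}   modules: {self.n_modules}   "
            f"unassigned: {int((self.assignment == 0).sum())}",
            f"cut height: {self.cut_height:.4g}   min module size: {self.min_module_size}",
            "-" * 60,
        ]
        rows = []
        for m in sizes.index:
            rows.append({"module": m, "n_genes": int(sizes[m]),
                         "direction": self.direction.get(m, "")})
        lines.append(pd.DataFrame(rows).to_string(index=False))
        if self.direction_contrast:
            lines.append(f"direction contrast: {self.direction_contrast}")
        return "\n".join(lines)


class CoexpressionNetwork:
    """Model object detecting co-expression modules in a log-expression
    matrix (genes x samples).

    Parameters
    ----------
    matrix : ExpressionMatrix
        Log-scale expression (logCPM/logTPM) of coding genes.
    min_module_size : int
        Clusters below this size are left unassigned (module 0).
    n_modules : int or "auto"
        Cut the dendrogram at the smallest height producing at least this
        many clusters of qualifying size; "auto" maximises that number.
    """

    def __init__(self, matrix: ExpressionMatrix, *, min_module_size: int = 30,
                 linkage: str = "average", n_modules: int | str = "auto"):
        if matrix.shape[1] < 3:
            raise ValidationError("module detection requires >= 3 samples")
        if matrix.shape[0] < min_module_size:
            raise ValidationError(
                f"fewer genes ({matrix.shape[0]}) than min_module_size ({min_module_size})")
        if linkage != "average":
            raise ValueError(f"unsupported linkage {linkage!r}")
        self.matrix = matrix
        self.min_module_size = min_module_size
        self.n_modules = n_modules

    def fit(self) -> ModuleResults:
        z = _standardize(self.matrix.values)
        genes = list(z.index)
        link = scipy_linkage(z.to_numpy(), method="average", metric="euclidean")
        heights = np.concatenate([[0.0], np.unique(link[:, 2])])
        # Cut at the LARGEST height still yielding the target number of
        # qualifying clusters: just below the merges that fuse modules, so
        # each cluster has absorbed its full membership.  ("auto" targets
        # the maximum achievable number of qualifying clusters.)
        best = None  # (n_big, height), maximised lexicographically
        want = None if self.n_modules == "auto" else int(self.n_modules)
        chosen = None
        for h in heights:
            labels = fcluster(link, t=h, criterion="distance")
            sizes = np.bincount(labels)
            n_big = int((sizes[1:] >= self.min_module_size).sum())
            if want is not None and n_big >= want:
                chosen = h
            key = (n_big, h)
            if best is None or key > best:
                best = key
        if chosen is None:
            chosen = best[1]
        labels = fcluster(link, t=chosen, criterion="distance")
        assignment = self._relabel(labels, genes)
        eig = eigengene(self.matrix, assignment)
        return ModuleResults(assignment, eig, cut_height=float(chosen),
                             min_module_size=self.min_module_size)

    def _relabel(self, labels: np.ndarray, genes: list[str]) -> pd.Series:
        """Number qualifying clusters 1..K by decreasing size (ties broken by
        first member position); the rest become module 0."""
        sizes: dict[int, int] = {}
        first: dict[int, int] = {}
        for i, lab in enumerate(labels):
            sizes[lab] = sizes.get(lab, 0) + 1
            first.setdefault(lab, i)
        big = [lab for lab, n in sizes.items() if n >= self.min_module_size]
        big.sort(key=lambda lab: (-sizes[lab], first[lab]))
        mapping = {lab: k for k, lab in enumerate(big, start=1)}
        out = pd.Series([mapping.get(lab, 0) for lab in labels], index=genes,
                        name="module")
        n_small = sum(n for lab, n in sizes.items() if lab not in mapping)
        if n_small:
            logger.info("module detection: %d genes in sub-threshold clusters -> module 0",
                        n_small)
        return out


def detect_modules(m: ExpressionMatrix, min_module_size: int = 30,
                   linkage: str = "average",
                   n_modules: int | str = "auto") -> ModuleResults:
    """Functional entry point; see :class:`CoexpressionNetwork`."""
    return CoexpressionNetwork(m, min_module_size=min_module_size,
                               linkage=linkage, n_modules=n_modules).fit()


def eigengene(m: ExpressionMatrix, assignment: pd.Series) -> pd.DataFrame:
    """First-PC eigengene per module, unit sample variance, mean loading
    positive.  A single-gene module's eigengene is that gene's standardised
    profile."""
    modules = sorted(set(assignment[assignment > 0]))
    rows = {}
    for k in modules:
        genes = assignment.index[assignment == k]
        if len(genes) == 0:
            raise ValidationError(f"module {k} has no genes")
        z = _standardize(m.values.loc[genes]).to_numpy()
        if len(genes) == 1:
            score = z[0]
        else:
            u, s, vt = np.linalg.svd(z, full_matrices=False)
            score = vt[0]
            if u[:, 0].mean() < 0:
                score = -score
        sd = score.std(ddof=1)
        if sd > 0:
            score = (score - score.mean()) / sd
        rows[k] = score
    return pd.DataFrame.from_dict(rows, orient="index", columns=m.sample_ids)


@dataclass
class AssociationTable:
    """Module x TE-type correlation grid plus the global concordance test."""

    r: pd.DataFrame                  # modules x TE types, NaN where undefined
    p: pd.DataFrame
    sig: pd.DataFrame                # boolean; False where r undefined
    alpha: float
    contingency: pd.DataFrame | None = None  # rows activated/suppressed, cols +/-
    chi2: float = np.nan
    chi2_p: float = np.nan
    fisher_p: float = np.nan

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for mod in self.r.index:
            for te in self.r.columns:
                rows.append({"module": mod, "te_type": te,
                             "r": self.r.loc[mod, te], "p": self.p.loc[mod, te],
                             "sig": bool(self.sig.loc[mod, te])})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            "Module x TE-type association",
            "=" * 60,
            f"cell significance: p <= {self.alpha:g}   "
            f"significant cells: {int(self.sig.to_numpy().sum())} "
            f"of {self.sig.size}",
        ]
        if self.contingency is not None:
            lines += ["-" * 60, "sign concordance (directional modules only):",
                      self.contingency.to_string(),
                      f"chi2 = {self.chi2:.4g}, p = {self.chi2_p:.4g} "
                      f"(Fisher exact p = {self.fisher_p:.4g})"]
        return "\n".join(lines)


def correlate_te(eig: pd.DataFrame, te: AggregatedTEMatrix,
                 alpha: float = 0.05) -> AssociationTable:
    """Pearson correlation of each module eigengene against each TE-type
    profile; two-sided p via t = r sqrt((n-2)/(1-r^2)) on n-2 df.

    Zero-variance TE profiles give NaN r and are never significant.
    """
    if list(eig.columns) != list(te.sample_ids):
        if set(eig.columns) != set(te.sample_ids):
            raise ValidationError("eigengene and TE matrices cover different samples")
        te_vals = te.values[list(eig.columns)]
    else:
        te_vals = te.values
    n = eig.shape[1]
    if n < 4:
        raise ValidationError(f"need >= 4 samples for correlation tests, got {n}")
    e = eig.to_numpy(dtype=float)
    t_mat = te_vals.to_numpy(dtype=float)
    ez = e - e.mean(axis=1, keepdims=True)
    tz = t_mat - t_mat.mean(axis=1, keepdims=True)
    e_sd = np.sqrt((ez ** 2).sum(axis=1))
    t_sd = np.sqrt((tz ** 2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (ez @ tz.T) / np.outer(e_sd, t_sd)
    r = np.where(np.outer(e_sd > 0, t_sd > 0), r, np.nan)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = r * np.sqrt((n - 2) / np.maximum(1.0 - r ** 2, 0.0))
    p = 2.0 * stats.t.sf(np.abs(tstat), n - 2)
    p = np.where(np.isnan(r), np.nan, np.where(np.isinf(tstat), 0.0, p))
    r_df = pd.DataFrame(r, index=eig.index, columns=te_vals.index)
    p_df = pd.DataFrame(p, index=eig.index, columns=te_vals.index)
    sig = (p_df <= alpha) & r_df.notna()
    n_na = int(np.isnan(r).sum())
    if n_na:
        logger.info("correlate_te: %d undefined cells (zero variance) flagged NA", n_na)
    return AssociationTable(r_df, p_df, sig, alpha)


def module_direction(modules: ModuleResults, de: DEResults,
                     alpha: float = 0.05, n_perm: int = 1000,
                     seed: int = 0) -> ModuleResults:
    """Assign each module an immune-activity direction from the competitive
    test of its member genes on the contrast's moderated-t values."""
    rng = np.random.default_rng(seed)
    direction: dict[int, str] = {}
    for k in range(1, modules.n_modules + 1):
        genes = modules.genes_in(k)
        try:
            res = competitive_test(de, genes, n_perm, rng, set_name=f"module_{k}")
        except ValidationError as err:
            logger.info("module %d: %s -> direction none", k, err)
            direction[k] = NONE
            continue
        if res.p <= alpha:
            direction[k] = ACTIVATED if res.score > 0 else SUPPRESSED
        else:
            direction[k] = NONE
    modules.direction = direction
    modules.direction_contrast = de.contrast.label
    return modules


def chi2_2x2(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square for a 2x2 table, df=1, no continuity correction:
    chi2 = n (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d))."""
    (a, b), (c, d) = np.asarray(table, dtype=float)
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        raise ConcordanceError(
            "2x2 contingency table has a zero margin; chi-square undefined -- "
            "use the Fisher exact p provided alongside")
    chi2 = n * (a * d - b * c) ** 2 / denom
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def concordance_chi2(assoc: AssociationTable, modules: ModuleResults,
                     te_types: list[str] | None = None) -> AssociationTable:
    """Fill the 2x2 sign-concordance table and chi-square into ``assoc``.

    Rows: module immune direction (activated / suppressed in group a).
    Columns: sign of the correlation, over significant cells only.
    ``te_types`` optionally restricts the TE types counted (default: all).
    """
    directional = modules.directional_modules()
    if not directional:
        raise ValidationError("no directional modules; concordance test undefined")
    cols = list(assoc.r.columns) if te_types is None else [
        t for t in te_types if t in assoc.r.columns]
    counts = np.zeros((2, 2), dtype=int)
    for mod in directional:
        if mod not in assoc.r.index:
            continue
        row = 0 if modules.direction[mod] == ACTIVATED else 1
        for te in cols:
            if assoc.sig.loc[mod, te]:
                col = 0 if assoc.r.loc[mod, te] > 0 else 1
                counts[row, col] += 1
    if counts.sum() == 0:
        raise ValidationError(
            "no significant correlation cells in directional modules")
    assoc.contingency = pd.DataFrame(
        counts, index=["activated", "suppressed"], columns=["positive", "negative"])
    assoc.fisher_p = float(stats.fisher_exact(counts)[1])
    chi2, p = chi2_2x2(counts)  # raises ConcordanceError on a zero margin
    assoc.chi2, assoc.chi2_p = chi2, p
    return assoc
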