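"""Moderated-t differential expression for TE transcripts, TE types, and
coding genes.

The model is the classic empirical-Bayes moderated t-statistic on log2
expression.  Per feature g a contrast effect (``logFC``) and a residual
variance s_g^2 with d degrees of freedom are computed -- from group means
and the pooled within-group variance (unpaired), or from per-patient
differences (paired).  The ensemble of variances is shrunk towards a common
prior: assuming s_g^2 ~ s0^2 * F(d, d0), the prior parameters (d0, s0^2)
are fitted by the method of moments on log s_g^2, and the posterior
variance is

    s_post^2 = (d0 * s0^2 + d * s_g^2) / (d0 + d).

The moderated statistic t_g = logFC_g / (s_post * c_n) is referred to a t
distribution with d0 + d degrees of freedom; c_n is sqrt(1/n_a + 1/n_b)
(unpaired) or sqrt(1/n_pairs) (paired).  FDR control uses
Benjamini-Hochberg step-up.

Exposed both as module-level functions (:func:`fit_de`, :func:`bh_adjust`,
:func:`lfc_quantiles`, :func:`regulator_panel`) and as a
``DifferentialExpression(...).fit() -> DEResults`` model pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .containers import ExpressionMatrix, SampleMetadata, TEAnnotation, ValidationError
from .quant import to_cpm

logger = logging.getLogger("retroscope")


@dataclass(frozen=True)
class Contrast:
    """A two-group comparison; ``logFC`` is group_a minus group_b (log2)."""

    group_a: str
    group_b: str
    paired: bool = False
    pairing_key: str = "patient_id"

    def flipped(self) -> "Contrast":
        return Contrast(self.group_b, self.group_a, self.paired, self.pairing_key)

    @property
    def label(self) -> str:
        return f"{self.group_a}_vs_{self.group_b}" + ("_paired" if self.paired else "")


# ---------------------------------------------------------------------------
# empirical-Bayes prior fit
# ---------------------------------------------------------------------------

def _trigamma_inverse(x: float, tol: float = 1e-10, max_iter: int = 100) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        raise ValueError("trigamma inverse requires x > 0")
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < tol * y:
            break
    return float(y)


def fit_variance_prior(s2: np.ndarray, d: float) -> tuple[float, float]:
    """Method-of-moments fit of (d0, s0^2) to residual variances.

    Works on z = log(s^2): under s^2 ~ s0^2 F(d, d0),
    E[z] = log s0^2 + psi(d/2) - log(d/2) - psi(d0/2) + log(d0/2) and
    Var[z] = psi'(d/2) + psi'(d0/2).  If the observed dispersion of z does
    not exceed the trigamma floor psi'(d/2), d0 = inf (complete pooling).

    Returns (d0, s0_squared); d0 may be ``numpy.inf``.
    """
    s2 = np.asarray(s2, dtype=float)
    pos = s2[s2 > 0]
    if len(pos) == 0:
        logger.warning("all residual variances are zero; using d0=inf, s0^2=0")
        return np.inf, 0.0
    if len(pos) < len(s2):
        logger.info("variance prior fit excludes %d zero variances", len(s2) - len(pos))
    z = np.log(pos)
    e = z - special.polygamma(0, d / 2.0) + np.log(d / 2.0)
    e_bar = float(np.mean(e))
    if len(e) < 2:
        return np.inf, float(np.exp(e_bar))
    v = float(np.var(e, ddof=1))
    target = v - float(special.polygamma(1, d / 2.0))
    if not np.isfinite(target) or target <= 0:
        return np.inf, float(np.exp(e_bar))
    try:
        d0 = 2.0 * _trigamma_inverse(target)
    except (ValueError, FloatingPointError):
        logger.warning("prior df estimate non-finite; falling back to d0=inf")
        return np.inf, float(np.exp(e_bar))
    if not np.isfinite(d0) or d0 <= 0:
        logger.warning("prior df estimate non-finite; falling back to d0=inf")
        return np.inf, float(np.exp(e_bar))
    log_s0 = e_bar + float(special.polygamma(0, d0 / 2.0)) - np.log(d0 / 2.0)
    return float(d0), float(np.exp(log_s0))


# ---------------------------------------------------------------------------
# BH step-up
# ---------------------------------------------------------------------------

def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValidationError("bh_adjust expects a 1-d vector")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    n = len(p)
    if n == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    # step-up: running minimum from the largest p downwards
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


# ---------------------------------------------------------------------------
# results object
# ---------------------------------------------------------------------------

@dataclass
class QuantileSummary:
    probs: np.ndarray
    values: np.ndarray
    n_features: int
    contrast: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"prob": self.probs, "abs_logFC_quantile": self.values})


@dataclass
class DEResults:
    """Per-feature moderated-t differential expression results.

    ``table`` columns: feature_id, logFC (log2), t_mod, p, fdr, mean_expr.
    """

    table: pd.DataFrame
    contrast: Contrast
    d0: float
    s0_squared: float
    df_residual: float
    n_a: int
    n_b: int
    n_pairs: int | None = None
    dropped_features: list[str] = field(default_factory=list)

    @property
    def df_total(self) -> float:
        return self.d0 + self.df_residual

    def __len__(self) -> int:
        return len(self.table)

    def lfc_quantiles(self, probs=(0.25, 0.5, 0.75, 0.9, 0.95),
                      only_significant: bool = True,
                      alpha: float = 0.05) -> QuantileSummary:
        """Empirical quantiles (type-7 interpolation) of |logFC|, optionally
        over the FDR-significant features only."""
        probs = np.asarray(probs, dtype=float)
        if (probs < 0).any() or (probs > 1).any():
            raise ValidationError("quantile probs must lie in [0, 1]")
        tab = self.table
        if only_significant:
            tab = tab[tab["fdr"] <= alpha]
        if tab.empty:
            logger.warning("lfc_quantiles: no features pass fdr <= %g; empty summary", alpha)
            return QuantileSummary(probs, np.array([]), 0, self.contrast.label)
        vals = np.quantile(np.abs(tab["logFC"].to_numpy()), probs)  # type 7 = linear
        return QuantileSummary(probs, vals, len(tab), self.contrast.label)

    def regulator_panel(self, symbols, annotation: TEAnnotation | None = None,
                        alpha: float = 0.05,
                        adjusted: bool = False) -> tuple[pd.DataFrame, list[str]]:
        """Subset results to a named gene panel (e.g. TE post-transcriptional
        regulators: ATG5, KIAA0430, LAMP2, HSP90AA1, DHX9, DHX15, ...).

        Returns (panel table with a ``significant`` flag, missing symbols).
        Unknown symbols are reported, not raised.
        """
        symbols = list(dict.fromkeys(symbols))
        if annotation is not None:
            sym_of = annotation.symbol_of()
            id_of = {v: k for k, v in sym_of.items()}
        else:
            id_of = {f: f for f in self.table["feature_id"]}
        rows, missing = [], []
        present = set(self.table["feature_id"])
        for s in symbols:
            fid = id_of.get(s)
            if fid is None or fid not in present:
                missing.append(s)
                continue
            row = self.table[self.table["feature_id"] == fid].iloc[0].to_dict()
            row["gene_symbol"] = s
            rows.append(row)
        panel = pd.DataFrame(rows, columns=list(self.table.columns) + ["gene_symbol"])
        crit = panel["fdr"] if adjusted else panel["p"]
        panel["significant"] = crit <= alpha
        return panel, missing

    def summary(self, top: int = 10) -> str:
        c = self.contrast
        lines = [
            "Moderated-t differential expression",
            "=" * 60,
            f"contrast: {c.group_a} vs {c.group_b} "
            + ("(paired)" if c.paired else "(unpaired)"),
            f"features tested: {len(self.table)}   dropped: {len(self.dropped_features)}",
            f"samples: n_a={self.n_a}, n_b={self.n_b}"
            + (f", pairs={self.n_pairs}" if self.n_pairs else ""),
            f"prior: d0={self.d0:.4g}, s0^2={self.s0_squared:.4g}; "
            f"residual df={self.df_residual:.4g}",
            "-" * 60,
        ]
        show = self.table.sort_values("p").head(top)
        lines.append(show.to_string(index=False,
                                    float_format=lambda x: f"{x:.4g}"))
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------

class DifferentialExpression:
    """Moderated-t model comparing two groups of samples.

    Accepts raw counts (converted internally to log2(1 + CPM), after
    excluding features with total count below ``min_total_count`` across the
    contrast's samples) or an already log2-transformed matrix.

    Examples
    --------
    >>> model = DifferentialExpression(counts, meta, Contrast("LSC", "Blast"))
    >>> res = model.fit()
    >>> print(res.summary())
    """

    def __init__(self, matrix: ExpressionMatrix, metadata: SampleMetadata,
                 contrast: Contrast, *, min_total_count: int = 10,
                 pseudocount: float = 1.0, library_size=None):
        self.metadata = metadata
        self.contrast = contrast
        self.min_total_count = min_total_count
        self.pseudocount = pseudocount
        # CPM must be computed against the full sequencing library: when
        # ``matrix`` is a feature subset (e.g. TE transcripts only), pass the
        # whole-matrix per-sample totals here, or compositional shifts in the
        # subset masquerade as fold changes.
        self.library_size = library_size
        self.matrix = matrix

    # -- sample selection ------------------------------------------------
    def _design(self) -> tuple[list[str], list[str], list[str] | None]:
        c = self.contrast
        meta = self.metadata
        for g in (c.group_a, c.group_b):
            if g not in meta.table["group"].values:
                raise ValidationError(f"group {g!r} not present in metadata")
        a = [s for s in meta.samples_in_group(c.group_a) if s in self.matrix.sample_ids]
        b = [s for s in meta.samples_in_group(c.group_b) if s in self.matrix.sample_ids]
        if not c.paired:
            if len(a) < 2 or len(b) < 2:
                raise ValidationError(
                    f"need >=2 samples per group; got {len(a)} vs {len(b)}")
            return a, b, None
        pat = meta.patient_of()
        pa = {pat[s]: s for s in a if pat[s]}
        pb = {pat[s]: s for s in b if pat[s]}
        patients = sorted(set(pa) & set(pb))
        incomplete = sorted((set(pa) | set(pb)) - set(patients))
        if incomplete:
            logger.warning("dropping patients without both groups: %s", incomplete)
        if len(patients) < 2:
            raise ValidationError(f"need >=2 complete pairs; got {len(patients)}")
        return [pa[p] for p in patients], [pb[p] for p in patients], patients

    def _log_expression(self, samples: list[str]) -> pd.DataFrame:
        m = self.matrix
        if m.unit == "count":
            sub = m.subset_samples(samples)
            total = sub.values.sum(axis=1)
            keep = total >= self.min_total_count
            dropped = list(sub.values.index[~keep])
            if dropped:
                logger.info("excluding %d features with total count < %d",
                            len(dropped), self.min_total_count)
            sub = sub.subset_features(sub.values.index[keep])
            self._dropped = dropped
            if self.library_size is not None:
                lib = pd.Series(self.library_size).astype(float)
                missing = [s for s in samples if s not in lib.index]
                if missing:
                    raise ValidationError(f"library_size missing samples: {missing}")
                if (lib.loc[samples] <= 0).any():
                    raise ValidationError("library_size must be positive")
                cpm_values = sub.values / lib.loc[samples] * 1e6
            else:
                cpm_values = to_cpm(sub).values
            return np.log2(self.pseudocount + cpm_values)
        if m.unit in ("logCPM", "logTPM"):
            if m.log_base not in (2, 2.0):
                raise ValidationError(
                    "moderated-t requires log2 expression; got log base "
                    f"{m.log_base}")
            vals = m.values[samples]
            keep = ~(vals == 0).all(axis=1)
            self._dropped = list(vals.index[~keep])
            if self._dropped:
                logger.info("excluding %d all-zero features", len(self._dropped))
            return vals[keep]
        raise ValidationError(f"cannot fit on unit {m.unit!r}; pass counts or log2 values")

    # -- fitting ---------------------------------------------------------
    def fit(self, prior_df_method: str = "moment") -> DEResults:
        if prior_df_method != "moment":
            raise ValueError(f"unknown prior_df_method {prior_df_method!r}")
        a, b, patients = self._design()
        logexpr = self._log_expression(a + b)
        xa = logexpr[a].to_numpy()
        xb = logexpr[b].to_numpy()
        n_a, n_b = xa.shape[1], xb.shape[1]
        if self.contrast.paired:
            diffs = xa - xb
            n = diffs.shape[1]
            logfc = diffs.mean(axis=1)
            s2 = diffs.var(axis=1, ddof=1)
            d = float(n - 1)
            c_n = np.sqrt(1.0 / n)
            n_pairs = n
        else:
            logfc = xa.mean(axis=1) - xb.mean(axis=1)
            ssa = xa.var(axis=1, ddof=1) * (n_a - 1)
            ssb = xb.var(axis=1, ddof=1) * (n_b - 1)
            d = float(n_a + n_b - 2)
            s2 = (ssa + ssb) / d
            c_n = np.sqrt(1.0 / n_a + 1.0 / n_b)
            n_pairs = None

        d0, s0_2 = fit_variance_prior(s2, d)
        if np.isinf(d0):
            s2_post = np.full_like(s2, s0_2)
            df_total = np.inf
        else:
            s2_post = (d0 * s0_2 + d * s2) / (d0 + d)
            df_total = d0 + d

        se = np.sqrt(s2_post) * c_n
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, logfc / np.where(se > 0, se, 1.0),
                         np.where(logfc == 0, 0.0, np.sign(logfc) * np.inf))
        if np.isinf(df_total):
            p = 2.0 * stats.norm.sf(np.abs(t))
        else:
            p = 2.0 * stats.t.sf(np.abs(t), df_total)
        p = np.where(np.isinf(t), 0.0, p)
        p = np.where((se == 0) & (logfc == 0), 1.0, p)

        table = pd.DataFrame({
            "feature_id": logexpr.index,
            "logFC": logfc,
            "t_mod": t,
            "p": np.clip(p, 0.0, 1.0),
            "fdr": bh_adjust(np.clip(p, 0.0, 1.0)),
            "mean_expr": logexpr.to_numpy().mean(axis=1),
        }).reset_index(drop=True)
        return DEResults(table, self.contrast, d0, s0_2, d, n_a, n_b,
                         n_pairs, getattr(self, "_dropped", []))


def fit_de(m: ExpressionMatrix, meta: SampleMetadata, contrast: Contrast,
           prior_df_method: str = "moment", **kwargs) -> DEResults:
    """Functional entry point; see :class:`DifferentialExpression`."""
    return DifferentialExpression(m, meta, contrast, **kwargs).fit(prior_df_method)


def lfc_quantiles(res: DEResults, probs=(0.25, 0.5, 0.75, 0.9, 0.95),
                  only_significant: bool = True, alpha: float = 0.05) -> QuantileSummary:
    return res.lfc_quantiles(probs, only_significant, alpha)


def regulator_panel(res: DEResults, symbols, annotation: TEAnnotation | None = None,
                    alpha: float = 0.05, adjusted: bool = False):
    return res.regulator_panel(symbols, annotation, alpha, adjusted)


#: Canonical panel of genes regulating TEs post-transcriptionally
#: (autophagy, RNA interference, zinc-finger antiviral, DExH helicases).
TE_REGULATOR_PANEL = (
    "ATG5", "KIAA0430", "CALCOCO2", "ZC3HAV1", "HNRNPL", "PABPC1",
    "LAMP2", "HSP90AA1", "DROSHA", "DICER1", "DGCR8", "DHX9", "DHX15",
)
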