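"""Moderated-t differential expression: brute-force oracles, external
cross-checks (statsmodels BH, R/limma), and statistical invariants."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, special, stats

from retroscope import (
    Contrast,
    DifferentialExpression,
    ExpressionMatrix,
    SampleMetadata,
    ValidationError,
    bh_adjust,
    fit_de,
)
from retroscope.de import QuantileSummary, fit_variance_prior


# ---------------------------------------------------------------------------
# independent brute-force oracle
# ---------------------------------------------------------------------------

def bruteforce_moderated_t(xa, xb, paired):
    """Moderated t computed with explicit loops and an independent
    (brentq-based) solve of the log-variance moment equations."""
    n_feat = xa.shape[0]
    logfc = np.zeros(n_feat)
    s2 = np.zeros(n_feat)
    if paired:
        d = xa.shape[1] - 1
        c_n = np.sqrt(1.0 / xa.shape[1])
        for g in range(n_feat):
            diffs = [xa[g, i] - xb[g, i] for i in range(xa.shape[1])]
            logfc[g] = sum(diffs) / len(diffs)
            s2[g] = sum((v - logfc[g]) ** 2 for v in diffs) / (len(diffs) - 1)
    else:
        na, nb = xa.shape[1], xb.shape[1]
        d = na + nb - 2
        c_n = np.sqrt(1.0 / na + 1.0 / nb)
        for g in range(n_feat):
            ma = sum(xa[g]) / na
            mb = sum(xb[g]) / nb
            logfc[g] = ma - mb
            ssa = sum((v - ma) ** 2 for v in xa[g])
            ssb = sum((v - mb) ** 2 for v in xb[g])
            s2[g] = (ssa + ssb) / d
    # moment fit on log s^2
    z = np.log(s2[s2 > 0])
    e = z - special.digamma(d / 2) + np.log(d / 2)
    ebar = e.mean()
    target = e.var(ddof=1) - special.polygamma(1, d / 2)
    if target <= 0:
        d0, s0 = np.inf, float(np.exp(ebar))
    else:
        y = optimize.brentq(lambda v: special.polygamma(1, v) - target, 1e-8, 1e8)
        d0 = 2 * y
        s0 = float(np.exp(ebar + special.digamma(d0 / 2) - np.log(d0 / 2)))
    if np.isinf(d0):
        s2post = np.full(n_feat, s0)
        df = np.inf
    else:
        s2post = (d0 * s0 + d * s2) / (d0 + d)
        df = d0 + d
    t = logfc / (np.sqrt(s2post) * c_n)
    if np.isinf(df):
        p = 2 * stats.norm.sf(np.abs(t))
    else:
        p = 2 * stats.t.sf(np.abs(t), df)
    return logfc, t, p, d0, s0


def _log2_matrix(values, samples, features=None):
    features = features or [f"g{i}" for i in range(values.shape[0])]
    m = ExpressionMatrix(pd.DataFrame(values, index=features, columns=samples),
                         unit="logCPM")
    m.log_base = 2.0
    return m


def _meta(samples, groups, patients=None):
    return SampleMetadata(pd.DataFrame({
        "sample_id": samples, "group": groups,
        "patient_id": patients or [""] * len(samples)}))


class TestModeratedT:
    @pytest.mark.parametrize("paired", [False, True])
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce_oracle(self, seed, paired):
        rng = np.random.default_rng(seed)
        n_feat, n = 40, 4
        samples = [f"a{i}" for i in range(n)] + [f"b{i}" for i in range(n)]
        groups = ["A"] * n + ["B"] * n
        patients = ([f"p{i}" for i in range(n)] * 2 if paired
                    else [f"q{i}" for i in range(2 * n)])
        x = rng.normal(5, 1, size=(n_feat, 2 * n))
        m = _log2_matrix(x, samples)
        res = fit_de(m, _meta(samples, groups, patients),
                     Contrast("A", "B", paired=paired))
        logfc, t, p, d0, s0 = bruteforce_moderated_t(
            x[:, :n], x[:, n:], paired)
        np.testing.assert_allclose(res.table["logFC"], logfc, atol=1e-8)
        np.testing.assert_allclose(res.table["t_mod"], t, atol=1e-8)
        np.testing.assert_allclose(res.table["p"], p, atol=1e-10)
        assert res.d0 == pytest.approx(d0, rel=1e-6)
        assert res.s0_squared == pytest.approx(s0, rel=1e-6)

    def test_null_feature_gives_zero_t_unit_p(self):
        x = np.vstack([np.array([5.0, 6.0, 7.0, 5.0, 6.0, 7.0]),
                       np.array([4.0, 5.0, 8.0, 3.0, 6.0, 9.0])])
        samples = [f"s{i}" for i in range(6)]
        m = _log2_matrix(x, samples)
        res = fit_de(m, _meta(samples, ["A"] * 3 + ["B"] * 3), Contrast("A", "B"))
        row = res.table.iloc[0]
        assert row["logFC"] == 0.0
        assert row["t_mod"] == 0.0
        assert row["p"] == pytest.approx(1.0)

    def test_infinite_prior_df_limit_matches_pooled_z(self):
        # identical s^2 everywhere -> no spread in log s^2 -> d0 = inf,
        # t reduces to logFC / (s0 * c_n)
        rng = np.random.default_rng(3)
        base = rng.normal(0, 1, size=6)
        x = np.vstack([base + rng.normal(0, 1e-9, 6) + shift
                       for shift in rng.normal(0, 2, size=25)])
        samples = [f"s{i}" for i in range(6)]
        m = _log2_matrix(x, samples)
        res = fit_de(m, _meta(samples, ["A"] * 3 + ["B"] * 3), Contrast("A", "B"))
        assert np.isinf(res.d0)
        c_n = np.sqrt(1 / 3 + 1 / 3)
        expected = res.table["logFC"] / (np.sqrt(res.s0_squared) * c_n)
        np.testing.assert_allclose(res.table["t_mod"], expected, rtol=1e-9)

    def test_group_swap_antisymmetry(self):
        rng = np.random.default_rng(5)
        x = rng.normal(5, 1, size=(30, 8))
        samples = [f"s{i}" for i in range(8)]
        meta = _meta(samples, ["A"] * 4 + ["B"] * 4)
        m = _log2_matrix(x, samples)
        fwd = fit_de(m, meta, Contrast("A", "B")).table
        rev = fit_de(m, meta, Contrast("B", "A")).table
        np.testing.assert_allclose(fwd["logFC"], -rev["logFC"], atol=1e-12)
        np.testing.assert_allclose(fwd["t_mod"], -rev["t_mod"], atol=1e-12)
        np.testing.assert_allclose(fwd["p"], rev["p"], atol=1e-12)

    def test_pairing_absorbs_patient_offsets(self):
        rng = np.random.default_rng(8)
        n_feat, n_pairs = 200, 7
        offsets = rng.normal(0, 3, size=n_pairs)
        xa = rng.normal(5, 0.5, size=(n_feat, n_pairs)) + offsets
        xb = rng.normal(5, 0.5, size=(n_feat, n_pairs)) + offsets
        samples = [f"a{i}" for i in range(n_pairs)] + [f"b{i}" for i in range(n_pairs)]
        patients = [f"p{i}" for i in range(n_pairs)] * 2
        meta = _meta(samples, ["A"] * n_pairs + ["B"] * n_pairs, patients)
        m = _log2_matrix(np.hstack([xa, xb]), samples)
        paired = fit_de(m, meta, Contrast("A", "B", paired=True))
        unpaired = fit_de(m, meta, Contrast("A", "B", paired=False))
        # residual variance absorbed by pairing (compare prior-scale s0^2)
        assert paired.s0_squared < unpaired.s0_squared / 2

    def test_incomplete_pairs_dropped_with_warning(self, caplog):
        samples = ["a1", "a2", "a3", "b1", "b2"]
        meta = _meta(samples, ["A", "A", "A", "B", "B"],
                     ["p1", "p2", "p3", "p1", "p2"])
        x = np.random.default_rng(0).normal(5, 1, size=(10, 5))
        m = _log2_matrix(x, samples)
        with caplog.at_level("WARNING", logger="retroscope"):
            res = fit_de(m, meta, Contrast("A", "B", paired=True))
        assert res.n_pairs == 2
        assert any("p3" in r.message for r in caplog.records)

    def test_too_few_samples_raises(self):
        samples = ["a1", "b1"]
        m = _log2_matrix(np.ones((5, 2)), samples)
        with pytest.raises(ValidationError, match=">=2"):
            fit_de(m, _meta(samples, ["A", "B"]), Contrast("A", "B"))


@pytest.mark.skipif(shutil.which("Rscript") is None,
                    reason="Rscript not available")
class TestAgainstLimma:
    def test_moderated_t_close_to_limma(self, tmp_path):
        """Independent cross-check: same matrix through Bioconductor limma
        (lmFit + eBayes) agrees on logFC exactly and on moderated t within
        the tolerance of the two prior-fitting routines."""
        rng = np.random.default_rng(42)
        n_feat, n = 80, 5
        x = rng.normal(6, 1, size=(n_feat, 2 * n))
        samples = [f"a{i}" for i in range(n)] + [f"b{i}" for i in range(n)]
        m = _log2_matrix(x, samples)
        res = fit_de(m, _meta(samples, ["A"] * n + ["B"] * n), Contrast("A", "B"))
        mat = tmp_path / "x.tsv"
        pd.DataFrame(x).to_csv(mat, sep="\t", index=False, header=False)
        rscript = tmp_path / "limma.R"
        rscript.write_text(f"""
suppressMessages(library(limma))
x <- as.matrix(read.delim("{mat}", header=FALSE))
design <- cbind(Intercept=1, A=c(rep(1,{n}), rep(0,{n})))
fit <- eBayes(lmFit(x, design))
out <- data.frame(logFC=fit$coefficients[,"A"], t=fit$t[,"A"], p=fit$p.value[,"A"])
write.table(out, "{tmp_path / 'out.tsv'}", sep="\\t", row.names=FALSE)
cat(fit$df.prior, fit$s2.prior, "\\n")
""")
        proc = subprocess.run(["Rscript", str(rscript)], capture_output=True,
                              text=True, timeout=300)
        assert proc.returncode == 0, proc.stderr
        limma = pd.read_csv(tmp_path / "out.tsv", sep="\t")
        np.testing.assert_allclose(res.table["logFC"], limma["logFC"], atol=1e-8)
        np.testing.assert_allclose(res.table["t_mod"], limma["t"], rtol=5e-3)
        np.testing.assert_allclose(res.table["p"], limma["p"], rtol=2e-2, atol=1e-12)


class TestVariancePrior:
    def test_known_f_distribution_recovered(self):
        rng = np.random.default_rng(1)
        d, d0, s0 = 6.0, 10.0, 2.0
        s2 = s0 * stats.f.rvs(d, d0, size=20000, random_state=rng)
        d0_hat, s0_hat = fit_variance_prior(s2, d)
        assert d0_hat == pytest.approx(d0, rel=0.15)
        assert s0_hat == pytest.approx(s0, rel=0.05)

    def test_degenerate_spread_gives_infinite_df(self):
        d, val = 5.0, 3.0
        d0, s0 = fit_variance_prior(np.full(50, val), d=d)
        assert np.isinf(d0)
        # log s^2 is downward-biased by digamma(d/2) - log(d/2); the moment
        # estimator corrects for it
        expected = float(np.exp(np.log(val) - special.digamma(d / 2)
                                + np.log(d / 2)))
        assert s0 == pytest.approx(expected, rel=1e-9)
        assert s0 > val


class TestBH:
    def test_worked_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.9]),
                                   [0.03, 0.03, 0.9])

    def test_ties_all_equal(self):
        np.testing.assert_allclose(bh_adjust([0.2] * 5), [0.2] * 5)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_independent_stepup(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=rng.integers(1, 60))
        # independent step-up oracle, explicit loop
        order = sorted(range(len(p)), key=lambda i: p[i])
        n = len(p)
        adj = [None] * n
        running = 1.0
        for rank in range(n, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * n / rank)
            adj[i] = running
        np.testing.assert_allclose(bh_adjust(p), adj, atol=1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(9)
        p = rng.uniform(size=100)
        np.testing.assert_allclose(bh_adjust(p),
                                   multipletests(p, method="fdr_bh")[1],
                                   atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.5])


class TestQuantilesAndPanel:
    def _results(self, logfc, fdr=None):
        n = len(logfc)
        table = pd.DataFrame({
            "feature_id": [f"g{i}" for i in range(n)],
            "logFC": logfc, "t_mod": np.zeros(n),
            "p": np.zeros(n), "fdr": fdr if fdr is not None else np.zeros(n),
            "mean_expr": np.zeros(n)})
        from retroscope.de import DEResults
        return DEResults(table, Contrast("A", "B"), 4.0, 1.0, 4.0, 3, 3)

    def test_median_of_symmetric_pair(self):
        qs = self._results([-2.0, 2.0]).lfc_quantiles(probs=[0.5])
        np.testing.assert_allclose(qs.values, [2.0])

    def test_all_zero(self):
        qs = self._results([0.0] * 5).lfc_quantiles(probs=[0.1, 0.9])
        np.testing.assert_allclose(qs.values, [0.0, 0.0])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_sorted_interpolation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        logfc = rng.normal(0, 2, size=37)
        probs = np.sort(rng.uniform(size=5))
        qs = self._results(logfc).lfc_quantiles(probs=probs,
                                                only_significant=False)
        # type-7 oracle: h = (n-1)p, linear interpolation on sorted values
        v = np.sort(np.abs(logfc))
        expected = []
        for p in probs:
            h = (len(v) - 1) * p
            lo = int(np.floor(h))
            hi = min(lo + 1, len(v) - 1)
            expected.append(v[lo] + (h - lo) * (v[hi] - v[lo]))
        np.testing.assert_allclose(qs.values, expected, atol=1e-12)

    def test_empty_after_filter_warns(self, caplog):
        res = self._results([1.0, 2.0], fdr=[0.5, 0.9])
        with caplog.at_level("WARNING", logger="retroscope"):
            qs = res.lfc_quantiles(alpha=0.05)
        assert isinstance(qs, QuantileSummary)
        assert qs.n_features == 0

    def test_panel_missing_symbol_reported(self):
        res = self._results([1.0])
        panel, missing = res.regulator_panel({"ATG5"})
        assert panel.empty
        assert missing == ["ATG5"]

    def test_panel_identity_when_all_features_requested(self):
        res = self._results([1.0, -1.0, 0.5])
        panel, missing = res.regulator_panel(["g0", "g1", "g2"])
        assert missing == []
        assert list(panel["feature_id"]) == ["g0", "g1", "g2"]
        np.testing.assert_allclose(panel["logFC"], res.table["logFC"])
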