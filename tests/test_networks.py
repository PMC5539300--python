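"""Co-expression modules, eigengenes, TE association, and the concordance
chi-square: planted-partition recovery, SVD/correlation/chi-square oracles,
and direction antisymmetry."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from retroscope import (
    AggregatedTEMatrix,
    Contrast,
    ExpressionMatrix,
    ValidationError,
    chi2_2x2,
    concordance_chi2,
    correlate_te,
    detect_modules,
    eigengene,
    module_direction,
)
from retroscope.de import DEResults
from retroscope.networks import ACTIVATED, NONE, SUPPRESSED, ConcordanceError, ModuleResults


def _log_matrix(values, features=None, samples=None):
    features = features or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    m = ExpressionMatrix(pd.DataFrame(values, index=features, columns=samples),
                         unit="logCPM")
    m.log_base = 2.0
    return m


def _two_block_matrix(seed=0, n_per_block=50, n_samples=12, noise=0.1):
    rng = np.random.default_rng(seed)
    f1, f2 = rng.standard_normal(n_samples), rng.standard_normal(n_samples)
    rows = [5 + f1 + rng.normal(0, noise, n_samples) for _ in range(n_per_block)]
    rows += [5 + f2 + rng.normal(0, noise, n_samples) for _ in range(n_per_block)]
    return _log_matrix(np.array(rows))


class TestDetectModules:
    def test_two_planted_blocks_recovered_exactly(self):
        from retroscope.experiments import adjusted_rand_index
        m = _two_block_matrix()
        mods = detect_modules(m, min_module_size=20)
        truth = [1] * 50 + [2] * 50
        assert mods.n_modules == 2
        assert adjusted_rand_index(truth, mods.assignment.to_numpy()) == 1.0

    def test_identical_profiles_form_one_module(self):
        rng = np.random.default_rng(1)
        profile = rng.standard_normal(8)
        m = _log_matrix(np.tile(profile, (40, 1)))
        mods = detect_modules(m, min_module_size=10)
        assert mods.n_modules == 1
        assert (mods.assignment == 1).all()

    def test_gene_order_invariance_up_to_relabeling(self):
        m = _two_block_matrix(seed=3)
        mods = detect_modules(m, min_module_size=20)
        rng = np.random.default_rng(5)
        perm = rng.permutation(m.shape[0])
        m2 = ExpressionMatrix(m.values.iloc[perm], unit="logCPM", log_base=2.0)
        mods2 = detect_modules(m2, min_module_size=20)
        from retroscope.experiments import adjusted_rand_index
        a = mods.assignment.loc[m.feature_ids].to_numpy()
        b = mods2.assignment.loc[m.feature_ids].to_numpy()
        assert adjusted_rand_index(a, b) == 1.0

    def test_too_few_samples_rejected(self):
        m = _log_matrix(np.random.default_rng(0).normal(size=(50, 2)))
        with pytest.raises(ValidationError, match="samples"):
            detect_modules(m, min_module_size=10)


class TestEigengene:
    def test_identical_genes_reproduce_shared_profile(self):
        rng = np.random.default_rng(2)
        profile = rng.standard_normal(10)
        m = _log_matrix(np.tile(profile, (15, 1)))
        assignment = pd.Series([1] * 15, index=m.feature_ids)
        eig = eigengene(m, assignment)
        z = (profile - profile.mean()) / profile.std(ddof=1)
        np.testing.assert_allclose(eig.loc[1].to_numpy(), z, atol=1e-9)

    def test_sign_orientation_antisymmetric_under_negation(self):
        # mean-loading-positive orientation tracks the genes: negating every
        # gene negates the module's activity summary
        rng = np.random.default_rng(4)
        m = _log_matrix(rng.normal(size=(20, 9)))
        assignment = pd.Series([1] * 20, index=m.feature_ids)
        eig = eigengene(m, assignment)
        neg = ExpressionMatrix(-m.values, unit="logCPM", log_base=2.0)
        eig_neg = eigengene(neg, assignment)
        np.testing.assert_allclose(eig.loc[1], -eig_neg.loc[1], atol=1e-9)

    def test_single_gene_module_is_standardized_profile(self):
        rng = np.random.default_rng(6)
        m = _log_matrix(rng.normal(size=(1, 7)))
        eig = eigengene(m, pd.Series([1], index=m.feature_ids))
        x = m.values.iloc[0]
        np.testing.assert_allclose(eig.loc[1], (x - x.mean()) / x.std(ddof=1),
                                   atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_svd(self, seed):
        rng = np.random.default_rng(seed)
        m = _log_matrix(rng.normal(size=(25, 8)))
        assignment = pd.Series([1] * 25, index=m.feature_ids)
        eig = eigengene(m, assignment).loc[1].to_numpy()
        # oracle: SVD of the standardized matrix, scores scaled to unit var
        x = m.values.to_numpy()
        z = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, ddof=1,
                                                        keepdims=True)
        u, s, vt = np.linalg.svd(z)
        score = vt[0] / vt[0].std(ddof=1)
        match_pos = np.allclose(eig, score - score.mean(), atol=1e-8)
        match_neg = np.allclose(eig, -(score - score.mean()), atol=1e-8)
        assert match_pos or match_neg
        # the convention fixes the sign: mean loading positive
        genes_corr = np.mean([np.corrcoef(z[i], eig)[0, 1] for i in range(25)])
        assert genes_corr >= 0


def _te_matrix(values, types=None, samples=None):
    types = types or [f"T{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    return AggregatedTEMatrix(
        pd.DataFrame(values, index=types, columns=samples),
        unit="logCPM", level="type",
        parent_map={t: "C" for t in types}, log_base=10.0)


class TestCorrelateTE:
    def test_identical_profile_perfect_correlation(self):
        rng = np.random.default_rng(0)
        prof = rng.normal(size=6)
        eig = pd.DataFrame([prof], index=[1], columns=[f"s{i}" for i in range(6)])
        te = _te_matrix(np.array([prof]))
        tab = correlate_te(eig, te)
        assert tab.r.iloc[0, 0] == pytest.approx(1.0)
        assert bool(tab.sig.iloc[0, 0])

    def test_orthogonal_profile_r_zero(self):
        eig = pd.DataFrame([[1.0, -1.0, 1.0, -1.0]], index=[1],
                           columns=list("abcd"))
        te = _te_matrix(np.array([[1.0, 1.0, -1.0, -1.0]]), samples=list("abcd"))
        tab = correlate_te(eig, te)
        assert tab.r.iloc[0, 0] == pytest.approx(0.0, abs=1e-12)
        assert tab.p.iloc[0, 0] == pytest.approx(1.0)

    def test_zero_variance_te_flagged_na(self):
        rng = np.random.default_rng(1)
        eig = pd.DataFrame(rng.normal(size=(1, 5)), index=[1],
                           columns=[f"s{i}" for i in range(5)])
        te = _te_matrix(np.ones((1, 5)))
        tab = correlate_te(eig, te)
        assert np.isnan(tab.r.iloc[0, 0])
        assert not bool(tab.sig.iloc[0, 0])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scipy_pearson_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 12
        eig = pd.DataFrame(rng.normal(size=(4, n)), index=[1, 2, 3, 4],
                           columns=[f"s{i}" for i in range(n)])
        te = _te_matrix(rng.normal(size=(6, n)))
        tab = correlate_te(eig, te)
        for k in eig.index:
            for t in te.values.index:
                r, p = stats.pearsonr(eig.loc[k], te.values.loc[t])
                assert tab.r.loc[k, t] == pytest.approx(r, abs=1e-10)
                assert tab.p.loc[k, t] == pytest.approx(p, abs=1e-10)


class TestModuleDirection:
    def _de(self, t_values):
        n = len(t_values)
        table = pd.DataFrame({
            "feature_id": [f"g{i}" for i in range(n)], "logFC": np.zeros(n),
            "t_mod": t_values, "p": np.zeros(n), "fdr": np.zeros(n),
            "mean_expr": np.zeros(n)})
        return DEResults(table, Contrast("A", "B"), 4.0, 1.0, 4.0, 3, 3)

    def _modules(self, assignment_list):
        genes = [f"g{i}" for i in range(len(assignment_list))]
        assignment = pd.Series(assignment_list, index=genes)
        eig = pd.DataFrame(np.zeros((max(assignment_list), 3)),
                           index=range(1, max(assignment_list) + 1),
                           columns=["a", "b", "c"])
        return ModuleResults(assignment, eig)

    def test_planted_up_module_activated(self):
        rng = np.random.default_rng(0)
        t = rng.normal(size=300)
        t[:30] += 2.0
        mods = self._modules([1] * 30 + [0] * 270)
        out = module_direction(mods, self._de(t), n_perm=500, seed=1)
        assert out.direction[1] == ACTIVATED

    def test_contrast_swap_flips_directions(self):
        rng = np.random.default_rng(3)
        t = rng.normal(size=300)
        t[:30] += 2.0
        t[30:60] -= 2.0
        mods = self._modules([1] * 30 + [2] * 30 + [0] * 240)
        fwd = module_direction(self._modules([1] * 30 + [2] * 30 + [0] * 240),
                               self._de(t), n_perm=500, seed=1).direction
        rev = module_direction(mods, self._de(-t), n_perm=500, seed=1).direction
        flip = {ACTIVATED: SUPPRESSED, SUPPRESSED: ACTIVATED, NONE: NONE}
        assert rev == {k: flip[v] for k, v in fwd.items()}

    def test_null_independent_gene_module_mostly_none(self):
        hits = 0
        n_runs = 100
        for seed in range(n_runs):
            rng = np.random.default_rng(seed)
            t = rng.normal(size=400)
            mods = self._modules([1] * 30 + [0] * 370)
            out = module_direction(mods, self._de(t), n_perm=300, seed=seed)
            hits += out.direction[1] == NONE
        assert hits >= 90

    def test_small_module_gets_none(self, caplog):
        rng = np.random.default_rng(5)
        t = rng.normal(size=100)
        mods = self._modules([1] * 3 + [0] * 97)
        with caplog.at_level("INFO", logger="retroscope"):
            out = module_direction(mods, self._de(t), n_perm=100, seed=0)
        assert out.direction[1] == NONE


class TestConcordanceChi2:
    def test_perfect_diagonal_closed_form(self):
        chi2, p = chi2_2x2(np.array([[10, 0], [0, 10]]))
        assert chi2 == pytest.approx(20.0)
        assert p == pytest.approx(stats.chi2.sf(20.0, 1))

    def test_perfect_independence(self):
        chi2, p = chi2_2x2(np.array([[5, 5], [5, 5]]))
        assert chi2 == 0.0
        assert p == 1.0

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_scipy_oracle(self, seed):
        rng = np.random.default_rng(seed)
        tab = rng.integers(1, 30, size=(2, 2))
        chi2, p = chi2_2x2(tab)
        expected = stats.chi2_contingency(tab, correction=False)
        assert chi2 == pytest.approx(expected.statistic, rel=1e-12)
        assert p == pytest.approx(expected.pvalue, abs=1e-12)

    def test_zero_margin_raises_with_fisher_advice(self):
        with pytest.raises(ConcordanceError, match="Fisher"):
            chi2_2x2(np.array([[3, 2], [0, 0]]))

    def test_full_table_construction_and_fisher_fallback(self):
        """Contingency counts significant cells of directional modules; the
        Fisher exact p is attached even when the chi-square is defined."""
        r = pd.DataFrame([[0.9, -0.9, 0.1], [-0.9, 0.9, 0.2]],
                         index=[1, 2], columns=["Alu", "L1", "MIR"])
        p = pd.DataFrame([[0.01, 0.01, 0.8], [0.01, 0.01, 0.7]],
                         index=[1, 2], columns=["Alu", "L1", "MIR"])
        sig = p <= 0.05
        from retroscope.networks import AssociationTable
        assoc = AssociationTable(r, p, sig, alpha=0.05)
        genes = [f"g{i}" for i in range(4)]
        mods = ModuleResults(pd.Series([1, 1, 2, 2], index=genes),
                             eigengene=pd.DataFrame())
        mods.direction = {1: ACTIVATED, 2: SUPPRESSED}
        out = concordance_chi2(assoc, mods)
        np.testing.assert_array_equal(out.contingency.to_numpy(),
                                      [[1, 1], [1, 1]])
        assert out.chi2 == 0.0
        assert out.fisher_p == pytest.approx(
            stats.fisher_exact([[1, 1], [1, 1]])[1])

    def test_no_directional_modules_rejected(self):
        from retroscope.networks import AssociationTable
        r = pd.DataFrame([[0.9]], index=[1], columns=["Alu"])
        assoc = AssociationTable(r, r * 0.01, r > 0, alpha=0.05)
        mods = ModuleResults(pd.Series([1], index=["g0"]),
                             eigengene=pd.DataFrame())
        mods.direction = {1: NONE}
        with pytest.raises(ValidationError, match="directional"):
            concordance_chi2(assoc, mods)
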