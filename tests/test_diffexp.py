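import itertools

import numpy as np
import pytest
import scipy.sparse as sp
import scipy.stats as st

from tmecrosstalk import diffexp, preprocess, synthdata
from tmecrosstalk.io import CountMatrix
from tmecrosstalk.preprocess import NormMatrix


def _counts(x):
    x = np.asarray(x)
    return CountMatrix(sp.csr_matrix(x),
                       [f"g{i}" for i in range(x.shape[0])],
                       [f"c{j}" for j in range(x.shape[1])])


def _masks(n_a, n_b):
    a = np.zeros(n_a + n_b, dtype=bool)
    a[:n_a] = True
    return a, ~a


class TestExactTest:
    def test_all_zero_genes_give_p_one(self):
        cm = _counts(np.zeros((5, 8), dtype=int))
        a, b = _masks(4, 4)
        with pytest.raises(ValueError):
            # all-zero cells have zero totals: size factors undefined
            diffexp.sseq_test(cm, a, b)
        # with one expressed gene the rest are all-zero and get p = 1
        x = np.zeros((5, 8), dtype=int)
        x[0] = 1
        res = diffexp.sseq_test(_counts(x), a, b)
        assert (res.p_value[1:] == 1.0).all()
        assert (res.log2fc[1:] == 0.0).all()

    def test_poisson_limit_matches_conditional_binomial(self):
        """phi = 0: the exact test is the conditional binomial test.

        Checked against the closed form for every split of every total
        up to 30 (criterion: agreement to 1e-10).
        """
        sf_a = np.ones(7)
        sf_b = np.ones(5)
        pr = sf_a.sum() / (sf_a.sum() + sf_b.sum())
        for t in range(31):
            pmf = st.binom.pmf(np.arange(t + 1), t, pr)
            for ka in range(t + 1):
                oracle = pmf[pmf <= pmf[ka] * (1 + 1e-12)].sum()
                got = diffexp.nb_exact_pvalue(ka, t - ka, 2.0, 0.0,
                                              sf_a, sf_b)
                assert got == pytest.approx(oracle, abs=1e-10)

    def test_matches_bruteforce_split_enumeration(self):
        """NB exact p agrees with direct enumeration of all splits."""
        rng = np.random.default_rng(17)
        sf_a = rng.uniform(0.5, 2.0, 6)
        sf_b = rng.uniform(0.5, 2.0, 4)
        for ka, kb, mu0, phi in [(3, 9, 1.0, 0.2), (10, 2, 0.8, 0.5),
                                 (0, 7, 0.5, 0.1), (15, 15, 2.0, 0.05)]:
            t = ka + kb
            m_a, v_a = diffexp._sum_nb_params(mu0, phi, sf_a)
            m_b, v_b = diffexp._sum_nb_params(mu0, phi, sf_b)

            def nbpmf(k, m, v):
                r = m * m / (v - m)
                return st.nbinom.pmf(k, r, r / (r + m))

            probs = np.array([nbpmf(a, m_a, v_a) * nbpmf(t - a, m_b, v_b)
                              for a in range(t + 1)])
            oracle = probs[probs <= probs[ka] * (1 + 1e-12)].sum() / probs.sum()
            got = diffexp.nb_exact_pvalue(ka, kb, mu0, phi, sf_a, sf_b)
            assert got == pytest.approx(oracle, rel=1e-9)

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(3)
        cm = _counts(rng.poisson(4.0, size=(30, 20)))
        a, b = _masks(12, 8)
        ab = diffexp.sseq_test(cm, a, b)
        ba = diffexp.sseq_test(cm, b, a)
        np.testing.assert_allclose(ab.p_value, ba.p_value, rtol=1e-9)
        np.testing.assert_allclose(ab.log2fc, -ba.log2fc, atol=1e-12)

    def test_null_calibration(self):
        """2,000 null NB genes (mu=5, phi=0.1, 50 vs 50): empirical
        type-I error at alpha = 0.05 lies in [0.03, 0.07]."""
        cm, a, b = synthdata.simulate_null_counts(2000, 5.0, 0.1, 50, 50,
                                                  seed=211)
        res = diffexp.sseq_test(cm, a, b)
        frac = float((res.p_value < 0.05).mean())
        assert 0.03 <= frac <= 0.07

    def test_empty_group_rejected(self):
        cm = _counts(np.ones((3, 4), dtype=int))
        with pytest.raises(ValueError, match="non-empty"):
            diffexp.sseq_test(cm, np.zeros(4, dtype=bool),
                              np.ones(4, dtype=bool))


class TestDispersionShrinkage:
    def test_shrunk_between_estimate_and_target(self):
        rng = np.random.default_rng(23)
        cm = _counts(rng.negative_binomial(5, 0.5, size=(200, 60)))
        a, b = _masks(30, 30)
        res = diffexp.sseq_test(cm, a, b)
        xi = res.attrs["shrinkage_target"]
        lo = np.minimum(res.dispersion_mm, xi) - 1e-12
        hi = np.maximum(res.dispersion_mm, xi) + 1e-12
        assert ((res.dispersion_shrunk >= lo)
                & (res.dispersion_shrunk <= hi)).all()

    def test_weight_in_unit_interval(self):
        rng = np.random.default_rng(24)
        cm = _counts(rng.poisson(3.0, size=(100, 40)))
        res = diffexp.sseq_test(cm, *_masks(20, 20))
        assert 0.0 <= res.attrs["shrinkage_weight"] <= 1.0


class TestMWU:
    def _norm(self, xa, xb):
        x = np.concatenate([xa, xb], axis=1)
        return NormMatrix(x, [f"g{i}" for i in range(x.shape[0])],
                          [f"c{j}" for j in range(x.shape[1])],
                          np.ones(x.shape[1])), \
            _masks(xa.shape[1], xb.shape[1])

    def test_identical_groups_p_one(self):
        xa = np.tile([[1.0], [2.0]], (1, 5))
        norm, (a, b) = self._norm(xa, xa)
        res = diffexp.mwu_test(norm, a, b)
        assert (res.p_value == 1.0).all()

    def test_complete_separation_exact_p(self):
        # (1,2,3) vs (4,5,6): U = 0; exact two-sided p = 2 * 1/C(6,3) = 0.1
        norm, (a, b) = self._norm(np.array([[1.0, 2.0, 3.0]]),
                                  np.array([[4.0, 5.0, 6.0]]))
        res = diffexp.mwu_test(norm, a, b)
        assert res.p_value.iloc[0] == pytest.approx(0.1)

    def test_exact_p_matches_permutation_enumeration(self):
        vals = np.array([0.3, 1.1, 2.0, 2.7, 3.5, 4.2])
        norm, (a, b) = self._norm(vals[None, :3], vals[None, 3:])
        res = diffexp.mwu_test(norm, a, b)
        # enumerate all 20 assignments of the 6 values to group A
        obs_u = st.mannwhitneyu(vals[:3], vals[3:]).statistic
        n1n2 = 9
        extreme = 0
        total = 0
        for comb in itertools.combinations(range(6), 3):
            rest = [i for i in range(6) if i not in comb]
            u = st.mannwhitneyu(vals[list(comb)], vals[rest]).statistic
            total += 1
            if min(u, n1n2 - u) <= min(obs_u, n1n2 - obs_u):
                extreme += 1
        assert res.p_value.iloc[0] == pytest.approx(extreme / total)

    def test_shift_alternative_power(self):
        rng = np.random.default_rng(41)
        n_genes = 200
        xa = rng.normal(0.0, 1.0, size=(n_genes, 200))
        xb = rng.normal(1.0, 1.0, size=(n_genes, 200))
        norm, (a, b) = self._norm(xa, xb)
        res = diffexp.mwu_test(norm, a, b)
        assert (res.p_value < 0.05).mean() > 0.9


class TestOneVsRest:
    def test_two_labels_mirrored_log2fc(self):
        rng = np.random.default_rng(51)
        cm = _counts(rng.poisson(4.0, size=(50, 30)))
        labels = np.array(["A"] * 18 + ["B"] * 12)
        res = diffexp.one_vs_rest(cm, labels)
        merged = res["A"].sort_index()["log2fc"] + \
            res["B"].sort_index()["log2fc"]
        np.testing.assert_allclose(merged, 0.0, atol=1e-12)

    def test_planted_signatures_recovered(self, macrophage_scenario):
        sub, _, true_state = macrophage_scenario
        res = diffexp.one_vs_rest(sub, true_state.to_numpy(), lfc_min=0.0)
        for state in ("IL1B", "SPP1", "C1QC"):
            table = res[state]
            up = table[table["log2fc"] > 0]
            top = set(up.head(40)["gene"])
            # planted program genes: the hallmark plus its block of 29
            start = sub.gene_ids.index(state)
            program = set(sub.gene_ids[start:start + 30])
            recall = len(top & program) / len(program)
            assert recall >= 0.9

    def test_singleton_label_skipped(self):
        rng = np.random.default_rng(52)
        cm = _counts(rng.poisson(4.0, size=(20, 11)))
        labels = np.array(["A"] * 10 + ["B"])
        with pytest.warns(UserWarning, match="skipped"):
            res = diffexp.one_vs_rest(cm, labels)
        assert "B" not in res


class TestFDR:
    def test_bh_monotone_in_alpha(self):
        rng = np.random.default_rng(61)
        x = rng.poisson(3.0, size=(300, 60))
        x[:30, :30] *= 4
        cm = _counts(x)
        a, b = _masks(30, 30)
        strict = diffexp.sseq_test(cm, a, b, alpha=0.01)
        loose = diffexp.sseq_test(cm, a, b, alpha=0.05)
        assert set(strict.index[strict.significant]) <= \
            set(loose.index[loose.significant])

    def test_untested_genes_excluded_from_fdr(self):
        x = np.zeros((4, 10), dtype=int)
        x[0] = 5
        x[1, 0] = 1  # detected in a single cell: below min_cells
        res = diffexp.sseq_test(_counts(x), *_masks(5, 5))
        assert not res.loc["g1", "tested"]
        assert np.isnan(res.loc["g1", "fdr"])
        assert res.loc["g1", "p_value"] == 1.0
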