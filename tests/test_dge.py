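"""Moderated t, BH adjustment and DEG selection against independent oracles."""

from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bloodstage import (
    SimulationConfig,
    bh_adjust,
    generate_cohort,
    generate_signatures,
    moderated_t_test,
    run_contrasts,
    select_degs,
)
from bloodstage.dge import trigamma_inverse
from conftest import make_annotation, make_expression


def _two_group_matrix(rng, n_genes=50, n_per=5):
    X = make_expression(rng.normal(8.0, 1.0, size=(n_genes, 2 * n_per)), scale="log2")
    ann = make_annotation(["CON"] * n_per + ["AD"] * n_per, prefix="c1_s")
    return X, ann


class TestModeratedT:
    def test_d0_zero_equals_ordinary_pooled_t(self, rng):
        X, ann = _two_group_matrix(rng, n_genes=1000)
        res = moderated_t_test(X, ann, ("AD", "CON"), d0_override=0.0)
        a = X.values.iloc[:, 5:].to_numpy()
        b = X.values.iloc[:, :5].to_numpy()
        t_ref, p_ref = stats.ttest_ind(a, b, axis=1, equal_var=True)
        np.testing.assert_allclose(res.table["t"], t_ref, atol=1e-10)
        np.testing.assert_allclose(res.table["p"], p_ref, atol=1e-10)

    def test_shrunk_variance_on_zero_variance_gene(self):
        """2v2 with within-group variance 0: t = delta / (s_tilde * sqrt(1))
        where s_tilde^2 = d0*s0^2/(d0+2), evaluated by hand."""
        r = np.random.default_rng(0)
        # heterogeneous gene variances so the prior df comes out finite
        filler = 3.0 + r.normal(size=(15, 4)) * np.exp(r.normal(0, 1.5, size=(15, 1)))
        vals = np.vstack([[0.0, 0.0, 1.0, 1.0], filler])
        X = make_expression(vals, scale="log2")
        ann = make_annotation(["CON", "CON", "AD", "AD"], prefix="c1_s")
        res = moderated_t_test(X, ann, ("AD", "CON"))
        d0, s0 = res.d0, res.s0_sq
        assert d0 > 0
        s_tilde = np.sqrt(d0 * s0 / (d0 + 2))
        expected_t = 1.0 / (s_tilde * np.sqrt(0.5 + 0.5))
        assert res.table["t"].iloc[0] == pytest.approx(expected_t, rel=1e-12)
        assert np.isfinite(res.table["t"]).all()

    def test_identical_group_means_give_t0_p1(self):
        vals = np.vstack([np.array([3.0, 5.0, 3.0, 5.0])] * 12)
        vals += np.arange(12)[:, None] * 0.1  # distinct genes, same group means
        X = make_expression(vals, scale="log2")
        ann = make_annotation(["CON", "CON", "AD", "AD"], prefix="c1_s")
        res = moderated_t_test(X, ann, ("AD", "CON"))
        np.testing.assert_allclose(res.table["t"], 0.0, atol=1e-12)
        np.testing.assert_allclose(res.table["p"], 1.0, atol=1e-12)

    def test_limits_of_shrinkage(self, rng):
        """d0 -> infinity pins the posterior variance at s0^2."""
        X, ann = _two_group_matrix(rng, n_genes=200)
        res = moderated_t_test(X, ann, ("AD", "CON"), d0_override=1e8)
        delta = res.table["delta"].to_numpy()
        se = np.sqrt(res.s0_sq * (1 / 5 + 1 / 5))
        # at d0=1e8 the pooled s2 contributes ~1e-8 of the posterior
        np.testing.assert_allclose(res.table["t"], delta / se, rtol=1e-6)

    def test_small_group_raises(self, rng):
        X, _ = _two_group_matrix(rng)
        ann = make_annotation(["CON"] + ["AD"] * 9, prefix="c1_s")
        with pytest.raises(ValueError, match=">=2 samples"):
            moderated_t_test(X, ann, ("AD", "CON"))

    def test_invariance_to_gene_constant_shift(self, rng):
        X, ann = _two_group_matrix(rng)
        res1 = moderated_t_test(X, ann, ("AD", "CON"))
        X2 = X.copy()
        X2.values.iloc[0] += 100.0  # same constant added to all samples of a gene
        res2 = moderated_t_test(X2, ann, ("AD", "CON"))
        np.testing.assert_allclose(res1.table["t"], res2.table["t"], rtol=1e-9)

    def test_trigamma_inverse_roundtrip(self):
        from scipy.special import polygamma

        for y in [1e-5, 0.01, 0.5, 2.0, 100.0, 1e6]:
            x = trigamma_inverse(y)
            assert polygamma(1, x) == pytest.approx(y, rel=1e-6)


def bh_bruteforce(p):
    """Literal step-up definition: find largest i with p_(i) <= i*a/m by
    scanning every alpha; equivalently q_i = min over j>=rank(i) of m*p_(j)/j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    for pos, idx in enumerate(order):
        candidates = [m * p[order[j]] / (j + 1) for j in range(pos, m)]
        q[idx] = min(1.0, min(candidates))
    return q


class TestBHAdjust:
    def test_hand_worked_example(self):
        np.testing.assert_allclose(bh_adjust(np.array([0.01, 0.04, 0.03])), [0.03, 0.04, 0.04])

    def test_edge_cases(self):
        np.testing.assert_allclose(bh_adjust(np.ones(5)), 1.0)
        np.testing.assert_allclose(bh_adjust(np.array([0.2])), [0.2])
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.5, 1.5]))

    def test_matches_bruteforce_on_all_permutations(self):
        base = [0.001, 0.02, 0.02, 0.3, 0.77, 1.0]
        for perm in set(permutations(base)):
            p = np.array(perm)
            np.testing.assert_allclose(bh_adjust(p), bh_bruteforce(p), atol=1e-12)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=200)
        _, q_ref, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(bh_adjust(p), q_ref, atol=1e-12)


class TestSelectDegs:
    def test_thresholds(self, rng):
        X, ann = _two_group_matrix(rng)
        results = {("AD", "CON"): moderated_t_test(X, ann, ("AD", "CON"))}
        per, union = select_degs(results, q_threshold=0.0)
        assert union == [] or all(
            results[("AD", "CON")].table.loc[g, "q"] == 0 for g in union
        )

    def test_planted_de_sensitivity(self):
        """Strong planted effects are recovered at q <= 0.05 in the union."""
        cfg = SimulationConfig(
            n_genes=400, n_celltypes=5, genes_per_signature=6,
            group_sizes={"CON": 15, "MCI": 15, "AD": 15},
            n_de_genes=30, de_effect_size=1.0, seed=3,
        )
        S = generate_signatures(cfg)
        hits = total = 0
        for rep in range(5):
            X, ann, truth = generate_cohort(cfg, S, "c1", noise_seed=100 + rep)
            from bloodstage import log_transform, normalize_library_size

            L = log_transform(normalize_library_size(X))
            _, union = select_degs(run_contrasts(L, ann), q_threshold=0.05)
            planted = set(truth.de_genes["gene"])
            hits += len(planted & set(union))
            total += len(planted)
        assert hits / total >= 0.9
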