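"""Permutation tests, FDR, partial correlation, NBS, group reports."""

import numpy as np
import pytest

from morphkls import (
    cohens_d,
    compare_groups,
    fdr_correct,
    nbs,
    partial_correlation,
    permutation_test,
    permutation_test_matrix,
)

from . import oracles


class TestPermutationTest:
    def test_identical_constant_groups_p_one(self):
        d, p = permutation_test([1.0] * 5, [1.0] * 5, n_perm=200, seed=0)
        assert d == 0.0 and p == 1.0

    def test_strong_shift_detected(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 20)
        b = rng.normal(1.5, 1, 20)
        _, p = permutation_test(a, b, n_perm=999, seed=2)
        assert p < 0.01

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 10), rng.normal(0, 1, 10)
        assert permutation_test(a, b, 500, seed=7) == permutation_test(a, b, 500, seed=7)

    def test_degenerate_group_rejected(self):
        with pytest.raises(ValueError):
            permutation_test([1.0], [1.0, 2.0], 10, 0)

    def test_matrix_agrees_with_columnwise(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 1, (8, 3)), rng.normal(0, 1, (9, 3))
        diffs, ps = permutation_test_matrix(a, b, 500, seed=5)
        for j in range(3):
            dj, pj = permutation_test(a[:, j], b[:, j], 500, seed=5)
            assert diffs[j] == pytest.approx(dj) and ps[j] == pytest.approx(pj)


class TestEffectSizeAndFDR:
    def test_cohens_d_hand_value(self):
        assert cohens_d([1, 2, 3], [2, 3, 4]) == pytest.approx(-1.0)

    def test_cohens_d_zero_and_antisymmetric(self):
        a = [0.2, 0.4, 0.9]
        assert cohens_d(a, a) == 0.0
        b = [1.0, 1.4, 2.0]
        assert cohens_d(a, b) == pytest.approx(-cohens_d(b, a))

    def test_bh_step_up_by_hand(self):
        rej, adj = fdr_correct([0.01, 0.02, 0.04, 0.5], q=0.05)
        assert list(rej) == [True, True, False, False]

    def test_all_ones_none_rejected(self):
        rej, _ = fdr_correct([1.0] * 6)
        assert not rej.any()

    def test_bh_matches_brute_force(self):
        rng = np.random.default_rng(6)
        for _ in range(100):
            p = rng.random(rng.integers(3, 40))
            rej, _ = fdr_correct(p, q=0.05)
            assert np.array_equal(rej, oracles.brute_bh(p, 0.05))

    def test_never_rejects_more_than_uncorrected(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            p = rng.random(30)
            rej, _ = fdr_correct(p, q=0.05)
            assert rej.sum() <= (p < 0.05).sum()


class TestPartialCorrelation:
    def test_identity_r_one(self):
        rng = np.random.default_rng(8)
        x = rng.normal(0, 1, 15)
        cov = rng.normal(0, 1, (15, 2))
        pc = partial_correlation(x, x, cov)
        assert pc.r == pytest.approx(1.0)

    def test_orthogonal_covariates_reduce_to_pearson(self):
        rng = np.random.default_rng(9)
        x, y = rng.normal(0, 1, 200), rng.normal(0, 1, 200)
        x, y = x - x.mean(), y - y.mean()
        # covariate orthogonal to both by construction (Gram-Schmidt)
        c = rng.normal(0, 1, 200)
        c -= c @ x / (x @ x) * x + c @ y / (y @ y) * y
        c -= c.mean() * 0  # keep intercept in the design
        pc = partial_correlation(x, y, c)
        plain = np.corrcoef(x, y)[0, 1]
        assert pc.r == pytest.approx(plain, abs=1e-6)

    def test_small_set_matches_brute_residualisation(self):
        x = np.array([1.0, 2.0, 3.5, 2.2, 5.1, 4.0])
        y = np.array([0.3, 1.1, 0.9, 2.2, 2.5, 3.1])
        cov = np.array([[1, 0], [0, 1], [1, 1], [2, 0], [0, 2], [1, 2]], float)
        pc = partial_correlation(x, y, cov)
        assert pc.r == pytest.approx(oracles.brute_partial_r(x, y, cov), abs=1e-10)

    def test_matches_pingouin(self):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(10)
        df = pd.DataFrame(rng.normal(0, 1, (25, 4)), columns=list("xyab"))
        pc = partial_correlation(df["x"], df["y"], df[["a", "b"]].to_numpy())
        ref = pg.partial_corr(df, x="x", y="y", covar=["a", "b"])
        assert pc.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-9)
        assert pc.p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-9)

    def test_rank_deficient_rejected(self):
        rng = np.random.default_rng(11)
        x, y = rng.normal(0, 1, 10), rng.normal(0, 1, 10)
        c = np.ones((10, 2))  # collinear with the intercept
        with pytest.raises(ValueError, match="rank"):
            partial_correlation(x, y, c)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="n >"):
            partial_correlation([1, 2, 3], [2, 1, 3], np.array([[1.0], [0.0], [2.0]]))


class TestNBS:
    def test_component_size_counts_connections(self):
        rng = np.random.default_rng(12)
        n, nn = 10, 20
        iu, ju = np.triu_indices(nn, 1)
        a = rng.normal(0.5, 0.05, (n, iu.size))
        b = rng.normal(0.5, 0.05, (n, iu.size))
        # weaken a 4-node path (3 edges) strongly
        planted = [e for e in range(iu.size)
                   if (iu[e], ju[e]) in {(0, 1), (1, 2), (2, 3)}]
        a[:, planted] -= 0.5
        r = nbs(a, b, nn, primary_p=0.005, n_perm=200, direction="decreased", seed=0)
        sizes = sorted((c.size for c in r.components), reverse=True)
        assert sizes[0] >= 3  # edges, not the 4 nodes
        top = max(r.components, key=lambda c: c.size)
        assert {(0, 1), (1, 2), (2, 3)} <= set(top.edges)
        assert top.p_corrected < 0.05

    def test_direction_separation(self):
        rng = np.random.default_rng(13)
        nn = 15
        iu, ju = np.triu_indices(nn, 1)
        a = rng.normal(0.5, 0.05, (12, iu.size))
        b = rng.normal(0.5, 0.05, (12, iu.size))
        a[:, :4] += 0.5  # group A stronger on 4 edges
        up = nbs(a, b, nn, 0.005, 200, "increased", seed=1)
        down = nbs(a, b, nn, 0.005, 200, "decreased", seed=1)
        assert any(c.p_corrected < 0.05 for c in up.components)
        assert not any(c.p_corrected < 0.05 for c in down.components)

    def test_invalid_inputs(self):
        x = np.zeros((3, 10))
        with pytest.raises(ValueError):
            nbs(x, x, 5, direction="sideways")
        with pytest.raises(ValueError):
            nbs(x, x, 5, primary_p=1.5)
        with pytest.raises(ValueError):
            nbs(x[:1], x, 5)
        with pytest.raises(ValueError):
            nbs(x, x, 9)  # 9 nodes -> 36 edges != 10


@pytest.fixture(scope="module")
def null_report():
    import pandas as pd

    from morphkls.metrics import GLOBAL_METRICS, NODAL_METRICS

    rng = np.random.default_rng(14)
    regions = [f"R{i:02d}" for i in range(90)]

    def frame(n, cols):
        return pd.DataFrame(rng.normal(0, 1, (n, len(cols))), columns=cols)

    ga, gb = frame(20, GLOBAL_METRICS), frame(20, GLOBAL_METRICS)
    na = {m: frame(20, regions) for m in NODAL_METRICS}
    nb = {m: frame(20, regions) for m in NODAL_METRICS}
    return compare_groups(ga, gb, na, nb, n_perm=500, seed=15)


class TestCompareGroups:
    def test_bookkeeping_counts(self, null_report):
        assert len(null_report.global_table) == 7
        assert len(null_report.nodal_table) == 270

    def test_null_rejection_rates(self, null_report):
        pre = (null_report.nodal_table["p"] < 0.05).mean()
        assert 0.01 <= pre <= 0.10  # ~5% pre-FDR
        assert null_report.nodal_table["significant"].sum() <= 3  # ~0 post-FDR
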