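import numpy as np
import pandas as pd
import pytest

from cartoptics.stats import (
    dunn_posthoc,
    run_all_tests,
    run_group_test,
    select_branch,
)


class TestSelectBranch:
    def test_common_normal_groups_mostly_parametric(self):
        rng = np.random.default_rng(0)
        hits = 0
        for _ in range(100):
            groups = [rng.normal(10.0, 2.0, 30) for _ in range(3)]
            branch, _ = select_branch(groups)
            hits += branch == "parametric"
        assert hits >= 90

    def test_exponential_group_mostly_nonparametric(self):
        rng = np.random.default_rng(1)
        hits = 0
        for _ in range(100):
            groups = [
                rng.normal(10.0, 2.0, 30),
                rng.normal(10.0, 2.0, 30),
                rng.exponential(10.0, 30),
            ]
            branch, _ = select_branch(groups)
            hits += branch == "nonparametric"
        assert hits > 50

    def test_constant_groups_degenerate_nonparametric(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            branch, _ = select_branch([np.ones(5), np.ones(5) * 2.0])
        assert branch == "nonparametric"

    def test_small_groups_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="excluded"):
            select_branch([np.arange(10.0), np.arange(10.0) + 1, np.array([1.0, 2.0])])
        with pytest.raises(ValueError):
            select_branch([np.arange(10.0), np.array([1.0])])


class TestDunn:
    def test_frozen_hand_computed_example(self):
        # groups (1,2,3),(4,5,6),(7,8,9): mean ranks 2/5/8, no ties,
        # z = dR / sqrt(7.5 * 2/3); Bonferroni x3
        mat = dunn_posthoc(
            [np.array([1.0, 2, 3]), np.array([4.0, 5, 6]), np.array([7.0, 8, 9])],
            ["A", "B", "C"],
        )
        assert mat.loc["A", "B"] == pytest.approx(0.539137, abs=1e-5)
        assert mat.loc["A", "C"] == pytest.approx(0.021871, abs=1e-5)
        assert mat.loc["B", "C"] == pytest.approx(0.539137, abs=1e-5)

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(3)
        groups = [rng.normal(i, 1.0, 12) for i in range(4)]
        bonf = dunn_posthoc(groups, list("ABCD"), adjust="bonferroni")
        holm = dunn_posthoc(groups, list("ABCD"), adjust="holm")
        m = 6
        for a in "ABCD":
            for b in "ABCD":
                if a >= b:
                    continue
                raw_equiv = bonf.loc[a, b] / m  # invert the Bonferroni factor
                assert bonf.loc[a, b] >= raw_equiv - 1e-12
                assert holm.loc[a, b] >= raw_equiv - 1e-12

    def test_matrix_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(4)
        mat = dunn_posthoc([rng.normal(0, 1, 8) for _ in range(3)], list("XYZ"))
        assert np.allclose(mat.values, mat.values.T)
        assert np.allclose(np.diag(mat.values), 1.0)
        assert np.all((mat.values >= 0) & (mat.values <= 1))


class TestRunGroupTest:
    def test_identical_groups_null_identity(self):
        g = np.array([1.0, 2, 3, 4, 5])
        for branch in ("parametric", "nonparametric"):
            res = run_group_test([g, g.copy(), g.copy()], ["a", "b", "c"], branch)
            assert res.omnibus_p == pytest.approx(1.0, abs=1e-9)
            assert not res.significant_pairs()

    def test_shifted_group_detected_both_branches(self):
        a = np.array([1.0, 2, 3, 4, 5])
        b = a + 100.0
        res_p = run_group_test([a, b, a.copy()], ["g1", "g2", "g3"], "parametric")
        assert res_p.posthoc.loc["g1", "g2"] < 0.001
        assert res_p.posthoc.loc["g2", "g3"] < 0.001
        assert res_p.posthoc.loc["g1", "g3"] > 0.9
        res_n = run_group_test([a, b, a.copy()], ["g1", "g2", "g3"], "nonparametric")
        assert res_n.posthoc.loc["g1", "g2"] < 0.05
        assert res_n.posthoc.loc["g1", "g3"] > 0.5

    def test_posthoc_permutation_equivariance(self):
        rng = np.random.default_rng(5)
        groups = [rng.normal(i * 2.0, 1.0, 15) for i in range(3)]
        res = run_group_test(groups, ["a", "b", "c"], "parametric")
        perm = [groups[2], groups[0], groups[1]]
        res_perm = run_group_test(perm, ["c", "a", "b"], "parametric")
        for x in "abc":
            for y in "abc":
                assert res.posthoc.loc[x, y] == pytest.approx(
                    res_perm.posthoc.loc[x, y], abs=1e-9
                )

    def test_diagonal_is_one(self):
        rng = np.random.default_rng(6)
        res = run_group_test(
            [rng.normal(0, 1, 10) for _ in range(3)], ["a", "b", "c"], "parametric"
        )
        assert np.allclose(np.diag(res.posthoc.values), 1.0)


def _fit_frame(rng, dz_shift=0.0, n=12):
    rows = []
    for zone in ("SZ", "MZ", "DZ"):
        for loc in ("FL", "FM"):
            shift = dz_shift if zone == "DZ" else 0.0
            for _ in range(n):
                rows.append(
                    {
                        "zone": zone,
                        "location": loc,
                        "alpha": rng.normal(20.0 + shift, 8.0),
                        "b": rng.normal(1.4, 0.3),
                        "c": np.clip(rng.normal(0.1, 0.05), 0, 1),
                    }
                )
    return pd.DataFrame(rows)


class TestRunAllTests:
    def test_planted_dz_shift_flags_expected_pairs(self):
        rng = np.random.default_rng(7)
        df = _fit_frame(rng, dz_shift=15.0)
        results = run_all_tests(df, parameters=("alpha",))
        t1 = [r for r in results if r.test_id == 1][0]
        pairs = t1.significant_pairs()
        assert ("DZ", "SZ") in pairs or ("SZ", "DZ") in pairs
        assert ("DZ", "MZ") in pairs or ("MZ", "DZ") in pairs
        assert ("MZ", "SZ") not in pairs and ("SZ", "MZ") not in pairs

    def test_four_stratifications_present(self):
        rng = np.random.default_rng(8)
        results = run_all_tests(_fit_frame(rng), parameters=("alpha", "b"))
        ids = {r.test_id for r in results}
        assert ids == {1, 2, 3, 4}

    def test_single_location_skips_location_tests(self):
        rng = np.random.default_rng(9)
        df = _fit_frame(rng)
        df = df[df["location"] == "FL"]
        results = run_all_tests(df, parameters=("alpha",))
        t3 = [r for r in results if r.test_id == 3]
        assert all(r.skipped for r in t3)
        t1 = [r for r in results if r.test_id == 1]
        assert not t1[0].skipped

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            run_all_tests(pd.DataFrame({"zone": [], "alpha": []}), parameters=("alpha",))
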