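import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cna import (
    centrality_tertiles,
    compare_drug_groups,
    correlate_profiles,
    deactivated_cna,
    group_label_permutation,
    permutation_test,
    select_uncorrelated_pairs,
    stratified_association,
)
from cna.association import fisher_z_compare


@pytest.fixture
def cna_vec(rng):
    return pd.Series(rng.standard_normal(40), index=[f"s{i}" for i in range(40)])


class TestCorrelateProfiles:
    def test_self_correlation_is_one(self, cna_vec):
        resp = pd.DataFrame([cna_vec], index=["d1"])
        out = correlate_profiles(cna_vec, resp)
        assert out.loc["d1", "r"] == pytest.approx(1.0)

    def test_sign_flip(self, cna_vec):
        resp = pd.DataFrame([-cna_vec], index=["d1"])
        assert correlate_profiles(cna_vec, resp).loc["d1", "r"] == pytest.approx(-1.0)

    def test_missing_values_pairwise_complete(self, cna_vec):
        row = cna_vec * 0.5 + 1.0
        row.iloc[0] = np.nan
        resp = pd.DataFrame([row], index=["d1"])
        out = correlate_profiles(cna_vec, resp)
        # oracle: direct Pearson on the reduced vectors
        expected = stats.pearsonr(cna_vec.iloc[1:], row.iloc[1:]).statistic
        assert out.loc["d1", "r"] == pytest.approx(expected, abs=1e-12)
        assert out.loc["d1", "n"] == 39

    def test_too_few_samples_skipped(self, cna_vec):
        sparse = pd.Series(np.nan, index=cna_vec.index)
        sparse.iloc[:2] = [1.0, 2.0]
        resp = pd.DataFrame([sparse, cna_vec], index=["sparse", "ok"])
        out = correlate_profiles(cna_vec, resp)
        assert list(out.index) == ["ok"]

    def test_no_qualifying_drug_errors(self, cna_vec):
        resp = pd.DataFrame([pd.Series(1.0, index=cna_vec.index)], index=["const"])
        with pytest.raises(ValueError, match="no drug qualified"):
            correlate_profiles(cna_vec, resp)


class TestPermutationTest:
    def test_add_one_floor(self, cna_vec):
        # perfect correlation beats every permutation
        r, p = permutation_test(cna_vec, cna_vec * 2.0, n_perm=1000, seed=1)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(1 / 1001)

    def test_constant_vector_errors(self, cna_vec):
        with pytest.raises(ValueError, match="constant"):
            permutation_test(pd.Series(1.0, index=cna_vec.index), cna_vec, seed=0)

    def test_seed_reproducibility(self, cna_vec, rng):
        row = pd.Series(rng.standard_normal(40), index=cna_vec.index)
        p1 = permutation_test(cna_vec, row, seed=7)[1]
        p2 = permutation_test(cna_vec, row, seed=7)[1]
        assert p1 == p2

    def test_null_p_roughly_uniform(self):
        # quick calibration check; the full KS test lives in the acceptance suite
        rng = np.random.default_rng(5)
        idx = [f"s{i}" for i in range(30)]
        ps = [
            permutation_test(
                pd.Series(rng.standard_normal(30), index=idx),
                pd.Series(rng.standard_normal(30), index=idx),
                n_perm=200, seed=int(rng.integers(2**31)))[1]
            for _ in range(60)
        ]
        assert 0.25 < np.mean(ps) < 0.75
        assert min(ps) >= 1 / 201


class TestCompareDrugGroups:
    def test_exact_enumeration_small_groups(self):
        # all of group B above group A: p = 2/20 over C(6,3) arrangements
        assert compare_drug_groups([0.1, 0.2, 0.3], [0.4, 0.5, 0.6]) == pytest.approx(0.1)

    def test_identical_multisets_give_one(self):
        assert compare_drug_groups([0.1, 0.2], [0.1, 0.2]) == pytest.approx(1.0)

    def test_singletons_exact(self):
        assert compare_drug_groups([0.3], [0.7]) == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            compare_drug_groups([], [0.1])

    def test_large_groups_detect_shift(self, rng):
        a = rng.normal(-0.3, 0.1, size=30)
        b = rng.normal(0.3, 0.1, size=30)
        assert compare_drug_groups(a, b) < 1e-6


class TestGroupLabelPermutation:
    def test_planted_shift_detected(self, rng):
        r = np.concatenate([rng.normal(-0.3, 0.1, 15), rng.normal(0.3, 0.1, 15)])
        drugs = [f"d{i}" for i in range(30)]
        records = pd.DataFrame({"r": r}, index=drugs)
        labels = pd.Series(["broad"] * 15 + ["targeted"] * 15, index=drugs)
        out = group_label_permutation(records, labels, n_perm=500, seed=3)
        assert out.loc[0, "p_perm"] < 0.05

    def test_null_not_significant_on_average(self, rng):
        ps = []
        for k in range(20):
            r = rng.standard_normal(20)
            drugs = [f"d{i}" for i in range(20)]
            records = pd.DataFrame({"r": r}, index=drugs)
            labels = pd.Series(["a"] * 10 + ["b"] * 10, index=drugs)
            out = group_label_permutation(records, labels, n_perm=99, seed=k)
            ps.append(out.loc[0, "p_perm"])
        assert np.mean(ps) > 0.2

    def test_singleton_category_skipped(self, rng):
        drugs = [f"d{i}" for i in range(5)]
        records = pd.DataFrame({"r": rng.standard_normal(5)}, index=drugs)
        labels = pd.Series(["a", "a", "b", "b", "c"], index=drugs)
        with pytest.warns(UserWarning, match="'c'"):
            out = group_label_permutation(records, labels, n_perm=19, seed=0)
        assert set(out["category_a"]) | set(out["category_b"]) == {"a", "b"}

    def test_insufficient_categories_error(self, rng):
        drugs = ["d0", "d1", "d2"]
        records = pd.DataFrame({"r": [0.1, 0.2, 0.3]}, index=drugs)
        labels = pd.Series(["a", "a", "b"], index=drugs)
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match=">=2 categories"):
                group_label_permutation(records, labels, n_perm=19, seed=0)


class TestStratifiedAssociation:
    @staticmethod
    def _setup(rng, n=120, r_mut=-0.5, r_wt=0.0, n_drugs=4):
        samples = [f"s{i}" for i in range(n)]
        cna = pd.Series(rng.standard_normal(n), index=samples)
        mut = pd.Series([1] * (n // 2) + [0] * (n - n // 2), index=samples)
        rows = {}
        for d in range(n_drugs):
            y = np.empty(n)
            for i, s in enumerate(samples):
                r = r_mut if mut[s] == 1 else r_wt
                y[i] = r * cna[s] + np.sqrt(1 - r * r) * rng.standard_normal()
            rows[f"d{d}"] = y
        resp = pd.DataFrame(rows).T
        resp.columns = samples
        return cna, resp, mut

    def test_all_wildtype_errors(self, rng):
        cna, resp, mut = self._setup(rng)
        with pytest.raises(ValueError, match="mutated stratum"):
            stratified_association(cna, resp, mut * 0)

    def test_planted_difference_flagged(self, rng):
        cna, resp, mut = self._setup(rng, r_mut=-0.6, r_wt=0.0)
        out = stratified_association(cna, resp, mut)
        assert out["per_drug"]["flagged"].mean() >= 0.75
        assert (out["mutated"]["r"] < 0).all()

    def test_identical_strata_mostly_unflagged(self, rng):
        flags = []
        for k in range(10):
            local = np.random.default_rng(k)
            cna, resp, mut = self._setup(local, r_mut=0.0, r_wt=0.0, n_drugs=5)
            out = stratified_association(cna, resp, mut)
            flags.extend(out["per_drug"]["flagged"].tolist())
        assert np.mean(flags) < 0.15  # nominal alpha=0.05 plus sampling slack

    def test_fisher_z_symmetric(self):
        assert fisher_z_compare(0.5, 50, 0.1, 60) == pytest.approx(
            fisher_z_compare(0.1, 60, 0.5, 50))


class TestCentralityTertiles:
    def test_nine_distinct_balanced(self):
        C = pd.Series(np.arange(9, dtype=float), index=[f"n{i}" for i in range(9)])
        t = centrality_tertiles(C)
        assert t.value_counts().to_dict() == {"low": 3, "mid": 3, "high": 3}
        assert set(t[t == "high"].index) == {"n6", "n7", "n8"}

    def test_tied_values_stable_split(self):
        C = pd.Series([1, 1, 1, 2, 2, 2, 3, 3, 3.0],
                      index=[f"n{i}" for i in range(9)])
        t = centrality_tertiles(C)
        assert t.value_counts().to_dict() == {"low": 3, "mid": 3, "high": 3}
        # stable label order within ties
        assert list(t[t == "low"].index) == ["n0", "n1", "n2"]

    def test_remainder_goes_low(self):
        C = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        t = centrality_tertiles(C)
        assert t.value_counts().to_dict() == {"low": 2, "mid": 1, "high": 1}
        assert set(t[t == "low"].index) == {"a", "b"}

    def test_all_identical_errors(self):
        with pytest.raises(ValueError, match="identical"):
            centrality_tertiles(pd.Series([1.0, 1.0, 1.0], index=list("abc")))

    def test_standardization_does_not_change_assignment(self, rng):
        C = pd.Series(rng.uniform(1, 2, 12), index=[f"n{i}" for i in range(12)])
        assert centrality_tertiles(C, True).equals(centrality_tertiles(C, False))


class TestDeactivatedCna:
    @pytest.fixture
    def centr(self, rng):
        return pd.DataFrame(
            1.0 + rng.uniform(0, 1, size=(4, 9)),
            index=[f"s{i}" for i in range(4)],
            columns=[f"n{i}" for i in range(9)])

    def test_all_active_is_identity(self, centr):
        terts = centrality_tertiles(centr.mean(axis=0))
        mod = deactivated_cna(centr, terts, {"low", "mid", "high"})
        assert np.allclose(mod, centr.sum(axis=1))

    def test_deactivate_everything_conserves_total(self, centr):
        terts = centrality_tertiles(centr.mean(axis=0))
        mod = deactivated_cna(centr, terts, set())
        assert np.allclose(mod, centr.sum(axis=1))

    def test_deactivate_high_matches_arithmetic(self, centr):
        terts = centrality_tertiles(centr.mean(axis=0))
        mod = deactivated_cna(centr, terts, {"low", "mid"})
        high = terts[terts == "high"].index
        keep = terts[terts != "high"].index
        expected = (centr[keep].sum(axis=1)
                    + len(high) * centr.mean(axis=1))
        assert np.allclose(mod, expected)

    def test_unknown_label_rejected(self, centr):
        terts = centrality_tertiles(centr.mean(axis=0))
        with pytest.raises(ValueError, match="unknown tertile"):
            deactivated_cna(centr, terts, {"extreme"})


class TestSelectUncorrelatedPairs:
    def test_identical_partner_excluded(self, rng):
        base = rng.standard_normal(50)
        samples = [f"s{i}" for i in range(50)]
        resp = pd.DataFrame(
            {"anchor": base, "twin": base,
             "noise": rng.standard_normal(50)}).T
        resp.columns = samples
        out = select_uncorrelated_pairs(resp, "anchor")
        assert not out.loc["twin", "candidate"]
        assert out.loc["twin", "r"] == pytest.approx(1.0)

    def test_independent_partner_usually_included(self, rng):
        samples = [f"s{i}" for i in range(50)]
        hits = 0
        for k in range(40):
            local = np.random.default_rng(1000 + k)
            resp = pd.DataFrame(
                {"anchor": local.standard_normal(50),
                 "indep": local.standard_normal(50)}).T
            resp.columns = samples
            hits += select_uncorrelated_pairs(resp, "anchor").loc["indep", "candidate"]
        assert hits >= 33  # ~0.95 expected inclusion at alpha=0.05

    def test_missing_anchor_rejected(self, rng):
        resp = pd.DataFrame({"d": rng.standard_normal(5)}).T
        with pytest.raises(ValueError, match="anchor"):
            select_uncorrelated_pairs(resp, "nope")
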