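"""Partial-correlation scan, effective tests, threshold and clustering."""

import numpy as np
import pandas as pd
import pytest

from braingap.association import (
    AssociationResult,
    HypothesisSpec,
    cluster_criteria,
    corrected_threshold,
    covariate_design,
    li_ji_meff,
    partial_scan,
    residualize,
)
from braingap.synthetic import CohortTable


def make_table(columns: dict, roles: dict) -> CohortTable:
    df = pd.DataFrame(columns)
    df.index = [f"S{i}" for i in range(len(df))]
    return CohortTable(data=df, roles=roles)


class TestResidualize:
    def test_intercept_only_is_centering(self, rng):
        y = rng.normal(size=30)
        res = residualize(y, None)
        assert np.allclose(res, y - y.mean())

    def test_orthogonal_value_only_centered(self, rng):
        c = rng.normal(size=50)
        y = rng.normal(size=50)
        y_orth = residualize(y, c)  # orthogonal to c by construction
        res = residualize(y_orth, c)
        assert np.allclose(res, y_orth - y_orth.mean(), atol=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        # 6-row worked example solved directly via the normal equations
        y = np.array([2.0, 3.5, 1.0, 4.2, 5.1, 0.3])
        C = rng.normal(size=(6, 2))
        X = np.column_stack([np.ones(6), C])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert np.allclose(residualize(y, C), y - X @ beta, atol=1e-10)

    def test_residuals_orthogonal_to_each_covariate(self, rng):
        C = rng.normal(size=(80, 4))
        y = rng.normal(size=80) + C @ np.array([1.0, -2.0, 0.5, 3.0])
        res = residualize(y, C)
        scale = np.linalg.norm(res) * np.linalg.norm(C, axis=0)
        assert np.all(np.abs(res @ C) / scale < 1e-8)

    def test_missing_entries_stay_missing(self, rng):
        y = rng.normal(size=20)
        y[[3, 7]] = np.nan
        res = residualize(y, rng.normal(size=(20, 2)))
        assert np.isnan(res[[3, 7]]).all()
        assert np.isfinite(np.delete(res, [3, 7])).all()

    def test_rank_deficient_design_names_columns(self, rng):
        c = rng.normal(size=40)
        with pytest.raises(ValueError, match="dup"):
            residualize(rng.normal(size=40), np.column_stack([c, c]),
                        names=["base", "dup"])


def _partial_r_recursive(x, y, z):
    """Textbook recursive formula for one conditioning variable."""
    rxy = np.corrcoef(x, y)[0, 1]
    rxz = np.corrcoef(x, z)[0, 1]
    ryz = np.corrcoef(y, z)[0, 1]
    return (rxy - rxz * ryz) / np.sqrt((1 - rxz**2) * (1 - ryz**2))


def _partial_r_precision(x, y, Z):
    """Partial correlation via the inverse correlation (precision) matrix."""
    M = np.column_stack([x, y, Z])
    P = np.linalg.inv(np.corrcoef(M, rowvar=False))
    return -P[0, 1] / np.sqrt(P[0, 0] * P[1, 1])


class TestPartialScan:
    def _table(self, rng, n=60):
        cols = {
            "sex": (rng.random(n) < 0.5).astype(float),
            "age": rng.uniform(61, 82, n),
            "tiv": rng.normal(1500, 100, n),
            "g": rng.normal(0, 3, n),
        }
        roles = {"sex": "covariate", "age": "covariate", "tiv": "covariate",
                 "g": "gap"}
        return cols, roles

    def test_self_correlation_is_one(self, rng):
        cols, roles = self._table(rng)
        cols["crit"] = cols["g"].copy()
        roles["crit"] = "criterion"
        table = make_table(cols, roles)
        res = partial_scan(table, HypothesisSpec({"crit": 1}))[0]
        assert res.r == pytest.approx(1.0, abs=1e-10)
        assert res.p_one < 1e-12

    def test_orthogonal_criterion_near_null(self, rng):
        cols, roles = self._table(rng, n=200)
        resid_g = residualize(cols["g"], np.column_stack(
            [cols["sex"], cols["age"], cols["age"] ** 2, cols["tiv"]]))
        noise = rng.normal(size=200)
        # orthogonalize the criterion against the residualized gap
        cols["crit"] = noise - (noise @ resid_g) / (resid_g @ resid_g) * resid_g
        roles["crit"] = "criterion"
        res = partial_scan(make_table(cols, roles),
                           HypothesisSpec({"crit": 1}))[0]
        assert abs(res.r) < 0.05
        assert res.p_one == pytest.approx(0.5, abs=0.1)

    def test_matches_recursive_formula_one_covariate(self, rng):
        n = 8
        cols = {"z": rng.normal(size=n), "g": rng.normal(size=n),
                "crit": rng.normal(size=n)}
        roles = {"z": "covariate", "g": "gap", "crit": "criterion"}
        res = partial_scan(make_table(cols, roles), HypothesisSpec({"crit": 1}),
                           covariate_labels=("z",))[0]
        expected = _partial_r_recursive(cols["g"], cols["crit"], cols["z"])
        assert res.r == pytest.approx(expected, abs=1e-10)
        assert res.df == n - 2 - 1
        t_expected = expected * np.sqrt(res.df) / np.sqrt(1 - expected**2)
        assert res.t == pytest.approx(t_expected, abs=1e-8)

    def test_matches_precision_formula_four_covariates(self, rng):
        cols, roles = self._table(rng, n=50)
        cols["crit"] = rng.normal(size=50) + 0.3 * cols["g"]
        roles["crit"] = "criterion"
        res = partial_scan(make_table(cols, roles),
                           HypothesisSpec({"crit": 1}))[0]
        Z = np.column_stack([cols["sex"], cols["age"], cols["age"] ** 2,
                             cols["tiv"]])
        expected = _partial_r_precision(cols["g"], cols["crit"], Z)
        assert res.r == pytest.approx(expected, abs=1e-10)

    def test_matches_pingouin_oracle(self, rng):
        pingouin = pytest.importorskip("pingouin")
        cols, roles = self._table(rng, n=80)
        cols["crit"] = rng.normal(size=80) + 0.2 * cols["g"]
        roles["crit"] = "criterion"
        table = make_table(cols, roles)
        res = partial_scan(table, HypothesisSpec({"crit": 1}))[0]
        df = table.data.assign(age2=table.data["age"] ** 2)
        oracle = pingouin.partial_corr(df, x="g", y="crit",
                                       covar=["sex", "age", "age2", "tiv"])
        assert res.r == pytest.approx(float(oracle["r"].iloc[0]), abs=1e-8)
        assert res.p_two == pytest.approx(float(oracle["p_val"].iloc[0]),
                                          abs=1e-6)

    def test_sign_coherence(self, rng):
        cols, roles = self._table(rng)
        cols["crit"] = rng.normal(size=60) + 0.2 * cols["g"]
        roles["crit"] = "criterion"
        table = make_table(cols, roles)
        p_plus = partial_scan(table, HypothesisSpec({"crit": 1}))[0].p_one
        p_minus = partial_scan(table, HypothesisSpec({"crit": -1}))[0].p_one
        assert p_plus + p_minus == pytest.approx(1.0, abs=1e-12)

    def test_dropping_covariate_changes_df_by_one(self, rng):
        cols, roles = self._table(rng)
        cols["crit"] = rng.normal(size=60)
        roles["crit"] = "criterion"
        table = make_table(cols, roles)
        hyp = HypothesisSpec({"crit": 1})
        full = partial_scan(table, hyp)[0]
        reduced = partial_scan(table, hyp,
                               covariate_labels=("sex", "age", "tiv"))[0]
        assert full.df == reduced.df - 1

    def test_missing_hypothesis_fails_before_computation(self, rng):
        cols, roles = self._table(rng)
        cols["crit"] = rng.normal(size=60)
        roles["crit"] = "criterion"
        with pytest.raises(KeyError, match="crit"):
            partial_scan(make_table(cols, roles), HypothesisSpec({}))

    def test_pairwise_rows_and_insufficient_pair_warning(self, rng):
        cols, roles = self._table(rng, n=40)
        sparse = rng.normal(size=40)
        sparse[5:] = np.nan  # 5 complete rows < k + 4
        cols["sparse"] = sparse
        cols["dense"] = rng.normal(size=40)
        roles.update({"sparse": "criterion", "dense": "criterion"})
        hyp = HypothesisSpec({"sparse": 1, "dense": 1})
        with pytest.warns(UserWarning, match="sparse"):
            results = partial_scan(make_table(cols, roles), hyp)
        assert [res.criterion for res in results] == ["dense"]
        assert results[0].n_pair == 40


class TestCovariateDesign:
    def test_age_squared_derived_internally(self, rng):
        cols = {"sex": rng.random(10), "age": rng.uniform(60, 80, 10),
                "tiv": rng.normal(1500, 50, 10)}
        table = make_table(cols, {k: "covariate" for k in cols})
        design, names = covariate_design(table)
        assert names == ["sex", "age", "age^2", "tiv"]
        assert np.allclose(design[:, 2], cols["age"] ** 2)


class TestLiJiMeff:
    def test_identity_returns_m(self):
        for m in (2, 5, 9):
            assert li_ji_meff(np.eye(m)).m_eff == m

    def test_duplicated_variable_collapses(self):
        # two perfectly correlated variables plus one independent:
        # eigenvalues (2, 1, 0) -> m_eff = 2
        R = np.array([[1.0, 1.0, 0.0], [1.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
        eff = li_ji_meff(R)
        assert sorted(np.round(eff.eigenvalues, 10)) == [0.0, 1.0, 2.0]
        assert eff.m_eff == 2

    def test_matches_direct_eigenvalue_formula(self, rng):
        A = rng.normal(size=(40, 6))
        R = np.corrcoef(A, rowvar=False)
        lam = np.abs(np.linalg.eigvals(R)).real
        expected = np.sum((lam >= 1) + (lam - np.floor(lam)))
        assert li_ji_meff(R).m_eff_raw == pytest.approx(expected, abs=1e-8)

    def test_invariant_under_reordering(self, rng):
        A = rng.normal(size=(30, 5))
        R = np.corrcoef(A, rowvar=False)
        perm = rng.permutation(5)
        assert li_ji_meff(R[np.ix_(perm, perm)]).m_eff_raw == pytest.approx(
            li_ji_meff(R).m_eff_raw, abs=1e-10)

    def test_rejects_invalid_input(self):
        with pytest.raises(ValueError):
            li_ji_meff(np.array([[1.0, 0.5], [0.1, 1.0]]))
        with pytest.raises(ValueError):
            li_ji_meff(np.array([[2.0, 0.0], [0.0, 1.0]]))


class TestCorrectedThreshold:
    def test_study_threshold(self):
        t = corrected_threshold(2, 22, 0.05)
        assert t == pytest.approx(0.05 / 44)
        assert round(t, 3) == 0.001

    @pytest.mark.parametrize("m1, m2, expected", [(1, 1, 0.05),
                                                  (2, 2, 0.0125)])
    def test_arithmetic(self, m1, m2, expected):
        assert corrected_threshold(m1, m2, 0.05) == pytest.approx(expected)

    def test_invalid(self):
        with pytest.raises(ValueError):
            corrected_threshold(0.5, 22, 0.05)
        with pytest.raises(ValueError):
            corrected_threshold(2, 22, 1.5)


def _brute_force_average_linkage(D):
    """Naive UPGMA oracle: repeatedly merge the closest pair of clusters,
    with cluster distance = mean over all between-cluster point pairs."""
    clusters = {i: [i] for i in range(len(D))}
    merges = []
    next_id = len(D)

    def cdist(a, b):
        return np.mean([D[i, j] for i in clusters[a] for j in clusters[b]])

    while len(clusters) > 1:
        pairs = [(a, b) for a in clusters for b in clusters if a < b]
        a, b = min(pairs, key=lambda p: (cdist(*p), p))
        merges.append((a, b, cdist(a, b)))
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return merges


class TestClusterCriteria:
    def test_identical_variables_merge_first_at_zero(self):
        R = np.array([
            [1.0, 1.0, 0.2],
            [1.0, 1.0, 0.2],
            [0.2, 0.2, 1.0]])
        Z, _ = cluster_criteria(R)
        assert Z[0, 0] == 0 and Z[0, 1] == 1
        assert Z[0, 2] == pytest.approx(0.0)

    def test_block_structure_recovered_at_half_distance(self):
        R = np.eye(6)
        R[:3, :3] = 0.8
        R[3:, 3:] = 0.8
        np.fill_diagonal(R, 1.0)
        _, labels = cluster_criteria(R, cut_distance=0.5)
        assert len(set(labels[:3])) == 1
        assert len(set(labels[3:])) == 1
        assert labels[0] != labels[3]

    def test_merge_heights_match_brute_force_oracle(self, rng):
        A = rng.normal(size=(25, 5))
        R = np.corrcoef(A, rowvar=False)
        D = 1 - np.abs(R)
        np.fill_diagonal(D, 0.0)
        Z, _ = cluster_criteria(R)
        oracle = _brute_force_average_linkage(D)
        assert np.allclose(sorted(Z[:, 2]), sorted(m[2] for m in oracle),
                           atol=1e-10)

    def test_missing_correlations_rejected(self):
        R = np.eye(3)
        R[0, 1] = R[1, 0] = np.nan
        with pytest.raises(ValueError):
            cluster_criteria(R)


class TestHypothesisSpec:
    def test_round_trip_file(self, tmp_path):
        spec = HypothesisSpec({"a": 1, "b": -1})
        path = tmp_path / "hyp.csv"
        spec.write_csv(path)
        assert HypothesisSpec.read_csv(path).signs == {"a": 1, "b": -1}

    def test_symbol_signs_parsed(self, tmp_path):
        path = tmp_path / "hyp.csv"
        path.write_text("crit_a,+\ncrit_b,-\n")
        signs = HypothesisSpec.read_csv(path).signs
        assert signs == {"crit_a": 1, "crit_b": -1}

    def test_invalid_sign_rejected(self):
        with pytest.raises(ValueError):
            HypothesisSpec({"a": 2})
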