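"""Sparse-representation selection and the group statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rfradiomics.selection import (
    compare_parameter_groups,
    iterative_sr,
    sr_fit_once,
    standardize_columns,
)

from oracles import ista_lasso


def labelled_matrix(rng, n=20, p=8):
    y = np.array([1] * (n // 2) + [0] * (n - n // 2))
    X = rng.standard_normal((n, p))
    return X, y


class TestSRFitOnce:
    def test_perfect_atom_dominates(self, rng):
        X, y = labelled_matrix(rng)
        ypm = np.where(y == 1, 1.0, -1.0)
        X[:, 3] = ypm  # plant the label as a column
        coef = sr_fit_once(X, y, lam=0.05)
        assert np.argmax(np.abs(coef)) == 3

    def test_lambda_above_max_zeroes_everything(self, rng):
        X, y = labelled_matrix(rng)
        ypm = np.where(y == 1, 1.0, -1.0)
        Xs = standardize_columns(X)
        lam_max = np.max(np.abs(Xs.T @ (ypm - ypm.mean()))) / len(y)
        coef = sr_fit_once(X, y, lam=lam_max * 1.01)
        assert np.all(coef == 0)

    def test_matches_ista_oracle_on_tiny_instance(self, rng):
        X = rng.standard_normal((6, 3))
        y = np.array([1, 1, 1, 0, 0, 0])
        lam = 0.1
        coef = sr_fit_once(X, y, lam)
        expected = ista_lasso(standardize_columns(X), np.where(y == 1, 1.0, -1.0), lam)
        np.testing.assert_allclose(coef, expected, atol=1e-6)

    def test_single_class_subset_rejected(self, rng):
        X = rng.standard_normal((6, 3))
        with pytest.raises(ValueError):
            sr_fit_once(X, np.ones(6), lam=0.1)


class TestIterativeSR:
    def test_reduces_to_single_fit(self, rng):
        X, y = labelled_matrix(rng, n=24, p=10)
        X[:, 2] += np.where(y == 1, 2.0, -2.0)
        sel = iterative_sr(X, y, n_iter=1, subsample_fraction=1.0, lam=0.05,
                           tal=0.0, seed=0)
        single = sr_fit_once(X, y, 0.05)
        order = np.argsort([-np.abs(s) for s in single], kind="stable")
        assert sel.ranking[0] == f"f{order[0]:05d}"
        assert len(sel.survivors) == len(sel.ranking)  # tal=0 keeps all

    def test_huge_tal_leaves_no_survivors(self, rng):
        X, y = labelled_matrix(rng)
        sel = iterative_sr(X, y, n_iter=3, lam=0.05, tal=np.inf, seed=0)
        assert sel.survivors == []

    def test_survivor_count_nonincreasing_in_tal(self, rng):
        X, y = labelled_matrix(rng, n=30, p=20)
        X[:, :3] += np.where(y == 1, 1.5, -1.5)[:, None]
        counts = [
            len(iterative_sr(X, y, n_iter=10, lam=0.02, tal=t, seed=3).survivors)
            for t in (0.0, 0.004, 0.04, 0.4)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_deterministic_under_seed(self, rng):
        X, y = labelled_matrix(rng, n=30, p=15)
        a = iterative_sr(X, y, n_iter=5, lam=0.05, seed=11)
        b = iterative_sr(X, y, n_iter=5, lam=0.05, seed=11)
        assert a.ranking == b.ranking
        assert a.coefficients == b.coefficients

    def test_ranking_invariant_to_column_order(self, rng):
        X, y = labelled_matrix(rng, n=30, p=12)
        X[:, 4] += np.where(y == 1, 2.0, -2.0)
        names = [f"g{j}" for j in range(12)]
        sel = iterative_sr(X, y, feature_names=names, n_iter=5, lam=0.05, seed=2)
        perm = np.arange(12)[::-1]
        sel_p = iterative_sr(X[:, perm], y,
                             feature_names=[names[j] for j in perm],
                             n_iter=5, lam=0.05, seed=2)
        assert sel.ranking == sel_p.ranking

    def test_bad_inputs_rejected(self, rng):
        X, y = labelled_matrix(rng)
        with pytest.raises(ValueError):
            iterative_sr(X, y, n_iter=0, lam=0.1)
        with pytest.raises(ValueError):
            iterative_sr(X, np.ones_like(y), lam=0.1)


class TestCompareParameterGroups:
    def _table(self, rng, shift=0.0):
        labels = np.array([1] * 10 + [0] * 10)
        df = pd.DataFrame({
            "DEA": rng.standard_normal(20) + shift * labels,
            "OND": rng.standard_normal(20) + 5,
            "SDSD": rng.standard_normal(20) + 2,
        })
        return df, labels

    def test_identical_groups_not_significant(self, rng):
        df, labels = self._table(rng, shift=0.0)
        anova, _ = compare_parameter_groups(df, labels)
        assert (anova["P"] > 0.05).all() or (anova["F"] < 5).all()

    def test_large_shift_significant_and_matches_f_identity(self, rng):
        df, labels = self._table(rng, shift=5.0)
        anova, tukey = compare_parameter_groups(df, labels)
        row = anova.loc[anova["parameter"] == "DEA"].iloc[0]
        assert row["P"] < 0.05
        # two groups: ANOVA F equals the squared pooled-variance t statistic
        g1 = df["DEA"][labels == 1]
        g0 = df["DEA"][labels == 0]
        t, _ = stats.ttest_ind(g0, g1)
        assert row["F"] == pytest.approx(t**2, rel=1e-10)
        assert len(tukey) == 3  # three pairwise parameter comparisons

    def test_degenerate_input_rejected(self):
        df = pd.DataFrame({"DEA": np.ones(8), "OND": np.ones(8), "SDSD": np.ones(8)})
        with pytest.raises(ValueError):
            compare_parameter_groups(df, np.array([1, 1, 1, 1, 0, 0, 0, 0]))
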