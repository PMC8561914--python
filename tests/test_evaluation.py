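"""NRMSE, grid-search CV, the replication protocol, Wilcoxon analysis."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import prognosit.evaluation as ev
from prognosit.evaluation import (
    HyperGrid,
    _select_best,
    all_features_partition,
    grid_search,
    nrmse,
    paired_ttest,
    paired_wilcoxon,
    run_replications,
    selection_frequencies,
)
from prognosit.geneset_io import map_to_features
from prognosit.mkl import MKLConfig
from prognosit.preprocess import cube_root
from prognosit.svr import SVRConfig
from prognosit.synthetic import SyntheticSpec, generate, generate_paired

FAST_MKL = MKLConfig(svr=SVRConfig(C=1.0, epsilon=0.0, tol=1e-6), max_iter=30)
SMALL_GRID = HyperGrid(C_values=(1.0, 10.0), multipliers=(0.25, 1.0), n_folds=3)


class TestNRMSE:
    def test_mean_predictor_scores_exactly_one(self, rng):
        y = rng.normal(size=25)
        assert nrmse(y, np.full(25, y.mean())) == pytest.approx(1.0, abs=1e-15)

    def test_perfect_prediction_scores_zero(self, rng):
        y = rng.normal(size=10)
        assert nrmse(y, y) == 0.0

    def test_hand_computed(self):
        assert nrmse(np.array([0.0, 2.0]), np.array([1.0, 1.0])) == pytest.approx(1.0)

    @settings(deadline=None, derandomize=True)
    @given(
        st.floats(min_value=0.1, max_value=50).flatmap(
            lambda a: st.tuples(
                st.just(a), st.floats(min_value=-100, max_value=100),
                st.integers(min_value=0, max_value=2**31 - 1),
            )
        )
    )
    def test_affine_invariance(self, params):
        a, b, seed = params
        r = np.random.default_rng(seed)
        y = r.normal(size=12)
        y_hat = y + r.normal(size=12, scale=0.3)
        assert nrmse(a * y + b, a * y_hat + b) == pytest.approx(
            nrmse(y, y_hat), abs=1e-12
        )

    def test_constant_y_rejected(self):
        with pytest.raises(ValueError):
            nrmse(np.ones(5), np.zeros(5))


class TestHyperGrid:
    def test_default_grid_is_the_study_grid(self):
        g = HyperGrid()
        np.testing.assert_allclose(g.C_values, [1e-3, 1e-2, 1e-1, 1, 10, 100, 1000])
        np.testing.assert_allclose(
            g.multipliers, [0, 0.25, 0.5, 0.75, 1.0, 1.25, 1.5, 1.75, 2.0]
        )
        assert g.n_folds == 4
        assert len(g.C_values) * len(g.multipliers) == 63


def tiny_problem(seed=3, n=24, d=8):
    r = np.random.default_rng(seed)
    X = r.normal(size=(n, d))
    y = np.sin(X[:, 0]) + 0.2 * r.normal(size=n)
    return X, y


class TestGridSearch:
    def test_enumerates_full_grid_across_folds(self):
        X, y = tiny_problem()
        part = all_features_partition(X.shape[1])
        res = grid_search(X, y, part, HyperGrid(), seed=0, mkl_config=FAST_MKL)
        assert len(res.table) == 63 * 4
        combos = set(
            itertools.product(HyperGrid().C_values, HyperGrid().multipliers)
        )
        seen = set(zip(res.table["C"], res.table["multiplier"]))
        assert seen == combos
        per_config = res.table.groupby(["C", "multiplier"]).size()
        assert (per_config == 4).all()

    def test_epsilon_is_multiplier_times_fold_training_std(self, monkeypatch):
        """Instrumented: every inner fit sees ε = multiplier × std(y_fold_train)."""
        calls = []
        real_fit = ev.mkl_fit

        def spy(stack, y_tr, cfg):
            calls.append((cfg.svr.epsilon, float(np.std(y_tr, ddof=1))))
            return real_fit(stack, y_tr, cfg)

        monkeypatch.setattr(ev, "mkl_fit", spy)
        X, y = tiny_problem()
        part = all_features_partition(X.shape[1])
        grid = HyperGrid(C_values=(1.0,), multipliers=(0.0, 0.5, 2.0), n_folds=3)
        grid_search(X, y, part, grid, seed=1, mkl_config=FAST_MKL)
        assert len(calls) == 3 * 3
        mults = [0.0, 0.5, 2.0] * 3
        for (eps, std_y), mult in zip(calls, mults):
            assert eps == pytest.approx(mult * std_y, abs=1e-12)

    def test_best_minimizes_mean_validation_nrmse(self):
        X, y = tiny_problem()
        part = all_features_partition(X.shape[1])
        res = grid_search(X, y, part, SMALL_GRID, seed=2, mkl_config=FAST_MKL)
        means = res.table.groupby(["C", "multiplier"])["nrmse"].mean()
        assert means.loc[(res.best_C, res.best_multiplier)] == pytest.approx(
            means.min()
        )

    def test_deterministic_under_seed(self):
        X, y = tiny_problem()
        part = all_features_partition(X.shape[1])
        a = grid_search(X, y, part, SMALL_GRID, seed=9, mkl_config=FAST_MKL)
        b = grid_search(X, y, part, SMALL_GRID, seed=9, mkl_config=FAST_MKL)
        assert (a.best_C, a.best_multiplier) == (b.best_C, b.best_multiplier)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_tie_break_prefers_small_C_then_small_multiplier(self):
        means = pd.Series(
            {
                (1.0, 0.25): 0.5,
                (1.0, 0.5): 0.5,
                (10.0, 0.25): 0.5,
                (10.0, 0.5): 0.7,
            }
        )
        assert _select_best(means) == (1.0, 0.25)


@pytest.fixture(scope="module")
def cohort():
    spec = SyntheticSpec(
        n_samples=40, n_genes=60, n_sets=4, informative_sets=(0,),
        noise_sd=0.3, seed=11,
    )
    expr, collection, volumes = generate(spec)
    part = map_to_features(collection, list(expr.columns))
    return expr.to_numpy(), cube_root(volumes.to_numpy()), part, collection


class TestRunReplications:
    def test_contract_and_determinism(self, cohort):
        X, y, part, _ = cohort
        grid = HyperGrid(C_values=(10.0,), multipliers=(0.25,), n_folds=2)
        res = run_replications(X, y, part, grid, n_reps=3, base_seed=4,
                               mkl_config=FAST_MKL)
        assert len(res) == 3
        for r in res:
            assert r.error is None
            assert r.test_nrmse >= 0
            assert r.used_gene_count <= X.shape[1]
        res2 = run_replications(X, y, part, grid, n_reps=3, base_seed=4,
                                mkl_config=FAST_MKL)
        assert [r.test_nrmse for r in res] == [r.test_nrmse for r in res2]

    def test_informative_sets_most_frequently_selected(self):
        """Two informative sets among twenty dominate the selection
        frequencies over ten replications."""
        spec = SyntheticSpec(
            n_samples=90, n_genes=300, n_sets=20, set_size=15,
            informative_sets=(0, 1), noise_sd=0.4, seed=11,
        )
        expr, collection, volumes = generate(spec)
        part = map_to_features(collection, list(expr.columns))
        X, y = expr.to_numpy(), cube_root(volumes.to_numpy())
        grid = HyperGrid(C_values=(10.0,), multipliers=(0.5,), n_folds=2)
        cfg = MKLConfig(svr=SVRConfig(C=1.0, epsilon=0.0, tol=1e-6), max_iter=200)
        res = run_replications(X, y, part, grid, n_reps=10, base_seed=0,
                               mkl_config=cfg)
        freq = selection_frequencies(res)
        counts = dict(zip(freq["set"], freq["frequency"]))
        informative = [collection.names[m] for m in spec.informative_sets]
        others = [counts[n] for n in collection.names if n not in informative]
        assert min(counts[n] for n in informative) > max(others)

    def test_failed_replication_recorded_not_raised(self, cohort, monkeypatch):
        X, y, part, _ = cohort
        grid = HyperGrid(C_values=(1.0,), multipliers=(0.25,), n_folds=2)
        real = ev.grid_search
        calls = {"n": 0}

        def flaky(*a, **kw):
            calls["n"] += 1
            if calls["n"] == 1:
                raise RuntimeError("boom")
            return real(*a, **kw)

        monkeypatch.setattr(ev, "grid_search", flaky)
        res = run_replications(X, y, part, grid, n_reps=2, base_seed=0,
                               mkl_config=FAST_MKL)
        assert res[0].error is not None and "boom" in res[0].error
        assert res[1].error is None


class TestSelectionFrequencies:
    def test_counting(self):
        from prognosit.evaluation import ReplicationResult

        mk = lambda i, sel: ReplicationResult(
            replication=i, seed=i, C=1, multiplier=0, test_nrmse=0.5,
            selected_sets=sel, used_gene_count=0,
            eta={"A": 0.5, "B": 0.3, "C": 0.2},
        )
        res = [mk(0, ["A"]), mk(1, ["A", "B"]), mk(2, ["A"])]
        freq = selection_frequencies(res)
        counts = dict(zip(freq["set"], freq["frequency"]))
        assert counts == {"A": 3, "B": 1, "C": 0}
        assert freq.attrs["mean_selected"] == pytest.approx(4 / 3)


def exact_signed_rank_p(diffs):
    """Enumeration oracle: two-sided p over all 2^n sign assignments."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    n = len(d)
    ranks = pd.Series(np.abs(d)).rank().to_numpy()
    w_obs = ranks[d > 0].sum()
    mean_w = ranks.sum() / 2
    stats = []
    for signs in itertools.product([0, 1], repeat=n):
        stats.append((ranks * np.array(signs)).sum())
    stats = np.array(stats)
    # two-sided: as or more extreme in |W − E[W]|
    p = np.mean(np.abs(stats - mean_w) >= np.abs(w_obs - mean_w) - 1e-12)
    return p


class TestPairedWilcoxon:
    def frames(self, t, n):
        genes = [f"G{i}" for i in range(t.shape[1])]
        idx = [f"P{i}" for i in range(t.shape[0])]
        return (
            pd.DataFrame(t, index=idx, columns=genes),
            pd.DataFrame(n, index=idx, columns=genes),
        )

    def test_all_positive_n6_exact_p(self):
        normal = np.zeros((6, 1))
        tumour = np.arange(1.0, 7.0).reshape(6, 1)
        t, n = self.frames(tumour, normal)
        df = paired_wilcoxon(t, n)
        assert df["p_value"][0] == pytest.approx(2 / 64)
        assert df["direction"][0] == "up"

    @pytest.mark.parametrize("n_pairs", [5, 7, 10])
    def test_exact_p_matches_sign_enumeration(self, n_pairs):
        r = np.random.default_rng(n_pairs)
        tumour = r.normal(size=(n_pairs, 4), loc=0.4)
        normal = r.normal(size=(n_pairs, 4))
        t, n = self.frames(tumour, normal)
        df = paired_wilcoxon(t, n)
        for j, gene in enumerate(t.columns):
            d = tumour[:, j] - normal[:, j]
            assert df.set_index("gene").loc[gene, "p_value"] == pytest.approx(
                exact_signed_rank_p(d), abs=1e-12
            )

    def test_identical_matrices_all_neutral(self):
        r = np.random.default_rng(0)
        m = r.normal(size=(8, 5))
        t, n = self.frames(m, m.copy())
        df = paired_wilcoxon(t, n)
        assert (df["p_value"] == 1.0).all()
        assert df["all_zero"].all()
        assert (~df["significant"]).all()
        assert (df["direction"] == "neutral").all()

    def test_pairing_invariance_under_consistent_permutation(self):
        r = np.random.default_rng(1)
        tumour = r.normal(size=(9, 6), loc=0.5)
        normal = r.normal(size=(9, 6))
        t, n = self.frames(tumour, normal)
        perm = r.permutation(9)
        tp, np_ = t.iloc[perm], n.iloc[perm]
        a = paired_wilcoxon(t, n)["p_value"]
        b = paired_wilcoxon(tp, np_)["p_value"]
        np.testing.assert_allclose(a, b)

    def test_validation_errors(self):
        r = np.random.default_rng(2)
        t, n = self.frames(r.normal(size=(6, 3)), r.normal(size=(6, 3)))
        with pytest.raises(ValueError, match="pairing mismatch"):
            paired_wilcoxon(t, n.rename(index={"P0": "QX"}))
        with pytest.raises(ValueError, match="genes"):
            paired_wilcoxon(t, n.rename(columns={"G0": "H0"}))
        t4, n4 = self.frames(r.normal(size=(3, 2)), r.normal(size=(3, 2)))
        with pytest.raises(ValueError, match="at least 4"):
            paired_wilcoxon(t4, n4)

    def test_null_pairs_flag_about_five_percent(self):
        spec = SyntheticSpec(
            n_genes=400, n_sets=4, within_corr=0.0, n_pairs=30,
            paired_shift=tuple([0.0] * 400), seed=21,
        )
        tumour, normal = generate_paired(spec)
        df = paired_wilcoxon(tumour, normal)
        rate = df["significant"].mean()
        assert 0.02 <= rate <= 0.09

    def test_bh_correction_column(self):
        r = np.random.default_rng(3)
        t, n = self.frames(r.normal(size=(10, 8)), r.normal(size=(10, 8)))
        df = paired_wilcoxon(t, n, bh_correct=True)
        assert "p_adjusted" in df
        assert (df["p_adjusted"] >= df["p_value"] - 1e-15).all()


class TestPairedTTest:
    def test_symmetric_inputs_give_p_one(self):
        a = np.array([0.5, 0.6, 0.7, 0.8])
        assert paired_ttest(a, a + 0.0) == pytest.approx(1.0) or np.isnan(
            paired_ttest(a, a)
        )

    def test_shifted_inputs_significant(self):
        r = np.random.default_rng(4)
        a = r.normal(size=30, loc=0.8, scale=0.05)
        b = a - 0.1 + r.normal(size=30, scale=0.01)
        assert paired_ttest(a, b) < 0.001
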