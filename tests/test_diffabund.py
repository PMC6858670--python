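import itertools
import statistics

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps
from hypothesis import given, settings, strategies as st

from codaplot.diffabund import (
    DirichletEffectEstimator,
    GroupDesign,
    MonteCarloEnsemble,
    aldex_effects,
    benjamini_hochberg,
    effect_plot_data,
    effect_statistics,
    ma_plot_data,
    per_instance_effects,
    per_instance_tests,
    sample_mc_instances,
)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def oracle_effect(pa, pb):
    """Brute-force pair enumeration of the effect estimands."""
    btw = [b - a for b in pb for a in pa]
    diff_btw = statistics.median(btw)
    n_pos = sum(1 for d in btw if d > 0)
    n_neg = sum(1 for d in btw if d < 0)
    n_zero = len(btw) - n_pos - n_neg
    overlap = min(
        (n_pos + 0.5 * n_zero) / len(btw), (n_neg + 0.5 * n_zero) / len(btw)
    )
    win_a = statistics.median(
        abs(u - v) for u, v in itertools.combinations(pa, 2)
    )
    win_b = statistics.median(
        abs(u - v) for u, v in itertools.combinations(pb, 2)
    )
    diff_win = max(win_a, win_b)
    if diff_win > 0:
        effect = diff_btw / diff_win
    elif diff_btw == 0:
        effect = 0.0
    else:
        effect = np.sign(diff_btw) * np.inf
    return diff_btw, diff_win, effect, overlap


def oracle_rank_sum_p(a, b):
    """Exact two-sided rank-sum p by enumerating all rank assignments."""
    pooled = sorted(a + b)
    n1 = len(a)
    obs = sum(pooled.index(v) + 1 for v in a)  # no ties assumed
    count = 0
    total = 0
    sums = [
        sum(c) for c in itertools.combinations(range(1, len(pooled) + 1), n1)
    ]
    mean = statistics.mean(sums)
    for s in sums:
        total += 1
        if abs(s - mean) >= abs(obs - mean):
            count += 1
    return count / total


def make_ensemble(instances):
    """Wrap a (K, F, S) array with generic ids."""
    arr = np.asarray(instances, dtype=float)
    return MonteCarloEnsemble(
        instances=arr,
        feature_ids=[f"f{i}" for i in range(arr.shape[1])],
        sample_ids=[f"s{j}" for j in range(arr.shape[2])],
        prior=0.5,
        seed=0,
    )


def two_group_design(n_a, n_b):
    ids = [f"s{j}" for j in range(n_a + n_b)]
    return GroupDesign(ids, ["A"] * n_a + ["B"] * n_b)


# ---------------------------------------------------------------------------
# Monte-Carlo sampling
# ---------------------------------------------------------------------------

class TestSampleMcInstances:
    def test_same_seed_is_bit_identical(self, small_table):
        e1 = sample_mc_instances(small_table, n_instances=8, seed=11)
        e2 = sample_mc_instances(small_table, n_instances=8, seed=11)
        assert np.array_equal(e1.instances, e2.instances)

    def test_different_seed_differs(self, small_table):
        e1 = sample_mc_instances(small_table, n_instances=8, seed=11)
        e2 = sample_mc_instances(small_table, n_instances=8, seed=12)
        assert not np.array_equal(e1.instances, e2.instances)

    def test_clr_columns_sum_to_zero(self, small_table):
        e = sample_mc_instances(small_table, n_instances=16, seed=0)
        np.testing.assert_allclose(e.instances.sum(axis=1), 0.0, atol=1e-9)

    def test_posterior_mean_matches_dirichlet_closed_form(self):
        # mean of Dirichlet(x + prior) is (x_j + prior) / (n + D * prior)
        x = np.array([[0, 5, 10, 100, 1]], dtype=float).T  # 5 features, 1 sample
        K = 2000
        ens = sample_mc_instances(x, n_instances=K, prior=0.5, seed=3,
                                  keep_proportions=True)
        props = ens.proportions[:, :, 0]
        expected = (x[:, 0] + 0.5) / (x.sum() + 0.5 * len(x))
        se = props.std(axis=0, ddof=1) / np.sqrt(K)
        assert (np.abs(props.mean(axis=0) - expected) <= 3 * se + 1e-12).all()

    def test_huge_equal_counts_concentrate_clr_at_zero(self):
        x = np.full((6, 1), 10**6)
        ens = sample_mc_instances(x, n_instances=128, seed=4)
        assert np.abs(ens.instances).max() < 0.01

    @pytest.mark.parametrize("kwargs", [{"n_instances": 0}, {"prior": 0.0}])
    def test_invalid_parameters_rejected(self, small_table, kwargs):
        with pytest.raises(ValueError):
            sample_mc_instances(small_table, **kwargs)


# ---------------------------------------------------------------------------
# effect statistics
# ---------------------------------------------------------------------------

class TestEffectStatistics:
    def test_hand_example_between_only(self):
        # P_A={0,0}, P_B={1,3}: between differences {1,3,1,3} -> median 2
        ens = make_ensemble([[[0.0, 0.0, 1.0, 3.0]]])
        eff = effect_statistics(ens, two_group_design(2, 2), mode="exact")
        assert eff["diff.btw"].iloc[0] == 2.0

    def test_hand_example_full(self):
        # P_A={0,2}, P_B={4,6}: btw median 4, within medians 2 and 2,
        # effect 2, no overlap
        ens = make_ensemble([[[0.0, 2.0, 4.0, 6.0]]])
        eff = effect_statistics(ens, two_group_design(2, 2), mode="exact")
        row = eff.iloc[0]
        assert row["diff.btw"] == 4.0
        assert row["diff.win"] == 2.0
        assert row["effect"] == 2.0
        assert row["overlap"] == 0.0
        assert row["rab.win.A"] == 1.0 and row["rab.win.B"] == 5.0

    def test_degenerate_constant_groups(self):
        ens = make_ensemble([[[1.0, 1.0, 1.0, 1.0]]])
        eff = effect_statistics(ens, two_group_design(2, 2), mode="exact")
        row = eff.iloc[0]
        assert row["diff.btw"] == 0.0
        assert row["diff.win"] == 0.0
        assert row["effect"] == 0.0  # 0/0 convention
        assert row["overlap"] == 0.5  # zero ties split evenly

    def test_signed_infinity_on_zero_dispersion(self):
        ens = make_ensemble([[[0.0, 0.0, 1.0, 1.0]]])
        eff = effect_statistics(ens, two_group_design(2, 2), mode="exact")
        assert eff["effect"].iloc[0] == np.inf

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10**6))
    def test_exact_mode_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(1, 4))
        n_a = int(rng.integers(2, 4))
        n_b = int(rng.integers(2, 4))
        while k * min(n_a, n_b) < 2 or k * max(n_a, n_b) > 12:
            k = int(rng.integers(1, 4))
            n_a = int(rng.integers(2, 4))
            n_b = int(rng.integers(2, 4))
        inst = rng.normal(size=(k, 2, n_a + n_b)).round(3)
        ens = make_ensemble(inst)
        design = two_group_design(n_a, n_b)
        eff = effect_statistics(ens, design, mode="exact")
        for f in range(2):
            pa = list(inst[:, f, :n_a].ravel())
            pb = list(inst[:, f, n_a:].ravel())
            db, dw, e, ov = oracle_effect(pa, pb)
            assert abs(eff["diff.btw"].iloc[f] - db) < 1e-12
            assert abs(eff["diff.win"].iloc[f] - dw) < 1e-12
            assert abs(eff["overlap"].iloc[f] - ov) < 1e-12
            if np.isfinite(e):
                assert abs(eff["effect"].iloc[f] - e) < 1e-12

    def test_subsample_converges_to_exact(self):
        rng = np.random.default_rng(0)
        inst = rng.normal(size=(4, 3, 8))
        ens = make_ensemble(inst)
        design = two_group_design(4, 4)
        exact = effect_statistics(ens, design, mode="exact")
        err = []
        for m in (100, 10000):
            sub = effect_statistics(ens, design, mode="subsample", max_pairs=m, seed=1)
            err.append(np.abs(sub["diff.btw"] - exact["diff.btw"]).max())
        assert err[1] < err[0]
        assert err[1] < 0.1

    def test_antisymmetry_under_label_swap(self):
        rng = np.random.default_rng(5)
        inst = rng.normal(size=(3, 4, 6))
        ens = make_ensemble(inst)
        fwd = effect_statistics(ens, two_group_design(3, 3), mode="exact")
        ids = [f"s{j}" for j in range(6)]
        # role swap: the second group now appears first, so B-minus-A flips
        swapped = GroupDesign(ids[3:] + ids[:3], ["A"] * 3 + ["B"] * 3)
        rev = effect_statistics(ens, swapped, mode="exact")
        np.testing.assert_allclose(rev["diff.btw"], -fwd["diff.btw"], atol=1e-12)
        np.testing.assert_allclose(rev["effect"], -fwd["effect"], atol=1e-12)
        np.testing.assert_allclose(rev["diff.win"], fwd["diff.win"], atol=1e-12)
        np.testing.assert_allclose(rev["overlap"], fwd["overlap"], atol=1e-12)

    def test_sign_consistency_property(self):
        rng = np.random.default_rng(9)
        inst = rng.normal(size=(2, 20, 8))
        eff = effect_statistics(
            make_ensemble(inst), two_group_design(4, 4), mode="exact"
        )
        assert (eff["diff.win"] >= 0).all()
        assert eff["overlap"].between(0, 0.5).all()
        nz = eff["diff.win"] > 0
        assert (
            np.sign(eff.loc[nz, "effect"]) == np.sign(eff.loc[nz, "diff.btw"])
        ).all()

    def test_group_with_one_pooled_value_rejected(self):
        ens = make_ensemble([[[0.0, 1.0, 2.0]]])
        ids = ["s0", "s1", "s2"]
        with pytest.raises(ValueError, match="at least 2 pooled"):
            effect_statistics(ens, GroupDesign(ids, ["A", "B", "B"]), mode="exact")


# ---------------------------------------------------------------------------
# per-instance tests and BH
# ---------------------------------------------------------------------------

class TestPerInstanceTests:
    def test_wilcoxon_exact_hand_value(self):
        # A=[1,2,3,4], B=[5,6,7,8]: two-sided exact p = 2/70
        inst = np.array([[[1.0, 2, 3, 4, 5, 6, 7, 8]]])
        out = per_instance_tests(make_ensemble(inst), two_group_design(4, 4))
        np.testing.assert_allclose(out["wi.ep"].iloc[0], 2 / 70, atol=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10**6))
    def test_wilcoxon_exact_agrees_with_enumeration_and_scipy(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = int(rng.integers(2, 5)), int(rng.integers(2, 5))
        a = list(rng.permutation(np.arange(1.0, n1 + n2 + 1))[:n1])
        b = [v for v in np.arange(1.0, n1 + n2 + 1) if v not in a]
        inst = np.array([[a + b]])
        out = per_instance_tests(make_ensemble(inst), two_group_design(n1, n2))
        expected = oracle_rank_sum_p(a, b)
        np.testing.assert_allclose(out["wi.ep"].iloc[0], expected, atol=1e-12)
        scipy_p = sps.mannwhitneyu(a, b, method="exact").pvalue
        np.testing.assert_allclose(out["wi.ep"].iloc[0], scipy_p, atol=1e-12)

    def test_constant_feature_has_p_one(self):
        inst = np.array([[[2.0] * 8, [1.0, 2, 3, 4, 5, 6, 7, 8]]])
        out = per_instance_tests(make_ensemble(inst), two_group_design(4, 4))
        assert out["we.ep"].iloc[0] == 1.0
        assert out["wi.ep"].iloc[0] == 1.0

    def test_zero_variance_unequal_means_gives_p_zero(self):
        inst = np.array([[[0.0, 0, 0, 1, 1, 1], [0.5, 1, 0, 1, 0.2, 0.9]]])
        out = per_instance_tests(make_ensemble(inst), two_group_design(3, 3))
        assert out["we.ep"].iloc[0] == 0.0

    def test_ebh_is_mean_of_per_instance_bh(self):
        # dual route: recompute per instance with scipy + statsmodels
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(17)
        inst = rng.normal(size=(5, 6, 8))
        ens = make_ensemble(inst)
        out = per_instance_tests(ens, two_group_design(4, 4))
        we, wi = [], []
        for k in range(5):
            a, b = inst[k, :, :4], inst[k, :, 4:]
            pw = sps.ttest_ind(a, b, axis=1, equal_var=False).pvalue
            pu = np.array(
                [
                    sps.mannwhitneyu(a[f], b[f], method="exact").pvalue
                    for f in range(6)
                ]
            )
            we.append(multipletests(pw, method="fdr_bh")[1])
            wi.append(multipletests(pu, method="fdr_bh")[1])
        np.testing.assert_allclose(out["we.eBH"], np.mean(we, axis=0), atol=1e-10)
        np.testing.assert_allclose(out["wi.eBH"], np.mean(wi, axis=0), atol=1e-10)

    def test_large_sample_uses_tie_corrected_normal_approximation(self):
        rng = np.random.default_rng(3)
        n = 15  # combined 30 > exact threshold
        a, b = rng.normal(0, 1, n), rng.normal(1, 1, n)
        inst = np.array([[np.concatenate([a, b])]])
        out = per_instance_tests(make_ensemble(inst), two_group_design(n, n))
        ref = sps.mannwhitneyu(a, b, method="asymptotic").pvalue
        np.testing.assert_allclose(out["wi.ep"].iloc[0], ref, atol=1e-10)

    def test_group_smaller_than_two_rejected(self):
        inst = np.zeros((1, 2, 3))
        ens = make_ensemble(inst)
        with pytest.raises(ValueError, match="at least 2 samples"):
            per_instance_tests(ens, GroupDesign(["s0", "s1", "s2"], ["A", "B", "B"]))


class TestBenjaminiHochberg:
    def test_hand_step_up(self):
        np.testing.assert_allclose(
            benjamini_hochberg([0.01, 0.02, 0.03, 0.04]), [0.04] * 4, atol=1e-15
        )

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(benjamini_hochberg([0.3]), [0.3])

    def test_all_ones(self):
        np.testing.assert_allclose(benjamini_hochberg([1.0, 1.0, 1.0]), 1.0)

    def test_nan_propagates_and_is_excluded_from_m(self):
        out = benjamini_hochberg([0.01, np.nan, 0.04])
        assert np.isnan(out[1])
        np.testing.assert_allclose(out[[0, 2]], [0.02, 0.04])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.1, 1.5])

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        p=st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=30)
    )
    def test_matches_statsmodels(self, p):
        from statsmodels.stats.multitest import multipletests

        ref = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(benjamini_hochberg(p), ref, atol=1e-12)


# ---------------------------------------------------------------------------
# plot records and estimator
# ---------------------------------------------------------------------------

def toy_effects():
    return pd.DataFrame(
        {
            "rab.all": [3.2, 1.0, 2.0],
            "diff.btw": [-1.1, 0.05, 2.0],
            "diff.win": [0.7, 0.5, 1.0],
            "effect": [-1.5, 0.1, 2.0],
            "wi.eBH": [0.2, 0.8, 0.01],
        },
        index=["g1", "g2", "g3"],
    )


class TestPlotData:
    def test_classing_rules(self):
        rec = effect_plot_data(toy_effects())
        assert rec.loc["g3", "class"] == "both"
        assert rec.loc["g2", "class"] == "nonsignificant"
        assert rec.loc["g1", "class"] == "effect_only"  # sign ignored

    def test_ma_plot_passthrough_and_shared_classing(self):
        eff = toy_effects()
        ma = ma_plot_data(eff)
        assert ma.loc["g1", "x"] == 3.2 and ma.loc["g1", "y"] == -1.1
        pd.testing.assert_series_equal(ma["class"], effect_plot_data(eff)["class"])

    def test_empty_effect_table_gives_empty_records(self):
        empty = toy_effects().iloc[:0]
        assert len(effect_plot_data(empty)) == 0

    def test_per_instance_effects_shape_and_quantile_cover(self):
        rng = np.random.default_rng(2)
        inst = rng.normal(size=(50, 3, 8))
        ens = make_ensemble(inst)
        eff_k = per_instance_effects(ens, two_group_design(4, 4))
        assert eff_k.shape == (50, 3)


class TestDirichletEffectEstimator:
    def test_fit_produces_aldex_dialect_table(self, synth_spiked):
        table, meta, truth = synth_spiked
        est = DirichletEffectEstimator(n_instances=16, max_pairs=2000, random_state=0)
        est.fit(table.counts.to_numpy().T, meta.column("group").to_numpy(),
                feature_names=table.feature_ids)
        assert list(est.classes_) == ["A", "B"]
        for col in ("rab.all", "diff.btw", "diff.win", "effect", "overlap",
                    "we.ep", "we.eBH", "wi.ep", "wi.eBH"):
            assert col in est.effects_.columns
        assert len(est.effects_) == table.shape[0]
        assert set(est.plot_frame("effect")["class"]) <= {
            "both", "effect_only", "test_significant", "nonsignificant"
        }

    def test_sklearn_clone_round_trip(self):
        from sklearn.base import clone

        est = DirichletEffectEstimator(n_instances=4, prior=0.1)
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()


class TestGroupDesign:
    def test_requires_exactly_two_labels(self):
        with pytest.raises(ValueError, match="two condition labels"):
            GroupDesign(["a", "b"], ["x", "x"])
        with pytest.raises(ValueError, match="two condition labels"):
            GroupDesign(["a", "b", "c"], ["x", "y", "z"])

    def test_label_order_by_first_appearance(self):
        d = GroupDesign(["a", "b", "c"], ["late", "early", "late"])
        assert d.labels == ("late", "early")

    def test_aldex_effects_round_trips_through_reader(self, synth_spiked, tmp_path):
        from codaplot.io import read_effect_table

        table, meta, _ = synth_spiked
        sub = table.select(features=table.feature_ids[:12])
        design = GroupDesign.from_metadata(meta, "group")
        eff = aldex_effects(sub, design, n_instances=8, seed=1, max_pairs=500)
        p = tmp_path / "eff.tsv"
        eff.to_csv(p, sep="\t", index_label="feature_id")
        back = read_effect_table(p)
        assert back.attrs["group_labels"] == ("A", "B")
        np.testing.assert_allclose(back["effect"], eff["effect"], atol=1e-9)
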