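import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from etpath import (
    AbundanceTable,
    OmicsError,
    differential,
    enrichment,
    filter_valid,
    impute_missing,
    make_omics_table,
    module_map,
    redox_ratio,
)
from etpath.omics import _running_sum_es
from etpath.simulate import OmicsDesign, metabolome_design

from oracle_utils import brute_force_bh


def _table(values: dict, groups: dict, log2=True) -> AbundanceTable:
    df = pd.DataFrame(values).T
    g = pd.Series({s: name for name, ss in groups.items() for s in ss})
    return AbundanceTable(values=df, groups=g, log2=log2)


GROUPS = {"patient": ["p1", "p2", "p3"], "control": ["c1", "c2", "c3"]}
COLS = ["p1", "p2", "p3", "c1", "c2", "c3"]


def _df(rows: dict) -> AbundanceTable:
    df = pd.DataFrame(rows, index=COLS).T
    g = pd.Series({s: n for n, ss in GROUPS.items() for s in ss})
    return AbundanceTable(values=df, groups=g, log2=True)


class TestFilterValid:
    def test_complete_in_one_group_kept(self):
        t = _df({"f1": [20, 21, 20, np.nan, 19, 19]})
        assert list(filter_valid(t).values.index) == ["f1"]

    def test_missing_in_every_group_dropped(self):
        t = _df({"f1": [20, np.nan, 20, np.nan, 19, 19]})
        assert len(filter_valid(t).values) == 0

    def test_matches_brute_force_on_synthetic_dropout(self):
        design = OmicsDesign(n_features=150, dropout_midpoint=21.0, seed=5)
        t, _ = make_omics_table(design)
        t = t.to_log2()
        kept = filter_valid(t).values.index
        expected = []
        for f in t.values.index:
            ok = False
            for g in t.group_names:
                if t.values.loc[f, t.samples_of(g)].notna().all():
                    ok = True
            if ok:
                expected.append(f)
        assert list(kept) == expected


class TestImputation:
    def test_no_missing_is_identity(self):
        t = _df({"f1": [20, 21, 20, 19, 19, 18], "f2": [10, 11, 10, 9, 9, 8]})
        out = impute_missing(t, seed=1)
        pd.testing.assert_frame_equal(out.values, t.values)

    def test_seed_reproducibility(self):
        t = _df({
            "f1": [20, 21, np.nan, 19, 19, 18],
            "f2": [10, 11, 10, np.nan, 9, 8],
            "f3": [15, 15, 16, 14, 15, 14],
            "f4": [17, 18, 17, 18, 17, 18],
        })
        a = impute_missing(t, seed=7).values
        b = impute_missing(t, seed=7).values
        pd.testing.assert_frame_equal(a, b)
        c = impute_missing(t, seed=8).values
        assert not a.equals(c)

    def test_downshifted_distribution(self):
        # one sample with many observed values and many missing ones:
        # imputed mean must sit at mean - 1.8 SD within Monte-Carlo error
        rng = np.random.default_rng(0)
        obs = rng.normal(20.0, 2.0, size=500)
        col = np.concatenate([obs, np.full(10_000, np.nan)])
        df = pd.DataFrame({"s1": col})
        t = AbundanceTable(values=df, groups=pd.Series({"s1": "g"}), log2=True)
        out = impute_missing(t, shift=1.8, width=0.3, seed=3)
        imputed = out.values["s1"].iloc[500:]
        mu, sd = np.mean(obs), np.std(obs, ddof=1)
        se = (0.3 * sd) / math.sqrt(len(imputed))
        assert imputed.mean() == pytest.approx(mu - 1.8 * sd, abs=3 * se)
        assert imputed.std(ddof=1) == pytest.approx(0.3 * sd, rel=0.05)

    def test_too_few_observed_errors(self):
        t = _df({"f1": [20, np.nan, np.nan, 19, 19, 18],
                 "f2": [np.nan, np.nan, 21, 18, 19, 17],
                 "f3": [np.nan, 20, 21, 18, 19, 17]})
        with pytest.raises(OmicsError):
            impute_missing(t, seed=0)


class TestDifferential:
    def test_identical_groups(self):
        t = _df({"f1": [20, 21, 19, 20, 21, 19]})
        d = differential(t, "patient", "control")
        assert d.loc["f1", "log2fc"] == pytest.approx(0.0)
        assert d.loc["f1", "p"] == pytest.approx(1.0)

    def test_constant_equal_feature_p_one_by_convention(self):
        t = _df({"f1": [5, 5, 5, 5, 5, 5], "f2": [20, 21, 19, 16, 17, 15]})
        d = differential(t, "patient", "control")
        assert d.loc["f1", "p"] == 1.0 and d.loc["f1", "t"] == 0.0

    def test_bh_hand_example(self):
        # four features engineered to give a known p-vector is fragile;
        # instead check the q-values on the spec'd p-vector directly
        q = brute_force_bh([0.01, 0.02, 0.04, 0.05])
        assert np.allclose(q, [0.04, 0.04, 0.05, 0.05])
        from statsmodels.stats.multitest import multipletests

        _, q2, _, _ = multipletests([0.01, 0.02, 0.04, 0.05], method="fdr_bh")
        assert np.allclose(q2, q)

    def test_planted_16fold_depletion_flagged(self):
        effects = OmicsDesign.pack_effects({"GSH": {"patient": 1 / 16}})
        t, _ = make_omics_table(OmicsDesign(n_features=121, cv=0.10,
                                            effects=effects, seed=11))
        d = differential(t.to_log2(), "patient", "control")
        assert d.loc["GSH", "log2fc"] == pytest.approx(-4.0, abs=0.5)
        assert bool(d.loc["GSH", "significant_bh"])

    def test_invariant_to_column_order_and_global_scaling(self):
        t, _ = make_omics_table(OmicsDesign(n_features=40, seed=2))
        t = t.to_log2()
        d1 = differential(t, "patient", "control")
        shuffled = t.values[np.random.default_rng(0).permutation(t.values.columns)]
        t2 = AbundanceTable(values=shuffled, groups=t.groups, log2=True)
        d2 = differential(t2, "patient", "control")
        pd.testing.assert_frame_equal(d1, d2)
        t3 = AbundanceTable(values=t.values + math.log2(7.3), groups=t.groups, log2=True)
        d3 = differential(t3, "patient", "control")
        assert np.allclose(d1["log2fc"], d3["log2fc"])
        assert np.allclose(d1["t"], d3["t"])

    def test_q_at_least_p(self):
        t, _ = make_omics_table(OmicsDesign(n_features=60, seed=4))
        d = differential(t.to_log2(), "patient", "control")
        assert (d["q"] >= d["p"] - 1e-12).all()


@settings(deadline=None, derandomize=True, max_examples=50)
@given(st.lists(st.floats(min_value=1e-12, max_value=1.0), min_size=1, max_size=60))
def test_bh_matches_brute_force_stepup(pvals):
    """BH q-values from statsmodels equal the literal step-up definition."""
    from statsmodels.stats.multitest import multipletests

    _, q, _, _ = multipletests(pvals, method="fdr_bh")
    assert np.allclose(q, brute_force_bh(pvals), rtol=1e-10, atol=1e-12)


class TestRedoxRatio:
    def test_identical_groups_f_zero(self):
        t = _df({"GSH": [20, 21, 19, 20, 21, 19], "GSSG": [18, 18, 18, 18, 18, 18]})
        r = redox_ratio(t)
        assert r.f_statistic == pytest.approx(0.0, abs=1e-9)
        assert r.p_value == pytest.approx(1.0, abs=1e-9)

    def test_planted_ratio_difference(self):
        # GSH 16-fold down and GSSG 2-fold up in patients: the log2
        # ratio difference between groups is ~log2(1/32) = -5
        effects = OmicsDesign.pack_effects(
            {"GSH": {"patient": 1 / 16}, "GSSG": {"patient": 2.0}}
        )
        t, _ = make_omics_table(OmicsDesign(n_features=10, cv=0.10,
                                            effects=effects, seed=21))
        r = redox_ratio(t.to_log2())
        diff = r.group_means["patient"] - r.group_means["control"]
        assert diff == pytest.approx(-5.0, abs=0.5)

    def test_three_group_tukey_significance(self):
        t, _ = make_omics_table(metabolome_design(seed=6))
        r = redox_ratio(t.to_log2())
        pw = r.pairwise.set_index(["group_a", "group_b"])["p_adj"]
        assert pw[("control", "nd5")] < 0.001
        assert pw[("control", "ndufs1")] < 0.001

    def test_anova_matches_permutation_oracle(self):
        # group sizes large enough that the permutation distribution of F
        # approximates the parametric null; at triplicate scale the
        # permutation null is too discrete to compare against
        effects = OmicsDesign.pack_effects({"GSH": {"patient": 1 / 1.6}, "GSSG": {}})
        design = OmicsDesign(n_features=5, cv=0.4, effects=effects, seed=9,
                             groups=(("patient", 6), ("control", 6)))
        t, _ = make_omics_table(design)
        t = t.to_log2()
        r = redox_ratio(t)
        # permutation oracle on the per-sample ratios
        vals = r.per_sample.to_numpy()
        labels = np.array([t.groups[s] for s in r.per_sample.index])
        obs_f = r.f_statistic
        rng = np.random.default_rng(0)
        count = 0
        n_perm = 4000
        from scipy.stats import f_oneway

        for _ in range(n_perm):
            perm = rng.permutation(labels)
            f = f_oneway(*[vals[perm == g] for g in np.unique(labels)])[0]
            count += f >= obs_f
        p_perm = (1 + count) / (1 + n_perm)
        mc_se = math.sqrt(max(p_perm * (1 - p_perm), 1e-4) / n_perm)
        assert r.p_value == pytest.approx(p_perm, abs=3 * mc_se + 0.03)

    def test_missing_feature_errors(self):
        t = _df({"GSH": [1, 2, 3, 4, 5, 6]})
        with pytest.raises(OmicsError):
            redox_ratio(t)


class TestEnrichment:
    def test_whole_universe_set_has_es_one(self):
        ranked = pd.Series(np.linspace(3, -3, 20), index=[f"g{i}" for i in range(20)])
        (res,) = enrichment(ranked, {"all": tuple(ranked.index)}, n_perm=50, seed=0)
        assert res.es == pytest.approx(1.0)

    def test_brute_force_running_sum_small_universe(self):
        # 10-feature universe, 3-feature set: evaluate the running sum by hand
        scores = np.array([5.0, 4.0, 3.0, 2.0, 1.0, -1.0, -2.0, -3.0, -4.0, -5.0])
        names = [f"g{i}" for i in range(10)]
        ranked = pd.Series(scores, index=names)
        members = {"g0", "g3", "g8"}
        # hand evaluation (weight p=1)
        hit_w = {"g0": 5.0, "g3": 2.0, "g8": 4.0}
        total = sum(hit_w.values())
        running, cur, best = [], 0.0, 0.0
        for n, sc in zip(names, scores):
            if n in members:
                cur += hit_w[n] / total
            else:
                cur -= 1.0 / 7.0
            if abs(cur) > abs(best):
                best = cur
        (res,) = enrichment(ranked, {"set": tuple(members)}, n_perm=20, min_size=3, seed=0)
        assert res.es == pytest.approx(best, rel=1e-12)

    def test_small_sets_excluded(self):
        ranked = pd.Series(np.arange(10.0), index=[f"g{i}" for i in range(10)])
        res = enrichment(ranked, {"tiny": ("g1", "g2"), "ok": tuple(f"g{i}" for i in range(5))},
                         n_perm=20, seed=0)
        by_id = {r.set_id: r for r in res}
        assert by_id["tiny"].excluded and "below minimum" in by_id["tiny"].reason
        assert not by_id["ok"].excluded

    def test_planted_module_depletion_specific(self):
        from etpath.simulate import proteome_design

        design, sets = proteome_design(seed=13)
        t, _ = make_omics_table(design)
        d = differential(t.to_log2(), "patient", "control")
        res = {r.set_id: r for r in enrichment(d["log2fc"], sets, n_perm=500, seed=13)}
        assert res["N"].q <= 0.05
        assert res["Q"].q > 0.05 and res["P"].q > 0.05

    def test_es_bounded(self):
        rng = np.random.default_rng(3)
        ranked = pd.Series(rng.normal(size=80), index=[f"g{i}" for i in range(80)])
        sets = {f"s{j}": tuple(rng.choice(ranked.index, 8, replace=False)) for j in range(5)}
        for r in enrichment(ranked, sets, n_perm=50, seed=1):
            assert -1.0 <= r.es <= 1.0 and 0.0 < r.p <= 1.0


class TestModuleMap:
    def test_uniform_module_mean(self):
        d = pd.DataFrame({"log2fc": [-1.0, -1.0, -1.0]}, index=["a", "b", "c"])
        mm = module_map(d, {"M": ("a", "b", "c")})
        assert mm.loc["M", "mean_log2fc"] == pytest.approx(-1.0)

    def test_absent_members_counted_nd(self):
        d = pd.DataFrame({"log2fc": [-1.0, -3.0]}, index=["a", "b"])
        mm = module_map(d, {"M": ("a", "b", "zz")})
        assert mm.loc["M", "n_nd"] == 1
        assert mm.loc["M", "mean_log2fc"] == pytest.approx(-2.0)

    def test_empty_module_is_nd(self):
        d = pd.DataFrame({"log2fc": [-1.0]}, index=["a"])
        mm = module_map(d, {"M": ("x", "y")})
        assert mm.loc["M", "n_detected"] == 0
        assert math.isnan(mm.loc["M", "mean_log2fc"])

    def test_planted_depletion_orders_modules(self):
        from etpath.simulate import proteome_design

        design, sets = proteome_design(seed=17)
        t, _ = make_omics_table(design)
        d = differential(t.to_log2(), "patient", "control")
        mm = module_map(d, sets)
        assert mm.loc["N", "mean_log2fc"] < mm.loc["Q", "mean_log2fc"]
        assert mm.loc["N", "mean_log2fc"] < mm.loc["P", "mean_log2fc"]
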