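import numpy as np
import pandas as pd
import pytest
from scipy import stats

from paleobrain.group_statistics import (
    anova_ryan,
    cohens_d,
    icv_adjust,
    laterality_analysis,
    ryan_alpha,
    volume_summary,
)

# cerebral/cerebellar volumes (cc) of the eight fossil reconstructions as
# printed in the study results
NT_VOLUMES = [(1304, 182), (1159, 140), (1268, 166), (912, 106)]
EH_VOLUMES = [(1075, 147), (1053, 146), (1205, 165), (1208, 156)]


def fossil_table():
    rows = []
    for g, vols in (("NT", NT_VOLUMES), ("EH", EH_VOLUMES)):
        for i, (cer, cb) in enumerate(vols):
            rows.append(dict(specimen=f"{g}{i}", group=g,
                             cerebrum_cc=float(cer), cerebellum_cc=float(cb)))
    return pd.DataFrame(rows)


class TestVolumeSummary:
    def test_published_fossil_volumetrics(self):
        s = volume_summary(fossil_table()).set_index("group")
        assert s.loc["NT", "cerebral_mean_cc"] == pytest.approx(1161, abs=0.5)
        assert s.loc["NT", "cerebral_sd_cc"] == pytest.approx(177, abs=0.5)
        assert s.loc["NT", "cerebellar_mean_cc"] == pytest.approx(149, abs=0.5)
        assert s.loc["EH", "cerebral_mean_cc"] == pytest.approx(1135, abs=0.5)
        assert s.loc["EH", "cerebellar_mean_cc"] == pytest.approx(153, abs=0.5)
        assert s.loc["NT", "ratio_mean"] == pytest.approx(0.127, abs=0.0005)
        assert s.loc["NT", "ratio_sd"] == pytest.approx(0.010, abs=0.0005)
        assert s.loc["EH", "ratio_mean"] == pytest.approx(0.135, abs=0.0005)

    def test_agrees_with_two_pass_computation(self):
        df = fossil_table()
        s = volume_summary(df).set_index("group")
        for g in ("NT", "EH"):
            sub = df[df.group == g]
            mean = sum(sub.cerebrum_cc) / len(sub)
            var = sum((x - mean) ** 2 for x in sub.cerebrum_cc) / (len(sub) - 1)
            assert s.loc[g, "cerebral_mean_cc"] == pytest.approx(mean, abs=1e-12)
            assert s.loc[g, "cerebral_sd_cc"] == pytest.approx(np.sqrt(var), abs=1e-12)

    def test_mean_of_ratios_not_ratio_of_means(self):
        df = pd.DataFrame(dict(specimen=["a", "b"], group=["G", "G"],
                               cerebrum_cc=[1000.0, 500.0],
                               cerebellum_cc=[100.0, 100.0]))
        s = volume_summary(df)
        assert s.ratio_mean[0] == pytest.approx((0.1 + 0.2) / 2)

    def test_identical_specimens_zero_sd(self):
        df = pd.DataFrame(dict(specimen=["a", "b"], group=["G", "G"],
                               cerebrum_cc=[1000.0, 1000.0],
                               cerebellum_cc=[120.0, 120.0]))
        s = volume_summary(df)
        assert s.cerebral_sd_cc[0] == 0.0
        assert s.ratio_mean[0] == pytest.approx(0.12)

    def test_single_specimen_group_flagged(self):
        df = pd.DataFrame(dict(specimen=["a"], group=["G"],
                               cerebrum_cc=[1000.0], cerebellum_cc=[100.0]))
        with pytest.raises(ValueError, match="SD undefined"):
            volume_summary(df)


class TestICVAdjust:
    def test_proportional_volumes_collapse_to_grand_mean(self):
        icv = np.array([1000.0, 1200, 1400, 1600])
        vol = 0.1 * icv
        adj = icv_adjust(vol, icv)
        assert np.allclose(adj, vol.mean(), atol=1e-10)

    def test_orthogonal_to_icv(self):
        rng = np.random.default_rng(0)
        icv = rng.normal(1450, 120, 200)
        vol = 0.08 * icv + rng.normal(0, 5, 200)
        adj = icv_adjust(vol, icv)
        assert abs(np.corrcoef(adj, icv)[0, 1]) < 1e-10

    def test_slope_recovered_noiseless(self):
        icv = np.linspace(1200, 1700, 50)
        vol = 3.0 + 0.07 * icv
        adj = icv_adjust(vol, icv)
        # perfect linear relation leaves only the grand mean
        assert np.allclose(adj, vol.mean(), atol=1e-6)

    def test_shift_invariance(self):
        rng = np.random.default_rng(1)
        icv = rng.normal(1450, 100, 50)
        vol = 0.1 * icv + rng.normal(0, 3, 50)
        assert np.allclose(icv_adjust(vol, icv), icv_adjust(vol, icv + 500.0),
                           atol=1e-9)

    def test_constant_icv_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            icv_adjust(np.ones(10), np.full(10, 1450.0))


class TestAnovaRyan:
    def test_error_df_full_cohort(self):
        rng = np.random.default_rng(2)
        groups = np.repeat(["NT", "EH", "MH"], [4, 4, 1185])
        res = anova_ryan(rng.normal(size=1193), groups)
        assert res[0].df == (2, 1190)
        for r in res[1:]:
            assert r.df == (1, 1190)

    def test_identical_groups_nothing_significant(self):
        vals = np.tile([1.0, 2.0, 3.0, 4.0], 3)
        groups = np.repeat(["A", "B", "C"], 4)
        res = anova_ryan(vals, groups)
        assert res[0].statistic == pytest.approx(0.0, abs=1e-12)
        assert not any(r.significant for r in res)

    def test_hand_executed_oracle_three_by_four(self):
        # fixture table stepped through the procedure by hand below
        vals = np.array([10.0, 11, 9, 10,      # A  (mean 10)
                         14.0, 15, 13, 14,     # B  (mean 14)
                         15.0, 16, 14, 15])    # C  (mean 15)
        groups = np.repeat(["A", "B", "C"], 4)
        res = anova_ryan(vals, groups, alpha=0.05)
        # independent step-through: grand mean 13, SSB, MSE
        msw = sum((vals[i] - [10, 14, 15][i // 4]) ** 2 for i in range(12)) / 9
        ssb = 4 * ((10 - 13) ** 2 + (14 - 13) ** 2 + (15 - 13) ** 2)
        F = (ssb / 2) / msw
        assert res[0].statistic == pytest.approx(F, rel=1e-12)
        by = {r.effect: r for r in res[1:]}
        # span r=3 pair (A, C): nominal level 2*.05/(3*2) = 0.05/3
        se = np.sqrt(msw * 0.5)
        t_ac = (10 - 15) / se
        p_ac = 2 * stats.t.sf(abs(t_ac), 9)
        r_ac = by["A vs C"]
        assert r_ac.statistic == pytest.approx(t_ac, rel=1e-12)
        assert r_ac.alpha_nominal == pytest.approx(ryan_alpha(0.05, 3, 3))
        assert r_ac.significant == (p_ac < 0.05 / 3)
        # adjacent pairs at nominal 2*.05/(3*1)
        assert by["A vs B"].alpha_nominal == pytest.approx(ryan_alpha(0.05, 3, 2))
        # step-down consistency: B vs C (p large) must not be significant
        assert not by["B vs C"].significant

    def test_k2_reduces_to_plain_t_test(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, 10)
        b = rng.normal(1, 1, 12)
        res = anova_ryan(np.concatenate([a, b]),
                         np.array(["A"] * 10 + ["B"] * 12))
        t, p = stats.ttest_ind(a, b)
        pair = res[1]
        assert abs(pair.statistic) == pytest.approx(abs(t), rel=1e-10)
        assert pair.p == pytest.approx(p, rel=1e-10)
        assert pair.alpha_nominal == 0.05

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            anova_ryan(np.ones(0), np.array([]))


class TestCohensD:
    def test_equal_groups_zero(self):
        a = np.array([1.0, 2, 3])
        assert cohens_d(a, a) == 0.0

    def test_unit_difference_unit_sd(self):
        rng = np.random.default_rng(4)
        a = rng.normal(1, 1, 100000)
        b = rng.normal(0, 1, 100000)
        assert cohens_d(a, b) == pytest.approx(1.0, abs=0.02)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(5)
        a = rng.normal(2, 3, 17)
        b = rng.normal(0, 2, 23)
        sp = np.sqrt((np.var(a, ddof=1) * 16 + np.var(b, ddof=1) * 22) / 38)
        assert cohens_d(a, b) == pytest.approx((a.mean() - b.mean()) / sp, rel=1e-12)

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(ValueError, match="pooled SD"):
            cohens_d(np.ones(3), np.ones(4))


class TestLaterality:
    def test_full_cohort_df_bookkeeping(self):
        rng = np.random.default_rng(6)
        N = 1193
        groups = np.repeat(["NT", "EH", "MH"], [4, 4, 1185])
        t = pd.DataFrame(dict(
            specimen=[f"s{i}" for i in range(N)], group=groups,
            icv=rng.normal(1450, 120, N), left=rng.normal(60, 5, N),
            right=rng.normal(60, 5, N),
        ))
        out = laterality_analysis(t)
        assert out["simple_main_effects"]["NT"].df == (1, 1190)
        any_pair = out["between_group"]["L"][1]
        assert any_pair.df == (1, 2380)

    def test_exactly_symmetric_volumes_give_null(self):
        rng = np.random.default_rng(7)
        n = 30
        vol = rng.normal(60, 5, n)
        t = pd.DataFrame(dict(specimen=[f"s{i}" for i in range(n)],
                              group=["G"] * n, icv=rng.normal(1450, 100, n),
                              left=vol, right=vol.copy()))
        out = laterality_analysis(t)
        r = out["simple_main_effects"]["G"]
        assert r.statistic == pytest.approx(0.0, abs=1e-12)
        assert r.p > 0.5

    def test_missing_side_rejected(self):
        t = pd.DataFrame(dict(specimen=["a", "b"], group=["G", "G"],
                              icv=[1400.0, 1500], left=[60.0, 61],
                              right=[59.0, np.nan]))
        with pytest.raises(ValueError, match="missing one side"):
            laterality_analysis(t)

    def test_flip_swaps_sides_exactly(self):
        rng = np.random.default_rng(8)
        n = 24
        t = pd.DataFrame(dict(specimen=[f"s{i}" for i in range(n)],
                              group=np.repeat(["A", "B"], 12),
                              icv=rng.normal(1450, 100, n),
                              left=rng.normal(62, 4, n),
                              right=rng.normal(58, 4, n)))
        flipped = t.rename(columns={"left": "right", "right": "left"})
        a = laterality_analysis(t)
        b = laterality_analysis(flipped)
        fa = a["simple_main_effects"]["A"]
        fb = b["simple_main_effects"]["A"]
        assert fa.statistic == pytest.approx(fb.statistic, rel=1e-9)


class TestSymmetrizedAtlas:
    def test_label_set_and_approximate_symmetry(self, canonical, region_table):
        from paleobrain.diffeo_registration import RegistrationConfig
        from paleobrain.group_statistics import build_symmetrized_atlas
        from paleobrain.synthetic_cohort import CohortSpec, sample_cohort

        spec = CohortSpec(n_per_group=2, variation_sd=0.4, seed=10)
        cohort = sample_cohort(spec, canonical)
        cfg = RegistrationConfig(n_levels=2, iters_per_level=(10, 6), tol=1e-4)
        sym, mir, tpl = build_symmetrized_atlas(
            [s.endocast_mask() for s in cohort], canonical.atlas_truth,
            region_table, cfg=cfg, n_outer=1,
        )
        assert set(sym.ids()) <= set(canonical.atlas_truth.ids())
        # template built from originals + flips is approximately symmetric
        mism = np.mean(np.abs(tpl.values - tpl.values[::-1, :, :]))
        assert mism / max(np.mean(np.abs(tpl.values)), 1e-12) < 0.02
        # mirrored variant preserves the label set (L/R ids swapped)
        assert set(mir.ids()) == set(sym.ids())
        # cerebellar L/R voxel counts near-balanced in the symmetrized atlas
        l_ids = region_table[region_table.cerebellum
                             & (region_table.hemisphere == "L")].region_id
        r_ids = region_table[region_table.cerebellum
                             & (region_table.hemisphere == "R")].region_id
        nl = np.isin(sym.labels, list(l_ids)).sum()
        nr = np.isin(sym.labels, list(r_ids)).sum()
        assert abs(nl - nr) / max(nl, nr) < 0.05
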