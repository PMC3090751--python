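"""Sensor groups, global measures, pointwise tests, rm-ANOVA,
permutations, post-hoc filtering, PCA and import transforms."""

import itertools

import numpy as np
import pytest
import scipy.stats

from emkit.stats import (
    Design,
    SensorGroup,
    global_dissimilarity,
    global_measures,
    import_transform,
    mirror_group,
    pca,
    permutation_test,
    pointwise_ttest,
    posthoc_spatiotemporal_filter,
    regional_summary,
    rm_anova,
    sensor_adjacency,
)


class TestMirrorGroup:
    def test_symmetric_pair_mapped_exactly(self, eeg_layout_64):
        # find a sensor with an exact mirror partner in the spiral layout?
        # construct an explicitly symmetric layout instead
        from emkit.containers import SensorLayout

        pos = np.array(
            [[3.0, 2.0, 6.0], [-3.0, 2.0, 6.0], [0.0, -4.0, 5.0], [2.0, -1.0, 7.0],
             [-2.0, -1.0, 7.0], [0.0, 6.0, 4.0]]
        )
        lay = SensorLayout(["R1", "L1", "Mid1", "R2", "L2", "Mid2"], pos)
        out = mirror_group(SensorGroup("right", ["R1", "R2"]), lay)
        assert out.members == ["L1", "L2"]
        assert out.mirror_of == "right"

    def test_involution_on_symmetric_layout(self):
        from emkit.containers import SensorLayout

        pos = np.array([[3.0, 2.0, 6.0], [-3.0, 2.0, 6.0]])
        lay = SensorLayout(["R", "L"], pos)
        g = SensorGroup("g", ["R"])
        assert mirror_group(mirror_group(g, lay), lay).members == ["R"]

    def test_jittered_layout_still_finds_partner(self, rng):
        from emkit.containers import SensorLayout

        # well-separated right-hemisphere sensors (pairwise distance >> jitter)
        right = np.array(
            [[3.0, y, z] for y in (-5.0, 0.0, 5.0) for z in (2.0, 6.0)]
            + [[6.0, y, 4.0] for y in (-4.0, 0.0, 4.0)] + [[5.0, 2.0, -1.0]]
        )
        left = right * [-1, 1, 1]
        pos = np.vstack([right, left])
        radius = np.linalg.norm(pos, axis=1).max()
        jitter = 0.02 * radius * rng.normal(size=pos.shape)
        lay = SensorLayout(
            [f"R{i}" for i in range(10)] + [f"L{i}" for i in range(10)], pos + jitter
        )
        out = mirror_group(SensorGroup("right", [f"R{i}" for i in range(10)]), lay)
        assert out.members == [f"L{i}" for i in range(10)]

    def test_midline_group_warns(self):
        from emkit.containers import SensorLayout

        lay = SensorLayout(["M1", "M2"], np.array([[0.0, 3.0, 7.0], [0.0, -3.0, 7.0]]))
        with pytest.warns(UserWarning, match="midline"):
            out = mirror_group(SensorGroup("mid", ["M1"]), lay)
        assert out.is_midline


class TestRegionalAndGlobal:
    def test_single_sensor_mean_is_identity(self, eeg_layout_32, rng):
        data = rng.normal(size=(32, 20))
        out = regional_summary(data, SensorGroup("one", ["E5"]), eeg_layout_32, "mean")
        assert np.array_equal(out, data[eeg_layout_32.index("E5")])

    def test_hand_computed_power_and_rms(self, eeg_layout_32):
        data = np.zeros((32, 1))
        i3, i4 = eeg_layout_32.index("E3"), eeg_layout_32.index("E4")
        data[i3, 0], data[i4, 0] = 3.0, 4.0
        g = SensorGroup("pair", ["E3", "E4"])
        assert regional_summary(data, g, eeg_layout_32, "power")[0] == pytest.approx(12.5)
        assert regional_summary(data, g, eeg_layout_32, "rms")[0] == pytest.approx(
            np.sqrt(12.5)
        )

    def test_rms_squared_equals_power(self, eeg_layout_32, rng):
        data = rng.normal(size=(32, 15))
        g = SensorGroup("g", ["E2", "E7", "E9"])
        rms = regional_summary(data, g, eeg_layout_32, "rms")
        power = regional_summary(data, g, eeg_layout_32, "power")
        assert np.allclose(rms**2, power)

    def test_global_measures_definitions(self, rng):
        data = rng.normal(size=(10, 7))
        out = global_measures(data)
        assert np.allclose(out["global_power"], (data**2).mean(axis=0))
        assert np.allclose(out["global_rms"] ** 2, out["global_power"])
        assert np.allclose(out["global_mean"], data.mean(axis=0))

    @pytest.mark.parametrize(
        "transform,expected",
        [(lambda m: m, 0.0), (lambda m: -m, 2.0), (lambda m: 5 * m, 0.0)],
    )
    def test_dissimilarity_cases(self, rng, transform, expected):
        m = rng.normal(size=20)
        m -= m.mean()
        assert global_dissimilarity(m, transform(m)) == pytest.approx(expected, abs=1e-12)

    def test_zero_map_rejected(self):
        with pytest.raises(ValueError):
            global_dissimilarity(np.zeros(5), np.ones(5))


class TestPointwiseTtest:
    def test_identical_paired_data_gives_zero(self, rng):
        a = rng.normal(size=(8, 4, 5))
        res = pointwise_ttest(a, a.copy(), paired=True)
        assert np.all(res.stat == 0) and np.all(res.p == 1)

    def test_constant_differences_deterministic_rule(self):
        a = np.array([1.0, 2.0, 3.0])[:, None]
        b = np.array([2.0, 3.0, 4.0])[:, None]
        res = pointwise_ttest(a, b, paired=True)
        assert np.isinf(res.stat[0]) and res.stat[0] < 0
        assert res.p[0] == 0.0
        assert res.degenerate is not None and res.degenerate[0]

    def test_matches_scipy_reference(self, rng):
        a = rng.normal(size=(12, 6))
        b = rng.normal(size=(12, 6))
        ours = pointwise_ttest(a, b, paired=True)
        ref_t, ref_p = scipy.stats.ttest_rel(a, b, axis=0)
        assert np.allclose(ours.stat, ref_t, atol=1e-10)
        assert np.allclose(ours.p, ref_p, atol=1e-10)
        ours2 = pointwise_ttest(a, b[:8], paired=False)
        ref_t2, ref_p2 = scipy.stats.ttest_ind(a, b[:8], axis=0)
        assert np.allclose(ours2.stat, ref_t2, atol=1e-10)
        assert np.allclose(ours2.p, ref_p2, atol=1e-10)


def _brute_force_2x2_within(Y):
    """Direct cell-mean SS decomposition for subjects x 2 x 2 data."""
    n = Y.shape[0]
    grand = Y.mean()
    mA = Y.mean(axis=(0, 2))
    mB = Y.mean(axis=(0, 1))
    mAB = Y.mean(axis=0)
    mS = Y.mean(axis=(1, 2))
    ss = {}
    ss["A"] = n * 2 * ((mA - grand) ** 2).sum()
    ss["B"] = n * 2 * ((mB - grand) ** 2).sum()
    ss["A x B"] = n * ((mAB - mA[:, None] - mB[None, :] + grand) ** 2).sum()
    mSA = Y.mean(axis=2)
    mSB = Y.mean(axis=1)
    ss["err_A"] = 2 * ((mSA - mS[:, None] - mA[None, :] + grand) ** 2).sum()
    ss["err_B"] = 2 * ((mSB - mS[:, None] - mB[None, :] + grand) ** 2).sum()
    resid = (
        Y
        - mAB[None]
        - mSA[:, :, None]
        - mSB[:, None, :]
        + mA[None, :, None]
        + mB[None, None, :]
        + mS[:, None, None]
        - grand
    )
    ss["err_AB"] = (resid**2).sum()
    ss["subjects"] = 4 * ((mS - grand) ** 2).sum()
    return ss


class TestRmAnova:
    def test_f_equals_paired_t_squared(self, rng):
        Y = rng.normal(size=(10, 2, 6))
        res = rm_anova(Y, Design(within=[("A", 2)]))
        t = pointwise_ttest(Y[:, 0], Y[:, 1], paired=True)
        assert np.allclose(res["A"].stat, t.stat**2, atol=1e-9)

    def test_f_equals_independent_t_squared(self, rng):
        Y = rng.normal(size=(14, 5))
        g = np.array([0] * 7 + [1] * 7)
        res = rm_anova(Y, Design(between=[("G", g)]))
        t = pointwise_ttest(Y[:7], Y[7:], paired=False)
        assert np.allclose(res["G"].stat, t.stat**2, atol=1e-9)

    def test_2x2_within_matches_brute_force(self, rng):
        Y = rng.normal(size=(8, 2, 2))
        res = rm_anova(Y[..., None], Design(within=[("A", 2), ("B", 2)]))
        ss = _brute_force_2x2_within(Y)
        n = 8
        for eff, err in [("A", "err_A"), ("B", "err_B"), ("A x B", "err_AB")]:
            F_ref = (ss[eff] / 1) / (ss[err] / (n - 1))
            assert res[eff].stat.ravel()[0] == pytest.approx(F_ref, abs=1e-8)
            assert res[eff].df == (1, n - 1)

    def test_2x3_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        Y = rng.normal(size=(9, 2, 3))
        rows = [
            {"s": s, "A": a, "B": b, "y": Y[s, a, b]}
            for s in range(9)
            for a in range(2)
            for b in range(3)
        ]
        aov = pg.rm_anova(
            data=pd.DataFrame(rows), dv="y", within=["A", "B"], subject="s",
            detailed=True,
        )
        res = rm_anova(Y[..., None], Design(within=[("A", 2), ("B", 3)]))
        for eff, key in [("A", "A"), ("B", "B"), ("A x B", "A * B")]:
            row = aov[aov.Source == key].iloc[0]
            assert res[eff].stat.ravel()[0] == pytest.approx(row.F, abs=1e-8)
            assert res[eff].p.ravel()[0] == pytest.approx(row.p_unc, abs=1e-8)

    def test_unbalanced_mixed_matches_type3_oracle(self):
        """Frozen oracle: sum-contrast Type III repeated-measures ANOVA
        (R car::Anova) on a 5+7 subject mixed design."""
        y0 = np.array([-0.626453810742332, 0.183643324222082, -0.835628612410047,
                       1.59528080213779, 0.329507771815361, -0.820468384118015,
                       0.487429052428485, 0.738324705129217, 0.575781351653492,
                       -0.305388387156356, 1.51178116845085, 0.389843236411431])
        y1 = np.array([-0.621240580541804, -2.2146998871775, 1.12493091814311,
                       -0.0449336090152309, -0.0161902630989461, 0.943836210685299,
                       0.821221195098089, 0.593901321217509, 0.918977371608218,
                       0.782136300731067, 0.0745649833651906, -1.98935169586337])
        g = np.array([0] * 5 + [1] * 7)
        Y = np.stack([y0, y1], axis=1)
        res = rm_anova(Y[..., None], Design(within=[("A", 2)], between=[("G", g)]))
        assert res["G"].stat.ravel()[0] == pytest.approx(1.48833, abs=1e-4)
        assert res["A"].stat.ravel()[0] == pytest.approx(0.36951, abs=1e-4)
        assert res["G x A"].stat.ravel()[0] == pytest.approx(0.22118, abs=1e-4)

    def test_six_within_factors_ss_conservation(self, rng):
        """A 2^6 within design completes; effect SS plus error SS plus the
        subject SS reconstruct the total SS."""
        Y = rng.normal(size=(4,) + (2,) * 6)
        design = Design(within=[(f"W{i}", 2) for i in range(6)])
        res = rm_anova(Y[..., None], design)
        assert len(res.maps) == 63
        F = np.array([m.stat.ravel()[0] for m in res.maps])
        assert np.all(np.isfinite(F)) and np.all(F >= 0)
        # conservation: the saturated Möbius decomposition over the axes
        # {subject, W1..W6} reconstructs the total SS exactly, and every
        # tested effect's SS appears in it (effect axes without subject)
        total = ((Y - Y.mean()) ** 2).sum()
        ss_sum = 0.0
        for r in range(1, 8):
            for keep in itertools.combinations(range(7), r):
                est = np.zeros_like(Y)
                for rr in range(len(keep) + 1):
                    for sub in itertools.combinations(keep, rr):
                        drop = tuple(a for a in range(7) if a not in sub)
                        sign = (-1) ** (len(keep) - rr)
                        est = est + sign * (
                            Y.mean(axis=drop, keepdims=True) if drop else Y
                        )
                ss_sum += (est**2).sum()
        assert ss_sum == pytest.approx(total, rel=1e-10)

    def test_p_uniform_under_global_null(self, rng):
        """Point-by-point ANOVA p values are uniform under the null (1000
        independent replications as points; KS test at alpha=0.01)."""
        Y = rng.normal(size=(10, 2, 1000))
        res = rm_anova(Y, Design(within=[("A", 2)]))
        stat, p = scipy.stats.kstest(res["A"].p, "uniform")
        assert p > 0.01

    def test_non_crossed_between_rejected(self, rng):
        Y = rng.normal(size=(6, 3))
        g1 = np.array([0, 0, 0, 1, 1, 1])
        g2 = np.array([0, 0, 0, 1, 1, 1])  # perfectly confounded -> empty cells
        with pytest.raises(ValueError, match="empty cells"):
            rm_anova(Y, Design(between=[("G1", g1), ("G2", g2)]))

    def test_roi_mode_posthoc(self, rng):
        Y = rng.normal(size=(9, 3))
        res = rm_anova(Y, Design(within=[("A", 3)]), roi=True)
        assert res.cell_means is not None
        assert len(res.posthoc) == 3  # 3 pairwise contrasts
        assert (res.posthoc.p_bonferroni >= res.posthoc.p_uncorrected - 1e-15).all()


class TestPermutation:
    def test_exact_sign_flip_hand_enumeration(self):
        """Differences {1,2,3}: the observed mean is the largest of the 8
        sign-flip outcomes, so one-sided exact p = 1/8."""
        d = np.array([1.0, 2.0, 3.0])[:, None]
        res = permutation_test(d, "paired_t", exact=True, tail="greater")
        assert res["p"][0] == pytest.approx(1 / 8)
        assert res["n_permutations"] == 8

    def test_exact_p_values_are_multiples(self, rng):
        d = rng.normal(size=(6, 4))
        res = permutation_test(d, "paired_t", exact=True)
        assert np.allclose(np.round(res["p"] * 64), res["p"] * 64, atol=1e-12)

    def test_constant_zero_data_p_one(self):
        d = np.zeros((5, 3))
        res = permutation_test(d, "paired_t", n_perm=200, seed=0)
        assert np.all(res["p"] == 1.0)

    def test_type_one_error_within_binomial_ci(self, rng):
        """1000 null simulations (as points): empirical alpha at 0.05 sits
        inside the 95% binomial interval."""
        d = rng.normal(size=(12, 1000))
        res = permutation_test(d, "paired_t", n_perm=500, seed=42)
        rate = (res["p"] <= 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / 1000)
        assert 0.05 - 1.96 * se <= rate <= 0.05 + 1.96 * se

    def test_exact_independent_relabelling(self, rng):
        x = rng.normal(size=(6, 2))
        groups = np.array([0, 0, 0, 1, 1, 1])
        res = permutation_test(x, "independent_t", groups=groups, exact=True)
        assert res["n_permutations"] == 20
        assert np.all((res["p"] * 20) % 1 < 1e-9)

    def test_exact_beyond_cap_suggests_montecarlo(self, rng):
        d = rng.normal(size=(30, 2))
        with pytest.raises(ValueError, match="n_perm"):
            permutation_test(d, "paired_t", exact=True, exact_cap=1000)


class TestPosthocFilter:
    def _toy(self):
        adjacency = np.array(
            [
                [0, 1, 1, 0],
                [1, 0, 1, 0],
                [1, 1, 0, 0],
                [0, 0, 0, 0],
            ],
            dtype=bool,
        )
        return adjacency

    def test_isolated_point_removed(self):
        p = np.ones((4, 10))
        p[0, 5] = 0.001
        mask = posthoc_spatiotemporal_filter(p, 0.05, 2, 1, self._toy())
        assert not mask.any()

    def test_sustained_cluster_retained(self):
        p = np.ones((4, 20))
        p[0:3, 5:15] = 0.001  # 10-sample run on 3 mutually adjacent sensors
        mask = posthoc_spatiotemporal_filter(p, 0.05, 5, 3, self._toy())
        assert mask[0:3, 5:15].all()
        assert not mask[3].any()

    def test_thresholds_one_one_is_noop(self, rng):
        p = rng.uniform(size=(4, 30))
        mask = posthoc_spatiotemporal_filter(p, 0.2, 1, 1, self._toy())
        assert np.array_equal(mask, p < 0.2)

    def test_mask_monotone_in_thresholds(self, rng):
        p = rng.uniform(size=(4, 30)) ** 2
        adj = self._toy()
        prev = posthoc_spatiotemporal_filter(p, 0.2, 1, 1, adj)
        for mt, ms in [(2, 1), (3, 2), (5, 3)]:
            cur = posthoc_spatiotemporal_filter(p, 0.2, mt, ms, adj)
            assert not (cur & ~prev).any()
            prev = cur

    def test_adjacency_matrix_sane(self, eeg_layout_64):
        adj = sensor_adjacency(eeg_layout_64)
        assert adj.shape == (64, 64)
        assert np.array_equal(adj, adj.T)
        assert not adj.diagonal().any()
        assert adj.sum(axis=1).min() >= 1


class TestPca:
    def test_rank_one_data(self, rng):
        u = rng.normal(size=20)
        v = rng.normal(size=8)
        X = np.outer(u, v)
        res = pca(X)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_reconstruction(self, rng):
        X = rng.normal(size=(15, 6))
        res = pca(X)
        rec = res.scores @ res.components + res.mean
        assert np.abs(rec - X).max() < 1e-8

    def test_components_orthonormal_variances_sorted(self, rng):
        X = rng.normal(size=(30, 5))
        res = pca(X)
        assert np.allclose(res.components @ res.components.T, np.eye(5), atol=1e-10)
        assert np.all(np.diff(res.explained_variance) <= 1e-12)


class TestImportTransform:
    def test_order_sensitivity(self):
        times = np.array([0.0, 0.1])
        data = np.array([[-1.0, 1.0]])
        rectified_first = import_transform(
            data, [("rectify", {}), ("interval_mean", {"t_min": 0, "t_max": 0.1})],
            times=times,
        )
        mean_first = import_transform(
            data, [("interval_mean", {"t_min": 0, "t_max": 0.1}), ("rectify", {})],
            times=times,
        )
        assert rectified_first[0] == pytest.approx(1.0)
        assert mean_first[0] == pytest.approx(0.0)

    def test_empty_spec_is_identity(self, rng):
        x = rng.normal(size=(3, 10))
        assert np.array_equal(import_transform(x, []), x)

    def test_baseline_on_statistics_warns(self, rng):
        x = rng.uniform(size=(2, 10))
        times = np.linspace(-0.1, 0.3, 10)
        with pytest.warns(UserWarning, match="statistical"):
            import_transform(
                x, [("baseline", {"t_min": -0.1, "t_max": 0.0})],
                times=times, is_statistic=True,
            )

    def test_unknown_transform_rejected(self, rng):
        with pytest.raises(ValueError, match="unknown transform"):
            import_transform(rng.normal(size=(2, 5)), [("fourier", {})])
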