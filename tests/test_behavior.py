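import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from vpalloc import behavior
from vpalloc.simulate import DesignConfig, generate_experiment


class TestEuclideanError:
    def test_basic_geometry(self):
        assert behavior.euclidean_error((0, 0), (0, 0)) == 0.0
        assert behavior.euclidean_error((0, 0), (3, 4)) == 5.0
        assert behavior.euclidean_error((3, 4), (0, 0)) == 5.0

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            behavior.euclidean_error((np.nan, 0), (0, 0))


class TestPrioritySummary:
    def test_monotone_on_priority_graded_data(self, exp2_cohort):
        summary = behavior.priority_summary(exp2_cohort)
        assert summary.attrs["monotone_error"]
        assert summary.attrs["monotone_radius"]
        assert list(summary["priority"]) == [0.6, 0.3, 0.1]

    def test_sem_is_sd_over_sqrt_n(self, exp2_cohort):
        summary = behavior.priority_summary(exp2_cohort)
        per = behavior.participant_priority_table(exp2_cohort)
        sub = per[per["priority"] == 0.6]["error"]
        assert summary.loc[0, "error_sem"] == pytest.approx(
            sub.std(ddof=1) / np.sqrt(len(sub))
        )

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            behavior.priority_summary(
                pd.DataFrame(columns=["participant", "priority", "error"])
            )


class TestStandardization:
    def test_idempotent_and_rank_preserving(self, exp2_cohort):
        z1 = behavior.standardize_within_participant(exp2_cohort)
        for pid, grp in z1.groupby("participant"):
            assert grp["z_error"].mean() == pytest.approx(0.0, abs=1e-12)
            assert grp["z_error"].std() == pytest.approx(1.0, rel=1e-12)
            rho_raw = stats.spearmanr(grp["error"], grp["radius"]).statistic
            rho_z = stats.spearmanr(grp["z_error"], grp["z_radius"]).statistic
            assert rho_z == pytest.approx(rho_raw)

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(offsets=st.lists(st.floats(-50, 50), min_size=3, max_size=3))
    def test_pooled_correlation_unmoved_by_participant_offsets(self, offsets):
        rng = np.random.default_rng(11)
        frames = []
        for pid, off in enumerate(offsets):
            n = 60
            e = rng.normal(size=n)
            r = 0.5 * e + rng.normal(size=n)
            frames.append(
                pd.DataFrame(
                    {
                        "participant": pid,
                        "priority": 0.6,
                        "error": 3 + e + off,
                        "radius": 2 + r + off,
                    }
                )
            )
        base = pd.concat(frames, ignore_index=True)
        z = behavior.standardize_within_participant(base)
        rho = stats.spearmanr(z["z_error"], z["z_radius"]).statistic
        # same data without the offsets
        z0 = base.copy()
        z0["error"] -= z0["participant"].map(dict(enumerate(offsets)))
        z0["radius"] -= z0["participant"].map(dict(enumerate(offsets)))
        z0 = behavior.standardize_within_participant(z0)
        rho0 = stats.spearmanr(z0["z_error"], z0["z_radius"]).statistic
        assert rho == pytest.approx(rho0, abs=1e-9)


class TestWithinPriorityCorrelation:
    def test_perfect_and_null_correlations(self):
        rng = np.random.default_rng(21)
        n = 300
        err = rng.gamma(2.0, size=n)
        base = pd.DataFrame(
            {
                "participant": np.repeat([0, 1, 2], n // 3),
                "priority": np.tile([0.6, 0.3, 0.1], n // 3),
                "error": err,
            }
        )
        perfect = base.assign(radius=base["error"])
        pooled, _ = behavior.within_priority_correlation(perfect)
        assert np.all(pooled["rho"] > 0.999)
        independent = base.assign(radius=rng.gamma(2.0, size=n))
        pooled_i, _ = behavior.within_priority_correlation(independent)
        assert np.all(np.abs(pooled_i["rho"]) < 0.25)

    def test_positive_on_shared_precision_data(self, exp2_cohort):
        pooled, per = behavior.within_priority_correlation(exp2_cohort)
        assert np.all(pooled["rho"] > 0)
        assert len(pooled) == 3
        assert set(per.columns) >= {"participant", "priority", "rho"}

    def test_correlation_grows_with_precision_variability(self):
        from vpalloc.fitting import ModelSpec

        rhos = []
        for tau in (0.05, 0.5, 1.5):
            spec = ModelSpec(experiment=2, strategy="proportional")
            tr = generate_experiment(
                spec,
                {"Jbar_total": 3.0, "tau": tau, "lam": 5.0},
                DesignConfig(n_trials=2000),
                rng_seed=31,
            )
            pooled, _ = behavior.within_priority_correlation(tr)
            rhos.append(pooled["rho"].mean())
        assert rhos[0] < rhos[1] < rhos[2]


class TestPermutationNull:
    def test_preserves_delay_driven_structure(self):
        """Radii that depend only on delay stay correlated under the
        delay-stratified shuffle: the observed value sits inside the null."""
        rng = np.random.default_rng(41)
        n = 420
        delays = rng.choice(np.arange(1000, 4001, 500), size=n)
        err = 0.001 * delays + rng.normal(scale=0.3, size=n)
        radius = 0.002 * delays + rng.normal(scale=0.3, size=n)
        tr = pd.DataFrame(
            {
                "participant": 0,
                "priority": 0.6,
                "target_x": 7.0,
                "target_y": 7.0,
                "error": np.abs(err),
                "radius": np.abs(radius),
                "delay_ms": delays,
            }
        )
        nd = behavior.permutation_null(tr, "delay", n_perm=800, rng_seed=1)[0]
        lo, hi = np.percentile(nd.null_rhos, [2.5, 97.5])
        assert lo <= nd.observed_rho <= hi

    def test_detects_shared_precision_coupling(self, exp2_cohort):
        for cov in ("location", "delay"):
            nulls = behavior.permutation_null(exp2_cohort, cov, n_perm=400, rng_seed=2)
            exceed = [nd.observed_rho > np.percentile(nd.null_rhos, 97.5) for nd in nulls]
            assert np.mean(exceed) > 0.6
            assert abs(np.mean([nd.null_median for nd in nulls])) < 0.05

    def test_reproducible_under_seed(self, exp2_cohort):
        a = behavior.permutation_null(exp2_cohort, "delay", n_perm=50, rng_seed=3)
        b = behavior.permutation_null(exp2_cohort, "delay", n_perm=50, rng_seed=3)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.null_rhos, y.null_rhos)


class TestSignedRankVsNull:
    def test_identical_pairs_degenerate(self):
        res = behavior.signed_rank_vs_null([0.2] * 6, [0.2] * 6)
        assert res.degenerate and res.pvalue == 1.0

    def test_large_consistent_differences(self):
        obs = 0.25 + 0.01 * np.arange(14)
        res = behavior.signed_rank_vs_null(obs, np.zeros(14))
        assert res.pvalue < 0.001  # exact n=14 all-positive: p = 2 * 2**-14

    def test_symmetric_under_pair_swap(self):
        rng = np.random.default_rng(51)
        a, b = rng.normal(size=8), rng.normal(size=8)
        assert behavior.signed_rank_vs_null(a, b).pvalue == pytest.approx(
            behavior.signed_rank_vs_null(b, a).pvalue
        )

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            behavior.signed_rank_vs_null([1, 2], [0, 0])
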