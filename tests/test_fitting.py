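import numpy as np
import pandas as pd
import pytest

from oracles import closed_form_marginal_pdf
from vpalloc.fitting import (
    FitResult,
    ModelSpec,
    compare_models,
    fit_model,
    information_criteria,
    loglik_exp1,
    loglik_exp2,
)
from vpalloc.simulate import DesignConfig, generate_experiment
from vpalloc.wager import RadiusGrid, softmax_radius_density


class TestModelSpec:
    @pytest.mark.parametrize(
        "experiment,strategy,n_params",
        [
            (1, "proportional", 2),
            (1, "flexible", 4),
            (1, "minimizing_error", 3),
            (2, "proportional", 3),
            (2, "flexible", 5),
            (2, "minimizing_error", 4),
            (2, "maximizing_points", 3),
        ],
    )
    def test_parameter_counts(self, experiment, strategy, n_params):
        assert ModelSpec(experiment, strategy).n_params == n_params

    def test_maximizing_points_needs_wager_experiment(self):
        with pytest.raises(ValueError):
            ModelSpec(experiment=1, strategy="maximizing_points")


class TestInformationCriteria:
    def test_direct_arithmetic(self):
        aicc, bic = information_criteria(-100.0, 2, 100)
        assert aicc == pytest.approx(204 + 12 / 97)
        assert bic == pytest.approx(200 + 2 * np.log(100))

    def test_zero_parameters(self):
        aicc, bic = information_criteria(-50.0, 0, 30)
        assert aicc == bic == 100.0

    def test_bic_penalty_outgrows_aicc(self):
        for k in (1, 2, 4):
            gaps = []
            for n in (40, 100, 1000, 10_000):
                aicc, bic = information_criteria(0.0, k, n)
                gaps.append(bic - aicc)
            assert np.all(np.diff(gaps) > 0)

    def test_too_few_trials(self):
        with pytest.raises(ValueError):
            information_criteria(-10.0, 5, 6)


class TestLoglikExp1:
    def test_additivity_under_duplication(self, exp1_flexible_trials):
        spec, theta, tr = exp1_flexible_trials
        th = [theta["Jbar_total"], theta["tau"], theta["p_high"], theta["p_med"]]
        ll = loglik_exp1(th, spec, tr)
        ll2 = loglik_exp1(th, spec, pd.concat([tr, tr], ignore_index=True))
        assert ll2 == pytest.approx(2 * ll, rel=1e-12)

    def test_single_trial_equals_closed_form(self):
        spec = ModelSpec(experiment=1, strategy="proportional")
        trial = pd.DataFrame({"priority": [0.6], "error": [1.3]})
        ll = loglik_exp1([4.0, 0.8], spec, trial)
        assert ll == pytest.approx(
            np.log(closed_form_marginal_pdf(1.3, 0.6 * 4.0, 0.8)), rel=1e-6
        )

    def test_density_matches_simulated_histogram(self):
        """exp(pointwise loglik) reproduces the generative error density."""
        spec = ModelSpec(experiment=1, strategy="proportional")
        rng = np.random.default_rng(12)
        Jbar, tau = 0.6 * 4.0, 0.8
        J = rng.gamma(Jbar / tau, scale=tau, size=100_000)
        err = np.hypot(*(rng.standard_normal((2, J.size)) / np.sqrt(J)))
        hist, edges = np.histogram(err, bins=np.linspace(0, 4, 25), density=True)
        centers = 0.5 * (edges[:-1] + edges[1:])
        dens = np.array(
            [
                np.exp(loglik_exp1([4.0, 0.8], spec, pd.DataFrame({"priority": [0.6], "error": [e]})))
                for e in centers
            ]
        )
        keep = hist > 0.02
        np.testing.assert_allclose(dens[keep], hist[keep], rtol=0.12)

    def test_trial_order_invariance(self, exp1_flexible_trials):
        spec, theta, tr = exp1_flexible_trials
        th = [theta["Jbar_total"], theta["tau"], theta["p_high"], theta["p_med"]]
        shuffled = tr.sample(frac=1.0, random_state=0).reset_index(drop=True)
        assert loglik_exp1(th, spec, shuffled) == pytest.approx(
            loglik_exp1(th, spec, tr), rel=1e-12
        )

    def test_out_of_bounds_theta_rejected(self, exp1_flexible_trials):
        spec, _, tr = exp1_flexible_trials
        with pytest.raises(ValueError, match="outside bounds"):
            loglik_exp1([1e4, 0.5, 0.49, 0.28], spec, tr)


class TestLoglikExp2:
    def test_infinite_decision_noise_factorizes(self, exp2_flexible_trials):
        """lam -> inf: the radius mass is uniform over the grid, so the joint
        likelihood is the error marginal times 1/n_grid."""
        spec, theta, tr = exp2_flexible_trials
        sub = tr.head(50)
        big = 1e5
        spec2 = ModelSpec(experiment=2, strategy="flexible", bounds={"lam": (0.01, 1e6)})
        ll_joint = loglik_exp2(
            [theta["Jbar_total"], theta["tau"], theta["p_high"], theta["p_med"], big],
            spec2,
            sub,
        )
        spec1 = ModelSpec(experiment=1, strategy="flexible")
        ll_err = loglik_exp1(
            [theta["Jbar_total"], theta["tau"], theta["p_high"], theta["p_med"]],
            spec1,
            sub,
        )
        n_grid = len(RadiusGrid().values)
        assert ll_joint == pytest.approx(ll_err - len(sub) * np.log(n_grid), rel=1e-4)

    def test_degenerate_gamma_factorizes(self):
        """tau -> 0: error term is Rayleigh at Jbar and the radius term is the
        softmax mass at J = Jbar."""
        spec = ModelSpec(
            experiment=2, strategy="flexible", bounds={"tau": (1e-6, 200.0)}
        )
        rgrid = RadiusGrid()
        trial = pd.DataFrame({"priority": [0.6], "error": [0.9], "radius": [1.5]})
        Jtot, ph, pm, lam = 4.0, 0.5, 0.3, 5.0
        ll = loglik_exp2([Jtot, 1e-6, ph, pm, lam], spec, trial)
        Jbar = ph * Jtot
        f_err = Jbar * 0.9 * np.exp(-Jbar * 0.9**2 / 2)
        p_rad = softmax_radius_density(Jbar, lam, rgrid=rgrid)[rgrid.snap(1.5)[0]]
        assert ll == pytest.approx(np.log(f_err * p_rad), rel=1e-4)

    def test_radius_marginal_matches_simulation(self, exp2_flexible_trials):
        """Chosen-radius frequencies agree with the model's implied radius
        mass (the same shared-J integral the likelihood computes)."""
        spec, theta, tr = exp2_flexible_trials
        from vpalloc.core import PrecisionDistribution, precision_grid
        from vpalloc.wager import softmax_radius_matrix

        rgrid = spec.rgrid
        sub = tr[tr["priority"] == 0.6]
        d = PrecisionDistribution(theta["p_high"] * theta["Jbar_total"], theta["tau"])
        grid = precision_grid(d, n_nodes=200)
        pmat = softmax_radius_matrix(grid.nodes, theta["lam"], rgrid=rgrid)
        model_mass = grid.weights @ pmat
        # coarse-bin the radius axis to keep counts well-populated
        bins = np.linspace(0.1, 6.0, 13)
        model_binned = [
            model_mass[(rgrid.values >= lo) & (rgrid.values < hi)].sum()
            for lo, hi in zip(bins[:-1], bins[1:])
        ]
        emp_binned, _ = np.histogram(sub["radius"], bins=bins)
        emp_binned = emp_binned / len(sub)
        # 3x the binomial standard error of the largest bin mass
        tol = 3 * np.sqrt(0.5 * 0.5 / len(sub))
        np.testing.assert_allclose(model_binned, emp_binned, atol=tol)

    def test_requires_radius_column(self, exp1_flexible_trials):
        spec1, theta, tr = exp1_flexible_trials
        spec = ModelSpec(experiment=2, strategy="flexible")
        with pytest.raises(ValueError, match="radius"):
            loglik_exp2([3.0, 0.5, 0.49, 0.28, 5.0], spec, tr)


class TestFitModel:
    def test_mle_dominates_generating_parameters(self, exp1_flexible_trials):
        spec, theta, tr = exp1_flexible_trials
        fit = fit_model(spec, tr, n_starts=5, rng_seed=1)
        th = [theta["Jbar_total"], theta["tau"], theta["p_high"], theta["p_med"]]
        assert fit.loglik >= loglik_exp1(th, spec, tr) - 0.5
        assert fit.loglik == pytest.approx(max(fit.start_logliks))

    def test_more_starts_never_hurt(self, exp1_flexible_trials):
        """The first starts are deterministic (method-of-moments), so a run
        with more starts maximizes over a superset."""
        spec, _, tr = exp1_flexible_trials
        small = fit_model(spec, tr.head(150), n_starts=1, rng_seed=3)
        large = fit_model(spec, tr.head(150), n_starts=2, rng_seed=3)
        assert large.loglik >= small.loglik - 1e-6

    def test_recovers_generating_allocation(self, exp1_flexible_trials):
        spec, theta, tr = exp1_flexible_trials
        fit = fit_model(spec, tr, n_starts=5, rng_seed=2)
        assert fit.theta_hat["p_high"] == pytest.approx(theta["p_high"], abs=0.05)
        assert fit.allocation[2] == pytest.approx(0.23, abs=0.05)

    def test_result_round_trips_as_json(self, tmp_path, exp1_flexible_trials):
        spec, _, tr = exp1_flexible_trials
        fit = fit_model(spec, tr.head(100), n_starts=1, rng_seed=4)
        path = tmp_path / "fit.json"
        fit.to_json(path)
        assert FitResult.from_json(path) == fit


class TestCompareModels:
    def _fits(self, deltas):
        out = {}
        for pid, d in enumerate(deltas):
            out[pid] = FitResult(
                spec_name="exp1:flexible",
                param_names=[],
                theta_hat={},
                allocation=[],
                loglik=0.0,
                aicc=float(d),
                bic=float(d),
                n_trials=600,
                n_starts=1,
                start_logliks=[0.0],
            )
        return out

    def test_self_comparison_is_null(self):
        fits = self._fits([10, 20, 30, 40, 50])
        comp = compare_models(fits, fits, n_boot=500, rng_seed=0)
        assert comp.median_delta_aicc == 0.0
        assert comp.ci_delta_aicc == (0.0, 0.0)

    def test_ci_brackets_median(self):
        a = self._fits([110, 125, 133, 148, 152, 160, 171])
        b = self._fits([100, 120, 130, 140, 150, 160, 170])
        comp = compare_models(a, b, n_boot=2000, rng_seed=1)
        lo, hi = comp.ci_delta_aicc
        assert lo <= comp.median_delta_aicc <= hi

    def test_mismatched_participants_rejected(self):
        a = self._fits([1, 2, 3])
        b = self._fits([1, 2, 3, 4])
        with pytest.raises(ValueError, match="participant sets"):
            compare_models(a, b)


class TestNesting:
    def test_flexible_mle_dominates_constrained_strategies(self, exp1_flexible_trials):
        """Flexible nests both Proportional and ME allocations, so its
        maximized log-likelihood can never fall meaningfully below theirs."""
        _, _, tr = exp1_flexible_trials
        ll = {
            s: fit_model(ModelSpec(1, s), tr, n_starts=4, rng_seed=8).loglik
            for s in ("proportional", "flexible", "minimizing_error")
        }
        assert ll["flexible"] >= ll["proportional"] - 0.2
        assert ll["flexible"] >= ll["minimizing_error"] - 0.2

    def test_flexible_beats_proportional_on_nonproportional_data(self):
        """Median AICc difference favors Flexible when the generating split
        deviates from the probe probabilities."""
        gen = ModelSpec(experiment=1, strategy="flexible")
        theta = {"Jbar_total": 3.0, "tau": 0.5, "p_high": 0.49, "p_med": 0.28}
        fits_p, fits_f = {}, {}
        ss = np.random.SeedSequence(88)
        for pid, child in enumerate(ss.spawn(3)):
            seeds = child.generate_state(3) % 2**31
            tr = generate_experiment(
                gen, theta, DesignConfig(n_trials=400), rng_seed=int(seeds[0]),
                participant=pid,
            )
            fits_p[pid] = fit_model(
                ModelSpec(1, "proportional"), tr, n_starts=3, rng_seed=int(seeds[1])
            )
            fits_f[pid] = fit_model(gen, tr, n_starts=3, rng_seed=int(seeds[2]))
        comp = compare_models(fits_p, fits_f, n_boot=2000, rng_seed=9)
        assert comp.median_delta_aicc > 0


class TestNestingPenalty:
    def test_proportional_wins_on_proportionally_allocated_data(self):
        """Flexible nests Proportional: when the generating allocation equals
        the probe probabilities, the extra parameters only cost AICc."""
        gen = ModelSpec(experiment=1, strategy="flexible")
        theta = {"Jbar_total": 3.0, "tau": 0.5, "p_high": 0.6, "p_med": 0.3}
        tr = generate_experiment(gen, theta, DesignConfig(n_trials=600), rng_seed=77)
        fit_prop = fit_model(ModelSpec(1, "proportional"), tr, n_starts=4, rng_seed=5)
        fit_flex = fit_model(gen, tr, n_starts=4, rng_seed=6)
        assert fit_flex.loglik >= fit_prop.loglik - 0.2  # nesting on loglik
        assert fit_prop.aicc < fit_flex.aicc
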