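"""Tests of the RSS_T objective, fit statistics, grid search and validation."""

import math

import numpy as np
import pytest

import packinetics as pk
from packinetics import estimation
from packinetics.estimation import _candidate_values, _Objective


def make_profile(times, means, label="toy", ses=None, ph_b=250.0):
    means = np.asarray(means, dtype=float)
    init = pk.SystemState(t=0.0, P=means[0, 0], A=means[0, 1], B=means[0, 2],
                          Q=means[0, 3], R=means[0, 4], E=means[0, 5])
    cond = pk.ReactionConditions(Ph_b=ph_b, initial_state=init,
                                 t_end=float(times[-1]),
                                 sampling_interval=float(times[1] - times[0]))
    return pk.ExperimentalProfile(label=label, conditions=cond, times=times,
                                  means=means, ses=ses)


class TestObjective:
    def test_zero_for_identical_profiles(self, noiseless_profiles):
        p = noiseless_profiles["30/36"]
        br = pk.rss_breakdown(p, p.means)
        assert br.rss_T == 0.0
        assert all(getattr(br, f"rss_{s}") == 0.0 for s in pk.SPECIES)

    def test_single_species_residuals(self):
        times = np.array([0.0, 30.0, 60.0])
        means = np.tile([1.0, 50.0, 40.0, 0.0, 0.0, 100.0], (3, 1))
        sim = means.copy()
        sim[1, 2] -= 1.0   # benzaldehyde residuals (1, 2)
        sim[2, 2] -= 2.0
        br = pk.rss_breakdown(make_profile(times, means), sim)
        assert br.rss_B == pytest.approx(5.0)
        assert br.rss_T == pytest.approx(5.0)

    def test_matches_brute_force_double_loop(self, opt_params,
                                             noiseless_profiles):
        """Vectorised RSS agrees with an element-by-element reference sum."""
        noisy = pk.generate_noisy_dataset(opt_params, seed=42,
                                          zero_byproducts=False)[0]
        traj = pk.simulate(opt_params, noisy.conditions)
        br = pk.rss_breakdown(noisy, traj)
        brute = 0.0
        for i in range(noisy.times.size):
            for j in range(6):
                brute += (noisy.means[i, j] - traj.sample_states[i, j]) ** 2
        assert br.rss_T == pytest.approx(brute, rel=1e-12)

    def test_include_P_flag(self):
        times = np.array([0.0, 30.0, 60.0])
        means = np.tile([1.0, 50.0, 40.0, 0.0, 0.0, 100.0], (3, 1))
        sim = means.copy()
        sim[:, 0] += 2.0   # PAC residuals only
        with_p = pk.rss_breakdown(make_profile(times, means), sim)
        without_p = pk.rss_breakdown(make_profile(times, means), sim,
                                     include_P=False)
        assert with_p.rss_T == pytest.approx(12.0)
        assert without_p.rss_T == 0.0
        assert without_p.rss_P == pytest.approx(12.0)  # reported, not summed

    def test_time_grid_mismatch_raises(self, opt_params, noiseless_profiles):
        p = noiseless_profiles["30/36"]
        short = pk.ReactionConditions(Ph_b=250.0,
                                      initial_state=p.conditions.initial_state,
                                      t_end=180.0, sampling_interval=30.0)
        traj = pk.simulate(opt_params, short)
        with pytest.raises(pk.AlignmentError):
            pk.rss_breakdown(p, traj)

    def test_additive_and_order_invariant_over_profiles(self, opt_params,
                                                        noiseless_profiles):
        pair = [noiseless_profiles["30/36"], noiseless_profiles["100/120"]]
        obj_fwd = _Objective(pair, 0.6, True)
        obj_rev = _Objective(pair[::-1], 0.6, True)
        singles = [_Objective([p], 0.6, True) for p in pair]
        pvec = pk.REFERENCE_INITIAL.to_array()
        total = obj_fwd(pvec)
        assert total == pytest.approx(obj_rev(pvec), rel=1e-14)
        assert total == pytest.approx(sum(o(pvec) for o in singles), rel=1e-14)

    def test_failed_simulation_rejected_not_raised(self, noiseless_profiles,
                                                   caplog):
        obj = _Objective([noiseless_profiles["30/36"]], 0.6, True)
        absurd = pk.REFERENCE_OPTIMIZED.replace(V_p=1e300).to_array()
        with caplog.at_level("WARNING"):
            value = obj(absurd)
        assert math.isinf(value)


class TestFitStatistics:
    def test_dof_convention(self):
        st = pk.fit_statistics_from_rss(380.0, n_obs=48, n_params=10)
        assert st.dof == 38
        assert st.mse == pytest.approx(10.0)

    def test_non_positive_dof_rejected(self):
        with pytest.raises(pk.ConfigurationError):
            pk.fit_statistics_from_rss(1.0, n_obs=10, n_params=10)

    def test_perfect_fit_r2_is_one(self, noiseless_profiles):
        p = noiseless_profiles["100/120"]
        br = pk.rss_breakdown(p, p.means)
        st = pk.profile_fit_statistics(br, p)
        assert st.r2 == pytest.approx(1.0)

    def test_combined_statistics_are_sums(self):
        a = pk.fit_statistics_from_rss(380.0, 48, 10, tss_T=1000.0)
        b = pk.fit_statistics_from_rss(76.0, 48, 10, tss_T=500.0)
        c = pk.combine_fit_statistics([a, b])
        assert c.rss_T == pytest.approx(456.0)
        assert c.mse == pytest.approx(a.mse + b.mse)
        assert c.dof == 76
        assert c.r2 == pytest.approx(1.0 - 456.0 / 1500.0)


class TestGridSearch:
    def test_out_of_bounds_candidates_never_generated(self):
        cands = _candidate_values(1.0, (0.5, 0.9, 1.1, 2.0), (0.85, 1.2))
        assert cands == [0.9, 1.1]

    def test_start_at_truth_terminates_immediately(self, opt_params,
                                                   noiseless_profiles):
        """On noiseless data generated at the start parameters the search
        stops after one sweep with the parameters unchanged."""
        profiles = [noiseless_profiles["30/36"], noiseless_profiles["100/120"]]
        fit = pk.grid_search_fit(profiles, opt_params)
        assert fit.params == opt_params
        assert fit.final_rss == 0.0
        assert len(fit.trace) <= 2

    def test_start_outside_bounds_rejected(self, noiseless_profiles):
        cfg = pk.SearchConfig(bounds={**estimation.default_bounds(
            pk.REFERENCE_INITIAL), "V_p": (1.0, 2.0)})
        with pytest.raises(pk.ConfigurationError):
            pk.grid_search_fit([noiseless_profiles["30/36"]],
                               pk.REFERENCE_INITIAL, cfg)

    def test_trace_non_increasing_and_rss_reduced(self, recovery_fit):
        trace = recovery_fit.trace
        assert all(b <= a * (1 + 1e-12) for a, b in zip(trace, trace[1:]))
        assert recovery_fit.final_rss <= recovery_fit.start_rss

    def test_weakly_identified_parameters_recovered_loosely(self, opt_params,
                                                            recovery_fit):
        """The binding and by-product constants are recovered within 25%,
        the refolding lag only to within about one integration step."""
        fitted = recovery_fit.params
        for name in ("K_b", "V_q", "V_r"):
            rel = abs(getattr(fitted, name) - getattr(opt_params, name)) \
                / getattr(opt_params, name)
            assert rel < 0.25, name
        assert abs(fitted.t_lag - opt_params.t_lag) < 0.6


class TestParameterErrors:
    def test_zero_standard_errors_give_zero_errors(self, opt_params,
                                                   noiseless_profiles,
                                                   fast_config):
        profiles = [noiseless_profiles["30/36"]]
        fit = pk.grid_search_fit(profiles, opt_params, fast_config)
        errors = pk.parameter_errors(fit, profiles, fast_config)
        assert all(v == 0.0 for v in errors.values())
        assert fit.param_errors == errors

    def test_half_range_definition(self, monkeypatch, opt_params,
                                   noiseless_profiles, fast_config):
        """error = |refit(+SE) - refit(-SE)| / 2 for every parameter."""
        profiles = [noiseless_profiles["30/36"]]
        fit = pk.grid_search_fit(profiles, opt_params, fast_config)
        fake = {+1: opt_params.replace(V_p=1.1 * opt_params.V_p),
                -1: opt_params.replace(V_p=0.9 * opt_params.V_p)}
        monkeypatch.setattr(estimation, "_refit_perturbed",
                            lambda fit, profiles, sign, config: fake[sign])
        # give the profile nonzero SEs so the refit branch is taken
        profiles[0].ses[:] = 0.01
        errors = pk.parameter_errors(fit, profiles, fast_config)
        assert errors["V_p"] == pytest.approx(0.1 * opt_params.V_p)
        assert errors["K_ma"] == 0.0
        profiles[0].ses[:] = 0.0

    def test_against_parametric_bootstrap(self, opt_params, fast_config):
        """For the well-identified constants the +/-SE half-range error
        agrees with a parametric-bootstrap standard deviation within a
        factor of 3.  The weakly identified constants (K_ma, k_a, t_lag and
        the deactivation pair) are excluded: a correlated systematic shift
        of the observations barely moves them, while bootstrap scatter
        explores their flat directions."""
        design = pk.StudyDesign(pairs=((30.0, 36.0), (100.0, 120.0)))
        data = pk.generate_noisy_dataset(opt_params, design, seed=11,
                                         zero_byproducts=False)
        fit = pk.grid_search_fit(data, opt_params, fast_config)
        errors = pk.parameter_errors(fit, data, fast_config)
        boots = []
        for r in range(12):
            ds = pk.generate_noisy_dataset(opt_params, design,
                                           seed=100000 + 17 * r,
                                           zero_byproducts=False)
            boots.append(pk.grid_search_fit(ds, opt_params,
                                            fast_config).params.to_array())
        sd = np.asarray(boots).std(axis=0, ddof=1)
        for name in ("V_p", "K_b", "h", "K_ma"):
            i = pk.PARAM_NAMES.index(name)
            assert errors[name] > 0, name
            ratio = errors[name] / sd[i]
            assert 1 / 3 < ratio < 3, (name, ratio)


class TestValidate:
    def test_truth_parameters_fit_their_own_profile(self, opt_params,
                                                    noiseless_profiles):
        res = pk.validate(opt_params, noiseless_profiles["50/60"])
        assert res.statistics.rss_T == pytest.approx(0.0, abs=1e-12)
        assert res.statistics.r2 == pytest.approx(1.0)

    def test_corrupted_parameter_worsens_fit(self, opt_params,
                                             noiseless_profiles):
        p = noiseless_profiles["50/60"]
        at_truth = pk.validate(opt_params, p).statistics.rss_T
        corrupted = pk.validate(opt_params.replace(V_p=10 * opt_params.V_p),
                                p).statistics.rss_T
        assert corrupted > at_truth

    def test_noisy_validation_mse_matches_injected_noise(self, opt_params):
        """Validating a noisy 50/60-style profile against its generating
        truth gives an RSS close to the summed variance of the replicate
        means (the only residual source)."""
        noise = pk.NoiseModel()
        design = pk.StudyDesign(pairs=((50.0, 60.0),))
        profile = pk.generate_noisy_dataset(opt_params, design, noise,
                                            seed=2024,
                                            zero_byproducts=False)[0]
        res = pk.validate(opt_params, profile)
        truth = pk.simulate(opt_params, profile.conditions).sample_states
        expected_rss = float((noise.sd(truth) ** 2).sum() / noise.replicates)
        assert 0.4 < res.statistics.rss_T / expected_rss < 2.5
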