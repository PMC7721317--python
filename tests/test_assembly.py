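"""Time expansion, linkers, diel couplings and the vacuolar capacity."""

import numpy as np
import pytest

from dielfba import (DielConstraintSet, apply_vacuole_capacity,
                     couple_water_loss, expand_diel, make_profile,
                     maximize_phloem, minimize_water, water_per_co2)
from dielfba.optimize import InfeasibleModelError, compile_model


class TestExpansion:
    def test_variable_counts(self, toy_net, env_default, cs_default):
        model = expand_diel(toy_net, env_default, cs_default)
        comp = compile_model(model)
        R, S = len(toy_net.reactions), len(toy_net.storables)
        assert comp.n_flux == 24 * R
        assert comp.n_link == 24 * S

    def test_number_of_steps_must_divide_day(self, toy_net, cs_default):
        env = make_profile(n_steps=12)
        env.n_steps = 7  # corrupt deliberately
        with pytest.raises(ValueError):
            expand_diel(toy_net, env, cs_default)

    def test_missing_tags_is_configuration_error(self, mini_net, env_default,
                                                 cs_default):
        with pytest.raises(ValueError, match="missing required role tags"):
            expand_diel(mini_net, env_default, cs_default)
        # relaxed mode accepts the same network
        expand_diel(mini_net, env_default, cs_default, strict_tags=False)

    def test_light_bounds_follow_the_diel_curve(self, toy_net, env_default,
                                                cs_default):
        model = expand_diel(toy_net, env_default, cs_default)
        j = toy_net.reaction_index("EX_PHOTON")
        assert np.allclose(model.ub[j, :], env_default.I)

    def test_rubisco_dark_inactivation(self, toy_net, env_default, cs_default):
        model = expand_diel(toy_net, env_default, cs_default)
        for tag in ("RUBISCO_CARB", "RUBISCO_OXY"):
            j = toy_net.reaction_index(toy_net.find_by_tag(tag).id)
            night = ~env_default.is_day
            assert np.all(model.ub[j, night] == 0.0)
            assert np.all(model.lb[j, night] == 0.0)

    def test_co2_uptake_cap(self, toy_net, env_default, cs_default):
        model = expand_diel(toy_net, env_default, cs_default)
        j = toy_net.reaction_index("EX_CO2_UPTAKE")
        assert np.all(model.ub[j, :] == cs_default.co2_uptake_max)
        assert np.all(model.lb[j, :] == 0.0)

    def test_maintenance_fixed_per_step(self, toy_net, env_default, cs_default):
        model = expand_diel(toy_net, env_default, cs_default)
        j_atp = toy_net.reaction_index("ATP_MAINT_c")
        j_nad = toy_net.reaction_index("NADPH_MAINT_c")
        day = env_default.is_day
        atp_day = cs_default.maintenance_per_light * env_default.I[day].mean()
        assert np.allclose(model.lb[j_atp, day], atp_day)
        assert np.allclose(model.ub[j_atp, day], atp_day)
        assert np.allclose(model.lb[j_atp, ~day], atp_day / 3.0)
        assert np.allclose(model.lb[j_nad], model.lb[j_atp] / 3.0)


@pytest.fixture(scope="module")
def solution(model_factory):
    return maximize_phloem(model_factory("C3"), flux_min=False)


class TestSolvedCouplings:
    """Ratio constraints verified on an actual optimal solution."""

    def test_phloem_day_night_ratio(self, solution, env_default):
        v = solution.fluxes.loc["PHLOEM_EXPORT"].to_numpy()
        day, night = v[env_default.is_day], v[~env_default.is_day]
        assert np.ptp(day) < 1e-8 and np.ptp(night) < 1e-8
        assert day[0] == pytest.approx(3.0 * night[0], rel=1e-6)

    def test_nitrate_day_night_ratio(self, solution, env_default):
        v = solution.fluxes.loc["EX_NO3"].to_numpy()
        day, night = v[env_default.is_day], v[~env_default.is_day]
        assert np.ptp(day) < 1e-8 and np.ptp(night) < 1e-8
        assert day[0] == pytest.approx(1.5 * night[0], rel=1e-6)

    def test_rubisco_carboxylation_oxygenation_ratio(self, solution,
                                                     env_default):
        carb = solution.fluxes.loc["RBC_CARB"].to_numpy()
        oxy = solution.fluxes.loc["RBC_OXY"].to_numpy()
        day = env_default.is_day
        assert np.allclose(carb[day], 3.0 * oxy[day], atol=1e-8)
        assert np.allclose(carb[~day], 0.0, atol=1e-9)

    def test_steady_state_and_cyclic_conservation(self, solution):
        assert solution.steady_state_residual() < 1e-9
        # closed cycle: every storable's net linker throughput cancels
        L = solution.linkers.to_numpy()
        assert np.allclose((np.roll(L, 1, axis=1) - L).sum(axis=1), 0.0,
                           atol=1e-9)


class TestLinkers:
    def test_linker_transfers_amount_to_next_step(self, model_factory):
        """A linker flux of 1 umol m-2 s-1 over a 1-h interval makes
        3.6 mmol m-2 available in the following interval."""
        from dielfba.reporting import linker_profiles

        sol = maximize_phloem(model_factory("C3"), flux_min=False)
        profiles = linker_profiles(sol).drop(columns="flagged")
        expected = sol.linkers.to_numpy() * 3600.0 * 1e-3
        assert np.allclose(profiles.to_numpy(), expected, atol=1e-12)
        assert profiles.to_numpy().max() > 1.0  # starch actually cycles

    def test_blocked_linkers_make_night_maintenance_infeasible(
            self, toy_net, env_default, cs_default):
        model = expand_diel(toy_net, env_default, cs_default)
        couple_water_loss(model)
        model.linker_ub = 0.0  # no diel carry-over at all
        with pytest.raises(InfeasibleModelError):
            maximize_phloem(model, flux_min=False)


class TestVacuoleCapacity:
    def test_negative_capacity_rejected(self, model_factory):
        with pytest.raises(ValueError):
            apply_vacuole_capacity(model_factory("C3"), -1.0)

    def test_cam_capacity_is_31x_c3(self, cs_default):
        assert cs_default.vacuole_capacity_cam == pytest.approx(
            3.1 * cs_default.vacuole_capacity_c3)

    def test_infinite_capacity_removes_constraint(self, model_factory):
        model = apply_vacuole_capacity(model_factory("C3"), float("inf"))
        assert model.vacuole_capacity is None
        assert compile_model(model).A_ub is None

    def test_zero_capacity_blocks_vacuole_but_not_starch(self, model_factory):
        model = model_factory(0.0)
        sol = maximize_phloem(model, flux_min=False)
        vac = [m for m in model.storables
               if model.base.metabolite(m).compartment == "vacuole"]
        assert np.allclose(sol.linkers.loc[vac].to_numpy(), 0.0, atol=1e-9)
        assert sol.linkers.loc["STARCH_p"].max() > 0.1

    def test_stored_amounts_respect_capacity(self, model_factory, cs_default,
                                             env_default):
        model = model_factory("CAM")
        sol = maximize_phloem(model, flux_min=False)
        vac = [m for m in model.storables
               if model.base.metabolite(m).compartment == "vacuole"]
        per_step = sol.linkers.loc[vac].to_numpy().sum(axis=0)
        stored_mol = per_step * env_default.step_seconds * 1e-6
        assert np.all(stored_mol <= cs_default.vacuole_capacity_cam * (1 + 1e-9))

    def test_relaxing_capacity_monotone(self, model_factory):
        """More storage can only help: max phloem weakly increases and
        minimal water at a fixed floor weakly decreases."""
        tight = model_factory("C3")
        loose = model_factory("unlimited")
        p_tight = maximize_phloem(tight, flux_min=False).phloem_output
        p_loose = maximize_phloem(loose, flux_min=False).phloem_output
        assert p_loose >= p_tight - 1e-9
        floor = 0.5 * p_tight
        w_tight = minimize_water(tight, floor, flux_min=False).water_total
        w_loose = minimize_water(loose, floor, flux_min=False).water_total
        assert w_loose <= w_tight + 1e-9


class TestWaterCoupling:
    def test_zero_uptake_forces_zero_water(self, toy_net, env_default,
                                           cs_default):
        model = expand_diel(toy_net, env_default, cs_default)
        couple_water_loss(model)
        model.set_bounds("EX_CO2_UPTAKE", lb=0.0, ub=0.0)
        sol = minimize_water(model, 0.0, flux_min=False)
        assert sol.water_total == pytest.approx(0.0, abs=1e-9)

    def test_water_coefficient_peaks_with_heat(self, model_factory,
                                               env_default):
        model = model_factory("C3")
        assert int(np.argmax(model.water_coeffs)) == int(np.argmax(env_default.T))
        assert np.allclose(model.water_coeffs,
                           water_per_co2(env_default.T, env_default.RH))

    def test_water_total_linear_in_uptake(self, model_factory, env_default):
        """The reported water total equals the independent closed-form
        integral of the uptake profile (solver-free bookkeeping)."""
        from dielfba.environment import total_water_loss

        sol = maximize_phloem(model_factory("C3"), flux_min=False)
        recomputed = total_water_loss(
            np.clip(sol.uptake_profile(), 0.0, None), env_default)
        assert sol.water_total == pytest.approx(recomputed, rel=1e-12)


class TestIntervalScaling:
    def test_coarser_time_intervals_give_similar_phloem(self, toy_net,
                                                        cs_default):
        """Daily phloem output is stable (<5% change) when the same diel cycle
        is discretised with 1-h or 2-h intervals."""
        outputs = {}
        for n in (24, 12):
            model = expand_diel(toy_net, make_profile(n_steps=n), cs_default)
            couple_water_loss(model)
            apply_vacuole_capacity(model, cs_default.vacuole_capacity_c3)
            outputs[n] = maximize_phloem(model, flux_min=False).phloem_output
        assert outputs[12] == pytest.approx(outputs[24], rel=0.05)
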