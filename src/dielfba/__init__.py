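"""dielfba: time-resolved, environment-coupled diel flux balance analysis of
leaf metabolism.

The package couples a compartmented plant core metabolic network, expanded
into a closed 24-h cycle with storage linker reactions, to a stomatal
gas-exchange model, and solves a lexicographic objective stack (phloem output
-> water loss -> L2 flux sum) to study C3/CAM water-use trade-offs across
environments.
"""

from .assembly import (DielConstraintSet, DielModel, apply_vacuole_capacity,
                       couple_water_loss, expand_diel)
from .environment import (EnvironmentProfile, GasExchangeParams, light_curve,
                          make_profile, skewed_diel_curve, total_water_loss,
                          water_per_co2)
from .network import (MetabolicNetwork, Metabolite, Reaction, ToyOptions,
                      build_toy_core, check_mass_consistency, read_sbml,
                      write_sbml)
from .optimize import (DielSolution, InfeasibleModelError, ParetoPoint,
                       maximize_phloem, minimize_flux, minimize_water,
                       pareto_scan)
from .reporting import (Budget, PhasePattern, atp_budget, co2_budget,
                        detect_phases, linker_profiles, write_solution)
from .scenarios import (ScanRecord, ScenarioConfig, ci_sensitivity,
                        environment_grid, records_to_frame, run_scenario)

__version__ = "0.1.0"

__all__ = [
    "DielConstraintSet", "DielModel", "DielSolution", "EnvironmentProfile",
    "GasExchangeParams", "MetabolicNetwork", "Metabolite", "ParetoPoint",
    "PhasePattern", "Budget", "Reaction", "ScanRecord", "ScenarioConfig",
    "ToyOptions", "InfeasibleModelError",
    "apply_vacuole_capacity", "atp_budget", "build_toy_core",
    "check_mass_consistency", "ci_sensitivity", "co2_budget",
    "couple_water_loss", "detect_phases", "environment_grid", "expand_diel",
    "light_curve", "linker_profiles", "make_profile", "maximize_phloem",
    "minimize_flux", "minimize_water", "pareto_scan", "read_sbml",
    "records_to_frame", "run_scenario", "skewed_diel_curve",
    "total_water_loss", "water_per_co2", "write_sbml", "write_solution",
]


def _rebuild_solution(outdir):
    """Reconstruct a DielSolution from a directory written by
    ``write_solution`` (uses the run configuration stored in summary.json)."""
    import numpy as np

    from .config import build_from_config, default_config
    from .reporting import read_solution_tables

    fluxes, linkers, summary = read_solution_tables(outdir)
    cfg = summary.get("run_params", {}).get("config") or default_config()
    net, env, cs, gas = build_from_config(cfg)
    model = expand_diel(net, env, cs, gas)
    couple_water_loss(model)
    up = fluxes.loc[net.find_by_tag("CO2_UPTAKE").id].to_numpy()
    water = total_water_loss(np.clip(up, 0, None), env, gas)
    return DielSolution(
        fluxes=fluxes, linkers=linkers,
        phloem_output=summary["phloem_output"], water_total=water,
        co2_total=summary["co2_total"], flux_sum_l1=summary["flux_sum_l1"],
        status=summary["status"], objectives=summary.get("objectives", {}),
        model=model)
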