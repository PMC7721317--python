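"""Diagnostic summaries of diel solutions: CO2 and ATP budgets, storage
(linker) profiles, CAM-phase detection, and file outputs."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .optimize import DielSolution

__all__ = [
    "Budget",
    "PhasePattern",
    "co2_budget",
    "atp_budget",
    "linker_profiles",
    "detect_phases",
    "write_solution",
    "read_solution_tables",
]

#: fluxes below this magnitude are zeroed in reports (not in solutions)
REPORT_ZERO_TOL = 1e-7


@dataclass
class Budget:
    """Signed per-step production/consumption of one balanced species class.

    ``contributions`` has one row per reaction whose |contribution| exceeds
    the threshold at >= 1 step (positive = the species is produced).
    ``cumulative`` is the signed daily total per reaction in mol m-2 d-1.
    ``turnover`` is the summed production over all reactions and steps in
    flux units (umol m-2 s-1).
    """

    species: str
    contributions: pd.DataFrame
    cumulative: pd.Series
    turnover: float
    threshold: float
    total_balance: float

    def producers(self) -> pd.Series:
        return self.cumulative[self.cumulative > 0].sort_values(ascending=False)

    def consumers(self) -> pd.Series:
        return self.cumulative[self.cumulative < 0].sort_values()


def _species_budget(sol: DielSolution, species: str, met_filter,
                    threshold: float) -> Budget:
    net = sol.model.base
    V = sol.fluxes.to_numpy()
    V = np.where(np.abs(V) < REPORT_ZERO_TOL, 0.0, V)
    step_mol = sol.model.env.step_seconds * 1e-6
    rows, index = [], []
    total = 0.0
    turnover = 0.0
    for j, rxn in enumerate(net.reactions):
        coeff = sum(c for mid, c in rxn.stoichiometry.items()
                    if met_filter(net.metabolite(mid)))
        if coeff == 0:
            continue
        contrib = coeff * V[j]
        total += contrib.sum()
        turnover += np.clip(contrib, 0.0, None).sum()
        if np.max(np.abs(contrib)) > threshold:
            rows.append(contrib)
            index.append(rxn.id)
    contributions = pd.DataFrame(rows, index=index,
                                 columns=sol.fluxes.columns)
    cumulative = contributions.sum(axis=1) * step_mol
    return Budget(species, contributions, cumulative, float(turnover),
                  threshold, float(total))


def co2_budget(sol: DielSolution, threshold: float = 0.5) -> Budget:
    """All reactions moving CO2/bicarbonate with |flux contribution| above
    ``threshold`` (umol m-2 s-1) at >= 1 step, signed by production.

    Exchange reactions are included, so the grand total over all rows and
    steps is zero up to solver precision.
    """
    return _species_budget(sol, "CO2", lambda m: m.is_co2_species, threshold)


def atp_budget(sol: DielSolution, threshold: float = 0.5) -> Budget:
    """ATP production/consumption budget; ``turnover`` is total production
    summed over the day in flux units (umol m-2 s-1)."""
    return _species_budget(
        sol, "ATP", lambda m: m.name.upper() == "ATP" or
        m.id.upper().startswith("ATP"), threshold)


def linker_profiles(sol: DielSolution, threshold: float = 0.5) -> pd.DataFrame:
    """Stored amount per storable per step in mmol m-2.

    Column t holds the amount transferred out of step t into step t+1
    (linker flux x step duration); a linker flux of 1 umol m-2 s-1 over a 1-h
    step is 3.6 mmol m-2. The boolean ``flagged`` column marks storables whose
    peak exceeds the flux-equivalent significance threshold.
    """
    factor = sol.model.env.step_seconds * 1e-3  # umol m-2 s-1 -> mmol m-2
    L = sol.linkers.to_numpy()
    L = np.where(np.abs(L) < REPORT_ZERO_TOL, 0.0, L)
    table = pd.DataFrame(L * factor, index=sol.linkers.index,
                         columns=sol.linkers.columns)
    table["flagged"] = table.max(axis=1) > threshold * factor
    return table


@dataclass
class PhasePattern:
    """Per-step CAM phase labels.

    I: dark period (nocturnal stomatal opening when uptake is present);
    II: dawn-adjacent daytime uptake; III: daytime stomatal closure (no
    uptake); IV: dusk-adjacent daytime uptake. ``phases_active`` counts phase
    I only when nocturnal uptake actually occurs.
    """

    labels: list
    uptake: np.ndarray
    is_day: np.ndarray
    tol: float

    @property
    def nocturnal_uptake(self) -> bool:
        return bool(np.any(self.uptake[~self.is_day] > self.tol))

    @property
    def phases_active(self) -> set:
        active = {lab for lab, day in zip(self.labels, self.is_day) if day}
        if self.nocturnal_uptake:
            active.add("I")
        return active


def detect_phases(sol: DielSolution, tol: float = 0.01,
                  noon: float = 12.0) -> PhasePattern:
    """Label each step with its CAM phase from the CO2-uptake profile and the
    light state.

    Day steps with uptake form phase II when their run touches dawn and phase
    IV when it touches dusk; isolated midday uptake islands count as II
    before solar noon and IV after. Day steps without uptake are phase III;
    all dark steps belong to phase I (the dark period).
    """
    env = sol.model.env
    uptake = np.clip(sol.uptake_profile(), 0.0, None)
    is_day = env.is_day
    N = env.n_steps
    labels = ["I"] * N
    day_idx = np.flatnonzero(is_day)
    if len(day_idx):
        dawn, dusk = day_idx[0], day_idx[-1]
        open_day = is_day & (uptake > tol)
        # contiguous runs of open day steps
        for t in day_idx:
            if not open_day[t]:
                labels[t] = "III"
        runs = []
        current = []
        for t in day_idx:
            if open_day[t]:
                current.append(t)
            elif current:
                runs.append(current)
                current = []
        if current:
            runs.append(current)
        midpoints = env.midpoints
        for run in runs:
            touches_dawn = run[0] == dawn
            touches_dusk = run[-1] == dusk
            if touches_dawn and touches_dusk:
                # uptake spans the whole photoperiod (C3-like): the morning
                # half is the dawn transition, the afternoon half the dusk one
                for t in run:
                    labels[t] = "II" if midpoints[t] < noon else "IV"
            elif touches_dawn:
                for t in run:
                    labels[t] = "II"
            elif touches_dusk:
                for t in run:
                    labels[t] = "IV"
            else:
                lab = "II" if midpoints[run[0]] < noon else "IV"
                for t in run:
                    labels[t] = lab
    return PhasePattern(labels, uptake, is_day, tol)


# ---------------------------------------------------------------------------
# File outputs
# ---------------------------------------------------------------------------

def write_solution(sol: DielSolution, outdir, run_params: dict | None = None):
    """Write fluxes.tsv, linkers.tsv and summary.json (with run parameters
    and solver status) to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    flux = sol.fluxes.copy()
    flux.index.name = "reaction_id"
    flux.to_csv(outdir / "fluxes.tsv", sep="\t")
    link = sol.linkers.copy()
    link.index.name = "storable"
    link.to_csv(outdir / "linkers.tsv", sep="\t")
    summary = {
        "phloem_output": sol.phloem_output,
        "water_total": sol.water_total,
        "co2_total": sol.co2_total,
        "flux_sum_l1": sol.flux_sum_l1,
        "status": sol.status,
        "objectives": sol.objectives,
        "n_steps": sol.model.n_steps,
        "run_params": run_params or {},
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    env = sol.model.env.to_frame()
    env.to_csv(outdir / "environment.csv", index=False)
    return outdir


def read_solution_tables(outdir):
    """Read back the flux/linker tables written by :func:`write_solution`."""
    outdir = Path(outdir)
    fluxes = pd.read_csv(outdir / "fluxes.tsv", sep="\t", index_col=0)
    fluxes.columns = fluxes.columns.astype(int)
    linkers = pd.read_csv(outdir / "linkers.tsv", sep="\t", index_col=0)
    linkers.columns = linkers.columns.astype(int)
    with open(outdir / "summary.json") as fh:
        summary = json.load(fh)
    return fluxes, linkers, summary
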