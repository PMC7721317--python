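"""Lexicographic optimization of diel models.

The objective stack is: (1) maximize daily phloem output (LP); (2) minimize
daily transpirational water loss at a fixed phloem floor (LP); (3) minimize
the metabolic flux sum as an L2 norm (QP) to select, among alternative
optima, the flux distribution with the least variation between time points.
Stage k+1 never degrades stage k beyond a relative tolerance of 1e-6.

The QP stage uses OSQP when importable and otherwise falls back to a
piecewise-linear convex approximation of the L2 objective solved as an LP
with HiGHS. Either way the returned solution is re-polished by an L1
projection LP (minimize the L1 distance to the QP point subject to all
original constraints), so final solutions satisfy steady state to LP
precision (~1e-10) regardless of the QP engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import linprog

from .assembly import DielModel
from .environment import total_water_loss

__all__ = [
    "DielSolution",
    "ParetoPoint",
    "InfeasibleModelError",
    "maximize_phloem",
    "minimize_water",
    "minimize_flux",
    "pareto_scan",
]

#: relative tolerance for pinning earlier-stage objectives
PIN_RTOL = 1e-6
_LP_OPTIONS = {"presolve": True}

try:  # optional fast QP engine; the LP fallback is always available
    import osqp as _osqp
    HAVE_OSQP = True
except Exception:  # pragma: no cover - depends on image
    _osqp = None
    HAVE_OSQP = False


class InfeasibleModelError(RuntimeError):
    """Raised when a stage LP/QP is infeasible or unbounded."""


# ---------------------------------------------------------------------------
# Compilation of a DielModel into matrices
# ---------------------------------------------------------------------------

@dataclass
class _Compiled:
    model: DielModel
    n_flux: int          # N*R step-reaction variables (step-major)
    n_link: int          # S*N linker variables
    n_vars: int
    A_eq: sparse.csr_matrix
    b_eq: np.ndarray
    A_ub: sparse.csr_matrix | None
    b_ub: np.ndarray | None
    lb: np.ndarray
    ub: np.ndarray
    c_phloem: np.ndarray | None
    c_water: np.ndarray | None
    idx_water: int | None
    idx_total_water: int | None

    def flux_index(self, rxn_id: str, t: int) -> int:
        R = len(self.model.base.reactions)
        return t * R + self.model.base.reaction_index(rxn_id)

    def link_index(self, storable: str, t: int) -> int:
        s = self.model.storables.index(storable)
        return self.n_flux + s * self.model.n_steps + t


def compile_model(model: DielModel) -> _Compiled:
    net, env = model.base, model.env
    N, R, M = model.n_steps, len(net.reactions), len(net.metabolites)
    S = net.stoichiometric_matrix()
    n_flux = N * R
    n_link = len(model.storables) * N
    n_aux = (N + 1) if model.water_coupled else 0
    n_vars = n_flux + n_link + n_aux

    # steady state: block-diagonal stoichiometry, step-major variable order
    A_ss = sparse.kron(sparse.identity(N, format="csr"), S, format="lil")
    A_ss.resize((N * M, n_vars))
    for s, mid in enumerate(model.storables):
        i = net.metabolite_index(mid)
        for t in range(N):
            col_in = n_flux + s * N + (t - 1) % N
            col_out = n_flux + s * N + t
            A_ss[t * M + i, col_in] += 1.0
            A_ss[t * M + i, col_out] -= 1.0
    rows = [A_ss.tocsr()]
    b_eq = [np.zeros(N * M)]

    # coupling rows (ratio constraints, shared day/night rates)
    if model.coupling_rows:
        data, ri, ci = [], [], []
        rhs = []
        for k, (entries, r) in enumerate(model.coupling_rows):
            for rxn_id, t, coeff in entries:
                ri.append(k)
                ci.append(t * R + net.reaction_index(rxn_id))
                data.append(coeff)
            rhs.append(r)
        rows.append(sparse.csr_matrix(
            (data, (ri, ci)), shape=(len(model.coupling_rows), n_vars)))
        b_eq.append(np.asarray(rhs, dtype=float))

    idx_water = idx_total = None
    if model.water_coupled:
        idx_water = n_flux + n_link
        idx_total = n_flux + n_link + N
        j_up = net.reaction_index(net.find_by_tag("CO2_UPTAKE").id)
        data, ri, ci = [], [], []
        for t in range(N):
            ri += [t, t]
            ci += [idx_water + t, t * R + j_up]
            data += [1.0, -float(model.water_coeffs[t])]
        # total water (mol m-2 d-1) = sum_t w_t * step_seconds * 1e-6
        ri += [N] * (N + 1)
        ci += [idx_total] + [idx_water + t for t in range(N)]
        data += [1.0] + [-env.step_seconds * 1e-6] * N
        rows.append(sparse.csr_matrix((data, (ri, ci)), shape=(N + 1, n_vars)))
        b_eq.append(np.zeros(N + 1))

    A_eq = sparse.vstack(rows, format="csr")
    b_eq = np.concatenate(b_eq)

    # vacuolar capacity inequality rows
    A_ub = b_ub = None
    if model.vacuole_capacity is not None:
        vac = model.vacuolar_storables
        if vac:
            factor = env.step_seconds * 1e-6  # flux -> mol carried
            data, ri, ci = [], [], []
            for t in range(N):
                for mid in vac:
                    w = model.cs.capacity_weights.get(mid, 1.0)
                    ri.append(t)
                    ci.append(n_flux + model.storables.index(mid) * N + t)
                    data.append(w * factor)
            A_ub = sparse.csr_matrix((data, (ri, ci)), shape=(N, n_vars))
            b_ub = np.full(N, float(model.vacuole_capacity))

    lb = np.empty(n_vars)
    ub = np.empty(n_vars)
    lb[:n_flux] = model.lb.T.ravel()
    ub[:n_flux] = model.ub.T.ravel()
    lb[n_flux:n_flux + n_link] = 0.0
    ub[n_flux:n_flux + n_link] = model.linker_ub
    if n_aux:
        lb[n_flux + n_link:] = 0.0
        ub[n_flux + n_link:] = np.inf

    try:
        j_ph = net.reaction_index(net.find_by_tag("PHLOEM_EXPORT").id)
    except KeyError:
        c_ph = None  # networks without a phloem role cannot use phloem stages
    else:
        c_ph = np.zeros(n_vars)
        for t in range(N):
            c_ph[t * R + j_ph] = env.step_seconds * 1e-6  # daily mol m-2
    c_w = None
    if model.water_coupled:
        c_w = np.zeros(n_vars)
        c_w[idx_total] = 1.0

    return _Compiled(model, n_flux, n_link, n_vars, A_eq, b_eq, A_ub, b_ub,
                     lb, ub, c_ph, c_w, idx_water, idx_total)


# ---------------------------------------------------------------------------
# LP / QP engines
# ---------------------------------------------------------------------------

def _stack_ub(comp: _Compiled, extra_rows, extra_rhs):
    blocks, rhs = [], []
    if comp.A_ub is not None:
        blocks.append(comp.A_ub)
        rhs.append(comp.b_ub)
    if extra_rows:
        blocks.append(sparse.vstack(extra_rows, format="csr"))
        rhs.append(np.asarray(extra_rhs, dtype=float))
    if not blocks:
        return None, None
    return sparse.vstack(blocks, format="csr"), np.concatenate(rhs)


def _solve_lp(comp: _Compiled, c, extra_rows=(), extra_rhs=(), stage=""):
    A_ub, b_ub = _stack_ub(comp, list(extra_rows), list(extra_rhs))
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=comp.A_eq, b_eq=comp.b_eq,
                  bounds=np.column_stack([comp.lb, comp.ub]),
                  method="highs", options=_LP_OPTIONS)
    if res.status != 0:
        kind = {2: "infeasible", 3: "unbounded"}.get(res.status, "failed")
        raise InfeasibleModelError(
            f"{stage or 'LP'} stage {kind}: {res.message} "
            "(check phloem floor vs maximum output, maintenance requirements "
            "vs storage/linker bounds, and day/night couplings)"
        )
    return res.x


def _row(comp: _Compiled, c_vec) -> sparse.csr_matrix:
    return sparse.csr_matrix(c_vec.reshape(1, -1))


def _solve_qp_osqp(comp: _Compiled, extra_rows, extra_rhs):
    n = comp.n_vars
    nq = comp.n_flux + comp.n_link
    P = sparse.diags(
        np.concatenate([np.full(nq, 2.0), np.zeros(n - nq)]), format="csc")
    A_ub, b_ub = _stack_ub(comp, list(extra_rows), list(extra_rhs))
    blocks = [comp.A_eq]
    l = [comp.b_eq]
    u = [comp.b_eq]
    if A_ub is not None:
        blocks.append(A_ub)
        l.append(np.full(A_ub.shape[0], -np.inf))
        u.append(b_ub)
    blocks.append(sparse.identity(n, format="csr"))
    l.append(comp.lb)
    u.append(comp.ub)
    A = sparse.vstack(blocks, format="csc")
    prob = _osqp.OSQP()
    prob.setup(P=P, q=np.zeros(n), A=A,
               l=np.concatenate(l), u=np.concatenate(u),
               eps_abs=1e-7, eps_rel=1e-7, max_iter=200000,
               polishing=True, verbose=False)
    res = prob.solve()
    if res.x is None or "solved" not in res.info.status:
        return None
    return res.x


#: breakpoints of the piecewise-linear convex surrogate for x^2 (umol m-2 s-1)
_PWL_BREAKS = np.array([0.0, 0.1, 0.3, 1.0, 3.0, 8.0, 20.0, 50.0, 120.0,
                        300.0, 1000.0, 10000.0])


def _solve_qp_pwl(comp: _Compiled, extra_rows, extra_rhs):
    """LP on a piecewise-linear convex surrogate of sum(v^2).

    Each flux/linker variable is split into signed segments with slopes
    b_k + b_{k+1} (the exact secant slopes of x^2 between breakpoints), so the
    surrogate agrees with x^2 at every breakpoint and the LP fills segments
    in order of increasing slope. A strictly positive lower bound (e.g. a
    fixed maintenance flux) is enforced by forcing the lowest segments to
    fill up to it; symmetrically for a negative upper bound.
    """
    A_ub, b_ub = _stack_ub(comp, list(extra_rows), list(extra_rhs))
    nq = comp.n_flux + comp.n_link
    orig_idx, signs, seg_lo, seg_hi, slopes = [], [], [], [], []
    for i in range(nq):
        for sign, cap, floor in (
            (1.0, max(comp.ub[i], 0.0), max(comp.lb[i], 0.0)),
            (-1.0, max(-comp.lb[i], 0.0), max(-comp.ub[i], 0.0)),
        ):
            if cap <= 0:
                continue
            bks = np.minimum(_PWL_BREAKS, cap)
            lens = np.diff(bks)
            ks = np.flatnonzero(lens > 0)
            lows = np.clip(floor - bks[ks], 0.0, lens[ks])
            orig_idx += [i] * len(ks)
            signs += [sign] * len(ks)
            seg_lo += list(lows)
            seg_hi += list(lens[ks])
            slopes += list(bks[ks] + bks[ks + 1])
    orig_idx = np.array(orig_idx, dtype=int)
    n_aux = comp.n_vars - nq
    n_seg = len(orig_idx)

    def expand(A):
        if A is None:
            return None
        A = A.tocsc()
        cols = A[:, orig_idx].multiply(np.asarray(signs))
        return sparse.hstack([cols, A[:, nq:]], format="csr")

    c = np.concatenate([slopes, np.zeros(n_aux)])
    lo = np.concatenate([seg_lo, comp.lb[nq:]])
    hi = np.concatenate([seg_hi, comp.ub[nq:]])
    res = linprog(c, A_ub=expand(A_ub), b_ub=b_ub, A_eq=expand(comp.A_eq),
                  b_eq=comp.b_eq, bounds=np.column_stack([lo, hi]),
                  method="highs", options=_LP_OPTIONS)
    if res.status != 0:
        return None
    x = np.zeros(comp.n_vars)
    np.add.at(x, orig_idx, np.asarray(signs) * res.x[:n_seg])
    x[nq:] = res.x[n_seg:]
    return x


def _polish_l1(comp: _Compiled, x0, extra_rows, extra_rhs):
    """Project a QP point back onto the constraint polytope by minimizing the
    L1 distance to it; restores steady state to LP precision."""
    nq = comp.n_flux + comp.n_link
    n = comp.n_vars
    A_ub, b_ub = _stack_ub(comp, list(extra_rows), list(extra_rhs))
    # variables: [x (n), d (nq)]; d >= |x - x0| on flux/linker block
    eye = sparse.identity(nq, format="csr")
    pad = sparse.csr_matrix((nq, n - nq))
    ineq = [sparse.hstack([eye, pad, -eye], format="csr"),
            sparse.hstack([-eye, pad, -eye], format="csr")]
    rhs = [x0[:nq], -x0[:nq]]
    if A_ub is not None:
        ineq.insert(0, sparse.hstack(
            [A_ub, sparse.csr_matrix((A_ub.shape[0], nq))], format="csr"))
        rhs.insert(0, b_ub)
    A_eq = sparse.hstack([comp.A_eq, sparse.csr_matrix((comp.A_eq.shape[0], nq))],
                         format="csr")
    c = np.concatenate([np.zeros(n), np.ones(nq)])
    lo = np.concatenate([comp.lb, np.zeros(nq)])
    hi = np.concatenate([comp.ub, np.full(nq, np.inf)])
    res = linprog(c, A_ub=sparse.vstack(ineq, format="csr"),
                  b_ub=np.concatenate(rhs), A_eq=A_eq, b_eq=comp.b_eq,
                  bounds=np.column_stack([lo, hi]),
                  method="highs", options=_LP_OPTIONS)
    if res.status != 0:
        raise InfeasibleModelError(f"L1 polish failed: {res.message}")
    return res.x[:n]


#: models below this size go to the exact QP engine first; larger diel models
#: use the PWL surrogate, on which ADMM converges poorly.
_OSQP_MAX_VARS = 800


def _minimize_flux_qp(comp: _Compiled, extra_rows, extra_rhs, engine="auto"):
    """Stage-3 engine dispatch, always followed by the L1 feasibility polish.

    ``auto`` uses the exact QP (OSQP) on small instances where it converges
    quickly and the piecewise-linear surrogate LP on full diel models.
    """
    status = x = None
    want_osqp = engine == "osqp" or (
        engine == "auto" and HAVE_OSQP and comp.n_vars <= _OSQP_MAX_VARS)
    if want_osqp and HAVE_OSQP:
        x = _solve_qp_osqp(comp, extra_rows, extra_rhs)
        status = "optimal" if x is not None else None
    if x is None and engine != "osqp":
        x = _solve_qp_pwl(comp, extra_rows, extra_rhs)
        status = "optimal_pwl_l2" if x is not None else None
    if x is None:
        raise InfeasibleModelError("flux-sum minimization failed in both QP engines")
    return _polish_l1(comp, x, extra_rows, extra_rhs), status


# ---------------------------------------------------------------------------
# Solutions
# ---------------------------------------------------------------------------

@dataclass
class DielSolution:
    """Per-reaction-per-step fluxes plus derived daily totals.

    ``water_total`` is recomputed from the CO2-uptake profile and the
    gas-exchange coefficients, independently of any solver auxiliary
    variable.
    """

    fluxes: pd.DataFrame          # reactions x steps, umol m-2 s-1
    linkers: pd.DataFrame         # storables x steps, umol m-2 s-1
    phloem_output: float          # mol m-2 d-1
    water_total: float            # mol m-2 d-1
    co2_total: float              # mol m-2 d-1
    flux_sum_l1: float            # umol m-2 s-1, step reactions + linkers
    status: str
    objectives: dict = field(default_factory=dict)
    model: DielModel | None = field(default=None, repr=False)

    def uptake_profile(self) -> np.ndarray:
        up = self.model.base.find_by_tag("CO2_UPTAKE").id
        return self.fluxes.loc[up].to_numpy()

    def steady_state_residual(self) -> float:
        """Max |S v| over metabolites and steps, linker terms included."""
        net = self.model.base
        S = net.stoichiometric_matrix()
        V = self.fluxes.to_numpy()
        L = self.linkers.to_numpy()
        resid = S @ V
        for s, mid in enumerate(self.model.storables):
            i = net.metabolite_index(mid)
            resid[i, :] += np.roll(L[s], 1) - L[s]
        return float(np.abs(resid).max())


def _extract(model: DielModel, comp: _Compiled, x, status, objectives) -> DielSolution:
    net, env = model.base, model.env
    N, R = model.n_steps, len(net.reactions)
    V = x[:comp.n_flux].reshape(N, R).T
    L = x[comp.n_flux:comp.n_flux + comp.n_link].reshape(len(model.storables), N)
    fluxes = pd.DataFrame(V, index=[r.id for r in net.reactions],
                          columns=range(N))
    linkers = pd.DataFrame(L, index=list(model.storables), columns=range(N))
    try:
        ph = net.find_by_tag("PHLOEM_EXPORT").id
        phloem = float(fluxes.loc[ph].sum() * env.step_seconds * 1e-6)
    except KeyError:
        phloem = float("nan")
    try:
        up = net.find_by_tag("CO2_UPTAKE").id
        uptake = np.clip(fluxes.loc[up].to_numpy(), 0.0, None)
        co2_total = float(uptake.sum() * env.step_seconds * 1e-6)
    except KeyError:
        co2_total = float("nan")
    water = total_water_loss(uptake, env, model.gas) if model.water_coupled else float("nan")
    l1 = float(np.abs(V).sum() + np.abs(L).sum())
    return DielSolution(fluxes, linkers, phloem, water, co2_total, l1,
                        status, objectives, model)


# ---------------------------------------------------------------------------
# Lexicographic stack
# ---------------------------------------------------------------------------

def maximize_phloem(model: DielModel, flux_min: bool = True,
                    engine: str = "auto") -> DielSolution:
    """Stage 1: maximize daily phloem output; optionally apply the flux-sum
    minimization afterwards without degrading the optimum."""
    comp = compile_model(model)
    if comp.c_phloem is None:
        raise ValueError("model network has no PHLOEM_EXPORT role")
    x = _solve_lp(comp, -comp.c_phloem, stage="phloem maximization")
    p_star = float(comp.c_phloem @ x)
    status = "optimal"
    if flux_min:
        floor = p_star * (1 - PIN_RTOL) - 1e-12
        pin = [_row(comp, -comp.c_phloem)]
        x, status = _minimize_flux_qp(comp, pin, [-floor], engine)
        achieved = float(comp.c_phloem @ x)
        assert achieved >= p_star - PIN_RTOL * max(1.0, abs(p_star)) * 2, \
            "flux minimization degraded the phloem optimum"
    return _extract(model, comp, x, status,
                    {"phloem_max": p_star})


def minimize_water(model: DielModel, phloem_floor: float,
                   flux_min: bool = True, engine: str = "auto") -> DielSolution:
    """Stage 2: minimize daily water loss subject to a minimum daily phloem
    output (mol m-2 d-1), then minimize the flux sum at fixed (phloem, water)."""
    if not model.water_coupled:
        raise ValueError("model has no water coupling; call couple_water_loss first")
    if phloem_floor < 0:
        raise ValueError("phloem floor must be non-negative")
    comp = compile_model(model)
    if comp.c_phloem is None:
        raise ValueError("model network has no PHLOEM_EXPORT role")
    pin_p = [_row(comp, -comp.c_phloem)]
    rhs_p = [-phloem_floor * (1 - PIN_RTOL)]
    x = _solve_lp(comp, comp.c_water, pin_p, rhs_p, stage="water minimization")
    w_star = float(comp.c_water @ x)
    status = "optimal"
    if flux_min:
        pins = pin_p + [_row(comp, comp.c_water)]
        rhs = rhs_p + [w_star * (1 + PIN_RTOL) + 1e-12]
        x, status = _minimize_flux_qp(comp, pins, rhs, engine)
        assert float(comp.c_water @ x) <= w_star + PIN_RTOL * max(1.0, w_star) * 2, \
            "flux minimization degraded the water optimum"
    sol = _extract(model, comp, x, status,
                   {"phloem_floor": phloem_floor, "water_min": w_star})
    return sol


def minimize_flux(model: DielModel, phloem_floor: float | None = None,
                  water_cap: float | None = None,
                  engine: str = "auto") -> DielSolution:
    """Stage 3 on its own: minimize sum(v^2) over all step reactions and
    linkers subject to optional pinned phloem/water objectives."""
    comp = compile_model(model)
    pins, rhs = [], []
    if phloem_floor is not None:
        pins.append(_row(comp, -comp.c_phloem))
        rhs.append(-phloem_floor * (1 - PIN_RTOL))
    if water_cap is not None:
        if not model.water_coupled:
            raise ValueError("water cap requires a water-coupled model")
        pins.append(_row(comp, comp.c_water))
        rhs.append(water_cap * (1 + PIN_RTOL))
    x, status = _minimize_flux_qp(comp, pins, rhs, engine)
    return _extract(model, comp, x, status,
                    {"phloem_floor": phloem_floor, "water_cap": water_cap})


@dataclass
class ParetoPoint:
    fraction: float               # % of maximum phloem output
    phloem_output: float          # mol m-2 d-1
    water_total: float            # mol m-2 d-1
    flux_sum_l1: float
    status: str
    solution: DielSolution | None = field(default=None, repr=False)


def pareto_scan(model: DielModel, step_pct: float = 5.0,
                floor_pct: float = 20.0, flux_min: bool = True,
                keep_solutions: bool = False) -> list:
    """Trade-off frontier between productivity and water loss.

    Starts from the productivity-optimal solution (100% phloem output,
    Pareto step 1) and lowers the required output in ``step_pct`` steps down
    to ``floor_pct``, minimizing water loss at each point. Per-point solver
    failures are recorded and the scan continues.
    """
    ref = maximize_phloem(model, flux_min=False)
    p_max = ref.phloem_output
    points = []
    fractions = np.arange(100.0, floor_pct - 1e-9, -step_pct)
    for f in fractions:
        try:
            sol = minimize_water(model, p_max * f / 100.0, flux_min=flux_min)
            points.append(ParetoPoint(
                float(f), sol.phloem_output, sol.water_total, sol.flux_sum_l1,
                sol.status, sol if keep_solutions else None))
        except InfeasibleModelError as exc:
            points.append(ParetoPoint(float(f), float("nan"), float("nan"),
                                      float("nan"), f"failed: {exc}", None))
    return points
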