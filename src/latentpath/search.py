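"""MILP enumeration of latent carbon-fixation pathways.

The search asks: which sets of reactions, run in which directions, can
jointly convert 3 CO2 into 1 pyruvate at steady state while every reaction
keeps a positive thermodynamic driving force for some choice of metabolite
concentrations within physiological bounds?

Each reversible reaction is split into forward/backward arcs with binary
activity indicators z and flux variables v (0 <= v <= V z, v >= eps z,
z_fwd + z_bwd <= 1).  Driving-force constraints are linked to activity with
a big-M term,

    -(d_i dG0'_i + RT sum_j S_ji d_i x_j) >= B - M (1 - z_i),

and the objective maximises B/RT - w * sum(z): the Max-min Driving Force in
units of RT minus the (weighted) number of reactions.  A floor B >= eps_B
restricts the search to thermodynamically feasible pathways, so the
integer-cut iteration walks exactly the positive-MDF solution space and
terminates at infeasibility.  Currency pseudo-reactions carry flux freely:
no indicator, no thermodynamic constraint, no contribution to pathway size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, linprog, milp

from .network import MetabolicNetwork, Reaction
from .thermo import (
    ConcentrationBounds,
    DrivingForceResult,
    ThermoParams,
    compute_mdf,
)

__all__ = [
    "PathwayQuery",
    "SearchOptions",
    "CandidatePathway",
    "SearchError",
    "enumerate_pathways",
    "pareto_front",
    "remove_oxygen_sensitive",
    "net_conversion",
    "atp_cost",
    "solve_support_fluxes",
    "DEFAULT_ATP_ACCOUNTING",
]


class SearchError(RuntimeError):
    pass


@dataclass(frozen=True)
class PathwayQuery:
    """Net conversion the pathway must achieve (default 3 CO2 -> 1 pyruvate)."""

    substrate: str = "co2_c"
    substrate_moles: float = 3.0
    product: str = "pyr_c"
    product_moles: float = 1.0

    def __post_init__(self) -> None:
        if self.substrate == self.product:
            raise ValueError("substrate and product must differ")
        if self.substrate_moles <= 0 or self.product_moles <= 0:
            raise ValueError("query moles must be positive")


@dataclass(frozen=True)
class SearchOptions:
    """MILP shape parameters.

    ``weight`` trades MDF (in RT units) against pathway size; ``big_m`` must
    exceed any attainable |dG'| (2000 kJ/mol is far above the vendored
    energies plus the maximal concentration term); ``min_flux`` forces every
    active arc to carry flux so supports equal flux supports; ``min_mdf`` is
    the positivity floor on B.
    """

    weight: float = 1.0
    big_m: float = 2000.0
    flux_cap: float = 1000.0
    min_flux: float = 1e-3
    min_mdf: float = 1e-4
    mip_gap: float = 1e-6
    time_limit: float | None = None


@dataclass
class CandidatePathway:
    """A directed reaction subset with fluxes scaled to 1 mole of product."""

    support: list[tuple[str, int]]  # (reaction id, +1/-1), sorted by id
    fluxes: dict[str, float]  # reaction id -> signed flux (+ = forward)
    net_conversion: dict[str, float]
    mdf: float
    n_reactions: int
    bottleneck_ids: list[str] = field(default_factory=list)

    @property
    def support_ids(self) -> frozenset[str]:
        return frozenset(rid for rid, _ in self.support)

    def directed_support(self) -> frozenset[tuple[str, int]]:
        return frozenset(self.support)

    def to_record(self) -> dict:
        return {
            "support": [[rid, d] for rid, d in self.support],
            "fluxes": {k: round(v, 9) for k, v in sorted(self.fluxes.items())},
            "net_conversion": {k: round(v, 9) for k, v in sorted(self.net_conversion.items())},
            "mdf_kj_mol": round(self.mdf, 6),
            "n_reactions": self.n_reactions,
        }


# ---------------------------------------------------------------------------
# Problem assembly
# ---------------------------------------------------------------------------


class _Problem:
    """Index bookkeeping shared by the MILP and the support-flux LPs."""

    def __init__(
        self,
        net: MetabolicNetwork,
        query: PathwayQuery,
        bounds: ConcentrationBounds,
        params: ThermoParams,
        options: SearchOptions,
    ):
        from .thermo import _is_excluded  # convention: no x for H2O / H+

        self.net = net
        self.query = query
        self.bounds = bounds
        self.params = params
        self.options = options

        self.real = [r for r in net.reactions if not r.pseudo]
        self.pseudo = [r for r in net.reactions if r.pseudo]
        for target in (query.substrate, query.product):
            if target not in net._met_index:
                raise SearchError(f"query species {target!r} not in network")
        missing_dg = [r.id for r in self.real if r.dg0_prime is None]
        if missing_dg:
            raise SearchError(f"reactions without dG'0: {missing_dg}")

        # arcs: (reaction index, direction)
        self.arcs: list[tuple[int, int]] = []
        for i, _ in enumerate(self.real):
            self.arcs.append((i, +1))
            self.arcs.append((i, -1))
        self.n_arc = len(self.arcs)
        self.n_pseudo = len(self.pseudo)

        # free species: anything a pseudo-reaction touches
        self.free_species = {m for r in self.pseudo for m in r.stoichiometry}
        self.met_ids = sorted(
            {m for r in self.real + self.pseudo for m in r.stoichiometry}
            | {query.substrate, query.product}
        )
        self.met_row = {m: i for i, m in enumerate(self.met_ids)}

        self.x_ids = sorted(
            {m for r in self.real for m in r.stoichiometry if not _is_excluded(m)}
        )
        self.x_col = {m: i for i, m in enumerate(self.x_ids)}

        self.b = np.zeros(len(self.met_ids))
        self.b[self.met_row[query.substrate]] = -query.substrate_moles
        self.b[self.met_row[query.product]] = query.product_moles

    def balance_matrix(self) -> tuple[sparse.csr_matrix, sparse.csr_matrix]:
        """(S over arcs, S over pseudo columns)."""
        rows, cols, vals = [], [], []
        for a, (ri, d) in enumerate(self.arcs):
            for m, coef in self.real[ri].stoichiometry.items():
                rows.append(self.met_row[m])
                cols.append(a)
                vals.append(d * coef)
        S_arc = sparse.csr_matrix(
            (vals, (rows, cols)), shape=(len(self.met_ids), self.n_arc)
        )
        rows, cols, vals = [], [], []
        for p, r in enumerate(self.pseudo):
            for m, coef in r.stoichiometry.items():
                rows.append(self.met_row[m])
                cols.append(p)
                vals.append(coef)
        S_pse = sparse.csr_matrix(
            (vals, (rows, cols)), shape=(len(self.met_ids), self.n_pseudo)
        )
        return S_arc, S_pse


def _solve_milp(prob: _Problem, cuts: list[list[int]]):
    """One MILP solve; returns (support arcs, arc fluxes) or None if infeasible."""
    opt = prob.options
    rt = prob.params.rt
    A, P, X = prob.n_arc, prob.n_pseudo, len(prob.x_ids)
    # variable layout: [v (A), z (A), w (P), x (X), B]
    n_var = 2 * A + P + X + 1
    iv, iz, iw, ix, iB = (
        0,
        A,
        2 * A,
        2 * A + P,
        2 * A + P + X,
    )

    S_arc, S_pse = prob.balance_matrix()
    blocks = []

    # mass balance (equality)
    M_bal = sparse.hstack(
        [
            S_arc,
            sparse.csr_matrix((len(prob.met_ids), A)),
            S_pse,
            sparse.csr_matrix((len(prob.met_ids), X + 1)),
        ]
    )
    blocks.append(LinearConstraint(M_bal, prob.b, prob.b))

    # v - V z <= 0 and eps z - v <= 0
    eye = sparse.eye(A, format="csr")
    zero_tail = sparse.csr_matrix((A, P + X + 1))
    cap = sparse.hstack([eye, -opt.flux_cap * eye, zero_tail])
    blocks.append(LinearConstraint(cap, -np.inf, 0.0))
    floor = sparse.hstack([-eye, opt.min_flux * eye, zero_tail])
    blocks.append(LinearConstraint(floor, -np.inf, 0.0))

    # z_fwd + z_bwd <= 1 per reaction
    R = len(prob.real)
    rows, cols = [], []
    for a, (ri, _) in enumerate(prob.arcs):
        rows.append(ri)
        cols.append(iz + a)
    pair = sparse.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(R, n_var))
    blocks.append(LinearConstraint(pair, -np.inf, 1.0))

    # thermo linking: d*RT*S.x + B + M z <= M - d*dG0
    rows, cols, vals = [], [], []
    rhs = np.zeros(A)
    for a, (ri, d) in enumerate(prob.arcs):
        r = prob.real[ri]
        for m, coef in r.stoichiometry.items():
            if m in prob.x_col:
                rows.append(a)
                cols.append(ix + prob.x_col[m])
                vals.append(d * rt * coef)
        rows.append(a)
        cols.append(iB)
        vals.append(1.0)
        rows.append(a)
        cols.append(iz + a)
        vals.append(opt.big_m)
        rhs[a] = opt.big_m - d * r.dg0_prime
    thermo = sparse.csr_matrix((vals, (rows, cols)), shape=(A, n_var))
    blocks.append(LinearConstraint(thermo, -np.inf, rhs))

    # integer cuts
    for support_arcs in cuts:
        row = np.zeros(n_var)
        row[[iz + a for a in support_arcs]] = 1.0
        blocks.append(LinearConstraint(row, -np.inf, len(support_arcs) - 1))

    lb = np.zeros(n_var)
    ub = np.full(n_var, np.inf)
    ub[iv : iv + A] = opt.flux_cap
    ub[iz : iz + A] = 1.0
    lb[iw : iw + P] = -opt.flux_cap
    ub[iw : iw + P] = opt.flux_cap
    for m, j in prob.x_col.items():
        clb, cub = prob.bounds.range_for(m)
        lb[ix + j] = math.log(clb)
        ub[ix + j] = math.log(cub)
    lb[iB] = opt.min_mdf
    ub[iB] = 1000.0

    c = np.zeros(n_var)
    c[iB] = -1.0 / rt
    c[iz : iz + A] = opt.weight

    integrality = np.zeros(n_var)
    integrality[iz : iz + A] = 1

    milp_options = {"mip_rel_gap": prob.options.mip_gap}
    if opt.time_limit is not None:
        milp_options["time_limit"] = opt.time_limit
    res = milp(
        c,
        constraints=blocks,
        integrality=integrality,
        bounds=Bounds(lb, ub),
        options=milp_options,
    )
    if res.status != 0 or res.x is None:
        return None
    z = res.x[iz : iz + A]
    v = res.x[iv : iv + A]
    support_arcs = [a for a in range(A) if z[a] > 0.5]
    return support_arcs, {a: float(v[a]) for a in support_arcs}


def _pathway_from_support(
    prob: _Problem, support_arcs: Sequence[int], arc_flux: Mapping[int, float]
) -> CandidatePathway:
    support = sorted(
        ((prob.real[ri].id, d) for ri, d in (prob.arcs[a] for a in support_arcs))
    )
    fluxes = {}
    for a in support_arcs:
        ri, d = prob.arcs[a]
        fluxes[prob.real[ri].id] = d * arc_flux[a]

    conv: dict[str, float] = {}
    for rid, v in fluxes.items():
        r = prob.net.reaction(rid)
        for m, coef in r.stoichiometry.items():
            conv[m] = conv.get(m, 0.0) + coef * v
    conv = {
        m: round(val, 9)
        for m, val in conv.items()
        if m not in prob.free_species and abs(val) > 1e-6
    }

    directed = [(prob.net.reaction(rid), d) for rid, d in support]
    mdf_res = compute_mdf(directed, bounds=prob.bounds, params=prob.params)
    return CandidatePathway(
        support=support,
        fluxes=fluxes,
        net_conversion=conv,
        mdf=mdf_res.mdf,
        n_reactions=len(support),
        bottleneck_ids=mdf_res.bottleneck_ids,
    )


def enumerate_pathways(
    net: MetabolicNetwork,
    query: PathwayQuery | None = None,
    bounds: ConcentrationBounds | None = None,
    params: ThermoParams | None = None,
    max_solutions: int = 20,
    exclude_oxygen_sensitive: bool = False,
    options: SearchOptions | None = None,
) -> list[CandidatePathway]:
    """Iterate the positive-MDF pathway space with integer cuts.

    The network should already be pruned to cytoplasmic reactions and
    augmented with currency pseudo-reactions (for networks that use currency
    metabolites).  Returns pathways in the order found; under the positivity
    floor on B the iteration yields exactly the inclusion-minimal directed
    supports whose exact MDF is positive.
    """
    query = query or PathwayQuery()
    params = params or ThermoParams()
    bounds = bounds if bounds is not None else ConcentrationBounds.physiological(params)
    options = options or SearchOptions()
    if exclude_oxygen_sensitive:
        net = remove_oxygen_sensitive(net)

    prob = _Problem(net, query, bounds, params, options)
    found: list[CandidatePathway] = []
    cuts: list[list[int]] = []
    while len(found) < max_solutions:
        sol = _solve_milp(prob, cuts)
        if sol is None:
            break
        support_arcs, arc_flux = sol
        if not support_arcs:
            break
        pathway = _pathway_from_support(prob, support_arcs, arc_flux)
        cuts.append(list(support_arcs))
        if pathway.mdf <= 1e-6:
            # big-M slack abuse guard: exact LP disagrees with embedded MDF
            break
        found.append(pathway)
    return found


# ---------------------------------------------------------------------------
# Post-processing
# ---------------------------------------------------------------------------


def pareto_front(pathways: Sequence[CandidatePathway]) -> list[CandidatePathway]:
    """Non-dominated subset under (maximise MDF, minimise reaction count).

    p dominates q when p.mdf >= q.mdf and p.n_reactions <= q.n_reactions with
    at least one strict; exact ties on both coordinates are all kept.
    """
    front = []
    for p in pathways:
        dominated = False
        for q in pathways:
            if q is p:
                continue
            if (
                q.mdf >= p.mdf
                and q.n_reactions <= p.n_reactions
                and (q.mdf > p.mdf or q.n_reactions < p.n_reactions)
            ):
                dominated = True
                break
        if not dominated:
            front.append(p)
    return front


def remove_oxygen_sensitive(net: MetabolicNetwork) -> MetabolicNetwork:
    """Copy of the network without oxygen-sensitive reactions (PFL, OBTFL)."""
    keep = [r for r in net.reactions if not r.oxygen_sensitive]
    return MetabolicNetwork(list(net.metabolites), keep, net.provenance + "+anox")


def net_conversion(
    pathway: CandidatePathway,
    net: MetabolicNetwork,
    free_species: set[str] | None = None,
    tol: float = 1e-6,
) -> dict[str, float]:
    """S.v restricted to non-free species; checks internal steady state.

    Raises if any species that is neither free nor part of the declared net
    conversion carries a non-zero balance.
    """
    if free_species is None:
        free_species = {
            m for r in net.reactions if r.pseudo for m in r.stoichiometry
        }
    conv: dict[str, float] = {}
    for rid, v in pathway.fluxes.items():
        for m, coef in net.reaction(rid).stoichiometry.items():
            conv[m] = conv.get(m, 0.0) + coef * v
    result = {}
    for m, val in conv.items():
        if m in free_species:
            continue
        if abs(val) > tol:
            result[m] = round(val, 9)
    stray = sorted(set(result) - set(pathway.net_conversion))
    if stray:
        raise SearchError(f"non-steady internal species: {stray}")
    return result


#: ATP-equivalent weights: one phosphoanhydride bond per ATP->ADP step, two
#: for ATP->AMP (PPi-releasing) steps.
DEFAULT_ATP_ACCOUNTING = {"ATP->ADP": 1.0, "ATP->AMP": 2.0}


def atp_cost(
    pathway: CandidatePathway,
    net: MetabolicNetwork,
    accounting: Mapping[str, float] | None = None,
    atp_base: str = "atp",
    adp_base: str = "adp",
    amp_base: str = "amp",
) -> float:
    """ATP equivalents consumed per mole of product (substrate-level
    phosphorylation credited).

    With weights w1 = ATP->ADP and w2 = ATP->AMP, a reaction consuming a mol
    ATP and producing m mol AMP per unit flux costs  w1*a + (w2-w1)*m :
    PEP synthetase (ATP -> AMP + Pi) counts double, kinases count once, and
    ATP-producing steps count negative.
    """
    from .network import split_compartment

    table = dict(accounting or DEFAULT_ATP_ACCOUNTING)
    for key in ("ATP->ADP", "ATP->AMP"):
        if key not in table:
            raise SearchError(f"cofactor conversion {key!r} missing from accounting table")
    w1, w2 = table["ATP->ADP"], table["ATP->AMP"]

    total = 0.0
    for rid, v in pathway.fluxes.items():
        r = net.reaction(rid)
        if r.pseudo:
            continue
        d_atp = d_adp = d_amp = 0.0
        for m, coef in r.stoichiometry.items():
            base = split_compartment(m)[0]
            if base == atp_base:
                d_atp += coef * v
            elif base == adp_base:
                d_adp += coef * v
            elif base == amp_base:
                d_amp += coef * v
        if abs(d_atp + d_adp + d_amp) > 1e-9:
            raise SearchError(
                f"reaction {rid!r} converts adenylates to a cofactor not in the table"
            )
        total += -d_atp * w1 + d_amp * (w2 - w1)
    return total


# ---------------------------------------------------------------------------
# Support-constrained flux solving (shared with fixtures / oracle)
# ---------------------------------------------------------------------------


def solve_support_fluxes(
    net: MetabolicNetwork,
    support: Sequence[tuple[str, int]],
    query: PathwayQuery | None = None,
    min_flux: float = 1e-3,
    flux_cap: float = 1000.0,
) -> dict[str, float] | None:
    """Fluxes achieving the query's net conversion on a directed support.

    Every support reaction must carry flux >= ``min_flux`` in its stated
    direction; currency pseudo-reactions in the network flow freely.  Returns
    signed fluxes (positive = forward as written) scaled to the query, or
    None if the support cannot achieve the conversion.  Minimises total flux,
    so the returned solution is the canonical (vertex) flux pattern.
    """
    query = query or PathwayQuery()
    pseudo = [r for r in net.reactions if r.pseudo]
    sup_rxns = [(net.reaction(rid), d) for rid, d in support]
    met_ids = sorted(
        {m for r, _ in sup_rxns for m in r.stoichiometry}
        | {m for r in pseudo for m in r.stoichiometry}
        | {query.substrate, query.product}
    )
    row = {m: i for i, m in enumerate(met_ids)}
    n_s, n_p = len(sup_rxns), len(pseudo)
    A_eq = np.zeros((len(met_ids), n_s + n_p))
    for j, (r, d) in enumerate(sup_rxns):
        for m, coef in r.stoichiometry.items():
            A_eq[row[m], j] = d * coef
    for j, r in enumerate(pseudo):
        for m, coef in r.stoichiometry.items():
            A_eq[row[m], n_s + j] = coef
    b_eq = np.zeros(len(met_ids))
    b_eq[row[query.substrate]] = -query.substrate_moles
    b_eq[row[query.product]] = query.product_moles

    c = np.concatenate([np.ones(n_s), np.zeros(n_p)])
    var_bounds = [(min_flux, flux_cap)] * n_s + [(-flux_cap, flux_cap)] * n_p
    res = linprog(c, A_eq=A_eq, b_eq=b_eq, bounds=var_bounds, method="highs")
    if not res.success:
        return None
    return {
        r.id: d * float(res.x[j]) for j, (r, d) in enumerate(sup_rxns)
    }


def build_pathway(
    net: MetabolicNetwork,
    support: Sequence[tuple[str, int]],
    query: PathwayQuery | None = None,
    bounds: ConcentrationBounds | None = None,
    params: ThermoParams | None = None,
) -> CandidatePathway:
    """Assemble a CandidatePathway for a known directed support.

    Solves for fluxes (scaled to 1 mole of product), evaluates the exact MDF,
    and computes the net conversion.  Raises if the support cannot achieve
    the query conversion.
    """
    query = query or PathwayQuery()
    params = params or ThermoParams()
    bounds = bounds if bounds is not None else ConcentrationBounds.physiological(params)
    fluxes = solve_support_fluxes(net, support, query)
    if fluxes is None:
        raise SearchError("support cannot achieve the requested net conversion")
    free = {m for r in net.reactions if r.pseudo for m in r.stoichiometry}
    conv: dict[str, float] = {}
    for rid, v in fluxes.items():
        for m, coef in net.reaction(rid).stoichiometry.items():
            conv[m] = conv.get(m, 0.0) + coef * v
    conv = {m: round(v, 9) for m, v in conv.items() if m not in free and abs(v) > 1e-6}
    directed = [(net.reaction(rid), d) for rid, d in support]
    mdf_res = compute_mdf(directed, bounds=bounds, params=params)
    return CandidatePathway(
        support=sorted(support),
        fluxes=fluxes,
        net_conversion=conv,
        mdf=mdf_res.mdf,
        n_reactions=len(support),
        bottleneck_ids=mdf_res.bottleneck_ids,
    )
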