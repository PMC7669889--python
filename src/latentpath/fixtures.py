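"""Synthetic data: the core-metabolism fixture network, random networks for
oracle tests, and noisy kinetic assay data.

The core fixture is a desk-scale stand-in for a genome-scale *E. coli*
reconstruction: glycolysis/gluconeogenesis, the Entner-Doudoroff pathway,
the oxidative and non-oxidative pentose phosphate pathway, pentose uptake,
fermentation sinks and a lumped respiratory chain, with optional
phosphoribulokinase/Rubisco and an optional compact TCA arm.  Every
metabolite carries a carbon count (acyl-only convention for thioesters) and
every internal reaction a vendored transformed standard Gibbs energy, so the
whole analysis (search, MDF, FBA, labeling) runs with no downloads.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np

from .kinetics import KineticParams, mm_rate
from .network import (
    DEFAULT_CURRENCY_IDS,
    MetabolicNetwork,
    Metabolite,
    NetworkError,
    Reaction,
    parse_equation,
    split_compartment,
)

__all__ = [
    "FixtureSpec",
    "build_core_model",
    "load_dg0_table",
    "random_network",
    "brute_force_enumerate",
    "synth_mm_data",
    "GED_CYCLE_SUPPORT",
    "RUBP_CYCLE_SUPPORT",
    "ged_cycle_pathway",
    "rubp_cycle_pathway",
]


@dataclass(frozen=True)
class FixtureSpec:
    include_rubp: bool = False
    include_tca: bool = False
    seed: int = 0


def load_dg0_table() -> dict[str, float]:
    """Vendored transformed standard Gibbs energies (kJ/mol) by reaction id."""
    text = (
        importlib.resources.files("latentpath").joinpath("data/dg0_prime.tsv").read_text()
    )
    table: dict[str, float] = {}
    for line in text.splitlines():
        if not line.strip() or line.startswith("#") or line.startswith("id\t"):
            continue
        fields = line.split("\t")
        table[fields[0]] = float(fields[1])
    return table


# (id, name, carbons) — cytosolic metabolites; carbons follow the acyl-only
# convention for thioesters (free CoA counts 0) and count the full adenine /
# nicotinamide skeletons for cofactors, which cancel within every reaction.
_CORE_METS = [
    ("glc__D", "D-glucose", 6),
    ("g6p", "glucose 6-phosphate", 6),
    ("f6p", "fructose 6-phosphate", 6),
    ("fdp", "fructose 1,6-bisphosphate", 6),
    ("dhap", "dihydroxyacetone phosphate", 3),
    ("g3p", "glyceraldehyde 3-phosphate", 3),
    ("13dpg", "1,3-bisphosphoglycerate", 3),
    ("3pg", "3-phosphoglycerate", 3),
    ("2pg", "2-phosphoglycerate", 3),
    ("pep", "phosphoenolpyruvate", 3),
    ("pyr", "pyruvate", 3),
    ("6pgl", "6-phosphogluconolactone", 6),
    ("6pgc", "6-phosphogluconate", 6),
    ("ru5p__D", "ribulose 5-phosphate", 5),
    ("r5p", "ribose 5-phosphate", 5),
    ("xu5p__D", "xylulose 5-phosphate", 5),
    ("e4p", "erythrose 4-phosphate", 4),
    ("s7p", "sedoheptulose 7-phosphate", 7),
    ("2ddg6p", "2-keto-3-deoxy-6-phosphogluconate", 6),
    ("xyl__D", "D-xylose", 5),
    ("xlu__D", "D-xylulose", 5),
    ("rib__D", "D-ribose", 5),
    ("lac__D", "D-lactate", 3),
    ("ac", "acetate", 2),
    ("actp", "acetyl phosphate", 2),
    ("acald", "acetaldehyde", 2),
    ("etoh", "ethanol", 2),
    ("for", "formate", 1),
    ("accoa", "acetyl-CoA (acyl carbons)", 2),
    ("coa", "coenzyme A (carrier)", 0),
    ("co2", "CO2 (dissolved)", 1),
    ("h2", "hydrogen", 0),
    ("o2", "oxygen", 0),
    ("nh4", "ammonium", 0),
    ("h", "proton", 0),
    ("h2o", "water", 0),
    ("pi", "phosphate", 0),
    ("atp", "ATP", 10),
    ("adp", "ADP", 10),
    ("amp", "AMP", 10),
    ("nad", "NAD+", 21),
    ("nadh", "NADH", 21),
    ("nadp", "NADP+", 21),
    ("nadph", "NADPH", 21),
]

_RUBP_METS = [("rubp", "ribulose 1,5-bisphosphate", 5)]

_TCA_METS = [
    ("oaa", "oxaloacetate", 4),
    ("cit", "citrate", 6),
    ("icit", "isocitrate", 6),
    ("akg", "2-oxoglutarate", 5),
    ("succoa", "succinyl-CoA (acyl carbons)", 4),
    ("succ", "succinate", 4),
    ("fum", "fumarate", 4),
    ("mal__L", "L-malate", 4),
]

_EXTERNAL_METS = ["glc__D", "xyl__D", "rib__D", "lac__D", "ac", "etoh", "for", "co2", "h2"]

# (id, equation on cytosolic metabolites, reversible, oxygen_sensitive)
_CORE_RXNS = [
    ("HEX1", "glc__D_c + atp_c -> g6p_c + adp_c + h_c", False, False),
    ("PGI", "g6p_c <-> f6p_c", True, False),
    ("PFK", "f6p_c + atp_c -> fdp_c + adp_c + h_c", False, False),
    ("FBP", "fdp_c + h2o_c -> f6p_c + pi_c", False, False),
    ("FBA", "fdp_c <-> dhap_c + g3p_c", True, False),
    ("TPI", "dhap_c <-> g3p_c", True, False),
    ("GAPD", "g3p_c + nad_c + pi_c <-> 13dpg_c + nadh_c + h_c", True, False),
    ("PGK", "13dpg_c + adp_c <-> 3pg_c + atp_c", True, False),
    ("PGM", "3pg_c <-> 2pg_c", True, False),
    ("ENO", "2pg_c <-> pep_c + h2o_c", True, False),
    ("PYK", "pep_c + adp_c + h_c -> pyr_c + atp_c", False, False),
    ("PPS", "pyr_c + atp_c + h2o_c -> pep_c + amp_c + pi_c + 2 h_c", False, False),
    ("ZWF", "g6p_c + nadp_c <-> 6pgl_c + nadph_c + h_c", True, False),
    ("PGL", "6pgl_c + h2o_c -> 6pgc_c + h_c", False, False),
    ("GND", "6pgc_c + nadp_c -> ru5p__D_c + co2_c + nadph_c", False, False),
    ("RPI", "r5p_c <-> ru5p__D_c", True, False),
    ("RPE", "ru5p__D_c <-> xu5p__D_c", True, False),
    ("TKT1", "r5p_c + xu5p__D_c <-> g3p_c + s7p_c", True, False),
    ("TALA", "g3p_c + s7p_c <-> e4p_c + f6p_c", True, False),
    ("TKT2", "e4p_c + xu5p__D_c <-> f6p_c + g3p_c", True, False),
    ("EDD", "6pgc_c -> 2ddg6p_c + h2o_c", False, False),
    ("EDA", "2ddg6p_c <-> g3p_c + pyr_c", True, False),
    ("XYLI", "xyl__D_c <-> xlu__D_c", True, False),
    ("XYLK", "xlu__D_c + atp_c -> xu5p__D_c + adp_c + h_c", False, False),
    ("RBK", "rib__D_c + atp_c -> r5p_c + adp_c + h_c", False, False),
    ("LDH_D", "pyr_c + nadh_c + h_c <-> lac__D_c + nad_c", True, False),
    ("PDH", "pyr_c + coa_c + nad_c -> accoa_c + co2_c + nadh_c", False, False),
    ("PFL", "pyr_c + coa_c -> accoa_c + for_c", False, True),
    ("PTAr", "accoa_c + pi_c <-> actp_c + coa_c", True, False),
    ("ACKr", "actp_c + adp_c <-> ac_c + atp_c", True, False),
    ("ACALD", "acald_c + coa_c + nad_c <-> accoa_c + nadh_c + h_c", True, False),
    ("ALCD2x", "etoh_c + nad_c <-> acald_c + nadh_c + h_c", True, False),
    ("STHD", "nadh_c + nadp_c <-> nad_c + nadph_c", True, False),
    ("ADK1", "amp_c + atp_c <-> 2 adp_c", True, False),
    ("ATPM", "atp_c + h2o_c -> adp_c + pi_c + h_c", False, False),
    (
        "OXPHOS",
        "nadh_c + 0.5 o2_c + 2 adp_c + 2 pi_c + 3 h_c -> nad_c + 2 atp_c + 3 h2o_c",
        False,
        False,
    ),
    ("H2DH", "h2_c + nad_c -> nadh_c + h_c", False, False),
]

_RUBP_RXNS = [
    ("PRK", "ru5p__D_c + atp_c -> rubp_c + adp_c + h_c", False, False),
    ("RBPC", "rubp_c + co2_c + h2o_c -> 2 3pg_c + 2 h_c", False, False),
]

_TCA_RXNS = [
    ("CS", "accoa_c + oaa_c + h2o_c -> cit_c + coa_c + h_c", False, False),
    ("ACONT", "cit_c <-> icit_c", True, False),
    ("ICDHyr", "icit_c + nadp_c <-> akg_c + co2_c + nadph_c", True, False),
    ("AKGDH", "akg_c + coa_c + nad_c -> succoa_c + co2_c + nadh_c", False, False),
    ("SUCOAS", "succoa_c + adp_c + pi_c <-> succ_c + atp_c + coa_c", True, False),
    ("SUCD", "succ_c + nad_c <-> fum_c + nadh_c", True, False),
    ("FUM", "fum_c + h2o_c <-> mal__L_c", True, False),
    ("MDH", "mal__L_c + nad_c <-> oaa_c + nadh_c + h_c", True, False),
    ("PPC", "pep_c + co2_c + h2o_c -> oaa_c + pi_c + h_c", False, False),
]


def build_core_model(spec: FixtureSpec | None = None) -> MetabolicNetwork:
    """Construct the curated core-metabolism fixture network.

    Deterministic for a fixed spec: the returned network (and its serialized
    form) is identical across runs.
    """
    spec = spec or FixtureSpec()
    dg0 = load_dg0_table()

    met_rows = list(_CORE_METS)
    if spec.include_rubp:
        met_rows += _RUBP_METS
    if spec.include_tca:
        met_rows += _TCA_METS

    mets = [
        Metabolite(
            id=f"{base}_c",
            name=name,
            carbon_count=carbons,
            compartment="c",
            is_currency=base in DEFAULT_CURRENCY_IDS,
        )
        for base, name, carbons in met_rows
    ]
    ext_names = {base: name for base, name, _ in met_rows}
    ext_carbons = {base: c for base, _, c in met_rows}
    mets += [
        Metabolite(
            id=f"{base}_e",
            name=ext_names[base],
            carbon_count=ext_carbons[base],
            compartment="e",
            is_currency=base in DEFAULT_CURRENCY_IDS,
        )
        for base in _EXTERNAL_METS
    ]

    rxn_rows = list(_CORE_RXNS)
    if spec.include_rubp:
        rxn_rows += _RUBP_RXNS
    if spec.include_tca:
        rxn_rows += _TCA_RXNS

    rxns = []
    for rid, eq, reversible, o2_sensitive in rxn_rows:
        rxns.append(
            Reaction(
                id=rid,
                stoichiometry=parse_equation(eq),
                dg0_prime=dg0[rid],
                oxygen_sensitive=o2_sensitive,
                lower_bound=-1000.0 if reversible else 0.0,
                upper_bound=1000.0,
                notes="fixture core model",
            )
        )
    # transports (uniport, transport energetics neglected at desk scale)
    for base in _EXTERNAL_METS:
        rxns.append(
            Reaction(
                id=f"{base.upper().replace('__D', '')}t",
                stoichiometry={f"{base}_e": -1.0, f"{base}_c": 1.0},
                dg0_prime=0.0,
                is_transport=True,
                notes="uniport",
            )
        )
    # exchanges: positive flux = secretion
    for base in _EXTERNAL_METS:
        rxns.append(
            Reaction(
                id=f"EX_{base}_e",
                stoichiometry={f"{base}_e": -1.0},
                is_exchange=True,
            )
        )
    for base in ("h", "h2o", "o2", "pi"):
        rxns.append(
            Reaction(
                id=f"EX_{base}_c",
                stoichiometry={f"{base}_c": -1.0},
                is_exchange=True,
            )
        )
    return MetabolicNetwork(
        mets,
        rxns,
        provenance=f"fixture-core(include_rubp={spec.include_rubp},"
        f"include_tca={spec.include_tca})",
    )


# ---------------------------------------------------------------------------
# Canonical fixture pathways
# ---------------------------------------------------------------------------

#: The GED cycle on the fixture: reductive carboxylation of Ru5P by Gnd
#: (reverse of the oxidative decarboxylation as written), the ED pathway,
#: gluconeogenesis through PEP synthetase, and pentose-phosphate regeneration.
GED_CYCLE_SUPPORT: tuple[tuple[str, int], ...] = (
    ("GND", -1),
    ("EDD", +1),
    ("EDA", +1),
    ("PPS", +1),
    ("ENO", -1),
    ("PGM", -1),
    ("PGK", -1),
    ("GAPD", -1),
    ("TPI", -1),
    ("FBA", -1),
    ("FBP", +1),
    ("TKT2", -1),
    ("TALA", -1),
    ("TKT1", -1),
    ("RPE", -1),
    ("RPI", +1),
)

#: The RuBP (Calvin-Benson) cycle on the fixture with PRK + Rubisco, producing
#: pyruvate through lower glycolysis.
RUBP_CYCLE_SUPPORT: tuple[tuple[str, int], ...] = (
    ("PRK", +1),
    ("RBPC", +1),
    ("PGK", -1),
    ("GAPD", -1),
    ("TPI", -1),
    ("FBA", -1),
    ("FBP", +1),
    ("TKT2", -1),
    ("TALA", -1),
    ("TKT1", -1),
    ("RPE", -1),
    ("RPI", +1),
    ("PGM", +1),
    ("ENO", +1),
    ("PYK", +1),
)


def _prepared(net: MetabolicNetwork) -> MetabolicNetwork:
    from .network import add_currency_exchanges, prune_for_search

    return add_currency_exchanges(prune_for_search(net))


def ged_cycle_pathway(net: MetabolicNetwork | None = None):
    """CandidatePathway for the fixture GED cycle (fluxes per 1 mol pyruvate)."""
    from .search import build_pathway

    net = net if net is not None else build_core_model()
    return build_pathway(_prepared(net), GED_CYCLE_SUPPORT)


def rubp_cycle_pathway(net: MetabolicNetwork | None = None):
    """CandidatePathway for the fixture RuBP cycle (requires include_rubp)."""
    from .search import build_pathway

    net = net if net is not None else build_core_model(FixtureSpec(include_rubp=True))
    return build_pathway(_prepared(net), RUBP_CYCLE_SUPPORT)


# ---------------------------------------------------------------------------
# Random networks + brute-force oracle
# ---------------------------------------------------------------------------


def random_network(
    n_metabolites: int = 6,
    n_reactions: int = 8,
    seed: int = 0,
    plant_route: bool = True,
    max_attempts: int = 1000,
) -> MetabolicNetwork:
    """Connected random carbon-balanced network for oracle tests.

    Metabolite ``sub`` (1 carbon) and ``prod`` (3 carbons) play the roles of
    CO2 and pyruvate; a simple balanced route 3 sub -> i0 -> ... -> prod is
    planted in half of the construction space (``plant_route``) so that
    feasible instances are common.  Coefficients are integers in {-2..2};
    random dG'0 values are drawn uniformly from [-40, 40] kJ/mol.  Currency
    metabolites are avoided entirely.  Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    for _ in range(max_attempts):
        net = _try_random_network(rng, n_metabolites, n_reactions, plant_route)
        if net is not None:
            return net
    raise NetworkError("could not construct a connected random network")


def _try_random_network(rng, n_metabolites, n_reactions, plant_route):
    carbons = {"sub": 1, "prod": 3}
    inner = [f"m{i}" for i in range(max(0, n_metabolites - 2))]
    for m in inner:
        carbons[m] = int(rng.integers(1, 5))
    ids = ["sub", "prod"] + inner

    rxns: list[Reaction] = []

    def add(stoich: dict[str, float]) -> None:
        rxns.append(
            Reaction(
                id=f"R{len(rxns)}",
                stoichiometry=stoich,
                dg0_prime=float(rng.uniform(-40.0, 40.0)),
            )
        )

    if plant_route and inner:
        chain = [inner[i] for i in rng.choice(len(inner), size=min(2, len(inner)), replace=False)]
        for m in chain:
            carbons[m] = 3
        add({"sub": -3.0, chain[0]: 1.0})
        prev = chain[0]
        for m in chain[1:]:
            add({prev: -1.0, m: 1.0})
            prev = m
        add({prev: -1.0, "prod": 1.0})

    attempts = 0
    while len(rxns) < n_reactions and attempts < 500:
        attempts += 1
        k = int(rng.integers(2, 5))
        members = [ids[i] for i in rng.choice(len(ids), size=min(k, len(ids)), replace=False)]
        coefs = rng.integers(-2, 3, size=len(members))
        if np.any(coefs == 0):
            continue
        if sum(c * carbons[m] for m, c in zip(members, coefs)) != 0:
            continue
        stoich = {m: float(c) for m, c in zip(members, coefs)}
        if all(v > 0 for v in stoich.values()) or all(v < 0 for v in stoich.values()):
            continue
        add(stoich)
    if len(rxns) < n_reactions:
        return None

    # connectivity over the metabolite-reaction bipartite graph
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(ids)
    for r in rxns:
        members = list(r.stoichiometry)
        for a, b in zip(members, members[1:]):
            g.add_edge(a, b)
    used = {m for r in rxns for m in r.stoichiometry}
    if not {"sub", "prod"} <= used:
        return None
    if not nx.has_path(g, "sub", "prod"):
        return None

    mets = [
        Metabolite(id=m, name=m, carbon_count=carbons[m], compartment="c")
        for m in ids
        if m in used
    ]
    return MetabolicNetwork(mets, rxns, provenance="random")


def brute_force_enumerate(
    net: MetabolicNetwork,
    query=None,
    bounds=None,
    params=None,
    min_mdf: float = 1e-4,
    max_reactions: int = 12,
):
    """Independent oracle: exhaustive subset search for minimal pathways.

    Every reaction subset is tested for a steady-state flux achieving the net
    conversion (one small LP per subset, skipping known supersets); for each
    inclusion-minimal feasible subset all direction patterns are enumerated
    and the exact MDF evaluated.  Returns CandidatePathways for every minimal
    directed support with MDF above ``min_mdf`` — the same family the MILP
    iteration walks.
    """
    from .search import PathwayQuery, build_pathway, solve_support_fluxes

    query = query or PathwayQuery(substrate="sub", product="prod")
    real = [r for r in net.reactions if not r.pseudo]
    n = len(real)
    if n > max_reactions:
        raise NetworkError(f"brute force capped at {max_reactions} reactions (got {n})")

    feasible_masks: list[int] = []

    def undirected_feasible(mask: int) -> bool:
        support = [(real[i].id, +1) for i in range(n) if mask >> i & 1]
        # allow either direction: solve with free signs by trying min_flux=0
        # on both arcs — equivalent LP: signed fluxes, no direction floor
        return _subset_feasible(net, [real[i] for i in range(n) if mask >> i & 1], query)

    masks_by_size = sorted(range(1, 1 << n), key=lambda m: bin(m).count("1"))
    for mask in masks_by_size:
        if any((mask & fm) == fm for fm in feasible_masks):
            continue  # superset of a feasible subset: feasible, not minimal
        if undirected_feasible(mask):
            feasible_masks.append(mask)

    pathways = []
    for mask in feasible_masks:
        idx = [i for i in range(n) if mask >> i & 1]
        for pattern in range(1 << len(idx)):
            support = [
                (real[i].id, +1 if pattern >> k & 1 else -1) for k, i in enumerate(idx)
            ]
            fluxes = solve_support_fluxes(net, support, query)
            if fluxes is None:
                continue
            p = build_pathway(net, support, query, bounds=bounds, params=params)
            if p.mdf > min_mdf:
                pathways.append(p)
    return pathways


def _subset_feasible(net: MetabolicNetwork, rxns: list[Reaction], query) -> bool:
    from scipy.optimize import linprog

    pseudo = [r for r in net.reactions if r.pseudo]
    cols = rxns + pseudo
    met_ids = sorted(
        {m for r in cols for m in r.stoichiometry} | {query.substrate, query.product}
    )
    row = {m: i for i, m in enumerate(met_ids)}
    A_eq = np.zeros((len(met_ids), len(cols)))
    for j, r in enumerate(cols):
        for m, coef in r.stoichiometry.items():
            A_eq[row[m], j] = coef
    b_eq = np.zeros(len(met_ids))
    b_eq[row[query.substrate]] = -query.substrate_moles
    b_eq[row[query.product]] = query.product_moles
    res = linprog(
        np.zeros(len(cols)),
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=[(-1000.0, 1000.0)] * len(cols),
        method="highs",
    )
    return bool(res.success)


# ---------------------------------------------------------------------------
# Synthetic kinetic assays
# ---------------------------------------------------------------------------


def synth_mm_data(
    params: KineticParams, n: int = 15, noise_cv: float = 0.05, seed: int = 0
):
    """Noisy Michaelis-Menten assay points on a log-spaced substrate grid.

    Substrate concentrations span [KM/10, 10 KM]; rates are the true curve
    perturbed by multiplicative Gaussian noise of the given CV.  Emulates a
    15-point assay design with triplicate-scale noise.
    """
    from .kinetics import AssayPoint

    if n < 4:
        raise ValueError("need at least 4 assay points")
    rng = np.random.default_rng(seed)
    s = np.geomspace(params.km / 10.0, params.km * 10.0, n)
    v = np.array([mm_rate(si, params) for si in s])
    v = v * (1.0 + rng.normal(0.0, noise_cv, size=n))
    return [AssayPoint(substrate_conc=float(si), rate=float(vi)) for si, vi in zip(s, v)]
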