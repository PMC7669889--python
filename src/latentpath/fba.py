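"""Flux balance analysis of pathway variants in non-growing cells.

Maximal product yields are computed by a direct LP over the network data
model: maximise product secretion subject to steady state, reaction bounds,
a fixed substrate uptake rate, and a fixed non-growth ATP maintenance flux.
Model curations (proton stoichiometry of transhydrogenase, removal of
disputed or unrealistic reactions, conditional deactivation of the
oxygen-sensitive formate lyases) target the genome-scale *E. coli*
reconstruction; on desk-scale models, curations whose targets are absent are
logged and skipped.  Pathway variants reroute sugar utilisation through either the GED
shunt/cycle (Gnd made reversible) or the RuBP shunt/cycle (PRK + Rubisco
added), with the canonical glycolytic entry blocked for shunt variants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import linprog

from .network import MetabolicNetwork, Metabolite, Reaction, split_compartment

logger = logging.getLogger(__name__)

__all__ = [
    "FBAConfig",
    "VariantSpec",
    "YieldResult",
    "FBAError",
    "apply_curations",
    "make_variant",
    "max_product_yield",
    "relative_yield_table",
    "VARIANT_NAMES",
]


class FBAError(RuntimeError):
    pass


@dataclass(frozen=True)
class FBAConfig:
    """Substrate, maintenance, aeration and electron-donor settings.

    Uptake rates follow fermentative chemostat measurements (xylose 10.8,
    glucose 13.1 mmol/gDW/h); ATPM defaults to the reconstruction's
    non-growth maintenance of 6.86 mmol/gDW/h.
    """

    substrate: str = "xyl__D_e"
    uptake: float = 10.8
    product: str = "ac_e"
    atpm: float = 6.86
    aerobic: bool = False
    extra_electron_donor: str | None = None  # "h2" opens the H2 exchange

    def __post_init__(self) -> None:
        if self.uptake <= 0:
            raise FBAError("uptake must be positive")
        if self.atpm < 0:
            raise FBAError("atpm must be non-negative")


#: Canonical-entry reactions blocked in shunt variants (BiGG ids; desk-scale
#: fixture synonyms resolved at application time).
_SHUNT_BLOCKS = ("PFK", "PFK_3", "F6PA", "G6PDH2r", "FBP")
_ID_SYNONYMS = {"G6PDH2r": ("ZWF",)}

VARIANT_NAMES = ("WT", "GED_shunt", "RuBP_shunt", "GED_cycle", "RuBP_cycle")


def _rubp_additions(model: MetabolicNetwork) -> tuple[list[Metabolite], list[Reaction]]:
    """PRK + Rubisco reactions (and the RuBP metabolite if absent)."""
    mets = []
    if "rubp_c" not in model._met_index:
        mets.append(
            Metabolite(
                id="rubp_c",
                name="ribulose 1,5-bisphosphate",
                carbon_count=5,
                compartment="c",
            )
        )
    rxns = [
        Reaction(
            id="PRK",
            stoichiometry={
                "ru5p__D_c": -1.0, "atp_c": -1.0,
                "rubp_c": 1.0, "adp_c": 1.0, "h_c": 1.0,
            },
            dg0_prime=-16.0,
            lower_bound=0.0,
        ),
        Reaction(
            id="RBPC",
            stoichiometry={
                "rubp_c": -1.0, "co2_c": -1.0, "h2o_c": -1.0,
                "3pg_c": 2.0, "h_c": 2.0,
            },
            dg0_prime=-31.8,
            lower_bound=0.0,
        ),
    ]
    return mets, rxns


@dataclass(frozen=True)
class VariantSpec:
    """A named pathway variant: blocked ids, added reactions, bound changes."""

    name: str
    blocked_reactions: tuple[str, ...] = ()
    add_rubp: bool = False
    gnd_reversible: bool = False

    @classmethod
    def for_name(cls, name: str) -> "VariantSpec":
        name_map = {n.lower(): n for n in VARIANT_NAMES}
        if name.lower() not in name_map:
            raise FBAError(f"unknown variant {name!r}; expected one of {VARIANT_NAMES}")
        name = name_map[name.lower()]
        shunt = name.endswith("_shunt")
        return cls(
            name=name,
            blocked_reactions=_SHUNT_BLOCKS if shunt else (),
            add_rubp=name.startswith("RuBP"),
            gnd_reversible=name.startswith("GED"),
        )


def apply_curations(model: MetabolicNetwork) -> MetabolicNetwork:
    """Apply the eight genome-scale model curations (copy; idempotent).

    (i) transhydrogenase translocates one proton; (ii) homoserine
    dehydrogenase irreversible; (iii) GLYCK and POR5 removed; (iv) exchanges
    of Fe2+, H2S, methionine, cysteine removed; (v) threonine cleavage
    blocked (THRA, THRD, GLYAT); (vi) DRPA and PAI2T removed; (vii) GLCDpp
    removed; (viii) PFL and OBTFL flagged oxygen-sensitive (deactivated only
    under aerobic conditions at solve time).  Missing ids are logged, not
    fatal, so the same routine runs on desk-scale models.
    """
    rxns = {r.id: r for r in model.reactions}

    def warn_missing(tag: str, ids: Sequence[str]) -> list[str]:
        present = [i for i in ids if i in rxns]
        for i in ids:
            if i not in rxns:
                logger.warning("curation %s: reaction %s absent, skipped", tag, i)
        return present

    # (i) THD2pp proton stoichiometry 1 instead of 2
    for rid in warn_missing("i", ["THD2pp"]):
        r = rxns[rid]
        stoich = dict(r.stoichiometry)
        for met in list(stoich):
            if split_compartment(met)[0] == "h" and abs(stoich[met]) > 1:
                stoich[met] = float(np.sign(stoich[met]))
        rxns[rid] = replace(r, stoichiometry=stoich)
    # (ii) HSDy irreversible (aspartate-semialdehyde -> homoserine only)
    for rid in warn_missing("ii", ["HSDy"]):
        r = rxns[rid]
        rxns[rid] = replace(r, lower_bound=0.0) if r.upper_bound > 0 else replace(
            r, upper_bound=0.0
        )
    # (iii, vi, vii) removals
    for tag, ids in (("iii", ["GLYCK", "POR5"]), ("vi", ["DRPA", "PAI2T"]), ("vii", ["GLCDpp"])):
        for rid in warn_missing(tag, ids):
            del rxns[rid]
    # (iv) exchange removals
    for rid in warn_missing("iv", ["EX_fe2_e", "EX_h2s_e", "EX_met__L_e", "EX_cys__L_e"]):
        del rxns[rid]
    # (v) threonine cleavage blocked
    for rid in warn_missing("v", ["THRA", "THRD", "GLYAT"]):
        rxns[rid] = replace(rxns[rid], lower_bound=0.0, upper_bound=0.0)
    # (viii) PFL / OBTFL oxygen-sensitive flag
    for rid in warn_missing("viii", ["PFL", "OBTFL"]):
        rxns[rid] = replace(rxns[rid], oxygen_sensitive=True)

    return MetabolicNetwork(
        list(model.metabolites), list(rxns.values()), model.provenance + "+curated"
    )


def make_variant(model: MetabolicNetwork, spec: VariantSpec) -> MetabolicNetwork:
    """Build a pathway variant from the curated model (copy)."""
    rxns = {r.id: r for r in model.reactions}
    for blocked in spec.blocked_reactions:
        targets = (blocked,) + _ID_SYNONYMS.get(blocked, ())
        hit = next((t for t in targets if t in rxns), None)
        if hit is None:
            logger.warning("variant %s: blocked reaction %s absent", spec.name, blocked)
            continue
        rxns[hit] = replace(rxns[hit], lower_bound=0.0, upper_bound=0.0)
    if spec.gnd_reversible and "GND" in rxns:
        rxns["GND"] = replace(rxns["GND"], lower_bound=-1000.0)
    mets = list(model.metabolites)
    if spec.add_rubp:
        new_mets, new_rxns = _rubp_additions(model)
        mets += new_mets
        for r in new_rxns:
            if r.id in rxns:
                raise FBAError(f"variant adds existing reaction {r.id!r}")
            rxns[r.id] = r
    return MetabolicNetwork(mets, list(rxns.values()), model.provenance + f"+{spec.name}")


def _exchange_for(model: MetabolicNetwork, met_id: str) -> str | None:
    for r in model.reactions:
        if r.is_exchange and met_id in r.stoichiometry:
            return r.id
    return None


@dataclass
class YieldResult:
    yield_mol_per_mol: float
    product_flux: float
    uptake: float
    byproducts: dict[str, float] = field(default_factory=dict)
    relative_yield: float | None = None
    fluxes: dict[str, float] = field(default_factory=dict)


def max_product_yield(model: MetabolicNetwork, config: FBAConfig) -> YieldResult:
    """LP: maximise product secretion in a non-growing cell.

    Substrate uptake and ATPM are fixed; CO2 exchange is unconstrained;
    every other carbon exchange is secretion-only.  Oxygen uptake and the
    oxygen-sensitive formate lyases follow the aerobic flag; the H2 exchange
    opens only when hydrogen is configured as an extra electron donor.
    Products without an exchange reaction get one auto-created.
    """
    model = model.copy()
    if config.substrate not in model._met_index:
        raise FBAError(f"substrate {config.substrate!r} not in model")
    sub_ex = _exchange_for(model, config.substrate)
    if sub_ex is None:
        raise FBAError(f"no exchange reaction for substrate {config.substrate!r}")
    if config.product not in model._met_index:
        raise FBAError(f"product {config.product!r} not in model")
    prod_ex = _exchange_for(model, config.product)
    if prod_ex is None:
        prod_ex = f"EX_{config.product}"
        model.reactions.append(
            Reaction(id=prod_ex, stoichiometry={config.product: -1.0}, is_exchange=True)
        )
        model = MetabolicNetwork(model.metabolites, model.reactions, model.provenance)

    lb: dict[str, float] = {}
    ub: dict[str, float] = {}
    for r in model.reactions:
        lb[r.id], ub[r.id] = r.lower_bound, r.upper_bound
        base = split_compartment(next(iter(r.stoichiometry)))[0] if r.is_exchange else None
        if r.is_exchange:
            carbons = model.metabolite(next(iter(r.stoichiometry))).carbon_count
            if base == "co2":
                lb[r.id], ub[r.id] = -1000.0, 1000.0  # unconstrained CO2
            elif carbons > 0:
                lb[r.id] = 0.0  # secretion only unless it is the substrate
                ub[r.id] = 1000.0
            elif base == "o2":
                lb[r.id] = -1000.0 if config.aerobic else 0.0
                ub[r.id] = 1000.0
            elif base == "h2":
                lb[r.id] = -1000.0 if config.extra_electron_donor == "h2" else 0.0
                ub[r.id] = 0.0 if config.extra_electron_donor != "h2" else 1000.0
            else:
                lb[r.id], ub[r.id] = -1000.0, 1000.0
        if r.oxygen_sensitive and config.aerobic:
            lb[r.id] = ub[r.id] = 0.0
        if r.id == "ATPM":
            lb[r.id] = ub[r.id] = config.atpm
    # H2 exchange is on an _e species with carbons == 0; handled above via base
    lb[sub_ex] = ub[sub_ex] = -config.uptake
    if "ATPM" not in {r.id for r in model.reactions} and config.atpm > 0:
        raise FBAError("model lacks an ATPM reaction but atpm > 0 requested")

    rids = [r.id for r in model.reactions]
    col = {rid: j for j, rid in enumerate(rids)}
    S = model.stoichiometric_matrix()
    c = np.zeros(len(rids))
    c[col[prod_ex]] = -1.0  # maximise secretion
    res = linprog(
        c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=[(lb[rid], ub[rid]) for rid in rids],
        method="highs",
    )
    if not res.success:
        binding = [
            rid for rid in rids if lb[rid] == ub[rid] and abs(lb[rid]) > 0
        ]
        raise FBAError(
            f"FBA infeasible for product {config.product!r} "
            f"(fixed-flux constraints: {binding}): {res.message}"
        )
    v = {rid: float(res.x[col[rid]]) for rid in rids}
    product_flux = v[prod_ex]
    byproducts = {}
    for r in model.reactions:
        if not r.is_exchange or r.id in (prod_ex, sub_ex):
            continue
        met = next(iter(r.stoichiometry))
        base = split_compartment(met)[0]
        if model.metabolite(met).carbon_count == 0 or base == "co2":
            continue
        if v[r.id] > 1e-6:
            byproducts[met] = round(v[r.id], 9)
    return YieldResult(
        yield_mol_per_mol=product_flux / config.uptake,
        product_flux=product_flux,
        uptake=config.uptake,
        byproducts=byproducts,
        fluxes=v,
    )


def relative_yield_table(
    model: MetabolicNetwork,
    variants: Sequence[VariantSpec | str],
    products: Sequence[str],
    config: FBAConfig,
):
    """Variant x product matrix of yields relative to the WT reference.

    Returns a pandas DataFrame of relative yields; absolute yields are
    attached as ``df.attrs["absolute"]``.  Products with zero WT yield get
    NaN relative entries (the absolute value is still reported).
    """
    import pandas as pd

    specs = [v if isinstance(v, VariantSpec) else VariantSpec.for_name(v) for v in variants]
    wt = VariantSpec.for_name("WT")
    if all(s.name != "WT" for s in specs):
        specs = [wt] + specs

    absolute = {}
    for spec in specs:
        variant_model = make_variant(model, spec)
        row = {}
        for product in products:
            cfg = replace(config, product=product)
            try:
                row[product] = max_product_yield(variant_model, cfg).yield_mol_per_mol
            except FBAError:
                row[product] = float("nan")
        absolute[spec.name] = row

    rel = {}
    for name, row in absolute.items():
        rel[name] = {}
        for product, y in row.items():
            wt_y = absolute["WT"][product]
            rel[name][product] = y / wt_y if wt_y and wt_y > 1e-9 else float("nan")
    df = pd.DataFrame(rel).T[list(products)]
    df.attrs["absolute"] = pd.DataFrame(absolute).T[list(products)]
    return df
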