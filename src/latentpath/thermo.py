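"""Transformed Gibbs-energy arithmetic and the Max-min Driving Force LP.

The Max-min Driving Force (MDF) of a directed pathway is the largest B such
that log-scale metabolite concentrations x = ln c can be chosen within
physiological bounds so that every pathway reaction i has driving force

    -dG'_i = -(dG0'_i + RT * sum_j S_ji x_j) >= B .

Maximising B is a linear program in (x, B).  Water and protons are excluded
from the concentration terms (their activity is folded into the transformed
standard energies); dissolved CO2 is pinned to its Henry's-law concentration
at the configured headspace partial pressure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import linprog

from .network import Reaction, split_compartment

__all__ = [
    "R_KJ",
    "ThermoParams",
    "ConcentrationBounds",
    "DrivingForceResult",
    "ThermoError",
    "transform_dg",
    "compute_mdf",
    "keq_from_dg",
    "dg_from_keq",
    "co2_pressure_to_conc",
    "co2_conc_to_pressure",
]

#: Gas constant, kJ/(mol K)
R_KJ = 0.008314

#: Base ids excluded from concentration terms by the transformed-energy
#: convention.
EXCLUDED_BASE_IDS = frozenset({"h", "h2o"})


class ThermoError(ValueError):
    pass


@dataclass(frozen=True)
class ThermoParams:
    """Reference conditions for the vendored dG'0 values.

    Energies are 25 C, pH 7.5, I = 0.25 M component-contribution values; pH
    and ionic strength are metadata only (inputs are already transformed).
    """

    temperature: float = 298.15  # K
    ph: float = 7.5
    ionic_strength: float = 0.25  # M
    henry_constant_co2: float = 0.0338  # M/bar at 25 C
    ambient_pressure_mbar: float = 1013.25

    @property
    def rt(self) -> float:
        return R_KJ * self.temperature  # ~2.479 kJ/mol


@dataclass
class ConcentrationBounds:
    """Molar concentration bounds for the MDF optimisation.

    ``fixed`` pins species to a single concentration (e.g. dissolved CO2 at
    200 mbar); fixed species may not also appear in ``overrides``.
    """

    default_lb: float = 1e-6
    default_ub: float = 1e-2
    overrides: dict[str, tuple[float, float]] = field(default_factory=dict)
    fixed: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for met, (lb, ub) in self.overrides.items():
            if not (0 < lb <= ub):
                raise ThermoError(f"invalid bounds for {met}: ({lb}, {ub})")
            if met in self.fixed:
                raise ThermoError(f"{met} both fixed and bounded")
        if not (0 < self.default_lb <= self.default_ub):
            raise ThermoError("invalid default bounds")
        for met, c in self.fixed.items():
            if c <= 0:
                raise ThermoError(f"non-positive fixed concentration for {met}")

    def range_for(self, met_id: str) -> tuple[float, float]:
        if met_id in self.fixed:
            c = self.fixed[met_id]
            return c, c
        return self.overrides.get(met_id, (self.default_lb, self.default_ub))

    @classmethod
    def physiological(
        cls,
        params: ThermoParams | None = None,
        co2_pressure_mbar: float = 200.0,
        compartment: str = "c",
    ) -> "ConcentrationBounds":
        """Default 1 uM - 10 mM range with CO2 pinned by Henry's law at the
        given headspace pressure, and O2/NH4 pinned at 1 mM."""
        params = params or ThermoParams()
        suffix = f"_{compartment}" if compartment else ""
        fixed = {
            f"co2{suffix}": co2_pressure_to_conc(co2_pressure_mbar, params),
            f"o2{suffix}": 1e-3,
            f"nh4{suffix}": 1e-3,
        }
        return cls(fixed=fixed)


@dataclass
class DrivingForceResult:
    mdf: float  # kJ/mol
    log_concentrations: dict[str, float]  # ln(molar)
    reaction_dg_prime: dict[str, float]  # kJ/mol at the optimum
    bottleneck_ids: list[str]

    def driving_forces(self) -> dict[str, float]:
        return {rid: -dg for rid, dg in self.reaction_dg_prime.items()}


def _is_excluded(met_id: str) -> bool:
    return split_compartment(met_id)[0] in EXCLUDED_BASE_IDS


def transform_dg(
    reaction: Reaction,
    params: ThermoParams | None = None,
    reference: Mapping[str, float] | None = None,
    bounds: ConcentrationBounds | None = None,
) -> float:
    """Transformed reaction energy at reference concentrations (kJ/mol).

    dG' = dG0' + RT * sum_i s_i ln(c_i), with water and protons excluded.
    Per-species reference concentrations come from ``reference`` (molar,
    default 1 mM for every participant); species fixed in ``bounds`` (such as
    dissolved CO2) take their fixed concentration instead.
    """
    params = params or ThermoParams()
    if reaction.dg0_prime is None:
        raise ThermoError(f"reaction {reaction.id!r} has no dG'0")
    total = reaction.dg0_prime
    for met, coef in reaction.stoichiometry.items():
        if _is_excluded(met):
            continue
        if bounds is not None and met in bounds.fixed:
            c = bounds.fixed[met]
        elif reference is not None:
            if met not in reference:
                raise ThermoError(f"no reference concentration for {met!r}")
            c = reference[met]
        else:
            c = 1e-3
        total += params.rt * coef * math.log(c)
    return total


def keq_from_dg(dg0: float, params: ThermoParams | None = None) -> float:
    """Keq = exp(-dG'0 / RT)."""
    params = params or ThermoParams()
    if not math.isfinite(dg0):
        raise ThermoError("non-finite dG'0")
    return math.exp(-dg0 / params.rt)


def dg_from_keq(keq: float, params: ThermoParams | None = None) -> float:
    params = params or ThermoParams()
    if not (keq > 0 and math.isfinite(keq)):
        raise ThermoError("Keq must be positive and finite")
    return -params.rt * math.log(keq)


def co2_pressure_to_conc(p_mbar: float, params: ThermoParams | None = None) -> float:
    """Dissolved CO2 (molar) at a headspace partial pressure (mbar)."""
    params = params or ThermoParams()
    if p_mbar < 0:
        raise ThermoError("negative partial pressure")
    return params.henry_constant_co2 * (p_mbar / 1000.0)


def co2_conc_to_pressure(c_molar: float, params: ThermoParams | None = None) -> float:
    """Headspace CO2 partial pressure (mbar) in equilibrium with ``c_molar``."""
    params = params or ThermoParams()
    if c_molar < 0:
        raise ThermoError("negative concentration")
    return 1000.0 * c_molar / params.henry_constant_co2


def compute_mdf(
    pathway: Sequence[tuple[Reaction, int]],
    bounds: ConcentrationBounds | None = None,
    params: ThermoParams | None = None,
    dg0: Mapping[str, float] | None = None,
) -> DrivingForceResult:
    """Solve the Max-min Driving Force LP for a directed pathway.

    ``pathway`` is a list of (reaction, direction) with direction +1 for the
    forward direction as written and -1 for the reverse.  Pseudo-reactions
    (currency regeneration) are skipped.  ``dg0`` may override per-reaction
    standard energies; otherwise ``reaction.dg0_prime`` is used.
    """
    params = params or ThermoParams()
    bounds = bounds if bounds is not None else ConcentrationBounds.physiological(params)
    rt = params.rt

    constrained = [(r, d) for r, d in pathway if not r.pseudo]
    if not constrained:
        raise ThermoError("no constrained reactions: MDF is unbounded")

    met_ids = sorted(
        {m for r, _ in constrained for m in r.stoichiometry if not _is_excluded(m)}
    )
    met_index = {m: i for i, m in enumerate(met_ids)}
    n_x = len(met_ids)

    # variables: [x_0..x_{n-1}, B]; maximize B
    c = np.zeros(n_x + 1)
    c[-1] = -1.0

    A_ub = np.zeros((len(constrained), n_x + 1))
    b_ub = np.zeros(len(constrained))
    for i, (r, d) in enumerate(constrained):
        dg0_i = dg0[r.id] if dg0 is not None else r.dg0_prime
        if dg0_i is None:
            raise ThermoError(f"reaction {r.id!r} has no dG'0")
        if d not in (1, -1):
            raise ThermoError(f"direction for {r.id!r} must be +1 or -1")
        # d*(dG0 + RT * S.x) + B <= 0
        for met, coef in r.stoichiometry.items():
            if _is_excluded(met):
                continue
            A_ub[i, met_index[met]] += d * rt * coef
        A_ub[i, -1] = 1.0
        b_ub[i] = -d * dg0_i

    var_bounds = []
    for m in met_ids:
        lb, ub = bounds.range_for(m)
        var_bounds.append((math.log(lb), math.log(ub)))
    var_bounds.append((None, None))  # B

    res = linprog(c, A_ub=A_ub, b_ub=b_ub, bounds=var_bounds, method="highs")
    if not res.success:
        raise ThermoError(f"MDF LP failed: {res.message}")

    x = res.x[:n_x]
    mdf = float(res.x[-1])
    log_conc = {m: float(x[met_index[m]]) for m in met_ids}
    rxn_dg = {}
    for r, d in constrained:
        dg0_i = dg0[r.id] if dg0 is not None else r.dg0_prime
        val = d * dg0_i
        for met, coef in r.stoichiometry.items():
            if _is_excluded(met):
                continue
            val += d * rt * coef * log_conc[met]
        rxn_dg[r.id] = float(val)
    bottlenecks = [rid for rid, dg in rxn_dg.items() if abs(-dg - mdf) < 1e-6]
    return DrivingForceResult(
        mdf=mdf,
        log_concentrations=log_conc,
        reaction_dg_prime=rxn_dg,
        bottleneck_ids=bottlenecks,
    )
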