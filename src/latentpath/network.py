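"""Metabolic network data model, readers/writers, and search preprocessing.

The network container is deliberately small: metabolites with carbon counts
and currency flags, reactions as signed stoichiometric mappings with optional
transformed standard Gibbs energies (kJ/mol), and a dense stoichiometric
matrix view.  It is the substrate for pathway search (MILP), MDF evaluation,
and flux balance analysis.

Two on-disk formats are supported:

* BiGG-style JSON, the dialect used by genome-scale reconstructions such as
  iML1515 (read only; carbon counts are parsed from chemical formulas);
* a tab-separated fixture format (read/write): ``metabolites.tsv`` with
  columns id / name / carbons / compartment / currency, and ``reactions.tsv``
  with id / equation / dg0_prime_kj_mol / oxygen_sensitive / notes, where the
  equation is a human-readable string like ``"a A + b B -> c C"``.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicNetwork",
    "NetworkError",
    "CurrencySpec",
    "DEFAULT_CURRENCY_IDS",
    "PSEUDO_PREFIX",
    "read_bigg_json",
    "read_network_table",
    "write_network_table",
    "prune_for_search",
    "add_currency_exchanges",
    "carbon_balance_check",
]


class NetworkError(ValueError):
    """Raised on malformed input files or contract violations."""


#: Base ids (compartment suffix stripped) treated as currency metabolites:
#: energy/redox cofactors and freely supplied inorganics.  CO2 is flagged as
#: currency for free supply but remains the counted substrate during pathway
#: search.
DEFAULT_CURRENCY_IDS = frozenset(
    {
        "atp", "adp", "amp", "pi", "ppi",
        "nad", "nadh", "nadp", "nadph",
        "h", "h2o", "o2", "nh3", "nh4", "co2",
    }
)

PSEUDO_PREFIX = "PSEUDO_"

_COMPARTMENT_RE = re.compile(r"^(?P<base>.+)_(?P<comp>[a-z][a-z0-9]?)$")


def split_compartment(met_id: str) -> tuple[str, str]:
    """Split a BiGG-style metabolite id into (base id, compartment).

    ``"6pgc_c" -> ("6pgc", "c")``.  Ids without a recognisable suffix are
    assigned the empty compartment.
    """
    m = _COMPARTMENT_RE.match(met_id)
    if m:
        return m.group("base"), m.group("comp")
    return met_id, ""


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    carbon_count: int = 0
    compartment: str = ""
    is_currency: bool = False
    fixed_concentration: float | None = None  # molar

    def __post_init__(self) -> None:
        if self.carbon_count < 0:
            raise NetworkError(f"carbon_count < 0 for metabolite {self.id!r}")

    @property
    def base_id(self) -> str:
        return split_compartment(self.id)[0]


@dataclass(frozen=True)
class Reaction:
    """A reaction as a signed stoichiometric mapping (negative = consumed).

    ``dg0_prime`` is the transformed standard reaction Gibbs energy in kJ/mol
    for the forward direction as written.  Flux bounds carry mmol/gDW/h
    semantics and are only honoured by FBA; pathway search treats every
    non-pseudo reaction as reversible.
    """

    id: str
    stoichiometry: Mapping[str, float]
    dg0_prime: float | None = None
    oxygen_sensitive: bool = False
    is_exchange: bool = False
    is_transport: bool = False
    lower_bound: float = -1000.0
    upper_bound: float = 1000.0
    pseudo: bool = False  # currency regeneration / free exchange marker
    notes: str = ""

    def __post_init__(self) -> None:
        if not self.stoichiometry:
            raise NetworkError(f"reaction {self.id!r} has empty stoichiometry")
        if all(abs(v) < 1e-12 for v in self.stoichiometry.values()):
            raise NetworkError(f"reaction {self.id!r} has zero net stoichiometry")
        if self.is_exchange and len(self.stoichiometry) != 1:
            raise NetworkError(
                f"exchange reaction {self.id!r} must touch exactly one metabolite"
            )
        object.__setattr__(self, "stoichiometry", dict(self.stoichiometry))

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound


@dataclass
class MetabolicNetwork:
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    provenance: str = ""
    _met_index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        if len(self._met_index) != len(self.metabolites):
            seen: set[str] = set()
            dups = [m.id for m in self.metabolites if m.id in seen or seen.add(m.id)]
            raise NetworkError(f"duplicate metabolite ids: {sorted(set(dups))}")
        rids = [r.id for r in self.reactions]
        if len(set(rids)) != len(rids):
            seen = set()
            dups = [r for r in rids if r in seen or seen.add(r)]
            raise NetworkError(f"duplicate reaction ids: {sorted(set(dups))}")
        for r in self.reactions:
            missing = [m for m in r.stoichiometry if m not in self._met_index]
            if missing:
                raise NetworkError(
                    f"reaction {r.id!r} references undeclared metabolites: {missing}"
                )

    # -- container protocol ------------------------------------------------
    def metabolite(self, met_id: str) -> Metabolite:
        return self.metabolites[self._met_index[met_id]]

    def reaction(self, rxn_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == rxn_id:
                return r
        raise KeyError(rxn_id)

    def has_reaction(self, rxn_id: str) -> bool:
        return any(r.id == rxn_id for r in self.reactions)

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def stoichiometric_matrix(self) -> np.ndarray:
        """Dense S with shape (n_metabolites, n_reactions)."""
        S = np.zeros((len(self.metabolites), len(self.reactions)))
        for j, r in enumerate(self.reactions):
            for met, coef in r.stoichiometry.items():
                S[self._met_index[met], j] = coef
        return S

    def copy(self) -> "MetabolicNetwork":
        return MetabolicNetwork(
            metabolites=list(self.metabolites),
            reactions=list(self.reactions),
            provenance=self.provenance,
        )

    def equals(self, other: "MetabolicNetwork") -> bool:
        """Field-by-field equality (ignoring provenance)."""
        if self.metabolite_ids != other.metabolite_ids:
            return False
        if self.reaction_ids != other.reaction_ids:
            return False
        for a, b in zip(self.metabolites, other.metabolites):
            if a != b:
                return False
        for ra, rb in zip(self.reactions, other.reactions):
            if replace(ra, notes="") != replace(rb, notes=""):
                return False
        return True


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_FORMULA_C_RE = re.compile(r"C(?![a-z])(\d*)")


def carbon_count_from_formula(formula: str | None) -> int:
    """Number of carbon atoms in a chemical formula string ('C6H12O6' -> 6)."""
    if not formula:
        return 0
    m = _FORMULA_C_RE.search(formula)
    if not m:
        return 0
    return int(m.group(1)) if m.group(1) else 1


def read_bigg_json(path: str | Path, currency_ids: frozenset[str] = DEFAULT_CURRENCY_IDS) -> MetabolicNetwork:
    """Read a BiGG-dialect JSON model (e.g. iML1515).

    Exchange reactions are detected by the ``EX_`` prefix; transport by a
    reaction touching the same base metabolite id in two or more compartments.
    """
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise NetworkError(f"malformed JSON in {path.name}: {exc}") from exc
    for key in ("metabolites", "reactions"):
        if key not in doc:
            raise NetworkError(f"BiGG JSON missing top-level key {key!r}")

    mets = []
    for m in doc["metabolites"]:
        base, comp = split_compartment(m["id"])
        mets.append(
            Metabolite(
                id=m["id"],
                name=m.get("name", ""),
                carbon_count=carbon_count_from_formula(m.get("formula")),
                compartment=m.get("compartment", comp),
                is_currency=base in currency_ids,
            )
        )
    rxns = []
    for r in doc["reactions"]:
        stoich = {k: float(v) for k, v in r["metabolites"].items()}
        comps = {split_compartment(k)[1] for k in stoich}
        bases = [split_compartment(k)[0] for k in stoich]
        is_transport = len(comps) > 1 and len(set(bases)) < len(bases)
        if len(comps) > 1 and not is_transport:
            # membrane reaction moving species between compartments
            is_transport = True
        rxns.append(
            Reaction(
                id=r["id"],
                stoichiometry=stoich,
                lower_bound=float(r.get("lower_bound", -1000.0)),
                upper_bound=float(r.get("upper_bound", 1000.0)),
                is_exchange=r["id"].startswith("EX_"),
                is_transport=is_transport and not r["id"].startswith("EX_"),
                notes=r.get("name", ""),
            )
        )
    return MetabolicNetwork(mets, rxns, provenance=f"bigg-json:{path.name}")


_ARROW_RE = re.compile(r"<->|<=>|->|=>")


def parse_equation(equation: str) -> dict[str, float]:
    """Parse ``"a A + b B -> c C"`` into a signed stoichiometry mapping."""
    arrow = _ARROW_RE.search(equation)
    if not arrow:
        raise NetworkError(f"unparseable equation (no arrow): {equation!r}")
    lhs, rhs = equation[: arrow.start()], equation[arrow.end():]
    stoich: dict[str, float] = {}

    def add_side(side: str, sign: float) -> None:
        side = side.strip()
        if not side:
            return
        for term in side.split("+"):
            term = term.strip()
            if not term:
                raise NetworkError(f"unparseable equation term in: {equation!r}")
            parts = term.split()
            if len(parts) == 1:
                coef, met = 1.0, parts[0]
            elif len(parts) == 2:
                try:
                    coef = float(parts[0])
                except ValueError as exc:
                    raise NetworkError(
                        f"unparseable coefficient {parts[0]!r} in: {equation!r}"
                    ) from exc
                met = parts[1]
            else:
                raise NetworkError(f"unparseable equation term {term!r} in: {equation!r}")
            stoich[met] = stoich.get(met, 0.0) + sign * coef

    add_side(lhs, -1.0)
    add_side(rhs, +1.0)
    # cancelled species (catalytic appearances on both sides) are dropped
    return {m: c for m, c in stoich.items() if abs(c) > 1e-12}


def format_equation(stoich: Mapping[str, float], reversible: bool = True) -> str:
    def side(items: Iterable[tuple[str, float]]) -> str:
        terms = []
        for met, coef in items:
            coef = abs(coef)
            if abs(coef - 1.0) < 1e-12:
                terms.append(met)
            elif abs(coef - round(coef)) < 1e-12:
                terms.append(f"{int(round(coef))} {met}")
            else:
                terms.append(f"{coef:g} {met}")
        return " + ".join(terms)

    subs = sorted((m, c) for m, c in stoich.items() if c < 0)
    prods = sorted((m, c) for m, c in stoich.items() if c > 0)
    arrow = "<->" if reversible else "->"
    return f"{side(subs)} {arrow} {side(prods)}"


def _read_tsv_rows(path: Path) -> tuple[list[str], list[tuple[int, list[str]]]]:
    header: list[str] | None = None
    rows: list[tuple[int, list[str]]] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if header is None:
            header = [f.strip() for f in fields]
        else:
            rows.append((lineno, fields))
    if header is None:
        return [], []
    return header, rows


def read_network_table(path: str | Path) -> MetabolicNetwork:
    """Read the tabular fixture format.

    ``path`` may point either at ``reactions.tsv`` (with ``metabolites.tsv``
    next to it) or at the directory containing both.
    """
    path = Path(path)
    if path.is_dir():
        rxn_path, met_path = path / "reactions.tsv", path / "metabolites.tsv"
    else:
        rxn_path, met_path = path, path.with_name("metabolites.tsv")
    if not met_path.exists():
        raise NetworkError(f"companion metabolite table not found: {met_path}")

    header, rows = _read_tsv_rows(met_path)
    col = {name: i for i, name in enumerate(header)}
    for required in ("id", "carbons"):
        if required not in col:
            raise NetworkError(f"metabolites.tsv missing column {required!r}")
    mets = []
    for lineno, fields in rows:
        met_id = fields[col["id"]].strip()
        base, comp = split_compartment(met_id)
        mets.append(
            Metabolite(
                id=met_id,
                name=fields[col["name"]].strip() if "name" in col else "",
                carbon_count=int(fields[col["carbons"]]),
                compartment=fields[col["compartment"]].strip()
                if "compartment" in col
                else comp,
                is_currency=fields[col["currency"]].strip() in ("1", "true", "True")
                if "currency" in col
                else base in DEFAULT_CURRENCY_IDS,
            )
        )
    declared = {m.id for m in mets}

    header, rows = _read_tsv_rows(rxn_path) if rxn_path.exists() else ([], [])
    col = {name: i for i, name in enumerate(header)}
    rxns = []
    for lineno, fields in rows:
        rid = fields[col["id"]].strip()
        equation = fields[col["equation"]].strip()
        try:
            stoich = parse_equation(equation)
        except NetworkError as exc:
            raise NetworkError(f"{rxn_path.name}:{lineno}: {exc}") from exc
        unknown = sorted(set(stoich) - declared)
        if unknown:
            raise NetworkError(
                f"{rxn_path.name}:{lineno}: unknown metabolites {unknown} in {rid!r}"
            )
        dg_field = fields[col["dg0_prime_kj_mol"]].strip() if "dg0_prime_kj_mol" in col else ""
        reversible = "<->" in equation or "<=>" in equation
        rxns.append(
            Reaction(
                id=rid,
                stoichiometry=stoich,
                dg0_prime=float(dg_field) if dg_field not in ("", "NA", "nan") else None,
                oxygen_sensitive="oxygen_sensitive" in col
                and fields[col["oxygen_sensitive"]].strip() in ("1", "true", "True"),
                is_exchange=rid.startswith("EX_"),
                is_transport=len({split_compartment(m)[1] for m in stoich}) > 1,
                lower_bound=-1000.0 if reversible else 0.0,
                upper_bound=1000.0,
                pseudo=rid.startswith(PSEUDO_PREFIX),
                notes=fields[col["notes"]].strip()
                if "notes" in col and len(fields) > col["notes"]
                else "",
            )
        )
    return MetabolicNetwork(mets, rxns, provenance=f"table:{rxn_path.name}")


def write_network_table(net: MetabolicNetwork, out_dir: str | Path) -> None:
    """Write ``metabolites.tsv`` and ``reactions.tsv`` (UTF-8, '#' comments)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "metabolites.tsv", "w") as fh:
        fh.write("id\tname\tcarbons\tcompartment\tcurrency\n")
        for m in net.metabolites:
            fh.write(
                f"{m.id}\t{m.name}\t{m.carbon_count}\t{m.compartment}\t"
                f"{1 if m.is_currency else 0}\n"
            )
    with open(out / "reactions.tsv", "w") as fh:
        fh.write("id\tequation\tdg0_prime_kj_mol\toxygen_sensitive\tnotes\n")
        for r in net.reactions:
            dg = "" if r.dg0_prime is None else f"{r.dg0_prime:g}"
            eq = format_equation(r.stoichiometry, reversible=r.reversible)
            fh.write(f"{r.id}\t{eq}\t{dg}\t{1 if r.oxygen_sensitive else 0}\t{r.notes}\n")


# ---------------------------------------------------------------------------
# Preprocessing for pathway search
# ---------------------------------------------------------------------------

def prune_for_search(net: MetabolicNetwork, compartment: str = "c") -> MetabolicNetwork:
    """Drop exchange/transport reactions and keep strictly cytoplasmic ones.

    A reaction survives iff it is not flagged exchange or transport and every
    metabolite it touches lives in ``compartment``.  The input is unmodified.
    """
    keep = []
    for r in net.reactions:
        if r.pseudo:  # currency pseudo-reactions survive preprocessing
            keep.append(r)
            continue
        if r.is_exchange or r.is_transport:
            continue
        comps = {net.metabolite(m).compartment for m in r.stoichiometry}
        if comps <= {compartment}:
            keep.append(r)
    used = {m for r in keep for m in r.stoichiometry}
    mets = [m for m in net.metabolites if m.id in used or m.compartment == compartment]
    return MetabolicNetwork(mets, keep, provenance=net.provenance + "+pruned")


@dataclass(frozen=True)
class CurrencySpec:
    """Which species are regenerated / freely exchanged during search.

    ``regeneration`` maps a pseudo-reaction name to its equation string;
    ``free_exchange`` lists base ids given a free single-metabolite exchange.
    """

    regeneration: Mapping[str, str] = field(
        default_factory=lambda: {
            "ATP_ADP": "adp + pi + h -> atp + h2o",
            "ATP_AMP": "amp + 2 pi + 2 h -> atp + 2 h2o",
            "NADH": "nad + h -> nadh",
            "NADPH": "nadp + h -> nadph",
        }
    )
    free_exchange: Sequence[str] = ("h", "h2o", "o2", "nh4")

    def is_empty(self) -> bool:
        return not self.regeneration and not self.free_exchange


def add_currency_exchanges(
    net: MetabolicNetwork,
    currency_spec: CurrencySpec | None = None,
    compartment: str = "c",
) -> MetabolicNetwork:
    """Append reversible currency pseudo-reactions (marked ``pseudo=True``).

    The pseudo-reactions regenerate ATP (from ADP and from AMP), NADH, and
    NADPH, and give free single-species exchange to protons, water, oxygen,
    and ammonia, emulating free flow of energy and electrons during pathway
    search.  Pseudo-reactions never count toward pathway size and carry no
    thermodynamic constraints.
    """
    spec = currency_spec if currency_spec is not None else CurrencySpec()
    if spec.is_empty():
        return net.copy()

    suffix = f"_{compartment}" if compartment else ""
    missing: list[str] = []
    new_rxns: list[Reaction] = []
    for name, eq in spec.regeneration.items():
        stoich = {f"{m}{suffix}": c for m, c in parse_equation(eq).items()}
        absent = [m for m in stoich if m not in net._met_index]
        if absent:
            missing.extend(absent)
            continue
        new_rxns.append(
            Reaction(
                id=f"{PSEUDO_PREFIX}{name}",
                stoichiometry=stoich,
                pseudo=True,
                notes="currency regeneration",
            )
        )
    for base in spec.free_exchange:
        met = f"{base}{suffix}"
        if met not in net._met_index:
            missing.append(met)
            continue
        new_rxns.append(
            Reaction(
                id=f"{PSEUDO_PREFIX}EXF_{base}",
                stoichiometry={met: -1.0},
                is_exchange=True,
                pseudo=True,
                notes="free currency exchange",
            )
        )
    if missing:
        raise NetworkError(f"currency species missing from network: {sorted(set(missing))}")
    out = net.copy()
    out.reactions = [r for r in out.reactions] + new_rxns
    return MetabolicNetwork(out.metabolites, out.reactions, net.provenance + "+currency")


def carbon_balance_check(net: MetabolicNetwork) -> list[str]:
    """Ids of non-exchange, non-pseudo reactions violating carbon balance.

    Requires known carbon counts for all non-currency participants; thioester
    carriers follow the acyl-only counting convention (free CoA counts 0).
    """
    violations = []
    for r in net.reactions:
        if r.is_exchange or r.pseudo:
            continue
        total = 0.0
        for met_id, coef in r.stoichiometry.items():
            total += coef * net.metabolite(met_id).carbon_count
        if abs(total) > 1e-9:
            violations.append(r.id)
    return violations
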