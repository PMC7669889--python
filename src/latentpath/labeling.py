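"""Positional 13C atom-transition simulation of the GED shunt.

The shunt has a short, fully determined carbon routing, so label propagation
is exact positional bookkeeping rather than a stochastic simulation:

* a pentose substrate (ribose or xylose) enters as Ru5P with its carbon
  order preserved (isomerase/epimerase steps do not permute carbons);
* Gnd carboxylation inserts CO2 as the new carboxylic carbon C1 of
  6-phosphogluconate and shifts Ru5P C1..C5 to 6PG C2..C6;
* the Entner-Doudoroff aldol cleavage splits at the C3-C4 bond: 6PG C1-C3
  become pyruvate C1-C3 (C1 = carboxyl) and 6PG C4-C6 become GAP C1-C3;
* lower glycolysis conserves positions, so GAP-derived pyruvate carries the
  GAP pattern.

The cellular pyruvate pool is a mixture of Eda-produced and GAP-derived
molecules (one of each per shunt turn, hence a 50:50 default).  Amino-acid
isotopologue distributions follow from their precursors: serine/glycine from
3PG (= GAP), alanine from pyruvate, valine from two independently drawn
pyruvates with the acceptor's carboxyl lost as CO2, and histidine from the
five R5P carbons plus serine's beta-carbon.  All arithmetic is exact
(fractions.Fraction).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from itertools import product as iter_product
from typing import Mapping, Sequence

__all__ = [
    "TracerSpec",
    "PositionalPools",
    "IsotopologueDistribution",
    "LabelingError",
    "propagate_labels",
    "pyruvate_pool_mixture",
    "amino_acid_isotopologues",
    "compare_distributions",
    "predict_amino_acids",
]

SUBSTRATE_CARBONS = {"ribose": 5, "xylose": 5}


class LabelingError(ValueError):
    pass


@dataclass(frozen=True)
class TracerSpec:
    """Which substrate carbons and whether the CO2 pool carry 13C.

    ``labeled_positions`` are 1-based carbon indices of the pentose substrate
    (carbonyl/aldehyde end first, the convention of commercial 1-13C sugars).
    """

    substrate: str = "ribose"
    labeled_positions: frozenset[int] = frozenset()
    co2_labeled: bool = False

    def __post_init__(self) -> None:
        if self.substrate not in SUBSTRATE_CARBONS:
            raise LabelingError(
                f"unknown substrate {self.substrate!r}; expected one of "
                f"{sorted(SUBSTRATE_CARBONS)}"
            )
        n = SUBSTRATE_CARBONS[self.substrate]
        bad = [i for i in self.labeled_positions if not 1 <= i <= n]
        if bad:
            raise LabelingError(f"labeled positions out of range: {bad}")


@dataclass(frozen=True)
class PositionalPools:
    """Per-carbon label patterns (True = 13C), index 0 = C1."""

    ru5p: tuple[bool, ...]
    pg6: tuple[bool, ...]
    eda_pyruvate: tuple[bool, ...]
    gap: tuple[bool, ...]

    @property
    def r5p(self) -> tuple[bool, ...]:
        return self.ru5p  # isomerase preserves carbon order

    @property
    def gap_pyruvate(self) -> tuple[bool, ...]:
        return self.gap  # lower glycolysis preserves positions


@dataclass
class IsotopologueDistribution:
    """M+k fractions for one species; exact rationals, sum to 1."""

    species: str
    fractions: list[Fraction]

    def __post_init__(self) -> None:
        total = sum(self.fractions, Fraction(0))
        if total != 1:
            raise LabelingError(f"{self.species}: fractions sum to {total}, not 1")
        if any(f < 0 for f in self.fractions):
            raise LabelingError(f"{self.species}: negative fraction")

    def as_floats(self) -> list[float]:
        return [float(f) for f in self.fractions]

    def expected_labels(self) -> Fraction:
        return sum((Fraction(k) * f for k, f in enumerate(self.fractions)), Fraction(0))


def propagate_labels(tracer: TracerSpec) -> PositionalPools:
    """Trace tracer carbons through the GED shunt's three atom maps."""
    n = SUBSTRATE_CARBONS[tracer.substrate]
    pentose = tuple(i + 1 in tracer.labeled_positions for i in range(n))
    ru5p = pentose  # pentose -> Ru5P, carbon order preserved
    pg6 = (tracer.co2_labeled,) + ru5p  # CO2 -> C1, Ru5P C1..5 -> C2..6
    eda_pyr = pg6[0:3]  # 6PG C1-C3
    gap = pg6[3:6]  # 6PG C4-C6
    return PositionalPools(ru5p=ru5p, pg6=pg6, eda_pyruvate=eda_pyr, gap=gap)


def _count(pattern: Sequence[bool]) -> int:
    return sum(1 for b in pattern if b)


def pyruvate_pool_mixture(
    eda_pattern: Sequence[bool],
    gap_pattern: Sequence[bool],
    mix: Fraction | float = Fraction(1, 2),
) -> IsotopologueDistribution:
    """Two-component pyruvate pool: ``mix`` Eda-derived, 1-mix GAP-derived."""
    mix = Fraction(mix).limit_denominator(10**9)
    if not 0 <= mix <= 1:
        raise LabelingError("mix fraction must lie in [0, 1]")
    fractions = [Fraction(0)] * 4
    fractions[_count(eda_pattern)] += mix
    fractions[_count(gap_pattern)] += 1 - mix
    return IsotopologueDistribution("PYR", fractions)


def _pool_patterns(
    eda_pattern: Sequence[bool], gap_pattern: Sequence[bool], mix: Fraction
) -> list[tuple[tuple[bool, ...], Fraction]]:
    return [
        (tuple(eda_pattern), mix),
        (tuple(gap_pattern), 1 - mix),
    ]


def amino_acid_isotopologues(
    pools: PositionalPools,
    mix: Fraction | float = Fraction(1, 2),
) -> dict[str, IsotopologueDistribution]:
    """Isotopologue distributions of SER, GLY, ALA, VAL, HIS.

    SER inherits 3PG (= GAP) carbons, GLY keeps SER C1-C2, ALA inherits the
    pyruvate pool, VAL condenses two independent pyruvate draws (donor keeps
    C1-C3, acceptor keeps C2-C3 and loses its carboxyl as CO2), and HIS takes
    the five R5P carbons plus serine's beta-carbon (C3).
    """
    mix = Fraction(mix).limit_denominator(10**9)
    pyr_draws = _pool_patterns(pools.eda_pyruvate, pools.gap_pyruvate, mix)

    ser_pattern = tuple(pools.gap)  # 3PG carbons, order preserved
    gly_pattern = ser_pattern[0:2]
    his_fixed = _count(pools.r5p) + (1 if ser_pattern[2] else 0)

    def delta(species: str, n_carbons: int, k: int) -> IsotopologueDistribution:
        fr = [Fraction(0)] * (n_carbons + 1)
        fr[k] = Fraction(1)
        return IsotopologueDistribution(species, fr)

    out = {
        "SER": delta("SER", 3, _count(ser_pattern)),
        "GLY": delta("GLY", 2, _count(gly_pattern)),
        "HIS": delta("HIS", 6, his_fixed),
    }

    ala = [Fraction(0)] * 4
    for pattern, w in pyr_draws:
        ala[_count(pattern)] += w
    out["ALA"] = IsotopologueDistribution("ALA", ala)

    val = [Fraction(0)] * 6
    for (donor, w1), (acceptor, w2) in iter_product(pyr_draws, pyr_draws):
        k = _count(donor) + _count(acceptor[1:3])  # acceptor C1 lost as CO2
        val[k] += w1 * w2
    out["VAL"] = IsotopologueDistribution("VAL", val)
    return out


def predict_amino_acids(
    tracer: TracerSpec, mix: Fraction | float = Fraction(1, 2)
) -> dict[str, IsotopologueDistribution]:
    """End-to-end prediction: tracer -> positional pools -> amino acids."""
    pools = propagate_labels(tracer)
    result = amino_acid_isotopologues(pools, mix=mix)
    result["PYR"] = pyruvate_pool_mixture(pools.eda_pyruvate, pools.gap_pyruvate, mix)
    result["GAP"] = IsotopologueDistribution(
        "GAP",
        [
            Fraction(1) if k == _count(pools.gap) else Fraction(0)
            for k in range(4)
        ],
    )
    return result


def compare_distributions(
    predicted: Mapping[str, IsotopologueDistribution] | IsotopologueDistribution,
    observed: Mapping[str, Sequence[float]] | Sequence[float],
) -> dict[str, float] | float:
    """L1 distance between predicted and observed M+k vectors.

    Shorter vectors are zero-padded; returns per-species distances (plus a
    ``"total"`` entry) for mapping inputs, or a single float for one species.
    """
    if isinstance(predicted, IsotopologueDistribution):
        return _l1(predicted.as_floats(), list(observed))
    out: dict[str, float] = {}
    total = 0.0
    for species, dist in predicted.items():
        if species not in observed:
            raise LabelingError(f"no observation for {species!r}")
        d = _l1(dist.as_floats(), list(observed[species]))
        out[species] = d
        total += d
    out["total"] = total
    return out


def _l1(a: list[float], b: list[float]) -> float:
    n = max(len(a), len(b))
    a = a + [0.0] * (n - len(a))
    b = b + [0.0] * (n - len(b))
    return float(sum(abs(x - y) for x, y in zip(a, b)))
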