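"""Michaelis-Menten model evaluation, nonlinear least-squares fitting, and
the pentose-isomerase equilibrium calculation used in assay design."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "KineticParams",
    "AssayPoint",
    "KineticsError",
    "mm_rate",
    "fit_mm",
    "ru5p_equilibrium",
]


class KineticsError(ValueError):
    pass


@dataclass(frozen=True)
class KineticParams:
    """kcat in 1/s, KM in mM, with optional standard errors and the assay
    enzyme concentration (uM)."""

    kcat: float
    km: float
    enzyme_conc: float | None = None
    kcat_se: float | None = None
    km_se: float | None = None

    def __post_init__(self) -> None:
        if self.kcat <= 0 or self.km <= 0:
            raise KineticsError("kcat and KM must be positive")


@dataclass(frozen=True)
class AssayPoint:
    substrate_conc: float  # mM
    rate: float  # per-enzyme turnover (1/s) or uM/s; units carry through

    def __post_init__(self) -> None:
        if self.substrate_conc < 0:
            raise KineticsError("negative substrate concentration")


def mm_rate(s: float, p: KineticParams) -> float:
    """v = kcat * s / (KM + s)."""
    if s < 0:
        raise KineticsError("negative substrate concentration")
    return p.kcat * s / (p.km + s)


def fit_mm(
    data: Sequence[AssayPoint],
    weighting: str = "none",
) -> KineticParams:
    """Least-squares Michaelis-Menten fit with standard errors.

    Deterministic initialisation: kcat0 = max observed rate, KM0 = substrate
    concentration closest to half the max rate.  ``weighting`` may be
    ``"none"`` (default, unweighted) or ``"1/v2"`` (relative-error weights).
    """
    if len(data) < 4:
        raise KineticsError("need at least 4 assay points to fit")
    s = np.array([p.substrate_conc for p in data], dtype=float)
    v = np.array([p.rate for p in data], dtype=float)
    if np.allclose(s, s[0]):
        raise KineticsError("all substrate concentrations equal; cannot fit KM")

    kcat0 = float(np.max(v))
    if kcat0 <= 0:
        raise KineticsError("all rates non-positive; nothing to fit")
    km0 = float(s[np.argmin(np.abs(v - kcat0 / 2.0))])
    km0 = max(km0, 1e-9)

    if weighting == "1/v2":
        sigma = np.maximum(np.abs(v), 1e-12)
    elif weighting == "none":
        sigma = None
    else:
        raise KineticsError(f"unknown weighting {weighting!r}")

    def model(sv, kcat, km):
        return kcat * sv / (km + sv)

    try:
        popt, pcov = curve_fit(
            model,
            s,
            v,
            p0=(kcat0, km0),
            sigma=sigma,
            absolute_sigma=False,
            bounds=((1e-12, 1e-12), (np.inf, np.inf)),
            maxfev=10000,
        )
    except RuntimeError as exc:
        raise KineticsError(f"Michaelis-Menten fit did not converge: {exc}") from exc
    se = np.sqrt(np.maximum(np.diag(pcov), 0.0))
    return KineticParams(
        kcat=float(popt[0]),
        km=float(popt[1]),
        kcat_se=float(se[0]),
        km_se=float(se[1]),
    )


def ru5p_equilibrium(r5p_initial: float, keq: float = 0.458) -> float:
    """Equilibrium Ru5P concentration from an initial R5P pool (mM).

    The isomerase partitions a conserved pentose-phosphate pool:
    [Ru5P]_eq = total * Keq / (1 + Keq), with Keq = [Ru5P]/[R5P] = 0.458 for
    the ribose-5-phosphate isomerase reaction.
    """
    if r5p_initial <= 0:
        raise KineticsError("initial R5P must be positive")
    if keq < 0:
        raise KineticsError("Keq must be non-negative")
    return r5p_initial * keq / (1.0 + keq)
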