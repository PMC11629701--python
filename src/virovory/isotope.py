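"""Stable-isotope bookkeeping for 13C/15N-labelled virus tracing.

Secondary-ion mass spectrometry reports carbon as the diatomic ratio
13C12C-/12C2- and nitrogen as 12C15N-/12C14N-.  Under independent binomial
assembly of the two-carbon ion from a pool with 13C atom fraction f,

    P(12C2) = (1-f)^2,  P(13C12C) = 2 f (1-f)

so the measured dimer ratio is 2 f/(1-f), i.e. exactly twice the atomic
13C/12C ratio, at every enrichment.  The CN ion carries a single nitrogen,
so its ratio equals the atomic 15N/14N ratio directly.

Enrichment is expressed either as atom percent excess (APE), the measured
rare-isotope atom percent above natural abundance, or as X_net: the
percent of a cell's carbon (or nitrogen) derived from the labelled
substrate, obtained by linear two-end-member mixing between the
natural-abundance composition and the substrate composition.  Under
exponential growth in which all newly synthesised biomass comes from the
substrate, X_net after d divisions is 100*(1 - 2^-d); 50% therefore marks
one division and 75% two.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

__all__ = [
    "IsotopeConstants",
    "IsotopeMeasurement",
    "carbon_ion_ratio_to_atom_fraction",
    "nitrogen_ion_ratio_to_atom_fraction",
    "atom_fraction_to_carbon_ion_ratio",
    "atom_fraction_to_nitrogen_ion_ratio",
    "ape",
    "x_net",
    "divisions_from_xnet",
    "xnet_from_divisions",
]

ArrayLike = Union[float, np.ndarray]

# Natural abundances: 13C on the VPDB scale, 15N from atmospheric N2.
NATURAL_13C_ATOM_FRACTION = 0.0111
NATURAL_15N_ATOM_FRACTION = 0.003676


@dataclass(frozen=True)
class IsotopeConstants:
    """Natural-abundance baselines and labelled-substrate end members.

    The source fractions default to the enrichment of the labelled virus
    stock (~40 at% 13C, ~80 at% 15N) but are per-experiment settings:
    labelling varies batch to batch.
    """

    f13C_nat: float = NATURAL_13C_ATOM_FRACTION
    f15N_nat: float = NATURAL_15N_ATOM_FRACTION
    f13C_source: float = 0.40
    f15N_source: float = 0.80

    def __post_init__(self) -> None:
        for nat, src, elem in (
            (self.f13C_nat, self.f13C_source, "13C"),
            (self.f15N_nat, self.f15N_source, "15N"),
        ):
            if not 0.0 < nat < src <= 1.0:
                raise ValueError(
                    f"{elem}: need 0 < natural fraction ({nat}) < source fraction ({src}) <= 1"
                )


def _check_nonnegative(value: ArrayLike, name: str) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if np.any(arr < 0) or np.any(~np.isfinite(arr)):
        raise ValueError(f"{name} must be finite and >= 0")
    return arr


def _check_fraction(value: ArrayLike, name: str) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1) or np.any(~np.isfinite(arr)):
        raise ValueError(f"{name} must lie in [0, 1]")
    return arr


def carbon_ion_ratio_to_atom_fraction(R_dimer: ArrayLike) -> ArrayLike:
    """13C atom fraction from the measured 13C12C-/12C2- dimer ratio.

    R = 2f/(1-f) under binomial pairing, so f = R/(R + 2).
    """
    R = _check_nonnegative(R_dimer, "dimer ratio")
    f = R / (R + 2.0)
    return float(f) if np.isscalar(R_dimer) else f


def nitrogen_ion_ratio_to_atom_fraction(R_CN: ArrayLike) -> ArrayLike:
    """15N atom fraction from the measured 12C15N-/12C14N- ratio (= 15N/14N)."""
    R = _check_nonnegative(R_CN, "CN ion ratio")
    f = R / (1.0 + R)
    return float(f) if np.isscalar(R_CN) else f


def atom_fraction_to_carbon_ion_ratio(f13C: ArrayLike) -> ArrayLike:
    """Inverse of :func:`carbon_ion_ratio_to_atom_fraction` (f must be < 1)."""
    f = _check_fraction(f13C, "f13C")
    if np.any(f >= 1.0):
        raise ValueError("f13C must be < 1 for a finite dimer ratio")
    R = 2.0 * f / (1.0 - f)
    return float(R) if np.isscalar(f13C) else R


def atom_fraction_to_nitrogen_ion_ratio(f15N: ArrayLike) -> ArrayLike:
    f = _check_fraction(f15N, "f15N")
    if np.any(f >= 1.0):
        raise ValueError("f15N must be < 1 for a finite CN ratio")
    R = f / (1.0 - f)
    return float(R) if np.isscalar(f15N) else R


def ape(f_meas: ArrayLike, f_nat: float) -> ArrayLike:
    """Atom percent excess: 100*(f_meas - f_nat), in at%.

    Negative values (measurement noise below natural abundance) are
    preserved; flooring at zero is a presentation choice, not applied here.
    """
    f = _check_fraction(f_meas, "f_meas")
    _check_fraction(f_nat, "f_nat")
    out = 100.0 * (f - f_nat)
    return float(out) if np.isscalar(f_meas) else out


def x_net(f_meas: ArrayLike, f_nat: float, f_source: float) -> ArrayLike:
    """Percent of an element derived from the labelled substrate.

    Linear two-end-member mixing between the natural-abundance baseline
    and the substrate composition:
    X_net = 100*(f_meas - f_nat)/(f_source - f_nat).
    """
    f = _check_fraction(f_meas, "f_meas")
    _check_fraction(f_nat, "f_nat")
    _check_fraction(f_source, "f_source")
    if f_source <= f_nat:
        raise ValueError(
            f"degenerate mixing line: f_source ({f_source}) must exceed f_nat ({f_nat})"
        )
    out = 100.0 * (f - f_nat) / (f_source - f_nat)
    return float(out) if np.isscalar(f_meas) else out


def divisions_from_xnet(xnet_percent: ArrayLike) -> ArrayLike:
    """Implied division count from X_net under fully substrate-fed growth.

    Each division doubles biomass with all new biomass substrate-derived,
    so X_net(d) = 100*(1 - 2^-d) and d = -log2(1 - X_net/100).
    """
    x = np.asarray(xnet_percent, dtype=float)
    if np.any(x < 0) or np.any(~np.isfinite(x)):
        raise ValueError("X_net must be finite and >= 0")
    if np.any(x >= 100.0):
        raise ValueError("X_net >= 100% implies infinite divisions")
    d = -np.log2(1.0 - x / 100.0)
    return float(d) if np.isscalar(xnet_percent) else d


def xnet_from_divisions(divisions: ArrayLike) -> ArrayLike:
    """X_net (%) after ``divisions`` doublings on purely substrate-derived growth."""
    d = np.asarray(divisions, dtype=float)
    if np.any(d < 0):
        raise ValueError("division count must be >= 0")
    x = 100.0 * (1.0 - 2.0 ** (-d))
    return float(x) if np.isscalar(divisions) else x


@dataclass(frozen=True)
class IsotopeMeasurement:
    """Derived isotope quantities for one ROI or cell.

    ``c_net``/``n_net`` are X_net for carbon and nitrogen (percent of
    biomass element from the labelled substrate); division counts are
    reported only where X_net < 100% and >= 0.
    """

    f13C: float
    f15N: float
    ape13C: float
    ape15N: float
    c_net: float
    n_net: float
    divisions_C: float
    divisions_N: float
    constants: IsotopeConstants

    @classmethod
    def from_atom_fractions(
        cls, f13C: float, f15N: float, constants: IsotopeConstants | None = None
    ) -> "IsotopeMeasurement":
        c = constants or IsotopeConstants()
        c_net = x_net(f13C, c.f13C_nat, c.f13C_source)
        n_net = x_net(f15N, c.f15N_nat, c.f15N_source)

        def _div(x: float) -> float:
            if 0.0 <= x < 100.0:
                return float(divisions_from_xnet(x))
            return float("nan")

        return cls(
            f13C=float(f13C),
            f15N=float(f15N),
            ape13C=ape(f13C, c.f13C_nat),
            ape15N=ape(f15N, c.f15N_nat),
            c_net=float(c_net),
            n_net=float(n_net),
            divisions_C=_div(float(c_net)),
            divisions_N=_div(float(n_net)),
            constants=c,
        )

    @classmethod
    def from_ion_ratios(
        cls, R_dimer: float, R_CN: float, constants: IsotopeConstants | None = None
    ) -> "IsotopeMeasurement":
        return cls.from_atom_fractions(
            carbon_ion_ratio_to_atom_fraction(R_dimer),
            nitrogen_ion_ratio_to_atom_fraction(R_CN),
            constants,
        )
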