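"""Exact algebra relating conversion, yield, enantiomer fractions and ee.

Sign convention used throughout the package: enantiomeric excess is signed
with the (R)-enantiomer positive, ``ee = (R - S) / (R + S)``.  Yields and
conversions are molar fractions of the initial substrate.

The central scientific result here is the oxidation-only bound: starting from
an alcohol of enantiomeric excess ``ee0``, no enantioselective *oxidation*
(however selective, and with any amount of unselective back-oxidation) can
raise the (R)-alcohol amount above its initial value ``(1 + ee0) / 2``.
Observing more (R)-alcohol than that proves a reduction step (re-reduction of
the intermediate ketone) took place — the tandem redox signature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "EnantiomerSplit",
    "ee_from_amounts",
    "split_from_ee",
    "max_R_yield_oxidation_only",
    "infer_reduction_present",
    "kinetic_resolution_E",
    "E_CAP",
]

#: Sentinel returned by :func:`kinetic_resolution_E` for (numerically) perfect
#: resolutions, where the true E diverges.
E_CAP = 1e6


@dataclass(frozen=True)
class EnantiomerSplit:
    """Partition of the alcohol pool into (R) and (S) enantiomers.

    All quantities are fractions of the initial substrate amount.
    ``ee`` is ``nan`` when ``total_alcohol`` is zero (undefined).
    """

    total_alcohol: float
    ee: float
    R_fraction: float
    S_fraction: float


def ee_from_amounts(R: float, S: float) -> float:
    """Signed enantiomeric excess ``(R - S) / (R + S)``, (R) positive.

    Raises
    ------
    ValueError
        If either amount is negative or both are zero (ee undefined).
    """
    if R < 0 or S < 0:
        raise ValueError(f"enantiomer amounts must be >= 0, got R={R}, S={S}")
    total = R + S
    if total == 0:
        raise ValueError("ee undefined: R + S = 0")
    return (R - S) / total


def split_from_ee(total_alcohol: float, ee: float) -> EnantiomerSplit:
    """Recover enantiomer fractions from a total alcohol fraction and its ee.

    ``R = total * (1 + ee) / 2`` and ``S = total * (1 - ee) / 2``; round-trips
    with :func:`ee_from_amounts`.  For ``total_alcohol == 0`` the split is
    degenerate and ``ee`` is reported as ``nan``.
    """
    if not 0.0 <= total_alcohol <= 1.0:
        raise ValueError(f"total_alcohol must be in [0, 1], got {total_alcohol}")
    if not -1.0 <= ee <= 1.0:
        raise ValueError(f"ee must be in [-1, 1], got {ee}")
    if total_alcohol == 0.0:
        return EnantiomerSplit(0.0, math.nan, 0.0, 0.0)
    R = total_alcohol * (1.0 + ee) / 2.0
    S = total_alcohol * (1.0 - ee) / 2.0
    return EnantiomerSplit(total_alcohol, ee, R, S)


def max_R_yield_oxidation_only(initial_ee: float) -> float:
    """Supremum of the (R)-alcohol yield attainable by oxidation alone.

    If the only available reaction consumes alcohol (oxidation to the ketone),
    the (R)-alcohol pool can never grow, so its yield is bounded by its
    initial fraction ``(1 + initial_ee) / 2``.  For a racemate the bound is
    exactly 50 %; exceeding it implies the ketone was re-reduced.
    """
    if not -1.0 <= initial_ee <= 1.0:
        raise ValueError(f"initial_ee must be in [-1, 1], got {initial_ee}")
    return (1.0 + initial_ee) / 2.0


def infer_reduction_present(
    observed: EnantiomerSplit, initial_ee: float
) -> tuple[bool, float]:
    """Decide whether a reduction step must have occurred.

    Returns ``(present, margin)`` where ``margin = observed.R_fraction -
    max_R_yield_oxidation_only(initial_ee)``.  The inference is conservative:
    exact equality with the bound returns ``False`` — claiming re-reduction
    requires a strict excess of (R)-alcohol over what selective destruction of
    (S)-alcohol could leave behind.
    """
    bound = max_R_yield_oxidation_only(initial_ee)
    margin = observed.R_fraction - bound
    return margin > 0.0, margin


def kinetic_resolution_E(conversion: float, ee_substrate: float) -> float:
    """Enantioselectivity ratio E of an irreversible kinetic resolution.

    Standard relation from conversion ``c`` and residual-substrate ee:
    ``E = ln[(1 - c)(1 - ee_s)] / ln[(1 - c)(1 + ee_s)]``, valid for two
    competing irreversible first-order consumptions of the enantiomers
    (``E = k_fast / k_slow``).  If a back-reaction (re-reduction) is active
    the relation is only an effective, time-dependent estimate.

    Returns :data:`E_CAP` when the slow enantiomer is numerically untouched
    (perfect resolution); raises for ``c`` of exactly 0 or 1 where E is
    undefined.
    """
    if not 0.0 < conversion < 1.0:
        raise ValueError(f"E undefined at conversion {conversion}")
    if not 0.0 <= ee_substrate < 1.0 + 1e-12:
        raise ValueError(f"ee_substrate must be in [0, 1), got {ee_substrate}")
    num = math.log((1.0 - conversion) * (1.0 - ee_substrate))
    den = math.log((1.0 - conversion) * (1.0 + ee_substrate))
    if den >= 0.0 or not math.isfinite(num):
        return E_CAP
    E = num / den
    return min(E, E_CAP)
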