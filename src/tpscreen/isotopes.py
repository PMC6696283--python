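"""Isotope-pattern simulation and goodness-of-fit scoring.

Patterns are aggregated at nominal-mass resolution (integer Da offsets from
the monoisotopic peak): a TOF instrument at the resolving power used for
small-molecule suspect screening separates the M, M+1, M+2 ... envelope but
not its fine structure (13C vs 2H vs 17O within one bin). Each bin carries
the abundance-weighted mean mass of its isotopologues.

The fit score is a root-mean-square deviation of base-peak-normalised
abundances over the union of occupied bins — a deterministic, scale-invariant
stand-in for vendor "Sigma"-style isotope-fit metrics, with 0 meaning a
perfect fit and larger values a worse one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

from .chemcore import (
    ADDUCT_FORMULAS,
    AdductIon,
    ElementTable,
    Formula,
)

__all__ = ["IsotopePattern", "theoretical_pattern", "sigma_score"]


class IncomparablePatternError(ValueError):
    """Two patterns share no nominal-mass bin."""


@dataclass(frozen=True)
class IsotopePattern:
    """Centroided isotope envelope: (mass, abundance) with base peak = 1.0."""

    peaks: Tuple[Tuple[float, float], ...]

    def __post_init__(self) -> None:
        if not self.peaks:
            raise ValueError("pattern must contain at least one peak")
        masses = [m for m, _ in self.peaks]
        if any(b <= a for a, b in zip(masses, masses[1:])):
            raise ValueError("peak masses must be strictly increasing")
        abund = [a for _, a in self.peaks]
        if not any(abs(a - 1.0) < 1e-12 for a in abund):
            raise ValueError("pattern must contain a base peak of abundance 1")
        if any(a <= 0 or a > 1 + 1e-12 for a in abund):
            raise ValueError("abundances must lie in (0, 1]")

    @property
    def masses(self) -> Tuple[float, ...]:
        return tuple(m for m, _ in self.peaks)

    @property
    def abundances(self) -> Tuple[float, ...]:
        return tuple(a for _, a in self.peaks)


# (probability, probability-weighted mean mass) per nominal-offset bin
_Dist = List[Tuple[float, float]]


def _convolve(a: _Dist, b: _Dist, max_bins: int) -> _Dist:
    out_p = [0.0] * min(len(a) + len(b) - 1, max_bins)
    out_m = [0.0] * len(out_p)
    for i, (pa, ma) in enumerate(a):
        if pa == 0.0:
            continue
        for j, (pb, mb) in enumerate(b):
            k = i + j
            if k >= len(out_p) or pb == 0.0:
                continue
            p = pa * pb
            out_p[k] += p
            out_m[k] += p * (ma + mb)
    return [(p, m / p if p > 0 else 0.0) for p, m in zip(out_p, out_m)]


def _element_power(isotopes, count: int, max_bins: int) -> _Dist:
    """Distribution of `count` atoms of one element, by nominal-mass offset."""
    base_nominal = isotopes[0].nominal
    single: _Dist = [(0.0, 0.0)] * (isotopes[-1].nominal - base_nominal + 1)
    for iso in isotopes:
        single[iso.nominal - base_nominal] = (iso.abundance, iso.exact_mass)
    result: _Dist = [(1.0, 0.0)]
    power = single
    n = count
    while n:  # exponentiation by squaring
        if n & 1:
            result = _convolve(result, power, max_bins)
        n >>= 1
        if n:
            power = _convolve(power, power, max_bins)
    return result


def theoretical_pattern(
    ion: AdductIon | Formula,
    prune: float = 1e-4,
    max_peaks: int = 6,
    table: ElementTable | None = None,
) -> IsotopePattern:
    """Aggregated isotope pattern of an adduct ion (or bare neutral formula).

    Per-element multinomial distributions are convolved over nominal-mass
    offsets; abundances are normalised to the base peak and bins below
    ``prune`` (fraction of base peak) are dropped, keeping at most
    ``max_peaks`` bins. For a cation the electron mass is subtracted from
    every centroid.
    """
    if not 0 < prune <= 0.1:
        raise ValueError("prune must lie in (0, 0.1]")
    if max_peaks < 2:
        raise ValueError("max_peaks must be >= 2")
    table = table or ElementTable.default()

    if isinstance(ion, Formula):
        composition, charge = ion, 0
    else:
        composition = ion.neutral + ADDUCT_FORMULAS[ion.adduct]
        charge = ion.charge

    max_bins = max_peaks + 4  # headroom before pruning
    dist: _Dist = [(1.0, 0.0)]
    for sym, count in composition:
        dist = _convolve(dist, _element_power(table.isotopes[sym], count,
                                              max_bins), max_bins)

    base = max(p for p, _ in dist) if dist else 0.0
    peaks = []
    for p, m in dist:
        if base > 0 and p / base >= prune:
            mz = (m - charge * table.electron_mass) / max(charge, 1)
            peaks.append((mz, p / base))
    peaks = peaks[:max_peaks]
    if not peaks:  # empty formula: single zero-mass bin
        peaks = [(0.0, 1.0)]
    return IsotopePattern(tuple(peaks))


def _bins(pattern: IsotopePattern, ref: float) -> Dict[int, float]:
    """Normalised abundance per integer nominal-mass offset from ``ref``."""
    out: Dict[int, float] = {}
    for m, a in pattern.peaks:
        out[round(m - ref)] = a
    return out


def sigma_score(theoretical: IsotopePattern,
                observed: IsotopePattern) -> float:
    """RMS deviation of normalised abundances over matched nominal bins.

    Peaks are matched by nearest nominal-mass bin (integer Da offset from
    the theoretical monoisotopic peak). A bin occupied in only one pattern
    contributes its full abundance as the deviation. 0 = perfect fit;
    symmetric in its arguments when both envelopes are complete; invariant
    under rescaling either pattern (both are base-peak normalised by
    construction).
    """
    ref = theoretical.masses[0]
    tb, ob = _bins(theoretical, ref), _bins(observed, ref)
    keys = sorted(set(tb) | set(ob))
    if not set(tb) & set(ob):
        raise IncomparablePatternError("patterns share no nominal-mass bin")
    sq = [(tb.get(k, 0.0) - ob.get(k, 0.0)) ** 2 for k in keys]
    return (sum(sq) / len(sq)) ** 0.5
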