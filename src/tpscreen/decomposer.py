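"""Accurate-mass molecular formula decomposition and candidate ranking.

Given an observed m/z, enumerate every elemental composition over
{C, H, N, O, Na} whose adduct m/z falls within a ppm tolerance, under
per-element count bounds, and rank the candidates by isotope fit and mass
error. The ppm window is applied on the adduct m/z (the measured quantity),
not on the back-computed neutral mass.

Enumeration is exact: nested bounded loops over Na, N, O and C with the
hydrogen count solved by mass closure inside the residual window, with
branch-and-bound pruning on the partial mass. At the default bounds this
visits a few thousand lattice points per adduct.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .chemcore import (
    ADDUCT_FORMULAS,
    AdductIon,
    ElementTable,
    Formula,
    adduct_mz,
    monoisotopic_mass,
    ppm_error,
)
from .isotopes import IsotopePattern, sigma_score, theoretical_pattern

__all__ = [
    "ElementBounds",
    "CandidateFormula",
    "decompose",
    "rank",
    "subformula_candidates",
    "rdbe",
]

logger = logging.getLogger(__name__)

#: Wide enough to cover a C36 polyether scaffold and its transformation
#: products plus distractors; N and Na admit adduct-bound atoms only.
DEFAULT_BOUNDS: Dict[str, Tuple[int, int]] = {
    "C": (0, 60), "H": (0, 120), "N": (0, 2), "O": (0, 20), "Na": (0, 1),
}

_LATTICE_GUARD = 100_000_000


class ResourceGuardError(ValueError):
    """Bounds admit too many lattice points; tighten them."""


@dataclass(frozen=True)
class ElementBounds:
    """Per-element (min, max) count bounds for the enumeration."""

    bounds: Mapping[str, Tuple[int, int]]

    def __post_init__(self) -> None:
        table = ElementTable.default()
        for sym, (lo, hi) in self.bounds.items():
            if sym not in table.isotopes:
                raise ValueError(f"element {sym!r} outside the alphabet")
            if not 0 <= lo <= hi:
                raise ValueError(f"invalid bounds for {sym}: ({lo}, {hi})")
        object.__setattr__(self, "bounds", dict(self.bounds))

    @classmethod
    def default(cls) -> "ElementBounds":
        return cls(DEFAULT_BOUNDS)

    def get(self, sym: str) -> Tuple[int, int]:
        return self.bounds.get(sym, (0, 0))

    def lattice_size(self) -> int:
        n = 1
        for lo, hi in self.bounds.values():
            n *= hi - lo + 1
        return n


@dataclass(frozen=True)
class CandidateFormula:
    """One decomposition hit: neutral formula + adduct with its mass errors."""

    formula: Formula
    adduct: str
    mz_calc: float
    ppm: float
    rdbe: float
    sigma: Optional[float] = None


def rdbe(f: Formula) -> float:
    """Ring + double bond equivalents C − H/2 + N/2 + 1 (Na excluded)."""
    return f["C"] - f["H"] / 2 + f["N"] / 2 + 1


def decompose(
    observed_mz: float,
    adducts: Iterable[str] = ("+Na",),
    tol: float = 3.0,
    bounds: ElementBounds | None = None,
    rdbe_filter: bool = True,
    rdbe_range: Tuple[float, float] = (0.0, 40.0),
    table: ElementTable | None = None,
) -> List[CandidateFormula]:
    """All formulas whose adduct m/z lies within ``tol`` ppm of the observed.

    Exhaustive over the bounded lattice for each adduct species; each
    (formula, adduct) pair appears exactly once. The optional RDBE filter
    keeps candidates with ring-double-bond equivalents inside ``rdbe_range``
    computed on the neutral formula. Result sorted by \\|ppm\\| ascending
    (ties: formula text, adduct).
    """
    if observed_mz <= 0:
        raise ValueError("observed m/z must be positive")
    if tol <= 0:
        raise ValueError("ppm tolerance must be positive")
    bounds = bounds or ElementBounds.default()
    if bounds.lattice_size() > _LATTICE_GUARD:
        raise ResourceGuardError(
            f"bounds admit more than {_LATTICE_GUARD:.0e} candidate lattice "
            "points; tighten the element bounds")
    table = table or ElementTable.default()

    out: List[CandidateFormula] = []
    m = {sym: table.monoisotopic(sym) for sym in ("C", "H", "N", "O", "Na")}
    # slightly widened window; the exact per-candidate ppm check is final
    half_width = observed_mz * tol * 1e-6 + 1e-9
    for adduct in adducts:
        if adduct not in ADDUCT_FORMULAS:
            raise ValueError(f"unsupported adduct species {adduct!r}")
        shift = monoisotopic_mass(ADDUCT_FORMULAS[adduct], table)
        # neutral-mass window equivalent to |ppm| <= tol on the adduct m/z
        lo_m = observed_mz - half_width - shift + table.electron_mass
        hi_m = observed_mz + half_width - shift + table.electron_mass
        (c0, c1), (h0, h1) = bounds.get("C"), bounds.get("H")
        (n0, n1), (o0, o1) = bounds.get("N"), bounds.get("O")
        na0, na1 = bounds.get("Na")
        for na in range(na0, na1 + 1):
            m_na = na * m["Na"]
            if m_na > hi_m:
                break
            for n in range(n0, n1 + 1):
                m_n = m_na + n * m["N"]
                if m_n > hi_m:
                    break
                for o in range(o0, o1 + 1):
                    m_o = m_n + o * m["O"]
                    if m_o > hi_m:
                        break
                    for c in range(c0, c1 + 1):
                        m_c = m_o + c * m["C"]
                        if m_c > hi_m:
                            break
                        # H solved by mass closure within the window
                        h_lo = max(h0, int((lo_m - m_c) / m["H"]) - 1)
                        while h_lo * m["H"] + m_c < lo_m:
                            h_lo += 1
                        h_hi = min(h1, int((hi_m - m_c) / m["H"]))
                        for h in range(h_lo, h_hi + 1):
                            counts = {"C": c, "H": h, "N": n, "O": o, "Na": na}
                            f = Formula(counts)
                            ion = AdductIon(f, adduct)
                            mz_calc = adduct_mz(ion, table)
                            ppm = ppm_error(observed_mz, mz_calc)
                            if abs(ppm) > tol:
                                continue
                            r = rdbe(f)
                            if rdbe_filter and not (
                                    rdbe_range[0] <= r <= rdbe_range[1]):
                                continue
                            out.append(CandidateFormula(
                                f, adduct, mz_calc, ppm, r))
    out.sort(key=lambda cand: (abs(cand.ppm), str(cand.formula), cand.adduct))
    return out


def rank(
    candidates: Sequence[CandidateFormula],
    observed_pattern: IsotopePattern | None = None,
    prune: float = 1e-4,
    max_peaks: int = 6,
) -> List[CandidateFormula]:
    """Rank candidates by isotope fit, then |ppm|, then formula text.

    The sigma score is computed per candidate from its theoretical pattern
    against the shared observed pattern. Without an observed pattern the
    ranking degrades to |ppm| only (logged as a warning).
    """
    if observed_pattern is None:
        logger.warning("no observed isotope pattern; ranking by |ppm| only")
        scored = list(candidates)
        scored.sort(key=lambda c: (abs(c.ppm), str(c.formula), c.adduct))
        return scored
    scored = []
    for cand in candidates:
        pattern = theoretical_pattern(
            AdductIon(cand.formula, cand.adduct), prune, max_peaks)
        scored.append(replace(
            cand, sigma=sigma_score(pattern, observed_pattern)))
    scored.sort(key=lambda c: (c.sigma, abs(c.ppm), str(c.formula), c.adduct))
    return scored


def subformula_candidates(
    fragment_mz: float,
    precursor: CandidateFormula,
    tol: float = 3.0,
    adducts: Iterable[str] = ("+H", "+Na"),
    table: ElementTable | None = None,
) -> List[CandidateFormula]:
    """Fragment formulas restricted to elementwise subsets of the precursor.

    Supports generic MS/MS subformula annotation: the element bounds are the
    precursor's own neutral counts, so every fragment is an elementwise
    subset of the precursor composition.
    """
    if fragment_mz > precursor.mz_calc * (1 + tol * 1e-6):
        raise ValueError("fragment m/z exceeds the precursor m/z")
    avail = precursor.formula
    sub_bounds = ElementBounds(
        {sym: (0, avail[sym]) for sym in ("C", "H", "N", "O", "Na")})
    out: List[CandidateFormula] = []
    for adduct in adducts:
        out.extend(decompose(fragment_mz, (adduct,), tol, sub_bounds,
                             rdbe_filter=False, table=table))
    out.sort(key=lambda cand: (abs(cand.ppm), str(cand.formula), cand.adduct))
    return out
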