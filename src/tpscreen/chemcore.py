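"""Element data, formula arithmetic and adduct m/z computation.

All mass arithmetic in the package runs through :class:`Formula` objects over
the five-element alphabet {C, H, N, O, Na} — carbon/hydrogen/oxygen for the
polyether scaffold of monensin-like analytes, nitrogen and sodium for the
ammonium and sodium adduct chemistry of electrospray ionisation. Monoisotopic
masses and isotope abundances ship as a versioned CSV resource
(``data/elements.csv``, IUPAC monoisotopic values).

Observed cations are modelled as singly charged adducts [M+H]+, [M+Na]+ or
[M+NH4]+; ``adduct_mz`` subtracts one electron mass, which is the convention
that reproduces published four-decimal m/z values for sodiated polyethers.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Iterator, Mapping, Tuple

__all__ = [
    "ELECTRON_MASS",
    "ElementTable",
    "Formula",
    "AdductIon",
    "ADDUCTS",
    "monoisotopic_mass",
    "adduct_mz",
    "adduct_pair_delta",
    "ppm_error",
    "formula_diff",
    "split_sodium",
]

#: CODATA electron rest mass in Da.
ELECTRON_MASS = 0.00054858

#: Composition (atoms added to the neutral) of each supported adduct species.
ADDUCTS: Dict[str, Dict[str, int]] = {
    "+H": {"H": 1},
    "+Na": {"Na": 1},
    "+NH4": {"N": 1, "H": 4},
}


class AlphabetError(ValueError):
    """An element symbol outside the supported alphabet."""


class AdductError(ValueError):
    """An adduct species outside the configured adduct set."""


@dataclass(frozen=True)
class Isotope:
    nominal: int
    exact_mass: float
    abundance: float


class ElementTable:
    """Isotope masses and abundances for the supported element alphabet.

    Loaded from a CSV resource with columns symbol, nominal, exact_mass,
    abundance. Per element, isotopes are sorted by exact mass; abundances
    must sum to 1 within 1e-6.
    """

    def __init__(self, isotopes: Mapping[str, Tuple[Isotope, ...]],
                 electron_mass: float = ELECTRON_MASS) -> None:
        self.isotopes: Dict[str, Tuple[Isotope, ...]] = {}
        self.electron_mass = electron_mass
        for sym, isos in isotopes.items():
            isos = tuple(sorted(isos, key=lambda i: i.exact_mass))
            total = sum(i.abundance for i in isos)
            if abs(total - 1.0) > 1e-6:
                raise ValueError(
                    f"abundances for {sym} sum to {total!r}, expected 1")
            masses = [i.exact_mass for i in isos]
            if any(b <= a for a, b in zip(masses, masses[1:])):
                raise ValueError(f"isotope masses for {sym} not increasing")
            self.isotopes[sym] = isos

    @classmethod
    def default(cls) -> "ElementTable":
        return _DEFAULT_TABLE

    @classmethod
    def from_csv(cls, path_or_file) -> "ElementTable":
        if hasattr(path_or_file, "read"):
            rows = list(csv.DictReader(path_or_file))
        else:
            with open(path_or_file, newline="") as fh:
                rows = list(csv.DictReader(fh))
        isotopes: Dict[str, list] = {}
        for row in rows:
            isotopes.setdefault(row["symbol"], []).append(
                Isotope(int(row["nominal"]), float(row["exact_mass"]),
                        float(row["abundance"])))
        return cls({k: tuple(v) for k, v in isotopes.items()})

    @property
    def alphabet(self) -> Tuple[str, ...]:
        return tuple(self.isotopes)

    def monoisotopic(self, symbol: str) -> float:
        """Exact mass of the lightest (principal) isotope of ``symbol``."""
        try:
            return self.isotopes[symbol][0].exact_mass
        except KeyError:
            raise AlphabetError(f"unknown element symbol {symbol!r}") from None


def _load_default_table() -> ElementTable:
    ref = resources.files("tpscreen.data").joinpath("elements.csv")
    with ref.open(newline="") as fh:
        return ElementTable.from_csv(fh)


_DEFAULT_TABLE = _load_default_table()

# Hill order for the fixed alphabet: C, H, then alphabetical.
_HILL_ORDER = ("C", "H", "N", "Na", "O")
_TOKEN_RE = re.compile(r"([A-Z][a-z]?)_?(\d*)_?")


@dataclass(frozen=True)
class Formula:
    """An elemental composition over {C, H, N, O, Na}; immutable and hashable.

    Supports + and - (elementwise; subtraction may not go negative) and
    parses both plain Hill notation ("C36H62O11") and the underscored table
    dialect ("C_36_H_62_O_11_Na").
    """

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        table = ElementTable.default()
        clean = {}
        for sym, n in self.counts.items():
            if sym not in table.isotopes:
                raise AlphabetError(f"unknown element symbol {sym!r}")
            if not isinstance(n, int) or n < 0:
                raise ValueError(f"count for {sym} must be a non-negative int")
            if n:
                clean[sym] = n
        object.__setattr__(self, "counts", dict(clean))

    @classmethod
    def parse(cls, text: str) -> "Formula":
        """Parse "C36H62O11" or the underscored dialect "C_36_H_62_O_11_Na"."""
        stripped = text.strip()
        counts: Dict[str, int] = {}
        pos = 0
        for m in _TOKEN_RE.finditer(stripped):
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {text!r}")
            if not m.group(0):
                break
            sym, num = m.group(1), m.group(2)
            counts[sym] = counts.get(sym, 0) + (int(num) if num else 1)
            pos = m.end()
        if pos != len(stripped) or (stripped and not counts):
            raise ValueError(f"cannot parse formula {text!r}")
        return cls(counts)

    def __str__(self) -> str:
        parts = []
        for sym in _HILL_ORDER:
            n = self.counts.get(sym, 0)
            if n == 1:
                parts.append(sym)
            elif n > 1:
                parts.append(f"{sym}{n}")
        return "".join(parts)

    def __getitem__(self, sym: str) -> int:
        return self.counts.get(sym, 0)

    def __iter__(self) -> Iterator[Tuple[str, int]]:
        return iter(self.counts.items())

    def __bool__(self) -> bool:
        return bool(self.counts)

    def __hash__(self) -> int:
        return hash(frozenset(self.counts.items()))

    def __eq__(self, other) -> bool:
        if isinstance(other, Formula):
            return self.counts == other.counts
        return NotImplemented

    def __add__(self, other: "Formula") -> "Formula":
        merged = dict(self.counts)
        for sym, n in other.counts.items():
            merged[sym] = merged.get(sym, 0) + n
        return Formula(merged)

    def __sub__(self, other: "Formula") -> "Formula":
        merged = dict(self.counts)
        for sym, n in other.counts.items():
            merged[sym] = merged.get(sym, 0) - n
        return Formula(merged)

    def apply_delta(self, delta: Mapping[str, int]) -> "Formula":
        """Apply a signed element-count delta; raises if any count goes < 0."""
        merged = dict(self.counts)
        for sym, n in delta.items():
            merged[sym] = merged.get(sym, 0) + n
        return Formula(merged)

    def contains(self, other: "Formula") -> bool:
        return all(self[sym] >= n for sym, n in other.counts.items())


#: Neutral compositions of the supported adducts, as Formula objects.
ADDUCT_FORMULAS: Dict[str, Formula] = {
    name: Formula(atoms) for name, atoms in ADDUCTS.items()
}


@dataclass(frozen=True)
class AdductIon:
    """A singly charged cation: neutral molecule plus +H, +Na or +NH4."""

    neutral: Formula
    adduct: str
    charge: int = 1

    def __post_init__(self) -> None:
        if self.adduct not in ADDUCTS:
            raise AdductError(f"unsupported adduct species {self.adduct!r}")
        if self.charge != 1:
            raise ValueError("only singly charged cations are supported")


def monoisotopic_mass(f: Formula, table: ElementTable | None = None) -> float:
    """Monoisotopic (lightest-isotope) mass of a neutral formula in Da."""
    table = table or ElementTable.default()
    return sum(n * table.monoisotopic(sym) for sym, n in f)


def adduct_mz(ion: AdductIon, table: ElementTable | None = None) -> float:
    """Observable m/z of a singly charged adduct cation.

    (neutral mass + adduct-atom mass - one electron mass) / charge.
    """
    table = table or ElementTable.default()
    m = monoisotopic_mass(ion.neutral, table)
    m += monoisotopic_mass(ADDUCT_FORMULAS[ion.adduct], table)
    return (m - table.electron_mass) / ion.charge


def adduct_pair_delta(a1: str, a2: str,
                      table: ElementTable | None = None) -> float:
    """Signed exact-mass difference a1 − a2 of two adduct species.

    Independent of the neutral: e.g. the [M+Na]+ / [M+NH4]+ spacing of
    4.9554 Da seen as paired peaks for every species in an ammoniated run.
    """
    table = table or ElementTable.default()
    for a in (a1, a2):
        if a not in ADDUCTS:
            raise AdductError(f"unsupported adduct species {a!r}")
    return (monoisotopic_mass(ADDUCT_FORMULAS[a1], table)
            - monoisotopic_mass(ADDUCT_FORMULAS[a2], table))


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass error in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical mass must be positive")
    return 1e6 * (observed - theoretical) / theoretical


def formula_diff(parent: Formula, product: Formula) -> Dict[str, int]:
    """Signed elementwise count difference product − parent."""
    syms = set(parent.counts) | set(product.counts)
    return {s: product[s] - parent[s] for s in sorted(syms)
            if product[s] - parent[s] != 0}


def split_sodium(f: Formula) -> Tuple[Formula, str]:
    """Split a printed "…Na" formula into (neutral, adduct) form.

    Published tables often print the sodiated composition (e.g.
    "C36H62O11Na"); this returns (C36H62O11, "+Na"). A sodium-free formula
    comes back unchanged with adduct "+H" left to the caller's discretion —
    here signalled as an empty string.
    """
    if f["Na"] >= 1:
        return f - Formula({"Na": 1}), "+Na"
    return f, ""
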