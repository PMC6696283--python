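"""Transformation-reaction labelling, suspect lists and structural grouping.

A transformation product (TP) differs from its parent by a net elemental
delta; this module explains such deltas as multisets of elementary reaction
steps (decarboxylation, O-demethylation, dehydration, ...), expands parents
into suspect lists of reachable product formulas with expected adduct m/z,
and groups identified TP records into structural classes.

Reaction deltas are net-atom semantics: R-COOH → R-H is net −CO2,
O-demethylation (OCH3 → OH) is net −CH2. Published shorthand labels can
disagree with the exact elemental difference; the delta derived from the
formulas is authoritative and any printed label is carried as an annotation
only.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .chemcore import AdductIon, Formula, adduct_mz, formula_diff

__all__ = [
    "ReactionStep",
    "DEFAULT_STEPS",
    "TransformationPath",
    "SuspectEntry",
    "TPRecordLike",
    "enumerate_paths",
    "suspect_list",
    "structural_classes",
]


@dataclass(frozen=True)
class ReactionStep:
    """A named elementary transformation with its net element-count delta."""

    name: str
    delta: Mapping[str, int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "delta",
                           {k: v for k, v in self.delta.items() if v})

    def __hash__(self) -> int:
        return hash(self.name)


ISOMERIZATION = ReactionStep("ISOMERIZATION", {})

#: Default elementary-reaction alphabet; names unique, deltas in net atoms.
DEFAULT_STEPS: Tuple[ReactionStep, ...] = (
    ReactionStep("DECARBOXYLATION", {"C": -1, "O": -2}),
    ReactionStep("DEMETHYLATION", {"C": -1, "H": -2}),
    ReactionStep("METHYLATION", {"C": 1, "H": 2}),
    ReactionStep("DEHYDROGENATION", {"H": -2}),
    ReactionStep("HYDROGENATION", {"H": 2}),
    ReactionStep("HYDRATION", {"H": 2, "O": 1}),
    ReactionStep("DEHYDRATION", {"H": -2, "O": -1}),
    ReactionStep("METHANOL_ADDITION", {"C": 1, "H": 4, "O": 1}),
    ISOMERIZATION,
)



@dataclass(frozen=True)
class TransformationPath:
    """A multiset of reaction steps linking a parent formula to a product."""

    parent: Formula
    product: Formula
    steps: Tuple[ReactionStep, ...]
    label: str = field(init=False)

    def __post_init__(self) -> None:
        ordered = tuple(sorted(self.steps, key=lambda s: s.name))
        object.__setattr__(self, "steps", ordered)
        object.__setattr__(self, "label",
                           " + ".join(s.name for s in ordered) or
                           ISOMERIZATION.name)
        total: Dict[str, int] = {}
        for s in ordered:
            for sym, v in s.delta.items():
                total[sym] = total.get(sym, 0) + v
        if {k: v for k, v in total.items() if v} != \
                formula_diff(self.parent, self.product):
            raise ValueError("step deltas do not sum to the formula delta")

    @property
    def n_steps(self) -> int:
        return len(self.steps)


@dataclass(frozen=True)
class SuspectEntry:
    """One suspect-list row: product formula, its path, and expected m/z."""

    formula: Formula
    path: TransformationPath
    adduct: str
    expected_mz: float


def _is_null_padded(combo: Sequence[ReactionStep]) -> bool:
    """True when the combo contains a nonempty zero-delta sub-multiset.

    Covers ISOMERIZATION mixed into longer paths, step/inverse pairs
    (hydration + dehydration, ...) and longer null cycles such as
    demethylation + dehydration + methanol addition.
    """
    if any(s.name == ISOMERIZATION.name for s in combo) and len(combo) > 1:
        return True
    for r in range(1, len(combo) + 1):
        for sub in itertools.combinations(range(len(combo)), r):
            if r == len(combo) and len(combo) == 1:
                continue  # a single real step is never null (deltas nonzero)
            total: Dict[str, int] = {}
            for i in sub:
                for sym, v in combo[i].delta.items():
                    total[sym] = total.get(sym, 0) + v
            if not any(total.values()):
                return True
    return False


def enumerate_paths(
    parent: Formula,
    product: Formula,
    max_steps: int = 3,
    steps: Sequence[ReactionStep] = DEFAULT_STEPS,
) -> List[TransformationPath]:
    """All ≤ ``max_steps`` reaction multisets explaining product − parent.

    Paths are multisets (step order is not modelled); results are sorted by
    step count then canonical label. Null-padded combinations — a step
    together with its exact inverse, or ISOMERIZATION mixed into a longer
    path — are excluded, so an identity delta is explained by the single
    path {ISOMERIZATION}. An empty list is a valid outcome.
    """
    if not 0 <= max_steps <= 4:
        raise ValueError("max_steps must lie in [0, 4]")
    target = formula_diff(parent, product)
    out: List[TransformationPath] = []
    if not target:
        out.append(TransformationPath(parent, product, (ISOMERIZATION,)))
    real_steps = [s for s in steps if s.delta]
    for k in range(1, max_steps + 1):
        for combo in itertools.combinations_with_replacement(real_steps, k):
            total: Dict[str, int] = {}
            for s in combo:
                for sym, v in s.delta.items():
                    total[sym] = total.get(sym, 0) + v
            if {k_: v for k_, v in total.items() if v} == target \
                    and not _is_null_padded(combo):
                out.append(TransformationPath(parent, product, combo))
    out.sort(key=lambda p: (p.n_steps, p.label))
    return out


def _reachable(parent: Formula, steps: Sequence[ReactionStep],
               max_steps: int) -> Dict[Formula, TransformationPath]:
    """Shortest path per reachable product (non-negative counts only)."""
    found: Dict[Formula, TransformationPath] = {
        parent: TransformationPath(parent, parent, (ISOMERIZATION,))}
    real_steps = [s for s in steps if s.delta]
    for k in range(1, max_steps + 1):
        for combo in itertools.combinations_with_replacement(real_steps, k):
            if _is_null_padded(combo):
                continue
            total: Dict[str, int] = {}
            for s in combo:
                for sym, v in s.delta.items():
                    total[sym] = total.get(sym, 0) + v
            try:
                product = parent.apply_delta(total)
            except ValueError:
                continue
            path = TransformationPath(parent, product, combo)
            prev = found.get(product)
            if prev is None or (path.n_steps, path.label) < \
                    (prev.n_steps, prev.label):
                found[product] = path
    return found


def suspect_list(
    parents: Sequence[Formula],
    steps: Sequence[ReactionStep] = DEFAULT_STEPS,
    max_steps: int = 3,
    adducts: Iterable[str] = ("+Na", "+NH4"),
) -> List[SuspectEntry]:
    """Expand parents into every reachable product with expected adduct m/z.

    Products are deduplicated across parents keeping the shortest path
    (ties resolved in favour of the earlier parent in ``parents``); each
    retained product yields one entry per adduct species. Formulas with a
    negative element count are unreachable by construction.
    """
    if not parents:
        raise ValueError("at least one parent formula is required")
    best: Dict[Formula, TransformationPath] = {}
    for parent in parents:
        for product, path in _reachable(parent, steps, max_steps).items():
            prev = best.get(product)
            if prev is None or path.n_steps < prev.n_steps:
                best[product] = path
    entries = []
    for product in sorted(best, key=str):
        path = best[product]
        for adduct in adducts:
            entries.append(SuspectEntry(
                product, path, adduct,
                adduct_mz(AdductIon(product, adduct))))
    return entries


@dataclass(frozen=True)
class TPRecordLike:
    """Minimal record contract for structural grouping.

    ``isomer_kind`` carries annotation that formula-level arithmetic cannot
    supply: "diastereomer" vs "ring-opened" for isomerisations, or
    "stereoisomer" for same-formula/same-path pairs resolved only by
    retention time.
    """

    id: str
    formula: Formula
    parent: Optional[Formula]
    path_label: str
    isomer_kind: str = ""


def structural_classes(
    records: Sequence[TPRecordLike],
) -> Tuple[int, Dict[Tuple[str, str], List[TPRecordLike]]]:
    """Group TP records into structural classes.

    The class key is (canonical path label relative to the record's own
    parent, isomer-kind annotation): the same net reaction applied to
    homologous parents is one structural transformation, stereoisomer
    duplicates collapse, and annotated isomerisation kinds (diastereomer vs
    ring-opened) remain distinct. Returns (class count, grouping).
    """
    groups: Dict[Tuple[str, str], List[TPRecordLike]] = {}
    for rec in records:
        if rec.parent is None:
            raise ValueError(f"record {rec.id!r} lacks a parent assignment")
        groups.setdefault((rec.path_label, rec.isomer_kind), []).append(rec)
    return len(groups), groups
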