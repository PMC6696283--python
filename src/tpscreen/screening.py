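"""Suspect-screening pipeline: scans → features → trends → TP report.

Stages
------
1. ``extract_features`` links centroided peaks across scans into features by
   greedy nearest-m/z matching within a ppm window (plus a retention-time
   window when the peak lists carry one — isomeric species share an exact
   mass and are separated chromatographically only).
2. ``classify_trend`` labels each feature precursor / product / flat from
   the Spearman rank correlation of its intensity trace against the scan
   axis (applied potential for electrochemistry runs, storage time for
   hydrolysis runs).
3. ``match_suspects`` assigns product features to suspect-list entries
   within a ppm tolerance, merging the [M+Na]+/[M+NH4]+ pair of one species
   into a single record.
4. ``intensity_class`` bins a TP's intensity relative to the parent into the
   reporting classes s / ms / w / vw.
5. ``occurrence_table`` renders presence/absence of species over sampling
   days per pH for hydrolysis series.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .chemcore import (
    AdductIon,
    Formula,
    adduct_mz,
    adduct_pair_delta,
    ppm_error,
)
from .tpmapper import SuspectEntry

__all__ = [
    "ScanSeries",
    "Feature",
    "TPRecord",
    "SpeciesDef",
    "extract_features",
    "classify_trend",
    "classify_features",
    "match_suspects",
    "intensity_class",
    "occurrence_table",
    "format_occurrence",
    "read_peaks_csv",
    "write_peaks_csv",
]

import logging

logger = logging.getLogger(__name__)

#: Half-open lower-inclusive intensity bins relative to the parent.
INTENSITY_CLASSES = (("s", 0.60), ("ms", 0.30), ("w", 0.10), ("vw", 0.0))


@dataclass
class ScanSeries:
    """Centroided peak lists over an ordered scan axis.

    ``axis_kind`` is "potential" (V) for electrochemistry ramps or "time"
    (days) for hydrolysis storage series. ``peaks[i]`` holds arrays
    (mz, intensity) — optionally (mz, intensity, rt) — for scan i.
    """

    axis_kind: str
    axis: np.ndarray
    peaks: List[Tuple[np.ndarray, ...]]
    ph: Optional[float] = None
    ramp_rate: Optional[float] = None

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        if self.axis.size == 0:
            raise ValueError("scan axis must be non-empty")
        if np.any(np.diff(self.axis) <= 0):
            raise ValueError("scan axis must be strictly increasing")
        if len(self.peaks) != self.axis.size:
            raise ValueError("one peak list per axis value is required")
        for arrs in self.peaks:
            if np.any(np.asarray(arrs[1]) < 0):
                raise ValueError("intensities must be non-negative")

    @property
    def n_scans(self) -> int:
        return int(self.axis.size)

    @property
    def has_rt(self) -> bool:
        return any(len(arrs) > 2 for arrs in self.peaks)


@dataclass
class Feature:
    """One species trace: representative m/z plus intensity per scan."""

    mz: float
    trace: np.ndarray
    rt: Optional[float] = None
    trend_class: Optional[str] = None
    trend_statistic: Optional[float] = None

    @property
    def max_intensity(self) -> float:
        return float(np.max(self.trace))


@dataclass
class TPRecord:
    """One identified transformation product (a report row)."""

    id: str
    mz: float
    formula: Formula
    adduct: str
    parent: Formula
    path_label: str
    ppm: float
    intensity: float
    intensity_class: Optional[str] = None
    rt: Optional[float] = None
    paired_adducts: bool = False


@dataclass(frozen=True)
class SpeciesDef:
    """A named species to track in occurrence analysis (formula + optional
    retention time to resolve isomers)."""

    name: str
    formula: Formula
    rt: Optional[float] = None
    adduct: str = "+Na"

    @property
    def mz(self) -> float:
        return adduct_mz(AdductIon(self.formula, self.adduct))


def extract_features(
    series: ScanSeries,
    mz_tol: float = 4.0,
    min_scans: int = 5,
    rt_tol: float = 10.0,
) -> List[Feature]:
    """Link peaks across scans into features by greedy nearest-m/z matching.

    A peak joins the feature with the closest representative m/z within
    ``mz_tol`` ppm (and within ``rt_tol`` of the feature's retention time
    when peak lists carry one); otherwise it seeds a new feature. The
    representative m/z (and rt) is the intensity-weighted mean of the
    feature's member peaks. Features observed in fewer than ``min_scans``
    scans are dropped; scans without a member peak read intensity 0.
    """
    if series.n_scans == 0:
        raise ValueError("empty scan series")
    feats: List[Dict] = []  # mz, rt, wsum, wmz, wrt, trace, n_obs
    for i in range(series.n_scans):
        arrs = series.peaks[i]
        mzs = np.asarray(arrs[0], dtype=float)
        intens = np.asarray(arrs[1], dtype=float)
        rts = np.asarray(arrs[2], dtype=float) if len(arrs) > 2 else None
        order = np.argsort(-intens)  # strongest peaks claim features first
        claimed = set()
        for j in order:
            mz, inten = float(mzs[j]), float(intens[j])
            rt = float(rts[j]) if rts is not None else None
            best, best_d = None, None
            for k, f in enumerate(feats):
                if k in claimed:
                    continue
                d = abs(mz - f["mz"]) / f["mz"] * 1e6
                if d > mz_tol:
                    continue
                if rt is not None and f["rt"] is not None \
                        and abs(rt - f["rt"]) > rt_tol:
                    continue
                if best_d is None or d < best_d:
                    best, best_d = k, d
            if best is None:
                feats.append({"mz": mz, "rt": rt, "wsum": inten,
                              "wmz": inten * mz,
                              "wrt": inten * rt if rt is not None else 0.0,
                              "trace": np.zeros(series.n_scans), "n_obs": 0})
                best = len(feats) - 1
            f = feats[best]
            claimed.add(best)
            f["trace"][i] += inten
            f["n_obs"] += 1
            f["wsum"] += inten
            f["wmz"] += inten * mz
            if f["wsum"] > 0:
                f["mz"] = f["wmz"] / f["wsum"]
            if rt is not None:
                f["wrt"] += inten * rt
                if f["wsum"] > 0 and f["rt"] is not None:
                    f["rt"] = f["wrt"] / f["wsum"]
    out = [Feature(f["mz"], f["trace"], f["rt"])
           for f in feats if f["n_obs"] >= min_scans]
    out.sort(key=lambda f: f.mz)
    return out


def classify_trend(
    feature: Feature,
    axis: np.ndarray,
    threshold: float = 0.6,
) -> str:
    """Label a feature by the Spearman correlation of intensity vs axis.

    rho >= +threshold → "product" (rises along the ramp/time axis),
    rho <= −threshold → "precursor" (decays), otherwise "flat". A constant
    trace is "flat" with statistic 0. The statistic is stored on the
    feature.
    """
    axis = np.asarray(axis, dtype=float)
    if axis.size < 4:
        raise ValueError("at least 4 scans are required for a trend")
    trace = feature.trace
    if np.all(trace == trace[0]):
        rho = 0.0
    else:
        rho = float(stats.spearmanr(axis, trace).statistic)
    feature.trend_statistic = rho
    if rho >= threshold:
        feature.trend_class = "product"
    elif rho <= -threshold:
        feature.trend_class = "precursor"
    else:
        feature.trend_class = "flat"
    return feature.trend_class


def classify_features(series: ScanSeries, features: Sequence[Feature],
                      threshold: float = 0.6) -> None:
    for f in features:
        classify_trend(f, series.axis, threshold)


def intensity_class(tp_intensity: float, parent_intensity: float) -> str:
    """Bin TP/parent intensity ratio: s ≥60%, ms 30–60%, w 10–30%, vw <10%.

    Bins are half-open and lower-inclusive (a ratio of exactly 0.30 is ms).
    """
    if parent_intensity <= 0:
        raise ValueError("parent intensity must be positive for classing")
    r = tp_intensity / parent_intensity
    for name, lo in INTENSITY_CLASSES:
        if r >= lo:
            return name
    return "vw"


def match_suspects(
    features: Sequence[Feature],
    suspects: Sequence[SuspectEntry],
    tol: float = 3.0,
    parent_intensity: Optional[float] = None,
) -> Tuple[List[TPRecord], List[Feature]]:
    """Assign product-classified features to suspects within ``tol`` ppm.

    Each product feature is matched to the suspect with the smallest |ppm|
    within tolerance (ambiguous matches are logged and resolved by |ppm|).
    The [M+Na]+/[M+NH4]+ features of one formula merge into a single record
    (flagged ``paired_adducts`` when both were seen at the expected spacing
    of 4.9554 Da). Unmatched product features are returned as unknowns.
    With ``parent_intensity`` given, records carry an intensity class
    relative to it.
    """
    if not suspects:
        raise ValueError("suspect list must be non-empty")
    matches: Dict[Formula, Dict[str, Tuple[Feature, float]]] = {}
    unknowns: List[Feature] = []
    paths = {}
    for feat in features:
        if feat.trend_class != "product":
            continue
        hits = []
        for s in suspects:
            ppm = ppm_error(feat.mz, s.expected_mz)
            if abs(ppm) <= tol:
                hits.append((abs(ppm), ppm, s))
        if not hits:
            unknowns.append(feat)
            continue
        hits.sort(key=lambda h: (h[0], str(h[2].formula), h[2].adduct))
        if len(hits) > 1:
            logger.warning(
                "ambiguous match at m/z %.4f: %s; keeping lowest |ppm|",
                feat.mz,
                ", ".join(f"{h[2].formula}{h[2].adduct} ({h[1]:+.2f} ppm)"
                          for h in hits))
        _, ppm, best = hits[0]
        matches.setdefault(best.formula, {})[best.adduct] = (feat, ppm)
        paths[best.formula] = best.path

    pair_delta = adduct_pair_delta("+Na", "+NH4")
    records: List[TPRecord] = []
    for i, formula in enumerate(sorted(matches, key=str), start=1):
        by_adduct = matches[formula]
        # prefer the sodium adduct as the reporting species
        adduct = "+Na" if "+Na" in by_adduct else sorted(by_adduct)[0]
        feat, ppm = by_adduct[adduct]
        paired = False
        if "+Na" in by_adduct and "+NH4" in by_adduct:
            dmz = by_adduct["+Na"][0].mz - by_adduct["+NH4"][0].mz
            window = feat.mz * tol * 1e-6
            paired = abs(dmz - pair_delta) <= 2 * window
        # intensity from the reporting adduct, so TP/parent ratios compare
        # like adducts (the ammonium adduct is systematically stronger)
        intensity = feat.max_intensity
        path = paths[formula]
        records.append(TPRecord(
            id=f"S{i}", mz=feat.mz, formula=formula, adduct=adduct,
            parent=path.parent, path_label=path.label, ppm=ppm,
            intensity=intensity,
            intensity_class=(intensity_class(intensity, parent_intensity)
                             if parent_intensity else None),
            rt=feat.rt, paired_adducts=paired))
    records.sort(key=lambda r: r.mz)
    for i, rec in enumerate(records, start=1):
        rec.id = f"S{i}"
    return records, unknowns


def occurrence_table(
    series_by_ph: Mapping[float, ScanSeries],
    species: Sequence[SpeciesDef],
    tol: float = 3.0,
    rt_tol: float = 10.0,
    detect_threshold: float = 0.01,
    min_scans: int = 1,
) -> pd.DataFrame:
    """Presence/absence of species over (sampling day × pH).

    A species is present on a day when its matched feature intensity is at
    least ``detect_threshold`` × (first-species intensity at the first
    sampled day of that series) — the first entry of ``species`` is taken
    as the parent reference. Rows are indexed (pH, species name); columns
    are the union of sampling days; cells are True / False / <NA> (day not
    measured in that series).
    """
    if not species:
        raise ValueError("species catalogue must be non-empty")
    day_sets = [tuple(s.axis.tolist()) for s in series_by_ph.values()]
    all_days = sorted({d for days in day_sets for d in days})
    rows = {}
    for ph in sorted(series_by_ph):
        series = series_by_ph[ph]
        feats = extract_features(series, mz_tol=2 * tol,
                                 min_scans=min_scans, rt_tol=rt_tol)

        def find(spec: SpeciesDef) -> Optional[Feature]:
            best, best_d = None, None
            for f in feats:
                d = abs(ppm_error(f.mz, spec.mz))
                if d > tol:
                    continue
                if spec.rt is not None and f.rt is not None \
                        and abs(f.rt - spec.rt) > rt_tol:
                    continue
                if best_d is None or d < best_d:
                    best, best_d = f, d
            return best

        parent_feat = find(species[0])
        if parent_feat is None or parent_feat.trace[0] <= 0:
            raise ValueError(
                f"parent species {species[0].name!r} not detected at the "
                f"first sampled day of the pH {ph} series")
        threshold = detect_threshold * parent_feat.trace[0]
        for spec in species:
            feat = find(spec)
            cells = {}
            for day in all_days:
                if day not in series.axis:
                    cells[day] = pd.NA  # not measured
                    continue
                idx = int(np.where(series.axis == day)[0][0])
                present = feat is not None and feat.trace[idx] >= threshold
                cells[day] = bool(present)
            rows[(ph, spec.name)] = cells
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index = pd.MultiIndex.from_tuples(table.index,
                                            names=["pH", "species"])
    table.columns.name = "day"
    return table


def format_occurrence(table: pd.DataFrame) -> pd.DataFrame:
    """Render an occurrence table with 'x' marks (empty = absent,
    'n.m.' = not measured)."""
    def fmt(v):
        if v is pd.NA or (isinstance(v, float) and np.isnan(v)):
            return "n.m."
        return "x" if v else ""
    return table.map(fmt)


def read_peaks_csv(path) -> ScanSeries:
    """Read the package's peak-list CSV dialect into a ScanSeries.

    Columns: scan_id, axis_value, mz, intensity and optionally rt, plus
    optional constant metadata columns axis_kind, ph, ramp_rate.
    """
    df = pd.read_csv(path)
    required = {"scan_id", "axis_value", "mz", "intensity"}
    if not required <= set(df.columns):
        raise ValueError(f"peak CSV must have columns {sorted(required)}")
    axis_kind = str(df["axis_kind"].iloc[0]) if "axis_kind" in df else "potential"
    ph = float(df["ph"].iloc[0]) if "ph" in df and df["ph"].notna().any() \
        else None
    ramp = float(df["ramp_rate"].iloc[0]) if "ramp_rate" in df else None
    has_rt = "rt" in df.columns and df["rt"].notna().any()
    axis, peaks = [], []
    for (_, axis_value), grp in df.groupby(["scan_id", "axis_value"],
                                           sort=True):
        axis.append(float(axis_value))
        arrs = [grp["mz"].to_numpy(float), grp["intensity"].to_numpy(float)]
        if has_rt:
            arrs.append(grp["rt"].to_numpy(float))
        peaks.append(tuple(arrs))
    return ScanSeries(axis_kind, np.asarray(axis), peaks, ph=ph,
                      ramp_rate=ramp)


def write_peaks_csv(series: ScanSeries, path) -> None:
    """Write a ScanSeries in the peak-list CSV dialect (see read_peaks_csv)."""
    rows = []
    for i in range(series.n_scans):
        arrs = series.peaks[i]
        rts = arrs[2] if len(arrs) > 2 else None
        for j in range(len(arrs[0])):
            row = {"scan_id": i, "axis_value": series.axis[i],
                   "mz": arrs[0][j], "intensity": arrs[1][j],
                   "axis_kind": series.axis_kind}
            if rts is not None:
                row["rt"] = rts[j]
            if series.ph is not None:
                row["ph"] = series.ph
            if series.ramp_rate is not None:
                row["ramp_rate"] = series.ramp_rate
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6f")
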