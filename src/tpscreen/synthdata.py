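"""Seeded generators for EC voltammograms, hydrolysis series and spectra.

The generators emulate the measurement structure the screening pipeline
assumes, with ground-truth manifests for every run:

* electrochemistry: each species emits an [M+Na]+/[M+NH4]+ peak pair
  (ammonium more intense, spacing 4.9554 Da) whose intensity follows a
  sigmoidal response along the 0–2.5 V ramp — precursors decay, products
  rise; m/z values carry ~1 ppm Gaussian error and intensities
  multiplicative log-normal noise, plus sparse random baseline peaks.
* hydrolysis: a linear first-order reaction network
  parent ⇌ diastereomer → ring-opened → dehydrated, integrated exactly by
  matrix exponential, with the acid-catalysed steps scaled by
  ([H+]/[H+]_ref)^alpha, sampled at the storage days and converted to peak
  intensities. Isomeric species are separated by a synthetic retention-time
  channel, as they are chromatographically in real measurements.
* single spectra: full isotope envelopes per adduct for decomposer and
  isotope-fit fixtures.

All randomness derives from one master seed per call; rerunning with the
same inputs is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.linalg import expm

from .chemcore import AdductIon, Formula, adduct_mz
from .isotopes import theoretical_pattern
from .screening import ScanSeries, SpeciesDef

__all__ = [
    "SpeciesSpec",
    "NoiseModel",
    "KineticSpec",
    "MON_A",
    "MON_B",
    "EC_TP_FORMULAS",
    "HYDROLYSIS_SPECIES",
    "SAMPLING_DAYS",
    "default_ec_species",
    "generate_voltammogram",
    "generate_hydrolysis_series",
    "generate_spectrum",
]

MON_A = Formula.parse("C36H62O11")
MON_B = Formula.parse("C35H60O11")

#: The five glassy-carbon EC products plus their per-run sigmoid midpoints.
EC_TP_FORMULAS: Dict[str, str] = {
    "TP1": "C33H56O9",
    "TP2": "C35H62O10",
    "TP3": "C34H58O9",
    "TP4": "C35H60O9",
    "TP5": "C36H64O10",
}

#: Hydrolysis network species with retention times (s) resolving the
#: isomers that share the parent's exact mass.
HYDROLYSIS_SPECIES: Tuple[SpeciesDef, ...] = (
    SpeciesDef("MON", MON_A, rt=162.0),
    SpeciesDef("TP10", MON_A, rt=75.0),
    SpeciesDef("TP11", MON_A, rt=99.0),
    SpeciesDef("TP12", Formula.parse("C36H60O10"), rt=86.0),
)

#: Storage-series sampling grid in days.
SAMPLING_DAYS: Tuple[float, ...] = (1, 2, 3, 4, 5, 8, 15, 30)


@dataclass(frozen=True)
class SpeciesSpec:
    """One emitted species: formula, response curve and intensity model.

    ``curve`` is "rise" / "decay" (logistic in the axis variable, with
    ``midpoint`` and ``steepness`` in axis units) or "constant". The
    ammonium adduct is ``adduct_ratio`` times the sodium adduct.
    """

    name: str
    formula: Formula
    curve: str = "constant"
    midpoint: float = 0.0
    steepness: float = 0.2
    base_intensity: float = 1e6
    adduct_ratio: float = 3.0
    rt: Optional[float] = None

    def __post_init__(self) -> None:
        if self.curve not in ("rise", "decay", "constant"):
            raise ValueError(f"unknown curve kind {self.curve!r}")
        if self.adduct_ratio <= 0:
            raise ValueError("NH4:Na adduct ratio must be positive")

    def response(self, axis: np.ndarray) -> np.ndarray:
        axis = np.asarray(axis, dtype=float)
        if self.curve == "constant":
            return np.full(axis.shape, self.base_intensity)
        z = (axis - self.midpoint) / self.steepness
        sig = 1.0 / (1.0 + np.exp(-z))
        if self.curve == "decay":
            sig = 1.0 - sig
        return self.base_intensity * sig


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise parameters of the emulated instrument."""

    mz_sigma_ppm: float = 0.7
    intensity_sigma: float = 0.05  # log-normal sigma (multiplicative)
    baseline_rate: float = 5.0     # mean baseline peaks per scan
    baseline_mz_range: Tuple[float, float] = (200.0, 1000.0)

    def __post_init__(self) -> None:
        if min(self.mz_sigma_ppm, self.intensity_sigma,
               self.baseline_rate) < 0:
            raise ValueError("noise parameters must be non-negative")


def default_ec_species(base_intensity: float = 1e6) -> List[SpeciesSpec]:
    """The default EC scenario: MON A + MON B decaying, five TPs rising.

    Midpoints stagger across the upper half of the 0–2.5 V ramp;
    steepness 0.15 V gives the sigmoidal rise seen in mass voltammograms.
    """
    species = [
        SpeciesSpec("MON A", MON_A, "decay", 1.2, 0.25, base_intensity),
        SpeciesSpec("MON B", MON_B, "decay", 1.2, 0.25, 0.2 * base_intensity),
    ]
    midpoints = {"TP1": 1.4, "TP2": 1.5, "TP3": 1.3, "TP4": 1.5, "TP5": 1.6}
    scale = {"TP1": 0.15, "TP2": 0.12, "TP3": 0.6, "TP4": 0.35, "TP5": 0.5}
    for name, hill in EC_TP_FORMULAS.items():
        species.append(SpeciesSpec(
            name, Formula.parse(hill), "rise", midpoints[name], 0.15,
            scale[name] * base_intensity))
    return species


def _emit_peaks(specs_and_intensities, noise: NoiseModel,
                rng: np.random.Generator, with_rt: bool):
    """One scan's peak arrays from (spec, true Na-adduct intensity) pairs."""
    mzs, intens, rts = [], [], []
    for spec, na_intensity in specs_and_intensities:
        for adduct, scale in (("+Na", 1.0), ("+NH4", spec.adduct_ratio)):
            mz = adduct_mz(AdductIon(spec.formula, adduct))
            mz *= 1.0 + rng.normal(0.0, noise.mz_sigma_ppm) * 1e-6
            inten = na_intensity * scale
            if noise.intensity_sigma > 0:
                inten *= rng.lognormal(0.0, noise.intensity_sigma)
            mzs.append(mz)
            intens.append(inten)
            rts.append(spec.rt if spec.rt is not None else 0.0)
    n_base = rng.poisson(noise.baseline_rate)
    lo, hi = noise.baseline_mz_range
    for _ in range(n_base):
        mzs.append(rng.uniform(lo, hi))
        intens.append(rng.exponential(1e2))
        rts.append(rng.uniform(0.0, 200.0))
    order = np.argsort(mzs)
    arrs = [np.asarray(mzs)[order], np.asarray(intens)[order]]
    if with_rt:
        arrs.append(np.asarray(rts)[order])
    return tuple(arrs)


def generate_voltammogram(
    species: Optional[Sequence[SpeciesSpec]] = None,
    axis: Optional[np.ndarray] = None,
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
    ramp_rate: float = 0.02,
) -> Tuple[ScanSeries, Dict]:
    """Simulate a mass voltammogram over a 0–2.5 V potential ramp.

    Every species emits its Na/NH4 adduct pair per scan with sigmoid
    response × multiplicative noise; the manifest records the true species,
    adduct m/z values and noise-free per-scan intensities.
    """
    if species is None:
        species = default_ec_species()
    if axis is None:
        axis = np.round(np.linspace(0.0, 2.5, 51), 6)
    axis = np.asarray(axis, dtype=float)
    if axis.min() < 0.0 or axis.max() > 3.5:
        raise ValueError("potential axis must lie within [0, 3.5] V")
    if not any(s.curve == "decay" for s in species):
        raise ValueError("at least one precursor (decay curve) is required")
    rng = np.random.default_rng(seed)
    true_curves = {s.name: s.response(axis) for s in species}
    peaks = []
    for i in range(axis.size):
        peaks.append(_emit_peaks(
            [(s, true_curves[s.name][i]) for s in species],
            noise, rng, with_rt=False))
    series = ScanSeries("potential", axis, peaks, ramp_rate=ramp_rate)
    manifest = {
        "kind": "voltammogram",
        "seed": seed,
        "axis": axis.tolist(),
        "species": [
            {"name": s.name, "formula": str(s.formula),
             "curve": s.curve, "midpoint": s.midpoint,
             "mz_na": adduct_mz(AdductIon(s.formula, "+Na")),
             "mz_nh4": adduct_mz(AdductIon(s.formula, "+NH4")),
             "adduct_ratio": s.adduct_ratio,
             "true_intensity": true_curves[s.name].tolist()}
            for s in species
        ],
    }
    return series, manifest


@dataclass(frozen=True)
class KineticSpec:
    """First-order rate constants (1/day) of the hydrolysis network at the
    reference pH, with the acid-catalysis scaling law.

    parent ⇌ diastereomer (k_iso_fwd / k_iso_rev), diastereomer →
    ring-opened (k_ring), ring-opened → dehydrated (k_dehydration). The
    cascade is acid-catalysed: every rate scales with ([H+]/[H+]_ref)^alpha.
    The defaults put the parent/diastereomer equilibration much faster than
    the ring-opening drain, which is what lets the parent persist for weeks
    while downstream products appear in sequence.
    """

    k_iso_fwd: float = 10.0
    k_iso_rev: float = 10.0
    k_ring: float = 0.15
    k_dehydration: float = 0.08
    alpha: float = 1.0
    ref_ph: float = 3.0
    ph_list: Tuple[float, ...] = (3.0, 4.0, 5.0)

    def __post_init__(self) -> None:
        if min(self.k_iso_fwd, self.k_iso_rev, self.k_ring,
               self.k_dehydration) < 0:
            raise ValueError("rate constants must be non-negative")

    def rate_matrix(self, ph: float) -> np.ndarray:
        """Generator matrix of the network at ``ph`` (state order:
        parent, diastereomer, ring-opened, dehydrated)."""
        s = (10.0 ** (self.ref_ph - ph)) ** self.alpha
        k1, k1r = self.k_iso_fwd * s, self.k_iso_rev * s
        k2, k3 = self.k_ring * s, self.k_dehydration * s
        return np.array([
            [-k1, k1r, 0.0, 0.0],
            [k1, -(k1r + k2), 0.0, 0.0],
            [0.0, k2, -k3, 0.0],
            [0.0, 0.0, k3, 0.0],
        ])

    def concentrations(self, ph: float, days: Sequence[float]) -> np.ndarray:
        """Exact concentrations, shape (n_days, 4), starting from pure
        parent at unit concentration."""
        K = self.rate_matrix(ph)
        c0 = np.array([1.0, 0.0, 0.0, 0.0])
        out = np.vstack([expm(K * t) @ c0 for t in days])
        if out.min() < -1e-8:
            raise RuntimeError("integration produced negative concentration")
        return np.clip(out, 0.0, None)


def generate_hydrolysis_series(
    kin: KineticSpec = KineticSpec(),
    days: Sequence[float] = SAMPLING_DAYS,
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
    base_intensity: float = 1e6,
    species: Sequence[SpeciesDef] = HYDROLYSIS_SPECIES,
) -> Tuple[Dict[float, ScanSeries], Dict]:
    """Simulate storage series (one ScanSeries per pH) for the hydrolysis
    network, sampled at the given days.

    Peak lists carry a retention-time channel so that the isomeric species
    (parent, diastereomer, ring-opened — one exact mass) remain separable,
    as they are by chromatography in real measurements.
    """
    if len(species) != 4:
        raise ValueError("the hydrolysis network defines exactly 4 species")
    rng = np.random.default_rng(seed)
    series_by_ph: Dict[float, ScanSeries] = {}
    manifest = {"kind": "hydrolysis", "seed": seed, "days": list(days),
                "species": [{"name": s.name, "formula": str(s.formula),
                             "rt": s.rt} for s in species],
                "ph": {}}
    for ph in kin.ph_list:
        conc = kin.concentrations(ph, days)
        peaks = []
        for i in range(len(days)):
            specs = [
                (SpeciesSpec(s.name, s.formula, "constant",
                             base_intensity=base_intensity, rt=s.rt),
                 base_intensity * conc[i, j])
                for j, s in enumerate(species)
            ]
            peaks.append(_emit_peaks(specs, noise, rng, with_rt=True))
        series_by_ph[ph] = ScanSeries(
            "time", np.asarray(days, dtype=float), peaks, ph=ph)
        manifest["ph"][ph] = {"concentrations": conc.tolist()}
    return series_by_ph, manifest


def generate_spectrum(
    species: Sequence[SpeciesSpec],
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
    prune: float = 1e-4,
    max_peaks: int = 6,
) -> Tuple[np.ndarray, np.ndarray]:
    """One centroided scan with full isotope envelopes per adduct.

    Returns (mz, intensity) arrays sorted by m/z. Envelope abundances come
    from the theoretical isotope pattern of each adduct ion, scaled by the
    species base intensity (Na) and the NH4:Na ratio.
    """
    rng = np.random.default_rng(seed)
    mzs, intens = [], []
    for spec in species:
        for adduct, scale in (("+Na", 1.0), ("+NH4", spec.adduct_ratio)):
            pattern = theoretical_pattern(
                AdductIon(spec.formula, adduct), prune, max_peaks)
            for m, a in pattern.peaks:
                mz = m * (1.0 + rng.normal(0.0, noise.mz_sigma_ppm) * 1e-6)
                inten = spec.base_intensity * scale * a
                if noise.intensity_sigma > 0:
                    inten *= rng.lognormal(0.0, noise.intensity_sigma)
                mzs.append(mz)
                intens.append(inten)
    n_base = rng.poisson(noise.baseline_rate)
    lo, hi = noise.baseline_mz_range
    for _ in range(n_base):
        mzs.append(rng.uniform(lo, hi))
        intens.append(rng.exponential(1e2))
    order = np.argsort(mzs)
    return np.asarray(mzs)[order], np.asarray(intens)[order]
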