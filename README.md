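# tpscreen

Suspect screening of drug **transformation products** (TPs) from
high-resolution mass spectrometry data, built around the polyether ionophore
antibiotic **monensin** (MON A, C36H62O11; MON B, C35H60O11) and the three
ways its TPs are generated at laboratory scale: electrochemical oxidation in
an EC/MS flow cell, microsomal metabolism, and pH-controlled hydrolysis.

The package is for analytical chemists who have centroided peak lists — a
mass voltammogram (spectra vs. applied potential, 0–2.5 V) or an LC/HRMS
storage series (spectra vs. days, per pH) — and want a reproducible pipeline
from raw peaks to a TP report:

1. **Exact-mass arithmetic** (`chemcore`). Formulas over {C, H, N, O, Na};
   singly charged adducts [M+H]+, [M+Na]+, [M+NH4]+ with the electron-mass
   correction: m/z = (M + m_adduct − m_e)/z. The fixed [M+Na]+/[M+NH4]+
   spacing of 4.9554 Da is used as a screening invariant — every real
   species shows the pair.
2. **Formula decomposition** (`decomposer`). All elemental compositions
   whose adduct m/z lies within a ppm tolerance (default 3 ppm), under
   element bounds, with an RDBE (ring + double bond equivalents,
   C − H/2 + N/2 + 1) plausibility filter.
3. **Isotope-pattern ranking** (`isotopes`). Nominal-mass-binned isotope
   envelopes by per-element multinomial convolution, scored against the
   observed envelope with a scale-invariant RMS fit (0 = perfect); the fit
   breaks ties between formula candidates.
4. **Transformation mapping** (`tpmapper`). Explains a TP's elemental delta
   as a multiset of elementary reactions (decarboxylation, O-demethylation,
   dehydration, methanol addition, ...), expands parents into suspect
   lists, and groups TP records into structural classes.
5. **Trend screening** (`screening`). Feature linking across scans,
   Spearman-based precursor/product classification along the potential or
   time axis, suspect matching with Na/NH4 pair merging, intensity classes
   (s/ms/w/vw relative to the parent), and pH-resolved occurrence tables.
6. **Synthetic data** (`synthdata`). Seeded generators for mass
   voltammograms, acid-catalysed hydrolysis series
   (parent ⇌ diastereomer → ring-opened → dehydrated, integrated exactly),
   and single spectra — each with a ground-truth manifest, so every
   pipeline stage is testable end to end.

## Worked example

```python
from tpscreen import (AdductIon, Formula, adduct_mz, decompose, rank,
                      theoretical_pattern)

mon_a = Formula.parse("C36H62O11")
print(round(adduct_mz(AdductIon(mon_a, "+Na")), 4))   # 693.4184
print(round(adduct_mz(AdductIon(mon_a, "+NH4")), 4))  # 688.463

candidates = decompose(693.4184, adducts=("+Na",), tol=3.0)
observed = theoretical_pattern(AdductIon(mon_a, "+Na"))
best = rank(candidates, observed)[0]
print(str(best.formula), round(best.ppm, 2), round(best.sigma, 4))
# C36H62O11 -0.05 0.0
```

693.4184 is the sodiated monensin A cation; 688.4630 its ammonium adduct,
4.9554 lower. Decomposition at 3 ppm returns three chemically bounded
candidates, and the isotope fit (sigma 0.0 = the observed envelope is
exactly the C36H62O11Na envelope) puts the true formula first at
−0.05 ppm.

The same flow from the shell:

```sh
tpscreen simulate ec --seed 1 --out sim/
tpscreen screen-ec --peaks sim/ec_peaks.csv \
    --parents C36H62O11,C35H60O11 --out report/
```

which writes `report/tp_report.csv` with one row per identified TP, e.g.

```
S2,633.3973,C34H58O9,+Na,C35H60O11,DECARBOXYLATION + DEHYDROGENATION,0.05,s,True
```

(m/z, formula, reporting adduct, formula-level parent, reaction path,
ppm error, intensity class, Na/NH4 pair seen). Note the parent column is
the *shortest formula-level explanation*; distinguishing homologous parents
(MON A vs MON B) for real data needs MS/MS evidence, which formula
arithmetic cannot supply.

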