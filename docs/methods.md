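# Methods

## Mass arithmetic and the adduct convention

All masses derive from the shipped element table
(`src/tpscreen/data/elements.csv`): IUPAC monoisotopic isotope masses and
abundances for C, H, N, O, Na, plus the electron mass (0.00054858 Da). The
alphabet is deliberately small: the analytes are C/H/O polyethers, and N
and Na enter only through ammonium and sodium adduct chemistry.

Observable cations are singly charged adducts. For an adduct X ∈
{+H, +Na, +NH4},

    m/z = (M_neutral + M_X − m_e) / 1

with the electron mass subtracted (cation convention). Reported m/z values
are rounded to 4 decimals (round-half-even). This convention reproduces the
published 4-decimal reference values for all sodiated monensin species to
±0.0005 Da with a single exception: one reference row (the bis-demethylated
microsomal product, C34H58O11Na printed as 665.3877) matches the
*uncorrected* sum exactly and the corrected value only to 0.0006 Da — i.e.
that printed value is high by one electron mass, which we treat as a typo
in the source table rather than a reason to switch conventions. The
acceptance tests encode both facts explicitly.

Formulas parse from plain Hill notation ("C36H62O11") and from the
underscored table dialect ("C_36_H_62_O_11_Na"); `split_sodium` separates a
printed sodiated composition into (neutral, +Na).

## Isotope patterns and the fit score

Patterns are simulated per element by multinomial convolution over
nominal-mass offsets (exponentiation-by-squaring on small arrays carrying
per-bin probability and abundance-weighted mean mass), then combined across
elements, normalised to base peak 1, pruned below 1e-4 of the base peak and
truncated at 6 peaks. Binning is at nominal-mass resolution: a TOF
instrument at suspect-screening resolving power separates M, M+1, M+2 but
not the fine structure within one bin, so simulating fine structure would
claim precision the data do not have. Equivalence with brute-force
isotopologue enumeration is tested for small formulas.

Vendor software ranks formula candidates with proprietary isotope-fit
metrics; we use a documented substitute: the RMS deviation of
base-peak-normalised abundances over the union of occupied nominal bins
(bins present in only one pattern contribute their full abundance). It is
deterministic, symmetric for complete envelopes, scale-invariant, and 0 for
a perfect fit. Only the *relative* ranking is meaningful; no absolute
acceptance threshold is defined.

## Formula decomposition

Enumeration is exact over the bounded lattice: nested loops over Na, N, O,
C with hydrogen solved by mass closure inside the residual window and
branch-and-bound pruning on partial mass; the per-candidate signed ppm
error (computed on the adduct m/z, the measured quantity) is the final
filter. Default bounds C 0–60, H 0–120, N 0–2, O 0–20, Na 0–1: wide enough
to contain a C36 scaffold's transformation products plus distractors while
keeping the lattice around 10^6 points; a guard rejects bounds admitting
more than 1e8 points. The RDBE filter (default on, range 0–40, computed on
the neutral formula with Na excluded) removes chemically absurd candidates;
none of the published formulas is excluded by it. Candidate order is
|ppm|, then formula text, then adduct; ranking with an observed pattern
sorts by (sigma, |ppm|, formula text) — fully specified so results are
reproducible. Whether the original data analysis bounded elements or
filtered by RDBE is unknown; both are exposed in the API/config.

## Transformation paths and structural classes

Reaction steps are net-atom deltas (decarboxylation −CO2, O-demethylation
−CH2, dehydration −H2O, methanol addition +CH4O, hydration +H2O,
(de)hydrogenation ±H2, methylation +CH2, isomerisation {}). Path
enumeration returns every multiset of ≤ max_steps steps (default 3, the
smallest value explaining all published TPs) whose deltas sum to the
product−parent difference, excluding *null-padded* multisets — any
combination containing a nonempty zero-sum subset (a step plus its inverse,
or cycles such as demethylation + dehydration + methanol addition). An
identity delta is therefore explained by exactly one path, {ISOMERIZATION}.
Published transformation shorthand is carried as annotation only; where it
disagrees with the printed formulas (two reference rows are short by −2H),
the formula-derived delta is authoritative.

Suspect lists expand parents over all reachable non-negative formulas,
deduplicated across parents keeping the shortest path (ties: earlier
parent). Structural classes group TP records by (canonical path label
relative to the record's own parent, isomer-kind annotation): the same net
reaction on homologous parents (MON A/MON B) is one transformation class,
stereoisomer duplicates collapse, and annotated isomerisation kinds
(diastereomer vs ring-opened — distinguishable only by retention/MSMS
metadata, not by formula arithmetic) remain distinct. Under this grouping
the twelve reference TP records form nine structural classes.

## Screening pipeline

Feature linking is greedy nearest-m/z within a ppm window (default 4 ppm,
twice the instrument-level mass accuracy), strongest peaks claiming
features first; representative m/z is the intensity-weighted mean. When
peak lists carry a retention-time channel (hydrolysis series, where three
species share one exact mass), linking and species matching additionally
require rt agreement (default 10 s). Features seen in fewer than 5 scans
are dropped — this is also what suppresses random baseline peaks.

Trend classification uses the Spearman rank correlation of the intensity
trace against the scan axis — robust to the sigmoidal (non-linear) response
along a potential ramp. Threshold 0.6 (|rho|) separates product (rising)
from precursor (falling) from flat; at the default noise level a sigmoid
rise classifies as product in ≥ 95% of replicates.

Suspect matching keeps the lowest-|ppm| suspect within 3 ppm (ambiguities
logged), merges the Na/NH4 features of one formula into a single record
(pair declared when both exist at the 4.9554 Da spacing), and reports
unmatched product features as unknowns. Intensity classes use the feature
maximum intensity of the reporting (Na) adduct relative to the parent's
maximum feature intensity in the run: s ≥ 60%, ms 30–60%, w 10–30%,
vw < 10%, half-open lower-inclusive (the source prints touching ranges
without resolving boundaries; whether areas or heights were used is also
unstated — we use heights).

Occurrence tables mark a species present on a sampling day when its feature
intensity reaches 1% (default) of the parent intensity at the first sampled
day of that series; days missing from a series are rendered "n.m.",
distinct from absent.

## Synthetic-data generator

The generators emulate the *structure* of the study's measurements, not the
instrument: centroided sticks with Gaussian m/z error (sigma 0.7 ppm,
consistent with sub-2-ppm mass accuracy), multiplicative log-normal
intensity noise (sigma 0.05), Poisson baseline peaks (5/scan, uniform over
m/z 200–1000), an NH4:Na intensity ratio of 3 (the source states only that
ammonium adducts are the more intense; the value is our choice,
configurable), and per-species logistic response curves along the 0–2.5 V
ramp (51 scans; midpoints 1.2–1.6 V, steepness 0.15–0.25 V). They do not
emulate profile peak shapes, detector saturation, chromatographic drift or
co-elution — so passing tests demonstrate pipeline correctness under the
stated statistical model, not robustness to every artefact of real data.

The hydrolysis network parent ⇌ diastereomer → ring-opened → dehydrated is
linear first-order and integrated exactly with `scipy.linalg.expm` (mass
balance holds to the numerical tolerance). Every rate scales with
([H+]/[H+]_ref)^alpha, alpha = 1, reference pH 3. Default rate constants at
pH 3 — forward/reverse isomerisation 10/day each, ring-opening 0.15/day,
dehydration 0.08/day — were calibrated once against the qualitative
published occurrence pattern (all three products visible at pH 3 with the
dehydrated species appearing on day 2; at pH 5 the diastereomer early, the
ring-opened species late, the dehydrated species not within 30 days; the
parent persisting throughout). The fast pre-equilibration regime
(isomerisation ≫ ring-opening drain) is what lets the parent persist for
weeks while downstream products appear in sequence. These values are
fitted-to-pattern, not measured. The source table's caption numbers its
hydrolysis products inconsistently ("TPs 10–13" for three defined species);
we follow the defined set TP10–12. Incubation temperature is inert
metadata.

Randomness: one master seed per generator call feeds a single
`numpy.random.Generator`; identical inputs give byte-identical CSV output.

## Problem sizes and limitations

Tests and the acceptance script run at desk scale: 51-scan voltammograms,
8-day × 3-pH hydrolysis grids, 20-seed recovery sweeps, brute-force oracle
equivalence below 200 Da and 6 atoms. Known limitations: parent assignment
is formula-level (shortest path), so homologue attribution differs from
MS/MS-based assignment; fragment annotation is generic subformula
enumeration, not a fragmentation model; no multiply charged ions, average
masses, or isotope-labelled formulas; trend classification assumes
monotone-in-expectation responses and will label transient intermediates
"flat".
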