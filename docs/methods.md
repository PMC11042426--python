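# Methods

## Scope and model

`snoglyc` implements a non-targeted, MS/MS-centric analysis of
PGC-LC-MS/MS N-glycomics data. Input are (a) MS/MS spectra in MGF format
(as produced by refinement tools such as PEAKS or MSConvert) and (b)
charge-deconvoluted, deisotoped MS1 feature tables (CSV). Glycans are
assumed to be PNGase-F-released and reduced to the alditol at the
innermost GlcNAc; all precursor masses therefore carry +2.01565 (two
hydrogens) in addition to the water of the free reducing end, and all
feature masses are kept on the singly protonated [M+H]⁺ scale.

## Mass arithmetic

Residue (dehydrated) monoisotopic masses to five decimals: Hex 162.05282,
HexNAc 203.07937, dHex 146.05791, Neu5Ac 291.09542, Neu5Gc 307.09033,
HexA 176.03209, sulfate (SO₃) 79.95682, O-acetyl 42.01057; water
18.01056, proton 1.00728. B-type oxonium fragments are residue sums plus
one proton; reduced-end Y-type fragments additionally carry water plus
the reduction hydrogens. For the reduced end we use the chemically exact
+2.01565; a few literature values for reduced-end ions (224.1118,
792.3234, 370.1697) deviate from sum-of-atoms arithmetic by ≈ 0.0011 amu
(consistent with two extra protons instead of two hydrogens); all agree
far inside the ±0.05 amu matching tolerance used throughout, so the
discrepancy has no downstream effect.

## Diagnostic-ion registry

The built-in registry (`data/diagnostic_ions.tsv`) holds 49 oxonium
ions. Compositions were assigned wherever the B/Y arithmetic reproduces
the tabulated mass (non-reduced within 0.002 amu, reduced within 0.005);
ions that are water-loss or adduct species (e.g. Neu5Ac−H₂O 274.0921,
HexNAc+H₂O 222.0972) or phospho-hexose (243.0264) carry no composition
and are matched by their tabulated m/z alone. Feature tags form a
controlled vocabulary (`n_glycan`, `neu5ac`, `neu5gc`, `fucose_antenna`,
`bisecting`, `alpha_gal`, `hnk1`, `hnk1_sulfo`, `sulfo_hexnac`,
`lacdinac_fuc`, `lewis_y`, `disialyl_lewis_c_ac/_gc`, `oac_neu5ac/_gc`,
`sda`, `sia_hexnac_ac/_gc`, `hexose_oligomer`, `other`). Per-ion eSNOG
cut-offs default to 0.01, except the SNOG (224.1118) ion at 0.03; the
TSV is user-editable because empirical cut-offs are instrument- and
collision-energy-dependent.

## Scores

SNOG = summed intensity of all peaks within ±0.05 amu of 224.1118,
divided by the spectrum TIC. The denominator choice (spectrum TIC rather
than base peak) makes the score scale-invariant and bounded in [0, 1];
a base-peak-relative variant would rank spectra identically only within
a spectrum, and TIC-relative is the more robust default. In-window peaks
are summed, not maximized, to be robust against split centroids. eSNOG
is the identical ratio for any other registry ion.

## Precursor aggregation

MS1 features are summed over the whole chromatographic run onto a fixed
grid with centers at 1000.0 + k·0.1 amu (bin half-width 0.05). The grid
origin is anchored at 1000.0 so that one-decimal printed masses coincide
with bin centers and binning is reproducible; features are assigned to
the nearest center and dropped (with a logged count) when that center
falls outside [1000, 5000]. Bins below the cumulative intensity
threshold (default 5×10⁶ a.u.) are removed first; MS/MS spectra are then
charge-deconvoluted ((m/z − p)·z + p) and attached to the nearest bin
within ±0.05 amu; finally bins whose aggregated SNOG falls below 0.03,
or that have no attached spectra at all, are rejected. The threshold is
applied before SNOG filtering; both steps are logged. Bin-level SNOG is
the intensity-weighted mean of the attached spectra's scores, weighted
by the triggering precursor intensity when the MGF carries it (uniform
otherwise); max-aggregation is available as an option. Replicates are
kept as separate samples and never merged automatically.

## In-silico composition database

Canonical N-glycan compositions are enumerated exhaustively under
biosynthetic plausibility rules: a chitobiose core of two HexNAc;
compositions with HexNAc = 2 follow the pauci-/oligomannose rule (Hex
3–9, no sialic acid, at most one core fucose); otherwise non-core HexNAc
is bounded by four antennae plus an optional bisecting GlcNAc, sialic
acids by the antenna count (one extra allowed when the disialyl-antenna
option is enabled; off by default), fucoses by antennae + 1, and Hex by
3 + 2 per antenna with a hybrid-type allowance of up to 9. Extended
residues (HexA, sulfate, O-acetyl) are excluded from the canonical
database by default — such structures are deliberately surfaced as
"unknown" and then mined via eSNOG, which is the workflow's mechanism for
discovering non-canonical modifications. The default rule set yields
2204 compositions in 1135 precursor mass bins over 1000–5000 amu; the
reference database it approximates reports 1429 compositions in 960
bins, and since its exact rule set is not published the counts are
logged as a diagnostic, never asserted. Annotation attaches every
composition whose reduced [M+H]⁺ lies within ±0.05 amu of a bin center
(isobaric candidates are all kept, e.g. Hex6HexNAc4Neu5Ac1 and
Hex5HexNAc4Fuc1Neu5Gc1 are exactly isobaric); bins without candidates
are flagged unknown and their TIC share reported.

## Stratification

A bin receives a category label when at least one attached spectrum
passes the category ion's eSNOG cut-off (a `min_spectra` quorum
parameter exists for stricter runs; the default quorum of one reflects
that the score cut-off itself is the specificity filter). Categories are
multi-label — a bin with both sialic-acid variants is both `neu5ac` and
`neu5gc`, so category TIC fractions may sum past 100 %. Either the
intact sialic-acid oxonium or its water-loss ion qualifies. Oligomannose
is assigned from the composition annotation (HexNAc = 2, Hex 4–9), not
from a fragment; `undecorated` is the exact complement of the five
positive categories. The rare-epitope screen reports, per feature, the
TIC fraction of bins with at least one qualifying spectrum plus the
contributing compositions.

## Isomer elution profiles

Retention times are normalized as a ratio to the apex retention time of
the Man5 (Hex5HexNAc2) trace of the same run — relative retention is the
standard scale-invariant normalization and cancels uniform gradient
drift. Profiles are built from MS1 features (quantitatively more
faithful than MS/MS trigger times), resampled onto a fixed relative-
retention grid (default 0.1–3.0, step 0.005) by nearest-point summation,
which conserves total intensity exactly. Optional window-3 moving-average
smoothing is off by default. Mode positions are local maxima above 5 %
of the profile maximum. Cosine similarity compares gridded profiles.
Because the Man5 reference is itself an empirical apex, recovered mode
positions can shift by one grid step.

## Cross-sample comparison

Samples are assembled into a union-of-bins matrix with per-sample TIC
normalization (absent bins contribute zero). Pearson correlation is
computed on these rows; hierarchical clustering uses Ward linkage on
Euclidean distances of the bin vectors directly. Clustering Euclidean
distances of a seeded t-SNE embedding is available behind a flag but is
not the default because the embedding is stochastic and third-party.
Samples are label-sorted before linkage so leaf order is deterministic.
Dendrograms export to Newick with merge heights as branch lengths.

## Synthetic data generator

The generator emulates exactly the structure the workflow consumes: per
glycan, MS1 features at its reduced [M+H]⁺ distributed over isomer modes
at fixed Man5-relative retention positions, and MS/MS spectra containing
the 224.1118 ion (relative intensity ≈ 0.2 of TIC, SNOG ≥ 0.05 by
construction) plus the diagnostic ion of every feature tag (relative
intensity 0.08, above the 0.01 cut-offs) and uninformative filler peaks
placed away from every diagnostic window. Contaminant hexose-oligomer
signals carry a Hex ion ladder (163.0601, 325.1129, …) and no 224.1118.
Defaults: intensity CV 10 %, m/z jitter SD 0.005 amu (truncated at
0.008 amu and additionally clipped to the feature's own bin margin, so a
feature can never cross a bin edge and ground-truth bins stay exact),
retention jitter SD 1 s, three features and two spectra per isomer mode.
The six-sample mouse panel encodes headline tissue contrasts
(Neu5Gc-dominated serum; Neu5Ac/bisecting/di-sialyl-Lewis-C brain;
fucose/HNK-1 kidney; alpha-Gal/sulfo pancreas; Lewis-Y seminal vesicle;
contamination-heavy liver where most raw bins are contaminant-only and
must be SNOG-rejected). Per-glycan intensities are set so each glycan
bin clears the 5×10⁶ threshold. What the generator does *not* model —
chromatographic peak shapes, isotope envelopes, co-isolation chimeras,
adducts, in-source fragmentation — bounds what passing tests show: they
validate the scoring/binning/classification logic, not robustness to
every instrument artifact of real raw data.

## Numerical choices and degenerate inputs

Matching tolerances are ±0.05 amu everywhere, mirroring the acquisition
resolution the defaults assume. Nearest-center assignment breaks ties by
distance (the 0.07 vs 0.03 case assigns to the closer center). Spectra
with unknown charge cannot be mass-deconvoluted and are skipped with a
log entry; all-zero spectra raise an undefined-score error rather than
returning 0. A histogram with zero TIC cannot be normalized (error); a
profile with no in-tolerance features is returned empty with a warning;
a missing Man5 reference raises an error instructing manual entry.

## Problem sizes

Tests and the acceptance script run the six-sample panel (plus duplicate
replicates for clustering) at roughly 30 glycan bins, 100 MS1 features
and 60 MS/MS spectra per sample — small enough for the whole end-to-end
analysis to complete in seconds while exercising every pipeline stage,
and chosen as the smallest panel in which every category, rare epitope,
isomer-mode and contaminant behavior appears at least once.

## Known limitations

Composition-level only: no topology, linkage or structure-graph
inference; Lewis X vs blood-group H and core vs antennary fucose cannot
be distinguished from MS/MS fragments alone and are left to retention-
library comparison by the user. The SNOG/eSNOG cut-offs shipped are
defaults, not instrument-calibrated values. DeCon2-style feature tables
are accepted only when they carry an explicit retention-time column
(the raw `scan_num`-only dialect would require a scan-to-RT map that a
CSV reader cannot supply). mzML/raw parsing, centroiding and deisotoping
are out of scope — upstream tools produce the MGF/CSV inputs.
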