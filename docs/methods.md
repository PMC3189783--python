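# Methods

This note records the modelling decisions behind `gridqsar`: what is
computed, which choices were genuinely open, and what the tests do and do
not demonstrate.

## Dataset encoding

The 60 arylpyrimidinedione records are transcribed into
`src/gridqsar/data/apd_table.csv` (id, aryl pattern X, R1, R2, pKi, test
flag).  Two printed activity values are corrected at load time and logged:
compound 28's "42" is read as 4.2 (it lies far outside the series' stated
3.8–9.3 range and is two orders of magnitude from every neighbouring
analog; the correction is flagged, not silent) and compound 49's bare "5"
as 5.0.  The 15 test compounds (ids 4, 5, 6, 7, 14, 21, 38, 39, 40, 41,
43, 45, 53, 56, 60) give the 3:1 train/test split; compounds 14 and 21 are
the documented prediction outliers and are excluded from r²pred but kept
everywhere else.

Structures are assembled from the scaffold SMILES template
`N1(R1)C(=O)N(aryl)C(=O)C=C1R2` with a fixed substituent vocabulary
(`dataset.SUBSTITUENT_SMILES`); attachment conventions (2-thienyl linked at
C2, sulfoxide as S(=O)CH3, etc.) are fixed there.  The 2,4-dione (lactam)
tautomer is assumed throughout; no protonation-state or tautomer
enumeration is attempted.

## Conformations, charges and atom typing

Each structure is embedded with ETKDG and minimised with MMFF94 (the
package's stand-in for the commercial force field of the original
workflow), with plain Gasteiger partial charges (stand-in for
Gasteiger–Hückel).  Both substitutions are known deviations: absolute
energies and charges differ, which is one reason printed third-party
statistics are matched only qualitatively.

**Template-based conformer policy.**  A congeneric-series field model is
extremely sensitive to irrelevant torsional noise: two analogs that share a
substituent should present it identically in space.  Historically this came
free, because analogs were built by modifying a common template.  The
package reproduces that workflow explicitly: the reference compound (58) is
embedded and minimised once; every other compound inherits the reference
coordinates over their maximum common substructure (element-matched, whole
rings) as distance-geometry constraints, and only the atoms that actually
differ are embedded freely and then relaxed with the template atoms fixed.
Because the freely embedded substituents still carry arbitrary torsions,
each compound contributes a small ensemble (default 6) of such constrained
conformers and its descriptor row is the ensemble mean of the per-conformer
fields.  This averaging is a variance-reduction device of the descriptor
computation — the dataset itself remains one record per compound, single
`embed_molecule` conformations are still available (`build_series`), and no
conformational analysis is performed or exported.  With a naive
one-independent-conformer-per-compound protocol the cross-validated q² of
the real-series model fluctuates by ±0.1 across embedding seeds;
ensemble-averaged template conformers stabilise it (≈ 0.61–0.67 across
seeds) for the same settings, which is why the policy deviates from a
single-conformer design.

Per-atom similarity properties: steric ω = vdW radius³; electrostatic ω =
Gasteiger charge; hydrophobic ω = Wildman–Crippen atomic logP increments;
donor/acceptor ω = 1 on donor/acceptor-typed atoms (RDKit Lipinski SMARTS),
else 0.  These follow the original similarity-index conventions; the probe
carries +1 for every property.

## Alignment

Rigid-body Kabsch superposition (proper rotation, no scaling or
reflection) over the 14 heavy atoms of the shared core: N1, C2, O2, N3,
C4, O4, C5, C6 and the six aryl-ring carbons, all weighted equally.  The
two-fold symmetry of the aryl ring yields two candidate atom mappings;
the one with lower post-fit RMSD wins, ties broken lexicographically.
Collinear cores raise an error (the rotation would be underdetermined).

## Grid and fields

The lattice has 2 Å spacing and extends 4 Å beyond the union bounding box
of all aligned conformers (margin configurable; 4 Å is the customary
region extension).  CoMFA steric energies use a general-purpose AMBER-style
element Lennard-Jones table with an sp³-carbon-like probe (well depth
0.107 kcal/mol, radius 1 Å per the stated probe settings); electrostatics
use 332.0637·q/r² (ε = r).  Both are truncated at 30 kcal/mol; at
sterically excluded points (steric at the cap) the electrostatic entry is
replaced by the column mean over non-excluded compounds, the conventional
treatment (configurable to keep raw clamped values).  CoMSIA needs no
truncation (the Gaussian is bounded); the printed leading minus sign of the
similarity index is kept — it rescales all coefficients consistently and
cannot affect model statistics, only the sign convention of contour values
(favoured regions for *larger* substituents carry negative steric field
values, hence the sign of stdev\*coeff peaks must be read against that
convention).

## PLS and statistics

Columns with standard deviation below 2.0 kcal/mol (CoMFA) or 0.05
(CoMSIA) are dropped — the customary minimum-sigma filter; thresholds are
configurable.  Filters and scales are computed on the training rows only.
Columns are centred and scaled block-wise: every column of a field block
shares the block's pooled standard deviation ("CoMFA standard" scaling),
so fields with different units contribute comparable variance.  The PLS
core is NIPALS (scikit-learn) with `scale=False` on the pre-processed
matrix; coefficients are back-transformed to original descriptor units for
contour maps.

Leave-one-out cross-validation refits the model n times per component
count; q²(c) = 1 − PRESS(c)/SS with SS about the full-sample mean, and the
block scales held fixed across folds (they change negligibly under LOO and
fixing them keeps folds comparable).  The selected component count is the
smallest whose q² lies within 5 % of the maximum (a parsimony heuristic;
`argmax` is available).  SEP = √(PRESS/(n−c−1)).  On the training fit:
SEE = √(RSS/(n−c−1)) and F = [r²/(1−r²)]·[(n−c−1)/c]; the
degrees-of-freedom-free ratio r²/(1−r²) is additionally reported as
`f_ratio` because the two conventions disagree in third-party tables.
Field contributions are the normalised per-field sums of |coefficient| ×
column sd in the modelling space.  External prediction uses
r²pred = 1 − PRESS/SD, SD about the training-set mean, with the two
documented outliers excluded; the outlier rule itself is a strict
|residual| > 1.0 log-unit threshold.

## Contour maps

stdev\*coeff values (original-unit coefficient × raw column sd) are placed
on the lattice, zero at filtered-out columns.  Favoured/disfavoured level
sets are the 80th/20th percentiles of the nonzero values (display
convention; the source figures print no numeric levels, so figure-level
comparisons are qualitative by construction).  Regions are 6-connected
lattice components, each annotated with the nearest substituent-position
label (ring positions 2′–6′, N1-R1, C6-R2) of the aligned reference and
the distance in Å.

## Synthetic validation

The generator emulates what makes field-QSAR well-posed: a rigid common
core (a 9-point scaffold in a fixed frame), three substituent sites ≥ 6 Å
apart with Bernoulli(0.6) occupancy and random physicochemical properties
spanning the ranges of the real series' atom tables, and an activity that
is exactly linear in the steric similarity field summed over the lattice
points within 2.5 Å of a designated site, plus Gaussian noise in log
units.  The noiseless signal is rescaled to a 1.2-log-unit standard
deviation to mimic the real series' pKi spread, and the default series
size (40, split 3:1) mirrors the real design.  What it deliberately omits:
real molecules' correlated substituent effects, conformational freedom,
charge transfer between sites — so a passing recovery test demonstrates
correctness of the machinery (fields, PLS, contours), not real-data
performance.  Recovery reports the best LOO q² over component counts (the
attainable cross-validated fit), per-site sign agreement between planted
and recovered aggregate coefficients, and the fraction of planted lattice
points inside the top decile of |stdev\*coeff|.  The all-zero-weight null
configuration (pure noise) is permitted deliberately so the no-signal
behaviour (q² ≤ 0 in expectation) can be exercised end to end.

## Problem sizes and determinism

The real-series pipeline runs in well under a minute on one CPU: 60
compounds × 6 conformers, a ≈ 1,500-point lattice, ≈ 7,000 similarity
columns before filtering, and 45 × 10 LOO refits.  Monte-Carlo checks use
12–40-molecule synthetic series and up to 100 seeds.  A single global seed
drives everything; per-compound and per-conformer sub-seeds are derived
deterministically from it, so identical configurations reproduce
byte-identical statistics.

## Known limitations

* Force field, charge model and the minimum-sigma filter differ from the
  commercial toolchain that produced the historical reference statistics;
  agreement with those numbers is expected at the level of model quality
  (q² above the 0.5 predictive bar, steric-field dominance), not digit for
  digit.
* Single-template alignment assumes the series shares one binding mode;
  receptor-derived poses, docking and flexible alignment are out of scope.
* The electrostatic field at buried points is imputed, not physical.
* Contour levels are display percentiles; absolute region volumes are not
  comparable across models with different value distributions.
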