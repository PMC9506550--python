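# Methods

## Mass arithmetic

Formulas are restricted to C, H, N, O, S, P with IUPAC most-abundant
isotope masses (C = 12 exactly, H = 1.00782503207, N = 14.0030740048,
O = 15.9949146196, S = 31.97207100, P = 30.97376163 Da).  Ion m/z for
the two singly charged species is M ± 1.00727646677 Da — the proton
mass, so the electron-mass correction is built in.  Relative mass error
is (measured − theoretical)/theoretical × 10⁶ ppm with the theoretical
mass as denominator; reconciliation against the reference library shows
this convention reproduces its printed Δppm column.  Annotation accepts
|Δ| ≤ 5 ppm by default.  Other adducts (Na⁺, K⁺, formate) are out of
scope for the bundled library but the ion type is extensible.

### Reference-library consistency flags

A library row is flagged `printed-inconsistency` when its printed
measured mass, formula and Δppm cannot be reconciled within 0.05 ppm
*plus the half-ulp of the printed measured mass* (a mass printed with
3–4 decimals cannot reproduce the ppm value computed from the unrounded
measurement; e.g. half an ulp of a 4-decimal mass at m/z 330 is already
0.15 ppm).  22 of 93 rows are flagged; inspection shows genuine
print-level defects (formulas missing an atom, calculated masses
belonging to a different formula, one row with no formula at all).
Flagged rows are carried verbatim — the package never "corrects" a
source value — and are simply excluded from mass-arithmetic
verification.

## Feature tables and preprocessing

A feature table is an m/z-feature × sample matrix with per-feature
(m/z, retention time, polarity) and per-sample (organ, line, experiment
block, replicate) metadata.  Positive- and negative-mode features live
in one table and are analysed jointly.  Missing entries and exact zeros
are both treated as below the detection limit, because gap-filling
steps upstream can emit either.  Imputation substitutes half the
per-feature minimum non-zero observation (idempotent by construction);
features with no observed value at all are dropped with a logged
warning.  Intensities are then log2 transformed.  The same
preprocessing feeds PCA and ANOVA.

## Two-way block ANOVA and DAM selection

Per feature, the additive model y = μ + block + organ + line +
organ:line + ε is fitted on log2 intensities with sequential (Type I)
sums of squares in that order, F-testing each fixed term against the
residual mean square (df = 41 on the full 48-sample design).  With two
blocks and a balanced design this fixed-block decomposition yields the
same F statistics as treating the experiment as a random block, and
Type I equals Type III; the test suite asserts both equivalences
against statsmodels.  The implementation is a single QR decomposition
of the shared design matrix applied to all features at once; a
statsmodels per-feature fit is kept as the independent oracle in tests,
never as the computation path.  Organ × line cells with fewer than two
observations make the design untestable and raise immediately.

A DAM ("differentially accumulating metabolite") is a feature with
p(line) ≤ p_max or p(interaction) ≤ p_max, and |log2 FC| > min_abs_fc
in the organ considered.  Defaults are p_max = 0.01 and
min_abs_fc = 1 (FC > 2); both are exposed, since figure-level analyses
of such designs sometimes use p < 0.05 with |log2 FC| > 1.5.  Fold
change is the difference of per-line log2 means (a geometric-mean
ratio), consistent with the transform preceding analysis.  No
multiple-testing correction is applied by default — DAM selection uses
raw p-value thresholds, BH correction appearing only at the pathway
stage — but an optional BH switch exists.  Whether fold changes should
instead be ratios of raw means is genuinely ambiguous in studies of
this type; the log2-mean convention used here is stated rather than
assumed equivalent.

PCA treats samples as observations and mean-centered features as
variables, via SVD; explained-variance fractions are non-increasing and
sum to ≤ 1.  Scores are reproduced (to sign) by an eigendecomposition
of the sample Gram matrix in tests.

## Synthetic data

The generator emulates the study design: 48 samples, log-normal
biological noise, an additive experiment-block shift with sum-zero
coding (+b in block 1, −b in block 2, b ~ N(0, σ_block)), and planted
effects:

| parameter | default | meaning |
|---|---|---|
| n_features | 2000 | features per table |
| base_mean, base_sd | 14, 2 log2 | baseline intensity and spread |
| sigma_bio | 0.5 log2 | replicate SD |
| sigma_block | 0.25 log2 | experiment-block SD |
| organ/line/interaction fractions | 0.2 / 0.1 / 0.05 | affected features |
| line_effect, interaction_effect | 2.0 log2 | planted \|log2 FC\| |
| lod_quantile | 0.05 | fraction of raw intensities censored |
| library_fraction | 0 | features given library ion m/z ± 3 ppm |

σ values are generator conventions chosen as typical of replicated
plant LC-MS intensities, not measured claims.  Censoring is rank-based
(the lowest raw intensities become missing), emulating a detection
limit rather than random missingness.  Ground truth is returned per
feature; a feature is a *planted* DAM in an organ iff its total planted
line difference there exceeds 1 log2 unit, matching the selection
threshold.  Spiked m/z values jitter uniformly within ±3 ppm of library
ion masses; decoys are kept ≥ 10 ppm from every library mass, so at the
5 ppm annotation tolerance spiked features are recovered exactly and
decoys never match (the generator rejects configurations whose jitter
exceeds the annotation tolerance).

What the simulation does not emulate: correlated features (adducts,
isotopologues, in-source fragments of one metabolite), retention-time
structure, heteroscedastic noise, or batch trends within a block.
Passing calibration and power checks on this generator therefore
validates the statistical machinery, not robustness to those real-data
pathologies.

## Pathway enrichment

The bundled database is a deliberately miniature stand-in for a full
organism-level metabolic database: 12 pathway names with curated
membership over library compounds plus common primary metabolites
(galactinol, raffinose, the pyridoxine series, purine nucleosides,
threonate/ascorbate, methylthioalkylmalates, amino acids …), with
within-pathway chain adjacency and cross-links through shared
compounds.  It exists to exercise the algorithms; a real KEGG-derived
database can be supplied through the same `PathwayGraph` interface.

Enrichment is the hypergeometric tail P(X ≥ hits) for drawing
|significant| compounds from the annotated universe, with pathway
membership clipped to that universe.  A seeded permutation null
(default 2000 resamples, add-one smoothed) is reported alongside and
agrees with the hypergeometric p within Monte-Carlo error; this is a
stated simplification of the mummichog activity-score machinery.
BH-FDR is applied across pathways on the hypergeometric p.  Impact is
the share of endpoint-inclusive betweenness centrality carried by hit
nodes within each pathway's own subgraph — 1 when all members are hit,
0 when none (or when the pathway has no centrality mass).  Reporting
defaults flag pathways with FDR < 0.03 and impact > 0.3.

## Fragmentation rule engine

Spectrum trees hold a precursor (high-resolution), polarity, and
MS2..MS5 scans of (m/z, relative intensity) with base-peak markers;
product ions from ion-trap MS^n are nominal, so product matching uses a
0.5–0.6 Da window while precursor gates use 5–10 ppm where the
chemistry warrants it.  Every rule is an independent pattern matcher
returning evidence (each item with its mass error) and a
diagnostic/supporting confidence.

Numerical and design choices that matter:

* **HQA regiochemistry** is gated on nominal precursors 353/337/367
  (one library row's printed measured mass is ~60 ppm from its formula,
  so a high-resolution gate would wrongly reject a genuine
  4-caffeoylquinate); base peak 173 → 4-acyl, base peak at the acid
  anion → 5-acyl, otherwise "unassigned-HQA" at supporting confidence.
* **Threonate esters** are gated at 10 ppm on the formula-derived
  caffeoyl/coumaroyl/feruloyl-threonate [M−H]⁻ — necessary because an
  unrelated flavone shares the nominal precursor 297 *and* the 118 Da
  loss pattern.  The dictionary stores the formula-derived threonate
  residue mass (118.0266 Da); the figure 118.0278 that circulates in the
  literature is treated as a measured value of the same loss.
* **Amides** require positive mode, precursor ≤ 450 Da (larger
  flavonoid [M+H]⁺ trees can show a coincidental 130 Da gap), and a
  putrescine (88) / agmatine (130) / spermidine (145) loss or the
  protonated-putrescine ion at 89.  When two library isomers share
  formula, class and spectrum, the call is annotated as a possible
  cis/trans conformer pair — geometry itself is not assignable from MS.
* **Flavonoid glycosides**: the aglycone is inferred among apigenin,
  luteolin, chrysoeriol, tricin, quercetin, isorhamnetin by a scored
  match (bare aglycone ion > +41/+71 C-series > di-C +83/+113 pair,
  with the 2″-O dehydrated series only counted when the tree shows
  O-glycoside behaviour), under a hard composition gate: the precursor
  minus aglycone must decompose into 1–4 sugar residues
  (162/146/132 Da) plus at most one acyl residue, an acyl being allowed
  only when its neutral loss is actually observed.  Ties between
  isobaric interpretations (apigenin+2 hexoses vs
  chrysoeriol+hexose+pentose are the same nominal mass) are broken by
  prevalence order.  Glycosidic class evidence is read from the
  precursor scan only; sugar-mass gaps in deeper scans are cross-ring
  completions of C-bound sugars and are ignored, as are O-losses that
  terminate on a C-signature ion.  Cross-ring losses alone (90/120,
  74/104) are supporting evidence and never class-defining.  Sugar
  identity is reported only at the hexose/deoxyhexose/pentose level —
  MS cannot separate glucose from galactose.  Position (7-O, 2″-O,
  6″-O) and interglycosidic-bond ((1→2) from [M+H−164]⁺, (1→6) from
  low-abundance −162/−146 with −308) annotations are tags, not classes.
* **Proanthocyanidins** are gated on the nominal mass lattice of
  flavan-3-ol monomers/dimers/trimers ((epi)catechin 290,
  (epi)gallocatechin 306 units; A-type = B-type − 2 Da).  Diagnostic
  evidence is a quinone-methide monomer ion (287/289/303/305) or a
  retro-Diels-Alder loss (152/168) together with heterocyclic ring
  fission (126); a precursor-mass match with fragments but no such
  pattern yields a supporting-confidence call.  Stereochemistry
  (catechin vs epicatechin) is not assignable.

`identify()` merges per-polarity matches (within the flavonoid family,
C-type and O-type evidence combine to O,C), ranks library candidates by
precursor mass error with class-compatible candidates first, and
assigns MSI levels: 1 requires a precursor match to a standard-linked
library record plus ≥ 60 % overlap with its recorded product ions, and
a retention-time match when both sides carry one (the bundled library
prints none, so the RT clause is vacuous for bundled records); 2 is the
same spectral match to a non-standard record; 3 is class-only.
Contradictory diagnostic classes produce an explicitly ambiguous call
with all candidates listed, never a silent override.

### Replay of the bundled spectra

Replaying all 93 bundled fragmentation pathways reproduces the curated
structural class for 87, with all 13 standard-confirmed compounds at
MSI level 1.  The six disagreements are properties of the printed
spectra, not free parameters: c08 (precursor mass inconsistent with
the HQA formula it prints; left "unassigned-HQA"), c52 (a di-O-glucoside
standard whose printed MS2 contains a C-glycoside signature ion), c55
(a spectrum mixing cross-ring and clean-loss signatures; engine reads
C, curation says O), c60 (an acylated glycoside whose sugar losses all
occur below the precursor scan; engine abstains), c65 (a lignan
glycoside — outside the rule vocabulary — that fragments like an
O-glycoside), and c69 (printed ions form a complete chrysoeriol di-C
pair that outscores the correct apigenin 2″-O reading at nominal
resolution).  This list is frozen in the test suite.

## Pipeline

Stages run in dependency order (enrichment requires annotation;
statistics require input tables or simulation), each logging row counts
in and out; the effective configuration (path-free) and a manifest of
relative output paths are written next to the outputs, and identical
configuration plus seed gives byte-identical files.  Feature-table TSVs
are read with round-trip float parsing so write→read is bit-exact.

## Problem sizes and verification

The shipped checks use a 2000-feature null simulation (calibration of
p(line): fraction below 0.01 expected in the binomial band
[0.005, 0.018]), a 200-feature planted-effect simulation
(|log2 FC| = 2, σ_bio = 0.5; DAM sensitivity ≥ 0.9 — at these settings
the per-organ FC estimate has SE ≈ 0.25, so power is essentially 1),
and a 400-feature demo determinism run; these sizes make the whole
suite run in seconds while leaving the binomial bands meaningful.
Oracle tests pin the ANOVA against hand sums-of-squares arithmetic
(1e-10) and statsmodels, the hypergeometric p against exhaustive
enumeration, BH against the hand step-up calculation, and PCA against
an independent eigendecomposition (1e-8, sign-adjusted).

## Known limitations

* The rule vocabulary covers phenylpropanoid/flavonoid chemistry plus
  free amino acids; lignans, benzoate glycosides, apocarotenoids and
  other classes in the library are deliberately left to abstention.
* Isobaric aglycone/sugar combinations are not always separable from
  nominal-resolution MS^n; the prevalence tie-break is a stated prior.
* The acylated-flavonoid pattern rests on a single exemplar in the
  reference material and is marked low confidence.
* The enrichment database is miniature; its FDR/impact values exercise
  the algorithms and are not comparable to organism-scale databases.
* Charge states > 1, isotope-pattern scoring and in-source fragment
  prediction from structures are out of scope.
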