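# Methods

## Affinity data model and the censored transform

Affinities are stored in nM throughout; readers never infer units. A cell
is *censored* when the table reports it only as exceeding the assay limit
(token `>10000`, or any numeric value strictly above `limit_nM`); a cell is
*absent* when empty. The binding-energy transform maps measured x nM to
log10(x) — proportional to the binding free energy — and fixes every
censored cell at a uniform ceiling (default 5.0, i.e. 100 µM, one log unit
above the default 10 µM limit). The ceiling must not fall below
log10(limit); pushing all non-binders to one value deliberately compresses
their contribution to correlations rather than discarding them.

Values reported exactly at the limit count as measured, not censored.
Below-limit (`<`) censoring is not modelled. Absent cells are excluded from
potency sets and handled pairwise-complete in correlations, never imputed;
the source panels this emulates are complete matrices, so absence handling
is this package's own extension.

## Activity homology

AH(A→B) = 100 · |P_A ∩ P_B| / |P_A| with P the potent set at a strict
threshold (default < 150 nM; the boundary value is not potent). Rows whose
potent set is empty are *undefined*, not zero — 0/0 has no meaning as a
conditional probability — and are dropped from clustering with a warning.
Curves order targets by descending AH with a chosen reference, ties broken
lexicographically by id; clustering uses average linkage on Euclidean row
(and column) distances, scipy's deterministic merge order, so figures are
bit-reproducible. Both linkage and metric are configurable.

## Profile correlation and disk plots

Pearson r over pairwise-complete inhibitors, minimum 3 shared points and
nonzero variance in both profiles, else undefined. Censored cells
participate at the ceiling; as the censored fraction grows, profiles
degenerate toward constancy and r becomes undefined rather than
misleadingly large. Disk hues interpolate linearly in RGB between the
anchors red (r=1.0), magenta (0.8), blue (0.5) and green (0.2), clamped
below 0.2; radii grow linearly from a minimal disk at r ≤ 0.2. Whether the
original figures' radii encoded r or a fixed size per hue class is not
documented; monotone radius was chosen as the least surprising reading.
The kinome layout is consumed as an input table (kinase, x, y, group) —
the classic dendrogram artwork is copyrighted, and any layout works.

## Pseudo-inhibitor PCA

Targets are observations, inhibitors variables. Columns are centered and,
by default, scaled to unit variance (correlation-matrix PCA; covariance
PCA by flag). The published description does not pin down which axis was
standardized; per-inhibitor standardization is consistent with treating
targets as t points in inhibitor space. The decomposition is the SVD of
the standardized matrix — numerically stabler than an explicit covariance
eigen-solve; tests cross-check both routes. Zero-variance columns are
dropped with a warning. Component signs are fixed by orienting each
loading column so its largest-magnitude coefficient is positive. k
defaults to min(t, n) − 1 (the rank bound after centering). Explained
variances use the ddof=1 convention, so on standardized input they sum to
the number of retained columns.

The family-separation diagnostic reports, per component, |mean score of a
group − mean of the rest| / max(within-group SD); a ratio above 2 on a
leading component is read as the group being isolated, mirroring how a
selectivity-orthogonal kinase family separates on one axis.

## Activity-state PLS

Single-response NIPALS PLS1: descriptors centered and unit-variance
scaled, the 0/1 activity state centered. R²_cum = 1 − SS_res/SS_tot on the
training data. Q²_cum = 1 − PRESS/SS_tot with PRESS pooled over all
held-out predictions of a stratified k-fold cross-validation (default 7
folds); each fold refits scaling and model on its training split. The
commercial implementation this mirrors keeps its exact component
significance rule proprietary, so the transparent surrogate used here adds
components while the cumulative Q² gain exceeds a threshold (default
0.01), capped at `max_components`. Fold assignment is keyed to sorted
structure ids and a seed, so it is reproducible and invariant to row
order. Angular descriptors are consumed as given (no circular statistics):
the descriptor table is precomputed upstream. Prediction applies the
stored coefficients on the training scaling; class calls threshold ŷ at
0.5.

## Structure superposition

Monomers are extracted one polymer chain at a time (gemmi handles PDB and
mmCIF); waters are dropped, non-polymer heterocompounds kept as ligand
annotations, altlocs resolved to the highest-occupancy conformer with ties
going to 'A'. Residue numbering is author numbering — the anchor presets
are author-numbered ranges, and the two EGFR alternatives correspond to
the mature-protein vs precursor conventions, selected per entry by which
hinge window is present. Anchor Cα atoms are paired positionally within
the stated ranges (they are equal-length curated windows, so no sequence
alignment is needed; unequal counts are an error). The rigid fit is Kabsch
least squares via SVD with the determinant sign correction, so reflections
are never returned; a quaternion (Horn) solver exists only as an
independent oracle in the tests. Aromatic ring centroids (Phe/Tyr/Trp/His
side-chain rings) across a superposed ensemble are clustered by single
linkage at a distance cutoff (default 2 Å) — equivalent to connected
components of the ≤cutoff graph — with labels numbered by lowest member
index.

## Synthetic data: what it emulates and what it does not

The affinity generator draws log10 Kd(i,j) = µ + a_f(i) + b_j + c_f(i),j +
ε_ij with independent Gaussian effects (binding free energies are additive
in log-affinity): a grand mean µ, a family shift a_f, an inhibitor
promiscuity term b_j, a family × inhibitor interaction c_fj that gives
family members correlated profiles, and measurement noise ε. One family
can be made an outlier via two independent knobs: a dedicated inhibitor
subset boosted in potency for it alone, and decoupling (its interaction
terms with all other inhibitors zeroed), so orthogonality and potency are
testable separately. Cells above the censoring limit are emitted censored.

Frozen defaults (the study conditions for all recovery tests and the
acceptance script): 4 families × 5 targets, 60 inhibitors, µ = 3.0 (1 µM —
a realistic panel median), family_effect_sd 0.3, inhibitor_effect_sd 0.5,
interaction_sd 0.8 (family identity carried by shared inhibitor
preferences, as in real panels), noise_sd 0.3 (≈ 2-fold assay error),
outlier family with 8 dedicated inhibitors at a 2.0 log-unit boost and
decoupling on, censoring at 10 µM (≈ 15% of cells). These values were
fixed once by a Monte-Carlo calibration of the recovery rates and are not
tuned per test.

The descriptor generator shifts `n_informative` of p standard-normal
descriptors by `shift_sd` SDs between balanced classes (defaults: 60 per
class, p = 233, 10 informative, shift 2 SD). The superposition generator
applies known random proper rotations and translations plus isotropic
Gaussian coordinate noise to a reference Cα trace, optionally planting
ideal phenylalanine rings at stated sites.

What the generators do *not* emulate: real kinases' affinity values or
chemotype structure (no chemistry-aware inhibitors), heavy-tailed or
correlated assay error, partially observed panels, descriptor correlation
structure or angular wrap-around, and real crystallographic pathologies
(missing loops, alternate chains). Passing recovery tests therefore shows
the machinery extracts planted structure of the assumed additive-Gaussian
form at realistic noise, not that it would resolve any particular real
kinase pair.

## Numerical choices and degenerate inputs

Correlations are clipped to [−1, 1] against rounding; Pearson is undefined
(NaN, never 0) for < 3 shared points or zero variance. PCA errors on
all-constant matrices and on absent cells (the caller completes or drops).
PLS errors on a constant response or folds < 2; zero-variance descriptors
are dropped with a warning, and NIPALS stops early when the deflated
response is numerically zero. Superposition errors below 3 matched anchor
Cα. All tie-breaks (curve ordering, cluster labels, loading signs) are
deterministic so seeded pipeline reruns are byte-identical.

## Problem sizes

The recovery statistics average 20 replicate panels of 20 × 60; the PLS
conditions are 120 × 233 with 7-fold CV; superposition ensembles are 10
members × 50 Cα plus two planted ring sites. These sizes give stable
Monte-Carlo estimates for the planted-structure checks while keeping the
full suite and the acceptance script fast to rerun.

## Known limitations

AH carries no significance testing or bootstrap intervals. PCA offers no
factor rotation or missing-data EM. PLS is single-response only, with no
orthogonal-PLS variant, and which upstream structural annotations define
"active/inactive" ground truth is inherited from the descriptor table, not
decided here. The superposition module does not detect kinase domains from
sequence or call DFG-in/out states from raw coordinates — conformational
state lives in the descriptor table. Historical ensemble statistics from
ever-growing structure archives are treated as non-reproducible
observations, not targets.
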