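# Methods

This note records the models, conventions and design choices behind
`dompaint`, in the order the pipeline runs them.

## Formula assignment

Peaks are assumed singly charged, even-electron [M−H]⁻ anions; the
neutral mass is m/z + 1.00727646 Da (proton mass, electron mass folded
in). Assignment enumerates every CHNOS composition inside the element
bounds whose exact monoisotopic mass (CODATA values, e.g. CH₂ =
14.0156500638 Da) matches the neutral mass within the ppm tolerance,
then filters by elemental-ratio windows and the even-electron rule
(DBE = 1 + C − H/2 + N/2 must be a non-negative integer; radical
species are excluded). Implementation detail: only the (C, N, O, S)
sub-lattice is materialized; the hydrogen count is recovered from the
residual mass, which makes per-peak cost a few vectorized passes while
remaining exactly equivalent to full enumeration (verified against an
independent five-dimensional lattice oracle in the tests).

Defaults — tolerance 0.5 ppm; C 1–100, H 1–200, N 0–4, O 0–80, S 0–2;
0.3 ≤ H/C ≤ 2.5; O/C ≤ 1.2 — follow common negative-mode FT-ICR
practice for natural organic matter and are fully configurable. When
several candidates survive, all are returned ordered by |ppm error| and
the lowest-error one is flagged primary; ambiguous peaks are not
discarded. Isotopologue (¹³C) verification and multiply charged species
are out of scope.

The modified aromaticity index uses the 0.5·O weighting with P = 0 and
is clamped to 0 whenever its numerator or denominator is non-positive.
The four compound classes partition the (AI_mod, H/C) plane; boundary
cases follow the inequalities exactly as written (aromatic is the
half-open interval (0.5, 0.67]).

## Chemodiversity profiling

Sample × formula matrices are TIC-normalized (each row divided by its
total intensity). Clustering uses Ward's criterion in its Ward.D2 form
(Lance–Williams on squared Euclidean distances with square-root
heights), delegated to `scipy.cluster.hierarchy.linkage(method="ward")`,
which implements exactly that convention. PCA is an SVD of the
centered (and by default standardized) matrix; all-zero/constant
columns must be removed before standardized PCA, and the pipeline does
so. Component signs are fixed by making each loading vector's
largest-magnitude entry positive. Quadrant signatures use strict sign
matching: a formula with loading exactly 0 on a ruled component is
excluded.

## Morphological profiling

Wells aggregate cells by per-feature mean and unbiased (n−1) variance
plus Pearson correlations across cells for a configurable pair list.
"Correlation" features are interpreted as across-cell correlations
within a well (the across-well reading would make them per-treatment,
not per-well, quantities). The default schema is 100 base features
(means + variances) and 72 pairs = 272 columns, matching the standard
dimensionality of compartmental Cell Painting readouts.

rMAD normalization is per plate and per feature against that plate's
vehicle-control wells: z = (x − median_ctrl)/MAD_ctrl with the **raw**
MAD (no 1.4826 consistency constant; togglable), so normalized controls
have median 0 and MAD 1 by construction. Features with zero control MAD
(or missing values from single-cell wells) are dropped and logged.

The Global Euclidean Distance is the ℓ2 norm of a treatment's median
(over its replicate wells) normalized profile — the deviation from the
control origin. The high/low activity partition is a reconstruction:
an exhaustive 1-D search over sorted split points for the two-group
partition maximizing between-group variance (Otsu's criterion); the
upper group is "high". Identical scores yield all-"low" plus a warning.

The fluorescence-interference assessment implements only the
subtraction arithmetic of a no-cell control experiment:
autofluorescence = sample − PBS blank; dye effect = mixture − dye
alone, negative values reported as quenching.

## Sparse PLS integration

Preprocessing: X is TIC-normalized, zero-variance peaks dropped
(tolerance 1e-12 absorbs float residue of the TIC division), and each
peak scaled to unit variance across samples; Y is the per-sample median
morphological profile. The merged (X|Y) row is then z-scored within
each sample and re-split. Row-wise z-scoring across heterogeneous
blocks is statistically unusual but implemented literally as the
primary path; `row_zscore=False` gives the column-standardized-only
variant. With many planted Y-signal columns, row scaling visibly
couples the blocks' scales — one reason the default synthetic study
plants a sparse (10-feature) morphology support.

Each component solves max cov(Xu, Yv) by NIPALS power iteration with
soft-thresholding of u and v to the keepX/keepY largest magnitudes
(threshold = the (keep+1)-th largest |entry|, i.e. the lasso shrinkage
that empties everything below the kept set), renormalized to unit norm.
With no thresholding the fixed point is the leading singular pair of
XᵀY, which is then used in closed form; the iterative path stops when
the loading change falls below 1e-9 or at 500 iterations (a cap hit
emits a warning; a loading collapsing to zero raises). Sign convention:
the largest-|u| entry is made positive (v flips with u), making fits
deterministic. Deflation is regression mode: X is deflated by its own
scores ξ = Xu, Y is regressed on ξ — chemistry predicts morphology.
Prediction uses the standard W(CᵀW)⁻¹ score reconstruction.

Q².total per component h is 1 − PRESS_h/RSS_{h−1}: PRESS sums squared
out-of-fold errors of the h-component model over all Y columns (10
folds × 5 repeats, fold assignment by seeded shuffle; centering is
fold-wise so held-out rows never touch training means), RSS_{h−1} is
the full-data residual sum of squares of the (h−1)-component model
(RSS₀ = total SS of Y). Components are retained while Q² > 0.0975,
stopping at the first failure. Sparsity tuning maximizes the Pearson
correlation of pooled out-of-fold component-1 scores (ξ, ω), averaged
over repeats, ties broken toward sparsity.

## Mass-difference networks and Kendrick analysis

The packaged transformation table has 40 entries composed from the
standard reaction categories of organic-matter chemistry (alkyl chain
extension, skeletal carbon addition, acylation, carbonylation,
oxidation/redox, hydroxylation/hydration, carboxylation, amino-related
including nitration/nitrosation, diazomethylation). Every delta keeps
hydrogen/nitrogen parity so it can connect two even-electron CHNOS
neutrals; the table is user-replaceable via CSV. Default edge mode is
elemental (exact composition difference), since nodes carry assigned
formulas; mass mode (default tolerance 0.0005 Da) exists for unassigned
mass lists. Subnetworks are connected components; transformation
frequencies count one per matching label per edge, ranked by count with
ties toward the smaller mass delta.

Kendrick: km = m × round(M_base)/M_base, nkm = round(km),
KMD = nkm − km, bases CH₂ (14.0156500638) and O (15.9949146221). KMD is
invariant under integer base-unit steps up to float rounding (~1e-13
over the DOM mass range). Series detection groups formulas whose KMD
agrees within 5e-4 and whose masses sit an integer number of base units
apart; each formula joins at most one series per base, series below two
members are discarded.

## Synthetic data

The generators emulate a 33-sample reference-material study: 9
terrestrial humic acids, 8 terrestrial fulvic acids, 2 microbially
derived fulvic acids, 14 aquatic fractions (the microbial archetype is
given two samples rather than a singleton so its within-archetype
spread is defined). Archetype windows are calibrated to the qualitative
van Krevelen geometry of such materials — terrestrial HA H/C 0.6–1.1 /
O/C 0.2–0.5, N-rich; terrestrial FA O/C 0.5–0.8 (tannin-like);
microbial H/C 1.5–2.0, N/S-rich, mass < 600 Da; aquatic intermediate,
CHO-dominated — illustrative, not fitted. Each archetype library draws
log-normal base abundances (σ = 1) shared by its samples, modulated by
per-sample multiplicative noise (σ = 0.3) and detection dropout that,
as in real spectra, affects low-abundance formulas (the base peak is
always detected; near-threshold peaks drop at about twice the average
10 % rate).

The planted chemistry → morphology model is linear-Gaussian: a sparse
±1 loading a over 20 chemical features defines the latent score
t = Za (Z the TIC'd, standardized matrix, t standardized); wells are
t·b + N(0, 0.5²) over a sparse ±1 morphology loading b (10 features by
default); controls are baseline noise. "Active" treatments additionally
shrink every nucleus mean feature by a stated number of control MADs
(MAD = 0.6745 σ for normal noise). The single-cell generator draws
nuclear area (180 ± 30 px² per cell, ± 6 px² well-to-well), derives the
diameter geometrically and couples cell area to nuclear area, so a
planted −5 MAD nuclear-area shift propagates through the correlated
features exactly as real shrinkage would.

What passing tests do and do not show: the generators have no plate
(edge) effects, no isotope patterns or adducts, no dose–response
nonlinearity, and within-archetype chemistry is far cleaner than field
samples; pipeline recovery on these data demonstrates correctness of
the computations, not expected performance on real mixtures. In
particular, planted-support recovery (F1 ≥ 0.9) holds under
independent-noise chemistry with a genuine rank-1 signal; on the
archetype-structured study matrix the strong within-archetype column
correlations make the specific support unidentifiable — sparse PLS then
selects archetype-covarying surrogates, which is the expected behavior
of any covariance-driven selector on collinear blocks.

## Problem sizes

Default test and acceptance runs use 33 samples × ~600 formulas,
500/80-dimensional integration blocks, 100-seed replications for the
stochastic claims and 200-peak assignment batches; these sizes keep the
complete verification under a few minutes on a single CPU while leaving
every statistical margin (e.g. ≥ 95/100 recovery) intact.
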