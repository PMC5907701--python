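# Methods

This note documents the model, the numerical choices, the synthetic data
the package is validated on, and the known limitations. Notation: the
contact map is an L×L symmetric score matrix; axis 0 (residue index i) is
x, axis 1 (residue index j) is y, so a parallel strand pairing advances
(+1, +1) on the map (ridge direction φ = π/4) and an antiparallel pairing
advances (+1, −1) (φ = 3π/4).

## Ridge model

A run of consecutive β-β contacts is modelled as a straight ridge: a curve
whose every point is a local maximum in the direction orthogonal to the
curve. Around a cell the map is approximated by the quadratic
f(x, y) = a + bx + cy + dx² + exy + gy², fitted by ordinary least squares
over the (2·`quad_half_width`+1)² neighbourhood (default 5×5, reflection
padding at map edges). The fit is a linear filter, so the six coefficients
are computed for all cells at once by correlation with six fixed stencils;
the fit is exact on any surface of total degree ≤ 2, which the test suite
checks to 1e−9.

The Hessian H = [[2d, e], [e, 2g]] is eigen-decomposed in closed 2×2 form
into λ_p ≤ λ_q with unit eigenvectors **v**_p (across the ridge) and
**v**_q (along it). Eigenvector signs are normalized so the first nonzero
component is positive, making φ single-valued; an exactly degenerate
Hessian (λ_p = λ_q) returns the axis-aligned pair. A cell is a ridge point
iff λ_p < 0 and |∇f·**v**_p| ≤ tol·max(‖∇f‖, ε) with tol = 0.1 and
ε = 1e−12. The exact condition ∇f·**v**_p = 0 holds only on continuous
surfaces; the relative tolerance makes it usable on discrete maps, and the
ε guard keeps exact local maxima (zero gradient) inside the ridge set.
Under the quadratic model the ridge is the line {x : **v**_p·(∇f + Hx) = 0};
its direction φ = angle(**v**_q) mod π and its distance from the cell is
d = |∇f·**v**_p| / |λ_p|.

## Scale selection, width and height

Ridge strength is NL = (λ_p² − λ_q²)², zero for isotropic curvature and
maximal for elongated (one-dimensionally curved) structure. The map is
smoothed with isotropic Gaussians (kernel truncated at 4σ, reflection
boundary) over the scale grid; the γ-normalized response NL_γ = σ⁶·NL is
evaluated per cell at each scale, and the best scale σ* is the grid argmax
over scales at which the cell passes the ridge test, refined by a parabolic
fit in log σ through the argmax and its two neighbours. For a continuous
Gaussian ridge of cross-section std s the response σ⁶·s⁴/(s²+σ²)⁶ peaks
exactly at σ = s, so the width estimate is w = c·σ* with c = 1 in theory.
On discrete maps the fixed 5×5 derivative stencil under-reads the curvature
of narrow ridges, shifting the optimum upward; the calibration constant is
therefore measured by a brute-force sweep over analytic Gaussian ridges
(`calibrate_width_constant`), giving the frozen c = 0.804 (mean over stds
1–3 cells). The residual bias is width-dependent (the ratio s/σ* runs from
~0.63 at s = 1 to ~0.93 at s = 3), so w is accurate near the strand-ridge
widths it is calibrated for and the *location* of the optimum remains
linear in s (R² ≈ 0.995), which is what scale selection requires.

Ridge height h is the amplitude of A·exp(−(t−μ)²/2s²) + b least-squares
fitted to the unsmoothed map sampled by bilinear interpolation along
**v**_p through the ridge-line foot point over a ±3w span (25 samples).
The additive baseline b absorbs the nonzero background of contact maps, so
h measures amplitude above background and adding a constant to the map
leaves d unchanged and h within fit tolerance. The fit runs as a damped
Gauss–Newton iteration batched over all valid cells with a fixed iteration
count (deterministic); a degenerate fit falls back to peak-minus-minimum.

Defaults: sigma grid = 12 log-spaced values in [0.5, 4.0] grid units
(strand-pairing ridges are 1–3 cells wide; the grid brackets that range and
the unique-interior-maximum property validates it). Cells that pass the
ridge test at no scale carry sentinels h = 0, φ = 0, d = −1, w = −1 and
valid = false; the sentinel −1 also marks out-of-map cells in 2D feature
windows, distinguishing boundary from a genuine zero score.

## Feature geometry

Stage-1 rows concatenate, for each of the three 2D maps (raw score, ridge
h, ridge φ — d and w are dropped by feature selection), the values under a
cross-shaped window mask (size ws, diagonal/anti-diagonal bands of width
dw = 3) centred on the pair; then H/E/C probabilities over length-ws
1D windows at i and at j (zeros outside the sequence); then the five
position features (j−i, i, L−1−i, j, L−1−j), 0-based; then two map-level
features (MSA depth per residue n_seqs/L, 0 when depth is unknown, and the
std of upper-triangle scores with j−i ≥ min_sep). For ws = 5 this gives
3·21 + 30 + 5 + 2 = 100 features. The 1D window length is tied to ws so the
1D and 2D context scale together. Candidate pairs are all i < j with
j−i ≥ min_sep = 3 (closer β partners are sterically impossible, and the
bound fixes the negative universe).

Stage-2 rows use a full 3×3 window over 14 maps — the four stage-1 score
maps with their per-row and per-column rank maps, plus ridge h and φ —
and length-3 SS windows: 14·9 + 18 = 144 features; position and map
features are dropped there by feature selection. Stage 3 is the same
construction on the single stage-2 map: 5·9 + 18 = 63 features. Ranks are
descending ordinal (1 = top of the row/column), ties broken by the smaller
index, normalized by L so they are length-invariant across proteins.

## Training protocol

All forests are scikit-learn `RandomForestClassifier`s with 500 trees by
default (other hyperparameters at library defaults) and derived,
per-(stage, window, fold) seeds, so two runs from one master seed produce
byte-identical models. Negatives are under-sampled per protein at 1:40
Pos/Neg from a stream keyed by (seed, protein id); all positives are kept,
the draw is capped at availability, and a protein with no positives still
contributes `ratio` negatives.

Model selection is protein-wise 5-fold cross-validation (fold sizes differ
by ≤ 1). Stage 2 trains on rows built from *out-of-fold* stage-1 maps and
stage 3 on out-of-fold stage-2 maps — training on in-fold predictions
would leak labels through the intermediate scores and inflate the later
stages; a provenance tag on every prediction map enforces this at the API
level. The suggested cutoff shipped in a bundle is the argmax of pooled
residue-level F1 over out-of-fold final-stage predictions on the grid
0.01…0.99 (step 0.01, ties to the smaller cutoff). After cross-validation
every stage is refit on the full training set; stage-2/3 final models keep
the out-of-fold rows as training data.

A model bundle stores the six forests, per-stage feature-schema manifests
(checked at prediction time), the suggested cutoff, the configuration
snapshot and the width-calibration constant; save/load round-trips to
identical predictions.

## Evaluation and restraints

Precision = TP/(TP+FP), Recall = TP/(TP+FN), F1 their harmonic mean, all
defined as 0 when the denominator is 0 (the zero-prediction edge case);
percentages print rounded half-up to two decimals. Strand-level
evaluation derives strands as maximal runs of E from a one-hot (DSSP-mode)
assignment — soft profiles are rejected because strand boundaries would be
ambiguous — and counts a strand pair as predicted/native if any residue
pair between the two strands is predicted/native; intra-strand pairs and
residues outside every strand contribute nothing.

Restraint export emits at most L records: every refined-map pair at or
above the cutoff as a strict 3.5–6 Å bound, topped up with raw-map pairs
in descending score that fall outside a (2k+1)² square window (k = 2 by
default; the window size is a package choice, configurable) around every
strict pair, as loose 3.5–10 Å bounds; control mode is the top-L raw pairs
at the uniform 3.5–8 Å bound. Files use 1-based indices (RR convention);
everything in memory is 0-based.

## Synthetic data

The generator emulates the regime the method is designed for, not the
physics of coevolution. Per protein: 2–7 strands of length 3–8 with ≥ 2
coil residues between them, a random spanning path of pairings (70%
antiparallel) with small register offsets so the topology is connected,
occasional helices in long coil stretches; truth contacts follow the
pairing rule (a1+k, b2−k−r) / (a1+k, b1+k+r). The map is |N(0, 0.4)|
background plus a Gaussian bump of amplitude 0.8 and std 1 cell at every
truth contact (runs of bumps form genuine ridges whose ground-truth width
is the bump std) plus 6 decoy diagonal/anti-diagonal segments at 0.8× the
signal amplitude placed away from truth cells, so brightness alone cannot
separate signal from decoys — the forests must use ridge geometry and
secondary structure. The SS profile's argmax matches the truth at 80% of
residues (comparable to the E-state accuracy of modern 3-state predictors),
with Dirichlet-distributed soft probabilities. All randomness flows from
one master seed through named child streams (stable CRC-derived entropy),
so datasets are reproducible and no two proteins share a map.

What this does *not* emulate: spatially correlated coevolution noise,
transitive-correlation artefacts, MSA-depth-dependent noise levels, β
bulges and irregular registers, or realistic secondary-structure error
correlations (errors here are independent per residue). Passing tests
therefore show that the pipeline recovers ridge-structured signal from
heavy unstructured noise under honest train/test separation — not that it
attains any particular accuracy on real contact maps.

## Problem sizes and determinism in the shipped checks

The test suite and `scripts/acceptance.py` use a scaled-down study: 40
training + 10 held-out proteins with L ∈ [60, 120] and 60-tree forests
(one run ≈ 3–4 minutes on one CPU; the determinism check repeats the full
run and compares pickled forests and predictions byte-for-byte). The
suggested cutoff, per-stage CV F1, held-out residue/strand F1, raw-map
best-threshold baseline and refinement gain are all recomputed from the
seed at run time.

## Limitations

- Ridge width w is calibrated at strand-ridge scales; it is biased for
  ridges much narrower than 1 or much wider than 3 cells.
- φ is reported modulo π; the two strand orientations map to π/4 and 3π/4,
  but a ridge direction never distinguishes which strand comes first.
- The ridge test at tol = 0.1 admits a noise-dependent fraction of
  spurious cells; downstream forests, not the detector, are responsible
  for rejecting them.
- Strand-level evaluation needs a one-hot assignment, so with predicted
  secondary structure only residue-level numbers are available.
- The forests are trained on synthetic maps when built from this package's
  generator; applying a bundle to real predictor output requires
  retraining on maps from that predictor (the training entry point is the
  same `train_full_pipeline` / `betaridge train`).
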