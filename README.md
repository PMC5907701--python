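# betaridge

Identification of residue pairing in interacting β-strands from a predicted
residue contact map.

## The problem

Sequence-based residue contact predictors (CCMpred-style coevolution
methods, deep-learning predictors) emit an L×L score matrix that is often
dominated by noise, especially for small protein families. Yet β-β
interactions leave a characteristic collective signature on that matrix:
consecutive hydrogen-bonded residue pairs of two paired strands form short
bright runs along the diagonal (parallel pairing) or anti-diagonal
(antiparallel pairing). A run of contacts is far harder for noise to imitate
than a single bright cell, so β-β pairing can be recovered even from maps
whose individual entries are unreliable. Recovered pairings translate
directly into distance restraints for contact-assisted folding of mainly-β
proteins, the targets that suffer most from noisy contact maps.

`betaridge` treats the contact map as a 2D image and makes that signature
explicit with scale-space ridge detection, then refines it into per-pair
β-β contact scores with a 3-stage random-forest framework.

## The method

**Ridge features.** For every cell, a quadratic surface is fitted to the
5×5 neighbourhood by ordinary least squares, giving the local gradient ∇f
and Hessian **H**. Eigen-decomposition of **H** yields principal curvatures
λ_p ≤ λ_q with directions **v**_p, **v**_q. A cell is a ridge point when

λ_p < 0 and ∇f·**v**_p = 0 (within a relative tolerance on discrete data).

Ridge strength is the squared principal-curvature difference
NL = (λ_p² − λ_q²)², and its γ-normalized form

NL_γ = σ⁶ (λ_p² − λ_q²)²,

evaluated after Gaussian smoothing at scales σ, peaks at the scale matching
the ridge width (Lindeberg scale selection). Each cell gets four features:
ridge direction φ ∈ [0, π) (φ ≈ π/4 ⇒ parallel, φ ≈ 3π/4 ⇒ antiparallel),
distance d to the ridge line, height h (amplitude of a Gaussian-plus-baseline
fit to the cross-section), and width w (calibrated from the NL_γ-optimal σ).

**Multi-stage random forests.** Stage 1 trains four 500-tree forests (window
sizes 3/5/7/9) on the raw map, ridge h and φ under cross-shaped window masks
of diagonal width 3, plus H/E/C secondary-structure windows, position and
map-level features. Stage 2 combines the four stage-1 score maps and their
per-row/per-column rank maps under a 3×3 window; stage 3 repeats this on the
stage-2 map. Negatives are under-sampled protein-wise at 1:40. Model
selection and the suggested score cutoff come from protein-wise 5-fold
cross-validation; later stages train only on out-of-fold earlier-stage
predictions. Evaluation uses precision, recall and F1 at residue level
(predicted pairs vs. truth) and strand level (two strands interact if ≥ 1
residue pair between them is predicted).

Everything is testable offline: a seeded generator produces synthetic β
proteins — strand topologies, ground-truth contacts, noisy maps in which
contact runs form genuine ridges among decoy segments, and imperfect
secondary-structure profiles.

## Worked example

`examples/train_and_evaluate.py` trains on 12 synthetic proteins (30-tree
forests) and evaluates 3 held-out ones:

```
cross-validation pooled F1 per stage:
  stage 1 (per window size): {3: 0.746, 5: 0.759, 7: 0.753, 9: 0.742}
  stage 2: 0.807   stage 3: 0.813
suggested cutoff: 0.67

held000: residue F1 0.974 (raw-map best 0.667), strand F1 1.000
held001: residue F1 0.737 (raw-map best 0.552), strand F1 0.500
held002: residue F1 0.769 (raw-map best 0.649), strand F1 0.857
```

Stage 2 gains ~5 F1 points over the best single stage-1 model by combining
window sizes; on unseen proteins the refined map beats the best single
threshold on the raw noisy map by 10–30 points. The other examples
demonstrate the ridge detector on analytic ground truth
(`ridge_features.py`), the synthetic generator (`simulate_and_inspect.py`)
and restraint export (`export_restraints.py`).

A thin CLI wraps the same API:

```bash
betaridge --seed 1 simulate -n 40 --out data/
betaridge train data/manifest.yaml --out model.joblib --n-trees 60
betaridge predict model.joblib data/syn000.map data/syn000.ss --out pred.txt
betaridge eval pred.txt data/syn000.labels --cutoff 0.67 --dssp data/syn000.dssp
betaridge export-restraints pred.txt data/syn000.map --cutoff 0.67 --out pred.rr
```

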