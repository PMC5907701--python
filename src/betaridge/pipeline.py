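"""The 3-stage random-forest framework.

Stage 1 trains four forests, one per window size (3/5/7/9), on 2D features
(raw map, ridge height, ridge direction) under a cross-shaped mask of
diagonal width 3, plus secondary-structure windows, position features and
map-level features.  Stage 2 combines, under a full 3x3 window, the four
stage-1 score maps and their per-row/per-column rank maps with the ridge
height/direction and the secondary-structure windows (position and map
features are dropped there by feature selection).  Stage 3 repeats the
protocol on the single stage-2 map.  All forests use 500 trees by default
and 1:40 Pos/Neg protein-wise under-sampling.

Model selection is protein-wise 5-fold cross-validation.  Later stages are
trained on *out-of-fold* earlier-stage predictions, never on in-fold ones
(which would leak the training labels through the intermediate scores); the
``provenance`` tag on :class:`PredictionMap` enforces this.  The suggested
score cutoff shipped with a model bundle maximizes the pooled residue-level
F1 over the out-of-fold final-stage predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple
from zlib import crc32

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .config import RunConfig
from .io import ContactMap, LabelSet, SecondaryStructureProfile
from .features import (
    WindowMask,
    build_window_mask,
    candidate_pairs,
    extract_pair_features,
    feature_schema,
    map_features,
)
from .ridge import RidgeFields, WIDTH_CONSTANT, compute_ridge_fields

__all__ = [
    "PredictionMap",
    "ProteinData",
    "ModelBundle",
    "rank_matrix",
    "undersample",
    "train_stage1",
    "predict_stage",
    "assemble_stage2_features",
    "assemble_stage3_features",
    "protein_folds",
    "pooled_best_f1",
    "train_full_pipeline",
    "predict_protein",
]

BUNDLE_FORMAT_VERSION = 1
STAGE1_MAP_NAMES = ("raw", "ridge_h", "ridge_phi")


# ---------------------------------------------------------------------------
# prediction maps and ranks


def rank_matrix(scores: np.ndarray, axis: int) -> np.ndarray:
    """Descending ordinal ranks along an axis, normalized by L.

    Rank 1 is the top score; ties are broken by the smaller index along the
    ranked axis; values lie in (0, 1].
    """
    scores = np.asarray(scores, dtype=float)
    L = scores.shape[axis]
    moved = np.moveaxis(scores, axis, -1)
    order = np.argsort(-moved, axis=-1, kind="stable")
    ranks = np.empty_like(order)
    np.put_along_axis(ranks, order, np.arange(1, L + 1)[None, :], axis=-1)
    return np.moveaxis(ranks, -1, axis).astype(float) / L


@dataclass
class PredictionMap:
    """A symmetric stage-output score map with derived rank maps.

    ``provenance`` records how the scores were produced relative to the
    protein: ``"oof"`` (out-of-fold CV prediction), ``"infold"`` (predicted
    by a model that saw this protein in training) or ``"final"`` (test-time
    prediction by the shipped model).
    """

    scores: np.ndarray
    provenance: str = "final"

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if not np.allclose(self.scores, self.scores.T, atol=0.0):
            raise ValueError("prediction map must be exactly symmetric")
        if np.any(self.scores < 0) or np.any(self.scores > 1):
            raise ValueError("prediction scores must lie in [0, 1]")
        self._row_rank: Optional[np.ndarray] = None
        self._col_rank: Optional[np.ndarray] = None

    @property
    def length(self) -> int:
        return self.scores.shape[0]

    @property
    def row_rank(self) -> np.ndarray:
        if self._row_rank is None:
            self._row_rank = rank_matrix(self.scores, axis=1)
        return self._row_rank

    @property
    def col_rank(self) -> np.ndarray:
        if self._col_rank is None:
            self._col_rank = rank_matrix(self.scores, axis=0)
        return self._col_rank


@dataclass
class ProteinData:
    """One protein's inputs (and lazily computed ridge fields)."""

    name: str
    cmap: ContactMap
    ss: SecondaryStructureProfile
    labels: Optional[LabelSet] = None
    ss_truth: Optional[str] = None
    _ridge: Optional[RidgeFields] = field(default=None, repr=False)

    @property
    def length(self) -> int:
        return self.cmap.length

    def ridge(self, config: RunConfig) -> RidgeFields:
        if self._ridge is None:
            self._ridge = compute_ridge_fields(self.cmap, config)
        return self._ridge


# ---------------------------------------------------------------------------
# sampling and feature assembly


def undersample(
    pairs: np.ndarray,
    labels: LabelSet,
    ratio: int,
    seed: int,
    protein_id: str,
) -> Tuple[np.ndarray, np.ndarray]:
    """Protein-wise Pos/Neg under-sampling of candidate pairs.

    Keeps all positives (``p`` of them) and draws ``min(ratio * p,
    available)`` negatives uniformly without replacement from a stream
    seeded by ``(seed, protein_id)``; a protein with no positives still
    contributes ``ratio`` negatives so it is never silently dropped.
    Returns the selected pairs and their 0/1 labels.
    """
    if ratio < 1:
        raise ValueError("ratio must be >= 1")
    pairs = np.atleast_2d(np.asarray(pairs, dtype=int))
    is_pos = np.array([(i, j) in labels.contacts for i, j in pairs], dtype=bool)
    pos = pairs[is_pos]
    neg = pairs[~is_pos]
    p = len(pos)
    want = ratio * p if p > 0 else ratio
    n_neg = min(want, len(neg))
    rng = np.random.default_rng(
        np.random.SeedSequence([int(seed), crc32(protein_id.encode())])
    )
    chosen = np.sort(rng.choice(len(neg), size=n_neg, replace=False)) if n_neg else []
    sel_pairs = np.vstack([pos, neg[chosen]]) if p else neg[chosen]
    sel_labels = np.concatenate([np.ones(p, dtype=int), np.zeros(n_neg, dtype=int)])
    return sel_pairs, sel_labels


def stage1_features(
    protein: ProteinData,
    mask: WindowMask,
    pairs: np.ndarray,
    config: RunConfig,
) -> np.ndarray:
    ridge = protein.ridge(config)
    maps2d = [protein.cmap.scores, ridge.h, ridge.phi]
    mf = map_features(protein.cmap, min_sep=config.min_sep)
    return extract_pair_features(maps2d, protein.ss, mf, mask, pairs)


def stage1_schema(mask: WindowMask) -> list:
    return feature_schema(STAGE1_MAP_NAMES, mask, ss_window=mask.ws)


def _stage_maps(preds: Sequence[PredictionMap], names: Sequence[str]):
    maps, labels = [], []
    for pm, name in zip(preds, names):
        maps.extend([pm.scores, pm.row_rank, pm.col_rank])
        labels.extend([f"{name}_score", f"{name}_rowrank", f"{name}_colrank"])
    return maps, labels


def assemble_stage2_features(
    stage1_preds: Sequence[PredictionMap],
    ridge: RidgeFields,
    ss: SecondaryStructureProfile,
    pairs: np.ndarray,
    window_sizes: Sequence[int] = (3, 5, 7, 9),
    for_training: bool = False,
) -> np.ndarray:
    """Stage-2 rows: 4 x (score, row rank, col rank) + ridge h/phi under a
    full 3x3 window, plus length-3 SS windows; 144 features for defaults.

    When ``for_training`` is set, every stage-1 map must carry out-of-fold
    provenance -- training a later stage on in-fold predictions of its own
    training proteins would leak labels.
    """
    if len(stage1_preds) != len(window_sizes):
        raise ValueError(
            f"expected {len(window_sizes)} stage-1 maps, got {len(stage1_preds)}"
        )
    if for_training:
        bad = [pm.provenance for pm in stage1_preds if pm.provenance != "oof"]
        if bad:
            raise ValueError(
                f"stage-2 training rows require out-of-fold stage-1 maps, got {bad}"
            )
    names = [f"s1w{w}" for w in window_sizes]
    maps, _ = _stage_maps(stage1_preds, names)
    maps += [ridge.h, ridge.phi]
    mask = build_window_mask(3, 3)
    return extract_pair_features(maps, ss, None, mask, pairs, include_position=False)


def stage2_schema(window_sizes: Sequence[int] = (3, 5, 7, 9)) -> list:
    names = []
    for w in window_sizes:
        names.extend([f"s1w{w}_score", f"s1w{w}_rowrank", f"s1w{w}_colrank"])
    names += ["ridge_h", "ridge_phi"]
    return feature_schema(names, build_window_mask(3, 3), ss_window=3,
                          include_position=False, include_map=False)


def assemble_stage3_features(
    stage2_pred: PredictionMap,
    ridge: RidgeFields,
    ss: SecondaryStructureProfile,
    pairs: np.ndarray,
    for_training: bool = False,
) -> np.ndarray:
    """Stage-3 rows: stage-2 score + its two rank maps + ridge h/phi under a
    full 3x3 window plus SS windows; 63 features."""
    if for_training and stage2_pred.provenance != "oof":
        raise ValueError(
            "stage-3 training rows require out-of-fold stage-2 maps, "
            f"got {stage2_pred.provenance!r}"
        )
    maps, _ = _stage_maps([stage2_pred], ["s2"])
    maps += [ridge.h, ridge.phi]
    mask = build_window_mask(3, 3)
    return extract_pair_features(maps, ss, None, mask, pairs, include_position=False)


def stage3_schema() -> list:
    names = ["s2_score", "s2_rowrank", "s2_colrank", "ridge_h", "ridge_phi"]
    return feature_schema(names, build_window_mask(3, 3), ss_window=3,
                          include_position=False, include_map=False)


# ---------------------------------------------------------------------------
# forests


def _derived_seed(master: int, *tags) -> int:
    entropy = [int(master)] + [crc32(str(t).encode()) for t in tags]
    return int(np.random.SeedSequence(entropy).generate_state(1)[0] % (2**31))


def _fit_forest(X: np.ndarray, y: np.ndarray, config: RunConfig, *seed_tags):
    if len(np.unique(y)) < 2:
        raise ValueError(
            "training set contains a single class; cannot fit a forest "
            "(check labels and under-sampling)"
        )
    model = RandomForestClassifier(
        n_estimators=config.n_trees,
        random_state=_derived_seed(config.seed, "forest", *seed_tags),
        n_jobs=1,
    )
    model.fit(X, y)
    return model


def train_stage1(
    proteins: Sequence[ProteinData],
    ws: int,
    config: RunConfig,
    sampled: Optional[dict] = None,
    seed_tags: tuple = (),
):
    """Fit one stage-1 forest for a window size on under-sampled rows."""
    if ws not in config.window_sizes:
        raise ValueError(f"ws={ws} not in configured window sizes")
    if not proteins:
        raise ValueError("empty training set")
    mask = build_window_mask(ws, config.diag_width)
    Xs, ys = [], []
    for p in proteins:
        if sampled is not None and p.name in sampled:
            sel_pairs, sel_labels = sampled[p.name]
        else:
            pairs = candidate_pairs(p.length, config.min_sep)
            sel_pairs, sel_labels = undersample(
                pairs, p.labels, config.pos_neg_ratio, config.seed, p.name
            )
        Xs.append(stage1_features(p, mask, sel_pairs, config))
        ys.append(sel_labels)
    return _fit_forest(np.vstack(Xs), np.concatenate(ys), config,
                       "stage1", ws, *seed_tags)


def _scores_to_map(scores: np.ndarray, pairs: np.ndarray, L: int) -> np.ndarray:
    mat = np.zeros((L, L))
    mat[pairs[:, 0], pairs[:, 1]] = scores
    mat[pairs[:, 1], pairs[:, 0]] = scores
    return mat


def predict_stage(
    model,
    X: np.ndarray,
    pairs: np.ndarray,
    L: int,
    schema: Sequence[str],
    provenance: str = "final",
) -> PredictionMap:
    """Predict candidate-pair scores and mirror them into a full map.

    Non-candidate cells stay 0; rank maps are recomputed from the symmetric
    matrix on demand.
    """
    if X.shape[1] != len(schema):
        raise ValueError(
            f"feature row length {X.shape[1]} does not match schema "
            f"({len(schema)}); wrong stage or window size?"
        )
    pos_col = int(np.nonzero(model.classes_ == 1)[0][0])
    scores = model.predict_proba(X)[:, pos_col]
    return PredictionMap(_scores_to_map(scores, pairs, L), provenance=provenance)


# ---------------------------------------------------------------------------
# cross-validation machinery


def protein_folds(names: Sequence[str], k: int, seed: int) -> List[List[str]]:
    """Protein-wise folds: disjoint, covering, sizes differing by at most 1."""
    if k > len(names):
        raise ValueError(f"cannot make {k} folds from {len(names)} proteins")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), crc32(b"folds")]))
    order = list(rng.permutation(list(names)))
    return [order[i::k] for i in range(k)]


def pooled_best_f1(
    per_protein: Iterable[Tuple[np.ndarray, np.ndarray]],
    grid: Optional[np.ndarray] = None,
) -> Tuple[float, float]:
    """Best pooled residue-level F1 over a cutoff grid, ties to the smaller
    cutoff.  ``per_protein`` yields (candidate scores, 0/1 labels)."""
    if grid is None:
        grid = np.round(np.arange(0.01, 1.0, 0.01), 2)
    scores = []
    labels = []
    for s, l in per_protein:
        scores.append(np.asarray(s, dtype=float))
        labels.append(np.asarray(l))
    scores = np.concatenate(scores)
    labels = np.concatenate(labels)
    order = np.argsort(scores, kind="stable")
    s_sorted = scores[order]
    l_sorted = labels[order]
    suffix_pos = np.concatenate([np.cumsum(l_sorted[::-1])[::-1], [0]])
    total_pos = int(labels.sum())
    best_f1, best_cut = 0.0, float(grid[0])
    for cutoff in grid:
        idx = np.searchsorted(s_sorted, cutoff, side="left")
        tp = int(suffix_pos[idx])
        npred = len(scores) - idx
        fp = npred - tp
        fn = total_pos - tp
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
        if f1 > best_f1 + 1e-12:
            best_f1, best_cut = float(f1), float(cutoff)
    return best_f1, best_cut


def _candidate_scores(pm: PredictionMap, pairs: np.ndarray) -> np.ndarray:
    return pm.scores[pairs[:, 0], pairs[:, 1]]


def _pair_labels(pairs: np.ndarray, labels: LabelSet) -> np.ndarray:
    return np.array([(i, j) in labels.contacts for i, j in pairs], dtype=int)


# ---------------------------------------------------------------------------
# bundle


@dataclass
class ModelBundle:
    """A trained pipeline: per-stage forests, feature-schema manifests, the
    cross-validated suggested cutoff, the configuration snapshot and the
    ridge-width calibration constant."""

    stage1: Dict[int, object]
    stage2: object
    stage3: object
    schemas: Dict[str, list]
    suggested_cutoff: float
    config: RunConfig
    width_constant: float = WIDTH_CONSTANT
    report: dict = field(default_factory=dict)

    def save(self, path) -> None:
        payload = {
            "format_version": BUNDLE_FORMAT_VERSION,
            "stage1": self.stage1,
            "stage2": self.stage2,
            "stage3": self.stage3,
            "schemas": self.schemas,
            "suggested_cutoff": self.suggested_cutoff,
            "config": self.config.to_dict(),
            "width_constant": self.width_constant,
            "report": self.report,
        }
        joblib.dump(payload, path, compress=0)

    @classmethod
    def load(cls, path) -> "ModelBundle":
        payload = joblib.load(path)
        version = payload.get("format_version")
        if version != BUNDLE_FORMAT_VERSION:
            raise ValueError(f"unsupported bundle format version {version!r}")
        return cls(
            stage1=payload["stage1"],
            stage2=payload["stage2"],
            stage3=payload["stage3"],
            schemas=payload["schemas"],
            suggested_cutoff=payload["suggested_cutoff"],
            config=RunConfig.from_dict(payload["config"]),
            width_constant=payload["width_constant"],
            report=payload.get("report", {}),
        )


def predict_protein(
    bundle: ModelBundle,
    protein: ProteinData,
    return_stages: bool = False,
):
    """Run the full 3-stage pipeline on one protein."""
    config = bundle.config
    pairs = candidate_pairs(protein.length, config.min_sep)
    ridge = protein.ridge(config)
    stage1_preds = []
    for ws in config.window_sizes:
        mask = build_window_mask(ws, config.diag_width)
        X = stage1_features(protein, mask, pairs, config)
        stage1_preds.append(
            predict_stage(bundle.stage1[ws], X, pairs, protein.length,
                          bundle.schemas[f"stage1_ws{ws}"])
        )
    X2 = assemble_stage2_features(stage1_preds, ridge, protein.ss, pairs,
                                  config.window_sizes)
    pm2 = predict_stage(bundle.stage2, X2, pairs, protein.length,
                        bundle.schemas["stage2"])
    X3 = assemble_stage3_features(pm2, ridge, protein.ss, pairs)
    pm3 = predict_stage(bundle.stage3, X3, pairs, protein.length,
                        bundle.schemas["stage3"])
    if return_stages:
        return pm3, {"stage1": stage1_preds, "stage2": pm2}
    return pm3


# ---------------------------------------------------------------------------
# full training


def train_full_pipeline(
    proteins: Sequence[ProteinData],
    config: Optional[RunConfig] = None,
    k: int = 5,
) -> ModelBundle:
    """Cross-validate for cutoff selection and stage chaining, then refit
    every stage on the full set.

    The returned bundle's ``report`` carries the per-stage pooled CV
    F1-scores (``cv_f1_stage1`` keyed by window size, ``cv_f1_stage2``,
    ``cv_f1_stage3``) and the suggested cutoff.  Deterministic for a fixed
    protein list, configuration and seed.
    """
    config = config or RunConfig()
    if any(p.labels is None for p in proteins):
        raise ValueError("training requires labelled proteins")
    by_name = {p.name: p for p in proteins}
    names = [p.name for p in proteins]
    folds = protein_folds(names, k, config.seed)
    fold_of = {n: fi for fi, fold in enumerate(folds) for n in fold}

    all_pairs = {p.name: candidate_pairs(p.length, config.min_sep) for p in proteins}
    pair_labels = {p.name: _pair_labels(all_pairs[p.name], p.labels) for p in proteins}
    sampled = {
        p.name: undersample(all_pairs[p.name], p.labels, config.pos_neg_ratio,
                            config.seed, p.name)
        for p in proteins
    }

    masks = {ws: build_window_mask(ws, config.diag_width) for ws in config.window_sizes}
    schemas = {f"stage1_ws{ws}": stage1_schema(masks[ws]) for ws in config.window_sizes}
    schemas["stage2"] = stage2_schema(config.window_sizes)
    schemas["stage3"] = stage3_schema()

    # ---- stage 1: per-fold models, out-of-fold maps -----------------------
    oof_stage1: Dict[str, list] = {n: [None] * len(config.window_sizes) for n in names}
    cv_f1_stage1: Dict[int, float] = {}
    for wi, ws in enumerate(config.window_sizes):
        for fi, fold in enumerate(folds):
            train_prots = [by_name[n] for n in names if fold_of[n] != fi]
            model = train_stage1(train_prots, ws, config, sampled=sampled,
                                 seed_tags=("fold", fi))
            for n in fold:
                p = by_name[n]
                X = stage1_features(p, masks[ws], all_pairs[n], config)
                oof_stage1[n][wi] = predict_stage(
                    model, X, all_pairs[n], p.length,
                    schemas[f"stage1_ws{ws}"], provenance="oof",
                )
        cv_f1_stage1[ws], _ = pooled_best_f1(
            (_candidate_scores(oof_stage1[n][wi], all_pairs[n]), pair_labels[n])
            for n in names
        )

    # ---- stage 2 ----------------------------------------------------------
    rows2 = {
        n: assemble_stage2_features(
            oof_stage1[n], by_name[n].ridge(config), by_name[n].ss,
            sampled[n][0], config.window_sizes, for_training=True,
        )
        for n in names
    }
    oof_stage2: Dict[str, PredictionMap] = {}
    for fi, fold in enumerate(folds):
        X = np.vstack([rows2[n] for n in names if fold_of[n] != fi])
        y = np.concatenate([sampled[n][1] for n in names if fold_of[n] != fi])
        model = _fit_forest(X, y, config, "stage2", "fold", fi)
        for n in fold:
            p = by_name[n]
            Xn = assemble_stage2_features(
                oof_stage1[n], p.ridge(config), p.ss, all_pairs[n],
                config.window_sizes,
            )
            oof_stage2[n] = predict_stage(model, Xn, all_pairs[n], p.length,
                                          schemas["stage2"], provenance="oof")
    cv_f1_stage2, _ = pooled_best_f1(
        (_candidate_scores(oof_stage2[n], all_pairs[n]), pair_labels[n])
        for n in names
    )

    # ---- stage 3 ----------------------------------------------------------
    rows3 = {
        n: assemble_stage3_features(
            oof_stage2[n], by_name[n].ridge(config), by_name[n].ss,
            sampled[n][0], for_training=True,
        )
        for n in names
    }
    oof_stage3: Dict[str, PredictionMap] = {}
    for fi, fold in enumerate(folds):
        X = np.vstack([rows3[n] for n in names if fold_of[n] != fi])
        y = np.concatenate([sampled[n][1] for n in names if fold_of[n] != fi])
        model = _fit_forest(X, y, config, "stage3", "fold", fi)
        for n in fold:
            p = by_name[n]
            Xn = assemble_stage3_features(oof_stage2[n], p.ridge(config), p.ss,
                                          all_pairs[n])
            oof_stage3[n] = predict_stage(model, Xn, all_pairs[n], p.length,
                                          schemas["stage3"], provenance="oof")
    cv_f1_stage3, suggested_cutoff = pooled_best_f1(
        (_candidate_scores(oof_stage3[n], all_pairs[n]), pair_labels[n])
        for n in names
    )

    # ---- final refit on the full set --------------------------------------
    final_stage1 = {
        ws: train_stage1(list(proteins), ws, config, sampled=sampled,
                         seed_tags=("final",))
        for ws in config.window_sizes
    }
    X2 = np.vstack([rows2[n] for n in names])
    y2 = np.concatenate([sampled[n][1] for n in names])
    final_stage2 = _fit_forest(X2, y2, config, "stage2", "final")
    X3 = np.vstack([rows3[n] for n in names])
    final_stage3 = _fit_forest(X3, y2, config, "stage3", "final")

    report = {
        "cv_f1_stage1": {int(ws): float(v) for ws, v in cv_f1_stage1.items()},
        "cv_f1_stage2": float(cv_f1_stage2),
        "cv_f1_stage3": float(cv_f1_stage3),
        "suggested_cutoff": float(suggested_cutoff),
        "n_proteins": len(proteins),
        "n_folds": k,
    }
    return ModelBundle(
        stage1=final_stage1,
        stage2=final_stage2,
        stage3=final_stage3,
        schemas=schemas,
        suggested_cutoff=float(suggested_cutoff),
        config=config,
        width_constant=WIDTH_CONSTANT,
        report=report,
    )
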