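"""Residue-level and strand-level evaluation.

Precision = TP/(TP+FP), Recall = TP/(TP+FN) and the F1-score is their
harmonic mean; whenever a denominator is zero the metric is defined as 0.
Residue-level evaluation compares predicted contacting pairs against the
truth pair set.  Strand-level evaluation regards two beta strands as
interacting if at least one residue pair between them is predicted as
contacting, and requires an unambiguous (one-hot / DSSP) strand assignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .io import LabelSet, SecondaryStructureProfile, ss_profile_from_string

__all__ = [
    "EvalResult",
    "f1_score",
    "binarize",
    "residue_eval",
    "strands_from_ss",
    "strand_eval",
    "pr_curve",
]


@dataclass
class EvalResult:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    level: str

    def as_percent(self, ndigits: int = 2) -> tuple:
        """(P, R, F1) in percent, rounded half-up."""
        import decimal

        def pct(x):
            q = decimal.Decimal(x * 100).quantize(
                decimal.Decimal(10) ** -ndigits, rounding=decimal.ROUND_HALF_UP
            )
            return float(q)

        return pct(self.precision), pct(self.recall), pct(self.f1)


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (0 when both are 0)."""
    if not (0 <= precision <= 1 and 0 <= recall <= 1):
        raise ValueError("precision and recall must lie in [0, 1]")
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def _result(tp: int, fp: int, fn: int, level: str) -> EvalResult:
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    return EvalResult(tp, fp, fn, precision, recall, f1_score(precision, recall), level)


def binarize(scores: np.ndarray, cutoff: float, min_sep: int = 1) -> set:
    """Pairs ``(i, j)``, ``i < j``, with score at or above the cutoff."""
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError("cutoff must lie in [0, 1]")
    scores = np.asarray(scores, dtype=float)
    i, j = np.triu_indices(scores.shape[0], k=min_sep)
    keep = scores[i, j] >= cutoff
    return set(zip(i[keep].tolist(), j[keep].tolist()))


def residue_eval(predicted: Iterable, truth: LabelSet) -> EvalResult:
    """Set comparison of predicted vs. native contacting residue pairs."""
    pred = {(min(i, j), max(i, j)) for i, j in predicted}
    true = truth.contacts
    tp = len(pred & true)
    return _result(tp, len(pred) - tp, len(true) - tp, "residue")


def strands_from_ss(assignment) -> list:
    """Maximal runs of the E state from a DSSP-mode assignment.

    Accepts a 3-state string or a one-hot profile; predicted (soft)
    profiles are rejected because strand boundaries would be ambiguous.
    """
    if isinstance(assignment, str):
        profile = ss_profile_from_string(assignment)
    else:
        profile = assignment
    if not profile.is_one_hot():
        raise ValueError(
            "strand derivation needs a one-hot (DSSP-mode) assignment; "
            "got soft probabilities"
        )
    is_e = profile.probs[:, SecondaryStructureProfile.E] == 1.0
    strands = []
    start = None
    for k, flag in enumerate(is_e):
        if flag and start is None:
            start = k
        elif not flag and start is not None:
            strands.append((start, k - 1))
            start = None
    if start is not None:
        strands.append((start, len(is_e) - 1))
    return strands


def _strand_of(strands: Sequence) -> dict:
    lookup = {}
    for s_idx, (a, b) in enumerate(strands):
        for r in range(a, b + 1):
            lookup[r] = s_idx
    return lookup


def _strand_pairs(pairs: Iterable, lookup: dict) -> set:
    out = set()
    for i, j in pairs:
        si, sj = lookup.get(i), lookup.get(j)
        if si is None or sj is None or si == sj:
            continue  # residue in no strand, or intra-strand pair
        out.add((min(si, sj), max(si, sj)))
    return out


def strand_eval(predicted: Iterable, truth: LabelSet, strands: Sequence) -> EvalResult:
    """Strand-pair comparison.

    A strand pair counts as predicted (or native) if any residue pair
    between the two strands is predicted (or native); intra-strand pairs and
    residues outside every strand contribute nothing.
    """
    lookup = _strand_of(strands)
    pred = _strand_pairs(predicted, lookup)
    true = _strand_pairs(truth.contacts, lookup)
    tp = len(pred & true)
    return _result(tp, len(pred) - tp, len(true) - tp, "strand")


def pr_curve(scores: np.ndarray, truth: LabelSet, grid: Sequence[float],
             min_sep: int = 1) -> list:
    """One ``(cutoff, EvalResult)`` per grid cutoff (grid sorted ascending).

    Cutoffs above the score range give the (0, 0) precision/recall point by
    the zero-denominator convention; recall is non-increasing in the cutoff.
    """
    grid = list(grid)
    if any(b < a for a, b in zip(grid, grid[1:])):
        raise ValueError("cutoff grid must be sorted ascending")
    out = []
    for cutoff in grid:
        if cutoff > 1.0:
            out.append((cutoff, _result(0, 0, len(truth.contacts), "residue")))
            continue
        pred = binarize(scores, cutoff, min_sep=min_sep)
        out.append((cutoff, residue_eval(pred, truth)))
    return out


def best_f1(scores: np.ndarray, truth: LabelSet, min_sep: int = 1,
            grid: Sequence[float] | None = None) -> tuple:
    """(best F1, cutoff attaining it) over a cutoff grid; ties -> smaller cutoff."""
    if grid is None:
        grid = np.round(np.arange(0.01, 1.0, 0.01), 2)
    best_cut, best_val = grid[0], -1.0
    for cutoff, res in pr_curve(scores, truth, list(grid), min_sep=min_sep):
        if res.f1 > best_val + 1e-12:
            best_val, best_cut = res.f1, cutoff
    return float(best_val), float(best_cut)
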