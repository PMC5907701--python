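"""Readers, writers and core container types.

File conventions: residue indices are 1-based in every file the package reads
or writes (CASP/RR convention) and 0-based everywhere in memory.  Contact maps
travel either as a plain whitespace-separated ``L x L`` matrix (the CCMpred
output dialect) or as a sparse ``i j score`` pair list.  Secondary structure
comes as per-residue 3-state probabilities (H/E/C columns) or as a 3- or
8-state DSSP string that is collapsed to 3 states and one-hot encoded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .config import RunConfig

__all__ = [
    "FormatError",
    "ContactMap",
    "SecondaryStructureProfile",
    "LabelSet",
    "Restraint",
    "RestraintList",
    "read_contact_map",
    "write_contact_map",
    "read_ss",
    "ss_profile_from_string",
    "read_labels",
    "write_labels",
    "write_prediction",
    "export_restraints",
    "write_restraints",
    "RESTRAINT_BOUNDS",
]


class FormatError(ValueError):
    """A file violates its declared dialect (ragged rows, bad state letters...)."""


# ---------------------------------------------------------------------------
# containers


@dataclass
class ContactMap:
    """A symmetric ``L x L`` matrix of residue-pair contact scores.

    ``n_seqs`` optionally records the MSA depth of the predictor run that
    produced the map; it feeds the sequence/residue-ratio map feature.
    """

    scores: np.ndarray
    n_seqs: Optional[int] = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[0] != self.scores.shape[1]:
            raise ValueError("contact map must be a square matrix")
        if self.scores.shape[0] < 2:
            raise ValueError("contact map needs L >= 2")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("contact map contains non-finite values")
        if self.n_seqs is not None and self.n_seqs < 0:
            raise ValueError("n_seqs must be nonnegative")

    @property
    def length(self) -> int:
        return self.scores.shape[0]

    def is_symmetric(self, atol: float = 0.0) -> bool:
        return bool(np.max(np.abs(self.scores - self.scores.T)) <= atol)

    def symmetrized(self) -> "ContactMap":
        """Average the map with its transpose (order-independent)."""
        return ContactMap(0.5 * (self.scores + self.scores.T), n_seqs=self.n_seqs)

    def rescaled(self) -> "ContactMap":
        """Optional min-max rescale to [0, 1] (constant maps map to 0)."""
        lo, hi = float(self.scores.min()), float(self.scores.max())
        if hi - lo <= 0:
            return ContactMap(np.zeros_like(self.scores), n_seqs=self.n_seqs)
        return ContactMap((self.scores - lo) / (hi - lo), n_seqs=self.n_seqs)


@dataclass
class SecondaryStructureProfile:
    """Per-residue 3-state probabilities, columns ordered (H, E, C)."""

    probs: np.ndarray

    H, E, C = 0, 1, 2  # column order

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 3:
            raise ValueError("SS profile must be L x 3")
        if np.any(self.probs < -1e-12) or np.any(self.probs > 1 + 1e-12):
            raise ValueError("SS probabilities must lie in [0, 1]")
        sums = self.probs.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise ValueError("SS probability rows must sum to 1")

    @property
    def length(self) -> int:
        return self.probs.shape[0]

    def is_one_hot(self) -> bool:
        return bool(np.all(np.isin(self.probs, (0.0, 1.0))))

    def argmax_string(self) -> str:
        return "".join("HEC"[k] for k in np.argmax(self.probs, axis=1))


@dataclass
class LabelSet:
    """Ground truth: contacting residue pairs plus beta-strand segments.

    ``contacts`` holds unordered pairs stored as ``(i, j)`` with ``i < j``;
    ``strands`` holds sorted, non-overlapping inclusive index intervals.
    """

    contacts: set = field(default_factory=set)
    strands: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.contacts = {(min(i, j), max(i, j)) for i, j in self.contacts}
        if any(i == j or i < 0 for i, j in self.contacts):
            raise ValueError("contacts must be distinct nonnegative index pairs")
        self.strands = sorted((int(a), int(b)) for a, b in self.strands)
        for (a, b) in self.strands:
            if a > b or a < 0:
                raise ValueError(f"bad strand interval ({a}, {b})")
        for (a, b), (c, d) in zip(self.strands, self.strands[1:]):
            if c <= b:
                raise ValueError("strand intervals overlap")

    def validate_against(self, L: int, min_sep: int = 1) -> None:
        for i, j in self.contacts:
            if j >= L:
                raise ValueError(f"contact ({i},{j}) outside [0,{L})")
            if j - i < min_sep:
                raise ValueError(f"contact ({i},{j}) violates min_sep={min_sep}")
        if self.strands and self.strands[-1][1] >= L:
            raise ValueError("strand interval outside sequence")


#: Distance bounds (angstrom) keyed by restraint tier.
RESTRAINT_BOUNDS = {
    "strict": (3.5, 6.0),
    "loose": (3.5, 10.0),
    "control": (3.5, 8.0),
}


@dataclass(frozen=True)
class Restraint:
    i: int
    j: int
    lower: float
    upper: float
    score: float
    tier: str


@dataclass
class RestraintList:
    records: list

    def __post_init__(self) -> None:
        seen = set()
        for r in self.records:
            if r.lower >= r.upper:
                raise ValueError("restraint must have lower < upper")
            if RESTRAINT_BOUNDS[r.tier] != (r.lower, r.upper):
                raise ValueError(f"bounds {(r.lower, r.upper)} do not match tier {r.tier}")
            key = (r.i, r.j)
            if key in seen:
                raise ValueError(f"duplicate restraint pair {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


# ---------------------------------------------------------------------------
# contact map I/O


def read_contact_map(
    path,
    dialect: str = "matrix",
    length_hint: Optional[int] = None,
    n_seqs: Optional[int] = None,
) -> ContactMap:
    """Read a contact map and return it symmetrized (average with transpose).

    ``matrix`` dialect: ``L`` whitespace-separated rows of ``L`` reals.
    ``pairlist`` dialect: lines ``i j score`` with 1-based indices; cells not
    listed default to 0 and ``length_hint`` (or the largest index) fixes L.
    """
    if dialect == "matrix":
        rows = []
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                parts = line.split()
                if not parts:
                    continue
                try:
                    rows.append([float(x) for x in parts])
                except ValueError as exc:
                    raise FormatError(f"{path}:{ln}: non-numeric entry") from exc
        if not rows:
            raise FormatError(f"{path}: empty matrix file")
        width = len(rows[0])
        if any(len(r) != width for r in rows):
            raise FormatError(f"{path}: ragged rows in matrix file")
        mat = np.asarray(rows, dtype=float)
        if mat.shape[0] != mat.shape[1]:
            raise FormatError(
                f"{path}: matrix is {mat.shape[0]}x{mat.shape[1]}, expected square"
            )
    elif dialect == "pairlist":
        entries = []
        max_idx = 0
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                parts = line.split()
                if not parts or parts[0].startswith("#"):
                    continue
                if len(parts) < 3:
                    raise FormatError(f"{path}:{ln}: expected 'i j score'")
                try:
                    i, j, s = int(parts[0]), int(parts[1]), float(parts[2])
                except ValueError as exc:
                    raise FormatError(f"{path}:{ln}: bad pair record") from exc
                if i < 1 or j < 1:
                    raise IndexError(f"{path}:{ln}: indices are 1-based")
                entries.append((i - 1, j - 1, s))
                max_idx = max(max_idx, i, j)
        L = length_hint if length_hint is not None else max_idx
        if L < max_idx:
            raise IndexError(
                f"{path}: pair index {max_idx} exceeds declared length {L}"
            )
        mat = np.zeros((L, L), dtype=float)
        for i, j, s in entries:
            mat[i, j] = s
            mat[j, i] = s
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    if not np.all(np.isfinite(mat)):
        raise ValueError(f"{path}: non-finite values in contact map")
    return ContactMap(mat, n_seqs=n_seqs).symmetrized()


def write_contact_map(cmap_or_matrix, path) -> None:
    """Write a matrix in the plain whitespace dialect at 6-decimal precision."""
    mat = cmap_or_matrix.scores if isinstance(cmap_or_matrix, ContactMap) else cmap_or_matrix
    np.savetxt(path, np.asarray(mat, dtype=float), fmt="%.6f")


# ---------------------------------------------------------------------------
# secondary structure I/O

_DSSP_TO_3 = {
    "B": "E", "E": "E",           # beta bridge and extended strand
    "G": "H", "H": "H", "I": "H",  # helices
}


def _collapse_dssp(letter: str) -> str:
    if letter in _DSSP_TO_3:
        return _DSSP_TO_3[letter]
    if letter.isalpha() or letter in "- ~.":
        return "C"
    raise FormatError(f"unknown secondary-structure letter {letter!r}")


def ss_profile_from_string(s: str) -> SecondaryStructureProfile:
    """One-hot profile from a 3-state or raw 8-state DSSP string.

    8-state letters collapse as B,E -> E; G,H,I -> H; everything else -> C.
    """
    s = s.strip().upper()
    if not s:
        raise FormatError("empty secondary-structure string")
    probs = np.zeros((len(s), 3), dtype=float)
    for k, letter in enumerate(s):
        state = letter if letter in "HEC" else _collapse_dssp(letter)
        probs[k, "HEC".index(state)] = 1.0
    return SecondaryStructureProfile(probs)


def read_ss(path, mode: str = "predicted_ss") -> SecondaryStructureProfile:
    """Read a secondary-structure profile.

    ``predicted_ss``: one line per residue, ``index pH pE pC``; row sums must
    be within 1e-3 of 1 and are renormalized exactly.  ``dssp_ss``: a single
    state string (whitespace/newlines ignored) that is one-hot encoded.
    """
    if mode == "dssp_ss":
        with open(path) as fh:
            s = "".join(fh.read().split())
        return ss_profile_from_string(s)
    if mode != "predicted_ss":
        raise ValueError(f"unknown mode {mode!r}")
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            if len(parts) < 4:
                raise FormatError(f"{path}:{ln}: expected 'index pH pE pC'")
            try:
                vals = [float(x) for x in parts[1:4]]
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: bad probability") from exc
            total = sum(vals)
            if abs(total - 1.0) > 1e-3:
                raise ValueError(f"{path}:{ln}: probabilities sum to {total:.4f}")
            rows.append([v / total for v in vals])
    if not rows:
        raise FormatError(f"{path}: empty SS file")
    return SecondaryStructureProfile(np.asarray(rows, dtype=float))


def write_ss(profile: SecondaryStructureProfile, path) -> None:
    with open(path, "w") as fh:
        for k, (h, e, c) in enumerate(profile.probs, 1):
            fh.write(f"{k} {h:.6f} {e:.6f} {c:.6f}\n")


# ---------------------------------------------------------------------------
# label I/O


def read_labels(path) -> LabelSet:
    """Read a label file of ``strand a b`` and ``contact i j`` lines (1-based)."""
    contacts, strands = set(), []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            kind = parts[0].lower()
            if kind == "strand" and len(parts) == 3:
                strands.append((int(parts[1]) - 1, int(parts[2]) - 1))
            elif kind == "contact" and len(parts) == 3:
                i, j = int(parts[1]) - 1, int(parts[2]) - 1
                contacts.add((min(i, j), max(i, j)))
            else:
                raise FormatError(f"{path}:{ln}: expected 'strand a b' or 'contact i j'")
    return LabelSet(contacts=contacts, strands=strands)


def write_labels(labels: LabelSet, path) -> None:
    with open(path, "w") as fh:
        for a, b in labels.strands:
            fh.write(f"strand {a + 1} {b + 1}\n")
        for i, j in sorted(labels.contacts):
            fh.write(f"contact {i + 1} {j + 1}\n")


# ---------------------------------------------------------------------------
# prediction output


def ranked_pairs(scores: np.ndarray, min_sep: int = 1) -> list:
    """All pairs ``i < j`` with ``j - i >= min_sep``, sorted by descending
    score, ties broken by ascending ``(i, j)``."""
    L = scores.shape[0]
    out = []
    for i in range(L):
        for j in range(i + min_sep, L):
            out.append((i, j, float(scores[i, j])))
    out.sort(key=lambda r: (-r[2], r[0], r[1]))
    return out


def write_prediction(scores: np.ndarray, path, form: str = "matrix",
                     min_sep: int = 1) -> None:
    """Write a prediction map as a matrix or as a ranked 1-based pair list."""
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("prediction contains non-finite values")
    if form == "matrix":
        write_contact_map(scores, path)
    elif form == "ranked_pairs":
        with open(path, "w") as fh:
            for i, j, s in ranked_pairs(scores, min_sep=min_sep):
                fh.write(f"{i + 1} {j + 1} {s:.6f}\n")
    else:
        raise ValueError(f"unknown output form {form!r}")


# ---------------------------------------------------------------------------
# restraint export


def export_restraints(
    final_scores: np.ndarray,
    raw: ContactMap,
    cutoff: float,
    mode: str = "refined",
    config: Optional[RunConfig] = None,
    ss: Optional[SecondaryStructureProfile] = None,
) -> RestraintList:
    """Build a top-``L`` distance-restraint list for contact-assisted folding.

    ``refined`` mode keeps every pair scoring at or above ``cutoff`` on the
    refined map as a *strict* 3.5-6 A restraint, then fills the list up to
    ``L`` records with the best raw-map pairs that fall outside a square
    redundancy window around every strict pair, as *loose* 3.5-10 A
    restraints.  ``control`` mode simply takes the top-``L`` raw pairs with
    the uniform 3.5-8 A bound.  ``ss`` is accepted for interface parity but
    the selection is purely score/geometry based.
    """
    config = config or RunConfig()
    if not 0.0 < cutoff < 1.0:
        raise ValueError("cutoff must lie in (0, 1)")
    final_scores = np.asarray(final_scores, dtype=float)
    L = raw.length
    if final_scores.shape != (L, L):
        raise ValueError("refined map and raw map sizes differ")
    min_sep, k = config.min_sep, config.redundancy_k

    raw_ranked = ranked_pairs(raw.scores, min_sep=min_sep)

    records: list[Restraint] = []
    if mode == "control":
        for i, j, s in raw_ranked[:L]:
            lo, hi = RESTRAINT_BOUNDS["control"]
            records.append(Restraint(i, j, lo, hi, s, "control"))
        return RestraintList(records)
    if mode != "refined":
        raise ValueError(f"unknown export mode {mode!r}")

    strict = [(i, j, float(final_scores[i, j]))
              for i, j, _ in ranked_pairs(final_scores, min_sep=min_sep)
              if final_scores[i, j] >= cutoff]
    if len(strict) > L:
        warnings.warn(
            f"{len(strict)} pairs above cutoff exceed L={L}; keeping top-L",
            stacklevel=2,
        )
        strict = strict[:L]
    lo, hi = RESTRAINT_BOUNDS["strict"]
    for i, j, s in strict:
        records.append(Restraint(i, j, lo, hi, s, "strict"))

    strict_pairs = {(i, j) for i, j, _ in strict}

    def redundant(i: int, j: int) -> bool:
        return any(abs(i - a) <= k and abs(j - b) <= k for a, b in strict_pairs)

    lo2, hi2 = RESTRAINT_BOUNDS["loose"]
    for i, j, s in raw_ranked:
        if len(records) >= L:
            break
        if (i, j) in strict_pairs or redundant(i, j):
            continue
        records.append(Restraint(i, j, lo2, hi2, s, "loose"))

    return RestraintList(records)


def write_restraints(restraints: RestraintList, path) -> None:
    """CASP-RR-like lines ``i j lower upper score`` (1-based), strict tier first."""
    with open(path, "w") as fh:
        for r in restraints:
            fh.write(f"{r.i + 1} {r.j + 1} {r.lower:.1f} {r.upper:.1f} {r.score:.6f}\n")
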