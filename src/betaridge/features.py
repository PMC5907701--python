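"""Feature assembly for candidate residue pairs.

Each candidate pair ``(i, j)`` becomes one fixed-length row concatenating:

1. 2D map features: for every input ``L x L`` map, the values at the cells
   selected by a window mask centred on ``(i, j)`` (square, or cross-shaped
   with diagonal/anti-diagonal bands of width ``dw``).  Cells outside the
   map carry the sentinel ``-1`` so the model can tell boundary from a
   genuine zero score.
2. 1D secondary-structure features: H/E/C probabilities over a length-``ws``
   window centred at ``i`` and at ``j`` (zeros outside the sequence).
3. Position features: ``(j - i, i, L-1-i, j, L-1-j)`` with 0-based indices.
4. Map-level features: MSA depth per residue (``n_seqs / L``, 0 when depth
   is unknown) and the standard deviation of the candidate region of the
   raw map.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .io import ContactMap, SecondaryStructureProfile

__all__ = [
    "WindowMask",
    "build_window_mask",
    "candidate_pairs",
    "position_features",
    "map_features",
    "extract_pair_features",
    "feature_schema",
]

POSITION_NAMES = ("seq_sep", "i_to_nterm", "i_to_cterm", "j_to_nterm", "j_to_cterm")
MAP_FEATURE_NAMES = ("n_seqs_per_res", "map_std")


@dataclass
class WindowMask:
    """Boolean stencil selecting neighbour cells around a focus pair.

    A cell ``(r, c)`` of the ``ws x ws`` grid is selected iff it lies within
    ``(dw-1)/2`` of the main diagonal or of the anti-diagonal; ``dw >= ws``
    selects the full square.  The mask is symmetric under 180-degree
    rotation.
    """

    ws: int
    dw: int
    cells: np.ndarray

    @property
    def n_cells(self) -> int:
        return int(self.cells.sum())

    @property
    def offsets(self) -> np.ndarray:
        """Selected-cell offsets relative to the centre, row-major order."""
        half = (self.ws - 1) // 2
        return np.argwhere(self.cells) - half


def build_window_mask(ws: int, dw: int) -> WindowMask:
    if ws < 1 or ws % 2 == 0:
        raise ValueError("ws must be odd and positive")
    if dw < 1 or dw % 2 == 0:
        raise ValueError("dw must be odd and positive")
    half_band = (dw - 1) // 2
    r, c = np.meshgrid(np.arange(ws), np.arange(ws), indexing="ij")
    cells = (np.abs(r - c) <= half_band) | (np.abs(r + c - (ws - 1)) <= half_band)
    return WindowMask(ws=ws, dw=dw, cells=cells)


def candidate_pairs(L: int, min_sep: int = 3) -> np.ndarray:
    """All pairs ``i < j`` with ``j - i >= min_sep``, lexicographic order.

    Returned as an ``(n, 2)`` integer array (possibly empty).
    """
    if L < 2:
        raise ValueError("need L >= 2")
    if min_sep < 1:
        raise ValueError("min_sep must be >= 1")
    i, j = np.triu_indices(L, k=min_sep)
    return np.column_stack([i, j])


def position_features(i: int, j: int, L: int) -> np.ndarray:
    """``(j - i, i, L-1-i, j, L-1-j)`` for a 0-based ordered pair."""
    if not 0 <= i < j < L:
        raise ValueError("require 0 <= i < j < L")
    return np.array([j - i, i, L - 1 - i, j, L - 1 - j], dtype=float)


def map_features(cmap: ContactMap, min_sep: int = 3) -> np.ndarray:
    """Sequence/residue ratio and the raw-map standard deviation.

    The std is taken over strict upper-triangle entries with
    ``j - i >= min_sep`` so the (uninformative) diagonal region never
    dilutes it.
    """
    L = cmap.length
    ratio = (cmap.n_seqs / L) if cmap.n_seqs is not None else 0.0
    iu, ju = np.triu_indices(L, k=min_sep)
    std = float(np.std(cmap.scores[iu, ju])) if iu.size else 0.0
    return np.array([ratio, std], dtype=float)


def feature_schema(
    map_names: Sequence[str],
    mask: WindowMask,
    ss_window: int,
    include_position: bool = True,
    include_map: bool = True,
) -> list:
    """Ordered feature names matching :func:`extract_pair_features`."""
    names = []
    for name in map_names:
        for dr, dc in mask.offsets:
            names.append(f"{name}[{dr:+d},{dc:+d}]")
    half = (ss_window - 1) // 2
    for who in ("i", "j"):
        for o in range(-half, half + 1):
            for state in "HEC":
                names.append(f"ss_{who}[{o:+d}]_{state}")
    if include_position:
        names.extend(POSITION_NAMES)
    if include_map:
        names.extend(MAP_FEATURE_NAMES)
    return names


def extract_pair_features(
    maps2d: Sequence[np.ndarray],
    ss: SecondaryStructureProfile,
    mapfeat: Optional[np.ndarray],
    mask: WindowMask,
    pairs: np.ndarray,
    include_position: bool = True,
) -> np.ndarray:
    """Feature rows for many pairs at once.

    ``pairs`` is ``(n, 2)`` with ``i < j``; returns ``(n, F)`` where ``F``
    follows :func:`feature_schema` with the same map order.  Passing
    ``mapfeat=None`` omits the map-feature block (later pipeline stages drop
    position and map features after feature selection).
    """
    pairs = np.atleast_2d(np.asarray(pairs, dtype=int))
    maps2d = [np.asarray(m, dtype=float) for m in maps2d]
    if not maps2d:
        raise ValueError("need at least one 2D map")
    L = maps2d[0].shape[0]
    for m in maps2d:
        if m.shape != (L, L):
            raise ValueError("all 2D maps must share the same shape")
    if ss.length != L:
        raise ValueError("SS profile length does not match maps")
    n = pairs.shape[0]
    if n and not np.all(pairs[:, 0] < pairs[:, 1]):
        raise ValueError("pairs must be ordered i < j")

    offs = mask.offsets                       # (m, 2)
    rows = pairs[:, 0, None] + offs[None, :, 0]
    cols = pairs[:, 1, None] + offs[None, :, 1]
    inside = (rows >= 0) & (rows < L) & (cols >= 0) & (cols < L)
    rc = np.clip(rows, 0, L - 1)
    cc = np.clip(cols, 0, L - 1)

    blocks = []
    for m in maps2d:
        vals = np.where(inside, m[rc, cc], -1.0)
        blocks.append(vals)

    half = (mask.ws - 1) // 2
    ss_off = np.arange(-half, half + 1)
    for col in (0, 1):
        idx = pairs[:, col, None] + ss_off[None, :]
        ok = (idx >= 0) & (idx < L)
        gathered = ss.probs[np.clip(idx, 0, L - 1)]      # (n, ws, 3)
        gathered = np.where(ok[:, :, None], gathered, 0.0)
        blocks.append(gathered.reshape(n, -1))

    if include_position:
        i, j = pairs[:, 0].astype(float), pairs[:, 1].astype(float)
        blocks.append(np.column_stack([j - i, i, L - 1 - i, j, L - 1 - j]))

    if mapfeat is not None:
        blocks.append(np.broadcast_to(np.asarray(mapfeat, float), (n, len(mapfeat))).copy())

    out = np.hstack(blocks)
    if not np.all(np.isfinite(out)):
        raise ValueError("non-finite feature values")
    return out
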