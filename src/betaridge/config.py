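"""Run configuration shared across the pipeline.

A single :class:`RunConfig` carries every tunable that more than one module
needs: window geometry, under-sampling ratio, forest size, the smoothing-scale
grid for ridge detection, the minimum sequence separation for candidate pairs,
and the master seed.  Defaults follow the optimized settings of the published
method (window sizes 3/5/7/9, diagonal width 3, 1:40 Pos/Neg under-sampling,
500 trees).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import yaml

#: Default smoothing-scale grid (grid units): 12 log-spaced values in [0.5, 4].
#: Strand-pairing ridges on contact maps are 1-3 cells wide, so the grid
#: brackets that range with margin on both sides.
DEFAULT_SIGMA_GRID: tuple[float, ...] = tuple(
    float(s) for s in np.geomspace(0.5, 4.0, 12)
)


@dataclass
class RunConfig:
    """Configuration for featurization, training and prediction.

    Parameters
    ----------
    window_sizes
        Side lengths of the square 2D feature windows used by the four
        first-stage models.  Must all be odd.
    diag_width
        Width of the diagonal/anti-diagonal bands of the cross-shaped window
        mask (odd).  ``diag_width >= window_size`` degenerates to the full
        square.
    pos_neg_ratio
        Negative-to-positive under-sampling ratio applied per protein when
        building training rows.
    n_trees
        Number of decision trees in every random forest.
    sigma_grid
        Strictly increasing Gaussian smoothing scales (grid units) scanned by
        the scale-space ridge detector.
    min_sep
        Minimum sequence separation ``j - i`` for a residue pair to be a
        prediction candidate.
    seed
        Master seed; every random stream in a run is derived from it.
    cutoff
        Default classification cutoff on final-stage scores; training
        replaces it with the cross-validated suggested cutoff.
    mode
        ``"predicted_ss"`` (3-state probabilities) or ``"dssp_ss"``
        (one-hot native assignment).
    ridge_tol
        Relative tolerance on the directional derivative in the discrete
        ridge-point test.
    quad_half_width
        Half width of the local least-squares neighbourhood (2 -> 5x5).
    redundancy_k
        Half width of the square redundancy window used when enriching
        restraint lists (2 -> 5x5).
    """

    window_sizes: tuple[int, ...] = (3, 5, 7, 9)
    diag_width: int = 3
    pos_neg_ratio: int = 40
    n_trees: int = 500
    sigma_grid: tuple[float, ...] = field(default_factory=lambda: DEFAULT_SIGMA_GRID)
    min_sep: int = 3
    seed: int = 0
    cutoff: float = 0.5
    mode: str = "predicted_ss"
    ridge_tol: float = 0.1
    quad_half_width: int = 2
    redundancy_k: int = 2

    def __post_init__(self) -> None:
        self.window_sizes = tuple(int(w) for w in self.window_sizes)
        self.sigma_grid = tuple(float(s) for s in self.sigma_grid)
        if any(w < 1 or w % 2 == 0 for w in self.window_sizes):
            raise ValueError("window_sizes must be odd positive integers")
        if self.diag_width < 1 or self.diag_width % 2 == 0:
            raise ValueError("diag_width must be odd and positive")
        if self.pos_neg_ratio < 1:
            raise ValueError("pos_neg_ratio must be >= 1")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        sg = np.asarray(self.sigma_grid, dtype=float)
        if sg.size == 0 or np.any(sg <= 0) or np.any(np.diff(sg) <= 0):
            raise ValueError("sigma_grid must be strictly increasing and positive")
        if self.min_sep < 1:
            raise ValueError("min_sep must be >= 1")
        if not 0.0 < self.cutoff < 1.0:
            raise ValueError("cutoff must lie in (0, 1)")
        if self.mode not in ("predicted_ss", "dssp_ss"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.ridge_tol < 0:
            raise ValueError("ridge_tol must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def replace(self, **kw) -> "RunConfig":
        d = self.to_dict()
        d.update(kw)
        return RunConfig.from_dict(d)
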