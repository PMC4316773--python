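"""Trial-level voxel data -> one response pattern per scene.

A slow event-related design presents each scene several times; the BOLD-like
response of every voxel in a region of interest (ROI) is sampled at uniformly
spaced timepoints through an event window.  The scene pattern is the response
averaged over repetitions and over the timepoints falling in the peak window
(6-8 s after onset by default, the average peak of the response time course).
Scene-by-scene correlation of these patterns, averaged across participants,
yields the neural scene space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .similarity import SimilarityMatrix, fisher_z, inverse_fisher_z

logger = logging.getLogger(__name__)


@dataclass
class TrialPatternArray:
    """Responses indexed by (scene, repetition, timepoint, voxel).

    ``t_spacing`` is the sampling interval in seconds; timepoint ``k`` has
    onset ``t_onset + k * t_spacing``.  NaN marks dropped trials.
    """

    responses: np.ndarray
    t_spacing: float = 2.0
    t_onset: float = 0.0
    roi: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses, dtype=float)
        if self.responses.ndim != 4:
            raise ValueError("responses must be 4-D (scene, repetition, timepoint, voxel)")
        if self.t_spacing <= 0:
            raise ValueError("t_spacing must be positive")

    @property
    def n_scenes(self) -> int:
        return self.responses.shape[0]

    @property
    def onsets(self) -> np.ndarray:
        """Onset in seconds of each timepoint."""
        return self.t_onset + self.t_spacing * np.arange(self.responses.shape[2])


@dataclass
class PatternMatrix:
    """One voxel pattern per scene (rows ordered by scene index)."""

    values: np.ndarray
    roi: str = ""
    window: tuple = (6.0, 8.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("pattern matrix must be 2-D scenes x voxels")


def apply_roi_mask(volumes: np.ndarray, mask: np.ndarray, index: pd.DataFrame,
                   *, t_spacing: float = 2.0, roi: str = "") -> TrialPatternArray:
    """Subset 4-D voxel data to an ROI and reshape to a trial array.

    ``volumes`` has shape (X, Y, Z, n_volumes) -- one volume per
    trial-timepoint -- and ``index`` maps each volume (in order) to its
    ``scene``, ``repetition`` and ``timepoint``.  The voxel axis enumerates
    mask-true positions in row-major grid order, so patterns are reproducible
    across runs.
    """
    vols = np.asarray(volumes, dtype=float)
    m = np.asarray(mask).astype(bool)
    if vols.ndim != 4:
        raise ValueError("volumes must be 4-D (X, Y, Z, n_volumes)")
    if m.shape != vols.shape[:3]:
        raise ValueError(f"mask shape {m.shape} != volume grid {vols.shape[:3]}")
    n_vox = int(m.sum())
    if n_vox == 0:
        raise ValueError("ROI mask selects no voxels")
    if len(index) != vols.shape[3]:
        raise ValueError("index rows must match number of volumes")

    data = vols[m, :].T  # (n_volumes, n_voxels), row-major voxel order

    scenes = index["scene"].to_numpy()
    reps = index["repetition"].to_numpy()
    tps = index["timepoint"].to_numpy()
    n_s, n_r, n_t = scenes.max() + 1, reps.max() + 1, tps.max() + 1
    out = np.full((n_s, n_r, n_t, n_vox), np.nan)
    out[scenes, reps, tps] = data
    return TrialPatternArray(out, t_spacing=t_spacing, roi=roi,
                             meta={"n_voxels": n_vox, "voxel_order": "row-major"})


def subset_repetitions(trials: TrialPatternArray, reps) -> TrialPatternArray:
    """A view of the trial array restricted to the given repetition indices."""
    return TrialPatternArray(trials.responses[:, np.asarray(reps, dtype=int)],
                             t_spacing=trials.t_spacing, t_onset=trials.t_onset,
                             roi=trials.roi, meta=dict(trials.meta))


def build_scene_patterns(trials: TrialPatternArray,
                         window: tuple = (6.0, 8.0)) -> PatternMatrix:
    """Average over repetitions, then over timepoints in the closed window.

    The window is closed on both sides: with 2 s spacing over an 0-8 s epoch,
    window (6, 8) averages the samples at 6 s and 8 s.  Repetitions with
    missing data are averaged over the available repetitions (count logged).
    """
    lo, hi = float(window[0]), float(window[1])
    onsets = trials.onsets
    if lo < onsets[0] - 1e-9 or hi > onsets[-1] + 1e-9:
        raise ValueError(f"window {window} outside recorded epoch "
                         f"[{onsets[0]}, {onsets[-1]}]")
    in_win = (onsets >= lo - 1e-9) & (onsets <= hi + 1e-9)
    if not in_win.any():
        raise ValueError(f"window {window} captures no timepoints")

    resp = trials.responses[:, :, in_win, :]
    n_missing = int(np.isnan(resp).any(axis=(2, 3)).sum())
    if n_missing:
        logger.info("build_scene_patterns: averaging over available repetitions "
                    "(%d scene-repetition cells missing)", n_missing)
    with np.errstate(invalid="ignore"):
        over_reps = np.nanmean(resp, axis=1)   # (scene, timepoint, voxel)
        pattern = np.nanmean(over_reps, axis=1)
    return PatternMatrix(pattern, roi=trials.roi, window=(lo, hi))


def average_across_participants(spaces: list[SimilarityMatrix],
                                *, fisher_first: bool = False) -> SimilarityMatrix:
    """Cell-wise mean of per-participant similarity matrices.

    The default averages raw r-values; ``fisher_first=True`` averages in
    Fisher-z space and transforms back (the alternative reading of the
    averaging/transform order).
    """
    if not spaces:
        raise ValueError("no matrices to average")
    n = spaces[0].n
    if any(s.n != n for s in spaces):
        raise ValueError("similarity matrices differ in dimension")
    stack = np.stack([s.values for s in spaces])
    if fisher_first:
        mean = inverse_fisher_z(np.nanmean(fisher_z(stack), axis=0))
    else:
        mean = np.nanmean(stack, axis=0)
    np.fill_diagonal(mean, 1.0)
    return SimilarityMatrix(mean, method=spaces[0].method,
                            meta={"n_participants": len(spaces),
                                  "fisher_first": fisher_first})
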