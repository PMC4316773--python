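"""First-order scene similarity spaces.

A *scene space* is the n x n matrix of pairwise Pearson correlations between
per-scene representations (voxel patterns, descriptor vectors, or behavioral
ratings).  For second-order analysis the strict upper triangle is vectorized
(row-major) into a length n(n-1)/2 vector and Fisher z-transformed, so that
correlations between scene spaces operate on approximately normal values.

Behavioral spaces come from pairwise similarity ratings (1-7, with 8 reserved
for "identical") collected in HITs of 11 trials, one of which is a catch trial
showing an identical pair.  Ratings are strongly right-skewed (most pairs are
judged "different"), so valid responses are log-transformed before averaging
per pair.  Cells with no surviving observations stay missing and propagate
into pairwise-complete second-order correlations.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: r = +/-1 is clamped to this magnitude before atanh so identical inputs do
#: not produce infinite z-values.
FISHER_R_MAX = 1.0 - 1e-7

#: Maximum allowed asymmetry |M - M.T| for a valid similarity matrix.
SYMMETRY_TOL = 1e-10


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class SimilarityMatrix:
    """n x n symmetric matrix of Pearson r with unit diagonal.

    Missing cells (behavioral pairs with no valid observations, zero-variance
    rows) are NaN.
    """

    values: np.ndarray
    method: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"similarity matrix must be square, got {v.shape}")
        finite = np.isfinite(v)
        asym = np.abs(np.where(finite & finite.T, v - v.T, 0.0)).max(initial=0.0)
        if asym > SYMMETRY_TOL:
            raise ValueError(f"matrix asymmetric beyond tolerance ({asym:.3g})")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class SceneSpaceVector:
    """Row-major strict upper triangle of a scene similarity matrix.

    ``transform`` records the scale of the values: ``"raw_r"`` (untransformed
    Pearson r), ``"fisher_z"`` or ``"log_rating"``.
    """

    values: np.ndarray
    transform: str = "raw_r"
    method: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        n = self.n_scenes  # validates triangular length

    @property
    def n_scenes(self) -> int:
        m = self.values.size
        n = int(round((1 + math.sqrt(1 + 8 * m)) / 2))
        if n * (n - 1) // 2 != m:
            raise ValueError(f"length {m} is not n(n-1)/2 for integer n")
        return n


def pair_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/column indices of the strict upper triangle in row-major order."""
    return np.triu_indices(n, k=1)


def pair_position(i: int, j: int, n: int) -> int:
    """Position of unordered pair (i, j), i < j, in the row-major triangle."""
    if not 0 <= i < j < n:
        raise ValueError(f"need 0 <= i < j < n, got ({i}, {j}) with n={n}")
    return i * n - i * (i + 1) // 2 + (j - i - 1)


# ---------------------------------------------------------------------------
# First-order similarity
# ---------------------------------------------------------------------------

def pairwise_similarity(features: np.ndarray, method: str = "") -> SimilarityMatrix:
    """Scene-by-scene Pearson correlation of rows of a scenes x dims matrix.

    Zero-variance rows cannot be correlated; their cells are set missing (NaN)
    and the affected scene indices are reported in ``meta["zero_variance"]``.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise ValueError("features must be a 2-D scenes x dims matrix")
    n, d = X.shape
    if n < 2 or d < 2:
        raise ValueError(f"need >= 2 scenes and >= 2 dims, got {X.shape}")
    if not np.all(np.isfinite(X)):
        raise ValueError("features contain non-finite values")

    degenerate = np.flatnonzero(np.ptp(X, axis=1) == 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(X)
    R = np.clip(R, -1.0, 1.0)
    if degenerate.size:
        logger.warning("pairwise_similarity: %d zero-variance scene(s): %s",
                       degenerate.size, degenerate.tolist())
        R[degenerate, :] = np.nan
        R[:, degenerate] = np.nan
    np.fill_diagonal(R, 1.0)
    return SimilarityMatrix(R, method=method,
                            meta={"zero_variance": degenerate.tolist()})


def behavioral_matrix(
    ratings,
    n: int,
    *,
    repeat_failure_min: int = 2,
    extreme_responses: frozenset = frozenset({1, 8}),
) -> SimilarityMatrix:
    """Log-mean similarity matrix from a trial-level rating table.

    Exclusion rules, applied in order:

    1. A HIT whose catch trial (identical pair) was not answered with 8 is
       dropped wholesale -- the rater was not attending during that HIT.
    2. A rater who failed at least ``repeat_failure_min`` catch trials *and*
       used only the extreme responses {1, 8} is removed entirely; such data
       is ambiguous between task completion and button mashing.

    Surviving non-catch responses are natural-log transformed (ratings are
    right-skewed) and averaged per unordered scene pair.  Pairs with zero
    valid observations are NaN.  Exclusion counts land in ``meta``.
    """
    df = getattr(ratings, "frame", ratings)
    df = pd.DataFrame(df)
    required = {"rater", "scene_a", "scene_b", "response", "is_catch", "hit"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"rating table missing columns: {sorted(missing)}")
    if not df["response"].between(1, 8).all():
        raise ValueError("responses must be integers in 1..8")

    catch = df[df["is_catch"]]
    failed = catch[catch["response"] != 8]
    bad_hits = set(failed["hit"])

    # whole-rater removal: repeated catch failures plus exclusive 1/8 use
    fails_per_rater = failed.groupby("rater").size()
    removed_raters = []
    for rater, n_fail in fails_per_rater.items():
        if n_fail < repeat_failure_min:
            continue
        used = set(df.loc[df["rater"] == rater, "response"])
        if used <= set(extreme_responses):
            removed_raters.append(rater)

    keep = (~df["hit"].isin(bad_hits)) & (~df["rater"].isin(removed_raters))
    valid = df[keep & ~df["is_catch"]]

    logger.info("behavioral_matrix: %d HITs dropped (catch failure), "
                "%d rater(s) removed entirely, %d/%d non-catch rows retained",
                len(bad_hits), len(removed_raters), len(valid),
                int((~df["is_catch"]).sum()))

    M = np.full((n, n), np.nan)
    np.fill_diagonal(M, 1.0)
    if len(valid):
        a = np.minimum(valid["scene_a"], valid["scene_b"]).to_numpy()
        b = np.maximum(valid["scene_a"], valid["scene_b"]).to_numpy()
        if a.max(initial=-1) >= n or b.max(initial=-1) >= n:
            raise ValueError("scene index out of range for n")
        logged = np.log(valid["response"].to_numpy(dtype=float))
        means = pd.DataFrame({"a": a, "b": b, "v": logged}).groupby(["a", "b"])["v"].mean()
        for (i, j), v in means.items():
            M[i, j] = M[j, i] = v

    return SimilarityMatrix(
        M, method="behavioral",
        meta={
            "n_bad_hits": len(bad_hits),
            "removed_raters": sorted(removed_raters),
            "n_rows_retained": int(len(valid)),
            "transform": "log_rating",
        },
    )


# ---------------------------------------------------------------------------
# Transforms and vectorization
# ---------------------------------------------------------------------------

def fisher_z(values):
    """Fisher z = atanh(r), with |r| = 1 clamped to ``FISHER_R_MAX``.

    NaN passes through (missing cells).  |r| > 1 is rejected.
    """
    r = np.asarray(values, dtype=float)
    finite = np.isfinite(r)
    if np.any(np.abs(r[finite]) > 1.0):
        raise ValueError("|r| > 1 passed to fisher_z")
    clamped = np.clip(r, -FISHER_R_MAX, FISHER_R_MAX)
    z = np.arctanh(clamped)
    if np.ndim(values) == 0:
        return float(z)
    return z


def inverse_fisher_z(values):
    """tanh, the inverse of :func:`fisher_z` away from the clamp."""
    z = np.asarray(values, dtype=float)
    r = np.tanh(z)
    if np.ndim(values) == 0:
        return float(r)
    return r


def upper_triangle(matrix: SimilarityMatrix, *, transform: str | None = None) -> SceneSpaceVector:
    """Vectorize the row-major strict upper triangle of a similarity matrix.

    With ``transform="fisher_z"`` the r-values are Fisher-transformed on the
    way out (the default for correlation-valued matrices); ``transform=None``
    keeps the matrix's native scale and tags behavioral matrices as
    ``log_rating``.  Missing cells stay NaN.
    """
    i, j = pair_indices(matrix.n)
    vals = matrix.values[i, j]
    tag = matrix.meta.get("transform", "raw_r")
    if transform == "fisher_z":
        if tag == "log_rating":
            raise ValueError("log-rating matrices are not correlation-valued")
        vals = fisher_z(vals)
        tag = "fisher_z"
    return SceneSpaceVector(vals, transform=tag, method=matrix.method)


def from_upper_triangle(vector: SceneSpaceVector) -> SimilarityMatrix:
    """Reconstruct the symmetric matrix (unit diagonal) from its triangle."""
    n = vector.n_scenes
    M = np.ones((n, n))
    i, j = pair_indices(n)
    M[i, j] = vector.values
    M[j, i] = vector.values
    meta = {}
    if vector.transform == "log_rating":
        meta["transform"] = "log_rating"
    return SimilarityMatrix(M, method=vector.method, meta=meta)


# ---------------------------------------------------------------------------
# Split-half reliability
# ---------------------------------------------------------------------------

def split_half(trials, by: str = "odd_even", *, window=(6.0, 8.0)):
    """Split repetitions into disjoint halves and correlate the scene spaces.

    ``by="session"`` assigns the first half of the repetitions to half 1 (a
    two-session acquisition presents each stimulus equally often per session);
    ``by="odd_even"`` interleaves.  Odd repetition counts place the extra
    repetition in the first half (logged).  Returns ``(space1, space2, r)``
    where the spaces are Fisher-z scene-space vectors.
    """
    from .neural import build_scene_patterns, subset_repetitions

    n_rep = trials.responses.shape[1]
    if n_rep < 2:
        raise ValueError("split-half needs >= 2 repetitions")
    reps = np.arange(n_rep)
    if by == "odd_even":
        first, second = reps[::2], reps[1::2]
    elif by == "session":
        cut = (n_rep + 1) // 2
        first, second = reps[:cut], reps[cut:]
    else:
        raise ValueError(f"unknown split {by!r}")
    if n_rep % 2:
        logger.info("split_half: odd repetition count %d, extra repetition in first half", n_rep)

    spaces = []
    for half in (first, second):
        pat = build_scene_patterns(subset_repetitions(trials, half), window=window)
        sim = pairwise_similarity(pat.values, method=f"{trials.roi}:reps{list(half)}")
        spaces.append(upper_triangle(sim, transform="fisher_z"))
    v1, v2 = spaces[0].values, spaces[1].values
    ok = np.isfinite(v1) & np.isfinite(v2)
    r = float(np.corrcoef(v1[ok], v2[ok])[0, 1])
    return spaces[0], spaces[1], r
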