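"""Second-order analysis: comparing scene spaces across methods.

Given vectorized (Fisher-z or log-rating) scene spaces from neural data,
behavioral ratings and computer-vision models, this module

* correlates every pair of spaces (pairwise-complete Pearson, t-based
  two-sided p, Bonferroni flags against either the 4950 scene-pair family
  or a declared model-comparison family of correlations);
* ranks candidate model spaces by their correlation with a target space;
* partitions variance by ordered hierarchical regression -- nested OLS fits
  adding predictor blocks in a fixed order (low-level features first,
  higher-level models later), reporting cumulative multiple R, the increment
  dR per block and an F-test on each R^2 increment;
* tests whether two models fit a target differently by bootstrap: scene-pair
  entries are resampled with replacement (jointly across target and models),
  r^2_A - r^2_B recomputed per resample, and a percentile confidence
  interval built; the difference is significant when 0 falls outside it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .similarity import SceneSpaceVector

logger = logging.getLogger(__name__)

#: default size of the regression comparison family for Bonferroni flags
#: (all ROI x model correlations declared in one analysis)
DEFAULT_FAMILY_M = 39

#: scene-pair family for a 100-scene stimulus set
SCENE_PAIR_FAMILY = 4950


def _values(space) -> np.ndarray:
    return np.asarray(getattr(space, "values", space), dtype=float).ravel()


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class CrossMethodMatrix:
    """m x m correlations between scene spaces, with p-values and flags."""

    r: np.ndarray
    p: np.ndarray
    significant: np.ndarray
    labels: list
    correction: str
    alpha_corrected: float


@dataclass
class HierarchicalFit:
    """Ordered-block regression summary.

    ``cumulative_r[k]`` is the multiple R of the nested model through block
    k; ``delta_r[k]`` its increment over the previous block (the first block's
    increment is its full R).  ``p[k]`` is the F-test p-value on the R^2
    increment; significance flags are given at the uncorrected and the
    Bonferroni-corrected alpha.
    """

    labels: list
    cumulative_r: np.ndarray
    delta_r: np.ndarray
    f: np.ndarray
    p: np.ndarray
    significant_uncorrected: np.ndarray
    significant_corrected: np.ndarray
    n_obs: int
    meta: dict = field(default_factory=dict)


@dataclass
class BootstrapResult:
    """Bootstrap comparison of two models' fit (r^2) to one target."""

    estimate: float
    ci_low: float
    ci_high: float
    level: float
    n_iterations: int
    seed: int
    significant: bool
    n_degenerate_redrawn: int = 0
    sign_a: float = 0.0
    sign_b: float = 0.0


# ---------------------------------------------------------------------------
# Correlations between spaces
# ---------------------------------------------------------------------------

def space_correlation(a, b) -> tuple[float, float, int]:
    """Pearson r between two scene spaces over jointly non-missing entries.

    Returns ``(r, p, n_complete)`` with a two-sided p from the t distribution
    on ``n_complete - 2`` degrees of freedom.
    """
    va, vb = _values(a), _values(b)
    if va.size != vb.size:
        raise ValueError("scene spaces differ in length")
    ok = np.isfinite(va) & np.isfinite(vb)
    n = int(ok.sum())
    if n < 3:
        raise ValueError(f"fewer than 3 complete pairs ({n})")
    r, p = stats.pearsonr(va[ok], vb[ok])
    return float(r), float(p), n


def correlation_table(spaces, labels=None, *,
                      correction: str = "bonferroni_pairs",
                      family_size: int | None = None,
                      alpha: float = 0.05) -> CrossMethodMatrix:
    """All pairwise space correlations with Bonferroni significance flags.

    ``correction="bonferroni_pairs"`` divides alpha by the number of scene
    pairs in the vectors (4950 for 100 scenes); ``"bonferroni_m"`` divides by
    a declared family of correlations (default 39).
    """
    if isinstance(spaces, dict):
        labels = list(spaces)
        spaces = list(spaces.values())
    if labels is None:
        labels = [getattr(s, "method", "") or f"space{i}"
                  for i, s in enumerate(spaces)]
    m = len(spaces)
    if m < 2:
        raise ValueError("need >= 2 spaces")
    lengths = {_values(s).size for s in spaces}
    if len(lengths) != 1:
        raise ValueError("spaces differ in length")

    if correction == "bonferroni_pairs":
        fam = lengths.pop() if family_size is None else family_size
    elif correction == "bonferroni_m":
        fam = DEFAULT_FAMILY_M if family_size is None else family_size
    else:
        raise ValueError(f"unknown correction {correction!r}")
    alpha_c = alpha / fam

    R = np.eye(m)
    P = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            r, p, _ = space_correlation(spaces[i], spaces[j])
            R[i, j] = R[j, i] = r
            P[i, j] = P[j, i] = p
    sig = (P < alpha_c) & ~np.eye(m, dtype=bool)
    return CrossMethodMatrix(r=R, p=P, significant=sig, labels=list(labels),
                             correction=correction, alpha_corrected=alpha_c)


def rank_models(target, models: dict, top_k: int | None = None):
    """Model spaces sorted by descending correlation with the target.

    Ties break by label order (logged).  Returns ``[(label, r), ...]``
    truncated to ``top_k`` when given.
    """
    if not models:
        raise ValueError("need >= 1 model")
    scored = []
    for label in models:
        r, _, _ = space_correlation(target, models[label])
        scored.append((label, r))
    scored.sort(key=lambda t: t[0])          # label order for ties
    scored.sort(key=lambda t: -t[1])         # stable: descending r
    rs = [r for _, r in scored]
    if len(set(np.round(rs, 12))) < len(rs):
        logger.info("rank_models: ties broken by label order")
    return scored[:top_k] if top_k else scored


# ---------------------------------------------------------------------------
# Hierarchical regression
# ---------------------------------------------------------------------------

def _r2(y: np.ndarray, X: np.ndarray) -> tuple[float, int]:
    """R^2 of OLS with intercept; returns (R^2, design rank)."""
    D = np.column_stack([np.ones(len(y)), X]) if X.size else np.ones((len(y), 1))
    beta, _, rank, _ = np.linalg.lstsq(D, y, rcond=None)
    resid = y - D @ beta
    tss = np.sum((y - y.mean()) ** 2)
    if tss == 0:
        raise ValueError("target has zero variance")
    return 1.0 - resid @ resid / tss, rank


def hierarchical_regression(target, blocks, *, alpha: float = 0.05,
                            family_size: int = DEFAULT_FAMILY_M) -> HierarchicalFit:
    """Ordered nested OLS over predictor blocks.

    ``blocks`` is an ordered mapping (or list of pairs) ``label ->``
    predictors, each a vector or (n, p) matrix.  Blocks are added in order;
    each step reports cumulative multiple R, dR, and an F-test on the R^2
    increment (numerator df = predictors added, denominator df =
    ``n - 1 - total predictors so far``).  Rows with any missing value are
    dropped (pairwise-complete at the block level would break nesting).
    Rank-deficient designs are reported with the offending block.
    """
    if hasattr(blocks, "items"):
        blocks = list(blocks.items())
    y = _values(target)
    mats = []
    for label, pred in blocks:
        if isinstance(pred, (list, tuple)):
            X = np.column_stack([_values(p) for p in pred])
        else:
            X = np.asarray(getattr(pred, "values", pred), dtype=float)
            if X.ndim == 1:
                X = X[:, None]
        if X.shape[0] != y.size:
            raise ValueError(f"block {label!r}: predictor length mismatch")
        mats.append((label, X))

    ok = np.isfinite(y)
    for _, X in mats:
        ok &= np.isfinite(X).all(axis=1)
    n = int(ok.sum())
    total_p = sum(X.shape[1] for _, X in mats)
    if total_p >= n:
        raise ValueError(f"{total_p} predictors for {n} observations")
    y = y[ok]

    labels, cum_r2, deltas, fs, ps = [], [], [], [], []
    X_sofar = np.empty((n, 0))
    r2_prev, p_prev = 0.0, 0
    for label, X in mats:
        X_sofar = np.column_stack([X_sofar, X[ok]])
        r2, rank = _r2(y, X_sofar)
        if rank < X_sofar.shape[1] + 1:
            logger.warning("hierarchical_regression: design rank-deficient "
                           "at block %r", label)
        r2 = min(max(r2, 0.0), 1.0)
        p_now = X_sofar.shape[1]
        df_num = p_now - p_prev
        df_den = n - 1 - p_now
        inc = max(r2 - r2_prev, 0.0)
        if 1.0 - r2 < 1e-12:
            F = np.inf
            pval = 0.0
        else:
            F = (inc / df_num) / ((1.0 - r2) / df_den)
            pval = float(stats.f.sf(F, df_num, df_den))
        labels.append(label)
        cum_r2.append(r2)
        deltas.append(np.sqrt(r2) - np.sqrt(r2_prev))
        fs.append(F)
        ps.append(pval)
        r2_prev, p_prev = r2, p_now

    cum_r = np.sqrt(cum_r2)
    ps = np.array(ps)
    return HierarchicalFit(
        labels=labels, cumulative_r=cum_r, delta_r=np.array(deltas),
        f=np.array(fs), p=ps,
        significant_uncorrected=ps < alpha,
        significant_corrected=ps < alpha / family_size,
        n_obs=n, meta={"cumulative_r2": np.array(cum_r2)})


# ---------------------------------------------------------------------------
# Bootstrap model comparison
# ---------------------------------------------------------------------------

def _r2_between(x: np.ndarray, y: np.ndarray) -> float:
    return float(np.corrcoef(x, y)[0, 1] ** 2)


def bootstrap_model_difference(target, model_a, model_b, *,
                               n_iter: int = 1000, level: float = 0.95,
                               seed: int = 0, family_size: int = 1,
                               unit: str = "pairs") -> BootstrapResult:
    """Percentile-bootstrap CI for r^2_A - r^2_B against one target.

    With ``unit="pairs"`` (default) scene-pair entries are resampled with
    replacement jointly across the three vectors -- pairs are the
    observations entering every correlation.  ``unit="scenes"`` resamples
    scenes instead and keeps the pairs among distinct resampled scenes, a
    sensitivity check that respects the dependence pairs inherit from
    shared scenes.  Each resample recomputes both squared correlations.
    With ``family_size > 1`` the CI level is Bonferroni-widened to
    ``1 - (1 - level) / family_size`` so the comparison survives a declared
    family of model comparisons.  Degenerate resamples (any vector with zero
    variance) are redrawn and counted.  Models are compared on r^2 -- the
    fit metric -- with the signs of the full-sample correlations reported
    alongside, since a negatively correlated model can still fit well.
    """
    if n_iter < 100:
        raise ValueError("n_iter must be >= 100")
    if unit not in ("pairs", "scenes"):
        raise ValueError(f"unknown resampling unit {unit!r}")
    vt, va, vb = _values(target), _values(model_a), _values(model_b)
    if not (vt.size == va.size == vb.size):
        raise ValueError("scene spaces differ in length")
    ok = np.isfinite(vt) & np.isfinite(va) & np.isfinite(vb)

    ra_full = np.corrcoef(vt[ok], va[ok])[0, 1]
    rb_full = np.corrcoef(vt[ok], vb[ok])[0, 1]
    estimate = float(ra_full ** 2 - rb_full ** 2)

    rng = np.random.default_rng(seed)
    if unit == "scenes":
        from .similarity import SceneSpaceVector, pair_position

        n_sc = SceneSpaceVector(vt).n_scenes
        resample = _scene_resampler(n_sc, rng)
    else:
        vt, va, vb = vt[ok], va[ok], vb[ok]
        n = vt.size
        if n < 3:
            raise ValueError("fewer than 3 complete entries")
        resample = lambda: rng.integers(0, n, n)

    diffs = np.empty(n_iter)
    n_redrawn = 0
    done = 0
    while done < n_iter:
        idx = resample()
        t, a, b = vt[idx], va[idx], vb[idx]
        keep = np.isfinite(t) & np.isfinite(a) & np.isfinite(b)
        t, a, b = t[keep], a[keep], b[keep]
        if t.size < 3 or t.std() == 0 or a.std() == 0 or b.std() == 0:
            n_redrawn += 1
            continue
        diffs[done] = _r2_between(t, a) - _r2_between(t, b)
        done += 1
    if n_redrawn:
        logger.info("bootstrap: %d degenerate resample(s) redrawn", n_redrawn)

    eff_level = 1.0 - (1.0 - level) / max(family_size, 1)
    tail = (1.0 - eff_level) / 2.0
    lo, hi = np.quantile(diffs, [tail, 1.0 - tail])
    return BootstrapResult(
        estimate=estimate, ci_low=float(lo), ci_high=float(hi),
        level=eff_level, n_iterations=n_iter, seed=seed,
        significant=not (lo <= 0.0 <= hi),
        n_degenerate_redrawn=n_redrawn,
        sign_a=float(np.sign(ra_full)), sign_b=float(np.sign(rb_full)))


def _scene_resampler(n_scenes: int, rng):
    """Index generator for scene-level resampling of a pair vector.

    Draws scenes with replacement and returns the pair-vector positions of
    all pairs of distinct resampled scenes.
    """
    from .similarity import pair_position

    def resample() -> np.ndarray:
        scenes = rng.integers(0, n_scenes, n_scenes)
        idx = []
        for a in range(n_scenes):
            for b in range(a + 1, n_scenes):
                i, j = scenes[a], scenes[b]
                if i == j:
                    continue
                idx.append(pair_position(min(i, j), max(i, j), n_scenes))
        return np.array(idx, dtype=int)

    return resample
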