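"""Synthetic stimuli, attribute tables, voxel data and ratings.

The generators emulate the statistical structure the analysis assumes, with
known ground truth so that the whole pipeline can be exercised end-to-end and
its recovery properties measured:

* a stimulus set of 100 scenes = 50 categories x 2 exemplars (procedural
  texture images whose category members share orientation / spatial
  frequency / hue, so simple descriptors carry real category signal);
* attribute-classifier score tables (category-level means plus exemplar
  noise);
* trial-level voxel responses whose induced scene-by-scene correlation
  structure is a known weighted mixture of model scene spaces plus white
  noise, sampled over repetitions and peristimulus timepoints with
  attenuated signal outside the peak window;
* similarity ratings on a 1-7 scale (8 = identical) organized in HITs of 11
  trials containing exactly one identical-pair catch trial, with ~20
  observations per pair and a strongly right-skewed response distribution.

All randomness flows from one seeded generator per call; identical seeds
reproduce every output bit-exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .features import AttributeScoreTable
from .neural import TrialPatternArray
from .similarity import SceneSpaceVector, pair_indices

logger = logging.getLogger(__name__)

HIT_SIZE = 11          # trials per HIT, one of which is a catch trial
HITS_PER_RATER = 17    # raters complete ~17 HITs each on average

#: marginal response probabilities for ratings 1..7 (majority "different",
#: giving the right-skewed distribution that motivates the log transform)
RESPONSE_PROBS = np.array([0.50, 0.22, 0.11, 0.07, 0.05, 0.03, 0.02])


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class StimulusSet:
    """Procedurally generated scene images with category structure."""

    n_categories: int
    exemplars_per_category: int
    images: list
    category_of: np.ndarray

    def __post_init__(self) -> None:
        self.category_of = np.asarray(self.category_of, dtype=int)
        n = self.n_categories * self.exemplars_per_category
        if len(self.images) != n or self.category_of.size != n:
            raise ValueError("total scenes must equal n_categories * exemplars")
        counts = np.bincount(self.category_of, minlength=self.n_categories)
        if not np.all(counts == self.exemplars_per_category):
            raise ValueError("every category must have exactly "
                             f"{self.exemplars_per_category} exemplars")

    @property
    def n_scenes(self) -> int:
        return len(self.images)


@dataclass
class GroundTruthMixture:
    """A known weighted mixture of model scene spaces plus noise."""

    model_spaces: list
    weights: np.ndarray
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.model_spaces) != self.weights.size:
            raise ValueError("one weight per model space required")
        if np.any(self.weights < 0) or self.noise_sd < 0:
            raise ValueError("weights and noise_sd must be nonnegative")
        lengths = {np.asarray(getattr(s, "values", s)).size for s in self.model_spaces}
        if len(lengths) != 1:
            raise ValueError("all model spaces must share one length")
        if self.noise_sd == 0 and not np.any(self.weights > 0):
            raise ValueError("need at least one positive weight when noise_sd=0")

    @property
    def n_scenes(self) -> int:
        return SceneSpaceVector(
            np.asarray(getattr(self.model_spaces[0], "values", self.model_spaces[0]))
        ).n_scenes

    def target_offdiagonal(self) -> np.ndarray:
        """The mixed upper-triangle similarity values."""
        stack = np.stack([np.asarray(getattr(s, "values", s), dtype=float)
                          for s in self.model_spaces])
        return self.weights @ stack


@dataclass
class RatingTable:
    """Long-format trial rows: (rater, scene_a, scene_b, response, is_catch, hit)."""

    frame: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.frame
        resp = df["response"]
        if not ((resp >= 1) & (resp <= 8)).all():
            raise ValueError("responses must be in 1..8")
        catch = df["is_catch"]
        if not (df.loc[catch, "scene_a"] == df.loc[catch, "scene_b"]).all():
            raise ValueError("catch rows must pair a scene with itself")
        if not (df.loc[~catch, "scene_a"] != df.loc[~catch, "scene_b"]).all():
            raise ValueError("non-catch rows must pair distinct scenes")


# ---------------------------------------------------------------------------
# Scene images
# ---------------------------------------------------------------------------

def gen_scene_images(n_categories: int, exemplars: int, size: int,
                     seed: int) -> StimulusSet:
    """Procedural scene images with per-category texture families.

    Each category draws an (orientation, spatial frequency, hue) triple; an
    exemplar is that family's oriented grating texture with small jitter of
    the parameters plus pixel noise, rendered as a 3-channel float image in
    [0, 1].  Within-category pairs are therefore more similar than
    between-category pairs under simple descriptors.
    """
    if n_categories < 2 or exemplars < 1:
        raise ValueError("need n_categories >= 2 and exemplars >= 1")
    if size < 32:
        raise ValueError("size must be >= 32 pixels")
    rng = np.random.default_rng(seed)
    from skimage.color import hsv2rgb

    yy, xx = np.mgrid[0:size, 0:size] / size
    images, category_of = [], []
    for c in range(n_categories):
        theta = rng.uniform(0, np.pi)
        freq = rng.uniform(4.0, 12.0)
        hue = rng.uniform(0, 1)
        phase = rng.uniform(0, 2 * np.pi)
        for _ in range(exemplars):
            th = theta + rng.normal(0, 0.05)
            fr = freq * (1 + rng.normal(0, 0.04))
            hu = (hue + rng.normal(0, 0.02)) % 1.0
            ph = phase + rng.normal(0, 0.3)
            carrier = np.sin(2 * np.pi * fr * (xx * np.cos(th) + yy * np.sin(th)) + ph)
            lum = 0.5 + 0.35 * carrier + rng.normal(0, 0.03, (size, size))
            lum = np.clip(lum, 0.0, 1.0)
            hsv = np.stack([np.full_like(lum, hu),
                            np.full_like(lum, 0.6),
                            lum], axis=-1)
            images.append(hsv2rgb(hsv))
            category_of.append(c)
    return StimulusSet(n_categories, exemplars, images, np.array(category_of))


# ---------------------------------------------------------------------------
# Attribute scores
# ---------------------------------------------------------------------------

def gen_attribute_scores(stimuli: StimulusSet, n_attributes: int,
                         category_effect: float, noise_sd: float,
                         seed: int) -> AttributeScoreTable:
    """Classifier-confidence table: category-level means + exemplar noise.

    ``category_effect`` scales the spread of the per-category attribute
    means; ``noise_sd`` is the exemplar-level deviation around them.
    """
    if n_attributes < 1:
        raise ValueError("n_attributes must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    cat_means = category_effect * rng.standard_normal(
        (stimuli.n_categories, n_attributes))
    scores = cat_means[stimuli.category_of] + noise_sd * rng.standard_normal(
        (stimuli.n_scenes, n_attributes))
    df = pd.DataFrame(scores, columns=[f"attr{j:03d}" for j in range(n_attributes)])
    return AttributeScoreTable(scores=df, categories=stimuli.category_of.copy())


# ---------------------------------------------------------------------------
# Voxel patterns
# ---------------------------------------------------------------------------

def _nearest_correlation(C: np.ndarray) -> np.ndarray:
    """Eigenvalue-clipped nearest PSD matrix, rescaled to unit diagonal."""
    vals, vecs = np.linalg.eigh(C)
    Cp = (vecs * np.clip(vals, 0.0, None)) @ vecs.T
    d = np.sqrt(np.clip(np.diag(Cp), 1e-12, None))
    Cp = Cp / np.outer(d, d)
    np.fill_diagonal(Cp, 1.0)
    return Cp


def gen_voxel_patterns(mixture: GroundTruthMixture, n_voxels: int,
                       n_repetitions: int, n_timepoints: int,
                       peak_window: tuple = (3, 4), *,
                       t_spacing: float = 2.0, attenuation: float = 0.3,
                       allow_projection: bool = False,
                       roi: str = "synthetic") -> TrialPatternArray:
    """Trial-level voxel responses embedding a target similarity structure.

    The target scene correlation matrix (unit diagonal, off-diagonal = the
    weighted mixture of model spaces) is factorized and embedded so that the
    Pearson correlation across voxels of the repetition- and window-averaged
    patterns reproduces it *exactly* at ``noise_sd = 0``: the signal rows are
    constructed in the orthogonal complement of the constant-voxel vector
    (this needs ``n_voxels >= n_scenes + 1``).  Independent Gaussian noise of
    sd ``mixture.noise_sd`` (relative to unit signal sd) is added per trial
    and timepoint; timepoints outside the closed index range ``peak_window``
    carry signal attenuated by ``attenuation``.

    A mixture implying a non-positive-semidefinite correlation matrix is an
    impossible target and raises; with ``allow_projection=True`` the nearest
    correlation matrix is used instead and reported in ``meta``.
    """
    n = mixture.n_scenes
    if n_voxels < max(2, n + 1):
        raise ValueError(f"need n_voxels >= n_scenes + 1 = {n + 1} for an "
                         "exact embedding")
    lo, hi = int(peak_window[0]), int(peak_window[1])
    if not 0 <= lo <= hi < n_timepoints:
        raise ValueError("peak_window out of range")

    C = np.eye(n)
    i, j = pair_indices(n)
    off = mixture.target_offdiagonal()
    C[i, j] = off
    C[j, i] = off

    eigvals = np.linalg.eigvalsh(C)
    projected = False
    if eigvals[0] < -1e-10:
        if not allow_projection:
            raise ValueError(
                f"mixture implies a non-PSD similarity (min eigenvalue "
                f"{eigvals[0]:.3g}); pass allow_projection=True to use the "
                "nearest correlation matrix")
        logger.warning("gen_voxel_patterns: projecting to nearest PSD "
                       "(min eigenvalue %.3g)", eigvals[0])
        C = _nearest_correlation(C)
        projected = True

    rng = np.random.default_rng(mixture.seed)
    vals, vecs = np.linalg.eigh(C)
    L = vecs * np.sqrt(np.clip(vals, 0.0, None))          # (n, n), L L^T = C

    # orthonormal, zero-mean voxel loading basis
    G = rng.standard_normal((n_voxels, n))
    G -= G.mean(axis=0, keepdims=True)
    Q, _ = np.linalg.qr(G)                                 # (n_voxels, n)
    signal = (L @ Q.T) * np.sqrt(n_voxels)                 # unit sd per row

    amp = np.full(n_timepoints, attenuation)
    amp[lo:hi + 1] = 1.0
    resp = signal[:, None, None, :] * amp[None, None, :, None]
    resp = np.broadcast_to(resp, (n, n_repetitions, n_timepoints, n_voxels)).copy()
    if mixture.noise_sd > 0:
        resp += mixture.noise_sd * rng.standard_normal(resp.shape)
    return TrialPatternArray(
        resp, t_spacing=t_spacing, roi=roi,
        meta={"weights": mixture.weights.tolist(),
              "noise_sd": mixture.noise_sd,
              "peak_window": (lo, hi),
              "psd_projected": projected})


def orthogonal_scene_spaces(n_scenes: int, n_spaces: int, seed: int,
                            scale: float = 0.08) -> list[SceneSpaceVector]:
    """Mutually orthogonal zero-mean model scene spaces for recovery tests.

    Entries are scaled to sd ``scale`` so that convex mixtures keep the
    implied correlation matrix positive definite at typical problem sizes.
    """
    m = n_scenes * (n_scenes - 1) // 2
    if n_spaces > m:
        raise ValueError("more spaces than scene pairs")
    rng = np.random.default_rng(seed)
    G = rng.standard_normal((m, n_spaces))
    G -= G.mean(axis=0, keepdims=True)
    Q, _ = np.linalg.qr(G)
    spaces = []
    for k in range(n_spaces):
        v = Q[:, k] * scale * np.sqrt(m)   # unit-norm column -> sd ~= scale
        spaces.append(SceneSpaceVector(v, transform="raw_r", method=f"model{k}"))
    return spaces


# ---------------------------------------------------------------------------
# Ratings
# ---------------------------------------------------------------------------

def gen_ratings(true_space: SceneSpaceVector, n_obs_per_pair: int,
                n_bad_raters: int, seed: int, *,
                rating_noise_sd: float = 1.0) -> RatingTable:
    """Similarity ratings with HIT / catch-trial structure and bad raters.

    Non-catch responses are a monotone discretization of the (standardized)
    true pair similarity plus Gaussian noise onto 1..7, with cut points
    placed so the pooled response distribution is strongly right-skewed.
    Observations are grouped into HITs of 11 rows containing exactly one
    catch trial (an identical pair, correct answer 8).  Attentive raters
    answer catches with 8; the ``n_bad_raters`` planted bad raters answer
    catch trials incorrectly and use only the extreme responses {1, 8},
    matching the whole-rater exclusion rule downstream.
    """
    if n_obs_per_pair < 1:
        raise ValueError("n_obs_per_pair must be >= 1")
    n = true_space.n_scenes
    rng = np.random.default_rng(seed)

    z = np.asarray(true_space.values, dtype=float)
    sd = z.std()
    z = (z - z.mean()) / sd if sd > 0 else np.zeros_like(z)

    m = z.size
    order = np.repeat(np.arange(m), n_obs_per_pair)
    rng.shuffle(order)
    per_hit = HIT_SIZE - 1
    n_hits = int(np.ceil(order.size / per_hit))

    cut = np.cumsum(RESPONSE_PROBS)[:-1]
    i_idx, j_idx = pair_indices(n)

    n_raters = max(int(np.ceil(n_hits / HITS_PER_RATER)), n_bad_raters + 1)
    if n_bad_raters >= n_raters:
        raise ValueError("n_bad_raters must leave at least one good rater")
    hit_rater = rng.permutation(np.arange(n_hits) % n_raters)
    bad = set(range(n_bad_raters))

    rows = []
    for h in range(n_hits):
        rater = int(hit_rater[h])
        chunk = order[h * per_hit:(h + 1) * per_hit]
        catch_pos = int(rng.integers(0, len(chunk) + 1))
        catch_scene = int(rng.integers(0, n))
        trial = 0
        for pos in range(len(chunk) + 1):
            if pos == catch_pos:
                if rater in bad:
                    resp = 1
                else:
                    resp = 8
                rows.append((rater, catch_scene, catch_scene, resp, True, h))
                continue
            p = int(chunk[trial]); trial += 1
            if rater in bad:
                resp = int(rng.choice([1, 8]))
            else:
                latent = z[p] + rating_noise_sd * rng.standard_normal()
                u = norm.cdf(latent / np.hypot(1.0, rating_noise_sd))
                resp = 1 + int(np.searchsorted(cut, u, side="right"))
            rows.append((rater, int(i_idx[p]), int(j_idx[p]), resp, False, h))

    df = pd.DataFrame(rows, columns=["rater", "scene_a", "scene_b",
                                     "response", "is_catch", "hit"])
    return RatingTable(df, meta={"n_raters": n_raters,
                                 "bad_raters": sorted(bad),
                                 "n_hits": n_hits})


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_stimulus_images(stimuli: StimulusSet, directory) -> list:
    """Write each image as scene%03d.png; returns the paths."""
    import os

    from PIL import Image as PILImage

    os.makedirs(directory, exist_ok=True)
    paths = []
    for s, img in enumerate(stimuli.images):
        arr = np.clip(np.asarray(img) * 255.0, 0, 255).astype(np.uint8)
        p = os.path.join(str(directory), f"scene{s:03d}.png")
        PILImage.fromarray(arr).save(p)
        paths.append(p)
    return paths


def read_images(paths) -> list:
    """Read PNG/JPEG images as float arrays in [0, 1]."""
    from PIL import Image as PILImage

    return [np.asarray(PILImage.open(p), dtype=float)[..., :3] / 255.0
            for p in paths]


def write_attribute_table(table: AttributeScoreTable, path) -> None:
    df = table.scores.copy()
    df.insert(0, "category", table.categories)
    df.to_csv(path, sep="\t", index_label="scene")


def read_attribute_table(path) -> AttributeScoreTable:
    df = pd.read_csv(path, sep="\t", index_col="scene")
    return AttributeScoreTable(scores=df.drop(columns=["category"]),
                               categories=df["category"].to_numpy())


def write_ratings(table: RatingTable, path) -> None:
    table.frame.to_csv(path, sep="\t", index=False)


def read_ratings(path) -> RatingTable:
    return RatingTable(pd.read_csv(path, sep="\t"))


def write_trials_tsv(trials: TrialPatternArray, path) -> None:
    """Flat long-format TSV: one row per (scene, repetition, timepoint)."""
    n_s, n_r, n_t, n_v = trials.responses.shape
    idx = pd.MultiIndex.from_product(
        [range(n_s), range(n_r), range(n_t)],
        names=["scene", "repetition", "timepoint"])
    df = pd.DataFrame(trials.responses.reshape(-1, n_v), index=idx,
                      columns=[f"v{q}" for q in range(n_v)])
    df.to_csv(path, sep="\t")


def read_trials_tsv(path, *, t_spacing: float = 2.0,
                    roi: str = "") -> TrialPatternArray:
    df = pd.read_csv(path, sep="\t",
                     index_col=["scene", "repetition", "timepoint"])
    n_s = df.index.get_level_values(0).max() + 1
    n_r = df.index.get_level_values(1).max() + 1
    n_t = df.index.get_level_values(2).max() + 1
    arr = df.to_numpy().reshape(n_s, n_r, n_t, df.shape[1])
    return TrialPatternArray(arr, t_spacing=t_spacing, roi=roi)


def write_trials_nifti(trials: TrialPatternArray, nifti_path, index_path,
                       grid: tuple) -> None:
    """One volume per trial-timepoint plus a sidecar TSV index.

    Voxels are laid out row-major on ``grid`` (padded with zeros if the grid
    exceeds the voxel count).
    """
    import nibabel as nib

    n_s, n_r, n_t, n_v = trials.responses.shape
    if int(np.prod(grid)) < n_v:
        raise ValueError("grid too small for the voxel count")
    flat = trials.responses.reshape(-1, n_v)
    vols = np.zeros((len(flat), int(np.prod(grid))))
    vols[:, :n_v] = flat
    data = vols.T.reshape(*grid, len(flat))
    nib.save(nib.Nifti1Image(data, affine=np.eye(4)), str(nifti_path))
    idx = pd.MultiIndex.from_product(
        [range(n_s), range(n_r), range(n_t)],
        names=["scene", "repetition", "timepoint"])
    pd.DataFrame(index=idx).reset_index().to_csv(index_path, sep="\t", index=False)
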