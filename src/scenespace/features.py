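"""Per-image descriptors for every computer-vision scene model.

Each method turns an image into a fixed-length vector; cross-correlating
those vectors across all scene pairs yields that method's scene space.

Global descriptor
    * GIST -- squared responses of a bank of oriented band-pass (Gabor-like)
      filters (8 orientations x 4 scales), block-averaged on a 4 x 4 grid:
      512 dimensions.

Local descriptors, pooled via bag-of-visual-words (k-means codebook,
nearest-centroid assignment, L2-normalized count histogram):
    * HOG 2x2 -- per-cell gradient-orientation histograms with
      contrast-sensitive, contrast-insensitive and texture components,
      stacked over 2x2 cell blocks; spatial histograms on 1x1 / 2x2 / 4x4
      pyramid grids (L0-L2).
    * Self-similarity (SSIM) -- local correlation surface of a 5x5 patch over
      a 40 px-radius window, pooled into log-polar bins; quantized into 300
      visual words.
    * Hue histogram, dense SIFT, Hue-SIFT, RGB-SIFT -- densely sampled color
      and gradient features with dictionary sizes k in {50, 250, 400, 1000}.

Attribute models (NEIL-style and SUN-style classifier confidences) enter as
score tables; for NEIL-style tables each attribute column is reweighted by
the exponentiated variance of its per-category means, up-weighting the
attributes that separate scene categories.

Geometric-layout (GEOM) probability maps per class {gnd, vrt, por, sky} are
block-averaged to an 8 x 8 grid (64-d per class; "all" concatenates).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)

GEOM_CLASSES = ("gnd", "vrt", "por", "sky")

#: luminance weights for grayscale conversion
_LUMA = np.array([0.299, 0.587, 0.114])


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class DescriptorVector:
    """A fixed-length descriptor with method / pyramid-level tags."""

    values: np.ndarray
    method: str = ""
    level: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(self.values)):
            raise ValueError("descriptor contains non-finite values")

    def __len__(self) -> int:
        return self.values.size


@dataclass
class Codebook:
    """k-means visual-word dictionary, canonicalized for reproducibility."""

    k: int
    centroids: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float)
        if self.centroids.shape[0] != self.k:
            raise ValueError("centroid count != k")


@dataclass
class AttributeScoreTable:
    """Scenes x attributes classifier-confidence scores with category labels."""

    scores: pd.DataFrame
    categories: np.ndarray

    def __post_init__(self) -> None:
        self.categories = np.asarray(self.categories)
        if len(self.scores) != len(self.categories):
            raise ValueError("one category label required per scene row")
        if self.scores.isna().any().any():
            raise ValueError("attribute scores must have no missing values")

    @property
    def n_scenes(self) -> int:
        return len(self.scores)


# ---------------------------------------------------------------------------
# Image helpers
# ---------------------------------------------------------------------------

def as_gray(image: np.ndarray) -> np.ndarray:
    """Luminance grayscale (weights 0.299 / 0.587 / 0.114), float in [0, 1]."""
    img = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite values")
    if img.ndim == 3:
        if img.shape[2] != 3:
            raise ValueError("color images must have 3 channels")
        return img @ _LUMA
    if img.ndim != 2:
        raise ValueError("image must be 2-D or 3-channel")
    return img


def hue_channel(image: np.ndarray) -> np.ndarray:
    """Hue of the HSV representation, in [0, 1) (circular)."""
    from skimage.color import rgb2hsv

    img = np.asarray(image, dtype=float)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("hue requires a 3-channel color image")
    return rgb2hsv(img)[..., 0]


def _block_means(arr: np.ndarray, grid: int) -> np.ndarray:
    """grid x grid block averages (uneven splits allowed via array_split)."""
    rows = np.array_split(arr, grid, axis=0)
    return np.array([[c.mean() for c in np.array_split(r, grid, axis=1)]
                     for r in rows])


# ---------------------------------------------------------------------------
# GIST
# ---------------------------------------------------------------------------

def _gabor_bank(size: int, n_orientations: int, n_scales: int) -> np.ndarray:
    """Frequency-domain bank of oriented log-Gabor transfer functions.

    Center frequencies are log-spaced (one octave apart, highest 0.25
    cycles/px); each filter is a Gaussian in log-frequency crossed with a
    Gaussian in orientation, with zero DC response.
    """
    fy = np.fft.fftfreq(size)[:, None]
    fx = np.fft.fftfreq(size)[None, :]
    fr = np.hypot(fx, fy)
    theta = np.arctan2(fy, fx)

    sigma_r = 0.65          # radial bandwidth, octaves
    sigma_t = 0.6 * np.pi / n_orientations

    bank = np.empty((n_scales * n_orientations, size, size))
    with np.errstate(divide="ignore"):
        log_fr = np.log2(np.where(fr > 0, fr, 1.0))
    i = 0
    for s in range(n_scales):
        f0 = 0.25 / (2 ** s)
        radial = np.exp(-((log_fr - np.log2(f0)) ** 2) / (2 * sigma_r ** 2))
        radial[fr == 0] = 0.0
        for o in range(n_orientations):
            t0 = np.pi * o / n_orientations
            dt = np.angle(np.exp(1j * (theta - t0)))
            bank[i] = radial * np.exp(-(dt ** 2) / (2 * sigma_t ** 2))
            i += 1
    return bank


def gist_descriptor(image: np.ndarray, n_orientations: int = 8,
                    n_scales: int = 4, grid: int = 4) -> DescriptorVector:
    """GIST: per-filter squared responses averaged on a ``grid x grid`` mesh.

    Output length is ``n_orientations * n_scales * grid**2`` (512 at the
    defaults).  The filters are band-pass, so a constant image maps to the
    zero vector.
    """
    gray = as_gray(image)
    h, w = gray.shape
    if h != w:
        raise ValueError("GIST expects a square image")
    if h < grid:
        raise ValueError(f"image side {h} smaller than pooling grid {grid}")

    bank = _gabor_bank(h, n_orientations, n_scales)
    F = np.fft.fft2(gray)
    out = np.empty((bank.shape[0], grid, grid))
    for i, G in enumerate(bank):
        resp = np.abs(np.fft.ifft2(F * G)) ** 2
        out[i] = _block_means(resp, grid)
    return DescriptorVector(out.ravel(), method="gist")


# ---------------------------------------------------------------------------
# HOG 2x2
# ---------------------------------------------------------------------------

def hog_cell_descriptors(image: np.ndarray, cell_size: int = 8,
                         n_signed_bins: int = 18, *,
                         raw: bool = False) -> np.ndarray:
    """Per-cell gradient histograms in the Felzenszwalb style.

    Each ``cell_size x cell_size`` cell yields ``n_signed_bins``
    contrast-sensitive bins + ``n_signed_bins//2`` contrast-insensitive bins
    + 4 texture (normalization-block energy) features, each component
    normalized against the 4 surrounding 2x2 cell blocks with truncation
    at 0.2.  Returns an (n_cells_y, n_cells_x, d) array.
    """
    if n_signed_bins % 2:
        raise ValueError("n_signed_bins must be even")
    gray = as_gray(image)
    h, w = gray.shape
    if min(h, w) < 4 * cell_size:
        raise ValueError("image too small for the cell grid")
    ny, nx = h // cell_size, w // cell_size
    gray = gray[: ny * cell_size, : nx * cell_size]

    gy, gx = np.gradient(gray)
    mag = np.hypot(gx, gy)
    ang = np.arctan2(gy, gx)  # [-pi, pi)
    b = np.floor(((ang + np.pi) / (2 * np.pi)) * n_signed_bins).astype(int) % n_signed_bins

    cy = np.arange(ny * cell_size) // cell_size
    cx = np.arange(nx * cell_size) // cell_size
    flat = (cy[:, None] * nx + cx[None, :]) * n_signed_bins + b
    hist = np.bincount(flat.ravel(), weights=mag.ravel(),
                       minlength=ny * nx * n_signed_bins)
    hist18 = hist.reshape(ny, nx, n_signed_bins)
    if raw:
        return hist18
    half = n_signed_bins // 2
    hist9 = hist18[..., :half] + hist18[..., half:]

    energy = (hist9 ** 2).sum(axis=2)
    pad = np.pad(energy, 1, mode="edge")
    # norms of the four 2x2 cell blocks containing each cell
    norms = np.empty((ny, nx, 4))
    for k, (dy, dx) in enumerate(((0, 0), (0, 1), (1, 0), (1, 1))):
        norms[..., k] = np.sqrt(pad[dy:dy + ny, dx:dx + nx]
                                + pad[dy:dy + ny, dx + 1:dx + 1 + nx]
                                + pad[dy + 1:dy + 1 + ny, dx:dx + nx]
                                + pad[dy + 1:dy + 1 + ny, dx + 1:dx + 1 + nx])
    inv = 1.0 / (norms + 1e-10)

    t18 = np.minimum(hist18[..., None, :] * inv[..., None], 0.2)  # (ny,nx,4,18)
    t9 = np.minimum(hist9[..., None, :] * inv[..., None], 0.2)
    feats = np.concatenate([
        0.5 * t18.sum(axis=2),
        0.5 * t9.sum(axis=2),
        0.2357 * t18.sum(axis=3),
    ], axis=2)
    return feats


def hog_block_descriptors(image: np.ndarray, cell_size: int = 8,
                          n_signed_bins: int = 18):
    """Stack 2x2 spatially overlapping cells into local block descriptors.

    Returns ``(blocks, centers)``: an (n_blocks, 4*d) array and the block
    centers in pixel coordinates (y, x) for spatial-pyramid pooling.
    """
    cells = hog_cell_descriptors(image, cell_size, n_signed_bins)
    ny, nx, d = cells.shape
    if ny < 2 or nx < 2:
        raise ValueError("need at least a 2x2 cell grid")
    blocks = np.concatenate([cells[:-1, :-1], cells[:-1, 1:],
                             cells[1:, :-1], cells[1:, 1:]], axis=2)
    by, bx = np.mgrid[0:ny - 1, 0:nx - 1]
    centers = np.stack([(by.ravel() + 1.0) * cell_size,
                        (bx.ravel() + 1.0) * cell_size], axis=1)
    return blocks.reshape(-1, 4 * d), centers


PYRAMID_GRIDS = {"L0": 1, "L1": 2, "L2": 4}


def hog_pyramid(image: np.ndarray, levels=("L0", "L1", "L2"), *,
                codebook: Codebook | None = None, cell_size: int = 8,
                n_signed_bins: int = 18) -> dict[str, DescriptorVector]:
    """Spatial-pyramid bag-of-words over quantized HOG 2x2 blocks.

    Block descriptors are assigned to the codebook's nearest visual word and
    histogrammed within each spatial bin of the level's grid (1x1 for L0,
    2x2 for L1, 4x4 for L2); each level's vector (length ``k * cells``) is
    L2-normalized.
    """
    if codebook is None:
        raise ValueError("hog_pyramid requires a trained codebook "
                         "(see train_codebook)")
    unknown = set(levels) - set(PYRAMID_GRIDS)
    if unknown:
        raise ValueError(f"unknown pyramid levels {sorted(unknown)}")
    blocks, centers = hog_block_descriptors(image, cell_size, n_signed_bins)
    words = assign_words(blocks, codebook)
    h, w = as_gray(image).shape
    k = codebook.k

    out = {}
    for lvl in levels:
        g = PYRAMID_GRIDS[lvl]
        sy = np.minimum((centers[:, 0] * g / h).astype(int), g - 1)
        sx = np.minimum((centers[:, 1] * g / w).astype(int), g - 1)
        cell_idx = sy * g + sx
        hist = np.bincount(cell_idx * k + words, minlength=g * g * k).astype(float)
        norm = np.linalg.norm(hist)
        if norm > 0:
            hist /= norm
        out[lvl] = DescriptorVector(hist, method="hog2x2", level=lvl)
    return out


# ---------------------------------------------------------------------------
# Self-similarity descriptors
# ---------------------------------------------------------------------------

def _log_polar_bins(radius: int, n_radial: int, n_angular: int):
    """Flat bin index (or -1) per displacement on the (2r+1)^2 offset grid."""
    dy, dx = np.mgrid[-radius:radius + 1, -radius:radius + 1]
    rad = np.hypot(dy, dx)
    edges = np.concatenate([[0.0], np.geomspace(2.0, radius + 1e-9, n_radial)])
    rbin = np.searchsorted(edges, rad, side="right") - 1
    rbin = np.clip(rbin, 0, n_radial - 1)
    abin = np.floor(((np.arctan2(dy, dx) + np.pi) / (2 * np.pi)) * n_angular)
    abin = abin.astype(int) % n_angular
    idx = rbin * n_angular + abin
    idx[rad > radius] = -1
    return idx


def ssim_descriptors(image: np.ndarray, patch: int = 5, radius: int = 40, *,
                     stride: int = 8, n_radial: int = 4, n_angular: int = 10):
    """Local self-similarity descriptors (log-polar pooled correlation map).

    At each sample point the ``patch x patch`` center patch is compared with
    every displaced patch within ``radius``; the similarity surface
    ``exp(-SSD / (patch^2 * var))`` is pooled by maximum into
    ``n_radial x n_angular`` log-polar bins.  Sample points whose window
    exits the image are skipped and zero-variance (degenerate) patches are
    excluded; both counts are reported.

    Returns ``(descriptors, info)`` with descriptors of shape
    (n_kept, n_radial * n_angular) and info counting skips/exclusions.
    """
    gray = as_gray(image)
    h, w = gray.shape
    half = patch // 2
    margin = radius + half
    if min(h, w) <= 2 * radius + patch:
        raise ValueError("image side must exceed 2*radius + patch")

    ys = np.arange(half, h - half, stride)
    xs = np.arange(half, w - half, stride)
    bins = _log_polar_bins(radius, n_radial, n_angular).ravel()
    inside = bins >= 0
    bin_idx = bins[inside]
    n_bins = n_radial * n_angular

    descs, positions = [], []
    n_skipped = n_degenerate = 0
    for y in ys:
        for x in xs:
            if y < margin or y >= h - margin or x < margin or x >= w - margin:
                n_skipped += 1
                continue
            P = gray[y - half:y + half + 1, x - half:x + half + 1]
            var_p = P.var()
            if var_p < 1e-12:
                n_degenerate += 1
                continue
            W = gray[y - margin:y + margin + 1, x - margin:x + margin + 1]
            wins = sliding_window_view(W, (patch, patch))
            ssd = ((wins - P) ** 2).sum(axis=(-1, -2)).ravel()[inside]
            sim = np.exp(-ssd / (patch * patch * var_p))
            d = np.zeros(n_bins)
            np.maximum.at(d, bin_idx, sim)
            descs.append(d)
            positions.append((y, x))

    logger.info("ssim_descriptors: %d points skipped (window exits image), "
                "%d degenerate patches excluded", n_skipped, n_degenerate)
    descs = np.array(descs) if descs else np.empty((0, n_bins))
    info = {"n_skipped": n_skipped, "n_degenerate": n_degenerate,
            "positions": positions}
    return descs, info


# ---------------------------------------------------------------------------
# Dense SIFT family and hue features
# ---------------------------------------------------------------------------

def _dense_sift_channel(channel: np.ndarray, stride: int, patch: int) -> np.ndarray:
    """Dense SIFT on one channel: 4x4 spatial sub-bins x 8 orientations.

    No keypoint detection or rotation normalization -- descriptors are
    sampled on a fixed grid, L2-normalized with truncation at 0.2 (then
    renormalized), 128-d each.
    """
    if patch % 4:
        raise ValueError("patch must be divisible by 4")
    sub = patch // 4
    h, w = channel.shape
    if h < patch or w < patch:
        raise ValueError("image smaller than the SIFT patch")
    gy, gx = np.gradient(channel.astype(float))
    mag = np.hypot(gx, gy)
    ob = np.floor(((np.arctan2(gy, gx) + np.pi) / (2 * np.pi)) * 8).astype(int) % 8

    # per-pixel flat (subcell, orientation) index within any patch is fixed
    local = (np.arange(patch) // sub)
    cell_of = local[:, None] * 4 + local[None, :]          # (patch, patch)

    out = []
    for y in range(0, h - patch + 1, stride):
        for x in range(0, w - patch + 1, stride):
            m = mag[y:y + patch, x:x + patch]
            b = ob[y:y + patch, x:x + patch]
            flat = cell_of * 8 + b
            d = np.bincount(flat.ravel(), weights=m.ravel(), minlength=128)
            n = np.linalg.norm(d)
            if n > 0:
                d = np.minimum(d / n, 0.2)
                d /= np.linalg.norm(d)
            out.append(d)
    return np.array(out)


def local_color_features(image: np.ndarray, variant: str, *,
                         stride: int = 8, patch: int = 16) -> np.ndarray:
    """Densely sampled local features: hue_hist, dense_sift, hue_sift, rgb_sift.

    ``dense_sift`` runs on luminance (128-d), ``hue_sift`` on the hue channel
    (128-d), ``rgb_sift`` concatenates per-channel SIFT (384-d).  ``hue_hist``
    samples local hue values embedded on the unit circle (cos h, sin h) so
    that k-means quantization respects circular hue distance.
    """
    img = np.asarray(image, dtype=float)
    if variant in ("hue_hist", "hue_sift", "rgb_sift") and (img.ndim != 3 or img.shape[2] != 3):
        raise ValueError(f"{variant} requires a 3-channel color image")

    if variant == "dense_sift":
        return _dense_sift_channel(as_gray(img), stride, patch)
    if variant == "hue_sift":
        return _dense_sift_channel(hue_channel(img), stride, patch)
    if variant == "rgb_sift":
        per = [_dense_sift_channel(img[..., c], stride, patch) for c in range(3)]
        return np.concatenate(per, axis=1)
    if variant == "hue_hist":
        hue = hue_channel(img)
        samples = hue[::stride, ::stride].ravel() * 2 * np.pi
        return np.stack([np.cos(samples), np.sin(samples)], axis=1)
    raise ValueError(f"unknown variant {variant!r}")


# ---------------------------------------------------------------------------
# Bag of visual words
# ---------------------------------------------------------------------------

def train_codebook(descriptors: np.ndarray, k: int, seed: int) -> Codebook:
    """Seeded k-means dictionary with canonically ordered centroids.

    Centroids are sorted by first coordinate (then lexicographically) so the
    same data and seed always produce the identical codebook regardless of
    k-means label order.
    """
    X = np.asarray(descriptors, dtype=float)
    if X.ndim != 2:
        raise ValueError("descriptors must be a 2-D array")
    if X.shape[0] < k:
        raise ValueError(f"need >= k={k} descriptors, got {X.shape[0]}")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # duplicate points can trigger convergence chatter
        km.fit(X)
    order = np.lexsort(km.cluster_centers_.T[::-1])
    return Codebook(k=k, centroids=km.cluster_centers_[order], seed=seed)


def assign_words(descriptors: np.ndarray, codebook: Codebook) -> np.ndarray:
    """Nearest-centroid assignment; ties break to the lowest centroid index."""
    X = np.atleast_2d(np.asarray(descriptors, dtype=float))
    if X.shape[1] != codebook.centroids.shape[1]:
        raise ValueError("descriptor dimensionality does not match codebook")
    return cdist(X, codebook.centroids).argmin(axis=1)


def bow_histogram(descriptors: np.ndarray, codebook: Codebook) -> DescriptorVector:
    """L2-normalized visual-word count histogram (length ``codebook.k``).

    An empty descriptor set yields the zero vector with a warning.
    """
    X = np.asarray(descriptors, dtype=float)
    if X.size == 0:
        logger.warning("bow_histogram: empty descriptor set, returning zeros")
        return DescriptorVector(np.zeros(codebook.k), method="bow")
    words = assign_words(X, codebook)
    hist = np.bincount(words, minlength=codebook.k).astype(float)
    hist /= np.linalg.norm(hist)
    return DescriptorVector(hist, method="bow")


# ---------------------------------------------------------------------------
# Geometric-class maps
# ---------------------------------------------------------------------------

def geom_descriptor(prob_maps: dict[str, np.ndarray],
                    grid: int = 8) -> dict[str, DescriptorVector]:
    """Block-average per-class probability maps to ``grid x grid``.

    ``prob_maps`` holds one 2-D map in [0, 1] per geometric class (ground,
    vertical, porous, sky); each class yields a ``grid**2`` vector and
    ``"all"`` is their concatenation in class order.
    """
    missing = set(GEOM_CLASSES) - set(prob_maps)
    if missing:
        raise ValueError(f"missing geometric classes: {sorted(missing)}")
    out = {}
    parts = []
    for cls in GEOM_CLASSES:
        m = np.asarray(prob_maps[cls], dtype=float)
        if m.ndim != 2:
            raise ValueError(f"{cls}: probability map must be 2-D")
        if m.min() < 0 or m.max() > 1:
            raise ValueError(f"{cls}: probabilities outside [0, 1]")
        v = _block_means(m, grid).ravel()
        out[cls] = DescriptorVector(v, method=f"geom_{cls}")
        parts.append(v)
    out["all"] = DescriptorVector(np.concatenate(parts), method="geom_all")
    return out


# ---------------------------------------------------------------------------
# Attribute reweighting
# ---------------------------------------------------------------------------

def reweight_attributes(table: AttributeScoreTable) -> AttributeScoreTable:
    """Scale each attribute column by exp(variance of its category means).

    For attribute a, ``v_a`` is the variance across categories of the mean
    score per category; every score in column a is multiplied by ``exp(v_a)``.
    Attributes whose scores separate the scene categories are thereby
    up-weighted.  Positive scaling preserves within-column scene ranking.
    """
    cats = np.unique(table.categories)
    if cats.size < 2:
        raise ValueError("reweighting requires >= 2 categories")
    means = table.scores.groupby(table.categories).mean()
    v = means.var(axis=0, ddof=0)
    weighted = table.scores * np.exp(v)
    return AttributeScoreTable(scores=weighted, categories=table.categories.copy())


# ---------------------------------------------------------------------------
# Scene-level extraction and I/O
# ---------------------------------------------------------------------------

def extract_descriptors(images: list[np.ndarray], method: str, *,
                        k: int = 300, seed: int = 0, stride: int = 8,
                        levels=("L0", "L1", "L2"), **kw) -> np.ndarray:
    """Scenes x dims descriptor matrix for one method over an image set.

    Bag-of-words methods train their codebook on the pooled local
    descriptors of all images (seeded), then histogram per image.  ``method``
    is one of ``gist``, ``hog2x2``, ``ssim``, ``hue_hist``, ``dense_sift``,
    ``hue_sift``, ``rgb_sift``.
    """
    if method == "gist":
        return np.stack([gist_descriptor(im, **kw).values for im in images])

    if method == "hog2x2":
        per_image = [hog_block_descriptors(im, **kw)[0] for im in images]
        cb = train_codebook(np.concatenate(per_image), k, seed)
        rows = []
        for im in images:
            levs = hog_pyramid(im, levels, codebook=cb, **kw)
            rows.append(np.concatenate([levs[l].values for l in levels]))
        return np.stack(rows)

    if method == "ssim":
        per_image = [ssim_descriptors(im, **kw)[0] for im in images]
        cb = train_codebook(np.concatenate(per_image), k, seed)
        return np.stack([bow_histogram(d, cb).values for d in per_image])

    if method in ("hue_hist", "dense_sift", "hue_sift", "rgb_sift"):
        per_image = [local_color_features(im, method, stride=stride, **kw)
                     for im in images]
        cb = train_codebook(np.concatenate(per_image), k, seed)
        return np.stack([bow_histogram(d, cb).values for d in per_image])

    raise ValueError(f"unknown method {method!r}")


def write_descriptor_matrix(path, matrix: np.ndarray, config: dict) -> None:
    """Write a scenes x dims matrix as TSV with a JSON config sidecar."""
    path = str(path)
    pd.DataFrame(np.asarray(matrix)).to_csv(path, sep="\t", index_label="scene")
    with open(path + ".json", "w") as fh:
        json.dump(config, fh, indent=2, sort_keys=True)


def read_descriptor_matrix(path) -> np.ndarray:
    return pd.read_csv(path, sep="\t", index_col="scene").to_numpy()
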