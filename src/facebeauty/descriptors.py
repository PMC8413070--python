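"""Secondary feature set (SFS) descriptors: texture, color and shape.

Three classical descriptor blocks complement the landmark ratios:

T — texture
    Four statistics of the gray-level co-occurrence matrix (GLCM):
    contrast, homogeneity, correlation and energy.  The GLCM p(i, j) is the
    normalized frequency of quantized gray-level pairs (i, j) at a fixed
    pixel offset; with several offsets the four statistics are computed per
    offset and averaged, which makes the block robust to texture direction.
C — color
    Per-channel histograms of the image in HSV space (hue is more aligned
    with how people describe skin color than RGB), each channel
    L1-normalized, concatenated H ++ S ++ V.
S — shape
    Hu's seven invariant moments of the grayscale image: algebraic
    combinations of normalized central moments that are invariant to
    translation, uniform scale and rotation; the seventh flips sign under
    reflection.

The fused vector is always ordered FS, T, C, S (present blocks only).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from skimage.color import rgb2hsv

from .ratios import RatioFeatureVector

__all__ = [
    "GLCMMatrix",
    "TextureFeatures",
    "HuVector",
    "ColorHistogram",
    "FusedFeatureVector",
    "DEFAULT_OFFSETS",
    "to_grayscale",
    "glcm",
    "texture_features",
    "hu_moments",
    "hsv_histogram",
    "fuse",
]

#: Default co-occurrence offsets (dy, dx): distance 1 at 0, 45, 90, 135 deg.
DEFAULT_OFFSETS: tuple[tuple[int, int], ...] = ((0, 1), (1, 1), (1, 0), (1, -1))


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """RGB -> 8-bit grayscale with BT.601 luma weights (0.299, 0.587, 0.114).

    Accepts an (H, W, 3) uint8 array; returns (H, W) uint8, rounded to the
    nearest integer.
    """
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(
            f"expected a 3-channel RGB image, got shape {img.shape}"
        )
    luma = (0.299 * img[..., 0].astype(float)
            + 0.587 * img[..., 1].astype(float)
            + 0.114 * img[..., 2].astype(float))
    return np.rint(luma).astype(np.uint8)


@dataclass(frozen=True)
class GLCMMatrix:
    """Per-offset gray-level co-occurrence matrices.

    ``p`` has shape (n_offsets, G, G); when normalized each offset's matrix
    sums to 1, and when symmetric each equals its transpose.
    """

    p: np.ndarray
    levels: int
    offsets: tuple[tuple[int, int], ...]
    symmetric: bool
    normalized: bool


def quantize_gray(gray: np.ndarray, levels: int) -> np.ndarray:
    """Uniformly quantize 8-bit intensities into ``levels`` bins (0..G-1)."""
    g = np.asarray(gray)
    return (g.astype(np.int64) * levels) // 256


def glcm(
    gray: np.ndarray,
    levels: int = 8,
    offsets: Iterable[tuple[int, int]] = DEFAULT_OFFSETS,
    symmetric: bool = True,
    normalize: bool = True,
) -> GLCMMatrix:
    """Gray-level co-occurrence matrices of an 8-bit grayscale image.

    For each offset (dy, dx), counts all in-bounds ordered pixel pairs
    (r, c) -> (r+dy, c+dx) of quantized levels, optionally adds the
    transpose (symmetric) and normalizes the matrix to sum 1.
    """
    g = np.asarray(gray)
    if g.ndim != 2:
        raise ValueError("glcm expects a 2-D grayscale image")
    if levels < 2:
        raise ValueError("levels must be >= 2")
    offsets = tuple(tuple(o) for o in offsets)
    if not offsets:
        raise ValueError("need at least one offset")
    q = quantize_gray(g, levels)
    h, w = q.shape
    mats = []
    for dy, dx in offsets:
        if abs(dy) >= h or abs(dx) >= w:
            raise ValueError(
                f"offset ({dy}, {dx}) exceeds image extent {q.shape}"
            )
        # source window and destination window shifted by (dy, dx)
        ys = slice(max(0, -dy), h - max(0, dy))
        xs = slice(max(0, -dx), w - max(0, dx))
        yd = slice(max(0, dy), h - max(0, -dy))
        xd = slice(max(0, dx), w - max(0, -dx))
        a = q[ys, xs].ravel()
        b = q[yd, xd].ravel()
        m = np.zeros((levels, levels), dtype=float)
        np.add.at(m, (a, b), 1.0)
        if symmetric:
            m = m + m.T
        if normalize:
            total = m.sum()
            if total > 0:
                m = m / total
        mats.append(m)
    return GLCMMatrix(p=np.stack(mats), levels=levels, offsets=offsets,
                      symmetric=symmetric, normalized=normalize)


@dataclass(frozen=True)
class TextureFeatures:
    """The four GLCM statistics (averaged over offsets).

    ``correlation`` is NaN — the flagged undefined value — for a constant
    image, where the marginal standard deviations are zero.
    """

    contrast: float
    homogeneity: float
    correlation: float
    energy: float

    def as_vector(self) -> np.ndarray:
        return np.array([self.contrast, self.homogeneity,
                         self.correlation, self.energy], dtype=float)

    names: tuple[str, ...] = ("glcm_contrast", "glcm_homogeneity",
                              "glcm_correlation", "glcm_energy")


def _texture_single(p: np.ndarray) -> tuple[float, float, float, float]:
    g = p.shape[0]
    i = np.arange(g, dtype=float)[:, None]
    j = np.arange(g, dtype=float)[None, :]
    contrast = float((np.abs(i - j) ** 2 * p).sum())
    homogeneity = float((p / (1.0 + np.abs(i - j))).sum())
    energy = float((p ** 2).sum())
    pi = p.sum(axis=1)
    pj = p.sum(axis=0)
    mu_i = float((np.arange(g) * pi).sum())
    mu_j = float((np.arange(g) * pj).sum())
    var_i = float(((np.arange(g) - mu_i) ** 2 * pi).sum())
    var_j = float(((np.arange(g) - mu_j) ** 2 * pj).sum())
    if var_i <= 0.0 or var_j <= 0.0:
        correlation = float("nan")
    else:
        correlation = float(
            (((i - mu_i) * (j - mu_j) * p).sum()) / np.sqrt(var_i * var_j)
        )
    return contrast, homogeneity, correlation, energy


def texture_features(matrix: GLCMMatrix) -> TextureFeatures:
    """Contrast, homogeneity, correlation and energy of a normalized GLCM.

    contrast    = sum |i-j|^2 p(i,j)
    homogeneity = sum p(i,j) / (1 + |i-j|)
    correlation = sum (i-mu_i)(j-mu_j) p(i,j) / (sigma_i sigma_j)
    energy      = sum p(i,j)^2

    With several offsets each statistic is computed per offset and the
    results averaged.  Correlation is NaN for a constant image.
    """
    if not matrix.normalized:
        raise ValueError("texture_features requires a normalized GLCM")
    stats = np.array([_texture_single(m) for m in matrix.p], dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # mean of all-NaN col
        contrast, homogeneity, correlation, energy = np.nanmean(stats, axis=0)
        if np.isnan(stats[:, 2]).all():
            correlation = float("nan")
    return TextureFeatures(float(contrast), float(homogeneity),
                           float(correlation), float(energy))


@dataclass(frozen=True)
class HuVector:
    """Hu's seven invariant moments h0..h6 of a grayscale image."""

    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.values) != 7:
            raise ValueError("HuVector needs exactly 7 values")

    def as_vector(self) -> np.ndarray:
        return np.array(self.values, dtype=float)

    names: tuple[str, ...] = tuple(f"hu_{k}" for k in range(7))


def _normalized_central_moments(gray: np.ndarray) -> dict[tuple[int, int], float]:
    img = np.asarray(gray, dtype=float)
    if img.ndim != 2:
        raise ValueError("hu_moments expects a 2-D grayscale image")
    m00 = img.sum()
    if m00 == 0.0:
        raise ValueError("zero-mass image: all pixels are zero")
    h, w = img.shape
    y = np.arange(h, dtype=float)[:, None]
    x = np.arange(w, dtype=float)[None, :]
    xbar = (img * x).sum() / m00
    ybar = (img * y).sum() / m00
    dx = x - xbar
    dy = y - ybar
    eta = {}
    for p in range(4):
        for q in range(4):
            if 2 <= p + q <= 3:
                mu = (img * dx ** p * dy ** q).sum()
                eta[(p, q)] = mu / m00 ** (1.0 + (p + q) / 2.0)
    return eta


def hu_moments(gray: np.ndarray, variant: str = "standard") -> HuVector:
    """Hu's seven moment invariants from normalized central moments.

    ``variant="standard"`` computes the classical invariants I1..I7.
    ``variant="verbatim"`` reproduces, for auditability, a circulating
    typographically corrupted transcription in which h2, h4 and h5 differ
    from the classical forms; it is not recommended for analysis.

    Moments are computed on the grayscale intensity surface (not a binary
    mask); no log transform is applied.
    """
    eta = _normalized_central_moments(gray)
    n20, n02, n11 = eta[(2, 0)], eta[(0, 2)], eta[(1, 1)]
    n30, n03, n21, n12 = eta[(3, 0)], eta[(0, 3)], eta[(2, 1)], eta[(1, 2)]
    A = n30 + n12
    B = n21 + n03
    h0 = n20 + n02
    h1 = (n20 - n02) ** 2 + 4 * n11 ** 2
    h3 = A ** 2 + B ** 2
    h6 = (3 * n21 - n03) * A * (A ** 2 - 3 * B ** 2) \
        - (n30 - 3 * n12) * B * (3 * A ** 2 - B ** 2)
    if variant == "standard":
        h2 = (n30 - 3 * n12) ** 2 + (3 * n21 - n03) ** 2
        h4 = (n30 - 3 * n12) * A * (A ** 2 - 3 * B ** 2) \
            + (3 * n21 - n03) * B * (3 * A ** 2 - B ** 2)
        h5 = (n20 - n02) * (A ** 2 - B ** 2) + 4 * n11 * A * B
    elif variant == "verbatim":
        h2 = (n30 - 3 * n12) ** 2 + (3 * n21 - n02) ** 2
        h4 = (n30 - 3 * n12) * A * (A ** 2 - 3 * B ** 2) \
            + (3 * n21 - n03) * (3 * A ** 2 - B ** 2)
        h5 = (n20 - 3 * n03) * (A ** 2 - B ** 2) \
            + 4 * n11 * (n30 + 3 * n12) * B
    else:
        raise ValueError(f"unknown Hu variant {variant!r}")
    return HuVector(tuple(float(v) for v in (h0, h1, h2, h3, h4, h5, h6)))


@dataclass(frozen=True)
class ColorHistogram:
    """Concatenated per-channel HSV histograms, each L1-normalized."""

    values: np.ndarray
    bins_per_channel: int

    @property
    def hue(self) -> np.ndarray:
        return self.values[: self.bins_per_channel]

    @property
    def saturation(self) -> np.ndarray:
        return self.values[self.bins_per_channel: 2 * self.bins_per_channel]

    @property
    def value(self) -> np.ndarray:
        return self.values[2 * self.bins_per_channel:]

    @property
    def names(self) -> tuple[str, ...]:
        b = self.bins_per_channel
        return tuple(f"hsv_{c}_{k:02d}" for c in "hsv" for k in range(b))

    def as_vector(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


def hsv_histogram(image: np.ndarray, bins_per_channel: int = 16) -> ColorHistogram:
    """Per-channel HSV histograms of an RGB image.

    H, S, V are each on [0, 1]; each channel is binned into
    ``bins_per_channel`` equal bins (values of exactly 1.0 fall in the top
    bin) and L1-normalized, then concatenated H ++ S ++ V.
    """
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("hsv_histogram expects a 3-channel RGB image")
    if bins_per_channel < 2:
        raise ValueError("bins_per_channel must be >= 2")
    hsv = rgb2hsv(img)
    b = bins_per_channel
    parts = []
    for c in range(3):
        chan = hsv[..., c].ravel()
        idx = np.clip((chan * b).astype(int), 0, b - 1)
        hist = np.bincount(idx, minlength=b).astype(float)
        parts.append(hist / hist.sum())
    return ColorHistogram(values=np.concatenate(parts), bins_per_channel=b)


_BLOCK_ORDER = ("T", "C", "S")


@dataclass(frozen=True)
class FusedFeatureVector:
    """FS concatenated with the requested descriptor blocks, order FS,T,C,S."""

    names: tuple[str, ...]
    values: np.ndarray
    blocks: tuple[str, ...]

    def as_vector(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return len(self.names)


def fuse(
    fs: RatioFeatureVector,
    texture: TextureFeatures | None = None,
    color: ColorHistogram | None = None,
    shape: HuVector | None = None,
    blocks: Iterable[str] = ("T", "C", "S"),
) -> FusedFeatureVector:
    """Concatenate the FS with descriptor blocks in the fixed order FS,T,C,S.

    ``blocks`` selects which of texture (T), color (C) and shape (S) to
    append; each requested block must be provided.  A NaN texture
    correlation (constant image) is mapped to 0 with a warning so batch
    extraction never aborts.
    """
    requested = tuple(blocks)
    unknown = set(requested) - set(_BLOCK_ORDER)
    if unknown:
        raise ValueError(f"unknown descriptor block(s): {sorted(unknown)}")
    provided = {"T": texture, "C": color, "S": shape}
    names: list[str] = list(fs.names)
    values: list[float] = list(fs.as_vector())
    for label in _BLOCK_ORDER:
        if label not in requested:
            continue
        obj = provided[label]
        if obj is None:
            raise ValueError(f"block {label!r} requested but not provided")
        vec = obj.as_vector()
        if label == "T" and np.isnan(vec).any():
            warnings.warn("undefined GLCM correlation mapped to 0 in fusion")
            vec = np.nan_to_num(vec, nan=0.0)
        names.extend(obj.names)
        values.extend(vec)
    return FusedFeatureVector(names=tuple(names),
                              values=np.array(values, dtype=float),
                              blocks=requested)
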