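"""Second feature extraction: the 70-feature texture battery per image.

Each 8-bit grayscale image (the B-mode ROI or a rendered parametric map)
yields 70 texture features: 16 first-order histogram statistics, 23
gray-level co-occurrence (GLCM), 13 run-length (GLRLM), 13 size-zone
(GLSZM) and 5 neighbourhood gray-tone difference (NGTDM) features.  A
one-level 2-D Haar wavelet decomposition produces four sub-band images
(LL, LH, HL, HH), each re-extracted for 280 further features, giving 350
per image.  Model vectors concatenate per-image blocks: GM (grayscale
image only) and DM (DEA map) are 350 long, DOM (DEA+OND) 700, DOSM
(DEA+OND+SDSD) 1050.

Matrix-based families quantise to 32 gray levels by default (equal-width
bins over [0, 255]).  GLCM and GLRLM matrices are symmetric/normalised and
averaged over the four in-plane directions at distance 1 before feature
computation; GLSZM zones are 8-connected; NGTDM uses a 3x3 neighbourhood
with masked-neighbour averaging.  Feature order is frozen; names have the
form ``<band>__<family>__<feature>`` (plus a ``<map>__`` prefix in model
vectors) and downstream code refers to names, never positions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

__all__ = [
    "FeatureVector",
    "quantize",
    "histogram_features",
    "glcm_matrix",
    "glcm_features",
    "glrlm_matrix",
    "glrlm_features",
    "glszm_matrix",
    "glszm_features",
    "ngtdm_features",
    "wavelet_subbands",
    "downsample_mask",
    "extract_70",
    "extract_350",
    "assemble_model_vector",
    "feature_names_70",
    "feature_names_350",
    "HIST_FEATURES",
    "GLCM_FEATURES",
    "GLRLM_FEATURES",
    "GLSZM_FEATURES",
    "NGTDM_FEATURES",
    "BANDS",
    "MODEL_MAPS",
    "MODEL_LENGTHS",
    "COARSENESS_CAP",
]

HIST_FEATURES = [
    "mean", "variance", "std", "skewness", "kurtosis", "energy", "entropy",
    "min", "max", "range", "median", "p10", "p90", "iqr", "mean_abs_dev",
    "uniformity",
]
GLCM_FEATURES = [
    "autocorrelation", "cluster_prominence", "cluster_shade",
    "cluster_tendency", "contrast", "correlation", "difference_average",
    "difference_entropy", "difference_variance", "dissimilarity", "energy",
    "entropy", "homogeneity", "inverse_difference_moment", "imc1", "imc2",
    "inverse_variance", "joint_average", "maximum_probability",
    "sum_average", "sum_entropy", "sum_variance", "variance",
]
GLRLM_FEATURES = [
    "short_run_emphasis", "long_run_emphasis", "gray_level_nonuniformity",
    "run_length_nonuniformity", "run_percentage", "low_gray_run_emphasis",
    "high_gray_run_emphasis", "short_run_low_gray_emphasis",
    "short_run_high_gray_emphasis", "long_run_low_gray_emphasis",
    "long_run_high_gray_emphasis", "gray_level_variance",
    "run_length_variance",
]
GLSZM_FEATURES = [
    "small_zone_emphasis", "large_zone_emphasis", "gray_level_nonuniformity",
    "zone_size_nonuniformity", "zone_percentage", "low_gray_zone_emphasis",
    "high_gray_zone_emphasis", "small_zone_low_gray_emphasis",
    "small_zone_high_gray_emphasis", "large_zone_low_gray_emphasis",
    "large_zone_high_gray_emphasis", "gray_level_variance",
    "zone_size_variance",
]
NGTDM_FEATURES = ["coarseness", "contrast", "busyness", "complexity", "strength"]

BANDS = ["orig", "LL", "LH", "HL", "HH"]
MODEL_MAPS = {
    "GM": ("gray",),
    "DM": ("dea",),
    "DOM": ("dea", "ond"),
    "DOSM": ("dea", "ond", "sdsd"),
}
MODEL_LENGTHS = {"GM": 350, "DM": 350, "DOM": 700, "DOSM": 1050}

#: 1/0 guard for NGTDM coarseness on a perfectly flat region.
COARSENESS_CAP = 1.0e6

_DIRECTIONS = ((0, 1), (1, 1), (1, 0), (1, -1))  # 0, 135, 90, 45 degrees


@dataclass
class FeatureVector:
    """Ordered, named radiomics feature vector."""

    values: np.ndarray
    names: List[str]
    layout: Optional[str] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.names) != self.values.size:
            raise ValueError("values and names must align 1:1")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")
        if self.layout is not None:
            expected = MODEL_LENGTHS.get(self.layout)
            if expected is not None and self.values.size != expected:
                raise ValueError(
                    f"layout {self.layout} requires {expected} features, "
                    f"got {self.values.size}"
                )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")

    def as_dict(self) -> Dict[str, float]:
        return dict(zip(self.names, self.values))


def quantize(image: np.ndarray, levels: int = 32) -> np.ndarray:
    """Equal-width quantisation of an 8-bit image into levels in [1, levels]."""
    if levels < 2:
        raise ValueError("levels must be >= 2")
    img = np.asarray(image)
    if np.any(img < 0) or np.any(img > 255):
        raise ValueError("expected 8-bit intensities in [0, 255]")
    return (img.astype(np.int64) * levels) // 256 + 1


def histogram_features(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """16 first-order statistics on the masked intensities (fixed order)."""
    img = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    x = img[mask]
    n = x.size
    mean = x.mean()
    var = x.var()
    sd = np.sqrt(var)
    if var > 0:
        skew = np.mean((x - mean) ** 3) / sd**3
        kurt = np.mean((x - mean) ** 4) / var**2 - 3.0
    else:
        skew = 0.0
        kurt = 0.0
    energy = float(np.sum(x**2))
    counts = np.bincount(x.astype(np.int64), minlength=256)
    p = counts[counts > 0] / n
    entropy = float(-np.sum(p * np.log2(p)))
    uniformity = float(np.sum(p**2))
    p10, p25, med, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    return np.array([
        mean, var, sd, skew, kurt, energy, entropy,
        x.min(), x.max(), x.max() - x.min(), med, p10, p90, p75 - p25,
        np.mean(np.abs(x - mean)), uniformity,
    ])


# ---------------------------------------------------------------------------
# GLCM


def glcm_matrix(
    quantized: np.ndarray,
    mask: np.ndarray,
    levels: int,
    direction: Tuple[int, int],
) -> np.ndarray:
    """Symmetric normalised co-occurrence matrix for one direction, distance 1.

    Only pixel pairs with both members inside the mask are counted.  Returns
    a (levels, levels) matrix summing to 1 (all-zero if the mask admits no
    pair in this direction).
    """
    q = np.asarray(quantized, dtype=np.int64)
    mask = np.asarray(mask, dtype=bool)
    dr, dc = direction
    h, w = q.shape
    a_r = slice(max(0, -dr), h - max(0, dr))
    a_c = slice(max(0, -dc), w - max(0, dc))
    b_r = slice(max(0, dr), h - max(0, -dr))
    b_c = slice(max(0, dc), w - max(0, -dc))
    va, vb = q[a_r, a_c], q[b_r, b_c]
    valid = mask[a_r, a_c] & mask[b_r, b_c]
    i, j = va[valid] - 1, vb[valid] - 1
    counts = np.bincount(i * levels + j, minlength=levels * levels).reshape(
        levels, levels
    ).astype(float)
    counts = counts + counts.T  # symmetric
    total = counts.sum()
    return counts / total if total > 0 else counts


def _glcm_feature_values(P: np.ndarray) -> np.ndarray:
    Ng = P.shape[0]
    i = np.arange(1, Ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    mu_x = float(np.sum(i * px))
    sigma_x = float(np.sqrt(np.sum((i - mu_x) ** 2 * px)))

    # p_{x+y}, p_{x-y}
    ks_sum = np.arange(2, 2 * Ng + 1)
    p_sum = np.array([P[ii + jj == k].sum() for k in ks_sum])
    ks_diff = np.arange(0, Ng)
    p_diff = np.array([P[np.abs(ii - jj) == k].sum() for k in ks_diff])

    def ent(p: np.ndarray) -> float:
        p = p[p > 0]
        return float(-np.sum(p * np.log2(p))) if p.size else 0.0

    autocorrelation = float(np.sum(ii * jj * P))
    dev = ii + jj - 2.0 * mu_x
    cluster_prominence = float(np.sum(dev**4 * P))
    cluster_shade = float(np.sum(dev**3 * P))
    cluster_tendency = float(np.sum(dev**2 * P))
    contrast = float(np.sum((ii - jj) ** 2 * P))
    if sigma_x > 0:
        correlation = (autocorrelation - mu_x * mu_x) / (sigma_x * sigma_x)
    else:
        correlation = 1.0  # degenerate single-level convention
    difference_average = float(np.sum(ks_diff * p_diff))
    difference_entropy = ent(p_diff)
    difference_variance = float(np.sum((ks_diff - difference_average) ** 2 * p_diff))
    dissimilarity = float(np.sum(np.abs(ii - jj) * P))
    energy = float(np.sum(P**2))
    entropy = ent(P.ravel())
    homogeneity = float(np.sum(P / (1.0 + np.abs(ii - jj))))
    idm = float(np.sum(P / (1.0 + (ii - jj) ** 2)))

    hx = ent(px)
    pxy = np.outer(px, px)
    nz = P > 0
    hxy1 = float(-np.sum(P[nz & (pxy > 0)] * np.log2(pxy[nz & (pxy > 0)])))
    hxy2 = ent(pxy.ravel())
    imc1 = (entropy - hxy1) / hx if hx > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - entropy)))))

    off = ii != jj
    inverse_variance = float(np.sum(P[off] / (ii[off] - jj[off]) ** 2))
    joint_average = mu_x
    maximum_probability = float(P.max())
    sum_average = float(np.sum(ks_sum * p_sum))
    sum_entropy = ent(p_sum)
    sum_variance = float(np.sum((ks_sum - sum_average) ** 2 * p_sum))
    variance = float(np.sum((ii - mu_x) ** 2 * P))

    return np.array([
        autocorrelation, cluster_prominence, cluster_shade, cluster_tendency,
        contrast, correlation, difference_average, difference_entropy,
        difference_variance, dissimilarity, energy, entropy, homogeneity,
        idm, imc1, imc2, inverse_variance, joint_average,
        maximum_probability, sum_average, sum_entropy, sum_variance, variance,
    ])


def glcm_features(
    quantized: np.ndarray, mask: np.ndarray, levels: int = 32
) -> np.ndarray:
    """23 co-occurrence features from the direction-averaged GLCM."""
    mats = [glcm_matrix(quantized, mask, levels, d) for d in _DIRECTIONS]
    P = np.mean(mats, axis=0)
    if P.sum() == 0:  # no valid pair anywhere: point mass at the modal level
        q = np.asarray(quantized)[np.asarray(mask, dtype=bool)]
        lvl = int(np.bincount(q).argmax()) - 1
        P = np.zeros((levels, levels))
        P[lvl, lvl] = 1.0
    return _glcm_feature_values(P)


# ---------------------------------------------------------------------------
# GLRLM


def _runs(values: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Run values and lengths of a 1-D array; zeros are separators."""
    a = values
    boundaries = np.flatnonzero(a[1:] != a[:-1]) + 1
    starts = np.concatenate(([0], boundaries))
    lengths = np.diff(np.concatenate((starts, [a.size])))
    vals = a[starts]
    keep = vals > 0
    return vals[keep], lengths[keep]


def _lines_for_direction(masked_q: np.ndarray, direction: Tuple[int, int]) -> np.ndarray:
    """Rearrange the image so runs along `direction` become horizontal lines.

    masked_q has 0 at out-of-mask pixels (run separators).  Diagonal
    directions are handled by skewing each row so diagonals align into
    columns of a padded matrix.
    """
    h, w = masked_q.shape
    if direction == (0, 1):
        return masked_q
    if direction == (1, 0):
        return masked_q.T
    skew = np.zeros((h, w + h), dtype=masked_q.dtype)
    rows = np.arange(h)
    if direction == (1, 1):
        for r in rows:  # element (r, c) -> column c + (h - 1 - r)
            skew[r, h - 1 - r : h - 1 - r + w] = masked_q[r]
    else:  # (1, -1)
        for r in rows:  # element (r, c) -> column c + r
            skew[r, r : r + w] = masked_q[r]
    return skew.T


def glrlm_matrix(
    quantized: np.ndarray,
    mask: np.ndarray,
    levels: int,
    direction: Tuple[int, int],
    max_len: Optional[int] = None,
) -> np.ndarray:
    """Run-length matrix R[level-1, length-1] for one direction."""
    q = np.asarray(quantized, dtype=np.int64)
    mask = np.asarray(mask, dtype=bool)
    h, w = q.shape
    if max_len is None:
        max_len = max(h, w)
    lines = _lines_for_direction(q * mask, direction)
    # separator column between lines so runs never wrap
    padded = np.hstack([lines, np.zeros((lines.shape[0], 1), dtype=lines.dtype)])
    vals, lens = _runs(padded.ravel())
    R = np.zeros((levels, max_len))
    np.add.at(R, (vals - 1, np.minimum(lens, max_len) - 1), 1.0)
    return R


def _rlm_style_features(
    M: np.ndarray, n_pixels: int, names_check: Sequence[str]
) -> np.ndarray:
    """The 13-feature family shared by GLRLM (runs) and GLSZM (zones)."""
    levels, max_len = M.shape
    i = np.arange(1, levels + 1)[:, None].astype(float)
    l = np.arange(1, max_len + 1)[None, :].astype(float)
    N = M.sum()
    p = M / N
    sre = float(np.sum(M / l**2) / N)
    lre = float(np.sum(M * l**2) / N)
    gln = float(np.sum(M.sum(axis=1) ** 2) / N)
    rln = float(np.sum(M.sum(axis=0) ** 2) / N)
    rp = float(N / n_pixels)
    lgre = float(np.sum(M / i**2) / N)
    hgre = float(np.sum(M * i**2) / N)
    srlge = float(np.sum(M / (i**2 * l**2)) / N)
    srhge = float(np.sum(M * i**2 / l**2) / N)
    lrlge = float(np.sum(M * l**2 / i**2) / N)
    lrhge = float(np.sum(M * i**2 * l**2) / N)
    mu_i = float(np.sum(p * i))
    glv = float(np.sum(p * (i - mu_i) ** 2))
    mu_l = float(np.sum(p * l))
    rlv = float(np.sum(p * (l - mu_l) ** 2))
    assert len(names_check) == 13
    return np.array([
        sre, lre, gln, rln, rp, lgre, hgre, srlge, srhge, lrlge, lrhge,
        glv, rlv,
    ])


def glrlm_features(
    quantized: np.ndarray, mask: np.ndarray, levels: int = 32
) -> np.ndarray:
    """13 run-length features from the direction-averaged GLRLM."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    h, w = np.asarray(quantized).shape
    max_len = max(h, w)
    mats = [
        glrlm_matrix(quantized, mask, levels, d, max_len) for d in _DIRECTIONS
    ]
    R = np.mean(mats, axis=0)
    return _rlm_style_features(R, int(mask.sum()), GLRLM_FEATURES)


# ---------------------------------------------------------------------------
# GLSZM


def glszm_matrix(
    quantized: np.ndarray, mask: np.ndarray, levels: int
) -> np.ndarray:
    """Size-zone matrix S[level-1, size-1]; zones are 8-connected."""
    q = np.asarray(quantized, dtype=np.int64)
    mask = np.asarray(mask, dtype=bool)
    n_pixels = int(mask.sum())
    S = np.zeros((levels, n_pixels))
    structure = np.ones((3, 3), dtype=bool)
    for lvl in np.unique(q[mask]):
        labelled, n_zones = ndimage.label(mask & (q == lvl), structure=structure)
        if n_zones == 0:
            continue
        sizes = np.bincount(labelled.ravel())[1:]
        np.add.at(S, (lvl - 1, sizes - 1), 1.0)
    return S


def glszm_features(
    quantized: np.ndarray, mask: np.ndarray, levels: int = 32
) -> np.ndarray:
    """13 size-zone features (8-connected zones)."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    S = glszm_matrix(quantized, mask, levels)
    return _rlm_style_features(S, int(mask.sum()), GLSZM_FEATURES)


# ---------------------------------------------------------------------------
# NGTDM


def ngtdm_features(
    quantized: np.ndarray, mask: np.ndarray, levels: int = 32
) -> np.ndarray:
    """Amadasun-King NGTDM features; 3x3 neighbourhood, masked-neighbour mean.

    A pixel contributes if it is inside the mask and has at least one
    in-mask neighbour.  Coarseness is capped at COARSENESS_CAP on perfectly
    flat regions.
    """
    q = np.asarray(quantized, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    kernel = np.ones((3, 3))
    kernel[1, 1] = 0.0
    nb_sum = ndimage.convolve(q * mask, kernel, mode="constant", cval=0.0)
    nb_cnt = ndimage.convolve(mask.astype(float), kernel, mode="constant", cval=0.0)
    valid = mask & (nb_cnt > 0)
    if not valid.any():
        raise ValueError("mask admits no pixel with an in-mask neighbour")
    a_bar = np.zeros_like(q)
    a_bar[valid] = nb_sum[valid] / nb_cnt[valid]

    lv = q[valid].astype(np.int64)
    diff = np.abs(q[valid] - a_bar[valid])
    N = lv.size
    n_i = np.bincount(lv, minlength=levels + 1)[1:].astype(float)
    s_i = np.bincount(lv, weights=diff, minlength=levels + 1)[1:]
    p_i = n_i / N

    present = p_i > 0
    i_vals = np.arange(1, levels + 1, dtype=float)
    ngp = int(present.sum())

    denom = float(np.sum(p_i * s_i))
    coarseness = min(COARSENESS_CAP, 1.0 / denom) if denom > 0 else COARSENESS_CAP

    if ngp > 1:
        pi_p, si_p, iv = p_i[present], s_i[present], i_vals[present]
        di = iv[:, None] - iv[None, :]
        pp = pi_p[:, None] * pi_p[None, :]
        contrast = float(np.sum(pp * di**2) / (ngp * (ngp - 1)) * np.sum(s_i) / N)
        ipi = iv * pi_p
        busy_den = float(np.sum(np.abs(ipi[:, None] - ipi[None, :])))
        busyness = float(np.sum(pi_p * si_p) / busy_den) if busy_den > 0 else 0.0
        complexity = float(
            np.sum(
                np.abs(di)
                * (pi_p[:, None] * si_p[:, None] + pi_p[None, :] * si_p[None, :])
                / (pi_p[:, None] + pi_p[None, :])
            )
            / N
        )
        s_sum = float(np.sum(s_i))
        strength = (
            float(np.sum((pi_p[:, None] + pi_p[None, :]) * di**2) / s_sum)
            if s_sum > 0
            else 0.0
        )
    else:
        contrast = busyness = complexity = strength = 0.0

    return np.array([coarseness, contrast, busyness, complexity, strength])


# ---------------------------------------------------------------------------
# Wavelet sub-bands


def _pad_to_even(a: np.ndarray) -> np.ndarray:
    pr = a.shape[0] % 2
    pc = a.shape[1] % 2
    if pr or pc:
        a = np.pad(a, ((0, pr), (0, pc)), mode="edge")
    return a


def wavelet_subbands(
    image: np.ndarray,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """One-level orthonormal 2-D Haar transform: (LL, LH, HL, HH).

    Raw coefficient sub-bands are returned (a constant image c gives
    LL = 2c, zero details).  Odd dimensions are edge-replicated to even, so
    each sub-band has shape ceil(input/2) per axis.  LH carries lateral
    (column) detail, HL axial (row) detail.
    """
    a = np.asarray(image, dtype=float)
    if a.ndim != 2 or a.shape[0] < 2 or a.shape[1] < 2:
        raise ValueError("image must be at least 2x2")
    a = _pad_to_even(a)
    a00 = a[0::2, 0::2]
    a01 = a[0::2, 1::2]
    a10 = a[1::2, 0::2]
    a11 = a[1::2, 1::2]
    ll = (a00 + a01 + a10 + a11) / 2.0
    lh = (a00 - a01 + a10 - a11) / 2.0
    hl = (a00 + a01 - a10 - a11) / 2.0
    hh = (a00 - a01 - a10 + a11) / 2.0
    return ll, lh, hl, hh


def downsample_mask(mask: np.ndarray) -> np.ndarray:
    """2x2 majority downsampling of a mask to the sub-band grid; ties inside."""
    m = np.asarray(mask, dtype=bool)
    m = _pad_to_even(m)
    s = (
        m[0::2, 0::2].astype(int) + m[0::2, 1::2] + m[1::2, 0::2] + m[1::2, 1::2]
    )
    return s >= 2


def _rescale_8bit(a: np.ndarray) -> np.ndarray:
    lo, hi = a.min(), a.max()
    if hi == lo:
        return np.full(a.shape, 128, dtype=np.uint8)
    return np.floor(255.0 * (a - lo) / (hi - lo) + 0.5).astype(np.uint8)


# ---------------------------------------------------------------------------
# Assembly


def feature_names_70() -> List[str]:
    names = [f"hist__{n}" for n in HIST_FEATURES]
    names += [f"glcm__{n}" for n in GLCM_FEATURES]
    names += [f"glrlm__{n}" for n in GLRLM_FEATURES]
    names += [f"glszm__{n}" for n in GLSZM_FEATURES]
    names += [f"ngtdm__{n}" for n in NGTDM_FEATURES]
    return names


def feature_names_350() -> List[str]:
    return [f"{band}__{n}" for band in BANDS for n in feature_names_70()]


def extract_70(
    image: np.ndarray, mask: np.ndarray, levels: int = 32
) -> np.ndarray:
    """The 70-feature battery on one 8-bit image (16+23+13+13+5)."""
    mask = np.asarray(mask, dtype=bool)
    q = quantize(image, levels)
    return np.concatenate([
        histogram_features(image, mask),
        glcm_features(q, mask, levels),
        glrlm_features(q, mask, levels),
        glszm_features(q, mask, levels),
        ngtdm_features(q, mask, levels),
    ])


def extract_350(
    image: np.ndarray, mask: Optional[np.ndarray] = None, levels: int = 32
) -> FeatureVector:
    """70 features on the original image + 70 on each Haar sub-band = 350.

    Sub-band coefficient images are min-max rescaled to 8-bit before
    texture extraction; the mask is downsampled by 2x2 majority.
    """
    img = np.asarray(image)
    if mask is None:
        mask = np.ones(img.shape, dtype=bool)
    blocks = [extract_70(img, mask, levels)]
    sub_mask = downsample_mask(mask)
    for band in wavelet_subbands(img.astype(float)):
        blocks.append(extract_70(_rescale_8bit(band), sub_mask, levels))
    return FeatureVector(values=np.concatenate(blocks), names=feature_names_350())


def assemble_model_vector(
    per_map: Dict[str, FeatureVector], model: str
) -> FeatureVector:
    """Concatenate per-map 350-blocks into a GM/DM/DOM/DOSM model vector.

    per_map keys are map identifiers ("gray", "dea", "ond", "sdsd"); the
    concatenation order is fixed (DEA, OND, SDSD; GM uses the grayscale
    image alone).
    """
    if model not in MODEL_MAPS:
        raise ValueError(f"unknown model {model!r}")
    values, names = [], []
    for map_name in MODEL_MAPS[model]:
        if map_name not in per_map:
            raise ValueError(f"model {model} requires map {map_name!r}")
        fv = per_map[map_name]
        if fv.values.size != 350:
            raise ValueError("per-map blocks must be 350 features long")
        values.append(fv.values)
        names.extend(f"{map_name}__{n}" for n in fv.names)
    return FeatureVector(values=np.concatenate(values), names=names, layout=model)
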