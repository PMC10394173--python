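"""CT radiomics: resampling, 25-HU quantization, 3D GLCM texture, wavelets.

The extraction pipeline mirrors the common CT texture-analysis recipe:
volumes are resampled to 1 x 1 x 3 mm, gray levels are quantized into fixed
25-HU bins anchored at the in-mask minimum (hence the ``25HUgl`` suffix on
every intensity feature name), and gray-level co-occurrence matrices are
accumulated over the 13 unique 3D direction offsets at distance 1 and
symmetrized before normalization.  A single-level undecimated separable 3D
wavelet transform (Coiflet-1 by default) produces 8 same-shape subbands
named LLL..HHH (letter = filter applied along x, y, z), so the original
mask applies to each subband unchanged.

Feature names follow ``<family>_<feature>[_<subband>]_25HUgl``; the three
features used by the published ovarian radiomic TLS model
(GLCM_Entrop_25HUgl, GLCM_InfCo1_HHL_25HUgl, GLCM_sumEnt_HLL_25HUgl) are
always present in the output vector.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
import pywt
from scipy import ndimage, stats
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist
from skimage import measure

from .synthetic import MaskedVolume

__all__ = [
    "RadiomicsConfig",
    "GLCM",
    "resample",
    "quantize",
    "glcm_compute",
    "glcm_features",
    "wavelet_subbands",
    "basic_features",
    "extract_feature_vector",
    "DIRECTIONS_3D",
]

# The 13 unique 3D neighbor offsets (first non-zero component positive).
DIRECTIONS_3D: tuple[tuple[int, int, int], ...] = tuple(
    d for d in product((0, 1, -1), repeat=3)
    if next((c for c in d if c != 0), 0) == 1
)
assert len(DIRECTIONS_3D) == 13


@dataclass
class RadiomicsConfig:
    bin_width: float = 25.0                       # HU per gray level
    target_spacing: tuple[float, float, float] = (1.0, 1.0, 3.0)
    wavelet: str = "coif1"
    distance: int = 1
    direction_aggregation: str = "sum"            # "sum" or "average"
    resample_first: bool = True


@dataclass
class GLCM:
    """Normalized gray-level co-occurrence probabilities."""

    P: np.ndarray
    n_levels: int
    distance: int = 1
    symmetric: bool = True

    def __post_init__(self):
        if self.P.shape != (self.n_levels, self.n_levels):
            raise ValueError("GLCM shape does not match n_levels")
        total = self.P.sum()
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"GLCM must sum to 1, got {total}")
        if np.any(self.P < 0):
            raise ValueError("GLCM probabilities must be non-negative")


def resample(
    vol: MaskedVolume, target_spacing: tuple[float, float, float] = (1.0, 1.0, 3.0)
) -> MaskedVolume:
    """Resample to the target spacing (trilinear image, nearest mask).

    The new dimension along each axis is round(dim * spacing / target), so
    the physical extent is preserved to within one voxel.
    """
    target = np.asarray(target_spacing, dtype=float)
    if np.any(target <= 0):
        raise ValueError("target spacing must be positive")
    old = np.asarray(vol.spacing, dtype=float)
    if np.allclose(old, target):
        return MaskedVolume(vol.intensities.copy(), vol.mask.copy(), tuple(target))
    zoom = old / target
    img = ndimage.zoom(vol.intensities, zoom, order=1, mode="nearest")
    mask = ndimage.zoom(vol.mask.astype(np.uint8), zoom, order=0, mode="nearest") > 0
    if not mask.any():
        raise ValueError("mask became empty after resampling")
    return MaskedVolume(img, mask, tuple(target))


def quantize(
    intensities: np.ndarray, mask: np.ndarray, bin_width: float = 25.0
) -> tuple[np.ndarray, int]:
    """Fixed-bin-width gray-level quantization anchored at the in-mask min.

    level(v) = floor((v - min_in_mask) / bin_width) + 1, so levels run
    1..Ng inside the mask (0 outside).  Anchoring at the minimum makes the
    level map invariant to global HU shifts.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    inside = np.asarray(intensities, dtype=float)[mask]
    levels = np.zeros(np.shape(intensities), dtype=np.int64)
    lv = np.floor((inside - inside.min()) / bin_width).astype(np.int64) + 1
    levels[mask] = lv
    return levels, int(lv.max())


def _glcm_counts(levels, mask, offset, n_levels):
    """Raw (unsymmetrized) co-occurrence counts for one voxel offset."""
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    for ax, d in enumerate(offset):
        if d > 0:
            src[ax], dst[ax] = slice(0, -d), slice(d, None)
        elif d < 0:
            src[ax], dst[ax] = slice(-d, None), slice(0, d)
    a = levels[tuple(src)]
    b = levels[tuple(dst)]
    valid = mask[tuple(src)] & mask[tuple(dst)]
    a, b = a[valid] - 1, b[valid] - 1
    counts = np.bincount(a * n_levels + b, minlength=n_levels * n_levels)
    return counts.reshape(n_levels, n_levels).astype(float)


def glcm_compute(
    levels: np.ndarray,
    mask: np.ndarray,
    n_levels: int | None = None,
    distance: int = 1,
    directions=DIRECTIONS_3D,
    symmetric: bool = True,
) -> GLCM:
    """Accumulate the GLCM over all in-mask voxel pairs and directions.

    Counts are summed over directions, symmetrized (each pair counted in
    both orders), and normalized to sum to 1.
    """
    mask = np.asarray(mask, dtype=bool)
    if n_levels is None:
        n_levels = int(levels[mask].max()) if mask.any() else 0
    if n_levels < 1:
        raise ValueError("need at least one gray level")
    total = np.zeros((n_levels, n_levels))
    for d in directions:
        off = tuple(int(c) * distance for c in d)
        total += _glcm_counts(levels, mask, off, n_levels)
    if symmetric:
        total = total + total.T
    s = total.sum()
    if s == 0:
        raise ValueError("no valid voxel pairs (mask too small for the offsets)")
    return GLCM(P=total / s, n_levels=n_levels, distance=distance, symmetric=symmetric)


def _xlog2x(p):
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


def glcm_features(glcm: GLCM) -> dict[str, float]:
    """Haralick texture features of one GLCM (entropies in bits).

    Includes the three features of the published radiomic TLS model:
    Entrop (joint entropy), sumEnt (sum entropy), InfCo1 (information
    measure of correlation 1, defined 0 when max(HX, HY) = 0).
    """
    P = glcm.P
    ng = glcm.n_levels
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    py = P.sum(axis=0)

    # p_{x+y}(k), k = 2..2Ng and p_{x-y}(k), k = 0..Ng-1
    psum = np.zeros(2 * ng + 1)
    np.add.at(psum, (ii + jj).ravel(), P.ravel())
    pdiff = np.zeros(ng)
    np.add.at(pdiff, np.abs(ii - jj).ravel(), P.ravel())

    hxy = -_xlog2x(P).sum()
    hx = -_xlog2x(px).sum()
    hy = -_xlog2x(py).sum()
    pxpy = np.outer(px, py)
    with np.errstate(divide="ignore"):
        log_pxpy = np.where(pxpy > 0, np.log2(np.where(pxpy > 0, pxpy, 1.0)), 0.0)
    hxy1 = -(P * log_pxpy).sum()
    hxy2 = -(pxpy * log_pxpy).sum()

    denom = max(hx, hy)
    infco1 = (hxy - hxy1) / denom if denom > 0 else 0.0
    arg = 1.0 - np.exp(-2.0 * max(hxy2 - hxy, 0.0) * np.log(2.0))
    infco2 = float(np.sqrt(max(arg, 0.0)))

    mu_x = (i * px).sum()
    mu_y = (i * py).sum()
    sd_x = np.sqrt(((i - mu_x) ** 2 * px).sum())
    sd_y = np.sqrt(((i - mu_y) ** 2 * py).sum())
    corr = (
        (((ii - mu_x) * (jj - mu_y) * P).sum() / (sd_x * sd_y))
        if sd_x > 0 and sd_y > 0
        else 0.0
    )

    k_sum = np.arange(2 * ng + 1)
    sum_avg = (k_sum * psum).sum()
    k_diff = np.arange(ng)

    return {
        "Entrop": float(hxy),
        "sumEnt": float(-_xlog2x(psum).sum()),
        "InfCo1": float(infco1),
        "InfCo2": infco2,
        "Energ": float((P**2).sum()),
        "MaxProb": float(P.max()),
        "Contrast": float(((ii - jj) ** 2 * P).sum()),
        "Dissim": float((np.abs(ii - jj) * P).sum()),
        "Homog": float((P / (1.0 + (ii - jj) ** 2)).sum()),
        "Corr": float(corr),
        "Var": float(((ii - mu_x) ** 2 * P).sum()),
        "SumAvg": float(sum_avg),
        "SumVar": float(((k_sum - sum_avg) ** 2 * psum).sum()),
        "DiffEnt": float(-_xlog2x(pdiff).sum()),
        "DiffVar": float(
            ((k_diff - (k_diff * pdiff).sum()) ** 2 * pdiff).sum()
        ),
        "AutoCorr": float((ii * jj * P).sum()),
    }


_SUBBAND_NAMES = ["".join(s) for s in product("LH", repeat=3)]  # LLL..HHH


def wavelet_subbands(
    intensities: np.ndarray, wavelet: str = "coif1"
) -> dict[str, np.ndarray]:
    """Single-level undecimated separable 3D wavelet decomposition.

    Returns 8 same-shape subbands keyed LLL..HHH, letter order = filter
    applied along the x, y, z array axes (L = low-pass, H = high-pass).
    Subbands keep the input shape, so the original mask applies unchanged.
    Dimensions shorter than the filter are rejected; odd dimensions are
    symmetrically padded to even and cropped back.
    """
    data = np.asarray(intensities, dtype=float)
    w = pywt.Wavelet(wavelet)
    if any(d < w.dec_len for d in data.shape):
        raise ValueError(
            f"every dimension must be >= the filter length {w.dec_len}"
        )
    pad = [(0, d % 2) for d in data.shape]
    padded = np.pad(data, pad, mode="symmetric") if any(p[1] for p in pad) else data
    coeffs = pywt.swtn(padded, w, level=1)[0]
    crop = tuple(slice(0, d) for d in data.shape)
    out = {}
    for key, arr in coeffs.items():
        name = key.replace("a", "L").replace("d", "H")
        out[name] = arr[crop]
    assert sorted(out) == sorted(_SUBBAND_NAMES)
    return out


def basic_features(vol: MaskedVolume, bin_width: float = 25.0) -> dict[str, float]:
    """First-order intensity statistics and mask shape features.

    First-order features are computed over in-mask intensities (histogram
    entropy on the fixed-width gray levels); shape features come from the
    mask geometry with voxel spacing applied.  A single-voxel mask yields
    NaN shape features with a warning.
    """
    vals = vol.intensities[vol.mask]
    n = vals.size
    levels, ng = quantize(vol.intensities, vol.mask, bin_width)
    hist = np.bincount(levels[vol.mask])[1:]
    p = hist / hist.sum()
    feats = {
        "mean": float(vals.mean()),
        "sd": float(vals.std()),
        "skew": float(stats.skew(vals)) if vals.std() > 0 else 0.0,
        "kurt": float(stats.kurtosis(vals)) if vals.std() > 0 else 0.0,
        "energy": float((vals**2).sum()),
        "entropy": float(-_xlog2x(p).sum()),
    }

    spacing = np.asarray(vol.spacing)
    voxel_vol = float(np.prod(spacing))
    shape_feats = {
        "volume_mm3": n * voxel_vol,
        "surface_mm2": np.nan,
        "sphericity": np.nan,
        "max_diameter_mm": np.nan,
    }
    if n < 2:
        warnings.warn("single-voxel mask: shape features degenerate")
    else:
        padded = np.pad(vol.mask, 1).astype(float)
        try:
            verts, faces, _, _ = measure.marching_cubes(
                padded, level=0.5, spacing=tuple(spacing)
            )
            area = float(measure.mesh_surface_area(verts, faces))
            shape_feats["surface_mm2"] = area
            v = shape_feats["volume_mm3"]
            shape_feats["sphericity"] = float(
                np.pi ** (1 / 3) * (6 * v) ** (2 / 3) / area
            )
        except (ValueError, RuntimeError):
            warnings.warn("marching cubes failed; surface features NaN")
        pts = np.argwhere(vol.mask) * spacing
        try:
            hull_pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            hull_pts = pts
        shape_feats["max_diameter_mm"] = float(pdist(hull_pts).max())
    return {"first_order": feats, "shape": shape_feats}


def _glcm_feature_block(levels, mask, ng, config: RadiomicsConfig) -> dict[str, float]:
    if config.direction_aggregation == "sum":
        g = glcm_compute(levels, mask, n_levels=ng, distance=config.distance)
        return glcm_features(g)
    if config.direction_aggregation == "average":
        acc: dict[str, list[float]] = {}
        for d in DIRECTIONS_3D:
            g = glcm_compute(
                levels, mask, n_levels=ng, distance=config.distance, directions=(d,)
            )
            for k, v in glcm_features(g).items():
                acc.setdefault(k, []).append(v)
        return {k: float(np.mean(v)) for k, v in acc.items()}
    raise ValueError(f"unknown aggregation {config.direction_aggregation!r}")


def extract_feature_vector(
    vol: MaskedVolume, config: RadiomicsConfig | None = None
) -> pd.Series:
    """Full radiomic feature vector for one tumor mass.

    Pipeline: resample -> wavelet subbands -> per image (original + 8
    subbands) quantize and compute GLCM + first-order features; shape
    features once from the mask.  Deterministic: identical input gives a
    bit-identical vector.
    """
    config = config or RadiomicsConfig()
    stage = "resample"
    try:
        work = resample(vol, config.target_spacing) if config.resample_first else vol
        stage = "wavelet"
        bands = wavelet_subbands(work.intensities, config.wavelet)
        images = {None: work.intensities, **bands}
        feats: dict[str, float] = {}
        for sub, img in images.items():
            tag = f"_{sub}" if sub else ""
            stage = f"quantize{tag}"
            levels, ng = quantize(img, work.mask, config.bin_width)
            stage = f"glcm{tag}"
            if ng == 1:
                block = glcm_features(GLCM(P=np.ones((1, 1)), n_levels=1))
            else:
                block = _glcm_feature_block(levels, work.mask, ng, config)
            for k, v in block.items():
                feats[f"GLCM_{k}{tag}_25HUgl"] = v
            stage = f"first_order{tag}"
            fo = basic_features(
                MaskedVolume(img, work.mask, work.spacing), config.bin_width
            )["first_order"]
            for k, v in fo.items():
                feats[f"FirstOrder_{k}{tag}_25HUgl"] = v
        stage = "shape"
        for k, v in basic_features(work, config.bin_width)["shape"].items():
            feats[f"Shape_{k}"] = v
    except Exception as exc:
        raise RuntimeError(f"feature extraction failed at stage {stage!r}: {exc}") from exc
    for required in ("GLCM_Entrop_25HUgl", "GLCM_InfCo1_HHL_25HUgl", "GLCM_sumEnt_HLL_25HUgl"):
        assert required in feats
    return pd.Series(feats)
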