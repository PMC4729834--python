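"""The fixed 213-feature morphological profile.

Each cell is profiled from its segmented brightfield object and its *full*
darkfield frame (darkfield speckle does not depict the cell outline, so it
is never masked). Features fall into the five classic morphological
profiling categories:

========================  ==========  =========
block                     brightfield darkfield
========================  ==========  =========
size & shape              17 + 30 Zernike   —
intensity                 16          16
radial distribution       12          12
texture (13 Haralick x3)  39          39
granularity spectrum      16          16
total                     130         83
========================  ==========  =========

for a grand total of 213 features per cell. The exact composition is
versioned in a :class:`FeatureManifest` (current: ``v1``); any change to
the list bumps the version so trained models can refuse mismatched tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import ConvexHull
from skimage import measure, morphology

from .segment import SegmentationParams, SegmentationResult, segment_brightfield
from .synth import CellRecord

__all__ = [
    "FeatureManifest",
    "feature_manifest",
    "shape_features",
    "zernike_magnitudes",
    "intensity_features",
    "radial_distribution",
    "cooccurrence_matrix",
    "haralick_stats",
    "haralick_texture",
    "granularity_spectrum",
    "extract_features",
    "integrated_stain_intensity",
    "profile_population",
]

N_FEATURES = 213
GLCM_LEVELS = 8
TEXTURE_SCALES = (1, 2, 4)
N_RINGS = 4
N_WEDGES = 8
GRANULARITY_LENGTH = 16

SHAPE_SCALARS = (
    "area",
    "perimeter",
    "form_factor",
    "eccentricity",
    "solidity",
    "extent",
    "euler_number",
    "orientation",
    "major_axis_length",
    "minor_axis_length",
    "compactness",
    "equivalent_diameter",
    "max_radius",
    "mean_radius",
    "median_radius",
    "min_feret",
    "max_feret",
)
INTENSITY_NAMES = (
    "integrated",
    "mean",
    "std",
    "mad",
    "min",
    "max",
    "median",
    "q1",
    "q3",
    "range",
    "edge_integrated",
    "edge_mean",
    "edge_std",
    "edge_min",
    "edge_max",
    "mass_displacement",
)
HARALICK_NAMES = (
    "asm",
    "contrast",
    "correlation",
    "variance",
    "idm",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "entropy",
    "diff_variance",
    "diff_entropy",
    "infocorr1",
    "infocorr2",
)


def zernike_indices(max_degree: int = 9) -> List[Tuple[int, int]]:
    """(n, m) pairs with n <= max_degree, m >= 0 and n - m even."""
    return [(n, m) for n in range(max_degree + 1) for m in range(n % 2, n + 1, 2)]


@dataclass(frozen=True)
class FeatureManifest:
    """Ordered, versioned list of the features the profile emits."""

    version: str
    names: Tuple[str, ...]
    channels: Tuple[str, ...]
    categories: Tuple[str, ...]

    def __post_init__(self):
        if len(self.names) != len(set(self.names)):
            raise ValueError("feature names must be unique")
        if not (len(self.names) == len(self.channels) == len(self.categories)):
            raise ValueError("manifest columns must align")

    def __len__(self):
        return len(self.names)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"name": self.names, "channel": self.channels, "category": self.categories}
        )


def _texture_names(prefix):
    return [f"{prefix}_tex_{s}_s{d}" for d in TEXTURE_SCALES for s in HARALICK_NAMES]


def _intensity_names(prefix):
    return [f"{prefix}_int_{s}" for s in INTENSITY_NAMES]


def _radial_names(prefix):
    return (
        [f"{prefix}_rad_fracatd_{i}" for i in range(1, N_RINGS + 1)]
        + [f"{prefix}_rad_meanfrac_{i}" for i in range(1, N_RINGS + 1)]
        + [f"{prefix}_rad_radialcv_{i}" for i in range(1, N_RINGS + 1)]
    )


def _granularity_names(prefix):
    return [f"{prefix}_gran_{i:02d}" for i in range(1, GRANULARITY_LENGTH + 1)]


@lru_cache(maxsize=1)
def feature_manifest() -> FeatureManifest:
    """The canonical v1 manifest: 130 brightfield + 83 darkfield features."""
    names: List[str] = []
    channels: List[str] = []
    categories: List[str] = []

    def add(block_names, channel, category):
        names.extend(block_names)
        channels.extend([channel] * len(block_names))
        categories.extend([category] * len(block_names))

    add([f"bf_shape_{s}" for s in SHAPE_SCALARS], "brightfield", "size_shape")
    add([f"bf_zernike_{n}_{m}" for n, m in zernike_indices()], "brightfield", "size_shape")
    add(_intensity_names("bf"), "brightfield", "intensity")
    add(_radial_names("bf"), "brightfield", "radial_distribution")
    add(_texture_names("bf"), "brightfield", "texture")
    add(_granularity_names("bf"), "brightfield", "granularity")
    add(_intensity_names("df"), "darkfield", "intensity")
    add(_radial_names("df"), "darkfield", "radial_distribution")
    add(_texture_names("df"), "darkfield", "texture")
    add(_granularity_names("df"), "darkfield", "granularity")
    m = FeatureManifest(
        version="v1", names=tuple(names), channels=tuple(channels), categories=tuple(categories)
    )
    assert len(m) == N_FEATURES
    return m


# ---------------------------------------------------------------------------
# size & shape


def _min_feret(coords: np.ndarray) -> float:
    """Minimum caliper width of a point set via its convex hull."""
    pts = np.unique(coords, axis=0).astype(float)
    if len(pts) < 3 or np.linalg.matrix_rank(pts - pts[0]) < 2:
        # degenerate (line/point): width across is ~1 px
        return 1.0
    hull = ConvexHull(pts)
    hp = pts[hull.vertices]
    edges = np.roll(hp, -1, axis=0) - hp
    norms = np.stack([-edges[:, 1], edges[:, 0]], axis=1)
    norms /= np.linalg.norm(norms, axis=1, keepdims=True)
    proj = hp @ norms.T
    widths = proj.max(axis=0) - proj.min(axis=0)
    return float(widths.min()) + 1.0  # +1: pixels have unit extent


def zernike_magnitudes(
    mask: np.ndarray, max_degree: int = 9, radius: Optional[float] = None
) -> np.ndarray:
    """Magnitudes of Zernike moments of a binary mask on the unit disk.

    The mask is centred at its centroid and scaled so its farthest pixel
    sits on the unit circle (or at ``radius`` px if given); pixel weights
    are normalised to sum to 1 so the magnitudes are size-invariant.
    """
    ys, xs = np.nonzero(mask)
    if len(ys) == 0:
        raise ValueError("empty mask")
    cy, cx = ys.mean(), xs.mean()
    dy, dx = ys - cy, xs - cx
    rr = np.hypot(dy, dx)
    R = radius if radius is not None else max(rr.max(), 1.0)
    rho = rr / R
    keep = rho <= 1.0
    rho, theta = rho[keep], np.arctan2(dy[keep], dx[keep])
    w = 1.0 / keep.sum()
    out = []
    for n, m in zernike_indices(max_degree):
        # radial polynomial R_nm(rho)
        rad = np.zeros_like(rho)
        for s in range((n - m) // 2 + 1):
            coef = (
                (-1) ** s
                * math.factorial(n - s)
                / (
                    math.factorial(s)
                    * math.factorial((n + m) // 2 - s)
                    * math.factorial((n - m) // 2 - s)
                )
            )
            rad += coef * rho ** (n - 2 * s)
        A = (n + 1) / np.pi * np.sum(w * rad * np.exp(-1j * m * theta))
        out.append(abs(A))
    return np.asarray(out)


def shape_features(mask: np.ndarray) -> np.ndarray:
    """17 shape scalars + 30 Zernike magnitudes (degree <= 9) of a mask."""
    mask = np.asarray(mask, bool)
    if mask.sum() == 0:
        raise ValueError("empty mask")
    props = measure.regionprops(mask.astype(np.uint8))[0]
    area = float(props.area)
    perimeter = float(max(props.perimeter, 1e-9))
    dist = ndi.distance_transform_edt(mask)
    radii = dist[mask]
    coords = props.coords
    scalars = [
        area,
        perimeter,
        4 * np.pi * area / perimeter**2,  # form factor: 1 for a disk
        float(props.eccentricity),
        float(props.solidity),
        float(props.extent),
        float(props.euler_number),
        float(props.orientation),
        float(props.axis_major_length),
        float(props.axis_minor_length),
        perimeter**2 / (4 * np.pi * area),  # compactness (1/form factor)
        float(props.equivalent_diameter_area),
        float(radii.max()),
        float(radii.mean()),
        float(np.median(radii)),
        _min_feret(coords),
        float(props.feret_diameter_max),
    ]
    return np.concatenate([scalars, zernike_magnitudes(mask)])


# ---------------------------------------------------------------------------
# intensity


def _region_mask(image: np.ndarray, region: Optional[np.ndarray]) -> np.ndarray:
    if region is None:
        return np.ones(image.shape, bool)
    return np.asarray(region, bool)


def _edge_mask(image_shape, region: Optional[np.ndarray]) -> np.ndarray:
    """1-px inner boundary of the region (border frame for full frames)."""
    if region is None:
        edge = np.zeros(image_shape, bool)
        edge[0, :] = edge[-1, :] = True
        edge[:, 0] = edge[:, -1] = True
        return edge
    region = np.asarray(region, bool)
    return region & ~ndi.binary_erosion(region, border_value=0)


def intensity_features(image: np.ndarray, region: Optional[np.ndarray] = None) -> np.ndarray:
    """16 intensity statistics of the image over the region.

    ``region=None`` means the full frame (darkfield convention); its edge
    statistics are then taken over the 1-px border frame.
    """
    image = np.asarray(image, dtype=float)
    mask = _region_mask(image, region)
    vals = image[mask]
    if vals.size == 0:
        raise ValueError("empty region")
    edge = _edge_mask(image.shape, region)
    evals = image[edge] if edge.any() else vals

    total = float(vals.sum())
    ys, xs = np.nonzero(mask)
    cy, cx = ys.mean(), xs.mean()
    if total > 0:
        wy = float((ys * image[mask]).sum() / total)
        wx = float((xs * image[mask]).sum() / total)
        displacement = float(np.hypot(wy - cy, wx - cx))
    else:
        displacement = 0.0
    q1, med, q3 = np.percentile(vals, [25, 50, 75])
    return np.array(
        [
            total,
            vals.mean(),
            vals.std(),
            float(np.median(np.abs(vals - med))),
            vals.min(),
            vals.max(),
            med,
            q1,
            q3,
            vals.max() - vals.min(),
            evals.sum(),
            evals.mean(),
            evals.std(),
            evals.min(),
            evals.max(),
            displacement,
        ],
        dtype=float,
    )


# ---------------------------------------------------------------------------
# radial distribution


def radial_distribution(
    image: np.ndarray, region: Optional[np.ndarray] = None, n_rings: int = N_RINGS
) -> np.ndarray:
    """FracAtD, MeanFrac and RadialCV over equal-width annuli.

    Rings are ``n_rings`` equal-width annuli from the region centroid out
    to its maximum radius (half-open ``[r_i, r_{i+1})``, last ring closed).
    FracAtD is the ring's share of total intensity, MeanFrac that share
    normalised by the ring's area share, and RadialCV the coefficient of
    variation of mean intensity over 8 angular wedges within the ring.
    Zero total intensity yields all-zero values.
    """
    image = np.asarray(image, dtype=float)
    mask = _region_mask(image, region)
    ys, xs = np.nonzero(mask)
    if len(ys) == 0:
        raise ValueError("empty region")
    if region is None:
        cy, cx = (image.shape[0] - 1) / 2.0, (image.shape[1] - 1) / 2.0
    else:
        cy, cx = ys.mean(), xs.mean()
    dy, dx = ys - cy, xs - cx
    rr = np.hypot(dy, dx)
    rmax = max(rr.max(), 1e-9)
    ring = np.minimum((rr / rmax * n_rings).astype(int), n_rings - 1)
    wedge = ((np.arctan2(dy, dx) + np.pi) / (2 * np.pi) * N_WEDGES).astype(int) % N_WEDGES
    vals = image[mask]
    total = vals.sum()

    frac = np.zeros(n_rings)
    meanfrac = np.zeros(n_rings)
    radialcv = np.zeros(n_rings)
    n_pix = len(vals)
    if total > 0:
        for i in range(n_rings):
            sel = ring == i
            if not sel.any():
                continue
            frac[i] = vals[sel].sum() / total
            area_frac = sel.sum() / n_pix
            meanfrac[i] = frac[i] / area_frac
            wedge_means = [
                vals[sel & (wedge == k)].mean() for k in range(N_WEDGES) if (sel & (wedge == k)).any()
            ]
            mu = np.mean(wedge_means)
            if len(wedge_means) > 1 and abs(mu) > 1e-12:
                radialcv[i] = np.std(wedge_means) / abs(mu)
    return np.concatenate([frac, meanfrac, radialcv])


# ---------------------------------------------------------------------------
# Haralick texture


def _quantize(vals: np.ndarray, levels: int = GLCM_LEVELS) -> np.ndarray:
    """Linear min-max quantization; ties at bin edges go to the lower bin."""
    vmin, vmax = vals.min(), vals.max()
    if vmax <= vmin:
        return np.zeros(vals.shape, dtype=np.intp)
    scaled = (vals - vmin) / (vmax - vmin) * levels
    return np.clip(np.ceil(scaled).astype(np.intp) - 1, 0, levels - 1)


def cooccurrence_matrix(
    quantized: np.ndarray,
    mask: np.ndarray,
    offset: Tuple[int, int],
    levels: int = GLCM_LEVELS,
) -> np.ndarray:
    """Symmetric, normalised gray-level co-occurrence matrix for one offset.

    Counts pairs ``(p, p + offset)`` with both pixels inside the mask, adds
    the transpose, and normalises to sum 1. If the offset yields no valid
    pair the conventional constant-region matrix (all mass at (0, 0)) is
    returned.
    """
    dy, dx = offset
    h, w = quantized.shape
    ys, xs = np.nonzero(mask)
    y2, x2 = ys + dy, xs + dx
    ok = (y2 >= 0) & (y2 < h) & (x2 >= 0) & (x2 < w)
    ys, xs, y2, x2 = ys[ok], xs[ok], y2[ok], x2[ok]
    ok = mask[y2, x2]
    a = quantized[ys[ok], xs[ok]]
    b = quantized[y2[ok], x2[ok]]
    if a.size == 0:
        P = np.zeros((levels, levels))
        P[0, 0] = 1.0
        return P
    P = np.zeros((levels, levels))
    np.add.at(P, (a, b), 1.0)
    P = P + P.T
    return P / P.sum()


def haralick_stats(P: np.ndarray) -> np.ndarray:
    """The 13 Haralick statistics of a normalised co-occurrence matrix.

    Degenerate conventions: correlation is 0 when a marginal is constant,
    information-correlation 1 is 0 when max(HX, HY) = 0, and 0·log 0 = 0
    throughout.
    """
    levels = P.shape[0]
    i = np.arange(levels)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mux, muy = (i * px).sum(), (i * py).sum()
    sx = np.sqrt(((i - mux) ** 2 * px).sum())
    sy = np.sqrt(((i - muy) ** 2 * py).sum())

    def _ent(p):
        p = p[p > 0]
        return float(-(p * np.log2(p)).sum())

    # p_{x+y}, p_{x-y}
    pxy_sum = np.zeros(2 * levels - 1)
    np.add.at(pxy_sum, ii.ravel() + jj.ravel(), P.ravel())
    pxy_diff = np.zeros(levels)
    np.add.at(pxy_diff, np.abs(ii - jj).ravel(), P.ravel())
    k_sum = np.arange(2 * levels - 1)
    k_diff = np.arange(levels)

    asm = float((P**2).sum())
    contrast = float(((ii - jj) ** 2 * P).sum())
    correlation = float(((ii * jj * P).sum() - mux * muy) / (sx * sy)) if sx * sy > 1e-12 else 0.0
    variance = float(((ii - mux) ** 2 * P).sum())
    idm = float((P / (1.0 + (ii - jj) ** 2)).sum())
    sum_avg = float((k_sum * pxy_sum).sum())
    sum_var = float(((k_sum - sum_avg) ** 2 * pxy_sum).sum())
    sum_ent = _ent(pxy_sum)
    entropy = _ent(P.ravel())
    diff_avg = float((k_diff * pxy_diff).sum())
    diff_var = float(((k_diff - diff_avg) ** 2 * pxy_diff).sum())
    diff_ent = _ent(pxy_diff)
    hx, hy = _ent(px), _ent(py)
    with np.errstate(divide="ignore"):
        logpxpy = np.where(px[:, None] * py[None, :] > 0, np.log2(px[:, None] * py[None, :]), 0.0)
    hxy1 = float(-(P * logpxpy).sum())
    hxy2 = float(-((px[:, None] * py[None, :]) * logpxpy).sum())
    infocorr1 = (entropy - hxy1) / max(hx, hy) if max(hx, hy) > 1e-12 else 0.0
    infocorr2 = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - entropy))))
    return np.array(
        [
            asm,
            contrast,
            correlation,
            variance,
            idm,
            sum_avg,
            sum_var,
            sum_ent,
            entropy,
            diff_var,
            diff_ent,
            infocorr1,
            infocorr2,
        ]
    )


def haralick_texture(
    image: np.ndarray,
    region: Optional[np.ndarray] = None,
    scales: Sequence[int] = TEXTURE_SCALES,
) -> np.ndarray:
    """13 Haralick statistics x len(scales) offsets (39 values by default).

    Pixels are quantized to 8 levels over the region's min-max range, so
    the statistics are invariant to affine intensity rescaling. Per scale,
    the symmetric co-occurrence matrix is averaged over the four principal
    directions before the statistics are computed.
    """
    image = np.asarray(image, dtype=float)
    mask = _region_mask(image, region)
    if mask.sum() < 2:
        raise ValueError("region must contain at least 2 pixels")
    q = np.zeros(image.shape, dtype=np.intp)
    q[mask] = _quantize(image[mask])
    out = []
    for d in scales:
        mats = [
            cooccurrence_matrix(q, mask, off)
            for off in ((0, d), (-d, d), (-d, 0), (-d, -d))
        ]
        out.append(haralick_stats(np.mean(mats, axis=0)))
    return np.concatenate(out)


# ---------------------------------------------------------------------------
# granularity


@lru_cache(maxsize=32)
def _disk_footprint(radius: int):
    # decomposed disk: sequence of small footprints whose chained
    # erosions/dilations approximate the full disk at a fraction of the cost
    return morphology.disk(radius, decomposition="sequence")


def granularity_spectrum(
    image: np.ndarray,
    region: Optional[np.ndarray] = None,
    length: int = GRANULARITY_LENGTH,
) -> np.ndarray:
    """Morphological granularity spectrum of the region.

    Background-subtracted (region minimum) image volume is eroded by
    grayscale openings with disks of radius 1..length; element ``i`` is the
    percentage of the initial volume removed between openings ``i-1`` and
    ``i``. Elements are non-negative and sum to at most 100.
    """
    image = np.asarray(image, dtype=float)
    mask = _region_mask(image, region)
    if mask.sum() == 0:
        raise ValueError("empty region")
    work = np.zeros(image.shape)
    work[mask] = image[mask] - image[mask].min()
    total = work.sum()
    spectrum = np.zeros(length)
    if total <= 0:
        return spectrum
    prev = work
    prev_sum = total
    for idx in range(1, length + 1):
        opened = morphology.opening(work, _disk_footprint(idx))
        opened = np.minimum(opened, prev)  # enforce decreasing volume
        opened[~mask] = 0.0
        cur = opened.sum()
        spectrum[idx - 1] = 100.0 * (prev_sum - cur) / total
        prev, prev_sum = opened, cur
    return spectrum


# ---------------------------------------------------------------------------
# assembly


def extract_features(
    record: CellRecord,
    seg: SegmentationResult,
    manifest: Optional[FeatureManifest] = None,
) -> np.ndarray:
    """Concatenate the full 213-feature profile for one cell.

    Brightfield blocks are computed on the segmented object; darkfield
    blocks on the full frame. Raises if no object was found or a channel is
    missing; non-finite outputs are the caller's cue to discard the cell.
    """
    if manifest is None:
        manifest = feature_manifest()
    if not seg.object_found:
        raise ValueError("cannot extract features without a segmented object")
    if record.brightfield is None or record.darkfield is None:
        raise ValueError("record must carry brightfield and darkfield channels")
    bf, df, mask = record.brightfield, record.darkfield, seg.mask
    vec = np.concatenate(
        [
            shape_features(mask),
            intensity_features(bf, mask),
            radial_distribution(bf, mask),
            haralick_texture(bf, mask),
            granularity_spectrum(bf, mask),
            intensity_features(df, None),
            radial_distribution(df, None),
            haralick_texture(df, None),
            granularity_spectrum(df, None),
        ]
    )
    assert vec.shape == (len(manifest),)
    return vec


def integrated_stain_intensity(record: CellRecord, seg: SegmentationResult) -> float:
    """Ground-truth DNA intensity: background-subtracted stain integral.

    Sums stain pixels within the brightfield mask dilated by 2 px (to make
    sure the whole nucleus is captured), after subtracting the stain
    frame's median background level.
    """
    if record.stain is None:
        raise ValueError("record has no stain channel")
    stain = np.asarray(record.stain, dtype=float)
    mask = ndi.binary_dilation(seg.mask, morphology.disk(2))
    bg = float(np.median(np.concatenate([stain[0, :], stain[-1, :], stain[:, 0], stain[:, -1]])))
    return float((stain[mask] - bg).sum())


def profile_population(
    records: Sequence[CellRecord],
    seg_params: SegmentationParams = SegmentationParams(),
    manifest: Optional[FeatureManifest] = None,
    with_stain: bool = True,
):
    """Segment and profile a population into a FeatureTable.

    Returns ``(features, stain, qc)``: a DataFrame of features (rows =
    kept cells, columns = manifest order), a Series of integrated stain
    intensities (NaN where no stain), and a DataFrame listing every cell
    with its kept/discarded status and reasons. Cells whose segmentation
    fails QC or whose profile contains non-finite values are discarded.
    """
    if manifest is None:
        manifest = feature_manifest()
    rows, stains, qc_rows = {}, {}, []
    for rec in records:
        seg = segment_brightfield(rec.brightfield, seg_params)
        reasons = sorted(seg.qc_flags & {"no_object", "too_small", "missing_values"})
        if not seg.object_found or reasons:
            qc_rows.append({"cell_id": rec.cell_id, "kept": False, "reasons": ";".join(reasons) or "no_object"})
            continue
        vec = extract_features(rec, seg, manifest)
        if not np.all(np.isfinite(vec)):
            qc_rows.append({"cell_id": rec.cell_id, "kept": False, "reasons": "missing_values"})
            continue
        rows[rec.cell_id] = vec
        if with_stain and rec.stain is not None:
            stains[rec.cell_id] = integrated_stain_intensity(rec, seg)
        else:
            stains[rec.cell_id] = np.nan
        qc_rows.append(
            {"cell_id": rec.cell_id, "kept": True, "reasons": ";".join(sorted(seg.qc_flags))}
        )
    features = pd.DataFrame.from_dict(rows, orient="index", columns=list(manifest.names))
    features.index.name = "cell_id"
    features.attrs["manifest_version"] = manifest.version
    stain = pd.Series(stains, name="stain_integrated")
    qc = pd.DataFrame(qc_rows)
    return features, stain, qc
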