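"""Reshaping single-cell images to a common size and tiling them into montages.

Imaging flow cytometers emit per-cell images of varying size (typically
30x30 to 60x60 px). Batch image processing wants a fixed geometry, so each
cell is brought to a common tile side — smaller images are centre-padded
with values sampled from their own background, larger ones centre-cropped —
and tiles are laid out row-major on a square grid (default 15x15, up to 225
cells per montage). An index map travels with each montage so tiles can be
mapped back to cell identities exactly.
"""

from __future__ import annotations

import json
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .synth import CellRecord

__all__ = [
    "BackgroundSampler",
    "Montage",
    "estimate_background",
    "reshape_image",
    "build_montages",
    "split_montage",
    "save_montage",
    "load_montage",
]

DEFAULT_TILE = 55
DEFAULT_GRID = 15
BORDER_WIDTH = 2  # px frame treated as image background


class BackgroundSampler:
    """Empirical sampler over the pixels of an image's border frame."""

    def __init__(self, values: np.ndarray):
        values = np.asarray(values, dtype=float).ravel()
        if values.size == 0:
            raise ValueError("background frame is empty")
        self.values = values

    def sample(self, shape, rng: np.random.Generator) -> np.ndarray:
        idx = rng.integers(0, self.values.size, size=shape)
        return self.values[idx]

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def std(self) -> float:
        return float(self.values.std())

    @property
    def median(self) -> float:
        return float(np.median(self.values))


def estimate_background(image: np.ndarray, border: int = BORDER_WIDTH) -> BackgroundSampler:
    """Sampler over the empirical distribution of the outer border frame.

    The outermost ``border`` pixels on every side are taken as background;
    label-free tiles have no annotation, and the frame is the safest proxy.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or min(image.shape) < 1:
        raise ValueError("image must be 2-D and non-empty")
    b = min(border, (min(image.shape) + 1) // 2)
    mask = np.zeros(image.shape, dtype=bool)
    mask[:b, :] = mask[-b:, :] = True
    mask[:, :b] = mask[:, -b:] = True
    return BackgroundSampler(image[mask])


def reshape_image(
    image: np.ndarray,
    target: int = DEFAULT_TILE,
    rng: Optional[np.random.Generator] = None,
    crop_tolerance: float = 0.02,
) -> np.ndarray:
    """Bring an image to ``target`` x ``target`` px without interpolation.

    Smaller images are centred and padded with values sampled from the
    image's own background frame; larger images are centre-cropped by
    discarding edge pixels. For odd gaps the extra row/column goes to the
    bottom/right. Content pixels are never rescaled.

    If cropping discards pixels that deviate from the background (more than
    3 background s.d. from the background mean, on more than
    ``crop_tolerance`` of the discarded pixels) a warning is raised: the
    crop has likely cut into the object, which the method assumes never
    happens on well-framed cytometer images.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or image.size == 0:
        raise ValueError("image must be a non-empty 2-D array")
    if target < 8:
        raise ValueError("target side must be >= 8 px")
    h, w = image.shape
    if (h, w) == (target, target):
        return image.copy()

    sampler = estimate_background(image)
    out = image

    # crop dimensions that are too large
    def _crop(arr, axis):
        n = arr.shape[axis]
        excess = n - target
        lo = excess // 2
        sl = [slice(None)] * 2
        sl[axis] = slice(lo, lo + target)
        discarded = np.delete(arr, np.r_[lo : lo + target], axis=axis)
        return arr[tuple(sl)], discarded

    discarded_pixels = []
    for axis in (0, 1):
        if out.shape[axis] > target:
            out, disc = _crop(out, axis)
            discarded_pixels.append(disc.ravel())
    if discarded_pixels:
        disc = np.concatenate(discarded_pixels)
        sd = max(sampler.std, 1e-12)
        frac_object = float(np.mean(np.abs(disc - sampler.mean) > 3 * sd))
        if frac_object > crop_tolerance:
            warnings.warn(
                f"cropping discarded {frac_object:.1%} non-background pixels; "
                "object may have been cut",
                stacklevel=2,
            )

    # pad dimensions that are too small
    h, w = out.shape
    if h < target or w < target:
        if rng is None:
            rng = np.random.default_rng(0)
        canvas = sampler.sample((target, target), rng)
        top = (target - h) // 2
        left = (target - w) // 2
        canvas[top : top + h, left : left + w] = out
        out = canvas
    return out


@dataclass
class Montage:
    """A square grid of fixed-size tiles plus the cell-id index map."""

    image: np.ndarray
    grid: int
    tile: int
    index_map: List[str]
    channel: str

    def __post_init__(self):
        side = self.grid * self.tile
        if self.image.shape != (side, side):
            raise ValueError(
                f"montage image must be {side}x{side} (grid {self.grid} x tile {self.tile})"
            )
        if len(self.index_map) > self.grid**2:
            raise ValueError("index_map longer than grid^2")
        if len(set(self.index_map)) != len(self.index_map):
            raise ValueError("index_map contains duplicate cell ids")


def _get_channel(record: CellRecord, channel: str) -> np.ndarray:
    img = {"brightfield": record.brightfield, "darkfield": record.darkfield, "stain": record.stain}[
        channel
    ]
    if img is None:
        raise ValueError(f"record {record.cell_id} lacks channel {channel!r}")
    return img


def build_montages(
    records: Sequence[CellRecord],
    grid: int = DEFAULT_GRID,
    tile: int = DEFAULT_TILE,
    channels: Sequence[str] = ("brightfield", "darkfield"),
    seed: int = 0,
) -> Dict[str, List[Montage]]:
    """Reshape each record's channels and tile them row-major into montages.

    Cells are placed in input order; ceil(n / grid^2) montages per channel.
    All channels share identical index maps. Unfilled slots are filled with
    the per-montage median background value. Padding RNG is seeded from
    ``(seed, cell_id)`` so individual tiles are reproducible.
    """
    if len(records) == 0:
        raise ValueError("cannot build montages from an empty record list")
    per = grid * grid
    out: Dict[str, List[Montage]] = {ch: [] for ch in channels}
    for start in range(0, len(records), per):
        chunk = records[start : start + per]
        ids = [r.cell_id for r in chunk]
        for ch in channels:
            tiles = []
            bg_medians = []
            for rec in chunk:
                img = _get_channel(rec, ch)
                rng = np.random.default_rng(
                    np.random.SeedSequence((seed, zlib.crc32(rec.cell_id.encode())))
                )
                tiles.append(reshape_image(img, tile, rng=rng))
                bg_medians.append(estimate_background(img).median)
            fill = float(np.median(bg_medians))
            canvas = np.full((grid * tile, grid * tile), fill)
            for k, t in enumerate(tiles):
                row, col = divmod(k, grid)
                canvas[row * tile : (row + 1) * tile, col * tile : (col + 1) * tile] = t
            out[ch].append(Montage(image=canvas, grid=grid, tile=tile, index_map=list(ids), channel=ch))
    return out


def split_montage(montage: Montage) -> List[Tuple[str, np.ndarray]]:
    """Inverse of tiling: return (cell_id, tile) pairs in index-map order."""
    if len(montage.index_map) > montage.grid**2:
        raise ValueError("index_map longer than grid^2")
    if len(set(montage.index_map)) != len(montage.index_map):
        raise ValueError("index_map contains duplicate cell ids")
    g, t = montage.grid, montage.tile
    out = []
    for k, cell_id in enumerate(montage.index_map):
        row, col = divmod(k, g)
        out.append((cell_id, montage.image[row * t : (row + 1) * t, col * t : (col + 1) * t].copy()))
    return out


def save_montage(montage: Montage, path) -> None:
    """Write the montage as 16-bit TIFF plus a `<path>.idx.json` sidecar."""
    import tifffile

    path = Path(path)
    data = np.round(np.clip(montage.image, 0, 1) * 65535).astype(np.uint16)
    tifffile.imwrite(path, data)
    sidecar = {
        "grid": montage.grid,
        "tile": montage.tile,
        "channel": montage.channel,
        "index_map": montage.index_map,
    }
    Path(str(path) + ".idx.json").write_text(json.dumps(sidecar, indent=1))


def load_montage(path) -> Montage:
    import tifffile

    path = Path(path)
    meta = json.loads(Path(str(path) + ".idx.json").read_text())
    image = tifffile.imread(path).astype(float) / 65535.0
    return Montage(
        image=image,
        grid=meta["grid"],
        tile=meta["tile"],
        index_map=list(meta["index_map"]),
        channel=meta["channel"],
    )
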