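"""DAPI-map immunofluorescence quantification.

A multichannel fluorescence image with nuclear DAPI staining in the blue
channel is converted into a binary "DAPI map" approximating the tissue
footprint, and marker-channel (red/green) intensities are then averaged
inside and outside that map.

Map construction, in fixed order:

1. balance the blue channel with a linear percentile contrast stretch
   (clip at the 1st/99th percentiles by default, rescale to full range);
2. binarize at ``threshold_fraction`` (default 20%) of the *balanced
   channel's own* maximum pixel intensity;
3. remove connected components smaller than ``min_component_area``
   pixels (8-connectivity) — non-nuclei debris;
4. morphological closing (dilation then erosion) with a disk structuring
   element of ``disk_radius`` pixels, connecting nuclei blobs into a
   contiguous tissue approximation.

Region statistics report per-channel mean pixel intensity, normalized to
a 0–1 scale by the bit-depth maximum, inside and outside the map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import imageio.v3 as iio
import tifffile
from skimage import measure, morphology

__all__ = ["ChannelImage", "DapiMapParams", "DapiMap", "RegionStats",
           "build_dapi_map", "region_channel_stats",
           "normalized_marker_intensity"]

CHANNELS = ("red", "green", "blue")


@dataclass
class ChannelImage:
    """An RGB image of unsigned 8- or 16-bit intensities."""

    pixels: np.ndarray  # (H, W, 3)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError("expected an (H, W, 3) RGB array")
        if px.dtype == np.uint8:
            self.bit_depth = 8
        elif px.dtype == np.uint16:
            self.bit_depth = 16
        else:
            raise ValueError("expected uint8 or uint16 pixels")
        self.pixels = px

    @property
    def max_scale(self) -> int:
        return 2 ** self.bit_depth - 1

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    def channel(self, name: str) -> np.ndarray:
        return self.pixels[:, :, CHANNELS.index(name)]

    @classmethod
    def read(cls, path) -> "ChannelImage":
        """Read an RGB TIFF or PNG."""
        path = Path(path)
        if path.suffix.lower() in {".tif", ".tiff"}:
            arr = tifffile.imread(path)
        else:
            arr = iio.imread(path)
        if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
            arr = arr[:, :, :3]
        return cls(arr)

    def write(self, path) -> None:
        path = Path(path)
        if path.suffix.lower() in {".tif", ".tiff"}:
            tifffile.imwrite(path, self.pixels)
        else:
            iio.imwrite(path, self.pixels)


@dataclass
class DapiMapParams:
    """Tissue-map construction parameters.

    threshold_fraction
        Binarization threshold as a fraction of the balanced blue
        channel's maximum (default 0.20).
    min_component_area
        Minimum connected-component area in pixels kept after
        thresholding (default 30).
    disk_radius
        Radius in pixels of the disk structuring element used for the
        closing (default 3).
    balance_percentiles
        Low/high percentiles of the linear contrast stretch balancing
        the blue channel (default (1, 99)).
    """

    threshold_fraction: float = 0.20
    min_component_area: int = 30
    disk_radius: int = 3
    balance_percentiles: tuple[float, float] = (1.0, 99.0)

    def __post_init__(self) -> None:
        if not 0 < self.threshold_fraction < 1:
            raise ValueError("threshold_fraction must be in (0, 1)")
        if self.disk_radius < 1:
            raise ValueError("disk_radius must be >= 1")
        if self.min_component_area < 0:
            raise ValueError("min_component_area must be >= 0")


@dataclass
class DapiMap:
    """Binary tissue mask plus the parameters that built it."""

    mask: np.ndarray  # bool (H, W)
    params: DapiMapParams
    area: int = field(init=False)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.area = int(self.mask.sum())

    def write(self, path) -> None:
        iio.imwrite(Path(path), (self.mask.astype(np.uint8) * 255))


@dataclass
class RegionStats:
    """Per-channel normalized mean and summed intensity in/outside the map."""

    inside_mean: dict[str, float]
    outside_mean: dict[str, float]
    inside_sum: dict[str, float]
    inside_area: int
    outside_area: int


def _balance(channel: np.ndarray, percentiles: tuple[float, float]) -> np.ndarray:
    lo, hi = np.percentile(channel, percentiles)
    if hi <= lo:
        return channel.astype(float)
    stretched = (channel.astype(float) - lo) / (hi - lo)
    return np.clip(stretched, 0.0, 1.0)


def build_dapi_map(img: ChannelImage, params: DapiMapParams | None = None) -> DapiMap:
    """Construct the DAPI map from the blue channel.

    An all-zero blue channel degenerates (its maximum is 0, so the
    threshold is meaningless); an empty map is returned with a warning.
    """
    params = params or DapiMapParams()
    blue = img.channel("blue")
    if blue.max() == 0:
        warnings.warn("blue channel is empty; returning an empty DAPI map")
        return DapiMap(np.zeros(img.shape, dtype=bool), params)
    balanced = _balance(blue, params.balance_percentiles)
    mask = balanced >= params.threshold_fraction * balanced.max()
    if params.min_component_area > 0:
        lab = measure.label(mask, connectivity=2)
        counts = np.bincount(lab.ravel())
        keep = np.flatnonzero(counts >= params.min_component_area)
        mask = np.isin(lab, keep[keep > 0])
    selem = morphology.disk(params.disk_radius)
    mask = morphology.erosion(morphology.dilation(mask, selem), selem)
    return DapiMap(mask, params)


def region_channel_stats(img: ChannelImage, dapi_map: DapiMap) -> RegionStats:
    """Mean normalized intensities inside and outside the DAPI map.

    Intensities are scaled to 0–1 by the bit-depth maximum. An empty
    region (empty or full mask) yields NaN means for that region.
    """
    if dapi_map.mask.shape != img.shape:
        raise ValueError("mask shape does not match image shape")
    inside = dapi_map.mask
    outside = ~inside
    scale = float(img.max_scale)
    inside_mean, outside_mean, inside_sum = {}, {}, {}
    for name in CHANNELS:
        ch = img.channel(name).astype(float) / scale
        inside_mean[name] = float(ch[inside].mean()) if inside.any() else float("nan")
        outside_mean[name] = float(ch[outside].mean()) if outside.any() else float("nan")
        inside_sum[name] = float(ch[inside].sum())
    return RegionStats(inside_mean, outside_mean, inside_sum,
                       int(inside.sum()), int(outside.sum()))


def normalized_marker_intensity(stats: RegionStats, channel: str,
                                normalizer: str = "dapi_area") -> float:
    """Marker intensity inside the map, normalized per figure convention.

    ``normalizer="dapi_area"`` divides the channel's summed inside
    intensity by the map area (giving the mean normalized intensity over
    tissue). Passing another channel name divides by that channel's
    inside mean instead (marker relative to a co-stain).
    """
    num = stats.inside_sum[channel]
    if normalizer == "dapi_area":
        if stats.inside_area == 0:
            raise ValueError("empty DAPI map: area normalizer is zero")
        return num / stats.inside_area
    if normalizer in CHANNELS:
        denom = stats.inside_mean[normalizer]
        if not denom or not np.isfinite(denom):
            raise ValueError(f"normalizer channel {normalizer!r} has zero/undefined mean")
        return num / denom
    raise ValueError(f"unknown normalizer {normalizer!r}")
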