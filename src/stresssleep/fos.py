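"""c-Fos-positive cell counting in fluorescence images.

Cells are detected as connected components brighter than a locally
determined background threshold and retained when their equivalent
circular diameter lies in the 9-30 um range typical of neuronal somata.
The local background is a running median over a configurable radius
(default 50 um), so detection is invariant to constant offsets and to
smooth illumination gradients; the threshold sits ``k_sigma`` robust
standard deviations (MAD-based) above that background.  Counts are
normalized by ROI area (per mm^2) and the two hemispheres of each region
are averaged per mouse.

Touching cells are not split (no watershed); on well-separated somata
this is exact, on dense tissue it undercounts - a documented limitation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import rank
from skimage.measure import label, regionprops
from skimage.morphology import disk

from .stats import TestResult, unpaired_t

DIAMETER_RANGE_UM = (9.0, 30.0)
MAD_TO_SIGMA = 1.4826


@dataclass
class FluorescenceImage:
    """Single-channel intensity image with um/px calibration and ROI mask."""

    data: np.ndarray
    um_per_px: float
    roi_mask: np.ndarray | None = None
    region: str = ""
    hemisphere: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("image must be 2-D")
        if np.any(self.data < 0):
            raise ValueError("intensities must be non-negative")
        if self.um_per_px <= 0:
            raise ValueError("um_per_px calibration must be positive")
        if self.roi_mask is not None:
            self.roi_mask = np.asarray(self.roi_mask, dtype=bool)
            if self.roi_mask.shape != self.data.shape:
                raise ValueError("ROI mask must match the image shape")
            if not self.roi_mask.any():
                raise ValueError("ROI mask is empty")

    @property
    def roi(self) -> np.ndarray:
        if self.roi_mask is None:
            return np.ones(self.data.shape, dtype=bool)
        return self.roi_mask

    @property
    def roi_area_mm2(self) -> float:
        return float(self.roi.sum()) * (self.um_per_px / 1000.0) ** 2


@dataclass
class Spot:
    centroid_px: tuple[float, float]
    area_px: int
    equivalent_diameter_um: float


@dataclass
class SpotSet:
    """Detected objects passing the size filter, with area-normalized count."""

    spots: list[Spot]
    roi_area_mm2: float
    region: str = ""
    hemisphere: str = ""

    @property
    def count(self) -> int:
        return len(self.spots)

    @property
    def count_density_mm2(self) -> float:
        return self.count / self.roi_area_mm2


@dataclass
class RegionCount:
    """Per-mouse, per-region cell count averaged over hemispheres."""

    region: str
    mouse_id: str
    left: float | None = None
    right: float | None = None
    left_density: float | None = None
    right_density: float | None = None
    single_hemisphere: bool = field(init=False, default=False)

    def __post_init__(self) -> None:
        present = [v for v in (self.left, self.right) if v is not None]
        if not present:
            raise ValueError("at least one hemisphere count required")
        self.single_hemisphere = len(present) == 1

    @property
    def mean_count(self) -> float:
        vals = [v for v in (self.left, self.right) if v is not None]
        return float(np.mean(vals))

    @property
    def mean_density(self) -> float | None:
        vals = [v for v in (self.left_density, self.right_density) if v is not None]
        return float(np.mean(vals)) if vals else None


def _local_median_background(img: np.ndarray, radius_px: int) -> np.ndarray:
    """Median filter of the given radius, via an 8-bit rank filter.

    The image is quantized to 256 levels over its own range before the
    histogram-based rank filter and the result mapped back to intensity
    units.  Quantization relative to the image range keeps the background
    estimate (and hence detection) invariant to constant offsets; the
    <= 1/255-range quantization error is negligible against k_sigma
    thresholds.
    """
    lo, hi = float(img.min()), float(img.max())
    if hi == lo:
        return np.full_like(img, lo)
    scaled = np.round((img - lo) / (hi - lo) * 255).astype(np.uint8)
    med = rank.median(scaled, disk(radius_px))
    return med.astype(float) / 255.0 * (hi - lo) + lo


def detect_spots(
    img: FluorescenceImage,
    k_sigma: float = 3.0,
    bg_radius_um: float = 50.0,
    diameter_range_um: tuple[float, float] = DIAMETER_RANGE_UM,
) -> SpotSet:
    """Detect bright objects against the local background, size-filtered.

    A pixel is foreground when its intensity exceeds the local median
    background by more than ``k_sigma`` times the robust spread (MAD x
    1.4826) of the in-ROI background residuals.  8-connected components
    become objects; an object is retained when its equivalent circular
    diameter ``2 sqrt(area_um2 / pi)`` lies within ``diameter_range_um``.
    """
    radius_px = max(1, int(round(bg_radius_um / img.um_per_px)))
    background = _local_median_background(img.data, radius_px)
    resid = (img.data - background)[img.roi]
    spread = MAD_TO_SIGMA * float(np.median(np.abs(resid - np.median(resid))))
    if spread == 0:
        spread = float(np.std(resid))
    fg = (img.data > background + k_sigma * spread) & img.roi
    labels = label(fg, connectivity=2)  # 8-connectivity
    lo, hi = diameter_range_um
    spots = []
    for rp in regionprops(labels):
        area_um2 = rp.area * img.um_per_px**2
        diam = 2.0 * np.sqrt(area_um2 / np.pi)
        if lo <= diam <= hi:
            spots.append(
                Spot(
                    centroid_px=tuple(rp.centroid),
                    area_px=int(rp.area),
                    equivalent_diameter_um=float(diam),
                )
            )
    return SpotSet(
        spots=spots,
        roi_area_mm2=img.roi_area_mm2,
        region=img.region,
        hemisphere=img.hemisphere,
    )


def hemisphere_average(
    region: str,
    mouse_id: str,
    left: SpotSet | float | None = None,
    right: SpotSet | float | None = None,
) -> RegionCount:
    """Average the two hemispheres' counts; single hemispheres pass through
    with a flag."""

    def unpack(s):
        if s is None:
            return None, None
        if isinstance(s, SpotSet):
            return float(s.count), s.count_density_mm2
        return float(s), None

    l_count, l_dens = unpack(left)
    r_count, r_dens = unpack(right)
    return RegionCount(
        region=region,
        mouse_id=mouse_id,
        left=l_count,
        right=r_count,
        left_density=l_dens,
        right_density=r_dens,
    )


def compare_groups(
    counts_by_group: dict[str, dict[str, list[float]]]
) -> list[TestResult]:
    """Unpaired t test per region between two groups of per-mouse counts.

    ``counts_by_group[group][region]`` is a list of per-mouse values
    (hemisphere-averaged counts or densities).  No multiplicity correction
    is applied across regions, matching the original analysis.
    """
    groups = list(counts_by_group)
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    g1, g2 = groups
    regions = sorted(set(counts_by_group[g1]) & set(counts_by_group[g2]))
    results = []
    for region in regions:
        res = unpaired_t(counts_by_group[g1][region], counts_by_group[g2][region])
        res.comparison = f"{region}: {g1} vs {g2}"
        results.append(res)
    return results
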