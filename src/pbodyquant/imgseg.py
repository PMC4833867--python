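"""Germ-cell segmentation from the membrane (CDH1) channel.

The operator chain follows the original automated image analysis: Gaussian
blur, local (window-mean) thresholding, skeletonization of the membrane
mask, hole filling of the enclosed regions, and filtering of candidate
cells by area and by the standard deviation of the boundary radius.
Cells are recovered as the regions enclosed by the skeletonized membrane
network; regions touching the image border are discarded so partial cells
never enter per-cell statistics.

Coordinates are 0-based ``(row, col)`` with the origin at the top-left;
areas are in px².
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize
from sklearn.base import BaseEstimator

__all__ = [
    "SegConfig",
    "CellLabelMap",
    "CellSummary",
    "GermCellSegmenter",
    "gaussian_blur",
    "local_threshold",
    "membrane_to_cell_masks",
    "radius_profile_sd",
    "segment_germ_cells",
]

# complement labelling uses 4-connectivity so the 8-connected 1-px skeleton
# actually separates inside from outside
_CROSS = ndimage.generate_binary_structure(2, 1)


@dataclass
class SegConfig:
    """Free parameters of the segmentation chain.

    ``threshold_offset`` is in the image's intensity units (a pixel is
    membrane iff it exceeds its local window mean by more than the offset);
    ``max_radius_sd_ratio`` is the scale-free form of the radius-SD filter
    (SD of the boundary radius divided by its mean).  An absolute cutoff in
    px can be used instead via ``max_radius_sd_px``.
    """

    blur_sigma: float = 2.0
    threshold_window_radius: int = 25
    threshold_offset: float = 20.0
    min_area: int = 300
    max_area: int = 50000
    max_radius_sd_ratio: float = 0.15
    max_radius_sd_px: Optional[float] = None

    def validate(self) -> None:
        if self.blur_sigma <= 0:
            raise ValueError("blur_sigma must be > 0")
        if self.threshold_window_radius < 1:
            raise ValueError("threshold_window_radius must be >= 1")
        if not 0 < self.min_area < self.max_area:
            raise ValueError("need 0 < min_area < max_area")
        if self.max_radius_sd_ratio <= 0:
            raise ValueError("max_radius_sd_ratio must be > 0")


@dataclass(frozen=True)
class CellSummary:
    label: int
    area: int
    centroid: tuple[float, float]
    radius_mean: float
    radius_sd: float


@dataclass
class CellLabelMap:
    """Integer-labelled germ-cell segmentation; 0 is background."""

    labels: np.ndarray
    cells: list[CellSummary] = field(default_factory=list)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def label_at(self, centroid: tuple[float, float]) -> int:
        r = int(round(centroid[0]))
        c = int(round(centroid[1]))
        if not (0 <= r < self.labels.shape[0] and 0 <= c < self.labels.shape[1]):
            return 0
        return int(self.labels[r, c])


def _as_image(img: np.ndarray) -> np.ndarray:
    arr = np.asarray(img, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D intensity image")
    if not np.all(np.isfinite(arr)):
        raise ValueError("image contains non-finite values")
    return arr


def gaussian_blur(img: np.ndarray, sigma: float) -> np.ndarray:
    """Isotropic Gaussian blur with reflective boundary (sum-preserving)."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    return ndimage.gaussian_filter(_as_image(img), sigma=sigma, mode="reflect")


def local_threshold(img: np.ndarray, window_radius: int, offset: float) -> np.ndarray:
    """Foreground where the pixel exceeds its local window mean plus ``offset``.

    The window is the square of side ``2 * window_radius + 1`` centred on
    the pixel, with reflective boundary handling.
    """
    arr = _as_image(img)
    if window_radius < 1:
        raise ValueError("window_radius must be >= 1")
    size = 2 * int(window_radius) + 1
    if size > min(arr.shape):
        raise ValueError(
            f"threshold window ({size} px) larger than image {arr.shape}"
        )
    local_mean = ndimage.uniform_filter(arr, size=size, mode="reflect")
    return arr > local_mean + offset


def membrane_to_cell_masks(mask: np.ndarray) -> CellLabelMap:
    """Skeletonize the membrane mask and label the regions it encloses.

    The thresholded membrane is reduced to 1-px-wide boundaries; connected
    components of the complement (4-connectivity) that do not touch the
    image border are the candidate cells — i.e. the holes of the boundary
    network, filled.  An empty mask yields an empty label map.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise ValueError("expected a 2-D boolean mask")
    skel = skeletonize(mask)
    regions, _ = ndimage.label(~skel, structure=_CROSS)
    border = np.unique(
        np.concatenate(
            [regions[0, :], regions[-1, :], regions[:, 0], regions[:, -1]]
        )
    )
    keep = np.setdiff1d(np.unique(regions), np.concatenate([[0], border]))
    labels = np.zeros(mask.shape, dtype=np.int32)
    cells: list[CellSummary] = []
    for new, old in enumerate(keep, start=1):
        region = regions == old
        labels[region] = new
        cells.append(_summarize(region, new))
    return CellLabelMap(labels=labels, cells=cells)


def _summarize(region: np.ndarray, label: int) -> CellSummary:
    area = int(region.sum())
    rr, cc = np.nonzero(region)
    centroid = (float(rr.mean()), float(cc.mean()))
    boundary = region & ~ndimage.binary_erosion(region, structure=_CROSS)
    br, bc = np.nonzero(boundary)
    if len(br) >= 8:
        mean_r, sd_r = radius_profile_sd(np.column_stack([br, bc]), centroid)
    else:  # tiny region; treat as maximally irregular so filters drop it
        mean_r, sd_r = float(np.hypot(br - centroid[0], bc - centroid[1]).mean() or 1.0), np.inf
    return CellSummary(label=label, area=area, centroid=centroid,
                       radius_mean=mean_r, radius_sd=sd_r)


def radius_profile_sd(
    boundary: np.ndarray, centroid: tuple[float, float]
) -> tuple[float, float]:
    """Mean and SD of the boundary radius about the centroid.

    ``boundary`` is an (n, 2) array of (row, col) boundary pixels; the
    radius is the Euclidean distance from the centroid to each of them.
    Needs at least 8 boundary pixels to say anything about roundness.
    """
    pts = np.asarray(boundary, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 8:
        raise ValueError("need an (n>=8, 2) array of boundary pixels")
    radii = np.hypot(pts[:, 0] - centroid[0], pts[:, 1] - centroid[1])
    return float(radii.mean()), float(radii.std(ddof=1))


class GermCellSegmenter(BaseEstimator):
    """Segment germ cells from a membrane-stained channel.

    A stateless scikit-learn-style transformer over 2-D intensity images:
    ``transform`` maps a membrane image to an integer label map (0 =
    background, 1..N = cells), and ``fit`` additionally stores the rich
    :class:`CellLabelMap` of the fitted image as ``labelmap_``.

    Parameters mirror :class:`SegConfig`; see there for semantics.
    """

    def __init__(
        self,
        blur_sigma: float = 2.0,
        threshold_window_radius: int = 25,
        threshold_offset: float = 20.0,
        min_area: int = 300,
        max_area: int = 50000,
        max_radius_sd_ratio: float = 0.15,
        max_radius_sd_px: Optional[float] = None,
    ):
        self.blur_sigma = blur_sigma
        self.threshold_window_radius = threshold_window_radius
        self.threshold_offset = threshold_offset
        self.min_area = min_area
        self.max_area = max_area
        self.max_radius_sd_ratio = max_radius_sd_ratio
        self.max_radius_sd_px = max_radius_sd_px

    def _config(self) -> SegConfig:
        cfg = SegConfig(**self.get_params())
        cfg.validate()
        return cfg

    def segment(self, img: np.ndarray) -> CellLabelMap:
        """Run the full chain and return the filtered, relabelled map."""
        cfg = self._config()
        blurred = gaussian_blur(img, cfg.blur_sigma)
        mask = local_threshold(blurred, cfg.threshold_window_radius, cfg.threshold_offset)
        candidates = membrane_to_cell_masks(mask)
        labels = np.zeros_like(candidates.labels)
        cells: list[CellSummary] = []
        for cell in candidates.cells:
            if not cfg.min_area <= cell.area <= cfg.max_area:
                continue
            if cfg.max_radius_sd_px is not None:
                if cell.radius_sd > cfg.max_radius_sd_px:
                    continue
            elif cell.radius_sd > cfg.max_radius_sd_ratio * cell.radius_mean:
                continue
            new = len(cells) + 1
            labels[candidates.labels == cell.label] = new
            cells.append(CellSummary(new, cell.area, cell.centroid,
                                     cell.radius_mean, cell.radius_sd))
        return CellLabelMap(labels=labels, cells=cells)

    def fit(self, X: np.ndarray, y=None) -> "GermCellSegmenter":
        self.labelmap_ = self.segment(X)
        self.n_cells_ = self.labelmap_.n_cells
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return self.segment(X).labels

    def fit_transform(self, X: np.ndarray, y=None) -> np.ndarray:
        self.fit(X)
        return self.labelmap_.labels


def segment_germ_cells(membrane: np.ndarray, cfg: Optional[SegConfig] = None) -> CellLabelMap:
    """Functional wrapper over :class:`GermCellSegmenter`."""
    cfg = cfg or SegConfig()
    cfg.validate()
    est = GermCellSegmenter(
        blur_sigma=cfg.blur_sigma,
        threshold_window_radius=cfg.threshold_window_radius,
        threshold_offset=cfg.threshold_offset,
        min_area=cfg.min_area,
        max_area=cfg.max_area,
        max_radius_sd_ratio=cfg.max_radius_sd_ratio,
        max_radius_sd_px=cfg.max_radius_sd_px,
    )
    return est.segment(membrane)
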