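"""Label-free cell detection and cropping from grayscale field images.

The pipeline standardizes a phase-contrast (or bright-field) frame into
100x100 single-cell crops:

    contrast stretch -> 5x5 adaptive (Wiener) filter -> grayscale dilation ->
    global Otsu binarization -> hole fill -> small-object (debris) removal ->
    erosion + minimum-area filter -> duplicate suppression -> centroid crops

Two size cuts are applied: components smaller than ``debris_side**2`` px^2
before erosion are debris; components smaller than ``min_object_area`` px^2
after erosion are likewise dropped. Objects whose crop window would leave the
image are edge-rejected; among near-coincident detections only the largest
survives. Every object receives exactly one terminal status, so detection
counts are conserved across the pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np
import tifffile
from scipy.ndimage import binary_fill_holes
from scipy.signal import wiener
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.morphology import dilation, disk, erosion
from skimage.transform import resize


class DetectionStatus(str, Enum):
    KEPT = "kept"
    EDGE_REJECTED = "edge_rejected"
    DUPLICATE_MERGED = "duplicate_merged"
    DEBRIS_REMOVED = "debris_removed"

    def __str__(self) -> str:
        return self.value


@dataclass
class FieldImage:
    """One grayscale frame with its nominal objective magnification."""

    pixels: np.ndarray
    magnification: str = "20x"
    source_id: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("FieldImage expects a single-channel 2-D image")
        if self.magnification not in ("10x", "20x"):
            raise ValueError("magnification must be '10x' or '20x'")

    @classmethod
    def from_tiff(cls, path: str | Path, magnification: str = "20x") -> "FieldImage":
        return cls(
            pixels=tifffile.imread(path),
            magnification=magnification,
            source_id=Path(path).name,
        )

    def to_tiff(self, path: str | Path) -> None:
        tifffile.imwrite(path, np.asarray(self.pixels, dtype=np.uint16))


@dataclass(frozen=True)
class SegmentationParams:
    filter_window: int = 5
    dilation_radius: int = 2
    erosion_radius: int = 3
    min_object_area: int = 2000  # px^2, applied after erosion
    debris_side: int = 30  # 30x30 px -> 900 px^2, applied before erosion
    crop_size: int = 100
    duplicate_distance: float = 30.0
    contrast_clip_percent: float = 1.0

    def __post_init__(self):
        if self.filter_window % 2 != 1 or self.filter_window < 3:
            raise ValueError("filter_window must be odd and >= 3")
        if self.crop_size % 2 != 0 or self.crop_size < self.debris_side:
            raise ValueError("crop_size must be even and >= debris_side")
        if self.dilation_radius < 1 or self.erosion_radius < 1:
            raise ValueError("structuring-element radii must be >= 1")


@dataclass
class DetectionRecord:
    centroid: tuple[float, float]  # (row, col)
    area: float  # px^2 of the eroded component (0 if eroded away)
    bounding_box: tuple[int, int, int, int]  # (row0, col0, row1, col1), half-open
    status: DetectionStatus


@dataclass
class CellCrop:
    """A crop_size x crop_size patch cut from the original field pixels."""

    pixels: np.ndarray
    source_id: str
    detection: DetectionRecord


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def adjust_contrast(
    image: np.ndarray, clip_percent: float = 1.0
) -> np.ndarray:
    """Linear stretch mapping the clip percentiles onto the full 16-bit range.

    Monotone non-decreasing; a constant image is returned unchanged with a
    warning. Returns float64 in [0, 65535].
    """
    img = np.asarray(image, dtype=np.float64)
    lo = np.percentile(img, clip_percent)
    hi = np.percentile(img, 100.0 - clip_percent)
    if hi <= lo:
        warnings.warn("constant (or near-constant) image: contrast left unchanged")
        return img
    out = (img - lo) * (65535.0 / (hi - lo))
    return np.clip(out, 0.0, 65535.0)


def adaptive_filter(image: np.ndarray, window: int = 5) -> np.ndarray:
    """Local adaptive (Wiener) noise suppression over window x window
    neighbourhoods, with the noise power estimated as the mean local variance."""
    if window % 2 != 1 or window < 3:
        raise ValueError("window must be odd and >= 3")
    img = np.asarray(image, dtype=np.float64)
    if np.ptp(img) == 0:
        return img.copy()
    with warnings.catch_warnings():
        # wiener emits a divide warning on locally constant patches
        warnings.simplefilter("ignore")
        out = wiener(img, mysize=window)
    return np.nan_to_num(out, nan=0.0)


def binarize_and_fill(
    image: np.ndarray, dilation_radius: int = 2, noise_floor_factor: float = 4.0
) -> np.ndarray:
    """Grayscale dilation (closing rim gaps), global Otsu threshold, hole fill.

    Cells in phase contrast deviate from the mid-gray background in both
    directions (bright rims and halos, dark flattened bodies), so the
    threshold is computed on the absolute deviation from the median
    background rather than on raw intensity -- a raw global threshold is
    bistable when dark and bright cells coexist in one frame. The deviation
    image is grayscale-dilated (closing 1-2 px rim gaps), Otsu-thresholded,
    and hole-filled, so a cell drawn as a closed boundary becomes one solid
    component.

    If the Otsu threshold does not clear ``noise_floor_factor`` robust
    standard deviations of the background, the frame is treated as empty
    (warning; all-background result), which keeps pure-noise frames from
    binarizing into speckle.
    """
    img = np.asarray(image, dtype=np.float64)
    dev = np.abs(img - np.median(img))
    dilated = dilation(dev, disk(dilation_radius))
    if np.ptp(dilated) == 0:
        warnings.warn("flat image after dilation: no objects detected")
        return np.zeros(img.shape, dtype=bool)
    sigma_bg = 1.4826 * np.median(dev)  # MAD estimate of background noise
    thresh = threshold_otsu(dilated)
    if thresh < noise_floor_factor * sigma_bg:
        warnings.warn("no structure above the background noise floor: empty mask")
        return np.zeros(img.shape, dtype=bool)
    mask = dilated > thresh
    if mask.all() or not mask.any():
        warnings.warn("degenerate binarization (all fore/background): empty mask")
        return np.zeros(img.shape, dtype=bool)
    return binary_fill_holes(mask)


def erode_and_filter(
    mask: np.ndarray, params: SegmentationParams = SegmentationParams()
) -> tuple[np.ndarray, list[DetectionRecord]]:
    """Erode, apply both debris cuts, and measure surviving components.

    Returns (labeled image of surviving eroded components, records), where
    records include a ``debris_removed`` entry for every object that fell to
    either size cut (pre-erosion < debris_side^2, post-erosion <
    min_object_area, or eroded away entirely).
    """
    mask = np.asarray(mask, dtype=bool)
    records: list[DetectionRecord] = []
    pre_labels = cc_label(mask, connectivity=2)
    keep_pre = np.zeros(pre_labels.max() + 1, dtype=bool)
    for region in regionprops(pre_labels):
        if region.area < params.debris_side**2:
            r0, c0, r1, c1 = region.bbox
            records.append(
                DetectionRecord(
                    centroid=tuple(region.centroid),
                    area=0.0,
                    bounding_box=(r0, c0, r1, c1),
                    status=DetectionStatus.DEBRIS_REMOVED,
                )
            )
        else:
            keep_pre[region.label] = True
    surviving_pre = keep_pre[pre_labels]

    eroded = erosion(surviving_pre, disk(params.erosion_radius))
    post_labels = cc_label(eroded, connectivity=2)

    # account for pre-erosion objects that vanished entirely (checked on the
    # component's own pixels: bounding boxes of distinct objects can overlap)
    for region in regionprops(pre_labels):
        if keep_pre[region.label]:
            r0, c0, r1, c1 = region.bbox
            window = (slice(r0, r1), slice(c0, c1))
            own = pre_labels[window] == region.label
            if not post_labels[window][own].any():
                records.append(
                    DetectionRecord(
                        centroid=tuple(region.centroid),
                        area=0.0,
                        bounding_box=(r0, c0, r1, c1),
                        status=DetectionStatus.DEBRIS_REMOVED,
                    )
                )

    keep_post = np.zeros(post_labels.max() + 1, dtype=bool)
    for region in regionprops(post_labels):
        r0, c0, r1, c1 = region.bbox
        rec = DetectionRecord(
            centroid=tuple(region.centroid),
            area=float(region.area),
            bounding_box=(r0, c0, r1, c1),
            status=DetectionStatus.KEPT,
        )
        if region.area < params.min_object_area:
            rec.status = DetectionStatus.DEBRIS_REMOVED
            rec.area = float(region.area)
        else:
            keep_post[region.label] = True
        records.append(rec)
    labeled = keep_post[post_labels] * post_labels
    return labeled, records


def suppress_duplicates(
    detections: list[DetectionRecord], duplicate_distance: float = 30.0
) -> list[DetectionRecord]:
    """Among mutually close candidates keep only the largest-area detection.

    Candidates are visited by decreasing area (ties broken by (row, col));
    a candidate within ``duplicate_distance`` of an already-kept centroid is
    demoted to ``duplicate_merged``. Non-candidate records pass through.
    Mutates statuses in place and returns the same list.
    """
    candidates = [d for d in detections if d.status is DetectionStatus.KEPT]
    order = sorted(candidates, key=lambda d: (-d.area, d.centroid[0], d.centroid[1]))
    kept: list[DetectionRecord] = []
    for det in order:
        close = any(
            np.hypot(det.centroid[0] - k.centroid[0], det.centroid[1] - k.centroid[1])
            < duplicate_distance
            for k in kept
        )
        if close:
            det.status = DetectionStatus.DUPLICATE_MERGED
        else:
            kept.append(det)
    return detections


def crop_at_centroid(
    image: np.ndarray,
    detection: DetectionRecord,
    crop_size: int = 100,
    source_id: str = "",
) -> CellCrop | None:
    """Half-open crop window [r-s/2, r+s/2) x [c-s/2, c+s/2) at the rounded
    centroid; if it exceeds the image bounds the detection is edge-rejected
    and None is returned."""
    img = np.asarray(image)
    half = crop_size // 2
    # round-half-up to integer pixel
    r = int(np.floor(detection.centroid[0] + 0.5))
    c = int(np.floor(detection.centroid[1] + 0.5))
    r0, c0 = r - half, c - half
    r1, c1 = r0 + crop_size, c0 + crop_size
    if r0 < 0 or c0 < 0 or r1 > img.shape[0] or c1 > img.shape[1]:
        detection.status = DetectionStatus.EDGE_REJECTED
        return None
    return CellCrop(
        pixels=img[r0:r1, c0:c1].copy(),
        source_id=source_id,
        detection=detection,
    )


def detect_and_crop(
    image: FieldImage | np.ndarray,
    params: SegmentationParams = SegmentationParams(),
) -> tuple[list[CellCrop], list[DetectionRecord]]:
    """Full pipeline: field image in, single-cell crops + status ledger out."""
    if isinstance(image, FieldImage):
        pixels, source_id = image.pixels, image.source_id
    else:
        pixels, source_id = np.asarray(image), ""
    adjusted = adjust_contrast(pixels, params.contrast_clip_percent)
    filtered = adaptive_filter(adjusted, params.filter_window)
    mask = binarize_and_fill(filtered, params.dilation_radius)
    _, records = erode_and_filter(mask, params)
    suppress_duplicates(records, params.duplicate_distance)
    crops = []
    for det in records:
        if det.status is DetectionStatus.KEPT:
            crop = crop_at_centroid(pixels, det, params.crop_size, source_id)
            if crop is not None:
                crops.append(crop)
    return crops, records


def resize_to_reference_magnification(image: FieldImage) -> FieldImage:
    """Upscale a 10x frame 2x (bilinear) so it matches the 20x reference
    scale; 20x input is returned unchanged."""
    if image.magnification == "20x":
        return image
    rows, cols = image.pixels.shape
    out = resize(
        image.pixels.astype(np.float64),
        (2 * rows, 2 * cols),
        order=1,
        preserve_range=True,
        anti_aliasing=False,
    )
    return FieldImage(
        pixels=np.clip(np.rint(out), 0, 65535).astype(np.uint16),
        magnification="20x",
        source_id=image.source_id,
    )


def detections_to_frame(records: list[DetectionRecord], source_id: str = ""):
    """Detections table: one row per record (CSV-friendly)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "source_id": source_id,
                "row": d.centroid[0],
                "col": d.centroid[1],
                "area": d.area,
                "status": d.status.value,
            }
            for d in records
        ]
    )
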