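"""Microscope-frame analysis: tip localization, cell detection, contact.

Tip localization follows background subtraction: the background model is
either supplied or the per-pixel temporal median of the stack; the
residual is Otsu-thresholded, the largest connected component is taken as
the probe, and the tip is the component's extreme point along its axis.

Contact detection uses a motion history image (MHI): pixels refreshed by
inter-frame change hold ``mhi_max`` and decay otherwise; the pixel mean
value (PMV) over a region of interest around the tip exceeding 1 signals
contact-induced membrane motion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import ndimage
from skimage import filters, measure, morphology, segmentation

__all__ = [
    "ImageStack",
    "TipEstimate",
    "CellDetection",
    "ContactVerdict",
    "NoTipError",
    "locate_tip",
    "detect_cells",
    "motion_history",
    "contact_pmv",
    "MHI_MAX",
    "DIFF_THRESHOLD",
    "DECAY",
]

MHI_MAX = 255.0
DIFF_THRESHOLD = 10.0 / 255.0   # on 0-1 intensity frames
DECAY = 25.5                    # MHI units per frame


class NoTipError(RuntimeError):
    pass


@dataclass
class ImageStack:
    """T x H x W grayscale frames with intensities in [0, 1]."""

    frames: np.ndarray
    frame_rate: float = 20.0     # Hz
    pixel_size: float = 0.5      # um / px

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be T x H x W")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")

    def __len__(self) -> int:
        return len(self.frames)

    def save(self, path) -> None:
        import tifffile
        arr = np.clip(self.frames * 65535, 0, 65535).astype(np.uint16)
        tifffile.imwrite(path, arr, photometric="minisblack")

    @classmethod
    def load(cls, path, frame_rate: float = 20.0, pixel_size: float = 0.5) -> "ImageStack":
        import tifffile
        arr = np.atleast_3d(tifffile.imread(path))
        if arr.ndim == 2:
            arr = arr[None]
        arr = arr.astype(float)
        if arr.max() > 1.0:
            arr /= 65535.0 if arr.max() > 255 else 255.0
        return cls(frames=arr, frame_rate=frame_rate, pixel_size=pixel_size)


@dataclass
class TipEstimate:
    position: tuple          # (x, y) px
    axis_angle: float        # degrees
    confidence: float        # 0-1


@dataclass
class CellDetection:
    contour: np.ndarray              # (N, 2) xy px, closed polygon
    nucleus_contour: np.ndarray      # (M, 2) xy px
    centroid: tuple                  # (x, y) px
    adherent: Optional[bool] = None  # ground truth when available


@dataclass
class ContactVerdict:
    mhi: np.ndarray          # final H x W map
    pmv: float
    contact: bool
    t_contact: Optional[float] = None   # s

    def __post_init__(self) -> None:
        if self.pmv < 0:
            raise ValueError("pmv must be >= 0")


def locate_tip(stack: ImageStack, background: Optional[np.ndarray] = None,
               frame_index: int = -1) -> TipEstimate:
    """Find the probe tip by background subtraction on one frame.

    Without a supplied background, the temporal median over the stack is
    used (needs >= 11 frames).  The residual is Otsu-thresholded; the
    largest connected component is the probe and the tip is its extreme
    point along the component axis, on the side facing the frame interior.
    """
    if len(stack) < 1:
        raise ValueError("need at least one frame")
    frame = stack.frames[frame_index]
    if background is None:
        if len(stack) < 11:
            raise ValueError("temporal-median background needs >= 11 frames")
        background = np.median(stack.frames, axis=0)
    residual = np.abs(frame - background)
    if residual.max() <= 1e-12:
        raise NoTipError("residual is empty: frame equals background")
    thr = filters.threshold_otsu(residual)
    mask = residual > thr
    mask = morphology.remove_small_objects(mask, max_size=8)
    labels = measure.label(mask)
    if labels.max() == 0:
        raise NoTipError("no component above threshold")
    props = measure.regionprops(labels)
    probe = max(props, key=lambda p: p.area)

    angle = float(np.degrees(probe.orientation))
    ys, xs = np.nonzero(labels == probe.label)
    pts = np.column_stack([xs, ys]).astype(float)
    # axis direction from orientation (skimage: angle of major axis vs rows)
    theta = probe.orientation
    axis = np.array([np.sin(theta), np.cos(theta)])  # (dx, dy) in xy
    proj = pts @ axis
    p_lo = pts[int(np.argmin(proj))]
    p_hi = pts[int(np.argmax(proj))]
    h, w = frame.shape

    def border_dist(p):
        return min(p[0], w - 1 - p[0], p[1], h - 1 - p[1])

    tip = p_hi if border_dist(p_hi) > border_dist(p_lo) else p_lo
    conf = float(min(1.0, probe.area / mask.sum())) if mask.sum() else 0.0
    return TipEstimate(position=(float(tip[0]), float(tip[1])),
                       axis_angle=angle, confidence=conf)


def _mask_to_contour(mask: np.ndarray) -> np.ndarray:
    """Largest closed contour of a binary mask as (N, 2) xy points (CCW)."""
    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        return np.zeros((0, 2))
    c = max(contours, key=len)           # rows, cols
    return c[:, ::-1]                    # -> x, y


def default_cell_detector(frame: np.ndarray) -> list:
    """Classical fallback: band-pass, threshold, watershed split.

    Cells render brighter than background with darker nuclei; touching
    cells are split by a distance-transform watershed.
    """
    if frame.size == 0:
        return []
    smooth = filters.gaussian(frame, sigma=2)
    bg = filters.gaussian(frame, sigma=25)
    band = smooth - bg
    if band.max() - band.min() < 1e-6:
        return []
    thr = filters.threshold_otsu(band)
    mask = band > thr
    mask = morphology.remove_small_objects(mask, max_size=64)
    mask = ndimage.binary_fill_holes(mask)
    if not mask.any():
        return []
    dist = ndimage.distance_transform_edt(mask)
    peaks = morphology.h_maxima(dist, h=3)
    markers = measure.label(peaks)
    if markers.max() == 0:
        markers = measure.label(mask)
    labels = segmentation.watershed(-dist, markers, mask=mask)

    detections = []
    for p in measure.regionprops(labels):
        if p.area < 100:
            continue
        cell_mask = labels == p.label
        contour = _mask_to_contour(cell_mask)
        if len(contour) < 4:
            continue
        # nucleus: darker-than-cytoplasm region inside the cell
        vals = smooth[cell_mask]
        nuc_thr = np.percentile(vals, 25)
        nuc_mask = cell_mask & (smooth < nuc_thr)
        nuc_mask = morphology.remove_small_objects(nuc_mask, max_size=16)
        nlabels = measure.label(nuc_mask)
        if nlabels.max() > 0:
            nprops = max(measure.regionprops(nlabels), key=lambda q: q.area)
            nuc_contour = _mask_to_contour(nlabels == nprops.label)
        else:
            nuc_contour = np.zeros((0, 2))
        cy, cx = p.centroid
        detections.append(CellDetection(contour=contour, nucleus_contour=nuc_contour,
                                        centroid=(float(cx), float(cy))))
    return detections


def detect_cells(frame: np.ndarray,
                 detector: Optional[Callable[[np.ndarray], list]] = None) -> list:
    """Detect cells on a single frame with a pluggable detector.

    The default is the classical fallback; a learned model with the same
    ``frame -> list[CellDetection]`` signature can be plugged in.
    """
    detector = detector or default_cell_detector
    return detector(np.asarray(frame, dtype=float))


def motion_history(stack: ImageStack, diff_threshold: float = DIFF_THRESHOLD,
                   decay: float = DECAY, mhi_max: float = MHI_MAX) -> np.ndarray:
    """Motion-history-image sequence, one map per frame pair.

    Per pixel: refreshed to ``mhi_max`` when the absolute inter-frame
    difference exceeds ``diff_threshold``, else decremented by ``decay``
    (floored at 0).  Returns an array of shape (T-1, H, W).
    """
    frames = stack.frames
    if len(frames) < 2:
        raise ValueError("need at least 2 frames")
    out = np.empty((len(frames) - 1,) + frames.shape[1:])
    mhi = np.zeros(frames.shape[1:])
    for t in range(1, len(frames)):
        moved = np.abs(frames[t] - frames[t - 1]) > diff_threshold
        mhi = np.where(moved, mhi_max, np.maximum(0.0, mhi - decay))
        out[t - 1] = mhi
    return out


def contact_pmv(mhi_sequence: np.ndarray, roi_center: tuple, roi_half: int = 10,
                threshold: float = 1.0, frame_rate: float = 20.0,
                sustain: int = 3) -> ContactVerdict:
    """PMV contact verdict over an ROI around the tip estimate.

    ``pmv`` is the largest ROI-mean MHI value over the sequence; contact is
    declared at the first frame where ``pmv > threshold`` holds for
    ``sustain`` consecutive frames.
    """
    mhi_sequence = np.asarray(mhi_sequence, dtype=float)
    if mhi_sequence.ndim != 3:
        raise ValueError("mhi_sequence must be T x H x W")
    h, w = mhi_sequence.shape[1:]
    x, y = int(round(roi_center[0])), int(round(roi_center[1]))
    x0, x1 = x - roi_half, x + roi_half + 1
    y0, y1 = y - roi_half, y + roi_half + 1
    if x0 < 0 or y0 < 0 or x1 > w or y1 > h:
        raise ValueError("ROI outside frame")
    pmvs = mhi_sequence[:, y0:y1, x0:x1].mean(axis=(1, 2))

    contact = False
    t_contact = None
    run = 0
    for t, v in enumerate(pmvs):
        run = run + 1 if v > threshold else 0
        if run >= sustain:
            contact = True
            t_contact = (t - sustain + 2) / frame_rate  # first frame of the run
            break
    return ContactVerdict(mhi=mhi_sequence[-1], pmv=float(pmvs.max()),
                          contact=contact, t_contact=t_contact)
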