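"""Mask construction for DRG section analysis.

Implements the mask algebra the per-neuron MHCII / RFX1 and T-cell density
quantifications are built from: the neuron-containing tissue mask, single
neuron instances (with nerve-fibre rejection), high-intensity non-neuronal
MHCII cells, nuclei, and the Shrink / Grow border operations with their
logical (set-difference) combination.

Shrink and Grow use a Euclidean disc structuring element of the stated
radius, so "decrease/expand the borders by N pixels" is isotropic.  Pixels
outside the frame count as background.
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np
from scipy import ndimage
from skimage import filters, measure, morphology

from .image_io import ImageIOError, ImageStack, LabelMap

logger = logging.getLogger(__name__)

Threshold = float | str  # absolute AFU or "otsu"


@dataclasses.dataclass
class SegmentationParams:
    """Tunable parameters for every masking stage.

    Size gates are given as equivalent diameters in μm and converted to
    pixel areas with the stack's ``pixel_area_um2``; explicit pixel-area
    overrides win when set.  Intensity thresholds left symbolic default to
    Otsu's method on the relevant channel and may be overridden with an
    absolute AFU value.
    """

    # tissue mask
    tissue_smooth_sigma: float = 3.0
    tissue_threshold: Threshold = "otsu"
    # neuron instances
    neuron_marker_threshold: Threshold = "otsu"
    neuron_marker_min_mpi: float = 0.0
    neuron_min_diam_um: float = 8.0
    neuron_max_diam_um: float = 60.0
    neuron_min_area_px: float | None = None
    neuron_max_area_px: float | None = None
    fiber_eccentricity_max: float = 0.97
    fiber_aspect_max: float = 5.0
    # border morphology
    shrink_px: int = 4
    grow_px: int = 7
    # non-neuronal MHCII cells
    nonneuronal_mhcii_min: float = 25_000.0
    immune_min_diam_um: float = 5.0
    immune_max_diam_um: float = 15.0
    immune_cell_min_area_px: float | None = None
    immune_cell_max_area_px: float | None = None
    # T cells
    cd3_threshold: Threshold = "otsu"
    cd4_threshold: Threshold = "otsu"
    cd3_min_mpi: float = 0.0
    cd4_min_mpi: float = 0.0
    cd4_overlap_frac: float = 0.5
    # nuclei
    dapi_threshold: Threshold = "otsu"
    dapi_min_mpi: float = 0.0
    nucleus_min_diam_um: float = 4.0
    nucleus_max_diam_um: float = 15.0
    nucleus_min_area_px: float | None = None
    nucleus_max_area_px: float | None = None
    # connectivity: 8-connected everywhere, fixed for determinism
    connectivity: int = 8

    def __post_init__(self) -> None:
        if self.shrink_px < 0 or self.grow_px < 0:
            raise ValueError("shrink_px and grow_px must be >= 0")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        for lo, hi, name in (
            (self.neuron_min_diam_um, self.neuron_max_diam_um, "neuron"),
            (self.immune_min_diam_um, self.immune_max_diam_um, "immune"),
            (self.nucleus_min_diam_um, self.nucleus_max_diam_um, "nucleus"),
        ):
            if not lo < hi:
                raise ValueError(f"{name} size gate requires min < max")

    def _area_bounds(self, lo_um, hi_um, lo_px, hi_px, pixel_area_um2):
        lo = lo_px if lo_px is not None else math.pi * (lo_um / 2) ** 2 / pixel_area_um2
        hi = hi_px if hi_px is not None else math.pi * (hi_um / 2) ** 2 / pixel_area_um2
        return lo, hi

    def neuron_area_bounds_px(self, pixel_area_um2: float) -> tuple[float, float]:
        return self._area_bounds(
            self.neuron_min_diam_um, self.neuron_max_diam_um,
            self.neuron_min_area_px, self.neuron_max_area_px, pixel_area_um2)

    def immune_area_bounds_px(self, pixel_area_um2: float) -> tuple[float, float]:
        return self._area_bounds(
            self.immune_min_diam_um, self.immune_max_diam_um,
            self.immune_cell_min_area_px, self.immune_cell_max_area_px, pixel_area_um2)

    def nucleus_area_bounds_px(self, pixel_area_um2: float) -> tuple[float, float]:
        return self._area_bounds(
            self.nucleus_min_diam_um, self.nucleus_max_diam_um,
            self.nucleus_min_area_px, self.nucleus_max_area_px, pixel_area_um2)


def _skimage_connectivity(connectivity: int) -> int:
    return 2 if connectivity == 8 else 1


def resolve_threshold(arr: np.ndarray, spec: Threshold) -> float:
    """Resolve a threshold spec to an AFU value.

    ``"otsu"`` uses Otsu's method; a constant image has no foreground and
    resolves to +inf so the resulting mask is empty.
    """
    if isinstance(spec, str):
        if spec != "otsu":
            raise ValueError(f"unknown threshold spec {spec!r}")
        arr = np.asarray(arr)
        if arr.max() == arr.min():
            return math.inf
        return float(filters.threshold_otsu(arr))
    return float(spec)


def tissue_mask(stack: ImageStack, params: SegmentationParams,
                channel: str = "PGP9.5") -> LabelMap:
    """Binary mask of neuron-containing tissue.

    The neuron-marker channel is Gaussian-smoothed, thresholded and
    hole-filled; the mask depends only on that channel.
    """
    ch = stack.channel(channel).astype(float)
    sm = ndimage.gaussian_filter(ch, sigma=params.tissue_smooth_sigma)
    thr = resolve_threshold(sm, params.tissue_threshold)
    mask = sm >= thr
    mask = ndimage.binary_fill_holes(mask)
    return LabelMap(mask.astype(np.int32), class_name="tissue")


def _component_table(bw: np.ndarray, intensity: np.ndarray, connectivity: int):
    lab = measure.label(bw, connectivity=_skimage_connectivity(connectivity))
    props = measure.regionprops(lab, intensity_image=intensity)
    return lab, props


def _is_fiber(region, params: SegmentationParams) -> bool:
    """Shape criterion for nerve-fibre rejection.

    Fibres are long thin ribbons: eccentricity close to 1, or a skeleton
    much longer than the component's mean width.
    """
    if region.eccentricity > params.fiber_eccentricity_max:
        return True
    skel = morphology.skeletonize(region.image)
    length = int(skel.sum())
    if length == 0:
        return False
    mean_width = region.area / length
    return length / mean_width > params.fiber_aspect_max


def neuron_instances(stack: ImageStack, params: SegmentationParams,
                     channel: str = "PGP9.5") -> LabelMap:
    """Single-neuron instances from the neuron-marker channel.

    Connected components of supra-threshold signal, gated by area (size)
    and mean intensity, with elongated fibre-like components removed.
    Labels are contiguous 1..K in scan order.
    """
    ch = stack.channel(channel).astype(float)
    thr = resolve_threshold(ch, params.neuron_marker_threshold)
    bw = ch >= thr
    lab, props = _component_table(bw, ch, params.connectivity)
    lo, hi = params.neuron_area_bounds_px(stack.pixel_area_um2)
    out = np.zeros_like(lab, dtype=np.int32)
    k = 0
    for region in props:
        if not (lo <= region.area <= hi):
            continue
        if region.intensity_mean < params.neuron_marker_min_mpi:
            continue
        if _is_fiber(region, params):
            logger.info("neuron_instances: dropped fibre-like component at %s "
                        "(area=%d, ecc=%.3f)", region.centroid, region.area,
                        region.eccentricity)
            continue
        k += 1
        rr, cc = region.coords[:, 0], region.coords[:, 1]
        out[rr, cc] = k
    return LabelMap(out, class_name="neuron")


def _erode_instance(mask: np.ndarray, k: int) -> np.ndarray:
    """Erosion by the Euclidean disc of radius k (out-of-frame = background).

    A pixel survives iff every pixel within Euclidean distance <= k lies in
    the instance, which equals ``edt(mask) > k`` on a zero-padded frame.
    """
    padded = np.pad(mask, 1, constant_values=False)
    dist = ndimage.distance_transform_edt(padded)
    return (dist > k)[1:-1, 1:-1]


def shrink_mask(labels: LabelMap, k: int) -> LabelMap:
    """Decrease each instance's borders by ``k`` pixels (disc erosion).

    Each instance is eroded independently; instances eroded to extinction
    are dropped with a log entry.  Surviving instances keep their ids.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if k == 0:
        return labels.copy()
    out = np.zeros_like(labels.labels)
    objects = ndimage.find_objects(labels.labels)
    for idx, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        eroded = _erode_instance(_with_margin(labels.labels, sl, idx, k), k)
        if not eroded.any():
            logger.info("shrink_mask: instance %d eroded to extinction at k=%d",
                        idx, k)
            continue
        rr, cc = np.nonzero(eroded)
        r0, c0 = _margin_origin(labels.labels.shape, sl, k)
        out[rr + r0, cc + c0] = idx
    return LabelMap(out, class_name=labels.class_name)


def _margin_origin(shape, sl, k):
    r0 = max(sl[0].start - (k + 1), 0)
    c0 = max(sl[1].start - (k + 1), 0)
    return r0, c0


def _with_margin(labels: np.ndarray, sl, idx: int, k: int) -> np.ndarray:
    """Instance mask on its bounding box expanded by k+1 px (clipped to frame)."""
    r0 = max(sl[0].start - (k + 1), 0)
    r1 = min(sl[0].stop + (k + 1), labels.shape[0])
    c0 = max(sl[1].start - (k + 1), 0)
    c1 = min(sl[1].stop + (k + 1), labels.shape[1])
    return labels[r0:r1, c0:c1] == idx


def grow_mask(labels: LabelMap, k: int) -> LabelMap:
    """Expand each instance's borders by ``k`` pixels (disc dilation).

    Where grown instances would overlap, pixels go to the nearest seed
    instance (smallest label wins exact distance ties).
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if k == 0:
        return labels.copy()
    arr = labels.labels
    ids = np.unique(arr)
    ids = ids[ids > 0]
    if ids.size == 0:
        return labels.copy()
    best_dist = np.full(arr.shape, np.inf)
    winner = np.zeros_like(arr)
    for idx in ids:  # ascending: later ids replace only on strictly smaller distance
        dist = ndimage.distance_transform_edt(arr != idx)
        take = dist < best_dist
        best_dist[take] = dist[take]
        winner[take] = idx
    out = np.where(best_dist <= k, winner, 0)
    return LabelMap(out.astype(arr.dtype), class_name=labels.class_name)


def nonneuronal_mhcii_mask(stack: ImageStack, params: SegmentationParams,
                           channel: str = "MHCII") -> LabelMap:
    """High-intensity non-neuronal MHCII⁺ cells (immune cells).

    Components of MHCII signal at or above ``nonneuronal_mhcii_min`` AFU
    with areas inside the immune-cell size gate.
    """
    ch = stack.channel(channel).astype(float)
    bw = ch >= params.nonneuronal_mhcii_min
    lab, props = _component_table(bw, ch, params.connectivity)
    lo, hi = params.immune_area_bounds_px(stack.pixel_area_um2)
    out = np.zeros_like(lab, dtype=np.int32)
    k = 0
    for region in props:
        if lo <= region.area <= hi:
            k += 1
            rr, cc = region.coords[:, 0], region.coords[:, 1]
            out[rr, cc] = k
    return LabelMap(out, class_name="immune")


def exclude_overlap(neurons: LabelMap, exclusion: LabelMap) -> LabelMap:
    """Per-pixel set difference: remove neuron pixels covered by the exclusion mask.

    Instance ids are preserved; an instance whose pixels are all excluded
    simply has no pixels in the output (callers flag it unmeasurable).
    """
    if neurons.shape != exclusion.shape:
        raise ImageIOError(
            f"shape mismatch: neurons {neurons.shape} vs exclusion {exclusion.shape}")
    out = np.where(exclusion.labels > 0, 0, neurons.labels)
    removed = set(neurons.instance_ids()) - set(np.unique(out[out > 0]))
    for idx in sorted(removed):
        logger.info("exclude_overlap: instance %d fully covered by exclusion mask",
                    idx)
    return LabelMap(out, class_name=neurons.class_name)


def nuclei_instances(stack: ImageStack, neurons: LabelMap,
                     params: SegmentationParams,
                     channel: str = "DAPI") -> tuple[LabelMap, LabelMap]:
    """Split DAPI nuclei into neuronal and non-neuronal populations.

    A size/intensity-gated DAPI component is "neuronal" iff its centroid
    pixel lies inside a neuron instance.  Returns (neuronal, non-neuronal)
    label maps, each relabelled 1..K.
    """
    ch = stack.channel(channel).astype(float)
    thr = resolve_threshold(ch, params.dapi_threshold)
    bw = ch >= thr
    lab, props = _component_table(bw, ch, params.connectivity)
    lo, hi = params.nucleus_area_bounds_px(stack.pixel_area_um2)
    neuronal = np.zeros_like(lab, dtype=np.int32)
    nonneuronal = np.zeros_like(lab, dtype=np.int32)
    kn = km = 0
    for region in props:
        if not (lo <= region.area <= hi):
            continue
        if region.intensity_mean < params.dapi_min_mpi:
            continue
        r, c = (int(round(x)) for x in region.centroid)
        r = min(max(r, 0), lab.shape[0] - 1)
        c = min(max(c, 0), lab.shape[1] - 1)
        rr, cc = region.coords[:, 0], region.coords[:, 1]
        if neurons.labels[r, c] > 0:
            kn += 1
            neuronal[rr, cc] = kn
        else:
            km += 1
            nonneuronal[rr, cc] = km
    return (LabelMap(neuronal, class_name="neuronal nuclei"),
            LabelMap(nonneuronal, class_name="non-neuronal nuclei"))
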