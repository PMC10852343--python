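"""Synthetic DRG-section and cultured-neuron scenes with full ground truth.

The study's raw images are not deposited, so every pipeline stage is
verified by parameter recovery on rendered scenes instead.  A scene
emulates the structure the real sections show: an elliptical patch of
neuron-containing tissue holding a bimodal population of near-circular
somata (small ≤25 μm and large >30 μm equivalent diameter), a fraction of
which carry MHCII signal with sub-cellular puncta; bright compact
non-neuronal immune cells whose MHCII intensity is several-fold the
neuronal level; CD3⁺CD4⁺ T cells; DAPI nuclei (one per soma plus scattered
non-neuronal nuclei) with RFX1 nuclear signal; and additive Gaussian noise
clipped to the container bit depth.  Isotype-control scenes share the exact
geometry of their matched section but carry only noise in the MHCII
channel.  Cultured-neuron scenes render isolated somata whose surface
signal is either uniform or concentrated into a polar cap of known area
fraction and fold change.

Objects are placed by uniform rejection sampling with a minimum gap, so
instances never touch — downstream segmentation is tested without
instance-splitting (a declared non-goal).  Everything is driven by one
integer seed: identical seeds give bitwise-identical scenes.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from scipy import ndimage

from .image_io import ImageStack

_TRUTH_COLUMNS = [
    "object_id", "class", "centroid_row", "centroid_col", "area_px",
    "true_diameter_um", "mhcii_positive", "rfx1_positive", "has_nucleus",
    "n_puncta", "puncta_area_px", "polarized_fraction",
]
_PUNCTA_COLUMNS = ["neuron_id", "centroid_row", "centroid_col", "area_px"]


class PlacementError(RuntimeError):
    """Raised when objects cannot be packed into the frame."""


@dataclasses.dataclass
class SceneSpec:
    """Parameters of one synthetic scene.

    Intensities are AFU on a 16-bit scale; diameters are μm.  The defaults
    describe a plausible L4 DRG section sampled at ~0.65 μm/px: at the
    coarse 2.6 μm/px morphometry scale a 4-px border erosion would consume
    every small soma and puncta could not span two pixels, so scenes are
    rendered at acquisition-like resolution while the morphometry
    conversion constant retains its own default.
    """

    image_size: tuple[int, int] = (768, 768)
    pixel_area_um2: float = 0.42
    bit_depth: int = 16
    # neurons: bimodal soma diameters, truncated normals
    n_neurons_small: int = 35
    n_neurons_large: int = 15
    small_diam_mean_um: float = 18.0
    small_diam_sd_um: float = 3.0
    small_diam_bounds_um: tuple[float, float] = (8.0, 25.0)
    large_diam_mean_um: float = 38.0
    large_diam_sd_um: float = 4.0
    large_diam_bounds_um: tuple[float, float] = (30.0, 60.0)
    neuron_marker_intensity: float = 10_000.0
    tissue_intensity: float = 1_500.0
    # MHCII
    neuron_mhcii_base: float = 4_000.0
    frac_mhcii_pos: float = 0.30
    puncta_per_pos_neuron: tuple[int, int] = (4, 12)   # uniform int, inclusive
    puncta_area_px: tuple[int, int] = (2, 6)           # uniform int, inclusive
    puncta_delta: float = 1_200.0
    puncta_margin_px: int = 6
    # immune cells (MHCII >= 5x neuronal base)
    n_immune: int = 8
    immune_mhcii_intensity: float = 28_000.0
    immune_diam_um: float = 10.0
    # T cells
    n_tcells: int = 4
    n_cd3_only: int = 3
    tcell_diam_um: float = 8.0
    cd3_intensity: float = 12_000.0
    cd4_intensity: float = 12_000.0
    # nuclei / RFX1
    n_nonneuronal_nuclei: int = 15
    nonneuronal_nucleus_diam_um: float = 7.0
    dapi_intensity: float = 8_000.0
    nucleus_frac_diam: float = 0.45
    frac_rfx1_pos: float = 0.40
    rfx1_pos_mpi: float = 600.0
    rfx1_neg_mpi: float = 0.0
    # scene
    tissue_fraction: float = 0.5
    noise_sd: float = 100.0
    min_gap_px: int = 2
    immune_gap_px: int = 12
    # culture scenes
    n_culture_neurons: int = 12
    culture_diam_mean_um: float = 30.0
    culture_diam_sd_um: float = 5.0
    culture_base: float = 2_000.0
    ova_base: float = 1_500.0
    cap_fraction: float = 0.12
    frac_polarized_cells: float = 0.5
    culture_fold: float = 2.0
    seed: int = 0
    max_place_attempts: int = 2_000

    def __post_init__(self) -> None:
        for name in ("n_neurons_small", "n_neurons_large", "n_immune",
                     "n_tcells", "n_cd3_only", "n_nonneuronal_nuclei",
                     "n_culture_neurons"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("frac_mhcii_pos", "frac_rfx1_pos", "tissue_fraction",
                     "frac_polarized_cells", "cap_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.pixel_area_um2 <= 0:
            raise ValueError("pixel_area_um2 must be positive")
        if self.puncta_area_px[0] < 2:
            raise ValueError("puncta must span at least 2 pixels")
        if self.immune_mhcii_intensity < 5 * self.neuron_mhcii_base:
            raise ValueError("immune MHCII intensity must be >= 5x the "
                             "neuronal base level")

    @property
    def pixel_width_um(self) -> float:
        return math.sqrt(self.pixel_area_um2)

    def um_to_px(self, um: float) -> float:
        return um / self.pixel_width_um


@dataclasses.dataclass
class TruthTable:
    """Ground truth for one scene: one row per planted object."""

    objects: pd.DataFrame
    puncta: pd.DataFrame
    tissue_area_px: int = 0

    def neurons(self) -> pd.DataFrame:
        return self.objects[self.objects["class"].str.startswith("neuron")]

    def tcells(self) -> pd.DataFrame:
        return self.objects[self.objects["class"] == "tcell"]

    def to_csv(self, path_prefix) -> tuple:
        obj_path = f"{path_prefix}_objects.csv"
        pun_path = f"{path_prefix}_puncta.csv"
        self.objects.to_csv(obj_path, index=False)
        self.puncta.to_csv(pun_path, index=False)
        return obj_path, pun_path


# --------------------------------------------------------------------------
# geometry primitives


def _truncated_normal(rng, mean, sd, lo, hi):
    """One draw from N(mean, sd) restricted to (lo, hi] by rejection."""
    for _ in range(10_000):
        x = rng.normal(mean, sd)
        if lo < x <= hi:
            return x
    raise PlacementError(
        f"truncated normal ({mean}, {sd}) on ({lo}, {hi}] failed to sample")


def _ellipse_pixels(center, a, b, theta, shape):
    """Pixel-centre rasterisation of a rotated ellipse; None if out of frame."""
    r0, c0 = center
    rad = int(math.ceil(max(a, b))) + 1
    rmin, rmax = int(math.floor(r0)) - rad, int(math.ceil(r0)) + rad
    cmin, cmax = int(math.floor(c0)) - rad, int(math.ceil(c0)) + rad
    if rmin < 1 or cmin < 1 or rmax >= shape[0] - 1 or cmax >= shape[1] - 1:
        return None
    rr, cc = np.mgrid[rmin:rmax + 1, cmin:cmax + 1]
    dy, dx = rr - r0, cc - c0
    u = dx * math.cos(theta) + dy * math.sin(theta)
    v = -dx * math.sin(theta) + dy * math.cos(theta)
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return rr[inside], cc[inside]


def _nearest_n_pixels(center, n, shape):
    """The n pixels nearest to ``center`` (ties broken by (row, col) order)."""
    r0, c0 = center
    rad = int(math.ceil(math.sqrt(n))) + 2
    rr, cc = np.mgrid[int(r0) - rad:int(r0) + rad + 1,
                      int(c0) - rad:int(c0) + rad + 1]
    rr, cc = rr.ravel(), cc.ravel()
    ok = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
    rr, cc = rr[ok], cc[ok]
    d2 = (rr - r0) ** 2 + (cc - c0) ** 2
    order = np.lexsort((cc, rr, d2))
    return rr[order[:n]], cc[order[:n]]


def _disc_structure(radius: int) -> np.ndarray:
    yy, xx = np.mgrid[-radius:radius + 1, -radius:radius + 1]
    return (yy * yy + xx * xx) <= radius * radius


def _tissue_ellipse(spec: SceneSpec) -> np.ndarray:
    h, w = spec.image_size
    if spec.tissue_fraction == 0:
        return np.zeros((h, w), dtype=bool)
    area = spec.tissue_fraction * h * w
    ratio = 1.3
    a = math.sqrt(area * ratio / math.pi)   # semi-axis along columns
    b = a / ratio
    if a >= w / 2 - 2 or b >= h / 2 - 2:
        # the requested patch cannot fit as an ellipse: use the largest that
        # does and top up with a centred rectangle border if ever needed
        a = min(a, w / 2 - 2)
        b = min(b, h / 2 - 2)
    rr, cc = np.mgrid[0:h, 0:w]
    return ((cc - w / 2 + 0.5) / a) ** 2 + ((rr - h / 2 + 0.5) / b) ** 2 <= 1.0


@dataclasses.dataclass
class _PlacedObject:
    object_id: int
    class_name: str
    center: tuple[float, float]
    pixels: tuple[np.ndarray, np.ndarray]
    diameter_um: float
    mhcii_positive: bool = False
    rfx1_positive: bool = False
    has_nucleus: bool = False
    nucleus_pixels: tuple | None = None
    puncta: list = dataclasses.field(default_factory=list)  # (rr, cc) tuples
    polarized_fraction: float = 0.0
    cap_pixels: tuple | None = None

    @property
    def area_px(self) -> int:
        return int(self.pixels[0].size)


class _Placer:
    """Rejection-sampling placement with per-class minimum gaps."""

    def __init__(self, spec: SceneSpec, region: np.ndarray, rng):
        self.spec = spec
        self.region = region
        self.rng = rng
        self.occupied = np.zeros(spec.image_size, dtype=bool)
        self.occupied_neurons = np.zeros(spec.image_size, dtype=bool)
        rows, cols = np.nonzero(region)
        if rows.size:
            self.bounds = (rows.min(), rows.max(), cols.min(), cols.max())
        else:
            self.bounds = None

    def _conflicts(self, rr, cc, gap, occupancy) -> bool:
        r0, r1 = rr.min(), rr.max()
        c0, c1 = cc.min(), cc.max()
        h, w = occupancy.shape
        R0, R1 = max(r0 - gap, 0), min(r1 + gap + 1, h)
        C0, C1 = max(c0 - gap, 0), min(c1 + gap + 1, w)
        window = occupancy[R0:R1, C0:C1]
        if not window.any():
            return False
        cand = np.zeros(window.shape, dtype=bool)
        cand[rr - R0, cc - C0] = True
        grown = ndimage.binary_dilation(cand, structure=_disc_structure(gap))
        return bool((grown & window).any())

    def place(self, make_pixels, is_neuron=False, neuron_gap=None):
        """Place one object; ``make_pixels(center)`` returns (rr, cc) or None."""
        if self.bounds is None:
            raise PlacementError("no tissue region to place objects in")
        rmin, rmax, cmin, cmax = self.bounds
        gap = self.spec.min_gap_px
        for _ in range(self.spec.max_place_attempts):
            center = (self.rng.uniform(rmin, rmax), self.rng.uniform(cmin, cmax))
            pix = make_pixels(center)
            if pix is None:
                continue
            rr, cc = pix
            if rr.size == 0 or not self.region[rr, cc].all():
                continue
            if self._conflicts(rr, cc, gap, self.occupied):
                continue
            if neuron_gap is not None and self._conflicts(
                    rr, cc, neuron_gap, self.occupied_neurons):
                continue
            self.occupied[rr, cc] = True
            if is_neuron:
                self.occupied_neurons[rr, cc] = True
            return center, (rr, cc)
        raise PlacementError(
            f"could not place object after {self.spec.max_place_attempts} "
            "attempts; the frame is too crowded for the requested counts")


# --------------------------------------------------------------------------
# scene construction


def _make_neuron(spec: SceneSpec, placer: _Placer, rng, object_id: int,
                 small: bool) -> _PlacedObject:
    if small:
        d = _truncated_normal(rng, spec.small_diam_mean_um, spec.small_diam_sd_um,
                              *spec.small_diam_bounds_um)
    else:
        d = _truncated_normal(rng, spec.large_diam_mean_um, spec.large_diam_sd_um,
                              *spec.large_diam_bounds_um)
    q = rng.uniform(0.8, 1.0)
    theta = rng.uniform(0.0, math.pi)
    area_px = math.pi * (d / 2.0) ** 2 / spec.pixel_area_um2
    a = math.sqrt(area_px / (math.pi * q))
    b = q * a

    center, pixels = placer.place(
        lambda ctr: _ellipse_pixels(ctr, a, b, theta, spec.image_size),
        is_neuron=True)
    obj = _PlacedObject(
        object_id=object_id,
        class_name="neuron_small" if small else "neuron_large",
        center=center, pixels=pixels, diameter_um=d)

    # nucleus: concentric disc, diameter clamped into the nucleus size gate
    nuc_d_um = min(max(spec.nucleus_frac_diam * d, 4.5), 13.0)
    r_nuc = min(spec.um_to_px(nuc_d_um) / 2.0, b - 1.0)
    if r_nuc >= 1.0:
        nuc = _ellipse_pixels(center, r_nuc, r_nuc, 0.0, spec.image_size)
        if nuc is not None and nuc[0].size > 0:
            obj.nucleus_pixels = nuc
            obj.has_nucleus = True
            obj.rfx1_positive = bool(rng.random() < spec.frac_rfx1_pos)
    obj.mhcii_positive = bool(rng.random() < spec.frac_mhcii_pos)
    if obj.mhcii_positive:
        _plant_puncta(spec, rng, obj)
    return obj


def _plant_puncta(spec: SceneSpec, rng, obj: _PlacedObject) -> None:
    """Plant non-touching puncta well inside the soma.

    Puncta sit at least ``puncta_margin_px`` from the soma border so that a
    border erosion of up to margin − 2 px cannot clip them, and at least
    2 px apart so they never merge into one component.  If the soma is too
    small for the drawn count, the truth records what was actually planted.
    """
    rr, cc = obj.pixels
    r0, c0 = rr.min(), cc.min()
    local = np.zeros((rr.max() - r0 + 1, cc.max() - c0 + 1), dtype=bool)
    local[rr - r0, cc - c0] = True
    allowed = ndimage.distance_transform_edt(
        np.pad(local, 1, constant_values=False))[1:-1, 1:-1] > spec.puncta_margin_px
    taken = np.zeros_like(local)
    lo, hi = spec.puncta_per_pos_neuron
    n_target = int(rng.integers(lo, hi + 1))
    placed = 0
    for _ in range(spec.max_place_attempts):
        if placed >= n_target or not allowed.any():
            break
        choices = np.argwhere(allowed & ~taken)
        if choices.size == 0:
            break
        pr, pc = choices[rng.integers(len(choices))]
        area = int(rng.integers(spec.puncta_area_px[0], spec.puncta_area_px[1] + 1))
        prr, pcc = _nearest_n_pixels((float(pr), float(pc)), area, local.shape)
        if prr.size < area or not allowed[prr, pcc].all():
            continue
        cand = np.zeros_like(local)
        cand[prr, pcc] = True
        grown = ndimage.binary_dilation(cand, structure=np.ones((3, 3), bool))
        if (grown & taken).any():
            continue
        taken |= grown  # reserve a 1-px moat so puncta never 8-touch
        obj.puncta.append((prr + r0, pcc + c0))
        placed += 1


def _make_disc_object(spec: SceneSpec, placer: _Placer, object_id: int,
                      class_name: str, diam_um: float,
                      neuron_gap=None) -> _PlacedObject:
    r = spec.um_to_px(diam_um) / 2.0
    center, pixels = placer.place(
        lambda ctr: _ellipse_pixels(ctr, r, r, 0.0, spec.image_size),
        neuron_gap=neuron_gap)
    return _PlacedObject(object_id=object_id, class_name=class_name,
                         center=center, pixels=pixels, diameter_um=diam_um)


def _build_section_scene(spec: SceneSpec):
    """Shared geometry for matched stained and isotype-control sections."""
    rng = np.random.default_rng(spec.seed)
    tissue = _tissue_ellipse(spec)
    placer = _Placer(spec, tissue, rng)
    objects: list[_PlacedObject] = []
    oid = 0
    for _ in range(spec.n_neurons_small):
        oid += 1
        objects.append(_make_neuron(spec, placer, rng, oid, small=True))
    for _ in range(spec.n_neurons_large):
        oid += 1
        objects.append(_make_neuron(spec, placer, rng, oid, small=False))
    for _ in range(spec.n_immune):
        oid += 1
        objects.append(_make_disc_object(
            spec, placer, oid, "immune", spec.immune_diam_um,
            neuron_gap=spec.immune_gap_px))
    for _ in range(spec.n_tcells):
        oid += 1
        objects.append(_make_disc_object(spec, placer, oid, "tcell",
                                         spec.tcell_diam_um))
    for _ in range(spec.n_cd3_only):
        oid += 1
        objects.append(_make_disc_object(spec, placer, oid, "cd3_only",
                                         spec.tcell_diam_um))
    for _ in range(spec.n_nonneuronal_nuclei):
        oid += 1
        objects.append(_make_disc_object(spec, placer, oid, "nucleus",
                                         spec.nonneuronal_nucleus_diam_um))
    return rng, tissue, objects


def _finish_channels(spec: SceneSpec, rng, channels: dict) -> dict:
    """Add clipped Gaussian noise and cast to the container dtype."""
    vmax = 2 ** spec.bit_depth - 1
    out = {}
    for name in sorted(channels):
        arr = channels[name]
        if spec.noise_sd > 0:
            arr = arr + rng.normal(0.0, spec.noise_sd, size=arr.shape)
        arr = np.clip(np.rint(arr), 0, vmax)
        out[name] = arr.astype(np.uint16 if spec.bit_depth <= 16 else np.uint32)
    return out


def _truth_from_objects(objects, tissue) -> TruthTable:
    rows, puncta_rows = [], []
    for o in objects:
        rows.append({
            "object_id": o.object_id, "class": o.class_name,
            "centroid_row": float(o.pixels[0].mean()) if o.area_px else float("nan"),
            "centroid_col": float(o.pixels[1].mean()) if o.area_px else float("nan"),
            "area_px": o.area_px, "true_diameter_um": o.diameter_um,
            "mhcii_positive": o.mhcii_positive, "rfx1_positive": o.rfx1_positive,
            "has_nucleus": o.has_nucleus, "n_puncta": len(o.puncta),
            "puncta_area_px": int(sum(p[0].size for p in o.puncta)),
            "polarized_fraction": o.polarized_fraction,
        })
        for prr, pcc in o.puncta:
            puncta_rows.append({
                "neuron_id": o.object_id,
                "centroid_row": float(prr.mean()), "centroid_col": float(pcc.mean()),
                "area_px": int(prr.size)})
    return TruthTable(
        objects=pd.DataFrame(rows, columns=_TRUTH_COLUMNS),
        puncta=pd.DataFrame(puncta_rows, columns=_PUNCTA_COLUMNS),
        tissue_area_px=int(tissue.sum()))


def _render_section(spec: SceneSpec, tissue, objects, isotype: bool):
    h, w = spec.image_size
    ch = {name: np.zeros((h, w)) for name in
          ("PGP9.5", "MHCII", "CD3", "CD4", "DAPI", "RFX1")}
    ch["PGP9.5"][tissue] = spec.tissue_intensity
    for o in objects:
        rr, cc = o.pixels
        if o.class_name.startswith("neuron"):
            ch["PGP9.5"][rr, cc] = spec.neuron_marker_intensity
            if o.mhcii_positive and not isotype:
                ch["MHCII"][rr, cc] = spec.neuron_mhcii_base
                for prr, pcc in o.puncta:
                    ch["MHCII"][prr, pcc] = spec.neuron_mhcii_base + spec.puncta_delta
            if o.nucleus_pixels is not None:
                nrr, ncc = o.nucleus_pixels
                ch["DAPI"][nrr, ncc] = spec.dapi_intensity
                ch["RFX1"][nrr, ncc] = (spec.rfx1_pos_mpi if o.rfx1_positive
                                        else spec.rfx1_neg_mpi)
        elif o.class_name == "immune":
            if not isotype:
                ch["MHCII"][rr, cc] = spec.immune_mhcii_intensity
        elif o.class_name == "tcell":
            ch["CD3"][rr, cc] = spec.cd3_intensity
            ch["CD4"][rr, cc] = spec.cd4_intensity
        elif o.class_name == "cd3_only":
            ch["CD3"][rr, cc] = spec.cd3_intensity
        elif o.class_name == "nucleus":
            ch["DAPI"][rr, cc] = spec.dapi_intensity
    return ch


def _section(spec: SceneSpec, isotype: bool):
    rng, tissue, objects = _build_section_scene(spec)
    channels = _render_section(spec, tissue, objects, isotype=isotype)
    channels = _finish_channels(spec, rng, channels)
    truth = _truth_from_objects(objects, tissue)
    if isotype:
        # nothing MHCII-specific is rendered: the truth reflects the render
        truth.objects["mhcii_positive"] = False
        truth.objects["n_puncta"] = 0
        truth.objects["puncta_area_px"] = 0
        truth.puncta = truth.puncta.iloc[0:0]
    kind = "isotype" if isotype else "section"
    stack = ImageStack(channels=channels, pixel_area_um2=spec.pixel_area_um2,
                       bit_depth=spec.bit_depth,
                       source_id=f"synthetic-{kind}-seed{spec.seed}")
    return stack, truth


def generate_section(spec: SceneSpec) -> tuple[ImageStack, TruthTable]:
    """Render one stained DRG section plus its ground truth."""
    return _section(spec, isotype=False)


def generate_isotype_section(spec: SceneSpec) -> tuple[ImageStack, TruthTable]:
    """Render the matched isotype-control section.

    Same geometry as :func:`generate_section` under the same seed; the
    MHCII channel contains only background noise (no signal on any object).
    """
    return _section(spec, isotype=True)


def generate_culture(spec: SceneSpec) -> tuple[ImageStack, TruthTable]:
    """Render sparse cultured neurons for surface-polarization scoring.

    Each soma carries uniform surface signal at ``culture_base``; a
    ``frac_polarized_cells`` fraction of cells additionally concentrate a
    polar cap — the ``cap_fraction`` of the cell's pixels furthest along a
    random direction — at ``culture_fold`` times the base level.  The truth
    records each cell's realised cap-area fraction.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    region = np.zeros((h, w), dtype=bool)
    region[2:h - 2, 2:w - 2] = True
    placer = _Placer(spec, region, rng)
    objects = []
    for oid in range(1, spec.n_culture_neurons + 1):
        d = _truncated_normal(rng, spec.culture_diam_mean_um,
                              spec.culture_diam_sd_um, 10.0, 60.0)
        q = rng.uniform(0.8, 1.0)
        theta = rng.uniform(0.0, math.pi)
        area_px = math.pi * (d / 2.0) ** 2 / spec.pixel_area_um2
        a = math.sqrt(area_px / (math.pi * q))
        b = q * a
        center, pixels = placer.place(
            lambda ctr: _ellipse_pixels(ctr, a, b, theta, spec.image_size),
            is_neuron=True)
        obj = _PlacedObject(object_id=oid, class_name="culture_neuron",
                            center=center, pixels=pixels, diameter_um=d)
        r_nuc = min(spec.um_to_px(min(max(spec.nucleus_frac_diam * d, 4.5), 13.0))
                    / 2.0, b - 1.0)
        nuc = _ellipse_pixels(center, r_nuc, r_nuc, 0.0, spec.image_size)
        if nuc is not None and nuc[0].size:
            obj.nucleus_pixels = nuc
            obj.has_nucleus = True
        if spec.cap_fraction > 0 and rng.random() < spec.frac_polarized_cells:
            rr, cc = pixels
            direction = rng.uniform(0.0, 2.0 * math.pi)
            proj = ((rr - center[0]) * math.sin(direction)
                    + (cc - center[1]) * math.cos(direction))
            n_cap = int(round(spec.cap_fraction * rr.size))
            if n_cap >= 1:
                order = np.lexsort((cc, rr, -proj))
                cap = order[:n_cap]
                obj.cap_pixels = (rr[cap], cc[cap])
                obj.polarized_fraction = n_cap / rr.size
        objects.append(obj)

    ch = {name: np.zeros((h, w)) for name in ("PGP9.5", "MHCII", "OVA", "DAPI")}
    for o in objects:
        rr, cc = o.pixels
        ch["PGP9.5"][rr, cc] = spec.neuron_marker_intensity
        ch["MHCII"][rr, cc] = spec.culture_base
        ch["OVA"][rr, cc] = spec.ova_base
        if o.cap_pixels is not None:
            ch["MHCII"][o.cap_pixels] = spec.culture_fold * spec.culture_base
        if o.nucleus_pixels is not None:
            ch["DAPI"][o.nucleus_pixels] = spec.dapi_intensity
    channels = _finish_channels(spec, rng, ch)
    truth = _truth_from_objects(objects, region)
    stack = ImageStack(channels=channels, pixel_area_um2=spec.pixel_area_um2,
                       bit_depth=spec.bit_depth,
                       source_id=f"synthetic-culture-seed{spec.seed}")
    return stack, truth
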