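"""Per-object intensity measurement (MPI) and classification rules.

MPI is the arithmetic mean pixel intensity of one channel over an object's
measurable pixels, in AFU.  Positivity rules are strict ``>`` comparisons
against a threshold that is either fixed (the nuclear RFX1 cutoff) or
derived from isotype-control sections as the 99th percentile of the
per-neuron MPI distribution.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .image_io import ImageIOError, ImageStack, LabelMap
from .segmentation import (SegmentationParams, _component_table,
                           resolve_threshold)


@dataclasses.dataclass
class CellRecord:
    """Measurements for one segmented object."""

    object_id: int
    class_name: str
    area_px: int
    area_um2: float
    mpi: dict[str, float] = dataclasses.field(default_factory=dict)
    flags: dict[str, bool] = dataclasses.field(default_factory=dict)
    diameter_um: float | None = None
    size_class: str | None = None
    measurable: bool = True
    has_nucleus: bool = False
    source_id: str = ""

    def to_row(self) -> dict:
        row = {
            "object_id": self.object_id,
            "class_name": self.class_name,
            "area_px": self.area_px,
            "area_um2": self.area_um2,
            "diameter_um": self.diameter_um,
            "size_class": self.size_class,
            "measurable": self.measurable,
            "has_nucleus": self.has_nucleus,
            "source_id": self.source_id,
        }
        for ch in sorted(self.mpi):
            row[f"mpi_{ch}"] = self.mpi[ch]
        for rule in sorted(self.flags):
            row[f"flag_{rule}"] = self.flags[rule]
        return row


@dataclasses.dataclass
class ThresholdModel:
    """A positivity threshold with its provenance."""

    rule_name: str
    threshold_afu: float
    provenance: str = "fixed"  # "isotype_p99" | "fixed"
    n_reference: int = 0

    def __post_init__(self) -> None:
        if self.threshold_afu < 0:
            raise ValueError("threshold_afu must be >= 0")
        if self.provenance not in ("isotype_p99", "fixed"):
            raise ValueError(f"unknown provenance {self.provenance!r}")


def measure_mpi(stack: ImageStack, labels: LabelMap, channel: str,
                expected_ids=None) -> list[CellRecord]:
    """Per-instance MPI of one channel over the instance's measurable pixels.

    ``expected_ids`` lets callers pass the full instance-id set from before
    border operations: ids with zero measurable pixels yield records flagged
    unmeasurable, which downstream statistics drop.
    """
    ch = stack.channel(channel).astype(float)
    arr = labels.labels
    n = int(arr.max()) + 1
    counts = np.bincount(arr.ravel(), minlength=n)
    sums = np.bincount(arr.ravel(), weights=ch.ravel(), minlength=n)
    ids = list(expected_ids) if expected_ids is not None else \
        [int(i) for i in np.unique(arr) if i > 0]
    records = []
    for idx in ids:
        npx = int(counts[idx]) if idx < n else 0
        if npx == 0:
            records.append(CellRecord(
                object_id=int(idx), class_name=labels.class_name or "object",
                area_px=0, area_um2=0.0, measurable=False,
                source_id=stack.source_id))
            continue
        records.append(CellRecord(
            object_id=int(idx), class_name=labels.class_name or "object",
            area_px=npx, area_um2=npx * stack.pixel_area_um2,
            mpi={channel: float(sums[idx] / npx)},
            source_id=stack.source_id))
    return records


def isotype_threshold(isotype_records, channel: str,
                      rule_name: str | None = None) -> ThresholdModel:
    """Positivity threshold from isotype-control sections.

    The threshold is the 99th percentile — linear interpolation between
    order statistics (position ``1 + 0.99·(n−1)``) — of the per-neuron MPI
    distribution measured on sections stained with an isotype control
    antibody.
    """
    mpis = [r.mpi[channel] for r in isotype_records
            if r.measurable and channel in r.mpi]
    if not mpis:
        raise ValueError("isotype_threshold requires at least one measurable "
                         "reference record")
    if len(mpis) < 20:
        warnings.warn(
            f"isotype reference has only {len(mpis)} neurons; the 99th "
            "percentile is unstable below ~20", stacklevel=2)
    thr = float(np.percentile(mpis, 99.0))  # linear interpolation ("type 7")
    return ThresholdModel(rule_name=rule_name or f"{channel}_positive",
                          threshold_afu=thr, provenance="isotype_p99",
                          n_reference=len(mpis))


def classify_positive(records, model: ThresholdModel, channel: str):
    """Flag each measurable record positive iff MPI strictly exceeds the threshold.

    Returns ``(records, positive_fraction)`` where the fraction is over
    measurable records only; an MPI exactly at the threshold is negative.
    """
    out = []
    n_meas = n_pos = 0
    for r in records:
        if not r.measurable or channel not in r.mpi:
            out.append(r)
            continue
        flag = r.mpi[channel] > model.threshold_afu
        flags = dict(r.flags)
        flags[model.rule_name] = bool(flag)
        out.append(dataclasses.replace(r, flags=flags))
        n_meas += 1
        n_pos += int(flag)
    fraction = n_pos / n_meas if n_meas else float("nan")
    return out, fraction


def find_cd4_tcells(stack: ImageStack, tissue: LabelMap,
                    params: SegmentationParams,
                    cd3_channel: str = "CD3",
                    cd4_channel: str = "CD4") -> list[CellRecord]:
    """CD3⁺CD4⁺ double-positive T cells within the tissue mask.

    CD3 and CD4 components are detected independently (threshold + size +
    MPI gates); a CD3 component counts as a CD4⁺ T cell when at least
    ``cd4_overlap_frac`` of its pixels fall inside a surviving CD4
    component and its centroid lies inside the tissue mask.
    """
    cd3 = stack.channel(cd3_channel).astype(float)
    cd4 = stack.channel(cd4_channel).astype(float)
    lo, hi = params.immune_area_bounds_px(stack.pixel_area_um2)

    def _cells(ch, thr_spec, min_mpi):
        thr = resolve_threshold(ch, thr_spec)
        _, props = _component_table(ch >= thr, ch, params.connectivity)
        return [p for p in props
                if lo <= p.area <= hi and p.intensity_mean >= min_mpi]

    cd3_cells = _cells(cd3, params.cd3_threshold, params.cd3_min_mpi)
    cd4_cells = _cells(cd4, params.cd4_threshold, params.cd4_min_mpi)
    cd4_bin = np.zeros(stack.shape, dtype=bool)
    for p in cd4_cells:
        cd4_bin[p.coords[:, 0], p.coords[:, 1]] = True

    records = []
    k = 0
    for p in cd3_cells:
        rr, cc = p.coords[:, 0], p.coords[:, 1]
        overlap = cd4_bin[rr, cc].mean()
        if overlap < params.cd4_overlap_frac:
            continue
        r, c = (int(round(x)) for x in p.centroid)
        r = min(max(r, 0), stack.shape[0] - 1)
        c = min(max(c, 0), stack.shape[1] - 1)
        if tissue.labels[r, c] == 0:
            continue
        k += 1
        records.append(CellRecord(
            object_id=k, class_name="tcell",
            area_px=int(p.area), area_um2=float(p.area * stack.pixel_area_um2),
            mpi={cd3_channel: float(p.intensity_mean),
                 cd4_channel: float(cd4[rr, cc].mean())},
            source_id=stack.source_id))
    return records


def tcell_density(tcells, tissue: LabelMap, pixel_area_um2: float) -> float:
    """CD4⁺ T cells per mm² of neuron-containing tissue (single section)."""
    area_px = int(tissue.binary().sum())
    return pooled_tcell_density([len(tcells)], [area_px], pixel_area_um2)


def pooled_tcell_density(counts, tissue_areas_px, pixel_area_um2: float) -> float:
    """Density pooled across sections: total cells over total tissue area.

    The ratio of sums — not the mean of per-section densities — so sections
    with more tissue weigh more, which is unbiased for unequal section areas.
    """
    total_cells = sum(counts)
    total_area_mm2 = sum(tissue_areas_px) * pixel_area_um2 * 1e-6
    if total_area_mm2 <= 0:
        raise ValueError("tissue area must be positive to compute a density")
    return total_cells / total_area_mm2
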