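"""End-to-end section analysis: segmentation → masking → measurement.

One :func:`analyze_section` call reproduces the full per-section procedure:

1. tissue mask from the neuron marker;
2. single-neuron instances (fibre-excluded);
3. Shrink the neuron borders (default 4 px) to keep satellite-glial signal
   out of the somatic measurement;
4. high-intensity non-neuronal MHCII cells, Grown by 7 px to catch their
   low-intensity fringe;
5. logical exclusion of the grown non-neuronal mask from the shrunk
   neurons, giving each neuron's *measurable* pixels;
6. per-neuron MHCII MPI, puncta, diameters and size classes;
7. CD3⁺CD4⁺ T cells within tissue, and nuclear RFX1 MPI per neuron with a
   visible (neuronal) nucleus.

MHCII positivity is applied afterwards with a threshold derived from
matched isotype-control sections (:func:`isotype_threshold_from_sections`).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import yaml

from . import segmentation as seg
from .classify import (CellRecord, ThresholdModel, classify_positive,
                       find_cd4_tcells, isotype_threshold, measure_mpi)
from .image_io import ChannelMapConfig, ImageStack, LabelMap
from .morphometry import MorphometryParams, classify_size
from .puncta import PunctaParams, PunctaSet, detect_puncta

MHCII_RULE = "MHCII_positive"
RFX1_RULE = "RFX1_positive"


@dataclasses.dataclass
class PipelineConfig:
    """All parameters of the section pipeline in one serialisable object."""

    channels: ChannelMapConfig = dataclasses.field(default_factory=ChannelMapConfig)
    segmentation: seg.SegmentationParams = dataclasses.field(
        default_factory=seg.SegmentationParams)
    puncta: PunctaParams = dataclasses.field(default_factory=PunctaParams)
    morphometry: MorphometryParams = dataclasses.field(
        default_factory=MorphometryParams)
    #: fixed nuclear RFX1 positivity cutoff (AFU, strict >)
    rfx1_threshold_afu: float = 37.19

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        kwargs = {}
        if "channels" in data:
            kwargs["channels"] = ChannelMapConfig(**data["channels"])
        if "segmentation" in data:
            kwargs["segmentation"] = seg.SegmentationParams(**data["segmentation"])
        if "puncta" in data:
            kwargs["puncta"] = PunctaParams(**data["puncta"])
        if "morphometry" in data:
            kwargs["morphometry"] = MorphometryParams(**data["morphometry"])
        if "rfx1_threshold_afu" in data:
            kwargs["rfx1_threshold_afu"] = float(data["rfx1_threshold_afu"])
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)
        return path


@dataclasses.dataclass
class SectionResult:
    """Everything measured on one section."""

    source_id: str
    tissue: LabelMap
    tissue_area_px: int
    neurons: LabelMap            # original instances (areas, diameters)
    measurable: LabelMap         # shrunk + exclusion-processed instances
    records: list[CellRecord]    # one per neuron instance
    puncta_sets: list[PunctaSet]
    tcells: list[CellRecord]
    n_neurons_with_nucleus: int = 0

    @property
    def n_neurons(self) -> int:
        return len(self.records)


def analyze_section(stack: ImageStack, config: PipelineConfig) -> SectionResult:
    """Run the full mask-and-measure procedure on one section."""
    ch = config.channels
    p = config.segmentation

    tissue = seg.tissue_mask(stack, p, channel=ch.resolve("neuron_marker"))
    neurons = seg.neuron_instances(stack, p, channel=ch.resolve("neuron_marker"))
    neuron_ids = [int(i) for i in neurons.instance_ids()]
    neuron_areas = neurons.areas()

    shrunk = seg.shrink_mask(neurons, p.shrink_px)
    mhcii_name = ch.resolve("mhcii")
    has_mhcii = mhcii_name in stack.channels
    if has_mhcii:
        nonneuronal = seg.nonneuronal_mhcii_mask(stack, p, channel=mhcii_name)
        grown = seg.grow_mask(nonneuronal, p.grow_px)
        measurable = seg.exclude_overlap(shrunk, grown)
    else:
        measurable = shrunk

    if has_mhcii:
        records = measure_mpi(stack, measurable, mhcii_name,
                              expected_ids=neuron_ids)
    else:
        records = measure_mpi(stack, measurable, ch.resolve("neuron_marker"),
                              expected_ids=neuron_ids)
    # report each neuron's *total* (pre-shrink) area so diameters describe
    # the whole soma, not the shrunk measurement region
    records = [
        dataclasses.replace(
            r, class_name="neuron",
            area_px=neuron_areas.get(r.object_id, 0),
            area_um2=neuron_areas.get(r.object_id, 0) * stack.pixel_area_um2)
        for r in records
    ]
    records = classify_size(records, config.morphometry)

    puncta_sets = (detect_puncta(stack, measurable, config.puncta,
                                 channel=mhcii_name, total_areas=neuron_areas)
                   if has_mhcii else [])

    cd3 = ch.roles.get("cd3", "")
    cd4 = ch.roles.get("cd4", "")
    tcells = (find_cd4_tcells(stack, tissue, p, cd3_channel=cd3, cd4_channel=cd4)
              if cd3 in stack.channels and cd4 in stack.channels else [])

    n_with_nucleus = 0
    dapi = ch.roles.get("dapi", "")
    rfx1 = ch.roles.get("rfx1", "")
    if dapi in stack.channels:
        records, n_with_nucleus = _score_rfx1(
            stack, neurons, records, config,
            dapi_channel=dapi,
            rfx1_channel=rfx1 if rfx1 in stack.channels else None)

    return SectionResult(
        source_id=stack.source_id,
        tissue=tissue, tissue_area_px=int(tissue.binary().sum()),
        neurons=neurons, measurable=measurable,
        records=records, puncta_sets=puncta_sets, tcells=tcells,
        n_neurons_with_nucleus=n_with_nucleus)


def _score_rfx1(stack, neurons, records, config, dapi_channel, rfx1_channel):
    """Mark neurons with a visible nucleus; flag nuclear RFX1 positivity.

    Only PGP9.5⁺ neurons with a neuronal nucleus enter the RFX1 fraction;
    the per-nucleus RFX1 MPI is compared strictly against the configured
    cutoff.
    """
    neuronal, _ = seg.nuclei_instances(stack, neurons, config.segmentation,
                                       channel=dapi_channel)
    rfx1_by_neuron: dict[int, float] = {}
    if neuronal.n_instances:
        rfx1_ch = (stack.channel(rfx1_channel).astype(float)
                   if rfx1_channel else None)
        for idx in neuronal.instance_ids():
            mask = neuronal.labels == idx
            rr, cc = np.nonzero(mask)
            owner = int(np.bincount(neurons.labels[rr, cc]).argmax())
            if owner == 0:
                continue
            if rfx1_ch is not None:
                rfx1_by_neuron[owner] = float(rfx1_ch[mask].mean())
            else:
                rfx1_by_neuron.setdefault(owner, float("nan"))
    out = []
    for r in records:
        if r.object_id in rfx1_by_neuron:
            mpi = rfx1_by_neuron[r.object_id]
            flags = dict(r.flags)
            new = dataclasses.replace(r, has_nucleus=True, flags=flags)
            if not np.isnan(mpi):
                new.mpi = dict(new.mpi)
                new.mpi["RFX1"] = mpi
                flags[RFX1_RULE] = mpi > config.rfx1_threshold_afu
            out.append(new)
        else:
            out.append(r)
    return out, len(rfx1_by_neuron)


def isotype_threshold_from_sections(isotype_stacks, config: PipelineConfig
                                    ) -> ThresholdModel:
    """Derive the MHCII positivity threshold from isotype-control sections.

    Runs the identical mask pipeline on each isotype section, pools the
    per-neuron MHCII MPIs across sections, and takes their 99th percentile.
    """
    records = []
    for stack in isotype_stacks:
        records.extend(analyze_section(stack, config).records)
    return isotype_threshold(records, config.channels.resolve("mhcii"),
                             rule_name=MHCII_RULE)


def apply_mhcii_threshold(result: SectionResult, model: ThresholdModel,
                          config: PipelineConfig) -> tuple[SectionResult, float]:
    """Flag MHCII positivity on a section's neuron records."""
    records, fraction = classify_positive(
        result.records, model, config.channels.resolve("mhcii"))
    return dataclasses.replace(result, records=records), fraction
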