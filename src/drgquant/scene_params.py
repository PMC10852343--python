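"""Pipeline parameters matched to a synthetic scene's intensity scales.

A scientist calibrates segmentation thresholds to their own staining and
instrument; the generator plays that role for its scenes.  Thresholds sit
midway between the intensity levels they must separate, so they are far
from both levels relative to the noise.
"""

from __future__ import annotations

from .image_io import ChannelMapConfig
from .morphometry import MorphometryParams
from .pipeline import PipelineConfig
from .puncta import PunctaParams
from .segmentation import SegmentationParams
from .synthetic import SceneSpec


def pipeline_config_for_scene(spec: SceneSpec) -> PipelineConfig:
    """A :class:`PipelineConfig` with absolute thresholds for a scene."""
    seg = SegmentationParams(
        tissue_smooth_sigma=3.0,
        tissue_threshold=spec.tissue_intensity / 2.0,
        neuron_marker_threshold=(spec.tissue_intensity
                                 + spec.neuron_marker_intensity) / 2.0,
        # gates open slightly beyond the planted truncation bounds so that
        # rasterisation jitter never drops a planted soma
        neuron_min_diam_um=6.0,
        neuron_max_diam_um=70.0,
        nonneuronal_mhcii_min=25_000.0,
        cd3_threshold=spec.cd3_intensity / 2.0,
        cd4_threshold=spec.cd4_intensity / 2.0,
        dapi_threshold=spec.dapi_intensity / 2.0,
    )
    return PipelineConfig(
        channels=ChannelMapConfig(),
        segmentation=seg,
        puncta=PunctaParams(),
        morphometry=MorphometryParams(pixel_area_um2=spec.pixel_area_um2),
        rfx1_threshold_afu=(spec.rfx1_pos_mpi + spec.rfx1_neg_mpi) / 2.0,
    )
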