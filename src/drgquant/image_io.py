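"""Image, label-map, configuration and measurement-table I/O.

Conventions used throughout the package:

* coordinates are row-major, 0-based ``(row, col)`` with the origin at the
  top-left of the frame;
* intensities are raw stored arbitrary fluorescent units (AFU) — no
  normalisation is applied anywhere, so every threshold in the pipeline is
  on the instrument scale;
* all derived masks are new objects: no operation mutates an input
  :class:`ImageStack` or :class:`LabelMap`.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

#: μm² per pixel of the widefield acquisitions used for soma morphometry.
DEFAULT_PIXEL_AREA_UM2 = 6.718

_META_TAG_KEYS = ("pixel_area_um2", "bit_depth", "source_id", "channel_order")


class ImageIOError(RuntimeError):
    """Raised for malformed images, configs or measurement tables."""


@dataclasses.dataclass
class ImageStack:
    """A multi-channel 2D fluorescence image.

    Parameters
    ----------
    channels
        Mapping of channel name (e.g. ``"PGP9.5"``, ``"MHCII"``) to a 2D
        intensity array in AFU.  All channels must share one shape.
    pixel_area_um2
        Physical area covered by one pixel, μm².
    bit_depth
        Container bit depth (12, 14 or 16).  ``None`` declares the stack
        "unbounded" (synthetic floating-point data).
    source_id
        Free-text provenance (mouse / section / slide identifiers).
    """

    channels: dict[str, np.ndarray]
    pixel_area_um2: float = DEFAULT_PIXEL_AREA_UM2
    bit_depth: int | None = 16
    source_id: str = ""

    def __post_init__(self) -> None:
        if not self.channels:
            raise ImageIOError("ImageStack requires at least one channel")
        shapes = {np.asarray(a).shape for a in self.channels.values()}
        if len(shapes) != 1:
            raise ImageIOError(f"channels differ in shape: {sorted(shapes)}")
        (shape,) = shapes
        if len(shape) != 2 or min(shape) < 1:
            raise ImageIOError(f"channels must be non-empty 2D arrays, got shape {shape}")
        if self.pixel_area_um2 <= 0:
            raise ImageIOError("pixel_area_um2 must be positive")
        for name, arr in self.channels.items():
            arr = np.asarray(arr)
            if arr.size and arr.min() < 0:
                raise ImageIOError(f"channel {name!r} has negative intensities")
            if self.bit_depth is not None and arr.size and arr.max() > 2**self.bit_depth - 1:
                raise ImageIOError(
                    f"channel {name!r} exceeds the {self.bit_depth}-bit range"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def channel_names(self) -> tuple[str, ...]:
        return tuple(self.channels)

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise ImageIOError(
                f"channel {name!r} not present; available: {sorted(self.channels)}"
            ) from None

    def copy(self) -> "ImageStack":
        return ImageStack(
            channels={k: v.copy() for k, v in self.channels.items()},
            pixel_area_um2=self.pixel_area_um2,
            bit_depth=self.bit_depth,
            source_id=self.source_id,
        )


@dataclasses.dataclass
class LabelMap:
    """Integer-labelled instance mask aligned to an :class:`ImageStack`.

    ``0`` is background.  After any relabelling operation labels are
    contiguous ``1..K``; intermediate operations (shrink, overlap
    exclusion) may leave gaps so that instance identities are preserved.
    """

    labels: np.ndarray
    class_name: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels)
        if arr.ndim != 2:
            raise ImageIOError("LabelMap requires a 2D array")
        if not np.issubdtype(arr.dtype, np.integer):
            raise ImageIOError("LabelMap requires an integer array")
        if arr.size and arr.min() < 0:
            raise ImageIOError("LabelMap labels must be non-negative")
        self.labels = arr

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def instance_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    @property
    def n_instances(self) -> int:
        return int(self.instance_ids().size)

    def areas(self) -> dict[int, int]:
        ids, counts = np.unique(self.labels[self.labels > 0], return_counts=True)
        return {int(i): int(c) for i, c in zip(ids, counts)}

    def binary(self) -> np.ndarray:
        return self.labels > 0

    def relabel(self) -> "LabelMap":
        """Return a copy with labels renumbered to contiguous 1..K (scan order)."""
        out = np.zeros_like(self.labels)
        for new, old in enumerate(self.instance_ids(), start=1):
            out[self.labels == old] = new
        return LabelMap(out, class_name=self.class_name)

    def copy(self) -> "LabelMap":
        return LabelMap(self.labels.copy(), class_name=self.class_name)


@dataclasses.dataclass
class ChannelMapConfig:
    """Binds stain roles to channel names and TIFF page order.

    ``channel_order`` gives the channel name of each TIFF page in order;
    ``roles`` maps a pipeline role (``neuron_marker``, ``mhcii``, ``cd3``,
    ``cd4``, ``dapi``, ``rfx1``, ``ova``) to one of those names.
    """

    channel_order: list[str] = dataclasses.field(
        default_factory=lambda: ["PGP9.5", "MHCII", "CD3", "CD4", "DAPI", "RFX1"]
    )
    roles: dict[str, str] = dataclasses.field(
        default_factory=lambda: {
            "neuron_marker": "PGP9.5",
            "mhcii": "MHCII",
            "cd3": "CD3",
            "cd4": "CD4",
            "dapi": "DAPI",
            "rfx1": "RFX1",
            "ova": "OVA",
        }
    )
    isotype_flag: bool = False
    pixel_area_um2: float | None = None
    bit_depth: int | None = None

    def resolve(self, role: str) -> str:
        try:
            return self.roles[role]
        except KeyError:
            raise ImageIOError(f"role {role!r} is not bound to a channel") from None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ChannelMapConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in data.items() if k in known})

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)
        return path


def read_image(path: str | Path, config: ChannelMapConfig) -> ImageStack:
    """Read a multi-page (or single-page multi-sample) grayscale TIFF.

    Pages are assigned channel names in ``config.channel_order``; metadata
    written by :func:`write_image` (pixel area, bit depth, source id) is
    recovered from the description tag, with any values set on ``config``
    taking precedence.
    """
    path = Path(path)
    if not path.exists():
        raise ImageIOError(f"no such image file: {path}")
    with tifffile.TiffFile(path) as tif:
        pages = [p.asarray() for p in tif.pages]
        description = tif.pages[0].description or ""
    if len(pages) == 1 and pages[0].ndim == 3:
        # single-page multi-sample: samples become channels
        arr = pages[0]
        pages = [arr[:, :, i] for i in range(arr.shape[2])]
    for i, page in enumerate(pages):
        if page.ndim != 2:
            raise ImageIOError(f"page {i} of {path} is not a grayscale 2D page")
    if len(pages) != len(config.channel_order):
        raise ImageIOError(
            f"{path} has {len(pages)} channel(s) but config expects "
            f"{len(config.channel_order)}: {config.channel_order}"
        )
    meta: dict = {}
    if description.startswith("{"):
        try:
            meta = json.loads(description)
        except json.JSONDecodeError:
            meta = {}
    order = meta.get("channel_order", config.channel_order)
    if list(order) != list(config.channel_order):
        order = config.channel_order
    pixel_area = config.pixel_area_um2 or meta.get("pixel_area_um2", DEFAULT_PIXEL_AREA_UM2)
    bit_depth = config.bit_depth or meta.get("bit_depth")
    if bit_depth is None and pages[0].dtype == np.uint16:
        bit_depth = 16
    return ImageStack(
        channels=dict(zip(order, pages)),
        pixel_area_um2=float(pixel_area),
        bit_depth=bit_depth,
        source_id=str(meta.get("source_id", path.stem)),
    )


def write_image(stack: ImageStack, path: str | Path) -> Path:
    """Write an :class:`ImageStack` as a multi-page grayscale TIFF.

    ``read_image(write_image(stack))`` is the identity on channel data
    (bitwise) and on the metadata carried in the description tag.
    """
    path = Path(path)
    arrays = [np.asarray(a) for a in stack.channels.values()]
    meta = {
        "pixel_area_um2": stack.pixel_area_um2,
        "bit_depth": stack.bit_depth,
        "source_id": stack.source_id,
        "channel_order": list(stack.channels),
    }
    try:
        tifffile.imwrite(
            path,
            np.stack(arrays),
            photometric="minisblack",
            description=json.dumps(meta),
        )
    except OSError as exc:
        raise ImageIOError(f"cannot write image to {path}: {exc}") from exc
    return path


def write_labels(labels: LabelMap, path: str | Path) -> Path:
    """Serialise a label map as a 16-bit (or 32-bit if needed) label TIFF."""
    path = Path(path)
    arr = labels.labels
    dtype = np.uint16 if (arr.size == 0 or arr.max() < 2**16) else np.uint32
    tifffile.imwrite(path, arr.astype(dtype), photometric="minisblack",
                     description=json.dumps({"class_name": labels.class_name}))
    return path


def read_labels(path: str | Path) -> LabelMap:
    with tifffile.TiffFile(path) as tif:
        arr = tif.pages[0].asarray()
        desc = tif.pages[0].description or ""
    class_name = ""
    if desc.startswith("{"):
        try:
            class_name = json.loads(desc).get("class_name", "")
        except json.JSONDecodeError:
            pass
    return LabelMap(arr.astype(np.int64), class_name=class_name)


def _record_to_row(record) -> dict:
    if isinstance(record, Mapping):
        return dict(record)
    if dataclasses.is_dataclass(record):
        if hasattr(record, "to_row"):
            return record.to_row()
        return dataclasses.asdict(record)
    raise ImageIOError(f"cannot serialise record of type {type(record).__name__}")


def write_records(records: Sequence, path: str | Path) -> Path:
    """Write measurement records as a CSV with a stable column order.

    One row per object; the header is always written, so an empty record
    list yields a header-only file.  All records must share one schema.
    Floats are written with ``repr`` precision so that a written-then-parsed
    table equals the source values exactly.
    """
    path = Path(path)
    rows = [_record_to_row(r) for r in records]
    schemas = {tuple(r.keys()) for r in rows}
    if len(schemas) > 1:
        raise ImageIOError(f"records have mixed schemas: {sorted(schemas)}")
    if rows:
        df = pd.DataFrame(rows, columns=list(rows[0].keys()))
    else:
        df = pd.DataFrame(columns=["object_id"])
    df.to_csv(path, index=False, float_format=None)
    return path


def read_records(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
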