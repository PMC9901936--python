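"""Image and label-mask handling for retinal field quantification.

Provides calibrated two-channel field containers, z-stack projection,
whole-image min-max normalization, a deterministic reference segmenter
(Gaussian smoothing, thresholding, connected components, optional
watershed splitting), and label-wise morphological erosion.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field as dc_field
from typing import Literal

import numpy as np
import tifffile
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import disk as disk_footprint
from skimage.segmentation import watershed

__all__ = [
    "FieldImage",
    "LabelMask",
    "SegmentationParams",
    "max_project",
    "normalize_channel",
    "segment_reference",
    "erode_labels",
    "read_field",
    "write_field",
    "read_labels",
    "write_labels",
]

DEFAULT_PX_PER_UM = 16.0  # 64 um field at 1024 px


class ImagingError(ValueError):
    """Raised on invalid images, masks, or parameters."""


@dataclass
class FieldImage:
    """A projected, calibrated multi-channel field.

    Parameters
    ----------
    channels
        Mapping of channel name (e.g. ``"red"``, ``"green"``) to a 2D
        array of equal shape, in detector units or normalized [0, 1].
    px_per_um
        Lateral resolution in pixels per micrometre.
    normalized
        Names of channels that have been min-max normalized to [0, 1].
    provenance
        Free-form source metadata (file path, projection planes, ...).
    """

    channels: dict[str, np.ndarray]
    px_per_um: float = DEFAULT_PX_PER_UM
    normalized: set[str] = dc_field(default_factory=set)
    provenance: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.channels:
            raise ImagingError("FieldImage requires at least one channel")
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) != 1:
            raise ImagingError(f"channel shapes differ: {shapes}")
        for name, ch in self.channels.items():
            if ch.ndim != 2:
                raise ImagingError(f"channel {name!r} is not 2D")
        if not self.px_per_um > 0:
            raise ImagingError("px_per_um must be positive")
        for name in self.normalized:
            ch = self.channels[name]
            if ch.size and np.any(ch != 0):
                if ch.min() < 0 or ch.max() > 1:
                    raise ImagingError(
                        f"channel {name!r} flagged normalized but outside [0, 1]"
                    )

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def field_size_um(self) -> float:
        return self.shape[0] / self.px_per_um

    def normalize(self, channel: str) -> "FieldImage":
        """Return a copy with ``channel`` min-max normalized to [0, 1]."""
        if channel not in self.channels:
            raise ImagingError(f"no channel named {channel!r}")
        channels = dict(self.channels)
        channels[channel] = normalize_channel(channels[channel])
        return FieldImage(
            channels=channels,
            px_per_um=self.px_per_um,
            normalized=self.normalized | {channel},
            provenance=dict(self.provenance),
        )


@dataclass
class LabelMask:
    """Integer-labelled segmentation aligned to a :class:`FieldImage`.

    Background is 0; each cell has a unique positive label. Labels need
    not be consecutive.
    """

    labels: np.ndarray
    channel_of_origin: str | None = None

    def __post_init__(self) -> None:
        if self.labels.ndim != 2:
            raise ImagingError("label mask must be 2D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ImagingError("label mask must have integer dtype")
        if self.labels.size and self.labels.min() < 0:
            raise ImagingError("label mask contains negative labels")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def label_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    @property
    def n_labels(self) -> int:
        return int(self.label_ids().size)


@dataclass
class SegmentationParams:
    """Parameters for the deterministic reference segmenter."""

    smooth_sigma_px: float = 2.0
    threshold_method: Literal["otsu"] | float = "otsu"
    min_area_px: int = 9
    split_touching: bool = False

    def __post_init__(self) -> None:
        if self.min_area_px < 1:
            raise ImagingError("min_area_px must be >= 1")
        if self.smooth_sigma_px < 0:
            raise ImagingError("smooth_sigma_px must be >= 0")
        if not (self.threshold_method == "otsu"
                or isinstance(self.threshold_method, (int, float))):
            raise ImagingError(
                "threshold_method must be 'otsu' or a fixed numeric value"
            )


def max_project(stack: np.ndarray, plane_range: tuple[int, int] | None = None) -> np.ndarray:
    """Pixel-wise maximum over an inclusive range of z-planes.

    ``plane_range=None`` projects the full stack. Output dtype equals
    input dtype.
    """
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ImagingError("stack must be 3D (planes, rows, cols)")
    nz = stack.shape[0]
    if plane_range is None:
        plane_range = (0, nz - 1)
    lo, hi = int(plane_range[0]), int(plane_range[1])
    if lo < 0 or hi >= nz or lo > hi:
        raise ImagingError(
            f"plane_range ({lo}, {hi}) invalid for stack of depth {nz}"
        )
    return stack[lo:hi + 1].max(axis=0)


def normalize_channel(image: np.ndarray) -> np.ndarray:
    """Min-max normalize a whole image to span [0, 1].

    A constant image maps to all zeros (with a warning): the
    division-by-zero case is defined as a signal-absent field.
    """
    image = np.asarray(image)
    if image.size == 0:
        raise ImagingError("cannot normalize an empty image")
    if not np.all(np.isfinite(image)):
        raise ImagingError("image contains non-finite values")
    image = image.astype(np.float64)
    mn = image.min()
    mx = image.max()
    if mx == mn:
        warnings.warn(
            "constant image: normalization returns all zeros", stacklevel=2
        )
        return np.zeros_like(image)
    return (image - mn) / (mx - mn)


def _canonical_relabel(labels: np.ndarray) -> np.ndarray:
    """Renumber labels 1..n in raster order of each label's first pixel."""
    flat = labels.ravel()
    ids, first = np.unique(flat, return_index=True)
    keep = ids > 0
    ids, first = ids[keep], first[keep]
    order = np.argsort(first, kind="stable")
    mapping = np.zeros(int(ids.max()) + 1 if ids.size else 1, dtype=labels.dtype)
    mapping[ids[order]] = np.arange(1, ids.size + 1, dtype=labels.dtype)
    return mapping[labels]


def segment_reference(image: np.ndarray, params: SegmentationParams | None = None) -> LabelMask:
    """Deterministic reference segmentation of a single channel.

    Pipeline: Gaussian smoothing -> global threshold (Otsu or fixed) ->
    8-connected components -> optional distance-transform watershed to
    split touching cells -> discard regions smaller than ``min_area_px``.
    Labels are renumbered canonically (raster order of first pixel) so
    identical input yields bit-identical output.
    """
    if params is None:
        params = SegmentationParams()
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ImagingError("image must be 2D")
    smoothed = (
        ndi.gaussian_filter(image, params.smooth_sigma_px)
        if params.smooth_sigma_px > 0
        else image
    )
    if params.threshold_method == "otsu":
        if np.ptp(smoothed) == 0:
            return LabelMask(labels=np.zeros(image.shape, dtype=np.int32))
        thr = threshold_otsu(smoothed)
    else:
        thr = float(params.threshold_method)
    binary = smoothed > thr
    labels = cc_label(binary, connectivity=2)

    if params.split_touching and labels.max() > 0:
        distance = ndi.distance_transform_edt(binary)
        min_dist = max(2, int(round(np.sqrt(params.min_area_px / np.pi))))
        coords = peak_local_max(
            distance, min_distance=min_dist, labels=labels, exclude_border=False
        )
        if len(coords):
            markers = np.zeros(image.shape, dtype=np.int32)
            markers[tuple(coords.T)] = np.arange(1, len(coords) + 1)
            labels = watershed(-distance, markers, mask=binary)

    if labels.max() > 0 and params.min_area_px > 1:
        areas = np.bincount(labels.ravel())
        small = np.flatnonzero(areas < params.min_area_px)
        if small.size:
            kill = np.isin(labels, small[small > 0])
            labels = np.where(kill, 0, labels)

    return LabelMask(labels=_canonical_relabel(labels.astype(np.int32)))


def erode_labels(
    mask: LabelMask,
    radius_px: int,
    element: Literal["disk", "square"] = "disk",
) -> tuple[LabelMask, list[int]]:
    """Erode every label independently by a structuring element.

    Each label is eroded on its own binary copy, so adjacent labels
    never interact. Label identities are preserved. Returns the eroded
    mask and the sorted list of labels that eroded to empty.
    """
    if radius_px < 0:
        raise ImagingError("erosion radius must be >= 0")
    if radius_px == 0:
        return LabelMask(mask.labels.copy(), mask.channel_of_origin), []
    if element == "disk":
        footprint = disk_footprint(radius_px)
    elif element == "square":
        footprint = np.ones((2 * radius_px + 1, 2 * radius_px + 1), dtype=bool)
    else:
        raise ImagingError(f"unknown structuring element {element!r}")

    labels = mask.labels
    out = np.zeros_like(labels)
    emptied: list[int] = []
    # find_objects needs small non-negative ints; our labels qualify.
    slices = ndi.find_objects(labels)
    for idx, sl in enumerate(slices, start=1):
        if sl is None:
            continue
        crop = labels[sl] == idx
        eroded = ndi.binary_erosion(crop, structure=footprint, border_value=0)
        if eroded.any():
            out[sl][eroded] = idx
        else:
            emptied.append(idx)
    # labels outside find_objects' consecutive assumption
    present = set(np.unique(labels).tolist()) - {0}
    handled = set(range(1, len(slices) + 1))
    for lab in sorted(present - handled):
        where = labels == lab
        eroded = ndi.binary_erosion(where, structure=footprint, border_value=0)
        if eroded.any():
            out[eroded] = lab
        else:
            emptied.append(int(lab))
    return LabelMask(out, mask.channel_of_origin), sorted(emptied)


# ---------------------------------------------------------------------------
# TIFF I/O


def write_field(path, field: FieldImage) -> None:
    """Write a field as a multi-channel TIFF with JSON metadata."""
    names = list(field.channels)
    arr = np.stack([field.channels[n] for n in names])
    meta = {
        "channels": names,
        "px_per_um": field.px_per_um,
        "normalized": sorted(field.normalized),
        "provenance": field.provenance,
    }
    tifffile.imwrite(
        path, arr, photometric="minisblack", description=json.dumps(meta)
    )


def read_field(path, plane_range: tuple[int, int] | None = None) -> FieldImage:
    """Read a field TIFF written by :func:`write_field`, or a raw stack.

    A file with channel metadata is returned as-is (``plane_range`` is
    rejected). A bare 3D array is treated as a single-channel z-stack
    and max-projected over ``plane_range`` (default: all planes); a bare
    2D array becomes a single ``"gray"`` channel.
    """
    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray()
        desc = tif.pages[0].description
    meta = None
    if desc:
        try:
            meta = json.loads(desc)
        except (TypeError, json.JSONDecodeError):
            meta = None
    if isinstance(meta, dict) and "channels" in meta:
        if plane_range is not None:
            raise ImagingError("plane_range not applicable to a channel TIFF")
        names = meta["channels"]
        if arr.ndim == 2:
            arr = arr[None]
        channels = {n: arr[i] for i, n in enumerate(names)}
        return FieldImage(
            channels=channels,
            px_per_um=float(meta.get("px_per_um", DEFAULT_PX_PER_UM)),
            normalized=set(meta.get("normalized", [])),
            provenance={"source": str(path), **meta.get("provenance", {})},
        )
    if arr.ndim == 3:
        projected = max_project(arr, plane_range)
        prov = {"source": str(path), "projection_planes": plane_range}
        return FieldImage(channels={"gray": projected}, provenance=prov)
    if arr.ndim == 2:
        if plane_range is not None:
            raise ImagingError("plane_range not applicable to a 2D image")
        return FieldImage(channels={"gray": arr}, provenance={"source": str(path)})
    raise ImagingError(f"unsupported TIFF dimensionality {arr.ndim}")


def write_labels(path, mask: LabelMask) -> None:
    """Write a label mask as an integer TIFF, widening dtype as needed."""
    labels = mask.labels
    max_label = int(labels.max()) if labels.size else 0
    dtype = np.uint16 if max_label < 2 ** 16 else np.uint32
    meta = {"label_mask": True, "channel_of_origin": mask.channel_of_origin}
    tifffile.imwrite(path, labels.astype(dtype), description=json.dumps(meta))


def read_labels(path, field: FieldImage | None = None) -> LabelMask:
    """Read a label TIFF; optionally check alignment against a field."""
    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray()
        desc = tif.pages[0].description
    origin = None
    if desc:
        try:
            origin = json.loads(desc).get("channel_of_origin")
        except (TypeError, json.JSONDecodeError, AttributeError):
            origin = None
    if arr.ndim != 2:
        raise ImagingError("label TIFF must contain a single 2D plane")
    mask = LabelMask(labels=arr.astype(np.int64), channel_of_origin=origin)
    if field is not None and mask.shape != field.shape:
        raise ImagingError(
            f"mask shape {mask.shape} does not match field shape {field.shape}"
        )
    return mask
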