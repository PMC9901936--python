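"""Per-cell GFP measurement, threshold calibration, double-positive
classification, GFP-only counting, and per-field summaries.

The measurement chain follows the screen's convention: segment cells on
the red marker channel, erode each label (default 10 px, to exclude
blur-contaminated borders), average the 0-1 normalized green signal over
the eroded remnant, and classify cells against a threshold calibrated so
that only a small fraction (default alpha = 0.05) of control cells
exceed it.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .imaging import FieldImage, LabelMask, erode_labels

__all__ = [
    "QuantConfig",
    "CellMeasurement",
    "ThresholdCalibration",
    "FieldSummary",
    "measure_cells",
    "calibrate_threshold",
    "classify_double_positive",
    "count_gfp_only",
    "summarize_field",
    "measurements_to_frame",
]

#: Published fixed thresholds for the two marker subtypes.
PAPER_FIXED_THRESHOLDS = {"L": 0.195, "S": 0.275}


class QuantError(ValueError):
    pass


@dataclass
class QuantConfig:
    erosion_radius_px: int = 10
    alpha: float = 0.05
    fixed_thresholds: dict[str, float] = dc_field(default_factory=dict)
    strict_greater: bool = True
    overlap_fraction: float = 0.5
    field_area_um2: float = 64.0 * 64.0

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise QuantError("alpha must be in (0, 1)")
        if self.erosion_radius_px < 0:
            raise QuantError("erosion_radius_px must be >= 0")
        for subtype, thr in self.fixed_thresholds.items():
            if not (0 <= thr <= 1):
                raise QuantError(
                    f"fixed threshold for {subtype!r} must be in [0, 1]"
                )
        if not (0 < self.overlap_fraction <= 1):
            raise QuantError("overlap_fraction must be in (0, 1]")
        if self.field_area_um2 <= 0:
            raise QuantError("field_area_um2 must be positive")


@dataclass
class CellMeasurement:
    """Geometry and mean normalized GFP of one segmented cell.

    ``valid`` is False when the label eroded to empty; such cells carry
    no mean and are excluded from downstream fractions.
    """

    field_id: str
    cell_id: int
    marker: str
    area_px: int
    eroded_area_px: int
    centroid: tuple[float, float]
    mean_norm_gfp: float | None
    valid: bool

    def __post_init__(self) -> None:
        if self.eroded_area_px > self.area_px:
            raise QuantError("eroded area cannot exceed original area")
        if self.valid:
            if self.mean_norm_gfp is None or not (0 <= self.mean_norm_gfp <= 1):
                raise QuantError("valid cells need mean_norm_gfp in [0, 1]")
        elif self.mean_norm_gfp is not None:
            raise QuantError("invalid cells must not carry a mean")


@dataclass
class ThresholdCalibration:
    subtype: str
    threshold: float
    alpha_target: float
    n_control_cells: int
    observed_exceedance: float
    source: str  # "calibrated" | "fixed"

    def __post_init__(self) -> None:
        if not (0 <= self.threshold <= 1):
            raise QuantError("threshold must be in [0, 1]")
        if (
            self.source == "calibrated"
            and self.n_control_cells > 0
            and self.observed_exceedance > self.alpha_target
        ):
            raise QuantError(
                "calibrated threshold violates the exceedance contract"
            )


@dataclass
class FieldSummary:
    field_id: str
    group: str | None
    counts: dict[str, int]
    densities_per_field: dict[str, int]
    densities_per_mm2: dict[str, float]
    double_positive_count: int | None
    double_positive_fraction: float | None
    gfp_only_count: int | None


def measure_cells(
    field: FieldImage,
    mask: LabelMask,
    config: QuantConfig | None = None,
    marker: str = "L",
    field_id: str = "field",
    green_channel: str = "green",
) -> list[CellMeasurement]:
    """Erode each label and average the normalized green channel over it.

    The green channel must already be min-max normalized (enforced, so
    the normalization step cannot be silently skipped). Labels that
    erode to empty are returned with ``valid=False``.
    """
    if config is None:
        config = QuantConfig()
    if green_channel not in field.channels:
        raise QuantError(f"field has no {green_channel!r} channel")
    if green_channel not in field.normalized:
        raise QuantError(
            f"channel {green_channel!r} is not normalized; call "
            "FieldImage.normalize first"
        )
    if mask.shape != field.shape:
        raise QuantError(
            f"mask shape {mask.shape} does not match field shape {field.shape}"
        )
    green = field.channels[green_channel]
    eroded, _ = erode_labels(mask, config.erosion_radius_px)

    ids = mask.label_ids()
    if ids.size == 0:
        return []
    areas = np.bincount(mask.labels.ravel())
    eroded_areas = np.bincount(eroded.labels.ravel(), minlength=len(areas))
    centroids = ndi.center_of_mass(np.ones_like(green), mask.labels, ids)
    surviving = ids[eroded_areas[ids] > 0]
    mean_by_label = dict(
        zip(surviving.tolist(), np.atleast_1d(ndi.mean(green, eroded.labels, surviving)))
    ) if surviving.size else {}

    out: list[CellMeasurement] = []
    for i, lab in enumerate(ids):
        lab = int(lab)
        e_area = int(eroded_areas[lab])
        valid = e_area > 0
        out.append(
            CellMeasurement(
                field_id=field_id,
                cell_id=lab,
                marker=marker,
                area_px=int(areas[lab]),
                eroded_area_px=e_area,
                centroid=(float(centroids[i][0]), float(centroids[i][1])),
                mean_norm_gfp=float(mean_by_label[lab]) if valid else None,
                valid=valid,
            )
        )
    return out


def measurements_to_frame(cells: list[CellMeasurement]) -> pd.DataFrame:
    """Tabulate measurements, one row per cell."""
    return pd.DataFrame(
        {
            "field_id": [c.field_id for c in cells],
            "cell_id": [c.cell_id for c in cells],
            "marker": [c.marker for c in cells],
            "area_px": [c.area_px for c in cells],
            "eroded_area_px": [c.eroded_area_px for c in cells],
            "centroid_y": [c.centroid[0] for c in cells],
            "centroid_x": [c.centroid[1] for c in cells],
            "mean_norm_gfp": [c.mean_norm_gfp for c in cells],
            "valid": [c.valid for c in cells],
        }
    )


def calibrate_threshold(
    control_values: np.ndarray | list[float],
    alpha: float = 0.05,
    subtype: str = "L",
    min_n: int = 20,
) -> ThresholdCalibration:
    """Choose the smallest observed value whose exceedance is <= alpha.

    This is the nearest-rank empirical (1 - alpha) quantile of the
    pooled control distribution: threshold = smallest observed value t
    such that the fraction of control values strictly greater than t is
    at most alpha. The observed exceedance is recorded alongside.
    """
    values = np.asarray(control_values, dtype=float)
    if values.ndim != 1 or values.size < min_n:
        raise QuantError(
            f"calibration needs >= {min_n} control values, got {values.size}"
        )
    if np.any((values < 0) | (values > 1)) or not np.all(np.isfinite(values)):
        raise QuantError("control values must be finite and in [0, 1]")
    if not (0 < alpha < 1):
        raise QuantError("alpha must be in (0, 1)")

    n = values.size
    uniq = np.unique(values)  # ascending
    # count strictly greater via searchsorted on the sorted pool
    sorted_vals = np.sort(values)
    n_greater = n - np.searchsorted(sorted_vals, uniq, side="right")
    ok = n_greater / n <= alpha
    threshold = float(uniq[np.argmax(ok)])  # first True; ok[-1] always True
    exceedance = float((values > threshold).mean())
    return ThresholdCalibration(
        subtype=subtype,
        threshold=threshold,
        alpha_target=alpha,
        n_control_cells=n,
        observed_exceedance=exceedance,
        source="calibrated",
    )


def fixed_calibration(subtype: str, threshold: float, alpha: float = 0.05) -> ThresholdCalibration:
    """Wrap a published fixed threshold (e.g. L: 0.195, S: 0.275)."""
    return ThresholdCalibration(
        subtype=subtype,
        threshold=threshold,
        alpha_target=alpha,
        n_control_cells=0,
        observed_exceedance=float("nan"),
        source="fixed",
    )


def classify_double_positive(
    cells: list[CellMeasurement],
    calibration: ThresholdCalibration,
    strict_greater: bool = True,
) -> tuple[list[bool], float]:
    """Per-cell positive/negative labels and the positive fraction.

    A valid cell is positive iff its mean normalized GFP strictly
    exceeds the threshold (or >=, with ``strict_greater=False``).
    Invalid cells (eroded to empty) are excluded from the fraction.
    """
    for c in cells:
        if c.valid and c.marker != calibration.subtype:
            raise QuantError(
                f"cell marker {c.marker!r} does not match calibration "
                f"subtype {calibration.subtype!r}"
            )
    valid = [c for c in cells if c.valid]
    if not valid:
        raise QuantError("no cells to classify")
    thr = calibration.threshold
    labels = [
        bool(c.valid and (
            c.mean_norm_gfp > thr if strict_greater else c.mean_norm_gfp >= thr
        ))
        for c in cells
    ]
    n_pos = sum(lab for lab, c in zip(labels, cells) if c.valid)
    return labels, n_pos / len(valid)


def count_gfp_only(
    green_mask: LabelMask,
    red_mask: LabelMask,
    overlap_fraction: float = 0.5,
) -> int:
    """Count green labels not explained by a segmented red cell.

    A green label is excluded when its fractional pixel overlap with
    some single red label reaches ``overlap_fraction``; all remaining
    green labels are counted as GFP-only cells.
    """
    if green_mask.shape != red_mask.shape:
        raise QuantError("green and red masks have different shapes")
    if not (0 < overlap_fraction <= 1):
        raise QuantError("overlap_fraction must be in (0, 1]")
    g = green_mask.labels
    r = red_mask.labels
    g_ids = green_mask.label_ids()
    if g_ids.size == 0:
        return 0
    areas = np.bincount(g.ravel())
    sel = (g > 0) & (r > 0)
    if not sel.any():
        return int(g_ids.size)
    pairs = np.stack([g[sel], r[sel]], axis=1)
    uniq_pairs, pair_counts = np.unique(pairs, axis=0, return_counts=True)
    excluded: set[int] = set()
    for (g_lab, _r_lab), cnt in zip(uniq_pairs, pair_counts):
        if cnt / areas[g_lab] >= overlap_fraction:
            excluded.add(int(g_lab))
    return int(g_ids.size - len(excluded))


def summarize_field(
    cells: list[CellMeasurement],
    classifications: list[bool] | None,
    config: QuantConfig | None = None,
    field_id: str = "field",
    group: str | None = None,
    gfp_only_count: int | None = None,
) -> FieldSummary:
    """Per-field counts, densities, and double-positive statistics.

    Densities are reported per field and per mm^2 (count divided by the
    field area in mm^2). With zero valid cells the double-positive
    fraction is recorded as missing, not 0.
    """
    if config is None:
        config = QuantConfig()
    if classifications is not None and len(classifications) != len(cells):
        raise QuantError("classifications must align with cells")

    counts: dict[str, int] = {}
    for c in cells:
        counts[c.marker] = counts.get(c.marker, 0) + 1
    area_mm2 = config.field_area_um2 / 1e6
    densities_mm2 = {k: v / area_mm2 for k, v in counts.items()}

    n_valid = sum(c.valid for c in cells)
    if classifications is not None and n_valid > 0:
        dp_count = sum(
            lab for lab, c in zip(classifications, cells) if c.valid
        )
        dp_fraction = dp_count / n_valid
    else:
        dp_count = None
        dp_fraction = None
    return FieldSummary(
        field_id=field_id,
        group=group,
        counts=counts,
        densities_per_field=dict(counts),
        densities_per_mm2=densities_mm2,
        double_positive_count=dp_count,
        double_positive_fraction=dp_fraction,
        gfp_only_count=gfp_only_count,
    )
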