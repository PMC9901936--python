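"""Synthetic retinal fields, cohorts, and expression matrices with known
ground truth.

Fields emulate confocal acquisition of a 64 um x 64 um patch of central
retina at 1024x1024 px: a jittered cone mosaic rendered as blurred disks
with population-specific intensities on a 12-bit detector scale, plus
background and Gaussian noise. Expression matrices follow a
negative-binomial (gamma-Poisson) count model with planted enriched gene
sets and a tunable rod-contamination mixture.

All randomness flows through ``numpy.random.Generator`` seeded with
PCG64, so identical spec + seed gives bit-identical output.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field as dc_field, replace
from typing import Literal

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.draw import disk as draw_disk

from .imaging import FieldImage, LabelMask
from .xpr import SUBTYPES, ExpressionMatrix

__all__ = [
    "IntensityParams",
    "MosaicSpec",
    "GroundTruth",
    "CohortSpec",
    "GroupSpec",
    "CohortBundle",
    "EnrichedSet",
    "SynthExpressionSpec",
    "generate_field",
    "generate_cohort",
    "generate_expression",
    "CrowdedFieldError",
    "SpecError",
]

DETECTOR_MAX = 4095  # 12-bit scale

RED_ONLY = "red_only"
GREEN_ONLY = "green_only"
DOUBLE_POSITIVE = "double_positive"


class SpecError(ValueError):
    pass


class CrowdedFieldError(RuntimeError):
    """Requested cells cannot be placed under the minimum-spacing rule."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise SpecError(msg)


@dataclass
class IntensityParams:
    """Per-population (mean, sd) of raw signal in detector units.

    ``double_*`` defaults to the green-only distribution so that
    classification difficulty is tunable independently. ``baseline_*``
    is the residual green signal in red-only cells (default mean: 5% of
    the green-only mean), which makes a minority of control cells exceed
    any calibrated threshold.
    """

    red_mean: float = 2000.0
    red_sd: float = 200.0
    green_only_mean: float = 2000.0
    green_only_sd: float = 200.0
    double_mean: float | None = None
    double_sd: float | None = None
    baseline_mean: float | None = None
    baseline_sd: float = 20.0

    def resolved(self) -> "IntensityParams":
        return replace(
            self,
            double_mean=self.green_only_mean if self.double_mean is None else self.double_mean,
            double_sd=self.green_only_sd if self.double_sd is None else self.double_sd,
            baseline_mean=(
                0.05 * self.green_only_mean if self.baseline_mean is None else self.baseline_mean
            ),
        )


@dataclass
class MosaicSpec:
    field_size_um: float = 64.0
    px_per_um: float = 16.0
    n_red_cells: int = 100
    n_green_only_cells: int = 0
    double_positive_fraction: float = 0.0
    cell_radius_um: float = 1.25
    min_spacing_um: float = 3.2
    intensity_params: IntensityParams = dc_field(default_factory=IntensityParams)
    psf_sigma_px: float = 2.0
    background_level: float = 100.0
    noise_sd: float = 10.0
    exact_counts: bool = False
    layout: Literal["rejection", "hex"] = "rejection"
    seed: int = 0

    def __post_init__(self) -> None:
        _require(0 <= self.double_positive_fraction <= 1,
                 "double_positive_fraction must be in [0, 1]")
        _require(self.n_red_cells >= 0 and self.n_green_only_cells >= 0,
                 "cell counts must be >= 0")
        _require(self.min_spacing_um > 0, "min_spacing_um must be > 0")
        _require(self.field_size_um > 0 and self.px_per_um > 0,
                 "field size and resolution must be positive")
        _require(self.cell_radius_um > 0, "cell_radius_um must be > 0")
        _require(self.psf_sigma_px >= 0 and self.noise_sd >= 0,
                 "psf_sigma_px and noise_sd must be >= 0")
        _require(self.layout in ("rejection", "hex"),
                 f"unknown layout {self.layout!r}")

    @property
    def size_px(self) -> int:
        return int(round(self.field_size_um * self.px_per_um))

    @property
    def n_cells(self) -> int:
        return self.n_red_cells + self.n_green_only_cells


@dataclass
class GroundTruth:
    """Noise-free mask plus per-cell true class and geometry."""

    label_mask: LabelMask
    cell_table: pd.DataFrame  # label, cell_class, y_um, x_um, radius_um

    def class_counts(self) -> dict[str, int]:
        return self.cell_table["cell_class"].value_counts().to_dict()

    @property
    def n_double_positive(self) -> int:
        return int((self.cell_table["cell_class"] == DOUBLE_POSITIVE).sum())


# ---------------------------------------------------------------------------
# cell placement


def _place_rejection(spec: MosaicSpec, rng: np.random.Generator) -> np.ndarray:
    n = spec.n_cells
    if n == 0:
        return np.empty((0, 2))
    lo = spec.cell_radius_um
    hi = spec.field_size_um - spec.cell_radius_um
    _require(hi > lo, "field too small for the requested cell radius")
    min_sq = spec.min_spacing_um ** 2
    centers = np.empty((n, 2))
    placed = 0
    max_attempts = 2000 * n
    attempts = 0
    while placed < n:
        if attempts >= max_attempts:
            raise CrowdedFieldError(
                f"field too crowded: placed {placed}/{n} cells after "
                f"{max_attempts} attempts (min_spacing_um={spec.min_spacing_um})"
            )
        cand = rng.uniform(lo, hi, size=2)
        attempts += 1
        if placed:
            d2 = np.sum((centers[:placed] - cand) ** 2, axis=1)
            if d2.min() < min_sq:
                continue
        centers[placed] = cand
        placed += 1
    return centers


def _place_hex(spec: MosaicSpec, rng: np.random.Generator) -> np.ndarray:
    """Jittered hexagonal lattice; spacing guaranteed by bounding jitter."""
    n = spec.n_cells
    if n == 0:
        return np.empty((0, 2))
    lo = spec.cell_radius_um
    hi = spec.field_size_um - spec.cell_radius_um
    extent = hi - lo
    _require(extent > 0, "field too small for the requested cell radius")

    def lattice(pitch: float) -> np.ndarray:
        dy = pitch * np.sqrt(3) / 2
        rows = int(np.floor(extent / dy)) + 1
        pts = []
        for r in range(rows):
            y = lo + r * dy
            offset = (pitch / 2) if r % 2 else 0.0
            cols = int(np.floor((extent - offset) / pitch)) + 1
            for c in range(cols):
                pts.append((y, lo + offset + c * pitch))
        return np.asarray(pts)

    # largest pitch (coarse scan) whose lattice still holds n sites
    pitch = spec.min_spacing_um
    sites = lattice(pitch)
    if len(sites) < n:
        raise CrowdedFieldError(
            f"field too crowded: hex lattice at pitch {pitch:.3g} um holds "
            f"only {len(sites)} sites for {n} cells"
        )
    for cand in np.linspace(spec.min_spacing_um, extent, 64)[::-1]:
        s = lattice(cand)
        if len(s) >= n:
            pitch, sites = cand, s
            break
    jitter_max = (pitch - spec.min_spacing_um) / 2
    chosen = sites[rng.choice(len(sites), size=n, replace=False)]
    if jitter_max > 0:
        theta = rng.uniform(0, 2 * np.pi, size=n)
        rad = jitter_max * np.sqrt(rng.uniform(0, 1, size=n))
        chosen = chosen + np.column_stack([rad * np.sin(theta), rad * np.cos(theta)])
    return np.clip(chosen, lo, hi)


def generate_field(spec: MosaicSpec) -> tuple[FieldImage, GroundTruth]:
    """Render one two-channel field and its noise-free ground truth.

    Red cells carry the red marker; a fraction of them (Bernoulli draws,
    or exactly round(f*n) under ``exact_counts``) are double-positive in
    green. Green-only cells have green signal and no red marker. The
    ground-truth mask labels red cells 1..n_red then green-only cells.
    """
    rng = np.random.default_rng(np.random.PCG64(spec.seed))
    ip = spec.intensity_params.resolved()
    size = spec.size_px

    centers_um = (
        _place_hex(spec, rng) if spec.layout == "hex" else _place_rejection(spec, rng)
    )
    n_red = spec.n_red_cells
    n = spec.n_cells

    if spec.exact_counts:
        n_dp = int(round(spec.double_positive_fraction * n_red))
        dp = np.zeros(n_red, dtype=bool)
        if n_dp:
            dp[rng.choice(n_red, size=n_dp, replace=False)] = True
    else:
        dp = rng.uniform(size=n_red) < spec.double_positive_fraction

    classes = np.array(
        [DOUBLE_POSITIVE if dp[i] else RED_ONLY for i in range(n_red)]
        + [GREEN_ONLY] * spec.n_green_only_cells
    )

    red_int = np.zeros(n)
    green_int = np.zeros(n)
    red_int[:n_red] = rng.normal(ip.red_mean, ip.red_sd, size=n_red)
    green_int[:n_red] = np.where(
        dp,
        rng.normal(ip.double_mean, ip.double_sd, size=n_red),
        rng.normal(ip.baseline_mean, ip.baseline_sd, size=n_red),
    )
    green_int[n_red:] = rng.normal(
        ip.green_only_mean, ip.green_only_sd, size=spec.n_green_only_cells
    )
    red_int = np.clip(red_int, 0, None)
    green_int = np.clip(green_int, 0, None)

    red = np.zeros((size, size))
    green = np.zeros((size, size))
    labels = np.zeros((size, size), dtype=np.int32)
    radius_px = spec.cell_radius_um * spec.px_per_um
    for i, (y_um, x_um) in enumerate(centers_um):
        rr, cc = draw_disk(
            (y_um * spec.px_per_um, x_um * spec.px_per_um), radius_px, shape=(size, size)
        )
        np.maximum.at(red, (rr, cc), red_int[i])
        np.maximum.at(green, (rr, cc), green_int[i])
        labels[rr, cc] = i + 1

    if spec.psf_sigma_px > 0:
        red = ndi.gaussian_filter(red, spec.psf_sigma_px)
        green = ndi.gaussian_filter(green, spec.psf_sigma_px)
    red = red + spec.background_level
    green = green + spec.background_level
    if spec.noise_sd > 0:
        red = red + rng.normal(0, spec.noise_sd, size=red.shape)
        green = green + rng.normal(0, spec.noise_sd, size=green.shape)

    def quantize(img: np.ndarray) -> np.ndarray:
        return np.clip(np.rint(img), 0, DETECTOR_MAX).astype(np.uint16)

    field = FieldImage(
        channels={"red": quantize(red), "green": quantize(green)},
        px_per_um=spec.px_per_um,
        provenance={"generator": "synthdata.generate_field", "seed": spec.seed},
    )
    table = pd.DataFrame(
        {
            "label": np.arange(1, n + 1, dtype=int),
            "cell_class": classes,
            "y_um": centers_um[:, 0] if n else np.array([]),
            "x_um": centers_um[:, 1] if n else np.array([]),
            "radius_um": np.full(n, spec.cell_radius_um),
        }
    )
    truth = GroundTruth(label_mask=LabelMask(labels, channel_of_origin="red"),
                        cell_table=table)
    return field, truth


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class GroupSpec:
    name: str
    n_fields: int
    mosaic: MosaicSpec

    def __post_init__(self) -> None:
        _require(self.n_fields >= 1, "each group needs >= 1 field")


@dataclass
class CohortSpec:
    groups: list[GroupSpec]
    base_seed: int = 0

    def __post_init__(self) -> None:
        _require(len(self.groups) >= 1, "cohort needs >= 1 group")
        names = [g.name for g in self.groups]
        _require(len(set(names)) == len(names), "group names must be unique")


@dataclass
class CohortBundle:
    fields: list[tuple[str, int, FieldImage, GroundTruth]]
    manifest: pd.DataFrame


def field_seed(base_seed: int, group_name: str, field_index: int) -> int:
    """Deterministic per-field seed from base seed, group name, and index."""
    name_key = zlib.crc32(group_name.encode("utf-8")) & 0xFFFFFFFF
    ss = np.random.SeedSequence([int(base_seed), name_key, int(field_index)])
    return int(ss.generate_state(1, dtype=np.uint64)[0])


def generate_cohort(cohort: CohortSpec) -> CohortBundle:
    fields = []
    rows = []
    for group in cohort.groups:
        for idx in range(group.n_fields):
            seed = field_seed(cohort.base_seed, group.name, idx)
            spec = replace(group.mosaic, seed=seed)
            try:
                field, truth = generate_field(spec)
            except (SpecError, CrowdedFieldError) as exc:
                raise type(exc)(
                    f"group {group.name!r} field {idx}: {exc}"
                ) from exc
            fields.append((group.name, idx, field, truth))
            counts = truth.class_counts()
            rows.append(
                {
                    "group": group.name,
                    "field_index": idx,
                    "seed": seed,
                    "n_red_cells": spec.n_red_cells,
                    "n_green_only_cells": spec.n_green_only_cells,
                    "true_double_positive_fraction": spec.double_positive_fraction,
                    "true_n_double_positive": counts.get(DOUBLE_POSITIVE, 0),
                }
            )
    return CohortBundle(fields=fields, manifest=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# expression matrices


@dataclass
class EnrichedSet:
    """A planted enriched gene set for one subtype.

    ``exclusive`` genes have zero mean outside their subtype (the
    rhodopsin-like pattern used by the contamination score).
    """

    subtype: str
    genes: list[str]
    fold: float = 10.0
    exclusive: bool = False

    def __post_init__(self) -> None:
        _require(self.subtype in SUBTYPES, f"unknown subtype {self.subtype!r}")
        _require(self.fold > 0, "fold must be > 0")


@dataclass
class SynthExpressionSpec:
    n_genes: int = 500
    n_samples_per_subtype: int | dict[str, int] = 6
    enriched_sets: list[EnrichedSet] = dc_field(default_factory=list)
    baseline_mean: float = 50.0
    dispersion: float = 0.2
    gene_length_range_bp: tuple[int, int] = (500, 4000)
    library_size: float = 1e7
    contamination_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        # YAML 1.1 parses exponent literals without a sign as strings
        self.library_size = float(self.library_size)
        self.baseline_mean = float(self.baseline_mean)
        self.dispersion = float(self.dispersion)
        self.contamination_fraction = float(self.contamination_fraction)
        _require(self.n_genes >= 1, "n_genes must be >= 1")
        _require(0 <= self.contamination_fraction < 1,
                 "contamination_fraction must be in [0, 1)")
        _require(self.baseline_mean > 0, "baseline_mean must be > 0")
        _require(self.dispersion >= 0, "dispersion must be >= 0")
        _require(self.library_size > 0, "library_size must be > 0")
        seen: dict[str, str] = {}
        for es in self.enriched_sets:
            for g in es.genes:
                if g in seen:
                    raise SpecError(
                        f"gene {g!r} appears in enriched sets for both "
                        f"{seen[g]!r} and {es.subtype!r}"
                    )
                seen[g] = es.subtype

    def samples_for(self, subtype: str) -> int:
        if isinstance(self.n_samples_per_subtype, dict):
            return int(self.n_samples_per_subtype.get(subtype, 0))
        return int(self.n_samples_per_subtype)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson negative binomial; dispersion 0 is pure Poisson."""
    mean = np.asarray(mean, dtype=float)
    if dispersion == 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    rate = np.where(mean > 0, rng.gamma(shape, mean * dispersion), 0.0)
    return rng.poisson(rate)


def generate_expression(
    spec: SynthExpressionSpec,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Draw a genes x samples count matrix with planted enrichment.

    Every gene has baseline mean expression in every subtype except
    where an enriched set raises (fold) or zeroes (exclusivity) it.
    Contamination mixes a fraction c of each non-rod sample's expected
    profile with the rod mean profile before drawing counts. Per-sample
    expected totals are scaled to ``library_size``. Returns the matrix
    and a truth table of planted genes.
    """
    rng = np.random.default_rng(np.random.PCG64(spec.seed))
    genes = [f"g{i:05d}" for i in range(spec.n_genes)]
    planted = {g for es in spec.enriched_sets for g in es.genes}
    unknown = planted - set(genes)
    _require(not unknown,
             f"enriched genes outside g00000..g{spec.n_genes - 1:05d}: {sorted(unknown)[:5]}")

    gene_idx = {g: i for i, g in enumerate(genes)}
    lo, hi = spec.gene_length_range_bp
    lengths = rng.integers(lo, hi + 1, size=spec.n_genes)

    # expected mean per (gene, subtype) before library scaling
    mean = {st: np.full(spec.n_genes, spec.baseline_mean) for st in SUBTYPES}
    for es in spec.enriched_sets:
        idx = [gene_idx[g] for g in es.genes]
        mean[es.subtype][idx] = spec.baseline_mean * es.fold
        if es.exclusive:
            for other in SUBTYPES:
                if other != es.subtype:
                    mean[other][idx] = 0.0

    # scale every subtype profile to the library size first, then mix:
    # the rod-derived read fraction in a contaminated sample is then
    # exactly the contamination fraction
    c = spec.contamination_fraction
    scaled_profiles = {}
    for st in SUBTYPES:
        total = mean[st].sum()
        scaled_profiles[st] = (
            mean[st] * (spec.library_size / total) if total > 0 else mean[st]
        )
    columns: dict[str, np.ndarray] = {}
    meta_rows = []
    for st in SUBTYPES:
        n_s = spec.samples_for(st)
        scaled = scaled_profiles[st]
        if c > 0 and st != "rod":
            scaled = (1 - c) * scaled + c * scaled_profiles["rod"]
        for rep in range(n_s):
            name = f"{st}_{rep + 1}"
            columns[name] = _nb_draw(rng, scaled, spec.dispersion)
            meta_rows.append({"sample": name, "subtype": st, "replicate": rep + 1})

    _require(bool(columns), "spec yields zero samples")
    counts = pd.DataFrame(columns, index=pd.Index(genes, name="gene"))
    metadata = pd.DataFrame(meta_rows).set_index("sample")
    matrix = ExpressionMatrix(
        counts=counts,
        gene_lengths=pd.Series(lengths, index=counts.index, name="length_bp"),
        totals=pd.Series(spec.library_size, index=counts.columns, name="total_mapped"),
        metadata=metadata,
    )
    truth = pd.DataFrame(
        [
            {"gene": g, "subtype": es.subtype, "fold": es.fold, "exclusive": es.exclusive}
            for es in spec.enriched_sets
            for g in es.genes
        ],
        columns=["gene", "subtype", "fold", "exclusive"],
    )
    return matrix, truth
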