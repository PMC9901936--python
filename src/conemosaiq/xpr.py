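"""Expression-matrix layer: FPKM, opsin aggregation, DEG and TF filters,
and the rhodopsin-based rod-contamination score.

Per-gene p-values can be ingested from an external differential-expression
package, or computed by a clearly-labelled stand-in (Welch's t on
log2(FPKM+1) with Benjamini-Hochberg adjustment). The filter layer is
identical either way.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExpressionMatrix",
    "DEGCriteria",
    "fpkm",
    "aggregate_genes",
    "per_gene_stats",
    "benjamini_hochberg",
    "deg_filter",
    "tf_expressed",
    "rod_contamination",
    "OPSIN_PRESETS",
]

SUBTYPES = ("rod", "UV", "S", "M", "L")

#: Built-in aggregation presets for the mid- and long-wavelength opsin
#: paralog groups.
OPSIN_PRESETS: dict[str, list[str]] = {
    "M-opsin": ["opn1mw1", "opn1mw2", "opn1mw3", "opn1mw4"],
    "L-opsin": ["opn1lw1", "opn1lw2"],
}


class ExpressionError(ValueError):
    pass


@dataclass
class ExpressionMatrix:
    """Genes x samples counts with lengths, totals, and sample metadata.

    ``counts`` is a DataFrame indexed by gene with one column per sample.
    ``gene_lengths`` (bp) is indexed by gene; ``totals`` (mapped reads)
    and ``metadata`` (with a ``subtype`` column) are indexed by sample.
    """

    counts: pd.DataFrame
    gene_lengths: pd.Series
    totals: pd.Series
    metadata: pd.DataFrame
    fpkm_layer: pd.DataFrame | None = dc_field(default=None, repr=False)

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ExpressionError("counts must be non-negative")
        missing_len = self.counts.index.difference(self.gene_lengths.index)
        if len(missing_len):
            raise ExpressionError(
                f"missing gene lengths for: {', '.join(map(str, missing_len[:5]))}"
            )
        if (self.gene_lengths.loc[self.counts.index] <= 0).any():
            raise ExpressionError("gene lengths must be positive")
        missing_tot = self.counts.columns.difference(self.totals.index)
        if len(missing_tot):
            raise ExpressionError(
                f"missing mapped-read totals for: {', '.join(map(str, missing_tot[:5]))}"
            )
        if (self.totals.loc[self.counts.columns] <= 0).any():
            raise ExpressionError("mapped-read totals must be positive")
        missing_meta = self.counts.columns.difference(self.metadata.index)
        if len(missing_meta):
            raise ExpressionError(
                f"metadata missing for samples: {', '.join(map(str, missing_meta[:5]))}"
            )
        if "subtype" not in self.metadata.columns:
            raise ExpressionError("metadata must contain a 'subtype' column")

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def samples_of(self, subtype: str) -> list[str]:
        meta = self.metadata.loc[self.samples]
        return list(meta.index[meta["subtype"] == subtype])

    def get_fpkm(self) -> pd.DataFrame:
        if self.fpkm_layer is None:
            self.fpkm_layer = fpkm(self)
        return self.fpkm_layer


@dataclass
class DEGCriteria:
    """Conjunction of differential-expression filter criteria.

    All comparisons are strict. ``rod_vs_cone_mode`` drops the
    fold-enrichment requirement so differences carried by one or two
    cone subtypes are not masked in pooled rod-vs-cone comparisons.
    """

    min_fold: float = 1.5
    max_p: float = 0.01
    max_padj: float = 0.1
    min_positive_fraction: float = 0.5
    rod_vs_cone_mode: bool = False
    fold_pseudocount: float = 0.01

    def __post_init__(self) -> None:
        if self.min_fold <= 0 or self.max_p <= 0 or self.max_padj <= 0:
            raise ExpressionError("thresholds must be positive")
        if not (0 < self.min_positive_fraction <= 1):
            raise ExpressionError("min_positive_fraction must be in (0, 1]")


def fpkm(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Fragments per kilobase of transcript per million mapped reads.

    FPKM[g, s] = counts[g, s] / (length_g / 1000) / (total_s / 1e6).
    """
    lengths = matrix.gene_lengths.loc[matrix.genes].astype(float)
    totals = matrix.totals.loc[matrix.samples].astype(float)
    out = matrix.counts.astype(float).div(lengths / 1e3, axis=0).div(
        totals / 1e6, axis=1
    )
    return out


def aggregate_genes(
    matrix: ExpressionMatrix,
    group_name: str,
    member_genes: list[str] | None = None,
    layer: str = "counts",
) -> pd.Series:
    """Per-sample sum over a set of member genes (e.g. opsin paralogs).

    ``member_genes=None`` looks up ``group_name`` in :data:`OPSIN_PRESETS`.
    """
    if member_genes is None:
        if group_name not in OPSIN_PRESETS:
            raise ExpressionError(
                f"no preset named {group_name!r}; available: {sorted(OPSIN_PRESETS)}"
            )
        member_genes = OPSIN_PRESETS[group_name]
    missing = [g for g in member_genes if g not in matrix.genes]
    if missing:
        raise ExpressionError(f"member genes absent from matrix: {missing}")
    values = matrix.counts if layer == "counts" else matrix.get_fpkm()
    row = values.loc[member_genes].sum(axis=0)
    row.name = group_name
    return row


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ExpressionError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def per_gene_stats(
    matrix: ExpressionMatrix,
    group_a: str,
    group_b: str,
    external: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-gene p and BH-adjusted p for a two-subtype comparison.

    If ``external`` (columns ``p`` and ``padj``, indexed by gene) is
    supplied — e.g. exported from a dedicated count-model package — it
    is ingested unchanged. Otherwise a stand-in Welch two-sample t-test
    on log2(FPKM+1) is computed per gene, with BH adjustment across
    genes; genes with zero variance in both groups get p = 1.
    """
    if external is not None:
        missing = matrix.genes.difference(external.index)
        if len(missing):
            raise ExpressionError(
                f"external stats missing genes: {', '.join(map(str, missing[:5]))}"
            )
        out = external.loc[matrix.genes, ["p", "padj"]].copy()
        out["method"] = "external"
        return out

    a = matrix.samples_of(group_a)
    b = matrix.samples_of(group_b)
    if len(a) < 2 or len(b) < 2:
        raise ExpressionError(
            f"need >= 2 samples per group ({group_a}: {len(a)}, {group_b}: {len(b)})"
        )
    log_fpkm = np.log2(matrix.get_fpkm() + 1.0)
    xa = log_fpkm[a].to_numpy()
    xb = log_fpkm[b].to_numpy()
    zero_var = (np.ptp(xa, axis=1) == 0) & (np.ptp(xb, axis=1) == 0)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # constant genes
        _, p = stats.ttest_ind(xa, xb, axis=1, equal_var=False)
    p = np.where(zero_var | ~np.isfinite(p), 1.0, p)
    return pd.DataFrame(
        {"p": p, "padj": benjamini_hochberg(p), "method": "welch_log2fpkm1"},
        index=matrix.genes,
    )


def deg_filter(
    matrix: ExpressionMatrix,
    group_a: str,
    group_b: str,
    criteria: DEGCriteria | None = None,
    stats_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Evaluate the differential-expression criteria for one comparison.

    Per gene: the enriched group is the one with the larger mean FPKM;
    fold enrichment divides by the other group's mean (0.01 FPKM
    pseudocount when it is zero); a gene passes iff fold > min_fold
    (skipped in rod-vs-cone mode) AND p < max_p AND padj < max_padj AND
    the fraction of enriched-group samples with positive raw counts
    exceeds min_positive_fraction. Returns one row per gene with
    per-criterion flags and the conjunction in ``pass_``.
    """
    if criteria is None:
        criteria = DEGCriteria()
    a = matrix.samples_of(group_a)
    b = matrix.samples_of(group_b)
    if not a or not b:
        known = sorted(set(matrix.metadata["subtype"]))
        raise ExpressionError(
            f"unknown comparison groups {group_a!r}/{group_b!r}; valid: {known}"
        )
    if stats_table is None:
        stats_table = per_gene_stats(matrix, group_a, group_b)

    fp = matrix.get_fpkm()
    mean_a = fp[a].mean(axis=1).to_numpy()
    mean_b = fp[b].mean(axis=1).to_numpy()
    a_enriched = mean_a >= mean_b
    enriched_group = np.where(a_enriched, group_a, group_b)
    mean_hi = np.where(a_enriched, mean_a, mean_b)
    mean_lo = np.where(a_enriched, mean_b, mean_a)
    denom = np.where(mean_lo > 0, mean_lo, criteria.fold_pseudocount)
    fold = mean_hi / denom

    pos_a = (matrix.counts[a] > 0).mean(axis=1).to_numpy()
    pos_b = (matrix.counts[b] > 0).mean(axis=1).to_numpy()
    pos_frac = np.where(a_enriched, pos_a, pos_b)

    p = stats_table.loc[matrix.genes, "p"].to_numpy(dtype=float)
    padj = stats_table.loc[matrix.genes, "padj"].to_numpy(dtype=float)

    fold_ok = (
        np.ones_like(fold, dtype=bool)
        if criteria.rod_vs_cone_mode
        else fold > criteria.min_fold
    )
    p_ok = p < criteria.max_p
    padj_ok = padj < criteria.max_padj
    pos_ok = pos_frac > criteria.min_positive_fraction

    return pd.DataFrame(
        {
            f"mean_fpkm_{group_a}": mean_a,
            f"mean_fpkm_{group_b}": mean_b,
            "enriched_group": enriched_group,
            "fold_enrichment": fold,
            "p": p,
            "padj": padj,
            "positive_fraction": pos_frac,
            "fold_ok": fold_ok,
            "fold_criterion": "skipped" if criteria.rod_vs_cone_mode else "applied",
            "p_ok": p_ok,
            "padj_ok": padj_ok,
            "positive_ok": pos_ok,
            "pass_": fold_ok & p_ok & padj_ok & pos_ok,
        },
        index=matrix.genes,
    )


def tf_expressed(
    matrix: ExpressionMatrix,
    tf_gene_list: list[str],
    min_sample_fraction: float = 0.2,
) -> tuple[list[str], list[str]]:
    """Transcription factors expressed in at least 20% of samples.

    A TF is retained iff the fraction of samples with positive raw
    counts is >= ``min_sample_fraction`` (at the 35-sample design, 7
    of 35). Returns ``(retained, unknown)`` where ``unknown`` lists the
    requested genes absent from the matrix (reported, skipped).
    """
    unknown = [g for g in tf_gene_list if g not in matrix.genes]
    known = [g for g in tf_gene_list if g in matrix.genes]
    if not known:
        return [], unknown
    frac = (matrix.counts.loc[known] > 0).mean(axis=1)
    retained = [g for g in known if frac[g] >= min_sample_fraction]
    return retained, unknown


def rod_contamination(matrix: ExpressionMatrix, rho_gene_id: str = "rho") -> pd.DataFrame:
    """Per-sample rod-contamination score from rhodopsin signal.

    score_s = 100 * FPKM_rho,s / mean(FPKM_rho over rod samples). Rod
    samples are reported too (expected near 100). Bands: low (< 5),
    moderate, high (> 15) — an interpretation of the published
    contamination bands; the exact published formula is unstated.
    """
    if rho_gene_id not in matrix.genes:
        raise ExpressionError(f"rho gene {rho_gene_id!r} absent from matrix")
    rods = matrix.samples_of("rod")
    if not rods:
        raise ExpressionError("need at least one rod sample as reference")
    fp = matrix.get_fpkm()
    rho = fp.loc[rho_gene_id]
    rod_mean = float(rho[rods].mean())
    if rod_mean == 0:
        raise ExpressionError("no rod reference signal: rod-mean rho FPKM is 0")
    score = 100.0 * rho / rod_mean
    band = pd.cut(
        score,
        bins=[-np.inf, 5.0, 15.0, np.inf],
        labels=["low", "moderate", "high"],
        right=False,
    ).astype(str)
    # boundary convention: <5 low, >15 high, [5, 15] moderate
    band[score == 15.0] = "moderate"
    return pd.DataFrame(
        {
            "subtype": matrix.metadata.loc[score.index, "subtype"],
            "rho_fpkm": rho,
            "contamination_pct": score,
            "band": band,
        }
    )
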