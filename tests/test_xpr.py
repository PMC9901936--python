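import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from conemosaiq.synthdata import EnrichedSet, SynthExpressionSpec, generate_expression
from conemosaiq.xpr import (
    DEGCriteria,
    ExpressionError,
    ExpressionMatrix,
    aggregate_genes,
    benjamini_hochberg,
    deg_filter,
    fpkm,
    per_gene_stats,
    rod_contamination,
    tf_expressed,
)


def toy_matrix(counts, lengths=None, totals=None, subtypes=None):
    counts = pd.DataFrame(counts)
    counts.index = [f"g{i}" for i in range(counts.shape[0])] if not isinstance(
        counts.index[0], str
    ) else counts.index
    if lengths is None:
        lengths = pd.Series(1000, index=counts.index)
    if totals is None:
        totals = pd.Series(1e6, index=counts.columns)
    if subtypes is None:
        subtypes = ["UV"] * counts.shape[1]
    metadata = pd.DataFrame({"subtype": subtypes}, index=counts.columns)
    return ExpressionMatrix(
        counts=counts,
        gene_lengths=pd.Series(lengths, index=counts.index)
        if np.isscalar(lengths) else lengths,
        totals=pd.Series(totals, index=counts.columns)
        if np.isscalar(totals) else totals,
        metadata=metadata,
    )


def brute_force_deg(matrix, group_a, group_b, stats_table, criteria):
    """Independent per-gene predicate evaluation by explicit loops."""
    fp = fpkm(matrix)
    a = matrix.samples_of(group_a)
    b = matrix.samples_of(group_b)
    passing = set()
    for gene in matrix.genes:
        mean_a = fp.loc[gene, a].mean()
        mean_b = fp.loc[gene, b].mean()
        if mean_a >= mean_b:
            hi, lo, enriched = mean_a, mean_b, a
        else:
            hi, lo, enriched = mean_b, mean_a, b
        fold = hi / (lo if lo > 0 else criteria.fold_pseudocount)
        pos = sum(matrix.counts.loc[gene, s] > 0 for s in enriched) / len(enriched)
        ok = True
        if not criteria.rod_vs_cone_mode and not (fold > criteria.min_fold):
            ok = False
        if not (stats_table.loc[gene, "p"] < criteria.max_p):
            ok = False
        if not (stats_table.loc[gene, "padj"] < criteria.max_padj):
            ok = False
        if not (pos > criteria.min_positive_fraction):
            ok = False
        if ok:
            passing.add(gene)
    return passing


class TestFpkm:
    def test_unit_case(self):
        m = toy_matrix({"s1": [10]}, lengths=1000, totals=1e6)
        assert fpkm(m).iloc[0, 0] == pytest.approx(10.0)

    def test_zero_counts(self):
        m = toy_matrix({"s1": [0]}, lengths=1234, totals=5e6)
        assert fpkm(m).iloc[0, 0] == 0.0

    def test_matches_double_loop(self, rng):
        counts = pd.DataFrame(
            rng.integers(0, 1000, size=(50, 10)),
            index=[f"g{i}" for i in range(50)],
            columns=[f"s{j}" for j in range(10)],
        )
        lengths = pd.Series(rng.integers(200, 5000, size=50), index=counts.index)
        totals = pd.Series(rng.integers(int(1e6), int(2e7), size=10).astype(float),
                           index=counts.columns)
        m = toy_matrix(counts, lengths=lengths, totals=totals)
        result = fpkm(m)
        for g in counts.index:
            for s in counts.columns:
                expected = counts.loc[g, s] / (lengths[g] / 1e3) / (totals[s] / 1e6)
                assert result.loc[g, s] == pytest.approx(expected, rel=1e-12)

    def test_doubling_totals_halves_fpkm(self, rng):
        counts = pd.DataFrame(rng.integers(0, 100, size=(20, 4)))
        counts.index = [f"g{i}" for i in range(20)]
        counts.columns = [f"s{j}" for j in range(4)]
        m1 = toy_matrix(counts, totals=1e6)
        m2 = toy_matrix(counts, totals=2e6)
        np.testing.assert_allclose(fpkm(m2).values, fpkm(m1).values / 2)

    def test_missing_length_reported(self):
        counts = pd.DataFrame({"s1": [1, 2]}, index=["gA", "gB"])
        lengths = pd.Series([100], index=["gA"])
        with pytest.raises(ExpressionError, match="gB"):
            toy_matrix(counts, lengths=lengths)


class TestAggregateGenes:
    def test_preset_sum(self):
        counts = pd.DataFrame(
            {"s1": [1, 2, 3, 4, 99]},
            index=["opn1mw1", "opn1mw2", "opn1mw3", "opn1mw4", "other"],
        )
        m = toy_matrix(counts)
        assert aggregate_genes(m, "M-opsin")["s1"] == 10

    def test_all_zero(self):
        counts = pd.DataFrame({"s1": [0, 0]}, index=["opn1lw1", "opn1lw2"])
        m = toy_matrix(counts)
        assert aggregate_genes(m, "L-opsin")["s1"] == 0

    def test_matches_loop(self, rng):
        genes = [f"g{i}" for i in range(10)]
        counts = pd.DataFrame(
            rng.integers(0, 50, size=(10, 3)), index=genes,
            columns=["s1", "s2", "s3"],
        )
        m = toy_matrix(counts)
        members = ["g1", "g4", "g7"]
        agg = aggregate_genes(m, "custom", members)
        for s in counts.columns:
            assert agg[s] == sum(counts.loc[g, s] for g in members)

    def test_missing_member_listed(self):
        m = toy_matrix(pd.DataFrame({"s1": [1]}, index=["opn1lw1"]))
        with pytest.raises(ExpressionError, match="opn1lw2"):
            aggregate_genes(m, "L-opsin")


class TestPerGeneStats:
    def test_identical_groups_p_one(self):
        counts = pd.DataFrame(
            {"a1": [5, 5], "a2": [5, 5], "b1": [5, 5], "b2": [5, 5]},
            index=["gA", "gB"],
        )
        m = toy_matrix(counts, subtypes=["UV", "UV", "S", "S"])
        out = per_gene_stats(m, "UV", "S")
        assert (out["p"] == 1.0).all()

    def test_bh_hand_values(self):
        adjusted = benjamini_hochberg(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(adjusted, [0.04, 0.04, 0.04, 0.04])

    def test_bh_step_up_generic(self):
        p = np.array([0.005, 0.009, 0.05, 0.5])
        # hand step-up: [0.02, 0.018->min chain, ...]
        expected = np.array([0.018, 0.018, 0.2 / 3, 0.5])
        np.testing.assert_allclose(benjamini_hochberg(p), expected)

    def test_bh_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=200)
        mine = benjamini_hochberg(p)
        _, ref, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(mine, ref, atol=1e-12)

    def test_welch_matches_scipy_reference(self, rng):
        spec = SynthExpressionSpec(
            n_genes=80,
            enriched_sets=[EnrichedSet("UV", ["g00005", "g00010"], fold=8)],
            seed=3,
        )
        matrix, _ = generate_expression(spec)
        out = per_gene_stats(matrix, "UV", "S")
        log_fp = np.log2(matrix.get_fpkm() + 1)
        a = matrix.samples_of("UV")
        b = matrix.samples_of("S")
        for gene in matrix.genes[:40]:
            xa = log_fp.loc[gene, a].to_numpy()
            xb = log_fp.loc[gene, b].to_numpy()
            if np.ptp(xa) == 0 and np.ptp(xb) == 0:
                assert out.loc[gene, "p"] == 1.0
            else:
                ref = sps.ttest_ind(xa, xb, equal_var=False)
                assert out.loc[gene, "p"] == pytest.approx(ref.pvalue, abs=1e-8)

    def test_external_stats_ingested_unchanged(self):
        counts = pd.DataFrame(
            {"a1": [5, 1], "a2": [4, 2], "b1": [5, 9], "b2": [6, 8]},
            index=["gA", "gB"],
        )
        m = toy_matrix(counts, subtypes=["UV", "UV", "S", "S"])
        external = pd.DataFrame(
            {"p": [0.123, 0.456], "padj": [0.2, 0.5]}, index=["gA", "gB"]
        )
        out = per_gene_stats(m, "UV", "S", external=external)
        assert out.loc["gA", "p"] == 0.123
        assert out.loc["gB", "padj"] == 0.5
        assert (out["method"] == "external").all()

    def test_too_few_samples_rejected(self):
        counts = pd.DataFrame({"a1": [5], "b1": [5], "b2": [5]}, index=["gA"])
        m = toy_matrix(counts, subtypes=["UV", "S", "S"])
        with pytest.raises(ExpressionError, match=">= 2"):
            per_gene_stats(m, "UV", "S")


class TestDegFilter:
    def _random_matrix(self, rng, n_genes=200):
        counts = pd.DataFrame(
            rng.integers(0, 40, size=(n_genes, 12)),
            index=[f"g{i:04d}" for i in range(n_genes)],
            columns=[f"s{j}" for j in range(12)],
        )
        # sprinkle zeros to exercise the positive-fraction criterion
        zero_mask = rng.uniform(size=counts.shape) < 0.35
        counts = counts.mask(zero_mask, 0)
        return toy_matrix(counts, subtypes=["UV"] * 6 + ["S"] * 6)

    def test_all_criteria_met_passes(self):
        counts = pd.DataFrame(
            {f"a{i}": [40] for i in range(6)} | {f"b{i}": [10] for i in range(6)},
            index=["gA"],
        )
        m = toy_matrix(counts, subtypes=["UV"] * 6 + ["S"] * 6)
        stats_table = pd.DataFrame({"p": [0.001], "padj": [0.05]}, index=["gA"])
        out = deg_filter(m, "UV", "S", DEGCriteria(), stats_table)
        assert bool(out.loc["gA", "pass_"])
        assert out.loc["gA", "enriched_group"] == "UV"
        assert out.loc["gA", "fold_enrichment"] == pytest.approx(4.0)

    def test_fold_criterion_toggled_in_rod_vs_cone_mode(self):
        counts = pd.DataFrame(
            {f"a{i}": [14] for i in range(6)} | {f"b{i}": [10] for i in range(6)},
            index=["gA"],
        )
        m = toy_matrix(counts, subtypes=["rod"] * 6 + ["UV"] * 6)
        stats_table = pd.DataFrame({"p": [0.001], "padj": [0.05]}, index=["gA"])
        strict = deg_filter(m, "rod", "UV", DEGCriteria(), stats_table)
        relaxed = deg_filter(
            m, "rod", "UV", DEGCriteria(rod_vs_cone_mode=True), stats_table
        )
        assert not bool(strict.loc["gA", "pass_"])  # fold 1.4 < 1.5
        assert bool(relaxed.loc["gA", "pass_"])
        assert relaxed.loc["gA", "fold_criterion"] == "skipped"

    def test_strictness_of_positive_fraction(self):
        # exactly 50% positive fails the strict > 0.5 requirement
        counts = pd.DataFrame(
            {"a1": [9], "a2": [9], "a3": [0], "a4": [0], "b1": [0], "b2": [0]},
            index=["gA"],
        )
        m = toy_matrix(counts, subtypes=["UV"] * 4 + ["S"] * 2)
        stats_table = pd.DataFrame({"p": [0.0001], "padj": [0.001]}, index=["gA"])
        out = deg_filter(m, "UV", "S", DEGCriteria(), stats_table)
        assert out.loc["gA", "positive_fraction"] == pytest.approx(0.5)
        assert not bool(out.loc["gA", "pass_"])

    def test_matches_brute_force_oracle(self, rng):
        for trial in range(10):
            m = self._random_matrix(rng)
            stats_table = pd.DataFrame(
                {
                    "p": rng.uniform(0, 0.05, size=len(m.genes)),
                    "padj": rng.uniform(0, 0.2, size=len(m.genes)),
                },
                index=m.genes,
            )
            criteria = DEGCriteria(rod_vs_cone_mode=bool(trial % 2))
            result = deg_filter(m, "UV", "S", criteria, stats_table)
            mine = set(result.index[result["pass_"]])
            oracle = brute_force_deg(m, "UV", "S", stats_table, criteria)
            assert mine == oracle

    def test_pass_is_conjunction_of_flags(self, rng):
        m = self._random_matrix(rng, n_genes=100)
        stats_table = pd.DataFrame(
            {"p": rng.uniform(size=100), "padj": rng.uniform(size=100)},
            index=m.genes,
        )
        out = deg_filter(m, "UV", "S", DEGCriteria(), stats_table)
        np.testing.assert_array_equal(
            out["pass_"].to_numpy(),
            (out["fold_ok"] & out["p_ok"] & out["padj_ok"] & out["positive_ok"]).to_numpy(),
        )

    def test_unknown_group_lists_valid_labels(self, rng):
        m = self._random_matrix(rng, n_genes=10)
        with pytest.raises(ExpressionError, match="valid"):
            deg_filter(m, "UV", "rod")


class TestTfExpressed:
    def _binary_matrix(self, rng, n_genes=40, n_samples=35):
        counts = pd.DataFrame(
            (rng.uniform(size=(n_genes, n_samples)) < 0.2).astype(int) * 7,
            index=[f"tf{i}" for i in range(n_genes)],
            columns=[f"s{j}" for j in range(n_samples)],
        )
        return toy_matrix(counts, subtypes=["rod"] * n_samples)

    def test_seven_of_35_retained(self):
        counts = pd.DataFrame(
            [[3] * 7 + [0] * 28], index=["tfA"], columns=[f"s{j}" for j in range(35)]
        )
        m = toy_matrix(counts, subtypes=["rod"] * 35)
        retained, _ = tf_expressed(m, ["tfA"])
        assert retained == ["tfA"]

    def test_six_of_35_dropped(self):
        counts = pd.DataFrame(
            [[3] * 6 + [0] * 29], index=["tfA"], columns=[f"s{j}" for j in range(35)]
        )
        m = toy_matrix(counts, subtypes=["rod"] * 35)
        retained, _ = tf_expressed(m, ["tfA"])
        assert retained == []

    def test_matches_brute_force(self, rng):
        m = self._binary_matrix(rng)
        tf_list = list(m.genes)
        retained, _ = tf_expressed(m, tf_list)
        oracle = [
            g
            for g in tf_list
            if sum(m.counts.loc[g, s] > 0 for s in m.samples) / len(m.samples) >= 0.2
        ]
        assert retained == oracle

    def test_unknown_genes_reported_skipped(self, rng):
        m = self._binary_matrix(rng, n_genes=5)
        retained, unknown = tf_expressed(m, ["tf0", "nope1", "nope2"])
        assert unknown == ["nope1", "nope2"]

    def test_empty_list_empty_result(self, rng):
        m = self._binary_matrix(rng, n_genes=3)
        assert tf_expressed(m, []) == ([], [])


class TestRodContamination:
    def _matrix_with_rho(self, cone_rho, rod_rho=(1000, 1000)):
        samples = [f"rod{i}" for i in range(len(rod_rho))] + [
            f"cone{i}" for i in range(len(cone_rho))
        ]
        counts = pd.DataFrame(
            [list(rod_rho) + list(cone_rho), [50] * len(samples)],
            index=["rho", "other"],
            columns=samples,
        )
        subtypes = ["rod"] * len(rod_rho) + ["L"] * len(cone_rho)
        return toy_matrix(counts, subtypes=subtypes)

    def test_zero_rho_scores_zero_band_low(self):
        report = rod_contamination(self._matrix_with_rho([0]))
        assert report.loc["cone0", "contamination_pct"] == 0.0
        assert report.loc["cone0", "band"] == "low"

    def test_hand_ratio(self):
        report = rod_contamination(self._matrix_with_rho([50]))
        assert report.loc["cone0", "contamination_pct"] == pytest.approx(5.0)

    def test_rod_samples_near_100(self):
        report = rod_contamination(self._matrix_with_rho([10]))
        assert report.loc["rod0", "contamination_pct"] == pytest.approx(100.0)

    def test_bands(self):
        report = rod_contamination(self._matrix_with_rho([10, 100, 400]))
        assert report.loc["cone0", "band"] == "low"       # 1%
        assert report.loc["cone1", "band"] == "moderate"  # 10%
        assert report.loc["cone2", "band"] == "high"      # 40%

    def test_invariant_to_joint_total_rescaling(self):
        m1 = self._matrix_with_rho([100])
        m2 = self._matrix_with_rho([100])
        m2.totals = m2.totals * 7.0
        r1 = rod_contamination(m1)
        r2 = rod_contamination(m2)
        np.testing.assert_allclose(
            r1["contamination_pct"].to_numpy(dtype=float),
            r2["contamination_pct"].to_numpy(dtype=float),
        )

    def test_zero_rod_reference_rejected(self):
        with pytest.raises(ExpressionError, match="no rod reference"):
            rod_contamination(self._matrix_with_rho([10], rod_rho=(0, 0)))

    def test_synthetic_mixture_recovers_contamination(self):
        scores = []
        for seed in range(5):
            spec = SynthExpressionSpec(
                n_genes=200,
                enriched_sets=[
                    EnrichedSet("rod", ["g00000"], fold=100, exclusive=True)
                ],
                contamination_fraction=0.2,
                dispersion=0.05,
                seed=seed,
            )
            matrix, _ = generate_expression(spec)
            # rho lives at g00000 in this construction
            report = rod_contamination(matrix, "g00000")
            cone_scores = report.loc[report["subtype"] != "rod", "contamination_pct"]
            scores.append(cone_scores.mean())
        # mixture weight 0.2 -> mean cone score near 20
        assert abs(np.mean(scores) - 20.0) < 5.0


class TestNullMatrixProperties:
    def test_null_pass_rate_bounded(self):
        spec = SynthExpressionSpec(n_genes=400, seed=21)  # no planted effects
        matrix, _ = generate_expression(spec)
        stats_table = per_gene_stats(matrix, "UV", "S")
        frac_p = (stats_table["p"] < 0.01).mean()
        # binomial bound around 0.01 at n=400 (the t-approximation at
        # n=6 makes this conservative, not exact)
        assert frac_p < 0.04
        result = deg_filter(matrix, "UV", "S", stats_table=stats_table)
        assert result["pass_"].mean() <= frac_p

    def test_planted_folds_recovered_with_high_sensitivity(self):
        hits, total = 0, 0
        for seed in range(8):
            planted = [f"g{i:05d}" for i in range(10)]
            spec = SynthExpressionSpec(
                n_genes=300,
                enriched_sets=[EnrichedSet("UV", planted, fold=10)],
                n_samples_per_subtype=6,
                dispersion=0.2,
                seed=seed,
            )
            matrix, truth = generate_expression(spec)
            result = deg_filter(matrix, "UV", "S")
            hits += int(result.loc[planted, "pass_"].sum())
            total += len(planted)
        assert hits / total >= 0.9
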