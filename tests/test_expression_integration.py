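import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from pnmeth import (
    cpm,
    expressed_filter,
    gene_report,
    methylation_expression_correlation,
    normalize_expression,
    pairwise_dm,
    significant_sites,
    tmm_factors,
)


class TestCPM:
    def test_direct_formula(self):
        counts = pd.DataFrame({"s": [10, 90]}, index=["g1", "g2"])
        out = cpm(counts)
        assert out["s"].tolist() == [1e5, 9e5]

    def test_zero_gene_and_column_sums(self, rng):
        counts = pd.DataFrame(rng.integers(0, 100, (20, 4)),
                              index=[f"g{i}" for i in range(20)], columns=list("abcd"))
        counts.iloc[0] = 0
        out = cpm(counts)
        assert (out.iloc[0] == 0).all()
        assert np.allclose(out.sum(axis=0), 1e6)

    def test_zero_library_rejected(self):
        counts = pd.DataFrame({"a": [1, 2], "b": [0, 0]})
        with pytest.raises(ValueError, match="zero library"):
            cpm(counts)


class TestExpressedFilter:
    def test_threshold_floor_at_47_samples(self, rng):
        """With 47 samples the 5% rule floors at 2 samples: >= 3 CPM in 2
        samples keeps the gene, in only 1 drops it."""
        n = 47
        counts = pd.DataFrame(1000, index=[f"g{i}" for i in range(50)],
                              columns=[f"s{i}" for i in range(n)])
        counts.loc["g_two"] = 0
        counts.loc["g_two", ["s0", "s1"]] = 10  # cpm ~ 200 in 2 samples
        counts.loc["g_one"] = 0
        counts.loc["g_one", "s0"] = 10
        counts.loc["g_zero"] = 0
        kept = expressed_filter(counts)
        assert "g_two" in kept
        assert "g_one" not in kept
        assert "g_zero" not in kept

    def test_boundary_inclusive(self):
        # 40 samples -> threshold = max(2, floor(2.0)) = 2
        counts = pd.DataFrame(1000, index=[f"g{i}" for i in range(10)],
                              columns=[f"s{i}" for i in range(40)])
        gene = pd.Series(0, index=counts.columns)
        gene[["s0", "s1"]] = counts["s0"].sum() * 3 // int(1e6) + 1
        counts.loc["g_edge"] = gene
        assert ("g_edge" in expressed_filter(counts)) == bool(
            (cpm(counts).loc["g_edge"] >= 3).sum() >= 2
        )


class TestTMM:
    def test_identical_columns_unit_factors(self):
        col = np.array([5, 50, 500, 20, 0, 80])
        counts = pd.DataFrame({c: col for c in "abcd"},
                              index=[f"g{i}" for i in range(6)])
        factors, _ = tmm_factors(counts)
        assert np.allclose(factors, 1.0)

    def test_pure_depth_difference_drops_out(self, rng):
        base = rng.negative_binomial(20, 0.1, size=300)
        counts = pd.DataFrame({"a": base, "b": base * 2, "c": base},
                              index=[f"g{i}" for i in range(300)])
        factors, _ = tmm_factors(counts)
        assert np.allclose(factors, 1.0, atol=1e-9)

    def test_matches_edger_calcnormfactors(self, tmp_path, rng):
        counts = pd.DataFrame(rng.negative_binomial(20, 0.1, size=(300, 4)),
                              index=[f"g{i}" for i in range(300)],
                              columns=list("abcd"))
        counts.iloc[:30, 0] *= 4  # composition bias
        factors, _ = tmm_factors(counts)
        cfile = tmp_path / "counts.tsv"
        counts.to_csv(cfile, sep="\t")
        script = tmp_path / "tmm.R"
        script.write_text(textwrap.dedent(f"""
            suppressMessages(library(edgeR))
            x <- as.matrix(read.table("{cfile}", header=TRUE, row.names=1, sep="\t"))
            cat(paste(calcNormFactors(x, method="TMM"), collapse=","), "\n")
        """))
        out = subprocess.run(["Rscript", str(script)], capture_output=True, text=True)
        assert out.returncode == 0, out.stderr
        edger = np.array([float(v) for v in out.stdout.strip().split(",")])
        assert np.allclose(factors.to_numpy(), edger, rtol=1e-10)

    def test_bad_trim_fractions_rejected(self, rng):
        counts = pd.DataFrame(rng.integers(1, 50, (10, 3)), columns=list("abc"))
        with pytest.raises(ValueError, match="trim"):
            tmm_factors(counts, trim_m=0.6)

    def test_geometric_mean_one(self, rng):
        counts = pd.DataFrame(rng.integers(0, 200, (200, 5)),
                              columns=[f"s{i}" for i in range(5)])
        factors, _ = tmm_factors(counts)
        assert np.exp(np.mean(np.log(factors))) == pytest.approx(1.0)


class TestCorrelation:
    def test_perfect_linear(self, cohort):
        # direct check of the vectorized Pearson path on a planted pair
        from pnmeth.expression_integration import _pearson_p
        r = np.array([1.0, 0.0])
        p = _pearson_p(r, 5)
        assert p[0] == 0.0 and p[1] == pytest.approx(1.0)

    def test_planted_linkage_recovered(self, cohort):
        dm = pairwise_dm(cohort.beta, cohort.truth.labels)
        sites = significant_sites(dm)
        expressed = expressed_filter(cohort.counts)
        expression = normalize_expression(cohort.counts, expressed)
        corr = methylation_expression_correlation(
            cohort.beta, expression, cohort.annotation, sites, expressed
        )
        linked = cohort.truth.linked_genes.set_index("gene")
        hit = corr[corr["gene"].isin(linked.index)]
        per_gene_sig = hit.assign(sig=hit["p_adj"] < 0.05).groupby("gene")["sig"].mean()
        assert per_gene_sig.mean() >= 0.90
        # recovered signs match the planted ones
        mean_r = hit.groupby("gene")["r"].mean()
        signs = np.sign(mean_r).astype(int)
        assert (signs == linked.loc[signs.index, "sign"]).mean() >= 0.95

    def test_unlinked_pairs_rarely_flagged(self, cohort):
        dm = pairwise_dm(cohort.beta, cohort.truth.labels)
        sites = significant_sites(dm)
        expressed = expressed_filter(cohort.counts)
        expression = normalize_expression(cohort.counts, expressed)
        corr = methylation_expression_correlation(
            cohort.beta, expression, cohort.annotation, sites, expressed
        )
        linked = set(cohort.truth.linked_genes["gene"])
        null = corr[~corr["gene"].isin(linked)]
        assert (null["p_adj"] < 0.05).mean() <= 0.06

    def test_constant_probe_skipped(self, cohort):
        from pnmeth import BetaMatrix

        expression = normalize_expression(cohort.counts)
        values = cohort.beta.values.copy()
        const_probe = values.index[0]
        values.loc[const_probe] = 0.42  # force a constant row
        beta = BetaMatrix(values, cohort.beta.sample_role)
        gene = cohort.annotation.gene_map.iloc[0]["gene"]
        sites = pd.Index([const_probe, cohort.truth.dm_probes["T1"][0]])
        corr = methylation_expression_correlation(
            beta, expression, cohort.annotation, sites,
            expressed_genes=pd.Index(cohort.counts.gene_ids),
        )
        assert const_probe not in set(corr["probe_id"])

    def test_too_few_shared_samples_rejected(self, cohort):
        expression = normalize_expression(cohort.counts)
        expression.log_expression = expression.log_expression.iloc[:, :2]
        with pytest.raises(ValueError, match="shared samples"):
            methylation_expression_correlation(
                cohort.beta, expression, cohort.annotation,
                pd.Index(cohort.truth.dm_probes["T1"]),
            )


class TestGeneReport:
    def _expression(self, cohort):
        return normalize_expression(cohort.counts, expressed_filter(cohort.counts))

    def test_planted_gene_body_linkage(self, cohort):
        linked = cohort.truth.linked_genes
        positive = linked.loc[linked["sign"] == 1, "gene"].iloc[0]
        report = gene_report(positive, cohort.beta, self._expression(cohort),
                             cohort.annotation, cohort.truth.labels)
        assert report.correlation_r > 0
        assert report.correlation_p < 0.05
        # probes come back in genomic order
        assert report.probes["position"].is_monotonic_increasing

    def test_contrast_flags_target_subgroup(self, cohort):
        linked = cohort.truth.linked_genes
        gene = linked["gene"].iloc[0]
        target = linked["subgroup"].iloc[0]
        report = gene_report(gene, cohort.beta, None, cohort.annotation,
                             cohort.truth.labels)
        row = report.contrasts.set_index("subgroup").loc[target, "p"]
        assert row < 0.01

    def test_unlinked_gene_weak_correlation(self, cohort):
        linked = set(cohort.truth.linked_genes["gene"])
        dm_genes = {g for gs in cohort.truth.dm_genes.values() for g in gs}
        unlinked = sorted(dm_genes - linked)[0]
        report = gene_report(unlinked, cohort.beta, self._expression(cohort),
                             cohort.annotation, cohort.truth.labels)
        assert abs(report.correlation_r) <= 0.3

    def test_single_probe_gene_median_is_probe_beta(self, cohort):
        gm = cohort.annotation.gene_map
        counts = gm.drop_duplicates(["probe_id", "gene"]).groupby("gene").size()
        single = counts.index[counts == 1][0]
        report = gene_report(single, cohort.beta, None, cohort.annotation,
                             cohort.truth.labels)
        probe = report.probes["probe_id"].iloc[0]
        expected = cohort.beta.tumour_values().loc[probe]
        assert np.allclose(report.sample_median_body_beta, expected)

    def test_unknown_gene_rejected(self, cohort):
        with pytest.raises(ValueError, match="no annotated probes"):
            gene_report("NOPE", cohort.beta, None, cohort.annotation,
                        cohort.truth.labels)
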