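import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.metrics import adjusted_rand_score

from pnmeth import (
    BetaMatrix,
    BinaryMatrix,
    SubtypeConfig,
    binary_distance_matrix,
    dichotomize,
    run_subtyping,
    select_promoter_probes,
    select_unmethylated_in_normals,
    select_variable_probes,
    silhouette_scan,
    truth_recovery_report,
    ward_cluster,
)


def _beta_from_normals(normal_rows):
    """One matrix with given normal beta rows plus two dummy tumours."""
    n = len(normal_rows[0])
    cols = [f"n{i}" for i in range(n)] + ["t1", "t2"]
    values = pd.DataFrame(
        [list(row) + [0.5, 0.5] for row in normal_rows],
        index=[f"cg{i}" for i in range(len(normal_rows))],
        columns=cols,
    )
    roles = pd.Series(["normal"] * n + ["tumour", "tumour"], index=cols)
    return BetaMatrix(values, roles)


class TestCascadeSelectors:
    def test_unmethylated_in_normals_strict(self):
        beta = _beta_from_normals([
            (0.10, 0.22, 0.29),  # all below -> retained
            (0.10, 0.31, 0.05),  # one above -> excluded
            (0.30, 0.10, 0.10),  # boundary: strict '<' -> excluded
        ])
        assert list(select_unmethylated_in_normals(beta)) == ["cg0"]

    def test_no_normals_rejected(self):
        values = pd.DataFrame([[0.1, 0.2]], index=["cg0"], columns=["a", "b"])
        beta = BetaMatrix(values, pd.Series("tumour", index=["a", "b"]))
        with pytest.raises(ValueError, match="no normal"):
            select_unmethylated_in_normals(beta)

    def test_promoter_any_membership(self, cohort):
        annot = cohort.annotation
        promoter = set(select_promoter_probes(annot))
        gm = annot.gene_map
        body_only = set(gm["probe_id"]) - set(
            gm.loc[gm["region"].isin({"TSS1500", "TSS200", "5'UTR", "1stExon"}), "probe_id"]
        )
        intergenic = set(annot.probe_ids) - set(gm["probe_id"])
        assert promoter.isdisjoint(body_only)
        assert promoter.isdisjoint(intergenic)

    def test_variable_probes_sd_boundary(self):
        cols = ["t1", "t2", "t3"]
        values = pd.DataFrame(
            [[0.1, 0.5, np.nan], [0.2, 0.2, 0.2], [0.1, 0.3, 0.5]],
            index=["cg_two", "cg_const", "cg_exact"], columns=cols,
        )
        # use only 2 samples for cg_two via a separate 2-column matrix
        two = BetaMatrix(values[["t1", "t2"]], pd.Series("tumour", index=cols[:2]))
        sel = select_variable_probes(two)
        assert "cg_two" in sel  # SD = 0.2828 > 0.2
        assert "cg_const" not in sel
        three = BetaMatrix(values.fillna(0.5), pd.Series("tumour", index=cols))
        assert "cg_exact" not in select_variable_probes(three)  # SD = 0.2 exactly
        assert "cg_exact" in select_variable_probes(three, inclusive=True)


class TestDichotomize:
    def test_boundary_is_presence(self):
        df = pd.DataFrame([[0.30, 0.29]], index=["cg0"], columns=["a", "b"])
        bm = dichotomize(df)
        assert bm.values.loc["cg0", "a"] == 1
        assert bm.values.loc["cg0", "b"] == 0

    def test_missing_rejected(self):
        df = pd.DataFrame([[0.3, np.nan]], index=["cg0"], columns=["a", "b"])
        with pytest.raises(ValueError, match="missing"):
            dichotomize(df)

    def test_fixed_point(self, rng):
        df = pd.DataFrame(rng.random((10, 4)), columns=list("abcd"))
        once = dichotomize(df).values.astype(float)
        assert dichotomize(once).values.equals(dichotomize(df).values)


class TestBinaryDistance:
    def test_identical_columns_zero(self):
        bm = BinaryMatrix(pd.DataFrame({"a": [1, 0, 1], "b": [1, 0, 1]}))
        d = binary_distance_matrix(bm)
        assert d.loc["a", "b"] == 0

    def test_enumerated_example(self):
        bm = BinaryMatrix(pd.DataFrame({"x": [1, 0, 1, 0], "y": [1, 1, 0, 0]}))
        d = binary_distance_matrix(bm)
        assert d.loc["x", "y"] == pytest.approx(2 / 3)

    def test_all_absent_pair_defined_zero(self):
        bm = BinaryMatrix(pd.DataFrame({"a": [0, 0], "b": [0, 0], "c": [1, 0]}))
        with pytest.warns(UserWarning, match="all-absent"):
            d = binary_distance_matrix(bm)
        assert d.loc["a", "b"] == 0

    def test_matches_agreement_category_oracle(self, rng):
        """Vectorized distances equal the a/b/c category count definition on
        random binary pairs."""
        X = (rng.random((60, 40)) < 0.4).astype(int)
        bm = BinaryMatrix(pd.DataFrame(X, columns=[f"s{i}" for i in range(40)]))
        d = binary_distance_matrix(bm)
        for _ in range(200):
            i, j = rng.integers(0, 40, size=2)
            x, y = X[:, i], X[:, j]
            a = int(((x == 1) & (y == 1)).sum())
            bc = int((x != y).sum())
            expected = 0.0 if a + bc == 0 else bc / (a + bc)
            assert d.iloc[i, j] == pytest.approx(expected)

    def test_distance_axioms(self, rng):
        X = (rng.random((30, 15)) < 0.5).astype(int)
        d = binary_distance_matrix(
            BinaryMatrix(pd.DataFrame(X, columns=[f"s{i}" for i in range(15)]))
        ).to_numpy()
        assert (d >= 0).all()
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)


def _dist_frame(D, names):
    return pd.DataFrame(D, index=names, columns=names)


class TestWardCluster:
    def test_zero_distance_pair_merges_first(self):
        values = pd.DataFrame({"a": [1, 1, 0], "b": [1, 1, 0], "c": [0, 0, 1]})
        d = binary_distance_matrix(BinaryMatrix(values))
        asg = ward_cluster(d, k=2)
        assert asg.labels["a"] == asg.labels["b"] != asg.labels["c"]
        assert asg.merges[0][:2] == (0, 1)

    def test_one_dimensional_toy(self):
        pts = np.array([0.0, 1.0, 10.0])
        D = np.abs(pts[:, None] - pts[None, :])
        asg = ward_cluster(_dist_frame(D, list("abc")), k=2)
        assert asg.labels["a"] == asg.labels["b"] != asg.labels["c"]
        assert asg.merges[0][2] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_scipy_ward_on_euclidean_data(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(15, 5))
        D = np.sqrt(((X[:, None] - X[None, :]) ** 2).sum(-1))
        names = [f"s{i}" for i in range(15)]
        asg = ward_cluster(_dist_frame(D, names), k=4)
        Z = hierarchy.linkage(pdist(X), method="ward")
        assert np.allclose([m[2] for m in asg.merges], Z[:, 2])
        scipy_labels = hierarchy.fcluster(Z, 4, criterion="maxclust")
        assert adjusted_rand_score(asg.labels.to_numpy(), scipy_labels) == 1.0

    def test_ward_d_variant_matches_r_hclust(self, tmp_path):
        """Classic ward.D merge heights agree with R's hclust(..., 'ward.D')."""
        rng = np.random.default_rng(3)
        X = rng.normal(size=(8, 3))
        D = np.sqrt(((X[:, None] - X[None, :]) ** 2).sum(-1))
        names = [f"s{i}" for i in range(8)]
        asg = ward_cluster(_dist_frame(D, names), k=1, variant="ward.D")
        dfile = tmp_path / "d.tsv"
        pd.DataFrame(D).to_csv(dfile, sep="\t", index=False)
        script = tmp_path / "ward.R"
        script.write_text(textwrap.dedent(f"""
            d <- as.dist(as.matrix(read.table("{dfile}", header=TRUE, sep="\t")))
            h <- hclust(d, method="ward.D")
            cat(paste(h$height, collapse=","), "\n")
        """))
        out = subprocess.run(["Rscript", str(script)], capture_output=True, text=True)
        assert out.returncode == 0, out.stderr
        r_heights = [float(v) for v in out.stdout.strip().split(",")]
        assert np.allclose(sorted(m[2] for m in asg.merges), sorted(r_heights))

    def test_sample_permutation_invariance(self, rng):
        X = rng.normal(size=(12, 4))
        D = np.sqrt(((X[:, None] - X[None, :]) ** 2).sum(-1))
        names = [f"s{i}" for i in range(12)]
        base = ward_cluster(_dist_frame(D, names), k=3)
        perm = rng.permutation(12)
        shuffled = ward_cluster(_dist_frame(D[np.ix_(perm, perm)],
                                            [names[i] for i in perm]), k=3)
        joined = pd.concat([base.labels.rename("a"), shuffled.labels.rename("b")], axis=1)
        assert adjusted_rand_score(joined["a"], joined["b"]) == 1.0

    def test_k_out_of_range(self):
        d = _dist_frame(np.zeros((3, 3)), list("abc"))
        with pytest.raises(ValueError, match="out of range"):
            ward_cluster(d, k=4)


class TestRunSubtyping:
    def test_noiseless_recovery_is_exact(self, clean_cohort):
        asg, trace, _ = run_subtyping(clean_cohort.beta, clean_cohort.annotation)
        assert truth_recovery_report(clean_cohort, asg).ari == 1.0

    def test_cascade_counts_non_increasing(self, cohort):
        _, trace, _ = run_subtyping(cohort.beta, cohort.annotation)
        counts = list(trace.counts.values())
        assert counts == sorted(counts, reverse=True)

    def test_genome_wide_mode_matches_promoter_mode(self, clean_cohort):
        """With all planted signal carried by gene-linked probes, skipping
        the promoter restriction yields the same partition."""
        promoter, _, _ = run_subtyping(clean_cohort.beta, clean_cohort.annotation)
        genome, _, _ = run_subtyping(clean_cohort.beta, clean_cohort.annotation,
                                     SubtypeConfig(genome_wide=True))
        joined = pd.concat([promoter.labels.rename("a"), genome.labels.rename("b")], axis=1)
        assert adjusted_rand_score(joined["a"], joined["b"]) == 1.0

    def test_probe_order_invariance(self, clean_cohort, rng):
        base, _, _ = run_subtyping(clean_cohort.beta, clean_cohort.annotation)
        order = rng.permutation(len(clean_cohort.beta.probe_ids))
        shuffled = clean_cohort.beta.subset_probes(clean_cohort.beta.probe_ids[order])
        again, _, _ = run_subtyping(shuffled, clean_cohort.annotation)
        joined = pd.concat([base.labels.rename("a"), again.labels.rename("b")], axis=1)
        assert adjusted_rand_score(joined["a"], joined["b"]) == 1.0

    def test_silhouette_scan_prefers_planted_k(self, clean_cohort):
        asg, trace, bm = run_subtyping(clean_cohort.beta, clean_cohort.annotation)
        d = binary_distance_matrix(bm)
        scores = silhouette_scan(d, range(2, 7))
        assert scores.idxmax() == 3
        assert ((scores > -1) & (scores < 1)).all()
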