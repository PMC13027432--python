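"""cluster_core: feature matrix, filtering, clustering, PCA, scans."""

import math

import numpy as np
import pandas as pd
import pytest
from oracles import ward_oracle_labels
from sklearn.metrics import adjusted_rand_score

from ptmatlas.cluster import (
    FeatureMatrix,
    agglomerative_cluster,
    build_feature_matrix,
    characterize_clusters,
    filter_and_normalize,
    kmeans_cluster,
    pca_project,
    silhouette_scan,
)
from ptmatlas.types import Enzyme


def _enzymes(descriptors):
    return {
        acc: Enzyme(acc, "MKTAYS", text_descriptors=terms.split(),
                    pathways={"p1"} if i % 2 else {"p2"},
                    ec_class="lyase" if i % 2 else "ligase")
        for i, (acc, terms) in enumerate(descriptors.items())
    }


def _metrics(accessions):
    rng = np.random.default_rng(0)
    return pd.DataFrame(
        {"ptm_density": rng.uniform(0, 1, len(accessions)),
         "n_sites_total": rng.integers(1, 50, len(accessions)),
         "is_rate_limiting": False},
        index=accessions,
    )


def _blob_matrix(seed=0, n_per=20, gap=8.0):
    rng = np.random.default_rng(seed)
    a = rng.normal(0, 1, size=(n_per, 4))
    b = rng.normal(gap, 1, size=(n_per, 4))
    values = pd.DataFrame(
        np.vstack([a, b]), index=[f"r{i}" for i in range(2 * n_per)]
    )
    values.columns = [f"c{i}" for i in range(4)]
    truth = [0] * n_per + [1] * n_per
    return FeatureMatrix(values, {"numeric": list(values.columns)}), truth


class TestFeatureMatrix:
    def test_shared_descriptors_give_identical_tfidf_rows(self):
        enzymes = _enzymes(
            {"A": "kinase flux tca", "B": "kinase flux tca", "C": "lipid detox x"}
        )
        fm = build_feature_matrix(_metrics(list(enzymes)), enzymes)
        tfidf = fm.values[fm.blocks["tfidf"]]
        assert np.allclose(tfidf.loc["A"], tfidf.loc["B"])

    def test_tfidf_matches_hand_computation(self):
        # 3 documents; token "shared" in all, "pair" in two (min_df=2
        # keeps only those); idf = ln((1+N)/(1+df)) + 1, raw tf, L2 rows
        enzymes = _enzymes(
            {"A": "shared pair", "B": "shared pair", "C": "shared only"}
        )
        fm = build_feature_matrix(_metrics(list(enzymes)), enzymes)
        idf_shared = math.log(4 / 4) + 1
        idf_pair = math.log(4 / 3) + 1
        norm = math.hypot(idf_shared, idf_pair)
        row = fm.values.loc["A"]
        assert row["tfidf_shared"] == pytest.approx(idf_shared / norm)
        assert row["tfidf_pair"] == pytest.approx(idf_pair / norm)

    def test_universal_token_gets_minimal_idf(self):
        enzymes = _enzymes(
            {"A": "common alpha alpha", "B": "common beta beta", "C": "common alpha beta"}
        )
        fm = build_feature_matrix(_metrics(list(enzymes)), enzymes)
        weights = {
            c: fm.values[c].max() for c in fm.blocks["tfidf"]
        }
        assert min(weights, key=weights.get) == "tfidf_common"

    def test_onehot_blocks_encode_pathways_and_ec(self):
        enzymes = _enzymes({"A": "x y", "B": "x z", "C": "y z"})
        fm = build_feature_matrix(_metrics(list(enzymes)), enzymes)
        assert "pathway_p1" in fm.values.columns
        assert "ec_lyase" in fm.values.columns
        assert set(fm.values["pathway_p1"].unique()) <= {0.0, 1.0}

    def test_missing_numeric_imputed_zero_and_reported(self):
        enzymes = _enzymes({"A": "x y", "B": "x z", "C": "y z"})
        metrics = _metrics(list(enzymes))
        metrics.loc["A", "ptm_density"] = np.nan
        fm = build_feature_matrix(metrics, enzymes)
        assert fm.values.loc["A", "ptm_density"] == 0.0
        assert fm.missingness["ptm_density"] == pytest.approx(1 / 3)


class TestFilterAndNormalize:
    def test_constant_and_sparse_columns_dropped(self):
        rng = np.random.default_rng(1)
        values = pd.DataFrame(
            {"ok": rng.normal(size=200), "const": 1.0,
             "sparse": [1.0] + [0.0] * 199},
            index=[f"r{i}" for i in range(200)],
        )
        fm = FeatureMatrix(values, {"numeric": ["ok", "const"],
                                    "onehot": ["sparse"]})
        out = filter_and_normalize(fm, sparsity_threshold=0.01)
        assert set(out.dropped_columns) == {"const", "sparse"}
        assert list(out.values.columns) == ["ok"]

    def test_zscore_contract_on_numeric_block(self, full_scale_metrics, full_scale_cohort):
        fm = filter_and_normalize(build_feature_matrix(full_scale_metrics,
                                                       full_scale_cohort.enzymes))
        numeric = fm.values[fm.blocks["numeric"]]
        assert np.abs(numeric.mean()).max() < 1e-9
        assert np.abs(numeric.std(ddof=0) - 1).max() < 1e-9

    def test_all_dropped_is_an_error(self):
        values = pd.DataFrame({"c": [1.0, 1.0, 1.0]}, index=list("abc"))
        with pytest.raises(ValueError):
            filter_and_normalize(FeatureMatrix(values, {"numeric": ["c"]}))


class TestExport:
    def test_dense_and_mtx_round_trip(self, tmp_path):
        from scipy.io import mmread

        from ptmatlas.cluster import export_feature_matrix

        fm, _ = _blob_matrix(n_per=5)
        export_feature_matrix(fm, tmp_path, fmt="tsv")
        dense = pd.read_csv(tmp_path / "feature_matrix.tsv", sep="\t",
                            index_col=0)
        assert np.allclose(dense.to_numpy(), fm.matrix)

        export_feature_matrix(fm, tmp_path, fmt="mtx")
        sparse = mmread(tmp_path / "feature_matrix.mtx").toarray()
        assert np.allclose(sparse, fm.matrix)
        cols = pd.read_csv(tmp_path / "feature_matrix_columns.tsv", sep="\t")
        assert list(cols["column"]) == list(fm.values.columns)
        assert set(cols["block"]) == {"numeric"}

        with pytest.raises(ValueError):
            export_feature_matrix(fm, tmp_path, fmt="parquet")


class TestClustering:
    def test_separated_blobs_recovered_exactly(self):
        fm, truth = _blob_matrix()
        for result in (agglomerative_cluster(fm, 2), kmeans_cluster(fm, 2, 0)):
            assert adjusted_rand_score(truth, result.labels.values) == 1.0
            assert result.silhouette > 0.5

    def test_duplicated_rows_share_labels(self):
        fm, _ = _blob_matrix()
        doubled = pd.concat([fm.values, fm.values.set_axis(
            [f"{i}_dup" for i in fm.values.index])])
        result = agglomerative_cluster(
            FeatureMatrix(doubled, fm.blocks), 2
        )
        for idx in fm.values.index:
            assert result.labels[idx] == result.labels[f"{idx}_dup"]

    def test_ward_merge_equals_naive_lance_williams_oracle(self):
        rng = np.random.default_rng(23)
        X = rng.normal(size=(15, 3))
        values = pd.DataFrame(X, index=[f"r{i}" for i in range(15)])
        values.columns = ["a", "b", "c"]
        fm = FeatureMatrix(values, {"numeric": list(values.columns)})
        for k in (2, 3, 5):
            ours = agglomerative_cluster(fm, k).labels.values
            oracle = ward_oracle_labels(X, k)
            assert adjusted_rand_score(ours, oracle) == 1.0

    def test_k_out_of_range(self):
        fm, _ = _blob_matrix()
        with pytest.raises(ValueError):
            agglomerative_cluster(fm, 1)
        with pytest.raises(ValueError):
            kmeans_cluster(fm, len(fm.values), 0)

    def test_determinism_and_column_order_invariance(self):
        fm, _ = _blob_matrix(seed=3)
        ref = kmeans_cluster(fm, 2, seed=11)
        again = kmeans_cluster(fm, 2, seed=11)
        assert (ref.labels == again.labels).all()
        assert ref.silhouette == again.silhouette
        permuted = FeatureMatrix(
            fm.values[list(fm.values.columns)[::-1]], fm.blocks
        )
        for method in (agglomerative_cluster, lambda f, k: kmeans_cluster(f, k, 11)):
            assert adjusted_rand_score(
                method(fm, 2).labels.values, method(permuted, 2).labels.values
            ) == 1.0


class TestScanAndPCA:
    def test_two_blobs_select_k2(self):
        fm, _ = _blob_matrix()
        scan = silhouette_scan(fm, range(2, 7))
        assert scan.selected_k == 2
        assert ((scan.per_k.fillna(0) >= -1) & (scan.per_k.fillna(0) <= 1)).all().all()

    def test_three_blobs_select_k3(self):
        rng = np.random.default_rng(5)
        centers = np.array([[0, 0], [12, 0], [6, 10]])
        X = np.vstack([rng.normal(c, 1.0, size=(15, 2)) for c in centers])
        values = pd.DataFrame(X, index=[f"r{i}" for i in range(45)],
                              columns=["x", "y"])
        scan = silhouette_scan(FeatureMatrix(values, {"numeric": ["x", "y"]}),
                               range(2, 7))
        assert scan.selected_k == 3

    def test_rank_one_matrix_explained_by_first_component(self):
        base = np.arange(10, dtype=float)
        values = pd.DataFrame(
            {"a": base, "b": 2 * base, "c": -base},
            index=[f"r{i}" for i in range(10)],
        )
        fm = FeatureMatrix(values, {"numeric": list(values.columns)})
        scores, evr = pca_project(fm, 2)
        assert evr[0] == pytest.approx(1.0)
        assert evr.sum() <= 1.0 + 1e-12

    def test_excess_components_reduced_with_warning(self):
        fm, _ = _blob_matrix(n_per=3)
        with pytest.warns(UserWarning, match="reduced"):
            scores, evr = pca_project(fm, 10)
        assert scores.shape[1] <= 5

    def test_projection_separates_planted_blobs(self):
        fm, truth = _blob_matrix(seed=9)
        scores, _ = pca_project(fm, 2)
        from sklearn.metrics import silhouette_score

        assert silhouette_score(scores, truth) > 0.0


class TestCharacterize:
    def test_planted_blob_characterization(self):
        fm, truth = _blob_matrix(seed=2)
        result = agglomerative_cluster(fm, 2)
        metrics = pd.DataFrame(
            {"ptm_density": fm.values["c0"],
             "n_hotspot_regions": fm.values["c1"],
             "is_rate_limiting": [t == 1 for t in truth]},
            index=fm.values.index,
        )
        pathway_sets = {"hot": set(fm.values.index[:20]),
                        "cold": set(fm.values.index[20:])}
        report = characterize_clusters(result, metrics, pathway_sets)
        assert {r.feature for r in report["contrasts"]} == {
            "ptm_density", "n_hotspot_regions"
        }
        assert all(r.q_value < 0.01 for r in report["contrasts"])
        assert sorted(report["cluster_sizes"].values()) == [20, 20]
        # each blob's own pathway label is its top enrichment
        for cid, enrich in report["enrichment"].items():
            top = min(enrich, key=lambda r: r.q_value)
            assert top.q_value < 0.01
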