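"""Multi-block feature matrix construction and cluster analysis.

The enzyme feature matrix concatenates three blocks, each with recorded
provenance:

* ``numeric`` — PTM density, per-type densities, PPR per type, total /
  predominant / hotspot / crosstalk / mutation counts (z-scored after
  filtering; undefined PPR imputed as 0 with a missingness report,
  since absence of eligible residues means no modification capacity and
  Ward linkage needs a complete matrix);
* ``tfidf`` — TF-IDF over concatenated region names, functional
  descriptions and process terms (lower-cased, tokenized on
  non-alphanumerics, minimum document frequency 2; raw term counts,
  idf = ln((1 + N) / (1 + df)) + 1, rows L2-normalized);
* ``onehot`` — pathway and EC-class memberships.

Filtering removes zero-variance columns and columns nonzero in fewer
than a configurable fraction of rows.  Clustering (Ward agglomerative
and seeded k-means++) runs on the full filtered matrix; PCA is for
visualization only and is never fed back into clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from sklearn.cluster import AgglomerativeClustering, KMeans
from sklearn.decomposition import PCA
from sklearn.feature_extraction.text import TfidfVectorizer
from sklearn.metrics import silhouette_score

from .types import Enzyme

#: numeric metric columns pulled from the metrics table when present
NUMERIC_PREFIXES = ("ptm_density", "density_", "ppr_", "n_sites_total",
                    "n_predominant_", "n_hotspot_regions",
                    "n_crosstalk_residues", "n_mutated_ptm_sites",
                    "n_domain_localized_sites")


@dataclass
class FeatureMatrix:
    values: pd.DataFrame                  # rows = accessions
    blocks: dict[str, list[str]]          # block name -> column ids
    missingness: dict[str, float] = field(default_factory=dict)
    dropped_columns: list[str] = field(default_factory=list)

    @property
    def matrix(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)


@dataclass
class ClusterResult:
    method: str                           # agglomerative_ward | kmeans
    k: int
    labels: pd.Series                     # indexed by accession
    silhouette: float
    linkage_tree: Optional[np.ndarray] = None
    seed: Optional[int] = None


def _is_numeric_metric(column: str) -> bool:
    return any(
        column == p or column.startswith(p) for p in NUMERIC_PREFIXES
    )


def build_feature_matrix(
    metrics: pd.DataFrame,
    enzymes: Mapping[str, Enzyme],
    min_df: int = 2,
) -> FeatureMatrix:
    """Assemble the numeric + TF-IDF + one-hot blocks, row-aligned on
    the metrics index."""
    accessions = list(metrics.index)
    missing = [acc for acc in accessions if acc not in enzymes]
    if missing:
        raise ValueError(f"metrics rows without enzyme entries: {missing[:5]}")

    numeric_cols = [c for c in metrics.columns if _is_numeric_metric(c)]
    numeric = metrics[numeric_cols].astype(float).copy()
    missingness = {
        c: float(numeric[c].isna().mean())
        for c in numeric_cols
        if numeric[c].isna().any()
    }
    numeric = numeric.fillna(0.0)

    documents = [
        " ".join(enzymes[acc].text_descriptors).lower() for acc in accessions
    ]
    tfidf_df = pd.DataFrame(index=accessions)
    if any(documents):
        vectorizer = TfidfVectorizer(
            lowercase=True,
            token_pattern=r"[a-z0-9]+",
            min_df=min_df,
            norm="l2",
            smooth_idf=True,
            sublinear_tf=False,
        )
        try:
            tfidf = vectorizer.fit_transform(documents)
            tfidf_df = pd.DataFrame(
                tfidf.toarray(),
                index=accessions,
                columns=[f"tfidf_{t}" for t in vectorizer.get_feature_names_out()],
            )
        except ValueError:  # empty vocabulary after min_df
            tfidf_df = pd.DataFrame(index=accessions)

    pathway_labels = sorted({p for acc in accessions for p in enzymes[acc].pathways})
    onehot = pd.DataFrame(
        {
            f"pathway_{p}": [float(p in enzymes[acc].pathways) for acc in accessions]
            for p in pathway_labels
        },
        index=accessions,
    )
    ec_values = sorted({enzymes[acc].ec_class for acc in accessions})
    for ec in ec_values:
        onehot[f"ec_{ec}"] = [float(enzymes[acc].ec_class == ec) for acc in accessions]

    values = pd.concat([numeric, tfidf_df, onehot], axis=1)
    blocks = {
        "numeric": list(numeric.columns),
        "tfidf": list(tfidf_df.columns),
        "onehot": list(onehot.columns),
    }
    return FeatureMatrix(values, blocks, missingness)


def filter_and_normalize(
    fm: FeatureMatrix,
    sparsity_threshold: float = 0.01,
    scale_all_blocks: bool = False,
) -> FeatureMatrix:
    """Drop zero-variance and sparse columns, then z-score the numeric
    block (all blocks when ``scale_all_blocks``); TF-IDF rows are
    already L2-normalized and one-hot columns keep their 0/1 scale."""
    values = fm.values.copy()
    n_rows = len(values)
    dropped: list[str] = []
    for col in list(values.columns):
        column = values[col]
        if column.nunique() <= 1:
            dropped.append(col)
        elif (column != 0).sum() / n_rows < sparsity_threshold:
            dropped.append(col)
    values = values.drop(columns=dropped)
    if values.shape[1] == 0:
        raise ValueError("all feature columns were filtered out")
    blocks = {
        name: [c for c in cols if c in values.columns]
        for name, cols in fm.blocks.items()
    }
    scale_cols = (
        list(values.columns) if scale_all_blocks else blocks.get("numeric", [])
    )
    for col in scale_cols:
        std = values[col].std(ddof=0)
        values[col] = (values[col] - values[col].mean()) / std
    return FeatureMatrix(values, blocks, dict(fm.missingness), dropped)


def agglomerative_cluster(fm: FeatureMatrix, k: int) -> ClusterResult:
    """Ward linkage on Euclidean distance over the full filtered matrix."""
    n = len(fm.values)
    if not (2 <= k < n):
        raise ValueError(f"k={k} out of range for {n} rows")
    X = fm.matrix
    model = AgglomerativeClustering(n_clusters=k, linkage="ward")
    labels = model.fit_predict(X)
    tree = linkage(X, method="ward")
    sil = _safe_silhouette(X, labels)
    return ClusterResult(
        "agglomerative_ward", k, pd.Series(labels, index=fm.values.index), sil, tree
    )


def kmeans_cluster(fm: FeatureMatrix, k: int, seed: int = 0) -> ClusterResult:
    """Seeded k-means++ with 10 restarts, best inertia kept."""
    n = len(fm.values)
    if not (2 <= k < n):
        raise ValueError(f"k={k} out of range for {n} rows")
    X = fm.matrix
    model = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
    labels = model.fit_predict(X)
    sil = _safe_silhouette(X, labels)
    return ClusterResult(
        "kmeans", k, pd.Series(labels, index=fm.values.index), sil, None, seed
    )


def _safe_silhouette(X: np.ndarray, labels: np.ndarray) -> float:
    if len(set(labels)) < 2:
        return float("nan")
    try:
        return float(silhouette_score(X, labels))
    except ValueError:
        return float("nan")


@dataclass
class SilhouetteScan:
    per_k: pd.DataFrame          # index k, columns per method
    selected_k: int
    selected_method: str


def silhouette_scan(
    fm: FeatureMatrix,
    k_range: Sequence[int] = range(2, 11),
    method: str = "agglomerative_ward",
    seed: int = 0,
) -> SilhouetteScan:
    """Mean silhouette per k for both methods; selection is the argmax
    for the configured method."""
    n = len(fm.values)
    ks = [k for k in k_range if 2 <= k < n]
    if not ks:
        raise ValueError("no feasible k in range")
    rows = {}
    for k in ks:
        rows[k] = {
            "agglomerative_ward": agglomerative_cluster(fm, k).silhouette,
            "kmeans": kmeans_cluster(fm, k, seed).silhouette,
        }
    per_k = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    scores = per_k[method]
    selected = int(scores.idxmax()) if scores.notna().any() else ks[0]
    return SilhouetteScan(per_k, selected, method)


def pca_project(fm: FeatureMatrix, n_components: int = 2, seed: int = 0):
    """Centered PCA scores for visualization (never fed back into
    clustering); returns (scores DataFrame, explained-variance ratios)."""
    X = fm.matrix
    rank = min(X.shape[0] - 1, X.shape[1])
    if n_components > rank:
        import warnings

        warnings.warn(
            f"n_components reduced from {n_components} to matrix rank {rank}",
            stacklevel=2,
        )
        n_components = rank
    pca = PCA(n_components=n_components, random_state=seed)
    scores = pca.fit_transform(X)
    df = pd.DataFrame(
        scores,
        index=fm.values.index,
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    return df, pca.explained_variance_ratio_


def export_feature_matrix(fm: FeatureMatrix, out_dir, fmt: str = "tsv") -> None:
    """Write the matrix as dense TSV, or as MTX with row/column TSVs."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if fmt == "tsv":
        fm.values.to_csv(out / "feature_matrix.tsv", sep="\t")
    elif fmt == "mtx":
        from scipy.io import mmwrite
        from scipy.sparse import csr_matrix

        mmwrite(str(out / "feature_matrix.mtx"), csr_matrix(fm.matrix))
        pd.Series(fm.values.index, name="accession").to_csv(
            out / "feature_matrix_rows.tsv", sep="\t", index=False
        )
        block_of = {c: b for b, cols in fm.blocks.items() for c in cols}
        pd.DataFrame(
            {"column": fm.values.columns,
             "block": [block_of.get(c, "") for c in fm.values.columns]}
        ).to_csv(out / "feature_matrix_columns.tsv", sep="\t", index=False)
    else:
        raise ValueError(f"unknown export format {fmt!r}")


def characterize_clusters(
    result: ClusterResult,
    metrics: pd.DataFrame,
    pathway_sets: Mapping[str, set],
    features: Optional[Sequence[str]] = None,
    q_threshold: float = 0.05,
) -> dict:
    """Per-feature contrasts between clusters and per-cluster pathway
    enrichment against the cohort background.

    With k = 2 a single contrast family is produced; for k > 2 all
    cluster pairs are contrasted with BH applied across the family.
    """
    from .stats import (
        CONTRAST_FEATURES,
        ContrastResult,
        bh_adjust,
        hypergeom_enrich,
        mann_whitney,
    )

    if features is None:
        features = [f for f in CONTRAST_FEATURES if f in metrics.columns]
    labels = result.labels
    clusters = sorted(labels.unique())
    contrasts: list[ContrastResult] = []
    for i, ca in enumerate(clusters):
        for cb in clusters[i + 1 :]:
            rows_a = labels[labels == ca].index
            rows_b = labels[labels == cb].index
            for feature in features:
                a = metrics.loc[rows_a, feature].dropna()
                b = metrics.loc[rows_b, feature].dropna()
                if a.empty or b.empty:
                    continue
                contrasts.append(
                    mann_whitney(a, b, feature, f"cluster_{ca}", f"cluster_{cb}")
                )
    if contrasts:
        q = bh_adjust([c.p_value for c in contrasts])
        contrasts = [
            ContrastResult(c.feature, c.group_a, c.group_b, c.n_a, c.n_b,
                           c.u_statistic, c.p_value, float(qv), c.direction)
            for c, qv in zip(contrasts, q)
        ]

    background = set(labels.index)
    enrichments = {
        int(c): hypergeom_enrich(set(labels[labels == c].index), background,
                                 pathway_sets)
        for c in clusters
    }
    rate_limiting = {}
    if "is_rate_limiting" in metrics.columns:
        for c in clusters:
            members = labels[labels == c].index
            rate_limiting[int(c)] = float(
                metrics.loc[members, "is_rate_limiting"].astype(bool).mean()
            )
    return {
        "contrasts": contrasts,
        "enrichment": enrichments,
        "rate_limiting_fraction": rate_limiting,
        "q_threshold": q_threshold,
        "cluster_sizes": {int(c): int((labels == c).sum()) for c in clusters},
    }
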