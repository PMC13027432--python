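"""Group statistics: Spearman matrices, Mann-Whitney contrasts,
Benjamini-Hochberg FDR, and hypergeometric set enrichment.

Conventions held fixed and documented here:

* Spearman rho uses midrank ties with p from the large-sample t
  approximation; missing values are deleted pairwise, never imputed.
* Mann-Whitney U is oriented on group A (number of (a, b) pairs with
  a > b plus half the ties).  For combined n <= 16 the two-sided p is
  computed by exhaustive enumeration of all group assignments of the
  pooled sample (valid under ties); larger samples use the normal
  approximation with tie correction.  Two-sided exact p is defined as
  P(|U - n_a n_b / 2| >= |U_obs - n_a n_b / 2|).
* FDR is adjusted per analysis family (one correlation matrix, one
  contrast family, one enrichment run at a time).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

EXACT_MW_MAX_N = 16  # combined-sample switch point exact -> asymptotic


@dataclass(frozen=True)
class CorrelationResult:
    feature_a: str
    feature_b: str
    rho: float
    p_value: float
    q_value: float = float("nan")
    n: int = 0


@dataclass(frozen=True)
class ContrastResult:
    feature: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    u_statistic: float
    p_value: float
    q_value: float = float("nan")
    direction: int = 0  # sign of median(a) - median(b)


@dataclass(frozen=True)
class EnrichmentResult:
    set_id: str
    k: int  # overlap
    K: int  # set size in background
    n: int  # selection size
    N: int  # background size
    p_value: float
    q_value: float = float("nan")


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, capped at 1."""
    arr = np.asarray(p_values, dtype=float)
    if arr.size == 0:
        return arr
    if np.any((arr < 0) | (arr > 1) | ~np.isfinite(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def spearman_matrix(
    feature_table: pd.DataFrame,
    pairs: Optional[Sequence[tuple[str, str]]] = None,
    min_n: int = 3,
) -> list[CorrelationResult]:
    """Spearman correlation for every feature pair, BH across all pairs.

    Missing values are deleted pairwise; constant features yield an
    undefined (NaN) rho and are excluded from the BH family.
    """
    columns = list(feature_table.columns)
    if pairs is None:
        pairs = list(combinations(columns, 2))
    results: list[tuple[str, str, float, float, int]] = []
    for a, b in pairs:
        sub = feature_table[[a, b]].dropna()
        n = len(sub)
        if n < min_n or sub[a].nunique() < 2 or sub[b].nunique() < 2:
            results.append((a, b, float("nan"), float("nan"), n))
            continue
        res = sps.spearmanr(sub[a], sub[b])
        results.append((a, b, float(res.statistic), float(res.pvalue), n))
    defined = [i for i, r in enumerate(results) if np.isfinite(r[3])]
    q = np.full(len(results), np.nan)
    if defined:
        q[defined] = bh_adjust([results[i][3] for i in defined])
    return [
        CorrelationResult(a, b, rho, p, float(qv), n)
        for (a, b, rho, p, n), qv in zip(results, q)
    ]


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for group a with midrank tie handling."""
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    r_a = ranks[: len(a)].sum()
    return float(r_a - len(a) * (len(a) + 1) / 2)


def _exact_two_sided_p(a: np.ndarray, b: np.ndarray, u_obs: float) -> float:
    """Enumerate all C(n_a+n_b, n_a) group assignments of the pooled
    sample and count assignments at least as extreme as observed."""
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    n_a = len(a)
    n = len(pooled)
    mu = n_a * (n - n_a) / 2
    offset = n_a * (n_a + 1) / 2
    extreme = 0
    total = comb(n, n_a)
    threshold = abs(u_obs - mu) - 1e-12
    for idx in combinations(range(n), n_a):
        u = ranks[list(idx)].sum() - offset
        if abs(u - mu) >= threshold:
            extreme += 1
    return extreme / total


def mann_whitney(
    values_a: Sequence[float],
    values_b: Sequence[float],
    feature: str = "",
    group_a: str = "a",
    group_b: str = "b",
) -> ContrastResult:
    """Two-sided Mann-Whitney U contrast (exact for small samples)."""
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    u = _u_statistic(a, b)
    if a.size + b.size <= EXACT_MW_MAX_N:
        p = _exact_two_sided_p(a, b, u)
    else:
        p = float(
            sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
        )
    direction = int(np.sign(np.median(a) - np.median(b)))
    return ContrastResult(feature, group_a, group_b, int(a.size), int(b.size),
                          u, float(p), float("nan"), direction)


def hypergeom_enrich(
    selection: set,
    background: set,
    pathway_sets: Mapping[str, set],
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric enrichment of a selection against the
    full cohort background, BH-adjusted across sets."""
    if not selection <= background:
        raise ValueError("selection must be a subset of the background")
    N = len(background)
    n = len(selection)
    raw: list[tuple[str, int, int, float]] = []
    for set_id, members in sorted(pathway_sets.items()):
        in_bg = members & background
        K = len(in_bg)
        k = len(in_bg & selection)
        p = float(sps.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        raw.append((set_id, k, K, min(1.0, p)))
    q = bh_adjust([p for _, _, _, p in raw]) if raw else np.array([])
    return [
        EnrichmentResult(set_id, k, K, n, N, p, float(qv))
        for (set_id, k, K, p), qv in zip(raw, q)
    ]


#: features contrasted between enzyme strata when present in the table
CONTRAST_FEATURES = (
    "ptm_density",
    "ppr_mean",
    "n_predominant_total",
    "n_hotspot_regions",
    "n_crosstalk_residues",
    "n_mutated_ptm_sites",
)


def contrast_by_flag(
    metrics: pd.DataFrame,
    flag_column: str,
    features: Sequence[str] = CONTRAST_FEATURES,
    label_true: str = "",
    label_false: str = "",
) -> list[ContrastResult]:
    """Mann-Whitney contrasts of each feature across one dichotomy,
    BH-adjusted within the family.  An empty stratum skips the family."""
    mask = metrics[flag_column].astype(bool)
    label_true = label_true or flag_column
    label_false = label_false or f"not_{flag_column}"
    if mask.sum() == 0 or (~mask).sum() == 0:
        return []
    results = []
    for feature in features:
        if feature not in metrics.columns:
            continue
        col = metrics[feature]
        a = col[mask].dropna()
        b = col[~mask].dropna()
        if a.empty or b.empty:
            continue
        results.append(mann_whitney(a, b, feature, label_true, label_false))
    if results:
        q = bh_adjust([r.p_value for r in results])
        results = [
            ContrastResult(r.feature, r.group_a, r.group_b, r.n_a, r.n_b,
                           r.u_statistic, r.p_value, float(qv), r.direction)
            for r, qv in zip(results, q)
        ]
    return results


def standard_contrasts(
    metrics: pd.DataFrame,
    features: Sequence[str] = CONTRAST_FEATURES,
) -> dict[str, list[ContrastResult]]:
    """The standard contrast families: rate-limiting vs not, and
    mitochondrial vs not, each BH-adjusted as its own family."""
    out = {}
    for flag, a_label, b_label in (
        ("is_rate_limiting", "rate_limiting", "non_rate_limiting"),
        ("is_mitochondrial", "mitochondrial", "non_mitochondrial"),
    ):
        if flag in metrics.columns:
            out[flag] = contrast_by_flag(metrics, flag, features, a_label, b_label)
    return out


def correlation_table(results: Sequence[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"feature_a": r.feature_a, "feature_b": r.feature_b, "rho": r.rho,
             "p_value": r.p_value, "q_value": r.q_value, "n": r.n}
            for r in results
        ],
        columns=["feature_a", "feature_b", "rho", "p_value", "q_value", "n"],
    )


def contrast_frame(results: Sequence[ContrastResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"feature": r.feature, "group_a": r.group_a, "group_b": r.group_b,
             "n_a": r.n_a, "n_b": r.n_b, "U": r.u_statistic,
             "p_value": r.p_value, "q_value": r.q_value,
             "direction": r.direction}
            for r in results
        ],
        columns=["feature", "group_a", "group_b", "n_a", "n_b", "U",
                 "p_value", "q_value", "direction"],
    )


def enrichment_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"set_id": r.set_id, "k": r.k, "K": r.K, "n": r.n, "N": r.N,
             "p_value": r.p_value, "q_value": r.q_value}
            for r in results
        ],
        columns=["set_id", "k", "K", "n", "N", "p_value", "q_value"],
    )


def null_pvalue_rate(
    n_replicates: int = 500,
    n_enzymes: int = 200,
    seed: int = 0,
    features: Sequence[str] = CONTRAST_FEATURES,
) -> dict:
    """Type-I calibration under the null generator (multiplier 1).

    Each replicate draws a fresh cohort in which the planted groups
    carry no signal, computes the metrics table and both standard
    contrast families, and pools the nominal p-values.  Returns the
    fraction below 0.05 together with binomial 99% bounds computed at
    the replicate count (conservative for within-replicate dependence).
    """
    from .pipeline import compute_metrics  # local import to avoid a cycle
    from .synthetic import SyntheticConfig, generate_cohort

    rng = np.random.default_rng(seed)
    p_values: list[float] = []
    for _ in range(n_replicates):
        cfg = SyntheticConfig(
            n_enzymes=n_enzymes,
            enrichment_multiplier=1.0,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        cohort = generate_cohort(cfg)
        metrics = compute_metrics(cohort)
        for family in standard_contrasts(metrics, features).values():
            p_values.extend(r.p_value for r in family)
    arr = np.asarray(p_values)
    rate = float(np.mean(arr < 0.05))
    half = 2.5758 * np.sqrt(0.05 * 0.95 / n_replicates)
    return {
        "n_pvalues": int(arr.size),
        "n_replicates": n_replicates,
        "rate_p_below_0.05": rate,
        "bound_low": max(0.0, 0.05 - float(half)),
        "bound_high": 0.05 + float(half),
    }
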