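"""Enzyme-level quantitative PTM metrics.

* PTM density = unique observed sites / protein length (sites per
  residue); modification-specific densities partition it by type.
* PTM potentiality rate (PPR) = unique sites of a type / number of
  residues chemically eligible for that type; undefined (``None``) when
  the sequence has no eligible residue — never coerced to 0.
* Predominant sites: per enzyme and PTM type, sites ranked by detection
  count (ties broken by ascending position) and accumulated until the
  cumulative count first reaches the threshold fraction (default 60%)
  of total detections; the crossing site is included.  A sensitivity
  scan recomputes calls at 50/60/70%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .types import Enzyme, PTMSite
from .vocab import DEFAULT_ELIGIBILITY


class EligibilityMap:
    """Residue alphabet per PTM type, with observed-residue fallback.

    Types absent from the configured table fall back to the residues
    actually observed for that type in a reference catalog (set via
    :meth:`fit_fallback`), so nonstandard types still obtain a defined,
    data-driven denominator.
    """

    def __init__(self, table: Optional[Mapping[str, Iterable[str]]] = None):
        base = table if table is not None else DEFAULT_ELIGIBILITY
        self._table: dict[str, frozenset[str]] = {
            k: frozenset(v) for k, v in base.items()
        }
        self._fallback: dict[str, frozenset[str]] = {}

    def fit_fallback(self, sites: Iterable[PTMSite]) -> "EligibilityMap":
        observed: dict[str, set[str]] = {}
        for s in sites:
            observed.setdefault(s.ptm_type, set()).add(s.residue)
        self._fallback = {
            t: frozenset(res) for t, res in observed.items() if t not in self._table
        }
        return self

    def residues(self, ptm_type: str) -> frozenset[str]:
        if ptm_type in self._table:
            return self._table[ptm_type]
        if ptm_type in self._fallback:
            return self._fallback[ptm_type]
        raise KeyError(f"no eligibility alphabet known for PTM type {ptm_type!r}")

    def __contains__(self, ptm_type: str) -> bool:
        return ptm_type in self._table or ptm_type in self._fallback


@dataclass
class PredominantCall:
    accession: str
    ptm_type: str
    predominant_positions: list[int]
    threshold: float
    total_detections: int


def ptm_density(sites: Sequence[PTMSite], length: int) -> float:
    """Unique (position, ptm_type) records divided by sequence length."""
    if length < 1:
        raise ValueError("length must be >= 1")
    unique = {(s.position, s.ptm_type) for s in sites}
    return len(unique) / length


def per_type_density(
    sites: Sequence[PTMSite], length: int, zero_fill: Optional[Iterable[str]] = None
) -> dict[str, float]:
    """Per-type unique-site count / length; sums to the total density.

    Types with no sites are absent unless listed in ``zero_fill``.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    counts: dict[str, set[int]] = {}
    for s in sites:
        counts.setdefault(s.ptm_type, set()).add(s.position)
    out = {t: len(pos) / length for t, pos in counts.items()}
    if zero_fill:
        for t in zero_fill:
            out.setdefault(t, 0.0)
    return out


def ppr(
    sites: Sequence[PTMSite],
    sequence: str,
    ptm_type: str,
    eligibility: EligibilityMap,
) -> Optional[float]:
    """Observed unique sites of a type / eligible residues; None if no
    residue in the sequence is eligible (undefined, not zero)."""
    residues = eligibility.residues(ptm_type)  # KeyError for unknown type
    n_eligible = sum(1 for ch in sequence if ch in residues)
    if n_eligible == 0:
        return None
    n_sites = len({s.position for s in sites if s.ptm_type == ptm_type})
    return n_sites / n_eligible


def call_predominant(
    sites: Sequence[PTMSite], threshold: float = 0.60
) -> PredominantCall:
    """Cumulative-detection predominant call for one enzyme and type."""
    if not sites:
        raise ValueError("cannot call predominant sites on an empty site list")
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must lie in (0, 1]")
    accs = {s.accession for s in sites}
    typs = {s.ptm_type for s in sites}
    if len(accs) > 1 or len(typs) > 1:
        raise ValueError("predominant calling expects one enzyme and one PTM type")
    ranked = sorted(sites, key=lambda s: (-s.detection_count, s.position))
    total = sum(s.detection_count for s in ranked)
    cutoff = threshold * total
    chosen: list[int] = []
    cumulative = 0
    for s in ranked:
        cumulative += s.detection_count
        chosen.append(s.position)
        if cumulative >= cutoff:
            break
    return PredominantCall(accs.pop(), typs.pop(), chosen, threshold, total)


def predominant_table(
    sites: Sequence[PTMSite], threshold: float = 0.60
) -> pd.DataFrame:
    """Predominant calls for every (enzyme, type) pair in a catalog."""
    rows = []
    groups: dict[tuple[str, str], list[PTMSite]] = {}
    for s in sites:
        groups.setdefault((s.accession, s.ptm_type), []).append(s)
    for (acc, ptm_type), group in sorted(groups.items()):
        call = call_predominant(group, threshold)
        by_pos = {s.position: s.detection_count for s in group}
        for rank, pos in enumerate(call.predominant_positions, start=1):
            rows.append(
                {"accession": acc, "ptm_type": ptm_type, "position": pos,
                 "rank": rank, "detection_count": by_pos[pos],
                 "threshold": threshold}
            )
    return pd.DataFrame(
        rows, columns=["accession", "ptm_type", "position", "rank",
                       "detection_count", "threshold"]
    )


@dataclass
class SensitivityScan:
    thresholds: list[float]
    counts: pd.DataFrame            # per-enzyme predominant counts per threshold
    rank_correlations: dict[tuple[float, float], float]
    top_decile_overlap: dict[tuple[float, float], float]


def sensitivity_scan(
    sites: Sequence[PTMSite],
    thresholds: Sequence[float] = (0.50, 0.60, 0.70),
) -> SensitivityScan:
    """Predominant-site counts at several thresholds plus robustness
    statistics (Spearman rank agreement, top-decile overlap)."""
    for t in thresholds:
        if not (0.0 < t <= 1.0):
            raise ValueError(f"threshold {t} outside (0, 1]")
    groups: dict[tuple[str, str], list[PTMSite]] = {}
    for s in sites:
        groups.setdefault((s.accession, s.ptm_type), []).append(s)
    accessions = sorted({acc for acc, _ in groups})
    counts = pd.DataFrame(0, index=accessions, columns=list(thresholds))
    for (acc, _), group in groups.items():
        for t in thresholds:
            counts.loc[acc, t] += len(call_predominant(group, t).predominant_positions)

    correlations: dict[tuple[float, float], float] = {}
    overlaps: dict[tuple[float, float], float] = {}
    n_top = max(1, len(accessions) // 10)
    for a, b in combinations(thresholds, 2):
        if counts[a].nunique() > 1 and counts[b].nunique() > 1:
            rho = float(sps.spearmanr(counts[a], counts[b]).statistic)
        else:
            rho = float("nan")
        correlations[(a, b)] = rho
        top_a = set(counts[a].nlargest(n_top).index)
        top_b = set(counts[b].nlargest(n_top).index)
        overlaps[(a, b)] = len(top_a & top_b) / n_top
    return SensitivityScan(list(thresholds), counts, correlations, overlaps)


@dataclass
class DistributionSummary:
    n: int
    minimum: float
    q1: float
    median: float
    q3: float
    maximum: float
    mean: float
    histogram_counts: list[int]
    histogram_edges: list[float]
    right_skewed: bool


def summarize_distribution(values: Sequence[float], bins: int = 20) -> DistributionSummary:
    """Quartiles (linear-interpolation convention), histogram, and a
    mean>median right-skew indicator."""
    arr = np.asarray([v for v in values if np.isfinite(v)], dtype=float)
    if arr.size == 0:
        raise ValueError("no finite values to summarize")
    q1, med, q3 = np.percentile(arr, [25, 50, 75])  # linear interpolation
    hist, edges = np.histogram(arr, bins=bins)
    return DistributionSummary(
        n=int(arr.size),
        minimum=float(arr.min()),
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        maximum=float(arr.max()),
        mean=float(arr.mean()),
        histogram_counts=hist.tolist(),
        histogram_edges=edges.tolist(),
        right_skewed=bool(arr.mean() > med),
    )


def enzyme_metrics_table(
    enzymes: Mapping[str, Enzyme],
    sites: Sequence[PTMSite],
    eligibility: Optional[EligibilityMap] = None,
    predominant_threshold: float = 0.60,
) -> pd.DataFrame:
    """One row per enzyme: density, per-type density, PPR per type,
    site and predominant counts.  Architecture counts (hotspots,
    crosstalk, mutation overlap, domain localization) are merged in by
    :func:`ptmatlas.architecture.architecture_counts`."""
    if eligibility is None:
        eligibility = EligibilityMap().fit_fallback(sites)
    by_enzyme: dict[str, list[PTMSite]] = {acc: [] for acc in enzymes}
    for s in sites:
        if s.accession in by_enzyme:
            by_enzyme[s.accession].append(s)

    all_types = sorted({s.ptm_type for s in sites})
    rows = []
    for acc, enzyme in enzymes.items():
        esites = by_enzyme[acc]
        row: dict = {
            "accession": acc,
            "length": enzyme.length,
            "n_sites_total": len({(s.position, s.ptm_type) for s in esites}),
            "ptm_density": ptm_density(esites, enzyme.length),
            "is_rate_limiting": enzyme.is_rate_limiting,
            "is_mitochondrial": enzyme.is_mitochondrial,
        }
        ptd = per_type_density(esites, enzyme.length)
        n_predominant_total = 0
        ppr_values = []
        for t in all_types:
            row[f"density_{t}"] = ptd.get(t, 0.0)
            value = ppr(esites, enzyme.sequence, t, eligibility) if t in eligibility else None
            row[f"ppr_{t}"] = np.nan if value is None else value
            if value is not None:
                ppr_values.append(value)
            tsites = [s for s in esites if s.ptm_type == t]
            n_pred = (
                len(call_predominant(tsites, predominant_threshold).predominant_positions)
                if tsites else 0
            )
            row[f"n_predominant_{t}"] = n_pred
            n_predominant_total += n_pred
        row["n_predominant_total"] = n_predominant_total
        row["ppr_mean"] = float(np.mean(ppr_values)) if ppr_values else np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("accession")
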