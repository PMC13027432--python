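"""Sequence-architecture features derived from a harmonized catalog.

Hotspots: for every site at position p, the closed window [p-7, p+7]
(clipped to the sequence) is scanned; it qualifies when it contains at
least ``min_neighbors`` (default 5) unique (position, type) records
besides the central record itself.  Overlapping qualifying windows are
merged, and each maximal merged interval is one hotspot region.  A
window counts PTM records, not residues, so a dual-modified residue
contributes two.

Crosstalk: in residue mode (the default, used for headline counts) a
crosstalk residue is a single position carrying >= 2 distinct PTM
types; window mode instead asks whether the +/- half_window
neighborhood of a position spans >= 2 types.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .types import Enzyme, PTMSite, RegionAnnotation, VariantRecord


@dataclass(frozen=True)
class HotspotRegion:
    accession: str
    start: int
    end: int
    n_sites: int
    seed_positions: tuple[int, ...]


@dataclass(frozen=True)
class CrosstalkResidue:
    accession: str
    position: int
    ptm_types: frozenset[str]
    mode: str = "residue"


@dataclass(frozen=True)
class SiteLocalization:
    accession: str
    position: int
    ptm_type: str
    labels: frozenset[str]


@dataclass(frozen=True)
class MutationOverlap:
    accession: str
    position: int
    ptm_types: frozenset[str]
    variants: tuple[VariantRecord, ...]
    any_missense: bool


def detect_hotspots(
    sites: Sequence[PTMSite],
    length: int,
    half_window: int = 7,
    min_neighbors: int = 5,
    count_unique_positions: bool = False,
) -> list[HotspotRegion]:
    """Hotspot regions for one enzyme's sites.

    ``count_unique_positions`` switches the window load from unique
    (position, type) records to unique positions.
    """
    if half_window < 1:
        raise ValueError("half_window must be >= 1")
    if not sites:
        return []
    records = sorted({(s.position, s.ptm_type) for s in sites})
    positions = np.array([p for p, _ in records])
    if count_unique_positions:
        uniq = np.array(sorted(set(positions)))
        load_positions = uniq
    else:
        load_positions = positions  # one entry per (position, type) record

    intervals = []
    seeds = []
    for pos, _ptm in records:
        lo = np.searchsorted(load_positions, pos - half_window, side="left")
        hi = np.searchsorted(load_positions, pos + half_window, side="right")
        in_window = int(hi - lo)
        # exclude only the central record, not other records at the
        # central position
        neighbors = in_window - 1
        if neighbors >= min_neighbors:
            intervals.append((max(1, pos - half_window), min(length, pos + half_window)))
            seeds.append(pos)
    if not intervals:
        return []

    merged: list[HotspotRegion] = []
    order = sorted(range(len(intervals)), key=lambda i: intervals[i])
    cur_start, cur_end = intervals[order[0]]
    cur_seeds = [seeds[order[0]]]
    out: list[tuple[int, int, list[int]]] = []
    for i in order[1:]:
        start, end = intervals[i]
        if start <= cur_end:  # shares at least one residue
            cur_end = max(cur_end, end)
            cur_seeds.append(seeds[i])
        else:
            out.append((cur_start, cur_end, cur_seeds))
            cur_start, cur_end, cur_seeds = start, end, [seeds[i]]
    out.append((cur_start, cur_end, cur_seeds))

    acc = sites[0].accession
    for start, end, region_seeds in out:
        n_sites = int(np.sum((positions >= start) & (positions <= end)))
        merged.append(
            HotspotRegion(acc, start, end, n_sites, tuple(sorted(set(region_seeds))))
        )
    return merged


def detect_crosstalk(
    sites: Sequence[PTMSite],
    mode: str = "residue",
    half_window: int = 7,
) -> list[CrosstalkResidue]:
    """Crosstalk residues for one enzyme's sites."""
    if mode not in ("residue", "window"):
        raise ValueError(f"unknown crosstalk mode {mode!r}")
    if not sites:
        return []
    acc = sites[0].accession
    types_at: dict[int, set[str]] = {}
    for s in sites:
        types_at.setdefault(s.position, set()).add(s.ptm_type)
    result = []
    if mode == "residue":
        for pos in sorted(types_at):
            if len(types_at[pos]) >= 2:
                result.append(CrosstalkResidue(acc, pos, frozenset(types_at[pos]), mode))
    else:
        positions = sorted(types_at)
        for pos in positions:
            nearby: set[str] = set()
            for q in positions:
                if abs(q - pos) <= half_window:
                    nearby |= types_at[q]
            if len(nearby) >= 2:
                result.append(CrosstalkResidue(acc, pos, frozenset(nearby), mode))
    return result


def crosstalk_hotspots(
    hotspots: Sequence[HotspotRegion],
    crosstalk: Sequence[CrosstalkResidue],
    min_residues: int = 3,
) -> list[HotspotRegion]:
    """Optional derived summary: hotspot regions containing at least
    ``min_residues`` crosstalk residues (dense multi-type clusters)."""
    positions: dict[str, list[int]] = {}
    for c in crosstalk:
        positions.setdefault(c.accession, []).append(c.position)
    return [
        h for h in hotspots
        if sum(h.start <= p <= h.end for p in positions.get(h.accession, []))
        >= min_residues
    ]


def localize_sites(
    sites: Sequence[PTMSite],
    regions: Sequence[RegionAnnotation],
    enzymes: Mapping[str, Enzyme],
) -> tuple[list[SiteLocalization], pd.DataFrame]:
    """Label each site with every region type covering its position.

    A site inside no annotated region is labelled ``unannotated``
    (always alone).  The enrichment table reports, per (region_type,
    ptm_type), the observed site count, residues covered by that region
    type, and the in-region vs out-of-region site rate ratio.
    """
    by_enzyme: dict[str, list[RegionAnnotation]] = {}
    for r in regions:
        by_enzyme.setdefault(r.accession, []).append(r)

    localizations: list[SiteLocalization] = []
    for s in sites:
        labels = {
            r.region_type
            for r in by_enzyme.get(s.accession, [])
            if r.start <= s.position <= r.end
        }
        if not labels:
            labels = {"unannotated"}
        localizations.append(SiteLocalization(s.accession, s.position, s.ptm_type,
                                              frozenset(labels)))

    # residues covered per region type (union of intervals per enzyme)
    covered: Counter = Counter()
    total_residues = sum(e.length for e in enzymes.values())
    region_types = sorted({r.region_type for r in regions})
    for rt in region_types:
        for acc, rlist in by_enzyme.items():
            if acc not in enzymes:
                continue
            mask = np.zeros(enzymes[acc].length, dtype=bool)
            for r in rlist:
                if r.region_type == rt:
                    mask[r.start - 1 : r.end] = True
            covered[rt] += int(mask.sum())

    rows = []
    ptm_types = sorted({s.ptm_type for s in sites})
    for rt in region_types:
        n_cov = covered[rt]
        n_uncov = total_residues - n_cov
        for pt in ptm_types:
            observed = sum(
                1 for loc in localizations
                if loc.ptm_type == pt and rt in loc.labels
            )
            n_type_total = sum(1 for loc in localizations if loc.ptm_type == pt)
            rate_in = observed / n_cov if n_cov else np.nan
            rate_out = (n_type_total - observed) / n_uncov if n_uncov else np.nan
            ratio = rate_in / rate_out if rate_out and np.isfinite(rate_out) else np.nan
            rows.append(
                {"region_type": rt, "ptm_type": pt, "observed_sites": observed,
                 "covered_residues": n_cov, "rate_in": rate_in,
                 "rate_out": rate_out, "rate_ratio": ratio}
            )
    table = pd.DataFrame(
        rows, columns=["region_type", "ptm_type", "observed_sites",
                       "covered_residues", "rate_in", "rate_out", "rate_ratio"]
    )
    return localizations, table


def overlap_variants(
    sites: Sequence[PTMSite],
    variants: Sequence[VariantRecord],
) -> tuple[list[MutationOverlap], dict]:
    """One overlap record per PTM-bearing position carrying >= 1 variant."""
    types_at: dict[tuple[str, int], set[str]] = {}
    residue_at: dict[tuple[str, int], str] = {}
    for s in sites:
        key = (s.accession, s.position)
        types_at.setdefault(key, set()).add(s.ptm_type)
        residue_at[key] = s.residue
    variants_at: dict[tuple[str, int], list[VariantRecord]] = {}
    for v in variants:
        key = (v.accession, v.position)
        if key in types_at:
            variants_at.setdefault(key, []).append(v)

    overlaps = [
        MutationOverlap(
            accession=acc,
            position=pos,
            ptm_types=frozenset(types_at[(acc, pos)]),
            variants=tuple(vlist),
            any_missense=any(v.variant_class == "missense" for v in vlist),
        )
        for (acc, pos), vlist in sorted(variants_at.items())
    ]
    class_counts: Counter = Counter(
        v.variant_class for o in overlaps for v in o.variants
    )
    residue_counts: Counter = Counter(
        residue_at[(o.accession, o.position)] for o in overlaps
    )
    summary = {
        "n_overlapped_positions": len(overlaps),
        "variant_class_counts": dict(class_counts),
        "residue_counts": dict(residue_counts),
    }
    return overlaps, summary


def architecture_counts(
    enzymes: Mapping[str, Enzyme],
    sites: Sequence[PTMSite],
    regions: Sequence[RegionAnnotation] = (),
    variants: Sequence[VariantRecord] = (),
    half_window: int = 7,
    min_neighbors: int = 5,
    crosstalk_mode: str = "residue",
) -> pd.DataFrame:
    """Per-enzyme architecture counts, for merging into the metrics table:
    hotspot regions, crosstalk residues, mutated PTM positions, and
    domain-localized sites."""
    by_enzyme: dict[str, list[PTMSite]] = {acc: [] for acc in enzymes}
    for s in sites:
        if s.accession in by_enzyme:
            by_enzyme[s.accession].append(s)
    overlaps, _ = overlap_variants(sites, variants)
    mutated: Counter = Counter(o.accession for o in overlaps)

    domain_regions: dict[str, list[RegionAnnotation]] = {}
    for r in regions:
        if r.region_type == "domain":
            domain_regions.setdefault(r.accession, []).append(r)

    rows = []
    for acc, enzyme in enzymes.items():
        esites = by_enzyme[acc]
        hotspots = detect_hotspots(esites, enzyme.length, half_window, min_neighbors)
        crosstalk = detect_crosstalk(esites, crosstalk_mode, half_window)
        n_domain_sites = sum(
            1
            for s in esites
            if any(r.start <= s.position <= r.end
                   for r in domain_regions.get(acc, []))
        )
        rows.append(
            {"accession": acc,
             "n_hotspot_regions": len(hotspots),
             "n_crosstalk_residues": len(crosstalk),
             "n_mutated_ptm_sites": int(mutated.get(acc, 0)),
             "n_domain_localized_sites": n_domain_sites}
        )
    return pd.DataFrame(rows).set_index("accession")


def hotspot_table(hotspots: Sequence[HotspotRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"accession": h.accession, "start": h.start, "end": h.end,
             "n_sites": h.n_sites,
             "seed_positions": ",".join(map(str, h.seed_positions))}
            for h in hotspots
        ],
        columns=["accession", "start", "end", "n_sites", "seed_positions"],
    )


def crosstalk_table(residues: Sequence[CrosstalkResidue]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"accession": c.accession, "position": c.position,
             "ptm_types": "|".join(sorted(c.ptm_types)), "mode": c.mode}
            for c in residues
        ],
        columns=["accession", "position", "ptm_types", "mode"],
    )
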