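"""site_architecture: hotspots, crosstalk, localization, variant overlap."""

import numpy as np
import pytest
from oracles import crosstalk_oracle, hotspot_oracle

from ptmatlas.architecture import (
    detect_crosstalk,
    detect_hotspots,
    localize_sites,
    overlap_variants,
)
from ptmatlas.synthetic import SyntheticConfig, generate_cohort
from ptmatlas.types import PTMSite, RegionAnnotation, VariantRecord


def _site(pos, ptm_type="phosphorylation", acc="E1", residue="S"):
    return PTMSite(acc, pos, residue, ptm_type, 1)


class TestHotspots:
    def test_six_contiguous_sites_form_one_region(self):
        sites = [_site(p) for p in range(10, 16)]
        regions = detect_hotspots(sites, length=100)
        assert len(regions) == 1
        # every site's window holds the 5 others; windows merge into one
        assert regions[0].start == 3 and regions[0].end == 22
        assert regions[0].n_sites == 6
        assert regions[0].seed_positions == tuple(range(10, 16))

    def test_sparse_sites_yield_no_hotspot(self):
        sites = [_site(p) for p in range(10, 200, 15)]
        assert detect_hotspots(sites, length=300) == []

    def test_overlapping_windows_merge_to_one_region(self):
        sites = [_site(p) for p in (10, 11, 12, 13, 14, 15, 16, 17)]
        regions = detect_hotspots(sites, length=100)
        assert len(regions) == 1

    def test_dual_modified_residue_counts_twice(self):
        # five records in the window, two sharing a position
        sites = [_site(10), _site(11), _site(12), _site(13),
                 _site(14, "o-linked glycosylation", residue="T"),
                 _site(14)]
        regions = detect_hotspots(sites, length=50)
        assert len(regions) == 1

    def test_window_clipping_at_sequence_start(self):
        sites = [_site(p) for p in (1, 2, 3, 4, 5, 6)]
        regions = detect_hotspots(sites, length=30)
        assert regions[0].start == 1

    def test_equals_exhaustive_oracle_on_cohort(self, cohort200, sites_by_enzyme):
        for acc, enzyme in cohort200.enzymes.items():
            got = [
                (h.start, h.end)
                for h in detect_hotspots(sites_by_enzyme[acc], enzyme.length)
            ]
            assert got == hotspot_oracle(sites_by_enzyme[acc], enzyme.length), acc

    def test_sensitivity_grows_as_min_neighbors_decreases(self, cohort200,
                                                          sites_by_enzyme):
        """Lowering the neighbor load can only add qualifying windows:
        seed counts and covered extent grow monotonically (merged-region
        counts need not, since new windows bridge existing regions)."""
        for acc in list(cohort200.enzymes)[:50]:
            length = cohort200.enzymes[acc].length
            seeds, covered = [], []
            for m in (7, 5, 3):
                regions = detect_hotspots(sites_by_enzyme[acc], length,
                                          min_neighbors=m)
                seeds.append(sum(len(r.seed_positions) for r in regions))
                covered.append(sum(r.end - r.start + 1 for r in regions))
            assert seeds == sorted(seeds)
            assert covered == sorted(covered)

    def test_planted_bursts_are_recovered(self, full_scale_cohort):
        """At least 90% of planted dense bursts intersect a detected
        hotspot region."""
        by = {acc: [] for acc in full_scale_cohort.enzymes}
        for s in full_scale_cohort.sites:
            by[s.accession].append(s)
        hit = total = 0
        for acc, intervals in full_scale_cohort.truth.burst_intervals.items():
            regions = detect_hotspots(by[acc], full_scale_cohort.enzymes[acc].length)
            for (lo, hi), n_placed in zip(intervals,
                                          full_scale_cohort.truth.burst_site_counts[acc]):
                if n_placed < 6:
                    continue
                total += 1
                if any(r.start <= hi and r.end >= lo for r in regions):
                    hit += 1
        assert total > 50
        assert hit / total >= 0.9


class TestCrosstalk:
    def test_two_types_same_residue(self):
        sites = [_site(100), _site(100, "o-linked glycosylation")]
        found = detect_crosstalk(sites)
        assert len(found) == 1
        assert found[0].position == 100
        assert found[0].ptm_types == frozenset(
            {"phosphorylation", "o-linked glycosylation"}
        )

    def test_repeated_single_type_is_not_crosstalk(self):
        sites = [PTMSite("E1", 5, "S", "phosphorylation", 3),
                 PTMSite("E1", 5, "S", "phosphorylation", 1)]
        assert detect_crosstalk(sites) == []

    def test_window_mode_counts_nearby_types(self):
        sites = [_site(10), _site(14, "acetylation", residue="K")]
        assert detect_crosstalk(sites, mode="residue") == []
        windowed = detect_crosstalk(sites, mode="window")
        assert [c.position for c in windowed] == [10, 14]

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            detect_crosstalk([_site(1)], mode="bogus")

    def test_matches_per_position_tally_on_cohort(self, cohort200, sites_by_enzyme):
        for acc, esites in sites_by_enzyme.items():
            got = [c.position for c in detect_crosstalk(esites)]
            assert got == crosstalk_oracle(esites), acc

    def test_injected_crosstalk_positions_detected(self, cohort200, sites_by_enzyme):
        for acc, injected in cohort200.truth.crosstalk_positions.items():
            found = {c.position for c in detect_crosstalk(sites_by_enzyme[acc])}
            assert set(injected) <= found


class TestCrosstalkHotspots:
    def test_regions_with_enough_crosstalk_residues(self, cohort200,
                                                    sites_by_enzyme):
        from ptmatlas.architecture import crosstalk_hotspots

        hotspots, crosstalk = [], []
        for acc, enzyme in cohort200.enzymes.items():
            hotspots.extend(detect_hotspots(sites_by_enzyme[acc], enzyme.length))
            crosstalk.extend(detect_crosstalk(sites_by_enzyme[acc]))
        dense = crosstalk_hotspots(hotspots, crosstalk, min_residues=3)
        assert set(dense) <= set(hotspots)
        by_acc = {}
        for c in crosstalk:
            by_acc.setdefault(c.accession, []).append(c.position)
        for h in dense:
            inside = [p for p in by_acc.get(h.accession, [])
                      if h.start <= p <= h.end]
            assert len(inside) >= 3


class TestLocalization:
    def test_single_and_multi_label(self):
        from ptmatlas.types import Enzyme

        enzymes = {"E1": Enzyme("E1", "S" * 100)}
        regions = [RegionAnnotation("E1", "domain", 40, 60, "D1"),
                   RegionAnnotation("E1", "disordered", 55, 80, "IDR")]
        sites = [_site(50), _site(58), _site(90)]
        locs, table = localize_sites(sites, regions, enzymes)
        assert locs[0].labels == frozenset({"domain"})
        assert locs[1].labels == frozenset({"domain", "disordered"})
        assert locs[2].labels == frozenset({"unannotated"})
        domain_row = table[(table.region_type == "domain")
                           & (table.ptm_type == "phosphorylation")].iloc[0]
        assert domain_row.observed_sites == 2
        assert domain_row.covered_residues == 21

    def test_planted_domain_fraction_recovered(self):
        """Base placement targets 40% of sites inside domains; realized
        fraction matches within 3 binomial SE (bursts disabled so every
        site follows the biased placement)."""
        cohort = generate_cohort(
            SyntheticConfig(n_enzymes=300, burst_rate=0.0, crosstalk_rate=0.0,
                            enrichment_multiplier=1.0, seed=17)
        )
        locs, _ = localize_sites(cohort.sites, cohort.regions, cohort.enzymes)
        in_domain = np.array(["domain" in loc.labels for loc in locs])
        p = in_domain.mean()
        se = np.sqrt(0.4 * 0.6 / len(in_domain))
        assert abs(p - 0.4) <= 3 * se


class TestVariantOverlap:
    def test_overlap_classes_and_missense_flag(self):
        sites = [_site(293)]
        variants = [
            VariantRecord("E1", 293, "S", "A", "engineered"),
            VariantRecord("E1", 293, "S", "F", "missense"),
            VariantRecord("E1", 10, "K", "R", "missense"),  # no PTM there
        ]
        overlaps, summary = overlap_variants(sites, variants)
        assert len(overlaps) == 1
        assert overlaps[0].any_missense
        assert {v.variant_class for v in overlaps[0].variants} == {
            "engineered", "missense"
        }
        assert summary["n_overlapped_positions"] == 1
        assert summary["variant_class_counts"] == {"engineered": 1, "missense": 1}

    def test_engineered_only_site_not_missense(self):
        sites = [_site(293)]
        variants = [VariantRecord("E1", 293, "S", "A", "engineered")]
        overlaps, _ = overlap_variants(sites, variants)
        assert not overlaps[0].any_missense

    def test_summary_counts_on_cohort(self, cohort200):
        overlaps, summary = overlap_variants(cohort200.sites, cohort200.variants)
        positions = {(s.accession, s.position) for s in cohort200.sites}
        expected = {
            (v.accession, v.position)
            for v in cohort200.variants
            if (v.accession, v.position) in positions
        }
        assert summary["n_overlapped_positions"] == len(expected)
        # missense dominates the planted variant class mixture
        assert max(summary["variant_class_counts"],
                   key=summary["variant_class_counts"].get) == "missense"
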