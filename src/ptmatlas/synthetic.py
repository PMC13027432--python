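"""Seeded synthetic cohorts with planted, recoverable structure.

The generator emulates the statistical shape of a residue-level PTM
catalog on a metabolic-enzyme cohort without using any real database:

* a right-skewed per-enzyme modification burden (gamma-distributed
  per-enzyme rate driving a binomial site placement over eligible
  residues, so most enzymes are sparsely modified and a minority are
  dense);
* residue-specific eligibility per PTM type (sites never occupy
  chemically ineligible residues);
* burst-like site placement that produces detectable hotspots at known
  (planted) locations;
* explicit crosstalk injection (a second PTM type added to an already
  modified residue), the only mechanism that produces multi-type
  residues, so ``crosstalk_rate = 0`` implies none exist;
* heavy-tailed per-site detection counts (geometric);
* region and variant tracks, and two planted enzyme groups
  (PTM-enriched vs sparse) carrying pathway labels and rate-limiting
  flags against which downstream clustering is scored.

Everything is reproducible from the single config seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import yaml

from .types import Enzyme, PTMSite, RegionAnnotation, VariantRecord
from .vocab import AMINO_ACIDS, DEFAULT_ELIGIBILITY, EC_CLASSES

# Relative per-eligible-residue placement rates.  Multiplied by the
# per-enzyme gamma rate they set the expected modification burden;
# ordering mirrors the field's coverage hierarchy (phosphorylation
# dominant, then acetylation/ubiquitination/methylation, acyl and
# glycosyl marks rarer).
DEFAULT_PTM_RATES: dict[str, float] = {
    "phosphorylation": 1.0,
    "acetylation": 0.5,
    "ubiquitination": 0.45,
    "methylation": 0.35,
    "succinylation": 0.25,
    "o-linked glycosylation": 0.15,
}

_ENRICHED_TERMS = [
    "glycolytic", "tca", "oxidative", "carbon", "flux", "allosteric",
    "tetramer", "kinase", "substrate", "cofactor", "nad", "catalytic",
]
_SPARSE_TERMS = [
    "lipid", "xenobiotic", "transfer", "amino", "nucleotide", "salvage",
    "membrane", "hydrolase", "conjugation", "detox", "branched", "urea",
]
_SHARED_TERMS = ["enzyme", "metabolic", "binding", "domain", "activity", "protein"]
# nonempty subsets of the three source tags, grouped by size
_SOURCE_SUBSETS: dict[int, list[frozenset[str]]] = {
    1: [frozenset({"psp"}), frozenset({"dbptm"}), frozenset({"qptm"})],
    2: [frozenset({"psp", "dbptm"}), frozenset({"psp", "qptm"}),
        frozenset({"dbptm", "qptm"})],
    3: [frozenset({"psp", "dbptm", "qptm"})],
}

_DOMAIN_NAMES = [
    "Lyase_1", "FumaraseC_C", "TIM_barrel", "Rossmann_fold", "NAD_binding",
    "Kinase_dom", "Aldolase_II", "FAD_binding", "CoA_transf", "PLP_dep",
]


@dataclass
class SyntheticConfig:
    """Parameters of a generated cohort.

    Rates that are probabilities live in [0, 1]; ``enrichment_multiplier``
    scales density, burst rate and crosstalk rate in the planted
    PTM-enriched group and must be >= 1.
    """

    n_enzymes: int = 200
    length_range: tuple[int, int] = (250, 800)
    ptm_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PTM_RATES)
    )
    # gamma family for the per-enzyme site rate (per eligible residue);
    # within-group burden is concentrated (CV ~ 0.27) and the cohort-level
    # right skew arises from the enriched/sparse mixture
    density_gamma_shape: float = 14.0
    density_gamma_mean: float = 0.35
    burst_rate: float = 1.0          # expected bursts per baseline enzyme
    burst_width: int = 15            # residues spanned by one burst
    burst_fill: float = 0.9          # per-residue placement prob inside a burst
    crosstalk_rate: float = 0.1      # P(second type on a modified residue)
    detection_geom_p: float = 0.35   # shifted-geometric detection counts
    enriched_fraction: float = 0.15
    enrichment_multiplier: float = 3.0
    pathway_labels: dict[str, list[str]] = field(
        default_factory=lambda: {
            "enriched": ["core", "glycolysis", "tca_cycle"],
            "sparse": ["lipid_metabolism", "amino_acid_metabolism",
                       "nucleotide_metabolism", "xenobiotic_metabolism"],
        }
    )
    core_label_prob: tuple[float, float] = (0.8, 0.05)  # P("core") enriched/sparse
    domain_site_fraction: float = 0.4  # target fraction of sites inside domains
    rate_limiting_fraction: float = 0.08
    mitochondrial_fraction: float = 0.3
    variant_overlap_rate: float = 0.5
    variant_background_rate: float = 0.005
    functional_note_rate: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_enzymes < 1:
            raise ValueError("n_enzymes must be positive")
        if not (0.0 < self.enriched_fraction < 1.0):
            raise ValueError("enriched_fraction must lie in (0,1)")
        if self.enrichment_multiplier < 1.0:
            raise ValueError("enrichment_multiplier must be >= 1")
        for name, prob in [
            ("burst_fill", self.burst_fill),
            ("crosstalk_rate", self.crosstalk_rate),
            ("domain_site_fraction", self.domain_site_fraction),
            ("variant_overlap_rate", self.variant_overlap_rate),
            ("variant_background_rate", self.variant_background_rate),
        ]:
            if not (0.0 <= prob <= 1.0):
                raise ValueError(f"{name} must lie in [0,1]")
        for ptm_type in self.ptm_rates:
            if not DEFAULT_ELIGIBILITY.get(ptm_type):
                raise ValueError(f"no eligibility alphabet for active type {ptm_type!r}")

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "SyntheticConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**data)
        if isinstance(cfg.length_range, list):
            cfg.length_range = tuple(cfg.length_range)
        if isinstance(cfg.core_label_prob, list):
            cfg.core_label_prob = tuple(cfg.core_label_prob)
        return cfg


@dataclass
class SyntheticTruth:
    """Planted parameters of a generated cohort, for recovery tests."""

    group_label: dict[str, str]                  # accession -> enriched|sparse
    burst_intervals: dict[str, list[tuple[int, int]]]
    burst_site_counts: dict[str, list[int]]
    crosstalk_positions: dict[str, list[int]]
    rate_limiting: list[str]
    expected_base_sites: float   # sum of placement probabilities (exact)
    expected_base_variance: float
    realized_base_sites: int
    config: dict

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "SyntheticTruth":
        d = json.loads(Path(path).read_text())
        d["burst_intervals"] = {
            k: [tuple(iv) for iv in v] for k, v in d["burst_intervals"].items()
        }
        return cls(**d)


@dataclass
class Cohort:
    """In-memory bundle of everything a generated cohort contains."""

    enzymes: dict[str, Enzyme]
    sites: list[PTMSite]
    regions: list[RegionAnnotation]
    variants: list[VariantRecord]
    truth: SyntheticTruth


def _place_domains(rng, length: int) -> list[tuple[int, int]]:
    """2-3 non-overlapping domain intervals, each spanning 12-20% of the
    sequence (typical of real domain annotations on enzymes)."""
    n_dom = int(rng.integers(2, 4))
    intervals: list[tuple[int, int]] = []
    for _ in range(n_dom):
        span = max(20, int(length * rng.uniform(0.12, 0.20)))
        if span >= length:
            continue
        for _attempt in range(20):
            start = int(rng.integers(1, length - span + 1))
            end = start + span - 1
            if all(end < s or start > e for s, e in intervals):
                intervals.append((start, end))
                break
    return sorted(intervals)


def generate_cohort(config: SyntheticConfig) -> Cohort:
    """Generate one cohort; fully deterministic given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    aa = np.frombuffer(AMINO_ACIDS.encode(), dtype="S1").astype("U1")

    types = list(config.ptm_rates)
    rates = np.array([config.ptm_rates[t] for t in types])
    elig_masks = {t: np.isin(aa, list(DEFAULT_ELIGIBILITY[t])) for t in types}
    # residue letter -> indices of eligible types (for bursts / crosstalk)
    residue_types = {
        letter: [j for j, t in enumerate(types) if letter in DEFAULT_ELIGIBILITY[t]]
        for letter in AMINO_ACIDS
    }

    n = config.n_enzymes
    accessions = [f"SYN{i:04d}" for i in range(n)]
    n_enriched = max(1, int(round(config.enriched_fraction * n)))
    enriched_idx = rng.choice(n, size=n_enriched, replace=False)
    is_enriched = np.zeros(n, dtype=bool)
    is_enriched[enriched_idx] = True

    lengths = rng.integers(config.length_range[0], config.length_range[1] + 1, size=n)
    lam = rng.gamma(
        config.density_gamma_shape,
        config.density_gamma_mean / config.density_gamma_shape,
        size=n,
    )
    lam = np.where(is_enriched, lam * config.enrichment_multiplier, lam)

    enzymes: dict[str, Enzyme] = {}
    sites: list[PTMSite] = []
    regions: list[RegionAnnotation] = []
    variants: list[VariantRecord] = []
    burst_intervals: dict[str, list[tuple[int, int]]] = {}
    burst_counts: dict[str, list[int]] = {}
    crosstalk_positions: dict[str, list[int]] = {}
    expected_base = 0.0
    expected_var = 0.0
    realized_base = 0

    vclass_names = ["missense", "engineered", "nonsense", "other"]
    vclass_probs = [0.90, 0.05, 0.03, 0.02]

    for i, acc in enumerate(accessions):
        length = int(lengths[i])
        seq_idx = rng.integers(0, 20, size=length)
        seq_arr = aa[seq_idx]
        sequence = "".join(seq_arr)
        domains = _place_domains(rng, length)

        in_domain = np.zeros(length, dtype=bool)
        for start, end in domains:
            in_domain[start - 1 : end] = True

        # per-residue, per-type placement probabilities (mutually
        # exclusive types per residue; crosstalk is injected separately)
        prob = np.zeros((length, len(types)))
        for j, t in enumerate(types):
            prob[elig_masks[t][seq_idx], j] = lam[i] * rates[j]
        # Domain bias with probability mass conservation: rescale the
        # in-domain and out-of-domain zones toward the configured
        # expected in-domain site fraction, re-clipping per-residue
        # totals at 0.95 and letting unclipped residues absorb the
        # deficit (a few proportional-fitting rounds).
        total_p = prob.sum()
        cov = prob[in_domain].sum() / total_p if total_p > 0 else 0.0
        if 0.0 < cov < 1.0:
            f = config.domain_site_fraction
            targets = {True: f * total_p, False: (1 - f) * total_p}
            for _ in range(6):
                p_total = prob.sum(axis=1)
                over = p_total > 0.95
                prob[over] *= (0.95 / p_total[over])[:, None]
                p_total = prob.sum(axis=1)
                for zone in (True, False):
                    zmask = in_domain == zone
                    free = zmask & ~over & (p_total > 0)
                    fixed_mass = p_total[zmask & over].sum()
                    free_mass = p_total[free].sum()
                    if free_mass > 0 and targets[zone] > fixed_mass:
                        prob[free] *= (targets[zone] - fixed_mass) / free_mass
        p_total = prob.sum(axis=1)
        over = p_total > 0.95
        if over.any():  # keep residue-level probability a probability
            prob[over] *= (0.95 / p_total[over])[:, None]
            p_total = prob.sum(axis=1)
        expected_base += float(p_total.sum())
        expected_var += float((p_total * (1 - p_total)).sum())

        u = rng.random(length)
        hit = u < p_total
        realized_base += int(hit.sum())
        site_type: dict[int, int] = {}
        if hit.any():
            hit_pos = np.flatnonzero(hit)
            cum = np.cumsum(prob[hit_pos], axis=1)
            pick = (u[hit_pos, None] >= np.column_stack(
                [np.zeros(len(hit_pos)), cum[:, :-1]])).sum(axis=1) - 1
            for pos0, j in zip(hit_pos, pick):
                site_type[int(pos0) + 1] = int(j)

        # planted bursts: dense placement inside a short window
        rate = config.burst_rate * (
            config.enrichment_multiplier if is_enriched[i] else 1.0
        )
        n_bursts = int(rng.poisson(rate))
        ivals, counts = [], []
        half = config.burst_width // 2
        for _ in range(n_bursts):
            if length <= config.burst_width + 2:
                break
            center = int(rng.integers(1 + half, length - half))
            lo, hi = center - half, center + half
            placed = 0
            for pos in range(lo, hi + 1):
                if pos in site_type:
                    placed += 1
                    continue
                if rng.random() >= config.burst_fill:
                    continue
                options = residue_types[sequence[pos - 1]]
                if not options:
                    continue
                site_type[pos] = int(rng.choice(options))
                placed += 1
            ivals.append((lo, hi))
            counts.append(placed)
        burst_intervals[acc] = ivals
        burst_counts[acc] = counts

        # crosstalk injection: second type on an already-modified residue
        injected: list[int] = []
        xrate = config.crosstalk_rate * (
            config.enrichment_multiplier if is_enriched[i] else 1.0
        )
        xrate = min(1.0, xrate)
        site_types: dict[int, set[int]] = {p: {j} for p, j in site_type.items()}
        if xrate > 0:
            for pos in sorted(site_type):
                if rng.random() >= xrate:
                    continue
                options = [
                    j for j in residue_types[sequence[pos - 1]]
                    if j not in site_types[pos]
                ]
                if not options:
                    continue
                site_types[pos].add(int(rng.choice(options)))
                injected.append(pos)
        crosstalk_positions[acc] = injected

        # canonical catalog order: (position, type name), matching the
        # harmonizer's sort so round-trips compare equal
        records = sorted(
            ((pos, j) for pos, js in site_types.items() for j in js),
            key=lambda r: (r[0], types[r[1]]),
        )
        n_rec = len(records)
        detections = rng.geometric(config.detection_geom_p, size=n_rec)
        n_src = 1 + rng.binomial(2, 0.3, size=n_rec)
        src_pick = rng.integers(0, 3, size=n_rec)
        note_u = rng.random(size=n_rec)
        note_kind = rng.random(size=n_rec)
        for r, (pos, j) in enumerate(records):
            srcs = _SOURCE_SUBSETS[int(n_src[r])][int(src_pick[r]) % len(
                _SOURCE_SUBSETS[int(n_src[r])])]
            note = None
            if note_u[r] < config.functional_note_rate:
                note = "activation" if note_kind[r] < 0.5 else "inhibition"
            sites.append(
                PTMSite(acc, pos, sequence[pos - 1], types[j],
                        int(detections[r]), srcs, note)
            )

        enzyme_regions = [
            RegionAnnotation(
                acc, "domain", start, end,
                _DOMAIN_NAMES[int(rng.integers(0, len(_DOMAIN_NAMES)))],
            )
            for start, end in domains
        ]
        # one disordered stretch near a terminus for about half the enzymes
        if rng.random() < 0.5:
            span = int(rng.integers(15, 40))
            if span < length:
                if rng.random() < 0.5:
                    enzyme_regions.append(RegionAnnotation(acc, "disordered", 1, span, "IDR"))
                else:
                    enzyme_regions.append(
                        RegionAnnotation(acc, "disordered", length - span + 1, length, "IDR")
                    )
        regions.extend(enzyme_regions)

        # variants: on PTM positions at the overlap rate, elsewhere sparse
        ptm_positions = sorted(site_types)
        overlap_mask = rng.random(len(ptm_positions)) < config.variant_overlap_rate
        hit_positions = [p for p, m in zip(ptm_positions, overlap_mask) if m]
        alt_shift = rng.integers(1, 20, size=len(hit_positions))
        vclasses = rng.choice(vclass_names, size=len(hit_positions), p=vclass_probs)
        for pos, shift, vclass in zip(hit_positions, alt_shift, vclasses):
            ref = sequence[pos - 1]
            alt = AMINO_ACIDS[(AMINO_ACIDS.index(ref) + int(shift)) % 20]
            variants.append(VariantRecord(acc, pos, ref, alt, str(vclass), "synthetic"))
        others = np.setdiff1d(np.arange(1, length + 1), np.array(ptm_positions, dtype=int))
        n_bg = int(rng.binomial(len(others), config.variant_background_rate))
        if n_bg:
            bg_positions = rng.choice(others, size=n_bg, replace=False)
            bg_shift = rng.integers(1, 20, size=n_bg)
            for pos, shift in zip(bg_positions, bg_shift):
                pos = int(pos)
                ref = sequence[pos - 1]
                alt = AMINO_ACIDS[(AMINO_ACIDS.index(ref) + int(shift)) % 20]
                variants.append(VariantRecord(acc, pos, ref, alt, "missense", "synthetic"))

        # annotations: pathways, flags, text descriptors
        group = "enriched" if is_enriched[i] else "sparse"
        pool = list(config.pathway_labels[group])
        pathways: set[str] = set()
        core_p = config.core_label_prob[0 if group == "enriched" else 1]
        if "core" in config.pathway_labels.get("enriched", []):
            if rng.random() < core_p:
                pathways.add("core")
        pool_wo_core = [p for p in pool if p != "core"]
        k_path = int(rng.integers(1, 3))
        if pool_wo_core:
            pathways |= {
                str(p)
                for p in rng.choice(pool_wo_core, size=min(k_path, len(pool_wo_core)),
                                    replace=False)
            }
        other_group = "sparse" if group == "enriched" else "enriched"
        if rng.random() < 0.1:  # mild cross-contamination of labels
            other_pool = [p for p in config.pathway_labels[other_group] if p != "core"]
            if other_pool:
                pathways.add(str(rng.choice(other_pool)))

        terms = _ENRICHED_TERMS if group == "enriched" else _SPARSE_TERMS
        n_terms = int(rng.integers(4, 9))
        descriptors = list(rng.choice(terms, size=min(n_terms, len(terms)), replace=False))
        descriptors += list(rng.choice(_SHARED_TERMS, size=3, replace=False))
        descriptors += [r.name for r in enzyme_regions if r.name]

        enzymes[acc] = Enzyme(
            accession=acc,
            sequence=sequence,
            gene_symbol=f"G{i:04d}",
            ec_class=str(rng.choice(list(EC_CLASSES))),
            pathways=pathways,
            is_rate_limiting=False,
            is_mitochondrial=bool(rng.random() < config.mitochondrial_fraction),
            text_descriptors=descriptors,
        )

    # rate-limiting flags: a subset of the planted enriched group
    n_rl = min(n_enriched, max(1, int(round(config.rate_limiting_fraction * n))))
    rl_idx = rng.choice(enriched_idx, size=n_rl, replace=False)
    rate_limiting = sorted(accessions[int(j)] for j in rl_idx)
    for acc in rate_limiting:
        enzymes[acc].is_rate_limiting = True

    truth = SyntheticTruth(
        group_label={
            acc: ("enriched" if is_enriched[i] else "sparse")
            for i, acc in enumerate(accessions)
        },
        burst_intervals=burst_intervals,
        burst_site_counts=burst_counts,
        crosstalk_positions=crosstalk_positions,
        rate_limiting=rate_limiting,
        expected_base_sites=expected_base,
        expected_base_variance=expected_var,
        realized_base_sites=realized_base,
        config=dataclasses.asdict(config),
    )
    return Cohort(enzymes, sites, regions, variants, truth)


def cohort_to_files(cohort: Cohort, out_dir: Union[str, Path]) -> dict[str, Path]:
    """Write a cohort in exactly the formats the loaders read.

    Round-trip contract: loading the written files reproduces the
    in-memory cohort (sequence, catalog, regions, variants, flags).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out / "enzymes.fasta",
        "sites": out / "ptm_sites.tsv",
        "regions": out / "regions.tsv",
        "variants": out / "variants.tsv",
        "annotations": out / "annotations.tsv",
        "truth": out / "truth.json",
    }
    with open(paths["fasta"], "w") as fh:
        for enzyme in cohort.enzymes.values():
            fh.write(f">sp|{enzyme.accession}|{enzyme.gene_symbol}_SYN\n")
            seq = enzyme.sequence
            for k in range(0, len(seq), 60):
                fh.write(seq[k : k + 60] + "\n")

    from .io import write_catalog

    write_catalog(cohort.sites, paths["sites"])

    import pandas as pd

    pd.DataFrame(
        [
            {"accession": r.accession, "region_type": r.region_type,
             "start": r.start, "end": r.end, "name": r.name}
            for r in cohort.regions
        ],
        columns=["accession", "region_type", "start", "end", "name"],
    ).to_csv(paths["regions"], sep="\t", index=False)

    pd.DataFrame(
        [
            {"accession": v.accession, "position": v.position,
             "ref_residue": v.ref_residue, "alt_residue": v.alt_residue,
             "variant_class": v.variant_class, "source": v.source}
            for v in cohort.variants
        ],
        columns=["accession", "position", "ref_residue", "alt_residue",
                 "variant_class", "source"],
    ).to_csv(paths["variants"], sep="\t", index=False)

    pd.DataFrame(
        [
            {
                "accession": e.accession,
                "gene_symbol": e.gene_symbol,
                "ec_class": e.ec_class,
                "pathways": "|".join(sorted(e.pathways)),
                "is_rate_limiting": int(e.is_rate_limiting),
                "is_mitochondrial": int(e.is_mitochondrial),
                "text_descriptors": "|".join(e.text_descriptors),
            }
            for e in cohort.enzymes.values()
        ]
    ).to_csv(paths["annotations"], sep="\t", index=False)

    cohort.truth.to_json(paths["truth"])
    return paths


def load_cohort(in_dir: Union[str, Path], strict: bool = False) -> Cohort:
    """Reload a cohort written by :func:`cohort_to_files` via the loaders."""
    from . import io as ptm_io

    in_dir = Path(in_dir)
    enzymes = ptm_io.load_sequences(in_dir / "enzymes.fasta", strict=strict)
    sites = ptm_io.load_catalog(in_dir / "ptm_sites.tsv")
    sites, _ = ptm_io.harmonize_sites(sites, enzymes)
    regions, _ = ptm_io.load_regions(in_dir / "regions.tsv", enzymes)
    variants, _ = ptm_io.load_variants(in_dir / "variants.tsv")
    ptm_io.load_enzyme_annotations(in_dir / "annotations.tsv", enzymes)
    truth_path = in_dir / "truth.json"
    truth = SyntheticTruth.from_json(truth_path) if truth_path.exists() else None
    return Cohort(enzymes, sites, regions, variants, truth)
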