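"""Core record types shared across the pipeline.

All coordinates are 1-based inclusive, following UniProt convention;
every window and region in the package is a closed interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .vocab import CANONICAL_RESIDUES, EC_CLASSES


@dataclass
class Enzyme:
    """One catalog entry per protein.

    ``length`` always equals ``len(sequence)``; ``pathways`` holds
    pathway identifiers, ``text_descriptors`` free-text annotation
    strings (region names, functional descriptions, process terms) used
    by the TF-IDF block of the clustering matrix.
    """

    accession: str
    sequence: str
    gene_symbol: str = ""
    ec_class: str = "unknown"
    pathways: set[str] = field(default_factory=set)
    is_rate_limiting: bool = False
    is_mitochondrial: bool = False
    text_descriptors: list[str] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def validate(self, strict: bool = False) -> list[str]:
        """Return a list of problems (empty when valid)."""
        problems = []
        if not self.accession:
            problems.append("empty accession")
        if not self.sequence:
            problems.append("empty sequence")
        allowed = CANONICAL_RESIDUES if strict else CANONICAL_RESIDUES | {"X"}
        bad = set(self.sequence) - allowed
        if bad:
            problems.append(f"non-canonical residues {sorted(bad)}")
        if self.ec_class != "unknown" and self.ec_class not in EC_CLASSES:
            problems.append(f"unknown EC class {self.ec_class!r}")
        return problems


@dataclass(frozen=True)
class RawPTMRecord:
    """A single source-database row, prior to harmonization."""

    accession: str
    position: int
    residue: str
    ptm_type: str
    source: str = "unknown"
    study_count: int = 1
    functional_note: Optional[str] = None
    is_standard_type: bool = True


@dataclass(frozen=True)
class PTMSite:
    """A harmonized site: unique per (accession, position, ptm_type).

    ``detection_count`` is the cumulative number of supporting reports
    across all contributing sources (at least 1 per source record).
    """

    accession: str
    position: int
    residue: str
    ptm_type: str
    detection_count: int
    sources: frozenset[str] = frozenset({"unknown"})
    functional_note: Optional[str] = None


@dataclass(frozen=True)
class RegionAnnotation:
    accession: str
    region_type: str  # domain | family | conserved_site | repeat | disordered
    start: int
    end: int
    name: str = ""


@dataclass(frozen=True)
class VariantRecord:
    accession: str
    position: int
    ref_residue: str
    alt_residue: str
    variant_class: str = "missense"  # missense|nonsense|synonymous|engineered|other
    source: str = "unknown"


REGION_TYPES = ("domain", "family", "conserved_site", "repeat", "disordered")
VARIANT_CLASSES = ("missense", "nonsense", "synonymous", "engineered", "other")


def sites_frame(sites: list[PTMSite]) -> pd.DataFrame:
    """Tabular view of a harmonized catalog (one row per site)."""
    return pd.DataFrame(
        {
            "accession": [s.accession for s in sites],
            "position": [s.position for s in sites],
            "residue": [s.residue for s in sites],
            "ptm_type": [s.ptm_type for s in sites],
            "detection_count": [s.detection_count for s in sites],
            "sources": ["|".join(sorted(s.sources)) for s in sites],
            "functional_note": [s.functional_note or "" for s in sites],
        }
    )
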