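"""Readers, validators and the residue-level harmonization step.

The harmonizer consolidates PTM annotations from several database
dialects into one deduplicated catalog keyed to reference sequences:
records are grouped by exact (accession, position, modification type),
detection counts are summed across sources, and any record whose
annotated residue conflicts with the reference sequence is excluded and
itemized in the report.  Sites are retained irrespective of how many
studies support them; a single-study site has detection count 1.
"""

from __future__ import annotations

import dataclasses
import json
import re
import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import pandas as pd
from Bio import SeqIO

from .types import (
    Enzyme,
    PTMSite,
    RawPTMRecord,
    RegionAnnotation,
    VariantRecord,
    REGION_TYPES,
    VARIANT_CLASSES,
)
from .vocab import EC_CLASSES, normalize_ptm_type

PTM_DIALECTS = ("psp_like", "dbptm_like", "qptm_like", "generic_tsv")

# "sp|P07954|FUMH_HUMAN" or "tr|Q...|..." UniProt-style headers
_UNIPROT_HEADER = re.compile(r"^(?:sp|tr)\|(?P<acc>[^|]+)\|(?P<name>\S+)")
_JOINT_SITE = re.compile(r"^(?P<res>[A-Za-z])(?P<pos>\d+)")


class PTMIOError(ValueError):
    """Raised for unrecoverable input problems (bad dialect, bad file)."""


@dataclass
class LoadReport:
    """Per-file accounting of rows that could not be used."""

    n_rows: int = 0
    n_loaded: int = 0
    n_dropped: int = 0
    dropped: list[dict] = field(default_factory=list)

    def drop(self, reason: str, **context) -> None:
        self.n_dropped += 1
        self.dropped.append({"reason": reason, **context})


@dataclass
class HarmonizationReport:
    n_input_records: int = 0
    n_accepted_records: int = 0
    n_sites: int = 0
    rejections: list[dict] = field(default_factory=list)

    def reject(self, reason: str, **context) -> None:
        self.rejections.append({"reason": reason, **context})

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


def load_sequences(fasta_path: Union[str, Path], strict: bool = False) -> dict[str, Enzyme]:
    """Parse reference sequences into Enzyme skeletons keyed by accession.

    Accepts both UniProt ``sp|ACC|NAME`` headers and bare-accession
    headers.  Duplicate accessions and empty sequences are errors;
    non-canonical residues are an error in strict mode, otherwise a
    warning (the record is retained).
    """
    fasta_path = Path(fasta_path)
    if not fasta_path.exists():
        raise PTMIOError(f"FASTA file not found: {fasta_path}")
    enzymes: dict[str, Enzyme] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        m = _UNIPROT_HEADER.match(rec.id)
        if m:
            accession = m.group("acc")
            gene = m.group("name").split("_")[0]
        else:
            accession = rec.id
            gene = ""
        if accession in enzymes:
            raise PTMIOError(f"duplicate accession in FASTA: {accession}")
        enzyme = Enzyme(accession=accession, sequence=str(rec.seq).upper(), gene_symbol=gene)
        problems = enzyme.validate(strict=True)
        if problems:
            if strict or not enzyme.sequence:
                raise PTMIOError(f"{accession}: {'; '.join(problems)}")
            warnings.warn(f"{accession}: {'; '.join(problems)}", stacklevel=2)
        enzymes[accession] = enzyme
    return enzymes


def _split_joint_site(token: str) -> tuple[Optional[str], Optional[int]]:
    """Split a joint residue+position token such as 'S293' (or 'S293-p')."""
    m = _JOINT_SITE.match(token.strip())
    if not m:
        return None, None
    return m.group("res").upper(), int(m.group("pos"))


# Column layouts per dialect.  Each maps our field names to the column
# names expected in the input file; ``joint_site`` dialects encode
# residue and position in a single token.
_DIALECT_COLUMNS: dict[str, dict] = {
    "generic_tsv": {
        "required": ["accession", "position", "residue", "ptm_type"],
        "optional": {"source": "source", "study_count": "study_count",
                     "functional_note": "functional_note"},
        "joint_site": None,
        "default_source": "generic",
    },
    "psp_like": {
        "required": ["ACC_ID", "MOD_RSD", "MOD_TYPE"],
        "optional": {"study_count": "LIT_COUNT", "functional_note": "ON_FUNCTION"},
        "joint_site": "MOD_RSD",
        "accession": "ACC_ID",
        "ptm_type": "MOD_TYPE",
        "default_source": "psp",
    },
    "dbptm_like": {
        "required": ["UniprotID", "Position", "Residue", "PTM_type"],
        "optional": {"study_count": "N_reports", "functional_note": "Note"},
        "joint_site": None,
        "accession": "UniprotID",
        "position": "Position",
        "residue": "Residue",
        "ptm_type": "PTM_type",
        "default_source": "dbptm",
    },
    "qptm_like": {
        "required": ["accession", "site", "ptm"],
        "optional": {"study_count": "num_studies"},
        "joint_site": "site",
        "ptm_type": "ptm",
        "default_source": "qptm",
    },
}


def load_ptm_table(
    path: Union[str, Path], dialect: str = "generic_tsv"
) -> tuple[list[RawPTMRecord], LoadReport]:
    """Read one source database table into raw PTM records.

    PTM-type strings are normalized through the shipped synonym table.
    Rows with unparseable or out-of-range positions are dropped and
    counted in the returned :class:`LoadReport`.
    """
    if dialect not in PTM_DIALECTS:
        raise PTMIOError(f"unknown dialect {dialect!r}; expected one of {PTM_DIALECTS}")
    spec = _DIALECT_COLUMNS[dialect]
    try:
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    except (OSError, pd.errors.ParserError) as exc:
        raise PTMIOError(f"cannot read PTM table {path}: {exc}") from exc
    missing = [c for c in spec["required"] if c not in df.columns]
    if missing:
        raise PTMIOError(f"{path}: dialect {dialect!r} requires columns {missing}")

    report = LoadReport(n_rows=len(df))
    records: list[RawPTMRecord] = []
    acc_col = spec.get("accession", "accession")
    type_col = spec.get("ptm_type", "ptm_type")
    opt = spec["optional"]
    for idx, row in df.iterrows():
        if spec["joint_site"]:
            token = row[spec["joint_site"]]
            residue, position = _split_joint_site(token)
            if position is None:
                report.drop("unparseable_site", row=int(idx), token=token)
                continue
        else:
            pos_col = spec.get("position", "position")
            res_col = spec.get("residue", "residue")
            try:
                position = int(float(row[pos_col]))
            except (TypeError, ValueError):
                report.drop("unparseable_position", row=int(idx), value=row[pos_col])
                continue
            residue = str(row[res_col]).strip().upper()
        if position < 1:
            report.drop("nonpositive_position", row=int(idx), position=position)
            continue
        ptm_type, standard = normalize_ptm_type(row[type_col])
        count = 1
        if "study_count" in opt and opt["study_count"] in df.columns:
            raw_count = str(row[opt["study_count"]]).strip()
            if raw_count:
                try:
                    count = max(0, int(float(raw_count)))
                except ValueError:
                    count = 1
        note_col = opt.get("functional_note")
        note = str(row[note_col]).strip() if note_col and note_col in df.columns else ""
        source = spec["default_source"]
        if "source" in opt and opt["source"] in df.columns and str(row[opt["source"]]).strip():
            source = str(row[opt["source"]]).strip()
        records.append(
            RawPTMRecord(
                accession=str(row[acc_col]).strip(),
                position=position,
                residue=residue,
                ptm_type=ptm_type,
                source=source,
                study_count=count,
                functional_note=note or None,
                is_standard_type=standard,
            )
        )
        report.n_loaded += 1
    return records, report


def _contributions(record: Union[RawPTMRecord, PTMSite]):
    """Normalize raw records and already-harmonized sites to one shape.

    Accepting PTMSite inputs makes harmonization idempotent by
    construction: a site contributes its full detection count and its
    source set, so re-harmonizing a catalog is a no-op.
    """
    if isinstance(record, PTMSite):
        notes = record.functional_note.split("|") if record.functional_note else []
        return (record.accession, record.position, record.residue.upper(),
                record.ptm_type, record.detection_count, set(record.sources), notes)
    count = max(1, record.study_count)  # every source record is >=1 report
    notes = [record.functional_note] if record.functional_note else []
    return (record.accession, record.position, record.residue.upper(),
            record.ptm_type, count, {record.source}, notes)


def harmonize_sites(
    raw: Iterable[Union[RawPTMRecord, PTMSite]],
    enzymes: Mapping[str, Enzyme],
) -> tuple[list[PTMSite], HarmonizationReport]:
    """Merge raw records into one deduplicated site catalog.

    Records are grouped by (accession, position, ptm_type); detection
    counts sum across sources; sources union.  Records referencing
    unknown accessions, positions beyond the sequence, or residues that
    conflict with the sequence character at that position are excluded
    with itemized reason codes.  Conflicting functional notes are kept,
    pipe-joined in sorted order.
    """
    report = HarmonizationReport()
    groups: dict[tuple, dict] = defaultdict(
        lambda: {"count": 0, "sources": set(), "notes": set(), "residue": None}
    )
    for record in raw:
        report.n_input_records += 1
        acc, pos, residue, ptm_type, count, sources, notes = _contributions(record)
        enzyme = enzymes.get(acc)
        if enzyme is None:
            report.reject("unknown_accession", accession=acc, position=pos, ptm_type=ptm_type)
            continue
        if pos > enzyme.length:
            report.reject("position_out_of_bounds", accession=acc, position=pos,
                          length=enzyme.length)
            continue
        seq_res = enzyme.sequence[pos - 1]
        if residue != seq_res:
            report.reject("residue_mismatch", accession=acc, position=pos,
                          annotated=residue, in_sequence=seq_res)
            continue
        report.n_accepted_records += 1
        g = groups[(acc, pos, ptm_type)]
        g["count"] += count
        g["sources"] |= sources
        g["notes"].update(n for n in notes if n)
        g["residue"] = seq_res

    sites = [
        PTMSite(
            accession=acc,
            position=pos,
            residue=g["residue"],
            ptm_type=ptm_type,
            detection_count=g["count"],
            sources=frozenset(g["sources"]),
            functional_note="|".join(sorted(g["notes"])) or None,
        )
        for (acc, pos, ptm_type), g in sorted(groups.items())
    ]
    report.n_sites = len(sites)
    return sites, report


def load_regions(
    path: Union[str, Path], enzymes: Mapping[str, Enzyme]
) -> tuple[list[RegionAnnotation], LoadReport]:
    """Read region annotations (accession, region_type, start, end, name).

    Out-of-bounds regions are clipped to [1, length] with a warning;
    start > end or unknown region types are rejected into the report.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = ["accession", "region_type", "start", "end"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise PTMIOError(f"{path}: region table missing columns {missing}")
    report = LoadReport(n_rows=len(df))
    regions: list[RegionAnnotation] = []
    for idx, row in df.iterrows():
        try:
            start, end = int(row["start"]), int(row["end"])
        except ValueError:
            report.drop("unparseable_bounds", row=int(idx))
            continue
        if row["region_type"] not in REGION_TYPES:
            report.drop("unknown_region_type", row=int(idx), region_type=row["region_type"])
            continue
        if start > end:
            report.drop("start_after_end", row=int(idx), start=start, end=end)
            continue
        acc = row["accession"].strip()
        enzyme = enzymes.get(acc)
        if enzyme is None:
            report.drop("unknown_accession", row=int(idx), accession=acc)
            continue
        if start < 1 or end > enzyme.length:
            clipped = (max(1, start), min(enzyme.length, end))
            warnings.warn(
                f"region [{start},{end}] on {acc} clipped to {list(clipped)}",
                stacklevel=2,
            )
            start, end = clipped
        regions.append(RegionAnnotation(acc, row["region_type"], start, end,
                                        row.get("name", "")))
        report.n_loaded += 1
    return regions, report


def load_variants(path: Union[str, Path]) -> tuple[list[VariantRecord], LoadReport]:
    """Read a variant table (accession, position, ref/alt residue, class)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = ["accession", "position", "ref_residue", "alt_residue", "variant_class"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise PTMIOError(f"{path}: variant table missing columns {missing}")
    report = LoadReport(n_rows=len(df))
    variants: list[VariantRecord] = []
    for idx, row in df.iterrows():
        try:
            position = int(row["position"])
        except ValueError:
            report.drop("unparseable_position", row=int(idx))
            continue
        if position < 1:
            report.drop("nonpositive_position", row=int(idx), position=position)
            continue
        vclass = row["variant_class"].strip().lower() or "other"
        if vclass not in VARIANT_CLASSES:
            vclass = "other"
        ref = row["ref_residue"].strip().upper()
        alt = row["alt_residue"].strip().upper()
        if vclass == "missense" and ref == alt:
            report.drop("missense_without_change", row=int(idx), position=position)
            continue
        variants.append(
            VariantRecord(row["accession"].strip(), position, ref, alt, vclass,
                          row.get("source", "unknown") or "unknown")
        )
        report.n_loaded += 1
    return variants, report


def load_enzyme_annotations(
    path: Union[str, Path], enzymes: Mapping[str, Enzyme]
) -> dict[str, Enzyme]:
    """Merge pathway/EC/flag/descriptor fields into loaded enzymes.

    Expected columns: accession, ec_class, pathways (pipe-separated),
    is_rate_limiting, is_mitochondrial, text_descriptors
    (pipe-separated); gene_symbol optional.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if "accession" not in df.columns:
        raise PTMIOError(f"{path}: annotation table missing 'accession'")
    truthy = {"1", "true", "yes", "y"}
    for _, row in df.iterrows():
        enzyme = enzymes.get(row["accession"].strip())
        if enzyme is None:
            continue
        if row.get("gene_symbol", ""):
            enzyme.gene_symbol = row["gene_symbol"].strip()
        ec = row.get("ec_class", "").strip().lower()
        if ec in EC_CLASSES:
            enzyme.ec_class = ec
        if row.get("pathways", ""):
            enzyme.pathways = {p for p in row["pathways"].split("|") if p}
        enzyme.is_rate_limiting = row.get("is_rate_limiting", "").strip().lower() in truthy
        enzyme.is_mitochondrial = row.get("is_mitochondrial", "").strip().lower() in truthy
        if row.get("text_descriptors", ""):
            enzyme.text_descriptors = [t for t in row["text_descriptors"].split("|") if t]
    return dict(enzymes)


def write_catalog(sites: list[PTMSite], path: Union[str, Path]) -> None:
    """Write a harmonized catalog as TSV."""
    from .types import sites_frame

    sites_frame(sites).to_csv(path, sep="\t", index=False)


def load_catalog(path: Union[str, Path]) -> list[PTMSite]:
    """Read back a catalog written by :func:`write_catalog`."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return [
        PTMSite(
            accession=row["accession"],
            position=int(row["position"]),
            residue=row["residue"],
            ptm_type=row["ptm_type"],
            detection_count=int(row["detection_count"]),
            sources=frozenset(row["sources"].split("|")),
            functional_note=row["functional_note"] or None,
        )
        for _, row in df.iterrows()
    ]
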