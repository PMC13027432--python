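"""Controlled vocabulary for PTM types and residue eligibility.

PTM names arriving from different source databases use inconsistent
spellings ("Phosphorylation", "phospho", "Phosphoserine", ...).  All
records are normalized to a canonical lower-case vocabulary before any
merging, so that sites reported under synonymous labels consolidate.
Types outside the canonical table are retained but flagged nonstandard;
they are never silently reclassified.
"""

from __future__ import annotations

# Canonical PTM type names observed on human metabolic enzymes.
CANONICAL_PTM_TYPES: tuple[str, ...] = (
    "phosphorylation",
    "acetylation",
    "ubiquitination",
    "methylation",
    "sumoylation",
    "succinylation",
    "malonylation",
    "glutarylation",
    "glutathionylation",
    "s-nitrosylation",
    "s-palmitoylation",
    "sulfoxidation",
    "n-linked glycosylation",
    "o-linked glycosylation",
    "neddylation",
    "adp-ribosylation",
    "carbamidation",
    "deamidation",
    "farnesylation",
    "geranylgeranylation",
    "gpi-anchor",
    "hydroxylation",
    "lipoylation",
    "pyruvation",
    "oxidation",
    "biotinylation",
    "dephosphorylation",
)

# Synonym spellings mapped onto the canonical names.  Keys are matched
# after lower-casing and stripping surrounding whitespace.
_SYNONYMS: dict[str, str] = {
    "phospho": "phosphorylation",
    "phosphoserine": "phosphorylation",
    "phosphothreonine": "phosphorylation",
    "phosphotyrosine": "phosphorylation",
    "p": "phosphorylation",
    "acetyl": "acetylation",
    "n6-acetyllysine": "acetylation",
    "ac": "acetylation",
    "ubiquitylation": "ubiquitination",
    "ubiquitin": "ubiquitination",
    "ub": "ubiquitination",
    "methyl": "methylation",
    "monomethylation": "methylation",
    "dimethylation": "methylation",
    "trimethylation": "methylation",
    "me": "methylation",
    "sumo": "sumoylation",
    "sumoylation (sumo)": "sumoylation",
    "succinyl": "succinylation",
    "malonyl": "malonylation",
    "glutaryl": "glutarylation",
    "s-glutathionylation": "glutathionylation",
    "nitrosylation": "s-nitrosylation",
    "s-nitrosocysteine": "s-nitrosylation",
    "palmitoylation": "s-palmitoylation",
    "methionine sulfoxide": "sulfoxidation",
    "n-glycosylation": "n-linked glycosylation",
    "n-linked_glycosylation": "n-linked glycosylation",
    "o-glycosylation": "o-linked glycosylation",
    "o-linked_glycosylation": "o-linked glycosylation",
    "o-glcnacylation": "o-linked glycosylation",
    "o-glcnac": "o-linked glycosylation",
    "neddyl": "neddylation",
    "adp ribosylation": "adp-ribosylation",
    "adp-ribosyl": "adp-ribosylation",
    "gpi anchor": "gpi-anchor",
    "gpi-anchor addition": "gpi-anchor",
    "hydroxyl": "hydroxylation",
    "lipoyl": "lipoylation",
    "biotinyl": "biotinylation",
}

#: Residue alphabets per PTM type.  Only the phosphorylation and
#: acetylation examples are fixed by convention in the source material;
#: the rest follow standard residue chemistry and are override-able via
#: :class:`ptmatlas.metrics.EligibilityMap`.
DEFAULT_ELIGIBILITY: dict[str, frozenset[str]] = {
    "phosphorylation": frozenset("STY"),
    "dephosphorylation": frozenset("STY"),
    "acetylation": frozenset("K"),
    "ubiquitination": frozenset("K"),
    "sumoylation": frozenset("K"),
    "neddylation": frozenset("K"),
    "methylation": frozenset("KR"),
    "succinylation": frozenset("K"),
    "malonylation": frozenset("K"),
    "glutarylation": frozenset("K"),
    "biotinylation": frozenset("K"),
    "lipoylation": frozenset("K"),
    "s-nitrosylation": frozenset("C"),
    "glutathionylation": frozenset("C"),
    "s-palmitoylation": frozenset("C"),
    "sulfoxidation": frozenset("M"),
    "n-linked glycosylation": frozenset("N"),
    "o-linked glycosylation": frozenset("ST"),
    "hydroxylation": frozenset("PK"),
    "farnesylation": frozenset("C"),
    "geranylgeranylation": frozenset("C"),
    "deamidation": frozenset("NQ"),
    "carbamidation": frozenset("CK"),
    "adp-ribosylation": frozenset("RSEDK"),
    "oxidation": frozenset("CM"),
}

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
CANONICAL_RESIDUES: frozenset[str] = frozenset(AMINO_ACIDS)

EC_CLASSES: tuple[str, ...] = (
    "oxidoreductase",
    "transferase",
    "hydrolase",
    "lyase",
    "isomerase",
    "ligase",
)


def normalize_ptm_type(name: str) -> tuple[str, bool]:
    """Map a raw PTM-type string to the canonical vocabulary.

    Returns ``(canonical_name, is_standard)``.  Unknown names are
    lower-cased and passed through with ``is_standard=False``.
    """
    key = name.strip().lower().replace("_", " ")
    if key in CANONICAL_PTM_TYPES:
        return key, True
    key2 = key.replace(" ", "-")
    if key2 in CANONICAL_PTM_TYPES:
        return key2, True
    if key in _SYNONYMS:
        return _SYNONYMS[key], True
    return key, False
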