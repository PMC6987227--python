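"""The canonical 52-feature catalogue.

The feature set covers four families: protein sequential (12), protein
structural (9), DNA sequential (22) and DNA structural (9).  Column order is
fixed and used for tie-breaking in feature ranking and for table layout.
"""

from __future__ import annotations

# Ten nearest-neighbor dinucleotide classes of a Watson-Crick duplex, in the
# conventional top-strand/bottom-strand notation (CA/GT means 5'-CA-3' paired
# with 3'-GT-5').  Order follows the standard listing.
NN_LABELS = [
    "CA/GT", "GC/CG", "GG/CC", "CG/GC", "TA/AT",
    "AT/TA", "AA/TT", "GT/CA", "GA/CT", "CT/GA",
]


def nn_feature_name(label: str, pct: bool = False) -> str:
    stem = label.replace("/", "_")
    return f"nn_{'pct' if pct else 'count'}_{stem}"


PROTEIN_SEQUENTIAL = [
    "protein_mass",
    "hbond_count",
    "hydrophilic_count",
    "hydrophilic_pct",
    "hydrophobic_count",
    "hydrophobic_pct",
    "aromatic_positive_count",
    "aromatic_positive_pct",
    "polar_count",
    "polar_pct",
    "charged_count",
    "charged_pct",
]

PROTEIN_STRUCTURAL = [
    "helix_segment_count",
    "helix_residue_count",
    "helix_residue_pct",
    "sheet_segment_count",
    "sheet_residue_count",
    "sheet_residue_pct",
    "helix_mass",
    "sheet_mass",
    "total_sasa",
]

DNA_SEQUENTIAL = (
    ["dna_mass", "nucleotide_count"]
    + [nn_feature_name(lbl) for lbl in NN_LABELS]
    + [nn_feature_name(lbl, pct=True) for lbl in NN_LABELS]
)

DNA_STRUCTURAL = [
    "ensemble_diversity",
    "mfe_frequency",
    "cww_pair_count",
    "xix_count",
    "xix_pct",
    "xx_count",
    "xx_pct",
    "bp_total_count",
    "paired_fraction",
]

FEATURE_CATALOGUE: list[str] = (
    PROTEIN_SEQUENTIAL + PROTEIN_STRUCTURAL + DNA_SEQUENTIAL + DNA_STRUCTURAL
)

assert len(FEATURE_CATALOGUE) == 52

CATALOGUE_ORDER = {name: i for i, name in enumerate(FEATURE_CATALOGUE)}

# Fixed per-class feature sets used in "paper" evaluation mode, one set per
# DNA-form class (SS, duplex subclasses I-III by binding-site percentage,
# miscellaneous).
PAPER_FEATURE_SETS: dict[str, list[str]] = {
    "SS": [
        "sheet_mass",
        "sheet_segment_count",
        nn_feature_name("GA/CT"),
        nn_feature_name("GC/CG"),
    ],
    "DOUBLE_I": ["polar_pct", "xix_count", "xix_pct"],
    "DOUBLE_II": [
        "helix_mass",
        "hydrophilic_count",
        nn_feature_name("AA/TT"),
        nn_feature_name("CA/GT"),
    ],
    "DOUBLE_III": [
        nn_feature_name("AA/TT"),
        nn_feature_name("CA/GT"),
        nn_feature_name("GA/CT"),
    ],
    "MISC": [
        "helix_mass",
        "helix_segment_count",
        "aromatic_positive_count",
        "hbond_count",
    ],
}
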