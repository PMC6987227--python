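"""Binding-site detection and DNA-form classification of complexes.

A protein residue is a binding-site residue when any of its atoms lies
within 5.0 Å of any DNA atom.  Complexes are classified by the fraction of
paired nucleotides (single-stranded / duplex / miscellaneous) and, for
duplexes, by the binding-site residue percentage into Double I (≤10%),
Double II (10-20%) and Double III (≥20%).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .structure import ComplexStructure

BINDING_CUTOFF = 5.0  # Å
SS_MAX_PAIRED_FRACTION = 0.2
DUPLEX_MIN_PAIRED_FRACTION = 0.6
DOUBLE_I_MAX_BINDING_PCT = 10.0
DOUBLE_III_MIN_BINDING_PCT = 20.0

CLASS_LABELS = ("SS", "DOUBLE_I", "DOUBLE_II", "DOUBLE_III", "MISC")


@dataclass
class BindingSiteResult:
    binding_residues: set[tuple[str, int, str]]
    binding_pct: float


@dataclass(frozen=True)
class ComplexClass:
    label: str
    paired_fraction: float
    binding_pct: float


def find_binding_residues(
    cs: ComplexStructure, cutoff: float = BINDING_CUTOFF
) -> BindingSiteResult:
    """Protein residues with any atom within ``cutoff`` Å (inclusive) of any
    DNA atom, plus their percentage of all protein residues."""
    dna_coords = cs.dna_atom_coords()
    residues = list(cs.protein_residues())
    total = len(residues)
    if dna_coords.shape[0] == 0 or total == 0:
        return BindingSiteResult(set(), 0.0)
    tree = cKDTree(dna_coords)
    binding: set[tuple[str, int, str]] = set()
    for res in residues:
        if not res.atoms:
            continue
        coords = np.vstack([a.coords for a in res.atoms])
        d, _ = tree.query(coords, k=1)
        if float(np.min(d)) <= cutoff:
            binding.add(res.id)
    return BindingSiteResult(binding, 100.0 * len(binding) / total)


def assign_class(
    paired_fraction: float,
    binding_pct: float,
    ss_max_pf: float = SS_MAX_PAIRED_FRACTION,
    duplex_min_pf: float = DUPLEX_MIN_PAIRED_FRACTION,
    double1_max: float = DOUBLE_I_MAX_BINDING_PCT,
    double3_min: float = DOUBLE_III_MIN_BINDING_PCT,
) -> ComplexClass:
    """Classify by paired fraction, then by binding-site percentage.

    paired_fraction ≤ 0.2 -> SS; ≥ 0.6 -> duplex, split into DOUBLE_I
    (binding_pct ≤ 10), DOUBLE_III (≥ 20) and DOUBLE_II between; the band
    in between is MISC.  Both boundary percentages use the closed rules
    (exactly 10 -> DOUBLE_I, exactly 20 -> DOUBLE_III).
    """
    if not 0.0 <= paired_fraction <= 1.0:
        raise ValueError(f"paired_fraction {paired_fraction} outside [0, 1]")
    if not 0.0 <= binding_pct <= 100.0:
        raise ValueError(f"binding_pct {binding_pct} outside [0, 100]")
    if paired_fraction <= ss_max_pf:
        label = "SS"
    elif paired_fraction >= duplex_min_pf:
        if binding_pct <= double1_max:
            label = "DOUBLE_I"
        elif binding_pct >= double3_min:
            label = "DOUBLE_III"
        else:
            label = "DOUBLE_II"
    else:
        label = "MISC"
    return ComplexClass(label, paired_fraction, binding_pct)


def classify_complex(
    cs: ComplexStructure, cutoff: float = BINDING_CUTOFF, **thresholds
) -> ComplexClass:
    """End-to-end classification of a parsed complex."""
    from .dna import detect_wc_pairs

    _, paired_fraction = detect_wc_pairs(cs)
    site = find_binding_residues(cs, cutoff)
    return assign_class(paired_fraction, site.binding_pct, **thresholds)
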