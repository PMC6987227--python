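"""DNA sequential and structural features.

Sequential features: molecular mass from the nucleotide count (single-strand
or duplex closed form) and nearest-neighbor dinucleotide class counts, where
the 16 dinucleotide steps collapse to 10 classes under reverse-complement
equivalence.

Structural features: geometric Watson-Crick base-pair detection (Saenger
family XIX for G·C, XX for A·T) from purine-N1/pyrimidine-N3 and C1'-C1'
distances, plus an adapter for externally computed folding features
(ensemble diversity and MFE-structure frequency).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np

from .catalogue import NN_LABELS, nn_feature_name
from .structure import ComplexStructure, Residue

logger = logging.getLogger(__name__)

# ssDNA: per-nucleotide average base mass + terminal correction.
SS_BASE_MASS = 303.7
SS_OFFSET = 79.0
# dsDNA: per-base-pair average mass + terminal correction.
DS_PAIR_MASS = 607.4
DS_OFFSET = 157.9

SS_FORM = "SS_FORM"
DUPLEX_FORM = "DUPLEX_FORM"

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}

# Default geometric thresholds for Watson-Crick pair detection, from
# canonical B-DNA geometry (hydrogen-bonded N1···N3 ≈ 2.8-2.9 Å; glycosidic
# C1'···C1' ≈ 10.4 Å).
N1N3_RANGE = (2.4, 3.5)
C1C1_RANGE = (9.0, 11.5)


def revcomp(seq: str) -> str:
    try:
        return "".join(_COMPLEMENT[c] for c in reversed(seq))
    except KeyError as exc:
        raise ValueError(f"non-ACGT base {exc.args[0]!r}") from None


# Steps whose 5'->3' top strand names a class directly.
_CLASS_BY_TOP = {label.split("/")[0]: label for label in NN_LABELS}


def nn_class_of(step: str) -> str:
    """Nearest-neighbor class label of a dinucleotide step.

    A step and its reverse complement describe the same duplex stack, so the
    16 steps collapse to the 10 classes in :data:`~predba.catalogue.NN_LABELS`.
    """
    if len(step) != 2:
        raise ValueError(f"dinucleotide step expected, got {step!r}")
    step = step.upper()
    if any(c not in _COMPLEMENT for c in step):
        raise ValueError(f"non-ACGT base in step {step!r}")
    if step in _CLASS_BY_TOP:
        return _CLASS_BY_TOP[step]
    return _CLASS_BY_TOP[revcomp(step)]


def nn_counts(sequences: list[str]) -> tuple[dict[str, int], dict[str, float]]:
    """Class counts and percentages over every adjacent step of every strand.

    All strands contribute (a duplex contributes both of its strands); the
    percentage denominator is the total number of steps.
    """
    counts = {label: 0 for label in NN_LABELS}
    total = 0
    for seq in sequences:
        for i in range(len(seq) - 1):
            counts[nn_class_of(seq[i : i + 2])] += 1
            total += 1
    if total:
        pcts = {label: 100.0 * c / total for label, c in counts.items()}
    else:
        pcts = {label: 0.0 for label in NN_LABELS}
    return counts, pcts


def dna_mass(nucleotide_count: int, form: str) -> float:
    """DNA molecular mass (Da) from the nucleotide count.

    Single-strand: count * 303.7 + 79.0.  Duplex: pairs * 607.4 + 157.9 with
    pairs = round(count / 2) (607.4 is the average mass of one base pair).
    """
    if nucleotide_count < 1:
        raise ValueError("nucleotide_count must be >= 1")
    if form == SS_FORM:
        return nucleotide_count * SS_BASE_MASS + SS_OFFSET
    if form == DUPLEX_FORM:
        pairs = round(nucleotide_count / 2)
        return pairs * DS_PAIR_MASS + DS_OFFSET
    raise ValueError(f"unknown DNA form {form!r}")


@dataclass(frozen=True)
class BasePair:
    res_a: tuple[str, int, str]  # purine residue id
    res_b: tuple[str, int, str]  # pyrimidine residue id
    pair_type: str  # "XIX" (G·C) or "XX" (A·T)
    n1n3_dist: float
    c1c1_dist: float


def _wc_atoms(res: Residue) -> tuple[str, np.ndarray, np.ndarray] | None:
    """(base, WC-edge N coords, C1' coords) or None if atoms are missing."""
    base = res.base
    if base is None:
        return None
    n_name = "N1" if base in PURINES else "N3"
    n_atom = res.atom(n_name)
    c1_atom = res.atom("C1'")
    if n_atom is None or c1_atom is None:
        logger.warning(
            "nucleotide %s%s (%s): missing %s or C1', excluded from pairing",
            res.chain_id, res.seq_number, res.res_name, n_name,
        )
        return None
    return base, n_atom.coords, c1_atom.coords


def detect_wc_pairs(
    cs: ComplexStructure,
    n1n3_range: tuple[float, float] = N1N3_RANGE,
    c1c1_range: tuple[float, float] = C1C1_RANGE,
) -> tuple[list[BasePair], float]:
    """Watson-Crick pairs and the paired fraction of nucleotides.

    Candidates are complementary purine/pyrimidine nucleotides whose
    purine-N1 to pyrimidine-N3 distance and C1'-C1' distance fall in the
    given windows; they are matched greedily in ascending N1-N3 distance so
    each nucleotide joins at most one pair.  G·C pairs are Saenger family
    XIX, A·T pairs family XX.  paired_fraction = 2*pairs / total nucleotides.
    """
    nucleotides = list(cs.dna_residues())
    total = len(nucleotides)
    entries = []
    for res in nucleotides:
        wc = _wc_atoms(res)
        if wc is not None:
            entries.append((res, *wc))

    candidates = []
    for i in range(len(entries)):
        res_i, base_i, n_i, c1_i = entries[i]
        if base_i not in PURINES:
            continue
        for j in range(len(entries)):
            res_j, base_j, n_j, c1_j = entries[j]
            if base_j not in PYRIMIDINES:
                continue
            if _COMPLEMENT[base_i] != base_j:
                continue
            d_n = float(np.linalg.norm(n_i - n_j))
            d_c1 = float(np.linalg.norm(c1_i - c1_j))
            if n1n3_range[0] <= d_n <= n1n3_range[1] and (
                c1c1_range[0] <= d_c1 <= c1c1_range[1]
            ):
                candidates.append((d_n, d_c1, res_i, res_j))

    # Greedy matching, ascending N1-N3 distance; residue ids break ties so
    # the result is deterministic.
    candidates.sort(key=lambda t: (t[0], t[2].id, t[3].id))
    used: set[tuple] = set()
    pairs: list[BasePair] = []
    for d_n, d_c1, res_i, res_j in candidates:
        if res_i.id in used or res_j.id in used:
            continue
        used.add(res_i.id)
        used.add(res_j.id)
        pair_type = "XIX" if res_i.base == "G" else "XX"
        pairs.append(BasePair(res_i.id, res_j.id, pair_type, d_n, d_c1))

    paired_fraction = (2.0 * len(pairs) / total) if total else 0.0
    return pairs, paired_fraction


def base_pair_stats(pairs: list[BasePair], total_nucleotides: int) -> dict[str, float]:
    """XIX/XX counts and percentages (denominator: total nucleotides), plus
    the combined cis-WC/WC pair count."""
    xix = sum(1 for p in pairs if p.pair_type == "XIX")
    xx = sum(1 for p in pairs if p.pair_type == "XX")
    denom = total_nucleotides or 1
    return {
        "xix_count": xix,
        "xix_pct": 100.0 * xix / denom,
        "xx_count": xx,
        "xx_pct": 100.0 * xx / denom,
        "cww_pair_count": xix + xx,
        "bp_total_count": len(pairs),
    }


_FOLDING_RE = re.compile(
    r"frequency of mfe structure in ensemble\s+([0-9.eE+-]+);\s*"
    r"ensemble diversity\s+([0-9.eE+-]+)"
)


def parse_folding_features(text: str) -> tuple[float, float]:
    """(ensemble_diversity, mfe_frequency) from RNAfold ``-p`` output text."""
    m = _FOLDING_RE.search(text)
    if m is None:
        raise ValueError(
            "folding output: 'frequency of mfe structure in ensemble ...; "
            "ensemble diversity ...' line not found"
        )
    mfe_frequency = float(m.group(1))
    ensemble_diversity = float(m.group(2))
    return ensemble_diversity, mfe_frequency


def dna_feature_block(
    cs: ComplexStructure,
    folding_text: str | None = None,
    duplex_min_paired_fraction: float = 0.6,
    n1n3_range: tuple[float, float] = N1N3_RANGE,
    c1c1_range: tuple[float, float] = C1C1_RANGE,
) -> dict[str, float]:
    """All 31 DNA features (sequential + structural) for one complex.

    The mass formula switches to the duplex form when the detected paired
    fraction reaches ``duplex_min_paired_fraction``.  Folding features are
    NaN (missing) unless adapter text is supplied.
    """
    from .structure import dna_sequence

    seqs = dna_sequence(cs)
    total = sum(len(s) for s in seqs)
    pairs, paired_fraction = detect_wc_pairs(cs, n1n3_range, c1c1_range)

    out: dict[str, float] = {}
    form = DUPLEX_FORM if paired_fraction >= duplex_min_paired_fraction else SS_FORM
    out["dna_mass"] = dna_mass(total, form)
    out["nucleotide_count"] = total
    counts, pcts = nn_counts(seqs)
    for label in NN_LABELS:
        out[nn_feature_name(label)] = counts[label]
        out[nn_feature_name(label, pct=True)] = pcts[label]
    if folding_text is not None:
        diversity, freq = parse_folding_features(folding_text)
        out["ensemble_diversity"] = diversity
        out["mfe_frequency"] = freq
    else:
        out["ensemble_diversity"] = float("nan")
        out["mfe_frequency"] = float("nan")
    out.update(base_pair_stats(pairs, total))
    out["paired_fraction"] = paired_fraction
    return out
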