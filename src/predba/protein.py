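"""Protein sequential and structural features.

Sequential features are computed from the one-letter sequence: molecular
mass (average residue masses plus one water per chain), counts and
percentages of five physico-chemical residue classes, and the number of
backbone hydrogen bonds under the Kabsch-Sander electrostatic model.

Structural features come from header HELIX/SHEET annotations (or an optional
DSSP-output adapter): segment and residue counts, residue percentages, the
mass of helix and sheet residues, and the total solvent-accessible surface
area from a Shrake-Rupley quadrature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structure import (
    AMINO3_TO_1,
    ComplexStructure,
    Residue,
    SegmentAnnotation,
    SegmentKind,
)

logger = logging.getLogger(__name__)

# Average (not monoisotopic) residue masses, Da.
AVERAGE_RESIDUE_MASS = {
    "A": 71.08, "R": 156.19, "N": 114.10, "D": 115.09, "C": 103.14,
    "E": 129.12, "Q": 128.13, "G": 57.05, "H": 137.14, "I": 113.16,
    "L": 113.16, "K": 128.17, "M": 131.19, "F": 147.18, "P": 97.12,
    "S": 87.08, "T": 101.10, "W": 186.21, "Y": 163.18, "V": 99.13,
}
WATER_MASS = 18.02
UNKNOWN_RESIDUE_MASS = 110.0  # mean residue mass, used for X

VDW_RADII = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80, "H": 1.20,
}
DEFAULT_VDW_RADIUS = 1.70

# Kabsch-Sander electrostatic hydrogen-bond model constants.
KS_COUPLING = 0.084 * 332.0  # kcal/mol * Å
KS_ENERGY_CUTOFF = -0.5  # kcal/mol
NH_BOND_LENGTH = 1.0  # Å, reconstructed amide hydrogen


@dataclass(frozen=True)
class ResidueClassTable:
    """Physico-chemical residue classes (one-letter codes).

    hydrophobic/hydrophilic partition the 20 standard residues; the other
    three classes may overlap them and each other.
    """

    hydrophobic: frozenset[str] = frozenset("AVLIMFWCPG")
    hydrophilic: frozenset[str] = frozenset("RNDQEHKSTY")
    aromatic_positive: frozenset[str] = frozenset("FWYHRK")
    polar: frozenset[str] = frozenset("STNQCY")
    charged: frozenset[str] = frozenset("DEKRH")

    def __post_init__(self):
        twenty = frozenset(AMINO3_TO_1.values())
        if self.hydrophobic | self.hydrophilic != twenty:
            raise ValueError("hydrophobic ∪ hydrophilic must be the 20 codes")
        if self.hydrophobic & self.hydrophilic:
            raise ValueError("hydrophobic ∩ hydrophilic must be empty")


DEFAULT_CLASS_TABLE = ResidueClassTable()

CLASS_NAMES = ("hydrophilic", "hydrophobic", "aromatic_positive", "polar", "charged")


def residue_class_counts(
    seq: str, table: ResidueClassTable = DEFAULT_CLASS_TABLE
) -> dict[str, tuple[int, float]]:
    """Count and percentage of each residue class in ``seq``.

    ``X`` (nonstandard) positions belong to no class but do count toward the
    sequence length used for percentages.
    """
    if not seq:
        raise ValueError("empty protein sequence")
    n = len(seq)
    out = {}
    for name in CLASS_NAMES:
        members = getattr(table, name)
        count = sum(1 for c in seq if c in members)
        out[name] = (count, 100.0 * count / n)
    return out


def protein_mass(seq: str) -> float:
    """Average molecular mass of one chain, Da (one water per chain)."""
    if not seq:
        raise ValueError("empty protein sequence")
    total = WATER_MASS
    for c in seq:
        total += AVERAGE_RESIDUE_MASS.get(c, UNKNOWN_RESIDUE_MASS)
    return total


def _residue_mass_3letter(res_name: str) -> float:
    one = AMINO3_TO_1.get(res_name)
    if one is None:
        return UNKNOWN_RESIDUE_MASS
    return AVERAGE_RESIDUE_MASS[one]


def kabsch_sander_energy(
    n: np.ndarray, h: np.ndarray, c: np.ndarray, o: np.ndarray
) -> float:
    """Electrostatic H-bond energy (kcal/mol) between a donor N-H and an
    acceptor C=O: E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)."""
    r_on = np.linalg.norm(o - n)
    r_ch = np.linalg.norm(c - h)
    r_oh = np.linalg.norm(o - h)
    r_cn = np.linalg.norm(c - n)
    return KS_COUPLING * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)


def _backbone(res: Residue) -> dict[str, np.ndarray] | None:
    atoms = {}
    for name in ("N", "CA", "C", "O"):
        a = res.atom(name)
        if a is None:
            return None
        atoms[name] = a.coords
    return atoms


def count_hydrogen_bonds(
    cs: ComplexStructure, energy_cutoff: float = KS_ENERGY_CUTOFF
) -> int:
    """Backbone-backbone hydrogen bonds in the protein, Kabsch-Sander model.

    The amide hydrogen is reconstructed 1.0 Å from N, opposite the preceding
    residue's carbonyl O->C direction.  Chain-first residues and prolines are
    not donors; pairs closer than two positions along the same chain are
    excluded (the donor's H is built from the peptide bond to i-1).  Each
    (donor, acceptor) pair is counted once.
    """
    entries = []  # (chain_index, pos, backbone, h_coords or None, is_pro)
    for ci, chain in enumerate(cs.protein_chains):
        prev_bb = None
        for pos, res in enumerate(chain):
            bb = _backbone(res)
            if bb is None:
                logger.warning(
                    "%s %s%s: missing backbone atom, skipped in H-bond count",
                    cs.complex_id, res.chain_id, res.seq_number,
                )
                prev_bb = None
                continue
            h = None
            if prev_bb is not None and res.res_name != "PRO":
                direction = prev_bb["C"] - prev_bb["O"]
                norm = np.linalg.norm(direction)
                if norm > 0:
                    h = bb["N"] + NH_BOND_LENGTH * direction / norm
            entries.append((ci, pos, bb, h))
            prev_bb = bb

    if len(entries) < 2:
        return 0

    ca = np.vstack([e[2]["CA"] for e in entries])
    tree = cKDTree(ca)
    count = 0
    for i, j in tree.query_pairs(r=9.0):
        for di, ai in ((i, j), (j, i)):
            ci_d, pos_d, bb_d, h_d = entries[di]
            ci_a, pos_a, bb_a, _ = entries[ai]
            if h_d is None:
                continue
            if ci_d == ci_a and abs(pos_d - pos_a) <= 1:
                continue
            e = kabsch_sander_energy(bb_d["N"], h_d, bb_a["C"], bb_a["O"])
            if e < energy_cutoff:
                count += 1
    return count


def _clip_segment_residues(
    seg: SegmentAnnotation, cs: ComplexStructure
) -> list[Residue]:
    found = []
    for chain in cs.protein_chains:
        if chain.chain_id != seg.chain_id:
            continue
        for res in chain:
            if seg.start_seq <= res.seq_number <= seg.end_seq:
                found.append(res)
    span = seg.end_seq - seg.start_seq + 1
    if len(found) < span:
        logger.warning(
            "%s: %s segment %s %d-%d clipped to %d existing residues",
            cs.complex_id, seg.kind.value, seg.chain_id,
            seg.start_seq, seg.end_seq, len(found),
        )
    return found


def secondary_structure_stats(
    cs: ComplexStructure,
    helix_segments: list[SegmentAnnotation] | None = None,
    sheet_segments: list[SegmentAnnotation] | None = None,
) -> dict[str, float]:
    """Helix/sheet segment counts, residue counts and percentages, masses.

    By default uses the structure's header annotations; pass explicit segment
    lists (e.g. from :func:`read_dssp`) to override.  Masses are sums of
    average residue masses over the annotated residues (no water term);
    percentages are relative to the total protein residue count.
    """
    helices = cs.helix_segments if helix_segments is None else helix_segments
    sheets = cs.sheet_segments if sheet_segments is None else sheet_segments
    total = sum(len(ch) for ch in cs.protein_chains)

    out: dict[str, float] = {}
    for prefix, segments in (("helix", helices), ("sheet", sheets)):
        residues: dict[tuple, Residue] = {}
        for seg in segments:
            for res in _clip_segment_residues(seg, cs):
                residues[res.id] = res
        n_res = len(residues)
        out[f"{prefix}_segment_count"] = len(segments)
        out[f"{prefix}_residue_count"] = n_res
        out[f"{prefix}_residue_pct"] = 100.0 * n_res / total if total else 0.0
        out[f"{prefix}_mass"] = sum(
            _residue_mass_3letter(r.res_name) for r in residues.values()
        )
    return out


# DSSP one-letter states mapped onto the two families we track.
_DSSP_HELIX = {"H", "G", "I"}
_DSSP_SHEET = {"E", "B"}


def read_dssp(text: str) -> tuple[list[SegmentAnnotation], list[SegmentAnnotation]]:
    """Adapter for classic fixed-column DSSP output.

    Returns (helix_segments, sheet_segments) built from contiguous runs of
    helix (H/G/I) and strand (E/B) states in column 17.
    """
    lines = text.splitlines()
    start = None
    for i, line in enumerate(lines):
        if line.lstrip().startswith("#  RESIDUE"):
            start = i + 1
            break
    if start is None:
        raise ValueError("not a DSSP file: residue table header not found")

    helix: list[SegmentAnnotation] = []
    sheet: list[SegmentAnnotation] = []
    run: tuple[str, str, int, int] | None = None  # (family, chain, start, end)

    def flush():
        nonlocal run
        if run is None:
            return
        family, chain, s, e = run
        seg = SegmentAnnotation(
            SegmentKind.HELIX if family == "helix" else SegmentKind.SHEET,
            chain, s, e,
        )
        (helix if family == "helix" else sheet).append(seg)
        run = None

    for line in lines[start:]:
        if len(line) < 17 or line[13] == "!":  # chain break marker
            flush()
            continue
        try:
            seq = int(line[5:10])
        except ValueError:
            flush()
            continue
        chain = line[11].strip()
        ss = line[16]
        family = (
            "helix" if ss in _DSSP_HELIX else "sheet" if ss in _DSSP_SHEET else None
        )
        if family is None:
            flush()
            continue
        if run is not None and run[0] == family and run[1] == chain and seq == run[3] + 1:
            run = (family, chain, run[2], seq)
        else:
            flush()
            run = (family, chain, seq, seq)
    flush()
    return helix, sheet


def golden_spiral_points(n: int) -> np.ndarray:
    """n quasi-uniform unit-sphere points (deterministic golden-spiral)."""
    i = np.arange(n)
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def sasa_from_atoms(
    coords: np.ndarray,
    elements: list[str],
    probe: float = 1.4,
    n_points: int = 960,
) -> np.ndarray:
    """Per-atom Shrake-Rupley solvent-accessible surface areas (Å²)."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[0] == 0:
        raise ValueError("need at least one atom")
    radii = np.empty(len(elements))
    for k, el in enumerate(elements):
        r = VDW_RADII.get(el.upper())
        if r is None:
            logger.warning("unknown element %r: default vdW radius used", el)
            r = DEFAULT_VDW_RADIUS
        radii[k] = r
    expanded = radii + probe
    sphere = golden_spiral_points(n_points)
    tree = cKDTree(coords)
    max_reach = expanded.max()
    areas = np.empty(len(coords))
    for k in range(len(coords)):
        pts = coords[k] + expanded[k] * sphere
        neighbors = [
            j for j in tree.query_ball_point(coords[k], expanded[k] + max_reach)
            if j != k
        ]
        if neighbors:
            nb = np.asarray(neighbors)
            d2 = ((pts[:, None, :] - coords[nb][None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (expanded[nb] ** 2)[None, :]).any(axis=1)
            exposed = int((~buried).sum())
        else:
            exposed = n_points
        areas[k] = 4.0 * np.pi * expanded[k] ** 2 * exposed / n_points
    return areas


def shrake_rupley_sasa(
    cs: ComplexStructure, probe: float = 1.4, n_points: int = 960
) -> float:
    """Total solvent-accessible surface area of the protein component, Å²."""
    atoms = [a for r in cs.protein_residues() for a in r.atoms]
    if not atoms:
        raise ValueError("no protein atoms")
    coords = np.vstack([a.coords for a in atoms])
    elements = [a.element for a in atoms]
    return float(sasa_from_atoms(coords, elements, probe, n_points).sum())


@dataclass
class ProteinFeatureBlock:
    """The 21 protein features keyed by catalogue name."""

    values: dict[str, float] = field(default_factory=dict)


def protein_feature_block(
    cs: ComplexStructure,
    class_table: ResidueClassTable = DEFAULT_CLASS_TABLE,
    sasa_points: int = 960,
) -> dict[str, float]:
    """All 21 protein features (sequential + structural) for one complex.

    Multi-chain proteins are treated as the concatenation of their chains;
    the mass includes one water term per chain.
    """
    from .structure import protein_sequence

    seqs = protein_sequence(cs)
    full = "".join(seqs)
    out: dict[str, float] = {}
    out["protein_mass"] = sum(protein_mass(s) for s in seqs if s)
    out["hbond_count"] = count_hydrogen_bonds(cs)
    for name, (count, pct) in residue_class_counts(full, class_table).items():
        out[f"{name}_count"] = count
        out[f"{name}_pct"] = pct
    out.update(secondary_structure_stats(cs))
    out["total_sasa"] = shrake_rupley_sasa(cs, n_points=sasa_points)
    return out
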