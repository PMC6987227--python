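import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from predba.protein import (
    DEFAULT_CLASS_TABLE,
    count_hydrogen_bonds,
    golden_spiral_points,
    kabsch_sander_energy,
    protein_mass,
    read_dssp,
    residue_class_counts,
    sasa_from_atoms,
    secondary_structure_stats,
    shrake_rupley_sasa,
)
from predba.structure import (
    Atom,
    Chain,
    ComplexStructure,
    Residue,
    ResidueKind,
    SegmentAnnotation,
    SegmentKind,
    parse_pdb,
)
from predba.synthetic import (
    EXTENDED_PHI,
    EXTENDED_PSI,
    HELIX_PHI,
    HELIX_PSI,
    ToyComplexSpec,
    build_backbone,
    make_toy_complex,
)

AMINO20 = "ACDEFGHIKLMNPQRSTVWY"


# --- residue classes -------------------------------------------------------

@pytest.mark.parametrize(
    "seq,cls,count,pct",
    [
        ("KKKK", "charged", 4, 100.0),
        ("KKKK", "hydrophobic", 0, 0.0),
        ("AAAA", "hydrophobic", 4, 100.0),
        ("AAAA", "polar", 0, 0.0),
        ("AAAA", "charged", 0, 0.0),
        ("AK", "hydrophilic", 1, 50.0),
    ],
)
def test_residue_class_examples(seq, cls, count, pct):
    result = residue_class_counts(seq)
    assert result[cls] == (count, pytest.approx(pct))


def test_empty_sequence_rejected():
    with pytest.raises(ValueError):
        residue_class_counts("")
    with pytest.raises(ValueError):
        protein_mass("")


@settings(derandomize=True, deadline=None)
@given(st.text(alphabet=AMINO20 + "X", min_size=1, max_size=80))
def test_hydrophobicity_partitions_standard_residues(seq):
    result = residue_class_counts(seq)
    n_standard = sum(1 for c in seq if c != "X")
    assert result["hydrophobic"][0] + result["hydrophilic"][0] == n_standard
    assert all(0.0 <= pct <= 100.0 for _, pct in result.values())


def test_class_tables_cover_twenty_codes():
    t = DEFAULT_CLASS_TABLE
    assert t.hydrophobic | t.hydrophilic == frozenset(AMINO20)
    assert not (t.hydrophobic & t.hydrophilic)


# --- masses ----------------------------------------------------------------

def test_protein_mass_hand_sums():
    assert protein_mass("G") == pytest.approx(75.07)
    assert protein_mass("GG") == pytest.approx(132.12)
    # X contributes the mean residue mass
    assert protein_mass("X") == pytest.approx(110.0 + 18.02)


# --- hydrogen bonds --------------------------------------------------------

def _protein_only_cs(backbone, names=None):
    residues = []
    for i, bb in enumerate(backbone):
        residues.append(
            Residue(
                "A", i + 1, "", (names or ["ALA"] * len(backbone))[i],
                [Atom(n, n[0], bb[n]) for n in ("N", "CA", "C", "O")],
                ResidueKind.AMINO_ACID,
            )
        )
    dna = Residue(
        "B", 1, "", "DA",
        [Atom("C1'", "C", np.array([500.0, 0, 0]))], ResidueKind.NUCLEOTIDE,
    )
    return ComplexStructure("hb", [Chain("A", residues)], [Chain("B", [dna])])


def _ks_oracle(backbone):
    """Direct evaluation of the electrostatic model on the coordinates."""
    count = 0
    for i in range(1, len(backbone)):
        d = backbone[i - 1]["C"] - backbone[i - 1]["O"]
        h = backbone[i]["N"] + d / np.linalg.norm(d)
        for j in range(len(backbone)):
            if abs(i - j) <= 1:
                continue
            e = kabsch_sander_energy(
                backbone[i]["N"], h, backbone[j]["C"], backbone[j]["O"]
            )
            if e < -0.5:
                count += 1
    return count


def test_ideal_helix_bond_count_matches_direct_evaluation():
    bb = build_backbone([(HELIX_PHI, HELIX_PSI)] * 12)
    cs = _protein_only_cs(bb)
    expected = _ks_oracle(bb)
    assert expected >= 8  # every i -> i+4 donor pair present
    # each i,i+4 pair individually satisfies the energy criterion
    for i in range(4 + 1, 12):
        d = bb[i - 1]["C"] - bb[i - 1]["O"]
        h = bb[i]["N"] + d / np.linalg.norm(d)
        e = kabsch_sander_energy(bb[i]["N"], h, bb[i - 4]["C"], bb[i - 4]["O"])
        assert e < -0.5
    assert count_hydrogen_bonds(cs) == expected


def test_extended_strand_matches_direct_evaluation():
    bb = build_backbone([(EXTENDED_PHI, EXTENDED_PSI)] * 10)
    assert count_hydrogen_bonds(_protein_only_cs(bb)) == _ks_oracle(bb)


def test_far_apart_residues_no_bonds():
    bb = build_backbone([(EXTENDED_PHI, EXTENDED_PSI)] * 2)
    far = {k: v + np.array([300.0, 0, 0]) for k, v in bb[1].items()}
    assert count_hydrogen_bonds(_protein_only_cs([bb[0], far])) == 0


def test_single_residue_no_bonds():
    bb = build_backbone([(HELIX_PHI, HELIX_PSI)])
    assert count_hydrogen_bonds(_protein_only_cs(bb)) == 0


def test_proline_is_not_a_donor():
    bb = build_backbone([(HELIX_PHI, HELIX_PSI)] * 12)
    all_pro = _protein_only_cs(bb, names=["PRO"] * 12)
    assert count_hydrogen_bonds(all_pro) == 0


# --- secondary structure ---------------------------------------------------

def test_header_helix_stats():
    spec = ToyComplexSpec(n_protein_res=10, helix_span=(2, 4), n_bp=4, seed=1)
    pdb_text, _ = make_toy_complex(spec)
    cs = parse_pdb(pdb_text)
    stats = secondary_structure_stats(cs)
    assert stats["helix_segment_count"] == 1
    assert stats["helix_residue_count"] == 3
    assert stats["helix_residue_pct"] == pytest.approx(30.0)
    assert stats["sheet_segment_count"] == 0
    assert stats["sheet_mass"] == 0.0


def test_no_annotations_all_zero():
    spec = ToyComplexSpec(n_protein_res=6, n_bp=4, seed=2)
    pdb_text, _ = make_toy_complex(spec)
    cs = parse_pdb(pdb_text)
    stats = secondary_structure_stats(cs)
    assert all(
        stats[k] == 0
        for k in (
            "helix_segment_count", "helix_residue_count", "sheet_segment_count",
            "sheet_residue_count", "helix_mass", "sheet_mass",
        )
    )


def test_helix_mass_of_three_glycines():
    bb = build_backbone([(HELIX_PHI, HELIX_PSI)] * 5)
    cs = _protein_only_cs(bb, names=["GLY"] * 5)
    cs.helix_segments = [SegmentAnnotation(SegmentKind.HELIX, "A", 2, 4)]
    stats = secondary_structure_stats(cs)
    assert stats["helix_mass"] == pytest.approx(3 * 57.05)


def test_segment_clipped_to_existing_residues():
    bb = build_backbone([(HELIX_PHI, HELIX_PSI)] * 4)
    cs = _protein_only_cs(bb)
    cs.helix_segments = [SegmentAnnotation(SegmentKind.HELIX, "A", 3, 9)]
    stats = secondary_structure_stats(cs)
    assert stats["helix_residue_count"] == 2  # residues 3 and 4 exist
    helix = stats["helix_residue_count"]
    sheet = stats["sheet_residue_count"]
    assert helix + sheet <= 4


def test_dssp_adapter_segments():
    header = "  #  RESIDUE AA STRUCTURE BP1 BP2  ACC"
    rows = [
        "    1    1 A M              0   0  200",
        "    2    2 A K  H            0   0  100",
        "    3    3 A L  H            0   0  100",
        "    4    4 A V  E            0   0   50",
        "    5    5 A I  E            0   0   50",
    ]
    helix, sheet = read_dssp("\n".join(["junk", header] + rows))
    assert [(s.chain_id, s.start_seq, s.end_seq) for s in helix] == [("A", 2, 3)]
    assert [(s.chain_id, s.start_seq, s.end_seq) for s in sheet] == [("A", 4, 5)]


def test_dssp_adapter_rejects_non_dssp():
    with pytest.raises(ValueError):
        read_dssp("not a dssp file")


# --- SASA ------------------------------------------------------------------

def test_isolated_carbon_matches_analytic_sphere():
    area = sasa_from_atoms(np.zeros((1, 3)), ["C"]).sum()
    analytic = 4 * np.pi * (1.70 + 1.4) ** 2
    assert area == pytest.approx(analytic, rel=0.02)


def test_disjoint_spheres_are_additive():
    one = sasa_from_atoms(np.zeros((1, 3)), ["C"]).sum()
    two = sasa_from_atoms(np.array([[0.0, 0, 0], [100.0, 0, 0]]), ["C", "C"]).sum()
    assert two == pytest.approx(2 * one, rel=1e-12)


def test_fully_enclosed_atom_has_zero_sasa():
    # 60 surrounding carbons at 2.0 Å bury the central atom completely;
    # verified with a brute-force point test at 10000 quadrature points.
    shell = 2.0 * golden_spiral_points(60)
    coords = np.vstack([[0.0, 0.0, 0.0], shell])
    elements = ["C"] * 61
    areas = sasa_from_atoms(coords, elements, n_points=10000)
    # brute force: every central-sphere point inside some neighbor sphere
    pts = (1.70 + 1.4) * golden_spiral_points(10000)
    d = np.linalg.norm(pts[:, None, :] - shell[None, :, :], axis=2)
    assert (d.min(axis=1) < 1.70 + 1.4).all()
    assert areas[0] == 0.0


def test_sasa_monotone_under_approach():
    # A second atom approaching from infinity never increases the first
    # atom's exposed area.
    prev = np.inf
    for dist in np.linspace(20.0, 1.0, 20):
        areas = sasa_from_atoms(
            np.array([[0.0, 0, 0], [dist, 0, 0]]), ["C", "C"]
        )
        assert areas[0] <= prev + 1e-9
        prev = areas[0]


def test_unknown_element_gets_default_radius():
    area = sasa_from_atoms(np.zeros((1, 3)), ["Zz"]).sum()
    assert area == pytest.approx(4 * np.pi * (1.70 + 1.4) ** 2, rel=0.02)


def test_structure_level_sasa_uses_protein_atoms_only():
    bb = build_backbone([(EXTENDED_PHI, EXTENDED_PSI)] * 3)
    cs = _protein_only_cs(bb)
    total = shrake_rupley_sasa(cs)
    coords = np.vstack([a.coords for r in cs.protein_residues() for a in r.atoms])
    elements = [a.element for r in cs.protein_residues() for a in r.atoms]
    assert total == pytest.approx(sasa_from_atoms(coords, elements).sum())
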