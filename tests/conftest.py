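import numpy as np
import pytest

from predba.structure import (
    Atom,
    Chain,
    ComplexStructure,
    Residue,
    ResidueKind,
)

SIMPLE_PDB = """\
HELIX    1   1 ALA A    2  ALA A    3  1                                    2
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  CA  ALA A   2      10.900   6.450  -2.000  1.00  0.00           C
ATOM      4  CA  ALA A   3      10.100   6.450  -1.000  1.00  0.00           C
TER
ATOM      5  P    DA B   1       1.000   2.000   3.000  1.00  0.00           P
ATOM      6  C1'  DA B   1       2.500   2.000   3.000  1.00  0.00           C
ATOM      7  N1   DA B   1       4.000   2.000   3.000  1.00  0.00           N
ATOM      8  P    DA B   2       1.000   2.000   6.400  1.00  0.00           P
TER
HETATM    9  O   HOH C   1       9.000   9.000   9.000  1.00  0.00           O
END
"""


@pytest.fixture
def simple_pdb_text():
    return SIMPLE_PDB


def single_atom_residue(chain_id, seq, res_name, kind, atom_name, element, xyz):
    return Residue(
        chain_id=chain_id,
        seq_number=seq,
        insertion_code="",
        res_name=res_name,
        atoms=[Atom(atom_name, element, np.asarray(xyz, dtype=float))],
        kind=kind,
    )


def point_complex(protein_points, dna_points):
    """Minimal complex: one single-atom protein residue per protein point and
    one single-atom DNA residue per DNA point."""
    prot = [
        single_atom_residue("A", i + 1, "ALA", ResidueKind.AMINO_ACID, "CA", "C", p)
        for i, p in enumerate(protein_points)
    ]
    dna = [
        single_atom_residue("B", i + 1, "DA", ResidueKind.NUCLEOTIDE, "P", "P", p)
        for i, p in enumerate(dna_points)
    ]
    return ComplexStructure(
        complex_id="points",
        protein_chains=[Chain("A", prot)],
        dna_chains=[Chain("B", dna)],
    )
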