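"""Backbone hydrogen bonds and solvent-accessible surface area.

Builds an ideal 12-residue α-helix (φ = -57°, ψ = -47°) and shows that the
Kabsch-Sander electrostatic model finds the i -> i+4 hydrogen-bond ladder,
then computes the Shrake-Rupley SASA of the same backbone.
"""

import numpy as np

from predba import count_hydrogen_bonds, shrake_rupley_sasa
from predba.structure import Atom, Chain, ComplexStructure, Residue, ResidueKind
from predba.synthetic import HELIX_PHI, HELIX_PSI, build_backbone

backbone = build_backbone([(HELIX_PHI, HELIX_PSI)] * 12)
residues = [
    Residue("A", i + 1, "", "ALA",
            [Atom(n, n[0], bb[n]) for n in ("N", "CA", "C", "O")],
            ResidueKind.AMINO_ACID)
    for i, bb in enumerate(backbone)
]
# a token nucleotide far away so the container is a valid complex
dna = Residue("B", 1, "", "DA", [Atom("C1'", "C", np.array([500.0, 0.0, 0.0]))],
              ResidueKind.NUCLEOTIDE)
cs = ComplexStructure("helix", [Chain("A", residues)], [Chain("B", [dna])])

print(f"hydrogen bonds in a 12-residue ideal helix : {count_hydrogen_bonds(cs)}")
print(f"backbone SASA                              : {shrake_rupley_sasa(cs):.1f} A^2")
# An ideal α-helix hydrogen-bonds each backbone amide to the carbonyl four
# residues earlier; the SASA is the area a 1.4 Å water probe can touch.
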