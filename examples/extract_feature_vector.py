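"""Extract the 52-feature vector from a protein-DNA complex.

The catalogue covers protein sequential features (mass, hydrogen bonds,
residue-class counts), protein structural features (helix/sheet statistics,
SASA), DNA sequential features (mass, nearest-neighbor dinucleotide classes)
and DNA structural features (Watson-Crick pair statistics).
"""

from predba import extract_features, parse_pdb
from predba.synthetic import ToyComplexSpec, make_toy_complex

spec = ToyComplexSpec(
    n_protein_res=15, helix_span=(3, 9), n_bp=6, unpaired_tail=0,
    min_contact_dist=4.5, gc_fraction=0.5, seed=7,
)
pdb_text, _ = make_toy_complex(spec)
values = extract_features(parse_pdb(pdb_text, "example"))

print(f"{len(values)} features extracted; a selection:")
for name in (
    "protein_mass", "hbond_count", "helix_residue_pct", "total_sasa",
    "dna_mass", "nn_count_AA_TT", "xix_count", "paired_fraction",
):
    print(f"  {name:24s} {values[name]:10.3f}")
# protein_mass/dna_mass are in Da, total_sasa in Å²; counts are integers and
# percentages run 0-100.  ensemble_diversity / mfe_frequency are NaN here
# because no external folding output was supplied.
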