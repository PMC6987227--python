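"""Classify a protein-DNA complex by DNA form and binding-site fraction.

Builds a small idealized complex (a 6-bp duplex plus a 2-nt single-stranded
tail, contacted by a 12-residue protein), then runs the geometric classifier.
"""

from predba import classify_complex, find_binding_residues, detect_wc_pairs, parse_pdb
from predba.synthetic import ToyComplexSpec, make_toy_complex

spec = ToyComplexSpec(
    n_protein_res=12, n_bp=6, unpaired_tail=2, min_contact_dist=4.0, seed=42
)
pdb_text, truth = make_toy_complex(spec)
cs = parse_pdb(pdb_text, complex_id="example")

pairs, paired_fraction = detect_wc_pairs(cs)
site = find_binding_residues(cs)
result = classify_complex(cs)

print(f"Watson-Crick pairs detected : {len(pairs)} (built with {truth.n_bp})")
print(f"paired fraction             : {paired_fraction:.3f}")
print(f"binding-site residues       : {len(site.binding_residues)} "
      f"({site.binding_pct:.1f}% of the protein)")
print(f"class label                 : {result.label}")
# The paired fraction (2*pairs / nucleotides) decides SS vs duplex vs MISC;
# duplexes are then split by the binding-site percentage (<=10 / 10-20 / >=20).
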