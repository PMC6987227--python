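"""Convert dissociation constants to dissociation free energies.

ΔG = -R·T·ln(Kd) with R = 1.987e-3 kcal/(mol·K): a tighter binder (smaller
Kd) dissociates with a larger positive free energy.
"""

from predba import delta_g_from_kd

for kd, t in [(1.0, 298.15), (1e-6, 298.15), (1e-9, 298.15), (1e-9, 310.0)]:
    print(f"Kd = {kd:8.1e} M at T = {t:6.2f} K  ->  "
          f"dG = {delta_g_from_kd(kd, t):7.3f} kcal/mol")
# Note the log-linearity: each 1000-fold drop in Kd adds the same increment.
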