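"""Adduct masses and theoretical isotope envelopes for halogenated contaminants.

Run:  python examples/01_isotope_patterns.py
"""

import hocscreen as h

for text in ("C10H8", "C6Cl6", "C12H6Br4O"):
    formula = h.parse_formula(text)
    neutral = h.monoisotopic_mass(formula)
    radical = h.adduct_mz(formula, h.AdductKind.RADICAL_CATION)
    protonated = h.adduct_mz(formula, h.AdductKind.PROTONATED)
    print(f"\n{text}: neutral {neutral:.4f} Da, M+. {radical:.4f}, [M+H]+ {protonated:.4f}")

    pattern = h.isotope_pattern(formula, h.AdductKind.RADICAL_CATION)
    print("  isotopologue envelope (m/z, % of base):")
    for mz, ri in pattern.peaks:
        print(f"    {mz:10.4f}  {ri:6.2f}")

# The envelope is what the isotope-pattern gate compares against a measured
# envelope: note that for C6Cl6 the most abundant isotopologue is M+2, not
# the all-35Cl ion, so the base-peak m/z used for mass matching shifts too.
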