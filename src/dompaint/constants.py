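"""Physical constants for exact-mass arithmetic.

Monoisotopic atomic masses (Da) of the lightest stable isotope of each
element considered (C, H, N, O, S; phosphorus is fixed at zero in this
package). Values carry enough digits that formula masses are exact to
well below 1e-9 Da over the bounded composition space.
"""

MASS_C = 12.0
MASS_H = 1.0078250319
MASS_N = 14.0030740052
MASS_O = 15.9949146221
MASS_S = 31.97207069

#: Mass of a proton (Da). Converting an [M-H]- anion m/z back to the
#: neutral mass adds this value (the electron mass is folded in).
MASS_PROTON = 1.00727646

#: Exact mass of a CH2 (methylene) repeat unit.
MASS_CH2 = MASS_C + 2 * MASS_H

ELEMENT_MASSES = {
    "c": MASS_C,
    "h": MASS_H,
    "n": MASS_N,
    "o": MASS_O,
    "s": MASS_S,
}
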