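"""Unit conventions and conversion constants.

Geometry is expressed in micrometres (μm) with ``z`` the cortical depth
(0 at the pial surface, increasing downward).  Pressures cross the API
boundary in mmHg; internally everything hydrodynamic is SI
(Pa, m, m^3/s).
"""

MMHG_TO_PA = 133.322
PA_TO_MMHG = 1.0 / MMHG_TO_PA

UM_TO_M = 1e-6
M_TO_UM = 1e6

#: 1 femtolitre in m^3 (RBC volumes are quoted in fL)
FL_TO_M3 = 1e-18

#: 1 m^3/s in nl/s (flow rates are reported in nl/s)
M3S_TO_NLS = 1e12
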