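"""Physical constants shared across the package."""

import math

#: Proton gyromagnetic ratio over 2*pi, in Hz per tesla.
GAMMA_HZ = 42.577478e6

#: Proton gyromagnetic ratio in rad s^-1 T^-1.
GAMMA = 2.0 * math.pi * GAMMA_HZ

#: Vacuum permeability, T m / A.
MU0 = 4.0e-7 * math.pi
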