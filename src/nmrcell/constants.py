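"""Physical constants and reference susceptibilities.

Single source of truth for every module. Volume susceptibilities are
quoted in ppm (SI volume convention, dimensionless × 1e-6); negative
values are diamagnetic.
"""

import math

#: Vacuum permeability, H/m.
MU_0 = 4.0e-7 * math.pi

#: Proton gyromagnetic ratio over 2π, MHz/T.
GAMMA_1H_MHZ_PER_T = 42.577

#: Literature volume susceptibility of H2O at room temperature, ppm.
CHI_H2O_PPM = -9.05

#: Volume susceptibility of D2O, ppm (χ_H2O minus the 0.04 ppm isotope
#: difference, rounded to the 2-decimal reporting convention).
CHI_D2O_PPM = -9.01

#: Volume susceptibility of air, ppm (dominated by paramagnetic O2).
#: Used as the default scene background.
CHI_AIR_PPM = 0.36

#: Measured susceptibility of printed Formlabs Clear V4 resin, ppm.
CHI_CLEARV4_PPM = -9.40

#: Susceptibility of Shigemi tube glass matched to D2O, ppm.
CHI_SHIGEMI_GLASS_PPM = -9.08

#: NaCl dependence of aqueous susceptibility, ppm per mol/L.
NACL_SLOPE_PPM_PER_M = 0.2

#: Validated NaCl concentration range for the linear salt model, mol/L.
NACL_RANGE_M = (0.0, 2.0)

#: Default 1H spectrometer frequency, MHz (600 MHz class instrument).
DEFAULT_SPECTROMETER_MHZ = 600.13
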