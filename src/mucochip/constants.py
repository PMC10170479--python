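"""Physical constants and unit conversion factors used across the package.

All internal computation is SI; user-facing quantities follow the
conventions of the airway-on-chip literature (viscosity in cP, shear in
dyn/cm^2, capacitance in nF, trajectory coordinates in um).
"""

BOLTZMANN_J_K = 1.380649e-23  # exact SI definition

CP_PER_PA_S = 1_000.0         # 1 Pa*s = 1000 cP
DYN_CM2_PER_PA = 10.0         # 1 Pa = 10 dyn/cm^2
NF_PER_F = 1e9
UM_PER_M = 1e6
M_PER_UM = 1e-6

# 1 uL/min in m^3/s
M3_S_PER_UL_MIN = 1e-9 / 60.0

#: Room temperature (K); microrheology acquisitions equilibrate at RT.
ROOM_TEMPERATURE_K = 298.15
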