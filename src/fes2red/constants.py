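"""Physical constants and unit conventions.

Internal units are fixed throughout the package: temperature in K,
aqueous concentrations in mol L^-1, gas partial pressures in bar,
energies in kJ mol^-1, electrode potentials in mV vs SHE.
"""

import math

#: Gas constant, J mol^-1 K^-1
R_J = 8.31446
#: Gas constant, kJ mol^-1 K^-1
R_KJ = R_J * 1e-3
#: Gas constant, L bar mol^-1 K^-1 (for headspace ideal-gas bookkeeping)
R_LBAR = 0.0831446
#: Faraday constant, C mol^-1
FARADAY = 96485.0
#: 1 atm in bar
ATM_TO_BAR = 1.01325

LN10 = math.log(10.0)

#: Reference temperature for tabulated formation energies, K (25 C)
T_REF = 298.15
#: Incubation temperature used throughout the study conditions, K (38 C)
T_38C = 311.15

#: Davies A parameter at 25 C, kg^1/2 mol^-1/2
DAVIES_A_25C = 0.509
#: Davies A parameter at 38 C (temperature-adjusted alternative)
DAVIES_A_38C = 0.520


def davies_a_for_temperature(temperature_k: float) -> float:
    """Davies A parameter interpolated linearly between the 25 C and 38 C anchors.

    Adequate over the narrow 20-45 C span this package targets; outside it
    the nearest anchor slope is simply extrapolated.
    """
    slope = (DAVIES_A_38C - DAVIES_A_25C) / (T_38C - T_REF)
    return DAVIES_A_25C + slope * (temperature_k - T_REF)
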