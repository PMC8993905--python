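"""Physical constants for dipolar-coupling calculations.

Gyromagnetic ratios in rad s^-1 T^-1.  The proton value is CODATA; the
13C value is the standard literature value (13C is not a CODATA quantity).
"""

from scipy.constants import hbar, mu_0, pi

GAMMA_1H = 2.6752218708e8
GAMMA_13C = 6.728284e7

#: cos of the tetrahedral (methyl H-C-C3axis) angle, 109.47 deg
COS_TETRAHEDRAL = -1.0 / 3.0

__all__ = ["GAMMA_1H", "GAMMA_13C", "COS_TETRAHEDRAL", "hbar", "mu_0", "pi"]
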