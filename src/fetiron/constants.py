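"""Physical constants shared by every module.

Single source of truth: all relaxation and shift expressions import from
here, so the proton/electron frequency ratio, spin quantum number etc. are
defined exactly once (CODATA 2018 values).
"""
from __future__ import annotations

from typing import Final

#: electron g-factor (free-electron value used for high-spin Fe3+)
G_E: Final[float] = 2.0023
#: total electron spin of high-spin d5 Fe3+
S_FE: Final[float] = 2.5
#: Bohr magneton, J/T
MU_B: Final[float] = 9.2740100783e-24
#: proton gyromagnetic ratio, rad s^-1 T^-1
GAMMA_H: Final[float] = 2.6752218744e8
#: 17O gyromagnetic ratio, rad s^-1 T^-1 (magnitude)
GAMMA_O17: Final[float] = 3.62808e7
#: reduced Planck constant, J s
HBAR: Final[float] = 1.054571817e-34
#: Boltzmann constant, J/K
K_B: Final[float] = 1.380649e-23
#: molar gas constant, J mol^-1 K^-1
R_GAS: Final[float] = 8.31446261815324
#: Planck constant, J s
H_PLANCK: Final[float] = 6.62607015e-34
#: Avogadro constant, mol^-1
N_A: Final[float] = 6.02214076e23
#: mu_0 / 4 pi, T m / A
MU0_4PI: Final[float] = 1e-7
#: molarity of pure water, mol/L
WATER_MOLARITY: Final[float] = 55.6
#: electron/proton Larmor frequency ratio, omega_S = RATIO * omega_I
OMEGA_S_OVER_OMEGA_I: Final[float] = 658.21
#: reference temperature for all "298" parameters, K
T_REF: Final[float] = 298.15
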