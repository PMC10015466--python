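"""Ground-truth parameter bundles for the Fe(III)-Tiron system.

Read-only transcriptions of the published equilibrium constants
(0.15 M NaNO3, 25 C), the simultaneous-fit relaxation parameters of the
three Tiron complexes (plus the hexaaqua reference), and the
transchelation rate constants.  These drive the synthetic-data
generators and serve as defaults throughout the package.
"""
from __future__ import annotations

from types import MappingProxyType

from .kinetics import KineticRateModel
from .oxygen17 import O17Params
from .relaxometry import RelaxParams
from .speciation import SpeciesModel

__all__ = [
    "TABLE1_CONSTANTS",
    "RELAX_FIXTURES",
    "O17_FIXTURES",
    "KINETIC_CONSTANTS",
    "COMPARISON_KD",
    "get_relax_params",
    "get_o17_params",
]

#: equilibrium constants at I = 0.15 M NaNO3, 25 C
TABLE1_CONSTANTS = SpeciesModel(
    logK1H=12.40,
    logK2H=7.46,
    logK_FeL=20.32,
    logK_FeL2=14.49,
    logK_FeL3=9.83,
    logK_FeL2Hm1=7.86,
    pKw=13.77,
    pA=0.02,
)

_SHARED_OS = dict(D298_m2s=2.24e-9, E_D=20.0e3, a_A=3.5)

#: relaxation-parameter bundles from the simultaneous 1H/17O fit
_RELAX = {
    # [Fe(Tiron)3]9-: q = 0, relaxivity is second + outer sphere only
    "FeL3": RelaxParams(
        q=0,
        q_SS=5,
        r_SS_A=3.50,
        tauR_SS298_ps=52.7,
        E_R_SS=15.3e3,
        Delta2_s2=9.7e20,
        E_Delta=4.6e3,
        tauv298_ps=6.9,
        E_v=1.0e3,
        tauM_SS_s=1e-9,
        **_SHARED_OS,
    ),
    # [Fe(Tiron)2(H2O)2]5-
    "FeL2": RelaxParams(
        q=2,
        r_MH_A=2.70,
        tauR298_ps=70.0,
        E_R=16.0e3,
        tauM298_s=272e-9,
        dH_M=56.2e3,
        q_SS=2,
        r_SS_A=3.25,
        tauR_SS298_ps=31.2,
        E_R_SS=11.0e3,
        Delta2_s2=12.2e20,
        E_Delta=2.7e3,
        tauv298_ps=5.6,
        E_v=1.0e3,
        tauM_SS_s=1e-9,
        **_SHARED_OS,
    ),
    # [Fe(Tiron)(H2O)4]-
    "FeL1": RelaxParams(
        q=4,
        r_MH_A=2.70,
        tauR298_ps=34.7,
        E_R=15.0e3,
        tauM298_s=18000e-9,
        dH_M=57.5e3,
        q_SS=0,
        Delta2_s2=5.5e20,
        E_Delta=3.3e3,
        tauv298_ps=9.2,
        E_v=1.0e3,
        **_SHARED_OS,
    ),
    # [Fe(H2O)6]3+ reference column (no activation energies reported)
    "FeAqua": RelaxParams(
        q=6,
        r_MH_A=2.69,
        tauR298_ps=60.7,
        E_R=17.9e3,
        tauM298_s=25000e-9,
        dH_M=31.4e3,
        q_SS=0,
        Delta2_s2=4.2e20,
        E_Delta=0.0,
        tauv298_ps=5.3,
        E_v=1.0e3,
        **_SHARED_OS,
    ),
}
RELAX_FIXTURES = MappingProxyType(_RELAX)

_O17 = {
    "FeL2": O17Params(
        A_O_over_hbar=-50.1e6,
        tauM298_s=272e-9,
        dH_M=56.2e3,
        C_os=0.04,
        q=2,
        B0_T=11.74,
        Delta2_s2=12.2e20,
        E_Delta=2.7e3,
        tauv298_ps=5.6,
        E_v=1.0e3,
    ),
    "FeL1": O17Params(
        A_O_over_hbar=-71.6e6,
        tauM298_s=18000e-9,
        dH_M=57.5e3,
        C_os=0.05,
        q=4,
        B0_T=11.74,
        Delta2_s2=5.5e20,
        E_Delta=3.3e3,
        tauv298_ps=9.2,
        E_v=1.0e3,
    ),
    "FeAqua": O17Params(
        A_O_over_hbar=-99.3e6,
        tauM298_s=25000e-9,
        dH_M=31.4e3,
        C_os=0.038,
        q=6,
        B0_T=11.74,
        Delta2_s2=4.2e20,
        E_Delta=0.0,
        tauv298_ps=5.3,
        E_v=1.0e3,
    ),
}
O17_FIXTURES = MappingProxyType(_O17)

#: transchelation rate law of the Fe(III)-Tiron system with CDTA
KINETIC_CONSTANTS = KineticRateModel(
    k0=8e-5,
    k1=3.9e3,
    k4=7e5,
    logK_FeL3_kin=9.20,
)

#: printed pH-7.4 dissociation rate constants (s^-1) of the comparison
#: complexes, for half-life ordering checks
COMPARISON_KD = MappingProxyType(
    {"FeTiron": 1.1e-4, "FeEDTA": 2.9e-6, "FeCDTA": 2.1e-9}
)


def get_relax_params(name: str) -> RelaxParams:
    """Look up a relaxation fixture by complex name (FeL1/FeL2/FeL3/FeAqua)."""
    try:
        return RELAX_FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown complex {name!r}; choose from {sorted(RELAX_FIXTURES)}"
        ) from None


def get_o17_params(name: str) -> O17Params:
    """Look up a 17O fixture by complex name (FeL1/FeL2/FeAqua)."""
    try:
        return O17_FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown complex {name!r}; choose from {sorted(O17_FIXTURES)}"
        ) from None
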