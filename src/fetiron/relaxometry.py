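"""Field- and temperature-dependent water-proton relaxivity of Fe3+ chelates.

The longitudinal relaxivity r1(B, T) is modelled as the sum of three
contributions:

* inner sphere (IS): dipolar relaxation of the q metal-bound water
  protons (Solomon-Bloembergen-Morgan), exchanging with bulk with
  residence time tau_M;
* second sphere (SS): the same functional form applied to q_SS
  hydrogen-bonded waters at distance r_SS with their own rotational
  correlation time and a short residence time (1 ns by default);
* outer sphere (OS): Freed's hard-sphere translational-diffusion model.

Electron-spin relaxation (T1e, T2e) enters all three terms and is
described by the transient zero-field-splitting (Bloembergen-Morgan)
expressions for S = 5/2, governed by the mean-square ZFS energy Delta^2
and its correlation time tau_v.  Temperature dependences: Arrhenius for
correlation times, Delta^2 and diffusion, Eyring for the water-exchange
rate 1/tau_M.

Scalar (contact) contributions to 1H relaxation are omitted: proton
relaxation in these complexes is dominated by the dipole-dipole
mechanism.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np

from .constants import (
    G_E,
    GAMMA_H,
    HBAR,
    K_B,
    MU0_4PI,
    MU_B,
    N_A,
    OMEGA_S_OVER_OMEGA_I,
    R_GAS,
    S_FE,
    T_REF,
    WATER_MOLARITY,
)

__all__ = [
    "FieldPoint",
    "RelaxParams",
    "temperature_scale",
    "electron_relaxation",
    "inner_sphere_r1",
    "second_sphere_r1",
    "outer_sphere_r1",
    "total_r1",
    "nmrd_profile",
]


@dataclass(frozen=True)
class FieldPoint:
    """One magnetic-field point, specified by the proton Larmor frequency."""

    nu_MHz: float

    def __post_init__(self) -> None:
        if self.nu_MHz <= 0:
            raise ValueError("proton Larmor frequency must be positive")

    @property
    def omega_I(self) -> float:
        """Proton angular frequency, rad/s."""
        return 2.0 * np.pi * self.nu_MHz * 1e6

    @property
    def omega_S(self) -> float:
        """Electron angular frequency, rad/s."""
        return OMEGA_S_OVER_OMEGA_I * self.omega_I


@dataclass(frozen=True)
class RelaxParams:
    """Physical parameters of one complex for the three-term r1 model.

    Units follow the conventions of the relaxometric literature; every
    field name carries its unit.  ``*298`` values refer to 298.15 K.

    Inner sphere: ``q`` bound waters at Fe-H distance ``r_MH_A`` (angstrom),
    rotation ``tauR298_ps`` with Arrhenius energy ``E_R`` (J/mol), exchange
    ``tauM298_s`` with Eyring enthalpy ``dH_M`` (J/mol).

    Electron relaxation: mean-square transient ZFS ``Delta2_s2`` (s^-2)
    with Arrhenius energy ``E_Delta``; correlation time ``tauv298_ps``
    with energy ``E_v``.

    Second sphere: ``q_SS`` waters at ``r_SS_A`` with ``tauR_SS298_ps``,
    ``E_R_SS`` and residence time ``tauM_SS_s`` (default 1 ns, short
    enough not to limit relaxivity).

    Outer sphere: relative diffusion coefficient ``D298_m2s`` (m^2/s)
    with energy ``E_D`` and closest-approach distance ``a_A``.
    """

    q: int = 0
    r_MH_A: float = 2.70
    tauR298_ps: float = 70.0
    E_R: float = 16.0e3
    tauM298_s: float = 272e-9
    dH_M: float = 56.2e3
    Delta2_s2: float = 12.2e20
    E_Delta: float = 2.7e3
    tauv298_ps: float = 5.6
    E_v: float = 1.0e3
    q_SS: int = 0
    r_SS_A: float = 3.50
    tauR_SS298_ps: float = 52.7
    E_R_SS: float = 15.3e3
    tauM_SS_s: float = 1e-9
    D298_m2s: float = 2.24e-9
    E_D: float = 20.0e3
    a_A: float = 3.5

    def __post_init__(self) -> None:
        if self.q < 0 or self.q_SS < 0:
            raise ValueError("water counts must be non-negative")
        if self.r_MH_A <= 0 or self.r_SS_A <= 0 or self.a_A <= 0:
            raise ValueError("distances must be positive")
        for t in (self.tauR298_ps, self.tauM298_s, self.tauv298_ps, self.tauM_SS_s):
            if t <= 0:
                raise ValueError("correlation/residence times must be positive")
        if self.Delta2_s2 < 0:
            raise ValueError("Delta^2 must be non-negative")
        if self.D298_m2s <= 0:
            raise ValueError("diffusion coefficient must be positive")

    def updated(self, **kwargs: float) -> "RelaxParams":
        return replace(self, **kwargs)


TempLaw = Literal["arrhenius-time", "arrhenius-rate", "eyring-exchange"]


def temperature_scale(x298: float, E: float, T: float, law: TempLaw) -> float:
    """Scale a 298.15 K reference value to temperature T (K).

    * ``arrhenius-time``: correlation times, tau(T) = tau298 exp[E/R (1/T - 1/T0)]
      (shrink with rising T for E > 0); also used for Delta^2.
    * ``arrhenius-rate``: rates/diffusion, x(T) = x298 exp[E/R (1/T0 - 1/T)].
    * ``eyring-exchange``: residence time via the Eyring exchange rate
      k_ex(T) = k_ex298 (T/T0) exp[dH/R (1/T0 - 1/T)]; returns tau_M(T).
    """
    if law == "arrhenius-time":
        return x298 * np.exp(E / R_GAS * (1.0 / T - 1.0 / T_REF))
    if law == "arrhenius-rate":
        return x298 * np.exp(E / R_GAS * (1.0 / T_REF - 1.0 / T))
    if law == "eyring-exchange":
        kex = (1.0 / x298) * (T / T_REF) * np.exp(E / R_GAS * (1.0 / T_REF - 1.0 / T))
        return 1.0 / kex
    raise ValueError(f"unknown temperature law: {law!r}")


def electron_relaxation(
    omega_S: float, Delta2: float, tauv: float
) -> tuple[float, float]:
    """Electron relaxation times (T1e, T2e) from the transient-ZFS model.

    Bloembergen-Morgan expressions for S = 5/2:

        1/T1e = (Delta2 tauv / 25) [4S(S+1) - 3] [u1 + 4 u2]
        1/T2e = (Delta2 tauv / 50) [4S(S+1) - 3] [3 + 5 u1 + 2 u2]

    with u_n = 1 / (1 + n^2 omega_S^2 tauv^2).  At zero field
    T1e = T2e; for Delta2 = 0 both are infinite.
    """
    if Delta2 < 0 or tauv <= 0:
        raise ValueError("Delta2 must be >= 0 and tauv > 0")
    if Delta2 == 0.0:
        return np.inf, np.inf
    pref = Delta2 * tauv * (4.0 * S_FE * (S_FE + 1.0) - 3.0)
    u1 = 1.0 / (1.0 + omega_S**2 * tauv**2)
    u2 = 1.0 / (1.0 + 4.0 * omega_S**2 * tauv**2)
    rate1 = pref / 25.0 * (u1 + 4.0 * u2)
    rate2 = pref / 50.0 * (3.0 + 5.0 * u1 + 2.0 * u2)
    return 1.0 / rate1, 1.0 / rate2


#: dipolar prefactor without the 1/r^6, SI
_DIP_K = (
    (2.0 / 15.0)
    * MU0_4PI**2
    * GAMMA_H**2
    * G_E**2
    * MU_B**2
    * S_FE
    * (S_FE + 1.0)
)


def _dipolar_sphere_r1(
    q: int,
    r_A: float,
    tauR: float,
    tauM: float,
    T1e: float,
    T2e: float,
    B: FieldPoint,
) -> float:
    """Exchange-limited dipolar relaxivity of q waters at distance r (per mM).

    r1 = P_m / (T1M + tauM) with P_m = q * 1 mM / 55.6 M and

        1/T1M = K/r^6 [3 tc1 / (1 + wI^2 tc1^2) + 7 tc2 / (1 + wS^2 tc2^2)],
        1/tc_i = 1/tauR + 1/tauM + 1/T_ie.
    """
    if q == 0:
        return 0.0
    r = r_A * 1e-10
    tc1 = 1.0 / (1.0 / tauR + 1.0 / tauM + 1.0 / T1e)
    tc2 = 1.0 / (1.0 / tauR + 1.0 / tauM + 1.0 / T2e)
    inv_T1M = (_DIP_K / r**6) * (
        3.0 * tc1 / (1.0 + B.omega_I**2 * tc1**2)
        + 7.0 * tc2 / (1.0 + B.omega_S**2 * tc2**2)
    )
    P_m = q * 1e-3 / WATER_MOLARITY
    return P_m / (1.0 / inv_T1M + tauM)


def _electron_times(p: RelaxParams, B: FieldPoint, T: float) -> tuple[float, float]:
    Delta2 = temperature_scale(p.Delta2_s2, p.E_Delta, T, "arrhenius-time")
    tauv = temperature_scale(p.tauv298_ps * 1e-12, p.E_v, T, "arrhenius-time")
    return electron_relaxation(B.omega_S, Delta2, tauv)


def inner_sphere_r1(p: RelaxParams, B: FieldPoint, T: float = T_REF) -> float:
    """Inner-sphere relaxivity, mM^-1 s^-1. Zero when q = 0."""
    if p.q == 0:
        return 0.0
    T1e, T2e = _electron_times(p, B, T)
    tauR = temperature_scale(p.tauR298_ps * 1e-12, p.E_R, T, "arrhenius-time")
    tauM = temperature_scale(p.tauM298_s, p.dH_M, T, "eyring-exchange")
    return _dipolar_sphere_r1(p.q, p.r_MH_A, tauR, tauM, T1e, T2e, B)


def second_sphere_r1(p: RelaxParams, B: FieldPoint, T: float = T_REF) -> float:
    """Second-sphere relaxivity, mM^-1 s^-1. Zero when q_SS = 0."""
    if p.q_SS == 0:
        return 0.0
    T1e, T2e = _electron_times(p, B, T)
    tauR_SS = temperature_scale(p.tauR_SS298_ps * 1e-12, p.E_R_SS, T, "arrhenius-time")
    return _dipolar_sphere_r1(p.q_SS, p.r_SS_A, tauR_SS, p.tauM_SS_s, T1e, T2e, B)


def _freed_J(omega: float, tauD: float, Tje: float) -> float:
    """Freed hard-sphere spectral density (dimensionless)."""
    z = np.sqrt(1j * omega * tauD + tauD / Tje)
    return float(np.real((1.0 + z / 4.0) / (1.0 + z + 4.0 * z**2 / 9.0 + z**3 / 9.0)))


def outer_sphere_r1(p: RelaxParams, B: FieldPoint, T: float = T_REF) -> float:
    """Outer-sphere relaxivity from Freed's translational model, mM^-1 s^-1.

    Uses tau_D = a^2/D with the temperature-scaled relative diffusion
    coefficient, and the finite electron relaxation times in the
    spectral densities.  Vanishes as D -> infinity.
    """
    D = temperature_scale(p.D298_m2s, p.E_D, T, "arrhenius-rate")
    a = p.a_A * 1e-10
    tauD = a**2 / D
    T1e, T2e = _electron_times(p, B, T)
    gamma_S = G_E * MU_B / HBAR
    # number density of a 1 mM solution: 1 mol/m^3
    pref = (
        (32.0 * np.pi / 405.0)
        * MU0_4PI**2
        * GAMMA_H**2
        * gamma_S**2
        * HBAR**2
        * S_FE
        * (S_FE + 1.0)
        * N_A
        * 1.0
        / (a * D)
    )
    return pref * (
        3.0 * _freed_J(B.omega_I, tauD, T1e) + 7.0 * _freed_J(B.omega_S, tauD, T2e)
    )


def total_r1(
    p: RelaxParams, B: FieldPoint, T: float = T_REF
) -> dict[str, float]:
    """Total relaxivity and its component breakdown at one (B, T) point.

    Returns a dict with keys ``IS``, ``SS``, ``OS``, ``total`` (all in
    mM^-1 s^-1) and ``pct_IS``/``pct_SS``/``pct_OS`` percentages that sum
    to 100.
    """
    comp = {
        "IS": inner_sphere_r1(p, B, T),
        "SS": second_sphere_r1(p, B, T),
        "OS": outer_sphere_r1(p, B, T),
    }
    tot = comp["IS"] + comp["SS"] + comp["OS"]
    comp["total"] = tot
    for k in ("IS", "SS", "OS"):
        comp[f"pct_{k}"] = 100.0 * comp[k] / tot if tot > 0 else 0.0
    return comp


def nmrd_profile(
    p: RelaxParams,
    freqs_MHz: np.ndarray,
    T: float = T_REF,
) -> np.ndarray:
    """Total r1 over an array of proton Larmor frequencies (MHz)."""
    freqs_MHz = np.asarray(freqs_MHz, dtype=float)
    return np.array([total_r1(p, FieldPoint(f), T)["total"] for f in freqs_MHz])
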