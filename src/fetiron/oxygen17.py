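"""Swift-Connick analysis of reduced 17O NMR data vs temperature.

The reduced transverse relaxation rate R2r and reduced chemical shift
dOmega_r of bulk water in a solution of a paramagnetic aqua complex
report on the bound-water scalar coupling (A_O/hbar), its residence time
tau_M, and the electron relaxation.  The bound-site transverse
relaxation is scalar-dominated (it scales with the square of the
hyperfine coupling constant); the 17O dipolar term is omitted.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .constants import G_E, HBAR, K_B, MU_B, S_FE, T_REF
from .relaxometry import electron_relaxation, temperature_scale

__all__ = ["O17Params", "bound_shift", "swift_connick", "classify_regime", "o17_curve"]


@dataclass(frozen=True)
class O17Params:
    """Parameters governing the 17O observables of one complex.

    ``A_O_over_hbar`` is the scalar hyperfine coupling constant in rad/s
    (Table-style values are quoted in 10^6 rad/s; pass the full value,
    e.g. -50.1e6).  ``C_os`` is the empirical outer-sphere shift
    coefficient: it adds ``C_os * dOmega_m`` to the reduced shift and
    does not contribute to R2r.  tau_M and the electron-relaxation
    parameters (Delta2, tau_v and their activation energies) are shared
    with the 1H relaxivity model in a global fit.
    """

    A_O_over_hbar: float = -50.1e6
    tauM298_s: float = 272e-9
    dH_M: float = 56.2e3
    C_os: float = 0.04
    q: int = 2
    B0_T: float = 11.74
    Delta2_s2: float = 12.2e20
    E_Delta: float = 2.7e3
    tauv298_ps: float = 5.6
    E_v: float = 1.0e3

    def __post_init__(self) -> None:
        if self.q < 1:
            raise ValueError("17O analysis requires at least one bound water (q >= 1)")
        if self.B0_T <= 0:
            raise ValueError("field must be positive")
        if self.tauM298_s <= 0:
            raise ValueError("tauM must be positive")

    def updated(self, **kwargs: float) -> "O17Params":
        return replace(self, **kwargs)


def bound_shift(params: O17Params, T: float = T_REF) -> float:
    """Chemical shift of bound-water 17O, dOmega_m in rad/s.

    Standard scalar-coupling (Curie) expression

        dOmega_m = g_e mu_B S(S+1) B0 / (3 k_B T) * (A_O/hbar);

    linear in B0, sign follows A_O/hbar.
    """
    return (
        G_E * MU_B * S_FE * (S_FE + 1.0) * params.B0_T / (3.0 * K_B * T)
    ) * params.A_O_over_hbar


def _omega_S_at_B0(B0_T: float) -> float:
    """Electron Larmor angular frequency at field B0, rad/s."""
    return G_E * MU_B / HBAR * B0_T


def _scalar_T2m(params: O17Params, T: float) -> tuple[float, float]:
    """Bound 17O transverse relaxation time (scalar mechanism) and tau_M.

    1/T2m = S(S+1)/3 * (A_O/hbar)^2 * tau_s with 1/tau_s = 1/tau_M + 1/T1e,
    T1e from the shared transient-ZFS model evaluated at omega_S(B0).
    """
    tauM = temperature_scale(params.tauM298_s, params.dH_M, T, "eyring-exchange")
    Delta2 = temperature_scale(params.Delta2_s2, params.E_Delta, T, "arrhenius-time")
    tauv = temperature_scale(params.tauv298_ps * 1e-12, params.E_v, T, "arrhenius-time")
    T1e, _ = electron_relaxation(_omega_S_at_B0(params.B0_T), Delta2, tauv)
    tau_s = 1.0 / (1.0 / tauM + 1.0 / T1e)
    inv_T2m = (S_FE * (S_FE + 1.0) / 3.0) * params.A_O_over_hbar**2 * tau_s
    return 1.0 / inv_T2m, tauM


def swift_connick(params: O17Params, T: float = T_REF) -> tuple[float, float]:
    """Reduced 17O rate and shift (R2r in s^-1, dOmega_r in rad/s) at T.

    Full Swift-Connick expression,

        R2r = (1/tauM) * [T2m^-2 + (T2m tauM)^-1 + dOm^2]
                         / [(T2m^-1 + tauM^-1)^2 + dOm^2]
        dOmega_r = dOm / [(1 + tauM/T2m)^2 + (tauM dOm)^2] + C_os * dOm

    Limits: tauM -> 0 gives R2r -> 1/T2m (fast exchange); tauM >> T2m
    gives R2r -> 1/tauM (slow exchange).
    """
    T2m, tauM = _scalar_T2m(params, T)
    dOm = bound_shift(params, T)
    inv_T2m = 1.0 / T2m
    inv_tauM = 1.0 / tauM
    R2r = inv_tauM * (
        (inv_T2m**2 + inv_T2m * inv_tauM + dOm**2)
        / ((inv_T2m + inv_tauM) ** 2 + dOm**2)
    )
    dOmega_r = dOm / ((1.0 + tauM / T2m) ** 2 + (tauM * dOm) ** 2) + params.C_os * dOm
    return R2r, dOmega_r


def classify_regime(
    params: O17Params, temperatures: Sequence[float]
) -> list[str]:
    """Label each temperature slow/intermediate/fast by tau_M vs T2m.

    slow: tau_M/T2m > 10; fast: tau_M/T2m < 0.1; intermediate otherwise.
    """
    labels = []
    for T in temperatures:
        T2m, tauM = _scalar_T2m(params, float(T))
        ratio = tauM / T2m
        if ratio > 10.0:
            labels.append("slow")
        elif ratio < 0.1:
            labels.append("fast")
        else:
            labels.append("intermediate")
    return labels


def o17_curve(
    params: O17Params, temperatures: Sequence[float]
) -> tuple[np.ndarray, np.ndarray]:
    """(R2r, dOmega_r) arrays over a temperature grid."""
    pairs = [swift_connick(params, float(T)) for T in temperatures]
    R2r = np.array([p[0] for p in pairs])
    dOm = np.array([p[1] for p in pairs])
    return R2r, dOm
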