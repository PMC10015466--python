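"""Independent brute-force / transcription oracles used by the tests.

These are deliberately plain, scalar transcriptions of the published
model equations, written and validated against the printed relaxivity
values before the package implementation and kept free of any package
imports.  The package is tested *against* them, never through them.
"""
import numpy as np

MU0_4PI = 1e-7
GE = 2.0023
MUB = 9.2740100783e-24
GAMMA_H = 2.6752218744e8
HBAR = 1.054571817e-34
KB = 1.380649e-23
NA = 6.02214076e23
R = 8.31446261815324
S = 2.5
T0 = 298.15
OMEGA_RATIO = 658.21
WATER_M = 55.6


# ---------------------------------------------------------------- relaxometry
def arrh_time(x298, E, T):
    return x298 * np.exp(E / R * (1.0 / T - 1.0 / T0))


def arrh_rate(x298, E, T):
    return x298 * np.exp(E / R * (1.0 / T0 - 1.0 / T))


def eyring_tau(tau298, dH, T):
    return 1.0 / ((1.0 / tau298) * (T / T0) * np.exp(dH / R * (1.0 / T0 - 1.0 / T)))


def electron_relax_oracle(omega_S, D2, tv):
    if D2 == 0.0:
        return np.inf, np.inf
    pref = D2 * tv * (4 * S * (S + 1) - 3)
    r1e = pref / 25.0 * (1.0 / (1 + omega_S**2 * tv**2) + 4.0 / (1 + 4 * omega_S**2 * tv**2))
    r2e = pref / 50.0 * (3.0 + 5.0 / (1 + omega_S**2 * tv**2) + 2.0 / (1 + 4 * omega_S**2 * tv**2))
    return 1.0 / r1e, 1.0 / r2e


def dipolar_r1_oracle(q, r_m, tauR, tauM, T1e, T2e, omega_I, omega_S):
    if q == 0:
        return 0.0
    K = (2.0 / 15.0) * MU0_4PI**2 * GAMMA_H**2 * GE**2 * MUB**2 * S * (S + 1) / r_m**6
    tc1 = 1.0 / (1.0 / tauR + 1.0 / tauM + 1.0 / T1e)
    tc2 = 1.0 / (1.0 / tauR + 1.0 / tauM + 1.0 / T2e)
    inv_T1M = K * (3 * tc1 / (1 + omega_I**2 * tc1**2) + 7 * tc2 / (1 + omega_S**2 * tc2**2))
    return (q * 1e-3 / WATER_M) / (1.0 / inv_T1M + tauM)


def freed_J_oracle(omega, tauD, Tje):
    z = np.sqrt(1j * omega * tauD + tauD / Tje)
    return np.real((1 + z / 4) / (1 + z + 4 * z**2 / 9 + z**3 / 9))


def freed_r1_oracle(a, D, T1e, T2e, omega_I, omega_S):
    tauD = a**2 / D
    gammaS = GE * MUB / HBAR
    pref = (
        (32 * np.pi / 405) * MU0_4PI**2 * GAMMA_H**2 * gammaS**2 * HBAR**2
        * S * (S + 1) * NA / (a * D)
    )
    return pref * (3 * freed_J_oracle(omega_I, tauD, T1e) + 7 * freed_J_oracle(omega_S, tauD, T2e))


def total_r1_oracle(p, nu_MHz, T):
    """p: dict with SI-unit entries (see tests for construction)."""
    omega_I = 2 * np.pi * nu_MHz * 1e6
    omega_S = OMEGA_RATIO * omega_I
    D2 = arrh_time(p["D2"], p.get("E_D2", 0.0), T)
    tv = arrh_time(p["tv"], p.get("E_v", 0.0), T)
    T1e, T2e = electron_relax_oracle(omega_S, D2, tv)
    IS = 0.0
    if p.get("q", 0) > 0:
        IS = dipolar_r1_oracle(
            p["q"], p["r"], arrh_time(p["tauR"], p.get("E_R", 0.0), T),
            eyring_tau(p["tauM"], p.get("dH_M", 0.0), T), T1e, T2e, omega_I, omega_S,
        )
    SS = 0.0
    if p.get("qSS", 0) > 0:
        SS = dipolar_r1_oracle(
            p["qSS"], p["rSS"], arrh_time(p["tauR_SS"], p.get("E_R_SS", 0.0), T),
            p.get("tauM_SS", 1e-9), T1e, T2e, omega_I, omega_S,
        )
    OS = freed_r1_oracle(
        p["a"], arrh_rate(p["Ddiff"], p.get("E_Ddiff", 0.0), T), T1e, T2e, omega_I, omega_S
    )
    return {"IS": IS, "SS": SS, "OS": OS, "total": IS + SS + OS}


def relax_params_to_oracle_dict(rp):
    """Convert a package RelaxParams to the oracle's SI dict (pure unit math)."""
    return dict(
        q=rp.q, r=rp.r_MH_A * 1e-10, tauR=rp.tauR298_ps * 1e-12, E_R=rp.E_R,
        tauM=rp.tauM298_s, dH_M=rp.dH_M, D2=rp.Delta2_s2, E_D2=rp.E_Delta,
        tv=rp.tauv298_ps * 1e-12, E_v=rp.E_v, qSS=rp.q_SS, rSS=rp.r_SS_A * 1e-10,
        tauR_SS=rp.tauR_SS298_ps * 1e-12, E_R_SS=rp.E_R_SS, tauM_SS=rp.tauM_SS_s,
        Ddiff=rp.D298_m2s, E_Ddiff=rp.E_D, a=rp.a_A * 1e-10,
    )


# ---------------------------------------------------------------- oxygen-17
def bound_shift_oracle(A_over_hbar, B0, T):
    return GE * MUB * S * (S + 1) * B0 / (3 * KB * T) * A_over_hbar


def swift_connick_oracle(A_over_hbar, tauM298, dH_M, C_os, B0, D2_298, E_D2, tv298, E_v, T):
    tauM = eyring_tau(tauM298, dH_M, T)
    omega_S = GE * MUB / HBAR * B0
    T1e, _ = electron_relax_oracle(omega_S, arrh_time(D2_298, E_D2, T), arrh_time(tv298, E_v, T))
    tau_s = 1.0 / (1.0 / tauM + 1.0 / T1e)
    inv_T2m = S * (S + 1) / 3.0 * A_over_hbar**2 * tau_s
    dOm = bound_shift_oracle(A_over_hbar, B0, T)
    R2r = (1.0 / tauM) * (inv_T2m**2 + inv_T2m / tauM + dOm**2) / (
        (inv_T2m + 1.0 / tauM) ** 2 + dOm**2
    )
    shift = dOm / ((1.0 + tauM * inv_T2m) ** 2 + (tauM * dOm) ** 2) + C_os * dOm
    return R2r, shift


# ---------------------------------------------------------------- speciation
def speciation_grid_oracle(logKs, FeT, LT, pH, include_hydroxo=True, n_grid=100_000):
    """Grid search over free [L4-] on a log axis, refined by bisection.

    logKs: (logK1H, logK2H, logK_FeL, logK_FeL2, logK_FeL3, logK_FeL2Hm1).
    Returns a dict of species concentrations.
    """
    K1H, K2H, KFeL, KFeL2, KFeL3, Km1 = [10.0**x for x in logKs]
    h = 10.0 ** (-pH)
    aH = 1 + K1H * h + K1H * K2H * h * h
    b1 = KFeL
    b2 = KFeL * KFeL2
    b3 = b2 * KFeL3
    hx = 1.0 / (Km1 * h) if include_hydroxo else 0.0

    def residual(l):
        fe = FeT / (1 + b1 * l + b2 * l * l * (1 + hx) + b3 * l**3)
        return l * aH + fe * (b1 * l + 2 * b2 * l * l * (1 + hx) + 3 * b3 * l**3) - LT

    grid = np.logspace(-28, -1, n_grid)
    res = np.array([residual(l) for l in grid]) if n_grid <= 1000 else _vec_residual(
        grid, FeT, LT, aH, b1, b2, b3, hx
    )
    sign = np.sign(res)
    idx = np.nonzero(np.diff(sign) != 0)[0]
    if idx.size == 0:
        lo, hi = grid[np.argmin(np.abs(res))] / 10, grid[np.argmin(np.abs(res))] * 10
    else:
        lo, hi = grid[idx[0]], grid[idx[0] + 1]
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if residual(lo) * residual(mid) <= 0:
            hi = mid
        else:
            lo = mid
        if hi / lo - 1 < 1e-15:
            break
    l = np.sqrt(lo * hi)
    fe = FeT / (1 + b1 * l + b2 * l * l * (1 + hx) + b3 * l**3)
    return {
        "L": l, "HL": K1H * h * l, "H2L": K1H * K2H * h * h * l, "Fe": fe,
        "FeL": b1 * l * fe, "FeL2": b2 * l * l * fe, "FeL3": b3 * l**3 * fe,
        "FeL2Hm1": b2 * l * l * fe * hx,
    }


def _vec_residual(grid, FeT, LT, aH, b1, b2, b3, hx):
    fe = FeT / (1 + b1 * grid + b2 * grid**2 * (1 + hx) + b3 * grid**3)
    return grid * aH + fe * (b1 * grid + 2 * b2 * grid**2 * (1 + hx) + 3 * b3 * grid**3) - LT
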