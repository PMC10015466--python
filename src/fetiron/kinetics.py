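"""Transchelation kinetics of the Fe(III)-Tiron system with CDTA.

Under a large CDTA excess the loss of the Tiron chromophore follows a
single-exponential absorbance decay with observed rate constant kd.
The rate law combines three pathways, weighted by the FeL3/FeL2 mole
fractions delivered by the speciation model:

    kd = x_FeL3 * k0 + x_FeL2 * (k1 [H+] + k4 [H+] [CDTA])

* ``k0``: spontaneous dissociation of [Fe(Tiron)3]9- (rate-limiting loss
  of the first Tiron);
* ``k1``: proton-assisted dissociation of [Fe(Tiron)2]5- via a
  protonated intermediate;
* ``k4``: proton- and CDTA-assisted dissociation via a ternary
  intermediate, linear in [CDTA].

The FeL3/FeL2 split uses the kinetically determined stability constant
``logK_FeL3_kin`` (it may differ from the equilibrium value) and
neglects the minor hydroxo species.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .datasets import KineticTrace
from .results import FitResult, covariance_from_jacobian
from .speciation import SolutionConditions, SpeciesModel, solve_speciation

__all__ = [
    "KineticRateModel",
    "fit_trace",
    "observed_kd",
    "half_life",
    "hydroxide_pathway_kd",
    "RateLawFit",
    "refine_rate_constants",
    "DegenerateTraceError",
]


class DegenerateTraceError(ValueError):
    """Raised when an absorbance trace carries no decay signal."""


@dataclass(frozen=True)
class KineticRateModel:
    """Rate and equilibrium constants of the transchelation rate law."""

    k0: float = 8e-5  # s^-1
    k1: float = 3.9e3  # M^-1 s^-1
    k4: float = 7e5  # M^-2 s^-1
    logK_FeL3_kin: float = 9.20

    def __post_init__(self) -> None:
        if self.k0 < 0 or self.k1 < 0 or self.k4 < 0:
            raise ValueError("rate constants must be non-negative")

    def updated(self, **kwargs: float) -> "KineticRateModel":
        return replace(self, **kwargs)


def fit_trace(
    trace: KineticTrace,
    fix_endpoints: bool = False,
) -> FitResult:
    """Fit A(t) = A_p + (A0 - A_p) exp(-kd t) to one absorbance trace.

    Endpoints A0 and A_p are fitted by default (endpoint drift); with
    ``fix_endpoints`` they are frozen at the first/last observed values.
    Returns a :class:`FitResult` whose params carry ``kd`` (s^-1) and,
    when free, ``A0`` and ``Ap``.  A constant trace raises
    :class:`DegenerateTraceError`.
    """
    t = trace.times_s
    A = trace.absorbance
    span = float(np.max(A) - np.min(A))
    if span <= 1e-12 * max(1.0, float(np.max(np.abs(A)))):
        raise DegenerateTraceError("absorbance trace shows no signal change")

    A0_guess, Ap_guess = float(A[0]), float(A[-1])
    # log-linear slope for the rate guess
    mid = Ap_guess + 0.368 * (A0_guess - Ap_guess)
    idx = int(np.argmin(np.abs(A - mid)))
    kd_guess = 1.0 / max(t[idx], t[1] if t[0] == 0 else t[0])

    warnings: list[str] = []
    if len(t) < 5:
        warnings.append("fewer than 5 points; kd poorly constrained")
    if not trace.pseudo_first_order and trace.conditions:
        warnings.append("CDTA excess below 20x Fe: pseudo-first-order assumption weak")

    if fix_endpoints:
        def resid(theta: np.ndarray) -> np.ndarray:
            return Ap_guess + (A0_guess - Ap_guess) * np.exp(-theta[0] * t) - A

        sol = least_squares(resid, [kd_guess], bounds=([0.0], [np.inf]), xtol=1e-15, ftol=1e-15)
        names = ["kd"]
    else:
        def resid(theta: np.ndarray) -> np.ndarray:
            kd, A0, Ap = theta
            return Ap + (A0 - Ap) * np.exp(-kd * t) - A

        sol = least_squares(
            resid,
            [kd_guess, A0_guess, Ap_guess],
            bounds=([0.0, -np.inf, -np.inf], [np.inf, np.inf, np.inf]),
            xtol=1e-15,
            ftol=1e-15,
        )
        names = ["kd", "A0", "Ap"]

    if sol.x[0] * (t[-1] - t[0]) < 2.0 * np.log(2.0):
        warnings.append("trace spans fewer than 2 half-lives; kd poorly constrained")
    cov, cov_warn = covariance_from_jacobian(sol.jac, sol.fun, len(names))
    stderr = np.sqrt(np.abs(np.diag(cov))) if cov is not None else np.full(len(names), np.nan)
    return FitResult(
        params=dict(zip(names, sol.x.tolist())),
        stderr=dict(zip(names, stderr.tolist())),
        fixed={"A0": A0_guess, "Ap": Ap_guess} if fix_endpoints else {},
        objective=float(sol.fun @ sol.fun),
        success=bool(sol.success),
        message=sol.message,
        nfev=sol.nfev,
        cov=cov,
        warnings=warnings + cov_warn,
        meta={"model": "ExponentialTraceFit", "n_points": len(t)},
    )


def observed_kd(
    model: KineticRateModel,
    species: SpeciesModel,
    pH: float,
    total_Fe: float,
    total_L: float,
    cdta_M: float = 0.0,
) -> float:
    """Observed pseudo-first-order dissociation rate constant, s^-1.

    Solves speciation with the *kinetic* FeL3 stability constant and the
    hydroxo species excluded, then weights the pathways by the FeL3/FeL2
    mole fractions (renormalised over those two species, which dominate
    under the experimental conditions).
    """
    kin_species = species.with_constants(logK_FeL3=model.logK_FeL3_kin)
    kin_species = replace(kin_species, include_hydroxo=False)
    state = solve_speciation(
        kin_species, SolutionConditions(total_Fe=total_Fe, total_L=total_L, pH=pH)
    )
    c2, c3 = state["FeL2"], state["FeL3"]
    tot = c2 + c3
    if tot <= 0:
        raise ValueError(
            f"no FeL2/FeL3 present at pH={pH}; rate law does not apply"
        )
    x3 = c3 / tot
    x2 = c2 / tot
    h = 10.0 ** (-pH)
    return x3 * model.k0 + x2 * (model.k1 * h + model.k4 * h * cdta_M)


def half_life(kd: float, unit: str = "h") -> float:
    """Dissociation half-life t1/2 = ln 2 / kd, in hours (or seconds)."""
    if kd <= 0:
        raise ValueError("kd must be positive")
    t = np.log(2.0) / kd
    if unit == "s":
        return float(t)
    if unit == "h":
        return float(t / 3600.0)
    raise ValueError("unit must be 'h' or 's'")


def hydroxide_pathway_kd(
    k0: float, kOH: float, kOH2: float, pH: float, pKw: float = 13.77
) -> float:
    """kd for complexes dissociating via hydroxide-assisted pathways.

    kd = k0 + kOH [OH-] + kOH2 [OH-]^2 with [OH-] = 10^(pH - pKw).
    Used for the Fe(EDTA)-/Fe(CDTA)- inertness comparison.
    """
    oh = 10.0 ** (pH - pKw)
    return k0 + kOH * oh + kOH2 * oh * oh


class RateLawFit:
    """Weighted least-squares refinement of the transchelation rate law.

    Construct from a table of (conditions, kd) observations; conditions
    are dicts with keys ``pH``, ``total_Fe``, ``total_L``, ``cdta_M``.
    Rate constants are optimised in log10 space (positivity by
    construction); residuals are relative (kd values span decades).
    """

    _FREE_ALL = ("k0", "k1", "k4", "logK_FeL3_kin")

    def __init__(
        self,
        kd_table: Sequence[tuple[dict, float]],
        model0: KineticRateModel,
        species: SpeciesModel,
        free: Sequence[str] = _FREE_ALL,
    ) -> None:
        unknown = set(free) - set(self._FREE_ALL)
        if unknown:
            raise ValueError(f"unknown free parameters: {sorted(unknown)}")
        if len(kd_table) < len(free):
            raise ValueError("fewer observations than free constants")
        self.kd_table = list(kd_table)
        self.model0 = model0
        self.species = species
        self.free = list(free)
        # identifiability screen: k4 needs CDTA variation
        cdtas = {round(c.get("cdta_M", 0.0), 12) for c, _ in kd_table}
        self._k4_identifiable = len(cdtas) > 1 or any(x > 0 for x in cdtas)

    def _theta_to_model(self, theta: np.ndarray) -> KineticRateModel:
        kwargs = {}
        for name, value in zip(self.free, theta):
            kwargs[name] = value if name == "logK_FeL3_kin" else 10.0**value
        return self.model0.updated(**kwargs)

    def _residuals(self, theta: np.ndarray) -> np.ndarray:
        model = self._theta_to_model(theta)
        out = np.empty(len(self.kd_table))
        for i, (cond, kd_obs) in enumerate(self.kd_table):
            kd = observed_kd(
                model,
                self.species,
                pH=cond["pH"],
                total_Fe=cond.get("total_Fe", 1e-4),
                total_L=cond.get("total_L", 5e-4),
                cdta_M=cond.get("cdta_M", 0.0),
            )
            out[i] = (kd - kd_obs) / kd_obs
        return out

    def fit(self) -> FitResult:
        theta0 = np.array(
            [
                getattr(self.model0, n)
                if n == "logK_FeL3_kin"
                else np.log10(getattr(self.model0, n))
                for n in self.free
            ]
        )
        sol = least_squares(self._residuals, theta0, xtol=1e-15, ftol=1e-15, gtol=1e-15)
        cov, warns = covariance_from_jacobian(sol.jac, sol.fun, theta0.size)
        if "k4" in self.free and not self._k4_identifiable:
            warns.append("k4 unidentifiable: no CDTA variation in the design")
        model = self._theta_to_model(sol.x)
        params = {n: getattr(model, n) for n in self.free}
        # delta-method errors back to linear scale for the log-fitted constants
        stderr = {}
        diag = np.sqrt(np.abs(np.diag(cov))) if cov is not None else np.full(theta0.size, np.nan)
        for i, n in enumerate(self.free):
            if n == "logK_FeL3_kin":
                stderr[n] = float(diag[i])
            else:
                stderr[n] = float(params[n] * np.log(10.0) * diag[i])
        return FitResult(
            params=params,
            stderr=stderr,
            fixed={
                n: getattr(self.model0, n)
                for n in self._FREE_ALL
                if n not in self.free
            },
            objective=float(sol.fun @ sol.fun),
            success=bool(sol.success),
            message=sol.message,
            nfev=sol.nfev,
            cov=cov,
            warnings=warns,
            meta={"model": "RateLawFit", "n_points": len(self.kd_table)},
        )


def refine_rate_constants(
    kd_table: Sequence[tuple[dict, float]],
    model0: KineticRateModel,
    species: SpeciesModel,
    free: Sequence[str] = RateLawFit._FREE_ALL,
) -> FitResult:
    """Functional wrapper over :class:`RateLawFit`."""
    return RateLawFit(kd_table, model0, species, free).fit()
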