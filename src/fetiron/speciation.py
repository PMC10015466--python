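"""Multi-equilibrium speciation of the Fe(III)-Tiron system.

Tiron (4,5-dihydroxy-1,3-benzenedisulfonate, L^4-) binds Fe3+ stepwise to
form [FeL]^-, [FeL2]^5-, and [FeL3]^9-; at 1:2 metal-to-ligand ratios a
mixed hydroxo species [FeL2(OH)]^6- (written FeL2H-1) appears above
pH ~ 7.9.  This module solves the coupled mass balances at fixed pH,
builds species-distribution diagrams, simulates spectrophotometric and
base-volume titrations, and refines equilibrium constants from titration
data.

Conventions
-----------
Protonation constants are stepwise association constants
``K_i^H = [H_iL] / ([H_{i-1}L][H+])``; complex stability constants are
stepwise ``K_FeLx = [FeLx] / ([FeLx-1][L])``; the hydroxo species is
parameterised through the protonation constant
``K_FeL2Hm1 = [FeL2] / ([FeL2H-1][H+])`` so that FeL2H-1 grows above
pH = log10(K_FeL2Hm1).  All constants are concentration constants at the
working ionic strength; no activity corrections are applied.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq, least_squares

from .results import FitResult, covariance_from_jacobian

FE_SPECIES = ("Fe", "FeL", "FeL2", "FeL3", "FeL2Hm1")
LIGAND_SPECIES = ("L", "HL", "H2L")
#: ligand units bound per Fe species
_LIGANDS_PER_FE = {"Fe": 0, "FeL": 1, "FeL2": 2, "FeL3": 3, "FeL2Hm1": 2}


class SpeciationError(RuntimeError):
    """Raised when the mass-balance solver cannot converge."""


@dataclass(frozen=True)
class SpeciesModel:
    """Equilibrium constants defining the Fe(III)-Tiron solution chemistry.

    All constants are decadic logarithms. ``pKw`` is the stoichiometric
    water ionic product, ``pA`` the offset between electrode pH and
    -log[H+] (pH_true = pH_read - pA for measured data).
    """

    logK1H: float = 12.40
    logK2H: float = 7.46
    logK_FeL: float = 20.32
    logK_FeL2: float = 14.49
    logK_FeL3: float = 9.83
    logK_FeL2Hm1: float = 7.86
    pKw: float = 13.77
    pA: float = 0.02
    #: set False to drop the mixed hydroxo species from the model
    include_hydroxo: bool = True

    def __post_init__(self) -> None:
        for name in ("logK1H", "logK2H", "logK_FeL", "logK_FeL2", "logK_FeL3"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.logK1H <= self.logK2H:
            raise ValueError("first ligand protonation must be stronger: logK1H > logK2H")

    @property
    def logbeta2(self) -> float:
        return self.logK_FeL + self.logK_FeL2

    @property
    def logbeta3(self) -> float:
        return self.logbeta2 + self.logK_FeL3

    def with_constants(self, **kwargs: float) -> "SpeciesModel":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class SolutionConditions:
    """Total concentrations and pH of one solution.

    temperature and ionic_strength are metadata only (constants are
    concentration constants at fixed ionic strength).
    """

    total_Fe: float
    total_L: float
    pH: float
    temperature: float = 298.15
    ionic_strength: float = 0.15

    def __post_init__(self) -> None:
        if self.total_Fe < 0 or self.total_L < 0:
            raise ValueError("total concentrations must be non-negative")
        if not np.isfinite(self.pH):
            raise ValueError("pH must be finite")


@dataclass(frozen=True)
class SpeciationState:
    """Solved equilibrium concentrations (mol/L) and Fe mole fractions."""

    concentrations: dict[str, float]
    fe_fractions: dict[str, float]
    conditions: SolutionConditions

    def __getitem__(self, species: str) -> float:
        return self.concentrations[species]

    def fraction(self, species: str) -> float:
        return self.fe_fractions[species]


def _beta_terms(model: SpeciesModel, h: float) -> tuple[float, float, float, float, float]:
    """Return (alpha_H, beta1, beta2, beta3, hydroxo factor) at [H+] = h."""
    K1H = 10.0 ** model.logK1H
    K2H = 10.0 ** model.logK2H
    alpha_H = 1.0 + K1H * h + K1H * K2H * h * h
    beta1 = 10.0 ** model.logK_FeL
    beta2 = 10.0 ** model.logbeta2
    beta3 = 10.0 ** model.logbeta3
    hx = 1.0 / (10.0 ** model.logK_FeL2Hm1 * h) if model.include_hydroxo else 0.0
    return alpha_H, beta1, beta2, beta3, hx


def solve_speciation(model: SpeciesModel, cond: SolutionConditions) -> SpeciationState:
    """Solve the coupled Fe/ligand mass balances at fixed [H+] = 10^-pH.

    The iron balance is linear in free [Fe3+] at given free ligand, so
    [Fe3+] is eliminated exactly and a single monotone equation in
    log10[L4-] remains; it is bracketed on [-40, 0] and solved by Brent's
    method, which guarantees a positive root.
    """
    h = 10.0 ** (-cond.pH)
    alpha_H, b1, b2, b3, hx = _beta_terms(model, h)
    FeT, LT = cond.total_Fe, cond.total_L

    if LT == 0.0:
        conc = {s: 0.0 for s in LIGAND_SPECIES + FE_SPECIES}
        conc["Fe"] = FeT
        fracs = _fe_fractions(conc, FeT)
        return SpeciationState(conc, fracs, cond)

    def fe_free(l: float) -> float:
        if FeT == 0.0:
            return 0.0
        return FeT / (1.0 + b1 * l + b2 * l * l * (1.0 + hx) + b3 * l**3)

    def ligand_residual(logl: float) -> float:
        l = 10.0 ** logl
        fe = fe_free(l)
        bound = fe * (b1 * l + 2.0 * b2 * l * l * (1.0 + hx) + 3.0 * b3 * l**3)
        return l * alpha_H + bound - LT

    lo, hi = -40.0, 0.0
    try:
        if ligand_residual(lo) > 0 or ligand_residual(hi) < 0:
            raise ValueError("root not bracketed")
        logl = brentq(ligand_residual, lo, hi, xtol=1e-15, rtol=8.9e-16, maxiter=200)
    except ValueError as exc:  # pragma: no cover - defensive
        raise SpeciationError(
            f"speciation solver failed at pH={cond.pH}, total_Fe={FeT}, total_L={LT}: {exc}"
        ) from exc

    l = 10.0 ** logl
    fe = fe_free(l)
    K1H = 10.0 ** model.logK1H
    K2H = 10.0 ** model.logK2H
    conc = {
        "L": l,
        "HL": K1H * h * l,
        "H2L": K1H * K2H * h * h * l,
        "Fe": fe,
        "FeL": b1 * l * fe,
        "FeL2": b2 * l * l * fe,
        "FeL3": b3 * l**3 * fe,
        "FeL2Hm1": b2 * l * l * fe * hx,
    }
    return SpeciationState(conc, _fe_fractions(conc, FeT), cond)


def _fe_fractions(conc: dict[str, float], FeT: float) -> dict[str, float]:
    if FeT <= 0.0:
        return {s: 0.0 for s in FE_SPECIES}
    return {s: conc.get(s, 0.0) / FeT for s in FE_SPECIES}


def distribution_curve(
    model: SpeciesModel,
    total_Fe: float,
    total_L: float,
    pH_grid: Sequence[float],
) -> pd.DataFrame:
    """Fe mole fractions and free-species concentrations along a pH grid.

    Returns a DataFrame with one row per pH, the Fe mole fraction of each
    Fe-containing species, and the free ligand concentration.
    """
    pH_grid = np.asarray(pH_grid, dtype=float)
    if pH_grid.ndim != 1 or np.any(np.diff(pH_grid) <= 0):
        raise ValueError("pH_grid must be 1-D and strictly increasing")
    rows = []
    for pH in pH_grid:
        try:
            state = solve_speciation(
                model, SolutionConditions(total_Fe=total_Fe, total_L=total_L, pH=float(pH))
            )
        except SpeciationError as exc:
            raise SpeciationError(f"distribution_curve failed at pH={pH}") from exc
        row = {"pH": pH, "free_L": state["L"]}
        for s in FE_SPECIES:
            row[f"x_{s}"] = state.fraction(s)
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class TitrationDataset:
    """A titration dataset: absorbance vs pH or base volume vs pH.

    For absorbance data, ``molar_absorptivities`` maps species name ->
    {wavelength_nm: epsilon (L mol^-1 cm^-1)}; every species with a
    non-negligible concentration and a missing epsilon raises when
    simulated.  ``conditions`` fixes the totals; the independent variable
    is pH (already corrected for the electrode offset pA).
    """

    pH: np.ndarray
    observable: np.ndarray
    observable_kind: Literal["absorbance", "base_volume"]
    total_Fe: float
    total_L: float
    wavelength: float | None = None
    molar_absorptivities: dict[str, dict[float, float]] = field(default_factory=dict)
    path_length: float = 1.0
    sigma: np.ndarray | None = None
    #: base-volume titration setup (mol/L and L)
    titrant_conc: float = 0.1
    initial_volume: float = 6e-3
    initial_acid: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "pH", np.asarray(self.pH, dtype=float))
        object.__setattr__(self, "observable", np.asarray(self.observable, dtype=float))
        if self.pH.shape != self.observable.shape:
            raise ValueError("pH and observable must have the same shape")
        if np.any(np.diff(self.pH) <= 0):
            raise ValueError("points must be sorted by increasing pH")
        for sp, eps in self.molar_absorptivities.items():
            if any(e < 0 for e in eps.values()):
                raise ValueError(f"negative molar absorptivity for {sp}")


#: species that absorb in the visible charge-transfer band
ABSORBING_SPECIES = ("FeL", "FeL2", "FeL3", "FeL2Hm1")


def simulate_absorbance(
    model: SpeciesModel,
    pH: np.ndarray,
    total_Fe: float,
    total_L: float,
    epsilons: dict[str, float],
    path_length: float = 1.0,
) -> np.ndarray:
    """Beer-Lambert absorbance A(pH) = l * sum_s eps_s [s] at one wavelength.

    ``epsilons`` maps species name -> epsilon (L mol^-1 cm^-1); species
    absent from the table but present above 1e-12 of total Fe raise a
    validation error unless their epsilon is zero by omission of the
    whole table entry.
    """
    pH = np.asarray(pH, dtype=float)
    A = np.zeros_like(pH)
    for i, p in enumerate(pH):
        state = solve_speciation(model, SolutionConditions(total_Fe, total_L, float(p)))
        a = 0.0
        for sp in ABSORBING_SPECIES:
            c = state[sp]
            if sp in epsilons:
                a += epsilons[sp] * c
            elif total_Fe > 0 and c > 1e-6 * total_Fe:
                raise ValueError(
                    f"species {sp} present ({c:.3g} M) but has no molar absorptivity"
                )
        A[i] = path_length * a
    return A


def simulate_base_volume(
    model: SpeciesModel,
    pH: np.ndarray,
    total_Fe0: float,
    total_L0: float,
    initial_acid: float,
    titrant_conc: float,
    initial_volume: float,
) -> np.ndarray:
    """Base volume (L) needed to reach each pH in a potentiometric titration.

    Proton bookkeeping relative to the fully deprotonated ligand L^4-:
    the ligand is delivered as H2L (catechol protons on), so the total
    dissociable proton content is ``initial_acid + 2*total_L0`` (mol/L in
    the initial volume).  At each pH the proton balance

        n_H(total) - n_base = V * ([H+] - [OH-] + [HL] + 2[H2L] - [FeL2H-1])

    is solved for the added volume, accounting for dilution.
    """
    pH = np.asarray(pH, dtype=float)
    V0 = initial_volume
    n_H0 = (initial_acid + 2.0 * total_L0) * V0
    n_Fe0 = total_Fe0 * V0
    n_L0 = total_L0 * V0
    Kw = 10.0 ** (-model.pKw)
    out = np.empty_like(pH)

    for i, p in enumerate(pH):
        h = 10.0 ** (-p)
        oh = Kw / h

        def residual(vb: float) -> float:
            V = V0 + vb
            state = solve_speciation(
                model, SolutionConditions(n_Fe0 / V, n_L0 / V, float(p))
            )
            bound_H = state["HL"] + 2.0 * state["H2L"] - state["FeL2Hm1"]
            return (n_H0 - titrant_conc * vb) - V * (h - oh + bound_H)

        lo, hi = 0.0, max(10.0 * V0, 2.0 * n_H0 / titrant_conc)
        if residual(lo) < 0:
            out[i] = 0.0
            continue
        out[i] = brentq(residual, lo, hi, xtol=1e-15)
    return out


def simulate_observable(model: SpeciesModel, dataset: TitrationDataset) -> np.ndarray:
    """Forward-model the observable of a titration dataset."""
    if dataset.observable_kind == "absorbance":
        if dataset.wavelength is None:
            raise ValueError("absorbance dataset needs a wavelength")
        eps = {
            sp: table[dataset.wavelength]
            for sp, table in dataset.molar_absorptivities.items()
            if dataset.wavelength in table
        }
        return simulate_absorbance(
            model, dataset.pH, dataset.total_Fe, dataset.total_L, eps, dataset.path_length
        )
    return simulate_base_volume(
        model,
        dataset.pH,
        dataset.total_Fe,
        dataset.total_L,
        dataset.initial_acid,
        dataset.titrant_conc,
        dataset.initial_volume,
    )


_REFINABLE = (
    "logK1H",
    "logK2H",
    "logK_FeL",
    "logK_FeL2",
    "logK_FeL3",
    "logK_FeL2Hm1",
)


class TitrationFit:
    """Least-squares refinement of equilibrium constants from titrations.

    statsmodels-style model object: construct from one or more
    :class:`TitrationDataset` plus a starting :class:`SpeciesModel`, name
    the constants to free, call :meth:`fit`.

    Parameters
    ----------
    datasets : list of TitrationDataset
    model0 : SpeciesModel
        Starting model; fixed constants keep these values.
    free : sequence of str
        Names of logK constants to refine (subset of the SpeciesModel
        constants).
    free_epsilons : sequence of (species, wavelength) tuples, optional
        Molar absorptivities to refine alongside the constants.
    """

    def __init__(
        self,
        datasets: Sequence[TitrationDataset],
        model0: SpeciesModel,
        free: Sequence[str],
        free_epsilons: Sequence[tuple[str, float]] = (),
    ) -> None:
        if not datasets:
            raise ValueError("need at least one dataset")
        unknown = set(free) - set(_REFINABLE)
        if unknown:
            raise ValueError(f"unknown constants in free mask: {sorted(unknown)}")
        self.datasets = list(datasets)
        self.model0 = model0
        self.free = list(free)
        self.free_epsilons = list(free_epsilons)

    def _apply(self, theta: np.ndarray) -> tuple[SpeciesModel, list[TitrationDataset]]:
        model = self.model0.with_constants(
            **{name: theta[i] for i, name in enumerate(self.free)}
        )
        datasets = self.datasets
        if self.free_epsilons:
            datasets = []
            k = len(self.free)
            for ds in self.datasets:
                eps = {sp: dict(tbl) for sp, tbl in ds.molar_absorptivities.items()}
                for j, (sp, wl) in enumerate(self.free_epsilons):
                    if sp in eps and wl in eps[sp]:
                        eps[sp][wl] = theta[k + j]
                datasets.append(replace(ds, molar_absorptivities=eps))
        return model, datasets

    def _residuals(self, theta: np.ndarray) -> np.ndarray:
        model, datasets = self._apply(theta)
        res = []
        for ds in datasets:
            sim = simulate_observable(model, ds)
            w = 1.0 / ds.sigma if ds.sigma is not None else 1.0
            res.append((sim - ds.observable) * w)
        return np.concatenate(res)

    def fit(self) -> FitResult:
        theta0 = np.array(
            [getattr(self.model0, n) for n in self.free]
            + [
                self.datasets[0].molar_absorptivities[sp][wl]
                for sp, wl in self.free_epsilons
            ]
        )
        names = self.free + [f"eps_{sp}_{wl:g}" for sp, wl in self.free_epsilons]
        n_points = sum(ds.pH.size for ds in self.datasets)
        if theta0.size == 0:
            r = self._residuals(theta0)
            return FitResult(
                params={},
                stderr={},
                fixed=_fixed_record(self.model0, self.free),
                objective=float(r @ r),
                success=True,
                message="no free parameters; objective evaluated at model0",
                meta={"model": "TitrationFit", "n_points": n_points},
            )
        sol = least_squares(self._residuals, theta0, method="lm", xtol=1e-14, ftol=1e-14)
        cov, warns = covariance_from_jacobian(sol.jac, sol.fun, theta0.size)
        stderr = np.sqrt(np.abs(np.diag(cov))) if cov is not None else np.full(theta0.size, np.nan)
        return FitResult(
            params=dict(zip(names, sol.x.tolist())),
            stderr=dict(zip(names, stderr.tolist())),
            fixed=_fixed_record(self.model0, self.free),
            objective=float(sol.fun @ sol.fun),
            success=bool(sol.success),
            message=sol.message,
            nfev=sol.nfev,
            cov=cov,
            warnings=warns,
            meta={"model": "TitrationFit", "n_points": n_points},
        )


def _fixed_record(model: SpeciesModel, free: Sequence[str]) -> dict[str, float]:
    return {
        n: getattr(model, n) for n in _REFINABLE + ("pKw", "pA") if n not in free
    }


def refine_constants(
    datasets: Sequence[TitrationDataset],
    model0: SpeciesModel,
    free: Sequence[str],
    free_epsilons: Sequence[tuple[str, float]] = (),
) -> FitResult:
    """Functional wrapper over :class:`TitrationFit`."""
    return TitrationFit(datasets, model0, free, free_epsilons).fit()
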