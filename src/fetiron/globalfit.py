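"""Simultaneous fitting of 1H NMRD profiles and 17O NMR data.

A single parameter vector — the union of the 1H relaxivity parameters
(:class:`~fetiron.relaxometry.RelaxParams`) and the 17O parameters
(:class:`~fetiron.oxygen17.O17Params`) — is refined against any number
of multi-temperature NMRD profiles and reduced-17O datasets at once.
tau_M, its exchange enthalpy and the electron-relaxation parameters are
shared between the two branches, which is what makes the combination
informative: 17O pins the exchange and hyperfine parameters while the
NMRD profile shapes constrain rotation and electron relaxation.

The model object follows the statsmodels convention:
``GlobalRelaxationFit(...).fit(seed=...)`` returns a
:class:`GlobalFitResults` carrying estimates, 1-sigma uncertainties from
the Jacobian-based covariance, residual tables and a ``summary()``.
Optimisation is bounded nonlinear least squares with a seeded
multi-start scheme (the provided initial vector plus log-uniform draws
within bounds), so a fit is deterministic given its seed.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .datasets import NMRDDataset, O17Dataset
from .oxygen17 import O17Params, o17_curve
from .relaxometry import RelaxParams, nmrd_profile
from .results import FitResult, covariance_from_jacobian

__all__ = ["GlobalRelaxationFit", "GlobalFitResults", "SHARED_PARAMS"]

#: parameters shared between the 1H and 17O branches
SHARED_PARAMS = ("tauM298_s", "dH_M", "Delta2_s2", "E_Delta", "tauv298_ps", "E_v")

#: parameters optimised on a log10 scale (positive by construction)
_LOG_SCALE = {
    "tauR298_ps",
    "tauM298_s",
    "Delta2_s2",
    "tauv298_ps",
    "tauR_SS298_ps",
    "tauM_SS_s",
    "D298_m2s",
    "r_MH_A",
    "r_SS_A",
    "a_A",
}
#: magnitude optimised on log10 scale, sign frozen at the initial sign
_SIGNED_LOG = {"A_O_over_hbar"}

_RELAX_FIELDS = set(RelaxParams.__dataclass_fields__)
_O17_FIELDS = set(O17Params.__dataclass_fields__)


@dataclass
class GlobalFitResults(FitResult):
    """FitResult plus the best-fit parameter objects."""

    relax_params: RelaxParams | None = None
    o17_params: O17Params | None = None

    def predict_nmrd(self, freqs_MHz: np.ndarray, T: float) -> np.ndarray:
        return nmrd_profile(self.relax_params, freqs_MHz, T)

    def predict_o17(self, temperatures: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return o17_curve(self.o17_params, temperatures)


class GlobalRelaxationFit:
    """Joint model for NMRD profiles and 17O datasets with shared parameters.

    Parameters
    ----------
    nmrd : sequence of NMRDDataset
    o17 : sequence of O17Dataset
    relax0 : RelaxParams
        Starting 1H parameters; fixed parameters keep these values.
    o17_0 : O17Params, optional
        Starting 17O parameters (required when 17O data are supplied).
        Shared fields are taken from ``relax0`` and kept consistent.
    free : sequence of str
        Field names to refine (union of RelaxParams/O17Params fields).
    bounds : dict, optional
        ``name -> (lo, hi)`` in natural units; defaults to one decade
        around the start for log-scale parameters and +/- a factor of 3
        spread for linear ones.
    weights : dict, optional
        Per-dataset-label weights multiplying the default normalisation
        (each dataset's residuals are divided by its mean observed
        magnitude so 1H and 17O blocks contribute comparably).
    n_starts : int
        Multi-start count (start 0 is the provided initial vector).
    """

    def __init__(
        self,
        nmrd: Sequence[NMRDDataset],
        o17: Sequence[O17Dataset],
        relax0: RelaxParams,
        o17_0: O17Params | None = None,
        free: Sequence[str] = ("Delta2_s2", "tauv298_ps", "tauR298_ps"),
        bounds: dict[str, tuple[float, float]] | None = None,
        weights: dict[str, float] | None = None,
        n_starts: int = 8,
    ) -> None:
        if not nmrd and not o17:
            raise ValueError("need at least one dataset")
        if o17 and o17_0 is None:
            raise ValueError("o17_0 required when 17O datasets are supplied")
        unknown = set(free) - (_RELAX_FIELDS | _O17_FIELDS)
        if unknown:
            raise ValueError(f"unknown parameters in free mask: {sorted(unknown)}")
        self.nmrd = list(nmrd)
        self.o17 = list(o17)
        self.relax0 = relax0
        self.o17_0 = o17_0
        self.free = list(free)
        self.weights = weights or {}
        self.n_starts = n_starts
        self._user_bounds = bounds or {}
        self._start = self._initial_values()
        self._signs = {
            n: np.sign(self._start[n]) or 1.0 for n in self.free if n in _SIGNED_LOG
        }
        self._pre_warnings: list[str] = []
        if (
            relax0.q == 0
            and not self.o17
            and any(n in ("tauM298_s", "A_O_over_hbar", "dH_M") for n in self.free)
        ):
            self._pre_warnings.append(
                "q = 0 with no 17O data: exchange/hyperfine parameters are "
                "unconstrained and should be fixed"
            )

    # -- parameter plumbing -------------------------------------------------

    def _initial_values(self) -> dict[str, float]:
        vals = {}
        for n in self.free:
            if n in _RELAX_FIELDS:
                vals[n] = float(getattr(self.relax0, n))
            else:
                vals[n] = float(getattr(self.o17_0, n))
        return vals

    def _default_bounds(self, name: str) -> tuple[float, float]:
        x0 = self._start[name]
        if name in _LOG_SCALE:
            return (x0 / 10.0, x0 * 10.0)
        if name in _SIGNED_LOG:
            m = abs(x0)
            return tuple(sorted((np.sign(x0) * m / 10.0, np.sign(x0) * m * 10.0)))
        spread = 3.0 * max(abs(x0), 1.0)
        return (x0 - spread, x0 + spread)

    def _internal(self, name: str, x: float) -> float:
        if name in _LOG_SCALE:
            return np.log10(x)
        if name in _SIGNED_LOG:
            return np.log10(abs(x))
        return x

    def _natural(self, name: str, u: float) -> float:
        if name in _LOG_SCALE:
            return 10.0**u
        if name in _SIGNED_LOG:
            return self._signs[name] * 10.0**u
        return u

    def _apply(self, theta: np.ndarray) -> tuple[RelaxParams, O17Params | None]:
        vals = {n: self._natural(n, theta[i]) for i, n in enumerate(self.free)}
        relax = self.relax0.updated(
            **{n: v for n, v in vals.items() if n in _RELAX_FIELDS}
        )
        o17p = None
        if self.o17_0 is not None:
            o17p = self.o17_0.updated(
                **{n: v for n, v in vals.items() if n in _O17_FIELDS}
            )
            # keep shared parameters consistent with the 1H branch
            o17p = o17p.updated(
                **{n: getattr(relax, n) for n in SHARED_PARAMS}
            )
        return relax, o17p

    # -- objective ----------------------------------------------------------

    def _residual_blocks(
        self, theta: np.ndarray
    ) -> dict[str, np.ndarray]:
        relax, o17p = self._apply(theta)
        blocks: dict[str, np.ndarray] = {}
        for i, ds in enumerate(self.nmrd):
            label = ds.label or f"nmrd{i}"
            model = nmrd_profile(relax, ds.freq_MHz, ds.temperature_K)
            scale = ds.sigma if ds.sigma is not None else np.mean(np.abs(ds.r1))
            w = self.weights.get(label, 1.0)
            blocks[label] = w * (model - ds.r1) / scale
        for i, ds in enumerate(self.o17):
            label = ds.label or f"o17_{i}"
            R2r, dOm = o17_curve(o17p, ds.temperature_K)
            s_r = ds.sigma_R2r if ds.sigma_R2r is not None else np.mean(np.abs(ds.R2r))
            s_d = (
                ds.sigma_dOmega_r
                if ds.sigma_dOmega_r is not None
                else np.mean(np.abs(ds.dOmega_r))
            )
            w = self.weights.get(label, 1.0)
            blocks[f"{label}:R2r"] = w * (R2r - ds.R2r) / s_r
            blocks[f"{label}:shift"] = w * (dOm - ds.dOmega_r) / s_d
        return blocks

    def objective(self, theta_natural: dict[str, float] | None = None) -> float:
        """Sum of weighted squared residuals at a parameter point.

        With no argument, evaluates at the starting values.
        """
        vals = dict(self._start)
        if theta_natural:
            vals.update(theta_natural)
        theta = np.array([self._internal(n, vals[n]) for n in self.free])
        r = np.concatenate(list(self._residual_blocks(theta).values()))
        return float(r @ r)

    def _flat_residuals(self, theta: np.ndarray) -> np.ndarray:
        return np.concatenate(list(self._residual_blocks(theta).values()))

    # -- fitting ------------------------------------------------------------

    def fit(self, seed: int = 0) -> GlobalFitResults:
        """Bounded multi-start least squares; deterministic given seed."""
        n_points = sum(len(d) for d in self.nmrd) + 2 * sum(len(d) for d in self.o17)
        if not self.free:
            r = self._flat_residuals(np.empty(0))
            relax, o17p = self._apply(np.empty(0))
            return GlobalFitResults(
                params={},
                stderr={},
                fixed=self._fixed_record(),
                objective=float(r @ r),
                success=True,
                message="no free parameters; objective evaluated at the inputs",
                relax_params=relax,
                o17_params=o17p,
                meta={"model": "GlobalRelaxationFit", "n_points": n_points},
            )

        lo = np.empty(len(self.free))
        hi = np.empty(len(self.free))
        for i, n in enumerate(self.free):
            b0, b1 = self._user_bounds.get(n, self._default_bounds(n))
            u0, u1 = self._internal(n, b0), self._internal(n, b1)
            lo[i], hi[i] = min(u0, u1), max(u0, u1)
        theta0 = np.array([self._internal(n, self._start[n]) for n in self.free])
        theta0 = np.clip(theta0, lo, hi)

        rng = np.random.default_rng(seed)
        starts = [theta0] + [
            lo + rng.random(len(self.free)) * (hi - lo)
            for _ in range(max(self.n_starts - 1, 0))
        ]

        best = None
        for s in starts:
            sol = least_squares(
                self._flat_residuals,
                s,
                bounds=(lo, hi),
                xtol=1e-12,
                ftol=1e-12,
                gtol=1e-12,
            )
            if best is None or sol.cost < best.cost - 1e-15:
                best = sol

        cov_int, warns = covariance_from_jacobian(best.jac, best.fun, theta0.size)
        # delta method back to natural units
        grad = np.array(
            [
                self._natural(n, best.x[i]) * np.log(10.0)
                if (n in _LOG_SCALE or n in _SIGNED_LOG)
                else 1.0
                for i, n in enumerate(self.free)
            ]
        )
        cov_nat = cov_int * np.outer(grad, grad) if cov_int is not None else None
        stderr = (
            np.sqrt(np.abs(np.diag(cov_nat)))
            if cov_nat is not None
            else np.full(theta0.size, np.nan)
        )
        relax, o17p = self._apply(best.x)
        params = {n: self._natural(n, best.x[i]) for i, n in enumerate(self.free)}
        blocks = self._residual_blocks(best.x)
        return GlobalFitResults(
            params=params,
            stderr={n: abs(float(s)) for n, s in zip(self.free, stderr)},
            fixed=self._fixed_record(),
            objective=float(best.fun @ best.fun),
            success=bool(best.success),
            message=best.message,
            nfev=best.nfev,
            cov=cov_nat,
            residuals=blocks,
            warnings=self._pre_warnings + warns,
            relax_params=relax,
            o17_params=o17p,
            meta={
                "model": "GlobalRelaxationFit",
                "n_points": n_points,
                "seed": seed,
                "n_starts": self.n_starts,
            },
        )

    def _fixed_record(self) -> dict[str, float]:
        fixed = {}
        for n in sorted(_RELAX_FIELDS):
            if n not in self.free:
                fixed[n] = getattr(self.relax0, n)
        if self.o17_0 is not None:
            for n in sorted(_O17_FIELDS - set(SHARED_PARAMS)):
                if n not in self.free:
                    fixed[f"o17.{n}"] = getattr(self.o17_0, n)
        return fixed
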