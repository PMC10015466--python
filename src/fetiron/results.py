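"""Shared fit-result container used by every Model.fit() in the package."""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np


@dataclass
class FitResult:
    """Best-fit parameter values with uncertainties and diagnostics.

    Attributes
    ----------
    params : dict
        Best-fit values of the *free* parameters.
    stderr : dict
        1-sigma uncertainties of the free parameters, from the
        Jacobian-based covariance at the optimum (NaN where the
        covariance is singular).
    fixed : dict
        Record of every parameter held fixed during the fit, for
        provenance.
    objective : float
        Sum of weighted squared residuals at the optimum.
    success : bool
        Convergence flag. On failure the best-so-far values are still
        reported.
    message : str
        Solver message.
    nfev : int
        Number of model evaluations.
    cov : ndarray or None
        Covariance matrix of the free parameters (order of ``params``).
    residuals : dict
        Per-dataset weighted residual arrays.
    warnings : list of str
        Rank-deficiency and identifiability warnings raised during the
        fit.
    """

    params: dict[str, float]
    stderr: dict[str, float]
    fixed: dict[str, Any]
    objective: float
    success: bool
    message: str = ""
    nfev: int = 0
    cov: np.ndarray | None = None
    residuals: dict[str, np.ndarray] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    meta: dict[str, Any] = field(default_factory=dict)

    def summary(self) -> str:
        """Formatted summary table of the fit."""
        lines = []
        title = self.meta.get("model", "Fit")
        lines.append(f"{title} results")
        lines.append("=" * 58)
        lines.append(f"{'converged':<22}{self.success}")
        lines.append(f"{'objective':<22}{self.objective:.6g}")
        lines.append(f"{'n model evaluations':<22}{self.nfev}")
        npts = self.meta.get("n_points")
        if npts is not None:
            lines.append(f"{'n data points':<22}{npts}")
        lines.append("-" * 58)
        lines.append(f"{'parameter':<22}{'value':>14}{'std err':>14}")
        for name, value in self.params.items():
            se = self.stderr.get(name, float("nan"))
            lines.append(f"{name:<22}{value:>14.6g}{se:>14.3g}")
        if self.fixed:
            lines.append("-" * 58)
            lines.append("fixed:")
            for name, value in self.fixed.items():
                if isinstance(value, (int, float)):
                    lines.append(f"  {name:<20}{value:>14.6g}")
                else:
                    lines.append(f"  {name:<20}{value!r:>14}")
        for w in self.warnings:
            lines.append(f"WARNING: {w}")
        return "\n".join(lines)


def covariance_from_jacobian(
    jac: np.ndarray, residuals: np.ndarray, n_params: int
) -> tuple[np.ndarray | None, list[str]]:
    """Covariance of the estimates from the Jacobian at the optimum.

    Scales J^T J inverse by the residual variance; returns (cov, warnings).
    A rank-deficient Jacobian yields a pseudo-inverse covariance and a
    warning naming the deficiency.
    """
    warnings: list[str] = []
    m, n = jac.shape
    dof = max(m - n_params, 1)
    s2 = float(residuals @ residuals) / dof
    u, s, vt = np.linalg.svd(jac, full_matrices=False)
    tol = np.finfo(float).eps * max(m, n) * (s[0] if s.size else 0.0)
    rank = int(np.sum(s > tol))
    if rank < n:
        warnings.append(
            f"rank-deficient Jacobian (rank {rank} < {n} free parameters); "
            "some parameters are not identifiable from the data"
        )
    with np.errstate(divide="ignore"):
        s_inv2 = np.where(s > tol, 1.0 / s**2, 0.0)
    cov = (vt.T * s_inv2) @ vt * s2
    return cov, warnings
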