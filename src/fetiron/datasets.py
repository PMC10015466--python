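"""Typed measurement containers: NMRD profiles, 17O series, kinetic traces.

Titration data live in :mod:`fetiron.speciation` next to their forward
model.  All containers wrap plain numpy arrays plus the metadata needed
by the forward models, and validate on construction.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np


@dataclass(frozen=True)
class NMRDDataset:
    """A 1H NMRD profile: r1 vs proton Larmor frequency at one temperature."""

    freq_MHz: np.ndarray
    temperature_K: float
    r1: np.ndarray
    sigma: np.ndarray | None = None
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "freq_MHz", np.asarray(self.freq_MHz, dtype=float))
        object.__setattr__(self, "r1", np.asarray(self.r1, dtype=float))
        if self.freq_MHz.shape != self.r1.shape:
            raise ValueError("freq_MHz and r1 must have the same shape")
        if np.any(self.freq_MHz <= 0):
            raise ValueError("frequencies must be positive")
        if self.sigma is not None:
            object.__setattr__(self, "sigma", np.asarray(self.sigma, dtype=float))

    def __len__(self) -> int:
        return self.freq_MHz.size


@dataclass(frozen=True)
class O17Dataset:
    """Reduced 17O rates and shifts vs temperature at fixed field."""

    temperature_K: np.ndarray
    R2r: np.ndarray
    dOmega_r: np.ndarray
    B0_T: float = 11.74
    sigma_R2r: np.ndarray | None = None
    sigma_dOmega_r: np.ndarray | None = None
    label: str = ""

    def __post_init__(self) -> None:
        for name in ("temperature_K", "R2r", "dOmega_r"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (self.temperature_K.shape == self.R2r.shape == self.dOmega_r.shape):
            raise ValueError("temperature_K, R2r and dOmega_r must share a shape")
        if np.any(self.R2r <= 0):
            raise ValueError("reduced rates must be positive")

    def __len__(self) -> int:
        return self.temperature_K.size


@dataclass(frozen=True)
class KineticTrace:
    """Absorbance decay of one transchelation run under pseudo-first-order
    conditions.

    ``conditions`` carries pH, total CDTA, Fe and Tiron concentrations
    (mol/L).  The pseudo-first-order flag requires at least a 20-fold
    CDTA excess over Fe.
    """

    times_s: np.ndarray
    absorbance: np.ndarray
    conditions: dict[str, Any] = field(default_factory=dict)
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "times_s", np.asarray(self.times_s, dtype=float))
        object.__setattr__(self, "absorbance", np.asarray(self.absorbance, dtype=float))
        if self.times_s.shape != self.absorbance.shape:
            raise ValueError("times and absorbances must share a shape")
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def pseudo_first_order(self) -> bool:
        """True when [CDTA] >= 20 [Fe] (valid pseudo-first-order excess)."""
        cdta = self.conditions.get("cdta_M")
        fe = self.conditions.get("fe_M")
        if cdta is None or fe is None or fe == 0:
            return False
        return cdta >= 20.0 * fe

    def __len__(self) -> int:
        return self.times_s.size
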