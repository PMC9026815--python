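"""Exchange-energy estimation from ees-vs-eeg data.

The procedure: simulate an ees(eeg) isotherm at each exchange energy on a
grid, score each against the observed data with an unweighted sum of squared
residuals (chi-square), fit a cubic polynomial to chi2(exchange energy) and
take the interior minimum of the cubic as the best estimate.

Common random numbers are used across the grid (the same per-point seeds for
every exchange energy), so chi2 varies smoothly with the exchange energy and
the cubic fit is stable.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .lattice import ModelParams
from .mc import IsothermResult, MCSettings, isotherm_scan

logger = logging.getLogger(__name__)

__all__ = [
    "ExperimentDataset",
    "FitResult",
    "chi_square",
    "exchange_energy_scan",
    "cubic_fit_minimum",
    "fit_exchange_energy",
]


@dataclass(frozen=True)
class ExperimentDataset:
    """Rows of (gas-phase ee, observed surface ee), real or synthetic.

    Rows are stored sorted by ``eeg`` (order is irrelevant to the fit).
    ``metadata`` carries provenance: temperature, label, and generator
    parameters for synthetic data.
    """

    eeg: tuple[float, ...]
    ees_obs: tuple[float, ...]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.eeg) != len(self.ees_obs):
            raise ValueError("eeg and ees_obs must have equal length")
        if len(self.eeg) == 0:
            raise ValueError("dataset must be non-empty")
        g = np.asarray(self.eeg, dtype=float)
        s = np.asarray(self.ees_obs, dtype=float)
        if (np.abs(g) > 1).any() or (np.abs(s) > 1).any():
            raise ValueError("eeg and ees values must lie in [-1, 1]")
        if np.unique(g).size != g.size:
            raise ValueError("eeg values must be unique")
        order = np.argsort(g)
        object.__setattr__(self, "eeg", tuple(float(x) for x in g[order]))
        object.__setattr__(self, "ees_obs", tuple(float(x) for x in s[order]))

    def __len__(self) -> int:
        return len(self.eeg)

    def to_csv(self, path) -> None:
        pd.DataFrame({"eeg": self.eeg, "ees": self.ees_obs}).to_csv(
            path, index=False, float_format="%.17g"
        )

    @classmethod
    def from_csv(cls, path, metadata: dict | None = None) -> "ExperimentDataset":
        df = pd.read_csv(path, float_precision="round_trip")
        if not {"eeg", "ees"} <= set(df.columns):
            raise ValueError("dataset CSV must have columns 'eeg' and 'ees'")
        return cls(
            eeg=tuple(df["eeg"].astype(float)),
            ees_obs=tuple(df["ees"].astype(float)),
            metadata=dict(metadata or {}),
        )


@dataclass(frozen=True)
class FitResult:
    """chi2 over an exchange-energy grid plus the cubic-minimum estimate.

    ``grid`` and ``best_exchange_energy`` are in J/mol.  The cubic
    coefficients are for chi2 as a polynomial in the exchange energy in
    kJ/mol (highest power first), matching the scale on which the fit is
    performed.
    """

    grid: tuple[float, ...]
    chi_square: tuple[float, ...]
    cubic_coefficients: tuple[float, float, float, float] | None = None
    best_exchange_energy: float | None = None
    boundary_flag: bool = False

    def __post_init__(self) -> None:
        if len(self.grid) != len(self.chi_square):
            raise ValueError("grid and chi_square must have equal length")
        if len(self.grid) < 4:
            raise ValueError("grid must have >= 4 points (cubic fit)")
        g = np.asarray(self.grid)
        if not (np.diff(g) > 0).all():
            raise ValueError("grid must be strictly increasing")
        if (np.asarray(self.chi_square) < 0).any():
            raise ValueError("chi_square values must be >= 0")
        if (
            self.best_exchange_energy is not None
            and not self.boundary_flag
            and not (g[0] <= self.best_exchange_energy <= g[-1])
        ):
            raise ValueError("interior minimum must lie within the grid range")

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "exch_energy_kj_mol": np.asarray(self.grid) / 1000.0,
                "chi_square": self.chi_square,
            }
        ).to_csv(path, index=False)

    def summary(self) -> dict:
        return {
            "grid_j_mol": list(self.grid),
            "chi_square": list(self.chi_square),
            "cubic_coefficients": (
                None if self.cubic_coefficients is None else list(self.cubic_coefficients)
            ),
            "best_exchange_energy_j_mol": self.best_exchange_energy,
            "best_exchange_energy_kj_mol": (
                None
                if self.best_exchange_energy is None
                else self.best_exchange_energy / 1000.0
            ),
            "boundary_flag": self.boundary_flag,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2)


def chi_square(dataset: ExperimentDataset, isotherm: IsothermResult) -> float:
    """Unweighted sum of squared residuals between data and simulation.

    The isotherm must have been evaluated at exactly the dataset's eeg
    values (same sorted grid).
    """
    if len(isotherm.eeg) != len(dataset) or not np.allclose(
        isotherm.eeg, dataset.eeg, atol=1e-12
    ):
        raise ValueError("isotherm eeg grid does not match the dataset")
    resid = np.asarray(dataset.ees_obs) - isotherm.ees_mean
    return float((resid**2).sum())


DEFAULT_GRID = tuple(2100.0 + 100.0 * k for k in range(7))
"""Default exchange-energy grid: 2100..2700 J/mol in 100 J/mol steps."""


def exchange_energy_scan(
    dataset: ExperimentDataset,
    grid: Sequence[float],
    params_base: ModelParams,
    settings: MCSettings,
    side: int = 100,
) -> FitResult:
    """chi2 at each grid exchange energy (no cubic stage yet).

    One Monte Carlo isotherm per grid energy, evaluated at the dataset's
    eeg values with identical per-point seeds (common random numbers).
    """
    grid = tuple(float(g) for g in grid)
    chi2 = []
    for exch in grid:
        params = params_base.replace(exch_energy=exch)
        iso = isotherm_scan(params, dataset.eeg, settings, side=side)
        c2 = chi_square(dataset, iso)
        logger.info("scan: exch=%.1f J/mol chi2=%.6f", exch, c2)
        chi2.append(c2)
    return FitResult(grid=grid, chi_square=tuple(chi2))


def cubic_fit_minimum(result: FitResult) -> FitResult:
    """Fit chi2(exchange energy) with an OLS cubic and locate its minimum.

    The fit is performed with the energy in kJ/mol for conditioning.  The
    minimum is the real root of the cubic's derivative inside the grid range
    with positive second derivative; if there is none, ``boundary_flag`` is
    set and the raw grid argmin is reported.
    """
    x = np.asarray(result.grid) / 1000.0
    y = np.asarray(result.chi_square)
    if np.unique(x).size != x.size:
        raise ValueError("duplicate grid values")
    coeffs = np.polyfit(x, y, 3)
    a, b, c, _ = coeffs
    # derivative 3a x^2 + 2b x + c = 0
    roots = np.roots([3 * a, 2 * b, c])
    best_kj = None
    best_val = math.inf
    for r in roots:
        if abs(r.imag) > 1e-9:
            continue
        xr = float(r.real)
        if not (x[0] <= xr <= x[-1]):
            continue
        if 6 * a * xr + 2 * b <= 0:  # need a local minimum
            continue
        val = float(np.polyval(coeffs, xr))
        if val < best_val:
            best_kj, best_val = xr, val
    if best_kj is None:
        return replace(
            result,
            cubic_coefficients=tuple(float(v) for v in coeffs),
            best_exchange_energy=float(result.grid[int(np.argmin(y))]),
            boundary_flag=True,
        )
    return replace(
        result,
        cubic_coefficients=tuple(float(v) for v in coeffs),
        best_exchange_energy=best_kj * 1000.0,
        boundary_flag=False,
    )


def fit_exchange_energy(
    dataset: ExperimentDataset,
    params_base: ModelParams,
    settings: MCSettings,
    grid: Sequence[float] = DEFAULT_GRID,
    side: int = 100,
) -> FitResult:
    """Full pipeline: grid scan then cubic-minimum extraction."""
    return cubic_fit_minimum(
        exchange_energy_scan(dataset, grid, params_base, settings, side=side)
    )
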