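"""Closed-form references and a small-lattice exact-enumeration oracle.

* Onsager's spontaneous order parameter for the zero-field square-lattice
  model, expressed as the surface enantiomeric excess reached in equilibrium
  with a racemic gas on an achiral surface below the critical temperature.
* The corresponding critical temperature ``R*Tc = exch_energy/ln(1+sqrt 2)``.
* Langmuir single-component and competitive adsorption isotherms (the
  non-interacting baselines).
* Boltzmann-exact expectations on 3x3/4x4 lattices by full enumeration,
  used as ground truth for the Monte Carlo sampler.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .lattice import (
    GAS_CONSTANT,
    ModelParams,
    pair_coupling,
    site_field,
)

__all__ = [
    "onsager_ees",
    "critical_temperature",
    "langmuir_coverage",
    "competitive_coverages",
    "ExactExpectations",
    "exact_enumeration",
]

#: Critical coupling of the square lattice: exch_energy/(R*Tc) = ln(1+sqrt(2)).
CRITICAL_COUPLING = math.log(1.0 + math.sqrt(2.0))


def onsager_ees(exch_energy: float, temperature: float) -> float:
    """Spontaneous surface enantiomeric excess at zero field.

    ``ees = (1 - sinh(x)^-4)^(1/8)`` with ``x = exch_energy/(R*T)`` for
    ``x > ln(1+sqrt 2)`` (i.e. T < Tc); 0 otherwise.  Heterochiral-favouring
    systems (``exch_energy <= 0``) have a racemic monolayer and return 0.
    """
    if not temperature > 0:
        raise ValueError("temperature must be > 0")
    if exch_energy <= 0:
        return 0.0
    x = exch_energy / (GAS_CONSTANT * temperature)
    if x <= CRITICAL_COUPLING:
        return 0.0
    # sinh(x)^-4 via logs: log(sinh x) = x + log1p(-exp(-2x)) - log 2,
    # overflow-safe for arbitrarily low temperatures.
    inv_sinh4 = math.exp(-4.0 * (x + math.log1p(-math.exp(-2.0 * x)) - math.log(2.0)))
    return (1.0 - inv_sinh4) ** 0.125


def critical_temperature(exch_energy: float) -> float:
    """Critical temperature Tc = exch_energy / (R * ln(1+sqrt 2)), K."""
    if exch_energy <= 0:
        raise ValueError("no transition for exch_energy <= 0")
    return exch_energy / (GAS_CONSTANT * CRITICAL_COUPLING)


def langmuir_coverage(equilibrium_constant: float, pressure: float) -> float:
    """Single-component Langmuir coverage K*P / (1 + K*P)."""
    kp = equilibrium_constant * pressure
    if kp < 0:
        raise ValueError("K*P must be >= 0")
    return kp / (1.0 + kp)


def competitive_coverages(
    k_a: float, p_a: float, k_b: float, p_b: float
) -> tuple[float, float]:
    """Two-component competitive Langmuir coverages (theta_A, theta_B).

    With equal equilibrium constants the saturated-surface excess
    ``(theta_A - theta_B)/(theta_A + theta_B)`` equals the gas-phase excess:
    the non-interacting model predicts no amplification.
    """
    ka_pa = k_a * p_a
    kb_pb = k_b * p_b
    if ka_pa < 0 or kb_pb < 0:
        raise ValueError("K*P products must be >= 0")
    denom = 1.0 + ka_pa + kb_pb
    return ka_pa / denom, kb_pb / denom


@dataclass(frozen=True)
class ExactExpectations:
    """Boltzmann-exact small-lattice expectations."""

    ees: float
    abs_ees: float
    energy_per_site: float
    homochiral_fraction: float
    side: int


def _nn_pairs(side: int) -> list[tuple[int, int]]:
    """Unordered periodic NN pairs as flat site indices (2*N^2 pairs)."""
    pairs = []
    for i in range(side):
        for j in range(side):
            a = i * side + j
            pairs.append((a, ((i + 1) % side) * side + j))
            pairs.append((a, i * side + (j + 1) % side))
    return pairs


def exact_enumeration(params: ModelParams, side: int) -> ExactExpectations:
    """Exact Boltzmann averages over all 2^(N^2) configurations.

    Restricted to ``side in {3, 4}`` (cost guard) and a finite field.
    """
    if side not in (3, 4):
        raise ValueError(f"exact enumeration supported for side in {{3, 4}}, got {side}")
    h = site_field(params)
    if not math.isfinite(h):
        raise ValueError("exact enumeration undefined for gas_ee = +/-1")
    j = pair_coupling(params)
    n2 = side * side
    n_cfg = 1 << n2
    idx = np.arange(n_cfg, dtype=np.uint32)
    spins = (((idx[:, None] >> np.arange(n2, dtype=np.uint32)) & 1) * 2 - 1).astype(np.int8)
    mag = spins.sum(axis=1, dtype=np.int64)
    pair_sum = np.zeros(n_cfg, dtype=np.int64)
    for a, b in _nn_pairs(side):
        pair_sum += spins[:, a].astype(np.int64) * spins[:, b]
    energy = -h * mag - j * pair_sum
    beta = 1.0 / params.rt
    logw = -beta * energy
    w = np.exp(logw - logw.max())
    z = w.sum()
    ees = float((w * mag).sum() / z) / n2
    abs_ees = float((w * np.abs(mag)).sum() / z) / n2
    e_site = float((w * energy).sum() / z) / n2
    pfrac = (1.0 + float((w * pair_sum).sum() / z) / (2 * n2)) / 2.0
    return ExactExpectations(
        ees=ees, abs_ees=abs_ees, energy_per_site=e_site,
        homochiral_fraction=pfrac, side=side,
    )


def onsager_curve(exch_energy: float, temperatures: np.ndarray) -> np.ndarray:
    """Vectorized ``onsager_ees`` over a temperature grid."""
    return np.array([onsager_ees(exch_energy, float(t)) for t in temperatures])
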