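"""Saturated-monolayer lattice model of competitive enantiomer adsorption.

A saturated monolayer of two enantiomers on a square grid of equivalent
adsorption sites maps onto a two-state lattice model: each site carries a
chirality label ``chi = +1`` (D-enantiomer) or ``chi = -1`` (L-enantiomer)
and the lattice is periodic in both directions.  The configurational energy
is

    H = -h * sum_i chi_i  -  J_pair * sum_{<ij>} chi_i chi_j

where ``h`` is the effective per-site field combining the enantiospecific
adsorption-energy difference with the gas-phase chemical-potential
difference ``R*T*ln(P_D/P_L)``, ``J_pair`` is the coupling per unordered
nearest-neighbour pair, and ``<ij>`` runs over the 2*N^2 unordered periodic
nearest-neighbour pairs.

Sign and factor conventions
---------------------------
``J_pair = exch_energy / 2``.  With this choice the zero-field model has the
standard square-lattice critical point ``R*Tc = exch_energy / ln(1+sqrt(2))``
and the spontaneous surface excess follows the Onsager closed form with
argument ``exch_energy / (R*T)`` (see :mod:`chiradsorb.analytic`).  A
positive ``exch_energy`` favours homochiral (D-D / L-L) neighbour pairs.

``h = effective_field / 2 = (ads_energy_diff + R*T*ln(P_D/P_L)) / 2``.  The
half is forced by detailed balance: replacing an L by a D at an isolated
site must change the field energy by ``-2h*chi`` and yield the occupancy
ratio ``P(D)/P(L) = (P_D/P_L) * exp(ads_energy_diff/(R*T))``.  Only this
convention reduces the non-interacting model to the competitive Langmuir
identity ``ees = eeg`` (equal adsorption constants, saturated surface); the
same single-site argument gives ``ees = tanh(h/(R*T)) = eeg`` exactly when
``exch_energy = 0``.

All energies are in J/mol; temperatures in K.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

#: Molar gas constant, J/(mol K).
GAS_CONSTANT = 8.314

__all__ = [
    "GAS_CONSTANT",
    "ModelParams",
    "LatticeState",
    "effective_field",
    "site_field",
    "pair_coupling",
    "total_energy",
    "flip_delta_energy",
    "surface_ee",
    "homochiral_pair_fraction",
]


@dataclass(frozen=True)
class ModelParams:
    """Physical parameters of the adsorption model.

    Parameters
    ----------
    temperature
        Absolute temperature, K (> 0).
    exch_energy
        Homochiral-minus-heterochiral pair energy difference, J/mol.
        Positive values favour homochiral clustering.
    ads_energy_diff
        D-minus-L adsorption energy difference, J/mol.  Zero on an achiral
        surface.
    gas_ee
        Gas-phase enantiomeric excess ``(P_D - P_L)/(P_D + P_L)`` in
        [-1, +1].
    """

    temperature: float
    exch_energy: float = 0.0
    ads_energy_diff: float = 0.0
    gas_ee: float = 0.0
    gas_constant: float = field(default=GAS_CONSTANT, init=False, repr=False)

    def __post_init__(self) -> None:
        if not self.temperature > 0:
            raise ValueError(f"temperature must be > 0, got {self.temperature}")
        if not -1.0 <= self.gas_ee <= 1.0:
            raise ValueError(f"gas_ee must lie in [-1, 1], got {self.gas_ee}")

    @property
    def rt(self) -> float:
        """Thermal energy R*T, J/mol."""
        return self.gas_constant * self.temperature

    def replace(self, **changes) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        import dataclasses

        return dataclasses.replace(self, **changes)


class LatticeState:
    """N x N periodic grid of chirality labels, +1 = D and -1 = L.

    The monolayer is always saturated: every site is occupied by exactly one
    enantiomer.  ``side >= 3`` is enforced so the four periodic neighbours of
    a site are distinct.
    """

    __slots__ = ("chirality",)

    def __init__(self, chirality: np.ndarray) -> None:
        chi = np.asarray(chirality)
        if chi.ndim != 2 or chi.shape[0] != chi.shape[1]:
            raise ValueError(f"chirality must be a square 2-D grid, got shape {chi.shape}")
        if chi.shape[0] < 3:
            raise ValueError(f"side must be >= 3, got {chi.shape[0]}")
        if not np.isin(chi, (-1, 1)).all():
            raise ValueError("chirality entries must all be +1 or -1")
        self.chirality = chi.astype(np.int8)

    @property
    def side(self) -> int:
        return self.chirality.shape[0]

    @property
    def n_sites(self) -> int:
        return self.chirality.size

    def copy(self) -> "LatticeState":
        return LatticeState(self.chirality.copy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LatticeState):
            return NotImplemented
        return np.array_equal(self.chirality, other.chirality)

    def __repr__(self) -> str:  # pragma: no cover
        return f"LatticeState(side={self.side}, ees={surface_ee(self):+.4f})"

    # ---- constructors -------------------------------------------------

    @classmethod
    def all_d(cls, side: int) -> "LatticeState":
        """Pure-D lattice."""
        return cls(np.ones((side, side), dtype=np.int8))

    @classmethod
    def all_l(cls, side: int) -> "LatticeState":
        """Pure-L lattice."""
        return cls(-np.ones((side, side), dtype=np.int8))

    @classmethod
    def checkerboard(cls, side: int) -> "LatticeState":
        """Alternating D/L pattern (fully heterochiral for even side)."""
        ij = np.add.outer(np.arange(side), np.arange(side))
        return cls(np.where(ij % 2 == 0, 1, -1).astype(np.int8))

    @classmethod
    def random_racemic(cls, side: int, rng: np.random.Generator) -> "LatticeState":
        """Each site independently D or L with probability 1/2."""
        chi = rng.integers(0, 2, size=(side, side)).astype(np.int8) * 2 - 1
        return cls(chi)

    @classmethod
    def with_ee(cls, side: int, ee: float, rng: np.random.Generator) -> "LatticeState":
        """Lattice with surface excess as close to ``ee`` as site counts allow,
        with the D sites placed uniformly at random."""
        if not -1.0 <= ee <= 1.0:
            raise ValueError(f"ee must lie in [-1, 1], got {ee}")
        n = side * side
        n_d = int(round(n * (1.0 + ee) / 2.0))
        flat = np.full(n, -1, dtype=np.int8)
        flat[:n_d] = 1
        rng.shuffle(flat)
        return cls(flat.reshape(side, side))


# ---- energetics ------------------------------------------------------


def effective_field(params: ModelParams) -> float:
    """Per-site field h, J/mol.

    ``h = ads_energy_diff + R*T*ln((1 + eeg)/(1 - eeg))``.  For an
    enantiopure gas (``gas_ee = +/-1``) the chemical-potential term diverges
    and a signed infinity is returned; samplers must treat that as a frozen
    pure-D (or pure-L) lattice.
    """
    eeg = params.gas_ee
    if eeg >= 1.0:
        return math.inf
    if eeg <= -1.0:
        return -math.inf
    return params.ads_energy_diff + params.rt * math.log((1.0 + eeg) / (1.0 - eeg))


def site_field(params: ModelParams) -> float:
    """Per-site field h entering the Hamiltonian, J/mol.

    ``h = effective_field(params) / 2`` — see the module docstring for why
    detailed balance of a single-site D<->L exchange forces the half.
    """
    return effective_field(params) / 2.0


def pair_coupling(params: ModelParams) -> float:
    """Coupling J_pair per unordered nearest-neighbour pair, J/mol.

    ``J_pair = exch_energy / 2`` — the convention under which
    ``R*Tc = exch_energy / ln(1+sqrt(2))`` (see module docstring).
    """
    return params.exch_energy / 2.0


def _pair_sum(chi: np.ndarray) -> int:
    """Sum of chi_i*chi_j over the 2*N^2 unordered periodic NN pairs."""
    c = chi.astype(np.int64)
    return int((c * np.roll(c, 1, axis=0)).sum() + (c * np.roll(c, 1, axis=1)).sum())


def total_energy(lattice: LatticeState, params: ModelParams) -> float:
    """Configurational energy of the lattice, J/mol.

    Each unordered nearest-neighbour pair is counted exactly once
    (2*N^2 pairs).  Raises ``ValueError`` for a degenerate (infinite) field.
    """
    h = site_field(params)
    if not math.isfinite(h):
        raise ValueError("total_energy undefined for gas_ee = +/-1 (divergent field)")
    j = pair_coupling(params)
    return -h * int(lattice.chirality.sum()) - j * _pair_sum(lattice.chirality)


def flip_delta_energy(lattice: LatticeState, params: ModelParams, site: tuple[int, int]) -> float:
    """Energy change from flipping the chirality at ``site``, J/mol.

    Exactly equals ``total_energy(after) - total_energy(before)``.
    """
    h = site_field(params)
    if not math.isfinite(h):
        raise ValueError("flip_delta_energy undefined for gas_ee = +/-1 (divergent field)")
    i, j = site
    n = lattice.side
    if not (0 <= i < n and 0 <= j < n):
        raise IndexError(f"site {site} out of bounds for side {n}")
    chi = lattice.chirality
    nn = int(chi[(i + 1) % n, j]) + int(chi[(i - 1) % n, j]) \
        + int(chi[i, (j + 1) % n]) + int(chi[i, (j - 1) % n])
    return 2.0 * float(chi[i, j]) * (h + pair_coupling(params) * nn)


def surface_ee(lattice: LatticeState) -> float:
    """Surface enantiomeric excess (mean chirality); positive = D excess."""
    return float(lattice.chirality.mean())


def homochiral_pair_fraction(lattice: LatticeState) -> float:
    """Fraction of the 2*N^2 periodic NN pairs with matching chirality."""
    n_pairs = 2 * lattice.n_sites
    return (1.0 + _pair_sum(lattice.chirality) / n_pairs) / 2.0
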