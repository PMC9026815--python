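"""Metropolis sampling of the saturated-monolayer adsorption model.

``equilibrate_and_measure`` is the workhorse: it burns in a lattice under a
given :class:`~chiradsorb.lattice.ModelParams`, then samples the surface
enantiomeric excess, energy and homochiral pair fraction, returning batch-
mean error bars.  ``isotherm_scan`` repeats this over a grid of gas-phase
enantiomeric excesses, which is the computation behind an ees-vs-eeg
isotherm.

One sweep = N^2 attempted single-site flips at uniformly random sites, each
accepted with the Metropolis probability ``min(1, exp(-dE/(R*T)))``, so the
chain satisfies detailed balance with respect to ``exp(-H/(R*T))``.

The inner loop is JIT-compiled with numba when available and falls back to
the identical pure-Python code otherwise (both draw from the same
Mersenne-Twister stream, so trajectories are seed-reproducible either way).

An enantiopure gas phase (``gas_ee = +/-1``) short-circuits to the
deterministic pure lattice: the effective field is infinite and no sampling
is performed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .lattice import (
    LatticeState,
    ModelParams,
    pair_coupling,
    site_field,
)

logger = logging.getLogger(__name__)

__all__ = [
    "MCSettings",
    "EquilibriumEstimate",
    "IsothermResult",
    "metropolis_sweep",
    "equilibrate_and_measure",
    "isotherm_scan",
    "snapshot",
    "write_snapshot_csv",
    "read_snapshot_csv",
    "ISOTHERM_COLUMNS",
]

try:  # pragma: no cover - exercised implicitly
    from numba import njit as _njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def _njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


InitMode = Literal["random_racemic", "all_D", "all_L", "fixed_ee"]


@dataclass(frozen=True)
class MCSettings:
    """Sampler configuration.

    ``measure_sweeps // sample_interval`` samples are collected after
    ``burn_in_sweeps`` of equilibration; standard errors come from batch
    means over ``batches`` contiguous blocks.
    """

    seed: int = 0
    burn_in_sweeps: int = 2000
    measure_sweeps: int = 5000
    sample_interval: int = 1
    init_mode: InitMode = "random_racemic"
    init_ee: float | None = None
    batches: int = 20

    def __post_init__(self) -> None:
        if self.burn_in_sweeps < 0:
            raise ValueError("burn_in_sweeps must be >= 0")
        if self.measure_sweeps < 1:
            raise ValueError("measure_sweeps must be >= 1")
        if self.sample_interval < 1:
            raise ValueError("sample_interval must be >= 1")
        if self.batches < 10:
            raise ValueError("batches must be >= 10")
        if self.measure_sweeps < self.batches:
            raise ValueError("measure_sweeps must be >= batches")
        if self.n_samples < self.batches:
            raise ValueError(
                f"{self.n_samples} samples < {self.batches} batches; "
                "reduce sample_interval or batches"
            )
        if self.init_mode == "fixed_ee" and self.init_ee is None:
            raise ValueError("init_mode='fixed_ee' requires init_ee")

    @property
    def n_samples(self) -> int:
        return self.measure_sweeps // self.sample_interval


@dataclass(frozen=True)
class EquilibriumEstimate:
    """Equilibrium observables with batch-mean standard errors."""

    mean_ees: float
    mean_abs_ees: float
    std_error_ees: float
    mean_energy_per_site: float
    mean_homochiral_fraction: float
    n_samples: int
    seed: int
    std_error_abs_ees: float = math.nan
    std_error_energy_per_site: float = math.nan
    std_error_homochiral_fraction: float = math.nan

    def __post_init__(self) -> None:
        if not (abs(self.mean_ees) <= self.mean_abs_ees + 1e-12 <= 1.0 + 2e-12):
            raise ValueError(
                f"require |mean_ees| <= mean_abs_ees <= 1, got "
                f"{self.mean_ees}, {self.mean_abs_ees}"
            )
        if not self.std_error_ees >= 0:
            raise ValueError("std_error_ees must be >= 0")


# ---------------------------------------------------------------------------
# kernel


@_njit(cache=True)
def _run_chain(chi, n_burn, n_meas, interval, beta_h, beta_j, seed):  # pragma: no cover
    """Run burn-in plus measurement sweeps in place.

    Returns per-sample site-summed magnetization and NN pair sums.
    ``beta_h`` and ``beta_j`` are the field and pair coupling divided by R*T.
    """
    np.random.seed(seed)
    n = chi.shape[0]
    n_sites = n * n
    n_samples = n_meas // interval
    mags = np.empty(n_samples, dtype=np.float64)
    pairs = np.empty(n_samples, dtype=np.float64)
    k = 0
    for sweep in range(n_burn + n_meas):
        for _ in range(n_sites):
            i = np.random.randint(0, n)
            j = np.random.randint(0, n)
            nn = (
                chi[(i + 1) % n, j]
                + chi[(i - 1) % n, j]
                + chi[i, (j + 1) % n]
                + chi[i, (j - 1) % n]
            )
            d = 2.0 * chi[i, j] * (beta_h + beta_j * nn)
            if d <= 0.0 or np.random.random() < math.exp(-d):
                chi[i, j] = -chi[i, j]
        if sweep >= n_burn and (sweep - n_burn + 1) % interval == 0:
            m = 0
            p = 0
            for a in range(n):
                for b in range(n):
                    c = chi[a, b]
                    m += c
                    p += c * (chi[(a + 1) % n, b] + chi[a, (b + 1) % n])
            mags[k] = m
            pairs[k] = p
            k += 1
    return mags, pairs


def _kernel_seed(*parts: int) -> int:
    """Deterministic uint32 stream seed mixed from integer parts."""
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0])


def metropolis_sweep(
    lattice: LatticeState, params: ModelParams, rng: np.random.Generator
) -> LatticeState:
    """One sweep (N^2 attempted random-site flips), updating in place.

    Reference implementation driven by a ``numpy.random.Generator``; the
    batch sampler uses the compiled kernel with the same update rule.
    """
    h = site_field(params)
    if not math.isfinite(h):
        raise ValueError("metropolis_sweep undefined for gas_ee = +/-1; "
                         "the lattice is frozen enantiopure")
    beta = 1.0 / params.rt
    beta_h = h * beta
    beta_j = pair_coupling(params) * beta
    chi = lattice.chirality
    n = lattice.side
    sites = rng.integers(0, n, size=(n * n, 2))
    accept = rng.random(n * n)
    for k in range(n * n):
        i, j = sites[k]
        nn = (
            int(chi[(i + 1) % n, j])
            + int(chi[(i - 1) % n, j])
            + int(chi[i, (j + 1) % n])
            + int(chi[i, (j - 1) % n])
        )
        d = 2.0 * chi[i, j] * (beta_h + beta_j * nn)
        if d <= 0.0 or accept[k] < math.exp(-d):
            chi[i, j] = -chi[i, j]
    return lattice


def _initial_lattice(side: int, settings: MCSettings) -> LatticeState:
    rng = np.random.default_rng(np.random.SeedSequence([settings.seed, 0xA5]))
    if settings.init_mode == "random_racemic":
        return LatticeState.random_racemic(side, rng)
    if settings.init_mode == "all_D":
        return LatticeState.all_d(side)
    if settings.init_mode == "all_L":
        return LatticeState.all_l(side)
    if settings.init_mode == "fixed_ee":
        return LatticeState.with_ee(side, settings.init_ee, rng)
    raise ValueError(f"unknown init_mode {settings.init_mode!r}")


def _batch_stats(samples: np.ndarray, batches: int) -> tuple[float, float]:
    """(mean, batch-mean standard error) over contiguous blocks."""
    n = samples.size - samples.size % batches
    block_means = samples[:n].reshape(batches, -1).mean(axis=1)
    se = float(block_means.std(ddof=1) / math.sqrt(batches))
    return float(samples.mean()), se


def _pure_lattice_estimate(params: ModelParams, settings: MCSettings) -> EquilibriumEstimate:
    """Deterministic estimate for an enantiopure gas (infinite field).

    The field energy per site is -h*ees and diverges; it is reported as a
    signed infinity.
    """
    sign = 1.0 if params.gas_ee > 0 else -1.0
    return EquilibriumEstimate(
        mean_ees=sign,
        mean_abs_ees=1.0,
        std_error_ees=0.0,
        mean_energy_per_site=-math.inf,
        mean_homochiral_fraction=1.0,
        n_samples=0,
        seed=settings.seed,
        std_error_abs_ees=0.0,
        std_error_energy_per_site=0.0,
        std_error_homochiral_fraction=0.0,
    )


def equilibrate_and_measure(
    params: ModelParams,
    settings: MCSettings,
    side: int = 100,
    return_lattice: bool = False,
) -> EquilibriumEstimate | tuple[EquilibriumEstimate, LatticeState]:
    """Equilibrate a lattice and measure equilibrium observables.

    Parameters
    ----------
    params
        Physical parameters; ``gas_ee = +/-1`` short-circuits to the frozen
        enantiopure lattice without sampling.
    settings
        Sampler configuration (seed, sweep counts, init mode, batches).
    side
        Lattice edge length N (default 100).
    return_lattice
        Also return the final :class:`LatticeState` (e.g. for snapshots).
    """
    if abs(params.gas_ee) >= 1.0:
        est = _pure_lattice_estimate(params, settings)
        lattice = LatticeState.all_d(side) if params.gas_ee > 0 else LatticeState.all_l(side)
        logger.info(
            "mc: enantiopure short-circuit eeg=%+g -> ees=%+g", params.gas_ee, est.mean_ees
        )
        return (est, lattice) if return_lattice else est

    h = site_field(params)
    j = pair_coupling(params)
    beta = 1.0 / params.rt
    lattice = _initial_lattice(side, settings)
    logger.info(
        "mc: side=%d T=%gK exch=%g ads=%g eeg=%+g burn=%d measure=%d seed=%d",
        side, params.temperature, params.exch_energy, params.ads_energy_diff,
        params.gas_ee, settings.burn_in_sweeps, settings.measure_sweeps, settings.seed,
    )
    mags, pairs = _run_chain(
        lattice.chirality,
        settings.burn_in_sweeps,
        settings.measure_sweeps,
        settings.sample_interval,
        h * beta,
        j * beta,
        _kernel_seed(settings.seed),
    )
    n_sites = side * side
    ees = mags / n_sites
    pfrac = (1.0 + pairs / (2 * n_sites)) / 2.0
    e_site = (-h * mags - j * pairs) / n_sites

    mean_ees, se_ees = _batch_stats(ees, settings.batches)
    mean_abs, se_abs = _batch_stats(np.abs(ees), settings.batches)
    mean_e, se_e = _batch_stats(e_site, settings.batches)
    mean_p, se_p = _batch_stats(pfrac, settings.batches)
    est = EquilibriumEstimate(
        mean_ees=mean_ees,
        mean_abs_ees=mean_abs,
        std_error_ees=se_ees,
        mean_energy_per_site=mean_e,
        mean_homochiral_fraction=mean_p,
        n_samples=ees.size,
        seed=settings.seed,
        std_error_abs_ees=se_abs,
        std_error_energy_per_site=se_e,
        std_error_homochiral_fraction=se_p,
    )
    return (est, lattice) if return_lattice else est


# ---------------------------------------------------------------------------
# isotherms

ISOTHERM_COLUMNS = [
    "eeg",
    "ees_mean",
    "ees_abs_mean",
    "ees_stderr",
    "energy_per_site",
    "homochiral_fraction",
    "n_samples",
    "seed",
]


@dataclass(frozen=True)
class IsothermResult:
    """ees-vs-eeg scan: one equilibrium estimate per gas-phase excess."""

    eeg: tuple[float, ...]
    estimates: tuple[EquilibriumEstimate, ...]
    params_base: ModelParams | None = None
    settings: MCSettings | None = None

    def __post_init__(self) -> None:
        if len(self.eeg) != len(self.estimates):
            raise ValueError("eeg and estimates must have equal length")
        diffs = np.diff(self.eeg)
        if len(diffs) and not (diffs > 0).all():
            raise ValueError("eeg values must be strictly increasing")

    @property
    def ees_mean(self) -> np.ndarray:
        return np.array([e.mean_ees for e in self.estimates])

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            (
                g,
                e.mean_ees,
                e.mean_abs_ees,
                e.std_error_ees,
                e.mean_energy_per_site,
                e.mean_homochiral_fraction,
                e.n_samples,
                e.seed,
            )
            for g, e in zip(self.eeg, self.estimates)
        ]
        return pd.DataFrame(rows, columns=ISOTHERM_COLUMNS)

    def to_csv(self, path) -> None:
        # %.17g guarantees float64 round-trips through the text format
        self.to_dataframe().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path) -> "IsothermResult":
        df = pd.read_csv(path, float_precision="round_trip")
        missing = set(ISOTHERM_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"isotherm CSV missing columns: {sorted(missing)}")
        ests = tuple(
            EquilibriumEstimate(
                mean_ees=r.ees_mean,
                mean_abs_ees=r.ees_abs_mean,
                std_error_ees=r.ees_stderr,
                mean_energy_per_site=r.energy_per_site,
                mean_homochiral_fraction=r.homochiral_fraction,
                n_samples=int(r.n_samples),
                seed=int(r.seed),
            )
            for r in df.itertuples()
        )
        return cls(eeg=tuple(df["eeg"]), estimates=ests)


def isotherm_scan(
    params_base: ModelParams,
    eeg_values: Sequence[float],
    settings: MCSettings,
    side: int = 100,
) -> IsothermResult:
    """Run one equilibrium measurement per gas-phase excess.

    Per-point seeds are mixed deterministically from ``settings.seed`` and
    the grid index (``SeedSequence([seed, index])``), so points are
    statistically independent yet the whole scan is reproducible — and
    rerunning with the same seed at a different exchange energy reuses the
    same random streams (common random numbers for smooth parameter scans).
    """
    eeg_values = [float(g) for g in eeg_values]
    arr = np.asarray(eeg_values)
    if arr.size == 0:
        raise ValueError("eeg_values must be non-empty")
    if (np.abs(arr) > 1).any():
        raise ValueError("eeg values must lie in [-1, 1]")
    if np.unique(arr).size != arr.size:
        raise ValueError("duplicate eeg values")
    if arr.size > 1 and not (np.diff(arr) > 0).all():
        raise ValueError("eeg values must be strictly increasing")
    estimates = []
    for idx, eeg in enumerate(eeg_values):
        pt_settings = replace(settings, seed=_kernel_seed(settings.seed, idx))
        params = params_base.replace(gas_ee=eeg)
        estimates.append(equilibrate_and_measure(params, pt_settings, side=side))
    return IsothermResult(
        eeg=tuple(eeg_values),
        estimates=tuple(estimates),
        params_base=params_base,
        settings=settings,
    )


# ---------------------------------------------------------------------------
# snapshots


def snapshot(lattice: LatticeState) -> list[list[str]]:
    """Row-major grid of 'D'/'L' labels (lossless with the CSV reader)."""
    return [["D" if c > 0 else "L" for c in row] for row in lattice.chirality]


def write_snapshot_csv(lattice: LatticeState, path) -> None:
    with open(path, "w") as fh:
        for row in snapshot(lattice):
            fh.write(",".join(row) + "\n")


def read_snapshot_csv(path) -> LatticeState:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            rows.append([1 if tok == "D" else -1 for tok in line.split(",")])
    return LatticeState(np.array(rows, dtype=np.int8))
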