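# chiradsorb

Lattice-model simulation and analysis of **competitive enantiomer adsorption
on achiral surfaces**.

A saturated monolayer of D- and L-enantiomers on a square grid of equivalent
adsorption sites maps onto a two-state (Ising-type) lattice model: each site
carries a chirality label ±1, an effective field encodes the enantiospecific
adsorption-energy difference plus the gas-phase chemical-potential difference
`R·T·ln(P_D/P_L)`, and a nearest-neighbour coupling encodes the
homochiral-minus-heterochiral exchange energy. The package provides:

- **`chiradsorb.lattice`** — model parameters, lattice state, Hamiltonian,
  single-flip energy increments, surface enantiomeric excess (ees) and
  homochiral pair fraction observables.
- **`chiradsorb.mc`** — seeded Metropolis Monte Carlo (numba-accelerated, with
  a pure-Python fallback): equilibrium estimates with batch-mean error bars,
  ees-vs-eeg isotherm scans, lattice snapshots as D/L CSV grids.
- **`chiradsorb.analytic`** — Onsager spontaneous ees and critical temperature
  `R·Tc = ΔΔE_exch/ln(1+√2)`, Langmuir single-component and competitive
  isotherms, and an exact-enumeration oracle for 3×3/4×4 lattices.
- **`chiradsorb.fitting`** — χ² grid scan over exchange energies against an
  (eeg, ees) dataset with common random numbers, cubic-polynomial fit of
  χ²(ΔΔE) and analytic minimum extraction.
- **`chiradsorb.synth`** — synthetic ees-vs-eeg "experiments" (equilibrium
  curve plus Gaussian measurement noise, exact enantiopure endpoints) for
  end-to-end pipeline tests.
- **`chiradsorb.cli`** — `simulate`, `isotherm`, `onsager`, `fit`, `synth`
  subcommands with YAML config support and per-run manifests.

At 460 K with an exchange energy of 2.31 kJ/mol the model amplifies a small
gas-phase enantiomeric excess several-fold on the surface, and below the
critical temperature (≈ 315 K) it spontaneously breaks chiral symmetry,
reaching near-enantiopure monolayers from a racemic gas.

## CLI

Energies are given in kJ/mol on the command line (converted to J/mol
internally); every run writes a `manifest.json` with the resolved
configuration.

```bash
# critical temperature and spontaneous-ees curve
chiradsorb onsager --exch-kjmol 2.31 --out runs/onsager

# one equilibrium run at 460 K, racemic gas, with a lattice snapshot
chiradsorb simulate --temp-k 460 --exch-kjmol 2.31 --eeg 0.0 --snapshot \
    --out runs/simulate

# ees-vs-eeg isotherm
chiradsorb isotherm --exch-kjmol 2.31 --eeg-points 21 --out runs/isotherm

# synthetic dataset + exchange-energy fit (2.1–2.7 kJ/mol grid)
chiradsorb synth --exch-kjmol 2.31 --noise 0.03 --out runs/synth
chiradsorb fit --data runs/synth/dataset.csv --grid-min 2.1 --grid-max 2.7 \
    --grid-step 0.1 --out runs/fit
```

A YAML config file can supply defaults (`chiradsorb --config cfg.yaml
simulate ...`); explicit flags win. Exit codes: 0 success, 1 runtime error,
2 configuration error.

## Conventions

- +1 = D-enantiomer, −1 = L; positive ees means D excess.
- Pair coupling is `ΔΔE_exch/2` per unordered nearest-neighbour pair and the
  Hamiltonian site field is half the combination
  `ΔΔE_ads + R·T·ln((1+eeg)/(1−eeg))` — both factors are fixed by requiring
  the standard square-lattice critical point and the non-interacting
  (competitive Langmuir) reduction `ees = eeg`; see
  `chiradsorb/lattice.py` for the derivation.
- An enantiopure gas (`eeg = ±1`) has a divergent field and short-circuits to
  the frozen pure lattice.
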