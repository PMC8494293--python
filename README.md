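# parbclamp

Kinetic modeling of ParB CTP-clamp loading, centromere (parS) ultra-affinity,
one-dimensional spreading, and the associated in-vitro assay models.

ParB partition proteins bind CTP, close into ring-shaped DNA clamps in a
reaction catalyzed by the 16-bp parS centromere site, slide onto flanking DNA,
and are recycled by CTP hydrolysis. Because hydrolysis consumes nucleotide,
the stationary state of this cycle is not an equilibrium: the apparent
dissociation constant of the total protein pool for parS can fall far below
the equilibrium constant of the binding-competent open form — an energy-driven
"ultra-affinity". This package is for quantitative biologists who want to
compute, simulate, and test that mechanism without wet-lab data: everything
runs on kinetic parameters and seeded synthetic datasets.

## The model

The coarse cycle has four protein species (open/closed × free/DNA-bound) plus
free DNA. Only the open form binds or releases DNA, with equilibrium constant
K_d^open; closure runs at k_oc off DNA and k_oc^DNA on DNA (k_oc^parS when the
substrate is parS), spontaneous opening at k_co / k_co^DNA, and hydrolysis
returns closed protein to the open pool at k_h on and off DNA alike. Balancing
fluxes at stationarity gives

    K_d^obs = K_d^open · (k_co^DNA + k_h)/(k_co + k_h)
                       · (k_oc + k_co + k_h)/(k_oc^DNA + k_co^DNA + k_h)

which reduces to K_d^open for a hydrolysis-dead mutant (with unchanged
conformational equilibrium) and for nonspecific DNA, and in the recycling
regime (k_h ≫ k_co, k_oc and k_oc^parS ≫ k_co^parS) to

    K_d^obs ≈ K_d^open · k_h / (k_oc^parS + k_h),

a fold reduction of (k_oc^parS + k_h)/k_h — 61 at k_h ~ 1/min and
k_oc^parS ~ 1/s.

Around this core the package provides:

- `kinetics` — the analytic steady state, limiting cases, and an ODE
  relaxation oracle;
- `ssa` — direct-method exact stochastic simulation of the coarse scheme and
  of a detailed scheme with nucleotide states and the post-hydrolysis
  exchange-vs-unload competition;
- `spreading` — a 1D lattice simulator of loading at parS, diffusive sliding,
  and hydrolysis-driven unloading, with ChIP-style binning, peak-width
  metrics, and bedGraph output;
- `assays` — the 1:1 Wiseman ITC isotherm with displaced-volume injection
  correction and Levenberg–Marquardt fitting, BLI-style off-rate fits, the
  CTP-retention competition model, and CTPase slope fits;
- `synth` — seeded generators of noisy synthetic versions of all of the
  above, with ground truth embedded for round-trip testing.

## Worked example

```sh
python examples/ultra_affinity.py
```

prints

```
kd_open              = 1 uM  (equilibrium, open form)
kd_observed          = 0.01732 uM  (full steady-state expression)
kd_observed_approx   = 0.01639 uM  (recycling-regime approximation)
fold_reduction       = 61
catalytic_capacity   = 60 closures per turnover
bound fraction at [parS] = kd_open: 0.9830 (vs 0.5 at equilibrium)
```

At hydrolysis ~1/min and catalyzed closure ~1/s the apparent K_d drops 61-fold
below the open-form equilibrium value, so at a parS concentration equal to
K_d^open — where an equilibrium binder would be half-saturated — 98.3% of the
protein pool is bound. The catalytic capacity of 60 closures per hydrolysis
turnover explains why strongly substoichiometric parS suffices to keep the
whole pool cycling. The other example scripts
(`stochastic_network.py`, `spreading_profiles.py`, `assay_fits.py`) show the
exact sampler reproducing the analytic stationary state, the wider flatter
profiles of hydrolysis-dead mutants, and the assay fitters recovering their
generating parameters.

A thin CLI wraps the same functions for pipeline use:

```sh
parbclamp ultraaffinity --config rates.yaml --out out/
parbclamp simulate spreading --config spreading.yaml --out out/
parbclamp fit itc data/itc.tsv --out out/
parbclamp make-synthetic --config generator.yaml --out data/
```

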