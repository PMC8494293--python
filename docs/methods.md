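# Methods

## The clamp-cycle model

The package models a partition protein (treated as a single unit per dimer)
that interconverts between an **open** conformation, which can bind and
release DNA, and a **closed** clamp conformation, which can do neither.
Closure is a CTP-dependent gate-engagement step; hydrolysis of the bound CTP
reopens the gate and recycles the protein. The coarse network tracks five
species — open/closed × free/DNA-bound protein, plus free DNA — with rates

| parameter | meaning | unit | typical value |
|---|---|---|---|
| `k_oc`, `k_co` | closure / opening of free protein | s⁻¹ | ~10⁻³ (slow) |
| `k_oc_dna`, `k_co_dna` | same on DNA; `k_oc_dna` ≈ 1 s⁻¹ on parS | s⁻¹ | substrate-dependent |
| `k_h` | CTP hydrolysis, equal on and off DNA | s⁻¹ | ~1/60 (≈1 min⁻¹) |
| `kd_open` | open-form dissociation constant for the substrate | μM | free parameter |
| `k_on` | open-form association rate (dynamic solvers only) | μM⁻¹s⁻¹ | defaulted, see below |

Canonical units are s⁻¹ and μM; config files may tag rates as `min-1` and the
readers convert. The hydrolysis rate is taken identical on and off DNA, and
only CTP-bound states appear in the coarse model (nucleotide exchange is
treated as fast); the detailed stochastic network relaxes both assumptions.

At stationarity each conformational pair satisfies
`[open]/[closed] = (k_co* + k_h)/k_oc*` and the binding edge enforces
`[open][DNA] = kd_open·[open·DNA]`, giving the observed dissociation constant
of the total pool

```
Kd_obs = kd_open · (k_co_dna + k_h)/(k_co + k_h)
                 · (k_oc + k_co + k_h)/(k_oc_dna + k_co_dna + k_h)
```

This is an identity of the model, and the test suite checks it against the
steady-state solver for random rate sets to 1e-9 relative. Its limiting
cases: no hydrolysis with matched conformational equilibria → `kd_open`
(hydrolysis-dead mutant); on-DNA rates equal to off-DNA rates → `kd_open`
(nonspecific DNA); catalyzed closure with recycling-dominant hydrolysis →
`kd_open·k_h/(k_oc_dna + k_h)`.

**Hydrolysis routing.** Hydrolysis of a DNA-bound closed clamp returns it to
the *bound open* state rather than ejecting it directly; unloading then
proceeds by ordinary open-state release. This keeps the coarse network
minimal (closed states never touch the DNA-binding equilibrium) and makes the
flux-balance solution exact.

**Default association rate.** The analytic theory needs only `kd_open`, but
the ODE and stochastic solvers need `k_on` and `k_off_open = k_on·kd_open`
separately. When `k_on` is not supplied, it is set so that `k_off_open` is
100× the fastest conformational rate: binding is then pre-equilibrated on the
conformational timescale and the dynamic solvers agree with the analytic
steady state regardless of the (physically unconstrained) absolute binding
timescale. Any supplied `k_on` overrides this.

**Degenerate parameterizations** (e.g. `k_co = k_h = 0`, which strands the
free closed pool) raise `DegenerateParameterizationError` naming the zero
denominator instead of returning a limit.

## Stochastic simulation

`simulate` is a direct-method exact sampler: exponential waiting times from
the total propensity, reaction selection proportional to propensities, with
block-drawn uniforms from a seeded `numpy` generator. The networks are small
(≤ ~11 reactions), so exactness costs little and no leaping approximation is
used. `(seed, network)` fully determines a trajectory; the trajectory stores
event times and reaction indices and reconstructs count series on demand.
Default copy number is 500 protein units per simulated volume — a statistical-
precision choice, not an estimate of cellular abundance.

The detailed network resolves nucleotide occupancy (apo/CTP), the tethered,
untethered and gate-closed conformations, parS engagement, and the fate of a
DNA-loaded clamp after hydrolysis: with probability
`p_retain = [CTP]/([CTP] + Kd_CTP)` the clamp exchanges CDP for fresh CTP in
place and stays loaded; otherwise it unloads and reverts to the apo dimer.
The exchange-vs-unload split is modeled as this single outcome probability
rather than explicit CDP-release micro-steps, since only the outcome is
experimentally constrained. Untethering/retethering rates are free
parameters with no measured values; tests that compare the detailed and
coarse schemes place them in the fast-exchange limit (CTP binding and
untethering fast, no retethering, negligible re-capture), where the detailed
scheme provably collapses onto the coarse cycle.

`hydrolysis_flux` mirrors the solution CTPase measurement: hydrolysis-tagged
events per protein per unit time after a burn-in of 10× the slowest network
timescale (bimolecular constants are scaled by partner-moiety capacity when
computing that yardstick).

## Spreading simulator

Clamps are injected at the parS lattice site at a constant rate, hop left or
right by 1 bp at rate `D` per direction (macroscopic diffusion coefficient
`D` bp²/s), and are removed at `k_off·(1 − p_retain)`. The steady-state
occupancy on an unbounded lattice is the two-sided geometric profile with
ratio `r` solving `D(r + 1/r) = 2D + k_off_eff` — the discrete analogue of
the continuum exponential with decay length `λ = √(D/k_off_eff)` — and total
clamp number `loading_rate / k_off_eff`; `analytic_profile` implements this
closed form as the simulator's oracle (valid without exclusion or roadblocks
and with boundaries many λ from parS). With `k_off = 0` (hydrolysis-dead
mode) there is no steady state and a loaded bolus broadens as `√(2Dt)`,
which is why hydrolysis-dead profiles are wider and flatter than wild-type
ones at matched occupancy.

No measured value of `D` exists for a sliding clamp in vivo, so `D` is a free
config parameter and all absolute widths are functions of `(D, rates)`; the
published ~15 kb (wild-type) vs ~40 kb (hydrolysis-dead) peak widths are
treated as a qualitative ordering target only. Clamps are point particles by
default; an exclusion option (one clamp per site, injection blocked while
parS is occupied) exists because the clamp footprint is not specified.
Profile asymmetry is modeled only through explicit roadblocks (reflecting or
absorbing sites); no default roadblock is placed because the mechanism behind
the observed one-sidedness is unresolved. Output uses 0-based half-open bins
(bedGraph convention); ChIP-style post-processing bins at 1 kb by default.
`peak_width` offers interpolated FWHM (2λ·ln 2 for an exponential) and a
central-mass width (smallest peak-containing run of bins holding fraction q
of the occupancy).

## Assay models

**ITC.** The cumulative heat of a 1:1 isotherm is the Wiseman closed form
`Q = Mt·ΔH·Vo/2·[1 + Xt/Mt + 1/(K·Mt) − √((1 + Xt/Mt + 1/(K·Mt))² − 4Xt/Mt)]`,
whose bracket is the bound fraction from the binding quadratic (the
discriminant is clipped at zero against round-off; a genuinely negative
discriminant raises). Per-injection heats apply the displaced-volume
correction `ΔQ(i) = Q(i) + (dVi/Vo)·(Q(i)+Q(i−1))/2 − Q(i−1)` with Q(0)=0;
the volume ratio is injection volume over cell volume, the standard
perfusion-cell correction. Fitting is Levenberg–Marquardt least squares over
(ln K, ΔH) — the log scale keeps the association constant positive and
well-conditioned — with deterministic initialization (ΔH from the first
injection, K from a mid-transition heuristic) and asymptotic standard errors
from the Jacobian. Stoichiometry is fixed at 1:1; no floating n-parameter.
The default synthetic schedule is a 280-μL cell at 100 μM protein, 2 mM
syringe, 20 × 2 μL injections.

**BLI.** The dissociation phase is fit as `A·exp(−k_app·t) + c` with the
baseline offset estimated rather than assumed zero (real sensors drift). A
non-decaying trace returns `k_app = 0` with a flag instead of failing. The
retention model treats post-hydrolysis fate as a competition between CTP
re-capture and opening: apparent unloading rate
`k_h·Kd_CTP/([CTP] + Kd_CTP)`, strictly decreasing in [CTP], bounded by
`k_h`, half-maximal exactly at `[CTP] = Kd_CTP`. The package reports the
CTP-free BLI off-rate and the solution hydrolysis rate as separate
observables and does not force them equal; they differ in the underlying
measurements and the model has no constraint tying them.

**CTPase.** Phosphate time courses (direct μM or OD620 through a linear
standard curve) are fit by an initial linear slope normalized per protein.
Nonmonotonic series trigger a flagged Theil–Sen robust slope instead of OLS.

## Synthetic data

Every generator takes an explicit `NoiseSpec` (gaussian-additive,
gaussian-relative, or poisson) with a mandatory seed — there is no global
random state — and embeds its ground truth and seed in the output metadata,
making every generator/fitter pair an exact round trip at zero noise. The
ChIP generator draws per-bin Poisson counts with IP mean
`depth·(background + occupancy)` and a flat control; background defaults to
10% of peak occupancy (a free parameter, as no measured background level is
assumed). The generators emulate the *shapes and noise families* of the real
assays, not instrument systematics (ITC baseline drift, BLI mass transport,
sequencing mappability): passing recovery tests demonstrates estimator
correctness under the stated noise models, not robustness to every artifact
of real instruments.

## Problem sizes and numerical choices

Stochastic validation runs use 400–500 copies, horizons ≥100× the slowest
network timescale, and 3–6 replicate seeds, comparing means within 3
standard errors; the spreading shape test pools terminal particle positions
from ~120 short independent runs for a Kolmogorov–Smirnov test at α = 0.01.
These sizes were chosen so each statistical check has comfortable power while
the whole suite stays fast. ODE relaxation uses LSODA at rtol 1e-10 (binding
is deliberately stiff relative to conformational rates); ITC fits iterate to
relative tolerance 1e-10 with a 500-iteration cap and a flagged (never
silent) non-convergence result.

## Known limitations

- The coarse model treats a dimer as one unit: no dimerization stoichiometry,
  no protein–protein bridging or condensation contributions to focus
  retention, which may matter in vivo.
- The spreading model has no explicit replication/transcription machinery —
  only generic roadblocks — and no 3D nucleoid structure.
- No fitting of cycle rates to in-vivo data is provided; the kinetic
  parameters are inputs.
- The detailed scheme's untether/retether rates are unconstrained by
  measurement; conclusions drawn from the detailed network should be checked
  for sensitivity to them.
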