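# Methods

## Model

The central control operon of RK2 is transcribed from a single promoter and
encodes its own repressors, KorA and KorB. The model tracks monomer and
dimer concentrations of both proteins (nM, seconds) with consolidated
synthesis (transcription + translation + mRNA turnover collapsed into one
first-order rate per protein), reversible dimerization, and first-order
loss by dilution only (`gamma_P`), appropriate for exponentially growing
cells in which both proteins are stable.

Promoter occupancy is treated quasi-statically: association/dissociation is
fast relative to synthesis and dilution, so at each instant the promoter
DNA is partitioned over the unoccupied (D), KorA-bound (X), KorB-bound (Y)
and doubly bound (Z) configurations. Synthesis proceeds at the full rate
from D, at fractions `pi_X` and `pi_Y` from X and Y (partial repression
applies equally to both genes since the operon is co-transcribed) and not
at all from Z. Dimers bound to promoter DNA (at most `D0` = 4.5 nM against
free pools of hundreds of nM) are not subtracted from the free pools.

### Promoter partition

The measured dissociation constants violate thermodynamic cycle closure
(`k1*k4 = 40.0`, `k2*k3 = 28.8` nM²), so a Boltzmann equilibrium over the
four states is not uniquely defined. The default partition is therefore the
stationary distribution of the four-state association/dissociation cycle
`D <-> X <-> Z <-> Y <-> D` with one association rate constant and
dissociation rates proportional to `k1..k4`; the association constant
cancels from the stationary solution. By the Markov-chain tree theorem the
stationary weights are

```
w_D = k1*k2*(k3+k4) + B2*k2*k3 + A2*k1*k4
w_X = A2*(k2*(k3+k4) + k4*(A2+B2))
w_Y = B2*(k1*(k3+k4) + k3*(A2+B2))
w_Z = A2*B2*(A2+B2+k1+k2)
```

with `A2`, `B2` the free dimer concentrations. Two path-equilibrium
conventions (`Z` weight `A2*B2/(k1*k4)` or `A2*B2/(k2*k3)`) are available
behind the `partition_convention` switch; all three coincide whenever the
cycle closes — in particular for the cooperativity-knockout mutant, where
`k3 = k1`, `k4 = k2` makes detailed balance exact. The chain-stationary
form is the default because it is the only partition derivable from the
reaction scheme without extra assumptions, and because it reproduces the
published variant steady states to better than 2% whereas either path
convention misses by up to 16%.

### Default parameter values

| symbol | meaning | default | unit |
|---|---|---|---|
| `k1`, `k2` | KorA/KorB dimer Kd on naked DNA | 12.9, 9.3 | nM |
| `k3`, `k4` | Kd on the partner-bound complex | 3.1, 3.1 | nM |
| `lambda_A/B` | dimerization rate | 0.001 | nM⁻¹s⁻¹ |
| `sigma_A/B` | monomerization rate | 0 | s⁻¹ |
| `gamma_P` | dilution rate | 0.0003875 | s⁻¹ |
| `D0` | promoter DNA | 4.5 | nM |
| cell volume | count ↔ nM conversion | 4.15 | µm³ |

`gamma_P` is the tabulated measured value and equals 1/2580 s⁻¹, the
reciprocal of the ~43 min doubling time; note it is not ln2/t_double. The
synthesis rates `k_A`, `k_B` and the scaling factors have no defaults — they
are what the inference estimates, and the five variant presets carry their
fitted modes.

## Steady states

At any fixed point the dimer balance gives
`A2 = lambda_A*A1²/(2*(sigma_A+gamma_P))` exactly, which reduces the
four-dimensional root problem to two equations in the monomer
concentrations. Because repressors can only decrease promoter activity,
each reduced residual is strictly decreasing in its own variable, so a
bracketing scan over the admissible range (`A_tot` at most
`D0*k_A/gamma_P`, the unrepressed closed form) enumerates every root
reliably. The fast path is a damped Newton iteration on
`(ln A1, ln B1)` with finite-difference Jacobian (relative residual
tolerance 1e-11, capped log-steps, backtracking line search), warm-started
inside the sampler from the previous accepted solution; the scan is the
fallback and the multi-start policy. If distinct roots ever disagree by
more than 0.1%, the root reached by integrating the ODEs from the empty
cell is reported as canonical and the multiplicity is flagged; across all
tested configurations the model has shown a single root. Time integration
uses a stiff-capable LSODA solver with rtol 1e-8 / atol 1e-10.

`unrepressed_total = D0*k_syn/gamma_P` follows from the dimerization terms
cancelling out of the total-monomer budget; the dimer gain of
`lambda/2 * monomer²` is the unique stoichiometry consistent with the
monomer equation and mass conservation, and it reproduces all printed
no-repression totals exactly.

## Bayesian inference

The three observations — total KorA and KorB monomers in the wild type and
total KorB in the cooperativity-knockout mutant (modes 1600, 400, 920 nM) —
enter the likelihood as independent lognormal factors whose analytic mode
is the measured value and whose cv is the measurement error: 0.5 for the
standard runs, 0.1 for the runs that estimate the scaling parameters
(`tight=True`, which also caps the measured-parameter prior cvs at 0.1).
The lognormal mode/cv parameterization is `s² = ln(1+cv²)`,
`mu = ln(mode) + s²`. The mutant prediction re-solves the steady state with
`k3 = k1`, `k4 = k2`.

Priors: lognormal mode/cv for every measured parameter (Table above),
uniform [0, 1] for `pi_X`, `pi_Y`, and wide log-uniform for the unmeasured
synthesis (1e-5..1e5 s⁻¹) and monomerization (1e-30..1e10 s⁻¹, 40 decades)
rates. On the log sampling scale the log-uniform priors are flat, so the
multiplicative proposals explore all orders of magnitude without bias.

The sampler is blocked Metropolis–Hastings: all positive parameters form
one block updated jointly by multiplying each by `exp(N(0, 0.05))`
(symmetric on the log scale, where the walk actually lives; prior densities
carry the log-scale Jacobian), and `pi_X` and `pi_Y` form two
single-parameter blocks with additive `N(0, 0.08)` proposals, rejected
through the prior when they leave [0, 1]. Blocks rotate deterministically.
Chains are reproducible bit-for-bit from their seed. Defaults: burn-in 10%,
thinning 360 for summaries of long chains.

Posterior modes are kernel-density estimates computed on the log scale for
positive parameters with the change-of-variables term included (the
maximiser of `log f(y) − y`, `y = ln x`), so the reported mode is the
natural-scale density mode; cv is sd/mean on the natural scale and
intervals are central quantiles.

### Desk-scale sampler settings

The full-model posterior is bimodal: a dimer-dominated regime (high
synthesis, monomerization far below dilution, promoter mostly doubly
bound) and a monomer-dominated regime (synthesis rates ~2 orders of
magnitude lower, monomerization above ~10² s⁻¹, promoter mostly free). A
profile-likelihood scan over the monomerization rate shows the two basins
differ by less than one log-posterior unit at their connecting ridge — the
separation is diffusive, not energetic, spanning ~6 decades of sigma that a
0.05-step random walk crosses only on the multi-million-iteration scale.
The test suite therefore samples the full model with four chains of 1e5
iterations whose sigma starting points are stratified across the prior
support (1e-25, 1e-15, 1e-5, 1e5 s⁻¹) and pools them after 10% burn-in;
within each basin the chains equilibrate quickly, and the pooled marginal
exhibits the bimodal synthesis-rate structure and the flat, many-decade
monomerization marginal. Variant fits (sigma fixed at 0) are unimodal and
use single chains of 0.8–1.2e5 iterations.

## Metabolic control analysis

Concentration control coefficients are central log-log differences of the
steady-state output with respect to each parameter,
`[ln S(p·e^h) − ln S(p·e^−h)]/(2h)`, with `h` halved from 0.1 until two
successive estimates agree to 1e-4 (absolute floor 1e-6); an
implicit-function-theorem computation on the reduced fixed-point system
serves as an independent oracle in the tests. A parameter fixed at zero has
no multiplicative perturbation and its coefficient is reported as exactly
zero. Because the steady state is invariant under a common rescaling of all
time-dimensioned rates, the coefficients of
`{k_A, k_B, sigma_*, lambda_*, gamma_P}` sum to zero per output — used as a
structural diagnostic (tolerance 1e-3). Magnitude classes: strong |C| ≥
0.5, negligible |C| < 0.05, moderate between.

## Repression variants and copy-number curves

Variant labels fix the scaling factors (`1` → 1, `0` → 0, `u` → free/fitted)
and zero the monomerization rates. The repression ratio is the closed-form
unrepressed KorA total divided by the regulated steady state. Copy-number
curves convert `n` plasmids to nM via the 4.15 µm³ cell volume
(11 plasmids ≈ 4.40 nM); the tabulated physiological column is computed at
`D0 = 4.5 nM` exactly, matching the measured DNA abundance. The benchmark
crossing is the smallest integer copy number whose ratio reaches 91.8.
Posterior-ensemble curves take every 360th post-burn-in sample, compute the
ratio per sample and copy number, and summarize each copy number by the
mode of a log-moment-fitted lognormal with a delta-method standard error.

## Synthetic data

The generator emulates the study's observation model only: steady-state
population-average abundances perturbed by independent lognormal noise with
mode at the noiseless value and stated cv. It does not emulate single-cell
variability, growth-phase drift, or Western-blot calibration bias, so
passing recovery tests demonstrate correctness of the inference machinery
under the assumed noise model, not robustness to real measurement
pathologies. Default ground truths are the fitted `uu` and `u0`
parameterizations. The closed-loop calibration check refits `k_A`, `k_B`
(all else held at truth) on 20 seeded replicates at cv = 0.1 with
6000-iteration chains and requires the 90% credible interval to cover the
true `k_A` in at least 80% of replicates.

## Known limitations

* The partition convention is a genuine reconstruction ambiguity of the
  measured, cycle-violating affinities; all outputs log the convention used.
* Mode estimates from desk-scale chains carry a few percent of
  sampler-settings uncertainty (bandwidth, burn-in, thinning).
* The acceptance probability of the `pi` blocks under additive sd-0.08
  proposals is ~0.7–0.9, not the 0.234 design target: with the broad
  scaling-factor posteriors this model produces (posterior sd ≈ 0.3), small
  symmetric proposals are almost always accepted. The per-block rates are
  reported by `tune_acceptance` and the adjustment suggestions are advisory.
* No mRNA submodel, no repressor interaction in solution, no stochastic
  (Gillespie) simulation — outside the model's intended scope.
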