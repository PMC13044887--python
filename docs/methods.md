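# Methods

`taqsim` is a mechanistic ("digital twin") simulator of singleplex TaqMan
real-time PCR.  It predicts the full fluorescence-vs-cycle amplification
curve (AC) — exponential phase, linear phase and plateau — from sequences,
concentrations and a small set of thermokinetic hyperparameters, and
recovers those hyperparameters from dilution-series data by global
optimization.  This note records the model, its assumptions, the defaults,
the numerical choices, and what the synthetic-data generator does and does
not emulate.

## Reaction network

Twelve molecular species are tracked per cycle: the double-stranded
amplicon `AA`; its single strands `A_for`, `A_rev`; the primers `P_for`,
`P_rev`; the hydrolysis probe `Q`; the primer-template hybrids `H1`
(`A_for·P_rev`) and `H2` (`A_rev·P_for`); the probe hybrids `AQ`
(`A_for·Q`), `AQP` (primer added to `AQ`) and `H1Q` (probe added to `H1`);
and the primer dimer `PD`.  `AQP` and `H1Q` are structurally identical but
are kept as separate state entries because they form and dissociate through
distinct reaction channels.  By convention the probe binds the forward
strand, in the same orientation as the reverse primer.  Off-site primer
binding, probe–primer dimers and three-oligo complexes without template are
not modeled.

A PCR cycle is three operations:

1. **Denaturation** — assumed complete: every hybrid dissociates into its
   constituent single molecules.  No kinetics; the step time only enters
   through the enzyme-decay law.
2. **Annealing** — mass-action kinetics of the 12 species integrated over
   `time_annealing`.  The 12 coupled ODEs conserve five family totals
   (A_for-, A_rev-, P_for-, P_rev- and Q-containing species), giving 17
   relations in total; the conservation identities hold algebraically in
   the right-hand side and are verified numerically along every trace.
3. **Elongation** — a fraction `Eff_c` of each extendable hybrid (`H1`,
   `H2`, `AQP`, `H1Q`) converts instantaneously to `AA`; the rest remains
   as hybrid and is dissolved by the next denaturation.  `AQ` is never
   extended (the probe's 3' end is blocked) and `PD` is inert.  Elongating
   `AQP`/`H1Q` cleaves the probe; cumulative cleaved probe is the
   fluorescence readout, at one arbitrary unit per cleaved molecule
   (numerically mol/L).  No instrument response model is applied: the
   mapping from cleaved probe to measured signal is assumed linear.
   Extension time/temperature are accepted in the protocol but carry no
   kinetics of their own.

## Thermodynamics and rate constants

Duplex free energies come from unified nearest-neighbor (NN) sums
(Biopython's `DNA_NN3` table by default; recorded as `table_id` in all
result metadata).  For each oligo the perfect-match duplex against its
binding site (oligo length = duplex length) gives ΔH, ΔS, then
ΔG = ΔH − TΔS and K = exp(−ΔG/RT), all evaluated at the annealing
temperature.  Thermodynamics default to the tabulated 1 M Na⁺ reference
state; an optional monovalent-salt entropy correction
(ΔS += 0.368·(N−1)·ln[Na⁺] cal/mol/K) can be enabled, since assay buffers
are far from 1 M Na⁺ — the default is off because the effective ionic
correction is partly absorbed by the fitted association rate.

Association rates are not sequence-resolved: a single user-set (or fitted)
`k_on` applies to all oligos, and each dissociation rate follows
`k_off = k_on / K`.  Amplicon reannealing (`A_for + A_rev → AA`) has its own
`kr_on` and is irreversible (`kr_off = 0`): the free energy of a
full-length duplex makes dissociation at annealing temperature negligible.

The primer dimer is generally not a perfect-match duplex, so its ΔG comes
from a pluggable provider.  The default scans every ungapped antiparallel
alignment register of the two primers, NN-scores each maximal complementary
run of ≥ 2 bp as a perfect-match duplex, and takes the minimum ΔG; an
external secondary-structure engine or a user constant can be registered
instead.  When no register has two consecutive complementary pairs the PD
reaction is disabled (`kPD_on = 0`) rather than assigned a huge off-rate,
which would only add stiffness.

## Enzyme thermal decay

Polymerase activity at cycle `c` follows the two-parameter
stretched-exponential law

    Eff_c = Eff0 · exp(−(k_deg · time_denaturation · c)^β),  Eff0 = 1.

`k_deg` (1/s) sets the decay rate accumulated during the hot denaturation
steps; `β` (dimensionless, > 0) shapes the profile, with `β = 1` recovering
classical first-order decay.  `Eff` is evaluated at the current 1-based
cycle index, so cycle 1 already shows decay when `k_deg > 0`; cycle 0 is
the pre-PCR baseline with full activity.

## Quantification

* **Ct** — second-derivative-maximum: the central second difference
  `F(c+1) − 2F(c) + F(c−1)` is maximized over interior cycles; ties resolve
  to the earliest cycle; the Ct is an integer cycle (a quadratic
  interpolation refinement exists behind a flag, default off).  A curve is
  called undetected when its amplitude falls below 5% of the batch's
  largest amplitude (single curves: an absolute floor only).  Both rules
  are package choices; no community standard fixes them.
* **Standard curve** — ordinary least squares of Ct on log10(concentration)
  over detected, non-NTC dilutions.  At perfect doubling the slope is
  −log2(10) ≈ −3.32 cycles/decade.
* **Sigmoid descriptors** — the five-parameter logistic
  `F(c) = Fb + Fm / (1 + exp(Sc·(c − Cs)))^As` fit by bounded
  trust-region-reflective least squares.  `Fm` is the final fluorescence
  intensity (FFI); increasing curves have `Sc < 0`.  Initialization: `Fb` at
  the minimum, `Fm` at the amplitude, `Cs` at the Ct (mid-grid fallback),
  `Sc = −0.3`, `As = 1`, with `Fb, Fm ≥ 0` and `As ∈ (10⁻³, 10²]`.

## Hyperparameter fitting

The fit recovers `args = {k_deg, β, k_on, kr_on, dna_high, p_for, p_rev,
q}` (any subset free, the rest fixed) from a dilution series of
experimental ACs.  The forward model simulates exact 10-fold steps downward
from `dna_high`, matching the experimental series length; NTC curves are
excluded from the objective.  In `primer_probe_ratio` mode only the probe
concentration is free and the primers follow fixed primer-to-probe ratios,
reflecting that absolute oligo concentrations are poorly identified while
their ratios shape the curve family.

The objective is a scaled mean squared error: per curve, baseline (min)
subtraction and amplitude (max − min) normalization, then the mean squared
difference over cycles, averaged across curves.  Two scalings are
available and pluggable: the default normalizes each curve by its own
baseline/amplitude, which makes the objective invariant to affine unit
changes on either side — necessary because simulated curves are in molar
cleaved-probe units while experimental ones are in instrument units — and
an `"experimental"` mode normalizes both curves by the experimental
statistics for same-unit comparisons.

The optimizer is scipy differential evolution, `best1bin`, mutation
0.5–1.0, recombination 0.7, convergence tolerance 1e-6, with a final local
polish; population size and iteration caps are configurable.  Candidates
whose forward simulation fails are assigned a large finite penalty (10×
the worst successful objective so far, floored at 1e3) so the search
continues.  Fits are bit-reproducible for a fixed seed.  Because several
hyperparameter sets can produce nearly indistinguishable curve families,
seed-to-seed agreement is assessed on predicted curves (mutual scaled MSE),
not on the recovered parameter vectors.

`compare_decay_models` runs the fit twice — β free versus β pinned at 1 —
under identical bounds and stopping criteria, quantifying how much the
stretched-exponential decay improves over first-order decay on a given
dataset.

## Numerical choices

* **Integrator** — the annealing system is stiff (concentrations span
  from single copies, ~1.7e-18 M, to hundreds of nM).  LSODA is the
  default, BDF and Radau are available, all supplied with the analytic
  12×12 Jacobian.  Defaults `rtol = 1e-6`, `atol = 1e-26` M.  The atol sits
  below any physically meaningful concentration (one copy/µL is 1.66e-18
  M) so that template-family species are always resolved relatively; with
  looser absolute tolerances the low-copy species are error-dominated and
  mass conservation degrades by many orders of magnitude.  With these
  defaults the five family totals are conserved to ~1e-15 relative along
  traces, and LSODA and BDF agree to better than 1e-4 on final states.
* **Negative concentrations** — after integration, values above
  −(10·atol + rtol·max(y)) are clipped to zero (stiff-solver noise);
  anything more negative raises, since it indicates a defect rather than
  roundoff.  Fluorescence increments use pre-clipping hybrid values.
* **Trace grid** — annealing is reported on a uniform 100-point grid per
  cycle by default (`n_out` configurable).
* **Unit conversion** — copies/µL ↔ mol/L uses the exact 2019-SI Avogadro
  constant: `c[M] = x · 1e6 / N_A`.

## Synthetic data

`make_assay` generates random assays with the real geometry: an amplicon
(60–150 nt, GC content bounded), a forward primer equal to its 5' end, a
reverse primer reverse-complementary to its 3' end, and a probe
reverse-complementary to a central, non-overlapping internal site.
`make_pseudo_experiment` simulates a 10-fold dilution series under known
hyperparameters and adds additive Gaussian noise (σ as a fraction of the
series plateau) plus an optional affine gain/offset that mimics arbitrary
instrument units.  Default conditions are the regime the simulator is
designed around: primers 450 nM, probe 150 nM, `k_on = 1e6 /M/s`,
`kr_on = 1e7 /M/s`, `k_deg = 1e-4 /s`, `β = 1`, top template 1e7
copies/µL, 15 s denaturation / 30 s annealing at 95/60 °C.

What the generator does **not** emulate: sequence-dependent amplification
biases beyond NN thermodynamics, secondary structures (hairpins,
G-quadruplexes), baseline drift, well-to-well variability, inhibitors, or
truncated amplicons.  Tests passing on pseudo-experiments therefore
demonstrate internal consistency of the model and the invertibility of its
parameters under its own assumptions — not accuracy against wet-lab data,
which requires instrument measurements outside the scope of this package.

## Problem sizes used by the test suite

The recovery experiments use 3 dilutions × 45 cycles (noiseless) with a
reduced differential-evolution population (6×) and a capped generation
count ahead of the polish step; these sizes were chosen so the full suite
runs comfortably on a single CPU while leaving the optimizer enough budget
to resolve the weakly identified decay constant.  Conservation sweeps use
50 random configurations; sigmoid noise statistics use 50 replicates at
σ = 1%.

## Known limitations

* Complete denaturation and instantaneous elongation are idealizations;
  very short step times are not penalized.
* `k_on` shared across oligos ignores sequence- and length-dependent
  association kinetics; it is an effective, assay-level parameter.
* The decay law attributes all efficiency loss to the enzyme; reagent
  depletion is modeled mechanistically but other late-cycle effects
  (e.g. nonspecific polymerase sequestration) are not.
* `k_deg` is weakly identified when decay is mild (activity changes a few
  percent over the run); the fit diagnoses this via seed-repetition on
  predicted curves rather than claiming unique parameter recovery.
* Multiplex PCR, melting curves and intercalating-dye chemistries are out
  of scope.
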