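# Methods

## Model

Two transcription factors (TFs), fixed in the population immediately after a
gene duplication, regulate `n_G` genes (one binding site per gene, length
`L`, 4-letter alphabet).  Binding energy is additive in mismatches: a site
at `k` mismatches from a TF's consensus binds with equilibrium occupancy
`C e^{-eps k} / (1 + Σ C e^{-eps k})`, summed over active TFs.  Two binary
environmental signals occur with frequencies `f1, f2` and correlation
`rho`; the induced joint law over the four environments is
`α_11 = f1 f2 + rho·sqrt(f1(1-f1)f2(1-f2))` with the remaining cells fixed
by the marginals, valid only when `α_11` lies in the Fréchet interval
`[max(0, f1+f2-1), min(f1, f2)]` (outside it the package raises an
impossible-signal-statistics error, and phase maps label the cell
Impossible).  Each TF carries a two-bit sensing allele; an active TF has
concentration `C0` regardless of how many of its signals are present
(binary activation, no additivity).  Genes split evenly between the two
signals (first half → signal 1); `n_G = 1` is additionally accepted as a
validation configuration because the exhaustive full-sequence oracles are
only affordable with a single gene.

Fitness penalises squared deviation of occupancy from the signal-matched
ideal, weighted by environment probability and by error weights `β` (1 for
a missed induction, ½ for a spurious one, both configurable).  Repressor
mode transforms expression to `1 − occupancy` and changes nothing else; with
uniform `β` it is the exact mirror of the activator model.

Evolution is origin–fixation: transition rates are
`2 N μ_xy Φ(ΔF)`, with the Kimura diffusion form
`Φ = (1−e^{−2ΔF})/(1−e^{−2NΔF})`.  Three microscopic mutation classes are
modelled — binding-site point mutations (rate `μ/3` per position per target
letter), TF consensus point mutations (`r_TF μ/3`), and sensing-bit flips
(`r_S μ`) — plus promiscuity toggles (`r_P μ`) in the extension.

## Reduced genotypes and exact lumping

All sequences collapse onto `{M, k_ij, σ_i}`.  The degeneracy of a mismatch
pair, `N_seq(k1, k2 | M)`, is computed by summing exact integer arrangement
counts over site compositions (the five position classes a/b/c/d/e defined
in `combinatorics.py`); it is validated against direct enumeration of all
`4^L` sequences for every `(k1, k2, M)` up to `L = 6`.  The neutral weight
of a state is `C(L, M) 3^{L−M} Π_j N_seq`, sensing alleles counting 1 each.

The reduced chain is not strongly lumpable, so lumped mutation rates are
defined as expectations of the microscopic rates over the within-class
(uniform) composition law.  Two structural facts make these expectations
exact, closed-form products rather than Monte-Carlo averages: site
compositions are independent across genes given the consensus pair, and for
a consensus mutation the per-gene mismatch change depends on the position
class at a single, exchangeable position.  The implementation enumerates
per-gene three-point laws for each consensus-mutation class (agreement
position; disagreement position mutating into, or away from, the other
consensus) and convolves them across genes.  At `L = 2, n_G = 1` the
resulting rate matrix agrees with the explicitly marginalised
65,536-state full-sequence chain to machine precision, and the steady
states agree to TV ~1e-15.

A consequence used heavily in the numerics: the lumped chain is *exactly
reversible* with respect to `P0 · e^{2(N−1)F}`, because class-averaged
neutral rates inherit detailed balance from the symmetric microscopic rates
and the Kimura ratio `Φ(ΔF)/Φ(−ΔF) = e^{2(N−1)ΔF}` supplies the tilt.  The
closed-form steady state `P0 · e^{2NF}` differs only in the `2N` vs
`2(N−1)` exponent, an `O(s)` discrepancy (TV ≈ 2e-4 at baseline).

## Strong/weak binding and macrostates

Every TF–gene interaction is called *strong* when the single TF at
concentration `C0` would occupy the site with probability > ½, i.e.
`k < ln(C0)/eps`; the call is a function of `k_ij` alone.  The default
concentration scale is `C0 = e^{1.5 eps}` (~90 at `eps = 3`), which
saturates consensus sites (`p(0) ≈ 0.989`) while placing the half-occupancy
point at `k* = 1.5` — strictly between integers, so the call never sits on
a tie, and only near-consensus sites (`k ≤ 1`) count as strong.  This
choice was pinned down by a robustness requirement of the model itself: with
the cut between `k = 1` and `k = 2` the Specialize-Both / One-TF-Lost phase
boundary is *independent of L* (ρ* = 0.85 at L = 4, 5, 6) and the
No-Regulation : Specialize-Both genotype-count contrast is ~3×10⁴, whereas
a looser cut (`k* = 2.5`) destroys the boundary altogether at `L = 4` and
collapses the count contrast to ~7×10². `C0` remains fully configurable.

Macrostates are assigned by the first matching rule: Specialize Both (the
strong matrix is a TF↔gene-group permutation with no cross-binding and each
TF senses exactly its group's signal); Specialize Binding (such a
permutation, both TFs sense something); Initial (everything strong, both
TFs sense both signals); One TF Lost (one TF strongly binds every gene and
senses something, the other binds nothing — its sensing is unconstrained);
No Regulation (no strong bond from a signal-responsive TF); Partial
(everything else).  The rules are total and disjoint in this order; for
`n_G > 2` the permutation is over gene *groups*.  Free fitness of a
macrostate is the soft-max `F̂(z) = (2N)^{-1} ln Σ_{G∈z} P0(G) e^{2NF(G)}`,
so that steady-state macrostate weights are exactly `∝ e^{2N F̂}`.

Two caveats on headline numbers.  The count contrast between
No Regulation and Specialize Both is a step function of the strong/weak
convention (7×10² or 3.2×10⁴ at L = 5; nothing in between) — the package
reports the computed value for the adopted convention rather than
interpolating toward a rounder order of magnitude.  Relatedly,
No-Regulation's free fitness
is only *approximately* independent of signal correlation here, because
weak (`k = 2`) interactions still carry occupancy ≈ 0.18; the tests assert
it is several-fold more ρ-robust than the crosstalk-prone macrostates
rather than exactly constant.

## Numerical choices

* **Fixation probability**: `expm1`-based evaluation with a neutral branch
  at `|N ΔF| < 1e-10` and a log-space branch for strongly deleterious
  mutants (underflows smoothly to 0 below `ΔF ≈ −0.37` at `N = 1000`).
* **Steady state**: closed form by log-sum-exp; the independent null-space
  route fixes the distribution at a reference state and solves the
  remaining balance equations (direct sparse LU below 5,000 states, ILU
  (`drop_tol 1e-5, fill 15`) preconditioned GMRES above, residual-checked to
  `‖Q^T π‖∞ / max|Q| ≤ 1e-8`).
* **Hitting times**: the absorbing system `−Q̃ T = 1` is symmetrised with
  the reversible weights and solved by Jacobi-scaled conjugate gradients
  (tens of iterations even for the 36,720-state baseline); the residual of
  the *original* system is always verified, with ILU-GMRES and direct LU
  fallbacks, so correctness never rests on the reversibility argument.
* **Dynamics**: uniformization (Poissonised jump chain, truncation mass
  1e-12) as the exact default; the per-generation Euler update is provided
  for fidelity to the forward-integration description, with automatic
  substepping when the largest per-step exit probability exceeds 0.1.
* **Time units**: `t_g = 1` generation, `μ = 1e-5` per site per generation
  (keeping `2Nμ ≪ 1`, the origin–fixation condition); reported times are
  multiplied by `μ` to land in units of 1/μ, where steady states are exactly
  invariant to rescaling `μ`, `r_S`, `r_TF` (asserted in tests).
* **Dwell times**: mean first-exit time from a macrostate averaged over its
  states with steady-state-conditional weights by default (uniform
  available); simulated sojourns are compared against the entry-flow-
  weighted analytic value, which is the like-for-like quantity.

## Stochastic simulation

The reduced-chain Gillespie sampler draws exponential waiting times from
precomputed rate rows; replicates are seeded as `default_rng([root, i])`,
making ensembles independent of execution order.  The explicit-sequence
simulator proposes every single mutation with its microscopic rate and
accepts through `Φ`; its reduced projection reproduces the lumped chain's
occupancy statistics (TV < 0.05 at `L = 3`) and its neutral TF–TF match
distribution is Binomial(L, ¼).  With `r_P = 0` the promiscuity extension
adds no proposals and is bit-for-bit the base simulator under the same
seed.

Pathways to specialization are classified per trajectory: *slow* if One TF
Lost is visited before first reaching Specialize Both, *fast* otherwise,
*unresolved* at the horizon.  The deleterious-fixation fraction counts
accepted substitutions with `ΔF < 0` up to arrival.

**Promiscuity extension.**  A promiscuity-promoting mutation marks one
consensus position as insensitive; effective mismatches count only specific
positions, so gaining promiscuity never increases any mismatch.  Gains
occur at `r_P μ` per specific position; reversion re-specifies the position
at total rate `r_P μ` with the preferred letter drawn uniformly from the
four bases (a stored-letter mode is available; uniform is the default since
the re-specified preference is itself a random mutation).  Promiscuity has
no explicit cost — costs emerge through crosstalk binding.  The extension
runs only on the explicit-sequence simulator: under masks the reduced state
is no longer a sufficient statistic, and the quantities of interest are
trajectory statistics anyway.

## Study conditions and problem sizes

Baseline parameters throughout: `L = 5`, `eps = 3`, `r_S = r_TF = 1`,
`n_G = 2`, `N = 1000` with `s` set from the requested `Ns` (default 25),
`f1 = f2 = ½`, `rho = 0`.  The acceptance computations use: the full
36,720-state baseline space; phase maps on a ρ-grid of step 0.05 with the
boundary-robustness check at `L = 4, 5, 6`; 400 Gillespie replicates for
specialization times (horizon 1000/μ, no censoring in practice); and the
four-gene promiscuity experiment at `Ns = 25` with 100 replicates per
condition and horizon 50/μ, where mean times are horizon-censored means
(the unresolved fraction is reported alongside).  These sizes were chosen
so every quantity is either exact or has a standard error well below the
effects being measured.

## What the model does and does not emulate

The generator/simulator realises the model's own idealisations: one binding
site per gene, a uniform mismatch energy (no position-specific energy
matrix beyond the promiscuity mask), binary signals and binary TF
activation, monomorphic origin–fixation dynamics (no clonal interference,
recombination or diploidy), and a static environment distribution.  Tests
passing therefore certify internal consistency of the landscape, the exact
combinatorics and the dynamics — not that real TF families evolve at these
rates; in particular absolute times (in 1/μ) translate to years only
through organism-specific μ and generation times, and the sensing alleles
compress what is in reality a graded ligand-specificity continuum.

## Known limitations

* State-space enumeration grows as `(#feasible pairs)^{n_G}`; the lumped
  chain is practical up to `L ≈ 6, n_G = 2` (an explicit size guard raises
  beyond ~5×10⁶ states).  Larger `n_G` runs on the explicit-sequence
  simulator only.
* The ILU-preconditioned null-space solve at the baseline size takes ~2
  minutes; the closed form (exact up to the `2N` vs `2(N−1)` exponent) is
  the default everywhere else.
* Conditional pathway times depend on the simulation horizon through the
  unresolved fraction; defaults keep that fraction at zero for the baseline
  and report it for the multi-gene runs.
* `Φ` underflow makes strongly deleterious transitions exact zeros in the
  generator; this is harmless for the quantities computed here but means
  the generator's sparsity pattern is slightly selection-dependent.
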