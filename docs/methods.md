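# Methods

`lnpkmc` simulates the post-mixing growth stage of RNA-loaded lipid
nanoparticle (LNP) self-assembly and the population statistics that
determine therapeutic payload quality: the fraction of empty particles,
the RNA-copy distribution and its variance, and the final size
distribution. This note records the model, its assumptions, the default
parameters and why they hold their values, and what the synthetic study
conditions do and do not establish about real formulations.

## Physical model

**Coalescence kinetics.** After turbulent mixing, the suspension is
treated as well mixed and spatially structureless. N spherical LNPs in a
volume `Vsystem` undergo pairwise fusion with rates

    k_ij = Kcollide(R_i, R_j) * exp(-E_b(i, j)) / Vsystem,

where `Kcollide = (2 kBT / 3 eta) (R_i + R_j)^2 / (R_i R_j)` is the
Brownian (Smoluchowski) collision kernel for spheres and `E_b` (in kBT)
is an Arrhenius fusion barrier. The dynamics are simulated exactly with
a Gillespie algorithm: a pair is drawn with probability `k_ij / sum(k)`,
time advances by an exponential variate with mean `1/sum(k)` (a
deterministic mean-increment mode is available as a config option), the
pair merges, and only the N−1 rates involving the merged particle are
recomputed. Merging conserves lipid and RNA content exactly; the bare
radius follows from `(4/3) pi R^3 = V_constituents / (1 - fw)` with
`fw = 0.2` the internal water fraction, so equal spheres merge to
`2^(1/3) R`.

**Fusion barrier.** `E_b = E_PEG + W*`, with

* `E_PEG = c_PEG * 2 pi (RF^3 / v0)(1 - fw) * R_i R_j (R_i phi_i^PEG +
  R_j phi_j^PEG) / (R_i + R_j)` — the entropic cost of clearing mobile
  PEG-lipid from the contact zone. `RF = a n^(3/5)` is the PEG Flory
  radius (`a = 0.37` nm, `n` the degree of polymerization), `v0` the
  volume per lipid, and `phi^PEG` the PEG-lipid volume fraction. For
  equal particles this reduces to `E_PEG ∝ phi_PEG R^2`: the barrier
  grows quadratically with size, which is what makes growth
  self-limiting and the final size insensitive to the initial size.
* `W* = max_d W(d)`, the maximum over surface separation of the DLVO
  profile `W(d)` combining van der Waals attraction (Hamaker constant
  `A`) and screened electrostatic repulsion between constant-potential
  spheres (Hogg–Healy–Fuerstenau form) with Debye length `lD(csalt)`.
  Purely attractive profiles contribute no barrier. For equal particles
  the electrostatic barrier grows only linearly in R, which is why PEG
  dominates size selection.

**Charge regulation.** Each particle's reduced surface potential
`psi = e0 psi0 / kBT` solves the self-consistency problem of a
permeable, uniformly charged sphere (Donnan approximation inside, the
potential treated as uniform and equal to the surface value):

    rho(psi) = (1 - fw) (alpha_MC3 rho_MC3 phi_MC3
               + alpha_RNA rho_RNA phi_RNA) - 2 fw csalt NA sinh(psi)
    psi      = (4 pi / 3) lB rho R^2 / (1 + R / lD)

with `lB` the Bjerrum length and `rho_RNA < 0`. The residual is strictly
decreasing in `psi`, so the root is unique; it is found by bracketed
root-finding to |residual| < 1e-10 and memoized per particle type.
RNA-loaded particles are closer to neutral than empty ones (at N/P = 6
and the mean load, the internal amine and phosphate charge nearly
cancel), so empty LNPs repel each other more strongly — the mechanism
behind the transient early rise of the empty fraction and the faster
merging of loaded particles.

**Dialysis schedule.** Environment changes are time-stamped overrides
(default: at t = 1 h, csalt 0.025 → 0.15 M and ionizable-lipid
ionization `alpha` from 1.0 to the Henderson–Hasselbalch value
`1/(1 + 10^(7.4 - 6.44)) ≈ 0.099` at pH 7.4, pKa 6.44). Events never
straddle a change point: the waiting time is truncated at the change,
the environment updated, all surface potentials re-solved and the full
rate table rebuilt, and the (memoryless) event clock redrawn.

**Initialization.** Mixing produces mostly empty primary particles. The
initial population has `round(theta0 * N0)` empty LNPs (default
`theta0 = 0.83` at the mixing time) of bare radius `R0`; the remaining
particles share the conserved RNA total, which follows from the N/P
ratio bookkeeping (amines per particle / 6 / 44 phosphates per RNA).
The allocation law is zero-truncated Poisson by default (geometric and
equal-split alternatives exposed), repaired to exact conservation.
`Vsystem` is derived from the siRNA mass concentration (20 µg/mL), its
molecular weight (14 kDa), N/P = 6 and the lipid content per particle,
giving ~1e10 nm³ for 2500 particles. `R0` can be given directly or
derived from mixing conditions: the flow-rate correlation
`tau_M = (b1/1.75) Q^(-alpha1)` (b1 = 1.3e3, alpha1 = 1.5, turbulent
regime Q ≥ 10 mL/min) or the shear-layer relation `tau_M = l²/2D`
(D calibrated so tau_M(110 nm) = 25 µs), followed by constant-kernel
mean-field coalescence `n(t) = n0/(1 + 4 kBT n0 t / 3 eta)` up to
`R0 = seed (n0/n)^(1/3)`.

## Units and numerics

Lengths are nm, time s, energies kBT, salt mol/L; conversions are
localized in `physchem`. The DLVO barrier maximum is located on a
72-point log-spaced grid over `d ∈ [0.3 nm, 10 lD]` followed by one
exact evaluation at the parabolic apex through the best grid point in
log d; this agrees with a 4000-point grid to < 1e-3 kBT. The rate table
is a dense symmetric matrix with per-row totals (O(N) selection and
update per event, exact O(N²) rebuild at initialization and environment
changes, deduplicated over identical `(lipid units, RNA copies)`
particle types — exact because all particles descend from identical
primaries). Degenerate inputs: csalt = 0 raises an unscreened-regime
error; zero total rate freezes the run gracefully; `theta0 = 1` is the
RNA-free corner. Exponential-variate time steps are the default
(`time_increment: mean` reproduces the deterministic mean-waiting-time
variant).

## Default parameters

| Parameter | Default | Why |
|---|---|---|
| molar ratios MC3:DSPC:chol:PEG | 50:10:38.5:1.5 | benchmark siRNA formulation |
| PEG MW | 2000 Da (RF = 3.65 nm) | benchmark PEG-lipid |
| v0 | 1.3 nm³ | typical lipid molecular volume |
| fw | 0.2 | internal water fraction of LNPs |
| N/P | 6 | formulation stoichiometry |
| charges per RNA | 44 | 22 bp siRNA phosphates |
| RNA volume | 12.8 nm³ | 14 kDa at ~0.55 cm³/g |
| csalt | 0.025 M → 0.15 M at 1 h | acetate buffer, then PBS dialysis |
| alpha_MC3 | 1.0 → 0.099 at 1 h | fully protonated at pH 4; pKa 6.44 at pH 7.4 |
| Hamaker A | 1e-20 J | standard lipid-colloid magnitude |
| T, eta | 298 K, 8.9e-4 Pa s | water at room temperature |
| N0 | 2500 | study population size (2000 used for kernel-ablation checks) |
| theta0 | 0.83 | empty fraction at the mixing time |
| c_PEG (PEG multiplier) | 0.02 | see below |
| t_end | 18 h | measurement endpoint |

**PEG barrier calibration.** The printed grouping of the steric-barrier
prefactor leaves its absolute energy scale ambiguous (a literal nm
evaluation read as kBT gives ~400 kBT at contact for 9-nm particles,
freezing all dynamics). The formula is therefore implemented literally
with a single dimensionless multiplier `c_PEG`, calibrated once so the
default formulation reaches the reported kinetic regime — a number-mean
bare radius of ≈ 20 nm at 18 h. All scaling statements (R² growth,
linearity in `phi_PEG`, RF³ dependence of the MW effect) are independent
of this constant. `c_PEG = 0.02` corresponds to ~22 kBT at the 20-nm
self-limiting size.

**Mean-field seed density.** The seed number density used to map
`tau_M(Q)` to `R0` (6.9e-6 nm⁻³ with 1-nm seeds) is an effective value
calibrated so that Q = 10–30 mL/min spans R0 ≈ 10–6 nm, the study's
initial-radius range; the literal lipid number density over-predicts
early growth because sub-spherical intermediates diffuse and fuse more
slowly than spheres.

## Charge-regulation surrogate

The exact solver is cheap, so the engine uses it by default; the
surrogate exists for API parity and large-scale screening. Direct
regression of `psi(R, phi_RNA, csalt)` is ill-conditioned: near charge
neutralization at low salt, `psi` is a sigmoid of composition with
width ~1e-3 in `phi_RNA`. The surrogate instead interpolates the
two-parameter reduced family `psi/kappa + sinh(psi) = sinh(a)`
(`a = asinh` of the fixed-to-mobile charge ratio, `kappa` the coupling
of sphere potential to mobile screening) on a 61×31 cubic grid in
`(a, log kappa)`, mapping composition to `(a, kappa)` in closed form at
query time. Held-out parity against the exact solver: max relative
error 3e-5 over 1000 random envelope points (contract: < 1%). The
surrogate is trained for one ionization state; runs whose schedule
changes `alpha` mid-run should use the exact solver (the default).

## Payload variance and the empty fraction

Payload variances are population variances (divisor N) of RNA copy
counts, with and without empty particles; divisor N is used
consistently for both flavors. Because RNA is conserved while
particles merge, the copy-count variance grows roughly additively with
the number of primaries per final particle. Consequently "variance
increases with empty fraction" is a statement about a *matched
ensemble*: comparing mixing rates at fixed formulation (same final
size, different R0), slower mixing concentrates the conserved RNA into
fewer loaded particles and raises both variance flavors together with
`theta_empty` (rank correlation ≈ +0.8 across the R0 ensemble). Pooling
across PEG-MW values reverses the sign, because high-MW formulations
freeze early (high `theta_empty`, near-initial variance) while low-MW
formulations merge ~70-fold (low `theta_empty`, ~70× variance). The
package reports the statistic per population; which populations are
compared is the analyst's choice, and the monotonicity test uses the
matched mixing-rate ensemble.

A related consequence concerns feature importances: over the study
ranges, PEG MW changes RF³ by ~18× and hence the self-limited final
radius by ~4×; through volumetric scaling
`theta_empty = theta0^((R/R0)^3)` this swings the empty fraction across
nearly its full range, so the random forest attributes most of the
`theta_empty` variance to PEG MW, with initial radius second. For the
final size, both the initial radius and the salt concentration carry
negligible importance: R0 because growth is self-limiting, and csalt
because under the default dialysis schedule salt acts only during the
first hour and the pre-dialysis head start is erased by the later
PEG-limited growth.

## What the synthetic conditions do and do not show

The generator emulates the study conditions: a single benchmark
formulation, monodisperse initial size per run, a fixed 83% empty
fraction at the mixing time, and a single-step dialysis. It does not
emulate polydisperse primary particles, RNA release or exchange,
fission/disassembly, Ostwald ripening, spatial or shear structure,
non-spherical morphologies, or lot-to-lot chemistry variation. Passing
tests therefore demonstrate the internal consistency of the kinetic
model and its stated scalings — not quantitative agreement with any
particular instrument's measurements. The 2.8× DLS-to-bare-radius
rescale is a deterministic helper for comparing against
intensity-weighted sizing data, not an instrument model.

## Problem sizes used in tests

Full-protocol checks (final-size invariance, target t3) run at
N0 = 2500 with 10 seeds per condition. Monotonicity and sweep ensembles
run at N0 = 400–800 with 10-seed medians: the derived `Vsystem` is
proportional to N0, so number densities — and hence the intensive
dynamics — are independent of N0, which only sets counting noise. The
sweep used for design-rule extraction is the 3⁴ factorial over
R0 ∈ {6, 8, 10} nm, PEG MW ∈ {1000, 3000, 5000} Da, PEG ratio
∈ {1, 2, 3}%, csalt ∈ {10, 80, 150} mM with 2 replicates per row.

## Known limitations

* The PEG-barrier energy scale is calibrated, not ab initio; absolute
  times and sizes inherit that one-parameter freedom, scalings do not.
* The constant-potential DLVO form is used at all separations;
  charge-regulating surfaces at close approach would interpolate toward
  constant-charge behavior.
* Surface potentials are re-solved on composition or environment
  change, assuming instantaneous ionic equilibration.
* The flow-rate → R0 map relies on an effective seed density; only its
  monotonicity and range are constrained by the study inputs.
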