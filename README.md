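# lnpkmc

Kinetic Monte Carlo simulation of RNA-loaded lipid nanoparticle (LNP)
self-assembly, for formulation scientists and modelers who need to
understand — and design against — **payload heterogeneity**: why a large
fraction of LNPs comes out empty, why the RNA-copy distribution is
bimodal, and which handles (mixing rate, PEG-lipid size and content,
salt) move the size distribution versus the payload distribution.

## Model

After turbulent mixing, N spherical LNPs in a volume V undergo pairwise
Brownian coalescence with Arrhenius-suppressed rates

```
k_ij = Kcollide(R_i, R_j) · exp(−E_b) / V,
Kcollide = (2 k_B T / 3η) (R_i + R_j)² / (R_i R_j),
E_b  = E_PEG + W*                      [in units of k_B T]
```

* `E_PEG ∝ (R_F³/v₀)(1−f_w) · R_i R_j (R_i φᵢᴾᴱᴳ + R_j φⱼᴾᴱᴳ)/(R_i+R_j)`
  — steric cost of excluding the PEG brush (Flory radius
  `R_F = a·n^(3/5)`) from the fusion zone; grows as R² for equal sizes.
* `W* = max_d W(d)` — barrier of the DLVO profile (van der Waals +
  screened electrostatics between constant-potential spheres).
* Each particle's surface potential solves a Donnan-type
  charge-regulation problem: ionizable-lipid (+) and RNA (−) fixed
  charge, screened by mobile salt, on a permeable sphere
  `e₀ψ₀/k_BT = (4π/3) λ_B ρ R²/(1 + R/l_D)` — found by bracketed
  root-finding, unique by monotonicity.

Runs start from a mostly empty population (83% empty at the mixing
time, initial radius R₀ set directly or derived from the flow rate via
`τ_M = (b₁/1.75)·Q^(−1.5)` and mean-field coalescence), and apply a
dialysis schedule (salt 25 → 150 mM, ionizable-lipid deprotonation) at
1 h. The analysis layer computes the empty fraction
`θ_empty = N_empty/N_total`, payload histograms and pooled variances,
the volumetric-scaling law `θ_empty = θ₀^((R/R₀)³)`, aggregation-bias
ratios `K(v₁,v₂)/K(v/2,v/2)`, and random-forest (Gini) feature
importances over parameter sweeps.

## Worked example

```python
import numpy as np
import lnpkmc as L
from lnpkmc import analysis
from lnpkmc.initializer import (InitPopulationSpec,
                                build_initial_population,
                                derive_system_volume)

form, env, ip = L.Formulation(), L.Environment(), L.InteractionParams()
spec = InitPopulationSpec(n0=2500, r0=10.0)     # slow-mixing condition
rng = np.random.default_rng(0)
pop = build_initial_population(spec, form, env, rng)
v = derive_system_volume(spec, form)
traj = L.simulate(pop, form, env, ip, v,
                  schedule=L.EnvironmentSchedule.dialysis(), seed=rng)
last = traj.snapshots.iloc[-1]
print(f"particles: {spec.n0} -> {int(last.n_particles)}")
print(f"mean bare radius at 18 h: {last.mean_radius_nm:.1f} nm")
print(f"empty fraction: 0.83 -> {last.theta_empty:.3f}")
print("volumetric-scaling prediction:",
      round(analysis.volumetric_scaling_prediction(
          0.83, 10.0, last.mean_radius_nm), 3))
```

prints

```
particles: 2500 -> 340
mean bare radius at 18 h: 19.4 nm
empty fraction: 0.83 -> 0.206
volumetric-scaling prediction: 0.256
```

Reading: 2500 primary LNPs of 10 nm coalesce into 340 particles of
≈ 19 nm mean bare radius by 18 h; growth is self-limited by the
R²-growing PEG barrier, so this final size barely depends on R₀. The
empty fraction falls from 0.83 to 0.21 — close to, and slightly below,
the volumetric prediction 0.83^((19.4/10)³) ≈ 0.26, because the
size-and-charge-dependent kernel preferentially consumes small empty
particles. Repeating with `r0=6.0` (fast mixing) gives the same ~19 nm
size but θ_empty ≈ 0: mixing rate tunes the payload distribution
almost independently of the final size.

The same protocol is available from the shell:

```
lnpkmc simulate --config run.yml --seed 7 --out out/   # one trajectory
lnpkmc sweep --out sweep/                              # 3^4 design sweep
lnpkmc importance --table sweep/sweep.csv --out imp/   # design rules
lnpkmc analyze --run out/ --out summary/               # recompute stats
```

All outputs are CSV/JSON with a manifest (config echo, hash, seed);
identical (config, seed) reruns are byte-identical.

## Layout

| module | contents |
|---|---|
| `lnpkmc.physchem` | screening lengths, Flory radius, collision kernel, PEG/DLVO barriers, charge regulation, fusion rate |
| `lnpkmc.initializer` | mixing-time relations, mean-field R₀, system volume, initial population |
| `lnpkmc.engine` | Gillespie engine, environment schedule, trajectory recording |
| `lnpkmc.analysis` | empty ratio, payload histograms/variances, volumetric scaling, bias ratios, DLS rescale |
| `lnpkmc.ml_design` | parameter sweeps, random-forest importances, charge-regulation surrogate |
| `lnpkmc.config` / `cli` / `outputs` | YAML config schema, CLI, atomic CSV/JSON writers |

See `docs/methods.md` for the full model description, parameter
defaults and rationale, numerical choices, and known limitations.
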