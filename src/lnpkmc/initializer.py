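"""From mixing conditions to the kMC starting population.

Turbulent mixing sets a characteristic interdiffusion time tau_M, during
which lipids coalesce RNA-free; the population entering the kMC stage is
therefore mostly empty LNPs of a mixing-rate-dependent initial radius R0.
This module provides

* the printed flow-rate correlation tau_M = (b1/1.75) Q^-alpha1,
* the shear-layer relation tau_M = l^2/(2D),
* mean-field coalescence growth to R0 (constant-kernel Smoluchowski),
* system-volume bookkeeping from the RNA mass concentration and N/P ratio,
* construction of the seeded initial population with an 83%-empty fraction
  and conservation-exact RNA allocation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import brentq

from .constants import NA, NM3_PER_M3
from .physchem import Environment, Formulation
from .population import Population

__all__ = [
    "MixingConditions",
    "InitPopulationSpec",
    "AllocationError",
    "mixing_time_from_flow",
    "mixing_time_from_layer",
    "mixing_time_seconds",
    "meanfield_initial_radius",
    "derive_initial_radius",
    "derive_system_volume",
    "build_initial_population",
]

ALLOCATION_LAWS = ("zero-truncated-poisson", "geometric", "equal")


class AllocationError(ValueError):
    """RNA allocation impossible under the requested law (e.g. fewer RNA
    copies than loaded particles for a zero-truncated law)."""


@dataclass(frozen=True)
class MixingConditions:
    """Mixing-rate inputs: either a flow rate Q or a shear-layer half-width l.

    ``b1``/``alpha1`` are the turbulent-correlation constants of
    tau_M = (b1/1.75) Q^-alpha1 (Q in mL/min); the formula output is read
    in units of ``tau_unit_s`` seconds (milliseconds by default).  ``d_inter``
    is the RNA/lipid inter-diffusion constant in nm^2/us, calibrated by
    default so that tau_M(l = 110 nm) = 25 us.  ``seed_radius`` and
    ``seed_number_density`` parametrize the mean-field growth from molecular
    seeds to R0; the density is calibrated once so that Q = 10-30 mL/min
    maps onto the R0 ~ 6-10 nm range.
    """

    q: Optional[float] = None  # mL/min
    l: Optional[float] = None  # nm
    b1: float = 1.3e3
    alpha1: float = 1.5
    tau_unit_s: float = 1e-3
    d_inter: float = 242.0  # nm^2/us
    seed_radius: float = 1.0  # nm
    seed_number_density: float = 6.9e-6  # 1/nm^3

    @classmethod
    def from_calibration(cls, l_ref: float, tau_ref_us: float, **kwargs):
        """Layer mode with D fixed by a reference point tau_M(l_ref)."""
        if l_ref <= 0 or tau_ref_us <= 0:
            raise ValueError("calibration pair must be positive")
        return cls(d_inter=l_ref**2 / (2.0 * tau_ref_us), **kwargs)

    def __post_init__(self):
        if self.q is None and self.l is None:
            raise ValueError("provide a flow rate q or a layer half-width l")
        if self.q is not None and self.q <= 0:
            raise ValueError("flow rate q must be > 0")
        if self.l is not None and self.l < 0:
            raise ValueError("layer half-width l must be >= 0")
        if self.b1 <= 0 or self.alpha1 <= 0:
            raise ValueError("b1 and alpha1 must be > 0")
        if self.d_inter <= 0:
            raise ValueError("inter-diffusion constant must be > 0")


def mixing_time_from_flow(mc: MixingConditions) -> float:
    """Turbulent mixing time tau_M = (b1/1.75) * Q^-alpha1.

    Returned in the configured formula units (``mc.tau_unit_s`` seconds
    each; milliseconds by default).  Valid in the turbulent regime
    Q >= 10 mL/min; a warning is emitted below that.
    """
    if mc.q is None or mc.q <= 0:
        raise ValueError("flow rate q must be set and > 0")
    if mc.q < 10.0:
        import warnings

        warnings.warn(
            "flow rate below the turbulent regime (Q < 10 mL/min); the "
            "power-law mixing-time correlation may not apply",
            stacklevel=2,
        )
    return (mc.b1 / 1.75) * mc.q ** (-mc.alpha1)


def mixing_time_from_layer(l: float, d_inter: float = 242.0) -> float:
    """Shear-layer mixing time tau_M = l^2 / (2 D) in us (l nm, D nm^2/us)."""
    if d_inter <= 0:
        raise ValueError("inter-diffusion constant must be > 0")
    if l < 0:
        raise ValueError("layer half-width must be >= 0")
    return l * l / (2.0 * d_inter)


def mixing_time_seconds(mc: MixingConditions) -> float:
    """tau_M in seconds from whichever mixing input is configured."""
    if mc.q is not None:
        return mixing_time_from_flow(mc) * mc.tau_unit_s
    return mixing_time_from_layer(mc.l, mc.d_inter) * 1e-6


def meanfield_initial_radius(tau_m: float, seed_radius: float,
                             number_density: float, env: Environment) -> float:
    """Initial kMC radius from size-free mean-field coalescence.

    Constant-kernel Smoluchowski decay n(t) = n0/(1 + 4 kBT n0 t / 3 eta)
    conserves volume, so R(tau_M) = seed_radius * (n0/n(tau_M))^(1/3);
    strictly increasing in tau_M.
    """
    if tau_m < 0 or seed_radius <= 0 or number_density <= 0:
        raise ValueError("inputs must be positive (tau_m >= 0)")
    coeff = 4.0 * env.kbt / (3.0 * env.viscosity) * NM3_PER_M3  # nm^3/s
    growth = 1.0 + coeff * number_density * tau_m
    return seed_radius * growth ** (1.0 / 3.0)


def derive_initial_radius(mc: MixingConditions, env: Environment) -> float:
    """R0 (nm) implied by the mixing conditions via mean-field growth."""
    return meanfield_initial_radius(
        mixing_time_seconds(mc), mc.seed_radius, mc.seed_number_density, env
    )


@dataclass(frozen=True)
class InitPopulationSpec:
    """Initial-population controls.

    ``n0`` initial LNP count; ``r0`` initial bare radius (nm); ``theta0``
    the empty fraction at tau_M; RNA allocated over loaded particles by
    ``allocation``; ``sirna_conc`` the mass concentration (ug/mL) from
    which, with the N/P ratio, total RNA and the system volume follow.
    An explicit ``v_system`` (nm^3) overrides the derivation.
    """

    n0: int = 2500
    r0: float = 9.0
    theta0: float = 0.83
    allocation: str = "zero-truncated-poisson"
    sirna_conc: float = 20.0  # ug/mL
    v_system: Optional[float] = None  # nm^3

    def __post_init__(self):
        if self.n0 < 2:
            raise ValueError("n0 must be >= 2")
        if not 0.0 <= self.theta0 <= 1.0:
            raise ValueError("theta0 must be in [0, 1]")
        if self.r0 <= 0:
            raise ValueError("r0 must be > 0")
        if self.allocation not in ALLOCATION_LAWS:
            raise ValueError(f"allocation must be one of {ALLOCATION_LAWS}")
        if self.sirna_conc <= 0:
            raise ValueError("sirna_conc must be > 0")
        if self.v_system is not None and self.v_system <= 0:
            raise ValueError("v_system must be > 0")


def lipids_per_particle(r0: float, form: Formulation) -> float:
    """Lipid molecules in one initial LNP of bare radius r0 (nm)."""
    v_lipid = (1.0 - form.fw) * (4.0 / 3.0) * math.pi * r0**3
    return v_lipid / form.mean_lipid_volume


def total_rna_copies(n0: int, r0: float, form: Formulation) -> int:
    """System-wide RNA copy count from per-particle N/P bookkeeping.

    amines = lipids * x_ionizable * charges_per_ionizable;
    phosphates = amines / (N/P); copies = phosphates / charges_per_rna.
    """
    lipids = n0 * lipids_per_particle(r0, form)
    amines = lipids * form.molar_fractions[0] * form.charges_per_ionizable
    return int(round(amines / (form.np_ratio * form.charges_per_rna)))


def derive_system_volume(spec: InitPopulationSpec, form: Formulation) -> float:
    """Simulation volume Vsystem (nm^3) for ``n0`` LNPs.

    Chains the RNA mass concentration -> phosphate molarity -> (via N/P)
    total lipid molarity -> LNP number density at radius r0 -> volume
    holding n0 LNPs.  Doubling n0 doubles Vsystem; halving the RNA
    concentration doubles it at fixed n0.
    """
    if spec.v_system is not None:
        return spec.v_system
    x_ion = form.molar_fractions[0]
    if x_ion <= 0 or form.charges_per_ionizable <= 0:
        raise ValueError(
            "system volume derivation needs a charged ionizable-lipid fraction"
        )
    rna_molar = spec.sirna_conc * 1e-6 * 1e3 / form.rna_mw  # mol/L
    phosphate_molar = rna_molar * form.charges_per_rna
    amine_molar = phosphate_molar * form.np_ratio
    lipid_molar = amine_molar / (x_ion * form.charges_per_ionizable)
    lipid_per_nm3 = lipid_molar * NA / 1e24
    lnp_per_nm3 = lipid_per_nm3 / lipids_per_particle(spec.r0, form)
    return spec.n0 / lnp_per_nm3


def _ztp_lambda(mean: float) -> float:
    """Rate of a zero-truncated Poisson with the given mean (> 1)."""
    if mean <= 1.0:
        raise AllocationError(
            "zero-truncated Poisson needs mean > 1 RNA per loaded particle"
        )
    # mean = lam / (1 - exp(-lam)); bracket between mean-1 and mean
    return brentq(lambda lam: lam / -np.expm1(-lam) - mean,
                  max(mean - 1.0, 1e-12), mean, xtol=1e-12)


def _allocate_rna(n_loaded: int, total: int, law: str,
                  rng: np.random.Generator) -> np.ndarray:
    if n_loaded == 0:
        if total > 0:
            raise AllocationError("RNA present but no loaded particles")
        return np.zeros(0, dtype=np.int64)
    if total < n_loaded:
        raise AllocationError(
            f"{total} RNA copies cannot give >= 1 copy to each of "
            f"{n_loaded} loaded particles; reduce theta0 or the particle count"
        )
    mean = total / n_loaded
    if law == "equal":
        loads = np.full(n_loaded, total // n_loaded, dtype=np.int64)
        extra = rng.choice(n_loaded, size=total - int(loads.sum()), replace=False)
        loads[extra] += 1
        return loads
    if law == "zero-truncated-poisson":
        lam = _ztp_lambda(mean) if mean > 1.0 else None
        if lam is None:
            loads = np.ones(n_loaded, dtype=np.int64)
        else:
            # rejection-free ZTP sampling via inverse CDF on U(exp(-lam), 1)
            u = rng.uniform(np.exp(-lam), 1.0, size=n_loaded)
            from scipy.stats import poisson

            loads = poisson.ppf(u, lam).astype(np.int64)
            loads = np.maximum(loads, 1)
    elif law == "geometric":
        loads = rng.geometric(min(1.0, 1.0 / mean), size=n_loaded).astype(np.int64)
    else:  # pragma: no cover - guarded by InitPopulationSpec
        raise ValueError(f"unknown allocation law {law!r}")
    # repair to exact conservation
    diff = total - int(loads.sum())
    while diff != 0:
        if diff > 0:
            k = min(diff, n_loaded)
            idx = rng.integers(0, n_loaded, size=k)
            np.add.at(loads, idx, 1)
            diff -= k
        else:
            candidates = np.flatnonzero(loads > 1)
            if candidates.size == 0:
                raise AllocationError("cannot repair allocation to total")
            k = min(-diff, candidates.size)
            idx = rng.choice(candidates, size=k, replace=False)
            loads[idx] -= 1
            diff += k
    return loads


def build_initial_population(spec: InitPopulationSpec, form: Formulation,
                             env: Environment, seed) -> Population:
    """Seeded initial population: ``round(theta0*n0)`` empty LNPs of radius
    r0 and the conserved RNA total distributed over the rest.

    Identical (spec, seed) inputs reproduce the population exactly.  Loaded
    particles are slightly larger than r0 because the RNA volume adds to
    the lipid complement.
    """
    rng = np.random.default_rng(seed)
    n0 = spec.n0
    n_empty = int(round(spec.theta0 * n0))
    n_loaded = n0 - n_empty
    total = total_rna_copies(n0, spec.r0, form)
    rna = np.zeros(n0, dtype=np.int64)
    if n_loaded > 0:
        rna[n_empty:] = _allocate_rna(n_loaded, total, spec.allocation, rng)
    # theta0 = 1 is the RNA-free corner: every particle stays empty
    pop = Population(
        units=np.ones(n0, dtype=np.int64),
        rna=rna,
        lipids_per_unit=lipids_per_particle(spec.r0, form),
        form=form,
    )
    pop.solve_psi(env)
    return pop
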