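"""Pair interactions and per-particle electrostatics for LNP coalescence.

This module holds every physical formula used by the simulator:

* Brownian collision kernel for two spheres (Smoluchowski),
* steric PEG-brush exclusion barrier,
* DLVO energy profile (van der Waals + screened electrostatics) and the
  fusion barrier obtained as its maximum over approach distance,
* Donnan-type charge regulation: the self-consistent net charge density
  and surface potential of a permeable, uniformly charged sphere,
* the fusion rate combining all of the above.

Units: lengths nm, time s, energies kBT, salt mol/L.  Surface potentials
are carried in reduced units ``e0*psi/kBT`` throughout; conversion to
volts happens only inside the DLVO prefactor.

All pair formulas exist in two layers: array kernels (``pair_*``,
``dlvo_*``) broadcasting over numpy arrays, used by the simulation
engine, and thin per-particle wrappers operating on :class:`ParticleState`
objects.  Both layers share the same code path, so spot-checking a single
pair against the engine's rate table is exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.optimize import brentq

from .constants import EPS0, E0, KB, NA, NM3_PER_M3, PER_NM3_PER_MOLAR

__all__ = [
    "Environment",
    "Formulation",
    "ParticleState",
    "InteractionParams",
    "UnscreenedRegimeError",
    "StaleCacheError",
    "KERNEL_MODES",
    "debye_length",
    "bjerrum_length",
    "flory_radius",
    "collision_rate",
    "peg_barrier",
    "dlvo_energy",
    "dlvo_barrier",
    "charge_regulation_residual",
    "solve_charge_regulation",
    "fusion_rate",
    "pair_barrier",
    "pair_rate",
]

KERNEL_MODES = ("full", "constant", "diffusion-only", "peg-only", "dlvo-only")

# PEG-barrier calibration multiplier.  The printed grouping of the steric
# barrier leaves its prefactor's absolute scale ambiguous (the literal nm
# evaluation read as kBT overestimates the barrier by ~50x and would freeze
# the population at the initial size).  The multiplier is calibrated once so
# that the default formulation (PEG 2000 at 1.5 mol%, 25 mM salt with
# dialysis to 150 mM at 1 h) reaches a number-mean bare radius of ~20 nm at
# 18 h, the reported kinetic regime.  All scaling conclusions (R^2 growth,
# linearity in phi_PEG, RF^3 dependence) are independent of this constant.
DEFAULT_PEG_CALIBRATION = 0.02


class UnscreenedRegimeError(ValueError):
    """Raised when a screened-electrostatics formula is used at csalt = 0."""


class StaleCacheError(RuntimeError):
    """Raised when a particle's cached surface potential does not match the
    environment it is being used under."""


@dataclass(frozen=True)
class Environment:
    """Solvent and ionization state.

    Parameters
    ----------
    temperature : float
        Absolute temperature T (K).
    viscosity : float
        Dynamic viscosity eta (Pa*s).
    relative_permittivity : float
        Relative permittivity of the solvent (dimensionless).
    csalt : float
        Monovalent salt molarity (mol/L).
    alpha_ionizable : float
        Degree of ionization of the ionizable lipid, in [0, 1].
    alpha_rna : float
        Degree of ionization of RNA phosphates, in [0, 1].
    """

    temperature: float = 298.0
    viscosity: float = 8.9e-4
    relative_permittivity: float = 78.5
    csalt: float = 0.025
    alpha_ionizable: float = 1.0
    alpha_rna: float = 1.0

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if self.viscosity <= 0:
            raise ValueError("viscosity must be > 0")
        if self.csalt < 0:
            raise ValueError("csalt must be >= 0")
        for name in ("alpha_ionizable", "alpha_rna"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")

    @property
    def kbt(self) -> float:
        """Thermal energy kB*T in J."""
        return KB * self.temperature

    @property
    def permittivity(self) -> float:
        """Absolute solvent permittivity epsilon (F/m)."""
        return self.relative_permittivity * EPS0

    def tag(self) -> tuple:
        """Hashable identity used to validate cached surface potentials."""
        return (
            self.temperature,
            self.viscosity,
            self.relative_permittivity,
            self.csalt,
            self.alpha_ionizable,
            self.alpha_rna,
        )

    def evolve(self, **changes) -> "Environment":
        return replace(self, **changes)


def debye_length(env: Environment) -> float:
    """Debye screening length lD (nm) for a 1:1 electrolyte.

    lD = sqrt(eps*kB*T / (2*NA*e0^2*csalt*1e3)); about 0.78 nm at 150 mM
    and 1.92 nm at 25 mM in water at 298 K.
    """
    if env.csalt <= 0:
        raise UnscreenedRegimeError(
            "Debye length diverges at csalt = 0; cap the salt concentration"
        )
    ld_m = math.sqrt(
        env.permittivity * env.kbt / (2.0 * NA * E0**2 * env.csalt * 1e3)
    )
    return ld_m * 1e9


def bjerrum_length(env: Environment) -> float:
    """Bjerrum length lambda_B (nm): e0^2/(4 pi eps kB T), ~0.7 nm in water."""
    lb_m = E0**2 / (4.0 * math.pi * env.permittivity * env.kbt)
    return lb_m * 1e9


def flory_radius(mw: float, a: float = 0.37, monomer_mw: float = 44.0) -> float:
    """Flory radius RF = a * n^(3/5) of a PEG chain of molecular weight ``mw``.

    ``a`` is the monomer size (nm) and ``n = mw / monomer_mw`` the degree of
    polymerization.  RF(2000 Da) ~ 3.6 nm.
    """
    if a <= 0 or monomer_mw <= 0 or mw <= 0:
        raise ValueError("flory_radius arguments must be positive")
    if mw < monomer_mw:
        raise ValueError("mw must be at least one monomer")
    return a * (mw / monomer_mw) ** 0.6


@dataclass(frozen=True)
class Formulation:
    """Lipid/RNA composition of the formulation.

    Species order everywhere: (ionizable lipid, helper lipid, cholesterol,
    PEG-lipid).  Default mole ratios 50:10:38.5:1.5 mirror the benchmark
    siRNA formulation.  Per-molecule volumes default to the mean lipid
    volume ``v0``; the RNA molecular volume follows from its molecular
    weight at a partial specific volume of ~0.55 cm^3/g.
    """

    molar_fractions: tuple = (0.50, 0.10, 0.385, 0.015)
    peg_mw: float = 2000.0
    peg_monomer_size: float = 0.37  # nm
    peg_monomer_mw: float = 44.0  # Da
    v0: float = 1.3  # mean volume per lipid, nm^3
    species_volumes: Optional[tuple] = None  # nm^3 per molecule, defaults to v0
    fw: float = 0.2  # water volume fraction inside the LNP
    charges_per_ionizable: float = 1.0  # elementary charges, positive
    charges_per_rna: float = 44.0  # elementary charges, magnitude (negative)
    np_ratio: float = 6.0  # nitrogen-to-phosphate ratio
    rna_mw: float = 14000.0  # Da (22 bp siRNA duplex)
    rna_volume: float = 12.8  # nm^3 per RNA molecule

    def __post_init__(self):
        x = np.asarray(self.molar_fractions, dtype=float)
        if x.shape != (4,) or np.any(x < 0):
            raise ValueError("molar_fractions must be 4 nonnegative numbers")
        if abs(float(x.sum()) - 1.0) > 1e-9:
            raise ValueError("molar_fractions must sum to 1 within 1e-9")
        if not 0.0 <= self.fw < 1.0:
            raise ValueError("fw must be in [0, 1)")
        if self.v0 <= 0:
            raise ValueError("v0 must be > 0")
        if self.species_volumes is not None:
            v = np.asarray(self.species_volumes, dtype=float)
            if v.shape != (4,) or np.any(v <= 0):
                raise ValueError("species_volumes must be 4 positive numbers")

    @property
    def volumes(self) -> np.ndarray:
        """Per-molecule volumes (nm^3) in species order."""
        if self.species_volumes is None:
            return np.full(4, self.v0)
        return np.asarray(self.species_volumes, dtype=float)

    @property
    def mean_lipid_volume(self) -> float:
        """Mole-fraction-weighted mean volume per lipid (nm^3)."""
        return float(np.dot(self.molar_fractions, self.volumes))

    @property
    def rho_ionizable(self) -> float:
        """Charge number density of the pure ionizable-lipid phase (e/nm^3)."""
        return self.charges_per_ionizable / self.volumes[0]

    @property
    def rho_rna(self) -> float:
        """Charge number density of the pure RNA phase (e/nm^3), negative."""
        return -self.charges_per_rna / self.rna_volume

    @property
    def flory_radius(self) -> float:
        return flory_radius(self.peg_mw, self.peg_monomer_size, self.peg_monomer_mw)


@dataclass
class InteractionParams:
    """Knobs of the pair-interaction model.

    ``hamaker`` (J) sets van der Waals attraction; ``dmin`` (nm) is the
    closest approach at which the DLVO profile is evaluated and
    ``dmax_debye`` the far end of the barrier search in units of the Debye
    length.  ``peg_mult`` / ``dlvo_mult`` are dimensionless calibration
    multipliers on the two barrier contributions.  ``kernel_mode`` selects
    the aggregation-kernel ablation.
    """

    hamaker: float = 1.0e-20
    dmin: float = 0.3
    dmax_debye: float = 10.0
    peg_mult: float = DEFAULT_PEG_CALIBRATION
    dlvo_mult: float = 1.0
    kernel_mode: str = "full"
    n_grid: int = 72

    def __post_init__(self):
        if self.hamaker < 0:
            raise ValueError("hamaker must be >= 0")
        if self.dmin <= 0:
            raise ValueError("dmin must be > 0")
        if self.peg_mult <= 0 or self.dlvo_mult <= 0:
            raise ValueError("calibration multipliers must be > 0")
        if self.kernel_mode not in KERNEL_MODES:
            raise ValueError(f"kernel_mode must be one of {KERNEL_MODES}")
        if self.n_grid < 8:
            raise ValueError("n_grid must be >= 8")


@dataclass
class ParticleState:
    """One LNP: composition, size and cached electrostatic state.

    ``lipid_counts`` are per-species molecule counts (floats; merging adds
    them exactly), ``rna`` the integer RNA copy number.  The bare radius
    follows from the constituent volume and the water fraction:
    (4/3) pi R^3 = (sum_s n_s v_s + n_RNA v_RNA) / (1 - fw).
    """

    lipid_counts: np.ndarray
    rna: int
    radius: float
    phi_ionizable: float
    phi_rna: float
    phi_peg: float
    psi0: Optional[float] = None  # reduced units e0 psi0 / kBT
    rho: Optional[float] = None  # net charge density, e/nm^3
    psi_env_tag: Optional[tuple] = field(default=None, repr=False)

    @classmethod
    def from_counts(cls, lipid_counts, rna: int, form: Formulation) -> "ParticleState":
        counts = np.asarray(lipid_counts, dtype=float)
        if counts.shape != (4,) or np.any(counts < 0):
            raise ValueError("lipid_counts must be 4 nonnegative numbers")
        if rna < 0:
            raise ValueError("rna count must be >= 0")
        vols = form.volumes
        v_const = float(np.dot(counts, vols)) + rna * form.rna_volume
        if v_const <= 0:
            raise ValueError("particle must contain material")
        radius = (3.0 * v_const / (4.0 * math.pi * (1.0 - form.fw))) ** (1.0 / 3.0)
        return cls(
            lipid_counts=counts,
            rna=int(rna),
            radius=radius,
            phi_ionizable=counts[0] * vols[0] / v_const,
            phi_rna=rna * form.rna_volume / v_const,
            phi_peg=counts[3] * vols[3] / v_const,
        )

    def require_psi(self, env: Environment) -> float:
        if self.psi0 is None or self.psi_env_tag != env.tag():
            raise StaleCacheError(
                "particle surface potential not solved for this environment; "
                "call solve_charge_regulation first"
            )
        return self.psi0


# ---------------------------------------------------------------------------
# array kernels
# ---------------------------------------------------------------------------

def collision_rate(ri, rj, env: Environment):
    """Brownian collision kernel (2kBT/3eta)*(Ri+Rj)^2/(Ri*Rj) in nm^3/s.

    Symmetric in (Ri, Rj); equals 8kBT/3eta for equal radii.  Broadcasts
    over numpy arrays.
    """
    ri = np.asarray(ri, dtype=float)
    rj = np.asarray(rj, dtype=float)
    if np.any(ri <= 0) or np.any(rj <= 0):
        raise ValueError("radii must be > 0")
    pref = 2.0 * env.kbt / (3.0 * env.viscosity) * NM3_PER_M3
    out = pref * (ri + rj) ** 2 / (ri * rj)
    return out if out.ndim else float(out)


def pair_peg_barrier(ri, rj, phi_i, phi_j, rf: float, v0: float, fw: float,
                     mult: float = 1.0):
    """Steric PEG-exclusion barrier in kBT (array kernel).

    E = mult * 2 pi (RF^3/v0)(1-fw) * Ri Rj (Ri phi_i + Rj phi_j)/(Ri+Rj),
    with all lengths in nm.  For equal radii and equal phi this reduces to
    mult * 2 pi (RF^3/v0)(1-fw) * phi * R^2, i.e. E = C_PEG R1 R2.
    """
    ri = np.asarray(ri, dtype=float)
    rj = np.asarray(rj, dtype=float)
    pref = mult * 2.0 * math.pi * (rf**3 / v0) * (1.0 - fw)
    return pref * ri * rj * (ri * phi_i + rj * phi_j) / (ri + rj)


def _dlvo_profile(d, a2, b2, vdw_c, ld):
    """DLVO energy (kBT) at separation ``d`` for precomputed pair factors.

    g = Ri Rj/(Ri+Rj) (nm); a2 = psi_i^2 + psi_j^2, b2 = 2 psi_i psi_j in
    reduced units; vdw_c = (A/kBT) * g / 6 ; the electrostatic prefactor
    g/(16 pi lB) is folded into a2/b2 by the caller.
    """
    x = np.exp(-np.asarray(d, dtype=float) / ld)
    # log((1+x)/(1-x)) and log(1-x^2), stable for x < 1
    l1 = np.log1p(x) - np.log1p(-x)
    l2 = np.log1p(-x * x)
    return -vdw_c / d + b2 * l1 + a2 * l2


def _pair_factors(ri, rj, psi_i, psi_j, env: Environment, ip: InteractionParams):
    ri = np.asarray(ri, dtype=float)
    rj = np.asarray(rj, dtype=float)
    psi_i = np.asarray(psi_i, dtype=float)
    psi_j = np.asarray(psi_j, dtype=float)
    g = ri * rj / (ri + rj)
    lb = bjerrum_length(env)
    epref = ip.dlvo_mult * g / (16.0 * math.pi * lb)
    a2 = epref * (psi_i**2 + psi_j**2)
    b2 = epref * 2.0 * psi_i * psi_j
    vdw_c = ip.dlvo_mult * (ip.hamaker / env.kbt) * g / 6.0
    return a2, b2, vdw_c


def dlvo_energy(d, pi_or_ri, pj_or_rj, env: Environment, ip: InteractionParams,
                psi_i=None, psi_j=None):
    """DLVO interaction energy W(d) in kBT at surface separation d (nm).

    Accepts either two :class:`ParticleState` objects (using their cached
    reduced surface potentials) or raw radii plus explicit ``psi_i/psi_j``.
    W(d) = -A Ri Rj/(6 d (Ri+Rj)) + eps Ri Rj (psi_i^2+psi_j^2)/(4(Ri+Rj))
    * [ (2 psi_i psi_j/(psi_i^2+psi_j^2)) ln((1+e^-d/lD)/(1-e^-d/lD))
        + ln(1-e^-2d/lD) ].
    """
    if np.any(np.asarray(d, dtype=float) <= 0):
        raise ValueError("separation d must be > 0")
    if isinstance(pi_or_ri, ParticleState):
        ri, rj = pi_or_ri.radius, pj_or_rj.radius
        psi_i = pi_or_ri.require_psi(env)
        psi_j = pj_or_rj.require_psi(env)
    else:
        ri, rj = pi_or_ri, pj_or_rj
        if psi_i is None or psi_j is None:
            raise ValueError("psi_i and psi_j required with raw radii")
    a2, b2, vdw_c = _pair_factors(ri, rj, psi_i, psi_j, env, ip)
    ld = debye_length(env)
    out = _dlvo_profile(d, a2, b2, vdw_c, ld)
    return out if np.ndim(out) else float(out)


def dlvo_barrier_arrays(ri, rj, psi_i, psi_j, env: Environment,
                        ip: InteractionParams):
    """Fusion barrier: max_d W(d) over d in [dmin, dmax_debye*lD], >= 0.

    Vectorized over pair arrays.  The maximum is located on a log-spaced
    ``n_grid``-point grid (shared across pairs, since lD is a property of
    the environment) and sharpened by one exact evaluation at the parabolic
    apex through the best grid point and its neighbours in log d.
    Purely attractive profiles contribute no barrier (floored at 0).
    """
    ri = np.atleast_1d(np.asarray(ri, dtype=float))
    rj = np.atleast_1d(np.asarray(rj, dtype=float))
    psi_i = np.atleast_1d(np.asarray(psi_i, dtype=float))
    psi_j = np.atleast_1d(np.asarray(psi_j, dtype=float))
    a2, b2, vdw_c = _pair_factors(ri, rj, psi_i, psi_j, env, ip)
    ld = debye_length(env)
    dmax = max(ip.dmax_debye * ld, ip.dmin * 2.0)
    grid = np.geomspace(ip.dmin, dmax, ip.n_grid)

    best = np.full(ri.shape, -np.inf)
    best_k = np.zeros(ri.shape, dtype=np.int64)
    for k, d in enumerate(grid):
        w = _dlvo_profile(d, a2, b2, vdw_c, ld)
        mask = w > best
        best[mask] = w[mask]
        best_k[mask] = k

    # parabolic apex in log d through (k-1, k, k+1) for interior maxima
    interior = (best_k > 0) & (best_k < ip.n_grid - 1)
    if np.any(interior):
        km = best_k[interior] - 1
        kp = best_k[interior] + 1
        wm = _dlvo_profile(grid[km], a2[interior], b2[interior],
                           vdw_c[interior], ld)
        wp = _dlvo_profile(grid[kp], a2[interior], b2[interior],
                           vdw_c[interior], ld)
        w0 = best[interior]
        h = math.log(grid[1] / grid[0])
        denom = wm - 2.0 * w0 + wp
        with np.errstate(divide="ignore", invalid="ignore"):
            off = np.where(np.abs(denom) > 1e-300,
                           0.5 * h * (wm - wp) / denom, 0.0)
        off = np.clip(off, -h, h)
        d_star = np.exp(np.log(grid[best_k[interior]]) + off)
        w_star = _dlvo_profile(d_star, a2[interior], b2[interior],
                               vdw_c[interior], ld)
        best[interior] = np.maximum(w0, w_star)

    return np.maximum(best, 0.0)


def dlvo_barrier(pi: ParticleState, pj: ParticleState, env: Environment,
                 ip: InteractionParams) -> float:
    """Fusion barrier (kBT) between two particles; see dlvo_barrier_arrays."""
    out = dlvo_barrier_arrays(
        pi.radius, pj.radius, pi.require_psi(env), pj.require_psi(env), env, ip
    )
    return float(out[0])


def peg_barrier(pi: ParticleState, pj: ParticleState, form: Formulation,
                mult: float = 1.0) -> float:
    """Steric PEG barrier (kBT) between two particles."""
    return float(
        pair_peg_barrier(
            pi.radius, pj.radius, pi.phi_peg, pj.phi_peg,
            form.flory_radius, form.v0, form.fw, mult,
        )
    )


# ---------------------------------------------------------------------------
# charge regulation
# ---------------------------------------------------------------------------

def _net_charge_density(psi0, fw, fixed, csalt):
    """Net charge density (e/nm^3): fixed charge screened by mobile ions."""
    mobile = 2.0 * fw * csalt * PER_NM3_PER_MOLAR * np.sinh(psi0)
    return fixed - mobile


def _sphere_potential(rho, radius, lb, ld):
    """Reduced surface potential of a screened uniformly charged sphere:
    e0 psi0/kBT = (4 pi/3) lB rho R^2 / (1 + R/lD)."""
    return (4.0 * math.pi / 3.0) * lb * rho * radius**2 / (1.0 + radius / ld)


def _fixed_charge(phi_ionizable, phi_rna, form: Formulation, env: Environment):
    return (1.0 - form.fw) * (
        env.alpha_ionizable * form.rho_ionizable * phi_ionizable
        + env.alpha_rna * form.rho_rna * phi_rna
    )


def charge_regulation_residual(psi0: float, p: ParticleState,
                               form: Formulation, env: Environment) -> float:
    """Self-consistency residual psi_pred(rho(psi0)) - psi0 (reduced units).

    Strictly decreasing in psi0, hence the root is unique.  Zero for an
    uncharged particle at psi0 = 0.
    """
    fixed = _fixed_charge(p.phi_ionizable, p.phi_rna, form, env)
    rho = _net_charge_density(psi0, form.fw, fixed, env.csalt)
    pred = _sphere_potential(rho, p.radius, bjerrum_length(env), debye_length(env))
    return float(pred - psi0)


def solve_charge_regulation_scalar(radius: float, phi_ionizable: float,
                                   phi_rna: float, form: Formulation,
                                   env: Environment) -> tuple:
    """Root-find the reduced surface potential; returns (rho, psi0).

    Uses a bracketing solver on the (monotone) residual with an expanding
    bracket; converges to |residual| < 1e-10.
    """
    if env.csalt <= 0:
        raise UnscreenedRegimeError("charge regulation requires csalt > 0")
    lb = bjerrum_length(env)
    ld = debye_length(env)
    fixed = _fixed_charge(phi_ionizable, phi_rna, form, env)

    def resid(psi):
        rho = _net_charge_density(psi, form.fw, fixed, env.csalt)
        return _sphere_potential(rho, radius, lb, ld) - psi

    if fixed == 0.0:
        return 0.0, 0.0
    lo, hi = -1.0, 1.0
    # residual is strictly decreasing: expand until it brackets the root
    for _ in range(20):
        if resid(lo) > 0.0 and resid(hi) < 0.0:
            break
        lo *= 4.0
        hi *= 4.0
        if hi > 700.0:  # sinh overflow guard; physically unreachable
            raise RuntimeError(
                f"charge-regulation bracket failure: R={radius}, "
                f"phi_ionizable={phi_ionizable}, phi_rna={phi_rna}, "
                f"csalt={env.csalt}"
            )
    psi = brentq(resid, lo, hi, xtol=1e-14, rtol=8.9e-16, maxiter=200)
    rho = _net_charge_density(psi, form.fw, fixed, env.csalt)
    return float(rho), float(psi)


def solve_charge_regulation(p: ParticleState, form: Formulation,
                            env: Environment) -> tuple:
    """Solve charge regulation for a particle and cache (rho, psi0) on it."""
    rho, psi = solve_charge_regulation_scalar(
        p.radius, p.phi_ionizable, p.phi_rna, form, env
    )
    p.rho = rho
    p.psi0 = psi
    p.psi_env_tag = env.tag()
    return rho, psi


# ---------------------------------------------------------------------------
# fusion rate
# ---------------------------------------------------------------------------

def pair_barrier(ri, rj, phi_peg_i, phi_peg_j, psi_i, psi_j,
                 form: Formulation, env: Environment, ip: InteractionParams):
    """Total fusion barrier Eb (kBT) per kernel mode (array kernel)."""
    mode = ip.kernel_mode
    if mode in ("constant", "diffusion-only"):
        return np.zeros(np.broadcast(np.asarray(ri), np.asarray(rj)).shape)
    eb = 0.0
    if mode in ("full", "peg-only"):
        eb = eb + pair_peg_barrier(ri, rj, phi_peg_i, phi_peg_j,
                                   form.flory_radius, form.v0, form.fw,
                                   ip.peg_mult)
    if mode in ("full", "dlvo-only"):
        eb = eb + dlvo_barrier_arrays(ri, rj, psi_i, psi_j, env, ip)
    return eb


def pair_rate(ri, rj, phi_peg_i, phi_peg_j, psi_i, psi_j,
              form: Formulation, env: Environment, ip: InteractionParams,
              v_system: float):
    """Fusion rate k_ij = Kcollide * exp(-Eb) / Vsystem in 1/s (array kernel).

    In ``constant`` mode all pairs share the equal-size Brownian kernel
    8kBT/3eta / Vsystem.
    """
    if v_system <= 0:
        raise ValueError("v_system must be > 0")
    if ip.kernel_mode == "constant":
        k = 8.0 * env.kbt / (3.0 * env.viscosity) * NM3_PER_M3
        shape = np.broadcast(np.asarray(ri), np.asarray(rj)).shape
        return np.full(shape, k / v_system)
    eb = pair_barrier(ri, rj, phi_peg_i, phi_peg_j, psi_i, psi_j, form, env, ip)
    with np.errstate(over="ignore"):
        boltz = np.exp(-np.asarray(eb, dtype=float))
    return collision_rate(ri, rj, env) * boltz / v_system


def fusion_rate(pi: ParticleState, pj: ParticleState, env: Environment,
                form: Formulation, ip: InteractionParams,
                v_system: float) -> float:
    """Fusion rate (1/s) between two specific particles in volume Vsystem."""
    if ip.kernel_mode in ("full", "dlvo-only"):
        psi_i = pi.require_psi(env)
        psi_j = pj.require_psi(env)
    else:
        psi_i = psi_j = 0.0
    out = pair_rate(
        np.atleast_1d(float(pi.radius)), np.atleast_1d(float(pj.radius)),
        pi.phi_peg, pj.phi_peg, psi_i, psi_j, form, env, ip, v_system,
    )
    return float(np.asarray(out).ravel()[0])
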