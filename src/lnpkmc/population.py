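"""Array-of-structs container for an LNP population.

Every particle in a run descends from identical initial LNPs by pairwise
fusion, so its lipid complement is an exact integer multiple (``units``)
of the initial per-particle lipid content; only the RNA copy number
varies independently.  Storing ``(units, rna)`` as integers keeps mass
bookkeeping exact and makes particle "types" hashable, which the engine
exploits to deduplicate rate and charge-regulation work.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import physchem
from .physchem import Environment, Formulation, ParticleState


@dataclass
class Population:
    """A population of LNPs sharing one formulation.

    ``units[i]`` counts how many initial LNPs' worth of lipid particle i
    contains; ``lipids_per_unit`` is the (float) number of lipid molecules
    in one unit.  ``rna[i]`` is the RNA copy number.  ``ids`` are stable
    particle identities for event logging.
    """

    units: np.ndarray
    rna: np.ndarray
    lipids_per_unit: float
    form: Formulation
    ids: np.ndarray = field(default=None)
    psi: Optional[np.ndarray] = None
    rho: Optional[np.ndarray] = None
    psi_env_tag: Optional[tuple] = field(default=None, repr=False)

    def __post_init__(self):
        self.units = np.asarray(self.units, dtype=np.int64)
        self.rna = np.asarray(self.rna, dtype=np.int64)
        if self.units.shape != self.rna.shape:
            raise ValueError("units and rna must have the same shape")
        if np.any(self.units <= 0) or np.any(self.rna < 0):
            raise ValueError("units must be >= 1 and rna >= 0")
        if self.ids is None:
            self.ids = np.arange(self.units.size, dtype=np.int64)

    def __len__(self) -> int:
        return int(self.units.size)

    # -- derived geometry ---------------------------------------------------

    @property
    def lipid_volume(self) -> np.ndarray:
        """Total lipid volume per particle (nm^3)."""
        return self.units * self.lipids_per_unit * self.form.mean_lipid_volume

    @property
    def constituent_volume(self) -> np.ndarray:
        """Lipid + RNA volume per particle (nm^3), excluding water."""
        return self.lipid_volume + self.rna * self.form.rna_volume

    @property
    def radii(self) -> np.ndarray:
        """Bare radii (nm): (4/3) pi R^3 = constituent volume / (1 - fw)."""
        v_bare = self.constituent_volume / (1.0 - self.form.fw)
        return (3.0 * v_bare / (4.0 * math.pi)) ** (1.0 / 3.0)

    def _phi(self, species: int) -> np.ndarray:
        x = self.form.molar_fractions[species]
        v = self.form.volumes[species]
        return self.units * self.lipids_per_unit * x * v / self.constituent_volume

    @property
    def phi_ionizable(self) -> np.ndarray:
        return self._phi(0)

    @property
    def phi_peg(self) -> np.ndarray:
        return self._phi(3)

    @property
    def phi_rna(self) -> np.ndarray:
        return self.rna * self.form.rna_volume / self.constituent_volume

    # -- electrostatic state ------------------------------------------------

    def solve_psi(self, env: Environment) -> np.ndarray:
        """Solve charge regulation for every particle; cache and return psi.

        Deduplicates by (units, rna) type since psi depends only on
        composition, size and environment.
        """
        keys = np.stack([self.units, self.rna], axis=1)
        uniq, inverse = np.unique(keys, axis=0, return_inverse=True)
        psi_u = np.empty(uniq.shape[0])
        rho_u = np.empty(uniq.shape[0])
        vbar = self.form.mean_lipid_volume
        for k, (u, m) in enumerate(uniq):
            v_const = u * self.lipids_per_unit * vbar + m * self.form.rna_volume
            r = (3.0 * v_const / (4.0 * math.pi * (1.0 - self.form.fw))) ** (1 / 3)
            phi_ion = u * self.lipids_per_unit * self.form.molar_fractions[0] \
                * self.form.volumes[0] / v_const
            phi_rna = m * self.form.rna_volume / v_const
            rho_u[k], psi_u[k] = physchem.solve_charge_regulation_scalar(
                r, phi_ion, phi_rna, self.form, env
            )
        self.psi = psi_u[inverse]
        self.rho = rho_u[inverse]
        self.psi_env_tag = env.tag()
        return self.psi

    def require_psi(self, env: Environment) -> np.ndarray:
        if self.psi is None or self.psi_env_tag != env.tag():
            raise physchem.StaleCacheError(
                "population psi cache is stale; call solve_psi(env)"
            )
        return self.psi

    # -- conversions ---------------------------------------------------------

    def particle(self, i: int) -> ParticleState:
        """Export particle i as a standalone :class:`ParticleState`."""
        counts = self.units[i] * self.lipids_per_unit \
            * np.asarray(self.form.molar_fractions, dtype=float)
        p = ParticleState.from_counts(counts, int(self.rna[i]), self.form)
        if self.psi is not None:
            p.psi0 = float(self.psi[i])
            if self.rho is not None:
                p.rho = float(self.rho[i])
            p.psi_env_tag = self.psi_env_tag
        return p

    def copy(self) -> "Population":
        return Population(
            units=self.units.copy(),
            rna=self.rna.copy(),
            lipids_per_unit=self.lipids_per_unit,
            form=self.form,
            ids=self.ids.copy(),
            psi=None if self.psi is None else self.psi.copy(),
            rho=None if self.rho is None else self.rho.copy(),
            psi_env_tag=self.psi_env_tag,
        )
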