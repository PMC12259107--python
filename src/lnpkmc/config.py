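"""Hierarchical run configuration: schema, defaults, validation, manifest.

A run is described by one YAML file with blocks ``formulation``,
``environment``, ``schedule``, ``mixing``, ``population``,
``interactions``, ``kmc`` and a top-level ``seed``.  Every default is
materialized on load, unknown keys are rejected with their full path, and
the normalized config (plus a stable hash) is echoed into each run
manifest so sweeps stay auditable.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass
from typing import Optional

import yaml

from .engine import EnvironmentSchedule
from .initializer import (ALLOCATION_LAWS, InitPopulationSpec,
                          MixingConditions, derive_initial_radius)
from .physchem import (DEFAULT_PEG_CALIBRATION, KERNEL_MODES, Environment,
                       Formulation, InteractionParams)

__all__ = ["RunConfig", "ConfigError", "load_config", "default_config",
           "build_objects"]


class ConfigError(ValueError):
    """Schema violation, reported with the offending field path."""


def _hh_alpha(ph: float, pka: float) -> float:
    """Henderson-Hasselbalch protonated fraction of the ionizable lipid."""
    return 1.0 / (1.0 + 10.0 ** (ph - pka))


DEFAULTS = {
    "formulation": {
        # mole ratios ionizable : helper : cholesterol : PEG-lipid
        "molar_ratios": [50.0, 10.0, 38.5, 1.5],
        "peg_mw": 2000.0,
        "peg_monomer_size_nm": 0.37,
        "peg_monomer_mw": 44.0,
        "v0_nm3": 1.3,
        "species_volumes_nm3": None,
        "fw": 0.2,
        "charges_per_ionizable": 1.0,
        "charges_per_rna": 44.0,
        "np_ratio": 6.0,
        "rna_mw": 14000.0,
        "rna_volume_nm3": 12.8,
    },
    "environment": {
        "temperature_k": 298.0,
        "viscosity_pa_s": 8.9e-4,
        "relative_permittivity": 78.5,
        "csalt_m": 0.025,
        "ph": 4.0,
        "pka_ionizable": 6.44,
        "alpha_ionizable": 1.0,  # fully protonated at formulation pH 4
        "alpha_rna": 1.0,
    },
    "schedule": {
        # post-mixing dialysis: salt jump + deprotonation at pH 7.4
        "enabled": True,
        "time_s": 3600.0,
        "csalt_m": 0.15,
        "ph": 7.4,
        "alpha_ionizable": None,  # None -> Henderson-Hasselbalch at ph
    },
    "mixing": {
        "flow_rate_ml_min": None,
        "layer_half_width_nm": None,
        "b1": 1.3e3,
        "alpha1": 1.5,
        "tau_unit_s": 1e-3,
        "d_inter_nm2_us": 242.0,
        "seed_radius_nm": 1.0,
        "seed_number_density_nm3": 6.9e-6,
    },
    "population": {
        "n0": 2500,
        "r0_nm": 9.0,  # null -> derived from the mixing block
        "theta0": 0.83,
        "allocation": "zero-truncated-poisson",
        "sirna_conc_ug_ml": 20.0,
        "v_system_nm3": None,
    },
    "interactions": {
        "hamaker_j": 1.0e-20,
        "dmin_nm": 0.3,
        "dmax_debye": 10.0,
        "peg_mult": DEFAULT_PEG_CALIBRATION,
        "dlvo_mult": 1.0,
        "kernel_mode": "full",
        "n_grid": 72,
    },
    "kmc": {
        "t_end_s": 64800.0,  # 18 h
        "n_snapshots": 64,
        "snapshot_t_min_s": 1e-6,
        "stop_count": None,
        "time_increment": "exponential",
        "record_particles": False,
        "use_surrogate": False,
    },
    "seed": 0,
}

# (low, high) sanity bounds; values outside flag probable unit mistakes
_BOUNDS = {
    "environment.temperature_k": (150.0, 500.0),
    "environment.viscosity_pa_s": (1e-5, 10.0),
    "environment.csalt_m": (0.0, 10.0),
    "environment.alpha_ionizable": (0.0, 1.0),
    "environment.alpha_rna": (0.0, 1.0),
    "population.theta0": (0.0, 1.0),
    "population.r0_nm": (0.5, 200.0),
    "population.n0": (2, 10**7),
    "formulation.fw": (0.0, 0.999),
    "formulation.peg_mw": (44.0, 1e6),
    "interactions.dmin_nm": (1e-3, 100.0),
    "kmc.t_end_s": (0.0, 1e9),
}


def _merge(defaults, user, path=""):
    if user is None:
        return json.loads(json.dumps(defaults))
    if not isinstance(user, dict):
        raise ConfigError(f"{path or 'config'}: expected a mapping")
    out = {}
    for key, dval in defaults.items():
        here = f"{path}.{key}" if path else key
        if key in user and isinstance(dval, dict):
            out[key] = _merge(dval, user[key], here)
        elif key in user:
            out[key] = user[key]
        else:
            out[key] = json.loads(json.dumps(dval))
    unknown = set(user) - set(defaults)
    if unknown:
        where = f"{path}." if path else ""
        raise ConfigError(
            f"unknown config key(s): {sorted(where + u for u in unknown)}"
        )
    return out


def _check_bounds(data):
    for dotted, (lo, hi) in _BOUNDS.items():
        block, key = dotted.split(".")
        val = data[block][key]
        if val is None:
            continue
        if not (lo <= val <= hi):
            raise ConfigError(
                f"{dotted}: value {val} outside sane range [{lo}, {hi}] "
                f"(check units)"
            )


def _validate(data):
    _check_bounds(data)
    ratios = data["formulation"]["molar_ratios"]
    if len(ratios) != 4 or any(r < 0 for r in ratios):
        raise ConfigError("formulation.molar_ratios: need 4 nonnegative values")
    if sum(ratios) <= 0:
        raise ConfigError("formulation.molar_ratios: must not all be zero")
    if data["population"]["allocation"] not in ALLOCATION_LAWS:
        raise ConfigError(
            f"population.allocation: must be one of {ALLOCATION_LAWS}"
        )
    if data["interactions"]["kernel_mode"] not in KERNEL_MODES:
        raise ConfigError(
            f"interactions.kernel_mode: must be one of {KERNEL_MODES}"
        )
    if data["kmc"]["time_increment"] not in ("exponential", "mean"):
        raise ConfigError(
            "kmc.time_increment: must be 'exponential' or 'mean'"
        )
    theta0 = data["population"]["theta0"]
    if not 0.0 <= theta0 <= 1.0:
        raise ConfigError(f"population.theta0: {theta0} not in [0, 1]")
    if not isinstance(data["seed"], int):
        raise ConfigError("seed: must be an integer")


@dataclass(frozen=True)
class RunConfig:
    """Validated, fully-defaulted run configuration."""

    data: dict

    @property
    def seed(self) -> int:
        return self.data["seed"]

    def hash(self) -> str:
        payload = json.dumps(self.data, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def manifest(self) -> dict:
        from . import __version__

        return {
            "config": self.data,
            "config_hash": self.hash(),
            "seed": self.seed,
            "package": {"name": "lnpkmc", "version": __version__},
        }

    def emit(self) -> str:
        """Canonical YAML text; load(emit(load(x))) is idempotent."""
        return yaml.safe_dump(self.data, sort_keys=True)


def default_config(**top_level_overrides) -> RunConfig:
    data = _merge(DEFAULTS, top_level_overrides or None)
    _validate(data)
    return RunConfig(data)


def load_config(path) -> RunConfig:
    """Load, default-fill and validate a YAML config file."""
    with open(path, "r", encoding="utf-8") as fh:
        user = yaml.safe_load(fh)
    data = _merge(DEFAULTS, user)
    _validate(data)
    return RunConfig(data)


def loads_config(text: str) -> RunConfig:
    data = _merge(DEFAULTS, yaml.safe_load(text))
    _validate(data)
    return RunConfig(data)


def build_objects(config: RunConfig):
    """Materialize domain objects from a config.

    Returns (Formulation, Environment, InteractionParams,
    InitPopulationSpec, EnvironmentSchedule, kmc-controls dict).
    """
    d = config.data
    f = d["formulation"]
    total = sum(f["molar_ratios"])
    try:
        form = Formulation(
            molar_fractions=tuple(r / total for r in f["molar_ratios"]),
            peg_mw=f["peg_mw"],
            peg_monomer_size=f["peg_monomer_size_nm"],
            peg_monomer_mw=f["peg_monomer_mw"],
            v0=f["v0_nm3"],
            species_volumes=None if f["species_volumes_nm3"] is None
            else tuple(f["species_volumes_nm3"]),
            fw=f["fw"],
            charges_per_ionizable=f["charges_per_ionizable"],
            charges_per_rna=f["charges_per_rna"],
            np_ratio=f["np_ratio"],
            rna_mw=f["rna_mw"],
            rna_volume=f["rna_volume_nm3"],
        )
        e = d["environment"]
        alpha = e["alpha_ionizable"]
        if alpha is None:
            alpha = _hh_alpha(e["ph"], e["pka_ionizable"])
        env = Environment(
            temperature=e["temperature_k"],
            viscosity=e["viscosity_pa_s"],
            relative_permittivity=e["relative_permittivity"],
            csalt=e["csalt_m"],
            alpha_ionizable=alpha,
            alpha_rna=e["alpha_rna"],
        )
        i = d["interactions"]
        ip = InteractionParams(
            hamaker=i["hamaker_j"],
            dmin=i["dmin_nm"],
            dmax_debye=i["dmax_debye"],
            peg_mult=i["peg_mult"],
            dlvo_mult=i["dlvo_mult"],
            kernel_mode=i["kernel_mode"],
            n_grid=i["n_grid"],
        )
        p = d["population"]
        r0 = p["r0_nm"]
        if r0 is None:
            m = d["mixing"]
            mc = MixingConditions(
                q=m["flow_rate_ml_min"],
                l=m["layer_half_width_nm"],
                b1=m["b1"],
                alpha1=m["alpha1"],
                tau_unit_s=m["tau_unit_s"],
                d_inter=m["d_inter_nm2_us"],
                seed_radius=m["seed_radius_nm"],
                seed_number_density=m["seed_number_density_nm3"],
            )
            r0 = derive_initial_radius(mc, env)
        spec = InitPopulationSpec(
            n0=p["n0"],
            r0=r0,
            theta0=p["theta0"],
            allocation=p["allocation"],
            sirna_conc=p["sirna_conc_ug_ml"],
            v_system=p["v_system_nm3"],
        )
        s = d["schedule"]
        if s["enabled"]:
            alpha_post = s["alpha_ionizable"]
            if alpha_post is None:
                alpha_post = _hh_alpha(s["ph"], d["environment"]["pka_ionizable"])
            schedule = EnvironmentSchedule(changes=(
                (s["time_s"], {"csalt": s["csalt_m"],
                               "alpha_ionizable": alpha_post}),
            ))
        else:
            schedule = EnvironmentSchedule()
        k = d["kmc"]
        import numpy as np

        t_end = k["t_end_s"]
        grid = np.geomspace(
            max(k["snapshot_t_min_s"], 1e-12),
            max(t_end, k["snapshot_t_min_s"]),
            k["n_snapshots"],
        ) if t_end > 0 else []
        kmc = {
            "t_end": t_end,
            "snapshot_times": grid,
            "time_increment": k["time_increment"],
            "stop_count": k["stop_count"],
            "record_particles": k["record_particles"],
            "use_surrogate": k["use_surrogate"],
        }
    except (ValueError, TypeError) as exc:
        if isinstance(exc, ConfigError):
            raise
        raise ConfigError(str(exc)) from exc
    if math.isnan(spec.r0):
        raise ConfigError("population.r0_nm: could not derive from mixing")
    return form, env, ip, spec, schedule, kmc
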