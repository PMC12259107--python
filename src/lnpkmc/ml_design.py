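"""Parameter sweeps and design-rule extraction.

Runs ensembles of kMC simulations over the formulation/mixing parameter
space (initial radius R0, PEG molecular weight, PEG mole ratio, salt
concentration), collects 18-hour outcomes into a tidy table, and fits
per-output random forests whose Gini (mean-decrease-in-impurity) feature
importances quantify which handle controls which outcome.  Also provides
a smooth surrogate for the charge-regulation solver.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator
from sklearn.ensemble import RandomForestRegressor
from sklearn.metrics import mean_squared_error
from sklearn.model_selection import KFold
from sklearn.preprocessing import StandardScaler

from . import physchem
from .engine import EnvironmentSchedule, simulate
from .initializer import (InitPopulationSpec, build_initial_population,
                          derive_system_volume)
from .physchem import Environment, Formulation, InteractionParams

__all__ = [
    "SweepDesign",
    "ImportanceReport",
    "SurrogateTrainingError",
    "PotentialSurrogate",
    "FEATURE_COLUMNS",
    "OUTPUT_COLUMNS",
    "run_parameter_sweep",
    "fit_feature_importance",
    "train_potential_surrogate",
]

FEATURE_COLUMNS = ("r0_nm", "peg_mw", "peg_ratio", "csalt_m")
OUTPUT_COLUMNS = ("final_mean_radius_nm", "theta_empty",
                  "payload_var_total", "payload_var_loaded")


class SurrogateTrainingError(RuntimeError):
    """Surrogate failed its parity check against the exact solver."""


@dataclass(frozen=True)
class SweepDesign:
    """Input-space design for the kMC parameter sweep.

    Default ranges span the study space: R0 6-10 nm, PEG MW 1000-5000 Da,
    PEG mole ratio 1-3%, csalt 10-150 mM.  ``mode`` is a full factorial
    grid by default; ``lhs`` draws ``n_samples`` Latin-hypercube points.
    """

    r0_values: tuple = (6.0, 8.0, 10.0)
    peg_mw_values: tuple = (1000.0, 3000.0, 5000.0)
    peg_ratio_values: tuple = (0.01, 0.02, 0.03)
    csalt_values: tuple = (0.01, 0.08, 0.15)
    mode: str = "grid"
    n_samples: int = 0

    def rows(self, rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
        if self.mode == "grid":
            grid = np.array(np.meshgrid(
                self.r0_values, self.peg_mw_values,
                self.peg_ratio_values, self.csalt_values,
                indexing="ij",
            )).reshape(4, -1).T
            return pd.DataFrame(grid, columns=list(FEATURE_COLUMNS))
        if self.mode == "lhs":
            if self.n_samples < 1:
                raise ValueError("lhs mode needs n_samples >= 1")
            rng = rng if rng is not None else np.random.default_rng()
            lows = np.array([min(self.r0_values), min(self.peg_mw_values),
                             min(self.peg_ratio_values), min(self.csalt_values)])
            highs = np.array([max(self.r0_values), max(self.peg_mw_values),
                              max(self.peg_ratio_values), max(self.csalt_values)])
            u = np.empty((self.n_samples, 4))
            for k in range(4):
                perm = rng.permutation(self.n_samples)
                u[:, k] = (perm + rng.random(self.n_samples)) / self.n_samples
            return pd.DataFrame(lows + u * (highs - lows),
                                columns=list(FEATURE_COLUMNS))
        raise ValueError("mode must be 'grid' or 'lhs'")


def formulation_with_peg(base: Formulation, peg_mw: float,
                         peg_ratio: float) -> Formulation:
    """Adjust PEG MW and PEG-lipid mole fraction, renormalizing the other
    lipids proportionally."""
    x = np.asarray(base.molar_fractions, dtype=float)
    scale = (1.0 - peg_ratio) / (1.0 - x[3])
    new = (x[0] * scale, x[1] * scale, x[2] * scale, peg_ratio)
    return physchem.Formulation(
        molar_fractions=new,
        peg_mw=peg_mw,
        peg_monomer_size=base.peg_monomer_size,
        peg_monomer_mw=base.peg_monomer_mw,
        v0=base.v0,
        species_volumes=base.species_volumes,
        fw=base.fw,
        charges_per_ionizable=base.charges_per_ionizable,
        charges_per_rna=base.charges_per_rna,
        np_ratio=base.np_ratio,
        rna_mw=base.rna_mw,
        rna_volume=base.rna_volume,
    )


def _run_one(r0, peg_mw, peg_ratio, csalt, seed, *, base_form, base_env,
             ip, n0, theta0, t_end, schedule):
    form = formulation_with_peg(base_form, peg_mw, peg_ratio)
    env = base_env.evolve(csalt=csalt)
    spec = InitPopulationSpec(n0=n0, r0=r0, theta0=theta0)
    rng = np.random.default_rng(seed)
    pop = build_initial_population(spec, form, env, rng)
    v_system = derive_system_volume(spec, form)
    traj = simulate(pop, form, env, ip, v_system,
                    schedule=schedule, t_end=t_end, seed=rng)
    final = traj.final
    radii = final.radii
    rna = final.rna
    loaded = rna[rna > 0]
    return {
        "final_mean_radius_nm": float(radii.mean()),
        "theta_empty": float(np.mean(rna == 0)),
        "payload_var_total": float(np.var(rna)),
        "payload_var_loaded": float(np.var(loaded)) if loaded.size else np.nan,
    }


def run_parameter_sweep(design: SweepDesign = SweepDesign(),
                        replicates: int = 2,
                        seed: int = 0,
                        base_form: Optional[Formulation] = None,
                        base_env: Optional[Environment] = None,
                        ip: Optional[InteractionParams] = None,
                        n0: int = 400,
                        theta0: float = 0.83,
                        t_end: float = 64800.0,
                        schedule: Optional[EnvironmentSchedule] = None,
                        checkpoint: Optional[str] = None) -> pd.DataFrame:
    """Run one kMC simulation per (design row, replicate); average outputs.

    Seeds derive deterministically from (seed, row, replicate), so an
    identical call reproduces the table exactly.  Failed runs are flagged
    (``ok = False``, NaN outputs) and the sweep continues.  If
    ``checkpoint`` names a CSV file, completed rows are appended there and
    skipped on re-run.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    base_form = base_form if base_form is not None else Formulation()
    base_env = base_env if base_env is not None else Environment()
    ip = ip if ip is not None else InteractionParams()
    if schedule is None:
        schedule = EnvironmentSchedule.dialysis()
    rows = design.rows(np.random.default_rng(seed))

    done: dict = {}
    if checkpoint and Path(checkpoint).exists():
        prev = pd.read_csv(checkpoint)
        done = {int(r["row"]): r for _, r in prev.iterrows()}

    records = []
    for idx, row in rows.iterrows():
        if idx in done:
            records.append(dict(done[idx]))
            continue
        reps = []
        ok = True
        err = ""
        for rep in range(replicates):
            child = np.random.SeedSequence([seed, int(idx), rep])
            try:
                reps.append(_run_one(
                    row["r0_nm"], row["peg_mw"], row["peg_ratio"],
                    row["csalt_m"], child,
                    base_form=base_form, base_env=base_env, ip=ip,
                    n0=n0, theta0=theta0, t_end=t_end, schedule=schedule,
                ))
            except Exception as exc:  # noqa: BLE001 - flagged, sweep continues
                ok = False
                err = f"{type(exc).__name__}: {exc}"
        rec = {"row": int(idx), **{c: float(row[c]) for c in FEATURE_COLUMNS}}
        if reps and ok:
            for c in OUTPUT_COLUMNS:
                rec[c] = float(np.nanmean([r[c] for r in reps]))
        else:
            for c in OUTPUT_COLUMNS:
                rec[c] = np.nan
        rec["ok"] = ok
        rec["error"] = err
        rec["replicates"] = len(reps)
        records.append(rec)
        if checkpoint:
            pd.DataFrame(records).to_csv(checkpoint, index=False)
    return pd.DataFrame(records)


@dataclass
class ImportanceReport:
    """Random-forest Gini importances and cross-validated error for one
    output column."""

    target: str
    importances: dict  # feature -> importance, sums to 1
    cv_rmse: float
    hyperparameters: dict
    seed: int
    degenerate: bool = False


def fit_feature_importance(table: pd.DataFrame, target: str, seed: int = 0,
                           n_estimators: int = 500,
                           n_folds: int = 5) -> ImportanceReport:
    """Fit a random forest of ``target`` on the four design features.

    Inputs are standardized before training; importances are mean decrease
    in impurity (Gini), normalized to sum to 1; the model is scored by
    ``n_folds``-fold cross-validated RMSE.  Deterministic given the seed.
    """
    data = table.dropna(subset=[target])
    if len(data) < 25:
        raise ValueError("need at least 25 sweep rows to fit importances")
    x = StandardScaler().fit_transform(data[list(FEATURE_COLUMNS)].to_numpy())
    y = data[target].to_numpy(dtype=float)
    hyper = {"n_estimators": n_estimators, "max_depth": None,
             "random_state": seed}
    if np.ptp(y) == 0.0:
        warnings.warn(f"target {target!r} is constant; importances degenerate",
                      stacklevel=2)
        return ImportanceReport(
            target=target,
            importances={f: 0.25 for f in FEATURE_COLUMNS},
            cv_rmse=0.0,
            hyperparameters=hyper,
            seed=seed,
            degenerate=True,
        )
    forest = RandomForestRegressor(**hyper)
    forest.fit(x, y)
    imp = forest.feature_importances_
    imp = imp / imp.sum()
    rmses = []
    for train, test in KFold(n_splits=n_folds, shuffle=True,
                             random_state=seed).split(x):
        f = RandomForestRegressor(**hyper).fit(x[train], y[train])
        rmses.append(mean_squared_error(y[test], f.predict(x[test])) ** 0.5)
    return ImportanceReport(
        target=target,
        importances=dict(zip(FEATURE_COLUMNS, imp.tolist())),
        cv_rmse=float(np.mean(rmses)),
        hyperparameters=hyper,
        seed=seed,
    )


class PotentialSurrogate:
    """Smooth (R, phi_RNA, csalt) -> reduced surface potential map.

    The charge-regulation root depends on its inputs only through two
    dimensionless groups: the fixed-to-mobile charge ratio
    xi = rho_fixed / (2 fw csalt NA) and the coupling
    kappa = C * (2 fw csalt NA) with C = (4 pi/3) lB R^2/(1 + R/lD), via
    psi/kappa + sinh(psi) = xi.  The surrogate is cubic interpolation of
    that two-parameter solution family on an (asinh xi, log kappa) grid;
    composition coordinates (R, phi_RNA, csalt) map to (xi, kappa) in
    closed form at query time.  This stays accurate through the
    charge-neutralization region, where psi is a stiff sigmoid of
    composition.  Carries its parity report against the exact solver.
    """

    def __init__(self, interpolator, bounds, form, alpha_ionizable,
                 alpha_rna, env_ref, parity: dict):
        self._interp = interpolator
        self.bounds = bounds
        self.form = form
        self.alpha_ionizable = alpha_ionizable
        self.alpha_rna = alpha_rna
        self._env_ref = env_ref
        self.parity = parity

    def _reduced_coords(self, radius, phi_rna, csalt):
        radius = np.atleast_1d(np.asarray(radius, dtype=float))
        phi_rna = np.atleast_1d(np.asarray(phi_rna, dtype=float))
        csalt = np.atleast_1d(np.asarray(csalt, dtype=float))
        form = self.form
        phi_ion = (1.0 - phi_rna) * form.molar_fractions[0] \
            * form.volumes[0] / form.mean_lipid_volume
        fixed = (1.0 - form.fw) * (
            self.alpha_ionizable * form.rho_ionizable * phi_ion
            + self.alpha_rna * form.rho_rna * phi_rna
        )
        mobile = 2.0 * form.fw * csalt * (6.02214076e23 / 1e24)
        lb = physchem.bjerrum_length(self._env_ref)
        ld = np.array([
            physchem.debye_length(self._env_ref.evolve(csalt=float(c)))
            for c in csalt
        ])
        coupling = (4.0 * math.pi / 3.0) * lb * radius**2 / (1.0 + radius / ld)
        return np.arcsinh(fixed / mobile), np.log(coupling * mobile)

    def __call__(self, radius, phi_rna, csalt):
        a, k = self._reduced_coords(radius, phi_rna, csalt)
        out = self._interp(np.column_stack([a, k]))
        return out if np.ndim(radius) else float(out[0])


def _exact_psi(radius, phi_rna, csalt, form, env):
    """Exact psi at matched lipid composition: the non-RNA volume keeps the
    formulation's internal lipid ratios."""
    phi_ion = (1.0 - phi_rna) * form.molar_fractions[0] * form.volumes[0] \
        / form.mean_lipid_volume
    _, psi = physchem.solve_charge_regulation_scalar(
        radius, phi_ion, phi_rna, form, env.evolve(csalt=csalt)
    )
    return psi


def _reduced_psi(a: float, k: float) -> float:
    """Solve psi/exp(k) + sinh(psi) = sinh(a); odd in a, |psi| <= |a|."""
    if a == 0.0:
        return 0.0
    from scipy.optimize import brentq

    kappa = math.exp(k)
    target = math.sinh(a)

    def g(psi):
        return psi / kappa + math.sinh(psi) - target

    lo, hi = (0.0, a) if a > 0 else (a, 0.0)
    return brentq(g, lo, hi, xtol=1e-14, rtol=8.9e-16)


def train_potential_surrogate(r_range=(4.0, 40.0),
                              phi_rna_range=(0.0, 0.30),
                              csalt_range=(0.01, 0.15),
                              grid_shape=(61, 31),
                              n_holdout: int = 1000,
                              max_rel_error: float = 0.01,
                              seed: int = 0,
                              form: Optional[Formulation] = None,
                              env: Optional[Environment] = None):
    """Train and validate the charge-regulation surrogate.

    The stated (R, phi_RNA, csalt) envelope is mapped to the reduced
    (asinh xi, log kappa) rectangle (with 5% margin), the exact root is
    solved on a ``grid_shape`` regular grid there, and cubic interpolation
    is fitted.  Parity is then checked on ``n_holdout`` random points of
    the original envelope against the exact solver: the maximum relative
    error must stay below ``max_rel_error`` or a
    :class:`SurrogateTrainingError` is raised and the surrogate rejected.
    """
    form = form if form is not None else Formulation()
    env = env if env is not None else Environment()
    proto = PotentialSurrogate(None, None, form, env.alpha_ionizable,
                               env.alpha_rna, env, {})
    # reduced-coordinate bounds from the envelope corners (monotone maps)
    rs = np.array([r_range[0], r_range[1]])
    corners_a = []
    corners_k = []
    for r in r_range:
        for p in phi_rna_range:
            for c in csalt_range:
                a, k = proto._reduced_coords(r, p, c)
                corners_a.append(a[0])
                corners_k.append(k[0])
    a_hi = max(abs(min(corners_a)), abs(max(corners_a))) * 1.05
    k_lo, k_hi = min(corners_k), max(corners_k)
    pad = 0.05 * (k_hi - k_lo)
    a_ax = np.linspace(-a_hi, a_hi, grid_shape[0])  # odd count -> 0 on grid
    k_ax = np.linspace(k_lo - pad, k_hi + pad, grid_shape[1])
    values = np.array([[_reduced_psi(a, k) for k in k_ax] for a in a_ax])
    interp = RegularGridInterpolator((a_ax, k_ax), values, method="cubic",
                                     bounds_error=True)
    surrogate = PotentialSurrogate(
        interp,
        bounds={"radius": r_range, "phi_rna": phi_rna_range,
                "csalt": csalt_range},
        form=form,
        alpha_ionizable=env.alpha_ionizable,
        alpha_rna=env.alpha_rna,
        env_ref=env,
        parity={},
    )
    rng = np.random.default_rng(seed)
    r_s = rng.uniform(*r_range, n_holdout)
    p_s = rng.uniform(*phi_rna_range, n_holdout)
    c_s = np.exp(rng.uniform(np.log(csalt_range[0]), np.log(csalt_range[1]),
                             n_holdout))
    exact = np.array([
        _exact_psi(r, p, c, form, env) for r, p, c in zip(r_s, p_s, c_s)
    ])
    approx = surrogate(r_s, p_s, c_s)
    nonzero = np.abs(exact) > 0
    rel = np.abs(approx[nonzero] - exact[nonzero]) / np.abs(exact[nonzero])
    parity = {
        "n_holdout": n_holdout,
        "max_rel_error": float(rel.max()),
        "rms_error": float(np.sqrt(np.mean((approx - exact) ** 2))),
        "seed": seed,
        "grid_shape": tuple(grid_shape),
    }
    surrogate.parity.update(parity)
    if parity["max_rel_error"] >= max_rel_error:
        raise SurrogateTrainingError(
            f"surrogate parity failure: max relative error "
            f"{parity['max_rel_error']:.3e} >= {max_rel_error:.3e}"
        )
    return surrogate
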