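"""Population summaries and derived payload/size statistics.

Operates on :class:`~lnpkmc.population.Population` objects (or raw RNA
count arrays) and on snapshot tables written by the engine.  Variances
are population variances (divisor N), consistently for both the
all-particle and loaded-only flavors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from . import physchem
from .physchem import Environment, Formulation, InteractionParams

__all__ = [
    "PopulationSummary",
    "empty_ratio",
    "payload_histogram",
    "pooled_payload_variance",
    "volumetric_scaling_prediction",
    "aggregation_bias_ratio",
    "dls_rescale",
    "size_summary",
]

DLS_TO_BARE_FACTOR = 2.8


def _rna_counts(population) -> np.ndarray:
    rna = getattr(population, "rna", population)
    rna = np.asarray(rna)
    if rna.size == 0:
        raise ValueError("population is empty")
    if np.any(rna < 0):
        raise ValueError("RNA counts must be >= 0")
    return rna


@dataclass(frozen=True)
class PopulationSummary:
    """Headline statistics of one LNP population snapshot."""

    n_total: int
    n_empty: int
    theta_empty: float
    mean_radius: float
    median_radius: float
    radius_hist: tuple  # (bin_edges, counts)
    payload_hist: tuple  # (copy values, normalized frequencies)
    payload_var_total: float
    payload_var_loaded: float


def empty_ratio(population) -> float:
    """Fraction of LNPs containing no RNA: theta_empty = Nempty/Ntotal."""
    rna = _rna_counts(population)
    return float(np.mean(rna == 0))


def payload_histogram(population, bin_width: int = 1):
    """Normalized RNA-copy frequency table.

    Returns (bin_lefts, frequencies); frequencies sum to 1.  The zero-copy
    bin (empty LNPs) is always reported separately as the first entry,
    regardless of bin width.
    """
    if bin_width < 1:
        raise ValueError("bin width must be >= 1 copy")
    rna = _rna_counts(population)
    n = rna.size
    zeros = int(np.sum(rna == 0))
    loaded = rna[rna > 0]
    lefts = [0]
    counts = [zeros]
    if loaded.size:
        top = int(loaded.max())
        edges = np.arange(1, top + bin_width + 1, bin_width)
        hist, _ = np.histogram(loaded, bins=np.append(edges, edges[-1] + bin_width) - 0.5)
        for left, c in zip(edges, hist):
            if c > 0 or left <= top:
                lefts.append(int(left))
                counts.append(int(c))
    freqs = np.asarray(counts, dtype=float) / n
    return np.asarray(lefts), freqs


def pooled_payload_variance(population, include_empty: bool = True) -> float:
    """Population variance (divisor N) of RNA copy counts.

    ``include_empty=False`` restricts to RNA-containing LNPs; raises if
    there are none.
    """
    rna = _rna_counts(population)
    if not include_empty:
        rna = rna[rna > 0]
        if rna.size == 0:
            raise ValueError("no loaded particles to take a variance over")
    return float(np.var(rna))


def volumetric_scaling_prediction(theta0: float, r0: float, r: float) -> float:
    """Empty-LNP fraction predicted by volumetric scaling.

    theta_empty = theta0^m with m = (R/R0)^3 the mean number of initial
    particles merged into one of radius R.  E.g. theta0 = 0.83, R = 2 R0
    gives 0.83^8 ~ 0.225.
    """
    if not 0.0 <= theta0 <= 1.0:
        raise ValueError("theta0 must be in [0, 1]")
    if r0 <= 0:
        raise ValueError("r0 must be > 0")
    if r < r0:
        raise ValueError("r must be >= r0 (particles only grow)")
    return theta0 ** ((r / r0) ** 3)


def aggregation_bias_ratio(v1: float, v2: float,
                           form: Optional[Formulation] = None,
                           env: Optional[Environment] = None,
                           ip: Optional[InteractionParams] = None,
                           phi_peg: float = 0.015,
                           psi: float = 2.0) -> float:
    """Size-selective merging bias K(v1, v2) / K(v/2, v/2), v = v1 + v2.

    The probability of coalescing particles of volumes v1 and v2 relative
    to two equal halves of the same total volume, at matched composition
    (same PEG fraction ``phi_peg`` and reduced surface potential ``psi``
    on every particle).  Equals 1 exactly at v1 = v2; kernels with a
    barrier favour asymmetric merges (ratio > 1).
    """
    if v1 <= 0 or v2 <= 0:
        raise ValueError("volumes must be > 0")
    form = form if form is not None else Formulation()
    env = env if env is not None else Environment()
    ip = ip if ip is not None else InteractionParams()

    def kernel(va, vb):
        ra = (3.0 * va / (4.0 * math.pi)) ** (1.0 / 3.0)
        rb = (3.0 * vb / (4.0 * math.pi)) ** (1.0 / 3.0)
        out = physchem.pair_rate(
            np.atleast_1d(ra), np.atleast_1d(rb),
            phi_peg, phi_peg, psi, psi,
            form, env, ip, v_system=1.0,
        )
        return float(np.asarray(out).ravel()[0])

    v = v1 + v2
    return kernel(v1, v2) / kernel(v / 2.0, v / 2.0)


def dls_rescale(r_dls: float, factor: float = DLS_TO_BARE_FACTOR) -> float:
    """Convert a DLS-derived radius to a bare (cryo-TEM-like) radius.

    Intensity-weighted DLS radii run about 2.8x larger than number-mean
    bare radii; this helper simply divides by that factor.
    """
    if r_dls <= 0:
        raise ValueError("r_dls must be > 0")
    return r_dls / factor


def size_summary(population, bin_edges=None) -> PopulationSummary:
    """Deterministic summary of a population: sizes, payload, histograms.

    Mean radius is number-weighted over bare radii.
    """
    rna = _rna_counts(population)
    radii = np.asarray(population.radii)
    if bin_edges is None:
        bin_edges = np.linspace(0.0, max(float(radii.max()) * 1.05, 1.0), 41)
    counts, edges = np.histogram(radii, bins=bin_edges)
    loaded = rna[rna > 0]
    lefts, freqs = payload_histogram(population)
    return PopulationSummary(
        n_total=int(rna.size),
        n_empty=int(np.sum(rna == 0)),
        theta_empty=float(np.mean(rna == 0)),
        mean_radius=float(radii.mean()),
        median_radius=float(np.median(radii)),
        radius_hist=(edges, counts),
        payload_hist=(lefts, freqs),
        payload_var_total=float(np.var(rna)),
        payload_var_loaded=float(np.var(loaded)) if loaded.size else float("nan"),
    )


def snapshot_summaries(snapshots: pd.DataFrame) -> pd.DataFrame:
    """Pass-through/validation of an engine snapshot table (see engine
    External Interfaces); recomputes theta consistency checks."""
    required = {"time_s", "n_particles", "mean_radius_nm", "theta_empty"}
    missing = required - set(snapshots.columns)
    if missing:
        raise ValueError(f"snapshot table missing columns: {sorted(missing)}")
    return snapshots.sort_values("time_s").reset_index(drop=True)
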