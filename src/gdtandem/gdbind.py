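"""Gd3+ binding analytics: equilibrium dialysis, Job plots, XO displacement.

The carrier proteins hold Gd3+ in n identical, independent calmodulin-loop
sites, so all equilibria here are per-site 1:1: Kd = [site_free][Gd_free] /
[site:Gd].  Equilibrium dialysis lets free Gd3+ equilibrate across a
semipermeable membrane between the protein chamber (volume v_in) and a
protein-free chamber (v_out); the measured free concentration plus mass
balance inverts to the dissociation constant, reported as the geometric mean
over replicates (mKd).  Binding stoichiometry comes from the continuous-
variation (Job) method: at a fixed total concentration the complex peaks at
the mole fraction matching the stoichiometric ratio (x = 0.5 for 1:1).
Displacement of Gd3+ from its xylenol-orange (XO) complex — read out as an
absorbance change at 570 nm — gives the same information by competition.

All solvers bracket a monotone mass-balance residual (Brent's method),
conserving mass to ~1e-12 relative and returning non-negative species.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "DialysisSetup",
    "DialysisState",
    "JobExperiment",
    "NoBindingError",
    "DataInconsistencyError",
    "solve_dialysis_equilibrium",
    "estimate_mkd",
    "geometric_mean_kd",
    "complex_1to1",
    "job_curve",
    "find_job_maximum",
    "xo_displacement_titration",
]

_XTOL = 1e-12  # absolute bracketing tolerance, µM


class NoBindingError(ValueError):
    """Measured free ligand implies zero complex (Kd division by zero)."""


class DataInconsistencyError(ValueError):
    """Measured free ligand exceeds what mass balance allows."""


# ---------------------------------------------------------------------------
# Equilibrium dialysis (forward)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DialysisSetup:
    """Dialysis experiment: per-site protein and Gd totals in the inner chamber.

    Concentrations are µM relative to the inner volume ``v_in`` (mL); the
    outer chamber ``v_out`` initially contains buffer only.
    """

    site_total: float
    gd_total: float
    kd: float
    v_in: float = 2.0
    v_out: float = 2.0

    def __post_init__(self) -> None:
        if min(self.site_total, self.gd_total, self.kd) < 0:
            raise ValueError("concentrations and kd must be >= 0")
        if self.v_in <= 0 or self.v_out <= 0:
            raise ValueError("chamber volumes must be > 0")


@dataclass(frozen=True)
class DialysisState:
    """Equilibrium species: free sites, free Gd (both chambers), complex (µM)."""

    mbs_free: float
    gd_free: float
    complex: float


def solve_dialysis_equilibrium(setup: DialysisSetup) -> DialysisState:
    """Unique non-negative equilibrium of the dialysis mass-balance system.

    Mass balance: ``complex + mbs_free = site_total`` (inner chamber) and
    ``complex*v_in + gd_free*(v_in + v_out) = gd_total*v_in``; the bound
    fraction follows the per-site isotherm ``complex = site_total * gd_free /
    (kd + gd_free)``.  The residual in ``gd_free`` is strictly increasing, so
    Brent bracketing on [0, gd_total*v_in/(v_in+v_out)] is exact.
    """
    S, G, kd = setup.site_total, setup.gd_total, setup.kd
    v_in, v_tot = setup.v_in, setup.v_in + setup.v_out
    if G == 0.0 or (S == 0.0 and G == 0.0):
        return DialysisState(S, 0.0, 0.0)

    def bound(g_free: float) -> float:
        if kd == 0.0:  # infinite affinity: all Gd reaching sites is bound
            return S if g_free > 0 else min(S, G * v_in / v_in)
        return S * g_free / (kd + g_free)

    g_max = G * v_in / v_tot
    if kd == 0.0:
        total_gd_in_sites = min(S, G)  # per inner-chamber volume
        g_free = max(0.0, (G - total_gd_in_sites) * v_in / v_tot)
        return DialysisState(S - total_gd_in_sites, g_free, total_gd_in_sites)

    def residual(g_free: float) -> float:
        return bound(g_free) * v_in + g_free * v_tot - G * v_in

    if residual(g_max) <= 0.0:  # no sites / negligible binding
        g = g_max
    else:
        g = brentq(residual, 0.0, g_max, xtol=_XTOL)
    c = bound(g)
    return DialysisState(S - c, g, c)


# ---------------------------------------------------------------------------
# Kd estimation (inverse)
# ---------------------------------------------------------------------------

def estimate_mkd(
    gd_free_measured: float,
    site_total: float,
    gd_total: float,
    v_in: float = 2.0,
    v_out: float = 2.0,
) -> float:
    """Dissociation constant from one measured free-Gd concentration (µM).

    Reconstructs the complex and free-site concentrations from mass balance
    and returns ``gd_free * mbs_free / complex`` — the exact inverse of
    :func:`solve_dialysis_equilibrium`.
    """
    if gd_free_measured < 0:
        raise ValueError("measured concentration must be >= 0")
    v_tot = v_in + v_out
    complex_ = (gd_total * v_in - gd_free_measured * v_tot) / v_in
    if complex_ < -1e-9 * max(1.0, gd_total):
        raise DataInconsistencyError(
            "measured free Gd exceeds the total placed in the inner chamber"
        )
    complex_ = max(complex_, 0.0)
    if complex_ == 0.0:
        raise NoBindingError("no complex formed: Kd is unbounded")
    mbs_free = site_total - complex_
    if mbs_free < 0:
        raise DataInconsistencyError("implied complex exceeds total sites")
    return gd_free_measured * mbs_free / complex_


def geometric_mean_kd(kds: Sequence[float]) -> float:
    """Geometric mean of replicate Kd estimates (the mKd convention)."""
    arr = np.asarray(kds, dtype=float)
    if arr.size == 0 or np.any(arr <= 0):
        raise ValueError("need positive Kd estimates")
    return float(np.exp(np.mean(np.log(arr))))


# ---------------------------------------------------------------------------
# Job plot (continuous variation)
# ---------------------------------------------------------------------------

def complex_1to1(p_total: float, l_total: float, kd: float) -> float:
    """Closed-form 1:1 complex concentration from totals and Kd."""
    if p_total < 0 or l_total < 0 or kd < 0:
        raise ValueError("totals and kd must be >= 0")
    b = p_total + l_total + kd
    disc = b * b - 4.0 * p_total * l_total
    c = 0.5 * (b - np.sqrt(max(disc, 0.0)))
    return float(min(c, p_total, l_total))


@dataclass(frozen=True)
class JobExperiment:
    """Continuous-variation setup: fixed total, mole-fraction grid, per-site Kd.

    ``x_grid`` holds the ligand (Gd3+) mole fractions; per-site protein
    concentration at each x is ``(1-x)*c_total``.
    """

    c_total: float
    kd: float
    x_grid: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.c_total <= 0:
            raise ValueError("c_total must be > 0")
        xs = tuple(float(x) for x in self.x_grid)
        if any(not 0.0 <= x <= 1.0 for x in xs):
            raise ValueError("mole fractions must lie in [0, 1]")
        if list(xs) != sorted(xs):
            raise ValueError("x_grid must be sorted")
        object.__setattr__(self, "x_grid", xs)


def job_curve(experiment: JobExperiment) -> np.ndarray:
    """Complex concentration at each mole fraction of the grid (µM)."""
    return np.array(
        [
            complex_1to1(
                (1.0 - x) * experiment.c_total, x * experiment.c_total, experiment.kd
            )
            for x in experiment.x_grid
        ]
    )


def find_job_maximum(experiment: JobExperiment) -> float:
    """Mole fraction of the Job-curve maximum, parabolically refined.

    The grid argmax is refined by fitting a parabola through the peak point
    and its neighbours; for a 1:1 per-site model the maximum sits at x = 0.5
    (n:1 per-molecule binding peaks at n/(n+1)).
    """
    if len(experiment.x_grid) < 3:
        raise ValueError("need at least 3 grid points")
    xs = np.asarray(experiment.x_grid)
    ys = job_curve(experiment)
    k = int(np.argmax(ys))
    if k == 0 or k == len(xs) - 1:
        return float(xs[k])
    x0, x1, x2 = xs[k - 1], xs[k], xs[k + 1]
    y0, y1, y2 = ys[k - 1], ys[k], ys[k + 1]
    denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
    a = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
    b = (x2 * x2 * (y0 - y1) + x1 * x1 * (y2 - y0) + x0 * x0 * (y1 - y2)) / denom
    if a == 0.0:
        return float(x1)
    return float(np.clip(-b / (2.0 * a), x0, x2))


# ---------------------------------------------------------------------------
# Xylenol-orange displacement
# ---------------------------------------------------------------------------

def xo_displacement_titration(
    gd_total: float,
    xo_total: float,
    kd_xo: float,
    kd_protein: float,
    protein_site_grid: Sequence[float],
) -> np.ndarray:
    """[Gd-XO] along a protein titration (signal proportional to A570).

    Solves the three-species competition (Gd shared between XO and protein
    sites) at each titration point by bracketing the free-Gd residual;
    the curve is monotone non-increasing in the protein-site concentration.
    """
    if min(gd_total, xo_total) < 0 or any(p < 0 for p in protein_site_grid):
        raise ValueError("concentrations must be >= 0")
    if kd_xo <= 0 or kd_protein <= 0:
        raise ValueError("kd values must be > 0")

    out = []
    for p_total in protein_site_grid:

        def residual(g: float) -> float:
            gd_xo = xo_total * g / (kd_xo + g)
            gd_p = p_total * g / (kd_protein + g)
            return g + gd_xo + gd_p - gd_total

        if gd_total == 0.0:
            out.append(0.0)
            continue
        g = brentq(residual, 0.0, gd_total, xtol=_XTOL)
        out.append(xo_total * g / (kd_xo + g))
    return np.asarray(out)
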