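"""Inversion-recovery T1 fitting and r1 relaxivity regression.

A paramagnetic Gd3+ centre shortens the longitudinal relaxation time T1 of
surrounding water protons; the relaxivity r1 (mM^-1 s^-1) is the slope of
the relaxation rate 1/T1 against Gd3+ concentration and summarises contrast
efficiency.  T1 itself is measured with an inversion-recovery spin-echo
sequence: the signal as a function of inversion time TI follows

    SI = k * [1 - (1 - cos f) * exp(-TI/T1)
              - 2 cos f * exp(-(TR - TE/2)/T1) + cos f * exp(-TR/T1)]

with flip angle f (180 deg for a perfect inversion, where the bracket
reduces to ``1 - 2 exp(-TI/T1)`` at long TR), repetition time TR and echo
time TE.  Fitting uses multi-start nonlinear least squares because the IR
magnitude curve has a well-known spurious local minimum near the null
crossing TI = T1 ln 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "IRModel",
    "RelaxivitySeries",
    "NonIdentifiableError",
    "ir_signal",
    "fit_t1",
    "compute_r1",
    "PAPER_TI_GRID_MS",
]

#: TI sampling grid (ms) used for the carrier-protein relaxivity series.
PAPER_TI_GRID_MS: tuple[float, ...] = (50, 100, 200, 400, 600, 800, 1000, 1500, 1980)


class NonIdentifiableError(ValueError):
    """The (TI, SI) data do not constrain T1 (e.g. a flat signal)."""


@dataclass(frozen=True)
class IRModel:
    """Inversion-recovery signal model parameters.

    ``k`` is an arbitrary signal scale; ``f`` the inversion flip angle in
    degrees; times in ms.
    """

    k: float
    t1: float
    tr: float = 16000.0
    te: float = 7.1
    f: float = 180.0

    def __post_init__(self) -> None:
        if self.t1 <= 0:
            raise ValueError("t1 must be > 0")
        if not self.tr > self.te >= 0:
            raise ValueError("need tr > te >= 0")
        if not 0.0 <= self.f <= 360.0:
            raise ValueError("flip angle must lie in [0, 360] degrees")


def ir_signal(model: IRModel, ti) -> np.ndarray | float:
    """Inversion-recovery signal at inversion time(s) ``ti`` (ms)."""
    ti_arr = np.asarray(ti, dtype=float)
    if np.any(ti_arr < 0):
        raise ValueError("ti must be >= 0")
    cf = math.cos(math.radians(model.f))
    t1 = model.t1
    out = model.k * (
        1.0
        - (1.0 - cf) * np.exp(-ti_arr / t1)
        - 2.0 * cf * np.exp(-(model.tr - model.te / 2.0) / t1)
        + cf * np.exp(-model.tr / t1)
    )
    return out if out.ndim else float(out)


def fit_t1(
    ti_list: Sequence[float],
    si_list: Sequence[float],
    tr: float = 16000.0,
    te: float = 7.1,
    f: float = 180.0,
    fit_f: bool = False,
    magnitude_mode: bool = False,
    t1_grid: Sequence[float] | None = None,
) -> dict:
    """Fit (T1, k[, f]) to an inversion-recovery series by least squares.

    Multi-start over a log-spaced T1 grid (10..5000 ms by default) guards
    against the null-point local minimum; ``magnitude_mode`` fits |SI| for
    MRI magnitude data that has lost its sign.  Returns a dict with ``t1``,
    ``k``, ``f``, and the residual 2-norm ``residual``.
    """
    ti = np.asarray(ti_list, dtype=float)
    si = np.asarray(si_list, dtype=float)
    if ti.size < 4:
        raise ValueError("need at least 4 (TI, SI) points")
    if np.any(np.diff(ti) <= 0):
        raise ValueError("ti_list must be strictly increasing")
    if np.ptp(si) == 0.0:
        raise NonIdentifiableError("signal is constant: T1 not identifiable")

    scale = float(np.max(np.abs(si))) or 1.0

    def predict(params: np.ndarray) -> np.ndarray:
        k, t1 = params[0], params[1]
        flip = params[2] if fit_f else f
        model = IRModel(k=k, t1=t1, tr=tr, te=te, f=flip)
        pred = ir_signal(model, ti)
        return np.abs(pred) if magnitude_mode else pred

    def resid(params: np.ndarray) -> np.ndarray:
        return predict(params) - (np.abs(si) if magnitude_mode else si)

    starts = np.asarray(t1_grid if t1_grid is not None else
                        np.geomspace(10.0, 5000.0, 12))
    lower = [-np.inf, 1e-3] + ([90.0] if fit_f else [])
    upper = [np.inf, 1e6] + ([270.0] if fit_f else [])
    best = None
    for t1_0 in starts:
        x0 = [scale, float(t1_0)] + ([f] if fit_f else [])
        try:
            sol = least_squares(resid, x0, bounds=(lower, upper))
        except ValueError:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise NonIdentifiableError("all fit starts failed")
    k_hat, t1_hat = float(best.x[0]), float(best.x[1])
    f_hat = float(best.x[2]) if fit_f else float(f)
    residual = float(np.linalg.norm(resid(best.x)))
    return {"t1": t1_hat, "k": k_hat, "f": f_hat, "residual": residual}


@dataclass(frozen=True)
class RelaxivitySeries:
    """r1 regression result over a concentration series.

    ``conc_mM`` and ``t1_ms`` are the inputs; ``r1`` is the ordinary
    least-squares slope of 1/T1 (s^-1) on concentration (mM), and
    ``intercept`` the buffer relaxation rate (s^-1).
    """

    conc_mM: tuple[float, ...]
    t1_ms: tuple[float, ...]
    r1: float
    intercept: float

    def __post_init__(self) -> None:
        if len(self.conc_mM) != len(self.t1_ms) or len(self.conc_mM) < 2:
            raise ValueError("need equal-length series with >= 2 points")
        if any(t <= 0 for t in self.t1_ms):
            raise ValueError("t1 values must be > 0")


def compute_r1(
    conc: Sequence[float],
    t1: Sequence[float],
    conc_unit: str = "mM",
) -> RelaxivitySeries:
    """Relaxivity r1: OLS slope of 1/T1 (s^-1) versus concentration (mM).

    ``conc_unit`` may be "mM" or "uM"/"µM" (auto-converted), making the
    result invariant to the declared concentration scale.  A negative fitted
    slope is diagnostically suspect but reported as-is.
    """
    c = np.asarray(conc, dtype=float)
    t = np.asarray(t1, dtype=float)
    if c.size != t.size or c.size < 2:
        raise ValueError("need >= 2 matched (conc, T1) points")
    if np.unique(c).size < 2:
        raise ValueError("need >= 2 distinct concentrations")
    if np.any(t <= 0):
        raise ValueError("t1 values must be > 0")
    unit = conc_unit.replace("µ", "u")
    if unit == "uM":
        c = c / 1000.0
    elif unit != "mM":
        raise ValueError(f"unknown concentration unit {conc_unit!r}")
    rates = 1000.0 / t  # ms -> s^-1
    slope, intercept = np.polyfit(c, rates, 1)
    return RelaxivitySeries(
        conc_mM=tuple(map(float, c)),
        t1_ms=tuple(map(float, t)),
        r1=float(slope),
        intercept=float(intercept),
    )
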