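"""Fractional-inhibition analysis: dose curve and its inverse.

Maps the fractional reduction f of a kinetic parameter to the relative
extracellular protein collected over an 18 h media window (treated/control
ratio R_x), and inverts an observed R_x back to the fractional inhibition
that reproduces it.  For the secretion rate constant k_out_Si the map runs
monotonically from (0, 1) to (1, 0); inversion uses bisection on that
monotone curve.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .model_core import ParameterSet
from .protocols import INHIBITOR_WINDOW_H, run_inhibitor_treatment

__all__ = ["inhibition_sweep", "invert_inhibition"]

#: Inversion terminates when the simulated ratio is within this of the target.
INVERT_TOL = 1e-8


def inhibition_sweep(params: ParameterSet, target_param: str,
                     grid: Sequence[float],
                     duration: float = INHIBITOR_WINDOW_H) -> np.ndarray:
    """Extracellular ratio R_x over a grid of inhibition fractions.

    Returns an (n, 2) array of (f, R_x) rows, one per grid point.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("fraction grid must be non-empty")
    if np.any(grid < 0) or np.any(grid > 1):
        raise ValueError("inhibition fractions must lie in [0, 1]")
    curve = np.empty((grid.size, 2))
    for i, f in enumerate(grid):
        r_x, _ = run_inhibitor_treatment(params, target_param, float(f), duration)
        curve[i] = (f, r_x)
    return curve


def invert_inhibition(params: ParameterSet, target_param: str,
                      observed_R_x: float,
                      duration: float = INHIBITOR_WINDOW_H,
                      tol: float = INVERT_TOL) -> float:
    """Fractional inhibition f of ``target_param`` reproducing ``observed_R_x``.

    Deterministic bisection on the monotone f -> R_x map.  Raises if the
    observed ratio exceeds 1 (reducing a rate cannot raise the collected
    extracellular protein), is negative, lies below the ratio reachable at
    full blockade of the chosen target, or if the map is not monotone for
    that target.
    """
    if observed_R_x > 1:
        raise ValueError(
            f"observed ratio {observed_R_x} > 1: inhibition of {target_param!r} "
            "cannot raise extracellular protein above control"
        )
    if observed_R_x < 0:
        raise ValueError(f"observed ratio must be >= 0, got {observed_R_x}")

    def ratio(f: float) -> float:
        r_x, _ = run_inhibitor_treatment(params, target_param, f, duration)
        return r_x

    # Monotonicity guard on a coarse grid.
    coarse = [ratio(f) for f in (0.0, 0.25, 0.5, 0.75, 1.0)]
    if not all(a >= b for a, b in zip(coarse, coarse[1:])):
        raise ValueError(
            f"R_x is not monotone decreasing in the inhibition of {target_param!r}; "
            "inversion is not defined for this target"
        )
    r0, r1 = coarse[0], coarse[-1]
    if abs(observed_R_x - r0) <= tol:
        return 0.0
    if abs(observed_R_x - r1) <= tol:
        return 1.0
    if observed_R_x > r0 or observed_R_x < r1:
        raise ValueError(
            f"observed ratio {observed_R_x} outside the reachable range "
            f"[{r1:.6g}, {r0:.6g}] for target {target_param!r}"
        )

    lo, hi = 0.0, 1.0  # ratio(lo) >= observed >= ratio(hi)
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        r_mid = ratio(mid)
        if abs(r_mid - observed_R_x) < tol:
            return mid
        if r_mid > observed_R_x:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-14:
            break
    return 0.5 * (lo + hi)
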