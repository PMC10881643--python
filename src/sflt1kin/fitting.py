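"""Parameter estimation from heterogeneous secretion time courses.

The model is fit jointly to fold-change time courses (pulse-chase,
densitometry-style accumulation) and absolute-concentration time courses
(conditioned-media ELISA), by weighted least squares over log-transformed
rate parameters with multi-start Nelder–Mead, followed by
profile-likelihood uncertainty intervals.

Key structural facts the fitting machinery respects:

* Fold-change observables are invariant to the production rate k_prod
  (normalization cancels the scale), so fold-change-only fits leave k_prod
  structurally non-identifiable — the profile is flat.  One absolute
  concentration dataset pins the scale.
* Each dataset gets equal total weight by default regardless of how many
  points it carries, so a dense fold-change series cannot swamp the sparse
  absolute series that anchors k_prod.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import qmc

from .model_core import PARAMETER_NAMES, ParameterSet
from .protocols import run_accumulation, run_cell_free_decay, run_pulse_chase
from .units import Geometry, molecules_per_cell_to_ng_per_ml

__all__ = [
    "Dataset",
    "FitResult",
    "ProfileResult",
    "DEFAULT_BOUNDS",
    "predict_observables",
    "objective",
    "fit",
    "profile_likelihood",
]

VALID_UNITS = ("fold_change", "ng_per_ml", "molecules_per_cell")
VALID_COMPARTMENTS = ("intracellular", "extracellular")

REQUIRED_COLUMNS = ("experiment_id", "protocol", "time_h", "compartment",
                    "value", "unit", "replicate")

#: Optimization bounds (natural scale).  Rates span the biologically
#: plausible range for protein turnover/secretion; k_prod spans sub-molecule
#: to very high expression; the transit delay is bounded by a working day.
DEFAULT_BOUNDS: Dict[str, Tuple[float, float]] = {
    "k_prod": (1.0, 1e7),
    "tau": (0.0, 8.0),
    "k_out_Si": (1e-4, 1e2),
    "k_deg_Si": (1e-4, 1e2),
    "k_deg_Sx": (1e-4, 1e2),
}

#: 95% chi-square quantile with 1 degree of freedom: profile-likelihood
#: interval threshold on the cost above its optimum.
PROFILE_THRESHOLD_95 = 3.84

_LOG_PARAMS = ("k_prod", "k_out_Si", "k_deg_Si", "k_deg_Sx")
_PENALTY = 1e12  # finite cost for parameter regions where the observable is undefined


# ---------------------------------------------------------------------------
# Dataset
# ---------------------------------------------------------------------------

@dataclass
class Dataset:
    """Observed time-course records plus the metadata needed to predict them.

    ``df`` columns: experiment_id, protocol, time_h, compartment, value,
    unit, replicate, and optionally sigma (per-point measurement SD on the
    observed scale).  ``protocol_spec`` describes the generating experiment
    (e.g. ``{"kind": "pulse_chase", "pulse_duration": 2.0}``);
    ``normalization`` the observable convention (``{"mode": ...}``);
    ``geometry`` is required iff the unit is a concentration.
    """

    name: str
    df: pd.DataFrame
    protocol_spec: dict
    normalization: dict = field(default_factory=lambda: {"mode": "none"})
    geometry: Optional[Geometry] = None

    def __post_init__(self) -> None:
        self.validate()

    @property
    def unit(self) -> str:
        return str(self.df["unit"].iloc[0])

    @property
    def kind(self) -> str:
        return str(self.protocol_spec["kind"])

    def validate(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"dataset {self.name!r} missing columns: {missing}")
        if len(self.df) == 0:
            raise ValueError(f"dataset {self.name!r} is empty")
        if (self.df["time_h"] < 0).any():
            rows = self.df.index[self.df["time_h"] < 0].tolist()
            raise ValueError(f"dataset {self.name!r}: negative time at rows {rows}")
        if (self.df["value"] < 0).any():
            rows = self.df.index[self.df["value"] < 0].tolist()
            raise ValueError(f"dataset {self.name!r}: negative value at rows {rows}")
        units = set(self.df["unit"])
        if len(units) != 1:
            raise ValueError(f"dataset {self.name!r} mixes units {sorted(units)}")
        unit = units.pop()
        if unit not in VALID_UNITS:
            raise ValueError(f"unknown unit {unit!r}; valid units: {VALID_UNITS}")
        bad = set(self.df["compartment"]) - set(VALID_COMPARTMENTS)
        if bad:
            raise ValueError(f"unknown compartments {sorted(bad)}")
        if unit == "ng_per_ml" and self.geometry is None:
            raise ValueError(
                f"dataset {self.name!r} uses ng_per_ml but has no geometry "
                "(n_cells, media_volume_ml, molecular_weight_g_per_mol)"
            )
        if "kind" not in self.protocol_spec:
            raise ValueError("protocol_spec must carry a 'kind'")

    @property
    def sigmas(self) -> Optional[np.ndarray]:
        if "sigma" in self.df.columns:
            s = self.df["sigma"].to_numpy(dtype=float)
            if np.all(np.isfinite(s)) and np.all(s > 0):
                return s
        return None

    # Datasets are treated as immutable once constructed; the fitting loop
    # caches the design (times, row mapping, residual scales) on first use.
    def _ensure_cache(self) -> dict:
        cache = getattr(self, "_cache", None)
        if cache is not None:
            return cache
        times = self.df["time_h"].to_numpy(dtype=float)
        comps_col = self.df["compartment"].to_numpy()
        comp_names = sorted(set(comps_col))
        comp_times, maps = {}, []
        for c in comp_names:
            sel = comps_col == c
            ct = np.unique(times[sel])
            comp_times[c] = ct
            maps.append((c, sel, np.searchsorted(ct, times[sel])))
        all_times = np.unique(times)
        obs = self.df["value"].to_numpy(dtype=float)
        denom = self.sigmas
        if denom is None:
            scale = float(np.mean(np.abs(obs))) or 1.0
            denom = np.full_like(obs, scale)
        cache = {
            "comp_times": comp_times,
            "maps": maps,
            "all_times": all_times,
            "design_idx": {c: np.searchsorted(all_times, ct)
                           for c, ct in comp_times.items()},
            "obs": obs,
            "denom": denom,
        }
        object.__setattr__(self, "_cache", cache)
        return cache


# ---------------------------------------------------------------------------
# Observable prediction
# ---------------------------------------------------------------------------

def _model_design_values(params: ParameterSet, dataset: Dataset) -> Dict[str, np.ndarray]:
    """Noise-free model values at the dataset's (compartment, time) design.

    Returns {compartment: values aligned with ``times_for(compartment)``},
    already in the dataset's unit and normalization.
    """
    spec = dataset.protocol_spec
    kind = spec["kind"]
    norm = dataset.normalization
    mode = norm.get("mode", "none")
    unit = dataset.unit

    cache = dataset._ensure_cache()
    comp_times = cache["comp_times"]

    if kind == "pulse_chase":
        if unit != "fold_change":
            raise ValueError("pulse-chase datasets are fold-change observables")
        convention = norm.get("convention", mode if mode in
                              ("per_compartment", "shared_initial") else "per_compartment")
        res = run_pulse_chase(params, float(spec["pulse_duration"]),
                              cache["all_times"], normalization=convention)
        out = {}
        for c, times in comp_times.items():
            source = (res.intracellular_fold if c == "intracellular"
                      else res.extracellular_fold)
            out[c] = source[cache["design_idx"][c]]
        return out

    if kind in ("accumulation", "cell_free_decay"):
        out = {}
        for c, times in comp_times.items():
            ref_time = float(norm["reference_time"]) if mode == "reference_time" else None
            sim_times = times
            if ref_time is not None and not np.any(np.isclose(times, ref_time)):
                sim_times = np.sort(np.append(times, ref_time))
            if kind == "accumulation":
                traj = run_accumulation(params, sim_times)
                vals = traj.channel(c)
            else:
                if c != "extracellular":
                    raise ValueError("cell-free decay has no intracellular compartment")
                traj = run_cell_free_decay(params, float(spec.get("S_x0", 1.0)), sim_times)
                vals = traj.S_x
            if unit == "ng_per_ml":
                vals = molecules_per_cell_to_ng_per_ml(vals, dataset.geometry)
            if mode == "reference_time":
                ref_val = vals[np.isclose(sim_times, ref_time)][0]
                if ref_val == 0:
                    raise ValueError(
                        f"normalization reference value at t={ref_time} h is zero; "
                        "choose a later reference time or 'max' normalization"
                    )
                vals = vals / ref_val
            elif mode == "max":
                sel = np.isin(sim_times, times)
                m = vals[sel].max()
                if m == 0:
                    raise ValueError("cannot normalize to an all-zero maximum")
                vals = vals / m
            elif mode != "none":
                raise ValueError(f"unknown normalization mode {mode!r} for {kind}")
            if unit == "fold_change" and mode == "none":
                raise ValueError("fold_change unit requires a normalization mode")
            keep = np.isin(sim_times, times)
            out[c] = vals[keep]
        return out

    raise ValueError(f"cannot predict observables for protocol kind {kind!r}")


def predict_observables(params: ParameterSet, dataset: Dataset) -> np.ndarray:
    """Model predictions aligned row-by-row with ``dataset.df``.

    Runs the dataset's protocol, converts to its unit via the experiment
    geometry, and applies the dataset's own normalization to the model
    prediction (the data are never re-normalized).
    """
    design = _model_design_values(params, dataset)
    cache = dataset._ensure_cache()
    pred = np.empty(len(dataset.df))
    for c, sel, idx in cache["maps"]:
        pred[sel] = design[c][idx]
    return pred


# ---------------------------------------------------------------------------
# Objective
# ---------------------------------------------------------------------------

def _residuals(params: ParameterSet, dataset: Dataset) -> np.ndarray:
    cache = dataset._ensure_cache()
    pred = predict_observables(params, dataset)
    return (cache["obs"] - pred) / cache["denom"]


def objective(params: ParameterSet, datasets: Sequence[Dataset],
              weights: Optional[Sequence[float]] = None) -> float:
    """Weighted sum of squared residuals across datasets.

    Residuals are scaled by per-point sigma when the dataset provides it,
    otherwise by the dataset's mean observed value (relative error).  With
    ``weights=None`` each dataset receives weight 1/n_points so every
    dataset carries equal total weight; explicit weights are applied as
    given (cost_k = w_k * sum of squared residuals).
    """
    if len(datasets) == 0:
        raise ValueError("objective requires at least one dataset")
    if weights is not None and len(weights) != len(datasets):
        raise ValueError("weights must match datasets in length")
    total = 0.0
    for i, ds in enumerate(datasets):
        r = _residuals(params, ds)
        w = (1.0 / r.size) if weights is None else float(weights[i])
        total += w * float(np.dot(r, r))
    return total


# ---------------------------------------------------------------------------
# Multi-start fit
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Outcome of a multi-start fit."""

    params: ParameterSet
    objective: float
    residuals: Dict[str, np.ndarray]
    success: bool
    start_objectives: np.ndarray
    non_identifiable: List[str]
    bounds: Dict[str, Tuple[float, float]]
    seed: int
    n_starts: int

    @property
    def start_dispersion(self) -> float:
        """Spread of converged start objectives (max - min of finite ones)."""
        finite = self.start_objectives[np.isfinite(self.start_objectives)]
        return float(finite.max() - finite.min()) if finite.size else float("nan")


def _to_x(params: ParameterSet) -> np.ndarray:
    return np.array([
        np.log10(params.k_prod) if params.k_prod > 0 else -300.0,
        params.tau,
        np.log10(params.k_out_Si) if params.k_out_Si > 0 else -300.0,
        np.log10(params.k_deg_Si) if params.k_deg_Si > 0 else -300.0,
        np.log10(params.k_deg_Sx) if params.k_deg_Sx > 0 else -300.0,
    ])


def _from_x(x: np.ndarray) -> ParameterSet:
    return ParameterSet(
        k_prod=10.0 ** x[0], tau=float(x[1]), k_out_Si=10.0 ** x[2],
        k_deg_Si=10.0 ** x[3], k_deg_Sx=10.0 ** x[4],
    )


def _transformed_bounds(bounds: Dict[str, Tuple[float, float]]):
    order = ("k_prod", "tau", "k_out_Si", "k_deg_Si", "k_deg_Sx")
    out = []
    for name in order:
        lo, hi = bounds[name]
        if name in _LOG_PARAMS:
            if lo <= 0:
                raise ValueError(f"bound for {name} must be positive for log-scale fitting")
            out.append((np.log10(lo), np.log10(hi)))
        else:
            out.append((float(lo), float(hi)))
    return out


def _safe_cost(x: np.ndarray, datasets, weights) -> float:
    try:
        return objective(_from_x(x), datasets, weights)
    except (ValueError, FloatingPointError):
        return _PENALTY


def fit(datasets: Sequence[Dataset],
        bounds: Optional[Dict[str, Tuple[float, float]]] = None,
        n_starts: int = 20, seed: int = 0,
        weights: Optional[Sequence[float]] = None,
        maxiter: int = 2500) -> FitResult:
    """Estimate the five kinetic parameters by multi-start local optimization.

    Rates and k_prod are optimized on a log10 scale within box bounds; the
    delay on a linear scale.  Starting points come from a seeded Latin
    hypercube, each refined by bounded Nelder–Mead; the best optimum is
    polished by a simplex restart.  Deterministic given the seed.

    A cheap structural-identifiability probe perturbs each fitted parameter
    by ±5%: parameters whose perturbation leaves the cost unchanged (e.g.
    k_prod under fold-change-only data) are flagged non-identifiable.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    bounds = dict(DEFAULT_BOUNDS, **(bounds or {}))
    tb = _transformed_bounds(bounds)
    lo = np.array([b[0] for b in tb])
    hi = np.array([b[1] for b in tb])

    sampler = qmc.LatinHypercube(d=5, seed=seed)
    starts = lo + sampler.random(n_starts) * (hi - lo)

    nm_opts = dict(xatol=1e-9, fatol=1e-13, maxiter=maxiter, adaptive=True)
    best_x, best_f = None, np.inf
    start_objs = np.full(n_starts, np.nan)
    for i in range(n_starts):
        res = minimize(_safe_cost, starts[i], args=(datasets, weights),
                       method="Nelder-Mead", bounds=tb, options=nm_opts)
        start_objs[i] = res.fun
        if res.fun < best_f:
            best_f, best_x = res.fun, res.x
    if best_x is None or not np.isfinite(best_f) or best_f >= _PENALTY:
        raise RuntimeError(
            "no optimization start converged to a finite cost; "
            f"start objectives: {start_objs}"
        )
    # simplex restart polish
    res = minimize(_safe_cost, best_x, args=(datasets, weights),
                   method="Nelder-Mead", bounds=tb, options=nm_opts)
    if res.fun < best_f:
        best_f, best_x = res.fun, res.x

    opt = _from_x(best_x)
    non_ident = []
    for j, name in enumerate(("k_prod", "tau", "k_out_Si", "k_deg_Si", "k_deg_Sx")):
        flat = True
        for delta in (+1, -1):
            x_pert = best_x.copy()
            if name == "tau":
                x_pert[j] = np.clip(x_pert[j] + delta * 0.1, lo[j], hi[j])
            else:
                x_pert[j] = np.clip(x_pert[j] + delta * np.log10(1.05), lo[j], hi[j])
            if x_pert[j] == best_x[j]:
                continue
            if _safe_cost(x_pert, datasets, weights) > best_f + 1e-9 * (1.0 + best_f):
                flat = False
                break
        if flat:
            non_ident.append(name)

    residuals = {ds.name: _residuals(opt, ds) for ds in datasets}
    return FitResult(params=opt, objective=float(best_f), residuals=residuals,
                     success=True, start_objectives=start_objs,
                     non_identifiable=non_ident, bounds=bounds, seed=seed,
                     n_starts=n_starts)


# ---------------------------------------------------------------------------
# Profile likelihood
# ---------------------------------------------------------------------------

@dataclass
class ProfileResult:
    """Profile-likelihood curve and confidence interval for one parameter.

    ``interval`` is (lo, hi) on the natural scale; an endpoint equal to the
    parameter's bound with the profile still under threshold there marks the
    interval as open on that side.  ``flat`` is True when the entire profile
    stays within the threshold band — the structural non-identifiability
    signature (e.g. k_prod under fold-change-only data).
    """

    param: str
    grid: np.ndarray
    costs: np.ndarray
    interval: Tuple[float, float]
    lower_open: bool
    upper_open: bool
    threshold: float
    optimum_value: float
    optimum_cost: float

    @property
    def flat(self) -> bool:
        return self.lower_open and self.upper_open

    @property
    def finite(self) -> bool:
        return not (self.lower_open or self.upper_open)


def _default_grid(param: str, bounds: Dict[str, Tuple[float, float]],
                  n_grid: int) -> np.ndarray:
    lo, hi = bounds[param]
    if param in _LOG_PARAMS:
        return np.geomspace(lo, hi, n_grid)
    return np.linspace(lo, hi, n_grid)


def profile_likelihood(fit_result: FitResult, datasets: Sequence[Dataset],
                       param: str, grid: Optional[Sequence[float]] = None,
                       threshold: float = PROFILE_THRESHOLD_95,
                       weights: Optional[Sequence[float]] = None,
                       n_grid: int = 15, maxiter: int = 800) -> ProfileResult:
    """Profile the cost over one parameter, re-optimizing the other four.

    Walks outward from the optimum in both directions, warm-starting each
    constrained re-optimization from its neighbour.  The 95% interval is
    where the profile cost stays within ``threshold`` of the optimum
    (linear interpolation at the crossings).
    """
    if param not in PARAMETER_NAMES:
        raise KeyError(f"unknown parameter {param!r}")
    if not fit_result.success:
        raise ValueError("profile_likelihood requires a converged fit")
    bounds = fit_result.bounds
    p_lo, p_hi = bounds[param]
    grid = np.asarray(grid if grid is not None else
                      _default_grid(param, bounds, n_grid), dtype=float)
    if np.any(grid < p_lo - 1e-12) or np.any(grid > p_hi + 1e-12):
        raise ValueError(f"profile grid outside bounds [{p_lo}, {p_hi}] for {param!r}")
    grid = np.sort(grid)
    opt_value = getattr(fit_result.params, param)
    if not np.any(np.isclose(grid, opt_value, rtol=1e-9)):
        grid = np.sort(np.append(grid, np.clip(opt_value, p_lo, p_hi)))

    order = ("k_prod", "tau", "k_out_Si", "k_deg_Si", "k_deg_Sx")
    j = order.index(param)
    free = [k for k in range(5) if k != j]
    x_opt = _to_x(fit_result.params)
    tb_full = _transformed_bounds(bounds)
    tb_free = [tb_full[k] for k in free]
    nm_opts = dict(xatol=1e-8, fatol=1e-12, maxiter=maxiter, adaptive=True)

    def fixed_coord(value: float) -> float:
        return np.log10(value) if param in _LOG_PARAMS else value

    def profile_at(value: float, x_free_start: np.ndarray):
        def cost(xf):
            x = x_opt.copy()
            x[j] = fixed_coord(value)
            x[free] = xf
            return _safe_cost(x, datasets, weights)
        res = minimize(cost, x_free_start, method="Nelder-Mead",
                       bounds=tb_free, options=nm_opts)
        # also try from the global optimum's free coordinates
        if not np.allclose(x_free_start, x_opt[free]):
            res2 = minimize(cost, x_opt[free], method="Nelder-Mead",
                            bounds=tb_free, options=nm_opts)
            if res2.fun < res.fun:
                res = res2
        return float(res.fun), res.x

    costs = np.empty(grid.size)
    i_opt = int(np.argmin(np.abs(grid - opt_value)))
    # outward walk, warm-started
    xf = x_opt[free].copy()
    for i in range(i_opt, grid.size):
        costs[i], xf = profile_at(grid[i], xf)
    xf = x_opt[free].copy()
    for i in range(i_opt - 1, -1, -1):
        costs[i], xf = profile_at(grid[i], xf)

    limit = fit_result.objective + threshold
    inside = costs <= limit

    def crossing(i_in: int, i_out: int) -> float:
        """Interpolate the threshold crossing between an inside/outside pair."""
        x1, x2 = grid[i_in], grid[i_out]
        c1, c2 = costs[i_in], costs[i_out]
        if param in _LOG_PARAMS:
            x1, x2 = np.log10(x1), np.log10(x2)
        frac = (limit - c1) / (c2 - c1)
        x = x1 + frac * (x2 - x1)
        return 10.0 ** x if param in _LOG_PARAMS else x

    if not inside.any():
        lo_val = hi_val = opt_value
        lower_open = upper_open = False
    else:
        first, last = int(np.argmax(inside)), int(grid.size - 1 - np.argmax(inside[::-1]))
        lower_open = first == 0
        upper_open = last == grid.size - 1
        lo_val = grid[first] if lower_open else crossing(first, first - 1)
        hi_val = grid[last] if upper_open else crossing(last, last + 1)

    return ProfileResult(param=param, grid=grid, costs=costs,
                         interval=(float(lo_val), float(hi_val)),
                         lower_open=lower_open, upper_open=upper_open,
                         threshold=threshold, optimum_value=float(opt_value),
                         optimum_cost=float(fit_result.objective))
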