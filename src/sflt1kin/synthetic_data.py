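"""Synthetic time-course generator with densitometry-style statistics.

Emulates the statistical structure of the data the model is fit to in
practice: sparse sampling (<= 10 time points), a handful of replicates,
multiplicative (lognormal) measurement noise, and fold-change normalization
computed per replicate against its own reference point — the way band
intensities actually become fold changes, which induces the characteristic
zero-variance observation at the reference time.

Noise is applied to the raw signal *before* normalization.
"""

from __future__ import annotations

from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .fitting import Dataset
from .model_core import ParameterSet
from .protocols import pulse_chase_raw, run_accumulation, run_cell_free_decay
from .units import Geometry, molecules_per_cell_to_ng_per_ml

__all__ = ["generate_dataset", "generate_fit_benchmark", "BENCHMARK_RANGES"]

#: Ranges the fit benchmark draws true parameters from (log-uniform for all
#: but tau, which is uniform).  They bracket the phenotypes of constitutive
#: endothelial secretion: intracellular turnover on the 1–10 h timescale,
#: near-stable conditioned media, and a sub-2 h transit delay.
BENCHMARK_RANGES: Dict[str, Tuple[float, float]] = {
    "k_prod": (1e3, 1e5),
    "tau": (0.25, 1.5),
    "k_out_Si": (0.1, 1.0),
    "k_deg_Si": (0.1, 1.0),
    "k_deg_Sx": (0.01, 0.1),
}

#: Benchmark observation design: pulse-chase fold changes (both
#: compartments, 8 chase points over 8 h) and absolute conditioned-media
#: concentration (6 points over 24 h).
BENCHMARK_PULSE_DURATION = 2.0
BENCHMARK_CHASE_TIMES = (0.0, 0.5, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0)
BENCHMARK_ACCUM_TIMES = (2.0, 4.0, 8.0, 12.0, 18.0, 24.0)
BENCHMARK_GEOMETRY = Geometry(n_cells=1e6, media_volume_ml=2.0,
                              molecular_weight_g_per_mol=1e5)


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise with mean 1 and coefficient of variation ``cv``."""
    if cv == 0:
        return np.ones(size)
    s2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-0.5 * s2, sigma=np.sqrt(s2), size=size)


def _raw_design(params: ParameterSet, protocol_spec: dict,
                sample_times: np.ndarray, compartments: Sequence[str],
                unit: str, geometry: Optional[Geometry]) -> Dict[str, np.ndarray]:
    """Noise-free raw signal per compartment, pre-normalization.

    For absolute units the raw signal is already on the observed scale; for
    fold-change observables it is the underlying (arbitrary-scale) signal
    that normalization will be applied to.
    """
    kind = protocol_spec["kind"]
    if kind == "pulse_chase":
        traj = pulse_chase_raw(params, float(protocol_spec["pulse_duration"]), sample_times)
        keep = np.isclose(traj.times[:, None], sample_times, atol=1e-9).any(axis=1)
        return {
            c: (traj.S_i if c == "intracellular" else traj.S_x)[keep]
            for c in compartments
        }
    out = {}
    for c in compartments:
        if kind == "accumulation":
            traj = run_accumulation(params, sample_times)
            vals = traj.channel(c)
        elif kind == "cell_free_decay":
            if c != "extracellular":
                raise ValueError("cell-free decay has no intracellular compartment")
            vals = run_cell_free_decay(params, float(protocol_spec.get("S_x0", 1.0)),
                                       sample_times).S_x
        else:
            raise ValueError(f"cannot generate data for protocol kind {kind!r}")
        if unit == "ng_per_ml":
            if geometry is None:
                raise ValueError("ng_per_ml generation requires a geometry")
            vals = molecules_per_cell_to_ng_per_ml(vals, geometry)
        out[c] = np.asarray(vals, dtype=float)
    return out


def _normalize_replicate(noisy: Dict[str, np.ndarray], times: np.ndarray,
                         mode: str, reference_time: Optional[float]) -> Dict[str, np.ndarray]:
    """Apply the declared normalization to one replicate's noisy signal."""
    def at_time(values: np.ndarray, t: float) -> float:
        hit = np.isclose(times, t)
        if not hit.any():
            raise ValueError(
                f"normalization reference time {t} h is not among the sampled "
                f"times {times.tolist()}"
            )
        return float(values[hit][0])

    if mode == "none":
        return noisy
    if mode == "reference_time":
        return {c: v / at_time(v, reference_time) for c, v in noisy.items()}
    if mode == "max":
        return {c: v / v.max() for c, v in noisy.items()}
    if mode == "per_compartment":
        out = {}
        for c, v in noisy.items():
            out[c] = v / (at_time(v, 0.0) if c == "intracellular" else v.max())
        return out
    if mode == "shared_initial":
        if "intracellular" not in noisy:
            raise ValueError("shared_initial normalization needs the intracellular channel")
        ref = at_time(noisy["intracellular"], 0.0)
        return {c: v / ref for c, v in noisy.items()}
    raise ValueError(f"unknown normalization mode {mode!r}")


def generate_dataset(params: ParameterSet, protocol_spec: dict,
                     sample_times: Sequence[float],
                     compartments: Sequence[str] = ("extracellular",),
                     noise_cv: float = 0.2, n_replicates: int = 3,
                     unit: str = "molecules_per_cell",
                     normalization: Optional[dict] = None,
                     geometry: Optional[Geometry] = None,
                     seed: int = 0, name: str = "synthetic") -> Dataset:
    """Simulate a protocol and emit a noisy replicated :class:`Dataset`.

    Each observation of each replicate receives an independent lognormal
    factor with mean 1 and coefficient of variation ``noise_cv``; the
    declared normalization is then applied within each replicate, so
    fold-change replicates are normalized against their own noisy reference.
    Fully determined by ``seed``.  When ``noise_cv > 0`` a per-point sigma
    column (noise_cv times the noise-free observed value) is attached.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    normalization = normalization or {"mode": "none"}
    mode = normalization.get("mode", "none")
    if unit == "fold_change" and mode == "none":
        raise ValueError("fold_change unit requires a normalization mode")
    if unit != "fold_change" and mode != "none":
        raise ValueError(f"absolute unit {unit!r} cannot carry normalization {mode!r}")

    times = np.asarray(sample_times, dtype=float)
    raw = _raw_design(params, protocol_spec, times, compartments, unit, geometry)
    clean = _normalize_replicate({c: v.copy() for c, v in raw.items()},
                                 times, mode, normalization.get("reference_time"))

    rng = np.random.default_rng(seed)
    rows = []
    for r in range(n_replicates):
        noisy = {c: v * _lognormal_factors(rng, noise_cv, v.shape) for c, v in raw.items()}
        obs = _normalize_replicate(noisy, times, mode, normalization.get("reference_time"))
        for c in compartments:
            for t, value, ref in zip(times, obs[c], clean[c]):
                row = dict(experiment_id=name, protocol=protocol_spec["kind"],
                           time_h=t, compartment=c, value=value, unit=unit,
                           replicate=f"r{r + 1}")
                if noise_cv > 0:
                    row["sigma"] = noise_cv * abs(ref)
                rows.append(row)
    df = pd.DataFrame(rows)
    return Dataset(name=name, df=df, protocol_spec=dict(protocol_spec),
                   normalization=dict(normalization), geometry=geometry)


def generate_fit_benchmark(seed: int, noise_cv: float = 0.2,
                           n_replicates: int = 3) -> Tuple[ParameterSet, list]:
    """Standard parameter-recovery fixture.

    Draws a true parameter set from :data:`BENCHMARK_RANGES` and generates
    the two dataset types the model is calibrated with in practice: a
    pulse-chase fold-change series (both compartments, normalized to the
    intracellular labeled signal at chase start) and an absolute
    conditioned-media concentration series with its geometry attached.

    Returns ``(theta_true, [pulse_chase_dataset, accumulation_dataset])``.
    """
    rng = np.random.default_rng(seed)
    draws = {}
    for pname, (lo, hi) in BENCHMARK_RANGES.items():
        if pname == "tau":
            draws[pname] = rng.uniform(lo, hi)
        else:
            draws[pname] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    theta = ParameterSet(**draws)

    seed_pc, seed_acc = (int(s) for s in rng.integers(0, 2**31 - 1, size=2))
    ds_pc = generate_dataset(
        theta,
        {"kind": "pulse_chase", "pulse_duration": BENCHMARK_PULSE_DURATION},
        BENCHMARK_CHASE_TIMES,
        compartments=("intracellular", "extracellular"),
        noise_cv=noise_cv, n_replicates=n_replicates, unit="fold_change",
        normalization={"mode": "shared_initial"},
        seed=seed_pc, name="pulse_chase_fold",
    )
    ds_acc = generate_dataset(
        theta,
        {"kind": "accumulation"},
        BENCHMARK_ACCUM_TIMES,
        compartments=("extracellular",),
        noise_cv=noise_cv, n_replicates=n_replicates, unit="ng_per_ml",
        normalization={"mode": "none"}, geometry=BENCHMARK_GEOMETRY,
        seed=seed_acc, name="media_concentration",
    )
    return theta, [ds_pc, ds_acc]
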