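"""Declarative simulators of the four secretion experiment classes.

Each experiment the model is confronted with is one of:

* ``accumulation`` — media change at t=0, then secreted protein accumulates
  in fresh media while the cells sit at their constitutive steady state.
* ``pulse_chase`` — protein synthesized during a labeling pulse is followed
  through the chase as fold changes in both compartments.
* ``cell_free_decay`` — conditioned media incubated without cells, probing
  extracellular stability alone.
* ``inhibitor_treatment`` — an 18 h media window with one kinetic parameter
  fractionally reduced, reported as treated/control ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .model_core import (
    PARAMETER_NAMES,
    ParameterSet,
    Trajectory,
    simulate,
    steady_state,
)

__all__ = [
    "Protocol",
    "PulseChaseResult",
    "run_accumulation",
    "run_pulse_chase",
    "run_cell_free_decay",
    "run_inhibitor_treatment",
]

PROTOCOL_KINDS = ("accumulation", "pulse_chase", "cell_free_decay", "inhibitor_treatment")

#: Duration of the inhibitor media window, hours.
INHIBITOR_WINDOW_H = 18.0

PULSE_CHASE_NORMALIZATIONS = ("per_compartment", "shared_initial")


@dataclass
class Protocol:
    """Declarative description of one experiment.

    ``production_schedule`` is a piecewise-constant gate: a list of
    (start time, gate value) pairs, each holding until the next start.
    ``media_events`` are times at which the extracellular pool is reset to
    zero (media change).  ``inhibitions`` are (parameter name, fraction in
    [0,1], onset time) triples; the parameter is scaled by (1 - fraction)
    from the onset on.  ``history`` selects the pre-t=0 state: a culture at
    its constitutive steady state, or a system with no prior synthesis.
    """

    kind: str
    horizon: float
    production_schedule: List[Tuple[float, float]] = field(default_factory=lambda: [(0.0, 1.0)])
    media_events: List[float] = field(default_factory=list)
    inhibitions: List[Tuple[str, float, float]] = field(default_factory=list)
    history: str = "steady_state"
    sample_times: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.kind not in PROTOCOL_KINDS:
            raise ValueError(f"unknown protocol kind {self.kind!r}; valid: {PROTOCOL_KINDS}")
        if self.horizon < 0:
            raise ValueError("horizon must be >= 0")
        if self.history not in ("steady_state", "zero"):
            raise ValueError(f"history must be 'steady_state' or 'zero', got {self.history!r}")
        for t, g in self.production_schedule:
            if not 0.0 <= g <= 1.0:
                raise ValueError(f"production gate must be in [0, 1], got {g}")
        for t in self.media_events:
            if not 0.0 <= t <= self.horizon:
                raise ValueError(f"media event at {t} h outside [0, {self.horizon}] h")
        for name, f, onset in self.inhibitions:
            if name not in PARAMETER_NAMES:
                raise KeyError(f"unknown inhibition target {name!r}")
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"inhibition fraction must be in [0, 1], got {f}")
            if not 0.0 <= onset <= self.horizon:
                raise ValueError(f"inhibition onset {onset} h outside [0, {self.horizon}] h")
        if self.sample_times is not None:
            st = np.asarray(self.sample_times, dtype=float)
            if st.size and (st.min() < 0 or st.max() > self.horizon):
                raise ValueError("sample_times must lie within [0, horizon]")
            self.sample_times = st

    def to_dict(self) -> dict:
        d = {
            "kind": self.kind,
            "horizon": float(self.horizon),
            "production_schedule": [[float(t), float(g)] for t, g in self.production_schedule],
            "media_events": [float(t) for t in self.media_events],
            "inhibitions": [[str(n), float(f), float(o)] for n, f, o in self.inhibitions],
            "history": self.history,
        }
        if self.sample_times is not None:
            d["sample_times"] = [float(t) for t in self.sample_times]
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "Protocol":
        known = {"kind", "horizon", "production_schedule", "media_events",
                 "inhibitions", "history", "sample_times"}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown protocol keys {sorted(unknown)}")
        kwargs = dict(data)
        if "production_schedule" in kwargs:
            kwargs["production_schedule"] = [tuple(x) for x in kwargs["production_schedule"]]
        if "inhibitions" in kwargs:
            kwargs["inhibitions"] = [
                (str(n), float(f), float(o)) for n, f, o in kwargs["inhibitions"]
            ]
        if "sample_times" in kwargs and kwargs["sample_times"] is not None:
            kwargs["sample_times"] = np.asarray(kwargs["sample_times"], dtype=float)
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# Accumulation (media-change) experiment
# ---------------------------------------------------------------------------

def accumulation_protocol(horizon: float) -> Protocol:
    return Protocol(kind="accumulation", horizon=horizon,
                    production_schedule=[(0.0, 1.0)], media_events=[0.0],
                    history="steady_state")


def run_accumulation(params: ParameterSet, sample_times: Sequence[float],
                     engine: str = "exact") -> Trajectory:
    """Secreted-protein accumulation after a media change.

    Cells sit at the constitutive steady state (S_i(0) = S_i*), the media is
    replaced at t=0 (S_x(0) = 0), and production stays on throughout.
    """
    sample_times = np.asarray(sample_times, dtype=float)
    proto = accumulation_protocol(float(sample_times.max()))
    return simulate(params, proto, sample_times, engine=engine)


# ---------------------------------------------------------------------------
# Pulse-chase
# ---------------------------------------------------------------------------

@dataclass
class PulseChaseResult:
    """Fold-change time courses of a labeled cohort during the chase.

    ``times`` are chase times (h, 0 = chase start).  Normalization modes:

    * ``per_compartment`` — intracellular fold change relative to its value
      at chase start; extracellular relative to its own maximum over the
      sampled chase.
    * ``shared_initial`` — both compartments relative to the intracellular
      labeled signal at chase start, preserving the intra/extra amplitude
      ratio (and with it the secreted fraction).
    """

    times: np.ndarray
    intracellular_fold: np.ndarray
    extracellular_fold: np.ndarray
    normalization: str
    raw: Trajectory  # unnormalized labeled-cohort trajectory (chase clock)


def pulse_chase_raw(params: ParameterSet, pulse_duration: float,
                    sample_times: Sequence[float], engine: str = "exact") -> Trajectory:
    """Unnormalized labeled-cohort trajectory; times on the chase clock.

    The labeled cohort obeys the same kinetics as bulk protein but with
    production on only during the pulse window [-pulse_duration, 0); by
    linearity it is independent of the unlabeled pool.  Internally the
    simulation clock starts at the beginning of the pulse.
    """
    if pulse_duration <= 0:
        raise ValueError("pulse_duration must be > 0")
    chase_times = np.asarray(sample_times, dtype=float)
    if np.any(chase_times < 0):
        raise ValueError("chase sample times must be >= 0")
    pd_ = float(pulse_duration)
    grid = chase_times + pd_
    if not np.any(np.isclose(grid, pd_)):
        grid = np.sort(np.append(grid, pd_))
    proto = Protocol(kind="pulse_chase", horizon=float(grid.max()),
                     production_schedule=[(0.0, 1.0), (pd_, 0.0)],
                     media_events=[], history="zero")
    traj = simulate(params, proto, grid, engine=engine)
    traj.times = traj.times - pd_
    return traj


def run_pulse_chase(params: ParameterSet, pulse_duration: float,
                    sample_times: Sequence[float],
                    normalization: str = "per_compartment",
                    engine: str = "exact") -> PulseChaseResult:
    """Fold-change read-out of a pulse-chase labeling experiment."""
    if normalization not in PULSE_CHASE_NORMALIZATIONS:
        raise ValueError(
            f"unknown normalization {normalization!r}; valid: {PULSE_CHASE_NORMALIZATIONS}"
        )
    chase_times = np.asarray(sample_times, dtype=float)
    traj = pulse_chase_raw(params, pulse_duration, chase_times, engine=engine)
    keep = np.isclose(traj.times[:, None], chase_times, atol=1e-9).any(axis=1)
    at_start = np.isclose(traj.times, 0.0)
    si_ref = float(traj.S_i[at_start][0]) if at_start.any() else float(
        np.interp(0.0, traj.times, traj.S_i))
    if si_ref <= 0:
        raise ValueError(
            "intracellular labeled signal at chase start is zero (delay exceeds "
            "the pulse window); switch normalization to a later reference time "
            "or lengthen the pulse"
        )
    s_i = traj.S_i[keep]
    s_x = traj.S_x[keep]
    if normalization == "per_compartment":
        sx_ref = float(s_x.max())
        if sx_ref <= 0:
            raise ValueError(
                "extracellular labeled signal is identically zero; cannot "
                "normalize to its maximum — use 'shared_initial' normalization"
            )
        ex_fold = s_x / sx_ref
    else:
        ex_fold = s_x / si_ref
    return PulseChaseResult(
        times=traj.times[keep],
        intracellular_fold=s_i / si_ref,
        extracellular_fold=ex_fold,
        normalization=normalization,
        raw=traj,
    )


# ---------------------------------------------------------------------------
# Cell-free extracellular decay
# ---------------------------------------------------------------------------

def run_cell_free_decay(params: ParameterSet, S_x0: float,
                        sample_times: Sequence[float]) -> Trajectory:
    """Conditioned media incubated without cells: pure first-order decay.

    S_x(t) = S_x0 * exp(-k_deg_Sx * t); no intracellular channel exists.
    """
    if S_x0 < 0:
        raise ValueError("S_x0 must be >= 0")
    t = np.asarray(sample_times, dtype=float)
    if np.any(t < 0):
        raise ValueError("sample times must be >= 0")
    s_x = S_x0 * np.exp(-params.k_deg_Sx * t)
    zeros = np.zeros_like(t)
    return Trajectory(times=t, S_i=None, S_x=s_x,
                      cum_produced=zeros, cum_secreted=zeros, cum_deg_i=zeros,
                      cum_deg_x=S_x0 - s_x, cum_removed=zeros,
                      S_i0=0.0, S_x0=float(S_x0))


# ---------------------------------------------------------------------------
# Inhibitor treatment
# ---------------------------------------------------------------------------

def inhibitor_protocol(target_param: str, fraction: float,
                       duration: float = INHIBITOR_WINDOW_H) -> Protocol:
    return Protocol(kind="inhibitor_treatment", horizon=duration,
                    production_schedule=[(0.0, 1.0)], media_events=[0.0],
                    inhibitions=[(target_param, fraction, 0.0)],
                    history="steady_state")


def run_inhibitor_treatment(params: ParameterSet, target_param: str, f: float,
                            duration: float = INHIBITOR_WINDOW_H,
                            engine: str = "exact") -> Tuple[float, float]:
    """Treated/control ratios after an inhibitor media window.

    Both arms start from the unperturbed constitutive steady state with a
    media change at t=0; the treated arm runs with ``target_param`` scaled
    by (1 - f) from t=0.  Returns (R_x, R_i): extracellular and
    intracellular treated/control ratios at t=duration.
    """
    if target_param not in PARAMETER_NAMES:
        raise KeyError(
            f"unknown parameter {target_param!r}; valid names: {', '.join(PARAMETER_NAMES)}"
        )
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"inhibition fraction must be in [0, 1], got {f}")
    t_end = np.array([duration])
    control = simulate(params, accumulation_protocol(duration), t_end, engine=engine)
    treated = simulate(params, inhibitor_protocol(target_param, f, duration),
                       t_end, engine=engine)
    r_x = float(treated.S_x[-1] / control.S_x[-1])
    r_i = float(treated.S_i[-1] / control.S_i[-1])
    return r_x, r_i
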