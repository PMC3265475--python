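"""Deterministic computational experiments on oscillation-driven motifs.

The experiments mirror the questions the models are built to answer: how does
the stationary expression of the target gene respond to the *period* of the
input oscillation (period sweeps), to its temporal *shape* at fixed duty
structure (shape sweeps), and to a transient step stimulus (sign-sensitive
delay, pulse generation)?  All pipelines run through the closed-form
stationary machinery, so results are exact and bit-reproducible — there is no
randomness anywhere in the core.

Regime classification.  For a feed-forward loop with single-crossing drive
the qualitative period response falls into four classes, determined purely by
two threshold orderings: the direct-branch input threshold ``K_xz`` versus
the indirect-branch input threshold ``K_xy``, and the intermediate threshold
``K_yz`` versus the intermediate's stationary mean ``⟨Y⟩`` (which is
period-invariant, so the class label is too).  Degenerate equalities are
reported as ``boundary`` rather than silently forced into a class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .analytic import (
    StationaryResponse,
    simulate_motif,
    stationary_mean,
    stationary_response,
)
from .motifs import DigitalTrace, MotifConfig, MotifError
from .signals import AnchorProfile, PeriodicSignal, StepSignal

__all__ = [
    "RegimeLabel",
    "StepResponseResult",
    "default_period_grid",
    "period_sweep",
    "shape_sweep",
    "classify_regime",
    "step_response",
]

_SWEEP_COLUMNS = [
    "motif",
    "gate",
    "shape",
    "period",
    "dimensionless_period",
]


@dataclass(frozen=True)
class RegimeLabel:
    """Qualitative period-response class of an FFL configuration."""

    case: str  # "A" | "B" | "C" | "D" | "boundary"
    motif: str
    gate: str


@dataclass(frozen=True)
class StepResponseResult:
    """Event-exact characterization of a motif's response to a step stimulus."""

    on_delay: float
    off_delay: float
    n_pulses: int
    pulse_durations: tuple[float, ...]


def default_period_grid(
    stage_degradation: float = 1.0, n: int = 25
) -> np.ndarray:
    """Log-spaced periods spanning dimensionless periods 1e-1 to 1e2.

    Covers both asymptotic regimes of the stationary extrema: amplitude
    collapse onto the mean at short periods and saturation at the two
    equilibria at long periods.
    """
    taus = np.logspace(-1, 2, n)
    return taus / stage_degradation


def _stats_row(resp: StationaryResponse) -> dict[str, float]:
    row: dict[str, float] = {}
    for gene, st in resp.stats.items():
        g = gene.lower()
        row[f"{g}_mean"] = st.mean
        row[f"{g}_min"] = st.y_min
        row[f"{g}_max"] = st.y_max
        row[f"{g}_duty_in"] = st.duty_in
        if not math.isnan(st.duty_out):
            row[f"{g}_duty_out"] = st.duty_out
            row[f"{g}_onset_delay"] = st.onset_delay
            row[f"{g}_offset_delay"] = st.offset_delay
    return row


def period_sweep(
    config: MotifConfig,
    shape: AnchorProfile,
    periods,
) -> pd.DataFrame:
    """Stationary statistics of every gene across a grid of input periods.

    One row per period; the dimensionless period column is the period
    measured in units of the responding (last) gene's lifetime.
    """
    periods = np.asarray(periods, dtype=float)
    if periods.size < 2:
        raise MotifError("a period sweep needs at least 2 periods")
    last = config.gene_order()[-1]
    alpha = config.stages[last].degradation
    rows = []
    for T in periods:
        resp = stationary_response(config, PeriodicSignal(shape, float(T)))
        row = {
            "motif": config.motif_name,
            "gate": config.gate or "",
            "shape": shape.label,
            "period": float(T),
            "dimensionless_period": float(T) * alpha,
        }
        row.update(_stats_row(resp))
        rows.append(row)
    return pd.DataFrame(rows)


def shape_sweep(
    config: MotifConfig,
    shapes,
    period: float,
) -> pd.DataFrame:
    """Stationary statistics for several input shapes at one fixed period.

    Intended for shapes sharing the same duty structure, so that differences
    between rows isolate the effect of the temporal profile alone.
    """
    frames = []
    last = config.gene_order()[-1]
    alpha = config.stages[last].degradation
    for shape in shapes:
        resp = stationary_response(config, PeriodicSignal(shape, float(period)))
        row = {
            "motif": config.motif_name,
            "gate": config.gate or "",
            "shape": shape.label,
            "period": float(period),
            "dimensionless_period": float(period) * alpha,
        }
        row.update(_stats_row(resp))
        frames.append(row)
    return pd.DataFrame(frames)


def classify_regime(config: MotifConfig, input_signal) -> RegimeLabel:
    """Assign the four-class period-response label of an FFL configuration.

    The two defining orderings are evaluated from the configuration and the
    input's duty structure only (the intermediate mean is period-invariant):

    =====  ==================  ==================
    case   input thresholds    intermediate threshold
    =====  ==================  ==================
    A      K_xy < K_xz         K_yz < ⟨Y⟩
    B      K_xy < K_xz         K_yz > ⟨Y⟩
    C      K_xy > K_xz         K_yz < ⟨Y⟩
    D      K_xy > K_xz         K_yz > ⟨Y⟩
    =====  ==================  ==================

    Ties in either ordering yield ``case="boundary"``.
    """
    if config.topology != "ffl":
        raise MotifError("regime classification is defined for FFL topologies only")
    k_xy = config.edge("X", "Y").threshold
    k_xz = config.edge("X", "Z").threshold
    k_yz = config.edge("Y", "Z").threshold
    duty = input_signal.duty_fraction(k_xy)
    y_mean = stationary_mean(duty, config.stages["Y"])
    if k_xy == k_xz or k_yz == y_mean:
        case = "boundary"
    elif k_xy < k_xz:
        case = "A" if k_yz < y_mean else "B"
    else:
        case = "C" if k_yz < y_mean else "D"
    return RegimeLabel(case=case, motif=config.motif_name, gate=config.gate or "")


def step_response(
    config: MotifConfig,
    step: StepSignal,
    tail: float = 10.0,
) -> StepResponseResult:
    """Characterize the target gene's synthesis pulses under a step stimulus.

    ``on_delay`` is the lag from stimulus onset to the first instant of target
    synthesis; ``off_delay`` the lag from stimulus removal to the last
    shutdown of synthesis (0 when synthesis stops at the very instant the
    stimulus ends, the coherent-loop sign-sensitive behaviour).  A step too
    short or too weak to trigger any synthesis reports zero pulses rather
    than an error.
    """
    if config.topology != "ffl":
        raise MotifError("step_response is defined for FFL topologies only")
    horizon = step.off_time + tail
    resp = simulate_motif(config, step, horizon)
    gate: DigitalTrace = resp.digitals["gate"]
    pulses = [
        (a, b) for a, b in gate.intervals(1) if a >= step.on_time
    ]
    if not pulses:
        return StepResponseResult(math.nan, math.nan, 0, ())
    on_delay = pulses[0][0] - step.on_time
    last_off = pulses[-1][1]
    off_delay = max(last_off - step.off_time, 0.0)
    durations = tuple(b - a for a, b in pulses)
    return StepResponseResult(
        on_delay=on_delay,
        off_delay=off_delay,
        n_pulses=len(pulses),
        pulse_durations=durations,
    )
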