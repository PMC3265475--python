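"""Exact event-driven solution of motif dynamics and stationary-regime analysis.

Between threshold crossings every gene in these models obeys a linear ODE with
constant synthesis rate ``β`` and degradation ``α``,

    dy/dt = β − α y,

whose solution is a single exponential relaxing toward the equilibrium
``β/α``.  A full trajectory is therefore a chain of exponential segments glued
at the switching events, represented exactly by
:class:`PiecewiseExpTrajectory` — no numerical integration anywhere in this
module.

Stationary regime.  Under a periodic drive the one-period return map
``y(T) = F·y(0) + B`` is affine with contraction factor ``F = e^{−αT} < 1``,
so the periodic attractor is the closed-form fixed point ``y* = B/(1 − F)``;
:func:`stationary_cycle` builds one exactly periodic cycle from it (no
burn-in).  From the cycle follow the stationary statistics: the time average
is the duty-weighted average of the two equilibria (independent of period and
shape for a fixed duty fraction), the cycle extrema collapse onto that average
as the dimensionless period ``τ = αT → 0`` and spread to the two equilibria
as ``τ → ∞``, and the onset/offset delays of a downstream threshold are
closed-form logarithms, from which the downstream duty fraction follows.

The cascade structure (direct, two-step, FFL) is strictly feed-forward, so
each stage's drive is periodic once its upstream is stationary and the whole
stationary response is computed stage by stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .motifs import (
    DigitalTrace,
    GeneStage,
    MotifConfig,
    MotifError,
    digitize,
    gate_combine,
)

__all__ = [
    "PiecewiseExpTrajectory",
    "StationaryStats",
    "MotifResponse",
    "StationaryResponse",
    "NeverCrossesError",
    "ClosedFormInapplicableError",
    "propagate",
    "propagate_drive",
    "stationary_cycle",
    "stationary_mean",
    "onset_delay",
    "square_wave_extrema",
    "downstream_duty",
    "simulate_motif",
    "stationary_response",
]

_TIE_TOL = 1e-12


class NeverCrossesError(ValueError):
    """A relaxation trajectory never reaches the requested threshold."""


class ClosedFormInapplicableError(ValueError):
    """The single-crossing closed forms do not apply; use the event-driven path."""


class PiecewiseExpTrajectory:
    """A concentration trajectory made of contiguous exponential segments.

    Segment ``i`` covers ``[t0[i], t1[i]]`` and evaluates as
    ``asym[i] + (y0[i] − asym[i])·exp(−rate[i]·(t − t0[i]))``; each segment's
    asymptote is the equilibrium (synthesis rate)/(degradation) active on that
    interval, and segments are continuous at junctions.
    """

    __slots__ = ("t0", "t1", "asym", "y0", "rate", "_yend")

    def __init__(self, t0, t1, asym, y0, rate) -> None:
        self.t0 = np.asarray(t0, dtype=float)
        self.t1 = np.asarray(t1, dtype=float)
        self.asym = np.asarray(asym, dtype=float)
        self.y0 = np.asarray(y0, dtype=float)
        self.rate = np.asarray(rate, dtype=float)
        n = self.t0.size
        if not (self.t1.size == self.asym.size == self.y0.size == self.rate.size == n):
            raise ValueError("segment arrays must have equal length")
        if n == 0:
            raise ValueError("trajectory needs at least one segment")
        if np.any(self.t1 <= self.t0):
            raise ValueError("segments must have positive length")
        if np.any(self.t0[1:] - self.t1[:-1] > _TIE_TOL) or np.any(
            self.t1[:-1] - self.t0[1:] > _TIE_TOL
        ):
            raise ValueError("segments must be contiguous")
        self._yend = self.asym + (self.y0 - self.asym) * np.exp(
            -self.rate * (self.t1 - self.t0)
        )

    # -- basic geometry -----------------------------------------------------

    @property
    def window(self) -> tuple[float, float]:
        return (float(self.t0[0]), float(self.t1[-1]))

    @property
    def n_segments(self) -> int:
        return self.t0.size

    @property
    def end_value(self) -> float:
        return float(self._yend[-1])

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        idx = np.clip(np.searchsorted(self.t1, t, side="left"), 0, self.n_segments - 1)
        val = self.asym[idx] + (self.y0[idx] - self.asym[idx]) * np.exp(
            -self.rate[idx] * (t - self.t0[idx])
        )
        return val if val.ndim else float(val)

    def extrema(self) -> tuple[float, float]:
        """(min, max) over the whole window — exact, since segments are monotone."""
        vals = np.concatenate([self.y0, self._yend])
        return float(vals.min()), float(vals.max())

    def integral(self) -> float:
        """Exact time integral over the window (closed-form per segment)."""
        length = self.t1 - self.t0
        decay = -np.expm1(-self.rate * length)  # 1 - exp(-r L), accurately
        return float(
            np.sum(self.asym * length + (self.y0 - self.asym) * decay / self.rate)
        )

    def mean(self) -> float:
        a, b = self.window
        return self.integral() / (b - a)

    # -- threshold structure -------------------------------------------------

    def crossings(
        self, threshold: float, window: tuple[float, float] | None = None
    ) -> list[tuple[float, str]]:
        """Exact (time, direction) threshold crossings, optionally windowed.

        Each segment is monotone, so a crossing exists in a segment iff its
        endpoint values straddle the threshold; the time solves a single
        logarithm.  Junction values exactly at the threshold are crossing
        points when the state changes across them.
        """
        out: list[tuple[float, str]] = []
        above_start = self.y0 > threshold
        above_end = self._yend > threshold
        for i in range(self.n_segments):
            ya, yb = float(self.y0[i]), float(self._yend[i])
            if above_start[i] == above_end[i]:
                continue
            direction = "up" if yb > ya else "down"
            if ya == threshold:
                t = float(self.t0[i])
            elif yb == threshold:
                t = float(self.t1[i])
            else:
                a = float(self.asym[i])
                t = float(self.t0[i]) + math.log((ya - a) / (threshold - a)) / float(
                    self.rate[i]
                )
            out.append((t, direction))
        # State changes across junctions between segments are already captured
        # because endpoint values are shared; dedupe exact touches.
        dedup: list[tuple[float, str]] = []
        for ev in out:
            if dedup and abs(ev[0] - dedup[-1][0]) <= _TIE_TOL:
                dedup.pop()
            else:
                dedup.append(ev)
        if window is not None:
            t0, t1 = window
            dedup = [ev for ev in dedup if t0 <= ev[0] < t1]
        return dedup


def propagate(
    initial_value: float,
    rate_trace: Sequence[tuple[float, float, float]],
    degradation: float,
    window: tuple[float, float] | None = None,
) -> PiecewiseExpTrajectory:
    """Exactly solve dy/dt = β(t) − α·y for a piecewise-constant β.

    ``rate_trace`` is an ordered list of (start, end, synthesis rate)
    intervals covering the window; the solution on each is a single
    exponential toward β/α, continuous at the junctions.
    """
    if initial_value < 0:
        raise ValueError(f"initial value must be >= 0, got {initial_value!r}")
    if not degradation > 0:
        raise ValueError("degradation must be > 0")
    segs = [(float(a), float(b), float(r)) for a, b, r in rate_trace if b > a]
    if window is not None:
        segs = _clip_rate_trace(segs, window)
    if not segs:
        raise ValueError("rate trace does not cover the window")
    t0s, t1s, asyms, y0s = [], [], [], []
    y = float(initial_value)
    for a, b, beta in segs:
        t0s.append(a)
        t1s.append(b)
        asym = beta / degradation
        asyms.append(asym)
        y0s.append(y)
        y = asym + (y - asym) * math.exp(-degradation * (b - a))
    return PiecewiseExpTrajectory(
        t0s, t1s, asyms, y0s, [degradation] * len(t0s)
    )


def _clip_rate_trace(segs, window):
    t0, t1 = window
    out = []
    for a, b, r in segs:
        a2, b2 = max(a, t0), min(b, t1)
        if b2 > a2:
            out.append((a2, b2, r))
    return out


def propagate_drive(
    initial_value: float, drive: DigitalTrace, stage: GeneStage
) -> PiecewiseExpTrajectory:
    """Propagate a gene stage under a digital drive (off/on synthesis rates)."""
    trace = [
        (a, b, stage.synth_on if s else stage.synth_off) for a, b, s in drive.states()
    ]
    return propagate(initial_value, trace, stage.degradation)


def stationary_cycle(
    drive: DigitalTrace, stage: GeneStage, period: float
) -> PiecewiseExpTrajectory:
    """One exactly periodic cycle of a gene stage under a periodic drive.

    The one-period return map is affine, ``y(T) = F·y(0) + B`` with
    ``F = e^{−αT}``, composed segment by segment; the returned trajectory
    starts from the closed-form fixed point ``B/(1 − F)``, so its value at the
    end of the cycle equals its value at the start exactly (no burn-in).
    """
    t0, t1 = drive.window
    if abs((t1 - t0) - period) > _TIE_TOL * max(1.0, period):
        raise MotifError(
            f"drive window {drive.window!r} does not span one period ({period!r})"
        )
    factor, offset = 1.0, 0.0
    for a, b, s in drive.states():
        beta = stage.synth_on if s else stage.synth_off
        asym = beta / stage.degradation
        f = math.exp(-stage.degradation * (b - a))
        # y -> asym + (y - asym) f = f·y + asym(1 - f)
        factor *= f
        offset = f * offset + asym * (1.0 - f)
    y_star = offset / (1.0 - factor)
    return propagate_drive(y_star, drive, stage)


def stationary_mean(duty_in: float, stage: GeneStage) -> float:
    """Stationary time-averaged expression under a drive with given duty.

    The duty-weighted average of the two equilibria,
    ``(1 − f)·synth_off/α + f·synth_on/α`` — equal to the exact time integral
    of the stationary cycle divided by the period, for any drive shape and any
    period with that duty fraction.
    """
    if not 0.0 <= duty_in <= 1.0:
        raise ValueError(f"duty must lie in [0, 1], got {duty_in!r}")
    return (1.0 - duty_in) * stage.eq_off + duty_in * stage.eq_on


def onset_delay(
    y_start: float, asymptote: float, threshold: float, degradation: float
) -> float:
    """Time for an exponential relaxation from ``y_start`` toward ``asymptote``
    to reach ``threshold``.

    Closed form ``ln[(y_start − a)/(threshold − a)] / α`` for both the rising
    and the falling case.  Raises :class:`NeverCrossesError` when the
    threshold is not strictly between the start value and the asymptote (the
    trajectory approaches the asymptote only asymptotically, so a threshold at
    or beyond it is never reached).
    """
    if not degradation > 0:
        raise ValueError("degradation must be > 0")
    if threshold == y_start:
        return 0.0
    denom = threshold - asymptote
    numer = y_start - asymptote
    if denom == 0.0 or numer == 0.0 or (numer / denom) < 1.0:
        raise NeverCrossesError(
            f"threshold {threshold!r} is not between start {y_start!r} and "
            f"asymptote {asymptote!r}: trajectory never crosses it"
        )
    return math.log(numer / denom) / degradation


def square_wave_extrema(
    duty: float, stage: GeneStage, period: float
) -> tuple[float, float]:
    """Stationary cycle extrema under a single-pulse drive of given duty.

    For a drive that is on for ``f·T`` and off for ``(1−f)·T`` per cycle the
    periodic fixed point gives two-exponential closed forms (τ = αT):

        y_end_on  = [y_on·(1 − e^{−fτ}) + y_off·(1 − e^{−(1−f)τ})·e^{−fτ}] / (1 − e^{−τ})
        y_end_off = y_off + (y_end_on − y_off)·e^{−(1−f)τ}

    For an activator stage these are (y_max, y_min); for an inhibitor the
    roles swap.  Returned as ``(y_min, y_max)``.  These apply to *any*
    periodic drive with a single on-interval per cycle — the intermediate
    concentration depends on the input only through its digitized drive.
    """
    if not 0.0 < duty < 1.0:
        raise ValueError(f"duty must lie in (0, 1), got {duty!r}")
    tau = stage.degradation * period
    e_on = math.exp(-duty * tau)
    e_off = math.exp(-(1.0 - duty) * tau)
    y_on, y_off = stage.eq_on, stage.eq_off
    y_end_on = (y_on * (1.0 - e_on) + y_off * (1.0 - e_off) * e_on) / (
        1.0 - e_on * e_off
    )
    y_end_off = y_off + (y_end_on - y_off) * e_off
    return (min(y_end_on, y_end_off), max(y_end_on, y_end_off))


@dataclass
class StationaryStats:
    """Stationary-regime summary for one gene stage.

    ``duty_in`` is the on-fraction of the stage's own drive; ``duty_out`` the
    fraction of the cycle the stage's concentration activates a downstream
    threshold (NaN when there is no downstream edge).  Delays are measured
    from the drive's on/off switching to the stage's own crossing of the
    downstream threshold, modulo the period.
    """

    gene: str
    mean: float
    y_min: float
    y_max: float
    duty_in: float
    n_pulses_in: int
    dimensionless_period: float
    duty_out: float = math.nan
    onset_delay: float = math.nan
    offset_delay: float = math.nan


@dataclass
class MotifResponse:
    """Transient event-exact response of a motif over a bounded window."""

    window: tuple[float, float]
    input_signal: object
    trajectories: dict[str, PiecewiseExpTrajectory]
    digitals: dict[str, DigitalTrace]
    config: MotifConfig

    def event_times(self) -> np.ndarray:
        """All exact switching instants (input crossings, gate events) in order."""
        times = np.concatenate(
            [d.switch_times for d in self.digitals.values()]
            or [np.empty(0)]
        )
        times = np.unique(times)
        return times

    def sample(self, ts) -> dict[str, np.ndarray]:
        ts = np.asarray(ts, dtype=float)
        out = {"time": ts, "X": np.asarray(self.input_signal(ts), dtype=float)}
        for name, traj in self.trajectories.items():
            out[name] = np.asarray(traj(ts), dtype=float)
        for name, dig in self.digitals.items():
            out[name] = np.asarray(dig.value(ts), dtype=float)
        return out


@dataclass
class StationaryResponse:
    """Stationary (periodic-attractor) response of a motif, stage by stage."""

    period: float
    cycles: dict[str, PiecewiseExpTrajectory]
    digitals: dict[str, DigitalTrace]
    stats: dict[str, StationaryStats]
    config: MotifConfig


def simulate_motif(
    config: MotifConfig,
    input_signal,
    horizon: float,
    initial: dict[str, float] | None = None,
) -> MotifResponse:
    """Event-exact cascade simulation on [0, horizon] from given initial values.

    Evaluation is in topological order: digitize the input, propagate Y,
    digitize Y at the downstream threshold, combine gate inputs, propagate Z.
    All switching instants are exact; defaults start every gene at zero
    concentration.
    """
    if not horizon > 0:
        raise MotifError(f"horizon must be positive, got {horizon!r}")
    init = {g: 0.0 for g in config.gene_order()}
    if initial:
        init.update(initial)
    window = (0.0, float(horizon))
    digitals: dict[str, DigitalTrace] = {}
    trajectories: dict[str, PiecewiseExpTrajectory] = {}

    theta_xy = digitize(input_signal, config.edge("X", "Y"), window)
    digitals["theta_xy"] = theta_xy
    y_traj = propagate_drive(init["Y"], theta_xy, config.stages["Y"])
    trajectories["Y"] = y_traj

    if config.topology == "direct":
        return MotifResponse(window, input_signal, trajectories, digitals, config)

    theta_yz = digitize(y_traj, config.edge("Y", "Z"), window)
    digitals["theta_yz"] = theta_yz
    if config.topology == "two_step":
        drive_z = theta_yz
    else:  # ffl
        theta_xz = digitize(input_signal, config.edge("X", "Z"), window)
        digitals["theta_xz"] = theta_xz
        drive_z = gate_combine(config.gate, theta_xz, theta_yz)
        digitals["gate"] = drive_z
    z_traj = propagate_drive(init["Z"], drive_z, config.stages["Z"])
    trajectories["Z"] = z_traj
    return MotifResponse(window, input_signal, trajectories, digitals, config)


def stationary_response(config: MotifConfig, input_signal) -> StationaryResponse:
    """Stationary-regime cycles and statistics for every gene in the motif.

    Requires a periodic input (an object with a ``period``).  Each stage's
    drive is periodic once its upstream is stationary (feed-forward
    structure), so each stage is solved by its own period-map fixed point.
    """
    period = getattr(input_signal, "period", None)
    if period is None:
        raise MotifError("stationary_response requires a periodic input signal")
    T = float(period)
    window = (0.0, T)
    digitals: dict[str, DigitalTrace] = {}
    cycles: dict[str, PiecewiseExpTrajectory] = {}
    stats: dict[str, StationaryStats] = {}

    y_stage = config.stages["Y"]
    theta_xy = digitize(input_signal, config.edge("X", "Y"), window)
    digitals["theta_xy"] = theta_xy
    y_cyc = stationary_cycle(theta_xy, y_stage, T)
    cycles["Y"] = y_cyc
    y_min, y_max = y_cyc.extrema()
    y_stats = StationaryStats(
        gene="Y",
        mean=y_cyc.integral() / T,
        y_min=y_min,
        y_max=y_max,
        duty_in=theta_xy.measure() / T,
        n_pulses_in=_pulses_per_cycle(theta_xy),
        dimensionless_period=T * y_stage.degradation,
    )

    if config.topology == "direct":
        stats["Y"] = y_stats
        return StationaryResponse(T, cycles, digitals, stats, config)

    edge_yz = config.edge("Y", "Z")
    theta_yz = digitize(y_cyc, edge_yz, window)
    digitals["theta_yz"] = theta_yz
    y_stats.duty_out = theta_yz.measure() / T
    y_stats.onset_delay, y_stats.offset_delay = _stationary_delays(
        theta_xy, y_cyc, edge_yz.threshold, T
    )
    stats["Y"] = y_stats

    if config.topology == "two_step":
        drive_z = theta_yz
    else:
        theta_xz = digitize(input_signal, config.edge("X", "Z"), window)
        digitals["theta_xz"] = theta_xz
        drive_z = gate_combine(config.gate, theta_xz, theta_yz)
        digitals["gate"] = drive_z
    z_stage = config.stages["Z"]
    z_cyc = stationary_cycle(drive_z, z_stage, T)
    cycles["Z"] = z_cyc
    z_min, z_max = z_cyc.extrema()
    stats["Z"] = StationaryStats(
        gene="Z",
        mean=z_cyc.integral() / T,
        y_min=z_min,
        y_max=z_max,
        duty_in=drive_z.measure() / T,
        n_pulses_in=_pulses_per_cycle(drive_z),
        dimensionless_period=T * z_stage.degradation,
    )
    return StationaryResponse(T, cycles, digitals, stats, config)


def _pulses_per_cycle(trace: DigitalTrace) -> int:
    """On-pulses per cycle of a periodic trace (wraparound-aware)."""
    n = len(trace.switch_times)
    if n == 0:
        return 0
    # Periodic: state(t0) == state(t1), so switches come in up/down pairs.
    return n // 2


def _stationary_delays(
    drive: DigitalTrace, cycle: PiecewiseExpTrajectory, threshold: float, period: float
) -> tuple[float, float]:
    """Onset/offset delay of the gene's threshold activation behind its drive.

    Measured between the drive's up (down) switch and the gene concentration's
    up (down) crossing of the downstream threshold, modulo the period; NaN
    when either the drive or the crossing structure is not a single pulse per
    cycle (accumulation delay is then ill-defined).
    """
    ups = [t for t, d in zip(drive.switch_times, _switch_dirs(drive)) if d == "up"]
    downs = [t for t, d in zip(drive.switch_times, _switch_dirs(drive)) if d == "down"]
    cross = cycle.crossings(threshold)
    y_ups = [t for t, d in cross if d == "up"]
    y_downs = [t for t, d in cross if d == "down"]
    if len(ups) != 1 or len(downs) != 1 or len(y_ups) != 1 or len(y_downs) != 1:
        return (math.nan, math.nan)
    onset = (y_ups[0] - ups[0]) % period
    offset = (y_downs[0] - downs[0]) % period
    return (onset, offset)


def _switch_dirs(trace: DigitalTrace) -> list[str]:
    state = trace.initial_state
    dirs = []
    for _ in trace.switch_times:
        dirs.append("up" if state == 0 else "down")
        state ^= 1
    return dirs


def downstream_duty(
    stats: StationaryStats, threshold: float, stage: GeneStage, period: float
) -> float:
    """Closed-form fraction of the cycle the intermediate activates a threshold.

    Valid when the intermediate's drive has a single on-interval per cycle.
    If the threshold lies below the cycle minimum the intermediate activates
    the downstream gene all the time (returns 1); above the maximum, never
    (returns 0).  In the interior the duty is the drive duty corrected by the
    two logarithmic delay terms,

        f_out = f_in + [δ_off − δ_on] / T,

    where δ_on is the accumulation delay from the cycle minimum toward the
    induced equilibrium and δ_off the decay delay from the maximum toward the
    basal equilibrium (roles mirrored for an inhibitor stage).  Either
    logarithm can be positive or negative, so the downstream gene can be
    active longer or shorter than the intermediate's own drive.
    """
    if stats.n_pulses_in != 1:
        raise ClosedFormInapplicableError(
            "closed form requires a single drive pulse per cycle; "
            "use the event-driven stationary path instead"
        )
    if threshold <= stats.y_min:
        return 1.0
    if threshold >= stats.y_max:
        return 0.0
    alpha = stage.degradation
    if stage.rate_sign > 0:
        d_on = onset_delay(stats.y_min, stage.eq_on, threshold, alpha)
        d_off = onset_delay(stats.y_max, stage.eq_off, threshold, alpha)
        return stats.duty_in + (d_off - d_on) / period
    # Inhibitor stage: concentration falls during the on-phase.
    d_down = onset_delay(stats.y_max, stage.eq_on, threshold, alpha)
    d_up = onset_delay(stats.y_min, stage.eq_off, threshold, alpha)
    return (1.0 - stats.duty_in) + (d_down - d_up) / period
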