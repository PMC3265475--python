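"""Oscillatory and step input signals for transcription-factor driven gene models.

The input to every regulatory motif in this package is the normalized nuclear
concentration of a transcription factor, ``X(t) ∈ [0, 1]``.  Periodic inputs are
built from an :class:`AnchorProfile` — a unit-interval shape defined by a short
list of anchor points and interpolated with a monotone shape-preserving
piecewise cubic — which is then stretched to a period ``T`` (hours) and
repeated.  The three canonical shapes (left-skewed, symmetric, right-skewed)
all spend 75% of each cycle above the value 0.1 and 25% above 0.75, so that
comparing them isolates the effect of the temporal profile from the effect of
the overall activation time.

Threshold-crossing structure is the currency of the whole package: a gene's
synthesis rate switches when the regulating signal crosses its activation
threshold, so crossing times are located exactly (monotone bracketing plus a
bracketing root-finder) rather than by sampling.  A value exactly *at* a
threshold counts as not above it; this strict-inequality convention is used
everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq

__all__ = [
    "AnchorProfile",
    "PeriodicSignal",
    "StepSignal",
    "SquareWave",
    "CANONICAL_ANCHORS",
    "CANONICAL_LABELS",
    "build_profile",
    "canonical_profile",
    "crossing_times",
    "duty_fraction",
    "make_square_wave",
]

#: Anchor points of the three canonical unit-interval profiles.  Each is a
#: sequence of (time, value) pairs on [0, 1] x [0, 1]; the points at value 0.1
#: and 0.75 sit exactly on the thresholds that define the 75% / 25% duty
#: structure shared by the three shapes.
CANONICAL_ANCHORS: dict[str, tuple[tuple[float, float], ...]] = {
    "left_skewed": (
        (0.0, 0.0),
        (0.05, 0.1),
        (0.1, 0.75),
        (0.1333, 1.0),
        (0.35, 0.75),
        (0.8, 0.1),
        (1.0, 0.0),
    ),
    "symmetric": (
        (0.0, 0.0),
        (0.125, 0.1),
        (0.375, 0.75),
        (0.5, 1.0),
        (0.625, 0.75),
        (0.875, 0.1),
        (1.0, 0.0),
    ),
    "right_skewed": (
        (0.0, 0.0),
        (0.2, 0.1),
        (0.65, 0.75),
        (0.8667, 1.0),
        (0.9, 0.75),
        (0.95, 0.1),
        (1.0, 0.0),
    ),
}

CANONICAL_LABELS: tuple[str, ...] = tuple(CANONICAL_ANCHORS)

# Root-finder tolerances for crossing refinement.  Event times feed closed-form
# propagation downstream, so they are refined essentially to machine precision.
_XTOL = 1e-15
_RTOL = 4 * np.finfo(float).eps


class SignalError(ValueError):
    """Invalid signal construction (bad anchors, duty, window...)."""


def _validate_anchors(anchors: Sequence[tuple[float, float]]) -> np.ndarray:
    arr = np.asarray(anchors, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise SignalError("anchors must be a sequence of (time, value) pairs")
    if arr.shape[0] < 3:
        raise SignalError(f"need at least 3 anchors, got {arr.shape[0]}")
    t, v = arr[:, 0], arr[:, 1]
    for i in range(len(t) - 1):
        if not t[i + 1] > t[i]:
            raise SignalError(
                f"anchor times must be strictly increasing; anchor {i + 1} "
                f"has time {t[i + 1]!r} after {t[i]!r}"
            )
    if t[0] != 0.0 or t[-1] != 1.0:
        raise SignalError("anchor times must start at 0 and end at 1")
    for i, val in enumerate(v):
        if not 0.0 <= val <= 1.0:
            raise SignalError(f"anchor {i} has value {val!r} outside [0, 1]")
    if v[0] != 0.0 or v[-1] != 0.0:
        raise SignalError("first and last anchor values must be 0")
    return arr


@dataclass(frozen=True)
class AnchorProfile:
    """A normalized one-cycle signal shape on the unit interval.

    The shape passes exactly through every anchor and is monotone between
    consecutive anchors (PCHIP interpolation), hence never leaves the local
    anchor-value interval and stays inside [0, 1].
    """

    anchors: tuple[tuple[float, float], ...]
    label: str = "custom"
    _interp: PchipInterpolator = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        arr = _validate_anchors(self.anchors)
        object.__setattr__(self, "anchors", tuple(map(tuple, arr)))
        object.__setattr__(self, "_interp", PchipInterpolator(arr[:, 0], arr[:, 1]))

    @property
    def anchor_times(self) -> np.ndarray:
        return np.array([a[0] for a in self.anchors])

    @property
    def anchor_values(self) -> np.ndarray:
        return np.array([a[1] for a in self.anchors])

    def __call__(self, u):
        """Evaluate the shape at unit-interval time(s) ``u`` in [0, 1]."""
        return self._interp(u)

    # -- threshold structure ------------------------------------------------

    def crossings(self, threshold: float) -> list[tuple[float, str]]:
        """Exact threshold crossings on [0, 1] as (time, 'up'|'down') pairs.

        The shape is monotone between consecutive anchors, so each anchor
        interval holds at most one crossing; anchors sitting exactly on the
        threshold are themselves the crossing points.  A touch that does not
        change the above/below state is not a crossing.
        """
        t, v = self.anchor_times, self.anchor_values
        out: list[tuple[float, str]] = []
        above = v > threshold  # strict: at-threshold counts as not above
        for i in range(len(t) - 1):
            if above[i] == above[i + 1]:
                continue
            direction = "up" if v[i + 1] > v[i] else "down"
            if v[i] == threshold:
                root = t[i]
            elif v[i + 1] == threshold:
                root = t[i + 1]
            else:
                root = brentq(
                    lambda u: float(self._interp(u)) - threshold,
                    t[i],
                    t[i + 1],
                    xtol=_XTOL,
                    rtol=_RTOL,
                )
            out.append((float(root), direction))
        return out

    def duty_fraction(self, threshold: float) -> float:
        """Measure of {u : shape(u) > threshold} on the unit interval."""
        events = self.crossings(threshold)
        above = bool(self.anchor_values[0] > threshold)
        total, prev = 0.0, 0.0
        for time, _direction in events:
            if above:
                total += time - prev
            above = not above
            prev = time
        if above:
            total += 1.0 - prev
        return total


def build_profile(
    anchors: Iterable[tuple[float, float]], label: str = "custom"
) -> AnchorProfile:
    """Build an evaluable unit-interval shape through the given anchors.

    Raises :class:`SignalError` with a diagnostic naming the offending anchor
    for non-increasing times, values outside [0, 1] or fewer than 3 anchors.
    """
    return AnchorProfile(tuple(tuple(a) for a in anchors), label=label)


def canonical_profile(label: str) -> AnchorProfile:
    """One of the three canonical profiles: left_skewed, symmetric, right_skewed."""
    try:
        anchors = CANONICAL_ANCHORS[label]
    except KeyError:
        raise SignalError(
            f"unknown canonical profile {label!r}; expected one of {CANONICAL_LABELS}"
        ) from None
    return AnchorProfile(anchors, label=label)


@dataclass(frozen=True)
class PeriodicSignal:
    """An anchor profile stretched to period ``period`` (hours) and repeated.

    ``signal(t) = profile(((t - phase) mod period) / period)``.
    """

    profile: AnchorProfile
    period: float
    phase: float = 0.0

    def __post_init__(self) -> None:
        if not self.period > 0:
            raise SignalError(f"period must be positive, got {self.period!r}")

    @property
    def label(self) -> str:
        return self.profile.label

    def __call__(self, t):
        u = np.mod(np.asarray(t, dtype=float) - self.phase, self.period) / self.period
        return self.profile(u)

    def crossings(
        self, threshold: float, window: tuple[float, float]
    ) -> list[tuple[float, str]]:
        """All threshold crossings in ``window``, strictly increasing in time.

        Crossings within one cycle are located on the unit profile and then
        translated, so stretching the period rescales them exactly linearly.
        """
        t0, t1 = window
        if not t1 > t0:
            raise SignalError(f"empty or inverted window {window!r}")
        base = self.profile.crossings(threshold)
        if not base:
            return []
        k0 = int(np.floor((t0 - self.phase) / self.period)) - 1
        k1 = int(np.ceil((t1 - self.phase) / self.period)) + 1
        out = []
        for k in range(k0, k1 + 1):
            for u, direction in base:
                time = self.phase + (k + u) * self.period
                if t0 <= time < t1:
                    out.append((time, direction))
        out.sort(key=lambda e: e[0])
        return out

    def duty_fraction(self, threshold: float) -> float:
        """Fraction of each period spent strictly above ``threshold``.

        Independent of the period: stretching time does not change the
        fraction of the cycle spent over any given level.
        """
        return self.profile.duty_fraction(threshold)


@dataclass(frozen=True)
class StepSignal:
    """A step stimulus: ``level`` on [on_time, off_time), 0 elsewhere."""

    on_time: float
    off_time: float
    level: float = 1.0

    def __post_init__(self) -> None:
        if not self.off_time > self.on_time:
            raise SignalError(
                f"off_time ({self.off_time!r}) must exceed on_time ({self.on_time!r})"
            )

    @property
    def label(self) -> str:
        return "step"

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        return np.where((t >= self.on_time) & (t < self.off_time), self.level, 0.0)

    def crossings(
        self, threshold: float, window: tuple[float, float]
    ) -> list[tuple[float, str]]:
        t0, t1 = window
        if not t1 > t0:
            raise SignalError(f"empty or inverted window {window!r}")
        if not 0.0 < threshold < self.level:
            return []
        out = []
        if t0 <= self.on_time < t1:
            out.append((self.on_time, "up"))
        if t0 <= self.off_time < t1:
            out.append((self.off_time, "down"))
        return out


@dataclass(frozen=True)
class SquareWave:
    """Idealized 0/1 periodic drive: 1 for the first ``duty`` of each cycle.

    Used as an analytically trivial input for exercising the closed-form
    stationary extrema against the two-exponential self-consistency solution.
    """

    duty: float
    period: float
    phase: float = 0.0
    high: float = 1.0
    low: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.duty < 1.0:
            raise SignalError(f"duty must lie in (0, 1), got {self.duty!r}")
        if not self.period > 0:
            raise SignalError(f"period must be positive, got {self.period!r}")

    @property
    def label(self) -> str:
        return "square"

    def __call__(self, t):
        u = np.mod(np.asarray(t, dtype=float) - self.phase, self.period) / self.period
        return np.where(u < self.duty, self.high, self.low)

    def crossings(
        self, threshold: float, window: tuple[float, float]
    ) -> list[tuple[float, str]]:
        t0, t1 = window
        if not t1 > t0:
            raise SignalError(f"empty or inverted window {window!r}")
        if not self.low <= threshold < self.high:
            return []
        k0 = int(np.floor((t0 - self.phase) / self.period)) - 1
        k1 = int(np.ceil((t1 - self.phase) / self.period)) + 1
        out = []
        for k in range(k0, k1 + 1):
            up = self.phase + k * self.period
            down = up + self.duty * self.period
            if t0 <= up < t1:
                out.append((up, "up"))
            if t0 <= down < t1:
                out.append((down, "down"))
        out.sort(key=lambda e: e[0])
        return out

    def duty_fraction(self, threshold: float) -> float:
        if threshold >= self.high:
            return 0.0
        if threshold >= self.low:
            return self.duty
        return 1.0


def crossing_times(signal, threshold: float, window: tuple[float, float]):
    """Ordered (time, direction) threshold crossings of any signal in a window.

    Thin dispatcher over each signal type's exact crossing structure.  A
    threshold outside the signal's range yields an empty list, not an error.
    """
    return signal.crossings(threshold, window)


def duty_fraction(signal, threshold: float) -> float:
    """Fraction of one period a periodic signal spends strictly above threshold."""
    return signal.duty_fraction(threshold)


def make_square_wave(duty: float, period: float, phase: float = 0.0) -> SquareWave:
    """A unit square wave with the given on-fraction per cycle."""
    return SquareWave(duty=duty, period=period, phase=phase)
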