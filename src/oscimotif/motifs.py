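"""Regulatory motif topologies, gene kinetics and threshold/gate logic.

A gene stage is a first-order birth–death process whose synthesis rate
switches between a basal rate ``synth_off`` and an induced rate ``synth_on``
according to a digital (0/1) drive obtained by thresholding the regulator's
concentration.  ``synth_on > synth_off`` makes the regulating edge an
activator, ``synth_on < synth_off`` an inhibitor.  Repression can equivalently
be encoded on the thresholding side with ``sense="active_below"`` (the drive
is 1 while the regulator is *below* its threshold), which is how the
incoherent-FFL repressor arm is written.

Supported topologies are feed-forward only (the input oscillation is given,
not generated): direct regulation X→Y, the two-step cascade X→Y→Z, and the
eight feed-forward loops X→Y, X→Z, Y→Z whose direct and indirect conditions
are combined by an AND or OR gate.  FFL types follow the published numbering
convention: types 1–4 are the coherent loops C1–C4 (type 1 = all activators)
and types 5–8 the incoherent loops I1–I4.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "GeneStage",
    "RegulatoryEdge",
    "MotifConfig",
    "DigitalTrace",
    "MotifError",
    "FFL_SIGN_TABLE",
    "FFL_NAMES",
    "digitize",
    "gate_combine",
    "synthesis_rate_trace",
]

Sense = Literal["active_above", "active_below"]

# Absolute slop for merging coincident switch events (hours).
_TIE_TOL = 1e-12


class MotifError(ValueError):
    """Invalid motif configuration or trace algebra."""


@dataclass(frozen=True)
class GeneStage:
    """One gene's kinetics: switchable synthesis plus linear degradation.

    Rates are concentration/hour; ``degradation`` (1/hour) must be strictly
    positive so both equilibria ``synth_off/degradation`` and
    ``synth_on/degradation`` are finite.
    """

    name: str
    synth_off: float
    synth_on: float
    degradation: float

    def __post_init__(self) -> None:
        if self.synth_off < 0 or self.synth_on < 0:
            raise MotifError(f"gene {self.name!r}: synthesis rates must be >= 0")
        if not self.degradation > 0:
            raise MotifError(
                f"gene {self.name!r}: degradation must be > 0, "
                f"got {self.degradation!r}"
            )

    @property
    def eq_off(self) -> float:
        """Equilibrium concentration under the basal synthesis rate."""
        return self.synth_off / self.degradation

    @property
    def eq_on(self) -> float:
        """Equilibrium concentration under the induced synthesis rate."""
        return self.synth_on / self.degradation

    @property
    def rate_sign(self) -> int:
        """+1 if induction raises synthesis (activator target), -1 if it lowers it."""
        if self.synth_on == self.synth_off:
            raise MotifError(f"gene {self.name!r}: synth_on equals synth_off")
        return 1 if self.synth_on > self.synth_off else -1


@dataclass(frozen=True)
class RegulatoryEdge:
    """A thresholded interaction: source concentration gates target synthesis."""

    source: str
    target: str
    threshold: float
    sense: Sense = "active_above"

    def __post_init__(self) -> None:
        if not self.threshold > 0:
            raise MotifError(
                f"edge {self.source}->{self.target}: threshold must be > 0"
            )
        if self.sense not in ("active_above", "active_below"):
            raise MotifError(
                f"edge {self.source}->{self.target}: unknown sense {self.sense!r}"
            )

    @property
    def sense_sign(self) -> int:
        return 1 if self.sense == "active_above" else -1


class DigitalTrace:
    """A 0/1 piecewise-constant function of time on a bounded window.

    Defined by an initial state and strictly increasing switch times at which
    the state flips; the trace is right-continuous (the new state holds *at*
    the switch instant).  This is the "digital signal" a thresholded analog
    concentration is converted into, and the algebra of logic gates operates
    directly on switch times — no sampling.
    """

    __slots__ = ("window", "switch_times", "initial_state")

    def __init__(
        self,
        window: tuple[float, float],
        switch_times: Sequence[float] = (),
        initial_state: int = 0,
    ) -> None:
        t0, t1 = float(window[0]), float(window[1])
        if not t1 > t0:
            raise MotifError(f"empty or inverted window {window!r}")
        times = np.asarray(switch_times, dtype=float)
        if times.size and not np.all(np.diff(times) > 0):
            raise MotifError("switch times must be strictly increasing")
        if times.size and (times[0] < t0 or times[-1] > t1):
            raise MotifError("switch times must lie inside the window")
        self.window = (t0, t1)
        self.switch_times = times
        self.initial_state = int(bool(initial_state))

    # -- queries ------------------------------------------------------------

    def value(self, t):
        """State at time(s) t (right-continuous at switches)."""
        idx = np.searchsorted(self.switch_times, np.asarray(t, dtype=float), "right")
        return (self.initial_state + idx) % 2

    def __call__(self, t):
        return self.value(t)

    def states(self) -> list[tuple[float, float, int]]:
        """The trace as ordered (start, end, state) intervals covering the window."""
        t0, t1 = self.window
        edges = [t0, *self.switch_times.tolist(), t1]
        state = self.initial_state
        out = []
        for a, b in zip(edges[:-1], edges[1:]):
            if b > a:
                out.append((a, b, state))
            state ^= 1
        return out

    def intervals(self, state: int = 1) -> list[tuple[float, float]]:
        """Maximal intervals on which the trace equals ``state``."""
        return [(a, b) for a, b, s in self.states() if s == state]

    def measure(self, state: int = 1) -> float:
        """Total time spent in ``state`` within the window."""
        return float(sum(b - a for a, b in self.intervals(state)))

    def final_state(self) -> int:
        return (self.initial_state + len(self.switch_times)) % 2

    def complement(self) -> "DigitalTrace":
        return DigitalTrace(self.window, self.switch_times, 1 - self.initial_state)

    def n_pulses(self, state: int = 1) -> int:
        return len(self.intervals(state))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"DigitalTrace(window={self.window}, initial={self.initial_state}, "
            f"switches={self.switch_times.tolist()})"
        )


def digitize(signal, edge: RegulatoryEdge, window: tuple[float, float]) -> DigitalTrace:
    """Convert an analog trace into the 0/1 drive seen through ``edge``.

    State 1 exactly where the signal is strictly above the edge threshold
    (``active_above``) or strictly below-or-at it (``active_below``); switch
    times are the exact threshold crossings.  Works for any object exposing
    ``crossings(threshold, window)`` and point evaluation — input signals and
    piecewise-exponential trajectories alike.
    """
    t0, t1 = window
    events = signal.crossings(edge.threshold, window)
    times = _dedupe_touches([t for t, _ in events])
    # An event exactly at the window edge just sets the initial state.
    times = [t for t in times if t > t0 + _TIE_TOL]
    # The sign of (signal - threshold) is constant between crossings, so the
    # state on the first interval is read off at its midpoint — robust to the
    # signal sitting exactly at the threshold at t0.
    probe = 0.5 * (t0 + (times[0] if times else t1))
    above0 = float(np.asarray(signal(probe))) > edge.threshold
    state0 = above0 if edge.sense == "active_above" else not above0
    return DigitalTrace(window, times, int(state0))


def _dedupe_touches(times: list[float]) -> list[float]:
    """Drop coincident event pairs (a touch without a state change)."""
    out: list[float] = []
    for t in times:
        if out and abs(t - out[-1]) <= _TIE_TOL:
            out.pop()
        else:
            out.append(t)
    return out


def gate_combine(gate: str, a: DigitalTrace, b: DigitalTrace) -> DigitalTrace:
    """Pointwise boolean AND/OR of two digital traces on a common window.

    Exact on switch-time algebra: the result's switch times are a merge of the
    inputs' switch times with redundant events removed and coincident events
    merged.
    """
    if gate not in ("AND", "OR"):
        raise MotifError(f"unknown gate {gate!r}; expected 'AND' or 'OR'")
    if (
        abs(a.window[0] - b.window[0]) > _TIE_TOL
        or abs(a.window[1] - b.window[1]) > _TIE_TOL
    ):
        raise MotifError(f"mismatched windows {a.window!r} and {b.window!r}")
    op = (lambda x, y: x & y) if gate == "AND" else (lambda x, y: x | y)

    merged: list[float] = []
    for t in sorted(np.concatenate([a.switch_times, b.switch_times]).tolist()):
        if not merged or t - merged[-1] > _TIE_TOL:
            merged.append(t)

    sa, sb = a.initial_state, b.initial_state
    state = op(sa, sb)
    initial = state
    switches: list[float] = []
    for t in merged:
        ia = bisect.bisect_right(a.switch_times.tolist(), t + _TIE_TOL / 2)
        ib = bisect.bisect_right(b.switch_times.tolist(), t + _TIE_TOL / 2)
        new = op((a.initial_state + ia) % 2, (b.initial_state + ib) % 2)
        if new != state:
            switches.append(t)
            state = new
    return DigitalTrace(a.window, switches, initial)


def synthesis_rate_trace(
    stage: GeneStage, drive: DigitalTrace
) -> list[tuple[float, float, float]]:
    """The piecewise-constant synthesis rate (start, end, rate) under a drive."""
    return [
        (a, b, stage.synth_on if s else stage.synth_off) for a, b, s in drive.states()
    ]


# -- FFL sign conventions ----------------------------------------------------

#: type -> (sign X→Y, sign Y→Z, sign X→Z); +1 activation, -1 repression.
#: Types 1–4 are coherent (C1–C4), 5–8 incoherent (I1–I4); type 1 (C1) is the
#: all-activator loop and type 5 (I1) the classic activator/activator/repressor
#: pulse generator.
FFL_SIGN_TABLE: dict[int, tuple[int, int, int]] = {
    1: (1, 1, 1),
    2: (-1, -1, 1),
    3: (1, -1, -1),
    4: (-1, 1, -1),
    5: (1, -1, 1),
    6: (-1, -1, -1),
    7: (1, 1, -1),
    8: (-1, 1, 1),
}

FFL_NAMES: dict[int, str] = {
    1: "CFFL-1", 2: "CFFL-2", 3: "CFFL-3", 4: "CFFL-4",
    5: "IFFL-1", 6: "IFFL-2", 7: "IFFL-3", 8: "IFFL-4",
}

_TOPOLOGY_EDGES = {
    "direct": {("X", "Y")},
    "two_step": {("X", "Y"), ("Y", "Z")},
    "ffl": {("X", "Y"), ("X", "Z"), ("Y", "Z")},
}


@dataclass(frozen=True)
class MotifConfig:
    """A validated motif: topology, gate logic, gene kinetics and edges.

    The edge set must match the declared topology exactly (cycles are
    impossible by construction — only feed-forward edge sets are accepted).
    For FFLs the coherence class derived from edge senses and rate orderings
    must match the declared ``ffl_type``.
    """

    topology: Literal["direct", "two_step", "ffl"]
    stages: dict[str, GeneStage]
    edges: tuple[RegulatoryEdge, ...]
    ffl_type: int | None = None
    gate: Literal["AND", "OR"] | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.topology not in _TOPOLOGY_EDGES:
            raise MotifError(f"unknown topology {self.topology!r}")
        object.__setattr__(self, "edges", tuple(self.edges))
        got = {(e.source, e.target) for e in self.edges}
        want = _TOPOLOGY_EDGES[self.topology]
        if got != want:
            raise MotifError(
                f"topology {self.topology!r} requires edges {sorted(want)}, "
                f"got {sorted(got)} (cyclic or malformed edge sets are rejected)"
            )
        if len(got) != len(self.edges):
            raise MotifError("duplicate edges")
        genes = {"direct": {"Y"}, "two_step": {"Y", "Z"}, "ffl": {"Y", "Z"}}[
            self.topology
        ]
        if set(self.stages) != genes:
            raise MotifError(
                f"topology {self.topology!r} requires gene stages {sorted(genes)}, "
                f"got {sorted(self.stages)}"
            )
        for name, stage in self.stages.items():
            if stage.name != name:
                raise MotifError(
                    f"stage key {name!r} does not match stage name {stage.name!r}"
                )
        if self.topology == "ffl":
            if self.gate not in ("AND", "OR"):
                raise MotifError("FFL configs must declare gate 'AND' or 'OR'")
            if self.ffl_type not in FFL_SIGN_TABLE:
                raise MotifError(
                    f"ffl_type must be one of 1..8, got {self.ffl_type!r}"
                )
            derived = self.derived_signs()
            if derived != FFL_SIGN_TABLE[self.ffl_type]:
                raise MotifError(
                    f"declared ffl_type {self.ffl_type} "
                    f"({FFL_NAMES[self.ffl_type]}) implies signs "
                    f"{FFL_SIGN_TABLE[self.ffl_type]} (X→Y, Y→Z, X→Z) but the "
                    f"edges/rates imply {derived}"
                )

    # -- helpers ------------------------------------------------------------

    def edge(self, source: str, target: str) -> RegulatoryEdge:
        for e in self.edges:
            if e.source == source and e.target == target:
                return e
        raise MotifError(f"no edge {source}->{target} in this motif")

    def gene_order(self) -> tuple[str, ...]:
        """Genes in cascade (topological) order."""
        return ("Y",) if self.topology == "direct" else ("Y", "Z")

    def derived_signs(self) -> tuple[int, int, int]:
        """Net signs (X→Y, Y→Z, X→Z) from edge senses and rate orderings.

        The X→Y sign combines the digitizing sense with the Y rate ordering.
        For the gate edges into Z the shared Z rate ordering multiplies both
        branches, which leaves the coherence class unchanged.
        """
        if self.topology != "ffl":
            raise MotifError("derived_signs is defined for FFL topologies only")
        z_sign = self.stages["Z"].rate_sign
        s_xy = self.edge("X", "Y").sense_sign * self.stages["Y"].rate_sign
        s_yz = self.edge("Y", "Z").sense_sign * z_sign
        s_xz = self.edge("X", "Z").sense_sign * z_sign
        return (s_xy, s_yz, s_xz)

    @property
    def is_coherent(self) -> bool:
        s_xy, s_yz, s_xz = self.derived_signs()
        return s_xy * s_yz == s_xz

    @property
    def motif_name(self) -> str:
        if self.topology == "ffl":
            return FFL_NAMES[self.ffl_type]  # type: ignore[index]
        return self.topology
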