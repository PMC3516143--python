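"""Piecewise-constant stimulus designs (control vector parameterization).

A design is a set of amplitudes ``w_1..w_Nw`` and segment durations
``dt_1..dt_{Nw-1}`` over an experimental horizon ``T``.  The stimulus is
right-continuous: segment ``i`` holds amplitude ``w_i`` from the cumulative
start time of the segment up to (but excluding) its end.  If the cumulative
durations end before ``T`` the final amplitude extends to ``T``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class DesignSpace:
    """Feasible region for a stimulus design.

    Parameters
    ----------
    u_max : upper amplitude bound (lower bound is 0, stimulus units).
    horizon : total experiment time ``T`` (time units of the model).
    n_segments : number of piecewise-constant segments ``Nw``.
    dt_min : minimum segment duration (dwell-time constraint).
    """

    u_max: float
    horizon: float
    n_segments: int
    dt_min: float = 0.0

    def __post_init__(self) -> None:
        if self.n_segments < 1:
            raise ValueError("n_segments must be >= 1")
        if self.u_max < 0 or self.horizon <= 0 or self.dt_min < 0:
            raise ValueError("u_max >= 0, horizon > 0, dt_min >= 0 required")
        if self.dt_min * (self.n_segments - 1) > self.horizon:
            raise ValueError(
                f"infeasible design space: dt_min * (Nw-1) = "
                f"{self.dt_min * (self.n_segments - 1):g} exceeds horizon {self.horizon:g}"
            )

    @property
    def n_design_vars(self) -> int:
        """Length of the flat design vector: Nw amplitudes + (Nw-1) durations."""
        return 2 * self.n_segments - 1


def apply_dwell_constraint(space: DesignSpace, tau_min: float) -> DesignSpace:
    """Raise the minimum segment duration to ``tau_min`` (actuator dwell time).

    Raises ``ValueError`` if the tightened space is infeasible
    (``tau_min * (Nw - 1) > T``).
    """
    if tau_min < 0:
        raise ValueError("tau_min must be >= 0")
    dt_min = max(space.dt_min, tau_min)
    return DesignSpace(space.u_max, space.horizon, space.n_segments, dt_min)


@dataclass(frozen=True)
class StimulusDesign:
    """A concrete piecewise-constant stimulus u(t).

    ``amplitudes`` has length Nw; ``durations`` has length Nw-1 (the last
    segment runs to the horizon).  Breakpoints are the cumulative duration
    sums; evaluation is right-continuous.
    """

    amplitudes: np.ndarray
    durations: np.ndarray
    horizon: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "amplitudes", np.atleast_1d(np.asarray(self.amplitudes, float)))
        object.__setattr__(self, "durations", np.atleast_1d(np.asarray(self.durations, float))
                           if np.size(self.durations) else np.empty(0))
        if self.durations.size != self.amplitudes.size - 1:
            raise ValueError("need exactly Nw - 1 durations for Nw amplitudes")
        if np.any(self.durations < 0):
            raise ValueError("durations must be nonnegative")
        if self.horizon <= 0:
            raise ValueError("horizon must be positive")

    @property
    def breakpoints(self) -> np.ndarray:
        """Interior segment boundaries (cumulative durations), clipped to the horizon."""
        bp = np.cumsum(self.durations)
        return bp[bp < self.horizon]

    def segment_edges(self) -> np.ndarray:
        """All segment edges [0, b_1, ..., T] used for restart integration."""
        return np.concatenate(([0.0], self.breakpoints, [self.horizon]))

    def segment_amplitudes(self) -> np.ndarray:
        """Amplitude in force on each interval of ``segment_edges``."""
        return self.amplitudes[: self.breakpoints.size + 1]

    def value_at(self, t: float | np.ndarray) -> np.ndarray | float:
        """Evaluate u(t); right-continuous, final amplitude held to the horizon."""
        bp = self.breakpoints
        idx = np.searchsorted(bp, np.asarray(t, float), side="right")
        amps = self.segment_amplitudes()
        return amps[np.minimum(idx, amps.size - 1)]


def constant_stimulus(level: float, horizon: float) -> StimulusDesign:
    """A single-segment constant stimulus over the horizon."""
    return StimulusDesign(np.array([level]), np.empty(0), horizon)


@dataclass
class ClipReport:
    """Distance by which an encoded design vector violated its bounds."""

    amplitude_clip: float = 0.0
    duration_clip: float = 0.0

    @property
    def total(self) -> float:
        return self.amplitude_clip + self.duration_clip


def encode_design(design: StimulusDesign) -> np.ndarray:
    """Flatten a design to [amplitudes..., durations...]."""
    return np.concatenate([design.amplitudes, design.durations])


def decode_design(
    vector: np.ndarray, space: DesignSpace
) -> tuple[StimulusDesign, ClipReport]:
    """Rebuild a design from a flat vector, clipping out-of-bound entries.

    Returns the (clipped, feasible) design plus a :class:`ClipReport` with the
    Euclidean clip distances, which the optimization objective turns into a
    penalty so the search is steered back into bounds.
    """
    vector = np.asarray(vector, float)
    if vector.size != space.n_design_vars:
        raise ValueError(
            f"design vector length {vector.size} != {space.n_design_vars} "
            f"(2*Nw - 1 for Nw = {space.n_segments})"
        )
    nw = space.n_segments
    amps_raw, durs_raw = vector[:nw], vector[nw:]
    amps = np.clip(amps_raw, 0.0, space.u_max)
    durs = np.clip(durs_raw, space.dt_min, space.horizon)
    report = ClipReport(
        amplitude_clip=float(np.linalg.norm(amps - amps_raw)),
        duration_clip=float(np.linalg.norm(durs - durs_raw)),
    )
    return StimulusDesign(amps, durs, space.horizon), report
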