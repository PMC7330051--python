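"""The stochastic rule-based twitching cycle.

Each twitcher cycles through REST -> EXTENSION -> RETRACTION:

* A resting twitcher has probability ``rest_exit_prob`` (default 10%)
  per unit time tau of beginning pilus extension; the draw happens on
  tau boundaries only, so rest durations are geometric with mean
  ``tau / rest_exit_prob``.
* Extension lasts exactly ``extension_duration`` (default 10 tau); at
  its end the pilus anchor is placed instantaneously a distance ``L_0``
  from the head, rotated by a uniform random angle within the adhesion
  cone ``[-pi/4, pi/4]`` about the current polar axis.  The anchor is
  fixed in the lab frame.
* Retraction ends at the first of: ARRIVE (head-anchor distance below
  ``L_R``), SNAP (distance above ``L_S``), or EXHAUST (retraction older
  than ``t_M``); the checks run every integration step in that priority
  order.  The twitcher then drops the anchor and rests, with no memory
  of the previous pilus.

Boundary updates (rest exits, anchor placements) are applied here in
Python between unit-time kernel calls, with random draws ordered by
twitcher index for reproducibility; the per-step termination checks
live in the integrator kernel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kinematics import polar_vectors
from .params import Phase, SimulationParams

__all__ = ["MotilityEvent", "EVENT_KINDS", "boundary_update", "place_anchor"]

#: Event kind names, indexed by the integer codes used in the kernels.
EVENT_KINDS = ("REST_EXIT", "ANCHOR_PLACED", "ARRIVE", "SNAP", "EXHAUST")


@dataclass(frozen=True)
class MotilityEvent:
    """A single transition of one twitcher's motility cycle."""

    twitcher: int
    kind: str
    time: float

    def __post_init__(self):
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")


def place_anchor(
    head_pos: np.ndarray,
    polar: np.ndarray,
    params: SimulationParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw an adhesion point ``L_0`` from the head within the cone.

    The cone is symmetric about the polar (tail-to-head) axis at the
    instant of adhesion; the anchor is wrapped into the box.
    """
    alpha = rng.uniform(-params.cone_half_angle, params.cone_half_angle)
    ca, sa = np.cos(alpha), np.sin(alpha)
    d = np.array(
        [ca * polar[0] - sa * polar[1], sa * polar[0] + ca * polar[1]]
    )
    anchor = np.asarray(head_pos, float) + params.pilus_L0 * d
    return np.mod(anchor, params.box_L)


def boundary_update(
    phase: np.ndarray,
    phase_entry: np.ndarray,
    anchor: np.ndarray,
    retr_clock: np.ndarray,
    pos: np.ndarray,
    pos_unwrapped: np.ndarray,
    t_now: float,
    params: SimulationParams,
    rng: np.random.Generator,
) -> list[MotilityEvent]:
    """Apply the tau-boundary motility rules in place.

    Extension completions are processed before rest-exit draws, so a
    twitcher leaving rest at this boundary starts its 10-tau extension
    now and adheres 10 boundaries later.  Returns the events generated.
    """
    n = phase.shape[0]
    events: list[MotilityEvent] = []
    pol = None
    for g in range(n):
        if phase[g] == int(Phase.EXTENSION) and (
            t_now - phase_entry[g] >= params.extension_duration - 1e-9
        ):
            if pol is None:
                pol = polar_vectors(pos_unwrapped)
            head = pos[4 * g + 3]
            anchor[g] = place_anchor(head, pol[g], params, rng)
            phase[g] = int(Phase.RETRACTION)
            phase_entry[g] = t_now
            retr_clock[g] = 0
            events.append(MotilityEvent(g, "ANCHOR_PLACED", t_now))
    for g in range(n):
        if phase[g] == int(Phase.REST):
            if rng.random() < params.rest_exit_prob:
                phase[g] = int(Phase.EXTENSION)
                phase_entry[g] = t_now
                events.append(MotilityEvent(g, "REST_EXIT", t_now))
    return events
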