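"""Model parameters, unit conventions and coverage geometry.

All quantities are expressed in reduced Lennard-Jones units: length in the
sphere diameter ``sigma``, mass in the sphere mass ``m``, energy in the WCA
well depth ``epsilon`` and time in ``tau = sqrt(m sigma^2 / epsilon)``.
A twitcher is a stiff chain of four spheres of total body length
``L_body = 4 sigma``; its footprint is a rod of length ``L_body`` with
circular end caps of diameter ``sigma``.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, fields

__all__ = [
    "Phase",
    "SimulationParams",
    "SPHERES_PER_TWITCHER",
    "twitcher_area",
    "coverage_fraction",
    "twitcher_count_for_coverage",
    "critical_coverage",
]

#: Number of integrated spheres composing one twitcher body.
SPHERES_PER_TWITCHER = 4


class Phase(enum.IntEnum):
    """Motility-cycle phase of a single twitcher.

    The cycle always proceeds REST -> EXTENSION -> RETRACTION -> REST.
    A twitcher is self-motile only while retracting its pilus.
    """

    REST = 0
    EXTENSION = 1
    RETRACTION = 2

    @property
    def letter(self) -> str:
        return {Phase.REST: "R", Phase.EXTENSION: "E", Phase.RETRACTION: "T"}[self]

    @classmethod
    def from_letter(cls, s: str) -> "Phase":
        try:
            return {"R": cls.REST, "E": cls.EXTENSION, "T": cls.RETRACTION}[s]
        except KeyError:
            raise ValueError(f"unknown phase letter {s!r}") from None


@dataclass
class SimulationParams:
    """All model constants, with the defaults of the twitcher model.

    Parameters
    ----------
    sphere_size:
        Sphere diameter ``sigma`` (length unit).
    sphere_mass:
        Sphere mass ``m`` (mass unit).
    energy_scale:
        WCA well depth ``epsilon`` (energy unit).
    temperature:
        Thermal energy ``k_B T`` of the Langevin bath.  Bacteria are
        dominated by biological (motility) noise, so this is nearly zero;
        the thermal term is implemented but dynamically negligible.
    friction:
        Langevin drag coefficient ``zeta`` per sphere (mass/time).
    dt:
        Integration step (time).  ``dt * steps_per_tau`` must equal one
        unit time ``tau``.
    total_steps:
        Number of integration steps of a run; frames are sampled every
        ``steps_per_tau`` steps.
    box_L:
        Edge of the square periodic simulation box.
    wca_cutoff:
        Cut-off ``r_c = 2^(1/6) sigma`` of the purely repulsive WCA pair
        potential (acts between *all* sphere pairs, bonded ones included).
    fene_R0, fene_kF:
        Maximum extension and spring constant of the FENE bonds joining
        consecutive spheres.
    angle_kH, angle_theta0:
        Harmonic three-body stiffness keeping the chain straight
        (``theta_0 = pi``).
    body_length:
        Nominal body length ``L_body`` used for coverage geometry.
    pilus_kP:
        Magnitude of the constant pilus retraction force on the head.
    pilus_r0:
        Cut-off distance below which the pilus force vanishes.
    pilus_L0:
        Distance from the head at which the pilus anchor is placed.
    arrive_LR, snap_LS, exhaust_tM:
        Retraction termination thresholds: arrival distance, snap
        distance, and maximum adhesion time (in tau).
    rest_exit_prob:
        Probability per tau for a resting twitcher to begin extending.
    extension_duration:
        Fixed duration of the pilus extension phase (tau).
    cone_half_angle:
        Half-angle of the adhesion cone about the body axis.
    n_twitchers:
        Number of twitchers ``N`` in the box.
    seed:
        Seed for all pseudo-randomness of a run.
    """

    sphere_size: float = 1.0
    sphere_mass: float = 1.0
    energy_scale: float = 1.0
    temperature: float = 2e-7
    friction: float = 1.0
    dt: float = 0.01
    steps_per_tau: int = 100
    total_steps: int = 10**8
    box_L: float = 100.0
    wca_cutoff: float = 2.0 ** (1.0 / 6.0)
    fene_R0: float = 1.5
    fene_kF: float = 50.0
    angle_kH: float = 33.0
    angle_theta0: float = math.pi
    body_length: float = 4.0
    pilus_kP: float = 1.0
    pilus_r0: float = 0.2
    pilus_L0: float = 2.4
    arrive_LR: float = 0.2
    snap_LS: float = 3.0
    exhaust_tM: float = 70.0
    rest_exit_prob: float = 0.1
    extension_duration: float = 10.0
    cone_half_angle: float = math.pi / 4.0
    n_twitchers: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        for name in (
            "sphere_size", "box_L", "wca_cutoff", "fene_R0", "body_length",
            "pilus_L0", "arrive_LR", "snap_LS", "pilus_r0",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 < self.rest_exit_prob <= 1.0):
            raise ValueError("rest_exit_prob must lie in (0, 1]")
        if not (self.arrive_LR < self.pilus_L0 < self.snap_LS):
            raise ValueError("require arrive_LR < pilus_L0 < snap_LS")
        if self.dt <= 0 or self.steps_per_tau <= 0:
            raise ValueError("dt and steps_per_tau must be positive")
        if not math.isclose(self.dt * self.steps_per_tau, self.tau, rel_tol=1e-9):
            raise ValueError("dt * steps_per_tau must equal one unit time tau")
        if self.n_twitchers < 0:
            raise ValueError("n_twitchers must be non-negative")
        if self.total_steps < 0:
            raise ValueError("total_steps must be non-negative")

    # ------------------------------------------------------------------
    @property
    def tau(self) -> float:
        """Unit time ``tau = sqrt(m sigma^2 / epsilon)``."""
        return math.sqrt(
            self.sphere_mass * self.sphere_size**2 / self.energy_scale
        )

    @property
    def n_spheres(self) -> int:
        return SPHERES_PER_TWITCHER * self.n_twitchers

    @property
    def n_tau(self) -> int:
        """Number of whole unit-time intervals in the run."""
        return self.total_steps // self.steps_per_tau

    @property
    def box_area(self) -> float:
        return self.box_L**2

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationParams":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**d)

    def replace(self, **kw) -> "SimulationParams":
        d = self.to_dict()
        d.update(kw)
        return SimulationParams.from_dict(d)


# ----------------------------------------------------------------------
# Coverage geometry
# ----------------------------------------------------------------------

def twitcher_area(params: SimulationParams | None = None) -> float:
    """Footprint area of one twitcher.

    The body is a rod of length ``L_body`` and width ``sigma`` with
    circular end caps: ``A = (L_body - sigma) sigma + pi (sigma/2)^2``.
    With the defaults this is ``3 + pi/4 = 3.7854`` (to four decimals).
    """
    p = params or SimulationParams(total_steps=0)
    s = p.sphere_size
    return (p.body_length - s) * s + math.pi * (s / 2.0) ** 2


def coverage_fraction(n: int, params: SimulationParams | None = None) -> float:
    """Surface coverage ``phi = N A_twitch / A_box`` of ``n`` twitchers."""
    if n < 0:
        raise ValueError("twitcher count must be non-negative")
    p = params or SimulationParams(total_steps=0)
    return n * twitcher_area(p) / p.box_area


def twitcher_count_for_coverage(
    phi: float, params: SimulationParams | None = None
) -> int:
    """Twitcher count whose coverage is closest to ``phi``."""
    if phi < 0:
        raise ValueError("coverage must be non-negative")
    p = params or SimulationParams(total_steps=0)
    return round(phi * p.box_area / twitcher_area(p))


def critical_coverage(
    params: SimulationParams | None = None, a_twitch: float | None = None
) -> float:
    """Critical coverage ``phi* = A_twitch / (pi (L_body/2)^2)``.

    This is the coverage at which the mean area available per twitcher
    equals the disc a rotating body sweeps; above it, excluded-volume
    collisions become continuous rather than episodic and collective
    dynamics emerge.  Defaults give ``phi* ~= 0.3``.
    """
    p = params or SimulationParams(total_steps=0)
    a = twitcher_area(p) if a_twitch is None else a_twitch
    return a / (math.pi * (p.body_length / 2.0) ** 2)
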