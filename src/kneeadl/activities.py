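"""Activity classes and their kinematic profiles.

Eight activities of daily living are simulated.  Each activity is
described by an :class:`ActivityProfile`: a flexion range of motion
(ROM), a cycle rate, a waveform family, and a few simulator-specific
parameters (how much of the flexion is expressed by the femoral
segment, and the amplitude of footstrike transients).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

#: Canonical class ordering used everywhere (files, model outputs, reports).
ACTIVITY_LABELS: tuple[str, ...] = (
    "jogging",
    "knee_bending",
    "sitting_down",
    "standing_up",
    "walking",
    "standing_still",
    "stair_ascent",
    "stair_descent",
)


class Waveform(str, Enum):
    """Flexion-angle waveform family for one activity."""

    PERIODIC = "periodic"            # continuous raised-cosine oscillation
    HALF_CYCLE_DOWN = "half_cycle_down"  # single ramp rom_min -> rom_max
    HALF_CYCLE_UP = "half_cycle_up"      # single ramp rom_max -> rom_min
    QUASI_STATIC = "quasi_static"        # low-amplitude sway


#: Activities streamed as long multi-cycle recordings.
CONTINUOUS_ACTIVITIES = frozenset(
    {"jogging", "walking", "standing_still", "stair_ascent", "stair_descent"}
)

#: Activities recorded one repetition at a time (neutral position to end).
TRANSITIONAL_ACTIVITIES = frozenset({"sitting_down", "standing_up", "knee_bending"})


@dataclass(frozen=True)
class ActivityProfile:
    """Kinematic parameters driving the simulator for one activity.

    Parameters
    ----------
    name
        One of :data:`ACTIVITY_LABELS`.
    rom_min, rom_max
        Flexion range of motion bounds in degrees.
    rate
        Cycle frequency in Hz.
    waveform
        Waveform family; see :class:`Waveform`.
    femoral_share
        Fraction of the knee flexion expressed as femoral-segment
        rotation in the world frame, in ``[0, 1]``.
    impact_amplitude
        Peak amplitude (m/s^2) of decaying footstrike transients;
        zero for everything but jogging.
    thigh_ramp
        Peak thigh-inclination (degrees) added to the femoral segment,
        ramped synchronously with the flexion ramp.  Non-zero for the
        sit/stand transitions.
    """

    name: str
    rom_min: float
    rom_max: float
    rate: float
    waveform: Waveform
    femoral_share: float = 0.35
    impact_amplitude: float = 0.0
    thigh_ramp: float = 0.0

    def __post_init__(self) -> None:
        if self.name not in ACTIVITY_LABELS:
            raise ValueError(
                f"unknown activity {self.name!r}; expected one of {ACTIVITY_LABELS}"
            )
        if not self.rom_min < self.rom_max:
            raise ValueError("rom_min must be < rom_max")
        if not 0.0 < self.rate <= 2.0:
            raise ValueError("rate must be in (0, 2] Hz")
        if not 0.0 <= self.femoral_share <= 1.0:
            raise ValueError("femoral_share must be in [0, 1]")

    @property
    def rom_span(self) -> float:
        return self.rom_max - self.rom_min

    @property
    def period(self) -> float:
        """Full cycle duration in seconds."""
        return 1.0 / self.rate


def default_profiles() -> dict[str, ActivityProfile]:
    """The eight default activity profiles.

    ROM and rate follow the simulated-movement table; waveform family,
    femoral share, thigh ramps and impact amplitudes are simulator
    design choices that make the femoral and tibial channels carry
    class-discriminating structure.
    """
    profiles = [
        ActivityProfile("walking", 7, 62, 0.94, Waveform.PERIODIC,
                        femoral_share=0.35),
        ActivityProfile("jogging", 7, 62, 1.4, Waveform.PERIODIC,
                        femoral_share=0.35, impact_amplitude=6.0),
        ActivityProfile("stair_ascent", 13, 94, 0.56, Waveform.PERIODIC,
                        femoral_share=0.55),
        ActivityProfile("stair_descent", 14, 98, 0.58, Waveform.PERIODIC,
                        femoral_share=0.15),
        ActivityProfile("sitting_down", 6, 94, 0.16, Waveform.HALF_CYCLE_DOWN,
                        femoral_share=0.30, thigh_ramp=90.0),
        ActivityProfile("standing_up", 6, 94, 0.16, Waveform.HALF_CYCLE_UP,
                        femoral_share=0.30, thigh_ramp=90.0),
        ActivityProfile("knee_bending", 4, 98, 0.13, Waveform.PERIODIC,
                        femoral_share=0.10),
        ActivityProfile("standing_still", 7, 13, 0.1, Waveform.QUASI_STATIC,
                        femoral_share=0.50),
    ]
    return {p.name: p for p in profiles}
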