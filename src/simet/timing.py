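"""Closed-form treatment delivery-time model for step-and-shoot scanning.

The total delivery time decomposes into four terms:

* irradiation: the arm dwells at each beam position until the prescription
  dose D_P is delivered, so ``T_irr = (D_P / dose_rate) · N_B`` — note beam
  *positions*, not spots: a composited pair splits one position's dose, not
  doubles it;
* arm motion: total scan-path length over the arm speed, ``T_move = L / V_S``;
* energy switching: ``T_E · (N_E − 1)`` for N_E occupied energy groups
  delivered energy-by-energy;
* beam gating: the beam stops and restarts around every spot,
  ``T_onoff = 2 · T_O · N_S``.

Defaults describe the reference machine: 15 Gy/s dose rate, 50 mm/s robotic
arm, 2 s energy switch, 20 ms beam stop/restart.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

from .sequencer import ScanPlan

__all__ = [
    "MachineParams",
    "PlanSummary",
    "TimeBreakdown",
    "irradiation_time",
    "move_time",
    "energy_switch_time",
    "onoff_time",
    "delivery_time",
]


@dataclass(frozen=True)
class MachineParams:
    """Delivery hardware characteristics.

    dose_rate in Gy/s, arm_speed in mm/s, energy_switch_time and
    beam_onoff_time in s; all strictly positive.
    """

    dose_rate: float = 15.0
    arm_speed: float = 50.0
    energy_switch_time: float = 2.0
    beam_onoff_time: float = 0.020

    def __post_init__(self) -> None:
        if min(
            self.dose_rate, self.arm_speed, self.energy_switch_time, self.beam_onoff_time
        ) <= 0:
            raise ValueError("all machine parameters must be strictly positive")

    def to_json(self, path: str | Path) -> None:
        doc = {
            "dose_rate_Gy_per_s": self.dose_rate,
            "arm_speed_mm_per_s": self.arm_speed,
            "energy_switch_s": self.energy_switch_time,
            "beam_onoff_s": self.beam_onoff_time,
        }
        Path(path).write_text(json.dumps(doc, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "MachineParams":
        doc = json.loads(Path(path).read_text())
        return cls(
            dose_rate=doc["dose_rate_Gy_per_s"],
            arm_speed=doc["arm_speed_mm_per_s"],
            energy_switch_time=doc["energy_switch_s"],
            beam_onoff_time=doc["beam_onoff_s"],
        )


@dataclass(frozen=True)
class PlanSummary:
    """The five numbers the time model needs from a plan."""

    n_beam_positions: int
    n_spots: int
    n_energies: int
    path_length_mm: float
    prescription_gy: float = 15.0

    def __post_init__(self) -> None:
        if self.n_spots < self.n_beam_positions:
            raise ValueError("n_spots must be >= n_beam_positions")
        if self.n_energies < 1:
            raise ValueError("n_energies must be >= 1")
        if self.path_length_mm < 0:
            raise ValueError("path length must be non-negative")
        if self.prescription_gy <= 0:
            raise ValueError("prescription must be positive")

    @classmethod
    def from_plan(cls, plan: ScanPlan, path_length_mm: float) -> "PlanSummary":
        return cls(
            n_beam_positions=plan.n_beam_positions,
            n_spots=plan.n_spots,
            n_energies=plan.n_energies,
            path_length_mm=path_length_mm,
            prescription_gy=plan.prescription_gy,
        )


@dataclass(frozen=True)
class TimeBreakdown:
    """Delivery-time components in seconds; the total is their exact sum."""

    irradiation: float
    move: float
    energy_switching: float
    onoff: float

    @property
    def delivery(self) -> float:
        return self.irradiation + self.move + self.energy_switching + self.onoff

    @property
    def irradiation_fraction(self) -> float:
        """Irradiation share of the total, percent."""
        return 100.0 * self.irradiation / self.delivery if self.delivery else 0.0

    def rounded(self) -> dict:
        """Reporting view: total to the nearest second, components to 0.01 s."""
        return {
            "T_irradiation_s": round(self.irradiation, 2),
            "T_move_s": round(self.move, 2),
            "T_energyswitching_s": round(self.energy_switching, 2),
            "T_onoff_s": round(self.onoff, 2),
            "T_delivery_s": round(self.delivery),
            "irradiation_fraction_percent": round(self.irradiation_fraction),
        }

    def to_dict(self) -> dict:
        d = asdict(self)
        d["delivery"] = self.delivery
        d["irradiation_fraction"] = self.irradiation_fraction
        return d


def irradiation_time(prescription_gy: float, dose_rate: float, n_beam_positions: int) -> float:
    """Dwell time to deliver the prescription at every beam position (s)."""
    if dose_rate <= 0:
        raise ValueError("dose rate must be positive")
    if prescription_gy <= 0 or n_beam_positions <= 0:
        raise ValueError("prescription and beam-position count must be positive")
    return (prescription_gy / dose_rate) * n_beam_positions


def move_time(path_length_mm: float, arm_speed: float) -> float:
    """Arm travel time over the total scan path length (s)."""
    if arm_speed <= 0:
        raise ValueError("arm speed must be positive")
    if path_length_mm < 0:
        raise ValueError("path length must be non-negative")
    return path_length_mm / arm_speed


def energy_switch_time(switch_time: float, n_energies: int) -> float:
    """Total energy-switch time: one switch between consecutive groups (s)."""
    if n_energies < 1:
        raise ValueError("at least one energy group is required")
    return switch_time * (n_energies - 1)


def onoff_time(onoff: float, n_spots: int) -> float:
    """Beam gating time: one stop and one restart per scan spot (s)."""
    if n_spots < 0:
        raise ValueError("spot count must be non-negative")
    return 2.0 * onoff * n_spots


def delivery_time(summary: PlanSummary, machine: MachineParams) -> TimeBreakdown:
    """Evaluate the four-term delivery-time model for a plan summary."""
    return TimeBreakdown(
        irradiation=irradiation_time(
            summary.prescription_gy, machine.dose_rate, summary.n_beam_positions
        ),
        move=move_time(summary.path_length_mm, machine.arm_speed),
        energy_switching=energy_switch_time(
            machine.energy_switch_time, summary.n_energies
        ),
        onoff=onoff_time(machine.beam_onoff_time, summary.n_spots),
    )
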