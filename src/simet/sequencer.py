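"""Scan-spot generation, energy grouping, and the initial zigzag order.

Each beam position needs a beam whose R90 reaches the target's distal edge.
The R90 table supplies either a single machine energy (one scan spot of
weight 1) or a two-energy composite (two scan spots at the same position
whose weights split the prescription dose).  Because switching energy costs
seconds while moving the arm costs milliseconds, spots are delivered
energy-by-energy: one group per energy, each group scanned as an open path.
The initial path is a raster zigzag — rows taken top to bottom, traversal
direction alternating, starting left-to-right on the topmost occupied row.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .pdd import EnergySpec, R90Table
from .phantom import DepthMap

__all__ = [
    "ScanSpot",
    "EnergyGroup",
    "ScanPlan",
    "TargetTooDeepError",
    "assign_energy",
    "make_spots",
    "group_by_energy",
    "zigzag_order",
    "make_plan",
]

logger = logging.getLogger(__name__)

#: tolerance for binning spots into lattice rows (mm)
ROW_TOL = 1e-6


class TargetTooDeepError(ValueError):
    """The distal edge lies beyond the deepest available beam R90."""


@dataclass(frozen=True)
class ScanSpot:
    x: float
    y: float
    energy_id: int
    weight: float  # fraction of the prescription dose at this position

    def __post_init__(self) -> None:
        if not 0.0 < self.weight <= 1.0:
            raise ValueError("spot weight must lie in (0, 1]")

    @property
    def position(self) -> tuple[float, float]:
        return (self.x, self.y)


@dataclass(frozen=True)
class EnergyGroup:
    """All scan spots sharing one energy; the spot order is the scan path."""

    energy_id: int
    spots: tuple[ScanSpot, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "spots", tuple(self.spots))
        if any(s.energy_id != self.energy_id for s in self.spots):
            raise ValueError("all spots in a group must share its energy_id")

    def __len__(self) -> int:
        return len(self.spots)

    def positions(self) -> np.ndarray:
        return np.array([[s.x, s.y] for s in self.spots], dtype=float)


@dataclass(frozen=True)
class ScanPlan:
    """A deliverable plan: per-energy ordered spot groups plus bookkeeping."""

    n_beam_positions: int
    groups: tuple[EnergyGroup, ...]
    prescription_gy: float = 15.0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "groups", tuple(self.groups))
        if self.n_spots < self.n_beam_positions:
            raise ValueError("spot count cannot be below the beam-position count")
        # per-position dose conservation: weights at each position sum to 1
        totals: dict[tuple[float, float], float] = {}
        for g in self.groups:
            for s in g.spots:
                key = (round(s.x, 6), round(s.y, 6))
                totals[key] = totals.get(key, 0.0) + s.weight
        if len(totals) != self.n_beam_positions:
            raise ValueError("distinct spot positions must equal n_beam_positions")
        if any(abs(t - 1.0) > 1e-9 for t in totals.values()):
            raise ValueError("spot weights at each beam position must sum to 1")

    @property
    def n_spots(self) -> int:
        return sum(len(g) for g in self.groups)

    @property
    def n_energies(self) -> int:
        return len(self.groups)

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "prescription_Gy": self.prescription_gy,
            "N_B": self.n_beam_positions,
            "groups": [
                {
                    "energy_id": g.energy_id,
                    "spots": [
                        {"x_mm": s.x, "y_mm": s.y, "weight": s.weight} for s in g.spots
                    ],
                }
                for g in self.groups
            ],
            "provenance": self.provenance,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, doc: dict) -> "ScanPlan":
        groups = tuple(
            EnergyGroup(
                g["energy_id"],
                tuple(
                    ScanSpot(s["x_mm"], s["y_mm"], g["energy_id"], s["weight"])
                    for s in g["spots"]
                ),
            )
            for g in doc["groups"]
        )
        return cls(
            n_beam_positions=doc["N_B"],
            groups=groups,
            prescription_gy=doc["prescription_Gy"],
            provenance=doc.get("provenance", {}),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "ScanPlan":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def spots_frame(self) -> pd.DataFrame:
        """All spots as a DataFrame with a group column, order preserved."""
        rows = [
            {
                "energy_id": g.energy_id,
                "order_in_group": i,
                "x_mm": s.x,
                "y_mm": s.y,
                "weight": s.weight,
            }
            for g in self.groups
            for i, s in enumerate(g.spots)
        ]
        return pd.DataFrame(rows)


def assign_energy(
    distal_depth: float,
    proximal_depth: float,
    table: R90Table,
    deep_tolerance: float = 0.0,
) -> EnergySpec:
    """Select the table entry whose R90 covers the target's distal edge.

    The required R90 is the ceiling in whole millimetres of the distal-to-
    proximal distance, clamped to the table's key range.  A distal edge more
    than ``deep_tolerance`` mm beyond the deepest key raises
    :class:`TargetTooDeepError`.
    """
    span = distal_depth - proximal_depth
    required = math.ceil(span)
    if required > table.key_max:
        if span > table.key_max + deep_tolerance:
            raise TargetTooDeepError(
                f"distal edge at {span:g} mm exceeds the deepest available "
                f"R90 of {table.key_max} mm"
            )
        required = table.key_max
    if required < table.key_min:
        logger.warning(
            "target depth %g mm below the shallowest R90 %d mm; clamping",
            span,
            table.key_min,
        )
        required = table.key_min
    return table[required]


def make_spots(depthmap: DepthMap, table: R90Table) -> list[ScanSpot]:
    """Expand each beam position into its scan spot(s).

    A pure table entry yields one spot of weight 1; a composited entry yields
    two spots at the same position with weights (w_low, 1 − w_low) on the low
    and high energies.
    """
    spots: list[ScanSpot] = []
    for (x, y), distal, prox in zip(
        depthmap.positions, depthmap.distal_depth, depthmap.proximal_depth
    ):
        spec = assign_energy(float(distal), float(prox), table)
        if spec.kind == "pure":
            spots.append(ScanSpot(float(x), float(y), spec.low_id, 1.0))
        else:
            spots.append(ScanSpot(float(x), float(y), spec.low_id, spec.w_low))
            spots.append(ScanSpot(float(x), float(y), spec.high_id, spec.w_high))
    return spots


def group_by_energy(spots: list[ScanSpot]) -> list[EnergyGroup]:
    """Partition spots into one group per distinct energy, ascending id."""
    by_id: dict[int, list[ScanSpot]] = {}
    for s in spots:
        by_id.setdefault(s.energy_id, []).append(s)
    return [EnergyGroup(eid, tuple(by_id[eid])) for eid in sorted(by_id)]


def zigzag_order(group: EnergyGroup) -> EnergyGroup:
    """Order a group's spots in a raster zigzag.

    Spots are binned into rows by y (descending, i.e. top to bottom); the
    topmost occupied row is traversed left-to-right and subsequent occupied
    rows alternate direction.  Missing lattice sites are simply absent — the
    path jumps straight to the next present spot.
    """
    if len(group) <= 1:
        return group
    spots = list(group.spots)
    ys = sorted({round(s.y / ROW_TOL) * ROW_TOL for s in spots}, reverse=True)
    rows: list[list[ScanSpot]] = [[] for _ in ys]
    for s in spots:
        idx = min(range(len(ys)), key=lambda i: abs(s.y - ys[i]))
        rows[idx].append(s)
    ordered: list[ScanSpot] = []
    for i, row in enumerate(rows):
        row.sort(key=lambda s: s.x, reverse=(i % 2 == 1))
        ordered.extend(row)
    return EnergyGroup(group.energy_id, tuple(ordered))


def make_plan(
    depthmap: DepthMap,
    table: R90Table,
    prescription_gy: float = 15.0,
) -> ScanPlan:
    """Depth map → spots → energy groups → zigzag-ordered :class:`ScanPlan`."""
    spots = make_spots(depthmap, table)
    groups = tuple(zigzag_order(g) for g in group_by_energy(spots))
    provenance = {
        "depthmap": depthmap.meta,
        "table_keys": [table.key_min, table.key_max],
    }
    plan = ScanPlan(
        n_beam_positions=len(depthmap),
        groups=groups,
        prescription_gy=prescription_gy,
        provenance=provenance,
    )
    return plan


def reorder_group(group: EnergyGroup, order: list[int]) -> EnergyGroup:
    """A copy of ``group`` with spots permuted by index list ``order``."""
    if sorted(order) != list(range(len(group))):
        raise ValueError("order must be a permutation of the group's indices")
    return replace(group, spots=tuple(group.spots[i] for i in order))
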