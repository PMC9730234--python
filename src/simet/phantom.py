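"""Synthetic applicator apertures and target depth maps.

Intraoperative electron therapy irradiates an exposed tumour bed through a
collimating applicator.  Planning needs, per lateral beam position inside the
aperture, the depth of the target's distal edge (and optionally a proximal
edge; for an exposed bed the proximal edge is the surface, depth 0).  Real
plans derive this from patient CT; this module generates smooth synthetic
depth maps standing in for that anatomy: flat slabs, hemiellipsoidal caps,
Gaussian-bump fields, and band-limited random surfaces, all seeded and
bit-reproducible.

Coordinates are continuous millimetres, origin at the aperture centre, y up.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

__all__ = ["ApplicatorSpec", "DepthMap", "beam_positions", "generate_phantom"]

logger = logging.getLogger(__name__)

#: boundary-inclusion tolerance for the point-in-aperture test (mm)
BOUNDARY_TOL = 1e-9

PhantomKind = Literal["flat", "hemiellipsoid", "gaussian_bumps", "random_smooth"]


@dataclass(frozen=True)
class ApplicatorSpec:
    """Aperture geometry: square or circular, with a lateral scan resolution."""

    shape: Literal["square", "circular"]
    size: float  # side length or diameter, mm
    lateral_resolution: float = 5.0  # mm

    def __post_init__(self) -> None:
        if self.shape not in ("square", "circular"):
            raise ValueError(f"unknown aperture shape {self.shape!r}")
        if not self.lateral_resolution > 0:
            raise ValueError("lateral_resolution must be positive")
        if self.size < self.lateral_resolution:
            raise ValueError("aperture size must be >= lateral_resolution")


def beam_positions(applicator: ApplicatorSpec) -> np.ndarray:
    """Lattice of beam positions inside the aperture, shape (N, 2), mm.

    The lattice has spacing ``lateral_resolution``, is centred on the
    aperture centroid, and includes a point iff its centre lies inside the
    aperture boundary (boundary-inclusive to 1e-9 mm).  Positions are ordered
    row-major from the top row down, left to right within a row.
    """
    half = applicator.size / 2.0
    res = applicator.lateral_resolution
    n = int(math.floor((half + BOUNDARY_TOL) / res))
    axis = np.arange(-n, n + 1) * res
    xx, yy = np.meshgrid(axis, axis)
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    if applicator.shape == "circular":
        keep = pts[:, 0] ** 2 + pts[:, 1] ** 2 <= half**2 + BOUNDARY_TOL
        pts = pts[keep]
    order = np.lexsort((pts[:, 0], -pts[:, 1]))  # top row first, x ascending
    return pts[order]


@dataclass(frozen=True)
class DepthMap:
    """Distal (and proximal) target depth per beam position.

    Invariants: positions are unique lattice points; every distal depth
    exceeds its proximal depth; proximal depths are >= 0 (0 = the exposed
    surface under the applicator).
    """

    positions: np.ndarray  # (N, 2) mm
    distal_depth: np.ndarray  # (N,) mm
    proximal_depth: np.ndarray | None = None  # (N,) mm, default all-zero
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        distal = np.asarray(self.distal_depth, dtype=float)
        prox = (
            np.zeros(len(pos))
            if self.proximal_depth is None
            else np.asarray(self.proximal_depth, dtype=float)
        )
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "distal_depth", distal)
        object.__setattr__(self, "proximal_depth", prox)
        if pos.ndim != 2 or pos.shape[1] != 2:
            raise ValueError("positions must have shape (N, 2)")
        if distal.shape != (len(pos),) or prox.shape != (len(pos),):
            raise ValueError("depth arrays must match the number of positions")
        if len(np.unique(pos, axis=0)) != len(pos):
            raise ValueError("positions must be unique")
        if np.any(prox < 0):
            raise ValueError("proximal depths must be >= 0")
        if np.any(distal <= prox):
            raise ValueError("every distal depth must exceed its proximal depth")

    def __len__(self) -> int:
        return len(self.positions)

    # -- CSV + JSON-header round trip ---------------------------------------

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "x_mm": self.positions[:, 0],
                "y_mm": self.positions[:, 1],
                "distal_depth_mm": self.distal_depth,
                "proximal_depth_mm": self.proximal_depth,
            }
        )
        df.to_csv(path, index=False)
        if self.meta:
            Path(path).with_suffix(".json").write_text(json.dumps(self.meta, indent=2))

    @classmethod
    def from_csv(cls, path: str | Path) -> "DepthMap":
        df = pd.read_csv(path)
        header = Path(path).with_suffix(".json")
        meta = json.loads(header.read_text()) if header.exists() else {}
        return cls(
            positions=df[["x_mm", "y_mm"]].to_numpy(),
            distal_depth=df["distal_depth_mm"].to_numpy(),
            proximal_depth=df["proximal_depth_mm"].to_numpy(),
            meta=meta,
        )


def _rescale(values: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Affinely map values onto [lo, hi]; a constant field maps to hi."""
    vmin, vmax = float(values.min()), float(values.max())
    if vmax - vmin < 1e-12:
        return np.full_like(values, hi)
    return lo + (values - vmin) * (hi - lo) / (vmax - vmin)


def generate_phantom(
    kind: PhantomKind,
    applicator: ApplicatorSpec,
    depth_min: float,
    depth_max: float,
    seed: int = 0,
) -> DepthMap:
    """Generate a seeded synthetic distal-depth map over the aperture lattice.

    Kinds
    -----
    ``flat``
        Constant distal depth ``depth_max`` everywhere (use
        ``depth_min == depth_max`` for a named depth).
    ``hemiellipsoid``
        Dome with apex ``depth_max`` at the centre falling radially to
        ``depth_min`` at the aperture boundary — a bulging tumour bed.
    ``gaussian_bumps``
        Sum of 2–4 random Gaussian mounds, rescaled to the depth range.
    ``random_smooth``
        Band-limited random cosine surface rescaled to the depth range.

    Depths outside the 9–37 mm span coverable by the default energy library
    are allowed but logged as a warning.
    """
    if depth_min > depth_max:
        raise ValueError("depth_min must not exceed depth_max")
    if depth_min <= 0:
        raise ValueError("depths must be positive")
    if not (9.0 <= depth_min and depth_max <= 37.0):
        logger.warning(
            "depth range [%g, %g] mm exceeds the 9-37 mm span of the default "
            "energy library; deeper targets will be rejected at planning time",
            depth_min,
            depth_max,
        )
    pts = beam_positions(applicator)
    if len(pts) == 0:
        raise ValueError("aperture contains no lattice points")
    x, y = pts[:, 0], pts[:, 1]
    rng = np.random.default_rng(seed)
    half = applicator.size / 2.0

    if kind == "flat":
        depth = np.full(len(pts), float(depth_max))
    elif kind == "hemiellipsoid":
        radius = half * (math.sqrt(2.0) if applicator.shape == "square" else 1.0)
        rel = np.sqrt(np.clip(1.0 - (x**2 + y**2) / radius**2, 0.0, 1.0))
        depth = depth_min + (depth_max - depth_min) * rel
    elif kind == "gaussian_bumps":
        n_bumps = int(rng.integers(2, 5))
        fld = np.zeros(len(pts))
        for _ in range(n_bumps):
            cx, cy = rng.uniform(-half, half, size=2)
            sigma = rng.uniform(0.25, 0.75) * half
            amp = rng.uniform(0.5, 1.0)
            fld += amp * np.exp(-((x - cx) ** 2 + (y - cy) ** 2) / (2 * sigma**2))
        depth = _rescale(fld, depth_min, depth_max)
    elif kind == "random_smooth":
        fld = np.zeros(len(pts))
        scale = max(half, applicator.lateral_resolution)
        for m in range(3):
            for n in range(3):
                a, b = rng.normal(size=2)
                fld += a * np.cos(np.pi * (m * x + n * y) / (2 * scale)) + b * np.sin(
                    np.pi * (m * x - n * y) / (2 * scale)
                )
        depth = _rescale(fld, depth_min, depth_max)
    else:
        raise ValueError(f"unknown phantom kind {kind!r}")

    depth = np.clip(depth, depth_min, depth_max)
    meta = {
        "kind": kind,
        "seed": int(seed),
        "applicator": {
            "shape": applicator.shape,
            "size_mm": applicator.size,
            "lateral_resolution_mm": applicator.lateral_resolution,
        },
        "depth_min_mm": float(depth_min),
        "depth_max_mm": float(depth_max),
    }
    return DepthMap(pts, depth, meta=meta)
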