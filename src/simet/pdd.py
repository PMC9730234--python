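"""Percent-depth-dose modelling and discrete-energy composition.

An electron beam's clinically useful range is its therapeutic depth R90: the
depth on the falling (distal) side of the percent-depth-dose (PDD) curve where
the dose drops to 90% of its maximum.  A scanning accelerator offers only a
few discrete energies, but any intermediate R90 can be synthesised by mixing
two adjacent energies in a weight ratio and reading the R90 of the composite
curve.  This module provides:

* :class:`PDDCurve` — a sampled, normalised PDD curve on a uniform depth grid;
* :func:`r90_of` — distal-side R90 extraction by linear interpolation;
* :func:`synth_pdd` — a parametric generator of realistic electron PDD shapes
  (buildup to a dose maximum, then a logistic distal falloff) whose R90 is
  solved to a requested value;
* :func:`composite` / :func:`find_weight` — two-energy mixing and the
  exhaustive 0.5%-step weight search;
* :class:`EnergyLibrary` / :func:`build_r90_table` — the machine's energy set
  and the 1 mm-step R90 → energy lookup table used during planning.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Literal, Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "PDDCurve",
    "EnergySpec",
    "LibraryEntry",
    "EnergyLibrary",
    "R90Table",
    "r90_of",
    "synth_pdd",
    "composite",
    "find_weight",
    "build_r90_table",
]

#: depth-grid spacing used for all curves (mm)
GRID_STEP = 0.01

#: default weight-search resolution (fraction): exhaustive search in 0.5% steps
WEIGHT_STEP = 0.005

#: nominal R90 values (mm) of the default four-energy machine
DEFAULT_LIBRARY_R90S = (9.0, 19.0, 29.0, 37.0)


class PDDError(ValueError):
    """Raised for invalid PDD curves or infeasible curve requests."""


@dataclass(frozen=True)
class PDDCurve:
    """A percent-depth-dose curve sampled on a uniform depth grid.

    Parameters
    ----------
    depths
        Strictly increasing uniform grid starting at 0, in mm.
    dose
        Dose in percent of the curve's own maximum; ``max(dose) == 100``.
    """

    depths: np.ndarray
    dose: np.ndarray

    def __post_init__(self) -> None:
        depths = np.asarray(self.depths, dtype=float)
        dose = np.asarray(self.dose, dtype=float)
        object.__setattr__(self, "depths", depths)
        object.__setattr__(self, "dose", dose)
        if depths.ndim != 1 or dose.shape != depths.shape:
            raise PDDError("depths and dose must be 1-d arrays of equal length")
        if depths.size < 2:
            raise PDDError("a PDD curve needs at least two samples")
        if depths[0] != 0.0:
            raise PDDError("depth grid must start at 0")
        steps = np.diff(depths)
        if np.any(steps <= 0) or not np.allclose(steps, steps[0], rtol=0, atol=1e-9):
            raise PDDError("depth grid must be strictly increasing and uniform")
        if abs(dose.max() - 100.0) > 1e-9:
            raise PDDError("dose must be normalised so max(dose) == 100")
        if dose.min() < -1e-12:
            raise PDDError("dose must be non-negative")

    @property
    def grid_step(self) -> float:
        return float(self.depths[1] - self.depths[0])

    def same_grid(self, other: "PDDCurve") -> bool:
        return self.depths.shape == other.depths.shape and np.allclose(
            self.depths, other.depths, rtol=0, atol=1e-9
        )


@dataclass(frozen=True)
class EnergySpec:
    """A pure or two-energy-composited beam realising one integer R90.

    ``w_low`` is the weight of the lower energy; the pair's weights sum to 1.
    A pure entry has ``w_low == 1`` on ``low_id`` and no ``high_id``.
    """

    kind: Literal["pure", "composited"]
    low_id: int
    r90: int
    high_id: int | None = None
    w_low: float = 1.0

    def __post_init__(self) -> None:
        if self.kind == "pure":
            if self.high_id is not None or self.w_low != 1.0:
                raise ValueError("pure spec must have w_low=1 and no high_id")
        elif self.kind == "composited":
            if self.high_id is None:
                raise ValueError("composited spec needs a high_id")
            if not 0.0 < self.w_low < 1.0:
                raise ValueError("composited spec needs 0 < w_low < 1")
        else:
            raise ValueError(f"unknown kind {self.kind!r}")

    @property
    def w_high(self) -> float:
        return 1.0 - self.w_low


def r90_of(curve: PDDCurve) -> float:
    """Depth (mm) where the distal side of the curve crosses 90% dose.

    The crossing is located by linear interpolation between grid samples on
    the falling side of the dose maximum.  Raises :class:`PDDError` if the
    curve is not normalised or never falls to 90% within its grid.
    """
    dose = curve.dose
    if abs(dose.max() - 100.0) > 1e-6:
        raise PDDError("curve is not normalised to max 100")
    i_max = int(np.argmax(dose))
    distal = dose[i_max:]
    below = np.nonzero(distal < 90.0)[0]
    if below.size == 0:
        raise PDDError("dose never falls to 90% on the distal side of the grid")
    j = int(below[0])
    if j == 0:  # max itself below 90 cannot happen (max == 100)
        raise PDDError("malformed curve: distal side starts below 90%")
    d_hi, d_lo = distal[j - 1], distal[j]
    z_hi = curve.depths[i_max + j - 1]
    z_lo = curve.depths[i_max + j]
    # linear interpolation between the bracketing samples
    return float(z_hi + (d_hi - 90.0) / (d_hi - d_lo) * (z_lo - z_hi))


def _pdd_values(
    z: np.ndarray,
    z_peak: float,
    z50: float,
    steepness: float,
    surface_dose: float,
) -> np.ndarray:
    """Unnormalised piecewise PDD: sinusoidal buildup + logistic falloff."""
    g = 1.0 / (1.0 + np.exp(steepness * (z - z50)))
    g_peak = 1.0 / (1.0 + math.exp(steepness * (z_peak - z50)))
    falloff = 100.0 * g / g_peak
    buildup = surface_dose + (100.0 - surface_dose) * np.sin(
        0.5 * np.pi * np.clip(z / z_peak, 0.0, 1.0)
    ) ** 2
    return np.where(z < z_peak, buildup, falloff)


def synth_pdd(
    r90: float,
    surface_dose: float = 80.0,
    peak_frac: float = 0.6,
    falloff_steepness: float | None = None,
    grid_max: float | None = None,
    grid_step: float = GRID_STEP,
) -> PDDCurve:
    """Generate a synthetic electron PDD curve with a prescribed R90.

    The shape emulates measured electron beams: dose builds up from
    ``surface_dose`` percent at the surface to 100% at depth
    ``peak_frac * r90``, then falls off along a logistic whose midpoint is
    solved (Brent root-finding) so that ``r90_of`` of the result equals
    ``r90`` to well within 0.05 mm.

    Parameters
    ----------
    r90
        Target therapeutic depth in mm (> 0).
    surface_dose
        Entrance dose in percent, 0 < surface_dose < 100.  Real electron
        beams enter at roughly 75–95%.
    peak_frac
        Depth of dose maximum as a fraction of R90; must leave the peak
        proximal to R90.
    falloff_steepness
        Logistic rate in 1/mm.  Defaults to ``12 / r90`` so the distal
        falloff width scales with the beam range, as it does physically.
    grid_max
        Grid extent in mm; defaults to ``1.5 * r90``.  Pass a common value
        when curves must share a grid for compositing.
    """
    if r90 <= 0:
        raise PDDError("r90 must be positive")
    if not 0.0 < surface_dose < 100.0:
        raise PDDError("surface_dose must lie strictly between 0 and 100")
    z_peak = peak_frac * r90
    if z_peak <= 0 or z_peak >= r90:
        raise PDDError("peak_frac must place the dose maximum before R90")
    s = 12.0 / r90 if falloff_steepness is None else falloff_steepness
    if s <= 0:
        raise PDDError("falloff_steepness must be positive")
    if grid_max is None:
        grid_max = 1.5 * r90

    g = lambda z, z50: 1.0 / (1.0 + math.exp(s * (z - z50)))

    def resid(z50: float) -> float:
        return g(r90, z50) / g(z_peak, z50) - 0.9

    # midpoint bracket: at z50 = z_peak the composite ratio is far below 0.9;
    # pushing z50 deep makes both factors -> 1.
    lo, hi = z_peak, r90 + 200.0 / s
    if resid(lo) > 0 or resid(hi) < 0:
        raise PDDError("infeasible parameter combination for synth_pdd")
    z50 = brentq(resid, lo, hi, xtol=1e-10)

    depths = np.arange(0.0, grid_max + 0.5 * grid_step, grid_step)
    if depths[-1] < r90 + 2.0 / s:
        raise PDDError("grid_max too small to contain the distal falloff")
    dose = _pdd_values(depths, z_peak, z50, s, surface_dose)
    dose *= 100.0 / dose.max()
    return PDDCurve(depths, dose)


def composite(curve_low: PDDCurve, curve_high: PDDCurve, w_low: float) -> PDDCurve:
    """Mix two PDD curves pointwise and renormalise the result to max 100.

    ``w_low`` weights the lower-energy curve; the curves must share a grid.
    """
    if not 0.0 <= w_low <= 1.0:
        raise PDDError("w_low must lie in [0, 1]")
    if not curve_low.same_grid(curve_high):
        raise PDDError("curves must share a depth grid")
    dose = w_low * curve_low.dose + (1.0 - w_low) * curve_high.dose
    dose = dose * (100.0 / dose.max())
    return PDDCurve(curve_low.depths.copy(), dose)


def find_weight(
    curve_low: PDDCurve,
    curve_high: PDDCurve,
    target_r90: float,
    step: float = WEIGHT_STEP,
) -> float:
    """Exhaustive search for the low-energy weight hitting a target R90.

    Every weight on the grid {0, step, 2·step, …, 1} is evaluated and the one
    minimising ``|r90_of(composite) − target_r90|`` is returned; ties break
    toward the larger ``w_low`` (the shallower, safer composite).
    """
    r_low = r90_of(curve_low)
    r_high = r90_of(curve_high)
    if not (min(r_low, r_high) - 1e-9 <= target_r90 <= max(r_low, r_high) + 1e-9):
        raise PDDError(
            f"target R90 {target_r90} mm outside the pair's bracket "
            f"[{r_low:.2f}, {r_high:.2f}] mm"
        )
    n = int(round(1.0 / step))
    best_w, best_err = 0.0, math.inf
    for k in range(n + 1):
        w = k * step
        err = abs(r90_of(composite(curve_low, curve_high, w)) - target_r90)
        if err <= best_err:  # ascending w: ties resolve to larger w_low
            best_w, best_err = w, err
    return best_w


@dataclass(frozen=True)
class LibraryEntry:
    energy_id: int
    r90: float  # nominal therapeutic depth, mm
    curve: PDDCurve


@dataclass(frozen=True)
class EnergyLibrary:
    """The machine's discrete energies, ordered by increasing R90."""

    entries: tuple[LibraryEntry, ...]
    pdd_params: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        r90s = [e.r90 for e in self.entries]
        if len(r90s) < 1:
            raise PDDError("library must contain at least one energy")
        if any(b <= a for a, b in zip(r90s, r90s[1:])):
            raise PDDError("library R90 values must be strictly increasing")
        grid0 = self.entries[0].curve
        if any(not e.curve.same_grid(grid0) for e in self.entries[1:]):
            raise PDDError("library curves must share a depth grid")

    def __iter__(self) -> Iterator[LibraryEntry]:
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def by_id(self, energy_id: int) -> LibraryEntry:
        for e in self.entries:
            if e.energy_id == energy_id:
                return e
        raise KeyError(f"no energy with id {energy_id}")

    @property
    def r90_min(self) -> float:
        return self.entries[0].r90

    @property
    def r90_max(self) -> float:
        return self.entries[-1].r90

    @classmethod
    def default(
        cls,
        r90s: tuple[float, ...] = DEFAULT_LIBRARY_R90S,
        surface_dose: float = 80.0,
        peak_frac: float = 0.6,
    ) -> "EnergyLibrary":
        """Four synthetic energies with R90 = 9, 19, 29 and 37 mm on a shared grid."""
        grid_max = 1.5 * max(r90s)
        entries = tuple(
            LibraryEntry(
                energy_id=i + 1,
                r90=float(r),
                curve=synth_pdd(
                    r, surface_dose=surface_dose, peak_frac=peak_frac, grid_max=grid_max
                ),
            )
            for i, r in enumerate(r90s)
        )
        params = {"surface_dose": surface_dose, "peak_frac": peak_frac}
        return cls(entries, params)

    # -- JSON round-trip: curves are regenerated from their parameters -------

    def to_json(self, path: str | Path) -> None:
        doc = {
            "pdd_params": dict(self.pdd_params),
            "energies": [{"id": e.energy_id, "r90_mm": e.r90} for e in self.entries],
        }
        Path(path).write_text(json.dumps(doc, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "EnergyLibrary":
        doc = json.loads(Path(path).read_text())
        params = doc.get("pdd_params", {})
        r90s = tuple(float(e["r90_mm"]) for e in doc["energies"])
        ids = [int(e["id"]) for e in doc["energies"]]
        lib = cls.default(r90s=r90s, **params)
        if ids != [e.energy_id for e in lib.entries]:
            entries = tuple(
                LibraryEntry(i, e.r90, e.curve) for i, e in zip(ids, lib.entries)
            )
            lib = cls(entries, params)
        return lib


@dataclass(frozen=True)
class R90Table:
    """Lookup table mapping every integer R90 (mm) to an :class:`EnergySpec`.

    Keys cover every integer millimetre from the library's minimum to its
    maximum R90 in 1 mm steps, realising arbitrary therapeutic depths from
    the machine's few discrete energies.
    """

    specs: Mapping[int, EnergySpec]
    library: EnergyLibrary

    def __post_init__(self) -> None:
        keys = sorted(self.specs)
        lo = int(math.ceil(self.library.r90_min - 1e-9))
        hi = int(math.floor(self.library.r90_max + 1e-9))
        if keys != list(range(lo, hi + 1)):
            raise PDDError("table keys must cover every integer mm of the library span")

    def __getitem__(self, key: int) -> EnergySpec:
        return self.specs[key]

    def __contains__(self, key: int) -> bool:
        return key in self.specs

    def __len__(self) -> int:
        return len(self.specs)

    @property
    def key_min(self) -> int:
        return min(self.specs)

    @property
    def key_max(self) -> int:
        return max(self.specs)

    def realize(self, key: int) -> PDDCurve:
        """The composite (or pure) PDD curve the table entry stands for."""
        spec = self.specs[key]
        low = self.library.by_id(spec.low_id).curve
        if spec.kind == "pure":
            return low
        high = self.library.by_id(spec.high_id).curve
        return composite(low, high, spec.w_low)

    def to_csv(self, path: str | Path) -> None:
        rows = [
            {
                "r90_mm": k,
                "low_id": s.low_id,
                "high_id": "" if s.high_id is None else s.high_id,
                "w_low": s.w_low,
            }
            for k, s in sorted(self.specs.items())
        ]
        pd.DataFrame(rows).to_csv(path, index=False)


def build_r90_table(library: EnergyLibrary, step: float = 1.0) -> R90Table:
    """Build the R90 → energy table in 1 mm steps over the library span.

    Integer depths matching a library energy's nominal R90 become pure
    entries; every other depth is composited from the *adjacent* bracketing
    pair via the exhaustive 0.5%-step weight search.
    """
    if len(library) < 2:
        raise PDDError("need at least two energies to build a composition table")
    if step != 1.0:
        raise PDDError("the table is defined on a 1 mm grid")
    nominal = {int(round(e.r90)): e for e in library if abs(e.r90 - round(e.r90)) < 1e-9}
    lo = int(math.ceil(library.r90_min - 1e-9))
    hi = int(math.floor(library.r90_max + 1e-9))
    specs: dict[int, EnergySpec] = {}
    for key in range(lo, hi + 1):
        if key in nominal:
            specs[key] = EnergySpec("pure", nominal[key].energy_id, r90=key)
            continue
        # adjacent bracketing pair in the library
        for e_lo, e_hi in zip(library.entries, library.entries[1:]):
            if e_lo.r90 < key < e_hi.r90:
                w = find_weight(e_lo.curve, e_hi.curve, float(key))
                specs[key] = EnergySpec(
                    "composited", e_lo.energy_id, r90=key, high_id=e_hi.energy_id, w_low=w
                )
                break
        else:  # pragma: no cover - excluded by the key range
            raise PDDError(f"no bracketing pair for key {key}")
    return R90Table(specs, library)
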