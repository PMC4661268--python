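"""Pore hydration analysis: water density profiles and wetting classification.

The water number density along the channel axis is computed in 1 A thick
slices; the volume of each slice is a cylinder of fixed radius equal to the
pore radius at the reference (T112-equivalent) position, so

    density(z) = <waters per frame in [z, z+1)> / (pi r_ref^2 * 1 A)

in molecules/A^3. A hydrophobic segment whose density drops below a fraction
of the bulk value is classified as dewetted; contiguous slices are merged
into wetted/dewetted intervals that tile the profiled range.

Bulk water at 1.000 g/ml corresponds to 0.03343 molecules/A^3 via the
first-principles conversion g/ml = density * M_water / N_A * 1e24.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from porepmf.constants import M_WATER, N_AVOGADRO

#: bulk water number density at 1.000 g/ml, molecules/A^3
BULK_DENSITY = 0.03343
#: default dewetting threshold as a fraction of bulk density
DEFAULT_THRESHOLD_FRACTION = 0.5


@dataclass
class PoreGeometry:
    """Cylinder convention for slice volumes.

    ``reference_radius`` is the pore radius (A) at the reference position
    (the T112-equivalent ring); it fixes the cross-section of every slice.
    """

    reference_radius: float
    z_range: tuple[float, float]

    def __post_init__(self) -> None:
        if self.reference_radius <= 0:
            raise ValueError("reference_radius must be > 0")
        lo, hi = self.z_range
        if hi - lo < 1.0:
            raise ValueError("z_range must span at least one 1 A slice")

    @property
    def slice_volume(self) -> float:
        """Volume of one 1 A slice, A^3."""
        return math.pi * self.reference_radius**2

    def slice_edges(self) -> np.ndarray:
        lo, hi = self.z_range
        n = int(math.floor(hi - lo))
        return lo + np.arange(n + 1, dtype=float)


@dataclass
class DensityProfile:
    """Water number density (molecules/A^3) vs pore-axis coordinate z."""

    z_centers: np.ndarray
    density: np.ndarray
    n_frames: int
    slice_volume: float

    def __post_init__(self) -> None:
        if np.any(self.density < 0):
            raise ValueError("densities must be >= 0")

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "z": self.z_centers,
                "density_molec_per_A3": self.density,
                "density_g_per_ml": convert_density(self.density),
            }
        ).to_csv(path, index=False, float_format="%.6f")


def density_profile(
    occupancy: Sequence[np.ndarray], geometry: PoreGeometry
) -> DensityProfile:
    """Average water number density per 1 A slice over all frames.

    ``occupancy`` is a per-frame sequence of water z-coordinates. Slices tile
    ``geometry.z_range`` half-open [z, z+1).
    """
    n_frames = len(occupancy)
    if n_frames == 0:
        raise ValueError("need at least one frame")
    edges = geometry.slice_edges()
    counts = np.zeros(len(edges) - 1)
    for zs in occupancy:
        if len(zs):
            counts += np.histogram(zs, bins=edges)[0]
    density = counts / n_frames / geometry.slice_volume
    return DensityProfile(
        z_centers=0.5 * (edges[:-1] + edges[1:]),
        density=density,
        n_frames=n_frames,
        slice_volume=geometry.slice_volume,
    )


def convert_density(d, to: str = "g_per_ml"):
    """Convert molecules/A^3 <-> g/ml for water (exact inverse round-trip).

    ``to='g_per_ml'`` takes molecules/A^3 in, ``to='molec_per_A3'`` the
    inverse. Negative densities are rejected.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("density must be >= 0")
    factor = M_WATER / N_AVOGADRO * 1e24
    if to == "g_per_ml":
        out = d * factor
    elif to == "molec_per_A3":
        out = d / factor
    else:
        raise ValueError("to must be 'g_per_ml' or 'molec_per_A3'")
    return float(out) if out.ndim == 0 else out


@dataclass
class WettingInterval:
    """One contiguous wetted or dewetted stretch of the pore axis."""

    z_lo: float
    z_hi: float
    state: str  # "wetted" | "dewetted"


def classify_wetting(
    p: DensityProfile,
    bulk: float = BULK_DENSITY,
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
) -> list[WettingInterval]:
    """Partition the profiled z-range into wetted and dewetted intervals.

    Slices with density < threshold_fraction * bulk are dewetted; contiguous
    slices of equal state are merged. The returned intervals tile the range
    in z order with no overlap.
    """
    if bulk <= 0:
        raise ValueError("bulk density must be > 0")
    dewetted = p.density < threshold_fraction * bulk
    edges_lo = p.z_centers - 0.5
    edges_hi = p.z_centers + 0.5

    intervals: list[WettingInterval] = []
    for i in range(len(dewetted)):
        state = "dewetted" if dewetted[i] else "wetted"
        if intervals and intervals[-1].state == state:
            intervals[-1].z_hi = float(edges_hi[i])
        else:
            intervals.append(WettingInterval(float(edges_lo[i]), float(edges_hi[i]), state))
    return intervals


def write_wetting_json(intervals: list[WettingInterval], path: str | Path) -> None:
    payload = [
        {"z_lo": iv.z_lo, "z_hi": iv.z_hi, "state": iv.state} for iv in intervals
    ]
    Path(path).write_text(json.dumps(payload, indent=2))
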