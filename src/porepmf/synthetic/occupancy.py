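"""Synthetic pore-water occupancy series.

Emulates per-frame water z-coordinates inside a channel pore: bulk-like
Poisson occupancy in 1 A slices along the pore axis, with an optional
hydrophobic zone that alternates between fully wetted and empty states
(two-state wetting/dewetting flicker). Feeds the hydration module's density
profiling the same way per-frame water coordinates from MD would.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd


@dataclass
class OccupancySeriesSpec:
    """Generator settings for a pore-occupancy series.

    Parameters
    ----------
    z_range : (z_lo, z_hi) along the pore axis, A; sliced at 1 A.
    pore_radius_profile : pore radius in A as a function of z, or a constant.
    mean_bulk_density : molecules/A^3 expected outside any dewetting zone.
    dewetting_zone : optional (z_lo, z_hi) sub-interval whose slices flicker
        between wetted (bulk-like) and empty as one collective unit.
    flicker_rate : per-frame probability that the zone switches state.
    seed : RNG seed.
    start_wetted : initial state of the dewetting zone.
    """

    z_range: tuple[float, float]
    pore_radius_profile: Callable[[float], float] | float = 5.0
    mean_bulk_density: float = 0.03343
    dewetting_zone: tuple[float, float] | None = None
    flicker_rate: float = 0.0
    seed: int = 0
    start_wetted: bool = True

    def __post_init__(self) -> None:
        lo, hi = self.z_range
        if not lo < hi:
            raise ValueError(f"invalid z_range {self.z_range}")
        if self.mean_bulk_density < 0:
            raise ValueError("mean_bulk_density must be >= 0")
        if not 0.0 <= self.flicker_rate <= 1.0:
            raise ValueError("flicker_rate must be in [0, 1]")
        if self.dewetting_zone is not None:
            zlo, zhi = self.dewetting_zone
            if not (lo <= zlo < zhi <= hi):
                raise ValueError("dewetting_zone must lie within z_range")

    def radius_at(self, z: float) -> float:
        r = self.pore_radius_profile
        return float(r(z)) if callable(r) else float(r)

    def slice_edges(self) -> np.ndarray:
        """Half-open 1 A slice edges tiling z_range: [z, z+1)."""
        lo, hi = self.z_range
        n = int(math.floor(hi - lo))
        if n < 1:
            raise ValueError("z_range must span at least one 1 A slice")
        return lo + np.arange(n + 1, dtype=float)

    def expected_slice_counts(self) -> np.ndarray:
        """Expected waters per frame in each slice when wetted (Poisson mean)."""
        edges = self.slice_edges()
        centers = 0.5 * (edges[:-1] + edges[1:])
        return np.array(
            [
                self.mean_bulk_density * math.pi * self.radius_at(c) ** 2
                for c in centers
            ]
        )


def generate_occupancy_series(
    spec: OccupancySeriesSpec, n_frames: int
) -> list[np.ndarray]:
    """Generate per-frame water z-coordinates.

    Each 1 A slice receives a Poisson-distributed number of waters with mean
    ``density * pi * r(z)^2 * 1 A``, positions uniform within the slice.
    Slices whose centers fall in the dewetting zone are emptied whenever the
    zone is in its dry state; the zone flips state with probability
    ``flicker_rate`` between consecutive frames.
    """
    if n_frames <= 0:
        raise ValueError(f"n_frames must be positive, got {n_frames}")
    rng = np.random.default_rng(spec.seed)
    edges = spec.slice_edges()
    centers = 0.5 * (edges[:-1] + edges[1:])
    lam = spec.expected_slice_counts()
    n_slices = len(centers)

    in_zone = np.zeros(n_slices, dtype=bool)
    if spec.dewetting_zone is not None:
        zlo, zhi = spec.dewetting_zone
        in_zone = (centers >= zlo) & (centers < zhi)

    # Two-state zone trajectory: symmetric switching -> stationary occupancy
    # 1/2 for any flicker_rate > 0, regardless of the initial state.
    flips = rng.random(n_frames) < spec.flicker_rate
    wetted = np.empty(n_frames, dtype=bool)
    state = spec.start_wetted
    for t in range(n_frames):
        if t > 0 and flips[t]:
            state = not state
        wetted[t] = state

    counts = rng.poisson(lam[None, :], size=(n_frames, n_slices))
    counts[:, in_zone] *= wetted[:, None]

    frames: list[np.ndarray] = []
    for t in range(n_frames):
        zs = []
        for s in range(n_slices):
            c = counts[t, s]
            if c:
                zs.append(edges[s] + rng.random(c))
        frames.append(np.concatenate(zs) if zs else np.empty(0))
    return frames


def write_occupancy_csv(frames: Sequence[np.ndarray], path: str | Path) -> None:
    """Write per-frame water z-coordinates as CSV with header ``frame,z``."""
    idx = np.concatenate(
        [np.full(len(zs), i, dtype=int) for i, zs in enumerate(frames)]
    ) if any(len(zs) for zs in frames) else np.empty(0, dtype=int)
    z = np.concatenate([zs for zs in frames]) if frames else np.empty(0)
    pd.DataFrame({"frame": idx, "z": z}).to_csv(path, index=False, float_format="%.4f")


def read_occupancy_csv(path: str | Path, n_frames: int | None = None) -> list[np.ndarray]:
    """Read a ``frame,z`` CSV back into per-frame z arrays.

    Frames with no waters are preserved as empty arrays when ``n_frames``
    is given (CSV rows only exist for present waters).
    """
    df = pd.read_csv(path)
    if not {"frame", "z"}.issubset(df.columns):
        raise ValueError("occupancy CSV must have columns ['frame', 'z']")
    last = int(df["frame"].max()) + 1 if len(df) else 0
    total = max(n_frames or 0, last)
    out = [np.empty(0) for _ in range(total)]
    for frame, group in df.groupby("frame"):
        out[int(frame)] = group["z"].to_numpy()
    return out
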