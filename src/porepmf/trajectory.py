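"""Reaction-coordinate trajectories.

The two reaction coordinates (zeta1, zeta2) are the diagonal Calpha-Calpha
distances across the channel pore between marker residues of opposing chains.
Every estimator downstream of the sampler consumes this container.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class RCTrajectory:
    """Time series of (zeta1, zeta2) in angstrom with frame metadata.

    Parameters
    ----------
    zeta : (n, 2) array of reaction-coordinate values in A.
    frames : (n,) integer frame indices (defaults to 0..n-1).
    acceptance_rate : Metropolis acceptance fraction, if produced by a sampler.
    meta : free-form provenance (seed, surface kind, bias parameters ...).
    """

    zeta: np.ndarray
    frames: np.ndarray | None = None
    acceptance_rate: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.zeta = np.asarray(self.zeta, dtype=float)
        if self.zeta.ndim != 2 or self.zeta.shape[1] != 2:
            raise ValueError(f"zeta must be (n, 2), got shape {self.zeta.shape}")
        if self.frames is None:
            self.frames = np.arange(len(self.zeta))
        else:
            self.frames = np.asarray(self.frames, dtype=int)
            if len(self.frames) != len(self.zeta):
                raise ValueError("frames and zeta lengths differ")
        if not np.all(np.isfinite(self.zeta)):
            raise ValueError("non-finite reaction-coordinate values")

    def __len__(self) -> int:
        return len(self.zeta)

    @property
    def zeta1(self) -> np.ndarray:
        return self.zeta[:, 0]

    @property
    def zeta2(self) -> np.ndarray:
        return self.zeta[:, 1]

    def mirrored(self) -> "RCTrajectory":
        """Exchange zeta1 and zeta2 (the tetramer's exchange symmetry)."""
        return RCTrajectory(
            self.zeta[:, ::-1].copy(),
            self.frames.copy(),
            self.acceptance_rate,
            dict(self.meta),
        )

    def slice(self, start: int) -> "RCTrajectory":
        return RCTrajectory(
            self.zeta[start:].copy(),
            self.frames[start:].copy(),
            self.acceptance_rate,
            dict(self.meta),
        )

    def to_csv(self, path: str | Path) -> None:
        """Write CSV with header ``frame,zeta1,zeta2`` at 6 decimal places."""
        df = pd.DataFrame(
            {"frame": self.frames, "zeta1": self.zeta1, "zeta2": self.zeta2}
        )
        df.to_csv(path, index=False, float_format="%.6f")

    @classmethod
    def from_csv(cls, path: str | Path) -> "RCTrajectory":
        df = pd.read_csv(path)
        required = {"frame", "zeta1", "zeta2"}
        if not required.issubset(df.columns):
            raise ValueError(f"trajectory CSV must have columns {sorted(required)}")
        return cls(
            df[["zeta1", "zeta2"]].to_numpy(), df["frame"].to_numpy(dtype=int)
        )
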