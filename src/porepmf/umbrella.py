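"""Umbrella-window planning and biased-sampling orchestration.

Each umbrella window restrains the system near a chosen (zeta1_0, zeta2_0)
with the 2D quadratic bias

    V(zeta1, zeta2) = 1/2 [ k1 (zeta1 - zeta1_0)^2 + k2 (zeta2 - zeta2_0)^2 ]

with force constants of 3 kcal/mol/A^2 by default. Windows are laid out on a
0.5 A square lattice over the reaction-coordinate domain; three plans are
supported:

``full_grid``
    every lattice point (12 x 12 = 144 windows on the default domain);
``symmetric_half``
    the exchange symmetry F(zeta1, zeta2) = F(zeta2, zeta1) lets half the
    grid be reconstructed by reflection, leaving floor(n^2/2) = 72 windows
    (all strictly-lower-triangle points plus every second diagonal point);
``diagonal``
    lattice points with zeta1_0 = zeta2_0 only (12 windows), sufficient when
    the off-diagonal surface rises steeply and only the symmetric opening
    profile is of interest.

Exact unordered-pair counting on an n x n lattice actually leaves
n(n+1)/2 = 78 windows for n = 12; ``symmetric_half`` keeps the floor(n^2/2)
convention, and ``pair_count=True`` switches to the exact 78-window plan.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from porepmf.synthetic.surfaces import ModelSurfaceSpec
from porepmf.synthetic.sampler import SamplerConfig, sample_biased
from porepmf.trajectory import RCTrajectory

DEFAULT_FORCE_CONSTANT = 3.0  # kcal/mol/A^2
DEFAULT_DOMAIN = (8.0, 13.5)  # A; 12 lattice points at 0.5 A spacing
DEFAULT_SPACING = 0.5  # A
#: default burn-in fraction of each window's trajectory
DEFAULT_BURN_IN_FRACTION = 0.2

_MODES = ("full_grid", "symmetric_half", "diagonal")


@dataclass(frozen=True)
class BiasPotential:
    """Harmonic umbrella restraint centered at (center1, center2)."""

    center1: float
    center2: float
    k1: float = DEFAULT_FORCE_CONSTANT
    k2: float = DEFAULT_FORCE_CONSTANT

    def __post_init__(self) -> None:
        # k = 0 is allowed and means an unbiased window (used by the WHAM
        # single-window identity); planned umbrella windows always use k > 0.
        if self.k1 < 0 or self.k2 < 0:
            raise ValueError("force constants must be >= 0")

    def energy(self, zeta1, zeta2):
        """Bias energy in kcal/mol; >= 0, zero only at the center."""
        return 0.5 * (
            self.k1 * (np.asarray(zeta1) - self.center1) ** 2
            + self.k2 * (np.asarray(zeta2) - self.center2) ** 2
        )


def bias_energy(b: BiasPotential, point: tuple[float, float]) -> float:
    """Evaluate the harmonic bias at a point (kcal/mol)."""
    z1, z2 = point
    if not (math.isfinite(z1) and math.isfinite(z2)):
        raise ValueError("bias_energy requires finite inputs")
    return float(b.energy(z1, z2))


@dataclass
class UmbrellaWindow:
    """One biased simulation: its restraint and (optionally) its trajectory."""

    id: str
    bias: BiasPotential
    trajectory: RCTrajectory | None = None
    burn_in_frames: int = 0

    def __post_init__(self) -> None:
        if self.trajectory is not None and self.burn_in_frames >= len(self.trajectory):
            raise ValueError(
                f"window {self.id}: burn_in_frames must be < trajectory length"
            )


@dataclass
class WindowPlan:
    """A set of umbrella-window centers over the reaction-coordinate domain."""

    windows: list[UmbrellaWindow]
    mode: str
    spacing: float
    domain: tuple[float, float]

    def __post_init__(self) -> None:
        centers = [(w.bias.center1, w.bias.center2) for w in self.windows]
        if len(set(centers)) != len(centers):
            raise ValueError("window centers must be unique")
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")
        if self.mode == "diagonal" and any(c1 != c2 for c1, c2 in centers):
            raise ValueError("diagonal plan requires zeta1_0 == zeta2_0")

    def __len__(self) -> int:
        return len(self.windows)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "mode": self.mode,
            "spacing": self.spacing,
            "domain": list(self.domain),
            "windows": [
                {
                    "id": w.id,
                    "center": [w.bias.center1, w.bias.center2],
                    "k": [w.bias.k1, w.bias.k2],
                }
                for w in self.windows
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "WindowPlan":
        payload = json.loads(Path(path).read_text())
        windows = [
            UmbrellaWindow(
                id=w["id"],
                bias=BiasPotential(w["center"][0], w["center"][1], w["k"][0], w["k"][1]),
            )
            for w in payload["windows"]
        ]
        return cls(
            windows, payload["mode"], payload["spacing"], tuple(payload["domain"])
        )


def lattice_points(domain: tuple[float, float], spacing: float) -> np.ndarray:
    """1D lattice covering the domain inclusively at the given spacing."""
    lo, hi = domain
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    n = int(round((hi - lo) / spacing)) + 1
    if n < 2:
        raise ValueError(f"domain {domain} spans less than one spacing {spacing}")
    return lo + spacing * np.arange(n)


def plan_windows(
    domain: tuple[float, float] = DEFAULT_DOMAIN,
    spacing: float = DEFAULT_SPACING,
    mode: str = "full_grid",
    k: float = DEFAULT_FORCE_CONSTANT,
    pair_count: bool = False,
) -> WindowPlan:
    """Lay out umbrella-window centers on the square lattice.

    ``mode`` selects ``full_grid`` (n^2 windows), ``symmetric_half``
    (floor(n^2/2); or n(n+1)/2 with ``pair_count=True``) or ``diagonal``
    (n windows on zeta1_0 = zeta2_0). Every window carries k1 = k2 = k.
    """
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {_MODES}")
    if k <= 0:
        raise ValueError("planned windows require k > 0")
    pts = lattice_points(domain, spacing)
    n = len(pts)

    centers: list[tuple[float, float]] = []
    if mode == "full_grid":
        centers = [(pts[i], pts[j]) for i in range(n) for j in range(n)]
    elif mode == "diagonal":
        centers = [(z, z) for z in pts]
    else:  # symmetric_half
        # strictly-lower-triangle points: the upper triangle is recovered by
        # the exchange reflection at analysis time
        centers = [(pts[i], pts[j]) for i in range(n) for j in range(i)]
        if pair_count:
            diag_idx = range(n)  # all diagonal points: n(n+1)/2 total
        else:
            diag_idx = range(1, n, 2)  # every second: floor(n^2/2) total
        centers.extend((pts[i], pts[i]) for i in diag_idx)

    windows = [
        UmbrellaWindow(id=f"w{idx:03d}", bias=BiasPotential(c1, c2, k, k))
        for idx, (c1, c2) in enumerate(centers)
    ]
    return WindowPlan(windows, mode, spacing, tuple(domain))


def run_umbrella_set(
    plan: WindowPlan,
    spec: ModelSurfaceSpec,
    config: SamplerConfig,
    burn_in_fraction: float | None = None,
) -> list[UmbrellaWindow]:
    """Run one biased sampler per window of the plan.

    Per-window seeds are derived deterministically from the master seed in
    ``config``. Burn-in frames are marked on each window (either
    ``config.burn_in_steps`` or, if that is zero and ``burn_in_fraction`` is
    unset, the default initial 20% of frames); :func:`strip_burn_in` removes
    them before histogramming.
    """
    if burn_in_fraction is None:
        burn_in = config.burn_in_steps or int(DEFAULT_BURN_IN_FRACTION * config.n_steps)
    else:
        if not 0 <= burn_in_fraction < 1:
            raise ValueError("burn_in_fraction must be in [0, 1)")
        burn_in = int(burn_in_fraction * config.n_steps)

    seeds = np.random.SeedSequence(config.seed).generate_state(len(plan.windows))
    out = []
    for w, seed in zip(plan.windows, seeds):
        cfg = SamplerConfig(
            n_steps=config.n_steps,
            temperature=config.temperature,
            step_size=config.step_size,
            seed=int(seed),
            burn_in_steps=0,
            kB=config.kB,
            proposal=config.proposal,
        )
        try:
            traj = sample_biased(spec, w.bias, cfg)
        except Exception as exc:  # annotate with the window id
            raise type(exc)(f"window {w.id}: {exc}") from exc
        traj.meta["window_id"] = w.id
        out.append(
            UmbrellaWindow(id=w.id, bias=w.bias, trajectory=traj, burn_in_frames=burn_in)
        )
    return out


def strip_burn_in(w: UmbrellaWindow) -> RCTrajectory:
    """Drop the initial non-equilibrium frames of a window's trajectory."""
    if w.trajectory is None:
        raise ValueError(f"window {w.id} has no trajectory")
    if w.burn_in_frames >= len(w.trajectory):
        raise ValueError(
            f"window {w.id}: burn-in ({w.burn_in_frames}) leaves no frames"
        )
    return w.trajectory.slice(w.burn_in_frames)


def write_manifest(
    windows: list[UmbrellaWindow], out_dir: str | Path, temperature: float
) -> Path:
    """Write per-window trajectory CSVs plus the manifest JSON the WHAM stage reads."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for w in windows:
        fname = f"{w.id}.csv"
        w.trajectory.to_csv(out_dir / fname)
        entries.append(
            {
                "id": w.id,
                "center": [w.bias.center1, w.bias.center2],
                "k": [w.bias.k1, w.bias.k2],
                "burn_in_frames": w.burn_in_frames,
                "trajectory": fname,
            }
        )
    manifest = {"temperature_K": temperature, "windows": entries}
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path


def read_manifest(path: str | Path) -> tuple[list[UmbrellaWindow], float]:
    """Load windows (with trajectories) from a manifest written by :func:`write_manifest`."""
    path = Path(path)
    payload = json.loads(path.read_text())
    windows = []
    for e in payload["windows"]:
        traj = RCTrajectory.from_csv(path.parent / e["trajectory"])
        windows.append(
            UmbrellaWindow(
                id=e["id"],
                bias=BiasPotential(e["center"][0], e["center"][1], e["k"][0], e["k"][1]),
                trajectory=traj,
                burn_in_frames=e["burn_in_frames"],
            )
        )
    return windows, float(payload["temperature_K"])
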