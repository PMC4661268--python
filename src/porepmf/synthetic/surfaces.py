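"""Analytic model free-energy surfaces F(zeta1, zeta2).

These play the role of the physical system's unknown PMF: the sampler draws
Boltzmann samples from exp(-(F+V)/kT), and the WHAM pipeline must recover F.
Four kinds are supported:

``harmonic_well``
    Isotropic paraboloid, F = k/2 * |z - c|^2. The Gaussian target with known
    per-axis variance kT/k — the equipartition oracle.
``double_well_diagonal``
    Two minima on the zeta1 = zeta2 diagonal separated by a quartic barrier,
    plus harmonic confinement transverse to the diagonal. Exchange-symmetric.
``plateau_barrier``
    Minimum at a closed-bundle distance, optional barrier, then a flat plateau
    at larger separations — the shape of a helix-bundle opening profile where
    the open state sits on a shallow shelf above the closed minimum. Built from
    C1 cubic smoothstep segments so the diagonal profile (and hence the
    constructed opening free energy) is known in closed form. Exchange-symmetric.
``tabulated_grid``
    Bilinear interpolation of a user-supplied grid.

All energies kcal/mol, lengths angstrom.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.interpolate import RegularGridInterpolator

_KINDS = ("harmonic_well", "double_well_diagonal", "plateau_barrier", "tabulated_grid")

#: inverse sqrt(2): orthogonal distance from the diagonal per unit (z1 - z2)
_INV_SQRT2 = 1.0 / math.sqrt(2.0)


class DomainError(ValueError):
    """Point outside the surface's domain."""


@dataclass
class ModelSurfaceSpec:
    """Specification of an analytic 2D free-energy surface.

    Parameters
    ----------
    kind : one of ``harmonic_well``, ``double_well_diagonal``,
        ``plateau_barrier``, ``tabulated_grid``.
    parameters : kind-specific parameter map (A, kcal/mol); see module docs.
    domain : (zeta_min, zeta_max) in A, applied to both axes.
    """

    kind: str
    parameters: dict = field(default_factory=dict)
    domain: tuple[float, float] = (8.0, 13.5)

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown surface kind {self.kind!r}; choose from {_KINDS}")
        lo, hi = self.domain
        if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
            raise ValueError(f"invalid domain {self.domain}")
        self._validate_parameters()

    def _validate_parameters(self) -> None:
        p = self.parameters
        if self.kind == "harmonic_well":
            p.setdefault("k", 3.0)
            p.setdefault("center", (9.5, 9.5))
            if p["k"] < 0:
                raise ValueError("harmonic_well k must be >= 0")
        elif self.kind == "double_well_diagonal":
            for key in ("well_a", "well_b", "barrier_height"):
                if key not in p:
                    raise ValueError(f"double_well_diagonal requires {key!r}")
            p.setdefault("transverse_k", 3.0)
            if not p["well_a"] < p["well_b"]:
                raise ValueError("well_a must be < well_b")
            if p["barrier_height"] < 0:
                raise ValueError("barrier_height must be >= 0")
        elif self.kind == "plateau_barrier":
            p.setdefault("min_zeta", 9.5)
            p.setdefault("barrier_zeta", p["min_zeta"] + 1.0)
            p.setdefault("barrier_height", 0.0)
            p.setdefault("plateau_height", p["barrier_height"])
            p.setdefault(
                "plateau_zeta", p["barrier_zeta"] + (p["barrier_zeta"] - p["min_zeta"])
            )
            p.setdefault("wall_k", 3.0)
            p.setdefault("transverse_k", 3.0)
            if not p["min_zeta"] < p["barrier_zeta"] <= p["plateau_zeta"]:
                raise ValueError("need min_zeta < barrier_zeta <= plateau_zeta")
        elif self.kind == "tabulated_grid":
            values = np.asarray(p.get("values"), dtype=float)
            if values.ndim != 2 or min(values.shape) < 2:
                raise ValueError("tabulated_grid requires a 2D 'values' grid (>= 2x2)")
            if not np.all(np.isfinite(values)):
                raise ValueError("tabulated_grid values must be finite")
            p["values"] = values

    # -- convenience constructors -------------------------------------------

    @classmethod
    def flat(cls, domain: tuple[float, float] = (8.0, 13.5)) -> "ModelSurfaceSpec":
        """F = 0 everywhere: the uniform-target surface."""
        lo, hi = domain
        mid = 0.5 * (lo + hi)
        return cls(
            "plateau_barrier",
            {
                "min_zeta": lo,
                "barrier_zeta": mid,
                "barrier_height": 0.0,
                "plateau_height": 0.0,
                "wall_k": 0.0,
                "transverse_k": 0.0,
            },
            domain,
        )

    @classmethod
    def opening_profile(
        cls,
        delta_g_open: float,
        min_zeta: float = 9.5,
        barrier_height: float | None = None,
        barrier_zeta: float = 10.5,
        domain: tuple[float, float] = (8.0, 13.5),
        transverse_k: float = 3.0,
    ) -> "ModelSurfaceSpec":
        """Helix-bundle opening surface: closed minimum, plateau at the open state.

        ``delta_g_open`` is the plateau height above the minimum, i.e. the
        constructed free-energy cost of opening. A barrier higher than the
        plateau may be placed between the states; by default the profile rises
        monotonically onto the plateau (no barrier).
        """
        if barrier_height is None:
            barrier_height = delta_g_open
        return cls(
            "plateau_barrier",
            {
                "min_zeta": min_zeta,
                "barrier_zeta": barrier_zeta,
                "barrier_height": barrier_height,
                "plateau_height": delta_g_open,
                "transverse_k": transverse_k,
            },
            domain,
        )

    def in_domain(self, z1: float, z2: float) -> bool:
        lo, hi = self.domain
        return lo <= z1 <= hi and lo <= z2 <= hi


def _smoothstep(u):
    """C1 cubic ramp: 0 at u<=0, 1 at u>=1, zero slope at both ends."""
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def _plateau_diag_scalar(s: float, p: dict) -> float:
    """Scalar closed-form diagonal profile of the plateau_barrier surface."""
    s0, sb, sp = p["min_zeta"], p["barrier_zeta"], p["plateau_zeta"]
    hb, hp = p["barrier_height"], p["plateau_height"]
    if s < s0:
        return 0.5 * p["wall_k"] * (s - s0) ** 2
    if s < sb:
        u = (s - s0) / (sb - s0)
        return hb * u * u * (3.0 - 2.0 * u)
    if sp > sb and s < sp:
        u = (s - sb) / (sp - sb)
        return hb + (hp - hb) * u * u * (3.0 - 2.0 * u)
    return hp


def _plateau_diag(s, p):
    """Diagonal profile of the plateau_barrier surface (closed form)."""
    scalar = np.ndim(s) == 0
    s = np.atleast_1d(np.asarray(s, dtype=float))
    s0, sb, sp = p["min_zeta"], p["barrier_zeta"], p["plateau_zeta"]
    hb, hp = p["barrier_height"], p["plateau_height"]
    out = np.empty_like(s)
    below = s < s0
    out[below] = 0.5 * p["wall_k"] * (s[below] - s0) ** 2
    rise = (s >= s0) & (s < sb)
    out[rise] = hb * _smoothstep((s[rise] - s0) / (sb - s0))
    if sp > sb:
        settle = (s >= sb) & (s < sp)
        out[settle] = hb + (hp - hb) * _smoothstep((s[settle] - sb) / (sp - sb))
        out[s >= sp] = hp
    else:
        out[s >= sb] = hp
    return out[0] if scalar else out


def make_scalar_evaluator(spec: ModelSurfaceSpec) -> Callable[[float, float], float]:
    """Pure-Python scalar ``f(z1, z2)`` — the sampler's inner-loop fast path."""
    p = spec.parameters
    if spec.kind == "harmonic_well":
        k, (c1, c2) = p["k"], p["center"]
        return lambda z1, z2: 0.5 * k * ((z1 - c1) ** 2 + (z2 - c2) ** 2)
    if spec.kind == "double_well_diagonal":
        a, b = p["well_a"], p["well_b"]
        h, kt_ = p["barrier_height"], p["transverse_k"]
        m, w = 0.5 * (a + b), 0.5 * (b - a)
        w4 = w**4

        def f(z1, z2):
            s = 0.5 * (z1 + z2)
            q = (s - m) ** 2 - w * w
            return h * q * q / w4 + 0.25 * kt_ * (z1 - z2) ** 2

        return f
    if spec.kind == "plateau_barrier":
        params, kt_ = dict(p), p["transverse_k"]

        def f(z1, z2):
            return _plateau_diag_scalar(0.5 * (z1 + z2), params) + 0.25 * kt_ * (
                z1 - z2
            ) ** 2

        return f
    vec = make_evaluator(spec)
    return lambda z1, z2: float(np.asarray(vec(z1, z2)))


def make_evaluator(spec: ModelSurfaceSpec) -> Callable:
    """Return a vectorized ``f(z1, z2) -> kcal/mol`` for the surface.

    The returned callable does no domain checking (the sampler keeps its walk
    inside the domain by reflection); use :func:`evaluate_surface` for checked
    point evaluation.
    """
    p = spec.parameters
    if spec.kind == "harmonic_well":
        k = p["k"]
        c1, c2 = p["center"]

        def f(z1, z2):
            return 0.5 * k * ((z1 - c1) ** 2 + (z2 - c2) ** 2)

    elif spec.kind == "double_well_diagonal":
        a, b = p["well_a"], p["well_b"]
        h = p["barrier_height"]
        kt_ = p["transverse_k"]
        m, w = 0.5 * (a + b), 0.5 * (b - a)
        w4 = w**4

        def f(z1, z2):
            s = 0.5 * (z1 + z2)
            d = (z1 - z2) * _INV_SQRT2
            q = (s - m) ** 2 - w * w
            return h * q * q / w4 + 0.5 * kt_ * d * d

    elif spec.kind == "plateau_barrier":
        kt_ = p["transverse_k"]
        params = dict(p)

        def f(z1, z2):
            s = 0.5 * (z1 + z2)
            d = (z1 - z2) * _INV_SQRT2
            return _plateau_diag(s, params) + 0.5 * kt_ * d * d

    else:  # tabulated_grid
        lo, hi = spec.domain
        values = p["values"]
        ax1 = np.linspace(lo, hi, values.shape[0])
        ax2 = np.linspace(lo, hi, values.shape[1])
        interp = RegularGridInterpolator(
            (ax1, ax2), values, method="linear", bounds_error=False, fill_value=None
        )

        def f(z1, z2):
            pts = np.stack(np.broadcast_arrays(z1, z2), axis=-1)
            out = interp(pts)
            return out if np.ndim(z1) else float(np.asarray(out).ravel()[0])

    return f


def evaluate_surface(spec: ModelSurfaceSpec, point: tuple[float, float]) -> float:
    """Evaluate F(zeta1, zeta2) in kcal/mol at a point inside the domain.

    Raises
    ------
    DomainError
        If the point lies outside the surface's domain.
    """
    z1, z2 = float(point[0]), float(point[1])
    if not spec.in_domain(z1, z2):
        raise DomainError(
            f"point ({z1}, {z2}) outside domain {spec.domain} (both axes)"
        )
    val = float(np.asarray(make_evaluator(spec)(z1, z2)))
    if not math.isfinite(val):
        raise ArithmeticError(f"non-finite surface value at ({z1}, {z2})")
    return val


def diagonal_reference(spec: ModelSurfaceSpec, zeta: np.ndarray) -> np.ndarray:
    """Analytic diagonal profile F(zeta, zeta), zero-referenced at its minimum.

    The independent oracle for PMF-recovery tests: WHAM output along the
    diagonal is compared against this closed form.
    """
    zeta = np.asarray(zeta, dtype=float)
    f = make_evaluator(spec)
    vals = np.asarray(f(zeta, zeta), dtype=float)
    return vals - vals.min()
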