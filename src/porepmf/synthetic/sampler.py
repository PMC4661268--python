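"""Metropolis sampler over the reaction-coordinate plane.

Stands in for the biased MD simulations: draws Boltzmann-distributed
(zeta1, zeta2) samples from exp(-(F + V)/kT), where F is a model surface and
V an optional harmonic umbrella bias. Only the equilibrium distribution
matters for unbiasing, not kinetics, so Metropolis moves suffice. Two
proposal schemes are available:

``walk`` (default)
    Random walk with isotropic Gaussian steps and reflecting domain
    boundaries — mimics the short, local moves of an MD trajectory.
    Successive frames are correlated (integrated autocorrelation time of
    order (sigma/step)^2, never below a few), which inflates histogram noise
    relative to independent sampling.
``bias``
    Independence Metropolis: each proposal is drawn fresh from the umbrella
    bias's own Gaussian, and accepted with probability exp(-dF_surface/kT).
    On a flat surface every in-domain proposal is accepted and the frames are
    exactly independent; on gently varying surfaces they are nearly so. This
    is the mode to use when an estimator's error budget assumes independent
    per-window counts. Requires a bias with positive force constants.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from porepmf.constants import KB_KCAL_MOL_K
from porepmf.trajectory import RCTrajectory
from porepmf.synthetic.surfaces import ModelSurfaceSpec, make_scalar_evaluator


@dataclass
class SamplerConfig:
    """Metropolis run parameters.

    Parameters
    ----------
    temperature : K (default 300, the simulated ensemble temperature).
    n_steps : number of Metropolis steps (one frame recorded per step).
    step_size : std dev of the isotropic Gaussian proposal, A.
    seed : RNG seed; identical seed + config gives a bit-identical trajectory.
    burn_in_steps : initial frames dropped from the returned trajectory.
    kB : Boltzmann constant, kcal/mol/K.
    proposal : "walk" (random-walk Metropolis) or "bias" (independence
        Metropolis from the umbrella Gaussian); see module docs.
    """

    n_steps: int
    temperature: float = 300.0
    step_size: float = 0.15
    seed: int = 0
    burn_in_steps: int = 0
    kB: float = KB_KCAL_MOL_K
    proposal: str = "walk"

    def __post_init__(self) -> None:
        if self.proposal not in ("walk", "bias"):
            raise ValueError("proposal must be 'walk' or 'bias'")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if self.n_steps <= 0:
            raise ValueError("n_steps must be > 0")
        if not 0 <= self.burn_in_steps < self.n_steps:
            raise ValueError("need n_steps > burn_in_steps >= 0")
        if self.step_size <= 0:
            raise ValueError("step_size must be > 0")

    @property
    def kT(self) -> float:
        """Thermal energy in kcal/mol."""
        return self.kB * self.temperature


def _reflect(x: float, lo: float, hi: float) -> float:
    """Fold a coordinate back into [lo, hi] by mirror reflection."""
    if lo <= x <= hi:
        return x
    period = 2.0 * (hi - lo)
    y = (x - lo) % period
    if y > hi - lo:
        y = period - y
    return lo + y


def sample_biased(
    spec: ModelSurfaceSpec,
    bias,
    config: SamplerConfig,
    start: tuple[float, float] | None = None,
) -> RCTrajectory:
    """Run a Metropolis walk targeting exp(-(F + V)/kT) on the surface domain.

    Parameters
    ----------
    spec : model surface F.
    bias : a BiasPotential (umbrella restraint), or None for unbiased sampling.
    config : sampler parameters.
    start : starting point; defaults to the bias center (clipped to the
        domain) or, unbiased, the domain center.

    Returns
    -------
    RCTrajectory with frames after ``config.burn_in_steps``; the Metropolis
    acceptance rate is recorded on the trajectory.

    Raises
    ------
    ArithmeticError
        If a non-finite surface value is encountered (the offending point is
        named in the message).
    """
    lo, hi = spec.domain
    surf = make_scalar_evaluator(spec)
    if bias is not None:
        b1, b2, k1, k2 = bias.center1, bias.center2, bias.k1, bias.k2

        def energy(z1: float, z2: float) -> float:
            return (
                surf(z1, z2)
                + 0.5 * k1 * (z1 - b1) ** 2
                + 0.5 * k2 * (z2 - b2) ** 2
            )

    else:
        energy = surf

    if start is None:
        if bias is not None:
            x1 = min(max(bias.center1, lo), hi)
            x2 = min(max(bias.center2, lo), hi)
        else:
            x1 = x2 = 0.5 * (lo + hi)
    else:
        x1 = _reflect(float(start[0]), lo, hi)
        x2 = _reflect(float(start[1]), lo, hi)

    kT = config.kT
    n = config.n_steps
    rng = np.random.default_rng(config.seed)
    # Pre-draw all proposals and the log of the acceptance uniforms; the
    # chain itself is inherently sequential.
    log_u = np.log(rng.random(n))
    out = np.empty((n, 2))
    accepted = 0

    if config.proposal == "bias":
        if bias is None or bias.k1 <= 0 or bias.k2 <= 0:
            raise ValueError(
                "proposal='bias' requires a bias with positive force constants"
            )
        # independence proposals from the umbrella Gaussian truncated to the
        # domain: both the bias and the truncation constant cancel from the
        # Metropolis ratio, leaving only the surface difference
        s1, s2 = math.sqrt(kT / bias.k1), math.sqrt(kT / bias.k2)
        prop = rng.normal((b1, b2), (s1, s2), size=(n, 2))
        bad = np.flatnonzero(
            (prop[:, 0] < lo) | (prop[:, 0] > hi) | (prop[:, 1] < lo) | (prop[:, 1] > hi)
        )
        while len(bad):
            prop[bad] = rng.normal((b1, b2), (s1, s2), size=(len(bad), 2))
            bad = bad[
                (prop[bad, 0] < lo)
                | (prop[bad, 0] > hi)
                | (prop[bad, 1] < lo)
                | (prop[bad, 1] > hi)
            ]
        e = surf(x1, x2)
        if not math.isfinite(e):
            raise ArithmeticError(f"non-finite energy at start ({x1}, {x2})")
        for i in range(n):
            y1, y2 = prop[i]
            e_new = surf(y1, y2)
            if math.isinf(e_new) or math.isnan(e_new):
                raise ArithmeticError(f"non-finite energy at ({y1}, {y2})")
            de = e_new - e
            if de <= 0.0 or log_u[i] < -de / kT:
                x1, x2, e = y1, y2, e_new
                accepted += 1
            out[i, 0] = x1
            out[i, 1] = x2
    else:
        dx = rng.normal(0.0, config.step_size, size=(n, 2))
        e = energy(x1, x2)
        if not math.isfinite(e):
            raise ArithmeticError(f"non-finite energy at start ({x1}, {x2})")
        for i in range(n):
            y1 = _reflect(x1 + dx[i, 0], lo, hi)
            y2 = _reflect(x2 + dx[i, 1], lo, hi)
            e_new = energy(y1, y2)
            if math.isinf(e_new) or math.isnan(e_new):
                raise ArithmeticError(f"non-finite energy at ({y1}, {y2})")
            de = e_new - e
            if de <= 0.0 or log_u[i] < -de / kT:
                x1, x2, e = y1, y2, e_new
                accepted += 1
            out[i, 0] = x1
            out[i, 1] = x2

    traj = RCTrajectory(
        out,
        acceptance_rate=accepted / n,
        meta={
            "seed": config.seed,
            "surface_kind": spec.kind,
            "temperature_K": config.temperature,
        },
    )
    return traj.slice(config.burn_in_steps) if config.burn_in_steps else traj
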