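"""Non-polar model solvent built from SPC water.

The hydrophobic contribution to bundle-opening free energies can be probed by
solvating the system in a water-like but non-polar liquid: standard rigid
3-site SPC water whose oxygen Lennard-Jones well depth is replaced by that of
an aliphatic lipid-tail carbon and whose molecular dipole is halved. The
dipole reduction is realized by uniform scaling of the point charges at fixed
rigid geometry — the unique linear, geometry-preserving implementation — which
keeps the molecule exactly neutral and scales the dipole by the same factor.

Parameter sets are emitted in a tool-agnostic plain-text table (no MD engine
is in scope).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from porepmf.constants import EA_TO_DEBYE

#: typical aliphatic-carbon LJ well depth, kcal/mol — a documented stand-in
#: default for the reduced-lipid-model value, which is a configuration input.
DEFAULT_ALIPHATIC_EPSILON = 0.12


@dataclass(frozen=True)
class SolventSite:
    """One interaction site: name, point charge (e), LJ sigma (A), epsilon (kcal/mol)."""

    name: str
    charge: float
    sigma: float = 0.0
    epsilon: float = 0.0


@dataclass
class SolventParamSet:
    """Rigid 3-site solvent parameters: sites, geometry and molecular dipole.

    Geometry is O-H bond length (A) and H-O-H angle (degrees). The stored
    dipole (Debye) must match the one computed from charges + geometry; it is
    recomputed and checked on construction.
    """

    sites: tuple[SolventSite, ...]
    oh_length: float = 1.0
    hoh_angle_deg: float = 109.47
    dipole: float | None = None

    def __post_init__(self) -> None:
        net = sum(s.charge for s in self.sites)
        if abs(net) > 1e-9:
            raise ValueError(f"molecule must be neutral, net charge {net:+.4f} e")
        computed = compute_dipole(self)
        if self.dipole is None:
            self.dipole = computed
        elif abs(self.dipole - computed) > 1e-6:
            raise ValueError(
                f"stored dipole {self.dipole} D inconsistent with computed {computed} D"
            )

    def site(self, name: str) -> SolventSite:
        for s in self.sites:
            if s.name == name:
                return s
        raise KeyError(name)

    def site_positions(self) -> dict[str, np.ndarray]:
        """Rigid coordinates: O at the origin, hydrogens in the xz plane."""
        half = math.radians(self.hoh_angle_deg) / 2.0
        r = self.oh_length
        pos = {}
        for s in self.sites:
            if s.name.startswith("O"):
                pos[s.name] = np.zeros(3)
        h_names = [s.name for s in self.sites if s.name.startswith("H")]
        signs = (1.0, -1.0)
        for name, sign in zip(h_names, signs):
            pos[name] = np.array([sign * r * math.sin(half), 0.0, r * math.cos(half)])
        return pos


def spc_water() -> SolventParamSet:
    """Standard SPC: O -0.82 e / H +0.41 e, sigma_O 3.166 A, eps_O 0.1554 kcal/mol."""
    return SolventParamSet(
        sites=(
            SolventSite("O", -0.82, sigma=3.166, epsilon=0.1554),
            SolventSite("H1", 0.41),
            SolventSite("H2", 0.41),
        ),
        oh_length=1.0,
        hoh_angle_deg=109.47,
    )


def compute_dipole(params: SolventParamSet) -> float:
    """Molecular dipole |sum q_i r_i| in Debye from charges and rigid geometry.

    Requires a neutral molecule (the dipole of a charged species is
    origin-dependent).
    """
    net = sum(s.charge for s in params.sites)
    if abs(net) > 1e-9:
        raise ValueError("dipole undefined for a non-neutral molecule")
    pos = params.site_positions()
    mu = np.zeros(3)
    for s in params.sites:
        mu += s.charge * pos[s.name]
    return float(np.linalg.norm(mu)) * EA_TO_DEBYE


@dataclass(frozen=True)
class ModificationSpec:
    """How to turn SPC into the non-polar solvent.

    ``epsilon_source`` is the LJ well depth (kcal/mol) substituted onto the
    oxygen site (the aliphatic-carbon value of a reduced lipid model);
    ``dipole_scale`` multiplies every point charge (0.5 halves the dipole).
    """

    epsilon_source: float = DEFAULT_ALIPHATIC_EPSILON
    dipole_scale: float = 0.5

    def __post_init__(self) -> None:
        if self.epsilon_source <= 0:
            raise ValueError("epsilon_source must be > 0")
        if not 0 < self.dipole_scale <= 1:
            raise ValueError("dipole_scale must be in (0, 1]")


def make_nonpolar_solvent(
    base: SolventParamSet, mod: ModificationSpec
) -> SolventParamSet:
    """Substitute the oxygen LJ well depth and scale all charges uniformly.

    Uniform scaling preserves neutrality for any factor and scales the dipole
    linearly, so the output dipole is ``dipole_scale`` times the base dipole;
    sigma and rigid geometry are unchanged.
    """
    sites = []
    for s in base.sites:
        eps = mod.epsilon_source if s.name.startswith("O") else s.epsilon
        sites.append(replace(s, charge=s.charge * mod.dipole_scale, epsilon=eps))
    return SolventParamSet(
        sites=tuple(sites),
        oh_length=base.oh_length,
        hoh_angle_deg=base.hoh_angle_deg,
    )


def write_param_file(params: SolventParamSet, path: str | Path) -> None:
    """Emit a self-describing plain-text parameter table (lossless round-trip)."""
    lines = [
        "# solvent parameter set",
        "# site  charge_e  sigma_A  epsilon_kcal_mol",
    ]
    for s in params.sites:
        lines.append(f"{s.name:<6s} {s.charge:+.10f} {s.sigma:.10f} {s.epsilon:.10f}")
    lines += [
        "# geometry",
        f"oh_length_A {params.oh_length:.10f}",
        f"hoh_angle_deg {params.hoh_angle_deg:.10f}",
        f"# dipole_debye {params.dipole:.6f}",
        "",
    ]
    Path(path).write_text("\n".join(lines))


def read_param_file(path: str | Path) -> SolventParamSet:
    """Read a parameter table written by :func:`write_param_file`."""
    sites = []
    oh = angle = None
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if parts[0] == "oh_length_A":
            oh = float(parts[1])
        elif parts[0] == "hoh_angle_deg":
            angle = float(parts[1])
        else:
            sites.append(
                SolventSite(parts[0], float(parts[1]), float(parts[2]), float(parts[3]))
            )
    if oh is None or angle is None or not sites:
        raise ValueError(f"malformed solvent parameter file {path}")
    return SolventParamSet(sites=tuple(sites), oh_length=oh, hoh_angle_deg=angle)
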