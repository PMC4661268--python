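"""Toy 4-chain helix bundles with exact marker geometry.

Builds a minimal tetrameric bundle whose two diagonal marker C-alpha
distances equal requested (zeta1, zeta2) exactly: chains A and C sit on the
x axis at +/- zeta1/2, chains B and D on the y axis at +/- zeta2/2, markers
in the z = 0 plane. Each chain is a short pseudo-helix of glycines; only the
marker residue's C-alpha carries meaning, the rest are decorative backbone
placeholders.
"""
from __future__ import annotations

import math

import numpy as np
import biotite.structure as struc

from porepmf.structures import BundleStructure, DEFAULT_MARKER_RESIDUE

_CHAIN_IDS = ("A", "B", "C", "D")
_RESIDUES_PER_CHAIN = 7  # marker +/- 3
_RISE = 1.5  # A per residue along the pore axis
_TWIST = math.radians(100.0)


def make_toy_bundle(
    zeta1: float,
    zeta2: float,
    marker_residue_index: int = DEFAULT_MARKER_RESIDUE,
) -> BundleStructure:
    """Build a 4-chain bundle with diagonal marker distances (zeta1, zeta2).

    Chains A/C form the zeta1 diagonal, B/D the zeta2 diagonal. Raises
    ``ValueError`` for non-positive distances.
    """
    if zeta1 <= 0 or zeta2 <= 0:
        raise ValueError(
            f"reaction coordinates must be positive, got ({zeta1}, {zeta2})"
        )
    half = _RESIDUES_PER_CHAIN // 2
    if marker_residue_index <= half:
        raise ValueError(f"marker_residue_index must exceed {half}")

    bases = {
        "A": np.array([zeta1 / 2.0, 0.0, 0.0]),
        "C": np.array([-zeta1 / 2.0, 0.0, 0.0]),
        "B": np.array([0.0, zeta2 / 2.0, 0.0]),
        "D": np.array([0.0, -zeta2 / 2.0, 0.0]),
    }

    records = []  # (chain, res_id, atom_name, element, coord)
    for cid in _CHAIN_IDS:
        base = bases[cid]
        for o in range(-half, half + 1):
            res_id = marker_residue_index + o
            z = _RISE * o
            # helical wobble on CA, vanishing at the marker residue (o = 0)
            wob = 0.4 * np.array(
                [math.sin(_TWIST * o), math.cos(_TWIST * o) - 1.0, 0.0]
            )
            records.append((cid, res_id, "N", "N", base + [0.0, 0.0, z - 0.45]))
            records.append((cid, res_id, "CA", "C", base + wob + [0.0, 0.0, z]))
            records.append((cid, res_id, "C", "C", base + [0.0, 0.0, z + 0.45]))

    atoms = struc.AtomArray(len(records))
    atoms.coord = np.array([r[4] for r in records])
    atoms.chain_id = np.array([r[0] for r in records])
    atoms.res_id = np.array([r[1] for r in records])
    atoms.res_name = np.array(["GLY"] * len(records))
    atoms.atom_name = np.array([r[2] for r in records])
    atoms.element = np.array([r[3] for r in records])
    atoms.hetero = np.zeros(len(records), dtype=bool)
    return BundleStructure(atoms, marker_residue_index)
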