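"""4-chain helix-bundle structures and reaction-coordinate geometry.

The conformational state of the tetrameric bundle is summarized by two
distances: zeta1 and zeta2, the Euclidean C-alpha--C-alpha distances between
the marker residues (G116-equivalent) of the two diagonally opposed chain
pairs across the channel pore. This module reads 4-chain PDB structures,
extracts (zeta1, zeta2), and generates new structures along the opening
pathway by rigid-body radial interpolation between a closed and an open
endpoint.

PDB parsing and writing go through biotite.
"""
from __future__ import annotations

import io
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import biotite.structure as struc
from biotite.structure.io import pdb as pdb_io

#: default marker residue (G116 in the KcsA M2 numbering)
DEFAULT_MARKER_RESIDUE = 116


class StructureError(ValueError):
    """Structure does not satisfy the 4-chain bundle contract."""


class DegenerateInterpolationError(ValueError):
    """Endpoints give no direction of motion for the requested target."""


@dataclass
class ReactionCoordinatePair:
    """The two diagonal marker C-alpha distances, in A.

    ``pairing`` records which chains form each diagonal:
    ``((chain_for_zeta1_a, chain_for_zeta1_b), (chain_for_zeta2_a, chain_for_zeta2_b))``.
    """

    zeta1: float
    zeta2: float
    pairing: tuple[tuple[str, str], tuple[str, str]]

    def __post_init__(self) -> None:
        if self.zeta1 <= 0 or self.zeta2 <= 0:
            raise ValueError("reaction coordinates must be positive distances")

    def as_tuple(self) -> tuple[float, float]:
        return (self.zeta1, self.zeta2)


class BundleStructure:
    """A 4-chain helix bundle with one marker C-alpha per chain.

    Wraps a biotite :class:`AtomArray`; chains are kept in chain-ID order.
    """

    def __init__(
        self, atoms: struc.AtomArray, marker_residue_index: int = DEFAULT_MARKER_RESIDUE
    ):
        if not np.all(np.isfinite(atoms.coord)):
            raise StructureError("non-finite coordinates")
        chain_ids = sorted(set(atoms.chain_id))
        if len(chain_ids) != 4:
            raise StructureError(
                f"expected exactly 4 chains, found {len(chain_ids)}: {chain_ids}"
            )
        for cid in chain_ids:
            sel = (
                (atoms.chain_id == cid)
                & (atoms.res_id == marker_residue_index)
                & (atoms.atom_name == "CA")
            )
            if np.count_nonzero(sel) != 1:
                raise StructureError(
                    f"chain {cid} lacks a unique C-alpha at marker residue "
                    f"{marker_residue_index}"
                )
        # reorder atoms by chain id so chain order is canonical
        order = np.argsort(atoms.chain_id, kind="stable")
        self.atoms = atoms[order]
        self.marker_residue_index = marker_residue_index
        self.chain_ids = chain_ids

    def marker_positions(self) -> dict[str, np.ndarray]:
        """Marker C-alpha coordinate per chain, in chain-ID order."""
        out = {}
        for cid in self.chain_ids:
            sel = (
                (self.atoms.chain_id == cid)
                & (self.atoms.res_id == self.marker_residue_index)
                & (self.atoms.atom_name == "CA")
            )
            out[cid] = self.atoms.coord[sel][0].astype(float)
        return out

    def chain_coords(self, cid: str) -> np.ndarray:
        return self.atoms.coord[self.atoms.chain_id == cid]

    def translated(self, shifts: dict[str, np.ndarray]) -> "BundleStructure":
        """New structure with each chain rigid-body translated by its shift."""
        atoms = self.atoms.copy()
        for cid, vec in shifts.items():
            mask = atoms.chain_id == cid
            atoms.coord[mask] += np.asarray(vec, dtype=float)
        return BundleStructure(atoms, self.marker_residue_index)

    def pore_axis(self) -> tuple[np.ndarray, np.ndarray]:
        """(centroid, unit normal) of the best-fit plane of the 4 marker CAs.

        The pore axis passes through the marker centroid perpendicular to
        that plane.
        """
        pts = np.stack(list(self.marker_positions().values()))
        centroid = pts.mean(axis=0)
        _, _, vt = np.linalg.svd(pts - centroid)
        return centroid, vt[-1]

    def to_pdb(self, path: str | Path) -> None:
        f = pdb_io.PDBFile()
        f.set_structure(self.atoms)
        # add chain-terminating TER records (biotite omits them)
        lines = f.lines
        out, prev_chain = [], None
        for line in lines:
            if line.startswith(("ATOM", "HETATM")):
                chain = line[21]
                if prev_chain is not None and chain != prev_chain:
                    out.append("TER")
                prev_chain = chain
            out.append(line)
        if prev_chain is not None:
            out.append("TER")
        Path(path).write_text("\n".join(out) + "\n")


def read_structure(
    pdb_source: str | Path | io.TextIOBase,
    marker_residue_index: int = DEFAULT_MARKER_RESIDUE,
) -> BundleStructure:
    """Read a 4-chain bundle from PDB text.

    Keeps altloc 'A' (or blank); rejects insertion codes; requires exactly
    4 chains each bearing a C-alpha at the marker residue.
    """
    if isinstance(pdb_source, (str, Path)):
        f = pdb_io.PDBFile.read(str(pdb_source))
    else:
        f = pdb_io.PDBFile.read(pdb_source)
    atoms = f.get_structure(model=1, altloc="first", extra_fields=["b_factor"])
    ins = atoms.ins_code if "ins_code" in atoms.get_annotation_categories() else None
    if ins is not None and np.any(ins != ""):
        raise StructureError("insertion codes are not supported")
    return BundleStructure(atoms, marker_residue_index)


_MATCHINGS = (((0, 1), (2, 3)), ((0, 2), (1, 3)), ((0, 3), (1, 2)))


def extract_reaction_coordinates(s: BundleStructure) -> ReactionCoordinatePair:
    """Compute (zeta1, zeta2) from the marker C-alpha geometry.

    The diagonal pairing (opposing, not adjacent, chains) is the perfect
    matching of the four chains with the largest total inter-marker distance;
    zeta1 is the diagonal containing the first chain by ID. If all pairings
    are equivalent (degenerate geometry, e.g. a regular tetrahedron of
    markers) a warning is issued and the lexicographic pairing
    (first+third, second+fourth) is used.
    """
    markers = s.marker_positions()
    cids = s.chain_ids
    pts = np.stack([markers[c] for c in cids])

    def pair_dist(i: int, j: int) -> float:
        return float(np.linalg.norm(pts[i] - pts[j]))

    sums = [pair_dist(*m[0]) + pair_dist(*m[1]) for m in _MATCHINGS]
    best = int(np.argmax(sums))
    if np.ptp(sums) < 1e-9:
        warnings.warn(
            "diagonal pairing ambiguous (all chain pairings equidistant); "
            "using lexicographic pairing",
            stacklevel=2,
        )
        best = 1  # (first+third, second+fourth)
    (i, j), (k, l) = _MATCHINGS[best]
    # zeta1 is the diagonal containing the lexicographically first chain
    if 0 not in (i, j):
        (i, j), (k, l) = (k, l), (i, j)
    return ReactionCoordinatePair(
        zeta1=pair_dist(i, j),
        zeta2=pair_dist(k, l),
        pairing=((cids[i], cids[j]), (cids[k], cids[l])),
    )


def _pair_target_shifts(
    markers: dict[str, np.ndarray],
    pair: tuple[str, str],
    target: float,
    axis_normal: np.ndarray,
) -> dict[str, np.ndarray]:
    """In-plane symmetric translations bringing a marker pair to distance target."""
    a, b = pair
    v = markers[a] - markers[b]
    v_in = v - np.dot(v, axis_normal) * axis_normal
    norm_in = np.linalg.norm(v_in)
    if norm_in < 1e-9:
        raise DegenerateInterpolationError(
            f"chains {a} and {b} are coaxial; no radial direction exists"
        )
    h2 = float(np.dot(v, v) - norm_in**2)
    if target**2 <= h2:
        raise DegenerateInterpolationError(
            f"target {target} A unreachable by in-plane motion for pair {pair} "
            f"(out-of-plane separation {np.sqrt(h2):.3f} A)"
        )
    delta = 0.5 * (np.sqrt(target**2 - h2) - norm_in)
    u = v_in / norm_in
    return {a: delta * u, b: -delta * u}


def interpolate_structures(
    closed: BundleStructure,
    open_: BundleStructure,
    targets: list[tuple[float, float]],
    tol: float = 1e-3,
) -> list[BundleStructure]:
    """Generate bundle structures at requested (zeta1, zeta2) values.

    Each chain is rigid-body translated radially in the plane normal to the
    pore axis: a first guess linearly interpolates (or extrapolates) each
    chain's closed-to-open displacement, then an exact in-plane correction
    pins each diagonal marker distance to its target. Intra-chain geometry is
    untouched (pure translations).
    """
    if closed.chain_ids != open_.chain_ids:
        raise StructureError("endpoint structures have different chain IDs")
    for cid in closed.chain_ids:
        if len(closed.chain_coords(cid)) != len(open_.chain_coords(cid)):
            raise StructureError(f"chain {cid} atom counts differ between endpoints")

    rc_closed = extract_reaction_coordinates(closed)
    rc_open = extract_reaction_coordinates(open_)
    pairing = rc_closed.pairing
    centroid, normal = closed.pore_axis()
    m_closed = closed.marker_positions()
    m_open = open_.marker_positions()

    closed_d = rc_closed.as_tuple()
    open_d = (rc_open.zeta1, rc_open.zeta2)

    out: list[BundleStructure] = []
    for target in targets:
        shifts: dict[str, np.ndarray] = {}
        for pair, t, dc, do in zip(pairing, target, closed_d, open_d):
            # 1e-6 tolerance: marker coordinates are stored in float32
            if abs(do - dc) < 1e-6:
                if abs(t - dc) > 1e-6:
                    raise DegenerateInterpolationError(
                        f"endpoints share distance {dc:.4f} A for pair {pair}; "
                        f"cannot reach target {t}"
                    )
                lam = 0.0
            else:
                lam = (t - dc) / (do - dc)
            for cid in pair:
                shifts[cid] = lam * (m_open[cid] - m_closed[cid])
        guess = closed.translated(shifts)

        # exact in-plane correction on top of the linear guess
        g_markers = guess.marker_positions()
        fix: dict[str, np.ndarray] = {}
        for pair, t in zip(pairing, target):
            fix.update(_pair_target_shifts(g_markers, pair, t, normal))
        result = guess.translated(fix)

        achieved = extract_reaction_coordinates(result).as_tuple()
        if max(abs(a - t) for a, t in zip(achieved, target)) > tol:
            raise DegenerateInterpolationError(
                f"could not reach target {target}; achieved {achieved}"
            )
        out.append(result)
    return out
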