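"""Bundle structures: PDB I/O, reaction-coordinate extraction, interpolation."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from porepmf.structures import (
    DegenerateInterpolationError,
    StructureError,
    extract_reaction_coordinates,
    interpolate_structures,
    read_structure,
)
from porepmf.synthetic.bundle import make_toy_bundle


@pytest.mark.parametrize("zetas", [(9.4, 9.6), (10.0, 10.0), (11.5, 11.5), (12.5, 9.0)])
def test_toy_bundle_extraction_round_trip(zetas):
    """extract o make = identity on (zeta1, zeta2) to 1e-6 A."""
    rc = extract_reaction_coordinates(make_toy_bundle(*zetas))
    assert rc.zeta1 == pytest.approx(zetas[0], abs=1e-6)
    assert rc.zeta2 == pytest.approx(zetas[1], abs=1e-6)


def test_pdb_file_round_trip(tmp_path):
    bundle = make_toy_bundle(9.4, 9.6)
    path = tmp_path / "bundle.pdb"
    bundle.to_pdb(path)
    text = path.read_text()
    assert text.count("TER") == 4
    assert sum(1 for ln in text.splitlines() if ln.startswith("ATOM")) == 84
    rc = extract_reaction_coordinates(read_structure(path))
    assert rc.zeta1 == pytest.approx(9.4, abs=1e-5)
    assert rc.zeta2 == pytest.approx(9.6, abs=1e-5)


def test_diagonal_pairing_is_opposing_chains():
    rc = extract_reaction_coordinates(make_toy_bundle(10.0, 12.0))
    assert rc.pairing == (("A", "C"), ("B", "D"))


def test_square_geometry_warns_and_uses_lexicographic_pairing():
    """Four markers at the corners of a regular tetrahedron make every pairing
    equivalent; the extractor warns and falls back to (A,C),(B,D)."""
    bundle = make_toy_bundle(10.0, 10.0)
    atoms = bundle.atoms.copy()
    # place markers at alternating tetrahedron vertices: all 6 pairwise
    # distances equal, so the three matchings have equal total length
    verts = {
        "A": (1.0, 1.0, 1.0),
        "B": (1.0, -1.0, -1.0),
        "C": (-1.0, 1.0, -1.0),
        "D": (-1.0, -1.0, 1.0),
    }
    for cid, v in verts.items():
        sel = (
            (atoms.chain_id == cid)
            & (atoms.res_id == bundle.marker_residue_index)
            & (atoms.atom_name == "CA")
        )
        atoms.coord[sel] = np.array(v) * 5.0
    from porepmf.structures import BundleStructure

    degen = BundleStructure(atoms, bundle.marker_residue_index)
    with pytest.warns(UserWarning, match="ambiguous"):
        rc = extract_reaction_coordinates(degen)
    assert rc.pairing == (("A", "C"), ("B", "D"))


def test_chain_relabeling_swaps_zeta1_and_zeta2():
    """Swapping the A/B and C/D labels exchanges the two diagonals."""
    bundle = make_toy_bundle(9.0, 12.0)
    atoms = bundle.atoms.copy()
    relabel = {"A": "B", "B": "A", "C": "D", "D": "C"}
    atoms.chain_id = np.array([relabel[c] for c in atoms.chain_id])
    from porepmf.structures import BundleStructure

    swapped = BundleStructure(atoms, bundle.marker_residue_index)
    rc = extract_reaction_coordinates(swapped)
    assert (rc.zeta1, rc.zeta2) == pytest.approx((12.0, 9.0), abs=1e-6)


def test_wrong_chain_count_rejected(tmp_path):
    bundle = make_toy_bundle(10.0, 10.0)
    two_chains = bundle.atoms[np.isin(bundle.atoms.chain_id, ["A", "B"])]
    path = tmp_path / "two.pdb"
    from biotite.structure.io import pdb as pdb_io

    f = pdb_io.PDBFile()
    f.set_structure(two_chains)
    f.write(str(path))
    with pytest.raises(StructureError, match="4 chains"):
        read_structure(path)


def test_missing_marker_calpha_names_the_chain(tmp_path):
    bundle = make_toy_bundle(10.0, 10.0)
    marker = bundle.marker_residue_index
    keep = ~(
        (bundle.atoms.chain_id == "C")
        & (bundle.atoms.res_id == marker)
        & (bundle.atoms.atom_name == "CA")
    )
    path = tmp_path / "broken.pdb"
    from biotite.structure.io import pdb as pdb_io

    f = pdb_io.PDBFile()
    f.set_structure(bundle.atoms[keep])
    f.write(str(path))
    with pytest.raises(StructureError, match="chain C"):
        read_structure(path)


def test_nonpositive_zeta_rejected():
    with pytest.raises(ValueError):
        make_toy_bundle(0.0, 10.0)
    with pytest.raises(ValueError):
        make_toy_bundle(10.0, -1.0)


@settings(deadline=None, derandomize=True, max_examples=25)
@given(
    t1=st.floats(min_value=6.6, max_value=15.5),
    t2=st.floats(min_value=6.6, max_value=15.5),
)
def test_interpolation_round_trip_property(t1, t2):
    """extract o interpolate = target within the +/-3 A extrapolation band."""
    closed = make_toy_bundle(9.6, 9.6)
    open_ = make_toy_bundle(12.5, 12.5)
    (result,) = interpolate_structures(closed, open_, [(t1, t2)])
    rc = extract_reaction_coordinates(result)
    assert rc.zeta1 == pytest.approx(t1, abs=1e-3)
    assert rc.zeta2 == pytest.approx(t2, abs=1e-3)


def test_interpolation_identity_at_closed_coordinates():
    closed = make_toy_bundle(9.6, 9.6)
    open_ = make_toy_bundle(12.5, 12.5)
    (result,) = interpolate_structures(closed, open_, [(9.6, 9.6)])
    np.testing.assert_allclose(result.atoms.coord, closed.atoms.coord, atol=1e-5)


def test_interpolation_preserves_intra_chain_geometry():
    closed = make_toy_bundle(9.6, 9.6)
    open_ = make_toy_bundle(12.5, 12.5)
    (result,) = interpolate_structures(closed, open_, [(11.05, 11.05)])
    for cid in "ABCD":
        a = closed.chain_coords(cid)
        b = result.chain_coords(cid)
        da = np.linalg.norm(a[:, None] - a[None, :], axis=-1)
        db = np.linalg.norm(b[:, None] - b[None, :], axis=-1)
        np.testing.assert_allclose(da, db, atol=1e-5)


def test_degenerate_endpoints_rejected():
    closed = make_toy_bundle(9.6, 9.6)
    with pytest.raises(DegenerateInterpolationError):
        interpolate_structures(closed, closed, [(11.0, 11.0)])
    # same endpoints but target equal to their coordinate is fine
    (result,) = interpolate_structures(closed, closed, [(9.6, 9.6)])
    rc = extract_reaction_coordinates(result)
    assert rc.zeta1 == pytest.approx(9.6, abs=1e-6)
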