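"""Structure container, PDB round-trips, selection, superposition, RMSD."""

import numpy as np
import pytest

from modetrap.design import Sequence
from modetrap.structure import (
    EmptyStructureError,
    PairingError,
    SelectionError,
    StructureError,
    kabsch,
    read_pdb,
    rmsd,
    select_atoms,
    sequence_of,
    structure_from_arrays,
    superpose,
    write_pdb,
)


# ---------------------------------------------------------------- reading

def test_read_minimal_pdb_identity(minimal_pdb):
    s = read_pdb(minimal_pdb)
    assert len(s) == 3
    np.testing.assert_allclose(s.coords[0], [1.0, 2.0, 3.0])
    np.testing.assert_allclose(s.coords[1], [2.5, 2.0, 3.0])
    assert list(s.name) == ["N", "CA", "C"]
    assert s.residue_name[0] == "ALA"


def test_read_missing_file():
    with pytest.raises(FileNotFoundError):
        read_pdb("/nonexistent/file.pdb")


def test_read_excludes_water_hetatm_hydrogen(tmp_path):
    text = (
        "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C\n"
        "ATOM      2  H   ALA A   1       0.500   0.000   0.000  1.00  0.00           H\n"
        "HETATM    3  O   HOH A  90       5.000   5.000   5.000  1.00  0.00           O\n"
        "END\n"
    )
    p = tmp_path / "mixed.pdb"
    p.write_text(text)
    s = read_pdb(p)
    assert len(s) == 1
    assert s.name[0] == "CA"


def test_read_altloc_keeps_first(tmp_path):
    text = (
        "ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.50  0.00           C\n"
        "ATOM      2  CA BALA A   1       1.000   0.000   0.000  0.50  0.00           C\n"
        "END\n"
    )
    p = tmp_path / "altloc.pdb"
    p.write_text(text)
    s = read_pdb(p)
    assert len(s) == 1
    np.testing.assert_allclose(s.coords[0], [0.0, 0.0, 0.0])


def test_read_nonstandard_residue_strict_vs_lenient(tmp_path):
    text = (
        "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C\n"
        "ATOM      2  CA  XYZ A   2       3.800   0.000   0.000  1.00  0.00           C\n"
        "END\n"
    )
    p = tmp_path / "nonstd.pdb"
    p.write_text(text)
    assert len(read_pdb(p)) == 1  # dropped with a warning
    with pytest.raises(StructureError):
        read_pdb(p, strict=True)


def test_read_no_protein_atoms(tmp_path):
    p = tmp_path / "empty.pdb"
    p.write_text("HETATM    1  O   HOH A   1       0.0     0.0     0.0  1.00  0.00           O\nEND\n")
    with pytest.raises(EmptyStructureError):
        read_pdb(p)


# ---------------------------------------------------------------- writing

def test_write_read_roundtrip_fixpoint(minimal_pdb, tmp_path):
    s = read_pdb(minimal_pdb)
    p1 = tmp_path / "a.pdb"
    p2 = tmp_path / "b.pdb"
    write_pdb(s, p1)
    s1 = read_pdb(p1)
    write_pdb(s1, p2)
    # 3-decimal quantization applied once: second round trip is byte-stable
    assert p1.read_text() == p2.read_text()
    np.testing.assert_array_equal(s1.coords, read_pdb(p2).coords)


def test_write_empty_structure_errors(tmp_path, helix12):
    empty = helix12.subset(np.zeros(len(helix12), dtype=bool))
    with pytest.raises(EmptyStructureError):
        write_pdb(empty, tmp_path / "x.pdb")


def test_write_resid_overflow_errors(tmp_path):
    s = structure_from_arrays(np.zeros((1, 3)), residue_ids=[10000])
    with pytest.raises(StructureError):
        write_pdb(s, tmp_path / "x.pdb")


# ---------------------------------------------------------------- selection

def test_select_ca_on_helix(helix12):
    assert len(select_atoms(helix12, "name CA")) == 12


def test_select_resid_pair_and_name(helix12):
    sub = select_atoms(helix12, "name CA and resid 4,9")
    assert len(sub) == 2
    assert sorted(sub.residue_id) == [4, 9]


def test_select_resid_range(helix12):
    assert len(select_atoms(helix12, "resid 3:7")) == 5


def test_select_absent_chain_errors(helix12):
    with pytest.raises(SelectionError):
        select_atoms(helix12, "chain Z")


def test_select_preserves_order(helix12):
    sub = select_atoms(helix12, "resid 1:12")
    assert list(sub.residue_id) == list(helix12.residue_id)


# ---------------------------------------------------------------- superposition

def _quaternion_superpose_rmsd(mobile, ref):
    """Independent oracle: Horn's closed-form quaternion solution."""
    mc, rc = mobile.mean(axis=0), ref.mean(axis=0)
    a, b = mobile - mc, ref - rc
    m = a.T @ b
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    k = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    lam = np.linalg.eigvalsh(k)[-1]
    sq = np.sum(a**2) + np.sum(b**2) - 2 * lam
    return np.sqrt(max(sq, 0.0) / len(mobile))


def test_superpose_self_zero(random_cloud):
    _, val = superpose(random_cloud, random_cloud)
    assert val < 1e-10


def test_superpose_removes_rigid_rotation(random_cloud):
    rot = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
    moved = random_cloud.with_coords(random_cloud.coords @ rot.T + [3.0, -1.0, 2.0])
    fitted, val = superpose(moved, random_cloud)
    assert val < 1e-9
    np.testing.assert_allclose(fitted.coords, random_cloud.coords, atol=1e-9)


def test_superpose_matches_quaternion_oracle(rng):
    a = structure_from_arrays(rng.uniform(-5, 5, (10, 3)))
    b = structure_from_arrays(rng.uniform(-5, 5, (10, 3)))
    _, val = superpose(a, b)
    assert abs(val - _quaternion_superpose_rmsd(a.coords, b.coords)) < 1e-8


def test_superpose_idempotent(rng):
    a = structure_from_arrays(rng.uniform(-5, 5, (10, 3)))
    b = structure_from_arrays(rng.uniform(-5, 5, (10, 3)))
    fitted, v1 = superpose(a, b)
    _, v2 = superpose(fitted, b)
    assert abs(v1 - v2) < 1e-9


def test_superpose_mismatched_sets(helix12, random_cloud):
    with pytest.raises(PairingError):
        superpose(helix12, random_cloud)


def test_kabsch_needs_three_atoms():
    with pytest.raises(PairingError):
        kabsch(np.zeros((2, 3)), np.zeros((2, 3)))


# ---------------------------------------------------------------- rmsd

def test_rmsd_identity_and_shift(helix12):
    assert rmsd(helix12, helix12) == 0.0
    shifted = helix12.with_coords(helix12.coords + [2.0, 0.0, 0.0])
    assert abs(rmsd(helix12, shifted) - 2.0) < 1e-12


def test_rmsd_matches_hand_formula_and_symmetry(rng):
    a = structure_from_arrays(rng.uniform(-5, 5, (8, 3)))
    b = structure_from_arrays(rng.uniform(-5, 5, (8, 3)))
    expected = np.sqrt(np.mean(np.sum((a.coords - b.coords) ** 2, axis=1)))
    assert abs(rmsd(a, b) - expected) < 1e-10
    assert rmsd(a, b) == rmsd(b, a)


# ---------------------------------------------------------------- sequences

def test_sequence_of_polyala():
    s = structure_from_arrays(
        np.arange(15, dtype=float).reshape(5, 3), residue_names=["ALA"] * 5
    )
    assert sequence_of(s).letters == "AAAAA"


def test_sequence_of_unknown_residue(tmp_path):
    s = structure_from_arrays(np.zeros((1, 3)), residue_names=["UNK"])
    with pytest.raises(StructureError):
        sequence_of(s)
    assert sequence_of(s, strict=False).letters == "X"


def test_sequence_numbering_parallel(helix12):
    seq = sequence_of(helix12)
    assert isinstance(seq, Sequence)
    assert seq.numbering == tuple(range(1, 13))
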