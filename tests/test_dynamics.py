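"""Ensemble analyses: loading, distances, RMSF, projections, statistics."""

import itertools

import numpy as np
import pytest

from modetrap.dynamics import (
    AnalysisError,
    TrajectoryEnsemble,
    density_peaks,
    distance_series,
    load_ensemble,
    mann_whitney_u,
    project_ensemble,
    rmsf,
    rmsf_correlation,
)
from modetrap.structure import (
    SelectionError,
    structure_from_arrays,
    write_multimodel_pdb,
)


def random_ensemble(topology, n_frames, sigma=0.4, seed=0):
    rng = np.random.default_rng(seed)
    frames = topology.coords[None] + sigma * rng.standard_normal(
        (n_frames, len(topology), 3)
    )
    return TrajectoryEnsemble(topology=topology, coords=frames)


def rigid_transform(coords, rng):
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    return coords @ rot.T + rng.uniform(-10, 10, 3)


# ---------------------------------------------------------------- loading

def test_load_multimodel_pdb_three_frames(tmp_path, helix12):
    rng = np.random.default_rng(1)
    frames = [helix12.coords + 0.1 * rng.standard_normal(helix12.coords.shape) for _ in range(3)]
    p = tmp_path / "ens.pdb"
    write_multimodel_pdb(helix12, frames, p)
    ens = load_ensemble(p)
    assert ens.n_frames == 3
    np.testing.assert_allclose(ens.coords[1], np.round(frames[1], 3), atol=1e-3)


def test_load_concatenates_with_replica_boundaries(tmp_path, helix12):
    p1, p2 = tmp_path / "a.pdb", tmp_path / "b.pdb"
    write_multimodel_pdb(helix12, [helix12.coords, helix12.coords + 0.1], p1)
    write_multimodel_pdb(helix12, [helix12.coords + 0.2, helix12.coords + 0.3], p2)
    ens = load_ensemble([p1, p2], topology=helix12)
    assert ens.n_frames == 4
    assert ens.replica_boundaries == (2, 2)
    assert len(ens.per_replica()) == 2


def test_mdtraj_adapter_agrees_with_native_reader(tmp_path, helix12):
    pytest.importorskip("mdtraj")
    from modetrap.dynamics import load_ensemble_mdtraj

    rng = np.random.default_rng(2)
    frames = [helix12.coords + 0.2 * rng.standard_normal(helix12.coords.shape) for _ in range(4)]
    p = tmp_path / "ens.pdb"
    write_multimodel_pdb(helix12, frames, p)
    native = load_ensemble(p)
    adapted = load_ensemble_mdtraj([p], topology_pdb=p, topology=helix12)
    d1 = distance_series(native, 1, 12).values
    d2 = distance_series(adapted, 1, 12).values
    np.testing.assert_allclose(d1, d2, atol=1e-3)


# ---------------------------------------------------------------- distances

def test_distance_three_four_five():
    s = structure_from_arrays(np.array([[0.0, 0, 0], [3.0, 4.0, 0]]))
    ens = TrajectoryEnsemble(topology=s, coords=s.coords[None])
    assert distance_series(ens, 1, 2).values[0] == pytest.approx(5.0)


def test_distance_constant_trajectory(helix12):
    ens = TrajectoryEnsemble(topology=helix12, coords=np.repeat(helix12.coords[None], 5, axis=0))
    vals = distance_series(ens, 2, 9).values
    assert np.ptp(vals) == 0.0


def test_distance_matches_hand_formula(helix12):
    ens = random_ensemble(helix12, 7, seed=3)
    vals = distance_series(ens, 1, 12).values
    expected = np.linalg.norm(ens.coords[:, 11] - ens.coords[:, 0], axis=1)
    np.testing.assert_allclose(vals, expected, atol=1e-10)


def test_distance_missing_residue(helix12):
    ens = random_ensemble(helix12, 3)
    with pytest.raises(SelectionError):
        distance_series(ens, 1, 99)


def test_distance_invariant_under_rigid_motion(helix12):
    ens = random_ensemble(helix12, 6, seed=4)
    rng = np.random.default_rng(5)
    moved = TrajectoryEnsemble(
        topology=helix12,
        coords=np.array([rigid_transform(f, rng) for f in ens.coords]),
    )
    np.testing.assert_allclose(
        distance_series(ens, 2, 10).values,
        distance_series(moved, 2, 10).values,
        atol=1e-6,
    )


# ---------------------------------------------------------------- RMSF

def test_rmsf_identical_frames_zero(helix12):
    ens = TrajectoryEnsemble(topology=helix12, coords=np.repeat(helix12.coords[None], 4, axis=0))
    _, vals = rmsf(ens)
    np.testing.assert_allclose(vals, 0.0, atol=1e-12)


def test_rmsf_single_frame_degenerate(helix12):
    ens = TrajectoryEnsemble(topology=helix12, coords=helix12.coords[None])
    with pytest.raises(AnalysisError):
        rmsf(ens)


def naive_two_pass_rmsf(coords, ref_idx=None):
    """Independent reference implementation (explicit loops)."""
    from modetrap.structure import kabsch

    sel = np.arange(coords.shape[1]) if ref_idx is None else ref_idx
    mean = coords[0, sel]  # frame-0 seed, as documented
    for _ in range(2):
        fitted = []
        for f in coords:
            rot, trans = kabsch(f[sel], mean)
            fitted.append(f @ rot.T + trans)
        fitted = np.array(fitted)
        mean = fitted[:, sel].mean(axis=0)
    dev = fitted[:, sel] - mean
    return np.sqrt((dev**2).sum(axis=2).mean(axis=0))


def test_rmsf_matches_naive_reference(helix12):
    ens = random_ensemble(helix12, 12, seed=6)
    _, vals = rmsf(ens)
    np.testing.assert_allclose(vals, naive_two_pass_rmsf(ens.coords), atol=1e-9)


def test_rmsf_invariant_under_rigid_motion(helix12):
    ens = random_ensemble(helix12, 8, seed=7)
    rng = np.random.default_rng(8)
    moved = TrajectoryEnsemble(
        topology=helix12,
        coords=np.array([rigid_transform(f, rng) for f in ens.coords]),
    )
    _, a = rmsf(ens)
    _, b = rmsf(moved)
    np.testing.assert_allclose(a, b, atol=1e-6)


def test_rmsf_correlation_bounds_and_errors():
    a = np.array([1.0, 2.0, 3.0, 4.0])
    assert rmsf_correlation(a, a) == pytest.approx(1.0)
    assert rmsf_correlation(a, -a) == pytest.approx(-1.0)
    b = np.array([0.7, 1.1, 0.4, 2.2])
    am, bm = a - a.mean(), b - b.mean()
    expected = (am @ bm) / np.sqrt((am @ am) * (bm @ bm))
    assert rmsf_correlation(a, b) == pytest.approx(expected, abs=1e-12)
    with pytest.raises(AnalysisError):
        rmsf_correlation(a, np.ones(4))


# ---------------------------------------------------------------- projections

def test_projection_recovers_constructed_coefficients(two_domain, two_domain_modes):
    s = two_domain.structure
    v7 = two_domain_modes.eigenvectors[:, 6].reshape(-1, 3)
    frames = np.array([s.coords + c * v7 for c in (-2.0, 0.0, 2.0)])
    ens = TrajectoryEnsemble(topology=s, coords=frames)
    proj = project_ensemble(ens, two_domain_modes, s, modes=(7, 8), fit=False)
    np.testing.assert_allclose(proj[:, 0], [-2.0, 0.0, 2.0], atol=1e-10)
    np.testing.assert_allclose(proj[:, 1], 0.0, atol=1e-10)


def test_projection_reference_only_zero(two_domain, two_domain_modes):
    s = two_domain.structure
    ens = TrajectoryEnsemble(topology=s, coords=np.repeat(s.coords[None], 3, axis=0))
    proj = project_ensemble(ens, two_domain_modes, s, modes=(7, 8))
    np.testing.assert_allclose(proj, 0.0, atol=1e-8)


def test_projection_two_mode_mixture(two_domain, two_domain_modes):
    s = two_domain.structure
    v7 = two_domain_modes.eigenvectors[:, 6].reshape(-1, 3)
    v8 = two_domain_modes.eigenvectors[:, 7].reshape(-1, 3)
    pairs = [(1.5, -0.7), (-2.1, 0.4), (0.0, 1.1)]
    frames = np.array([s.coords + c7 * v7 + c8 * v8 for c7, c8 in pairs])
    ens = TrajectoryEnsemble(topology=s, coords=frames)
    proj = project_ensemble(ens, two_domain_modes, s, modes=(7, 8), fit=False)
    np.testing.assert_allclose(proj, pairs, atol=1e-8)


def test_projection_handles_rigid_motion(two_domain, two_domain_modes):
    s = two_domain.structure
    v7 = two_domain_modes.eigenvectors[:, 6].reshape(-1, 3)
    rng = np.random.default_rng(9)
    frames = np.array(
        [rigid_transform(s.coords + c * v7, rng) for c in (-1.0, 0.5, 1.0)]
    )
    ens = TrajectoryEnsemble(topology=s, coords=frames)
    proj = project_ensemble(ens, two_domain_modes, s, modes=(7,))
    np.testing.assert_allclose(proj[:, 0], [-1.0, 0.5, 1.0], atol=1e-3)


def test_projection_parseval_completeness(two_domain, two_domain_modes):
    s = two_domain.structure
    rng = np.random.default_rng(10)
    frames = s.coords[None] + 0.2 * rng.standard_normal((4, len(s), 3))
    ens = TrajectoryEnsemble(topology=s, coords=frames)
    all_modes = tuple(range(1, two_domain_modes.n_modes + 1))
    proj = project_ensemble(ens, two_domain_modes, s, modes=all_modes, fit=False)
    for f in range(4):
        sq_coeff = float(np.sum(proj[f] ** 2))
        sq_dev = float(np.sum((frames[f] - s.coords) ** 2))
        assert sq_coeff == pytest.approx(sq_dev, abs=1e-8)


# ---------------------------------------------------------------- Mann-Whitney

def exact_two_sided_p(x, y):
    """Oracle: enumerate all C(n+m, n) label assignments of the pooled ranks."""
    import scipy.stats

    pooled = np.concatenate([x, y])
    ranks = scipy.stats.rankdata(pooled)
    n = len(x)
    u_obs = ranks[:n].sum() - n * (n + 1) / 2
    m = len(y)
    us = []
    for combo in itertools.combinations(range(n + m), n):
        u = ranks[list(combo)].sum() - n * (n + 1) / 2
        us.append(u)
    us = np.array(us)
    mean_u = n * m / 2
    p = np.mean(np.abs(us - mean_u) >= abs(u_obs - mean_u) - 1e-12)
    return float(p)


def test_mann_whitney_minimal_example():
    res = mann_whitney_u([1.0, 2.0], [3.0, 4.0])
    assert res.u_statistic == 0.0
    assert res.p_value == pytest.approx(1.0 / 3.0, abs=1e-12)
    assert res.method == "exact"


def test_mann_whitney_identical_samples():
    x = np.arange(30, dtype=float)
    res = mann_whitney_u(x, x)
    assert res.p_value >= 0.99


def test_mann_whitney_exact_branch_matches_enumeration():
    rng = np.random.default_rng(12)
    for _ in range(3):
        x = rng.normal(size=5)
        y = rng.normal(loc=0.5, size=5)
        res = mann_whitney_u(x, y)
        assert res.method == "exact"
        assert res.p_value == pytest.approx(exact_two_sided_p(x, y), abs=1e-12)


def test_mann_whitney_u_sum_identity():
    rng = np.random.default_rng(13)
    x = rng.integers(0, 5, size=12).astype(float)  # ties on purpose
    y = rng.integers(0, 5, size=9).astype(float)
    a = mann_whitney_u(x, y)
    b = mann_whitney_u(y, x)
    assert a.u_statistic + b.u_statistic == pytest.approx(len(x) * len(y))


def test_mann_whitney_empty_sample():
    with pytest.raises(AnalysisError):
        mann_whitney_u([], [1.0])


# ---------------------------------------------------------------- density peaks

def test_density_single_gaussian_one_peak():
    rng = np.random.default_rng(14)
    x = rng.normal(loc=17.0, scale=1.2, size=5000)
    res = density_peaks(x, bandwidth=0.6)
    assert len(res.peaks) == 1
    assert abs(res.peaks[0] - x.mean()) < 0.12  # 0.1 sigma


def test_density_bimodal_two_peaks():
    rng = np.random.default_rng(15)
    x = np.concatenate(
        [rng.normal(17.0, 0.5, 4000), rng.normal(20.0, 0.5, 4000)]
    )
    res = density_peaks(x)
    assert len(res.peaks) == 2
    assert sorted(res.peaks) == pytest.approx([17.0, 20.0], abs=0.25)


def test_density_degenerate_series():
    res = density_peaks(np.full(50, 4.2))
    assert res.peaks == (4.2,)


def test_density_needs_enough_values():
    with pytest.raises(AnalysisError):
        density_peaks(np.arange(5, dtype=float))
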