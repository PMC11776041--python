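"""Conformational-ensemble analysis: collective coordinates, RMSF,
mode projections, rank-sum comparison and density-peak detection.

An ensemble is an ordered stack of coordinate frames over one topology
(natively multi-model PDB; binary trajectory containers through the
optional mdtraj adapter, which must produce identical series).  Analyses
mirror the standard evaluation of a dynamics-engineering run: a
pair-distance collective coordinate tracking a cleft (e.g. the Cα 47–109
distance across the lysozyme substrate cleft), per-residue RMSF after
superposition onto the ensemble mean, projection of frames onto
low-frequency normal modes, and Mann–Whitney comparison of coordinate
distributions between systems.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence as TypingSequence

import numpy as np
import scipy.signal
import scipy.stats

from .enm import ModeSet, mode_vector
from .structure import (
    PairingError,
    SelectionError,
    Structure,
    kabsch,
    read_multimodel_pdb,
    selection_mask,
)


class AnalysisError(ValueError):
    pass


@dataclass
class TrajectoryEnsemble:
    """Ordered conformations sharing one atom topology."""

    topology: Structure
    coords: np.ndarray                     # (F, N, 3) Å
    replica_boundaries: tuple[int, ...] = ()   # frames per source file
    frame_interval: float | None = None    # time units, metadata only
    sources: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise AnalysisError("coords must be (F, N, 3)")
        if self.coords.shape[0] < 1:
            raise AnalysisError("ensemble needs at least one frame")
        if self.coords.shape[1] != len(self.topology):
            raise PairingError("frame atom count differs from topology")
        if not self.replica_boundaries:
            self.replica_boundaries = (self.coords.shape[0],)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def frame(self, i: int) -> Structure:
        return self.topology.with_coords(self.coords[i])

    def per_replica(self) -> list["TrajectoryEnsemble"]:
        out = []
        start = 0
        for count in self.replica_boundaries:
            out.append(
                TrajectoryEnsemble(
                    topology=self.topology,
                    coords=self.coords[start:start + count],
                    frame_interval=self.frame_interval,
                )
            )
            start += count
        return out


@dataclass
class CoordinateSeries:
    """One scalar collective coordinate per frame."""

    values: np.ndarray
    label: str
    replica: str = ""
    units: str = "Å"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise AnalysisError("non-finite coordinate values")


def load_ensemble(
    paths: TypingSequence[str | Path] | str | Path,
    topology: Structure | None = None,
) -> TrajectoryEnsemble:
    """Load and concatenate multi-model PDB files into one ensemble.

    Per-file frame order is preserved and replica boundaries recorded.  The
    first frame provides the topology when none is given; every frame must
    match it atom-for-atom.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    frames: list[np.ndarray] = []
    boundaries: list[int] = []
    topo = topology
    for p in paths:
        models = read_multimodel_pdb(p)
        if topo is None:
            topo = models[0]
        for m in models:
            if len(m) != len(topo):
                raise PairingError(
                    f"{p}: frame atom count {len(m)} != topology {len(topo)}"
                )
            frames.append(m.coords)
        boundaries.append(len(models))
    return TrajectoryEnsemble(
        topology=topo,
        coords=np.array(frames),
        replica_boundaries=tuple(boundaries),
        sources=tuple(str(p) for p in paths),
    )


def load_ensemble_mdtraj(
    paths: TypingSequence[str | Path] | str | Path,
    topology_pdb: str | Path,
    topology: Structure | None = None,
) -> TrajectoryEnsemble:
    """Adapter: read trajectory containers via mdtraj (optional dependency).

    Postconditions match :func:`load_ensemble`: same frame order, replica
    boundaries per file, coordinates converted nm → Å.
    """
    import mdtraj  # noqa: deferred optional import

    from .structure import read_pdb

    if isinstance(paths, (str, Path)):
        paths = [paths]
    topo = topology if topology is not None else read_pdb(topology_pdb)
    frames: list[np.ndarray] = []
    boundaries: list[int] = []
    for p in paths:
        traj = mdtraj.load(str(p), top=str(topology_pdb))
        sel = traj.topology.select("not element H and protein")
        if len(sel) != len(topo):
            raise PairingError(
                f"{p}: {len(sel)} heavy atoms != topology {len(topo)}"
            )
        xyz = traj.xyz[:, sel, :] * 10.0  # nm -> Å
        frames.extend(np.asarray(xyz, dtype=float))
        boundaries.append(traj.n_frames)
    return TrajectoryEnsemble(
        topology=topo,
        coords=np.array(frames),
        replica_boundaries=tuple(boundaries),
        sources=tuple(str(p) for p in paths),
    )


def concatenate(ensembles: TypingSequence[TrajectoryEnsemble]) -> TrajectoryEnsemble:
    """Join ensembles over one topology, keeping replica boundaries."""
    topo = ensembles[0].topology
    coords = []
    bounds: list[int] = []
    for e in ensembles:
        if e.coords.shape[1] != len(topo):
            raise PairingError("ensembles have differing atom counts")
        coords.append(e.coords)
        bounds.extend(e.replica_boundaries)
    return TrajectoryEnsemble(
        topology=topo, coords=np.concatenate(coords), replica_boundaries=tuple(bounds)
    )


# ---------------------------------------------------------------------------
# Collective coordinates
# ---------------------------------------------------------------------------

def _ca_atom_index(topo: Structure, residue_id: int) -> int:
    hit = np.flatnonzero(
        (topo.name.astype(str) == "CA") & (topo.residue_id == residue_id)
    )
    if hit.size == 0:
        raise SelectionError(f"no Cα atom for residue {residue_id}")
    return int(hit[0])


def distance_series(
    t: TrajectoryEnsemble, res_a: int, res_b: int, replica: str = ""
) -> CoordinateSeries:
    """Per-frame Cα–Cα distance between two residues (Å)."""
    ia = _ca_atom_index(t.topology, res_a)
    ib = _ca_atom_index(t.topology, res_b)
    d = np.linalg.norm(t.coords[:, ia, :] - t.coords[:, ib, :], axis=1)
    return CoordinateSeries(
        values=d, label=f"d(CA{res_a}-CA{res_b})", replica=replica
    )


# ---------------------------------------------------------------------------
# RMSF
# ---------------------------------------------------------------------------

def _superpose_frames(
    coords: np.ndarray, sel: np.ndarray, ref_sel_xyz: np.ndarray
) -> np.ndarray:
    out = np.empty_like(coords)
    for f in range(coords.shape[0]):
        rot, trans = kabsch(coords[f, sel], ref_sel_xyz)
        out[f] = coords[f] @ rot.T + trans
    return out


def rmsf(
    t: TrajectoryEnsemble, selector: str = "name CA"
) -> tuple[np.ndarray, np.ndarray]:
    """Per-selected-atom RMSF after two-pass superposition onto the mean.

    Frames are first fitted (selector atoms) onto the mean of the raw
    frames, the mean is recomputed from the fitted frames, the frames are
    re-fitted onto that refined mean, and RMSF_i = √⟨|x_i − ⟨x_i⟩|²⟩ over
    the final fit.  Returns ``(residue_ids, rmsf_values)`` over selected
    atoms.
    """
    if t.n_frames < 2:
        raise AnalysisError("RMSF needs at least two frames")
    sel = np.flatnonzero(selection_mask(t.topology, selector))
    if sel.size < 3:
        raise SelectionError("RMSF selection needs >= 3 atoms")
    # seed the reference from frame 0 (not the raw mean) so arbitrary
    # per-frame rigid motions cannot leak into the mean structure
    mean_sel = t.coords[0, sel, :]
    for _ in range(2):
        coords = _superpose_frames(t.coords, sel, mean_sel)
        mean_sel = coords[:, sel, :].mean(axis=0)
    dev = coords[:, sel, :] - mean_sel[None, :, :]
    vals = np.sqrt(np.mean(np.sum(dev**2, axis=2), axis=0))
    return t.topology.residue_id[sel].copy(), vals


def rmsf_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation between two per-residue fluctuation profiles."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise AnalysisError("profiles must match and have length >= 3")
    if np.std(a) == 0 or np.std(b) == 0:
        raise AnalysisError("zero-variance profile: correlation undefined")
    return float(scipy.stats.pearsonr(a, b).statistic)


# ---------------------------------------------------------------------------
# Mode projections
# ---------------------------------------------------------------------------

def project_ensemble(
    t: TrajectoryEnsemble,
    ms: ModeSet,
    ref: Structure,
    modes: TypingSequence[int] = (7, 8),
    fit_selector: str = "all",
    fit: bool = True,
) -> np.ndarray:
    """(F, len(modes)) projection coefficients of each frame onto modes.

    Each frame is rigid-body fitted onto ``ref`` over the mode node atoms
    (skip with ``fit=False`` when frames are already aligned, which keeps
    the projection exactly linear), then c_k = (x − x_ref)·v_k with v_k
    restricted to those atoms and renormalized.  Trajectory and reference
    must share atom ordering.
    """
    if len(ref) != t.coords.shape[1]:
        raise PairingError("reference and ensemble atom counts differ")
    node_atoms = (
        ms.atom_indices if ms.atom_indices is not None else np.arange(len(ref))
    )
    fit_mask = selection_mask(ref, fit_selector)
    fit_idx = np.intersect1d(np.flatnonzero(fit_mask), node_atoms)
    if fit_idx.size < 3:
        raise SelectionError("projection fit needs >= 3 atoms")
    ref_xyz = ref.coords
    vs = np.stack(
        [mode_vector(ms, k, subset=np.arange(len(node_atoms))) for k in modes],
        axis=1,
    )  # (3n_nodes, K) — full node set, renormalized (norm already 1)
    out = np.empty((t.n_frames, len(modes)))
    for f in range(t.n_frames):
        if fit:
            rot, trans = kabsch(t.coords[f, fit_idx], ref_xyz[fit_idx])
            fitted = t.coords[f] @ rot.T + trans
        else:
            fitted = t.coords[f]
        diff = (fitted - ref_xyz)[node_atoms].ravel()
        out[f] = diff @ vs
    return out


# ---------------------------------------------------------------------------
# Rank-sum comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MannWhitneyResult:
    u_statistic: float
    p_value: float
    method: str  # 'exact' | 'asymptotic'


def mann_whitney_u(x, y) -> MannWhitneyResult:
    """Two-sided Mann–Whitney U test (U reported for the first sample).

    Exact p by enumeration when min(n, m) ≤ 8 and there are no ties;
    otherwise the normal approximation with tie and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise AnalysisError("samples must be non-empty")
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    if min(x.size, y.size) <= 8 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = scipy.stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return MannWhitneyResult(
        u_statistic=float(res.statistic), p_value=float(res.pvalue), method=method
    )


# ---------------------------------------------------------------------------
# Density peaks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DensityPeaks:
    peaks: tuple[float, ...]        # modal values, density-descending
    densities: tuple[float, ...]
    bandwidth: float
    grid: np.ndarray
    density: np.ndarray


def density_peaks(
    series: CoordinateSeries | np.ndarray,
    bandwidth: float | str = "auto",
    prominence_fraction: float = 0.05,
    grid_points: int = 512,
) -> DensityPeaks:
    """Modes of a Gaussian KDE of a coordinate distribution.

    The density is evaluated on a fixed grid spanning the data range plus
    three bandwidths; peaks are strict local maxima with prominence above
    ``prominence_fraction`` of the maximum density, returned sorted by
    density descending.  Bandwidth 'auto' is Silverman's rule.  An all-equal
    series degenerates to a single peak at that value.
    """
    values = series.values if isinstance(series, CoordinateSeries) else np.asarray(series, dtype=float)
    if values.size < 10:
        raise AnalysisError("need at least 10 values for density estimation")
    if np.ptp(values) == 0:
        v = float(values[0])
        return DensityPeaks(
            peaks=(v,), densities=(np.inf,), bandwidth=0.0,
            grid=np.array([v]), density=np.array([np.inf]),
        )
    kde = scipy.stats.gaussian_kde(
        values, bw_method="silverman" if bandwidth == "auto" else None
    )
    if bandwidth != "auto":
        kde.set_bandwidth(float(bandwidth) / values.std(ddof=1))
    bw = float(kde.factor * values.std(ddof=1))
    lo, hi = values.min() - 3 * bw, values.max() + 3 * bw
    grid = np.linspace(lo, hi, grid_points)
    dens = kde(grid)
    idx, _ = scipy.signal.find_peaks(dens, prominence=prominence_fraction * dens.max())
    order = np.argsort(dens[idx])[::-1]
    idx = idx[order]
    return DensityPeaks(
        peaks=tuple(float(grid[i]) for i in idx),
        densities=tuple(float(dens[i]) for i in idx),
        bandwidth=bw,
        grid=grid,
        density=dens,
    )
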