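"""Elastic network models and normal mode analysis.

A protein is reduced to point nodes joined by harmonic springs; the Hessian
of the network energy is assembled from pairwise super-elements and
diagonalized to give the full vibrational spectrum.  For a connected,
non-linear 3D network exactly six eigenvalues vanish (rigid translations and
rotations); the first nontrivial mode is "mode 7" in the 1-based convention
used throughout, and for hinged architectures it is typically the
hinge-bending motion.

Presets
-------
``inverse-power``  (default)
    springs between every node pair within ``cutoff`` with force constant
    ``k = c / d**p`` (default ``p = 2``) — a parameter-free, distance-
    weighted all-heavy-atom network.
``cutoff``
    uniform force constant inside ``cutoff`` (the classic anisotropic
    network model).
``calpha-inverse-power`` / ``calpha-cutoff``
    same spring rules on the Cα trace only.

Eigenvalues are in model-energy units per Å² (relative scale: ENM spectra
are meaningful up to a global factor).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.linalg
from scipy.spatial import cKDTree

from .structure import Structure, select_atoms, StructureError

TRIVIAL_TOL = 1e-8  # eigenvalue < TRIVIAL_TOL * max(eigenvalue) counts as trivial


class ENMError(ValueError):
    pass


@dataclass(frozen=True)
class ENMPreset:
    """Spring-placement rule for :func:`build_network`."""

    kind: str = "inverse-power"     # 'inverse-power' | 'cutoff'
    cutoff: float = 10.0            # Å
    force_constant: float = 1.0     # uniform k (cutoff) or prefactor c (inverse-power)
    power: float = 2.0              # exponent p for inverse-power
    calpha_only: bool = False

    @classmethod
    def named(cls, name: str, **overrides) -> "ENMPreset":
        presets = {
            "inverse-power": cls(kind="inverse-power", calpha_only=False),
            "cutoff": cls(kind="cutoff", calpha_only=False),
            "calpha-inverse-power": cls(kind="inverse-power", calpha_only=True),
            "calpha-cutoff": cls(kind="cutoff", calpha_only=True),
        }
        if name not in presets:
            raise ENMError(f"unknown preset {name!r}; choose from {sorted(presets)}")
        base = presets[name]
        return dataclass_replace(base, **overrides) if overrides else base

    def describe(self) -> str:
        sel = "calpha" if self.calpha_only else "all-heavy"
        if self.kind == "inverse-power":
            return (f"{self.kind}(c={self.force_constant}, p={self.power}, "
                    f"rc={self.cutoff} Å, atoms={sel})")
        return f"{self.kind}(k={self.force_constant}, rc={self.cutoff} Å, atoms={sel})"


def dataclass_replace(obj, **changes):
    from dataclasses import replace

    return replace(obj, **changes)


@dataclass
class ElasticNetwork:
    """Nodes + springs; the minimal harmonic model admitting mode analysis."""

    node_positions: np.ndarray          # (N, 3) Å
    spring_i: np.ndarray                # (M,) int, i < j
    spring_j: np.ndarray                # (M,) int
    force_constants: np.ndarray         # (M,) > 0
    preset: ENMPreset
    masses: np.ndarray | None = None    # (N,) amu; None = uniform 1
    atom_indices: np.ndarray | None = None  # node -> atom ordinal in source Structure
    source: Structure | None = None
    connected: bool = True
    n_components: int = 1

    @property
    def n_nodes(self) -> int:
        return self.node_positions.shape[0]

    @property
    def n_springs(self) -> int:
        return self.spring_i.shape[0]

    def springs(self) -> list[tuple[int, int, float]]:
        return [
            (int(i), int(j), float(k))
            for i, j, k in zip(self.spring_i, self.spring_j, self.force_constants)
        ]


@dataclass
class ModeSet:
    """Full eigendecomposition of an elastic-network Hessian.

    ``eigenvalues`` ascend; ``eigenvectors`` columns are orthonormal.
    ``n_trivial`` counts near-zero eigenvalues (6 for a connected non-linear
    network); 1-based mode index 7 is then the softest genuine motion.
    """

    eigenvalues: np.ndarray    # (3N,) ascending
    eigenvectors: np.ndarray   # (3N, 3N), columns
    n_trivial: int
    preset: ENMPreset
    atom_indices: np.ndarray | None = None
    source: Structure | None = None
    mass_weighted: bool = False

    @property
    def n_nodes(self) -> int:
        return self.eigenvalues.shape[0] // 3

    @property
    def n_modes(self) -> int:
        return self.eigenvalues.shape[0]

    @property
    def frequencies(self) -> np.ndarray:
        """sqrt of clipped eigenvalues — relative vibrational frequencies."""
        return np.sqrt(np.clip(self.eigenvalues, 0.0, None))

    def is_trivial(self, index: int) -> bool:
        """1-based: modes 1..n_trivial are rigid-body (or floppy-zero) modes."""
        self._check_index(index)
        return index <= self.n_trivial

    def _check_index(self, index: int) -> None:
        if not 1 <= index <= self.n_modes:
            raise ENMError(f"mode index {index} outside [1, {self.n_modes}]")

    def eigenvalue(self, index: int) -> float:
        self._check_index(index)
        return float(self.eigenvalues[index - 1])


def build_network(s: Structure, preset: ENMPreset | str | None = None) -> ElasticNetwork:
    """Place springs on a structure according to a preset rule.

    Every node pair with distance ≤ cutoff gets one spring.  A disconnected
    network is returned with ``connected=False`` (and diagonalize will then
    report more than six trivial modes) rather than raising.
    """
    if preset is None:
        preset = ENMPreset()
    elif isinstance(preset, str):
        preset = ENMPreset.named(preset)
    if preset.cutoff <= 0:
        raise ENMError("cutoff must be positive")
    if len(s) == 0:
        raise StructureError("cannot build a network on an empty structure")

    nodes = s
    atom_indices = np.arange(len(s))
    if preset.calpha_only:
        from .structure import selection_mask

        mask = selection_mask(s, "name CA")
        if not mask.any():
            raise ENMError("calpha preset requested but structure has no CA atoms")
        atom_indices = np.flatnonzero(mask)
        nodes = s.subset(mask)

    xyz = nodes.coords
    tree = cKDTree(xyz)
    pairs = tree.query_pairs(r=preset.cutoff, output_type="ndarray")
    if pairs.size:
        order = np.lexsort((pairs[:, 1], pairs[:, 0]))
        pairs = pairs[order]
        i, j = pairs[:, 0], pairs[:, 1]
        d = np.linalg.norm(xyz[j] - xyz[i], axis=1)
        zero = d < 1e-6
        if zero.any():
            raise ENMError("coincident nodes produce singular springs")
        if preset.kind == "cutoff":
            k = np.full(len(d), float(preset.force_constant))
        elif preset.kind == "inverse-power":
            k = preset.force_constant / d ** preset.power
        else:
            raise ENMError(f"unknown spring rule {preset.kind!r}")
    else:
        i = j = np.zeros(0, dtype=int)
        k = np.zeros(0)

    n_comp = _count_components(len(xyz), i, j)
    net = ElasticNetwork(
        node_positions=xyz.copy(),
        spring_i=i,
        spring_j=j,
        force_constants=k,
        preset=preset,
        atom_indices=atom_indices,
        source=s,
        connected=n_comp == 1,
        n_components=n_comp,
    )
    return net


def _count_components(n: int, i: np.ndarray, j: np.ndarray) -> int:
    parent = np.arange(n)

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a, b in zip(i, j):
        ra, rb = find(int(a)), find(int(b))
        if ra != rb:
            parent[ra] = rb
    return len({find(a) for a in range(n)})


def hessian(net: ElasticNetwork) -> np.ndarray:
    """Assemble the 3N×3N network Hessian from pairwise super-elements.

    For a spring (i, j, k) at equilibrium separation d with unit bond vector
    u, the off-diagonal block is ``-k · u uᵀ`` and the diagonal blocks
    accumulate ``+k · u uᵀ`` — the standard anisotropic-network form.
    The result is symmetric, blockwise translation-invariant and positive
    semidefinite.
    """
    n = net.n_nodes
    h = np.zeros((3 * n, 3 * n))
    if net.n_springs == 0:
        return h
    xyz = net.node_positions
    i, j, k = net.spring_i, net.spring_j, net.force_constants
    dvec = xyz[j] - xyz[i]
    d = np.linalg.norm(dvec, axis=1)
    u = dvec / d[:, None]
    blocks = k[:, None, None] * np.einsum("mi,mj->mij", u, u)  # (M,3,3)
    for m in range(net.n_springs):
        a, b = int(i[m]), int(j[m])
        blk = blocks[m]
        h[3 * a:3 * a + 3, 3 * a:3 * a + 3] += blk
        h[3 * b:3 * b + 3, 3 * b:3 * b + 3] += blk
        h[3 * a:3 * a + 3, 3 * b:3 * b + 3] -= blk
        h[3 * b:3 * b + 3, 3 * a:3 * a + 3] -= blk
    return h


def network_energy(net: ElasticNetwork, coords: np.ndarray) -> float:
    """Harmonic network energy ½Σ k (d − d₀)² at arbitrary coordinates."""
    xyz0 = net.node_positions
    xyz = np.asarray(coords, dtype=float).reshape(xyz0.shape)
    d0 = np.linalg.norm(xyz0[net.spring_j] - xyz0[net.spring_i], axis=1)
    d = np.linalg.norm(xyz[net.spring_j] - xyz[net.spring_i], axis=1)
    return float(0.5 * np.sum(net.force_constants * (d - d0) ** 2))


def diagonalize(net: ElasticNetwork, mass_weighted: bool = False) -> ModeSet:
    """Full spectrum of the network Hessian, sorted ascending.

    Trivial modes are those with eigenvalue below ``1e-8 ×`` the largest
    eigenvalue.  The sign of each eigenvector is fixed so its largest-
    magnitude component is positive, making downstream direction labels
    (open/closed) reproducible.
    """
    h = hessian(net)
    if mass_weighted:
        masses = (
            net.masses if net.masses is not None else np.ones(net.n_nodes)
        )
        inv_sqrt_m = np.repeat(1.0 / np.sqrt(masses), 3)
        h = h * inv_sqrt_m[:, None] * inv_sqrt_m[None, :]
    try:
        evals, evecs = scipy.linalg.eigh(h)
    except scipy.linalg.LinAlgError as exc:  # pragma: no cover
        raise ENMError(
            f"eigensolver failure (N={net.n_nodes}, "
            f"|H|_max={np.abs(h).max():.3g}): {exc}"
        ) from exc
    # eigh returns ascending order already; enforce + clean tiny negatives
    order = np.argsort(evals, kind="stable")
    evals = evals[order]
    evecs = evecs[:, order]
    vmax = float(evals[-1]) if evals.size else 0.0
    n_trivial = int(np.sum(np.abs(evals) < TRIVIAL_TOL * max(vmax, 1e-300)))
    # deterministic sign: largest-|component| positive
    amax = np.argmax(np.abs(evecs), axis=0)
    signs = np.sign(evecs[amax, np.arange(evecs.shape[1])])
    signs[signs == 0] = 1.0
    evecs = evecs * signs[None, :]
    return ModeSet(
        eigenvalues=evals,
        eigenvectors=evecs,
        n_trivial=n_trivial,
        preset=net.preset,
        atom_indices=net.atom_indices,
        source=net.source,
        mass_weighted=mass_weighted,
    )


def mode_vector(
    ms: ModeSet, index: int, subset: np.ndarray | None = None
) -> np.ndarray:
    """Eigenvector of 1-based mode ``index``, optionally restricted to a node
    subset and renormalized to unit length.

    ``subset`` is an array of node ordinals (into the ModeSet's node order).
    Returns a flat array of length ``3 * n_selected``.
    """
    ms._check_index(index)
    v = ms.eigenvectors[:, index - 1]
    if subset is None:
        return v.copy()
    subset = np.asarray(subset, dtype=int)
    comp = v.reshape(-1, 3)[subset].ravel()
    norm = np.linalg.norm(comp)
    if norm < 1e-12:
        raise ENMError(f"mode {index} has no amplitude on the requested subset")
    return comp / norm


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def modeset_to_text(ms: ModeSet) -> str:
    """Documented plain-text format: header, eigenvalue table, eigenvector
    matrix (whitespace-delimited, one 3N-row per line, modes as columns)."""
    buf = io.StringIO()
    n = ms.n_nodes
    buf.write(f"# modetrap modeset v1\n")
    buf.write(f"# n_nodes {n}\n")
    buf.write(f"# n_trivial {ms.n_trivial}\n")
    buf.write(f"# mass_weighted {int(ms.mass_weighted)}\n")
    buf.write(f"# preset {ms.preset.describe()}\n")
    buf.write("# eigenvalues\n")
    np.savetxt(buf, ms.eigenvalues[None, :], fmt="%.12g")
    buf.write("# eigenvectors (rows = 3N coordinates, cols = modes)\n")
    np.savetxt(buf, ms.eigenvectors, fmt="%.12g")
    return buf.getvalue()


def modeset_from_text(text: str) -> ModeSet:
    lines = text.splitlines()
    meta: dict[str, str] = {}
    rows: list[str] = []
    for ln in lines:
        if ln.startswith("#"):
            parts = ln[1:].strip().split(None, 1)
            if len(parts) == 2 and parts[0] in {"n_nodes", "n_trivial", "mass_weighted"}:
                meta[parts[0]] = parts[1]
        elif ln.strip():
            rows.append(ln)
    n = int(meta["n_nodes"])
    data = np.loadtxt(io.StringIO("\n".join(rows)))
    evals = np.atleast_2d(data)[0]
    evecs = np.atleast_2d(data)[1:]
    if evecs.shape != (3 * n, 3 * n):
        raise ENMError("malformed modeset text")
    return ModeSet(
        eigenvalues=evals,
        eigenvectors=evecs,
        n_trivial=int(meta["n_trivial"]),
        preset=ENMPreset(),
        mass_weighted=bool(int(meta.get("mass_weighted", "0"))),
    )


def write_nmd(ms: ModeSet, path: str | Path, n_modes: int = 10) -> None:
    """NMD-style export (viewer compatibility): coordinates line + one
    ``mode`` line per nontrivial mode, scaled by inverse sqrt eigenvalue."""
    src = ms.source
    with open(path, "w") as fh:
        fh.write("nmwiz_load modetrap.nmd\n")
        fh.write("name modetrap_modes\n")
        if src is not None and ms.atom_indices is not None:
            sub = src.subset(ms.atom_indices)
            fh.write("resnames " + " ".join(map(str, sub.residue_name)) + "\n")
            fh.write("resids " + " ".join(map(str, sub.residue_id)) + "\n")
            fh.write("atomnames " + " ".join(map(str, sub.name)) + "\n")
            coords = sub.coords.ravel()
        elif src is not None:
            coords = src.coords.ravel()
        else:
            coords = np.zeros(ms.n_modes)
        fh.write("coordinates " + " ".join(f"{x:.3f}" for x in coords) + "\n")
        first = ms.n_trivial
        last = min(ms.n_modes, first + n_modes)
        for idx in range(first, last):
            ev = ms.eigenvalues[idx]
            scale = 1.0 / np.sqrt(ev) if ev > 0 else 1.0
            vec = ms.eigenvectors[:, idx]
            fh.write(
                f"mode {idx + 1} {scale:.6g} "
                + " ".join(f"{x:.6f}" for x in vec)
                + "\n"
            )
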