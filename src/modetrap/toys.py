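"""Synthetic test systems and a desk-scale conformational sampler.

These generators stand in for a real protein (crystal structure + long MD)
so the whole displace–relax–design–evaluate loop runs in seconds:

* :func:`make_helix` — ideal α-helix Cα trace (geometry oracle, connected
  ENM fixture);
* :func:`make_linear_triatomic` — three collinear beads, the analytic
  eigensolver oracle (a central-force network on a line has *seven* zero
  modes: 3 translations, 2 rotations, and 2 bending modes with no
  harmonic restoring force; the nontrivial longitudinal eigenvalues are
  k and 3k for unit masses);
* :func:`make_two_domain` — two compact Cα clusters bridged by a
  double-strand zigzag linker below an open cleft.  The softest genuine
  mode (mode 7) is the cleft scissor motion, verified at construction by
  projecting the probe-separation direction onto the low modes;
* :func:`sample_landscape` — Metropolis sampling in normal-mode
  coefficient space over a harmonic-plus-contact energy, the equilibrium
  stand-in for MD used to test whether designed sequences shift the cleft
  distance distribution in the intended direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence as TypingSequence

import numpy as np
from scipy.spatial.distance import pdist

from .design import (
    AA_ORDER,
    ContactDefinition,
    ContactEnergyModel,
    Sequence,
    load_energy_matrix,
    switching_weight,
)
from .dynamics import TrajectoryEnsemble
from .enm import ENMPreset, ModeSet, build_network, diagonalize
from .structure import Structure, structure_from_arrays


class ToyError(ValueError):
    pass


@dataclass
class ToySystem:
    """A synthetic structure with a known cleft and hinge mode."""

    structure: Structure
    probe_pair: tuple[int, int]          # author residue ids across the cleft
    expected_hinge_mode: int = 7
    analytic_data: dict = field(default_factory=dict)


@dataclass(frozen=True)
class SamplerConfig:
    """Metropolis walk controls (coefficient space, Å per mode)."""

    seed: int
    kT: float = 0.01                 # model energy units
    step_sigma: float = 1.5          # Å in mode-coefficient space
    n_steps: int = 30_000
    burn_in: int = 2_000
    thin: int = 20
    mode_subspace: tuple[int, ...] = (7, 8, 9)

    def __post_init__(self) -> None:
        if self.kT <= 0:
            raise ToyError("kT must be > 0")
        if self.n_steps <= self.burn_in:
            raise ToyError("n_steps must exceed burn_in")
        if self.thin < 1 or self.step_sigma <= 0:
            raise ToyError("thin >= 1 and step_sigma > 0 required")


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

#: Default residue-letter cycle for toy systems: neutral-polar letters only
#: (no formal charges, no strong hydrophobics), so the undesigned landscape
#: carries no strong sequence-driven bias for the design stage to compete with.
_TOY_LETTER_CYCLE = "NTSGQASTQG"


def _cycle_letters(n: int) -> list[str]:
    return [_TOY_LETTER_CYCLE[i % len(_TOY_LETTER_CYCLE)] for i in range(n)]


def make_helix(n_res: int) -> Structure:
    """Ideal α-helix Cα trace: rise 1.5 Å, 100°/residue, radius 2.3 Å."""
    if n_res < 4:
        raise ToyError("need at least 4 residues for a helix")
    i = np.arange(n_res)
    t = np.deg2rad(100.0) * i
    coords = np.c_[2.3 * np.cos(t), 2.3 * np.sin(t), 1.5 * i]
    from .structure import ONE_TO_THREE

    return structure_from_arrays(
        coords,
        residue_names=[ONE_TO_THREE[a] for a in _cycle_letters(n_res)],
        provenance="make_helix",
    )


def _domain_points(n: int, spacing: float = 3.8) -> np.ndarray:
    """Compact blob: the n cubic-lattice points closest to the origin."""
    rng = range(-3, 4)
    pts = np.array(
        [[i, j, k] for i in rng for j in rng for k in rng], dtype=float
    ) * spacing
    order = np.argsort(np.linalg.norm(pts, axis=1) + 1e-6 * np.arange(len(pts)))
    return pts[order[:n]]


def make_two_domain(
    n_per_domain: int = 12,
    linker_len: int = 4,
    jitter: float = 0.0,
    seed: int = 0,
) -> ToySystem:
    """Two compact Cα clusters over a double-strand linker, cleft on top.

    The linker strands sit below the cleft at y = ±2.5 Å with alternating
    ±1.2 Å z-zigzag (so no bead has collinear neighbors and the network has
    exactly six zero modes).  The cleft width adapts to the linker length —
    longer linkers can brace a wider cleft.  The probe pair is the topmost
    bead of each domain; the in-plane scissor motion that opens and closes
    their separation is the softest genuine mode, which is verified by
    projecting the separation direction onto modes 7–12 and recorded in
    ``analytic_data['probe_sensitivity']``.

    ``jitter`` adds deterministic Gaussian coordinate noise (Å) so one call
    site can build a family of structurally distinct systems; everything is
    reproducible from the arguments.
    """
    if n_per_domain < 8:
        raise ToyError("need n_per_domain >= 8")
    if linker_len < 2:
        raise ToyError("need linker_len >= 2")
    d0 = _domain_points(n_per_domain)
    radius = float(np.linalg.norm(d0, axis=1).max())
    cleft = 11.0 if linker_len >= 6 else (8.0 if linker_len >= 4 else 6.0)
    gap = 2 * radius + cleft
    left = d0 + np.array([-gap / 2, 0.0, 0.0])
    right = d0 + np.array([+gap / 2, 0.0, 0.0])
    n_a = (linker_len + 1) // 2
    n_b = linker_len // 2

    def strand(n2: int, y: float, flip: int) -> np.ndarray:
        if n2 == 0:
            return np.zeros((0, 3))
        span = min(4.0 * (n2 - 1), gap - 8.0)
        xs = np.linspace(-span / 2, span / 2, n2) if n2 > 1 else np.array([0.0])
        zz = -6.0 + 1.2 * (-1.0) ** (np.arange(n2) + flip)
        return np.c_[xs, np.full(n2, y), zz]

    # protruding cleft probes: one bead per domain, raised above the top
    # bead and leaning into the cleft — few intra-domain contacts, so their
    # identity is dominated by what (if anything) they touch across the cleft
    top_l = int(np.argmax(left[:, 2]))
    top_r = int(np.argmax(right[:, 2]))
    # probes lean into the cleft, but never closer than the ENM cutoff —
    # a direct tip-tip spring would stiffen the very hinge they report on
    tip_sep = max(cleft + 0.3, 10.5)
    tip_in = (right[top_r][0] - left[top_l][0] - tip_sep) / 2.0
    tip_l = left[top_l] + np.array([+tip_in, 0.0, 3.0])
    tip_r = right[top_r] + np.array([-tip_in, 0.0, 3.0])
    coords = np.vstack(
        [left, strand(n_a, 2.5, 0), strand(n_b, -2.5, 1), right, tip_l, tip_r]
    )
    if jitter > 0:
        rng = np.random.default_rng(seed)
        coords = coords + jitter * rng.standard_normal(coords.shape)
    n = coords.shape[0]
    ia, ib = n - 2, n - 1
    from .structure import ONE_TO_THREE

    letters = _cycle_letters(n)
    letters[ia] = letters[ib] = "L"  # sticky cleft faces: the wild type genuinely closes
    s = structure_from_arrays(
        coords,
        residue_names=[ONE_TO_THREE[a] for a in letters],
        provenance=f"make_two_domain({n_per_domain},{linker_len},{jitter},{seed})",
    )
    sys_ = ToySystem(
        structure=s,
        probe_pair=(ia + 1, ib + 1),  # residue ids are 1-based ordinals
        expected_hinge_mode=7,
    )
    # verification: how strongly each low mode moves the probe separation
    net = build_network(s, ENMPreset())
    ms = diagonalize(net)
    u = coords[ib] - coords[ia]
    u = u / np.linalg.norm(u)
    sens = {}
    for k in range(7, min(13, ms.n_modes + 1)):
        v = ms.eigenvectors[:, k - 1].reshape(-1, 3)
        sens[k] = float(abs((v[ib] - v[ia]) @ u))
    sys_.analytic_data["probe_sensitivity"] = sens
    sys_.analytic_data["n_trivial"] = ms.n_trivial
    sys_.analytic_data["connected"] = net.connected
    sys_.analytic_data["probe_distance"] = float(
        np.linalg.norm(coords[ib] - coords[ia])
    )
    return sys_


def make_linear_triatomic(k: float = 1.0, m: float = 1.0) -> ToySystem:
    """Three collinear unit-spaced beads with two springs — eigen oracle.

    ``analytic_data['eigenvalues']`` holds the closed-form spectrum of the
    central-force Hessian (unit masses): seven zeros and {k, 3k}.
    """
    if k <= 0 or m <= 0:
        raise ToyError("k and m must be positive")
    spacing = 3.8
    coords = np.array([[0.0, 0, 0], [spacing, 0, 0], [2 * spacing, 0, 0]])
    s = structure_from_arrays(coords, provenance="make_linear_triatomic")
    analytic = {
        "eigenvalues": np.array([0.0] * 7 + [k, 3 * k]),
        "eigenvalues_mass_weighted": np.array([0.0] * 7 + [k / m, 3 * k / m]),
        "preset": ENMPreset(kind="cutoff", cutoff=1.5 * spacing, force_constant=k),
        "mass": m,
    }
    return ToySystem(
        structure=s,
        probe_pair=(1, 3),
        expected_hinge_mode=8,  # first nontrivial is index 8 here (7 zeros)
        analytic_data=analytic,
    )


# ---------------------------------------------------------------------------
# Toy contact model
# ---------------------------------------------------------------------------

def toy_contact_model(
    scale: float = 0.04,
    cutoff: float = 6.5,
    switch_width: float = 1.5,
) -> ContactEnergyModel:
    """The rank-two potential reweighted for Cα-bead toys.

    The representative atom is Cα (the only atom) with a 6.5 Å cutoff
    and a wide 1.5 Å switching region (Cα beads on a ~3.8 Å lattice).
    Relative to the shipped all-atom default, charge interactions and the
    burial cost are emphasized (charge weight 1.2, burial cost 1.5) so that
    sparsely contacted surface beads genuinely prefer polar identities —
    the regime in which redesign of a cleft face can either create a salt
    bridge across it or armor it with like charges.  ``scale`` converts
    contact units into a few sampler kT so both basins of a cleft stay
    thermally accessible.
    """
    from .design import build_rank2_contact_model

    return build_rank2_contact_model(
        hydrophobic_weight=1.0,
        charge_weight=1.2,
        burial_cost=1.5,
        contact_definition=ContactDefinition(
            representative="CA", cutoff=cutoff, switch_width=switch_width
        ),
        scale=scale,
    )


# ---------------------------------------------------------------------------
# Mode-space Metropolis sampler
# ---------------------------------------------------------------------------

def sample_landscape(
    sys_: ToySystem | Structure,
    ms: ModeSet,
    seq: Sequence | None,
    model: ContactEnergyModel | None,
    cfg: SamplerConfig,
    hessian_weight: float = 1.0,
) -> TrajectoryEnsemble:
    """Equilibrium Metropolis walk in normal-mode coefficient space.

    Conformations are ``x(c) = x_ref + Σ_k c_k v_k`` over the configured
    mode subspace, with energy

        E(c) = hessian_weight · ½ Σ_k κ_k c_k²  +  U_contact(x(c) | seq)

    (the contact term is omitted when ``seq`` or ``model`` is None, leaving
    the exactly-solvable harmonic landscape).  Proposals perturb all
    subspace coefficients by independent Gaussians of width ``step_sigma``;
    frames are emitted after ``burn_in`` at the ``thin`` interval.  Same
    seed, same inputs → identical ensemble.
    """
    s = sys_.structure if isinstance(sys_, ToySystem) else sys_
    for k in cfg.mode_subspace:
        if ms.is_trivial(k):
            raise ToyError(f"mode {k} is trivial; sampling subspace must be genuine")
    kappas = np.array([ms.eigenvalue(k) for k in cfg.mode_subspace])
    vs = np.stack([ms.eigenvectors[:, k - 1] for k in cfg.mode_subspace], axis=1)
    x_ref = s.coords.copy()
    n_atoms = x_ref.shape[0]

    use_contact = seq is not None and model is not None
    if use_contact:
        from .design import representative_coords

        idx = seq.as_indices()
        if len(seq) != s.n_residues:
            raise ToyError("sequence length must equal residue count")
        # Cα-bead toys: every atom is its residue representative, so the
        # pair energies can be fixed once and only weights recomputed.
        if n_atoms != s.n_residues:
            raise ToyError("sampler requires one-bead-per-residue structures")
        iu = np.triu_indices(n_atoms, k=1)
        eps_cond = model.pair_matrix[idx[iu[0]], idx[iu[1]]]
        mu_sum = float(model.reference_energies[idx].sum())
        cd = model.contact_definition

        def contact_u(x: np.ndarray) -> float:
            w = switching_weight(pdist(x), cd)
            return float(eps_cond @ w) + mu_sum
    else:
        def contact_u(x: np.ndarray) -> float:
            return 0.0

    def energy(c: np.ndarray) -> float:
        e = hessian_weight * 0.5 * float(kappas @ (c * c))
        if use_contact:
            x = x_ref + (vs @ c).reshape(n_atoms, 3)
            e += contact_u(x)
        return e

    rng = np.random.default_rng(cfg.seed)
    c = np.zeros(len(cfg.mode_subspace))
    e = energy(c)
    if not np.isfinite(e):
        raise ToyError("non-finite energy at the starting conformation")
    frames: list[np.ndarray] = []
    coeff_trace: list[np.ndarray] = []
    n_acc = 0
    for step in range(cfg.n_steps):
        prop = c + cfg.step_sigma * rng.standard_normal(len(c))
        e_prop = energy(prop)
        if e_prop <= e or rng.random() < np.exp(-(e_prop - e) / cfg.kT):
            c, e = prop, e_prop
            n_acc += 1
        if step >= cfg.burn_in and (step - cfg.burn_in) % cfg.thin == 0:
            frames.append(x_ref + (vs @ c).reshape(n_atoms, 3))
            coeff_trace.append(c.copy())
    ens = TrajectoryEnsemble(
        topology=s,
        coords=np.array(frames),
        frame_interval=float(cfg.thin),
    )
    ens.metadata = {  # type: ignore[attr-defined]
        "acceptance_rate": n_acc / cfg.n_steps,
        "mode_subspace": list(cfg.mode_subspace),
        "coefficients": np.array(coeff_trace),
        "kT": cfg.kT,
        "hessian_weight": hessian_weight,
        "seed": cfg.seed,
    }
    return ens
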