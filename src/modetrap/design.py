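"""Fixed-backbone Monte Carlo sequence design on a contact potential.

The sequence-dependent energy of a conformation R with sequence M is

    U(R | M) = Σ_{i<j} ε(aᵢ, aⱼ) · w(dᵢⱼ)  +  Σᵢ μ(aᵢ)

where dᵢⱼ is the distance between residue representative atoms (Cβ, falling
back to Cα), w is 1 inside ``cutoff − width`` and cosine-switched to 0 at
``cutoff``, ε is a symmetric 20×20 residue-pair contact matrix and μ a
per-residue reference energy.  Because the backbone is fixed, the contact
weights never change during design: optimizing the sequence is a discrete
search over 20^L letters, done here by staged Metropolis Monte Carlo with
single-position substitution moves followed by a deterministic greedy
quench (which also makes the all-ties case reproducible: ties resolve to
the lexicographically first letter).

Designing a sequence for a displaced-and-relaxed conformation R_opt and
comparing U(R_opt|·) and U(R_min|·) between the wild-type and engineered
sequences classifies the outcome as an energy-landscape *trap* (the
displaced basin becomes the deeper minimum for the new sequence) or
*smoothing* (the two basins level out), the two scenarios the displacement
design can produce.

The shipped default matrix (``data/contact_hydrophobic_synthetic.txt``) is a
synthetic rank-two statistical potential built from the Kyte–Doolittle
hydrophobicity scale plus a formal-charge pair term; any user 20×20 matrix
in the same whitespace-delimited format can be loaded instead.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence as TypingSequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .structure import PairingError, Structure, StructureError

#: Canonical amino-acid ordering for all 20-vectors/matrices in this module.
AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}

DEFAULT_MATRIX_RESOURCE = "contact_hydrophobic_synthetic.txt"

#: Kyte-Doolittle hydropathy (positive = hydrophobic).
KD_HYDROPATHY = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}

#: Formal side-chain charge at neutral pH (His half-protonated).
FORMAL_CHARGE = {"D": -1.0, "E": -1.0, "K": 1.0, "R": 1.0, "H": 0.5}


class DesignError(ValueError):
    pass


@dataclass(frozen=True)
class Sequence:
    """One-letter amino-acid string with parallel author residue numbering."""

    letters: str
    numbering: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        bad = set(self.letters) - set(AA_ORDER) - {"X"}
        if bad:
            raise DesignError(f"non-standard letters {sorted(bad)}")
        if self.numbering is not None:
            numbering = tuple(int(x) for x in self.numbering)
            if len(numbering) != len(self.letters):
                raise DesignError("numbering must parallel letters")
            object.__setattr__(self, "numbering", numbering)

    def __len__(self) -> int:
        return len(self.letters)

    def __getitem__(self, i: int) -> str:
        return self.letters[i]

    def letter_at(self, residue_id: int) -> str:
        """Letter at an author residue id (requires numbering)."""
        if self.numbering is None:
            raise DesignError("sequence has no numbering")
        try:
            return self.letters[self.numbering.index(residue_id)]
        except ValueError as exc:
            raise DesignError(f"residue id {residue_id} not in numbering") from exc

    def with_letter(self, pos: int, letter: str) -> "Sequence":
        letters = self.letters[:pos] + letter + self.letters[pos + 1:]
        return Sequence(letters=letters, numbering=self.numbering)

    def as_indices(self) -> np.ndarray:
        return np.array([AA_INDEX[a] for a in self.letters], dtype=int)

    def to_fasta(self, path: str | Path, header: str = "sequence") -> None:
        with open(path, "w") as fh:
            fh.write(f">{header}\n")
            for i in range(0, len(self.letters), 60):
                fh.write(self.letters[i:i + 60] + "\n")

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Sequence":
        letters: list[str] = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(">"):
                    continue
                letters.append(line)
        if not letters:
            raise DesignError(f"no sequence in {path}")
        return cls(letters="".join(letters))


@dataclass(frozen=True)
class ContactDefinition:
    """How residue-residue contacts are measured on the backbone."""

    representative: str = "CB-or-CA"  # Cβ per residue, Cα fallback (always Gly)
    cutoff: float = 6.5               # Å, weight reaches 0 here
    switch_width: float = 1.0         # Å, cosine switching region

    def __post_init__(self) -> None:
        if not 0 < self.switch_width <= self.cutoff:
            raise DesignError("need 0 < switch_width <= cutoff")


@dataclass
class ContactEnergyModel:
    """Symmetric 20×20 pair matrix + per-residue reference energies."""

    pair_matrix: np.ndarray                    # (20, 20), AA_ORDER indexed
    reference_energies: np.ndarray             # (20,)
    contact_definition: ContactDefinition = field(default_factory=ContactDefinition)
    name: str = "custom"

    def __post_init__(self) -> None:
        self.pair_matrix = np.asarray(self.pair_matrix, dtype=float)
        self.reference_energies = np.asarray(self.reference_energies, dtype=float)
        if self.pair_matrix.shape != (20, 20):
            raise DesignError("pair_matrix must be 20x20")
        if self.reference_energies.shape != (20,):
            raise DesignError("reference_energies must have length 20")
        if not np.all(np.isfinite(self.pair_matrix)):
            raise DesignError("pair_matrix entries must be finite")
        if not np.allclose(self.pair_matrix, self.pair_matrix.T, atol=1e-9):
            raise DesignError("pair_matrix must be symmetric")


def load_energy_matrix(
    path: str | Path | None = None,
    contact_definition: ContactDefinition | None = None,
) -> ContactEnergyModel:
    """Load a whitespace-delimited 20×20 matrix with a one-letter header row.

    An optional ``REF`` row supplies per-residue reference energies
    (defaults to zero).  ``path=None`` loads the shipped synthetic
    hydrophobicity–charge matrix.
    """
    if path is None:
        ref = importlib.resources.files("modetrap.data") / DEFAULT_MATRIX_RESOURCE
        text = ref.read_text()
        name = DEFAULT_MATRIX_RESOURCE
    else:
        text = Path(path).read_text()
        name = Path(path).name
    header: list[str] | None = None
    rows: dict[str, list[float]] = {}
    ref_row: list[float] | None = None
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if header is None:
            header = parts
            if sorted(header) != sorted(AA_ORDER):
                raise DesignError("header must list the 20 one-letter codes")
            continue
        if parts[0] == "REF":
            ref_row = [float(x) for x in parts[1:]]
            continue
        rows[parts[0]] = [float(x) for x in parts[1:]]
    if header is None or len(rows) != 20:
        raise DesignError("matrix file must contain a header and 20 rows")
    mat = np.zeros((20, 20))
    for a, values in rows.items():
        if len(values) != 20:
            raise DesignError(f"row {a} has {len(values)} entries")
        for b, v in zip(header, values):
            mat[AA_INDEX[a], AA_INDEX[b]] = v
    refs = np.zeros(20)
    if ref_row is not None:
        if len(ref_row) != 20:
            raise DesignError("REF row must have 20 entries")
        for b, v in zip(header, ref_row):
            refs[AA_INDEX[b]] = v
    return ContactEnergyModel(
        pair_matrix=mat,
        reference_energies=refs,
        contact_definition=contact_definition or ContactDefinition(),
        name=name,
    )


def build_rank2_contact_model(
    hydrophobic_weight: float = 1.0,
    charge_weight: float = 0.5,
    burial_cost: float = 0.6,
    contact_definition: ContactDefinition | None = None,
    scale: float = 1.0,
) -> ContactEnergyModel:
    """Construct the synthetic rank-two potential with explicit weights.

    With φ_a = (KD_a/4.5 + 1)/2 ∈ [0, 1] (0 = most polar) and q_a the
    formal charge,

        ε(a,b) = scale · (−hydrophobic_weight·φ_a φ_b + charge_weight·q_a q_b)
        μ(a)   = scale · burial_cost · φ_a

    so hydrophobic burial and salt bridges attract, like charges repel, and
    exposing hydrophobic residues costs energy.  The shipped data file is
    this model at the default weights.
    """
    phi = np.array([(KD_HYDROPATHY[a] / 4.5 + 1.0) / 2.0 for a in AA_ORDER])
    q = np.array([FORMAL_CHARGE.get(a, 0.0) for a in AA_ORDER])
    eps = -hydrophobic_weight * np.outer(phi, phi) + charge_weight * np.outer(q, q)
    mu = burial_cost * phi
    return ContactEnergyModel(
        pair_matrix=eps * scale,
        reference_energies=mu * scale,
        contact_definition=contact_definition or ContactDefinition(),
        name=(
            f"rank2(hw={hydrophobic_weight},cw={charge_weight},"
            f"bc={burial_cost},x{scale})"
        ),
    )


# ---------------------------------------------------------------------------
# Contact geometry
# ---------------------------------------------------------------------------

def representative_coords(s: Structure, cd: ContactDefinition) -> np.ndarray:
    """(L, 3) representative-atom coordinates, one per residue."""
    res_index = s.residue_index()
    n_res = res_index.max() + 1 if len(s) else 0
    coords = np.full((n_res, 3), np.nan)
    names = s.name.astype(str)
    if cd.representative in ("CB-or-CA", "CB"):
        primary, fallback = "CB", "CA"
    elif cd.representative == "CA":
        primary, fallback = "CA", None
    else:
        raise DesignError(f"unknown representative {cd.representative!r}")
    for i in range(len(s)):
        r = res_index[i]
        if names[i] == primary:
            coords[r] = s.coords[i]
        elif fallback and names[i] == fallback and np.isnan(coords[r, 0]):
            coords[r] = s.coords[i]
    if np.isnan(coords).any():
        missing = np.flatnonzero(np.isnan(coords[:, 0]))
        raise StructureError(
            f"residues without a representative atom: ordinals {missing.tolist()}"
        )
    return coords


def switching_weight(d: np.ndarray, cd: ContactDefinition) -> np.ndarray:
    """1 inside cutoff−width, cosine-switched to 0 at cutoff."""
    d = np.asarray(d, dtype=float)
    inner = cd.cutoff - cd.switch_width
    w = np.zeros_like(d)
    w[d <= inner] = 1.0
    ramp = (d > inner) & (d < cd.cutoff)
    w[ramp] = 0.5 * (1.0 + np.cos(np.pi * (d[ramp] - inner) / cd.switch_width))
    return w


@dataclass
class ContactMap:
    """Fixed-backbone contact weights, precomputed once per conformation."""

    pair_i: np.ndarray       # (M,) residue ordinals, i < j
    pair_j: np.ndarray
    weights: np.ndarray      # (M,) in (0, 1]
    n_residues: int
    neighbor_lists: list[np.ndarray] | None = None  # per residue: rows of pairs

    @classmethod
    def from_structure(
        cls,
        s: Structure,
        cd: ContactDefinition,
        neighbor_radius: float | None = None,
    ) -> "ContactMap":
        rep = representative_coords(s, cd)
        n = rep.shape[0]
        if n < 2:
            return cls(
                pair_i=np.zeros(0, dtype=int),
                pair_j=np.zeros(0, dtype=int),
                weights=np.zeros(0),
                n_residues=n,
            )
        d = pdist(rep)
        iu = np.triu_indices(n, k=1)
        w = switching_weight(d, cd)
        limit = neighbor_radius if neighbor_radius is not None else cd.cutoff
        keep = (w > 0) & (d <= limit)
        pi, pj, w = iu[0][keep], iu[1][keep], w[keep]
        nb: list[list[int]] = [[] for _ in range(n)]
        for row, (a, b) in enumerate(zip(pi, pj)):
            nb[a].append(row)
            nb[b].append(row)
        return cls(
            pair_i=pi,
            pair_j=pj,
            weights=w,
            n_residues=n,
            neighbor_lists=[np.array(r, dtype=int) for r in nb],
        )


def contact_energy(
    s: Structure, m: Sequence, model: ContactEnergyModel
) -> float:
    """U(R | M) for one conformation and one sequence."""
    cmap = ContactMap.from_structure(s, model.contact_definition)
    return contact_energy_from_map(cmap, m, model)


def contact_energy_from_map(
    cmap: ContactMap, m: Sequence, model: ContactEnergyModel
) -> float:
    if len(m) != cmap.n_residues:
        raise PairingError(
            f"sequence length {len(m)} != residue count {cmap.n_residues}"
        )
    idx = m.as_indices()
    e_pairs = model.pair_matrix[idx[cmap.pair_i], idx[cmap.pair_j]]
    return float(e_pairs @ cmap.weights + model.reference_energies[idx].sum())


# ---------------------------------------------------------------------------
# Monte Carlo design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DesignConfig:
    """Controls for :func:`mc_design`.

    ``neighbor_radius`` limits which pair terms are re-evaluated when a
    position mutates; with the default 10 Å (≥ contact cutoff) incremental
    updates are exact.  Two independent designs per conformation are simply
    two seeds.
    """

    seed: int
    designable_positions: tuple[int, ...] | None = None  # author residue ids
    schedule: tuple[tuple[float, int], ...] = ((1.0, 2000), (0.3, 2000), (0.1, 2000))
    neighbor_radius: float = 10.0
    final_quench: bool = True

    def __post_init__(self) -> None:
        for kt, n in self.schedule:
            if kt <= 0 or n <= 0:
                raise DesignError("schedule entries need kT > 0 and n_steps > 0")


@dataclass
class DesignResult:
    final_sequence: Sequence          # state at the end of the MC chain
    best_sequence: Sequence           # lowest-energy sequence found (M_eng)
    initial_energy: float
    final_energy: float
    best_energy: float
    energy_trace: np.ndarray          # energy after every accepted move
    acceptance_rate: float
    mutations: list[tuple[int, str, str]]  # (author residue id, wt, new)
    seed: int
    metadata: dict = field(default_factory=dict)


def _delta_u(
    cmap: ContactMap,
    model: ContactEnergyModel,
    idx: np.ndarray,
    pos: int,
    new_aa: int,
) -> float:
    """Incremental energy change for substituting position ``pos``."""
    old_aa = idx[pos]
    if new_aa == old_aa:
        return 0.0
    rows = cmap.neighbor_lists[pos]
    du = float(
        model.reference_energies[new_aa] - model.reference_energies[old_aa]
    )
    if rows.size:
        partners = np.where(cmap.pair_i[rows] == pos, cmap.pair_j[rows], cmap.pair_i[rows])
        p_idx = idx[partners]
        du += float(
            (
                model.pair_matrix[new_aa, p_idx]
                - model.pair_matrix[old_aa, p_idx]
            )
            @ cmap.weights[rows]
        )
    return du


def _greedy_quench(
    cmap: ContactMap,
    model: ContactEnergyModel,
    idx: np.ndarray,
    designable: np.ndarray,
    max_sweeps: int = 50,
) -> np.ndarray:
    """Deterministic coordinate descent; ties go to the lexicographically
    first letter (which is index order, since AA_ORDER is alphabetical)."""
    idx = idx.copy()
    for _ in range(max_sweeps):
        changed = False
        for pos in designable:
            deltas = np.array(
                [_delta_u(cmap, model, idx, int(pos), aa) for aa in range(20)]
            )
            best = int(np.argmin(deltas))  # first minimum = lexicographic tie-break
            improves = deltas[best] < -1e-12
            tie_to_earlier = abs(deltas[best]) <= 1e-12 and best < idx[pos]
            if (improves or tie_to_earlier) and best != idx[pos]:
                idx[pos] = best
                changed = True
        if not changed:
            break
    return idx


def mc_design(
    s: Structure,
    m0: Sequence,
    model: ContactEnergyModel,
    cfg: DesignConfig,
) -> DesignResult:
    """Optimize the sequence for a fixed conformation by Metropolis MC.

    Single-position substitution proposals (uniform over the 19
    alternatives) with staged temperatures, incremental ΔU over the
    neighbor lists, best-so-far tracking and an optional deterministic
    greedy quench from the best state.  Identical seed and inputs give
    identical output.
    """
    cmap = ContactMap.from_structure(
        s, model.contact_definition, neighbor_radius=cfg.neighbor_radius
    )
    if len(m0) != cmap.n_residues:
        raise PairingError(
            f"sequence length {len(m0)} != residue count {cmap.n_residues}"
        )
    numbering = (
        m0.numbering
        if m0.numbering is not None
        else tuple(int(r) for (_, r, _) in s.residue_keys())
    )
    m0 = Sequence(letters=m0.letters, numbering=numbering)
    if cfg.designable_positions is None:
        designable = np.arange(cmap.n_residues)
    else:
        id_to_ord = {rid: i for i, rid in enumerate(numbering)}
        missing = [p for p in cfg.designable_positions if p not in id_to_ord]
        if missing:
            raise DesignError(f"designable positions absent from structure: {missing}")
        designable = np.array(
            sorted(id_to_ord[p] for p in cfg.designable_positions), dtype=int
        )

    rng = np.random.default_rng(cfg.seed)
    idx = m0.as_indices()
    u = contact_energy_from_map(cmap, m0, model)
    u0 = u
    best_idx, best_u = idx.copy(), u
    trace = [u]
    n_prop = n_acc = 0
    for kt, n_steps in cfg.schedule:
        for _ in range(n_steps):
            pos = int(designable[rng.integers(len(designable))])
            new_aa = int(rng.integers(19))
            if new_aa >= idx[pos]:
                new_aa += 1
            du = _delta_u(cmap, model, idx, pos, new_aa)
            n_prop += 1
            if du <= 0 or rng.random() < np.exp(-du / kt):
                idx[pos] = new_aa
                u += du
                n_acc += 1
                trace.append(u)
                if u < best_u - 1e-12:
                    best_u, best_idx = u, idx.copy()

    final_seq = Sequence(
        letters="".join(AA_ORDER[a] for a in idx), numbering=numbering
    )
    if cfg.final_quench:
        best_idx = _greedy_quench(cmap, model, best_idx, designable)
    best_seq = Sequence(
        letters="".join(AA_ORDER[a] for a in best_idx), numbering=numbering
    )
    best_u = contact_energy_from_map(cmap, best_seq, model)
    mutations = [
        (numbering[i], a, b)
        for i, (a, b) in enumerate(zip(m0.letters, best_seq.letters))
        if a != b
    ]
    return DesignResult(
        final_sequence=final_seq,
        best_sequence=best_seq,
        initial_energy=u0,
        final_energy=u,
        best_energy=best_u,
        energy_trace=np.array(trace),
        acceptance_rate=n_acc / max(n_prop, 1),
        mutations=mutations,
        seed=cfg.seed,
        metadata={
            "neighbor_radius": cfg.neighbor_radius,
            "schedule": list(cfg.schedule),
            "matrix": model.name,
            "note": "neighbor_radius limits incremental pair re-evaluation "
                    "(side-chain repacking has no coarse-grained analogue)",
        },
    )


# ---------------------------------------------------------------------------
# Landscape classification
# ---------------------------------------------------------------------------

def classify_landscape(
    u_opt_wt: float,
    u_opt_eng: float,
    u_min_wt: float,
    u_min_eng: float,
    tol: float = 0.5,
) -> str:
    """Classify a design outcome as ``'trap'``, ``'smoothing'`` or ``'neither'``.

    With U(R_opt|·) the energy at the displaced local minimum and U(R_min|·)
    at the original one:

    * **trap** — the engineered sequence stabilizes the displaced basin
      below the wild-type value *and* makes it the deeper of its own two
      basins: ``u_opt_eng < u_opt_wt`` and ``u_opt_eng < u_min_eng − tol``;
    * **smoothing** — the engineered sequence levels the basins:
      ``u_opt_eng < u_opt_wt`` and ``|u_opt_eng − u_min_eng| ≤ tol``;
    * **neither** otherwise.

    The boundary is an adopted interpretation of the two scenarios (deeper
    displaced minimum vs. leveled landscape) and ``tol`` is configurable.
    """
    vals = [u_opt_wt, u_opt_eng, u_min_wt, u_min_eng, tol]
    if not all(np.isfinite(v) for v in vals):
        raise ValueError("all energies must be finite")
    if u_opt_eng < u_opt_wt and u_opt_eng < u_min_eng - tol:
        return "trap"
    if u_opt_eng < u_opt_wt and abs(u_opt_eng - u_min_eng) <= tol:
        return "smoothing"
    return "neither"


# ---------------------------------------------------------------------------
# Mutation reporting
# ---------------------------------------------------------------------------

def mutation_report(
    wt: Sequence,
    designs: Mapping[str, Sequence],
    groups: Mapping[str, Iterable[str]] | None = None,
) -> pd.DataFrame:
    """Per-position comparison of designed sequences against the wild type.

    ``groups`` maps a group label (e.g. ``"OP"``, ``"CL"``) to design
    labels; when omitted, groups are inferred from leading alphabetic
    prefixes of the design labels.  Flags:

    * ``group_specific`` — every group converged on its own non-wt letter
      and at least two groups disagree (e.g. both open designs pick D where
      both closed designs pick K);
    * ``global_convergence`` — all designs share one non-wt letter.
    """
    labels = list(designs)
    for lab in labels:
        if len(designs[lab]) != len(wt):
            raise DesignError(f"design {lab!r} length differs from wild type")
    if groups is None:
        inferred: dict[str, list[str]] = {}
        for lab in labels:
            prefix = "".join(ch for ch in lab if ch.isalpha()) or lab
            inferred.setdefault(prefix, []).append(lab)
        groups = inferred
    rows = []
    numbering = wt.numbering or tuple(range(1, len(wt) + 1))
    for i, rid in enumerate(numbering):
        letters = {lab: designs[lab].letters[i] for lab in labels}
        wt_letter = wt.letters[i]
        any_mut = any(v != wt_letter for v in letters.values())
        per_group = {
            g: {letters[lab] for lab in members}
            for g, members in groups.items()
        }
        group_conv = {
            g: next(iter(v)) if len(v) == 1 else None for g, v in per_group.items()
        }
        group_specific = (
            all(v is not None and v != wt_letter for v in group_conv.values())
            and len(set(group_conv.values())) > 1
        )
        global_conv = (
            len(set(letters.values())) == 1
            and next(iter(letters.values())) != wt_letter
        )
        rows.append(
            {
                "residue_id": rid,
                "wt": wt_letter,
                **letters,
                "mutated": any_mut,
                "group_specific": group_specific,
                "global_convergence": global_conv,
            }
        )
    return pd.DataFrame(rows)
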