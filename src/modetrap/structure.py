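"""Protein structure container, PDB I/O, atom selection, superposition and RMSD.

The :class:`Structure` is a light array-of-records container over parallel
numpy arrays (one entry per heavy atom).  File I/O goes through biotite's
fixed-width PDB reader/writer; everything downstream (elastic networks,
displacement, relaxation, ensemble analysis) consumes this one container.

Conventions adopted here and relied on elsewhere:

* residue numbering is the author numbering of the source PDB file
  (no renumbering), with insertion codes part of the residue identity;
* hydrogens, waters and HETATM ligands are excluded on read — the elastic
  network and the contact potential are heavy-atom models;
* alternate locations are resolved to the first listed conformer.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence as TypingSequence

import numpy as np

logger = logging.getLogger(__name__)

#: 3-letter -> 1-letter codes for the 20 standard amino acids.
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}
STANDARD_RESIDUES = frozenset(THREE_TO_ONE)


class StructureError(ValueError):
    """Base class for structure-level errors."""


class EmptyStructureError(StructureError):
    """Raised when a file or selection yields no atoms."""


class PairingError(StructureError):
    """Raised when two structures that must match atom-for-atom do not."""


class SelectionError(StructureError):
    """Raised for selections that match nothing or reference absent atoms."""


@dataclass(frozen=True)
class AtomRecord:
    """One heavy atom of a protein structure."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_id: int
    insertion_code: str
    chain_id: str
    position: np.ndarray  # (3,) Å
    occupancy: float = 1.0
    altloc: str = ""


@dataclass
class Structure:
    """An ordered collection of heavy atoms with stable identity keys.

    Parallel arrays keep the container cheap to slice and to hand to
    numerics; :meth:`atom_records` materializes :class:`AtomRecord` views.
    """

    serial: np.ndarray          # (N,) int
    name: np.ndarray            # (N,) str
    element: np.ndarray         # (N,) str
    residue_name: np.ndarray    # (N,) str, 3-letter
    residue_id: np.ndarray      # (N,) int, author numbering
    insertion_code: np.ndarray  # (N,) str
    chain_id: np.ndarray        # (N,) str
    coords: np.ndarray          # (N, 3) float, Å
    occupancy: np.ndarray       # (N,) float
    provenance: str = ""
    model: int = 1

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise StructureError("coords must be (N, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise StructureError("non-finite coordinates")

    # -- basic container protocol ------------------------------------
    def __len__(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return len(self)

    def atom_records(self) -> Iterator[AtomRecord]:
        for i in range(len(self)):
            yield AtomRecord(
                serial=int(self.serial[i]),
                name=str(self.name[i]),
                element=str(self.element[i]),
                residue_name=str(self.residue_name[i]),
                residue_id=int(self.residue_id[i]),
                insertion_code=str(self.insertion_code[i]),
                chain_id=str(self.chain_id[i]),
                position=self.coords[i].copy(),
                occupancy=float(self.occupancy[i]),
            )

    @property
    def atom_index_map(self) -> dict[tuple[str, int, str, str], int]:
        """(chain, residue_id, insertion_code, atom_name) -> ordinal."""
        keys = zip(self.chain_id, self.residue_id, self.insertion_code, self.name)
        out: dict[tuple[str, int, str, str], int] = {}
        for i, (c, r, ic, n) in enumerate(keys):
            key = (str(c), int(r), str(ic), str(n))
            if key in out:
                raise StructureError(f"duplicate atom key {key}")
            out[key] = i
        return out

    def residue_keys(self) -> list[tuple[str, int, str]]:
        """Unique (chain, residue_id, insertion_code) in order of appearance."""
        seen: dict[tuple[str, int, str], None] = {}
        for c, r, ic in zip(self.chain_id, self.residue_id, self.insertion_code):
            seen.setdefault((str(c), int(r), str(ic)), None)
        return list(seen)

    @property
    def n_residues(self) -> int:
        return len(self.residue_keys())

    def residue_index(self) -> np.ndarray:
        """Per-atom ordinal of the residue it belongs to (appearance order)."""
        order = {k: i for i, k in enumerate(self.residue_keys())}
        return np.array(
            [order[(str(c), int(r), str(ic))]
             for c, r, ic in zip(self.chain_id, self.residue_id, self.insertion_code)],
            dtype=int,
        )

    def subset(self, mask: np.ndarray) -> "Structure":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask.astype(int)
        return Structure(
            serial=self.serial[idx],
            name=self.name[idx],
            element=self.element[idx],
            residue_name=self.residue_name[idx],
            residue_id=self.residue_id[idx],
            insertion_code=self.insertion_code[idx],
            chain_id=self.chain_id[idx],
            coords=self.coords[idx],
            occupancy=self.occupancy[idx],
            provenance=self.provenance,
            model=self.model,
        )

    def with_coords(self, coords: np.ndarray) -> "Structure":
        """Copy of this structure with replaced coordinates (same topology)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != self.coords.shape:
            raise PairingError(
                f"coordinate shape {coords.shape} != {self.coords.shape}"
            )
        return replace(self, coords=coords.copy())

    def same_topology(self, other: "Structure") -> bool:
        return (
            len(self) == len(other)
            and np.array_equal(self.name, other.name)
            and np.array_equal(self.residue_id, other.residue_id)
            and np.array_equal(self.chain_id, other.chain_id)
        )


def _require_same_topology(a: Structure, b: Structure) -> None:
    if not a.same_topology(b):
        raise PairingError("structures do not share atom ordering/identity")


def structure_from_arrays(
    coords: np.ndarray,
    *,
    names: TypingSequence[str] | None = None,
    residue_names: TypingSequence[str] | None = None,
    residue_ids: TypingSequence[int] | None = None,
    chain_id: str = "A",
    elements: TypingSequence[str] | None = None,
    provenance: str = "arrays",
) -> Structure:
    """Build a Structure from bare coordinates, one atom per residue by default.

    Convenience for synthetic systems (Cα traces, toy hinges).
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    names = list(names) if names is not None else ["CA"] * n
    residue_names = (
        list(residue_names) if residue_names is not None else ["ALA"] * n
    )
    residue_ids = (
        np.asarray(residue_ids, dtype=int)
        if residue_ids is not None
        else np.arange(1, n + 1)
    )
    elements = list(elements) if elements is not None else ["C"] * n
    return Structure(
        serial=np.arange(1, n + 1),
        name=np.array(names, dtype=object),
        element=np.array(elements, dtype=object),
        residue_name=np.array(residue_names, dtype=object),
        residue_id=residue_ids,
        insertion_code=np.array([""] * n, dtype=object),
        chain_id=np.array([chain_id] * n, dtype=object),
        coords=coords,
        occupancy=np.ones(n),
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# PDB I/O (biotite-backed)
# ---------------------------------------------------------------------------

def _from_atom_array(arr, provenance: str, model: int) -> Structure:
    import biotite.structure as struc

    n = arr.array_length()
    occ = (
        arr.get_annotation("occupancy")
        if "occupancy" in arr.get_annotation_categories()
        else np.ones(n)
    )
    return Structure(
        serial=np.arange(1, n + 1),
        name=np.array(arr.atom_name, dtype=object),
        element=np.array(arr.element, dtype=object),
        residue_name=np.array(arr.res_name, dtype=object),
        residue_id=np.array(arr.res_id, dtype=int),
        insertion_code=np.array(
            [ic if ic else "" for ic in arr.ins_code], dtype=object
        ),
        chain_id=np.array(arr.chain_id, dtype=object),
        coords=np.array(arr.coord, dtype=float),
        occupancy=np.asarray(occ, dtype=float),
        provenance=provenance,
        model=model,
    )


def read_pdb(path: str | Path, model: int = 1, strict: bool = False) -> Structure:
    """Read protein heavy atoms from one model of a PDB file.

    Waters, hydrogens and HETATM ligands are excluded; alternate locations
    collapse to the first conformer.  Non-standard residues are dropped with
    a warning, or raise when ``strict`` is true.
    """
    import biotite.structure.io.pdb as pdbio

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    pdb_file = pdbio.PDBFile.read(str(path))
    arr = pdb_file.get_structure(
        model=model, altloc="first", extra_fields=["occupancy"]
    )
    keep = ~arr.hetero
    keep &= arr.element != "H"
    keep &= arr.element != "D"
    arr = arr[keep]
    nonstd = ~np.isin(arr.res_name, sorted(STANDARD_RESIDUES))
    if nonstd.any():
        dropped = sorted(set(arr.res_name[nonstd]))
        if strict:
            raise StructureError(f"non-standard residues {dropped} (strict mode)")
        logger.warning("dropping non-standard residues: %s", dropped)
        arr = arr[~nonstd]
    if arr.array_length() == 0:
        raise EmptyStructureError(f"no protein ATOM records in {path} model {model}")
    return _from_atom_array(arr, provenance=str(path), model=model)


def _to_atom_array(s: Structure):
    import biotite.structure as struc

    arr = struc.AtomArray(len(s))
    arr.coord = np.round(s.coords.astype(np.float32), 3)
    arr.chain_id = np.array([str(c) for c in s.chain_id])
    arr.res_id = s.residue_id.astype(int)
    arr.ins_code = np.array([str(ic) for ic in s.insertion_code])
    arr.res_name = np.array([str(r) for r in s.residue_name])
    arr.atom_name = np.array([str(n) for n in s.name])
    arr.element = np.array([str(e) for e in s.element])
    arr.hetero = np.zeros(len(s), dtype=bool)
    arr.set_annotation("occupancy", s.occupancy.astype(float))
    arr.set_annotation("b_factor", np.zeros(len(s)))
    return arr


def write_pdb(s: Structure, path: str | Path) -> None:
    """Write a Structure as a fixed-width PDB file (coordinates to 3 decimals)."""
    import biotite.structure.io.pdb as pdbio

    if len(s) == 0:
        raise EmptyStructureError("refusing to write an empty structure")
    if np.any(s.residue_id > 9999) or np.any(s.residue_id < -999):
        raise StructureError("residue_id outside the PDB fixed-width range")
    arr = _to_atom_array(s)
    pdb_file = pdbio.PDBFile()
    pdb_file.set_structure(arr)
    pdb_file.write(str(path))


def write_multimodel_pdb(
    structures: TypingSequence[Structure] | Structure,
    coords_list: TypingSequence[np.ndarray] | None,
    path: str | Path,
) -> None:
    """Write an ensemble as a multi-model PDB.

    Either pass a list of topology-sharing Structures, or one topology
    Structure plus a list/array of coordinate frames.
    """
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdbio

    if coords_list is None:
        seq = list(structures)  # type: ignore[arg-type]
        topo, frames = seq[0], [st.coords for st in seq]
        for st in seq[1:]:
            _require_same_topology(topo, st)
    else:
        topo = structures  # type: ignore[assignment]
        frames = [np.asarray(c, dtype=float) for c in coords_list]
    if len(frames) == 0:
        raise EmptyStructureError("no frames to write")
    arr = _to_atom_array(topo)
    stack = struc.stack([arr] * len(frames))
    stack.coord = np.round(
        np.asarray(frames, dtype=np.float32), 3
    )
    pdb_file = pdbio.PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(str(path))


def read_multimodel_pdb(path: str | Path) -> list[Structure]:
    """Read every model of a (multi-model) PDB file as a list of Structures."""
    import biotite.structure.io.pdb as pdbio

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    pdb_file = pdbio.PDBFile.read(str(path))
    n_models = pdb_file.get_model_count()
    return [read_pdb(path, model=m) for m in range(1, n_models + 1)]


# ---------------------------------------------------------------------------
# Selection
# ---------------------------------------------------------------------------

def _parse_resid_token(token: str) -> list[tuple[int, int]]:
    """'47,109' or '2:5' or '2:5,9' -> list of inclusive (lo, hi) ranges."""
    ranges: list[tuple[int, int]] = []
    for part in token.split(","):
        part = part.strip()
        if not part:
            continue
        if ":" in part or "-" in part[1:]:
            sep = ":" if ":" in part else "-"
            lo_s, hi_s = part.split(sep, 1)
            ranges.append((int(lo_s), int(hi_s)))
        else:
            v = int(part)
            ranges.append((v, v))
    if not ranges:
        raise SelectionError(f"empty residue-id token {token!r}")
    return ranges


def selection_mask(s: Structure, selector: str) -> np.ndarray:
    """Boolean mask for a minimal selection grammar.

    Clauses joined by ``and``:

    * ``name CA,CB`` — atom-name list
    * ``resid 47,109`` / ``resid 40:50`` — residue-id values or ranges
    * ``chain A,B`` — chain ids
    * ``all`` — everything

    Example: ``"name CA and resid 47,109 and chain A"``.
    """
    selector = (selector or "all").strip()
    mask = np.ones(len(s), dtype=bool)
    for clause in selector.split(" and "):
        clause = clause.strip()
        if not clause or clause == "all":
            continue
        try:
            keyword, _, arg = clause.partition(" ")
            arg = arg.strip()
            if keyword == "name":
                wanted = {t.strip() for t in arg.split(",") if t.strip()}
                mask &= np.isin(s.name.astype(str), sorted(wanted))
            elif keyword == "resid":
                sub = np.zeros(len(s), dtype=bool)
                rid = s.residue_id
                for lo, hi in _parse_resid_token(arg):
                    sub |= (rid >= lo) & (rid <= hi)
                mask &= sub
            elif keyword == "chain":
                wanted = {t.strip() for t in arg.split(",") if t.strip()}
                mask &= np.isin(s.chain_id.astype(str), sorted(wanted))
            else:
                raise SelectionError(f"unknown selection keyword {keyword!r}")
        except (ValueError, IndexError) as exc:
            raise SelectionError(f"cannot parse clause {clause!r}: {exc}") from exc
    return mask


def select_atoms(s: Structure, selector: str) -> Structure:
    """Subset of ``s`` matching ``selector``; original atom order preserved.

    Raises :class:`SelectionError` if nothing matches (never silently empty).
    """
    mask = selection_mask(s, selector)
    if not mask.any():
        raise SelectionError(f"selection {selector!r} matched no atoms")
    return s.subset(mask)


# ---------------------------------------------------------------------------
# Superposition & RMSD
# ---------------------------------------------------------------------------

def kabsch(mobile_xyz: np.ndarray, ref_xyz: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rotation matrix and translation mapping mobile onto ref.

    Returns ``(R, t)`` with ``ref ≈ mobile @ R.T + t``; proper rotation
    enforced via the SVD determinant correction.
    """
    mobile_xyz = np.asarray(mobile_xyz, dtype=float)
    ref_xyz = np.asarray(ref_xyz, dtype=float)
    if mobile_xyz.shape != ref_xyz.shape or mobile_xyz.shape[0] < 3:
        raise PairingError("superposition needs matched sets of >= 3 atoms")
    mc = mobile_xyz.mean(axis=0)
    rc = ref_xyz.mean(axis=0)
    h = (mobile_xyz - mc).T @ (ref_xyz - rc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = rc - rot @ mc
    return rot, trans


def _matched_selection(a: Structure, b: Structure, selector: str) -> tuple[np.ndarray, np.ndarray]:
    ma = selection_mask(a, selector)
    mb = selection_mask(b, selector)
    if ma.sum() == 0 or mb.sum() == 0:
        raise SelectionError(f"selection {selector!r} matched no atoms")
    sa, sb = a.subset(ma), b.subset(mb)
    if len(sa) != len(sb) or not np.array_equal(sa.name, sb.name):
        raise PairingError("selected atom sets differ in size or identity")
    return sa.coords, sb.coords


def superpose(
    mobile: Structure, reference: Structure, selector: str = "all"
) -> tuple[Structure, float]:
    """Rigid-body fit of ``mobile`` onto ``reference`` over selected atoms.

    The rotation/translation is solved on the selected atoms and applied to
    every atom of ``mobile``; the returned RMSD is the post-fit value over
    the selection.
    """
    mob_sel, ref_sel = _matched_selection(mobile, reference, selector)
    rot, trans = kabsch(mob_sel, ref_sel)
    moved = mobile.with_coords(mobile.coords @ rot.T + trans)
    fitted_sel = mob_sel @ rot.T + trans
    post = float(np.sqrt(np.mean(np.sum((fitted_sel - ref_sel) ** 2, axis=1))))
    return moved, post


def rmsd(a: Structure, b: Structure, selector: str = "all") -> float:
    """Root-mean-square deviation over matched selected atoms, no fitting."""
    xa, xb = _matched_selection(a, b, selector)
    return float(np.sqrt(np.mean(np.sum((xa - xb) ** 2, axis=1))))


# ---------------------------------------------------------------------------
# Sequence extraction
# ---------------------------------------------------------------------------

def sequence_of(s: Structure, chain: str | None = None, strict: bool = True):
    """One-letter sequence of a chain, ordered by author residue numbering.

    Returns a :class:`modetrap.design.Sequence` (letters + parallel residue
    ids).  Unknown 3-letter codes raise in strict mode and become ``'X'``
    otherwise.
    """
    from .design import Sequence  # local import to avoid a cycle

    if chain is not None:
        mask = s.chain_id.astype(str) == chain
        if not mask.any():
            raise SelectionError(f"chain {chain!r} not present")
        s = s.subset(mask)
    letters: list[str] = []
    numbering: list[int] = []
    for (c, rid, ic) in s.residue_keys():
        rows = np.flatnonzero(
            (s.chain_id.astype(str) == c)
            & (s.residue_id == rid)
            & (s.insertion_code.astype(str) == ic)
        )
        res3 = str(s.residue_name[rows[0]])
        if res3 not in THREE_TO_ONE:
            if strict:
                raise StructureError(f"unknown residue {res3} at {c}{rid}{ic}")
            letters.append("X")
        else:
            letters.append(THREE_TO_ONE[res3])
        numbering.append(int(rid))
    return Sequence(letters="".join(letters), numbering=numbering)
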