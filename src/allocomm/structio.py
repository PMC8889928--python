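"""Structure and ensemble I/O, residue-numbering conventions, and body selections.

Protein kinase-domain constructs are frequently numbered in two frames: the
*nascent* reading frame (including the signal peptide) and the *mature* frame
(signal peptide removed).  For HER3 the signal peptide is 19 residues, so
nascent = mature + 19 (e.g. nascent F704 is mature 685).  Every structure and
selection in this package carries an explicit numbering convention so that
residue lists from either frame can be used interchangeably.

PDB parsing and writing are delegated to :mod:`biotite`; binary MD trajectory
formats (DCD/XTC/...) are read through an :mod:`mdtraj` adapter that converts
to Å and preserves topology atom order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import NumberingError, SelectionError, StructureError

NASCENT = "nascent"
MATURE = "mature"
#: Length of the HER3 signal peptide relating the two numbering frames.
SIGNAL_PEPTIDE_OFFSET = 19

#: Default atom-name filter for information-theoretic bodies.
DEFAULT_BODY_ATOMS = ("CA", "CB")

_CONVENTIONS = (NASCENT, MATURE)


def _check_convention(convention: str) -> str:
    if convention not in _CONVENTIONS:
        raise ValueError(
            f"unknown numbering convention {convention!r}; expected one of {_CONVENTIONS}"
        )
    return convention


@dataclass
class StructureModel:
    """A single protein structure: parallel per-atom annotation arrays plus coordinates.

    Coordinates are in Å.  ``hetero`` flags waters and other HETATM records,
    which are retained on reading but excluded from residue-based selections.
    """

    atom_names: np.ndarray
    elements: np.ndarray
    residue_numbers: np.ndarray
    residue_names: np.ndarray
    chain_ids: np.ndarray
    coords: np.ndarray
    hetero: np.ndarray | None = None
    numbering_convention: str = MATURE
    signal_peptide_offset: int = SIGNAL_PEPTIDE_OFFSET

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.atom_names = np.asarray(self.atom_names, dtype="U6")
        self.elements = np.asarray(self.elements, dtype="U2")
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=int)
        self.residue_names = np.asarray(self.residue_names, dtype="U5")
        self.chain_ids = np.asarray(self.chain_ids, dtype="U4")
        if self.hetero is None:
            self.hetero = np.zeros(self.n_atoms, dtype=bool)
        self.hetero = np.asarray(self.hetero, dtype=bool)
        _check_convention(self.numbering_convention)
        if self.signal_peptide_offset < 0:
            raise ValueError("signal_peptide_offset must be >= 0")
        if self.n_atoms == 0:
            raise StructureError("empty structure: no atoms")
        if self.coords.shape != (self.n_atoms, 3):
            raise StructureError(
                f"coords shape {self.coords.shape} inconsistent with {self.n_atoms} atoms"
            )
        if not np.all(np.isfinite(self.coords)):
            raise StructureError("non-finite coordinates in structure")
        triples = list(zip(self.chain_ids, self.residue_numbers, self.atom_names))
        if len(set(triples)) != len(triples):
            raise StructureError(
                "duplicate (chain, residue, atom name) triples; "
                "resolve altlocs/insertion codes before constructing a StructureModel"
            )

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    def with_coords(self, coords: np.ndarray) -> "StructureModel":
        """Copy of this model with replaced coordinates."""
        return StructureModel(
            atom_names=self.atom_names,
            elements=self.elements,
            residue_numbers=self.residue_numbers,
            residue_names=self.residue_names,
            chain_ids=self.chain_ids,
            coords=np.asarray(coords, dtype=float),
            hetero=self.hetero,
            numbering_convention=self.numbering_convention,
            signal_peptide_offset=self.signal_peptide_offset,
        )

    def residue_numbers_as(self, convention: str) -> np.ndarray:
        """Residue numbers of all atoms expressed in the requested convention."""
        return np.asarray(
            convert_numbering(
                self.residue_numbers,
                self.numbering_convention,
                convention,
                offset=self.signal_peptide_offset,
            )
        )


@dataclass
class Ensemble:
    """A multi-frame coordinate ensemble bound to a topology.

    ``coords`` has shape (n_frames, n_atoms, 3), in Å.  ``frame_spacing`` is
    the time between stored frames in arbitrary (caller-defined) units and is
    carried as metadata only.
    """

    topology: StructureModel
    coords: np.ndarray
    frame_spacing: float = 1.0
    label: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise StructureError(f"ensemble coords must be (frames, atoms, 3), got {self.coords.shape}")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise StructureError(
                f"ensemble has {self.coords.shape[1]} atoms but topology has {self.topology.n_atoms}"
            )
        if self.n_frames < 1:
            raise StructureError("ensemble must contain at least one frame")
        if not np.all(np.isfinite(self.coords)):
            raise StructureError("non-finite coordinates in ensemble")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def frame(self, i: int) -> StructureModel:
        """Single frame as a StructureModel."""
        return self.topology.with_coords(self.coords[i])


@dataclass
class BodySelection:
    """An ordered atom-index set defining one information-theoretic body.

    ``role`` distinguishes the NbIT transmitter (information source), receiver
    (information sink), channel (candidate mediating residue) and the atoms
    used only for rigid-body fitting.
    """

    atom_indices: np.ndarray
    residue_numbers: list[int]
    numbering_convention: str = MATURE
    atom_name_filter: tuple[str, ...] = DEFAULT_BODY_ATOMS
    role: str = "channel"
    missing_residues: list[int] = field(default_factory=list)
    missing_atoms: int = 0

    def __post_init__(self) -> None:
        idx = np.asarray(self.atom_indices, dtype=int)
        if idx.size == 0:
            raise SelectionError("empty selection: no atoms")
        if len(np.unique(idx)) != idx.size:
            raise SelectionError("selection contains duplicate atom indices")
        self.atom_indices = np.sort(idx)
        _check_convention(self.numbering_convention)
        if self.role not in ("transmitter", "receiver", "channel", "fit"):
            raise ValueError(f"unknown selection role {self.role!r}")

    @property
    def n_atoms(self) -> int:
        return self.atom_indices.size

    @property
    def n_dims(self) -> int:
        """Dimensionality of the Cartesian coordinate vector of this body."""
        return 3 * self.n_atoms

    def overlaps(self, other: "BodySelection") -> bool:
        return bool(np.intersect1d(self.atom_indices, other.atom_indices).size)


def convert_numbering(
    residues: Iterable[int] | np.ndarray,
    from_convention: str,
    to_convention: str,
    offset: int = SIGNAL_PEPTIDE_OFFSET,
) -> list[int]:
    """Convert residue numbers between the nascent and mature frames.

    nascent -> mature subtracts the signal-peptide offset; mature -> nascent
    adds it.  The round trip is the identity.
    """
    _check_convention(from_convention)
    _check_convention(to_convention)
    if offset < 0:
        raise ValueError("offset must be >= 0")
    res = [int(r) for r in residues]
    if from_convention == to_convention:
        return res
    delta = -offset if (from_convention == NASCENT and to_convention == MATURE) else offset
    out = [r + delta for r in res]
    bad = [r for r in out if r <= 0]
    if bad:
        raise NumberingError(
            f"conversion {from_convention}->{to_convention} (offset {offset}) produced "
            f"non-positive residue numbers: {bad}"
        )
    return out


def select_body(
    topology: StructureModel,
    residues: Sequence[int],
    convention: str | None = None,
    atom_names: Sequence[str] = DEFAULT_BODY_ATOMS,
    role: str = "channel",
    chain_id: str | None = None,
    allow_missing: bool = False,
) -> BodySelection:
    """Select the atoms of the given residues, by name, as an NbIT body.

    Residue numbers may be given in either convention (default: the
    topology's own).  Glycine naturally contributes only its Cα when Cβ is
    requested.  Residues absent from the topology raise
    :class:`SelectionError` unless ``allow_missing`` is set, in which case
    they are recorded in ``missing_residues``.  A non-glycine residue that is
    present but lacks a requested atom (crystallographic disorder) triggers a
    warning and is used with its available atoms; the count is recorded in
    ``missing_atoms``.
    """
    convention = topology.numbering_convention if convention is None else convention
    wanted = convert_numbering(
        residues, convention, topology.numbering_convention, topology.signal_peptide_offset
    )
    atom_names = tuple(atom_names)
    name_mask = np.isin(topology.atom_names, atom_names)
    usable = name_mask & ~topology.hetero
    if chain_id is not None:
        usable &= topology.chain_ids == chain_id

    indices: list[int] = []
    missing_res: list[int] = []
    missing_atoms = 0
    for res in wanted:
        res_mask = usable & (topology.residue_numbers == res)
        hits = np.flatnonzero(res_mask)
        if hits.size == 0:
            missing_res.append(res)
            continue
        res_name = topology.residue_names[hits[0]]
        expected = len(atom_names) - (1 if (res_name == "GLY" and "CB" in atom_names) else 0)
        if hits.size < expected:
            missing_atoms += expected - hits.size
            warnings.warn(
                f"residue {res} ({res_name}) provides {hits.size}/{expected} of the "
                f"requested atoms {atom_names}; proceeding with available atoms",
                stacklevel=2,
            )
        indices.extend(int(i) for i in hits)

    if missing_res and not allow_missing:
        raise SelectionError(
            f"residues not found in topology ({topology.numbering_convention} frame): {missing_res}"
        )
    if not indices:
        raise SelectionError(f"no atoms matched residues {list(residues)} with names {atom_names}")
    return BodySelection(
        atom_indices=np.array(sorted(indices), dtype=int),
        residue_numbers=[r for r in wanted if r not in missing_res],
        numbering_convention=topology.numbering_convention,
        atom_name_filter=atom_names,
        role=role,
        missing_residues=missing_res,
        missing_atoms=missing_atoms,
    )


def ca_selection(topology: StructureModel, role: str = "fit", chain_id: str | None = None) -> BodySelection:
    """All Cα atoms of the (non-hetero) topology — the default fit selection."""
    residues = sorted(
        set(
            int(r)
            for r, h in zip(topology.residue_numbers, topology.hetero)
            if not h
        )
    )
    return select_body(
        topology, residues, atom_names=("CA",), role=role, chain_id=chain_id, allow_missing=True
    )


# ---------------------------------------------------------------------------
# PDB reading / writing (biotite-backed)
# ---------------------------------------------------------------------------

def _from_atom_array(arr, convention: str, offset: int) -> StructureModel:
    if "ins_code" in arr.get_annotation_categories():
        ins = np.asarray(arr.ins_code)
        if np.any(ins != ""):
            raise StructureError(
                "structure contains insertion codes, which are not supported; "
                "renumber the affected residues first"
            )
    return StructureModel(
        atom_names=arr.atom_name,
        elements=arr.element,
        residue_numbers=arr.res_id,
        residue_names=arr.res_name,
        chain_ids=arr.chain_id,
        coords=arr.coord,
        hetero=arr.hetero,
        numbering_convention=convention,
        signal_peptide_offset=offset,
    )


def _to_atom_array(model: StructureModel):
    import biotite.structure as struc

    arr = struc.AtomArray(model.n_atoms)
    arr.coord = np.asarray(model.coords, dtype=np.float32)
    arr.atom_name = model.atom_names
    arr.element = model.elements
    arr.res_id = model.residue_numbers
    arr.res_name = model.residue_names
    arr.chain_id = model.chain_ids
    arr.hetero = model.hetero
    return arr


def read_structure(
    path: str | Path,
    convention: str = MATURE,
    signal_peptide_offset: int = SIGNAL_PEPTIDE_OFFSET,
) -> StructureModel:
    """Read a PDB file into a StructureModel tagged with a numbering convention.

    Altlocs are resolved to the highest-occupancy alternative; waters and
    heteroatoms are retained but flagged.  Multi-model files yield the first
    model (use :func:`read_ensemble` for the full stack).
    """
    from biotite.structure.io.pdb import PDBFile

    _check_convention(convention)
    try:
        pdb = PDBFile.read(str(path))
        arr = pdb.get_structure(model=1, altloc="occupancy")
    except StructureError:
        raise
    except Exception as exc:  # biotite raises several parse-error types
        raise StructureError(f"cannot parse PDB file {path}: {exc}") from exc
    if arr.array_length() == 0:
        raise StructureError(f"PDB file {path} contains no atoms")
    return _from_atom_array(arr, convention, signal_peptide_offset)


def read_ensemble(
    path: str | Path,
    convention: str = MATURE,
    label: str = "",
    frame_spacing: float = 1.0,
    signal_peptide_offset: int = SIGNAL_PEPTIDE_OFFSET,
) -> Ensemble:
    """Read a multi-model PDB file as an Ensemble (one frame per MODEL block)."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    _check_convention(convention)
    try:
        pdb = PDBFile.read(str(path))
        obj = pdb.get_structure(altloc="occupancy")
    except Exception as exc:
        raise StructureError(f"cannot parse PDB file {path}: {exc}") from exc
    if isinstance(obj, struc.AtomArray):
        obj = struc.stack([obj])
    if obj.array_length() == 0:
        raise StructureError(f"PDB file {path} contains no atoms")
    topology = _from_atom_array(obj[0], convention, signal_peptide_offset)
    return Ensemble(
        topology=topology,
        coords=np.asarray(obj.coord, dtype=float),
        frame_spacing=frame_spacing,
        label=label or Path(path).stem,
    )


def write_structure(model: StructureModel, path: str | Path) -> None:
    """Write a StructureModel to a PDB file."""
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile()
    pdb.set_structure(_to_atom_array(model))
    pdb.write(str(path))


def write_ensemble(ensemble: Ensemble, path: str | Path) -> None:
    """Write an Ensemble as a multi-model PDB file."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    frames = [_to_atom_array(ensemble.topology.with_coords(c)) for c in ensemble.coords]
    pdb = PDBFile()
    pdb.set_structure(struc.stack(frames))
    pdb.write(str(path))


def load_trajectory(
    traj_path: str | Path,
    topology_path: str | Path,
    convention: str = MATURE,
    label: str = "",
    stride: int = 1,
    signal_peptide_offset: int = SIGNAL_PEPTIDE_OFFSET,
) -> Ensemble:
    """Adapter for binary MD trajectory formats (DCD, XTC, ...) via mdtraj.

    Contract: frames are returned in Å (mdtraj's nm are converted), in the
    atom order of the topology file, with the topology's residue numbering
    tagged with the supplied convention.
    """
    import mdtraj

    topology = read_structure(topology_path, convention, signal_peptide_offset)
    try:
        traj = mdtraj.load(str(traj_path), top=str(topology_path), stride=stride)
    except Exception as exc:
        raise StructureError(f"cannot load trajectory {traj_path}: {exc}") from exc
    coords = np.asarray(traj.xyz, dtype=float) * 10.0  # nm -> Å
    if coords.shape[1] != topology.n_atoms:
        raise StructureError(
            f"trajectory atom count {coords.shape[1]} != topology atom count {topology.n_atoms}"
        )
    return Ensemble(
        topology=topology,
        coords=coords,
        frame_spacing=float(stride),
        label=label or Path(traj_path).stem,
    )


def parse_residue_spec(spec: str) -> list[int]:
    """Parse a residue list like ``"683,685,696-704"`` into sorted integers."""
    out: set[int] = set()
    for token in spec.replace(" ", "").split(","):
        if not token:
            continue
        if "-" in token[1:]:  # allow leading minus to fail loudly below
            lo, hi = token.split("-", 1)
            out.update(range(int(lo), int(hi) + 1))
        else:
            out.add(int(token))
    if not out:
        raise ValueError(f"empty residue specification: {spec!r}")
    return sorted(out)
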