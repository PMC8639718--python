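"""Multi-model PDB ensembles and atom bookkeeping.

An :class:`Ensemble` is an ordered list of coordinate models (frames) that
share one topology — the in-memory stand-in for a simulation trajectory
written as a multi-model PDB file.  All downstream analyses (contacts,
clustering, surface areas) consume these containers.

PDB parsing and writing are delegated to :mod:`biotite.structure.io.pdb`;
this module adds topology validation across models, van der Waals radius
assignment, and the atom selections used throughout the pipeline.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "AtomRecord",
    "StructureModel",
    "Ensemble",
    "ResidueClassification",
    "DEFAULT_VDW_RADII",
    "DEFAULT_CLASSIFICATION",
    "PDBParseError",
    "TopologyError",
    "SelectionError",
    "read_pdb_ensemble",
    "write_pdb_ensemble",
    "assign_radii",
    "select_atoms",
]

#: Element-keyed van der Waals radii (Å) used for SASA and patch detection.
#: These are the classic united-atom rolling-ball radii, appropriate for
#: structures without explicit hydrogens (the carbon radius absorbs its
#: hydrogens).  Config-overridable.
DEFAULT_VDW_RADII: dict[str, float] = {
    "C": 2.00,
    "N": 1.70,
    "O": 1.40,
    "S": 1.85,
    "H": 1.20,
}

#: Backbone heavy-atom names of a standard amino-acid residue.
BACKBONE_ATOMS = ("N", "CA", "C", "O")


class PDBParseError(ValueError):
    """An ATOM record could not be parsed; carries the 1-based line number."""


class TopologyError(ValueError):
    """Models in one ensemble do not share an identical atom topology."""


class SelectionError(ValueError):
    """An atom selection matched nothing (prevents silent empty analyses)."""


@dataclass
class AtomRecord:
    """One atom of one model.

    ``radius`` is a van der Waals radius in Å assigned by
    :func:`assign_radii`; it is 0.0 (meaning *unassigned*) after parsing.
    """

    serial: int
    name: str
    residue_name: str
    chain_id: str
    residue_index: int
    coords: np.ndarray
    element: str
    radius: float = 0.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,):
            raise ValueError("coords must be a 3-vector")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")
        if not self.name:
            raise ValueError("atom name must be non-empty")


@dataclass
class StructureModel:
    """An ordered list of atoms forming one conformation (one PDB MODEL)."""

    atoms: list[AtomRecord]
    model_id: int = 1

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("a model must contain at least one atom")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array in Å."""
        return np.array([a.coords for a in self.atoms], dtype=float)

    @property
    def radii(self) -> np.ndarray:
        return np.array([a.radius for a in self.atoms], dtype=float)

    def topology_key(self) -> tuple:
        return tuple(
            (a.chain_id, a.residue_index, a.residue_name, a.name) for a in self.atoms
        )

    def residue_ids(self) -> list[tuple[str, int]]:
        """Unique (chain, residue_index) pairs in first-appearance order."""
        seen: dict[tuple[str, int], None] = {}
        for a in self.atoms:
            seen.setdefault((a.chain_id, a.residue_index), None)
        return list(seen)

    def residue_names(self) -> dict[tuple[str, int], str]:
        out: dict[tuple[str, int], str] = {}
        for a in self.atoms:
            out.setdefault((a.chain_id, a.residue_index), a.residue_name)
        return out

    def with_coords(self, coords: np.ndarray, model_id: int | None = None) -> "StructureModel":
        """Copy of this model with replaced coordinates (same topology)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape does not match atom count")
        atoms = [replace(a, coords=c.copy()) for a, c in zip(self.atoms, coords)]
        return StructureModel(atoms, self.model_id if model_id is None else model_id)


@dataclass
class Ensemble:
    """Ordered models sharing one topology plus frame-time metadata.

    ``frame_interval`` is the simulated time between successive frames in
    picoseconds (the stride at which coordinates were written).
    """

    models: list[StructureModel]
    frame_interval: float = 2.0

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError("an ensemble must contain at least one model")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive (ps)")
        key = self.models[0].topology_key()
        for m in self.models[1:]:
            if m.topology_key() != key:
                raise TopologyError(
                    f"model {m.model_id} does not match the topology of model "
                    f"{self.models[0].model_id}"
                )
        self.topology_key = key

    def __len__(self) -> int:
        return len(self.models)

    @property
    def n_frames(self) -> int:
        return len(self.models)

    def coords(self, indices: Sequence[int] | None = None) -> np.ndarray:
        """(n_frames, n_sel, 3) coordinate array, optionally restricted."""
        arr = np.stack([m.coords for m in self.models])
        if indices is not None:
            arr = arr[:, np.asarray(indices, dtype=int), :]
        return arr

    def frame_times_ps(self) -> np.ndarray:
        return np.arange(self.n_frames, dtype=float) * self.frame_interval

    def subset(self, frame_indices: Sequence[int]) -> "Ensemble":
        """New ensemble containing only the given frames (order preserved).

        The frame interval is kept; callers taking non-uniform subsets are
        responsible for interpreting times accordingly.
        """
        models = [self.models[i] for i in frame_indices]
        return Ensemble(copy.deepcopy(models), self.frame_interval)


@dataclass(frozen=True)
class ResidueClassification:
    """Residue-level chemistry used by the exposure and interaction analyses.

    ``hydrophobic_set`` holds the seven aliphatic/aromatic residues whose
    per-residue hydrophobic surface area is tracked; ``charge_atoms`` maps a
    charged residue to its formal sign and the side-chain atoms carrying it.
    """

    hydrophobic_set: frozenset[str] = frozenset(
        {"ALA", "LEU", "VAL", "ILE", "PHE", "PRO", "TRP"}
    )
    charge_atoms: Mapping[str, tuple[int, tuple[str, ...]]] = field(
        default_factory=lambda: {
            "ARG": (+1, ("NE", "NH1", "NH2")),
            "LYS": (+1, ("NZ",)),
            "ASP": (-1, ("OD1", "OD2")),
            "GLU": (-1, ("OE1", "OE2")),
        }
    )


DEFAULT_CLASSIFICATION = ResidueClassification()


def _infer_element(atom_name: str) -> str:
    """Element from an atom name when PDB columns 77-78 are absent.

    Follows PDB naming: a leading digit is a position index (e.g. ``1HB``);
    two-character elements occurring in proteins are only recognised when
    unambiguous.
    """
    name = atom_name.strip()
    while name and name[0].isdigit():
        name = name[1:]
    if not name:
        raise ValueError(f"cannot infer element from atom name {atom_name!r}")
    return name[0].upper()


def _locate_bad_atom_line(path) -> int | None:
    """1-based line number of the first malformed ATOM/HETATM record."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM", "HETATM")):
                continue
            try:
                int(line[6:11])
                int(line[22:26])
                for lo, hi in ((30, 38), (38, 46), (46, 54)):
                    float(line[lo:hi])
            except (ValueError, IndexError):
                return lineno
    return None


def read_pdb_ensemble(path, frame_interval: float = 2.0) -> Ensemble:
    """Read a (multi-)model PDB file into an :class:`Ensemble`.

    A file without MODEL records is treated as a one-frame ensemble.  Atom
    order is preserved exactly as in the file.  Alternate locations other
    than blank/"A" are dropped with a warning; all models must share one
    topology or a :class:`TopologyError` naming the first offending model
    is raised.
    """
    from biotite.structure.io.pdb import PDBFile

    try:
        pdb = PDBFile.read(str(path))
        n_models = pdb.get_model_count()
        stacks = [pdb.get_structure(model=i, altloc="first") for i in range(1, n_models + 1)]
    except FileNotFoundError:
        raise
    except Exception as exc:  # biotite raises several parse-error types
        lineno = _locate_bad_atom_line(path)
        where = f" at line {lineno}" if lineno is not None else ""
        raise PDBParseError(f"could not parse {path}{where}: {exc}") from exc

    models: list[StructureModel] = []
    for model_id, arr in enumerate(stacks, start=1):
        atoms: list[AtomRecord] = []
        for i in range(arr.array_length()):
            name = str(arr.atom_name[i])
            element = str(arr.element[i]).strip()
            if not element:
                element = _infer_element(name)
            atoms.append(
                AtomRecord(
                    serial=i + 1,
                    name=name,
                    residue_name=str(arr.res_name[i]),
                    chain_id=str(arr.chain_id[i]) or "A",
                    residue_index=int(arr.res_id[i]),
                    coords=np.asarray(arr.coord[i], dtype=float),
                    element=element.upper(),
                )
            )
        models.append(StructureModel(atoms, model_id))

    key = models[0].topology_key()
    for m in models[1:]:
        if m.topology_key() != key:
            raise TopologyError(
                f"model {m.model_id} in {path} does not match the topology of model 1"
            )
    return Ensemble(models, frame_interval=frame_interval)


def write_pdb_ensemble(ensemble: Ensemble, path) -> None:
    """Write an ensemble as a standard multi-model PDB (MODEL/ENDMDL).

    Coordinates are written to 3 decimals, so a read/write round trip
    preserves them to 1e-3 Å.
    """
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n_atoms = len(ensemble.models[0])
    template = ensemble.models[0]
    arr = struc.AtomArray(n_atoms)
    arr.chain_id = np.array([a.chain_id for a in template.atoms], dtype="U4")
    arr.res_id = np.array([a.residue_index for a in template.atoms], dtype=int)
    arr.res_name = np.array([a.residue_name for a in template.atoms], dtype="U5")
    arr.atom_name = np.array([a.name for a in template.atoms], dtype="U6")
    arr.element = np.array([a.element for a in template.atoms], dtype="U2")
    arr.hetero = np.zeros(n_atoms, dtype=bool)

    stack = struc.stack([arr] * ensemble.n_frames)
    stack.coord = ensemble.coords()

    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))

    # A 1-frame stack is written as a bare structure; wrap it so every
    # ensemble file carries explicit MODEL/ENDMDL records.
    if ensemble.n_frames == 1:
        with open(path) as fh:
            lines = fh.readlines()
        if not any(line.startswith("MODEL") for line in lines):
            with open(path, "w") as fh:
                fh.write("MODEL        1\n")
                fh.writelines(lines)
                fh.write("ENDMDL\n")


def assign_radii(
    ensemble: Ensemble, radii_table: Mapping[str, float] | None = None
) -> Ensemble:
    """Return a copy of the ensemble with van der Waals radii assigned.

    Every element in the ensemble must appear in ``radii_table``
    (default :data:`DEFAULT_VDW_RADII`); otherwise a :class:`KeyError`
    naming the missing element is raised.
    """
    table = dict(DEFAULT_VDW_RADII if radii_table is None else radii_table)
    elements = {a.element for m in ensemble.models for a in m.atoms}
    missing = sorted(elements - set(table))
    if missing:
        raise KeyError(
            f"no van der Waals radius for element(s): {', '.join(missing)}"
        )
    models = []
    for m in ensemble.models:
        atoms = [replace(a, radius=float(table[a.element])) for a in m.atoms]
        models.append(StructureModel(atoms, m.model_id))
    return Ensemble(models, ensemble.frame_interval)


def select_atoms(
    model: StructureModel,
    selector: str | Mapping[str, object],
    classification: ResidueClassification = DEFAULT_CLASSIFICATION,
) -> list[int]:
    """Indices (model order) of atoms matching a selector.

    ``selector`` is either a shorthand string — ``"CA"`` (one alpha carbon
    per residue), ``"backbone"`` (N, CA, C, O), ``"hydrophobic"`` (all atoms
    of hydrophobic residues), any other atom name — or a mapping with keys
    ``atom_names`` and/or ``residue_names``.  An empty match raises
    :class:`SelectionError`.
    """
    atom_names: set[str] | None = None
    residue_names: set[str] | None = None
    if isinstance(selector, str):
        if selector == "backbone":
            atom_names = set(BACKBONE_ATOMS)
        elif selector == "hydrophobic":
            residue_names = set(classification.hydrophobic_set)
        else:
            atom_names = {selector}
    else:
        if "atom_names" in selector:
            atom_names = set(selector["atom_names"])  # type: ignore[arg-type]
        if "residue_names" in selector:
            residue_names = set(selector["residue_names"])  # type: ignore[arg-type]
        if atom_names is None and residue_names is None:
            raise ValueError("selector mapping needs atom_names and/or residue_names")

    indices = [
        i
        for i, a in enumerate(model.atoms)
        if (atom_names is None or a.name in atom_names)
        and (residue_names is None or a.residue_name in residue_names)
    ]
    if not indices:
        raise SelectionError(f"selector {selector!r} matched no atoms")
    return indices
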