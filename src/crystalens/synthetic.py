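"""Synthetic toy ensembles with planted ground truth.

The toy protein caricatures a two-sheet β-sandwich: two rigid straight
"sheet" blocks stacked face to face, each residue reduced to a Cα plus one
side-chain pseudo-atom.  Hydrophobic side chains in the tightly packed
part of the interface point into the gap (buried in the native state);
polar side chains point outward.  The inter-block gap widens slightly
along the chain (a wedge), so the wide-end native contacts sit close to
the 6.5 Å cutoff: a rigid-body separation of the two blocks — the
continuous unfolding coordinate ``lambda`` — peels contacts progressively
from the wide end inward while raising the hydrophobic exposure of every
interface residue, giving known monotone ground truth for every pipeline
stage.

Also provides an ideal-geometry peptide builder used for the extended
Ala-X-Ala tripeptide references of the hydrophobic-exposure analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .io import AtomRecord, Ensemble, StructureModel

__all__ = [
    "ToyTopology",
    "PlantedEnsembleSpec",
    "GroundTruth",
    "build_native_toy",
    "apply_unfolding",
    "sample_planted_ensemble",
    "unfolding_lambda_for_fraction",
    "make_tripeptide",
    "write_ground_truth",
]

# Toy geometry constants (Å).  Chosen so that the native inter-block Cα
# distances sit inside the 6.5 Å contact cutoff, the tight-end interface
# side chains are sandwiched below the 50 Å² burial threshold, and the
# wide-end contacts are close enough to the cutoff to break early.
CA_SPACING = 3.8          # along-strand Cα-Cα distance
GAP_MIN = 3.4             # inter-block Cα separation at the tight end
GAP_MAX = 5.2             # ... at the wide end of the wedge
BURIED_GAP_LIMIT = 4.0    # positions this tight carry interface hydrophobes
SIDECHAIN_LENGTH = 1.6    # Cα → side-chain pseudo-atom bond
OPEN_PER_LAMBDA = 1.0     # block separation rate, Å per unit lambda

_HYDROPHOBIC_CYCLE = ("LEU", "VAL", "ILE", "PHE")
_POLAR_CYCLE = ("SER", "THR", "ASN", "GLN")


@dataclass
class ToyTopology:
    """Sequence plus rigid-block layout of the toy protein."""

    n_residues: int
    sequence: list[str]
    block_of: np.ndarray          # 0 (fixed block) or 1 (mobile block) per residue
    open_direction: np.ndarray    # unit vector of the block-1 rigid separation
    interface_hydrophobes: list[int]  # 1-based residue indices

    def __post_init__(self) -> None:
        if self.n_residues < 8:
            raise ValueError("toy topology needs at least 8 residues")


@dataclass
class PlantedEnsembleSpec:
    """Mixture definition for a planted two-(or k-)state ensemble."""

    topology: ToyTopology
    native: StructureModel
    states: list[tuple[float, float]]   # (unfolding lambda, weight)
    noise_sigma: float = 0.1
    n_frames: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        weights = [w for _, w in self.states]
        if abs(sum(weights) - 1.0) > 1e-9:
            raise ValueError("state weights must sum to 1")
        if any(lam < 0 for lam, _ in self.states):
            raise ValueError("unfolding lambda must be >= 0")


@dataclass
class GroundTruth:
    """Planted truth recorded while sampling an ensemble."""

    frame_state_labels: np.ndarray
    per_state_native_fraction: list[float]
    per_state_exposed_residues: list[set[int]]
    state_lambdas: list[float] = field(default_factory=list)
    state_weights: list[float] = field(default_factory=list)


def _wedge_gap(k: int, length: int) -> float:
    """Inter-block Cα separation at strand position ``k`` of ``length``."""
    return GAP_MIN + (GAP_MAX - GAP_MIN) * k / max(length - 1, 1)


def _toy_sequence(n_residues: int) -> tuple[list[str], list[bool]]:
    """Sequence with hydrophobic residues at the tightly packed positions.

    Interior positions of each strand whose wedge gap is at most
    ``BURIED_GAP_LIMIT`` are hydrophobic with the side chain pointing
    into the interface — a contiguous run at the tight end, so the
    exposed interface forms a connected surface patch once the sandwich
    opens.  Everything else is polar, pointing outward; strand ends are
    always polar.
    """
    m = n_residues // 2
    seq: list[str] = []
    interface: list[bool] = []
    h = p = 0
    for block in (0, 1):
        length = m if block == 0 else n_residues - m
        for k in range(length):
            tight = _wedge_gap(k, length) <= BURIED_GAP_LIMIT
            if 0 < k < length - 1 and k <= 2 and tight:
                seq.append(_HYDROPHOBIC_CYCLE[h % len(_HYDROPHOBIC_CYCLE)])
                interface.append(True)
                h += 1
            else:
                seq.append(_POLAR_CYCLE[p % len(_POLAR_CYCLE)])
                interface.append(False)
                p += 1
    return seq, interface


def build_native_toy(
    n_residues: int = 16, seed: int = 0
) -> tuple[ToyTopology, StructureModel]:
    """Deterministic native toy structure with a buried hydrophobic interface.

    Block 0 runs along x at y = 0; block 1 runs parallel above it at the
    wedge gap (``GAP_MIN`` at x = 0 widening to ``GAP_MAX``).  Hydrophobic
    side chains of the tight positions point into the gap.  A small seeded
    jitter (0.03 Å) breaks exact symmetry so that downstream tie-breaks
    are exercised without perturbing any planted property.
    """
    if n_residues < 8:
        raise ValueError("n_residues must be >= 8")
    m = n_residues // 2
    seq, interface = _toy_sequence(n_residues)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x70F]))

    atoms: list[AtomRecord] = []
    block_of = np.zeros(n_residues, dtype=int)
    serial = 1
    for res_i in range(n_residues):
        block = 0 if res_i < m else 1
        length = m if block == 0 else n_residues - m
        k = res_i if block == 0 else res_i - m
        block_of[res_i] = block
        y_ca = 0.0 if block == 0 else _wedge_gap(k, length)
        inward = 1.0 if block == 0 else -1.0
        x = k * CA_SPACING
        ca = np.array([x, y_ca, 0.0])
        if interface[res_i]:
            cb = ca + np.array([0.0, inward * SIDECHAIN_LENGTH, 0.0])
        else:
            # Outward side chain; polar residues flanking the buried
            # hydrophobic run lean over it (45° tilt) so its outer face
            # stays shielded, as flanking residues do in a real sheet.
            tilt = 0.0
            if res_i + 1 < n_residues and interface[res_i + 1]:
                tilt = 1.0
            elif res_i - 1 >= 0 and interface[res_i - 1]:
                tilt = -1.0
            length_cb = SIDECHAIN_LENGTH if tilt == 0.0 else 2.0
            direction = np.array([tilt, -inward, 0.0])
            direction /= np.linalg.norm(direction)
            cb = ca + length_cb * direction
        for name, pos in (("CA", ca), ("CB", cb)):
            atoms.append(
                AtomRecord(
                    serial=serial,
                    name=name,
                    residue_name=seq[res_i],
                    chain_id="A",
                    residue_index=res_i + 1,
                    coords=pos + rng.normal(0.0, 0.03, size=3),
                    element="C",
                )
            )
            serial += 1

    topology = ToyTopology(
        n_residues=n_residues,
        sequence=seq,
        block_of=block_of,
        open_direction=np.array([0.0, 1.0, 0.0]),
        interface_hydrophobes=[i + 1 for i in range(n_residues) if interface[i]],
    )
    return topology, StructureModel(atoms, model_id=1)


def apply_unfolding(
    native: StructureModel, topology: ToyTopology, lam: float
) -> StructureModel:
    """Rigid-body separation of block 1 from block 0, scaled by ``lam``.

    Block 1 translates along ``open_direction`` by ``OPEN_PER_LAMBDA *
    lam`` Å.  ``lam = 0`` returns the native coordinates unchanged; every
    inter-block distance grows monotonically with ``lam``, so the native
    contact fraction is non-increasing and the interface hydrophobic
    exposure non-decreasing.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if lam == 0:
        return native.with_coords(native.coords)
    shift = OPEN_PER_LAMBDA * lam * topology.open_direction
    coords = native.coords.copy()
    for i, a in enumerate(native.atoms):
        if topology.block_of[a.residue_index - 1] == 1:
            coords[i] = coords[i] + shift
    return native.with_coords(coords)


def _state_models(spec: PlantedEnsembleSpec) -> list[StructureModel]:
    return [
        apply_unfolding(spec.native, spec.topology, lam) for lam, _ in spec.states
    ]


def _state_truth(
    spec: PlantedEnsembleSpec, state_models: list[StructureModel]
) -> tuple[list[float], list[set[int]]]:
    """Noiseless per-state contact fractions and exposed hydrophobes."""
    from .contacts import contact_fraction, reference_contacts
    from .io import Ensemble as _Ens, assign_radii
    from .sasa import BURIAL_THRESHOLD, residue_hsasa, shrake_rupley

    reference = reference_contacts(spec.native)
    fractions = [contact_fraction(m, reference) for m in state_models]
    exposed: list[set[int]] = []
    for m in state_models:
        m_rad = assign_radii(_Ens([m])).models[0]
        sasa = shrake_rupley(m_rad)
        rhsasa = residue_hsasa(m_rad, sasa)
        exposed.append(
            {idx for (_, idx), area in rhsasa.items() if area >= BURIAL_THRESHOLD}
        )
    return fractions, exposed


def sample_planted_ensemble(
    spec: PlantedEnsembleSpec,
) -> tuple[Ensemble, GroundTruth]:
    """Draw a seeded mixture ensemble and record the planted truth.

    Each frame picks a state by weight, applies that state's unfolding, and
    adds isotropic Gaussian coordinate noise of sd ``noise_sigma`` to every
    atom.  Separate child streams are used for state draws and noise, so
    adding draws of one kind never perturbs the other.
    """
    root = np.random.SeedSequence(spec.seed)
    state_rng, noise_rng = (np.random.default_rng(s) for s in root.spawn(2))

    state_models = _state_models(spec)
    weights = np.array([w for _, w in spec.states])
    labels = state_rng.choice(len(spec.states), size=spec.n_frames, p=weights)
    n_atoms = len(spec.native)

    models: list[StructureModel] = []
    for frame_i, s in enumerate(labels):
        coords = state_models[s].coords
        if spec.noise_sigma > 0:
            coords = coords + noise_rng.normal(
                0.0, spec.noise_sigma, size=(n_atoms, 3)
            )
        models.append(spec.native.with_coords(coords, model_id=frame_i + 1))

    fractions, exposed = _state_truth(spec, state_models)
    truth = GroundTruth(
        frame_state_labels=labels,
        per_state_native_fraction=fractions,
        per_state_exposed_residues=exposed,
        state_lambdas=[lam for lam, _ in spec.states],
        state_weights=list(weights),
    )
    return Ensemble(models, frame_interval=2.0), truth


def unfolding_lambda_for_fraction(
    topology: ToyTopology,
    native: StructureModel,
    target_percent: float,
    lam_grid: np.ndarray | None = None,
) -> float:
    """Smallest grid lambda whose noiseless contact fraction is nearest the target."""
    from .contacts import contact_fraction, reference_contacts

    reference = reference_contacts(native)
    grid = np.arange(0.0, 12.0, 0.05) if lam_grid is None else lam_grid
    fractions = np.array(
        [
            contact_fraction(apply_unfolding(native, topology, lam), reference)
            for lam in grid
        ]
    )
    return float(grid[int(np.argmin(np.abs(fractions - target_percent)))])


def write_ground_truth(truth: GroundTruth, path) -> None:
    """JSON sidecar for a planted ensemble fixture."""
    payload = {
        "frame_state_labels": truth.frame_state_labels.tolist(),
        "per_state_native_fraction": truth.per_state_native_fraction,
        "per_state_exposed_residues": [
            sorted(s) for s in truth.per_state_exposed_residues
        ],
        "state_lambdas": truth.state_lambdas,
        "state_weights": truth.state_weights,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


# --------------------------------------------------------------------------
# Ideal-geometry peptide builder (extended Ala-X-Ala references)
# --------------------------------------------------------------------------

def _place(a, b, c, bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """NeRF placement: position D bonded to C with given internal coordinates."""
    angle = np.radians(angle_deg)
    dihedral = np.radians(dihedral_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(angle),
            bond * np.sin(angle) * np.cos(dihedral),
            bond * np.sin(angle) * np.sin(dihedral),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


# (atom, (ref_a, ref_b, ref_c), bond Å, angle °, dihedral °) per residue;
# refs are names within the same residue.  Chi angles are extended (180°)
# with branches at ±60/120°; rings are planar.
_SIDECHAIN_TEMPLATES: dict[str, list[tuple[str, tuple[str, str, str], float, float, float]]] = {
    "GLY": [],
    "ALA": [("CB", ("C", "N", "CA"), 1.530, 110.4, -122.6)],
    "SER": [
        ("CB", ("C", "N", "CA"), 1.530, 110.4, -122.6),
        ("OG", ("N", "CA", "CB"), 1.417, 111.1, 180.0),
    ],
    "VAL": [
        ("CB", ("C", "N", "CA"), 1.540, 111.5, -122.6),
        ("CG1", ("N", "CA", "CB"), 1.521, 110.5, 180.0),
        ("CG2", ("N", "CA", "CB"), 1.521, 110.5, -60.0),
    ],
    "LEU": [
        # mt rotamer (chi1 = -60, chi2 = 180): the most exposed ideal rotamer
        ("CB", ("C", "N", "CA"), 1.530, 110.4, -122.6),
        ("CG", ("N", "CA", "CB"), 1.530, 116.3, -60.0),
        ("CD1", ("CA", "CB", "CG"), 1.521, 110.7, 180.0),
        ("CD2", ("CA", "CB", "CG"), 1.521, 110.7, -60.0),
    ],
    "ILE": [
        ("CB", ("C", "N", "CA"), 1.540, 111.5, -122.6),
        ("CG1", ("N", "CA", "CB"), 1.530, 110.4, 180.0),
        ("CG2", ("N", "CA", "CB"), 1.521, 110.5, -60.0),
        ("CD1", ("CA", "CB", "CG1"), 1.513, 113.8, 180.0),
    ],
    "PRO": [
        ("CB", ("C", "N", "CA"), 1.530, 103.0, -120.0),
        ("CG", ("N", "CA", "CB"), 1.492, 104.5, -30.0),
        ("CD", ("CA", "CB", "CG"), 1.503, 106.1, 35.0),
    ],
    "PHE": [
        ("CB", ("C", "N", "CA"), 1.530, 110.4, -122.6),
        ("CG", ("N", "CA", "CB"), 1.502, 113.8, 180.0),
        ("CD1", ("CA", "CB", "CG"), 1.384, 120.7, 90.0),
        ("CD2", ("CA", "CB", "CG"), 1.384, 120.7, -90.0),
        ("CE1", ("CB", "CG", "CD1"), 1.382, 120.7, 180.0),
        ("CE2", ("CB", "CG", "CD2"), 1.382, 120.7, 180.0),
        ("CZ", ("CG", "CD1", "CE1"), 1.382, 120.0, 0.0),
    ],
    "TRP": [
        ("CB", ("C", "N", "CA"), 1.530, 110.4, -122.6),
        ("CG", ("N", "CA", "CB"), 1.498, 113.6, 180.0),
        ("CD1", ("CA", "CB", "CG"), 1.365, 126.9, 90.0),
        ("CD2", ("CA", "CB", "CG"), 1.433, 126.8, -90.0),
        ("NE1", ("CB", "CG", "CD1"), 1.374, 110.2, 180.0),
        ("CE2", ("CB", "CG", "CD2"), 1.409, 107.2, 180.0),
        ("CE3", ("CB", "CG", "CD2"), 1.398, 133.9, 0.0),
        ("CZ2", ("CG", "CD2", "CE2"), 1.394, 122.4, 180.0),
        ("CZ3", ("CG", "CD2", "CE3"), 1.382, 118.7, 180.0),
        ("CH2", ("CD2", "CE2", "CZ2"), 1.368, 117.5, 0.0),
    ],
}

# Engh-Huber-style backbone internal coordinates.
_BB = {
    "N_CA": 1.458,
    "CA_C": 1.525,
    "C_O": 1.231,
    "C_N": 1.329,
    "N_CA_C": 111.0,
    "CA_C_N": 116.2,
    "C_N_CA": 121.7,
    "CA_C_O": 120.8,
}


def build_peptide(sequence: list[str], phi: float = 180.0, psi: float = 180.0) -> StructureModel:
    """Ideal-geometry peptide with uniform backbone dihedrals (default extended)."""
    unknown = [r for r in sequence if r.upper() not in _SIDECHAIN_TEMPLATES]
    if unknown:
        raise ValueError(
            f"no side-chain template for residue(s): {', '.join(unknown)}"
        )
    omega = 180.0
    backbone: list[dict[str, np.ndarray]] = []
    for i in range(len(sequence)):
        res: dict[str, np.ndarray] = {}
        if i == 0:
            res["N"] = np.zeros(3)
            res["CA"] = np.array([_BB["N_CA"], 0.0, 0.0])
            ang = np.radians(180.0 - _BB["N_CA_C"])
            res["C"] = res["CA"] + _BB["CA_C"] * np.array(
                [np.cos(ang), np.sin(ang), 0.0]
            )
        else:
            prev = backbone[i - 1]
            res["N"] = _place(
                prev["N"], prev["CA"], prev["C"], _BB["C_N"], _BB["CA_C_N"], psi
            )
            res["CA"] = _place(
                prev["CA"], prev["C"], res["N"], _BB["N_CA"], _BB["C_N_CA"], omega
            )
            res["C"] = _place(
                prev["C"], res["N"], res["CA"], _BB["CA_C"], _BB["N_CA_C"], phi
            )
        res["O"] = _place(
            res["N"], res["CA"], res["C"], _BB["C_O"], _BB["CA_C_O"], psi - 180.0
        )
        backbone.append(res)

    atoms: list[AtomRecord] = []
    serial = 1
    for i, code in enumerate(sequence):
        code = code.upper()
        placed = dict(backbone[i])
        order = ["N", "CA", "C", "O"]
        for name, refs, bond, angle, dihedral in _SIDECHAIN_TEMPLATES[code]:
            placed[name] = _place(
                placed[refs[0]], placed[refs[1]], placed[refs[2]], bond, angle, dihedral
            )
            order.append(name)
        for name in order:
            atoms.append(
                AtomRecord(
                    serial=serial,
                    name=name,
                    residue_name=code,
                    chain_id="A",
                    residue_index=i + 1,
                    coords=placed[name],
                    element="N" if name.startswith("N") else name[0],
                )
            )
            serial += 1
    return StructureModel(atoms, model_id=1)


def make_tripeptide(center_residue: str) -> StructureModel:
    """Extended (φ = ψ = 180°) Ala-X-Ala tripeptide with ideal geometry.

    This is the maximally exposed reference conformation used to normalise
    per-residue hydrophobic SASA.
    """
    return build_peptide(["ALA", center_residue.upper(), "ALA"])
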