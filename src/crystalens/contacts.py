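"""Native-contact statistic, fold classification, and interaction counters.

The native-contact reference is the set of Cα-Cα pairs in the native
structure that are closer than 6.5 Å and at least 3 residues apart in
sequence (non-local).  The percentage of those pairs retained in a frame
measures its foldedness; a cluster whose mean retention is 60% or greater
is classified folded.  Distance rules are strict ("closer than"): a pair
exactly at the cutoff does not count, and likewise for the 4 Å ionic rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import (
    DEFAULT_CLASSIFICATION,
    Ensemble,
    ResidueClassification,
    StructureModel,
)

__all__ = [
    "NativeContactSet",
    "ContactFractionSeries",
    "FoldLabel",
    "InteractionCriteria",
    "BlockErrorEstimate",
    "reference_contacts",
    "contact_fraction",
    "contact_fraction_series",
    "cluster_contact_percentage",
    "classify_fold",
    "ionic_interactions",
    "hydrogen_bonds",
    "block_errors",
    "CONTACT_CUTOFF",
    "MIN_SEPARATION",
    "FOLD_THRESHOLD",
]

CONTACT_CUTOFF = 6.5      # Å, Cα-Cα
MIN_SEPARATION = 3        # residues (non-local contacts only)
FOLD_THRESHOLD = 60.0     # %, inclusive


@dataclass
class NativeContactSet:
    """Reference residue-pair set derived from the native structure."""

    pairs: frozenset[tuple[int, int]]
    cutoff: float = CONTACT_CUTOFF
    min_separation: int = MIN_SEPARATION
    reference_id: str = ""

    def __post_init__(self) -> None:
        for a, b in self.pairs:
            if a >= b:
                raise ValueError(f"pair ({a}, {b}) must be ordered a < b")
            if b - a < self.min_separation:
                raise ValueError(
                    f"pair ({a}, {b}) violates min_separation {self.min_separation}"
                )

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class ContactFractionSeries:
    """Per-frame native-contact percentages for one ensemble."""

    per_frame_fraction: np.ndarray
    reference: NativeContactSet


@dataclass
class FoldLabel:
    """Folded/unfolded call for a cluster-level mean contact percentage."""

    label: str
    mean_fraction: float
    threshold: float = FOLD_THRESHOLD

    @property
    def is_folded(self) -> bool:
        return self.label == "folded"


@dataclass
class InteractionCriteria:
    """Distance/angle rules for ionic interactions and hydrogen bonds."""

    positive_atoms: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {"ARG": ("NE", "NH1", "NH2"), "LYS": ("NZ",)}
    )
    negative_atoms: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
    )
    ionic_cutoff: float = 4.0       # Å, strict <
    hbond_da_cutoff: float = 3.0    # Å, donor-acceptor, inclusive
    hbond_angle_cutoff: float = 20.0  # degrees off linear at H

    def __post_init__(self) -> None:
        if min(self.ionic_cutoff, self.hbond_da_cutoff, self.hbond_angle_cutoff) <= 0:
            raise ValueError("interaction cutoffs must be positive")


@dataclass
class BlockErrorEstimate:
    """Mean and between-block standard deviation of a time series."""

    mean: float
    sd: float
    block_length: float   # ps
    n_blocks: int


def _ca_positions(model: StructureModel) -> dict[int, np.ndarray]:
    """Residue index → Cα coordinate; errors if a residue lacks a Cα."""
    ca: dict[int, np.ndarray] = {}
    residues = set()
    for a in model.atoms:
        residues.add(a.residue_index)
        if a.name == "CA":
            ca[a.residue_index] = a.coords
    missing = sorted(residues - set(ca))
    if missing:
        raise ValueError(f"residue(s) {missing} have no CA atom")
    return ca


def reference_contacts(
    native: StructureModel,
    cutoff: float = CONTACT_CUTOFF,
    min_separation: int = MIN_SEPARATION,
    reference_id: str = "native",
) -> NativeContactSet:
    """Native contacts: Cα pairs closer than ``cutoff`` and ≥ ``min_separation`` apart."""
    ca = _ca_positions(native)
    indices = sorted(ca)
    pairs = set()
    for ii, a in enumerate(indices):
        for b in indices[ii + 1 :]:
            if b - a < min_separation:
                continue
            if np.linalg.norm(ca[a] - ca[b]) < cutoff:
                pairs.add((a, b))
    return NativeContactSet(frozenset(pairs), cutoff, min_separation, reference_id)


def contact_fraction(frame: StructureModel, reference: NativeContactSet) -> float:
    """Percentage of reference contacts retained by one frame."""
    if not reference.pairs:
        raise ValueError("reference contact set is empty")
    ca = _ca_positions(frame)
    present = sum(
        1
        for a, b in reference.pairs
        if np.linalg.norm(ca[a] - ca[b]) < reference.cutoff
    )
    return 100.0 * present / len(reference.pairs)


def contact_fraction_series(
    ensemble: Ensemble, reference: NativeContactSet
) -> ContactFractionSeries:
    values = np.array([contact_fraction(m, reference) for m in ensemble.models])
    return ContactFractionSeries(values, reference)


def cluster_contact_percentage(
    fractions: np.ndarray | list[float],
) -> tuple[float, float]:
    """Unweighted mean and sd of member frames' contact percentages."""
    fractions = np.asarray(fractions, dtype=float)
    if fractions.size == 0:
        raise ValueError("cluster has no member frames")
    return float(fractions.mean()), float(fractions.std())


def classify_fold(mean_fraction: float, threshold: float = FOLD_THRESHOLD) -> FoldLabel:
    """Folded iff the mean native-contact percentage is ≥ threshold (inclusive)."""
    if not 0.0 <= mean_fraction <= 100.0:
        raise ValueError(f"mean_fraction {mean_fraction} outside [0, 100]")
    label = "folded" if mean_fraction >= threshold else "unfolded"
    return FoldLabel(label, mean_fraction, threshold)


def _charged_atom_coords(
    model: StructureModel, residue_index: int, names: tuple[str, ...]
) -> np.ndarray:
    found = {
        a.name: a.coords
        for a in model.atoms
        if a.residue_index == residue_index and a.name in names
    }
    missing = [n for n in names if n not in found]
    if missing:
        raise ValueError(
            f"residue {residue_index} is missing charged atom(s) {missing}"
        )
    return np.array([found[n] for n in names])


def ionic_interactions(
    ensemble: Ensemble,
    pair: tuple[int, int],
    criteria: InteractionCriteria | None = None,
) -> tuple[np.ndarray, float]:
    """Per-frame presence of a salt bridge between two residues, plus occupancy %.

    ``pair`` is (positively charged residue index, negatively charged
    residue index).  A frame counts as bonded when the minimum over all
    positive-atom x negative-atom distances (e.g. the six Arg-Asp
    distances) is strictly below the ionic cutoff.
    """
    criteria = criteria or InteractionCriteria()
    pos_res, neg_res = pair
    names = ensemble.models[0].residue_names()
    name_of = {idx: rn for (_, idx), rn in names.items()}
    try:
        pos_atoms = criteria.positive_atoms[name_of[pos_res]]
        neg_atoms = criteria.negative_atoms[name_of[neg_res]]
    except KeyError as exc:
        raise ValueError(
            f"residue {exc.args[0]!r} has no charged-atom definition"
        ) from exc

    present = np.zeros(ensemble.n_frames, dtype=bool)
    for fi, model in enumerate(ensemble.models):
        p = _charged_atom_coords(model, pos_res, pos_atoms)
        q = _charged_atom_coords(model, neg_res, neg_atoms)
        d = np.linalg.norm(p[:, None, :] - q[None, :, :], axis=-1)
        present[fi] = bool(np.min(d) < criteria.ionic_cutoff)
    occupancy = 100.0 * present.mean()
    return present, occupancy


def _hbond_partners(model: StructureModel):
    """Heuristic donor/acceptor typing from N/O heavy atoms.

    All N and hydroxyl O atoms can donate; all O atoms (and His ring N)
    can accept.  Hydrogens, when present, are associated with the nearest
    donor heavy atom.
    """
    donors, acceptors, hydrogens = [], [], []
    for i, a in enumerate(model.atoms):
        if a.element == "N":
            donors.append(i)
            if a.name in ("ND1", "NE2"):
                acceptors.append(i)
        elif a.element == "O":
            acceptors.append(i)
            if a.name in ("OG", "OG1", "OH", "OW"):
                donors.append(i)
        elif a.element == "H":
            hydrogens.append(i)
    return donors, acceptors, hydrogens


def hydrogen_bonds(
    frame: StructureModel, criteria: InteractionCriteria | None = None
) -> list[tuple[int, int]]:
    """Hydrogen bonds as (donor atom index, acceptor atom index) pairs.

    A bond requires donor-acceptor distance ≤ the cutoff and — when the
    structure contains hydrogens — a D-H···A angle within the angular
    cutoff of linear.  Without hydrogens the criterion degrades to
    distance-only (a notice is logged once per call).
    """
    import logging

    criteria = criteria or InteractionCriteria()
    donors, acceptors, hydrogens = _hbond_partners(frame)
    coords = frame.coords
    have_h = bool(hydrogens)
    if not have_h:
        logging.getLogger(__name__).info(
            "no hydrogens present; hydrogen bonds use the distance-only criterion"
        )
    h_of_donor: dict[int, list[int]] = {}
    if have_h:
        for h in hydrogens:
            dists = [np.linalg.norm(coords[h] - coords[d]) for d in donors]
            nearest = donors[int(np.argmin(dists))]
            if min(dists) < 1.3:
                h_of_donor.setdefault(nearest, []).append(h)

    bonds: list[tuple[int, int]] = []
    for d in donors:
        for acc in acceptors:
            if acc == d:
                continue
            if frame.atoms[d].residue_index == frame.atoms[acc].residue_index:
                continue
            if np.linalg.norm(coords[d] - coords[acc]) > criteria.hbond_da_cutoff:
                continue
            if have_h and d in h_of_donor:
                ok = False
                for h in h_of_donor[d]:
                    dh = coords[d] - coords[h]
                    ha = coords[acc] - coords[h]
                    cosang = np.dot(dh, ha) / (
                        np.linalg.norm(dh) * np.linalg.norm(ha)
                    )
                    angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
                    # D-H...A angle: 180° is linear
                    if 180.0 - angle <= criteria.hbond_angle_cutoff:
                        ok = True
                        break
                if not ok:
                    continue
            elif have_h:
                # donors without an attached hydrogen cannot donate
                continue
            bonds.append((d, acc))
    return bonds


def block_errors(
    series: np.ndarray | list[float],
    frame_interval: float,
    block_length: float = 10000.0,
) -> BlockErrorEstimate:
    """Block-averaged mean and standard deviation of a per-frame series.

    The series is cut into consecutive blocks of ``block_length`` ps
    (default 10 ns); the trailing partial block is discarded.  The sd is
    the sample standard deviation over per-block means — at least 2 full
    blocks are required.
    """
    series = np.asarray(series, dtype=float)
    frames_per_block = int(block_length / frame_interval)
    if frames_per_block < 1:
        raise ValueError("block_length shorter than one frame interval")
    n_blocks = series.size // frames_per_block
    if n_blocks < 2:
        raise ValueError(
            f"series spans {series.size * frame_interval:g} ps; "
            f"need at least 2 blocks of {block_length:g} ps"
        )
    trimmed = series[: n_blocks * frames_per_block]
    block_means = trimmed.reshape(n_blocks, frames_per_block).mean(axis=1)
    return BlockErrorEstimate(
        mean=float(block_means.mean()),
        sd=float(block_means.std(ddof=1)),
        block_length=block_length,
        n_blocks=n_blocks,
    )
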