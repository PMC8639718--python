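"""Solvent-accessible surface area and hydrophobic patch detection.

Implements the rolling-ball (Shrake–Rupley) algorithm with a deterministic
Fibonacci-lattice quadrature, the per-residue hydrophobic SASA (rhSASA)
readout, the 50 Å² burial mask, tripeptide reference areas, and detection
of continuous hydrophobic surface patches — the aggregation-propensity
signal of the pipeline.

rhSASA here is whole-residue area (backbone + side chain) of hydrophobic
residues, consistent with the Ala-X-Ala reference convention; a
side-chain-only variant is available via ``sidechain_only=True``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .io import (
    DEFAULT_CLASSIFICATION,
    Ensemble,
    ResidueClassification,
    StructureModel,
)

__all__ = [
    "SASAResult",
    "PatchSet",
    "fibonacci_sphere",
    "shrake_rupley",
    "residue_hsasa",
    "buried_mask",
    "tripeptide_reference",
    "hydrophobic_patches",
    "grouped_rhsasa",
    "BURIAL_THRESHOLD",
]

#: rhSASA below this (Å²) classifies a residue as buried.
BURIAL_THRESHOLD = 50.0

#: Default probe (water) radius in Å.
PROBE_RADIUS = 1.4

#: Default number of quadrature points per atom sphere.
N_SPHERE_POINTS = 960


@dataclass
class SASAResult:
    """Per-atom and per-residue accessible areas (Å²) for one model."""

    per_atom_area: np.ndarray
    per_residue_area: dict[tuple[str, int], float]
    probe_radius: float
    n_sphere_points: int


@dataclass
class PatchSet:
    """Connected hydrophobic surface patches.

    Each patch is a (residue-id set, combined rhSASA Å²) pair; patches are
    disjoint and each forms a connected van der Waals contact graph.
    """

    patches: list[tuple[frozenset[tuple[str, int]], float]]
    contact_tolerance: float

    @property
    def largest_area(self) -> float:
        return max((area for _, area in self.patches), default=0.0)

    @property
    def total_area(self) -> float:
        """Combined exposed hydrophobic area over all patches."""
        return sum(area for _, area in self.patches)


def fibonacci_sphere(n: int) -> np.ndarray:
    """``n`` near-uniform unit-sphere points on a Fibonacci (golden) lattice.

    Deterministic, so every SASA value in the package is reproducible
    bit-for-bit.
    """
    i = np.arange(n, dtype=float)
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = 2.0 * np.pi * i / golden
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def shrake_rupley(
    model: StructureModel,
    probe: float = PROBE_RADIUS,
    n_points: int = N_SPHERE_POINTS,
) -> SASAResult:
    """Rolling-ball SASA of one model.

    Each atom's area is the unoccluded fraction of ``n_points`` lattice
    points on its probe-expanded sphere times 4π(r+probe)².  All atoms
    must carry assigned van der Waals radii (see
    :func:`crystalens.io.assign_radii`).
    """
    if n_points < 92:
        raise ValueError("n_points must be >= 92 for a usable quadrature")
    radii = model.radii
    if np.any(radii <= 0):
        bad = model.atoms[int(np.argmin(radii))]
        raise ValueError(
            f"unassigned van der Waals radius on atom {bad.name} "
            f"(residue {bad.residue_name} {bad.residue_index}); "
            "run assign_radii first"
        )
    coords = model.coords
    n_atoms = len(model)
    sphere = fibonacci_sphere(n_points)
    expanded = radii + probe

    tree = cKDTree(coords)
    # Neighbour lists: atom j can occlude i iff |xi - xj| < Ri' + Rj'.
    max_r = expanded.max()
    pairs = tree.query_pairs(2.0 * max_r, output_type="ndarray")
    neighbours: list[list[int]] = [[] for _ in range(n_atoms)]
    if len(pairs):
        d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
        keep = d < expanded[pairs[:, 0]] + expanded[pairs[:, 1]]
        for i, j in pairs[keep]:
            neighbours[i].append(j)
            neighbours[j].append(i)

    areas = np.empty(n_atoms)
    for i in range(n_atoms):
        pts = coords[i] + expanded[i] * sphere
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbours[i]:
            if not accessible.any():
                break
            d2 = np.einsum(
                "ij,ij->i", pts[accessible] - coords[j], pts[accessible] - coords[j]
            )
            sub = d2 >= expanded[j] ** 2
            idx = np.flatnonzero(accessible)
            accessible[idx[~sub]] = False
        areas[i] = accessible.sum() / n_points * 4.0 * np.pi * expanded[i] ** 2

    per_res: dict[tuple[str, int], float] = {}
    for a, area in zip(model.atoms, areas):
        key = (a.chain_id, a.residue_index)
        per_res[key] = per_res.get(key, 0.0) + float(area)
    return SASAResult(areas, per_res, probe, n_points)


def residue_hsasa(
    model: StructureModel,
    sasa: SASAResult,
    classification: ResidueClassification = DEFAULT_CLASSIFICATION,
    sidechain_only: bool = False,
) -> dict[tuple[str, int], float]:
    """Per-residue hydrophobic SASA (rhSASA, Å²).

    Reported only for residues whose 3-letter code is in the hydrophobic
    set; other residues are omitted (not zero-filled).
    """
    names = model.residue_names()
    if sidechain_only:
        from .io import BACKBONE_ATOMS

        per_res: dict[tuple[str, int], float] = {}
        for a, area in zip(model.atoms, sasa.per_atom_area):
            if a.name in BACKBONE_ATOMS:
                continue
            key = (a.chain_id, a.residue_index)
            per_res[key] = per_res.get(key, 0.0) + float(area)
    else:
        per_res = dict(sasa.per_residue_area)
    return {
        key: per_res.get(key, 0.0)
        for key in names
        if names[key] in classification.hydrophobic_set
    }


def buried_mask(
    rhsasa: dict[tuple[str, int], float], threshold: float = BURIAL_THRESHOLD
) -> dict[tuple[str, int], bool]:
    """Buried iff rhSASA is strictly below ``threshold`` (default 50 Å²)."""
    return {key: area < threshold for key, area in rhsasa.items()}


_TRIPEPTIDE_CACHE: dict[tuple[str, float, int], float] = {}


def tripeptide_reference(
    residue: str, probe: float = PROBE_RADIUS, n_points: int = N_SPHERE_POINTS
) -> float:
    """Maximally exposed reference rhSASA (Å²) of a hydrophobic residue.

    Computed as the central-residue SASA of an extended Ala-X-Ala
    tripeptide; cached per residue.
    """
    residue = residue.upper()
    if residue not in DEFAULT_CLASSIFICATION.hydrophobic_set:
        raise ValueError(
            f"{residue} is not in the hydrophobic reference set "
            f"{sorted(DEFAULT_CLASSIFICATION.hydrophobic_set)}"
        )
    key = (residue, probe, n_points)
    if key not in _TRIPEPTIDE_CACHE:
        from .synthetic import make_tripeptide
        from .io import assign_radii, Ensemble

        model = make_tripeptide(residue)
        model = assign_radii(Ensemble([model])).models[0]
        sasa = shrake_rupley(model, probe=probe, n_points=n_points)
        chain = model.atoms[0].chain_id
        _TRIPEPTIDE_CACHE[key] = sasa.per_residue_area[(chain, 2)]
    return _TRIPEPTIDE_CACHE[key]


def hydrophobic_patches(
    model: StructureModel,
    sasa: SASAResult,
    classification: ResidueClassification = DEFAULT_CLASSIFICATION,
    exposure_floor: float = BURIAL_THRESHOLD,
    contact_tolerance: float = 0.5,
) -> PatchSet:
    """Continuous hydrophobic surface patches.

    Nodes are hydrophobic residues with rhSASA ≥ ``exposure_floor``; two
    nodes are connected when any inter-residue atom pair is within van der
    Waals contact (d < r_i + r_j + ``contact_tolerance``).  Patches are the
    connected components; a patch's area is the sum of its members' rhSASA.
    """
    import networkx as nx

    if exposure_floor < 0:
        raise ValueError("exposure_floor must be >= 0")
    rhsasa = residue_hsasa(model, sasa, classification)
    nodes = [key for key, area in rhsasa.items() if area >= exposure_floor]
    graph = nx.Graph()
    graph.add_nodes_from(nodes)

    atom_by_res: dict[tuple[str, int], list[int]] = {}
    for i, a in enumerate(model.atoms):
        atom_by_res.setdefault((a.chain_id, a.residue_index), []).append(i)
    coords = model.coords
    radii = model.radii
    for ia, ra in enumerate(nodes):
        for rb in nodes[ia + 1 :]:
            ai = atom_by_res[ra]
            bi = atom_by_res[rb]
            d = np.linalg.norm(
                coords[ai][:, None, :] - coords[bi][None, :, :], axis=-1
            )
            lim = radii[ai][:, None] + radii[bi][None, :] + contact_tolerance
            if np.any(d < lim):
                graph.add_edge(ra, rb)

    patches = [
        (frozenset(comp), float(sum(rhsasa[r] for r in comp)))
        for comp in nx.connected_components(graph)
    ]
    patches.sort(key=lambda p: (-p[1], sorted(p[0])))
    return PatchSet(patches, contact_tolerance)


def grouped_rhsasa(
    ensemble: Ensemble,
    frame_groups: dict[str, list[int]],
    classification: ResidueClassification = DEFAULT_CLASSIFICATION,
    probe: float = PROBE_RADIUS,
    n_points: int = N_SPHERE_POINTS,
    hotspot_threshold: float = 3.0,
) -> tuple[dict[str, dict[tuple[str, int], float]], list[tuple[str, int]]]:
    """Mean per-residue rhSASA of the folded and unfolded frame groups.

    ``frame_groups`` maps a group name (typically ``"folded"`` /
    ``"unfolded"``) to frame indices; every listed group must be non-empty.
    Returns the per-group mean rhSASA and the exposure hotspots — residues
    whose unfolded-minus-folded difference exceeds ``hotspot_threshold``
    (Å²; only computed when both canonical groups are present).
    """
    means: dict[str, dict[tuple[str, int], float]] = {}
    for name, frames in frame_groups.items():
        if not frames:
            raise ValueError(
                f"group {name!r} has no frames; run in single-group mode by "
                "omitting it"
            )
        acc: dict[tuple[str, int], float] = {}
        for fi in frames:
            model = ensemble.models[fi]
            sasa = shrake_rupley(model, probe=probe, n_points=n_points)
            for key, area in residue_hsasa(model, sasa, classification).items():
                acc[key] = acc.get(key, 0.0) + area
        means[name] = {key: area / len(frames) for key, area in acc.items()}

    hotspots: list[tuple[str, int]] = []
    if "folded" in means and "unfolded" in means:
        for key in means["unfolded"]:
            diff = means["unfolded"][key] - means["folded"].get(key, 0.0)
            if diff > hotspot_threshold:
                hotspots.append(key)
        hotspots.sort()
    return means, hotspots
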