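"""Superposition and per-frame/per-residue conformational descriptors.

Covers optimal rigid-body superposition (Kabsch), radius of gyration,
RMSF about an iteratively refined mean structure, Cα-covariance principal
component analysis, two-coordinate free-energy surfaces, and the Schlitter
upper-bound configurational entropy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import constants
from scipy.spatial.transform import Rotation

from .io import Ensemble, StructureModel

__all__ = [
    "SuperpositionResult",
    "CovarianceModel",
    "FreeEnergySurface",
    "kabsch_superpose",
    "radius_of_gyration",
    "rmsf",
    "iterative_mean_structure",
    "pca_modes",
    "free_energy_surface",
    "schlitter_entropy",
    "covariance_model",
    "CARBON_MASS_KG",
]

#: Mass of a carbon atom in kg (used for all-Cα covariances).
CARBON_MASS_KG = 12.011e-3 / constants.N_A


@dataclass
class SuperpositionResult:
    """Optimal proper rotation + translation mapping mobile onto reference."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class CovarianceModel:
    """Mass/temperature context for the Schlitter entropy.

    ``covariance`` is the 3N×3N positional covariance in Å²;
    ``masses`` are per-atom masses in kg.
    """

    mean_coords: np.ndarray
    covariance: np.ndarray
    temperature: float
    masses: np.ndarray


@dataclass
class FreeEnergySurface:
    """Binned −kT·ln P surface; empty bins are NaN (unset), minimum is 0."""

    free_energy: np.ndarray   # kcal/mol, (bins, bins)
    edges1: np.ndarray
    edges2: np.ndarray
    temperature: float


def kabsch_superpose(
    mobile: np.ndarray, reference: np.ndarray
) -> SuperpositionResult:
    """Least-squares rigid superposition of two matched point sets.

    Returns the proper rotation (reflections excluded) and translation
    minimising the RMSD of ``mobile`` onto ``reference``.  Degenerate
    (collinear or < 3 point) inputs are rejected because the rotation is
    then underdetermined.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("point sets must both be (n, 3)")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("superposition needs at least 3 points")
    if not (np.all(np.isfinite(mobile)) and np.all(np.isfinite(reference))):
        raise ValueError("coordinates must be finite")

    mob_c = mobile - mobile.mean(axis=0)
    ref_c = reference - reference.mean(axis=0)
    # Collinear sets leave a free rotation about the common axis.
    for pts in (mob_c, ref_c):
        if np.linalg.matrix_rank(pts, tol=1e-8) < 2:
            raise ValueError("degenerate (collinear) point set")

    rot, _ = Rotation.align_vectors(ref_c, mob_c)
    matrix = rot.as_matrix()
    translation = reference.mean(axis=0) - rot.apply(mobile.mean(axis=0))
    # evaluate the residual directly: the Gram-based shortcut loses ~7
    # digits to cancellation for near-identical sets
    residual = mob_c @ matrix.T - ref_c
    rmsd = float(np.sqrt(np.mean(np.sum(residual**2, axis=1))))
    return SuperpositionResult(matrix, translation, rmsd)


def radius_of_gyration(
    model: StructureModel, selection: list[int] | None = None
) -> float:
    """Unweighted radius of gyration (Å) over the selected atoms."""
    coords = model.coords
    if selection is not None:
        if len(selection) == 0:
            raise ValueError("selection is empty")
        coords = coords[np.asarray(selection, dtype=int)]
    centroid = coords.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum((coords - centroid) ** 2, axis=1))))


def iterative_mean_structure(
    coords: np.ndarray, n_iter: int = 5
) -> tuple[np.ndarray, np.ndarray]:
    """Superpose frames onto an iteratively refined mean.

    Starts from the first frame, alternates superposition and averaging
    ``n_iter`` times.  Returns (superposed frames, mean coordinates).
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 3 or coords.shape[0] < 2:
        raise ValueError("need a (n_frames >= 2, n_atoms, 3) coordinate array")
    mean = coords[0]
    aligned = coords
    for _ in range(n_iter):
        aligned = np.stack(
            [kabsch_superpose(f, mean).apply(f) for f in coords]
        )
        mean = aligned.mean(axis=0)
    return aligned, mean


def rmsf(ensemble: Ensemble, selection: list[int]) -> np.ndarray:
    """Per-atom root mean square fluctuation (Å) about the refined mean.

    Frames are superposed onto the iteratively refined mean structure of
    the selection before fluctuations are measured, so rigid-body motion
    contributes nothing.
    """
    if ensemble.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    coords = ensemble.coords(selection)
    aligned, mean = iterative_mean_structure(coords)
    sq = np.sum((aligned - mean) ** 2, axis=2)   # (frames, atoms)
    return np.sqrt(sq.mean(axis=0))


def pca_modes(
    ensemble: Ensemble, selection: list[int]
) -> tuple[np.ndarray, np.ndarray, float]:
    """Principal components of the superposed Cα covariance.

    Returns (eigenvalues Å² descending, eigenvectors as columns,
    concerted-motion magnitude).  The magnitude is defined here as the
    square root of the first eigenvalue (Å) — the RMS amplitude along the
    dominant collective mode; raw eigenvalues are returned so other
    definitions can be applied.
    """
    if ensemble.n_frames < 2:
        raise ValueError("PCA needs at least 2 frames")
    coords = ensemble.coords(selection)
    aligned, mean = iterative_mean_structure(coords)
    flat = (aligned - mean).reshape(aligned.shape[0], -1)
    cov = np.cov(flat, rowvar=False, bias=True)
    cov = np.atleast_2d(cov)
    eigenvalues, eigenvectors = np.linalg.eigh(cov)
    order = np.argsort(eigenvalues)[::-1]
    eigenvalues = np.clip(eigenvalues[order], 0.0, None)
    eigenvectors = eigenvectors[:, order]
    return eigenvalues, eigenvectors, float(np.sqrt(eigenvalues[0]))


def free_energy_surface(
    proj1: np.ndarray,
    proj2: np.ndarray,
    temperature: float = 300.0,
    bins: int = 25,
) -> FreeEnergySurface:
    """Two-coordinate free-energy surface F = −kT·ln(P/P_max) in kcal/mol.

    The most occupied bin is exactly 0; bins with no frames are NaN
    rather than an infinite/sentinel value.
    """
    proj1 = np.asarray(proj1, dtype=float)
    proj2 = np.asarray(proj2, dtype=float)
    if proj1.shape != proj2.shape:
        raise ValueError("projections must have equal length")
    if bins < 2:
        raise ValueError("bins must be >= 2")
    counts, e1, e2 = np.histogram2d(proj1, proj2, bins=bins)
    kt = constants.k * temperature * constants.N_A / 4184.0   # kcal/mol
    with np.errstate(divide="ignore"):
        logp = np.log(counts / counts.max())
    fes = np.where(counts > 0, -kt * logp, np.nan)
    return FreeEnergySurface(fes, e1, e2, temperature)


def covariance_model(
    ensemble: Ensemble,
    selection: list[int],
    temperature: float = 300.0,
    masses: np.ndarray | None = None,
) -> CovarianceModel:
    """Mass-annotated Cα-fluctuation covariance of a superposed ensemble.

    By default every selected atom is given the carbon mass (all-Cα
    convention).
    """
    coords = ensemble.coords(selection)
    aligned, mean = iterative_mean_structure(coords)
    flat = (aligned - mean).reshape(aligned.shape[0], -1)
    cov = np.atleast_2d(np.cov(flat, rowvar=False, bias=True))
    n_atoms = coords.shape[1]
    if masses is None:
        masses = np.full(n_atoms, CARBON_MASS_KG)
    return CovarianceModel(mean.reshape(-1), cov, temperature, np.asarray(masses))


def schlitter_entropy(model: CovarianceModel) -> float:
    """Schlitter upper-bound configurational entropy, J·mol⁻¹·K⁻¹.

    S = (k_B/2)·ln det(1 + k_B·T·e²/ħ² · M·σ), with σ the positional
    covariance (converted to m²) and M the per-coordinate mass matrix;
    the k_B prefactor is multiplied by Avogadro's number to report a
    per-mole value.  Zero covariance gives S = 0; scaling σ up can only
    increase S.
    """
    if model.temperature <= 0:
        raise ValueError("temperature must be positive")
    if np.any(model.masses <= 0):
        raise ValueError("masses must be positive")
    cov = np.asarray(model.covariance, dtype=float)
    if cov.shape[0] != cov.shape[1] or cov.shape[0] != 3 * model.masses.size:
        raise ValueError("covariance must be 3N x 3N matching the masses")
    sym_err = np.abs(cov - cov.T).max()
    if sym_err > 1e-8:
        raise ValueError("covariance is not symmetric")
    eigvals = np.linalg.eigvalsh(cov)
    if eigvals.min() < -1e-8 * max(1.0, abs(eigvals.max())):
        raise ValueError("covariance is not positive semi-definite")

    cov_m2 = cov * 1e-20
    mass_per_coord = np.repeat(model.masses, 3)
    alpha = (
        constants.k
        * model.temperature
        * np.e**2
        / constants.hbar**2
    )
    arg = np.eye(cov.shape[0]) + alpha * (mass_per_coord[:, None] * cov_m2)
    sign, logdet = np.linalg.slogdet(arg)
    if sign <= 0:
        raise ValueError("determinant argument not positive definite")
    return float(0.5 * constants.k * constants.N_A * logdet)
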