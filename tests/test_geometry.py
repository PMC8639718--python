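"""Superposition, Rg, RMSF, PCA, free-energy surfaces, Schlitter entropy."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import constants, optimize
from scipy.spatial.transform import Rotation

from crystalens.geometry import (
    CARBON_MASS_KG,
    CovarianceModel,
    covariance_model,
    free_energy_surface,
    kabsch_superpose,
    pca_modes,
    radius_of_gyration,
    rmsf,
    schlitter_entropy,
)
from crystalens.io import Ensemble, select_atoms
from crystalens.synthetic import PlantedEnsembleSpec, build_native_toy, sample_planted_ensemble

RNG = np.random.default_rng(42)


# ---------------------------------------------------------------- Kabsch

def test_identical_sets_superpose_to_zero_rmsd():
    pts = RNG.normal(size=(6, 3))
    result = kabsch_superpose(pts, pts)
    assert result.rmsd == pytest.approx(0.0, abs=1e-10)
    np.testing.assert_allclose(result.rotation, np.eye(3), atol=1e-8)


def test_rmsd_invariant_under_rigid_motion():
    pts = RNG.normal(size=(8, 3))
    rot = Rotation.from_euler("xyz", [0.3, -1.1, 2.0]).as_matrix()
    moved = pts @ rot.T + np.array([5.0, -2.0, 1.5])
    result = kabsch_superpose(moved, pts)
    assert result.rmsd == pytest.approx(0.0, abs=1e-8)
    assert np.linalg.det(result.rotation) == pytest.approx(1.0, abs=1e-9)


def test_kabsch_agrees_with_rotation_search_oracle():
    """4-point set with one displaced point vs direct minimisation."""
    ref = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
    mob = ref.copy()
    mob[3] += [0.0, 0.0, 1.0]  # 1 Å displacement

    ref_c = ref - ref.mean(axis=0)
    mob_c = mob - mob.mean(axis=0)

    def rmsd_of(euler):
        rot = Rotation.from_euler("xyz", euler).as_matrix()
        return np.sqrt(np.mean(np.sum((mob_c @ rot.T - ref_c) ** 2, axis=1)))

    best = np.inf
    for seed in range(20):
        start = np.random.default_rng(seed).uniform(-np.pi, np.pi, 3)
        res = optimize.minimize(rmsd_of, start, method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12})
        best = min(best, res.fun)
    assert kabsch_superpose(mob, ref).rmsd == pytest.approx(best, abs=1e-3)


def test_rmsd_is_symmetric():
    a = RNG.normal(size=(5, 3))
    b = RNG.normal(size=(5, 3))
    assert kabsch_superpose(a, b).rmsd == pytest.approx(
        kabsch_superpose(b, a).rmsd, abs=1e-10
    )


@pytest.mark.parametrize(
    "mobile",
    [
        np.zeros((2, 3)),
        np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]]),  # collinear
    ],
)
def test_degenerate_point_sets_are_rejected(mobile):
    with pytest.raises(ValueError):
        kabsch_superpose(mobile, mobile)


# ------------------------------------------------------- radius of gyration

def _point_model(points):
    from crystalens.io import AtomRecord, StructureModel

    atoms = [
        AtomRecord(i + 1, "CA", "GLY", "A", i + 1, np.asarray(p, float), "C")
        for i, p in enumerate(points)
    ]
    return StructureModel(atoms)


def test_rg_single_atom_is_zero():
    assert radius_of_gyration(_point_model([[1.0, 2.0, 3.0]])) == 0.0


def test_rg_two_atoms_is_half_distance():
    model = _point_model([[0, 0, 0], [0, 0, 3.0]])
    assert radius_of_gyration(model) == pytest.approx(1.5)


def test_rg_cube_corners_edge_two_is_sqrt_three():
    corners = [[x, y, z] for x in (0, 2) for y in (0, 2) for z in (0, 2)]
    assert radius_of_gyration(_point_model(corners)) == pytest.approx(np.sqrt(3.0))


def test_rg_empty_selection_rejected(toy16):
    _, native = toy16
    with pytest.raises(ValueError):
        radius_of_gyration(native, [])


# ------------------------------------------------------------------- RMSF

def _ensemble_from_coords(frames):
    """Frames: (n_frames, n_atoms, 3) of CA pseudo-atoms."""
    base = _point_model(frames[0])
    return Ensemble([base.with_coords(f, model_id=i + 1) for i, f in enumerate(frames)])


def test_rmsf_zero_for_identical_frames():
    pts = RNG.normal(size=(5, 3)) * 4.0
    ens = _ensemble_from_coords(np.stack([pts] * 4))
    np.testing.assert_allclose(rmsf(ens, list(range(5))), 0.0, atol=1e-12)


def test_rmsf_zero_after_removing_rigid_body_motion():
    pts = RNG.normal(size=(6, 3)) * 4.0
    frames = []
    for k in range(5):
        rot = Rotation.from_euler("z", 0.4 * k).as_matrix()
        frames.append(pts @ rot.T + k * np.array([1.0, -2.0, 0.5]))
    ens = _ensemble_from_coords(np.stack(frames))
    np.testing.assert_allclose(rmsf(ens, list(range(6))), 0.0, atol=1e-8)


def test_rmsf_requires_two_frames():
    ens = _ensemble_from_coords(RNG.normal(size=(1, 4, 3)))
    with pytest.raises(ValueError):
        rmsf(ens, list(range(4)))


# -------------------------------------------------------------------- PCA

def test_pca_zero_variance_gives_zero_eigenvalues():
    pts = RNG.normal(size=(5, 3))
    ens = _ensemble_from_coords(np.stack([pts] * 3))
    eigenvalues, _, concerted = pca_modes(ens, list(range(5)))
    np.testing.assert_allclose(eigenvalues, 0.0, atol=1e-12)
    assert concerted == 0.0


def test_pca_planted_oscillation_recovers_amplitude():
    """Breathing mode of amplitude a: first eigenvalue = a^2/2.

    The mode is radial (orthogonal to every rigid-body motion), so the
    internal superposition leaves it untouched; a unit-norm collective
    mode with coefficient a·sin(ωt) has variance a²/2 along itself.
    """
    corners = np.array(
        [[x, y, z] for x in (-2.0, 2.0) for y in (-2.0, 2.0) for z in (-2.0, 2.0)]
    )
    radial = corners / np.linalg.norm(corners, axis=1, keepdims=True)
    mode = radial / np.sqrt(len(corners))   # unit norm as a 3N vector
    amplitude = 0.5
    phases = 2 * np.pi * np.arange(2000) / 200.0
    frames = corners + amplitude * np.sin(phases)[:, None, None] * mode
    ens = _ensemble_from_coords(frames)
    eigenvalues, _, concerted = pca_modes(ens, list(range(8)))
    assert eigenvalues[0] == pytest.approx(amplitude**2 / 2.0, rel=0.05)
    assert eigenvalues[1] == pytest.approx(0.0, abs=1e-6)
    assert concerted == pytest.approx(np.sqrt(eigenvalues[0]))


def test_pca_trace_equals_total_variance(planted):
    _, _, ensemble, _ = planted
    sub = ensemble.subset(range(0, 100))
    ca = select_atoms(sub.models[0], "CA")
    eigenvalues, _, _ = pca_modes(sub, ca)
    from crystalens.geometry import iterative_mean_structure

    aligned, mean = iterative_mean_structure(sub.coords(ca))
    flat = (aligned - mean).reshape(aligned.shape[0], -1)
    assert eigenvalues.sum() == pytest.approx(flat.var(axis=0).sum(), abs=1e-8)


# ---------------------------------------------------- free-energy surface

def test_fes_uniform_occupancy_is_flat_zero():
    proj = np.repeat([0.5, 1.5, 2.5, 3.5], 25)
    fes = free_energy_surface(proj, proj, 300.0, bins=4)
    diag = np.diag(fes.free_energy)
    np.testing.assert_allclose(diag, 0.0, atol=1e-12)


def test_fes_80_20_occupancy_matches_closed_form():
    proj1 = np.array([0.25] * 80 + [0.75] * 20)
    proj2 = np.full(100, 0.5)
    fes = free_energy_surface(proj1, proj2, 300.0, bins=2)
    kt = constants.k * 300.0 * constants.N_A / 4184.0
    values = fes.free_energy[np.isfinite(fes.free_energy)]
    assert sorted(values) == pytest.approx([0.0, -kt * np.log(0.25)], abs=1e-9)
    assert -kt * np.log(0.25) == pytest.approx(0.826, abs=0.005)


def test_fes_invariant_to_doubling_counts():
    rng = np.random.default_rng(0)
    p1, p2 = rng.normal(size=100), rng.normal(size=100)
    once = free_energy_surface(p1, p2, 300.0, bins=5).free_energy
    twice = free_energy_surface(
        np.concatenate([p1, p1]), np.concatenate([p2, p2]), 300.0, bins=5
    ).free_energy
    np.testing.assert_allclose(once, twice, equal_nan=True, atol=1e-12)


def test_fes_empty_bins_are_nan_not_infinite():
    fes = free_energy_surface(np.zeros(10), np.zeros(10), 300.0, bins=3)
    assert np.isnan(fes.free_energy).sum() == 8
    assert np.nanmin(fes.free_energy) == 0.0


# -------------------------------------------------------- Schlitter entropy

def _cov_model(cov, masses=None, temperature=300.0):
    n = cov.shape[0] // 3
    masses = np.full(n, CARBON_MASS_KG) if masses is None else masses
    return CovarianceModel(np.zeros(cov.shape[0]), cov, temperature, masses)


def test_schlitter_zero_covariance_is_zero_entropy():
    assert schlitter_entropy(_cov_model(np.zeros((3, 3)))) == 0.0


def test_schlitter_scalar_closed_form():
    """One fluctuating coordinate: S = (R/2) ln(1 + kTe^2 m sigma^2 / hbar^2)."""
    sigma_sq = 0.01  # Å²
    cov = np.diag([sigma_sq, 0.0, 0.0])
    expected = (
        0.5
        * constants.R
        * np.log(
            1.0
            + constants.k
            * 300.0
            * np.e**2
            * CARBON_MASS_KG
            * (sigma_sq * 1e-20)
            / constants.hbar**2
        )
    )
    assert schlitter_entropy(_cov_model(cov)) == pytest.approx(expected, rel=1e-12)


def test_schlitter_monotone_in_covariance_scale():
    rng = np.random.default_rng(1)
    a = rng.normal(size=(6, 6))
    cov = a @ a.T * 0.01
    small = schlitter_entropy(_cov_model(cov))
    large = schlitter_entropy(_cov_model(4.0 * cov))
    assert large > small > 0.0


def test_schlitter_rejects_non_psd_covariance():
    cov = np.diag([1.0, -0.5, 0.2])
    with pytest.raises(ValueError, match="positive semi-definite"):
        schlitter_entropy(_cov_model(cov))


def test_disorder_ordering_entropy_and_rmsf(toy16):
    """More planted disorder -> larger Schlitter entropy and mean RMSF."""
    topo, native = toy16
    entropies, mean_rmsfs = [], []
    for sigma in (0.1, 0.25, 0.5):
        spec = PlantedEnsembleSpec(
            topo, native, states=[(0.0, 1.0)], noise_sigma=sigma,
            n_frames=300, seed=3,
        )
        ens, _ = sample_planted_ensemble(spec)
        ca = select_atoms(ens.models[0], "CA")
        entropies.append(schlitter_entropy(covariance_model(ens, ca)))
        mean_rmsfs.append(float(rmsf(ens, ca).mean()))
    assert entropies == sorted(entropies)
    assert mean_rmsfs == sorted(mean_rmsfs)
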