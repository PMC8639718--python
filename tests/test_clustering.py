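"""GROMOS peeling, network components, centroids, entropy, convergence."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, strategies as st

from crystalens.clustering import (
    PairwiseRMSDMatrix,
    centroid_structure,
    cluster_entropy,
    convergence_windows,
    gromos_cluster,
    network_cluster,
    pairwise_rmsd_matrix,
)
from crystalens.geometry import kabsch_superpose
from crystalens.io import Ensemble, select_atoms
from crystalens.synthetic import (
    PlantedEnsembleSpec,
    build_native_toy,
    sample_planted_ensemble,
)


def _matrix(values):
    values = np.asarray(values, dtype=float)
    return PairwiseRMSDMatrix(values, list(range(values.shape[0])))


def _random_matrix(rng, n, scale=5.0):
    pts = rng.uniform(0, scale, size=(n, 2))
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    return _matrix(d)


def _gromos_oracle(values, cutoff):
    """Literal peeling re-implementation used as an independent oracle."""
    n = values.shape[0]
    pool = set(range(n))
    clusters = []
    while pool:
        best_centre, best_members = None, None
        for c in sorted(pool):
            members = {j for j in pool if j != c and values[c, j] < cutoff}
            if best_members is None or len(members) > len(best_members):
                best_centre, best_members = c, members
        clusters.append((best_centre, best_members | {best_centre}))
        pool -= best_members | {best_centre}
    return clusters


# ---------------------------------------------------------- RMSD matrix

def test_duplicated_frame_gives_zero_off_diagonal(toy16):
    _, native = toy16
    ens = Ensemble([native.with_coords(native.coords, model_id=i) for i in (1, 2)])
    matrix = pairwise_rmsd_matrix(ens, select_atoms(native, "CA"))
    assert matrix.values[0, 1] == pytest.approx(0.0, abs=1e-9)


def test_rigid_motion_between_frames_gives_zero_rmsd(toy16):
    from scipy.spatial.transform import Rotation

    _, native = toy16
    rot = Rotation.from_euler("xyz", [0.2, 0.4, -0.6]).as_matrix()
    moved = native.coords @ rot.T + np.array([3.0, 1.0, -2.0])
    ens = Ensemble([native, native.with_coords(moved, model_id=2)])
    matrix = pairwise_rmsd_matrix(ens, select_atoms(native, "CA"))
    assert matrix.values[0, 1] == pytest.approx(0.0, abs=1e-8)


def test_matrix_agrees_with_per_pair_superposition_oracle(toy16):
    topo, native = toy16
    spec = PlantedEnsembleSpec(
        topo, native, states=[(0.5, 1.0)], noise_sigma=0.4, n_frames=5, seed=2
    )
    ens, _ = sample_planted_ensemble(spec)
    ca = select_atoms(ens.models[0], "CA")
    matrix = pairwise_rmsd_matrix(ens, ca)
    coords = ens.coords(ca)
    for i in range(5):
        for j in range(5):
            expected = 0.0 if i == j else kabsch_superpose(coords[j], coords[i]).rmsd
            assert matrix.values[i, j] == pytest.approx(expected, abs=1e-9)


def test_matrix_validation_rejects_asymmetry():
    bad = np.array([[0.0, 1.0], [2.0, 0.0]])
    with pytest.raises(ValueError, match="symmetric"):
        _matrix(bad)


# ------------------------------------------------------ GROMOS clustering

def test_cutoff_above_max_is_one_cluster():
    rng = np.random.default_rng(0)
    matrix = _random_matrix(rng, 8)
    result = gromos_cluster(matrix, cutoff=matrix.values.max() + 1.0)
    assert result.n_clusters == 1
    assert result.populations[0] == pytest.approx(100.0)


def test_cutoff_below_min_positive_gives_singletons():
    rng = np.random.default_rng(1)
    matrix = _random_matrix(rng, 7)
    positive = matrix.values[matrix.values > 0]
    result = gromos_cluster(matrix, cutoff=positive.min() / 2.0)
    assert result.n_clusters == 7
    assert all(p == pytest.approx(100 / 7) for p in result.populations)


def test_two_tight_triads_recover_two_clusters():
    # frames 0-2 mutually within 1 Å, frames 3-5 likewise; groups 10 Å apart
    v = np.full((6, 6), 10.0)
    for grp in ([0, 1, 2], [3, 4, 5]):
        for i in grp:
            for j in grp:
                v[i, j] = 0.0 if i == j else 1.0
    result = gromos_cluster(_matrix(v), cutoff=2.0)
    assert result.n_clusters == 2
    assert set(result.labels[:3]) == {1} and set(result.labels[3:]) == {2}
    oracle = _gromos_oracle(v, 2.0)
    assert {frozenset(m) for _, m in oracle} == {
        frozenset([0, 1, 2]),
        frozenset([3, 4, 5]),
    }


@given(st.integers(0, 500), st.floats(0.5, 6.0))
def test_gromos_matches_peeling_oracle(seed, cutoff):
    rng = np.random.default_rng(seed)
    matrix = _random_matrix(rng, rng.integers(3, 10))
    result = gromos_cluster(matrix, cutoff)
    oracle = _gromos_oracle(matrix.values, cutoff)
    assert {frozenset(m) for _, m in oracle} == {
        frozenset(np.flatnonzero(result.labels == c).tolist())
        for c in range(1, result.n_clusters + 1)
    }


@given(st.integers(0, 200))
def test_gromos_cluster_count_non_increasing_in_cutoff(seed):
    rng = np.random.default_rng(seed)
    matrix = _random_matrix(rng, 8)
    counts = [
        gromos_cluster(matrix, c).n_clusters for c in (0.5, 1.5, 3.0, 6.0, 12.0)
    ]
    assert counts == sorted(counts, reverse=True)


def test_gromos_permutation_equivariance():
    rng = np.random.default_rng(9)
    matrix = _random_matrix(rng, 9)
    perm = rng.permutation(9)
    permuted = _matrix(matrix.values[np.ix_(perm, perm)])
    base = gromos_cluster(matrix, 2.5)
    shuffled = gromos_cluster(permuted, 2.5)
    base_parts = {
        frozenset(np.flatnonzero(base.labels == c).tolist())
        for c in range(1, base.n_clusters + 1)
    }
    shuffled_parts = {
        frozenset(perm[i] for i in np.flatnonzero(shuffled.labels == c))
        for c in range(1, shuffled.n_clusters + 1)
    }
    assert base_parts == shuffled_parts


# ----------------------------------------------------- network clustering

def test_auto_cutoff_on_uniform_matrix_gives_singletons():
    v = np.full((5, 5), 2.0)
    np.fill_diagonal(v, 0.0)
    result = network_cluster(_matrix(v), "auto")
    assert result.cutoff == pytest.approx(2.0)
    assert result.n_clusters == 5   # strict < leaves no edges


def test_planted_two_state_components_have_planted_populations(planted, planted_assignment):
    _, _, _, truth = planted
    _, assignment = planted_assignment
    counts = np.bincount(truth.frame_state_labels, minlength=2)
    assert assignment.n_clusters == 2
    assert assignment.populations[0] == pytest.approx(100 * counts.max() / 500, abs=1e-9)
    assert abs(assignment.populations[0] - 90.0) <= 5.0
    assert abs(assignment.populations[1] - 10.0) <= 5.0


def test_duplicated_frame_network_is_single_component(toy16):
    _, native = toy16
    ens = Ensemble(
        [native.with_coords(native.coords, model_id=i + 1) for i in range(20)]
    )
    matrix = pairwise_rmsd_matrix(ens, select_atoms(native, "CA"))
    result = network_cluster(matrix, cutoff=1.0)
    assert result.n_clusters == 1
    assert result.populations[0] == pytest.approx(100.0)


# ------------------------------------------------------------- centroids

def test_singleton_cluster_centroid_is_that_frame():
    v = np.zeros((3, 3))
    assert centroid_structure(_matrix(v), [2]) == 2


def test_three_frames_on_a_line_pick_the_middle():
    v = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 1.0], [2.0, 1.0, 0.0]])
    assert centroid_structure(_matrix(v), [0, 1, 2]) == 1


def test_symmetric_tie_breaks_to_lower_frame_id():
    v = np.array([[0.0, 1.0], [1.0, 0.0]])
    assert centroid_structure(_matrix(v), [0, 1]) == 0


@given(st.integers(0, 300))
def test_centroid_matches_mean_distance_oracle(seed):
    rng = np.random.default_rng(seed)
    matrix = _random_matrix(rng, 8)
    members = sorted(rng.choice(8, size=5, replace=False).tolist())
    medoid = centroid_structure(matrix, members)
    sub = matrix.values[np.ix_(members, members)]
    means = sub.mean(axis=1)  # constant offset from /(k-1) does not matter
    assert medoid == members[int(np.argmin(means))]


# --------------------------------------------------------- cluster entropy

def test_entropy_of_single_cluster_is_zero():
    assert cluster_entropy([1.0]) == 0.0


def test_entropy_uniform_four_is_ln_four():
    assert cluster_entropy([0.25] * 4) == pytest.approx(np.log(4.0))


def test_entropy_direct_formula_example():
    assert cluster_entropy([0.5, 0.25, 0.25]) == pytest.approx(1.0397, abs=1e-4)


def test_entropy_rejects_negative_probability():
    with pytest.raises(ValueError):
        cluster_entropy([1.2, -0.2])


@given(st.lists(st.floats(0.01, 1.0), min_size=1, max_size=8))
def test_entropy_bounded_by_log_cluster_count(weights):
    p = np.array(weights) / np.sum(weights)
    assert -1e-12 <= cluster_entropy(p) <= np.log(len(p)) + 1e-9


# ------------------------------------------------------------ convergence

def _stationary_ensemble(n_frames, interval_ps=1000.0):
    topo, native = build_native_toy(8, seed=4)
    spec = PlantedEnsembleSpec(
        topo, native, states=[(0.0, 1.0)], noise_sigma=0.05,
        n_frames=n_frames, seed=6,
    )
    ens, _ = sample_planted_ensemble(spec)
    ens.frame_interval = interval_ps
    return ens


def test_stationary_ensemble_has_constant_single_cluster():
    ens = _stationary_ensemble(60)   # 60 ns at 1 ns/frame
    ca = select_atoms(ens.models[0], "CA")
    report = convergence_windows(ens, ca, window_ns=20.0, cutoff=5.0)
    assert np.all(report.n_clusters_per_window == 1)
    np.testing.assert_allclose(report.entropy_per_window, 0.0, atol=1e-12)


def test_state_switch_shifts_cluster_count_at_the_boundary():
    topo, native = build_native_toy(8, seed=4)
    half_a, _ = sample_planted_ensemble(PlantedEnsembleSpec(
        topo, native, states=[(0.0, 1.0)], noise_sigma=0.05, n_frames=30, seed=1))
    half_b, _ = sample_planted_ensemble(PlantedEnsembleSpec(
        topo, native, states=[(6.0, 1.0)], noise_sigma=0.05, n_frames=30, seed=2))
    ens = Ensemble(half_a.models + half_b.models, frame_interval=1000.0)
    ca = select_atoms(ens.models[0], "CA")
    # 2 Å cutoff resolves the two states (their Cα RMSD is a few Å)
    report = convergence_windows(ens, ca, window_ns=20.0, step_ns=10.0, cutoff=2.0)
    assert report.n_clusters_per_window.max() >= 2   # mixed window
    assert report.n_clusters_per_window[0] == 1
    assert report.n_clusters_per_window[-1] == 1


def test_window_equal_to_span_is_one_window():
    ens = _stationary_ensemble(20)
    ca = select_atoms(ens.models[0], "CA")
    report = convergence_windows(ens, ca, window_ns=20.0, step_ns=20.0, cutoff=5.0)
    assert len(report.window_starts_ns) == 1


def test_window_longer_than_span_is_rejected():
    ens = _stationary_ensemble(10)
    ca = select_atoms(ens.models[0], "CA")
    with pytest.raises(ValueError, match="exceeds"):
        convergence_windows(ens, ca, window_ns=20.0)
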