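"""Shared fixtures: toy structures and the planted two-state ensemble."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from crystalens.io import Ensemble, assign_radii, select_atoms
from crystalens.synthetic import (
    PlantedEnsembleSpec,
    build_native_toy,
    sample_planted_ensemble,
    unfolding_lambda_for_fraction,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy16():
    """Deterministic 16-residue native toy: (topology, structure)."""
    return build_native_toy(16, seed=1)


@pytest.fixture(scope="session")
def toy16_radii(toy16):
    """Native toy with van der Waals radii assigned."""
    _, native = toy16
    return assign_radii(Ensemble([native])).models[0]


@pytest.fixture(scope="session")
def planted(toy16):
    """Two-state planted ensemble: ~75%/~45% contact fractions, 0.9/0.1.

    Matches the recovery study conditions (500 frames, seed 7); radii are
    assigned so SASA stages can run directly.
    """
    topo, native = toy16
    lam_folded = unfolding_lambda_for_fraction(topo, native, 75.0)
    lam_unfolded = unfolding_lambda_for_fraction(topo, native, 45.0)
    spec = PlantedEnsembleSpec(
        topo,
        native,
        states=[(lam_folded, 0.9), (lam_unfolded, 0.1)],
        n_frames=500,
        seed=7,
    )
    ensemble, truth = sample_planted_ensemble(spec)
    return topo, native, assign_radii(ensemble), truth


@pytest.fixture(scope="session")
def planted_assignment(planted):
    """Network clustering (auto cutoff) of the planted ensemble."""
    from crystalens.clustering import network_cluster, pairwise_rmsd_matrix

    _, _, ensemble, _ = planted
    ca = select_atoms(ensemble.models[0], "CA")
    matrix = pairwise_rmsd_matrix(ensemble, ca)
    return matrix, network_cluster(matrix, "auto")
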