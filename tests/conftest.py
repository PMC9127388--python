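"""Shared fixtures: analytic ring geometries and pre-solved benchmarks."""

from __future__ import annotations

import numpy as np
import pytest

from plaquefatigue.cohort import CohortConfig, VesselGeometry, generate_cohort
from plaquefatigue.fe import SolverConfig, solve_inflation
from plaquefatigue.material import material_table
from plaquefatigue.preprocess import ReferenceGeometry, build_mesh


def make_ring(r_lumen: float, r_eem: float, n: int = 64,
              p_min: float = 0.0, p_max: float = 1.0) -> VesselGeometry:
    """Concentric circular ring cross-section (polygonal approximation)."""
    th = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    lum = np.column_stack([r_lumen * np.cos(th), r_lumen * np.sin(th)])
    eem = np.column_stack([r_eem * np.cos(th), r_eem * np.sin(th)])
    return VesselGeometry("P01", "S001", "baseline", lum, eem, [], p_min, p_max)


@pytest.fixture(scope="session")
def materials():
    return material_table()


@pytest.fixture(scope="session")
def thin_ring_mesh():
    """Thin-wall cylinder t/r = 0.1 (r = 2 mm, t = 0.2 mm), coarse mesh.

    256 contour vertices keep the polygonal ripple well below the
    discretization error, so the axisymmetric oracle applies.
    """
    ref = ReferenceGeometry(make_ring(2.0, 2.2, n=256), 1.0, axial_shrinkage=0.0)
    return build_mesh(ref, target_edge_length=0.1)


@pytest.fixture(scope="session")
def thin_ring_solution(thin_ring_mesh, materials):
    """Small-load inflation of the thin ring (P = 0.2 kPa, lambda_z = 1)."""
    cfg = SolverConfig(n_load_increments=4, axial_stretch=1.0)
    return solve_inflation(thin_ring_mesh, materials, 0.2, cfg)


@pytest.fixture(scope="session")
def small_cohort():
    """2 patients x 5 slices, default generative link."""
    return generate_cohort(
        CohortConfig(n_patients=2, slices_per_patient=(5, 5), n_slices_total=None,
                     seed=7)
    )


@pytest.fixture(scope="session")
def surrogate_table():
    """Full-scale synthetic cohort feature table (surrogate mechanics)."""
    from plaquefatigue.features import cohort_feature_table

    cohort = generate_cohort(CohortConfig(seed=11))
    return cohort_feature_table(cohort.pairs, mode="surrogate")
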