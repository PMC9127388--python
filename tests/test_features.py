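"""Factor extraction: amplitude identities, morphology, outcome labelling."""

from types import SimpleNamespace

import numpy as np
import pytest
from shapely.geometry import Polygon

from plaquefatigue.features import (
    FACTOR_COLUMNS,
    cohort_feature_table,
    fatigue_amplitudes,
    luminal_stats,
    morphology,
    slice_features_surrogate,
    stenosis_outcome,
)
from conftest import make_ring


def fake_solution(mesh, stress_values, strain_values, pressure=10.0):
    """FESolution stand-in with prescribed nodal fields (synthetic)."""
    n = mesh.n_nodes
    return SimpleNamespace(
        mesh=mesh,
        pressure=pressure,
        node_max_stress=np.broadcast_to(stress_values, (n,)).copy(),
        node_max_strain=np.broadcast_to(strain_values, (n,)).copy(),
        lumen_area=7.0,
        wall_area=6.0,
        eem_area=13.0,
    )


class TestLuminalStats:
    def test_uniform_field(self, thin_ring_mesh):
        sol = fake_solution(thin_ring_mesh, 5.0, 0.1)
        (smax, savg), (emax, eavg) = luminal_stats(sol)
        assert (smax, savg) == (5.0, 5.0)
        assert (emax, eavg) == pytest.approx((0.1, 0.1))

    def test_max_and_mean(self, thin_ring_mesh):
        sol = fake_solution(thin_ring_mesh, 0.0, 0.0)
        nodes = thin_ring_mesh.lumen_nodes[:3]
        sol.node_max_stress[nodes] = [1.0, 2.0, 3.0]
        smax, savg = luminal_stats(sol, nodes)[0]
        assert (smax, savg) == (3.0, 2.0)

    def test_empty_node_set_rejected(self, thin_ring_mesh):
        sol = fake_solution(thin_ring_mesh, 1.0, 0.0)
        with pytest.raises(ValueError, match="empty"):
            luminal_stats(sol, np.array([], dtype=int))


class TestFatigueAmplitudes:
    def test_identical_solutions_zero(self, thin_ring_mesh):
        sol = fake_solution(thin_ring_mesh, 4.0, 0.05)
        amps = fatigue_amplitudes(sol, sol)
        assert all(v == 0.0 for v in amps.values())

    def test_direct_subtraction(self, thin_ring_mesh):
        lo = fake_solution(thin_ring_mesh, 0.0, 0.0)
        hi = fake_solution(thin_ring_mesh, 0.0, 0.0)
        nodes = thin_ring_mesh.lumen_nodes
        # luminal (max, avg) stress (10, 8) -> (16, 12)
        lo.node_max_stress[nodes] = 8.0
        lo.node_max_stress[nodes[0]] = 10.0
        hi.node_max_stress[nodes] = 12.0
        hi.node_max_stress[nodes[0]] = 16.0
        amps = fatigue_amplitudes(lo, hi)
        n = len(nodes)
        assert amps["max_stress_amplitude"] == pytest.approx(6.0)
        assert amps["avg_stress_amplitude"] == pytest.approx(
            (12.0 + 4.0 / n) - (8.0 + 2.0 / n)
        )

    def test_mesh_mismatch_rejected(self, thin_ring_mesh, materials):
        from plaquefatigue.preprocess import ReferenceGeometry, build_mesh

        other = build_mesh(ReferenceGeometry(make_ring(1.0, 1.4, n=32), 1.0), 0.3)
        a = fake_solution(thin_ring_mesh, 1.0, 0.0)
        b = fake_solution(other, 1.0, 0.0)
        with pytest.raises(ValueError, match="same mesh"):
            fatigue_amplitudes(a, b)


class TestMorphology:
    def test_plaque_burden_and_areas(self):
        at_pmin = SimpleNamespace(lumen_area=6.0, wall_area=6.0, eem_area=12.0)
        at_pmax = SimpleNamespace(lumen_area=7.2, wall_area=6.1, eem_area=13.3)
        m = morphology(at_pmin, at_pmax)
        assert m["pb_at_pmin"] == 50.0
        assert m["wall_area_at_pmin"] == 6.0
        assert m["lumen_area_amplitude"] == pytest.approx(1.2)
        assert m["wall_area_amplitude"] == pytest.approx(0.1)

    def test_amplitude_example(self):
        at_pmin = SimpleNamespace(lumen_area=6.8, wall_area=6.0, eem_area=12.8)
        at_pmax = SimpleNamespace(lumen_area=7.2, wall_area=6.1, eem_area=13.3)
        m = morphology(at_pmin, at_pmax)
        assert m["lumen_area_amplitude"] == pytest.approx(0.4)
        assert m["wall_area_amplitude"] == pytest.approx(0.1)

    def test_degenerate_rejected(self):
        bad = SimpleNamespace(lumen_area=-1.0, wall_area=6.0, eem_area=5.0)
        with pytest.raises(ValueError):
            morphology(bad, bad)

    def test_polygon_circle_area(self):
        contour = make_ring(1.0, 2.0).lumen_contour  # 64-vertex unit circle
        assert Polygon(contour).area == pytest.approx(np.pi, rel=0.002)


class TestStenosisOutcome:
    @pytest.mark.parametrize(
        "base, follow, dla, label",
        [(8.0, 6.5, 1.5, 1), (6.5, 8.0, -1.5, 0), (7.0, 7.0, 0.0, 0)],
    )
    def test_examples(self, base, follow, dla, label):
        got_dla, got_label = stenosis_outcome(base, follow)
        assert got_dla == pytest.approx(dla)
        assert got_label == label

    def test_nonpositive_area_rejected(self):
        with pytest.raises(ValueError):
            stenosis_outcome(0.0, 1.0)


class TestFeatureTable:
    def test_nineteen_columns_in_fixed_order(self, surrogate_table):
        assert len(FACTOR_COLUMNS) == 19
        expected = ["patient_id", "slice_id", *FACTOR_COLUMNS, "dla", "label"]
        assert list(surrogate_table.columns) == expected

    def test_label_consistent_with_dla(self, surrogate_table):
        np.testing.assert_array_equal(
            surrogate_table.label.to_numpy(),
            (surrogate_table.dla > 0).astype(int).to_numpy(),
        )

    def test_amplitude_identities_exact(self, surrogate_table):
        t = surrogate_table
        for amp, hi, lo in [
            ("max_stress_amplitude", "max_stress_at_pmax", "max_stress_at_pmin"),
            ("avg_stress_amplitude", "avg_stress_at_pmax", "avg_stress_at_pmin"),
            ("max_strain_amplitude", "max_strain_at_pmax", "max_strain_at_pmin"),
            ("avg_strain_amplitude", "avg_strain_at_pmax", "avg_strain_at_pmin"),
            ("lumen_area_amplitude", "lumen_area_at_pmax", "lumen_area_at_pmin"),
            ("wall_area_amplitude", "wall_area_at_pmax", "wall_area_at_pmin"),
        ]:
            np.testing.assert_allclose(t[amp], t[hi] - t[lo], rtol=0, atol=1e-12)

    def test_plaque_burden_bounds(self, surrogate_table):
        assert surrogate_table.pb_at_pmin.between(0, 100).all()

    def test_fatigue_dla_sign_recovery(self):
        """With gamma_fatigue > 0 the stress-amplitude/DLA correlation is +."""
        from plaquefatigue.cohort import CohortConfig, generate_cohort

        for seed in (1, 2, 3, 4, 5):
            cohort = generate_cohort(CohortConfig(seed=seed))
            table = cohort_feature_table(cohort.pairs, mode="surrogate")
            corr = np.corrcoef(table.avg_stress_amplitude, table.dla)[0, 1]
            assert corr > 0
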