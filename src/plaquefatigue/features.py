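"""Per-slice predictors: fatigue amplitudes, morphology, and the outcome.

Twelve biomechanical factors (maximum and average of the max-principal
stress and strain on the lumen boundary, at minimum and maximum pressure,
plus their four cardiac-cycle amplitudes) and seven morphological factors
(plaque burden at minimum pressure, lumen/wall areas at both pressures, and
their amplitudes) are extracted per baseline slice.  Stenosis progression is
measured by the delta lumen area DLA = baseline - follow-up lumen area; a
slice is labelled 1 (narrowing) iff DLA > 0.

Amplitudes are definitions — max-pressure quantity minus min-pressure
quantity, exactly.  Luminal "average" is the unweighted mean over lumen
boundary nodes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import VesselGeometry, radius_profile
from .fe import FESolution, SolverConfig, solve_pair

__all__ = [
    "FACTOR_COLUMNS",
    "SliceFeatures",
    "luminal_stats",
    "fatigue_amplitudes",
    "morphology",
    "stenosis_outcome",
    "slice_features_surrogate",
    "slice_features_fe",
    "cohort_feature_table",
]

#: The 19 predictor columns, in fixed order (12 biomechanical + 7 morphological).
FACTOR_COLUMNS = [
    "max_stress_at_pmin",
    "avg_stress_at_pmin",
    "max_stress_at_pmax",
    "avg_stress_at_pmax",
    "max_strain_at_pmin",
    "avg_strain_at_pmin",
    "max_strain_at_pmax",
    "avg_strain_at_pmax",
    "max_stress_amplitude",
    "avg_stress_amplitude",
    "max_strain_amplitude",
    "avg_strain_amplitude",
    "pb_at_pmin",
    "lumen_area_at_pmin",
    "lumen_area_at_pmax",
    "wall_area_at_pmin",
    "wall_area_at_pmax",
    "lumen_area_amplitude",
    "wall_area_amplitude",
]


@dataclass
class SliceFeatures:
    """The 19 baseline factors plus outcome for one slice pair."""

    patient_id: str
    slice_id: str
    factors: dict[str, float]
    dla: float
    label: int

    def __post_init__(self) -> None:
        missing = set(FACTOR_COLUMNS) - set(self.factors)
        if missing:
            raise ValueError(f"missing factors: {sorted(missing)}")
        if self.label != int(self.dla > 0):
            raise ValueError("label must be 1 iff dla > 0")
        pb = self.factors["pb_at_pmin"]
        if not 0.0 <= pb <= 100.0:
            raise ValueError(f"plaque burden {pb:.3g} outside [0, 100]")

    def to_row(self) -> dict:
        row = {"patient_id": self.patient_id, "slice_id": self.slice_id}
        row.update({k: self.factors[k] for k in FACTOR_COLUMNS})
        row.update({"dla": self.dla, "label": self.label})
        return row


def luminal_stats(solution: FESolution, lumen_nodes: np.ndarray | None = None):
    """(max, average) of nodal max-principal stress and strain on the lumen.

    Returns ``((max_stress, avg_stress), (max_strain, avg_strain))``.
    """
    nodes = solution.mesh.lumen_nodes if lumen_nodes is None else np.asarray(lumen_nodes)
    if len(nodes) == 0:
        raise ValueError("empty lumen node set")
    s = solution.node_max_stress[nodes]
    e = solution.node_max_strain[nodes]
    return (float(s.max()), float(s.mean())), (float(e.max()), float(e.mean()))


def fatigue_amplitudes(sol_min: FESolution, sol_max: FESolution) -> dict[str, float]:
    """Cardiac-cycle amplitudes of luminal max/average stress and strain."""
    if sol_min.mesh is not sol_max.mesh and not np.array_equal(
        sol_min.mesh.elements, sol_max.mesh.elements
    ):
        raise ValueError("solutions are not on the same mesh")
    (smax0, savg0), (emax0, eavg0) = luminal_stats(sol_min)
    (smax1, savg1), (emax1, eavg1) = luminal_stats(sol_max)
    return {
        "max_stress_amplitude": smax1 - smax0,
        "avg_stress_amplitude": savg1 - savg0,
        "max_strain_amplitude": emax1 - emax0,
        "avg_strain_amplitude": eavg1 - eavg0,
    }


def morphology(at_pmin, at_pmax) -> dict[str, float]:
    """Plaque burden and lumen/wall areas at both pressures, plus amplitudes.

    Accepts any objects exposing ``lumen_area``, ``wall_area`` and
    ``eem_area`` in the corresponding deformed configuration
    (:class:`~plaquefatigue.fe.FESolution` or
    :class:`~plaquefatigue.cohort.VesselGeometry`).
    """
    for obj in (at_pmin, at_pmax):
        if obj.lumen_area <= 0 or obj.eem_area <= 0:
            raise ValueError("non-positive area (degenerate or self-intersecting contour)")
    plaque = at_pmin.eem_area - at_pmin.lumen_area
    return {
        "pb_at_pmin": 100.0 * plaque / at_pmin.eem_area,
        "lumen_area_at_pmin": at_pmin.lumen_area,
        "lumen_area_at_pmax": at_pmax.lumen_area,
        "wall_area_at_pmin": at_pmin.wall_area,
        "wall_area_at_pmax": at_pmax.wall_area,
        "lumen_area_amplitude": at_pmax.lumen_area - at_pmin.lumen_area,
        "wall_area_amplitude": at_pmax.wall_area - at_pmin.wall_area,
    }


def stenosis_outcome(baseline_lumen_area: float, followup_lumen_area: float):
    """DLA (mm^2) and the binary progression label (1 = narrowing).

    DLA = 0 counts as non-narrowing (label 0).
    """
    if baseline_lumen_area <= 0 or followup_lumen_area <= 0:
        raise ValueError("lumen areas must be positive")
    dla = baseline_lumen_area - followup_lumen_area
    return dla, int(dla > 0)


# ---------------------------------------------------------------------------
# Surrogate feature path: closed-form thin-wall mechanics, for generation-time
# checks and fast end-to-end runs without the FE solver.


def slice_features_surrogate(
    baseline: VesselGeometry,
    followup: VesselGeometry,
    e_eff: float = 400.0,
    n_rays: int = 64,
) -> SliceFeatures:
    """Thin-wall (Laplace) surrogate of the full FE feature extraction.

    Hoop stress ``p r / t`` (mean thickness for the average, thinnest point
    for the maximum), linearized strain ``sigma / E`` with an effective wall
    modulus that stiffens with plaque burden (``E = e_eff * (1 + 0.8 PB)``),
    and linearized pressure-area compliance.  Useful wherever relative
    ordering, not absolute stress accuracy, matters.
    """
    g = baseline
    center = g.lumen_centroid
    thetas = np.linspace(0.0, 2.0 * np.pi, n_rays, endpoint=False)
    t = radius_profile(g.eem_contour, center, thetas) - radius_profile(
        g.lumen_contour, center, thetas
    )
    if np.any(t <= 0):
        raise ValueError("non-positive wall thickness")
    t_mean, t_min = float(t.mean()), float(t.min())
    a_lum = g.lumen_area
    a_eem = g.eem_area
    r_eq = math.sqrt(a_lum / math.pi)
    r_eem_eq = math.sqrt(a_eem / math.pi)
    p0, p1 = g.pressure_min, g.pressure_max
    # plaque-laden walls are effectively stiffer; also decouples strain
    # features from being exact multiples of the stress features
    e_eff = e_eff * (1.0 + 0.8 * (a_eem - a_lum) / a_eem)

    def stress(p):
        return p * r_eq / t_mean, p * r_eq / t_min  # (avg, max)

    savg0, smax0 = stress(p0)
    savg1, smax1 = stress(p1)

    def lumen_area(p):
        return a_lum * (1.0 + 2.0 * (p - p0) * r_eq / (t_mean * e_eff))

    def eem_area(p):
        return a_eem + (lumen_area(p) - a_lum) * (r_eq / r_eem_eq)

    al0, al1 = lumen_area(p0), lumen_area(p1)
    aw0, aw1 = eem_area(p0) - al0, eem_area(p1) - al1

    factors = {
        "max_stress_at_pmin": smax0,
        "avg_stress_at_pmin": savg0,
        "max_stress_at_pmax": smax1,
        "avg_stress_at_pmax": savg1,
        "max_strain_at_pmin": smax0 / e_eff,
        "avg_strain_at_pmin": savg0 / e_eff,
        "max_strain_at_pmax": smax1 / e_eff,
        "avg_strain_at_pmax": savg1 / e_eff,
        "max_stress_amplitude": smax1 - smax0,
        "avg_stress_amplitude": savg1 - savg0,
        "max_strain_amplitude": (smax1 - smax0) / e_eff,
        "avg_strain_amplitude": (savg1 - savg0) / e_eff,
        "pb_at_pmin": 100.0 * aw0 / (al0 + aw0),
        "lumen_area_at_pmin": al0,
        "lumen_area_at_pmax": al1,
        "wall_area_at_pmin": aw0,
        "wall_area_at_pmax": aw1,
        "lumen_area_amplitude": al1 - al0,
        "wall_area_amplitude": aw1 - aw0,
    }
    dla, label = stenosis_outcome(baseline.lumen_area, followup.lumen_area)
    return SliceFeatures(g.patient_id, g.slice_id, factors, dla, label)


# ---------------------------------------------------------------------------
# Full FE feature path.


def slice_features_fe(
    baseline: VesselGeometry,
    followup: VesselGeometry,
    materials: dict | None = None,
    solver_config: SolverConfig | None = None,
    target_edge_length: float = 0.08,
    shrink_tolerance: float = 0.01,
) -> SliceFeatures:
    """Extract the 19 factors by shrink + mesh + inflate at both pressures.

    DLA uses the imaged (minimum-pressure-matched) lumen areas of the two
    timepoints, as an image-derived quantity.
    """
    from dataclasses import replace

    from .material import material_table
    from .preprocess import build_mesh, find_circumferential_shrink

    materials = materials or material_table()
    config = solver_config or SolverConfig()
    ref = find_circumferential_shrink(
        baseline, materials, tolerance=shrink_tolerance,
        target_edge_length=target_edge_length, solver_config=config,
    )
    mesh = build_mesh(ref, target_edge_length)
    config = replace(config, axial_stretch=ref.axial_stretch)
    sol_min, sol_max = solve_pair(
        mesh, materials, baseline.pressure_min, baseline.pressure_max, config
    )
    (smax0, savg0), (emax0, eavg0) = luminal_stats(sol_min)
    (smax1, savg1), (emax1, eavg1) = luminal_stats(sol_max)
    factors = {
        "max_stress_at_pmin": smax0,
        "avg_stress_at_pmin": savg0,
        "max_stress_at_pmax": smax1,
        "avg_stress_at_pmax": savg1,
        "max_strain_at_pmin": emax0,
        "avg_strain_at_pmin": eavg0,
        "max_strain_at_pmax": emax1,
        "avg_strain_at_pmax": eavg1,
    }
    factors.update(fatigue_amplitudes(sol_min, sol_max))
    factors.update(morphology(sol_min, sol_max))
    dla, label = stenosis_outcome(baseline.lumen_area, followup.lumen_area)
    return SliceFeatures(baseline.patient_id, baseline.slice_id, factors, dla, label)


def cohort_feature_table(
    pairs,
    mode: str = "surrogate",
    **kwargs,
) -> pd.DataFrame:
    """Feature table for a cohort: one row per baseline slice.

    Columns: patient_id, slice_id, the 19 factors (fixed order), dla, label.
    This table is the contract between the mechanics and statistics stages.
    """
    if mode == "surrogate":
        rows = [slice_features_surrogate(b, f, **kwargs).to_row() for b, f in pairs]
    elif mode == "fe":
        rows = [slice_features_fe(b, f, **kwargs).to_row() for b, f in pairs]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return pd.DataFrame(rows, columns=["patient_id", "slice_id", *FACTOR_COLUMNS, "dla", "label"])
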