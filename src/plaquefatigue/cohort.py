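"""Synthetic baseline/follow-up IVUS slice-pair cohorts.

Real VH-IVUS pullbacks for this kind of study are not publicly deposited, so
the pipeline is exercised on synthetic cohorts that reproduce the structure
the analysis assumes: a handful of patients each contributing tens of
cross-sections; smooth eccentric lumen and external-elastic-membrane (EEM)
contours with optional lipid/calcification inclusions; per-patient diastolic
and systolic pressures; and a generative rule in which the follow-up change
of lumen area (DLA, mm^2) depends positively on the pulsatile hoop-stress
amplitude and negatively on plaque burden, with a patient-level random
intercept:

    DLA = gamma0 + gamma_fatigue * A_surr + gamma_pb * PB + b_patient + eps

where ``A_surr`` is the thin-wall (Laplace) hoop-stress amplitude surrogate,
``b_patient ~ N(0, sigma_patient^2)`` and ``eps ~ N(0, sigma_noise^2)``.

Contours are 64-vertex polygons built from a radius function
``r(theta) = base * (1 + eccentricity*cos(theta - phi) + low-order Fourier)``,
which gives IVUS-like smooth eccentric lumens.  The follow-up geometry
rescales only the lumen (uniformly, to the new area); the EEM is held fixed.
"""

from __future__ import annotations

import json
import math
import pathlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from shapely.geometry import LinearRing, LineString, Point, Polygon

__all__ = [
    "CohortConfig",
    "VesselGeometry",
    "Cohort",
    "generate_cohort",
    "surrogate_stress_amplitude",
    "polygon_area",
    "radius_profile",
    "save_cohort",
    "load_geometry",
    "load_cohort",
]


def polygon_area(vertices: np.ndarray) -> float:
    """Area of a simple polygon (shoelace, via shapely)."""
    return Polygon(np.asarray(vertices)).area


@dataclass
class VesselGeometry:
    """One cross-section at one timepoint: contours in mm, pressures in kPa."""

    patient_id: str
    slice_id: str
    timepoint: str  # "baseline" | "followup"
    lumen_contour: np.ndarray  # (n, 2), closed implicitly, CCW
    eem_contour: np.ndarray
    components: list[tuple[str, np.ndarray]] = field(default_factory=list)
    pressure_min: float = 10.67
    pressure_max: float = 16.0
    slice_thickness: float = 0.5

    def __post_init__(self) -> None:
        self.lumen_contour = np.asarray(self.lumen_contour, dtype=float)
        self.eem_contour = np.asarray(self.eem_contour, dtype=float)
        self.components = [(t, np.asarray(p, dtype=float)) for t, p in self.components]
        if self.slice_thickness <= 0:
            raise ValueError("slice_thickness must be positive")
        if self.timepoint not in ("baseline", "followup"):
            raise ValueError(f"unknown timepoint {self.timepoint!r}")

    def validate(self, tol: float = 1e-9) -> None:
        """Check contour invariants: simple, CCW, properly nested."""
        lum = Polygon(self.lumen_contour)
        eem = Polygon(self.eem_contour)
        for name, ring in (("lumen", lum), ("eem", eem)):
            if not ring.is_valid:
                raise ValueError(f"{name} contour is self-intersecting")
        for name, contour in (("lumen", self.lumen_contour), ("eem", self.eem_contour)):
            if not LinearRing(contour).is_ccw:
                raise ValueError(f"{name} contour is not counter-clockwise")
        if not eem.contains(lum):
            raise ValueError("lumen is not strictly inside the EEM")
        ring = eem.difference(lum)
        for tissue, poly in self.components:
            if tissue not in ("lipid", "calcium"):
                raise ValueError(f"unknown tissue {tissue!r}")
            if not ring.buffer(tol).contains(Polygon(poly)):
                raise ValueError(f"{tissue} component is not inside the wall ring")

    @property
    def lumen_area(self) -> float:
        return polygon_area(self.lumen_contour)

    @property
    def eem_area(self) -> float:
        return polygon_area(self.eem_contour)

    @property
    def wall_area(self) -> float:
        return self.eem_area - self.lumen_area

    @property
    def plaque_burden(self) -> float:
        """Plaque burden in percent: (wall ring area / EEM area) * 100."""
        return 100.0 * self.wall_area / self.eem_area

    @property
    def lumen_centroid(self) -> np.ndarray:
        c = Polygon(self.lumen_contour).centroid
        return np.array([c.x, c.y])


def radius_profile(contour: np.ndarray, center: np.ndarray, thetas: np.ndarray) -> np.ndarray:
    """Distance from *center* to the contour along each ray angle.

    The contour must be star-shaped with respect to *center* (true for all
    generated geometries); for each angle the farthest boundary intersection
    is taken.
    """
    ring = LinearRing(contour)
    span = 4.0 * float(np.max(np.abs(np.asarray(contour) - center))) + 1.0
    out = np.empty(len(thetas))
    cpt = Point(center)
    for k, th in enumerate(thetas):
        far = center + span * np.array([math.cos(th), math.sin(th)])
        hit = ring.intersection(LineString([center, far]))
        if hit.is_empty:
            raise ValueError("ray does not intersect contour (center outside?)")
        pts = [hit] if hit.geom_type == "Point" else list(getattr(hit, "geoms", [hit]))
        out[k] = max(cpt.distance(g) for g in pts)
    return out


def surrogate_stress_amplitude(geometry: VesselGeometry, n_rays: int = 64) -> float:
    """Laplace thin-wall hoop-stress amplitude, kPa.

    ``dP * r_equiv / t_mean`` with ``r_equiv = sqrt(lumen area / pi)`` and
    ``t_mean`` the mean radial wall thickness.  Fast stand-in for the FE
    solution in generation and quick tests.
    """
    center = geometry.lumen_centroid
    thetas = np.linspace(0.0, 2.0 * np.pi, n_rays, endpoint=False)
    t = radius_profile(geometry.eem_contour, center, thetas) - radius_profile(
        geometry.lumen_contour, center, thetas
    )
    t_mean = float(np.mean(t))
    if t_mean <= 0 or np.any(t <= 0):
        raise ValueError("non-positive wall thickness")
    r_eq = math.sqrt(geometry.lumen_area / math.pi)
    dp = geometry.pressure_max - geometry.pressure_min
    return dp * r_eq / t_mean


@dataclass
class CohortConfig:
    """Study conditions for the synthetic cohort.

    Defaults emulate the target study scale: 7 patients, 305 paired slices,
    coronary-sized lumens, ~80/120 mmHg pulse pressure, and a DLA link sized
    so that roughly 145/305 slices narrow.
    """

    n_patients: int = 7
    slices_per_patient: tuple[int, int] = (40, 50)
    n_slices_total: int | None = 305
    lumen_radius: tuple[float, float] = (1.5, 0.3)  # mm (mean, sd)
    wall_thickness: tuple[float, float] = (0.75, 0.15)  # mm (mean, sd)
    eccentricity: float = 0.25  # max; per-slice drawn U(0, eccentricity)
    p_lipid: float = 0.5
    p_calcium: float = 0.25
    pressure_min: tuple[float, float] = (10.67, 0.8)  # kPa per patient (mean, sd)
    pressure_max: tuple[float, float] = (16.0, 0.9)
    gamma0: float = 1.25  # mm^2
    gamma_fatigue: float = 0.15  # mm^2 per kPa of stress amplitude
    gamma_pb: float = -0.05  # mm^2 per % plaque burden
    sigma_patient: float = 0.15  # mm^2
    sigma_noise: float = 0.25  # mm^2
    slice_thickness: float = 0.5  # mm
    n_vertices: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_patient < 0 or self.sigma_noise < 0:
            raise ValueError("standard deviations must be non-negative")
        for p in (self.p_lipid, self.p_calcium):
            if not 0.0 <= p <= 1.0:
                raise ValueError("inclusion probabilities must lie in [0, 1]")
        if not (self.pressure_max[0] > self.pressure_min[0] > 0):
            raise ValueError("need pressure_max > pressure_min > 0")
        if self.lumen_radius[0] <= 0 or self.wall_thickness[0] <= 0:
            raise ValueError("radii and thicknesses must be positive")
        if not 0.0 <= self.eccentricity < 1.0:
            raise ValueError("eccentricity must lie in [0, 1)")


@dataclass
class Cohort:
    """Generated slice pairs plus the generative ground truth."""

    pairs: list[tuple[VesselGeometry, VesselGeometry]]
    truth: pd.DataFrame  # patient_id, slice_id, b_patient, a_surrogate, pb, dla
    config: CohortConfig

    def __len__(self) -> int:
        return len(self.pairs)


def _slice_counts(cfg: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    lo, hi = cfg.slices_per_patient
    counts = rng.integers(lo, hi + 1, size=cfg.n_patients)
    if cfg.n_slices_total is not None:
        # deterministic round-robin adjustment to hit the exact total
        diff = cfg.n_slices_total - int(counts.sum())
        step = 1 if diff > 0 else -1
        i = 0
        while diff != 0:
            counts[i % cfg.n_patients] += step
            diff -= step
            i += 1
        if np.any(counts < 1):
            raise ValueError("n_slices_total too small for n_patients")
    return counts


def _sector_polygon(r_inner, r_outer, th0, th1, n=24) -> np.ndarray:
    """Closed CCW annular-sector polygon between two radius functions of theta."""
    th = np.linspace(th0, th1, n)
    outer = np.column_stack([r_outer(th) * np.cos(th), r_outer(th) * np.sin(th)])
    inner = np.column_stack([r_inner(th) * np.cos(th), r_inner(th) * np.sin(th)])
    return np.vstack([outer, inner[::-1]])


def _clip_components(components, eem, lumen, margin: float = 1e-6):
    """Clip component polygons to the wall ring of a (changed) lumen.

    An enlarged follow-up lumen may cut into a baseline inclusion; the
    follow-up geometry keeps the part of each inclusion still inside its own
    wall ring (minimal plaque-remodeling assumption).
    """
    ring = Polygon(eem).difference(Polygon(lumen).buffer(margin))
    out = []
    for tissue, poly in components:
        clipped = Polygon(poly).intersection(ring)
        if clipped.geom_type == "MultiPolygon":
            clipped = max(clipped.geoms, key=lambda g: g.area)
        if clipped.geom_type == "Polygon" and clipped.area > 1e-4:
            coords = np.asarray(clipped.exterior.coords[:-1])
            if not LinearRing(coords).is_ccw:
                coords = coords[::-1]
            out.append((tissue, coords))
    return out


def _draw_slice_geometry(cfg: CohortConfig, rng: np.random.Generator):
    """Radius functions and component polygons for one cross-section."""
    base = max(0.6, rng.normal(*cfg.lumen_radius))
    t0 = max(0.3, rng.normal(*cfg.wall_thickness))
    ecc = rng.uniform(0.0, cfg.eccentricity)
    phi = rng.uniform(0.0, 2.0 * np.pi)
    amps = rng.uniform(0.0, 0.03, size=2)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=2)
    w_t = rng.uniform(0.0, 0.35)
    phi_t = phi + np.pi + rng.uniform(-0.5, 0.5)

    def r_lum(th):
        r = base * (1.0 + ecc * np.cos(th - phi))
        for k, (a, p) in enumerate(zip(amps, phases), start=2):
            r = r + base * a * np.cos(k * th + p)
        return r

    def thick(th):
        return t0 * (1.0 + w_t * np.cos(th - phi_t))

    def r_eem(th):
        return r_lum(th) + thick(th)

    components: list[tuple[str, np.ndarray]] = []
    if rng.uniform() < cfg.p_lipid:
        span = rng.uniform(np.deg2rad(40.0), np.deg2rad(120.0))
        poly = _sector_polygon(
            lambda th: r_lum(th) + 0.25 * thick(th),
            lambda th: r_lum(th) + 0.75 * thick(th),
            phi_t - span / 2.0,
            phi_t + span / 2.0,
        )
        components.append(("lipid", poly))
    if rng.uniform() < cfg.p_calcium:
        span = rng.uniform(np.deg2rad(20.0), np.deg2rad(60.0))
        c0 = phi_t + rng.uniform(-1.2, 1.2)
        poly = _sector_polygon(
            lambda th: r_lum(th) + 0.78 * thick(th),
            lambda th: r_lum(th) + 0.92 * thick(th),
            c0 - span / 2.0,
            c0 + span / 2.0,
        )
        components.append(("calcium", poly))
    return r_lum, r_eem, components


def generate_cohort(config: CohortConfig) -> Cohort:
    """Draw a reproducible synthetic cohort of baseline/follow-up pairs.

    Each patient gets an independent deterministic sub-stream derived from
    the global seed, so the cohort is bit-for-bit reproducible and stable
    under parallel generation.
    """
    top = np.random.default_rng(np.random.SeedSequence(config.seed))
    counts = _slice_counts(config, top)
    thetas = np.linspace(0.0, 2.0 * np.pi, config.n_vertices, endpoint=False)

    pairs: list[tuple[VesselGeometry, VesselGeometry]] = []
    rows = []
    n_draws = 0
    n_fail = 0
    for j in range(config.n_patients):
        rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(j,)))
        pid = f"P{j + 1:02d}"
        b_j = rng.normal(0.0, config.sigma_patient) if config.sigma_patient > 0 else 0.0
        p_min = max(2.0, rng.normal(*config.pressure_min))
        p_max = max(p_min + 1.0, rng.normal(*config.pressure_max))
        for i in range(int(counts[j])):
            sid = f"S{i + 1:03d}"
            for attempt in range(100):
                n_draws += 1
                r_lum, r_eem, comps = _draw_slice_geometry(config, rng)
                lum = np.column_stack(
                    [r_lum(thetas) * np.cos(thetas), r_lum(thetas) * np.sin(thetas)]
                )
                eem = np.column_stack(
                    [r_eem(thetas) * np.cos(thetas), r_eem(thetas) * np.sin(thetas)]
                )
                base = VesselGeometry(
                    pid, sid, "baseline", lum, eem, comps, p_min, p_max,
                    config.slice_thickness,
                )
                eps = rng.normal(0.0, config.sigma_noise) if config.sigma_noise > 0 else 0.0
                a_surr = surrogate_stress_amplitude(base)
                pb = base.plaque_burden
                dla = (
                    config.gamma0
                    + config.gamma_fatigue * a_surr
                    + config.gamma_pb * pb
                    + b_j
                    + eps
                )
                area_b = base.lumen_area
                area_f = area_b - dla
                if area_f <= 0.2:
                    n_fail += 1
                    continue
                scale = math.sqrt(area_f / area_b)
                c = base.lumen_centroid
                lum_f = c + scale * (lum - c)
                if scale > 1.0 and not Polygon(eem).contains(Polygon(lum_f)):
                    n_fail += 1
                    continue
                follow = VesselGeometry(
                    pid, sid, "followup", lum_f, eem,
                    _clip_components(comps, eem, lum_f), p_min, p_max,
                    config.slice_thickness,
                )
                break
            else:
                raise RuntimeError(
                    f"could not draw a feasible geometry for {pid}/{sid} in 100 attempts"
                )
            pairs.append((base, follow))
            rows.append(
                dict(patient_id=pid, slice_id=sid, b_patient=b_j,
                     a_surrogate=a_surr, pb=pb, dla=dla)
            )
    if n_fail > 0.01 * n_draws and n_fail > 10:
        raise RuntimeError(
            f"geometry distributions infeasible: {n_fail}/{n_draws} draws rejected"
        )
    return Cohort(pairs=pairs, truth=pd.DataFrame(rows), config=config)


# ---------------------------------------------------------------------------
# Contour file I/O: one JSON per slice, coordinates in mm, first vertex not
# repeated.


def geometry_to_dict(g: VesselGeometry) -> dict:
    return {
        "patient_id": g.patient_id,
        "slice_id": g.slice_id,
        "timepoint": g.timepoint,
        "lumen_contour": np.asarray(g.lumen_contour).tolist(),
        "eem_contour": np.asarray(g.eem_contour).tolist(),
        "components": [[t, np.asarray(p).tolist()] for t, p in g.components],
        "pressure_min": g.pressure_min,
        "pressure_max": g.pressure_max,
        "slice_thickness": g.slice_thickness,
    }


def geometry_from_dict(d: dict) -> VesselGeometry:
    return VesselGeometry(
        patient_id=d["patient_id"],
        slice_id=d["slice_id"],
        timepoint=d["timepoint"],
        lumen_contour=np.asarray(d["lumen_contour"], dtype=float),
        eem_contour=np.asarray(d["eem_contour"], dtype=float),
        components=[(t, np.asarray(p, dtype=float)) for t, p in d["components"]],
        pressure_min=float(d["pressure_min"]),
        pressure_max=float(d["pressure_max"]),
        slice_thickness=float(d.get("slice_thickness", 0.5)),
    )


def save_cohort(cohort: Cohort, out_dir: str | pathlib.Path) -> list[pathlib.Path]:
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for base, follow in cohort.pairs:
        for g in (base, follow):
            path = out / f"{g.patient_id}_{g.slice_id}_{g.timepoint}.json"
            path.write_text(json.dumps(geometry_to_dict(g)))
            written.append(path)
    (out / "truth.csv").write_text(cohort.truth.to_csv(index=False))
    (out / "config.json").write_text(json.dumps(asdict(cohort.config)))
    return written


def load_geometry(path: str | pathlib.Path) -> VesselGeometry:
    return geometry_from_dict(json.loads(pathlib.Path(path).read_text()))


def load_cohort(in_dir: str | pathlib.Path) -> list[tuple[VesselGeometry, VesselGeometry]]:
    """Re-pair saved contour files by (patient, slice)."""
    by_key: dict[tuple[str, str], dict[str, VesselGeometry]] = {}
    for path in sorted(pathlib.Path(in_dir).glob("*_*.json")):
        if path.name == "config.json":
            continue
        g = load_geometry(path)
        by_key.setdefault((g.patient_id, g.slice_id), {})[g.timepoint] = g
    pairs = []
    for key in sorted(by_key):
        tp = by_key[key]
        if "baseline" in tp and "followup" in tp:
            pairs.append((tp["baseline"], tp["followup"]))
    return pairs
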