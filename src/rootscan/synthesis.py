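"""Synthetic root scenes with exact ground truth.

Generates *Brassica*-like seedling root systems — a single primary root with
first-order laterals — as continuous geometry, renders them as
scanner-style images (roots brighter than wet germination paper, moisture
gradients, paper texture, condensation specks), and simulates trait
populations with known variance components. Every downstream module is
testable against the exact geometry this module records.

The growth model mirrors the screen the defaults come from: primary length
follows a logistic curve over 3-18 days after sowing (DAS); laterals
initiate along newly grown primary at a fixed linear density (a Poisson
process), emerge a fixed lag after the primary tip passes, and then
elongate at a constant per-root rate given by a quadratic function of
emergence day (basal laterals fastest). Default trait levels are the
published platform means for the reference genotype: 12 cm primary at 18
DAS, 2.61 laterals per cm, 77.3 degree insertion angle, 0.49 / 0.38 mm
primary / lateral diameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .imaging import CM_PER_INCH, BinaryMask, RasterImage

MM_PER_INCH = 25.4


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with the platform's defaults."""

    # population / design
    n_genotypes: int = 2
    plants_per_genotype: int = 4
    runs: int = 5
    scanners_per_run: int = 8
    plants_per_scanner: int = 2

    # imaging geometry
    dpi: float = 300.0
    width_cm: float = 10.0
    height_cm: float = 14.0
    margin_top_cm: float = 0.5

    # time axis (days after sowing; transfer to the platform at 3 DAS)
    das_start: float = 3.0
    das_end: float = 18.0
    transfer_das: float = 3.0

    # primary-root logistic growth (inflection in DAS, scale per day);
    # the asymptote mean is chosen so the reference plant reaches ~12 cm
    # of primary root by 18 DAS
    phi1_mean: float = 13.7
    phi1_genotype_sd: float = 2.0
    phi1_plant_sd: float = 0.8
    phi2: float = 8.82
    phi3: float = 0.211
    genotype_asymptotes: dict[str, float] | None = None

    # primary shape: gentle heading wiggle around vertical
    wiggle_amplitude_deg: float = 5.0
    wiggle_wavelength_cm: float = 6.0

    # laterals
    branching_density: float = 2.61  # per cm of primary
    emergence_lag_days: float = 2.0  # tip passage -> visible lateral
    insertion_angle_mean: float = 77.3
    insertion_angle_sd: float = 4.5
    primary_diameter_mm: float = 0.49
    primary_diameter_sd: float = 0.03
    lateral_diameter_mm: float = 0.38
    lateral_diameter_sd: float = 0.02
    # lateral elongation rate (cm/day) as a quadratic in days after transfer
    rate_intercept: float = 0.26
    rate_intercept_genotype_sd: float = 0.03
    rate_linear: float = 0.02
    rate_quadratic: float = -0.004
    rate_noise_sd: float = 0.03
    min_rate: float = 0.02

    # rendering / noise
    background_level: float = 110.0
    root_brightness: float = 70.0
    gradient_amplitude: float = 20.0
    texture_sd: float = 5.0
    speck_count: int = 20
    speck_radius_px: int = 3
    additive_noise_sd: float = 2.0

    # population variance components (trait units), single-genotype design
    grand_mean: float = 112.0
    sigma_run: float = 29.5
    sigma_scanner: float = 28.4
    sigma_genotype: float = 0.0
    sigma_genotype_run: float = 0.0
    sigma_genotype_scanner: float = 0.0
    sigma_genotype_run_scanner: float = 0.0
    sigma_residual: float = 30.2


@dataclass
class LateralTruth:
    emergence_das: float
    position_cm: float  # arc-length along primary
    side: int  # +1 / -1
    angle_deg: float  # insertion angle off the primary's local tangent
    diameter_mm: float
    rate_cm_per_day: float

    def length_at(self, das: float) -> float:
        return max(0.0, (das - self.emergence_das) * self.rate_cm_per_day)


@dataclass
class PlantTruth:
    """Exact geometry and growth parameters of one simulated plant."""

    plant_id: str
    genotype: str
    phi1: float
    phi2: float
    phi3: float
    primary_diameter_mm: float
    wiggle_phase: float
    wiggle_amplitude_deg: float
    wiggle_wavelength_cm: float
    laterals: list[LateralTruth] = field(default_factory=list)
    _arc: np.ndarray | None = None  # cached primary path samples (s, x, y)
    _step_cm: float = 0.02

    def primary_length(self, das: float) -> float:
        return self.phi1 / (1.0 + np.exp(-self.phi3 * (das - self.phi2)))

    def _path(self) -> np.ndarray:
        """Dense primary path (s, x, y, theta) out to the asymptote; cached."""
        if self._arc is None:
            n = int(np.ceil(self.phi1 / self._step_cm)) + 2
            s = np.arange(n) * self._step_cm
            theta = np.deg2rad(self.wiggle_amplitude_deg) * np.sin(
                2 * np.pi * s / self.wiggle_wavelength_cm + self.wiggle_phase
            )
            # heading measured from straight-down (+y)
            x = np.concatenate([[0.0], np.cumsum(np.sin(theta[:-1]) * self._step_cm)])
            y = np.concatenate([[0.0], np.cumsum(np.cos(theta[:-1]) * self._step_cm)])
            self._arc = np.column_stack([s, x, y, theta])
        return self._arc

    def primary_polyline(self, das: float) -> np.ndarray:
        """(n, 2) x/y cm polyline of the primary up to its length at ``das``."""
        arc = self._path()
        L = self.primary_length(das)
        keep = arc[:, 0] <= L
        return arc[keep][:, 1:3]

    def _point_at(self, s: float) -> tuple[float, float, float]:
        arc = self._path()
        i = min(int(s / self._step_cm), len(arc) - 1)
        return arc[i, 1], arc[i, 2], arc[i, 3]

    def lateral_polyline(self, lat: LateralTruth, das: float) -> np.ndarray | None:
        """Straight lateral of its current length, or None if not yet emerged."""
        length = lat.length_at(das)
        if length <= 0:
            return None
        x0, y0, theta = self._point_at(lat.position_cm)
        phi = theta + lat.side * np.deg2rad(lat.angle_deg)
        n = max(int(np.ceil(length / self._step_cm)), 1) + 1
        s = np.linspace(0, length, n)
        return np.column_stack([x0 + np.sin(phi) * s, y0 + np.cos(phi) * s])

    def emerged_laterals(self, das: float) -> list[LateralTruth]:
        return [l for l in self.laterals if l.length_at(das) > 0]

    def traits_at(self, das: float, min_lateral_cm: float = 0.0) -> dict[str, float]:
        """Analytic per-plant traits at ``das`` (no rasterization involved)."""
        prim = self.primary_length(das)
        lats = [
            l for l in self.emerged_laterals(das) if l.length_at(das) >= min_lateral_cm
        ]
        tot_lat = float(sum(l.length_at(das) for l in lats))
        return {
            "primary_root_length": prim,
            "primary_root_diameter": self.primary_diameter_mm,
            "lateral_branching_density": len(lats) / prim if prim > 0 else 0.0,
            "mean_lateral_length": float(np.mean([l.length_at(das) for l in lats])) if lats else np.nan,
            "mean_lateral_diameter": float(np.mean([l.diameter_mm for l in lats])) if lats else np.nan,
            "mean_insertion_angle": float(np.mean([l.angle_deg for l in lats])) if lats else np.nan,
            "total_lateral_length": tot_lat,
            "total_root_length": prim + tot_lat,
            "n_laterals": float(len(lats)),
        }


def _tip_passage_day(s: float, phi1: float, phi2: float, phi3: float) -> float:
    """Day the primary tip reaches arc-length s (inverse logistic)."""
    s = min(s, phi1 * (1 - 1e-9))
    return phi2 - np.log(phi1 / s - 1.0) / phi3


def simulate_architecture(
    config: SimulationConfig,
    genotype: str = "g0",
    seed: int = 0,
    plant_id: str | None = None,
) -> PlantTruth:
    """Draw one plant's full growth trajectory as exact geometry.

    Reproducible: the RNG is seeded from ``seed`` alone, and draws are made
    in a fixed order (asymptote, wiggle, primary diameter, then per lateral:
    position gaps, side, angle, diameter, rate noise).
    """
    rng = np.random.default_rng(seed)
    if config.genotype_asymptotes and genotype in config.genotype_asymptotes:
        phi1_g = config.genotype_asymptotes[genotype]
    else:
        phi1_g = config.phi1_mean
    phi1 = max(1.0, phi1_g + rng.normal(0.0, config.phi1_plant_sd))
    plant = PlantTruth(
        plant_id=plant_id or f"{genotype}_s{seed}",
        genotype=genotype,
        phi1=phi1,
        phi2=config.phi2,
        phi3=config.phi3,
        primary_diameter_mm=max(
            0.1, config.primary_diameter_mm + rng.normal(0.0, config.primary_diameter_sd)
        ),
        wiggle_phase=rng.uniform(0, 2 * np.pi),
        wiggle_amplitude_deg=config.wiggle_amplitude_deg,
        wiggle_wavelength_cm=config.wiggle_wavelength_cm,
    )
    if config.branching_density <= 0:
        return plant
    # Poisson process along the primary: exponential gaps between insertions
    intercept_g = config.rate_intercept + (
        rng.normal(0.0, config.rate_intercept_genotype_sd) if config.rate_intercept_genotype_sd > 0 else 0.0
    )
    L_final = plant.primary_length(config.das_end)
    s = rng.exponential(1.0 / config.branching_density)
    while s < L_final:
        t_pass = _tip_passage_day(s, plant.phi1, plant.phi2, plant.phi3)
        t_e = max(config.transfer_das, t_pass) + config.emergence_lag_days
        side = 1 if rng.random() < 0.5 else -1
        angle = float(
            np.clip(rng.normal(config.insertion_angle_mean, config.insertion_angle_sd), 20.0, 160.0)
        )
        diam = max(0.08, config.lateral_diameter_mm + rng.normal(0.0, config.lateral_diameter_sd))
        te_rel = t_e - config.transfer_das
        rate = (
            intercept_g
            + config.rate_linear * te_rel
            + config.rate_quadratic * te_rel**2
            + (rng.normal(0.0, config.rate_noise_sd) if config.rate_noise_sd > 0 else 0.0)
        )
        plant.laterals.append(
            LateralTruth(
                emergence_das=float(t_e),
                position_cm=float(s),
                side=side,
                angle_deg=angle,
                diameter_mm=diam,
                rate_cm_per_day=max(config.min_rate, float(rate)),
            )
        )
        s += rng.exponential(1.0 / config.branching_density)
    return plant


def _stamp_polylines(
    shape: tuple[int, int],
    polys_px: list[tuple[np.ndarray, float]],
) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize (polyline, radius_px) strokes.

    Returns (mask, soft) where ``mask`` is the boolean union of strokes
    (pixels within the rounded radius of a centerline) and ``soft`` a [0, 1]
    anti-aliased coverage field. Strokes are grouped by rounded radius and
    painted with one distance transform per group.
    """
    mask = np.zeros(shape, dtype=bool)
    soft = np.zeros(shape, dtype=float)
    groups: dict[int, list[np.ndarray]] = {}
    for pts, radius in polys_px:
        groups.setdefault(int(round(radius)), []).append(pts)
    for r_px, polys in sorted(groups.items()):
        center = np.zeros(shape, dtype=bool)
        for pts in polys:
            ij = np.round(pts).astype(int)
            ij[:, 0] = np.clip(ij[:, 0], 0, shape[0] - 1)
            ij[:, 1] = np.clip(ij[:, 1], 0, shape[1] - 1)
            center[ij[:, 0], ij[:, 1]] = True
        if not center.any():
            continue
        dist = ndimage.distance_transform_edt(~center)
        mask |= dist <= r_px + 1e-6
        soft = np.maximum(soft, np.clip(r_px + 0.75 - dist, 0.0, 1.0))
    return mask, soft


def _resample_px(poly_cm: np.ndarray, config: SimulationConfig) -> np.ndarray:
    """cm geometry -> (row, col) px samples dense enough to leave no gaps."""
    px_per_cm = config.dpi / CM_PER_INCH
    col = poly_cm[:, 0] * px_per_cm + config.width_cm * px_per_cm / 2.0
    row = (poly_cm[:, 1] + config.margin_top_cm) * px_per_cm
    pts = np.column_stack([row, col])
    # geometry is sampled every 0.02 cm ~ 2.4 px at 300 dpi; refine 4x
    out = [pts[:1]]
    for a, b in zip(pts[:-1], pts[1:]):
        n = max(int(np.ceil(np.hypot(*(b - a)) / 0.5)), 1)
        frac = np.arange(1, n + 1)[:, None] / n
        out.append(a + (b - a) * frac)
    return np.vstack(out)


def render_image(
    truth: PlantTruth,
    das: float,
    config: SimulationConfig,
    seed: int = 0,
    color: bool = True,
) -> tuple[RasterImage, BinaryMask]:
    """Render a plant at one day as a scanner image plus its truth mask.

    The truth mask is the rasterized geometry alone; all noise (moisture
    gradient, paper texture, condensation specks, sensor noise) goes into
    the image only. Roots are brightest in the red channel, as on a real
    scan of white roots over damp paper.
    """
    rng = np.random.default_rng(seed)
    px_per_cm = config.dpi / CM_PER_INCH
    shape = (
        int(round(config.height_cm * px_per_cm)),
        int(round(config.width_cm * px_per_cm)),
    )
    px_per_mm = config.dpi / MM_PER_INCH

    polys: list[tuple[np.ndarray, float]] = []
    prim = truth.primary_polyline(das)
    if len(prim) >= 2:
        polys.append((_resample_px(prim, config), (truth.primary_diameter_mm * px_per_mm - 1) / 2.0))
    for lat in truth.laterals:
        lp = truth.lateral_polyline(lat, das)
        if lp is not None and len(lp) >= 2:
            polys.append((_resample_px(lp, config), (lat.diameter_mm * px_per_mm - 1) / 2.0))
    mask, soft = _stamp_polylines(shape, polys)

    img = np.full(shape, config.background_level, dtype=float)
    if config.gradient_amplitude > 0:
        gy = np.linspace(0, 1, shape[0])[:, None]
        gx = np.linspace(0, 1, shape[1])[None, :]
        img += config.gradient_amplitude * (0.7 * gy + 0.3 * np.sin(np.pi * gx))
    if config.texture_sd > 0:
        texture = rng.normal(0.0, config.texture_sd, shape)
        img += ndimage.gaussian_filter(texture, 1.0) * 2.0  # correlated paper grain
    max_rad = max(config.speck_radius_px, 1)
    for _ in range(config.speck_count):
        rad = int(rng.integers(1, max_rad + 1))
        r = int(rng.integers(max_rad, shape[0] - max_rad))
        c = int(rng.integers(max_rad, shape[1] - max_rad))
        rr, cc = np.ogrid[-rad : rad + 1, -rad : rad + 1]
        disk = rr**2 + cc**2 <= rad**2
        img[r - rad : r + rad + 1, c - rad : c + rad + 1][disk] += config.root_brightness * 0.8
    img += config.root_brightness * soft
    if config.additive_noise_sd > 0:
        img += rng.normal(0.0, config.additive_noise_sd, shape)
    red = np.clip(img, 0, 255)

    if not color:
        return RasterImage(red, config.dpi), BinaryMask(mask, config.dpi)
    base = np.clip(img - 0.6 * config.root_brightness * soft, 0, 255)
    rgb = np.stack([red, base * 0.85, base * 0.75], axis=2)
    return RasterImage(np.clip(rgb, 0, 255), config.dpi), BinaryMask(mask, config.dpi)


def simulate_population(
    config: SimulationConfig, seed: int = 0
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Simulate a trait table from the additive random-effects model.

    value = grand mean + run + scanner + genotype + genotype x run +
    genotype x scanner + genotype x run x scanner + residual, every effect
    a zero-mean Gaussian with its configured SD. Returns the table and the
    true effect draws (for oracle tests).

    The layout mirrors the physical platform: the same bank of scanners is
    reused in every run (scanner effects are per device, crossed with run),
    and the plants sharing one scanner in one run are of one genotype (one
    germination sheet per scanner). Genotype-to-scanner assignment is
    re-randomized every run, so genotype x scanner pairs recur across runs
    and the genotype x scanner term stays separable from
    genotype x run x scanner. Draw order: runs,
    scanners, genotypes, genotype x run, genotype x scanner,
    genotype x run x scanner, then residuals plant by plant.
    """
    rng = np.random.default_rng(seed)
    nr, ns = config.runs, config.scanners_per_run
    ng = config.n_genotypes
    runs = [f"run{i}" for i in range(nr)]
    scanners = [f"sc{j}" for j in range(ns)]
    genos = [f"g{k}" for k in range(ng)]

    def draw(sd, shape):
        return rng.normal(0, sd, shape) if sd > 0 else np.zeros(shape)

    a = draw(config.sigma_run, nr)
    b = draw(config.sigma_scanner, ns)
    g = draw(config.sigma_genotype, ng)
    ag = draw(config.sigma_genotype_run, (ng, nr))
    bg = draw(config.sigma_genotype_scanner, (ng, ns))
    abg = draw(config.sigma_genotype_run_scanner, (ng, nr, ns))

    rows = []
    pid = 0
    for i, r in enumerate(runs):
        # one genotype per scanner sheet; fresh randomized assignment per run
        assignment = rng.permutation(np.resize(np.arange(ng), ns))
        for j, sc in enumerate(scanners):
            k = int(assignment[j])
            for _p in range(config.plants_per_scanner):
                eps = rng.normal(0, config.sigma_residual) if config.sigma_residual > 0 else 0.0
                value = (
                    config.grand_mean
                    + a[i]
                    + b[j]
                    + g[k]
                    + ag[k, i]
                    + bg[k, j]
                    + abg[k, i, j]
                    + eps
                )
                rows.append(
                    dict(
                        plant_id=f"p{pid:04d}",
                        genotype=genos[k],
                        run=r,
                        scanner=sc,
                        das=config.das_end,
                        value=value,
                    )
                )
                pid += 1
    truth = {
        "run": a,
        "scanner": b,
        "genotype": g,
        "genotype:run": ag,
        "genotype:scanner": bg,
        "genotype:run:scanner": abg,
    }
    return pd.DataFrame(rows), truth


def truth_trait_table(
    plants: list[PlantTruth],
    das_values: np.ndarray | list[float],
    min_lateral_cm: float = 0.0,
    metadata: dict[str, dict[str, str]] | None = None,
) -> pd.DataFrame:
    """Analytic per-plant, per-day trait table straight from the geometry."""
    rows = []
    for plant in plants:
        meta = (metadata or {}).get(plant.plant_id, {})
        for das in das_values:
            rec = dict(
                plant_id=plant.plant_id,
                genotype=plant.genotype,
                run=meta.get("run", "run0"),
                scanner=meta.get("scanner", "sc0"),
                das=float(das),
            )
            rec.update(plant.traits_at(float(das), min_lateral_cm=min_lateral_cm))
            rows.append(rec)
    return pd.DataFrame(rows)
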