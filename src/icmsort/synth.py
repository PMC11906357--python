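"""Seeded generators emulating the statistical structure of each input class.

Every generator is a pure function of its spec and seed (same spec → byte
identical CSV output) and returns a ground-truth sidecar sufficient to
compute each downstream stage's expected result without re-running the
generator.  The generators emulate: outward-biased PrE vs neutral EPI radial
motion with surface retention; embryo populations across size classes with a
fixed PrE fraction and noisy cap geometry; bimodal log-normal fate-marker
intensities with exponential z-decay; closed contours with localised
protrusions; and Laplace-law micropipette aspiration with pressure noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .geometry import EmbryoGeometry, ScalingConstants, icm_areas, Outcome
from .quantify import AspirationMeasurement, Contour2D
from .tracks import TrackSet


# ---------------------------------------------------------------------------
# Trajectories


@dataclass
class TrackSpec:
    """Radial drift–diffusion trajectories with surface retention.

    Defaults mirror the imaging conditions: 20-min frame interval over 10 h,
    a ~30-cell ICM with 60% PrE, outward PrE drift and neutral EPI motion
    inside a 20-μm aggregate.  Drift/diffusion are per frame.
    """

    n_epi: int = 12
    n_pre: int = 18
    duration: float = 600.0            # min
    frame_interval: float = 20.0       # min
    drift_pre: float = 0.5             # μm/frame, radially outward
    drift_epi: float = 0.0
    diffusion: float = 0.8             # isotropic s.d., μm/frame
    surface_radius: float = 20.0       # μm
    retention: bool = True
    seed: int = 0


def gen_tracks(spec: TrackSpec) -> tuple[TrackSet, dict]:
    """Generate fate-labelled 3D tracks; PrE biased outward, EPI neutral.

    PrE cells reaching the surface radius are retained there (absorbing in
    r, with residual tangential jitter).  Reporter intensity is high for PrE
    and low for EPI.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_epi + spec.n_pre
    fates = np.array(["EPI"] * spec.n_epi + ["PRE"] * spec.n_pre)
    n_frames = int(spec.duration / spec.frame_interval) + 1
    # uniform initial positions inside 0.8×surface radius
    u = rng.random(n)
    r0 = spec.surface_radius * 0.8 * u ** (1 / 3)
    v = rng.normal(size=(n, 3))
    pos = (v / np.linalg.norm(v, axis=1, keepdims=True)) * r0[:, None]
    drift = np.where(fates == "PRE", spec.drift_pre, spec.drift_epi)

    rows = []
    stuck = np.zeros(n, bool)
    for fr in range(n_frames):
        t = fr * spec.frame_interval
        for i in range(n):
            rows.append((i, -1, t, *pos[i], fates[i],
                         1000.0 if fates[i] == "PRE" else 100.0))
        if fr == n_frames - 1:
            break
        r = np.linalg.norm(pos, axis=1)
        radial = np.where(r[:, None] > 0, pos / np.maximum(r, 1e-9)[:, None], 0)
        step = drift[:, None] * radial + rng.normal(
            scale=spec.diffusion, size=(n, 3))
        if spec.retention:
            step[stuck] *= 0.1          # retained cells only jitter
        pos = pos + step
        r = np.linalg.norm(pos, axis=1)
        over = r > spec.surface_radius
        if spec.retention:
            stuck |= over & (fates == "PRE")
        pos[over] *= (spec.surface_radius / r[over])[:, None]
    df = pd.DataFrame(rows, columns=["track_id", "parent_id", "t_min",
                                     "x_um", "y_um", "z_um", "fate",
                                     "reporter"])
    truth = {"spec": asdict(spec), "fates": {int(i): f for i, f in enumerate(fates)}}
    return TrackSet(df, frame_interval=spec.frame_interval), truth


# ---------------------------------------------------------------------------
# Embryo populations


@dataclass
class EmbryoPopulationSpec:
    """Population of cap-geometry embryos across size classes.

    ``base_n`` is the mean ICM cell count of a normal-size (1×) embryo;
    counts scale linearly with the size ratio with Poisson noise, and
    n_pre ~ Binomial(n_total, f).  ``p_monolayer`` is the configured fraction
    of embryos whose interface area is drawn inside the monolayer band
    (the remainder split evenly between gap and multilayer sides);
    ``shape_ratio`` h/R and its noise control cap proportions.
    """

    n_embryos: int = 200
    base_n: float = 40.0
    size_ratios: tuple = (0.25, 0.375, 0.5, 1.0, 2.0, 3.0, 4.0)
    f: float = 0.6
    p_monolayer: float = 0.8
    shape_ratio: float = 0.35          # h / R
    shape_noise: float = 0.05
    geometry_noise: float = 0.03       # multiplicative s.d. on (R, H, h)
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.p_monolayer <= 1:
            raise ValueError("p_monolayer must lie in [0, 1]")


def gen_embryo_population(spec: EmbryoPopulationSpec,
                          constants: ScalingConstants | None = None
                          ) -> tuple[list[EmbryoGeometry], dict]:
    """Generate embryos whose interface areas hit the monolayer band with the
    configured probability; the true outcome of each embryo is recorded."""
    constants = constants or ScalingConstants(f=spec.f)
    rng = np.random.default_rng(spec.seed)
    embryos = []
    outcomes = []
    for i in range(spec.n_embryos):
        ratio = spec.size_ratios[i % len(spec.size_ratios)]
        n_total = max(4, int(rng.poisson(spec.base_n * ratio)))
        n_pre = int(rng.binomial(n_total, spec.f))
        a_min = constants.f * n_total * constants.q10
        a_max = constants.f * n_total * constants.q90
        u = rng.random()
        if u < spec.p_monolayer:
            A_target = rng.uniform(a_min, a_max)
        elif u < spec.p_monolayer + (1 - spec.p_monolayer) / 2:
            A_target = a_max * rng.uniform(1.05, 1.5)      # gap side
        else:
            A_target = a_min * rng.uniform(0.5, 0.95)      # multilayer side
        # shape variability enters through ρ = h/R and H; R and h then follow
        # exactly from the drawn interface area, so the configured in-band
        # fraction is realised (up to the binomial draw above)
        rho = max(0.05, rng.normal(spec.shape_ratio, spec.shape_noise))
        # A = π (R² + h²) with h = ρR  →  R = sqrt(A / (π (1 + ρ²)))
        R = np.sqrt(A_target / (np.pi * (1 + rho * rho)))
        h = rho * R
        H = R * max(1.05 * rho + 0.2,
                    rng.normal(1.0, 0.1) * (1 + rng.normal(0.0, spec.geometry_noise)))
        g = EmbryoGeometry(R=R, H=max(H, h + 1e-6), h=h,
                           n_total=n_total, n_pre=n_pre, size_ratio=ratio)
        embryos.append(g)
        outcomes.append(icm_areas(g, constants).outcome.value)
    truth = {
        "spec": asdict(spec),
        "outcomes": outcomes,
        "p_monolayer_realised": outcomes.count(Outcome.MONOLAYER.value)
        / len(outcomes),
    }
    return embryos, truth


# ---------------------------------------------------------------------------
# Contours


@dataclass
class ContourSpec:
    """Closed circular contour with Gaussian-bump protrusions.

    Bump angles are radians measured from the cavity axis (+x); intensity
    hotspots are co-located with the bumps unless ``intensity_offset`` shifts
    them.
    """

    radius: float = 50.0               # px
    n_points: int = 360
    pixel_size: float = 0.25           # μm/px
    bump_angles: tuple = (0.0,)
    bump_amplitude: float = 6.0        # px
    bump_width: float = 0.25           # rad
    intensity_base: float = 100.0
    intensity_peak: float = 400.0
    intensity_offset: float = 0.0      # rad shift of hotspots vs bumps
    seed: int = 0


def gen_contour(spec: ContourSpec) -> tuple[Contour2D, dict]:
    """Generate the contour with its analytic curvature field as ground truth.

    For the polar curve ρ(θ), curvature is
    κ(θ) = (ρ² + 2ρ′² − ρρ″) / (ρ² + ρ′²)^(3/2).
    """
    import warnings

    angles = np.asarray(spec.bump_angles, float)
    if len(angles) > 1:
        gaps = np.diff(np.sort(angles))
        if np.any(gaps < 4 * spec.bump_width):
            warnings.warn("overlapping protrusion bumps", stacklevel=2)
    theta = np.linspace(0, 2 * np.pi, spec.n_points, endpoint=False)

    def wrap(x):
        return (x + np.pi) % (2 * np.pi) - np.pi

    rho = np.full_like(theta, spec.radius)
    drho = np.zeros_like(theta)
    d2rho = np.zeros_like(theta)
    for a in angles:
        u = wrap(theta - a)
        g = spec.bump_amplitude * np.exp(-0.5 * (u / spec.bump_width) ** 2)
        rho += g
        drho += -u / spec.bump_width**2 * g
        d2rho += (u**2 / spec.bump_width**4 - 1 / spec.bump_width**2) * g
    kappa_px = (rho**2 + 2 * drho**2 - rho * d2rho) / (rho**2 + drho**2) ** 1.5

    pts = np.column_stack([rho * np.cos(theta), rho * np.sin(theta)])
    inten = np.full_like(theta, spec.intensity_base)
    for a in angles:
        u = wrap(theta - (a + spec.intensity_offset))
        inten += (spec.intensity_peak - spec.intensity_base) * np.exp(
            -0.5 * (u / spec.bump_width) ** 2)
    contour = Contour2D(pts, pixel_size=spec.pixel_size, closed=True,
                        intensity=inten, cavity_axis=np.array([1.0, 0.0]))
    truth = {"spec": asdict(spec), "theta": theta.tolist(),
             "curvature_per_um": (kappa_px / spec.pixel_size).tolist()}
    return contour, truth


# ---------------------------------------------------------------------------
# Marker intensities


@dataclass
class IntensitySpec:
    """Bimodal log-normal GATA6/NANOG intensities with exponential z-decay.

    ``separation`` is the distance between the two log-intensity modes in
    units of the mode s.d. (per channel); the default 3 s.d. reflects the
    clear bimodality of these markers in fixed embryos.  GATA6 and NANOG are
    anti-correlated (high GATA6 ⇔ low NANOG ⇔ PrE).
    """

    n_cells: int = 120
    f_pre: float = 0.6
    log_mean_low: float = 4.0
    sigma: float = 0.4
    separation: float = 3.0            # mode distance in s.d. units
    z_max: float = 40.0                # μm
    z_decay: float = 60.0              # μm; np.inf disables the depth effect
    seed: int = 0


def gen_intensity_and_fates(spec: IntensitySpec) -> tuple[pd.DataFrame, dict]:
    """Per-cell GATA6/NANOG intensities with depth decay and true fates."""
    rng = np.random.default_rng(spec.seed)
    n_pre = int(round(spec.f_pre * spec.n_cells))
    fates = np.array(["PRE"] * n_pre + ["EPI"] * (spec.n_cells - n_pre))
    rng.shuffle(fates)
    delta = spec.separation * spec.sigma
    hi = spec.log_mean_low + delta
    mu_g6 = np.where(fates == "PRE", hi, spec.log_mean_low)
    mu_ng = np.where(fates == "PRE", spec.log_mean_low, hi)
    z = rng.uniform(0, spec.z_max, spec.n_cells)
    decay = np.exp(-z / spec.z_decay) if np.isfinite(spec.z_decay) else 1.0
    g6 = np.exp(rng.normal(mu_g6, spec.sigma)) * decay
    ng = np.exp(rng.normal(mu_ng, spec.sigma)) * decay
    df = pd.DataFrame({"cell_id": np.arange(spec.n_cells),
                       "gata6": g6, "nanog": ng, "z": z})
    truth = {"spec": asdict(spec),
             "fates": {int(i): f for i, f in enumerate(fates)}}
    return df, truth


# ---------------------------------------------------------------------------
# Aspiration


@dataclass
class AspirationSpec:
    """Young–Laplace aspiration records with multiplicative pressure noise.

    Pipette radii ~3.5–4 μm (7–8 μm diameter pipettes) against ICM surface
    cells of 8–15 μm curvature radius.
    """

    n: int = 40
    gamma_true: float = 500.0          # pN·μm⁻¹
    r_p_range: tuple = (3.5, 4.0)      # μm
    r_c_range: tuple = (8.0, 15.0)     # μm
    pressure_noise: float = 0.05       # relative s.d.
    seed: int = 0

    def __post_init__(self):
        if self.gamma_true <= 0:
            raise ValueError("true tension must be positive")


def gen_aspiration(spec: AspirationSpec) -> tuple[list[AspirationMeasurement], dict]:
    """Pressures computed from the Young–Laplace law plus noise."""
    rng = np.random.default_rng(spec.seed)
    out = []
    for _ in range(spec.n):
        r_p = rng.uniform(*spec.r_p_range)
        r_c = rng.uniform(*spec.r_c_range)
        p = 2 * spec.gamma_true * (1 / r_p - 1 / r_c)
        p *= 1.0 + rng.normal(0.0, spec.pressure_noise)
        out.append(AspirationMeasurement(P_c=p, R_p=r_p, R_c=r_c))
    truth = {"spec": asdict(spec), "gamma_true": spec.gamma_true}
    return out, truth


# ---------------------------------------------------------------------------
# CSV writers (canonical schemas + JSON sidecars)


def write_with_sidecar(df: pd.DataFrame, truth: dict, path) -> None:
    import json
    from pathlib import Path

    path = Path(path)
    df.to_csv(path, index=False)
    path.with_suffix(".truth.json").write_text(json.dumps(truth, indent=1))
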