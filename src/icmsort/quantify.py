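"""Image-derived scalar operators.

Covers the quantification pipeline applied to micropipette-aspiration
records, fluorescence intensity profiles, manually traced 2D cell contours
and per-cell marker intensities: Young–Laplace interfacial tension, apical
polarization index, binned/normalised intensity profiles, circumcircle-based
membrane curvature, cavity-axis-anchored boundary binning, shape and
protrusion descriptors, z-corrected k-means fate classification and
colocalization coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd


@dataclass
class AspirationMeasurement:
    """One micropipette aspiration record.

    P_c — equilibrium aspiration pressure (Pa); R_p — pipette radius (μm);
    R_c — curvature radius of the free cell surface (μm).  Because
    1 Pa = 1 pN·μm⁻², the derived tension P_c/[2(1/R_p − 1/R_c)] carries the
    unit pN·μm⁻¹ with no numeric conversion.
    """

    P_c: float
    R_p: float
    R_c: float

    def __post_init__(self):
        if self.R_p <= 0:
            raise ValueError("pipette radius must be positive")


def laplace_tension(m: AspirationMeasurement) -> float:
    """Interfacial tension γ = P_c / (2 (1/R_p − 1/R_c)) in pN·μm⁻¹.

    ``R_c = inf`` gives the flat-surface limit γ = P_c R_p / 2.  A reading
    with R_c ≤ R_p has a non-positive denominator and is rejected as an
    invalid steady state.
    """
    if m.P_c <= 0:
        raise ValueError("aspiration pressure must be positive")
    inv = 1.0 / m.R_p - (0.0 if np.isinf(m.R_c) else 1.0 / m.R_c)
    if inv <= 0:
        raise ValueError(
            f"invalid measurement: R_c={m.R_c} must exceed R_p={m.R_p}")
    return float(m.P_c / (2.0 * inv))


@dataclass
class IntensityProfile:
    """Intensity sampled along a normalised spatial coordinate ∈ [0, 1]."""

    positions: np.ndarray
    intensities: np.ndarray
    channel: str = ""
    normalized: bool = False

    def __post_init__(self):
        self.positions = np.asarray(self.positions, float)
        self.intensities = np.asarray(self.intensities, float)
        if self.positions.shape != self.intensities.shape:
            raise ValueError("positions and intensities must align")
        if np.any(np.diff(self.positions) < 0):
            raise ValueError("positions must be sorted")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def n_bins(self) -> int:
        return len(self.positions)


def polarization_index(profile: IntensityProfile) -> float:
    """Outer-quarter over inner-quarter mean intensity.

    The profile runs from the inner edge (position 0, toward the aggregate
    centroid) to the outer edge (position 1, facing the fluid interface):
    PI = mean I(pos ≥ 0.75) / mean I(pos ≤ 0.25).
    """
    outer = profile.intensities[profile.positions >= 0.75]
    inner = profile.intensities[profile.positions <= 0.25]
    if outer.size == 0 or inner.size == 0:
        raise ValueError("profile must cover both the inner and outer quarter")
    denom = float(np.mean(inner))
    if denom == 0:
        raise ValueError("inner-quarter mean intensity is zero; PI undefined")
    return float(np.mean(outer)) / denom


def intensity_profile(positions, intensities, n_bins: int = 20,
                      normalize: bool = True, window: int = 3,
                      channel: str = "") -> IntensityProfile:
    """Bin raw intensity samples into ``n_bins`` equal-width positional bins.

    Positions are first mapped to [0, 1] (normalising segment length), bin
    means are taken, optionally divided by the maximum bin value, and finally
    smoothed with a centred rolling average of ``window`` bins.  Empty bins
    become NaN (flagged, never silently zero).
    """
    from .tracks import rolling_mean

    if n_bins < 2:
        raise ValueError("need at least two bins")
    pos = np.asarray(positions, float)
    inten = np.asarray(intensities, float)
    span = pos.max() - pos.min()
    frac = (pos - pos.min()) / span if span > 0 else np.zeros_like(pos)
    idx = np.minimum((frac * n_bins).astype(int), n_bins - 1)
    sums = np.bincount(idx, weights=inten, minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    if normalize:
        peak = np.nanmax(means)
        if peak > 0:
            means = means / peak
    if window > 1:
        means = rolling_mean(means, window)
    centres = (np.arange(n_bins) + 0.5) / n_bins
    return IntensityProfile(centres, means, channel=channel,
                            normalized=normalize)


@dataclass
class Contour2D:
    """Ordered planar boundary points (pixel units) of a traced cell outline."""

    points: np.ndarray                      # (n, 2) in px
    pixel_size: float = 1.0                 # μm per px
    closed: bool = True
    intensity: np.ndarray | None = None     # optional per-point channel
    cavity_axis: np.ndarray | None = None   # unit vector toward the cavity

    def __post_init__(self):
        self.points = np.asarray(self.points, float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("contour points must be (n, 2)")
        if len(self.points) < 3:
            raise ValueError("contour needs at least three points")
        if np.any(np.all(np.diff(self.points, axis=0) == 0, axis=1)):
            raise ValueError("duplicated consecutive contour points")
        if self.closed and np.allclose(self.points[0], self.points[-1]):
            self.points = self.points[:-1]
            if self.intensity is not None:
                self.intensity = np.asarray(self.intensity, float)[:-1]
        if self.intensity is not None:
            self.intensity = np.asarray(self.intensity, float)
            if len(self.intensity) != len(self.points):
                raise ValueError("per-point intensity must match the contour")

    @property
    def n(self) -> int:
        return len(self.points)

    def signed_area(self) -> float:
        """Shoelace area in px²; positive for counter-clockwise orientation."""
        p = self.points
        q = np.roll(p, -1, axis=0)
        return 0.5 * float(np.sum(p[:, 0] * q[:, 1] - q[:, 0] * p[:, 1]))

    def perimeter(self) -> float:
        """Polygonal perimeter in px (implicit closure when closed)."""
        p = self.points
        seg = np.diff(p, axis=0)
        total = float(np.sum(np.hypot(seg[:, 0], seg[:, 1])))
        if self.closed:
            total += float(np.hypot(*(p[0] - p[-1])))
        return total

    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)


def curvature_profile(contour: Contour2D, offset: int = 10) -> np.ndarray:
    """Per-point membrane curvature (μm⁻¹) from circumscribed circles.

    For point i the circle through points (i − offset, i, i + offset) is
    fitted (cyclic indexing on closed contours; endpoints are skipped and
    returned as NaN on open ones).  Curvature is the inverse circumradius,
    exactly 0 for collinear triples, and signed positive where the contour is
    locally convex outward (protrusion), using the contour orientation to fix
    the interior side.
    """
    p = contour.points
    n = contour.n
    if contour.closed and n <= 2 * offset:
        raise ValueError("closed contour needs more than 2×offset points")
    orient = 1.0 if contour.signed_area() > 0 else -1.0
    scale = float(np.max(np.ptp(p, axis=0))) ** 2
    kappa = np.full(n, np.nan)
    idx = range(n) if contour.closed else range(offset, n - offset)
    for i in idx:
        p1 = p[(i - offset) % n]
        p2 = p[i]
        p3 = p[(i + offset) % n]
        a = p2 - p1
        b = p3 - p2
        cross = a[0] * b[1] - a[1] * b[0]
        if abs(cross) < 1e-9 * max(scale, 1.0):
            kappa[i] = 0.0
            continue
        la = np.hypot(*a)
        lb = np.hypot(*b)
        lc = np.hypot(*(p3 - p1))
        k_px = 2.0 * abs(cross) / (la * lb * lc)
        # convex outward (turn agrees with orientation) → positive
        kappa[i] = np.sign(cross) * orient * k_px
    return kappa / contour.pixel_size


class BoundaryBins(NamedTuple):
    mean_curvature: np.ndarray
    mean_intensity: np.ndarray
    argmax_curvature: int
    argmax_intensity: int
    tie_curvature: bool
    tie_intensity: bool


def boundary_bin_orientation(contour: Contour2D, axis=None, k: int = 6,
                             offset: int = 10) -> BoundaryBins:
    """Equal-arc-length binning of the contour anchored to the cavity axis.

    The closed contour is split into ``k`` contiguous intervals of equal arc
    length, with bin 0 centred on the cavity-facing pole (the contour point
    whose direction from the centroid best aligns with ``axis``).  Returns
    per-bin mean curvature and intensity and the argmax bin for each; exact
    ties resolve to the lowest bin index and are flagged.
    """
    if not contour.closed:
        raise ValueError("boundary binning requires a closed contour")
    if axis is None:
        axis = contour.cavity_axis
    axis = np.asarray(axis, float)
    norm = np.hypot(*axis)
    if norm == 0:
        raise ValueError("cavity axis must be non-zero")
    axis = axis / norm
    p = contour.points
    n = contour.n
    rel = p - contour.centroid()
    pole = int(np.argmax(rel @ axis))

    seg = np.hypot(*(np.roll(p, -1, axis=0) - p).T)   # seg[i]: i → i+1
    total = float(seg.sum())
    # arc-length coordinate of each point, measured from the pole point and
    # shifted by half a bin so the pole sits at the centre of bin 0
    s = np.concatenate(([0.0], np.cumsum(seg)))[:-1]
    s = (s - s[pole] + total / (2 * k)) % total
    bins = np.minimum((s / total * k).astype(int), k - 1)

    kappa = curvature_profile(contour, offset=offset)
    mean_k = np.array([np.nanmean(kappa[bins == b]) for b in range(k)])
    if contour.intensity is not None:
        mean_i = np.array([np.nanmean(contour.intensity[bins == b])
                           for b in range(k)])
    else:
        mean_i = np.full(k, np.nan)

    def argmax_tie(v):
        if np.all(np.isnan(v)):
            return 0, True
        best = np.nanmax(v)
        hits = np.flatnonzero(np.isclose(v, best, rtol=1e-12, atol=1e-12))
        return int(hits[0]), len(hits) > 1

    ak, tk = argmax_tie(mean_k)
    ai, ti = argmax_tie(mean_i)
    return BoundaryBins(mean_k, mean_i, ak, ai, tk, ti)


# ---------------------------------------------------------------------------
# Fate classification


class FateClassification(NamedTuple):
    fates: np.ndarray               # "EPI" / "PRE" per cell
    corrected: pd.DataFrame         # z-corrected log intensities
    slopes: dict                    # fitted log-intensity-vs-z slope per channel


def classify_fates_kmeans(cells: pd.DataFrame, k: int = 2, seed: int = 0,
                          channels=("gata6", "nanog")) -> FateClassification:
    """Unbiased EPI/PrE classification from marker intensities.

    Per channel, intensities are log-transformed, a straight line is fitted
    to log intensity versus imaging depth z (fluorescence decays with depth),
    and the fitted trend is subtracted.  2-class k-means on the z-corrected
    (GATA6, NANOG) log values assigns fates; the cluster with the higher
    corrected GATA6 mean is PrE.  Deterministic for a given ``seed``.
    """
    from sklearn.cluster import KMeans

    if len(cells) < k:
        raise ValueError("fewer cells than clusters")
    missing = [c for c in (*channels, "z") if c not in cells.columns]
    if missing:
        raise ValueError(f"missing cell columns: {missing}")
    if (cells[list(channels)] <= 0).any().any():
        raise ValueError("intensities must be positive for log transform")

    z = cells["z"].to_numpy(float)
    corrected = {}
    slopes = {}
    for ch in channels:
        logi = np.log(cells[ch].to_numpy(float))
        slope, intercept = np.polyfit(z, logi, 1)
        corrected[ch] = logi - slope * z
        slopes[ch] = float(slope)
    X = np.column_stack([corrected[ch] for ch in channels])
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(X)
    labels = km.labels_
    g6 = corrected[channels[0]]
    pre_cluster = max(range(k), key=lambda c: g6[labels == c].mean())
    fates = np.where(labels == pre_cluster, "PRE", "EPI")
    return FateClassification(fates, pd.DataFrame(corrected), slopes)


# ---------------------------------------------------------------------------
# Shape, protrusions, colocalization


class ShapeMetrics(NamedTuple):
    aspect_ratio: float
    circularity: float
    protrusion_length: float | None
    protrusion_angle: float | None


def _polygon_moments(p: np.ndarray):
    """Area and central second moments of a polygon (Green's theorem)."""
    x, y = p[:, 0], p[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    A = 0.5 * cross.sum()
    cx = np.sum((x + xn) * cross) / (6 * A)
    cy = np.sum((y + yn) * cross) / (6 * A)
    Ixx = np.sum((y * y + y * yn + yn * yn) * cross) / 12 - A * cy * cy
    Iyy = np.sum((x * x + x * xn + xn * xn) * cross) / 12 - A * cx * cx
    Ixy = np.sum((x * yn + 2 * x * y + 2 * xn * yn + xn * y) * cross) / 24 \
        - A * cx * cy
    return abs(A), np.array([[Iyy, Ixy], [Ixy, Ixx]]) / abs(A) * np.sign(A)


def shape_and_protrusion_metrics(contour: Contour2D, protrusion_tip=None,
                                 cavity_normal_point=None) -> ShapeMetrics:
    """Shape descriptors and protrusion geometry of a traced cell outline.

    Aspect ratio is the major/minor axis ratio of the second-moments ellipse
    fit; circularity is 4πA/P² with polygonal area and perimeter.  When a
    protrusion tip and a cavity reference point are given, protrusion length
    is the centre→tip distance (μm) and the protrusion angle is the angle at
    the centre between the centre→tip and centre→cavity segments, in degrees
    ∈ [0, 180].
    """
    A, M = _polygon_moments(contour.points)
    if A <= 0:
        raise ValueError("degenerate contour with zero area")
    w = np.linalg.eigvalsh(M)
    if w[0] <= 0:
        raise ValueError("degenerate contour: zero minor axis")
    aspect = float(np.sqrt(w[1] / w[0]))
    circ = float(4 * np.pi * A / contour.perimeter() ** 2)

    length = angle = None
    if protrusion_tip is not None and cavity_normal_point is not None:
        centre = contour.centroid()
        tip = np.asarray(protrusion_tip, float)
        cav = np.asarray(cavity_normal_point, float)
        v1 = tip - centre
        v2 = cav - centre
        if np.allclose(v1, 0) or np.allclose(v2, 0):
            raise ValueError("tip/cavity reference coincides with the centre")
        length = float(np.hypot(*v1) * contour.pixel_size)
        cosang = np.clip(v1 @ v2 / (np.hypot(*v1) * np.hypot(*v2)), -1, 1)
        angle = float(np.degrees(np.arccos(cosang)))
    return ShapeMetrics(aspect, circ, length, angle)


class Colocalization(NamedTuple):
    pearson_r: float
    manders_m1: float
    manders_m2: float


def colocalization(channel_a, channel_b, threshold_a: float = 0.0,
                   threshold_b: float = 0.0) -> Colocalization:
    """Pearson and Manders overlap coefficients between two channels.

    Pearson r is computed over the union of above-threshold voxels;
    M1 = Σ A over B-positive voxels / Σ A (and symmetrically M2), with sums
    over above-threshold signal.
    """
    A = np.asarray(channel_a, float)
    B = np.asarray(channel_b, float)
    if A.shape != B.shape:
        raise ValueError("channels must have identical shapes")
    if threshold_a < 0 or threshold_b < 0:
        raise ValueError("thresholds must be non-negative")
    pa = A > threshold_a
    pb = B > threshold_b
    union = pa | pb
    if not union.any():
        raise ValueError("no above-threshold signal in either channel")
    a = A[union]
    b = B[union]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        r = np.nan     # constant channel: correlation undefined, flagged
    else:
        r = float(np.corrcoef(a, b)[0, 1])
    sum_a = A[pa].sum()
    sum_b = B[pb].sum()
    m1 = float(A[pa & pb].sum() / sum_a) if sum_a > 0 else 0.0
    m2 = float(B[pa & pb].sum() / sum_b) if sum_b > 0 else 0.0
    return Colocalization(r, m1, m2)


def normalized_cortical_intensity(cortical_mean: float,
                                  nuclear_reference_mean: float) -> float:
    """Cortical signal normalised by a nuclear reference (e.g. ppMRLC / DAPI).

    Scale-invariant: multiplying both channels by a common factor leaves the
    ratio unchanged.
    """
    if nuclear_reference_mean <= 0:
        raise ValueError("nuclear reference intensity must be positive")
    return float(cortical_mean / nuclear_reference_mean)
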