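"""Cross-species spherical-cap model of ICM geometry and PrE monolayer scaling.

The inner cell mass is approximated as the solid between two spherical caps
sharing a base circle of radius R: the major cap (height H, the
trophectoderm-facing dome) minus the minor cap (height h, the elevation of
the ICM–fluid interface).  With a fixed PrE fate fraction f and the 10th/90th
percentiles (q10, q90) of single-cell apical area, an ICM of n cells can tile
its fluid interface with a PrE monolayer only when the interface area falls
inside the band (f·n·q10, f·n·q90); smaller interfaces force a multilayer,
larger ones leave a gap.  Because interface area scales like V^(2/3) while
the PrE complement scales linearly with cell number, monolayer feasibility
holds only on a contiguous interval of embryo sizes.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd


class Outcome(str, Enum):
    GAP = "GAP"
    MONOLAYER = "MONOLAYER"
    MULTILAYER = "MULTILAYER"


#: Species scenario presets: stated PrE fraction used in the scenario
#: calculations (fitted slopes are reproducible only from measurement data).
SPECIES_PRESETS = {"mouse": 0.6, "monkey": 0.7, "human": 0.55}


@dataclass
class ScalingConstants:
    """Constants of the monolayer-scaling model."""

    f: float = 0.6           # PrE fate fraction
    q10: float = 157.0       # 10th percentile apical area, μm²
    q90: float = 376.0       # 90th percentile apical area, μm²
    c: float = 1907.0        # mean cell volume, μm³ (through-origin fit)

    def __post_init__(self):
        if not 0 < self.f < 1:
            raise ValueError("f must lie in (0, 1)")
        if not 0 < self.q10 < self.q90:
            raise ValueError("require 0 < q10 < q90")
        if self.c <= 0:
            raise ValueError("mean cell volume must be positive")


@dataclass
class EmbryoGeometry:
    """Per-embryo spherical-cap measurements and fate counts.

    ``interface_sign`` is +1 for the concave (mouse-type) ICM–fluid interface
    and −1 for a convex one (human-type); the same cap formulas apply with h
    measured toward the cavity, only the ICM volume bookkeeping flips the
    sign of the minor-cap term.
    """

    R: float
    H: float
    h: float
    n_total: int
    n_pre: int
    species: str = "mouse"
    size_ratio: float = 1.0
    interface_sign: int = 1

    def __post_init__(self):
        if self.R <= 0:
            raise ValueError("base radius must be positive")
        if not self.H > self.h >= 0:
            raise ValueError("require H > h >= 0")
        if not 0 <= self.n_pre <= self.n_total:
            raise ValueError("require 0 <= n_pre <= n_total")
        if self.interface_sign not in (1, -1):
            raise ValueError("interface_sign must be +1 or -1")


@dataclass
class EmbryoAreas:
    """Derived areas/volumes and the monolayer classification."""

    V_icm: float
    A_interface: float
    A_pre_min: float
    A_pre_max: float
    outcome: Outcome

    def __post_init__(self):
        if not self.A_pre_min < self.A_pre_max:
            raise ValueError("require A_pre_min < A_pre_max")


def cap_geometry(r: float, h: float) -> dict:
    """Volume and surface area of a spherical cap with base radius r, height h.

    volume = (π h / 6)(3 r² + h²);  area = π (r² + h²).
    """
    if r <= 0 or h < 0:
        raise ValueError("require r > 0 and h >= 0")
    return {
        "volume": np.pi * h * (3 * r * r + h * h) / 6.0,
        "area": np.pi * (r * r + h * h),
    }


def classify_outcome(A_interface: float, A_pre_min: float,
                     A_pre_max: float) -> Outcome:
    """GAP if the interface exceeds the maximal PrE area, MULTILAYER if it is
    below the minimal one; boundary equality counts as MONOLAYER (the stated
    inequalities for gap/multilayer are strict)."""
    if A_interface > A_pre_max:
        return Outcome.GAP
    if A_interface < A_pre_min:
        return Outcome.MULTILAYER
    return Outcome.MONOLAYER


def icm_areas(g: EmbryoGeometry, k: ScalingConstants,
              f: float | None = None) -> EmbryoAreas:
    """ICM volume, fluid-interface area and PrE-area bounds for one embryo.

    V_icm = capV(R, H) − sign · capV(R, h);  A_interface = capA(R, h);
    A_pre = (f · n_total · q10, f · n_total · q90).  ``f`` overrides the
    constant's fraction for scenario calculations.
    """
    f = k.f if f is None else f
    major = cap_geometry(g.R, g.H)
    minor = cap_geometry(g.R, g.h)
    V = major["volume"] - g.interface_sign * minor["volume"]
    A_int = minor["area"]
    a_min = f * g.n_total * k.q10
    a_max = f * g.n_total * k.q90
    return EmbryoAreas(V, A_int, a_min, a_max,
                       classify_outcome(A_int, a_min, a_max))


def hemisphere_area_from_count(N: float, c: float) -> float:
    """Hemispherical-interface reference area for a spherical ICM of N cells.

    The ICM is idealised as a sphere of volume V = cN whose fluid interface
    is one hemisphere of its surface: with r = (3V/4π)^(1/3),
    A = 2πr² = 3^(2/3) (π/2)^(1/3) (cN)^(2/3).
    """
    if np.any(np.asarray(N) < 1) or c <= 0:
        raise ValueError("require N >= 1 and c > 0")
    return 3.0 ** (2.0 / 3.0) * (np.pi / 2.0) ** (1.0 / 3.0) * (c * N) ** (2.0 / 3.0)


def fit_through_origin(x, y) -> tuple[float, float]:
    """Least-squares slope of y = b·x and its standard error."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    sxx = float(np.sum(x * x))
    if sxx == 0:
        raise ValueError("all abscissae are zero; slope undefined")
    b = float(np.sum(x * y) / sxx)
    resid = y - b * x
    dof = max(len(x) - 1, 1)
    se = float(np.sqrt(np.sum(resid**2) / dof / sxx))
    return b, se


def fit_scaling(volume_counts, pre_counts) -> dict:
    """Through-origin fits of the two scaling relations.

    ``volume_counts``: pairs (n_total, V_icm) → slope c of V = c·N;
    ``pre_counts``: pairs (n_total, n_pre) → slope f of n_pre = f·n_total.
    Returns {"c", "c_se", "f", "f_se"}.
    """
    vc = np.asarray(volume_counts, float)
    pc = np.asarray(pre_counts, float)
    if len(vc) < 2 or len(pc) < 2:
        raise ValueError("need at least two measurements per fit")
    c, c_se = fit_through_origin(vc[:, 0], vc[:, 1])
    f, f_se = fit_through_origin(pc[:, 0], pc[:, 1])
    return {"c": c, "c_se": c_se, "f": f, "f_se": f_se}


def outcome_probabilities(population, constants: ScalingConstants,
                          scenario_f: float | None = None,
                          by: str = "size_ratio") -> pd.DataFrame:
    """Relative frequency of gap / monolayer / multilayer per size class.

    ``population`` is a sequence of :class:`EmbryoGeometry`.  Outcomes are
    recomputed under ``scenario_f`` (e.g. 0.4 / 0.6 / 0.8); probabilities are
    relative frequencies with binomial standard errors √(p(1−p)/n), and the
    three probabilities sum to 1 within each class.
    """
    population = list(population)
    if not population:
        raise ValueError("empty population")
    rows = []
    for g in population:
        areas = icm_areas(g, constants, f=scenario_f)
        rows.append({by: getattr(g, by), "outcome": areas.outcome.value})
    df = pd.DataFrame(rows)
    out = []
    for cls, grp in df.groupby(by):
        n = len(grp)
        rec = {by: cls, "n": n}
        for oc in Outcome:
            p = float((grp["outcome"] == oc.value).mean())
            rec[f"p_{oc.value.lower()}"] = p
            rec[f"se_{oc.value.lower()}"] = float(np.sqrt(p * (1 - p) / n))
        out.append(rec)
    return pd.DataFrame(out)


def blastocyst_volume(major: float, minor: float) -> float:
    """Sphere volume from the mean of the fitted-ellipse axes (μm³).

    d = (major + minor)/2;  V = (4/3) π (d/2)³.  Symmetric in the two axes.
    """
    if major <= 0 or minor <= 0:
        raise ValueError("axes must be positive")
    d = 0.5 * (major + minor)
    return 4.0 / 3.0 * np.pi * (d / 2.0) ** 3


def read_geometry_csv(path) -> list[EmbryoGeometry]:
    """Load embryo geometry measurements from the canonical CSV schema."""
    df = pd.read_csv(path)
    required = {"embryo_id", "species", "size_ratio", "R_um", "H_um", "h_um",
                "n_total", "n_pre"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        EmbryoGeometry(R=row.R_um, H=row.H_um, h=row.h_um,
                       n_total=int(row.n_total), n_pre=int(row.n_pre),
                       species=row.species, size_ratio=float(row.size_ratio))
        for row in df.itertuples()
    ]
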