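"""Statistics over fate-labelled 3D cell trajectories.

Operators mirror the live-imaging analysis of EPI/PrE segregation in isolated
inner cell masses: radial position series relative to the per-frame geometric
centroid, the pairwise sorting score, displacement maps binned by radial
position and time, first-passage probabilities of directed motion toward the
blastocyst cavity, and reporter-based fate-switch detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

FATES = ("EPI", "PRE", "UNKNOWN")

TRACK_COLUMNS = ["track_id", "parent_id", "t_min", "x_um", "y_um", "z_um",
                 "fate", "reporter"]


@dataclass
class TrackSet:
    """Per-cell fate-labelled 3D position time series.

    ``data`` holds one row per (cell, frame) with columns ``track_id``,
    ``parent_id``, ``t_min``, ``x_um``, ``y_um``, ``z_um``, ``fate`` and
    optionally ``reporter``.
    """

    data: pd.DataFrame
    frame_interval: float | None = None

    def __post_init__(self):
        required = {"track_id", "t_min", "x_um", "y_um", "z_um", "fate"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"missing track columns: {sorted(missing)}")
        bad = set(self.data["fate"].unique()) - set(FATES)
        if bad:
            raise ValueError(f"unknown fate labels: {sorted(bad)}")
        for tid, g in self.data.groupby("track_id"):
            t = g["t_min"].to_numpy()
            if np.any(np.diff(t) <= 0):
                raise ValueError(f"track {tid}: times must strictly increase")
        if self.frame_interval is None:
            t = np.sort(self.data["t_min"].unique())
            if len(t) > 1:
                self.frame_interval = float(np.min(np.diff(t)))

    @property
    def n_cells(self) -> int:
        return self.data["track_id"].nunique()

    def fates(self) -> pd.Series:
        return self.data.groupby("track_id")["fate"].first()

    @classmethod
    def from_csv(cls, path: str | Path) -> "TrackSet":
        df = pd.read_csv(path)
        required = {"track_id", "t_min", "x_um", "y_um", "z_um", "fate"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        return cls(df)

    def to_csv(self, path: str | Path) -> None:
        cols = [c for c in TRACK_COLUMNS if c in self.data.columns]
        self.data[cols].to_csv(path, index=False)


@dataclass
class RadialSeries:
    """Raw radial distance r (μm) and normalised position d ∈ [0, 1] per cell
    and frame, with the per-frame aggregate centroid series."""

    data: pd.DataFrame          # track_id, t_min, fate, r_um, d
    centroids: pd.DataFrame     # t_min, cx, cy, cz

    def __post_init__(self):
        d = self.data["d"].to_numpy()
        if np.any(d < -1e-9) or np.any(d > 1 + 1e-9):
            raise ValueError("normalised positions must lie in [0, 1]")
        if np.any(self.data["r_um"].to_numpy() < 0):
            raise ValueError("radial distances must be non-negative")


def rolling_mean(x: np.ndarray, window: int) -> np.ndarray:
    """Centred rolling average; shorter windows are used near the edges."""
    if window <= 1:
        return np.asarray(x, float)
    s = pd.Series(x, dtype=float)
    return s.rolling(window, center=True, min_periods=1).mean().to_numpy()


def radial_series(tracks: TrackSet, smoothing_window: int = 1) -> RadialSeries:
    """Radial distances to the per-frame geometric centroid of all cells.

    The centroid is the plain mean of all cell positions at that frame; the
    normalised position d divides r by the maximum cell radius at the frame
    (outermost cell ⇒ d = 1, centroid ⇒ d = 0).  An optional centred rolling
    average of ``smoothing_window`` frames smooths each cell's r series
    (d is recomputed from the smoothed r).
    """
    df = tracks.data.copy()
    cent = df.groupby("t_min")[["x_um", "y_um", "z_um"]].mean()
    if df.groupby("t_min").size().min() < 1:
        raise ValueError("every frame needs at least one cell")
    merged = df.join(cent, on="t_min", rsuffix="_c")
    r = np.sqrt((merged["x_um"] - merged["x_um_c"]) ** 2
                + (merged["y_um"] - merged["y_um_c"]) ** 2
                + (merged["z_um"] - merged["z_um_c"]) ** 2)
    out = df[["track_id", "t_min", "fate"]].copy()
    out["r_um"] = r.to_numpy()
    if smoothing_window > 1:
        out["r_um"] = out.groupby("track_id")["r_um"].transform(
            lambda s: rolling_mean(s.to_numpy(), smoothing_window))
    rmax = out.groupby("t_min")["r_um"].transform("max")
    out["d"] = np.where(rmax > 0, out["r_um"] / rmax, 0.0)
    cents = cent.reset_index().rename(
        columns={"x_um": "cx", "y_um": "cy", "z_um": "cz"})
    return RadialSeries(out, cents)


def sorting_score(radii, fates) -> float:
    """Mean sign of pairwise radial differences, sign(r_PrE − r_EPI).

    +1 ⇔ every PrE cell lies strictly outside every EPI cell; ties
    contribute 0.
    """
    radii = np.asarray(radii, float)
    fates = np.asarray(fates)
    r_pre = radii[fates == "PRE"]
    r_epi = radii[fates == "EPI"]
    if r_pre.size == 0 or r_epi.size == 0:
        raise ValueError("sorting score needs at least one EPI and one PrE cell")
    return float(np.mean(np.sign(r_pre[:, None] - r_epi[None, :])))


def sorting_score_series(tracks: TrackSet) -> pd.DataFrame:
    """Sorting score at every frame of a track set."""
    rs = radial_series(tracks)
    rows = []
    for t, g in rs.data.groupby("t_min"):
        rows.append({"t_min": t,
                     "sorting_score": sorting_score(g["r_um"], g["fate"])})
    return pd.DataFrame(rows)


def binned_displacements(radial: RadialSeries, fates=None, r_bins=None,
                         t_bins=None) -> pd.DataFrame:
    """Mean radial displacement per (fate, radial-position bin, time bin).

    Displacement of a step is r(t+1) − r(t) (positive = outward), assigned to
    bins by the step's *starting* radial position and time.  ``fates``
    optionally overrides the fate labels carried by the series (a mapping
    track_id → fate).  Empty bins are reported with count 0 and NaN mean,
    never silently zero.
    """
    df = radial.data.sort_values(["track_id", "t_min"])
    if fates is not None:
        df = df.assign(fate=df["track_id"].map(fates))
    if r_bins is None or t_bins is None:
        raise ValueError("r_bins and t_bins are required")
    rows = []
    for (tid, fate), g in df.groupby(["track_id", "fate"], sort=False):
        r = g["r_um"].to_numpy()
        t = g["t_min"].to_numpy()
        if len(r) < 2:
            continue
        rows.append(pd.DataFrame({
            "fate": fate, "r_start": r[:-1], "t_start": t[:-1],
            "dr": np.diff(r)}))
    if not rows:
        raise ValueError("need at least two frames in some track")
    steps = pd.concat(rows, ignore_index=True)
    r_bins = np.asarray(r_bins, float)
    t_bins = np.asarray(t_bins, float)
    steps["r_bin"] = pd.cut(steps["r_start"], r_bins, include_lowest=True)
    steps["t_bin"] = pd.cut(steps["t_start"], t_bins, include_lowest=True)
    out = []
    for fate in steps["fate"].unique():
        sub = steps[steps["fate"] == fate]
        grp = sub.groupby(["r_bin", "t_bin"], observed=False)["dr"]
        agg = grp.agg(["mean", "count"]).reset_index()
        agg.insert(0, "fate", fate)
        out.append(agg)
    table = pd.concat(out, ignore_index=True)
    table.rename(columns={"mean": "mean_dr_um", "count": "n_steps"},
                 inplace=True)
    table.loc[table["n_steps"] == 0, "mean_dr_um"] = np.nan
    return table


def first_passage_probabilities(series: dict, threshold: float = 3.0,
                                min_separation: float = 3.0,
                                x0_bins=None) -> pd.DataFrame:
    """Probability that a cell first exits a ±threshold corridor toward the
    cavity, as a function of its starting distance-to-lumen X₀.

    ``series`` maps cell-ID → (times_min, distance_to_lumen_um).  For each
    admissible starting sample X₀ (successive X₀ samples of one trajectory
    separated by at least ``min_separation`` minutes), the trajectory is
    scanned forward for the first time the distance leaves [X₀ − threshold,
    X₀ + threshold]; an exit below is counted as toward the lumen.
    Trajectories that never exit are censored (counted, not included in the
    probability).
    """
    events = []
    censored = 0
    for cid, (t, d) in series.items():
        t = np.asarray(t, float)
        d = np.asarray(d, float)
        next_t0 = -np.inf
        for i in range(len(t)):
            if t[i] < next_t0:
                continue
            next_t0 = t[i] + min_separation
            x0 = d[i]
            exited = False
            for j in range(i + 1, len(t)):
                if d[j] <= x0 - threshold:
                    events.append((x0, 1))
                    exited = True
                    break
                if d[j] >= x0 + threshold:
                    events.append((x0, 0))
                    exited = True
                    break
            if not exited:
                censored += 1
    if not events:
        raise ValueError("no corridor exits found in any trajectory")
    ev = pd.DataFrame(events, columns=["x0", "toward"])
    if x0_bins is None:
        x0_bins = np.linspace(ev["x0"].min(), ev["x0"].max() + 1e-9, 6)
    ev["x0_bin"] = pd.cut(ev["x0"], np.asarray(x0_bins, float),
                          include_lowest=True)
    out = ev.groupby("x0_bin", observed=False)["toward"].agg(
        ["mean", "count"]).reset_index()
    out.rename(columns={"mean": "p_toward_lumen", "count": "n_events"},
               inplace=True)
    out.attrs["n_censored"] = censored
    return out


@dataclass
class FateSwitchResult:
    events: pd.DataFrame = field(default_factory=pd.DataFrame)
    n_to_pre: int = 0
    n_to_epi: int = 0


def fate_switch_events(tracks: TrackSet, high_threshold: float,
                       low_threshold: float,
                       min_persist: int = 2) -> FateSwitchResult:
    """Hysteresis detection of reporter-driven fate switches.

    A switch to PrE is a reporter crossing above ``high_threshold`` sustained
    for at least ``min_persist`` frames, starting from below
    ``low_threshold`` (and symmetrically for a switch to EPI).
    """
    if not low_threshold < high_threshold:
        raise ValueError("thresholds inverted: require low < high")
    if "reporter" not in tracks.data.columns:
        raise ValueError("tracks carry no reporter series")
    rows = []
    for tid, g in tracks.data.groupby("track_id"):
        rep = g["reporter"].to_numpy(float)
        t = g["t_min"].to_numpy(float)
        state = ("high" if rep[0] >= high_threshold
                 else "low" if rep[0] <= low_threshold else "mid")
        for i in range(1, len(rep)):
            if state != "high" and rep[i] >= high_threshold:
                run_len = 1
                j = i + 1
                while j < len(rep) and rep[j] >= high_threshold:
                    run_len += 1
                    j += 1
                if run_len >= min_persist and state == "low":
                    rows.append({"track_id": tid, "t_min": t[i],
                                 "direction": "to_PRE"})
                if run_len >= min_persist:
                    state = "high"
            elif state != "low" and rep[i] <= low_threshold:
                run_len = 1
                j = i + 1
                while j < len(rep) and rep[j] <= low_threshold:
                    run_len += 1
                    j += 1
                if run_len >= min_persist and state == "high":
                    rows.append({"track_id": tid, "t_min": t[i],
                                 "direction": "to_EPI"})
                if run_len >= min_persist:
                    state = "low"
    events = pd.DataFrame(rows, columns=["track_id", "t_min", "direction"])
    return FateSwitchResult(
        events,
        n_to_pre=int((events["direction"] == "to_PRE").sum()),
        n_to_epi=int((events["direction"] == "to_EPI").sum()))


def hysteresis_thresholds(reporter: np.ndarray, band: float = 0.1,
                          seed: int = 0) -> tuple[float, float]:
    """Default fate-switch thresholds: midpoint of the two reporter modes
    (2-class 1D k-means) ± ``band`` × mode distance."""
    from sklearn.cluster import KMeans

    x = np.asarray(reporter, float).reshape(-1, 1)
    km = KMeans(n_clusters=2, n_init=10, random_state=seed).fit(x)
    lo, hi = np.sort(km.cluster_centers_.ravel())
    mid = 0.5 * (lo + hi)
    return mid + band * (hi - lo), mid - band * (hi - lo)
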