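"""Derived observables: avalanche detection, power-law fits,
correlations, radial profiles, trajectories and packing statistics.

An *avalanche* is a discontinuous, tissue-scale rearrangement detected
as a super-threshold jump of the mean cell area between consecutive
frames (threshold 0.1 square microns, after a 30 h burn-in); its
magnitude is the percent discontinuity of the total tissue area across
the same frames.  Magnitudes pooled over an ensemble of runs are
fitted to a power law p(x) ~ x^(-tau) by linear least squares on
log-spaced histogram bins, with a companion semi-log (exponential) fit
for model comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .mesh import (
    TissueState,
    cell_area,
    cell_centroid_safe,
    polygon_area,
    polygon_perimeter,
    tissue_boundary_polygon,
)


class FitError(ValueError):
    """Distribution fit impossible (degenerate or insufficient data)."""


@dataclass
class FrameRecord:
    """Per-frame scalars plus the per-cell snapshot table."""

    time: float
    total_area: float
    anterior_area: float
    posterior_area: float
    n_cells: int
    mean_cell_area: float
    posterior_length: float = 0.0
    t1_count: int = 0
    division_count: int = 0
    radial_std: float = np.nan           # across-bin std of the radial profile
    cells: pd.DataFrame | None = None    # id, x, y, area, sides, pressure, c, region


def _radial_std(xs, ys, areas, n_bins: int = 10) -> float:
    w = areas
    if w.sum() <= 0:
        return float("nan")
    cx = float((xs * w).sum() / w.sum())
    cy = float((ys * w).sum() / w.sum())
    r = np.hypot(xs - cx, ys - cy)
    edges = np.linspace(0.0, float(r.max()) * (1 + 1e-12), n_bins + 1)
    idx = np.clip(np.digitize(r, edges) - 1, 0, n_bins - 1)
    means = [w[idx == b].mean() for b in range(n_bins) if (idx == b).any()]
    return float(np.std(means))


def record_frame(
    tissue: TissueState,
    pressure: dict[int, float] | None = None,
    t1_count: int = 0,
    division_count: int = 0,
    posterior_length: float = 0.0,
    with_cells: bool = True,
    with_radial_std: bool = False,
) -> FrameRecord:
    """Snapshot the observables of the current tissue state.

    Furrow cells are attributed to the anterior compartment for area
    accounting."""
    rows = []
    xs, ys, ars = [], [], []
    total = ant = post = 0.0
    for cid in sorted(tissue.cells):
        cell = tissue.cells[cid]
        a = cell_area(tissue, cid)
        g = cell_centroid_safe(tissue, cid)
        total += a
        if cell.region in ("anterior", "MF"):
            ant += a
        else:
            post += a
        xs.append(g[0])
        ys.append(g[1])
        ars.append(a)
        if with_cells:
            rows.append(
                (cid, g[0], g[1], a, len(cell.vertices),
                 1000.0 * pressure.get(cid, np.nan) if pressure else np.nan,
                 cell.c, cell.region)
            )
    n = len(tissue.cells)
    table = (
        pd.DataFrame(rows, columns=["id", "x", "y", "area", "sides", "pressure", "c", "region"])
        if with_cells
        else None
    )
    rstd = (
        _radial_std(np.asarray(xs), np.asarray(ys), np.asarray(ars))
        if (with_radial_std and n > 0)
        else np.nan
    )
    return FrameRecord(
        time=tissue.time,
        total_area=total,
        anterior_area=ant,
        posterior_area=post,
        n_cells=n,
        mean_cell_area=total / n if n else np.nan,
        posterior_length=posterior_length,
        t1_count=t1_count,
        division_count=division_count,
        radial_std=rstd,
        cells=table,
    )


def frames_to_table(frames: list[FrameRecord]) -> pd.DataFrame:
    """Scalar observables of a frame sequence as a tidy table."""
    return pd.DataFrame(
        {
            "time": [f.time for f in frames],
            "total_area": [f.total_area for f in frames],
            "anterior_area": [f.anterior_area for f in frames],
            "posterior_area": [f.posterior_area for f in frames],
            "n_cells": [f.n_cells for f in frames],
            "mean_cell_area": [f.mean_cell_area for f in frames],
            "posterior_length": [f.posterior_length for f in frames],
            "t1_count": [f.t1_count for f in frames],
            "division_count": [f.division_count for f in frames],
            "radial_std": [f.radial_std for f in frames],
        }
    )


# ----------------------------------------------------------------------
# avalanches
# ----------------------------------------------------------------------
@dataclass
class AvalancheEvent:
    time: float                     # onset (pre-jump frame time, hours)
    magnitude: float                # percent jump of the total area
    mean_area_jump: float           # square microns
    compartment: str                # "total" | "anterior" | "posterior"
    pre_mean_area: float            # square microns, frame before the jump
    pre_radial_std: float = np.nan  # radial inhomogeneity before the jump
    magnitude_raw: float = np.nan   # percent jump before growth correction


def detect_avalanches(
    frames,
    threshold: float = 0.1,
    burn_in: float = 30.0,
    length_scale: float = 1.0,
    radial_std: dict[int, float] | None = None,
    growth_corrected: bool = False,
    merge_consecutive: bool = True,
) -> list[AvalancheEvent]:
    """Detect avalanches in a time-ordered frame sequence.

    ``frames`` is a list of :class:`FrameRecord` or the table from
    :func:`frames_to_table`; areas are converted to square microns with
    ``length_scale`` (microns per simulation length unit).  A jump of
    the mean cell area >= ``threshold`` (square microns) between
    consecutive frames after ``burn_in`` hours opens an event; runs of
    consecutive super-threshold jumps merge into a single event.
    ``radial_std`` optionally maps frame index -> pre-event radial
    inhomogeneity.

    With ``growth_corrected=True`` the magnitude is the *excess*
    percent total-area jump over the run's smooth-growth baseline (the
    median per-frame percent growth of the quiescent post-burn-in
    frames, times the event's frame span); events whose excess is not
    positive are dropped.  This isolates the discontinuous part of the
    growth curve, which matters when the configured doubling time is
    short compared to the frame cadence."""
    table = frames if isinstance(frames, pd.DataFrame) else frames_to_table(frames)
    if len(table) < 2:
        return []
    t = table["time"].to_numpy()
    scale2 = length_scale**2
    m = table["mean_cell_area"].to_numpy() * scale2
    A = table["total_area"].to_numpy() * scale2
    ant = table["anterior_area"].to_numpy() * scale2
    post = table["posterior_area"].to_numpy() * scale2
    rstd_col = (
        table["radial_std"].to_numpy() * scale2 if "radial_std" in table else None
    )
    jumps = np.diff(m)
    hot = (jumps >= threshold) & (t[:-1] >= burn_in)
    with np.errstate(divide="ignore", invalid="ignore"):
        growth_pct = 100.0 * np.diff(A) / A[:-1]
    quiet = (~hot) & (t[:-1] >= burn_in)
    baseline = float(np.median(growth_pct[quiet])) if (growth_corrected and quiet.any()) else 0.0
    events = []
    i = 0
    nj = len(jumps)
    while i < nj:
        if not hot[i]:
            i += 1
            continue
        j = i
        while merge_consecutive and j + 1 < nj and hot[j + 1]:
            j += 1
        s, e = i, j + 1                      # frame span of the event
        d_ant, d_post = ant[e] - ant[s], post[e] - post[s]
        if abs(d_ant) < 1e-12 and abs(d_post) < 1e-12:
            comp = "total"
        else:
            comp = "anterior" if d_ant >= d_post else "posterior"
        raw = 100.0 * (A[e] - A[s]) / A[s]
        mag = raw - baseline * (e - s)
        if growth_corrected and mag <= 0:
            i = j + 1
            continue
        events.append(
            AvalancheEvent(
                time=float(t[s]),
                magnitude=float(mag),
                mean_area_jump=float(m[e] - m[s]),
                compartment=comp,
                pre_mean_area=float(m[s]),
                pre_radial_std=(
                    float(radial_std.get(s, np.nan))
                    if radial_std
                    else (float(rstd_col[s]) if rstd_col is not None else np.nan)
                ),
                magnitude_raw=float(raw),
            )
        )
        i = j + 1
    return events


# ----------------------------------------------------------------------
# power-law fit
# ----------------------------------------------------------------------
@dataclass
class PowerLawFit:
    tau: float                      # exponent of p(x) ~ x^-tau
    stderr: float                   # standard error of the exponent
    x_min: float
    x_cut: float
    r2_loglog: float
    r2_semilog: float               # companion exponential fit diagnostic
    n_events: int
    n_bins: int
    x_star: float = np.inf          # finite-size cutoff scale (inf: none found)
    tau_cutoff_aware: float = np.nan  # exponent of the x^-tau exp(-x/x*) fit
    bin_centers: np.ndarray = field(default_factory=lambda: np.array([]))
    density: np.ndarray = field(default_factory=lambda: np.array([]))

    def summary(self) -> str:
        return (
            f"power-law fit: tau = {self.tau:.3f} +/- {self.stderr:.3f} "
            f"on [{self.x_min:.3g}, {self.x_cut:.3g}] "
            f"({self.n_events} events, {self.n_bins} bins); "
            f"R2 log-log = {self.r2_loglog:.3f}, semi-log = {self.r2_semilog:.3f}"
        )


def fit_power_law(
    magnitudes,
    bins_per_decade: int = 10,
    x_min: float | None = None,
    x_cut: float | None = None,
) -> PowerLawFit:
    """Fit p(x) ~ x^-tau on log-spaced histogram bins.

    The probability density is estimated on log-spaced bins
    (``bins_per_decade``).  The fit range excludes both detection
    censoring and the finite-size cutoff: ``x_min`` defaults to the
    histogram mode (detection thresholds censor small events, so the
    density rises up to an apparent mode before the power-law decay
    begins), and ``x_cut`` is chosen to maximize the fit R^2 so the
    exponential finite-size tail is excluded.  The exponent comes from
    a linear least-squares fit of log10(density) against log10(x) on
    that range; a semi-log linear fit is returned alongside for
    exponential-model comparison."""
    x = np.asarray(magnitudes, dtype=float)
    x = x[np.isfinite(x) & (x > 0)]
    if len(x) < 50:
        warnings.warn(f"only {len(x)} magnitudes; power-law fit will be noisy")
    if len(x) < 5 or np.ptp(x) == 0:
        raise FitError("degenerate magnitude sample: need spread-out positive values")
    lo_all = float(x.min())
    hi_all = float(x.max())
    if not lo_all < hi_all:
        raise FitError("empty fit range")
    decades = np.log10(hi_all / lo_all)
    nbins = max(int(np.ceil(decades * bins_per_decade)), 4)
    edges = np.logspace(np.log10(lo_all), np.log10(hi_all), nbins + 1)
    dens, _ = np.histogram(x, bins=edges, density=True)
    centers = np.sqrt(edges[:-1] * edges[1:])
    keep = dens > 0
    centers, dens = centers[keep], dens[keep]
    if len(centers) < 2:
        raise FitError("fewer than 2 usable histogram bins")
    if x_min is None:
        mode = int(np.argmax(dens))
        # only trust the mode as a censoring floor if enough decaying
        # bins remain to its right
        if len(centers) - mode >= 4:
            lo = float(centers[mode])
        else:
            lo = lo_all
    else:
        lo = float(x_min)
    sel0 = centers >= lo
    centers, dens = centers[sel0], dens[sel0]
    if len(centers) < 2:
        raise FitError("fewer than 2 usable histogram bins above x_min")

    def linfit(upper):
        sel = centers <= upper
        if sel.sum() < 2:
            return None
        res = stats.linregress(np.log10(centers[sel]), np.log10(dens[sel]))
        return res, int(sel.sum())

    # locate the finite-size cutoff by fitting p ~ x^-tau exp(-x/x*);
    # the power-law exponent is then read off the pre-cutoff bins only
    x_star, tau_ca = np.inf, np.nan
    if len(centers) >= 4:
        try:
            from scipy.optimize import curve_fit

            def model(logx, logA, tau, xstar):
                xv = 10.0**logx
                return logA - tau * logx - (xv / xstar) / np.log(10.0)

            popt, _ = curve_fit(
                model,
                np.log10(centers),
                np.log10(dens),
                p0=(float(np.log10(dens[0])), 1.5, float(centers[-1])),
                maxfev=20000,
            )
            if popt[2] > 0:
                x_star, tau_ca = float(popt[2]), float(popt[1])
        except Exception:
            pass

    if x_cut is None:
        if np.isfinite(x_star) and x_star < centers[-1] and (centers <= x_star).sum() >= 3:
            x_cut = float(x_star)
            res, nb = linfit(x_cut)
        else:
            # no resolvable cutoff inside the data: widest high-R^2 range
            best = None
            min_bins = min(5, len(centers))
            for upper in centers[min_bins - 1 :]:
                out = linfit(upper)
                if out is None:
                    continue
                res, nb = out
                r2 = res.rvalue**2
                if best is None or r2 > best[0] + 1e-12:
                    best = (r2, upper, res, nb)
            r2, x_cut, res, nb = best
    else:
        out = linfit(x_cut)
        if out is None:
            raise FitError("fewer than 2 bins inside the requested fit range")
        res, nb = out
    sel = centers <= x_cut
    semi = stats.linregress(centers[sel], np.log10(dens[sel]))
    return PowerLawFit(
        tau=-float(res.slope),
        stderr=float(res.stderr),
        x_min=float(lo),
        x_cut=float(x_cut),
        r2_loglog=float(res.rvalue**2),
        r2_semilog=float(semi.rvalue**2),
        n_events=int(len(x)),
        n_bins=nb,
        x_star=x_star,
        tau_cutoff_aware=tau_ca,
        bin_centers=centers,
        density=dens,
    )


# ----------------------------------------------------------------------
# correlations and profiles
# ----------------------------------------------------------------------
def spearman(x, y) -> tuple[float, float]:
    """Tie-aware Spearman rank correlation with two-sided p-value.

    Constant input has undefined correlation and returns (nan, nan)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length paired samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return (np.nan, np.nan)
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def radial_profile(frame: FrameRecord, n_bins: int = 10):
    """Mean cell area binned by centroid distance from the tissue center.

    The center is the area-weighted centroid of all cells.  Returns
    (bin centers, per-bin mean area, across-bin std); empty bins are
    NaN and excluded from the std (the radial-inhomogeneity
    statistic)."""
    cells = frame.cells
    if cells is None or len(cells) == 0:
        raise ValueError("frame carries no per-cell table")
    w = cells["area"].to_numpy()
    cx = float((cells["x"] * w).sum() / w.sum())
    cy = float((cells["y"] * w).sum() / w.sum())
    r = np.hypot(cells["x"].to_numpy() - cx, cells["y"].to_numpy() - cy)
    edges = np.linspace(0.0, float(r.max()) * (1 + 1e-12), n_bins + 1)
    idx = np.clip(np.digitize(r, edges) - 1, 0, n_bins - 1)
    means = np.full(n_bins, np.nan)
    for b in range(n_bins):
        sel = idx == b
        if sel.any():
            means[b] = w[sel].mean()
    centers = 0.5 * (edges[:-1] + edges[1:])
    spread = float(np.nanstd(means))
    return centers, means, spread


def trajectories(frame_a: FrameRecord, frame_b: FrameRecord) -> pd.DataFrame:
    """Per-cell centroid displacements between two frames.

    Cells born or removed between the frames are excluded; the angle is
    the inverse tangent (atan2) of the displacement relative to the
    x-axis."""
    a, b = frame_a.cells, frame_b.cells
    if a is None or b is None:
        raise ValueError("frames carry no per-cell tables")
    merged = a[["id", "x", "y"]].merge(b[["id", "x", "y"]], on="id", suffixes=("_a", "_b"))
    if len(merged) == 0:
        raise ValueError("frames share no cell ids")
    dx = merged["x_b"] - merged["x_a"]
    dy = merged["y_b"] - merged["y_a"]
    return pd.DataFrame(
        {
            "id": merged["id"],
            "dx": dx,
            "dy": dy,
            "length": np.hypot(dx, dy),
            "angle": np.arctan2(dy, dx),
        }
    )


# ----------------------------------------------------------------------
# packing statistics
# ----------------------------------------------------------------------
@dataclass
class PackingStats:
    lewis_slope: float              # d(mean A_n / mean A)/dn
    lewis_intercept: float
    lewis_r2: float
    side_distribution: dict[int, float]  # polygon class -> relative frequency
    degenerate: bool = False        # single polygon class, Lewis fit undefined


def packing_stats(frames) -> PackingStats:
    """Lewis-law fit and polygon-class distribution pooled over frames."""
    if isinstance(frames, FrameRecord):
        frames = [frames]
    sides, areas = [], []
    for f in frames:
        if f.cells is None:
            continue
        sides.append(f.cells["sides"].to_numpy())
        areas.append(f.cells["area"].to_numpy())
    sides = np.concatenate(sides)
    areas = np.concatenate(areas)
    classes = np.unique(sides)
    dist = {int(n): float((sides == n).mean()) for n in classes}
    if len(classes) < 2:
        return PackingStats(np.nan, np.nan, np.nan, dist, degenerate=True)
    rel = np.array([areas[sides == n].mean() for n in classes]) / areas.mean()
    res = stats.linregress(classes.astype(float), rel)
    return PackingStats(
        lewis_slope=float(res.slope),
        lewis_intercept=float(res.intercept),
        lewis_r2=float(res.rvalue**2),
        side_distribution=dist,
    )


def circularity(tissue: TissueState) -> float:
    """Circularity index 4 pi A / P^2 of the tissue outline (1 = circle)."""
    coords = tissue_boundary_polygon(tissue)
    A = polygon_area(coords)
    P = polygon_perimeter(coords)
    return float(4.0 * np.pi * A / P**2)


# ----------------------------------------------------------------------
# basic plots (matplotlib is an optional extra)
# ----------------------------------------------------------------------
def plot_powerlaw(fit: PowerLawFit, path) -> None:
    """Log-log histogram of avalanche magnitudes with the fitted line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    ax.loglog(fit.bin_centers, fit.density, "o", ms=4, label="density")
    sel = fit.bin_centers <= fit.x_cut
    xs = fit.bin_centers[sel]
    if len(xs) >= 2:
        ref = fit.density[sel][0] * (xs / xs[0]) ** (-fit.tau)
        ax.loglog(xs, ref, "-", label=f"tau = {fit.tau:.2f}")
    ax.set_xlabel("avalanche magnitude (% total area)")
    ax.set_ylabel("probability density")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_growth(table, path) -> None:
    """Total area and mean cell area vs time for one run."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 1, sharex=True, figsize=(5, 4.5))
    axes[0].plot(table["time"], table["total_area"])
    axes[0].set_ylabel("total area")
    axes[1].plot(table["time"], table["mean_cell_area"])
    axes[1].set_ylabel("mean cell area")
    axes[1].set_xlabel("time (h)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
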