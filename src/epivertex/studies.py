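"""Reproduction studies: ensemble avalanche statistics, eye-disc
kinematics, and ground-state phase analysis.

These drivers bundle the full pipelines behind the headline results:

* :func:`uniform_avalanche_study` - an ensemble of uniform-growth runs,
  avalanche detection (0.1 square-micron mean-area jump threshold after
  burn-in), power-law fit of the magnitude distribution, and the
  packing / inhomogeneity rank correlations;
* :func:`eyedisc_kinematics_study` - one eye-disc run, unit
  calibration, and the posterior-length kinematics (furrow speed and
  linearity) plus the growth-rate decay at the furrow's halfway point;
* :func:`soft_network_transition` (re-exported from mechanics) - the
  bulk-tension point of the hexagonal-to-soft ground-state transition.

Study sizes default to desk scale: tissues and run lengths are reduced
relative to the full-scale study conditions while preserving the
dimensionless groups that control the phenomenology (see the methods
note); pass the ``full`` presets and 150 runs to reproduce the
full-scale conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .analysis import (
    AvalancheEvent,
    PowerLawFit,
    detect_avalanches,
    fit_power_law,
    spearman,
)
from .mechanics import soft_network_transition
from .scenarios import (
    POSTERIOR_CELL_AREA_UM2,
    CalibrationScales,
    RunResult,
    calibrate,
    measure_mf_speed,
    preset,
    run_eyedisc,
    run_uniform,
)


@dataclass
class AvalancheStudyResult:
    events: list[AvalancheEvent]
    fit: PowerLawFit | None
    rho_packing: float              # Spearman(pre-event mean area, magnitude)
    p_packing: float
    rho_inhomogeneity: float        # Spearman(pre-event radial std, magnitude)
    p_inhomogeneity: float
    n_runs: int
    runs_summary: list[dict] = field(default_factory=list)


def run_length_scale(table, burn_in: float) -> float:
    """Microns per simulation length unit for a uniform run, anchoring
    the post-burn-in mean cell area to 9 square microns."""
    sel = table[table["time"] >= burn_in]
    if len(sel) == 0:
        sel = table
    return float(np.sqrt(POSTERIOR_CELL_AREA_UM2 / sel["mean_cell_area"].mean()))


def uniform_avalanche_study(
    n_runs: int = 30,
    seed: int = 0,
    area_multiple: float = 8.0,
    max_time: float = 10.0,
    burn_in: float = 0.5,
    threshold: float = 0.1,
    fit: bool = True,
) -> AvalancheStudyResult:
    """Ensemble of uniform-growth runs with pooled avalanche statistics.

    Desk-scale defaults: the 3 h doubling clock of the desk preset (the
    constant-rate model is freely rescalable in time) and runs
    terminated at ``area_multiple`` times the initial area.  At this
    reduced size the avalanche-active regime is the early,
    boundary-packed phase of growth rather than the late large-tissue
    phase of the full-scale study, so the burn-in reduces to a short
    settling window that only excludes the fixture's initial
    equilibration.  Magnitudes are growth-corrected percent total-area
    jumps pooled over the ensemble."""
    events: list[AvalancheEvent] = []
    summaries = []
    for k in range(n_runs):
        cfg = preset("uniform-desk", seed=seed + k)
        cfg.termination.area_multiple = area_multiple
        cfg.termination.max_time = max_time
        run = run_uniform(cfg)
        table = run.table()
        scale = run_length_scale(table, burn_in)
        # each super-threshold discontinuity counts as one avalanche
        # (no merging of consecutive hot frames)
        evs = detect_avalanches(
            table,
            threshold=threshold,
            burn_in=burn_in,
            length_scale=scale,
            growth_corrected=True,
            merge_consecutive=False,
        )
        events.extend(evs)
        summaries.append(
            {
                "seed": cfg.seed,
                "n_events": len(evs),
                "final_cells": run.tissue.n_cells,
                "final_time": float(table["time"].iloc[-1]),
                "length_scale_um": scale,
            }
        )
    mags = [e.magnitude for e in events]
    pl = fit_power_law(mags) if (fit and len(mags) >= 5) else None
    pre_area = [e.pre_mean_area for e in events]
    rho_a, p_a = spearman(pre_area, mags) if len(events) >= 3 else (np.nan, np.nan)
    rstd = [(e.pre_radial_std, e.magnitude) for e in events if np.isfinite(e.pre_radial_std)]
    if len(rstd) >= 3:
        rho_s, p_s = spearman([r for r, _ in rstd], [m for _, m in rstd])
    else:
        rho_s, p_s = np.nan, np.nan
    return AvalancheStudyResult(
        events=events,
        fit=pl,
        rho_packing=rho_a,
        p_packing=p_a,
        rho_inhomogeneity=rho_s,
        p_inhomogeneity=p_s,
        n_runs=n_runs,
        runs_summary=summaries,
    )


@dataclass
class EyeDiscStudyResult:
    run: RunResult
    calibration: CalibrationScales
    mf_speed_um_per_h: float
    posterior_length_r2: float
    growth_decrease_at_halfway_pct: float
    final_cells: int
    final_area_um2: float


def growth_decrease_at_halfway(run: RunResult) -> float:
    """Percent decrease of the growth rate when the furrow is halfway.

    Evaluates the exponential growth law exp(-delta_PL * L_p) at the
    frame where the furrow midpoint is closest to the tissue's
    anterior-posterior center."""
    delta = run.config.growth.delta_pl
    # AP center from the final tissue extent; the frame-wise posterior
    # length series provides L_p at the halfway frame
    table = run.table()
    lp = table["posterior_length"].to_numpy()
    # halfway: L_p equals half the current AP extent; approximate the
    # extent by posterior length at termination (furrow at the anterior
    # edge, so the final L_p spans the tissue)
    lp_final = float(lp[lp > 0][-1]) if (lp > 0).any() else 0.0
    if lp_final <= 0:
        return float("nan")
    idx = int(np.argmin(np.abs(lp - 0.5 * lp_final)))
    k_ratio = float(np.exp(-delta * lp[idx]))
    return 100.0 * (1.0 - k_ratio)


def eyedisc_kinematics_study(seed: int = 0, scale: str = "desk") -> EyeDiscStudyResult:
    """One eye-disc run with calibration and kinematic observables."""
    cfg = preset(f"eyedisc-{scale}", seed=seed)
    run = run_eyedisc(cfg)
    table = run.table()
    cal = calibrate(run)
    v_sim, r2 = measure_mf_speed(table, t_min=cfg.signaling.flux_cutoff)
    return EyeDiscStudyResult(
        run=run,
        calibration=cal,
        mf_speed_um_per_h=cal.speed_um_per_h(v_sim),
        posterior_length_r2=r2,
        growth_decrease_at_halfway_pct=growth_decrease_at_halfway(run),
        final_cells=run.tissue.n_cells,
        final_area_um2=cal.area_um2(float(table["total_area"].iloc[-1])),
    )


def mf_speed_physical(run: RunResult, cal: CalibrationScales) -> float:
    v_sim, _ = measure_mf_speed(run.table())
    return cal.speed_um_per_h(v_sim)


def count_avalanches_simple(run: RunResult, burn_in: float, threshold: float = 0.1) -> int:
    """Avalanche count of a single run (per-run length calibration)."""
    table = run.table()
    scale = run_length_scale(table, burn_in)
    return len(
        detect_avalanches(table, threshold=threshold, burn_in=burn_in, length_scale=scale)
    )


__all__ = [
    "AvalancheStudyResult",
    "EyeDiscStudyResult",
    "uniform_avalanche_study",
    "eyedisc_kinematics_study",
    "growth_decrease_at_halfway",
    "soft_network_transition",
    "run_length_scale",
    "count_avalanches_simple",
]
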