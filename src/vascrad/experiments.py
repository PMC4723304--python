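"""In-silico experiment protocols built on the automaton.

The common protocol is the dynamic-equilibrium run: a vessel pattern is
fixed, the domain is seeded with cells, and the automaton is stepped
until the cell count changes by less than 1% for 50 consecutive steps.
Cellularity and the cellular-oxygen histogram are then recorded and
averaged over a further 100 steps, and the averaged histogram is
irradiated to obtain the expected surviving-cell count.  On top of this
sit the density sweeps (regular and uniform-random vessel placements),
the critical-density search for healthy tissue, tumour growth curves, and
the correlation of the mean Ripley's-L organisation statistic with
radiation outcome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .automaton import AutomatonConfig, run_automaton_step
from .parameters import ModelParameters
from .radiation import bin_cell_oxygen, irradiate
from .ripley import mean_L, pearson
from .runio import substream
from .state import TissueState
from .vessels import (VesselPattern, generate_random,
                      realisable_regular_thetas, regular_grid_for_count,
                      regular_pattern_for_theta)

__all__ = [
    "EquilibriumRecord",
    "SimulationFamily",
    "run_to_equilibrium",
    "regular_density_sweep",
    "critical_density_search",
    "tumour_growth_experiment",
    "random_family",
    "organisation_correlation_analysis",
]

log = logging.getLogger(__name__)

#: occupiable-site occupancy at or above which a run is judged to sit at
#: carrying capacity 1 (every non-vessel site occupied, modulo the
#: stochastic death/rebirth flicker of marginal sites)
CAPACITY_THRESHOLD = 0.999

#: equilibrium rule: < 1% change in cell number for 50 consecutive steps,
#: then record and average 100 further steps
EQUILIBRIUM_REL_TOL = 0.01
EQUILIBRIUM_STABLE_STEPS = 50
EQUILIBRIUM_WINDOW = 100


def histogram_moments(hist: np.ndarray, dc: float) -> tuple[float, float, float]:
    """Mean, standard deviation and skewness of a cellular-oxygen
    histogram, using bin midpoints."""
    hist = np.asarray(hist, dtype=np.float64)
    total = hist.sum()
    if total == 0:
        return float("nan"), float("nan"), float("nan")
    mids = (np.arange(len(hist)) + 0.5) * dc
    mean = float((hist * mids).sum() / total)
    var = float((hist * (mids - mean) ** 2).sum() / total)
    std = float(np.sqrt(var))
    if std == 0:
        return mean, 0.0, float("nan")
    skew = float((hist * (mids - mean) ** 3).sum() / total / std**3)
    return mean, std, skew


@dataclass
class EquilibriumRecord:
    """Summary of one dynamic-equilibrium run (time-averaged over the
    100-step recording window)."""

    v: int
    N: int
    theta: float
    seed: int | None
    initial: str
    equilibrated: bool
    steps_to_equilibrium: int
    cellularity: float            # cells / N² (vessels in the denominator)
    occupancy: float              # cells / occupiable (non-vessel) sites
    at_capacity: bool
    cell_count: float
    histogram: np.ndarray = field(repr=False)
    oxygen_mean: float = float("nan")
    oxygen_std: float = float("nan")
    oxygen_skew: float = float("nan")
    mean_L: float = float("nan")
    dose: float = float("nan")
    n_fractions: int = 1
    survivors: float = float("nan")
    surviving_fraction: float = float("nan")

    def summary_row(self) -> dict:
        return {k: getattr(self, k) for k in (
            "v", "N", "theta", "seed", "initial", "equilibrated",
            "steps_to_equilibrium", "cellularity", "occupancy",
            "at_capacity", "cell_count", "oxygen_mean", "oxygen_std",
            "oxygen_skew", "mean_L", "dose", "survivors",
            "surviving_fraction")}


def run_to_equilibrium(pattern: VesselPattern, initial: str,
                       params: ModelParameters, config: AutomatonConfig,
                       rng: np.random.Generator, dose: float = 2.0,
                       n_fractions: int = 1, step_cap: int = 2000,
                       seed: int | None = None,
                       relax_kwargs: dict | None = None,
                       return_state: bool = False):
    """Step the automaton to dynamic equilibrium, then average 100 steps.

    ``initial`` is ``"healthy"``, ``"tumour"`` or ``"central-tumour"``.
    Equilibrium means < 1% change in cell number for 50 consecutive steps
    (an empty domain counts as converged).  The averaged cellular-oxygen
    histogram is irradiated at ``dose`` to obtain expected survivors.  If
    ``step_cap`` is reached first, the record is flagged non-equilibrated
    (callers exclude such records from family summaries).
    """
    state = TissueState.from_pattern(pattern, fill=initial, c0=params.c0)
    prev = state.cell_count()
    stable = 0
    steps = 0
    while stable < EQUILIBRIUM_STABLE_STEPS and steps < step_cap:
        run_automaton_step(state, params, config, rng, relax_kwargs)
        steps += 1
        cur = state.cell_count()
        if cur == 0 or abs(cur - prev) / max(prev, 1) < EQUILIBRIUM_REL_TOL:
            stable += 1
        else:
            stable = 0
        prev = cur
    equilibrated = stable >= EQUILIBRIUM_STABLE_STEPS
    if not equilibrated:
        log.warning("run (v=%d, N=%d, seed=%s) hit the %d-step cap without "
                    "equilibrating", pattern.v, pattern.N, seed, step_cap)

    hist_acc = np.zeros(params.M_bins)
    count_acc = 0.0
    for _ in range(EQUILIBRIUM_WINDOW):
        run_automaton_step(state, params, config, rng, relax_kwargs)
        hist_acc += bin_cell_oxygen(state, params)
        count_acc += state.cell_count()
    hist_mean = hist_acc / EQUILIBRIUM_WINDOW
    count_mean = count_acc / EQUILIBRIUM_WINDOW
    occupiable = pattern.N**2 - pattern.v
    occupancy = count_mean / occupiable if occupiable else 0.0
    o_mean, o_std, o_skew = histogram_moments(hist_mean, params.dc_bin)
    ml = mean_L(pattern) if pattern.v >= 2 else float("nan")
    outcome = irradiate(hist_mean, dose, n_fractions, params)
    record = EquilibriumRecord(
        v=pattern.v, N=pattern.N, theta=pattern.theta, seed=seed,
        initial=initial, equilibrated=equilibrated,
        steps_to_equilibrium=steps,
        cellularity=count_mean / pattern.N**2,
        occupancy=occupancy,
        at_capacity=occupancy >= CAPACITY_THRESHOLD,
        cell_count=count_mean, histogram=hist_mean,
        oxygen_mean=o_mean, oxygen_std=o_std, oxygen_skew=o_skew,
        mean_L=ml, dose=dose, n_fractions=n_fractions,
        survivors=outcome.survivors,
        surviving_fraction=outcome.surviving_fraction)
    if return_state:
        return record, state
    return record


def regular_density_sweep(theta_list, params: ModelParameters,
                          config: AutomatonConfig, N: int = 100,
                          master_seed: int = 0, reps: int = 1,
                          initial: str = "healthy", dose: float = 2.0,
                          max_axis_diff: int = 1) -> list[EquilibriumRecord]:
    """Equilibrium records for near-square regular grids at the realisable
    densities closest to each requested Θ (the realised Θ is reported)."""
    records = []
    for theta in theta_list:
        pattern = regular_pattern_for_theta(N, theta,
                                            max_axis_diff=max_axis_diff)
        for rep in range(reps):
            seed_tag = f"regular-sweep-{pattern.v}"
            rng = substream(master_seed, seed_tag, rep)
            records.append(run_to_equilibrium(
                pattern, initial, params, config, rng, dose=dose,
                seed=rep))
    return records


def critical_density_search(params: ModelParameters, config: AutomatonConfig,
                            N: int = 100, master_seed: int = 0,
                            reps: int = 3, k_min: int = 4, k_max: int = 7,
                            initial: str = "healthy"
                            ) -> dict:
    """Bracket the critical regular vessel density for healthy tissue.

    Scans realisable near-square regular grids in increasing density; for
    each density the capacity verdict is the majority over ``reps``
    replicate automaton seeds.  Returns the bracketing pair: the largest
    density with carrying capacity below 1 and the smallest with capacity
    1, together with the per-density records.
    """
    thetas = realisable_regular_thetas(N, k_min=k_min, k_max=k_max)
    rows = []
    for theta, kx, ky in thetas:
        pattern = regular_grid_for_count(N, kx, ky)
        recs = [run_to_equilibrium(
                    pattern, initial, params, config,
                    substream(master_seed, f"critical-{kx}x{ky}", rep),
                    seed=rep)
                for rep in range(reps)]
        mean_occ = float(np.mean([r.occupancy for r in recs]))
        rows.append({"theta": pattern.theta, "kx": kx, "ky": ky,
                     "v": pattern.v, "mean_occupancy": mean_occ,
                     "at_capacity": mean_occ >= CAPACITY_THRESHOLD,
                     "records": recs})
    below = [r for r in rows if not r["at_capacity"]]
    above = [r for r in rows if r["at_capacity"]]
    return {
        "scan": rows,
        "theta_below": max((r["theta"] for r in below), default=float("nan")),
        "theta_above": min((r["theta"] for r in above), default=float("nan")),
    }


def tumour_growth_experiment(params: ModelParameters, config: AutomatonConfig,
                             theta_list=(0.0072, 0.0041, 0.0033, 0.0025,
                                         0.0013),
                             N: int = 100, master_seed: int = 0,
                             t_end_days: float = 190.0,
                             record_every: int = 1) -> dict:
    """Tumour growth curves in regularly vascularised healthy tissue.

    The domain starts full of healthy cells with a single central tumour
    cell; an extra vessel is placed at the domain centre so growth is not
    extinguished by starting in a necrotic pocket.  Returns, per realised
    density, the tumour-cell count versus time (in days) and the final
    automaton state.
    """
    steps = int(np.ceil(t_end_days * 24.0 / params.tau
                        * config.updates_per_cell_cycle))
    out = {}
    for theta in theta_list:
        pattern = regular_pattern_for_theta(N, theta, max_axis_diff=4,
                                            add_central_vessel=True)
        rng = substream(master_seed, f"growth-{pattern.v}")
        state = TissueState.from_pattern(pattern, fill="central-tumour",
                                         c0=params.c0)
        times, counts = [0.0], [state.cell_count(2)]
        for step in range(1, steps + 1):
            run_automaton_step(state, params, config, rng)
            if step % record_every == 0:
                times.append(state.time_nd * params.tau / 24.0)
                counts.append(state.cell_count(2))
        out[pattern.theta] = {
            "pattern": pattern,
            "time_days": np.asarray(times),
            "tumour_cells": np.asarray(counts),
            "final_state": state,
        }
    return out


@dataclass
class SimulationFamily:
    """Replicate runs sharing a vessel count and domain size."""

    v: int
    N: int
    records: list
    summary: dict

    @property
    def theta(self) -> float:
        return self.v / self.N**2

    def valid_records(self) -> list:
        return [r for r in self.records if r.equilibrated]

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.summary_row() for r in self.records])


def _family_summary(records: list[EquilibriumRecord]) -> dict:
    def stats_for(values):
        values = np.asarray(values, dtype=np.float64)
        med = float(np.median(values))
        q25, q75 = (float(q) for q in np.percentile(values, [25, 75]))
        sd = float(values.std(ddof=1)) if len(values) > 1 else 0.0
        mean = float(values.mean())
        outliers = (np.abs(values - mean) > 2.7 * sd).sum() if sd else 0
        return {"mean": mean, "median": med, "q25": q25, "q75": q75,
                "std": sd, "n_outliers": int(outliers)}

    return {
        "n_valid": len(records),
        "cellularity": stats_for([r.cellularity for r in records]),
        "survivors": stats_for([r.survivors for r in records]),
        "mean_L": stats_for([r.mean_L for r in records]),
    }


def random_family(v: int, params: ModelParameters, config: AutomatonConfig,
                  n_reps: int = 25, N: int = 73, master_seed: int = 0,
                  initial: str = "tumour", dose: float = 2.0,
                  step_cap: int = 2000) -> SimulationFamily:
    """Replicate equilibrium runs with fresh uniform-random vessel
    patterns of ``v`` vessels each.

    Matches the box-plot conventions of the density-sweep figures:
    medians, quartiles and outliers beyond ~2.7 standard deviations.  The
    family is flagged invalid if fewer than 90% of replicates reach
    equilibrium.
    """
    if not 1 <= v <= N * N:
        raise ValueError(f"vessel count {v} outside [1, N^2]")
    records = []
    for rep in range(n_reps):
        pat_rng = substream(master_seed, f"family-{v}-pattern", rep)
        run_rng = substream(master_seed, f"family-{v}-run", rep)
        pattern = generate_random(N, v, pat_rng)
        records.append(run_to_equilibrium(
            pattern, initial, params, config, run_rng, dose=dose,
            step_cap=step_cap, seed=rep))
    valid = [r for r in records if r.equilibrated]
    summary = _family_summary(valid) if valid else {"n_valid": 0}
    summary["valid"] = len(valid) >= 0.9 * n_reps
    if not summary["valid"]:
        log.warning("family v=%d: only %d/%d replicates equilibrated",
                    v, len(valid), n_reps)
    return SimulationFamily(v=v, N=N, records=records, summary=summary)


def organisation_correlation_analysis(families: list[SimulationFamily]
                                      ) -> dict:
    """Pearson correlations of vessel organisation (mean Ripley's L)
    against surviving cells and against cellularity, per family.

    Also reports the density at which mean survivors peaks across
    families, and whether the lowest- and highest-density families show
    a correlation sign change (opposite-signed significant r).
    """
    rows = []
    for fam in sorted(families, key=lambda f: f.theta):
        recs = fam.valid_records()
        if len(recs) < 10:
            log.warning("family v=%d skipped: only %d valid replicates",
                        fam.v, len(recs))
            continue
        ml = [r.mean_L for r in recs]
        surv = [r.survivors for r in recs]
        cel = [r.cellularity for r in recs]
        p_surv = pearson(ml, surv)
        p_cel = pearson(ml, cel)
        if not p_surv.valid:
            log.warning("family v=%d: survivor correlation undefined (%s)",
                        fam.v, p_surv.reason)
        rows.append({
            "v": fam.v, "N": fam.N, "theta": fam.theta,
            "mean_survivors": float(np.mean(surv)),
            "r_survivors": p_surv.r, "p_survivors": p_surv.p,
            "valid_survivors": p_surv.valid,
            "r_cellularity": p_cel.r, "p_cellularity": p_cel.p,
            "valid_cellularity": p_cel.valid,
        })
    table = pd.DataFrame(rows)
    result = {"table": table, "peak_theta": float("nan"),
              "sign_change": False, "low": None, "high": None}
    if len(table):
        peak = table.loc[table["mean_survivors"].idxmax()]
        result["peak_theta"] = float(peak["theta"])
        defined = table[table["valid_survivors"]]
        if len(defined) >= 2:
            low = defined.iloc[0]
            high = defined.iloc[-1]
            result["low"] = low.to_dict()
            result["high"] = high.to_dict()
            result["sign_change"] = bool(
                np.sign(low["r_survivors"]) != np.sign(high["r_survivors"])
                and low["p_survivors"] < 0.05 and high["p_survivors"] < 0.05)
    return result
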