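"""Scripted computational experiments over the green-beard simulator.

Each driver runs a parameter sweep, returns a tidy table (one row per
parameter tuple, every row carrying the full tuple and the trial count
that produced it) and, where a closed form exists, an analytic overlay
column computed by :mod:`greenbeard.core` — the formulas are never
duplicated here.  All randomness derives from a single root seed plus
structural indices, so re-running any experiment with the same
configuration and seed reproduces its tables bit for bit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from greenbeard.core import GMatrix, greenbeard_response, threshold_correlation
from greenbeard.simulate import (
    SimConfig,
    invasion_experiment,
    one_generation_response,
    run_evolution,
    trial_rng,
)

__all__ = [
    "LONGTERM_PRESETS",
    "ThresholdValidation",
    "LongtermResult",
    "response_surface",
    "threshold_validation",
    "longterm",
    "invasion_sweep",
]

#: Long-term presets: (rho0, psi) pairs at beta_s=1, beta_n=-1, n=15, m=50.
LONGTERM_PRESETS: dict[str, dict[str, float]] = {
    "a": {"rho0": 0.0, "psi": 1.0},
    "b": {"rho0": 0.6, "psi": 1.0},
    "c": {"rho0": -0.3, "psi": 1.0},
    "d": {"rho0": 0.6, "psi": 0.01},
    "e": {"rho0": 0.6, "psi": 0.1},
}


def _analytic_prediction(cfg: SimConfig, mean_fitness: float) -> np.ndarray:
    """Closed-form response divided by realized mean fitness."""
    g = GMatrix.from_correlation(cfg.sd0**2, cfg.sd0**2, cfg.rho0)
    # mean aggregation divides the interaction term by N-1, which is the
    # same model as sum aggregation with an effective psi/(N-1)
    psi_eff = cfg.psi if cfg.aggregation == "sum" else cfg.psi / (cfg.n - 1)
    pred = greenbeard_response(g, psi_eff, cfg.beta_n, cfg.beta_s, cfg.n).as_array()
    return pred / mean_fitness


def _response_row(cfg: SimConfig, trials: int, seed_material) -> dict:
    est = one_generation_response(cfg, trials, seed=seed_material)
    pred = _analytic_prediction(cfg, est.mean_fitness)
    return {
        "m": cfg.m,
        "n": cfg.n,
        "beta_n": cfg.beta_n,
        "beta_s": cfg.beta_s,
        "psi": cfg.psi,
        "rho0": cfg.rho0,
        "alpha": cfg.alpha,
        "aggregation": cfg.aggregation,
        "trials": trials,
        "resp_s": est.mean.s,
        "resp_a": est.mean.a,
        "se_s": est.se.s,
        "se_a": est.se.a,
        "pred_s": pred[0],
        "pred_a": pred[1],
        "mean_fitness": est.mean_fitness,
        "clamp_fraction": est.clamp_fraction,
    }


def response_surface(
    config: SimConfig,
    beta_s_values=(1.0,),
    psi_values=(1.0,),
    rho_values=(0.0,),
    trials: int = 200,
    seed=None,
) -> pd.DataFrame:
    """One-generation mean responses on a (beta_s, psi, rho) grid.

    Defaults in :class:`SimConfig` (m=5, n=10 for this experiment's
    classic shape) are whatever ``config`` carries; every grid axis is
    explicit.  Each grid point averages ``trials`` independent
    one-generation trials and carries the analytic overlay.
    """
    if not (len(beta_s_values) and len(psi_values) and len(rho_values)):
        raise ValueError("grid axes must be nonempty")
    seed = config.seed if seed is None else seed
    rows = []
    idx = 0
    for bs in beta_s_values:
        for psi in psi_values:
            for rho in rho_values:
                cfg = replace(config, beta_s=float(bs), psi=float(psi), rho0=float(rho))
                rows.append(_response_row(cfg, trials, (seed, idx)))
                idx += 1
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ThresholdValidation:
    """Per-correlation responses plus the estimated sign-change point."""

    table: pd.DataFrame
    rho_threshold: float  # analytic
    rho_crossing: float  # simulated (NaN when the grid does not bracket it)
    warning: str | None


def threshold_validation(
    config: SimConfig, rho_values, trials: int = 100, seed=None
) -> ThresholdValidation:
    """Empirical recovery of the threshold correlation.

    Sweeps the initial genetic correlation, measures the mean altruism
    response at each value, and locates the response's sign change by
    linear interpolation between the two bracketing grid points (the
    response is linear in the genetic covariance, hence in rho).
    """
    rho_values = [float(r) for r in sorted(rho_values)]
    if len(rho_values) < 2:
        raise ValueError("need at least two correlation values")
    seed = config.seed if seed is None else seed
    rows = [
        _response_row(replace(config, rho0=rho), trials, (seed, i))
        for i, rho in enumerate(rho_values)
    ]
    table = pd.DataFrame(rows)
    psi_eff = config.psi if config.aggregation == "sum" else config.psi / (config.n - 1)
    rho_t = threshold_correlation(
        config.beta_n, config.beta_s, psi_eff, config.n, config.sd0**2, config.sd0**2
    )
    resp = table["resp_a"].to_numpy()
    rho = table["rho0"].to_numpy()
    crossing = float("nan")
    warning = None
    sign_change = np.nonzero(np.sign(resp[:-1]) * np.sign(resp[1:]) < 0)[0]
    if sign_change.size:
        i = int(sign_change[0])
        crossing = rho[i] - resp[i] * (rho[i + 1] - rho[i]) / (resp[i + 1] - resp[i])
        crossing = float(crossing)
    else:
        warning = (
            f"correlation grid [{rho[0]:g}, {rho[-1]:g}] does not bracket a sign "
            f"change of the altruism response (analytic threshold {rho_t:g})"
        )
        warnings.warn(warning, stacklevel=2)
    return ThresholdValidation(table, float(rho_t), crossing, warning)


_STAT_FIELDS = [
    "mean_a_s",
    "mean_a_a",
    "mean_z_s",
    "mean_z_a",
    "var_a_s",
    "var_a_a",
    "cov_a",
    "corr_a",
    "n_haplotypes",
    "mean_fitness",
    "n_fitness_clamped",
]


@dataclass(frozen=True)
class LongtermResult:
    """Cross-replicate trajectory summary and per-replicate outcomes."""

    trajectory: pd.DataFrame  # per generation: mean and sd of every stat
    replicates: pd.DataFrame  # per replicate: fixation generation, final state


def longterm(
    config: SimConfig, generations: int = 500, replicates: int = 20, seed=None
) -> LongtermResult:
    """Replicated long-term evolution trajectories.

    Runs ``replicates`` independent populations for ``generations``
    generations each and aggregates every per-generation statistic into
    a cross-replicate mean and standard deviation.  The per-replicate
    table records when (if ever) each population became monomorphic.
    """
    if replicates < 1:
        raise ValueError(f"replicates must be >= 1, got {replicates}")
    seed = config.seed if seed is None else seed
    cfg = replace(config, generations=generations, stop_when_fixed=False)
    runs = []
    rep_rows = []
    for r in range(replicates):
        stats = run_evolution(cfg, rng=trial_rng(seed, r))
        frame = pd.DataFrame([s.as_dict() for s in stats])
        runs.append(frame)
        fixed = frame.index[frame["n_haplotypes"] == 1]
        rep_rows.append(
            {
                "replicate": r,
                "fixation_generation": int(fixed[0]) if len(fixed) else np.nan,
                "final_n_haplotypes": int(frame["n_haplotypes"].iloc[-1]),
                "final_mean_a_s": float(frame["mean_a_s"].iloc[-1]),
                "final_mean_a_a": float(frame["mean_a_a"].iloc[-1]),
                "final_mean_z_s": float(frame["mean_z_s"].iloc[-1]),
                "final_mean_z_a": float(frame["mean_z_a"].iloc[-1]),
            }
        )
    stacked = np.stack([f[_STAT_FIELDS].to_numpy(dtype=float) for f in runs])
    out = {"generation": np.arange(generations)}
    with warnings.catch_warnings():
        # corr_a is NaN once a variance hits zero; nan-aggregation over
        # all-NaN generations is the documented encoding, not an error
        warnings.simplefilter("ignore", category=RuntimeWarning)
        for j, name in enumerate(_STAT_FIELDS):
            out[f"{name}_mean"] = np.nanmean(stacked[:, :, j], axis=0)
            out[f"{name}_sd"] = np.nanstd(stacked[:, :, j], axis=0, ddof=0)
    return LongtermResult(pd.DataFrame(out), pd.DataFrame(rep_rows))


def invasion_sweep(
    config: SimConfig,
    vary: str,
    values,
    rho0_values=(0.0, 0.45, 0.9),
    repeats: int = 50,
    trials: int = 200,
    burn_in: int = 500,
    post: int = 500,
    seed=None,
) -> pd.DataFrame:
    """Cheater invasion rate versus population structure.

    Varies either the number of groups (``vary="groups"``, fixed group
    size) or the group size (``vary="group_size"``, fixed number of
    groups), at several initial correlations.  Each row reports the mean
    and standard deviation of the invasion rate over ``repeats``
    independent batches of ``trials`` trials.
    """
    if vary not in ("groups", "group_size"):
        raise ValueError(f"vary must be 'groups' or 'group_size', got {vary!r}")
    values = [int(v) for v in values]
    if not values:
        raise ValueError("value list must be nonempty")
    if repeats < 1 or trials < 1:
        raise ValueError("repeats and trials must be >= 1")
    seed = config.seed if seed is None else seed
    rows = []
    for vi, value in enumerate(values):
        cfg = replace(config, m=value) if vary == "groups" else replace(config, n=value)
        for ri, rho0 in enumerate(rho0_values):
            cfg_r = replace(cfg, rho0=float(rho0))
            rates = np.empty(repeats)
            for b in range(repeats):
                result = invasion_experiment(
                    cfg_r,
                    burn_in=burn_in,
                    post=post,
                    trials=trials,
                    seed=(seed, vi, ri, b),
                )
                rates[b] = result.invasion_rate
            rows.append(
                {
                    "vary": vary,
                    "m": cfg_r.m,
                    "n": cfg_r.n,
                    "rho0": rho0,
                    "psi": cfg_r.psi,
                    "repeats": repeats,
                    "trials": trials,
                    "burn_in": burn_in,
                    "post": post,
                    "rate_mean": float(rates.mean()),
                    "rate_sd": float(rates.std(ddof=1)) if repeats > 1 else float("nan"),
                    "rate_se": float(rates.std(ddof=1) / np.sqrt(repeats))
                    if repeats > 1
                    else float("nan"),
                }
            )
    return pd.DataFrame(rows)
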