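"""Per-vegetation-type calibration of the two maximum light-use efficiencies.

The shaded- and sunlit-leaf maximum LUEs are fitted against observed
daily tower GPP by maximizing the Willmott agreement index d with the
shuffled complex evolution (SCE-UA) global optimizer.  Sites are split
75/25 into calibration and validation pools (by site, not by day), the
objective pools all calibration days of a vegetation type, and held-out
sites report validation d and per-site R^2.

Because daily modeled GPP is linear in (eps_msh, eps_msu) at fixed
forcing, the per-day APAR-times-scalars bases are precomputed once and
each objective evaluation is a dot product, which keeps the optimizer
cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import PftParameters, run_series

DEFAULT_BOUNDS = ((0.01, 10.0), (0.01, 10.0))  # (eps_msh, eps_msu), g C MJ-1


def agreement_index(estimates, measurements):
    """Willmott agreement index

        d = 1 - sum (E_n - M_n)^2 / sum (|E_n - Mbar| + |M_n - Mbar|)^2

    with Mbar the mean of the measurements.  d = 1 for perfect
    agreement and 0 for complete disagreement; d is bounded in [0, 1].
    The denominator is zero only when every estimate and measurement
    equals Mbar, which is rejected as degenerate.
    """
    e = np.asarray(estimates, dtype=float)
    m = np.asarray(measurements, dtype=float)
    if e.shape != m.shape or e.size < 2:
        raise ValueError("estimates and measurements must have equal length >= 2")
    if not (np.all(np.isfinite(e)) and np.all(np.isfinite(m))):
        raise ValueError("agreement index requires finite values")
    m_bar = m.mean()
    denom = np.sum((np.abs(e - m_bar) + np.abs(m - m_bar)) ** 2)
    if denom == 0.0:
        raise ValueError("degenerate input: all values equal the measurement mean")
    # analytically in [0, 1] (triangle inequality); clip roundoff spill
    return float(np.clip(1.0 - np.sum((e - m) ** 2) / denom, 0.0, 1.0))


@dataclass
class SceUaConfig:
    """SCE-UA sizing for a low-dimensional problem.

    Defaults follow the standard published sizing for n parameters:
    ``n_complexes`` complexes of 2n+1 points, simplexes of n+1 points,
    2n+1 evolution steps per complex per shuffling loop.
    """

    n_complexes: int = 4
    points_per_complex: int = None
    simplex_size: int = None
    evolutions_per_complex: int = None
    max_evaluations: int = 10000
    convergence_loops: int = 5  # loops over which relative improvement is judged
    convergence_tol: float = 1e-6
    alpha: float = 1.0  # reflection coefficient
    beta: float = 0.5  # contraction coefficient


def _resolved(config: SceUaConfig, ndim: int):
    npg = config.points_per_complex or 2 * ndim + 1
    nps = config.simplex_size or ndim + 1
    nspl = config.evolutions_per_complex or 2 * ndim + 1
    return npg, nps, nspl


def sce_ua_maximize(objective, bounds, seed, config: SceUaConfig = None):
    """Shuffled complex evolution (SCE-UA) maximization over a box.

    The population is partitioned into complexes; each complex evolves by
    competitive complex evolution (simplex reflection / contraction /
    random replacement on triangular-weighted sub-simplexes), then the
    complexes are shuffled.  Deterministic for a fixed seed.

    Returns ``(x_best, f_best, trace)`` where trace is the best objective
    after each shuffling loop.
    """
    config = config or SceUaConfig()
    bounds = np.asarray(bounds, dtype=float)
    ndim = len(bounds)
    low, high = bounds[:, 0], bounds[:, 1]
    if not np.all(low < high):
        raise ValueError("each bound must satisfy low < high")
    rng = np.random.default_rng(seed)
    npg, nps, nspl = _resolved(config, ndim)
    npop = config.n_complexes * npg

    x = low + rng.random((npop, ndim)) * (high - low)
    f = np.array([objective(xi) for xi in x], dtype=float)
    if np.sum(~np.isfinite(f)) > 0.5 * npop:
        raise RuntimeError("objective non-finite on most of the initial population")
    f = np.where(np.isfinite(f), f, -np.inf)
    n_eval = npop
    trace = []

    # triangular selection weights within a complex (best most likely)
    probs = (2.0 * (npg - np.arange(npg))) / (npg * (npg + 1))

    while True:
        order = np.argsort(-f)
        x, f = x[order], f[order]
        trace.append(f[0])
        if len(trace) > config.convergence_loops:
            past = trace[-config.convergence_loops - 1]
            rel = abs(trace[-1] - past) / max(abs(past), 1e-12)
            if rel < config.convergence_tol:
                break
        if n_eval >= config.max_evaluations:
            break

        for ic in range(config.n_complexes):
            idx = np.arange(ic, npop, config.n_complexes)  # systematic assignment
            cx, cf = x[idx].copy(), f[idx].copy()
            for _ in range(nspl):
                sub = np.sort(rng.choice(npg, size=nps, replace=False, p=probs))
                sx, sf = cx[sub], cf[sub]
                worst = np.argmin(sf)
                centroid = np.mean(np.delete(sx, worst, axis=0), axis=0)
                new = centroid + config.alpha * (centroid - sx[worst])
                if np.any(new < low) or np.any(new > high):
                    new = low + rng.random(ndim) * (high - low)
                fn = objective(new)
                n_eval += 1
                if not np.isfinite(fn) or fn < sf[worst]:
                    new = centroid + config.beta * (sx[worst] - centroid)
                    fn = objective(new)
                    n_eval += 1
                    if not np.isfinite(fn) or fn < sf[worst]:
                        new = low + rng.random(ndim) * (high - low)
                        fn = objective(new)
                        n_eval += 1
                        fn = fn if np.isfinite(fn) else -np.inf
                sx[worst], sf[worst] = new, fn
                cx[sub], cf[sub] = sx, sf
                order_c = np.argsort(-cf)
                cx, cf = cx[order_c], cf[order_c]
            x[idx], f[idx] = cx, cf

    best = int(np.argmax(f))
    return x[best].copy(), float(f[best]), np.asarray(trace)


@dataclass
class CalibrationTask:
    pft_code: str
    records: pd.DataFrame  # screened daily records with gpp_obs, site column
    base_params: PftParameters  # fixed non-LUE parameters for the type
    bounds: tuple = DEFAULT_BOUNDS
    split_fraction: float = 0.75
    seed: int = 0
    sce_config: SceUaConfig = field(default_factory=SceUaConfig)


@dataclass
class CalibrationResult:
    pft_code: str
    eps_msh_hat: float
    eps_msu_hat: float
    d_calibration: float
    d_validation: float
    r2_validation: dict  # per-site daily R^2
    n_site_years: int
    calibration_sites: list
    validation_sites: list
    trace: np.ndarray


def split_sites(sites, split_fraction, seed):
    """Seeded random split of site identifiers into (calibration, validation).

    With fewer than 2 sites the split degenerates to using every site for
    both roles (leave-none-out).
    """
    sites = sorted(set(sites))
    if len(sites) < 2:
        return list(sites), list(sites)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(sites))
    n_cal = max(1, min(len(sites) - 1, int(round(split_fraction * len(sites)))))
    cal = [sites[i] for i in sorted(perm[:n_cal])]
    val = [sites[i] for i in sorted(perm[n_cal:])]
    return cal, val


def _linear_bases(records: pd.DataFrame, params: PftParameters):
    """Per-day (shade, sun) GPP bases at unit LUE, so that
    gpp = eps_msh * base_sh + eps_msu * base_su."""
    unit = PftParameters(**{**params.__dict__, "eps_msh": 1.0, "eps_msu": 1.0})
    sim = run_series(records.sort_values("date").reset_index(drop=True), unit)
    return sim["gpp_shade"].to_numpy(), sim["gpp_sun"].to_numpy()


def calibrate_pft(task: CalibrationTask) -> CalibrationResult:
    """Fit (eps_msh, eps_msu) for one vegetation type.

    Sites are split by seed; the objective is the agreement index over
    all pooled calibration days; validation metrics come from held-out
    sites run with the fitted parameters.
    """
    rec = task.records.dropna(subset=["gpp_obs"]).copy()
    if len(rec) == 0:
        raise ValueError("no usable records for calibration")
    cal_sites, val_sites = split_sites(rec["site"], task.split_fraction, task.seed)

    def bases_and_obs(site_list):
        sub = rec[rec["site"].isin(site_list)]
        parts = []
        for _, grp in sub.groupby("site"):
            grp = grp.sort_values("date").reset_index(drop=True)
            b_sh, b_su = _linear_bases(grp, task.base_params)
            parts.append((b_sh, b_su, grp["gpp_obs"].to_numpy()))
        b_sh = np.concatenate([p[0] for p in parts])
        b_su = np.concatenate([p[1] for p in parts])
        obs = np.concatenate([p[2] for p in parts])
        return b_sh, b_su, obs

    b_sh, b_su, obs = bases_and_obs(cal_sites)

    def objective(theta):
        est = theta[0] * b_sh + theta[1] * b_su
        try:
            return agreement_index(est, obs)
        except ValueError:
            return -np.inf

    x_best, d_cal, trace = sce_ua_maximize(
        objective, task.bounds, task.seed, task.sce_config)

    v_sh, v_su, v_obs = bases_and_obs(val_sites)
    v_est = x_best[0] * v_sh + x_best[1] * v_su
    d_val = agreement_index(v_est, v_obs)

    r2 = {}
    for site, grp in rec[rec["site"].isin(val_sites)].groupby("site"):
        grp = grp.sort_values("date").reset_index(drop=True)
        s_sh, s_su = _linear_bases(grp, task.base_params)
        est = x_best[0] * s_sh + x_best[1] * s_su
        o = grp["gpp_obs"].to_numpy()
        if np.std(o) > 0 and np.std(est) > 0:
            r2[site] = float(np.corrcoef(est, o)[0, 1] ** 2)
        else:
            r2[site] = np.nan

    years = pd.to_datetime(rec["date"]).dt.year
    n_site_years = rec.assign(_y=years).groupby(["site", "_y"]).ngroups
    return CalibrationResult(
        pft_code=task.pft_code,
        eps_msh_hat=float(x_best[0]), eps_msu_hat=float(x_best[1]),
        d_calibration=float(d_cal), d_validation=float(d_val),
        r2_validation=r2, n_site_years=int(n_site_years),
        calibration_sites=cal_sites, validation_sites=val_sites,
        trace=trace,
    )
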