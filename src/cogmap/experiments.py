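"""Parameter sweeps, power-law fits, critical probabilities and the learning
region.

Lowering the synaptic modes delays map formation: the learning time diverges
as ``T_min ~ (p_hat - p_crit)^-kappa`` (and analogously in ``q_hat`` with a
smaller exponent), and below the critical mode the ensemble never recovers
the environment's Betti numbers.  This module orchestrates sweeps over
``(p_hat, q_hat, s, f, N)`` with common random numbers within each repeat,
fits the divergence exponents and critical points, and maps the region of
ensemble parameters for which learning succeeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .pipeline import EffectiveRun, SessionConfig, run_effective, simulate_session
from .synapses import SynapticModel

__all__ = [
    "SweepConfig",
    "SweepResult",
    "FitResult",
    "run_sweep",
    "fit_power_law",
    "estimate_critical",
    "critical_surface",
    "learning_region",
    "compensation_check",
]


@dataclass(frozen=True)
class SweepConfig:
    """Grid of synaptic modes (and optionally ensemble parameters), number of
    repeats (independent place-field configurations) and the target Betti
    tuple.  Within a repeat, every grid point shares the seed, so sweeps over
    the synaptic modes are coupled by common random numbers."""

    p_hats: tuple[float, ...] = (1.0,)
    q_hats: tuple[float, ...] = (1.0,)
    repeats: int = 10
    base_seed: int = 0
    target: tuple[int, int] = (1, 1)
    c_p: float = 0.04
    c_q: float = 0.04

    def __post_init__(self) -> None:
        if not self.p_hats or not self.q_hats:
            raise ValueError("grid must be non-empty")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


@dataclass
class SweepResult:
    """Tidy per-(grid point, repeat) outcomes."""

    table: pd.DataFrame

    def success_fraction(self, by: str = "p_hat") -> pd.Series:
        return self.table.groupby(by)["success"].mean()

    def median_t_min(self, by: str = "p_hat") -> pd.Series:
        return self.table.groupby(by)["t_min"].median()


@dataclass(frozen=True)
class FitResult:
    exponent: float
    exponent_se: float
    critical: float
    critical_se: float
    r2: float
    flagged_nondivergent: bool = False
    saturated: bool = False


def _run_row(run: EffectiveRun, **extra) -> dict:
    horizon = run.session.config.duration
    return {
        "success": bool(run.outcome.correct),
        "t_min": run.outcome.t_min if run.outcome.t_min is not None else math.nan,
        "b0_final": run.outcome.final_betti[0],
        "b1_final": run.outcome.final_betti[1],
        "n_edges": run.n_edges,
        "n2": run.n2,
        "n_spurious": run.stats.n_spurious,
        "mean_birth": run.stats.mean_birth,
        "mean_death": run.stats.mean_death,
        "mean_length": run.stats.mean_length,
        "horizon": horizon,
        **extra,
    }


def run_sweep(cfg: SweepConfig, base: SessionConfig) -> SweepResult:
    """Sweep the synaptic modes over a fixed session per repeat.

    Per repeat one session (trajectory, ensemble, base spikes) is simulated
    with seed ``base_seed + repeat``; every ``(p_hat, q_hat)`` point screens
    that same session, so degradation along the grid is monotone up to the
    readout noise.  Failures at a grid point are recorded, not fatal.
    """
    base = replace(base, target_betti=cfg.target)
    rows = []
    for rep in range(cfg.repeats):
        seed = cfg.base_seed + rep
        session = simulate_session(base, seed=seed)
        for p_hat in cfg.p_hats:
            for q_hat in cfg.q_hats:
                model = SynapticModel(p_hat=p_hat, q_hat=q_hat,
                                      c_p=cfg.c_p, c_q=cfg.c_q)
                try:
                    run = run_effective(session, model, representatives=False)
                    rows.append(_run_row(run, p_hat=p_hat, q_hat=q_hat,
                                         repeat=rep, seed=seed, error=""))
                except Exception as exc:  # pragma: no cover - defensive
                    rows.append({"p_hat": p_hat, "q_hat": q_hat, "repeat": rep,
                                 "seed": seed, "success": False,
                                 "t_min": math.nan, "error": str(exc)})
    return SweepResult(table=pd.DataFrame(rows))


def fit_power_law(
    x: np.ndarray,
    t_min: np.ndarray,
    *,
    n_grid: int = 400,
    min_points: int = 5,
) -> FitResult:
    """Joint fit of ``T = A (x - x_crit)^-kappa`` by least squares of
    ``log T`` against ``log(x - x_crit)`` over a grid of critical-point
    candidates (coarse scan, then refinement around the minimum).

    Data whose dynamic range is small (max/min < 2) or whose fitted exponent
    is tiny are flagged non-divergent.
    """
    x = np.asarray(x, dtype=float)
    t = np.asarray(t_min, dtype=float)
    ok = np.isfinite(x) & np.isfinite(t) & (t > 0)
    x, t = x[ok], t[ok]
    if len(x) < min_points:
        raise ValueError(f"need at least {min_points} points above the critical estimate")
    logt = np.log(t)
    xmin, xmax = x.min(), x.max()
    span = xmax - xmin

    def sse_at(xc: float) -> tuple[float, float, float, float]:
        lx = np.log(x - xc)
        A = np.vander(lx, 2)  # [lx, 1]
        coef, res, *_ = np.linalg.lstsq(A, logt, rcond=None)
        pred = A @ coef
        sse = float(((logt - pred) ** 2).sum())
        return sse, -coef[0], coef[1], float(np.corrcoef(pred, logt)[0, 1] ** 2 if len(x) > 2 else 1.0)

    # coarse-to-fine scan of the critical point strictly below min(x)
    lo, hi = xmin - 2.0 * span, xmin - 1e-9 * max(span, 1.0)
    best = None
    for _ in range(3):
        grid = np.linspace(lo, hi, n_grid)
        scores = [sse_at(xc) for xc in grid]
        k = int(np.argmin([s[0] for s in scores]))
        best = (grid[k], *scores[k])
        step = grid[1] - grid[0]
        lo, hi = grid[k] - step, min(grid[k] + step, xmin - 1e-9 * max(span, 1.0))
    xc, sse, kappa, _, r2 = best
    # exponent SE from the linear regression at the optimal critical point
    lx = np.log(x - xc)
    dof = max(len(x) - 2, 1)
    sigma2 = sse / dof
    sxx = float(((lx - lx.mean()) ** 2).sum())
    kappa_se = math.sqrt(sigma2 / sxx) if sxx > 0 else math.inf
    # critical SE from the SSE profile: range where SSE <= SSE_min + sigma2
    grid = np.linspace(xmin - 2.0 * span, xmin - 1e-9 * max(span, 1.0), n_grid)
    prof = np.array([sse_at(g)[0] for g in grid])
    inside = grid[prof <= sse + sigma2]
    crit_se = float((inside.max() - inside.min()) / 2) if len(inside) > 1 else float(grid[1] - grid[0])
    flagged = (kappa < 0.05) or (t.max() / t.min() < 2.0)
    return FitResult(exponent=float(kappa), exponent_se=float(kappa_se),
                     critical=float(xc), critical_se=crit_se, r2=float(r2),
                     flagged_nondivergent=bool(flagged))


def estimate_critical(
    sweep: SweepResult | pd.DataFrame,
    success_threshold: float = 0.5,
    by: str = "p_hat",
) -> float:
    """Critical mode from the success-fraction curve: the threshold crossing
    between the bracketing grid points, refined by a logistic fit when it
    converges (linear interpolation otherwise).

    Raises if the sweep does not span both regimes.
    """
    table = sweep.table if isinstance(sweep, SweepResult) else sweep
    frac = table.groupby(by)["success"].mean().sort_index()
    xs = frac.index.to_numpy(dtype=float)
    ys = frac.to_numpy(dtype=float)
    above = ys >= success_threshold
    if above.all():
        raise ValueError("no failure regime in sweep; critical point undefined")
    if not above.any():
        raise ValueError("no success regime in sweep; critical point undefined")
    # smallest grid value from which successes persist
    k = len(above) - 1
    while k > 0 and above[k - 1]:
        k -= 1
    x_hi, x_lo = xs[k], xs[k - 1]
    y_hi, y_lo = ys[k], ys[k - 1]
    if y_lo == 0.0 and y_hi == 1.0:
        # a sharp 0 -> 1 step: the transition is unresolved by the grid, so
        # the first fully successful grid point is the (conservative) estimate
        return float(x_hi)
    linear = x_lo + (success_threshold - y_lo) / (y_hi - y_lo) * (x_hi - x_lo)

    def logistic(x, x0, s):
        z = np.clip((x - x0) / s, -50.0, 50.0)
        return 1.0 / (1.0 + np.exp(-z))

    try:
        popt, _ = curve_fit(
            logistic, xs, ys, p0=[linear, max((xs.max() - xs.min()) / 10, 1e-3)],
            maxfev=5000,
        )
        x0 = float(popt[0])
        if xs.min() <= x0 <= xs.max():
            return x0
    except RuntimeError:
        pass
    return float(linear)


def critical_surface(
    param_values: np.ndarray,
    criticals: np.ndarray,
    *,
    flatten_slope: float = 0.05,
) -> FitResult:
    """Log-log fit of the critical probability against one ensemble parameter
    (``p_crit ~ param^slope``).

    A saturating tail (successive log-log slope magnitude below
    ``flatten_slope``, or a sign reversal) is excluded from the fit and
    flagged.
    """
    x = np.asarray(param_values, dtype=float)
    y = np.asarray(criticals, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least two grid points")
    order = np.argsort(x)
    x, y = x[order], y[order]
    lx, ly = np.log(x), np.log(y)
    slopes = np.diff(ly) / np.diff(lx)
    sign = np.sign(np.median(slopes))
    cut = len(x)
    for k, s in enumerate(slopes):
        if abs(s) < flatten_slope or np.sign(s) != sign:
            cut = k + 1
            break
    saturated = cut < len(x)
    lx_f, ly_f = lx[:cut], ly[:cut]
    if len(lx_f) < 2:
        raise ValueError("saturation leaves too few points to fit")
    A = np.vander(lx_f, 2)
    coef, *_ = np.linalg.lstsq(A, ly_f, rcond=None)
    pred = A @ coef
    resid = ly_f - pred
    dof = max(len(lx_f) - 2, 1)
    sxx = float(((lx_f - lx_f.mean()) ** 2).sum())
    se = math.sqrt(float((resid**2).sum()) / dof / sxx) if sxx > 0 else math.inf
    r2 = float(np.corrcoef(pred, ly_f)[0, 1] ** 2) if len(lx_f) > 2 else 1.0
    return FitResult(exponent=float(coef[0]), exponent_se=float(se),
                     critical=math.nan, critical_se=math.nan, r2=r2,
                     saturated=bool(saturated))


def learning_region(
    s_values,
    f_values,
    n_values,
    base: SessionConfig,
    model: SynapticModel = SynapticModel(),
    repeats: int = 3,
    base_seed: int = 0,
    success_threshold: float = 0.5,
) -> pd.DataFrame:
    """Success fraction and mean learning time per ``(s, f, N)`` voxel at a
    fixed synaptic model.  The learning region is the set of voxels with
    success fraction >= the threshold (column ``in_region``)."""
    rows = []
    for s in s_values:
        for f in f_values:
            for n in n_values:
                cfg = base.with_ensemble(N=int(n), f=float(f), s=float(s))
                succ, tmins = [], []
                for rep in range(repeats):
                    session = simulate_session(cfg, seed=base_seed + rep)
                    run = run_effective(session, model, representatives=False)
                    succ.append(run.outcome.correct)
                    if run.outcome.t_min is not None:
                        tmins.append(run.outcome.t_min)
                frac = float(np.mean(succ))
                rows.append({
                    "s": s, "f": f, "N": n,
                    "success_fraction": frac,
                    "mean_t_min": float(np.mean(tmins)) if tmins else math.nan,
                    "in_region": frac >= success_threshold,
                })
    return pd.DataFrame(rows)


def compensation_check(
    p_hat: float,
    q_hat: float,
    delta_p: float,
    *,
    kappa: float,
    varkappa: float,
    p_crit: float,
    q_crit: float,
) -> float:
    """Readout-mode change compensating a transmission-mode change:

        delta_q = -(kappa / varkappa) * delta_p * (q_hat - q_crit) / (p_hat - p_crit)

    keeps the learning time unchanged to first order.  Raises if the base
    point lies at or below either critical mode.
    """
    if p_hat <= p_crit or q_hat <= q_crit:
        raise ValueError("base point must lie above both critical modes")
    return -(kappa / varkappa) * delta_p * (q_hat - q_crit) / (p_hat - p_crit)
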