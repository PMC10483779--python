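"""Parameter estimation from backscatter and bioreactor time series.

Two fitting stages:

* :func:`fit_rbale` — nonlinear least squares of the piecewise-exponential
  rbALE model against blank-corrected backscatter, recovering one specific
  growth rate per batch plus the shared dilution factor and the initial
  biomass. A log-linear slope per batch (:func:`loglinear_mu`) serves both
  as the starting guess and as an independent oracle.
* :func:`fit_monod_hierarchical` — joint weighted least squares of the
  Monod batch model over replicate bioreactors, with the kinetic parameters
  (mu_max, K_S, Y_X/S) global across reactors and the initial conditions
  (X0, S0) local to each.

Uncertainty comes from a residual-resampling bootstrap
(:func:`bootstrap_ci`) with percentile intervals.

Identifiability note: given only backscatter, the calibration slope/offset
and the initial biomass are jointly degenerate (any (a, b, X0) with the
same a*X0 + b fits equally well). The default therefore fixes a=1, b=0 and
reports biomass in backscatter units; joint calibration estimation is an
opt-in that requires pinning X0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from . import units
from .core_models import (
    Calibration,
    MonodLocal,
    MonodParams,
    RbaleParams,
    rbale_trajectory,
    simulate_monod_batch,
)
from .errors import ConfigurationError

__all__ = [
    "BatchSlice",
    "FitResult",
    "RbaleFitConfig",
    "MonodFitConfig",
    "segment_and_normalize",
    "loglinear_mu",
    "fit_rbale",
    "fit_monod_hierarchical",
    "bootstrap_ci",
    "per_batch_rates",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class BatchSlice:
    """Blank-corrected observations of one batch in one well."""

    batch: int  # 1-based
    well: str
    group: str
    t: np.ndarray  # h
    bs: np.ndarray  # blank-corrected backscatter
    include: bool = True

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.bs = np.asarray(self.bs, dtype=float)
        if self.t.shape != self.bs.shape:
            raise ConfigurationError("t and bs must have equal length")


@dataclass
class FitResult:
    """Point estimates, residual diagnostics and (optional) intervals."""

    estimates: dict
    ci: dict = field(default_factory=dict)  # name -> (lower, upper)
    ci_level: float | None = None
    residuals: np.ndarray = field(default_factory=lambda: np.empty(0))
    objective: float = 0.0
    converged: bool = False
    n_starts: int = 1
    seed: int = 0
    meta: dict = field(default_factory=dict)
    # internals used by the bootstrap: fitted values in residual space and a
    # warm-started refit closure mapping a perturbed observation vector to a
    # flat parameter vector (+ names + convergence flag)
    _predicted: np.ndarray | None = field(default=None, repr=False)
    _refit: Callable[[np.ndarray], tuple[np.ndarray, bool]] | None = field(
        default=None, repr=False
    )
    _param_names: list[str] = field(default_factory=list, repr=False)
    _param_vector: np.ndarray | None = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

def _slices_from_events(
    ts: pd.DataFrame, events: pd.DataFrame, min_points: int
) -> list[BatchSlice]:
    out: list[BatchSlice] = []
    ev = events.copy()
    ev["source"] = ev["source"].fillna("").astype(str)
    ev["dest"] = ev["dest"].fillna("").astype(str)
    inoc = ev[ev["kind"] == "inoculate"]
    trig = ev[ev["kind"] == "trigger"]
    for row in inoc.itertuples():
        well = row.dest
        match = trig[
            (trig["group"] == row.group)
            & (trig["batch"] == row.batch)
            & (trig["source"] == well)
        ]
        if match.empty:
            continue
        t0, t1 = float(row.time_h), float(match["time_h"].iloc[0])
        sub = ts[(ts["well"] == well) & (ts["time_h"] >= t0 - 1e-9) & (ts["time_h"] <= t1 + 1e-9)]
        pre = ts[(ts["well"] == well) & (ts["time_h"] < t0 - 1e-9)]
        blank = float(pre["value"].iloc[-1]) if not pre.empty else 0.0
        out.append(
            BatchSlice(
                batch=int(row.batch),
                well=well,
                group=str(row.group),
                t=sub["time_h"].to_numpy(),
                bs=sub["value"].to_numpy() - blank,
            )
        )
    out.sort(key=lambda s: (s.group, s.t[0] if s.t.size else np.inf))
    return _apply_min_points(out, min_points)


def _slices_by_detection(
    ts: pd.DataFrame, drop_frac: float, min_points: int
) -> list[BatchSlice]:
    """Segment without an event log: a transfer is called wherever the raw
    signal of the run drops by more than ``drop_frac`` between consecutive
    readings. Each well-segment's first reading (taken during tempering,
    before inoculation) is its blank."""
    segments: list[tuple[str, np.ndarray, np.ndarray]] = []
    for well, sub in ts.groupby("well"):
        sub = sub.sort_values("time_h")
        t = sub["time_h"].to_numpy()
        v = sub["value"].to_numpy()
        cut = np.flatnonzero(v[1:] < (1 - drop_frac) * v[:-1]) + 1
        for a, b in zip(np.concatenate([[0], cut]), np.concatenate([cut, [len(v)]])):
            if b > a:
                segments.append((str(well), t[a:b], v[a:b]))
    segments.sort(key=lambda s: s[1][0])
    out = []
    for i, (well, t, v) in enumerate(segments, start=1):
        blank = v[0]
        out.append(
            BatchSlice(batch=i, well=well, group=well[0], t=t[1:], bs=v[1:] - blank)
        )
    return _apply_min_points(out, min_points)


def _apply_min_points(slices: list[BatchSlice], min_points: int) -> list[BatchSlice]:
    for s in slices:
        if s.t.size < min_points:
            s.include = False
            logger.warning(
                "batch %d in well %s has %d < %d points; excluded from fitting",
                s.batch,
                s.well,
                s.t.size,
                min_points,
            )
    return slices


def segment_and_normalize(
    ts: pd.DataFrame,
    events: pd.DataFrame | None = None,
    drop_frac: float = 0.5,
    min_points: int = 4,
) -> list[BatchSlice]:
    """Cut a long-format backscatter table into blank-corrected batch slices.

    With an event log, each slice spans inoculation to trigger of its batch
    and is normalized by the destination well's last pre-inoculation
    reading. Without one, transfers are detected as signal drops larger
    than ``drop_frac`` between consecutive cycles. Slices with fewer than
    ``min_points`` observations are kept but flagged excluded.
    """
    if events is not None:
        return _slices_from_events(ts, events, min_points)
    return _slices_by_detection(ts, drop_frac, min_points)


def loglinear_mu(slice_: BatchSlice) -> float:
    """Least-squares slope of ln(BS) over time — the model-free growth rate.

    Exact on noiseless exponential data; used as the starting value and the
    independent oracle for the model-based per-batch rates.
    """
    if np.any(slice_.bs <= 0):
        raise ValueError(
            f"batch {slice_.batch}: non-positive blank-corrected values; slice rejected"
        )
    if slice_.t.size < 2:
        raise ValueError("need at least two points for a slope")
    return float(np.polyfit(slice_.t, np.log(slice_.bs), 1)[0])


# ---------------------------------------------------------------------------
# rbALE fit
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RbaleFitConfig:
    n_starts: int = 10
    seed: int = 0
    group: str | None = None  # fit this group's slices (default: first group)
    exclude_batches: tuple[int, ...] = ()  # explicit user mask, 1-based
    fit_calibration: bool = False  # opt-in joint (a, b) estimation
    fixed_X0: float | None = None  # required when fit_calibration is set
    f_dil_init: float = 17.0
    xtol: float = 1e-8
    max_nfev: int = 500
    jitter_sd: float = 0.2


def _multistart(
    residual: Callable[[np.ndarray], np.ndarray],
    x0: np.ndarray,
    bounds: tuple[np.ndarray, np.ndarray],
    n_starts: int,
    seed: int,
    jitter_sd: float,
    xtol: float,
    max_nfev: int,
):
    """Best-of-n seeded local least squares; start 0 is the plain initial guess."""
    rng = np.random.default_rng(seed)
    best = None
    objectives = []
    for i in range(n_starts):
        start = x0.copy()
        if i > 0:
            start = np.clip(
                start * np.exp(jitter_sd * rng.standard_normal(start.size)),
                bounds[0] + 1e-12,
                bounds[1],
            )
        try:
            res = least_squares(
                residual,
                start,
                bounds=bounds,
                xtol=xtol,
                ftol=xtol,
                gtol=xtol,
                max_nfev=max_nfev,
            )
        except Exception as exc:  # noqa: BLE001 — collected as diagnostics
            objectives.append(math.inf)
            logger.warning("start %d failed: %s", i, exc)
            continue
        objectives.append(2 * res.cost)
        if best is None or res.cost < best.cost:
            best = res
    return best, objectives


def fit_rbale(
    ts: pd.DataFrame,
    events: pd.DataFrame | None = None,
    config: RbaleFitConfig | None = None,
) -> FitResult:
    """Fit the piecewise-exponential rbALE model to one run's backscatter.

    Minimizes the sum of squared deviations between blank-corrected
    measurements and the model trajectory over one growth rate per batch,
    the shared dilution factor and the initial biomass, by multi-start
    trust-region least squares. Starting values: per-batch log-linear
    slopes, f_dil = 17 from the pipetting volumes, X0 from the first
    observation. Batches listed in ``config.exclude_batches`` (and slices
    flagged by segmentation) keep their log-linear rate but contribute no
    residuals.
    """
    cfg = config or RbaleFitConfig()
    slices = segment_and_normalize(ts, events)
    if not slices:
        raise ConfigurationError("no batch slices found")
    group = cfg.group or slices[0].group
    slices = [s for s in slices if s.group == group]
    n = len(slices)
    for s in slices:
        if s.batch in cfg.exclude_batches:
            s.include = False

    mu_init = np.array(
        [max(loglinear_mu(s), 1e-3) if s.t.size >= 2 else 0.1 for s in slices]
    )
    x0_init = max(float(slices[0].bs[0]), 1e-6)
    free = np.array([s.include for s in slices])
    if not free.any():
        raise ConfigurationError("all batches excluded; nothing to fit")

    t_obs = np.concatenate([s.t for s in slices if s.include])
    y_obs = np.concatenate([s.bs for s in slices if s.include])
    transfer_times = np.array([s.t[-1] for s in slices[:-1]])
    start_time = float(slices[0].t[0])
    lag = (
        float(np.median([slices[i + 1].t[0] - slices[i].t[-1] for i in range(n - 1)]))
        if n > 1
        else 0.0
    )

    fit_calib = cfg.fit_calibration
    if fit_calib and cfg.fixed_X0 is None:
        raise ConfigurationError(
            "joint calibration estimation requires fixed_X0 (X0, a, b are degenerate)"
        )

    n_free = int(free.sum())

    def unpack(theta: np.ndarray):
        mu = mu_init.copy()
        mu[free] = theta[:n_free]
        f_dil = theta[n_free]
        if fit_calib:
            a, b = theta[n_free + 1], theta[n_free + 2]
            x0 = cfg.fixed_X0
        else:
            a, b = 1.0, 0.0
            x0 = theta[n_free + 1]
        return mu, f_dil, x0, Calibration(a=a, b=b)

    def model_bs(theta: np.ndarray) -> np.ndarray:
        mu, f_dil, x0, calib = unpack(theta)
        params = RbaleParams(mu=tuple(mu), f_dil=f_dil, X0=x0, calib=calib)
        _, bs = rbale_trajectory(
            params, transfer_times, t_obs, lag_h=lag, start_time=start_time
        )
        return bs

    theta0 = np.concatenate(
        [
            mu_init[free],
            [cfg.f_dil_init],
            [1.0, 0.0] if fit_calib else [x0_init],
        ]
    )
    lo = np.concatenate(
        [np.zeros(n_free), [1.0 + 1e-6], [1e-6, 0.0] if fit_calib else [1e-9]]
    )
    hi = np.concatenate(
        [np.full(n_free, 5.0), [1e4], [1e4, 1e3] if fit_calib else [1e6]]
    )

    def residual_for(y: np.ndarray) -> Callable[[np.ndarray], np.ndarray]:
        return lambda theta: model_bs(theta) - y

    best, objectives = _multistart(
        residual_for(y_obs),
        theta0,
        (lo, hi),
        cfg.n_starts,
        cfg.seed,
        cfg.jitter_sd,
        cfg.xtol,
        cfg.max_nfev,
    )
    if best is None:
        return FitResult(
            estimates={},
            converged=False,
            n_starts=cfg.n_starts,
            seed=cfg.seed,
            meta={"start_objectives": objectives, "group": group},
        )

    mu_hat, f_hat, x0_hat, calib_hat = unpack(best.x)
    names = [f"mu[{s.batch}]" for s, isfree in zip(slices, free) if isfree] + ["f_dil"]
    names += ["a", "b"] if fit_calib else ["X0"]

    def refit(y_new: np.ndarray) -> tuple[np.ndarray, bool]:
        res = least_squares(
            residual_for(y_new),
            best.x,
            bounds=(lo, hi),
            xtol=cfg.xtol,
            ftol=cfg.xtol,
            gtol=cfg.xtol,
            max_nfev=cfg.max_nfev,
        )
        return res.x, res.status > 0

    estimates = {
        "mu": mu_hat,
        "f_dil": float(f_hat),
        "X0": float(x0_hat),
        "batches": [s.batch for s in slices],
        "included": free.tolist(),
    }
    if fit_calib:
        estimates["a"], estimates["b"] = calib_hat.a, calib_hat.b
    return FitResult(
        estimates=estimates,
        residuals=best.fun,
        objective=float(2 * best.cost),
        converged=best.status > 0,
        n_starts=cfg.n_starts,
        seed=cfg.seed,
        meta={
            "start_objectives": objectives,
            "group": group,
            "lag_h": lag,
            "n_obs": int(y_obs.size),
        },
        _predicted=y_obs + best.fun,
        _refit=refit,
        _param_names=names,
        _param_vector=best.x.copy(),
    )


def per_batch_rates(fit: FitResult, slices: Sequence[BatchSlice] | None = None) -> pd.DataFrame:
    """Per-batch rate table (group, batch, mu_est, ci_lo, ci_hi, n_points)."""
    mus = np.asarray(fit.estimates["mu"])
    batches = fit.estimates.get("batches", list(range(1, mus.size + 1)))
    rows = []
    for b, m in zip(batches, mus):
        lo, hi = fit.ci.get(f"mu[{b}]", (np.nan, np.nan))
        npts = 0
        if slices is not None:
            match = [s for s in slices if s.batch == b]
            npts = int(match[0].t.size) if match else 0
        rows.append((fit.meta.get("group", ""), b, float(m), lo, hi, npts))
    return pd.DataFrame(
        rows, columns=["group", "batch", "mu_est", "ci_lo", "ci_hi", "n_points"]
    )


# ---------------------------------------------------------------------------
# Hierarchical Monod fit
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MonodFitConfig:
    n_starts: int = 3
    seed: int = 0
    xtol: float = 1e-8
    max_nfev: int = 500
    jitter_sd: float = 0.2
    rtol: float = 1e-7  # ODE tolerance during fitting
    molar_mass: float = units.MOLAR_MASS_ETHANOL
    ci_level: float = 0.95
    #: a parameter whose delta-method CI spans more than this ratio is
    #: flagged weakly identifiable
    identifiability_ratio: float = 10.0


def fit_monod_hierarchical(
    tables: pd.DataFrame, config: MonodFitConfig | None = None
) -> FitResult:
    """Joint Monod fit over replicate reactors: global kinetics, local ICs.

    Observations are weighted by the reciprocal range of each observable
    (CDW and substrate differ by an order of magnitude in units) and all
    reactors enter one least-squares problem. Approximate intervals come
    from the Jacobian-based covariance at the optimum; parameters whose
    interval spans more than ``identifiability_ratio`` (e.g. K_S when the
    start substrate is far above it) are flagged weakly identifiable.
    """
    cfg = config or MonodFitConfig()
    reactors = sorted(tables["reactor"].unique())
    if not reactors:
        raise ConfigurationError("no reactors in table")
    grids, xs, ss = [], [], []
    for r in reactors:
        sub = tables[tables["reactor"] == r].sort_values("time_h")
        if len(sub) < 4:
            raise ConfigurationError(f"reactor {r} has fewer than 4 time points")
        grids.append(sub["time_h"].to_numpy())
        xs.append(sub["cdw_gL"].to_numpy())
        ss.append(units.mm_to_gl(sub["ethanol_mM"].to_numpy(), cfg.molar_mass))

    wx = 1.0 / max(max(x.max() for x in xs) - min(x.min() for x in xs), 1e-9)
    ws = 1.0 / max(max(s.max() for s in ss) - min(s.min() for s in ss), 1e-9)
    nr = len(reactors)

    def unpack(theta):
        mu_max, ks, y = theta[0], theta[1], theta[2]
        locs = tuple(
            MonodLocal(X0=theta[3 + 2 * i], S0=theta[4 + 2 * i]) for i in range(nr)
        )
        return MonodParams(mu_max=mu_max, K_S=ks, Y_XS=y, locals=locs)

    def model(theta) -> np.ndarray:
        params = unpack(theta)
        parts = []
        for i in range(nr):
            x, s = simulate_monod_batch(
                params, replicate=i, grid=grids[i], rtol=cfg.rtol, atol=1e-9
            )
            parts.append(wx * x)
            parts.append(ws * s)
        return np.concatenate(parts)

    y_obs = np.concatenate(
        [np.concatenate([wx * xs[i], ws * ss[i]]) for i in range(nr)]
    )

    # initial guesses from the data
    y_init = []
    mu_init = []
    for i in range(nr):
        dx = xs[i][-1] - xs[i][0]
        ds = ss[i][0] - min(ss[i].min(), ss[i][-1])
        y_init.append(dx / ds if ds > 1e-9 else 0.5)
        early = ss[i] > 0.2 * ss[i][0]
        if early.sum() >= 2 and np.all(xs[i][early] > 0):
            mu_init.append(np.polyfit(grids[i][early], np.log(xs[i][early]), 1)[0])
    y0 = float(np.clip(np.median(y_init), 0.05, 0.95))
    mu0 = float(np.clip(np.median(mu_init) if mu_init else 0.2, 1e-3, 2.0))
    theta0 = np.concatenate(
        [[mu0, 0.1, y0]]
        + [[max(xs[i][0], 1e-3), max(ss[i][0], 1e-3)] for i in range(nr)]
    )
    lo = np.concatenate([[1e-4, 1e-6, 0.01], np.tile([1e-6, 1e-6], nr)])
    hi = np.concatenate([[5.0, 50.0, 0.99], np.tile([1e3, 1e3], nr)])

    def residual_for(y):
        return lambda theta: model(theta) - y

    best, objectives = _multistart(
        residual_for(y_obs),
        theta0,
        (lo, hi),
        cfg.n_starts,
        cfg.seed,
        cfg.jitter_sd,
        cfg.xtol,
        cfg.max_nfev,
    )
    if best is None:
        return FitResult(
            estimates={},
            converged=False,
            n_starts=cfg.n_starts,
            seed=cfg.seed,
            meta={"start_objectives": objectives},
        )

    params = unpack(best.x)
    names = ["mu_max", "K_S", "Y_XS"]
    for r in reactors:
        names += [f"X0[{r}]", f"S0[{r}]"]

    # delta-method covariance at the optimum
    ci: dict[str, tuple[float, float]] = {}
    weak: list[str] = []
    dof = max(y_obs.size - best.x.size, 1)
    s2 = 2 * best.cost / dof
    try:
        jtj = best.jac.T @ best.jac
        cov = np.linalg.pinv(jtj) * s2
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
        from scipy.stats import norm

        z = norm.ppf(0.5 + cfg.ci_level / 2)
        for nm, est, s_ in zip(names, best.x, se):
            low = max(est - z * s_, 1e-12)
            high = est + z * s_
            ci[nm] = (float(low), float(high))
            if high / max(low, 1e-12) > cfg.identifiability_ratio:
                weak.append(nm)
    except np.linalg.LinAlgError:  # pragma: no cover
        pass

    def refit(y_new: np.ndarray) -> tuple[np.ndarray, bool]:
        res = least_squares(
            residual_for(y_new),
            best.x,
            bounds=(lo, hi),
            xtol=cfg.xtol,
            ftol=cfg.xtol,
            gtol=cfg.xtol,
            max_nfev=cfg.max_nfev,
        )
        return res.x, res.status > 0

    estimates = {
        "mu_max": params.mu_max,
        "K_S": params.K_S,
        "Y_XS": params.Y_XS,
        "locals": {
            r: {"X0": params.locals[i].X0, "S0": params.locals[i].S0}
            for i, r in enumerate(reactors)
        },
    }
    return FitResult(
        estimates=estimates,
        ci=ci,
        ci_level=cfg.ci_level,
        residuals=best.fun,
        objective=float(2 * best.cost),
        converged=best.status > 0,
        n_starts=cfg.n_starts,
        seed=cfg.seed,
        meta={
            "start_objectives": objectives,
            "reactors": reactors,
            "weights": {"cdw": wx, "substrate": ws},
            "weakly_identifiable": weak,
        },
        _predicted=y_obs + best.fun,
        _refit=refit,
        _param_names=names,
        _param_vector=best.x.copy(),
    )


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def bootstrap_ci(
    fit: FitResult,
    n_boot: int = 100,
    seed: int = 0,
    level: float = 0.95,
) -> FitResult:
    """Residual-resampling bootstrap percentile intervals.

    Resamples the fit's residuals with replacement, adds them to the fitted
    values, refits from the point estimate, and takes percentile intervals
    of the parameter draws. If fewer than half the replicates converge the
    intervals are flagged unreliable in ``meta``.
    """
    if not fit.converged or fit._refit is None or fit._predicted is None:
        raise ConfigurationError("bootstrap requires a converged fit with refit support")
    rng = np.random.default_rng(seed)
    resid = fit.residuals
    m = resid.size
    draws = []
    ok = 0
    for _ in range(n_boot):
        # residuals are stored as model - y, so the data-space errors are -resid
        y_star = fit._predicted - resid[rng.integers(0, m, m)]
        theta, conv = fit._refit(y_star)
        if conv:
            ok += 1
            draws.append(theta)
    if not draws:
        raise ConfigurationError("no bootstrap replicate converged")
    draws = np.asarray(draws)
    alpha = (1 - level) / 2
    lo = np.quantile(draws, alpha, axis=0)
    hi = np.quantile(draws, 1 - alpha, axis=0)
    ci = {nm: (float(a), float(b)) for nm, a, b in zip(fit._param_names, lo, hi)}

    out = FitResult(
        estimates=fit.estimates,
        ci=ci,
        ci_level=level,
        residuals=fit.residuals,
        objective=fit.objective,
        converged=fit.converged,
        n_starts=fit.n_starts,
        seed=seed,
        meta={
            **fit.meta,
            "n_boot": n_boot,
            "boot_converged": ok,
            "bootstrap_unreliable": ok < 0.5 * n_boot,
        },
        _predicted=fit._predicted,
        _refit=fit._refit,
        _param_names=fit._param_names,
        _param_vector=fit._param_vector,
    )
    return out
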