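"""Growth and bioprocess models for repetitive-batch ALE (rbALE) experiments.

This module holds the model equations everything else builds on:

* a linear backscatter calibration ``X = (BS - b) / a`` mapping the
  microbioreactor's scattered-light signal to biomass concentration;
* the piecewise-exponential rbALE model — substrate-independent exponential
  growth within a batch, instantaneous dilution of biomass by a factor
  ``f_dil`` at every transfer event, and an optional tempering lag during
  which the freshly inoculated culture does not yet grow;
* a two-population competition variant of the rbALE model describing the
  takeover of a faster-growing mutant during serial transfer;
* classical Monod batch kinetics for lab-scale bioreactor cultivations.

All models with closed-form solutions are evaluated analytically; numeric
integration (``rbale_trajectory_ode``) is provided as an independent
cross-check, not as the primary path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .errors import ConfigurationError, IntegrationError, NegativeBiomassError

__all__ = [
    "Calibration",
    "RbaleParams",
    "CompetitionParams",
    "MonodLocal",
    "MonodParams",
    "DerivedRates",
    "CompetitionTrajectory",
    "apply_calibration",
    "generations_between",
    "rbale_trajectory",
    "rbale_trajectory_ode",
    "competition_trajectory",
    "simulate_monod_batch",
    "derived_rates",
]


# ---------------------------------------------------------------------------
# Parameter records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Calibration:
    """Linear backscatter calibration ``X = (BS - b) / a``.

    Parameters
    ----------
    a : slope, backscatter units per g_CDW L^-1 (must be > 0).
    b : offset, backscatter units (must be >= 0).

    The default identity calibration (a=1, b=0) reports biomass in
    backscatter units, which is the working convention whenever no
    calibration table is available.
    """

    a: float = 1.0
    b: float = 0.0

    def __post_init__(self) -> None:
        if not (self.a > 0):
            raise ConfigurationError(f"calibration slope a must be > 0, got {self.a}")
        if self.b < 0:
            raise ConfigurationError(f"calibration offset b must be >= 0, got {self.b}")

    def to_biomass(self, bs):
        """Forward map BS -> X = (BS - b)/a; raises if BS < b."""
        bs = np.asarray(bs, dtype=float)
        if np.any(bs < self.b):
            raise NegativeBiomassError(
                f"backscatter below calibration offset b={self.b}: negative biomass"
            )
        out = (bs - self.b) / self.a
        return float(out) if out.ndim == 0 else out

    def to_backscatter(self, x):
        """Inverse map X -> BS = a*X + b."""
        x = np.asarray(x, dtype=float)
        out = self.a * x + self.b
        return float(out) if out.ndim == 0 else out


def apply_calibration(value, calib: Calibration, direction: str = "to_biomass"):
    """Apply the linear calibration in either direction.

    ``direction`` is ``"to_biomass"`` (BS -> X) or ``"to_backscatter"``
    (X -> BS). The two directions are exact inverses.
    """
    value = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(value)):
        raise ConfigurationError("calibration input must be finite")
    if direction == "to_biomass":
        return calib.to_biomass(value)
    if direction == "to_backscatter":
        return calib.to_backscatter(value)
    raise ConfigurationError(f"unknown calibration direction {direction!r}")


@dataclass(frozen=True)
class RbaleParams:
    """Parameters of the piecewise-exponential rbALE model.

    mu    : per-batch specific growth rates mu_i (h^-1); one entry per batch,
            or a single entry reused for every batch.
    f_dil : dilution factor at each transfer (dimensionless, > 1); 17 for the
            standard 50 uL inoculum into 800 uL fresh medium.
    X0    : biomass at the first inoculation (g_CDW L^-1, or backscatter
            units under the identity calibration).
    calib : linear backscatter calibration.
    """

    mu: tuple[float, ...]
    f_dil: float = 17.0
    X0: float = 8.0
    calib: Calibration = field(default_factory=Calibration)

    def __post_init__(self) -> None:
        object.__setattr__(self, "mu", tuple(float(m) for m in np.atleast_1d(self.mu)))
        if len(self.mu) == 0:
            raise ConfigurationError("mu must contain at least one rate")
        if any(m < 0 for m in self.mu):
            raise ConfigurationError("all growth rates mu_i must be >= 0")
        if not (self.f_dil > 1):
            raise ConfigurationError(f"dilution factor f_dil must be > 1, got {self.f_dil}")
        if not (self.X0 > 0):
            raise ConfigurationError(f"initial biomass X0 must be > 0, got {self.X0}")

    def mu_for_batch(self, i: int) -> float:
        """Growth rate of batch ``i`` (0-based); a single-rate record applies
        its rate to every batch."""
        if len(self.mu) == 1:
            return self.mu[0]
        if i >= len(self.mu):
            raise ConfigurationError(
                f"batch {i} requested but only {len(self.mu)} rates configured"
            )
        return self.mu[i]


@dataclass(frozen=True)
class CompetitionParams:
    """Wild-type/mutant competition during serial transfer.

    A mutant with ``mu_evo > mu_wt`` appears in batch ``emergence_batch``
    (1-based) at biomass fraction ``initial_fraction`` of the total. Both
    subpopulations grow exponentially and are diluted identically at
    transfers, so the mutant fraction rises batch by batch and the apparent
    population growth rate climbs from mu_wt toward mu_evo.
    """

    mu_wt: float
    mu_evo: float
    emergence_batch: int = 1
    initial_fraction: float = 1e-6
    f_dil: float = 17.0
    X0: float = 8.0
    calib: Calibration = field(default_factory=Calibration)

    def __post_init__(self) -> None:
        if not (self.mu_evo > self.mu_wt >= 0):
            raise ConfigurationError(
                f"require mu_evo > mu_wt >= 0, got mu_evo={self.mu_evo}, mu_wt={self.mu_wt}"
            )
        if not (0 < self.initial_fraction < 1):
            raise ConfigurationError("initial_fraction must lie in (0, 1)")
        if self.emergence_batch < 1:
            raise ConfigurationError("emergence_batch is 1-based and must be >= 1")
        if not (self.f_dil > 1 and self.X0 > 0):
            raise ConfigurationError("require f_dil > 1 and X0 > 0")


@dataclass(frozen=True)
class MonodLocal:
    """Per-reactor initial conditions (local parameters)."""

    X0: float  # g_CDW L^-1
    S0: float  # g L^-1

    def __post_init__(self) -> None:
        if not (self.X0 > 0 and self.S0 > 0):
            raise ConfigurationError("X0 and S0 must be > 0")


@dataclass(frozen=True)
class MonodParams:
    """Monod batch model: globals shared across replicate reactors, locals per reactor.

    dX/dt = mu_max * S/(K_S + S) * X
    dS/dt = -(1/Y_XS) * mu_max * S/(K_S + S) * X
    """

    mu_max: float  # h^-1
    K_S: float  # g L^-1
    Y_XS: float  # g_CDW per g substrate
    locals: tuple[MonodLocal, ...] = ()

    def __post_init__(self) -> None:
        if not (self.mu_max > 0):
            raise ConfigurationError("mu_max must be > 0")
        if not (self.K_S > 0):
            raise ConfigurationError("K_S must be > 0")
        if not (0 < self.Y_XS < 1):
            raise ConfigurationError("Y_XS must lie in (0, 1)")
        object.__setattr__(self, "locals", tuple(self.locals))


@dataclass(frozen=True)
class DerivedRates:
    """Substrate uptake rate derived from Monod globals at S >> K_S."""

    q_S: float  # mmol g_CDW^-1 h^-1
    Y_XS_g: float  # g/g
    molar_mass: float  # g mol^-1

    def __post_init__(self) -> None:
        if not (self.q_S > 0):
            raise ConfigurationError("q_S must be > 0")


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------

def generations_between(bs_start: float, bs_end: float) -> float:
    """Number of generations between two backscatter readings, log2(end/start).

    Inputs are blank-corrected backscatter (or biomass) values and must be
    positive. With the standard start of ~8 and trigger threshold of 60 this
    gives log2(60/8) = 2.91, i.e. about three generations per batch.
    """
    if not (bs_start > 0 and bs_end > 0):
        raise ValueError(
            f"backscatter values must be positive, got ({bs_start}, {bs_end})"
        )
    return math.log2(bs_end / bs_start)


def _batch_growth_starts(
    transfer_times: np.ndarray, start_time: float, lag_h: float
) -> np.ndarray:
    """Growth-clock start of each batch: first batch at ``start_time``, later
    batches one tempering lag after their transfer event."""
    starts = np.concatenate([[start_time], transfer_times + lag_h])
    if np.any(np.diff(np.concatenate([[start_time], transfer_times])) <= 0):
        raise ConfigurationError("transfer_times must be strictly increasing")
    if transfer_times.size and np.any(transfer_times[1:] < starts[1:-1]):
        raise ConfigurationError("transfers closer together than the tempering lag")
    return starts


def _resolve_mu(params: RbaleParams, n_batches: int) -> np.ndarray:
    if len(params.mu) == 1:
        return np.full(n_batches, params.mu[0])
    if len(params.mu) != n_batches:
        raise ConfigurationError(
            f"{len(params.mu)} rates configured for {n_batches} batches"
        )
    return np.asarray(params.mu)


def rbale_trajectory(
    params: RbaleParams,
    transfer_times: Sequence[float],
    grid: Sequence[float],
    lag_h: float = 0.0,
    start_time: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise-analytic biomass and backscatter of an rbALE run.

    Within batch i the biomass grows as ``X(t) = X_start_i * exp(mu_i (t - s_i))``
    where ``s_i`` is the batch's growth start; at each transfer time the
    biomass is divided by ``f_dil`` instantaneously, and during the tempering
    lag ``lag_h`` after a transfer the diluted culture holds constant.

    The trajectory is left-continuous at transfers: evaluating exactly at a
    transfer time returns the pre-dilution biomass (the last observation of
    the closing batch).

    Returns ``(X, BS)`` evaluated on ``grid``.
    """
    transfer_times = np.asarray(transfer_times, dtype=float)
    grid = np.asarray(grid, dtype=float)
    n_batches = transfer_times.size + 1
    mu = _resolve_mu(params, n_batches)
    starts = _batch_growth_starts(transfer_times, start_time, lag_h)

    # recursion for the batch start states
    x_start = np.empty(n_batches)
    x_start[0] = params.X0
    for k, tau in enumerate(transfer_times):
        x_end = x_start[k] * math.exp(mu[k] * (tau - starts[k]))
        x_start[k + 1] = x_end / params.f_dil

    idx = np.searchsorted(transfer_times, grid, side="left")
    dt = np.clip(grid - starts[idx], 0.0, None)
    x = x_start[idx] * np.exp(mu[idx] * dt)
    return x, params.calib.to_backscatter(x)


def rbale_trajectory_ode(
    params: RbaleParams,
    transfer_times: Sequence[float],
    grid: Sequence[float],
    lag_h: float = 0.0,
    start_time: float = 0.0,
    rtol: float = 1e-8,
    atol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray]:
    """Adaptive ODE integration of the rbALE model (cross-check for
    :func:`rbale_trajectory`); integrates dX/dt = mu_i X batch by batch and
    applies the dilution jumps between segments."""
    transfer_times = np.asarray(transfer_times, dtype=float)
    grid = np.asarray(grid, dtype=float)
    n_batches = transfer_times.size + 1
    mu = _resolve_mu(params, n_batches)
    starts = _batch_growth_starts(transfer_times, start_time, lag_h)
    bounds = np.concatenate([transfer_times, [max(grid[-1], starts[-1])]])

    x_out = np.empty_like(grid)
    x0 = params.X0
    for k in range(n_batches):
        seg = (grid > (transfer_times[k - 1] if k else -np.inf)) & (grid <= bounds[k])
        if k == n_batches - 1:
            seg = grid > (transfer_times[-1] if transfer_times.size else -np.inf)
        t_eval = grid[seg]
        # lag portion: constant at x0
        in_lag = t_eval < starts[k]
        x_out[np.flatnonzero(seg)[in_lag]] = x0
        t_grow = t_eval[~in_lag]
        t_end = max(bounds[k], starts[k], t_grow[-1] if t_grow.size else starts[k])
        rate = mu[k]
        sol = solve_ivp(
            lambda t, y: rate * y,
            (starts[k], t_end),
            [x0],
            t_eval=t_grow if t_grow.size else None,
            rtol=rtol,
            atol=atol,
            dense_output=True,
        )
        if not sol.success:
            raise IntegrationError("rbALE ODE segment failed", {"message": sol.message})
        if t_grow.size:
            x_out[np.flatnonzero(seg)[~in_lag]] = sol.y[0]
        x_end = float(sol.sol(max(bounds[k], starts[k]))[0])
        x0 = x_end / params.f_dil
    return x_out, params.calib.to_backscatter(x_out)


@dataclass
class CompetitionTrajectory:
    """Result of :func:`competition_trajectory`."""

    grid: np.ndarray
    X_wt: np.ndarray
    X_evo: np.ndarray
    X_tot: np.ndarray
    backscatter: np.ndarray
    #: apparent (population-average) growth rate of each batch,
    #: ln(X_tot_end / X_tot_start) / batch duration
    apparent_mu: np.ndarray


def competition_trajectory(
    params: CompetitionParams,
    transfer_times: Sequence[float],
    grid: Sequence[float],
    lag_h: float = 0.0,
    start_time: float = 0.0,
) -> CompetitionTrajectory:
    """Two-population rbALE trajectory and per-batch apparent growth rates.

    Both subpopulations share every transfer (each divided by ``f_dil``), so
    the mutant fraction follows the closed-form recursion
    ``odds_{k+1} = odds_k * exp((mu_evo - mu_wt) * dt_k)`` — dilution leaves
    the fraction unchanged. Apparent rates are bounded by [mu_wt, mu_evo]
    and rise monotonically as the mutant takes over.
    """
    transfer_times = np.asarray(transfer_times, dtype=float)
    grid = np.asarray(grid, dtype=float)
    n_batches = transfer_times.size + 1
    if params.emergence_batch > n_batches:
        raise ConfigurationError(
            f"emergence_batch {params.emergence_batch} beyond run of {n_batches} batches"
        )
    starts = _batch_growth_starts(transfer_times, start_time, lag_h)
    ends = np.concatenate([transfer_times, [grid[-1]]])

    wt_start = np.empty(n_batches)
    evo_start = np.zeros(n_batches)
    wt0, evo0 = params.X0, 0.0
    f = params.initial_fraction
    for k in range(n_batches):
        if k == params.emergence_batch - 1:
            # mutant appears at fraction f of the total at the batch start
            evo0 = f / (1.0 - f) * (wt0 + evo0)
        wt_start[k], evo_start[k] = wt0, evo0
        dt = max(ends[k] - starts[k], 0.0)
        wt_end = wt0 * math.exp(params.mu_wt * dt)
        evo_end = evo0 * math.exp(params.mu_evo * dt)
        wt0, evo0 = wt_end / params.f_dil, evo_end / params.f_dil

    idx = np.searchsorted(transfer_times, grid, side="left")
    dt = np.clip(grid - starts[idx], 0.0, None)
    x_wt = wt_start[idx] * np.exp(params.mu_wt * dt)
    x_evo = evo_start[idx] * np.exp(params.mu_evo * dt)
    x_tot = x_wt + x_evo

    app = np.empty(n_batches)
    for k in range(n_batches):
        dt_k = ends[k] - starts[k]
        if dt_k <= 0:
            app[k] = np.nan
            continue
        tot0 = wt_start[k] + evo_start[k]
        tot1 = wt_start[k] * math.exp(params.mu_wt * dt_k) + evo_start[k] * math.exp(
            params.mu_evo * dt_k
        )
        app[k] = math.log(tot1 / tot0) / dt_k

    return CompetitionTrajectory(
        grid=grid,
        X_wt=x_wt,
        X_evo=x_evo,
        X_tot=x_tot,
        backscatter=params.calib.to_backscatter(x_tot),
        apparent_mu=app,
    )


def simulate_monod_batch(
    params: MonodParams,
    replicate: int = 0,
    grid: Sequence[float] | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate one Monod batch for the given replicate's initial conditions.

    Returns ``(X, S)`` in g L^-1 on ``grid`` (hours, starting at 0). The
    substrate is clipped at zero inside the right-hand side so the trajectory
    is well-behaved through depletion; the linear combination
    ``X + Y_XS * S`` is conserved to solver tolerance.
    """
    if replicate >= len(params.locals):
        raise ConfigurationError(
            f"no local record for replicate {replicate} ({len(params.locals)} defined)"
        )
    loc = params.locals[replicate]
    grid = np.asarray(grid if grid is not None else np.linspace(0, 20, 81), dtype=float)
    if grid[0] != 0:
        raise ConfigurationError("grid must start at t=0")

    mu_max, ks, y = params.mu_max, params.K_S, params.Y_XS

    def rhs(t, yv):
        s = max(yv[1], 0.0)
        r = mu_max * s / (ks + s)
        return [r * yv[0], -r * yv[0] / y]

    sol = solve_ivp(
        rhs,
        (0.0, float(grid[-1])),
        [loc.X0, loc.S0],
        t_eval=grid,
        rtol=rtol,
        atol=atol,
        method="RK45",
    )
    if not sol.success:
        raise IntegrationError(
            "Monod batch integration failed",
            {"message": sol.message, "t_reached": sol.t[-1] if sol.t.size else None},
        )
    x, s = sol.y
    return x, np.clip(s, 0.0, None)


def derived_rates(monod: MonodParams, molar_mass: float) -> DerivedRates:
    """Specific substrate uptake rate at S >> K_S.

    At substrate excess mu = mu_max, and the yield links growth to uptake:
    ``q_S = mu_max / (Y_XS * M) * 1000`` in mmol g_CDW^-1 h^-1.
    """
    q = monod.mu_max / (monod.Y_XS * molar_mass) * 1000.0
    return DerivedRates(q_S=q, Y_XS_g=monod.Y_XS, molar_mass=molar_mass)
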