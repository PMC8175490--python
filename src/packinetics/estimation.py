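"""Parameter estimation and goodness-of-fit for the PAC biotransformation model.

The objective is the total residual sum of squares RSS_T: for each observed
profile, squared deviations between replicate-mean observations and the
simulated values at the same sampling times are summed over time points and
species, then over profiles.  Residuals are unweighted across species (mM and
% scales enter as-is).  The enzyme-stability, substrate and by-product
profiles always contribute; the PAC component RSS_P is included by default
and can be switched off to reproduce the originally reported five-component
(A, B, Q, R, E) form of the objective.

Estimation is a derivative-free multiplicative grid search: each constant is
perturbed by a fixed set of multipliers in a round-robin sweep and the best
candidate is kept, with a pattern (net-sweep-direction) acceleration move
after each sweep, sqrt-refinement of the multiplier grid when a sweep stalls,
and the study's convergence search criterion (CSC): the search phase stops
when one full sweep improves RSS_T by less than 1% (relative).  Because the
objective has strongly correlated, nearly flat directions -- V_p with K_ma,
and K_b with h -- a Powell-type direction-set stage (multiplicative line
searches along an evolving set of directions in log-parameter space; no
gradients) then follows the valley down to the minimum.  Search-phase and
refinement-stage cycles alternate until a full cycle no longer improves.

Fit statistics follow the degrees-of-freedom convention of the study:
per-profile DOF = (sampling times x 6 species) - 10 parameters = 38 for the
8-point design; MSE = RSS_T / DOF; combined RSS_T and combined MSE are the
sums of the per-profile values.  R^2 = 1 - RSS_T / TSS_T with TSS_T the sum,
over included species, of squared deviations of each species' observations
about that species' own mean.
"""

from __future__ import annotations

import logging
import math
import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize as scipy_minimize

from .kinetic_model import (
    PARAM_NAMES,
    SPECIES,
    ConfigurationError,
    KineticParameters,
    ReactionConditions,
    Trajectory,
    _euler_path,
    _time_grid,
    simulate,
)

logger = logging.getLogger(__name__)

N_PARAMS = len(PARAM_NAMES)

#: span (decades either side of the starting value) of the default bounds
DEFAULT_BOUND_DECADES = 3.0


def default_bounds(start: KineticParameters,
                   decades: float = DEFAULT_BOUND_DECADES
                   ) -> dict[str, tuple[float, float]]:
    """Default fitting bounds: ``decades`` decades around the start values.

    Rate and binding constants are positive scale parameters; allowing three
    orders of magnitude either side of the starting guess is generous for
    any physically plausible fit while keeping the search out of degenerate
    regions where saturation terms collapse.  The Hill coefficient is
    restricted to the physically sensible (1, 3], and the refolding lag to
    [0, 30] min.
    """
    factor = 10.0 ** decades
    bounds = {n: (getattr(start, n) / factor, getattr(start, n) * factor)
              for n in PARAM_NAMES}
    bounds["h"] = (1.0 + 1e-9, 3.0)
    bounds["t_lag"] = (0.0, 30.0)
    return bounds


class AlignmentError(ValueError):
    """Observed and simulated time grids do not match."""


@dataclass
class ExperimentalProfile:
    """Replicate-averaged observations of one biotransformation run.

    ``means`` and ``ses`` are (n_times, 6) arrays in :data:`SPECIES` order
    (P, A, B, Q, R, E); concentrations in mM, enzyme activity in %.
    """

    label: str
    conditions: ReactionConditions
    times: np.ndarray
    means: np.ndarray
    ses: np.ndarray | None = None
    n_replicates: int = 1

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        if self.ses is None:
            self.ses = np.zeros_like(self.means)
        self.ses = np.asarray(self.ses, dtype=float)
        if self.times.ndim != 1 or self.means.shape != (self.times.size, 6):
            raise ValueError("means must have shape (n_times, 6)")
        if self.ses.shape != self.means.shape:
            raise ValueError("ses must match the shape of means")
        if self.times[0] != 0 or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing and start at 0")
        if np.any(~np.isfinite(self.means)) or np.any(self.means < 0):
            raise ValueError("observation means must be finite and >= 0")
        if np.any(~np.isfinite(self.ses)) or np.any(self.ses < 0):
            raise ValueError("standard errors must be finite and >= 0")

    @property
    def n_observations(self) -> int:
        """Number of regressed data points: sampling times x 6 species."""
        return self.times.size * 6

    def species(self, name: str) -> np.ndarray:
        return self.means[:, SPECIES.index(name)]

    def perturbed(self, sign: int) -> "ExperimentalProfile":
        """Copy with observations shifted to mean + sign * SE (floored at 0)."""
        shifted = np.clip(self.means + sign * self.ses, 0.0, None)
        return ExperimentalProfile(label=self.label, conditions=self.conditions,
                                   times=self.times.copy(), means=shifted,
                                   ses=self.ses.copy(),
                                   n_replicates=self.n_replicates)


@dataclass(frozen=True)
class ObjectiveBreakdown:
    """Per-species residual sums of squares and their total RSS_T."""

    rss_P: float
    rss_A: float
    rss_B: float
    rss_Q: float
    rss_R: float
    rss_E: float
    include_P: bool = True

    @property
    def rss_T(self) -> float:
        total = self.rss_A + self.rss_B + self.rss_Q + self.rss_R + self.rss_E
        if self.include_P:
            total += self.rss_P
        return total

    def as_dict(self) -> dict:
        return {"RSS_P": self.rss_P, "RSS_A": self.rss_A, "RSS_B": self.rss_B,
                "RSS_Q": self.rss_Q, "RSS_R": self.rss_R, "RSS_E": self.rss_E,
                "RSS_T": self.rss_T, "include_P": self.include_P}


@dataclass(frozen=True)
class FitStatistics:
    """RSS_T with its degrees of freedom, mean square error and R^2."""

    rss_T: float
    dof: int
    mse: float
    r2: float | None = None
    tss_T: float | None = None

    def as_dict(self) -> dict:
        return {"RSS_T": self.rss_T, "DOF": self.dof, "MSE": self.mse,
                "R2": self.r2}


@dataclass
class SearchConfig:
    """Tunables of the grid-search estimator.

    ``csc`` is the convergence search criterion: a search-phase sweep that
    improves RSS_T by less than this relative fraction stops the phase.  The
    multiplier set, sweep cap and refinement stage are implementation choices
    (the original estimation procedure specifies only "grid search" and the
    1% CSC); all are configurable here.
    """

    csc: float = 0.01
    multipliers: tuple[float, ...] = (0.5, 0.8, 0.9, 0.95, 1.05, 1.1, 1.25, 2.0)
    max_sweeps: int = 200
    bounds: dict[str, tuple[float, float]] | None = None
    step: float = 0.6
    include_P: bool = True
    max_moves_per_parameter: int = 30
    refine: bool = True
    refine_max_iter: int = 300
    refine_ftol: float = 1e-14
    max_cycles: int = 8
    cycle_ftol: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.csc < 1:
            raise ConfigurationError(f"csc must be in (0, 1), got {self.csc!r}")
        if any(m <= 0 for m in self.multipliers):
            raise ConfigurationError("multipliers must be > 0")
        if self.max_sweeps < 1:
            raise ConfigurationError("max_sweeps must be >= 1")


@dataclass
class FitResult:
    """Outcome of :func:`grid_search_fit`."""

    params: KineticParameters
    start_params: KineticParameters
    trace: list[float]                      # RSS_T per sweep, non-increasing
    per_profile: dict[str, tuple[ObjectiveBreakdown, FitStatistics]]
    combined: FitStatistics
    n_evaluations: int
    param_errors: dict[str, float] | None = None

    @property
    def start_rss(self) -> float:
        return self.trace[0]

    @property
    def final_rss(self) -> float:
        return self.trace[-1]

    def as_dict(self) -> dict:
        d = {
            "parameters": self.params.to_dict(),
            "start_parameters": self.start_params.to_dict(),
            "parameter_errors": self.param_errors,
            "per_profile": {
                label: {"breakdown": br.as_dict(), "statistics": st.as_dict()}
                for label, (br, st) in self.per_profile.items()
            },
            "combined": self.combined.as_dict(),
            "search_trace": list(self.trace),
            "n_evaluations": self.n_evaluations,
        }
        return d


@dataclass(frozen=True)
class ValidationResult:
    """Fixed-parameter assessment of one held-out profile."""

    breakdown: ObjectiveBreakdown
    statistics: FitStatistics


# -- objective ---------------------------------------------------------------


def rss_breakdown(observed: ExperimentalProfile,
                  simulated: Trajectory | np.ndarray,
                  include_P: bool = True) -> ObjectiveBreakdown:
    """Per-species residual sums of squares between observation and model.

    ``simulated`` is either a :class:`Trajectory` (its sampled states are
    used; the sampling grid must match the observed times) or a plain
    (n_times, 6) array already aligned with ``observed.times``.
    """
    if isinstance(simulated, Trajectory):
        if (simulated.sample_times.size != observed.times.size
                or not np.allclose(simulated.sample_times, observed.times,
                                   atol=1e-6)):
            raise AlignmentError(
                "simulated sampling times do not match observed times")
        sim = simulated.sample_states
    else:
        sim = np.asarray(simulated, dtype=float)
        if sim.shape != observed.means.shape:
            raise AlignmentError(
                f"simulated array shape {sim.shape} does not match "
                f"observations {observed.means.shape}")
    sq = (observed.means - sim) ** 2
    per_species = sq.sum(axis=0)
    return ObjectiveBreakdown(rss_P=float(per_species[0]),
                              rss_A=float(per_species[1]),
                              rss_B=float(per_species[2]),
                              rss_Q=float(per_species[3]),
                              rss_R=float(per_species[4]),
                              rss_E=float(per_species[5]),
                              include_P=include_P)


def total_sum_of_squares(observed: ExperimentalProfile,
                         include_P: bool = True) -> float:
    """TSS_T: per-species total squares about each species' own mean, summed."""
    dev = observed.means - observed.means.mean(axis=0, keepdims=True)
    per_species = (dev ** 2).sum(axis=0)
    idx = range(6) if include_P else range(1, 6)
    return float(sum(per_species[i] for i in idx))


def fit_statistics_from_rss(rss_T: float, n_obs: int, n_params: int = N_PARAMS,
                            tss_T: float | None = None) -> FitStatistics:
    """MSE/DOF/R^2 from an RSS_T value under the study's DOF convention.

    DOF = n_obs - n_params must be positive (8 sampling times x 6 species
    and 10 parameters give DOF = 38).
    """
    dof = n_obs - n_params
    if dof <= 0:
        raise ConfigurationError(
            f"non-positive degrees of freedom: {n_obs} observations, "
            f"{n_params} parameters")
    r2 = None if tss_T is None else 1.0 - rss_T / tss_T
    return FitStatistics(rss_T=float(rss_T), dof=dof, mse=float(rss_T) / dof,
                         r2=r2, tss_T=tss_T)


def profile_fit_statistics(breakdown: ObjectiveBreakdown,
                           observed: ExperimentalProfile,
                           n_params: int = N_PARAMS) -> FitStatistics:
    """Fit statistics of one profile from its objective breakdown."""
    return fit_statistics_from_rss(
        breakdown.rss_T, observed.n_observations, n_params,
        tss_T=total_sum_of_squares(observed, include_P=breakdown.include_P))


def combine_fit_statistics(stats: list[FitStatistics]) -> FitStatistics:
    """Combined statistics over profiles: RSS, MSE and DOF are summed.

    Summing the per-profile MSEs (rather than dividing the pooled RSS by the
    pooled DOF) is the convention under which the per-profile and combined
    values printed for this model are mutually consistent.
    """
    if not stats:
        raise ValueError("no statistics to combine")
    rss = sum(s.rss_T for s in stats)
    mse = sum(s.mse for s in stats)
    dof = sum(s.dof for s in stats)
    tss = None
    if all(s.tss_T is not None for s in stats):
        tss = sum(s.tss_T for s in stats)
    r2 = None if tss is None else 1.0 - rss / tss
    return FitStatistics(rss_T=rss, dof=dof, mse=mse, r2=r2, tss_T=tss)


# -- fast objective evaluation ------------------------------------------------


class _Objective:
    """RSS_T(parameters) summed over profiles, via the compiled Euler kernel.

    A simulation that fails or produces non-finite values makes the candidate
    infinitely bad (it is rejected, with a logged warning) rather than
    raising.
    """

    def __init__(self, profiles: list[ExperimentalProfile], step: float,
                 include_P: bool):
        self.step = step
        self.include_P = include_P
        self.n_evaluations = 0
        self._profiles = []
        for p in profiles:
            sampling = np.round(p.times, 9)
            self._profiles.append((p, sampling,
                                   p.conditions.initial_state.species_array(),
                                   p.conditions.Ph_b, p.conditions.t_end))

    def simulated(self, pvec: np.ndarray, entry) -> np.ndarray:
        p, sampling, y0, ph_b, t_end = entry
        times = _time_grid(self.step, t_end, sampling, pvec[9])
        states, _ = _euler_path(times, y0, pvec, ph_b)
        return states[np.isin(times, sampling)]

    def __call__(self, pvec: np.ndarray) -> float:
        self.n_evaluations += 1
        total = 0.0
        try:
            with np.errstate(over="ignore", invalid="ignore"):
                for entry in self._profiles:
                    sim = self.simulated(pvec, entry)
                    sq = (entry[0].means - sim) ** 2
                    if not self.include_P:
                        sq = sq[:, 1:]
                    total += float(sq.sum())
        except (FloatingPointError, ValueError, ZeroDivisionError) as exc:
            logger.warning("candidate rejected: simulation failed (%s)", exc)
            return math.inf
        if not math.isfinite(total):
            logger.warning("candidate rejected: non-finite RSS_T")
            return math.inf
        return total


def _candidate_values(value: float, multipliers, bounds: tuple[float, float]):
    """Candidate parameter values ``value * m`` that respect the bounds.

    Out-of-bounds candidates are never evaluated.
    """
    lo, hi = bounds
    return [value * m for m in multipliers if lo <= value * m <= hi]


# -- search phases ------------------------------------------------------------


#: strongly correlated parameter pairs searched on a joint candidate grid:
#: the saturation constants trade off against their rate/shape partners
#: (V_p with K_ma in the Michaelis-Menten term, K_b with h in the Hill term),
#: and one-parameter-at-a-time moves can slide into a spurious basin along
#: the near-degenerate direction
_PAIRED = {"K_ma": "V_p", "h": "K_b"}


def _coordinate_phase(objective, cur: dict, best: float, config: SearchConfig,
                      trace: list[float]) -> tuple[dict, float]:
    """Multiplicative coordinate sweeps with pattern acceleration.

    The multiplier grid sqrt-shrinks towards 1 whenever a sweep stalls
    (improves by less than the CSC); the phase ends when a sweep on the
    refined grid improves by less than the CSC, per the study's convergence
    criterion.
    """
    mults = np.array(config.multipliers, dtype=float)
    names = list(PARAM_NAMES)

    def as_vec(d):
        return np.array([d[n] for n in names])

    for _ in range(config.max_sweeps):
        sweep_start = best
        prev = dict(cur)
        moved = False
        for name in names:
            partner = _PAIRED.get(name)
            for _ in range(config.max_moves_per_parameter):
                cands = []
                for c in _candidate_values(cur[name], mults,
                                           config.bounds[name]):
                    trial = dict(cur)
                    trial[name] = c
                    cands.append(trial)
                    if partner is not None:
                        for pc in _candidate_values(cur[partner], mults,
                                                    config.bounds[partner]):
                            joint = dict(trial)
                            joint[partner] = pc
                            cands.append(joint)
                if not cands:
                    break
                vals = [objective(as_vec(t)) for t in cands]
                i = int(np.argmin(vals))
                if vals[i] < best * (1.0 - 1e-12):
                    best = vals[i]
                    cur = cands[i]
                    moved = True
                else:
                    break
        # pattern move: greedy multiplicative line search along the net
        # direction of the sweep, to accelerate through correlated valleys
        logr = {}
        for n in names:
            if prev[n] > 0 and cur[n] > 0:
                logr[n] = math.log(cur[n] / prev[n])
            else:
                logr[n] = 0.0
        if any(abs(v) > 1e-15 for v in logr.values()):
            for _ in range(60):
                improved = False
                for alpha in (2.0, 1.0, 0.5):
                    trial = {}
                    for n in names:
                        lo, hi = config.bounds[n]
                        trial[n] = min(max(cur[n] * math.exp(alpha * logr[n]),
                                           lo), hi)
                    v = objective(as_vec(trial))
                    if v < best * (1.0 - 1e-12):
                        best = v
                        cur = trial
                        moved = True
                        improved = True
                        break
                if not improved:
                    break
        trace.append(best)
        refined = float(np.abs(mults - 1.0).max()) < 1e-3
        improvement = 0.0 if sweep_start == 0 else (sweep_start - best) / sweep_start
        if sweep_start == 0 or (refined and improvement < config.csc):
            break
        if not moved or improvement < config.csc:
            mults = np.sqrt(mults)
    return cur, best


def _refine_phase(objective, cur: dict, best: float,
                  config: SearchConfig) -> tuple[dict, float]:
    """Powell-type direction-set refinement in log-parameter space.

    Powell's conjugate-direction method (derivative-free line minimisations
    along an evolving direction set; no gradients) follows the correlated,
    nearly flat valleys of the objective down to the minimum.  t_lag is
    frozen here: it shifts the branch point of the integration grid, so the
    objective is not smooth in it, and line
    searches would stall on the resulting jitter; the coordinate phase
    already locates it on the multiplier grid (it is in any case identified
    only to within about one integration step).
    """
    names = [n for n in PARAM_NAMES if n != "t_lag"]
    t_lag = cur["t_lag"]

    def pack(d):
        return np.array([math.log(d[n]) for n in names])

    def unpack(z):
        d = {}
        for i, n in enumerate(names):
            lo, hi = config.bounds[n]
            d[n] = min(max(math.exp(min(max(z[i], -700.0), 700.0)), lo), hi)
        d["t_lag"] = t_lag
        return d

    def f(z):
        d = unpack(z)
        return objective(np.array([d[n] for n in PARAM_NAMES]))

    res = scipy_minimize(f, pack(cur), method="Powell",
                         options={"maxiter": config.refine_max_iter,
                                  "xtol": 1e-12,
                                  "ftol": config.refine_ftol})
    if res.fun < best:
        return unpack(res.x), float(res.fun)
    return cur, best


def grid_search_fit(profiles: list[ExperimentalProfile],
                    start: KineticParameters,
                    config: SearchConfig | None = None) -> FitResult:
    """Estimate the ten kinetic constants by RSS_T-minimising grid search.

    Each profile is simulated under its own reaction conditions; RSS_T sums
    the squared residuals over all profiles.  The returned RSS_T never
    exceeds the RSS_T at ``start``, and the trace recorded per sweep is
    non-increasing.
    """
    if not profiles:
        raise ValueError("at least one profile is required")
    config = config or SearchConfig()
    if config.bounds is None:
        config = dataclasses.replace(config, bounds=default_bounds(start))
    for n in PARAM_NAMES:
        lo, hi = config.bounds[n]
        v = getattr(start, n)
        if not lo <= v <= hi:
            raise ConfigurationError(
                f"start value {n}={v} violates bounds [{lo}, {hi}]")
    objective = _Objective(profiles, config.step, config.include_P)
    cur = start.to_dict()
    best = objective(start.to_array())
    trace = [best]

    for _ in range(config.max_cycles):
        cycle_start = best
        cur, best = _coordinate_phase(objective, cur, best, config, trace)
        if config.refine and best > 0:
            cur, best = _refine_phase(objective, cur, best, config)
            trace.append(best)
        if cycle_start <= 0:
            break
        if (cycle_start - best) / cycle_start < config.cycle_ftol:
            break

    fitted = KineticParameters.from_dict(cur)
    per_profile: dict[str, tuple[ObjectiveBreakdown, FitStatistics]] = {}
    stats_list = []
    for p in profiles:
        traj = simulate(fitted, p.conditions, step=config.step)
        br = rss_breakdown(p, traj, include_P=config.include_P)
        st = profile_fit_statistics(br, p)
        per_profile[p.label] = (br, st)
        stats_list.append(st)
    combined = combine_fit_statistics(stats_list)
    logger.info("grid search: RSS_T %.6g -> %.6g in %d evaluations",
                trace[0], best, objective.n_evaluations)
    return FitResult(params=fitted, start_params=start, trace=trace,
                     per_profile=per_profile, combined=combined,
                     n_evaluations=objective.n_evaluations)


# -- parameter errors and validation ------------------------------------------


def _refit_perturbed(fit: FitResult, profiles: list[ExperimentalProfile],
                     sign: int, config: SearchConfig) -> KineticParameters:
    """Refit against observations shifted to mean + sign * SE."""
    shifted = [p.perturbed(sign) for p in profiles]
    return grid_search_fit(shifted, fit.params, config).params


def parameter_errors(fit: FitResult, profiles: list[ExperimentalProfile],
                     config: SearchConfig | None = None) -> dict[str, float]:
    """Per-parameter errors from +/- standard-error refits.

    The observation set is perturbed to mean + SE and to mean - SE, the model
    is refitted from the fitted optimum against each, and each parameter's
    error is reported as half the absolute range between its two refitted
    values.  This transparent sensitivity scheme stands in for the original
    (externally described) point-wise error propagation and is labelled as
    such in reports.
    """
    config = config or SearchConfig()
    if all(np.all(p.ses == 0) for p in profiles):
        logger.info("all observation standard errors are zero; "
                    "parameter errors are zero")
        errors = {n: 0.0 for n in PARAM_NAMES}
    else:
        upper = _refit_perturbed(fit, profiles, +1, config)
        lower = _refit_perturbed(fit, profiles, -1, config)
        errors = {n: abs(getattr(upper, n) - getattr(lower, n)) / 2.0
                  for n in PARAM_NAMES}
    fit.param_errors = errors
    return errors


def validate(params: KineticParameters, profile: ExperimentalProfile,
             step: float = 0.6, include_P: bool = True) -> ValidationResult:
    """Assess fixed parameters against an independent (held-out) profile.

    Simulates under the profile's own conditions and returns the objective
    breakdown together with fit statistics; no parameter is updated.  The
    caller is responsible for the profile not having been used in fitting.
    """
    logger.info("validating parameters against held-out profile %r",
                profile.label)
    traj = simulate(params, profile.conditions, step=step)
    br = rss_breakdown(profile, traj, include_P=include_P)
    st = profile_fit_statistics(br, profile)
    return ValidationResult(breakdown=br, statistics=st)
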