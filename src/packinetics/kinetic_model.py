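"""Six-species kinetic model of batch (R)-phenylacetylcarbinol (PAC) biotransformation.

Partially purified pyruvate decarboxylase (PDC) carboligates benzaldehyde (B)
with pyruvate (A) to form PAC (P).  Direct decarboxylation of pyruvate gives
acetaldehyde (Q), two units of which condense into acetoin (R).  The driving
force of every reaction is the relative carboligase activity E (% of a
reference volumetric activity), which decays first-order -- with an extra
benzaldehyde-dependent term -- and is stabilised at a constant (zeroth-order)
rate by the phosphate buffer species, after an initial refolding lag during
which E is constant.

Rate equations (concentrations in mM, activity in %, time in min):

    dP/dt = V_p * [K_b B^h / (1 + K_b B^h)] * [A / (K_ma + A)] * E
    dA/dt = -dP/dt - dQ/dt - 2 dR/dt
    dB/dt = -dP/dt
    dQ/dt = V_q A E - V_r A Q E
    dR/dt = V_r A Q E
    dE/dt = 0                                   for t <  t_lag
          = -(k_d1 + k_d2 B) E + k_a Ph_b       for t >= t_lag

where Ph_b is the (constant) phosphate buffer concentration in mM.  Hill-type
binding of benzaldehyde (h ~ 2) reflects the dimeric operating form of PDC;
pyruvate binding is Michaelis-Menten.

Trajectories are produced by explicit (Euler-Cauchy) forward integration on a
fixed grid, the convention used when these parameters were originally
estimated; the default increment is 0.01 h = 0.6 min.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields, replace

import numpy as np

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f


logger = logging.getLogger(__name__)

#: names of the ten kinetic constants, in canonical (reporting) order
PARAM_NAMES = ("V_p", "K_b", "h", "K_ma", "V_q", "V_r", "k_d1", "k_d2", "k_a", "t_lag")

#: state-vector species order used throughout the package
SPECIES = ("P", "A", "B", "Q", "R", "E")

#: clamping beyond this magnitude (mM) suggests the Euler step is too coarse
CLAMP_WARN_MM = 0.1


class ConfigurationError(ValueError):
    """Inconsistent simulation or search configuration."""


@dataclass(frozen=True)
class KineticParameters:
    """The ten constants of the PAC biotransformation model.

    Attributes
    ----------
    V_p : float
        Overall PAC formation rate constant, mM min^-1 %^-1.
    K_b : float
        Intrinsic benzaldehyde binding constant, mM^(1-h).
    h : float
        Hill coefficient for benzaldehyde binding (dimensionless).
    K_ma : float
        Pyruvate affinity constant, mM.
    V_q : float
        Acetaldehyde formation rate constant, min^-1 %^-1.
    V_r : float
        Acetoin formation rate constant, min^-1 mM^-1 %^-1.
    k_d1 : float
        First-order background deactivation constant, min^-1.
    k_d2 : float
        First-order benzaldehyde-dependent deactivation constant,
        min^-1 mM^-1.
    k_a : float
        Zeroth-order activation rate constant due to phosphate buffer
        species, % min^-1 mM^-1.
    t_lag : float
        Initial refolding period of constant enzyme stability, min.

    All constants must be strictly positive except ``t_lag`` which may be
    zero.  The physically sensible range of ``h`` -- (1, 3] -- is enforced as
    a fitting bound, not here.
    """

    V_p: float
    K_b: float
    h: float
    K_ma: float
    V_q: float
    V_r: float
    k_d1: float
    k_d2: float
    k_a: float
    t_lag: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v):
                raise ValueError(f"parameter {f.name} must be finite, got {v!r}")
            if f.name == "t_lag":
                if v < 0:
                    raise ValueError(f"t_lag must be >= 0, got {v!r}")
            elif v <= 0:
                raise ValueError(f"parameter {f.name} must be > 0, got {v!r}")

    def to_array(self) -> np.ndarray:
        """Return the constants as a float array in :data:`PARAM_NAMES` order."""
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values) -> "KineticParameters":
        return cls(**dict(zip(PARAM_NAMES, map(float, values))))

    def to_dict(self) -> dict:
        return {n: getattr(self, n) for n in PARAM_NAMES}

    @classmethod
    def from_dict(cls, d: dict) -> "KineticParameters":
        missing = set(PARAM_NAMES) - set(d)
        if missing:
            raise ValueError(f"missing kinetic parameter(s): {sorted(missing)}")
        return cls(**{n: float(d[n]) for n in PARAM_NAMES})

    def replace(self, **changes) -> "KineticParameters":
        return replace(self, **changes)


@dataclass(frozen=True)
class SystemState:
    """Concentrations (mM) and relative enzyme activity (%) at time ``t`` (min)."""

    t: float
    P: float
    A: float
    B: float
    Q: float
    R: float
    E: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v):
                raise ValueError(f"state field {f.name} must be finite, got {v!r}")
            if v < 0:
                raise ValueError(f"state field {f.name} must be >= 0, got {v!r}")

    def species_array(self) -> np.ndarray:
        """State vector [P, A, B, Q, R, E] without the time coordinate."""
        return np.array([self.P, self.A, self.B, self.Q, self.R, self.E], dtype=float)


@dataclass(frozen=True)
class ReactionConditions:
    """Fixed conditions of one batch biotransformation run.

    ``Ph_b`` is the phosphate (Gomori) buffer concentration in mM; it enters
    the enzyme-stability equation through the activation term ``k_a * Ph_b``.
    """

    Ph_b: float
    initial_state: SystemState
    t_end: float = 210.0
    sampling_interval: float = 30.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.Ph_b) and self.Ph_b > 0):
            raise ConfigurationError(f"Ph_b must be > 0, got {self.Ph_b!r}")
        if not (math.isfinite(self.t_end) and self.t_end > 0):
            raise ConfigurationError(f"t_end must be > 0, got {self.t_end!r}")
        if self.sampling_interval <= 0:
            raise ConfigurationError("sampling_interval must be > 0")
        ratio = self.t_end / self.sampling_interval
        if abs(ratio - round(ratio)) > 1e-9:
            raise ConfigurationError(
                f"sampling_interval {self.sampling_interval} does not divide "
                f"t_end {self.t_end}"
            )
        if self.initial_state.t != 0:
            raise ConfigurationError("initial_state must be at t = 0")

    @property
    def sampling_times(self) -> np.ndarray:
        n = int(round(self.t_end / self.sampling_interval))
        return np.linspace(0.0, self.t_end, n + 1)


@dataclass
class Trajectory:
    """A simulated run: full Euler grid plus the subset at sampling times."""

    times: np.ndarray            # internal integration grid, shape (n,)
    states: np.ndarray           # shape (n, 6), columns in SPECIES order
    sample_times: np.ndarray     # shape (k,)
    sample_states: np.ndarray    # shape (k, 6)
    conditions: ReactionConditions | None = None
    max_clamp: float = field(default=0.0)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("trajectory times must be strictly increasing")

    def species(self, name: str, sampled: bool = True) -> np.ndarray:
        col = SPECIES.index(name)
        return (self.sample_states if sampled else self.states)[:, col]


# -- reference parameter sets -------------------------------------------------

#: literature-averaged starting values for the grid search (C. utilis PDC
#: carboligation constants; deactivation/activation constants from whole-cell
#: C. tropicalis TISTR 5350 in 20 mM - 1 M phosphate buffer)
REFERENCE_INITIAL = KineticParameters(
    V_p=1.55e-2, K_b=9.00e-5, h=1.98, K_ma=4.84, V_q=6.38e-6,
    V_r=9.88e-7, k_d1=8.89e-3, k_d2=3.30e-5, k_a=1.34e-5, t_lag=1.00,
)

#: optimised constants for partially purified C. tropicalis TISTR 5350 PDC
#: in 250 mM phosphate buffer (pH 7.0, 4 degC)
REFERENCE_OPTIMIZED = KineticParameters(
    V_p=6.71e-2, K_b=1.01e-4, h=1.94, K_ma=0.70, V_q=1.68e-5,
    V_r=6.06e-6, k_d1=5.99e-3, k_d2=1.33e-5, k_a=9.38e-6, t_lag=0.42,
)

#: apparent initial states of the three studied benzaldehyde/pyruvate pairs
#: (label -> SystemState); by-products start at zero, PAC at the 0.01 mM
#: apparent baseline
STUDY_INITIAL_STATES = {
    "30/36": SystemState(t=0.0, P=0.01, A=35.2, B=30.9, Q=0.0, R=0.0, E=89.4),
    "50/60": SystemState(t=0.0, P=0.01, A=59.1, B=50.4, Q=0.0, R=0.0, E=96.4),
    "100/120": SystemState(t=0.0, P=0.01, A=116.0, B=100.0, Q=0.0, R=0.0, E=114.0),
}

#: the buffer concentration (mM) of the model-calibration experiments
STUDY_BUFFER_MM = 250.0


def study_conditions(label: str, Ph_b: float = STUDY_BUFFER_MM,
                     t_end: float = 210.0,
                     sampling_interval: float = 30.0) -> ReactionConditions:
    """Reaction conditions for one of the canonical substrate pairs."""
    if label not in STUDY_INITIAL_STATES:
        raise KeyError(f"unknown condition pair {label!r}; "
                       f"choose from {sorted(STUDY_INITIAL_STATES)}")
    return ReactionConditions(Ph_b=Ph_b, initial_state=STUDY_INITIAL_STATES[label],
                              t_end=t_end, sampling_interval=sampling_interval)


# -- rate equations -----------------------------------------------------------

def _check_finite(**kwargs) -> None:
    for name, v in kwargs.items():
        if not math.isfinite(v):
            raise ValueError(f"{name} must be finite, got {v!r}")


def _hill_fraction(B: float, K_b: float, h: float) -> float:
    """Saturating Hill term K_b B^h / (1 + K_b B^h), robust to overflow."""
    if B <= 0:
        return 0.0
    try:
        x = K_b * B ** h
    except OverflowError:
        return 1.0
    if not math.isfinite(x):
        return 1.0
    return x / (1.0 + x)


def pac_rate(state: SystemState, params: KineticParameters) -> float:
    """PAC formation rate dP/dt in mM min^-1.

    Hill-type in benzaldehyde, Michaelis-Menten in pyruvate, first-order in
    relative enzyme activity.  Zero whenever A, B or E is zero.
    """
    _check_finite(A=state.A, B=state.B, E=state.E)
    return (params.V_p
            * _hill_fraction(state.B, params.K_b, params.h)
            * (state.A / (params.K_ma + state.A))
            * state.E)


def byproduct_rates(state: SystemState,
                    params: KineticParameters) -> tuple[float, float]:
    """Acetaldehyde and acetoin formation rates (dQ/dt, dR/dt) in mM min^-1.

    Acetaldehyde is produced from pyruvate (V_q A E) and consumed by the
    carboligation of two acetaldehyde units into acetoin (V_r A Q E).
    """
    _check_finite(A=state.A, Q=state.Q, E=state.E)
    ligation = params.V_r * state.A * state.Q * state.E
    dQ = params.V_q * state.A * state.E - ligation
    return dQ, ligation


def substrate_rates(dP: float, dQ: float, dR: float) -> tuple[float, float]:
    """Substrate consumption rates (dA/dt, dB/dt) from the formation rates.

    Stoichiometry: one pyruvate per PAC and per acetaldehyde, two per acetoin
    (via two acetaldehyde units); one benzaldehyde per PAC.
    """
    _check_finite(dP=dP, dQ=dQ, dR=dR)
    return -dP - dQ - 2.0 * dR, -dP


def enzyme_rate(state: SystemState, params: KineticParameters,
                conditions: ReactionConditions, t: float) -> float:
    """Rate of change of relative enzyme activity dE/dt in % min^-1.

    Exactly zero during the refolding lag (t < t_lag); afterwards first-order
    deactivation by background species and benzaldehyde, plus the
    zeroth-order phosphate-buffer activation term ``k_a * Ph_b``.
    """
    if t < 0:
        raise ValueError(f"t must be >= 0, got {t!r}")
    _check_finite(B=state.B, E=state.E)
    if t < params.t_lag:
        return 0.0
    return (-(params.k_d1 + params.k_d2 * state.B) * state.E
            + params.k_a * conditions.Ph_b)


def derivatives(t: float, state: SystemState, params: KineticParameters,
                conditions: ReactionConditions) -> np.ndarray:
    """Full state derivative [dP, dA, dB, dQ, dR, dE] at time ``t``."""
    dP = pac_rate(state, params)
    dQ, dR = byproduct_rates(state, params)
    dA, dB = substrate_rates(dP, dQ, dR)
    dE = enzyme_rate(state, params, conditions, t)
    return np.array([dP, dA, dB, dQ, dR, dE])


# -- Euler-Cauchy integration -------------------------------------------------

@njit(cache=False)
def _euler_path(times, y0, pv, ph_b):  # pragma: no cover - exercised via simulate
    """Explicit-Euler integration of the six rate equations on a fixed grid.

    ``pv`` holds the constants in PARAM_NAMES order.  Negative overshoots are
    clamped at zero; the largest clamped magnitude is returned so the caller
    can warn about too-coarse steps.
    """
    n = times.shape[0]
    out = np.empty((n, 6))
    for j in range(6):
        out[0, j] = y0[j]
    V_p, K_b, h, K_ma = pv[0], pv[1], pv[2], pv[3]
    V_q, V_r, k_d1, k_d2, k_a, t_lag = pv[4], pv[5], pv[6], pv[7], pv[8], pv[9]
    clamp = 0.0
    P, A, B, Q, R, E = y0[0], y0[1], y0[2], y0[3], y0[4], y0[5]
    for i in range(n - 1):
        t = times[i]
        dt = times[i + 1] - t
        if B > 0.0:
            x = K_b * B ** h
            if np.isfinite(x):
                fB = x / (1.0 + x)
            else:
                fB = 1.0
        else:
            fB = 0.0
        dP = V_p * fB * (A / (K_ma + A)) * E
        lig = V_r * A * Q * E
        dQ = V_q * A * E - lig
        dR = lig
        dA = -dP - dQ - 2.0 * dR
        dB = -dP
        if t < t_lag:
            dE = 0.0
        else:
            dE = -(k_d1 + k_d2 * B) * E + k_a * ph_b
        P += dt * dP
        A += dt * dA
        B += dt * dB
        Q += dt * dQ
        R += dt * dR
        E += dt * dE
        if P < 0.0:
            clamp = max(clamp, -P); P = 0.0
        if A < 0.0:
            clamp = max(clamp, -A); A = 0.0
        if B < 0.0:
            clamp = max(clamp, -B); B = 0.0
        if Q < 0.0:
            clamp = max(clamp, -Q); Q = 0.0
        if R < 0.0:
            clamp = max(clamp, -R); R = 0.0
        if E < 0.0:
            clamp = max(clamp, -E); E = 0.0
        out[i + 1, 0] = P
        out[i + 1, 1] = A
        out[i + 1, 2] = B
        out[i + 1, 3] = Q
        out[i + 1, 4] = R
        out[i + 1, 5] = E
    return out, clamp


def _time_grid(step: float, t_end: float, sampling_times: np.ndarray,
               t_lag: float) -> np.ndarray:
    """Integration grid: multiples of ``step`` plus sampling times and t_lag.

    Splitting the step containing ``t_lag`` makes the enzyme-stability branch
    switch exactly at the lag boundary.  Times are de-duplicated at 1e-9 min
    resolution so a t_lag (or sampling time) that coincides with a grid point
    is not counted twice.
    """
    base = np.arange(0.0, t_end + step / 2.0, step)
    extras = [sampling_times, np.array([t_end])]
    if 0.0 < t_lag < t_end:
        extras.append(np.array([t_lag]))
    grid = np.unique(np.round(np.concatenate([base] + extras), 9))
    return grid[(grid >= 0.0) & (grid <= np.round(t_end, 9))]


def simulate(params: KineticParameters, conditions: ReactionConditions,
             step: float = 0.6) -> Trajectory:
    """Integrate the model by explicit Euler-Cauchy stepping.

    Parameters
    ----------
    params, conditions
        Kinetic constants and run conditions (buffer, initial state, horizon).
    step : float
        Time increment in minutes.  The default 0.6 min equals the 0.01 h
        increment used when the reference constants were estimated.  Must be
        positive and no larger than the sampling interval.

    Returns
    -------
    Trajectory
        States on the full internal grid and at every sampling time.
    """
    if not (math.isfinite(step) and step > 0):
        raise ConfigurationError(f"step must be > 0, got {step!r}")
    if step > conditions.sampling_interval:
        raise ConfigurationError(
            f"step {step} exceeds sampling interval {conditions.sampling_interval}")
    sampling = np.round(conditions.sampling_times, 9)
    times = _time_grid(step, conditions.t_end, sampling, params.t_lag)
    if not np.isclose(times[-1], conditions.t_end, atol=1e-9):
        raise ConfigurationError(
            f"t_end {conditions.t_end} is not reachable on the time grid")
    y0 = conditions.initial_state.species_array()
    states, clamp = _euler_path(times, y0, params.to_array(), conditions.Ph_b)
    if clamp > 0.0:
        msg = (f"negative overshoot of {clamp:.3g} mM clamped to 0 "
               f"during Euler integration (step={step} min)")
        if clamp > CLAMP_WARN_MM:
            logger.warning("%s; consider a smaller step", msg)
        else:
            logger.debug(msg)
    mask = np.isin(times, sampling)
    return Trajectory(times=times, states=states, sample_times=times[mask],
                      sample_states=states[mask], conditions=conditions,
                      max_clamp=clamp)
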