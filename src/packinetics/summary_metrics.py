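"""Summary quantities of one PAC profile.

From a sampled time course these are: the maximum PAC concentration P_max
(mM) and its sampling time; the maximum PAC formation rate
r_Pmax = max_{t>0} P(t)/t (mM min^-1); the reaction time, defined as
P_max / r_Pmax rounded to the nearest multiple of the sampling interval; and
the molar yields Y_Pmax/B = P_max / (B0 - B(t_Pmax)) and
Y_Pmax/A = P_max / (A0 - A(t_Pmax)) on benzaldehyde and pyruvate consumed up
to the (earliest) time of maximum PAC.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .estimation import ExperimentalProfile
from .kinetic_model import SPECIES, Trajectory

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SummaryMetrics:
    """Headline quantities of a batch PAC biotransformation run."""

    P_max: float            # mM
    t_Pmax: float           # min, earliest sampling time attaining P_max
    r_Pmax: float           # mM min^-1
    reaction_time: float    # min, multiple of the sampling interval
    Y_Pmax_B: float         # molar yield on benzaldehyde, dimensionless
    Y_Pmax_A: float         # molar yield on pyruvate, dimensionless

    def as_dict(self) -> dict:
        return {"P_max_mM": self.P_max, "t_Pmax_min": self.t_Pmax,
                "r_Pmax_mM_per_min": self.r_Pmax,
                "reaction_time_min": self.reaction_time,
                "Y_Pmax_B": self.Y_Pmax_B, "Y_Pmax_A": self.Y_Pmax_A}


def reaction_time(P_max: float, r_Pmax: float, interval: float = 30.0) -> float:
    """Reaction time: P_max / r_Pmax rounded to the nearest multiple of
    ``interval`` (ties round up, so e.g. exactly half an interval rounds to
    the longer time)."""
    if r_Pmax <= 0:
        raise ValueError("reaction time is undefined for r_Pmax <= 0")
    if interval <= 0:
        raise ValueError("interval must be > 0")
    return math.floor(P_max / r_Pmax / interval + 0.5) * interval


def _extract(profile) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, float]:
    if isinstance(profile, Trajectory):
        times = profile.sample_times
        states = profile.sample_states
        interval = (profile.conditions.sampling_interval
                    if profile.conditions is not None
                    else float(np.diff(times).min()))
    elif isinstance(profile, ExperimentalProfile):
        times = profile.times
        states = profile.means
        interval = profile.conditions.sampling_interval
    else:
        raise TypeError("profile must be an ExperimentalProfile or Trajectory")
    iP, iA, iB = SPECIES.index("P"), SPECIES.index("A"), SPECIES.index("B")
    return times, states[:, iP], states[:, iA], states[:, iB], interval


def summarize_profile(profile: ExperimentalProfile | Trajectory) -> SummaryMetrics:
    """Compute :class:`SummaryMetrics` from a sampled profile.

    P_max is taken at the earliest sampling time attaining the maximum (the
    tie-break matters when the PAC level plateaus); yields use substrate
    consumption measured at that time.  Raises if a substrate shows no net
    consumption while PAC is nonzero (the yield would be undefined).
    """
    times, P, A, B, interval = _extract(profile)
    if times[0] != 0 or times.size < 3:
        raise ValueError("profile must start at t=0 and have >= 2 later "
                         "sampling times")
    i_max = int(np.argmax(P))          # earliest index attaining the maximum
    P_max = float(P[i_max])
    t_Pmax = float(times[i_max])
    with np.errstate(divide="ignore"):
        rates = P[1:] / times[1:]
    r_Pmax = float(rates.max())
    consumed_B = float(B[0] - B[i_max])
    consumed_A = float(A[0] - A[i_max])
    if P_max > 0 and (consumed_B <= 0 or consumed_A <= 0):
        raise ValueError(
            "molar yield undefined: nonzero P_max with no substrate consumption")
    Y_B = P_max / consumed_B if consumed_B > 0 else 0.0
    Y_A = P_max / consumed_A if consumed_A > 0 else 0.0
    for name, y in (("Y_Pmax/B", Y_B), ("Y_Pmax/A", Y_A)):
        if y > 1.0:
            logger.info("%s = %.3f exceeds 1 (analytical overshoot)", name, y)
    t_rxn = reaction_time(P_max, r_Pmax, interval) if r_Pmax > 0 else 0.0
    return SummaryMetrics(P_max=P_max, t_Pmax=t_Pmax, r_Pmax=r_Pmax,
                          reaction_time=t_rxn, Y_Pmax_B=Y_B, Y_Pmax_A=Y_A)
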