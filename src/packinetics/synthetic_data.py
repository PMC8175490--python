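"""Synthetic experimental datasets with the structure of the batch PAC study.

The study design these generators emulate: three initial
benzaldehyde/pyruvate pairs (30/36, 50/60, 100/120 mM; pyruvate:benzaldehyde
molar ratio 1.2), phosphate buffer at 20/250/500/1000 mM (model calibration
at 250 mM), 8 sampling times (0-210 min every 30 min), quintuplicate
replicates with small standard errors, initial relative enzyme activity in
the 89-114% range, and by-products at or near the detection limit.

Replicate observations are drawn as truth + Gaussian noise with
sd = max(CV * truth, floor) and optional truncation at zero; stored profiles
carry replicate means and standard errors, reproducible from the master
seed (one fixed-offset child seed per profile).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .estimation import ExperimentalProfile
from .kinetic_model import (
    STUDY_BUFFER_MM,
    STUDY_INITIAL_STATES,
    KineticParameters,
    ReactionConditions,
    SystemState,
    simulate,
)

logger = logging.getLogger(__name__)

#: species columns holding concentrations (mM); the last column is E (%)
_CONC_COLS = slice(0, 5)

#: fixed per-profile child-seed offset (a prime, to avoid accidental overlap
#: with nearby master seeds)
_SEED_OFFSET = 7919


@dataclass(frozen=True)
class NoiseModel:
    """Replicate noise: sd = max(cv * truth, floor), Gaussian, truncated at 0.

    Error bars in the emulated study were small; the 2% coefficient of
    variation with 0.1 mM / 0.5% absolute floors is an assumption, not a
    measured value, and is configurable.
    """

    cv: float = 0.02
    floor_mM: float = 0.1
    floor_pct: float = 0.5
    replicates: int = 5
    truncate: bool = True

    def __post_init__(self) -> None:
        if self.cv < 0 or self.floor_mM < 0 or self.floor_pct < 0:
            raise ValueError("cv and noise floors must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    def sd(self, truth: np.ndarray) -> np.ndarray:
        """Per-observation standard deviation for a (n_times, 6) truth array."""
        floors = np.array([self.floor_mM] * 5 + [self.floor_pct])
        return np.maximum(self.cv * np.abs(truth), floors)


@dataclass(frozen=True)
class StudyDesign:
    """Condition structure of the emulated batch biotransformation study."""

    pairs: tuple[tuple[float, float], ...] = ((30.0, 36.0), (50.0, 60.0),
                                              (100.0, 120.0))
    buffers_mM: tuple[float, ...] = (20.0, 250.0, 500.0, 1000.0)
    fit_buffer_mM: float = STUDY_BUFFER_MM
    enzyme_activity_range: tuple[float, float] = (89.0, 114.0)
    t_end: float = 210.0
    sampling_interval: float = 30.0
    master_seed: int = 0

    def __post_init__(self) -> None:
        for b, a in self.pairs:
            if b <= 0 or a <= 0:
                raise ValueError("substrate concentrations must be > 0")
        if any(b <= 0 for b in self.buffers_mM):
            raise ValueError("buffer concentrations must be > 0")

    @staticmethod
    def pair_label(pair: tuple[float, float]) -> str:
        return f"{pair[0]:g}/{pair[1]:g}"

    def conditions_for_pair(self, pair: tuple[float, float],
                            buffer_mM: float | None = None,
                            rng: np.random.Generator | None = None,
                            ) -> ReactionConditions:
        """Reaction conditions for one substrate pair.

        The three canonical pairs use the study's apparent initial states;
        other pairs use the nominal concentrations with an initial enzyme
        activity drawn uniformly from the design range (midpoint when no
        ``rng`` is given) and the 0.01 mM apparent PAC baseline.
        """
        buffer_mM = self.fit_buffer_mM if buffer_mM is None else buffer_mM
        label = self.pair_label(pair)
        if label in STUDY_INITIAL_STATES:
            init = STUDY_INITIAL_STATES[label]
        else:
            lo, hi = self.enzyme_activity_range
            E0 = float(rng.uniform(lo, hi)) if rng is not None else (lo + hi) / 2
            init = SystemState(t=0.0, P=0.01, A=pair[1], B=pair[0],
                               Q=0.0, R=0.0, E=E0)
        return ReactionConditions(Ph_b=buffer_mM, initial_state=init,
                                  t_end=self.t_end,
                                  sampling_interval=self.sampling_interval)


def generate_noiseless_profile(params: KineticParameters,
                               conditions: ReactionConditions,
                               label: str = "",
                               step: float = 0.6) -> ExperimentalProfile:
    """Ground-truth profile: the sampled simulation, zero standard errors."""
    traj = simulate(params, conditions, step=step)
    return ExperimentalProfile(label=label, conditions=conditions,
                               times=traj.sample_times.copy(),
                               means=traj.sample_states.copy(),
                               ses=np.zeros_like(traj.sample_states),
                               n_replicates=1)


def generate_noisy_dataset(params: KineticParameters,
                           design: StudyDesign | None = None,
                           noise: NoiseModel | None = None,
                           seed: int | None = None,
                           buffer_mM: float | None = None,
                           zero_byproducts: bool = True,
                           step: float = 0.6) -> list[ExperimentalProfile]:
    """One noisy replicate-averaged profile per condition pair of the design.

    Parameters
    ----------
    params, design, noise
        Generating truth, condition structure and noise model.
    seed
        Master seed; per-profile child seeds are derived by fixed offsets, so
        the dataset is a pure function of (params, design, noise, seed).
    buffer_mM
        Phosphate buffer for all profiles (design's calibration buffer when
        omitted).
    zero_byproducts
        Emulate the by-product detection limit by recording acetaldehyde and
        acetoin observations as 0 (the default, mirroring the emulated
        study, where neither by-product was detected).
    """
    design = design or StudyDesign()
    noise = noise or NoiseModel()
    master = design.master_seed if seed is None else seed
    profiles = []
    for i, pair in enumerate(design.pairs):
        child = (master + _SEED_OFFSET * (i + 1)) % (2 ** 31)
        rng = np.random.default_rng(child)
        conditions = design.conditions_for_pair(pair, buffer_mM=buffer_mM,
                                                rng=rng)
        traj = simulate(params, conditions, step=step)
        truth = traj.sample_states
        sd = noise.sd(truth)
        reps = truth[None, :, :] + rng.normal(size=(noise.replicates,)
                                              + truth.shape) * sd[None, :, :]
        if noise.truncate:
            reps = np.clip(reps, 0.0, None)
        means = reps.mean(axis=0)
        if noise.replicates > 1:
            ses = reps.std(axis=0, ddof=1) / np.sqrt(noise.replicates)
        else:
            ses = np.zeros_like(means)
        if zero_byproducts:
            means[:, 3:5] = 0.0
            ses[:, 3:5] = 0.0
        profiles.append(ExperimentalProfile(
            label=design.pair_label(pair), conditions=conditions,
            times=traj.sample_times.copy(), means=means, ses=ses,
            n_replicates=noise.replicates))
    logger.info("generated %d noisy profiles from master seed %d",
                len(profiles), master)
    return profiles
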