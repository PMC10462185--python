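"""Synthetic two-group longitudinal tumor-growth generator.

Produces realistic study fixtures: per animal, log tumor volume grows
linearly in time around an animal-specific intercept, with a stationary
AR(1) residual process across the measurement grid supplying the strong
positive adjacent-time-point correlation typical of xenograft growth data.
Volumes are exponentiated back to the raw mm^3 scale.

This is a fixture engine for exercising the tests, not a mechanistic
growth-kinetics model: it has no Gompertz deceleration, dropout, or
detection limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import StudyTable, study_from_records
from .exceptions import HomtestError

#: a typical twice-to-thrice-weekly caliper schedule (days)
DEFAULT_TIMES = (3.0, 5.0, 7.0, 12.0, 14.0, 17.0, 19.0, 21.0, 24.0)


@dataclass
class GrowthSimParams:
    """Parameters of the log-linear AR(1) growth generator.

    Defaults give two arms of 10 animals starting near 4 mm^3 on day 3,
    group 0 growing ~20% per day on the log scale and the treated arm
    growing slightly slower, with AR(1) phi = 0.95 and residual SD 0.3 so
    that adjacent-time within-group correlations land in the high range
    (roughly 0.7-0.99) seen in real growth curves.
    """

    n_per_group: int = 10
    times: tuple[float, ...] = DEFAULT_TIMES
    log_intercept_mean: float = float(np.log(4.0)) - 3 * 0.20  # ~4 mm^3 at day 3
    log_intercept_sd: float = 0.10
    growth_rate: float = 0.20       # log-volume slope per day, group 0
    treatment_effect: float = -0.03  # slope difference, group 1 minus group 0
    ar1_phi: float = 0.95
    noise_sd: float = 0.30          # stationary SD of the AR(1) residual (log scale)
    seed: int = 0
    group_labels: dict[int, str] = field(default_factory=lambda: {0: "control", 1: "treated"})

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        if times.size < 2 or np.any(np.diff(times) <= 0):
            raise HomtestError("times must be strictly increasing with length >= 2")
        if self.noise_sd < 0:
            raise HomtestError("noise_sd must be >= 0")
        if not abs(self.ar1_phi) < 1:
            raise HomtestError("ar1_phi must satisfy |phi| < 1")
        if self.n_per_group < 1:
            raise HomtestError("n_per_group must be >= 1")


def _ar1_path(rng: np.random.Generator, k: int, phi: float, sd: float) -> np.ndarray:
    """Stationary AR(1) residuals over k grid points with marginal SD sd."""
    e = np.empty(k)
    e[0] = sd * rng.standard_normal()
    innov_sd = sd * np.sqrt(1.0 - phi**2)
    for j in range(1, k):
        e[j] = phi * e[j - 1] + innov_sd * rng.standard_normal()
    return e


def generate_growth_study(params: GrowthSimParams) -> StudyTable:
    """Generate a StudyTable; bit-identical under a fixed seed."""
    rng = np.random.default_rng(np.random.SeedSequence(params.seed))
    times = np.asarray(params.times, dtype=float)
    records = []
    for g in (0, 1):
        slope = params.growth_rate + (params.treatment_effect if g == 1 else 0.0)
        for i in range(params.n_per_group):
            animal = f"g{g}_a{i:03d}"
            intercept = params.log_intercept_mean + params.log_intercept_sd * rng.standard_normal()
            resid = _ar1_path(rng, times.size, params.ar1_phi, params.noise_sd)
            logvol = intercept + slope * times + resid
            for t, lv in zip(times, logvol):
                records.append((animal, g, float(t), float(np.exp(lv))))
    return study_from_records(records, group_labels=params.group_labels)
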