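"""Monte-Carlo power and type-I-error engine.

Simulates the interaction regression model at a single time point,

    y = b0 + b1*x + b2*y_prev + b3*x*y_prev + eps,  eps ~ N(0, sigma^2),
    y_prev ~ N(0, 1) i.i.d. per animal,

and estimates rejection rates of the homologous test (df n - 4) and the
pooled two-sample t-test (df n - 2) over a grid of (sigma, b1, b2, b3).

The two tests answer subtly different questions, and the engine calibrates
them accordingly.  The homologous test compares conditional means given each
group's observed covariate mean; with ``center_covariate`` (the default) the
covariate is mean-centered within each group before the homologous responses
are generated, pinning both conditional means to the same covariate value so
that only the treatment effect b1 separates them.  This makes the homologous
power exactly invariant to b2 and b3 and exactly the noncentral-t
probability that :func:`analytic_power` evaluates; without it the rejection
rate would also pick up replicate-to-replicate covariate-mean imbalance and
run higher.  The t-test, by contrast, addresses the marginal mean difference
and is evaluated on responses generated from the *uncentered* covariate
(sharing the same noise draws), whose group variance is inflated to
sigma^2 + b2^2 (group 0) and sigma^2 + (b2+b3)^2 (group 1) — the classical
cross-sectional analysis the homologous test is benchmarked against.
Centering the t-test's data instead would remove the covariate's
contribution to the mean difference while leaving it in the pooled variance,
making the t-test spuriously conservative.

Per-grid-cell random streams are derived from the root seed and the cell's
parameter values, so results are independent of grid traversal order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import core
from .classical import two_sample_t
from .data import TimepointPairData
from .exceptions import HomtestError, NoClosedFormError, SingularDesignError


@dataclass
class SimConfig:
    """Configuration of one simulation cell.

    ``n_per_group`` defaults to 7 animals per arm: with the covariate
    centered, the pooled-t power at (sigma, b1) with b2 = b3 = 0 is a
    noncentral t with df 2m - 2 and noncentrality b1 / (sigma * sqrt(2/m)),
    and m = 7 places those powers in the mid-0.1 to high-0.9 range the
    engine's reference tables span.
    """

    sigma: float = 0.4
    beta0: float = 0.0
    beta1: float = 0.0
    beta2: float = 0.0
    beta3: float = 0.0
    n_per_group: int = 7
    reps: int = 1000
    alpha: float = 0.05
    alternative: str = "two-sided"
    seed: int = 0
    center_covariate: bool = True

    def __post_init__(self):
        if not self.sigma > 0:
            raise HomtestError(f"sigma must be > 0, got {self.sigma}")
        if self.reps < 1:
            raise HomtestError(f"reps must be >= 1, got {self.reps}")
        if not 0 < self.alpha < 1:
            raise HomtestError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.n_per_group < 3:
            raise HomtestError(f"n_per_group must be >= 3 (n > 4), got {self.n_per_group}")


@dataclass
class PowerResult:
    config: SimConfig
    power_homologous: float
    power_ttest: float
    rejections_homologous: int
    rejections_ttest: int
    degenerate_replicates: int = 0

    @property
    def mc_se_homologous(self) -> float:
        p = self.power_homologous
        return float(np.sqrt(p * (1 - p) / self.config.reps))

    @property
    def mc_se_ttest(self) -> float:
        p = self.power_ttest
        return float(np.sqrt(p * (1 - p) / self.config.reps))

    def to_record(self) -> dict:
        c = self.config
        return {
            "sigma": c.sigma, "beta1": c.beta1, "beta2": c.beta2, "beta3": c.beta3,
            "power_hom": self.power_homologous, "power_ttest": self.power_ttest,
            "mc_se_hom": self.mc_se_homologous, "mc_se_ttest": self.mc_se_ttest,
            "reps": c.reps, "n_per_group": c.n_per_group, "seed": c.seed,
        }


@dataclass
class PowerGridResult:
    results: list[PowerResult] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.to_record() for r in self.results])

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _draw_views(
    config: SimConfig, rng: np.random.Generator
) -> tuple[TimepointPairData, np.ndarray, np.ndarray]:
    """One replicate: the calibrated pair plus the marginal t-test responses.

    A single covariate draw and a single error draw feed both views.  The
    returned :class:`TimepointPairData` uses the (optionally) within-group
    centered covariate for the homologous test; the extra pair of response
    vectors uses the raw covariate and is what the comparator t-test sees.
    With ``center_covariate=False`` the views coincide.
    """
    m = config.n_per_group
    yp0 = rng.standard_normal(m)
    yp1 = rng.standard_normal(m)
    eps0 = rng.standard_normal(m) * config.sigma
    eps1 = rng.standard_normal(m) * config.sigma

    def responses(p0: np.ndarray, p1: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return (
            config.beta0 + config.beta2 * p0 + eps0,
            config.beta0 + config.beta1 + (config.beta2 + config.beta3) * p1 + eps1,
        )

    if config.center_covariate:
        yp0c = yp0 - yp0.mean()
        yp1c = yp1 - yp1.mean()
    else:
        yp0c, yp1c = yp0, yp1
    yc0, yc1 = responses(yp0c, yp1c)
    pair = TimepointPairData(
        time_prev=0.0, time_curr=1.0,
        y_prev_0=yp0c, y_curr_0=yc0, y_prev_1=yp1c, y_curr_1=yc1,
    )
    if config.center_covariate:
        yt0, yt1 = responses(yp0, yp1)
    else:
        yt0, yt1 = yc0, yc1
    return pair, yt0, yt1


def simulate_replicate(config: SimConfig, rng: np.random.Generator) -> TimepointPairData:
    """Draw one replicate of the single-time-point model.

    The covariate (previous-time volume) is standard normal per animal;
    with ``center_covariate`` it is mean-centered within each group before
    the response is generated.  Responses add i.i.d. N(0, sigma^2) noise to
    the regression mean.
    """
    pair, _, _ = _draw_views(config, rng)
    return pair


def estimate_power(config: SimConfig) -> PowerResult:
    """Monte-Carlo rejection rates of both tests at level alpha.

    The homologous test runs on the calibrated view of each replicate, the
    pooled t-test on the marginal view (see module docstring).  A replicate
    whose design is numerically singular is redrawn once; if still singular
    it counts as a non-rejection (never expected for a continuous
    covariate).
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    rej_hom = 0
    rej_t = 0
    degenerate = 0
    for _ in range(config.reps):
        pair, yt0, yt1 = _draw_views(config, rng)
        try:
            res = core.homologous_test(
                pair, alternative=config.alternative, with_group_estimates=False
            )
        except SingularDesignError:
            pair, yt0, yt1 = _draw_views(config, rng)
            try:
                res = core.homologous_test(
                    pair, alternative=config.alternative, with_group_estimates=False
                )
            except SingularDesignError:
                degenerate += 1
                res = None
        if res is not None and res.p_value <= config.alpha:
            rej_hom += 1
        tt = two_sample_t(yt0, yt1, variant="pooled", alternative=config.alternative)
        if tt.p_value <= config.alpha:
            rej_t += 1
    return PowerResult(
        config=config,
        power_homologous=rej_hom / config.reps,
        power_ttest=rej_t / config.reps,
        rejections_homologous=rej_hom,
        rejections_ttest=rej_t,
        degenerate_replicates=degenerate,
    )


def _cell_seed(base_seed: int, sigma: float, b1: float, b2: float, b3: float) -> np.random.SeedSequence:
    """Deterministic per-cell seed derived from the parameter values.

    Hashing the float bit patterns (not grid positions) makes every cell's
    stream invariant to the order grids are supplied in.
    """
    words = [int(np.float64(v).view(np.uint64)) & 0xFFFFFFFF for v in (sigma, b1, b2, b3)]
    words += [int(np.float64(v).view(np.uint64)) >> 32 for v in (sigma, b1, b2, b3)]
    return np.random.SeedSequence(entropy=int(base_seed), spawn_key=tuple(words))


def run_grid(
    base: SimConfig,
    sigmas: list[float],
    beta1s: list[float],
    beta2s: list[float],
    beta3s: list[float],
) -> PowerGridResult:
    """Evaluate the cartesian (sigma, b1, b2, b3) grid.

    Output rows are sorted canonically (sigma, b1, b2, b3 ascending) and
    each cell gets an independent seeded sub-stream, so permuting the input
    lists changes nothing.
    """
    if not (sigmas and beta1s and beta2s and beta3s):
        raise HomtestError("all four grids must be nonempty")
    cells = sorted(set(product(map(float, sigmas), map(float, beta1s),
                               map(float, beta2s), map(float, beta3s))))
    results = []
    for sigma, b1, b2, b3 in cells:
        ss = _cell_seed(base.seed, sigma, b1, b2, b3)
        cell_cfg = replace(
            base, sigma=sigma, beta1=b1, beta2=b2, beta3=b3,
            seed=int(ss.generate_state(1, dtype=np.uint32)[0]) % (2**31),
        )
        results.append(estimate_power(cell_cfg))
    return PowerGridResult(results=results)


#: the reference-table grid: sigma x b1 x b2 x b3
DEFAULT_GRID = {
    "sigmas": [0.4, 0.7, 1.0],
    "beta1s": [0.0, 0.5, 1.0],
    "beta2s": [0.0, 0.5, 1.0],
    "beta3s": [0.0, 0.5, 1.0],
}


def analytic_power(config: SimConfig, test: str = "homologous") -> float:
    """Closed-form power oracle for the centered-covariate design.

    homologous
        Exact: with the covariate centered within groups, the contrast is
        (0, 1, 0, 0) and the leverage identity gives Var(D_hat) =
        sigma^2 * 2/m, so D_hat / s is noncentral t with df 2m - 4 and
        noncentrality b1 / (sigma * sqrt(2/m)) for any b2, b3.
    ttest
        On the marginal view the group variances are sigma^2 + b2^2 and
        sigma^2 + (b2 + b3)^2.  With b3 = 0 they are equal and the pooled t
        is an exact noncentral t with df 2m - 2 and noncentrality
        b1 / sqrt((sigma^2 + b2^2) * 2/m).  With b3 != 0 an
        unequal-variance normal approximation is returned (two-sided only)
        and is approximate.

    Raises :class:`NoClosedFormError` for unsupported combinations rather
    than silently approximating.
    """
    m = config.n_per_group
    alpha = config.alpha
    if test == "homologous":
        if not config.center_covariate:
            raise NoClosedFormError(
                "homologous closed form requires center_covariate=True"
            )
        df = 2 * m - 4
        ncp = config.beta1 / (config.sigma * np.sqrt(2.0 / m))
        return _nct_power(ncp, df, alpha, config.alternative)
    if test == "ttest":
        if config.beta3 == 0:
            df = 2 * m - 2
            sd = np.sqrt(config.sigma**2 + config.beta2**2)
            ncp = config.beta1 / (sd * np.sqrt(2.0 / m))
            return _nct_power(ncp, df, alpha, config.alternative)
        if config.alternative != "two-sided":
            raise NoClosedFormError(
                "t-test power with nonzero beta3 is only approximated for "
                "the two-sided alternative"
            )
        v0 = config.sigma**2 + config.beta2**2
        v1 = config.sigma**2 + (config.beta2 + config.beta3) ** 2
        se = np.sqrt((v0 + v1) / m)
        zcrit = stats.norm.ppf(1 - alpha / 2)
        shift = config.beta1 / se
        return float(stats.norm.sf(zcrit - shift) + stats.norm.cdf(-zcrit - shift))
    raise HomtestError(f"unknown test {test!r}")


def _nct_power(ncp: float, df: int, alpha: float, alternative: str) -> float:
    if alternative == "two-sided":
        tcrit = stats.t.ppf(1 - alpha / 2, df)
        return float(stats.nct.sf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp))
    tcrit = stats.t.ppf(1 - alpha, df)
    if alternative == "greater":
        return float(stats.nct.sf(tcrit, df, ncp))
    if alternative == "less":
        return float(stats.nct.cdf(-tcrit, df, ncp))
    raise HomtestError(f"unknown alternative {alternative!r}")
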