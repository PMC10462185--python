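"""The homologous hypothesis test.

A cross-sectional two-group mean comparison at time point j that conditions
each group's mean on the group's observed mean at the preceding time point
j-1.  Operationally it is an interaction ANCOVA: fit

    y_j = b0 + b1*x + b2*y_{j-1} + b3*x*y_{j-1} + eps,   eps ~ N(0, sigma_j^2)

jointly over both groups (x the 0/1 treatment indicator), then test the
contrast

    D_j = z . beta,   z = (0, 1, ybar_{1,j-1} - ybar_{0,j-1}, ybar_{1,j-1}),

which evaluates each group's fitted conditional mean at that group's own
covariate mean.  The point estimate is algebraically identical to the raw
difference of group means at time j, but its variance shrinks by roughly
(1 - rho^2) when the adjacent-time correlation rho is strong, because the
covariate absorbs between-animal variation.  Under the model, D_hat / s_Dhat
follows a central t with n - 4 degrees of freedom at the null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

from .data import TimepointPairData
from .exceptions import InsufficientDataError, SingularDesignError

_DESIGN_COLUMNS = ("intercept", "group", "y_prev", "group:y_prev")
#: relative singular-value threshold below which a design column is collinear
RANK_RTOL = 1e-12

ALTERNATIVES = ("two-sided", "greater", "less")


@dataclass
class RegressionFit:
    """OLS fit of the four-parameter interaction model at one time point.

    ``beta_hat`` is (b0, b1, b2, b3); ``sse`` the residual sum of squares;
    ``mse = sse / df`` with ``df = n - 4``.
    """

    beta_hat: np.ndarray
    xtx_inv: np.ndarray
    sse: float
    df: int
    n0: int
    n1: int

    @property
    def mse(self) -> float:
        return self.sse / self.df

    @property
    def n(self) -> int:
        return self.n0 + self.n1


@dataclass
class ContrastVector:
    """The 1x4 contrast evaluating the between-group difference of
    conditional means, each group at its own covariate mean."""

    z: np.ndarray
    ybar_prev_0: float
    ybar_prev_1: float


@dataclass
class GroupConditional:
    """Per-group conditional-mean estimate from the within-group simple
    regression of y_curr on y_prev.

    ``estimate`` equals the group sample mean of y_curr (the regression line
    evaluated at the covariate mean passes through the mean point);
    ``se = sqrt(mse / n_g)`` with ``mse`` on n_g - 2 denominator; ``rho`` is
    the within-group Pearson correlation (NaN when y_prev is constant, in
    which case ``degenerate`` is set).
    """

    estimate: float
    se: float
    rho: float
    mse: float
    n: int
    degenerate: bool = False


@dataclass
class HomologousResult:
    """Result of the homologous test at one time point.

    ``d_hat`` is group 1 minus group 0 in volume units; the p-value comes
    from the central t distribution with ``df = n - 4`` degrees of freedom.
    ``group_estimates`` carries the descriptive per-group conditional
    estimates and SEs; ``correlations`` the per-group adjacent-time Pearson
    correlations.
    """

    d_hat: float
    se: float
    t_stat: float
    df: int
    p_value: float
    alternative: str
    n0: int
    n1: int
    group_estimates: dict[int, GroupConditional]
    correlations: tuple[float, float]
    time_prev: float | None = None
    time_curr: float | None = None

    def to_record(self) -> dict:
        """Flatten to a serializable record (CSV row / JSON object)."""
        return {
            "time_prev": self.time_prev,
            "time_curr": self.time_curr,
            "n0": self.n0,
            "n1": self.n1,
            "d_hat": self.d_hat,
            "se": self.se,
            "t": self.t_stat,
            "df": self.df,
            "p": self.p_value,
            "rho0": self.correlations[0],
            "rho1": self.correlations[1],
            "method": "homologous",
        }


def build_design(pair: TimepointPairData) -> tuple[np.ndarray, np.ndarray]:
    """Stack the two groups into the response vector and n x 4 design matrix.

    Rows are [1, x, y_prev, x * y_prev], group-0 animals first; the
    interaction column is zero on every group-0 row.
    """
    n = pair.n
    if n < 5:
        raise InsufficientDataError(
            f"n = {n} animals: need n >= 5 for df = n - 4 >= 1"
        )
    if pair.n0 == 0 or pair.n1 == 0:
        raise InsufficientDataError("both groups must be nonempty")
    y = np.concatenate([pair.y_curr_0, pair.y_curr_1])
    x = np.concatenate([np.zeros(pair.n0), np.ones(pair.n1)])
    yprev = np.concatenate([pair.y_prev_0, pair.y_prev_1])
    design = np.column_stack([np.ones(n), x, yprev, x * yprev])
    return y, design


def fit_ols(response: np.ndarray, design: np.ndarray, n0: int | None = None, n1: int | None = None) -> RegressionFit:
    """Least-squares fit of the interaction model via SVD.

    SSE is computed as ``y'y - beta'X'y``, clipped at zero against roundoff.
    A rank-deficient design raises :class:`SingularDesignError` naming the
    first column implicated (its largest loading in the null space).
    """
    response = np.asarray(response, dtype=float)
    design = np.asarray(design, dtype=float)
    n, p = design.shape
    u, s, vt = np.linalg.svd(design, full_matrices=False)
    if s[0] == 0 or s[-1] < RANK_RTOL * s[0]:
        # aggregate null-space loadings; prefer naming a covariate column,
        # since a constant covariate also drags the intercept/group columns in
        small = s < RANK_RTOL * max(s[0], 1.0)
        loadings = np.abs(vt[small]).sum(axis=0)
        if p == 4 and loadings[2:].max() > 0.1:
            column = _DESIGN_COLUMNS[2 + int(np.argmax(loadings[2:]))]
        elif p == 4:
            column = _DESIGN_COLUMNS[int(np.argmax(loadings))]
        else:
            column = f"column {int(np.argmax(loadings))}"
        raise SingularDesignError(
            f"rank-deficient design (collinearity involving {column!r}); "
            "within-group-constant covariates are a common cause",
            column=column,
        )
    s_inv = 1.0 / s
    beta = vt.T @ (s_inv * (u.T @ response))
    xtx_inv = (vt.T * s_inv**2) @ vt
    sse = float(response @ response - beta @ (design.T @ response))
    sse = max(sse, 0.0)
    if n0 is None:
        n1 = int(design[:, 1].sum())
        n0 = n - n1
    return RegressionFit(beta_hat=beta, xtx_inv=xtx_inv, sse=sse, df=n - p, n0=n0, n1=n1)


def contrast_vector(pair: TimepointPairData) -> ContrastVector:
    """Contrast evaluating D = E[Y1,j | ybar_{1,j-1}] - E[Y0,j | ybar_{0,j-1}]."""
    m0 = float(np.mean(pair.y_prev_0))
    m1 = float(np.mean(pair.y_prev_1))
    return ContrastVector(z=np.array([0.0, 1.0, m1 - m0, m1]), ybar_prev_0=m0, ybar_prev_1=m1)


def _t_pvalue(t: float, df: int, alternative: str) -> float:
    # scipy.special.stdtr is the t CDF; cheaper than scipy.stats.t for tight loops
    if alternative == "two-sided":
        return float(2.0 * special.stdtr(df, -abs(t)))
    if alternative == "greater":
        return float(special.stdtr(df, -t))
    if alternative == "less":
        return float(special.stdtr(df, t))
    raise ValueError(f"alternative must be one of {ALTERNATIVES}, got {alternative!r}")


def conditional_group_estimates(pair: TimepointPairData) -> dict[int, GroupConditional]:
    """Within-group simple regressions of y_curr on y_prev (descriptive path).

    For group g the conditional-mean estimate at the group covariate mean is
    exactly the sample mean of y_curr; MSE_g uses the n_g - 2 denominator and
    the reported SE is sqrt(MSE_g / n_g).  With y_prev constant within the
    group the slope and rho are undefined: rho is returned NaN and the group
    is flagged degenerate (SE falls back to the conventional s / sqrt(n)).
    """
    out: dict[int, GroupConditional] = {}
    for g, (yp, yc) in ((0, (pair.y_prev_0, pair.y_curr_0)), (1, (pair.y_prev_1, pair.y_curr_1))):
        ng = yc.size
        if ng < 3:
            raise InsufficientDataError(
                f"group {g} has n = {ng} pairs; need >= 3 for the within-group regression"
            )
        mean_c = float(np.mean(yc))
        dp = yp - np.mean(yp)
        dc = yc - mean_c
        ssp = float(dp @ dp)
        ssc = float(dc @ dc)
        if ssp == 0.0:
            se_conv = float(np.sqrt(ssc / (ng - 1) / ng)) if ng > 1 else np.nan
            out[g] = GroupConditional(
                estimate=mean_c, se=se_conv, rho=np.nan, mse=np.nan, n=ng, degenerate=True
            )
            continue
        slope = float(dp @ dc) / ssp
        resid = dc - slope * dp
        mse = float(resid @ resid) / (ng - 2)
        rho = float(dp @ dc) / np.sqrt(ssp * ssc) if ssc > 0 else np.nan
        out[g] = GroupConditional(
            estimate=mean_c, se=float(np.sqrt(mse / ng)), rho=rho, mse=mse, n=ng
        )
    return out


def homologous_test(
    pair: TimepointPairData,
    alternative: str = "two-sided",
    with_group_estimates: bool = True,
) -> HomologousResult:
    """Run the homologous test on one adjacent-time-point pair.

    Fits the joint interaction model, forms the contrast at the per-group
    covariate means, and refers ``d_hat / se`` to the central t with n - 4
    degrees of freedom.  The point estimate always equals the raw difference
    of group means of ``y_curr`` (group 1 minus group 0).

    Parameters
    ----------
    pair : TimepointPairData
    alternative : {"two-sided", "greater", "less"}
        ``greater`` tests D > 0, i.e. group 1 mean exceeding group 0.
    with_group_estimates : bool
        Skip the descriptive per-group conditional path (and correlations)
        when false; used by tight simulation loops.
    """
    if alternative not in ALTERNATIVES:
        raise ValueError(f"alternative must be one of {ALTERNATIVES}, got {alternative!r}")
    y, design = build_design(pair)
    fit = fit_ols(y, design, n0=pair.n0, n1=pair.n1)
    zc = contrast_vector(pair)
    d_hat = float(zc.z @ fit.beta_hat)
    var = fit.mse * float(zc.z @ fit.xtx_inv @ zc.z)
    se = float(np.sqrt(var))
    if se > 0:
        t_stat = d_hat / se
        p = _t_pvalue(t_stat, fit.df, alternative)
    else:
        # degenerate: zero residual variance; treat exact zero difference as null
        t_stat = 0.0 if d_hat == 0 else np.sign(d_hat) * np.inf
        p = _t_pvalue(t_stat, fit.df, alternative) if np.isfinite(t_stat) else 0.0
        if d_hat == 0 and alternative == "two-sided":
            p = 1.0
    if with_group_estimates:
        estimates = conditional_group_estimates(pair)
        correlations = (estimates[0].rho, estimates[1].rho)
    else:
        estimates = {}
        correlations = (np.nan, np.nan)
    return HomologousResult(
        d_hat=d_hat,
        se=se,
        t_stat=t_stat,
        df=fit.df,
        p_value=p,
        alternative=alternative,
        n0=pair.n0,
        n1=pair.n1,
        group_estimates=estimates,
        correlations=correlations,
        time_prev=pair.time_prev,
        time_curr=pair.time_curr,
    )
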