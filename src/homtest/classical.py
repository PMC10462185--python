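"""Classical comparators: the two-sample t-test and Pearson correlation.

These are the benchmarks the homologous test is measured against.  The
default t-test variant is the pooled-variance Student t (n0 + n1 - 2 df),
matching the equal-error-variance model under which both tests are compared;
Welch's unequal-variance version is available by flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import InsufficientDataError

VARIANTS = ("pooled", "welch")
ALTERNATIVES = ("two-sided", "greater", "less")


@dataclass
class TTestResult:
    mean0: float
    mean1: float
    diff: float  # mean1 - mean0
    se: float
    t_stat: float
    df: float
    p_value: float
    variant: str
    alternative: str

    def to_record(self) -> dict:
        return {
            "d_hat": self.diff,
            "se": self.se,
            "t": self.t_stat,
            "df": self.df,
            "p": self.p_value,
            "method": f"ttest-{self.variant}",
        }


def two_sample_t(
    y0: np.ndarray,
    y1: np.ndarray,
    variant: str = "pooled",
    alternative: str = "two-sided",
) -> TTestResult:
    """Two-sample t-test of mean(y1) - mean(y0).

    ``variant="pooled"`` uses the pooled variance estimate with
    ``n0 + n1 - 2`` degrees of freedom; ``"welch"`` uses per-group variances
    with Satterthwaite df.  Two constant, equal samples give t = 0, p = 1.
    """
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}, got {variant!r}")
    if alternative not in ALTERNATIVES:
        raise ValueError(f"alternative must be one of {ALTERNATIVES}, got {alternative!r}")
    y0 = np.asarray(y0, dtype=float)
    y1 = np.asarray(y1, dtype=float)
    n0, n1 = y0.size, y1.size
    if n0 < 2 or n1 < 2:
        raise InsufficientDataError("each group needs at least 2 observations")
    mean0, mean1 = float(np.mean(y0)), float(np.mean(y1))
    v0 = float(np.var(y0, ddof=1))
    v1 = float(np.var(y1, ddof=1))
    if variant == "pooled":
        df = float(n0 + n1 - 2)
        sp2 = ((n0 - 1) * v0 + (n1 - 1) * v1) / df
        se = float(np.sqrt(sp2 * (1.0 / n0 + 1.0 / n1)))
    else:
        se = float(np.sqrt(v0 / n0 + v1 / n1))
        if v0 == 0 and v1 == 0:
            df = float(n0 + n1 - 2)
        else:
            df = (v0 / n0 + v1 / n1) ** 2 / (
                (v0 / n0) ** 2 / (n0 - 1) + (v1 / n1) ** 2 / (n1 - 1)
            )
    diff = mean1 - mean0
    if se == 0:
        # both samples constant; equal means are a null-consistent degenerate case
        t_stat = 0.0 if diff == 0 else np.sign(diff) * np.inf
    else:
        t_stat = diff / se
    if np.isfinite(t_stat):
        res = stats.ttest_ind(
            y1, y0, equal_var=(variant == "pooled"), alternative=alternative
        )
        # scipy returns NaN for zero-variance input; our t=0 convention covers it
        p = float(res.pvalue) if np.isfinite(res.pvalue) else _degenerate_p(t_stat, alternative)
    else:
        p = 0.0 if alternative == "two-sided" else (
            0.0 if (alternative == "greater") == (t_stat > 0) else 1.0
        )
    return TTestResult(
        mean0=mean0, mean1=mean1, diff=diff, se=se, t_stat=float(t_stat),
        df=df, p_value=p, variant=variant, alternative=alternative,
    )


def _degenerate_p(t_stat: float, alternative: str) -> float:
    if alternative == "two-sided":
        return 1.0
    return 0.5 if t_stat == 0 else (1.0 if t_stat < 0 else 0.0)


def pearson_r(a: np.ndarray, b: np.ndarray) -> float:
    """Product-moment correlation; NaN when either vector is constant.

    Raises on length mismatch or fewer than 2 observations.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.size} vs {b.size}")
    if a.size < 2:
        raise InsufficientDataError("correlation needs at least 2 observations")
    da = a - a.mean()
    db = b - b.mean()
    ssa = float(da @ da)
    ssb = float(db @ db)
    if ssa == 0.0 or ssb == 0.0:
        return float("nan")
    return float(np.clip((da @ db) / np.sqrt(ssa * ssb), -1.0, 1.0))
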