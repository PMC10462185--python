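"""Per-time-point study scanner.

Applies both the homologous test and the classical two-sample t-test at every
eligible time point of a study and assembles a report table: per-group means,
conventional SEs (s_g / sqrt(n_g)), homologous SEs (sqrt(MSE_g / n_g)),
adjacent-time Pearson correlations, and both p-values.  The earliest time
point has no predecessor, so it carries only the t-test; a degenerate
homologous fit falls back to missing homologous fields with a warning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from . import core
from .classical import two_sample_t
from .data import StudyTable, extract_pair
from .exceptions import (
    HomtestError,
    InsufficientDataError,
    PairExtractionError,
    SingularDesignError,
    StudyValidationError,
)

#: output CSV schema, in column order
SCAN_COLUMNS = (
    "time", "n0", "n1", "mean0", "se0_conv", "se0_hom", "rho0",
    "mean1", "se1_conv", "se1_hom", "rho1", "d_hat", "p_hom", "p_ttest",
)


@dataclass
class ScanOptions:
    alternative: str = "two-sided"
    t_variant: str = "pooled"
    log_transform: bool = False
    adjust: str = "none"  # none | holm (applied to the homologous p-values)


@dataclass
class ScanTable:
    """Ordered per-time-point report plus provenance."""

    table: pd.DataFrame  # columns SCAN_COLUMNS, sorted by time ascending
    group_labels: dict[int, str]
    options: ScanOptions
    warnings: list[str] = field(default_factory=list)

    def __iter__(self) -> Iterable[pd.Series]:
        return (row for _, row in self.table.iterrows())


def _holm(pvals: np.ndarray) -> np.ndarray:
    """Holm step-down adjustment, NaN-preserving."""
    adj = np.full_like(pvals, np.nan, dtype=float)
    mask = ~np.isnan(pvals)
    p = pvals[mask]
    m = p.size
    if m == 0:
        return adj
    order = np.argsort(p)
    # cumulative max enforces monotonicity of the step-down procedure
    stepped = np.maximum.accumulate((m - np.arange(m)) * p[order])
    out = np.empty(m)
    out[order] = np.minimum(stepped, 1.0)
    adj[mask] = out
    return adj


def scan_study(study: StudyTable, options: ScanOptions | None = None) -> ScanTable:
    """Scan every observed time point of the study.

    The reported group means and conventional SEs use all animals observed
    at that time; homologous quantities use the complete-case adjacent pair.
    Scanning is deterministic: identical inputs give identical tables.
    """
    options = options or ScanOptions()
    df = study.data
    if options.log_transform:
        if study.volume_scale == "log":
            raise StudyValidationError("study is already on the log scale")
        if (df["volume"] <= 0).any():
            raise StudyValidationError("log transform requested but nonpositive volumes present")
        df = df.assign(volume=np.log(df["volume"]))
        study = StudyTable(
            data=df, group_labels=study.group_labels, volume_scale="log", report=study.report
        )
    times = study.times
    if times.size < 2:
        raise StudyValidationError("study must contain at least two time points to scan")

    warnings: list[str] = []
    rows: list[dict] = []
    for k, t in enumerate(times):
        at_t = df[np.isclose(df["time"], t)]
        y0 = at_t.loc[at_t["group"] == 0, "volume"].to_numpy(float)
        y1 = at_t.loc[at_t["group"] == 1, "volume"].to_numpy(float)
        tt = two_sample_t(y0, y1, variant=options.t_variant, alternative=options.alternative)
        row = {
            "time": float(t),
            "n0": y0.size,
            "n1": y1.size,
            "mean0": tt.mean0,
            "se0_conv": float(np.std(y0, ddof=1) / np.sqrt(y0.size)),
            "mean1": tt.mean1,
            "se1_conv": float(np.std(y1, ddof=1) / np.sqrt(y1.size)),
            "d_hat": tt.diff,
            "p_ttest": tt.p_value,
            "se0_hom": np.nan, "rho0": np.nan, "se1_hom": np.nan, "rho1": np.nan,
            "p_hom": np.nan,
        }
        if k > 0:
            try:
                pair = extract_pair(study, t)
                res = core.homologous_test(pair, alternative=options.alternative)
                ge = res.group_estimates
                row.update(
                    se0_hom=ge[0].se, rho0=ge[0].rho,
                    se1_hom=ge[1].se, rho1=ge[1].rho,
                    p_hom=res.p_value,
                )
                if any(d > 0 for d in pair.dropped.values()):
                    warnings.append(
                        f"t={t:g}: dropped incomplete animals per group {pair.dropped}"
                    )
            except (SingularDesignError, PairExtractionError, InsufficientDataError) as exc:
                warnings.append(f"t={t:g}: homologous fit unavailable ({exc}); t-test only")
        rows.append(row)

    table = pd.DataFrame(rows, columns=list(SCAN_COLUMNS)).sort_values("time", ignore_index=True)
    if options.adjust == "holm":
        table["p_hom"] = _holm(table["p_hom"].to_numpy(float))
    elif options.adjust != "none":
        raise HomtestError(f"unknown adjustment {options.adjust!r}")
    return ScanTable(table=table, group_labels=dict(study.group_labels), options=options, warnings=warnings)


def write_scan_csv(scan: ScanTable, path: str | Path) -> None:
    """Write the scan table; missing values become empty fields."""
    scan.table.to_csv(path, index=False, na_rep="", columns=list(SCAN_COLUMNS))


def read_scan_csv(path: str | Path) -> pd.DataFrame:
    """Read back a scan CSV (convenience for round-trip checks)."""
    return pd.read_csv(path)
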