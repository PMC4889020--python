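"""Exploratory association of 3D focus density with 1-year FVC change.

A single ordinary least-squares regression of forced-vital-capacity
percentage change over one year on focus number density (per mm^3).  One
exploratory test, so no multiple-testing correction; cohorts this deep
into micro-CT imaging are tiny (n of order 4), so fits at such n carry a
wide-uncertainty warning flag rather than being refused.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

P_THRESHOLD = 0.05
SMALL_N = 10


@dataclass
class RegressionResult:
    """OLS fit of FVC % change on focus density."""

    slope: float            # FVC % change per (focus / mm^3)
    intercept: float
    r_squared: float
    p_value: float          # two-sided, H0: slope = 0
    stderr: float
    n: int
    significant: bool       # labeled flag at p < 0.05, never a filter
    small_n_warning: bool

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def fit_density_fvc(density_per_mm3, fvc_pct_change) -> RegressionResult:
    """Closed-form OLS; p from the t distribution with n - 2 df.

    Requires n >= 3 and a non-constant predictor.
    """
    x = np.asarray(density_per_mm3, dtype=float)
    y = np.asarray(fvc_pct_change, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("density and FVC change must be matching 1D arrays")
    n = len(x)
    if n < 3:
        raise ValueError(f"need >= 3 cases for a regression, got {n}")
    if np.allclose(x, x[0]):
        raise ValueError("constant density predictor: slope is not identifiable")
    fit = stats.linregress(x, y)
    r2 = float(fit.rvalue ** 2)
    pv = float(fit.pvalue)
    if np.allclose(y, y[0]):  # constant response: zero slope, no variance explained
        r2, pv = 0.0, 1.0
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=r2,
        p_value=pv,
        stderr=float(fit.stderr),
        n=n,
        significant=bool(fit.pvalue < P_THRESHOLD),
        small_n_warning=n < SMALL_N,
    )


def fit_from_csv(path: str | Path) -> RegressionResult:
    """Fit from a CSV with columns case_id, density_per_mm3, fvc_pct_change."""
    df = pd.read_csv(path)
    return fit_density_fvc(df["density_per_mm3"], df["fvc_pct_change"])
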