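"""Regression validation of back-calculated against prepared concentrations.

A successful reference-free quantification puts the back-calculated
concentrations on the identity line: ordinary least squares of
back-calculated (y) on prepared (x) should give slope ~ 1, intercept ~ 0
and R^2 ~ 1. The slope is the sensitive diagnostic for receiver-gain
nonlinearity, since gain bias is concentration-correlated whenever the
usable RG range depends on sample strength.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats


@dataclass
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float
    n: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError(f"r_squared must be in [0, 1], got {self.r_squared}")
        if self.n < 2:
            raise ValueError(f"regression needs n >= 2 points, got {self.n}")

    def equation(self) -> str:
        return f"y = {self.slope:.4f}x + {self.intercept:.4f} (R^2 = {self.r_squared:.4f})"


def fit_regression(prepared_mM: Sequence[float],
                   backcalc_mM: Sequence[float]) -> RegressionFit:
    """Unweighted OLS of back-calculated on prepared concentrations.

    ``r_squared`` is the squared Pearson correlation, identical to the OLS
    coefficient of determination for simple linear regression.
    """
    x = np.asarray(prepared_mM, dtype=float)
    y = np.asarray(backcalc_mM, dtype=float)
    if x.shape != y.shape:
        raise ValueError(
            f"length mismatch: {len(x)} prepared vs {len(y)} back-calculated"
        )
    if len(x) < 2:
        raise ValueError("regression needs at least 2 points")
    if np.allclose(x, x[0]):
        raise ValueError("prepared concentrations are all identical (degenerate x)")
    res = stats.linregress(x, y)
    # constant y: Pearson r is undefined (0/0); report zero correlation
    r2 = 0.0 if not np.isfinite(res.rvalue) else float(res.rvalue ** 2)
    return RegressionFit(slope=float(res.slope), intercept=float(res.intercept),
                         r_squared=r2, n=len(x))
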