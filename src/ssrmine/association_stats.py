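"""Pearson correlations across assembly summaries.

Cross-assembly association between SSR abundance and genome properties is
tested with the Pearson product-moment correlation and a two-sided t-test
on n - 2 degrees of freedom (the conventional ``cor.test`` behaviour):

    r = sum((x - mx)(y - my)) / sqrt(sum((x - mx)^2) sum((y - my)^2))
    t = r sqrt((n - 2) / (1 - r^2))

No multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: Variable pairs of the cross-assembly suite.
SUITE_PAIRS = (
    ("n_loci", "freq_per_mb"),
    ("n_loci", "density_bp_per_mb"),
    ("size_mb", "n_loci"),
    ("gc_pct", "n_loci"),
    ("size_mb", "freq_per_mb"),
    ("size_mb", "density_bp_per_mb"),
)


class CorrelationError(ValueError):
    pass


@dataclass(frozen=True)
class CorrelationResult:
    var_x: str
    var_y: str
    n: int
    r: float
    t_stat: float
    p_two_sided: float

    @property
    def significant_05(self) -> bool:
        return self.p_two_sided < 0.05

    @property
    def significant_01(self) -> bool:
        return self.p_two_sided < 0.01

    def to_row(self) -> dict:
        return {
            "var_x": self.var_x,
            "var_y": self.var_y,
            "n": self.n,
            "r": self.r,
            "t_stat": self.t_stat,
            "p_two_sided": self.p_two_sided,
            "significant_0.05": self.significant_05,
            "significant_0.01": self.significant_01,
        }


def pearson(x, y, var_x: str = "x", var_y: str = "y") -> CorrelationResult:
    """Product-moment correlation with a two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise CorrelationError("x and y must be 1-d vectors of equal length")
    n = x.size
    if n < 3:
        raise CorrelationError(f"need n >= 3 observations, got {n}")
    dx = x - x.mean()
    dy = y - y.mean()
    sxx = float(dx @ dx)
    syy = float(dy @ dy)
    if sxx == 0.0 or syy == 0.0:
        raise CorrelationError(
            f"correlation undefined: zero variance in {var_x if sxx == 0 else var_y}"
        )
    r = float(dx @ dy) / np.sqrt(sxx * syy)
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        t = np.inf if r > 0 else -np.inf
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return CorrelationResult(var_x, var_y, n, r, float(t), float(p))


def correlation_suite(summaries: pd.DataFrame) -> list[CorrelationResult]:
    """Run the standard pair suite over an assembly-summary table.

    Requires >= 3 rows; pairs whose columns are absent (e.g. no SSR GC
    column in a transcribed table) are skipped.
    """
    if len(summaries) < 3:
        raise CorrelationError(f"need >= 3 assemblies, got {len(summaries)}")
    results = []
    for vx, vy in SUITE_PAIRS:
        if vx not in summaries.columns or vy not in summaries.columns:
            continue
        results.append(pearson(summaries[vx], summaries[vy], vx, vy))
    return results


def suite_to_frame(results: list[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in results])
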