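"""Pearson chi-square internal-validity check on detection-mode tables."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd
from scipy.stats import chi2

__all__ = ["GofResult", "pearson_chi_square"]


@dataclass(frozen=True)
class GofResult:
    """Chi-square statistic with per-cell contributions.

    Degrees of freedom follow the convention (number of cells) minus
    (number of fitted parameters), which reproduces the published d.f.
    for the UK (9 cells - 3 = 6) and Funen (7 cells - 3 = 4) tables.
    """

    statistic: float
    df: int
    p_value: float
    contributions: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        rows = [{"cell": k, "contribution": v} for k, v in self.contributions.items()]
        return pd.DataFrame(rows)


def pearson_chi_square(
    observed: Mapping[str, float],
    expected: Mapping[str, float],
    n_params: int,
) -> GofResult:
    """Sum of (O - E)^2 / E over cells, df = cells - n_params.

    Cells are never pooled and no continuity correction is applied, so
    small expected counts contribute as printed.
    """
    obs = {k: v for k, v in observed.items() if v is not None}
    if set(obs) != set(k for k in expected if expected[k] is not None):
        missing = set(obs).symmetric_difference(expected)
        raise ValueError(f"observed/expected cell keys differ: {sorted(missing)}")
    if len(obs) - n_params < 1:
        raise ValueError("degrees of freedom would be < 1")
    contributions = {}
    for k, o in obs.items():
        e = expected[k]
        if not e > 0:
            raise ValueError(f"expected count for cell {k!r} must be > 0, got {e}")
        contributions[k] = (o - e) ** 2 / e
    stat = float(sum(contributions.values()))
    df = len(obs) - n_params
    return GofResult(
        statistic=stat,
        df=df,
        p_value=float(chi2.sf(stat, df)),
        contributions=contributions,
    )
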