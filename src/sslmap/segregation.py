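"""Chi-square goodness-of-fit tests of F2 marker-genotype counts.

For a codominant marker in an F2 population the three genotype classes are
expected in a 1:2:1 ratio; the Pearson statistic with df = classes - 1 is
compared against the chi-square critical value at the chosen alpha.  No
continuity correction is applied (it is a two-class device, and class
counts here are large).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["SegregationTestResult", "chisq_segregation", "write_segtest_report"]

#: tabulated chi-square critical values, df=2
CRITICAL_DF2 = {0.05: 5.991464547107979, 0.01: 9.21034037197618}


@dataclass(frozen=True)
class SegregationTestResult:
    marker: str
    observed: tuple[int, ...]
    ratio: tuple[float, ...]
    chi2: float
    df: int
    p: float
    alpha: float
    critical: float
    consistent: bool


def chisq_segregation(
    observed: Sequence[int],
    ratio: Sequence[float] = (1, 2, 1),
    alpha: float = 0.01,
    marker: str = "marker",
) -> SegregationTestResult:
    """Pearson chi-square test of observed counts against a Mendelian ratio.

    ``consistent`` is True when the statistic falls below the critical
    value at ``alpha`` (df = number of classes - 1); the exact p-value is
    reported alongside.
    """
    obs = np.asarray(observed, dtype=float)
    weights = np.asarray(ratio, dtype=float)
    if len(obs) != len(weights):
        raise ValueError("observed and ratio must have equal length")
    if np.any(obs < 0):
        raise ValueError("negative counts")
    if np.any(weights <= 0):
        raise ValueError("ratio weights must be positive")
    total = obs.sum()
    if total <= 0:
        raise ValueError("total count must be positive")
    expected = total * weights / weights.sum()
    chi2, p = stats.chisquare(obs, f_exp=expected)
    df = len(obs) - 1
    critical = float(stats.chi2.ppf(1 - alpha, df))
    return SegregationTestResult(
        marker=marker,
        observed=tuple(int(o) for o in obs),
        ratio=tuple(float(w) for w in weights),
        chi2=float(chi2),
        df=df,
        p=float(p),
        alpha=alpha,
        critical=critical,
        consistent=bool(chi2 < critical),
    )


def write_segtest_report(results: Sequence[SegregationTestResult], path: str | Path) -> None:
    rows = [
        {
            "marker": r.marker,
            **{f"n{i + 1}": n for i, n in enumerate(r.observed)},
            "ratio": ":".join(f"{w:g}" for w in r.ratio),
            "chi2": r.chi2,
            "df": r.df,
            "p": r.p,
            "consistent": r.consistent,
        }
        for r in results
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
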