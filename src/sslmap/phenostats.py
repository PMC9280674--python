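"""Trait arithmetic and the statistical toolbox for percentage phenotypes.

Grain chalkiness is scored by three percentages: PCG (percentage of chalky
grains), PCA (percentage of chalky area per chalky grain) and their product
PGC = PCG x PCA / 100 (percentage of grain chalkiness).  All significance
tests on percentage traits run on the arcsine-square-root transformed scale,
where the sampling variance is approximately stabilized; group means are
reported back on the raw percent scale.

Provided tests:

* two-sample Student/Welch t-test,
* Dunnett many-to-one comparisons against a control with family-wise
  adjusted p-values (equicoordinate multivariate t),
* a least-significance-range multiple-range test realized as the
  Student-Newman-Keuls stepwise studentized-range procedure with a
  compact-letter display,
* simple least-squares regression for the PCG/PCA -> PGC decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PGC_PRODUCT_TOLERANCE",
    "ComparisonResult",
    "RegressionResult",
    "compute_pgc",
    "arcsine_sqrt",
    "t_test_vs_control",
    "dunnett_vs_control",
    "lsr_multiple_range",
    "simple_regression",
    "read_phenotypes",
    "write_phenotypes",
]

#: max |PGC - PCG*PCA/100| (percentage points) before a record is rejected
PGC_PRODUCT_TOLERANCE = 0.5

# scipy's Dunnett CDF uses randomized quasi-Monte-Carlo integration; a fixed
# generator keeps reports byte-identical across runs (error ~1e-4 on p).
_DUNNETT_RNG_SEED = 0x5551


@dataclass(frozen=True)
class ComparisonResult:
    """One treatment-vs-control comparison from a Dunnett family."""

    line: str
    trait: str
    n_line: int
    n_control: int
    mean_line: float
    mean_control: float
    p_raw: float
    p_adjusted: float
    class_: str  # "lower" | "higher" | "ns"


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r: float
    n: int

    @property
    def r2(self) -> float:
        return self.r**2


def compute_pgc(pcg: float, pca: float) -> float:
    """PGC = PCG x PCA / 100, all on the percent scale."""
    pcg_a, pca_a = np.asarray(pcg, dtype=float), np.asarray(pca, dtype=float)
    if np.any((pcg_a < 0) | (pcg_a > 100)) or np.any((pca_a < 0) | (pca_a > 100)):
        raise ValueError(f"PCG/PCA must lie in [0, 100], got PCG={pcg}, PCA={pca}")
    out = pcg_a * pca_a / 100.0
    return float(out) if out.ndim == 0 else out


def arcsine_sqrt(p: float) -> float:
    """Variance-stabilizing transform arcsin(sqrt(p)) for a proportion p.

    Input is a proportion in [0, 1]; output is in radians, [0, pi/2].
    """
    p_a = np.asarray(p, dtype=float)
    if np.any((p_a < 0) | (p_a > 1)):
        raise ValueError(f"proportion outside [0, 1]: {p}")
    out = np.arcsin(np.sqrt(p_a))
    return float(out) if out.ndim == 0 else out


def t_test_vs_control(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    variant: str = "student",
) -> tuple[float, float, float]:
    """Two-sided two-sample t-test; returns (t, df, p).

    ``student`` pools the variances (the default, matching a classical
    two-group comparison); ``welch`` does not.  Two identical constant
    samples give t=0, p=1 by convention.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError(f"each sample needs n >= 2, got {len(a)} and {len(b)}")
    if variant not in {"student", "welch"}:
        raise ValueError(f"unknown variant {variant!r}")
    if np.var(a) == 0 and np.var(b) == 0:
        if np.mean(a) == np.mean(b):
            df = len(a) + len(b) - 2 if variant == "student" else float(len(a) + len(b) - 2)
            return 0.0, float(df), 1.0
        return float("inf"), float(len(a) + len(b) - 2), 0.0
    res = stats.ttest_ind(a, b, equal_var=(variant == "student"))
    return float(res.statistic), float(res.df), float(res.pvalue)


def _pooled_mse(groups: Sequence[np.ndarray]) -> tuple[float, int]:
    """Pooled within-group mean square and its df across all groups."""
    sse = sum(float(np.sum((g - g.mean()) ** 2)) for g in groups)
    df = sum(len(g) - 1 for g in groups)
    return sse / df, df


def dunnett_vs_control(
    control: Sequence[float],
    treatments: Sequence[Sequence[float]],
    alpha: float = 0.05,
    labels: Sequence[str] | None = None,
    trait: str = "trait",
    control_label: str = "control",
) -> list[ComparisonResult]:
    """Many-to-one comparisons against a control, Dunnett-adjusted.

    All groups share a pooled error variance.  ``p_raw`` is the unadjusted
    two-sided p of the pooled-variance t statistic; ``p_adjusted`` accounts
    for the family of k comparisons through the k-variate t distribution.
    A treatment is classed ``lower``/``higher`` by its mean difference when
    p_adjusted < alpha, else ``ns``.
    """
    ctrl = np.asarray(control, dtype=float)
    trts = [np.asarray(t, dtype=float) for t in treatments]
    if len(trts) < 1:
        raise ValueError("need at least one treatment group")
    if len(ctrl) < 2 or any(len(t) < 2 for t in trts):
        raise ValueError("every group needs n >= 2")
    if labels is None:
        labels = [f"treatment_{i + 1}" for i in range(len(trts))]

    mse, df = _pooled_mse([ctrl, *trts])
    res = stats.dunnett(
        *trts, control=ctrl, rng=np.random.default_rng(_DUNNETT_RNG_SEED)
    )
    out = []
    for label, t_vals, p_adj in zip(labels, trts, res.pvalue):
        diff = float(t_vals.mean() - ctrl.mean())
        if mse > 0:
            se = np.sqrt(mse * (1 / len(t_vals) + 1 / len(ctrl)))
            t_stat = diff / se
            p_raw = 2 * stats.t.sf(abs(t_stat), df)
        else:
            p_raw = 1.0 if diff == 0 else 0.0
        p_adj = max(float(p_adj), float(p_raw))  # exact constraint; quadrature noise
        if p_adj < alpha:
            class_ = "lower" if diff < 0 else "higher"
        else:
            class_ = "ns"
        out.append(
            ComparisonResult(
                line=label,
                trait=trait,
                n_line=len(t_vals),
                n_control=len(ctrl),
                mean_line=float(t_vals.mean()),
                mean_control=float(ctrl.mean()),
                p_raw=float(p_raw),
                p_adjusted=p_adj,
                class_=class_,
            )
        )
    return out


def lsr_multiple_range(
    groups: Sequence[Sequence[float]],
    alpha: float = 0.05,
    labels: Sequence[str] | None = None,
) -> dict[str, str]:
    """Multiple-range test with a compact letter display.

    Stepwise studentized-range comparisons of the ordered group means
    (Student-Newman-Keuls): the range spanning p ordered means is declared
    significant when it exceeds q(alpha; p, df) * sqrt(MSE / n_h), n_h the
    harmonic mean group size, and non-significant ranges are not subdivided.
    Groups sharing no letter differ at ``alpha``.  Ties in means order
    stably by label.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) < 2 for a in arrays):
        raise ValueError("every group needs n >= 2")
    if labels is None:
        labels = [f"group_{i + 1}" for i in range(len(arrays))]

    mse, df = _pooled_mse(arrays)
    order = sorted(range(len(arrays)), key=lambda i: (arrays[i].mean(), labels[i]))
    means = [arrays[i].mean() for i in order]
    ns = [len(arrays[i]) for i in order]
    k = len(order)

    nonsig = np.zeros((k, k), dtype=bool)  # True: i..j not separable

    def mark_nonsig(i: int, j: int) -> None:
        nonsig[i : j + 1, i : j + 1] = True

    def test_range(i: int, j: int) -> None:
        if j <= i or nonsig[i, j]:
            return
        span = j - i + 1
        n_h = span / sum(1 / ns[m] for m in range(i, j + 1))
        if mse == 0:
            significant = means[j] > means[i]
        else:
            q_crit = stats.studentized_range.ppf(1 - alpha, span, df)
            significant = (means[j] - means[i]) > q_crit * np.sqrt(mse / n_h)
        if significant:
            test_range(i, j - 1)
            test_range(i + 1, j)
        else:
            mark_nonsig(i, j)

    test_range(0, k - 1)
    np.fill_diagonal(nonsig, True)

    # compact letters: one letter per maximal run of mutually non-separable
    # ordered means (the non-significance relation is interval-shaped here)
    intervals: list[tuple[int, int]] = []
    for i in range(k):
        j = i
        while j + 1 < k and nonsig[i, j + 1]:
            j += 1
        if not intervals or j > intervals[-1][1]:
            intervals.append((i, j))
    letters_by_pos: list[str] = ["" for _ in range(k)]
    for idx, (i, j) in enumerate(intervals):
        letter = chr(ord("a") + idx)
        for m in range(i, j + 1):
            letters_by_pos[m] += letter
    return {labels[order[pos]]: letters_by_pos[pos] for pos in range(k)}


def simple_regression(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """Least-squares slope/intercept and Pearson r for y on x."""
    x_a = np.asarray(x, dtype=float)
    y_a = np.asarray(y, dtype=float)
    if len(x_a) != len(y_a) or len(x_a) < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.var(x_a) == 0:
        raise ValueError("x has zero variance")
    res = stats.linregress(x_a, y_a)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        n=len(x_a),
    )


def read_phenotypes(path: str | Path, validate_product: bool = True) -> pd.DataFrame:
    """Read the long phenotype CSV ``line,year,season,plant,PCG,PCA,PGC``.

    Seasons are FCS (first/hot cropping season) and SCS (second/cooler).
    When PCG, PCA and PGC are all present the product identity
    PGC = PCG x PCA / 100 must hold to within ``PGC_PRODUCT_TOLERANCE``.
    """
    df = pd.read_csv(path)
    required = ["line", "year", "season", "plant", "PCG", "PCA", "PGC"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype table missing columns: {missing}")
    bad_season = set(df["season"].dropna()) - {"FCS", "SCS"}
    if bad_season:
        raise ValueError(f"unknown season codes: {sorted(bad_season)}")
    for col in ("PCG", "PCA", "PGC"):
        vals = df[col].dropna()
        if ((vals < 0) | (vals > 100)).any():
            raise ValueError(f"{col} outside [0, 100]")
    if validate_product:
        full = df.dropna(subset=["PCG", "PCA", "PGC"])
        resid = (full["PGC"] - full["PCG"] * full["PCA"] / 100.0).abs()
        if (resid > PGC_PRODUCT_TOLERANCE).any():
            worst = full.loc[resid.idxmax()]
            raise ValueError(
                "PGC != PCG*PCA/100 beyond tolerance, e.g. line "
                f"{worst['line']} year {worst['year']} plant {worst['plant']}"
            )
    return df


def write_phenotypes(df: pd.DataFrame, path: str | Path) -> None:
    cols = ["line", "year", "season", "plant", "PCG", "PCA", "PGC"]
    df.to_csv(path, index=False, columns=cols)
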