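"""Additive/dominance effect estimation and temperature-response classes.

The additive effect of a mapped QTL is operationalized as the full
line-minus-recipient mean difference on the percent scale (for an SSSL the
two lines differ by one homozygous segment, so this difference is twice the
classical half-homozygote-difference ``a``; both conventions are reported
by :func:`dominance_from_f2`).  Environments are the two cropping seasons:
FCS (first, hot) and SCS (second, cooler).  A QTL whose additive effect is
significantly larger in magnitude in the hot season is classed
``enhanced_by_high_temperature``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .phenostats import arcsine_sqrt, lsr_multiple_range, t_test_vs_control

__all__ = [
    "EffectEstimate",
    "DominanceResult",
    "GxEComparison",
    "additive_effect",
    "dominance_from_f2",
    "compare_effects_across_envs",
    "write_effects_report",
    "write_gxe_report",
]

SEASONS = ("FCS", "SCS")


@dataclass(frozen=True)
class EffectEstimate:
    """Additive effect of a line's donor segment in one environment."""

    qtl_id: str
    env: str  # "FCS" | "SCS" | "pooled"
    a: float  # percentage points, line mean - control mean
    se: float
    p: float
    n_line: int = 0
    n_control: int = 0

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ValueError("standard error must be >= 0")


@dataclass(frozen=True)
class DominanceResult:
    """Gene action at a QTL from F2 genotype-class phenotypes.

    ``a`` is the classical additive effect (half the homozygote difference,
    signed as P2/P2 minus P1/P1), ``d`` the heterozygote's deviation from
    the homozygote midpoint, ``degree`` = d/|a|.
    """

    qtl_id: str
    mean_p1p1: float
    mean_het: float
    mean_p2p2: float
    a: float
    d: float
    degree: float
    class_: str  # additive | incomplete_dominance | complete_dominance | overdominance


@dataclass(frozen=True)
class GxEComparison:
    """Season contrast of a QTL's additive effect."""

    qtl_id: str
    a_FCS: float
    a_SCS: float
    p_interaction: float
    class_: str  # enhanced_by_high_temperature | suppressed_by_high_temperature | insensitive

    @property
    def delta(self) -> float:
        """a_FCS - a_SCS, percentage points."""
        return self.a_FCS - self.a_SCS


def _stratum(
    pheno: pd.DataFrame, line: str, trait: str, env: str | None
) -> np.ndarray:
    sel = pheno["line"] == line
    if env is not None and env != "pooled":
        sel &= pheno["season"] == env
    vals = pheno.loc[sel, trait].dropna().to_numpy(dtype=float)
    if len(vals) < 2:
        raise ValueError(
            f"fewer than 2 plants for line {line!r} with season filter {env!r}"
        )
    return vals


def additive_effect(
    pheno: pd.DataFrame,
    line: str,
    control: str,
    env: str | None = None,
    trait: str = "PGC",
    qtl_id: str | None = None,
) -> EffectEstimate:
    """Line-minus-control mean difference in one environment.

    The effect and its pooled two-sample standard error are on the percent
    scale; the p-value comes from a pooled t-test on the arcsine-square-root
    scale, where percentage noise is closer to homoscedastic.
    """
    line_vals = _stratum(pheno, line, trait, env)
    ctrl_vals = _stratum(pheno, control, trait, env)
    a = float(line_vals.mean() - ctrl_vals.mean())
    n1, n2 = len(line_vals), len(ctrl_vals)
    sp2 = (
        (n1 - 1) * line_vals.var(ddof=1) + (n2 - 1) * ctrl_vals.var(ddof=1)
    ) / (n1 + n2 - 2)
    se = float(np.sqrt(sp2 * (1 / n1 + 1 / n2)))
    _, _, p = t_test_vs_control(
        arcsine_sqrt(line_vals / 100.0), arcsine_sqrt(ctrl_vals / 100.0), "student"
    )
    return EffectEstimate(
        qtl_id=qtl_id or line,
        env=env or "pooled",
        a=a,
        se=se,
        p=p,
        n_line=n1,
        n_control=n2,
    )


def dominance_from_f2(
    class_values: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
    qtl_id: str = "qtl",
) -> DominanceResult:
    """Gene-action classification from F2 genotype-class phenotypes.

    ``class_values`` keys the three genotype classes "P1/P1", "P1/P2",
    "P2/P2" to their per-plant trait values (percent).  The
    heterozygote-vs-midparent linear contrast decides whether any dominance
    is present; it is evaluated on the percent scale, where ``d`` is
    defined (the arcsine transform is nonlinear, so the transformed-scale
    midparent is a different null).  The multiple-range letters, computed
    on the transformed scale as for every group comparison, decide which
    homozygote(s) the heterozygote separates from.  The classification is
    symmetric under swapping the homozygote labels.
    """
    keys = ("P1/P1", "P1/P2", "P2/P2")
    missing = [k for k in keys if k not in class_values or len(class_values[k]) == 0]
    if missing:
        raise ValueError(f"empty genotype classes: {missing}")
    raw = {k: np.asarray(class_values[k], dtype=float) for k in keys}
    if any(len(v) < 2 for v in raw.values()):
        raise ValueError("every genotype class needs n >= 2")
    trans = {k: arcsine_sqrt(v / 100.0) for k, v in raw.items()}

    m11, m12, m22 = (float(raw[k].mean()) for k in keys)
    a = (m22 - m11) / 2.0
    mid = (m11 + m22) / 2.0
    d = m12 - mid
    degree = d / abs(a) if a != 0 else float("inf") if d != 0 else 0.0

    # heterozygote vs midparent contrast (percent scale), pooled variance
    groups = [raw[k] for k in keys]
    sse = sum(float(np.sum((g - g.mean()) ** 2)) for g in groups)
    df = sum(len(g) - 1 for g in groups)
    mse = sse / df
    n1, nh, n2 = (len(raw[k]) for k in keys)
    contrast = d
    if mse > 0:
        se_c = np.sqrt(mse * (1 / nh + 1 / (4 * n1) + 1 / (4 * n2)))
        p_d = 2 * stats.t.sf(abs(contrast) / se_c, df)
    else:
        p_d = 1.0 if contrast == 0 else 0.0

    letters = lsr_multiple_range([trans[k] for k in keys], alpha=alpha, labels=list(keys))

    def separated(k1: str, k2: str) -> bool:
        return not set(letters[k1]) & set(letters[k2])

    het_vs_p1 = separated("P1/P2", "P1/P1")
    het_vs_p2 = separated("P1/P2", "P2/P2")
    lo, hi = min(m11, m22), max(m11, m22)
    between = lo < m12 < hi

    if p_d >= alpha:
        class_ = "additive"
    elif het_vs_p1 and het_vs_p2:
        class_ = "incomplete_dominance" if between else "overdominance"
    elif het_vs_p1 != het_vs_p2:
        class_ = "complete_dominance"
    else:
        # significant d but letters separate nothing: fall back on degree
        mag = abs(degree)
        if mag < 0.2:
            class_ = "additive"
        elif mag <= 0.8:
            class_ = "incomplete_dominance"
        elif mag <= 1.2:
            class_ = "complete_dominance"
        else:
            class_ = "overdominance"

    return DominanceResult(
        qtl_id=qtl_id,
        mean_p1p1=m11,
        mean_het=m12,
        mean_p2p2=m22,
        a=a,
        d=d,
        degree=degree,
        class_=class_,
    )


def compare_effects_across_envs(
    pheno: pd.DataFrame,
    line: str,
    control: str,
    env_a: str = "FCS",
    env_b: str = "SCS",
    alpha: float = 0.05,
    trait: str = "PGC",
    qtl_id: str | None = None,
) -> GxEComparison:
    """Test whether a line's additive effect differs between two seasons.

    The interaction p-value is the t-test of the 2x2 interaction contrast
    (line - control) in env_a minus (line - control) in env_b — i.e. the
    season difference of the additive effect itself, on the percent scale
    on which the effect is defined — with Welch-type cell variances and
    Satterthwaite degrees of freedom (chalkiness variance shrinks with the
    mean, so cells are heteroscedastic on the percent scale).  Plants
    (years pooled) are the replicates.  A significantly larger |a| in
    ``env_a`` (the hot season by default) means
    ``enhanced_by_high_temperature``.
    """
    eff_a = additive_effect(pheno, line, control, env=env_a, trait=trait, qtl_id=qtl_id)
    eff_b = additive_effect(pheno, line, control, env=env_b, trait=trait, qtl_id=qtl_id)

    cells = [
        _stratum(pheno, ln, trait, env)
        for ln in (line, control)
        for env in (env_a, env_b)
    ]
    means = [float(c.mean()) for c in cells]
    ns = [len(c) for c in cells]
    variances = [float(c.var(ddof=1)) for c in cells]
    # contrast: (line,a) - (line,b) - (control,a) + (control,b)
    contrast = means[0] - means[1] - means[2] + means[3]
    var_c = sum(v / n for v, n in zip(variances, ns))
    if var_c > 0:
        df = var_c**2 / sum(
            (v / n) ** 2 / (n - 1) for v, n in zip(variances, ns)
        )
        p_int = float(2 * stats.t.sf(abs(contrast) / np.sqrt(var_c), df))
    else:
        p_int = 1.0 if contrast == 0 else 0.0

    if p_int >= alpha:
        class_ = "insensitive"
    elif abs(eff_a.a) > abs(eff_b.a):
        class_ = "enhanced_by_high_temperature"
    else:
        class_ = "suppressed_by_high_temperature"

    return GxEComparison(
        qtl_id=qtl_id or line,
        a_FCS=eff_a.a,
        a_SCS=eff_b.a,
        p_interaction=p_int,
        class_=class_,
    )


def write_effects_report(effects: Sequence[EffectEstimate], path: str | Path) -> None:
    rows = [
        {"qtl": e.qtl_id, "env": e.env, "a": e.a, "se": e.se, "p": e.p} for e in effects
    ]
    pd.DataFrame(rows, columns=["qtl", "env", "a", "se", "p"]).to_csv(
        path, sep="\t", index=False
    )


def write_gxe_report(comparisons: Sequence[GxEComparison], path: str | Path) -> None:
    rows = [
        {
            "qtl": g.qtl_id,
            "a_FCS": g.a_FCS,
            "a_SCS": g.a_SCS,
            "delta": g.delta,
            "p_interaction": g.p_interaction,
            "class": g.class_,
        }
        for g in comparisons
    ]
    pd.DataFrame(
        rows, columns=["qtl", "a_FCS", "a_SCS", "delta", "p_interaction", "class"]
    ).to_csv(path, sep="\t", index=False)
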