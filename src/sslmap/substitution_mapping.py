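"""Overlap-based substitution mapping of QTLs.

A line whose trait differs significantly from the recipient must carry the
QTL somewhere on its donor segment; a line that does not differ provides
evidence that the QTL lies outside its donor material.  The candidate
region is therefore

    intersection over divergent lines of their *estimated* segments
    minus the union over non-significant lines of their *core* segments,

using the estimated (midpoint-extended) bounds where the QTL could plausibly
sit, but excluding only where non-divergent lines provably carry donor
genotype.  Both choices are configurable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .genome_model import LineProfile, MarkerMap
from .phenostats import ComparisonResult, arcsine_sqrt, dunnett_vs_control

logger = logging.getLogger(__name__)

__all__ = [
    "LineClassification",
    "QTLIntervalResult",
    "InconsistentDivergentSetError",
    "ContradictoryExclusionError",
    "classify_lines",
    "localize_qtl",
    "flanking_markers",
    "write_mapping_report",
]

CHROMOSOME_START = "chromosome_start"
CHROMOSOME_END = "chromosome_end"


class InconsistentDivergentSetError(ValueError):
    """Divergent lines share no common region: >=2 QTLs or misclassification."""


class ContradictoryExclusionError(ValueError):
    """Non-significant lines' segments erase the whole candidate region."""


@dataclass(frozen=True)
class LineClassification:
    line: str
    trait: str
    class_: str  # "divergent_low" | "divergent_high" | "ns"
    evidence: ComparisonResult


@dataclass(frozen=True)
class QTLIntervalResult:
    """A localized QTL: candidate interval(s) and their provenance."""

    qtl_id: str
    chromosome: str
    intervals: tuple[tuple[int, int], ...]
    flank_left: str
    flank_right: str
    supporting_lines: tuple[str, ...]
    excluding_lines: tuple[str, ...]
    direction: str  # "donor_decreases" | "donor_increases"
    ambiguous: bool = field(default=False)

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.intervals)

    @property
    def start(self) -> int:
        return self.intervals[0][0]

    @property
    def end(self) -> int:
        return self.intervals[-1][1]


def classify_lines(
    pheno: pd.DataFrame,
    control: str,
    trait: str = "PGC",
    alpha: float = 0.05,
    lines: Sequence[str] | None = None,
) -> list[LineClassification]:
    """Dunnett-classify every line against the control on one trait.

    Percent values are arcsine-square-root transformed before testing;
    direction comes from the sign of the (transformed) mean difference.
    Lines named in ``lines`` but absent from the table are skipped with a
    warning.
    """
    if control not in set(pheno["line"]):
        raise ValueError(f"control line {control!r} absent from phenotype table")
    present = [ln for ln in pheno["line"].unique() if ln != control]
    if lines is not None:
        wanted = [ln for ln in lines if ln != control]
        missing = [ln for ln in wanted if ln not in present]
        for ln in missing:
            logger.warning("line %s absent from phenotype table; skipped", ln)
        present = [ln for ln in wanted if ln in present]
    if not present:
        raise ValueError("no non-control lines to classify")

    def transformed(ln: str):
        vals = pheno.loc[pheno["line"] == ln, trait].dropna().to_numpy(dtype=float)
        return arcsine_sqrt(vals / 100.0)

    ctrl_vals = transformed(control)
    groups = [transformed(ln) for ln in present]
    comparisons = dunnett_vs_control(
        ctrl_vals, groups, alpha=alpha, labels=present, trait=trait, control_label=control
    )
    out = []
    for comp in comparisons:
        class_ = {"lower": "divergent_low", "higher": "divergent_high", "ns": "ns"}[comp.class_]
        out.append(LineClassification(line=comp.line, trait=trait, class_=class_, evidence=comp))
    return out


# ---------------------------------------------------------------------------
# interval algebra on closed bp intervals, kept as sorted disjoint lists


def _normalize(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    ivs = sorted((int(s), int(e)) for s, e in intervals if e >= s)
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _intersect(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out = []
    for s1, e1 in a:
        for s2, e2 in b:
            s, e = max(s1, s2), min(e1, e2)
            if s <= e:
                out.append((s, e))
    return _normalize(out)


def _subtract(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out = []
    for s1, e1 in a:
        pieces = [(s1, e1)]
        for s2, e2 in b:
            next_pieces = []
            for s, e in pieces:
                if e2 < s or s2 > e:
                    next_pieces.append((s, e))
                    continue
                if s < s2:
                    next_pieces.append((s, s2))
                if e2 < e:
                    next_pieces.append((e2, e))
            pieces = next_pieces
        out.extend(pieces)
    return _normalize([iv for iv in out if iv[1] > iv[0]])


def flanking_markers(
    interval: tuple[int, int], marker_map: MarkerMap, chromosome: str
) -> tuple[str, str]:
    """Nearest mapped markers bounding an interval.

    Left flank: rightmost marker at or left of the interval start; right
    flank: leftmost marker at or right of the interval end.  Sentinels are
    returned where the interval runs past the mapped markers.
    """
    start, end = interval
    markers = marker_map.on_chromosome(chromosome)
    left = [m for m in markers if m.position <= start]
    right = [m for m in markers if m.position >= end]
    return (
        left[-1].name if left else CHROMOSOME_START,
        right[0].name if right else CHROMOSOME_END,
    )


def localize_qtl(
    classifications: Sequence[LineClassification],
    profiles: Sequence[LineProfile],
    chromosome: str,
    marker_map: MarkerMap | None = None,
    qtl_id: str | None = None,
    exclusion_rule: str = "core",
) -> QTLIntervalResult:
    """Localize one QTL on one chromosome by segment-overlap logic.

    Only homozygous segments participate.  Divergent lines contribute their
    estimated segment spans; non-significant lines subtract their core (or
    estimated, with ``exclusion_rule='estimated'``) spans.  More than one
    surviving disjoint interval is reported with ``ambiguous=True``.
    """
    if exclusion_rule not in {"core", "estimated"}:
        raise ValueError(f"unknown exclusion_rule {exclusion_rule!r}")
    by_line = {p.line: p for p in profiles}
    divergent = [c for c in classifications if c.class_.startswith("divergent")]
    ns = [c for c in classifications if c.class_ == "ns"]

    supporting: list[str] = []
    candidate: list[tuple[int, int]] | None = None
    for c in divergent:
        profile = by_line.get(c.line)
        if profile is None:
            logger.warning("no genotype profile for divergent line %s; skipped", c.line)
            continue
        segs = profile.on_chromosome(chromosome, zygosity="homozygous")
        if not segs:
            continue
        span = _normalize((s.est_start, s.est_end) for s in segs)
        supporting.append(c.line)
        candidate = span if candidate is None else _intersect(candidate, span)
        if not candidate:
            raise InconsistentDivergentSetError(
                f"divergent lines share no common region on {chromosome}: "
                f"{', '.join(supporting)} (suggests >=2 QTLs or misclassification)"
            )
    if candidate is None:
        raise ValueError(
            f"no divergent line with a homozygous segment on chromosome {chromosome}"
        )

    excluding: list[str] = []
    for c in ns:
        profile = by_line.get(c.line)
        if profile is None:
            continue
        segs = profile.on_chromosome(chromosome, zygosity="homozygous")
        if not segs:
            continue
        if exclusion_rule == "core":
            span = _normalize((s.core_start, s.core_end) for s in segs)
        else:
            span = _normalize((s.est_start, s.est_end) for s in segs)
        reduced = _subtract(candidate, span)
        if reduced != candidate:
            excluding.append(c.line)
        candidate = reduced
        if not candidate:
            raise ContradictoryExclusionError(
                f"candidate region on {chromosome} fully erased by non-significant "
                f"lines: {', '.join(excluding)}"
            )

    directions = {c.class_ for c in divergent if c.line in supporting}
    direction = "donor_decreases" if "divergent_low" in directions else "donor_increases"
    if len(directions) > 1:
        logger.warning("divergent lines disagree in direction on %s", chromosome)

    if marker_map is not None:
        flank_left, _ = flanking_markers(candidate[0], marker_map, chromosome)
        _, flank_right = flanking_markers(candidate[-1], marker_map, chromosome)
    else:
        flank_left, flank_right = CHROMOSOME_START, CHROMOSOME_END

    return QTLIntervalResult(
        qtl_id=qtl_id or f"q{classifications[0].trait}_{chromosome}",
        chromosome=chromosome,
        intervals=tuple(candidate),
        flank_left=flank_left,
        flank_right=flank_right,
        supporting_lines=tuple(supporting),
        excluding_lines=tuple(excluding),
        direction=direction,
        ambiguous=len(candidate) > 1,
    )


def write_mapping_report(
    results: Sequence[QTLIntervalResult], tsv_path: str | Path, json_path: str | Path | None = None
) -> None:
    """Write the mapping report TSV (one row per interval) and a JSON twin."""
    rows = [
        {
            "qtl": r.qtl_id,
            "chrom": r.chromosome,
            "start": s,
            "end": e,
            "length_bp": r.length,
            "flank_left": r.flank_left,
            "flank_right": r.flank_right,
            "direction": r.direction,
            "supporting": ",".join(r.supporting_lines),
            "excluding": ",".join(r.excluding_lines),
            "ambiguous": r.ambiguous,
        }
        for r in results
        for s, e in r.intervals
    ]
    cols = [
        "qtl", "chrom", "start", "end", "length_bp", "flank_left",
        "flank_right", "direction", "supporting", "excluding", "ambiguous",
    ]
    pd.DataFrame(rows, columns=cols).to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        payload = [
            {
                "qtl": r.qtl_id,
                "chromosome": r.chromosome,
                "intervals": [list(iv) for iv in r.intervals],
                "length_bp": r.length,
                "flank_left": r.flank_left,
                "flank_right": r.flank_right,
                "direction": r.direction,
                "supporting_lines": list(r.supporting_lines),
                "excluding_lines": list(r.excluding_lines),
                "ambiguous": r.ambiguous,
            }
            for r in results
        ]
        Path(json_path).write_text(json.dumps(payload, indent=2) + "\n")
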