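"""Marker maps, line genotypes, and donor substitution-segment inference.

A single-segment substitution line (SSSL) library is genotyped with a panel
of PCR markers laid out on physical coordinates.  Each line's donor segments
are reconstructed from runs of non-recipient marker calls: the *core*
interval is spanned by the outermost donor-typed markers of a run, and the
*estimated* interval extends each core bound to the midpoint between that
marker and the nearest flanking recipient-typed marker — the usual
graphical-genotype convention for where the true recombination breakpoint
is expected to lie.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Call",
    "Marker",
    "MarkerMap",
    "GenotypeRecord",
    "GenotypeTable",
    "SubstitutionSegment",
    "LineProfile",
    "GenotypeFormatError",
    "read_marker_map",
    "read_genotypes",
    "write_genotypes",
    "infer_segments",
    "segment_length",
    "write_segments",
]

#: genotype file cell codes -> calls
_CODE_TO_CALL = {"A": "REC", "B": "DON", "H": "HET", "-": "MISSING"}
_CALL_TO_CODE = {v: k for k, v in _CODE_TO_CALL.items()}


class Call(str, Enum):
    """Marker genotype call relative to the recipient background."""

    REC = "REC"  # recipient homozygous
    DON = "DON"  # donor homozygous
    HET = "HET"  # heterozygous
    MISSING = "MISSING"


class GenotypeFormatError(ValueError):
    """Raised for malformed marker-map or genotype tables."""


@dataclass(frozen=True, order=True)
class Marker:
    chromosome: str
    position: int  # bp, 1-based
    name: str = field(compare=False)


class MarkerMap:
    """Ordered physical marker positions, the coordinate backbone.

    Markers are kept sorted by (chromosome, position); names are unique and
    positions strictly increase within a chromosome.
    """

    def __init__(self, markers: Iterable[Marker]):
        markers = sorted(markers)
        names = [m.name for m in markers]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise GenotypeFormatError(f"duplicate marker names: {', '.join(dup)}")
        for a, b in zip(markers, markers[1:]):
            if a.chromosome == b.chromosome and a.position == b.position:
                raise GenotypeFormatError(
                    f"markers {a.name} and {b.name} share position "
                    f"{a.position} on chromosome {a.chromosome}"
                )
        self._markers = markers
        self._by_name = {m.name: m for m in markers}

    @property
    def markers(self) -> list[Marker]:
        return list(self._markers)

    @property
    def names(self) -> list[str]:
        return [m.name for m in self._markers]

    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for m in self._markers:
            seen.setdefault(m.chromosome, None)
        return list(seen)

    def on_chromosome(self, chromosome: str) -> list[Marker]:
        return [m for m in self._markers if m.chromosome == chromosome]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> Marker:
        return self._by_name[name]

    def __len__(self) -> int:
        return len(self._markers)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, MarkerMap) and self._markers == other._markers

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker": [m.name for m in self._markers],
                "chrom": [m.chromosome for m in self._markers],
                "pos_bp": [m.position for m in self._markers],
            }
        )


@dataclass(frozen=True)
class GenotypeRecord:
    line: str
    marker: str
    call: Call


class GenotypeTable:
    """Per-line marker calls; wraps a lines x markers call matrix."""

    def __init__(self, calls: Mapping[str, Mapping[str, Call]], marker_order: Sequence[str]):
        self._calls = {line: dict(mk) for line, mk in calls.items()}
        self._marker_order = [m for m in marker_order]

    @property
    def lines(self) -> list[str]:
        return list(self._calls)

    @property
    def marker_order(self) -> list[str]:
        return list(self._marker_order)

    def calls_for(self, line: str) -> dict[str, Call]:
        return dict(self._calls[line])

    def records(self) -> list[GenotypeRecord]:
        return [
            GenotypeRecord(line, marker, call)
            for line, mk in self._calls.items()
            for marker, call in mk.items()
        ]

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, GenotypeTable)
            and self._calls == other._calls
            and self._marker_order == other._marker_order
        )


@dataclass(frozen=True)
class SubstitutionSegment:
    """One donor segment of a line.

    ``core`` is the interval spanned by the run's outermost non-recipient
    markers; ``est`` extends each bound toward the nearest flanking
    recipient marker (midpoint rule) or stays at the core bound when no
    recipient marker flanks that side.
    """

    line: str
    chromosome: str
    donor: str
    zygosity: str  # "homozygous" | "heterozygous"
    core_start: int
    core_end: int
    est_start: int
    est_end: int

    def __post_init__(self) -> None:
        if not (self.est_start <= self.core_start <= self.core_end <= self.est_end):
            raise ValueError(
                f"segment bounds violate est_start <= core_start <= core_end <= est_end: "
                f"{self.est_start}, {self.core_start}, {self.core_end}, {self.est_end}"
            )

    @property
    def length(self) -> int:
        return self.est_end - self.est_start


def segment_length(segment: SubstitutionSegment) -> int:
    """Estimated segment length in bp: ``est_end - est_start``."""
    return segment.length


@dataclass(frozen=True)
class LineProfile:
    """A line and its inferred donor segments.

    role: ``recipient`` (no segments), ``SSSL`` (exactly one homozygous
    segment) or ``NIL`` (anything else with >= 1 segment).
    """

    line: str
    role: str
    segments: tuple[SubstitutionSegment, ...]

    def on_chromosome(self, chromosome: str, zygosity: str | None = None) -> list[SubstitutionSegment]:
        return [
            s
            for s in self.segments
            if s.chromosome == chromosome and (zygosity is None or s.zygosity == zygosity)
        ]


def read_marker_map(path: str | Path) -> MarkerMap:
    """Read a marker map TSV with columns ``marker  chrom  pos_bp``."""
    df = pd.read_csv(path, sep="\t", dtype={"marker": str, "chrom": str})
    required = {"marker", "chrom", "pos_bp"}
    if not required.issubset(df.columns):
        raise GenotypeFormatError(
            f"marker map must have columns {sorted(required)}, got {list(df.columns)}"
        )
    try:
        positions = df["pos_bp"].astype(int)
    except (TypeError, ValueError) as exc:
        raise GenotypeFormatError(f"pos_bp not parseable as integer: {exc}") from exc
    if (positions <= 0).any():
        bad = df.loc[positions <= 0, "marker"].tolist()
        raise GenotypeFormatError(f"non-positive positions for markers: {bad}")
    return MarkerMap(
        Marker(chromosome=c, position=int(p), name=n)
        for n, c, p in zip(df["marker"], df["chrom"], positions)
    )


def write_marker_map(marker_map: MarkerMap, path: str | Path) -> None:
    marker_map.to_frame().to_csv(path, sep="\t", index=False)


def read_genotypes(path: str | Path, marker_map: MarkerMap) -> GenotypeTable:
    """Read a wide genotype TSV: ``line`` column plus one column per marker.

    Cells use codes A/B/H/- for recipient / donor / heterozygous / missing.
    Columns that are not in the marker map are rejected; mapped markers
    without a column simply yield no records (a warning is logged).
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("-")
    if "line" not in df.columns:
        raise GenotypeFormatError("genotype table must have a 'line' column")
    marker_cols = [c for c in df.columns if c != "line"]
    unknown = [c for c in marker_cols if c not in marker_map]
    if unknown:
        raise GenotypeFormatError(f"genotype columns not in marker map: {unknown}")
    absent = [m for m in marker_map.names if m not in marker_cols]
    if absent:
        logger.warning("markers in map but absent from genotype table: %s", absent)
    if df["line"].duplicated().any():
        dup = df.loc[df["line"].duplicated(), "line"].tolist()
        raise GenotypeFormatError(f"duplicate line rows: {dup}")

    calls: dict[str, dict[str, Call]] = {}
    for _, row in df.iterrows():
        line = row["line"]
        calls[line] = {}
        for marker in marker_cols:
            code = row[marker]
            if code not in _CODE_TO_CALL:
                raise GenotypeFormatError(
                    f"invalid genotype code {code!r} at line {line!r}, marker {marker!r}"
                )
            calls[line][marker] = Call(_CODE_TO_CALL[code])
    return GenotypeTable(calls, marker_order=marker_cols)


def write_genotypes(table: GenotypeTable, path: str | Path) -> None:
    """Write the wide genotype TSV (inverse of :func:`read_genotypes`)."""
    rows = []
    for line in table.lines:
        calls = table.calls_for(line)
        rows.append({"line": line, **{m: _CALL_TO_CODE[calls[m].value] for m in table.marker_order}})
    pd.DataFrame(rows, columns=["line", *table.marker_order]).to_csv(path, sep="\t", index=False)


def _est_bound(run_edge: Marker, markers: Sequence[Marker], calls: Mapping[str, Call], side: int) -> int:
    """Midpoint toward the nearest flanking REC marker; run edge if none.

    ``side`` is -1 for the left bound, +1 for the right.  Markers with
    MISSING or heterozygous/donor calls between the run and the nearest
    recipient marker are skipped: only a recipient-typed marker caps the
    segment.
    """
    idx = markers.index(run_edge)
    scan = range(idx - 1, -1, -1) if side < 0 else range(idx + 1, len(markers))
    for j in scan:
        if calls.get(markers[j].name, Call.MISSING) == Call.REC:
            return (run_edge.position + markers[j].position) // 2
    return run_edge.position


def infer_segments(
    line: str,
    calls: Mapping[str, Call],
    marker_map: MarkerMap,
    donor: str = "donor",
    boundary_rule: str = "midpoint",
) -> LineProfile:
    """Infer a line's donor segments from its marker calls.

    Maximal runs of consecutive equal non-recipient calls (donor-homozygous
    or heterozygous) become segments; MISSING markers inside a run are
    bridged (logged), so a run broken only by missing data stays one
    segment.  ``boundary_rule`` selects the estimated bounds: ``midpoint``
    (default) extends toward flanking recipient markers, ``core-only``
    keeps est == core.
    """
    if boundary_rule not in {"midpoint", "core-only"}:
        raise ValueError(f"unknown boundary_rule {boundary_rule!r}")
    segments: list[SubstitutionSegment] = []
    for chromosome in marker_map.chromosomes():
        markers = marker_map.on_chromosome(chromosome)
        typed = [m for m in markers if m.name in calls]
        if not typed:
            continue
        # group consecutive non-REC markers, skipping MISSING
        run: list[Marker] = []
        run_call: Call | None = None

        def flush() -> None:
            nonlocal run, run_call
            if run:
                core_start, core_end = run[0].position, run[-1].position
                if boundary_rule == "midpoint":
                    est_start = _est_bound(run[0], markers, calls, side=-1)
                    est_end = _est_bound(run[-1], markers, calls, side=+1)
                else:
                    est_start, est_end = core_start, core_end
                segments.append(
                    SubstitutionSegment(
                        line=line,
                        chromosome=chromosome,
                        donor=donor,
                        zygosity="homozygous" if run_call == Call.DON else "heterozygous",
                        core_start=core_start,
                        core_end=core_end,
                        est_start=est_start,
                        est_end=est_end,
                    )
                )
            run, run_call = [], None

        for m in typed:
            call = calls[m.name]
            if call == Call.MISSING:
                if run:
                    logger.debug("line %s: missing call at %s bridged into run", line, m.name)
                continue
            if call == Call.REC:
                flush()
            elif call == run_call:
                run.append(m)
            else:
                flush()
                run, run_call = [m], call
        flush()

    n_hom = sum(1 for s in segments if s.zygosity == "homozygous")
    if not segments:
        role = "recipient"
    elif len(segments) == 1 and n_hom == 1:
        role = "SSSL"
    else:
        role = "NIL"
    return LineProfile(line=line, role=role, segments=tuple(segments))


def write_segments(profiles: Iterable[LineProfile], path: str | Path) -> None:
    """Write the segments report TSV."""
    rows = [
        {
            "line": s.line,
            "chrom": s.chromosome,
            "donor": s.donor,
            "zygosity": s.zygosity,
            "core_start": s.core_start,
            "core_end": s.core_end,
            "est_start": s.est_start,
            "est_end": s.est_end,
            "length_bp": s.length,
        }
        for p in profiles
        for s in p.segments
    ]
    cols = [
        "line", "chrom", "donor", "zygosity",
        "core_start", "core_end", "est_start", "est_end", "length_bp",
    ]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
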