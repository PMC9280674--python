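"""Synthetic SSSL chalkiness studies with known ground truth.

The generator emulates the design the analysis assumes: a recipient line
with season-dependent grain chalkiness (hot first cropping season higher
than the cooler second), single-segment substitution lines (SSSLs) whose
donor segments carry chalkiness QTLs with season-specific additive
effects, and near-isogenic lines (NILs) subdividing a parent segment so
that overlap mapping can localize each QTL.  Phenotypes are drawn on the
arcsine-square-root scale — the scale on which the analysis assumes
homoscedastic noise — then back-transformed, and the three chalkiness
percentages respect the product identity PGC = PCG x PCA / 100.

Segments are prescribed spans, not products of simulated meiosis; marker
genotypes follow deterministically from the spans.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genome_model import Call, GenotypeTable, Marker, MarkerMap
from .phenostats import arcsine_sqrt

logger = logging.getLogger(__name__)

__all__ = [
    "QTLSpec",
    "LineRecipe",
    "SimulationConfig",
    "SimulatedStudy",
    "simulate_study",
    "simulate_f2",
    "default_config",
    "write_study",
]

MB = 1_000_000


@dataclass(frozen=True)
class QTLSpec:
    """A true QTL: position plus per-season additive effects on PGC.

    ``a_fcs``/``a_scs`` are the full carrier-minus-recipient differences in
    percentage points (negative = donor allele reduces chalkiness); ``d``
    is the heterozygote's deviation from the homozygote midpoint, used only
    by the F2 simulator.
    """

    qtl_id: str
    chromosome: str
    position: int
    a_fcs: float
    a_scs: float
    d: float = 0.0

    def a(self, season: str) -> float:
        return self.a_fcs if season == "FCS" else self.a_scs


@dataclass(frozen=True)
class LineRecipe:
    """A library line: homozygous donor spans as (chrom, start, end) bp."""

    line: str
    spans: tuple[tuple[str, int, int], ...]

    def carries(self, qtl: QTLSpec) -> bool:
        return any(
            c == qtl.chromosome and s <= qtl.position <= e for c, s, e in self.spans
        )


@dataclass
class SimulationConfig:
    seed: int = 0
    chromosomes: dict[str, int] = field(
        default_factory=lambda: {"chr5": 30 * MB, "chr6": 31 * MB}
    )
    marker_spacing: int = MB
    qtls: list[QTLSpec] = field(default_factory=list)
    recipient: str = "HJX74"
    # season-dependent recipient PGC baselines, percent
    baseline_fcs: float = 25.8
    baseline_scs: float = 16.6
    pca_baseline: float = 40.0
    pca_sd: float = 5.0
    noise_sd_transformed: float = 0.05  # radians on the arcsine scale
    n_plants: int = 10
    years: tuple[int, ...] = (2017, 2018, 2019)
    seasons: tuple[str, ...] = ("FCS", "SCS")
    library: list[LineRecipe] = field(default_factory=list)

    def validate(self) -> None:
        for pct in (self.baseline_fcs, self.baseline_scs, self.pca_baseline):
            if not 0 <= pct <= 100:
                raise ValueError(f"percentage out of [0, 100]: {pct}")
        if self.noise_sd_transformed <= 0:
            raise ValueError("noise_sd_transformed must be > 0")
        for qtl in self.qtls:
            if qtl.chromosome not in self.chromosomes:
                raise ValueError(f"QTL {qtl.qtl_id} on unknown chromosome {qtl.chromosome}")
            if not any(recipe.carries(qtl) for recipe in self.library):
                raise ValueError(
                    f"QTL {qtl.qtl_id} at {qtl.chromosome}:{qtl.position} lies outside "
                    "every library segment"
                )

    def baseline(self, season: str) -> float:
        return self.baseline_fcs if season == "FCS" else self.baseline_scs


@dataclass
class SimulatedStudy:
    marker_map: MarkerMap
    genotypes: GenotypeTable
    phenotypes: pd.DataFrame
    truth: dict


def default_config(seed: int = 0) -> SimulationConfig:
    """The reference study design: recipient, two SSSLs, eight NILs.

    One major chalkiness QTL sits on each SSSL segment, with hot-season
    effects larger in magnitude than cool-season ones; the eight NILs tile
    the chromosome-5 segment so that five carry the QTL and three do not.
    """
    qtls = [
        QTLSpec("qA", "chr5", int(16.9 * MB), a_fcs=-18.6, a_scs=-12.3, d=4.0),
        QTLSpec("qB", "chr6", int(1.6 * MB), a_fcs=-21.6, a_scs=-13.1, d=5.0),
    ]
    library = [
        LineRecipe("SSSL-A", (("chr5", int(5.0 * MB), int(22.81 * MB)),)),
        LineRecipe("SSSL-B", (("chr6", int(0.4 * MB), int(4.32 * MB)),)),
        # five NILs covering the chr5 QTL position
        LineRecipe("NIL-A1", (("chr5", int(14.5 * MB), int(22.81 * MB)),)),
        LineRecipe("NIL-A2", (("chr5", int(12.0 * MB), int(18.5 * MB)),)),
        LineRecipe("NIL-A3", (("chr5", int(16.0 * MB), int(20.0 * MB)),)),
        LineRecipe("NIL-A4", (("chr5", int(15.5 * MB), int(17.5 * MB)),)),
        LineRecipe("NIL-A5", (("chr5", int(16.3 * MB), int(22.81 * MB)),)),
        # three NILs outside it
        LineRecipe("NIL-A6", (("chr5", int(5.0 * MB), int(12.5 * MB)),)),
        LineRecipe("NIL-A7", (("chr5", int(5.0 * MB), int(15.5 * MB)),)),
        LineRecipe("NIL-A8", (("chr5", int(18.0 * MB), int(22.81 * MB)),)),
    ]
    return SimulationConfig(seed=seed, qtls=qtls, library=library)


def _shift_on_transformed_scale(baseline_pct: float, a_pct: float, theta_base: float) -> float:
    """Transformed-scale offset matching a percent-scale effect ``a_pct``."""
    target = np.clip(baseline_pct + a_pct, 0.01, 99.99)
    return arcsine_sqrt(target / 100.0) - theta_base


def _marker_grid(config: SimulationConfig) -> MarkerMap:
    markers = []
    for chrom, length in config.chromosomes.items():
        positions = range(config.marker_spacing, length + 1, config.marker_spacing)
        markers.extend(
            Marker(chromosome=chrom, position=pos, name=f"M{chrom[3:]}_{i + 1:03d}")
            for i, pos in enumerate(positions)
        )
    return MarkerMap(markers)


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Generate marker map, line genotypes and per-plant phenotypes.

    Per plant, the transformed PGC is the recipient's seasonal baseline
    plus the transformed-scale shift of every QTL the line carries plus
    N(0, noise_sd_transformed); PCA is drawn around its baseline, and PCG
    is derived so the product identity holds exactly (clipped to 100, with
    PCA raised to PGC, when a plant's PGC exceeds its drawn PCA).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    marker_map = _marker_grid(config)

    lines = [config.recipient, *[r.line for r in config.library]]
    spans_by_line = {r.line: r.spans for r in config.library}
    spans_by_line[config.recipient] = ()

    calls: dict[str, dict[str, Call]] = {}
    for line in lines:
        spans = spans_by_line[line]
        calls[line] = {
            m.name: (
                Call.DON
                if any(c == m.chromosome and s <= m.position <= e for c, s, e in spans)
                else Call.REC
            )
            for m in marker_map.markers
        }
    genotypes = GenotypeTable(calls, marker_order=marker_map.names)

    carried = {
        line: [q for q in config.qtls if LineRecipe(line, spans_by_line[line]).carries(q)]
        for line in lines
    }

    rows = []
    n_clipped = 0
    for line in lines:
        for year in config.years:
            for season in config.seasons:
                base = config.baseline(season)
                theta_base = arcsine_sqrt(base / 100.0)
                mu = theta_base + sum(
                    _shift_on_transformed_scale(base, q.a(season), theta_base)
                    for q in carried[line]
                )
                theta = rng.normal(mu, config.noise_sd_transformed, size=config.n_plants)
                pgc = 100.0 * np.sin(np.clip(theta, 0.0, np.pi / 2)) ** 2
                pca = np.clip(
                    rng.normal(config.pca_baseline, config.pca_sd, size=config.n_plants),
                    1.0,
                    100.0,
                )
                low = pca < pgc
                n_clipped += int(low.sum())
                pca = np.where(low, pgc, pca)
                pcg = 100.0 * pgc / pca
                for plant in range(config.n_plants):
                    rows.append(
                        {
                            "line": line,
                            "year": year,
                            "season": season,
                            "plant": f"p{plant + 1:02d}",
                            "PCG": float(pcg[plant]),
                            "PCA": float(pca[plant]),
                            "PGC": float(pgc[plant]),
                        }
                    )
    if n_clipped:
        logger.debug("PCA raised to PGC for %d plants to keep PCG <= 100", n_clipped)

    phenotypes = pd.DataFrame(rows)
    truth = {
        "seed": config.seed,
        "recipient": config.recipient,
        "baseline_fcs": config.baseline_fcs,
        "baseline_scs": config.baseline_scs,
        "qtls": [asdict(q) for q in config.qtls],
        "library": {r.line: [list(s) for s in r.spans] for r in config.library},
        "carriers": {
            line: [q.qtl_id for q in qs] for line, qs in carried.items() if qs
        },
    }
    return SimulatedStudy(
        marker_map=marker_map, genotypes=genotypes, phenotypes=phenotypes, truth=truth
    )


def simulate_f2(
    a: float,
    d: float,
    midparent: float,
    sd: float,
    n: int,
    seed: int,
    ratio: Sequence[float] = (0.25, 0.5, 0.25),
) -> tuple[tuple[int, int, int], dict[str, np.ndarray]]:
    """Simulate one F2 family at a codominant marker linked to a QTL.

    Genotype classes P1/P1 : P1/P2 : P2/P2 are multinomial with the given
    probabilities; class phenotype means follow the (m - a, m + d, m + a)
    convention on the percent scale with N(0, sd) plant noise, clipped to
    [0, 100].
    """
    if n < 3:
        raise ValueError("need n >= 3 plants")
    probs = np.asarray(ratio, dtype=float)
    probs = probs / probs.sum()
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n, probs)
    means = {"P1/P1": midparent - a, "P1/P2": midparent + d, "P2/P2": midparent + a}
    values = {
        key: np.clip(rng.normal(means[key], sd, size=cnt), 0.0, 100.0)
        for key, cnt in zip(("P1/P1", "P1/P2", "P2/P2"), counts)
    }
    return (int(counts[0]), int(counts[1]), int(counts[2])), values


def write_study(study: SimulatedStudy, outdir: str | Path) -> dict[str, Path]:
    """Emit marker_map.tsv, genotypes.tsv, phenotypes.csv and truth.json."""
    from .genome_model import write_genotypes, write_marker_map
    from .phenostats import write_phenotypes

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "marker_map": outdir / "marker_map.tsv",
        "genotypes": outdir / "genotypes.tsv",
        "phenotypes": outdir / "phenotypes.csv",
        "truth": outdir / "truth.json",
    }
    write_marker_map(study.marker_map, paths["marker_map"])
    write_genotypes(study.genotypes, paths["genotypes"])
    write_phenotypes(study.phenotypes, paths["phenotypes"])
    paths["truth"].write_text(json.dumps(study.truth, indent=2) + "\n")
    return paths
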