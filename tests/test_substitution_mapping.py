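"""Line classification and overlap-based QTL localization."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sslmap.genome_model import LineProfile, Marker, MarkerMap, SubstitutionSegment
from sslmap.phenostats import ComparisonResult
from sslmap.substitution_mapping import (
    CHROMOSOME_END,
    ContradictoryExclusionError,
    InconsistentDivergentSetError,
    LineClassification,
    classify_lines,
    flanking_markers,
    localize_qtl,
)
from sslmap.synthetic_data import simulate_study

from conftest import single_qtl_config

MB = 1_000_000


def _profile(line, spans, core_shrink=0):
    """Helper: one homozygous segment per (start, end) span (bp)."""
    segs = tuple(
        SubstitutionSegment(
            line=line,
            chromosome="chr5",
            donor="donor",
            zygosity="homozygous",
            core_start=s + core_shrink,
            core_end=e - core_shrink,
            est_start=s,
            est_end=e,
        )
        for s, e in spans
    )
    return LineProfile(line=line, role="NIL", segments=segs)


def _cls(line, class_):
    evidence = ComparisonResult(
        line=line, trait="PGC", n_line=10, n_control=10,
        mean_line=5.0 if class_ != "ns" else 25.0, mean_control=25.0,
        p_raw=0.001 if class_ != "ns" else 0.8,
        p_adjusted=0.001 if class_ != "ns" else 0.9,
        class_={"divergent_low": "lower", "divergent_high": "higher", "ns": "ns"}[class_],
    )
    return LineClassification(line=line, trait="PGC", class_=class_, evidence=evidence)


class TestClassifyLines:
    def test_pattern_of_low_and_ns_lines(self, rng):
        # 5 lines near 5% and 3 near 25% against a 25% control
        rows = []
        def add(line, mean):
            theta = np.arcsin(np.sqrt(mean / 100))
            vals = 100 * np.sin(rng.normal(theta, 0.05, 10)) ** 2
            for i, v in enumerate(vals):
                rows.append({"line": line, "year": 2017, "season": "FCS",
                             "plant": f"p{i}", "PCG": v, "PCA": 100.0, "PGC": v})
        import pandas as pd
        add("HJX74", 25.0)
        for i in range(5):
            add(f"low{i}", 5.0)
        for i in range(3):
            add(f"null{i}", 25.0)
        pheno = pd.DataFrame(rows)
        cls = {c.line: c.class_ for c in classify_lines(pheno, control="HJX74")}
        assert all(cls[f"low{i}"] == "divergent_low" for i in range(5))
        assert all(cls[f"null{i}"] == "ns" for i in range(3))

    def test_absent_line_skipped_with_warning(self, rng, caplog):
        import pandas as pd
        rows = [
            {"line": ln, "year": 2017, "season": "FCS", "plant": f"p{i}",
             "PCG": v, "PCA": 100.0, "PGC": v}
            for ln, mu in [("HJX74", 25.0), ("L1", 5.0)]
            for i, v in enumerate(rng.normal(mu, 1, 10))
        ]
        pheno = pd.DataFrame(rows)
        with caplog.at_level("WARNING"):
            cls = classify_lines(pheno, control="HJX74", lines=["L1", "ghost"])
        assert [c.line for c in cls] == ["L1"]
        assert any("ghost" in r.message for r in caplog.records)


class TestLocalizeQTL:
    def test_interval_algebra_hand_worked(self):
        classifications = [
            _cls("d1", "divergent_low"),
            _cls("d2", "divergent_low"),
            _cls("d3", "divergent_low"),
            _cls("n1", "ns"),
        ]
        profiles = [
            _profile("d1", [(10 * MB, 20 * MB)]),
            _profile("d2", [(12 * MB, 25 * MB)]),
            _profile("d3", [(15 * MB, 30 * MB)]),
            _profile("n1", [(18 * MB, 28 * MB)]),
        ]
        res = localize_qtl(classifications, profiles, "chr5")
        assert res.intervals == ((15 * MB, 18 * MB),)
        assert res.length == 3 * MB
        assert res.direction == "donor_decreases"
        assert set(res.supporting_lines) == {"d1", "d2", "d3"}
        assert res.excluding_lines == ("n1",)

    def test_single_divergent_line_whole_segment(self):
        res = localize_qtl(
            [_cls("d1", "divergent_low")], [_profile("d1", [(10 * MB, 20 * MB)])], "chr5"
        )
        assert res.intervals == ((10 * MB, 20 * MB),)

    def test_disjoint_divergent_segments_error(self):
        with pytest.raises(InconsistentDivergentSetError, match="d1.*d2"):
            localize_qtl(
                [_cls("d1", "divergent_low"), _cls("d2", "divergent_low")],
                [_profile("d1", [(10 * MB, 15 * MB)]), _profile("d2", [(20 * MB, 25 * MB)])],
                "chr5",
            )

    def test_contradictory_exclusion_error(self):
        with pytest.raises(ContradictoryExclusionError):
            localize_qtl(
                [_cls("d1", "divergent_low"), _cls("n1", "ns")],
                [_profile("d1", [(10 * MB, 20 * MB)]), _profile("n1", [(9 * MB, 21 * MB)])],
                "chr5",
            )

    def test_ambiguous_split_interval(self):
        res = localize_qtl(
            [_cls("d1", "divergent_low"), _cls("n1", "ns")],
            [_profile("d1", [(10 * MB, 20 * MB)]), _profile("n1", [(13 * MB, 17 * MB)])],
            "chr5",
        )
        assert res.ambiguous
        assert res.intervals == ((10 * MB, 13 * MB), (17 * MB, 20 * MB))
        assert res.length == 6 * MB

    def test_order_independence(self):
        classifications = [
            _cls("d1", "divergent_low"),
            _cls("d2", "divergent_low"),
            _cls("n1", "ns"),
        ]
        profiles = [
            _profile("d1", [(10 * MB, 20 * MB)]),
            _profile("d2", [(12 * MB, 25 * MB)]),
            _profile("n1", [(18 * MB, 28 * MB)]),
        ]
        base = localize_qtl(classifications, profiles, "chr5").intervals
        for perm in itertools.permutations(range(3)):
            got = localize_qtl(
                [classifications[i] for i in perm], [profiles[i] for i in perm], "chr5"
            ).intervals
            assert got == base

    def test_monotone_shrinkage(self):
        classifications = [_cls("d1", "divergent_low")]
        profiles = [_profile("d1", [(10 * MB, 20 * MB)])]
        base = localize_qtl(classifications, profiles, "chr5")
        with_ns = localize_qtl(
            classifications + [_cls("n1", "ns")],
            profiles + [_profile("n1", [(18 * MB, 25 * MB)])],
            "chr5",
        )
        with_div = localize_qtl(
            classifications + [_cls("d2", "divergent_low")],
            profiles + [_profile("d2", [(14 * MB, 30 * MB)])],
            "chr5",
        )
        assert with_ns.length <= base.length
        assert with_div.length <= base.length

    def test_heterozygous_segments_ignored(self):
        het_seg = SubstitutionSegment(
            line="d2", chromosome="chr5", donor="donor", zygosity="heterozygous",
            core_start=25 * MB, core_end=28 * MB, est_start=24 * MB, est_end=29 * MB,
        )
        profiles = [
            _profile("d1", [(10 * MB, 20 * MB)]),
            LineProfile(line="d2", role="NIL", segments=(het_seg,)),
        ]
        res = localize_qtl(
            [_cls("d1", "divergent_low"), _cls("d2", "divergent_low")], profiles, "chr5"
        )
        # d2's heterozygous segment contributes nothing
        assert res.intervals == ((10 * MB, 20 * MB),)
        assert res.supporting_lines == ("d1",)


class TestFlankingMarkers:
    def test_by_inspection(self):
        mm = MarkerMap(
            Marker(chromosome="chr5", position=p * MB, name=f"m{p}") for p in (14, 16, 19)
        )
        assert flanking_markers((15 * MB, 18 * MB), mm, "chr5") == ("m14", "m19")

    def test_exact_endpoints_are_their_own_flanks(self):
        mm = MarkerMap(
            Marker(chromosome="chr5", position=p * MB, name=f"m{p}") for p in (14, 16, 19)
        )
        assert flanking_markers((14 * MB, 19 * MB), mm, "chr5") == ("m14", "m19")

    def test_sentinel_beyond_last_marker(self):
        mm = MarkerMap([Marker(chromosome="chr5", position=14 * MB, name="m14")])
        left, right = flanking_markers((15 * MB, 18 * MB), mm, "chr5")
        assert (left, right) == ("m14", CHROMOSOME_END)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(data=st.data())
def test_localize_matches_brute_force_interval_algebra(data):
    """Analytic interval algebra equals pointwise brute force on a grid."""
    n_lines = data.draw(st.integers(1, 6))
    lines = []
    for i in range(n_lines):
        s = data.draw(st.integers(0, 28))
        e = data.draw(st.integers(s + 1, 30))
        divergent = data.draw(st.booleans()) if i > 0 else True
        lines.append((f"L{i}", s, e, divergent))
    if not any(d for _, _, _, d in lines):
        lines[0] = (lines[0][0], lines[0][1], lines[0][2], True)

    classifications = [
        _cls(name, "divergent_low" if d else "ns") for name, _, _, d in lines
    ]
    profiles = [_profile(name, [(s * MB, e * MB)]) for name, s, e, _ in lines]

    # brute force: test membership of every half-unit point
    points = [x + 0.5 for x in range(30)]
    member = [
        all(s <= p <= e for name, s, e, d in lines if d)
        and not any(s <= p <= e for name, s, e, d in lines if not d)
        for p in points
    ]
    try:
        res = localize_qtl(classifications, profiles, "chr5")
        got = [
            any(s < p * MB < e for s, e in res.intervals) for p in points
        ]
        assert got == member
    except (InconsistentDivergentSetError, ContradictoryExclusionError):
        assert not any(member)


def test_recovered_interval_contains_truth_single_study():
    """End-to-end: simulated study localizes the true QTL position."""
    from sslmap.genome_model import infer_segments

    study = simulate_study(single_qtl_config(seed=7))
    profiles = [
        infer_segments(line, study.genotypes.calls_for(line), study.marker_map)
        for line in study.genotypes.lines
    ]
    cls = classify_lines(study.phenotypes, control="HJX74")
    res = localize_qtl(cls, profiles, "chr5", marker_map=study.marker_map)
    truth_pos = study.truth["qtls"][0]["position"]
    assert any(s <= truth_pos <= e for s, e in res.intervals)
    # containment/disjointness postconditions
    by_line = {p.line: p for p in profiles}
    for s, e in res.intervals:
        for line in res.supporting_lines:
            segs = by_line[line].on_chromosome("chr5", zygosity="homozygous")
            assert any(seg.est_start <= s and e <= seg.est_end for seg in segs)
        for line in res.excluding_lines:
            for seg in by_line[line].on_chromosome("chr5", zygosity="homozygous"):
                assert min(e, seg.core_end) - max(s, seg.core_start) <= 0
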