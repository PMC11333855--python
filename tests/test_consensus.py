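import itertools

import pytest
from hypothesis import given, settings, strategies as st

from cazpipe.config import PipelineConfig
from cazpipe.consensus import (
    accept_ec,
    accept_sulfatase,
    filter_mags,
    merge_calls,
)
from cazpipe.io import MagMeta

from oracles import make_hit, merge_oracle

LABELS = ["GH16", "GH13", "PL6"]
SOURCES = ["HMMER", "eCAMI", "DIAMOND"]


class TestMergeCalls:
    def test_two_of_three_agree_with_priority(self):
        hits = [
            make_hit(source="HMMER", label="GH16"),
            make_hit(source="eCAMI", label="GH16"),
            make_hit(source="DIAMOND", label="GH13"),
        ]
        call = merge_calls(hits)
        assert call.family == "GH16"
        assert call.supporting_sources == {"HMMER", "eCAMI"}
        assert call.mechanism == "GH"

    def test_no_agreement_gives_no_call(self):
        hits = [
            make_hit(source="HMMER", label="GH16"),
            make_hit(source="eCAMI", label="GH13"),
            make_hit(source="DIAMOND", label="PL6"),
        ]
        assert merge_calls(hits) is None

    def test_subfamilies_collapse_before_agreement(self):
        hits = [
            make_hit(source="HMMER", label="GH13_10"),
            make_hit(source="DIAMOND", label="GH13_28"),
        ]
        assert merge_calls(hits).family == "GH13"

    def test_multiple_proteins_rejected(self):
        with pytest.raises(ValueError):
            merge_calls([make_hit(protein="a"), make_hit(protein="b")])

    def test_exhaustive_against_enumeration_oracle(self):
        """Agreement over every assignment of <=3 streams to 3 labels."""
        n_cases = 0
        for k in range(0, 4):
            for srcs in itertools.combinations(SOURCES, k):
                for labels in itertools.product(LABELS, repeat=k):
                    assignment = dict(zip(srcs, labels))
                    hits = [make_hit(source=s, label=l) for s, l in assignment.items()]
                    expected = merge_oracle(assignment)
                    got = merge_calls(hits) if hits else None
                    if expected is None:
                        assert got is None, assignment
                    else:
                        assert got is not None, assignment
                        assert (got.family, got.supporting_sources) == expected
                    n_cases += 1
        assert n_cases >= 40

    def test_output_family_always_among_input_labels(self):
        for labels in itertools.product(LABELS, repeat=3):
            hits = [make_hit(source=s, label=l) for s, l in zip(SOURCES, labels)]
            call = merge_calls(hits)
            if call is not None:
                assert call.family in labels

    def test_removing_a_stream_never_creates_a_call(self):
        for labels in itertools.product(LABELS, repeat=3):
            hits = [make_hit(source=s, label=l) for s, l in zip(SOURCES, labels)]
            full = merge_calls(hits)
            for drop in SOURCES:
                reduced = merge_calls([h for h in hits if h.source != drop])
                if full is None:
                    assert reduced is None

    def test_best_evalue_kept_per_source(self):
        hits = [
            make_hit(source="HMMER", label="GH13", evalue=1e-5),
            make_hit(source="HMMER", label="GH16", evalue=1e-40),
            make_hit(source="eCAMI", label="GH16"),
        ]
        assert merge_calls(hits).family == "GH16"

    def test_multilabel_intersection_counts_as_agreement(self):
        hits = [
            make_hit(source="HMMER", label="GH16,GH30"),
            make_hit(source="DIAMOND", label="GH30"),
        ]
        assert merge_calls(hits).family == "GH30"


class TestEcFilter:
    @pytest.mark.parametrize(
        "coverage,identity,expected",
        [
            (0.40, 0.30, True),   # inclusive boundary
            (0.39, 0.95, False),  # below coverage bound
            (0.95, 0.29, False),  # below identity bound
            (1.0, 1.0, True),
            (0.0, 0.0, False),
        ],
    )
    def test_boundaries(self, config, coverage, identity, expected):
        hit = make_hit(coverage=coverage, identity=identity, ec="3.2.1.21")
        assert accept_ec(hit, config) is expected

    def test_grid_is_upper_right_rectangle(self, config):
        grid = [round(0.1 * i, 1) for i in range(11)]
        for cov in grid:
            for ident in grid:
                hit = make_hit(coverage=cov, identity=ident, ec="3.2.1.21")
                assert accept_ec(hit, config) == (cov >= 0.40 and ident >= 0.30)

    @given(
        cov=st.floats(0, 1), ident=st.floats(0, 1),
        cov2=st.floats(0, 1), ident2=st.floats(0, 1),
    )
    @settings(derandomize=True, max_examples=200, deadline=None)
    def test_monotone_in_both_arguments(self, cov, ident, cov2, ident2):
        cfg = PipelineConfig()
        a = accept_ec(make_hit(coverage=cov, identity=ident, ec="x"), cfg)
        b = accept_ec(
            make_hit(coverage=max(cov, cov2), identity=max(ident, ident2), ec="x"),
            cfg,
        )
        assert b or not a  # raising either argument never loses acceptance

    def test_requires_ec(self, config):
        with pytest.raises(ValueError):
            accept_ec(make_hit(ec=None), config)


class TestSulfataseFilter:
    def test_inclusive_boundary_accepted(self, config):
        hit = make_hit(label="S1_15", coverage=0.50, identity=0.30,
                       domains={"PF00884"})
        call = accept_sulfatase(hit, config)
        assert call is not None and call.s1_family == "S1_15"

    def test_missing_domain_rejected(self, config):
        hit = make_hit(label="S1_15", coverage=0.90, identity=0.80)
        assert accept_sulfatase(hit, config) is None

    @pytest.mark.parametrize("coverage,identity", [(0.49, 0.9), (0.9, 0.29)])
    def test_below_threshold_rejected(self, config, coverage, identity):
        hit = make_hit(label="S1_7", coverage=coverage, identity=identity,
                       domains={"PF00884"})
        assert accept_sulfatase(hit, config) is None

    @given(st.data())
    @settings(derandomize=True, max_examples=200, deadline=None)
    def test_raising_thresholds_never_grows_accepted_set(self, data):
        hits = [
            make_hit(
                protein=f"p{i}",
                label="S1_15",
                coverage=data.draw(st.floats(0, 1)),
                identity=data.draw(st.floats(0, 1)),
                domains={"PF00884"} if data.draw(st.booleans()) else set(),
            )
            for i in range(10)
        ]
        lo = PipelineConfig(sulf_min_coverage=0.5)
        hi = PipelineConfig(sulf_min_coverage=0.6)
        accepted_lo = {h.protein_id for h in hits if accept_sulfatase(h, lo)}
        accepted_hi = {h.protein_id for h in hits if accept_sulfatase(h, hi)}
        assert accepted_hi <= accepted_lo


class TestMagFilter:
    def _meta(self, completeness, contamination):
        return MagMeta(
            mag_id="M1",
            taxonomy=("Bacteria",) + ("unclassified",) * 6,
            completeness=completeness,
            contamination=contamination,
            n_genes=1000,
            genome_size=2_000_000,
        )

    def test_retained_range_is_kept(self):
        assert filter_mags([self._meta(75.0, 6.4)]) != []

    def test_below_completeness_rejected(self):
        assert filter_mags([self._meta(49.9, 5.0)]) == []

    def test_contamination_bound_is_strict(self):
        assert filter_mags([self._meta(99.5, 10.0)]) == []
        assert filter_mags([self._meta(99.5, 9.99)]) != []

    def test_order_independent(self):
        metas = [self._meta(60, 1), self._meta(40, 1), self._meta(80, 11)]
        for i, m in enumerate(metas):
            object.__setattr__(m, "mag_id", f"M{i}")
        kept = {m.mag_id for m in filter_mags(metas)}
        kept_rev = {m.mag_id for m in filter_mags(metas[::-1])}
        assert kept == kept_rev == {"M0"}
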