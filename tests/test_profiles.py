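import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cazpipe.config import PipelineConfig
from cazpipe.io import MagMeta, SampleMeta
from cazpipe.profiles import (
    MagProfile,
    bray_curtis_matrix,
    cazyme_density,
    compare_density_classes,
    genus_section_summary,
    pool_enzyme_counts,
)

from oracles import bray_curtis, kruskal_h, ranksum_exact


def _meta(mag="M1", n_genes=2000, genome_size=2_500_000, genus="Alistipes"):
    return MagMeta(
        mag_id=mag,
        taxonomy=("Bacteria", "Bacteroidota", "Bacteroidia", "Bacteroidales",
                  "Rikenellaceae", genus, f"{mag} sp."),
        completeness=90.0, contamination=1.0,
        n_genes=n_genes, genome_size=genome_size,
    )


def _calls(fams, mag="M1"):
    return pd.DataFrame(
        [(f"p{i}", mag, f) for i, f in enumerate(fams)],
        columns=["protein_id", "mag_id", "family"],
    )


def _profile(mag, cls, density, fams=None, n_genes=1000):
    return MagProfile(
        mag_id=mag, class_label=cls, genus_label="g", n_genes=n_genes,
        n_cazymes=sum((fams or {}).values()), density=density,
        family_counts=fams or {},
    )


class TestDensity:
    def test_per_1000_genes(self):
        p = cazyme_density(_meta(n_genes=2000), _calls(["GH3"] * 50))
        assert p.density == pytest.approx(25.0)
        assert p.n_cazymes == 50

    def test_zero_cazymes(self):
        p = cazyme_density(_meta(), _calls([]))
        assert p.density == 0.0

    def test_per_mbp_unit(self):
        cfg = PipelineConfig(density_unit="per_mbp")
        p = cazyme_density(_meta(genome_size=2_500_000), _calls(["GH3"] * 50), cfg)
        assert p.density == pytest.approx(20.0)

    def test_zero_genes_rejected(self):
        meta = _meta()
        object.__setattr__(meta, "n_genes", 0)
        with pytest.raises(ValueError):
            cazyme_density(meta, _calls([]))

    def test_subfamilies_collapse_in_family_counts(self):
        p = cazyme_density(_meta(), _calls(["GH13_10", "GH13_28"]))
        assert p.family_counts == {"GH13": 2}


class TestRankSum:
    def test_identical_multisets_give_p_near_one(self):
        profiles = [_profile(f"a{i}", "A", d) for i, d in enumerate([1, 2, 3])]
        profiles += [_profile(f"b{i}", "B", d) for i, d in enumerate([1, 2, 3])]
        _, p = compare_density_classes(profiles, "A", "B")
        assert p > 0.99

    def test_matches_exact_enumeration_oracle(self):
        a, b = [1.0, 2.0, 3.0], [10.0, 11.0, 12.0]
        profiles = [_profile(f"a{i}", "A", d) for i, d in enumerate(a)]
        profiles += [_profile(f"b{i}", "B", d) for i, d in enumerate(b)]
        w, p = compare_density_classes(profiles, "A", "B")
        w_exact, p_exact = ranksum_exact(a, b)
        assert w == pytest.approx(w_exact)
        assert p == pytest.approx(0.1)
        assert p == pytest.approx(p_exact)

    @pytest.mark.parametrize(
        "a,b",
        [
            ([1.0, 5.0, 2.0], [3.0, 4.0, 8.0, 9.0]),
            ([4.0, 1.0, 6.0, 2.0], [3.0, 5.0, 8.0, 7.0]),
        ],
    )
    def test_statistic_matches_oracle_on_small_samples(self, a, b):
        profiles = [_profile(f"a{i}", "A", d) for i, d in enumerate(a)]
        profiles += [_profile(f"b{i}", "B", d) for i, d in enumerate(b)]
        w, p = compare_density_classes(profiles, "A", "B")
        w_exact, p_exact = ranksum_exact(a, b)
        assert w == pytest.approx(w_exact)
        assert p == pytest.approx(p_exact, abs=1e-9)

    def test_tied_data_keeps_exact_statistic(self):
        """Ties switch the p-value to the corrected normal approximation,
        but the rank-sum statistic itself still matches the oracle."""
        a, b = [2.0, 2.0, 7.0, 1.0], [5.0, 6.0, 3.0, 9.0]
        profiles = [_profile(f"a{i}", "A", d) for i, d in enumerate(a)]
        profiles += [_profile(f"b{i}", "B", d) for i, d in enumerate(b)]
        w, p = compare_density_classes(profiles, "A", "B")
        w_exact, _ = ranksum_exact(a, b)
        assert w == pytest.approx(w_exact)
        assert 0 < p <= 1

    def test_small_class_rejected(self):
        profiles = [_profile("a", "A", 1.0), _profile("b1", "B", 1.0),
                    _profile("b2", "B", 2.0)]
        with pytest.raises(ValueError):
            compare_density_classes(profiles, "A", "B")


class TestBrayCurtis:
    def test_identical_profiles_zero(self):
        ps = [_profile("a", "A", 1, {"GH3": 2, "PL6": 1}),
              _profile("b", "A", 1, {"GH3": 2, "PL6": 1})]
        m = bray_curtis_matrix(ps, feature="counts")
        assert m.loc["a", "b"] == pytest.approx(0.0)

    def test_disjoint_supports_one(self):
        ps = [_profile("a", "A", 1, {"GH3": 2}), _profile("b", "A", 1, {"PL6": 3})]
        m = bray_curtis_matrix(ps, feature="counts")
        assert m.loc["a", "b"] == pytest.approx(1.0)

    def test_direct_formula_value(self):
        ps = [_profile("a", "A", 1, {"f1": 1, "f2": 2}),
              _profile("b", "A", 1, {"f1": 2, "f2": 1})]
        m = bray_curtis_matrix(ps, feature="counts")
        assert m.loc["a", "b"] == pytest.approx(1 / 3)
        assert m.loc["a", "b"] == pytest.approx(bray_curtis([1, 2], [2, 1]))

    def test_symmetric_zero_diagonal_bounded(self, default_community):
        _, _, _, results = default_community
        m = results["bray_curtis"]
        v = m.values
        finite = np.isfinite(v)
        assert (v[finite] >= 0).all() and (v[finite] <= 1 + 1e-12).all()
        assert np.allclose(v, v.T, equal_nan=True)
        assert np.allclose(np.diag(v), 0)

    def test_all_zero_pair_flagged_nan(self):
        ps = [_profile("a", "A", 0, {}), _profile("b", "A", 0, {}),
              _profile("c", "A", 1, {"GH3": 1})]
        m = bray_curtis_matrix(ps, feature="counts")
        assert np.isnan(m.loc["a", "b"])
        assert m.loc["a", "c"] == pytest.approx(1.0)

    def test_density_feature_scales_by_gene_count(self):
        # same composition at different assembly sizes -> dissimilarity 0
        ps = [_profile("a", "A", 1, {"GH3": 2, "PL6": 2}, n_genes=1000),
              _profile("b", "A", 1, {"GH3": 4, "PL6": 4}, n_genes=2000)]
        m = bray_curtis_matrix(ps, feature="density")
        assert m.loc["a", "b"] == pytest.approx(0.0)


def _samples(n_fish=3, sections=("IV", "V")):
    return [
        SampleMeta(f"S{f}_{sec}", f"fish{f}", sec)
        for f in range(1, n_fish + 1)
        for sec in sections
    ]


class TestSectionSummary:
    def _abundance(self, values_by_section, samples, mag="M1"):
        rows = {}
        counters = {sec: 0 for sec in values_by_section}
        for s in samples:
            rows[s.sample_id] = [values_by_section[s.section][counters[s.section]]]
            counters[s.section] += 1
        return pd.DataFrame.from_dict(rows, orient="index", columns=[mag])

    def test_identical_sections_give_h0_p1(self):
        samples = _samples(3)
        ab = self._abundance({"IV": [5, 5, 5], "V": [5, 5, 5]}, samples)
        df = genus_section_summary(ab, samples, [_meta()], "genus")
        assert (df["kw_h"] == 0).all() and (df["kw_p"] == 1).all()

    def test_h_matches_formula_oracle(self):
        samples = _samples(3)
        ab = self._abundance({"IV": [1, 2, 3], "V": [4, 5, 6]}, samples)
        df = genus_section_summary(ab, samples, [_meta()], "genus")
        h = df["kw_h"].iloc[0]
        assert h == pytest.approx(kruskal_h([[1, 2, 3], [4, 5, 6]]))
        assert df["kw_p"].iloc[0] == pytest.approx(stats.chi2.sf(h, 1))

    def test_means_and_sds_per_section(self):
        samples = _samples(3)
        ab = self._abundance({"IV": [10, 20, 30], "V": [40, 50, 60]}, samples)
        df = genus_section_summary(ab, samples, [_meta()], "genus")
        iv = df[df["section"] == "IV"].iloc[0]
        assert iv["mean_pct"] == pytest.approx(20.0)
        assert iv["sd_pct"] == pytest.approx(10.0)


class TestPooledCounts:
    def test_direct_sum(self, catalog):
        calls = pd.DataFrame(
            [("p1", "M1", "GH3"), ("p2", "M1", "GH3"), ("p3", "M1", "GH3"),
             ("p4", "M2", "GH3")],
            columns=["protein_id", "mag_id", "family"],
        )
        metas = [_meta("M1"), _meta("M2")]
        df = pool_enzyme_counts(calls, {"B1": ["M1", "M2"]}, metas, catalog)
        row = df[(df["group"] == "B1") & (df["enzyme_label"] == "beta-glucosidase")].iloc[0]
        assert row["gene_count"] == 4 and row["mag_count"] == 2
        assert row["weight_class"] == "LMW"

    def test_absent_enzyme_has_no_row(self, catalog):
        calls = pd.DataFrame(
            [("p1", "M1", "GH3")], columns=["protein_id", "mag_id", "family"]
        )
        df = pool_enzyme_counts(calls, {"B1": ["M1"]}, [_meta("M1")], catalog)
        assert "lambda-carrageenase" not in set(df["enzyme_label"])

    def test_ungrouped_mags_pooled_separately(self, catalog):
        calls = pd.DataFrame(
            [("p1", "M9", "GH3")], columns=["protein_id", "mag_id", "family"]
        )
        df = pool_enzyme_counts(calls, {"B1": ["M1"]}, [_meta("M9")], catalog)
        assert set(df["group"]) == {"ungrouped"}
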