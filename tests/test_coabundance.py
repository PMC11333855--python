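import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cazpipe.coabundance import (
    correlate,
    delineate_groups,
    group_capability_panel,
    section_fold_change,
)
from cazpipe.io import SampleMeta
from cazpipe.synthetic import Block, sample_abundances

from oracles import pearson_formula


def _ab(data: dict, samples=None) -> pd.DataFrame:
    df = pd.DataFrame(data)
    df.index = samples or [f"s{i}" for i in range(len(df))]
    return df


class TestCorrelate:
    def test_identical_vectors_r_one(self):
        ab = _ab({"a": [1, 2, 3, 4], "b": [1, 2, 3, 4]})
        corr = correlate(ab)
        assert corr.r.loc["a", "b"] == pytest.approx(1.0)
        assert corr.p.loc["a", "b"] == 0.0

    def test_perfect_anticorrelation(self):
        ab = _ab({"a": [1, 2, 3, 4], "b": [4, 3, 2, 1]})
        assert correlate(ab).r.loc["a", "b"] == pytest.approx(-1.0)

    def test_matches_independent_formula_and_scipy(self):
        x, y = [1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 5.0]
        corr = correlate(_ab({"a": x, "b": y}))
        r_ref = pearson_formula(x, y)
        r_scipy, p_scipy = stats.pearsonr(x, y)
        assert corr.r.loc["a", "b"] == pytest.approx(r_ref, abs=1e-12)
        assert corr.r.loc["a", "b"] == pytest.approx(r_scipy, abs=1e-12)
        assert corr.p.loc["a", "b"] == pytest.approx(p_scipy, abs=1e-12)

    def test_fewer_than_three_samples_rejected(self):
        with pytest.raises(ValueError):
            correlate(_ab({"a": [1, 2], "b": [2, 1]}))

    def test_constant_mags_excluded_with_warning(self):
        ab = _ab({"a": [1, 2, 3, 4], "b": [5, 5, 5, 5]})
        with pytest.warns(UserWarning, match="constant"):
            corr = correlate(ab)
        assert list(corr.r.columns) == ["a"]

    def test_symmetry_and_unit_diagonal(self, default_community):
        _, _, _, results = default_community
        corr = results["correlation"]
        assert np.allclose(corr.r.values, corr.r.values.T, atol=1e-12)
        assert np.allclose(np.diag(corr.r.values), 1.0)
        assert np.allclose(corr.p.values, corr.p.values.T, atol=1e-12)


SAMPLES_IVV = [
    SampleMeta(f"S{f}_{sec}", f"fish{f}", sec)
    for f in range(1, 4)
    for sec in ("IV", "V")
]


class TestFoldChange:
    def _ab(self, iv, v):
        data = {"M1": []}
        idx = []
        for f, (a, b) in enumerate(zip(iv, v), start=1):
            data["M1"] += [a, b]
            idx += [f"S{f}_IV", f"S{f}_V"]
        return pd.DataFrame(data, index=idx)

    def test_tenfold_increase(self):
        ab = self._ab([1.0] * 3, [10.0] * 3)
        (fc,) = section_fold_change(ab, SAMPLES_IVV, epsilon=0.0)
        assert fc.log10_fc == pytest.approx(1.0)

    def test_equal_means_zero(self):
        ab = self._ab([2.0] * 3, [2.0] * 3)
        (fc,) = section_fold_change(ab, SAMPLES_IVV, epsilon=0.0)
        assert fc.log10_fc == pytest.approx(0.0)

    def test_pseudocount_guards_zero_mean(self):
        ab = self._ab([0.0] * 3, [1.0] * 3)
        (fc,) = section_fold_change(ab, SAMPLES_IVV, epsilon=0.01)
        assert fc.log10_fc == pytest.approx(np.log10(1.01 / 0.01))
        assert fc.log10_fc == pytest.approx(2.0043, abs=1e-4)

    def test_absent_mag_omitted(self):
        ab = self._ab([0.0] * 3, [0.0] * 3)
        assert section_fold_change(ab, SAMPLES_IVV) == []


class TestGroups:
    def test_no_significant_pairs_gives_zero_groups(self):
        rng = np.random.default_rng(42)
        ab = pd.DataFrame(
            rng.lognormal(0, 1, size=(10, 6)),
            index=[f"s{i}" for i in range(10)],
            columns=[f"M{i}" for i in range(6)],
        )
        groups = delineate_groups(correlate(ab), alpha=1e-6)
        assert groups == []

    def test_single_strong_pair_forms_two_member_group(self):
        rng = np.random.default_rng(0)
        base = rng.lognormal(0, 1, size=12)
        ab = pd.DataFrame(
            {
                "M1": base * rng.lognormal(0, 0.05, 12),
                "M2": base * rng.lognormal(0, 0.05, 12),
                "M3": rng.lognormal(0, 1, 12),
            },
            index=[f"s{i}" for i in range(12)],
        )
        groups = delineate_groups(correlate(ab))
        assert len(groups) == 1
        assert sorted(groups[0].members) == ["M1", "M2"]
        assert groups[0].mean_within_r > 0.9

    def test_planted_blocks_recovered(self):
        rng = np.random.default_rng(17)
        mags = [f"M{i}" for i in range(9)]
        samples = [
            SampleMeta(f"s{i}", f"fish{i // 2 + 1}", "IV" if i % 2 == 0 else "V")
            for i in range(12)
        ]
        ab = sample_abundances(
            {m: 10.0 for m in mags},
            [Block(mags[:5], sd=0.8), Block(mags[5:], sd=0.8)],
            samples,
            rng,
        )
        groups = delineate_groups(correlate(ab))
        assert sorted(sorted(g.members) for g in groups) == [
            sorted(mags[:5]), sorted(mags[5:])
        ]

    def test_output_invariant_to_mag_order(self):
        rng = np.random.default_rng(3)
        mags = [f"M{i}" for i in range(6)]
        samples = [
            SampleMeta(f"s{i}", f"fish{i // 2 + 1}", "IV" if i % 2 == 0 else "V")
            for i in range(10)
        ]
        ab = sample_abundances(
            {m: 10.0 for m in mags},
            [Block(mags[:3], sd=0.8), Block(mags[3:], sd=0.8)],
            samples,
            rng,
        )
        g1 = delineate_groups(correlate(ab))
        g2 = delineate_groups(correlate(ab[ab.columns[::-1]]))
        assert sorted(sorted(g.members) for g in g1) == sorted(
            sorted(g.members) for g in g2
        )

    def test_group_labels_follow_section_trend(self, default_community):
        _, _, truth, results = default_community
        for g in results["groups"]:
            if g.section_trend == "IV-enriched":
                assert g.group_id.startswith("A")
            else:
                assert g.group_id.startswith("B")


class TestGroupPanel:
    def test_group_without_substrate_calls_has_no_rows(self, catalog):
        from cazpipe.coabundance import CoabundGroup

        groups = [CoabundGroup("B1", ["M1"], 0.9)]
        calls = pd.DataFrame(columns=["protein_id", "mag_id", "family"])
        df = group_capability_panel(groups, calls, catalog)
        assert len(df) == 0

    def test_single_mag_group_mirrors_its_profile(self, catalog):
        from cazpipe.coabundance import CoabundGroup

        groups = [CoabundGroup("B1", ["M1"], 0.9)]
        calls = pd.DataFrame(
            [("p1", "M1", "PL6"), ("p2", "M1", "GH3")],
            columns=["protein_id", "mag_id", "family"],
        )
        df = group_capability_panel(groups, calls, catalog)
        alg = df[(df["substrate"] == "alginate") & (df["weight_class"] == "HMW")].iloc[0]
        lam = df[(df["substrate"] == "laminarin") & (df["weight_class"] == "LMW")].iloc[0]
        assert alg["gene_count"] == 1 and alg["mag_fraction"] == 1.0
        assert lam["gene_count"] == 1

    def test_missing_hmw_capacity_visible_in_panel(self, catalog):
        """A group rich in exo enzymes but lacking endo-laminarinase shows
        LMW-laminarin rows without HMW-laminarin rows."""
        from cazpipe.coabundance import CoabundGroup

        groups = [CoabundGroup("B3", ["M1", "M2"], 0.9)]
        calls = pd.DataFrame(
            [("p1", "M1", "GH3"), ("p2", "M2", "GH3"), ("p3", "M1", "GH2")],
            columns=["protein_id", "mag_id", "family"],
        )
        df = group_capability_panel(groups, calls, catalog)
        lam = df[df["substrate"] == "laminarin"]
        assert set(lam["weight_class"]) == {"LMW"}
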