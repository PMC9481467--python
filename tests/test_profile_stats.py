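"""Profiling: relative abundance, 5% prevalence bins, LOW/MEDIUM groups,
core-microbiota test, alpha diversity, the Wilcoxon signed-rank test, and
annotation summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from opucall.profile_stats import (
    AnnotationTable,
    build_opu_table,
    chao1,
    core_microbiota_test,
    group_prevalence,
    paired_wilcoxon,
    prevalence_bin,
    prevalence_profile,
    relative_abundance,
    round_half_up,
    shannon,
    summarize_annotations,
)
from opucall.seq_io import ManifestRow, SampleManifest


class TestOpuTable:
    def test_two_by_two_hand_count(self):
        table = build_opu_table(
            {"S1": {"OPU_1": 10, "OPU_2": 5}, "S2": {"OPU_1": 3}}
        )
        assert table.loc["OPU_1", "S1"] == 10
        assert table.loc["OPU_2", "S2"] == 0  # absent OPU is zero
        assert table.values.sum() == 18

    def test_relative_abundance_normalizes_columns(self):
        table = build_opu_table({"S1": {"A": 10, "B": 30}, "S2": {"A": 7}})
        rel = relative_abundance(table)
        assert rel["S1"].tolist() == [0.25, 0.75]
        assert rel["S2"].tolist() == [1.0, 0.0]
        scaled = relative_abundance(table * 1000)
        assert np.allclose(scaled.values, rel.values)

    def test_zero_total_sample_named_in_error(self):
        table = pd.DataFrame({"S1": [1], "S2": [0]}, index=["A"])
        with pytest.raises(ValueError, match="S2"):
            relative_abundance(table)


def _survey_scaled_table():
    """1,731 OPUs x 196 samples with a survey-scale prevalence layout:
    1,480 OPUs in <5% of samples, 151 in 5-10%, 53 in 10-15%, and 47 in the
    medium group topping out at 55% of the eyes."""
    n_samples = 196
    presence = (
        [1 + i % 9 for i in range(1480)]  # < 9.8 samples: <5%
        + [10 + i % 10 for i in range(151)]  # <10%
        + [20 + i % 10 for i in range(53)]  # <15%
        + [30 + i % 77 for i in range(46)]  # medium, < 55%
        + [107]  # the single 55% OPU
    )
    mat = np.zeros((len(presence), n_samples), dtype=int)
    for i, k in enumerate(presence):
        cols = [(i + j) % n_samples for j in range(k)]
        mat[i, cols] = 1
    return pd.DataFrame(
        mat,
        index=[f"OPU_{i + 1:04d}" for i in range(len(presence))],
        columns=[f"S{j + 1:03d}" for j in range(n_samples)],
    )


class TestPrevalence:
    def test_bins_partition_unit_interval(self):
        assert prevalence_bin(0.0) == 0
        assert prevalence_bin(1 / 196) == 0
        assert prevalence_bin(0.05) == 1
        assert prevalence_bin(0.9999) == 19
        assert prevalence_bin(1.0) == 19  # final bin closed

    def test_single_presence_is_low(self):
        table = pd.DataFrame(
            np.eye(1, 196, dtype=int), index=["OPU_1"],
            columns=[f"S{j}" for j in range(196)],
        )
        profile = prevalence_profile(table)
        row = profile.per_opu.loc["OPU_1"]
        assert row["prevalence"] == pytest.approx(1 / 196)
        assert row["bin"] == 0 and row["group"] == "LOW"

    def test_ubiquitous_opu_is_medium_top_bin(self):
        table = pd.DataFrame(
            np.ones((1, 10), dtype=int), index=["OPU_1"],
            columns=[f"S{j}" for j in range(10)],
        )
        row = prevalence_profile(table).per_opu.loc["OPU_1"]
        assert row["prevalence"] == 1.0 and row["bin"] == 19
        assert row["group"] == "MEDIUM"

    def test_survey_scale_low_prevalence_split(self):
        table = _survey_scaled_table()
        profile = prevalence_profile(table)
        assert profile.low_count == 1684
        assert round_half_up(100 * profile.low_count / 1731, 2) == 97.28
        assert profile.medium_count == 47
        lt5 = int((profile.per_opu["prevalence"] < 0.05).sum())
        assert lt5 == 1480
        assert round_half_up(100 * lt5 / 1731, 1) == 85.5
        assert profile.per_bin["opu_count"].sum() == 1731
        shares = profile.group_read_share(table)
        assert shares["LOW"] + shares["MEDIUM"] == pytest.approx(1.0)

    def test_no_core_in_survey_scale_profile(self):
        profile = prevalence_profile(_survey_scaled_table())
        assert profile.per_opu["prevalence"].max() <= 0.55
        assert core_microbiota_test(profile) == []

    def test_synthetic_core_detected(self):
        mat = np.zeros((3, 10), dtype=int)
        mat[0, :9] = 4  # 90% of samples
        mat[1, 0] = 1
        mat[2, 1] = 2
        table = pd.DataFrame(mat, index=["core", "r1", "r2"],
                             columns=[f"S{j}" for j in range(10)])
        profile = prevalence_profile(table)
        assert core_microbiota_test(profile) == ["core"]
        assert sorted(core_microbiota_test(profile, core_cutoff=0.0)) == [
            "core", "r1", "r2",
        ]


class TestAlphaDiversity:
    def test_shannon_uniform_closed_form(self):
        assert shannon([5, 5, 5, 5]) == pytest.approx(np.log(4))

    def test_single_taxon_degenerate(self):
        assert shannon([7]) == 0.0
        assert chao1([7]) == 1.0

    def test_chao1_formula_arithmetic(self):
        # S_obs = 10, F1 = 4, F2 = 2 -> 10 + 4*3/(2*3) = 12
        counts = [1, 1, 1, 1, 2, 2, 3, 4, 5, 6]
        assert chao1(counts) == 12.0

    def test_chao1_never_below_observed_richness(self, rng):
        for _ in range(20):
            counts = rng.integers(0, 5, size=30)
            if counts.sum() == 0:
                continue
            assert chao1(counts) >= (counts > 0).sum()

    def test_shannon_maximal_at_uniform(self, rng):
        uniform = shannon([10] * 8)
        for _ in range(10):
            skewed = rng.integers(1, 50, size=8)
            assert shannon(skewed) <= uniform + 1e-12

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            shannon([0, 0])
        with pytest.raises(ValueError):
            chao1([0, 0])


def _enumerated_p(diff):
    """Exact two-sided p by brute force over all sign assignments."""
    diff = np.asarray(diff, dtype=float)
    diff = diff[diff != 0]
    n = len(diff)
    ranks = sps.rankdata(np.abs(diff))
    w_obs = min(ranks[diff > 0].sum(), ranks[diff < 0].sum())
    count = 0
    for signs in itertools.product((0, 1), repeat=n):
        w_plus = sum(r for s, r in zip(signs, ranks) if s)
        if w_plus <= w_obs + 1e-9:
            count += 1
    return min(1.0, 2 * count / 2**n)


class TestPairedWilcoxon:
    def test_identical_vectors_p_one(self):
        with pytest.warns(UserWarning):
            out = paired_wilcoxon([1, 2, 3, 4, 5, 6], [1, 2, 3, 4, 5, 6])
        assert out["p_value"] == 1.0

    def test_doubling_pairs_exact_tail(self):
        left = [1, 2, 3, 4, 5, 6]
        right = [2, 4, 6, 8, 10, 12]
        out = paired_wilcoxon(left, right)
        assert out["statistic"] == 0.0
        assert out["p_value"] == pytest.approx(2 / 64)

    @pytest.mark.parametrize("seed", range(12))
    def test_exact_p_matches_sign_enumeration(self, seed):
        rng = np.random.default_rng(4000 + seed)
        n = int(rng.integers(4, 11))
        # integer differences create ties; enumeration handles them too
        left = rng.integers(0, 6, size=n).astype(float)
        right = rng.integers(0, 6, size=n).astype(float)
        if np.all(left == right):
            left[0] += 1
        ours = paired_wilcoxon(left, right)["p_value"]
        assert ours == pytest.approx(_enumerated_p(left - right), abs=1e-12)

    def test_matches_scipy_exact_without_ties(self, rng):
        left = rng.normal(size=14)
        right = rng.normal(size=14)
        ours = paired_wilcoxon(left, right)
        ref = sps.wilcoxon(left, right, mode="exact")
        assert ours["p_value"] == pytest.approx(ref.pvalue)

    def test_matches_scipy_normal_approximation(self, rng):
        left = rng.normal(size=67)
        right = left + rng.normal(scale=0.5, size=67)
        ours = paired_wilcoxon(left, right)
        ref = sps.wilcoxon(left, right, mode="approx", correction=True)
        assert ours["p_value"] == pytest.approx(ref.pvalue, rel=1e-9)


class TestGroupPrevalence:
    def _manifest(self, groups):
        rows = [
            ManifestRow(f"S{i:03d}", f"subj{i}", "L", g, "", False)
            for i, g in enumerate(groups)
        ]
        return SampleManifest(rows)

    def test_high_priority_fraction(self):
        groups = ["children"] * 21 + ["elderly"] * 10
        manifest = self._manifest(groups)
        mat = np.zeros((2, 31), dtype=int)
        mat[0, :17] = 1  # 17 of the 21 children samples: 80.95%
        mat[1, 21:] = 2
        table = pd.DataFrame(
            mat, index=["OPU_1", "OPU_2"],
            columns=[f"S{i:03d}" for i in range(31)],
        )
        out = group_prevalence(table, manifest)
        high = out["children"]["high_prevalence"]
        assert round_half_up(100 * high["OPU_1"], 2) == 80.95
        assert "OPU_1" not in out["elderly"]["high_prevalence"]

    def test_exactly_sixty_percent_not_listed(self):
        manifest = self._manifest(["youth"] * 20)
        mat = np.zeros((1, 20), dtype=int)
        mat[0, :12] = 1  # exactly 60%
        table = pd.DataFrame(mat, index=["OPU_1"],
                             columns=[f"S{i:03d}" for i in range(20)])
        out = group_prevalence(table, manifest)
        assert out["youth"]["high_prevalence"] == {}

    def test_richness_moments_hand_computed(self):
        manifest = self._manifest(["middle"] * 3)
        table = pd.DataFrame(
            [[1, 0, 2], [3, 1, 0], [0, 0, 5]],
            index=["A", "B", "C"],
            columns=["S000", "S001", "S002"],
        )
        out = group_prevalence(table, manifest)["middle"]
        assert out["mean_opus"] == pytest.approx(np.mean([2, 1, 2]))
        assert out["sd_opus"] == pytest.approx(np.std([2, 1, 2], ddof=1))

    def test_unmapped_sample_rejected(self):
        manifest = self._manifest(["youth"])
        table = pd.DataFrame([[1, 2]], index=["A"], columns=["S000", "SX"])
        with pytest.raises(ValueError, match="SX"):
            group_prevalence(table, manifest)


def _survey_annotation_fixture():
    """796 species with survey-scale origin-category, human-subsite,
    and infection-history counts."""
    categories = (
        [("environment", "")] * 294
        + [("human", "oral and upper respiratory tract")] * 91
        + [("human", "blood")] * 44
        + [("human", "intestinal and fecal")] * 40
        + [("human", "infected wounds and abscesses")] * 23
        + [("human", "skin")] * 16
        + [("human", "clinical effusion")] * 9
        + [("human", "eyes")] * 8
        + [("human", "uterus and vagina")] * 8
        + [("human", "other clinical samples")] * 36
        + [("plant", "")] * 72
        + [("animal", "")] * 39
        + [("food", "")] * 24
        + [("other", "")] * 92
    )
    assert len(categories) == 796
    records = {
        f"sp{i:04d}": {
            "origin_category": cat,
            "human_subsite": sub,
            "infection": i < 170,
        }
        for i, (cat, sub) in enumerate(categories)
    }
    species = sorted(records)
    return species, AnnotationTable.from_records(records)


class TestSummarizeAnnotations:
    def test_survey_scale_percentages(self):
        species, ann = _survey_annotation_fixture()
        out = summarize_annotations(species, ann)
        cats = {c: v["percent"] for c, v in out["categories"].items()}
        assert cats == {
            "environment": 36.93,
            "human": 34.55,
            "plant": 9.05,
            "animal": 4.90,
            "food": 3.02,
            "other": 11.56,
        }
        subs = {s: v for s, v in out["human_subsites"].items()}
        assert subs["oral and upper respiratory tract"] == {
            "count": 91,
            "percent": 33.09,
        }
        assert subs["blood"]["percent"] == 16.00
        assert subs["eyes"]["percent"] == 2.91
        assert out["infection"] == {"count": 170, "percent": 21.36}

    def test_no_flags_zero_percent(self):
        ann = AnnotationTable.from_records(
            {"spA": {"origin_category": "plant", "human_subsite": "", "infection": False}}
        )
        out = summarize_annotations(["spA"], ann)
        assert out["infection"] == {"count": 0, "percent": 0.00}

    def test_unannotated_species_counted(self):
        ann = AnnotationTable.from_records(
            {"spA": {"origin_category": "human", "human_subsite": "skin",
                     "infection": True}}
        )
        out = summarize_annotations(["spA", "mystery"], ann)
        assert out["unannotated"] == 1

    def test_subsite_on_nonhuman_rejected(self):
        with pytest.raises(ValueError):
            AnnotationTable.from_records(
                {"spA": {"origin_category": "plant", "human_subsite": "skin",
                         "infection": False}}
            )
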