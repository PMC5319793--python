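"""Variant calling, cutoff selection, FDR estimation, quantification."""

import numpy as np
import pandas as pd
import pytest

from editevol import discovery


def _pileup(rows):
    df = pd.DataFrame(rows, columns=["site_id", "sample_id", "ref_base",
                                     "n_A", "n_C", "n_G", "n_T"])
    df["coverage"] = df[["n_A", "n_C", "n_G", "n_T"]].sum(axis=1)
    return df


class TestCallVariants:
    def test_threshold_boundary(self):
        pu = _pileup([("s1", "x", "A", 98, 0, 2, 0),
                      ("s2", "x", "A", 99, 0, 1, 0)])
        calls = discovery.call_variants(pu, min_alt=2)
        assert len(calls) == 1
        c = calls[0]
        assert (c.site_id, c.mismatch) == ("s1", "A-to-G")
        assert c.level == pytest.approx(0.02)

    def test_bidirectional_sites_dropped(self):
        pu = _pileup([("s1", "x", "A", 50, 0, 50, 0)])
        calls = discovery.call_variants(pu, bidirectional_sites={"s1"})
        assert calls == []

    def test_multiple_mismatch_types(self):
        pu = _pileup([("s1", "x", "A", 90, 5, 5, 0)])
        calls = discovery.call_variants(pu)
        assert {c.mismatch for c in calls} == {"A-to-C", "A-to-G"}


class TestCutoffSelection:
    def test_smallest_passing_cutoff(self):
        curve = pd.DataFrame({"cutoff": [0.01, 0.05, 0.10],
                              "n_variants": [10, 10, 10],
                              "atog_fraction": [0.6, 0.75, 0.85]})
        cutoff, _ = discovery.select_frequency_cutoff(curve)
        assert cutoff == 0.10

    def test_all_pass_returns_smallest(self):
        curve = pd.DataFrame({"cutoff": [0.01, 0.05],
                              "n_variants": [5, 5],
                              "atog_fraction": [0.9, 0.95]})
        assert discovery.select_frequency_cutoff(curve)[0] == 0.01

    def test_none_pass_is_error_with_best(self):
        curve = pd.DataFrame({"cutoff": [0.01, 0.05],
                              "n_variants": [5, 5],
                              "atog_fraction": [0.5, 0.7]})
        with pytest.raises(ValueError, match="0.700"):
            discovery.select_frequency_cutoff(curve)


class TestSharedEditing:
    def _ortho(self, ids):
        return pd.DataFrame({"site_id": ids, "species_a": "a", "species_b": "b",
                             "contig_b": ids, "pos_b": 0, "strand_flip": False,
                             "site_id_b": ids})

    def test_retained_and_dropped_by_cutoff(self):
        pa = _pileup([("s1", "x", "A", 88, 0, 12, 0),
                      ("s2", "x", "A", 88, 0, 12, 0)])
        pb = _pileup([("s1", "x", "A", 88, 0, 12, 0),
                      ("s2", "x", "A", 92, 0, 8, 0)])
        ca = discovery.call_variants(pa)
        cb = discovery.call_variants(pb)
        out = discovery.identify_shared_editing(ca, cb, self._ortho(["s1", "s2"]),
                                                cutoff=0.10)
        assert list(out["site_id"]) == ["s1"]

    def test_conflicting_mismatch_types_excluded(self):
        pa = _pileup([("s1", "x", "A", 80, 0, 20, 0)])
        pb = _pileup([("s1", "x", "A", 80, 20, 0, 0)])  # A-to-C in species b
        out = discovery.identify_shared_editing(
            discovery.call_variants(pa), discovery.call_variants(pb),
            self._ortho(["s1"]), cutoff=0.10)
        assert len(out) == 0


class TestFdrWithNull:
    def test_zero_null_reads_is_genuine_without_testing(self):
        wt = _pileup([("s1", "wt", "A", 80, 0, 20, 0)])
        null = _pileup([("s1", "null", "A", 100, 0, 0, 0)])
        table, fdr = discovery.estimate_fdr_with_null(wt, null)
        assert table.loc[0, "status"] == "genuine"
        assert fdr == 0.0

    def test_identical_proportions_not_genuine(self):
        wt = _pileup([("s1", "wt", "A", 97, 0, 3, 0)])
        null = _pileup([("s1", "null", "A", 97, 0, 3, 0)])
        table, fdr = discovery.estimate_fdr_with_null(wt, null)
        assert table.loc[0, "status"] == "not_genuine"
        assert fdr == 1.0

    def test_missing_null_coverage_unevaluable(self):
        wt = _pileup([("s1", "wt", "A", 80, 0, 20, 0)])
        null = _pileup([("s2", "null", "A", 100, 0, 0, 0)])
        table, fdr = discovery.estimate_fdr_with_null(wt, null)
        assert table.loc[0, "status"] == "unevaluable"
        assert np.isnan(fdr)

    def test_candidate_thresholds(self):
        # 2 altered reads is not "more than two"; 1% level is below 1.5%
        wt = _pileup([("s1", "wt", "A", 98, 0, 2, 0),
                      ("s2", "wt", "A", 990, 0, 10, 0)])
        null = _pileup([("s1", "null", "A", 100, 0, 0, 0),
                        ("s2", "null", "A", 100, 0, 0, 0)])
        table, _ = discovery.estimate_fdr_with_null(wt, null)
        assert len(table) == 0


class TestQuantify:
    def test_level_is_g_over_a_plus_g(self):
        pu = _pileup([("s1", "x", "A", 75, 0, 25, 0)])
        lm = discovery.quantify_levels(pu, min_cov=20)
        assert lm.loc[0, "level"] == pytest.approx(0.25)

    def test_below_coverage_undefined(self):
        pu = _pileup([("s1", "x", "A", 15, 0, 4, 0)])
        lm = discovery.quantify_levels(pu, min_cov=20)
        assert len(lm) == 0

    def test_non_a_dna_base_is_level_zero(self):
        pu = _pileup([("s1", "x", "A", 10, 0, 90, 0)])
        lm = discovery.quantify_levels(pu, min_cov=20, dna_base={"s1": "G"})
        assert lm.loc[0, "level"] == 0.0
        assert bool(lm.loc[0, "non_a"])

    def test_scale_free(self):
        pu1 = _pileup([("s1", "x", "A", 60, 0, 40, 0)])
        pu3 = _pileup([("s1", "x", "A", 180, 0, 120, 0)])
        l1 = discovery.quantify_levels(pu1, 20).loc[0, "level"]
        l3 = discovery.quantify_levels(pu3, 20).loc[0, "level"]
        assert l1 == pytest.approx(l3)


class TestCombinePlatforms:
    def _mm(self, rows):
        return pd.DataFrame(rows, columns=["site_id", "sample_id", "replicate",
                                           "level", "coverage"])

    def test_replicate_mean_wins_over_rnaseq(self):
        rs = pd.DataFrame([("s1", "x", 0.5, 100, "rnaseq")],
                          columns=["site_id", "sample_id", "level", "coverage",
                                   "platform"])
        mm = self._mm([("s1", "x", 1, 0.30, 60), ("s1", "x", 2, 0.35, 60)])
        out = discovery.combine_platforms(rs, mm)
        assert len(out) == 1
        assert out.loc[0, "level"] == pytest.approx(0.325)
        assert out.loc[0, "platform"] == "mmpcr"

    def test_discordant_replicates_fall_back_to_rnaseq(self):
        rs = pd.DataFrame([("s1", "x", 0.5, 100, "rnaseq")],
                          columns=["site_id", "sample_id", "level", "coverage",
                                   "platform"])
        mm = self._mm([("s1", "x", 1, 0.30, 60), ("s1", "x", 2, 0.45, 60)])
        out = discovery.combine_platforms(rs, mm)
        assert out.loc[0, "platform"] == "rnaseq"
        assert out.loc[0, "level"] == 0.5

    def test_low_coverage_replicate_dropped(self):
        rs = pd.DataFrame([], columns=["site_id", "sample_id", "level",
                                       "coverage", "platform"])
        mm = self._mm([("s1", "x", 1, 0.30, 40), ("s1", "x", 2, 0.32, 60)])
        out = discovery.combine_platforms(rs, mm)
        assert len(out) == 0

    def test_rnaseq_only(self):
        rs = pd.DataFrame([("s1", "x", 0.2, 30, "rnaseq")],
                          columns=["site_id", "sample_id", "level", "coverage",
                                   "platform"])
        out = discovery.combine_platforms(rs, self._mm([]))
        assert out.loc[0, "level"] == 0.2


class TestRepresentativeLevel:
    def test_maximum_over_samples(self):
        lm = pd.DataFrame({"site_id": ["s1"] * 3, "sample_id": list("abc"),
                           "level": [0.05, 0.40, 0.12],
                           "coverage": [30, 30, 30]})
        rep = discovery.representative_level(lm)
        assert rep["s1"] == pytest.approx(0.40)

    def test_single_entry(self):
        lm = pd.DataFrame({"site_id": ["s1"], "sample_id": ["a"],
                           "level": [0.07], "coverage": [25]})
        assert discovery.representative_level(lm)["s1"] == pytest.approx(0.07)

    def test_all_below_coverage_undefined(self):
        lm = pd.DataFrame({"site_id": ["s1"], "sample_id": ["a"],
                           "level": [0.5], "coverage": [10]})
        rep = discovery.representative_level(lm)
        assert "s1" not in rep.index
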