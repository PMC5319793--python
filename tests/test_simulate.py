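"""The synthetic-data generator: its stated statistical structure."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as scistats

from editevol import simulate, structure, utr3


def test_zero_branch_lengths_freeze_levels():
    tree = "(((((a:0,b:0):0,c:0):0,d:0):0,e:0):0,f:0);"
    cfg = simulate.SimConfig(tree=tree, anchor="a", n_sites=50, rng_seed=1)
    levels, truth = simulate.simulate_levels(cfg)
    for _, row in levels.iterrows():
        nz = row[row > 0]
        if len(nz) > 1:
            assert nz.nunique() == 1  # every descendant equals the birth level


def test_zero_walk_sd_keeps_levels_identical():
    cfg = simulate.SimConfig(n_sites=50, rng_seed=2, level_walk_sd=0.0)
    levels, _ = simulate.simulate_levels(cfg)
    for _, row in levels.iterrows():
        nz = row[row > 0]
        if len(nz) > 1:
            assert nz.nunique() == 1


def test_walk_divergence_grows_with_path_distance():
    """Mean |level difference| between leaves increases with path time
    (Monte-Carlo against the random-walk variance over 20 replicates)."""
    diffs_close, diffs_far = [], []
    for seed in range(20):
        cfg = simulate.SimConfig(n_sites=80, rng_seed=seed, level_walk_sd=0.03)
        levels, _ = simulate.simulate_levels(cfg)
        both = levels[(levels["mel"] > 0) & (levels["sim"] > 0) & (levels["vir"] > 0)]
        if len(both):
            diffs_close.append(np.abs(both["mel"] - both["sim"]).mean())
            diffs_far.append(np.abs(both["mel"] - both["vir"]).mean())
    assert np.mean(diffs_far) > np.mean(diffs_close)


def test_species_outside_birth_clade_have_zero_level():
    cfg = simulate.SimConfig(n_sites=100, rng_seed=3)
    levels, truth = simulate.simulate_levels(cfg)
    born_root = truth.sites["birth_branch"] == "root"
    # sites not born at the root must leave at least one species at 0
    non_root = levels[~born_root.to_numpy()]
    assert ((non_root == 0).any(axis=1)).all()


class TestReads:
    def test_zero_level_zero_error_gives_no_g(self):
        cfg = simulate.SimConfig(tree="(a:1,b:1);", anchor="a", rng_seed=1,
                                 error_rate=0.0)
        levels = pd.DataFrame({"a": [0.0] * 20, "b": [0.0] * 20},
                              index=[f"s{i}" for i in range(20)])
        pileup = simulate.simulate_reads(levels, cfg, samples=("x",))
        assert (pileup["n_G"] == 0).all()
        assert (pileup["n_C"] == 0).all() and (pileup["n_T"] == 0).all()

    def test_full_level_approaches_coverage(self):
        cfg = simulate.SimConfig(tree="(a:1,b:1);", anchor="a", rng_seed=1,
                                 error_rate=0.0, coverage_mean=200)
        levels = pd.DataFrame({"a": [1.0] * 20, "b": [1.0] * 20},
                              index=[f"s{i}" for i in range(20)])
        pileup = simulate.simulate_reads(levels, cfg, samples=("x",),
                                         null_sample=False)
        assert (pileup["n_G"] == pileup["coverage"]).all()

    def test_observed_level_matches_binomial_expectation(self):
        """Mean observed level over 1000 sites ~ level + err*(1-level)."""
        cfg = simulate.SimConfig(tree="(a:1,b:1);", anchor="a", rng_seed=5,
                                 coverage_mean=500, coverage_dispersion=20)
        level = 0.30
        levels = pd.DataFrame({"a": [level] * 1000, "b": [0.0] * 1000},
                              index=[f"s{i}" for i in range(1000)])
        pileup = simulate.simulate_reads(levels, cfg, samples=("x",),
                                         null_sample=False)
        a = pileup[pileup["sample_id"] == "a_x"]
        obs = (a["n_G"] / a["coverage"]).mean()
        assert obs == pytest.approx(level + 0.01 * (1 - level), abs=0.01)

    def test_null_sample_is_error_only(self):
        cfg = simulate.SimConfig(tree="(a:1,b:1);", anchor="a", rng_seed=5,
                                 coverage_mean=500)
        levels = pd.DataFrame({"a": [0.8] * 200, "b": [0.0] * 200},
                              index=[f"s{i}" for i in range(200)])
        pileup = simulate.simulate_reads(levels, cfg, samples=("x",))
        null = pileup[pileup["sample_id"] == "a_adar_null"]
        assert (null["n_G"] / null["coverage"]).mean() == pytest.approx(0.01, abs=0.005)


class TestSequences:
    def test_planted_stem_recovered(self, small_sequences):
        cfg, truth, seqs, _ = small_sequences
        planted = truth.sites[truth.sites["stem_np"] > 0]
        assert len(planted) > 5
        for _, row in planted.head(10).iterrows():
            seq = seqs[truth.anchor][row["site_id"]]
            cands = structure.fold_window(seq, simulate.SITE_OFFSET)
            best = structure.find_proximal_ecs(cands, simulate.SITE_OFFSET,
                                               sequence=seq)
            assert best is not None
            assert best.n_pairs >= 20

    def test_uncoupled_stems_independent_of_levels(self):
        cfg = simulate.SimConfig(n_sites=500, rng_seed=6, motif_effect=0.0,
                                 structure_effect=0.0)
        levels, truth = simulate.simulate_levels(cfg)
        simulate.simulate_sequences(truth, cfg)
        anchor = truth.levels[truth.anchor]
        edited = anchor > 0
        np_vals = truth.sites["stem_np"].to_numpy()[edited.to_numpy()]
        lv = anchor[edited].to_numpy()
        if np.std(np_vals) > 0:
            r = np.corrcoef(np_vals, lv)[0, 1]
            assert abs(r) < 0.12

    def test_logistic_link_recovered(self):
        """Coupled regime: level rises with planted paired-base count."""
        cfg = simulate.SimConfig(n_sites=500, rng_seed=7, structure_effect=1.5)
        levels, truth = simulate.simulate_levels(cfg)
        simulate.simulate_sequences(truth, cfg)
        has_stem = truth.sites["stem_np"] > 0
        x = truth.sites.loc[has_stem, "stem_np"].to_numpy(dtype=float)
        y = truth.levels.loc[has_stem.to_numpy(), truth.anchor].to_numpy()
        res = scistats.linregress(x, y)
        assert res.slope > 0
        assert res.pvalue < 0.01

    def test_absent_species_loses_a_planted_property(self, small_sequences):
        cfg, truth, seqs, _ = small_sequences
        dm = truth.extras["disrupted_motif"]
        ds = truth.extras["disrupted_stem"]
        anchor = truth.levels[truth.anchor]
        for sp in truth.species:
            if sp == truth.anchor:
                continue
            absent = ((anchor >= 0.10) & (truth.levels[sp] <= 0.015)).to_numpy()
            lost = dm[sp] | ds[sp]
            assert (lost[absent]).all()


def test_conservation_classes_by_construction():
    cfg = simulate.SimConfig(n_sites=120, rng_seed=8)
    _, truth = simulate.simulate_levels(cfg)
    track = simulate.simulate_conservation(truth, cfg)
    c = simulate.SITE_OFFSET
    s_lo, s_hi = c - 15, c + 31
    for _, row in truth.sites.iterrows():
        s = track.get_range(row["site_id"], s_lo, s_hi)
        f = np.concatenate([track.get_range(row["site_id"], s_lo - 46, s_lo),
                            track.get_range(row["site_id"], s_hi, s_hi + 46)])
        if row["constraint_class"] == "high":
            assert s.mean() > 0.9 and f.mean() > 0.9
        elif row["constraint_class"] == "moderate":
            assert s.mean() > 0.9 and f.mean() < 0.8
        else:
            assert s.mean() < 0.8


def test_expression_shift_and_seed_plant():
    cfg = simulate.SimConfig(n_sites=200, rng_seed=9, expression_shift=0.8)
    _, truth = simulate.simulate_levels(cfg)
    simulate.simulate_sequences(truth, cfg)
    expr, utrs, mirnas, mexpr = simulate.simulate_expression(truth, cfg)
    multi = expr[expr["n_utr3_sites"] > 1]["log2fc"]
    none = expr[expr["n_utr3_sites"] == 0]["log2fc"]
    if len(multi) >= 3:
        assert multi.median() > none.median()
    # every planted seed gain is found by the scanner, exactly as planted
    fr = dict(zip(mexpr["mirna_id"], mexpr["fraction"]))
    for _, g in truth.seed_gains.iterrows():
        found = utr3.scan_mirna_seed_changes(utrs[g["gene"]], [g["edit_pos"]],
                                             mirnas, fr)
        gained = [m for m in found if m.status == "gained_by_editing"
                  and m.match_type == "8mer"]
        assert len(gained) == 1
        assert gained[0].mirna_id == g["mirna_id"]
        assert (gained[0].start, gained[0].end) == (g["match_start"], g["match_end"])


def test_same_seed_same_output():
    cfg = simulate.SimConfig(n_sites=40, rng_seed=11, structure_effect=1.0)
    l1, t1 = simulate.simulate_levels(cfg)
    s1, _ = simulate.simulate_sequences(t1, cfg)
    p1 = simulate.simulate_reads(l1, cfg)
    l2, t2 = simulate.simulate_levels(cfg)
    s2, _ = simulate.simulate_sequences(t2, cfg)
    p2 = simulate.simulate_reads(l2, cfg)
    assert l1.equals(l2) and s1 == s2 and p1.equals(p2)


def test_config_validation():
    with pytest.raises(ValueError):
        simulate.SimConfig(error_rate=1.5)
    with pytest.raises(ValueError):
        simulate.SimConfig(coverage_mean=-1)
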