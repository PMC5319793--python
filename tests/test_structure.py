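"""Stem finding, duplex features, free energy, conservation smoothing."""

from functools import lru_cache

import numpy as np
import pytest

from editevol import structure
from editevol.io import ConservationTrack, revcomp
from editevol.structure import (
    PAIRS_OBJECTIVE,
    DuplexStructure,
    best_duplex,
    extract_features,
    find_distal_ecs,
    find_proximal_ecs,
    fold_window,
    free_energy,
    smooth_conservation,
    split_duplex,
)

_PAIRABLE = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"),
             ("G", "U"), ("U", "G")}


def max_pairs_oracle(seq: str, min_loop: int = 4) -> int:
    """Exhaustive maximum paired-base duplex (two disjoint arms,
    non-crossing monotone pairing) by plain recursion."""
    n = len(seq)

    @lru_cache(maxsize=None)
    def g(i, j):
        if i < 0 or j >= n:
            return 0
        best = max(g(i - 1, j), g(i, j + 1))
        if j - i > min_loop and (seq[i], seq[j]) in _PAIRABLE:
            best = max(best, g(i - 1, j + 1) + 1)
        return best

    return g(n - 1, 0)


def make_hairpin(stem: str, loop: str = "AAAAAAAAAA", pad: int = 30,
                 rng=None) -> tuple[str, int]:
    """Hairpin with non-pairing (poly-A) padding; returns (sequence, a
    site index inside the 5' arm)."""
    if rng is not None:
        left = "".join(rng.choice(list("ACGU"), size=pad))
        right = "".join(rng.choice(list("ACGU"), size=pad))
    else:
        left = right = "A" * pad
    seq = left + stem + loop + revcomp(stem) + right
    return seq, pad + len(stem) // 2


class TestFoldWindow:
    def test_planted_perfect_stem_recovered(self):
        stem = "GCUAGCAUGGCAUCGAUGCAGGCAUCGAUC"  # 30 nt
        seq, site = make_hairpin(stem)
        cands = fold_window(seq, site, half_window=200)
        best = find_proximal_ecs(cands, site)
        assert best is not None
        assert best.n_pairs == 30
        assert best.max_bulge() == 0

    def test_poly_a_has_no_candidates(self):
        seq = "A" * 200
        assert fold_window(seq, 100) == []

    def test_short_window_warns_and_returns_empty(self, caplog):
        seq = "ACGU" * 8  # 32 nt
        with caplog.at_level("WARNING"):
            out = fold_window(seq, 16)
        assert out == []
        assert any("40" in r.message for r in caplog.records)

    def test_banded_search_equals_exhaustive_enumeration(self):
        """On windows <= 30 nt the search attains the same maximum
        paired-base count as exhaustive enumeration."""
        rng = np.random.default_rng(123)
        for _ in range(40):
            n = int(rng.integers(12, 31))
            seq = "".join(rng.choice(list("ACGU"), size=n))
            want = max_pairs_oracle(seq)
            got = best_duplex(seq, scoring=PAIRS_OBJECTIVE, n_candidates=8)
            got_pairs = got.n_pairs if got else 0
            assert got_pairs == want, seq


class TestProximalFilters:
    def _stem(self, n, bulge_at=None, bulge_len=0):
        edit = list(range(100, 100 + n))
        ecs = list(range(200 + n, 200, -1))
        if bulge_at is not None:
            edit = edit[:bulge_at] + [e + bulge_len for e in edit[bulge_at:]]
        return DuplexStructure(edit, ecs, ["WC"] * n)

    def test_thresholds(self):
        assert find_proximal_ecs([self._stem(30)], 110) is not None
        assert find_proximal_ecs([self._stem(19)], 110) is None
        bulgy = self._stem(25, bulge_at=10, bulge_len=9)
        # a 9-base bulge splits the stem into <20-pair halves
        assert find_proximal_ecs([bulgy], 110) is None

    def test_must_cover_site(self):
        assert find_proximal_ecs([self._stem(30)], 500) is None

    def test_split_duplex(self):
        bulgy = self._stem(25, bulge_at=10, bulge_len=9)
        parts = split_duplex(bulgy, max_bulge=8)
        assert [p.n_pairs for p in parts] == [10, 15]


class TestSmoothing:
    def _track(self, values):
        t = ConservationTrack()
        t.add_segment("c", 0, np.array(values, dtype=float))
        return t

    def test_constant_track_unchanged(self):
        sm = smooth_conservation(self._track([0.8] * 200), 51)
        assert sm.get("c", 100) == pytest.approx(0.8)
        assert sm.get("c", 0) == pytest.approx(0.8)  # truncated edge window

    def test_single_spike(self):
        vals = [0.0] * 201
        vals[100] = 1.0
        sm = smooth_conservation(self._track(vals), 51)
        assert sm.get("c", 100) == pytest.approx(1 / 51)

    def test_step_becomes_ramp(self):
        vals = [0.0] * 100 + [1.0] * 100
        sm = smooth_conservation(self._track(vals), 51)
        mid = [sm.get("c", p) for p in range(70, 130)]
        assert all(b >= a - 1e-12 for a, b in zip(mid, mid[1:]))
        assert sm.get("c", 99) == pytest.approx(25 / 51)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            smooth_conservation(self._track([0.5] * 10), 50)


class TestDistalEcs:
    def _setup(self, distance, score):
        rng = np.random.default_rng(5)
        stem = "GCAUGCAUGGCCAUGGCAUGGCAUCG"  # 26 nt
        n = distance + 600
        seq = list("".join(rng.choice(list("ACGU"), size=n)))
        site = 300
        seq[site - 13:site + 13] = list(stem)
        block_lo = site + distance
        seq[block_lo:block_lo + 26] = list(revcomp(stem))
        track = ConservationTrack()
        vals = np.full(n, 0.4)
        vals[block_lo - 5:block_lo + 31] = score
        track.add_segment("c", 0, vals)
        return "".join(seq), site, track

    def test_planted_conserved_block_found(self):
        seq, site, track = self._setup(1000, 0.95)
        hit = find_distal_ecs(seq, track, site, "c")
        assert hit is not None
        assert hit.n_pairs >= 20

    def test_distance_filter(self):
        seq, site, track = self._setup(3000, 0.95)
        assert find_distal_ecs(seq, track, site, "c") is None

    def test_conservation_filter(self):
        seq, site, track = self._setup(1000, 0.85)
        assert find_distal_ecs(seq, track, site, "c") is None

    def test_no_track_coverage(self):
        seq, site, _ = self._setup(1000, 0.95)
        assert find_distal_ecs(seq, ConservationTrack(), site, "c") is None


class TestFreeEnergy:
    def _perfect(self, seq, start_e, start_s, n):
        edit = list(range(start_e, start_e + n))
        ecs = list(range(start_s + n - 1, start_s - 1, -1))
        return DuplexStructure(edit, ecs, ["WC"] * n)

    def test_empty_duplex_zero(self):
        assert free_energy(DuplexStructure(), "ACGU") == 0.0

    def test_longer_gc_stem_is_more_stable(self):
        seq = "G" * 30 + "AAAA" + "C" * 30
        d30 = self._perfect(seq, 0, 34, 30)
        d20 = self._perfect(seq, 0, 44, 20)
        e30 = free_energy(d30, seq)
        e20 = free_energy(d20, seq)
        assert e30 < e20 < 0

    def test_bulge_raises_energy(self):
        seq = "G" * 21 + "AAAA" + "C" * 21  # G at 0-20, C at 25-45
        flat = self._perfect(seq, 0, 25, 20)
        bulged = DuplexStructure(
            list(range(0, 10)) + list(range(11, 21)),
            list(range(45, 35, -1)) + list(range(35, 25, -1)),
            ["WC"] * 20)
        assert free_energy(bulged, seq) > free_energy(flat, seq)

    def test_adding_wc_pair_never_raises_energy(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            n = int(rng.integers(2, 15))
            bases = rng.choice(["G", "C", "A", "U"], size=n)
            comp = {"G": "C", "C": "G", "A": "U", "U": "A"}
            left = "".join(bases)
            right = "".join(comp[b] for b in reversed(left))
            seq = left + "AAAAA" + right
            full = self._perfect(seq, 0, n + 5, n)
            inner = DuplexStructure(full.edit_positions[1:],
                                    full.ecs_positions[1:],
                                    full.pair_types[1:])
            assert free_energy(full, seq) <= free_energy(inner, seq) + 1e-9


class TestFeatures:
    def test_perfect_stem_features(self):
        stem = "GCAUGGCAUCGAUGCAGGCAUCGAUCGGCA"  # 30 nt
        rng = np.random.default_rng(3)
        seq, _ = make_hairpin(stem, rng=rng)
        edit = list(range(30, 60))
        ecs = list(range(99, 69, -1))
        d = DuplexStructure(edit, ecs, ["WC"] * 30)
        site = 35  # 5 nt from the 5' outermost pair
        f = extract_features(d, site, seq)
        assert f.stem_length == 30
        assert f.paired_total == 30
        assert f.pct_paired == 1.0
        assert f.max_bulge == 0
        assert f.dist_to_edge == 5
        assert f.paired_upstream == 5
        assert f.paired_downstream == 24
        assert f.paired_upstream + f.paired_downstream + 1 == f.paired_total

    def test_bulge_on_editing_side(self):
        edit = list(range(0, 10)) + list(range(13, 23))
        ecs = list(range(60, 40, -1))
        d = DuplexStructure(edit, ecs, ["WC"] * 20)
        f = extract_features(d, 5, "G" * 30 + "C" * 70)
        assert f.max_bulge == 3  # positions 10-12 unpaired on the editing side
        assert f.pct_paired < 1.0
        assert f.stem_length == 23

    def test_site_outside_stem_is_error(self):
        d = DuplexStructure([10, 11, 12], [50, 49, 48], ["WC"] * 3)
        with pytest.raises(ValueError):
            extract_features(d, 30, "G" * 60)

    def test_planted_features_match_truth(self, small_sequences):
        from editevol import simulate
        cfg, truth, seqs, _ = small_sequences
        planted = truth.sites[truth.sites["stem_np"] > 0].head(15)
        for _, row in planted.iterrows():
            e_lo, e_hi, s_lo, s_hi = row["stem_coords"]
            seq = seqs[truth.anchor][row["site_id"]]
            d = DuplexStructure(list(range(e_lo, e_hi)),
                                list(range(s_hi - 1, s_lo - 1, -1)),
                                ["WC"] * row["stem_np"])
            f = extract_features(d, simulate.SITE_OFFSET, seq)
            assert f.paired_total == row["stem_np"]
            assert f.stem_length == row["stem_np"]
            assert f.max_bulge == 0
            assert f.free_energy < -15
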