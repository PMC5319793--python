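"""dsRNA stem prediction around editing sites and structural features.

ADAR requires a double-stranded substrate: each edited adenosine pairs
with an editing-complementary sequence (ECS) either nearby (proximal,
within 200 bp) or in a conserved intronic region up to 2,500 bp away.
This module finds candidate stems by local alignment of the
site-containing segment against the reverse complement of its
surrounding window (match = Watson-Crick pair, GU wobble allowed,
gap = bulge), evaluates duplex free energy with an embedded
nearest-neighbour stacking model, and extracts the 8 structural
features consumed downstream: free energy, stem length, max bulge,
percent paired, distance from the site to the closest stem edge, and
total / downstream / upstream paired-base counts.

The stem finder and the energy evaluator are deliberately pluggable:
any external thermodynamic folder producing a base-pair list can stand
in for either piece.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .io import ConservationTrack

logger = logging.getLogger(__name__)

__all__ = [
    "DuplexStructure",
    "StructureFeatures",
    "Scoring",
    "PAIRS_OBJECTIVE",
    "FEATURE_NAMES",
    "fold_window",
    "find_proximal_ecs",
    "find_distal_ecs",
    "split_duplex",
    "extract_features",
    "free_energy",
    "smooth_conservation",
]

_NEG_INF = -1e9

_WC = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C")}
_GU = {("G", "U"), ("U", "G")}


def pair_type(x: str, y: str) -> str | None:
    if (x, y) in _WC:
        return "WC"
    if (x, y) in _GU:
        return "GU"
    return None


@dataclass(frozen=True)
class Scoring:
    """Alignment scoring for the complementarity search.

    Gaps are affine (bulge opening is expensive, extension cheap-ish),
    so spurious chains of short complementary runs do not outscore a
    genuine contiguous stem.
    """

    match_wc: float = 3.0
    match_gu: float = 1.5
    mismatch: float = -10.0
    gap_open: float = -12.0
    gap_extend: float = -2.0
    min_loop: int = 4  # minimum unpaired separation between a base and its partner


#: Scoring that maximises the paired-base count outright: gaps cost a
#: vanishing amount (tie-break toward compact stems), mismatches are
#: forbidden.  Used when the object of interest is the maximum duplex.
PAIRS_OBJECTIVE = Scoring(match_wc=1.0, match_gu=1.0, mismatch=_NEG_INF,
                          gap_open=-1e-3, gap_extend=-1e-3)


@dataclass
class DuplexStructure:
    """A predicted editing stem: matched base-pair lists.

    ``edit_positions`` ascend along the editing side, ``ecs_positions``
    descend along the ECS side; pair k is
    (edit_positions[k], ecs_positions[k]).  Coordinates are absolute
    0-based positions in the source sequence.
    """

    edit_positions: list[int] = field(default_factory=list)
    ecs_positions: list[int] = field(default_factory=list)
    pair_types: list[str] = field(default_factory=list)

    @property
    def n_pairs(self) -> int:
        return len(self.edit_positions)

    @property
    def edit_span(self) -> tuple[int, int]:
        return (self.edit_positions[0], self.edit_positions[-1])

    @property
    def ecs_span(self) -> tuple[int, int]:
        return (min(self.ecs_positions), max(self.ecs_positions))

    def covers(self, pos: int) -> bool:
        lo, hi = self.edit_span
        return lo <= pos <= hi

    def max_bulge(self) -> int:
        """Longest unpaired run strictly inside the stem, per-side max."""
        worst = 0
        for positions in (sorted(self.edit_positions), sorted(self.ecs_positions)):
            for a, b in zip(positions, positions[1:]):
                worst = max(worst, b - a - 1)
        return worst

    def dot_bracket(self, start: int, end: int) -> str:
        """Parenthesis string for [start, end) for inspection."""
        out = ["." for _ in range(end - start)]
        for p, q in zip(self.edit_positions, self.ecs_positions):
            lo, hi = (p, q) if p < q else (q, p)
            if start <= lo < end:
                out[lo - start] = "("
            if start <= hi < end:
                out[hi - start] = ")"
        return "".join(out)


FEATURE_NAMES = [
    "free_energy",
    "stem_length",
    "max_bulge",
    "pct_paired",
    "dist_to_edge",
    "paired_total",
    "paired_downstream",
    "paired_upstream",
]


@dataclass
class StructureFeatures:
    free_energy: float
    stem_length: int
    max_bulge: int
    pct_paired: float
    dist_to_edge: int
    paired_total: int
    paired_downstream: int
    paired_upstream: int

    def as_vector(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FEATURE_NAMES], dtype=float)


# ---------------------------------------------------------------------------
# alignment core

def _score_matrix(seq: str, a_lo: int, a_hi: int, b_positions: np.ndarray,
                  scoring: Scoring, orientation: str | None = None) -> np.ndarray:
    """S[i, j] = score of pairing position a_lo+i with b_positions[j]."""
    a_pos = np.arange(a_lo, a_hi)
    m, n = a_pos.size, b_positions.size
    codes = np.frombuffer(seq.encode(), dtype=np.uint8)
    xa = codes[a_pos]
    xb = codes[b_positions]
    S = np.full((m, n), scoring.mismatch)
    A, C, G, U = (ord(c) for c in "ACGU")
    wc = (
        ((xa[:, None] == A) & (xb[None, :] == U))
        | ((xa[:, None] == U) & (xb[None, :] == A))
        | ((xa[:, None] == C) & (xb[None, :] == G))
        | ((xa[:, None] == G) & (xb[None, :] == C))
    )
    gu = ((xa[:, None] == G) & (xb[None, :] == U)) | (
        (xa[:, None] == U) & (xb[None, :] == G)
    )
    S[wc] = scoring.match_wc
    S[gu] = scoring.match_gu
    # forbid a base pairing with itself or across too short a loop; an
    # orientation restriction ("down": partner strictly downstream,
    # "up": strictly upstream) keeps a path from wrapping through the
    # hairpin centre and picking up its own mirror image
    delta = b_positions[None, :] - a_pos[:, None]
    if orientation == "down":
        S[delta <= scoring.min_loop] = _NEG_INF
    elif orientation == "up":
        S[-delta <= scoring.min_loop] = _NEG_INF
    else:
        S[np.abs(delta) <= scoring.min_loop] = _NEG_INF
    return S


def _sw_fill(S: np.ndarray, scoring: Scoring):
    """Gotoh local-alignment fill (affine gaps), vectorised over
    antidiagonals.  Returns (H, E, F) where E/F hold the best
    gap-in-A / gap-in-B scores."""
    m, n = S.shape
    go, ge = -scoring.gap_open, -scoring.gap_extend
    H = np.zeros((m + 1, n + 1))
    E = np.full((m + 1, n + 1), _NEG_INF)
    F = np.full((m + 1, n + 1), _NEG_INF)
    for d in range(2, m + n + 1):
        lo = max(1, d - n)
        hi = min(m, d - 1)
        if lo > hi:
            continue
        i = np.arange(lo, hi + 1)
        j = d - i
        E[i, j] = np.maximum(H[i, j - 1] - go, E[i, j - 1] - ge)
        F[i, j] = np.maximum(H[i - 1, j] - go, F[i - 1, j] - ge)
        diag = H[i - 1, j - 1] + S[i - 1, j - 1]
        H[i, j] = np.maximum(0.0, np.maximum(diag, np.maximum(E[i, j], F[i, j])))
    return H, E, F


def _traceback(H, E, F, S: np.ndarray, scoring: Scoring,
               start: tuple[int, int]) -> list[tuple[int, int]]:
    """Follow one local alignment back from ``start``; return matched cells."""
    go, ge = -scoring.gap_open, -scoring.gap_extend
    i, j = start
    state = "H"
    matches: list[tuple[int, int]] = []
    while i > 0 and j > 0:
        if state == "H":
            h = H[i, j]
            if h <= 0:
                break
            if math.isclose(h, H[i - 1, j - 1] + S[i - 1, j - 1], abs_tol=1e-9):
                if S[i - 1, j - 1] > 0:
                    matches.append((i - 1, j - 1))
                i, j = i - 1, j - 1
            elif math.isclose(h, E[i, j], abs_tol=1e-9):
                state = "E"
            elif math.isclose(h, F[i, j], abs_tol=1e-9):
                state = "F"
            else:  # numerical dead end; stop
                break
        elif state == "E":
            if math.isclose(E[i, j], H[i, j - 1] - go, abs_tol=1e-9):
                j -= 1
                state = "H"
            else:
                j -= 1
        else:  # "F"
            if math.isclose(F[i, j], H[i - 1, j] - go, abs_tol=1e-9):
                i -= 1
                state = "H"
            else:
                i -= 1
    matches.reverse()
    return matches


def _alignment_to_duplexes(seq: str, matches: list[tuple[int, int]], a_lo: int,
                           b_positions: np.ndarray) -> list[DuplexStructure]:
    """Convert matched cells to duplexes, splitting where orientation flips.

    Along a path the editing-side position p increases and the partner
    position q decreases, so q - p changes sign at most once (only
    possible when the two ranges overlap); each consistent run is a
    valid non-crossing duplex.
    """
    runs: list[list[tuple[int, int]]] = []
    current: list[tuple[int, int]] = []
    sign = 0
    for i, j in matches:
        p = a_lo + i
        q = int(b_positions[j])
        s = 1 if q > p else -1
        if sign != 0 and s != sign:
            runs.append(current)
            current = []
        sign = s
        current.append((p, q))
    if current:
        runs.append(current)
    out = []
    for run in runs:
        if not run:
            continue
        d = DuplexStructure()
        for p, q in run:
            d.edit_positions.append(p)
            d.ecs_positions.append(q)
            d.pair_types.append(pair_type(seq[p], seq[q]))
        out.append(d)
    return out


def _duplex_search(seq: str, a_lo: int, a_hi: int, b_positions: np.ndarray,
                   scoring: Scoring, n_candidates: int = 4,
                   min_pairs: int = 4,
                   orientation: str | None = None) -> list[DuplexStructure]:
    """Repeated local alignment; each round masks the ECS region used."""
    S = _score_matrix(seq, a_lo, a_hi, b_positions, scoring, orientation)
    found: list[DuplexStructure] = []
    seen: set[frozenset] = set()
    stop_score = min_pairs * min(scoring.match_wc, scoring.match_gu)
    for _ in range(n_candidates):
        H, E, F = _sw_fill(S, scoring)
        best = np.unravel_index(np.argmax(H), H.shape)
        if H[best] < stop_score:
            break
        matches = _traceback(H, E, F, S, scoring, best)
        if not matches:
            break
        for duplex in _alignment_to_duplexes(seq, matches, a_lo, b_positions):
            key = frozenset(
                frozenset(pq) for pq in zip(duplex.edit_positions, duplex.ecs_positions)
            )
            if key not in seen and duplex.n_pairs >= 1:
                seen.add(key)
                found.append(duplex)
        j_used = [j for _, j in matches]
        S[:, min(j_used) : max(j_used) + 1] = _NEG_INF
    found.sort(key=lambda d: -d.n_pairs)
    return found


# ---------------------------------------------------------------------------
# public operations

def fold_window(sequence: str, site_index: int, half_window: int = 200,
                seg_half: int = 35, scoring: Scoring | None = None,
                n_candidates: int = 4) -> list[DuplexStructure]:
    """Candidate duplexes for the region within ``half_window`` of a site.

    The segment containing the site (+- ``seg_half`` nt) is locally
    aligned against the reverse complement of the whole window.
    Candidates are returned sorted by paired-base count (descending).
    Windows shorter than 40 nt yield an empty list with a warning.
    """
    scoring = scoring or Scoring()
    n = len(sequence)
    if not 0 <= site_index < n:
        raise ValueError("site outside sequence")
    w0 = max(0, site_index - half_window)
    w1 = min(n, site_index + half_window + 1)
    if w1 - w0 < 40:
        logger.warning("window around site %d shorter than 40 nt; skipping", site_index)
        return []
    a_lo = max(w0, site_index - seg_half)
    a_hi = min(w1, site_index + seg_half + 1)
    # reverse traversal of the window == aligning against its reverse complement
    b_positions = np.arange(w1 - 1, w0 - 1, -1)
    found = []
    for orientation in ("down", "up"):
        found.extend(_duplex_search(sequence, a_lo, a_hi, b_positions, scoring,
                                    n_candidates=n_candidates,
                                    orientation=orientation))
    found.sort(key=lambda d: -d.n_pairs)
    return found


def best_duplex(sequence: str, scoring: Scoring | None = None,
                n_candidates: int = 6) -> DuplexStructure | None:
    """Best duplex anywhere in a (short) sequence, both arms free.

    Used for exhaustive-comparison checks and small inputs; the
    orientation restriction makes the two arms disjoint by
    construction.
    """
    scoring = scoring or Scoring()
    n = len(sequence)
    b_positions = np.arange(n - 1, -1, -1)
    cands = _duplex_search(sequence, 0, n, b_positions, scoring,
                           n_candidates=n_candidates, min_pairs=1,
                           orientation="down")
    return max(cands, key=lambda d: d.n_pairs, default=None)


def split_duplex(duplex: DuplexStructure, max_bulge: int) -> list[DuplexStructure]:
    """Split a duplex wherever either side has an unpaired run > max_bulge."""
    if duplex.n_pairs == 0:
        return []
    parts: list[DuplexStructure] = []
    cur = DuplexStructure([duplex.edit_positions[0]], [duplex.ecs_positions[0]],
                          [duplex.pair_types[0]])
    for k in range(1, duplex.n_pairs):
        gap_edit = duplex.edit_positions[k] - duplex.edit_positions[k - 1] - 1
        gap_ecs = abs(duplex.ecs_positions[k - 1] - duplex.ecs_positions[k]) - 1
        if gap_edit > max_bulge or gap_ecs > max_bulge:
            parts.append(cur)
            cur = DuplexStructure([], [], [])
        cur.edit_positions.append(duplex.edit_positions[k])
        cur.ecs_positions.append(duplex.ecs_positions[k])
        cur.pair_types.append(duplex.pair_types[k])
    parts.append(cur)
    return parts


def find_proximal_ecs(candidates: list[DuplexStructure], site: int,
                      min_paired: int = 20, max_bulge: int = 8,
                      site_margin: int = 2, sequence: str | None = None,
                      max_energy: float = -15.0) -> DuplexStructure | None:
    """Best candidate with >= min_paired pairs, bulges <= max_bulge,
    whose editing side covers the site (within ``site_margin`` nt).

    When ``sequence`` is supplied, candidates must also reach
    ``max_energy`` (kcal/mol) -- a thermodynamic-credibility gate that
    stands in for ensemble folding: chains of short complementary
    fragments satisfy the pairing filters by accident far more often
    than they form stable duplexes.
    """
    best = None
    for cand in candidates:
        for piece in split_duplex(cand, max_bulge):
            if piece.n_pairs < min_paired:
                continue
            lo, hi = piece.edit_span
            if not (lo - site_margin <= site <= hi + site_margin):
                continue
            if sequence is not None and free_energy(piece, sequence) > max_energy:
                continue
            if best is None or piece.n_pairs > best.n_pairs:
                best = piece
    return best


def smooth_conservation(track: ConservationTrack, window: int = 51) -> ConservationTrack:
    """Centered moving average; truncated near segment edges."""
    if window % 2 == 0:
        raise ValueError("smoothing window must be odd")
    kernel = np.ones(window)
    out = ConservationTrack()
    for contig in track.contigs:
        for start, values in track.segments(contig):
            if values.size == 0:
                continue
            sums = np.convolve(values, kernel, mode="same")
            counts = np.convolve(np.ones_like(values), kernel, mode="same")
            out.add_segment(contig, start, sums / counts)
    return out


def find_distal_ecs(sequence: str, smoothed: ConservationTrack, site: int,
                    contig: str, max_dist: int = 2500, min_len: int = 20,
                    min_score: float = 0.90, seg_half: int = 35,
                    min_paired: int = 20, max_bulge: int = 8,
                    max_energy: float = -15.0,
                    scoring: Scoring | None = None) -> DuplexStructure | None:
    """Fold conserved candidate regions near the site against the site segment.

    Candidate ECS regions must lie within ``max_dist`` of the site, span
    at least ``min_len`` bases, and have smoothed conservation >=
    ``min_score`` throughout.  Stem filters are those of
    :func:`find_proximal_ecs`.
    """
    scoring = scoring or Scoring()
    n = len(sequence)
    lo = max(0, site - max_dist)
    hi = min(n, site + max_dist + 1)
    scores = smoothed.get_range(contig, lo, hi)
    if np.all(np.isnan(scores)):
        logger.info("no conservation coverage near site %d; no distal ECS", site)
        return None
    good = ~np.isnan(scores) & (scores >= min_score)
    a_lo = max(0, site - seg_half)
    a_hi = min(n, site + seg_half + 1)
    best = None
    # maximal runs of conserved positions
    idx = np.flatnonzero(good)
    if idx.size == 0:
        return None
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.r_[idx[0], idx[breaks + 1]]
    ends = np.r_[idx[breaks], idx[-1]]
    for s, e in zip(starts, ends):
        run_lo, run_hi = lo + int(s), lo + int(e) + 1
        if run_hi - run_lo < min_len:
            continue
        if run_lo <= site < run_hi:  # the site's own region is not its ECS
            continue
        b_positions = np.arange(run_hi - 1, run_lo - 1, -1)
        for cand in _duplex_search(sequence, a_lo, a_hi, b_positions, scoring):
            for piece in split_duplex(cand, max_bulge):
                if piece.n_pairs < min_paired or not piece.covers(site):
                    continue
                if free_energy(piece, sequence) > max_energy:
                    continue
                if best is None or piece.n_pairs > best.n_pairs:
                    best = piece
    return best


# ---------------------------------------------------------------------------
# nearest-neighbour free energy

def _stack_table() -> dict[tuple[str, str], float]:
    wc = {
        ("CG", "CG"): -3.26, ("CG", "GC"): -3.42, ("GC", "CG"): -2.36,
        ("GC", "GC"): -3.26,
        ("AU", "AU"): -0.93, ("AU", "UA"): -1.10, ("UA", "AU"): -1.33,
        ("UA", "UA"): -0.93,
        ("AU", "CG"): -2.24, ("AU", "GC"): -2.08, ("UA", "CG"): -2.35,
        ("UA", "GC"): -2.11,
        ("CG", "AU"): -2.11, ("CG", "UA"): -2.08, ("GC", "AU"): -2.35,
        ("GC", "UA"): -2.24,
    }
    strength = {"CG": 3.3, "GC": 3.3, "AU": 1.1, "UA": 1.1, "GU": 0.5, "UG": 0.5}
    table = dict(wc)
    pairs = list(strength)
    for x in pairs:
        for y in pairs:
            if (x, y) not in table:
                # GU-containing stacks: modest, always stabilising
                table[(x, y)] = -(0.5 + 0.25 * min(strength[x], strength[y]))
    return table


_STACKS = _stack_table()
_TERMINAL_PENALTY = 0.5  # closing AU/GU pairs
_LOOP_A = 3.0            # bulge/internal-loop initiation, kcal/mol
_LOOP_B = 1.1            # length-dependent term, * ln(loop size)


def free_energy(duplex: DuplexStructure, sequence: str) -> float:
    """Duplex free energy (kcal/mol) from the embedded stacking model.

    Consecutive pairs with no intervening bases contribute a stacking
    term; interruptions contribute a length-dependent loop penalty
    ``3.0 + 1.1 ln(l)`` where ``l`` counts unpaired bases on both
    sides.  Terminal AU/GU pairs are penalised 0.5 each.  Two-segment
    duplexes are treated as joined by a linker contributing no pairs,
    so only the stem itself is scored.  An empty duplex has energy 0.
    """
    if duplex.n_pairs == 0:
        return 0.0
    pairs = [sequence[p] + sequence[q]
             for p, q in zip(duplex.edit_positions, duplex.ecs_positions)]
    energy = 0.0
    for k in range(1, duplex.n_pairs):
        gap_edit = duplex.edit_positions[k] - duplex.edit_positions[k - 1] - 1
        gap_ecs = abs(duplex.ecs_positions[k - 1] - duplex.ecs_positions[k]) - 1
        if gap_edit == 0 and gap_ecs == 0:
            energy += _STACKS[(pairs[k - 1], pairs[k])]
        else:
            loop = gap_edit + gap_ecs
            energy += _LOOP_A + _LOOP_B * math.log(loop)
    for end in (pairs[0], pairs[-1]):
        if end in ("AU", "UA", "GU", "UG"):
            energy += _TERMINAL_PENALTY
    return energy


def extract_features(duplex: DuplexStructure, site: int, sequence: str) -> StructureFeatures:
    """The 8 structural features of a stem around an editing site."""
    if duplex.n_pairs == 0:
        raise ValueError("cannot extract features from an empty duplex")
    lo, hi = duplex.edit_span
    if not lo <= site <= hi:
        raise ValueError("site outside the editing-side stem span; "
                         "distance to stem edge undefined")
    stem_length = hi - lo + 1
    paired_edit = set(duplex.edit_positions)
    return StructureFeatures(
        free_energy=free_energy(duplex, sequence),
        stem_length=stem_length,
        max_bulge=duplex.max_bulge(),
        pct_paired=len(paired_edit) / stem_length,
        dist_to_edge=min(site - lo, hi - site),
        paired_total=duplex.n_pairs,
        paired_downstream=sum(1 for p in duplex.edit_positions if p > site),
        paired_upstream=sum(1 for p in duplex.edit_positions if p < site),
    )
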