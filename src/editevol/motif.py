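"""ADAR sequence-motif analysis on the nucleotide triplet around a site.

ADAR's preference is captured by the bases immediately 5' and 3' of the
edited adenosine (a U at -1 and a G at +1 are favoured).  A position
weight matrix is deduced from the triplets of highly edited sites
(>= 50% by default), each of the 16 possible N-A-N triplets is scored
by log-odds against a uniform background, and the raw scores are
rescaled to 0-10.  Cross-species site pairs are classified as
Presence/Absence (edited >= 10% in the anchor species, <= 1.5%
everywhere in the other) or Presence/Presence, and an exact binomial
test asks whether Presence/Absence pairs carry better motifs in the
species where editing is present.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import binomial_two_sided, binomial_upper_tail

__all__ = [
    "MotifMatrix",
    "build_motif_matrix",
    "average_motif_matrix",
    "score_triplets",
    "classify_site_pair",
    "binomial_error_test",
    "motif_asymmetry_test",
    "ALL_TRIPLETS",
]

_ALPHABET = "ACGU"
ALL_TRIPLETS = tuple(x + "A" + y for x in _ALPHABET for y in _ALPHABET)


@dataclass
class MotifMatrix:
    """Probabilities for positions -1 and +1 over ACGU (centre fixed to A)."""

    upstream: dict[str, float]
    downstream: dict[str, float]
    pseudocount: float

    def __post_init__(self):
        for probs in (self.upstream, self.downstream):
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"position probabilities sum to {total}, not 1")


def build_motif_matrix(triplets, pseudocount: float = 0.5) -> MotifMatrix:
    """Position-wise frequencies with additive smoothing.

    ``triplets`` are the 3-mers around highly edited sites; every
    centre base must be A.
    """
    triplets = [t.upper().replace("T", "U") for t in triplets]
    if not triplets:
        raise ValueError("at least one triplet required")
    for t in triplets:
        if len(t) != 3 or t[1] != "A":
            raise ValueError(f"triplet {t!r} does not have centre base A")
    out = []
    for pos in (0, 2):
        counts = {b: pseudocount for b in _ALPHABET}
        for t in triplets:
            counts[t[pos]] += 1
        total = sum(counts.values())
        out.append({b: counts[b] / total for b in _ALPHABET})
    return MotifMatrix(upstream=out[0], downstream=out[1], pseudocount=pseudocount)


def average_motif_matrix(matrices: list[MotifMatrix]) -> MotifMatrix:
    """Arithmetic mean of per-species position probabilities, renormalised.

    Motif matrices are essentially identical across species, so a
    single shared matrix is used for cross-species scoring.
    """
    if not matrices:
        raise ValueError("no matrices to average")
    up = {b: np.mean([m.upstream[b] for m in matrices]) for b in _ALPHABET}
    dn = {b: np.mean([m.downstream[b] for m in matrices]) for b in _ALPHABET}
    for probs in (up, dn):
        total = sum(probs.values())
        for b in _ALPHABET:
            probs[b] /= total
    return MotifMatrix(upstream=up, downstream=dn,
                       pseudocount=matrices[0].pseudocount)


def score_triplets(matrix: MotifMatrix) -> pd.DataFrame:
    """Log-odds scores of the 16 N-A-N triplets, rescaled to [0, 10].

    Raw score = sum over positions -1/+1 of log2(p(base)/0.25).  The
    affine rescaling sends the minimum raw score to 0 and the maximum
    to 10, so triplet ordering is preserved.  A degenerate matrix in
    which every triplet ties scores 0 everywhere with
    ``degenerate=True``.
    """
    if matrix.pseudocount <= 0 and (
        any(p == 0 for p in matrix.upstream.values())
        or any(p == 0 for p in matrix.downstream.values())
    ):
        raise ValueError("zero probabilities require a positive pseudocount")
    raw = {
        t: float(np.log2(matrix.upstream[t[0]] / 0.25)
                 + np.log2(matrix.downstream[t[2]] / 0.25))
        for t in ALL_TRIPLETS
    }
    values = np.array([raw[t] for t in ALL_TRIPLETS])
    lo, hi = values.min(), values.max()
    degenerate = np.isclose(hi, lo)
    if degenerate:
        scaled = {t: 0.0 for t in ALL_TRIPLETS}
    else:
        scaled = {t: 10.0 * (raw[t] - lo) / (hi - lo) for t in ALL_TRIPLETS}
    df = pd.DataFrame({
        "triplet": ALL_TRIPLETS,
        "raw_score": [raw[t] for t in ALL_TRIPLETS],
        "scaled_score": [scaled[t] for t in ALL_TRIPLETS],
    })
    df.attrs["degenerate"] = bool(degenerate)
    return df


def classify_site_pair(levels_anchor, levels_other,
                       presence_level: float = 0.10,
                       absence_level: float = 0.015) -> str:
    """Label a cross-species site pair.

    presence_absence: anchor edited >= 10% in at least one dataset and
    the other species <= 1.5% in every dataset with a measurement.
    presence_presence: both species edited >= 10% somewhere.
    Anything else is "other".
    """
    la = np.asarray(levels_anchor, dtype=float)
    lo = np.asarray(levels_other, dtype=float)
    if la.size == 0 or lo.size == 0:
        raise ValueError("each species needs at least one measurement")
    anchor_present = (la >= presence_level).any()
    other_present = (lo >= presence_level).any()
    other_absent = (lo <= absence_level).all()
    if anchor_present and other_absent:
        return "presence_absence"
    if anchor_present and other_present:
        return "presence_presence"
    return "other"


def binomial_error_test(alt_reads: int, coverage: int,
                        error_rate: float = 0.01) -> float:
    """Is the A-to-G count above the typical sequencing error rate?

    One-sided upper-tail exact binomial P(X >= alt | n, error_rate).
    """
    return binomial_upper_tail(alt_reads, coverage, error_rate)


def motif_asymmetry_test(score_anchor, score_other):
    """Excess of better motifs in the species where editing is present.

    Among pairs whose triplet scores differ, counts how many score
    higher in the anchor vs the other species and applies a two-sided
    exact binomial test against 0.5 (ties excluded from n).

    Returns (fraction higher in anchor, fraction higher in other, p);
    p is NaN when no pair differs.
    """
    sa = np.asarray(score_anchor, dtype=float)
    so = np.asarray(score_other, dtype=float)
    if sa.size != so.size:
        raise ValueError("paired score vectors must have equal length")
    n_total = sa.size
    if n_total == 0:
        return 0.0, 0.0, float("nan")
    higher_anchor = int((sa > so).sum())
    higher_other = int((so > sa).sum())
    n_diff = higher_anchor + higher_other
    if n_diff == 0:
        return 0.0, 0.0, float("nan")
    p = binomial_two_sided(higher_anchor, n_diff, 0.5)
    return higher_anchor / n_total, higher_other / n_total, p
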