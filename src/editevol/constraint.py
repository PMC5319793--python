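"""Evolutionary-constraint classification of editing sites.

The region spanning an editing site (S_region: 15 bp upstream and 30 bp
downstream on the transcribed strand, 46 bases including the site) is
compared with its two 46-bp flanks (F_region, pooled) using per-base
phastCons-style conservation scores.  A site whose S and F regions both
average > 0.9 is highly constrained; otherwise, a significantly higher
S-region score distribution (two-sample Kolmogorov-Smirnov, BH-corrected
across the batch) makes it moderately constrained; anything else is
unconstrained.  The excess of constrained sites among edited vs lowly
edited sites estimates the fraction of likely-functional editing events.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ConservationTrack
from .stats import bh_adjust, fisher_exact, ks_two_sample

__all__ = [
    "ConstraintCall",
    "window_profile",
    "region_scores",
    "classify_constraint",
    "normalized_conservation_profile",
    "functional_fraction",
    "ks_two_sample",
]


@dataclass
class ConstraintCall:
    site_id: str
    constraint_class: str  # high | moderate | none | unevaluable
    mean_s: float
    mean_f: float
    ks_d: float
    p_raw: float
    p_fdr: float


def _clean(values: np.ndarray, mask: np.ndarray | None) -> np.ndarray:
    if mask is not None:
        values = values[~mask]
    return values[~np.isnan(values)]


def window_profile(track: ConservationTrack, contig: str, site: int,
                   window: int = 30, flank: int = 60,
                   genic_mask=None) -> dict[int, np.ndarray]:
    """Sliding-window score samples across +-flank bp of a site.

    Returns {window start offset relative to the site: scores}.
    Windows containing any masked or undefined base are dropped.
    ``genic_mask`` is a callable(pos) -> bool marking disallowed bases
    (e.g. non-CDS flanks of a CDS site).  A site entirely uncovered by
    the track is an error.
    """
    region = track.get_range(contig, site - flank, site + flank + 1)
    if np.all(np.isnan(region)):
        raise ValueError(f"site {contig}:{site} has no conservation coverage")
    out: dict[int, np.ndarray] = {}
    for off in range(-flank, flank - window + 2):
        positions = np.arange(site + off, site + off + window)
        values = track.get_range(contig, positions[0], positions[-1] + 1)
        if np.isnan(values).any():
            continue
        if genic_mask is not None and any(genic_mask(int(p)) for p in positions):
            continue
        out[off] = values
    return out


def region_scores(track: ConservationTrack, contig: str, site: int,
                  upstream: int = 15, downstream: int = 30,
                  flank_len: int = 46, genic_mask=None):
    """(S_region scores, pooled F_region scores) around a site.

    S_region is [site - upstream, site + downstream] inclusive of the
    site (46 bases with the defaults); F_region is the ``flank_len``
    bases on each side of the S_region, pooled.  Masked and undefined
    bases are excluded.
    """
    s_lo, s_hi = site - upstream, site + downstream + 1
    s = track.get_range(contig, s_lo, s_hi)
    f = np.concatenate([
        track.get_range(contig, s_lo - flank_len, s_lo),
        track.get_range(contig, s_hi, s_hi + flank_len),
    ])
    if genic_mask is not None:
        s_mask = np.array([genic_mask(p) for p in range(s_lo, s_hi)])
        f_mask = np.array([genic_mask(p) for p in range(s_lo - flank_len, s_lo)]
                          + [genic_mask(p) for p in range(s_hi, s_hi + flank_len)])
    else:
        s_mask = f_mask = None
    return _clean(s, s_mask), _clean(f, f_mask)


def classify_constraint(track: ConservationTrack, sites: pd.DataFrame,
                        genic_masks: dict | None = None,
                        high_mean: float = 0.9, alpha: float = 0.05,
                        upstream: int = 15, downstream: int = 30,
                        flank_len: int = 46) -> list[ConstraintCall]:
    """Constraint class for a batch of sites.

    ``sites`` needs columns site_id, contig, pos.  BH correction is
    applied across every site tested in this invocation (the sites
    already called high are classified without a test, as are sites
    whose S_region is fully masked, which come back unevaluable).
    """
    genic_masks = genic_masks or {}
    calls: list[ConstraintCall] = []
    tested_idx: list[int] = []
    pvals: list[float] = []
    for row in sites.itertuples(index=False):
        mask = genic_masks.get(row.site_id)
        try:
            s, f = region_scores(track, row.contig, row.pos, upstream, downstream,
                                 flank_len, mask)
        except Exception:
            s = np.array([])
            f = np.array([])
        if s.size == 0:
            calls.append(ConstraintCall(row.site_id, "unevaluable",
                                        np.nan, np.nan, np.nan, np.nan, np.nan))
            continue
        mean_s = float(s.mean())
        mean_f = float(f.mean()) if f.size else np.nan
        if f.size and mean_s > high_mean and mean_f > high_mean:
            calls.append(ConstraintCall(row.site_id, "high", mean_s, mean_f,
                                        np.nan, np.nan, np.nan))
            continue
        if f.size == 0:
            calls.append(ConstraintCall(row.site_id, "unevaluable",
                                        mean_s, np.nan, np.nan, np.nan, np.nan))
            continue
        d, p = ks_two_sample(s, f)
        calls.append(ConstraintCall(row.site_id, "none", mean_s, mean_f, d, p, np.nan))
        tested_idx.append(len(calls) - 1)
        pvals.append(p)
    if tested_idx:
        adj = bh_adjust(pvals)
        for k, idx in enumerate(tested_idx):
            call = calls[idx]
            call.p_fdr = float(adj[k])
            if call.p_fdr < alpha and call.mean_s > call.mean_f:
                call.constraint_class = "moderate"
    return calls


def normalized_conservation_profile(windows: dict[int, np.ndarray]) -> dict[int, float]:
    """Profile of -D (KS statistic) relative to the most conserved window.

    The window with the highest mean score is the reference (value 0);
    every other window's value is minus its KS distance from the
    reference, so less conserved windows dip below 0.
    """
    if not windows:
        return {}
    best_off = max(windows, key=lambda off: windows[off].mean())
    best = windows[best_off]
    out = {}
    for off, values in windows.items():
        if off == best_off:
            out[off] = 0.0
        else:
            d, _ = ks_two_sample(values, best)
            out[off] = -float(d)
    return out


def functional_fraction(constrained_edited: int, total_edited: int,
                        constrained_low: int, total_low: int):
    """Excess constrained fraction among edited vs lowly edited sites.

    Treating lowly edited (< 1.5%) sites as a neutral baseline, the
    difference between the constrained fraction of edited sites and of
    lowly edited sites estimates the fraction of editing events that
    are functionally relevant.  Returns (excess, two-sided Fisher p).
    """
    if total_edited == 0 or total_low == 0:
        raise ValueError("both strata must be non-empty")
    frac_edited = constrained_edited / total_edited
    frac_low = constrained_low / total_low
    table = [
        [constrained_edited, total_edited - constrained_edited],
        [constrained_low, total_low - constrained_low],
    ]
    return frac_edited - frac_low, fisher_exact(table)
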