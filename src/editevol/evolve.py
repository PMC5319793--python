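"""Evolution of editing levels: divergence, trees, dating, clustering.

Editing-level divergence between two species is 1 - Spearman's rho over
the editing levels of shared sites (mid-ranks, so the many sites tied
at 0 are handled).  Divergence matrices feed a neighbour-joining tree,
which for neutrally evolving levels recapitulates the species
phylogeny, and a regression of divergence against species divergence
time.  Each anchor-species site is dated by parsimony: its age class
is the most distantly related species in which it is also edited.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _st

from .stats import rank_group_test, spearman_rho  # noqa: F401 (rank_group_test re-exported)

__all__ = [
    "editing_divergence",
    "divergence_matrix",
    "build_nj_tree",
    "divergence_time_regression",
    "call_editing_status",
    "AgeAssignment",
    "assign_age",
    "cluster_fraction",
    "level_difference_metrics",
    "rank_group_test",
]


def editing_divergence(levels_a, levels_b) -> float:
    """1 - Spearman's rho over paired per-site levels.

    Pairs where either level is undefined (NaN) are dropped; fewer
    than 3 shared defined sites leaves the distance undefined (NaN).
    Sites whose DNA base is not A must already be set to level 0.
    """
    a = np.asarray(levels_a, dtype=float)
    b = np.asarray(levels_b, dtype=float)
    ok = ~np.isnan(a) & ~np.isnan(b)
    if ok.sum() < 3:
        return float("nan")
    rho = spearman_rho(a[ok], b[ok])
    return 1.0 - rho


def divergence_matrix(levels: pd.DataFrame) -> pd.DataFrame:
    """Symmetric divergence matrix from a sites x species level table."""
    species = list(levels.columns)
    mat = pd.DataFrame(0.0, index=species, columns=species)
    for i, a in enumerate(species):
        for b in species[i + 1:]:
            d = editing_divergence(levels[a], levels[b])
            mat.loc[a, b] = mat.loc[b, a] = d
    return mat


def build_nj_tree(dist: pd.DataFrame):
    """Saitou-Nei neighbour joining on a divergence matrix.

    Negative branch lengths are clamped to 0 with the deficit
    transferred to the adjacent branch, preserving total path lengths.
    Returns an unrooted scikit-bio ``TreeNode``.
    """
    from skbio import DistanceMatrix
    from skbio.tree import nj

    arr = dist.to_numpy(dtype=float)
    if arr.shape[0] != arr.shape[1] or not np.allclose(arr, arr.T):
        raise ValueError("distance matrix must be square and symmetric")
    if arr.shape[0] < 3:
        raise ValueError("neighbour joining needs at least 3 taxa")
    dm = DistanceMatrix(arr, ids=[str(c) for c in dist.columns])
    return nj(dm, neg_as_zero=True)


def divergence_time_regression(distances, times):
    """OLS fit and rank correlation of divergence distance vs time.

    Returns (slope, intercept, spearman rho).  Pairs with unknown
    divergence time (NaN) are excluded.
    """
    d = np.asarray(distances, dtype=float)
    t = np.asarray(times, dtype=float)
    ok = ~np.isnan(d) & ~np.isnan(t)
    d, t = d[ok], t[ok]
    if d.size < 3:
        raise ValueError("need at least 3 pairs with known divergence time")
    if np.all(t == t[0]):
        raise ValueError("divergence times are constant; slope undefined")
    res = _st.linregress(t, d)
    return float(res.slope), float(res.intercept), spearman_rho(d, t)


def call_editing_status(levels, coverages, dna_base: str = "A",
                        edited_level: float = 0.02,
                        absence_level: float = 0.015,
                        min_cov: int = 20) -> str:
    """Edited / unedited / undefined status of a site in one species.

    Edited: level >= 2% in at least one dataset.  Unedited: every
    dataset has >= 20 reads and level <= 1.5% (or the DNA base is not
    A, which cannot be edited).  Anything else is undefined: absence
    cannot be asserted from thin coverage.
    """
    if dna_base != "A":
        return "unedited"
    levels = np.asarray(levels, dtype=float)
    coverages = np.asarray(coverages, dtype=float)
    if levels.size == 0:
        return "undefined"
    if (levels >= edited_level).any():
        return "edited"
    if (coverages >= min_cov).all() and (levels <= absence_level).all():
        return "unedited"
    return "undefined"


@dataclass
class AgeAssignment:
    site_id: str
    age_class: str | None      # most distant edited species, or None if undated
    dated: bool
    n_defined: int
    status: dict[str, str]


def assign_age(site_id: str, status: dict[str, str], species_order: list[str],
               min_defined: int = 5) -> AgeAssignment:
    """Parsimony dating of an anchor-species editing site.

    ``species_order`` lists species from the anchor outward by
    divergence (anchor first).  The age class is the most distantly
    related species in which the site is also edited; intervening
    losses are allowed.  Sites with defined (edited or unedited)
    status in fewer than ``min_defined`` species are not dated.
    """
    anchor = species_order[0]
    if status.get(anchor) != "edited":
        raise ValueError(f"site {site_id}: anchor species {anchor} is not edited")
    n_defined = sum(1 for s in species_order if status.get(s) in ("edited", "unedited"))
    if n_defined < min_defined:
        return AgeAssignment(site_id, None, False, n_defined, dict(status))
    age = anchor
    for sp in species_order[1:]:
        if status.get(sp) == "edited":
            age = sp
    return AgeAssignment(site_id, age, True, n_defined, dict(status))


def cluster_fraction(positions, max_dist: int = 30, n_bootstrap: int = 1000,
                     rng=None) -> tuple[float, float]:
    """Fraction of sites whose nearest neighbouring site is <= max_dist away.

    Positions must be on one contig/strand.  Returns (fraction,
    bootstrap SD over sites); a single site is unclustered by
    definition.
    """
    pos = np.sort(np.asarray(positions, dtype=int))
    n = pos.size
    if n == 0:
        raise ValueError("no positions supplied")
    if n == 1:
        return 0.0, 0.0
    gaps = np.diff(pos)
    nearest = np.minimum(np.r_[gaps, np.inf], np.r_[np.inf, gaps])
    clustered = nearest <= max_dist
    frac = float(clustered.mean())
    rng = np.random.default_rng(rng)
    boot = clustered[rng.integers(0, n, size=(n_bootstrap, n))].mean(axis=1)
    return frac, float(boot.std(ddof=1))


def level_difference_metrics(e1: float, e2: float) -> dict[str, float]:
    """Normalised editing difference and editing conservation.

    normalized_diff = |e1 - e2| / mean(e1, e2);
    conservation = 1 - |e1 - e2| / (e1 + e2) = 1 - normalized_diff / 2.
    Undefined (ValueError) when both levels are 0.
    """
    if e1 + e2 <= 0:
        raise ValueError("metrics undefined when both levels are 0")
    diff = abs(e1 - e2)
    return {
        "normalized_diff": diff / ((e1 + e2) / 2),
        "conservation": 1.0 - diff / (e1 + e2),
    }
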