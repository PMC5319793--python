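"""Editing-site discovery and level quantification from pileup counts.

A-to-I editing appears as A-to-G mismatches between RNA reads and the
DNA reference.  Discovery proceeds by calling RNA variants per species,
intersecting them across species pairs through an orthology map, and
choosing the minimum-frequency cutoff at which the shared-variant set
is at least 80% A-to-G (the signature of genuine editing).  An
ADAR-null sample provides a direct false-positive estimate: candidate
sites still showing A-to-G reads without the editing enzyme are tested
site-by-site with Fisher's exact test, Benjamini-Hochberg corrected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import bh_adjust, fisher_exact

logger = logging.getLogger(__name__)

__all__ = [
    "VariantCall",
    "call_variants",
    "atog_fraction_curve",
    "select_frequency_cutoff",
    "identify_shared_editing",
    "estimate_fdr_with_null",
    "quantify_levels",
    "combine_platforms",
    "representative_level",
]

_BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class VariantCall:
    site_id: str
    sample_id: str
    ref_base: str
    alt_base: str
    alt_reads: int
    coverage: int

    @property
    def level(self) -> float:
        return self.alt_reads / self.coverage

    @property
    def mismatch(self) -> str:
        return f"{self.ref_base}-to-{self.alt_base}"


def call_variants(pileup: pd.DataFrame, min_alt: int = 2,
                  bidirectional_sites: set | None = None) -> list[VariantCall]:
    """One call per (site, sample, mismatch type) with >= min_alt reads.

    Sites in bidirectionally transcribed regions (overlapping sense and
    antisense genes) are removed regardless of their counts, since the
    mismatch cannot be assigned to a strand there.
    """
    bidirectional_sites = bidirectional_sites or set()
    calls: list[VariantCall] = []
    for row in pileup.itertuples(index=False):
        if row.site_id in bidirectional_sites:
            continue
        coverage = row.n_A + row.n_C + row.n_G + row.n_T
        if coverage == 0:
            continue
        for base in _BASES:
            if base == row.ref_base:
                continue
            n = getattr(row, f"n_{base}")
            if n >= min_alt:
                calls.append(VariantCall(row.site_id, row.sample_id, row.ref_base,
                                         base, int(n), int(coverage)))
    return calls


def atog_fraction_curve(variants: pd.DataFrame, grid) -> pd.DataFrame:
    """Fraction of variants that are A-to-G at each minimum-level cutoff.

    ``variants`` needs columns ``mismatch`` and ``level``.
    """
    rows = []
    for cutoff in grid:
        passing = variants[variants["level"] >= cutoff]
        n = len(passing)
        frac = float((passing["mismatch"] == "A-to-G").mean()) if n else np.nan
        rows.append((cutoff, n, frac))
    return pd.DataFrame(rows, columns=["cutoff", "n_variants", "atog_fraction"])


def select_frequency_cutoff(curve: pd.DataFrame, min_fraction: float = 0.80):
    """Smallest cutoff whose A-to-G fraction reaches ``min_fraction``.

    Returns (cutoff, curve).  Raises if no cutoff achieves the target,
    reporting the best achievable fraction.
    """
    ok = curve[curve["atog_fraction"] >= min_fraction]
    if len(ok) == 0:
        best = float(np.nanmax(curve["atog_fraction"])) if len(curve) else float("nan")
        raise ValueError(
            f"no cutoff reaches an A-to-G fraction of {min_fraction:.2f}; "
            f"best achievable is {best:.3f}"
        )
    return float(ok["cutoff"].min()), curve


def _calls_frame(calls: list[VariantCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.site_id, c.sample_id, c.mismatch, c.level, c.coverage) for c in calls],
        columns=["site_id", "sample_id", "mismatch", "level", "coverage"],
    )


def identify_shared_editing(calls_a: list[VariantCall], calls_b: list[VariantCall],
                            ortho: pd.DataFrame, cutoff: float) -> pd.DataFrame:
    """Sites called A-to-G at >= cutoff in both species of a pair.

    ``ortho`` maps species-a site_ids to species-b coordinates
    (columns site_id, contig_b, pos_b, strand_flip); species-b calls
    are keyed by "contig:pos".  Both pileups are sense-strand, so a
    flipped mapping still reads A-to-G on its own transcribed strand;
    a site whose mismatch types disagree between species is excluded
    and logged.  Orthologous sites are merged (counted once).
    """
    fa = _calls_frame(calls_a)
    fb = _calls_frame(calls_b)
    if len(fa) == 0 or len(fb) == 0:
        return pd.DataFrame(columns=["site_id", "site_id_b", "mismatch",
                                     "level_a", "level_b"])
    # best (max-level) call per site and mismatch, pooling samples
    fa = fa.sort_values("level").groupby(["site_id", "mismatch"], as_index=False).last()
    fb = fb.sort_values("level").groupby(["site_id", "mismatch"], as_index=False).last()
    ortho = ortho.copy()
    if "site_id_b" not in ortho.columns:
        ortho["site_id_b"] = (
            ortho["contig_b"].astype(str) + ":" + ortho["pos_b"].astype(str)
        )
    merged = fa.merge(ortho[["site_id", "site_id_b"]], on="site_id", how="inner")
    merged = merged.merge(fb, left_on="site_id_b", right_on="site_id",
                          suffixes=("_a", "_b"))
    conflict = merged["mismatch_a"] != merged["mismatch_b"]
    for site in merged.loc[conflict, "site_id_a"].unique():
        logger.info("site %s maps to different mismatch types across species; "
                    "excluded", site)
    same = merged[~conflict]
    shared = same[
        (same["mismatch_a"] == "A-to-G")
        & (same["level_a"] >= cutoff)
        & (same["level_b"] >= cutoff)
    ]
    out = shared.rename(columns={"site_id_a": "site_id",
                                 "mismatch_a": "mismatch"})
    out = out[["site_id", "site_id_b", "mismatch", "level_a", "level_b"]]
    return out.drop_duplicates(subset=["site_id"]).reset_index(drop=True)


def estimate_fdr_with_null(wt: pd.DataFrame, null: pd.DataFrame,
                           alpha: float = 0.05, min_alt: int = 3,
                           min_level: float = 0.015):
    """Validate wild-type A-to-G candidates against an ADAR-null sample.

    Candidates are wild-type sites with more than two altered reads
    (``min_alt`` = 3) and editing level >= 1.5%.  A candidate with zero
    altered reads in the null sample is genuine outright; otherwise a
    two-sided Fisher's exact test on [[G_wt, A_wt], [G_null, A_null]]
    is applied, BH-corrected, and candidates significant at ``alpha``
    are genuine.  Sites the null sample does not cover are reported
    unevaluable and excluded from the FDR denominator.

    Returns (per-site table, estimated FDR).
    """
    null_idx = null.set_index("site_id") if len(null) else pd.DataFrame()
    rows = []
    for row in wt.itertuples(index=False):
        cov = row.n_A + row.n_G
        if cov == 0 or row.n_G < min_alt or row.n_G / cov < min_level:
            continue
        if len(null_idx) == 0 or row.site_id not in null_idx.index:
            rows.append((row.site_id, row.n_G, row.n_A, np.nan, np.nan, "unevaluable"))
            continue
        nrow = null_idx.loc[row.site_id]
        if nrow["n_G"] == 0:
            rows.append((row.site_id, row.n_G, row.n_A, int(nrow["n_G"]),
                         int(nrow["n_A"]), "genuine"))
        else:
            p = fisher_exact([[row.n_G, row.n_A], [nrow["n_G"], nrow["n_A"]]])
            rows.append((row.site_id, row.n_G, row.n_A, int(nrow["n_G"]),
                         int(nrow["n_A"]), p))
    table = pd.DataFrame(rows, columns=["site_id", "g_wt", "a_wt", "g_null",
                                        "a_null", "status"])
    table["status"] = table["status"].astype(object)
    tested = table["status"].apply(lambda s: isinstance(s, float))
    if tested.any():
        padj = bh_adjust(table.loc[tested, "status"].astype(float).to_numpy())
        verdict = np.where(padj < alpha, "genuine", "not_genuine")
        table.loc[tested, "p_fdr"] = padj
        table.loc[tested, "status"] = verdict
    evaluable = table["status"] != "unevaluable"
    n_eval = int(evaluable.sum())
    n_bad = int((table["status"] == "not_genuine").sum())
    fdr = n_bad / n_eval if n_eval else float("nan")
    return table, fdr


def quantify_levels(pileup: pd.DataFrame, min_cov: int,
                    dna_base: dict[str, str] | None = None,
                    platform: str = "rnaseq") -> pd.DataFrame:
    """Editing level G/(A+G) per (site, sample) on the transcribed strand.

    Entries with A+G coverage below ``min_cov`` are undefined and
    dropped.  A site whose DNA base is not 'A' has editing level 0 by
    definition (flagged ``non_a``) -- its orthologous position cannot
    be edited.
    """
    dna_base = dna_base or {}
    rows = []
    for row in pileup.itertuples(index=False):
        base = dna_base.get(row.site_id, row.ref_base)
        cov = row.n_A + row.n_G
        if cov < min_cov:
            continue
        if base != "A":
            rows.append((row.site_id, row.sample_id, 0.0, int(cov), platform, True))
        else:
            rows.append((row.site_id, row.sample_id, row.n_G / cov, int(cov),
                         platform, False))
    return pd.DataFrame(rows, columns=["site_id", "sample_id", "level", "coverage",
                                       "platform", "non_a"])


def combine_platforms(rnaseq: pd.DataFrame, mmpcr: pd.DataFrame,
                      min_cov_mmpcr: int = 50,
                      replicate_max_diff: float = 0.10) -> pd.DataFrame:
    """Merge RNA-seq and replicate mmPCR-seq measurements.

    mmPCR entries (``replicate`` column distinguishing the two
    biological replicates) are kept only when each replicate has >= 50
    reads and the replicates agree within 10%; the combined value is
    the replicate mean.  Where both platforms measure a site, the
    mmPCR-seq value wins.  Provenance is recorded per entry.
    """
    keep = []
    if len(mmpcr):
        for (site, sample), grp in mmpcr.groupby(["site_id", "sample_id"]):
            if len(grp) < 2:
                continue
            reps = grp.sort_values("replicate").head(2)
            if (reps["coverage"] < min_cov_mmpcr).any():
                continue
            l1, l2 = reps["level"].to_numpy()[:2]
            if abs(l1 - l2) > replicate_max_diff:
                continue
            keep.append((site, sample, (l1 + l2) / 2,
                         int(reps["coverage"].min()), "mmpcr"))
    mm = pd.DataFrame(keep, columns=["site_id", "sample_id", "level", "coverage",
                                     "platform"])
    rs = rnaseq[["site_id", "sample_id", "level", "coverage", "platform"]].copy()
    if len(mm) == 0:
        return rs.reset_index(drop=True)
    mm_keys = set(zip(mm["site_id"], mm["sample_id"]))
    rs = rs[[k not in mm_keys for k in zip(rs["site_id"], rs["sample_id"])]]
    if len(rs) == 0:
        return mm
    return pd.concat([mm, rs], ignore_index=True)


def representative_level(levels: pd.DataFrame, min_cov: int = 20) -> pd.Series:
    """Per-site representative level: the maximum across all samples
    with coverage >= min_cov.  Sites with no qualifying entry are
    absent from the result."""
    ok = levels[levels["coverage"] >= min_cov]
    return ok.groupby("site_id")["level"].max()
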