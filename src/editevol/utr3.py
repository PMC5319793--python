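"""Functional analysis of 3'UTR editing.

Three questions: (i) do genes edited in their 3'UTR change expression
when editing is abolished (catalytically dead ADAR vs wild type),
(ii) do 3'UTR sites lose editing between nascent and polyA+ RNA (a
signature of edited-transcript degradation), and (iii) do individual
A-to-G edits create or destroy canonical miRNA seed matches (8mer,
7mer-m8, 7mer-A1) in the 3'UTR?
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import revcomp, to_rna
from .stats import rank_group_test

__all__ = [
    "SeedMatch",
    "group_expression_comparison",
    "nascent_polya_comparison",
    "scan_mirna_seed_changes",
    "seed_sites",
]

MATCH_TYPES = ("8mer", "7mer-m8", "7mer-A1")


@dataclass(frozen=True)
class SeedMatch:
    mirna_id: str
    match_type: str           # 8mer | 7mer-m8 | 7mer-A1
    start: int                # UTR interval, 0-based half-open
    end: int
    status: str = "unchanged"  # gained_by_editing | lost_by_editing | unchanged


def group_expression_comparison(groups: pd.DataFrame,
                                control: str = "control") -> pd.DataFrame:
    """Mann-Whitney U of log2 fold change, each group vs the control.

    ``groups`` needs columns gene, group, log2fc.  The control group is
    typically genes edited only in CDS/5'UTR.  Returns per-group n,
    median log2fc, and the two-sided p-value.
    """
    ctrl = groups.loc[groups["group"] == control, "log2fc"].to_numpy()
    if ctrl.size == 0:
        raise ValueError(f"control group {control!r} is empty")
    rows = []
    for name, grp in groups.groupby("group"):
        vals = grp["log2fc"].to_numpy()
        p = np.nan if name == control else rank_group_test(vals, ctrl)
        rows.append((name, len(vals), float(np.median(vals)), p))
    return pd.DataFrame(rows, columns=["group", "n", "median_log2fc", "p_mwu"])


def nascent_polya_comparison(nascent: pd.DataFrame, polya: pd.DataFrame,
                             categories: dict[str, str],
                             min_cov: int = 20,
                             min_nascent_level: float = 0.05):
    """Per-site polyA-minus-nascent level differences, 3'UTR vs CDS.

    Sites need >= min_cov reads in both datasets and a nascent editing
    level > 5%.  ``categories`` maps site_id to "3UTR" or a CDS
    category.  Returns (per-site table, MWU p comparing the difference
    distributions of 3'UTR vs CDS sites).
    """
    n = nascent.set_index("site_id")
    p = polya.set_index("site_id")
    shared = n.index.intersection(p.index)
    rows = []
    for site in shared:
        nr, pr = n.loc[site], p.loc[site]
        if nr["coverage"] < min_cov or pr["coverage"] < min_cov:
            continue
        if nr["level"] <= min_nascent_level:
            continue
        cat = categories.get(site)
        if cat is None:
            continue
        group = "3UTR" if cat == "3UTR" else "CDS"
        rows.append((site, group, float(pr["level"] - nr["level"])))
    table = pd.DataFrame(rows, columns=["site_id", "group", "difference"])
    utr = table.loc[table["group"] == "3UTR", "difference"]
    cds = table.loc[table["group"] == "CDS", "difference"]
    if len(utr) and len(cds):
        if np.allclose(table["difference"], 0):
            pval = 1.0
        else:
            pval = rank_group_test(utr, cds)
    else:
        pval = float("nan")
    return table, pval


def seed_sites(utr: str, mirna: str, mirna_id: str) -> list[SeedMatch]:
    """Canonical TargetScan site types of one miRNA in one UTR.

    With the miRNA written 5'->3', the seed is positions 2-8.  On the
    mRNA: 7mer-m8 = reverse complement of positions 2-8; 8mer = that
    followed by an A (opposite miRNA position 1); 7mer-A1 = reverse
    complement of positions 2-7 followed by the A anchor.
    """
    utr = to_rna(utr)
    mirna = to_rna(mirna)
    if len(mirna) < 8:
        raise ValueError(f"miRNA {mirna_id} shorter than 8 nt")
    m8 = revcomp(mirna[1:8])      # positions 2-8
    m7 = revcomp(mirna[1:7])      # positions 2-7
    patterns = {
        "8mer": m8 + "A",
        "7mer-m8": m8,
        "7mer-A1": m7 + "A",
    }
    out = []
    for mtype, pat in patterns.items():
        start = utr.find(pat)
        while start != -1:
            out.append(SeedMatch(mirna_id, mtype, start, start + len(pat)))
            start = utr.find(pat, start + 1)
    return out


def _match_key(m: SeedMatch):
    return (m.mirna_id, m.match_type, m.start, m.end)


def scan_mirna_seed_changes(utr: str, edit_positions, mirnas: dict[str, str],
                            expression: dict[str, float] | None = None,
                            min_fraction: float = 0.001) -> list[SeedMatch]:
    """Seed matches gained or lost by editing a 3'UTR.

    Each edit position (must be an A in the unedited UTR) is applied
    independently as an A->G substitution; matches present only in the
    edited sequence are gained, matches present only in the unedited
    sequence *and overlapping the edit* are lost.  miRNAs below the
    expression fraction threshold are skipped when ``expression`` is
    given.
    """
    utr = to_rna(utr)
    if expression is not None:
        mirnas = {mid: seq for mid, seq in mirnas.items()
                  if expression.get(mid, 0.0) > min_fraction}
    baseline: dict[tuple, SeedMatch] = {}
    for mid, seq in mirnas.items():
        for m in seed_sites(utr, seq, mid):
            baseline[_match_key(m)] = m
    changes: list[SeedMatch] = []
    for pos in edit_positions:
        if not 0 <= pos < len(utr) or utr[pos] != "A":
            raise ValueError(f"edit position {pos} is not an A in the UTR")
        edited = utr[:pos] + "G" + utr[pos + 1:]
        for mid, seq in mirnas.items():
            now = {_match_key(m): m for m in seed_sites(edited, seq, mid)}
            for key, m in now.items():
                if key not in baseline:
                    changes.append(SeedMatch(m.mirna_id, m.match_type, m.start,
                                             m.end, "gained_by_editing"))
            for key, m in baseline.items():
                if m.mirna_id != mid:
                    continue
                if key not in now and m.start <= pos < m.end:
                    changes.append(SeedMatch(m.mirna_id, m.match_type, m.start,
                                             m.end, "lost_by_editing"))
    return changes
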