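"""Readers and writers for the external formats the pipeline consumes.

Conventions
-----------
* All coordinates are 0-based half-open internally.  fixedStep wiggle
  input, which is 1-based, is converted on read and back on write.
* Sequences are handled in the RNA alphabet (ACGU) on the transcribed
  strand: minus-strand loci are reverse-complemented at read time and
  DNA ``T`` maps to ``U``.  Editing is an A->G substitution in sequence
  space.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GenomicPosition",
    "SITE_CATEGORIES",
    "ConservationTrack",
    "read_site_table",
    "write_site_table",
    "read_pileup",
    "write_pileup",
    "read_conservation",
    "write_conservation",
    "read_fasta",
    "write_fasta",
    "read_level_matrix",
    "write_level_matrix",
    "read_orthology",
    "read_expression",
    "read_mirna_expression",
    "write_result_table",
    "revcomp",
    "to_rna",
]

SITE_CATEGORIES = frozenset(
    {"nonsynonymous", "synonymous", "stoploss", "5UTR", "3UTR", "intron"}
)

_RNA_COMPLEMENT = str.maketrans("ACGUacgu", "UGCAugca")


def to_rna(seq: str) -> str:
    """Map a DNA/RNA string to uppercase RNA (T -> U)."""
    return seq.upper().replace("T", "U")


def revcomp(seq: str) -> str:
    """Reverse complement in RNA space."""
    return to_rna(seq).translate(_RNA_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicPosition:
    contig: str
    pos: int  # 0-based
    strand: str = "+"

    def __post_init__(self):
        if self.pos < 0:
            raise ValueError(f"negative position: {self.pos}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


# ---------------------------------------------------------------------------
# site tables

_SITE_COLS = ["contig", "start", "end", "site_id", "category", "strand", "gene"]


def read_site_table(path) -> pd.DataFrame:
    """Read a BED-like editing-site table (single-base sites, 0-based)."""
    rows = []
    with _open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != len(_SITE_COLS):
                raise ValueError(
                    f"{path}: line {lineno}: expected {len(_SITE_COLS)} columns, "
                    f"got {len(parts)}"
                )
            contig, start, end, site_id, category, strand, gene = parts
            try:
                start, end = int(start), int(end)
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer coordinate") from exc
            if end != start + 1:
                raise ValueError(
                    f"{path}: line {lineno}: editing sites are single bases "
                    f"(end must equal start+1, got {start}..{end})"
                )
            if category not in SITE_CATEGORIES:
                raise ValueError(
                    f"{path}: line {lineno}: unknown category {category!r}"
                )
            if strand not in ("+", "-"):
                raise ValueError(f"{path}: line {lineno}: bad strand {strand!r}")
            rows.append((contig, start, end, site_id, category, strand, gene))
    return pd.DataFrame(rows, columns=_SITE_COLS)


def write_site_table(table: pd.DataFrame, path) -> None:
    table[_SITE_COLS].to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# pileups

_PILEUP_COLS = ["site_id", "sample_id", "ref_base", "n_A", "n_C", "n_G", "n_T"]


def read_pileup(path) -> pd.DataFrame:
    """Read a per-site base-count table; coverage is the sum of counts."""
    df = pd.read_csv(
        path, sep="\t", names=_PILEUP_COLS, header=None, comment="#",
        dtype={"site_id": str, "sample_id": str, "ref_base": str},
    )
    if len(df) == 0:
        df = pd.DataFrame(columns=_PILEUP_COLS + ["coverage"])
        return df
    counts = df[["n_A", "n_C", "n_G", "n_T"]]
    if (counts.to_numpy() < 0).any():
        bad = df.index[(counts < 0).any(axis=1)][0]
        raise ValueError(f"{path}: negative count at row {bad + 1}")
    dup = df.duplicated(subset=["site_id", "sample_id"])
    if dup.any():
        key = df.loc[dup.idxmax(), ["site_id", "sample_id"]].tolist()
        raise ValueError(f"{path}: duplicate (site, sample) key {tuple(key)}")
    df["coverage"] = counts.sum(axis=1)
    return df


def write_pileup(df: pd.DataFrame, path) -> None:
    df[_PILEUP_COLS].to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# conservation tracks

class ConservationTrack:
    """Per-base conservation scores in [0, 1], addressed 0-based.

    Internally a list of (start, values) segments per contig.  Positions
    not covered by any segment are undefined and report as ``None`` /
    NaN rather than 0.
    """

    def __init__(self):
        self._segments: dict[str, list[tuple[int, np.ndarray]]] = {}

    def add_segment(self, contig: str, start: int, values) -> None:
        values = np.asarray(values, dtype=float)
        if values.size and ((values < 0).any() or (values > 1).any()):
            raise ValueError("conservation scores must lie in [0, 1]")
        self._segments.setdefault(contig, []).append((start, values))
        self._segments[contig].sort(key=lambda s: s[0])

    @property
    def contigs(self):
        return list(self._segments)

    def segments(self, contig: str):
        return list(self._segments.get(contig, []))

    def get(self, contig: str, pos: int) -> Optional[float]:
        for start, values in self._segments.get(contig, []):
            if start <= pos < start + len(values):
                return float(values[pos - start])
        return None

    def get_range(self, contig: str, start: int, end: int) -> np.ndarray:
        """Scores for [start, end); undefined positions are NaN."""
        out = np.full(max(end - start, 0), np.nan)
        for seg_start, values in self._segments.get(contig, []):
            lo = max(start, seg_start)
            hi = min(end, seg_start + len(values))
            if lo < hi:
                out[lo - start : hi - start] = values[lo - seg_start : hi - seg_start]
        return out

    def shifted(self, offset: int) -> "ConservationTrack":
        """A copy with every segment translated by ``offset`` bases."""
        t = ConservationTrack()
        for contig, segs in self._segments.items():
            for start, values in segs:
                t.add_segment(contig, start + offset, values.copy())
        return t


def read_conservation(path) -> ConservationTrack:
    """Read a fixedStep (step=1) wiggle track; 1-based input coordinates."""
    track = ConservationTrack()
    contig, start, values = None, None, []

    def flush():
        if contig is not None and values:
            track.add_segment(contig, start, np.array(values, dtype=float))

    with _open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("track"):
                continue
            if line.startswith("fixedStep"):
                flush()
                fields = dict(kv.split("=") for kv in line.split()[1:])
                if int(fields.get("step", 1)) != 1:
                    raise ValueError(f"{path}: line {lineno}: only step=1 supported")
                contig = fields["chrom"]
                start = int(fields["start"]) - 1  # 1-based -> 0-based
                values = []
            else:
                v = float(line)
                if not 0.0 <= v <= 1.0:
                    raise ValueError(
                        f"{path}: line {lineno}: score {v} outside [0, 1]"
                    )
                values.append(v)
    flush()
    return track


def write_conservation(track: ConservationTrack, path) -> None:
    with open(path, "w") as fh:
        for contig in track.contigs:
            for start, values in track.segments(contig):
                fh.write(f"fixedStep chrom={contig} start={start + 1} step=1\n")
                for v in values:
                    fh.write(f"{v:g}\n")


# ---------------------------------------------------------------------------
# sequences

def read_fasta(path) -> dict[str, str]:
    """Read FASTA into {name: RNA sequence} (T mapped to U)."""
    return {rec.id: to_rna(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# level matrices and misc tables

_LEVEL_COLS = ["site_id", "sample_id", "level", "coverage", "platform"]


def read_level_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#",
                     dtype={"site_id": str, "sample_id": str, "platform": str})
    missing = set(_LEVEL_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: level matrix missing columns {sorted(missing)}")
    return df


def write_level_matrix(df: pd.DataFrame, path) -> None:
    df[_LEVEL_COLS].to_csv(path, sep="\t", index=False)


def read_orthology(path) -> pd.DataFrame:
    """site_id, species_a, species_b, contig_b, pos_b, strand_flip (0/1)."""
    df = pd.read_csv(
        path, sep="\t", comment="#",
        names=["site_id", "species_a", "species_b", "contig_b", "pos_b", "strand_flip"],
        dtype={"site_id": str, "contig_b": str},
    )
    df["strand_flip"] = df["strand_flip"].astype(bool)
    return df


def read_expression(path) -> pd.DataFrame:
    """gene, log2fc, mean_expr."""
    return pd.read_csv(path, sep="\t", comment="#",
                       names=["gene", "log2fc", "mean_expr"], dtype={"gene": str})


def read_mirna_expression(path) -> pd.DataFrame:
    """mirna_id, fraction (of total miRNA reads)."""
    return pd.read_csv(path, sep="\t", comment="#",
                       names=["mirna_id", "fraction"], dtype={"mirna_id": str})


def write_result_table(df: pd.DataFrame, path, config=None) -> None:
    """Write a TSV with a header comment recording version and config hash."""
    from . import __version__

    with open(path, "w") as fh:
        line = f"# editevol {__version__}"
        if config is not None:
            line += f" config={config.hash()} seed={config.rng_seed}"
        fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=False)


def _open(path):
    if hasattr(path, "read"):
        return _io.StringIO(path.read()) if not isinstance(path, _io.StringIO) else path
    return open(path)
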