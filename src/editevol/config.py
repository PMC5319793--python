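"""Pipeline-wide configuration.

Every threshold used by the analysis stages lives here with its default,
so a run is fully described by one serializable object.  Defaults follow
the published conventions for *Drosophila* A-to-I editing analyses:
coverage minima of 20 (RNA-seq) and 50 (mmPCR-seq) reads, presence at
>=10% editing, absence at <=1.5%, an edited call at >=2%, a 1% A-to-G
sequencing error rate, and the editing-complementary-sequence (ECS)
filters of >=20 paired bases with a maximum bulge of 8 within 200 bp
(proximal) or 2,500 bp (distal, smoothed conservation >=0.90).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml


@dataclass
class PipelineConfig:
    # variant calling / site discovery
    min_alt_reads: int = 2          # >=2 supporting reads for a variant call
    fdr_min_alt_reads: int = 3      # "more than two" altered reads for FDR candidates
    fdr_min_level: float = 0.015
    fdr_alpha: float = 0.05
    atog_fraction: float = 0.80     # A-to-G purity required of the shared-variant set
    cutoff_grid: tuple = (0.01, 0.015, 0.02, 0.03, 0.05, 0.10, 0.15, 0.20)

    # quantification
    min_cov_rnaseq: int = 20
    min_cov_mmpcr: int = 50
    replicate_max_diff: float = 0.10
    error_rate: float = 0.01        # typical A-to-G sequencing error rate

    # presence / absence / dating calls
    presence_level: float = 0.10
    absence_level: float = 0.015
    edited_call_level: float = 0.02
    min_defined_species: int = 5

    # motif
    motif_high_level: float = 0.50
    motif_pseudocount: float = 0.5

    # structure / ECS
    half_window: int = 200
    ecs_min_paired: int = 20
    ecs_max_bulge: int = 8
    distal_max_dist: int = 2500
    distal_min_len: int = 20
    distal_min_score: float = 0.90
    smooth_window: int = 51

    # constraint
    constraint_window: int = 30
    constraint_flank: int = 60
    s_region_upstream: int = 15
    s_region_downstream: int = 30
    f_region_len: int = 46
    high_constraint_mean: float = 0.9

    # random forest
    rf_ntree: int = 1000            # configurable up to 10000
    rf_mtry: int = 3

    # 3'UTR / expression
    expr_min_level: float = 0.05
    expr_min_cov: int = 20
    mirna_min_fraction: float = 0.001
    gene_min_abs_log2fc: float = 0.2

    rng_seed: int = 0
    paths: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cutoff_grid"] = list(self.cutoff_grid)
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "cutoff_grid" in data:
            data = dict(data)
            data["cutoff_grid"] = tuple(data["cutoff_grid"])
        return cls(**data)

    def replace(self, **kwargs) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)

    def hash(self) -> str:
        """Stable short hash of the effective configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
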