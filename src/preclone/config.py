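"""Pipeline configuration.

Every tunable of the analysis lives here with its default.  Defaults are the
printed values of the study protocol this package re-implements: somatic
filters require more than 10 reads of coverage with at least 3 variant reads
in tumor and at most 1 in the matched control; force-calling uses a VAF
threshold of 0.02; copy number is computed in 500-Kb windows against a 3-Gb
diploid genome with gain/loss cutoffs at total CN 2.5 and 1.5 (ploidy 2);
the CCF grid has 100 points on [0.01, 1] with a clonal boundary of 0.8; and
signature refitting excludes samples with fewer than 50 SNVs.

The serialized config (and its hash) is stamped into every output header so
that any result file can be traced back to the exact settings that produced
it.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, fields

import yaml


@dataclass
class PipelineConfig:
    # --- somatic filtering ---------------------------------------------
    min_tumor_depth: int = 11       # "more than 10" reads, strict
    min_tumor_alt: int = 3          # "at least 3" variant reads, inclusive
    min_control_depth: int = 11
    max_control_alt: int = 1        # "at most 1", inclusive
    vaf_absent: float = 0.02        # force-calling: present iff VAF >= 0.02
    vaf_germline: float = 0.02      # germline iff control VAF > 0.02

    # --- copy number ----------------------------------------------------
    window_kb: float = 500.0
    genome_gb: float = 3.0          # diploid genome size behind the 500/3 constant
    gain_cn: float = 2.5            # total CN at ploidy 2 -> log2(2.5/2) cutoff
    loss_cn: float = 1.5
    cbs_alpha: float = 0.01
    cbs_n_perm: int = 1000
    cbs_min_width: int = 1      # allow single-window focal segments at desk scale
    loh_baf_threshold: float = 0.15
    loh_min_snps: int = 5
    gc_bins: int = 10

    # --- clonality ------------------------------------------------------
    ccf_grid_size: int = 100        # grid 0.01 .. 1.00
    clonal_cutoff: float = 0.8      # CCF < 0.8 is subclonal

    # --- phylogeny ------------------------------------------------------
    exhaustive_max_leaves: int = 8
    nni_restarts: int = 10

    # --- signatures -----------------------------------------------------
    min_signature_snvs: int = 50
    min_signature_weight: float = 0.06

    # --- cohort statistics ---------------------------------------------
    callable_mb: float = 30.0       # denominator for densities; never stated upstream
    n_perm: int = 10000

    # --- bookkeeping ----------------------------------------------------
    seed: int = 0
    out_dir: str = "preclone_out"

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        data = yaml.safe_load(text) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]


DEFAULT_CONFIG = PipelineConfig()
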