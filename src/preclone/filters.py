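"""Somatic-variant filtering, force-calling and driver determination.

Candidate sites (from upstream joint calling) are retained only when
(1) tumor coverage exceeds 10 reads with at least 3 variant reads in some
sample; (2) the matched control also exceeds 10 reads with at most 1 variant
read; (3) the site is absent from dbSNP 135 unless documented in COSMIC; and
(4) the site is absent from the ESP exome database.  "More than 10" is read
strictly (>= 11); "at least 3" and "at most 1" are inclusive.

Force-calling then rescues sensitivity across regions of the same patient:
once a site is confidently called in one sample, every sibling sample is
genotyped at a relaxed threshold -- present iff its VAF >= 0.02, absent iff
VAF < 0.02 -- while a germline-control VAF > 0.02 removes the site for the
whole patient as a germline variant.

A non-synonymous mutation counts as a putative driver when its gene is in
the squamous-carcinoma significantly-mutated-gene list, is documented in
COSMIC, or belongs to the KEGG pathways-in-cancer gene set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import DEFAULT_CONFIG, PipelineConfig

#: recurrently mutated genes of squamous esophageal carcinoma used as the
#: significantly-mutated-gene criterion (module-level default, overridable)
ESCC_SMG = frozenset({
    "TP53", "NFE2L2", "NOTCH1", "NOTCH2", "ZNF750", "PIK3CA", "FAT1",
    "CDKN2A", "KMT2D", "KMT2C", "EP300", "CREBBP", "AJUBA", "RB1", "FBXW7",
})

#: compact pathways-in-cancer gene set (KEGG-style) for the third criterion
KEGG_CANCER_GENES = frozenset({
    "TP53", "PIK3CA", "KRAS", "NRAS", "HRAS", "EGFR", "ERBB2", "MYC",
    "CCND1", "CDKN2A", "RB1", "PTEN", "APC", "CTNNB1", "SMAD4", "TGFBR2",
    "STK11", "VHL", "MLH1", "BRCA2", "FGFR1", "FGFR2", "FGFR3", "NOTCH1",
    "AKT1", "MTOR", "JAK2", "STAT3", "NFKB1", "WNT5A", "SOX2",
})


@dataclass
class SiteEvidence:
    """Read support and annotation for one candidate somatic site."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    tumor_counts: dict[str, tuple[int, int]]     # sample -> (alt, total)
    control_counts: tuple[int, int] | None       # (alt, total) in germline control
    in_dbsnp: bool = False
    in_cosmic: bool = False
    in_esp: bool = False
    gene: str = ""
    effect: str = "non-silent"                   # 'silent' | 'non-silent'
    effect_detail: str = ""
    needs_review: bool = False                   # set for INDELs (manual-review stand-in)

    def __post_init__(self) -> None:
        for s, (a, n) in self.tumor_counts.items():
            if not (0 <= a <= n):
                raise ValueError(f"{self.chrom}:{self.pos} sample {s}: require 0 <= alt <= total")
        self.needs_review = self.needs_review or len(self.ref) != len(self.alt)

    @property
    def site_id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


@dataclass
class PresenceMatrix:
    """Mutation x sample presence with per-cell VAF and call status."""

    presence: pd.DataFrame   # bool
    vaf: pd.DataFrame        # float
    status: pd.DataFrame     # 'called' | 'force_called' | 'absent' | 'germline_removed'
    removed_germline: list[str] = field(default_factory=list)


def _sample_passes(alt: int, total: int, cfg: PipelineConfig) -> bool:
    return total >= cfg.min_tumor_depth and alt >= cfg.min_tumor_alt


def apply_somatic_filters(
    sites: list[SiteEvidence],
    config: PipelineConfig = DEFAULT_CONFIG,
) -> tuple[list[SiteEvidence], pd.DataFrame]:
    """Apply the four somatic criteria; returns (passing sites, rejection log).

    A site passes when at least one tumor sample meets the depth/alt-read
    requirement, the control meets its depth/alt requirement, and the
    population-database rules hold.  The log records, per rejected site,
    every criterion that failed (1 = tumor support, 2 = control, 3 = dbSNP
    without COSMIC, 4 = ESP).
    """
    passed, log_rows = [], []
    for site in sites:
        if site.control_counts is None:
            raise ValueError(f"missing germline control counts at {site.site_id}")
        failed: list[int] = []
        if not any(_sample_passes(a, n, config) for a, n in site.tumor_counts.values()):
            failed.append(1)
        c_alt, c_tot = site.control_counts
        if not (c_tot >= config.min_control_depth and c_alt <= config.max_control_alt):
            failed.append(2)
        if site.in_dbsnp and not site.in_cosmic:
            failed.append(3)
        if site.in_esp:
            failed.append(4)
        if failed:
            log_rows.append((site.site_id, ",".join(map(str, failed))))
        else:
            passed.append(site)
    log = pd.DataFrame(log_rows, columns=["site", "failed_criteria"])
    return passed, log


def force_call(
    patient_sites: list[SiteEvidence],
    samples: list[str],
    config: PipelineConfig = DEFAULT_CONFIG,
) -> PresenceMatrix:
    """Genotype every (retained site) x (sample) cell of one patient.

    A cell is 'called' when the sample itself passes the standard tumor
    criteria, 'force_called' when it only clears the relaxed VAF >= 0.02
    rule, 'absent' when VAF < 0.02.  Sites whose germline-control VAF
    exceeds 0.02 are removed for the whole patient ('germline_removed').
    Every retained site must be called in at least one sample; a site called
    nowhere raises (there is nothing to rescue).
    """
    ids = [s.site_id for s in patient_sites]
    presence = pd.DataFrame(False, index=ids, columns=samples)
    vaf = pd.DataFrame(0.0, index=ids, columns=samples)
    status = pd.DataFrame("absent", index=ids, columns=samples)
    removed = []
    for site in patient_sites:
        sid = site.site_id
        c_alt, c_tot = site.control_counts if site.control_counts else (0, 0)
        germline_vaf = c_alt / c_tot if c_tot > 0 else 0.0
        if germline_vaf > config.vaf_germline:
            status.loc[sid, :] = "germline_removed"
            removed.append(sid)
            continue
        any_called = False
        for s in samples:
            a, n = site.tumor_counts.get(s, (0, 0))
            v = a / n if n > 0 else 0.0
            vaf.loc[sid, s] = v
            if _sample_passes(a, n, config):
                presence.loc[sid, s] = True
                status.loc[sid, s] = "called"
                any_called = True
            elif v >= config.vaf_absent:
                presence.loc[sid, s] = True
                status.loc[sid, s] = "force_called"
        if not any_called:
            raise ValueError(f"site {sid} not confidently called in any sample: nothing to rescue")
    if removed:
        presence = presence.drop(index=removed)
        vaf = vaf.drop(index=removed)
    return PresenceMatrix(presence=presence, vaf=vaf, status=status,
                          removed_germline=removed)


def classify_driver(
    gene: str,
    effect: str,
    smg_list: frozenset[str] | set[str] = ESCC_SMG,
    cosmic_set: frozenset[str] | set[str] = frozenset(),
    kegg_cancer_genes: frozenset[str] | set[str] = KEGG_CANCER_GENES,
) -> tuple[bool, int | None]:
    """Putative-driver call for a non-synonymous mutation.

    Returns (is_driver, matched criterion): 1 = significantly-mutated-gene
    list, 2 = documented in COSMIC, 3 = KEGG pathways-in-cancer.  Silent
    mutations are not eligible and raise.
    """
    if effect == "silent":
        raise ValueError("driver classification applies to non-synonymous mutations only")
    if gene in smg_list:
        return True, 1
    if gene in cosmic_set:
        return True, 2
    if gene in kegg_cancer_genes:
        return True, 3
    return False, None


def mutation_density(n_mutations: int, callable_mb: float) -> float:
    """Mutations per megabase of callable territory."""
    if callable_mb <= 0:
        raise ValueError("callable_mb must be positive")
    if n_mutations < 0:
        raise ValueError("n_mutations must be non-negative")
    return n_mutations / callable_mb
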