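"""End-to-end orchestration: filter -> cn -> ccf -> tree -> het -> cohort -> sig.

``run_pipeline`` consumes a cohort of per-patient read-count tables (either
a synthetic :class:`~preclone.synthetic.Cohort` or frames loaded from the
interchange TSVs), runs every stage in the order the analysis proceeds, and
writes tidy per-patient and cohort-level reports.  Purity and ploidy are
taken from the sample sheet (they come from upstream allele-specific
fitting); segment-level tumor copy number is recovered from the windowed
coverage track with the sheet purity, LOH from the BAF track with the
purity-aware threshold, and CCFs from the presence matrix plus local copy
number.  Outputs carry the config hash and seed, so identical inputs and
settings reproduce byte-identical reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clonality, copy_number as cnmod, filters, heterogeneity as het
from . import io as pio
from . import phylogeny as phylo
from . import signatures as sigs
from .config import DEFAULT_CONFIG, PipelineConfig
from .synthetic import Cohort, GENE_LOCI


@dataclass
class PatientResult:
    patient_id: str
    presence: pd.DataFrame              # mutations x samples bool
    categories: pd.Series               # trunk/shared/private per mutation
    trunk_proportion: float
    newick: str | None
    ccf: pd.DataFrame                   # mutation, sample, map_ccf, clonal, ...
    pair_metrics: list[het.PairMetrics]
    segments: pd.DataFrame              # per-sample segment calls
    sample_summary: pd.DataFrame        # per-sample purity/ploidy/FGA/doubled/loh17


@dataclass
class CohortReport:
    patients: dict[str, PatientResult]
    gene_frequency: pd.DataFrame
    group_summary: pd.DataFrame
    kruskal: dict[str, tuple[float, float]]
    trunk_bias: dict[str, het.ContingencyResult]
    two_hit: tuple[het.ContingencyResult, pd.DataFrame] | None
    doubling_ccnd1: tuple[int, float] | None
    signature_weights: pd.DataFrame
    burden: pd.DataFrame                # per-sample non-silent mutation counts


# ---------------------------------------------------------------------------
# per-patient stages
# ---------------------------------------------------------------------------

def _sites_from_frames(variants: pd.DataFrame, controls: pd.DataFrame,
                       samples: list[str]) -> list[filters.SiteEvidence]:
    ctrl = controls.set_index("mutation_id")
    out = []
    for mid, grp in variants.groupby("mutation_id", sort=False):
        first = grp.iloc[0]
        counts = {row["sample"]: (int(row.a), int(row.n)) for _, row in grp.iterrows()}
        for s in samples:
            counts.setdefault(s, (0, 0))
        out.append(
            filters.SiteEvidence(
                chrom=first.chrom, pos=int(first.pos), ref=first.ref, alt=first.alt,
                tumor_counts=counts,
                control_counts=(int(ctrl.loc[mid, "a"]), int(ctrl.loc[mid, "n"])),
                gene=first.gene, effect=first.effect,
                effect_detail=str(first.get("protein_change", "")),
            )
        )
    return out


def _segment_sample(cov: pd.DataFrame, baf: pd.DataFrame, purity: float,
                    dat_gb: float, config: PipelineConfig,
                    genome_gb: float) -> pd.DataFrame:
    """Window CN -> segmentation -> tumor CN / allele CN / status / LOH."""
    cov = cov.sort_values(["chrom", "start"]).reset_index(drop=True)
    windows = [cnmod.CoverageWindow(r.chrom, int(r.start), int(r.end),
                                    float(r.cov_kb), float(r.gc))
               for r in cov.itertuples()]
    widths = cov.end - cov.start
    cn_eff = cnmod.window_cn(
        cov.cov_kb.to_numpy() * (config.window_kb * 1000 / widths.to_numpy()),
        dat_gb, window_kb=config.window_kb, genome_gb=genome_gb,
        gc=cov.gc.to_numpy(), gc_bins=config.gc_bins,
    )
    segs = cnmod.segment_cn(windows, cn_eff, alpha=config.cbs_alpha,
                            min_width=config.cbs_min_width,
                            n_perm=config.cbs_n_perm, seed=config.seed)
    p = purity
    rows = []
    for seg in segs:
        # absolute tumor copy number from the effective (mixture) CN
        cn_tumor = max((seg.mean_cn - 2.0 * (1 - p)) / p, 0.0)
        cn_int = int(round(cn_tumor))
        sel = baf[(baf.chrom == seg.chrom) & (baf.pos > seg.start) & (baf.pos <= seg.end)]
        n_snps = len(sel)
        minor = None
        loh = None
        if n_snps >= config.loh_min_snps and cn_int >= 1:
            folded = np.minimum(sel.baf, 1 - sel.baf)
            denom = cn_int * p + 2 * (1 - p)
            minor = int(np.clip(round((folded.mean() * denom - (1 - p)) / p),
                                0, cn_int // 2))
            loh = cnmod.call_loh(sel.baf.to_numpy(),
                                 threshold=config.loh_baf_threshold,
                                 min_snps=config.loh_min_snps,
                                 purity=p, cn=cn_int)
        rows.append({
            "chrom": seg.chrom, "start": seg.start, "end": seg.end,
            "n_windows": seg.n_windows, "mean_cn": seg.mean_cn,
            "cn_tumor": cn_tumor, "cn_int": cn_int,
            "minor": minor,
            "major": None if minor is None else cn_int - minor,
            "n_snps": n_snps, "loh": loh,
        })
    return pd.DataFrame(rows)


def analyze_patient(
    patient_id: str,
    variants: pd.DataFrame,
    controls: pd.DataFrame,
    coverage: pd.DataFrame,
    baf: pd.DataFrame,
    sheet: pd.DataFrame,
    config: PipelineConfig = DEFAULT_CONFIG,
    genome_gb: float | None = None,
) -> PatientResult:
    samples = list(sheet["sample"])
    purity = dict(zip(sheet["sample"], sheet["purity"]))

    # --- filter + force-calling --------------------------------------
    sites = _sites_from_frames(variants, controls, samples)
    passed, _log = filters.apply_somatic_filters(sites, config)
    matrix = filters.force_call(passed, samples, config)

    # --- copy number ---------------------------------------------------
    if genome_gb is None:
        span = coverage.groupby("chrom")["end"].max().sum()
        genome_gb = span / 1e9
    seg_frames, summary_rows = [], []
    for s in samples:
        srow = sheet[sheet["sample"] == s].iloc[0]
        segs = _segment_sample(coverage[coverage["sample"] == s],
                               baf[baf["sample"] == s], float(srow.purity),
                               float(srow.dat_gb), config, genome_gb)
        ploidy = float(
            (segs.cn_tumor * (segs.end - segs.start)).sum()
            / (segs.end - segs.start).sum()
        )
        segs["status"] = [cnmod.call_gain_loss(r.cn_tumor, ploidy,
                                               config.gain_cn, config.loss_cn)
                          for r in segs.itertuples()]
        cn_segments = [
            cnmod.Segment(r.chrom, int(r.start), int(r.end), int(r.n_windows),
                          r.mean_cn, r.status, r.loh,
                          int(r.n_snps), r.major, r.minor)
            for r in segs.itertuples()
        ]
        fga = cnmod.fraction_genome_altered(cn_segments)
        doubled = cnmod.call_genome_doubling(cn_segments)
        tp53_chrom = GENE_LOCI["TP53"][0]
        tp53_pos = GENE_LOCI["TP53"][1]
        in_seg = segs[(segs.chrom == tp53_chrom) & (segs.start < tp53_pos)
                      & (segs.end >= tp53_pos)]
        loh17 = bool(in_seg.loh.iloc[0]) if len(in_seg) and in_seg.loh.iloc[0] is not None else False
        ccnd1 = GENE_LOCI["CCND1"]
        amp_seg = segs[(segs.chrom == ccnd1[0]) & (segs.start < ccnd1[1])
                       & (segs.end >= ccnd1[1])]
        ccnd1_amp = bool(len(amp_seg) and amp_seg.cn_int.iloc[0] >= 5)
        segs.insert(0, "sample", s)
        seg_frames.append(segs)
        summary_rows.append({
            "sample": s, "purity": float(srow.purity), "ploidy": ploidy,
            "fga": fga, "doubled": doubled, "tp53_loh": loh17,
            "ccnd1_amp": ccnd1_amp,
        })
    segments = pd.concat(seg_frames, ignore_index=True)
    sample_summary = pd.DataFrame(summary_rows)

    # --- CCF ------------------------------------------------------------
    var_idx = variants.set_index(["mutation_id", "sample"])
    pos_of = variants.drop_duplicates("mutation_id").set_index("mutation_id")
    ccf_rows = []
    for mid in matrix.presence.index:
        vrow = pos_of.loc[_strip_site(mid, pos_of)]
        for s in samples:
            if not matrix.presence.loc[mid, s]:
                continue
            a, n = var_idx.loc[(vrow.name, s), ["a", "n"]].astype(int)
            if n == 0:
                continue
            p = float(purity[s])
            seg = segments[(segments["sample"] == s) & (segments.chrom == vrow.chrom)
                           & (segments.start < vrow.pos) & (segments.end >= vrow.pos)]
            if len(seg):
                cn = max(int(seg.cn_int.iloc[0]), 1)
                major = seg.major.iloc[0]
                minor = seg.minor.iloc[0]
            else:
                cn, major, minor = 2, 1, 1
            if major is None or pd.isna(major) or major < 1:
                cnt = 1
            else:
                cnt, _ = clonality.choose_cnt(int(a), int(n), p, cn,
                                              int(major), int(max(minor, 0)))
            est = clonality.ccf_posterior(
                clonality.CcfInput(int(a), int(n), p, cn, min(cnt, cn)),
                grid_size=config.ccf_grid_size,
                clonal_cutoff=config.clonal_cutoff,
            )
            ccf_rows.append({
                "mutation_id": mid, "sample": s, "map_ccf": est.map_ccf,
                "clonal": est.clonal, "a": int(a), "n": int(n),
                "cn": cn, "cnt": min(cnt, cn),
            })
    ccf = pd.DataFrame(ccf_rows)

    # --- phylogeny ------------------------------------------------------
    cm = phylo.CharacterMatrix(matrix.presence.T.astype(bool)) if len(samples) >= 2 else None
    if cm is not None:
        categories = phylo.classify_trunk_shared_private(cm)
        trunk_prop = phylo.trunk_proportion(cm)
        tree = phylo.build_parsimony_tree(
            cm, exhaustive_max=config.exhaustive_max_leaves,
            nni_restarts=config.nni_restarts, seed=config.seed,
        )
        newick = tree.newick
    else:
        categories = pd.Series(dtype=object)
        trunk_prop = float("nan")
        newick = None

    # --- heterogeneity --------------------------------------------------
    grades = dict(zip(sheet["sample"], sheet["grade"]))
    try:
        pairs = het.group_pairs(matrix.presence, grades, config.callable_mb)
    except ValueError:
        pairs = []

    return PatientResult(
        patient_id=patient_id, presence=matrix.presence, categories=categories,
        trunk_proportion=trunk_prop, newick=newick, ccf=ccf,
        pair_metrics=pairs, segments=segments, sample_summary=sample_summary,
    )


def _strip_site(site_id: str, pos_of: pd.DataFrame):
    """Map a site id chrom:pos:ref>alt back to its mutation_id row."""
    if site_id in pos_of.index:
        return site_id
    chrom, pos, change = site_id.split(":")
    ref, alt = change.split(">")
    match = pos_of[(pos_of.chrom == chrom) & (pos_of.pos == int(pos))
                   & (pos_of.ref == ref) & (pos_of.alt == alt)]
    if len(match) != 1:
        raise KeyError(f"cannot map site {site_id} to a mutation id")
    return match.index[0]


# ---------------------------------------------------------------------------
# cohort level
# ---------------------------------------------------------------------------

def run_pipeline(
    cohort: Cohort,
    config: PipelineConfig = DEFAULT_CONFIG,
    outdir: str | Path | None = None,
) -> CohortReport:
    """Run every stage over a cohort and assemble the report bundle."""
    patients: dict[str, PatientResult] = {}
    for pt in cohort.patients:
        reads = pt.reads
        patients[pt.patient_id] = analyze_patient(
            pt.patient_id, reads.variants, reads.controls, reads.coverage,
            reads.baf, reads.sample_sheet, config,
        )

    sheet = cohort.sample_sheet

    # mutation burden per sample (non-silent, detected)
    burden_rows = []
    gene_hits: dict[str, set[str]] = {}
    for pid, res in patients.items():
        reads = next(p.reads for p in cohort.patients if p.patient_id == pid)
        ann = reads.variants.drop_duplicates("mutation_id").set_index("mutation_id")
        for s in res.presence.columns:
            present = res.presence.index[res.presence[s]]
            mids = [_strip_site(m, ann) for m in present]
            nonsil = [m for m in mids if ann.loc[m, "effect"] == "non-silent"]
            burden_rows.append({"patient": pid, "sample": s,
                                "cohort": sheet[sheet["sample"] == s].cohort.iloc[0],
                                "n_nonsilent": len(nonsil)})
            for m in nonsil:
                gene_hits.setdefault(ann.loc[m, "gene"], set()).add(pid)
    burden = pd.DataFrame(burden_rows)

    n_patients = len(patients)
    gene_frequency = pd.DataFrame(
        sorted(((g, len(pids) / n_patients) for g, pids in gene_hits.items()),
               key=lambda t: -t[1]),
        columns=["gene", "frequency"],
    )

    # pairwise heterogeneity groups across the cohort
    all_pairs = [m for res in patients.values() for m in res.pair_metrics]
    group_summary = (
        pd.DataFrame([{"group": m.group, "hi": m.hi, "euclidean": m.euclidean,
                       "intersection_density": m.intersection_density}
                      for m in all_pairs])
        .groupby("group").median().reset_index()
        if all_pairs else pd.DataFrame(columns=["group", "hi", "euclidean",
                                                "intersection_density"])
    )
    kruskal = {}
    if all_pairs:
        for metric in ("hi", "euclidean"):
            groups = {}
            for m in all_pairs:
                groups.setdefault(m.group, []).append(getattr(m, metric))
            if len(groups) >= 2 and all(groups.values()):
                kruskal[metric] = het.kruskal_wallis(
                    {g: np.array(v) for g, v in groups.items()}
                )

    # trunk bias per driver gene, pooled over multi-sample patients
    trunk_counts: dict[str, list[int]] = {}
    tot_trunk = tot_branch = 0
    for pid, res in patients.items():
        if res.categories.empty:
            continue
        reads = next(p.reads for p in cohort.patients if p.patient_id == pid)
        ann = reads.variants.drop_duplicates("mutation_id").set_index("mutation_id")
        for sid, cat in res.categories.items():
            mid = _strip_site(sid, ann)
            gene = ann.loc[mid, "gene"]
            is_trunk = cat == "trunk"
            tot_trunk += is_trunk
            tot_branch += not is_trunk
            if gene in filters.ESCC_SMG:
                trunk_counts.setdefault(gene, [0, 0])[0 if is_trunk else 1] += 1
    trunk_bias = {}
    for gene, (t, b) in trunk_counts.items():
        trunk_bias[gene] = het.trunk_bias_test(t, b, tot_trunk - t, tot_branch - b)

    # TP53 two-hit across cohorts
    statuses = []
    for pid, res in patients.items():
        reads = next(p.reads for p in cohort.patients if p.patient_id == pid)
        ann = reads.variants.drop_duplicates("mutation_id").set_index("mutation_id")
        for s in res.presence.columns:
            present = res.presence.index[res.presence[s]]
            mids = [_strip_site(m, ann) for m in present]
            n_tp53 = sum(1 for m in mids
                         if ann.loc[m, "gene"] == "TP53"
                         and ann.loc[m, "effect"] == "non-silent")
            row = res.sample_summary[res.sample_summary["sample"] == s].iloc[0]
            statuses.append(het.TwoHitStatus(
                sample_id=s,
                group=sheet[sheet["sample"] == s].cohort.iloc[0],
                n_mutations=n_tp53, loh=bool(row.tp53_loh),
            ))
    two_hit = None
    groups_present = {st.group for st in statuses if not st.excluded}
    if len(groups_present) >= 2:
        two_hit = het.two_hit_analysis(statuses)

    # genome doubling x CCND1 amplification
    doubling_ccnd1 = None
    summ = pd.concat([r.sample_summary for r in patients.values()], ignore_index=True)
    known = summ[summ.doubled.notna()]
    if len(known) >= 2 and known.doubled.astype(bool).any():
        doubling_ccnd1 = het.cooccurrence_permutation(
            known.doubled.astype(bool).to_numpy(),
            known.ccnd1_amp.astype(bool).to_numpy(),
            n_perm=config.n_perm, seed=config.seed,
        )

    # signatures per sample
    refs = sigs.reference_signatures()
    sig_rows = []
    for pid, res in patients.items():
        reads = next(p.reads for p in cohort.patients if p.patient_id == pid)
        ann = reads.variants.drop_duplicates("mutation_id").set_index("mutation_id")
        for s in res.presence.columns:
            present = res.presence.index[res.presence[s]]
            mids = [_strip_site(m, ann) for m in present]
            spec = sigs.spectrum(ann.loc[mids, ["ref", "alt", "context"]])
            dec = sigs.decompose(spec, refs,
                                 min_snvs=config.min_signature_snvs,
                                 min_weight=config.min_signature_weight)
            for name, w in dec.weights.items():
                sig_rows.append({"patient": pid, "sample": s,
                                 "signature": name, "weight": w,
                                 "excluded": dec.excluded})
            if dec.excluded:
                sig_rows.append({"patient": pid, "sample": s, "signature": None,
                                 "weight": float("nan"), "excluded": True})
    signature_weights = pd.DataFrame(sig_rows)

    report = CohortReport(
        patients=patients, gene_frequency=gene_frequency,
        group_summary=group_summary, kruskal=kruskal, trunk_bias=trunk_bias,
        two_hit=two_hit, doubling_ccnd1=doubling_ccnd1,
        signature_weights=signature_weights, burden=burden,
    )
    if outdir is not None:
        _write_report(report, cohort, config, Path(outdir))
    return report


def _write_report(report: CohortReport, cohort: Cohort, config: PipelineConfig,
                  outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    seed = cohort.seed
    pio.write_tsv(report.gene_frequency, outdir / "gene_frequency.tsv",
                  None, config, seed)
    pio.write_tsv(report.burden, outdir / "burden.tsv", None, config, seed)
    pio.write_tsv(report.group_summary, outdir / "group_summary.tsv",
                  None, config, seed)
    pio.write_tsv(report.signature_weights, outdir / "signature_weights.tsv",
                  None, config, seed)
    pairs = pd.DataFrame(
        [{"patient": pid, "sample_a": m.sample_a, "sample_b": m.sample_b,
          "group": m.group, "hi": m.hi, "euclidean": m.euclidean,
          "intersection_density": m.intersection_density}
         for pid, res in report.patients.items() for m in res.pair_metrics]
    )
    pio.write_tsv(pairs, outdir / "pair_metrics.tsv", None, config, seed)
    segs = pd.concat(
        [res.segments.assign(patient=pid) for pid, res in report.patients.items()],
        ignore_index=True,
    )
    pio.write_tsv(segs, outdir / "segments.seg.tsv", None, config, seed)
    summaries = pd.concat(
        [res.sample_summary.assign(patient=pid)
         for pid, res in report.patients.items()],
        ignore_index=True,
    )
    pio.write_tsv(summaries, outdir / "sample_summary.tsv", None, config, seed)
    ccf = pd.concat(
        [res.ccf.assign(patient=pid) for pid, res in report.patients.items()
         if len(res.ccf)],
        ignore_index=True,
    )
    pio.write_tsv(ccf, outdir / "ccf.tsv", None, config, seed)
    stat_lines = [f"# config_hash: {config.config_hash()}", f"# seed: {seed}"]
    if report.two_hit is not None:
        res, summary = report.two_hit
        stat_lines.append(f"two_hit_p\t{res.p_value:.6g}")
        stat_lines.append("two_hit_table\t" + summary.to_json(orient="records"))
    if report.doubling_ccnd1 is not None:
        obs, p = report.doubling_ccnd1
        stat_lines.append(f"doubling_ccnd1_observed\t{obs}")
        stat_lines.append(f"doubling_ccnd1_p\t{p:.6g}")
    for gene, res in report.trunk_bias.items():
        stat_lines.append(f"trunk_bias_{gene}_p\t{res.p_value:.6g}")
    for metric, (h, p) in report.kruskal.items():
        stat_lines.append(f"kruskal_{metric}\tH={h:.4g}\tp={p:.6g}")
    (outdir / "cohort_stats.tsv").write_text("\n".join(stat_lines) + "\n")
    for pid, res in report.patients.items():
        if res.newick:
            pio.write_newick(res.newick, outdir / f"tree_{pid}.nwk")
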