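"""Readers and writers for the pipeline's text interchange formats.

All interchange is TSV-first, with commented ``#`` header lines carrying
provenance (package version, config hash, seed).  Coordinate conventions:
MAF-like variant tables and VCF are 1-based inclusive; BED-like window
coverage is 0-based half-open.  Schemas:

* MAF-like variants: mutation_id, sample, chrom, pos, ref, alt, gene,
  effect, context, protein_change, a (alt reads), n (total depth)
* sample sheet: patient, sample, grade (N/LD/HD/ESCC/MET/NTD),
  cohort (TD/NTD), adjacent, purity, ploidy, callable_mb, dat_gb
* window coverage (BED-like): sample, chrom, start, end, cov_kb, gc
* BAF table: sample, chrom, pos, depth, baf
* SEG segments: sample, chrom, start, end, n_windows, mean_cn, status, loh

A minimal VCF reader (AD/DP genotype fields) is provided for variant input;
round-trips through write/read are lossless on canonical frames.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import pandas as pd

from . import __version__ as _pkg_version
from .config import PipelineConfig

GRADES = {"N", "LD", "HD", "ESCC", "MET", "NTD"}

SCHEMAS: dict[str, list[str]] = {
    "variants": ["mutation_id", "sample", "chrom", "pos", "ref", "alt",
                 "gene", "effect", "context", "protein_change", "a", "n"],
    "sample_sheet": ["patient", "sample", "grade", "cohort", "adjacent",
                     "purity", "ploidy", "callable_mb", "dat_gb"],
    "coverage": ["sample", "chrom", "start", "end", "cov_kb", "gc"],
    "baf": ["sample", "chrom", "pos", "depth", "baf"],
    "segments": ["sample", "chrom", "start", "end", "n_windows", "mean_cn",
                 "status", "loh"],
}


def _header_lines(config: PipelineConfig | None, seed: int | None,
                  extra: dict | None = None) -> list[str]:
    lines = [f"# preclone_version: {_pkg_version}"]
    if config is not None:
        lines.append(f"# config_hash: {config.config_hash()}")
    if seed is not None:
        lines.append(f"# seed: {seed}")
    for k, v in (extra or {}).items():
        lines.append(f"# {k}: {v}")
    return lines


def write_tsv(
    df: pd.DataFrame,
    path: str | Path,
    schema: str | None = None,
    config: PipelineConfig | None = None,
    seed: int | None = None,
    extra_header: dict | None = None,
) -> Path:
    """Write a frame as TSV with a commented provenance header."""
    path = Path(path)
    if schema is not None:
        cols = SCHEMAS[schema]
        missing = set(cols) - set(df.columns)
        if missing:
            raise ValueError(f"{schema} frame lacks columns {sorted(missing)}")
        df = df[cols]
    buf = _io.StringIO()
    for line in _header_lines(config, seed, extra_header):
        buf.write(line + "\n")
    df.to_csv(buf, sep="\t", index=False)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(buf.getvalue())
    return path


def read_tsv(path: str | Path, schema: str | None = None) -> pd.DataFrame:
    """Read a commented-header TSV, validating the schema when named."""
    path = Path(path)
    n_fields = None
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if line.startswith("#") or not line.strip():
            continue
        k = line.count("\t") + 1
        if n_fields is None:
            n_fields = k
        elif k != n_fields:
            raise ValueError(
                f"malformed TSV {path}: line {lineno} has {k} fields, "
                f"expected {n_fields}")
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed TSV {path}: {exc}") from exc
    for col in df.columns:
        if df[col].dtype == object:
            df[col] = df[col].fillna("")
    if schema is not None:
        missing = set(SCHEMAS[schema]) - set(df.columns)
        if missing:
            raise ValueError(f"{path} is not a valid {schema} table; "
                             f"missing columns {sorted(missing)}")
        if schema == "variants":
            for c in ("gene", "effect", "context", "protein_change"):
                df[c] = df[c].fillna("").astype(str)
        if schema == "sample_sheet":
            bad = set(df.grade) - GRADES
            if bad:
                raise ValueError(f"{path}: unknown grades {sorted(bad)}")
    return df


def read_vcf(path: str | Path, sample_of: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a minimal VCF (v4.x with AD or DP/AF) into the variants schema.

    Positions stay 1-based.  ``sample_of`` optionally renames VCF sample
    columns.  Only the first ALT allele of each record is used.
    """
    import pysam

    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if not rec.alts:
                continue
            alt = rec.alts[0]
            gene = rec.info.get("GENE", "") if "GENE" in rec.header.info else ""
            for sample in rec.samples:
                call = rec.samples[sample]
                ad = call.get("AD")
                if ad is not None and len(ad) >= 2 and ad[0] is not None:
                    a = int(ad[1])
                    n = int(sum(x for x in ad if x is not None))
                else:
                    n = int(call.get("DP") or 0)
                    a = int(round((call.get("AF") or 0.0) * n))
                name = (sample_of or {}).get(sample, sample)
                rows.append(
                    (f"{rec.chrom}:{rec.pos}:{rec.ref}>{alt}", name, rec.chrom,
                     rec.pos, rec.ref, alt, gene, "non-silent", "", "", a, n)
                )
    return pd.DataFrame(rows, columns=SCHEMAS["variants"])


def write_newick(newick: str, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(newick.rstrip() + "\n")
    return path


def write_dataset(reads, outdir: str | Path,
                  config: PipelineConfig | None = None) -> dict[str, Path]:
    """Write a synthetic read set as its five interchange files."""
    outdir = Path(outdir)
    seed = reads.seed
    return {
        "variants": write_tsv(reads.variants, outdir / "variants.maf.tsv",
                              "variants", config, seed),
        "sample_sheet": write_tsv(reads.sample_sheet, outdir / "sample_sheet.tsv",
                                  "sample_sheet", config, seed),
        "coverage": write_tsv(reads.coverage, outdir / "coverage.bed.tsv",
                              "coverage", config, seed),
        "baf": write_tsv(reads.baf, outdir / "baf.tsv", "baf", config, seed),
        "controls": write_tsv(reads.controls, outdir / "controls.tsv",
                              None, config, seed),
        "truth": write_tsv(reads.truth, outdir / "truth.tsv", None, config, seed),
        "segment_truth": write_tsv(reads.segment_truth, outdir / "segment_truth.tsv",
                                   None, config, seed),
    }
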