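"""Windowed copy number from low-depth WGS, segmentation and CNA calls.

Copy number per 500-Kb window follows from the sequencing arithmetic of a
3-Gb diploid genome: at 1x depth a window of width w Kb collects w Kb of
coverage, so with observed window coverage Cov (Kb) and total data volume
Dat (Gb),

    CN / 2 = (Cov / Dat) / (w / G)        (default w = 500 Kb, G = 3 Gb)

after GC normalization (windows binned by GC content, divided by their
bin's median coverage and rescaled to the genome median).  Windows are
merged into segments by recursive binary segmentation in the circular-
binary-segmentation style: the split maximizing the between-segment
t-statistic is accepted when its permutation p-value clears alpha.

Segment calls: with sample ploidy pl, x = log2(CN / pl) is a gain when
x >= log2(2.5/2) and a loss when x <= log2(1.5/2) (inclusive boundaries).
LOH is a mean B-allele-frequency deviation from 0.5 above threshold
(default 0.15, >= 5 supporting SNPs; a purity-aware threshold of half the
expected full-LOH deviation is available when purity and CN are known).
Genome doubling is called when the major allele has CN >= 2 over more than
half of the assessed genome length -- the convention of allele-specific
callers, since no printed criterion exists.  The fraction of genome altered
is the summed length of non-neutral segments over the total segment length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CoverageWindow", "Segment", "SampleCnProfile",
    "window_cn", "segment_values", "segment_cn", "call_gain_loss",
    "fraction_genome_altered", "call_loh", "loh_threshold_purity_aware",
    "call_genome_doubling", "estimate_purity_ploidy", "classify_cna_ubiquity",
]

GAIN_LOG2 = float(np.log2(2.5 / 2.0))
LOSS_LOG2 = float(np.log2(1.5 / 2.0))
_EPS = 1e-12


@dataclass(frozen=True)
class CoverageWindow:
    chrom: str
    start: int  # 0-based half-open
    end: int
    cov_kb: float
    gc: float = 0.4


@dataclass
class Segment:
    chrom: str
    start: int
    end: int
    n_windows: int
    mean_cn: float
    status: str = "neutral"          # gain | loss | neutral
    loh: bool | None = None          # None = indeterminate
    n_snps: int = 0
    major: int | None = None
    minor: int | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SampleCnProfile:
    sample_id: str
    purity: float
    ploidy: float
    segments: list[Segment]
    doubled: bool | None = None
    fga: float | None = None
    warning: str = ""


def window_cn(
    cov_kb: np.ndarray,
    dat_gb: float,
    window_kb: float = 500.0,
    genome_gb: float = 3.0,
    gc: np.ndarray | None = None,
    gc_bins: int = 10,
) -> np.ndarray:
    """Per-window copy number: CN = 2 (Cov/Dat) / (window_kb/genome_gb).

    When ``gc`` is given, coverage is first normalized within GC bins
    (quantile bins; each window divided by its bin's median and rescaled to
    the genome-wide median).
    """
    if dat_gb <= 0:
        raise ValueError("total data volume must be positive")
    cov = np.asarray(cov_kb, dtype=float).copy()
    if np.any(cov < 0):
        raise ValueError("window coverage must be non-negative")
    if gc is not None and len(cov) >= gc_bins:
        gc = np.asarray(gc, dtype=float)
        overall = np.median(cov)
        if overall > 0:
            qs = np.quantile(gc, np.linspace(0, 1, gc_bins + 1))
            bins = np.clip(np.searchsorted(qs, gc, side="right") - 1, 0, gc_bins - 1)
            for b in range(gc_bins):
                mask = bins == b
                med = np.median(cov[mask]) if mask.any() else 0.0
                if med > 0:
                    cov[mask] = cov[mask] / med * overall
    return 2.0 * (cov / dat_gb) / (window_kb / genome_gb)


def _max_t_split(x: np.ndarray, min_width: int) -> tuple[int | None, float]:
    """Best single changepoint by the two-sample t-statistic."""
    n = len(x)
    best_k, best_t = None, 0.0
    csum = np.cumsum(x)
    csq = np.cumsum(x * x)
    for k in range(min_width, n - min_width + 1):
        n1, n2 = k, n - k
        s1, s2 = csum[k - 1], csum[-1] - csum[k - 1]
        m1, m2 = s1 / n1, s2 / n2
        ss1 = csq[k - 1] - n1 * m1 * m1
        ss2 = (csq[-1] - csq[k - 1]) - n2 * m2 * m2
        if n <= 2:
            continue
        pooled = (ss1 + ss2) / (n - 2)
        denom = np.sqrt(max(pooled, 0.0) * (1 / n1 + 1 / n2))
        diff = abs(m1 - m2)
        t = np.inf if denom < _EPS and diff > _EPS else (diff / denom if denom >= _EPS else 0.0)
        if t > best_t:
            best_k, best_t = k, t
    return best_k, best_t


def segment_values(
    values: np.ndarray,
    alpha: float = 0.01,
    min_width: int = 2,
    n_perm: int = 1000,
    seed: int = 0,
) -> list[tuple[int, int, float]]:
    """Recursive changepoint segmentation of one ordered value track.

    Returns (start, end, mean) index triplets (end exclusive).  A candidate
    split (the maximal-|t| changepoint) is accepted when fewer than
    alpha * (n_perm + 1) - 1 permutations of the segment achieve an equal
    or larger statistic; an infinite statistic (two exactly-constant,
    different-mean halves) is accepted outright.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        return [(0, len(x), float(x.mean()) if len(x) else float("nan"))]
    rng = np.random.default_rng(seed)
    out: list[tuple[int, int, float]] = []

    def rec(lo: int, hi: int) -> None:
        seg = x[lo:hi]
        if hi - lo < 2 * min_width or np.ptp(seg) < _EPS:
            out.append((lo, hi, float(seg.mean())))
            return
        k, t = _max_t_split(seg, min_width)
        accept = False
        if k is not None and np.isinf(t):
            accept = True
        elif k is not None and t > 0:
            exceed = 0
            for _ in range(n_perm):
                perm = rng.permutation(seg)
                _, tp = _max_t_split(perm, min_width)
                if tp >= t:
                    exceed += 1
            pval = (1 + exceed) / (n_perm + 1)
            accept = pval < alpha
        if accept:
            rec(lo, lo + k)
            rec(lo + k, hi)
        else:
            out.append((lo, hi, float(seg.mean())))

    rec(0, len(x))
    return sorted(out)


def segment_cn(
    windows: list[CoverageWindow],
    cn_values: np.ndarray,
    alpha: float = 0.01,
    min_width: int = 2,
    n_perm: int = 1000,
    seed: int = 0,
) -> list[Segment]:
    """Segment per-window CN values chromosome by chromosome."""
    if len(windows) != len(cn_values):
        raise ValueError("windows and cn_values must align")
    if len(windows) < 2:
        raise ValueError("need at least 2 windows to segment")
    df = pd.DataFrame(
        {
            "chrom": [w.chrom for w in windows],
            "start": [w.start for w in windows],
            "end": [w.end for w in windows],
            "cn": np.asarray(cn_values, dtype=float),
        }
    )
    segments: list[Segment] = []
    for chrom, grp in df.groupby("chrom", sort=False):
        grp = grp.sort_values("start").reset_index(drop=True)
        if len(grp) == 1:
            segments.append(Segment(chrom, int(grp.start[0]), int(grp.end[0]), 1,
                                    float(grp.cn[0])))
            continue
        for lo, hi, mean in segment_values(grp.cn.to_numpy(), alpha=alpha,
                                           min_width=min_width, n_perm=n_perm,
                                           seed=seed):
            segments.append(
                Segment(chrom, int(grp.start[lo]), int(grp.end[hi - 1]),
                        hi - lo, mean)
            )
    return segments


def call_gain_loss(cn: float, ploidy: float,
                   gain_cn: float = 2.5, loss_cn: float = 1.5) -> str:
    """Gain/loss/neutral from ploidy-scaled log2 ratio (inclusive cutoffs)."""
    if ploidy <= 0:
        raise ValueError("ploidy must be positive")
    if cn <= 0:
        return "loss"
    x = np.log2(cn / ploidy)
    if x >= np.log2(gain_cn / 2.0) - _EPS:
        return "gain"
    if x <= np.log2(loss_cn / 2.0) + _EPS:
        return "loss"
    return "neutral"


def fraction_genome_altered(segments: list[Segment]) -> float:
    """Length of gained or lost segments over the total segment length."""
    total = sum(s.length for s in segments)
    if total <= 0:
        raise ValueError("profile has zero total segment length")
    altered = sum(s.length for s in segments if s.status != "neutral")
    return altered / total


def loh_threshold_purity_aware(purity: float, cn: int) -> float:
    """Half the expected BAF deviation of a full (minor = 0) LOH.

    For minor CN 0 at purity p and total CN the expected B-allele frequency
    is (1-p) / (CN p + 2 (1-p)), hence a deviation of 0.5 minus that; the
    decision threshold sits halfway between no-LOH (0) and full LOH.
    """
    if not (0 < purity <= 1) or cn < 1:
        raise ValueError("need purity in (0,1] and CN >= 1")
    dev_full = 0.5 - (1 - purity) / (cn * purity + 2 * (1 - purity))
    return max(dev_full / 2.0, 0.0)


def call_loh(
    baf_values: np.ndarray,
    threshold: float = 0.15,
    min_snps: int = 5,
    purity: float | None = None,
    cn: int | None = None,
) -> bool | None:
    """LOH iff mean |BAF - 0.5| exceeds the threshold; None when indeterminate.

    With ``purity`` and ``cn`` supplied, the purity-aware threshold replaces
    the fixed default.  Fewer than ``min_snps`` supporting SNPs (or an empty
    list) yields the indeterminate status rather than an exception.
    """
    baf = np.asarray(baf_values, dtype=float)
    if len(baf) < min_snps:
        return None
    if purity is not None and cn is not None:
        threshold = loh_threshold_purity_aware(purity, cn)
    return bool(np.mean(np.abs(baf - 0.5)) > threshold)


def call_genome_doubling(segments: list[Segment]) -> bool | None:
    """Doubled iff major CN >= 2 over more than half the assessed length.

    Requires major CN on at least 50% of the total segment length;
    otherwise indeterminate (None).
    """
    total = sum(s.length for s in segments)
    informative = [s for s in segments if s.major is not None]
    if total <= 0 or sum(s.length for s in informative) < 0.5 * total:
        return None
    assessed = sum(s.length for s in informative)
    doubled_len = sum(s.length for s in informative if s.major >= 2)
    return bool(doubled_len > 0.5 * assessed)


def estimate_purity_ploidy(
    depth_ratios: np.ndarray,
    mean_bafs: np.ndarray,
    lengths: np.ndarray,
    purity_grid: np.ndarray | None = None,
    ploidy_grid: np.ndarray | None = None,
    max_cn: int = 8,
) -> tuple[float, float, bool]:
    """Grid purity/ploidy fit from per-segment depth ratios and BAFs.

    Plumbing that replaces a full allele-specific likelihood fit: for each
    candidate (p, ploidy) every segment is assigned its best integer
    (CN, minor) and the candidate minimizing the length-weighted squared
    error of (depth ratio, BAF) wins; ties break toward lower ploidy, then
    higher purity.  A flat, balanced profile is unidentifiable and returns
    (1, 2) with the warning flag set.
    """
    dr = np.asarray(depth_ratios, dtype=float)
    baf = np.asarray(mean_bafs, dtype=float)
    w = np.asarray(lengths, dtype=float)
    if len(dr) == 0:
        raise ValueError("need at least one segment")
    if np.ptp(dr) < 0.02 and abs(dr.mean() - 1.0) < 0.05 and np.all(np.abs(baf - 0.5) < 0.05):
        return 1.0, 2.0, True
    if purity_grid is None:
        purity_grid = np.round(np.arange(0.10, 1.0001, 0.05), 2)
    if ploidy_grid is None:
        ploidy_grid = np.round(np.arange(1.5, 5.0001, 0.1), 1)
    # candidate states (CN, minor)
    states = [(cn, m) for cn in range(0, max_cn + 1) for m in range(0, cn // 2 + 1)]
    cn_arr = np.array([s[0] for s in states], dtype=float)
    minor_arr = np.array([s[1] for s in states], dtype=float)
    best = None
    for pl in ploidy_grid:           # outer loop in ploidy order -> lower wins ties
        for p in purity_grid[::-1]:  # higher purity wins ties
            denom_seg = cn_arr * p + 2 * (1 - p)                 # per state
            denom_sample = pl * p + 2 * (1 - p)
            pred_dr = denom_seg / denom_sample                   # (n_states,)
            pred_baf = (minor_arr * p + (1 - p)) / np.maximum(denom_seg, _EPS)
            err = ((dr[:, None] - pred_dr[None, :]) ** 2
                   + (baf[:, None] - pred_baf[None, :]) ** 2)    # (n_seg, n_states)
            cost = float((w * err.min(axis=1)).sum())
            if best is None or cost < best[0] - 1e-12:
                best = (cost, float(p), float(pl))
    return best[1], best[2], False


def classify_cna_ubiquity(
    statuses: dict[str, str],
    breakpoints: dict[str, tuple[int, int]] | None = None,
    tolerance_bp: int = 500_000,
) -> tuple[str, bool | None]:
    """Is a recurrent CNA event ubiquitous, partial or absent in a patient?

    ``statuses`` maps sample -> gain/loss/neutral for the event region;
    non-neutral counts as carrying the event.  With per-sample breakpoints
    supplied, concordance is true when every carrier's start and end agree
    within ``tolerance_bp`` (one window by default) -- shared breakpoints
    support early, pre-divergence acquisition of the event.
    """
    if len(statuses) < 2:
        raise ValueError("need at least 2 samples")
    carrier = {s: st != "neutral" for s, st in statuses.items()}
    n_car = sum(carrier.values())
    if n_car == len(carrier):
        label = "ubiquitous"
    elif n_car > 0:
        label = "partial"
    else:
        label = "absent"
    concordant: bool | None = None
    if breakpoints is not None:
        carriers = [s for s, c in carrier.items() if c and s in breakpoints]
        if len(carriers) >= 2:
            starts = [breakpoints[s][0] for s in carriers]
            ends = [breakpoints[s][1] for s in carriers]
            concordant = (max(starts) - min(starts) <= tolerance_bp
                          and max(ends) - min(ends) <= tolerance_bp)
    return label, concordant
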