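"""Pairwise heterogeneity metrics and cohort-level statistics.

For two samples with mutation sets A and B the heterogeneity index is the
Jaccard distance

    HI = 1 - |A ∩ B| / |A ∪ B|

(0 for identical regions, 1 for disjoint ones).  Euclidean distance on the
binary presence vectors and the density of intersecting mutations (shared
mutations per callable Mb, negated for display so that larger always means
more heterogeneous) are companion metrics.  Pairs are grouped
carcinoma-carcinoma (C-C), carcinoma-dysplasia (C-D) and
dysplasia-dysplasia (D-D) -- low- and high-grade dysplasia both count as D,
normals are excluded -- and compared with the tie-corrected Kruskal-Wallis
test.

Cohort tests: a Fisher exact test for whether a driver gene's mutations are
biased toward the trunk (the gene's trunk/branch split against all other
mutations pooled); a margin-preserving permutation test for co-occurrence
of genome doubling and CCND1-like amplification; and the TP53 two-hit
contingency analysis (two-hit = mutation AND LOH, with samples carrying
more than one mutation but no LOH excluded, since their second hit may be
the second mutation).  Copy-number concordance between two regions is the
Pearson correlation of depth ratios over breakpoint-harmonized segments.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairMetrics", "TwoHitStatus", "ContingencyResult",
    "heterogeneity_index", "pair_distances", "group_pairs", "kruskal_wallis",
    "trunk_bias_test", "cooccurrence_permutation", "two_hit_analysis",
    "cna_concordance",
]

DYSPLASIA_GRADES = {"LD", "HD", "NTD"}
CARCINOMA_GRADES = {"ESCC", "MET"}


@dataclass
class PairMetrics:
    sample_a: str
    sample_b: str
    group: str                 # C-C | C-D | D-D
    hi: float
    euclidean: float
    intersection_density: float   # shared mutations per callable Mb (positive)


@dataclass
class TwoHitStatus:
    sample_id: str
    group: str                 # cohort or grade label used for the contingency
    n_mutations: int           # non-silent mutations in the gene
    loh: bool

    @property
    def two_hit(self) -> bool:
        return self.n_mutations >= 1 and self.loh

    @property
    def excluded(self) -> bool:
        # a second point mutation can substitute for LOH as the second hit
        return self.n_mutations > 1 and not self.loh


@dataclass
class ContingencyResult:
    table: np.ndarray
    odds_ratio: float
    p_value: float
    test: str


def heterogeneity_index(a: set, b: set) -> float:
    """HI = 1 - |A ∩ B| / |A ∪ B| (Jaccard distance between mutation sets)."""
    union = a | b
    if not union:
        raise ValueError("both mutation sets are empty")
    return 1.0 - len(a & b) / len(union)


def pair_distances(
    vec_a: np.ndarray,
    vec_b: np.ndarray,
    callable_mb: float = 30.0,
) -> tuple[float, float]:
    """(Euclidean distance, intersection density) for one pair.

    Vectors are binary presence over the union of the patient's mutations.
    Intersection density = |A ∩ B| / callable Mb; report it negated when
    ordering by heterogeneity.
    """
    va = np.asarray(vec_a, dtype=float)
    vb = np.asarray(vec_b, dtype=float)
    if va.shape != vb.shape:
        raise ValueError("presence vectors must have equal length")
    if callable_mb <= 0:
        raise ValueError("callable_mb must be positive")
    dist = float(np.linalg.norm(va - vb))
    shared = float(np.sum((va > 0) & (vb > 0)))
    return dist, shared / callable_mb


def _pair_group(grade_a: str, grade_b: str) -> str:
    kinds = []
    for g in (grade_a, grade_b):
        if g in CARCINOMA_GRADES:
            kinds.append("C")
        elif g in DYSPLASIA_GRADES:
            kinds.append("D")
        else:
            raise ValueError(f"unknown histology grade {g!r}")
    return "-".join(sorted(kinds))


def group_pairs(
    presence: pd.DataFrame,
    grades: dict[str, str],
    callable_mb: float = 30.0,
    use_vaf: pd.DataFrame | None = None,
) -> list[PairMetrics]:
    """All unordered sample pairs of one patient with metrics and C/D group.

    ``presence`` is mutations x samples boolean; normals (grade 'N') are
    excluded; an unknown grade raises naming the sample.  With ``use_vaf``
    the Euclidean distance runs on VAF vectors instead of binary presence.
    """
    for s in presence.columns:
        grade = grades.get(s)
        if grade is None:
            raise ValueError(f"sample {s} has no histology grade")
        if grade != "N" and grade not in DYSPLASIA_GRADES | CARCINOMA_GRADES:
            raise ValueError(f"sample {s} has unknown histology grade {grade!r}")
    samples = [s for s in presence.columns if grades[s] != "N"]
    out = []
    for sa, sb in combinations(samples, 2):
        group = _pair_group(grades[sa], grades[sb])
        set_a = set(presence.index[presence[sa]])
        set_b = set(presence.index[presence[sb]])
        hi = heterogeneity_index(set_a, set_b)
        if use_vaf is not None:
            dist = float(np.linalg.norm(use_vaf[sa] - use_vaf[sb]))
            density = len(set_a & set_b) / callable_mb
        else:
            dist, density = pair_distances(
                presence[sa].to_numpy(), presence[sb].to_numpy(), callable_mb
            )
        out.append(PairMetrics(sa, sb, group, hi, dist, density))
    return out


def kruskal_wallis(groups: dict[str, np.ndarray]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value."""
    if len(groups) < 2 or any(len(v) == 0 for v in groups.values()):
        raise ValueError("need >= 2 non-empty groups")
    values = [np.asarray(v, dtype=float) for v in groups.values()]
    if np.ptp(np.concatenate(values)) == 0:
        return 0.0, 1.0
    h, p = stats.kruskal(*values)
    return float(h), float(p)


def trunk_bias_test(
    gene_trunk: int,
    gene_branch: int,
    background_trunk: int,
    background_branch: int,
) -> ContingencyResult:
    """Fisher exact test: is a gene's trunk/branch split biased vs background?

    Background = all other mutations pooled across the cohort.
    """
    if gene_trunk + gene_branch == 0:
        raise ValueError("alteration observed in no patient")
    table = np.array([[gene_trunk, gene_branch],
                      [background_trunk, background_branch]])
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return ContingencyResult(table=table, odds_ratio=float(odds),
                             p_value=float(p), test="fisher_exact")


def cooccurrence_permutation(
    flags_a: np.ndarray,
    flags_b: np.ndarray,
    n_perm: int = 10000,
    seed: int = 0,
    patient_ids: np.ndarray | None = None,
) -> tuple[int, float]:
    """Margin-preserving permutation test of flag co-occurrence.

    The observed count of samples carrying both flags is compared against
    ``n_perm`` shuffles of ``flags_b`` (the amplification labels); the
    empirical p-value uses the add-one estimator
    (1 + #{perm >= obs}) / (n_perm + 1), so its floor is 1/(n_perm + 1).
    With ``patient_ids``, whole patients are shuffled as blocks instead of
    samples (an option, since sample-level exchangeability is an
    assumption).
    """
    a = np.asarray(flags_a, dtype=bool)
    b = np.asarray(flags_b, dtype=bool)
    if a.shape != b.shape or len(a) < 2:
        raise ValueError("flag vectors must have equal length >= 2")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    observed = int(np.sum(a & b))
    if patient_ids is None:
        B = np.tile(b.astype(np.int64), (n_perm, 1))
        B = rng.permuted(B, axis=1)
        perm_counts = B @ a.astype(np.int64)
    else:
        pids = np.asarray(patient_ids)
        unique = pd.unique(pids)
        blocks = [np.flatnonzero(pids == u) for u in unique]
        perm_counts = np.empty(n_perm, dtype=int)
        for i in range(n_perm):
            order = rng.permutation(len(blocks))
            shuffled = np.concatenate([b[blocks[j]] for j in order])[:len(b)]
            perm_counts[i] = int(np.sum(a & shuffled))
    p = (1 + int(np.sum(perm_counts >= observed))) / (n_perm + 1)
    return observed, float(p)


def two_hit_analysis(
    statuses: list[TwoHitStatus],
) -> tuple[ContingencyResult, pd.DataFrame]:
    """Group x two-hit contingency after applying the exclusion rule.

    Samples with more than one mutation but no LOH are excluded (their
    second mutation may itself be the second hit).  Returns the test result
    (Fisher exact for 2 groups, chi-square otherwise) and the per-group
    count table (two_hit / no_two_hit / excluded).
    """
    rows = []
    for st in statuses:
        rows.append((st.sample_id, st.group, st.two_hit, st.excluded))
    df = pd.DataFrame(rows, columns=["sample", "group", "two_hit", "excluded"])
    kept = df[~df.excluded]
    if kept.empty:
        raise ValueError("all samples excluded by the two-hit rule")
    summary_rows = []
    for g, sub in df.groupby("group"):
        k = sub[~sub.excluded]
        summary_rows.append(
            (g, int(k.two_hit.sum()), int((~k.two_hit).sum()), int(sub.excluded.sum()))
        )
    summary = pd.DataFrame(
        summary_rows, columns=["group", "two_hit", "no_two_hit", "excluded"]
    )
    groups = sorted(kept.group.unique())
    table = np.array([
        [int(((kept.group == g) & kept.two_hit).sum()),
         int(((kept.group == g) & ~kept.two_hit).sum())]
        for g in groups
    ])
    if table.shape[0] == 2:
        odds, p = stats.fisher_exact(table)
        res = ContingencyResult(table, float(odds), float(p), "fisher_exact")
    elif table.shape[0] < 2:
        raise ValueError("need at least 2 groups after exclusion")
    else:
        chi2, p, _, _ = stats.chi2_contingency(table)
        res = ContingencyResult(table, float("nan"), float(p), "chi2_contingency")
    return res, summary


def cna_concordance(
    seg_a: pd.DataFrame,
    seg_b: pd.DataFrame,
) -> tuple[float, int]:
    """Pearson r of depth ratios over breakpoint-harmonized segments.

    Both frames need chrom/start/end/depth_ratio columns.  Partially
    overlapping segments are split at the union of the two samples'
    breakpoints and each harmonized piece contributes one (unweighted)
    paired observation.  Returns (r, number of harmonized segments);
    r is NaN when either profile is flat over the shared territory.
    """
    required = {"chrom", "start", "end", "depth_ratio"}
    for name, df in (("A", seg_a), ("B", seg_b)):
        if not required <= set(df.columns):
            raise ValueError(f"profile {name} lacks columns {required - set(df.columns)}")
    xs, ys = [], []
    for chrom in sorted(set(seg_a.chrom) & set(seg_b.chrom)):
        sa = seg_a[seg_a.chrom == chrom]
        sb = seg_b[seg_b.chrom == chrom]
        cuts = sorted(set(sa.start) | set(sa.end) | set(sb.start) | set(sb.end))
        for lo, hi in zip(cuts[:-1], cuts[1:]):
            mid = (lo + hi) / 2
            ra = sa[(sa.start <= mid) & (sa.end > mid)]
            rb = sb[(sb.start <= mid) & (sb.end > mid)]
            if len(ra) == 1 and len(rb) == 1:
                xs.append(float(ra.depth_ratio.iloc[0]))
                ys.append(float(rb.depth_ratio.iloc[0]))
    if not xs:
        raise ValueError("profiles share no covered territory")
    x, y = np.array(xs), np.array(ys)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), len(x)
    r = float(np.corrcoef(x, y)[0, 1])
    return r, len(x)
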