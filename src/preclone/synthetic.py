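"""Synthetic multi-region tumor/precursor datasets with known ground truth.

Every downstream stage of the pipeline is tested against data produced here:
a rooted clone tree per patient (root = founding clone; mutations on a node
are inherited by all descendants, so the root set is the trunk), regions
that are purity-diluted mixtures of clones, and read counts drawn from the
same expected-VAF model the clonality module inverts.  Because the truth
(per-mutation CCF, per-segment copy number, doubling status) is emitted
alongside the reads, recovery can be checked exactly.

What is emulated: branched clonal evolution with trunk/shared/private
mutation structure; deamination-dominated (Signature.1-heavy) trinucleotide
contexts; arm-level copy-number events including a trunk 3q-like gain,
monoallelic TP53-locus deletion (the LOH half of a two-hit), focal CCND1-like
amplification and optional whole-genome doubling; region purities in the
0.3-0.9 range typical of microdissected lesions; Poisson depth / binomial
alt-count sampling at a configurable mean depth (default 80x, matching
targeted-region practice) and a low-depth whole-genome coverage track.

What is NOT emulated: read-level artifacts (mapping, FFPE damage beyond an
optional uniform low-VAF noise rate), spatial geometry of regions, germline
variation beyond heterozygous-SNP BAF draws.

The genome model is configurable; the default is the 22 autosomes at
hg19 lengths scaled by 1/100 so that window counts stay desk-scale while
chromosome structure is preserved.  All randomness flows from one integer
seed through spawned child generators; every artifact records its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clonality import expected_vaf
from . import signatures as sigs

#: (name, length) of the 22 autosomes, hg19 lengths / 100 (desk-scale).
DEFAULT_GENOME: tuple[tuple[str, int], ...] = tuple(
    (f"chr{i + 1}", length // 100)
    for i, length in enumerate(
        [
            249250621, 243199373, 198022430, 191154276, 180915260, 171115067,
            159138663, 146364022, 141213431, 135534747, 135006516, 133851895,
            115169878, 107349540, 102531392, 90354753, 81195210, 78077248,
            59128983, 63025520, 48129895, 51304566,
        ]
    )
)

#: landmark gene positions on the scaled genome (hg19 starts / 100)
GENE_LOCI: dict[str, tuple[str, int]] = {
    "TP53": ("chr17", 75_712),
    "CCND1": ("chr11", 694_556),
    "SOX2": ("chr3", 1_814_298),
    "PIK3CA": ("chr3", 1_789_211),
    "NFE2L2": ("chr2", 1_780_953),
    "NOTCH1": ("chr9", 1_393_886),
    "MYC": ("chr8", 1_287_480),
    "FGFR1": ("chr8", 382_684),
    "RB1": ("chr13", 488_777),
    "EGFR": ("chr7", 550_868),
}


@dataclass(frozen=True)
class SegmentCN:
    """Allele-specific copy number of one genomic interval in one clone."""

    chrom: str
    start: int  # 0-based half-open
    end: int
    total: int
    major: int
    minor: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("segment end must exceed start")
        if self.minor < 0 or self.major < self.minor or self.total != self.major + self.minor:
            raise ValueError("require total = major + minor and major >= minor >= 0")


@dataclass(frozen=True)
class Mutation:
    id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    context: str        # reference-strand trinucleotide
    gene: str
    effect: str         # 'silent' | 'non-silent'
    protein_change: str
    clone: int          # clone on which the mutation arose


@dataclass
class CloneTree:
    """Rooted clone tree: node 0 is the founding clone (its mutations are the trunk)."""

    chromosomes: tuple[tuple[str, int], ...]
    parent: dict[int, int | None]                 # node -> parent (root -> None)
    mutations: dict[int, list[Mutation]]          # novel mutations per node
    segments: dict[int, list[SegmentCN]]          # full CN profile per node
    doubled_clone: int | None = None              # clone where genome doubling occurred
    seed: int | None = None

    @property
    def nodes(self) -> list[int]:
        return sorted(self.parent)

    def ancestors_or_self(self, node: int) -> list[int]:
        out, cur = [], node
        while cur is not None:
            out.append(cur)
            cur = self.parent[cur]
        return out

    def clone_mutations(self, node: int) -> list[Mutation]:
        """All mutations carried by a clone (own plus inherited)."""
        out: list[Mutation] = []
        for a in reversed(self.ancestors_or_self(node)):
            out.extend(self.mutations[a])
        return out

    def all_mutations(self) -> list[Mutation]:
        return [m for n in self.nodes for m in self.mutations[n]]

    def carriers(self, mutation: Mutation) -> set[int]:
        """Clones carrying a mutation = the subtree below its origin node."""
        origin = mutation.clone
        return {n for n in self.nodes if origin in self.ancestors_or_self(n)}

    def is_doubled(self, node: int) -> bool:
        return self.doubled_clone is not None and self.doubled_clone in self.ancestors_or_self(node)

    def segment_at(self, node: int, chrom: str, pos: int) -> SegmentCN:
        for seg in self.segments[node]:
            if seg.chrom == chrom and seg.start < pos <= seg.end:
                return seg
        raise KeyError(f"no segment covering {chrom}:{pos} in clone {node}")


@dataclass
class RegionMixture:
    """One sequenced region: a purity-diluted mixture over the clone tree."""

    sample_id: str
    histology: str      # N | LD | HD | ESCC | MET | NTD
    cohort: str         # TD | NTD
    purity: float
    fractions: dict[int, float]   # clone -> fraction of cancer cells, sums to 1

    def __post_init__(self) -> None:
        if not (0 <= self.purity <= 1):
            raise ValueError("purity must lie in [0, 1]")
        tot = sum(self.fractions.values())
        if any(f < 0 for f in self.fractions.values()) or abs(tot - 1) > 1e-9:
            raise ValueError("clone fractions must be >= 0 and sum to 1")

    @property
    def dominant_clone(self) -> int:
        return max(sorted(self.fractions), key=lambda c: self.fractions[c])


@dataclass
class SyntheticReadSet:
    """Read-count level output plus the generating truth."""

    variants: pd.DataFrame      # mutation_id, sample, chrom, pos, ref, alt, gene, effect, context, a, n
    controls: pd.DataFrame      # mutation_id, a, n in the germline control
    truth: pd.DataFrame         # mutation_id, sample, true_ccf, cn, cnt, vafe
    coverage: pd.DataFrame      # sample, chrom, start, end, cov_kb, gc
    baf: pd.DataFrame           # sample, chrom, pos, depth, baf
    sample_sheet: pd.DataFrame  # patient, sample, grade, cohort, adjacent, purity, ploidy, callable_mb, dat_gb
    segment_truth: pd.DataFrame  # sample, chrom, start, end, total, major, minor, doubled
    seed: int


# ---------------------------------------------------------------------------
# clone tree
# ---------------------------------------------------------------------------

def _diploid_profile(genome) -> list[SegmentCN]:
    return [SegmentCN(c, 0, ln, 2, 1, 1) for c, ln in genome]


def _apply_event(profile: list[SegmentCN], chrom: str, start: int, end: int,
                 total: int, major: int, minor: int) -> list[SegmentCN]:
    """Overwrite [start, end) on one chromosome with the given allele CN."""
    out: list[SegmentCN] = []
    for seg in profile:
        if seg.chrom != chrom or seg.end <= start or seg.start >= end:
            out.append(seg)
            continue
        if seg.start < start:
            out.append(SegmentCN(chrom, seg.start, start, seg.total, seg.major, seg.minor))
        out.append(SegmentCN(chrom, max(seg.start, start), min(seg.end, end), total, major, minor))
        if seg.end > end:
            out.append(SegmentCN(chrom, end, seg.end, seg.total, seg.major, seg.minor))
    return out


def _double(profile: list[SegmentCN]) -> list[SegmentCN]:
    return [SegmentCN(s.chrom, s.start, s.end, 2 * s.total, 2 * s.major, 2 * s.minor)
            for s in profile]


def simulate_clone_tree(
    n_clones: int,
    n_trunk: int,
    n_per_branch: int,
    seed: int,
    genome: tuple[tuple[str, int], ...] = DEFAULT_GENOME,
    signature_weights: dict[str, float] | None = None,
    references: pd.DataFrame | None = None,
    topology: dict[int, int] | None = None,
    trunk_3q_gain: bool = False,
    tp53_two_hit: bool = False,
    doubled_clone: int | None = None,
    ccnd1_amp_clone: int | None = None,
    frac_non_silent: float = 0.8,
) -> CloneTree:
    """Simulate a rooted clone tree with mutations and CN profiles.

    The root (clone 0) carries exactly ``n_trunk`` mutations -- the trunk --
    and every other clone acquires ``n_per_branch`` novel mutations.
    Trinucleotide contexts are drawn from a signature mixture (default 0.7
    weight on the deamination-like Signature.1, the remainder uniform), so
    cohort spectra are Signature.1-dominated by construction.  Optional
    copy-number events: a trunk gain of the whole 3q-like chromosome 3, a
    monoallelic TP53-locus deletion on the trunk (LOH), a focal CCND1-like
    amplification, and a whole-genome doubling at ``doubled_clone`` (applied
    to that clone and inherited by its descendants; mutations acquired at or
    above the doubled clone sit on two copies afterwards).
    """
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    if n_trunk < 0 or n_per_branch < 0:
        raise ValueError("mutation counts must be non-negative")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    if references is None:
        references = sigs.reference_signatures()
    if signature_weights is None:
        signature_weights = {"Signature.1": 0.7}
        rest = 0.3 / (len(references) - 1)
        for name in references.index[1:]:
            signature_weights[name] = rest

    if topology is None:
        parent: dict[int, int | None] = {0: None}
        for node in range(1, n_clones):
            parent[node] = int(rng.integers(0, node))
    else:
        parent = {0: None, **{k: v for k, v in topology.items() if k != 0}}
        if sorted(parent) != list(range(n_clones)):
            raise ValueError("topology must cover clones 0..n_clones-1")

    # mutations
    chrom_names = [c for c, _ in genome]
    chrom_lens = np.array([ln for _, ln in genome], dtype=float)
    chrom_p = chrom_lens / chrom_lens.sum()
    mutations: dict[int, list[Mutation]] = {n: [] for n in range(n_clones)}
    counter = 0

    def draw(node: int, n_mut: int, forced_gene: str | None = None) -> None:
        nonlocal counter
        ctxs = sigs.sample_contexts(n_mut, signature_weights, references, rng)
        for ref, alt, ctx in ctxs:
            counter += 1
            if forced_gene and counter == 1 and node == 0:
                pass  # forced drivers are added separately below
            ci = rng.choice(len(genome), p=chrom_p)
            pos = int(rng.integers(1, genome[ci][1]))
            effect = "non-silent" if rng.random() < frac_non_silent else "silent"
            gene = f"G{rng.integers(1, 2000):04d}"
            mutations[node].append(
                Mutation(
                    id=f"m{counter:05d}", chrom=chrom_names[ci], pos=pos,
                    ref=ref, alt=alt, context=ctx, gene=gene, effect=effect,
                    protein_change=f"p.X{counter}Y" if effect == "non-silent" else "",
                    clone=node,
                )
            )

    draw(0, n_trunk)
    for node in range(1, n_clones):
        draw(node, n_per_branch)

    if tp53_two_hit and n_trunk > 0:
        # replace one trunk passenger with a TP53 missense (keeps the count exact)
        old = mutations[0][0]
        chrom, pos = GENE_LOCI["TP53"]
        mutations[0][0] = Mutation(
            id=old.id, chrom=chrom, pos=pos, ref="C", alt="T", context="ACG",
            gene="TP53", effect="non-silent", protein_change="p.R175H", clone=0,
        )

    # copy-number profiles, inherited parent -> child
    segments: dict[int, list[SegmentCN]] = {}
    for node in range(n_clones):
        prof = _diploid_profile(genome) if parent[node] is None else list(segments[parent[node]])
        if node == 0:
            if trunk_3q_gain:
                ln = dict(genome)["chr3"]
                prof = _apply_event(prof, "chr3", 0, ln, 3, 2, 1)
            if tp53_two_hit:
                chrom, pos = GENE_LOCI["TP53"]
                prof = _apply_event(prof, chrom, 0, dict(genome)[chrom], 1, 1, 0)
        if doubled_clone is not None and node == doubled_clone:
            prof = _double(prof)
        if ccnd1_amp_clone is not None and node == ccnd1_amp_clone:
            # focal high-level amplification wide enough to cover a window
            chrom, pos = GENE_LOCI["CCND1"]
            lo, hi = max(0, pos - 300_000), pos + 300_000
            prof = _apply_event(prof, chrom, lo, hi, 6, 5, 1)
        segments[node] = prof

    return CloneTree(
        chromosomes=tuple(genome), parent=parent, mutations=mutations,
        segments=segments, doubled_clone=doubled_clone, seed=seed,
    )


# ---------------------------------------------------------------------------
# regions
# ---------------------------------------------------------------------------

def simulate_regions(
    tree: CloneTree,
    n_regions: int,
    purity_range: tuple[float, float] = (0.3, 0.9),
    mixing: float = 0.0,
    seed: int = 0,
    histologies: list[str] | None = None,
    cohort: str = "TD",
    dominant_clones: list[int] | None = None,
    sample_prefix: str = "S",
) -> list[RegionMixture]:
    """Draw sequenced regions from a clone tree.

    Each region is dominated by one clone; a ``mixing`` fraction of its
    cancer cells belongs to the dominant clone's parent (regions dominated
    by the root stay pure).  With mixing = 0 every region is a single pure
    clone, so all its mutations are fully clonal (true CCF 1).  Purities are
    drawn uniformly from ``purity_range``.
    """
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    if not tree.parent:
        raise ValueError("empty clone tree")
    if not (0 <= mixing < 1):
        raise ValueError("mixing must lie in [0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    nodes = tree.nodes
    if dominant_clones is None:
        order = list(rng.permutation(nodes))
        dominant_clones = [order[i % len(order)] for i in range(n_regions)]
    if histologies is None:
        histologies = ["ESCC"] * n_regions
    regions = []
    for i in range(n_regions):
        dom = dominant_clones[i]
        par = tree.parent[dom]
        if mixing > 0 and par is not None:
            fractions = {dom: 1.0 - mixing, par: mixing}
        else:
            fractions = {dom: 1.0}
        purity = float(rng.uniform(*purity_range))
        regions.append(
            RegionMixture(
                sample_id=f"{sample_prefix}{i + 1}",
                histology=histologies[i], cohort=cohort,
                purity=purity, fractions=fractions,
            )
        )
    return regions


def true_ccf(tree: CloneTree, region: RegionMixture, mutation: Mutation) -> float:
    """Ground-truth CCF: summed fractions of the clones carrying the mutation."""
    carriers = tree.carriers(mutation)
    return float(sum(f for c, f in region.fractions.items() if c in carriers))


def true_ccf_table(tree: CloneTree, regions: list[RegionMixture]) -> pd.DataFrame:
    """Mutations x regions matrix of ground-truth CCFs."""
    muts = tree.all_mutations()
    data = {
        r.sample_id: [true_ccf(tree, r, m) for m in muts] for r in regions
    }
    return pd.DataFrame(data, index=[m.id for m in muts])


def _site_cn(tree: CloneTree, region: RegionMixture, mut: Mutation) -> tuple[int, int]:
    """Local (CN, CNt) for a mutation in a region, from the dominant clone.

    A mutation sits on 2 copies when the dominant clone's lineage doubled at
    or below the mutation's origin (the event duplicated the mutant allele),
    capped by the segment's major CN; otherwise on 1 copy.
    """
    dom = region.dominant_clone
    seg = tree.segment_at(dom, mut.chrom, mut.pos)
    cnt = 1
    if tree.doubled_clone is not None and tree.is_doubled(dom):
        if mut.clone in tree.ancestors_or_self(tree.doubled_clone):
            cnt = min(2, max(seg.major, 1))
    cn = max(seg.total, 1)
    return cn, min(cnt, cn)


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

def simulate_reads(
    tree: CloneTree,
    regions: list[RegionMixture],
    mean_depth: int = 80,
    wgs_depth: float = 1.0,
    seed: int = 0,
    window_kb: float = 500.0,
    baf_snps_per_segment: int = 20,
    noise_rate: float = 0.0,
    noise_vaf: float = 0.01,
    patient: str = "P1",
) -> SyntheticReadSet:
    """Draw read counts, low-depth coverage windows and SNP BAFs.

    Per mutation and region: N ~ Poisson(mean_depth) and
    A ~ Binomial(N, VAFe(true CCF, purity, CN, CNt)), with VAFe the same
    expected-VAF model the clonality module inverts.  Window coverage has
    expectation (effective CN / 2) x depth x window width, so the window-CN
    formula recovers the mixture copy number.  BAF draws come from the
    allele-specific CN of the dominant clone with purity dilution.  An
    optional ``noise_rate`` plants low-VAF (default 0.01) noise at absent
    sites, emulating residual FFPE-type artifacts.
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    ss = np.random.SeedSequence(seed).spawn(3)
    rng_v = np.random.default_rng(ss[0])
    rng_c = np.random.default_rng(ss[1])
    rng_b = np.random.default_rng(ss[2])

    muts = tree.all_mutations()
    genome_gb = sum(ln for _, ln in tree.chromosomes) / 1e9

    var_rows, truth_rows = [], []
    for region in regions:
        p = region.purity
        for mut in muts:
            ccf = true_ccf(tree, region, mut)
            cn, cnt = _site_cn(tree, region, mut)
            if ccf > 0 and p > 0:
                vafe = float(np.clip(expected_vaf(p, cn, cnt, ccf), 0.0, 1.0))
            else:
                vafe = 0.0
            vaf = vafe
            if vaf == 0.0 and noise_rate > 0 and rng_v.random() < noise_rate:
                vaf = noise_vaf
            n = int(rng_v.poisson(mean_depth))
            a = int(rng_v.binomial(n, vaf)) if n > 0 else 0
            var_rows.append(
                (mut.id, region.sample_id, mut.chrom, mut.pos, mut.ref, mut.alt,
                 mut.gene, mut.effect, mut.context, mut.protein_change, a, n)
            )
            truth_rows.append((mut.id, region.sample_id, ccf, cn, cnt, vafe))

    variants = pd.DataFrame(
        var_rows,
        columns=["mutation_id", "sample", "chrom", "pos", "ref", "alt",
                 "gene", "effect", "context", "protein_change", "a", "n"],
    )
    truth = pd.DataFrame(
        truth_rows, columns=["mutation_id", "sample", "true_ccf", "cn", "cnt", "vafe"]
    )
    # germline control: no variant reads at somatic sites
    controls = pd.DataFrame(
        {
            "mutation_id": [m.id for m in muts],
            "a": 0,
            "n": rng_v.poisson(mean_depth, size=len(muts)).astype(int),
        }
    )

    # low-depth WGS coverage windows (0-based half-open), expectation follows
    # Cov_kb = (CN_eff / 2) * depth * window_kb
    window_bp = int(window_kb * 1000)
    cov_rows, segt_rows, sheet_rows, baf_rows = [], [], [], []
    for region in regions:
        p = region.purity
        dom = region.dominant_clone
        for chrom, ln in tree.chromosomes:
            for start in range(0, ln, window_bp):
                end = min(start + window_bp, ln)
                mid = (start + end) // 2
                cn_mix = sum(
                    f * tree.segment_at(c, chrom, max(mid, 1)).total
                    for c, f in region.fractions.items()
                )
                cn_eff = p * cn_mix + (1 - p) * 2.0
                width_kb = (end - start) / 1000.0
                exp_cov_kb = (cn_eff / 2.0) * wgs_depth * width_kb
                reads = rng_c.poisson(exp_cov_kb * 10.0)  # 100-bp read granularity
                gc = 0.38 + 0.1 * ((hash(chrom) % 7) / 7.0) + 0.02 * rng_c.random()
                cov_rows.append((region.sample_id, chrom, start, end, reads / 10.0, round(gc, 4)))
        # BAF of germline heterozygous SNPs over the dominant clone's segments
        for seg in tree.segments[dom]:
            denom = p * seg.total + 2.0 * (1 - p)
            n_snps = max(1, int(round(baf_snps_per_segment * (seg.end - seg.start)
                                      / max(window_bp, 1) / 4)))
            positions = rng_b.integers(seg.start + 1, seg.end + 1, size=n_snps)
            for pos in positions:
                allele = seg.minor if rng_b.random() < 0.5 else seg.major
                f_b = (p * allele + (1 - p) * 1.0) / denom
                d = max(1, int(rng_b.poisson(mean_depth)))
                b = int(rng_b.binomial(d, min(max(f_b, 0.0), 1.0)))
                baf_rows.append((region.sample_id, seg.chrom, int(pos), d, b / d))
            segt_rows.append(
                (region.sample_id, seg.chrom, seg.start, seg.end,
                 seg.total, seg.major, seg.minor, tree.is_doubled(dom))
            )
        glen = sum(ln for _, ln in tree.chromosomes)
        ploidy = sum((s.end - s.start) * s.total for s in tree.segments[dom]) / glen
        sheet_rows.append(
            (patient, region.sample_id, region.histology, region.cohort,
             True, round(p, 4), round(ploidy, 3), 30.0, round(wgs_depth * genome_gb, 6))
        )

    coverage = pd.DataFrame(
        cov_rows, columns=["sample", "chrom", "start", "end", "cov_kb", "gc"]
    )
    baf = pd.DataFrame(baf_rows, columns=["sample", "chrom", "pos", "depth", "baf"])
    sample_sheet = pd.DataFrame(
        sheet_rows,
        columns=["patient", "sample", "grade", "cohort", "adjacent",
                 "purity", "ploidy", "callable_mb", "dat_gb"],
    )
    segment_truth = pd.DataFrame(
        segt_rows,
        columns=["sample", "chrom", "start", "end", "total", "major", "minor", "doubled"],
    )
    return SyntheticReadSet(
        variants=variants, controls=controls, truth=truth, coverage=coverage,
        baf=baf, sample_sheet=sample_sheet, segment_truth=segment_truth, seed=seed,
    )


# ---------------------------------------------------------------------------
# cohort presets
# ---------------------------------------------------------------------------

@dataclass
class Patient:
    patient_id: str
    tree: CloneTree
    regions: list[RegionMixture]
    reads: SyntheticReadSet


@dataclass
class Cohort:
    patients: list[Patient]
    seed: int

    @property
    def sample_sheet(self) -> pd.DataFrame:
        return pd.concat([p.reads.sample_sheet for p in self.patients], ignore_index=True)


#: fixed preset topology for multi-region patients: two divergent dysplasia
#: branches (clones 1, 2) and a deeper carcinoma lineage (3 -> 4)
_TD_TOPOLOGY = {1: 0, 2: 0, 3: 0, 4: 3}


def simulate_patient(
    patient_id: str,
    preset: str,
    seed: int,
    n_regions: int | None = None,
    mean_depth: int = 80,
    mixing: float = 0.0,
) -> Patient:
    """One synthetic patient under the TD (tumor-bearing) or NTD preset.

    TD: a 5-clone tree (trunk 25 + 25 per branch, burden per sample 50-100),
    TP53 two-hit configuration on the trunk (missense + 17p monoallelic
    loss), trunk chr3 gain, genome doubling with a co-occurring CCND1-like
    focal amplification in 70% of patients on the carcinoma lineage, 3-6
    regions spanning LD/HD/ESCC with purities 0.3-0.9.  NTD: a single
    low-burden clone (34 mutations), diploid genome, no two-hit (TP53
    mutated without LOH in ~30% of patients).
    """
    ss = np.random.SeedSequence(seed).spawn(4)
    rng = np.random.default_rng(ss[0])
    tree_seed = int(ss[1].generate_state(1)[0] % (2**31))
    region_seed = int(ss[2].generate_state(1)[0] % (2**31))
    read_seed = int(ss[3].generate_state(1)[0] % (2**31))
    if preset == "TD":
        doubled = 3 if rng.random() < 0.7 else None
        tree = simulate_clone_tree(
            n_clones=5, n_trunk=25, n_per_branch=25, seed=tree_seed,
            topology=_TD_TOPOLOGY, trunk_3q_gain=True, tp53_two_hit=True,
            doubled_clone=doubled, ccnd1_amp_clone=doubled,
        )
        if n_regions is None:
            n_regions = int(rng.integers(3, 7))
        plan = [("LD", 1), ("HD", 2), ("ESCC", 3), ("ESCC", 4), ("MET", 4), ("ESCC", 3)]
        plan = plan[:n_regions]
        regions = simulate_regions(
            tree, n_regions, purity_range=(0.3, 0.9), mixing=mixing,
            seed=region_seed, histologies=[h for h, _ in plan],
            dominant_clones=[c for _, c in plan], cohort="TD",
            sample_prefix=f"{patient_id}_",
        )
    elif preset == "NTD":
        tp53 = rng.random() < 0.3
        tree = simulate_clone_tree(
            n_clones=1, n_trunk=34, n_per_branch=0, seed=tree_seed,
            tp53_two_hit=False,
        )
        if tp53:
            old = tree.mutations[0][0]
            chrom, pos = GENE_LOCI["TP53"]
            tree.mutations[0][0] = Mutation(
                id=old.id, chrom=chrom, pos=pos, ref="C", alt="T", context="ACG",
                gene="TP53", effect="non-silent", protein_change="p.R248Q", clone=0,
            )
        regions = simulate_regions(
            tree, 1, purity_range=(0.3, 0.9), mixing=0.0, seed=region_seed,
            histologies=["NTD"], dominant_clones=[0], cohort="NTD",
            sample_prefix=f"{patient_id}_",
        )
    else:
        raise ValueError(f"unknown preset {preset!r} (expected 'TD' or 'NTD')")
    reads = simulate_reads(tree, regions, mean_depth=mean_depth, seed=read_seed,
                           patient=patient_id)
    return Patient(patient_id=patient_id, tree=tree, regions=regions, reads=reads)


def simulate_cohort(
    n_patients: int,
    preset: str = "TD",
    seed: int = 0,
    n_regions: int | None = None,
    mean_depth: int = 80,
) -> Cohort:
    """A cohort of independent synthetic patients under one preset."""
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    children = np.random.SeedSequence(seed).spawn(n_patients)
    patients = []
    for i, child in enumerate(children):
        pid = f"{preset}{i + 1:02d}"
        patients.append(
            simulate_patient(
                pid, preset, seed=int(child.generate_state(1)[0] % (2**31)),
                n_regions=n_regions, mean_depth=mean_depth,
            )
        )
    return Cohort(patients=patients, seed=seed)
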