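# Methods

This note documents the models implemented in `preclone`, the assumptions
behind them, the defaults of every tunable that matters, and what the
synthetic data generator does and does not emulate.

## Variant filtering and force-calling

The pipeline starts at candidate somatic sites with per-sample read counts;
alignment and primary calling are upstream and out of scope. A site is
retained when (1) some tumor sample has strictly more than 10 reads of
coverage (interpreted as ≥ 11) with at least 3 variant reads, (2) the
matched control has strictly more than 10 reads with at most 1 variant
read, (3) the site is not a known population variant (dbSNP) unless
documented as somatic in COSMIC, and (4) it is absent from the ESP exome
database. Rejections are logged per criterion. Force-calling then revisits
every retained site in all regions of the patient: presence is VAF ≥ 0.02,
absence strictly below, and a control VAF strictly above 0.02 voids the
site patient-wide as germline. The boundary conventions (inclusive 3 and 1;
present at exactly 0.02; germline only above 0.02) are pinned by tests.
INDELs are flagged `needs_review` rather than auto-filtered, standing in
for a manual-inspection step. Driver status of a non-synonymous mutation is
membership in any of three configurable gene sets: an ESCC
significantly-mutated-gene list, a COSMIC-documented set, and a
pathways-in-cancer set; the matched criterion is returned.

## Cancer cell fraction

The expected VAF of a mutation carried by a fraction CCF of cancer cells is
`p·CNt·CCF / (CN·p + 2(1−p))`, with the matched normal fixed at 2 copies
(sex chromosomes excluded upstream). The likelihood of the observed counts
is binomial at that rate, evaluated on a fixed grid of 100 CCF values
0.01…1.00 and normalized under a flat prior; computation runs in log space
so depths of 10⁶ are exact. Ties at the maximum resolve to the larger CCF
(favoring the clonal call); CCF ≥ 0.8 is clonal, below is subclonal. The
mutant-allele copy number is chosen between the major and minor CN by
maximized grid likelihood, preferring the major allele on ties. Pairwise
CCF comparison places shared mutations on the (CCF_x, CCF_y) plane and
clusters occupied cells of a 0.05-resolution 2-D histogram into connected
components; the clonal/subclonal quadrant labels are what identifies
ancestor–descendant relationships between regions.

## Copy number, LOH, doubling

Window copy number follows the sequencing arithmetic of a diploid genome:
`CN = 2·(Cov/Dat)/(w/G)` with window width w = 500 Kb and genome size
G = 3 Gb by default (both configurable; the synthetic genome passes its own
G). GC correction bins windows into GC deciles, divides by the bin median
and rescales to the genome median — this flattens GC trends but anchors the
scale to the genome median, which is the intended behavior for a
mostly-diploid genome. Segmentation is recursive changepoint search in the
circular-binary-segmentation style: the maximal between-segment t-statistic
split is accepted when its within-segment permutation p-value is below
α = 0.01 (1000 seeded permutations; an infinite statistic, i.e. two exactly
constant halves, is accepted outright). The minimum split width defaults to
one window so that desk-scale focal events (a single amplified window)
remain visible. Gain and loss are called on the ploidy-scaled log₂ ratio at
the inclusive cutoffs log₂(2.5/2) and log₂(1.5/2); a sweep test pins the
first gained copy number at exactly 2.5. Fraction of genome altered is the
non-neutral length over total segment length, invariant under segment
subdivision.

LOH is a mean |BAF − 0.5| above threshold with at least 5 supporting SNPs
(below that: indeterminate, not an error). The fixed default threshold is
0.15; when purity and local CN are known, a purity-aware threshold of half
the expected full-LOH deviation, `0.5·(0.5 − (1−p)/(CN·p + 2(1−p)))`, is
used instead — at purity 0.3 a monoallelic deletion deviates by only ~0.09,
invisible to the fixed default. The pipeline uses the purity-aware form
with the segment's estimated integer CN. Genome doubling is called when the
major allele has CN ≥ 2 over more than 50% of the length with
allele-specific information (requiring such information on at least half
the genome), the convention of allele-specific callers; no printed
criterion exists, so this is an explicit package decision. The grid
purity/ploidy fit (p ∈ [0.1, 1] × ploidy ∈ [1.5, 5], steps 0.05/0.1)
assigns each segment its best integer (CN, minor) state against
sample-mean-normalized depth ratios and BAFs and minimizes length-weighted
squared error; ties break toward lower ploidy, and a flat balanced profile
returns (1, 2) with a warning flag. Because relative depth ratios admit the
classic genome-halving ambiguity, the pipeline takes purity and ploidy from
the sample sheet (upstream allele-specific fitting) and uses the fit only
as standalone plumbing.

## Phylogeny

Mutations present in all of a patient's samples are trunk, in exactly one
private, otherwise shared; the categories partition the mutation set and
are undefined for single-sample patients. Trees are built over samples from
the binary presence/absence matrix by maximum parsimony with the germline
(all-zero) state as the root: Fitch small parsimony scores each topology
(one extra change when the root set excludes the germline state), with
exhaustive enumeration of rooted topologies up to 8 leaves and, beyond
that, nearest-neighbor-interchange hill climbing from a neighbor-joining
start plus 10 seeded random restarts. Equally parsimonious topologies
resolve to the lexicographically smallest canonical encoding, making
results deterministic. Mutations are assigned to edges by Fitch
backtracking (parent state kept when admissible); branch length is the
number of assigned events and characters requiring more than one change are
reported as homoplasy — the mutations that "do not fit" the tree, e.g.
through copy-number loss or clone intermixing. Characters are binary
presence/absence rather than concatenated flanking sequences: for variants
embedded in otherwise-identical flanks both encodings induce the same
parsimony ranking, and the binary matrix keeps the characters explicit.
Normal-tissue samples are excluded from the leaves and enter only as the
root state.

## Heterogeneity and cohort statistics

The heterogeneity index is the Jaccard distance between two regions'
mutation sets; Euclidean distance runs on binary presence vectors over the
union (a VAF-vector option exists behind a flag) and intersection density
is shared mutations per callable Mb (default 30 Mb — the upstream callable
territory is never stated, so this is configuration; it is negated only for
display ordering). Pairs group as C-C, C-D, D-D with low- and high-grade
dysplasia both counting as D and normals excluded; groups are compared by
tie-corrected Kruskal–Wallis. The trunk-bias test is Fisher's exact test of
one gene's trunk/branch counts against all other mutations pooled across
patients (the exact 2×2 construction upstream is unstated; this pooled
background is the package's documented choice, validated against a
hypergeometric oracle). The doubling × amplification test permutes the
amplification labels across samples (patient-block shuffling available,
since sample exchangeability is an assumption) with the add-one empirical
p-value, whose floor is 1/(n_perm+1); calibration under the null is checked
to be super-uniform. Two-hit analysis counts mutation-AND-LOH samples per
group after excluding samples with more than one mutation but no LOH
(their second mutation may itself be the second hit), Fisher-testing the
2×2. Copy-number concordance splits both profiles at the union of their
breakpoints and correlates per-piece depth ratios without length weighting;
a flat profile yields NaN with a warning rather than a value.

## Signatures

Spectra use the canonical 96 channels (6 pyrimidine-centric substitution
classes × 16 flanking contexts); purine-strand records are
reverse-complemented, making the spectrum strand-invariant. Decomposition
is forward-selection NNLS against a fixed reference set: add the signature
whose inclusion most reduces squared reconstruction error, stop when the
improvement is below 1e-6, drop final weights below 0.06, refit and
renormalize to sum 1. Samples with fewer than 50 SNVs are excluded. The
packaged reference set is a deterministic synthetic stand-in for a 30-entry
catalog — profile 1 models spontaneous CpG deamination (75% of mass on the
four N[C>T]G channels) and the remainder are sparse random spectra —
because the catalog itself is not redistributable here; all refitting
semantics are unchanged and mixture recovery is exact to ±0.05 on 10⁴-SNV
spectra. Trinucleotide-frequency renormalization (exome vs genome) is off
by default.

## Synthetic data generator

The generator is the package's study-condition stand-in for multi-region
sequencing of dysplasia and carcinoma. A patient is a rooted clone tree
(root = founding clone; mutations inherit down the tree, so the root set is
the trunk) over a configurable genome — by default the 22 autosomes at
hg19 lengths scaled by 1/100, keeping ~60 windows while preserving
chromosome structure. Regions are purity-diluted clone mixtures: each
region is dominated by one clone with a `mixing` fraction given to its
parent (region geometry and real mixing levels are unknown, so `mixing` is
a free parameter, 0 by default); purities are uniform on 0.3–0.9, the
range expected of microdissected lesions. Read counts are
N ~ Poisson(mean depth 80, matching ~80× targeted practice) and
A ~ Binomial(N, VAFe) with VAFe computed by the same model the CCF module
inverts — so expected VAFs are correct by construction and recovery is a
genuine round trip. The coverage track scales window expectation by the
mixture copy number at 1× genome depth; BAF draws come from the dominant
clone's allele-specific CN with purity dilution at the same mean depth.

Two presets define cohort conditions. **TD** (tumor-bearing): five clones —
two divergent dysplasia branches off the trunk and a two-step carcinoma
lineage — 25 trunk + 25 per-branch mutations (per-sample burden 50–100,
trunk proportion 20%), a trunk TP53 missense plus monoallelic chr17 loss
(the two-hit configuration), a trunk chr3 gain, and in 70% of patients a
genome doubling on the carcinoma lineage with a co-occurring focal
CCND1-region amplification; 3–6 regions labeled LD/HD/ESCC/MET with
dysplasia regions drawn from the divergent branches (which is what makes
median HI(C-D) exceed HI(C-C)). **NTD** (no tumor): one clone, 34
mutations, diploid genome, no two-hit; TP53 mutated without LOH in ~30% of
patients. Contexts are drawn with weight 0.7 on the deamination-like
reference signature, so cohort spectra rank it first. All randomness flows
from one integer seed through spawned generators; identical seeds give
byte-identical output files.

Not emulated: read-level artifacts, FFPE damage beyond an optional uniform
low-VAF noise rate, spatial geometry, subclonal copy number within a
region, germline variation beyond heterozygous-SNP BAFs. Passing tests
therefore demonstrate correctness of the estimators under the stated
generative model, not robustness to alignment or fixation artifacts of
real FFPE data.

## Problem sizes and numerical choices

Tests and the acceptance checks run at desk scale by design: clone trees of
1–5 clones, 3–9 regions, depths 80–10⁶ (the infinite-depth boundary sweep
uses exact expected counts at N = 10⁶), 5,000 mutations for CCF recovery,
50 random ≤ 6-leaf matrices against the brute-force parsimony oracle, 500
replicates × 999 permutations for null calibration, and TD/NTD cohorts of
4–6 patients end to end. Posterior normalization is exact to 1e-12;
segmentation, NNI search and all permutation tests are seeded; boundary
comparisons use a 1e-12 epsilon on log-ratios so printed cutoffs are hit
exactly. Degenerate inputs have defined behavior rather than exceptions
where a value is still meaningful (indeterminate LOH/doubling, NaN
concordance on flat profiles, single-segment output for constant tracks);
true contract violations (zero depth, empty sets, unknown grades, missing
controls) raise with the offending site or sample named.

## Known limitations

Purity/ploidy estimation is a deliberately simple grid fit subject to the
genome-halving ambiguity; the pipeline therefore treats sample-sheet purity
and ploidy as inputs. The windowed CN model assumes the data volume tracks
genome-average depth, which breaks for extreme aneuploidy. The parsimony
heuristic beyond 8 leaves is a local search: optimality is guaranteed only
in the exhaustive regime (all acceptance-checked patients are within it).
The reference signature set is synthetic; weights are comparable within
this package but not against external catalogs.
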