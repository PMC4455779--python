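# Methods

## Scope and data model

`soysv` re-implements a dual-platform genic structural-variant survey as
a reusable, fully tested pipeline. The unit of analysis is the gene
model; the two measurement channels are (i) array-CGH probe log2
intensity ratios of each test genotype against a common reference
genotype and (ii) per-gene uniquely-mapped read counts from whole-genome
resequencing. Raw platform processing (array spatial correction, read
alignment, duplicate marking) is out of scope: normalized probe ratios
and gene-level counts are the interfaces. Coordinates are 0-based
half-open everywhere internally; only GFF3 output is 1-based.

## Synthetic panel

The generator emulates the survey's statistical structure at a reduced
genome size so the full pipeline runs in seconds:

| parameter | default | rationale |
|---|---|---|
| chromosomes × length | 2 × 1.5 Mb | scaled-down genome; enough probes (~6k) for stable per-genotype threshold estimation |
| genes | 240 | ~1.6 kb median lognormal lengths, non-overlapping |
| probe spacing | 500 bp median, 50–70 bp probes | the array design being emulated |
| paralog fraction | 0.60 | the surveyed genome's retained-paralog share |
| test genotypes | 41 (+ reference) | panel design: one 31× hub line, minors uniform 2–8×, reference 13× |
| CGH probe noise | Gaussian, SD 0.15 | gives the ~±0.45/±0.30 thresholds typical of such comparisons |
| read counts | Poisson, mean `depth · len/150 · copy` | shot noise of shallow resequencing |
| planted event sizes | lognormal, median 2,775 bp, mean 14,958 bp | the observed Down-segment size distribution; truncated at 30 kb for the miniature genome |

Planted events carry per-genotype integer copy states consistent with
their category (e.g. Multi-Allelic UpCNV defaults to allele groups of 3
and 10 copies, the Rhg1-like pattern); carrier counts are drawn from a
1/k neutral-like spectrum by default. The CGH channel represents the
absent state (copy 0) as a ratio floor of 1/16 (log2 = −4), standing in
for residual cross-hybridization; the floor is configurable and the
true absent-state intensity of real arrays is platform-specific.
Intra-line heterogeneity is modeled asymmetrically by sampling design:
the sequencing channel draws counts from a bulk mixture copy state
(default weight 0.5 carrier / 0.5 reference-like) while the CGH channel
sees the single sampled plant. All randomness derives from one master
seed through labelled substreams, so adding a stage never perturbs
another stage's draws.

What the generator does **not** model: probe GC/affinity bias, dye
effects, mappability variation, segmental homology between paralogs
(paralogy is a label, not a sequence property), linkage between planted
events, and partial-gene deletions (an event sets the copy state of every
overlapped gene). Passing tests therefore demonstrate the pipeline's
statistical logic, not robustness to platform artifacts.

## Calling

Normalization is per-genotype median centering — a deliberate,
documented stand-in for vendor spatial/qspline correction, which is
array-geometry-specific. Thresholds are `mean − 3·SD` / `mean + 2·SD` of
each genotype's probe ratio distribution, recomputed per comparison and
reused for gene-level scores; comparisons are strict, so values exactly
at a threshold are neutral. If a channel is exactly constant (possible
only in noise-free simulation), the library function raises; the
pipeline substitutes epsilon-width thresholds so a null panel yields
zero calls rather than an abort.

Segmentation is a stand-in for the proprietary array segmentation tool,
which fixes only four parameters (`min_diff = 0.1`, `min_len = 2`,
`acceptance = 0.99`, `n_perm = 10`). We use recursive best-window
(CBS-style) changepoint search: the statistic is
`|mean(window) − mean(complement)|` maximized over contiguous windows of
2–200 probes; a window is accepted when the statistic is ≥ `min_diff`
and at or above the `acceptance` quantile of the same statistic under
`n_perm` within-window permutations (ties accept), then recursion
continues in the three resulting pieces. A single-changepoint statistic
was rejected during design: permutations concentrate extreme probes at
window edges, so a short interior feature (e.g. a two-probe deletion,
which `min_len = 2` is explicitly meant to admit) can never beat its
permutation distribution. A final merge pass joins adjacent segments
whose means differ by less than `min_diff`, so the output satisfies the
adjacent-difference contract globally. Segment means are exactly the
means of their member probes.

Sequence calling removes genes with zero reads in every genotype, then
splits streams: zero reference reads with a test count > 1 marks a
reference-absent gene (candidate UpPAV; ratios are undefined, so copy
number comes from absolute RPKM scaled by the genotype's median
normal-stream RPKM per copy); reference reads with a zero test count
flags that cell potential-DownCNV (ratio −∞, always called Down). Genes
with a zero reference count but no test count above 1 match neither
published rule; they are retained in the flag stream and logged.
Thresholds are computed on each genotype's finite normal-stream ratios.
No pseudocounts are used anywhere.

## Cross-validation and classification

Candidates are genes inside a significant CGH segment in any genotype,
plus genes appearing on both the CGH-Probe and Sequence lists (each in
any genotype — gene-level list intersection). Copy estimates are
`max(ref_copy, floor) · 2^score` per platform. Clustering is 1-D
single-linkage per axis at half the required separation (`gap_min/2`
with `gap_min = 0.75` copies), intersected across axes; a gene
cross-validates when some pair of joint clusters separates by ≥
`gap_min` on both axes, or when all genotypes are beyond threshold on
both platforms. The half-linkage/center-separation construction was
chosen over splitting directly at `gap_min` point gaps because Poisson
depth noise at 2–8× coverage makes adjacent point clouds touch while
their centers remain ~1 copy apart; validating center separation keeps
the decision rule deterministic and auditable while matching the
"clearly split clusters" intent. A genotype beyond threshold on one
platform but within 1 SD of the mean on the other receives no integer
call and a heterogeneity flag.

Integer calls are `round_half_away(ref · 2^mean(cgh, seq))` (log-scale
averaging halves the noisier channel's influence), with copy 0 asserted
when the CGH score is below the Down threshold and the gene has zero
test reads. Classification order: reference copy (0 vs 1) → presence of
zero-copy parents → multiplicity of distinct above-one copy groups,
where groups are distinct when integer calls differ. Every
cross-validated gene receives exactly one category or an explicit
`unclassifiable`.

## Segments and spectra

Adjacency is defined in gene order: cross-validated CNV genes of the
direction's subclasses (Down: DownCNV/PAV only; Up: UpCNV and
Multi-Allelic UpCNV) merge while consecutive in the retained gene list
with no intervening non-SV gene **and** while sharing at least one
significant guide segment (running intersection of (genotype, segment)
cover sets; a run is split where the intersection empties, which also
splits runs spanning two guide segments). Base-pair distance is not
used. A genotype is a segment carrier when at least one member gene —
the same gene on both platforms — exceeds both thresholds in that
genotype; the stricter same-gene reading was chosen because it is the
natural unit of cross-validated evidence. Zero-carrier segments are
dropped with a warning rather than entering the spectrum.

## Neutral null

Loci are independent and non-overlapping, one per CGH segment (~14 kb).
The simulator is a Hudson-style coalescent: without recombination, a
level-wise Kingman tree with Poisson(θ/2 · k · t) mutations per level;
with recombination, lineages carry ancestral-material intervals with
per-interval descendant sets, recombination acts at rate ρ/2 times each
lineage's breakable span, and mutations fall on lineages at rate θ/2 per
unit ancestral material, inheriting the leaf set of the interval they
hit — equivalent to Poisson mutation on the marginal trees of the ARG,
without materializing the trees. Intervals that reach their local MRCA
are retired, so only segregating mutations are produced (infinite
sites). msprime serves as an independent cross-check in the test suite,
never as the implementation.

θ per locus uses Watterson's estimator `S / a_{n−1}`,
`a_{n−1} = Σ_{i=1}^{n−1} 1/i`, applied to the ascertainment-uncorrected
observed segment count; n = 42 chromosomes (41 inbred lines as haploids
plus the designated reference, which is row 0 of every haplotype
matrix). Reference ascertainment discards sites derived in row 0 and
counts derived alleles among the rest, thinning the θ/k spectrum by
(n−k)/n. Spectrum comparisons report per-class proportion differences,
the singleton-class excess, and a χ² distance with a Monte-Carlo p from
10,000 multinomial resamples of the simulated spectrum. Monte-Carlo
standard errors for spectrum-shape checks are cluster-robust over loci
(sites within a locus share one genealogy), not naive multinomial.

## Enrichment and paralogs

Domain enrichment is the hypergeometric upper tail P(X ≥ obs) with
expected count K·n/N (reported rounded to integer in tables).
Family-wise adjustment follows the min-p resampling scheme: the null
distribution of the minimum raw p over all domains is built from random
same-size gene lists (default 10,000), and a domain's adjusted p is the
fraction of null minima at or below its raw p — monotone in the raw p by
construction, with significance stars at adjusted P < 0.01 (\*) and
P < 0.001 (\*\*). Clan aggregation (e.g. the 11 leucine-rich-repeat
models as one clan) is an input mapping in the domain catalog. The
paralog contrast is a 2×2 (SV × retained-paralog) table with rates,
their fold ratio, and a two-sided Fisher exact p.

## Numerical and design choices

* Rounding of copy estimates: half away from zero.
* Tie-breaks at thresholds: strict inequalities, equality is neutral.
* Segmentation permutation ties accept (the observed arrangement is as
  extreme as the permuted one); the acceptance quantile over 10
  permutations at 0.99 is effectively the permutation maximum.
* Degenerate inputs: zero-SD channels raise in library code and fall
  back to epsilon thresholds in the pipeline; infeasible genome sizing
  raises before any placement; unplaceable events are skipped with a
  warning.
* Problem sizes in tests and the acceptance script (240-gene genomes,
  10⁴ coalescent loci at θ = 1, three noisy replicates) were chosen as
  the smallest panels at which the binomial/Monte-Carlo error bands of
  the checked statistics are informative; the spectrum-shape checks are
  θ-invariant, so a small θ simply controls the site count.

## Known limitations

* The six-category rules assume a haploid (inbred) copy state per line;
  heterozygous states are only represented through the heterogeneity
  mixture.
* Reference-absent (UpPAV) copy estimation by median-RPKM scaling is
  coarse below ~4× coverage; categories 2 and 3 are accordingly the
  least certain, mirroring the platform reality that the reference
  carries no probes for truly reference-absent sequence.
* The recombining coalescent is O(events²) per locus in the worst case
  and is intended for locus-scale ρ (tens), not chromosome-scale.
* Enrichment resampling assumes a fixed, fully annotated universe;
  unannotated genes count against every domain.
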