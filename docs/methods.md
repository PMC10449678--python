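# Methods

This note documents the models, the synthetic-data generator, the numeric
choices, and the places where the design was genuinely open.

## Copy-number model

Depth is averaged in 500 bp bins.  With a disomic baseline mean μ and SD σ
(estimated from a user-chosen control region; in simulations, the disomic
control chromosome), the depth interval for total copy state k is
`[μ·k/2 − 2σ, μ·k/2 + 2σ]` — every interval has width 4σ and is symmetric
about μ·k/2.  The defaults μ = 58.44, σ = 13.41 are the calibration of the
motivating case.  Note a mild inconsistency in the source material's printed
bounds (e.g. six-copy 148.49/202.13 versus the formula's 148.50/202.14, and
σ printed as both 13.41 and 13.42); the implementation applies the formula
to the stated (μ, σ) and reports values at two decimals.

Per-bin calling uses the even states (2, 4, 6), whose intervals are
disjoint at the default calibration.  An odd state cannot be called per
bin: five copies have expected depth μ·5/2 ≈ 146, which straddles the
four-copy upper and six-copy lower bounds, so five-copy bins scatter
between "4", "6" and unassigned.  Segmentation therefore works in stages:

1. run-length encoding of per-bin states;
2. absorption of short uncalled runs (≤ 2 bins) between agreeing flanks;
3. collapse of *oscillating stretches* — consecutive sub-4-bin runs
   spanning ≥ 5 bins in which a called state recurs — into one uncalled
   segment (the per-bin signature of an odd copy state);
4. absorption of single-bin called outliers between agreeing flanks;
5. mean-depth refinement of uncalled segments (nearest μ·k/2 within 2σ,
   now including k = 5: a multi-bin mean is far less noisy than one bin);
6. least-squares boundary polish: each boundary between different called
   states may slide up to 12 bins to the cut minimizing squared deviation
   from the two expected depths (the maximum-likelihood position under
   Gaussian noise), which matters for four↔five transitions whose expected
   depths differ by only ~29 reads.

A genuine short block between two *different* flanking states survives all
of this — the motivating case contains a real 2-bin (1 kb) two-copy block.

Finally, blocks are reconciled with SV junction breakpoints
(`harmonize_blocks_with_breakpoints`): junction coordinates are
base-precise while depth boundaries wander a few bins, so depth boundaries
within 6 bins of a breakpoint snap onto it; breakpoints strictly inside a
block split it (depth cannot separate genomically adjacent blocks that
share a copy state — only SV evidence can); called blocks shorter than
5 bins with no junction support at their boundaries are treated as
segmentation noise and merged into a neighbour; and states are re-assigned
per final segment from its mean depth without re-merging across
junction-supported boundaries.

## Trio phasing and BAF

Informative SNVs are child-het sites in one of three configurations:
parents homozygous for different alleles (both child alleles traceable),
father het / mother hom (only the allele absent from the mother is
paternal-unambiguous), and the mirror case.  Reads vote per covered
informative SNV; 'either' votes (the shared allele in the het-parent
configurations) abstain rather than count — counting them in either
direction would bias the classification, and the shared allele simply
carries no information.  Reads with votes for both parents are marked
conflicting and excluded downstream.

At a site with N total copies and m copies carrying the B allele, BAF
concentrates near m/N; `infer_allelic_copy` maps an observed BAF to the
nearest m (ties broken toward smaller m, a fixed deterministic rule).
Haplotype shifts along a constant-N region are detected by binary
segmentation of the per-SNV m sequence: the split minimizing the summed
squared deviation from segment means is accepted when the modal m differs
between flanks and both flanks hold ≥ 10 SNVs (min_seg), recursively.
This is a deliberately simple changepoint stand-in for what the original
analysis judged from BAF scatter by eye.

### Locating BAF peaks

`modal_baf` reports the position of the tallest BAF peak at two decimals.
The peak is seeded by a kernel density estimate (fixed 0.02–0.03
bandwidth, well below the 1/6 spacing of neighbouring peaks) and reported
as the mean of the observations in the peak's basin (between the flanking
density minima) — the peak's center of mass, which for loci at one
allelic state is an unbiased estimate of m/N.  Rounding each locus first
and taking the most frequent value is a coin flip whenever m/N sits on a
rounding-cell edge, as 1/6 = 0.1667 does between the 0.16 and 0.17 cells;
the finite-depth ratio distribution is also right-skewed, which biases a
raw histogram argmax low.

## SV filtering

A patient call is kept iff size ≥ 100 bp, support ≥ 5 reads, no parental
SV breakpoint within ±300 bp of either patient breakpoint, and both
parents' depth ≥ 10 at both patient breakpoints.  Proximity is measured
breakpoint-to-breakpoint (the comparable coordinate across SV types), and
the parental-depth rule is applied at both breakpoints of the candidate —
the conservative reading.  Each rejection records the first failing rule,
in the order above.  Note that at ~11× parental coverage the depth rule is
genuinely aggressive: Poisson-scale noise around 11 puts roughly a third
of loci below 10, so true de novo SVs can be (correctly, per the rule)
discarded; the junction-resolution stage consumes assembled consensus
sequences and is not gated on this filter.

## Junction resolution and mechanisms

The upstream reference flank is aligned semi-globally to a consensus
prefix (flank prefix skippable for free, consensus consumed from its first
base) and the downstream flank, reversed, to a consensus suffix.  Scoring
is match +1, mismatch −2, gap −3, with an acceptance threshold of 0.6 ×
the alignable flank length — assembly-polished consensus sequences are
near-exact, so permissive scoring is unnecessary.  Overlap of the two
match coordinates is microhomology; a gap is the inserted sequence; exact
abutment is blunt.  Mechanisms are assigned per *event* (a multi-junction
rearrangement counts once) in dominance order: any insertion > 10 bp →
FoSTeS/MMBIR; else any homology in 2–100 bp → alt-EJ; else homology
> 100 bp → NAHR candidate; else NHEJ.  The NAHR bound is the upper end of
the alt-EJ homology range.  Insertion origins are sought by exact 15-mer
seeds on both strands with ungapped full-window extension, reported at
≥ 90% identity over ≥ 90% of the insertion — a deliberately simple seeded
search; it suffices for near-exact templated insertions and is not a
general local aligner.

## Structure reconstruction

Blocks and junctions define a graph on oriented block ends; the derivative
is modeled as `arm + center + mirror(arm)` where the center is the unique
odd-copy block (it contributes one copy at the pivot, and the rest split
evenly between the mirrored arms) and `mirror` reverses order and flips
orientations.  Arms are depth-first walks from the centromere-proximal
anchor that consume exactly the per-arm multiplicities and end adjacent to
the center; enumeration is deterministic (reference edges before junction
edges, blocks by label) and capped at 10,000 walks with a flag.

Candidates are scored by the minimal number of events from {insert a copy
of a contiguous segment, either orientation; invert a contiguous segment}
transforming the reference block order into the candidate, by
breadth-first search bounded at depth 4 (beyond it the candidate is
reported unranked at bound+1).  Deletions are excluded: formation by
breakage-fusion-bridge cycles duplicates content.  Search states are
pruned to sequences whose length and per-block usage never exceed the
candidate's, with a 2×10⁶-node budget.

Models are ranked first by unused junction edges (each junction is
physical evidence and a complete structure should traverse all of them —
without this, tandem-vs-inverted duplication decoys that ignore one
junction can out-score the truth), then by event score, then
lexicographically.  A validator run on every output asserts multiplicity
accounting, palindromy and edge support.

Two caveats are inherent rather than implementation limits.  First, a
boundary between genomically adjacent same-copy blocks with no junction is
invisible to any method; structures are therefore compared as chains of
oriented genomic intervals after canonical merging.  Second, a palindrome
reads the same end-joints in both arm directions, so distinct structures
can share all junction evidence; parsimony then decides, and when it
cannot (ties), the tie is reported rather than resolved.  In the
motivating case this residual ambiguity was resolved by FISH, which is out
of scope here.  The event-count integers themselves depend on the
operation semantics: for the published three-pattern example our scorer
gives 2/3/2 against the informal counting of 1/3/1, but the decisive
*ranking* — the two-insertion-plus-inversion pattern strictly worse — is
reproduced and is what the tests assert.

## Allele-specific methylation and expression

Per CpG, methylated/unmethylated counts of maternal vs paternal reads form
a 2×2 table tested two-sided by Fisher's exact test at α = 0.001.  Sites
with fewer than 10 reads *in total* are excluded (the coverage sentence
names CpGs, not per-parent strata; an additional ≥ 1 read per parent is
required for the proportion to exist).  Hypermethylation direction is the
parent with the higher methylated proportion, only for significant sites.
Feature-level and per-chromosome comparisons use a 1-df chi-square
goodness of fit of (maternal, paternal) site counts against 50:50 with no
continuity correction — χ² = (n_mat − n_pat)²/(n_mat + n_pat) — which
reproduces the published enrichment values, e.g. (90, 58) → p = 0.0085
(printed 0.01).  When annotation intervals overlap, features resolve by a
fixed priority (alpha satellite > simple repeat > Alu > L1 > LTR >
promoter > gene > non-repeat intergenic; a choice, since none is given in
the source); promoters are the strand-aware 1 kb upstream of a TSS and
centromeric means within ±2 Mb of the centromere midpoint.  No
multiple-testing correction is applied anywhere: the fixed α thresholds
are the decision rule.

Allelic expression balance at an SNV with b B-reads and a A-reads uses the
same 1-df chi-square statistic (b − a)²/(b + a), no continuity correction,
minimum 10 reads.  This test was identified forensically: it reproduces
the published worked example p = 2.74×10⁻¹⁶ for (100, 13) where an exact
binomial gives ≈ 9×10⁻¹⁸.  Percentages are exact-rational, rounded
half-up to one decimal.  Copy-class expression ratios are compared by
two-sided Wilcoxon rank-sum (Mann–Whitney) tests; classes with fewer than
two genes are reported untested, and genes with zero control expression
are excluded (undefined ratio).

Power note: at α = 0.001 the Fisher test detects a 0.4 methylation-rate
shift reliably only at aneusomic coverage (≈ 117× with a 3:1 maternal
split gives > 90% power from a 0.55 baseline rate); at ~20 reads per
parent, power is below 50% by ordinary two-proportion arithmetic.  The
power regression test therefore runs at the aneusomic coverage the
generator actually produces.

## The synthetic trio generator

`simtrio` emulates, with a known ground truth: a reference laid out as
consecutive blocks on one derivative-carrying chromosome plus a disomic
control chromosome; binned depth with expectation μ·c/2 and a
gamma-Poisson (negative-binomial-like) noise model with constant SD σ
across copy states — matching the constant-width intervals of the copy
model; pure Poisson would understate real depth variance, and when the
requested variance is below the Poisson floor the model falls back to
Poisson.  Child-het SNVs arise as a Poisson process (0.8/kb, a realistic
heterozygous density) and fall into the three informative configurations
(75%) or a both-parents-het non-informative configuration; the maternal
allele is carried by the one normal maternal homolog plus every derivative
copy, so B-copy counts are c−1 or 1 at total copy c.  Reads are generated
per block at copy-proportional counts (maternal:paternal = (c−1):1), stay
within their block (so the parental mixture is well defined), and report
SNV alleles error-free plus a per-read methylation call at each covered
CpG (8/kb), with the maternal rate raised by `meth_effect` (default 0.35
above a 0.55 baseline) inside the aneusomic region only.  RNA counts per
informative SNV are binomial with success probability m/N at Poisson depth
60.  Junction consensus sequences are built from the final reference with
engineered signatures: microhomology is imposed by editing the acceptor
flank's first bases, templated insertions are copied from a random
reference interval (either strand), novel insertions are random sequence.
Patient SV calls cover every junction plus four decoys that each fail
exactly one filter rule; parent call sets and depth tracks (11.2× with a
deliberate low-coverage pocket) exercise the parental rules.

All randomness flows from one `numpy` generator seeded by `SimConfig.seed`;
identical configurations produce byte-identical files (tested).

Two generator-level guarantees make recovery testing well posed.
`random_design(n_events=k)` builds the truth arm by applying k random
operations to the reference arm and re-draws until (a) the arm's minimal
event count really is k (random op sequences occasionally compose into a
shorter description), and (b) the truth is the top-ranked — or tied —
structure among all structures consistent with its own junction evidence.
Without (b) a draw can be unrecoverable *by construction* (the palindrome
ambiguity above), which would measure the generator, not the method.
`design_derivative` likewise returns the parsimony-ranked structure for
the given blocks and junctions, so a design's ground truth is the
structure its own evidence best supports.

What the generator does **not** emulate — hence what passing tests do not
show about real data: sequencing/base-calling errors and chimeric reads
(read classification is error-free, so the conflicting-read path is
exercised only by unit tests), mappability and GC artifacts, reads
spanning block boundaries, recombination-induced haplotype shifts (the
changepoint detector is tested on directly simulated m-sequences instead),
satellite/repeat structure in insertions, and real chr21 sequence content.

## Problem sizes

Defaults keep every simulation at desk scale: blocks of 8–20 kb (a ~50 kb
derivative chromosome and 30 kb control), ~2,400 reads, ~600 CpG sites,
BAF-peak simulations at 2,000–4,000 loci, null calibrations at 20,000
sites, and 20-design recovery sweeps — each chosen as the smallest size at
which the targeted statistic is stable (e.g. 3-SE calibration bands,
binomial SEs on modal BAF well inside a rounding cell).

## Known limitations

- Segmentation is thresholding plus local refinement, not an HMM/CBS; a
  copy state whose expected depth falls exactly on an interval boundary at
  low bin counts can still fragment.
- The parsimony scorer is exact only within its depth bound (4) and
  operation set; biologically distinct histories with equal junction
  evidence and equal cost are reported as ties, never resolved silently.
- `find_insertion_origin` is exact-seeded and ungapped; diverged or
  rearranged insertion sources will be reported 'not found'.
- The per-chromosome methylation comparison assumes phasing quality is
  homogeneous across chromosomes; on real data, informative-SNV density
  varies and would confound a naive comparison.
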