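# Methods

## The analysis model

`rsmscope` treats an RNA affinity-purification sequencing experiment as a
signal-versus-matched-background problem. For one protein and one
biological replicate, the pulldown library and the total-RNA control are
samples from two multinomial distributions over genome positions; a bound
transcript is one whose pulldown sampling rate exceeds the rate predicted
from its control abundance after depth scaling. Everything downstream —
consensus, cut-offs, annotation, set comparison — is deterministic
arithmetic over the peak records.

### Peak calling

Tags are 5′ positions of aligned reads. Each tag is extended
`extension_length` d = 100 nt toward 3′ on its own strand (the libraries
are unstranded downstream; strand only orients the extension). The genome
is tiled into `bin_width` w = 10 nt bins, and the statistic per bin is the
number of extended fragments overlapping the bin — marginally Poisson with
an effective footprint of w + d nt. The local expectation is

λ_local = max(λ_BG, λ_d, λ_1000, λ_5000, λ_10000),

each term the control fragment-midpoint mass in a window centred on the
bin, rescaled to the w + d footprint and to the treatment depth (control
scaled linearly to treatment by total tag count). λ_BG is the genome-wide
control rate. The fragment-size window λ_d matters specifically for RNA
data: transcript-shaped control signal is concentrated, and kilobase-scale
windows average a short ncRNA's control mass over mostly empty flanks —
without λ_d every short, well-expressed RNA looks "enriched" against its
diluted background. With λ_d the background is density-matched and, in the
null, FE ≈ 1 everywhere.

Bins with `poisson_sf_score(k, λ) > −10·log₁₀(candidate_pvalue)`
(default p = 1e-5, i.e. score 50) are merged when separated by ≤ d nt,
intervals shorter than 2 w are dropped, and each peak records the summit
(leftmost maximum of the treatment pileup), the tag count over the
interval, the summit-bin score (PV) and summit-bin fold enrichment
(k/λ). The Poisson tail is computed in log space
(`scipy.stats.poisson.logsf`, with a log-sum fallback deep in the tail),
accurate to scores of several thousand.

The empirical FDR of a peak with score s is
100 · #(swapped peaks ≥ s) / #(forward peaks ≥ s), where the swapped list
comes from exchanging treatment and control; a running maximum from the
top score downwards enforces that a better-scoring peak never reports a
larger FDR.

### Replicate logic and cut-offs

Only peaks reproduced in all technical replicates survive: a consensus
peak is a chain of peaks, one per replicate, all pairwise overlapping by
≥ 1 nt, matched greedily left-to-right with each peak used once; its
interval is the union and its FE/PV the arithmetic mean of the members
(configurable to median).

Cut-offs are derived from the score distributions. For each technical
replicate the lower 95% confidence limit of the FE and of the PV
distribution is computed on the *raw* peak list of that replicate — raw,
because the irreproducible single-extraction peaks are part of the
distribution being summarised, exactly as the hundreds of sub-cut-off
peaks were part of the published distributions — and the per-biological-
replicate limit is the mean of its technical-replicate limits. Two limit
estimators are provided:

- `t_mean` — the textbook t-based CI of the mean,
  mean − t₀.₉₇₅,ₙ₋₁·s/√n. This is the `ci_lower_limit` default.
- `percentile` — the largest observed value not exceeding the α/2
  quantile (a conservative lower order statistic; for small n this is the
  sample minimum, for large n the empirical 2.5th percentile). This is the
  *pipeline* default: a mean-level cut-off is meaningful when the
  distribution is dominated by sub-threshold background (as in the
  original data, where it discarded ~60% of peaks), but on distributions
  where most peaks are genuine it would discard half of the real regulon
  by construction.

The cut-off rule itself is fixed: FE cut-off = minimum across biological-
replicate limits rounded down to the nearest 0.05; PV cut-off = arithmetic
mean across biological-replicate limits rounded down to the nearest 5.
This pair of rules reproduces all six published cut-offs (FE 2.15/4/2.5,
PV 130/170/145) from the published per-replicate limits; the mapping is
not uniquely determined by six values, so both components are explicit and
configurable. A target then survives only if it is present (by interval
overlap) in **every** retained biological replicate with FE ≥ cut-off and
PV > cut-off in each.

### Annotation and comparison

Because libraries are unstranded, an enriched region is compared with
features on both strands. The feature containing the summit wins;
otherwise the longest overlap wins, exact ties are flagged ambiguous with
all tied candidates kept, and regions overlapping nothing are intergenic
targets labelled by their flanking loci. Peaks landing in one identical
repeat copy report the sibling copies as shared placements. Multiple
regions in one RNA collapse to a single unique target (highest PV kept);
regulon comparison operates on these unique-locus sets with exact
inclusion–exclusion. Recovery against a planted truth counts an ambiguous
assignment as a true positive if any tied candidate is planted
(strict mode disables this). The competitive colonization fitness index is
(wt/mut in the inoculum)/(wt/mut recovered), 1 meaning equal fitness; it
is scale-invariant in each percentage pair and undefined when a strain is
not recovered.

## The synthetic benchmark

`synthio` emulates the structure — not the sequence content — of the
experiment: one replicon (default 500 kb) carrying 240 non-overlapping
features (genes 300–800 nt, ~8% ncRNAs of 80–300 nt, 15 divergent
head-to-head gene pairs sharing an 80–150 nt upstream gap, 3 groups of 3
position-identical IS-like repeat copies), spread over the whole replicon
with ≥ 300 nt inter-unit gaps. Transcript abundances are log-normal
(σ = 1.0, median 1); repeat copies share one draw split uniformly.
Controls draw tags multinomially from abundance-proportional weights with
a 5% uniform background floor; pulldowns multiply each planted target's
abundance by its enrichment factor (log-uniform on [4, 16]) *before*
renormalisation, so the effective observed enrichment is f/Z with Z the
normalisation constant (~1.7–2.2 at the default design) — as in a real
pulldown, where enrichment is relative to the sampled pool. Per protein
and biological replicate there are one control (400k tags) and three
technical-replicate pulldowns (200k tags each, roughly one fifth of the
published per-sample tag counts); biological replicates default to 2/3/2
for RsmA/RsmE/RsmI, mirroring the study's retained cultures. Biological
replicates share base abundances with a σ = 0.1 log-normal jitter;
technical replicates are independent draws from the bio-replicate
expectation (a `resample_fraction` < 1 instead copies part of a shared
master draw). Each technical replicate additionally gives 8 random loci a
mild nonspecific "carryover" boost (log-uniform 1.5–3.5×): single-
extraction affinity artifacts. They are the reason the three-technical-
replicate consensus rule exists, and they populate the sub-cut-off tail of
the score distributions that the adaptive cut-offs then remove.

The planted regulons realise a designed seven-class Venn partition
exactly. The default desk-scale design (sizes 17/18/14, union 30, triple
class 5) preserves the shape of the published regulons (241/261/206,
union 437, triple 75 — available as `FULL_SCALE_VENN_DESIGN`, whose
pairwise classes are forced to 36/40/45 by inclusion–exclusion on the
published totals). Two benchmark-design constraints keep every planted
target *identifiable*:

- planted loci are floored at 0.9× the median abundance ("targets are
  expressed transcripts"): under the genome-wide background rate λ_BG at
  the default depths, a weakly expressed transcript with enrichment 4 is
  statistically undetectable, so planting it would measure the depth
  budget, not the method;
- no two targets of the same protein sit on adjacent features (their
  enriched regions would merge into one peak and could only be counted as
  one target). Both constraints are configurable off.

### What the generator does not emulate

No sequence content (no FASTA/FASTQ, no mappability or GC structure), no
rRNA-depletion artifacts, no strand-specific effects, no operon-level
covariance of abundances, no quality-failure mode for biological
replicates, and no weakly-expressed true targets (see the expression
floor above). Passing the recovery benchmark therefore shows that the
cascade correctly identifies *detectable* planted enrichment under
realistic replicate noise and nonspecific carryover; it does not show that
targets near or below the expression detection limit of a real experiment
would be recovered — the original study accepted the same limitation by
choosing deliberately strict cut-offs.

## Numerical and procedural choices

- Internal coordinates are 0-based half-open everywhere; GFF3 converts at
  the boundary (1-based closed). TSV numeric fields serialise at 4
  decimals for diff-stable outputs.
- Summit ties break leftmost; greedy consensus matching is
  left-to-right; histogram bins are upper-limit inclusive.
- Floor-to-step rounding uses `floor(round(x/step, 9))·step` so values
  sitting exactly on a step (2.15, 145) are not pushed down by binary
  representation error.
- One master seed; every library's substream derives from
  `SeedSequence((seed, stage, protein, bio, tech, role))`, so adding a
  library never perturbs another, and identical configuration + seed
  reproduce byte-identical artifacts (verified via SHA-256 manifests).
- Degenerate inputs: empty treatment regions yield empty peak lists (not
  errors); a replicate with fewer than two raw peaks makes cut-offs
  underivable and the pipeline reports zero targets for that protein
  rather than guessing; zero-variance CI input returns the common value.
- Benchmark scale: the recovery benchmark runs the full cascade at the
  default configuration for seeds 1–5 and evaluates pooled per-protein
  precision/recall and the per-class mean of the recovered Venn counts
  across seeds; the null benchmark runs 20 seeds at a reduced scale
  (100 kb, 40 features, 30k/60k tags) with no planted enrichment and no
  carryover. These sizes were chosen to keep the whole suite at desk
  scale while leaving the per-target detection margin large (weakest
  planted target ≈ 2× the candidate threshold in expectation).

## Known limitations

- The cut-off reconstruction (min/floor-0.05, mean/floor-5) is one of
  several rules consistent with the six published values; treat it as a
  faithful reconstruction, not the authors' code.
- The greedy consensus matcher is order-dependent by design (documented,
  deterministic); a maximum-matching variant would differ on pathological
  overlap chains.
- Interval-overlap matching across biological replicates can, in
  principle, chain two distinct but overlapping targets; with the default
  spacing this does not occur in the benchmark.
- `empirical_fdr` is exposed but not part of the default cascade (the
  filtering criteria are FE/PV cut-offs, as in the study).
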