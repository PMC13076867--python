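# Methods

## Coordinate and signal conventions

All intervals are 0-based, half-open. Gene models store genomic
`start < end`; the biological 5′/3′ ends (TSS/TES) are strand-aware
properties, so on the minus strand the TSS is the genomic end and every
downstream window extends genomically leftward. Coverage is held as
per-(chromosome, strand) arrays of per-base-pair signal on a fixed bin grid;
bedGraph is the canonical on-disk format and intervals spanning partial bins
are rasterized with length-weighted means so total signal mass is conserved.
Antisense signal is never mixed into sense-strand metrics: readthrough,
pausing and elongation are sense-strand phenomena, and only the strandless
replication-initiation-zone quantification sums both strands.

A track's normalization state (`raw`, `per-100M`, `spike-scaled`) is carried
with it and every applied factor is recorded once. Region quantification
multiplies raw tracks by `per/library_total` and passes pre-scaled tracks
through unchanged, so the termination index is invariant under any global
rescaling (the factor cancels in the ratio) — asserted as a property test.

## Per-gene metrics

**Termination index.** `TI = log2(dog_density / body_density)` with the DoG
window `[TES, TES + 2500)` in transcription direction and the body
`[TSS, TES)`, both length-normalized. No pseudocounts are used: a zero body
density makes the call unclassifiable (NaN) and a zero DoG density yields a
−∞ sentinel; both are flagged and excluded from summaries, on the view that
the analysis universe is restricted to well-covered genes (mean density
> 50 in both conditions) where zeros indicate out-of-universe genes rather
than data. NDT/NIT classification uses strict `ΔTI > threshold`; the
threshold has no privileged value and defaults to 0.5, roughly half the
planted effect size of the default scenario, and is recorded in the run
manifest so results are auditable.

**Pausing index** divides the `[TSS, TSS+w)` density by the
`[TSS+w, TES)` density with `w = 300` bp by default — a conventional margin
around the 20–60-bp pause site; the window is configurable and recorded.
Note that when the analysis window is wider than the true pause peak the
index is diluted toward 1 (visible in the worked example: 6.8 recovered for
a planted 8-fold, 250-bp peak measured with a 300-bp window).

**Elongation index.** Each gene body is linearly rescaled to 40 bins
(10-bp source resolution over a 400-bin deepTools-style geometry collapses
to the same shape); per bin, EI = mean(labeling track) / mean(occupancy
track), with zero-occupancy bins masked rather than imputed, and the
aggregate profile is the unweighted mean over genes ignoring masks.
Metagene matrices use the same scaled-body geometry with fixed-width flank
bins; minus-strand rows are reversed so column 0 is always biological 5′.

**Splicing efficiency** counts a read as spliced when its alignment carries
a gap (≥ 2 blocks) and divides by all strand-matched reads overlapping the
unit. Units may be genes, exons or junction windows; the pipeline uses
genes.

## Gene universes

The analysis universe filters are conjunctive and order-independent:
expression above threshold; no other gene (either strand) within 2.5 kb of
the TSS or TES — the both-strand interpretation is deliberately
conservative, since the filter exists to keep neighboring-gene signal out of
the TI windows, and is configurable; length > 2 kb; and mean normalized
density strictly > 50 over both the body and the termination region in both
conditions. Last exons are the strand-aware final exon of multi-exon genes
longer than 2 kb; single-exon genes are filtered silently.

## Replication-initiation zones

Zones are scored BED intervals, treated strandless (replication initiation
has no strand) with both-strand mean signal per bp. Classification uses the
strict ratio rule `log2(perturbed/control) > log2(1.25)` → P-A; zones with
zero control signal are left unscored so P-A ∪ P-NA ∪ unscored partitions
the set. Mean-per-bp rather than total signal is used in the ratio — the
choice is size-invariant and the classification is identical because the
length cancels. Distance to the closest gene is the edge-to-edge gap on
either strand, 0 for overlap.

## Elongation-rate estimation

Treated/untreated coverage is compared per gene: candidates must be longer
than 60 kb (so a ~2 kb/min × 30 min ≈ 60 kb front lies inside the gene) and
show > 70% density reduction over `[TSS+1 kb, TSS+20 kb)`, eliminating
high-background genes. The transition point is the breakpoint of a
two-segment piecewise-constant least-squares fit over 1-kb bins of the
treated track, found by an exhaustive candidate scan implemented with
cumulative sums (O(n)); values are mean-centered first so the sum-of-squares
identity does not suffer catastrophic cancellation and a constant track
yields an exact all-way tie. Ties break toward the smallest position, and a
best fit at either extreme boundary is flagged uncalled (this is how flat
tracks exit). The caller is verified bin-for-bin against a direct O(n²)
residual-sum search. The fit is on raw binned coverage, not log-transformed,
because the cleared wavefront is a step in the mean. Rate = front / time;
replicate consistency keeps genes whose two fronts agree within 2 kb
(two bins) by default — the tolerance is not canonical and is exposed.

## BrdU-IP replication pipeline

Read centers (`floor((start+end)/2)`, half-open grid) are counted into 1-kb
bins. Bins with input `CI < 5` are masked for enrichment, but the
normalizations `NB = CB/ΣCB` and `NI = CI/ΣCI` use grand totals over all
bins — the formulas normalize before masking, and masking applies only to
`EB = NB/NI`. Smoothing is a centered moving average over `2m+1 = 21` bins
that shrinks to the available valid bins at edges and across masked bins (no
padding, so no signal is fabricated at chromosome ends). For condition
subtraction the smoothed enrichment is expressed on a percent scale
(100 × EB) so the ±10 background band operates on values of order 100; the
band and the scale are configurable since the subtraction units are a free
choice. Plus/minus zones are maximal runs strictly outside the band, and
swapping the condition order swaps the zone sets exactly, so either
subtraction orientation is a label swap.

Per-gene readthrough deltas are the mean perturbed-minus-control nascent
signal over `[TES+2.5 kb, TES+5 kb)`; windows overlapping exactly one zone
sign join that group. The group comparison log10-transforms the deltas,
excluding non-positive values with the excluded count reported — an offset
transform is the configurable alternative. The Brunner–Munzel test
estimates p̂ = P(X<Y) + ½P(X=Y) from midranks, studentizes with Welch-type
degrees of freedom and takes two-sided p-values from the t distribution; it
is cross-checked in the tests against both an exhaustive pairwise-count
oracle and an independent library implementation. When every pairwise
comparison agrees (complete separation) the rank variance is zero and the
studentized statistic is undefined; the pipeline then falls back to a
seeded permutation test on p̂ and flags the fallback in its output.

## Synthetic-data generator

The generator is a pure function of (scenario, condition); a scenario seed
fixes every stream (genome, coverage, time course, reads, replication
counts) independently. It emulates, on one synthetic chromosome:

* **Gene layout** — equal-length genes (10 kb default) alternating strands
  at 20-kb spacing, each with first/last exons for the splicing and
  last-exon analyses, and one RI zone 3 kb downstream of each TES (4 kb
  long, log-uniform scores over the observed 0.0363–265.5 range).
* **Nascent coverage** — 250-bp pause boxcar at `pause_height` (8×) the
  body density (0.5 reads/bp), uniform body, exponential post-TES decay
  (scale 500 bp), plus a small uniform background of 0.005 reads/bp on both
  strands representing pervasive intergenic transcription — chosen so that
  zone baselines are positive (a zone with literally zero baseline signal is
  unscorable by the ratio rule) while remaining two orders of magnitude
  below genic signal. Deterministic expected profiles in noise-free mode;
  Poisson counts per bin otherwise. The perturbed condition gives a planted
  half of the genes a readthrough plateau (50% of body density over 10 kb)
  before the decay.
* **Spike-ins** — tallies only (the normalization formula consumes counts;
  no metric reads spike coverage), at a 5% spike fraction.
* **CDK9-inhibition waves** — at time t, `[TSS, TSS + v·t)` is suppressed
  to 5% residual; v = 2 kb/min, t = 30 min by default; the true front
  `min(v·t, gene length)` is recorded per gene.
* **Junction reads** — reads spanning exon junctions, gapped with the
  planted probability 0.7; the enumeration mode realizes exactly
  `floor(k·f)` gapped reads among every prefix of k reads for closed-form
  tests.
* **Replication counts** — uniform input (mean 50/bin); IP counts follow
  alternating 50-kb early/late domains (3× early enrichment). The perturbed
  condition multiplies IP rates by 0.2 over each planted gene's defective
  span — the readthrough extension plus the invaded zone (~14 kb), i.e. the
  whole region the invading polymerase occupies — and boosts late domains
  1.5×, emulating redistribution of early-S synthesis. The 14-kb width
  matters: the 21-bin smoothing window would dilute a much narrower dip
  below the ±10 band.

What the generator does **not** emulate: sequence-level effects (no
FASTA/FASTQ, fragment-length or GC structure), isoform mixtures, antisense
or convergent transcription, variable gene lengths or expression-dependent
signal, replication-timing gradients beyond a two-level early/late
structure, or mappability gaps. Passing recovery tests therefore shows that
the estimators invert the generative model they assume — correct windows,
strand handling, normalization and thresholds — not that they are robust to
every artifact of real libraries.

## Problem sizes

The default scenario uses 100 genes of 10 kb on a ~3-Mb chromosome at 25-bp
coverage bins; the rate analysis uses 20 genes of 100 kb (long enough to
contain the 60-kb front); the changepoint-oracle comparison uses 1,000
random tracks of up to 200 bins; the rank-test calibration uses 2,000 null
replicates at n = 30 per group. These sizes make every recovery check exact
or tightly concentrated while keeping the full suite under a minute.

## Known limitations

* The NDT/NIT ΔTI cutoff is a free parameter; there is no canonical value.
* The elongation-rate caller assumes a single clean step per gene; genes
  with partial clearing or internal TSSs would need a multi-segment model.
* The ±10 background band for replication-delta zones is tied to the
  percent scale of the smoothed enrichment; other unit choices require
  rescaling the band.
* The Brunner–Munzel test is asymptotic; for tiny groups or complete
  separation the permutation fallback is the honest alternative and is
  applied automatically.
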