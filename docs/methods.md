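# Methods

This note records the models, parameter choices and numerical
conventions behind `dualinit`, and what the synthetic-data tests do and
do not establish about real CAGE data.

## Coordinates and formats

Everything internal is 0-based, half-open. CTSS tag tables are a BED6
dialect (`start` = the transcript's 5′ base, `end = start + 1`, score =
raw tag count); GTF is converted from 1-based closed coordinates on
read. For a CTSS at position *p*, the initiator dinucleotide in
transcript orientation is `(genome[p-1], genome[p])` on the plus strand
and the reverse complement of `(genome[p+1], genome[p])` on the minus
strand. Any classification whose decisive window touches an N (or runs
off a contig) is demoted to an explicit undetermined state
(OTHER / YC-other / not-assessed) rather than guessed. Multi-sample
tables are an outer join on (contig, position, strand) with absent
counts as zero. When a gene has several annotated transcript starts,
the 5′-most is kept; this is a convention, flagged for sensitivity
analysis, since annotation sources differ here.

## Power-law normalization

CAGE tag counts follow an approximate power law: the reverse-cumulative
count distribution (number of CTSS with count ≥ c) is close to linear
on log–log axes. Each sample is normalized by mapping its fitted law
onto a reference law with slope −α (default α = 1.05) and total tag
mass T = 10⁶, so normalized values read as tags per million:

1. fit log₁₀(rank) against log₁₀(count) by least squares over the
   unique raw count values inside `fit_range` (default [5, 1000] —
   below ~5 counts discreteness distorts the curve, above ~1000 ranks
   are too sparse), giving slope −a and rank-1 count x₀ₛ;
2. map each count c to `(c / x₀ₛ)^(a/α) · x₀ᵣ`, where x₀ᵣ is the rank-1
   count of the reference law.

x₀ᵣ is fixed by matching the reference law's total tag mass to T via
the closed form `T = α (x₀^α − x₀) / (α − 1)` (continuous integral of
count over rank), inverted numerically. An alternative convention fixes
the rank-1 count directly; the two differ by a constant factor, and
total-mass matching is used because it makes "10⁶ tags" literal. The
mapping is strictly increasing, so ranks are always preserved; a sample
already on the reference law is a fixed point; and the post-normalization
reverse-cumulative slope equals −α by construction. Samples whose fit
is degenerate (fewer than two distinct counts in range) fall back to
plain library-size scaling (`count / total × 10⁶`) with a warning.
α and the fit range are configuration, not constants: α = 1.05 and
[5, 1000] are the de-facto community defaults for CAGE libraries.

## Clustering and promoter units

CTSS supported by ≥ 0.5 TPM in at least one sample are clustered per
(contig, strand) by single linkage with a 20 bp maximum gap. Because
the data are points on a line, consecutive-gap runs equal the full
transitive closure; tests verify this against an O(n²) union-find
oracle. Clusters are trimmed to the 10th–90th expression percentiles:
the trimmed start is the 5′-most position whose left-inclusive
cumulative TPM reaches q_low·total, the trimmed end the first position
reaching q_high·total (kept inclusively). With ≥ thresholds the
retained mass is guaranteed ≥ (q_high − q_low)·total; ties resolve to
the 5′-most qualifying position. Note the rule is deliberately
asymmetric at exact boundaries: a uniform profile loses a position at
the right edge but not the left, because the first position's
cumulative mass already meets the left threshold. Clusters with trimmed
mass strictly > 5 TPM survive; the floor applies to the pooled
(across-samples) TPM by default, with per-sample filtering available,
since the upstream description ("per transcriptional cluster") does not
distinguish the two. Tag clusters within 100 bp aggregate into
consensus clusters (union envelopes, stable ids in coordinate order).
Aggregation is strand-specific: initiator classes are defined in
transcript orientation, so cross-strand merging would corrupt them.
A consensus cluster is assigned to a gene when its span overlaps
[TSS − 500, TSS + 500] on the same strand (width configurable; no
canonical value exists); among several overlapping windows the nearest
TSS wins, with exact ties going to the lexicographically smaller gene
id, logged. TPM of multiple clusters assigned to one gene is summed.

## Initiator classes

Dinucleotides {CA, CG, TA, TG} are YR, {CC, TC} are YC, everything else
OTHER. YC starts are subtyped by the pyrimidine count of the first five
transcribed bases: 5 → TOP, 4 → TOP-degenerate, ≤ 3 → YC-other. The
"4 of 5" reading (purine at any one of positions 2–5) is used for
TOP-degenerate rather than a literal ordered C-Y-Y-Y-R string. Internal
TOP is an unbroken run of five pyrimidines anywhere in the transcript's
first 50 nt; canonical 5′TOP transcripts are exempt from that scan, and
a flag optionally extends the exemption to TOP-degenerate starts.
Every CTSS is classified and class TPM summed per promoter (rather than
classifying only the dominant CTSS); OTHER is tallied separately and
excluded from YC:YR ratios.

## DIP calling and dynamics

A promoter is a DIP when both YR and YC TPM are strictly > 1 in
strictly more than half the samples; an integer minimum-sample override
exists because published analyses vary between "majority" phrasings.
YC:YR ratios use a pseudocount ε = 0.01 TPM in numerator and
denominator (zero handling is otherwise undefined); per-promoter
normalized ratios divide by the across-sample mean, making
mean(r̃) = 1 exactly. Cohort comparisons:

- **paired ratio test** — per promoter, d = mean log₂ r over condition
  samples − mean over reference samples; one-sample two-tailed t-test
  of d against 0 across promoters. Skipped below n = 3; a zero-variance
  d is reported as degenerate with p = 0.
- **class totals** — Pearson chi-squared (no continuity correction) on
  rounded YC/YR TPM totals of two groups. TPM are not counts; the
  rounding approximation is logged, and a zero cell triggers the
  Haldane 0.5 odds-ratio correction.
- **trajectories** — promoters whose cohort-mean metric is strictly
  monotone along a given cohort order. The metric is the cohort mean of
  log₂ r (the geometric mean of r), chosen for symmetry of up/down
  changes; the treatment variant orders cohorts by the mean change in
  log₂ r upon treatment. Under an exchangeable null the selected
  fraction is 1/k! for k cohorts, which the tests verify by simulation.
- ratio distributions export on fixed log₂-spaced bins (32 bins over
  ±5) for cross-run comparability; batch per-promoter testing reports
  Benjamini–Hochberg FDR alongside raw p where applicable.

The RT–qPCR utility estimates YC expression by subtraction
(yc = max(total − yr, 0)) with a tolerance flag for primer
inconsistency; doubling time is T·ln2 / ln(X/seed); relative survival
is a ratio of means with first-order error propagation.

## Motif enrichment

JASPAR count matrices become log₂-odds PWMs with
`w[b,i] = log₂((n[b,i] + 0.8·bg_b) / (colsum_i + 0.8) / bg_b)` under a
uniform background. "90 % match" is interpreted as a relative score —
(S − S_min)/(S_max − S_min) — of at least 0.9, the standard convention
behind that phrase. Windows run 150 bp upstream to 50 bp downstream of
the dominant CTSS (the highest-TPM member position; ties break 5′-most
in transcript orientation), truncated and flagged at contig edges, and
are scanned on both strands by default (single-strand scanning is a
flag; the convention upstream is unstated). Enrichment of hits in a
gene set versus all other consensus clusters uses the exact two-sided
Fisher test (two-sided by summing hypergeometric probabilities ≤ the
observed table's). N in a window scores −∞ (relative score 0); a flat
(degenerate) PWM is flagged and scores every ACGT window 1.

## Synthetic data

The generator emulates the structure the analysis assumes. Promoters
sit at fixed 400 bp spacing on random-sequence contigs; each has a
≤ 20 bp core of CTSS in 6 bp steps so that every start's −1/+4 context
block can be rewritten into the genome without overlaps, keeping the
registry and the emitted FASTA consistent by construction (tests
re-read the FASTA and re-derive every class). Half the promoters are
dual-initiation (alternating YR/YC starts), the rest YR-only — echoing
the observation that non-DIP promoters are almost exclusively YR.
Per-promoter YC fractions are Beta-distributed with cohort means
0.35 / 0.25 / 0.15 (responsive / moderate / non-responsive), spanning
the observed range of 5′-C transcript content between the most and
least radiotherapy-responsive samples; concentration 20 gives realistic
promoter-to-promoter spread. 30 % of dual promoters are "trajectory"
promoters with per-cohort fractions redrawn until strictly ordered; the
rest share one fraction across cohorts (an exchangeable null).
Irradiated samples multiply the YC fraction by a cohort treatment
effect (0.55 / 0.72 / 0.95, i.e. 45 % / 28 % / 5 % YC depletion along
the responsiveness gradient). Expression is a rank-based discrete power
law with reverse-cumulative slope −1.05 scaled to the library depth
(default 10⁶ tags), sampled per library as Poisson totals split
YC/YR binomially and spread over member CTSS with fixed geometric
weights; intergenic noise tags land uniformly at 2 per kb with whatever
contexts the random genome provides (mostly OTHER). YC 5-mers are TOP /
TOP-degenerate / YC-other at 0.3/0.3/0.4; 10 % of promoters get a
planted internal-TOP leader; a motif consensus (default `CCGGAAGT`,
ETS-like) is written 60 bp upstream of the promoter core in 30 % of
trajectory ("signature") promoters versus 10 % of the background. All
draws come from one seeded generator; identical seeds give
byte-identical files.

What passing recovery tests shows: the pipeline's stages are correct
and well-calibrated on data satisfying their assumptions (clean power
law, non-overlapping promoters, exact initiator contexts, no mapping
error). What they do not show: robustness to FFPE degradation, mappability
artefacts, overlapping or bidirectional promoters, sequencing error, or
deviations from the power law — none of which the generator models.

## Problem sizes

The standard synthetic cohort used by `scripts/acceptance.py` and the
acceptance tests is 1,000 promoters, 3 cohorts × 2 samples, 10⁶ tags
per library; under the rank-based power law the least-expressed
promoter then carries ~150 TPM, so recovery failures reflect pipeline
defects rather than threshold noise. Calibration simulations use 200
null replicates (paired test, Fisher) and 100 power replicates at the
planted-motif configuration (30 % vs 10 % hit rates, n = 150/1500).
Normalization checks build libraries that sit exactly on the reference
law from the rank side — rounding count values directly shifts the
empirical survival curve by half a step at small counts and biases the
fitted slope, which is a property of discretization, not of the
normalizer — and restrict the upper fit bound to the well-populated
regime (rank ≳ 10) for the smallest libraries.

## Known limitations

- G-correction operates on tables carrying the observed read first
  base; when starting from positional tag tables without that column
  (as the simulator emits), the stage is a no-op by design.
- The chi-squared test on TPM totals inherits the upstream
  approximation of treating normalized expression as counts.
- Promoter windows of adjacent genes can overlap; nearest-TSS
  assignment is deterministic but can mis-assign clusters of genes with
  shared promoters.
- Trajectory selection requires strict monotonicity of cohort means; it
  has no significance control of its own (the 1/k! null rate is the
  relevant baseline, and downstream tests provide inference).
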