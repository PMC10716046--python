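# dualinit

Analysis of **dual-initiation promoters** from CAGE 5′-end data.

CAGE-seq reads out the 5′ ends of capped mRNAs at single-nucleotide
resolution, so each CAGE transcription start site (CTSS) can be labelled
by its initiator dinucleotide — the genomic bases at the −1/+1 positions
in transcript orientation. Most mammalian transcription initiates from
the canonical pyrimidine/purine **YR** motif (CA, CG, TA, TG); a second,
non-canonical class initiates on a cytosine (**YC**: CC, TC) and is
tightly linked to 5′ terminal oligopyrimidine (5′TOP) transcripts, whose
translation is controlled by PI3K–Akt–mTOR signalling. Many promoters
produce *both* transcript classes, intermingled at the same promoter —
dual-initiation promoters (DIPs) — and the balance between the two
(the YC:YR ratio) shifts with tumour differentiation state,
radiosensitivity, and irradiation itself.

`dualinit` implements the full desk-side analysis:

- **I/O** — FASTA genomes, BED6-dialect CTSS tag tables (score = raw tag
  count), GTF gene models, JASPAR count matrices, sample sheets; one
  0-based half-open coordinate convention throughout.
- **CTSS pipeline** — optional removal of the untemplated 5′ G added by
  the CAGE protocol; per-sample tag normalization onto a reference power
  law (slope −1.05, 10⁶-tag library → tags per million, TPM); tag
  clustering (max 20 bp between neighbouring CTSS, supported at
  ≥ 0.5 TPM), trimming to the 10th–90th expression percentiles, a strict
  \> 5 TPM cluster floor; consensus clusters across samples (within
  100 bp) and assignment to annotated TSS windows.
- **Initiator classification** — YR / YC / OTHER per CTSS; YC subtypes
  from the transcript's first five bases (5 pyrimidines = TOP, 4/5 =
  TOP-degenerate, otherwise YC-other); internal-TOP detection (unbroken
  5-pyrimidine run within the first 50 nt).
- **DIP dynamics** — DIP calling (> 1 TPM for both classes in a majority
  of samples), YC:YR ratios with per-promoter normalization, paired
  two-tailed t-tests on log₂ ratio changes, chi-squared tests on class
  totals, strict-monotone trajectory selection along an ordered cohort
  ranking, gene-set Venn intersections, and closed-form utilities
  (RT–qPCR YC-by-subtraction, doubling time, relative survival).
- **Motif enrichment** — log₂-odds PWM scanning of promoter windows
  (−150/+50 bp around the dominant CTSS, ≥ 90 % of the PWM score range
  counts as a hit) and two-sided Fisher exact enrichment of a gene set
  versus all other promoters.
- **Synthetic data** — a generator that emits genome, annotation and
  multi-sample CTSS tables with known per-promoter YC fractions, cohort
  and irradiation effects, power-law tag counts, planted TOP contexts
  and promoter motifs, so every stage is verifiable without downloads.

## Worked example

Simulate a small cohort (three responsiveness cohorts × two samples,
200 promoters, 2 × 10⁵ tags per library) and run the pipeline:

```sh
cat > cfg.yaml <<EOF
n_promoters: 200
depth: 200000
seed: 8
EOF
dualinit simulate --config cfg.yaml --out sim
dualinit pipeline \
    --genome sim/genome.fa --annotation sim/genes.gtf \
    --samples sim/samples.tsv \
    --cohort-order responsive,moderate,non_responsive \
    --out run
```

which prints

```
88 DIPs of 582 consensus clusters -> run
```

and writes per-stage tables under `run/`. The per-sample class totals
(`run/class_totals.tsv`, TPM summed over CTSS inside consensus
clusters) show the simulated YC enrichment gradient — YC transcription
highest in the responsive cohort, lowest in the non-responsive cohort,
with YR roughly constant:

```
                        YR       YC   OTHER
moderate_1        301823.0  47115.0   855.0
moderate_2        302017.0  47054.0   936.0
non_responsive_1  302957.0  39312.0  1208.0
non_responsive_2  307398.0  39289.0  1125.0
responsive_1      303301.0  53400.0   830.0
responsive_2      306707.0  53626.0   828.0
```

`run/report.json` summarizes the cohort statistics: the paired
two-tailed t-test of per-DIP log₂ YC:YR changes between the responsive
and non-responsive cohorts gives mean log₂FC = 0.666 at p = 3.5 × 10⁻⁷
(the responsive cohort is YC-enriched), and 37 of the 88 DIPs follow a
strictly monotone YC:YR trajectory across the three cohorts
(`run/trajectory_ratio.txt`).

The same stages are available as library functions
(`dualinit.workflow.run_pipeline`) and as standalone subcommands
(`dualinit classify`, `dualinit dips`, `dualinit motifs`).

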